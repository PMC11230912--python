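"""Fluorescence-detected linear dichroism (FDLD) mapping.

A sample is excited sequentially with vertically and horizontally
polarized light; by photoselection, emitters absorb preferentially when
their transition dipole is parallel to the excitation polarization.
With thioflavin T bound to amyloid (dipole parallel to the fibril long
axis), the per-pixel contrast between the two images reports local
fibril orientation.

The primary map is the bounded dichroism d = (I_V − I_H)/(I_V + I_H)
∈ [−1, 1]: +1 vertical, −1 horizontal, 0 no preferential orientation.
The unbounded sum/difference ratio (I_V + I_H)/(I_V − I_H) is also
computed (``literal_map``) since some instruments report that form; it
is singular where I_V = I_H.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.restoration import estimate_sigma

# diverging colour anchors: horizontal → blue, none → grey, vertical → yellow
_BLUE = np.array([0.12, 0.35, 0.85])
_GREY = np.array([0.5, 0.5, 0.5])
_YELLOW = np.array([0.95, 0.85, 0.1])


@dataclass
class DichroismResult:
    """Per-pixel dichroism map with a validity mask.

    ``d_map`` is NaN outside ``valid_mask`` (total intensity below the
    floor). ``literal_map`` is NaN additionally where I_V = I_H.
    """

    d_map: np.ndarray
    valid_mask: np.ndarray
    literal_map: np.ndarray
    floor: float

    def __post_init__(self) -> None:
        valid = self.d_map[self.valid_mask]
        if valid.size and np.nanmax(np.abs(valid)) > 1 + 1e-9:
            raise ValueError("dichroism out of [-1, 1] on valid pixels")


def dichroism_map(
    i_v: np.ndarray, i_h: np.ndarray, floor: float | None = None
) -> DichroismResult:
    """Per-pixel dichroism from a co-registered polarized image pair.

    Pixels with I_V + I_H ≤ ``floor`` are masked; the default floor is
    3× the background noise sd estimated from the sum image (dichroism of
    near-dark pixels is dominated by noise).
    """
    i_v = np.asarray(i_v, dtype=float)
    i_h = np.asarray(i_h, dtype=float)
    if i_v.shape != i_h.shape:
        raise ValueError("polarized images must have the same shape")
    total = i_v + i_h
    if floor is None:
        sigma = estimate_sigma(total)
        floor = 3.0 * float(sigma) if np.isfinite(sigma) else 0.0
    valid = total > floor
    if not valid.any():
        warnings.warn("all pixels below the intensity floor", stacklevel=2)

    d = np.full(i_v.shape, np.nan)
    np.divide(i_v - i_h, total, out=d, where=valid)

    diff = i_v - i_h
    literal = np.full(i_v.shape, np.nan)
    np.divide(total, diff, out=literal, where=valid & (diff != 0))
    return DichroismResult(d, valid, literal, float(floor))


def colorize(result: DichroismResult) -> np.ndarray:
    """False-colour RGB render of a dichroism map.

    d = −1 → blue (horizontal order), 0 → grey (no preferential
    orientation), +1 → yellow (vertical order); piecewise-linear in
    between. Masked pixels are black. Returns float RGB in [0, 1].
    """
    d = np.nan_to_num(result.d_map, nan=0.0)
    rgb = np.empty(d.shape + (3,))
    neg = np.clip(-d, 0.0, 1.0)[..., None]
    pos = np.clip(d, 0.0, 1.0)[..., None]
    rgb[:] = _GREY
    rgb = _GREY * (1.0 - neg - pos) + _BLUE * neg + _YELLOW * pos
    rgb[~result.valid_mask] = 0.0
    return rgb


def interface_orientation_score(
    result: DichroismResult,
    center: tuple[float, float],
    radius_px: float,
    annulus: tuple[float, float] = (0.85, 1.05),
    min_valid_fraction: float = 0.25,
) -> float:
    """Tangential-order score of the dichroism around a droplet interface.

    Fibrils everywhere tangent to the circle produce d(φ) = cos 2φ at
    angular position φ (ThT dipole parallel to the fibril axis), fibrils
    everywhere normal produce −cos 2φ. The score projects the annulus
    dichroism onto that mode, normalized so the ideal tangential field
    scores +1, the ideal radial field −1 and random orientation ≈ 0:

        score = Σ d(φ)·cos 2φ / Σ cos² 2φ  over valid annulus pixels.

    Returns NaN when fewer than ``min_valid_fraction`` of the annulus
    pixels are valid.
    """
    lo, hi = annulus
    if not 0 < lo < hi:
        raise ValueError("annulus bounds must satisfy 0 < lo < hi")
    ny, nx = result.d_map.shape
    cx, cy = center
    yy, xx = np.mgrid[0:ny, 0:nx]
    rr = np.hypot(xx - cx, yy - cy) / radius_px
    in_annulus = (rr >= lo) & (rr <= hi)
    if not in_annulus.any():
        return float("nan")
    sel = in_annulus & result.valid_mask
    if sel.sum() < min_valid_fraction * in_annulus.sum():
        return float("nan")
    phi = np.arctan2(-(yy - cy), xx - cx)  # image y points down
    c2 = np.cos(2.0 * phi[sel])
    denom = np.sum(c2**2)
    if denom == 0:
        return float("nan")
    return float(np.sum(result.d_map[sel] * c2) / denom)
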