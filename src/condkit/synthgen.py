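"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator is a pure function of a truth object (which carries its
own seed), so every analysis stage — segmentation, dichroism mapping,
FRAP and FCS fitting, half-time extraction, regime classification — can
be tested against the parameters that produced its input, with no
external data.

Physical conventions: 0-based pixel coordinates with origin top-left;
fibril-axis angles are axes modulo π measured counterclockwise from the
horizontal image axis; the thioflavin-T transition dipole is taken
parallel to the fibril axis, so polarized excitation photoselects
fibrils by a cos² factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .imaging import ImageStack
from .kinetics import KineticTrace


# --------------------------------------------------------------------------
# truth objects
# --------------------------------------------------------------------------

@dataclass
class DropletFieldTruth:
    """Ground truth for a field of non-overlapping circular condensates."""

    centers: list[tuple[float, float]]      # (x, y) px
    radii: list[float]                      # px
    dilute_level: float
    dense_level: float
    rim_level: float | None = None          # None → no interface rim
    rim_width_frac: float = 0.15            # rim annulus width, fraction of r
    pixel_size_um: float = 0.1
    noise_sd: float = 0.0
    shape: tuple[int, int] = (256, 256)     # (ny, nx)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.centers) != len(self.radii):
            raise ValueError("centers and radii differ in length")
        if any(r <= 0 for r in self.radii):
            raise ValueError("radii must be positive")
        if not 0 <= self.dilute_level <= self.dense_level:
            raise ValueError("need dense_level ≥ dilute_level ≥ 0")
        if self.rim_level is not None and self.rim_level < self.dense_level:
            raise ValueError("rim_level must be ≥ dense_level")
        ny, nx = self.shape
        for (x, y), r in zip(self.centers, self.radii):
            if x - r < 0 or y - r < 0 or x + r > nx - 1 or y + r > ny - 1:
                raise ValueError(f"droplet at ({x}, {y}) extends outside the frame")
        for i, ((x1, y1), r1) in enumerate(zip(self.centers, self.radii)):
            for (x2, y2), r2 in list(zip(self.centers, self.radii))[i + 1 :]:
                if np.hypot(x1 - x2, y1 - y2) < r1 + r2:
                    raise ValueError("droplets overlap")


@dataclass
class OrientationField:
    """Per-pixel fibril-axis angle (mod π) and emitter density."""

    theta: np.ndarray                # radians from horizontal axis
    amplitude: np.ndarray            # emitter density ≥ 0
    isotropic_fraction: float = 0.0  # fraction of unoriented emitters

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.theta.shape != self.amplitude.shape:
            raise ValueError("theta and amplitude must have equal shape")
        if np.any(self.amplitude < 0):
            raise ValueError("amplitude must be non-negative")
        if not 0.0 <= self.isotropic_fraction <= 1.0:
            raise ValueError("isotropic_fraction must be in [0, 1]")


@dataclass
class FrapTruth:
    """Ground truth of an exponential-recovery photobleaching trace."""

    mobile_fraction: float
    recovery_time_s: float
    prebleach_level: float = 1000.0
    postbleach_level: float = 200.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mobile_fraction <= 1.0:
            raise ValueError("mobile_fraction must be in [0, 1]")
        if self.recovery_time_s <= 0:
            raise ValueError("recovery_time_s must be positive")
        if self.postbleach_level >= self.prebleach_level:
            raise ValueError("postbleach level must be below prebleach level")


@dataclass
class ThtTruth:
    """Ground truth of a ThT aggregation curve (hours)."""

    shape: str = "sigmoid"          # "sigmoid" | "biphasic"
    t_half_h: float = 20.0
    steepness_per_h: float = 0.5
    plateau: float = 100.0
    baseline: float = 5.0
    drift_slope_per_h: float = 0.0  # biphasic only: slow late rise
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in ("sigmoid", "biphasic"):
            raise ValueError("shape must be 'sigmoid' or 'biphasic'")
        if self.t_half_h <= 0:
            raise ValueError("t_half must be positive")
        if self.plateau < self.baseline:
            raise ValueError("plateau must be ≥ baseline")
        if self.drift_slope_per_h < 0:
            raise ValueError("drift_slope must be ≥ 0")


@dataclass
class FcsTruth:
    """Ground truth of a one-component 3-D diffusion autocorrelation curve."""

    n_particles: float = 5.0
    tau_d_s: float = 1e-4
    k: float = 7.0                      # axial/lateral aspect ratio
    lag_grid_s: np.ndarray = field(
        default_factory=lambda: np.geomspace(1e-6, 1.0, 120)
    )
    noise_sd: float = 0.0               # lognormal sd (multiplicative)
    seed: int = 0

    def __post_init__(self) -> None:
        self.lag_grid_s = np.asarray(self.lag_grid_s, dtype=float)
        if self.n_particles <= 0 or self.tau_d_s <= 0:
            raise ValueError("N and tau_D must be positive")
        if self.k <= 1:
            raise ValueError("structural parameter k must exceed 1")
        if np.any(self.lag_grid_s <= 0) or not np.all(np.diff(self.lag_grid_s) > 0):
            raise ValueError("lag grid must be positive and strictly increasing")


@dataclass
class DoseResponseTruth:
    """Ground truth of a re-entrant turbidity dome vs RNA concentration."""

    rna_concentrations: np.ndarray = field(
        default_factory=lambda: np.array(
            [0.0, 1.0, 2.5, 5.0, 8.0, 12.0, 18.0, 25.0, 50.0, 100.0, 250.0, 500.0]
        )
    )
    turbidity_peak_location: float = 12.0   # ng/µl
    peak_height: float = 0.5                # OD above baseline at the peak
    baseline: float = 0.02                  # OD with no dense phase
    suppression_scale: float = 40.0         # ng/µl; np.inf → no re-entrance
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.rna_concentrations = np.asarray(self.rna_concentrations, dtype=float)
        if np.any(self.rna_concentrations < 0):
            raise ValueError("RNA concentrations must be ≥ 0")
        if self.turbidity_peak_location <= 0 or self.suppression_scale <= 0:
            raise ValueError("peak location and suppression scale must be positive")
        if self.peak_height < 0:
            raise ValueError("peak_height must be ≥ 0")


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------

def gen_droplet_image(truth: DropletFieldTruth) -> ImageStack:
    """Render a single-frame image of the droplet field.

    Background pixels have mean ``dilute_level``; droplet interiors
    ``dense_level``; when ``rim_level`` is set, an annulus of width
    ``rim_width_frac``·r inside each droplet edge has mean ``rim_level``.
    Additive Gaussian noise with sd ``noise_sd``; the same truth (same
    seed) produces a bit-identical frame.
    """
    ny, nx = truth.shape
    frame = np.full((ny, nx), float(truth.dilute_level))
    yy, xx = np.mgrid[0:ny, 0:nx]
    for (x, y), r in zip(truth.centers, truth.radii):
        dist = np.hypot(xx - x, yy - y)
        inside = dist <= r
        frame[inside] = truth.dense_level
        if truth.rim_level is not None:
            rim = inside & (dist >= r * (1.0 - truth.rim_width_frac))
            frame[rim] = truth.rim_level
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        frame = frame + rng.normal(0.0, truth.noise_sd, size=frame.shape)
    return ImageStack(frame, pixel_size_um=truth.pixel_size_um, channel="synthetic")


def gen_polarized_pair(
    field_: OrientationField, gain: float = 1.0, cos4: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Vertically/horizontally polarized excitation images of a fibril field.

    Single cos² photoselection (excitation polarized, detection
    unpolarized): the oriented fraction of emitters at axis angle θ
    contributes sin²θ to the vertical image and cos²θ to the horizontal
    one; the isotropic fraction splits evenly. Intensity is conserved:
    I_V + I_H = gain·amplitude pixel-wise. ``cos4=True`` squares the
    photoselection factors (polarized detection aligned with excitation),
    which sharpens contrast but breaks the sum rule.
    """
    iso = field_.isotropic_fraction
    s2 = np.sin(field_.theta) ** 2
    c2 = np.cos(field_.theta) ** 2
    if cos4:
        s2, c2 = s2**2, c2**2
    i_v = gain * field_.amplitude * ((1.0 - iso) * s2 + iso / 2.0)
    i_h = gain * field_.amplitude * ((1.0 - iso) * c2 + iso / 2.0)
    return i_v, i_h


def gen_oriented_ring(
    radius: float,
    width: float,
    shape: tuple[int, int] | None = None,
    mode: str = "tangential",
    amplitude: float = 1.0,
    isotropic_fraction: float = 0.0,
) -> OrientationField:
    """Annulus of fibrils tangent ("tangential") or normal ("radial") to a circle.

    At angular position φ the tangential fibril axis is θ = φ + π/2 and
    the radial one θ = φ (both mod π). The amplitude is ``amplitude``
    inside the annulus [radius − width/2, radius + width/2], 0 outside.
    """
    if not radius > width > 0:
        raise ValueError("need radius > width > 0")
    if mode not in ("tangential", "radial"):
        raise ValueError("mode must be 'tangential' or 'radial'")
    if shape is None:
        half = int(np.ceil(radius + width)) + 2
        shape = (2 * half + 1, 2 * half + 1)
    ny, nx = shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    yy, xx = np.mgrid[0:ny, 0:nx]
    # image y grows downward; φ measured counterclockwise from +x
    phi = np.arctan2(-(yy - cy), xx - cx)
    dist = np.hypot(xx - cx, yy - cy)
    in_ring = np.abs(dist - radius) <= width / 2.0
    theta = (phi + (np.pi / 2.0 if mode == "tangential" else 0.0)) % np.pi
    amp = np.where(in_ring, float(amplitude), 0.0)
    return OrientationField(theta, amp, isotropic_fraction)


def gen_tangential_ring(radius: float, width: float, **kwargs) -> OrientationField:
    """Ring of fibrils aligned parallel to the condensate interface."""
    return gen_oriented_ring(radius, width, mode="tangential", **kwargs)


def gen_frap_trace(truth: FrapTruth, t_grid_s: np.ndarray) -> KineticTrace:
    """Photobleaching trace: flat prebleach, exponential recovery after t = 0.

    I(t<0) = I_pre; I(t≥0) = I_post + f·(I_pre − I_post)·(1 − e^(−t/τ_rec)),
    plus additive Gaussian noise. The grid must contain samples on both
    sides of the bleach (t < 0 and t ≥ 0).
    """
    t = np.asarray(t_grid_s, dtype=float)
    if not (np.any(t < 0) and np.any(t >= 0)):
        raise ValueError("t_grid must contain prebleach (t<0) and postbleach (t≥0) samples")
    depth = truth.prebleach_level - truth.postbleach_level
    signal = np.where(
        t < 0,
        truth.prebleach_level,
        truth.postbleach_level
        + truth.mobile_fraction * depth * (1.0 - np.exp(-np.maximum(t, 0) / truth.recovery_time_s)),
    )
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        signal = signal + rng.normal(0.0, truth.noise_sd, size=t.shape)
    return KineticTrace(t, signal, condition="frap", time_unit="s")


def tht_expectation(truth: ThtTruth, t_h: np.ndarray) -> np.ndarray:
    """Noise-free expectation of the ThT curve on an arbitrary grid."""
    t = np.asarray(t_h, dtype=float)
    sig = truth.baseline + (truth.plateau - truth.baseline) / (
        1.0 + np.exp(-truth.steepness_per_h * (t - truth.t_half_h))
    )
    if truth.shape == "biphasic":
        sig = sig + truth.drift_slope_per_h * np.clip(t - truth.t_half_h, 0.0, None)
    return sig


def gen_tht_curve(truth: ThtTruth, t_grid_h: np.ndarray) -> KineticTrace:
    """ThT aggregation curve: logistic rise, plus a slow linear drift after
    the rise for the biphasic shape (fast fibril growth followed by slow
    late-stage signal increase)."""
    t = np.asarray(t_grid_h, dtype=float)
    if t[0] < 0 or not np.all(np.diff(t) > 0):
        raise ValueError("t_grid must be increasing and start at t ≥ 0")
    signal = tht_expectation(truth, t)
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        signal = signal + rng.normal(0.0, truth.noise_sd, size=t.shape)
    return KineticTrace(t, signal, condition=truth.shape, time_unit="h")


def gen_fcs_curve(truth: FcsTruth) -> tuple[np.ndarray, np.ndarray]:
    """Autocorrelation curve of one freely diffusing component.

    G(τ) = (1/N)(1 + τ/τ_D)⁻¹ (1 + τ/(k²τ_D))^(−1/2), multiplied by
    lognormal noise of the stated sd (correlation-estimate noise grows
    multiplicatively at long lags).
    """
    tau = truth.lag_grid_s
    g = (
        (1.0 / truth.n_particles)
        / (1.0 + tau / truth.tau_d_s)
        / np.sqrt(1.0 + tau / (truth.k**2 * truth.tau_d_s))
    )
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        g = g * rng.lognormal(0.0, truth.noise_sd, size=tau.shape)
    return tau, g


def dose_response_expectation(truth: DoseResponseTruth, conc: np.ndarray) -> np.ndarray:
    """Noise-free re-entrant turbidity dome.

    OD(c) = baseline + A·(1 − e^(−c/r))·e^(−c/s): a saturating rise
    (heterotypic promotion of condensation) times an exponential
    suppression (re-entrant charge inversion). The rise scale r is solved
    so the dome peaks exactly at ``turbidity_peak_location``
    (c* = r·ln(1 + s/r)); A normalizes the peak to ``peak_height``.
    With s = ∞ the curve is monotone saturating with scale set by the
    nominal peak location (no re-entrance).
    """
    c = np.asarray(conc, dtype=float)
    s = truth.suppression_scale
    c_star = truth.turbidity_peak_location
    if not np.isfinite(s):
        shape_fn = 1.0 - np.exp(-c / c_star)
        return truth.baseline + truth.peak_height * shape_fn
    # c* = r ln(1 + s/r) is increasing in r with limit s·? — bracket and solve
    f = lambda r: r * np.log1p(s / r) - c_star
    if f(1e-9) > 0:
        raise ValueError("peak location unreachable: must be < suppression_scale limit")
    hi = max(c_star, 1.0)
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e12:
            raise ValueError("peak location unreachable for this suppression scale")
    r = brentq(f, 1e-9, hi)
    shape_fn = (1.0 - np.exp(-c / r)) * np.exp(-c / s)
    peak_val = (1.0 - np.exp(-c_star / r)) * np.exp(-c_star / s)
    return truth.baseline + truth.peak_height * shape_fn / peak_val


def gen_dose_response(truth: DoseResponseTruth) -> tuple[np.ndarray, np.ndarray]:
    """Turbidity (OD400) versus RNA mass concentration with per-point noise."""
    od = dose_response_expectation(truth, truth.rna_concentrations)
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        od = od + rng.normal(0.0, truth.noise_sd, size=od.shape)
    return truth.rna_concentrations.copy(), od
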