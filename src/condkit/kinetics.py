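"""Plate-reader kinetics: ThT aggregation curves and turbidity.

Normalizes thioflavin-T traces, extracts aggregation half-times (first
interpolated crossing of half-maximal normalized fluorescence), compares
half-time groups with the Kruskal–Wallis rank test, checks endpoint
linearity against total protein concentration, reduces turbidity traces
to a dense-phase-volume proxy, and classifies the protein–RNA phase
regime (homotypic / heterotypic / re-entrant).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats
from scipy.signal import medfilt

BELOW_SATURATION = "below_saturation"


class FlatCurveError(ValueError):
    """Raised when a trace has no dynamic range to normalize."""


@dataclass
class KineticTrace:
    """A (time, signal) series for one well/condition/replicate.

    Time is in hours for plate-reader data (ThT, turbidity) and seconds
    for FRAP; ``time_unit`` records which. Time must be strictly
    increasing and the signal finite.
    """

    time: np.ndarray
    signal: np.ndarray
    condition: str = ""
    replicate: str | int = 0
    time_unit: str = "h"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape or self.time.ndim != 1:
            raise ValueError("time and signal must be matching 1-D arrays")
        if len(self.time) >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal must be finite")


@dataclass
class HalfTimeResult:
    """Half-time of an aggregation curve with provenance flags."""

    t_half: float | None
    normalized: KineticTrace
    method: str = "interpolated-0.5-crossing"
    flags: list[str] = field(default_factory=list)


@dataclass
class KruskalResult:
    H: float
    p_value: float
    df: int
    method: str  # "chi2" or "permutation"
    n_permutations: int | None = None


def normalize_tht(trace: KineticTrace, smooth: bool = True) -> KineticTrace:
    """Rescale a ThT trace to [0, 1] using its own extrema.

    A 3-point running median (optional, on by default) stops a single
    spiky sample from defining "maximum fluorescence". The output signal
    is (I − I_min)/(I_max − I_min) of the smoothed trace.
    """
    if len(trace.time) < 10:
        raise ValueError("need at least 10 samples to normalize a ThT trace")
    sig = trace.signal
    if smooth and len(sig) >= 3:
        sig = medfilt(sig, kernel_size=3)
    lo, hi = float(sig.min()), float(sig.max())
    if hi == lo:
        raise FlatCurveError("flat trace: I_max equals I_min")
    return replace(trace, signal=(sig - lo) / (hi - lo))


def half_time(normalized: KineticTrace) -> HalfTimeResult:
    """First upward 0.5-crossing of a normalized curve, linearly interpolated.

    Flags: ``no_crossing`` when the curve never reaches 0.5 upward,
    ``non_monotone_plateau`` when the signal drops below 0.5 again after
    the crossing (non-plateaued or noisy late phase).
    """
    t, n = normalized.time, normalized.signal
    flags: list[str] = []
    above = n >= 0.5
    t_half = None
    for i in range(1, len(t)):
        if not above[i - 1] and above[i]:
            frac = (0.5 - n[i - 1]) / (n[i] - n[i - 1])
            t_half = float(t[i - 1] + frac * (t[i] - t[i - 1]))
            if np.any(n[i:] < 0.5):
                flags.append("non_monotone_plateau")
            break
    else:
        if above[0]:
            t_half = float(t[0])
        else:
            flags.append("no_crossing")
    return HalfTimeResult(t_half, normalized, flags=flags)


def _kw_statistic(groups: list[np.ndarray]) -> float:
    """Tie-corrected Kruskal–Wallis H from pooled ranks."""
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(tie_counts**3 - tie_counts) / (n**3 - n)
    if correction == 0:
        return 0.0
    return h / correction


def kruskal_wallis(groups: list, method: str = "auto") -> KruskalResult:
    """Kruskal–Wallis rank test across ≥ 2 groups.

    ``method``: "chi2" (tie-corrected H against the χ²(g−1) upper tail),
    "permutation" (exact enumeration of group assignments when the
    multinomial count is ≤ 200 000, Monte-Carlo otherwise), or "auto"
    (permutation when total n ≤ 12, else chi2).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need ≥ 2 groups with ≥ 2 values each")
    pooled = np.concatenate(groups)
    df = len(groups) - 1
    if np.all(pooled == pooled[0]):
        return KruskalResult(0.0, 1.0, df, "degenerate")

    if method == "auto":
        method = "permutation" if pooled.size <= 12 else "chi2"

    h_obs = _kw_statistic(groups)
    if method == "chi2":
        h_scipy, p = stats.kruskal(*groups)
        return KruskalResult(float(h_scipy), float(p), df, "chi2")
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")

    sizes = [g.size for g in groups]
    n = pooled.size
    n_assign = 1
    rest = n
    for s in sizes:
        n_assign *= comb(rest, s)
        rest -= s

    def _h_for(order: np.ndarray) -> float:
        parts, start = [], 0
        for s in sizes:
            parts.append(pooled[order[start : start + s]])
            start += s
        return _kw_statistic(parts)

    tol = 1e-12
    if n_assign <= 200_000:
        count = 0
        total = 0

        def _recurse(remaining: tuple, chosen: list) -> None:
            nonlocal count, total
            if len(chosen) == len(sizes):
                order = np.array([i for grp in chosen for i in grp])
                total += 1
                if _h_for(order) >= h_obs - tol:
                    count += 1
                return
            s = sizes[len(chosen)]
            for pick in combinations(remaining, s):
                _recurse(tuple(x for x in remaining if x not in pick), chosen + [pick])

        _recurse(tuple(range(n)), [])
        return KruskalResult(h_obs, count / total, df, "permutation", total)

    rng = np.random.default_rng(0)
    n_mc = 20_000
    count = sum(
        _h_for(rng.permutation(n)) >= h_obs - tol for _ in range(n_mc)
    )
    return KruskalResult(h_obs, (count + 1) / (n_mc + 1), df, "permutation", n_mc)


def concentration_independence(groups: list, alpha: float = 0.05) -> dict:
    """Pipeline check: no dependence of half-times on bulk concentration.

    Passes when the Kruskal–Wallis p across protein-concentration groups
    exceeds ``alpha``.
    """
    res = kruskal_wallis(groups, method="chi2" if sum(len(g) for g in groups) > 12 else "auto")
    return {"H": res.H, "p_value": res.p_value, "independent": res.p_value > alpha}


def endpoint_linearity(points: list[tuple[float, float]]) -> dict:
    """OLS of plateau ThT intensity against total protein concentration.

    Returns slope, intercept, R² and a ``linear`` flag (R² ≥ 0.9).
    Constant endpoints are reported as slope 0 with R² = 0 by convention.
    """
    if len(points) < 3:
        raise ValueError("need ≥ 3 concentration points")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.ptp(y) == 0:
        return {"slope": 0.0, "intercept": float(y[0]), "r_squared": 0.0, "linear": False}
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue**2)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": r2,
        "linear": r2 >= 0.9,
    }


def turbidity_proxy(trace: KineticTrace, window_min: float = 30.0) -> float:
    """Maximum OD400 within the first ``window_min`` minutes.

    Used as a proxy of total dense-phase volume; samples after the window
    do not contribute. Trace time is in hours.
    """
    window_h = window_min / 60.0
    if trace.time[0] > window_h:
        raise ValueError("trace does not cover the proxy window")
    sel = trace.time <= window_h + 1e-12
    if not sel.any():
        raise ValueError("empty proxy window")
    return float(trace.signal[sel].max())


def classify_regime(rna_conc_ng_ul: float, droplets_present: bool) -> int | str:
    """Three-regime protein–RNA phase classification at fixed protein conc.

    1 — condensates without RNA (homotypic); 2 — condensates with RNA
    (homotypic + heterotypic); 3 — RNA present but no condensates
    (re-entrant suppression). No RNA and no condensates is the
    below-saturation sentinel, not a regime.
    """
    if rna_conc_ng_ul < 0:
        raise ValueError("RNA concentration must be ≥ 0")
    if rna_conc_ng_ul == 0:
        return 1 if droplets_present else BELOW_SATURATION
    return 2 if droplets_present else 3
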