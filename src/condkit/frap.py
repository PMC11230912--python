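"""FRAP analysis: normalization, mobile-fraction fitting, group comparison.

A small spot (≈ one tenth of the droplet diameter) is bleached and the
fluorescence recovery tracked for tens of seconds. Traces are normalized
to prebleach = 1 and first-postbleach = 0, then fitted with a single
exponential n(t) = f·(1 − e^(−t/τ_rec)); the fitted plateau f is the
mobile fraction, reported as "% recovery". Conditions are compared with
the two-sided Wilcoxon rank-sum test (exact for small samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .kinetics import KineticTrace


@dataclass
class FrapFit:
    """Mobile fraction and recovery time of one normalized trace.

    Out-of-range mobile fractions (f < 0 or f > 1) are reported as
    estimated — never clipped — with an ``out_of_range`` flag, so that
    aggregation over replicates stays unbiased.
    """

    mobile_fraction: float
    mobile_fraction_se: float
    recovery_time_s: float
    recovery_time_se: float
    normalized: KineticTrace
    residual_sd: float
    endpoint_recovery: float     # last observed normalized point
    converged: bool = True
    model: str = "single-exponential"
    flags: list[str] = field(default_factory=list)


def normalize_frap(raw: KineticTrace, bleach_index: int | None = None) -> KineticTrace:
    """Map a raw trace to prebleach mean = 1, first postbleach point = 0.

    ``bleach_index`` is the index of the first postbleach sample; when
    None it is taken as the first sample with t ≥ 0 if the time axis has
    negative (prebleach) times, otherwise as the largest single-step
    intensity drop. At least two prebleach points are required.
    """
    t, sig = raw.time, raw.signal
    if bleach_index is None:
        if np.any(t < 0):
            bleach_index = int(np.argmax(t >= 0))
        else:
            bleach_index = int(np.argmin(np.diff(sig))) + 1
    if bleach_index < 2:
        raise ValueError("need ≥ 2 prebleach points")
    i_pre = float(sig[:bleach_index].mean())
    i_post0 = float(sig[bleach_index])
    if i_pre == i_post0:
        raise ValueError("no bleach depth: prebleach equals first postbleach point")
    norm = (sig - i_post0) / (i_pre - i_post0)
    return KineticTrace(t, norm, condition=raw.condition, replicate=raw.replicate,
                        time_unit=raw.time_unit)


def fit_recovery(normalized: KineticTrace) -> FrapFit:
    """Least-squares single-exponential fit of the postbleach recovery.

    Only samples with t ≥ 0 enter the fit (≥ 8 required). Non-convergence
    returns a flagged fit with NaN parameters rather than raising.
    """
    post = normalized.time >= 0
    t = normalized.time[post]
    n = normalized.signal[post]
    if len(t) < 8:
        raise ValueError("need ≥ 8 postbleach points")

    def model(tt, f, tau):
        return f * (1.0 - np.exp(-tt / tau))

    t_span = float(t[-1] - t[0]) or 1.0
    p0 = (max(float(n[-1]), 0.1), t_span / 5.0)
    try:
        popt, pcov = curve_fit(
            model, t, n, p0=p0, bounds=([-np.inf, 1e-9], [np.inf, np.inf]),
            maxfev=10000,
        )
        perr = np.sqrt(np.diag(pcov))
        resid = n - model(t, *popt)
        converged = bool(np.all(np.isfinite(perr)))
    except RuntimeError:
        popt = (float("nan"), float("nan"))
        perr = (float("nan"), float("nan"))
        resid = np.full_like(n, np.nan)
        converged = False

    flags = []
    if not converged:
        flags.append("non_convergence")
    if converged and not 0.0 <= popt[0] <= 1.0:
        flags.append("out_of_range")
    if converged and perr[1] > 10.0 * popt[1]:
        flags.append("wide_tau_uncertainty")
    return FrapFit(
        mobile_fraction=float(popt[0]),
        mobile_fraction_se=float(perr[0]),
        recovery_time_s=float(popt[1]),
        recovery_time_se=float(perr[1]),
        normalized=normalized,
        residual_sd=float(np.nanstd(resid)),
        endpoint_recovery=float(n[-1]),
        converged=converged,
        flags=flags,
    )


def _fractions(group) -> np.ndarray:
    vals = [g.mobile_fraction if isinstance(g, FrapFit) else float(g) for g in group]
    return np.asarray(vals, dtype=float)


def compare_recovery(group_a, group_b) -> dict:
    """Two-condition comparison of mobile fractions.

    Accepts lists of FrapFit or bare fractions (≥ 3 each). Reports
    per-group mean ± sd and the two-sided Wilcoxon rank-sum p-value
    (exact enumeration when both groups are small and tie-free).
    Identical groups are reported with p = 1 and a note.
    """
    a, b = _fractions(group_a), _fractions(group_b)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need ≥ 3 fits per group")
    out = {
        "mean_a": float(a.mean()), "sd_a": float(a.std(ddof=1)),
        "mean_b": float(b.mean()), "sd_b": float(b.std(ddof=1)),
        "n_a": len(a), "n_b": len(b), "note": "",
    }
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        out["p_value"] = 1.0
        out["note"] = "degenerate: all values identical"
        return out
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) + len(b) <= 20 and not has_ties) else "auto"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    out["p_value"] = float(res.pvalue)
    return out
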