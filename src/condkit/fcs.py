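"""FCS: one-component 3-D diffusion fits and dilute-phase concentration.

The autocorrelation of fluorescence fluctuations in a confocal volume,

    G(τ) = (1/N)·(1 + τ/τ_D)⁻¹·(1 + τ/(k²·τ_D))^(−1/2),

gives the mean particle number N in the effective focal volume (G(0) =
1/N) and the diffusion time τ_D; k is the axial/lateral aspect ratio of
the detection volume. No triplet term is included. The focal volume is
calibrated from a reference dye of known diffusion coefficient
(w₀ = √(4·D·τ_D), V_eff = π^{3/2}·k·w₀³), after which N converts to an
absolute molar concentration. Sample dilution with unlabelled protein
and sub-unity labelling efficiency are corrected multiplicatively, and
the monomer conversion follows as 1 − C_dilute/C_initial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

AVOGADRO = 6.02214076e23  # mol⁻¹


@dataclass
class FcsFit:
    n_particles: float
    tau_d_s: float
    k: float
    g_inf: float
    n_se: float = float("nan")
    tau_d_se: float = float("nan")
    residual_sd: float = float("nan")
    k_fixed: bool = False
    converged: bool = True
    flags: list[str] = field(default_factory=list)


@dataclass
class FocalVolume:
    """Effective confocal detection volume; V_eff = π^{3/2}·k·w₀³."""

    v_eff_l: float          # litres
    k: float
    w0_m: float             # lateral 1/e² radius, metres

    def __post_init__(self) -> None:
        if self.v_eff_l <= 0:
            raise ValueError("V_eff must be positive")


@dataclass
class ConcentrationResult:
    c_labeled_m: float      # molar, labelled species only
    c_total_m: float        # molar, corrected for dilution and labelling
    dilution_factor: float
    labeling_efficiency: float


def fcs_model(tau, n_particles: float, tau_d: float, k: float) -> np.ndarray:
    """Normalized one-component 3-D diffusion autocorrelation."""
    if n_particles <= 0 or tau_d <= 0 or k <= 0:
        raise ValueError("parameters must be positive")
    tau = np.asarray(tau, dtype=float)
    return (
        (1.0 / n_particles)
        / (1.0 + tau / tau_d)
        / np.sqrt(1.0 + tau / (k**2 * tau_d))
    )


def fit_fcs(
    lag_s: np.ndarray,
    g: np.ndarray,
    fixed_k: float | None = None,
    sigma: np.ndarray | None = None,
    fit_offset: bool = True,
) -> FcsFit:
    """Weighted least-squares fit of the one-component model (+ offset).

    Weights default to σ ∝ G(τ) (multiplicative, lognormal-like
    correlation noise); pass per-lag ``sigma`` from replicate curves when
    available. ``fixed_k`` pins the structural parameter to a calibrated
    value (standard practice — the aspect ratio is an instrument
    property, not a sample property). Requires ≥ 20 lags spanning at
    least 3 decades. A fit that fails to converge or lands on a bound is
    returned flagged with NaN errors, not raised.
    """
    lag_s = np.asarray(lag_s, dtype=float)
    g = np.asarray(g, dtype=float)
    if len(lag_s) < 20:
        raise ValueError("need ≥ 20 lag points")
    if lag_s[-1] / lag_s[0] < 1e3:
        raise ValueError("lag grid must span ≥ 3 decades")
    if sigma is None:
        sigma = np.maximum(np.abs(g), 1e-12 * max(abs(g).max(), 1.0))

    g0 = float(np.mean(g[:3]))
    if g0 <= 0:
        return FcsFit(float("nan"), float("nan"), fixed_k or float("nan"),
                      0.0, converged=False, flags=["non_convergence"])
    n0 = 1.0 / g0
    # initial diffusion time: lag where G first falls to half its amplitude
    half_idx = np.argmax(g <= 0.5 * g0) or len(g) // 2
    tau0 = float(lag_s[half_idx])

    if fixed_k is not None:
        def model(tau, n, tau_d, off):
            return fcs_model(tau, n, tau_d, fixed_k) + off
        p0 = [n0, tau0, 0.0]
        lb, ub = [1e-12, 1e-12, -np.inf], [np.inf, np.inf, np.inf]
    else:
        def model(tau, n, tau_d, k, off):
            return fcs_model(tau, n, tau_d, k) + off
        p0 = [n0, tau0, 5.0, 0.0]
        lb, ub = [1e-12, 1e-12, 1.0 + 1e-9, -np.inf], [np.inf] * 3 + [np.inf]
    if not fit_offset:
        p0 = p0[:-1]
        lb, ub = lb[:-1], ub[:-1]
        base = model
        if fixed_k is not None:
            model = lambda tau, n, tau_d: base(tau, n, tau_d, 0.0)
        else:
            model = lambda tau, n, tau_d, k: base(tau, n, tau_d, k, 0.0)

    try:
        popt, pcov = curve_fit(
            model, lag_s, g, p0=p0, sigma=sigma, absolute_sigma=False,
            bounds=(lb, ub), maxfev=20000,
        )
        perr = np.sqrt(np.diag(pcov))
        resid = g - model(lag_s, *popt)
        converged = bool(np.all(np.isfinite(perr[:2])))
    except (RuntimeError, ValueError):
        nanfit = FcsFit(float("nan"), float("nan"), fixed_k or float("nan"), 0.0,
                        converged=False, flags=["non_convergence"])
        return nanfit

    flags = []
    at_bound = any(
        np.isclose(p, b, rtol=1e-6) for p, b in zip(popt, lb) if np.isfinite(b)
    )
    if at_bound:
        flags.append("parameter_at_bound")
        converged = False
    if not converged and "non_convergence" not in flags:
        flags.append("non_convergence")

    n_hat, tau_hat = float(popt[0]), float(popt[1])
    k_hat = fixed_k if fixed_k is not None else float(popt[2])
    off = float(popt[-1]) if fit_offset else 0.0
    return FcsFit(
        n_particles=n_hat, tau_d_s=tau_hat, k=float(k_hat), g_inf=off,
        n_se=float(perr[0]), tau_d_se=float(perr[1]),
        residual_sd=float(np.std(resid)), k_fixed=fixed_k is not None,
        converged=converged, flags=flags,
    )


def calibrate_focal_volume(
    lag_s: np.ndarray, g: np.ndarray, d_dye_m2_s: float
) -> FocalVolume:
    """Focal-volume calibration from a reference-dye correlation curve.

    Fits the dye curve (k free), then w₀ = √(4·D_dye·τ_D) and
    V_eff = π^{3/2}·k·w₀³ (in litres: 1 m³ = 10³ L).
    """
    if d_dye_m2_s <= 0:
        raise ValueError("dye diffusion coefficient must be positive")
    fit = fit_fcs(lag_s, g, fixed_k=None)
    if not fit.converged:
        raise RuntimeError("dye calibration fit did not converge")
    w0 = float(np.sqrt(4.0 * d_dye_m2_s * fit.tau_d_s))
    v_eff_m3 = np.pi**1.5 * fit.k * w0**3
    return FocalVolume(v_eff_l=float(v_eff_m3 * 1e3), k=fit.k, w0_m=w0)


def concentration_from_fit(
    fit: FcsFit,
    focal_volume: FocalVolume,
    dilution_factor: float = 10.0,
    labeling_efficiency: float = 0.64,
) -> ConcentrationResult:
    """Absolute dilute-phase concentration from a converged fit.

    C_labeled = N/(N_A·V_eff); the total protein concentration corrects
    for mixing labelled protein 1:``dilution_factor`` with unlabelled
    protein and for the labelling efficiency of the dye conjugation:
    C_total = C_labeled · dilution / efficiency.
    """
    if not fit.converged:
        raise ValueError("cannot convert a non-converged fit to a concentration")
    if not 0.0 < labeling_efficiency <= 1.0:
        raise ValueError("labelling efficiency must be in (0, 1]")
    if dilution_factor < 1.0:
        raise ValueError("dilution factor must be ≥ 1")
    c_lab = fit.n_particles / (AVOGADRO * focal_volume.v_eff_l)
    return ConcentrationResult(
        c_labeled_m=float(c_lab),
        c_total_m=float(c_lab * dilution_factor / labeling_efficiency),
        dilution_factor=dilution_factor,
        labeling_efficiency=labeling_efficiency,
    )


def monomer_conversion(c_dilute_m: float, c_initial_m: float) -> dict:
    """Fraction of initial soluble protein consumed into the dense phase
    and fibrils: 1 − C_dilute/C_initial. The reported value is clipped to
    [0, 1]; estimates outside that range (measurement noise) keep the raw
    value alongside an ``out_of_range`` flag.
    """
    if c_initial_m <= 0:
        raise ValueError("initial concentration must be positive")
    if c_dilute_m < 0:
        raise ValueError("dilute-phase concentration must be ≥ 0")
    raw = 1.0 - c_dilute_m / c_initial_m
    return {
        "conversion": float(np.clip(raw, 0.0, 1.0)),
        "raw": float(raw),
        "out_of_range": not 0.0 <= raw <= 1.0,
    }
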