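"""File I/O, configuration and the end-to-end pipeline drivers.

The pipeline chains the analysis stages into the study's headline
workflows: turbidity + bright-field droplet detection → phase regimes;
ThT traces → half-times and concentration-independence; images → rim
enrichment and interface dichroism scores; FRAP traces → mobile
fractions; FCS curves → dilute-phase concentration and monomer
conversion. Every run is deterministic given (config, seed); outputs
are CSV tables stamped with the config hash plus a JSON run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import fcs as fcs_mod
from . import fdld, frap, imaging, kinetics, stoich, synthgen

ANALYSES = ("aggregation", "frap", "fdld", "fcs", "phase")


@dataclass
class ExperimentConfig:
    """Declarative description of one pipeline run.

    Paths are optional: any input left unset is generated synthetically
    from the seed, which makes a full no-data "replay" run possible.
    """

    output_dir: str = "results/run"
    seed: int = 0
    pixel_size_um: float = 0.1
    frame_interval_s: float | None = None
    protein_conc_um: float = 10.0
    rna_conc_ng_ul: float = 0.0
    # FCS constants
    fcs_dilution_factor: float = 10.0
    fcs_labeling_efficiency: float = 0.64
    fcs_dye_diffusion_m2_s: float = 3.3e-10
    # optional input files (long-format CSV / TIFF)
    tht_traces_csv: str | None = None
    frap_traces_csv: str | None = None
    image_tiff: str | None = None
    fcs_curves_csv: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def save_image_stack(stack: imaging.ImageStack, path: str | Path) -> None:
    """Write a float32 TIFF plus a JSON metadata sidecar (<path>.json)."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32), photometric="minisblack")
    meta = {
        "pixel_size_um": stack.pixel_size_um,
        "frame_interval_s": stack.frame_interval_s,
        "channel": stack.channel,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def load_image_stack(
    path: str | Path,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
    channel: str = "",
) -> imaging.ImageStack:
    """Read a grayscale TIFF into an ImageStack.

    Pixel size is taken from an explicit argument or the JSON sidecar;
    a stack without one is a hard error — silent length defaults corrupt
    every µm-denominated quantity downstream. RGB input is rejected.
    """
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 3 and frames.shape[-1] in (3, 4) and frames.shape[-1] < min(frames.shape[:2]):
        raise ValueError("RGB TIFF not supported: provide single-channel grayscale")
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    if px is None:
        raise ValueError(f"{path}: pixel size missing (no argument, no sidecar)")
    fi = frame_interval_s if frame_interval_s is not None else meta.get("frame_interval_s")
    return imaging.ImageStack(frames, pixel_size_um=px, frame_interval_s=fi,
                              channel=channel or meta.get("channel", ""))


def load_trace_table(path: str | Path) -> list[kinetics.KineticTrace]:
    """Read a long-format CSV into one KineticTrace per (condition, replicate).

    Requires columns ``time`` (or ``time_h``/``time_s``, the suffix fixing
    the unit), ``signal``, ``condition``, ``replicate``. Rows may arrive
    in any order; duplicate time points within a trace are an error.
    """
    df = pd.read_csv(path)
    time_col = next((c for c in ("time_h", "time_s", "time") if c in df.columns), None)
    if time_col is None or not {"signal", "condition", "replicate"} <= set(df.columns):
        raise ValueError("CSV must have time[_h|_s], signal, condition, replicate columns")
    unit = {"time_h": "h", "time_s": "s"}.get(time_col, "h")
    if not np.issubdtype(df[time_col].dtype, np.number) or not np.issubdtype(
        df["signal"].dtype, np.number
    ):
        raise ValueError("non-numeric time or signal cells")
    traces = []
    for (cond, rep), grp in df.groupby(["condition", "replicate"], sort=True):
        grp = grp.sort_values(time_col)
        t = grp[time_col].to_numpy(dtype=float)
        if np.any(np.diff(t) == 0):
            raise ValueError(f"duplicate time points in trace ({cond}, {rep})")
        traces.append(
            kinetics.KineticTrace(t, grp["signal"].to_numpy(dtype=float),
                                  condition=str(cond), replicate=rep, time_unit=unit)
        )
    return traces


def write_plate_long(traces: list[kinetics.KineticTrace], path: str | Path) -> None:
    """Write traces back to the long CSV format (unit suffix on the time column)."""
    unit = traces[0].time_unit if traces else "h"
    rows = [
        {f"time_{unit}": t, "signal": s, "condition": tr.condition, "replicate": tr.replicate}
        for tr in traces
        for t, s in zip(tr.time, tr.signal)
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.8g")


def plate_to_long(df: pd.DataFrame, well_conditions: dict, time_col: str = "time_h") -> pd.DataFrame:
    """Narrow converter from plate-shaped exports (one column per well)."""
    rows = []
    for well, (cond, rep) in well_conditions.items():
        if well not in df.columns:
            raise KeyError(f"well {well!r} not in table")
        for t, s in zip(df[time_col], df[well]):
            rows.append({time_col: t, "signal": s, "condition": cond, "replicate": rep})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# pipeline stages (each returns a dict of DataFrames)
# --------------------------------------------------------------------------

def _rng_seed(config: ExperimentConfig, offset: int) -> int:
    return (config.seed * 1000 + offset) % (2**31 - 1)


def _aggregation_stage(config: ExperimentConfig) -> dict[str, pd.DataFrame]:
    """ThT half-times per condition, concentration-independence, endpoint OLS."""
    if config.tht_traces_csv:
        traces = load_trace_table(config.tht_traces_csv)
        conc_of = {tr.condition: np.nan for tr in traces}
    else:
        t_grid = np.arange(0.0, 72.25, 0.25)  # 15-min sampling over 3 days
        concentrations = [5.0, 10.0, 20.0]
        traces, conc_of = [], {}
        for i, conc in enumerate(concentrations):
            for rep in range(3):
                truth = synthgen.ThtTruth(
                    shape="sigmoid", t_half_h=20.0, steepness_per_h=0.5,
                    plateau=10.0 * conc, baseline=5.0, noise_sd=0.01 * 10.0 * conc,
                    seed=_rng_seed(config, 10 + 10 * i + rep),
                )
                tr = synthgen.gen_tht_curve(truth, t_grid)
                tr.condition, tr.replicate = f"{conc:g}uM", rep
                conc_of[tr.condition] = conc
                traces.append(tr)
    rows, groups, endpoints = [], {}, {}
    for tr in traces:
        norm = kinetics.normalize_tht(tr)
        res = kinetics.half_time(norm)
        rows.append({
            "condition": tr.condition, "replicate": tr.replicate,
            "t_half_h": res.t_half, "flags": ";".join(res.flags),
        })
        groups.setdefault(tr.condition, []).append(res.t_half)
        endpoints.setdefault(tr.condition, []).append(float(tr.signal[-1]))
    half_df = pd.DataFrame(rows)
    valid_groups = [
        [v for v in g if v is not None] for g in groups.values()
    ]
    indep = kinetics.concentration_independence([g for g in valid_groups if len(g) >= 2])
    indep_df = pd.DataFrame([indep])
    pts = [
        (conc_of[c], float(np.mean(endpoints[c])))
        for c in groups if np.isfinite(conc_of[c])
    ]
    lin_df = pd.DataFrame([kinetics.endpoint_linearity(pts)]) if len(pts) >= 3 else pd.DataFrame()
    return {"half_times": half_df, "concentration_independence": indep_df,
            "endpoint_linearity": lin_df}


def _frap_stage(config: ExperimentConfig) -> dict[str, pd.DataFrame]:
    """Mobile fractions for early/late homotypic vs heterotypic condensates."""
    if config.frap_traces_csv:
        traces = load_trace_table(config.frap_traces_csv)
    else:
        t_grid = np.concatenate([np.linspace(-5, -1, 5), np.linspace(0, 30, 61)])
        scenarios = {  # condition -> mean mobile fraction emulated
            "homotypic_30min": 0.96, "heterotypic_30min": 0.91,
            "homotypic_2h": 0.54, "heterotypic_2h": 0.91,
        }
        traces = []
        for i, (cond, f) in enumerate(scenarios.items()):
            for rep in range(10):
                rng = np.random.default_rng(_rng_seed(config, 100 + 20 * i + rep))
                f_i = float(np.clip(rng.normal(f, 0.04), 0.0, 1.0))
                truth = synthgen.FrapTruth(
                    mobile_fraction=f_i, recovery_time_s=5.0,
                    noise_sd=10.0, seed=_rng_seed(config, 500 + 20 * i + rep),
                )
                tr = synthgen.gen_frap_trace(truth, t_grid)
                tr.condition, tr.replicate = cond, rep
                traces.append(tr)
    fits, rows = {}, []
    for tr in traces:
        fit = frap.fit_recovery(frap.normalize_frap(tr))
        fits.setdefault(tr.condition, []).append(fit)
        rows.append({
            "condition": tr.condition, "replicate": tr.replicate,
            "mobile_fraction": fit.mobile_fraction,
            "recovery_time_s": fit.recovery_time_s,
            "endpoint_recovery": fit.endpoint_recovery,
            "converged": fit.converged, "flags": ";".join(fit.flags),
        })
    fit_df = pd.DataFrame(rows)
    comp_rows = []
    conds = sorted(fits)
    for i, a in enumerate(conds):
        for b in conds[i + 1:]:
            if len(fits[a]) >= 3 and len(fits[b]) >= 3:
                cmp_ = frap.compare_recovery(fits[a], fits[b])
                cmp_.update({"group_a": a, "group_b": b})
                comp_rows.append(cmp_)
    return {"frap_fits": fit_df, "frap_comparisons": pd.DataFrame(comp_rows)}


def _fdld_stage(config: ExperimentConfig) -> dict[str, pd.DataFrame]:
    """Interface orientation scores for tangential / radial / isotropic rings."""
    rows = []
    for mode, iso in (("tangential", 0.0), ("radial", 0.0), ("tangential", 1.0)):
        ring = synthgen.gen_oriented_ring(30.0, 6.0, shape=(101, 101), mode=mode,
                                          isotropic_fraction=iso)
        i_v, i_h = synthgen.gen_polarized_pair(ring, gain=100.0)
        res = fdld.dichroism_map(i_v, i_h, floor=1.0)
        score = fdld.interface_orientation_score(res, (50.0, 50.0), 30.0,
                                                 annulus=(0.9, 1.1))
        label = "isotropic" if iso == 1.0 else mode
        rows.append({"fixture": label, "orientation_score": score})
    return {"fdld_scores": pd.DataFrame(rows)}


def _phase_stage(config: ExperimentConfig) -> dict[str, pd.DataFrame]:
    """Turbidity dose–response, droplet detection and regime table."""
    truth = synthgen.DoseResponseTruth(noise_sd=0.005, seed=_rng_seed(config, 7))
    conc, od = synthgen.gen_dose_response(truth)
    dose_df = pd.DataFrame({"rna_ng_ul": conc, "od400": od})

    rows = []
    rng = np.random.default_rng(_rng_seed(config, 8))
    for c, o in zip(conc, od):
        # bright-field confirmation emulated: droplets only below re-entrance
        has_droplets = c <= 50.0
        if has_droplets:
            centers, radii = _random_disks(rng, n=6, shape=(128, 128))
            field_truth = synthgen.DropletFieldTruth(
                centers, radii, dilute_level=10.0, dense_level=100.0,
                pixel_size_um=config.pixel_size_um, noise_sd=5.0,
                shape=(128, 128), seed=int(rng.integers(2**31 - 1)),
            )
            img = synthgen.gen_droplet_image(field_truth)
            droplets = imaging.segment_droplets(img, min_diameter_um=0.5)
            n_droplets = droplets.count
        else:
            n_droplets = 0
        regime = kinetics.classify_regime(c, n_droplets > 0)
        rows.append({"rna_ng_ul": c, "od400": o, "n_droplets": n_droplets,
                     "regime": regime})
    return {"dose_response": dose_df, "regimes": pd.DataFrame(rows)}


def _fcs_stage(config: ExperimentConfig) -> dict[str, pd.DataFrame]:
    """Calibration, dilute-phase concentrations and monomer conversion."""
    # dye calibration curve chosen to reproduce a 0.72 fL volume at k ≈ 7
    k_cal = 7.05
    v_eff_l = 0.72e-15
    w0 = (v_eff_l * 1e-3 / (np.pi**1.5 * k_cal)) ** (1.0 / 3.0)
    tau_d_dye = w0**2 / (4.0 * config.fcs_dye_diffusion_m2_s)
    dye_truth = synthgen.FcsTruth(n_particles=8.0, tau_d_s=tau_d_dye, k=k_cal,
                                  noise_sd=0.005, seed=_rng_seed(config, 300))
    fv = fcs_mod.calibrate_focal_volume(*synthgen.gen_fcs_curve(dye_truth),
                                        config.fcs_dye_diffusion_m2_s)

    c_init = config.protein_conc_um * 1e-6
    scenarios = {"no_rna": 0.83, "rna_50ng_ul": 0.75, "rna_500ng_ul": 0.53}
    rows = []
    for i, (cond, conv) in enumerate(scenarios.items()):
        c_dilute = (1.0 - conv) * c_init
        # labelled-species particle number the instrument would see
        n_true = (
            c_dilute / config.fcs_dilution_factor * config.fcs_labeling_efficiency
            * fcs_mod.AVOGADRO * fv.v_eff_l
        )
        for rep in range(3):
            truth = synthgen.FcsTruth(
                n_particles=n_true, tau_d_s=5e-4, k=fv.k, noise_sd=0.01,
                seed=_rng_seed(config, 400 + 10 * i + rep),
            )
            fit = fcs_mod.fit_fcs(*synthgen.gen_fcs_curve(truth), fixed_k=fv.k)
            conc = fcs_mod.concentration_from_fit(
                fit, fv, config.fcs_dilution_factor, config.fcs_labeling_efficiency
            )
            mc = fcs_mod.monomer_conversion(conc.c_total_m, c_init)
            rows.append({
                "condition": cond, "replicate": rep,
                "n_particles": fit.n_particles, "tau_d_s": fit.tau_d_s,
                "c_dilute_um": conc.c_total_m * 1e6,
                "monomer_conversion": mc["conversion"],
            })
    df = pd.DataFrame(rows)
    summary = (
        df.groupby("condition")["monomer_conversion"]
        .agg(["mean", "std"]).reset_index()
    )
    cal_df = pd.DataFrame([{"v_eff_fl": fv.v_eff_l * 1e15, "k": fv.k, "w0_nm": fv.w0_m * 1e9}])
    return {"fcs_calibration": cal_df, "fcs_concentrations": df,
            "monomer_conversion_summary": summary}


def _random_disks(rng, n, shape, r_range=(6.0, 14.0), max_tries=2000):
    """Rejection-sample n non-overlapping disks fully inside the frame."""
    ny, nx = shape
    centers, radii = [], []
    tries = 0
    while len(centers) < n and tries < max_tries:
        tries += 1
        r = float(rng.uniform(*r_range))
        x = float(rng.uniform(r + 1, nx - r - 2))
        y = float(rng.uniform(r + 1, ny - r - 2))
        if all(np.hypot(x - cx, y - cy) >= r + cr + 2 for (cx, cy), cr in zip(centers, radii)):
            centers.append((x, y))
            radii.append(r)
    return centers, radii


_STAGES = {
    "aggregation": _aggregation_stage,
    "frap": _frap_stage,
    "fdld": _fdld_stage,
    "fcs": _fcs_stage,
    "phase": _phase_stage,
}


def run_pipeline(config: ExperimentConfig, analysis: str = "all") -> dict[str, pd.DataFrame]:
    """Run one (or every) analysis stage and write its tables.

    Deterministic given (config, seed): rerunning with an equal config
    hash reproduces byte-identical CSVs. Each table carries the config
    hash; a ``manifest.json`` records the config, its hash and the tables
    written. A stage failure aborts with the stage name in the message.
    """
    names = list(ANALYSES) if analysis == "all" else [analysis]
    if any(n not in _STAGES for n in names):
        raise ValueError(f"unknown analysis {analysis!r}; choose from {ANALYSES} or 'all'")
    if "fcs" in names and not 0 < config.fcs_labeling_efficiency <= 1:
        raise ValueError("fcs stage: labelling efficiency must be in (0, 1]")

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    tables: dict[str, pd.DataFrame] = {}
    for name in names:
        try:
            stage_tables = _STAGES[name](config)
        except Exception as exc:
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
        for tname, df in stage_tables.items():
            df = df.copy()
            df["config_hash"] = cfg_hash
            df.to_csv(out_dir / f"{tname}.csv", index=False, float_format="%.8g")
            tables[tname] = df
    manifest = {
        "tool": "condkit 0.1.0",
        "config": config.to_dict(),
        "config_hash": cfg_hash,
        "seed": config.seed,
        "analyses": names,
        "tables": sorted(tables),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return tables
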