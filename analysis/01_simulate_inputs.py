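"""Generate one full synthetic dataset with ground truth.

Writes every input the downstream analyses consume — a droplet field
with a bright interface rim (TIFF + JSON truth sidecar), polarized image
pairs for the dichroism analysis, FRAP / ThT / turbidity trace tables
(long CSV) and FCS correlation curves — under results/synthetic/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from condkit import imaging, interface, synthgen

OUT = Path("results/synthetic")
OUT.mkdir(parents=True, exist_ok=True)
SEED = 1

# droplet field with a 2x interface rim, SNR 10
rng = np.random.default_rng(SEED)
from condkit.interface import _random_disks  # noqa: E402

centers, radii = _random_disks(rng, 8, (256, 256), r_range=(8, 18))
field = synthgen.DropletFieldTruth(
    centers, radii, dilute_level=20.0, dense_level=120.0, rim_level=240.0,
    noise_sd=10.0, shape=(256, 256), seed=SEED,
)
img = synthgen.gen_droplet_image(field)
interface.save_image_stack(img, OUT / "droplet_field.tif")
(OUT / "droplet_field.truth.json").write_text(json.dumps({
    "centers": centers, "radii": radii, "dense_level": 120.0,
    "rim_level": 240.0, "dilute_level": 20.0, "noise_sd": 10.0, "seed": SEED,
}))

# polarized pair: fibrils tangent to a condensate interface
ring = synthgen.gen_tangential_ring(30.0, 6.0, shape=(101, 101))
i_v, i_h = synthgen.gen_polarized_pair(ring, gain=100.0)
interface.save_image_stack(
    imaging.ImageStack(np.stack([i_v, i_h]), 0.1, channel="V,H"),
    OUT / "polarized_pair.tif",
)

# FRAP traces, four conditions x 10 droplets
t_frap = np.concatenate([np.linspace(-5, -1, 5), np.linspace(0, 30, 61)])
traces = []
for i, (cond, f) in enumerate({"homotypic_30min": 0.96, "heterotypic_30min": 0.91,
                               "homotypic_2h": 0.54, "heterotypic_2h": 0.91}.items()):
    for rep in range(10):
        g = np.random.default_rng(SEED * 100 + 20 * i + rep)
        truth = synthgen.FrapTruth(float(np.clip(g.normal(f, 0.04), 0, 1)), 5.0,
                                   noise_sd=10.0, seed=SEED * 200 + 20 * i + rep)
        tr = synthgen.gen_frap_trace(truth, t_frap)
        tr.condition, tr.replicate = cond, rep
        traces.append(tr)
interface.write_plate_long(traces, OUT / "frap_traces.csv")

# ThT curves at three protein concentrations (15-min sampling, 72 h)
t_tht = np.arange(0.0, 72.25, 0.25)
tht = []
for i, conc in enumerate((5.0, 10.0, 20.0)):
    for rep in range(3):
        truth = synthgen.ThtTruth(t_half_h=20.0, plateau=10 * conc, baseline=5.0,
                                  noise_sd=0.1 * conc, seed=SEED * 10 + 3 * i + rep)
        tr = synthgen.gen_tht_curve(truth, t_tht)
        tr.condition, tr.replicate = f"{conc:g}uM", rep
        tht.append(tr)
interface.write_plate_long(tht, OUT / "tht_traces.csv")

# turbidity dose-response and FCS curves
conc, od = synthgen.gen_dose_response(synthgen.DoseResponseTruth(noise_sd=0.005,
                                                                seed=SEED))
pd.DataFrame({"rna_ng_ul": conc, "od400": od}).to_csv(
    OUT / "turbidity_dose_response.csv", index=False)

rows = []
for rep in range(3):
    truth = synthgen.FcsTruth(5.0, 1e-4, 7.0, noise_sd=0.01, seed=SEED + rep)
    lag, g = synthgen.gen_fcs_curve(truth)
    rows.append(pd.DataFrame({"lag_s": lag, "G": g, "replicate": rep}))
pd.concat(rows).to_csv(OUT / "fcs_curves.csv", index=False)

print(f"wrote synthetic dataset with {field.shape} droplet field "
      f"({len(centers)} droplets), {len(traces)} FRAP traces, "
      f"{len(tht)} ThT traces, dose-response over {len(conc)} RNA levels "
      f"-> {OUT}")
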