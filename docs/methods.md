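# Methods

This note records the models behind each analysis stage, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical choices that affect results.

## Droplet segmentation and morphometrics

Condensates are bright, near-circular objects on a darker dilute phase.
Segmentation is deliberately simple and reproducible: global Otsu
threshold → hole filling → connected components → filters on
area-equivalent diameter (default minimum 1 µm) and circularity
(4πA/P² ≥ 0.7, Crofton perimeter). A guard rejects "foreground" whose
mean lies within 2 background standard deviations of the background
mean, so pure-noise frames yield zero droplets rather than speckle.
Components that fail the circularity filter are re-examined with a
distance-transform watershed (smoothed with σ = 1 px) so touching
droplets can be separated; isolated disks are never split, because they
pass the circularity test outright. Frames with more than 1 % of pixels
at the frame maximum are flagged saturated but still processed.

"Size" is the diameter of the area-equivalent circle, and the
surface-to-volume ratio treats each droplet as a sphere whose equatorial
section is the segmented circle: S/V = 3/r = 6/d in µm⁻¹. Both choices
reflect that a single confocal slice cannot distinguish a sphere from a
cap; the labels in the output say what was computed.

Radial profiles average intensity in concentric annuli of equal radial
width out to 1.5 R (15 bins by default — wide enough to resolve a rim
of 15–20 % relative width, narrow enough that single-pixel noise
averages out). Bins whose outer circle crosses the frame border are
flagged partial. Rim enrichment is the count-weighted mean over
r/R ∈ [0.8, 1.0] divided by the core mean over [0, 0.6]; with a rim
annulus narrower than the [0.8, 1.0] band the ratio underestimates the
true rim/core intensity contrast by the dilution of the band — the
score is a detector (ratio > 1 ⇒ interface enrichment), not an
estimator of the rim brightness itself.

## Polarized imaging and FDLD

The generator and the analysis share one physical model: excitation is
polarized (vertical or horizontal), detection is unpolarized, and the
absorption probability of an emitter whose transition dipole makes
angle θ with the horizontal axis is cos² of the angle to the
polarization. The oriented fraction (1 − iso) of emitters at a pixel
contributes sin²θ to the vertical image and cos²θ to the horizontal
one; the isotropic fraction splits evenly. This conserves intensity
exactly: I_V + I_H = gain·amplitude. A cos⁴ variant (polarized
detection co-aligned with excitation) is available but not default,
since only the excitation beam is modulated in the instrument this
emulates. Angles are axes modulo π, counterclockwise from the
horizontal image axis, in 0-based pixel coordinates with the origin
top-left (the angular position φ used below is computed with the image
y-axis flipped so that φ increases counterclockwise on screen).

The primary dichroism map is d = (I_V − I_H)/(I_V + I_H), bounded in
[−1, 1] and zero for unoriented pixels, which is what a diverging
blue–grey–yellow colour scale requires. The sum/difference ratio
(I_V + I_H)/(I_V − I_H) that some instruments print is also computed
(`literal_map`); it is unbounded and singular at I_V = I_H, so it is
stored for fidelity, never used for scoring. Pixels with total
intensity below a floor (default 3× the background noise sd estimated
from the sum image) are masked: the dichroism of near-dark pixels is
noise.

For a droplet interface, tangential fibrils give d(φ) = cos 2φ around
the ring and radial fibrils −cos 2φ. The interface orientation score
projects the measured annulus (default r/R ∈ [0.85, 1.05]) onto that
mode, normalized by the projection of the ideal field:
score = Σ d·cos 2φ / Σ cos² 2φ. It is +1 for perfectly tangential
fibrils, −1 for radial, 0 in expectation for random orientation, and is
reported missing when fewer than 25 % of annulus pixels are valid.

## FRAP

Traces are normalized to prebleach mean = 1 and first postbleach
point = 0, then the postbleach segment is fitted with
n(t) = f·(1 − e^(−t/τ_rec)). The single exponential is appropriate when
the bleached spot is small compared to the droplet (here one tenth of
the diameter), where recovery is dominated by a single exchange
timescale; no reference-bleach correction is applied by default (a
reference-trace hook exists). "% recovery" is the fitted plateau f, not
the last observed point, which makes 30 s windows that end before full
recovery usable; the endpoint value is reported alongside for
transparency. Mobile fractions outside [0, 1] are reported as estimated
with an `out_of_range` flag — clipping would bias group means. Group
comparisons use the two-sided Wilcoxon rank-sum test, computed exactly
(full enumeration) when both groups are small and tie-free.

## ThT and turbidity kinetics

ThT curves are normalized with their own extrema after an optional
3-point running median, so a single spiky sample cannot define "maximum
fluorescence". The half-time is the first upward crossing of 0.5 of the
normalized curve, linearly interpolated between the bracketing samples;
linear interpolation was chosen for reproducibility since any smooth
interpolant agrees to within the grid spacing on near-monotone rises.
Curves that never plateau are normalized to their final observed
maximum and flagged (`non_monotone_plateau` when the signal re-crosses
0.5). Half-time groups are compared with the tie-corrected
Kruskal–Wallis statistic; the p-value comes from the χ²(g−1) upper tail,
with an exact permutation option (full enumeration of group
assignments) used automatically at total n ≤ 12. The
concentration-independence check passes when p > 0.05.

The turbidity proxy of dense-phase volume is the maximum OD400 within
the first 30 minutes. Regime classification combines the RNA
concentration with droplet presence from imaging (not turbidity alone,
since turbidity cannot distinguish few large from many small droplets):
no RNA + droplets → regime 1, RNA + droplets → 2, RNA + no droplets →
3; no RNA and no droplets is a below-saturation sentinel.

## FCS

The autocorrelation model is one freely diffusing component without a
triplet term: G(τ) = (1/N)(1 + τ/τ_D)⁻¹(1 + τ/(k²τ_D))^(−1/2), plus a
constant offset in the fit. Weighted least squares uses σ ∝ G(τ) by
default (multiplicative correlation noise grows relative to the
shrinking signal at long lags); replicate-derived σ can be passed
instead. When protein curves are fitted, the structural parameter k is
fixed to the dye-calibration value — the aspect ratio is an instrument
property. Calibration uses w₀ = √(4·D_dye·τ_D) and
V_eff = π^{3/2}·k·w₀³; the default dye diffusion coefficient is
3.3 × 10⁻¹⁰ m²/s (a typical small organic fluorophore in water at room
temperature) and is a config input, since the calibration standard
varies between labs. Concentrations use N_A = 6.02214076 × 10²³ mol⁻¹;
the dilution factor (default 10, labelled:unlabelled mixing) and
labelling efficiency (default 0.64) are multiplicative corrections
C_total = C_labeled·dilution/efficiency. Monomer conversion is
1 − C_dilute/C_initial, clipped to [0, 1] for reporting with the raw
value kept under a flag.

## Stoichiometry

RNA chain molarity is (mass concentration in g/L)/mean MW, with a
default mean chain mass of 900 kDa and 306.2 Da per internal uridine
residue (so ≈ 2939 nt per chain). The charge ratio counts one negative
charge per nucleotide against a user-supplied count of positive charges
per protein molecule; there is deliberately no default for the protein
charge, because the count depends on convention (Arg+Lys only, His
inclusion, termini) and a silent default would fabricate biology. The
convention string is embedded in every output.

## Synthetic generators: what they do and do not emulate

Every generator is a pure function of a truth object carrying its own
seed (NumPy `default_rng`), so identical truth gives bit-identical
output. Defaults describe the study conditions the pipeline targets:
droplet fields at SNR ≈ 10 with diameters of a few µm at 0.1 µm/px;
interface rims at 15 % relative width; FRAP with recovery times of
seconds over a 30 s window and 5 s prebleach; sigmoidal ThT curves with
20 h half-times sampled every 15 min over 72 h (plus a biphasic variant
adding a slow post-rise drift); FCS with N ≈ 5, τ_D ≈ 10⁻⁴ s, k ≈ 7 and
1 % lognormal noise; a turbidity dome peaking at 12 ng/µl with
re-entrant suppression above ~50 ng/µl. The dome is
OD(c) = baseline + A(1 − e^(−c/r))e^(−c/s) with the rise scale r solved
(via c* = r·ln(1 + s/r)) so the peak sits exactly at the requested
location; s → ∞ degenerates to a monotone saturating curve.

Noise models: additive Gaussian for images and kinetic traces,
multiplicative lognormal for G(τ). Not emulated: optics (no PSF, so
segmentation fixtures have sharper edges than real confocal data),
photobleaching during FRAP recovery, 3-D structure, droplet motion or
fusion, baseline drift in plate readers, and detector afterpulsing in
FCS. Passing tests therefore demonstrate correctness of the estimators
under their stated models, not robustness to every real-data artefact;
the parameter-recovery suites (FRAP at 5 % noise, FCS at 1 %
correlation noise, segmentation at SNR 10) probe realistic noise levels
but idealized structure.

## Problem sizes and numerical choices

The test suite and the acceptance script use 50 FCS curves, 200 FRAP
simulations, 12-droplet 512² segmentation fields and full permutation
enumeration only below ~2 × 10⁵ assignments — sizes at which every
Monte-Carlo criterion is stable to reruns while the whole pipeline
executes in seconds. Fits use `scipy.optimize.curve_fit` with positivity
bounds where physical (τ_rec, N, τ_D, k > 1); non-convergence and
parameters at bounds are flagged, never silently clipped. Ties in exact
rank tests fall back to the large-sample method. Degenerate inputs have
defined behaviour throughout: flat ThT curves raise a typed error,
identical rank-test groups report p = 1, empty droplet sets produce an
explicit empty summary.

## Known limitations

The interface orientation score assumes circular interfaces; deformed
droplets need a local-normal generalization. The rim-enrichment ratio
depends on the fixed band definition and on segmentation accuracy of R.
The single-exponential FRAP model underestimates mobility when the
bleach spot is not small relative to the droplet. The charge-ratio
calculator is a bookkeeping device under its stated convention, not a
polyelectrolyte theory.
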