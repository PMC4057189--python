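# Methods

## Scope and model

`qctlung` studies how tube-current (mAs) reduction affects quantitative
CT lung densitometry. Because no raw animal scans are available, the
package pairs the analysis code (densitometry, agreement statistics,
dosimetry) with a synthetic phantom generator that reproduces the
*study conditions*: healthy and ARDS lung compositions, the measured
noise levels at the four studied mAs values, and the paired-scan design
(two consecutive scans of the same subject at different mAs).

### Densitometry

A voxel at HU value h contributes tissue mass
`voxel_volume_ml × (clamp(h, −1000, +200) + 1000)/1000` grams — the
standard convention that density varies linearly from 0 g/ml at pure
gas (−1000 HU) to 1 g/ml at water (0 HU). Compartment membership uses
the HU value rounded to the nearest integer (ties away from zero), so
the printed integer thresholds (e.g. "−900 to −501") are honoured
exactly; equivalently the real line splits at −900.5, −500.5, −100.5.
Voxels rounding above +200 HU are excluded from volume, mass and
fractions but tallied (count and mass), because this exclusion is the
mechanism behind the apparent volume loss at ultra-low dose. Voxels
below −1000 HU are clamped to −1000 (zero mass) rather than excluded;
this is a deliberate design choice for a quantity the conventions leave
open. A configuration switch (`default_scheme(exclusion_hu=500)`)
raises the exclusion bound, extending the nonaerated compartment.
Conservation holds exactly: compartment masses plus excluded mass equal
the mass computed without the exclusion.

The mass-frequency histogram uses 24 bins of 50 HU from −1000 to +200,
aligned with the compartment boundaries, as percentages of included
mass.

### Phantom

The phantom is an elliptic soft-tissue body (default +40 HU), two
ellipsoidal lung fields, and a uniform cylindrical aorta insert
(+45 HU) used as the noise ROI. Default grid 128×128×64 voxels at
3×3×5 mm gives ≈3 L lungs (≈66 000 voxels) and an aorta ROI of ≈13 000
voxels — large enough that a single scan estimates an injected σ to
within a percent — while keeping a full six-arm study around one
minute of CPU. Geometry is configurable and affects no contracted
quantity.

Lung voxels realise a target *mass* composition. Since mass per voxel
scales with density ρc = (HUc+1000)/1000, compartment c receives a
voxel-number share proportional to fc/ρc (largest-remainder rounding).
Within a compartment, HU values are an evenly spaced grid over a
symmetric uniform band, so the realised compartment mean equals the
nominal mean exactly and realised mass fractions match the targets to
well under 0.1 percentage points (the contract is 0.5).

Compartment bands: hyperinflated [−980, −920], normally aerated
[−850, −550], poorly aerated [−450, −150], nonaerated [0, 100] HU.
Two considerations fix these bands. First, they stay ≥ 50 HU clear of
every compartment boundary: with ≈37 HU noise (15 mAs) essentially no
mass crosses a boundary, while ≈74 HU noise (7.5 mAs) moves several
percent — exactly the dose-agreement pattern the study conditions
require (biases < 1 point down to 15 mAs, visible shifts only at
7.5 mAs). Second, the nonaerated band sits at 0–100 HU, close enough
to the +200 HU exclusion bound that heavy noise pushes part of that
mass out of the computation, reproducing the volume-underestimation
mechanism.

Default compositions are the two study arms' mean mass fractions
(healthy 0.6/86.6/11.5/1.4, ARDS 0.0/9.1/27.3/63.5 %), renormalised to
sum exactly to 100 (the printed, rounded values sum to 100.1 and 99.9).

Spatial structure: healthy phantoms mix compartments uniformly; ARDS
phantoms sort lung voxels by gravity coordinate plus logistic jitter
(scale 15 mm) and assign compartments from least to most dense, giving
dependent consolidation with a sigmoid transition. Only the mass
fractions are contracted; the spatial map is a plausible invention.

### Scan simulation and the noise model

A scan is truth + i.i.d. zero-mean Gaussian HU noise applied everywhere
(lung, body, aorta), with SD σ(mAs). Reconstruction-filter correlation
is out of scope; an optional isotropic Gaussian smoothing of the noise
field (variance-preserving) can mimic it qualitatively.

σ(mAs) follows √(a/mAs + b): quantum noise falling as 1/√mAs plus an
electronic floor. The four measured points (10.0, 15.9, 37.5, 73.8 HU
at 140, 60, 15, 7.5 mAs) are, however, *steeper* than any such law can
be — with a, b ≥ 0 the ratio σ(7.5)/σ(140) is bounded by
√(140/7.5) ≈ 4.3, while the measurements give 7.4. (The measured
7.5-mAs noise exceeding the quantum-law prediction is a real feature of
the data; its cause is not established.) The model therefore carries
the measured points as an exact lookup that takes precedence over the
parametric law: `fit_noise_model` performs the non-negative least
squares calibration of (a, b) on σ² and reports per-point residuals
honestly, while `noise_sigma` returns measured values at tabulated mAs
and the fitted law elsewhere. The study pipeline always runs at the
measured (lookup) noise levels — they *are* the study conditions.

### Segmentation

Automatic segmentation targets high-contrast (healthy) volumes:
threshold at −200 HU, remove components touching the volume border
(exterior air), drop components below a minimum volume (default
100 ml), binary closing (2 iterations, 6-connected structure) plus hole
filling. On healthy phantoms this achieves Dice ≥ 0.99 against ground
truth at every studied noise level and never captures the aorta. On
consolidated (ARDS) phantoms the dense tissue is invisible to the
threshold; when more than 25 % of the segmented voxels are denser than
−500 HU a `ConsolidationWarning` asks for a manually drawn mask (the
25 % cut separates the two conditions with a wide margin: healthy scans
stay near 5–11 % even at the highest noise, ARDS scans exceed 50 %).
Robust clinical segmentation of consolidated lungs is a non-goal.

### Agreement statistics

Differences are reference (60 mAs) minus compared throughout — the
orientation that matches the published sign conventions. Bland–Altman:
bias, SD (n−1), limits of agreement at ±1.96 SD (so bias is exactly the
LOA midpoint), proportional-bias regression of difference on pair mean,
and r² of compared on reference (direction-invariant for simple OLS).
Paired tests select between the paired t-test and Wilcoxon signed-rank
by a Shapiro–Wilk check on the differences at α = 0.05 (the "as
appropriate" rule made explicit); all-zero differences return p = 1
flagged degenerate. Histogram comparisons run the same paired test per
50-HU bin with no multiple-testing correction, matching the original
presentation. The dose/noise summary uses one-way ANOVA with a rank
transform when any group fails normality or Levene's test. Pairs are
treated as independent (no per-subject clustering adjustment), again
matching the original analysis — replicated, not endorsed.

### Dosimetry

CTDIvol = c·mAs (exactly linear at fixed kVp/pitch; default
c = 9.2/60 mGy/mAs anchored at the reference acquisition — the printed
per-mAs ratios scatter within ±5 % of this), DLP = CTDIvol × scan
length (phantom z-extent for simulated studies), E = DLP × k with
k = 0.0204 mSv/(mGy·cm) calibrated from the printed E/DLP ratios of the
three lower-dose settings (the chest conversion coefficient itself is
not published; the calibrated value reproduces the high-dose row to
0.1 mSv). Dose reductions are reported as integer percentages. Image
noise is estimated as the mean per-scan SD of HU in the aorta ROI
(n−1 denominator).

### Study pipeline

Per pair: one phantom is sampled from the condition's base spec —
compartment targets jittered with the published between-animal SDs
(healthy 1.1/2.9/3.4/0.5, ARDS 0/9.5/13.7/21.4 points, clipped at zero
and renormalised) and lung size scaled with CV 0.1 per axis (volume
CV ≈ 0.3, matching the published volume spreads). Without this
between-subject variability the pair-r² and proportional-bias
regressions would be meaningless. Both scans of a pair share the truth
volume (one breath-hold) with independent noise draws, applied in
randomized order; the order and every derived seed are logged. All
randomness flows from the study seed through a spawned seed tree, so a
given configuration produces byte-identical report files.

## Problem sizes

Default desk-scale sizes, chosen once: phantom grid 128×128×64
(1.05 M voxels), 15 pairs per arm for the six-arm replication study
(≈ 180 simulated scans, ≈ 1 min), 1.05 M voxels for the analytic
convolution-oracle comparison, 10 scans for noise estimation. The test
suite runs in about half a minute.

## What the phantom does and does not show

Passing tests demonstrate that the *analysis chain* behaves correctly
under controlled noise: exact recovery at σ = 0, histograms matching
the analytic Gaussian convolution of the truth, and the qualitative
dose-agreement pattern (sub-point biases at 140/15 mAs, the
poorly-aerated/nonaerated/volume shifts at 7.5 mAs with widened limits
of agreement). They do not validate quantitative accuracy on real
scans: real noise is spatially correlated by the reconstruction filter,
real lungs have continuous (not banded) density distributions, real
ARDS ROIs are drawn manually with inter-operator variability, and
beam-hardening/kVp effects are absent. The phantom's within-compartment
bands in particular control the *magnitude* of cross-boundary leakage;
real magnitudes depend on the true local density spectrum near each
threshold.

## Known limitations

- i.i.d. Gaussian noise; no sinogram-level simulation, beam hardening
  or kVp-dependent calibration.
- The parametric σ(mAs) law cannot reproduce the full measured noise
  range (see above); off-table extrapolation below ~15 mAs will
  underpredict noise.
- Automatic segmentation is intentionally simple and unsuitable for
  consolidated lungs.
- No regional (lobe/ROI) analysis; no repeated-measures modelling of
  multiple pairs per subject.
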