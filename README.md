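# qctlung

Quantitative CT (qCT) lung densitometry with low-dose noise simulation
and paired-agreement analysis.

Serial quantitative CT is a powerful way to characterise lung aeration
in acute respiratory distress syndrome (ARDS) and to guide mechanical
ventilation, but repeated scanning accumulates radiation dose. Dose
scales linearly with the tube current–time product (mAs), while lower
mAs means higher image noise — and noise, convolved with the lung's
density distribution, can shift measured tissue between aeration
compartments. This package implements the full analysis loop needed to
study that trade-off at the desk: digital chest phantoms with known
aeration composition, scan simulation at any mAs, lung segmentation,
compartment densitometry, Bland–Altman agreement statistics, and
CTDIvol/DLP/effective-dose bookkeeping. It is aimed at imaging
researchers and physicists who want a reproducible, fully synthetic
testbed for low-dose qCT protocols.

## The model

Every voxel's density in Hounsfield units (HU) determines its tissue
fraction linearly: pure gas at −1000 HU, water-equivalent tissue at
0 HU,

```
tissue fraction = (HU + 1000) / 1000,     mass = voxel volume × tissue fraction
```

Lung tissue is decomposed into four compartments by the usual aeration
thresholds — hyperinflated (−1000 to −901 HU), normally aerated (−900
to −501), poorly aerated (−500 to −101) and nonaerated (−100 to +200) —
with voxels above +200 HU excluded from the computation (but tallied),
and the mass-frequency distribution is reported in 50-HU bins.

Image noise is modelled as zero-mean Gaussian HU noise whose SD follows
σ(mAs) = √(a/mAs + b) (quantum noise plus an electronic floor); a
lookup table of measured (mAs, σ) points — defaults 10.0/15.9/37.5/73.8
HU at 140/60/15/7.5 mAs — takes precedence when present. Agreement
between doses is quantified per Bland–Altman: bias = mean(reference −
compared), limits of agreement = bias ± 1.96·SD of the differences,
with proportional-bias regression and automatic paired-t/Wilcoxon
selection. Dose is tracked as CTDIvol = c·mAs, DLP = CTDIvol × scan
length, and effective dose E = DLP × k (DLP method, k = 0.0204
mSv/(mGy·cm) by default).

## Worked example

Simulate an ARDS phantom, scan it at the 60-mAs reference and at
7.5 mAs, and quantify both scans on the true lung mask:

```python
from qctlung import *

phantom = make_phantom(PhantomSpec(condition="ARDS",
                                   target_fractions=dict(ARDS_MASS_FRACTIONS), seed=7))
noise = NoiseModel.from_table()          # measured sigma per mAs
for mas, seed in ((60, 1), (7.5, 2)):
    scan = simulate_scan(phantom, AcquisitionSettings(mAs=mas), noise, seed=seed)
    r = quantify(scan, phantom.lung_mask)
    fr = r.compartment_fraction_pct
    print(f"{mas} mAs: volume {r.total_volume_ml:.0f} ml, mass {r.total_mass_g:.0f} g, "
          f"poorly {fr['poorly_aerated']:.1f}%, nonaerated {fr['nonaerated']:.1f}%, "
          f"excluded {r.excluded_voxels} voxels")
```

prints

```
60 mAs: volume 2983 ml, mass 2296 g, poorly 27.3%, nonaerated 63.6%, excluded 0 voxels
7.5 mAs: volume 2942 ml, mass 2246 g, poorly 28.0%, nonaerated 62.6%, excluded 912 voxels
```

At 7.5 mAs the injected noise (σ = 73.8 HU) smears the nonaerated peak:
part of its mass crosses down into the poorly aerated compartment
(27.3 → 28.0 %) and part crosses the +200 HU exclusion bound, which is
why total volume and mass shrink and the nonaerated fraction falls —
the characteristic ultra-low-dose artefact. At 140 or 15 mAs the same
comparison leaves every compartment bias below one percentage point.

The same workflow is available from the shell:

```sh
qct simulate --condition healthy --mas 60 --seed 7 --out scan.nii.gz
qct segment scan.nii.gz --out mask.nii.gz
qct analyze scan.nii.gz --mask mask.nii.gz --out result.json
qct dose --mas 60 --calib 0.1533 --length 39.4
qct study --config study.yaml
```

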