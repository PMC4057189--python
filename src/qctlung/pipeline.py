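"""End-to-end paired-dose study orchestration.

A study consists of arms: (condition, number of scan pairs, compared
mAs).  For each pair one ground-truth phantom is sampled (between-
subject variability in composition and lung size), then scanned twice
under independent noise draws -- once at the 60-mAs reference and once
at the compared mAs, in randomized order -- and both scans are
quantified with the phantom's true lung mask (the stand-in for the
study's manually drawn regions of interest).  Per (condition, compared
mAs) the pipeline emits the agreement table, the per-bin histogram
comparison, and a dose/noise summary across all mAs levels with one-way
ANOVA per row.

All randomness derives from the study seed through a spawned seed tree,
so identical configurations produce byte-identical report files.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dosimetry
from .agreement import AnovaResult, compare_histograms, compare_pairs, group_anova
from .lungmask import LungMask
from .phantom import (
    ARDS_MASS_FRACTIONS,
    HEALTHY_MASS_FRACTIONS,
    AcquisitionSettings,
    NoiseModel,
    Phantom,
    PhantomSpec,
    make_phantom,
    perturb_spec,
    simulate_scan,
)
from .qct import histogram_50hu, quantify
from .volume import CTVolume, load_volume, save_volume

__all__ = [
    "StudyArm",
    "StudyConfig",
    "StudyReport",
    "run_paired_study",
    "write_report",
    "scan_count",
    "load_volume",
    "save_volume",
    "save_result",
    "REFERENCE_MAS",
    "CONDITION_FRACTION_SD",
]

logger = logging.getLogger(__name__)

#: Reference tube current-time product; every pair couples this with a
#: higher or lower compared value.
REFERENCE_MAS = 60.0

#: Between-subject SD of the compartment mass fractions (percentage
#: points) used when sampling per-pair phantoms, per condition.  Values
#: follow the spread reported for the two study arms.
CONDITION_FRACTION_SD: dict[str, dict[str, float]] = {
    "healthy": {"hyperinflated": 1.1, "normally_aerated": 2.9, "poorly_aerated": 3.4, "nonaerated": 0.5},
    "ARDS": {"hyperinflated": 0.0, "normally_aerated": 9.5, "poorly_aerated": 13.7, "nonaerated": 21.4},
}

_CONDITION_FRACTIONS = {"healthy": HEALTHY_MASS_FRACTIONS, "ARDS": ARDS_MASS_FRACTIONS}


@dataclass(frozen=True)
class StudyArm:
    condition: str  # "healthy" | "ARDS"
    n_pairs: int
    mAs_alt: float

    def __post_init__(self) -> None:
        if self.condition not in _CONDITION_FRACTIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.n_pairs < 2:
            raise ValueError("each arm needs at least 2 pairs")
        if self.mAs_alt <= 0:
            raise ValueError("compared mAs must be positive")


@dataclass
class StudyConfig:
    """Configuration of a paired-dose study."""

    arms: list[StudyArm]
    seed: int = 0
    mAs_ref: float = REFERENCE_MAS
    noise_model: NoiseModel = field(default_factory=NoiseModel.from_table)
    phantom_specs: dict[str, PhantomSpec] | None = None
    size_cv: float = 0.1
    output_dir: str | os.PathLike | None = None
    make_figures: bool = False

    def __post_init__(self) -> None:
        if not self.arms:
            raise ValueError("study needs at least one arm")
        if self.mAs_ref != REFERENCE_MAS:
            raise ValueError(f"the reference mAs is fixed at {REFERENCE_MAS}")

    def base_spec(self, condition: str) -> PhantomSpec:
        if self.phantom_specs and condition in self.phantom_specs:
            return self.phantom_specs[condition]
        return PhantomSpec(condition=condition, target_fractions=dict(_CONDITION_FRACTIONS[condition]))

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        arms = [StudyArm(a["condition"], int(a["n_pairs"]), float(a["mAs_alt"])) for a in raw["arms"]]
        kwargs = {}
        if "noise_table" in raw:
            kwargs["noise_model"] = NoiseModel.from_table({float(k): float(v) for k, v in raw["noise_table"].items()})
        for key in ("seed", "size_cv", "output_dir", "make_figures"):
            if key in raw:
                kwargs[key] = raw[key]
        if "phantom" in raw:
            kwargs["phantom_specs"] = {
                cond: PhantomSpec(condition=cond, **{k: v for k, v in spec.items()})
                for cond, spec in raw["phantom"].items()
            }
        return cls(arms=arms, **kwargs)


@dataclass
class StudyReport:
    """All tables produced by one study run."""

    agreement_tables: dict[tuple[str, float], pd.DataFrame]
    histogram_tests: dict[tuple[str, float], pd.DataFrame]
    dose_table: pd.DataFrame
    noise_by_mas: dict[float, list[float]]
    scan_log: list[dict]
    seed: int


def scan_count(pairs_per_comparison) -> int:
    """Total number of CT scans implied by paired comparisons (two scans
    per pair)."""
    return 2 * int(sum(pairs_per_comparison))


def run_paired_study(config: StudyConfig) -> StudyReport:
    """Simulate and analyse the full paired-mAs study.

    Per pair: sample a phantom, scan it at the reference and compared
    mAs in randomized order with independent noise draws, quantify both
    scans on the true lung mask, and measure aortic noise on each scan.
    Aggregates agreement tables, histogram tests and the dose/noise
    summary (with ANOVA across mAs levels).
    """
    root_ss = np.random.SeedSequence(config.seed)
    arm_seeds = root_ss.spawn(len(config.arms))

    results: dict[tuple[str, float], list] = {}
    histograms: dict[tuple[str, float], list] = {}
    noise_by_mas: dict[float, list[float]] = {}
    scan_lengths: dict[float, list[float]] = {}
    scan_log: list[dict] = []

    for arm, arm_ss in zip(config.arms, arm_seeds):
        key = (arm.condition, arm.mAs_alt)
        results.setdefault(key, [])
        histograms.setdefault(key, [])
        base = config.base_spec(arm.condition)
        fraction_sd = CONDITION_FRACTION_SD[arm.condition]
        t0 = time.perf_counter()
        for pair_idx, pair_ss in enumerate(arm_ss.spawn(arm.n_pairs)):
            rng = np.random.default_rng(pair_ss)
            spec = perturb_spec(base, rng, fraction_sd=fraction_sd, size_cv=config.size_cv)
            try:
                phantom = make_phantom(spec)
                order = rng.permutation([config.mAs_ref, arm.mAs_alt])
                scans = {}
                for mas in order:
                    scan_seed = int(rng.integers(0, 2**31 - 1))
                    scans[mas] = simulate_scan(
                        phantom, AcquisitionSettings(mAs=mas), config.noise_model, seed=scan_seed
                    )
                    noise_by_mas.setdefault(float(mas), []).append(
                        dosimetry.estimate_noise([scans[mas]], phantom.aorta_mask)
                    )
                    scan_lengths.setdefault(float(mas), []).append(_scan_length_cm(phantom))
                    scan_log.append(
                        {
                            "condition": arm.condition,
                            "mAs_alt": arm.mAs_alt,
                            "pair": pair_idx,
                            "scan_order": int(np.where(order == mas)[0][0]),
                            "mAs": float(mas),
                            "seed": scan_seed,
                        }
                    )
                mask = LungMask(phantom.lung_mask, source="manual", voxel_spacing=spec.voxel_spacing)
                res_pair = tuple(quantify(scans[m], mask) for m in (config.mAs_ref, arm.mAs_alt))
                hist_pair = tuple(histogram_50hu(scans[m], mask) for m in (config.mAs_ref, arm.mAs_alt))
            except Exception:
                logger.exception(
                    "study aborted at arm (%s, %.1f mAs), pair %d", arm.condition, arm.mAs_alt, pair_idx
                )
                raise
            results[key].append(res_pair)
            histograms[key].append(hist_pair)
        logger.info(
            "arm (%s, %.1f mAs): %d pairs in %.1f s",
            arm.condition, arm.mAs_alt, arm.n_pairs, time.perf_counter() - t0,
        )

    agreement_tables = {k: compare_pairs(v) for k, v in results.items()}
    histogram_tests = {
        k: compare_histograms(v) for k, v in histograms.items() if len(v) >= 3
    }
    dose_table = _dose_noise_table(noise_by_mas, scan_lengths)

    report = StudyReport(
        agreement_tables=agreement_tables,
        histogram_tests=histogram_tests,
        dose_table=dose_table,
        noise_by_mas=noise_by_mas,
        scan_log=scan_log,
        seed=config.seed,
    )
    if config.output_dir is not None:
        write_report(report, config.output_dir, make_figures=config.make_figures)
    return report


def _scan_length_cm(phantom: Phantom) -> float:
    shape = phantom.truth_volume.shape
    return shape[2] * phantom.truth_volume.spacing[2] / 10.0


def _dose_noise_table(noise_by_mas, scan_lengths) -> pd.DataFrame:
    """Dose/noise summary: CTDIvol, DLP, E and measured image noise per
    mAs level, with a one-way ANOVA p-value per row across levels."""
    mas_levels = sorted(noise_by_mas, reverse=True)
    rows = {"CTDIvol (mGy)": {}, "DLP (mGy.cm)": {}, "E (mSv)": {}, "Image noise (HU)": {}}
    samples: dict[str, list[np.ndarray]] = {k: [] for k in rows}
    for mas in mas_levels:
        lengths = np.asarray(scan_lengths[mas])
        ctdi = np.full_like(lengths, dosimetry.ctdi_vol(mas))
        dlp = ctdi * lengths
        eff = dlp * dosimetry.DEFAULT_K_COEFF
        noise = np.asarray(noise_by_mas[mas])
        for name, vals in (("CTDIvol (mGy)", ctdi), ("DLP (mGy.cm)", dlp), ("E (mSv)", eff), ("Image noise (HU)", noise)):
            rows[name][mas] = (vals.mean(), vals.std(ddof=1) if len(vals) > 1 else 0.0)
            samples[name].append(vals)

    records = []
    for name in rows:
        rec = {"measure": name}
        for mas in mas_levels:
            mean, sd = rows[name][mas]
            rec[f"mean_{mas:g}"] = mean
            rec[f"sd_{mas:g}"] = sd
        if len(mas_levels) >= 2 and all(len(s) >= 2 for s in samples[name]):
            anova: AnovaResult = group_anova(samples[name])
            rec["anova_p"] = anova.p
        else:
            rec["anova_p"] = float("nan")
        records.append(rec)
    return pd.DataFrame(records).set_index("measure")


def write_report(report: StudyReport, outdir: str | os.PathLike, make_figures: bool = False) -> None:
    """Write report tables as CSV, the scan log and summary as JSON, and
    (optionally) Bland-Altman / histogram figures.  Output is
    deterministic: same report, same bytes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    for (condition, mas_alt), table in sorted(report.agreement_tables.items()):
        table.to_csv(outdir / f"agreement_{condition}_60_vs_{mas_alt:g}.csv", float_format="%.6g")
    for (condition, mas_alt), table in sorted(report.histogram_tests.items()):
        table.to_csv(outdir / f"histogram_tests_{condition}_60_vs_{mas_alt:g}.csv", float_format="%.6g")
    report.dose_table.to_csv(outdir / "dose_noise.csv", float_format="%.6g")

    with open(outdir / "scan_log.json", "w") as fh:
        json.dump({"seed": report.seed, "scans": report.scan_log}, fh, indent=1, sort_keys=True)

    if make_figures:
        _write_figures(report, outdir)


def _write_figures(report: StudyReport, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for (condition, mas_alt), table in sorted(report.histogram_tests.items()):
        fig, ax = plt.subplots(figsize=(8, 4))
        x = np.asarray(table.index, dtype=float)
        w = 20.0
        ax.bar(x - w / 2, table["mean_ref"], width=w, label="60 mAs")
        ax.bar(x + w / 2, table["mean_alt"], width=w, label=f"{mas_alt:g} mAs")
        for xi, sig in zip(x, table["significant"]):
            if sig:
                ax.annotate("*", (xi, float(max(table.loc[xi, "mean_ref"], table.loc[xi, "mean_alt"]))))
        ax.set_xlabel("HU (50-HU bins)")
        ax.set_ylabel("% of tissue mass")
        ax.set_title(f"{condition}: 60 vs {mas_alt:g} mAs")
        ax.legend()
        fig.tight_layout()
        fig.savefig(outdir / f"histogram_{condition}_60_vs_{mas_alt:g}.png", dpi=120)
        plt.close(fig)


def save_result(result, path: str | os.PathLike) -> None:
    """Serialise a quantitative result (or any object with ``as_dict``)
    as JSON."""
    payload = result.as_dict() if hasattr(result, "as_dict") else result
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
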