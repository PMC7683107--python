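"""End-to-end pipeline: cohort -> candidate regions -> features -> screening
-> classifier evaluation, for the three pairings.

* ``lesion_vs_mirror`` — lesion regions vs their contralateral mirrors
  (paired rows; with the reference cohort sizes, 38 + 38 = 76 regions).
* ``normal_vs_mirror`` — control-brain regions vs their mirrors
  (54 + 54 = 108 regions), the negative control: the two sides of a healthy
  brain should not be separable.
* ``lesion_vs_normal`` — lesion regions vs control regions at matched
  positions, one slice per control subject (38 + 18 = 56 regions, unpaired).

Midlines are always estimated from the images; generator ground truth is
never consulted here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluate import CLASSIFIER_FAMILIES, CVConfig, run_three_experiments
from .features import ExtractionConfig, extract_all, feature_registry
from .infogain import DEFAULT_THRESHOLDS, LabeledFeatureTable
from .io import dump_json
from .midline import CandidateRegion, make_candidate_pairs
from .phantom import LesionSpec, PhantomSpec, SyntheticSubject, generate_cohort

log = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "build_candidate_regions",
    "extract_feature_table",
    "pairing_tables",
    "run_all",
]

PAIRINGS = ("lesion_vs_mirror", "normal_vs_mirror", "lesion_vs_normal")


@dataclass(frozen=True)
class PipelineConfig:
    n_lesion: int = 38
    n_normal: int = 18
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    lesion: LesionSpec = field(default_factory=LesionSpec)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    classifiers: tuple[str, ...] = CLASSIFIER_FAMILIES
    k_bins: int = 10
    cv_folds: int = 4
    cv_repeats: int = 100
    paired_split: bool = True


def build_candidate_regions(cohort: list[SyntheticSubject]) -> list[CandidateRegion]:
    """Estimate every slice's midline and emit all candidate regions."""
    regions: list[CandidateRegion] = []
    for subject in cohort:
        for a, b in make_candidate_pairs(subject):
            regions.extend((a, b))
    return regions


def extract_feature_table(
    regions: list[CandidateRegion], config: ExtractionConfig | None = None
) -> pd.DataFrame:
    """Regions x features DataFrame with subject_id / pair_id / label columns."""
    config = config if config is not None else ExtractionConfig()
    registry = feature_registry(config)
    rows = []
    for region in regions:
        vec = extract_all(region.image, region.mask, config)
        row = {"subject_id": region.subject_id, "pair_id": region.pair_id, "label": region.label}
        row.update({k: vec[k] for k in registry})
        rows.append(row)
    return pd.DataFrame(rows)


def pairing_tables(table: pd.DataFrame) -> dict[str, LabeledFeatureTable]:
    """Split the extracted table into the three pairing tables."""
    meta = ["subject_id", "pair_id", "label"]
    feats = [c for c in table.columns if c not in meta]

    def build(df: pd.DataFrame, positive: str) -> LabeledFeatureTable:
        return LabeledFeatureTable(
            features=df[feats].reset_index(drop=True),
            y=(df["label"] == positive).astype(int).to_numpy(),
            pairing_id=df["pair_id"].to_numpy(),
        )

    a = table[table["label"].isin(["lesion", "mirror"])]
    b = table[table["label"].isin(["normal", "normal_mirror"])]
    # pairing C: lesion regions vs control regions, one slice per control subject
    lesions = table[table["label"] == "lesion"]
    normals = table[table["label"] == "normal"]
    first_slice = normals.groupby("subject_id", sort=True).head(1)
    c = pd.concat([lesions, first_slice], ignore_index=True)
    return {
        "lesion_vs_mirror": build(a, "lesion"),
        "normal_vs_mirror": build(b, "normal"),
        "lesion_vs_normal": build(c, "lesion"),
    }


def run_all(
    seed: int,
    out_dir: str | Path | None = None,
    config: PipelineConfig | None = None,
) -> dict:
    """Run the whole analysis and return (and optionally write) the report.

    Deterministic: the result is a pure function of ``seed`` and ``config``.
    """
    config = config if config is not None else PipelineConfig()
    root = np.random.SeedSequence(seed)
    cohort_seed, cv_seed = (int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(2))

    log.info("generating cohort (%d lesion, %d control subjects)", config.n_lesion, config.n_normal)
    cohort = generate_cohort(
        config.n_lesion, config.n_normal, spec=config.phantom,
        lesion_spec=config.lesion, seed=cohort_seed,
    )
    log.info("estimating midlines and building candidate regions")
    regions = build_candidate_regions(cohort)
    log.info("extracting %d features for %d regions", len(feature_registry(config.extraction)), len(regions))
    table = extract_feature_table(regions, config.extraction)
    tables = pairing_tables(table)

    cv_config = CVConfig(
        folds=config.cv_folds, repeats=config.cv_repeats,
        seed=cv_seed, paired_split=config.paired_split,
    )
    log.info("running the classifier panel")
    results = run_three_experiments(
        tables, thresholds=config.thresholds, classifiers=config.classifiers,
        config=cv_config, k_bins=config.k_bins,
    )

    report = {"seed": seed, "n_features": len(feature_registry(config.extraction)), "pairings": {}}
    for name in PAIRINGS:
        ig = results[name]["ig"]
        report["pairings"][name] = {
            "n_regions": int(tables[name].n),
            "ig_counts_by_threshold": {str(t): int(c) for t, c in ig.counts_by_threshold.items()},
            "cv": results[name]["report"].to_dict(),
        }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        dump_json(report, out_dir / "report.json")
        (out_dir / "report.txt").write_text(format_report(report))
    return report


def format_report(report: dict) -> str:
    """Human-readable threshold-count and accuracy tables."""
    lines = [f"strokesep separability report (seed {report['seed']}, "
             f"{report['n_features']} features)", ""]
    lines.append("Feature counts by information-gain threshold (strict >):")
    for name, p in report["pairings"].items():
        counts = ", ".join(f">{t}: {c}" for t, c in sorted(p["ig_counts_by_threshold"].items()))
        lines.append(f"  {name} (n={p['n_regions']}): {counts}")
    lines.append("")
    for name, p in report["pairings"].items():
        cv = p["cv"]
        lines.append(f"{name}: accuracy by classifier x threshold")
        thresholds = sorted(cv["threshold_averages"], key=float)
        header = "  {:<26}".format("classifier") + "".join(f"{t:>9}" for t in thresholds)
        lines.append(header)
        for clf, row in cv["grid"].items():
            lines.append("  {:<26}".format(clf) + "".join(f"{row[t]:>9.4f}" for t in thresholds))
        lines.append("  {:<26}".format("average") + "".join(
            f"{cv['threshold_averages'][t]:>9.4f}" for t in thresholds))
        lines.append(
            f"  overall average (thresholds >= 0.1): {cv['overall_average']:.4f}; "
            f"best {cv['best_accuracy']:.4f} ({cv['best_classifier']} @ IG > {cv['best_threshold']})"
        )
        lines.append("")
    lines.append(report["pairings"][next(iter(report["pairings"]))]["cv"]["note"])
    return "\n".join(lines) + "\n"
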