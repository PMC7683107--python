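#!/usr/bin/env python
"""Screen features by information gain for the three pairings.

For each pairing (lesion vs mirror, normal vs mirror, lesion vs normal) every
feature is discretized by equal-frequency binning and scored by
IG(X, Y) = H(Y) - H(Y|X); the table of how many features survive each
threshold (strict inequality) goes to results/, the full per-feature ranking
to scratch/.
"""

import argparse
import json
import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from strokesep.features import TRANSFORM_KINDS
from strokesep.infogain import screen_features
from strokesep.pipeline import pairing_tables

THRESHOLDS = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)


def split_name(feature: str) -> tuple[str, str]:
    """'wavelet_LL_glcm_Contrast' -> ('wavelet_LL', 'glcm')."""
    transform = max(
        (t for t in TRANSFORM_KINDS if feature.startswith(t + "_")), key=len
    )
    return transform, feature[len(transform) + 1 :].split("_", 1)[0]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--features-csv", type=Path, default=ROOT / "scratch" / "features.csv")
    ap.add_argument("--k-bins", type=int, default=10)
    args = ap.parse_args()

    table = pd.read_csv(args.features_csv)
    tables = pairing_tables(table)

    counts = {}
    rankings = []
    for pairing, t in tables.items():
        res = screen_features(t, thresholds=THRESHOLDS, k_bins=args.k_bins)
        counts[pairing] = {
            "n_regions": int(t.n),
            "h_y_bits": round(res.h_y, 4),
            "counts_by_threshold": {str(k): v for k, v in res.counts_by_threshold.items()},
            "top5": [
                {"feature": f, "ig_bits": round(float(res.ig[f]), 4)}
                for f in res.ordering[:5]
            ],
        }
        ranked = res.ig.sort_values(ascending=False)
        frame = ranked.rename("ig_bits").rename_axis("feature").reset_index()
        split = frame["feature"].map(split_name)
        frame["transform"] = split.str[0]
        frame["class"] = split.str[1]
        frame.insert(0, "pairing", pairing)
        rankings.append(frame)

    pd.concat(rankings).to_csv(ROOT / "scratch" / "infogain_ranking.csv", index=False)
    (ROOT / "results").mkdir(exist_ok=True)
    (ROOT / "results" / "infogain_counts.json").write_text(
        json.dumps(counts, indent=2) + "\n"
    )
    print(json.dumps(counts, indent=2))


if __name__ == "__main__":
    main()
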