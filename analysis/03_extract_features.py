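#!/usr/bin/env python
"""Extract the transform x texture feature bank for every candidate region.

Reads the cohort images (01) and candidate-region masks (02) and computes the
930-feature bank (10 image transforms x 93 features: first-order, GLCM,
GLRLM, GLSZM, GLDM, NGTDM) per region. The full regions-by-features CSV goes
to scratch/ (it is a few MB); a small summary goes to results/.
"""

import argparse
import json
import sys
import time
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from strokesep.features import ExtractionConfig, extract_all, feature_registry
from strokesep.io import load_mask_nifti, load_slice_nifti


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort-dir", type=Path, default=ROOT / "scratch" / "cohort")
    ap.add_argument("--regions-dir", type=Path, default=ROOT / "scratch" / "regions")
    args = ap.parse_args()

    regions = json.loads((args.regions_dir / "regions_manifest.json").read_text())
    config = ExtractionConfig()
    registry = feature_registry(config)

    rows = []
    t0 = time.time()
    for r in regions:
        image = load_slice_nifti(
            args.cohort_dir / f"{r['subject_id']}_s{r['slice_index']}_ct.nii.gz"
        )
        mask = load_mask_nifti(args.regions_dir / r["mask"])
        vec = extract_all(image, mask, config)
        row = {k: r[k] for k in ("subject_id", "pair_id", "label")}
        row.update(vec)
        rows.append(row)
    table = pd.DataFrame(rows)

    out_csv = ROOT / "scratch" / "features.csv"
    table.to_csv(out_csv, index=False)
    summary = {
        "n_regions": len(table),
        "n_features": len(registry),
        "elapsed_s": round(time.time() - t0, 1),
        "features_csv": str(out_csv.relative_to(ROOT)),
    }
    (ROOT / "results").mkdir(exist_ok=True)
    (ROOT / "results" / "features_summary.json").write_text(
        json.dumps(summary, indent=2) + "\n"
    )
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
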