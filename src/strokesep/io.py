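"""Serialization: NIfTI slices/masks, 16-bit PNG previews, JSON manifests."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .image import ImageSlice, ROIMask

__all__ = [
    "save_slice_nifti",
    "load_slice_nifti",
    "save_mask_nifti",
    "load_mask_nifti",
    "save_png16",
    "dump_json",
    "save_cohort",
    "load_cohort",
]


def _affine(spacing: tuple[float, float]) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], 1.0, 1.0])


def save_slice_nifti(image: ImageSlice, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(image.values.astype(np.float32), _affine(image.spacing)), str(path))


def load_slice_nifti(path: str | Path) -> ImageSlice:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    spacing = (float(img.affine[0, 0]), float(img.affine[1, 1]))
    return ImageSlice(data, spacing=spacing)


def save_mask_nifti(mask: ROIMask, path: str | Path, spacing=(1.0, 1.0)) -> None:
    nib.save(nib.Nifti1Image(mask.mask.astype(np.uint8), _affine(spacing)), str(path))


def load_mask_nifti(path: str | Path) -> ROIMask:
    return ROIMask(np.asarray(nib.load(str(path)).dataobj) > 0)


def save_png16(image: ImageSlice, path: str | Path, window: tuple[float, float] = (-100.0, 100.0)) -> None:
    """Windowed 16-bit PNG preview (default window covers brain tissue)."""
    lo, hi = window
    scaled = np.clip((image.values - lo) / (hi - lo), 0.0, 1.0)
    iio.imwrite(str(path), (scaled * 65535).astype(np.uint16))


def dump_json(obj, path: str | Path) -> None:
    """Deterministic JSON: sorted keys, fixed float formatting via repr."""
    Path(path).write_text(json.dumps(obj, sort_keys=True, indent=2) + "\n")


def save_cohort(cohort, out_dir: str | Path, seed: int | None = None) -> Path:
    """Write every slice/mask of a synthetic cohort as NIfTI plus a JSON
    manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "subjects": []}
    for subject in cohort:
        entry = {
            "subject_id": subject.subject_id,
            "group": subject.group,
            "true_midline": list(map(float, subject.true_midline)),
            "slices": [],
        }
        for k, rec in enumerate(subject.slices):
            stem = f"{subject.subject_id}_s{k}"
            paths = {
                "image": f"{stem}_ct.nii.gz",
                "roi": f"{stem}_roi.nii.gz",
                "brain": f"{stem}_brain.nii.gz",
            }
            save_slice_nifti(rec.image, out_dir / paths["image"])
            save_mask_nifti(rec.roi, out_dir / paths["roi"], spacing=rec.image.spacing)
            save_mask_nifti(rec.brain, out_dir / paths["brain"], spacing=rec.image.spacing)
            entry["slices"].append(paths)
        manifest["subjects"].append(entry)
    manifest_path = out_dir / "cohort_manifest.json"
    dump_json(manifest, manifest_path)
    return manifest_path


def load_cohort(manifest_path: str | Path):
    """Rebuild a cohort (list of SyntheticSubject) from a saved manifest."""
    from .phantom import SubjectSlice, SyntheticSubject

    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    cohort = []
    for entry in manifest["subjects"]:
        slices = tuple(
            SubjectSlice(
                image=load_slice_nifti(base / s["image"]),
                roi=load_mask_nifti(base / s["roi"]),
                brain=load_mask_nifti(base / s["brain"]),
            )
            for s in entry["slices"]
        )
        cohort.append(
            SyntheticSubject(
                subject_id=entry["subject_id"],
                group=entry["group"],
                slices=slices,
                true_midline=tuple(entry["true_midline"]),
            )
        )
    return cohort
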