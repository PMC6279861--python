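"""NIfTI and manifest I/O for simulated cohorts.

Images and masks are written as single-slice NIfTI volumes (affine =
identity scaled by the pixel spacing); ROI class labels live in the cohort
manifest CSV, not in the NIfTI header.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import ImageSlice, RoiMask, SubjectRecord

_META_COLUMNS = (
    "age",
    "sex",
    "interval_days",
    "fazekas",
    "hypertension",
    "diabetes",
    "hyperlipidemia",
    "smoking",
    "drinking",
    "atrial_fibrillation",
)


def _save_nifti(path: Path, data: np.ndarray, spacing: float) -> None:
    affine = np.diag([spacing, spacing, 1.0, 1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32)[:, :, None], affine)
    nib.save(img, str(path))


def _load_slice(path: Path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)[:, :, 0]
    spacing = float(img.header.get_zooms()[0])
    return data, spacing


def write_cohort(records: list[SubjectRecord], outdir: str | Path) -> Path:
    """Write every image/mask volume plus a manifest CSV; returns the
    manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        spacing = rec.baseline.spacing
        base_path = outdir / f"{rec.subject_id}_baseline.nii.gz"
        fu_path = outdir / f"{rec.subject_id}_followup.nii.gz"
        _save_nifti(base_path, rec.baseline.data, spacing)
        _save_nifti(fu_path, rec.followup.data, spacing)
        for mask in rec.masks:
            mask_path = outdir / f"{rec.subject_id}_mask_{mask.label}.nii.gz"
            _save_nifti(mask_path, mask.pixels.astype(np.float32), spacing)
            row = {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "roi_label": mask.label,
                "baseline_path": base_path.name,
                "followup_path": fu_path.name,
                "mask_path": mask_path.name,
            }
            row.update({k: rec.metadata.get(k) for k in _META_COLUMNS})
            rows.append(row)
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path: str | Path) -> list[SubjectRecord]:
    """Rebuild SubjectRecords from a manifest CSV written by
    :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    df = pd.read_csv(manifest_path)
    records: list[SubjectRecord] = []
    for subject_id, sub in df.groupby("subject_id", sort=False):
        first = sub.iloc[0]
        base_data, spacing = _load_slice(root / first["baseline_path"])
        fu_data, _ = _load_slice(root / first["followup_path"])
        masks = []
        for _, row in sub.iterrows():
            pixels, _ = _load_slice(root / row["mask_path"])
            masks.append(RoiMask(pixels > 0.5, row["roi_label"], subject_id))
        metadata = {
            k: first[k] for k in _META_COLUMNS if k in sub.columns and pd.notna(first[k])
        }
        records.append(
            SubjectRecord(
                subject_id=subject_id,
                group=first["group"],
                baseline=ImageSlice(base_data, spacing),
                followup=ImageSlice(fu_data, spacing),
                masks=masks,
                metadata=metadata,
            )
        )
    return records
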