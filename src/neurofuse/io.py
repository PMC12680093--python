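"""Cohort storage: NIfTI volumes plus a CSV manifest.

On disk, volumes follow NIfTI axis convention (height, width, depth[, channel])
with an identity affine; in memory everything is (channels, depth, height,
width).  DWI is a 4-D NIfTI with the three b-value volumes on the last axis;
T2 is 3-D.  Storage is lossless (float32 round-trip).
"""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import PatientSample

MANIFEST_COLUMNS = ["patient_id", "label", "dwi_path", "t2_path"]


class IOError_(IOError):
    """Raised for unreadable files or geometry mismatches at load time."""


def _to_disk_axes(vol: np.ndarray) -> np.ndarray:
    """(C, D, H, W) -> (H, W, D[, C]); channel axis dropped when singleton."""
    a = vol.transpose(2, 3, 1, 0)  # (H, W, D, C)
    return a[..., 0] if a.shape[-1] == 1 else a


def _from_disk_axes(a: np.ndarray) -> np.ndarray:
    """(H, W, D[, C]) -> (C, D, H, W)."""
    if a.ndim == 3:
        a = a[..., None]
    return np.ascontiguousarray(a.transpose(3, 2, 0, 1))


def write_cohort(samples: list[PatientSample], directory) -> Path:
    """Write one NIfTI per modality per patient plus manifest.csv; returns
    the manifest path.  Paths in the manifest are relative to its directory."""
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for s in samples:
            dwi_name = f"{s.patient_id}_dwi.nii.gz"
            t2_name = f"{s.patient_id}_t2.nii.gz"
            nib.save(nib.Nifti1Image(_to_disk_axes(s.dwi), np.eye(4)),
                     directory / dwi_name)
            nib.save(nib.Nifti1Image(_to_disk_axes(s.t2), np.eye(4)),
                     directory / t2_name)
            rows.append((s.patient_id, s.label, dwi_name, t2_name))
        manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
        path = directory / "manifest.csv"
        manifest.to_csv(path, index=False)
        return path
    except OSError as e:
        raise IOError_(f"failed to write cohort to {directory}: {e}") from e


def read_manifest(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise IOError_(f"manifest {path} missing columns {sorted(missing)}")
    if df["patient_id"].duplicated().any():
        dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise IOError_(f"duplicate patient_ids in manifest: {dupes}")
    df.attrs["root"] = str(path.parent)
    return df


def zscore(vol: np.ndarray) -> np.ndarray:
    """Per-channel z-score over (D, H, W); zero-variance channels map to 0."""
    out = np.empty_like(vol, dtype=np.float32)
    for c in range(vol.shape[0]):
        x = vol[c]
        sd = x.std()
        out[c] = 0.0 if sd == 0 else (x - x.mean()) / sd
    return out


def load_sample(row, root=None, normalize: bool = True,
                expect_dwi_shape=None, expect_t2_shape=None) -> PatientSample:
    """Load one manifest row into a PatientSample.

    Volumes are transposed to (channels, depth, height, width) and, by
    default, z-scored per channel (standard for arbitrary scanner units).
    """
    root = Path(root) if root is not None else Path(".")

    def _load(rel):
        p = root / rel
        if not os.path.exists(p):
            raise IOError_(f"volume file not found: {p}")
        try:
            return np.asarray(nib.load(p).get_fdata(dtype=np.float32))
        except Exception as e:  # nibabel raises several types
            raise IOError_(f"cannot read NIfTI {p}: {e}") from e

    dwi = _from_disk_axes(_load(row["dwi_path"]))
    t2 = _from_disk_axes(_load(row["t2_path"]))
    if dwi.shape[0] != 3:
        raise IOError_(f"DWI must have 3 b-value volumes, got {dwi.shape[0]}")
    if expect_dwi_shape is not None and dwi.shape[1:] != tuple(expect_dwi_shape):
        raise IOError_(f"DWI geometry {dwi.shape[1:]} != expected {expect_dwi_shape}")
    if expect_t2_shape is not None and t2.shape[1:] != tuple(expect_t2_shape):
        raise IOError_(f"T2 geometry {t2.shape[1:]} != expected {expect_t2_shape}")
    if normalize:
        dwi, t2 = zscore(dwi), zscore(t2)
    return PatientSample(patient_id=str(row["patient_id"]), dwi=dwi, t2=t2,
                         label=int(row["label"]),
                         lesion_mask=np.zeros(dwi.shape[1:], dtype=bool))


def load_cohort(manifest_path, normalize: bool = True) -> list[PatientSample]:
    df = read_manifest(manifest_path)
    root = df.attrs["root"]
    return [load_sample(row, root=root, normalize=normalize)
            for _, row in df.iterrows()]
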