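"""NIfTI reading/writing for synthetic studies and parameter maps."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["save_volume", "load_volume", "save_study", "load_study_arrays"]


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_volume(path, data, spacing=(1.0, 1.0, 1.4)) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(spacing))
    nib.save(img, str(path))
    return path


def load_volume(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float32), img.header.get_zooms()[:3]


def save_study(study, directory) -> dict:
    """Write one visit's 4D series, PD volume and ROI mask; returns the paths."""
    directory = Path(directory)
    sp = study.roi.spacing
    stem = f"{study.patient_id}_{study.visit}"
    paths = {
        "dce": save_volume(directory / f"{stem}_dce.nii.gz", study.dce, sp),
        "pd": save_volume(directory / f"{stem}_pd.nii.gz", study.pd_volume, sp),
        "mask": save_volume(directory / f"{stem}_mask.nii.gz",
                            study.roi.data.astype(np.float32), sp),
    }
    np.savetxt(directory / f"{stem}_frametimes.txt", study.acq.frame_times)
    return paths


def load_study_arrays(directory, patient_id: str, visit: str):
    """Load (dce, pd, mask, frame_times, spacing) written by `save_study`."""
    directory = Path(directory)
    stem = f"{patient_id}_{visit}"
    dce, sp = load_volume(directory / f"{stem}_dce.nii.gz")
    pd_vol, _ = load_volume(directory / f"{stem}_pd.nii.gz")
    mask, _ = load_volume(directory / f"{stem}_mask.nii.gz")
    frame_times = np.loadtxt(directory / f"{stem}_frametimes.txt")
    return dce, pd_vol, mask > 0.5, frame_times, tuple(float(s) for s in sp)
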