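"""On-disk study container: NIfTI volumes + JSON sidecars.

Layout of a study directory::

    <dir>/
      study.json                # subject id, group, per-slice AcquisitionMeta
      contours.json             # end-diastolic endo/epi polygons, mm
      <label>_magnitude.nii     # (nx, ny, 1, n_frames) float64
      <label>_phase_x.nii
      <label>_phase_y.nii

Serialization is deterministic: JSON keys are sorted and NIfTI headers are
fully specified, so two writes of the same study are byte-identical.
"""

from __future__ import annotations

import json
import os

import nibabel as nib
import numpy as np

from .model import (
    ALL_LABELS,
    AcquisitionMeta,
    ContourSet,
    DenseSlice,
    DenseStudy,
    IncompleteStudyError,
)

_CHANNELS = ("magnitude", "phase_x", "phase_y")


def _image_path(path: str, label: str, channel: str) -> str:
    return os.path.join(path, f"{label}_{channel}.nii")


def _to_nifti(stack: np.ndarray, pixel_spacing: float) -> nib.Nifti1Image:
    # store as (x, y, z=1, t) with the time axis last
    data = np.ascontiguousarray(np.transpose(stack, (2, 1, 0))[:, :, None, :])
    affine = np.diag([pixel_spacing, pixel_spacing, 1.0, 1.0])
    img = nib.Nifti1Image(data.astype(np.float64), affine)
    img.header.set_xyzt_units("mm", "msec")
    return img


def _from_nifti(img: nib.Nifti1Image) -> np.ndarray:
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4 or data.shape[2] != 1:
        raise ValueError(f"expected (nx, ny, 1, t) volume, got {data.shape}")
    return np.transpose(data[:, :, 0, :], (2, 1, 0))


def write_study(study: DenseStudy, path: str) -> None:
    """Write a validated study to ``path`` (created if absent)."""
    os.makedirs(path, exist_ok=True)
    sidecar = {"subject_id": study.subject_id,
               "group_label": study.group_label,
               "slices": {}}
    contours = {}
    for label in ALL_LABELS:
        sl = study.slices[label]
        m = sl.meta
        sidecar["slices"][label] = {
            "encoding_frequency": m.encoding_frequency,
            "pixel_spacing": m.pixel_spacing,
            "repetition_time": m.repetition_time,
            "frame_times": list(m.frame_times),
            "field_of_view": m.field_of_view,
            "matrix_size": m.matrix_size,
        }
        for channel in _CHANNELS:
            img = _to_nifti(getattr(sl, channel), m.pixel_spacing)
            nib.save(img, _image_path(path, label, channel))
        cs = study.ed_contours[label]
        contours[label] = {
            "frame_index": cs.frame_index,
            "endocardium": cs.endocardium.tolist(),
            "epicardium": cs.epicardium.tolist(),
        }
    for fname, payload in (("study.json", sidecar), ("contours.json", contours)):
        with open(os.path.join(path, fname), "w") as fh:
            json.dump(payload, fh, sort_keys=True, indent=1)
            fh.write("\n")


def read_study(path: str) -> DenseStudy:
    """Read and validate a study directory written by :func:`write_study`."""
    sidecar_path = os.path.join(path, "study.json")
    if not os.path.exists(sidecar_path):
        raise IncompleteStudyError(f"incomplete study: no study.json in {path}")
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    with open(os.path.join(path, "contours.json")) as fh:
        contours = json.load(fh)

    slices = {}
    ed_contours = {}
    for label in ALL_LABELS:
        if label not in sidecar.get("slices", {}):
            raise IncompleteStudyError(f"incomplete study: {label}")
        m = sidecar["slices"][label]
        meta = AcquisitionMeta(
            encoding_frequency=m["encoding_frequency"],
            pixel_spacing=m["pixel_spacing"],
            repetition_time=m["repetition_time"],
            frame_times=tuple(m["frame_times"]),
            field_of_view=m["field_of_view"],
            matrix_size=m["matrix_size"],
        )
        stacks = {}
        for channel in _CHANNELS:
            fpath = _image_path(path, label, channel)
            if not os.path.exists(fpath):
                raise IncompleteStudyError(f"incomplete study: {label}")
            stacks[channel] = _from_nifti(nib.load(fpath))
        slices[label] = DenseSlice(label=label, meta=meta, **stacks)
        c = contours[label]
        ed_contours[label] = ContourSet(
            endocardium=np.asarray(c["endocardium"]),
            epicardium=np.asarray(c["epicardium"]),
            frame_index=c["frame_index"],
        )
    return DenseStudy(
        slices=slices,
        ed_contours=ed_contours,
        subject_id=sidecar.get("subject_id", "subject"),
        group_label=sidecar.get("group_label"),
    )
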