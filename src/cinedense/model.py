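"""Shared data model for cine DENSE studies.

A DENSE acquisition stores, for every cine frame, one magnitude image and two
phase images whose pixel values encode the in-plane displacement of the tissue
at that pixel relative to its end-diastolic position (phase = 2*pi*ke*u).
A study consists of three short-axis slices (basal, mid, apical) and two
long-axis views (two-chamber, four-chamber), plus end-diastolic contours.

Conventions
-----------
* Image pixel (row, col) maps to physical (y, x) in mm via the pixel spacing;
  the origin is the image corner.  All downstream geometry is in mm.
* Frame 0 is end-diastole (first frame after the R-wave trigger); displacement
  is zero there by definition.
* Phase values live in the half-open interval (-pi, pi].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from shapely.geometry import Polygon

SHORT_AXIS_LABELS = ("basal", "mid", "apical")
LONG_AXIS_LABELS = ("two_chamber", "four_chamber")
ALL_LABELS = SHORT_AXIS_LABELS + LONG_AXIS_LABELS

#: Displacement-encoding frequencies (cycles/mm) used by the emulated protocol.
ENCODING_RANGE = (0.8, 1.0)

#: Myocardial density in mg/uL, the standard CMR mass convention.
MYOCARDIAL_DENSITY_MG_PER_UL = 1.05


class StudyValidationError(ValueError):
    """A study (or one of its components) violates a model invariant."""


class IncompleteStudyError(StudyValidationError):
    """A study is missing one of the five prescribed views."""


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition metadata for one DENSE slice.

    Parameters
    ----------
    encoding_frequency : float
        Displacement encoding frequency ke in cycles/mm.
    pixel_spacing : float
        In-plane pixel size in mm (= field_of_view / matrix_size).
    repetition_time : float
        TR in ms (one cine frame per TR).
    frame_times : tuple of float
        Time of each cine frame in ms from the R-wave trigger, strictly
        increasing, first entry >= 0.
    field_of_view : float
        In-plane field of view in mm.
    matrix_size : int
        Acquisition matrix (square images).
    """

    encoding_frequency: float
    pixel_spacing: float
    repetition_time: float
    frame_times: tuple
    field_of_view: float
    matrix_size: int

    def __post_init__(self):
        if not self.encoding_frequency > 0:
            raise StudyValidationError("encoding_frequency must be > 0")
        ft = np.asarray(self.frame_times, dtype=float)
        if ft.size == 0 or ft[0] < 0 or np.any(np.diff(ft) <= 0):
            raise StudyValidationError(
                "frame_times must be strictly increasing and start at >= 0"
            )
        object.__setattr__(self, "frame_times", tuple(float(t) for t in ft))
        if self.matrix_size <= 0:
            raise StudyValidationError("matrix_size must be positive")
        expected = self.field_of_view / self.matrix_size
        if not np.isclose(self.pixel_spacing, expected, rtol=1e-6):
            raise StudyValidationError(
                f"pixel_spacing {self.pixel_spacing} != field_of_view/matrix_size "
                f"{expected}"
            )

    @property
    def n_frames(self) -> int:
        return len(self.frame_times)


def validate_encoding_range(meta: AcquisitionMeta) -> list:
    """Return warnings for encoding frequencies outside the protocol range.

    The emulated protocol uses ke in [0.8, 1.0] cycles/mm (inclusive).  This
    never raises; it returns a (possibly empty) list of warning strings.
    """
    lo, hi = ENCODING_RANGE
    ke = meta.encoding_frequency
    if not (lo <= ke <= hi):
        return [
            f"encoding_frequency ke = {ke} cycles/mm outside protocol range "
            f"[{lo}, {hi}]"
        ]
    return []


@dataclass
class DenseSlice:
    """One cine DENSE slice: magnitude plus wrapped X/Y displacement phase.

    All three stacks are frame-indexed arrays of shape (n_frames, ny, nx);
    phase values must lie in (-pi, pi].
    """

    label: str
    magnitude: np.ndarray
    phase_x: np.ndarray
    phase_y: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self):
        if self.label not in ALL_LABELS:
            raise StudyValidationError(f"unknown slice label: {self.label!r}")
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.phase_x = np.asarray(self.phase_x, dtype=float)
        self.phase_y = np.asarray(self.phase_y, dtype=float)
        shapes = {self.magnitude.shape, self.phase_x.shape, self.phase_y.shape}
        if len(shapes) != 1 or self.magnitude.ndim != 3:
            raise StudyValidationError(
                f"stacks of slice {self.label!r} must share one 3D shape, got "
                f"{[a.shape for a in (self.magnitude, self.phase_x, self.phase_y)]}"
            )
        if self.magnitude.shape[0] != self.meta.n_frames:
            raise StudyValidationError(
                f"slice {self.label!r}: {self.magnitude.shape[0]} frames in "
                f"stacks but {self.meta.n_frames} frame_times"
            )
        for name, ph in (("phase_x", self.phase_x), ("phase_y", self.phase_y)):
            if np.any(ph <= -np.pi) or np.any(ph > np.pi):
                raise StudyValidationError(
                    f"slice {self.label!r}: {name} values outside (-pi, pi]"
                )

    @property
    def n_frames(self) -> int:
        return self.magnitude.shape[0]

    @property
    def shape(self) -> tuple:
        return self.magnitude.shape[1:]


@dataclass
class ContourSet:
    """Closed endo/epicardial polygons for one slice at one frame.

    Vertex coordinates are (x, y) in mm.  Polygons must be simple and the
    epicardium must strictly enclose the endocardium.
    """

    endocardium: np.ndarray
    epicardium: np.ndarray
    frame_index: int = 0

    def __post_init__(self):
        self.endocardium = np.asarray(self.endocardium, dtype=float)
        self.epicardium = np.asarray(self.epicardium, dtype=float)
        for name, poly in (("endocardium", self.endocardium),
                           ("epicardium", self.epicardium)):
            if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
                raise StudyValidationError(f"{name} must be an (N, 2) polygon")
            if not Polygon(poly).is_valid:
                raise StudyValidationError(f"{name} polygon is not simple")
        if not Polygon(self.epicardium).contains(Polygon(self.endocardium)):
            raise StudyValidationError(
                "epicardium does not strictly enclose endocardium"
            )

    @property
    def endo_polygon(self) -> Polygon:
        return Polygon(self.endocardium)

    @property
    def epi_polygon(self) -> Polygon:
        return Polygon(self.epicardium)


@dataclass
class DenseStudy:
    """A complete five-view DENSE study for one subject."""

    slices: dict
    ed_contours: dict
    subject_id: str = "subject"
    group_label: Optional[str] = None

    def __post_init__(self):
        for label in ALL_LABELS:
            if label not in self.slices:
                raise IncompleteStudyError(f"incomplete study: {label}")
        for label in self.slices:
            if label not in ALL_LABELS:
                raise StudyValidationError(f"unknown slice label: {label!r}")
            if self.slices[label].label != label:
                raise StudyValidationError(
                    f"slice stored under {label!r} is labelled "
                    f"{self.slices[label].label!r}"
                )
        missing = [l for l in ALL_LABELS if l not in self.ed_contours]
        if missing:
            raise IncompleteStudyError(
                f"incomplete study: missing end-diastolic contours for "
                f"{', '.join(missing)}"
            )
        for label, cs in self.ed_contours.items():
            if cs.frame_index != 0:
                raise StudyValidationError(
                    f"end-diastolic contours of {label!r} must be at frame 0"
                )

    @property
    def short_axis(self) -> dict:
        return {l: self.slices[l] for l in SHORT_AXIS_LABELS}

    @property
    def long_axis(self) -> dict:
        return {l: self.slices[l] for l in LONG_AXIS_LABELS}
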