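"""Image-grid containers shared by the phantom generator and the segmentation stage.

A *frame* is one 2-D grid of a cine study: either a gray-scale intensity image
(:class:`GrayFrame`) or its region labelling (:class:`LabelFrame`).  Short-axis
studies carry one frame per slice per cardiac phase; four-chamber studies carry a
single long-axis frame per phase.  Physical spacing travels with every frame so
that volumes and areas are always computed from millimetres, never raw pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np

__all__ = [
    "Label",
    "Phase",
    "ED",
    "ES",
    "GrayFrame",
    "LabelFrame",
    "LABEL_NAMES",
    "REGION_LABELS",
]


class Label(IntEnum):
    """Integer codes of the label grids.

    ``COMPACT``, ``TRABECULATION``, ``RECESS`` and ``CENTRAL_CAVITY`` are the four
    regions of the LV partition; ``PAPILLARY`` is tracked as a fifth, separate
    tissue label (papillary muscles are myocardial but detached from the wall).
    """

    BACKGROUND = 0
    COMPACT = 1
    TRABECULATION = 2
    RECESS = 3
    CENTRAL_CAVITY = 4
    PAPILLARY = 5


LABEL_NAMES = {
    Label.BACKGROUND: "background",
    Label.COMPACT: "compact",
    Label.TRABECULATION: "trabeculation",
    Label.RECESS: "recess",
    Label.CENTRAL_CAVITY: "central_cavity",
    Label.PAPILLARY: "papillary",
}

#: The four LV regions plus papillary — every label that contributes to quantities.
REGION_LABELS = (
    Label.COMPACT,
    Label.TRABECULATION,
    Label.RECESS,
    Label.CENTRAL_CAVITY,
    Label.PAPILLARY,
)

Phase = str
ED: Phase = "ED"
ES: Phase = "ES"

_PHASES = (ED, ES)


def _check_phase(phase: str) -> str:
    if phase not in _PHASES:
        raise ValueError(f"phase must be 'ED' or 'ES', got {phase!r}")
    return phase


@dataclass(frozen=True)
class GrayFrame:
    """One 2-D intensity grid with its physical metadata.

    Parameters
    ----------
    pixels : 2-D float array, arbitrary units (a.u.).
    pixel_spacing : isotropic in-plane pixel size, mm.
    slice_thickness : through-plane thickness, mm; ``None`` for four-chamber
        (area-based) views.
    phase : ``"ED"`` or ``"ES"``.
    view : ``"short_axis"`` or ``"four_chamber"``.
    slice_index : position in the short-axis stack (0 = most apical); ``None``
        for four-chamber views.
    """

    pixels: np.ndarray
    pixel_spacing: float
    slice_thickness: float | None
    phase: Phase
    view: str = "short_axis"
    slice_index: int | None = None
    study_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D grid")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixel intensities must be finite")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        if self.slice_thickness is not None and self.slice_thickness <= 0:
            raise ValueError("slice_thickness must be positive when given")
        _check_phase(self.phase)
        object.__setattr__(self, "pixels", px)

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_spacing**2

    def with_pixels(self, pixels: np.ndarray) -> "GrayFrame":
        return replace(self, pixels=np.asarray(pixels, dtype=float))


@dataclass(frozen=True)
class LabelFrame:
    """One 2-D label grid (codes of :class:`Label`) with the same metadata
    conventions as :class:`GrayFrame`."""

    labels: np.ndarray
    pixel_spacing: float
    slice_thickness: float | None
    phase: Phase
    view: str = "short_axis"
    slice_index: int | None = None
    study_id: str = ""
    diagnostics: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2 or lab.size == 0:
            raise ValueError("labels must be a non-empty 2-D grid")
        if not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("labels must be integer-coded")
        valid = {int(code) for code in Label}
        if not set(np.unique(lab)).issubset(valid):
            raise ValueError("label grid contains codes outside the label table")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        _check_phase(self.phase)
        object.__setattr__(self, "labels", lab.astype(np.uint8))

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_spacing**2

    def count(self, label: Label) -> int:
        return int(np.count_nonzero(self.labels == int(label)))

    def area_cm2(self, label: Label) -> float:
        """Label area in cm² (1 cm² = 100 mm²)."""
        return self.count(label) * self.pixel_area_mm2 / 100.0

    def volume_ml(self, label: Label) -> float:
        """Label volume in mL via pixel area × slice thickness (1 mL = 1000 mm³)."""
        if self.slice_thickness is None:
            raise ValueError("volume requested from a frame without slice thickness")
        return self.count(label) * self.pixel_area_mm2 * self.slice_thickness / 1000.0
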