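"""Slice areas, Simpson-rule stack volumes and ejection fraction.

Volumes follow the cardiology convention ("method of disks"): the volume of a
short-axis stack is the sum of per-slice cross-sectional areas multiplied by
the slice spacing, assuming no gaps between slices.  The synthetic cohort
uses a constant 8 mm slice spacing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .mask_morphology import STRUCTURE_LABELS, LABEL_LV, LabelMask

__all__ = [
    "SYNTHETIC_SLICE_SPACING_MM",
    "MaskStack",
    "VolumePair",
    "UndefinedEfError",
    "NegativeEfWarning",
    "slice_area",
    "stack_volume",
    "ejection_fraction",
    "volumes_from_stack",
]

#: Slice spacing (mm) assumed for all synthetically generated subjects.
SYNTHETIC_SLICE_SPACING_MM = 8.0

Phase = Literal["ED", "ES"]


class UndefinedEfError(ValueError):
    """EF is undefined when the end-diastolic volume is not positive."""


class NegativeEfWarning(UserWarning):
    """ESV exceeded EDV; the EF is negative and should be filtered out."""


@dataclass(frozen=True)
class MaskStack:
    """Ordered base-to-apex stack of (ED, ES) label-mask pairs.

    All slices must share grid shape and pixel spacing; ``slice_spacing``
    is the distance in mm between consecutive slice planes.
    """

    slices: tuple[tuple[LabelMask, LabelMask], ...]
    slice_spacing: float

    def __post_init__(self) -> None:
        slices = tuple(tuple(pair) for pair in self.slices)
        if len(slices) < 1:
            raise ValueError("a stack needs at least one slice")
        if self.slice_spacing <= 0:
            raise ValueError("slice_spacing must be > 0")
        ref = slices[0][0]
        for i, (ed, es) in enumerate(slices):
            for frame in (ed, es):
                if frame.shape != ref.shape or frame.pixel_spacing != ref.pixel_spacing:
                    raise ValueError(f"slice {i} differs in shape or pixel spacing")
        object.__setattr__(self, "slices", slices)
        object.__setattr__(self, "slice_spacing", float(self.slice_spacing))

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def pixel_spacing(self) -> tuple[float, float]:
        return self.slices[0][0].pixel_spacing

    def frames(self, phase: Phase) -> tuple[LabelMask, ...]:
        idx = 0 if phase == "ED" else 1
        return tuple(pair[idx] for pair in self.slices)


@dataclass(frozen=True)
class VolumePair:
    """End-diastolic and end-systolic LV volumes (ml) and their EF."""

    edv_ml: float
    esv_ml: float
    ef: float

    @classmethod
    def from_volumes(cls, edv_ml: float, esv_ml: float) -> "VolumePair":
        return cls(edv_ml=edv_ml, esv_ml=esv_ml, ef=ejection_fraction(edv_ml, esv_ml))


def slice_area(mask: LabelMask, label: int = LABEL_LV) -> float:
    """Cross-sectional area in mm² of one structure on one slice."""
    if label not in STRUCTURE_LABELS:
        raise ValueError(f"unknown structure label {label}")
    dr, dc = mask.pixel_spacing
    return float(np.count_nonzero(mask.grid == label)) * dr * dc


def stack_volume(stack: MaskStack, label: int = LABEL_LV, phase: Phase = "ED") -> float:
    """Method-of-disks volume in ml: sum of slice areas times slice spacing."""
    total_mm3 = sum(slice_area(m, label) for m in stack.frames(phase)) * stack.slice_spacing
    return total_mm3 / 1000.0


def ejection_fraction(edv_ml: float, esv_ml: float) -> float:
    """EF = (EDV − ESV) / EDV as a fraction.

    Raises :class:`UndefinedEfError` for non-positive EDV; warns (and returns
    the negative value) when ESV > EDV so the EF filter can drop the case.
    """
    if edv_ml <= 0:
        raise UndefinedEfError(f"EF undefined for EDV = {edv_ml} ml")
    if esv_ml < 0:
        raise ValueError("ESV cannot be negative")
    ef = (edv_ml - esv_ml) / edv_ml
    if ef < 0:
        warnings.warn(
            f"ESV ({esv_ml} ml) exceeds EDV ({edv_ml} ml): EF = {ef:.3f}",
            NegativeEfWarning,
            stacklevel=2,
        )
    return ef


def volumes_from_stack(stack: MaskStack, label: int = LABEL_LV) -> VolumePair:
    """EDV, ESV and EF of one stack (LV blood pool by default)."""
    return VolumePair.from_volumes(
        edv_ml=stack_volume(stack, label, "ED"),
        esv_ml=stack_volume(stack, label, "ES"),
    )
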