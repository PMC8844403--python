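"""Image and target normalization for the volume-regression network.

Frames are resampled to 1×1 mm, center-cropped (or zero-padded) to
150×150 pixels and intensity-normalized so the 3rd and 97th percentiles map
to 0 and 1.  Volume targets are divided by the subject's slice spacing and
then unity-normalized with the training-set minimum and maximum; inference
outputs are mapped back through the exact inverse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumetrics import MaskStack

__all__ = [
    "TARGET_SIZE",
    "SliceSample",
    "VolumeNormalizer",
    "resample_and_crop",
    "normalize_intensity",
    "select_slices",
    "ConstantImageWarning",
]

#: Network input side length (pixels at 1 mm resolution).
TARGET_SIZE = 150


class ConstantImageWarning(UserWarning):
    """Intensity normalization received a constant image."""


@dataclass(frozen=True)
class SliceSample:
    """One preprocessed (ED, ES) pair: 2×150×150, channel 0 = ED."""

    pixels: np.ndarray
    subject_id: str = ""
    slice_index: int = 0

    def __post_init__(self) -> None:
        pixels = np.asarray(self.pixels, dtype=np.float64)
        if pixels.shape != (2, TARGET_SIZE, TARGET_SIZE):
            raise ValueError(
                f"expected (2, {TARGET_SIZE}, {TARGET_SIZE}), got {pixels.shape}"
            )
        object.__setattr__(self, "pixels", pixels)


def resample_and_crop(
    image: np.ndarray,
    pixel_spacing: tuple[float, float],
    size: int = TARGET_SIZE,
) -> np.ndarray:
    """Bilinear resample to 1×1 mm, then center crop / zero-pad to ``size``.

    A dimension already at 1 mm is passed through untouched; cropping takes
    the central window, padding is symmetric with zeros.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    dr, dc = pixel_spacing
    if dr <= 0 or dc <= 0:
        raise ValueError("pixel spacing must be positive")

    if (dr, dc) != (1.0, 1.0):
        image = ndimage.zoom(image, (dr, dc), order=1, mode="nearest", grid_mode=True)

    out = image
    for axis in (0, 1):
        n = out.shape[axis]
        if n > size:
            start = (n - size) // 2
            out = out.take(range(start, start + size), axis=axis)
        elif n < size:
            before = (size - n) // 2
            pad = [(0, 0), (0, 0)]
            pad[axis] = (before, size - n - before)
            out = np.pad(out, pad, mode="constant")
    return out


def normalize_intensity(
    image: np.ndarray, q_lo: float = 0.03, q_hi: float = 0.97, clip: bool = True
) -> np.ndarray:
    """Map the [3%, 97%] intensity quantiles to [0, 1], clipping outside.

    Invariant to positive affine transforms of the input.  A constant image
    yields zeros with a :class:`ConstantImageWarning`.
    """
    image = np.asarray(image, dtype=np.float64)
    lo, hi = np.quantile(image, [q_lo, q_hi])
    if hi <= lo:
        warnings.warn("constant image: normalized to zeros", ConstantImageWarning, stacklevel=2)
        return np.zeros_like(image)
    out = (image - lo) / (hi - lo)
    return np.clip(out, 0.0, 1.0) if clip else out


def select_slices(stack, basal_index: int, apical_index: int):
    """Inclusive trim of a stack to the slices between base and apex planes."""
    n = stack.n_slices if isinstance(stack, MaskStack) else len(stack)
    if not 0 <= basal_index <= apical_index < n:
        raise ValueError(
            f"invalid slice window [{basal_index}, {apical_index}] for {n} slices"
        )
    if isinstance(stack, MaskStack):
        return MaskStack(
            stack.slices[basal_index : apical_index + 1], stack.slice_spacing
        )
    return stack[basal_index : apical_index + 1]


@dataclass
class VolumeNormalizer:
    """Unity-based normalization of spacing-normalized EDV/ESV targets.

    Fitted on the training set: each volume is divided by its subject's
    slice spacing, and the per-target minimum/maximum over the training set
    define the linear map onto [0, 1].  ``denormalize`` is the exact inverse;
    out-of-range inputs are passed through unclipped.
    """

    edv_min: float = np.nan
    edv_max: float = np.nan
    esv_min: float = np.nan
    esv_max: float = np.nan

    def fit(
        self, edv_ml: np.ndarray, esv_ml: np.ndarray, slice_spacing_mm: np.ndarray
    ) -> "VolumeNormalizer":
        edv = np.asarray(edv_ml, dtype=np.float64) / np.asarray(slice_spacing_mm)
        esv = np.asarray(esv_ml, dtype=np.float64) / np.asarray(slice_spacing_mm)
        self.edv_min, self.edv_max = float(edv.min()), float(edv.max())
        self.esv_min, self.esv_max = float(esv.min()), float(esv.max())
        if self.edv_max == self.edv_min or self.esv_max == self.esv_min:
            raise ValueError("degenerate training volumes: max == min")
        return self

    def _check(self) -> None:
        if np.isnan(self.edv_min):
            raise RuntimeError("normalizer not fitted")

    def normalize(
        self, edv_ml: float, esv_ml: float, slice_spacing_mm: float
    ) -> tuple[float, float]:
        self._check()
        return (
            (edv_ml / slice_spacing_mm - self.edv_min) / (self.edv_max - self.edv_min),
            (esv_ml / slice_spacing_mm - self.esv_min) / (self.esv_max - self.esv_min),
        )

    def denormalize(
        self, edv_norm: float, esv_norm: float, slice_spacing_mm: float
    ) -> tuple[float, float]:
        self._check()
        return (
            (edv_norm * (self.edv_max - self.edv_min) + self.edv_min) * slice_spacing_mm,
            (esv_norm * (self.esv_max - self.esv_min) + self.esv_min) * slice_spacing_mm,
        )


def preprocess_subject(
    images: list[tuple[np.ndarray, np.ndarray]],
    pixel_spacing: tuple[float, float],
    subject_id: str = "",
) -> list[SliceSample]:
    """Full image pipeline for one subject: resample, crop, normalize.

    ``images`` holds per-slice (ED, ES) grayscale frames at the given pixel
    spacing; quantile normalization is applied per frame.
    """
    samples = []
    for i, (ed, es) in enumerate(images):
        pair = np.stack(
            [
                normalize_intensity(resample_and_crop(ed, pixel_spacing)),
                normalize_intensity(resample_and_crop(es, pixel_spacing)),
            ]
        )
        samples.append(SliceSample(pixels=pair, subject_id=subject_id, slice_index=i))
    return samples
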