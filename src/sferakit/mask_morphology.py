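"""Shape-space operators on short-axis label masks.

Cardiac segmentation masks carry up to three structures on a background of
zeros: left-ventricular blood pool (label 1), LV myocardium (label 2) and
right ventricle (label 3).  This module provides the three primitives used to
manufacture new end-diastole/end-systole (ED/ES) mask pairs with a controlled
ejection fraction:

* the signed Euclidean distance transform (SDT) of a binary structure,
* level-set interpolation between an ED and an ES mask via convex
  combination of their SDTs, and
* affine rescaling of a mask about its foreground centroid.

The SDT convention is positive inside the structure, negative outside, with
magnitude equal to the Euclidean pixel distance to the nearest
opposite-region pixel; thresholding an SDT at ``> 0`` recovers the source
mask exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "LabelMask",
    "SdtField",
    "InterpolationParams",
    "RescaleParams",
    "DegenerateMaskError",
    "StructureVanishedWarning",
    "LABEL_BACKGROUND",
    "LABEL_LV",
    "LABEL_MYO",
    "LABEL_RV",
    "STRUCTURE_LABELS",
    "signed_distance",
    "interpolate_pair",
    "rescale_mask",
    "gamma_grid",
]

LABEL_BACKGROUND = 0
LABEL_LV = 1
LABEL_MYO = 2
LABEL_RV = 3
STRUCTURE_LABELS = (LABEL_LV, LABEL_MYO, LABEL_RV)

_VALID_LABELS = frozenset({LABEL_BACKGROUND, LABEL_LV, LABEL_MYO, LABEL_RV})


class DegenerateMaskError(ValueError):
    """Raised when a binary mask has no boundary (all fore- or background)."""


class StructureVanishedWarning(UserWarning):
    """A structure label disappeared during a morphological operation."""


@dataclass(frozen=True)
class LabelMask:
    """One 2D multi-label frame with physical pixel spacing.

    Parameters
    ----------
    grid
        2D integer array; 0 background, 1 LV blood pool, 2 myocardium, 3 RV.
    pixel_spacing
        (row mm, col mm), both strictly positive.
    """

    grid: np.ndarray
    pixel_spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 2 or grid.size == 0:
            raise ValueError("grid must be a non-empty 2D array")
        if not np.issubdtype(grid.dtype, np.integer):
            if not np.array_equal(grid, grid.astype(np.int64)):
                raise ValueError("grid must hold integer labels")
            grid = grid.astype(np.int64)
        labels = set(np.unique(grid).tolist())
        if not labels <= _VALID_LABELS:
            raise ValueError(f"unknown labels {sorted(labels - _VALID_LABELS)}")
        if len(self.pixel_spacing) != 2 or any(s <= 0 for s in self.pixel_spacing):
            raise ValueError("pixel_spacing components must be > 0")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(
            self, "pixel_spacing", (float(self.pixel_spacing[0]), float(self.pixel_spacing[1]))
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def binary(self, label: int) -> np.ndarray:
        """Binary foreground mask of one structure label."""
        return self.grid == label

    def labels_present(self) -> tuple[int, ...]:
        return tuple(l for l in STRUCTURE_LABELS if np.any(self.grid == l))


@dataclass(frozen=True)
class SdtField:
    """Signed distance transform of a binary mask.

    ``values`` is positive strictly inside the structure and negative
    outside; ``values > 0`` reproduces the source foreground exactly.
    Distances are in pixel units (the interpolation operates in index space,
    spacing is carried separately by the mask).
    """

    values: np.ndarray

    def foreground(self) -> np.ndarray:
        return self.values > 0


@dataclass(frozen=True)
class InterpolationParams:
    """Level-set interpolation setup: ``F`` intermediate frames, index alpha.

    The default ``F = 11`` matches the synthetic-generation workflow; for a
    single frame request, ``0 < alpha < F`` (endpoints are identities).
    """

    F: int = 11
    alpha: int | None = None

    def __post_init__(self) -> None:
        if self.F < 1:
            raise ValueError("F must be >= 1")
        if self.alpha is not None and not (0 < self.alpha < self.F):
            raise ValueError("alpha must lie strictly inside (0, F)")


@dataclass(frozen=True)
class RescaleParams:
    """Gamma grids for affine rescaling of ES (shrink) and ED (grow) masks.

    Thirteen uniformly spaced values over [0.7, 1) for ES and over [1, 1.2)
    for ED, both half-open (left endpoint included).
    """

    es_interval: tuple[float, float] = (0.7, 1.0)
    ed_interval: tuple[float, float] = (1.0, 1.2)
    n_samples: int = 13

    def __post_init__(self) -> None:
        for lo, hi in (self.es_interval, self.ed_interval):
            if not lo < hi:
                raise ValueError("gamma intervals must be non-empty")
            if lo <= 0:
                raise ValueError("gamma values must be positive")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


def signed_distance(mask: np.ndarray) -> SdtField:
    """Signed Euclidean distance transform of a binary mask.

    Positive inside (distance to the nearest background pixel), negative
    outside (distance to the nearest foreground pixel), in pixel units.

    Raises
    ------
    DegenerateMaskError
        If the mask is all foreground or all background — no boundary exists.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2 or mask.size == 0:
        raise ValueError("mask must be a non-empty 2D array")
    if mask.all() or not mask.any():
        raise DegenerateMaskError("mask has no boundary (all fore- or background)")
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    return SdtField(values=np.where(mask, inside, -outside))


def interpolate_pair(
    ed: LabelMask, es: LabelMask, params: InterpolationParams | None = None
) -> list[LabelMask]:
    """Interpolate between an ED and an ES mask by convex SDT combination.

    For ``alpha = 1..F`` the interpolated mask is built per structure label as

        IM_alpha = (alpha/F) * SDT_ed + ((F - alpha)/F) * SDT_es

    and each pixel is assigned to the structure with the largest positive
    combined SDT (background where none is positive).  ``alpha = F``
    reproduces the ED mask (endpoint identity); ``alpha`` near 0 approaches
    ES.  Returns ``F`` frames ordered by increasing alpha.  A structure
    present in only one of the two frames is skipped with a
    :class:`StructureVanishedWarning`.
    """
    params = params or InterpolationParams()
    if ed.shape != es.shape:
        raise ValueError(f"shape mismatch: ED {ed.shape} vs ES {es.shape}")
    if ed.pixel_spacing != es.pixel_spacing:
        raise ValueError("ED and ES pixel spacings differ")

    F = params.F
    sdt_pairs: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for label in STRUCTURE_LABELS:
        in_ed = bool(np.any(ed.grid == label))
        in_es = bool(np.any(es.grid == label))
        if in_ed != in_es:
            warnings.warn(
                f"label {label} present in only one frame; skipped in interpolation",
                StructureVanishedWarning,
                stacklevel=2,
            )
            continue
        if not in_ed:
            continue
        sdt_pairs[label] = (
            signed_distance(ed.binary(label)).values,
            signed_distance(es.binary(label)).values,
        )

    alphas = (params.alpha,) if params.alpha is not None else tuple(range(1, F + 1))
    frames: list[LabelMask] = []
    for alpha in alphas:
        w = alpha / F
        if not sdt_pairs:
            frames.append(LabelMask(np.zeros(ed.shape, dtype=np.int64), ed.pixel_spacing))
            continue
        labels = list(sdt_pairs)
        combined = np.stack(
            [w * sdt_pairs[l][0] + (1.0 - w) * sdt_pairs[l][1] for l in labels]
        )
        best = np.argmax(combined, axis=0)
        positive = np.take_along_axis(combined, best[None], axis=0)[0] > 0
        grid = np.where(positive, np.asarray(labels)[best], LABEL_BACKGROUND)
        frames.append(LabelMask(grid.astype(np.int64), ed.pixel_spacing))
    return frames


def rescale_mask(mask: LabelMask, gamma: float) -> LabelMask:
    """Scale all foreground structures by ``gamma`` about their joint centroid.

    Inverse-mapping with nearest-neighbor label lookup, so the output grid is
    fully covered and labels stay crisp; each structure's area scales by
    gamma**2 up to pixelation.  Emits :class:`StructureVanishedWarning` if a
    structure present in the input disappears (gamma too small).
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    fg = mask.grid != LABEL_BACKGROUND
    if not fg.any():
        raise ValueError("mask has no foreground to rescale")
    if gamma == 1.0:
        return mask

    cr, cc = (c.mean() for c in np.nonzero(fg))
    rows, cols = np.indices(mask.shape)
    src_r = np.rint(cr + (rows - cr) / gamma).astype(np.int64)
    src_c = np.rint(cc + (cols - cc) / gamma).astype(np.int64)
    valid = (src_r >= 0) & (src_r < mask.shape[0]) & (src_c >= 0) & (src_c < mask.shape[1])
    grid = np.zeros(mask.shape, dtype=np.int64)
    grid[valid] = mask.grid[src_r[valid], src_c[valid]]

    for label in mask.labels_present():
        if not np.any(grid == label):
            warnings.warn(
                f"label {label} vanished at gamma={gamma}",
                StructureVanishedWarning,
                stacklevel=2,
            )
    return LabelMask(grid, mask.pixel_spacing)


def gamma_grid(params: RescaleParams | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Uniform gamma samples over the half-open ES and ED intervals.

    Returns ``(es_gammas, ed_gammas)``, each of length ``n_samples``, left
    endpoint included and right endpoint excluded.
    """
    params = params or RescaleParams()

    def _grid(lo: float, hi: float) -> np.ndarray:
        return lo + (hi - lo) * np.arange(params.n_samples) / params.n_samples

    return _grid(*params.es_interval), _grid(*params.ed_interval)
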