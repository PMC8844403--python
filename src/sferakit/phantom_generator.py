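"""Analytic cardiac phantoms with closed-form ground truth.

Each phantom slice carries an elliptical LV blood pool, a surrounding
myocardial annulus of fixed thickness and a crescent-shaped RV; areas and
method-of-disks volumes are available in closed form, which makes phantom
stacks exact oracles for the mask-morphology and volumetric operators.  A
procedural renderer converts label masks into bSSFP-like grayscale frames
(bright blood pool, dark myocardium, smooth textured background, additive
Gaussian noise) and stands in for a learned mask-to-image backend.

End-systolic masks are built by shrinking each slice's blood pool by the
factor ``sqrt(1 - EF)``: areas then scale by ``1 - EF``, so the method-of-disks
EF of the stack equals the requested target exactly (up to rasterization).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mask_morphology import LABEL_LV, LABEL_MYO, LABEL_RV, LabelMask
from .volumetrics import (
    SYNTHETIC_SLICE_SPACING_MM,
    MaskStack,
    VolumePair,
)

__all__ = [
    "PhantomSpec",
    "RenderStyle",
    "make_phantom_subject",
    "make_cohort",
    "render_procedural",
]


@dataclass(frozen=True)
class RenderStyle:
    """Per-label base intensities and background texture for rendering.

    Defaults follow bSSFP contrast: blood pools bright, myocardium dark.
    Intensities are on an arbitrary [0, 1] scale.
    """

    lv_intensity: float = 0.90
    myo_intensity: float = 0.25
    rv_intensity: float = 0.80
    background_level: float = 0.35
    background_amplitude: float = 0.15
    noise_sd: float = 0.04


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and target function of one synthetic subject.

    ``lv_radius_profile`` holds per-slice ED blood-pool semi-axes (a, b) in
    mm, base to apex.  The realized (rasterized) EF tracks ``target_ef``
    because the ES shrink factor is solved analytically.
    """

    lv_radius_profile: tuple[tuple[float, float], ...]
    wall_thickness_mm: float = 6.0
    rv_offset_mm: float = 18.0
    rv_scale: float = 1.35
    target_ef: float = 0.55
    grid: tuple[int, int] = (150, 150)
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    slice_spacing_mm: float = SYNTHETIC_SLICE_SPACING_MM
    noise_sd: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_ef < 1.0:
            raise ValueError("target_ef must lie in (0, 1)")
        if len(self.lv_radius_profile) < 1:
            raise ValueError("need at least one slice")
        rows, cols = self.grid
        margin_mm = 2.0 * max(self.pixel_spacing)
        for a, b in self.lv_radius_profile:
            if a <= 0 or b <= 0:
                raise ValueError("LV semi-axes must be positive")
            extent = self.rv_offset_mm + self.rv_scale * max(a, b) + self.wall_thickness_mm
            if extent + margin_mm > min(rows * self.pixel_spacing[0], cols * self.pixel_spacing[1]) / 2:
                raise ValueError("phantom structures do not fit inside the grid")


def _ellipse(rows_mm: np.ndarray, cols_mm: np.ndarray, center, a: float, b: float) -> np.ndarray:
    return ((rows_mm - center[0]) / a) ** 2 + ((cols_mm - center[1]) / b) ** 2 <= 1.0


def _phantom_slice(
    spec: PhantomSpec, a: float, b: float, shrink: float
) -> LabelMask:
    """Rasterize one slice with LV semi-axes scaled by ``shrink``."""
    rows, cols = spec.grid
    dr, dc = spec.pixel_spacing
    rr = (np.arange(rows) + 0.5) * dr
    cc = (np.arange(cols) + 0.5) * dc
    rows_mm, cols_mm = np.meshgrid(rr, cc, indexing="ij")
    center = (rows * dr / 2.0, cols * dc / 2.0)

    a_s, b_s = a * shrink, b * shrink
    lv = _ellipse(rows_mm, cols_mm, center, a_s, b_s)
    epi = _ellipse(
        rows_mm, cols_mm, center, a_s + spec.wall_thickness_mm, b_s + spec.wall_thickness_mm
    )
    rv_center = (center[0], center[1] - spec.rv_offset_mm * shrink)
    rv_outer = _ellipse(
        rows_mm, cols_mm, rv_center, spec.rv_scale * a_s, spec.rv_scale * b_s
    )

    grid = np.zeros(spec.grid, dtype=np.int64)
    grid[rv_outer & ~epi] = LABEL_RV  # crescent: clipped by the epicardial ellipse
    grid[epi] = LABEL_MYO
    grid[lv] = LABEL_LV
    return LabelMask(grid, spec.pixel_spacing)


def make_phantom_subject(spec: PhantomSpec) -> tuple[MaskStack, VolumePair]:
    """Build one phantom stack plus its closed-form LV volumes.

    The analytic volumes use the method of disks on exact ellipse areas:
    EDV = Σ π·aᵢ·bᵢ·t, ESV = (1 − EF)·EDV.
    """
    shrink = math.sqrt(1.0 - spec.target_ef)
    pairs = []
    for a, b in spec.lv_radius_profile:
        ed = _phantom_slice(spec, a, b, shrink=1.0)
        es = _phantom_slice(spec, a, b, shrink=shrink)
        pairs.append((ed, es))
    stack = MaskStack(tuple(pairs), slice_spacing=spec.slice_spacing_mm)

    edv_mm3 = sum(math.pi * a * b for a, b in spec.lv_radius_profile) * spec.slice_spacing_mm
    esv_mm3 = (1.0 - spec.target_ef) * edv_mm3
    analytic = VolumePair.from_volumes(edv_mm3 / 1000.0, esv_mm3 / 1000.0)
    return stack, analytic


def _sample_ef(rng: np.random.Generator, ef_distribution: str) -> float:
    """Draw one EF from a named distribution, truncated to (0.05, 0.90)."""
    name, _, args = ef_distribution.partition(":")
    params = [float(x) for x in args.split(":")] if args else []
    for _ in range(1000):
        if name == "uniform":
            lo, hi = params if params else (0.10, 0.80)
            ef = rng.uniform(lo, hi)
        elif name == "normal":
            mu, sd = params if params else (0.57, 0.07)
            ef = rng.normal(mu, sd)
        else:
            raise ValueError(f"unknown EF distribution {name!r}")
        if 0.05 < ef < 0.90:
            return float(ef)
    raise RuntimeError("EF sampling failed to land in (0.05, 0.90)")


def make_cohort(
    n: int,
    ef_distribution: str = "normal:0.57:0.07",
    seed: int = 0,
    n_slices_range: tuple[int, int] = (6, 9),
    grid: tuple[int, int] = (150, 150),
) -> list[tuple[MaskStack, VolumePair, PhantomSpec]]:
    """Generate ``n`` seeded phantom subjects with EFs from a named law.

    ``ef_distribution`` is ``"uniform:lo:hi"`` or ``"normal:mu:sd"``
    (fractions).  Geometry (base radius, eccentricity, wall, slice count)
    varies per subject; everything derives from ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n):
        ef = _sample_ef(rng, ef_distribution)
        n_slices = int(rng.integers(n_slices_range[0], n_slices_range[1] + 1))
        base_r = rng.uniform(15.0, 31.0)
        ecc = rng.uniform(0.85, 1.0)
        # roughly ellipsoidal taper from base to apex
        taper = np.sqrt(np.clip(1.0 - (np.arange(n_slices) / n_slices) ** 2, 0.15, None))
        profile = tuple((float(base_r * t), float(base_r * ecc * t)) for t in taper)
        spec = PhantomSpec(
            lv_radius_profile=profile,
            wall_thickness_mm=float(rng.uniform(5.0, 8.0)),
            target_ef=ef,
            grid=grid,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        stack, analytic = make_phantom_subject(spec)
        cohort.append((stack, analytic, spec))
    return cohort


def render_procedural(
    mask: LabelMask,
    style: RenderStyle | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Render a label mask as a bSSFP-like grayscale frame.

    Label regions get their base intensities (LV brightest, myocardium
    darkest); the background receives a smooth low-frequency field; Gaussian
    noise of ``style.noise_sd`` is added everywhere.  Deterministic per
    ``(mask, style, seed)``.
    """
    style = style or RenderStyle()
    rng = np.random.default_rng(seed)
    rows, cols = mask.shape
    image = np.full(mask.shape, style.background_level, dtype=np.float64)

    # low-frequency background texture: a few random cosine modes
    rr, cc = np.meshgrid(np.linspace(0, 1, rows), np.linspace(0, 1, cols), indexing="ij")
    for _ in range(4):
        fr, fc = rng.uniform(1.0, 4.0, size=2)
        phase_r, phase_c = rng.uniform(0, 2 * np.pi, size=2)
        amp = style.background_amplitude * rng.uniform(0.3, 1.0)
        image += np.where(
            mask.grid == 0, amp * np.cos(2 * np.pi * fr * rr + phase_r) * np.cos(2 * np.pi * fc * cc + phase_c), 0.0
        )

    image[mask.grid == LABEL_LV] = style.lv_intensity
    image[mask.grid == LABEL_MYO] = style.myo_intensity
    image[mask.grid == LABEL_RV] = style.rv_intensity
    if style.noise_sd > 0:
        image += rng.normal(0.0, style.noise_sd, size=mask.shape)
    return image
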