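"""Expansion of real (ED, ES) mask stacks into an EF-balanced synthetic cohort.

The workflow mirrors the mask-generation pipeline used to widen an
EF-imbalanced training set:

1. **Lower-EF variants** — interpolate between each slice's ED and ES masks
   in signed-distance space; pairing the original ED with an interpolated
   frame as a new ES (or an interpolated frame as new ED with the original
   ES) yields subjects with reduced EF.
2. **Higher-EF variants** — rescale the ES mask by a gamma in [0.7, 1)
   (smaller ESV) and the ED mask by a gamma in [1, 1.2) (bigger EDV).
3. **Filter** to the physiologic EF window [10%, 80%].
4. **Rebalance** by seeded per-bin subsampling toward a uniform EF histogram.

The same alpha or gamma pair is applied to every slice of a subject so the
subject-level EF is coherent.  All volumes are computed at the synthetic
8 mm slice spacing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np

from .mask_morphology import (
    InterpolationParams,
    LabelMask,
    RescaleParams,
    interpolate_pair,
    rescale_mask,
    gamma_grid,
)
from .volumetrics import (
    SYNTHETIC_SLICE_SPACING_MM,
    MaskStack,
    NegativeEfWarning,
    volumes_from_stack,
    VolumePair,
)

__all__ = [
    "SyntheticSubject",
    "EfHistogramSpec",
    "expand_subject",
    "filter_by_ef",
    "balance_ef",
    "render_subject",
    "register_renderer",
    "available_renderers",
]

VariantKind = Literal["interp_ed_as_es", "interp_es_as_ed", "rescaled_pair"]


@dataclass(frozen=True)
class SyntheticSubject:
    """One synthetic stack with its volumes and generation provenance."""

    stack: MaskStack
    volumes: VolumePair
    source_id: str
    variant: VariantKind
    alpha: int | None = None
    gamma_ed: float | None = None
    gamma_es: float | None = None

    @property
    def ef(self) -> float:
        return self.volumes.ef


@dataclass(frozen=True)
class EfHistogramSpec:
    """Uniform-EF rebalancing: equal-width bins over [lo, hi], per-bin quota."""

    n_bins: int = 14
    per_bin_quota: int = 100
    lo: float = 0.10
    hi: float = 0.80
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.per_bin_quota < 1:
            raise ValueError("per_bin_quota must be >= 1")
        if not self.lo < self.hi:
            raise ValueError("EF window must be non-empty")


def _restack(
    stack: MaskStack,
    ed_frames: tuple[LabelMask, ...],
    es_frames: tuple[LabelMask, ...],
) -> MaskStack:
    return MaskStack(
        tuple(zip(ed_frames, es_frames)), slice_spacing=SYNTHETIC_SLICE_SPACING_MM
    )


def expand_subject(
    subject: MaskStack,
    source_id: str = "subject",
    interp: InterpolationParams | None = None,
    rescale: RescaleParams | None = None,
    gamma_pairing: Literal["indexed", "cross"] = "indexed",
) -> list[SyntheticSubject]:
    """Expand one stack into unfiltered lower- and higher-EF variants.

    For each interpolation index ``alpha = 1..F-1`` two variants are built:
    (original ED, interpolated frame as ES) and (interpolated frame as ED,
    original ES) — both reduce EF.  For each gamma pair, one variant with
    rescaled ED (gamma >= 1) and rescaled ES (gamma < 1) raises EF.  With
    the default index-matched pairing this yields ``2*(F-1) + n_samples``
    variants per subject.
    """
    interp = interp or InterpolationParams()
    rescale = rescale or RescaleParams()

    ed_frames = subject.frames("ED")
    es_frames = subject.frames("ES")

    # one interpolation run per slice, all alphas at once
    per_slice_frames = [
        interpolate_pair(ed, es, interp) for ed, es in subject.slices
    ]

    variants: list[SyntheticSubject] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NegativeEfWarning)

        for alpha in range(1, interp.F):  # alpha = F duplicates ED, skipped
            interp_frames = tuple(fs[alpha - 1] for fs in per_slice_frames)
            for kind, ed_new, es_new in (
                ("interp_ed_as_es", ed_frames, interp_frames),
                ("interp_es_as_ed", interp_frames, es_frames),
            ):
                stack = _restack(subject, ed_new, es_new)
                variants.append(
                    SyntheticSubject(
                        stack=stack,
                        volumes=volumes_from_stack(stack),
                        source_id=source_id,
                        variant=kind,
                        alpha=alpha,
                    )
                )

        es_gammas, ed_gammas = gamma_grid(rescale)
        if gamma_pairing == "indexed":
            pairs = list(zip(ed_gammas, es_gammas))
        elif gamma_pairing == "cross":
            pairs = [(ge, gs) for ge in ed_gammas for gs in es_gammas]
        else:
            raise ValueError(f"unknown gamma pairing {gamma_pairing!r}")

        for g_ed, g_es in pairs:
            ed_new = tuple(rescale_mask(m, g_ed) for m in ed_frames)
            es_new = tuple(rescale_mask(m, g_es) for m in es_frames)
            stack = _restack(subject, ed_new, es_new)
            variants.append(
                SyntheticSubject(
                    stack=stack,
                    volumes=volumes_from_stack(stack),
                    source_id=source_id,
                    variant="rescaled_pair",
                    gamma_ed=float(g_ed),
                    gamma_es=float(g_es),
                )
            )
    return variants


def filter_by_ef(
    subjects: list[SyntheticSubject], lo: float = 0.10, hi: float = 0.80
) -> list[SyntheticSubject]:
    """Keep subjects with ``lo <= EF <= hi`` (closed interval), order preserved."""
    return [s for s in subjects if lo <= s.ef <= hi]


def balance_ef(
    subjects: list[SyntheticSubject], spec: EfHistogramSpec | None = None
) -> list[SyntheticSubject]:
    """Seeded per-bin subsampling toward a uniform EF histogram.

    Up to ``per_bin_quota`` subjects are drawn without replacement from each
    equal-width EF bin; deficient bins keep all their candidates.
    """
    spec = spec or EfHistogramSpec()
    if not subjects:
        warnings.warn("no subjects to balance", UserWarning, stacklevel=2)
        return []
    edges = np.linspace(spec.lo, spec.hi, spec.n_bins + 1)
    efs = np.array([s.ef for s in subjects])
    # rightmost bin closed on both sides
    bins = np.clip(np.digitize(efs, edges[1:-1]), 0, spec.n_bins - 1)

    rng = np.random.default_rng(spec.seed)
    selected: list[int] = []
    any_filled = False
    for b in range(spec.n_bins):
        members = np.flatnonzero(bins == b)
        if members.size == 0:
            continue
        any_filled = True
        if members.size <= spec.per_bin_quota:
            selected.extend(members.tolist())
        else:
            selected.extend(
                rng.choice(members, size=spec.per_bin_quota, replace=False).tolist()
            )
    if not any_filled:
        warnings.warn("all EF bins empty", UserWarning, stacklevel=2)
        return []
    return [subjects[i] for i in sorted(selected)]


# renderer registry: name -> callable(LabelMask, seed) -> 2D float image
_RENDERERS: dict[str, Callable[..., np.ndarray]] = {}


def register_renderer(name: str, fn: Callable[..., np.ndarray]) -> None:
    """Register a mask-to-image backend under ``name``."""
    _RENDERERS[name] = fn


def available_renderers() -> tuple[str, ...]:
    return tuple(sorted(_RENDERERS))


def render_subject(
    subject: SyntheticSubject | MaskStack,
    renderer: str = "procedural",
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Render every (ED, ES) mask pair of a subject to grayscale images.

    The backend is looked up in the renderer registry; the default
    ``"procedural"`` backend draws bSSFP-like contrast (see
    :mod:`sferakit.phantom_generator`).  Per-frame seeds derive from ``seed``
    so repeated calls are bit-identical.
    """
    if renderer not in _RENDERERS:
        raise KeyError(
            f"renderer {renderer!r} not registered (have {available_renderers()})"
        )
    fn = _RENDERERS[renderer]
    stack = subject.stack if isinstance(subject, SyntheticSubject) else subject
    ss = np.random.SeedSequence(seed)
    images = []
    for (ed, es), child in zip(stack.slices, ss.spawn(stack.n_slices)):
        s_ed, s_es = child.spawn(2)
        images.append(
            (
                fn(ed, seed=int(s_ed.generate_state(1)[0] % (2**31))),
                fn(es, seed=int(s_es.generate_state(1)[0] % (2**31))),
            )
        )
    return images


def _default_procedural(mask: LabelMask, seed: int = 0) -> np.ndarray:
    from .phantom_generator import render_procedural

    return render_procedural(mask, seed=seed)


register_renderer("procedural", _default_procedural)
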