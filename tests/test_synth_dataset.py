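"""Subject expansion, EF filtering, histogram balancing and rendering."""

import numpy as np
import pytest

from sferakit.mask_morphology import InterpolationParams, RescaleParams
from sferakit.phantom_generator import make_cohort, make_phantom_subject
from sferakit.synth_dataset import (
    EfHistogramSpec,
    SyntheticSubject,
    balance_ef,
    expand_subject,
    filter_by_ef,
    render_subject,
)
from sferakit.volumetrics import VolumePair, volumes_from_stack


@pytest.fixture(scope="module")
def expanded(small_phantom_module):
    stack, _, _ = small_phantom_module
    return stack, expand_subject(stack, source_id="p0")


@pytest.fixture(scope="module")
def small_phantom_module():
    from sferakit.phantom_generator import PhantomSpec

    taper = np.sqrt(np.clip(1 - (np.arange(5) / 5) ** 2, 0.15, None))
    spec = PhantomSpec(
        lv_radius_profile=tuple((float(24 * t), float(22 * t)) for t in taper),
        target_ef=0.55,
        seed=3,
    )
    stack, analytic = make_phantom_subject(spec)
    return stack, analytic, spec


class TestExpandSubject:
    def test_variant_count(self, expanded):
        """2·(F−1) interpolation pairings + 13 index-matched gamma pairs."""
        _, variants = expanded
        assert len(variants) == 2 * 10 + 13

    def test_interpolation_variants_reduce_ef(self, expanded):
        stack, variants = expanded
        base_ef = volumes_from_stack(stack).ef
        for v in variants:
            if v.variant in ("interp_ed_as_es", "interp_es_as_ed"):
                assert v.ef <= base_ef + 1e-9

    def test_rescaled_variants_raise_ef(self, expanded):
        """gamma_es < 1 <= gamma_ed shrinks ESV and grows EDV, raising EF.

        Analytically EF' = 1 − (γes²/γed²)(1 − EF) for per-slice uniform
        scaling; every rescaled pair except the identity-most one must
        strictly exceed the source EF.
        """
        stack, variants = expanded
        base_ef = volumes_from_stack(stack).ef
        rescaled = [v for v in variants if v.variant == "rescaled_pair"]
        assert len(rescaled) == 13
        for v in rescaled:
            expected = 1 - (v.gamma_es**2 / v.gamma_ed**2) * (1 - base_ef)
            assert v.ef == pytest.approx(expected, abs=0.02)

    def test_identical_ed_es_filtered_out(self, small_phantom_module):
        from sferakit.phantom_generator import PhantomSpec

        _, _, spec = small_phantom_module
        zero_spec = PhantomSpec(
            lv_radius_profile=spec.lv_radius_profile, target_ef=1e-9, seed=0
        )
        stack, _ = make_phantom_subject(zero_spec)
        variants = expand_subject(stack)
        interp = [v for v in variants if v.variant != "rescaled_pair"]
        assert all(v.ef == pytest.approx(0.0) for v in interp)
        assert filter_by_ef(interp) == []

    def test_provenance_volumes_recomputable(self, expanded):
        """Stored volumes equal a fresh volumetric pass over the stack."""
        _, variants = expanded
        for v in variants[::5]:
            fresh = volumes_from_stack(v.stack)
            assert fresh.edv_ml == pytest.approx(v.volumes.edv_ml)
            assert fresh.esv_ml == pytest.approx(v.volumes.esv_ml)

    def test_ef_coverage_widens(self, expanded):
        """A mid-EF source expands into variants spanning low to high EF."""
        _, variants = expanded
        kept = filter_by_ef(variants)
        efs = [v.ef for v in kept]
        assert min(efs) <= 0.25 and max(efs) >= 0.70


def _tiny_stack():
    from sferakit.mask_morphology import LabelMask
    from sferakit.volumetrics import MaskStack

    grid = np.zeros((8, 8), dtype=np.int64)
    grid[3:5, 3:5] = 1
    mask = LabelMask(grid)
    return MaskStack(((mask, mask),), slice_spacing=8.0)


_STACK = _tiny_stack()


def _dummy(ef):
    """Synthetic subject carrying a requested EF on a placeholder stack."""
    return SyntheticSubject(
        stack=_STACK,
        volumes=VolumePair(edv_ml=100.0, esv_ml=100.0 * (1 - ef), ef=ef),
        source_id="x",
        variant="rescaled_pair",
    )


class TestFilterByEf:
    _dummy = staticmethod(_dummy)

    def test_boundary_inclusive(self):
        subjects = [self._dummy(ef) for ef in (0.05, 0.10, 0.45, 0.80, 0.85)]
        kept = filter_by_ef(subjects)
        assert [round(s.ef, 2) for s in kept] == [0.10, 0.45, 0.80]

    def test_empty_input(self):
        assert filter_by_ef([]) == []

    def test_range_containment_random_cohort(self):
        rng = np.random.default_rng(0)
        subjects = [self._dummy(float(ef)) for ef in rng.uniform(0, 1, 50)]
        kept = filter_by_ef(subjects)
        assert all(0.10 <= s.ef <= 0.80 for s in kept)


class TestBalanceEf:
    @staticmethod
    def _cohort(efs):
        return [_dummy(float(ef)) for ef in efs]

    def test_quota_met_in_dense_bins(self):
        rng = np.random.default_rng(1)
        efs = rng.triangular(0.10, 0.55, 0.80, size=1000)
        subjects = self._cohort(efs)
        spec = EfHistogramSpec(n_bins=7, per_bin_quota=50, seed=0)
        out = balance_ef(subjects, spec)
        edges = np.linspace(0.10, 0.80, 8)
        counts, _ = np.histogram([s.ef for s in out], bins=edges)
        available, _ = np.histogram(efs, bins=edges)
        np.testing.assert_array_equal(counts, np.minimum(available, 50))
        assert np.all(counts[available >= 50] == 50)

    def test_large_quota_returns_everything(self):
        subjects = self._cohort(np.linspace(0.12, 0.78, 30))
        out = balance_ef(subjects, EfHistogramSpec(n_bins=5, per_bin_quota=1000, seed=0))
        assert {id(s) for s in out} == {id(s) for s in subjects}

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        subjects = self._cohort(rng.uniform(0.10, 0.80, 300))
        spec = EfHistogramSpec(n_bins=14, per_bin_quota=10, seed=123)
        a = balance_ef(subjects, spec)
        b = balance_ef(subjects, spec)
        assert [s.ef for s in a] == [s.ef for s in b]

    def test_empty_warns(self):
        with pytest.warns(UserWarning):
            assert balance_ef([], EfHistogramSpec()) == []


class TestRenderSubject:
    def test_deterministic(self, small_phantom_module):
        stack, _, _ = small_phantom_module
        a = render_subject(stack, seed=5)
        b = render_subject(stack, seed=5)
        for (ae, ax), (be, bx) in zip(a, b):
            assert np.array_equal(ae, be) and np.array_equal(ax, bx)

    def test_lv_brighter_than_myocardium(self, small_phantom_module):
        stack, _, _ = small_phantom_module
        images = render_subject(stack, seed=5)
        ed_mask = stack.slices[0][0]
        ed_img = images[0][0]
        assert ed_img[ed_mask.grid == 1].mean() > ed_img[ed_mask.grid == 2].mean()

    def test_unregistered_backend(self, small_phantom_module):
        stack, _, _ = small_phantom_module
        with pytest.raises(KeyError, match="not registered"):
            render_subject(stack, renderer="learned-backend")
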