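"""Activity-flow prediction, noise ceiling, nulls and virtual lesions."""

import numpy as np
import pytest

from thalamoflow import actflow
from thalamoflow.actflow import (
    ActivityFlowModel,
    lesion_scan,
    noise_ceiling,
    nucleus_mean_reduction,
    permutation_null,
    predict_pattern,
    split_half_accuracy,
    virtual_lesion,
)
from thalamoflow.exceptions import ValidationError


class TestPredictPattern:
    def test_hand_arithmetic(self):
        p = predict_pattern([1.0, 2.0], [[1.0, 0.0], [0.0, 3.0]])
        assert np.allclose(p, [1.0, 6.0])

    def test_zero_evoked_and_identity_weights(self, rng):
        o = rng.normal(size=5)
        assert np.allclose(predict_pattern(np.zeros(5), rng.normal(size=(5, 3))), 0.0)
        assert np.allclose(predict_pattern(o, np.eye(5)), o)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValidationError):
            predict_pattern(np.ones(3), np.ones((4, 2)))

    def test_bilinearity_and_target_permutation(self, rng):
        o = rng.normal(size=6)
        w = rng.normal(size=(6, 4))
        assert np.allclose(predict_pattern(2 * o, w), 2 * predict_pattern(o, w))
        assert np.allclose(predict_pattern(o, 3 * w), 3 * predict_pattern(o, w))
        perm = rng.permutation(4)
        assert np.allclose(predict_pattern(o, w[:, perm]), predict_pattern(o, w)[perm])


class TestNoiseCeiling:
    def test_identical_halves(self, rng):
        p = rng.normal(size=20)
        nc = noise_ceiling(p, p)
        assert nc.vE == 0.0 and nc.r_nc == 1.0

    def test_sign_flipped_halves_give_one_fifth(self, rng):
        p = rng.normal(size=50)
        nc = noise_ceiling(p, -p)
        # var(p - (-p)) = 4 var(p)  =>  r_nc = 1/5
        assert nc.r_nc == pytest.approx(0.2)

    def test_independent_halves_tend_to_one_third(self, rng):
        vals = [noise_ceiling(rng.normal(size=5000), rng.normal(size=5000)).r_nc
                for _ in range(50)]
        assert abs(np.mean(vals) - 1.0 / 3.0) < 0.01

    def test_degenerate_flagged(self):
        nc = noise_ceiling(np.zeros(5), np.zeros(5))
        assert nc.degenerate and np.isnan(nc.r_nc)


def _halves_from(rng, V=30, P=20):
    o1, o2 = rng.normal(size=V), rng.normal(size=V)
    w1, w2 = rng.normal(size=(V, P)), rng.normal(size=(V, P))
    y1, y2 = rng.normal(size=P), rng.normal(size=P)
    return (o1, w1, y1), (o2, w2, y2)


class TestSplitHalfAccuracy:
    def test_perfect_prediction(self, rng):
        o = rng.normal(size=10)
        w = rng.normal(size=(10, 8))
        p = predict_pattern(o, w)
        res = split_half_accuracy(((o, w, p), (o, w, p)))
        assert res.raw_accuracy == pytest.approx(1.0)
        assert res.accuracy == pytest.approx(1.0)

    def test_anticorrelated_observation(self, rng):
        o = rng.normal(size=10)
        w = rng.normal(size=(10, 8))
        p = predict_pattern(o, w)
        res = split_half_accuracy(((o, w, -p), (o, w, -p)), normalize=False)
        assert res.raw_accuracy == pytest.approx(-1.0)

    def test_affine_invariance_of_raw_accuracy(self, rng):
        h1, h2 = _halves_from(rng)
        base = split_half_accuracy((h1, h2), normalize=False).raw_accuracy
        (o1, w1, y1), (o2, w2, y2) = h1, h2
        shifted = ((o1, w1, 3.0 * y1 + 7.0), (o2, w2, -2.0 * y2 + 1.0))
        # positive rescaling preserves r; negative flips the sign of that fold
        r = split_half_accuracy(shifted, normalize=False).raw_accuracy
        r1 = actflow._corr(3.0 * y1 + 7.0, predict_pattern(o2, w2))
        r2 = actflow._corr(-2.0 * y2 + 1.0, predict_pattern(o1, w1))
        assert r == pytest.approx(0.5 * (r1 + r2))
        assert np.isfinite(base)

    def test_constant_pattern_rejected(self, rng):
        h1, h2 = _halves_from(rng)
        bad = ((h1[0], h1[1], np.full(20, 2.0)), h2)
        with pytest.raises(ValidationError):
            split_half_accuracy(bad)


class TestPermutationNull:
    def test_single_permutation_p_values(self, rng):
        h = _halves_from(rng)
        _, p = permutation_null(h, n_perm=1, seed=0)
        assert p in (0.5, 1.0)

    def test_structureless_null_centered_at_zero(self, rng):
        h = _halves_from(rng, V=100, P=100)
        null, _ = permutation_null(h, kind="shuffle_evoked", n_perm=300, seed=1,
                                   normalize=False)
        se = null.std() / np.sqrt(null.size)
        assert abs(null.mean()) < max(3 * se, 0.02)

    def test_hub_data_beats_null(self, small_noiseless_dataset):
        res = ActivityFlowModel.from_dataset(
            small_noiseless_dataset, condition="EDS", use_censoring=False
        ).fit()
        for kind in ("shuffle_evoked", "shuffle_fc"):
            null, p = res.permutation_null(kind, n_perm=200, seed=3)
            assert res.accuracy > np.quantile(null, 0.975)
            assert p < 0.01

    def test_determinism(self, rng):
        h = _halves_from(rng)
        n1, p1 = permutation_null(h, n_perm=50, seed=7)
        n2, p2 = permutation_null(h, n_perm=50, seed=7)
        assert np.array_equal(n1, n2) and p1 == p2


class TestVirtualLesion:
    def test_zero_amplitude_voxels_cost_nothing(self, rng):
        V, P = 20, 10
        o = np.zeros(V)
        o[10:] = rng.normal(size=10) + 3.0
        w = rng.normal(size=(V, P))
        y = predict_pattern(o, w)
        h = ((o, w, y), (o, w, y))
        prof = virtual_lesion(h, fraction=0.2, window_start=1)
        assert np.allclose(o[prof.removed], 0.0)
        assert prof.reduction == pytest.approx(0.0, abs=1e-12)

    def test_full_lesion_degenerate(self, rng):
        h1, h2 = _halves_from(rng)
        prof = virtual_lesion((h1, h2), fraction=1.0, window_start=1)
        assert prof.degenerate and prof.accuracy_lesioned == 0.0

    def test_window_bounds_checked(self, rng):
        h = _halves_from(rng)
        with pytest.raises(ValidationError):
            virtual_lesion(h, fraction=0.2, window_start=81)
        with pytest.raises(ValidationError):
            virtual_lesion(h, fraction=0.2, window_start=0)

    def test_strongest_window_is_worst_on_hub_data(self, small_noiseless_dataset):
        res = ActivityFlowModel.from_dataset(
            small_noiseless_dataset, condition="EDS", use_censoring=False
        ).fit()
        profiles = res.lesion_scan()
        reductions = [p.reduction for p in profiles]
        assert int(np.argmax(reductions)) + 1 == 80

    def test_exact_removal_count(self, rng):
        h = _halves_from(rng, V=37)
        prof = virtual_lesion(h, fraction=0.2, window_start=40)
        assert prof.removed.size == int(np.ceil(0.2 * 37))


class TestNucleusMeanReduction:
    def test_uniform_reductions_equal_everywhere(self, rng):
        V = 30
        labels = np.array(["A"] * 10 + ["B"] * 10 + ["C"] * 10)
        o = rng.normal(size=V)
        w = rng.normal(size=(V, 10))
        y = predict_pattern(o, w)
        h = ((o, w, y), (o, w, y))
        profiles = lesion_scan(h, windows=[1, 20, 40])
        for p in profiles:
            p.accuracy_full, p.accuracy_lesioned = 1.0, 0.9  # uniform reduction
        out = nucleus_mean_reduction(profiles, labels)
        assert np.allclose(out.to_numpy(), 0.1)

    def test_single_nucleus_equals_global_mean(self, rng):
        h = _halves_from(rng, V=25)
        profiles = lesion_scan(h, windows=range(1, 81))
        labels = np.array(["only"] * 25)
        out = nucleus_mean_reduction(profiles, labels)
        sums = np.zeros(25)
        counts = np.zeros(25)
        for p in profiles:
            sums[p.removed] += p.reduction
            counts[p.removed] += 1
        covered = counts > 0
        expected = np.mean(sums[covered] / counts[covered])
        assert out["only"] == pytest.approx(expected)

    def test_hub_nuclei_rank_top(self, small_noiseless_dataset):
        ds = small_noiseless_dataset
        res = ActivityFlowModel.from_dataset(ds, condition="EDS",
                                             use_censoring=False).fit()
        out = res.nucleus_mean_reduction()
        top = set(out.sort_values(ascending=False).index[:len(ds.brain.hub_nuclei)])
        assert top == set(ds.brain.hub_nuclei)


class TestAlgebraicProperties:
    """Seeded property tests of the accuracy and noise-ceiling algebra."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(scale=st.floats(0.1, 50.0), seed=st.integers(0, 2**16))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_noise_ceiling_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        p1, p2 = rng.normal(size=40), rng.normal(size=40)
        a = noise_ceiling(p1, p2)
        b = noise_ceiling(scale * p1, scale * p2)
        assert b.r_nc == pytest.approx(a.r_nc, rel=1e-9)

    @given(a=st.floats(0.1, 10.0), b=st.floats(-5.0, 5.0), seed=st.integers(0, 2**16))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_raw_accuracy_invariant_to_positive_affine_maps(self, a, b, seed):
        rng = np.random.default_rng(seed)
        h1, h2 = _halves_from(rng)
        base = split_half_accuracy((h1, h2), normalize=False).raw_accuracy
        (o1, w1, y1), (o2, w2, y2) = h1, h2
        mapped = ((o1, w1, a * y1 + b), (o2, w2, a * y2 + b))
        assert split_half_accuracy(mapped, normalize=False).raw_accuracy == \
            pytest.approx(base, rel=1e-9, abs=1e-9)


class TestModelResultsApi:
    def test_fidelity_and_summary(self, small_noiseless_dataset):
        res = ActivityFlowModel.from_dataset(
            small_noiseless_dataset, condition="EDS", use_censoring=False
        ).fit()
        assert res.accuracy >= 0.99
        assert 0.0 <= res.noise_ceiling <= 1.0
        text = res.summary()
        assert "noise ceiling" in text and "accuracy" in text

    def test_roi_restricted_prediction_same_contract(self, rng):
        """Voxel-to-voxel prediction is the same operation with targets =
        voxels of one region."""
        V, P = 40, 15
        o = rng.normal(size=V)
        w = rng.normal(size=(V, P))
        y = predict_pattern(o, w)
        roi = np.arange(5)  # restrict to a 5-voxel region
        res = ActivityFlowModel(
            (o, o), (w[:, roi], w[:, roi]), (y[roi], y[roi])
        ).fit()
        assert res.raw_accuracy == pytest.approx(1.0)
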