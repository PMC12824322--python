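"""TTM construction, group matrices, trimming, alignment and masking."""

import numpy as np
import pytest

from tests.conftest import random_connectivity_tensor, random_symmetric_ttm
from ttmdyn.cohort import ParcelTimeseries, RatingSeries
from ttmdyn.phase import ConnectivityTensor
from ttmdyn.ttm import (
    TTM,
    behavioural_ttm,
    cv_ttm,
    lag_align,
    mask_autocorr,
    match_rest_length,
    mean_ttm,
    neural_ttm,
    trim_edges,
    usable_story_length,
)


def _pearson_oracle(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    am, bm = a - a.mean(), b - b.mean()
    return float((am * bm).sum() / np.sqrt((am**2).sum() * (bm**2).sum()))


class TestNeuralTTM:
    def test_identical_slices_give_all_ones(self):
        rng = np.random.default_rng(0)
        slice_ = rng.normal(size=(4, 4))
        slice_ = (slice_ + slice_.T) / 2
        np.fill_diagonal(slice_, 1.0)
        tensor = ConnectivityTensor(
            values=np.repeat(slice_[:, :, None], 5, axis=2),
            parcel_ids=list("abcd"),
            network_label="t",
        )
        np.testing.assert_allclose(neural_ttm(tensor).values, 1.0, atol=1e-12)

    def test_mean_reflected_slice_gives_minus_one(self):
        rng = np.random.default_rng(1)
        P = 4
        iu = np.triu_indices(P, 1)
        e1 = rng.uniform(-0.5, 0.5, size=len(iu[0]))
        e2 = 2 * e1.mean() - e1  # reflect around the mean -> r = -1
        vals = np.zeros((P, P, 2))
        for t, e in enumerate((e1, e2)):
            m = np.zeros((P, P))
            m[iu] = e
            m += m.T
            np.fill_diagonal(m, 1.0)
            vals[:, :, t] = m
        ttm = neural_ttm(
            ConnectivityTensor(values=vals, parcel_ids=list("abcd"), network_label="t")
        )
        assert ttm.values[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_loop_pearson_oracle(self):
        rng = np.random.default_rng(2)
        tensor = random_connectivity_tensor(rng, n_parcels=6, n_timepoints=20)
        ttm = neural_ttm(tensor)
        iu = np.triu_indices(6, 1)
        for t in range(20):
            for s in range(20):
                expected = _pearson_oracle(
                    tensor.values[iu[0], iu[1], t], tensor.values[iu[0], iu[1], s]
                )
                assert ttm.values[t, s] == pytest.approx(expected, abs=1e-12)

    def test_positive_semidefinite_and_symmetric(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            ttm = neural_ttm(random_connectivity_tensor(rng, 5, 15))
            assert np.allclose(ttm.values, ttm.values.T)
            assert np.linalg.eigvalsh(ttm.values).min() >= -1e-8

    def test_too_few_parcels_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError, match="3 parcels"):
            neural_ttm(random_connectivity_tensor(rng, 2, 10))

    def test_zero_variance_timepoint_named(self):
        vals = np.ones((4, 4, 3))  # every slice constant -> no edge variance
        tensor = ConnectivityTensor(values=vals, parcel_ids=list("abcd"), network_label="t")
        with pytest.raises(ValueError, match="timepoint"):
            neural_ttm(tensor)


class TestBehaviouralTTM:
    def test_constant_ratings_give_all_tens(self):
        r = RatingSeries("r0", np.full(10, 5))
        np.testing.assert_allclose(behavioural_ttm(r).values, 10.0)

    def test_extreme_pair(self):
        r = RatingSeries("r0", np.array([1, 9]))
        assert behavioural_ttm(r).values[0, 1] == pytest.approx(2.0)

    def test_matches_pairwise_distance_oracle(self):
        rng = np.random.default_rng(5)
        vals = rng.integers(1, 10, size=30)
        ttm = behavioural_ttm(RatingSeries("r0", vals))
        for i in range(30):
            for j in range(30):
                assert ttm.values[i, j] == 10.0 - abs(int(vals[i]) - int(vals[j]))

    def test_diagonal_and_range_bounds(self):
        rng = np.random.default_rng(6)
        ttm = behavioural_ttm(RatingSeries("r0", rng.integers(1, 10, size=25)))
        np.testing.assert_allclose(np.diag(ttm.values), 10.0)
        assert ttm.values.min() >= 2.0 and ttm.values.max() <= 10.0

    def test_translation_invariance(self):
        vals = np.array([2, 3, 5, 4, 2, 6])
        a = behavioural_ttm(RatingSeries("r0", vals))
        b = behavioural_ttm(RatingSeries("r0", vals + 3))
        np.testing.assert_array_equal(a.values, b.values)


class TestGroupTTMs:
    def test_mean_idempotent_on_identical_stack(self):
        rng = np.random.default_rng(7)
        t = random_symmetric_ttm(rng)
        out = mean_ttm([t, t, t])
        np.testing.assert_allclose(out.values, t.values)

    def test_mean_simple_arithmetic(self):
        a = TTM(values=np.full((3, 3), 0.4), kind="neural")
        b = TTM(values=np.full((3, 3), 0.6), kind="neural")
        assert mean_ttm([a, b]).values[0, 1] == pytest.approx(0.5)

    def test_mean_matches_loop_oracle(self):
        rng = np.random.default_rng(8)
        stack = [
            behavioural_ttm(RatingSeries(f"r{i}", rng.integers(1, 10, size=12)))
            for i in range(25)
        ]
        out = mean_ttm(stack)
        expected = sum(t.values for t in stack) / 25
        np.testing.assert_allclose(out.values, expected, atol=1e-12)

    def test_cv_zero_for_identical_stack(self):
        rng = np.random.default_rng(9)
        t = random_symmetric_ttm(rng)
        t.values = np.abs(t.values) + 0.1  # keep cell means away from 0
        t.values = (t.values + t.values.T) / 2
        np.testing.assert_allclose(cv_ttm([t, t, t]).values, 0.0, atol=1e-12)

    def test_cv_hand_computed_two_subjects(self):
        a = TTM(values=np.full((2, 2), 0.4), kind="neural")
        b = TTM(values=np.full((2, 2), 0.6), kind="neural")
        out = cv_ttm([a, b])
        # sample SD of {0.4, 0.6} = 0.141421..., mean 0.5 -> CV 0.282843
        assert out.values[0, 0] == pytest.approx(0.2828427, abs=1e-6)

    def test_cv_matches_loop_oracle(self):
        rng = np.random.default_rng(10)
        stack = []
        for _ in range(16):
            v = rng.uniform(0.2, 1.0, size=(6, 6))
            v = (v + v.T) / 2
            stack.append(TTM(values=v, kind="neural"))
        out = cv_ttm(stack)
        arr = np.stack([t.values for t in stack])
        np.testing.assert_allclose(
            out.values, arr.std(axis=0, ddof=1) / arr.mean(axis=0), atol=1e-12
        )

    def test_cv_zero_mean_cell_rejected(self):
        a = TTM(values=np.array([[1.0, 0.5], [0.5, 1.0]]), kind="neural")
        b = TTM(values=np.array([[1.0, -0.5], [-0.5, 1.0]]), kind="neural")
        with pytest.raises(ValueError, match="mean is 0"):
            cv_ttm([a, b])

    def test_group_ops_commute_with_timepoint_permutation(self):
        rng = np.random.default_rng(11)
        stack = [random_symmetric_ttm(rng, T=8) for _ in range(5)]
        for t in stack:
            t.values = np.abs(t.values) + 0.2
            t.values = (t.values + t.values.T) / 2
        perm = rng.permutation(8)
        permed = [
            TTM(values=t.values[np.ix_(perm, perm)], kind=t.kind) for t in stack
        ]
        for op in (mean_ttm, cv_ttm):
            direct = op(stack).values[np.ix_(perm, perm)]
            after = op(permed).values
            np.testing.assert_allclose(direct, after, atol=1e-12)


class TestTrimAlignMatch:
    def test_trim_150_to_144_with_id_bookkeeping(self):
        t = TTM(values=np.eye(150) * 0 + np.ones((150, 150)), kind="behavioural")
        out = trim_edges(t, 3, 3)
        assert out.n_timepoints == 144
        assert out.timepoint_ids[0] == 3
        assert out.timepoint_ids[-1] == 146

    def test_zero_trim_is_identity(self):
        rng = np.random.default_rng(12)
        t = random_symmetric_ttm(rng)
        out = trim_edges(t, 0, 0)
        np.testing.assert_array_equal(out.values, t.values)

    def test_over_trim_rejected(self):
        rng = np.random.default_rng(13)
        with pytest.raises(ValueError, match="trim"):
            trim_edges(random_symmetric_ttm(rng, T=5), 3, 3)

    def test_lag_align_sizes_and_pairing(self):
        rng = np.random.default_rng(14)
        n = random_symmetric_ttm(rng, T=150)
        b = random_symmetric_ttm(rng, T=150)
        na, ba = lag_align(n, b, 3)
        assert na.n_timepoints == ba.n_timepoints == 147
        assert na.timepoint_ids[0] == 3  # neural timepoint t pairs with
        assert ba.timepoint_ids[0] == 0  # behavioural timepoint t - 3

    def test_lag_align_zero_is_identity(self):
        rng = np.random.default_rng(15)
        n, b = random_symmetric_ttm(rng), random_symmetric_ttm(rng)
        na, ba = lag_align(n, b, 0)
        assert na is n and ba is b

    def test_match_rest_length(self):
        rest = ParcelTimeseries(
            "s0", "awake", "rest", np.zeros((251, 3)), 2.0, ["a", "b", "c"]
        )
        assert match_rest_length(rest, 150).n_timepoints == 150
        assert match_rest_length(rest, 251).n_timepoints == 251
        with pytest.raises(ValueError):
            match_rest_length(rest, 0)
        with pytest.raises(ValueError, match="shorter"):
            match_rest_length(rest, 300)

    def test_usable_story_length_bookkeeping(self):
        # 156 acquired - 5 dummy scans - 1 surplus final rating = 150
        assert usable_story_length(156, 5, 1) == 150
        with pytest.raises(ValueError):
            usable_story_length(6, 5, 1)


class TestMaskAutocorr:
    def test_k0_keeps_full_lower_triangle(self):
        rng = np.random.default_rng(16)
        a, b = random_symmetric_ttm(rng, T=12), random_symmetric_ttm(rng, T=12)
        ma, mb = mask_autocorr(a, b, 0)
        assert len(ma.values) == 12 * 11 // 2
        assert np.array_equal(ma.cell_index_pairs, mb.cell_index_pairs)

    def test_t5_k1_exact_cell_enumeration(self):
        rng = np.random.default_rng(17)
        a, b = random_symmetric_ttm(rng, T=5), random_symmetric_ttm(rng, T=5)
        ma, _ = mask_autocorr(a, b, 1)
        got = {tuple(p) for p in ma.cell_index_pairs}
        assert got == {(2, 0), (3, 0), (3, 1), (4, 0), (4, 1), (4, 2)}

    def test_empty_mask_rejected(self):
        rng = np.random.default_rng(18)
        a, b = random_symmetric_ttm(rng, T=6), random_symmetric_ttm(rng, T=6)
        with pytest.raises(ValueError, match="no cells"):
            mask_autocorr(a, b, 5)

    def test_larger_k_keeps_subset_of_cells(self):
        rng = np.random.default_rng(19)
        a, b = random_symmetric_ttm(rng, T=15), random_symmetric_ttm(rng, T=15)
        for k in range(0, 10):
            pa = {tuple(p) for p in mask_autocorr(a, b, k)[0].cell_index_pairs}
            pb = {tuple(p) for p in mask_autocorr(a, b, k + 1)[0].cell_index_pairs}
            assert pb <= pa

    def test_mask_uses_original_ids_after_trim(self):
        rng = np.random.default_rng(20)
        a = trim_edges(random_symmetric_ttm(rng, T=12), 3, 3)
        b = trim_edges(random_symmetric_ttm(rng, T=12), 3, 3)
        ma, _ = mask_autocorr(a, b, 2)
        assert ma.cell_index_pairs.min() >= 3
        assert np.all(ma.cell_index_pairs[:, 0] - ma.cell_index_pairs[:, 1] > 2)


class TestTTMValidation:
    def test_asymmetric_rejected(self):
        v = np.eye(3)
        v[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            TTM(values=v, kind="neural")

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            TTM(values=np.zeros((3, 4)), kind="neural")

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            TTM(values=np.eye(3), kind="spooky")
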