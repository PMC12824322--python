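"""IntSS, level contrasts, interaction ANOVAs, Bonferroni."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tests.conftest import random_symmetric_ttm
from ttmdyn.intersubject import (
    anova_level_by_network,
    anova_level_by_task,
    bonferroni,
    contrast_levels,
    fisher_z,
    intss_pairwise,
    wilcoxon_signed_rank,
)
from ttmdyn.ttm import TTM


class TestFisherZ:
    def test_odd_increasing_zero_at_zero(self):
        r = np.linspace(-0.99, 0.99, 41)
        z = fisher_z(r)
        assert fisher_z(np.array([0.0]))[0] == 0.0
        np.testing.assert_allclose(fisher_z(-r), -z, atol=1e-12)
        assert np.all(np.diff(z) > 0)

    def test_clamped_at_unit_correlation(self):
        assert np.isfinite(fisher_z(np.array([1.0, -1.0]))).all()


class TestIntSS:
    def test_identical_ttms_similarity_one(self):
        rng = np.random.default_rng(0)
        t = random_symmetric_ttm(rng, T=12)
        m = intss_pairwise([t, t])
        assert m.values[1, 0] == pytest.approx(1.0)

    def test_sixteen_subjects_give_120_pairs(self):
        rng = np.random.default_rng(1)
        stack = [random_symmetric_ttm(rng, T=10) for _ in range(16)]
        m = intss_pairwise(stack)
        assert len(m.pair_values()) == 16 * 15 // 2 == 120

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(2)
        stack = [random_symmetric_ttm(rng, T=10) for _ in range(5)]
        m = intss_pairwise(stack)
        il = np.tril_indices(10, k=-1)
        for i in range(5):
            for j in range(i):
                a = np.arctanh(np.clip(stack[i].values[il], -1 + 1e-12, 1 - 1e-12))
                b = np.arctanh(np.clip(stack[j].values[il], -1 + 1e-12, 1 - 1e-12))
                expected = np.corrcoef(a, b)[0, 1]
                assert m.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_common_timepoint_permutation(self):
        rng = np.random.default_rng(3)
        stack = [random_symmetric_ttm(rng, T=9) for _ in range(4)]
        perm = rng.permutation(9)
        permed = [
            TTM(values=t.values[np.ix_(perm, perm)], kind="neural") for t in stack
        ]
        a = intss_pairwise(stack).values
        b = intss_pairwise(permed).values
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_zero_variance_vector_rejected(self):
        flat = TTM(values=np.ones((6, 6)), kind="neural")
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError, match="zero-variance"):
            intss_pairwise([flat, random_symmetric_ttm(rng, T=6)])


def _intss_from_pairs(values, n=16, label="net", level="awake", task="story"):
    """Build an IntSSMatrix with prescribed lower-triangle pair values."""
    m = np.eye(n)
    il = np.tril_indices(n, k=-1)
    m[il] = values
    m.T[il] = values
    from ttmdyn.intersubject import IntSSMatrix

    return IntSSMatrix(
        network_label=label, level=level, task=task, values=m,
        subject_ids=[f"s{i}" for i in range(n)],
    )


class TestContrasts:
    def test_uniform_positive_shift_detected(self):
        rng = np.random.default_rng(5)
        base = rng.uniform(0.2, 0.6, size=120)
        a = _intss_from_pairs(base + 0.1)
        b = _intss_from_pairs(base, level="deep")
        res = contrast_levels(a, b, seed=0)
        assert res.z > 0
        assert res.p_raw < 0.001
        assert res.n_pairs == 120

    def test_equal_inputs_degenerate(self):
        rng = np.random.default_rng(6)
        base = rng.uniform(0.2, 0.6, size=120)
        a = _intss_from_pairs(base)
        b = _intss_from_pairs(base, level="deep")
        res = contrast_levels(a, b, seed=0)
        assert res.p_raw == 1.0
        assert res.method == "degenerate"

    def test_small_sample_matches_exact_enumeration(self):
        # for n = 8 the p must equal the brute-force two-sided tail over
        # all 2^8 sign patterns of the rank sum
        rng = np.random.default_rng(7)
        for _ in range(10):
            d = rng.normal(0.05, 0.2, size=8)
            d = d[d != 0]
            z, p, method = wilcoxon_signed_rank(d)
            assert method == "exact"
            ranks = stats.rankdata(np.abs(d))
            mu = ranks.sum() / 2
            w_obs = ranks[d > 0].sum()
            count = 0
            for bits in product([0, 1], repeat=len(d)):
                w = sum(r for r, b in zip(ranks, bits) if b)
                if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
                    count += 1
            assert p == pytest.approx(count / 2 ** len(d))

    def test_matches_scipy_for_large_n(self):
        rng = np.random.default_rng(8)
        d = rng.normal(0.1, 0.3, size=60)
        z, p, method = wilcoxon_signed_rank(d)
        assert method == "normal-approx"
        ref = stats.wilcoxon(d, correction=False, method="approx")
        assert p == pytest.approx(ref.pvalue, rel=1e-10)
        assert np.sign(z) == np.sign(np.median(d))

    def test_bootstrap_sem_reasonable_and_seeded(self):
        rng = np.random.default_rng(9)
        base = rng.uniform(0.2, 0.6, size=120)
        d = rng.normal(0.05, 0.1, size=120)
        a = _intss_from_pairs(base + d)
        b = _intss_from_pairs(base, level="deep")
        r1 = contrast_levels(a, b, n_boot=1000, seed=3)
        r2 = contrast_levels(a, b, n_boot=1000, seed=3)
        assert r1.sem_boot == r2.sem_boot
        assert r1.sem_boot == pytest.approx(d.std() / np.sqrt(120), rel=0.25)


def _balanced_table(effect, noise_sd, rng, networks=("A", "B"), n_per_cell=20,
                    levels=(1, 2, 3)):
    rows = []
    for net, lv in product(networks, levels):
        vals = effect(net, lv) + rng.normal(0, noise_sd, size=n_per_cell)
        rows += [{"network": net, "level": lv, "value": v} for v in vals]
    return pd.DataFrame(rows)


class TestAnovaLevelByNetwork:
    def test_null_rejection_rate_near_alpha(self):
        # identical level slopes in every network: the interaction p is
        # uniform, so rejections at alpha = 0.05 stay near 5%
        rng = np.random.default_rng(10)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            df = _balanced_table(lambda n, l: 0.5 * l, 1.0, rng)
            rejections += anova_level_by_network(df).p_interaction < 0.05
        assert 0.02 <= rejections / n_rep <= 0.09

    def test_opposite_slopes_detected(self):
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(50):
            df = _balanced_table(
                lambda n, l: (0.4 if n == "A" else -0.4) * l, 0.5, rng
            )
            hits += anova_level_by_network(df).p_interaction < 0.01
        assert hits / 50 >= 0.95

    def test_equal_slopes_zero_noise_gives_zero_f(self):
        rng = np.random.default_rng(12)
        jitter = rng.normal(0, 1, size=20)  # identical pattern in every cell
        rows = []
        for net, lv in product(("A", "B"), (1, 2, 3)):
            base = 0.5 * lv + (1.0 if net == "A" else -0.5)
            rows += [{"network": net, "level": lv, "value": base + j} for j in jitter]
        res = anova_level_by_network(pd.DataFrame(rows))
        assert res.F_interaction == pytest.approx(0.0, abs=1e-18)

    def test_single_network_rejected(self):
        rng = np.random.default_rng(13)
        df = _balanced_table(lambda n, l: l, 1.0, rng, networks=("A",))
        with pytest.raises(ValueError, match="2 networks"):
            anova_level_by_network(df)


class TestAnovaLevelByTask:
    @staticmethod
    def _table(effect, noise_sd, rng, n_per_cell=20):
        rows = []
        for task, lv in product(("story", "rest"), (1, 2, 3)):
            vals = effect(task, lv) + rng.normal(0, noise_sd, size=n_per_cell)
            rows += [{"task": task, "level": lv, "value": v} for v in vals]
        return pd.DataFrame(rows)

    def test_constant_task_effect_zero_noise_gives_zero_f(self):
        rng = np.random.default_rng(14)
        jitter = rng.normal(0, 1, size=15)
        rows = []
        for task, lv in product(("story", "rest"), (1, 2, 3)):
            base = 0.3 * lv + (0.5 if task == "story" else 0.0)
            rows += [{"task": task, "level": lv, "value": base + j} for j in jitter]
        res = anova_level_by_task(pd.DataFrame(rows))
        assert res.F_interaction == pytest.approx(0.0, abs=1e-18)

    def test_story_only_slope_detected(self):
        rng = np.random.default_rng(15)
        hits = 0
        for _ in range(50):
            df = self._table(
                lambda t, l: (0.5 * l if t == "story" else 0.0), 0.4, rng
            )
            hits += anova_level_by_task(df).p_interaction < 0.01
        assert hits / 50 >= 0.95

    def test_invariant_to_task_relabelling(self):
        rng = np.random.default_rng(16)
        df = self._table(lambda t, l: (0.4 * l if t == "story" else 0.1), 0.5, rng)
        swapped = df.assign(
            task=df["task"].map({"story": "rest", "rest": "story"})
        )
        f1 = anova_level_by_task(df).F_interaction
        f2 = anova_level_by_task(swapped).F_interaction
        assert f1 == pytest.approx(f2, rel=1e-10)


class TestBonferroni:
    def test_scales_by_family_size(self):
        assert bonferroni([0.01], m=18)[0] == pytest.approx(0.18)

    def test_caps_at_one(self):
        assert bonferroni([0.2], m=18)[0] == 1.0

    def test_identity_for_single_test(self):
        assert bonferroni([0.037])[0] == pytest.approx(0.037)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.2])
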