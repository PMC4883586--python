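"""Pairwise-difference Mantel test, q-values and classification."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import cmpscore as c
from cmpscore.prediction import ANTI, NA, NS, WELL, classify, compute_qvalues


def naive_signed_spearman(dx, dy):
    """Independent implementation of the full-ordered-pair rank correlation.

    Ranks each difference vector over the doubled set {d, -d}, centers, and
    takes the plain dot-product correlation.
    """
    from scipy.stats import rankdata

    m = len(dx)
    rx = rankdata(np.concatenate([dx, -dx]))[:m] - (2 * m + 1) / 2
    ry = rankdata(np.concatenate([dy, -dy]))[:m] - (2 * m + 1) / 2
    return float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))


def exhaustive_mantel_p(x, y):
    """Oracle: enumerate every sample-label permutation of y.

    Returns (rho, p_pos, p_neg) with the identity permutation included in
    the null.
    """
    n = len(x)
    iu, ju = np.triu_indices(n, 1)
    dx = x[iu] - x[ju]
    obs = naive_signed_spearman(dx, y[iu] - y[ju])
    ge = le = total = 0
    for perm in itertools.permutations(range(n)):
        yp = y[list(perm)]
        r = naive_signed_spearman(dx, yp[iu] - yp[ju])
        ge += r >= obs - 1e-12
        le += r <= obs + 1e-12
        total += 1
    return obs, ge / total, le / total


class TestPairwiseDifferences:
    def test_signed_ordered_pairs(self):
        assert c.pairwise_differences([1, 4, 2]).tolist() == [-3, -1, 2]

    def test_constant_vector_all_zero(self):
        assert not c.pairwise_differences([5, 5, 5, 5]).any()

    def test_length_is_n_choose_2(self):
        assert len(c.pairwise_differences(np.arange(5))) == 10


class TestMantel:
    def test_identical_vectors_minimal_p(self):
        cfg = c.PredictionConfig(n_permutations=199, rng_seed=0)
        v = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6])
        res = c.mantel_test(v, v, cfg)
        assert res.rho == pytest.approx(1.0)
        assert res.p_pos == pytest.approx(1 / 200)

    def test_negated_vector_minimal_lower_p(self):
        cfg = c.PredictionConfig(n_permutations=199, rng_seed=0)
        v = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6])
        res = c.mantel_test(v, -v, cfg)
        assert res.rho == pytest.approx(-1.0)
        assert res.p_neg == pytest.approx(1 / 200)

    def test_constant_input_not_evaluable(self):
        cfg = c.PredictionConfig(n_permutations=99)
        res = c.mantel_test(np.ones(6), np.arange(6.0), cfg)
        assert not res.evaluable

    def test_too_few_samples_not_evaluable(self):
        cfg = c.PredictionConfig(n_permutations=99)
        res = c.mantel_test(
            np.array([1.0, 2.0, np.nan, np.nan]), np.array([1.0, np.nan, 3.0, 4.0]), cfg
        )
        assert not res.evaluable

    def test_missing_samples_excluded_symmetrically(self):
        cfg = c.PredictionConfig(n_permutations=199, rng_seed=1)
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([1.0, 2.1, 2.9, 4.2, 5.1, np.nan])
        res = c.mantel_test(x, y, cfg)
        assert res.n_pairs == 10  # 5 usable samples

    def test_shift_invariance_of_rho(self):
        cfg = c.PredictionConfig(n_permutations=99, rng_seed=2)
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=8), rng.normal(size=8)
        r1 = c.mantel_test(x, y, cfg).rho
        r2 = c.mantel_test(x + 100.0, y - 7.0, cfg).rho
        assert r1 == pytest.approx(r2)

    def test_joint_reordering_invariance_of_rho(self):
        cfg = c.PredictionConfig(n_permutations=99, rng_seed=2)
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=8), rng.normal(size=8)
        order = rng.permutation(8)
        r1 = c.mantel_test(x, y, cfg).rho
        r2 = c.mantel_test(x[order], y[order], cfg).rho
        assert r1 == pytest.approx(r2)

    def test_sampled_p_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(10)
        cfg = c.PredictionConfig(n_permutations=2000, rng_seed=11)
        mantel_rng = np.random.default_rng(12)
        for n in (5, 6):
            for _ in range(3):
                x, y = rng.normal(size=n), rng.normal(size=n)
                _, p_pos_ex, _ = exhaustive_mantel_p(x, y)
                res = c.mantel_test(x, y, cfg, rng=mantel_rng)
                se = np.sqrt(p_pos_ex * (1 - p_pos_ex) / cfg.n_permutations)
                assert abs(res.p_pos - p_pos_ex) <= 3 * se + 2 / cfg.n_permutations


class TestQValues:
    def test_bh_step_up_for_few_pvalues(self):
        q = compute_qvalues([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_all_equal_p_all_equal_q(self):
        q = compute_qvalues([0.2] * 20)
        assert np.allclose(q, q[0])

    def test_uniform_null_pi0_near_one(self):
        # the boundary estimate is noisy for any single draw, so check the
        # mean over independent draws of 1000 uniform p-values
        from cmpscore.prediction import estimate_pi0

        estimates = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            estimates.append(estimate_pi0(rng.uniform(1e-6, 1.0, size=1000)))
        assert all(e >= 0.6 for e in estimates)
        assert 0.8 <= np.mean(estimates) <= 1.0

    def test_monotone_in_p_and_bounded_by_one(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(1e-4, 1.0, 200)
        q = compute_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert q.max() <= 1.0

    def test_q_at_least_p_when_pi0_is_one(self):
        p = np.array([0.001, 0.2, 0.5, 0.9, 1.0])
        q = compute_qvalues(p)  # m < 10 -> pi0 = 1
        assert np.all(q >= p - 1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            compute_qvalues([0.0, 0.5])

    def test_small_m_matches_independent_bh(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(0.001, 1.0, 9)
        assert np.allclose(compute_qvalues(p), compute_qvalues_pi0_one(p))


def compute_qvalues_pi0_one(p):
    """Independent BH step-up (pi0 = 1) for cross-checking."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(q_sorted[::-1])[::-1])
    out = np.empty(m)
    out[order] = q_sorted
    return out


class TestClassify:
    def _frame(self, rho, p_pos, q_pos, p_neg=0.9, q_neg=0.9):
        df = pd.DataFrame(
            {
                "rho": [rho],
                "p_pos": [p_pos],
                "p_neg": [p_neg],
                "n_pairs": [45],
                "evaluable": [True],
                "q_pos": [q_pos],
                "q_neg": [q_neg],
            },
            index=["C1"],
        )
        return df

    def _label(self, df):
        # classify recomputes q from p; with a single p-value q == p
        out = classify(df.drop(columns=["q_pos", "q_neg"]), c.PredictionConfig())
        return out["class"].iloc[0]

    def test_well_predicted_requires_both_cutoffs(self):
        assert self._label(self._frame(0.6, 0.001, None)) == WELL
        assert self._label(self._frame(0.6, 0.02, None)) == NS

    def test_anti_predicted_on_negative_tail(self):
        df = self._frame(-0.5, 0.9, None, p_neg=0.0005, q_neg=None)
        assert self._label(df) == ANTI

    def test_q_filter_blocks_classification(self):
        # many mediocre p-values inflate q above the threshold for a p just under it
        m = 60
        rng = np.random.default_rng(0)
        p_pos = rng.uniform(0.2, 1.0, m)
        p_pos[0] = 0.009
        df = pd.DataFrame(
            {
                "rho": np.full(m, 0.4),
                "p_pos": p_pos,
                "p_neg": np.full(m, 0.5),
                "n_pairs": 45,
                "evaluable": True,
            },
            index=[f"C{i}" for i in range(m)],
        )
        out = classify(df, c.PredictionConfig())
        assert (out["class"] == NS).all()

    def test_not_evaluable_passthrough(self):
        df = pd.DataFrame(
            {
                "rho": [np.nan],
                "p_pos": [np.nan],
                "p_neg": [np.nan],
                "n_pairs": [1],
                "evaluable": [False],
            },
            index=["C1"],
        )
        assert classify(df, c.PredictionConfig())["class"].iloc[0] == NA
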