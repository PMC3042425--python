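"""AUC and DeLong test against brute-force, bootstrap and closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from nestedroc import auc_mann_whitney, delong_paired_test
from nestedroc.roc import DegenerateLabelsError


# ---------------------------------------------------------------- oracles
def auc_pair_counting(scores, labels):
    """O(n1*n0) definition: fraction of (positive, negative) pairs won."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos, neg = scores[labels == 1], scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))


def delong_brute_force(sa, sb, labels):
    """Placement covariances from explicit pair matrices (independent path)."""
    sa, sb = np.asarray(sa, float), np.asarray(sb, float)
    labels = np.asarray(labels)
    out = []
    for s in (sa, sb):
        pos, neg = s[labels == 1], s[labels == 0]
        M = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
        out.append((M.mean(), M.mean(axis=1), M.mean(axis=0)))
    (auc_a, v10_a, v01_a), (auc_b, v10_b, v01_b) = out
    n1, n0 = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n1 \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n0
    return auc_a, auc_b, max(var, 0.0)


def random_paired(rng, n, ties=False):
    labels = np.zeros(n, dtype=np.int8)
    labels[: max(1, n // 3)] = 1
    rng.shuffle(labels)
    if not 0 < labels.sum() < n:
        labels[0], labels[-1] = 1, 0
    sa = rng.standard_normal(n) + 0.5 * labels
    sb = 0.6 * sa + 0.8 * rng.standard_normal(n) + 0.3 * labels
    if ties:
        sa, sb = np.round(sa, 1), np.round(sb, 1)
    return sa, sb, labels


# -------------------------------------------------------------------- AUC
class TestAUC:
    def test_worked_example(self):
        assert auc_mann_whitney([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_all_ties_give_half(self):
        assert auc_mann_whitney(np.ones(10), [0, 1] * 5) == 0.5

    def test_perfect_separation_gives_one(self):
        scores = np.r_[np.zeros(5), np.ones(5)]
        labels = np.r_[np.zeros(5), np.ones(5)]
        assert auc_mann_whitney(scores, labels) == 1.0

    def test_single_class_raises(self):
        with pytest.raises(DegenerateLabelsError):
            auc_mann_whitney([1.0, 2.0], [1, 1])

    @pytest.mark.parametrize("ties", [False, True])
    def test_equals_pair_counting_oracle(self, ties):
        rng = np.random.default_rng(42)
        for _ in range(50):
            s, _, labels = random_paired(rng, int(rng.integers(4, 40)), ties)
            assert auc_mann_whitney(s, labels) == pytest.approx(
                auc_pair_counting(s, labels), abs=1e-12
            )

    def test_equals_trapezoidal_roc_area(self):
        """Same number sklearn computes by sweeping thresholds."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(8)
        for ties in (False, True):
            s, _, labels = random_paired(rng, 60, ties)
            assert auc_mann_whitney(s, labels) == pytest.approx(
                roc_auc_score(labels, s), abs=1e-12
            )

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=40, deadline=None)
    def test_monotone_transform_invariance_and_reversal(self, seed):
        rng = np.random.default_rng(seed)
        s, _, labels = random_paired(rng, 30)
        a = auc_mann_whitney(s, labels)
        assert auc_mann_whitney(np.exp(s), labels) == pytest.approx(a, abs=1e-12)
        assert auc_mann_whitney(3 * s - 7, labels) == pytest.approx(a, abs=1e-12)
        assert auc_mann_whitney(-s, labels) == pytest.approx(1 - a, abs=1e-12)


# ----------------------------------------------------------------- DeLong
class TestDeLong:
    def test_identical_scores_degenerate(self):
        rng = np.random.default_rng(0)
        s, _, labels = random_paired(rng, 40)
        cmp = delong_paired_test(s, s.copy(), labels)
        assert cmp.degenerate
        assert cmp.p_value == 1.0
        assert cmp.auc_restricted == cmp.auc_expanded

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(1)
        sa, sb, labels = random_paired(rng, 80)
        ab = delong_paired_test(sa, sb, labels)
        ba = delong_paired_test(sb, sa, labels)
        assert ab.z_stat == pytest.approx(-ba.z_stat, abs=1e-12)
        assert ab.p_value == pytest.approx(ba.p_value, abs=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            delong_paired_test([1.0, 2.0], [1.0], [0, 1])

    @pytest.mark.parametrize("ties", [False, True])
    def test_matches_brute_force_pair_matrices(self, ties):
        rng = np.random.default_rng(17)
        for _ in range(30):
            sa, sb, labels = random_paired(rng, int(rng.integers(6, 50)), ties)
            cmp = delong_paired_test(sa, sb, labels)
            auc_a, auc_b, var = delong_brute_force(sa, sb, labels)
            assert cmp.auc_restricted == pytest.approx(auc_a, abs=1e-12)
            assert cmp.auc_expanded == pytest.approx(auc_b, abs=1e-12)
            assert cmp.var_diff == pytest.approx(var, abs=1e-12)

    def test_variance_never_negative_many_trials(self):
        rng = np.random.default_rng(99)
        for _ in range(10_000):
            sa, sb, labels = random_paired(rng, int(rng.integers(4, 30)))
            cmp = delong_paired_test(sa, sb, labels)
            assert cmp.var_diff >= 0.0
            assert 0.0 < cmp.p_value <= 1.0

    def test_variance_against_paired_bootstrap(self):
        """DeLong var(diff) tracks a stratified paired bootstrap (median over
        200 datasets within 25% relative error)."""
        rng = np.random.default_rng(2024)
        n, n_boot = 100, 2000
        rel_errors = []
        for _ in range(200):
            sa, sb, labels = random_paired(rng, n)
            cmp = delong_paired_test(sa, sb, labels)
            pos, neg = labels == 1, labels == 0
            Da = (sa[pos][:, None] > sa[neg][None, :]) + 0.5 * (
                sa[pos][:, None] == sa[neg][None, :]
            )
            Db = (sb[pos][:, None] > sb[neg][None, :]) + 0.5 * (
                sb[pos][:, None] == sb[neg][None, :]
            )
            D = Da - Db
            n1, n0 = D.shape
            rows = rng.integers(0, n1, size=(n_boot, n1))
            cols = rng.integers(0, n0, size=(n_boot, n0))
            diffs = np.array(
                [D[np.ix_(rows[b], cols[b])].mean() for b in range(n_boot)]
            )
            rel_errors.append(abs(cmp.var_diff - diffs.var(ddof=1)) / diffs.var(ddof=1))
        assert np.median(rel_errors) < 0.25

    def test_single_score_variance_approaches_binormal_truth(self):
        """For one AUC the placement variance S10/n1 + S01/n0 must approach
        the exact binormal sampling variance, whose Q1/Q2 terms are
        bivariate-normal orthant probabilities (correlation 1/2)."""
        from nestedroc.roc import _placements, _split_labels

        mu, n = 0.7, 4000
        rng = np.random.default_rng(7)
        labels = np.r_[np.ones(n // 2, dtype=np.int8), np.zeros(n // 2, dtype=np.int8)]
        scores = rng.standard_normal(n) + mu * labels
        pos, neg = _split_labels(labels)
        auc_hat, v10, v01 = _placements(scores, pos, neg)
        n1, n0 = n // 2, n // 2
        var_hat = v10.var(ddof=1) / n1 + v01.var(ddof=1) / n0

        A = stats.norm.cdf(mu / np.sqrt(2))
        bvn = stats.multivariate_normal(mean=[0, 0], cov=[[1, 0.5], [0.5, 1]])
        q = bvn.cdf([mu / np.sqrt(2), mu / np.sqrt(2)])  # = Q1 = Q2 here
        var_true = (
            A * (1 - A) + (n1 - 1) * (q - A**2) + (n0 - 1) * (q - A**2)
        ) / (n1 * n0)
        assert var_hat == pytest.approx(var_true, rel=0.10)
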