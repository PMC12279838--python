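"""Moderated t-test: oracle agreement, limiting cases, null calibration.

The oracle below re-implements the moment estimator from the definitions
alone (scipy root-finding on the trigamma equation, per-feature loops), with
no code shared with the package's vectorized implementation.
"""

import numpy as np
import pytest
from scipy import special, stats
from scipy.optimize import brentq

from crossmir import ExpressionMatrix, SampleGroups, moderated_t_test, run_dea_pair

from conftest import make_matrix


def _groups(n1, n2):
    ids = [f"c{i}" for i in range(n1)] + [f"d{i}" for i in range(n2)]
    return ids, SampleGroups(
        {s: ("control" if s.startswith("c") else "diseased") for s in ids}
    )


def _matrix(values, ids):
    values = np.asarray(values, float)
    return ExpressionMatrix(
        [f"f{i}" for i in range(values.shape[0])], ids, values, "compressed"
    )


def oracle_moderated_t(values, n1, n2):
    """Brute-force moderated t: per-feature loops + brentq on the trigamma eq."""
    G = values.shape[0]
    d = n1 + n2 - 2
    logfc = np.empty(G)
    s2 = np.empty(G)
    for g in range(G):
        a, b = values[g, :n1], values[g, n1:]
        logfc[g] = b.mean() - a.mean()
        s2[g] = (np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)) / d
    e = np.log(s2) - special.digamma(d / 2) + np.log(d / 2)
    var_e = np.var(e, ddof=1)
    rhs = var_e - special.polygamma(1, d / 2)
    if rhs <= 0:
        d0 = np.inf
        s0_sq = np.exp(np.mean(e))
        s2_post = np.full(G, s0_sq)
        df = np.inf
    else:
        half_d0 = brentq(lambda x: special.polygamma(1, x) - rhs, 1e-8, 1e8)
        d0 = 2 * half_d0
        s0_sq = np.exp(np.mean(e) + special.digamma(half_d0) - np.log(half_d0))
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df = d + d0
    t = logfc / np.sqrt(s2_post * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(np.abs(t), df)
    return logfc, t, p, d0, s0_sq


class TestModeratedT:
    def test_identical_group_means_null_feature(self):
        ids, groups = _groups(3, 3)
        v = np.vstack([
            [1.0, 2.0, 3.0, 3.0, 1.0, 2.0],   # same mean, same values
            [0.1, 0.4, 0.2, 0.9, 0.8, 0.6],   # non-null filler
            [0.5, 0.2, 0.6, 0.1, 0.5, 0.4],
        ])
        res = moderated_t_test(_matrix(v, ids), groups)
        assert res.logfc[0] == pytest.approx(0.0, abs=1e-12)
        assert res.moderated_t[0] == pytest.approx(0.0, abs=1e-12)
        assert res.p_raw[0] == pytest.approx(1.0, abs=1e-12)

    def test_equal_variances_give_infinite_prior_df(self):
        # all features share s_g^2 exactly -> var(e) = 0 < trigamma(d/2)
        ids, groups = _groups(3, 3)
        base = np.array([0.0, 1.0, 2.0, 0.5, 1.5, 2.5])
        v = np.vstack([base + shift for shift in np.linspace(0, 1, 8)])
        res = moderated_t_test(_matrix(v, ids), groups)
        assert np.isinf(res.d0)
        # every feature has s_g^2 = 1 and d = 4, so the prior reduces to
        # exp(e) with e = log 1 - digamma(2) + log 2, shared by all features
        expected_s0 = float(np.exp(-special.digamma(2.0) + np.log(2.0)))
        assert res.s0_sq == pytest.approx(expected_s0, rel=1e-9)
        # p-values come from the normal (infinite-df) limit
        z = res.logfc / np.sqrt(expected_s0 * (1 / 3 + 1 / 3))
        np.testing.assert_allclose(res.p_raw, 2 * stats.norm.sf(np.abs(z)), atol=1e-9)

    def test_matches_independent_oracle_to_1e6(self):
        rng = np.random.default_rng(42)
        n1 = n2 = 4
        # heterogeneous variances so d0 is finite
        sds = rng.uniform(0.1, 2.0, size=20)
        v = rng.normal(0, 1, size=(20, n1 + n2)) * sds[:, None]
        ids, groups = _groups(n1, n2)
        res = moderated_t_test(_matrix(v, ids), groups)
        logfc, t, p, d0, s0_sq = oracle_moderated_t(v, n1, n2)
        assert res.d0 == pytest.approx(d0, rel=1e-6)
        assert res.s0_sq == pytest.approx(s0_sq, rel=1e-6)
        np.testing.assert_allclose(res.logfc, logfc, atol=1e-9)
        np.testing.assert_allclose(res.moderated_t, t, atol=1e-6)
        np.testing.assert_allclose(res.p_raw, p, atol=1e-6)

    def test_d0_zero_reduces_to_pooled_t(self):
        rng = np.random.default_rng(7)
        v = rng.normal(size=(15, 9))
        ids, groups = _groups(4, 5)
        res = moderated_t_test(_matrix(v, ids), groups, d0_override=0.0)
        t_ref, p_ref = stats.ttest_ind(v[:, 4:], v[:, :4], axis=1, equal_var=True)
        np.testing.assert_allclose(res.moderated_t, t_ref, atol=1e-9)
        np.testing.assert_allclose(res.p_raw, p_ref, atol=1e-9)

    def test_logfc_invariant_to_global_shift(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=(10, 8))
        ids, groups = _groups(4, 4)
        r1 = moderated_t_test(_matrix(v, ids), groups)
        r2 = moderated_t_test(_matrix(v + 7.3, ids), groups)
        np.testing.assert_allclose(r1.logfc, r2.logfc, atol=1e-9)

    def test_p_in_unit_interval_and_monotone_in_t(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=(200, 10))
        ids, groups = _groups(5, 5)
        res = moderated_t_test(_matrix(v, ids), groups)
        assert np.all(res.p_raw > 0) and np.all(res.p_raw <= 1)
        order = np.argsort(np.abs(res.moderated_t))
        assert np.all(np.diff(res.p_raw[order]) <= 1e-12)

    def test_small_group_rejected(self):
        ids, groups = _groups(1, 5)
        v = np.random.default_rng(0).normal(size=(4, 6))
        with pytest.raises(ValueError, match=">=2"):
            moderated_t_test(_matrix(v, ids), groups)

    def test_null_pvalues_uniform(self):
        # 1000 null features: raw p-values should pass a KS uniformity test
        rng = np.random.default_rng(11)
        v = rng.normal(size=(1000, 10))
        ids, groups = _groups(5, 5)
        res = moderated_t_test(_matrix(v, ids), groups)
        ks = stats.kstest(res.p_raw, "uniform")
        assert ks.pvalue > 0.01


class TestRunDeaPair:
    def test_identical_inputs_identical_results(self):
        rng = np.random.default_rng(1)
        ids, groups = _groups(4, 4)
        Y = _matrix(rng.normal(size=(30, 8)), ids)
        a, b = run_dea_pair(Y, Y, groups)
        np.testing.assert_array_equal(a.logfc, b.logfc)
        np.testing.assert_array_equal(a.p_raw, b.p_raw)

    def test_positive_affine_prediction_scales_logfc(self):
        rng = np.random.default_rng(2)
        ids, groups = _groups(4, 4)
        v = rng.normal(size=(30, 8))
        Y = _matrix(v, ids)
        Yp = _matrix(1.8 * v + 0.2, ids)
        a, b = run_dea_pair(Y, Yp, groups)
        np.testing.assert_allclose(b.logfc, 1.8 * a.logfc, atol=1e-9)

    def test_mismatched_features_rejected(self):
        rng = np.random.default_rng(3)
        ids, groups = _groups(3, 3)
        Y1 = _matrix(rng.normal(size=(5, 6)), ids)
        Y2 = ExpressionMatrix([f"x{i}" for i in range(5)], ids, rng.normal(size=(5, 6)), "compressed")
        with pytest.raises(ValueError, match="feature"):
            run_dea_pair(Y1, Y2, groups)
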