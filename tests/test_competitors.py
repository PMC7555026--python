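import math
import warnings

import numpy as np
import pytest

from hiscom_gxe.competitors import (
    SnpLevelResults,
    effective_tests_gates,
    effective_tests_li_ji,
    ge_gates,
    ge_minp,
    ge_tprod,
    ge_tts,
    snp_gxe_scan,
    snp_gxe_test,
    tprod_statistic,
    tts_statistic,
)
from conftest import binom99_bounds


def zaykin_truncated_product_cdf(w, k, tau):
    """Analytic null CDF of the truncated p-value product for k independent
    uniform p-values (used as an independence-limit oracle)."""
    if w >= 1.0:
        return 1.0
    total = 0.0
    for j in range(1, k + 1):
        c = math.comb(k, j) * (1 - tau) ** (k - j)
        if w > tau**j:
            total += c * tau**j
        else:
            ln_term = j * math.log(tau) - math.log(w)
            total += c * w * sum(ln_term**s / math.factorial(s) for s in range(j))
    return total


# ---------------------------------------------------------------------------
# SNP-level test


def test_large_effect_detected(rng):
    n = 500
    x = rng.integers(0, 3, n).astype(float)
    z = rng.standard_normal(n)
    y = 1.0 * x * z + rng.standard_normal(n)
    assert snp_gxe_test(y, x, z) < 1e-6


def test_constant_snp_is_collinear(rng):
    n = 100
    with pytest.warns(RuntimeWarning, match="collinear"):
        p = snp_gxe_test(rng.standard_normal(n), np.ones(n), rng.standard_normal(n))
    assert p == 1.0


def test_matches_statsmodels_ols(rng):
    import statsmodels.api as sm

    n = 150
    x = rng.integers(0, 3, n).astype(float)
    z = rng.standard_normal(n)
    C = rng.standard_normal((n, 2))
    y = 0.3 * x + 0.2 * z + 0.25 * x * z + C[:, 0] + rng.standard_normal(n)
    ours = snp_gxe_test(y, x, z, C)
    A = sm.add_constant(np.column_stack([x, z, x * z, C]))
    ref = sm.OLS(y, A).fit().pvalues[3]
    assert ours == pytest.approx(ref, rel=1e-10)


def test_null_calibration_of_snp_test():
    rng = np.random.default_rng(101)
    n_rep = 1000
    hits = 0
    for _ in range(n_rep):
        x = rng.integers(0, 3, 100).astype(float)
        z = rng.standard_normal(100)
        y = rng.standard_normal(100)
        hits += snp_gxe_test(y, x, z) <= 0.05
    lo, hi = binom99_bounds(n_rep, 0.05)
    assert lo <= hits / n_rep <= hi


# ---------------------------------------------------------------------------
# effective numbers


def test_effective_tests_limits():
    eye = np.eye(5)
    ones = np.ones((5, 5))
    assert effective_tests_li_ji(eye) == pytest.approx(5.0)
    assert effective_tests_li_ji(ones) == pytest.approx(1.0)
    assert effective_tests_gates(eye) == pytest.approx(5.0)
    assert effective_tests_gates(ones) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# combiners


def test_single_snp_reduces_to_snp_pvalue():
    res = SnpLevelResults(np.array([0.037]), np.eye(1))
    assert ge_minp(res) == pytest.approx(0.037)
    assert ge_gates(res) == pytest.approx(0.037)


def test_minp_independence_limit():
    res = SnpLevelResults(np.array([0.01, 0.3, 0.5, 0.7, 0.9]), np.eye(5))
    assert ge_minp(res) == pytest.approx(1 - 0.99**5, rel=1e-12)


def test_minp_full_redundancy():
    res = SnpLevelResults(np.full(5, 0.02), np.ones((5, 5)))
    assert ge_minp(res) == pytest.approx(0.02)


def test_gates_reduces_to_simes_under_independence():
    p = np.array([0.01, 0.2, 0.5])
    res = SnpLevelResults(p, np.eye(3))
    simes = np.min(3 * np.sort(p) / np.arange(1, 4))
    assert ge_gates(res) == pytest.approx(simes, rel=1e-12)


def test_gates_and_minp_duplication_invariance(rng):
    n, k = 400, 4
    X = rng.integers(0, 3, (n, k)).astype(float)
    z = rng.standard_normal(n)
    y = 0.15 * X[:, 1] * z + rng.standard_normal(n)
    base = snp_gxe_scan(y, X, z)
    dup = snp_gxe_scan(y, np.column_stack([X, X[:, 0]]), z)
    assert ge_gates(dup) == pytest.approx(ge_gates(base), abs=0.01)
    assert ge_minp(dup) == pytest.approx(ge_minp(base), abs=0.01)


def test_truncated_statistics_arithmetic():
    assert tts_statistic([0.2, 0.6, 0.9], tau=0.05) == 0.0
    assert tts_statistic([0.01], tau=0.05) == pytest.approx(0.98)
    assert tprod_statistic([0.2, 0.6], tau=0.05) == 1.0
    assert tprod_statistic([0.01, 0.04, 0.5], tau=0.05) == pytest.approx(4e-4)


def test_tprod_matches_zaykin_formula_under_independence():
    """Permutation p-value of the truncated product agrees with the analytic
    independence-limit null within Monte-Carlo error."""
    rng = np.random.default_rng(11)
    n_perm = 499
    for rep in range(8):
        X = rng.integers(0, 3, (300, 10)).astype(float)
        z = rng.standard_normal(300)
        y = rng.standard_normal(300)
        obs = tprod_statistic(snp_gxe_scan(y, X, z).p_values, 0.05)
        p_perm = ge_tprod(y, X, z, tau=0.05, n_perm=n_perm, seed=rep)
        p_ref = zaykin_truncated_product_cdf(obs, 10, 0.05)
        mc3 = 3 * math.sqrt(max(p_ref * (1 - p_ref), 1e-4) / (n_perm + 1))
        assert p_perm == pytest.approx(p_ref, abs=mc3 + 1.0 / (n_perm + 1))


def test_tts_permutation_pvalue_bounds(rng):
    n = 200
    X = rng.integers(0, 3, (n, 5)).astype(float)
    z = rng.standard_normal(n)
    y = 0.6 * X[:, 2] * z + rng.standard_normal(n)
    p_strong = ge_tts(y, X, z, n_perm=199, seed=0)
    p_null = ge_tts(rng.standard_normal(n), X, z, n_perm=199, seed=0)
    assert 1 / 200 <= p_strong <= 1.0
    assert p_strong < 0.05 < p_null


def test_combiners_return_valid_probabilities(rng):
    n = 150
    X = rng.integers(0, 3, (n, 6)).astype(float)
    z = rng.standard_normal(n)
    y = rng.standard_normal(n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = snp_gxe_scan(y, X, z)
        vals = [
            ge_minp(res),
            ge_gates(res),
            ge_tts(y, X, z, n_perm=99, seed=1),
            ge_tprod(y, X, z, n_perm=99, seed=1),
        ]
    assert all(0.0 <= v <= 1.0 for v in vals)
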