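"""SNP-level interaction regression and gene-level p-value combination tests.

Comparator methods for the latent-component test: each SNP in a gene is
tested for interaction with the environment by ordinary least squares
(``y ~ 1 + x + z + x*z + covariates``, two-sided t-test on the product
term), and the K SNP-level p-values are combined into a single gene-level
p-value by one of four classical rules:

* ``ge_minp``  -- minimum p, Sidak-corrected with an effective number of
  tests (Li-Ji eigenvalue method on the genotype correlation matrix);
* ``ge_gates`` -- extended Simes (GATES): min over sorted p of
  ``Me * p_(j) / Me_(j)``, with effective numbers from the p-value
  correlation matrix (polynomial approximation from genotype r);
* ``ge_tts``   -- truncated tail strength with threshold tau, permutation null;
* ``ge_tprod`` -- truncated p-value product with threshold tau, permutation null.

The truncated statistics have no convenient analytic null under linkage
disequilibrium, so their significance is obtained from phenotype
permutations of the SNP-level tests (same permutation engine as the
latent-component test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SnpLevelResults",
    "snp_gxe_test",
    "snp_gxe_scan",
    "effective_tests_li_ji",
    "effective_tests_gates",
    "gates_pvalue_correlation",
    "ge_minp",
    "ge_gates",
    "ge_tts",
    "ge_tprod",
    "tts_statistic",
    "tprod_statistic",
]


@dataclass
class SnpLevelResults:
    """Per-SNP interaction p-values plus the gene's genotype correlation matrix."""

    p_values: np.ndarray
    genotype_corr: np.ndarray


def _design(x: np.ndarray, z: np.ndarray, C: np.ndarray | None) -> np.ndarray:
    cols = [np.ones_like(x), x, z, x * z]
    if C is not None and C.size:
        cols.append(C)
    return np.column_stack(cols)


def snp_gxe_test(y, x_k, z, C=None) -> float:
    """Two-sided OLS t-test p-value for the single-SNP interaction term.

    Returns p = 1 with a warning when the design is collinear (e.g. a
    monomorphic SNP).
    """
    y = np.asarray(y, float).ravel()
    x = np.asarray(x_k, float).ravel()
    z = np.asarray(z, float).ravel()
    if C is not None:
        C = np.asarray(C, float)
        if C.ndim == 1:
            C = C[:, None]
    A = _design(x, z, C)
    n, q = A.shape
    if np.linalg.matrix_rank(A) < q:
        warnings.warn("collinear interaction design; returning p = 1", RuntimeWarning)
        return 1.0
    AtA_inv = np.linalg.inv(A.T @ A)
    beta = AtA_inv @ (A.T @ y)
    resid = y - A @ beta
    dof = n - q
    s2 = float(resid @ resid) / dof
    se = np.sqrt(s2 * AtA_inv[3, 3])
    t = beta[3] / se
    return float(2.0 * stats.t.sf(abs(t), dof))


def snp_gxe_scan(y, X, z, C=None) -> SnpLevelResults:
    """SNP-level interaction p-values for every column of a gene's genotypes."""
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    p = np.array([snp_gxe_test(y, X[:, k], z, C) for k in range(X.shape[1])])
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.atleast_2d(np.nan_to_num(corr, nan=0.0))
    np.fill_diagonal(corr, 1.0)
    return SnpLevelResults(p_values=p, genotype_corr=corr)


def _permuted_snp_pvalues(y, X, z, C, perms: np.ndarray) -> np.ndarray:
    """SNP-level interaction p-values for each phenotype permutation.

    Vectorized over permutations: the design is permutation-invariant, so
    per SNP only the cross-products with y change.  Returns (B, K).
    """
    y = np.asarray(y, float).ravel()
    X = np.asarray(X, float)
    z = np.asarray(z, float).ravel()
    if C is not None:
        C = np.asarray(C, float)
        if C.ndim == 1:
            C = C[:, None]
    B, n = perms.shape
    k = X.shape[1]
    Y = y[perms].T  # N x B
    out = np.ones((B, k))
    for j in range(k):
        A = _design(X[:, j], z, C)
        q = A.shape[1]
        if np.linalg.matrix_rank(A) < q:
            continue  # p = 1 for every permutation
        AtA_inv = np.linalg.inv(A.T @ A)
        P = AtA_inv @ A.T  # q x N
        beta = P @ Y  # q x B
        fitted = A @ beta
        rss = np.square(Y - fitted).sum(axis=0)
        dof = n - q
        se = np.sqrt(rss / dof * AtA_inv[3, 3])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta[3] / se, 0.0)
        out[:, j] = 2.0 * stats.t.sf(np.abs(t), dof)
    return out


# ---------------------------------------------------------------------------
# effective numbers of tests


def effective_tests_li_ji(corr: np.ndarray) -> float:
    """Li-Ji effective number of independent tests from a correlation matrix.

    Me = sum_i [ I(|l_i| >= 1) + (|l_i| - floor(|l_i|)) ] over eigenvalues l_i.
    """
    lam = np.abs(np.linalg.eigvalsh(np.atleast_2d(np.asarray(corr, float))))
    return float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))


def gates_pvalue_correlation(r: np.ndarray) -> np.ndarray:
    """Approximate correlation between SNP-level p-values from genotype r.

    Sixth-order polynomial fit used by the extended-Simes (GATES) procedure.
    """
    r = np.asarray(r, float)
    return (
        0.2982 * r**6
        - 0.0127 * r**5
        + 0.0588 * r**4
        + 0.0099 * r**3
        + 0.6281 * r**2
        - 0.0009 * r
    )


def effective_tests_gates(corr: np.ndarray) -> float:
    """GATES effective number: Me = K - sum_{l_i > 1} (l_i - 1)."""
    corr = np.atleast_2d(np.asarray(corr, float))
    lam = np.linalg.eigvalsh(corr)
    return float(corr.shape[0] - np.sum(np.where(lam > 1, lam - 1, 0.0)))


# ---------------------------------------------------------------------------
# combiners


def ge_minp(results: SnpLevelResults) -> float:
    """Sidak-adjusted minimum p-value with the Li-Ji effective test count."""
    p = np.asarray(results.p_values, float)
    me = effective_tests_li_ji(results.genotype_corr)
    return float(min(1.0, 1.0 - (1.0 - p.min()) ** me))


def ge_gates(results: SnpLevelResults, corr_method: str = "pvalue-poly") -> float:
    """Extended-Simes (GATES) gene-level p-value.

    ``corr_method``: "pvalue-poly" transforms genotype correlations into
    p-value correlations with the GATES polynomial before computing
    effective numbers; "genotype" uses |r| directly.
    """
    p = np.asarray(results.p_values, float)
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    r = np.asarray(results.genotype_corr, float)[np.ix_(order, order)]
    if corr_method == "pvalue-poly":
        pcorr = gates_pvalue_correlation(r)
    elif corr_method == "genotype":
        pcorr = np.abs(r)
    else:
        raise ValueError(f"unknown corr_method {corr_method!r}")
    np.fill_diagonal(pcorr, 1.0)
    k = p.size
    me_all = effective_tests_gates(pcorr)
    me_top = np.array([effective_tests_gates(pcorr[: j + 1, : j + 1]) for j in range(k)])
    return float(min(1.0, np.min(me_all * p_sorted / me_top)))


def tts_statistic(p_values, tau: float = 0.05) -> float:
    """Truncated tail strength: (1/K) sum over p_(j) <= tau of (1 - p_(j)(K+1)/j)."""
    p = np.sort(np.asarray(p_values, float))
    k = p.size
    j = np.arange(1, k + 1)
    mask = p <= tau
    return float(np.sum(1.0 - p[mask] * (k + 1) / j[mask]) / k)


def tprod_statistic(p_values, tau: float = 0.05) -> float:
    """Truncated product of p-values: prod over p_j <= tau (1 if none)."""
    p = np.asarray(p_values, float)
    return float(np.prod(p[p <= tau])) if np.any(p <= tau) else 1.0


def _perm_indices(n: int, n_perm: int, seed) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return np.array([rng.permutation(n) for _ in range(n_perm)])


def ge_tts(y, X, z, C=None, *, tau: float = 0.05, n_perm: int = 999, seed=None) -> float:
    """Gene-level truncated-tail-strength p-value by phenotype permutation.

    Larger statistics are more extreme; the add-one estimator guarantees
    p in [1/(B+1), 1].
    """
    obs = tts_statistic(snp_gxe_scan(y, X, z, C).p_values, tau)
    perms = _perm_indices(np.asarray(y).size, n_perm, seed)
    null_p = _permuted_snp_pvalues(y, X, z, C, perms)
    null = np.array([tts_statistic(row, tau) for row in null_p])
    return float((1.0 + np.count_nonzero(null >= obs)) / (1.0 + n_perm))


def ge_tprod(y, X, z, C=None, *, tau: float = 0.05, n_perm: int = 999, seed=None) -> float:
    """Gene-level truncated-product p-value by phenotype permutation.

    Smaller products are more extreme (the empty product counts as 1).
    """
    obs = tprod_statistic(snp_gxe_scan(y, X, z, C).p_values, tau)
    perms = _perm_indices(np.asarray(y).size, n_perm, seed)
    null_p = _permuted_snp_pvalues(y, X, z, C, perms)
    null = np.array([tprod_statistic(row, tau) for row in null_p])
    return float((1.0 + np.count_nonzero(null <= obs)) / (1.0 + n_perm))
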