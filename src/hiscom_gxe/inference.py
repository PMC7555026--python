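"""Permutation null distribution for the latent interaction coefficient,
empirical p-values, and multiple-testing adjustment across genes.

The null hypothesis is beta12 = 0 (no latent gene-environment interaction).
Significance is assessed by re-running the full ALS fit at the same ridge
penalty for every permutation replicate and comparing |beta12| against its
permutation distribution with the add-one estimator

    p = (1 + #{ |beta12*| >= |beta12| }) / (1 + B).

Ties count as exceedances, so p is never zero and p in [1/(B+1), 1].

Two permutation schemes are available.  The default, ``"freedman-lane"``,
permutes the residuals of the nuisance regression of the phenotype on SNP
and environment main effects plus covariates and adds them back onto the
nuisance fit, so the permuted replicates retain the main-effect structure
while destroying any interaction.  ``"phenotype"`` permutes the raw
phenotype vector; it is exact when the phenotype is fully exchangeable
under the null (no main effects), but becomes conservative when a strong
unpermuted main effect lets the adaptive gene weights chase noise in the
replicates — see the methods documentation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .model import (
    HisComGxE,
    _als_gram,
    _fit_prepared,
    _GramCache,
    _standardize_cols,
)

logger = logging.getLogger(__name__)


@dataclass
class PermutationResult:
    """Observed statistic, permutation null and empirical p-value for one gene."""

    observed_stat: float
    null_stats: np.ndarray
    p_value: float
    n_perm: int
    seed: object
    n_failed: int = 0
    flagged: bool = False


@dataclass
class GxEResult:
    """Per-gene scan record."""

    gene_id: str
    n_snps: int
    beta12: float
    p_perm: float
    q_value: float = float("nan")


def permutation_pvalue(
    y,
    X,
    z,
    C=None,
    *,
    lambda_s: float,
    n_perm: int = 5000,
    seed=None,
    scheme: str = "freedman-lane",
    penalize_b: bool = True,
    tol: float = 1e-6,
    max_iter: int = 1000,
    init: str = "uniform",
) -> PermutationResult:
    """Permutation p-value for the latent interaction coefficient.

    The ridge penalty is held fixed at ``lambda_s`` across permutations.
    Replicate fits that do not converge are tallied; if more than 5% fail
    the result is flagged.  Deterministic given ``seed`` (an int or a
    ``numpy.random.SeedSequence``) regardless of execution order: all
    permutations are drawn up front.
    """
    X = HisComGxE._coerce(X)
    y = np.asarray(y, dtype=float).ravel()
    z = np.asarray(z, dtype=float).ravel()
    if C is not None:
        C = np.asarray(C, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    n, k = X.shape

    fit = _fit_prepared(
        y, X, z, C, float(lambda_s),
        init=init, tol=tol, max_iter=max_iter, penalize_b=penalize_b,
    )
    observed = abs(fit.beta12)
    st = fit._work
    ys = (y - st["y_mean"]) / st["y_sd"]
    # the standardized design is permutation-invariant; build its Gram once
    Xs, _, _ = _standardize_cols(X, st["x_means"], st["x_sds"])
    zs = (z - st["z_mean"]) / st["z_sd"]
    Cs = np.empty((n, 0))
    if C is not None and C.shape[1] > 0:
        Cs, _, _ = _standardize_cols(C, st["c_means"], st["c_sds"])
    cache = _GramCache(Xs, zs, Cs)
    w0 = st["w"].copy()
    sqrt_n = np.sqrt(n)
    y_sd = st["y_sd"]
    MtM = cache.MtM

    if scheme == "phenotype":
        base = ys
        nuisance_fit = None
    elif scheme == "freedman-lane":
        Dn = np.column_stack([np.ones(n), Xs, zs, Cs])
        coef, *_ = np.linalg.lstsq(Dn, ys, rcond=None)
        nuisance_fit = Dn @ coef
        base = ys - nuisance_fit
    else:
        raise ValueError(f"unknown permutation scheme {scheme!r}")

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    null = np.empty(n_perm)
    n_failed = 0
    for b in range(n_perm):
        yb = base[perms[b]]
        if nuisance_fit is not None:
            yb = nuisance_fit + yb
            yb = yb - yb.mean()
            sd = np.sqrt(np.mean(yb * yb))
            if sd > 0:
                yb = yb / sd
        w, bcoef, _, conv, _ = _als_gram(
            cache, cache.y_products(yb), float(lambda_s), w0, tol, max_iter,
            penalize_b,
        )
        if not conv:
            n_failed += 1
        nrm_r = np.sqrt(max(w @ (MtM @ w), 0.0))
        # |beta12| on the constraint/original scale
        null[b] = abs(bcoef[2]) * nrm_r / sqrt_n * y_sd if nrm_r > 0 else 0.0
    if n_failed:
        logger.warning("%d/%d permutation fits did not converge", n_failed, n_perm)
    flagged = n_failed > 0.05 * n_perm
    p = (1.0 + np.count_nonzero(null >= observed)) / (1.0 + n_perm)
    return PermutationResult(
        observed_stat=observed,
        null_stats=null,
        p_value=float(p),
        n_perm=n_perm,
        seed=seed,
        n_failed=n_failed,
        flagged=flagged,
    )


def bonferroni_threshold(alpha: float = 0.05, n_genes: int = 1) -> float:
    """Family-wise significance threshold alpha / n_genes."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    return alpha / n_genes


def bh_qvalues(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
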