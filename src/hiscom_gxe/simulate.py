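"""Synthetic genotype/phenotype generator and type-I-error / power harnesses.

Genotypes emulate LD-structured common variants with a Gaussian-copula
surrogate: two independent haplotype draws per subject from an AR(1)
latent normal are thresholded at the Hardy-Weinberg quantile of each SNP's
minor allele frequency and summed, so marginals follow HWE exactly and
between-SNP correlation decays geometrically with distance.

Phenotypes follow the additive interaction model

    y_i = beta0 + beta1 * sum_k w_k x_ik + beta2 * e_i
          + beta12 * (sum_k w_k x_ik) * e_i + eps_i,

with e_i the standardized environment, eps_i standard normal, and weights
w_k nonzero only on a randomly drawn causal subset
(round(causal_fraction * K) SNPs, at least one).

The experiment harnesses are method-agnostic: any callable mapping a
simulated dataset to a p-value plugs in; the built-in registry covers the
latent-component permutation test and the four p-value combiners.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .competitors import ge_gates, ge_minp, ge_tprod, ge_tts, snp_gxe_scan
from .inference import permutation_pvalue
from .io import GenotypeMatrix, VariantRecord, write_dosage_tsv
from .model import cross_validate_lambda


@dataclass
class SimulationConfig:
    """Study conditions for one simulated gene.

    ``maf`` may be a scalar, an explicit length-K array, or a (low, high)
    tuple from which per-SNP frequencies are drawn uniformly per dataset.
    ``env`` is "normal" (standard normal exposure) or "bernoulli"
    (balanced binary exposure).
    """

    n: int = 500
    k: int = 5
    maf: object = (0.05, 0.4)
    ld_rho: float = 0.5
    causal_fraction: float = 0.2
    w_causal: float = 0.5
    beta0: float = 0.0
    beta1: float = 1.0
    beta2: float = 0.0
    beta12: float = 0.0
    env: str = "normal"
    seed: object = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must lie in [0, 1)")
        if (self.beta1 != 0 or self.beta12 != 0) and int(
            np.ceil(self.causal_fraction * self.k)
        ) < 1:
            raise ValueError("need at least one causal SNP when beta1 or beta12 != 0")


@dataclass
class SimulatedDataset:
    X: GenotypeMatrix
    z: np.ndarray
    y: np.ndarray
    causal_indices: np.ndarray
    config: SimulationConfig = field(repr=False, default=None)


def _resolve_maf(maf, k: int, rng: np.random.Generator) -> np.ndarray:
    if np.isscalar(maf):
        out = np.full(k, float(maf))
    elif isinstance(maf, tuple) and len(maf) == 2:
        out = rng.uniform(maf[0], maf[1], size=k)
    else:
        out = np.asarray(maf, dtype=float)
        if out.size != k:
            raise ValueError(f"maf array has {out.size} entries for K = {k}")
    if np.any(out < 0.01) or np.any(out > 0.5):
        raise ValueError("minor allele frequencies must lie in [0.01, 0.5]")
    return out


def _ar1_normal(n: int, k: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    eps = rng.standard_normal((n, k))
    out = np.empty((n, k))
    out[:, 0] = eps[:, 0]
    scale = np.sqrt(1.0 - rho * rho)
    for j in range(1, k):
        out[:, j] = rho * out[:, j - 1] + scale * eps[:, j]
    return out


def simulate_genotypes(n: int, k: int, maf, ld_rho: float = 0.0, seed=None) -> GenotypeMatrix:
    """Draw an N x K additive genotype matrix with AR(1)-decaying LD.

    Each of two haplotypes per subject is an AR(1) standard-normal vector
    thresholded at the normal quantile of the per-SNP MAF (allele carried
    iff the latent value falls below it); the genotype is the haplotype sum,
    so each column's marginal follows Hardy-Weinberg proportions exactly.
    """
    if not 0.0 <= ld_rho < 1.0:
        raise ValueError("ld_rho must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    maf = _resolve_maf(maf, k, rng)
    thr = stats.norm.ppf(maf)
    h1 = (_ar1_normal(n, k, ld_rho, rng) < thr).astype(float)
    h2 = (_ar1_normal(n, k, ld_rho, rng) < thr).astype(float)
    vals = h1 + h2
    variants = [
        VariantRecord(chrom="1", pos=1 + 1000 * j, id=f"1:{1 + 1000 * j}")
        for j in range(k)
    ]
    samples = [f"s{i + 1:05d}" for i in range(n)]
    return GenotypeMatrix(vals, variants, samples)


def simulate_phenotype(X, config: SimulationConfig, seed=None):
    """Generate (y, z, causal_indices) from genotypes under the additive
    interaction model; the causal subset is drawn without replacement."""
    vals = X.values if isinstance(X, GenotypeMatrix) else np.asarray(X, float)
    rng = np.random.default_rng(seed)
    n, k = vals.shape
    n_causal = max(1, int(round(config.causal_fraction * k)))
    causal = np.sort(rng.choice(k, size=n_causal, replace=False))
    w = np.zeros(k)
    w[causal] = config.w_causal
    gsum = vals @ w
    if config.env == "normal":
        z = rng.standard_normal(n)
    elif config.env == "bernoulli":
        z = rng.binomial(1, 0.5, size=n).astype(float)
    else:
        raise ValueError(f"unknown environment spec {config.env!r}")
    zc = z - z.mean()
    sd = np.sqrt(np.mean(zc * zc))
    if sd == 0:
        raise ValueError("degenerate environment draw (constant)")
    e = zc / sd
    eps = rng.standard_normal(n)
    y = (
        config.beta0
        + config.beta1 * gsum
        + config.beta2 * e
        + config.beta12 * gsum * e
        + eps
    )
    return y, z, causal


def simulate_dataset(config: SimulationConfig, seed=None) -> SimulatedDataset:
    """One reproducible dataset: genotypes, environment and phenotype."""
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s_geno, s_pheno = ss.spawn(2)
    X = simulate_genotypes(config.n, config.k, config.maf, config.ld_rho, seed=s_geno)
    y, z, causal = simulate_phenotype(X, config, seed=s_pheno)
    return SimulatedDataset(X=X, z=z, y=y, causal_indices=causal, config=config)


def export_dataset(ds: SimulatedDataset, genotype_path, pheno_path) -> None:
    """Write a dataset to the dosage-TSV + phenotype-TSV formats of the readers."""
    write_dosage_tsv(ds.X, genotype_path)
    df = pd.DataFrame({"sample_id": ds.X.samples, "y": ds.y, "z": ds.z})
    df.to_csv(pheno_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# method registry


def pvalue_hiscom(ds: SimulatedDataset, n_perm: int = 199, seed=None, *,
                  lambda_s="cv", cv_folds: int = 5) -> float:
    """Latent-component interaction permutation p-value for one dataset."""
    X, y, z = ds.X.values, ds.y, ds.z
    if isinstance(lambda_s, str):
        if isinstance(seed, np.random.SeedSequence):
            cv_seed = int(seed.generate_state(1)[0] % (2**31))
        elif isinstance(seed, (int, np.integer)):
            cv_seed = int(seed) % (2**31)
        else:
            cv_seed = 0
        lam = cross_validate_lambda(y, X, z, folds=cv_folds, seed=cv_seed).chosen
    else:
        lam = float(lambda_s)
    res = permutation_pvalue(y, X, z, lambda_s=lam, n_perm=n_perm, seed=seed)
    return res.p_value


def pvalue_ge_minp(ds, n_perm=None, seed=None) -> float:
    return ge_minp(snp_gxe_scan(ds.y, ds.X.values, ds.z))


def pvalue_ge_gates(ds, n_perm=None, seed=None) -> float:
    return ge_gates(snp_gxe_scan(ds.y, ds.X.values, ds.z))


def pvalue_ge_tts(ds, n_perm=199, seed=None) -> float:
    return ge_tts(ds.y, ds.X.values, ds.z, n_perm=n_perm, seed=seed)


def pvalue_ge_tprod(ds, n_perm=199, seed=None) -> float:
    return ge_tprod(ds.y, ds.X.values, ds.z, n_perm=n_perm, seed=seed)


METHODS = {
    "hiscom": pvalue_hiscom,
    "ge_minp": pvalue_ge_minp,
    "ge_gates": pvalue_ge_gates,
    "ge_tts": pvalue_ge_tts,
    "ge_tprod": pvalue_ge_tprod,
}


def _resolve_method(method):
    if callable(method):
        return method, getattr(method, "__name__", "custom")
    try:
        return METHODS[method], method
    except KeyError:
        raise ValueError(
            f"unknown method {method!r}; expected one of {sorted(METHODS)} or a callable"
        ) from None


def _binom_ci(count: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval."""
    res = stats.binomtest(count, n).proportion_ci(confidence_level=level, method="exact")
    return float(res.low), float(res.high)


def _dataset_pvalues(config, n_datasets, method_items, seed, n_perm):
    """p-values per method over shared datasets; (n_datasets x n_methods)."""
    ss = np.random.SeedSequence(seed)
    data_seeds = ss.spawn(n_datasets)
    out = np.empty((n_datasets, len(method_items)))
    for i, dseed in enumerate(data_seeds):
        s_data, s_perm = dseed.spawn(2)
        ds = simulate_dataset(config, seed=s_data)
        for m, (fn, _) in enumerate(method_items):
            out[i, m] = fn(ds, n_perm, s_perm)
    return out


def type1_experiment(
    config: SimulationConfig,
    n_datasets: int = 1000,
    alpha_levels=(0.05, 0.01, 0.005),
    method="hiscom",
    seed=None,
    n_perm: int = 199,
) -> pd.DataFrame:
    """Empirical type-I error of one method under the null (beta12 = 0).

    Returns one row per nominal level with the rejection fraction and its
    exact binomial 95% confidence interval.
    """
    if config.beta12 != 0:
        raise ValueError("type-I-error experiment requires beta12 = 0")
    fn, name = _resolve_method(method)
    pvals = _dataset_pvalues(config, n_datasets, [(fn, name)], seed, n_perm)[:, 0]
    rows = []
    for a in alpha_levels:
        nrej = int(np.count_nonzero(pvals <= a))
        lo, hi = _binom_ci(nrej, n_datasets)
        rows.append(
            dict(method=name, alpha=a, n_datasets=n_datasets, n_reject=nrej,
                 rate=nrej / n_datasets, ci_low=lo, ci_high=hi)
        )
    return pd.DataFrame(rows)


def power_experiment(
    config: SimulationConfig,
    beta12_grid,
    methods=("hiscom",),
    n_datasets: int = 1000,
    alpha: float = 0.05,
    seed=None,
    n_perm: int = 199,
) -> pd.DataFrame:
    """Empirical power over a grid of interaction effect sizes.

    All methods are evaluated on the same datasets at each effect size.
    Returns one row per (method, beta12).
    """
    method_items = [_resolve_method(m) for m in methods]
    rows = []
    for b12 in np.asarray(beta12_grid, dtype=float):
        cfg = replace(config, beta12=float(b12))
        pvals = _dataset_pvalues(cfg, n_datasets, method_items, seed, n_perm)
        for m, (_, name) in enumerate(method_items):
            nrej = int(np.count_nonzero(pvals[:, m] <= alpha))
            lo, hi = _binom_ci(nrej, n_datasets)
            rows.append(
                dict(method=name, beta12=float(b12), alpha=alpha,
                     n_datasets=n_datasets, n_reject=nrej,
                     power=nrej / n_datasets, ci_low=lo, ci_high=hi)
            )
    return pd.DataFrame(rows)
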