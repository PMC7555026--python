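"""Latent-component gene-environment interaction model, fitted by penalized ALS.

The model collapses the K SNPs of a gene into one latent gene component
``g_i = sum_k w_k x_ik``, represents the environment as ``e_i = w_E z_i``,
forms the latent interaction ``r_i`` as the (standardized) elementwise
product ``g_i * e_i``, and regresses the phenotype on the three components
plus covariates:

    y_i = beta1 g_i + beta2 e_i + beta12 r_i + sum_p beta_p c_ip + eps_i

Weights and path coefficients are estimated jointly by minimizing the
ridge-penalized least squares

    phi = SS(y - yhat) + lambda_s * SS(W) + lambda_s * SS(B)

with alternating least squares: given the latents, B is an exact ridge
solve; given (w_E, B), the phenotype is linear in the gene weights w (design
columns ``beta1 * x_k + beta12 * center(x_k * e)``), so w is an exact ridge
solve too.  Each substep minimizes the same objective exactly, hence the
objective trace is monotone non-increasing.  The substeps touch only
K x K cross-product matrices, so a fit costs O(N K^2) once for the Gram
set-up plus O(K^3) per iteration, and a phenotype permutation costs only
O(N K) extra — the property that makes genome-wide permutation scans
practical.

Identification: latent scale is reported under the standardization
convention ``sum g^2 = sum e^2 = sum r^2 = N``; with a single environment
variable this forces ``w_E = sqrt(N / sum z^2)`` (fixed positive), so the
environment component is simply the standardized exposure and w_E carries
no free information.  The reflection indeterminacy is resolved by flipping
(w, beta1, beta12) so that ``sum_k w_k > 0``.

The ridge parameter is chosen by k-fold cross-validation over a grid of 15
values spanning [0, 0.5] by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from .io import GenotypeMatrix

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA_GRID = np.linspace(0.0, 0.5, 15)


class DegenerateComponentError(ValueError):
    """The gene component Xw is identically zero (degenerate weights)."""


@dataclass
class LatentScores:
    """Standardized latent components (each satisfies sum v^2 = N)."""

    g: np.ndarray
    e: np.ndarray
    r: np.ndarray


@dataclass
class HisComFit:
    """Result of one penalized ALS fit.

    ``W`` holds the gene weights on the constraint scale followed by the
    environment weight w_E; ``beta_cov`` holds one coefficient per covariate
    column.  ``objective_trace`` records the penalized objective once per
    ALS iteration (after the weight update) on the internal standardized
    scale and is non-increasing.
    """

    W: np.ndarray
    beta1: float
    beta2: float
    beta12: float
    beta_cov: np.ndarray
    latents: LatentScores
    lambda_s: float
    objective_trace: np.ndarray
    converged: bool
    n_iter: int
    # private working-scale parameters + standardization stats for prediction
    _work: dict = field(default_factory=dict, repr=False)

    @property
    def B(self) -> np.ndarray:
        return np.concatenate([[self.beta1, self.beta2, self.beta12], self.beta_cov])


@dataclass
class CVResult:
    grid: np.ndarray
    cv_error: np.ndarray
    chosen: float


# ---------------------------------------------------------------------------
# standardization helpers (population convention: sum v^2 = N after scaling)


def _standardize_vec(v: np.ndarray, mean: float | None = None, sd: float | None = None):
    v = np.asarray(v, dtype=float).ravel()
    if mean is None:
        mean = v.mean()
    c = v - mean
    if sd is None:
        sd = np.sqrt(np.mean(c * c))
    if sd == 0:
        raise ValueError("zero-variance vector cannot be standardized")
    return c / sd, mean, sd


def _standardize_cols(
    X: np.ndarray, means: np.ndarray | None = None, sds: np.ndarray | None = None
):
    X = np.asarray(X, dtype=float)
    if means is None:
        means = X.mean(axis=0)
    C = X - means
    if sds is None:
        sds = np.sqrt(np.mean(C * C, axis=0))
    out = np.zeros_like(C)
    ok = sds > 0
    if not ok.all():
        logger.info("dropping %d zero-variance column(s) from the fit", (~ok).sum())
    out[:, ok] = C[:, ok] / sds[ok]
    return out, means, sds


def _scale_to_n(v: np.ndarray) -> tuple[np.ndarray, float]:
    """Rescale so that sum v^2 = N; returns (scaled, factor applied)."""
    n = v.size
    nrm = np.linalg.norm(v)
    if nrm == 0:
        raise DegenerateComponentError("latent component is identically zero")
    c = np.sqrt(n) / nrm
    return v * c, c


# ---------------------------------------------------------------------------
# functional API


def build_latents(X: np.ndarray, z: np.ndarray, W: np.ndarray) -> tuple[LatentScores, dict]:
    """Build standardized latent components from weights.

    ``X`` must have mean-centered unit-variance columns and ``z`` likewise;
    ``W`` is (w_1..w_K, w_E).  Returns the latents (each rescaled so that
    sum v^2 = N; r additionally centered before scaling) together with the
    rescaling factors, so that weights can be back-normalized onto the
    constraint scale.
    """
    X = np.asarray(X, dtype=float)
    z = np.asarray(z, dtype=float).ravel()
    W = np.asarray(W, dtype=float).ravel()
    if W.size != X.shape[1] + 1:
        raise ValueError("W must hold one weight per SNP plus w_E")
    w, w_e = W[:-1], W[-1]
    if w_e == 0:
        raise DegenerateComponentError("environment weight w_E is zero")
    if not np.all(np.isfinite(W)):
        raise ValueError("non-finite weights")
    g, c_g = _scale_to_n(X @ w)
    e, c_e = _scale_to_n(w_e * z)
    raw = g * e
    r, c_r = _scale_to_n(raw - raw.mean())
    return LatentScores(g=g, e=e, r=r), {"c_g": c_g, "c_e": c_e, "c_r": c_r}


def objective_phi(
    y: np.ndarray,
    y_hat: np.ndarray,
    W: np.ndarray,
    B: np.ndarray,
    lambda_s: float,
    penalize_b: bool = True,
) -> float:
    """Penalized least-squares objective SS(y-yhat) + lambda*SS(W) [+ lambda*SS(B)]."""
    resid = np.asarray(y, float).ravel() - np.asarray(y_hat, float).ravel()
    phi = float(resid @ resid) + lambda_s * float(np.square(W).sum())
    if penalize_b:
        phi += lambda_s * float(np.square(B).sum())
    return phi


# ---------------------------------------------------------------------------
# ALS core on cross-product (Gram) matrices


class _GramCache:
    """Cross-products of the standardized design, reusable across phenotype
    permutations and ridge-penalty candidates."""

    __slots__ = (
        "n", "k", "p", "Xs", "zs", "Cs", "Mi_c",
        "XtX", "MtM", "XtM", "Xtz", "Mtz", "XtC", "MtC", "CtC", "Ctz",
    )

    def __init__(self, Xs: np.ndarray, zs: np.ndarray, Cs: np.ndarray):
        self.n, self.k = Xs.shape
        self.p = Cs.shape[1]
        Mi = Xs * zs[:, None]
        Mi_c = Mi - Mi.mean(axis=0)
        self.Xs, self.zs, self.Cs, self.Mi_c = Xs, zs, Cs, Mi_c
        self.XtX = Xs.T @ Xs
        self.MtM = Mi_c.T @ Mi_c
        self.XtM = Xs.T @ Mi_c
        self.Xtz = Xs.T @ zs
        self.Mtz = Mi_c.T @ zs
        self.XtC = Xs.T @ Cs
        self.MtC = Mi_c.T @ Cs
        self.CtC = Cs.T @ Cs
        self.Ctz = Cs.T @ zs

    def y_products(self, ys: np.ndarray) -> tuple:
        return (
            self.Xs.T @ ys,
            self.Mi_c.T @ ys,
            self.Cs.T @ ys,
            float(self.zs @ ys),
            float(ys @ ys),
        )


def _als_gram(cache: _GramCache, yprod, lam, w0, tol, max_iter, penalize_b):
    """Alternating exact ridge solves on precomputed cross-products.

    Works on the unconstrained parametrization (the constraint scale is
    restored by the caller); both substeps are exact penalized
    least-squares minimizers of the same objective, so phi is monotone
    non-increasing.  Returns (w, b, trace, converged, n_iter) with
    b = (b1, b2, b12, b_cov..).
    """
    Xty, Mty, Cty, zty, yty = yprod
    n, k, p = cache.n, cache.k, cache.p
    lam_b = lam if penalize_b else 0.0
    q = 3 + p
    lam_eye_k = lam * np.eye(k) if lam > 0 else None
    lam_eye_q = lam_b * np.eye(q) if lam_b > 0 else None
    solve = np.linalg.solve
    w = w0.copy()
    trace: list[float] = []
    phi_prev = np.inf
    converged = False
    A = np.empty((q, q))
    A[1, 1] = n
    if p:
        A[1, 3:] = cache.Ctz
        A[3:, 1] = cache.Ctz
        A[3:, 3:] = cache.CtC
    Dty = np.empty(q)
    Dty[1] = zty
    if p:
        Dty[3:] = Cty
    it = 0
    b = np.zeros(q)
    for it in range(1, max_iter + 1):
        XtXw = cache.XtX @ w
        XtMw = cache.XtM @ w
        MtXw = cache.XtM.T @ w
        MtMw = cache.MtM @ w
        # B-step: ridge of y on D = [g, e, r, C]
        A[0, 0] = w @ XtXw
        A[0, 1] = A[1, 0] = w @ cache.Xtz
        A[0, 2] = A[2, 0] = w @ XtMw
        A[1, 2] = A[2, 1] = w @ cache.Mtz
        A[2, 2] = w @ MtMw
        if p:
            A[0, 3:] = A[3:, 0] = w @ cache.XtC
            A[2, 3:] = A[3:, 2] = w @ cache.MtC
        Dty[0] = w @ Xty
        Dty[2] = w @ Mty
        lhs = A + lam_eye_q if lam_eye_q is not None else A
        try:
            b = solve(lhs, Dty)
        except np.linalg.LinAlgError:
            b = np.linalg.lstsq(lhs, Dty, rcond=None)[0]
        b0, b1, b2 = b[0], b[1], b[2]
        bc = b[3:]
        # w-step: ridge in the K gene weights, design b0*X + b2*center(X*e)
        A2 = b0 * b0 * cache.XtX + b0 * b2 * (cache.XtM + cache.XtM.T) \
            + b2 * b2 * cache.MtM
        v1 = Xty - b1 * cache.Xtz - (cache.XtC @ bc if p else 0.0)
        v2 = Mty - b1 * cache.Mtz - (cache.MtC @ bc if p else 0.0)
        rhs2 = b0 * v1 + b2 * v2
        lhs2 = A2 + lam_eye_k if lam_eye_k is not None else A2
        try:
            w_new = solve(lhs2, rhs2)
        except np.linalg.LinAlgError:
            w_new = np.linalg.lstsq(lhs2, rhs2, rcond=None)[0]
        if w_new.any():
            w = w_new
        # phi after the weight update: residual SS via cross-products
        tt = yty - 2.0 * b1 * zty + b1 * b1 * n
        if p:
            tt += -2.0 * (Cty @ bc) + 2.0 * b1 * (cache.Ctz @ bc) + bc @ cache.CtC @ bc
        A2w = A2 @ w
        resid2 = max(tt - 2.0 * (w @ rhs2) + w @ A2w, 0.0)
        phi = resid2 + lam * (float(w @ w) + 1.0)
        if penalize_b:
            phi += lam * float(b @ b)
        if not np.isfinite(phi):
            raise FloatingPointError("non-finite objective during ALS")
        trace.append(phi)
        if phi_prev < np.inf and abs(phi_prev - phi) / (1.0 + phi_prev) < tol:
            converged = True
            break
        phi_prev = phi
    return w, b, np.asarray(trace), converged, it


def _init_weights(k: int, init: str, rng: np.random.Generator | None) -> np.ndarray:
    if init == "uniform":
        return np.full(k, 1.0 / np.sqrt(k))
    if init == "random":
        rng = rng or np.random.default_rng()
        w = rng.standard_normal(k)
        return w / np.linalg.norm(w)
    raise ValueError(f"unknown init {init!r}")


# ---------------------------------------------------------------------------
# estimator


class HisComGxE(RegressorMixin, BaseEstimator):
    """Gene-based G-by-E interaction model (one gene, one environment).

    Parameters
    ----------
    lambda_s : float or "cv"
        Ridge penalty on weights and path coefficients.  ``"cv"`` selects it
        by k-fold cross-validation over ``lambda_grid``.
    lambda_grid : array-like or None
        Candidate penalties for CV; default 15 evenly spaced values in
        [0, 0.5].
    cv : int
        Number of CV folds.
    penalize_b : bool
        If False, only the weights W are penalized (phi = SS + lambda*SS(W)).
    tol, max_iter : float, int
        ALS convergence tolerance (relative change in phi) and iteration cap.
    init : {"uniform", "random"}
        Weight initializer; "uniform" is deterministic (w_k = 1/sqrt(K)).
    n_init : int
        Number of ALS starts (1 = the deterministic initializer only);
        additional starts use seeded random weights and the best objective
        wins, guarding against non-global fixed points of the biconvex
        objective.
    random_state : int or None
        Seed for CV fold shuffling and random initialization.

    Attributes
    ----------
    weights_ : ndarray of shape (K + 1,)
        Gene weights on the constraint scale, followed by w_E.
    beta1_, beta2_, beta12_ : float
        Path coefficients of the gene, environment and interaction
        components (phenotype units per standardized component).
    covar_coef_ : ndarray
        Covariate coefficients.
    latents_ : LatentScores
        Fitted components, each satisfying sum v^2 = N.
    lambda_ : float
        Penalty actually used (CV-selected if requested).
    cv_result_ : CVResult or None
    objective_trace_ : ndarray
        Non-increasing per-iteration penalized objective.
    converged_ : bool
    n_iter_ : int
    """

    def __init__(
        self,
        lambda_s="cv",
        lambda_grid=None,
        cv: int = 5,
        penalize_b: bool = True,
        tol: float = 1e-6,
        max_iter: int = 1000,
        init: str = "uniform",
        n_init: int = 1,
        random_state=None,
    ):
        self.lambda_s = lambda_s
        self.lambda_grid = lambda_grid
        self.cv = cv
        self.penalize_b = penalize_b
        self.tol = tol
        self.max_iter = max_iter
        self.init = init
        self.n_init = n_init
        self.random_state = random_state

    def _grid(self) -> np.ndarray:
        if self.lambda_grid is None:
            return DEFAULT_LAMBDA_GRID.copy()
        return np.asarray(self.lambda_grid, dtype=float)

    @staticmethod
    def _coerce(X):
        if isinstance(X, GenotypeMatrix):
            return X.values
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return X

    def fit(self, X, y, *, env, covariates=None):
        """Fit the model.

        Parameters
        ----------
        X : array-like or GenotypeMatrix of shape (N, K)
            Additive genotypes of one gene (no missing values).
        y : array-like of shape (N,)
            Quantitative phenotype.
        env : array-like of shape (N,)
            Environment variable.
        covariates : array-like of shape (N, P), optional
        """
        X = self._coerce(X)
        y = np.asarray(y, dtype=float).ravel()
        z = np.asarray(env, dtype=float).ravel()
        n, k = X.shape
        if y.size != n or z.size != n:
            raise ValueError("X, y and env must share the sample dimension")
        if np.isnan(X).any() or np.isnan(y).any() or np.isnan(z).any():
            raise ValueError("missing values must be handled before fitting")
        C = None
        if covariates is not None:
            C = np.asarray(covariates, dtype=float)
            if C.ndim == 1:
                C = C[:, None]

        rng = (
            np.random.default_rng(self.random_state)
            if self.random_state is not None
            else np.random.default_rng()
        )
        lam = self.lambda_s
        self.cv_result_ = None
        if isinstance(lam, str):
            if lam != "cv":
                raise ValueError(f"lambda_s must be a float or 'cv', got {lam!r}")
            self.cv_result_ = cross_validate_lambda(
                y, X, z, C,
                grid=self._grid(), folds=self.cv, seed=self.random_state,
                penalize_b=self.penalize_b, tol=self.tol, max_iter=self.max_iter,
                init=self.init,
            )
            lam = self.cv_result_.chosen
        lam = float(lam)

        fit = _fit_prepared(
            y, X, z, C, lam,
            init=self.init, rng=rng, tol=self.tol, max_iter=self.max_iter,
            penalize_b=self.penalize_b, n_init=self.n_init,
        )
        self.fit_ = fit
        self.weights_ = fit.W
        self.beta1_ = fit.beta1
        self.beta2_ = fit.beta2
        self.beta12_ = fit.beta12
        self.covar_coef_ = fit.beta_cov
        self.latents_ = fit.latents
        self.lambda_ = lam
        self.objective_trace_ = fit.objective_trace
        self.converged_ = fit.converged
        self.n_iter_ = fit.n_iter
        self.n_features_in_ = k
        return self

    def predict(self, X, *, env, covariates=None):
        check_is_fitted(self, "fit_")
        return _predict_fit(self.fit_, self._coerce(X), np.asarray(env, float).ravel(),
                            covariates)


def _prepare_arrays(y, X, z, C):
    """Standardize all inputs; returns arrays plus the statistics used."""
    n = np.asarray(y).size
    ys, y_mean, y_sd = _standardize_vec(y)
    Xs, x_means, x_sds = _standardize_cols(X)
    zs, z_mean, z_sd = _standardize_vec(z)
    if C is not None and C.shape[1] > 0:
        Cs, c_means, c_sds = _standardize_cols(C)
    else:
        Cs, c_means, c_sds = np.empty((n, 0)), np.empty(0), np.empty(0)
    stats = dict(
        y_mean=y_mean, y_sd=y_sd, x_means=x_means, x_sds=x_sds,
        z_mean=z_mean, z_sd=z_sd, c_means=c_means, c_sds=c_sds,
    )
    return ys, Xs, zs, Cs, stats


def _fit_prepared(
    y, X, z, C, lam, *, init="uniform", rng=None, tol=1e-6, max_iter=1000,
    penalize_b=True, w0=None, n_init=1,
) -> HisComFit:
    """Standardize inputs, run ALS (optionally multi-start), restore the
    constraint scale.

    ALS on the biconvex objective can settle in a non-global fixed point on
    noisy instances; ``n_init > 1`` reruns it from seeded random weight
    initializations and keeps the solution with the smallest objective.
    """
    ys, Xs, zs, Cs, stats = _prepare_arrays(y, X, z, C)
    cache = _GramCache(Xs, zs, Cs)
    k = Xs.shape[1]
    if w0 is None:
        w0 = _init_weights(k, init, rng)
    yprod = cache.y_products(ys)
    w, b, trace, converged, n_iter = _als_gram(
        cache, yprod, lam, w0, tol, max_iter, penalize_b
    )
    if n_init > 1:
        restart_rng = rng if rng is not None else np.random.default_rng(0)
        for _ in range(n_init - 1):
            w0_r = _init_weights(k, "random", restart_rng)
            cand = _als_gram(cache, yprod, lam, w0_r, tol, max_iter, penalize_b)
            if cand[2][-1] < trace[-1]:
                w, b, trace, converged, n_iter = cand
    if not converged:
        warnings.warn(
            f"ALS did not converge in {max_iter} iterations "
            f"(last relative change above tol)", RuntimeWarning,
        )
    stats["mi_means"] = (Xs * zs[:, None]).mean(axis=0)
    stats["penalize_b"] = penalize_b
    return _finalize_fit(
        w, b, lam, trace, converged, n_iter,
        ys=ys, Xs=Xs, zs=zs, Cs=Cs, Mi_c=cache.Mi_c, stats=stats,
    )


def _finalize_fit(w, b, lam, trace, converged, n_iter, *, ys, Xs, zs, Cs, Mi_c, stats):
    """Re-express working-scale ALS parameters on the constraint scale."""
    n = ys.size
    g_work = Xs @ w
    nrm_g = np.linalg.norm(g_work)
    if nrm_g == 0:
        raise DegenerateComponentError("fitted gene component is identically zero")
    c_g = np.sqrt(n) / nrm_g
    s = np.sign(w.sum())
    if s == 0:
        s = np.sign(w[np.flatnonzero(w)[0]]) if np.any(w != 0) else 1.0
    w_rep = s * c_g * w
    g = s * c_g * g_work
    e = zs  # w_E = 1 on the constraint scale of standardized z
    r_work = Mi_c @ w
    nrm_r = np.linalg.norm(r_work)
    if nrm_r == 0:
        # no interaction variation (e.g. X*e constant); degenerate
        raise DegenerateComponentError("latent interaction component is zero")
    c_r = np.sqrt(n) / nrm_r
    r = s * c_r * r_work
    y_sd = stats["y_sd"]
    beta1 = float(b[0] / (s * c_g) * y_sd)
    beta2 = float(b[1] * y_sd)
    beta12 = float(b[2] / (s * c_r) * y_sd)
    beta_cov = np.asarray(b[3:]) * y_sd
    W_full = np.concatenate([w_rep, [1.0]])
    fit = HisComFit(
        W=W_full,
        beta1=beta1,
        beta2=beta2,
        beta12=beta12,
        beta_cov=beta_cov,
        latents=LatentScores(g=g, e=e, r=r),
        lambda_s=lam,
        objective_trace=trace,
        converged=converged,
        n_iter=n_iter,
    )
    fit._work = dict(w=w, b=b, **stats)
    return fit


def _predict_fit(fit: HisComFit, X, z, covariates=None) -> np.ndarray:
    st = fit._work
    Xs, _, _ = _standardize_cols(X, st["x_means"], st["x_sds"])
    zs = (z - st["z_mean"]) / st["z_sd"]
    Mi_c = Xs * zs[:, None] - st["mi_means"]
    w, b = st["w"], st["b"]
    yhat = b[0] * (Xs @ w) + b[1] * zs + b[2] * (Mi_c @ w)
    if covariates is not None and len(b) > 3:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        Cs, _, _ = _standardize_cols(C, st["c_means"], st["c_sds"])
        yhat = yhat + Cs @ b[3:]
    return st["y_mean"] + st["y_sd"] * yhat


def fit_als(
    y, X, z, C=None, lambda_s: float = 0.0, *, init="uniform", tol=1e-6,
    max_iter=1000, penalize_b=True, random_state=None, n_init=1,
) -> HisComFit:
    """Fit one gene at a fixed ridge penalty; functional wrapper over the ALS core.

    ``n_init > 1`` adds seeded random restarts and keeps the best objective.
    """
    X = HisComGxE._coerce(X)
    if C is not None:
        C = np.asarray(C, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    rng = np.random.default_rng(random_state) if random_state is not None else None
    return _fit_prepared(
        np.asarray(y, float).ravel(), X, np.asarray(z, float).ravel(), C,
        float(lambda_s), init=init, rng=rng, tol=tol, max_iter=max_iter,
        penalize_b=penalize_b, n_init=n_init,
    )


def cross_validate_lambda(
    y, X, z, C=None, *, grid=None, folds: int = 5, seed=None,
    penalize_b=True, tol=1e-6, max_iter=1000, init="uniform",
) -> CVResult:
    """Select the ridge penalty by k-fold CV on held-out squared error.

    For each candidate, the model is trained on k-1 folds (standardization
    statistics from the training fold only) and used to predict the held-out
    phenotype; the candidate with the smallest mean squared prediction error
    wins, ties broken toward the larger (more regularized) value.
    """
    X = HisComGxE._coerce(X)
    y = np.asarray(y, dtype=float).ravel()
    z = np.asarray(z, dtype=float).ravel()
    if C is not None:
        C = np.asarray(C, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    if grid is None:
        grid = DEFAULT_LAMBDA_GRID.copy()
    grid = np.asarray(grid, dtype=float)
    n = y.size
    if n < folds:
        raise ValueError(f"need at least {folds} samples for {folds}-fold CV")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    sse = np.zeros(grid.size)
    k = X.shape[1]
    for tr, te in kf.split(np.arange(n)):
        Ctr = C[tr] if C is not None else None
        ys, Xs, zs, Cs, stats = _prepare_arrays(y[tr], X[tr], z[tr], Ctr)
        cache = _GramCache(Xs, zs, Cs)
        yprod = cache.y_products(ys)
        w0 = _init_weights(k, init, None)
        # held-out design standardized with training statistics
        Xs_te, _, _ = _standardize_cols(X[te], stats["x_means"], stats["x_sds"])
        zs_te = (z[te] - stats["z_mean"]) / stats["z_sd"]
        mi_means = (Xs * zs[:, None]).mean(axis=0)
        Mi_te = Xs_te * zs_te[:, None] - mi_means
        if C is not None:
            Cs_te, _, _ = _standardize_cols(C[te], stats["c_means"], stats["c_sds"])
        w_start = w0
        for i, lam in enumerate(grid):
            w, b, _, _, _ = _als_gram(
                cache, yprod, float(lam), w_start, tol, max_iter, penalize_b
            )
            w_start = w if w.any() else w0  # warm start along the penalty path
            pred = b[0] * (Xs_te @ w) + b[1] * zs_te + b[2] * (Mi_te @ w)
            if C is not None and len(b) > 3:
                pred = pred + Cs_te @ b[3:]
            pred = stats["y_mean"] + stats["y_sd"] * pred
            sse[i] += float(np.square(y[te] - pred).sum())
    cv_error = sse / n
    best = cv_error.min()
    chosen = float(grid[np.flatnonzero(cv_error == best).max()])
    return CVResult(grid=grid, cv_error=cv_error, chosen=chosen)
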