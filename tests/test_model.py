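import numpy as np
import pytest
from scipy import optimize

from hiscom_gxe.model import (
    DEFAULT_LAMBDA_GRID,
    DegenerateComponentError,
    HisComGxE,
    build_latents,
    cross_validate_lambda,
    fit_als,
    objective_phi,
    _predict_fit,
    _standardize_cols,
    _standardize_vec,
)


def _standardized_instance(y, X, z):
    """Independent construction of the standardized design and the penalized
    objective, used as the reference for optimizer comparisons."""
    ys, _, _ = _standardize_vec(y)
    Xs, _, _ = _standardize_cols(X)
    zs, _, _ = _standardize_vec(z)
    Mi = Xs * zs[:, None]
    Mi_c = Mi - Mi.mean(axis=0)

    def phi(w, b, lam):
        resid = ys - b[0] * (Xs @ w) - b[1] * zs - b[2] * (Mi_c @ w)
        return float(resid @ resid) + lam * (float(w @ w) + 1.0) + lam * float(b @ b)

    return ys, Xs, zs, Mi_c, phi


# ---------------------------------------------------------------------------
# latent construction


def test_build_latents_single_snp_identity(rng):
    x = rng.standard_normal(30)
    xs, _, _ = _standardize_vec(x)
    zs, _, _ = _standardize_vec(rng.standard_normal(30))
    lat, fac = build_latents(xs[:, None], zs, np.array([1.0, 1.0]))
    np.testing.assert_allclose(lat.g, xs, atol=1e-12)
    assert fac["c_g"] == pytest.approx(1.0)


@pytest.mark.parametrize("w_e", [0.3, -2.0])
def test_environment_component_is_signed_standardized_z(rng, w_e):
    zs, _, _ = _standardize_vec(rng.standard_normal(40))
    xs, _, _ = _standardize_vec(rng.standard_normal(40))
    lat, _ = build_latents(xs[:, None], zs, np.array([1.0, w_e]))
    np.testing.assert_allclose(lat.e, np.sign(w_e) * zs, atol=1e-12)
    assert np.sum(lat.e**2) == pytest.approx(40.0)


def test_build_latents_hand_computed_case():
    # two orthogonal +/-1 columns: after standardization and the sum-of-
    # squares = N rescale, the component is exactly (1, -1, 1, -1)
    X = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
    Xs, _, _ = _standardize_cols(X)
    z = np.array([1.0, 2.0, -1.0, -2.0])
    zs, _, _ = _standardize_vec(z)
    lat, _ = build_latents(Xs, zs, np.array([1.0, 1.0, 1.0]))
    np.testing.assert_allclose(lat.g, [1.0, -1.0, 1.0, -1.0], atol=1e-12)
    assert np.sum(lat.g**2) == pytest.approx(4.0)
    assert np.sum(lat.r**2) == pytest.approx(4.0)


def test_degenerate_weights_raise(rng):
    Xs, _, _ = _standardize_cols(rng.standard_normal((20, 2)))
    zs, _, _ = _standardize_vec(rng.standard_normal(20))
    with pytest.raises(DegenerateComponentError):
        build_latents(Xs, zs, np.array([0.0, 0.0, 1.0]))


# ---------------------------------------------------------------------------
# objective


def test_objective_phi_values():
    assert objective_phi([1, 2], [1, 2], [0.5], [1.0], 0.0) == 0.0
    # residual (1,1), W=(1), B=(2), lambda=0.5 -> 2 + 0.5*(1+4)
    assert objective_phi([1, 1], [0, 0], [1.0], [2.0], 0.5) == pytest.approx(4.5)
    assert objective_phi([1, 1], [0, 0], [1.0], [2.0], 0.5, penalize_b=False) == (
        pytest.approx(2.5)
    )


def test_als_beats_random_parameter_draws(rng):
    n, k, lam = 40, 3, 0.2
    X = rng.integers(0, 3, (n, k)).astype(float)
    z = rng.standard_normal(n)
    y = 0.5 * X[:, 0] + 0.4 * X[:, 2] * z + rng.standard_normal(n)
    fit = fit_als(y, X, z, lambda_s=lam, tol=1e-12, max_iter=5000)
    phi_als = fit.objective_trace[-1]
    _, _, _, _, phi = _standardized_instance(y, X, z)
    draws = rng.standard_normal((1000, k + 3))
    assert all(phi(d[:k], d[k:], lam) >= phi_als for d in draws)


# ---------------------------------------------------------------------------
# ALS correctness


def test_ols_limit_single_snp(rng):
    n = 60
    x = rng.integers(0, 3, n).astype(float)
    z = rng.standard_normal(n)
    y = 0.5 * x + 0.3 * z + 0.4 * x * z + rng.standard_normal(n)
    fit = fit_als(y, x, z, lambda_s=0.0)
    A = np.column_stack([np.ones(n), x, z, x * z])
    ols_fitted = A @ np.linalg.lstsq(A, y, rcond=None)[0]
    np.testing.assert_allclose(_predict_fit(fit, x[:, None], z), ols_fitted, atol=1e-8)


def test_noiseless_recovery_of_interaction_coefficient(rng):
    n, k = 60, 4
    X = rng.integers(0, 3, (n, k)).astype(float)
    z = rng.standard_normal(n)
    Xs, _, _ = _standardize_cols(X)
    zs, _, _ = _standardize_vec(z)
    w = np.array([0.5, 0.3, -0.2, 0.4])
    lat, _ = build_latents(Xs, zs, np.r_[w, 1.0])
    y = 0.7 * lat.g + 0.4 * lat.e + 0.6 * lat.r
    fit = fit_als(y, X, z, lambda_s=0.0, tol=1e-12, max_iter=10_000)
    assert fit.beta12 == pytest.approx(0.6, abs=1e-4)
    assert fit.beta1 == pytest.approx(0.7, abs=1e-4)
    assert fit.beta2 == pytest.approx(0.4, abs=1e-4)


@pytest.mark.parametrize("lam", [0.0, 0.2])
def test_als_matches_derivative_free_optimizer(lam):
    rng = np.random.default_rng(71)
    n, k = 30, 3
    X = rng.integers(0, 3, (n, k)).astype(float)
    z = rng.standard_normal(n)
    y = 0.3 * X[:, 0] + 0.2 * z + 0.3 * X[:, 1] * z + rng.standard_normal(n)
    fit = fit_als(y, X, z, lambda_s=lam, tol=1e-14, max_iter=20_000,
                  n_init=5, random_state=0)
    _, _, _, _, phi = _standardized_instance(y, X, z)
    best = np.inf
    for s in range(4):
        x0 = np.random.default_rng(100 + s).standard_normal(k + 3) * 0.5
        res = optimize.minimize(
            lambda t: phi(t[:k], t[k:], lam), x0, method="Nelder-Mead",
            options=dict(maxiter=20_000, xatol=1e-12, fatol=1e-14),
        )
        res = optimize.minimize(
            lambda t: phi(t[:k], t[k:], lam), res.x, method="Powell",
            options=dict(maxiter=20_000, xtol=1e-12, ftol=1e-14),
        )
        best = min(best, res.fun)
    assert fit.objective_trace[-1] == pytest.approx(best, rel=1e-6)


def test_trace_monotone_and_latent_norms(small_gxe_data):
    y, X, z = small_gxe_data
    fit = fit_als(y, X, z, lambda_s=0.15)
    assert np.all(np.diff(fit.objective_trace) <= 1e-10)
    n = y.size
    for v in (fit.latents.g, fit.latents.e, fit.latents.r):
        assert np.sum(v**2) == pytest.approx(n, abs=1e-8 * n)
    assert fit.converged


def test_sign_convention_and_init_invariance(small_gxe_data):
    y, X, z = small_gxe_data
    fits = [
        fit_als(y, X, z, lambda_s=0.1, init="random", random_state=s,
                tol=1e-12, max_iter=10_000)
        for s in (1, 2)
    ]
    for f in fits:
        assert f.W[:-1].sum() > 0
    for attr in ("beta1", "beta2", "beta12"):
        assert getattr(fits[0], attr) == pytest.approx(
            getattr(fits[1], attr), abs=1e-5
        )


def test_weight_shrinkage_monotone_in_lambda(small_gxe_data):
    y, X, z = small_gxe_data
    ssw = []
    for lam in np.linspace(0.05, 0.5, 10):
        f = fit_als(y, X, z, lambda_s=lam, tol=1e-12, max_iter=10_000)
        ssw.append(float(f._work["w"] @ f._work["w"]))
    assert np.all(np.diff(ssw) <= 1e-9)


def test_covariates_are_adjusted_for(rng):
    n = 200
    X = rng.integers(0, 3, (n, 2)).astype(float)
    z = rng.standard_normal(n)
    C = rng.standard_normal((n, 2))
    y = 2.0 * C[:, 0] - 1.0 * C[:, 1] + 0.5 * X[:, 0] * z + rng.standard_normal(n)
    fit = fit_als(y, X, z, C=C, lambda_s=0.0)
    # covariate coefficients recovered on the standardized-covariate scale
    assert fit.beta_cov[0] == pytest.approx(2.0, abs=0.2)
    assert abs(fit.beta12) > 0.1


# ---------------------------------------------------------------------------
# estimator interface


def test_estimator_sklearn_contract(small_gxe_data):
    y, X, z = small_gxe_data
    est = HisComGxE(lambda_s=0.1)
    assert est.get_params()["lambda_s"] == 0.1
    est.set_params(tol=1e-8).fit(X, y, env=z)
    assert est.weights_.shape == (X.shape[1] + 1,)
    assert est.weights_[-1] == 1.0  # w_E carries no free information
    assert est.latents_.g.shape == y.shape
    pred = est.predict(X, env=z)
    assert pred.shape == y.shape
    # refitting the clone gives the same coefficients
    from sklearn.base import clone

    est2 = clone(est).fit(X, y, env=z)
    assert est2.beta12_ == pytest.approx(est.beta12_, abs=1e-10)


def test_estimator_cv_selects_from_grid(small_gxe_data):
    y, X, z = small_gxe_data
    est = HisComGxE(lambda_s="cv", random_state=0).fit(X, y, env=z)
    assert est.lambda_ in est.cv_result_.grid
    assert est.cv_result_.grid.size == 15


# ---------------------------------------------------------------------------
# cross-validation


def test_cv_singleton_grid_forced(small_gxe_data):
    y, X, z = small_gxe_data
    cv = cross_validate_lambda(y, X, z, grid=[0.3], seed=0)
    assert cv.chosen == 0.3


def test_default_grid_spec():
    assert DEFAULT_LAMBDA_GRID.size == 15
    assert DEFAULT_LAMBDA_GRID[0] == 0.0
    assert DEFAULT_LAMBDA_GRID[-1] == 0.5


def test_cv_shrinks_under_pure_noise():
    """With many SNPs and a small sample of pure noise, CV should nearly
    always prefer a positive ridge penalty."""
    hits = 0
    n_rep = 100
    for rep in range(n_rep):
        rng = np.random.default_rng(5000 + rep)
        X = rng.integers(0, 3, (50, 20)).astype(float)
        z = rng.standard_normal(50)
        y = rng.standard_normal(50)
        hits += cross_validate_lambda(y, X, z, folds=5, seed=rep).chosen > 0
    assert hits / n_rep >= 0.9
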