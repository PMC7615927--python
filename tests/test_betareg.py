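"""Beta regression: likelihood correctness, oracle equivalence, recovery,
mixed-model behaviour, diagnostics and bootstrap."""

import numpy as np
import pytest
from scipy import integrate, special

from macrodiv.betareg import (
    BetaRegression,
    MixedBetaRegression,
    beta_loglik,
    model_selection,
    vif,
)


def make_data(n=128, seed=0, gamma1=0.25, family_sd=0.0, nfam=13):
    rng = np.random.default_rng(seed)
    X = np.column_stack(
        [np.ones(n), rng.normal(size=(n, 4)), rng.integers(0, 2, (n, 2))]
    )
    Z = np.column_stack([np.ones(n), rng.normal(size=n)])
    beta = np.array([-3.061, -0.220, 0.212, -0.009, -0.248, 0.234, 0.437])
    gamma = np.array([3.417, gamma1])
    fam = np.concatenate([np.arange(nfam), rng.integers(0, nfam, n - nfam)])
    eta = X @ beta
    if family_sd > 0:
        eta = eta + rng.normal(0, family_sd, nfam)[fam]
    mu = special.expit(eta)
    phi = np.exp(Z @ gamma)
    y = rng.beta(mu * phi, (1 - mu) * phi)
    return y, X, Z, beta, gamma, fam


def test_loglik_uniform_density_is_zero():
    # Beta(1,1) is uniform: mu=0.5, phi=2 gives log-density 0 at any y
    y = np.array([0.5])
    X = Z = np.ones((1, 1))
    ll = beta_loglik(y, X, Z, beta=[0.0], gamma=[np.log(2.0)])
    assert ll == pytest.approx(0.0, abs=1e-12)


def test_loglik_density_integrates_to_one(rng):
    X = Z = np.ones((1, 1))
    for _ in range(5):
        b, g = rng.normal(-1, 1), rng.normal(1.5, 0.5)
        total, _ = integrate.quad(
            lambda y: np.exp(beta_loglik(np.array([y]), X, Z, [b], [g])), 0, 1
        )
        assert total == pytest.approx(1.0, rel=1e-6)


def test_loglik_rejects_boundary_and_is_order_invariant(rng):
    y, X, Z, beta, gamma, _ = make_data(40, 3)
    perm = rng.permutation(40)
    assert beta_loglik(y, X, Z, beta, gamma) == pytest.approx(
        beta_loglik(y[perm], X[perm], Z[perm], beta, gamma)
    )
    with pytest.raises(ValueError, match="adjust_zeros"):
        beta_loglik(np.array([0.0, 0.5]), np.ones((2, 1)), np.ones((2, 1)), [0], [1])


def test_fit_matches_independent_optimizer():
    """Dual-route check: our Newton/quasi-Newton fit vs the independent
    generic-optimizer ML implementation in statsmodels, 20 random datasets."""
    from statsmodels.othermod.betareg import BetaModel

    worst = 0.0
    for seed in range(20):
        y, X, Z, *_ = make_data(100, seed)
        ours = BetaRegression(y, X, Z).fit()
        theirs = BetaModel(y, X, exog_precision=Z).fit(disp=0)
        assert ours.converged
        # accept either optimum being marginally tighter
        assert ours.llf >= theirs.llf - 1e-6
        worst = max(worst, np.max(np.abs(ours.params - theirs.params)))
    assert worst < 1e-4


def test_coefficient_recovery_within_3_se():
    y, X, Z, beta, gamma, _ = make_data(500, 11)
    res = BetaRegression(y, X, Z).fit()
    truth = np.concatenate([beta, gamma])
    assert np.all(np.abs(res.params - truth) < 3 * res.bse)


def test_intercept_only_moment_match(rng):
    y = rng.beta(0.3 * 40, 0.7 * 40, size=400)
    res = BetaRegression(y, np.ones((400, 1))).fit()
    mu_hat = special.expit(res.params[0])
    assert abs(mu_hat - y.mean()) < 2 * res.bse[0]


def test_fit_invariant_to_row_permutation(rng):
    y, X, Z, *_ = make_data(90, 4)
    res = BetaRegression(y, X, Z).fit()
    perm = rng.permutation(90)
    res_p = BetaRegression(y[perm], X[perm], Z[perm]).fit()
    assert np.allclose(res.params, res_p.params, atol=1e-8)


def test_rank_deficient_design_names_columns():
    y, X, Z, *_ = make_data(60, 5)
    Xbad = np.column_stack([X, X[:, 1]])
    with pytest.raises(ValueError, match="collinear"):
        BetaRegression(y, Xbad, Z, x_names=[f"c{i}" for i in range(8)])


def test_aic_identity_and_summary():
    y, X, Z, *_ = make_data(80, 6)
    res = BetaRegression(y, X, Z).fit()
    assert res.aic == pytest.approx(-2 * res.llf + 2 * res.k_params, abs=1e-9)
    assert np.all(res.fitted_mu > 0) and np.all(res.fitted_mu < 1)
    assert np.all(res.fitted_phi > 0)
    text = res.summary()
    assert "Precision submodel" in text and "pseudo R-squared" in text


def test_pseudo_r2_limits(rng):
    # noise-free limit: y generated at phi -> infinity collapses onto mu
    _, X, Z, beta, _, _ = make_data(200, 7)
    mu = special.expit(X @ beta)
    y = np.clip(mu + rng.normal(0, 1e-5, 200), 1e-8, 1 - 1e-8)
    res = BetaRegression(y, X).fit()
    assert res.pseudo_r2 > 0.999
    # response independent of X
    y0 = rng.beta(2, 30, 1000)
    Xn = np.column_stack([np.ones(1000), rng.normal(size=(1000, 3))])
    assert BetaRegression(y0, Xn).fit().pseudo_r2 < 0.02


def test_vif_orthogonal_collinear_and_oracle(rng):
    n = 200
    Q, _ = np.linalg.qr(rng.normal(size=(n, 4)))
    X = np.column_stack([np.ones(n), Q])
    v = vif(X, ["intercept", "a", "b", "c", "d"])
    assert np.allclose(v["vif"], 1.0, atol=1e-8)
    x1 = rng.normal(size=n)
    Xc = np.column_stack([np.ones(n), x1, x1 + rng.normal(0, 1e-3, n), rng.normal(size=n)])
    vc = vif(Xc)
    assert vc["vif"].iloc[0] > 5 and vc["vif"].iloc[1] > 5
    # oracle: statsmodels variance_inflation_factor
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    Xr = np.column_stack([np.ones(n), rng.normal(size=(n, 3)) @ rng.normal(size=(3, 3))])
    ours = vif(Xr)["vif"].to_numpy()
    theirs = [variance_inflation_factor(Xr, j) for j in range(1, 4)]
    assert np.allclose(ours, theirs, rtol=1e-8)


def test_mixed_null_variance_shrinks_to_zero():
    """With no real family effect the Laplace ML variance collapses toward
    the boundary in the large majority of replicates."""
    hits = 0
    trials = 40
    for s in range(trials):
        y, X, Z, *_, fam = make_data(128, 1000 + s, family_sd=0.0)
        fit = MixedBetaRegression(y, X, Z, groups=fam).fit()
        hits += fit.sigma**2 < 0.05
    assert hits >= 0.9 * trials


def test_mixed_detects_large_family_effect():
    detected = 0
    trials = 25
    for s in range(trials):
        y, X, Z, *_, fam = make_data(128, 2000 + s, family_sd=1.0)
        mfit = MixedBetaRegression(y, X, Z, groups=fam).fit()
        ffit = BetaRegression(y, X, Z).fit()
        lrt = 2 * (mfit.llf - ffit.llf)
        detected += (mfit.sigma > 0.3) and (lrt > 2.71)  # boundary 5% LRT
    assert detected >= 0.9 * trials


def test_mixed_single_family_errors():
    y, X, Z, *_ = make_data(50, 9)
    with pytest.raises(ValueError, match="2 groups"):
        MixedBetaRegression(y, X, Z, groups=np.zeros(50))


def test_model_selection_identities():
    y, X, Z, *_, fam = make_data(128, 21)
    table, winner, fits = model_selection(y, X, Z, fam)
    assert set(table["model"]) == {
        "fixed", "fixed+precision", "fixed+re", "fixed+precision+re"
    }
    for _, row in table.iterrows():
        fit = fits[row["model"]]
        assert row["aic"] == pytest.approx(-2 * fit.llf + 2 * fit.k_params, abs=1e-9)
    # nested fixed model never beats its superset on log-likelihood
    assert fits["fixed+precision"].llf >= fits["fixed"].llf - 1e-7
    assert fits["fixed+precision+re"].llf >= fits["fixed+precision"].llf - 1e-4


def test_bootstrap_deterministic_and_sane():
    y, X, Z, *_ = make_data(100, 31)
    res = BetaRegression(y, X, Z).fit()
    b1 = res.bootstrap(B=120, seed=7)
    b2 = BetaRegression(y, X, Z).fit().bootstrap(B=120, seed=7)
    assert np.array_equal(b1.params, b2.params)
    assert np.all(b1.ci_lower <= b1.ci_upper)
    inside = (res.params >= b1.ci_lower) & (res.params <= b1.ci_upper)
    assert inside.mean() >= 0.95
    with pytest.raises(ValueError):
        res.bootstrap(B=50)


def test_predict_effect_shapes(small_study):
    from macrodiv.predictors import assemble_design

    sp = small_study.species.rename(columns={"true_pi": "pi"})
    design = assemble_design(sp)
    res = BetaRegression.from_design(design).fit()
    curve = res.predict_effect(design, "body_size", n_grid=25)
    assert len(curve) == 25
    assert np.all((curve["mu"] > 0) & (curve["mu"] < 1))
    assert np.all(curve["ci_lower"] <= curve["mu"]) and np.all(
        curve["mu"] <= curve["ci_upper"]
    )
    # monotone on the response scale when driven by a single logit-linear term
    sign = np.sign(res.beta[design.x_names.index("body_size")])
    diffs = np.diff(curve["mu"].to_numpy())
    assert np.all(sign * diffs >= -1e-12)


def test_predict_effect_flat_for_zero_coefficient():
    rng = np.random.default_rng(8)
    n = 150
    from macrodiv.predictors import DesignMatrix

    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = rng.beta(2, 30, n)
    design = DesignMatrix(
        y=y, X=X, Z=np.ones((n, 1)), x_names=["intercept", "noise"],
        z_names=["intercept"], species_id=[str(i) for i in range(n)],
        family=["A"] * n,
    )
    res = BetaRegression.from_design(design).fit()
    forced = res.params.copy()
    forced[1] = 0.0
    res2 = BetaRegression.from_design(design).fit(start_params=forced)
    res2.params[1] = 0.0  # zero-coefficient predictor -> flat curve
    curve = res2.predict_effect(design, "noise", n_grid=10)
    assert np.ptp(curve["mu"].to_numpy()) < 1e-12
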