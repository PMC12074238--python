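"""Cumulative link mixed model fitting and the auxiliary statistics.

Oracles: closed-form multinomial cutpoints, an independent direct
log-likelihood summation, adaptive Gauss-Hermite quadrature (61 nodes),
statsmodels' OrderedModel for the no-random-effect case, hand-computed
mean-square fixtures for ICC, and brute-force midranks for Spearman.
"""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit
from scipy.stats import spearmanr

from oracles import agh_dataset_loglik, direct_cumlogit_loglik, midrank_spearman
from pamsim import (
    CumulativeLinkMixedModel,
    bartlett_sphericity,
    clmm_marginal_loglik,
    fit_clmm,
    icc3k,
    lr_test,
    rank_models,
    spearman_rho,
)
from pamsim.ordinal import _laplace_loglik
from pamsim.ratings import centered_cutpoints


def simulate_clmm(n_participants, per_group, beta, sd, seed, cutpoints=None):
    """Draw a long table straight from the model's own definition."""
    rng = np.random.default_rng(seed)
    cut = centered_cutpoints(0.0) if cutpoints is None else np.asarray(cutpoints)
    rows = []
    for p in range(n_participants):
        u = rng.normal(0.0, sd)
        x = rng.normal(0.0, 1.0, per_group)
        latent = beta * x + u + rng.logistic(size=per_group)
        y = 1 + np.digitize(latent, cut)
        for xi, yi in zip(x, y):
            rows.append({"participant": p, "x": xi, "rating": int(yi)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# marginal log-likelihood
# ---------------------------------------------------------------------------

def test_single_observation_null_loglik_is_log_half():
    data = pd.DataFrame({"rating": [1], "participant": [0]})
    ll = clmm_marginal_loglik([0.0], {}, 0.0, data, [])
    assert ll == pytest.approx(np.log(0.5), abs=1e-12)


def test_sd_zero_equals_direct_summation():
    rng = np.random.default_rng(3)
    data = pd.DataFrame({
        "rating": rng.integers(1, 8, 400),
        "x": rng.normal(size=400),
        "participant": np.arange(400) % 25,
    })
    cut = centered_cutpoints(0.3)
    ll = clmm_marginal_loglik(cut, {"x": 0.7}, 0.0, data, ["x"])
    direct = direct_cumlogit_loglik(cut, 0.7 * data["x"].to_numpy(), data["rating"].to_numpy())
    assert ll == pytest.approx(direct, abs=1e-10)


@pytest.mark.parametrize("sd,tol", [(0.1, 1e-4), (0.3, 1e-3)])
def test_laplace_matches_quadrature_for_small_heterogeneity(sd, tol):
    """In the small-sd regime (where the expansion is valid) the Laplace
    marginal agrees with 61-node adaptive Gauss-Hermite quadrature even for
    groups of 1-5 observations."""
    rng = np.random.default_rng(17)
    cut = centered_cutpoints(0.0)
    for _ in range(15):
        n_obs = int(rng.integers(1, 6))
        data = pd.DataFrame({
            "rating": rng.integers(1, 8, n_obs),
            "x": rng.normal(size=n_obs),
            "participant": 0,
        })
        ll = clmm_marginal_loglik(cut, {"x": 0.4}, sd, data, ["x"])
        exact = agh_dataset_loglik(cut, {"x": 0.4}, sd, data, ["x"])
        assert ll == pytest.approx(exact, abs=tol)


def test_laplace_bias_grows_with_random_intercept_sd():
    """Documented limitation: for a single observation per group at large sd
    the Laplace approximation deviates from the exact marginal by far more
    than in the small-sd regime (this is why AGQ exists)."""
    cut = centered_cutpoints(0.0)
    data = pd.DataFrame({"rating": [5], "participant": [0]})
    err = abs(
        clmm_marginal_loglik(cut, {}, 2.31, data, [])
        - agh_dataset_loglik(cut, {}, 2.31, data, [])
    )
    assert err > 1e-3  # orders of magnitude above the small-sd error


def test_loglik_rejects_bad_inputs():
    data = pd.DataFrame({"rating": [2], "participant": [0]})
    with pytest.raises(ValueError, match="increasing"):
        clmm_marginal_loglik([1.0, 0.5], {}, 0.0, data, [])
    with pytest.raises(ValueError, match="empty"):
        clmm_marginal_loglik([0.0], {}, 0.0, data.iloc[:0], [])
    with pytest.raises(ValueError, match="nonnegative"):
        clmm_marginal_loglik([0.0], {}, -1.0, data, [])


def test_shift_invariance_of_the_likelihood():
    """Adding a constant to all cutpoints and the linear predictor leaves the
    likelihood unchanged (no separate intercept is identifiable)."""
    rng = np.random.default_rng(5)
    data = pd.DataFrame({
        "rating": rng.integers(1, 8, 150),
        "x": rng.normal(size=150),
        "const": 1.0,
        "participant": np.arange(150) % 10,
    })
    cut = centered_cutpoints(0.0)
    base = clmm_marginal_loglik(cut, {"x": 0.4, "const": 0.0}, 1.0, data, ["x", "const"])
    shifted = clmm_marginal_loglik(cut + 2.5, {"x": 0.4, "const": 2.5}, 1.0, data, ["x", "const"])
    assert base == pytest.approx(shifted, abs=1e-8)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_null_model_cutpoints_are_logit_cumulative_proportions():
    rng = np.random.default_rng(8)
    y = rng.integers(1, 8, 500)
    data = pd.DataFrame({"rating": y, "participant": np.arange(500) % 20})
    fit = fit_clmm(data, [], estimate_random=False)
    counts = np.bincount(y, minlength=8)[1:]
    expected = logit(np.cumsum(counts[:-1]) / counts.sum())
    assert np.max(np.abs(fit.cutpoints - expected)) < 1e-6


def test_fit_matches_statsmodels_ordered_model():
    """With the random intercept off, the fit is a plain proportional-odds
    regression and must agree with an independent implementation."""
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    data = simulate_clmm(40, 10, beta=0.8, sd=0.0, seed=21)
    fit = fit_clmm(data, ["x"], estimate_random=False)
    sm_fit = OrderedModel(
        data["rating"].to_numpy(), data[["x"]].to_numpy(), distr="logit"
    ).fit(method="bfgs", disp=False)
    assert fit.slopes["x"] == pytest.approx(sm_fit.params[0], abs=1e-4)
    assert fit.loglik == pytest.approx(sm_fit.llf, abs=1e-6)


def test_aic_identity_and_param_count():
    data = simulate_clmm(30, 6, beta=0.5, sd=1.0, seed=2)
    fit = fit_clmm(data, ["x"])
    assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik, abs=1e-10)
    # 6 cutpoints + 1 slope + 1 random-intercept sd
    n_cats = data["rating"].nunique()
    assert fit.n_params == (n_cats - 1) + 1 + 1
    assert np.all(np.diff(fit.cutpoints) > 0)


def test_fit_requires_two_categories():
    data = pd.DataFrame({"rating": [3] * 10, "participant": range(10)})
    with pytest.raises(ValueError, match="2 distinct"):
        fit_clmm(data, [])


def test_unobserved_extreme_categories_are_collapsed():
    data = simulate_clmm(25, 8, beta=0.0, sd=0.5, seed=4)
    data = data[data["rating"].between(2, 6)].reset_index(drop=True)
    fit = fit_clmm(data, ["x"])
    assert len(fit.cutpoints) == data["rating"].nunique() - 1
    assert fit.converged


def test_null_slope_coverage():
    """Under beta = 0 the estimate stays within 3 SEs in >= 95% of replicates."""
    inside = 0
    reps = 60
    for rep in range(reps):
        data = simulate_clmm(1, 400, beta=0.0, sd=0.0, seed=1000 + rep)
        fit = fit_clmm(data, ["x"], estimate_random=False, compute_se=True)
        se = fit.slope_se["x"]
        inside += abs(fit.slopes["x"]) < 3 * se
    assert inside / reps >= 0.95


def test_estimator_is_sklearn_compatible():
    from sklearn.base import clone

    model = CumulativeLinkMixedModel(estimate_random=False)
    assert clone(model).get_params() == model.get_params()
    data = simulate_clmm(20, 8, beta=0.9, sd=0.0, seed=6)
    model.fit(data[["x"]], data["rating"])
    proba = model.predict_proba(data[["x"]])
    assert proba.shape == (len(data), data["rating"].nunique())
    assert np.allclose(proba.sum(axis=1), 1.0)
    preds = model.predict(data[["x"]])
    assert set(preds) <= set(model.categories_)
    # a positive slope pushes predictions up the scale
    hi = model.predict_proba(pd.DataFrame({"x": [3.0]}))[0]
    lo = model.predict_proba(pd.DataFrame({"x": [-3.0]}))[0]
    assert hi[-1] > lo[-1]


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

def test_lr_test_of_model_against_itself_is_null():
    data = simulate_clmm(15, 6, beta=0.4, sd=0.8, seed=10)
    fit = fit_clmm(data, ["x"])
    res = lr_test(fit, fit)
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_lr_statistic_formula_and_monotonicity():
    import dataclasses

    data = simulate_clmm(25, 8, beta=0.8, sd=0.8, seed=11)
    null = fit_clmm(data, [])
    full = fit_clmm(data, ["x"])
    res = lr_test(full, null)
    assert res.statistic == pytest.approx(2 * (full.loglik - null.loglik))
    assert res.df == 1
    # delta-loglik of 3 at one df gives statistic 6, and larger deltas give
    # larger statistics with smaller p-values
    inflated = dataclasses.replace(full, loglik=null.loglik + 3.0)
    res3 = lr_test(inflated, null)
    assert res3.statistic == pytest.approx(6.0)
    more = dataclasses.replace(full, loglik=null.loglik + 5.0)
    assert lr_test(more, null).statistic > res3.statistic
    assert lr_test(more, null).p_value < res3.p_value


def test_lr_test_rejects_different_data():
    a = fit_clmm(simulate_clmm(10, 5, 0.2, 0.5, seed=1), ["x"])
    b_null = fit_clmm(simulate_clmm(10, 5, 0.2, 0.5, seed=2), [])
    with pytest.raises(ValueError, match="different observations"):
        lr_test(a, b_null)


def test_rank_models_orders_by_aic_with_stable_ties():
    data = simulate_clmm(40, 4, beta=0.9, sd=1.0, seed=12)
    data["x_copy"] = data["x"]
    table = rank_models(data, [["x"], ["x_copy"]])
    assert list(table["aic"]) == sorted(table["aic"])
    tied = table[table["fixed_effects"].isin(["x", "x_copy"])]
    assert tied["aic"].iloc[0] == pytest.approx(tied["aic"].iloc[1], abs=1e-4)
    assert list(tied["fixed_effects"]) == ["x", "x_copy"]  # input order kept
    null_row = table[table["fixed_effects"] == "(null)"].iloc[0]
    assert null_row["lr"] == 0.0 and null_row["p_value"] == 1.0


def test_rank_models_prefers_the_generating_effect():
    """Data simulated with a real slope rank the slope model above the null
    in the majority of seeded replicates."""
    wins = 0
    reps = 30
    for rep in range(reps):
        data = simulate_clmm(30, 4, beta=0.6, sd=1.0, seed=300 + rep)
        table = rank_models(data, [["x"]])
        wins += table.iloc[0]["fixed_effects"] == "x"
    assert wins > reps / 2


def test_rank_models_survives_a_failing_candidate():
    data = simulate_clmm(20, 4, beta=0.5, sd=0.5, seed=13)
    table = rank_models(data, [["x"], ["missing_column"]])
    bad = table[table["fixed_effects"] == "missing_column"].iloc[0]
    assert bad["error"] != "" and np.isnan(bad["aic"])
    assert (table["error"] == "").sum() == 2  # null and the good candidate


# ---------------------------------------------------------------------------
# ICC, Spearman, Bartlett
# ---------------------------------------------------------------------------

def test_icc3k_perfect_consistency_is_one():
    m = np.tile([2.0, 5.0, 7.0], (4, 1))  # raters identical, items differ
    assert icc3k(m).icc == pytest.approx(1.0, abs=1e-12)


def test_icc3k_matches_hand_computed_mean_squares():
    m = [[2.0, 4.0, 6.0], [3.0, 5.0, 7.0], [2.0, 6.0, 7.0]]
    res = icc3k(m)
    # MS_items = 43/3, MS_error = 1/3 -> ICC = 42/43
    assert res.icc == pytest.approx(42 / 43, abs=1e-12)
    assert res.form == "ICC(3,k)" and res.n_raters == 3 and res.n_items == 3


def test_icc3k_matches_pingouin():
    import pingouin as pg

    rng = np.random.default_rng(30)
    m = rng.normal(size=(12, 4)) + np.linspace(0, 2, 4)
    long = pd.DataFrame(
        {
            "rater": np.repeat(np.arange(12), 4),
            "item": np.tile(np.arange(4), 12),
            "score": m.ravel(),
        }
    )
    pg_val = pg.intraclass_corr(long, targets="item", raters="rater", ratings="score")
    # ICC(C,k): two-way consistency, average of k raters == ICC(3,k)
    pg_icc3k = pg_val.loc[pg_val["Type"] == "ICC(C,k)", "ICC"].iloc[0]
    assert icc3k(m).icc == pytest.approx(pg_icc3k, abs=1e-10)


def test_icc3k_of_pure_noise_centers_on_zero():
    rng = np.random.default_rng(31)
    vals = [icc3k(rng.uniform(size=(50, 4))).icc for _ in range(200)]
    se = np.std(vals, ddof=1) / np.sqrt(len(vals))
    assert abs(np.mean(vals)) < 3 * se + 0.02


def test_icc3k_rejects_missing_cells_and_tiny_matrices():
    with pytest.raises(ValueError, match="missing"):
        icc3k([[1.0, np.nan], [2.0, 3.0]])
    with pytest.raises(ValueError, match="at least 2"):
        icc3k([[1.0, 2.0]])


def test_spearman_monotone_pairs():
    assert spearman_rho([1, 2, 5, 9], [2, 4, 5, 20]) == pytest.approx(1.0)
    assert spearman_rho([1, 2, 5, 9], [8, 6, 3, 1]) == pytest.approx(-1.0)


def test_spearman_ties_match_midrank_oracle_and_scipy():
    x = [1, 2, 2, 3, 5, 5, 5, 7, 8, 8]
    y = [2, 1, 4, 4, 6, 5, 8, 7, 9, 9]
    rho = spearman_rho(x, y)
    assert rho == pytest.approx(midrank_spearman(x, y), abs=1e-12)
    assert rho == pytest.approx(spearmanr(x, y).statistic, abs=1e-12)


def test_spearman_rejects_constant_or_short_input():
    with pytest.raises(ValueError, match="constant"):
        spearman_rho([1, 1, 1], [1, 2, 3])
    with pytest.raises(ValueError, match="at least 3"):
        spearman_rho([1, 2], [3, 4])


def test_bartlett_identity_correlation_gives_zero_statistic():
    X = np.array([[1.0, 1.0], [1.0, -1.0], [-1.0, 1.0], [-1.0, -1.0]] * 3)
    stat, df, p = bartlett_sphericity(X)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert df == 1 and p == pytest.approx(1.0)


def test_bartlett_df_formula():
    rng = np.random.default_rng(40)
    _, df, _ = bartlett_sphericity(rng.normal(size=(30, 4)))
    assert df == 6


def test_bartlett_matches_direct_formula_on_fixture():
    x = np.arange(10, dtype=float)
    y = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 7.0, 6.0, 9.0, 8.0, 10.0])
    stat, df, p = bartlett_sphericity(np.column_stack([x, y]))
    assert stat == pytest.approx(17.684233954326892, abs=1e-9)
    assert df == 1
    assert p == pytest.approx(2.607791347455895e-05, rel=1e-6)


def test_bartlett_rejects_degenerate_input():
    with pytest.raises(ValueError, match="singular"):
        x = np.arange(10.0)
        bartlett_sphericity(np.column_stack([x, 2 * x]))
    with pytest.raises(ValueError, match="more observations"):
        bartlett_sphericity(np.ones((2, 3)))
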