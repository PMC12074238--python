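"""Cumulative link mixed models and the surrounding rating-analysis statistics.

The centerpiece is a proportional-odds (cumulative logit) model with a
Gaussian random intercept per participant,

    P(Y_ij <= k | u_i) = logistic(theta_k - x_ij . beta - u_i),
    u_i ~ N(0, sigma^2),

whose marginal likelihood integrates each participant's intercept out by the
Laplace approximation around the conditional mode -- the same strategy R's
``ordinal::clmm`` uses by default.  There is no separate fixed intercept: it
is absorbed into the cutpoints ``theta``, so the likelihood is invariant
under a joint shift of cutpoints and linear predictor.

Also provided: likelihood-ratio tests, AIC model ranking, ICC(3,k)
inter-rater reliability, Spearman rank correlation, and Bartlett's test of
sphericity.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit
from sklearn.base import BaseEstimator

__all__ = [
    "CumulativeLinkMixedModel",
    "ClmmFit",
    "LRTestResult",
    "IccResult",
    "clmm_marginal_loglik",
    "fit_clmm",
    "lr_test",
    "rank_models",
    "icc3k",
    "spearman_rho",
    "bartlett_sphericity",
]

_SD_FLOOR = 1e-8  # below this the random intercept is treated as absent
_P_FLOOR = 1e-300


class ConvergenceWarning(UserWarning):
    pass


# ---------------------------------------------------------------------------
# marginal log-likelihood (Laplace)
# ---------------------------------------------------------------------------

def _category_terms(z_hi: np.ndarray, z_lo: np.ndarray):
    """log P, dlogP/du and d2logP/du2 for P = F(z_hi - u') - F(z_lo - u').

    ``z`` already includes the subtraction of eta and u.  Logistic density
    f = F(1-F) with f' = f(1-2F).
    """
    F_hi = expit(z_hi)
    F_lo = expit(z_lo)
    P = np.maximum(F_hi - F_lo, _P_FLOOR)
    f_hi = F_hi * (1.0 - F_hi)
    f_lo = F_lo * (1.0 - F_lo)
    dP = -(f_hi - f_lo)
    d2P = f_hi * (1.0 - 2.0 * F_hi) - f_lo * (1.0 - 2.0 * F_lo)
    g = dP / P
    return np.log(P), g, d2P / P - g * g


def _laplace_loglik(
    cutpoints: np.ndarray,
    eta: np.ndarray,
    sd: float,
    y: np.ndarray,
    group_idx: np.ndarray,
    n_groups: int,
    max_newton: int = 100,
) -> float:
    """Sum of per-group Laplace-approximate log marginal likelihoods.

    ``y`` holds categories 1..K with K = len(cutpoints) + 1; ``group_idx``
    maps observations to 0..n_groups-1.  With ``sd`` at zero this reduces
    exactly to the fixed-effects cumulative-logit log-likelihood.
    """
    ext = np.concatenate(([-np.inf], np.asarray(cutpoints, dtype=float), [np.inf]))
    a_hi = ext[y] - eta
    a_lo = ext[y - 1] - eta

    if sd < _SD_FLOOR:
        logp, _, _ = _category_terms(a_hi, a_lo)
        return float(np.sum(logp))

    inv_var = 1.0 / (sd * sd)

    def group_h(u: np.ndarray) -> np.ndarray:
        logp, _, _ = _category_terms(a_hi - u[group_idx], a_lo - u[group_idx])
        return np.bincount(group_idx, weights=logp, minlength=n_groups) - 0.5 * u * u * inv_var

    u = np.zeros(n_groups)
    h_cur = group_h(u)
    hess = np.full(n_groups, -inv_var)
    for _ in range(max_newton):
        logp, g, h2 = _category_terms(a_hi - u[group_idx], a_lo - u[group_idx])
        grad = np.bincount(group_idx, weights=g, minlength=n_groups) - u * inv_var
        hess = np.bincount(group_idx, weights=h2, minlength=n_groups) - inv_var
        if np.max(np.abs(grad)) < 1e-9:
            break
        step = -grad / hess
        np.clip(step, -5.0 * sd - 5.0, 5.0 * sd + 5.0, out=step)
        # damped Newton: halve steps for groups whose objective decreased
        for _half in range(30):
            h_new = group_h(u + step)
            worse = h_new < h_cur - 1e-13
            if not np.any(worse):
                break
            step[worse] *= 0.5
        u = u + step
        h_cur = group_h(u)
        if np.max(np.abs(step)) < 1e-12:
            break

    return float(np.sum(h_cur - 0.5 * np.log(-hess) - np.log(sd)))


def clmm_marginal_loglik(
    cutpoints,
    slopes: dict[str, float] | None,
    random_intercept_sd: float,
    dataset: pd.DataFrame,
    fixed: list[str] | None = None,
    outcome: str = "rating",
    group: str = "participant",
) -> float:
    """Laplace-approximate marginal log-likelihood at given parameter values.

    ``slopes`` maps covariate columns of ``dataset`` to coefficients; with
    ``random_intercept_sd = 0`` the value equals the plain cumulative-logit
    log-likelihood exactly.
    """
    cut = np.asarray(cutpoints, dtype=float)
    if cut.ndim != 1 or cut.size < 1:
        raise ValueError("need at least one cutpoint")
    if not np.all(np.diff(cut) > 0):
        raise ValueError("invalid parameters: cutpoints must be strictly increasing")
    if random_intercept_sd < 0:
        raise ValueError("random_intercept_sd must be nonnegative")
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    slopes = dict(slopes or {})
    if fixed is None:
        fixed = list(slopes)
    y = dataset[outcome].to_numpy()
    if np.any(y < 1) or np.any(y > cut.size + 1):
        raise ValueError(f"ratings must lie in 1..{cut.size + 1}")
    eta = np.zeros(len(dataset))
    for name in fixed:
        if name not in dataset.columns:
            raise ValueError(f"dataset missing covariate column {name!r}")
        eta += slopes.get(name, 0.0) * dataset[name].to_numpy(dtype=float)
    if group in dataset.columns:
        codes, uniques = pd.factorize(dataset[group])
        if (np.bincount(codes, minlength=len(uniques)) == 0).any():
            raise ValueError("empty participant group")
    else:
        codes, uniques = np.zeros(len(dataset), dtype=int), [0]
    return _laplace_loglik(cut, eta, float(random_intercept_sd), y.astype(int), codes, len(uniques))


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class CumulativeLinkMixedModel(BaseEstimator):
    """Proportional-odds regression with a per-group Gaussian random intercept.

    scikit-learn-style estimator: ``fit(X, y, groups=...)`` maximizes the
    Laplace marginal likelihood by quasi-Newton (L-BFGS-B) from a documented
    initialization (cutpoints at the logit of empirical cumulative
    proportions, slopes at zero, log-sd at zero).  The random-intercept
    standard deviation is optimized on the log scale to keep it positive.

    Parameters
    ----------
    estimate_random : bool
        If False the random intercept is fixed at zero and the fit is a plain
        cumulative-logit (proportional-odds) regression.
    max_iter : int
        L-BFGS-B iteration cap.
    compute_se : bool
        If True, slope standard errors are computed from the numerically
        differentiated observed information at the optimum.

    Attributes
    ----------
    cutpoints_ : ndarray
        Increasing threshold estimates (no separate intercept: it is absorbed
        here).
    coef_ : ndarray and slopes_ : dict
        Fixed-effect estimates.
    random_intercept_sd_ : float
    loglik_, aic_, n_params_, converged_, n_obs_, n_groups_ : fit summary.
    categories_ : ndarray
        Observed outcome categories; unobserved categories are collapsed away
        (with a warning) rather than failing.
    """

    def __init__(self, estimate_random: bool = True, max_iter: int = 500,
                 compute_se: bool = False):
        self.estimate_random = estimate_random
        self.max_iter = max_iter
        self.compute_se = compute_se

    # -- internal packing: [theta_1, log diff_2.., beta.., log sd?] ---------
    def _unpack(self, z: np.ndarray, n_cut: int, n_feat: int):
        cut = np.empty(n_cut)
        cut[0] = z[0]
        if n_cut > 1:
            cut[1:] = z[0] + np.cumsum(np.exp(z[1:n_cut]))
        beta = z[n_cut:n_cut + n_feat]
        sd = np.exp(z[-1]) if self.estimate_random else 0.0
        return cut, beta, sd

    def fit(self, X, y, groups=None):
        X, names = _as_matrix(X)
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        if np.any(y != np.floor(y)):
            raise ValueError("ordinal outcomes must be integers")
        y = y.astype(int)
        cats = np.unique(y)
        if cats.size < 2:
            raise ValueError("need at least 2 distinct rating categories")
        if self.estimate_random:
            if groups is None:
                raise ValueError("groups required when estimating a random intercept")
            group_idx, uniques = pd.factorize(np.asarray(groups))
            n_groups = len(uniques)
        else:
            group_idx = np.zeros(len(y), dtype=int)
            n_groups = 1

        # unobserved categories (extreme or interior) are collapsed away by
        # re-ranking the observed ones; interior gaps merit a warning
        y_mapped = np.searchsorted(cats, y) + 1
        if cats.size < cats.max() - cats.min() + 1:
            warnings.warn(
                "unobserved interior rating categories collapsed into neighbors",
                ConvergenceWarning, stacklevel=2,
            )
        K = cats.size
        n_cut = K - 1
        n_feat = X.shape[1]

        # documented initialization
        counts = np.bincount(y_mapped, minlength=K + 1)[1:]
        cum = np.cumsum(counts[:-1]) / counts.sum()
        cut0 = logit(cum)
        z0 = np.empty(n_cut + n_feat + (1 if self.estimate_random else 0))
        z0[0] = cut0[0]
        if n_cut > 1:
            z0[1:n_cut] = np.log(np.maximum(np.diff(cut0), 1e-6))
        z0[n_cut:n_cut + n_feat] = 0.0
        if self.estimate_random:
            z0[-1] = 0.0

        def negloglik(z):
            cut, beta, sd = self._unpack(z, n_cut, n_feat)
            eta = X @ beta
            return -_laplace_loglik(cut, eta, sd, y_mapped, group_idx, n_groups)

        res = optimize.minimize(
            negloglik, z0, method="L-BFGS-B",
            options={"maxiter": self.max_iter, "ftol": 1e-12, "gtol": 1e-8},
        )
        cut, beta, sd = self._unpack(res.x, n_cut, n_feat)
        self.converged_ = bool(res.success)
        if not res.success:
            warnings.warn(
                f"CLMM optimizer did not converge: {res.message}",
                ConvergenceWarning, stacklevel=2,
            )
        if n_feat and np.max(np.abs(beta)) > 30:
            self.converged_ = False
            warnings.warn(
                "possible complete separation: a slope diverged",
                ConvergenceWarning, stacklevel=2,
            )

        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = n_feat
        self.categories_ = cats
        self.cutpoints_ = cut
        self.coef_ = beta
        self.slopes_ = dict(zip(names, beta.tolist()))
        self.random_intercept_sd_ = float(sd)
        self.loglik_ = float(-res.fun)
        self.n_params_ = n_cut + n_feat + (1 if self.estimate_random else 0)
        self.aic_ = 2.0 * self.n_params_ - 2.0 * self.loglik_
        self.n_obs_ = int(len(y))
        self.n_groups_ = int(n_groups)
        self.se_ = None
        if self.compute_se:
            self.se_ = self._slope_se(negloglik, res.x, n_cut, n_feat, names)
        return self

    def _slope_se(self, negloglik, z_opt, n_cut, n_feat, names):
        """Slope SEs via central-difference observed information.

        The slopes are raw coordinates of the packed parameter, so their
        sampling variance is read off the inverse Hessian directly.
        """
        if n_feat == 0:
            return {}
        n = z_opt.size
        step = 1e-4 * np.maximum(1.0, np.abs(z_opt))
        H = np.empty((n, n))
        f0 = negloglik(z_opt)
        for i in range(n):
            for j in range(i, n):
                ei = np.zeros(n); ei[i] = step[i]
                ej = np.zeros(n); ej[j] = step[j]
                if i == j:
                    val = (negloglik(z_opt + ei) - 2 * f0 + negloglik(z_opt - ei)) / step[i] ** 2
                else:
                    val = (
                        negloglik(z_opt + ei + ej) - negloglik(z_opt + ei - ej)
                        - negloglik(z_opt - ei + ej) + negloglik(z_opt - ei - ej)
                    ) / (4 * step[i] * step[j])
                H[i, j] = H[j, i] = val
        try:
            cov = np.linalg.inv(H)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:  # pragma: no cover - singular information
            return {name: np.nan for name in names}
        return dict(zip(names, se[n_cut:n_cut + n_feat].tolist()))

    # -- prediction at the population median (u = 0) ------------------------
    def predict_proba(self, X):
        X, _ = _as_matrix(X, self.feature_names_in_)
        eta = X @ self.coef_
        ext = np.concatenate(([-np.inf], self.cutpoints_, [np.inf]))
        cdf = expit(ext[None, :] - eta[:, None])
        return np.diff(cdf, axis=1)

    def predict(self, X):
        return self.categories_[np.argmax(self.predict_proba(X), axis=1)]

    def score(self, X, y):
        """Mean conditional (u = 0) log-likelihood per observation."""
        proba = self.predict_proba(X)
        y = np.asarray(y).astype(int)
        idx = np.searchsorted(self.categories_, y)
        return float(np.mean(np.log(np.maximum(proba[np.arange(len(y)), idx], _P_FLOOR))))


def _as_matrix(X, expected_names=None):
    if X is None:
        raise ValueError("X must be an array or DataFrame (may have zero columns)")
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        mat = X.to_numpy(dtype=float)
    else:
        mat = np.asarray(X, dtype=float)
        if mat.ndim == 1:
            mat = mat[:, None]
        names = [f"x{i}" for i in range(mat.shape[1])]
    if expected_names is not None:
        expected = list(expected_names)
        if isinstance(X, pd.DataFrame):
            missing = [c for c in expected if c not in X.columns]
            if missing:
                raise ValueError(f"missing feature columns: {missing}")
            mat = X[expected].to_numpy(dtype=float)
            names = expected
        elif mat.shape[1] != len(expected):
            raise ValueError("feature count mismatch")
    return mat, names


# ---------------------------------------------------------------------------
# fit summaries and model comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClmmFit:
    """Summary of one fitted cumulative link mixed model."""

    cutpoints: np.ndarray
    slopes: dict[str, float]
    random_intercept_sd: float
    loglik: float
    n_params: int
    aic: float
    converged: bool
    n_obs: int
    n_groups: int
    fixed: tuple[str, ...] = ()
    slope_se: dict[str, float] | None = None
    data_hash: str = ""


@dataclass(frozen=True)
class LRTestResult:
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class IccResult:
    icc: float
    form: str
    n_items: int
    n_raters: int


def _hash_observations(y: np.ndarray, groups: np.ndarray) -> str:
    md = hashlib.md5()
    md.update(np.asarray(y).astype(np.int64).tobytes())
    md.update("|".join(map(str, np.asarray(groups))).encode())
    return md.hexdigest()


def fit_clmm(
    dataset: pd.DataFrame,
    fixed: list[str],
    estimate_random: bool = True,
    outcome: str = "rating",
    group: str = "participant",
    compute_se: bool = False,
    max_iter: int = 500,
) -> ClmmFit:
    """Fit a CLMM on a long-format rating table and return its summary."""
    for col in [outcome] + ([group] if estimate_random else []) + list(fixed):
        if col not in dataset.columns:
            raise ValueError(f"dataset missing column {col!r}")
    X = dataset[list(fixed)] if fixed else pd.DataFrame(index=dataset.index)
    y = dataset[outcome].to_numpy()
    groups = dataset[group].to_numpy() if group in dataset.columns else np.zeros(len(dataset))
    model = CumulativeLinkMixedModel(
        estimate_random=estimate_random, max_iter=max_iter, compute_se=compute_se
    )
    model.fit(X, y, groups=groups if estimate_random else None)
    return ClmmFit(
        cutpoints=model.cutpoints_,
        slopes=model.slopes_,
        random_intercept_sd=model.random_intercept_sd_,
        loglik=model.loglik_,
        n_params=model.n_params_,
        aic=model.aic_,
        converged=model.converged_,
        n_obs=model.n_obs_,
        n_groups=model.n_groups_,
        fixed=tuple(fixed),
        slope_se=model.se_,
        data_hash=_hash_observations(y, groups),
    )


def lr_test(full: ClmmFit, null: ClmmFit) -> LRTestResult:
    """Likelihood-ratio test of a nested null against a full model.

    The statistic is 2 * (loglik_full - loglik_null) with a chi-square
    upper-tail p-value on the parameter-count difference.  Both fits must
    come from identical observations and the null's fixed effects must be a
    subset of the full's.
    """
    if full.data_hash != null.data_hash or full.n_obs != null.n_obs:
        raise ValueError("models were fitted on different observations")
    if not set(null.fixed) <= set(full.fixed):
        raise ValueError("null model is not nested in the full model")
    stat = max(2.0 * (full.loglik - null.loglik), 0.0)
    df = full.n_params - null.n_params
    if df < 0:
        raise ValueError("null model has more parameters than the full model")
    if df == 0:
        p = 1.0 if stat < 1e-10 else 0.0
    else:
        p = float(stats.chi2.sf(stat, df))
    return LRTestResult(statistic=float(stat), df=df, p_value=p)


def rank_models(
    dataset: pd.DataFrame,
    candidate_fixed_sets: list[list[str]],
    outcome: str = "rating",
    group: str = "participant",
    estimate_random: bool = True,
) -> pd.DataFrame:
    """Fit candidate fixed-effect sets and rank them by ascending AIC.

    The random-intercept-only null model heads the comparison; each row
    reports AIC, maximized log-likelihood and the LR test against the null.
    Rows whose fit fails carry the error message and NaN statistics; ties
    keep input order (stable sort).
    """
    null = fit_clmm(dataset, [], estimate_random=estimate_random,
                    outcome=outcome, group=group)
    rows = [
        {
            "fixed_effects": "(null)",
            "aic": null.aic,
            "loglik": null.loglik,
            "lr": 0.0,
            "df": 0,
            "p_value": 1.0,
            "converged": null.converged,
            "error": "",
        }
    ]
    for fixed in candidate_fixed_sets:
        try:
            fit = fit_clmm(dataset, list(fixed), estimate_random=estimate_random,
                           outcome=outcome, group=group)
            test = lr_test(fit, null)
            rows.append({
                "fixed_effects": " + ".join(fixed) if fixed else "(null)",
                "aic": fit.aic,
                "loglik": fit.loglik,
                "lr": test.statistic,
                "df": test.df,
                "p_value": test.p_value,
                "converged": fit.converged,
                "error": "",
            })
        except Exception as exc:  # noqa: BLE001 - report per-row, continue others
            rows.append({
                "fixed_effects": " + ".join(fixed) if fixed else "(null)",
                "aic": np.nan, "loglik": np.nan, "lr": np.nan, "df": 0,
                "p_value": np.nan, "converged": False, "error": str(exc),
            })
    table = pd.DataFrame(rows)
    return table.sort_values("aic", kind="stable", na_position="last").reset_index(drop=True)


# ---------------------------------------------------------------------------
# reliability and auxiliary tests
# ---------------------------------------------------------------------------

def icc3k(wide_matrix) -> IccResult:
    """ICC(3,k): two-way mixed, consistency, average-measures reliability.

    ``wide_matrix`` is raters x items (e.g. participants x conditions).  From
    the two-way ANOVA mean squares, ICC(3,k) = (MS_items - MS_error) /
    MS_items.  Missing cells are rejected; no imputation.
    """
    m = np.asarray(wide_matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("need a 2-D raters x items matrix")
    n_raters, n_items = m.shape
    if n_raters < 2 or n_items < 2:
        raise ValueError("need at least 2 raters and 2 items")
    if np.any(~np.isfinite(m)):
        raise ValueError("missing cells are not allowed (no imputation)")
    grand = m.mean()
    ss_items = n_raters * np.sum((m.mean(axis=0) - grand) ** 2)
    ss_raters = n_items * np.sum((m.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_items - ss_raters
    ms_items = ss_items / (n_items - 1)
    ms_err = ss_err / ((n_items - 1) * (n_raters - 1))
    if ms_items == 0:
        raise ValueError("no between-item variance; ICC undefined")
    return IccResult(
        icc=float((ms_items - ms_err) / ms_items),
        form="ICC(3,k)",
        n_items=n_items,
        n_raters=n_raters,
    )


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of midranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant vector")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    return float(np.corrcoef(rx, ry)[0, 1])


def bartlett_sphericity(data_matrix) -> tuple[float, int, float]:
    """Bartlett's test that the correlation matrix is the identity.

    statistic = -(n - 1 - (2p + 5) / 6) * ln det(R) on the sample correlation
    matrix R of an n x p data matrix; df = p(p - 1)/2; chi-square upper-tail
    p-value.
    """
    X = np.asarray(data_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("need a 2-D observations x variables matrix")
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 variables")
    if n <= p:
        raise ValueError("need more observations than variables")
    R = np.corrcoef(X, rowvar=False)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0 or not np.isfinite(logdet):
        raise ValueError("singular correlation matrix")
    statistic = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    return float(statistic), int(df), float(stats.chi2.sf(statistic, df))
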