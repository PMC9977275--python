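"""Diversity-slope models: how community diversity predicts intra-species
diversity.

Cross-sectional fits regress an intra-species response (polymorphism rate,
strain count) on a community-diversity predictor (Shannon, richness, or
rarefied richness at a chosen rank), always with per-sample read count as a
covariate and with predictors standardized to zero mean and unit variance.
Temporal fits model change/gain/loss responses with a diversity × time-lag
interaction. Response families follow the response type: beta with logit
link for rates in (0,1) (diversity entering through an unpenalized B-spline
basis), zero-truncated Poisson / NB1 / NB2 for strain counts with the family
chosen by AIC, NB1 / NB2 for gain and loss counts, and Gaussian on a signed
log transform for polymorphism change. Inference is by drop-one likelihood
ratio tests, never Wald z-tests.

A single random-intercept grouping factor is supported through Gauss-Hermite
marginal likelihoods; the fixed-effects path delegates to statsmodels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize
from scipy.special import gammaln, roots_hermite
import statsmodels.api as sm
from statsmodels.discrete.discrete_model import NegativeBinomialP
from statsmodels.discrete.truncated_model import (
    TruncatedLFNegativeBinomialP,
    TruncatedLFPoisson,
)
from statsmodels.gam.smooth_basis import BSplines
from statsmodels.othermod.betareg import BetaModel

COUNT_FAMILIES_TRUNCATED = ("trunc_poisson", "trunc_nb_linear", "trunc_nb_quadratic")
COUNT_FAMILIES = ("nb_linear", "nb_quadratic")

ADMISSIBLE_FAMILIES = {
    "strain_count": COUNT_FAMILIES_TRUNCATED,
    "genes_lost": COUNT_FAMILIES,
    "genes_gained": COUNT_FAMILIES,
    "polymorphism_rate": ("beta_logit",),
    "polymorphism_change": ("gaussian_log_response",),
}


def standardize(x) -> np.ndarray:
    """Center to mean 0 and scale to unit sample SD (n−1 denominator).

    Raises ``ValueError`` on vectors without at least two distinct values.
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError("standardize expects a 1-D vector")
    if len(np.unique(arr)) < 2:
        raise ValueError("cannot standardize a constant vector")
    return (arr - arr.mean()) / arr.std(ddof=1)


def signed_log(x, scale: float = 1e-5) -> np.ndarray:
    """sign(x)·log1p(|x|/scale): a symmetric log transform for responses
    spanning orders of magnitude in both signs (polymorphism change)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.log1p(np.abs(x) / scale)


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: response/predictor pair, covariates, family policy."""

    response: str
    predictor: str = "shannon"
    rank: str = "species"
    covariates: tuple = ("read_count",)
    interaction_with_lag: bool = False
    random_effects: tuple = ()
    family: str | None = None          # None -> AIC over the admissible set
    smooth_df: int = 4                 # B-spline basis size for smooth terms
    smooth_predictor: bool = True      # smooth the diversity term in
    # beta/gaussian fits (count families are always linear on the log scale)

    def admissible_families(self) -> tuple:
        if self.family is not None:
            return (self.family,)
        if self.response not in ADMISSIBLE_FAMILIES:
            raise ValueError(f"unknown response '{self.response}'")
        return ADMISSIBLE_FAMILIES[self.response]


@dataclass
class LRTResult:
    term: str
    statistic: float
    df: int
    p_value: float


@dataclass
class SlopeFit:
    """A fitted diversity-slope model (or a diagnosed failure).

    ``params``/``bse``/``conf_int`` are indexed by design column;
    ``term_columns`` maps model terms (e.g. the smooth of the predictor) to
    their design columns for drop-one tests. ``slope`` is the diversity
    effect on the standardized-predictor scale: the coefficient for linear
    terms, the mean derivative of the fitted smooth otherwise.
    """

    spec: ModelSpec
    family: str | None = None
    success: bool = False
    failure_reason: str | None = None
    params: pd.Series | None = None
    bse: pd.Series | None = None
    conf_int: pd.DataFrame | None = None
    logL: float = np.nan
    aic: float = np.nan
    n_obs: int = 0
    slope: float = np.nan
    slope_ci: tuple = (np.nan, np.nan)
    term_columns: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    random_effect_sd: float | None = None
    # private refit handles
    _X: pd.DataFrame | None = None
    _y: np.ndarray | None = None
    _groups: np.ndarray | None = None
    _smoother: object | None = None
    _cov: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# family engines (fixed effects)
# ---------------------------------------------------------------------------

def _fit_family(family: str, y: np.ndarray, X: pd.DataFrame):
    """Fit one family by maximum likelihood.

    Returns (params, bse, conf_int, llf, aic, mu, var, cov) with pandas
    labels; ``mu``/``var`` are the fitted mean and model variance used for
    the overdispersion diagnostic (None where not meaningful). Raises on
    optimizer failure; the caller turns that into a fit-failure result.
    """
    Xv = X.to_numpy(dtype=float)
    names = list(X.columns)
    with warnings.catch_warnings(), np.errstate(all="ignore"):
        warnings.simplefilter("ignore")
        if family in COUNT_FAMILIES_TRUNCATED + COUNT_FAMILIES:
            start = sm.GLM(y, Xv, family=sm.families.Poisson()).fit().params
            if family == "trunc_poisson":
                res = TruncatedLFPoisson(y, Xv).fit(
                    start_params=start, method="bfgs", maxiter=500, disp=0
                )
            else:
                p = 1 if family.endswith("linear") else 2
                cls = (
                    TruncatedLFNegativeBinomialP
                    if family.startswith("trunc")
                    else NegativeBinomialP
                )
                res = cls(y, Xv, p=p).fit(
                    start_params=np.append(start, 0.5), method="bfgs",
                    maxiter=500, disp=0,
                )
                names = names + ["alpha"]
            if not np.all(np.isfinite(res.params)):
                raise RuntimeError("non-finite parameters")
            mu = np.exp(Xv @ res.params[: Xv.shape[1]])
            if family == "trunc_poisson":
                var = mu.copy()
            else:
                alpha = float(res.params[-1])
                var = mu * (1 + alpha) if family.endswith("linear") else mu * (1 + alpha * mu)
        elif family == "beta_logit":
            n = len(y)
            y_adj = np.clip((y * (n - 1) + 0.5) / n, 1e-12, 1 - 1e-12)
            res = BetaModel(y_adj, Xv, exog_precision=np.ones((n, 1))).fit(
                method="bfgs", maxiter=500, disp=0
            )
            names = names + ["ln_precision"]
            eta = Xv @ res.params[: Xv.shape[1]]
            mu = 1 / (1 + np.exp(-eta))
            phi = np.exp(res.params[-1])
            var = mu * (1 - mu) / (1 + phi)
        elif family == "gaussian_log_response":
            res = sm.OLS(y, Xv).fit()
            mu = np.asarray(res.fittedvalues)
            var = np.full_like(mu, float(res.scale))
        else:
            raise ValueError(f"unknown family '{family}'")
    params = pd.Series(np.asarray(res.params), index=names)
    bse = pd.Series(np.asarray(res.bse), index=names)
    ci = pd.DataFrame(np.asarray(res.conf_int()), index=names, columns=["lo", "hi"])
    cov = pd.DataFrame(np.asarray(res.cov_params()), index=names, columns=names)
    return params, bse, ci, float(res.llf), float(res.aic), mu, var, cov


# ---------------------------------------------------------------------------
# random-intercept marginal likelihoods (one grouping factor, Gauss-Hermite)
# ---------------------------------------------------------------------------

def _obs_loglik(family: str, y, eta, extra):
    """Per-observation log-likelihood at linear predictor eta."""
    if family == "trunc_poisson":
        mu = np.exp(eta)
        return y * eta - mu - gammaln(y + 1) - np.log1p(-np.exp(-np.clip(mu, 1e-12, 700)))
    if family in ("trunc_nb_linear", "trunc_nb_quadratic", "nb_linear", "nb_quadratic"):
        alpha = np.exp(extra[0])
        mu = np.exp(eta)
        if family.endswith("linear"):
            n = mu / alpha
            pr = np.full_like(mu, 1.0 / (1.0 + alpha))
        else:
            n = 1.0 / alpha
            pr = n / (n + mu)
        ll = (
            gammaln(y + n) - gammaln(n) - gammaln(y + 1)
            + n * np.log(pr) + y * np.log1p(-pr)
        )
        if family.startswith("trunc"):
            ll -= np.log1p(-np.exp(n * np.log(pr)))
        return ll
    if family == "gaussian_log_response":
        sigma = np.exp(extra[0])
        return stats.norm.logpdf(y, eta, sigma)
    if family == "beta_logit":
        phi = np.exp(extra[0])
        mu = 1 / (1 + np.exp(-eta))
        a = np.clip(mu * phi, 1e-8, None)
        b = np.clip((1 - mu) * phi, 1e-8, None)
        return stats.beta.logpdf(y, a, b)
    raise ValueError(family)


_N_EXTRA = {
    "trunc_poisson": 0,
    "trunc_nb_linear": 1,
    "trunc_nb_quadratic": 1,
    "nb_linear": 1,
    "nb_quadratic": 1,
    "gaussian_log_response": 1,
    "beta_logit": 1,
}


def _fit_family_mixed(family: str, y: np.ndarray, X: pd.DataFrame, groups: np.ndarray,
                      n_nodes: int = 25):
    """Random-intercept fit by Gauss-Hermite marginal likelihood.

    Parameters are (β, family dispersion on the log scale, log σ_u); group
    intercepts are integrated over N(0, σ_u²) with ``n_nodes`` Hermite
    nodes. Same return shape as :func:`_fit_family`.
    """
    y = np.asarray(y, dtype=float)
    Xv = X.to_numpy(dtype=float)
    names = list(X.columns)
    codes, _ = pd.factorize(pd.Series(groups))
    n_groups = int(codes.max()) + 1
    nodes, weights = roots_hermite(n_nodes)
    logw = np.log(weights) - 0.5 * np.log(np.pi)
    n_extra = _N_EXTRA[family]
    if family == "beta_logit":
        n = len(y)
        y = np.clip((y * (n - 1) + 0.5) / n, 1e-12, 1 - 1e-12)

    def negll(theta):
        beta = theta[: Xv.shape[1]]
        extra = theta[Xv.shape[1] : Xv.shape[1] + n_extra]
        sigma_u = np.exp(theta[-1])
        etas = (Xv @ beta)[:, None] + np.sqrt(2.0) * sigma_u * nodes[None, :]
        with np.errstate(all="ignore"):
            ll_obs = _obs_loglik(family, y[:, None], etas, extra)
        if not np.all(np.isfinite(ll_obs)):
            return 1e12
        grp_ll = np.zeros((n_groups, len(nodes)))
        np.add.at(grp_ll, codes, ll_obs)
        grp_ll += logw[None, :]
        m = grp_ll.max(axis=1, keepdims=True)
        return -float(np.sum(m[:, 0] + np.log(np.exp(grp_ll - m).sum(axis=1))))

    fe = _fit_family(family, y, X)
    beta0 = fe[0].to_numpy()[: Xv.shape[1]]
    extra0 = []
    if n_extra:
        if family in ("trunc_nb_linear", "trunc_nb_quadratic", "nb_linear", "nb_quadratic"):
            extra0 = [float(np.log(max(fe[0].iloc[-1], 1e-3)))]
        else:
            extra0 = [0.0]
    theta0 = np.concatenate([beta0, extra0, [np.log(0.3)]])
    res = minimize(negll, theta0, method="BFGS", options={"maxiter": 500, "gtol": 1e-6})
    hess_inv = np.asarray(
        res.hess_inv if isinstance(res.hess_inv, np.ndarray) else res.hess_inv.todense()
    )
    se = np.sqrt(np.clip(np.diag(hess_inv), 0, None))
    full_names = names + (["dispersion_log"] * n_extra) + ["log_sigma_u"]
    params = pd.Series(res.x, index=full_names)
    bse = pd.Series(se, index=full_names)
    ci = pd.DataFrame({"lo": res.x - 1.96 * se, "hi": res.x + 1.96 * se}, index=full_names)
    cov = pd.DataFrame(hess_inv, index=full_names, columns=full_names)
    llf = -float(res.fun)
    aic = 2 * len(res.x) - 2 * llf
    return params, bse, ci, llf, aic, None, None, cov


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _covariate_column(data: pd.DataFrame, name: str) -> np.ndarray:
    col = data[name].to_numpy(dtype=float)
    if name == "read_count":
        col = np.log(col)  # sequencing effort acts multiplicatively
    return standardize(col)


def _build_design(data: pd.DataFrame, spec: ModelSpec, temporal: bool):
    """Design matrix, term→columns map, and the smooth basis (or None).

    Raises ValueError (reported as a fit failure upstream) on constant or
    collinear columns.
    """
    n = len(data)
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(n)}
    terms: dict[str, list[str]] = {}
    smoother = None

    z = standardize(data[spec.predictor].to_numpy(dtype=float))
    use_smooth = (
        spec.smooth_predictor
        and spec.admissible_families()[0] in ("beta_logit", "gaussian_log_response")
        and not spec.interaction_with_lag
    )
    if use_smooth:
        smoother = BSplines(z, df=[spec.smooth_df], degree=[3], include_intercept=False)
        basis = smoother.basis
        names = [f"s({spec.predictor}).{i}" for i in range(basis.shape[1])]
        for nm, col in zip(names, basis.T):
            cols[nm] = col
        terms[spec.predictor] = names
    else:
        cols[spec.predictor] = z
        terms[spec.predictor] = [spec.predictor]

    if temporal:
        lag_raw = data["delta_days"].to_numpy(dtype=float)
        if (lag_raw <= 0).any():
            raise ValueError("delta_days must be positive for temporal fits")
        try:
            lag = standardize(np.log(lag_raw))
        except ValueError:
            raise ValueError(
                "time-lag term inestimable: a single common delta_days value "
                "makes the lag and interaction columns collinear with the intercept"
            )
        cols["log_lag"] = lag
        terms["log_lag"] = ["log_lag"]
        if spec.interaction_with_lag:
            nm = f"{spec.predictor}:log_lag"
            cols[nm] = z * lag
            terms[nm] = [nm]

    for cov_name in spec.covariates:
        cols[cov_name] = _covariate_column(data, cov_name)
        terms[cov_name] = [cov_name]

    X = pd.DataFrame(cols, index=data.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]} columns): "
            "collinear predictors"
        )
    return X, terms, smoother, z


def _mean_smooth_slope(z, smoother, basis_names, params, cov):
    """Mean derivative of the fitted smooth over the data (delta-method CI):
    the scalar 'slope' summary reported for smooth diversity terms."""
    h = 1e-4
    lo, hi = z.min(), z.max()
    zc = np.clip(z, lo + h, hi - h)
    b0 = smoother.transform(zc - h)
    b1 = smoother.transform(zc + h)
    grad = ((b1 - b0) / (2 * h)).mean(axis=0)
    beta = params[basis_names].to_numpy()
    slope = float(grad @ beta)
    sub = cov.loc[basis_names, basis_names].to_numpy()
    se = float(np.sqrt(np.clip(grad @ sub @ grad, 0, None)))
    return slope, (slope - 1.96 * se, slope + 1.96 * se)


# ---------------------------------------------------------------------------
# public fitting API
# ---------------------------------------------------------------------------

def _fit(data: pd.DataFrame, spec: ModelSpec, temporal: bool) -> SlopeFit:
    if len(spec.random_effects) > 1:
        return SlopeFit(
            spec=spec,
            failure_reason=(
                "at most one random-intercept grouping factor is supported; "
                f"got {spec.random_effects}"
            ),
        )
    try:
        X, terms, smoother, z = _build_design(data, spec, temporal)
    except (ValueError, KeyError) as e:
        return SlopeFit(spec=spec, failure_reason=str(e))
    y = data[spec.response].to_numpy(dtype=float)
    if spec.response == "polymorphism_change":
        y = signed_log(y)
    if spec.response == "strain_count" and (y < 1).any():
        return SlopeFit(spec=spec, failure_reason="strain counts must be >= 1 (zero-truncated)")

    groups = data[spec.random_effects[0]].to_numpy() if spec.random_effects else None
    candidates, errors = [], []
    for family in spec.admissible_families():
        try:
            out = (
                _fit_family_mixed(family, y, X, groups)
                if groups is not None
                else _fit_family(family, y, X)
            )
            candidates.append((family, out))
        except Exception as e:  # noqa: BLE001 - fit failures become diagnostics
            errors.append(f"{family}: {e}")
    if not candidates:
        return SlopeFit(spec=spec, failure_reason="all families failed: " + "; ".join(errors))
    family, (params, bse, ci, llf, aic, mu, var, cov) = min(candidates, key=lambda c: c[1][4])

    diagnostics = {"family_aic": {f: o[4] for f, o in candidates}, "errors": errors}
    if mu is not None and var is not None:
        resid_df = len(y) - len(params)
        pearson = float(np.sum((y - mu) ** 2 / np.clip(var, 1e-12, None)))
        diagnostics["overdispersion"] = pearson / max(resid_df, 1)

    fit = SlopeFit(
        spec=spec, family=family, success=True,
        params=params, bse=bse, conf_int=ci, logL=llf, aic=aic, n_obs=len(y),
        term_columns=terms, diagnostics=diagnostics,
        _X=X, _y=y, _groups=groups, _smoother=smoother, _cov=cov,
    )
    if groups is not None:
        fit.random_effect_sd = float(np.exp(params["log_sigma_u"]))

    pred_cols = terms[spec.predictor]
    if len(pred_cols) == 1:
        fit.slope = float(params[pred_cols[0]])
        fit.slope_ci = (float(ci.loc[pred_cols[0], "lo"]), float(ci.loc[pred_cols[0], "hi"]))
    else:
        fit.slope, fit.slope_ci = _mean_smooth_slope(z, smoother, pred_cols, params, cov)
    return fit


def fit_cross_sectional(data: pd.DataFrame, spec: ModelSpec, seed: int = 0) -> SlopeFit:
    """Fit the cross-sectional diversity-slope model for ``spec``.

    Count responses are fitted under every admissible family and the AIC
    winner returned. The fit is deterministic given the data (``seed`` is
    accepted for interface symmetry; the optimizers are deterministic).
    Failures (collinearity, non-convergence) come back as a SlopeFit with
    ``success=False`` and a named reason, never a silent fallback.
    """
    return _fit(data, spec, temporal=False)


def fit_temporal(data: pd.DataFrame, spec: ModelSpec, seed: int = 0) -> SlopeFit:
    """Fit the temporal model: response vs diversity at the earlier time
    point, the (log) time lag, and — when ``interaction_with_lag`` is set —
    their interaction. Requires a positive ``delta_days`` column."""
    return _fit(data, spec, temporal=True)


def _refit_without(fit: SlopeFit, drop_cols: list[str]) -> SlopeFit:
    keep = [c for c in fit._X.columns if c not in drop_cols]
    X2 = fit._X[keep]
    try:
        out = (
            _fit_family_mixed(fit.family, fit._y, X2, fit._groups)
            if fit._groups is not None
            else _fit_family(fit.family, fit._y, X2)
        )
    except Exception as e:  # noqa: BLE001
        return SlopeFit(spec=fit.spec, failure_reason=f"reduced fit failed: {e}")
    params, bse, ci, llf, aic, mu, var, cov = out
    return SlopeFit(
        spec=fit.spec, family=fit.family, success=True, params=params, bse=bse,
        conf_int=ci, logL=llf, aic=aic, n_obs=fit.n_obs,
        _X=X2, _y=fit._y, _groups=fit._groups,
    )


def drop_one_lrt(fit_full: SlopeFit, term: str) -> LRTResult:
    """Likelihood-ratio test for one model term.

    Refits without the term's design columns (family held fixed) and refers
    twice the log-likelihood difference to chi-square with one degree of
    freedom per dropped column. Dropping a smooth term drops its whole
    basis. An empty drop (identical models) gives statistic 0, p = 1.
    """
    if not fit_full.success:
        raise ValueError("cannot run an LRT on a failed fit")
    if term not in fit_full.term_columns:
        raise KeyError(f"term '{term}' not in the model ({list(fit_full.term_columns)})")
    drop_cols = [c for c in fit_full.term_columns[term] if c in fit_full._X.columns]
    if not drop_cols:
        return LRTResult(term=term, statistic=0.0, df=0, p_value=1.0)
    reduced = _refit_without(fit_full, drop_cols)
    if not reduced.success:
        return LRTResult(term=term, statistic=np.nan, df=len(drop_cols), p_value=np.nan)
    stat = max(2.0 * (fit_full.logL - reduced.logL), 0.0)
    df = len(drop_cols)
    return LRTResult(term=term, statistic=stat, df=df, p_value=float(stats.chi2.sf(stat, df)))


def null_model_comparison(fit_full: SlopeFit) -> dict:
    """Compare the full model to intercept(+random effects)-only.

    Returns ΔAIC = AIC_null − AIC_full and the associated LRT; identical
    models give ΔAIC 0.
    """
    if not fit_full.success:
        raise ValueError("cannot compare a failed fit")
    drop_cols = [c for c in fit_full._X.columns if c != "Intercept"]
    if not drop_cols:
        return {"delta_aic": 0.0, "lrt": LRTResult("all fixed effects", 0.0, 0, 1.0)}
    null = _refit_without(fit_full, drop_cols)
    if not null.success:
        return {"delta_aic": np.nan, "lrt": None, "failure": null.failure_reason}
    stat = max(2.0 * (fit_full.logL - null.logL), 0.0)
    df = len(drop_cols)
    return {
        "delta_aic": float(null.aic - fit_full.aic),
        "lrt": LRTResult(term="all fixed effects", statistic=stat, df=df,
                         p_value=float(stats.chi2.sf(stat, df))),
    }
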