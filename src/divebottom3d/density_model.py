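"""Count models of prey-encounter density versus trajectory shape.

The response is the bottom-phase PEE count per dive, modelled with a log
link and the log prospected volume as an offset, so the linear predictor
describes the PEE *density* while the likelihood stays a proper count
distribution.  The model ladder follows standard practice for
overdispersed, zero-heavy ecological counts:

1. Poisson GLM -- the baseline; its Pearson dispersion ``theta =
   sigma^2/mu`` diagnoses overdispersion;
2. negative binomial (NB2) -- allows variance ``mu + mu^2/theta``;
3. zero-inflated Poisson / negative binomial -- a logistic mixture
   component generates structural zeros in excess of the count
   distribution's own zeros.  Note the zero part models the probability
   of an *excess zero* (absence of encounters), not of presence.

Covariates are standardized (mean 0, SD 1) before fitting, so effects
read as "per SD" changes; quadratic terms are centered before squaring.
Model selection enumerates all covariate combinations, ranks by AIC and
returns the best-AIC fit in which every explanatory variable is
significant at the 5% level.  Non-nested families are compared with
Vuong's closeness test.  Fitting is delegated to ``statsmodels``; the
selection, dispersion and Vuong machinery lives here.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.discrete.count_model import (
    ZeroInflatedNegativeBinomialP,
    ZeroInflatedPoisson,
)
from statsmodels.discrete.discrete_model import NegativeBinomial, Poisson

__all__ = [
    "ModelSpec",
    "ModelFit",
    "standardize",
    "fit_count_model",
    "overdispersion",
    "select_model",
    "vuong_compare",
    "simulate_zinb",
]

FAMILIES = ("poisson", "negbin", "zip", "zinb")

COUNT_COVARIATE_MENU = (
    "mean_depth",
    "total_dispersion",
    "mc1_dispersion",
    "mc1_vertical_extent",
    "vertical_width",
    "horizontal_width",
    "speed_sd",
)
ZERO_COVARIATE_MENU = ("mean_depth", "speed_sd", "log_bottom_duration")


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: family plus covariate subsets per part."""

    family: str = "zinb"
    count_covariates: tuple = COUNT_COVARIATE_MENU
    zero_covariates: tuple = ZERO_COVARIATE_MENU
    count_quadratics: tuple = ()  # centered-then-squared terms, count part
    zero_quadratics: tuple = ()

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")


@dataclass
class ModelFit:
    """A fitted count model with the quantities used downstream."""

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    aic: float
    llf: float
    loglikeobs: np.ndarray
    theta: float  # NB shape (inf for Poisson families)
    pearson_dispersion: float
    converged: bool
    predicted_mean: np.ndarray
    observed: np.ndarray
    offset: np.ndarray
    pseudo_r2: float
    deviance_explained: float
    all_significant: bool = False
    flagged: str | None = None
    n_params: int = 0


def standardize(x: np.ndarray) -> np.ndarray:
    """Center and scale to unit SD (population SD of the sample)."""
    x = np.asarray(x, float)
    sd = x.std()
    if sd == 0:
        return x - x.mean()
    return (x - x.mean()) / sd


def _design(
    table: pd.DataFrame, covariates, quadratics, prefix: str
) -> tuple[np.ndarray, list[str]]:
    cols, names = [np.ones(len(table))], [f"{prefix}const"]
    for c in covariates:
        cols.append(standardize(table[c].to_numpy()))
        names.append(f"{prefix}{c}")
    for c in quadratics:
        centered = standardize(table[c].to_numpy())
        cols.append(standardize(centered**2))
        names.append(f"{prefix}{c}^2")
    return np.column_stack(cols), names


def _screen_collinearity(table: pd.DataFrame, covariates, r_max: float = 0.9) -> None:
    cov = [c for c in covariates if c in table.columns]
    if len(cov) < 2:
        return
    corr = np.corrcoef(np.column_stack([table[c] for c in cov]), rowvar=False)
    iu = np.triu_indices_from(corr, k=1)
    worst = np.nanmax(np.abs(corr[iu]))
    if worst > r_max:
        i, j = max(zip(*iu), key=lambda ij: abs(corr[ij]))
        raise ValueError(
            f"covariates {cov[i]!r} and {cov[j]!r} are collinear (|r|="
            f"{abs(corr[i, j]):.3f} > {r_max}); drop one before fitting"
        )


def fit_count_model(
    table: pd.DataFrame,
    spec: ModelSpec,
    offset_col: str = "volume",
    response_col: str = "pee_count",
    min_rows: int = 20,
    screen: bool = True,
) -> ModelFit:
    """Maximum-likelihood fit of one candidate count model.

    ``table`` holds one row per dive with the response, the prospected
    volume (whose log enters as offset) and the raw covariates; these are
    standardized internally.
    """
    cols = set(spec.count_covariates) | set(spec.zero_covariates) | set(
        spec.count_quadratics
    ) | set(spec.zero_quadratics) | {offset_col, response_col}
    data = table.dropna(subset=[c for c in cols if c in table.columns])
    if len(data) < min_rows:
        raise ValueError(f"only {len(data)} complete rows (need {min_rows})")
    if screen:
        _screen_collinearity(data, tuple(dict.fromkeys(
            tuple(spec.count_covariates) + tuple(spec.zero_covariates)
        )))
    y = data[response_col].to_numpy()
    offset = np.log(data[offset_col].to_numpy())
    exog, names = _design(data, spec.count_covariates, spec.count_quadratics, "")
    exog_infl, infl_names = _design(
        data, spec.zero_covariates, spec.zero_quadratics, "zero_"
    )
    if not np.any(y):
        # an all-zero response has no finite MLE under a log link
        warnings.warn("all-zero response: degenerate fit, dispersion undefined")
        k = len(names) + (len(infl_names) if spec.family in ("zip", "zinb") else 0)
        nan_series = pd.Series(np.full(k, np.nan), index=(
            (infl_names + names) if spec.family in ("zip", "zinb") else names
        ))
        return ModelFit(
            spec=spec, params=nan_series, bse=nan_series.copy(),
            pvalues=nan_series.copy(),
            conf_int=pd.DataFrame(
                np.full((k, 2), np.nan), index=nan_series.index, columns=["lo", "hi"]
            ),
            aic=np.nan, llf=np.nan, loglikeobs=np.full(len(y), np.nan),
            theta=np.nan, pearson_dispersion=np.nan, converged=False,
            predicted_mean=np.zeros(len(y)), observed=y, offset=offset,
            pseudo_r2=np.nan, deviance_explained=np.nan,
            all_significant=False, flagged="degenerate all-zero response",
            n_params=k,
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if spec.family == "poisson":
            model = Poisson(y, exog, offset=offset)
            res = model.fit(disp=0, maxiter=200)
        elif spec.family == "negbin":
            model = NegativeBinomial(y, exog, offset=offset, loglike_method="nb2")
            res = model.fit(disp=0, maxiter=500)
        elif spec.family == "zip":
            model = ZeroInflatedPoisson(
                y, exog, exog_infl=exog_infl, offset=offset, inflation="logit"
            )
            count_start = Poisson(y, exog, offset=offset).fit(disp=0).params
            p0 = float(np.clip(np.mean(y == 0) / 2, 0.02, 0.9))
            start = np.r_[np.log(p0 / (1 - p0)),
                          np.zeros(exog_infl.shape[1] - 1), count_start]
            res = model.fit(disp=0, maxiter=1000, method="lbfgs", start_params=start)
        else:
            model = ZeroInflatedNegativeBinomialP(
                y, exog, exog_infl=exog_infl, offset=offset, inflation="logit", p=2
            )
            nb = NegativeBinomial(
                y, exog, offset=offset, loglike_method="nb2"
            ).fit(disp=0, maxiter=500)
            p0 = float(np.clip(np.mean(y == 0) / 2, 0.02, 0.9))
            start = np.r_[np.log(p0 / (1 - p0)),
                          np.zeros(exog_infl.shape[1] - 1), nb.params]
            res = model.fit(disp=0, maxiter=1000, method="lbfgs", start_params=start)
            if not res.mle_retvals.get("converged", True):
                res = model.fit(disp=0, maxiter=1000, method="bfgs",
                                start_params=start)

    converged = True
    if hasattr(res, "mle_retvals") and isinstance(res.mle_retvals, dict):
        converged = bool(res.mle_retvals.get("converged", True))

    all_names = list(res.params.index) if isinstance(res.params, pd.Series) else None
    if all_names is None:
        # statsmodels names zero-inflated params inflate_x0... / x1...
        all_names = _statsmodels_param_names(spec, names, infl_names, res)
    params = pd.Series(np.asarray(res.params), index=all_names)
    bse = pd.Series(np.asarray(res.bse), index=all_names)
    pvalues = pd.Series(np.asarray(res.pvalues), index=all_names)
    ci = pd.DataFrame(np.asarray(res.conf_int()), index=all_names, columns=["lo", "hi"])

    with np.errstate(over="ignore", invalid="ignore"):
        mu = np.asarray(res.predict())  # mean response (mixture mean for ZI)
        pearson = float(
            np.sum((y - mu) ** 2 / np.maximum(mu, 1e-12))
            / max(len(y) - exog.shape[1], 1)
        )
    if not np.all(np.isfinite(mu)):
        converged = False
    if spec.family in ("negbin", "zinb"):
        alpha = float(params.get("alpha", np.nan))
        theta = 1.0 / alpha if alpha and alpha > 0 else np.inf
    else:
        theta = np.inf

    density_obs = 1e6 * y / np.exp(offset)
    density_hat = 1e6 * mu / np.exp(offset)
    if np.std(density_obs) > 0 and np.std(density_hat) > 0:
        pseudo_r2 = float(np.corrcoef(density_obs, density_hat)[0, 1] ** 2)
    else:
        pseudo_r2 = np.nan
    llf = float(res.llf)
    ll_null = _null_loglik(spec.family, y, offset, exog_infl)
    deviance_explained = float(1.0 - llf / ll_null) if ll_null != 0 else np.nan

    slope_names = [n for n in all_names if n not in ("const", "zero_const", "alpha")]
    all_sig = bool(all(pvalues[n] < 0.05 for n in slope_names)) if slope_names else True

    return ModelFit(
        spec=spec,
        params=params,
        bse=bse,
        pvalues=pvalues,
        conf_int=ci,
        aic=float(res.aic),
        llf=llf,
        loglikeobs=np.asarray(res.model.loglikeobs(res.params)),
        theta=theta,
        pearson_dispersion=pearson,
        converged=converged,
        predicted_mean=mu,
        observed=y,
        offset=offset,
        pseudo_r2=pseudo_r2,
        deviance_explained=deviance_explained,
        all_significant=all_sig,
        flagged=None if converged else "non-convergence",
        n_params=len(params),
    )


def _statsmodels_param_names(spec, names, infl_names, res):  # pragma: no cover
    k = len(np.asarray(res.params))
    if spec.family in ("zip", "zinb"):
        base = infl_names + names
    else:
        base = names
    if k == len(base) + 1:
        base = base + ["alpha"]
    return base[:k]


def _null_loglik(family, y, offset, exog_infl) -> float:
    """Log-likelihood of the same-family intercept-only model (with offset)."""
    ones = np.ones((len(y), 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if family == "poisson":
            res = Poisson(y, ones, offset=offset).fit(disp=0)
        elif family == "negbin":
            res = NegativeBinomial(y, ones, offset=offset, loglike_method="nb2").fit(disp=0)
        elif family == "zip":
            res = ZeroInflatedPoisson(y, ones, exog_infl=ones, offset=offset).fit(disp=0)
        else:
            res = ZeroInflatedNegativeBinomialP(
                y, ones, exog_infl=ones, offset=offset, p=2
            ).fit(disp=0)
    return float(res.llf)


def overdispersion(fit: ModelFit) -> float:
    """Pearson dispersion ``theta = sigma^2/mu`` of a Poisson fit.

    Values well above 1 indicate overdispersion and motivate the switch
    to the negative binomial family.  Undefined (NaN, flagged) for an
    all-zero response.
    """
    if not np.any(fit.observed) or not np.isfinite(fit.pearson_dispersion):
        warnings.warn("all-zero or degenerate response: dispersion undefined")
        return np.nan
    return fit.pearson_dispersion


def select_model(
    table: pd.DataFrame,
    family: str = "zinb",
    count_menu=COUNT_COVARIATE_MENU,
    zero_menu=ZERO_COVARIATE_MENU,
    count_quadratics=(),
    zero_quadratics=(),
    offset_col: str = "volume",
    response_col: str = "pee_count",
    max_candidates: int = 2**15,
) -> tuple[ModelFit, pd.DataFrame]:
    """Exhaustive AIC selection over covariate subsets.

    Every combination of count-part covariates (times zero-part subsets
    for zero-inflated families) is fitted and ranked by AIC; the winner is
    the lowest-AIC candidate whose every explanatory variable is
    significant at the 5% level.  If no candidate passes the filter, the
    overall lowest-AIC fit is returned flagged ``non-conforming``.

    Returns the selected fit and a selection ledger (one row per
    candidate: spec, AIC, significance flag).
    """
    count_sets = [
        tuple(c)
        for k in range(len(count_menu) + 1)
        for c in itertools.combinations(count_menu, k)
    ]
    if family in ("zip", "zinb"):
        zero_sets = [
            tuple(c)
            for k in range(len(zero_menu) + 1)
            for c in itertools.combinations(zero_menu, k)
        ]
    else:
        zero_sets = [()]
    candidates = [
        ModelSpec(
            family=family,
            count_covariates=cc,
            zero_covariates=zc,
            count_quadratics=tuple(q for q in count_quadratics if q in cc),
            zero_quadratics=tuple(q for q in zero_quadratics if q in zc),
        )
        for cc in count_sets
        for zc in zero_sets
    ]
    if len(candidates) > max_candidates:
        raise ValueError(f"{len(candidates)} candidates exceed cap {max_candidates}")
    rows, fits = [], []
    for spec in candidates:
        try:
            fit = fit_count_model(
                table, spec, offset_col=offset_col, response_col=response_col,
                screen=False,
            )
        except Exception as exc:  # noqa: BLE001 -- a failed candidate is skipped
            rows.append({"spec": spec, "aic": np.nan, "all_significant": False,
                         "converged": False, "error": str(exc)})
            continue
        if not fit.converged:
            rows.append({"spec": spec, "aic": fit.aic, "all_significant": False,
                         "converged": False, "error": "non-convergence"})
            continue
        fits.append(fit)
        rows.append({"spec": spec, "aic": fit.aic, "all_significant": fit.all_significant,
                     "converged": True, "error": None})
    ledger = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    if not fits:
        raise RuntimeError("no candidate model converged")
    fits.sort(key=lambda f: f.aic)
    for fit in fits:
        if fit.all_significant:
            return fit, ledger
    best = fits[0]
    best.flagged = "non-conforming (no candidate with all terms significant)"
    return best, ledger


def vuong_compare(fit_a: ModelFit, fit_b: ModelFit) -> tuple[float, float]:
    """Vuong closeness test for non-nested fits on the same response.

    ``z = sqrt(n) * mean(m_i) / sd(m_i)`` with ``m_i`` the pointwise
    log-likelihood ratios; positive z favours ``fit_a``.  Returns
    ``(z, two_sided_p)``; identical likelihood vectors give (0, 1).
    """
    m = fit_a.loglikeobs - fit_b.loglikeobs
    n = len(m)
    if len(fit_b.loglikeobs) != n:
        raise ValueError("fits must share the same response vector")
    sd = m.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return 0.0, 1.0
    z = float(np.sqrt(n) * m.mean() / sd)
    p = float(2 * stats.norm.sf(abs(z)))
    return z, p


def simulate_zinb(
    n: int,
    beta: np.ndarray,
    gamma: np.ndarray,
    theta: float,
    rng: np.random.Generator,
    offset: np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw a ZINB dataset with known coefficients (for recovery tests).

    ``beta`` are count-part coefficients (intercept first) on standard
    normal covariates; ``gamma`` the zero-part logistic coefficients.
    The NB2 shape is ``theta`` (variance ``mu + mu^2/theta``); ``offset``
    defaults to log-volumes spread over an order of magnitude.
    """
    k = len(beta) - 1
    kz = len(gamma) - 1
    x = rng.standard_normal((n, max(k, kz)))
    if offset is None:
        offset = np.log(rng.uniform(2e3, 2e4, n))
    eta = beta[0] + x[:, :k] @ beta[1:] + offset
    mu = np.exp(eta)
    pi = 1.0 / (1.0 + np.exp(-(gamma[0] + x[:, :kz] @ gamma[1:])))
    lam = rng.gamma(shape=theta, scale=mu / theta)
    y = rng.poisson(lam)
    y[rng.random(n) < pi] = 0
    out = {"pee_count": y, "volume": np.exp(offset)}
    for j in range(max(k, kz)):
        out[f"x{j + 1}"] = x[:, j]
    return pd.DataFrame(out)
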