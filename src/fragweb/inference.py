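"""All-subsets AICc model selection with conditional model averaging.

The protocol, applied per response (three Gaussian food-web indices and one
binomial richness ratio):

1. standardise every continuous explanatory variable to [0, 1];
2. enumerate every model nested in the global model (including the null),
   respecting marginality (an interaction only ever appears with both of its
   main effects);
3. rank models by AICc = AIC + 2k(k+1)/(n - k - 1);
4. keep the candidate set with delta AICc < 6 from the best model and give
   each member an Akaike weight w_i proportional to exp(-delta_i / 2);
5. average each coefficient over only those candidate models that contain
   it (conditional averaging, avoiding shrinkage towards zero), with the
   unconditional standard error
       SE_avg = sum_m w~_m * sqrt(se_m^2 + (beta_m - beta_avg)^2)
   combining within-model variance and between-model spread;
6. report each term's importance as the count of candidate models that
   contain it.

Terms are named L (% arable land), S (fragment size class, small=0/large=1),
C (log10 connectivity), their two-way interactions ``L:C``, ``S:C``, ``L:S``,
and R (the plant + leafhopper richness of the web, a free control covariate).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import RankDeficiencyError, StatisticalError

logger = logging.getLogger(__name__)

#: canonical term order used for enumeration tie-breaks and output tables
TERM_ORDER = ["R", "L", "S", "C", "L:C", "S:C", "L:S"]

DEFAULT_GLOBAL = tuple(TERM_ORDER)


def standardize01(x) -> np.ndarray:
    """Rescale a numeric vector linearly onto [0, 1]."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi <= lo:
        raise StatisticalError("cannot standardize a constant vector to [0, 1]")
    return (x - lo) / (hi - lo)


def term_parents(term: str) -> tuple[str, ...]:
    return tuple(term.split(":"))


def respects_marginality(terms) -> bool:
    terms = set(terms)
    return all(
        set(term_parents(t)) <= terms for t in terms if ":" in t
    )


def _sorted_terms(terms) -> list[str]:
    order = {t: i for i, t in enumerate(TERM_ORDER)}
    return sorted(terms, key=lambda t: (order.get(t, len(order)), t))


def enumerate_submodels(global_terms=DEFAULT_GLOBAL) -> list[frozenset]:
    """Every term subset of the global model respecting marginality.

    Includes the null (empty) model.  Deterministic order: by model size,
    then by canonical term order.
    """
    global_terms = list(global_terms)
    if not respects_marginality(global_terms):
        raise StatisticalError(f"global model violates marginality: {global_terms}")
    models = []
    for mask in range(1 << len(global_terms)):
        subset = frozenset(
            t for i, t in enumerate(global_terms) if mask >> i & 1
        )
        if respects_marginality(subset):
            models.append(subset)
    models.sort(key=lambda m: (len(m), [TERM_ORDER.index(t) for t in _sorted_terms(m)]))
    return models


def build_design(data: pd.DataFrame, terms) -> pd.DataFrame:
    """Design matrix (without intercept) for a term set.

    ``data`` must hold the main-effect columns (L, S, C, R as applicable);
    interaction columns are their products.
    """
    cols = {}
    for t in _sorted_terms(terms):
        parents = term_parents(t)
        col = np.ones(len(data))
        for p in parents:
            col = col * data[p].to_numpy(dtype=float)
        cols[t] = col
    return pd.DataFrame(cols, index=data.index)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    """Raise naming the aliased columns if [1 | X] is rank deficient."""
    full = np.column_stack([np.ones(len(X)), X])
    if np.linalg.matrix_rank(full) == full.shape[1]:
        return
    aliased = []
    kept = [np.ones(len(X))]
    for j, name in enumerate(names):
        trial = np.column_stack(kept + [X[:, j]])
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            kept.append(X[:, j])
        else:
            aliased.append(name)
    raise RankDeficiencyError(aliased)


@dataclass
class ModelFit:
    """One fitted model: coefficients, likelihood and information criterion."""

    terms: frozenset
    family: str  # "gaussian" | "binomial"
    params: pd.Series
    bse: pd.Series
    loglik: float
    k: int
    n: int
    aicc: float
    converged: bool = True
    r_squared: float = np.nan
    delta: float = np.nan
    weight: float = np.nan

    def sort_key(self):
        # AICc ties break by fewer terms, then canonical term order
        return (self.aicc, len(self.terms), [TERM_ORDER.index(t) for t in _sorted_terms(self.terms)])


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC; requires n - k - 1 > 0."""
    if n - k - 1 <= 0:
        raise StatisticalError(f"AICc undefined for n={n}, k={k} (n - k - 1 <= 0)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def fit_lm(y, X: pd.DataFrame, terms=None) -> ModelFit:
    """Ordinary least squares with Gaussian ML log-likelihood.

    ``k`` counts the intercept, the slopes and the residual-variance
    parameter, so AICc values are comparable across implementations.
    """
    y = np.asarray(y, dtype=float)
    names = list(X.columns)
    n = len(y)
    if n <= len(names) + 1:
        raise StatisticalError(f"too few observations (n={n}) for {len(names)} predictors")
    _check_rank(X.to_numpy(dtype=float), names)
    exog = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
    res = sm.OLS(y, exog).fit()
    index = ["Intercept"] + names
    k = len(index) + 1  # + residual variance
    return ModelFit(
        terms=frozenset(terms if terms is not None else names),
        family="gaussian",
        params=pd.Series(res.params, index=index),
        bse=pd.Series(res.bse, index=index),
        loglik=float(res.llf),
        k=k,
        n=n,
        aicc=aicc(float(res.llf), k, n),
        r_squared=float(res.rsquared) if names else 0.0,
    )


def fit_binom(successes, trials, X: pd.DataFrame, terms=None) -> ModelFit:
    """Binomial GLM (logit link) fitted by iteratively reweighted least squares.

    Non-converged or separated fits are flagged (``converged=False``) so the
    averaging step can drop them with a warning rather than fail.
    """
    successes = np.asarray(successes, dtype=float)
    trials = np.asarray(trials, dtype=float)
    if np.any(successes < 0) or np.any(successes > trials):
        raise StatisticalError("successes must satisfy 0 <= successes <= trials")
    names = list(X.columns)
    n = len(successes)
    if n <= len(names):
        raise StatisticalError(f"too few observations (n={n}) for {len(names)} predictors")
    _check_rank(X.to_numpy(dtype=float), names)
    exog = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
    endog = np.column_stack([successes, trials - successes])
    model = sm.GLM(endog, exog, family=sm.families.Binomial())
    index = ["Intercept"] + names
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=100, tol=1e-8)
    except Exception:  # IRLS blow-up under complete separation
        warnings.warn("binomial fit flagged: separation or non-convergence suspected")
        nan = pd.Series(np.nan, index=index)
        return ModelFit(
            terms=frozenset(terms if terms is not None else names),
            family="binomial", params=nan, bse=nan, loglik=-np.inf,
            k=len(index), n=n, aicc=np.inf, converged=False,
        )
    params = pd.Series(res.params, index=index)
    bse = pd.Series(res.bse, index=index)
    converged = bool(res.converged)
    if np.any(np.abs(params) > 15) or np.any(bse > 50) or not np.all(np.isfinite(bse)):
        converged = False  # quasi-complete separation
        warnings.warn("binomial fit flagged: separation or non-convergence suspected")
    k = len(index)
    fitted = res.fittedvalues
    with np.errstate(invalid="ignore"):
        obs = np.divide(successes, trials, out=np.full(n, np.nan), where=trials > 0)
    ok = np.isfinite(obs)
    r2 = float(np.corrcoef(obs[ok], fitted[ok])[0, 1] ** 2) if ok.sum() > 2 and np.ptp(fitted[ok]) > 0 else np.nan
    return ModelFit(
        terms=frozenset(terms if terms is not None else names),
        family="binomial",
        params=params,
        bse=bse,
        loglik=float(res.llf),
        k=k,
        n=n,
        aicc=aicc(float(res.llf), k, n) if n - k - 1 > 0 else np.nan,
        converged=converged,
        r_squared=r2,
    )


def candidate_set(fits: list[ModelFit], delta_threshold: float = 6.0) -> list[ModelFit]:
    """Models within ``delta_threshold`` AICc of the best, Akaike-reweighted.

    The threshold is strict (delta < 6).  Flagged (non-converged) fits are
    excluded with a warning before ranking.
    """
    usable = [f for f in fits if f.converged]
    dropped = len(fits) - len(usable)
    if dropped:
        warnings.warn(f"excluded {dropped} non-converged fit(s) from the candidate set")
    if not usable:
        raise StatisticalError("no converged model fits to rank")
    best = min(f.aicc for f in usable)
    kept = [f for f in usable if f.aicc - best < delta_threshold]
    raw = np.array([np.exp(-(f.aicc - best) / 2.0) for f in kept])
    weights = raw / raw.sum()
    for f, w in zip(kept, weights):
        f.delta = f.aicc - best
        f.weight = float(w)
    kept.sort(key=ModelFit.sort_key)
    return kept


@dataclass
class AveragedTerm:
    """Conditional model-averaged coefficient for one term."""

    term: str
    importance: int
    estimate: float
    se: float
    ci95: float
    z: float
    p_value: float
    significance: str


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def conditional_average(
    candidates: list[ModelFit], ci_level: float = 0.95
) -> list[AveragedTerm]:
    """Average each term over only the candidate models containing it.

    Weights are renormalised within the containing subset; the SE combines
    within-model variance and between-model coefficient spread.  Terms absent
    from every candidate are omitted.  ``ci95`` holds the half-width of the
    normal interval at ``ci_level``.
    """
    if not candidates:
        raise StatisticalError("conditional averaging needs a non-empty candidate set")
    z_crit = float(stats.norm.ppf(0.5 + ci_level / 2))
    all_terms = _sorted_terms({t for f in candidates for t in f.terms})
    out: list[AveragedTerm] = []
    for term in all_terms:
        containing = [f for f in candidates if term in f.terms]
        w = np.array([f.weight for f in containing])
        w = w / w.sum()
        beta = np.array([f.params[term] for f in containing])
        se_m = np.array([f.bse[term] for f in containing])
        estimate = float(w @ beta)
        se = float(w @ np.sqrt(se_m**2 + (beta - estimate) ** 2))
        if se > 0:
            z = estimate / se
            p = 2.0 * stats.norm.sf(abs(z))
        else:
            z = np.inf if estimate != 0 else 0.0
            p = 0.0 if estimate != 0 else 1.0
        out.append(
            AveragedTerm(
                term=term,
                importance=len(containing),
                estimate=estimate,
                se=se,
                ci95=z_crit * se,
                z=float(z),
                p_value=float(p),
                significance=_stars(p),
            )
        )
    return out


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per predictor: 1 / (1 - R^2_p).

    R^2_p comes from regressing predictor p on the remaining predictors
    (with intercept).  Perfect collinearity reports as infinity.
    """
    names = list(X.columns)
    if len(names) < 2:
        raise StatisticalError("VIF needs at least two predictors")
    M = X.to_numpy(dtype=float)
    values = {}
    for j, name in enumerate(names):
        y = M[:, j]
        others = np.column_stack(
            [np.ones(len(M))] + [M[:, i] for i in range(len(names)) if i != j]
        )
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        tss = float(((y - y.mean()) ** 2).sum())
        if tss == 0:
            raise StatisticalError(f"predictor {name!r} is constant")
        r2 = 1.0 - float((resid**2).sum()) / tss
        values[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(values)


# ---------------------------------------------------------------------------
# high-level protocol
# ---------------------------------------------------------------------------

@dataclass
class InferenceResult:
    response: str
    family: str
    full_model_r2: float
    n_models: int
    candidates: list[ModelFit]
    averaged: list[AveragedTerm]
    max_vif: float

    def table(self) -> pd.DataFrame:
        rows = [
            {
                "response": self.response,
                "r_squared": self.full_model_r2,
                "term": t.term,
                "importance": t.importance,
                "estimate": t.estimate,
                "ci95": t.ci95,
                "significance": t.significance,
            }
            for t in self.averaged
        ]
        return pd.DataFrame(rows)


def prepare_covariates(design: pd.DataFrame, metrics: pd.DataFrame) -> pd.DataFrame:
    """Merge design and metrics tables into the standardized covariate frame.

    Produces columns L (arable, [0,1]), S (size class 0/1), C (standardized
    log10 connectivity), R (standardized web richness), plus the responses.
    """
    df = design.merge(metrics, on="fragment_id", validate="one_to_one")
    out = pd.DataFrame({"fragment_id": df["fragment_id"]})
    out["L"] = standardize01(df["arable_pct"])
    out["S"] = (
        df["size_class"].map(
            lambda v: 1.0 if str(v).strip().casefold() in ("large", "1", "true") else 0.0
        )
    ).to_numpy()
    out["C"] = standardize01(np.log10(df["connectivity"].to_numpy(dtype=float)))
    out["R"] = standardize01(df["richness_covariate"])
    for col in ("H", "G", "V", "LD", "n_specialists", "n_generalists"):
        if col in df:
            out[col] = df[col].to_numpy()
    return out


def multimodel_inference(
    data: pd.DataFrame,
    response: str,
    family: str,
    global_terms=DEFAULT_GLOBAL,
    delta_threshold: float = 6.0,
    ci_level: float = 0.95,
) -> InferenceResult:
    """Run the full protocol for one response.

    ``family`` is ``"gaussian"`` (response = a metrics column) or
    ``"binomial"`` (response fixed to the specialist/generalist richness
    ratio, successes = n_specialists, trials = n_specialists +
    n_generalists).
    """
    specs = enumerate_submodels(global_terms)
    fits: list[ModelFit] = []
    for terms in specs:
        X = build_design(data, terms)
        if family == "gaussian":
            fit = fit_lm(data[response].to_numpy(), X, terms=terms)
        elif family == "binomial":
            s = data["n_specialists"].to_numpy(dtype=float)
            t = s + data["n_generalists"].to_numpy(dtype=float)
            fit = fit_binom(s, t, X, terms=terms)
        else:
            raise StatisticalError(f"unknown family {family!r}")
        fits.append(fit)
    global_fit = next(f for f in fits if f.terms == frozenset(global_terms))
    candidates = candidate_set(fits, delta_threshold)
    averaged = conditional_average(candidates, ci_level=ci_level)
    X_global = build_design(data, global_terms)
    max_vif = float(vif(X_global[[t for t in X_global.columns if ":" not in t]]).max())
    return InferenceResult(
        response=response,
        family=family,
        full_model_r2=float(global_fit.r_squared),
        n_models=len(fits),
        candidates=candidates,
        averaged=averaged,
        max_vif=max_vif,
    )


RESPONSES = [
    ("specialist_generalist", "binomial"),
    ("LD", "gaussian"),
    ("G", "gaussian"),
    ("H", "gaussian"),
]


def model_table(
    design: pd.DataFrame,
    metrics: pd.DataFrame,
    delta_threshold: float = 6.0,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Model-averaging summary for all four responses, one tidy table.

    Mirrors the published layout: response, full-model R^2 (squared
    observed-fitted correlation for the binomial response), term importance
    within the delta < 6 candidate set, conditional-average estimate with
    95% CI half-width, and significance stars.
    """
    data = prepare_covariates(design, metrics)
    frames = []
    for response, family in RESPONSES:
        result = multimodel_inference(
            data, response if family == "gaussian" else "specialist_generalist",
            family, delta_threshold=delta_threshold, ci_level=ci_level,
        )
        frames.append(result.table())
    return pd.concat(frames, ignore_index=True)
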