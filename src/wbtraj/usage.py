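"""Binomial GLMs linking intervention usage to sustained benefit.

Machinery for the model-selection table and the optimal-model table:
within-group z-standardisation of frequency-of-use, fixed-effects
logistic models predicting lasting benefit (1) over hedonic adaptation
(0) at the observation level, likelihood-ratio and AIC comparisons,
pseudo-R2 indices, hierarchy-respecting backward elimination, and
predicted probabilities.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import Cohort, ConfigError

__all__ = [
    "DEFAULT_TERMS",
    "TABLE_TIME_VALUES",
    "StandardizedUsage",
    "GlmFit",
    "ModelComparison",
    "PseudoR2",
    "SelectionResult",
    "standardize_usage",
    "build_usage_data",
    "fit_binomial_glm",
    "aic",
    "lrt",
    "pseudo_r2",
    "backward_select",
    "predicted_prob",
    "simulate_usage_glm",
]

logger = logging.getLogger(__name__)

#: maximal model: three-way interaction of frequency, adherence and time
DEFAULT_TERMS = (
    "freq",
    "adh",
    "time",
    "freq:adh",
    "freq:time",
    "adh:time",
    "freq:adh:time",
)

#: assessment days (pooled over samples) on which usage was recorded
TABLE_TIME_VALUES = (7, 14, 21, 28, 35, 37, 42, 72, 97, 132)

_BASE_COLUMNS = {"freq": "freq_z", "adh": "adh", "time": "time_c"}


@dataclass
class StandardizedUsage:
    """Observation-level usage predictors: freq z-scored within
    n_assigned group, binary adherence, grand-mean-centered time."""

    data: pd.DataFrame  # participant_id, day, n_assigned, freq_z, adh, time_c
    time_mean: float


@dataclass
class GlmFit:
    """A fitted (or reconstructed) binomial GLM.

    ``beta_std`` holds coefficients scaled by each predictor's SD (the
    outcome stays on the logit scale); the intercept's entry is 0.
    """

    terms: tuple[str, ...]
    b: pd.Series
    se: pd.Series
    z: pd.Series
    p: pd.Series
    beta_std: pd.Series
    loglik: float
    k: int
    n: int
    converged: bool = True

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglik

    @classmethod
    def from_loglik(cls, loglik: float, k: int, n: int = 0,
                    terms: Sequence[str] = ()) -> "GlmFit":
        """Reconstruct the comparison-relevant part of a fit from a
        reported log-likelihood and parameter count (e.g. a published
        model-selection table)."""
        empty = pd.Series(dtype=float)
        return cls(terms=tuple(terms), b=empty, se=empty, z=empty, p=empty,
                   beta_std=empty, loglik=float(loglik), k=int(k), n=int(n))


@dataclass
class ModelComparison:
    chi2: float
    delta_df: int
    p: float
    aic_full: float
    aic_reduced: float
    preferred: str  # "full" or "reduced"


@dataclass
class PseudoR2:
    cox_snell: float
    nagelkerke: float
    mcfadden: float


@dataclass
class SelectionResult:
    fits: list[GlmFit]
    comparisons: list[ModelComparison]
    chosen: GlmFit
    removed: list[str] = field(default_factory=list)


def standardize_usage(usage: pd.DataFrame) -> StandardizedUsage:
    """Standardise usage records for modeling.

    freq_sum is z-transformed with the sample SD within each n_assigned
    group (pooled over days); a constant group gets zeros with a
    warning.  time_c is day minus the grand mean day over the records.
    """
    df = usage[usage["n_assigned"] >= 1].copy()
    if not len(df):
        raise ConfigError("no usage records with assigned exercises")
    time_mean = float(df["day"].mean())

    def _z(group: pd.Series) -> pd.Series:
        sd = group.std(ddof=1)
        if not np.isfinite(sd) or sd <= 0:
            logger.warning("constant freq_sum in n_assigned=%s group; z set to 0",
                           group.name)
            return pd.Series(0.0, index=group.index)
        return (group - group.mean()) / sd

    df["freq_z"] = df.groupby("n_assigned")["freq_sum"].transform(_z)
    df["adh"] = df["adhered"].astype(float)
    df["time_c"] = df["day"] - time_mean
    cols = ["participant_id", "day", "n_assigned", "freq_z", "adh", "time_c"]
    return StandardizedUsage(data=df[cols].reset_index(drop=True), time_mean=time_mean)


def build_usage_data(
    cohort: Cohort,
    labels: Mapping[str, str],
    window_only: bool = True,
) -> pd.DataFrame:
    """Assemble the observation-level GLM table: standardized usage rows
    of participants labeled lasting_benefit (outcome 1) or
    hedonic_adaptation (outcome 0)."""
    keep = {p for p, l in labels.items()
            if l in ("lasting_benefit", "hedonic_adaptation")}
    usage = cohort.usage[cohort.usage["participant_id"].isin(keep)]
    if window_only and len(usage):
        hi = usage["sample_id"].map(lambda s: cohort.design_of(s).t_hi)
        usage = usage[usage["day"] <= hi]
    if not len(usage):
        raise ConfigError("no usage rows for lasting-benefit/hedonic-adaptation participants")
    std = standardize_usage(usage)
    data = std.data.copy()
    data["outcome"] = data["participant_id"].map(
        lambda p: 1.0 if labels[p] == "lasting_benefit" else 0.0
    )
    return data


def _design_matrix(data: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    X = pd.DataFrame({"intercept": np.ones(len(data))}, index=data.index)
    for term in terms:
        cols = [_BASE_COLUMNS[f] for f in term.split(":")]
        X[term] = data[cols].prod(axis=1)
    return X


def fit_binomial_glm(
    data: pd.DataFrame,
    terms: Sequence[str] = DEFAULT_TERMS,
    outcome: str = "outcome",
) -> GlmFit:
    """Maximum-likelihood logistic regression via IRLS.

    ``data`` must carry freq_z, adh, time_c and a binary outcome column;
    ``terms`` name main effects and ``:``-joined interactions (the
    intercept is always included).  Perfect separation and rank
    deficiency raise with the culprit named.
    """
    bad = [t for t in terms if any(f not in _BASE_COLUMNS for f in t.split(":"))]
    if bad:
        raise ConfigError(f"unknown term(s) {bad}; factors must be freq, adh, time")
    y = data[outcome].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ConfigError("outcome must be binary 0/1")
    X = _design_matrix(data, terms)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ConfigError(f"design matrix rank deficient for terms {tuple(terms)}")
    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        res = model.fit(maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError and kin
        raise ConfigError(f"logistic fit failed for terms {tuple(terms)}: {exc}") from exc
    mu = res.fittedvalues
    boundary = (mu < 1e-8) | (mu > 1 - 1e-8)
    if boundary.all():
        culprit = (res.params.drop("intercept", errors="ignore").abs()).idxmax()
        raise ConfigError(
            f"perfect separation: fit did not converge to finite estimates "
            f"(largest coefficient on term {culprit!r})"
        )
    if boundary.any():
        logger.warning("some fitted probabilities at the boundary; possible quasi-separation")
    sds = X.std(ddof=1)
    beta_std = res.params * sds
    beta_std["intercept"] = 0.0
    return GlmFit(
        terms=tuple(terms),
        b=res.params,
        se=res.bse,
        z=res.params / res.bse,
        p=pd.Series(2 * stats.norm.sf(np.abs(res.params / res.bse)), index=res.params.index),
        beta_std=beta_std,
        loglik=float(res.llf),
        k=X.shape[1],
        n=len(y),
        converged=bool(res.converged),
    )


def aic(fit: GlmFit) -> float:
    """Akaike information criterion, -2*loglik + 2*k."""
    return -2.0 * fit.loglik + 2.0 * fit.k


def lrt(reduced: GlmFit, full: GlmFit) -> ModelComparison:
    """Likelihood-ratio test of nested fits on the same data."""
    if not set(reduced.terms) < set(full.terms):
        raise ConfigError(
            f"models not nested: {set(reduced.terms)} vs {set(full.terms)}"
        )
    if reduced.n and full.n and reduced.n != full.n:
        raise ConfigError("nested models must be fitted on the same observations")
    delta_df = full.k - reduced.k
    if delta_df < 1:
        raise ConfigError("full model must estimate more parameters than the reduced one")
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = float(stats.chi2.sf(chi2, delta_df)) if chi2 > 0 else 1.0
    a_full, a_red = aic(full), aic(reduced)
    return ModelComparison(
        chi2=chi2,
        delta_df=delta_df,
        p=p,
        aic_full=a_full,
        aic_reduced=a_red,
        preferred="full" if a_full < a_red else "reduced",
    )


def pseudo_r2(fit: GlmFit, null_fit: GlmFit) -> PseudoR2:
    """Cox & Snell, Nagelkerke and McFadden pseudo-R2 against the
    intercept-only null on the same data."""
    ll1, ll0 = fit.loglik, null_fit.loglik
    n = fit.n or null_fit.n
    if n <= 0:
        raise ConfigError("need the observation count for pseudo-R2")
    if ll1 < ll0 - 1e-9:
        raise ConfigError("full-model loglik below null loglik; fits are inconsistent")
    cs = 1.0 - np.exp(2.0 * (ll0 - ll1) / n)
    denom = 1.0 - np.exp(2.0 * ll0 / n)
    nk = cs / denom if denom > 0 else 0.0
    mf = 1.0 - ll1 / ll0 if ll0 != 0 else 0.0
    return PseudoR2(cox_snell=float(cs), nagelkerke=float(nk), mcfadden=float(mf))


def _contained_in(term: str, other: str) -> bool:
    return term != other and set(term.split(":")) < set(other.split(":"))


def _removable(terms: Sequence[str]) -> list[str]:
    """Terms not contained in any remaining higher-order interaction."""
    return [t for t in terms if not any(_contained_in(t, o) for o in terms)]


def backward_select(
    data: pd.DataFrame,
    maximal_terms: Sequence[str] = DEFAULT_TERMS,
    criterion: str = "aic",
    alpha: float = 0.05,
    outcome: str = "outcome",
) -> SelectionResult:
    """Hierarchy-respecting backward elimination from the maximal model.

    At each step the removable (highest-order) term whose removal gives
    the best reduced model is dropped; main effects are never dropped
    while an interaction containing them remains.  With
    ``criterion='aic'`` a term is dropped when removal lowers the AIC;
    with ``criterion='lrt'`` when its likelihood-ratio p exceeds
    ``alpha``.  Stops when no candidate qualifies.
    """
    if criterion not in ("aic", "lrt"):
        raise ConfigError("criterion must be 'aic' or 'lrt'")
    current = list(maximal_terms)
    fit = fit_binomial_glm(data, current, outcome=outcome)
    fits = [fit]
    comparisons: list[ModelComparison] = []
    removed: list[str] = []
    while True:
        candidates = _removable(current)
        best: tuple[str, GlmFit, ModelComparison] | None = None
        for term in candidates:
            reduced_terms = [t for t in current if t != term]
            try:
                red = fit_binomial_glm(data, reduced_terms, outcome=outcome)
            except ConfigError:
                continue
            comp = lrt(red, fit)
            if best is None:
                best = (term, red, comp)
            elif criterion == "aic" and aic(red) < aic(best[1]):
                best = (term, red, comp)
            elif criterion == "lrt" and comp.p > best[2].p:
                best = (term, red, comp)
        if best is None:
            break
        term, red, comp = best
        drop = (aic(red) < aic(fit)) if criterion == "aic" else (comp.p > alpha)
        if not drop:
            break
        current.remove(term)
        removed.append(term)
        fit = red
        fits.append(fit)
        comparisons.append(comp)
        if not current:
            break
    return SelectionResult(fits=fits, comparisons=comparisons, chosen=fit, removed=removed)


def predicted_prob(fit: GlmFit, freq_z: float, adh: float, time_c: float):
    """Inverse-logit of the fitted linear predictor at the given
    (z-scored frequency, adherence, centered time) point."""
    eta = fit.b.get("intercept", 0.0)
    values = {"freq": freq_z, "adh": adh, "time": time_c}
    for term in fit.terms:
        x = 1.0
        for f in term.split(":"):
            x *= values[f]
        eta += fit.b[term] * x
    return float(1.0 / (1.0 + np.exp(-eta)))


def simulate_usage_glm(
    coeffs: Mapping[str, float],
    n: int,
    rng: np.random.Generator,
    time_values: Sequence[int] = TABLE_TIME_VALUES,
    adherence_rate: float = 0.5,
) -> pd.DataFrame:
    """Simulate observation-level usage data from a known logistic law
    (freq_z standard normal, adherence Bernoulli, time drawn from the
    assessment-day pool and grand-mean centered)."""
    freq = rng.normal(size=n)
    adh = (rng.random(n) < adherence_rate).astype(float)
    days = rng.choice(np.asarray(time_values, dtype=float), size=n)
    time_c = days - days.mean()
    eta = (
        coeffs.get("intercept", 0.0)
        + coeffs.get("freq", 0.0) * freq
        + coeffs.get("adh", 0.0) * adh
        + coeffs.get("time", 0.0) * time_c
        + coeffs.get("freq:adh", 0.0) * freq * adh
        + coeffs.get("freq:time", 0.0) * freq * time_c
        + coeffs.get("adh:time", 0.0) * adh * time_c
        + coeffs.get("freq:adh:time", 0.0) * freq * adh * time_c
    )
    p = 1.0 / (1.0 + np.exp(-eta))
    y = (rng.random(n) < p).astype(float)
    return pd.DataFrame(
        {"freq_z": freq, "adh": adh, "time_c": time_c, "outcome": y,
         "day": days.astype(int)}
    )
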