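"""Causal mediation on linear mixed-effects models.

The question: is the effect of learning progress (repetition number, the
treatment) on an event-related outcome (mid-frontal theta ERS or parietal
alpha ERD) transmitted through pre-stimulus band power (the mediator)?
Three models with subject random intercepts are fit on standardized data:

    M0:  outcome  ~ repetition + (1 | subject)     (total effect)
    M:   mediator ~ repetition + (1 | subject)     (a path)
    Y:   outcome  ~ mediator + repetition + (1 | subject)  (b, c' paths)

In this linear, no-interaction system the average causal mediation effect
is ACME = a*b, the average direct effect ADE = c', and total = ACME + ADE
exactly.  Uncertainty comes from a nonparametric cluster bootstrap that
resamples subjects with replacement and refits M and Y per draw
(percentile CIs); a quasi-Bayesian Monte-Carlo alternative draws the
coefficients from their asymptotic normal distributions instead, which is
far cheaper and serves as an independent cross-check of the bootstrap.
Opposite signs of ACME and ADE are flagged as inconsistent mediation:
the mediator suppresses or reverses the direct effect.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec", "LMMFit", "MediationResult",
    "standardize", "fit_lmm", "mediate",
]


@dataclass
class ModelSpec:
    """Specification of one model in the M0/M/Y system."""
    role: str                     # "M0", "M" or "Y"
    outcome: str
    treatment: str = "repetition"
    mediator: Optional[str] = None
    grouping: str = "subject"

    def __post_init__(self) -> None:
        if self.role not in ("M0", "M", "Y"):
            raise ValueError("role must be M0, M or Y")
        if self.role == "Y" and self.mediator is None:
            raise ValueError("model Y needs a mediator column")
        if self.role in ("M0", "M") and self.mediator is not None:
            raise ValueError(f"model {self.role} must not include a mediator")

    @property
    def predictors(self) -> list[str]:
        return ([self.mediator, self.treatment] if self.role == "Y"
                else [self.treatment])


@dataclass
class LMMFit:
    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame
    pvalues: pd.Series
    group_sd: float
    resid_sd: float
    method: str = "lmm"           # "ols" after zero-variance fallback
    converged: bool = True
    singular: bool = False
    spec: Optional[ModelSpec] = field(default=None, repr=False)
    sm_result: object = field(default=None, repr=False, compare=False)


@dataclass
class MediationResult:
    acme: float
    ade: float
    total: float
    prop_mediated: Optional[float]
    acme_ci: tuple[float, float]
    ade_ci: tuple[float, float]
    total_ci: tuple[float, float]
    prop_ci: Optional[tuple[float, float]]
    acme_p: float
    ade_p: float
    total_p: float
    n_draws: int
    ci_method: str
    seed: Optional[int]
    inconsistent_mediation: bool
    prop_undefined: bool
    premise_ok: bool
    n_failed_draws: int = 0
    a_path: float = float("nan")
    b_path: float = float("nan")


def standardize(table: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Z-score columns over all included rows (mean 0, sample SD 1)."""
    out = table.copy()
    for col in columns:
        x = out[col].astype(float)
        sd = x.std(ddof=1)
        if not sd > 0:
            raise ValueError(f"column {col!r} has zero variance")
        out[col] = (x - x.mean()) / sd
    return out


def fit_lmm(table: pd.DataFrame, spec: ModelSpec,
            min_group_levels: int = 5, start_params=None) -> LMMFit:
    """Linear mixed model with a random intercept for the grouping factor.

    Estimation delegates to statsmodels MixedLM (REML).  When the
    random-intercept variance is estimated at (numerically) zero, or the
    optimizer fails, the fit falls back to OLS with a logged warning; a
    zero-variance converged fit is reported as singular, not hidden.
    """
    groups = table[spec.grouping]
    n_levels = groups.nunique()
    if n_levels < min_group_levels:
        raise ValueError(
            f"random intercept for {spec.grouping!r} needs at least "
            f"{min_group_levels} levels, got {n_levels}"
        )
    endog = table[spec.outcome].astype(float).to_numpy()
    exog = sm.add_constant(
        table[spec.predictors].astype(float), has_constant="add")

    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.MixedLM(endog, exog.to_numpy(), groups=groups)
            result = model.fit(reml=True, maxiter=200,
                               start_params=start_params)
        except Exception as exc:          # noqa: BLE001 - report, fall back
            logger.warning("MixedLM failed (%s); falling back to OLS", exc)

    names = list(exog.columns)
    if result is not None and np.isfinite(result.params[: len(names)]).all():
        group_var = float(np.asarray(result.cov_re)[0, 0])
        singular = group_var <= 1e-10
        if not singular:
            params = pd.Series(result.params[: len(names)], index=names)
            bse = pd.Series(result.bse[: len(names)], index=names)
            ci = pd.DataFrame(
                result.conf_int()[: len(names)], index=names,
                columns=["lower", "upper"])
            pvals = pd.Series(result.pvalues[: len(names)], index=names)
            return LMMFit(params, bse, ci, pvals,
                          group_sd=float(np.sqrt(group_var)),
                          resid_sd=float(np.sqrt(result.scale)),
                          method="lmm",
                          converged=bool(result.converged),
                          singular=False, spec=spec,
                          sm_result=result)
        logger.warning(
            "random-intercept variance for %s estimated at zero; "
            "falling back to OLS", spec.grouping)

    ols = sm.OLS(endog, exog).fit()
    ci = ols.conf_int()
    ci.columns = ["lower", "upper"]
    return LMMFit(ols.params, ols.bse, ci, ols.pvalues,
                  group_sd=0.0, resid_sd=float(np.sqrt(ols.scale)),
                  method="ols", converged=True, singular=True, spec=spec)


def _paths(m_fit: LMMFit, y_fit: LMMFit, treatment: str, mediator: str):
    a = float(m_fit.params[treatment])
    b = float(y_fit.params[mediator])
    c_prime = float(y_fit.params[treatment])
    return a, b, c_prime


def _percentile_ci(draws: np.ndarray, alpha: float):
    return (float(np.percentile(draws, 100 * alpha / 2)),
            float(np.percentile(draws, 100 * (1 - alpha / 2))))


def _boot_p(draws: np.ndarray) -> float:
    """Two-sided percentile p: doubled crossing proportion, capped at 1."""
    if len(draws) == 0:
        return float("nan")
    p = 2.0 * min((draws <= 0).mean(), (draws >= 0).mean())
    return float(min(max(p, 1.0 / len(draws)), 1.0))


def mediate(
    table: pd.DataFrame,
    outcome: str,
    mediator: str,
    treatment: str = "repetition",
    grouping: str = "subject",
    n_draws: int = 1000,
    seed: int | None = None,
    ci_method: str = "bootstrap",
    alpha_level: float = 0.05,
    scale: bool = True,
) -> MediationResult:
    """Point estimates and CIs for ACME, ADE, total effect and proportion
    mediated on a long table (one row per subject x repetition).

    ``ci_method='bootstrap'`` resamples subjects (clusters) with
    replacement and refits M and Y per draw; failed refits are dropped and
    counted.  ``ci_method='montecarlo'`` draws (a, b, c') from independent
    normals centered on the fitted coefficients with their standard errors
    (the quasi-Bayesian approximation).  Variables are standardized over
    the included rows before fitting unless ``scale=False``.
    """
    if ci_method not in ("bootstrap", "montecarlo"):
        raise ValueError(f"unknown ci_method {ci_method!r}")
    cols = [outcome, mediator, treatment]
    data = table.dropna(subset=cols).copy()
    if scale:
        data = standardize(data, cols)

    m_spec = ModelSpec("M", outcome=mediator, treatment=treatment,
                       grouping=grouping)
    y_spec = ModelSpec("Y", outcome=outcome, treatment=treatment,
                       mediator=mediator, grouping=grouping)
    m0_spec = ModelSpec("M0", outcome=outcome, treatment=treatment,
                        grouping=grouping)

    m_fit = fit_lmm(data, m_spec)
    y_fit = fit_lmm(data, y_spec)
    m0_fit = fit_lmm(data, m0_spec)

    # premise: a treatment main effect in M0 or M
    premise_ok = (m0_fit.pvalues[treatment] < 0.05
                  or m_fit.pvalues[treatment] < 0.05)
    if not premise_ok:
        logger.warning(
            "no significant treatment effect in M0 or M; mediation "
            "estimates may not be meaningful")

    a, b, c_prime = _paths(m_fit, y_fit, treatment, mediator)
    acme, ade = a * b, c_prime
    total = acme + ade

    rng = np.random.default_rng(seed)
    n_failed = 0
    if ci_method == "montecarlo":
        a_d = rng.normal(a, m_fit.bse[treatment], n_draws)
        b_d = rng.normal(b, y_fit.bse[mediator], n_draws)
        c_d = rng.normal(c_prime, y_fit.bse[treatment], n_draws)
        acme_d, ade_d = a_d * b_d, c_d
    else:
        subjects = data[grouping].unique()
        data_ri = data.reset_index(drop=True)
        idx_by_subject = {
            s: g.index.to_numpy() for s, g in data_ri.groupby(grouping,
                                                              sort=False)
        }
        acme_l, ade_l = [], []
        for _ in range(n_draws):
            pick = rng.choice(subjects, size=len(subjects), replace=True)
            idx = np.concatenate([idx_by_subject[s] for s in pick])
            boot = data_ri.iloc[idx].copy()
            # resampled clusters stay distinct groups
            boot[grouping] = np.repeat(
                np.arange(len(pick)),
                [len(idx_by_subject[s]) for s in pick])
            m_start = (m_fit.sm_result.params_object
                       if m_fit.sm_result is not None else None)
            y_start = (y_fit.sm_result.params_object
                       if y_fit.sm_result is not None else None)
            try:
                bm = fit_lmm(boot, m_spec, start_params=m_start)
                by = fit_lmm(boot, y_spec, start_params=y_start)
            except Exception:             # noqa: BLE001 - count and drop
                n_failed += 1
                continue
            ab, bb, cb = _paths(bm, by, treatment, mediator)
            acme_l.append(ab * bb)
            ade_l.append(cb)
        if n_failed:
            logger.warning("%d bootstrap refits failed and were dropped",
                           n_failed)
        acme_d = np.asarray(acme_l)
        ade_d = np.asarray(ade_l)
    total_d = acme_d + ade_d

    prop_undefined = abs(total) < 0.01
    prop = None if prop_undefined else acme / total
    prop_ci = None
    if not prop_undefined:
        with np.errstate(divide="ignore", invalid="ignore"):
            prop_d = acme_d / total_d
        prop_d = prop_d[np.isfinite(prop_d)]
        if len(prop_d):
            prop_ci = _percentile_ci(prop_d, alpha_level)

    return MediationResult(
        acme=acme, ade=ade, total=total, prop_mediated=prop,
        acme_ci=_percentile_ci(acme_d, alpha_level),
        ade_ci=_percentile_ci(ade_d, alpha_level),
        total_ci=_percentile_ci(total_d, alpha_level),
        prop_ci=prop_ci,
        acme_p=_boot_p(acme_d), ade_p=_boot_p(ade_d),
        total_p=_boot_p(total_d),
        n_draws=n_draws, ci_method=ci_method, seed=seed,
        inconsistent_mediation=bool(acme * ade < 0),
        prop_undefined=prop_undefined,
        premise_ok=bool(premise_ok),
        n_failed_draws=n_failed,
        a_path=a, b_path=b,
    )
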