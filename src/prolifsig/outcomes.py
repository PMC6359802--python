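"""Outcome statistics: contingency, Kaplan-Meier/log-rank, logistic deviance.

Disease-control rates between strata are compared with the Yates-corrected
chi-square on 2x2 tables (identical mechanics to the screen's proportion
test). Survival uses the product-limit estimator truncated at a 5-year
horizon with two-group log-rank tests. The multivariate analysis fits a
binomial logistic regression of disease control on proliferation status,
PD-L1 positivity, histology, race, sex and age category, and reports a
sequential (Type-I) analysis-of-deviance table in that entry order: each
term's deviance reduction is tested against the chi-square distribution
with the term's degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy.stats import chi2

import statsmodels.api as sm

from .config import DEFAULT_THRESHOLDS
from .screen import pairwise_prop_test

#: coefficient magnitude on the logit scale treated as (quasi-)separation
SEPARATION_COEF_LIMIT = 15.0


@dataclass(frozen=True)
class ContingencyResult:
    """Two-group DC/NDC comparison with the Yates-corrected chi-square."""

    group_labels: Tuple[str, str]
    dc: Tuple[int, int]
    ndc: Tuple[int, int]
    statistic: float
    p_value: float
    df: int = 1

    @property
    def n(self) -> Tuple[int, int]:
        return (self.dc[0] + self.ndc[0], self.dc[1] + self.ndc[1])

    @property
    def dc_rates(self) -> Tuple[float, float]:
        n = self.n
        return (self.dc[0] / n[0], self.dc[1] / n[1])


def dc_contingency(groups: Mapping[str, Tuple[int, int]]) -> ContingencyResult:
    """Compare DC rates of exactly two groups.

    ``groups`` maps group label -> (DC count, NDC count). Larger
    comparisons are decomposed into stated pairs by the caller.
    """
    if len(groups) != 2:
        raise ValueError("dc_contingency takes exactly two groups")
    (la, (dca, ndca)), (lb, (dcb, ndcb)) = groups.items()
    na, nb = dca + ndca, dcb + ndcb
    if na == 0 or nb == 0:
        raise ValueError("empty group in contingency comparison")
    stat, p = pairwise_prop_test(dca, na, dcb, nb)
    return ContingencyResult(group_labels=(la, lb), dc=(dca, dcb),
                             ndc=(ndca, ndcb), statistic=stat, p_value=p)


@dataclass
class KMCurve:
    """Product-limit survival curve truncated at the analysis horizon."""

    times: np.ndarray          # event/censor times within horizon
    survival: np.ndarray       # S(t) at those times
    at_risk: np.ndarray        # number at risk just before each time
    censored: np.ndarray       # boolean: any censoring at this time
    median: float              # earliest time with S <= 0.5; inf if never
    n: int
    n_events: int
    horizon: float

    def to_frame(self) -> pd.DataFrame:
        """Tidy representation suitable for plotting or CSV export."""
        return pd.DataFrame({
            "time": self.times,
            "at_risk": self.at_risk,
            "survival": self.survival,
            "censored": self.censored,
        })


def _truncate(times, events, horizon: float):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("empty survival input")
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if (t < 0).any():
        raise ValueError("negative survival times")
    over = t > horizon
    t = np.where(over, horizon, t)
    e = np.where(over, False, e)
    return t, e


def km_estimate(times: Sequence[float], events: Sequence[bool],
                horizon: float = DEFAULT_THRESHOLDS.km_horizon_months) -> KMCurve:
    """Kaplan-Meier estimate over a fixed horizon (default 60 months).

    Observations beyond the horizon are administratively censored at the
    horizon. Ties at equal times are handled events-before-censorings (the
    product-limit convention). The median is the earliest observed time at
    which S(t) <= 0.5 and is ``inf`` when the curve never reaches 0.5.
    """
    t, e = _truncate(times, events, horizon)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    ev = kmf.event_table
    grid = ev.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(grid).to_numpy()
    return KMCurve(
        times=grid,
        survival=surv,
        at_risk=ev["at_risk"].to_numpy(),
        censored=ev["censored"].to_numpy() > 0,
        median=float(kmf.median_survival_time_),
        n=int(t.size),
        n_events=int(e.sum()),
        horizon=float(horizon),
    )


def logrank_test(times1, events1, times2, events2,
                 horizon: float = DEFAULT_THRESHOLDS.km_horizon_months
                 ) -> Tuple[float, float]:
    """Two-group log-rank chi-square (df=1) within the analysis horizon."""
    t1, e1 = _truncate(times1, events1, horizon)
    t2, e2 = _truncate(times2, events2, horizon)
    res = _ll_logrank(t1, t2, event_observed_A=e1, event_observed_B=e2)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class LogisticFit:
    """Binomial logistic fit with a sequential analysis-of-deviance table."""

    coefficients: pd.DataFrame     # term, estimate, std_error, z, p
    null_deviance: float
    null_df: int
    residual_deviance: float
    residual_df: int
    deviance_table: pd.DataFrame   # term, df, deviance, resid_df, resid_dev, p
    separation_terms: List[str] = field(default_factory=list)

    @property
    def separation_detected(self) -> bool:
        return bool(self.separation_terms)


#: default entry order of the multivariate model terms
DEFAULT_TERM_ORDER = ("proliferation", "pd_l1", "histology", "race", "sex",
                      "age_category")


def fit_dc_logistic(data: pd.DataFrame,
                    term_order: Sequence[str] = DEFAULT_TERM_ORDER,
                    max_iter: int = 100, tol: float = 1e-10) -> LogisticFit:
    """Fit DC ~ covariates by IRLS and decompose the deviance sequentially.

    ``data`` needs a binary ``dc`` column (1 = disease control) plus the
    covariate columns named in ``term_order``. Categorical covariates are
    treatment-coded against their first-sorted level; boolean/numeric
    columns enter as single columns. The sequential table adds terms in
    ``term_order`` and tests each deviance reduction as chi-square at the
    term's df. Coefficients beyond +-15 on the logit scale flag
    (quasi-)complete separation; estimates are still reported but the fit
    carries a divergence warning in ``separation_terms``.
    """
    if "dc" not in data.columns:
        raise ValueError("data must contain a binary 'dc' column")
    y = data["dc"].astype(float).to_numpy()
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("'dc' must be binary 0/1")
    missing = [t for t in term_order if t not in data.columns]
    if missing:
        raise ValueError(f"covariates absent from data: {missing}")

    blocks: Dict[str, pd.DataFrame] = {}
    for term in term_order:
        col = data[term]
        if col.dtype == bool or pd.api.types.is_numeric_dtype(col):
            blocks[term] = pd.DataFrame({term: col.astype(float)})
        else:
            dummies = pd.get_dummies(col.astype(str), prefix=term, dtype=float)
            ref = sorted(dummies.columns)[0]
            blocks[term] = dummies[sorted(dummies.columns)].drop(columns=[ref])

    n = len(data)
    X = pd.DataFrame({"(Intercept)": np.ones(n)}, index=data.index)
    fit0 = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=max_iter, tol=tol)
    null_dev, null_df = float(fit0.deviance), int(fit0.df_resid)

    rows = []
    prev_dev, prev_df = null_dev, null_df
    fit = fit0
    for term in term_order:
        X = pd.concat([X, blocks[term]], axis=1)
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=max_iter, tol=tol)
        dev, dfres = float(fit.deviance), int(fit.df_resid)
        ddf = prev_df - dfres
        drop = prev_dev - dev
        rows.append({
            "term": term, "df": ddf, "deviance": drop,
            "resid_df": dfres, "resid_deviance": dev,
            "p_value": float(chi2.sf(drop, ddf)) if ddf > 0 else float("nan"),
        })
        prev_dev, prev_df = dev, dfres

    coef = pd.DataFrame({
        "term": fit.params.index,
        "estimate": fit.params.to_numpy(),
        "std_error": fit.bse.to_numpy(),
        "z": fit.tvalues.to_numpy(),
        "p_value": fit.pvalues.to_numpy(),
    })
    sep = [t for t, b in zip(coef["term"], coef["estimate"])
           if abs(b) > SEPARATION_COEF_LIMIT]
    return LogisticFit(
        coefficients=coef,
        null_deviance=null_dev, null_df=null_df,
        residual_deviance=prev_dev, residual_df=prev_df,
        deviance_table=pd.DataFrame(rows),
        separation_terms=sep,
    )
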