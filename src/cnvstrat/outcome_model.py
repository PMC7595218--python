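"""Visual-outcome association: LOCF imputation and linear regression.

Follow-up logMAR change from baseline at months 3 and 12 is regressed on the
CNV score, optionally adjusting for age, sex and baseline logMAR.  Missing
follow-up values are imputed by last observation carried forward (LOCF);
patients with no post-baseline visit at all are excluded rather than imputed.
A negative score coefficient means higher (more PNV-like) scores predict
greater visual-acuity improvement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import CollinearityError, DomainError
from .phenotype_io import VisitSeries

__all__ = [
    "LocfResult",
    "RegressionResult",
    "locf_impute",
    "bcva_change",
    "fit_outcome_regression",
    "outcome_table",
]


@dataclass
class LocfResult:
    series: VisitSeries
    n_imputed: int
    has_followup: bool  # False = no post-baseline observation; exclude


@dataclass
class RegressionResult:
    terms: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    p_values: np.ndarray  # two-sided t, n - p - 1 df
    n_obs: int
    adjusted: bool
    outcome: str

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "B": self.coefficients,
                "SE": self.standard_errors,
                "p_value": self.p_values,
            }
        )


def locf_impute(series: VisitSeries, target_months: Sequence[int] = (3, 12)) -> LocfResult:
    """Fill each missing target month with the most recent earlier observation.

    Any post-baseline visit (scheduled or not) can be carried forward.
    Patients with no post-baseline observation are flagged for exclusion,
    not imputed from baseline.
    """
    if series.value_at(0) is None:
        raise DomainError(f"patient {series.patient_id}: baseline missing")
    observed = [(m, v) for m, v in series.visits if v is not None]
    has_followup = any(m > 0 for m, _ in observed)
    months = sorted(set(series.months) | set(int(m) for m in target_months))
    out: list[tuple[int, Optional[float]]] = []
    n_imputed = 0
    for m in months:
        v = series.value_at(m)
        if v is None and m in target_months and has_followup:
            earlier = [x for mm, x in observed if mm < m]
            if earlier:
                v = earlier[-1]
                n_imputed += 1
        out.append((m, v))
    return LocfResult(VisitSeries(series.patient_id, out), n_imputed, has_followup)


def bcva_change(series: VisitSeries, month: int) -> Optional[float]:
    """logMAR(month) - logMAR(baseline); negative = improvement; None if the
    month is unavailable even after imputation."""
    v = series.value_at(month)
    if v is None:
        return None
    return v - series.value_at(0)  # baseline guaranteed by VisitSeries


def fit_outcome_regression(
    data: pd.DataFrame,
    adjust: bool = True,
    outcome: str = "change",
) -> RegressionResult:
    """OLS of logMAR change on score (+ age, sex, baseline logMAR if adjusted).

    ``data`` needs columns change, score and — when adjusting — age, sex,
    baseline_logmar; rows with any missing value are dropped (complete-case
    after LOCF).  Standard errors from residual variance times the inverse
    Gram diagonal; two-sided t p-values.
    """
    terms = ["score"] + (["age", "sex", "baseline_logmar"] if adjust else [])
    cols = ["change"] + terms
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise DomainError(f"missing columns: {missing}")
    d = data[cols].dropna()
    n, p = len(d), len(terms)
    if n <= p + 1:
        raise DomainError(f"n={n} too small for {p} terms")
    x = sm.add_constant(d[terms].to_numpy(), has_constant="add")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise CollinearityError("rank-deficient design matrix")
    res = sm.OLS(d["change"].to_numpy(), x).fit()
    return RegressionResult(
        terms=["intercept"] + terms,
        coefficients=np.asarray(res.params),
        standard_errors=np.asarray(res.bse),
        p_values=np.asarray(res.pvalues),
        n_obs=n,
        adjusted=adjust,
        outcome=outcome,
    )


def outcome_table(
    visit_series: Sequence[VisitSeries],
    covariates: pd.DataFrame,
    months: Sequence[int] = (3, 12),
) -> dict[int, pd.DataFrame]:
    """Assemble per-month regression frames after LOCF.

    ``covariates`` is indexed by patient_id with columns score, age, sex.
    Returns {month: frame with change, score, age, sex, baseline_logmar},
    excluding patients without any post-baseline visit.
    """
    frames: dict[int, list[dict]] = {int(m): [] for m in months}
    for series in visit_series:
        loc = locf_impute(series, target_months=months)
        if not loc.has_followup:
            continue
        if series.patient_id not in covariates.index:
            continue
        cov = covariates.loc[series.patient_id]
        for m in months:
            ch = bcva_change(loc.series, int(m))
            if ch is None:
                continue
            frames[int(m)].append(
                {
                    "patient_id": series.patient_id,
                    "change": ch,
                    "score": float(cov["score"]),
                    "age": float(cov["age"]),
                    "sex": float(cov["sex"]),
                    "baseline_logmar": float(series.value_at(0)),
                }
            )
    return {m: pd.DataFrame(rows) for m, rows in frames.items()}
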