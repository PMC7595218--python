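"""The 7-parameter CNV score: derivation, application and validation.

The score is a linear log-odds model separating pachychoroid
neovasculopathy-type (PNV-type, positive scores) from conventional AMD-type
(negative scores) disease:

    score = intercept
            + w_age  * age/10          + w_sex  * sex(female=1)
            + w_cvh  * CVH(either eye) + w_rt   * RT_affected/100
            + w_sfa  * SFCT_affected/100 + w_sff * SFCT_fellow/100
            + w_da   * typeA_drusen(either eye)

with thicknesses in micrometres.  The published weights (intercept -7.04;
0.16, 0.52, 1.99, -0.34, 1.37, 1.24, -1.68) are 2-decimal roundings of a
logistic regression fitted on the clustering labels; this module can both
apply those constants and refit the model on any labeled cohort.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import (
    CollinearityError,
    ConvergenceError,
    DomainError,
    EmptyCohortError,
    ScoringError,
)
from .phenotype_io import PatientRecord

__all__ = [
    "ScoreWeights",
    "LogisticModel",
    "BinTable",
    "EvaluationReport",
    "PUBLISHED_WEIGHTS",
    "DEFAULT_CUTOFFS",
    "split_train_validation",
    "fit_logistic",
    "cnv_score",
    "score_cohort",
    "weights_from_model",
    "evaluate",
    "ppv_bins",
]

AMD = "AMD-type"
PNV = "PNV-type"

#: z multiplier for Wald 95% confidence intervals
_Z95 = 1.959964


@dataclass(frozen=True)
class ScoreWeights:
    """Intercept plus per-predictor (unit divisor, weight) on the log-odds scale."""

    intercept: float
    terms: tuple[tuple[str, float, float], ...]  # (feature name, divisor, weight)

    def __post_init__(self) -> None:
        if any(div <= 0 for _, div, _ in self.terms):
            raise DomainError("unit scalings must be positive")

    @property
    def predictor_names(self) -> list[str]:
        return [name for name, _, _ in self.terms]


#: published scoring constants (rounded log-odds coefficients)
PUBLISHED_WEIGHTS = ScoreWeights(
    intercept=-7.04,
    terms=(
        ("age", 10.0, 0.16),
        ("sex", 1.0, 0.52),
        ("cvh_either", 1.0, 1.99),
        ("retinal_thickness_affected", 100.0, -0.34),
        ("sfct_affected", 100.0, 1.37),
        ("sfct_fellow", 100.0, 1.24),
        ("drusen_a_either", 1.0, -1.68),
    ),
)

#: published score cutoffs delimiting the five predictive-value bins
DEFAULT_CUTOFFS = (-3.610, -1.966, 0.697, 2.629)


@dataclass
class LogisticModel:
    predictor_names: list[str]
    unit_divisors: list[float]
    coefficients: np.ndarray  # [intercept, beta_1..beta_m] log-odds
    standard_errors: np.ndarray
    p_values: np.ndarray
    converged: bool
    n_iterations: int
    n_obs: int

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients)

    @property
    def ci95(self) -> np.ndarray:
        lo = np.exp(self.coefficients - _Z95 * self.standard_errors)
        hi = np.exp(self.coefficients + _Z95 * self.standard_errors)
        return np.column_stack([lo, hi])

    def summary_frame(self) -> pd.DataFrame:
        ci = self.ci95
        return pd.DataFrame(
            {
                "term": ["intercept"] + self.predictor_names,
                "divisor": [1.0] + self.unit_divisors,
                "coefficient": self.coefficients,
                "se": self.standard_errors,
                "odds_ratio": self.odds_ratios,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "p_value": self.p_values,
            }
        )


@dataclass
class BinTable:
    """Score-cutoff contingency counts and per-bin predictive values."""

    cutoffs: tuple[float, ...]
    amd_counts: list[int]
    pnv_counts: list[int]
    directions: list[str]  # majority-direction class per bin (AMD below 0, PNV above)
    ppv: list[Optional[float]]  # percent, 1 decimal; None for empty bins

    def to_frame(self) -> pd.DataFrame:
        edges = [-math.inf, *self.cutoffs, math.inf]
        return pd.DataFrame(
            {
                "bin_low": edges[:-1],
                "bin_high": edges[1:],
                "amd_count": self.amd_counts,
                "pnv_count": self.pnv_counts,
                "direction": self.directions,
                "ppv_pct": self.ppv,
            }
        )


@dataclass
class EvaluationReport:
    threshold: float
    accuracy: float
    sensitivity: float  # PNV correctly called / all PNV
    specificity: float  # AMD correctly called / all AMD
    confusion: dict[str, int]  # tp, fp, tn, fn (PNV = positive class)
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    auc: float


# ---------------------------------------------------------------------------
# Train/validation split
# ---------------------------------------------------------------------------

def split_train_validation(
    records: Sequence,
    ratio: tuple[int, int] = (3, 1),
    seed: int = 0,
) -> tuple[list, list]:
    """Random disjoint partition at the given parts ratio (validation size
    = ceil(n * valid/(train+valid))), deterministic in ``seed``."""
    n = len(records)
    if n == 0:
        raise EmptyCohortError("cannot split an empty cohort")
    train_parts, valid_parts = ratio
    if train_parts <= 0 or valid_parts <= 0:
        raise DomainError("ratio parts must be positive")
    if n < train_parts + valid_parts:
        raise DomainError(f"n={n} smaller than ratio parts {train_parts + valid_parts}")
    n_valid = math.ceil(n * valid_parts / (train_parts + valid_parts))
    perm = np.random.default_rng(seed).permutation(n)
    valid_idx = set(perm[:n_valid].tolist())
    training = [records[i] for i in range(n) if i not in valid_idx]
    validation = [records[i] for i in range(n) if i in valid_idx]
    return training, validation


# ---------------------------------------------------------------------------
# Logistic fit and score application
# ---------------------------------------------------------------------------

def _design(
    records: Sequence[PatientRecord],
    predictors: Sequence[tuple[str, float]],
) -> np.ndarray:
    x = np.empty((len(records), len(predictors)))
    for i, rec in enumerate(records):
        for j, (name, div) in enumerate(predictors):
            v = rec.get(name)
            if v is None:
                raise ScoringError(f"record {rec.patient_id} missing predictor {name!r}")
            x[i, j] = v / div
    return x


def fit_logistic(
    records: Sequence[PatientRecord],
    labels: Sequence[str],
    predictors: Optional[Sequence[tuple[str, float]]] = None,
) -> LogisticModel:
    """Maximum-likelihood logistic regression of cluster label on unit-scaled
    predictors (PNV-type = 1).

    Newton-type fit via statsmodels; Wald standard errors from the inverse
    observed information.  Perfect separation raises
    :class:`ConvergenceError`, a singular information matrix
    :class:`CollinearityError`.
    """
    if predictors is None:
        predictors = [(name, div) for name, div, _ in PUBLISHED_WEIGHTS.terms]
    y = np.array([1.0 if l == PNV else 0.0 for l in labels])
    if len(set(y.tolist())) < 2:
        raise DomainError("both classes must be present to fit")
    x = sm.add_constant(_design(records, predictors), has_constant="add")
    names = [p for p, _ in predictors]

    def _separated(result) -> bool:
        # huge log-odds plus a perfect in-sample classification = separation
        preds = result.predict(x)
        return bool(
            np.max(np.abs(result.params)) > 30 and np.all((preds > 0.5) == (y > 0.5))
        )

    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, x).fit(disp=0, maxiter=100)
    except np.linalg.LinAlgError as exc:
        # Newton hit a singular information matrix: either separation drove
        # the weights off to infinity, or the design is collinear
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                probe = sm.Logit(y, x).fit(method="bfgs", maxiter=200, disp=0)
            except Exception:
                raise CollinearityError(f"singular information matrix: {exc}") from exc
        if _separated(probe):
            raise ConvergenceError(
                f"perfect separation among predictors {names}"
            ) from exc
        raise CollinearityError(f"singular information matrix: {exc}") from exc
    except Exception as exc:  # statsmodels PerfectSeparationError
        if "erfect" in type(exc).__name__ or "erfect" in str(exc):
            raise ConvergenceError(
                f"perfect separation among predictors {names}"
            ) from exc
        raise
    if _separated(res):
        raise ConvergenceError(f"perfect separation among predictors {names}")
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError(f"logistic fit did not converge for predictors {names}")
    se = np.asarray(res.bse)
    if not np.all(np.isfinite(se)):
        raise CollinearityError("non-finite standard errors: collinear design")
    return LogisticModel(
        predictor_names=[p for p, _ in predictors],
        unit_divisors=[d for _, d in predictors],
        coefficients=np.asarray(res.params),
        standard_errors=se,
        p_values=np.asarray(res.pvalues),
        converged=True,
        n_iterations=int(res.mle_retvals.get("iterations", 0)),
        n_obs=len(records),
    )


def weights_from_model(model: LogisticModel, decimals: Optional[int] = 2) -> ScoreWeights:
    """Score weights = fitted log-odds coefficients, rounded to ``decimals``
    (None keeps them exact)."""
    coefs = model.coefficients
    if decimals is not None:
        coefs = np.round(coefs, decimals)
    return ScoreWeights(
        intercept=float(coefs[0]),
        terms=tuple(
            (name, div, float(c))
            for name, div, c in zip(model.predictor_names, model.unit_divisors, coefs[1:])
        ),
    )


def cnv_score(
    record: Union[PatientRecord, Mapping[str, float]],
    weights: ScoreWeights = PUBLISHED_WEIGHTS,
) -> float:
    """Compute the CNV score for one patient.

    Positive scores indicate PNV-type disease.  Missing covariates raise
    :class:`ScoringError` naming the offender.
    """
    total = weights.intercept
    for name, div, w in weights.terms:
        v = record.get(name)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            pid = getattr(record, "patient_id", "<record>")
            raise ScoringError(f"{pid}: missing score covariate {name!r}")
        total += w * (v / div)
    return float(total)


def score_cohort(
    records: Sequence[PatientRecord],
    weights: ScoreWeights = PUBLISHED_WEIGHTS,
    threshold: float = 0.0,
) -> pd.DataFrame:
    """Per-patient score, logistic probability and predicted class."""
    rows = []
    for rec in records:
        s = cnv_score(rec, weights)
        rows.append(
            {
                "patient_id": rec.patient_id,
                "score": s,
                "probability": 1.0 / (1.0 + math.exp(-s)),
                "predicted": PNV if s > threshold else AMD,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def evaluate(
    scores: Sequence[float],
    labels: Sequence[str],
    threshold: float = 0.0,
) -> EvaluationReport:
    """Threshold diagnostics plus a full ROC sweep.

    PNV-type is the positive class; sensitivity = recall of PNV, specificity
    = recall of AMD.  The ROC sweeps every observed score; AUC by the
    trapezoid rule.
    """
    s = np.asarray(scores, dtype=float)
    y = np.array([1 if l == PNV else 0 for l in labels])
    if y.size == 0 or len(set(y.tolist())) < 2:
        raise DomainError("evaluation needs both classes present")
    pred = (s > threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    n_pos, n_neg = tp + fn, tn + fp

    # ROC: descending thresholds over the observed scores
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    # collapse tied scores to one operating point
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], y_sorted.size - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return EvaluationReport(
        threshold=threshold,
        accuracy=(tp + tn) / y.size,
        sensitivity=tp / n_pos,
        specificity=tn / n_neg,
        confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
        roc_fpr=fpr,
        roc_tpr=tpr,
        auc=auc,
    )


def ppv_bins(
    scores: Sequence[float],
    labels: Sequence[str],
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
) -> BinTable:
    """Contingency counts and predictive values over score-cutoff bins.

    Bins are half-open [c_i, c_{i+1}) with open ends below the first cutoff
    and at/above the last.  Each bin reports the predictive value of its
    majority-direction class — AMD-type for bins centred below zero, PNV-type
    above — as count/total x 100 rounded to one decimal; empty bins report
    None rather than zero.
    """
    cutoffs = tuple(float(c) for c in cutoffs)
    if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise DomainError("cutoffs must be strictly increasing")
    s = np.asarray(scores, dtype=float)
    y = np.array([1 if l == PNV else 0 for l in labels])
    edges = np.r_[-np.inf, cutoffs, np.inf]
    amd_counts, pnv_counts, directions, ppvs = [], [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (s >= lo) & (s < hi)
        n_pnv = int(y[mask].sum())
        n_amd = int(mask.sum()) - n_pnv
        # direction: the side of zero the bin lies on (finite edge for the
        # open-ended bins, midpoint otherwise)
        if not np.isfinite(lo):
            mid = hi
        elif not np.isfinite(hi):
            mid = lo
        else:
            mid = (lo + hi) / 2.0
        direction = PNV if mid > 0 else AMD
        total = n_amd + n_pnv
        if total == 0:
            ppv = None
        else:
            hits = n_pnv if direction == PNV else n_amd
            ppv = round(100.0 * hits / total, 1)
        amd_counts.append(n_amd)
        pnv_counts.append(n_pnv)
        directions.append(direction)
        ppvs.append(ppv)
    return BinTable(cutoffs, amd_counts, pnv_counts, directions, ppvs)
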