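"""Unsupervised patient stratification: standardize -> PCA -> gap statistic -> k-means.

The stage mirrors the field's standard recipe for phenotype-based patient
clustering: z-score the baseline feature matrix, rotate to principal
components, choose the number of clusters k with the gap statistic of
Tibshirani, Walther & Hastie (within-cluster dispersion W_k compared against
its expectation under a uniform reference null), then run k-means on all
retained components and label the two clusters semantically by mean
fellow-eye subfoveal choroidal thickness (the thicker-choroid cluster is the
pachychoroid-neovasculopathy type).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._kmeans_core import lloyd_restarts
from .errors import (
    DegeneratePartitionError,
    DomainError,
    EmptyCohortError,
    InsufficientDataError,
    LabelingError,
)
from .phenotype_io import FeatureSchema, PatientRecord

__all__ = [
    "FeatureMatrix",
    "PCAModel",
    "GapResult",
    "KMeansResult",
    "ClusterLabeling",
    "encode_records",
    "standardize",
    "fit_pca",
    "within_dispersion",
    "kmeans",
    "gap_statistic",
    "cluster_cohort",
    "compare_clusters",
]

AMD = "AMD-type"
PNV = "PNV-type"


@dataclass
class FeatureMatrix:
    """n x p numeric matrix with feature names and optional z-scoring stats."""

    values: np.ndarray
    feature_names: list[str]
    standardization: Optional[tuple[np.ndarray, np.ndarray]] = None  # (means, sds)
    constant_columns: Optional[np.ndarray] = None  # bool mask, set by standardize


@dataclass
class PCAModel:
    component_loadings: np.ndarray  # p x r, orthonormal columns
    explained_variance: np.ndarray  # length r, nonincreasing
    rank: int
    scores: np.ndarray  # n x r
    column_means: np.ndarray  # length p, for reconstruction


@dataclass
class GapResult:
    k_values: list[int]
    log_wk: np.ndarray
    e_log_wk: np.ndarray
    gap: np.ndarray  # e_log_wk - log_wk
    s_k: np.ndarray  # sd(log W*_k) * sqrt(1 + 1/B)
    chosen_k: int
    B: int
    rule: str

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with the conventional gap-table columns."""
        return pd.DataFrame(
            {
                "k": self.k_values,
                "logW": self.log_wk,
                "E.logW": self.e_log_wk,
                "gap": self.gap,
                "SE.sim": self.s_k,
            }
        )


@dataclass
class KMeansResult:
    assignments: np.ndarray
    centroids: np.ndarray
    inertia: float
    n_iter: int
    seed: int
    n_restarts: int


@dataclass
class ClusterLabeling:
    """cluster index -> semantic label, decided by mean fellow-eye SFCT."""

    labels: dict[int, str]
    mean_sfct_fellow: dict[int, float]


def encode_records(
    records: Sequence[PatientRecord], schema: FeatureSchema
) -> FeatureMatrix:
    """Stack complete records into an n x p matrix in schema order."""
    if not records:
        raise EmptyCohortError("no records to encode")
    names = schema.names
    values = np.empty((len(records), len(names)))
    for i, rec in enumerate(records):
        for j, name in enumerate(names):
            v = rec.get(name)
            if v is None:
                raise DomainError(
                    f"record {rec.patient_id} missing {name!r}; filter completeness first"
                )
            values[i, j] = v
    return FeatureMatrix(values, list(names))


def standardize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Z-score each column by its own mean and sample (n-1) sd.

    Constant columns map to all zeros and are flagged rather than dropped, so
    downstream shapes stay aligned with the schema.  Idempotent on already
    standardized data.
    """
    x = np.asarray(matrix.values, dtype=float)
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(x.shape[1])
    constant = sds <= 0
    safe = np.where(constant, 1.0, sds)
    z = (x - means) / safe
    z[:, constant] = 0.0
    return FeatureMatrix(
        z, list(matrix.feature_names), standardization=(means, sds), constant_columns=constant
    )


def fit_pca(matrix: FeatureMatrix, rank_tol: float = 1e-10) -> PCAModel:
    """PCA via SVD of the column-centered matrix.

    Loadings are eigenvectors of the sample covariance, variance-ordered;
    rank is truncated where eigenvalues fall below ``rank_tol`` times the
    largest.  Scores are the centered data projected on the loadings.
    """
    x = np.asarray(matrix.values, dtype=float)
    n, p = x.shape
    if n < 2:
        raise InsufficientDataError("PCA needs at least 2 rows")
    means = x.mean(axis=0)
    xc = x - means
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    eigvals = s**2 / (n - 1)
    if eigvals.size and eigvals[0] > 0:
        r = int(np.sum(eigvals > rank_tol * eigvals[0]))
    else:
        r = 0
    loadings = vt[:r].T
    scores = xc @ loadings
    return PCAModel(
        component_loadings=loadings,
        explained_variance=eigvals[:r],
        rank=r,
        scores=scores,
        column_means=means,
    )


def within_dispersion(
    points: np.ndarray,
    assignments: np.ndarray,
    metric: Literal["squared", "plain"] = "squared",
) -> float:
    """Pooled within-cluster dispersion W_k = sum_r D_r / (2 n_r).

    With the squared-Euclidean metric (the standard gap-statistic choice,
    matching R's clusGap) D_r is the sum over ordered within-cluster pairs of
    squared distances, which equals twice the cluster's sum of squares about
    its centroid — so W_k is computed through centroids.  ``metric="plain"``
    uses unsquared distances, evaluated pairwise.
    """
    points = np.asarray(points, dtype=float)
    assignments = np.asarray(assignments)
    labels = np.unique(assignments)
    if points.shape[0] == 0 or labels.size == 0:
        raise DegeneratePartitionError("no points / empty partition")
    total = 0.0
    for lab in labels:
        member = points[assignments == lab]
        if member.shape[0] == 0:
            raise DegeneratePartitionError(f"cluster {lab} is empty")
        if metric == "squared":
            centroid = member.mean(axis=0)
            total += float(((member - centroid) ** 2).sum())
        else:
            d = np.sqrt(
                np.maximum(
                    ((member[:, None, :] - member[None, :, :]) ** 2).sum(-1), 0.0
                )
            )
            total += float(d.sum()) / (2 * member.shape[0])
    return total


# ---------------------------------------------------------------------------
# k-means (Lloyd, k-means++ init, best-of-restarts)
# ---------------------------------------------------------------------------

def kmeans(
    points: np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 25,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> KMeansResult:
    """Lloyd's k-means with k-means++ initialization, best of ``n_restarts``.

    Deterministic given ``seed``; an empty-cluster event reseeds the empty
    centroid at the farthest point from its assigned center.
    """
    x = np.asarray(points, dtype=float)
    if x.ndim != 2:
        raise DomainError("points must be a 2-d array")
    n = x.shape[0]
    if k > n:
        raise DomainError(f"k={k} exceeds number of points n={n}")
    if k < 1:
        raise DomainError("k must be >= 1")
    inertia, assign, centers, n_iter = lloyd_restarts(
        x, k, max(1, n_restarts), seed, max_iter, tol
    )
    return KMeansResult(
        assignments=np.asarray(assign, dtype=int),
        centroids=np.asarray(centers),
        inertia=float(inertia),
        n_iter=int(n_iter),
        seed=seed,
        n_restarts=n_restarts,
    )


# ---------------------------------------------------------------------------
# Gap statistic
# ---------------------------------------------------------------------------

def _log_wk_per_k(
    x: np.ndarray,
    k_values: Sequence[int],
    seed: int,
    n_restarts: int,
    max_iter: int,
    tol: float,
    metric: str,
) -> np.ndarray:
    out = np.empty(len(k_values))
    for i, k in enumerate(k_values):
        if k == 1:
            assign = np.zeros(x.shape[0], dtype=int)
        else:
            assign = kmeans(
                x, k, seed=seed + k, n_restarts=n_restarts, max_iter=max_iter, tol=tol
            ).assignments
        out[i] = np.log(within_dispersion(x, assign, metric=metric))  # type: ignore[arg-type]
    return out


def gap_statistic(
    points: np.ndarray,
    k_max: int = 10,
    B: int = 100,
    seed: int = 0,
    rule: Literal["firstSEmax", "tibshirani2001"] = "firstSEmax",
    n_restarts: int = 10,
    ref_restarts: Optional[int] = None,
    max_iter: int = 300,
    tol: float = 1e-6,
    reference: Literal["pca", "aligned"] = "pca",
    metric: Literal["squared", "plain"] = "squared",
) -> GapResult:
    """Estimate the number of clusters by the gap statistic.

    For k = 1..k_max, gap(k) = E*[log W_k] - log W_k where the expectation is
    a Monte Carlo average over ``B`` reference datasets drawn uniformly on
    the bounding box of the data in PCA-rotated coordinates (``reference=
    "aligned"`` uses the raw axis-aligned box).  The reported standard error
    s_k = sd(log W*_k) * sqrt(1 + 1/B).

    ``ref_restarts`` defaults to ``n_restarts``: the data and reference
    dispersion curves must be optimized equally hard, otherwise the
    k-dependent suboptimality bias of the two curves differs and distorts
    the gap curve.

    Selection rules:

    - ``firstSEmax``: smallest k whose gap is within one s of the first local
      maximum of the gap curve.
    - ``tibshirani2001``: smallest k with gap(k) >= gap(k+1) - s_(k+1).
    """
    x = np.asarray(points, dtype=float)
    n = x.shape[0]
    if k_max < 2:
        raise DomainError("k_max must be >= 2")
    if B < 1:
        raise DomainError("B must be >= 1")
    if k_max >= n:
        raise DomainError(f"k_max={k_max} must be < n={n}")
    if ref_restarts is None:
        ref_restarts = n_restarts
    k_values = list(range(1, k_max + 1))
    log_wk = _log_wk_per_k(x, k_values, seed, n_restarts, max_iter, tol, metric)

    center = x.mean(axis=0)
    xc = x - center
    if reference == "pca" and x.shape[1] > 0:
        _, _, vt = np.linalg.svd(xc, full_matrices=False)
        rot = vt.T
        xr = xc @ rot
    else:
        rot = np.eye(x.shape[1])
        xr = xc
    lo, hi = xr.min(axis=0), xr.max(axis=0)

    rng = np.random.default_rng(seed)
    log_wk_ref = np.empty((B, len(k_values)))
    for b in range(B):
        ref = lo + (hi - lo) * rng.random(xr.shape)
        ref = ref @ rot.T + center
        log_wk_ref[b] = _log_wk_per_k(
            ref, k_values, int(rng.integers(2**31)), ref_restarts, max_iter, tol, metric
        )
    e_log_wk = log_wk_ref.mean(axis=0)
    sd_ref = log_wk_ref.std(axis=0, ddof=1) if B > 1 else np.zeros(len(k_values))
    s_k = sd_ref * np.sqrt(1.0 + 1.0 / B)
    gap = e_log_wk - log_wk

    chosen = _choose_k(np.asarray(k_values), gap, s_k, rule)
    return GapResult(
        k_values=k_values,
        log_wk=log_wk,
        e_log_wk=e_log_wk,
        gap=gap,
        s_k=s_k,
        chosen_k=chosen,
        B=B,
        rule=rule,
    )


def _choose_k(k_values: np.ndarray, gap: np.ndarray, s_k: np.ndarray, rule: str) -> int:
    m = len(gap)
    if rule == "tibshirani2001":
        for i in range(m - 1):
            if gap[i] >= gap[i + 1] - s_k[i + 1]:
                return int(k_values[i])
        return int(k_values[-1])
    if rule == "firstSEmax":
        # first local maximum of the gap curve, then the smallest k within
        # one standard error of it
        i_max = m - 1
        for i in range(m):
            left_ok = i == 0 or gap[i] >= gap[i - 1]
            right_ok = i == m - 1 or gap[i] >= gap[i + 1]
            if left_ok and right_ok:
                i_max = i
                break
        threshold = gap[i_max] - s_k[i_max]
        for i in range(i_max + 1):
            if gap[i] >= threshold:
                return int(k_values[i])
        return int(k_values[i_max])
    raise DomainError(f"unknown selection rule: {rule!r}")


# ---------------------------------------------------------------------------
# End-to-end clustering of a cohort
# ---------------------------------------------------------------------------

def cluster_cohort(
    records: Sequence[PatientRecord],
    schema: FeatureSchema,
    seed: int = 0,
    k_max: int = 10,
    B: int = 100,
    rule: Literal["firstSEmax", "tibshirani2001"] = "firstSEmax",
    n_restarts: int = 25,
    gap_restarts: int = 10,
) -> tuple[PCAModel, GapResult, KMeansResult, Optional[ClusterLabeling]]:
    """encode -> standardize -> PCA -> gap statistic -> k-means -> labeling.

    k-means runs on all retained principal components at the gap-chosen k.
    When k = 2 the clusters receive semantic labels by mean fellow-eye SFCT
    (strictly larger = PNV-type); ties raise rather than guess.  For k != 2
    the labeling is None.
    """
    matrix = standardize(encode_records(records, schema))
    pca = fit_pca(matrix)
    if pca.rank == 0:
        raise DegeneratePartitionError(
            "all records identical after standardization; nothing to cluster"
        )
    gap = gap_statistic(
        pca.scores,
        k_max=min(k_max, len(records) - 1),
        B=B,
        seed=seed,
        rule=rule,
        n_restarts=gap_restarts,
    )
    km = kmeans(pca.scores, gap.chosen_k, seed=seed, n_restarts=n_restarts)
    labeling = None
    if gap.chosen_k == 2:
        labeling = label_clusters(records, km.assignments)
    return pca, gap, km, labeling


def label_clusters(
    records: Sequence[PatientRecord], assignments: np.ndarray
) -> ClusterLabeling:
    """Assign AMD-type / PNV-type by mean fellow-eye SFCT (larger = PNV)."""
    assignments = np.asarray(assignments)
    idx = np.unique(assignments)
    if idx.size != 2:
        raise LabelingError(f"semantic labeling needs exactly 2 clusters, got {idx.size}")
    means = {}
    for c in idx:
        vals = [
            records[i].get("sfct_fellow")
            for i in range(len(records))
            if assignments[i] == c
        ]
        vals = [v for v in vals if v is not None]
        if not vals:
            raise LabelingError(f"cluster {c} has no fellow-eye SFCT values")
        means[int(c)] = float(np.mean(vals))
    (c1, m1), (c2, m2) = means.items()
    if m1 == m2:
        raise LabelingError("mean fellow-eye SFCT tied between clusters")
    labels = {c1: PNV, c2: AMD} if m1 > m2 else {c1: AMD, c2: PNV}
    return ClusterLabeling(labels=labels, mean_sfct_fellow=means)


def compare_clusters(
    records: Sequence[PatientRecord],
    labels: Sequence[str],
    schema: FeatureSchema,
) -> pd.DataFrame:
    """Per-feature two-group comparison table.

    Continuous features: group mean +- sd, two-sided Wilcoxon rank-sum
    (Mann-Whitney) p-value.  Binary features: counts and percentages,
    two-sided Fisher exact p-value.
    """
    labels = list(labels)
    groups = sorted(set(labels))
    if len(groups) != 2:
        raise DegeneratePartitionError(f"need exactly 2 groups, got {groups}")
    g1, g2 = groups
    i1 = [i for i, l in enumerate(labels) if l == g1]
    i2 = [i for i, l in enumerate(labels) if l == g2]
    if not i1 or not i2:
        raise DegeneratePartitionError("one comparison group is empty")

    rows = []
    for name, kind, unit in schema.entries:
        v1 = np.array([records[i].get(name) for i in i1], dtype=float)
        v2 = np.array([records[i].get(name) for i in i2], dtype=float)
        if kind == "continuous":
            if np.all(v1 == v1[0]) and np.all(v2 == v2[0]) and v1[0] == v2[0]:
                p = 1.0  # both groups constant and equal
            else:
                p = float(stats.mannwhitneyu(v1, v2, alternative="two-sided").pvalue)
            rows.append(
                {
                    "feature": name,
                    "kind": kind,
                    "unit": unit,
                    f"{g1}_mean": float(v1.mean()),
                    f"{g1}_sd": float(v1.std(ddof=1)) if v1.size > 1 else 0.0,
                    f"{g2}_mean": float(v2.mean()),
                    f"{g2}_sd": float(v2.std(ddof=1)) if v2.size > 1 else 0.0,
                    "p_value": p,
                    "test": "wilcoxon",
                }
            )
        else:
            a, b = int(v1.sum()), len(v1) - int(v1.sum())
            c, d = int(v2.sum()), len(v2) - int(v2.sum())
            p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
            rows.append(
                {
                    "feature": name,
                    "kind": kind,
                    "unit": unit,
                    f"{g1}_count": a,
                    f"{g1}_pct": 100.0 * a / len(v1),
                    f"{g2}_count": c,
                    f"{g2}_pct": 100.0 * c / len(v2),
                    "p_value": p,
                    "test": "fisher",
                }
            )
    return pd.DataFrame(rows)
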