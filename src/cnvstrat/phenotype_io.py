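"""Patient data model, CSV dialects, completeness filtering and derived quantities.

The unit conventions follow the clinical source tables: thicknesses in
micrometres, axial length in millimetres, visual acuity in logMAR, sex coded
male = 0 / female = 1.  All unit scalings used by the scoring system
(per-10-years, per-100-um) are applied inside the scoring module, never here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, IntegrityError, SchemaError

__all__ = [
    "FeatureSchema",
    "PatientRecord",
    "VisitSeries",
    "default_schema",
    "read_cohort",
    "write_cohort",
    "read_visits",
    "write_visits",
    "apply_completeness_filter",
    "brinkman_index",
    "to_logmar",
]

#: continuous baseline features with explicit clinical meaning
_NAMED_CONTINUOUS: tuple[tuple[str, str], ...] = (
    ("age", "years"),
    ("logmar_affected", "logMAR"),
    ("logmar_fellow", "logMAR"),
    ("axial_length_affected", "mm"),
    ("axial_length_fellow", "mm"),
    ("retinal_thickness_affected", "um"),
    ("sfct_affected", "um"),
    ("sfct_fellow", "um"),
    ("gld", "um"),
    ("cigarettes_per_day", "count"),
    ("smoking_years", "years"),
)

#: binary flags (imaging phenotypes and medical history), coded 0/1
_NAMED_BINARY: tuple[str, ...] = (
    "sex",  # male=0, female=1
    "cvh_either",
    "polyp_affected",
    "pachyvessel_either",
    "reduced_tessellation_either",
    "pseudodrusen_either",
    "drusen_a_either",
    "drusen_b_either",
    "drusen_c_either",
    "cnv_type1",
    "cnv_type2",
    "history_csc",
    "history_htn",
    "history_dm",
    "history_hld",
    "history_ci",
    "history_mi",
)

N_FEATURES_DEFAULT = 61


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered list of (name, kind, unit) describing one cohort table."""

    entries: tuple[tuple[str, Literal["continuous", "binary"], str], ...]

    def __post_init__(self) -> None:
        names = [e[0] for e in self.entries]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise SchemaError(f"duplicate feature names: {dupes}")

    @property
    def names(self) -> list[str]:
        return [e[0] for e in self.entries]

    @property
    def continuous(self) -> list[str]:
        return [e[0] for e in self.entries if e[1] == "continuous"]

    @property
    def binary(self) -> list[str]:
        return [e[0] for e in self.entries if e[1] == "binary"]

    def kind(self, name: str) -> str:
        for n, k, _ in self.entries:
            if n == name:
                return k
        raise SchemaError(f"unknown feature: {name}")

    def __len__(self) -> int:
        return len(self.entries)


def default_schema() -> FeatureSchema:
    """The default 61-feature baseline schema.

    28 features carry explicit clinical names; the remaining 33 auxiliary
    features (17 continuous, 16 binary) stand in for additional graded
    characteristics whose per-cluster parameters are not individually
    published, and default to distributions shared across clusters.
    """
    entries: list[tuple[str, str, str]] = []
    for name, unit in _NAMED_CONTINUOUS:
        entries.append((name, "continuous", unit))
    for name in _NAMED_BINARY:
        entries.append((name, "binary", "flag"))
    for i in range(1, 18):
        entries.append((f"aux_c{i:02d}", "continuous", "a.u."))
    for i in range(1, 17):
        entries.append((f"aux_b{i:02d}", "binary", "flag"))
    assert len(entries) == N_FEATURES_DEFAULT
    return FeatureSchema(tuple(entries))  # type: ignore[arg-type]


@dataclass
class PatientRecord:
    """One patient's baseline features, keyed by schema name.

    ``features`` holds every baseline value (missing = NaN / None);
    ``true_cluster`` is only populated by the synthetic generator and is
    never consumed by the analysis stages — it exists for recovery tests.
    """

    patient_id: str
    features: dict[str, Optional[float]]
    true_cluster: Optional[str] = None

    def get(self, name: str) -> Optional[float]:
        v = self.features.get(name)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return v

    def is_missing(self, name: str) -> bool:
        return self.get(name) is None


@dataclass
class VisitSeries:
    """Longitudinal visual-acuity series: ordered (month, logMAR) pairs.

    Month 0 is the baseline and must be present and non-missing; months are
    strictly increasing.  ``None`` marks a scheduled-but-missing measurement.
    """

    patient_id: str
    visits: list[tuple[int, Optional[float]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        months = [m for m, _ in self.visits]
        if sorted(set(months)) != months:
            raise DomainError(f"visit months must be strictly increasing: {months}")
        if 0 not in months:
            raise DomainError(f"patient {self.patient_id}: baseline (month 0) missing")
        if self.value_at(0) is None:
            raise DomainError(f"patient {self.patient_id}: baseline logMAR is missing")

    def value_at(self, month: int) -> Optional[float]:
        for m, v in self.visits:
            if m == month:
                if v is None or (isinstance(v, float) and math.isnan(v)):
                    return None
                return v
        return None

    @property
    def months(self) -> list[int]:
        return [m for m, _ in self.visits]


# ---------------------------------------------------------------------------
# CSV dialects: phenotype table and visit table
# ---------------------------------------------------------------------------

def _records_to_frame(records: Sequence[PatientRecord], schema: FeatureSchema) -> pd.DataFrame:
    rows = []
    for r in records:
        row: dict[str, object] = {"patient_id": r.patient_id}
        for name in schema.names:
            v = r.features.get(name)
            row[name] = np.nan if v is None else v
        if r.true_cluster is not None:
            row["true_cluster"] = r.true_cluster
        rows.append(row)
    df = pd.DataFrame(rows)
    cols = ["patient_id"] + schema.names
    if "true_cluster" in df.columns:
        cols.append("true_cluster")
    return df[cols]


def write_cohort(records: Sequence[PatientRecord], path, schema: FeatureSchema) -> None:
    """Write the phenotype CSV: header patient_id + schema names (+ true_cluster).

    Missing values serialize as empty cells.
    """
    df = _records_to_frame(records, schema)
    df.to_csv(path, index=False, na_rep="")


def read_cohort(path, schema: FeatureSchema) -> list[PatientRecord]:
    """Read a phenotype CSV into typed records.

    Unparsable numeric cells become missing markers, never silent zeros.
    Missing mandatory columns raise :class:`SchemaError` naming them;
    duplicate patient ids raise :class:`IntegrityError`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in ["patient_id"] + schema.names if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing mandatory columns: {missing_cols}")
    ids = df["patient_id"].tolist()
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise IntegrityError(f"duplicate patient_id values: {dupes}")
    records = []
    has_truth = "true_cluster" in df.columns
    for _, row in df.iterrows():
        feats: dict[str, Optional[float]] = {}
        for name in schema.names:
            raw = row[name].strip()
            if raw == "":
                feats[name] = None
            else:
                try:
                    feats[name] = float(raw)
                except ValueError:
                    feats[name] = None
        truth = row["true_cluster"].strip() if has_truth else ""
        records.append(
            PatientRecord(str(row["patient_id"]), feats, truth or None)
        )
    return records


def write_visits(series_list: Sequence[VisitSeries], path) -> None:
    """Visit CSV: columns patient_id, month, logmar (empty cell = missing)."""
    rows = [
        {"patient_id": s.patient_id, "month": m, "logmar": np.nan if v is None else v}
        for s in series_list
        for m, v in s.visits
    ]
    pd.DataFrame(rows, columns=["patient_id", "month", "logmar"]).to_csv(
        path, index=False, na_rep=""
    )


def read_visits(path) -> list[VisitSeries]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing_cols = [c for c in ("patient_id", "month", "logmar") if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing mandatory columns: {missing_cols}")
    out = []
    for pid, grp in df.groupby("patient_id", sort=False):
        grp = grp.sort_values("month")
        visits = [
            (int(m), None if pd.isna(v) else float(v))
            for m, v in zip(grp["month"], grp["logmar"])
        ]
        out.append(VisitSeries(str(pid), visits))
    return out


# ---------------------------------------------------------------------------
# Completeness filter and derived quantities
# ---------------------------------------------------------------------------

def apply_completeness_filter(
    records: Iterable[PatientRecord], required: Sequence[str]
) -> tuple[list[PatientRecord], list[tuple[PatientRecord, str]]]:
    """Partition records into complete and incomplete w.r.t. ``required``.

    A record is excluded iff any required field is missing; the reason is the
    first missing field in ``required`` order.  Mirrors the study's
    exclusion of patients lacking axial length, choroidal thickness etc.
    """
    kept: list[PatientRecord] = []
    excluded: list[tuple[PatientRecord, str]] = []
    for rec in records:
        reason = next((f for f in required if rec.is_missing(f)), None)
        if reason is None:
            kept.append(rec)
        else:
            excluded.append((rec, reason))
    return kept, excluded


def brinkman_index(cigarettes_per_day: float, smoking_years: float) -> float:
    """Brinkman index = cigarettes per day x years smoked."""
    if cigarettes_per_day < 0 or smoking_years < 0:
        raise DomainError("cigarettes_per_day and smoking_years must be >= 0")
    return cigarettes_per_day * smoking_years


def to_logmar(decimal_acuity: float) -> float:
    """Convert decimal visual acuity to logMAR: -log10(acuity)."""
    if decimal_acuity <= 0:
        raise DomainError("decimal acuity must be positive")
    return -math.log10(decimal_acuity)
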