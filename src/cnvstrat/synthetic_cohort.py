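"""Synthetic two-latent-class CNV cohorts.

The clinical cohort behind this analysis is not publicly deposited, so every
downstream stage is exercised on simulated cohorts that reproduce its
published statistical structure: a mixture of an AMD-type class (older, thin
choroid, drusen-driven) and a PNV-type class (younger, thick choroid,
pachychoroid features), with per-class means/SDs for continuous measurements
and per-class prevalences for binary imaging and history flags.

Continuous features are truncated Gaussians in native units; the affected- and
fellow-eye subfoveal choroidal thickness (SFCT) pair is correlated within
class (default r = 0.8) so the pooled SFCT distribution is bimodal in both
eyes, as observed clinically.  Follow-up visual acuity is simulated at months
0, 3 and 12 with class-specific logMAR-change distributions and per-visit
dropout.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .errors import DomainError, EmptyCohortError
from .phenotype_io import (
    FeatureSchema,
    PatientRecord,
    VisitSeries,
    default_schema,
)

__all__ = [
    "ClusterProfile",
    "FollowupConfig",
    "CohortConfig",
    "default_config",
    "simulate_cohort",
    "simulate_followup",
    "simulate_followups",
]

AMD = "AMD-type"
PNV = "PNV-type"


@dataclass
class ClusterProfile:
    """Generative parameters of one latent class."""

    label: str
    n: int
    continuous_params: dict[str, tuple[float, float]]  # name -> (mean, sd), native units
    binary_prevalences: dict[str, float]  # name -> probability

    def __post_init__(self) -> None:
        if self.n < 0:
            raise DomainError(f"cluster size must be >= 0, got {self.n}")
        for name, (_, sd) in self.continuous_params.items():
            if sd < 0:
                raise DomainError(f"sd must be >= 0 for {name!r}, got {sd}")
        for name, p in self.binary_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise DomainError(f"prevalence for {name!r} out of [0,1]: {p}")

    @property
    def feature_names(self) -> set[str]:
        return set(self.continuous_params) | set(self.binary_prevalences)


@dataclass
class FollowupConfig:
    """Visit simulation: schedule, per-class logMAR change, dropout."""

    months: tuple[int, ...] = (0, 3, 12)
    #: label -> {month -> mean logMAR change from baseline}
    change_mean: dict[str, dict[int, float]] = field(
        default_factory=lambda: {
            AMD: {3: -0.02, 12: -0.03},
            PNV: {3: -0.12, 12: -0.10},
        }
    )
    change_sd: float = 0.20
    dropout: float = 0.10  # probability each post-baseline visit is missing


@dataclass
class CohortConfig:
    profiles: list[ClusterProfile]
    seed: int = 0
    truncation_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    #: within-class correlation applied to each pair in correlated_pairs
    correlation_knob: float = 0.0
    correlated_pairs: list[tuple[str, str]] = field(default_factory=list)
    followup: FollowupConfig = field(default_factory=FollowupConfig)

    def __post_init__(self) -> None:
        if not -1.0 < self.correlation_knob < 1.0:
            raise DomainError("correlation_knob must lie in (-1, 1)")
        for name, (lo, hi) in self.truncation_bounds.items():
            if not lo < hi:
                raise DomainError(f"truncation bounds for {name!r} need low < high")
        name_sets = {frozenset(p.feature_names) for p in self.profiles}
        if len(name_sets) > 1:
            raise DomainError("profiles must share one feature-name set")

    @property
    def total_n(self) -> int:
        return sum(p.n for p in self.profiles)


# ---------------------------------------------------------------------------
# Default parameterization: published per-cluster summary statistics
# ---------------------------------------------------------------------------

# (mean, sd) per cluster for the individually published continuous features
_CONT_AMD = {
    "age": (75.03, 7.87),
    "logmar_affected": (0.377, 0.385),
    "axial_length_affected": (23.83, 1.10),
    "axial_length_fellow": (23.97, 1.13),
    "retinal_thickness_affected": (451.46, 230.42),
    "sfct_affected": (194.56, 74.19),
    "sfct_fellow": (194.24, 74.29),
}
_CONT_PNV = {
    "age": (70.87, 8.53),
    "logmar_affected": (0.259, 0.324),
    "axial_length_affected": (23.37, 1.01),
    "axial_length_fellow": (23.46, 1.02),
    "retinal_thickness_affected": (346.11, 161.47),
    "sfct_affected": (334.42, 93.65),
    "sfct_fellow": (327.85, 88.01),
}
# prevalences = published per-cluster counts / cluster size
_BIN_AMD = {
    "sex": 81 / 289,  # female
    "history_csc": 4 / 289,
    "cvh_either": 18 / 289,
    "polyp_affected": 127 / 289,
    "pachyvessel_either": 80 / 289,
    "reduced_tessellation_either": 33 / 289,
    "pseudodrusen_either": 28 / 289,
    "drusen_a_either": 82 / 289,
    "drusen_b_either": 107 / 289,
    "drusen_c_either": 56 / 289,
}
_BIN_PNV = {
    "sex": 69 / 248,
    "history_csc": 24 / 248,
    "cvh_either": 107 / 248,
    "polyp_affected": 127 / 248,
    "pachyvessel_either": 213 / 248,
    "reduced_tessellation_either": 200 / 248,
    "pseudodrusen_either": 1 / 248,
    "drusen_a_either": 11 / 248,
    "drusen_b_either": 177 / 248,
    "drusen_c_either": 122 / 248,
}

# features without published per-cluster parameters: neutral, shared across
# classes so cluster recovery cannot lean on them
_CONT_SHARED = {
    "logmar_fellow": (0.10, 0.25),
    "gld": (2500.0, 1500.0),
    "cigarettes_per_day": (10.0, 12.0),
    "smoking_years": (18.0, 19.0),
}
_BIN_SHARED = {
    "cnv_type1": 0.75,
    "cnv_type2": 0.25,
    "history_htn": 0.42,
    "history_dm": 0.16,
    "history_hld": 0.22,
    "history_ci": 0.04,
    "history_mi": 0.03,
}

_TRUNCATION = {
    "age": (40.0, 100.0),
    "logmar_affected": (-0.3, 2.0),
    "logmar_fellow": (-0.3, 2.0),
    "axial_length_affected": (20.0, 30.0),
    "axial_length_fellow": (20.0, 30.0),
    "retinal_thickness_affected": (50.0, 2000.0),
    "sfct_affected": (20.0, 800.0),
    "sfct_fellow": (20.0, 800.0),
    "gld": (100.0, 12000.0),
    "cigarettes_per_day": (0.0, 100.0),
    "smoking_years": (0.0, 80.0),
}


def default_config(seed: int = 0, schema: Optional[FeatureSchema] = None) -> CohortConfig:
    """Cohort configuration matching the published two-cluster summary table.

    289 AMD-type and 248 PNV-type patients (537 total); every published
    per-cluster (mean, sd) and prevalence transcribed; auxiliary features
    shared across classes; affected/fellow SFCT correlated at r = 0.8.
    """
    schema = schema or default_schema()
    profiles = []
    for label, n, cont, bins in (
        (AMD, 289, _CONT_AMD, _BIN_AMD),
        (PNV, 248, _CONT_PNV, _BIN_PNV),
    ):
        cp = dict(cont)
        bp = dict(bins)
        cp.update(_CONT_SHARED)
        bp.update(_BIN_SHARED)
        for name in schema.continuous:
            cp.setdefault(name, (0.0, 1.0))  # aux continuous, neutral
        for name in schema.binary:
            bp.setdefault(name, 0.2)  # aux binary, neutral
        profiles.append(ClusterProfile(label, n, cp, bp))
    return CohortConfig(
        profiles=profiles,
        seed=seed,
        truncation_bounds=dict(_TRUNCATION),
        correlation_knob=0.8,
        correlated_pairs=[("sfct_affected", "sfct_fellow")],
    )


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _draw_cluster(
    profile: ClusterProfile,
    config: CohortConfig,
    schema: FeatureSchema,
    rng: np.random.Generator,
) -> list[dict[str, float]]:
    n = profile.n
    cont_names = [f for f in schema.continuous if f in profile.continuous_params]
    bin_names = [f for f in schema.binary if f in profile.binary_prevalences]
    means = np.array([profile.continuous_params[f][0] for f in cont_names])
    sds = np.array([profile.continuous_params[f][1] for f in cont_names])
    idx = {f: j for j, f in enumerate(cont_names)}

    def draw_z(m: int) -> np.ndarray:
        z = rng.standard_normal((m, len(cont_names)))
        rho = config.correlation_knob
        for a, b in config.correlated_pairs:
            if a in idx and b in idx:
                ja, jb = idx[a], idx[b]
                z[:, jb] = rho * z[:, ja] + np.sqrt(1.0 - rho**2) * z[:, jb]
        return z

    lows = np.array(
        [config.truncation_bounds.get(f, (-np.inf, np.inf))[0] for f in cont_names]
    )
    highs = np.array(
        [config.truncation_bounds.get(f, (-np.inf, np.inf))[1] for f in cont_names]
    )
    x = means + sds * draw_z(n)
    # rejection: redraw whole rows that violate any truncation bound, so the
    # within-row correlation structure is preserved
    for _ in range(1000):
        bad = np.any((x < lows) | (x > highs), axis=1)
        if not bad.any():
            break
        x[bad] = means + sds * draw_z(int(bad.sum()))
    else:
        x = np.clip(x, lows, highs)  # pathological bounds: fall back to clipping

    b = (rng.random((n, len(bin_names))) < np.array(
        [profile.binary_prevalences[f] for f in bin_names]
    )).astype(float)

    rows = []
    for i in range(n):
        feats = {f: float(x[i, j]) for j, f in enumerate(cont_names)}
        feats.update({f: float(b[i, j]) for j, f in enumerate(bin_names)})
        rows.append(feats)
    return rows


def simulate_cohort(
    config: CohortConfig, schema: Optional[FeatureSchema] = None
) -> list[PatientRecord]:
    """Draw one cohort from the configured two-class mixture.

    Records carry their generating class in ``true_cluster`` (hidden from the
    analysis stages; used only by recovery tests).  The same seed always
    yields a byte-identical cohort.
    """
    schema = schema or default_schema()
    if config.total_n <= 0:
        raise EmptyCohortError("configured cohort has zero patients")
    rng = np.random.default_rng(config.seed)
    records: list[PatientRecord] = []
    pid = 0
    for profile in config.profiles:
        for feats in _draw_cluster(profile, config, schema, rng):
            pid += 1
            records.append(PatientRecord(f"P{pid:04d}", feats, profile.label))
    return records


def _followup_rng(record: PatientRecord, config: CohortConfig) -> np.random.Generator:
    # per-patient stream: deterministic in (config seed, patient id)
    return np.random.default_rng([config.seed, zlib.crc32(record.patient_id.encode())])


def simulate_followup(
    record: PatientRecord,
    config: CohortConfig,
    rng: Optional[np.random.Generator] = None,
) -> VisitSeries:
    """Simulate one patient's visit series from their class's change model.

    Post-baseline visits are missing with probability ``followup.dropout``;
    baseline is always present.
    """
    baseline = record.get("logmar_affected")
    if baseline is None:
        raise DomainError(f"patient {record.patient_id}: no baseline logMAR")
    rng = rng if rng is not None else _followup_rng(record, config)
    fu = config.followup
    label = record.true_cluster
    visits: list[tuple[int, Optional[float]]] = []
    for m in fu.months:
        if m == 0:
            visits.append((0, baseline))
            continue
        if rng.random() < fu.dropout:
            visits.append((m, None))
            continue
        if label in fu.change_mean:
            mu = fu.change_mean[label].get(m, 0.0)
        else:  # unlabeled record: pooled midpoint of the class means
            mus = [cm.get(m, 0.0) for cm in fu.change_mean.values()]
            mu = float(np.mean(mus)) if mus else 0.0
        visits.append((m, baseline + mu + fu.change_sd * rng.standard_normal()))
    return VisitSeries(record.patient_id, visits)


def simulate_followups(
    records: Sequence[PatientRecord], config: CohortConfig
) -> list[VisitSeries]:
    """Visit series for every record, each from its own deterministic stream."""
    return [simulate_followup(r, config) for r in records]


def config_to_dict(config: CohortConfig) -> dict:
    """YAML-ready plain-dict view of a config (every profile field addressable)."""
    d = asdict(config)
    for p in d["profiles"]:
        p["continuous_params"] = {k: list(v) for k, v in p["continuous_params"].items()}
    d["truncation_bounds"] = {k: list(v) for k, v in d["truncation_bounds"].items()}
    d["correlated_pairs"] = [list(p) for p in d["correlated_pairs"]]
    d["followup"]["months"] = list(d["followup"]["months"])
    return d


def config_from_dict(d: dict) -> CohortConfig:
    profiles = [
        ClusterProfile(
            label=p["label"],
            n=int(p["n"]),
            continuous_params={k: (float(v[0]), float(v[1])) for k, v in p["continuous_params"].items()},
            binary_prevalences={k: float(v) for k, v in p["binary_prevalences"].items()},
        )
        for p in d["profiles"]
    ]
    fu = d.get("followup", {})
    followup = FollowupConfig(
        months=tuple(fu.get("months", (0, 3, 12))),
        change_mean={
            str(k): {int(m): float(x) for m, x in v.items()}
            for k, v in fu.get("change_mean", FollowupConfig().change_mean).items()
        },
        change_sd=float(fu.get("change_sd", 0.20)),
        dropout=float(fu.get("dropout", 0.10)),
    )
    return CohortConfig(
        profiles=profiles,
        seed=int(d.get("seed", 0)),
        truncation_bounds={k: (float(v[0]), float(v[1])) for k, v in d.get("truncation_bounds", {}).items()},
        correlation_knob=float(d.get("correlation_knob", 0.0)),
        correlated_pairs=[tuple(p) for p in d.get("correlated_pairs", [])],
        followup=followup,
    )
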