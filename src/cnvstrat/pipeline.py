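"""End-to-end orchestration: filter -> cluster -> split -> score -> evaluate -> outcomes.

Every artifact written by :func:`run_pipeline` is re-derivable from the
configuration and its seeds alone; the run report deliberately contains no
timestamps so that identical configurations produce byte-identical reports.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from . import cluster_engine, cnv_score, outcome_model, phenotype_io, synthetic_cohort
from .errors import CnvStratError

__all__ = ["PipelineConfig", "run_pipeline", "default_pipeline_config"]

log = logging.getLogger("cnvstrat")


@dataclass
class PipelineConfig:
    cohort_csv: Optional[str] = None
    visits_csv: Optional[str] = None
    output_dir: str = "cnvstrat_run"
    simulate: bool = False
    seed_cohort: int = 0
    seed_split: int = 1
    seed_clustering: int = 2
    seed_reference_null: int = 3
    k_max: int = 10
    B: int = 100
    rule: str = "firstSEmax"
    n_restarts: int = 25
    gap_restarts: int = 10
    ratio: tuple[int, int] = (3, 1)
    decimals: Optional[int] = 2
    cutoffs: tuple[float, ...] = cnv_score.DEFAULT_CUTOFFS
    threshold: float = 0.0
    make_plots: bool = True

    def to_dict(self) -> dict:
        d = {**self.__dict__}
        d["ratio"] = list(self.ratio)
        d["cutoffs"] = list(self.cutoffs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "ratio" in d:
            d["ratio"] = tuple(d["ratio"])
        if "cutoffs" in d:
            d["cutoffs"] = tuple(d["cutoffs"])
        return cls(**d)


def default_pipeline_config() -> PipelineConfig:
    return PipelineConfig()


def _setup_logging(out: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s", "%Y-%m-%dT%H:%M:%S")
    for h in (logging.StreamHandler(sys.stderr), logging.FileHandler(out / "pipeline.log")):
        h.setFormatter(fmt)
        log.addHandler(h)


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, allow_nan=False) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the structured run report."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    schema = phenotype_io.default_schema()

    # --- load or simulate -------------------------------------------------
    if config.simulate:
        log.info("simulating cohort (seed=%d)", config.seed_cohort)
        cohort_cfg = synthetic_cohort.default_config(seed=config.seed_cohort)
        records = synthetic_cohort.simulate_cohort(cohort_cfg, schema)
        visits = synthetic_cohort.simulate_followups(records, cohort_cfg)
        phenotype_io.write_cohort(records, out / "cohort.csv", schema)
        phenotype_io.write_visits(visits, out / "visits.csv")
    else:
        if not config.cohort_csv or not Path(config.cohort_csv).exists():
            raise CnvStratError(f"cohort CSV not readable: {config.cohort_csv!r}")
        records = phenotype_io.read_cohort(config.cohort_csv, schema)
        visits = []
        if config.visits_csv:
            if not Path(config.visits_csv).exists():
                raise CnvStratError(f"visits CSV not readable: {config.visits_csv!r}")
            visits = phenotype_io.read_visits(config.visits_csv)
    log.info("loaded %d records, %d visit series", len(records), len(visits))

    # --- completeness filter ---------------------------------------------
    kept, excluded = phenotype_io.apply_completeness_filter(records, schema.names)
    log.info("completeness filter: kept %d, excluded %d", len(kept), len(excluded))
    if excluded:
        pd.DataFrame(
            [{"patient_id": r.patient_id, "reason": why} for r, why in excluded]
        ).to_csv(out / "excluded.csv", index=False)

    # --- clustering -------------------------------------------------------
    pca, gap, km, labeling = cluster_engine.cluster_cohort(
        kept,
        schema,
        seed=config.seed_clustering,
        k_max=config.k_max,
        B=config.B,
        rule=config.rule,  # type: ignore[arg-type]
        n_restarts=config.n_restarts,
        gap_restarts=config.gap_restarts,
    )
    log.info("gap statistic chose k=%d (rule=%s, B=%d)", gap.chosen_k, gap.rule, gap.B)
    gap.to_frame().to_csv(out / "gap_table.csv", index=False)
    if labeling is not None:
        labels = [labeling.labels[int(c)] for c in km.assignments]
    else:
        labels = [f"cluster_{int(c)}" for c in km.assignments]
    pd.DataFrame(
        {"patient_id": [r.patient_id for r in kept], "cluster": km.assignments, "label": labels}
    ).to_csv(out / "assignments.csv", index=False)

    report: dict = {
        "config": config.to_dict(),
        "n_records": len(records),
        "n_kept": len(kept),
        "n_excluded": len(excluded),
        "pca_rank": pca.rank,
        "chosen_k": gap.chosen_k,
        "gap_table": json.loads(gap.to_frame().to_json(orient="records")),
        "kmeans_inertia": km.inertia,
    }

    if config.make_plots:
        from . import plots

        plots.plot_gap_curve(gap, out / "gap_curve.png")
        plots.plot_pc_scatter(pca, labels, out / "pc_scatter.png")

    if labeling is None:
        log.warning("chosen k != 2; scoring and outcome stages skipped")
        _json_dump(report, out / "run_report.json")
        return report

    # --- cluster comparison ----------------------------------------------
    comparison = cluster_engine.compare_clusters(kept, labels, schema)
    comparison.to_csv(out / "cluster_comparison.csv", index=False)
    summary = (
        pd.DataFrame({"label": labels}).value_counts().rename("n").reset_index()
    )
    report["cluster_sizes"] = {
        row["label"]: int(row["n"]) for _, row in summary.iterrows()
    }

    # --- score derivation & validation ------------------------------------
    by_id = dict(zip([r.patient_id for r in kept], labels))
    training, validation = cnv_score.split_train_validation(
        kept, ratio=config.ratio, seed=config.seed_split
    )
    log.info("split: %d training / %d validation", len(training), len(validation))
    model = cnv_score.fit_logistic(training, [by_id[r.patient_id] for r in training])
    weights = cnv_score.weights_from_model(model, decimals=config.decimals)
    model.summary_frame().to_csv(out / "logistic_model.csv", index=False)
    _json_dump(
        {
            "intercept": weights.intercept,
            "terms": [
                {"name": n, "divisor": d, "weight": w} for n, d, w in weights.terms
            ],
        },
        out / "weights.json",
    )

    val_scores = cnv_score.score_cohort(validation, weights, threshold=config.threshold)
    val_scores.to_csv(out / "validation_scores.csv", index=False)
    val_labels = [by_id[r.patient_id] for r in validation]
    ev = cnv_score.evaluate(val_scores["score"], val_labels, threshold=config.threshold)
    bins = cnv_score.ppv_bins(val_scores["score"], val_labels, cutoffs=config.cutoffs)
    bins.to_frame().to_csv(out / "score_bins.csv", index=False)
    report["evaluation"] = {
        "threshold": ev.threshold,
        "accuracy": ev.accuracy,
        "sensitivity": ev.sensitivity,
        "specificity": ev.specificity,
        "auc": ev.auc,
        "confusion": ev.confusion,
    }
    log.info(
        "validation: accuracy=%.3f sens=%.3f spec=%.3f AUC=%.3f",
        ev.accuracy, ev.sensitivity, ev.specificity, ev.auc,
    )

    # --- outcome association ----------------------------------------------
    if visits:
        all_scores = cnv_score.score_cohort(kept, weights, threshold=config.threshold)
        covariates = pd.DataFrame(
            {
                "patient_id": [r.patient_id for r in kept],
                "score": all_scores["score"].to_numpy(),
                "age": [r.get("age") for r in kept],
                "sex": [r.get("sex") for r in kept],
            }
        ).set_index("patient_id")
        frames = outcome_model.outcome_table(visits, covariates, months=(3, 12))
        outcomes = {}
        for month, frame in frames.items():
            outcomes[str(month)] = {}
            for adjust in (False, True):
                res = outcome_model.fit_outcome_regression(frame, adjust=adjust)
                i = res.terms.index("score")
                outcomes[str(month)]["adjusted" if adjust else "unadjusted"] = {
                    "B": float(res.coefficients[i]),
                    "SE": float(res.standard_errors[i]),
                    "p": float(res.p_values[i]),
                    "n": res.n_obs,
                }
        report["outcomes"] = outcomes
        _json_dump(outcomes, out / "outcomes.json")

    _json_dump(report, out / "run_report.json")
    log.info("pipeline complete; artifacts in %s", out)
    return report
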