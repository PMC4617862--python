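"""End-to-end orchestration: data -> fit -> selection -> validation -> optima.

:func:`run_pipeline` executes the full analysis on either a patient CSV or a
synthetic cohort and writes every artifact (fit JSON, selection trace,
bootstrap table, VPC table/plot, ROC table/plot, per-patient optimal
concentrations, run log) into an output directory.  Stages run in order and
a failure aborts with a stage-tagged error; artifacts written before the
failure are retained.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as vio
from .errors import VpaPkPdError
from .optimal import DEFAULT_LOGIT_CUTOFF, invert_linear, invert_linear_parts, roc
from .pd_model import FINAL_MODEL_SPEC, FitResult, fit
from .selection import StepwiseCovariateSelector
from .synth import CohortConfig, generate_cohort
from .validation import bootstrap, vpc

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "predict_optimal_table"]


@dataclasses.dataclass
class PipelineConfig:
    """Settings for one end-to-end run."""

    input_csv: str | None = None  # mutually exclusive with synth
    synth: CohortConfig | None = None
    output_dir: str = "vpapkpd_out"
    seed: int = 0
    select_covariates: bool = False  # full stepwise search is slow; opt in
    n_bootstrap: int = 1000
    n_vpc: int = 1000
    n_roc_boot: int = 2000
    logit_cutoff: float | None = None  # None -> Youden from the data
    fit_n_starts: int = 3


class StageError(VpaPkPdError):
    def __init__(self, stage, exc):
        super().__init__(f"pipeline stage {stage!r} failed: {exc}")
        self.stage = stage


def predict_optimal_table(params, patients: pd.DataFrame, logit_cut: float) -> pd.DataFrame:
    """Per-patient optimal trough concentration table for a fitted linear model.

    ``params`` is either a :class:`PDParameters` (final-model shape) or any
    linear-form :class:`FitResult`.
    """
    per_patient = patients.groupby("patient_id", sort=True).first().reset_index()
    if isinstance(params, FitResult):
        A, S = params.intercept_slope_parts(per_patient)
        opts = [invert_linear_parts(a, s, logit_cut) for a, s in zip(A, S)]
    else:
        opts = [
            invert_linear(params, vio.covariates_from_row(row), logit_cut)
            for _, row in per_patient.iterrows()
        ]
    return pd.DataFrame(
        {
            "patient_id": per_patient["patient_id"],
            "age_years": per_patient["age_years"],
            "scn1a": per_patient["scn1a"],
            "seizure_locus": per_patient["seizure_locus"],
            "optimal_conc": [np.nan if o.value is None else o.value for o in opts],
            "status": [o.status for o in opts],
        }
    )


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; return a dict of artifact paths and headline numbers."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    artifacts: dict[str, str] = {}
    rng_seed = int(config.seed)

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s ...", name)

            def __exit__(self, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self.t0
                if exc is not None:
                    raise StageError(name, exc) from exc

        return _Timer()

    with stage("data"):
        if config.input_csv is not None:
            data = vio.read_patient_table(config.input_csv)
        else:
            synth_cfg = config.synth or CohortConfig(seed=rng_seed)
            data = generate_cohort(synth_cfg, seed=rng_seed)
        vio.write_patient_table(data, out / "dataset.csv")
        artifacts["dataset"] = str(out / "dataset.csv")

    with stage("fit"):
        if config.select_covariates:
            selector = StepwiseCovariateSelector(random_state=rng_seed)
            selector.fit(data)
            final = selector.final_result_
            selector.trace_.to_csv(out / "selection_trace.csv", index=False)
            artifacts["selection_trace"] = str(out / "selection_trace.csv")
        else:
            final = fit(data, FINAL_MODEL_SPEC, n_starts=config.fit_n_starts,
                        random_state=rng_seed)
        vio.fit_result_to_json(final, out / "fit.json")
        artifacts["fit"] = str(out / "fit.json")

    with stage("bootstrap"):
        boot = bootstrap(
            data,
            n_reps=config.n_bootstrap,
            seed=rng_seed + 1,
            point_fit=final,
        )
        boot.replicates.to_csv(out / "bootstrap_replicates.csv", index=False)
        boot.summary.to_csv(out / "bootstrap_summary.csv", index=False)
        artifacts["bootstrap"] = str(out / "bootstrap_summary.csv")

    with stage("vpc"):
        vpc_res = vpc(data, final, n_sim=config.n_vpc, seed=rng_seed + 2)
        vpc_res.table.to_csv(out / "vpc.csv", index=False)
        vpc_res.plot(out / "vpc.png")
        artifacts["vpc"] = str(out / "vpc.csv")

    with stage("roc"):
        logits = final.population_logit(data)
        roc_res = roc(logits, data["responder"].to_numpy(), n_boot=config.n_roc_boot,
                      seed=rng_seed + 3)
        pd.DataFrame(
            {
                "threshold": roc_res.thresholds,
                "sensitivity": roc_res.sensitivity,
                "specificity": roc_res.specificity,
            }
        ).to_csv(out / "roc.csv", index=False)
        _plot_roc(roc_res, out / "roc.png")
        artifacts["roc"] = str(out / "roc.csv")

    with stage("optimal"):
        cutoff = roc_res.youden_cutoff if config.logit_cutoff is None else config.logit_cutoff
        table = predict_optimal_table(final, data, cutoff)
        table.to_csv(out / "optimal_concentrations.csv", index=False)
        artifacts["optimal"] = str(out / "optimal_concentrations.csv")

    run_log = {
        "seed": rng_seed,
        "config_hash": _config_hash(config),
        "timings_s": timings,
        "objective": final.objective,
        "converged": final.converged,
        "auc": roc_res.auc,
        "auc_ci": list(roc_res.auc_ci),
        "youden_cutoff": roc_res.youden_cutoff,
        "logit_cutoff_used": cutoff,
        "bootstrap_successful": boot.n_successful,
        "bootstrap_requested": boot.n_requested,
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2)
    artifacts["run_log"] = str(out / "run_log.json")
    return {"artifacts": artifacts, **run_log}


def _plot_roc(roc_res, path):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    fpr = 1.0 - roc_res.specificity
    order = np.argsort(fpr)
    ax.plot(fpr[order], roc_res.sensitivity[order], "-", color="black",
            label=f"AUC = {roc_res.auc:.3f}")
    ax.plot([0, 1], [0, 1], ":", color="grey")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(frameon=False)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
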