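"""Model validation: stratified nonparametric bootstrap and visual predictive check.

The bootstrap resamples *subjects* with replacement, stratified so each
replicate preserves the per-stratum subject counts (strata default to SCN1A
genotype x seizure locus, the final model's categorical covariates), refits
the model on every replicate and summarises the successful fits by medians
and 2.5/97.5 percentiles.  A replicate counts as a successful minimisation
when the optimiser converged and the curvature at the optimum is positive
definite (all standard errors finite).

The visual predictive check simulates the responder outcome ``n_sim`` times
at the original design points (covariates and predicted concentrations),
redrawing one random effect per subject per replicate, and compares the
observed responder proportion per concentration bin with the simulated
2.5/50/97.5 percentile band.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import InvalidInputError, NumericalError
from .pd_model import FitResult, MixedEffectsLogit, fit

log = logging.getLogger(__name__)

__all__ = ["BootstrapResult", "VPCResult", "bootstrap", "vpc", "DEFAULT_STRATA"]

DEFAULT_STRATA = ("scn1a", "seizure_locus")


@dataclass
class BootstrapResult:
    """Bootstrap parameter-precision summary."""

    n_requested: int
    n_successful: int
    summary: pd.DataFrame  # parameter, median, ci_lower, ci_upper
    replicates: pd.DataFrame  # one row per successful replicate

    def ci(self, parameter: str) -> tuple[float, float]:
        row = self.summary.set_index("parameter").loc[parameter]
        return float(row["ci_lower"]), float(row["ci_upper"])


def _strata_labels(df: pd.DataFrame, strata) -> pd.Series:
    per_subject = df.groupby("patient_id", sort=True).first()
    cols = [c for c in strata if c in per_subject.columns]
    if not cols:
        return pd.Series("all", index=per_subject.index)
    return per_subject[cols].astype(str).agg("|".join, axis=1)


def _resample_subjects(df: pd.DataFrame, labels: pd.Series, rng) -> pd.DataFrame:
    """Draw subjects with replacement within each stratum; relabel ids so
    repeated draws of one subject stay distinct subjects."""
    groups = {pid: sub for pid, sub in df.groupby("patient_id", sort=True)}
    parts = []
    k = 0
    for stratum in sorted(labels.unique()):
        ids = labels.index[labels == stratum].to_numpy()
        draw = rng.choice(ids, size=len(ids), replace=True)
        for pid in draw:
            sub = groups[pid].copy()
            sub["patient_id"] = f"b{k}"
            k += 1
            parts.append(sub)
    return pd.concat(parts, ignore_index=True)


def bootstrap(
    dataset: pd.DataFrame,
    model_spec=None,
    n_reps: int = 1000,
    seed: int = 0,
    strata=DEFAULT_STRATA,
    point_fit: FitResult | None = None,
    identity_resample: bool = False,
    **fit_kwargs,
) -> BootstrapResult:
    """Stratified nonparametric bootstrap of the model parameters.

    Parameters
    ----------
    dataset : patient table (one row per visit).
    model_spec : ModelSpec; defaults to ``point_fit.spec`` when given.
    n_reps : number of replicates requested.
    strata : per-subject columns defining resampling strata.
    point_fit : optional original-data fit used to warm-start replicates.
    identity_resample : debugging hook — use the original subjects verbatim.
    """
    if n_reps < 1:
        raise InvalidInputError("n_reps must be >= 1")
    if point_fit is None:
        point_fit = fit(dataset, model_spec, **fit_kwargs)
    spec = point_fit.spec
    rng = np.random.default_rng(seed)
    labels = _strata_labels(dataset, strata)
    rows = []
    n_success = 0
    for rep in range(n_reps):
        sample = (
            dataset
            if identity_resample
            else _resample_subjects(dataset, labels, rng)
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                rep_fit = fit(
                    sample,
                    spec,
                    start=point_fit.estimates,
                    n_starts=1,
                    **fit_kwargs,
                )
        except (NumericalError, InvalidInputError) as exc:
            log.warning("bootstrap replicate %d failed: %s", rep, exc)
            continue
        if not (rep_fit.converged and rep_fit.se_finite()):
            continue
        n_success += 1
        rows.append({"replicate": rep, "objective": rep_fit.objective, **rep_fit.estimates})
    if n_success == 0:
        raise NumericalError(
            f"all {n_reps} bootstrap replicates failed to minimise successfully"
        )
    reps = pd.DataFrame(rows)
    params = [c for c in reps.columns if c not in ("replicate", "objective")]
    summary = pd.DataFrame(
        {
            "parameter": params,
            "median": [reps[p].median() for p in params],
            "ci_lower": [reps[p].quantile(0.025) for p in params],
            "ci_upper": [reps[p].quantile(0.975) for p in params],
        }
    )
    return BootstrapResult(n_reps, n_success, summary, reps)


@dataclass
class VPCResult:
    """Visual-predictive-check table: observed vs simulated responder proportions."""

    table: pd.DataFrame  # bin, conc_mid, n, observed, sim_lower, sim_median, sim_upper
    n_sim: int
    strata: tuple = ()

    def plot(self, path=None, ax=None):
        """Render the check: observed proportion over the simulated 95% band."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        t = self.table
        ax.fill_between(
            t["conc_mid"], t["sim_lower"], t["sim_upper"],
            alpha=0.3, color="tab:blue", label="simulated 95% PI",
        )
        ax.plot(t["conc_mid"], t["sim_median"], "--", color="tab:blue", label="simulated median")
        ax.plot(t["conc_mid"], t["observed"], "o-", color="black", label="observed")
        ax.set_xlabel("predicted trough VPA concentration (μg/ml)")
        ax.set_ylabel("proportion with >50% seizure reduction")
        ax.set_ylim(-0.02, 1.02)
        ax.legend(frameon=False, fontsize=8)
        if path is not None:
            ax.figure.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(ax.figure)
        return ax


def vpc(
    dataset: pd.DataFrame,
    fitted: FitResult,
    n_sim: int = 1000,
    bins: int = 10,
    seed: int = 0,
) -> VPCResult:
    """Simulate the responder outcome at the original design points.

    ``bins`` is either a count (quantile bins of predicted concentration,
    deciles by default) or an explicit array of bin edges.
    """
    if not fitted.converged:
        raise InvalidInputError("fitted model must have converged")
    if n_sim < 100:
        raise InvalidInputError("n_sim must be >= 100")
    est = MixedEffectsLogit(
        intercept_covariates=fitted.spec.intercept_covariates,
        slope_covariates=fitted.spec.slope_covariates,
        form=fitted.spec.form,
    )
    est.result_ = fitted
    base_logit = est.predict_logit(dataset)

    conc = dataset["conc"].to_numpy(float)
    y = dataset["responder"].to_numpy(float)
    ids, subj = np.unique(dataset["patient_id"].to_numpy(), return_inverse=True)
    m = len(ids)
    omega = float(np.sqrt(fitted.estimates["omega2"]))

    if np.isscalar(bins):
        qs = np.linspace(0, 1, int(bins) + 1)
        edges = np.unique(np.quantile(conc, qs))
    else:
        edges = np.asarray(bins, float)
    idx = np.clip(np.digitize(conc, edges[1:-1]), 0, len(edges) - 2)

    rng = np.random.default_rng(seed)
    n_bins = len(edges) - 1
    counts = np.bincount(idx, minlength=n_bins)
    keep = counts > 0
    if not keep.all():
        warnings.warn("empty concentration bin(s) dropped", RuntimeWarning)

    sims = np.empty((n_sim, n_bins))
    for s in range(n_sim):
        eta = rng.normal(0.0, omega, size=m)
        p = expit(base_logit + eta[subj])
        ysim = rng.random(len(p)) < p
        sims[s] = np.bincount(idx, weights=ysim, minlength=n_bins) / np.maximum(counts, 1)

    obs = np.bincount(idx, weights=y, minlength=n_bins) / np.maximum(counts, 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    lo, med, hi = np.percentile(sims, [2.5, 50.0, 97.5], axis=0)
    table = pd.DataFrame(
        {
            "bin": np.arange(n_bins),
            "conc_mid": mids,
            "n": counts,
            "observed": obs,
            "sim_lower": lo,
            "sim_median": med,
            "sim_upper": hi,
        }
    )[keep]
    return VPCResult(table.reset_index(drop=True), n_sim)
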