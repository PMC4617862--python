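"""ROC analysis, Youden cut-off, and inversion to the optimal trough concentration.

The fitted model's population logits (eta = 0) are scored against the
observed responder outcomes with a ROC curve whose AUC is the pairwise
concordance probability (ties count one half — the Mann–Whitney estimator),
with a stratified-bootstrap 95% CI.  The Youden index J = sensitivity +
specificity - 1 picks the operating logit cut-off; the fitted model is then
inverted in closed form at eta = 0 to the concentration at which each
patient's logit equals the cut-off — that patient's optimal trough
concentration.

For the linear model with covariate-adjusted intercept A and slope S (per
100 μg/ml), the inversion is ``conc = 100 * (A - cut) / (-S)`` when S < 0.
A patient whose logit never crosses the cut-off from above is flagged
``any_concentration`` (always above) or ``unattainable`` (always below).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .domain import PatientCovariates
from .errors import InvalidInputError
from .pd_model import PDParameters, QuadraticPDParameters, CONC_SCALE

__all__ = [
    "ROCResult",
    "OptimalConcentration",
    "roc",
    "youden_cutoff",
    "invert_linear",
    "invert_linear_parts",
    "invert_quadratic",
    "DEFAULT_LOGIT_CUTOFF",
]

#: Published operating cut-off on the logit scale.
DEFAULT_LOGIT_CUTOFF = 0.1


@dataclass
class ROCResult:
    """ROC curve, Mann–Whitney AUC with bootstrap CI, and Youden operating point."""

    thresholds: np.ndarray  # candidate cut-offs, ascending
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci: tuple
    youden_cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float


def _auc_mann_whitney(scores: np.ndarray, outcomes: np.ndarray) -> float:
    """Concordance probability: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = outcomes == 1
    n1 = int(pos.sum())
    n0 = len(outcomes) - n1
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _sens_spec(scores, outcomes, thresholds):
    """Sensitivity/specificity for 'positive iff score >= threshold'."""
    pos = outcomes == 1
    sens = np.array([(scores[pos] >= t).mean() for t in thresholds])
    spec = np.array([(scores[~pos] < t).mean() for t in thresholds])
    return sens, spec


def roc(
    logits,
    outcomes,
    n_boot: int = 2000,
    seed: int = 0,
    compute_ci: bool = True,
) -> ROCResult:
    """ROC analysis of model logits against observed binary response.

    Thresholds are the distinct observed logits; a record is classified
    positive when its logit is at or above the threshold.  The AUC CI is a
    percentile bootstrap stratified by outcome (``n_boot`` resamples).
    """
    scores = np.asarray(logits, float)
    y = np.asarray(outcomes)
    if scores.shape != y.shape or scores.ndim != 1:
        raise InvalidInputError("logits and outcomes must be 1-d arrays of equal length")
    if not np.isin(y, (0, 1)).all():
        raise InvalidInputError("outcomes must be 0/1")
    if len(np.unique(y)) < 2:
        raise InvalidInputError("ROC undefined: both outcome classes must be present")

    thresholds = np.unique(scores)
    sens, spec = _sens_spec(scores, y, thresholds)
    auc = _auc_mann_whitney(scores, y)

    ci = (float("nan"), float("nan"))
    if compute_ci:
        rng = np.random.default_rng(seed)
        pos_idx = np.flatnonzero(y == 1)
        neg_idx = np.flatnonzero(y == 0)
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            pi = rng.choice(pos_idx, size=len(pos_idx), replace=True)
            ni = rng.choice(neg_idx, size=len(neg_idx), replace=True)
            s = np.concatenate([scores[pi], scores[ni]])
            yy = np.concatenate([np.ones(len(pi)), np.zeros(len(ni))])
            aucs[b] = _auc_mann_whitney(s, yy)
        ci = tuple(np.percentile(aucs, [2.5, 97.5]))

    j = sens + spec - 1.0
    best = np.flatnonzero(j == j.max())[0]  # ties -> smallest threshold
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        auc_ci=ci,
        youden_cutoff=float(thresholds[best]),
        sens_at_cutoff=float(sens[best]),
        spec_at_cutoff=float(spec[best]),
    )


def youden_cutoff(result: ROCResult) -> float:
    """Threshold maximising J = sensitivity + specificity - 1.

    Exhaustive scan over the candidate thresholds; ties resolve to the
    smallest threshold (the lower required concentration).
    """
    j = result.sensitivity + result.specificity - 1.0
    best = np.flatnonzero(j == j.max())[0]
    return float(result.thresholds[best])


@dataclass(frozen=True)
class OptimalConcentration:
    """Per-patient optimal trough concentration, or why none exists.

    status:
      - ``attainable``: the logit crosses the cut-off at ``value`` μg/ml.
      - ``any_concentration``: the logit is at or above the cut-off at every
        nonnegative concentration (including zero).
      - ``unattainable``: the cut-off is never reached.
    """

    value: float | None
    status: str

    def __post_init__(self):
        if self.status not in ("attainable", "any_concentration", "unattainable"):
            raise InvalidInputError(f"bad status {self.status!r}")
        if self.status == "attainable" and not (self.value is not None and self.value > 0):
            raise InvalidInputError("attainable requires a positive value")


def invert_linear(
    p: PDParameters, cov: PatientCovariates, logit_cut: float = DEFAULT_LOGIT_CUTOFF
) -> OptimalConcentration:
    """Concentration at which the population logit equals ``logit_cut``.

    With A the covariate-adjusted intercept and S the adjusted slope (per
    100 μg/ml) at eta = 0: a negative S (response probability falls with
    exposure) yields ``100 * (A - cut) / (-S)``; a positive S yields the
    rising crossing ``100 * (cut - A) / S`` when A starts below the cut-off.
    """
    return invert_linear_parts(p.intercept_part(cov), p.slope_part(cov), logit_cut)


def invert_linear_parts(
    a: float, s: float, logit_cut: float = DEFAULT_LOGIT_CUTOFF
) -> OptimalConcentration:
    """Inversion from an already-computed intercept part A and slope part S."""
    if s < 0:
        value = CONC_SCALE * (a - logit_cut) / (-s)
        if value > 0:
            return OptimalConcentration(value, "attainable")
        return OptimalConcentration(None, "unattainable")
    if a >= logit_cut:
        return OptimalConcentration(None, "any_concentration")
    if s == 0:
        return OptimalConcentration(None, "unattainable")
    return OptimalConcentration(CONC_SCALE * (logit_cut - a) / s, "attainable")


def invert_quadratic(
    p: QuadraticPDParameters, logit_cut: float = DEFAULT_LOGIT_CUTOFF
) -> OptimalConcentration:
    """Smallest positive concentration solving the quadratic logit = cut at eta = 0."""
    if p.theta3 == 0:
        if p.theta1 >= logit_cut:
            return OptimalConcentration(None, "any_concentration")
        return OptimalConcentration(None, "unattainable")
    disc = (logit_cut - p.theta1) / p.theta3
    if disc < 0:
        return OptimalConcentration(None, "unattainable")
    r = np.sqrt(disc)
    roots = [p.theta2 - r, p.theta2 + r]
    positive = [x for x in roots if x > 0]
    if not positive:
        return OptimalConcentration(None, "unattainable")
    return OptimalConcentration(CONC_SCALE * min(positive), "attainable")
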