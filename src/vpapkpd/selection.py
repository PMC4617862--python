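"""Forward-inclusion / backward-elimination covariate search.

Each candidate covariate is tested on the intercept or the slope by the
change it induces in the objective function (-2 log marginal likelihood)
relative to the current model.  Changes of at least 3.84 (chi-square,
P < 0.05, df = 1) or 5.99 (df = 2, the genotype indicator pair) count as
significant; ties at exactly the threshold are significant.

Forward step: every candidate is tested one at a time against the base
model; all individually significant candidates are then incorporated
jointly into the full model.  Backward step: from the full model, each
retained covariate is removed one at a time; the least significant covariate
whose removal costs less than its threshold is dropped, and the step
iterates until every remaining covariate is significant.

Candidate order is fixed (the canonical screening order below) so a run is
deterministic for a given dataset and seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import chi2
from sklearn.base import BaseEstimator

from .errors import InvalidInputError, NumericalError
from .pd_model import BASE_MODEL_SPEC, FitResult, ModelSpec, fit, objective_difference

log = logging.getLogger(__name__)

__all__ = [
    "CandidateCovariate",
    "SelectionTrace",
    "DEFAULT_CANDIDATES",
    "chi2_threshold",
    "forward_search",
    "backward_search",
    "StepwiseCovariateSelector",
]

#: Canonical candidate screening order (covariate name as understood by
#: :class:`~vpapkpd.pd_model.ModelSpec`).
CANDIDATE_ORDER = (
    "female",
    "age",
    "partial",
    "symptomatic",
    "intellectual_disability",
    "CBZ",
    "CZP",
    "CLB",
    "GBP",
    "LTG",
    "PB",
    "PHT",
    "TPM",
    "ZNS",
    "scn1a",
)


@dataclass(frozen=True)
class CandidateCovariate:
    """One candidate effect: a covariate tested on the intercept or the slope."""

    name: str
    target: str  # "intercept" | "slope"

    def __post_init__(self):
        if self.name not in CANDIDATE_ORDER:
            raise InvalidInputError(f"unknown candidate covariate {self.name!r}")
        if self.target not in ("intercept", "slope"):
            raise InvalidInputError(f"target must be 'intercept' or 'slope', got {self.target!r}")

    @property
    def df(self) -> int:
        """Degrees of freedom: 2 for the genotype indicator pair, else 1."""
        return 2 if self.name == "scn1a" else 1


#: All candidates in canonical order, intercept effects before slope effects.
DEFAULT_CANDIDATES = tuple(
    CandidateCovariate(name, target)
    for target in ("intercept", "slope")
    for name in CANDIDATE_ORDER
)


def chi2_threshold(df: int) -> float:
    """95th percentile of chi-square with ``df`` degrees of freedom (3.84 / 5.99)."""
    if df not in (1, 2):
        raise InvalidInputError(f"df must be 1 or 2, got {df}")
    return float(chi2.ppf(0.95, df))


@dataclass
class TraceRow:
    step: str  # "forward" | "backward"
    covariate: str
    target: str
    delta_of: float
    threshold: float
    accepted: bool
    converged: bool = True


@dataclass
class SelectionTrace:
    """Ordered record of every candidate test made during a search."""

    rows: list = field(default_factory=list)

    def append(self, row: TraceRow):
        self.rows.append(row)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step": r.step,
                    "covariate": r.covariate,
                    "target": r.target,
                    "delta_of": r.delta_of,
                    "threshold": r.threshold,
                    "significant": "yes" if r.accepted else "no",
                    "converged": r.converged,
                }
                for r in self.rows
            ]
        )


def _try_fit(dataset, spec, fit_kwargs) -> FitResult | None:
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return fit(dataset, spec, **fit_kwargs)
    except (NumericalError, InvalidInputError) as exc:
        log.warning("candidate fit failed: %s", exc)
        return None


def forward_search(
    base: FitResult,
    candidates,
    dataset: pd.DataFrame,
    trace: SelectionTrace | None = None,
    **fit_kwargs,
):
    """Test each candidate against the base model; build and fit the full model.

    Returns ``(full_fit, trace)``.  Candidates whose single-addition fit does
    not converge are recorded and treated as not significant.
    """
    if not base.converged:
        raise InvalidInputError("base fit must have converged")
    trace = trace if trace is not None else SelectionTrace()
    accepted = []
    for cand in candidates:
        spec = base.spec.with_covariate(cand.name, cand.target)
        cand_fit = _try_fit(dataset, spec, fit_kwargs)
        thr = chi2_threshold(cand.df)
        if cand_fit is None or not cand_fit.converged:
            trace.append(
                TraceRow("forward", cand.name, cand.target, float("nan"), thr, False, False)
            )
            warnings.warn(
                f"forward fit for {cand.name} on {cand.target} did not converge; "
                "treated as not significant",
                RuntimeWarning,
            )
            continue
        delta = objective_difference(base, cand_fit)
        trace.append(TraceRow("forward", cand.name, cand.target, delta, thr, delta >= thr))
        if delta >= thr:
            accepted.append(cand)
    full_spec = base.spec
    for cand in accepted:
        full_spec = full_spec.with_covariate(cand.name, cand.target)
    if full_spec == base.spec:
        return base, trace
    full_fit = _try_fit(dataset, full_spec, fit_kwargs)
    if full_fit is None:
        raise NumericalError("joint full-model fit failed")
    return full_fit, trace


def backward_search(
    full: FitResult,
    dataset: pd.DataFrame,
    trace: SelectionTrace | None = None,
    **fit_kwargs,
):
    """Iteratively drop the least significant covariate from the full model.

    Returns ``(final_fit, trace)``.
    """
    if not full.converged:
        raise InvalidInputError("full fit must have converged")
    trace = trace if trace is not None else SelectionTrace()
    current = full

    def members(spec: ModelSpec):
        out = [CandidateCovariate(n, "intercept") for n in spec.intercept_covariates]
        out += [CandidateCovariate(n, "slope") for n in spec.slope_covariates]
        return out

    while True:
        tested = []
        for cand in members(current.spec):
            spec = current.spec.without_covariate(cand.name, cand.target)
            red_fit = _try_fit(dataset, spec, fit_kwargs)
            thr = chi2_threshold(cand.df)
            if red_fit is None or not red_fit.converged:
                trace.append(
                    TraceRow("backward", cand.name, cand.target, float("nan"), thr, True, False)
                )
                warnings.warn(
                    f"backward fit without {cand.name} on {cand.target} did not converge; "
                    "covariate retained",
                    RuntimeWarning,
                )
                continue
            delta = objective_difference(red_fit, current)
            keep = delta >= thr
            trace.append(TraceRow("backward", cand.name, cand.target, delta, thr, keep))
            tested.append((delta - thr, cand, red_fit))
        removable = [t for t in tested if t[0] < 0]
        if not removable:
            return current, trace
        # drop the covariate furthest below its threshold, refit, iterate
        _, worst, red_fit = min(removable, key=lambda t: t[0])
        log.info("backward: removing %s on %s", worst.name, worst.target)
        current = red_fit


class StepwiseCovariateSelector(BaseEstimator):
    """Full stepwise covariate search as a scikit-learn-style meta-estimator.

    Fits the base (covariate-free) model, runs the forward pass over
    ``candidates``, refits the joint full model, then runs backward
    elimination.

    Attributes (after ``fit``)
    --------------------------
    base_result_, full_result_, final_result_ : FitResult
    trace_ : pandas.DataFrame of every candidate test
    final_spec_ : ModelSpec
    """

    def __init__(self, candidates=DEFAULT_CANDIDATES, n_starts=2, random_state=0, **fit_options):
        self.candidates = candidates
        self.n_starts = n_starts
        self.random_state = random_state
        self.fit_options = fit_options

    def fit(self, X: pd.DataFrame, y=None):
        fit_kwargs = dict(
            n_starts=self.n_starts, random_state=self.random_state, compute_se=False,
            **self.fit_options,
        )
        base = fit(X, BASE_MODEL_SPEC, **fit_kwargs)
        trace = SelectionTrace()
        full, trace = forward_search(base, self.candidates, X, trace, **fit_kwargs)
        final, trace = backward_search(full, X, trace, **fit_kwargs)
        # refit the winner with standard errors
        final = fit(
            X,
            final.spec,
            start=final.estimates,
            n_starts=1,
            random_state=self.random_state,
            **self.fit_options,
        )
        self.base_result_ = base
        self.full_result_ = full
        self.final_result_ = final
        self.final_spec_ = final.spec
        self.trace_ = trace.to_frame()
        return self
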