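"""Mixed-effects logistic exposure-response model for seizure-frequency reduction.

The probability that a visit shows an over-50% reduction in seizure frequency
relative to the pre-treatment baseline is modelled on the logit scale as a
linear function of the predicted steady-state valproic-acid trough
concentration:

    logit(Pr_ij) = A_i + S_i * (C_i / 100) + eta_i
    A_i = intercept + sum_k beta_k^A * x_ik      (intercept covariates)
    S_i = slope     + sum_k beta_k^S * x_ik      (slope covariates)
    eta_i ~ Normal(0, omega^2)                   (one per subject)

with C_i the concentration in μg/ml (the slope therefore acts per
100 μg/ml) and repeated visits j of subject i sharing the single random
effect eta_i.  An alternative form replaces the linear predictor in C by a
quadratic ``theta1 + (C/100 - theta2)**2 * theta3``.

Estimation maximises the marginal likelihood, integrating eta out per
subject either by a Laplace approximation around the posterior mode (the
default, matching standard NONMEM-style Laplacian estimation) or by
adaptive-free Gauss–Hermite quadrature (>= 64 nodes), which is slower and
serves as the numerical reference.  The reported objective function is
-2 * log marginal likelihood including all normalising constants; only
differences between nested fits are interpreted.

:class:`MixedEffectsLogit` is a scikit-learn-style estimator
(``fit`` / ``predict_proba`` / ``get_params``); :func:`fit` is the thin
functional wrapper returning a :class:`FitResult`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from sklearn.base import BaseEstimator

from .domain import COMEDS, PatientCovariates, ResponseRecord
from .errors import InvalidComparisonError, InvalidInputError, NumericalError

__all__ = [
    "PDParameters",
    "QuadraticPDParameters",
    "ModelSpec",
    "FINAL_MODEL_SPEC",
    "BASE_MODEL_SPEC",
    "FitResult",
    "MixedEffectsLogit",
    "inv_logit",
    "linear_logit",
    "quadratic_logit",
    "subject_marginal_loglik",
    "fit",
    "objective_difference",
    "variance_reduction_percent",
]

#: Concentration unit of the slope coefficients: μg/ml per slope unit.
CONC_SCALE = 100.0


def inv_logit(x):
    """Inverse logit e**x / (1 + e**x), numerically stable for large |x|."""
    return expit(x)


@dataclass(frozen=True)
class PDParameters:
    """Fixed effects and random-effect variance of the final linear model.

    Intercept-side coefficients are in logit units (``beta_age`` per year);
    slope-side coefficients are in logit per 100 μg/ml.  ``omega2`` is the
    variance of the per-subject random effect eta (logit^2 units).
    """

    intercept: float
    beta_age: float = 0.0
    beta_cbz_i: float = 0.0
    beta_czp_i: float = 0.0
    beta_ga_i: float = 0.0
    beta_aa_i: float = 0.0
    slope: float = 0.0
    beta_partial_s: float = 0.0
    beta_pht_s: float = 0.0
    beta_tpm_s: float = 0.0
    beta_ga_s: float = 0.0
    beta_aa_s: float = 0.0
    omega2: float = 0.0

    def __post_init__(self):
        if self.omega2 < 0:
            raise InvalidInputError(f"omega2 must be nonnegative, got {self.omega2}")
        for f in self.__dataclass_fields__:
            if not np.isfinite(getattr(self, f)):
                raise InvalidInputError(f"{f} must be finite")

    def intercept_part(self, cov: PatientCovariates) -> float:
        """A(cov): covariate-adjusted intercept in logit units."""
        return (
            self.intercept
            + self.beta_age * cov.age
            + self.beta_cbz_i * cov.has("CBZ")
            + self.beta_czp_i * cov.has("CZP")
            + self.beta_ga_i * (cov.scn1a == "GA")
            + self.beta_aa_i * (cov.scn1a == "AA")
        )

    def slope_part(self, cov: PatientCovariates) -> float:
        """S(cov): covariate-adjusted slope in logit per 100 μg/ml."""
        return (
            self.slope
            + self.beta_partial_s * (cov.seizure_locus == "partial")
            + self.beta_pht_s * cov.has("PHT")
            + self.beta_tpm_s * cov.has("TPM")
            + self.beta_ga_s * (cov.scn1a == "GA")
            + self.beta_aa_s * (cov.scn1a == "AA")
        )


@dataclass(frozen=True)
class QuadraticPDParameters:
    """Parameters of the quadratic (vertex-form) alternative model."""

    theta1: float  # logit at the vertex
    theta2: float  # vertex location, in units of 100 μg/ml
    theta3: float  # curvature, logit per (100 μg/ml)^2
    omega2: float = 0.0

    def __post_init__(self):
        if self.omega2 < 0:
            raise InvalidInputError(f"omega2 must be nonnegative, got {self.omega2}")


def linear_logit(p: PDParameters, cov: PatientCovariates, conc: float, eta: float = 0.0) -> float:
    """Linear-model logit A(cov) + S(cov) * conc/100 + eta.  ``conc`` in μg/ml."""
    if conc < 0:
        raise InvalidInputError(f"conc must be nonnegative, got {conc}")
    return p.intercept_part(cov) + p.slope_part(cov) * (conc / CONC_SCALE) + eta


def quadratic_logit(p: QuadraticPDParameters, conc: float, eta: float = 0.0) -> float:
    """Quadratic-model logit theta1 + (conc/100 - theta2)**2 * theta3 + eta."""
    if conc < 0:
        raise InvalidInputError(f"conc must be nonnegative, got {conc}")
    return p.theta1 + (conc / CONC_SCALE - p.theta2) ** 2 * p.theta3 + eta


# ---------------------------------------------------------------------------
# Model specification and design construction
# ---------------------------------------------------------------------------

#: Covariate names accepted on the intercept or the slope.  ``scn1a`` expands
#: to the G/A and A/A indicators (G/G reference) and counts 2 df in selection.
COVARIATE_NAMES = (
    "age",
    "female",
    "partial",
    "symptomatic",
    "intellectual_disability",
    *COMEDS,
    "scn1a",
)


@dataclass(frozen=True)
class ModelSpec:
    """Which covariates enter the intercept and the slope, and the model form."""

    intercept_covariates: tuple = ()
    slope_covariates: tuple = ()
    form: str = "linear"

    def __post_init__(self):
        object.__setattr__(self, "intercept_covariates", tuple(self.intercept_covariates))
        object.__setattr__(self, "slope_covariates", tuple(self.slope_covariates))
        if self.form not in ("linear", "quadratic"):
            raise InvalidInputError(f"form must be 'linear' or 'quadratic', got {self.form!r}")
        if self.form == "quadratic" and (self.intercept_covariates or self.slope_covariates):
            raise InvalidInputError("the quadratic form takes no covariates")
        for name in (*self.intercept_covariates, *self.slope_covariates):
            if name not in COVARIATE_NAMES:
                raise InvalidInputError(f"unknown covariate {name!r}")
        for where in ("intercept_covariates", "slope_covariates"):
            vals = getattr(self, where)
            if len(set(vals)) != len(vals):
                raise InvalidInputError(f"duplicate covariate in {where}")

    def with_covariate(self, name: str, target: str) -> "ModelSpec":
        key = "intercept_covariates" if target == "intercept" else "slope_covariates"
        return replace(self, **{key: (*getattr(self, key), name)})

    def without_covariate(self, name: str, target: str) -> "ModelSpec":
        key = "intercept_covariates" if target == "intercept" else "slope_covariates"
        vals = tuple(v for v in getattr(self, key) if v != name)
        return replace(self, **{key: vals})


BASE_MODEL_SPEC = ModelSpec()

#: Final covariate model: age, CBZ, CZP and genotype on the intercept;
#: seizure locus, PHT, TPM and genotype on the slope.
FINAL_MODEL_SPEC = ModelSpec(
    intercept_covariates=("age", "CBZ", "CZP", "scn1a"),
    slope_covariates=("partial", "PHT", "TPM", "scn1a"),
)


def _covariate_columns(df: pd.DataFrame, name: str):
    """Expand one covariate name to (n, k) design columns and their labels."""
    if name == "age":
        return df["age_years"].to_numpy(float)[:, None], ["age"]
    if name == "female":
        return df["female"].to_numpy(float)[:, None], ["female"]
    if name == "partial":
        return (df["seizure_locus"] == "partial").to_numpy(float)[:, None], ["partial"]
    if name == "symptomatic":
        return (df["seizure_type"] == "symptomatic").to_numpy(float)[:, None], ["symptomatic"]
    if name == "intellectual_disability":
        col = df["intellectual_disability"].to_numpy(float)[:, None]
        return col, ["intellectual_disability"]
    if name in COMEDS:
        return df[name].to_numpy(float)[:, None], [name]
    if name == "scn1a":
        ga = (df["scn1a"] == "GA").to_numpy(float)
        aa = (df["scn1a"] == "AA").to_numpy(float)
        return np.column_stack([ga, aa]), ["scn1a_GA", "scn1a_AA"]
    raise InvalidInputError(f"unknown covariate {name!r}")


def build_design(df: pd.DataFrame, spec: ModelSpec):
    """Intercept/slope design matrices (leading constant column) and labels."""
    n = len(df)
    XA, names_a = [np.ones((n, 1))], ["intercept"]
    for name in spec.intercept_covariates:
        cols, labels = _covariate_columns(df, name)
        XA.append(cols)
        names_a.extend(labels)
    XS, names_s = [np.ones((n, 1))], ["slope"]
    for name in spec.slope_covariates:
        cols, labels = _covariate_columns(df, name)
        XS.append(cols)
        names_s.extend([f"slope:{la}" for la in labels])
    return np.hstack(XA), names_a, np.hstack(XS), names_s


@dataclass
class _Prepared:
    """Dataset flattened to arrays for the vectorised likelihood.

    Records are sorted by subject so per-subject sums reduce to
    ``np.add.reduceat`` over ``starts``.
    """

    XA: np.ndarray  # (n_records, pA)
    XS: np.ndarray  # (n_records, pS)
    c: np.ndarray  # conc / 100
    y: np.ndarray  # 0/1
    subj: np.ndarray  # subject index per record, 0..m-1 (sorted)
    m: int
    names_a: list = field(default_factory=list)
    names_s: list = field(default_factory=list)
    subject_ids: np.ndarray | None = None
    order: np.ndarray | None = None  # original-row position of each sorted record
    starts: np.ndarray | None = None  # first record index of each subject

    def __post_init__(self):
        if self.starts is None and len(self.subj):
            self.starts = np.flatnonzero(np.r_[1, np.diff(self.subj)])


def _prepare(df: pd.DataFrame, spec: ModelSpec) -> _Prepared:
    if "responder" not in df.columns or "conc" not in df.columns:
        raise InvalidInputError("dataset needs 'conc' and 'responder' columns")
    ids, subj = np.unique(df["patient_id"].to_numpy(), return_inverse=True)
    order = np.argsort(subj, kind="stable")
    df = df.iloc[order]
    subj = subj[order]
    y = df["responder"].to_numpy(float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise InvalidInputError("responder must be 0/1")
    c = df["conc"].to_numpy(float) / CONC_SCALE
    if (c < 0).any() or not np.isfinite(c).all():
        raise InvalidInputError("conc must be finite and nonnegative")
    XA, names_a, XS, names_s = build_design(df, spec)
    return _Prepared(XA, XS, c, y, subj, len(ids), names_a, names_s, ids, order)


# ---------------------------------------------------------------------------
# Marginal log-likelihood (vectorised over subjects)
# ---------------------------------------------------------------------------

_LOG_SQRT_PI = 0.5 * np.log(np.pi)


def _record_logits(theta, prep: _Prepared, form: str):
    if form == "linear":
        pA = prep.XA.shape[1]
        pS = prep.XS.shape[1]
        beta_a = theta[:pA]
        beta_s = theta[pA : pA + pS]
        return prep.XA @ beta_a + (prep.XS @ beta_s) * prep.c
    # quadratic: theta = [theta1, theta2, theta3, log_omega]
    t1, t2, t3 = theta[0], theta[1], theta[2]
    return t1 + (prep.c - t2) ** 2 * t3


def _bernoulli_ll(lin, y):
    # y*lin - log(1 + e**lin), stable
    return y * lin - np.logaddexp(0.0, lin)


def _posterior_modes(base, subj, y, counts, omega2: float, eta0=None):
    """Per-subject posterior mode of eta by safeguarded (bracketed) Newton.

    The mode solves sum_j (y_j - p_j) - eta/omega2 = 0, whose left side is
    strictly decreasing in eta; a bisection bracket guarantees progress when
    curvature is tiny (saturated subjects with large omega2).
    """
    m = len(counts)
    inv_o2 = 1.0 / omega2
    bound = counts * omega2 + 1.0  # |eta_hat| <= n_i * omega2
    lo, hi = -bound, bound.copy()
    eta = np.zeros(m) if eta0 is None else np.clip(eta0, lo, hi)
    for _ in range(100):
        lin = base + eta[subj]
        p = expit(lin)
        g = np.bincount(subj, weights=y - p, minlength=m) - eta * inv_o2
        h = -np.bincount(subj, weights=p * (1.0 - p), minlength=m) - inv_o2
        step = g / h
        if np.max(np.abs(step)) < 1e-11:
            break
        lo = np.where(g > 0, eta, lo)
        hi = np.where(g < 0, eta, hi)
        cand = eta - step
        outside = (cand <= lo) | (cand >= hi)
        eta = np.where(outside, 0.5 * (lo + hi), cand)
    return eta


def _laplace_subject_ll(base, prep: _Prepared, omega2: float):
    """Per-subject Laplace log marginal likelihood given record-level fixed logits."""
    m, subj, y = prep.m, prep.subj, prep.y
    if omega2 <= 1e-12:
        ll = _bernoulli_ll(base, y)
        return np.bincount(subj, weights=ll, minlength=m)
    counts = np.bincount(subj, minlength=m).astype(float)
    eta = _posterior_modes(base, subj, y, counts, omega2)
    inv_o2 = 1.0 / omega2
    lin = base + eta[subj]
    p = expit(lin)
    bern = np.bincount(subj, weights=_bernoulli_ll(lin, y), minlength=m)
    h = -np.bincount(subj, weights=p * (1.0 - p), minlength=m) - inv_o2
    # Gaussian-prior and Laplace 2*pi factors cancel exactly.
    return bern - 0.5 * eta**2 * inv_o2 - 0.5 * np.log(omega2) - 0.5 * np.log(-h)


def _quadrature_subject_ll(base, prep: _Prepared, omega2: float, n_nodes: int = 64):
    """Gauss–Hermite per-subject log marginal likelihood (numerical reference)."""
    m, subj, y = prep.m, prep.subj, prep.y
    if omega2 <= 1e-12:
        ll = _bernoulli_ll(base, y)
        return np.bincount(subj, weights=ll, minlength=m)
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    etas = np.sqrt(2.0 * omega2) * nodes
    ll_k = np.empty((n_nodes, m))
    for k, e in enumerate(etas):
        ll_k[k] = np.bincount(subj, weights=_bernoulli_ll(base + e, y), minlength=m)
    logw = np.log(weights) - _LOG_SQRT_PI
    return logsumexp(ll_k + logw[:, None], axis=0)


def _total_loglik(theta, prep: _Prepared, form: str, method: str, n_quad: int) -> float:
    base = _record_logits(theta, prep, form)
    omega2 = float(np.exp(2.0 * theta[-1]))
    if method == "laplace":
        ll = _laplace_subject_ll(base, prep, omega2)
    else:
        ll = _quadrature_subject_ll(base, prep, omega2, n_quad)
    total = float(np.sum(ll))
    if not np.isfinite(total):
        raise NumericalError("non-finite marginal log-likelihood encountered")
    return total


def _design_and_grad(theta, prep: _Prepared, form: str):
    """Record logits and the per-record Jacobian d(logit)/d(fixed effects)."""
    if form == "linear":
        G = np.hstack([prep.XA, prep.XS * prep.c[:, None]])
        return G @ theta[:-1], G
    t1, t2, t3 = theta[0], theta[1], theta[2]
    d = prep.c - t2
    base = t1 + d**2 * t3
    G = np.column_stack([np.ones_like(d), -2.0 * d * t3, d**2])
    return base, G


def _nll_grad_laplace(theta, prep: _Prepared, form: str, eta0=None):
    """Exact negative Laplace log-likelihood and its gradient.

    The gradient uses the envelope theorem for the mode-dependent terms and
    differentiates the log-curvature term through the mode via the implicit
    function theorem; verified against finite differences in the test suite.
    """
    base, G = _design_and_grad(theta, prep, form)
    u = theta[-1]
    omega2 = float(np.exp(2.0 * np.clip(u, -15.0, 15.0)))
    inv_o2 = 1.0 / omega2
    y, starts, m = prep.y, prep.starts, prep.m

    # Per-subject posterior mode: root of the (strictly decreasing) gradient
    # g(eta) = sum_j (y_j - p_j) - eta/omega2.  Safeguarded Newton: a bisection
    # bracket guarantees progress when the Newton step is wild (tiny curvature
    # under saturation with large omega2).
    def mode_grad(e):
        lin = base + e[prep.subj]
        p = expit(lin)
        g = np.add.reduceat(y - p, starts) - e * inv_o2
        h = -np.add.reduceat(p * (1.0 - p), starts) - inv_o2
        return g, h

    counts = np.diff(np.r_[starts, len(y)])
    bound = np.abs(np.add.reduceat(y - 0.5, starts)) * omega2 + counts * omega2
    np.clip(bound, 2.0, 1e6, out=bound)
    lo, hi = -bound, bound.copy()
    eta = np.zeros(m) if eta0 is None else np.clip(eta0, lo, hi)
    for _ in range(100):
        g, h = mode_grad(eta)
        step = g / h
        if np.max(np.abs(step)) < 1e-11:
            break
        lo = np.where(g > 0, eta, lo)
        hi = np.where(g < 0, eta, hi)
        cand = eta - step
        outside = (cand <= lo) | (cand >= hi)
        eta = np.where(outside, 0.5 * (lo + hi), cand)

    lin = base + eta[prep.subj]
    p = expit(lin)
    w = p * (1.0 - p)
    r = y - p
    W = np.add.reduceat(w, starts)
    h = -W - inv_o2  # subject curvature, negative
    negh = -h
    bern = np.add.reduceat(y * lin - np.logaddexp(0.0, lin), starts)
    ll = bern - 0.5 * eta**2 * inv_o2 - 0.5 * np.log(omega2) - 0.5 * np.log(negh)
    nll = -float(np.sum(ll))
    if not np.isfinite(nll):
        raise NumericalError("non-finite marginal log-likelihood encountered")

    wp = w * (1.0 - 2.0 * p)  # d[p(1-p)]/d(logit)
    U = np.add.reduceat(w[:, None] * G, starts, axis=0)  # (m, p)
    V = np.add.reduceat(wp[:, None] * G, starts, axis=0)
    T = np.add.reduceat(wp, starts)
    score = (r[:, None] * G).sum(axis=0)
    deta_dbeta = U / h[:, None]
    dnegh_dbeta = V + T[:, None] * deta_dbeta
    grad_beta = score - 0.5 * (dnegh_dbeta / negh[:, None]).sum(axis=0)
    deta_du = -(2.0 * eta * inv_o2) / h
    dnegh_du = -2.0 * inv_o2 + T * deta_du
    grad_u = float(np.sum(eta**2) * inv_o2 - m - 0.5 * np.sum(dnegh_du / negh))
    grad = -np.concatenate([grad_beta, [grad_u]])
    if not np.isfinite(grad).all():
        raise NumericalError("non-finite gradient encountered")
    return nll, grad, eta


# ---------------------------------------------------------------------------
# Single-subject reference implementation
# ---------------------------------------------------------------------------


def subject_marginal_loglik(
    params: PDParameters,
    cov: PatientCovariates,
    records: list[ResponseRecord],
    method: str = "laplace",
    n_quad: int = 64,
) -> float:
    """Log marginal likelihood of one subject's visit outcomes.

    Integrates the single random effect out of the product of Bernoulli
    visit likelihoods, either by Laplace approximation or by ``n_quad``-node
    Gauss–Hermite quadrature.  Scalar reference implementation; the fitting
    path uses an equivalent vectorised version.
    """
    if not records:
        raise InvalidInputError("need at least one record")
    if method not in ("laplace", "quadrature"):
        raise InvalidInputError(f"method must be 'laplace' or 'quadrature', got {method!r}")
    y = np.array([r.responder for r in records], float)
    base = np.array([linear_logit(params, cov, r.conc, 0.0) for r in records])
    prep = _Prepared(
        XA=np.empty(0), XS=np.empty(0), c=np.empty(0), y=y,
        subj=np.zeros(len(records), int), m=1,
    )
    if method == "laplace":
        return float(_laplace_subject_ll(base, prep, params.omega2)[0])
    return float(_quadrature_subject_ll(base, prep, params.omega2, n_quad)[0])


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Outcome of one maximum-marginal-likelihood fit.

    ``estimates``/``standard_errors`` are keyed by coefficient label
    (``intercept``, ``age``, ..., ``slope``, ``slope:partial``, ...,
    ``omega2``).  ``objective`` is -2 * log marginal likelihood.
    """

    estimates: dict
    standard_errors: dict
    objective: float
    converged: bool
    n_subjects: int
    n_records: int
    spec: ModelSpec
    theta: np.ndarray | None = None
    message: str = ""

    @property
    def omega2(self) -> float:
        return self.estimates["omega2"]

    def se_finite(self) -> bool:
        """Whether all standard errors are finite (positive-definite curvature)."""
        return all(np.isfinite(v) for v in self.standard_errors.values())

    def to_pd_parameters(self) -> PDParameters:
        """Map named estimates onto the final-model parameter container.

        Works for any linear spec whose covariates are a subset of the
        final model's.
        """
        if self.spec.form != "linear":
            raise InvalidInputError("only linear fits map onto PDParameters")
        e = self.estimates
        mapping = {
            "intercept": "intercept",
            "age": "beta_age",
            "CBZ": "beta_cbz_i",
            "CZP": "beta_czp_i",
            "scn1a_GA": "beta_ga_i",
            "scn1a_AA": "beta_aa_i",
            "slope": "slope",
            "slope:partial": "beta_partial_s",
            "slope:PHT": "beta_pht_s",
            "slope:TPM": "beta_tpm_s",
            "slope:scn1a_GA": "beta_ga_s",
            "slope:scn1a_AA": "beta_aa_s",
            "omega2": "omega2",
        }
        kwargs = {}
        for label, value in e.items():
            if label not in mapping:
                raise InvalidInputError(
                    f"coefficient {label!r} has no slot in PDParameters"
                )
            kwargs[mapping[label]] = value
        return PDParameters(**kwargs)

    def population_logit(self, df: pd.DataFrame) -> np.ndarray:
        """Population logit (eta = 0) for each row of a patient table."""
        if self.theta is None:
            raise InvalidInputError("fit carries no parameter vector")
        work = df if "responder" in df.columns else df.assign(responder=0)
        prep = _prepare(work, self.spec)
        sorted_logits = _record_logits(self.theta, prep, self.spec.form)
        out = np.empty_like(sorted_logits)
        out[prep.order] = sorted_logits
        return out

    def intercept_slope_parts(self, df: pd.DataFrame):
        """Per-row covariate-adjusted intercept A and slope S (per 100 μg/ml)."""
        if self.spec.form != "linear":
            raise InvalidInputError("intercept/slope decomposition requires the linear form")
        if self.theta is None:
            raise InvalidInputError("fit carries no parameter vector")
        XA, _, XS, _ = build_design(df, self.spec)
        pA = XA.shape[1]
        return XA @ self.theta[:pA], XS @ self.theta[pA : pA + XS.shape[1]]

    def summary(self) -> pd.DataFrame:
        rows = [
            {"parameter": k, "estimate": v, "se": self.standard_errors.get(k, np.nan)}
            for k, v in self.estimates.items()
        ]
        return pd.DataFrame(rows)


def _gradient_hessian(grad_f, x, rel_step=1e-6):
    """Hessian from central differences of an exact gradient (symmetrised)."""
    n = len(x)
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((n, n))
    for i in range(n):
        e = np.zeros(n)
        e[i] = h[i]
        H[i] = (grad_f(x + e) - grad_f(x - e)) / (2.0 * h[i])
    return 0.5 * (H + H.T)


def _numeric_hessian(f, x, rel_step=1e-4):
    n = len(x)
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


class MixedEffectsLogit(BaseEstimator):
    """Random-intercept logistic exposure-response model (scikit-learn style).

    Parameters
    ----------
    intercept_covariates, slope_covariates : sequence of str
        Covariates entering the intercept and the slope (see
        :data:`COVARIATE_NAMES`; ``scn1a`` expands to two indicators).
    form : {"linear", "quadratic"}
        Shape of the concentration term.
    method : {"laplace", "quadrature"}
        Random-effect integration used during fitting.
    n_quad : int
        Gauss–Hermite node count when ``method="quadrature"``.
    n_starts : int
        Number of optimiser starts (the first is data-driven, the rest are
        seeded perturbations of it).
    start : dict or None
        Optional warm start keyed by coefficient label (missing entries fall
        back to the default start); used by bootstrap refits.
    compute_se : bool
        Whether to evaluate the numerical Hessian for standard errors.
    random_state : int
        Seed for the start perturbations.

    Attributes (after ``fit``)
    --------------------------
    result_ : FitResult
    params_ : dict, estimates keyed by coefficient label
    objective_ : float, -2 log marginal likelihood
    converged_ : bool
    """

    def __init__(
        self,
        intercept_covariates=(),
        slope_covariates=(),
        form="linear",
        method="laplace",
        n_quad=64,
        n_starts=3,
        start=None,
        compute_se=True,
        tol=1e-6,
        max_iter=500,
        random_state=0,
    ):
        self.intercept_covariates = intercept_covariates
        self.slope_covariates = slope_covariates
        self.form = form
        self.method = method
        self.n_quad = n_quad
        self.n_starts = n_starts
        self.start = start
        self.compute_se = compute_se
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    # -- internal ----------------------------------------------------------

    def _spec(self) -> ModelSpec:
        return ModelSpec(
            intercept_covariates=tuple(self.intercept_covariates),
            slope_covariates=tuple(self.slope_covariates),
            form=self.form,
        )

    def _param_names(self, prep: _Prepared):
        if self.form == "linear":
            return [*prep.names_a, *prep.names_s, "omega2"]
        return ["theta1", "theta2", "theta3", "omega2"]

    def _starts(self, prep: _Prepared, names):
        rng = np.random.default_rng(self.random_state)
        k = len(names)  # includes omega2 slot; theta has log-omega there
        ybar = float(np.clip(prep.y.mean(), 0.02, 0.98))
        if self.form == "linear":
            theta0 = np.zeros(k)
            theta0[0] = np.log(ybar / (1.0 - ybar))
            theta0[-1] = np.log(1.5)  # log omega
        else:
            theta0 = np.array([np.log(ybar / (1 - ybar)), float(np.median(prep.c)), 0.0, np.log(1.5)])
        if self.start:
            for i, name in enumerate(names[:-1]):
                if name in self.start:
                    theta0[i] = self.start[name]
            if "omega2" in self.start and self.start["omega2"] > 0:
                theta0[-1] = 0.5 * np.log(self.start["omega2"])
        starts = [theta0]
        for _ in range(max(0, self.n_starts - 1)):
            pert = theta0 + rng.normal(scale=0.5, size=k)
            starts.append(pert)
        return starts

    @staticmethod
    def _newton_polish(nll_grad, theta, fun, jac, max_steps=15):
        """Damped Newton steps (finite-difference Hessian of the exact
        gradient) to push the gradient down after a coarse BFGS solve."""
        for _ in range(max_steps):
            if np.max(np.abs(jac)) < 1e-7 * (1.0 + abs(fun)):
                break
            try:
                H = _gradient_hessian(lambda th: nll_grad(th)[1], theta)
                step = np.linalg.solve(H, jac)
            except (np.linalg.LinAlgError, NumericalError):
                break
            improved = False
            for damp in (1.0, 0.5, 0.25, 0.1, 0.01):
                try:
                    f_new, g_new = nll_grad(theta - damp * step)
                except NumericalError:
                    continue
                if f_new <= fun + 1e-12:
                    theta = theta - damp * step
                    fun, jac = f_new, g_new
                    improved = True
                    break
            if not improved:
                break
        return theta, fun, jac

    # -- sklearn API -------------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None):
        """Fit by maximum marginal likelihood.

        ``X`` is a patient table (one row per visit) with ``patient_id``,
        ``conc`` and the covariate columns; ``y`` overrides the
        ``responder`` column when given.
        """
        df = X
        if y is not None:
            df = X.copy()
            df["responder"] = np.asarray(y)
        spec = self._spec()
        prep = _prepare(df, spec)
        if prep.m < 2:
            raise InvalidInputError("need at least 2 subjects")
        names = self._param_names(prep)
        for j, name in enumerate(names[:-1]):
            col = (
                prep.XA[:, j]
                if self.form == "linear" and j < prep.XA.shape[1]
                else None
            )
            if col is not None and j > 0 and np.ptp(col) == 0:
                raise InvalidInputError(f"covariate {name!r} does not vary in the data")
        if self.form == "linear":
            pA = prep.XA.shape[1]
            for j in range(1, prep.XS.shape[1]):
                if np.ptp(prep.XS[:, j]) == 0:
                    raise InvalidInputError(
                        f"covariate {names[pA + j]!r} does not vary in the data"
                    )

        nll = lambda th: -_total_loglik(th, prep, self.form, self.method, self.n_quad)
        eta_cache = {"eta": None}

        def nll_grad(th):
            nll_val, grad, eta = _nll_grad_laplace(th, prep, self.form, eta_cache["eta"])
            eta_cache["eta"] = eta
            return nll_val, grad

        best = None
        for theta0 in self._starts(prep, names):
            eta_cache["eta"] = None
            try:
                if self.method == "laplace":
                    res = minimize(
                        nll_grad,
                        theta0,
                        jac=True,
                        method="BFGS",
                        options={"gtol": 1e-6, "maxiter": self.max_iter},
                    )
                else:
                    res = minimize(
                        nll,
                        theta0,
                        method="BFGS",
                        options={"gtol": 1e-5, "maxiter": self.max_iter},
                    )
            except NumericalError:
                continue
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        if best is None:
            raise NumericalError("all optimiser starts failed")
        theta = np.asarray(best.x, float)
        fun = float(best.fun)
        jac = np.asarray(best.jac, float)
        if self.method == "laplace" and np.max(np.abs(jac)) > 1e-6:
            theta, fun, jac = self._newton_polish(nll_grad, theta, fun, jac)
        omega2 = float(np.exp(2.0 * theta[-1]))
        grad_ok = np.max(np.abs(jac)) < 1e-4 * (1.0 + abs(fun))
        converged = bool(best.success or grad_ok)

        estimates = {n: float(v) for n, v in zip(names[:-1], theta[:-1])}
        estimates["omega2"] = omega2
        ses = {n: np.nan for n in names}
        if self.compute_se:
            try:
                if self.method == "laplace":
                    H = _gradient_hessian(lambda th: nll_grad(th)[1], theta)
                else:
                    H = _numeric_hessian(nll, theta)
                cov = np.linalg.inv(H)
                diag = np.diag(cov)
                if (diag <= 0).any():
                    raise np.linalg.LinAlgError("non-positive-definite curvature")
                se_theta = np.sqrt(diag)
                for i, n in enumerate(names[:-1]):
                    ses[n] = float(se_theta[i])
                # delta method: omega2 = exp(2u)
                ses["omega2"] = float(2.0 * omega2 * se_theta[-1])
                if max(ses.values()) > 1e3:
                    warnings.warn(
                        "very large standard error: possible separation / unbounded estimate",
                        RuntimeWarning,
                    )
            except (np.linalg.LinAlgError, NumericalError):
                warnings.warn("Hessian not positive definite; SEs set to NaN", RuntimeWarning)

        self.result_ = FitResult(
            estimates=estimates,
            standard_errors=ses,
            objective=float(2.0 * fun),
            converged=converged,
            n_subjects=prep.m,
            n_records=len(prep.y),
            spec=spec,
            theta=theta,
            message=str(best.message),
        )
        self.params_ = estimates
        self.objective_ = self.result_.objective
        self.converged_ = converged
        self.n_subjects_ = prep.m
        self.n_records_ = len(prep.y)
        self._names = names
        return self

    def predict_logit(self, X: pd.DataFrame) -> np.ndarray:
        """Population logit (eta = 0) per row of ``X`` (original row order)."""
        return self.result_.population_logit(X)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Population response probabilities, shape (n, 2) sklearn-style."""
        p1 = expit(self.predict_logit(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_logit(X) > 0).astype(int)

    def score(self, X: pd.DataFrame, y=None) -> float:
        """Mean population log-likelihood per record (ignoring eta)."""
        df = X if y is None else X.assign(responder=np.asarray(y))
        lin = self.predict_logit(df)
        yv = df["responder"].to_numpy(float)
        return float(np.mean(_bernoulli_ll(lin, yv)))


def fit(
    dataset: pd.DataFrame,
    model_spec: ModelSpec = FINAL_MODEL_SPEC,
    start: dict | None = None,
    **kwargs,
) -> FitResult:
    """Fit ``model_spec`` to a patient table; functional wrapper over
    :class:`MixedEffectsLogit`."""
    est = MixedEffectsLogit(
        intercept_covariates=model_spec.intercept_covariates,
        slope_covariates=model_spec.slope_covariates,
        form=model_spec.form,
        start=start,
        **kwargs,
    )
    est.fit(dataset)
    return est.result_


def objective_difference(reduced: FitResult, full: FitResult) -> float:
    """Delta objective function: objective(reduced) - objective(full).

    Both fits must be converged and fitted on the same records.
    """
    if not (reduced.converged and full.converged):
        raise InvalidComparisonError("both fits must have converged")
    if (reduced.n_subjects, reduced.n_records) != (full.n_subjects, full.n_records):
        raise InvalidComparisonError("fits were not produced from the same records")
    return reduced.objective - full.objective


def variance_reduction_percent(omega2_base: float, omega2_final: float) -> float:
    """Percentage decrease in inter-individual variance from base to final model."""
    if omega2_base <= 0:
        raise InvalidInputError("base-model variance must be positive")
    return 100.0 * (omega2_base - omega2_final) / omega2_base
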