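"""Population pharmacokinetics of sustained-release valproic acid.

The PK model is fixed (not re-estimated here): apparent volume of
distribution and clearance are power functions of the daily dose with
multiplicative covariate effects on clearance,

    Vd = 110 * (Dose/1000)**1.51                                   [L]
    CL = 0.577 * (Dose/1000)**0.535 * 0.875**female
               * 1.22**CBZ * 1.10**PB * 1.40**PHT * 0.915**CLB     [L/h]

with Dose the daily dose in mg/day and the exponents 0/1 indicators.
Disposition follows a one-compartment model with first-order absorption and
an absorption lag; :func:`steady_state_conc` evaluates the standard
superposition (multiple-dose) solution at steady state.

Absorption rate, lag time and bioavailability are not identifiable from the
inputs this package consumes, so they are explicit configuration
(``ka = 1.0 /h``, ``tlag = 0.5 h``, ``F = 1`` by default) and the default
exposure summary handed to the PD model is the steady-state *average*
concentration ``F * daily_dose / (24 * CL)``, which depends on none of them.
Set ``exposure_mode="trough"`` to evaluate the full profile at ``t = tau``
instead.  Concentrations are in μg/ml (≡ mg/L).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .domain import DosingRegimen, PatientCovariates, PKParameters
from .errors import DegenerateKineticsError, InvalidInputError

# Multiplicative clearance covariate effects (indicator -> factor).
CL_COVARIATE_FACTORS = {"CBZ": 1.22, "PB": 1.10, "PHT": 1.40, "CLB": 0.915}

CL_BASE = 0.577  # L/h at 1000 mg/day, male, no interacting co-medication
CL_DOSE_EXP = 0.535
CL_FEMALE_FACTOR = 0.875
VD_BASE = 110.0  # L at 1000 mg/day
VD_DOSE_EXP = 1.51


@dataclass(frozen=True)
class PKConfig:
    """Exposure-prediction settings.

    exposure_mode : {"css_avg", "trough"}
        ``css_avg`` returns F*daily_dose/(24*CL); ``trough`` evaluates the
        full steady-state profile at t = tau.
    """

    exposure_mode: str = "css_avg"
    ka: float = 1.0
    tlag: float = 0.5
    F: float = 1.0
    tau: float = 12.0

    def __post_init__(self):
        if self.exposure_mode not in ("css_avg", "trough"):
            raise InvalidInputError(
                f"exposure_mode must be 'css_avg' or 'trough', got {self.exposure_mode!r}"
            )


DEFAULT_PK_CONFIG = PKConfig()


def clearance(regimen: DosingRegimen, cov: PatientCovariates) -> float:
    """Apparent oral clearance CL/F in L/h.

    Dose-dependent with multiplicative effects of sex and co-administered
    CBZ, PB, PHT and CLB; other co-medications do not enter.
    """
    cl = CL_BASE * (regimen.daily_dose / 1000.0) ** CL_DOSE_EXP
    if cov.female:
        cl *= CL_FEMALE_FACTOR
    for drug, factor in CL_COVARIATE_FACTORS.items():
        if cov.has(drug):
            cl *= factor
    return cl


def volume(regimen: DosingRegimen) -> float:
    """Apparent volume of distribution Vd/F in L (dose-dependent)."""
    return VD_BASE * (regimen.daily_dose / 1000.0) ** VD_DOSE_EXP


def steady_state_conc(t: float, regimen: DosingRegimen, pk: PKParameters) -> float:
    """Concentration (μg/ml) at time ``t`` hours after a dose, at steady state.

    Standard superposition solution of the one-compartment model with
    first-order absorption (rate ``ka``), first-order elimination
    (rate ``ke = CL/Vd``) and absorption lag ``tlag``, dosed every ``tau``
    hours:

        C(t') = F*D*ka / (Vd*(ka-ke)) * [ exp(-ke*t')/(1-exp(-ke*tau))
                                        - exp(-ka*t')/(1-exp(-ka*tau)) ]

    with ``t' = (t - tlag) mod tau``.  The modulo shift folds the lag of the
    current dose onto the tail of the previous one, which is exact at steady
    state.
    """
    tau = regimen.tau
    if not 0 <= t <= tau:
        raise InvalidInputError(f"t must lie in [0, tau]=[0, {tau}], got {t}")
    ke = pk.ke
    if math.isclose(pk.ka, ke, rel_tol=1e-12, abs_tol=0.0):
        raise DegenerateKineticsError(
            f"ka == ke == {ke:.6g} /h: first-order superposition formula is singular"
        )
    tp = (t - pk.tlag) % tau
    dose = regimen.dose_per_admin
    pref = pk.F * dose * pk.ka / (pk.Vd * (pk.ka - ke))
    term_e = math.exp(-ke * tp) / -math.expm1(-ke * tau)
    term_a = math.exp(-pk.ka * tp) / -math.expm1(-pk.ka * tau)
    return pref * (term_e - term_a)


def average_conc(regimen: DosingRegimen, cov: PatientCovariates, F: float = 1.0) -> float:
    """Steady-state average concentration F*daily_dose/(24*CL) in μg/ml."""
    return F * regimen.daily_dose / (24.0 * clearance(regimen, cov))


def pk_parameters(
    regimen: DosingRegimen, cov: PatientCovariates, config: PKConfig = DEFAULT_PK_CONFIG
) -> PKParameters:
    """Assemble the individual PK parameter set for one patient."""
    return PKParameters(
        CL=clearance(regimen, cov),
        Vd=volume(regimen),
        ka=config.ka,
        tlag=config.tlag,
        F=config.F,
    )


def predict_trough(
    regimen: DosingRegimen,
    cov: PatientCovariates,
    config: PKConfig = DEFAULT_PK_CONFIG,
) -> float:
    """Predicted steady-state exposure summary (μg/ml) for one patient.

    In ``css_avg`` mode (default) this is the dose-normalised average
    concentration; in ``trough`` mode the superposition profile is evaluated
    at ``t = tau`` (immediately before the next dose).
    """
    if config.exposure_mode == "css_avg":
        return average_conc(regimen, cov, F=config.F)
    pk = pk_parameters(regimen, cov, config)
    return steady_state_conc(regimen.tau, regimen, pk)
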