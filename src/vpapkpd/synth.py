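"""Synthetic cohort generation and small genetics/response utilities.

The generator emulates the margins of the study cohort this package models:
77 Japanese patients with epilepsy on sustained-release valproic acid,
729 visit records, ages 15.2 ± 8.2 years truncated to [0.8, 36.9], 37.7%
female, 87% partial seizures, daily doses 1120 ± 592.5 mg truncated to
[50, 3200], the listed co-medication prevalences, and an SCN1A rs3812718
A-allele frequency of 0.617 with genotypes drawn under Hardy–Weinberg
equilibrium.  Covariates are sampled independently (the joint distribution
was never reported — a documented simplification), the dose is held constant
within a patient, and each patient's exposure is the steady-state average
concentration from the PK module.  The responder outcome is drawn per visit
from the final exposure-response model (default: the published estimates)
with one normal random effect per subject.

Also here: the over-50% responder classification rule, the allele-frequency
estimator and the Hardy–Weinberg chi-square test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .domain import COMEDS, DosingRegimen, PatientCovariates
from .errors import InvalidInputError, UndefinedResponseError
from .pd_model import PDParameters, linear_logit
from .pk import average_conc

__all__ = [
    "CohortConfig",
    "GenotypeCounts",
    "DEFAULT_TRUE_PARAMS",
    "generate_cohort",
    "classify_response",
    "allele_frequency",
    "hwe_chi2",
]

#: Published final-model estimates, used as the default data-generating truth.
DEFAULT_TRUE_PARAMS = PDParameters(
    intercept=6.09,
    beta_age=0.98,
    beta_cbz_i=-1.75,
    beta_czp_i=-1.18,
    beta_ga_i=-5.87,
    beta_aa_i=-4.88,
    slope=-13.5,
    beta_partial_s=2.41,
    beta_pht_s=-3.62,
    beta_tpm_s=-1.73,
    beta_ga_s=10.1,
    beta_aa_s=9.48,
    omega2=11.3,
)

#: Cohort co-medication prevalences.
DEFAULT_COMED_PREVALENCE = {
    "CBZ": 0.610,
    "CZP": 0.273,
    "CLB": 0.429,
    "GBP": 0.104,
    "LTG": 0.039,
    "PB": 0.403,
    "PHT": 0.286,
    "TPM": 0.130,
    "ZNS": 0.338,
}


@dataclass(frozen=True)
class CohortConfig:
    """Sampling distributions for one synthetic cohort (defaults: the study cohort)."""

    n_patients: int = 77
    visits_mean: float = 729 / 77  # ≈ 9.47 visits per patient
    age_mean: float = 15.2
    age_sd: float = 8.2
    age_bounds: tuple = (0.8, 36.9)
    p_female: float = 0.377
    p_partial: float = 0.870
    p_symptomatic: float = 0.494
    p_intellectual_disability: float = 0.766
    comed_prevalence: dict = field(default_factory=lambda: dict(DEFAULT_COMED_PREVALENCE))
    allele_freq_A: float = 0.617
    dose_mean: float = 1120.0
    dose_sd: float = 592.5
    dose_bounds: tuple = (50.0, 3200.0)
    true_params: PDParameters = DEFAULT_TRUE_PARAMS
    tau: float = 12.0
    emit_frequencies: bool = False
    seed: int = 0

    def __post_init__(self):
        probs = [
            self.p_female,
            self.p_partial,
            self.p_symptomatic,
            self.p_intellectual_disability,
            self.allele_freq_A,
            *self.comed_prevalence.values(),
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise InvalidInputError("all prevalences must lie in [0, 1]")
        if self.n_patients < 1 or self.visits_mean <= 0:
            raise InvalidInputError("need n_patients >= 1 and visits_mean > 0")
        for lo, hi, sd in ((*self.age_bounds, self.age_sd), (*self.dose_bounds, self.dose_sd)):
            if not lo < hi or sd <= 0:
                raise InvalidInputError("infeasible truncation bounds or scale")


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(config: CohortConfig = CohortConfig(), seed: int | None = None) -> pd.DataFrame:
    """Draw one synthetic cohort as a canonical patient table (one row per visit).

    Columns: ``patient_id, age_years, female, seizure_locus, seizure_type,
    intellectual_disability, dose_mg_day,`` the nine co-medication flags,
    ``scn1a, conc, responder`` (plus ``baseline_seizure_freq`` /
    ``visit_seizure_freq`` when ``emit_frequencies`` is on).  Deterministic
    for a given seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_patients

    age = _truncnorm(rng, config.age_mean, config.age_sd, *config.age_bounds, n)
    dose = _truncnorm(rng, config.dose_mean, config.dose_sd, *config.dose_bounds, n)
    female = rng.random(n) < config.p_female
    partial = rng.random(n) < config.p_partial
    symptomatic = rng.random(n) < config.p_symptomatic
    intdis = rng.random(n) < config.p_intellectual_disability
    comed = {d: rng.random(n) < config.comed_prevalence.get(d, 0.0) for d in COMEDS}
    pa = config.allele_freq_A
    geno = rng.choice(
        np.array(["GG", "GA", "AA"]),
        size=n,
        p=[(1 - pa) ** 2, 2 * pa * (1 - pa), pa**2],
    )
    # Poisson visit counts clipped to >= 1 (truncation mass is negligible at
    # the default mean, so E[visits] ~ visits_mean and E[total] ~ 729).
    visits = np.maximum(rng.poisson(config.visits_mean, size=n), 1)
    eta = rng.normal(0.0, np.sqrt(config.true_params.omega2), size=n)

    rows = []
    for i in range(n):
        cov = PatientCovariates(
            age=float(age[i]),
            female=bool(female[i]),
            seizure_locus="partial" if partial[i] else "generalized",
            seizure_type="symptomatic" if symptomatic[i] else "cryptogenic",
            intellectual_disability=bool(intdis[i]),
            comeds=frozenset(d for d in COMEDS if comed[d][i]),
            scn1a=str(geno[i]),
        )
        regimen = DosingRegimen(daily_dose=float(dose[i]), tau=config.tau)
        conc = average_conc(regimen, cov)
        logit = linear_logit(config.true_params, cov, conc, float(eta[i]))
        p_resp = 1.0 / (1.0 + np.exp(-logit))
        y = rng.random(int(visits[i])) < p_resp
        for j, yj in enumerate(y):
            rows.append(
                {
                    "patient_id": f"P{i:03d}",
                    "visit": j,
                    "age_years": cov.age,
                    "female": int(cov.female),
                    "seizure_locus": cov.seizure_locus,
                    "seizure_type": cov.seizure_type,
                    "intellectual_disability": int(cov.intellectual_disability),
                    "dose_mg_day": regimen.daily_dose,
                    **{d: int(d in cov.comeds) for d in COMEDS},
                    "scn1a": cov.scn1a,
                    "conc": conc,
                    "responder": int(yj),
                }
            )
    df = pd.DataFrame(rows)

    if config.emit_frequencies:
        # Optional observational layer: monthly baseline seizure rate and a
        # visit rate consistent with the drawn responder label.
        base = rng.lognormal(mean=np.log(10.0), sigma=0.8, size=n)
        df["baseline_seizure_freq"] = base[
            df["patient_id"].str.slice(1).astype(int).to_numpy()
        ]
        ratio = np.where(df["responder"] == 1, 0.3, 0.9)
        df["visit_seizure_freq"] = rng.poisson(df["baseline_seizure_freq"] * ratio)
    return df


def classify_response(baseline_freq: float, observed_freq: float) -> int:
    """Responder rule: 1 iff the seizure frequency fell by *over* 50%.

    Exactly 50% does not qualify.  A zero baseline leaves the reduction
    undefined.
    """
    if baseline_freq <= 0:
        raise UndefinedResponseError(
            f"baseline seizure frequency must be positive, got {baseline_freq}"
        )
    if observed_freq < 0:
        raise InvalidInputError(f"observed frequency must be nonnegative, got {observed_freq}")
    return int(observed_freq < 0.5 * baseline_freq)


@dataclass(frozen=True)
class GenotypeCounts:
    """SCN1A rs3812718 genotype counts (G/G, G/A, A/A)."""

    n_gg: int
    n_ga: int
    n_aa: int

    def __post_init__(self):
        if min(self.n_gg, self.n_ga, self.n_aa) < 0:
            raise InvalidInputError("genotype counts must be nonnegative")
        if self.total == 0:
            raise InvalidInputError("need at least one genotyped subject")

    @property
    def total(self) -> int:
        return self.n_gg + self.n_ga + self.n_aa


def allele_frequency(g: GenotypeCounts) -> float:
    """Sample frequency of the A allele: (2 n_AA + n_GA) / (2 N)."""
    return (2 * g.n_aa + g.n_ga) / (2 * g.total)


def hwe_chi2(g: GenotypeCounts) -> tuple[float, float]:
    """Hardy–Weinberg goodness-of-fit chi-square (1 df) and its p-value.

    Expected counts come from the sample allele frequency.  A monomorphic
    sample is trivially in equilibrium: returns (0, 1).
    """
    p = allele_frequency(g)
    if p in (0.0, 1.0):
        import warnings

        warnings.warn("monomorphic sample: HWE test degenerate", RuntimeWarning)
        return 0.0, 1.0
    n = g.total
    expected = np.array([n * (1 - p) ** 2, n * 2 * p * (1 - p), n * p**2])
    observed = np.array([g.n_gg, g.n_ga, g.n_aa], float)
    chi2_stat = float(np.sum((observed - expected) ** 2 / expected))
    return chi2_stat, float(stats.chi2.sf(chi2_stat, df=1))
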