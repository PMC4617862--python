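"""Domain value types: patient covariates, dosing regimens, PK parameters.

These are lightweight frozen dataclasses with eager validation.  The modelling
code mostly operates on pandas DataFrames in the canonical patient-table
layout (see :mod:`vpapkpd.io`); the scalar types here are used at the API
boundary — single-patient prediction, optimal-concentration inversion, and as
the reference ("one record at a time") implementations that the vectorised
fitting path is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InvalidInputError

#: Co-administered antiepileptic drugs screened as covariates.
COMEDS = ("CBZ", "CZP", "CLB", "GBP", "LTG", "PB", "PHT", "TPM", "ZNS")

#: SCN1A rs3812718 genotypes (G/G reference).
GENOTYPES = ("GG", "GA", "AA")

SEIZURE_LOCI = ("generalized", "partial")
SEIZURE_TYPES = ("symptomatic", "cryptogenic")


@dataclass(frozen=True)
class PatientCovariates:
    """Fixed per-patient descriptors feeding the PK and PD predictors.

    Parameters
    ----------
    age : float
        Age in years; must be positive.
    female : bool
        Sex indicator (affects clearance).
    seizure_locus : {"generalized", "partial"}
    seizure_type : {"symptomatic", "cryptogenic"}
    intellectual_disability : bool
    comeds : frozenset of str
        Co-administered AEDs, a subset of :data:`COMEDS`.
    scn1a : {"GG", "GA", "AA"}
        SCN1A rs3812718 genotype.
    """

    age: float
    female: bool = False
    seizure_locus: str = "partial"
    seizure_type: str = "symptomatic"
    intellectual_disability: bool = False
    comeds: frozenset = field(default_factory=frozenset)
    scn1a: str = "GG"

    def __post_init__(self):
        if not self.age > 0:
            raise InvalidInputError(f"age must be positive, got {self.age}")
        if self.seizure_locus not in SEIZURE_LOCI:
            raise InvalidInputError(f"seizure_locus must be one of {SEIZURE_LOCI}")
        if self.seizure_type not in SEIZURE_TYPES:
            raise InvalidInputError(f"seizure_type must be one of {SEIZURE_TYPES}")
        if self.scn1a not in GENOTYPES:
            raise InvalidInputError(f"scn1a must be one of {GENOTYPES}, got {self.scn1a!r}")
        comeds = frozenset(self.comeds)
        unknown = comeds - set(COMEDS)
        if unknown:
            raise InvalidInputError(f"unknown co-medications: {sorted(unknown)}")
        object.__setattr__(self, "comeds", comeds)

    def has(self, drug: str) -> bool:
        return drug in self.comeds


@dataclass(frozen=True)
class DosingRegimen:
    """Daily valproic-acid dose split into equal administrations.

    ``dose_per_admin`` is derived as ``daily_dose * tau / 24`` so that the
    invariant ``dose_per_admin * (24 / tau) == daily_dose`` holds by
    construction.
    """

    daily_dose: float  # mg/day
    tau: float = 12.0  # dosing interval, hours

    def __post_init__(self):
        if not self.daily_dose > 0:
            raise InvalidInputError(f"daily_dose must be positive, got {self.daily_dose}")
        if not self.tau > 0:
            raise InvalidInputError(f"tau must be positive, got {self.tau}")
        n = 24.0 / self.tau
        if abs(n - round(n)) > 1e-9:
            raise InvalidInputError(f"tau must divide 24 hours, got {self.tau}")

    @property
    def dose_per_admin(self) -> float:
        """Dose per administration in mg."""
        return self.daily_dose * self.tau / 24.0


@dataclass(frozen=True)
class PKParameters:
    """One-compartment first-order-absorption parameters for one patient."""

    CL: float  # L/h
    Vd: float  # L
    ka: float = 1.0  # 1/h
    tlag: float = 0.5  # h
    F: float = 1.0  # bioavailability fraction

    def __post_init__(self):
        for name in ("CL", "Vd", "ka", "tlag"):
            v = getattr(self, name)
            if name == "tlag":
                if v < 0:
                    raise InvalidInputError(f"{name} must be nonnegative, got {v}")
            elif not v > 0:
                raise InvalidInputError(f"{name} must be positive, got {v}")
        if not 0 < self.F <= 1:
            raise InvalidInputError(f"F must lie in (0, 1], got {self.F}")

    @property
    def ke(self) -> float:
        """Elimination rate constant CL/Vd (1/h)."""
        return self.CL / self.Vd


@dataclass(frozen=True)
class ResponseRecord:
    """One visit: predicted trough concentration and binary responder flag."""

    patient_id: str
    conc: float  # μg/ml
    responder: int

    def __post_init__(self):
        if self.conc < 0:
            raise InvalidInputError(f"conc must be nonnegative, got {self.conc}")
        if self.responder not in (0, 1):
            raise InvalidInputError(f"responder must be 0 or 1, got {self.responder}")
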