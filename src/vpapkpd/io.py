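"""Patient-table reading/writing, model (de)serialisation, packaged estimates.

The canonical patient table is comma-separated UTF-8 with a header, one row
per visit.  Required columns: ``patient_id, age_years, female,
seizure_locus, seizure_type, intellectual_disability, dose_mg_day``, the
nine co-medication flags, and ``scn1a``.  The responder outcome may be given
directly (``responder`` 0/1) or derived from ``baseline_seizure_freq`` /
``visit_seizure_freq`` via the over-50%-reduction rule.  ``conc_observed``
is optional; predicted exposure is always recomputed from dose and
covariates unless a ``conc`` column is already present.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np
import pandas as pd

from .domain import COMEDS, GENOTYPES, SEIZURE_LOCI, SEIZURE_TYPES, DosingRegimen, PatientCovariates
from .errors import TableValidationError, UndefinedResponseError
from .pd_model import FitResult, ModelSpec, PDParameters
from .pk import DEFAULT_PK_CONFIG, PKConfig, predict_trough
from .synth import classify_response

__all__ = [
    "REQUIRED_COLUMNS",
    "read_patient_table",
    "write_patient_table",
    "add_predicted_conc",
    "covariates_from_row",
    "final_model_parameters",
    "final_model_info",
    "fit_result_to_json",
    "pd_parameters_from_json",
]

REQUIRED_COLUMNS = (
    "patient_id",
    "age_years",
    "female",
    "seizure_locus",
    "seizure_type",
    "intellectual_disability",
    "dose_mg_day",
    *COMEDS,
    "scn1a",
)

_BINARY_COLUMNS = ("female", "intellectual_disability", *COMEDS)


def covariates_from_row(row) -> PatientCovariates:
    """Build a :class:`PatientCovariates` from one canonical-table row."""
    return PatientCovariates(
        age=float(row["age_years"]),
        female=bool(int(row["female"])),
        seizure_locus=str(row["seizure_locus"]),
        seizure_type=str(row["seizure_type"]),
        intellectual_disability=bool(int(row["intellectual_disability"])),
        comeds=frozenset(d for d in COMEDS if int(row[d])),
        scn1a=str(row["scn1a"]),
    )


def add_predicted_conc(df: pd.DataFrame, config: PKConfig = DEFAULT_PK_CONFIG) -> pd.DataFrame:
    """Attach the model-predicted exposure as a ``conc`` column (μg/ml)."""
    out = df.copy()
    conc = np.empty(len(df))
    for i, (_, row) in enumerate(df.iterrows()):
        cov = covariates_from_row(row)
        regimen = DosingRegimen(daily_dose=float(row["dose_mg_day"]), tau=config.tau)
        conc[i] = predict_trough(regimen, cov, config)
    out["conc"] = conc
    return out


def _check_enum(df, col, allowed, path):
    bad = ~df[col].isin(allowed)
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 1
        raise TableValidationError(
            f"invalid value {df[col].iloc[row - 1]!r} (allowed: {sorted(allowed)}) in {path}",
            row=row,
            column=col,
        )


def read_patient_table(path, pk_config: PKConfig = DEFAULT_PK_CONFIG) -> pd.DataFrame:
    """Read and validate a patient CSV; derive ``responder`` and ``conc``.

    Raises :class:`TableValidationError` naming the first offending row
    (1-based, excluding the header) and column.
    """
    df = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise TableValidationError(f"missing required column in {path}", column=col)
    if df["patient_id"].isna().any() or (df["patient_id"].astype(str).str.len() == 0).any():
        row = int(np.flatnonzero(df["patient_id"].isna())[0]) + 1
        raise TableValidationError("empty patient id", row=row, column="patient_id")
    for col in ("age_years", "dose_mg_day"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~np.isfinite(vals) | (vals <= 0)
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 1
            raise TableValidationError(
                f"{col} must be a positive finite number, got {df[col].iloc[row - 1]!r}",
                row=row,
                column=col,
            )
        df[col] = vals
    for col in _BINARY_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~vals.isin([0, 1])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise TableValidationError(
                f"{col} must be 0 or 1, got {df[col].iloc[row - 1]!r}", row=row, column=col
            )
        df[col] = vals.astype(int)
    _check_enum(df, "seizure_locus", SEIZURE_LOCI, path)
    _check_enum(df, "seizure_type", SEIZURE_TYPES, path)
    _check_enum(df, "scn1a", GENOTYPES, path)

    if "responder" in df.columns:
        vals = pd.to_numeric(df["responder"], errors="coerce")
        bad = ~vals.isin([0, 1])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise TableValidationError("responder must be 0 or 1", row=row, column="responder")
        df["responder"] = vals.astype(int)
    elif {"baseline_seizure_freq", "visit_seizure_freq"} <= set(df.columns):
        resp = np.empty(len(df), int)
        for i, (_, row) in enumerate(df.iterrows()):
            try:
                resp[i] = classify_response(
                    float(row["baseline_seizure_freq"]), float(row["visit_seizure_freq"])
                )
            except UndefinedResponseError as exc:
                raise TableValidationError(
                    str(exc), row=i + 1, column="baseline_seizure_freq"
                ) from exc
        df["responder"] = resp

    if "conc" not in df.columns:
        df = add_predicted_conc(df, pk_config)
    return df


def write_patient_table(df: pd.DataFrame, path) -> None:
    """Write a dataset in the canonical CSV dialect (round-trips with the reader)."""
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Model serialisation
# ---------------------------------------------------------------------------


def final_model_info() -> dict:
    """Packaged final-model description (parameters, spec, operating cut-off)."""
    with resources.files("vpapkpd.data").joinpath("final_model.json").open() as fh:
        return json.load(fh)


def final_model_parameters() -> PDParameters:
    """The published final-model estimates as a :class:`PDParameters`."""
    return PDParameters(**final_model_info()["parameters"])


def fit_result_to_json(result: FitResult, path=None) -> str:
    """Serialise a fit (estimates, SEs, objective, convergence) to JSON."""
    payload = {
        "model_spec": {
            "form": result.spec.form,
            "intercept_covariates": list(result.spec.intercept_covariates),
            "slope_covariates": list(result.spec.slope_covariates),
        },
        "estimates": result.estimates,
        "standard_errors": {
            k: (None if not np.isfinite(v) else v) for k, v in result.standard_errors.items()
        },
        "objective": result.objective,
        "converged": result.converged,
        "n_subjects": result.n_subjects,
        "n_records": result.n_records,
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def pd_parameters_from_json(path) -> PDParameters:
    """Load either a packaged-style or a fit-result JSON into PDParameters."""
    with open(path) as fh:
        payload = json.load(fh)
    if "parameters" in payload:
        return PDParameters(**payload["parameters"])
    spec = ModelSpec(
        form=payload["model_spec"]["form"],
        intercept_covariates=tuple(payload["model_spec"]["intercept_covariates"]),
        slope_covariates=tuple(payload["model_spec"]["slope_covariates"]),
    )
    result = FitResult(
        estimates=payload["estimates"],
        standard_errors={},
        objective=payload["objective"],
        converged=payload["converged"],
        n_subjects=payload["n_subjects"],
        n_records=payload["n_records"],
        spec=spec,
    )
    return result.to_pd_parameters()
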