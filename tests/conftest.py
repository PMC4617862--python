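"""Shared fixtures: small synthetic cohorts and reference parameter sets.

Everything is generated programmatically and seeded; tests that need the
full study conditions build them from the generator defaults, while tests
of the estimation machinery use a deliberately moderate truth (balanced
response, modest random effect) so that likelihood-based checks are not
confounded by the saturation inherent to the published effect sizes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from vpapkpd.pd_model import ModelSpec, PDParameters
from vpapkpd.synth import CohortConfig, generate_cohort


#: Balanced, well-identified truth for machinery tests: response probability
#: spans mid-range over the cohort's concentration spread.
MODERATE_TRUTH = PDParameters(intercept=0.5, slope=-2.0, omega2=1.0)

MODERATE_SPEC = ModelSpec()  # intercept + slope + omega2 only


def make_moderate_cohort(n_patients: int, seed: int, **overrides) -> pd.DataFrame:
    overrides.setdefault("true_params", MODERATE_TRUTH)
    cfg = CohortConfig(n_patients=n_patients, seed=seed, **overrides)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def moderate_cohort_60() -> pd.DataFrame:
    return make_moderate_cohort(60, seed=11)


@pytest.fixture(scope="session")
def study_cohort_77() -> pd.DataFrame:
    """Default study conditions: 77 patients, published truth."""
    return generate_cohort(CohortConfig(seed=5))


@pytest.fixture(scope="session")
def published_params() -> PDParameters:
    from vpapkpd.io import final_model_parameters

    return final_model_parameters()
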