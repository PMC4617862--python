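"""Mixed-effects logistic model: logit algebra, marginal likelihood
(Laplace vs Gauss–Hermite), analytic gradient, and fitting contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from tests.conftest import MODERATE_SPEC, MODERATE_TRUTH, make_moderate_cohort
from vpapkpd.domain import PatientCovariates, ResponseRecord
from vpapkpd.errors import InvalidComparisonError, InvalidInputError
from vpapkpd.pd_model import (
    FINAL_MODEL_SPEC,
    MixedEffectsLogit,
    ModelSpec,
    PDParameters,
    QuadraticPDParameters,
    _nll_grad_laplace,
    _prepare,
    _total_loglik,
    fit,
    inv_logit,
    linear_logit,
    objective_difference,
    quadratic_logit,
    subject_marginal_loglik,
)


class TestLogitAlgebra:
    def test_inv_logit_reference_values(self):
        assert inv_logit(0.0) == 0.5
        assert inv_logit(0.1) == pytest.approx(0.52498, abs=1e-5)

    @given(st.floats(-12, 12))
    @settings(max_examples=60, deadline=None)
    def test_logit_probability_round_trip(self, x):
        # 1e-9 is the genuine double-precision round-trip scale here; for
        # larger |logit| the 1-p term loses relative accuracy
        p = inv_logit(x)
        assert 0.0 < p < 1.0
        assert np.log(p / (1 - p)) == pytest.approx(x, abs=1e-9, rel=1e-12)
        assert inv_logit(-x) == pytest.approx(1.0 - p, abs=1e-12)

    @given(st.floats(-700, 700))
    @settings(max_examples=60, deadline=None)
    def test_inv_logit_stable_and_bounded(self, x):
        p = inv_logit(x)
        assert 0.0 <= p <= 1.0 and np.isfinite(p)

    def test_linear_logit_final_model_worked_example(self, published_params):
        # age 5, generalized seizures, PHT co-medication, G/G genotype:
        # A = 6.09 + 0.98*5 = 10.99, S = -(13.5 + 3.62) = -17.12, and at
        # 63.5 μg/ml the logit sits just above the 0.1 operating cut-off.
        cov = PatientCovariates(
            age=5, seizure_locus="generalized", comeds=frozenset({"PHT"}), scn1a="GG"
        )
        assert published_params.intercept_part(cov) == pytest.approx(10.99, abs=1e-9)
        assert published_params.slope_part(cov) == pytest.approx(-17.12, abs=1e-9)
        assert linear_logit(published_params, cov, 63.5) == pytest.approx(0.1188, abs=1e-4)

    def test_linear_logit_zero_concentration_gives_intercept_part(self, published_params):
        cov = PatientCovariates(age=10, scn1a="GA", comeds=frozenset({"CBZ"}))
        expected = published_params.intercept_part(cov) + 0.7
        assert linear_logit(published_params, cov, 0.0, eta=0.7) == pytest.approx(expected)

    def test_linear_logit_intercept_only(self):
        p = PDParameters(intercept=2.5)
        for conc in (0.0, 50.0, 200.0):
            assert linear_logit(p, PatientCovariates(age=3), conc, eta=1.1) == pytest.approx(3.6)

    def test_linear_logit_rejects_negative_concentration(self, published_params):
        with pytest.raises(InvalidInputError):
            linear_logit(published_params, PatientCovariates(age=5), -1.0)

    @pytest.mark.parametrize(
        "params, conc, eta, expected",
        [
            (QuadraticPDParameters(1.0, 0.5, -2.0), 50.0, 0.3, 1.3),  # vertex
            (QuadraticPDParameters(0.7, 0.2, 0.0), 120.0, 0.0, 0.7),  # flat
            (QuadraticPDParameters(1.0, 0.5, -2.0), 150.0, 0.0, -1.0),
        ],
    )
    def test_quadratic_logit(self, params, conc, eta, expected):
        assert quadratic_logit(params, conc, eta) == pytest.approx(expected, abs=1e-12)


def _random_subject(rng, n_max=12, omega2_max=16.0, n_min=1):
    n = int(rng.integers(n_min, n_max + 1))
    params = PDParameters(
        intercept=float(rng.normal(0, 2)),
        slope=float(rng.normal(-2, 2)),
        omega2=float(rng.uniform(0.05, omega2_max)),
    )
    cov = PatientCovariates(age=float(rng.uniform(1, 35)))
    records = [
        ResponseRecord("s", float(rng.uniform(10, 140)), int(rng.random() < 0.6))
        for _ in range(n)
    ]
    return params, cov, records


class TestMarginalLikelihood:
    def test_zero_variance_reduces_to_bernoulli(self):
        params = PDParameters(intercept=0.8, slope=-2.0, omega2=0.0)
        cov = PatientCovariates(age=7)
        records = [ResponseRecord("s", c, y) for c, y in [(30, 1), (80, 0), (120, 0)]]
        expected = sum(
            y * linear_logit(params, cov, c) - np.logaddexp(0, linear_logit(params, cov, c))
            for c, y in [(30, 1), (80, 0), (120, 0)]
        )
        for method in ("laplace", "quadrature"):
            assert subject_marginal_loglik(params, cov, records, method) == pytest.approx(
                expected, abs=1e-12
            )

    def test_single_record_laplace_close_to_quadrature(self):
        # modest random-effect variance: the Gaussian expansion is accurate
        params = PDParameters(intercept=0.4, slope=-1.5, omega2=0.2)
        cov = PatientCovariates(age=12)
        records = [ResponseRecord("s", 75.0, 1)]
        lap = subject_marginal_loglik(params, cov, records, "laplace")
        quad = subject_marginal_loglik(params, cov, records, "quadrature", n_quad=64)
        assert lap == pytest.approx(quad, abs=1e-3)

    def test_laplace_tracks_quadrature_on_randomised_subjects(self):
        rng = np.random.default_rng(2024)
        worst = 0.0
        for _ in range(40):
            params, cov, records = _random_subject(rng, omega2_max=0.5)
            lap = subject_marginal_loglik(params, cov, records, "laplace")
            quad = subject_marginal_loglik(params, cov, records, "quadrature", n_quad=64)
            worst = max(worst, abs(lap - quad))
        assert worst < 1e-2

    def test_laplace_degrades_gracefully_at_large_variance(self):
        """With omega2 up to 16 a Bernoulli posterior can be strongly skewed
        (sigmoid times wide Gaussian); the Laplace error grows to O(0.1) for
        multi-record subjects but stays bounded."""
        rng = np.random.default_rng(2025)
        worst = 0.0
        for _ in range(40):
            params, cov, records = _random_subject(rng, n_min=3, omega2_max=16.0)
            lap = subject_marginal_loglik(params, cov, records, "laplace")
            quad = subject_marginal_loglik(params, cov, records, "quadrature", n_quad=64)
            worst = max(worst, abs(lap - quad))
        assert worst < 0.2

    def test_quadrature_node_count_converged(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            params, cov, records = _random_subject(rng, omega2_max=1.0)
            q64 = subject_marginal_loglik(params, cov, records, "quadrature", n_quad=64)
            q128 = subject_marginal_loglik(params, cov, records, "quadrature", n_quad=128)
            assert q64 == pytest.approx(q128, abs=1e-8)

    def test_saturated_responders_approach_certainty(self):
        params = PDParameters(intercept=60.0, omega2=4.0)
        cov = PatientCovariates(age=5)
        records = [ResponseRecord("s", 50.0, 1) for _ in range(6)]
        assert subject_marginal_loglik(params, cov, records, "laplace") == pytest.approx(
            0.0, abs=1e-6
        )

    def test_vectorised_likelihood_matches_scalar_reference(self):
        """The fitting path's per-subject integration must agree with the
        record-at-a-time reference implementation."""
        df = make_moderate_cohort(12, seed=3)
        params = PDParameters(intercept=0.5, slope=-2.0, omega2=1.4)
        total = _total_loglik(
            np.array([0.5, -2.0, 0.5 * np.log(1.4)]), _prepare(df, MODERATE_SPEC),
            "linear", "laplace", 64,
        )
        scalar = 0.0
        for _, sub in df.groupby("patient_id"):
            cov = PatientCovariates(age=float(sub["age_years"].iloc[0]))
            records = [
                ResponseRecord("s", float(r["conc"]), int(r["responder"]))
                for _, r in sub.iterrows()
            ]
            scalar += subject_marginal_loglik(params, cov, records, "laplace")
        assert total == pytest.approx(scalar, rel=1e-10)

    def test_analytic_gradient_matches_finite_differences(self):
        df = make_moderate_cohort(25, seed=9)
        prep = _prepare(df, FINAL_MODEL_SPEC)
        rng = np.random.default_rng(1)
        theta = rng.normal(scale=0.4, size=prep.XA.shape[1] + prep.XS.shape[1] + 1)
        _, grad, _ = _nll_grad_laplace(theta, prep, "linear")
        for i in range(len(theta)):
            e = np.zeros_like(theta)
            e[i] = 1e-6
            fp, _, _ = _nll_grad_laplace(theta + e, prep, "linear")
            fm, _, _ = _nll_grad_laplace(theta - e, prep, "linear")
            assert grad[i] == pytest.approx((fp - fm) / 2e-6, rel=1e-5, abs=1e-6)


class TestFitting:
    def test_recovers_moderate_truth_within_sampling_error(self):
        df = make_moderate_cohort(200, seed=21)
        res = fit(df, MODERATE_SPEC, random_state=0)
        assert res.converged and res.se_finite()
        truth = {"intercept": 0.5, "slope": -2.0, "omega2": 1.0}
        for name, true_val in truth.items():
            z = abs(res.estimates[name] - true_val) / res.standard_errors[name]
            assert z < 4.0, f"{name}: {res.estimates[name]:.3f} vs {true_val} (z={z:.1f})"

    def test_nested_models_objective_monotone(self, moderate_cohort_60):
        reduced = fit(moderate_cohort_60, MODERATE_SPEC, random_state=0, compute_se=False)
        full = fit(
            moderate_cohort_60,
            ModelSpec(intercept_covariates=("age",)),
            random_state=0,
            compute_se=False,
        )
        assert full.objective <= reduced.objective + 1e-6
        assert objective_difference(reduced, full) >= -1e-6

    def test_duplicating_every_subject_doubles_objective(self):
        df = make_moderate_cohort(30, seed=13)
        twin = df.copy()
        twin["patient_id"] = twin["patient_id"] + "_dup"
        doubled = pd.concat([df, twin], ignore_index=True)
        res1 = fit(df, MODERATE_SPEC, random_state=0, compute_se=False)
        res2 = fit(doubled, MODERATE_SPEC, random_state=0, compute_se=False)
        assert res2.objective == pytest.approx(2.0 * res1.objective, rel=1e-6)

    def test_objective_difference_rejects_mismatched_datasets(self):
        a = fit(make_moderate_cohort(20, seed=1), MODERATE_SPEC, compute_se=False)
        b = fit(make_moderate_cohort(25, seed=2), MODERATE_SPEC, compute_se=False)
        with pytest.raises(InvalidComparisonError):
            objective_difference(a, b)

    def test_identical_fits_have_zero_difference(self, moderate_cohort_60):
        res = fit(moderate_cohort_60, MODERATE_SPEC, random_state=0, compute_se=False)
        assert objective_difference(res, res) == 0.0

    def test_estimator_probabilities_well_formed(self, moderate_cohort_60):
        est = MixedEffectsLogit()
        est.fit(moderate_cohort_60)
        proba = est.predict_proba(moderate_cohort_60)
        assert proba.shape == (len(moderate_cohort_60), 2)
        assert np.all((proba > 0) & (proba < 1))
        assert np.allclose(proba.sum(axis=1), 1.0)
        # row order must be preserved even for unsorted subject ids
        logits = est.predict_logit(moderate_cohort_60)
        shuffled = moderate_cohort_60.sample(frac=1.0, random_state=4)
        assert np.allclose(est.predict_logit(shuffled), logits[shuffled.index.to_numpy()])

    def test_variance_estimate_nonnegative(self, moderate_cohort_60):
        res = fit(moderate_cohort_60, MODERATE_SPEC, compute_se=False)
        assert res.omega2 >= 0.0

    def test_non_varying_covariate_rejected(self):
        df = make_moderate_cohort(15, seed=2)
        df["PHT"] = 0
        with pytest.raises(InvalidInputError):
            fit(df, ModelSpec(intercept_covariates=("PHT",)), compute_se=False)

    def test_separation_flagged(self):
        # responder perfectly determined by CBZ: unbounded coefficient
        df = make_moderate_cohort(30, seed=8)
        df["responder"] = df["CBZ"].to_numpy()
        with pytest.warns(RuntimeWarning):
            fit(df, ModelSpec(intercept_covariates=("CBZ",)), random_state=0)

    def test_quadratic_form_recovers_vertex(self):
        # regenerate the outcome from a quadratic truth so the vertex is
        # identifiable inside the observed exposure range
        df = make_moderate_cohort(60, seed=17)
        rng = np.random.default_rng(3)
        ids, subj = np.unique(df["patient_id"], return_inverse=True)
        eta = rng.normal(0, np.sqrt(0.5), size=len(ids))
        c = df["conc"].to_numpy() / 100.0
        logit = 2.0 - 6.0 * (c - 0.6) ** 2 + eta[subj]
        df = df.assign(responder=(rng.random(len(df)) < expit(logit)).astype(int))
        res = fit(df, ModelSpec(form="quadratic"), random_state=0, compute_se=False)
        assert res.converged
        assert set(res.estimates) == {"theta1", "theta2", "theta3", "omega2"}
        assert res.estimates["theta3"] < 0
        assert 0.3 < res.estimates["theta2"] < 0.9

    def test_final_model_fit_maps_to_pd_parameters(self, study_cohort_77):
        res = fit(study_cohort_77, FINAL_MODEL_SPEC, random_state=0, compute_se=False)
        params = res.to_pd_parameters()
        cov = PatientCovariates(age=10.0, seizure_locus="partial", scn1a="GA")
        row = pd.DataFrame(
            [
                {
                    "patient_id": "x",
                    "age_years": 10.0,
                    "female": 0,
                    "seizure_locus": "partial",
                    "seizure_type": "symptomatic",
                    "intellectual_disability": 0,
                    "dose_mg_day": 1000.0,
                    **{d: 0 for d in ("CBZ", "CZP", "CLB", "GBP", "LTG", "PB", "PHT", "TPM", "ZNS")},
                    "scn1a": "GA",
                    "conc": 70.0,
                    "responder": 0,
                }
            ]
        )
        assert res.population_logit(row)[0] == pytest.approx(
            linear_logit(params, cov, 70.0), rel=1e-10
        )
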