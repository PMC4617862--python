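"""ROC/Youden machinery against brute-force oracles, and closed-form
inversion of the fitted logit to the optimal trough concentration."""

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from vpapkpd.domain import PatientCovariates
from vpapkpd.errors import InvalidInputError
from vpapkpd.optimal import (
    OptimalConcentration,
    invert_linear,
    invert_linear_parts,
    invert_quadratic,
    roc,
    youden_cutoff,
)
from vpapkpd.pd_model import PDParameters, QuadraticPDParameters, linear_logit, quadratic_logit


def _brute_force_auc(scores, outcomes):
    """Pairwise concordance with half-credit ties, by explicit double loop."""
    pos = scores[outcomes == 1]
    neg = scores[outcomes == 0]
    total = conc = 0.0
    for a in pos:
        for b in neg:
            total += 1
            if a > b:
                conc += 1
            elif a == b:
                conc += 0.5
    return conc / total


def _brute_force_youden(scores, outcomes):
    """Exhaustive scan of observed thresholds; ties to the smallest."""
    best_j, best_t = -np.inf, None
    for t in np.unique(scores):
        sens = np.mean(scores[outcomes == 1] >= t)
        spec = np.mean(scores[outcomes == 0] < t)
        j = sens + spec - 1
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return best_t, best_j


class TestROC:
    def test_perfect_separation(self):
        res = roc([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0], compute_ci=False)
        assert res.auc == 1.0
        assert res.youden_cutoff == 0.8  # smallest maximising observed threshold
        assert res.sens_at_cutoff == 1.0 and res.spec_at_cutoff == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_auc_equals_pairwise_concordance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 40))
        # coarse grid to force ties
        scores = rng.choice(np.linspace(-2, 2, 7), size=n)
        outcomes = rng.integers(0, 2, size=n)
        if len(np.unique(outcomes)) < 2:
            outcomes[0], outcomes[1] = 0, 1
        res = roc(scores, outcomes, compute_ci=False)
        assert res.auc == pytest.approx(_brute_force_auc(scores, outcomes), abs=1e-12)
        assert res.auc == pytest.approx(roc_auc_score(outcomes, scores), abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_youden_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(100 + seed)
        scores = rng.normal(size=30) + rng.integers(0, 2, 30)
        outcomes = rng.integers(0, 2, 30)
        outcomes[:2] = [0, 1]
        res = roc(scores, outcomes, compute_ci=False)
        t, j = _brute_force_youden(scores, outcomes)
        assert youden_cutoff(res) == pytest.approx(t)
        # optimality: J at the cut-off beats J at every observed logit
        assert res.sens_at_cutoff + res.spec_at_cutoff - 1 == pytest.approx(j)

    def test_tie_broken_toward_smaller_threshold(self):
        # thresholds 2 and 3 both achieve J = 0.5; the smaller must win
        res = roc([1.0, 2.0, 2.0, 3.0], [0, 1, 0, 1], compute_ci=False)
        assert res.youden_cutoff == 2.0

    def test_uninformative_scores_give_half_auc(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=4000)
        outcomes = rng.integers(0, 2, size=4000)
        res = roc(scores, outcomes, compute_ci=False)
        assert res.auc == pytest.approx(0.5, abs=0.04)

    def test_bootstrap_ci_brackets_auc(self):
        rng = np.random.default_rng(3)
        scores = np.concatenate([rng.normal(1, 1, 150), rng.normal(0, 1, 150)])
        outcomes = np.r_[np.ones(150, int), np.zeros(150, int)]
        res = roc(scores, outcomes, n_boot=500, seed=1)
        lo, hi = res.auc_ci
        assert lo < res.auc < hi
        assert 0 < lo and hi <= 1

    def test_single_class_rejected(self):
        with pytest.raises(InvalidInputError):
            roc([0.1, 0.2], [1, 1], compute_ci=False)


class TestInvertLinear:
    def test_published_worked_examples(self, published_params):
        # six simulated patients: generalized seizures + PHT, by age and genotype
        cases = [
            (5, "GG", 63.5),
            (5, "GA", 71.3),
            (5, "AA", 78.5),
            (10, "GG", 92.0),
            (10, "GA", 140.9),
            (10, "AA", 142.4),
        ]
        for age, geno, printed in cases:
            cov = PatientCovariates(
                age=age, seizure_locus="generalized", comeds=frozenset({"PHT"}), scn1a=geno
            )
            opt = invert_linear(published_params, cov, 0.1)
            assert opt.status == "attainable"
            assert opt.value == pytest.approx(printed, abs=1.0)

    def test_genotype_ordering_of_optima(self, published_params):
        # A-allele carriers need higher exposure for the same response target
        values = []
        for geno in ("GG", "GA", "AA"):
            cov = PatientCovariates(
                age=5, seizure_locus="generalized", comeds=frozenset({"PHT"}), scn1a=geno
            )
            values.append(invert_linear(published_params, cov, 0.1).value)
        assert values[0] <= values[1] <= values[2]

    def test_round_trip_identity(self, published_params):
        cov = PatientCovariates(
            age=8, seizure_locus="generalized", comeds=frozenset({"PHT"}), scn1a="GA"
        )
        opt = invert_linear(published_params, cov, 0.1)
        assert linear_logit(published_params, cov, opt.value) == pytest.approx(0.1, abs=1e-10)

    @given(
        a=st.floats(-10, 10),
        s=st.floats(-20, 20),
        cut=st.floats(-3, 3),
    )
    @settings(max_examples=200, deadline=None)
    def test_inversion_statuses_consistent(self, a, s, cut):
        assume(s == 0 or abs(s) > 1e-3)  # avoid catastrophic cancellation at s ~ 0
        opt = invert_linear_parts(a, s, cut)
        if opt.status == "attainable":
            assert opt.value > 0
            assert a + s * opt.value / 100.0 == pytest.approx(cut, abs=1e-9)
        elif opt.status == "any_concentration":
            assert s >= 0 and a >= cut
        else:  # unattainable
            assert (s <= 0 and a <= cut) or (s == 0 and a < cut)

    def test_rising_slope_crossing(self):
        opt = invert_linear_parts(-1.0, 2.0, 0.0)
        assert opt.status == "attainable"
        assert opt.value == pytest.approx(50.0)

    def test_flat_below_cut_unattainable(self):
        assert invert_linear_parts(-1.0, 0.0, 0.0).status == "unattainable"

    def test_always_above_cut(self):
        assert invert_linear_parts(2.0, 1.0, 0.1).status == "any_concentration"


class TestInvertQuadratic:
    def test_smallest_positive_root(self):
        p = QuadraticPDParameters(theta1=1.0, theta2=0.5, theta3=-2.0)
        opt = invert_quadratic(p, 0.0)
        assert opt.status == "attainable"
        assert opt.value == pytest.approx(100 * (0.5 + np.sqrt(0.5)), abs=1e-9)
        assert quadratic_logit(p, opt.value) == pytest.approx(0.0, abs=1e-10)

    def test_negative_discriminant_unattainable(self):
        p = QuadraticPDParameters(theta1=-1.0, theta2=0.5, theta3=-2.0)
        assert invert_quadratic(p, 0.0).status == "unattainable"

    def test_degenerate_curvature_constant_model(self):
        assert invert_quadratic(QuadraticPDParameters(1.0, 0.5, 0.0), 0.0).status == (
            "any_concentration"
        )
        assert invert_quadratic(QuadraticPDParameters(-1.0, 0.5, 0.0), 0.0).status == (
            "unattainable"
        )

    def test_attainable_requires_positive_value(self):
        with pytest.raises(InvalidInputError):
            OptimalConcentration(value=-5.0, status="attainable")
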