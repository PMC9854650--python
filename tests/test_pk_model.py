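"""Structural model, solver and error-model checks."""

import numpy as np
import pytest

from amikpk.pk_model import (
    CovariateRelationship,
    DoseEvent,
    ErrorModel,
    IndividualParams,
    StructuralParams,
    apply_covariate_model,
    apply_relationship,
    concentration_profile,
    predict_amounts,
    predict_concentrations,
    residual_sd,
    total_error_sd,
)
from conftest import ode_concentrations


class TestCovariateModel:
    def test_normalization_identity(self):
        p = StructuralParams(CL1=4.41, CL2=0.72, V1=20.40, Vp=16.32)
        ind = apply_covariate_model(p, egfr=70.0, tbw=76.5)
        assert ind.CL == pytest.approx(4.41)
        assert ind.V == pytest.approx(20.40)
        assert ind.Vp == pytest.approx(16.32)
        assert ind.Q == pytest.approx(5.43)

    def test_power_and_linear_scaling(self):
        p = StructuralParams(CL1=4.41, CL2=0.72, V1=20.40, Vp=16.32)
        ind = apply_covariate_model(p, egfr=280.0, tbw=153.0)
        assert ind.CL == pytest.approx(4.41 * 4.0**0.72)
        assert ind.V == pytest.approx(2 * 20.40)

    def test_nonpositive_covariates_rejected(self):
        p = StructuralParams(CL1=4.41, CL2=0.72, V1=20.40, Vp=16.32)
        with pytest.raises(ValueError):
            apply_covariate_model(p, egfr=0.0, tbw=76.5)
        with pytest.raises(ValueError):
            apply_covariate_model(p, egfr=70.0, tbw=-2.0)


class TestRelationshipForms:
    def test_power_normalizes_at_median(self):
        rel = CovariateRelationship("power", "EGFR", covariate_median=70.0, p2=0.72)
        assert apply_relationship(rel, 4.41, 70.0) == pytest.approx(4.41)

    def test_binary_linear_reference_class(self):
        rel = CovariateRelationship("binary_linear", "RRT", p2=2.5)
        assert apply_relationship(rel, 4.0, 0.0) == pytest.approx(4.0)
        assert apply_relationship(rel, 4.0, 1.0) == pytest.approx(6.5)

    def test_binary_exponential(self):
        rel = CovariateRelationship("binary_exponential", "RRT", p2=0.5)
        assert apply_relationship(rel, 4.0, 1.0) == pytest.approx(2.0)

    def test_allometric_fixed_exponent(self):
        rel = CovariateRelationship("allometric", "WT", covariate_median=76.5,
                                    allometric_exponent=0.75)
        assert apply_relationship(rel, 4.0, 153.0) == pytest.approx(4.0 * 2**0.75)

    def test_unknown_form_rejected(self):
        with pytest.raises(ValueError):
            CovariateRelationship("quadratic", "WT")

    def test_binary_covariate_domain(self):
        rel = CovariateRelationship("binary_linear", "RRT", p2=1.0)
        with pytest.raises(ValueError):
            apply_relationship(rel, 4.0, 0.5)


class TestSolver:
    def test_matches_ode_oracle_median_patient(self, median_patient, single_dose):
        times = np.array([0.25, 0.5, 1.0, 6.0, 24.0])
        ours = predict_concentrations(median_patient, single_dose, times)
        oracle = ode_concentrations(median_patient, single_dose, times)
        np.testing.assert_allclose(ours, oracle, rtol=1e-7)
        # C1h of a 2 g dose sits in the cohort's observed central range
        assert 50.0 < ours[2] < 90.0

    def test_zero_amount_gives_zero(self, median_patient):
        conc = predict_concentrations(
            median_patient, [DoseEvent(0.0, 0.0, 0.5)], [1.0, 2.0]
        )
        assert np.all(conc == 0.0)

    def test_dose_linearity(self, median_patient):
        times = [0.5, 1.0, 8.0]
        c1 = predict_concentrations(median_patient, [DoseEvent(0.0, 1000.0, 0.5)], times)
        c2 = predict_concentrations(median_patient, [DoseEvent(0.0, 2000.0, 0.5)], times)
        np.testing.assert_allclose(c2, 2.0 * c1, rtol=1e-12)

    def test_superposition_of_two_doses(self, median_patient):
        times = np.linspace(0.1, 48.0, 40)
        both = predict_concentrations(
            median_patient,
            [DoseEvent(0.0, 2000.0, 0.5), DoseEvent(12.0, 1500.0, 0.5)],
            times,
        )
        first = predict_concentrations(median_patient, [DoseEvent(0.0, 2000.0, 0.5)], times)
        second = predict_concentrations(median_patient, [DoseEvent(12.0, 1500.0, 0.5)], times)
        np.testing.assert_allclose(both, first + second, rtol=1e-9)

    def test_mass_balance_without_elimination(self):
        ind = IndividualParams(CL=0.0, V=20.4, Vp=16.32, Q=5.43)
        a1, a2 = predict_amounts(ind, [DoseEvent(0.0, 2000.0, 0.5)], [1.0, 12.0, 48.0])
        np.testing.assert_allclose(a1 + a2, 2000.0, rtol=1e-6)

    def test_continuity_at_infusion_end_and_decay(self, median_patient, single_dose):
        eps = 1e-7
        around_end = predict_concentrations(
            median_patient, single_dose, [0.5 - eps, 0.5 + eps]
        )
        assert around_end[1] == pytest.approx(around_end[0], rel=1e-4)
        late = predict_concentrations(
            median_patient, single_dose, np.linspace(6.0, 48.0, 200)
        )
        assert np.all(np.diff(late) < 0)

    def test_input_validation(self, median_patient, single_dose):
        with pytest.raises(ValueError):
            predict_concentrations(median_patient, single_dose, [-1.0, 1.0])
        with pytest.raises(ValueError):
            predict_concentrations(median_patient, single_dose, [2.0, 1.0])
        with pytest.raises(ValueError):
            DoseEvent(0.0, -100.0, 0.5)
        with pytest.raises(ValueError):
            DoseEvent(0.0, 100.0, 0.0)

    def test_vectorized_profile_matches_scalar(self, median_patient, single_dose):
        times = [1.0, 24.0, 48.0]
        scalar = predict_concentrations(median_patient, single_dose, times)
        cl = np.array([4.41, 2.0])
        v = np.array([20.40, 15.0])
        vp = np.array([16.32, 30.0])
        q = np.array([5.43, 5.43])
        vec = concentration_profile(cl, v, vp, q, single_dose, times)
        np.testing.assert_allclose(vec[0], scalar, rtol=1e-12)
        other = IndividualParams(CL=2.0, V=15.0, Vp=30.0, Q=5.43)
        np.testing.assert_allclose(
            vec[1], predict_concentrations(other, single_dose, times), rtol=1e-12
        )

    def test_rate_constant_parameterization(self, single_dose):
        # CL and Q read as first-order rate constants: k10 = CL, k12 = Q,
        # k21 = Q·V/Vp — equivalent to clearances CL·V and Q·V at same Vp
        ind = IndividualParams(CL=0.216, V=20.4, Vp=16.32, Q=0.266)
        ours = predict_concentrations(ind, single_dose, [1.0, 12.0],
                                      parameterization="rate_constant")
        clearance_ind = IndividualParams(CL=0.216 * 20.4, V=20.4,
                                         Vp=16.32, Q=0.266 * 20.4)
        ref = predict_concentrations(clearance_ind, single_dose, [1.0, 12.0])
        np.testing.assert_allclose(ours, ref, rtol=1e-12)


class TestErrorModel:
    def test_sd_polynomial(self):
        em = ErrorModel(kind="gamma", noise=1.5, c0=1.25, c1=0.05)
        assert residual_sd(0.0, em) == pytest.approx(1.25)
        assert residual_sd(100.0, em) == pytest.approx(6.25)

    def test_gamma_scaling(self):
        em = ErrorModel(kind="gamma", noise=1.5, c0=1.25, c1=0.05)
        assert total_error_sd(0.0, em) == pytest.approx(1.875)
        em1 = ErrorModel(kind="gamma", noise=1.0, c0=1.25, c1=0.05)
        obs = np.array([0.0, 10.0, 80.0])
        np.testing.assert_allclose(total_error_sd(obs, em1), residual_sd(obs, em1))

    def test_lambda_additive(self):
        em = ErrorModel(kind="lambda", noise=2.0, c0=1.25, c1=0.05)
        assert total_error_sd(0.0, em) == pytest.approx(np.sqrt(1.25**2 + 4.0))
        em0 = ErrorModel(kind="lambda", noise=0.0, c0=1.25, c1=0.05)
        assert total_error_sd(30.0, em0) == pytest.approx(residual_sd(30.0, em0))

    def test_degenerate_polynomial_rejected(self):
        em = ErrorModel(kind="gamma", noise=1.0, c0=-1.0, c1=0.0)
        with pytest.raises(ValueError):
            residual_sd(5.0, em)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ErrorModel(kind="epsilon", noise=1.0)
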