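"""Nyboer inversion, pump reference values and protocol-level analysis."""
import math

import numpy as np
import pytest

import wristbia as wb
from wristbia.diameter import PulsatileDecomposition, run_group_experiment, _ols_fit
from wristbia.errors import (
    ConfigurationError,
    EstimationError,
    GridMismatchError,
    ProtocolError,
)
from wristbia.synthetic import NO_NOISE, PhantomSpec, generate_group_experiment


class TestAreaChange:
    def test_no_change_gives_zero(self):
        assert wb.area_change_from_resistance(130.0, 130.0, 0.018, 0.72) == 0.0

    def test_matches_exact_algebra(self):
        # oracle: -l*(rt-r0)/(sigma*r0*rt) computed by hand
        got = wb.area_change_from_resistance(130.0, 131.0, 0.018, 0.72)
        assert got == pytest.approx(-0.018 * 1.0 / (0.72 * 130.0 * 131.0), rel=1e-12)
        assert got == pytest.approx(-1.468e-6, rel=1e-3)
        assert got < 0  # contraction

    def test_exact_inverse_of_parallel_forward_model(self):
        r0, l, sig = 104.0, 0.018, 0.7283
        for da in (-3.7e-6, -1e-7, 2e-6):
            rt = 1.0 / (1.0 / r0 + sig * da / l)
            assert wb.area_change_from_resistance(r0, rt, l, sig) == pytest.approx(
                da, rel=1e-12)

    def test_nonpositive_resistance_rejected(self):
        with pytest.raises(ConfigurationError):
            wb.area_change_from_resistance(-1.0, 130.0, 0.018, 0.72)


class TestDiameterFromArea:
    def test_unit_circle(self):
        assert wb.diameter_from_area(math.pi / 4.0) == pytest.approx(1.0, rel=1e-12)

    def test_printed_basal_area(self):
        # A0 = pi d0^2/4 of the 3.98 mm rod is about 12.44 mm^2
        assert wb.diameter_from_area(12.44e-6) == pytest.approx(3.98e-3, abs=5e-6)

    def test_zero_area(self):
        assert wb.diameter_from_area(0.0) == 0.0

    def test_negative_area_is_estimation_failure(self):
        with pytest.raises(EstimationError):
            wb.diameter_from_area(-1e-9)


class TestPumpReference:
    def test_printed_area_change(self):
        assert wb.reference_area_change(647.83e-9, 0.175) * 1e6 == pytest.approx(
            3.7019, abs=5e-5)

    def test_zero_volume(self):
        assert wb.reference_area_change(0.0, 0.175) == 0.0

    def test_small_step_division(self):
        assert wb.reference_area_change(80.98e-9, 0.175) * 1e6 == pytest.approx(
            80.98 / 175.0, rel=1e-12)

    @pytest.mark.parametrize("dv_mm3,d_mm", [
        (80.98, 3.91), (161.96, 3.83), (242.94, 3.75), (323.92, 3.67),
        (404.90, 3.59), (485.88, 3.51), (566.86, 3.42), (647.84, 3.34),
        (728.82, 3.25), (809.80, 3.15),
    ])
    def test_group_b_reference_diameters(self, table4_experiment, dv_mm3, d_mm):
        got = wb.reference_diameter(table4_experiment, dv_mm3 * 1e-9)
        assert round(got * 1e3, 2) == d_mm

    def test_zero_withdrawal_returns_d0(self, table4_experiment):
        assert wb.reference_diameter(table4_experiment, 0.0) == pytest.approx(
            3.98e-3, rel=1e-12)

    def test_excessive_withdrawal_rejected(self, table4_experiment):
        with pytest.raises(ConfigurationError):
            wb.reference_diameter(table4_experiment, 3e-6)

    def test_syringe_consistency_enforced(self):
        d_s = 0.012
        a_s = math.pi * d_s ** 2 / 4.0
        wb.PumpExperiment(d0=3.98e-3, artery_length=0.175, steps=(80.98e-9,),
                          syringe_inner_diameter=d_s,
                          plunger_displacements=(80.98e-9 / a_s,))
        with pytest.raises(ConfigurationError):
            wb.PumpExperiment(d0=3.98e-3, artery_length=0.175, steps=(80.98e-9,),
                              syringe_inner_diameter=d_s,
                              plunger_displacements=(1.0,))


class TestPercentError:
    def test_equal_values(self):
        assert wb.percent_error(3.34, 3.34) == 0.0

    def test_direct_formula(self):
        assert wb.percent_error(3.34, 3.4593) == pytest.approx(3.57, abs=0.005)

    def test_symmetric_deviations(self):
        assert wb.percent_error(3.0, 3.2) == pytest.approx(wb.percent_error(3.0, 2.8))

    def test_scale_invariance(self):
        assert wb.percent_error(3.34, 3.1) == pytest.approx(
            wb.percent_error(334.0, 310.0), rel=1e-12)


class TestPulsatileDecomposition:
    def test_parallel_identity_holds(self):
        d = PulsatileDecomposition(r0=130.0, rt=131.7)
        assert 1.0 / d.rt == pytest.approx(1.0 / d.r0 + 1.0 / d.rp, rel=1e-10)

    def test_open_branch_is_sentinel_not_infinity(self):
        d = PulsatileDecomposition(r0=130.0, rt=130.0)
        assert d.is_open and d.rp is None


class TestEstimateDiameter:
    def _sweep(self, r, c=1e-10, grid=None):
        from wristbia.synthetic import generate_mfia_sweep
        return generate_mfia_sweep(r, c, grid)

    def test_identical_sweeps_return_basal_diameter(self):
        a0 = 12.44e-6
        sweep = self._sweep(104.0)
        est = wb.estimate_diameter(sweep, sweep, 0.018, 0.7283, a0)
        assert est.sd == 0.0
        assert est.mean == pytest.approx(2 * math.sqrt(a0 / math.pi), rel=1e-12)

    def test_recovers_generator_truth_per_frequency(self, spec, group_b_noise_free):
        b = group_b_noise_free
        truth = b.manifest["d_true_mm"].to_numpy() * 1e-3
        for k, sweep in enumerate(b.step_sweeps):
            est = wb.estimate_diameter(b.basal_sweep, sweep, b.l_pu,
                                       spec.blood_sigma, spec.basal_area)
            np.testing.assert_allclose(est.diameters, truth[k], rtol=1e-9)

    def test_scalar_chain_oracle(self):
        # independent forward/inverse chain at one R0 and area change
        r0, l, sig, a0 = 104.23, 0.018, 0.7283, 12.44236e-6
        da = -3.7019e-6
        rt = 1.0 / (1.0 / r0 + sig * da / l)
        est = wb.estimate_diameter(self._sweep(r0, 0.0), self._sweep(rt, 0.0),
                                   l, sig, a0)
        assert est.mean * 1e3 == pytest.approx(3.34, abs=0.005)

    def test_mismatched_grids_rejected(self):
        s1 = self._sweep(104.0)
        s2 = self._sweep(104.0, grid=np.logspace(3, 6, 5))
        with pytest.raises(GridMismatchError):
            wb.estimate_diameter(s1, s2, 0.018, 0.7283, 12.44e-6)

    def test_negative_area_frequencies_excluded_and_logged(self, caplog):
        import logging
        r0 = np.full(10, 104.0)
        rt = r0.copy()
        rt[0] = 300.0  # absurd jump -> negative area at the first frequency
        rt[1:] += 0.001
        with caplog.at_level(logging.WARNING, logger="wristbia.diameter"):
            est = wb.estimate_diameter(self._sweep(r0), self._sweep(rt),
                                       0.018, 0.7283, 1e-7)
        assert len(est.excluded) == 1
        assert np.isnan(est.diameters[0])
        assert any("excluded" in r.message for r in caplog.records)

    def test_withdrawal_shrinks_estimated_diameter(self, spec, group_b_noise_free):
        b = group_b_noise_free
        est = wb.estimate_diameter(b.basal_sweep, b.step_sweeps[0], b.l_pu,
                                   spec.blood_sigma, spec.basal_area)
        assert est.mean < spec.artery_diameter


class TestGroupExperiment:
    def test_noise_free_group_b_percent_error_vanishes(self, spec, group_b_noise_free):
        b = group_b_noise_free
        res = run_group_experiment(b.experiment, b.basal_sweep,
                                   list(b.step_sweeps), l_pu=b.l_pu,
                                   sigma_b=spec.blood_sigma)
        assert res.table["pe_percent"].max() < 1e-6
        assert len(res.table) == 10

    def test_resistance_rises_monotonically_with_withdrawal(self, group_b_noise_free):
        rt = group_b_noise_free
        res_rt = [s.resistances().mean() for s in rt.step_sweeps]
        assert all(np.diff(res_rt) > 0)
        assert res_rt[0] > rt.basal_sweep.resistances().mean()

    def test_area_conserving_pe_has_positive_quadratic_curvature(self, spec):
        b = generate_group_experiment(spec, "B", NO_NOISE, mode="area_conserving")
        res = run_group_experiment(b.experiment, b.basal_sweep,
                                   list(b.step_sweeps), l_pu=b.l_pu,
                                   sigma_b=spec.blood_sigma)
        assert res.pe_fit_quadratic.coefficients[0] > 0
        # cross-check the fit with an independent normal-equation solve
        x = res.table["dv_mm3"].to_numpy()
        y = res.table["pe_percent"].to_numpy()
        design = np.vander(x, 3)
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        np.testing.assert_allclose(res.pe_fit_quadratic.coefficients, beta,
                                   rtol=1e-6)
        assert res.pe_fit_quadratic.r_squared > res.pe_fit_linear.r_squared

    def test_missing_sweeps_rejected(self, spec, group_b_noise_free):
        b = group_b_noise_free
        with pytest.raises(ProtocolError):
            run_group_experiment(b.experiment, b.basal_sweep,
                                 list(b.step_sweeps)[:-1], l_pu=b.l_pu,
                                 sigma_b=spec.blood_sigma)

    def test_r_squared_of_perfect_line_is_one(self):
        fit = _ols_fit(np.arange(5.0), 2.0 * np.arange(5.0) + 1.0, 1)
        assert fit.r_squared == pytest.approx(1.0)
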