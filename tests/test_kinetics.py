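"""Fluid-space model simulation: closed forms, covariates, derived quantities."""

import math

import numpy as np
import pytest

from catvk.dataio import InfusionSchedule, schedule_from_prescription
from catvk.kinetics import (GROUP_2VOFS, INDIVIDUAL_PARAMS, CategoricalEffect,
                            ContinuousEffect, CovariateModel, KineticsError,
                            ModelKind, VKParams, apply_covariates,
                            auc_expansion, half_life, simulate)


def _random_params(rng, kind):
    vc = rng.uniform(20, 400)
    k10 = 10 ** rng.uniform(-3, -1.3)
    if kind is ModelKind.ONE_VOFS:
        return VKParams(kind, vc, k10)
    return VKParams(kind, vc, k10, 10 ** rng.uniform(-2, 0.3),
                    10 ** rng.uniform(-2, 0.3))


class TestSimulate:
    def test_zero_rate_gives_zero_dilution(self):
        sch = InfusionSchedule(((0.0, 15.0, 0.0),))
        c = simulate(GROUP_2VOFS, sch, np.arange(0, 181.0, 5.0))
        np.testing.assert_array_equal(c.dilution, 0.0)

    def test_one_volume_closed_form_value(self):
        # tetrastarch justified model: x1(15) = (R0/k10)(1 − e^{−0.105})
        p = INDIVIDUAL_PARAMS["HES"]
        sch = schedule_from_prescription(5.0, 4.79, 15.0)
        c = simulate(p, sch, np.array([15.0]))
        r0 = sch.segments[0][2]
        expected = (r0 / p.k10) * (1 - math.exp(-p.k10 * 15))
        assert c.x1[-1] == pytest.approx(expected, rel=1e-12)
        assert c.x1[-1] == pytest.approx(22.74, abs=0.01)
        assert c.dilution[-1] == pytest.approx(0.283, abs=1e-3)

    def test_two_volume_group_end_of_bolus(self):
        # pooled-fluid model at the crystalloid study rate: ~0.30 dilution
        sch = schedule_from_prescription(20.0, 4.79, 15.0)
        c = simulate(GROUP_2VOFS, sch, np.array([15.0]))
        assert c.x1[-1] == pytest.approx(41.8, abs=0.3)
        assert c.dilution[-1] == pytest.approx(0.30, abs=0.01)

    @pytest.mark.parametrize("kind", [ModelKind.ONE_VOFS, ModelKind.TWO_VOFS])
    def test_closed_vs_numeric(self, kind, rng):
        """Exact segment-wise solution against the adaptive integrator."""
        sch = InfusionSchedule(((0.0, 15.0, 6.4), (60.0, 90.0, 0.5)))
        grid = np.arange(0.0, 181.0, 3.0)
        for _ in range(10):
            p = _random_params(rng, kind)
            a = simulate(p, sch, grid)
            b = simulate(p, sch, grid, method="numeric")
            scale = np.max(np.abs(b.x1)) or 1.0
            assert np.max(np.abs(a.x1 - b.x1)) / scale < 1e-8
            assert np.max(np.abs(a.x2 - b.x2)) / scale < 1e-8

    def test_volume_conservation(self, rng):
        grid = np.arange(0.0, 181.0, 1.0)
        sch = schedule_from_prescription(20.0, 4.79, 15.0)
        for _ in range(10):
            p = _random_params(rng, ModelKind.TWO_VOFS)
            c = simulate(p, sch, grid)
            np.testing.assert_allclose(c.infused,
                                       c.x1 + c.x2 + c.eliminated,
                                       atol=1e-9 * sch.total_volume)

    def test_superposition_in_rate(self):
        grid = np.arange(0.0, 181.0, 1.0)
        a = simulate(GROUP_2VOFS, schedule_from_prescription(10, 4.79, 15),
                     grid)
        b = simulate(GROUP_2VOFS, schedule_from_prescription(20, 4.79, 15),
                     grid)
        np.testing.assert_allclose(2 * a.dilution, b.dilution, rtol=1e-12)

    def test_steady_state_independent_of_distribution(self):
        """x1_ss = R0/k10 whatever k12/k21; x2_ss = (k12/k21)·x1_ss.

        The approach to steady state is governed by the slow eigenvalue
        λ1 ≈ −k10·k21/(k10+k12+k21), so the horizon scales with 1/|λ1|."""
        r0 = 0.5
        for k12, k21 in [(0.326, 0.19), (0.05, 0.4), (1.2, 0.08)]:
            p = VKParams(ModelKind.TWO_VOFS, 139, 0.007, k12, k21)
            lam_slow = p.k10 * k21 / (p.k10 + k12 + k21)
            horizon = 25.0 / lam_slow
            sch = InfusionSchedule(((0.0, horizon, r0),))
            c = simulate(p, sch, np.array([horizon]))
            assert c.x1[-1] == pytest.approx(r0 / p.k10, rel=1e-5)
            assert c.x2[-1] == pytest.approx((k12 / k21) * r0 / p.k10,
                                             rel=1e-5)

    def test_invalid_inputs(self):
        with pytest.raises(KineticsError):
            simulate(GROUP_2VOFS, InfusionSchedule(((0, 15, 1.0),)),
                     np.array([10.0, 5.0]))
        with pytest.raises(KineticsError):
            VKParams(ModelKind.ONE_VOFS, 100, 0.01, 0.3, 0.2)
        with pytest.raises(KineticsError):
            VKParams(ModelKind.TWO_VOFS, 100, 0.01)


class TestCovariates:
    def test_fluid_shift_on_central_volume(self):
        cm = CovariateModel(categorical=(
            CategoricalEffect("v_central", "fluid_type", "HS", -1.840),))
        p = apply_covariates(GROUP_2VOFS, cm, {"fluid_type": "HS"})
        assert p.v_central == pytest.approx(22.08, abs=0.01)
        unchanged = apply_covariates(GROUP_2VOFS, cm, {"fluid_type": "PLA"})
        assert unchanged.v_central == 139.0

    def test_map_power_on_distribution(self):
        cm = CovariateModel(continuous=(
            ContinuousEffect("k12", "MAP", 0.053, 84.0),))
        p = apply_covariates(GROUP_2VOFS, cm, {"MAP": 100.0})
        assert p.k12 / GROUP_2VOFS.k12 == pytest.approx(1.00929, abs=1e-5)
        ref = apply_covariates(GROUP_2VOFS, cm, {"MAP": 84.0})
        assert ref.k12 == GROUP_2VOFS.k12

    def test_zero_coefficient_is_identity(self):
        cm = CovariateModel(categorical=(
            CategoricalEffect("k10", "fluid_type", "HES", 0.0),))
        p = apply_covariates(GROUP_2VOFS, cm, {"fluid_type": "HES"})
        assert p == GROUP_2VOFS

    def test_missing_covariate_named(self):
        cm = CovariateModel(continuous=(
            ContinuousEffect("k12", "MAP", 0.053, 84.0),))
        with pytest.raises(KineticsError, match="MAP"):
            apply_covariates(GROUP_2VOFS, cm, {})


class TestDerivedQuantities:
    @pytest.mark.parametrize("k10,t_half", [
        (0.014, 49.51),                 # crystalloid: prints 49 min
        (math.log(2.0), 1.0),
        (0.007, 99.02),
    ])
    def test_half_life(self, k10, t_half):
        assert half_life(k10) == pytest.approx(t_half, abs=0.01)

    def test_half_life_domain(self):
        with pytest.raises(KineticsError):
            half_life(0.0)

    def test_auc_trivial(self):
        t = np.linspace(0, 100, 11)
        assert auc_expansion(t, np.full(11, 10.0)) == pytest.approx(1000.0)
        t = np.linspace(0, 60, 7)
        assert auc_expansion(t, 20 * t / 60) == pytest.approx(600.0)

    def test_auc_matches_analytic_integral(self):
        p = INDIVIDUAL_PARAMS["HES"]
        sch = schedule_from_prescription(5.0, 4.79, 15.0)
        grid = np.arange(0.0, 180.01, 0.05)
        c = simulate(p, sch, grid)
        # eliminated volume is k10 × exact ∫x1 dt
        assert auc_expansion(c.times, c.x1) == pytest.approx(
            c.eliminated[-1] / p.k10, rel=1e-3)

    def test_auc_unordered_rejected(self):
        with pytest.raises(KineticsError):
            auc_expansion([0, 10, 5], [0, 1, 2])
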