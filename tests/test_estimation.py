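"""Individual and population fits, model comparison, covariate search."""

import numpy as np
import pytest

from catvk.dataio import schedule_from_prescription
from catvk.dilution import DilutionSeries, dilution_series
from catvk.estimation import (EstimationError, PopulationFit, compare_models,
                              covariate_search, fit_individual,
                              fit_population, k10_from_urine)
from catvk.kinetics import (GROUP_2VOFS, CategoricalEffect, CovariateModel,
                            ModelKind, VKParams, simulate)
from catvk.synthcats import GeneratorConfig, generate_cohort

TIMES = np.array([0, 5, 10, 15, 20, 30, 40, 50, 60, 75, 90, 105, 120, 135,
                  150, 165, 180.0])


def _noise_free_series(params, schedule):
    d = simulate(params, schedule, TIMES).dilution
    return DilutionSeries("x", "PLA", TIMES, d, ["both"] * len(TIMES),
                          100.0, 7.0, 0.30)


class TestIndividualFit:
    def test_noise_free_one_volume_recovery(self):
        truth = VKParams(ModelKind.ONE_VOFS, 400.0, 0.003)
        sch = schedule_from_prescription(20, 4.79, 15)
        fit = fit_individual(_noise_free_series(truth, sch), sch,
                             ModelKind.ONE_VOFS, n_starts=5, seed=0)
        assert fit.params.v_central == pytest.approx(400.0, rel=1e-6)
        assert fit.params.k10 == pytest.approx(0.003, rel=1e-6)
        assert fit.residual_sd < 1e-8

    def test_noise_free_two_volume_recovery(self):
        sch = schedule_from_prescription(20, 4.79, 15)
        fit = fit_individual(_noise_free_series(GROUP_2VOFS, sch), sch,
                             ModelKind.TWO_VOFS, n_starts=10, seed=0)
        for name, truth in GROUP_2VOFS.as_dict().items():
            assert fit.params.as_dict()[name] == pytest.approx(truth,
                                                               rel=1e-4)

    def test_too_few_points_rejected(self):
        sch = schedule_from_prescription(20, 4.79, 15)
        t = np.array([0, 15, 30, 60, 120.0])
        d = simulate(GROUP_2VOFS, sch, t).dilution
        s = DilutionSeries("x", "PLA", t, d, ["both"] * 5, 100, 7, 0.3)
        with pytest.raises(EstimationError, match=">= 8"):
            fit_individual(s, sch, ModelKind.TWO_VOFS)

    def test_noisy_identified_combinations(self):
        """At study noise a single series pins the effective volume
        V_c(1+k12/k21) and, through urine, the product k10·V_c — not the
        individual parameters (the distribution transient is unsampled)."""
        ok_eff = ok_prod = 0
        n = 40
        for seed in range(n):
            cfg = GeneratorConfig(n_subjects=1, fluids=("PLA",), seed=seed)
            (rec,), ledger = generate_cohort(cfg)
            fit = fit_individual(dilution_series(rec), rec.schedule,
                                 ModelKind.TWO_VOFS, n_starts=6, seed=seed,
                                 urine_total=rec.urine_total)
            tr = ledger.records[0]["params"]
            e = fit.params.as_dict()
            veff = e["v_central"] * (1 + e["k12"] / e["k21"])
            veff_t = tr["v_central"] * (1 + tr["k12"] / tr["k21"])
            ok_eff += abs(veff / veff_t - 1) < 0.30
            prod = e["v_central"] * e["k10"]
            ok_prod += abs(prod / (tr["v_central"] * tr["k10"]) - 1) < 0.30
        assert ok_eff >= 0.75 * n
        assert ok_prod >= 0.70 * n


class TestUrineAnchor:
    def test_ratio(self):
        assert k10_from_urine(10.0, 1000.0) == pytest.approx(0.01)

    def test_scale_invariance(self):
        assert k10_from_urine(20.0, 2000.0) == k10_from_urine(10.0, 1000.0)

    def test_domain_errors(self):
        with pytest.raises(EstimationError):
            k10_from_urine(10.0, 0.0)
        with pytest.raises(EstimationError):
            k10_from_urine(0.0, 100.0)

    def test_study_scale_urine_gives_finite_k10(self):
        # study crystalloid urine 37.3 mL against a simulated expansion AUC
        sch = schedule_from_prescription(20, 4.79, 15)
        c = simulate(GROUP_2VOFS, sch, np.arange(0.0, 181.0, 1.0))
        auc = float(np.trapezoid(c.x1, c.times))
        k = k10_from_urine(37.3, auc)
        assert 0 < k < 1


class TestPopulationFit:
    def test_recovery_single_cohort(self, pla_subjects, pla_cohort):
        records, _ = pla_cohort
        pop = fit_population(pla_subjects, ModelKind.TWO_VOFS,
                             compute_ci=False,
                             urine_totals=[r.urine_total for r in records])
        for name, truth in GROUP_2VOFS.as_dict().items():
            assert pop.theta[name] == pytest.approx(truth, rel=0.30)
        assert pop.theta["v_central"] == pytest.approx(139.0, rel=0.25)
        assert pop.theta["k10"] == pytest.approx(0.007, rel=0.25)
        assert 0.01 < pop.residual_sd < 0.1
        assert np.isfinite(pop.minus_2ll)

    def test_cis_bracket_estimates(self, pla_subjects, pla_cohort):
        records, _ = pla_cohort
        pop = fit_population(pla_subjects, ModelKind.TWO_VOFS,
                             urine_totals=[r.urine_total for r in records])
        for name in ("v_central", "k10"):
            lo, hi = pop.theta_ci[name]
            assert lo < pop.theta[name] < hi

    def test_zero_iiv_shrinks_fitted_cvs(self, noise_free_cohort):
        records, _ = noise_free_cohort
        subjects = [(dilution_series(r), r.schedule, r.covariates())
                    for r in records]
        pop = fit_population(subjects, ModelKind.TWO_VOFS, compute_ci=False)
        assert all(cv < 5.0 for cv in pop.iiv_cv.values())

    def test_likelihood_invariant_to_subject_order(self, pla_subjects,
                                                   pla_cohort):
        """−2LL evaluated at a fixed parameter vector does not depend on the
        ordering of subjects (the per-subject computations are independent
        and the optimizer's conditional modes match subject-for-subject)."""
        import math

        from catvk.estimation import (_LaplaceObjective, _prepare_subjects)

        records, _ = pla_cohort
        ut = [r.urine_total for r in records]
        perm = [5, 2, 9, 0, 7, 1, 8, 3, 6, 4]

        def objective(subj, urine):
            sl, _covs, y, mask, times, r0, dur = _prepare_subjects(subj)
            anchors = np.full(len(sl), np.nan)
            for i, (s, u) in enumerate(zip(sl, urine)):
                t, d = s.valid()
                anchors[i] = math.log(u / np.trapezoid(np.maximum(d, 0), t))
            return _LaplaceObjective(y, mask, times, r0, dur,
                                     ModelKind.TWO_VOFS, [],
                                     anchor_log_ratios=anchors)

        xi = np.concatenate([np.log([140.0, 0.007, 0.3, 0.19]),
                             np.log([0.2, 0.2, 0.2, 0.2]),
                             [math.log(0.04)]])
        straight = objective(pla_subjects, ut)
        shuffled = objective([pla_subjects[i] for i in perm],
                             [ut[i] for i in perm])
        v1, v2 = straight(xi), shuffled(xi)
        assert v1 == pytest.approx(v2, abs=1e-9)
        # and the conditional modes are the same subject-for-subject
        np.testing.assert_allclose(straight.eta[perm], shuffled.eta,
                                   atol=1e-12)

    def test_too_few_subjects(self, pla_subjects):
        with pytest.raises(EstimationError, match="at least 4"):
            fit_population(pla_subjects[:3], ModelKind.TWO_VOFS)


class TestModelComparison:
    def _dummy(self, m2ll, n_params):
        return PopulationFit(
            model_kind=ModelKind.TWO_VOFS, theta={}, theta_ci={}, iiv_cv={},
            residual_sd=0.02, minus_2ll=m2ll, n_obs=160, n_params=n_params,
            covariates=[], empirical=[], eta=np.zeros((1, 1)),
            converged=True, seed=0, data_signature=(160, 1.0))

    def test_printed_reduction_justifies_richer_model(self):
        # the pooled-fluid analysis: 292 → 264, Δ = 28 > 6.64
        cmp_ = compare_models(self._dummy(292.0, 5), self._dummy(264.0, 9))
        assert cmp_.delta_minus_2ll == pytest.approx(28.0)
        assert cmp_.justified

    def test_boundary_is_strict(self):
        # delta exactly equal to the threshold does NOT justify the model
        cmp_ = compare_models(self._dummy(100.0, 5), self._dummy(92.0, 9),
                              threshold=8.0)
        assert cmp_.delta_minus_2ll == 8.0
        assert not cmp_.justified

    def test_different_data_rejected(self):
        a = self._dummy(100.0, 5)
        b = self._dummy(90.0, 9)
        b.data_signature = (150, 1.0)
        with pytest.raises(EstimationError, match="identical data"):
            compare_models(a, b)

    def test_non_nested_rejected(self):
        with pytest.raises(EstimationError, match="nest"):
            compare_models(self._dummy(100.0, 9), self._dummy(90.0, 5))

    def test_nesting_monotonicity(self, pla_subjects, pla_cohort):
        """With a nested warm start and no structural stabilizer, the richer
        model never fits worse (to optimizer tolerance)."""
        records, _ = pla_cohort
        ut = [r.urine_total for r in records]
        one = fit_population(pla_subjects, ModelKind.ONE_VOFS,
                             compute_ci=False, urine_totals=ut,
                             vc_stabilizer_sd=None)
        x1 = one.xi
        x0 = np.concatenate([[x1[0], x1[1], np.log(1e-3), np.log(0.2)],
                             [x1[2], x1[3], np.log(0.2), np.log(0.2)],
                             [x1[4]]])
        two = fit_population(pla_subjects, ModelKind.TWO_VOFS,
                             compute_ci=False, urine_totals=ut,
                             vc_stabilizer_sd=None, x0=x0)
        assert two.minus_2ll <= one.minus_2ll + 0.5


class TestCovariateSearch:
    def test_true_fluid_effect_selected(self):
        true_cov = CovariateModel(categorical=(
            CategoricalEffect("v_central", "fluid_type", "HS", -1.840),
            CategoricalEffect("v_central", "fluid_type", "HES", -1.298)))
        cfg = GeneratorConfig(seed=7)
        records, _ = generate_cohort(cfg, cov_effects=true_cov)
        subjects = [(dilution_series(r), r.schedule, r.covariates())
                    for r in records]
        fit, audit = covariate_search(
            subjects, ModelKind.TWO_VOFS,
            candidates=[("v_central", "fluid_type"), ("k10", "MAP")],
            seed=0,
            fit_kwargs={"urine_totals": [r.urine_total for r in records]})
        selected = {(c.parameter, c.covariate, c.level)
                    for c in fit.covariates}
        assert ("v_central", "fluid_type", "HS") in selected
        assert ("v_central", "fluid_type", "HES") in selected
        hs = next(c for c in fit.covariates if c.level == "HS")
        assert hs.estimate == pytest.approx(-1.84, abs=0.3)
        assert {"phase", "delta_minus_2ll", "action"} <= set(audit.columns)
        assert (audit["phase"] == "forward").any()

    def test_null_cohort_selects_nothing(self):
        cfg = GeneratorConfig(fluids=("PLA",),
                              true_params={"PLA": GROUP_2VOFS}, seed=17)
        records, _ = generate_cohort(cfg)
        subjects = [(dilution_series(r), r.schedule, r.covariates())
                    for r in records]
        fit, _ = covariate_search(
            subjects, ModelKind.TWO_VOFS,
            candidates=[("k12", "MAP"), ("k10", "MAP"),
                        ("v_central", "body_weight")],
            seed=0,
            fit_kwargs={"urine_totals": [r.urine_total for r in records]})
        assert fit.covariates == []

    def test_collinear_candidates_warn(self, pla_subjects):
        subjects = [(s, sch, {**c, "SAPcopy": c["SAP"] * 1.0001})
                    for s, sch, c in pla_subjects]
        with pytest.warns(UserWarning, match="collinear"):
            covariate_search(subjects, ModelKind.TWO_VOFS,
                             candidates=[("k10", "SAP"), ("k10", "SAPcopy")],
                             seed=0)
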