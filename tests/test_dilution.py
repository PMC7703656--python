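"""Plasma-dilution computation, baseline QC, sampling correction, exclusions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from catvk.dataio import SamplePoint
from catvk.dilution import (DilutionError, DilutionSeries,
                            baseline_from_duplicates, correct_hb_for_sampling,
                            dilution_series, plasma_dilution, qc_report,
                            screen_exclusions)
from catvk.estimation import fit_individual
from catvk.kinetics import ModelKind
from catvk.synthcats import GeneratorConfig, generate_cohort, inject_outlier


class TestPlasmaDilution:
    @pytest.mark.parametrize("hb0,hbt,rbc0,rbct,hct,expected", [
        (100, 100, 7.0, 7.0, 0.30, 0.0),
        (100, 80, 7.0, 5.6, 0.30, 0.357143),   # both terms equal 0.25/0.7
        (100, 90, 7.0, 6.5, 0.30, 0.134310),   # mean of 0.158730 and 0.109890
    ])
    def test_hand_values(self, hb0, hbt, rbc0, rbct, hct, expected):
        d, src = plasma_dilution(hb0, hbt, rbc0, rbct, hct)
        assert d == pytest.approx(expected, abs=1e-6)
        assert src == "both"

    def test_single_analyte_flagged(self):
        d, src = plasma_dilution(100, 80, None, None, 0.30)
        assert src == "hb-only"
        assert d == pytest.approx(0.357143, abs=1e-6)
        d, src = plasma_dilution(None, None, 7.0, 5.6, 0.30)
        assert src == "rbc-only"
        d, src = plasma_dilution(None, None, None, None, 0.30)
        assert src == "missing" and np.isnan(d)

    def test_nonpositive_rejected(self):
        with pytest.raises(DilutionError):
            plasma_dilution(100, 0.0, 7, 6, 0.3)
        with pytest.raises(DilutionError):
            plasma_dilution(100, 90, 7, 6, 1.5)

    @given(d=st.floats(-0.5, 2.0), hct=st.floats(0.15, 0.55),
           hb0=st.floats(60, 140))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_inversion_round_trip(self, d, hct, hb0):
        """hb_t = hb0/(1 + d(1−hct)) fed back through the dilution formula
        recovers d to addition-rounding precision."""
        hb_t = hb0 / (1.0 + d * (1.0 - hct))
        rec, _ = plasma_dilution(hb0, hb_t, hb0 / 14.2, hb_t / 14.2, hct)
        assert rec == pytest.approx(d, abs=1e-12, rel=1e-10)

    def test_averaging_property(self):
        # equal analyte ratios: the mean equals either term exactly
        d_both, _ = plasma_dilution(100, 85, 7.0, 5.95, 0.25)
        d_hb, _ = plasma_dilution(100, 85, None, None, 0.25)
        assert d_both == pytest.approx(d_hb, rel=1e-14)


class TestBaseline:
    def test_duplicate_mean_and_cv(self):
        d1 = SamplePoint(0, hb=99, rbc=6.9, hct=0.30)
        d2 = SamplePoint(0, hb=101, rbc=7.1, hct=0.32)
        hb0, rbc0, hct0, cv_hb, cv_rbc = baseline_from_duplicates(d1, d2)
        assert (hb0, rbc0, hct0) == (100, 7.0, pytest.approx(0.31))
        assert cv_hb == pytest.approx(1.414214, abs=1e-5)  # |Δ|/√2 / mean
        assert cv_rbc == pytest.approx(2.0203, abs=1e-3)

    def test_identical_duplicates_zero_cv(self):
        d = SamplePoint(0, hb=100, rbc=7.0, hct=0.3)
        assert baseline_from_duplicates(d, d)[3] == 0.0

    def test_missing_analyte_is_qc_error(self):
        d1 = SamplePoint(0, hb=100, rbc=None, hct=0.3)
        d2 = SamplePoint(0, hb=100, rbc=7.0, hct=0.3)
        with pytest.raises(DilutionError, match="rbc"):
            baseline_from_duplicates(d1, d2)


class TestSamplingCorrection:
    def test_zero_volume_identity(self):
        f = correct_hb_for_sampling([0, 5, 10, 30], sample_volume=0.0,
                                    body_weight=4.5)
        np.testing.assert_array_equal(f, 1.0)

    def test_product_factor(self):
        # 10 draws of 0.4 mL from a 300-mL pool: (1 − 0.4/300)^10
        times = np.arange(0.0, 100.0, 10.0)   # 0 + 9 later draws
        f = correct_hb_for_sampling(times, n_baseline_draws=1,
                                    sample_volume=0.4,
                                    blood_volume_ml_per_kg=60.0,
                                    body_weight=5.0)
        # at the last time, 1 baseline + 8 preceding draws = 9; extend one
        # more time point to see all 10 draws in effect
        f_last = (1 - 0.4 / 300.0) ** 10
        times2 = np.append(times, 95.0)
        f2 = correct_hb_for_sampling(times2, n_baseline_draws=1,
                                     sample_volume=0.4,
                                     blood_volume_ml_per_kg=60.0,
                                     body_weight=5.0)
        assert f2[-1] == pytest.approx(f_last, rel=1e-12)
        assert f2[-1] == pytest.approx(0.98675, abs=5e-5)

    def test_exhausted_pool_rejected(self):
        with pytest.raises(DilutionError, match="blood volume"):
            correct_hb_for_sampling(np.arange(0, 180.0, 1.0),
                                    sample_volume=2.0,
                                    blood_volume_ml_per_kg=60.0,
                                    body_weight=1.0)

    def test_correction_lowers_dilution_everywhere(self):
        cfg = GeneratorConfig(n_subjects=1, fluids=("PLA",), seed=4)
        (rec,), _ = generate_cohort(cfg)
        raw = dilution_series(rec, hb_correction=False)
        cor = dilution_series(rec, hb_correction=True)
        m = raw.times > 0
        assert np.all(cor.dilution[m] <= raw.dilution[m] + 1e-12)

    def test_correction_recovers_truth_under_simulated_loss(self):
        """On noise-free data carrying the serial-sampling hemoglobin loss,
        the corrected analysis recovers the generating parameters exactly,
        while the uncorrected fit underestimates elimination (the 'false
        dilution' masquerades as retained fluid)."""
        cfg = GeneratorConfig(n_subjects=1, fluids=("HES",), seed=1,
                              cv_hb=0.0, cv_rbc=0.0, iiv_cv={},
                              hb_per_rbc_cv=0.0,
                              simulate_sampling_loss=True)
        (rec,), ledger = generate_cohort(cfg)
        truth = ledger.records[0]["params"]
        raw = dilution_series(rec, hb_correction=False)
        cor = dilution_series(rec, hb_correction=True)
        np.testing.assert_allclose(
            cor.dilution, np.asarray(ledger.records[0]["dilution_true"]),
            atol=1e-12)
        f_raw = fit_individual(raw, rec.schedule, ModelKind.ONE_VOFS,
                               n_starts=4, seed=1)
        f_cor = fit_individual(cor, rec.schedule, ModelKind.ONE_VOFS,
                               n_starts=4, seed=1)
        assert f_cor.params.v_central == pytest.approx(truth["v_central"],
                                                       rel=1e-6)
        assert f_cor.params.k10 == pytest.approx(truth["k10"], rel=1e-6)
        assert f_raw.params.k10 < f_cor.params.k10

    def test_corrected_refit_shifts_by_a_few_percent_on_noisy_data(self):
        """At study noise the corrected and uncorrected fits differ by a
        modest relative amount (the artifact is small for 0.4-mL draws)."""
        for seed in (1, 2, 3):
            cfg = GeneratorConfig(n_subjects=1, fluids=("HES",), seed=seed,
                                  simulate_sampling_loss=True)
            (rec,), _ = generate_cohort(cfg)
            raw = dilution_series(rec, hb_correction=False)
            cor = dilution_series(rec, hb_correction=True)
            f_raw = fit_individual(raw, rec.schedule, ModelKind.ONE_VOFS,
                                   n_starts=4, seed=seed)
            f_cor = fit_individual(cor, rec.schedule, ModelKind.ONE_VOFS,
                                   n_starts=4, seed=seed)
            rel_v = f_cor.params.v_central / f_raw.params.v_central - 1
            assert abs(rel_v) < 0.15
            assert f_cor.params.k10 > f_raw.params.k10


class TestExclusionScreen:
    def _series(self, sid, dilution, times=None):
        times = np.asarray([0, 5, 10, 15, 20, 30, 45, 60, 90, 120, 150, 180.]
                           if times is None else times, dtype=float)
        return DilutionSeries(sid, "PLA", times, np.asarray(dilution),
                              ["both"] * len(times), 100.0, 7.0, 0.30)

    def test_gross_outlier_flagged_alone(self, rng):
        base = np.concatenate([[0.0], 0.25 * np.exp(-0.01 * np.arange(11))])
        cohort = []
        for i in range(9):
            noise = rng.normal(0, 0.01, 12)
            noise[0] = 0.0
            cohort.append(self._series(f"s{i}", base + noise))
        outlier = self._series("bad", base + np.r_[0.0, np.full(11, 0.30)])
        flagged = screen_exclusions(cohort + [outlier])
        assert [s.subject_id for s in flagged if s.qc.excluded] == ["bad"]

    def test_identical_series_none_flagged(self):
        base = np.concatenate([[0.0], np.full(11, 0.2)])
        cohort = [self._series(f"s{i}", base) for i in range(6)]
        assert not any(s.qc.excluded for s in screen_exclusions(cohort))

    def test_small_cohort_rejected(self):
        base = np.concatenate([[0.0], np.full(11, 0.2)])
        with pytest.raises(DilutionError):
            screen_exclusions([self._series("a", base),
                               self._series("b", base)])

    def test_injected_outlier_integration(self):
        """A 10-SD synthetic outlier is screened out; 2 SD is not; the QC
        report carries the flags (the study excluded 1 of 10 sets)."""
        cfg = GeneratorConfig(fluids=("PLA",), seed=6)
        records, _ = generate_cohort(cfg)
        shifted = inject_outlier(records, "cat03", 10.0)
        series = [dilution_series(r) for r in shifted]
        screen_exclusions(series)
        assert [s.subject_id for s in series if s.qc.excluded] == ["cat03"]
        report = qc_report(series)
        assert report["excluded"].sum() == 1
        assert (~report[report.subject_id == "cat03"]["exclusion_reason"]
                .str.contains("SD")).sum() == 0

        mild = inject_outlier(records, "cat03", 2.0)
        series = [dilution_series(r) for r in mild]
        screen_exclusions(series)
        assert not any(s.qc.excluded for s in series)

        zero = inject_outlier(records, "cat03", 0.0)
        series = [dilution_series(r) for r in zero]
        screen_exclusions(series)
        assert not any(s.qc.excluded for s in series)
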