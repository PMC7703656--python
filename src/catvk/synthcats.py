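"""Synthetic cohorts with the statistical structure of the cat cross-over
fluid study.

Each simulated experiment follows the study design end-to-end: a 15-min
intravenous bolus (20 mL/kg balanced crystalloid, 3.3 mL/kg hypertonic
saline, or 5 mL/kg tetrastarch), duplicate baseline hematology, blood
sampling at 0, 5, 10, 15, 20, 30, 40, 50, 60 min then every 15 min to 180
min, oscillometric pressures and heart rate at the same times, and bladder
volume estimates every 30 min.  Individual kinetic parameters are drawn
log-normally around the fluid's typical values, dilution-time curves are
simulated from the fluid-space models, and hematology is obtained by
inverting the plasma-dilution relation and applying multiplicative
measurement noise at the study's duplicate-baseline CVs.

A truth ledger (individual parameters, noiseless curves, per-interval
eliminated volumes) accompanies every cohort so estimation can be validated
by parameter recovery.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import dilution as dilution_mod
from .dataio import (FluidType, SamplePoint, SubjectRecord,
                     schedule_from_prescription, write_subjects)
from .kinetics import (GROUP_2VOFS, INDIVIDUAL_PARAMS, CovariateModel,
                       ModelKind, VKParams, apply_covariates, simulate)

__all__ = ["GeneratorConfig", "TruthLedger", "generate_cohort",
           "inject_outlier", "write_cohort", "SAMPLING_TIMES"]

#: The study sampling grid (min): every 5 min to 20, every 10 to 60, then
#: every 15 min to the 180-min horizon.
SAMPLING_TIMES = (0.0, 5.0, 10.0, 15.0, 20.0, 30.0, 40.0, 50.0, 60.0,
                  75.0, 90.0, 105.0, 120.0, 135.0, 150.0, 165.0, 180.0)

_DOSES = {"PLA": 20.0, "HS": 3.3, "HES": 5.0}     # mL/kg
# Inter-individual CVs (fractions) per parameter, from the group-analysis
# variability estimates (~17-33% range).
_IIV_CV = {"v_central": 0.205, "k10": 0.228, "k12": 0.325, "k21": 0.167}


def _omega(cv: float) -> float:
    """Log-normal scale parameter with coefficient of variation ``cv``."""
    return math.sqrt(math.log1p(cv * cv))


@dataclass
class GeneratorConfig:
    """Study-design knobs; the defaults reproduce the source study's
    conditions and are not meant to be tuned per run."""

    n_subjects: int = 10
    fluids: tuple[str, ...] = ("PLA", "HS", "HES")
    doses: dict = field(default_factory=lambda: dict(_DOSES))   # mL/kg
    infusion_duration: float = 15.0                             # min
    sampling_times: tuple[float, ...] = SAMPLING_TIMES
    body_weight_mean: float = 4.79                              # kg
    body_weight_sd: float = 0.69
    body_weight_min: float = 2.0
    age_weeks_median: float = 33.0
    true_params: dict = field(
        default_factory=lambda: dict(INDIVIDUAL_PARAMS))        # per fluid
    base_params: VKParams = GROUP_2VOFS     # used when covariate effects given
    iiv_cv: dict = field(default_factory=lambda: dict(_IIV_CV)) # fractions
    cv_hb: float = 0.0353            # duplicate-baseline CV, fraction
    cv_rbc: float = 0.0338
    baseline_hb_mean: float = 99.5   # g/L
    baseline_hb_sd: float = 11.0
    baseline_hct_mean: float = 0.303
    baseline_hct_sd: float = 0.034
    hb_per_rbc: float = 14.2         # g/L per 10^12/L (MCHC-like ratio)
    hb_per_rbc_cv: float = 0.05
    map_median: float = 86.0         # mmHg
    map_log_sd: float = 0.17         # between-subject
    map_ar_phi: float = 0.8          # within-subject AR(1)
    map_ar_sd: float = 0.04          # stationary log-SD of the jitter
    sap_over_map: float = 116.0 / 86.0
    hr_median: float = 157.0
    hr_log_sd: float = 0.15
    urine_interval: float = 30.0     # min
    urine_cv: float = 0.30           # observation noise on interval volumes
    initial_bladder_ml: float = 5.0
    # when on, serial draws deplete the hemoglobin/red-cell pool, producing
    # the 'false dilution' the sampling correction is designed to remove
    simulate_sampling_loss: bool = False
    sample_volume_ml: float = 0.4
    blood_volume_ml_per_kg: float = 60.0
    seed: int = 0


@dataclass
class TruthLedger:
    """Everything the generator knew: enables closed-loop recovery tests."""

    seed: int
    config: dict
    records: list  # per record: ids, true params, eta, noiseless curves
    n_redraws: int = 0

    def true_params(self, subject_id: str, fluid: str) -> dict[str, float]:
        for r in self.records:
            if r["subject_id"] == subject_id and r["fluid_type"] == fluid:
                return r["params"]
        raise KeyError((subject_id, fluid))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)


def _draw_truncated(rng, mean, sd, lo, hi=math.inf, max_tries=100):
    redraws = 0
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return x, redraws
        redraws += 1
    return min(max(lo + 1e-6, mean), hi), redraws  # degenerate config fallback


def _ar1_series(rng, n, phi, stationary_sd):
    if stationary_sd <= 0:
        return np.zeros(n)
    innov_sd = stationary_sd * math.sqrt(1.0 - phi * phi)
    z = np.empty(n)
    z[0] = rng.normal(0.0, stationary_sd)
    for i in range(1, n):
        z[i] = phi * z[i - 1] + rng.normal(0.0, innov_sd)
    return z


def _lognoise(rng, cv, size=None):
    """Multiplicative noise with unit mean and coefficient of variation cv."""
    if cv <= 0:
        return np.ones(size) if size is not None else 1.0
    s = _omega(cv)
    return np.exp(rng.normal(-0.5 * s * s, s, size=size))


def generate_cohort(config: GeneratorConfig | None = None,
                    cov_effects: CovariateModel | None = None,
                    ) -> tuple[list[SubjectRecord], TruthLedger]:
    """Simulate one cross-over cohort.

    Without ``cov_effects`` each fluid uses its own justified-model typical
    values (``config.true_params``).  With ``cov_effects`` all records share
    ``config.base_params`` individualized through the supplied covariate
    model (true coefficients), which is the scenario covariate-search
    calibration needs.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    times = np.asarray(config.sampling_times, dtype=float)
    post = times[times > 0]
    records: list[SubjectRecord] = []
    ledger_records: list[dict] = []
    n_redraws = 0

    for i in range(config.n_subjects):
        sid = f"cat{i + 1:02d}"
        bw, r = _draw_truncated(rng, config.body_weight_mean,
                                config.body_weight_sd, config.body_weight_min)
        n_redraws += r
        map_mean = config.map_median * math.exp(rng.normal(0, config.map_log_sd))
        hr_mean = config.hr_median * math.exp(rng.normal(0, config.hr_log_sd))

        for fluid in config.fluids:
            hb0, r1 = _draw_truncated(rng, config.baseline_hb_mean,
                                      config.baseline_hb_sd, 40.0, 200.0)
            hct0, r2 = _draw_truncated(rng, config.baseline_hct_mean,
                                       config.baseline_hct_sd, 0.12, 0.55)
            n_redraws += r1 + r2
            rbc0 = hb0 / config.hb_per_rbc * math.exp(
                rng.normal(0, config.hb_per_rbc_cv)) if config.hb_per_rbc_cv > 0 \
                else hb0 / config.hb_per_rbc

            map_series = map_mean * np.exp(
                _ar1_series(rng, times.size, config.map_ar_phi, config.map_ar_sd))
            sap_series = map_series * config.sap_over_map * np.exp(
                _ar1_series(rng, times.size, config.map_ar_phi, 0.03))
            dap_series = np.maximum((3.0 * map_series - sap_series) / 2.0, 20.0)
            hr_series = hr_mean * np.exp(
                _ar1_series(rng, times.size, config.map_ar_phi, 0.05))

            covs = {"fluid_type": fluid, "MAP": float(np.mean(map_series)),
                    "SAP": float(np.mean(sap_series)),
                    "DAP": float(np.mean(dap_series)),
                    "HR": float(np.mean(hr_series)),
                    "body_weight": bw, "age": config.age_weeks_median}
            if cov_effects is not None:
                typical = apply_covariates(config.base_params, cov_effects, covs)
            else:
                typical = config.true_params[fluid]

            names = typical.names
            eta = {n: rng.normal(0.0, _omega(config.iiv_cv.get(n, 0.0)))
                   if config.iiv_cv.get(n, 0.0) > 0 else 0.0 for n in names}
            vals = {n: v * math.exp(eta[n])
                    for n, v in typical.as_dict().items()}
            params = (VKParams(typical.model_kind, vals["v_central"], vals["k10"])
                      if typical.model_kind is ModelKind.ONE_VOFS else
                      VKParams(typical.model_kind, vals["v_central"], vals["k10"],
                               vals["k12"], vals["k21"]))

            dose = config.doses[fluid]
            schedule = schedule_from_prescription(dose, bw,
                                                  config.infusion_duration)
            curve = simulate(params, schedule, times)
            d = curve.dilution

            blood_ratio = 1.0 + d * (1.0 - hct0)     # Hb0/Hb(t)
            if config.simulate_sampling_loss:
                loss = dilution_mod.correct_hb_for_sampling(
                    times, n_baseline_draws=2,
                    sample_volume=config.sample_volume_ml,
                    blood_volume_ml_per_kg=config.blood_volume_ml_per_kg,
                    body_weight=bw)
            else:
                loss = np.ones_like(times)
            hb_true = hb0 * loss / blood_ratio
            rbc_true = rbc0 * loss / blood_ratio
            hct_true = hct0 * loss / blood_ratio
            hb_obs = hb_true * _lognoise(rng, config.cv_hb, times.size)
            rbc_obs = rbc_true * _lognoise(rng, config.cv_rbc, times.size)

            # duplicate baseline draws (independent measurement noise)
            dup_hb = hb0 * _lognoise(rng, config.cv_hb, 2)
            dup_rbc = rbc0 * _lognoise(rng, config.cv_rbc, 2)
            duplicates = tuple(
                SamplePoint(time=0.0, hb=float(dup_hb[j]), rbc=float(dup_rbc[j]),
                            hct=hct0, sap=float(sap_series[0]),
                            dap=float(dap_series[0]), map=float(map_series[0]),
                            hr=float(hr_series[0]))
                for j in range(2))

            samples: list[SamplePoint] = []
            for j, t in enumerate(times):
                if t == 0:
                    continue
                samples.append(SamplePoint(
                    time=float(t), hb=float(hb_obs[j]), rbc=float(rbc_obs[j]),
                    hct=float(hct_true[j]), sap=float(sap_series[j]),
                    dap=float(dap_series[j]), map=float(map_series[j]),
                    hr=float(hr_series[j])))
            samples.insert(0, _mean_sample(duplicates))

            urine_times = np.arange(0.0, times[-1] + 1e-9, config.urine_interval)
            elim_curve = simulate(params, schedule, urine_times).eliminated
            increments = np.diff(elim_curve)
            obs_inc = increments * _lognoise(rng, config.urine_cv,
                                             increments.size)
            bladder = config.initial_bladder_ml + np.concatenate(
                [[0.0], np.cumsum(obs_inc)])
            urine = list(zip(urine_times.tolist(), bladder.tolist()))

            records.append(SubjectRecord(
                subject_id=sid, body_weight=bw, age=config.age_weeks_median,
                fluid_type=FluidType(fluid), dose=dose,
                infusion_duration=config.infusion_duration, samples=samples,
                urine=urine, baseline_duplicates=duplicates))
            ledger_records.append({
                "subject_id": sid, "fluid_type": fluid,
                "body_weight": bw, "params": dict(vals),
                "typical": typical.as_dict(), "eta": dict(eta),
                "baseline": {"hb": hb0, "rbc": rbc0, "hct": hct0},
                "times": times.tolist(), "dilution_true": d.tolist(),
                "eliminated_per_interval": increments.tolist(),
                "covariates": covs,
            })

    cfg = dataclasses.asdict(config)
    cfg["true_params"] = {k: v.as_dict() for k, v in config.true_params.items()}
    cfg["base_params"] = config.base_params.as_dict()
    ledger = TruthLedger(seed=config.seed, config=cfg, records=ledger_records,
                         n_redraws=n_redraws)
    return records, ledger


def _mean_sample(duplicates) -> SamplePoint:
    d1, d2 = duplicates
    return SamplePoint(time=0.0, hb=0.5 * (d1.hb + d2.hb),
                       rbc=0.5 * (d1.rbc + d2.rbc), hct=0.5 * (d1.hct + d2.hct),
                       sap=d1.sap, dap=d1.dap, map=d1.map, hr=d1.hr)


def inject_outlier(cohort: list[SubjectRecord], subject_id: str,
                   offset_sd: float) -> list[SubjectRecord]:
    """Shift one subject's dilution-implied hematology by ``offset_sd``
    cohort standard deviations at every post-baseline point.

    The cohort SD is computed per time point across the *other* records'
    dilution series; the target record's hemoglobin and red-cell counts are
    re-derived from the shifted dilution so downstream screening sees a
    self-consistent aberrant profile.  Returns the modified cohort (the
    target records are replaced; others are untouched).
    """
    targets = [r for r in cohort if r.subject_id == subject_id]
    if not targets:
        raise KeyError(f"unknown subject {subject_id!r}")
    series = {id(r): dilution_mod.dilution_series(r) for r in cohort}
    out = []
    for rec in cohort:
        if rec.subject_id != subject_id:
            out.append(rec)
            continue
        others = [series[id(r)] for r in cohort
                  if r is not rec and r.fluid_type == rec.fluid_type]
        s = series[id(rec)]
        new_samples = []
        for p in rec.samples:
            if p.time == 0:
                new_samples.append(p)
                continue
            i = int(np.argmin(np.abs(s.times - p.time)))
            sd = float(np.std([o.dilution[int(np.argmin(np.abs(o.times - p.time)))]
                               for o in others], ddof=1)) if len(others) > 1 else 0.0
            d_new = s.dilution[i] + offset_sd * sd
            ratio = 1.0 + d_new * (1.0 - s.baseline_hct)
            new_samples.append(dataclasses.replace(
                p, hb=None if p.hb is None else s.baseline_hb / ratio,
                rbc=None if p.rbc is None else s.baseline_rbc / ratio))
        out.append(dataclasses.replace(rec, samples=new_samples))
    return out


def write_cohort(records: list[SubjectRecord], ledger: TruthLedger,
                 outdir: str | Path) -> dict[str, Path]:
    """Write the three study CSVs plus the truth ledger JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "hematology": outdir / "hematology.csv",
        "urine": outdir / "urine.csv",
        "metadata": outdir / "metadata.csv",
        "truth": outdir / "truth_ledger.json",
    }
    write_subjects(records, paths["hematology"], paths["urine"],
                   paths["metadata"])
    ledger.to_json(paths["truth"])
    return paths
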