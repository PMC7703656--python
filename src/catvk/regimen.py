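"""Derived clinical quantities: fluid potency and bolus+CRI prescriptions.

Potency compares fluids by the peak plasma dilution an identical standardized
dose produces.  Regimen design exploits the linearity of the kinetic models:
the steady-state infusion that maintains a target dilution d is exactly

    R0 = k10 · d · V_c

(set the derivatives to zero: at steady state elimination k10·x1 balances the
infusion and x1 = d·V_c, independent of the distribution constants), and the
bolus rate that reaches d at the end of a ``duration``-min bolus scales
linearly from a unit-rate simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import InfusionSchedule, schedule_from_prescription
from .kinetics import KineticsError, SimulatedCurve, VKParams, simulate

__all__ = [
    "Regimen",
    "potency_ratio",
    "maintenance_rate",
    "bolus_to_achieve",
    "design_regimen",
    "regimen_table",
    "PEAK_GRID_STEP_MIN",
]

PEAK_GRID_STEP_MIN = 0.1        # peak detection resolution
PEAK_WINDOW_AFTER_BOLUS = 60.0  # min past end of bolus scanned for the peak


def _peak_dilution(params: VKParams, dose_ml_per_kg: float, body_weight: float,
                   duration: float) -> float:
    schedule = schedule_from_prescription(dose_ml_per_kg, body_weight, duration)
    horizon = duration + PEAK_WINDOW_AFTER_BOLUS
    grid = np.arange(0.0, horizon + PEAK_GRID_STEP_MIN / 2, PEAK_GRID_STEP_MIN)
    return simulate(params, schedule, grid).peak_dilution


def potency_ratio(params_a: VKParams, params_b: VKParams,
                  standard_dose: float = 6.0, body_weight: float = 5.0,
                  duration: float = 15.0) -> float:
    """Peak-dilution ratio A/B for an identical standardized bolus.

    Default dose 6 mL/kg over 15 min in a 5 kg subject.  When the two
    parameter sets differ only in V_c the ratio equals V_c(B)/V_c(A) exactly
    (the expansion curves coincide; only the normalizing volume differs).
    """
    peak_a = _peak_dilution(params_a, standard_dose, body_weight, duration)
    peak_b = _peak_dilution(params_b, standard_dose, body_weight, duration)
    if peak_b <= 0:
        raise KineticsError("reference fluid produced no volume expansion")
    return peak_a / peak_b


def maintenance_rate(params: VKParams, target_dilution: float) -> float:
    """Constant-rate infusion (mL/min) holding ``target_dilution`` at steady
    state: k10 · target · V_c, independent of k12/k21."""
    if target_dilution < 0:
        raise KineticsError("target dilution must be >= 0")
    return params.k10 * target_dilution * params.v_central


def bolus_to_achieve(params: VKParams, target_dilution: float,
                     bolus_duration: float = 15.0,
                     body_weight: float = 5.0) -> tuple[float, float]:
    """Bolus reaching ``target_dilution`` at the end of a bolus of the given
    duration; returns (dose mL/kg, rate mL/min).

    Linearity in R0 makes this exact: a unit-rate bolus is simulated once and
    the required rate is target / (end-of-bolus dilution per unit rate).
    """
    if not target_dilution > 0:
        raise KineticsError("target dilution must be > 0")
    if not (bolus_duration > 0 and body_weight > 0):
        raise KineticsError("bolus duration and body weight must be > 0")
    unit = simulate(params, InfusionSchedule(((0.0, bolus_duration, 1.0),)),
                    np.array([bolus_duration]))
    d1 = float(unit.dilution[-1])     # dilution per unit infusion rate
    if d1 <= 0:
        raise KineticsError("unit bolus produced no dilution")
    rate = target_dilution / d1
    return rate * bolus_duration / body_weight, rate


@dataclass
class Regimen:
    """A bolus + constant-rate-infusion prescription for one target."""

    target_dilution: float
    bolus_dose: float            # mL/kg
    bolus_rate: float            # mL/min
    bolus_duration: float        # min
    maintenance_rate: float      # mL/min
    body_weight: float           # kg
    params: VKParams

    @property
    def maintenance_rate_ml_per_hr(self) -> float:
        return self.maintenance_rate * 60.0

    def simulate(self, horizon: float = 360.0,
                 step: float = PEAK_GRID_STEP_MIN) -> SimulatedCurve:
        """Dilution under the full prescription: bolus then CRI."""
        schedule = InfusionSchedule((
            (0.0, self.bolus_duration, self.bolus_rate),
            (self.bolus_duration, horizon, self.maintenance_rate)))
        grid = np.arange(0.0, horizon + step / 2, step)
        return simulate(self.params, schedule, grid)


def design_regimen(params: VKParams, target_dilution: float,
                   bolus_duration: float = 15.0,
                   body_weight: float = 5.0) -> Regimen:
    """Bolus achieving the target at end of bolus, then the steady-state CRI.

    The simulated dilution equals the target at the end of the bolus, never
    exceeds it afterwards, and converges back to the target as elimination
    and distribution equilibrate.  Two-volume fluids transiently dip below
    the target while the peripheral space fills (the redistribution dip);
    the one-volume model holds the target exactly.
    """
    dose, rate = bolus_to_achieve(params, target_dilution, bolus_duration,
                                  body_weight)
    return Regimen(target_dilution=target_dilution, bolus_dose=dose,
                   bolus_rate=rate, bolus_duration=bolus_duration,
                   maintenance_rate=maintenance_rate(params, target_dilution),
                   body_weight=body_weight, params=params)


def regimen_table(params_by_fluid: dict[str, VKParams],
                  targets: tuple[float, ...] = (0.15, 0.30),
                  body_weight: float = 5.0,
                  bolus_duration: float = 15.0) -> pd.DataFrame:
    """Prescription table across fluids and targets.

    Columns: fluid, target_pct, bolus_mL_per_kg, bolus_mL_per_min,
    cri_mL_per_min, cri_mL_per_hr.
    """
    rows = []
    for fluid, params in params_by_fluid.items():
        for target in targets:
            reg = design_regimen(params, target, bolus_duration, body_weight)
            rows.append({
                "fluid": fluid,
                "target_pct": 100.0 * target,
                "bolus_mL_per_kg": reg.bolus_dose,
                "bolus_mL_per_min": reg.bolus_rate,
                "cri_mL_per_min": reg.maintenance_rate,
                "cri_mL_per_hr": reg.maintenance_rate_ml_per_hr,
            })
    return pd.DataFrame(rows)
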