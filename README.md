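# catvk — volume kinetics of intravenous fluids in cats

`catvk` implements the volume-kinetic (VK) analysis of intravenous fluid
therapy in healthy conscious cats: how a 15-minute bolus of balanced
isotonic crystalloid (PLA, 20 mL/kg), 5% hypertonic saline (HS, 3.3 mL/kg)
or 6% tetrastarch 130/0.4 (HES, 5 mL/kg) distributes between body fluid
spaces and is eliminated, estimated from nothing more invasive than serial
hemoglobin and red-cell measurements plus bladder-ultrasound urine
estimates.  It is written for veterinary researchers and pharmacometricians
who want to reanalyse such experiments, design new ones, or simulate fluid
prescriptions.

## The model

Plasma dilution — the fractional expansion of plasma volume — is obtained
from serial hematology against the duplicate-baseline means:

    dilution(t) = ½ [ (Hb(0)/Hb(t) − 1) + (RBC(0)/RBC(t) − 1) ] / (1 − HCT(0))

Infused fluid expands one or two fluid spaces.  With central expansion
x₁ = v_c − V_c and peripheral expansion x₂ = v_p − V_p:

    1-VOFS:  dx₁/dt = R₀ − k₁₀·x₁
    2-VOFS:  dx₁/dt = R₀ − k₁₀·x₁ − k₁₂·x₁ + k₂₁·x₂
             dx₂/dt = k₁₂·x₁ − k₂₁·x₂

where R₀ is the infusion rate (mL/min), k₁₀ the first-order elimination
constant and k₁₂/k₂₁ the distribution constants.  Model dilution is
x₁/V_c; elimination half-life is t½ = ln 2 / k₁₀; urine output anchors
elimination through k₁₀ = urine / AUC(x₁).

The package provides

* exact (matrix-exponential) simulation of dilution-time curves for
  arbitrary piecewise-constant infusion schedules, with a numeric
  integrator as an independent cross-check (`catvk.kinetics`),
* plasma-dilution computation with duplicate-baseline QC, optional
  correction for hemoglobin lost to serial sampling, and a 3-SD cohort
  exclusion screen (`catvk.dilution`),
* individual and population (non-linear mixed-effects, Laplace/FOCE-class)
  estimation with likelihood-ratio model comparison and stepwise covariate
  search (`catvk.estimation`),
* fluid-potency comparison and bolus+CRI prescription design
  (`catvk.regimen`),
* a synthetic-cohort generator reproducing the cross-over study design for
  closed-loop validation (`catvk.synthcats`),
* a CLI (`catvk synth|dilution|fit|compare|covsearch|simulate|regimen|potency`).

## Worked example

```python
import numpy as np
from catvk import (GROUP_2VOFS, GROUP_VC_SHIFTS, ModelKind, VKParams,
                   half_life, maintenance_rate, potency_ratio,
                   schedule_from_prescription, simulate)

# crystalloid study bolus in a 4.79 kg cat: 20 mL/kg over 15 min
sch = schedule_from_prescription(20, 4.79, 15)
curve = simulate(GROUP_2VOFS, sch, np.arange(0, 181.0))
print(f"peak dilution {100 * curve.peak_dilution:.1f}%")

# potency: hypertonic saline vs tetrastarch, standardized 6 mL/kg bolus
import math
def group(fluid):
    b = GROUP_2VOFS
    return VKParams(ModelKind.TWO_VOFS,
                    b.v_central * math.exp(GROUP_VC_SHIFTS[fluid]),
                    b.k10, b.k12, b.k21)
print(f"HS/HES potency {potency_ratio(group('HS'), group('HES')):.2f}")
print(f"PLA half-life {half_life(0.014):.1f} min")
print(f"CRI to hold 15% expansion (PLA) "
      f"{maintenance_rate(group('PLA'), 0.15):.2f} mL/min")
```

prints

```
peak dilution 30.1%
HS/HES potency 1.72
PLA half-life 49.5 min
CRI to hold 15% expansion (PLA) 0.15 mL/min
```

i.e. the crystalloid bolus transiently expands plasma volume by ~30%,
hypertonic saline is ~1.7× as potent as tetrastarch volume-for-volume, the
crystalloid's plasma expansion half-life is ~49 min, and holding a 15%
expansion afterwards needs only 0.15 mL/min (9 mL/h) — a drastic step-down
from the 6.4 mL/min bolus rate.

The end-to-end analysis lives in `analysis/01_generate_cohort.py` …
`05_potency_and_regimens.py`: simulate the cohort, compute dilution + QC,
fit and compare the population models, run the covariate search, and
simulate potency/prescriptions.  Each script prints what it found and
writes tables under `results/`.

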