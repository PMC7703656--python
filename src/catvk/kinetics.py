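"""Volume-kinetic fluid-space models and forward simulation.

Infused fluid expands one or two expandable body fluid spaces.  With central
expansion x1 = v_c − V_c and peripheral expansion x2 = v_p − V_p, the models
are linear constant-coefficient ODEs driven by the infusion rate R0(t):

  one-volume (1-VOFS):   dx1/dt = R0 − k10·x1
  two-volume (2-VOFS):   dx1/dt = R0 − k10·x1 − k12·x1 + k21·x2
                         dx2/dt = k12·x1 − k21·x2

k10 is the first-order elimination rate constant (renal loss proportional to
central expansion); k12/k21 are the bidirectional distribution constants.
Plasma dilution is x1/V_c.  Only expansions are tracked: the equations never
need the peripheral baseline volume V_p, and x2(0) = 0.

Piecewise-constant infusion schedules are solved segment-by-segment with the
exact closed form (scalar exponential, or the 2×2 matrix exponential via its
spectral decomposition) and state handoff; an adaptive numeric integrator is
available as an independent cross-check and as a fallback for the measure-zero
case of nearly coincident eigenvalues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .dataio import InfusionSchedule

__all__ = [
    "ModelKind",
    "VKParams",
    "CategoricalEffect",
    "ContinuousEffect",
    "CovariateModel",
    "SimulatedCurve",
    "KineticsError",
    "simulate",
    "apply_covariates",
    "half_life",
    "auc_expansion",
    "GROUP_2VOFS",
    "GROUP_1VOFS",
    "GROUP_VC_SHIFTS",
    "INDIVIDUAL_PARAMS",
]

# Relative eigenvalue gap below which the spectral closed form is abandoned
# for the numeric integrator.
EIG_DEGENERACY_RTOL = 1e-10


class KineticsError(ValueError):
    """Raised for invalid kinetic parameters or simulation inputs."""


class ModelKind(str, Enum):
    ONE_VOFS = "1vofs"
    TWO_VOFS = "2vofs"


@dataclass(frozen=True)
class VKParams:
    """Structural volume-kinetic parameters.

    ``v_central`` is V (1-VOFS) or V_c (2-VOFS) in mL; rate constants are
    per minute.  k12/k21 must be absent for the one-volume model.
    """

    model_kind: ModelKind
    v_central: float          # mL
    k10: float                # /min
    k12: float | None = None  # /min, 2-VOFS only
    k21: float | None = None  # /min, 2-VOFS only

    def __post_init__(self) -> None:
        if not (self.v_central > 0 and self.k10 > 0):
            raise KineticsError(
                f"v_central and k10 must be positive, got {self.v_central}, {self.k10}")
        if self.model_kind is ModelKind.TWO_VOFS:
            if self.k12 is None or self.k21 is None or self.k12 <= 0 or self.k21 <= 0:
                raise KineticsError("2-VOFS requires positive k12 and k21")
        elif self.k12 is not None or self.k21 is not None:
            raise KineticsError("1-VOFS takes no k12/k21")

    def as_dict(self) -> dict[str, float]:
        d = {"v_central": self.v_central, "k10": self.k10}
        if self.model_kind is ModelKind.TWO_VOFS:
            d.update(k12=self.k12, k21=self.k21)
        return d

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.as_dict())


@dataclass(frozen=True)
class CategoricalEffect:
    """Multiplicative level shift: param ← param · e^coefficient when the
    subject's ``covariate`` equals ``level`` (reference level has no entry)."""

    parameter: str
    covariate: str
    level: str
    coefficient: float        # log-scale shift


@dataclass(frozen=True)
class ContinuousEffect:
    """Power model: param ← param · (value/reference)^exponent."""

    parameter: str
    covariate: str
    exponent: float
    reference: float          # covariate units

    def __post_init__(self) -> None:
        if not self.reference > 0:
            raise KineticsError("continuous-covariate reference must be > 0")


@dataclass(frozen=True)
class CovariateModel:
    categorical: tuple[CategoricalEffect, ...] = ()
    continuous: tuple[ContinuousEffect, ...] = ()

    def __post_init__(self) -> None:
        cat_keys = [(e.parameter, e.covariate, e.level) for e in self.categorical]
        cont_keys = [(e.parameter, e.covariate) for e in self.continuous]
        if len(set(cat_keys)) != len(cat_keys) or len(set(cont_keys)) != len(cont_keys):
            raise KineticsError(
                "at most one effect per (parameter, covariate[, level])")
        overlap = {(p, c) for p, c, _ in cat_keys} & set(cont_keys)
        if overlap:
            raise KineticsError(
                f"covariate assigned both categorical and continuous effects: {overlap}")

    @property
    def is_empty(self) -> bool:
        return not self.categorical and not self.continuous


def apply_covariates(params: VKParams, cov_model: CovariateModel,
                     covariates: Mapping[str, float | str]) -> VKParams:
    """Individualize population parameters under a covariate model.

    Categorical effects multiply by e^coefficient when the subject is at the
    stated level; continuous effects multiply by (value/reference)^exponent.
    Unlisted parameters pass through unchanged.
    """
    values = dict(params.as_dict())
    for eff in cov_model.categorical:
        if eff.covariate not in covariates:
            raise KineticsError(f"missing covariate value for {eff.covariate!r}")
        if str(covariates[eff.covariate]) == eff.level:
            values[eff.parameter] = values[eff.parameter] * math.exp(eff.coefficient)
    for eff in cov_model.continuous:
        if eff.covariate not in covariates:
            raise KineticsError(f"missing covariate value for {eff.covariate!r}")
        value = float(covariates[eff.covariate])
        values[eff.parameter] = values[eff.parameter] * \
            (value / eff.reference) ** eff.exponent
    return replace(params, v_central=values["v_central"], k10=values["k10"],
                   k12=values.get("k12"), k21=values.get("k21"))


@dataclass
class SimulatedCurve:
    """Simulated expansion trajectories on an output grid.

    ``eliminated`` is the cumulative volume removed by elimination,
    k10·∫x1 dt, so infused = x1 + x2 + eliminated at every time.
    """

    times: np.ndarray         # min
    x1: np.ndarray            # central expansion v_c − V_c, mL
    x2: np.ndarray            # peripheral expansion v_p − V_p, mL (zeros for 1-VOFS)
    dilution: np.ndarray      # x1 / V_c
    eliminated: np.ndarray    # mL
    infused: np.ndarray       # mL
    params: VKParams | None = None

    @property
    def peak_dilution(self) -> float:
        return float(np.max(self.dilution))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "time_min": self.times, "x1_mL": self.x1, "x2_mL": self.x2,
            "dilution": self.dilution, "eliminated_mL": self.eliminated,
        })


# ---------------------------------------------------------------------------
# closed-form segment propagation


def _eigs_2vofs(k10: float, k12: float, k21: float) -> tuple[float, float]:
    s = k10 + k12 + k21
    disc = math.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
    lam1 = 0.5 * (-s + disc)
    lam2 = 0.5 * (-s - disc)
    return lam1, lam2


def _propagate_2vofs(x1_0, x2_0, r0, k10, k12, k21, tau):
    """Exact state of the two-volume system at elapsed times ``tau`` within a
    constant-rate segment, plus ∫x1 dt over [0, tau].

    Spectral form: x(t) = x_ss + e^{λ1 t} a + e^{λ2 t} b with a, b the
    eigen-projections of x(0) − x_ss.  All arguments broadcast.
    """
    tau = np.asarray(tau, dtype=float)
    lam1, lam2 = _eigs_2vofs(k10, k12, k21)
    gap = abs(lam1 - lam2) / max(abs(lam1), abs(lam2))
    if gap < EIG_DEGENERACY_RTOL:
        raise _DegenerateEigs()
    x1_ss = r0 / k10
    x2_ss = k12 * r0 / (k10 * k21)
    w1 = x1_0 - x1_ss
    w2 = x2_0 - x2_ss
    delta = lam1 - lam2
    # first components of the eigen-projections of w
    a1 = ((-(k10 + k12) - lam2) * w1 + k21 * w2) / delta
    b1 = w1 - a1
    a2 = (k12 * w1 + (-k21 - lam2) * w2) / delta
    b2 = w2 - a2
    e1 = np.exp(lam1 * tau)
    e2 = np.exp(lam2 * tau)
    x1 = x1_ss + a1 * e1 + b1 * e2
    x2 = x2_ss + a2 * e1 + b2 * e2
    int_x1 = x1_ss * tau + a1 * (e1 - 1.0) / lam1 + b1 * (e2 - 1.0) / lam2
    return x1, x2, int_x1


def _propagate_1vofs(x1_0, r0, k10, tau):
    tau = np.asarray(tau, dtype=float)
    x1_ss = r0 / k10
    e = np.exp(-k10 * tau)
    x1 = x1_ss + (x1_0 - x1_ss) * e
    int_x1 = x1_ss * tau + (x1_0 - x1_ss) * (1.0 - e) / k10
    return x1, int_x1


class _DegenerateEigs(Exception):
    pass


def _segment_boundaries(schedule: InfusionSchedule, horizon: float) -> list[tuple[float, float, float]]:
    """Schedule plus zero-rate gaps, covering [0, horizon] contiguously."""
    segs: list[tuple[float, float, float]] = []
    cursor = 0.0
    for start, end, rate in schedule.segments:
        if start > cursor:
            segs.append((cursor, start, 0.0))
        segs.append((start, end, rate))
        cursor = end
    if horizon > cursor:
        segs.append((cursor, horizon, 0.0))
    return segs


def _simulate_closed(params: VKParams, schedule: InfusionSchedule,
                     times: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x1 = np.zeros_like(times)
    x2 = np.zeros_like(times)
    elim_int = np.zeros_like(times)   # ∫x1 up to each output time
    state = (0.0, 0.0, 0.0)           # x1, x2, ∫x1 at segment start
    for start, end, rate in _segment_boundaries(schedule, float(times[-1])):
        m = (times > start) & (times <= end)
        tau = times[m] - start
        if params.model_kind is ModelKind.TWO_VOFS:
            x1[m], x2[m], seg_int = _propagate_2vofs(
                state[0], state[1], rate, params.k10, params.k12, params.k21, tau)
            nx1, nx2, nint = _propagate_2vofs(
                state[0], state[1], rate, params.k10, params.k12, params.k21,
                end - start)
        else:
            x1[m], seg_int = _propagate_1vofs(state[0], rate, params.k10, tau)
            nx1, nint = _propagate_1vofs(state[0], rate, params.k10, end - start)
            nx2 = 0.0
        elim_int[m] = state[2] + seg_int
        state = (float(nx1), float(nx2), state[2] + float(nint))
    return x1, x2, elim_int


def _simulate_numeric(params: VKParams, schedule: InfusionSchedule,
                      times: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Adaptive-step integration of the same ODEs; independent cross-check."""
    two = params.model_kind is ModelKind.TWO_VOFS

    def rhs(t, y):
        r0 = schedule.rate_at(t)
        if two:
            x1, x2, _ = y
            d1 = r0 - params.k10 * x1 - params.k12 * x1 + params.k21 * x2
            d2 = params.k12 * x1 - params.k21 * x2
            return [d1, d2, x1]
        x1 = y[0]
        return [r0 - params.k10 * x1, 0.0, x1]

    breaks = sorted({0.0, float(times[-1])}
                    | {t for s in schedule.segments for t in s[:2]})
    t_eval = np.unique(np.concatenate([times, np.asarray(breaks)]))
    t_eval = t_eval[t_eval <= times[-1]]
    ys = []
    y0 = [0.0, 0.0, 0.0]
    for a, b in zip(breaks[:-1], breaks[1:]):
        seg_t = t_eval[(t_eval >= a) & (t_eval <= b)]
        sol = solve_ivp(rhs, (a, b), y0, t_eval=seg_t, method="LSODA",
                        rtol=1e-11, atol=1e-12)
        ys.append((sol.t, sol.y))
        y0 = sol.y[:, -1]
    t_all = np.concatenate([t for t, _ in ys])
    y_all = np.concatenate([y for _, y in ys], axis=1)
    idx = np.searchsorted(t_all, times)
    return y_all[0, idx], y_all[1, idx], y_all[2, idx]


def simulate(params: VKParams, schedule: InfusionSchedule,
             times: Sequence[float] | np.ndarray | None = None,
             method: str = "closed") -> SimulatedCurve:
    """Simulate expansion and dilution for a piecewise-constant schedule.

    ``times`` defaults to a 1-min grid over [0, 180].  ``method`` is
    ``"closed"`` (exact segment-wise solution; default) or ``"numeric"``
    (adaptive integrator, used as an independent cross-check).  The closed
    path falls back to the numeric one automatically if the two system
    eigenvalues nearly coincide.
    """
    if times is None:
        times = np.arange(0.0, 180.0 + 0.5, 1.0)
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 1 or np.any(np.diff(times) <= 0):
        raise KineticsError("times must be a strictly increasing 1-D grid")
    if times[0] < 0:
        raise KineticsError("times must be non-negative")
    if times[0] > 0:
        times = np.concatenate([[0.0], times])
        drop_first = True
    else:
        drop_first = False

    if method == "closed":
        try:
            x1, x2, elim_int = _simulate_closed(params, schedule, times)
        except _DegenerateEigs:
            x1, x2, elim_int = _simulate_numeric(params, schedule, times)
    elif method == "numeric":
        x1, x2, elim_int = _simulate_numeric(params, schedule, times)
    else:
        raise KineticsError(f"unknown method {method!r}")

    infused = np.array([sum(r * max(0.0, min(t, e) - s)
                            for s, e, r in schedule.segments) for t in times])
    if drop_first:
        x1, x2, elim_int, infused, times = (a[1:] for a in
                                            (x1, x2, elim_int, infused, times))
    return SimulatedCurve(times=times, x1=x1, x2=x2,
                          dilution=x1 / params.v_central,
                          eliminated=params.k10 * elim_int,
                          infused=infused, params=params)


def half_life(k10: float) -> float:
    """Elimination half-life t½ = ln 2 / k10, in minutes."""
    if not k10 > 0:
        raise KineticsError(f"k10 must be positive, got {k10!r}")
    return math.log(2.0) / k10


def auc_expansion(times: Sequence[float], expansion: Sequence[float]) -> float:
    """Trapezoidal area under the central expansion curve (mL·min).

    ``expansion`` is (v−V)(t) in mL; to use a dilution series multiply the
    dilution by V first.
    """
    times = np.asarray(times, dtype=float)
    expansion = np.asarray(expansion, dtype=float)
    if times.size < 2:
        raise KineticsError("AUC needs at least two time points")
    if np.any(np.diff(times) <= 0):
        raise KineticsError("times must be strictly increasing")
    return float(np.trapezoid(expansion, times))


# ---------------------------------------------------------------------------
# Published parameter sets (group and per-fluid analyses) used as simulation
# defaults and as ground truth for the synthetic cohorts.

#: Group (all fluids pooled, n=29) two-volume model typical values.
GROUP_2VOFS = VKParams(ModelKind.TWO_VOFS, v_central=139.0, k10=0.007,
                       k12=0.326, k21=0.190)

#: Group one-volume model typical values.
GROUP_1VOFS = VKParams(ModelKind.ONE_VOFS, v_central=409.0, k10=0.003)

#: Fluid-type shifts on V_c in the group model (log-scale, PLA reference).
GROUP_VC_SHIFTS = {"PLA": 0.0, "HS": -1.840, "HES": -1.298}

#: Per-fluid analyses: the statistically justified model for each fluid.
INDIVIDUAL_PARAMS = {
    "PLA": VKParams(ModelKind.TWO_VOFS, v_central=74.25, k10=0.014,
                    k12=0.753, k21=0.161),
    "HS": VKParams(ModelKind.TWO_VOFS, v_central=32.41, k10=0.002,
                   k12=0.141, k21=0.186),
    "HES": VKParams(ModelKind.ONE_VOFS, v_central=80.33, k10=0.007),
}


def group_covariate_model(map_reference: float = 84.0) -> CovariateModel:
    """The group-analysis covariate model: fluid type on V_c and a power-of-MAP
    effect on k12 (exponent 0.053, reference MAP in mmHg)."""
    return CovariateModel(
        categorical=(
            CategoricalEffect("v_central", "fluid_type", "HS", -1.840),
            CategoricalEffect("v_central", "fluid_type", "HES", -1.298),
        ),
        continuous=(
            ContinuousEffect("k12", "MAP", 0.053, map_reference),
        ),
    )
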