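"""Study data model and CSV input/output.

The unit conventions are fixed and enforced at the file boundary: time in
minutes from infusion start (time 0 = pre-infusion baseline), hemoglobin in
g/L, red-cell count in 10^12 cells/L, hematocrit as a fraction, pressures in
mmHg, volumes in mL, body weight in kg.  Readers reject files whose column
headers declare anything else rather than converting silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "FluidType",
    "SamplePoint",
    "SubjectRecord",
    "InfusionSchedule",
    "LoadReport",
    "ValidationError",
    "read_subjects",
    "write_subjects",
    "schedule_from_prescription",
]

OBSERVATION_HORIZON_MIN = 180.0

HEMATOLOGY_COLUMNS = [
    "subject_id", "fluid_type", "time_min", "hb_g_per_L", "rbc_1e12_per_L",
    "hct_frac", "sap_mmHg", "dap_mmHg", "map_mmHg", "hr_bpm",
]
URINE_COLUMNS = ["subject_id", "fluid_type", "time_min", "bladder_volume_mL"]
METADATA_COLUMNS = [
    "subject_id", "fluid_type", "body_weight_kg", "age_weeks",
    "dose_mL_per_kg", "infusion_duration_min",
]


class ValidationError(ValueError):
    """Raised when an input table or record violates the data contract."""


class FluidType(str, Enum):
    """The three intravenous fluids: balanced isotonic crystalloid (PLA),
    5% hypertonic saline (HS), and 6% tetrastarch 130/0.4 (HES)."""

    PLA = "PLA"
    HS = "HS"
    HES = "HES"


def _check_positive(name: str, value: float | None, context: str = "") -> None:
    if value is not None and not (value > 0 and math.isfinite(value)):
        where = f" ({context})" if context else ""
        raise ValidationError(f"{name} must be positive and finite, got {value!r}{where}")


@dataclass(frozen=True)
class SamplePoint:
    """One blood-sampling occasion with paired hemodynamic readings.

    ``None`` marks a missing analyte; a point missing both hb and rbc carries
    no dilution information but is retained and flagged rather than dropped.
    """

    time: float                      # min from infusion start
    hb: float | None = None          # g/L
    rbc: float | None = None         # 10^12 cells/L
    hct: float | None = None         # fraction of blood volume
    sap: float | None = None         # mmHg
    dap: float | None = None         # mmHg
    map: float | None = None         # mmHg
    hr: float | None = None          # beats/min

    def __post_init__(self) -> None:
        if not (self.time >= 0 and math.isfinite(self.time)):
            raise ValidationError(f"sample time must be >= 0, got {self.time!r}")
        ctx = f"time {self.time} min"
        _check_positive("hb", self.hb, ctx)
        _check_positive("rbc", self.rbc, ctx)
        if self.hct is not None and not (0.0 < self.hct < 1.0):
            raise ValidationError(
                f"hct must lie strictly between 0 and 1, got {self.hct!r} ({ctx})")
        for name in ("sap", "dap", "map", "hr"):
            _check_positive(name, getattr(self, name), ctx)

    @property
    def has_dilution_info(self) -> bool:
        return self.hb is not None or self.rbc is not None


@dataclass(frozen=True)
class InfusionSchedule:
    """Piecewise-constant infusion: ordered (start, end, rate mL/min) segments."""

    segments: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        prev_end = 0.0
        for i, (start, end, rate) in enumerate(self.segments):
            if not start < end:
                raise ValidationError(f"segment {i}: start {start} must precede end {end}")
            if start < prev_end - 1e-12:
                raise ValidationError(f"segment {i} overlaps the previous segment")
            if rate < 0 or not math.isfinite(rate):
                raise ValidationError(f"segment {i}: rate must be >= 0, got {rate!r}")
            prev_end = end

    @property
    def total_volume(self) -> float:
        """Total infused volume in mL, Σ rate·(end−start)."""
        return sum(r * (e - s) for s, e, r in self.segments)

    @property
    def end_time(self) -> float:
        return self.segments[-1][1] if self.segments else 0.0

    def rate_at(self, t: float) -> float:
        for start, end, rate in self.segments:
            if start <= t < end:
                return rate
        return 0.0


@dataclass
class SubjectRecord:
    """One cat-experiment: metadata plus aligned hematology/urine series.

    ``samples`` holds one point per sampling time (the time-0 entry is the
    duplicate-baseline mean when duplicates are present); ``urine`` holds
    (time, cumulative bladder volume in mL) pairs.
    """

    subject_id: str
    body_weight: float               # kg
    age: float | None                # weeks
    fluid_type: FluidType
    dose: float                      # mL/kg
    infusion_duration: float         # min
    samples: list[SamplePoint] = field(default_factory=list)
    urine: list[tuple[float, float]] = field(default_factory=list)
    baseline_duplicates: tuple[SamplePoint, SamplePoint] | None = None

    def __post_init__(self) -> None:
        for name, val in (("body_weight", self.body_weight), ("dose", self.dose),
                          ("infusion_duration", self.infusion_duration)):
            _check_positive(name, val, self.subject_id)
        times = [p.time for p in self.samples]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError(
                f"{self.subject_id}: sample times must be strictly increasing, got {times}")
        if times and times[-1] > OBSERVATION_HORIZON_MIN + 1e-9:
            raise ValidationError(
                f"{self.subject_id}: last sample at {times[-1]} min exceeds the "
                f"{OBSERVATION_HORIZON_MIN:.0f}-min observation horizon")
        if self.baseline_duplicates is not None:
            d1, d2 = self.baseline_duplicates
            if d1.time != 0 or d2.time != 0:
                raise ValidationError(
                    f"{self.subject_id}: baseline duplicates must both be at time 0")

    @property
    def schedule(self) -> InfusionSchedule:
        return schedule_from_prescription(self.dose, self.body_weight,
                                          self.infusion_duration)

    @property
    def key(self) -> tuple[str, str]:
        return (self.subject_id, self.fluid_type.value)

    @property
    def urine_total(self) -> float | None:
        """Net urine production over the window (last minus first bladder
        volume, mL); None when fewer than two bladder estimates exist."""
        if len(self.urine) >= 2:
            return max(self.urine[-1][1] - self.urine[0][1], 0.0)
        return None

    def mean_map(self) -> float | None:
        vals = [p.map for p in self.samples if p.map is not None]
        return float(sum(vals) / len(vals)) if vals else None

    def covariates(self) -> dict[str, float | str]:
        """Subject-level covariate table used by the covariate search."""
        out: dict[str, float | str] = {
            "fluid_type": self.fluid_type.value,
            "body_weight": self.body_weight,
        }
        if self.age is not None:
            out["age"] = self.age
        for name, attr in (("SAP", "sap"), ("DAP", "dap"), ("MAP", "map"), ("HR", "hr")):
            vals = [getattr(p, attr) for p in self.samples
                    if getattr(p, attr) is not None]
            if vals:
                out[name] = float(sum(vals) / len(vals))
        return out


@dataclass(frozen=True)
class LoadReport:
    """Row accounting for a cohort load: how many sampling rows carried no
    dilution information (missing both hb and rbc) out of the total."""

    n_rows: int
    n_missing: int
    missing_keys: tuple[tuple[str, str, float], ...] = ()

    @property
    def missing_fraction(self) -> float:
        return self.n_missing / self.n_rows if self.n_rows else 0.0

    def __str__(self) -> str:
        return (f"{self.n_missing} of {self.n_rows} sampling rows "
                f"({100 * self.missing_fraction:.1f}%) missing both hb and rbc")


def schedule_from_prescription(dose: float, body_weight: float,
                               duration: float) -> InfusionSchedule:
    """Single-segment schedule delivering ``dose`` mL/kg over ``duration`` min.

    The rate is dose·body_weight/duration; total infused volume equals
    dose·body_weight exactly.
    """
    for name, val in (("dose", dose), ("body_weight", body_weight),
                      ("duration", duration)):
        _check_positive(name, val)
    return InfusionSchedule(((0.0, float(duration),
                              dose * body_weight / duration),))


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # surface the offending file, keep pandas detail
        raise ValidationError(f"malformed CSV {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing required columns {missing}; unit-bearing headers "
            f"are mandatory (expected {list(required)})")
    return df


def _opt(value) -> float | None:
    return None if pd.isna(value) else float(value)


def _point_from_row(row: pd.Series, path, idx) -> SamplePoint:
    try:
        return SamplePoint(
            time=float(row["time_min"]), hb=_opt(row["hb_g_per_L"]),
            rbc=_opt(row["rbc_1e12_per_L"]), hct=_opt(row["hct_frac"]),
            sap=_opt(row["sap_mmHg"]), dap=_opt(row["dap_mmHg"]),
            map=_opt(row["map_mmHg"]), hr=_opt(row["hr_bpm"]))
    except ValidationError as exc:
        raise ValidationError(f"{path} row {idx + 2}: {exc}") from exc


def _mean_point(d1: SamplePoint, d2: SamplePoint) -> SamplePoint:
    def m(a, b):
        present = [x for x in (a, b) if x is not None]
        return sum(present) / len(present) if present else None

    return SamplePoint(time=0.0, hb=m(d1.hb, d2.hb), rbc=m(d1.rbc, d2.rbc),
                       hct=m(d1.hct, d2.hct), sap=m(d1.sap, d2.sap),
                       dap=m(d1.dap, d2.dap), map=m(d1.map, d2.map),
                       hr=m(d1.hr, d2.hr))


def read_subjects(hematology_csv: str | Path, urine_csv: str | Path,
                  metadata_csv: str | Path) -> tuple[list[SubjectRecord], LoadReport]:
    """Assemble one :class:`SubjectRecord` per (subject, fluid) from the three
    study tables.

    Two time-0 rows per record are interpreted as the duplicate baseline; the
    record's time-0 sample is their per-analyte mean.  Duplicate times
    anywhere else are a validation error.  Rows missing both hb and rbc are
    kept with missing flags and counted in the returned :class:`LoadReport`.
    """
    hema = _read_csv(hematology_csv, HEMATOLOGY_COLUMNS)
    urine = _read_csv(urine_csv, URINE_COLUMNS)
    meta = _read_csv(metadata_csv, METADATA_COLUMNS)

    if meta.duplicated(["subject_id", "fluid_type"]).any():
        dup = meta[meta.duplicated(["subject_id", "fluid_type"])].iloc[0]
        raise ValidationError(
            f"{metadata_csv}: duplicate metadata for ({dup['subject_id']}, "
            f"{dup['fluid_type']})")

    records: list[SubjectRecord] = []
    n_rows = 0
    missing_keys: list[tuple[str, str, float]] = []

    for _, mrow in meta.iterrows():
        sid = str(mrow["subject_id"])
        fluid = FluidType(str(mrow["fluid_type"]))
        hsub = hema[(hema["subject_id"].astype(str) == sid)
                    & (hema["fluid_type"] == fluid.value)]
        points: list[SamplePoint] = []
        duplicates: list[SamplePoint] = []
        seen_times: set[float] = set()
        for idx, row in hsub.iterrows():
            pt = _point_from_row(row, hematology_csv, idx)
            n_rows += 1
            if not pt.has_dilution_info:
                missing_keys.append((sid, fluid.value, pt.time))
            if pt.time == 0.0:
                duplicates.append(pt)
                if len(duplicates) > 2:
                    raise ValidationError(
                        f"{hematology_csv}: more than two time-0 rows for "
                        f"({sid}, {fluid.value})")
                continue
            if pt.time in seen_times:
                raise ValidationError(
                    f"{hematology_csv}: duplicate time {pt.time} min for "
                    f"({sid}, {fluid.value})")
            seen_times.add(pt.time)
            points.append(pt)

        baseline_pair = None
        if len(duplicates) == 2:
            baseline_pair = (duplicates[0], duplicates[1])
            points.insert(0, _mean_point(*duplicates))
        elif len(duplicates) == 1:
            points.insert(0, duplicates[0])
        points.sort(key=lambda p: p.time)

        usub = urine[(urine["subject_id"].astype(str) == sid)
                     & (urine["fluid_type"] == fluid.value)]
        useries = sorted((float(r["time_min"]), float(r["bladder_volume_mL"]))
                         for _, r in usub.iterrows())

        records.append(SubjectRecord(
            subject_id=sid,
            body_weight=float(mrow["body_weight_kg"]),
            age=_opt(mrow["age_weeks"]),
            fluid_type=fluid,
            dose=float(mrow["dose_mL_per_kg"]),
            infusion_duration=float(mrow["infusion_duration_min"]),
            samples=points,
            urine=useries,
            baseline_duplicates=baseline_pair,
        ))

    report = LoadReport(n_rows=n_rows, n_missing=len(missing_keys),
                        missing_keys=tuple(missing_keys))
    return records, report


def write_subjects(records: Iterable[SubjectRecord], hematology_csv: str | Path,
                   urine_csv: str | Path, metadata_csv: str | Path) -> None:
    """Write the three study tables; inverse of :func:`read_subjects`."""
    hema_rows, urine_rows, meta_rows = [], [], []
    for rec in records:
        meta_rows.append({
            "subject_id": rec.subject_id, "fluid_type": rec.fluid_type.value,
            "body_weight_kg": rec.body_weight, "age_weeks": rec.age,
            "dose_mL_per_kg": rec.dose,
            "infusion_duration_min": rec.infusion_duration,
        })
        if rec.baseline_duplicates is not None:
            pts: list[SamplePoint] = [*rec.baseline_duplicates,
                                      *[p for p in rec.samples if p.time > 0]]
        else:
            pts = list(rec.samples)
        for p in pts:
            hema_rows.append({
                "subject_id": rec.subject_id, "fluid_type": rec.fluid_type.value,
                "time_min": p.time, "hb_g_per_L": p.hb, "rbc_1e12_per_L": p.rbc,
                "hct_frac": p.hct, "sap_mmHg": p.sap, "dap_mmHg": p.dap,
                "map_mmHg": p.map, "hr_bpm": p.hr,
            })
        for t, vol in rec.urine:
            urine_rows.append({
                "subject_id": rec.subject_id, "fluid_type": rec.fluid_type.value,
                "time_min": t, "bladder_volume_mL": vol,
            })
    pd.DataFrame(hema_rows, columns=HEMATOLOGY_COLUMNS).to_csv(
        hematology_csv, index=False)
    pd.DataFrame(urine_rows, columns=URINE_COLUMNS).to_csv(
        urine_csv, index=False)
    pd.DataFrame(meta_rows, columns=METADATA_COLUMNS).to_csv(
        metadata_csv, index=False)
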