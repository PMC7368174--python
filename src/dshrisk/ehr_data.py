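"""Data model, readers and validators for longitudinal EHR timelines.

All times are decimal patient age in years (age-time scale); intervals are
half-open ``[start, end)``.  A cohort is exchanged as three flat CSV files:

* ``demographics.csv``: ``patient_id,sex,race,age_at_index``
* ``events.csv``: ``patient_id,event_age,kind,code,value,unit,dose_change``
* ``outcomes.csv``: ``patient_id,entry_age,exit_age,acm_event,mce_event``

Condition definitions (diagnosis code sets, lab indication thresholds,
control reference ranges, therapy-line maps) come from a YAML configuration;
:func:`load_conditions` ships defaults for type 2 diabetes, hypertension,
hyperlipidemia and obesity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

EVENT_KINDS = ("diagnosis", "lab", "vital", "medication")
DOSE_CHANGES = ("increase", "decrease", "none")

DEMOGRAPHICS_COLUMNS = ["patient_id", "sex", "race", "age_at_index"]
EVENTS_COLUMNS = ["patient_id", "event_age", "kind", "code", "value", "unit", "dose_change"]
OUTCOMES_COLUMNS = ["patient_id", "entry_age", "exit_age", "acm_event", "mce_event"]


class SchemaError(ValueError):
    """A CSV file does not conform to the documented schema."""


class ValidationError(ValueError):
    """Cross-record integrity violation (duplicate ids, unknown patients...)."""


class UnitError(ValueError):
    """A measurement carries a unit that cannot be reconciled."""


class WindowError(ValueError):
    """A query age falls outside the relevant study window."""


class ConfigurationError(ValueError):
    """Invalid or inconsistent configuration."""


@dataclass(frozen=True)
class Demographics:
    patient_id: str
    sex: str
    race: str
    age_at_index: float


@dataclass(frozen=True)
class ClinicalEvent:
    patient_id: str
    event_age: float
    kind: str
    code: str
    value: Optional[float] = None
    unit: Optional[str] = None
    dose_change: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValidationError(f"unknown event kind {self.kind!r}")
        if self.event_age <= 0:
            raise ValidationError(f"event_age must be positive, got {self.event_age}")
        has_value = self.value is not None and not pd.isna(self.value)
        if self.kind in ("lab", "vital") and not has_value:
            raise ValidationError(f"{self.kind} event {self.code!r} requires a numeric value")
        if self.kind in ("diagnosis", "medication") and has_value:
            raise ValidationError(f"{self.kind} event {self.code!r} must not carry a value")


@dataclass(frozen=True)
class Followup:
    entry_age: float
    exit_age: float
    acm_event: int
    mce_event: int

    def __post_init__(self) -> None:
        if not self.entry_age < self.exit_age:
            raise ValidationError(
                f"entry_age {self.entry_age} must precede exit_age {self.exit_age}"
            )


@dataclass
class PatientTimeline:
    demographics: Demographics
    events: list[ClinicalEvent]
    followup: Followup

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: (e.event_age, _KIND_ORDER[e.kind]))

    @property
    def patient_id(self) -> str:
        return self.demographics.patient_id

    def encounter_ages(self, window: tuple[float, float] | None = None) -> list[float]:
        """Distinct event ages, optionally restricted to half-open ``window``."""
        ages = sorted({e.event_age for e in self.events})
        if window is not None:
            lo, hi = window
            ages = [a for a in ages if lo <= a < hi]
        return ages

    def events_in(self, window: tuple[float, float]) -> list[ClinicalEvent]:
        lo, hi = window
        return [e for e in self.events if lo <= e.event_age < hi]


# tie-break when several events share an age: diagnoses, then medication
# orders, then measurements, so classification sees the day's actions first
_KIND_ORDER = {"diagnosis": 0, "medication": 1, "lab": 2, "vital": 2}


@dataclass(frozen=True)
class LabCriterion:
    measurement: str
    comparator: str  # one of >=, >, <=, <
    threshold: float

    def is_met(self, value: float) -> bool:
        if self.comparator == ">=":
            return value >= self.threshold
        if self.comparator == ">":
            return value > self.threshold
        if self.comparator == "<=":
            return value <= self.threshold
        if self.comparator == "<":
            return value < self.threshold
        raise ConfigurationError(f"unknown comparator {self.comparator!r}")


@dataclass(frozen=True)
class ControlCriterion:
    """Reference range; a value inside [lower, upper) counts as controlled."""

    measurement: str
    lower: float
    upper: float

    def in_range(self, value: float) -> bool:
        return self.lower <= value < self.upper


@dataclass
class ConditionDefinition:
    name: str
    diagnosis_codes: frozenset[str] = frozenset()
    lab_criteria: tuple[LabCriterion, ...] = ()
    control_criteria: tuple[ControlCriterion, ...] = ()
    therapy_lines: Mapping[str, str] = field(default_factory=dict)
    last_if_n_classes: Optional[int] = None
    severity_mode: str = "therapy"  # or "bands"
    band_measurement: Optional[str] = None
    band_thresholds: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not self.diagnosis_codes and not self.lab_criteria:
            raise ConfigurationError(
                f"condition {self.name!r} needs diagnosis codes or lab criteria"
            )
        if self.severity_mode not in ("therapy", "bands"):
            raise ConfigurationError(f"unknown severity_mode {self.severity_mode!r}")
        if self.severity_mode == "bands" and not self.band_measurement:
            raise ConfigurationError(f"bands condition {self.name!r} needs band_measurement")

    @property
    def drug_classes(self) -> frozenset[str]:
        return frozenset(self.therapy_lines)

    @property
    def control_measurements(self) -> frozenset[str]:
        return frozenset(c.measurement for c in self.control_criteria)


@dataclass(frozen=True)
class StudyWindows:
    """Baseline time window and prediction horizons on the age scale."""

    btw: tuple[float, float]
    horizons: tuple[float, ...] = (60.0, 65.0, 75.0, 80.0)
    truncation_age: float = 51.0

    def __post_init__(self) -> None:
        if not self.btw[0] < self.btw[1]:
            raise ConfigurationError("baseline time window is empty")
        if any(b >= a for a, b in zip(self.horizons[1:], self.horizons)):
            raise ConfigurationError("horizons must be strictly increasing")


@dataclass
class StudyConfig:
    """Conditions plus the measurement-unit registry."""

    conditions: dict[str, ConditionDefinition]
    measurement_units: dict[str, str]

    @property
    def diagnosis_vocabulary(self) -> frozenset[str]:
        out: set[str] = set()
        for c in self.conditions.values():
            out |= set(c.diagnosis_codes)
        return frozenset(out)

    @property
    def drug_vocabulary(self) -> frozenset[str]:
        out: set[str] = set()
        for c in self.conditions.values():
            out |= set(c.therapy_lines)
        return frozenset(out)

    @property
    def measurement_vocabulary(self) -> frozenset[str]:
        return frozenset(self.measurement_units)


def _parse_condition(name: str, raw: Mapping) -> ConditionDefinition:
    labs = tuple(
        LabCriterion(r["measurement"], r["comparator"], float(r["threshold"]))
        for r in raw.get("lab_criteria", [])
    )
    controls = tuple(
        ControlCriterion(r["measurement"], float(r["lower"]), float(r["upper"]))
        for r in raw.get("control_criteria", [])
    )
    return ConditionDefinition(
        name=name,
        diagnosis_codes=frozenset(raw.get("diagnosis_codes", [])),
        lab_criteria=labs,
        control_criteria=controls,
        therapy_lines=dict(raw.get("therapy_lines", {})),
        last_if_n_classes=raw.get("last_if_n_classes"),
        severity_mode=raw.get("severity_mode", "therapy"),
        band_measurement=raw.get("band_measurement"),
        band_thresholds=tuple(float(t) for t in raw.get("band_thresholds", [])),
    )


def load_conditions(path: str | Path | None = None) -> StudyConfig:
    """Load condition definitions; ``None`` loads the packaged defaults."""
    if path is None:
        text = resources.files("dshrisk.data").joinpath("conditions.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    conditions = {name: _parse_condition(name, body) for name, body in raw["conditions"].items()}
    return StudyConfig(conditions=conditions, measurement_units=dict(raw.get("measurements", {})))


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {', '.join(missing)}")


def _check_unit(measurement: str, unit, units: Mapping[str, str]) -> None:
    if measurement not in units:
        return
    if unit is None or (isinstance(unit, float) and pd.isna(unit)) or unit == "":
        return  # unit omitted: canonical assumed
    if str(unit) != units[measurement]:
        raise UnitError(
            f"measurement {measurement!r} expects unit {units[measurement]!r}, got {unit!r}"
        )


def read_cohort(
    demographics_path: str | Path,
    events_path: str | Path,
    outcomes_path: str | Path,
    config: StudyConfig,
) -> list[PatientTimeline]:
    """Read and validate a cohort from its three CSV files.

    Events with codes outside the configured vocabulary are rejected with a
    logged report; events dated at or after follow-up exit are dropped with a
    warning.  Duplicate patient ids or outcome rows for unknown patients
    raise :class:`ValidationError`.
    """
    # round_trip parsing so write_cohort -> read_cohort is bit-exact on floats
    demo = pd.read_csv(demographics_path, dtype={"patient_id": str},
                       float_precision="round_trip")
    events = pd.read_csv(events_path, dtype={"patient_id": str},
                         float_precision="round_trip")
    outcomes = pd.read_csv(outcomes_path, dtype={"patient_id": str},
                           float_precision="round_trip")
    _require_columns(demo, DEMOGRAPHICS_COLUMNS, "demographics file")
    _require_columns(events, ["patient_id", "event_age", "kind", "code"], "events file")
    _require_columns(outcomes, OUTCOMES_COLUMNS, "outcomes file")
    for opt in ("value", "unit", "dose_change"):
        if opt not in events.columns:
            events[opt] = None

    if demo["patient_id"].duplicated().any():
        dupes = demo.loc[demo["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValidationError(f"duplicate patient_id in demographics: {dupes}")
    known = set(demo["patient_id"])
    unknown_outcomes = set(outcomes["patient_id"]) - known
    if unknown_outcomes:
        raise ValidationError(f"outcomes for unknown patient_id: {sorted(unknown_outcomes)}")
    missing_outcomes = known - set(outcomes["patient_id"])
    if missing_outcomes:
        raise ValidationError(f"patients without outcomes: {sorted(missing_outcomes)}")

    vocab = config.diagnosis_vocabulary | config.drug_vocabulary | config.measurement_vocabulary
    bad = ~events["code"].isin(vocab)
    if bad.any():
        rejected = events.loc[bad, "code"].value_counts()
        logger.warning(
            "rejected %d event rows with unknown codes: %s",
            int(bad.sum()),
            rejected.to_dict(),
        )
        events = events.loc[~bad]

    out: list[PatientTimeline] = []
    exit_by_pid = outcomes.set_index("patient_id")
    for _, drow in demo.iterrows():
        pid = drow["patient_id"]
        orow = exit_by_pid.loc[pid]
        fu = Followup(
            entry_age=float(orow["entry_age"]),
            exit_age=float(orow["exit_age"]),
            acm_event=int(orow["acm_event"]),
            mce_event=int(orow["mce_event"]),
        )
        evrows = events[events["patient_id"] == pid]
        evs: list[ClinicalEvent] = []
        for _, r in evrows.iterrows():
            if float(r["event_age"]) >= fu.exit_age:
                logger.warning(
                    "patient %s: event %r at age %.3f on/after follow-up exit %.3f excluded",
                    pid, r["code"], float(r["event_age"]), fu.exit_age,
                )
                continue
            if r["kind"] in ("lab", "vital"):
                _check_unit(r["code"], r.get("unit"), config.measurement_units)
            value = r.get("value")
            value = None if pd.isna(value) else float(value)
            dose = r.get("dose_change")
            dose = None if (dose is None or pd.isna(dose) or dose == "") else str(dose)
            evs.append(
                ClinicalEvent(
                    patient_id=pid,
                    event_age=float(r["event_age"]),
                    kind=str(r["kind"]),
                    code=str(r["code"]),
                    value=value,
                    unit=None if pd.isna(r.get("unit")) else str(r.get("unit")),
                    dose_change=dose,
                )
            )
        out.append(
            PatientTimeline(
                demographics=Demographics(
                    patient_id=pid,
                    sex=str(drow["sex"]),
                    race=str(drow["race"]),
                    age_at_index=float(drow["age_at_index"]),
                ),
                events=evs,
                followup=fu,
            )
        )
    return out


def write_cohort(cohort: Iterable[PatientTimeline], out_dir: str | Path) -> dict[str, Path]:
    """Write a cohort back to its three CSV files; inverse of :func:`read_cohort`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    demo_rows, event_rows, outcome_rows = [], [], []
    for tl in cohort:
        d = tl.demographics
        demo_rows.append([d.patient_id, d.sex, d.race, d.age_at_index])
        for e in tl.events:
            event_rows.append(
                [e.patient_id, e.event_age, e.kind, e.code, e.value, e.unit, e.dose_change]
            )
        f = tl.followup
        outcome_rows.append([d.patient_id, f.entry_age, f.exit_age, f.acm_event, f.mce_event])
    paths = {
        "demographics": out_dir / "demographics.csv",
        "events": out_dir / "events.csv",
        "outcomes": out_dir / "outcomes.csv",
    }
    pd.DataFrame(demo_rows, columns=DEMOGRAPHICS_COLUMNS).to_csv(paths["demographics"], index=False)
    pd.DataFrame(event_rows, columns=EVENTS_COLUMNS).to_csv(paths["events"], index=False)
    pd.DataFrame(outcome_rows, columns=OUTCOMES_COLUMNS).to_csv(paths["outcomes"], index=False)
    return paths


def condition_indication(
    timeline: PatientTimeline,
    condition_def: ConditionDefinition,
    window: tuple[float, float],
    measurement_units: Mapping[str, str] | None = None,
) -> list[tuple[float, int]]:
    """Per-encounter condition indication within a half-open age window.

    An encounter indicates the condition when a diagnosis code matches or any
    lab criterion is met by a measurement recorded at that encounter age.
    Returns one ``(age, 0/1)`` pair per encounter; empty if no encounters.
    """
    units = measurement_units or {}
    crit_by_meas: dict[str, list[LabCriterion]] = {}
    for c in condition_def.lab_criteria:
        crit_by_meas.setdefault(c.measurement, []).append(c)

    result: list[tuple[float, int]] = []
    for age in timeline.encounter_ages(window):
        indicated = 0
        for e in timeline.events:
            if e.event_age != age:
                continue
            if e.kind == "diagnosis" and e.code in condition_def.diagnosis_codes:
                indicated = 1
                break
            if e.kind in ("lab", "vital") and e.code in crit_by_meas:
                _check_unit(e.code, e.unit, units)
                if any(c.is_met(e.value) for c in crit_by_meas[e.code]):
                    indicated = 1
                    break
        result.append((age, indicated))
    return result
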