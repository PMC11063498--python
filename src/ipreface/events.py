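"""Domain types for annotated CTG deceleration events and labor cases.

A labor case is an ordered stream of clinician-annotated decelerations plus
the three timeline marks the scoring windows anchor to: the decision for
emergency cesarean delivery, the removal of the CTG transducer, and the
delivery itself.  Each deceleration carries the four categorical axes of the
JSOG five-tier classification (baseline rate, variability, deceleration type,
severity); the risk level 1-5 is assigned by table lookup, with a clinician
override taking precedence.

The five-tier level table ships as editable YAML data
(``data/five_tier_jsog_v1.yaml``); all downstream code is table-agnostic.
"""

from __future__ import annotations

import json
import math
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .exceptions import ClassificationError, SchemaError, TimelineValidationError

DecelType = Literal["early", "late", "variable", "prolonged"]
Severity = Literal["mild", "severe"]
BaselineRate = Literal["bradycardia", "normal", "tachycardia"]
Variability = Literal["absent", "minimal", "moderate", "marked"]

#: axis domains of the five-tier rule table; "none" marks a tracing segment
#: with no deceleration (used only for table completeness, not for events)
BASELINE_RATES: tuple[str, ...] = ("bradycardia", "normal", "tachycardia")
VARIABILITIES: tuple[str, ...] = ("absent", "minimal", "moderate", "marked")
TABLE_DECEL_TYPES: tuple[str, ...] = ("none", "early", "late", "variable", "prolonged")
SEVERITIES: tuple[str, ...] = ("mild", "severe")

#: prolonged decelerations last >= 2 min; >= 10 min is treated as a baseline
#: change and rejected from event streams
PROLONGED_MIN_S = 120.0
PROLONGED_MAX_S = 600.0


class DecelerationEvent(BaseModel):
    """One annotated FHR deceleration.

    Times are seconds from recording start.  ``level`` is the five-tier risk
    level (1 normal ... 5 severe abnormality), either assigned by
    :func:`classify_level` or carried as a clinician ``level_override``.
    """

    model_config = ConfigDict(frozen=True)

    onset: float = Field(ge=0)
    duration: float = Field(gt=0)
    decel_type: DecelType
    severity: Severity
    baseline_rate: BaselineRate
    variability: Variability
    level: Optional[int] = Field(default=None, ge=1, le=5)
    level_override: Optional[int] = Field(default=None, ge=1, le=5)

    @model_validator(mode="after")
    def _check_prolonged_duration(self) -> "DecelerationEvent":
        if self.decel_type == "prolonged" and not (
            PROLONGED_MIN_S <= self.duration < PROLONGED_MAX_S
        ):
            raise ValueError(
                f"prolonged deceleration duration must lie in "
                f"[{PROLONGED_MIN_S:.0f}, {PROLONGED_MAX_S:.0f}) s, "
                f"got {self.duration:g} s (>= 10 min is a baseline change)"
            )
        return self

    @property
    def nadir_time(self) -> float:
        """Midpoint proxy for the nadir when it is not separately annotated."""
        return self.onset + self.duration / 2.0

    @property
    def end(self) -> float:
        return self.onset + self.duration

    @property
    def is_prolonged(self) -> bool:
        return self.decel_type == "prolonged"


class BloodGasPanel(BaseModel):
    """Umbilical artery blood-gas panel at birth."""

    model_config = ConfigDict(frozen=True)

    ph: float = Field(ge=6.5, le=7.6)
    pco2: float = Field(gt=0)  # mm Hg
    po2: float = Field(gt=0)  # mm Hg
    hco3: float = Field(gt=0)  # mmol/L
    be: float  # mEq/L
    lactate: float = Field(ge=0)  # mmol/L

    def acidemia(self, threshold: float = 7.2) -> bool:
        """Fetal acidemia predicate: pH below ``threshold`` (7.2 primary,
        7.1 and 7.0 secondary)."""
        return self.ph < threshold


class LaborCase(BaseModel):
    """A patient's deceleration stream, timeline marks, covariates and outcomes.

    Timeline invariant: recording_start <= decision_time <= removal_time
    <= delivery_time, and every event onset lies within the recording.
    """

    model_config = ConfigDict(frozen=True)

    case_id: str
    events: tuple[DecelerationEvent, ...] = ()
    recording_start: float = 0.0
    recording_end: float
    decision_time: float
    removal_time: float
    delivery_time: float
    coverage_gaps: tuple[tuple[float, float], ...] = ()
    maternal_age: Optional[float] = None
    parity: Optional[int] = None
    gestational_week: Optional[float] = None
    induction: Optional[bool] = None
    vacuum: Optional[bool] = None
    blood_gas: Optional[BloodGasPanel] = None
    apgar1: Optional[int] = Field(default=None, ge=0, le=10)
    apgar5: Optional[int] = Field(default=None, ge=0, le=10)
    nicu_asphyxia: Optional[bool] = None

    @model_validator(mode="after")
    def _check_timeline(self) -> "LaborCase":
        if not (
            self.recording_start
            <= self.decision_time
            <= self.removal_time
            <= self.delivery_time
        ):
            raise ValueError(
                f"case {self.case_id}: timeline must satisfy recording_start "
                f"<= decision_time <= removal_time <= delivery_time, got "
                f"({self.recording_start:g}, {self.decision_time:g}, "
                f"{self.removal_time:g}, {self.delivery_time:g})"
            )
        if self.recording_end < self.recording_start:
            raise ValueError(f"case {self.case_id}: recording ends before it starts")
        for ev in self.events:
            if not (self.recording_start <= ev.onset <= self.recording_end):
                raise ValueError(
                    f"case {self.case_id}: event onset {ev.onset:g} s outside "
                    f"recording [{self.recording_start:g}, {self.recording_end:g}]"
                )
        for lo, hi in self.coverage_gaps:
            if hi <= lo:
                raise ValueError(f"case {self.case_id}: empty coverage gap ({lo}, {hi})")
        return self

    def with_events(self, events: Iterable[DecelerationEvent]) -> "LaborCase":
        return self.model_copy(update={"events": tuple(events)})


class FiveTierRuleTable:
    """Mapping (baseline_rate, variability, decel_type, severity) -> level 1-5.

    The table is complete over the four categorical axes (the deceleration
    axis includes ``none`` for segments without a deceleration) and monotone
    in severity and in variability degradation.
    """

    def __init__(
        self,
        entries: dict[tuple[str, str, str, str], int],
        table_id: str = "custom",
        version: str = "0",
    ) -> None:
        self.entries = dict(entries)
        self.table_id = table_id
        self.version = version
        self.validate()

    def validate(self) -> None:
        for b in BASELINE_RATES:
            for v in VARIABILITIES:
                for d in TABLE_DECEL_TYPES:
                    for s in SEVERITIES:
                        key = (b, v, d, s)
                        if key not in self.entries:
                            raise ClassificationError(
                                f"rule table {self.table_id!r} missing entry {key}"
                            )
                        lvl = self.entries[key]
                        if lvl not in (1, 2, 3, 4, 5):
                            raise ClassificationError(
                                f"rule table {self.table_id!r}: level {lvl} at "
                                f"{key} outside 1..5"
                            )
        # monotone in severity and variability degradation
        for b in BASELINE_RATES:
            for d in TABLE_DECEL_TYPES:
                for v in VARIABILITIES:
                    if self.entries[(b, v, d, "severe")] < self.entries[(b, v, d, "mild")]:
                        raise ClassificationError(
                            f"rule table {self.table_id!r}: severity monotonicity "
                            f"violated at ({b}, {v}, {d})"
                        )
                for s in SEVERITIES:
                    if self.entries[(b, "absent", d, s)] < self.entries[(b, "moderate", d, s)]:
                        raise ClassificationError(
                            f"rule table {self.table_id!r}: variability monotonicity "
                            f"violated at ({b}, {d}, {s})"
                        )
        if self.entries[("normal", "moderate", "none", "mild")] != 1:
            raise ClassificationError(
                "rule table must map (normal, moderate, no deceleration) to level 1"
            )

    def lookup(self, baseline_rate: str, variability: str, decel_type: str, severity: str) -> int:
        key = (baseline_rate, variability, decel_type, severity)
        try:
            return self.entries[key]
        except KeyError:
            raise ClassificationError(f"rule table {self.table_id!r} has no entry {key}") from None

    # --- serialization -----------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FiveTierRuleTable":
        with open(path) as fh:
            return cls._from_mapping(yaml.safe_load(fh))

    @classmethod
    def _from_mapping(cls, doc: dict) -> "FiveTierRuleTable":
        entries = {
            (r["baseline_rate"], r["variability"], r["decel_type"], r["severity"]): int(r["level"])
            for r in doc["rows"]
        }
        return cls(entries, table_id=doc.get("table_id", "custom"), version=str(doc.get("version", "0")))

    def to_yaml(self, path: str | Path) -> None:
        rows = [
            {"baseline_rate": b, "variability": v, "decel_type": d, "severity": s, "level": lvl}
            for (b, v, d, s), lvl in sorted(self.entries.items())
        ]
        doc = {"table_id": self.table_id, "version": self.version, "rows": rows}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def default(cls) -> "FiveTierRuleTable":
        """The shipped default transcription of the JSOG five-tier table."""
        ref = resources.files("ipreface.data") / "five_tier_jsog_v1.yaml"
        return cls._from_mapping(yaml.safe_load(ref.read_text()))


def classify_level(event: DecelerationEvent, table: FiveTierRuleTable) -> DecelerationEvent:
    """Return a copy of ``event`` with its five-tier level assigned.

    A clinician-annotated ``level_override`` takes precedence over the table
    lookup.  The input event is not modified.
    """
    if event.level_override is not None:
        return event.model_copy(update={"level": event.level_override})
    level = table.lookup(event.baseline_rate, event.variability, event.decel_type, event.severity)
    return event.model_copy(update={"level": level})


def is_nrfs(level: int) -> bool:
    """Non-reassuring fetal status: five-tier levels 3-5."""
    if level not in (1, 2, 3, 4, 5):
        raise ValueError(f"five-tier level must be in 1..5, got {level!r}")
    return level >= 3


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

EVENT_COLUMNS = [
    "case_id", "onset_s", "duration_s", "decel_type", "severity",
    "baseline_rate", "variability", "level_override",
]
CASE_COLUMNS = [
    "case_id", "recording_start_s", "recording_end_s", "decision_time_s",
    "removal_time_s", "delivery_time_s", "maternal_age", "parity",
    "gestational_week", "induction", "vacuum", "ph", "pco2", "po2", "hco3",
    "be", "lactate", "apgar1", "apgar5", "nicu_asphyxia",
]

SCHEMA_VERSION = "1"


def _opt(val, cast=float):
    if val is None or (isinstance(val, float) and math.isnan(val)) or val == "":
        return None
    return cast(val)


def write_cases(cases: list[LaborCase], cases_path: str | Path, events_path: str | Path | None = None) -> None:
    """Write a cohort to the documented CSV (or JSON) schemas.

    ``cases_path`` ending in ``.json`` writes a single JSON document with
    events inline; otherwise a cases CSV is written and, if ``events_path``
    is given, a one-row-per-deceleration events CSV alongside it.
    """
    cases_path = Path(cases_path)
    if cases_path.suffix == ".json":
        doc = {
            "schema_version": SCHEMA_VERSION,
            "cases": [json.loads(c.model_dump_json()) for c in cases],
        }
        cases_path.write_text(json.dumps(doc, indent=1, sort_keys=True))
        return

    rows = []
    for c in cases:
        bg = c.blood_gas
        rows.append({
            "case_id": c.case_id,
            "recording_start_s": c.recording_start,
            "recording_end_s": c.recording_end,
            "decision_time_s": c.decision_time,
            "removal_time_s": c.removal_time,
            "delivery_time_s": c.delivery_time,
            "maternal_age": c.maternal_age,
            "parity": c.parity,
            "gestational_week": c.gestational_week,
            "induction": None if c.induction is None else int(c.induction),
            "vacuum": None if c.vacuum is None else int(c.vacuum),
            "ph": bg.ph if bg else None,
            "pco2": bg.pco2 if bg else None,
            "po2": bg.po2 if bg else None,
            "hco3": bg.hco3 if bg else None,
            "be": bg.be if bg else None,
            "lactate": bg.lactate if bg else None,
            "apgar1": c.apgar1,
            "apgar5": c.apgar5,
            "nicu_asphyxia": None if c.nicu_asphyxia is None else int(c.nicu_asphyxia),
        })
    # repr keeps the shortest round-trip representation of every real
    pd.DataFrame(rows, columns=CASE_COLUMNS).to_csv(
        cases_path, index=False, float_format=lambda v: repr(float(v)))

    if events_path is not None:
        erows = []
        for c in cases:
            for ev in c.events:
                erows.append({
                    "case_id": c.case_id,
                    "onset_s": ev.onset,
                    "duration_s": ev.duration,
                    "decel_type": ev.decel_type,
                    "severity": ev.severity,
                    "baseline_rate": ev.baseline_rate,
                    "variability": ev.variability,
                    "level_override": ev.level_override,
                })
        pd.DataFrame(erows, columns=EVENT_COLUMNS).to_csv(
            events_path, index=False, float_format=lambda v: repr(float(v)))


def read_cases(
    cases_path: str | Path,
    events_path: str | Path | None = None,
    schema_version: str = SCHEMA_VERSION,
) -> list[LaborCase]:
    """Read a cohort from the documented CSV/JSON schemas.

    Raises :class:`SchemaError` on malformed records (naming the offending
    record) and :class:`TimelineValidationError` when a record violates a
    timeline invariant.
    """
    cases_path = Path(cases_path)
    if not cases_path.exists():
        raise SchemaError(f"no such file: {cases_path}")
    if schema_version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version {schema_version!r}")

    if cases_path.suffix == ".json":
        doc = json.loads(cases_path.read_text())
        try:
            return [LaborCase.model_validate(c) for c in doc["cases"]]
        except ValueError as exc:
            raise TimelineValidationError(str(exc)) from exc

    df = pd.read_csv(cases_path, float_precision="round_trip")
    missing = set(CASE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{cases_path}: missing columns {sorted(missing)}")

    events_by_case: dict[str, list[DecelerationEvent]] = {}
    if events_path is not None:
        edf = pd.read_csv(events_path, float_precision="round_trip")
        emissing = set(EVENT_COLUMNS) - set(edf.columns)
        if emissing:
            raise SchemaError(f"{events_path}: missing columns {sorted(emissing)}")
        for i, row in edf.iterrows():
            try:
                ev = DecelerationEvent(
                    onset=float(row["onset_s"]),
                    duration=float(row["duration_s"]),
                    decel_type=row["decel_type"],
                    severity=row["severity"],
                    baseline_rate=row["baseline_rate"],
                    variability=row["variability"],
                    level_override=_opt(row["level_override"], int),
                )
            except ValueError as exc:
                raise SchemaError(f"{events_path}: record {i} ({row['case_id']}): {exc}") from exc
            events_by_case.setdefault(str(row["case_id"]), []).append(ev)

    cases = []
    for i, row in df.iterrows():
        cid = str(row["case_id"])
        bg_vals = {k: _opt(row[k]) for k in ("ph", "pco2", "po2", "hco3", "be", "lactate")}
        bg = BloodGasPanel(**bg_vals) if all(v is not None for v in bg_vals.values()) else None
        evs = sorted(events_by_case.get(cid, []), key=lambda e: e.onset)
        try:
            cases.append(LaborCase(
                case_id=cid,
                events=tuple(evs),
                recording_start=float(row["recording_start_s"]),
                recording_end=float(row["recording_end_s"]),
                decision_time=float(row["decision_time_s"]),
                removal_time=float(row["removal_time_s"]),
                delivery_time=float(row["delivery_time_s"]),
                maternal_age=_opt(row["maternal_age"]),
                parity=_opt(row["parity"], int),
                gestational_week=_opt(row["gestational_week"]),
                induction=_opt(row["induction"], lambda x: bool(int(x))),
                vacuum=_opt(row["vacuum"], lambda x: bool(int(x))),
                blood_gas=bg,
                apgar1=_opt(row["apgar1"], int),
                apgar5=_opt(row["apgar5"], int),
                nicu_asphyxia=_opt(row["nicu_asphyxia"], lambda x: bool(int(x))),
            ))
        except ValueError as exc:
            raise TimelineValidationError(f"{cases_path}: record {i} ({cid}): {exc}") from exc
    return cases
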