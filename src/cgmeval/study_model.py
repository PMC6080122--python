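"""Domain types for a CGM performance study and the CSV interchange format.

This module is the single source of truth for conventions: time is ISO 8601
UTC with second resolution, glucose is mg/dL, identifiers are opaque strings.
Readers never clamp values; clamping is a property of the synthetic
generator only.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

UTC = timezone.utc

#: mg/dL per mmol/L, used only as an optional reader conversion.
MGDL_PER_MMOLL = 18.016


class System(str, enum.Enum):
    """Sensor system family."""

    DG5_LIKE = "DG5-like"
    FL_LIKE = "FL-like"


class Site(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


class BodyLocation(str, enum.Enum):
    ABDOMEN = "abdomen"
    UPPER_ARM = "upper_arm"


class Method(str, enum.Enum):
    BGMS_CAPILLARY = "BGMS_capillary"
    HK_VENOUS = "HK_venous"


class Phase(str, enum.Enum):
    IN_HOUSE = "in_house"
    HOME_USE = "home_use"
    DYNAMIC = "dynamic"


class PairingMode(str, enum.Enum):
    LOCF = "LOCF"
    SCAN = "SCAN"
    INTERPOLATED = "INTERPOLATED"


#: Default display clamp per system, mg/dL (applied only by the generator).
DISPLAY_RANGE: dict[System, tuple[float, float]] = {
    System.DG5_LIKE: (40.0, 400.0),
    System.FL_LIKE: (40.0, 500.0),
}

#: Default warm-up (no data) duration after insertion, minutes.
DEFAULT_WARMUP_MINUTES: dict[System, int] = {
    System.DG5_LIKE: 120,
    System.FL_LIKE: 60,
}

#: Nominal storage cadence, minutes.
NOMINAL_CADENCE_MINUTES: dict[System, int] = {
    System.DG5_LIKE: 5,
    System.FL_LIKE: 15,
}


class SchemaError(ValueError):
    """A CSV file does not conform to the interchange schema."""


class StudyValidationError(ValueError):
    """One or more study invariants are violated.

    ``errors`` carries every violation found (validation is total: a
    malformed input never produces a partial silent load).
    """

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


def parse_time(s: str) -> datetime:
    """Parse an ISO 8601 UTC timestamp with second resolution."""
    dt = datetime.fromisoformat(s.replace("Z", "+00:00"))
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=UTC)
    return dt.astimezone(UTC).replace(microsecond=0)


def format_time(t: datetime) -> str:
    return t.astimezone(UTC).strftime("%Y-%m-%dT%H:%M:%SZ")


@dataclass(frozen=True, order=True)
class GlucosePoint:
    """One timestamped glucose value (UTC, mg/dL)."""

    t: datetime
    value: float


@dataclass
class SensorTrace:
    """One worn sensor's records.

    ``continuous`` holds the device-stored record at the system's nominal
    cadence; ``scans`` holds scan events (flash systems only, empty for
    DG5-like). All points lie in ``[wear_start + warmup, wear_end]``.
    """

    system: System
    participant_id: str
    site: Site
    body_location: BodyLocation
    sensor_seq: int
    wear_start: datetime
    wear_end: datetime
    warmup_minutes: int
    continuous: list[GlucosePoint] = field(default_factory=list)
    scans: list[GlucosePoint] = field(default_factory=list)

    @property
    def active_start(self) -> datetime:
        """First instant from which data may exist (warm-up excluded)."""
        return self.wear_start + timedelta(minutes=self.warmup_minutes)

    @property
    def label(self) -> str:
        return (
            f"{self.system.value}/{self.participant_id}/"
            f"{self.site.value}/seq{self.sensor_seq}"
        )

    def validate(self, display_range: tuple[float, float] | None = None) -> list[str]:
        """Return a list of invariant violations (empty if valid)."""
        errors: list[str] = []
        lo, hi = display_range or DISPLAY_RANGE[self.system]
        if self.wear_end <= self.wear_start:
            errors.append(f"{self.label}: wear_end not after wear_start")
        if self.sensor_seq < 1:
            errors.append(f"{self.label}: sensor_seq must be >= 1")
        if self.system is System.DG5_LIKE and self.scans:
            errors.append(f"{self.label}: DG5-like traces must not carry scans")
        for name, pts in (("continuous", self.continuous), ("scans", self.scans)):
            prev = None
            for p in pts:
                if prev is not None and p.t <= prev:
                    errors.append(
                        f"{self.label}: {name} timestamps not strictly "
                        f"increasing at {format_time(p.t)}"
                    )
                prev = p.t
                if not (self.active_start <= p.t <= self.wear_end):
                    errors.append(
                        f"{self.label}: {name} point {format_time(p.t)} outside "
                        f"[wear_start + warm-up, wear_end]"
                    )
                if not (lo <= p.value <= hi):
                    errors.append(
                        f"{self.label}: {name} value {p.value} outside display "
                        f"range [{lo}, {hi}]"
                    )
        return errors


@dataclass(frozen=True)
class ReferencePoint:
    """One reference glucose measurement (capillary BGMS or venous lab)."""

    t: datetime
    value: float
    method: Method
    replicate_group: str
    replicate_index: int
    is_final_replicate: bool
    therapeutic_decision: bool
    phase: Phase
    participant_id: str


@dataclass(frozen=True)
class PairedObservation:
    """One (reference, sensor) value pair.

    ``delta = cgm_value - ref.value``; ``rel_delta = delta / ref.value``.
    ``wear_start`` is carried along so wear-day stratification needs no
    trace lookup.
    """

    ref: ReferencePoint
    cgm_value: float
    cgm_time: datetime
    system: System
    participant_id: str
    site: Site
    sensor_seq: int
    pairing_mode: PairingMode
    delta: float
    rel_delta: float
    wear_start: datetime

    @classmethod
    def build(
        cls,
        ref: ReferencePoint,
        trace: SensorTrace,
        cgm_value: float,
        cgm_time: datetime,
        mode: PairingMode,
    ) -> "PairedObservation":
        delta = cgm_value - ref.value
        return cls(
            ref=ref,
            cgm_value=cgm_value,
            cgm_time=cgm_time,
            system=trace.system,
            participant_id=trace.participant_id,
            site=trace.site,
            sensor_seq=trace.sensor_seq,
            pairing_mode=mode,
            delta=delta,
            rel_delta=delta / ref.value,
            wear_start=trace.wear_start,
        )


@dataclass
class Study:
    """A full study: sensor traces plus reference measurements."""

    traces: list[SensorTrace] = field(default_factory=list)
    refs: list[ReferencePoint] = field(default_factory=list)

    def validate(self) -> None:
        """Raise :class:`StudyValidationError` listing every violation."""
        errors: list[str] = []
        for tr in self.traces:
            errors.extend(tr.validate())
        groups: dict[tuple[str, str], list[ReferencePoint]] = {}
        for r in self.refs:
            if r.replicate_index < 1:
                errors.append(
                    f"reference {r.replicate_group}: replicate_index must be >= 1"
                )
            groups.setdefault((r.participant_id, r.replicate_group), []).append(r)
        for (pid, gid), pts in groups.items():
            n_final = sum(p.is_final_replicate for p in pts)
            if n_final != 1:
                errors.append(
                    f"reference group {pid}/{gid}: expected exactly one final "
                    f"replicate, found {n_final}"
                )
        if errors:
            raise StudyValidationError(errors)

    def traces_for(self, participant_id: str) -> list[SensorTrace]:
        return [t for t in self.traces if t.participant_id == participant_id]


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

_TRACE_KEY_COLS = [
    "system",
    "participant_id",
    "site",
    "body_location",
    "sensor_seq",
    "wear_start",
    "wear_end",
    "warmup_minutes",
]
_CONT_COLS = _TRACE_KEY_COLS + ["t", "value"]
_REF_COLS = [
    "participant_id",
    "t",
    "value",
    "method",
    "replicate_group",
    "replicate_index",
    "is_final_replicate",
    "therapeutic_decision",
    "phase",
]


def _trace_key(tr: SensorTrace) -> tuple:
    return (
        tr.system.value,
        tr.participant_id,
        tr.site.value,
        tr.body_location.value,
        tr.sensor_seq,
        format_time(tr.wear_start),
        format_time(tr.wear_end),
        tr.warmup_minutes,
    )


def write_study(study: Study, path: str | os.PathLike) -> None:
    """Write ``continuous.csv``, ``scans.csv`` and ``reference.csv``.

    Output ordering and formatting are deterministic so regeneration under
    identical seeds is byte-identical.
    """
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    traces = sorted(study.traces, key=_trace_key)

    cont_rows, scan_rows = [], []
    for tr in traces:
        key = dict(zip(_TRACE_KEY_COLS, _trace_key(tr)))
        for p in tr.continuous:
            cont_rows.append({**key, "t": format_time(p.t), "value": repr(float(p.value))})
        for p in tr.scans:
            scan_rows.append({**key, "t": format_time(p.t), "value": repr(float(p.value))})

    ref_rows = []
    refs = sorted(
        study.refs,
        key=lambda r: (r.participant_id, r.t, r.method.value, r.replicate_group, r.replicate_index),
    )
    for r in refs:
        ref_rows.append(
            {
                "participant_id": r.participant_id,
                "t": format_time(r.t),
                "value": repr(float(r.value)),
                "method": r.method.value,
                "replicate_group": r.replicate_group,
                "replicate_index": r.replicate_index,
                "is_final_replicate": str(r.is_final_replicate),
                "therapeutic_decision": str(r.therapeutic_decision),
                "phase": r.phase.value,
            }
        )

    pd.DataFrame(cont_rows, columns=_CONT_COLS).to_csv(out / "continuous.csv", index=False)
    pd.DataFrame(scan_rows, columns=_CONT_COLS).to_csv(out / "scans.csv", index=False)
    pd.DataFrame(ref_rows, columns=_REF_COLS).to_csv(out / "reference.csv", index=False)


def _require_columns(df: pd.DataFrame, cols: Iterable[str], fname: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{fname}: missing required column(s) {missing}")


def _parse_bool(s: str) -> bool:
    return str(s).strip().lower() in {"true", "1", "yes"}


def read_study(
    path: str | os.PathLike,
    glucose_unit: str = "mg/dL",
    validate: bool = True,
) -> Study:
    """Read a study directory written by :func:`write_study`.

    ``glucose_unit="mmol/L"`` converts input values to mg/dL on read
    (factor 18.016). Validation is total: all invariant violations are
    collected (with CSV row numbers where available) and raised together.
    """
    if glucose_unit not in ("mg/dL", "mmol/L"):
        raise ValueError(f"unsupported glucose unit {glucose_unit!r}")
    factor = MGDL_PER_MMOLL if glucose_unit == "mmol/L" else 1.0
    p = Path(path)

    cont = pd.read_csv(p / "continuous.csv", dtype=str, keep_default_na=False)
    _require_columns(cont, _CONT_COLS, "continuous.csv")
    scans_path = p / "scans.csv"
    if scans_path.exists():
        scans = pd.read_csv(scans_path, dtype=str, keep_default_na=False)
        _require_columns(scans, _CONT_COLS, "scans.csv")
    else:
        scans = pd.DataFrame(columns=_CONT_COLS)
    refs_df = pd.read_csv(p / "reference.csv", dtype=str, keep_default_na=False)
    _require_columns(refs_df, _REF_COLS, "reference.csv")

    errors: list[str] = []
    traces: dict[tuple, SensorTrace] = {}

    def _row_points(df: pd.DataFrame, fname: str, stream: str) -> None:
        for idx, row in df.iterrows():
            rowno = int(idx) + 2  # header is row 1
            try:
                key = (
                    row["system"],
                    row["participant_id"],
                    row["site"],
                    row["body_location"],
                    int(row["sensor_seq"]),
                    row["wear_start"],
                    row["wear_end"],
                    int(row["warmup_minutes"]),
                )
                if key not in traces:
                    if stream == "scans":
                        errors.append(
                            f"{fname} row {rowno}: scan for unknown trace {key[:5]}"
                        )
                        continue
                    traces[key] = SensorTrace(
                        system=System(row["system"]),
                        participant_id=row["participant_id"],
                        site=Site(row["site"]),
                        body_location=BodyLocation(row["body_location"]),
                        sensor_seq=int(row["sensor_seq"]),
                        wear_start=parse_time(row["wear_start"]),
                        wear_end=parse_time(row["wear_end"]),
                        warmup_minutes=int(row["warmup_minutes"]),
                    )
                point = GlucosePoint(parse_time(row["t"]), float(row["value"]) * factor)
                getattr(traces[key], stream).append(point)
            except (ValueError, KeyError) as exc:
                errors.append(f"{fname} row {rowno}: {exc}")

    _row_points(cont, "continuous.csv", "continuous")
    _row_points(scans, "scans.csv", "scans")

    refs: list[ReferencePoint] = []
    for idx, row in refs_df.iterrows():
        rowno = int(idx) + 2
        try:
            refs.append(
                ReferencePoint(
                    t=parse_time(row["t"]),
                    value=float(row["value"]) * factor,
                    method=Method(row["method"]),
                    replicate_group=row["replicate_group"],
                    replicate_index=int(row["replicate_index"]),
                    is_final_replicate=_parse_bool(row["is_final_replicate"]),
                    therapeutic_decision=_parse_bool(row["therapeutic_decision"]),
                    phase=Phase(row["phase"]),
                    participant_id=row["participant_id"],
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append(f"reference.csv row {rowno}: {exc}")

    if errors:
        raise StudyValidationError(errors)

    study = Study(traces=[traces[k] for k in sorted(traces)], refs=refs)
    if validate:
        study.validate()
    return study


__all__ = [
    "UTC",
    "MGDL_PER_MMOLL",
    "System",
    "Site",
    "BodyLocation",
    "Method",
    "Phase",
    "PairingMode",
    "DISPLAY_RANGE",
    "DEFAULT_WARMUP_MINUTES",
    "NOMINAL_CADENCE_MINUTES",
    "SchemaError",
    "StudyValidationError",
    "GlucosePoint",
    "SensorTrace",
    "ReferencePoint",
    "PairedObservation",
    "Study",
    "read_study",
    "write_study",
    "parse_time",
    "format_time",
]
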