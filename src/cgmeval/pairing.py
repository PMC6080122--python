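"""Pairing rules turning sensor traces and reference points into pairs.

Three modes are supported:

* LOCF -- the last stored value within a closed window (default 5 min)
  before the reference measurement, emulating the displayed value.
* SCAN -- the scan event nearest to the reference time within a symmetric
  window (default +/-3 min), flash systems only; equidistant scans break
  toward the earlier one.
* INTERPOLATED -- linear interpolation of the continuous record to one
  value per minute; at the exact reference time the value is computed from
  the bracketing recorded points (never snapped to the minute grid).
  Interpolation never bridges gaps longer than a configurable limit
  (default 30 min) and never extrapolates.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from datetime import datetime, timedelta
from math import ceil, floor

import pandas as pd

from .study_model import (
    GlucosePoint,
    Method,
    PairedObservation,
    PairingMode,
    Phase,
    ReferencePoint,
    SensorTrace,
    Site,
    Study,
    StudyValidationError,
    System,
    format_time,
    parse_time,
)


@dataclass(frozen=True)
class PairingConfig:
    locf_window_minutes: float = 5.0
    scan_window_minutes: float = 3.0
    interpolation_step_minutes: int = 1  # fixed by contract
    max_interpolation_gap_minutes: float = 30.0
    warmup_excluded: bool = True

    def __post_init__(self):
        if self.locf_window_minutes <= 0 or self.scan_window_minutes <= 0:
            raise ValueError("pairing windows must be positive")
        if self.interpolation_step_minutes != 1:
            raise ValueError("interpolation step is fixed at 1 minute")
        if self.max_interpolation_gap_minutes <= 0:
            raise ValueError("max interpolation gap must be positive")


#: Default analysis modes per system: LOCF mirrors the displayed value for
#: real-time systems, SCAN mirrors it for flash systems; both systems also
#: get the minutely-interpolated continuous record.
DEFAULT_MODES: dict[System, tuple[PairingMode, ...]] = {
    System.DG5_LIKE: (PairingMode.LOCF, PairingMode.INTERPOLATED),
    System.FL_LIKE: (PairingMode.SCAN, PairingMode.INTERPOLATED),
}


def select_final_replicates(refs: list[ReferencePoint]) -> list[ReferencePoint]:
    """Keep exactly one point per replicate group: the final replicate."""
    out: list[ReferencePoint] = []
    seen: dict[tuple[str, str], int] = {}
    for r in refs:
        key = (r.participant_id, r.replicate_group)
        seen[key] = seen.get(key, 0)
        if r.is_final_replicate:
            seen[key] += 1
            out.append(r)
    missing = [k for k, n in seen.items() if n != 1]
    if missing:
        raise StudyValidationError(
            [f"replicate group {pid}/{gid}: expected exactly one final replicate"
             for pid, gid in missing]
        )
    return sorted(out, key=lambda r: (r.participant_id, r.t, r.method.value, r.replicate_group))


def match_locf(
    trace: SensorTrace, ref_time: datetime, cfg: PairingConfig | None = None
) -> GlucosePoint | None:
    """Latest continuous point in the closed window ``[t - w, t]``, or None."""
    cfg = cfg or PairingConfig()
    times = [p.t for p in trace.continuous]
    i = bisect_right(times, ref_time) - 1
    if i < 0:
        return None
    p = trace.continuous[i]
    if ref_time - p.t <= timedelta(minutes=cfg.locf_window_minutes):
        return p
    return None


def match_scan(
    trace: SensorTrace, ref_time: datetime, cfg: PairingConfig | None = None
) -> GlucosePoint | None:
    """Scan with minimal |t - ref_time| within the window; ties go earlier."""
    cfg = cfg or PairingConfig()
    if trace.system is not System.FL_LIKE:
        raise ValueError(f"match_scan requires an FL-like trace, got {trace.system.value}")
    window = timedelta(minutes=cfg.scan_window_minutes)
    times = [p.t for p in trace.scans]
    i = bisect_left(times, ref_time)
    candidates = []
    if i - 1 >= 0:
        candidates.append(trace.scans[i - 1])
    if i < len(times):
        candidates.append(trace.scans[i])
    best = None
    best_dist = None
    for p in candidates:  # earlier candidate first: strict < keeps it on ties
        dist = abs(p.t - ref_time)
        if dist <= window and (best_dist is None or dist < best_dist):
            best, best_dist = p, dist
    return best


def interpolate_at(
    trace: SensorTrace, t: datetime, cfg: PairingConfig | None = None
) -> float | None:
    """Linearly interpolated continuous value at exactly ``t``, or None.

    Returns the recorded value exactly when ``t`` is a recorded time; None
    outside the record span or across a gap wider than the configured limit.
    """
    cfg = cfg or PairingConfig()
    pts = trace.continuous
    times = [p.t for p in pts]
    i = bisect_right(times, t) - 1
    if i < 0 or t > times[-1]:
        return None
    if times[i] == t:
        return pts[i].value
    if i + 1 >= len(pts):
        return None
    left, right = pts[i], pts[i + 1]
    gap = (right.t - left.t).total_seconds()
    if gap > cfg.max_interpolation_gap_minutes * 60.0:
        return None
    frac = (t - left.t).total_seconds() / gap
    return left.value + frac * (right.value - left.value)


def interpolate_minutely(
    trace: SensorTrace,
    source: str = "continuous",
    cfg: PairingConfig | None = None,
) -> list[GlucosePoint]:
    """Resample the continuous record to one value per minute.

    Recorded points are preserved exactly; whole minutes strictly between
    recorded points are filled by linear interpolation where the spacing of
    the bracketing points does not exceed the gap limit. No extrapolation.
    """
    if source != "continuous":
        raise ValueError("interpolation operates on the continuous record only")
    cfg = cfg or PairingConfig()
    pts = trace.continuous
    if len(pts) < 2:
        raise ValueError(f"{trace.label}: need >= 2 continuous points to interpolate")

    out: list[GlucosePoint] = []
    first_minute = ceil(pts[0].t.timestamp() / 60.0)
    last_minute = floor(pts[-1].t.timestamp() / 60.0)
    grid = set(range(first_minute, last_minute + 1))
    recorded = {p.t.timestamp() / 60.0 for p in pts}

    for p in pts:
        out.append(p)
    from .study_model import UTC  # local import to avoid cycle noise

    for m in grid:
        if m in recorded:
            continue
        t = datetime.fromtimestamp(m * 60, tz=UTC)
        v = interpolate_at(trace, t, cfg)
        if v is not None:
            out.append(GlucosePoint(t, v))
    out.sort(key=lambda p: p.t)
    return out


def minutely_values(
    trace: SensorTrace, cfg: PairingConfig | None = None
) -> dict[int, float]:
    """Whole-minute series as {epoch minute: value} (for precision analysis)."""
    series = interpolate_minutely(trace, "continuous", cfg)
    out: dict[int, float] = {}
    for p in series:
        ts = p.t.timestamp()
        if ts % 60 == 0:
            out[int(ts // 60)] = p.value
    return out


def build_pairs(
    study: Study,
    cfg: PairingConfig | None = None,
    modes: dict[System, tuple[PairingMode, ...]] | None = None,
) -> list[PairedObservation]:
    """Pair every final-replicate reference with every concurrently worn sensor.

    Emits at most one pair per (sensor, mode); warm-up periods are excluded.
    """
    cfg = cfg or PairingConfig()
    modes = modes or DEFAULT_MODES
    finals = select_final_replicates(study.refs)
    by_participant: dict[str, list[SensorTrace]] = {}
    for tr in study.traces:
        by_participant.setdefault(tr.participant_id, []).append(tr)

    pairs: list[PairedObservation] = []
    for ref in finals:
        for tr in by_participant.get(ref.participant_id, []):
            start = tr.active_start if cfg.warmup_excluded else tr.wear_start
            if not (start <= ref.t <= tr.wear_end):
                continue
            for mode in modes.get(tr.system, ()):
                if mode is PairingMode.LOCF:
                    p = match_locf(tr, ref.t, cfg)
                    if p is not None:
                        pairs.append(PairedObservation.build(ref, tr, p.value, p.t, mode))
                elif mode is PairingMode.SCAN:
                    if tr.system is not System.FL_LIKE:
                        continue
                    p = match_scan(tr, ref.t, cfg)
                    if p is not None:
                        pairs.append(PairedObservation.build(ref, tr, p.value, p.t, mode))
                elif mode is PairingMode.INTERPOLATED:
                    if len(tr.continuous) < 2:
                        continue
                    v = interpolate_at(tr, ref.t, cfg)
                    if v is not None:
                        pairs.append(PairedObservation.build(ref, tr, v, ref.t, mode))
    pairs.sort(
        key=lambda p: (
            p.participant_id,
            p.ref.t,
            p.ref.method.value,
            p.system.value,
            p.site.value,
            p.sensor_seq,
            p.pairing_mode.value,
        )
    )
    return pairs


# ---------------------------------------------------------------------------
# pairs.csv interchange
# ---------------------------------------------------------------------------

_PAIR_COLS = [
    "system",
    "participant_id",
    "site",
    "sensor_seq",
    "pairing_mode",
    "cgm_time",
    "cgm_value",
    "delta",
    "rel_delta",
    "wear_start",
    "ref_t",
    "ref_value",
    "method",
    "replicate_group",
    "replicate_index",
    "is_final_replicate",
    "therapeutic_decision",
    "phase",
]


def write_pairs(pairs: list[PairedObservation], path) -> None:
    rows = []
    for p in pairs:
        rows.append(
            {
                "system": p.system.value,
                "participant_id": p.participant_id,
                "site": p.site.value,
                "sensor_seq": p.sensor_seq,
                "pairing_mode": p.pairing_mode.value,
                "cgm_time": format_time(p.cgm_time),
                "cgm_value": repr(float(p.cgm_value)),
                "delta": repr(float(p.delta)),
                "rel_delta": repr(float(p.rel_delta)),
                "wear_start": format_time(p.wear_start),
                "ref_t": format_time(p.ref.t),
                "ref_value": repr(float(p.ref.value)),
                "method": p.ref.method.value,
                "replicate_group": p.ref.replicate_group,
                "replicate_index": p.ref.replicate_index,
                "is_final_replicate": str(p.ref.is_final_replicate),
                "therapeutic_decision": str(p.ref.therapeutic_decision),
                "phase": p.ref.phase.value,
            }
        )
    pd.DataFrame(rows, columns=_PAIR_COLS).to_csv(path, index=False)


def read_pairs(path) -> list[PairedObservation]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _PAIR_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"pairs file missing column(s) {missing}")
    out: list[PairedObservation] = []
    for _, row in df.iterrows():
        ref = ReferencePoint(
            t=parse_time(row["ref_t"]),
            value=float(row["ref_value"]),
            method=Method(row["method"]),
            replicate_group=row["replicate_group"],
            replicate_index=int(row["replicate_index"]),
            is_final_replicate=row["is_final_replicate"].lower() == "true",
            therapeutic_decision=row["therapeutic_decision"].lower() == "true",
            phase=Phase(row["phase"]),
            participant_id=row["participant_id"],
        )
        out.append(
            PairedObservation(
                ref=ref,
                cgm_value=float(row["cgm_value"]),
                cgm_time=parse_time(row["cgm_time"]),
                system=System(row["system"]),
                participant_id=row["participant_id"],
                site=Site(row["site"]),
                sensor_seq=int(row["sensor_seq"]),
                pairing_mode=PairingMode(row["pairing_mode"]),
                delta=float(row["delta"]),
                rel_delta=float(row["rel_delta"]),
                wear_start=parse_time(row["wear_start"]),
            )
        )
    return out


__all__ = [
    "PairingConfig",
    "DEFAULT_MODES",
    "select_final_replicates",
    "match_locf",
    "match_scan",
    "interpolate_at",
    "interpolate_minutely",
    "minutely_values",
    "build_pairs",
    "write_pairs",
    "read_pairs",
]
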