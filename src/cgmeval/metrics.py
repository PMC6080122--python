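"""Deviation statistics (exceedance, MAD/MARD) and precision (PAD/PARD).

The 100 mg/dL split governs which scale a pair contributes to: absolute
differences (mg/dL) below the split, relative differences at or above it.
"Exceeding" a threshold is strict (>); the ISO-style "within limits" view
is its exact complement (<=). Percent rounding (half-up, one decimal) is
applied only when reports are rendered, never inside computations.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import timedelta
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .pairing import PairingConfig, minutely_values
from .study_model import Method, PairedObservation, SensorTrace


def round_half_up(x: float, digits: int = 1) -> float:
    """Decimal half-up rounding (24.25 -> 24.3 at one digit)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MetricConfig:
    split_mgdl: float = 100.0
    thresholds: tuple[float, ...] = (15.0, 20.0, 30.0, 50.0)
    round_digits: int = 1
    glucose_bins_mgdl: tuple[float, ...] = (70.0, 180.0)
    trend_threshold_mgdl_per_min: float = 1.0
    trend_max_neighbor_gap_minutes: float = 20.0

    def __post_init__(self):
        if self.split_mgdl <= 0:
            raise ValueError("split must be positive")
        th = self.thresholds
        if any(t <= 0 for t in th) or list(th) != sorted(th):
            raise ValueError("thresholds must be positive and sorted")


@dataclass(frozen=True)
class Stat:
    """Mean +/- population SD with its n; mean/sd are None when n == 0."""

    mean: float | None
    sd: float | None
    n: int

    @classmethod
    def of(cls, values) -> "Stat":
        x = np.asarray(values, dtype=float)
        if x.size == 0:
            return cls(None, None, 0)
        return cls(float(x.mean()), float(x.std(ddof=0)), int(x.size))


@dataclass(frozen=True)
class ExceedanceRow:
    threshold: float
    n_exceeding: int
    percent: float | None  # of all pairs, unrounded
    pct_cgm_below: float | None  # share of exceeding pairs with CGM < BGM
    pct_cgm_above: float | None


@dataclass(frozen=True)
class ExceedanceSummary:
    n_total: int
    rows: list[ExceedanceRow]


@dataclass(frozen=True)
class DeviationSummary:
    """MAD/MARD family over a pair set.

    ``mad`` is over pairs with reference < split (mg/dL); ``mard`` over
    pairs with reference >= split (percent). ``combined`` mixes the two
    scales per pair (|delta| mg/dL below the split, 100*|rel_delta| above);
    ``whole_range_mard`` is |rel_delta| in percent over all pairs.
    """

    n_pairs: int
    mad: Stat
    mard: Stat
    combined: Stat
    whole_range_mard: Stat


@dataclass(frozen=True)
class PrecisionSummary:
    """Sensor-to-sensor PAD (< split, mg/dL) and PARD (>= split, percent)."""

    pad: Stat
    pard: Stat


def _exceeds(p: PairedObservation, threshold: float, split: float) -> bool:
    if p.ref.value < split:
        return abs(p.delta) > threshold
    return abs(p.rel_delta) > threshold / 100.0


def exceedance_table(
    pairs: list[PairedObservation], cfg: MetricConfig | None = None
) -> ExceedanceSummary:
    """Per-threshold strict exceedance with under/over reading shares."""
    cfg = cfg or MetricConfig()
    n = len(pairs)
    rows: list[ExceedanceRow] = []
    for th in cfg.thresholds:
        exceeding = [p for p in pairs if _exceeds(p, th, cfg.split_mgdl)]
        k = len(exceeding)
        below = sum(1 for p in exceeding if p.delta < 0)
        rows.append(
            ExceedanceRow(
                threshold=th,
                n_exceeding=k,
                percent=(100.0 * k / n) if n else None,
                pct_cgm_below=(100.0 * below / k) if k else None,
                pct_cgm_above=(100.0 * (k - below) / k) if k else None,
            )
        )
    return ExceedanceSummary(n_total=n, rows=rows)


def within_limits_table(
    pairs: list[PairedObservation], cfg: MetricConfig | None = None
) -> ExceedanceSummary:
    """ISO-style complement: share of pairs within (<=) each limit."""
    cfg = cfg or MetricConfig()
    table = exceedance_table(pairs, cfg)
    rows = [
        ExceedanceRow(
            threshold=r.threshold,
            n_exceeding=table.n_total - r.n_exceeding,
            percent=(None if r.percent is None else 100.0 - r.percent),
            pct_cgm_below=None,
            pct_cgm_above=None,
        )
        for r in table.rows
    ]
    return ExceedanceSummary(n_total=table.n_total, rows=rows)


def mad_mard(
    pairs: list[PairedObservation], cfg: MetricConfig | None = None
) -> DeviationSummary:
    cfg = cfg or MetricConfig()
    split = cfg.split_mgdl
    abs_low = [abs(p.delta) for p in pairs if p.ref.value < split]
    rel_high = [100.0 * abs(p.rel_delta) for p in pairs if p.ref.value >= split]
    combined = [
        abs(p.delta) if p.ref.value < split else 100.0 * abs(p.rel_delta) for p in pairs
    ]
    whole = [100.0 * abs(p.rel_delta) for p in pairs]
    return DeviationSummary(
        n_pairs=len(pairs),
        mad=Stat.of(abs_low),
        mard=Stat.of(rel_high),
        combined=Stat.of(combined),
        whole_range_mard=Stat.of(whole),
    )


def thin_hourly(pairs: list[PairedObservation]) -> list[PairedObservation]:
    """Keep at most one pair per (sensor, mode, clock hour): the earliest."""
    best: dict[tuple, PairedObservation] = {}
    for p in sorted(pairs, key=lambda p: (p.ref.t, p.ref.replicate_group)):
        hour = p.ref.t.replace(minute=0, second=0, microsecond=0)
        key = (p.system, p.participant_id, p.site, p.sensor_seq, p.pairing_mode, hour)
        if key not in best:
            best[key] = p
    return sorted(best.values(), key=lambda p: (p.participant_id, p.ref.t, p.system.value, p.site.value, p.sensor_seq, p.pairing_mode.value))


def precision_diffs(
    trace_a: SensorTrace,
    trace_b: SensorTrace,
    pairing_cfg: PairingConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-minute (pair mean, |a - b|) arrays on common interpolated minutes."""
    if trace_a.system is not trace_b.system:
        raise ValueError("precision requires two sensors of the same system")
    if trace_a.participant_id != trace_b.participant_id:
        raise ValueError("precision requires two sensors on the same participant")
    try:
        sa = minutely_values(trace_a, pairing_cfg)
        sb = minutely_values(trace_b, pairing_cfg)
    except ValueError:
        return np.empty(0), np.empty(0)
    common = sorted(sa.keys() & sb.keys())
    a = np.array([sa[m] for m in common])
    b = np.array([sb[m] for m in common])
    return (a + b) / 2.0, np.abs(a - b)


def precision_summary_from_diffs(
    means: np.ndarray, diffs: np.ndarray, cfg: MetricConfig | None = None
) -> PrecisionSummary:
    cfg = cfg or MetricConfig()
    low = means < cfg.split_mgdl
    pad = Stat.of(diffs[low])
    high = ~low
    pard = Stat.of(100.0 * diffs[high] / means[high])
    return PrecisionSummary(pad=pad, pard=pard)


def pad_pard(
    trace_a: SensorTrace,
    trace_b: SensorTrace,
    cfg: MetricConfig | None = None,
    pairing_cfg: PairingConfig | None = None,
) -> PrecisionSummary:
    """Sensor-to-sensor precision on common interpolated minutes (symmetric)."""
    means, diffs = precision_diffs(trace_a, trace_b, pairing_cfg)
    return precision_summary_from_diffs(means, diffs, cfg)


STRATIFY_KEYS = (
    "phase",
    "wear_day",
    "glucose_range",
    "trend",
    "therapeutic_decision",
    "reference_method",
)


def _glucose_bin(value: float, bins: tuple[float, ...]) -> str:
    edges = sorted(bins)
    if value < edges[0]:
        return f"<{edges[0]:g}"
    for lo, hi in zip(edges, edges[1:]):
        if value <= hi:
            return f"{lo:g}-{hi:g}"
    return f">{edges[-1]:g}"


def _trend_labels(
    pairs: list[PairedObservation], cfg: MetricConfig
) -> dict[int, str]:
    """Classify each pair by the reference rate of change.

    Rate is a centered difference over the adjacent final-replicate values
    of the same participant and method, used only when both neighbors are
    within the configured spacing; otherwise the pair is 'unclassified'.
    """
    collected: dict[tuple[str, Method], set[tuple]] = {}
    for p in pairs:
        collected.setdefault((p.participant_id, p.ref.method), set()).add(
            (p.ref.t, p.ref.value)
        )
    series = {key: sorted(pts) for key, pts in collected.items()}
    position = {
        key: {t: i for i, (t, _) in enumerate(pts)} for key, pts in series.items()
    }

    max_gap = timedelta(minutes=cfg.trend_max_neighbor_gap_minutes)
    thr = cfg.trend_threshold_mgdl_per_min
    labels: dict[int, str] = {}
    for idx, p in enumerate(pairs):
        skey = (p.participant_id, p.ref.method)
        pts = series[skey]
        i = position[skey][p.ref.t]
        if 0 < i < len(pts) - 1:
            (t0, v0), (t1, v1) = pts[i - 1], pts[i + 1]
            if p.ref.t - t0 <= max_gap and t1 - p.ref.t <= max_gap:
                rate = (v1 - v0) / ((t1 - t0).total_seconds() / 60.0)
                if rate > thr:
                    labels[idx] = "rising"
                elif rate < -thr:
                    labels[idx] = "falling"
                else:
                    labels[idx] = "stable"
                continue
        labels[idx] = "unclassified"
    return labels


def stratify(
    pairs: list[PairedObservation],
    key: str,
    cfg: MetricConfig | None = None,
) -> dict[str, list[PairedObservation]]:
    """Partition pairs by a stratification key; groups tile the input."""
    cfg = cfg or MetricConfig()
    if key not in STRATIFY_KEYS:
        raise ValueError(f"unknown stratification key {key!r}; choose from {STRATIFY_KEYS}")
    groups: dict[str, list[PairedObservation]] = {}

    if key == "trend":
        labels = _trend_labels(pairs, cfg)
        for idx, p in enumerate(pairs):
            groups.setdefault(labels[idx], []).append(p)
        return groups

    for p in pairs:
        if key == "phase":
            label = p.ref.phase.value
        elif key == "wear_day":
            label = str(int((p.ref.t - p.wear_start) // timedelta(days=1)))
        elif key == "glucose_range":
            label = _glucose_bin(p.ref.value, cfg.glucose_bins_mgdl)
        elif key == "therapeutic_decision":
            label = "decision" if p.ref.therapeutic_decision else "no_decision"
        else:  # reference_method
            label = p.ref.method.value
        groups.setdefault(label, []).append(p)
    return groups


__all__ = [
    "MetricConfig",
    "Stat",
    "ExceedanceRow",
    "ExceedanceSummary",
    "DeviationSummary",
    "PrecisionSummary",
    "STRATIFY_KEYS",
    "round_half_up",
    "exceedance_table",
    "within_limits_table",
    "mad_mard",
    "thin_hourly",
    "precision_diffs",
    "precision_summary_from_diffs",
    "pad_pard",
    "stratify",
]
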