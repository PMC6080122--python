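"""Synthetic study generation: glucose process, sensors, reference schedule.

The generator emulates a 14-day, 20-participant design: three study-site
visits (48 h each) with hourly duplicate capillary measurements plus one
nightly measurement, induced rapid-excursion mornings with 15-min capillary
and venous sampling, home-use phases with five daily self-measurements,
two flash-style sensors (upper arms, full wear) and two pairs of
real-time-style sensors (abdomen, replaced mid-study) per participant.

The glucose process is phenomenological: baseline + circadian sinusoid +
meal response curves + Ornstein-Uhlenbeck noise at 1-minute resolution.
Sensors see a first-order lag-filtered copy of the true signal with
proportional + additive Gaussian noise, a fixed bias, display clamping and
i.i.d. dropout. Randomness uses independently seeded streams per
participant and per sensor derived from the master seed by a counter
scheme, so partial regeneration is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from math import exp, pi

import numpy as np
from scipy.signal import lfilter

from .study_model import (
    DEFAULT_WARMUP_MINUTES,
    DISPLAY_RANGE,
    NOMINAL_CADENCE_MINUTES,
    UTC,
    BodyLocation,
    GlucosePoint,
    Method,
    Phase,
    ReferencePoint,
    SensorTrace,
    Site,
    Study,
    System,
)

_PROFILE_STREAM = 0
_REFERENCE_STREAM = 1
_SENSOR_STREAM_BASE = 10


@dataclass(frozen=True)
class ProfileParams:
    """Parameters of the true glucose process (all deterministic terms in mg/dL)."""

    baseline_mgdl: float = 120.0
    circadian_amplitude_mgdl: float = 10.0
    circadian_peak_hour: float = 16.0
    meal_hours: tuple[float, ...] = (8.0, 12.5, 18.5)
    meal_amplitude_mgdl: float = 60.0
    meal_peak_minutes: float = 45.0
    ou_sd_mgdl: float = 8.0
    ou_tau_minutes: float = 60.0
    # Induced-excursion shape on dynamic days (replaces the breakfast bump):
    # oversized meal peak followed by an oversized insulin-response dip,
    # sized to guarantee >250 mg/dL then <70 mg/dL inside the dynamic span.
    dynamic_peak_mgdl: float = 200.0
    dynamic_peak_minutes: float = 60.0
    dynamic_peak_width_minutes: float = 35.0
    dynamic_dip_mgdl: float = 190.0
    dynamic_dip_minutes: float = 210.0
    dynamic_dip_width_minutes: float = 45.0
    clamp_mgdl: tuple[float, float] = (40.0, 450.0)

    @classmethod
    def flat(cls) -> "ProfileParams":
        """All variance terms zero, no meals: constant series at baseline."""
        return cls(
            circadian_amplitude_mgdl=0.0,
            meal_hours=(),
            meal_amplitude_mgdl=0.0,
            ou_sd_mgdl=0.0,
            dynamic_peak_mgdl=0.0,
            dynamic_dip_mgdl=0.0,
        )


@dataclass(frozen=True)
class SensorErrorModel:
    lag_tau_minutes: float = 8.0
    bias_mgdl: float = 0.0
    proportional_sd: float = 0.10
    additive_sd_mgdl: float = 5.0
    dropout_prob: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.lag_tau_minutes < 0:
            raise ValueError("lag time constant must be >= 0")
        if self.proportional_sd < 0 or self.additive_sd_mgdl < 0:
            raise ValueError("noise SDs must be >= 0")
        if not (0.0 <= self.dropout_prob <= 1.0):
            raise ValueError("dropout probability must be in [0, 1]")

    @classmethod
    def zero(cls) -> "SensorErrorModel":
        return cls(lag_tau_minutes=0.0, bias_mgdl=0.0, proportional_sd=0.0,
                   additive_sd_mgdl=0.0, dropout_prob=0.0)


#: Illustrative defaults chosen to land aggregate MARD in a plausible
#: ~10% region; they are not estimates of any real device's error.
DEFAULT_SENSOR_MODELS: dict[System, SensorErrorModel] = {
    System.DG5_LIKE: SensorErrorModel(
        lag_tau_minutes=8.0, proportional_sd=0.10, additive_sd_mgdl=4.0,
        dropout_prob=0.01),
    System.FL_LIKE: SensorErrorModel(
        lag_tau_minutes=8.0, proportional_sd=0.11, additive_sd_mgdl=5.0,
        dropout_prob=0.005),
}


@dataclass(frozen=True)
class StudyConfig:
    n_participants: int = 20
    n_days: int = 14
    visit_windows: tuple[tuple[int, int], ...] = ((0, 2), (5, 7), (12, 14))
    dynamic_days: tuple[int, ...] = (1, 6, 13)
    dg5_replacement_day: int = 7
    home_bgm_per_day: int = 5
    inhouse_bgm_interval_minutes: int = 60
    inhouse_bgm_start_hour: int = 6
    inhouse_bgm_end_hour: int = 24
    nightly_bgm_hour: int = 3
    dynamic_bgm_interval_minutes: int = 15
    dynamic_span_before_minutes: int = 30
    dynamic_span_after_minutes: int = 300
    breakfast_hour: float = 8.0
    bolus_delay_minutes: int = 45
    start_date: datetime = datetime(2016, 3, 1, tzinfo=UTC)
    bgms_proportional_sd: float = 0.025
    hk_proportional_sd: float = 0.02
    duplicate_limit_mgdl: float = 10.0
    duplicate_limit_pct: float = 10.0
    seed: int = 0
    profile: ProfileParams = field(default_factory=ProfileParams)

    def __post_init__(self):
        if self.n_participants < 1 or self.n_days < 1:
            raise ValueError("need at least one participant and one day")
        for a, b in self.visit_windows:
            if not (0 <= a < b <= self.n_days):
                raise ValueError(f"visit window ({a}, {b}) outside [0, {self.n_days}]")
        for d in self.dynamic_days:
            if not any(a <= d < b for a, b in self.visit_windows):
                raise ValueError(f"dynamic day {d} not inside a visit window")
        if min(self.inhouse_bgm_interval_minutes, self.dynamic_bgm_interval_minutes,
               self.home_bgm_per_day) <= 0:
            raise ValueError("schedule intervals/counts must be positive")

    def day_start(self, day: int) -> datetime:
        return self.start_date + timedelta(days=day)

    @property
    def study_end(self) -> datetime:
        return self.start_date + timedelta(days=self.n_days)

    def inhouse_days(self) -> list[int]:
        return [d for d in range(self.n_days)
                if any(a <= d < b for a, b in self.visit_windows)]

    def home_days(self) -> list[int]:
        inhouse = set(self.inhouse_days())
        return [d for d in range(self.n_days) if d not in inhouse]

    def dynamic_window(self, day: int) -> tuple[datetime, datetime]:
        breakfast = self.day_start(day) + timedelta(hours=self.breakfast_hour)
        return (
            breakfast - timedelta(minutes=self.dynamic_span_before_minutes),
            breakfast + timedelta(minutes=self.dynamic_span_after_minutes),
        )


@dataclass
class TrueGlucoseProfile:
    """Minute-resolution true glucose over the whole study span."""

    participant_id: str
    start: datetime
    values: np.ndarray  # mg/dL, one per minute, inclusive of both ends

    @property
    def end(self) -> datetime:
        return self.start + timedelta(minutes=len(self.values) - 1)

    def minutes_index(self, t: datetime) -> float:
        return (t - self.start).total_seconds() / 60.0

    def value_at(self, t: datetime) -> float:
        """Linear interpolation between minute nodes."""
        m = self.minutes_index(t)
        if m < 0 or m > len(self.values) - 1:
            raise ValueError(f"{t} outside profile span")
        i = int(m)
        if i == m or i + 1 >= len(self.values):
            return float(self.values[i])
        frac = m - i
        return float(self.values[i] * (1 - frac) + self.values[i + 1] * frac)

    def values_at(self, times: list[datetime]) -> np.ndarray:
        idx = np.array([self.minutes_index(t) for t in times])
        if (idx < 0).any() or (idx > len(self.values) - 1).any():
            raise ValueError("time(s) outside profile span")
        return np.interp(idx, np.arange(len(self.values)), self.values)


def _rng(config_seed: int, participant_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([config_seed, participant_index, stream])


def _meal_bump(minutes_after: np.ndarray, amplitude: float, peak: float) -> np.ndarray:
    """Gamma-like response: 0 at meal time, peak ``amplitude`` at ``peak`` min."""
    m = np.clip(minutes_after, 0.0, None) / peak
    return amplitude * m * np.exp(1.0 - m)


def simulate_profile(
    config: StudyConfig,
    participant_id: str,
    seed: int | None = None,
    participant_index: int = 0,
) -> TrueGlucoseProfile:
    """Simulate the true glucose process at 1-min resolution.

    Deterministic given (config, seed); on each dynamic day the induced
    excursion exceeds 250 mg/dL and then drops below 70 mg/dL within the
    dynamic span.
    """
    p = config.profile
    n_min = config.n_days * 1440 + 1
    t_min = np.arange(n_min, dtype=float)
    hours = (t_min / 60.0) % 24.0

    values = np.full(n_min, p.baseline_mgdl)
    values += p.circadian_amplitude_mgdl * np.sin(
        2 * pi * (hours - p.circadian_peak_hour + 6.0) / 24.0
    )

    dynamic = set(config.dynamic_days)
    for day in range(config.n_days):
        day_min = day * 1440.0
        for meal_hour in p.meal_hours:
            if day in dynamic and meal_hour == config.breakfast_hour:
                continue  # replaced by the induced excursion
            values += _meal_bump(t_min - (day_min + meal_hour * 60.0),
                                 p.meal_amplitude_mgdl, p.meal_peak_minutes)
        if day in dynamic:
            m = t_min - (day_min + config.breakfast_hour * 60.0)
            active = np.abs(m) < 6 * 60  # excursion support
            values[active] += p.dynamic_peak_mgdl * np.exp(
                -((m[active] - p.dynamic_peak_minutes) / p.dynamic_peak_width_minutes) ** 2
            )
            values[active] -= p.dynamic_dip_mgdl * np.exp(
                -((m[active] - p.dynamic_dip_minutes) / p.dynamic_dip_width_minutes) ** 2
            )

    if p.ou_sd_mgdl > 0:
        rng = np.random.default_rng(
            [config.seed if seed is None else seed, participant_index, _PROFILE_STREAM]
        )
        dt = 1.0
        a = np.exp(-dt / p.ou_tau_minutes)
        innovation_sd = p.ou_sd_mgdl * np.sqrt(1.0 - a * a)
        eps = rng.normal(0.0, innovation_sd, n_min)
        noise = lfilter([1.0], [1.0, -a], eps)
        values = values + noise

    values = np.clip(values, *p.clamp_mgdl)
    return TrueGlucoseProfile(participant_id, config.start_date, values)


def lag_filter(values: np.ndarray, dt_minutes: float, tau_minutes: float) -> np.ndarray:
    """First-order tissue lag filter, exact for piecewise-linear input.

    Solves y' = (g - y)/tau assuming g is linear between samples, so the
    closed form on a ramp (steady-state deviation -slope*tau) is reproduced
    to machine precision.
    """
    if tau_minutes <= 0:
        return values.astype(float).copy()
    v = values.astype(float)
    a = exp(-dt_minutes / tau_minutes)
    s = np.diff(v) / dt_minutes
    c = (v[1:] - s * tau_minutes) - a * (v[:-1] - s * tau_minutes)
    y = np.empty_like(v)
    y[0] = v[0]
    y[1:], _ = lfilter([1.0], [1.0, -a], c, zi=np.array([a * y[0]]))
    return y


def simulate_sensor(
    profile: TrueGlucoseProfile,
    model: SensorErrorModel,
    system: System,
    site: Site,
    body_location: BodyLocation,
    wear_start: datetime,
    wear_end: datetime,
    sensor_seq: int = 1,
    rng: np.random.Generator | None = None,
    scan_times: list[datetime] | None = None,
    cadence_minutes: int | None = None,
    warmup_minutes: int | None = None,
) -> SensorTrace:
    """Sample a noisy, lagged sensor trace from the true profile."""
    if wear_start < profile.start or wear_end > profile.end:
        raise ValueError("wear interval outside profile span")
    if wear_end <= wear_start:
        raise ValueError("wear interval must be non-empty")
    rng = rng or np.random.default_rng(model.seed)
    cadence = cadence_minutes or NOMINAL_CADENCE_MINUTES[system]
    warmup = DEFAULT_WARMUP_MINUTES[system] if warmup_minutes is None else warmup_minutes
    lo, hi = DISPLAY_RANGE[system]

    tissue = lag_filter(profile.values, 1.0, model.lag_tau_minutes)
    grid = np.arange(len(tissue), dtype=float)

    def tissue_at(times: list[datetime]) -> np.ndarray:
        idx = np.array([profile.minutes_index(t) for t in times])
        return np.interp(idx, grid, tissue)

    def measure(true_vals: np.ndarray) -> np.ndarray:
        noisy = true_vals * (1.0 + rng.normal(0.0, model.proportional_sd, len(true_vals)))
        noisy = noisy + rng.normal(0.0, model.additive_sd_mgdl, len(true_vals))
        noisy = noisy + model.bias_mgdl
        return np.clip(noisy, lo, hi)

    first = wear_start + timedelta(minutes=warmup)
    sample_times: list[datetime] = []
    t = first
    while t <= wear_end:
        sample_times.append(t)
        t += timedelta(minutes=cadence)
    cont_vals = measure(tissue_at(sample_times)) if sample_times else np.empty(0)
    keep = rng.random(len(sample_times)) >= model.dropout_prob
    continuous = [GlucosePoint(t, float(v))
                  for t, v, k in zip(sample_times, cont_vals, keep) if k]

    scans: list[GlucosePoint] = []
    if scan_times:
        valid = sorted(t for t in set(scan_times) if first <= t <= wear_end)
        if valid:
            scan_vals = measure(tissue_at(valid))
            scans = [GlucosePoint(t, float(v)) for t, v in zip(valid, scan_vals)]

    return SensorTrace(
        system=system,
        participant_id=profile.participant_id,
        site=site,
        body_location=body_location,
        sensor_seq=sensor_seq,
        wear_start=wear_start,
        wear_end=wear_end,
        warmup_minutes=warmup,
        continuous=continuous,
        scans=scans,
    )


# ---------------------------------------------------------------------------
# Reference schedule
# ---------------------------------------------------------------------------


def _duplicate_limit(config: StudyConfig, anchor_value: float) -> float:
    if anchor_value < 100.0:
        return config.duplicate_limit_mgdl
    return anchor_value * config.duplicate_limit_pct / 100.0


def replicate_group_values(
    true_value: float, sd: float, config: StudyConfig, rng: np.random.Generator
) -> list[float]:
    """Measured duplicate values; a third replicate when the pair is discordant."""
    v1 = true_value * (1.0 + rng.normal(0.0, sd))
    v2 = true_value * (1.0 + rng.normal(0.0, sd))
    values = [v1, v2]
    if abs(v2 - v1) > _duplicate_limit(config, v1):
        values.append(true_value * (1.0 + rng.normal(0.0, sd)))
    return values


def _bgm_slot_times(config: StudyConfig, day: int) -> list[tuple[datetime, bool]]:
    """(time, therapeutic_decision) of scheduled in-house BGMS slots on a day."""
    start = config.day_start(day)
    slots: list[tuple[datetime, bool]] = []
    decision_hours = {int(config.breakfast_hour), 12, 18}
    minute = config.inhouse_bgm_start_hour * 60
    end_minute = config.inhouse_bgm_end_hour * 60
    while minute < end_minute:
        t = start + timedelta(minutes=minute)
        slots.append((t, (minute // 60) in decision_hours and minute % 60 == 0))
        minute += config.inhouse_bgm_interval_minutes
    slots.append((start + timedelta(hours=config.nightly_bgm_hour), False))
    return sorted(slots)


def _home_check_times(config: StudyConfig, day: int) -> list[tuple[datetime, bool]]:
    start = config.day_start(day)
    base = [(6.75, False)]
    base += [(h - 1.0 / 6.0, True) for h in config.profile.meal_hours] or [
        (7.5, True), (12.25, True), (18.25, True)
    ]
    base += [(23.0, False)]
    extras = [(10.0, False), (15.0, False), (21.0, False)]
    wanted = base[: config.home_bgm_per_day]
    for e in extras:
        if len(wanted) >= config.home_bgm_per_day:
            break
        wanted.append(e)
    return sorted((start + timedelta(hours=h), dec) for h, dec in wanted)


def simulate_reference(
    profile: TrueGlucoseProfile,
    config: StudyConfig,
    participant_id: str,
    seed: int | None = None,
    participant_index: int = 0,
) -> list[ReferencePoint]:
    """Generate the scheduled reference measurements for one participant.

    Capillary BGMS measurements are in duplicate with a conditional third
    replicate when the duplicate rule fires; venous laboratory values are
    generated during dynamic phases only, as single measurements.
    """
    rng = np.random.default_rng(
        [config.seed if seed is None else seed, participant_index, _REFERENCE_STREAM]
    )
    dynamic = set(config.dynamic_days)
    refs: list[ReferencePoint] = []
    bgm_counter = 0
    ven_counter = 0

    def emit_bgm(t: datetime, phase: Phase, decision: bool) -> None:
        nonlocal bgm_counter
        bgm_counter += 1
        gid = f"{participant_id}-B{bgm_counter:05d}"
        values = replicate_group_values(
            profile.value_at(t), config.bgms_proportional_sd, config, rng
        )
        for i, v in enumerate(values, start=1):
            refs.append(
                ReferencePoint(
                    t=t + timedelta(seconds=30 * (i - 1)),
                    value=float(v),
                    method=Method.BGMS_CAPILLARY,
                    replicate_group=gid,
                    replicate_index=i,
                    is_final_replicate=(i == len(values)),
                    therapeutic_decision=decision,
                    phase=phase,
                    participant_id=participant_id,
                )
            )

    for day in config.inhouse_days():
        if day in dynamic:
            win_start, win_end = config.dynamic_window(day)
            breakfast = config.day_start(day) + timedelta(hours=config.breakfast_hour)
            bolus = breakfast + timedelta(minutes=config.bolus_delay_minutes)
            lunch_times = {
                config.day_start(day) + timedelta(hours=h)
                for h in config.profile.meal_hours
            }
            # hourly slots outside the dynamic window
            for t, dec in _bgm_slot_times(config, day):
                if win_start <= t <= win_end:
                    continue
                emit_bgm(t, Phase.IN_HOUSE, dec)
            # 15-min capillary + venous sampling inside the window
            t = win_start
            while t <= win_end:
                decision = t in (breakfast, bolus) or t in lunch_times
                emit_bgm(t, Phase.DYNAMIC, decision)
                ven_counter += 1
                refs.append(
                    ReferencePoint(
                        t=t,
                        value=float(
                            profile.value_at(t)
                            * (1.0 + rng.normal(0.0, config.hk_proportional_sd))
                        ),
                        method=Method.HK_VENOUS,
                        replicate_group=f"{participant_id}-V{ven_counter:05d}",
                        replicate_index=1,
                        is_final_replicate=True,
                        therapeutic_decision=decision,
                        phase=Phase.DYNAMIC,
                        participant_id=participant_id,
                    )
                )
                t += timedelta(minutes=config.dynamic_bgm_interval_minutes)
        else:
            for t, dec in _bgm_slot_times(config, day):
                emit_bgm(t, Phase.IN_HOUSE, dec)

    for day in config.home_days():
        for t, dec in _home_check_times(config, day):
            emit_bgm(t, Phase.HOME_USE, dec)

    refs.sort(key=lambda r: (r.t, r.method.value, r.replicate_group, r.replicate_index))
    return refs


def expected_replicate_group_counts(config: StudyConfig) -> dict[str, int]:
    """Closed-form per-phase replicate-group counts implied by the config."""
    n_inhouse = len(config.inhouse_days())
    n_dynamic = len(config.dynamic_days)
    n_home = len(config.home_days())

    slots_per_day = len(_bgm_slot_times(config, 0))
    if config.dynamic_days:
        day = config.dynamic_days[0]
        win_start, win_end = config.dynamic_window(day)
        skipped = sum(
            1 for t, _ in _bgm_slot_times(config, day) if win_start <= t <= win_end
        )
        span = (win_end - win_start).total_seconds() / 60.0
        dynamic_groups = int(span // config.dynamic_bgm_interval_minutes) + 1
    else:
        skipped = 0
        dynamic_groups = 0

    in_house = slots_per_day * n_inhouse - skipped * n_dynamic
    dynamic = dynamic_groups * n_dynamic
    home = config.home_bgm_per_day * n_home
    return {
        "in_house": in_house,
        "dynamic": dynamic,
        "home_use": home,
        "bgms_total": in_house + dynamic + home,
        "venous": dynamic,
    }


# ---------------------------------------------------------------------------
# Whole-study generation
# ---------------------------------------------------------------------------


def _participant_ids(n: int) -> list[str]:
    return [f"P{i + 1:03d}" for i in range(n)]


def generate_study(
    config: StudyConfig,
    models: dict[System, SensorErrorModel] | None = None,
) -> Study:
    """Generate a complete synthetic study (traces + reference points).

    Per participant: two FL-like sensors (left/right upper arm, full wear)
    and left/right DG5-like sensors replaced at ``dg5_replacement_day``
    when that day falls inside the study. Fully deterministic given
    config and seeds.
    """
    models = models or DEFAULT_SENSOR_MODELS
    traces: list[SensorTrace] = []
    refs: list[ReferencePoint] = []
    scan_jitter_minutes = 2.0

    for p_idx, pid in enumerate(_participant_ids(config.n_participants)):
        profile = simulate_profile(config, pid, participant_index=p_idx)
        p_refs = simulate_reference(profile, config, pid, participant_index=p_idx)
        refs.extend(p_refs)

        # Scans happen at every capillary measurement event: use the final
        # replicate time of each BGMS group, jittered so the +/-3 min scan
        # matcher is exercised near its edges.
        bgm_final_times = sorted(
            r.t for r in p_refs
            if r.method is Method.BGMS_CAPILLARY and r.is_final_replicate
        )

        wear_start = config.day_start(0) + timedelta(hours=7)
        wear_end = config.study_end

        sensor_stream = _SENSOR_STREAM_BASE
        fl_model = models[System.FL_LIKE]
        for site in (Site.LEFT, Site.RIGHT):
            rng = _rng(config.seed, p_idx, sensor_stream)
            sensor_stream += 1
            jitter = rng.uniform(-scan_jitter_minutes, scan_jitter_minutes,
                                 len(bgm_final_times))
            scan_times = [
                t + timedelta(seconds=round(j * 60.0))
                for t, j in zip(bgm_final_times, jitter)
            ]
            traces.append(
                simulate_sensor(
                    profile, fl_model, System.FL_LIKE, site, BodyLocation.UPPER_ARM,
                    wear_start, wear_end, sensor_seq=1, rng=rng, scan_times=scan_times,
                )
            )

        dg5_model = models[System.DG5_LIKE]
        if 0 < config.dg5_replacement_day < config.n_days:
            replacement = config.day_start(config.dg5_replacement_day) + timedelta(hours=7)
            wear_intervals = [(1, wear_start, replacement), (2, replacement, wear_end)]
        else:
            wear_intervals = [(1, wear_start, wear_end)]
        for site in (Site.LEFT, Site.RIGHT):
            for seq, ws, we in wear_intervals:
                rng = _rng(config.seed, p_idx, sensor_stream)
                sensor_stream += 1
                traces.append(
                    simulate_sensor(
                        profile, dg5_model, System.DG5_LIKE, site,
                        BodyLocation.ABDOMEN, ws, we, sensor_seq=seq, rng=rng,
                    )
                )

    study = Study(traces=traces, refs=refs)
    study.validate()
    return study


__all__ = [
    "ProfileParams",
    "SensorErrorModel",
    "DEFAULT_SENSOR_MODELS",
    "StudyConfig",
    "TrueGlucoseProfile",
    "simulate_profile",
    "lag_filter",
    "simulate_sensor",
    "replicate_group_values",
    "simulate_reference",
    "expected_replicate_group_counts",
    "generate_study",
]
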