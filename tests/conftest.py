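"""Shared fixtures and independent oracle helpers."""

from __future__ import annotations

import dataclasses
from datetime import datetime, timedelta, timezone

import pytest

from cgmeval.study_model import (
    BodyLocation,
    GlucosePoint,
    Method,
    PairedObservation,
    PairingMode,
    Phase,
    ReferencePoint,
    SensorTrace,
    Site,
    System,
)
from cgmeval.synthetic import (
    ProfileParams,
    SensorErrorModel,
    StudyConfig,
    generate_study,
)

UTC = timezone.utc
T0 = datetime(2016, 3, 1, 12, 0, 0, tzinfo=UTC)


def minutes(m: float) -> timedelta:
    return timedelta(minutes=m)


def make_trace(
    points: list[tuple[float, float]],
    system: System = System.DG5_LIKE,
    scans: list[tuple[float, float]] | None = None,
    wear_start: datetime | None = None,
    warmup_minutes: int = 0,
    wear_hours: float = 24.0,
    participant_id: str = "P001",
    site: Site = Site.LEFT,
    sensor_seq: int = 1,
) -> SensorTrace:
    """Trace from (minutes-after-T0, value) tuples; warm-up 0 by default."""
    ws = wear_start or (T0 - timedelta(hours=2))
    return SensorTrace(
        system=system,
        participant_id=participant_id,
        site=site,
        body_location=(
            BodyLocation.ABDOMEN if system is System.DG5_LIKE else BodyLocation.UPPER_ARM
        ),
        sensor_seq=sensor_seq,
        wear_start=ws,
        wear_end=ws + timedelta(hours=wear_hours),
        warmup_minutes=warmup_minutes,
        continuous=[GlucosePoint(T0 + minutes(m), v) for m, v in points],
        scans=[GlucosePoint(T0 + minutes(m), v) for m, v in (scans or [])],
    )


def make_ref(
    value: float,
    t: datetime | None = None,
    method: Method = Method.BGMS_CAPILLARY,
    group: str = "G1",
    phase: Phase = Phase.IN_HOUSE,
    decision: bool = False,
    participant_id: str = "P001",
    replicate_index: int = 1,
    is_final: bool = True,
) -> ReferencePoint:
    return ReferencePoint(
        t=t or T0,
        value=value,
        method=method,
        replicate_group=group,
        replicate_index=replicate_index,
        is_final_replicate=is_final,
        therapeutic_decision=decision,
        phase=phase,
        participant_id=participant_id,
    )


def make_pair(
    ref_value: float,
    cgm_value: float,
    t: datetime | None = None,
    mode: PairingMode = PairingMode.LOCF,
    system: System = System.DG5_LIKE,
    site: Site = Site.LEFT,
    sensor_seq: int = 1,
    participant_id: str = "P001",
    phase: Phase = Phase.IN_HOUSE,
    decision: bool = False,
    method: Method = Method.BGMS_CAPILLARY,
    group: str = "G1",
    wear_start: datetime | None = None,
) -> PairedObservation:
    t = t or T0
    ref = make_ref(
        ref_value, t=t, method=method, group=group, phase=phase,
        decision=decision, participant_id=participant_id,
    )
    delta = cgm_value - ref_value
    return PairedObservation(
        ref=ref,
        cgm_value=cgm_value,
        cgm_time=t,
        system=system,
        participant_id=participant_id,
        site=site,
        sensor_seq=sensor_seq,
        pairing_mode=mode,
        delta=delta,
        rel_delta=delta / ref_value,
        wear_start=wear_start or (t - timedelta(hours=10)),
    )


ZERO_MODELS = {
    System.DG5_LIKE: SensorErrorModel.zero(),
    System.FL_LIKE: SensorErrorModel.zero(),
}


def zero_noise_config(baseline: float = 120.0, seed: int = 11) -> StudyConfig:
    """2 participants, 3 days, flat profile, no measurement error anywhere."""
    return StudyConfig(
        n_participants=2,
        n_days=3,
        visit_windows=((0, 2),),
        dynamic_days=(1,),
        dg5_replacement_day=7,
        bgms_proportional_sd=0.0,
        hk_proportional_sd=0.0,
        seed=seed,
        profile=dataclasses.replace(ProfileParams.flat(), baseline_mgdl=baseline),
    )


@pytest.fixture(scope="session")
def small_noisy_study():
    """2 participants, 3 days, default error models (session-cached)."""
    cfg = StudyConfig(
        n_participants=2, n_days=3, visit_windows=((0, 2),), dynamic_days=(1,), seed=7
    )
    return cfg, generate_study(cfg)


@pytest.fixture(scope="session")
def zero_noise_study():
    cfg = zero_noise_config(baseline=120.0)
    return cfg, generate_study(cfg, ZERO_MODELS)


@pytest.fixture(scope="session")
def default_design_study():
    """The full default design (20 participants, 14 days), noisy."""
    cfg = StudyConfig(seed=5)
    return cfg, generate_study(cfg)
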