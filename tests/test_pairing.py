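from datetime import timedelta

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cgmeval.pairing import (
    DEFAULT_MODES,
    PairingConfig,
    build_pairs,
    interpolate_at,
    interpolate_minutely,
    match_locf,
    match_scan,
    select_final_replicates,
)
from cgmeval.study_model import (
    PairingMode,
    Phase,
    Study,
    StudyValidationError,
    System,
)
from cgmeval.synthetic import generate_study

from conftest import T0, ZERO_MODELS, make_ref, make_trace, minutes, zero_noise_config


# ---------------------------------------------------------------------------
# Final replicates
# ---------------------------------------------------------------------------


def test_final_of_duplicate_pair_selected():
    refs = [
        make_ref(100.0, group="G1", replicate_index=1, is_final=False),
        make_ref(104.0, t=T0 + minutes(0.5), group="G1", replicate_index=2, is_final=True),
    ]
    out = select_final_replicates(refs)
    assert [r.value for r in out] == [104.0]


def test_final_of_triplicate_selected():
    refs = [
        make_ref(100.0, group="G1", replicate_index=1, is_final=False),
        make_ref(140.0, t=T0 + minutes(0.5), group="G1", replicate_index=2, is_final=False),
        make_ref(102.0, t=T0 + minutes(1), group="G1", replicate_index=3, is_final=True),
    ]
    assert [r.value for r in select_final_replicates(refs)] == [102.0]


def test_empty_input_empty_output():
    assert select_final_replicates([]) == []


def test_group_without_final_is_error():
    refs = [make_ref(100.0, group="G1", is_final=False)]
    with pytest.raises(StudyValidationError):
        select_final_replicates(refs)


# ---------------------------------------------------------------------------
# LOCF
# ---------------------------------------------------------------------------


def test_locf_picks_latest_in_window():
    trace = make_trace([(-7, 90.0), (-3, 95.0)])
    p = match_locf(trace, T0)
    assert p is not None and p.value == 95.0


def test_locf_boundary_is_closed():
    """A reading exactly window minutes old qualifies (closed lower bound)."""
    trace = make_trace([(-5, 90.0)])
    p = match_locf(trace, T0)
    assert p is not None and p.value == 90.0
    # one second older: out of window
    trace2 = make_trace([(-5 - 1 / 60.0, 90.0)])
    assert match_locf(trace2, T0) is None


def test_locf_ignores_future_points():
    trace = make_trace([(1, 90.0), (4, 95.0)])
    assert match_locf(trace, T0) is None


def brute_force_locf(trace, ref_time, window_minutes=5.0):
    candidates = [
        p for p in trace.continuous
        if ref_time - timedelta(minutes=window_minutes) <= p.t <= ref_time
    ]
    return max(candidates, key=lambda p: p.t) if candidates else None


@settings(max_examples=200, deadline=None)
@given(
    offsets=st.lists(
        st.integers(min_value=-120, max_value=120), min_size=1, max_size=30, unique=True
    ),
    query=st.integers(min_value=-130, max_value=130),
)
def test_locf_matches_brute_force(offsets, query):
    """Oracle equivalence: bisect-based LOCF vs exhaustive scan."""
    pts = [(m, 100.0 + i) for i, m in enumerate(sorted(offsets))]
    trace = make_trace(pts, wear_start=T0 - minutes(500), wear_hours=24)
    ref_time = T0 + minutes(query)
    assert match_locf(trace, ref_time) == brute_force_locf(trace, ref_time)


# ---------------------------------------------------------------------------
# Scan matching
# ---------------------------------------------------------------------------


def test_scan_nearest_within_window():
    trace = make_trace([], system=System.FL_LIKE, scans=[(-4, 90.0), (2, 95.0)])
    p = match_scan(trace, T0)
    assert p is not None and p.value == 95.0


def test_scan_tie_breaks_earlier():
    trace = make_trace([], system=System.FL_LIKE, scans=[(-2, 90.0), (2, 95.0)])
    p = match_scan(trace, T0)
    assert p is not None and p.value == 90.0
    # exhaustive check: both candidates are equidistant and in-window
    assert abs((T0 - minutes(2)) - T0) == abs((T0 + minutes(2)) - T0)


def test_scan_none_outside_window():
    trace = make_trace([], system=System.FL_LIKE, scans=[(-3.5, 90.0), (3.5, 95.0)])
    assert match_scan(trace, T0) is None


def test_scan_on_dg5_trace_is_usage_error():
    trace = make_trace([(0, 100.0)], system=System.DG5_LIKE)
    with pytest.raises(ValueError, match="FL-like"):
        match_scan(trace, T0)


# ---------------------------------------------------------------------------
# Interpolation
# ---------------------------------------------------------------------------


def test_linear_midpoint():
    trace = make_trace([(0, 100.0), (10, 110.0)])
    series = {p.t: p.value for p in interpolate_minutely(trace)}
    assert series[T0 + minutes(5)] == pytest.approx(105.0)
    assert len(series) == 11  # one per minute, endpoints included


def test_gap_rule_blocks_interpolation():
    trace = make_trace([(0, 100.0), (45, 110.0)])
    series = interpolate_minutely(trace)
    assert [p.t for p in series] == [T0, T0 + minutes(45)]  # recorded only
    assert interpolate_at(trace, T0 + minutes(10)) is None


def test_constant_trace_constant_series():
    trace = make_trace([(0, 100.0), (15, 100.0), (30, 100.0)])
    series = interpolate_minutely(trace)
    assert len(series) == 31
    assert all(p.value == 100.0 for p in series)


def test_recorded_values_preserved_exactly():
    trace = make_trace([(0, 100.123456789), (5, 103.987654321)])
    series = {p.t: p.value for p in interpolate_minutely(trace)}
    assert series[T0] == 100.123456789
    assert series[T0 + minutes(5)] == 103.987654321


def test_no_extrapolation():
    trace = make_trace([(0, 100.0), (10, 110.0)])
    assert interpolate_at(trace, T0 - minutes(1)) is None
    assert interpolate_at(trace, T0 + minutes(11)) is None


def test_exact_reference_time_not_snapped():
    trace = make_trace([(0, 100.0), (10, 110.0)])
    t = T0 + timedelta(seconds=90)  # 1.5 min
    assert interpolate_at(trace, t) == pytest.approx(101.5)


def test_fewer_than_two_points_is_error():
    trace = make_trace([(0, 100.0)])
    with pytest.raises(ValueError, match="2 continuous points"):
        interpolate_minutely(trace)


def test_interpolation_idempotent_on_sample_times():
    trace = make_trace([(0, 100.0), (7, 93.0), (12, 120.0)])
    once = interpolate_minutely(trace)
    trace2 = make_trace([(0, 0)])
    trace2.continuous = list(once)
    twice = interpolate_minutely(trace2)
    values_once = {p.t: p.value for p in once}
    for p in twice:
        if p.t in values_once:
            assert p.value == values_once[p.t]


# ---------------------------------------------------------------------------
# build_pairs
# ---------------------------------------------------------------------------


def test_one_reference_two_sensors_two_modes():
    from cgmeval.study_model import Site

    traces = [
        make_trace([(-3, 100.0), (0, 101.0)], site=Site.LEFT),
        make_trace([(-3, 100.0), (0, 101.0)], site=Site.RIGHT),
    ]
    study = Study(traces=traces, refs=[make_ref(100.0)])
    pairs = build_pairs(study)
    assert len(pairs) == 4
    assert {(p.site.value, p.pairing_mode.value) for p in pairs} == {
        ("left", "LOCF"), ("left", "INTERPOLATED"),
        ("right", "LOCF"), ("right", "INTERPOLATED"),
    }


def test_reference_during_warmup_yields_no_pair():
    trace = make_trace(
        [(10, 100.0)], wear_start=T0 - minutes(120), warmup_minutes=120,
        wear_hours=24,
    )
    # reference 10 min before warm-up completes
    ref = make_ref(100.0, t=T0 - minutes(10))
    assert build_pairs(Study(traces=[trace], refs=[ref])) == []


def test_zero_error_study_all_deltas_zero():
    cfg = zero_noise_config(seed=21)
    study = generate_study(cfg, ZERO_MODELS)
    pairs = build_pairs(study)
    assert pairs
    assert all(p.delta == 0.0 for p in pairs)
    assert all(p.rel_delta == 0.0 for p in pairs)


def test_pair_counts_monotone_in_window_size():
    cfg = zero_noise_config(seed=22)
    study = generate_study(cfg, ZERO_MODELS)
    sizes = []
    for w in (5.0, 3.0, 1.0):
        pcfg = PairingConfig(locf_window_minutes=w, scan_window_minutes=min(w, 3.0))
        sizes.append(len(build_pairs(study, pcfg)))
    assert sizes[0] >= sizes[1] >= sizes[2]


def test_pairs_respect_post_warmup_wear_interval(small_noisy_study):
    _, study = small_noisy_study
    by_key = {
        (t.system, t.participant_id, t.site, t.sensor_seq): t for t in study.traces
    }
    for p in build_pairs(study):
        tr = by_key[(p.system, p.participant_id, p.site, p.sensor_seq)]
        assert tr.active_start <= p.cgm_time <= tr.wear_end


def test_delta_consistency(small_noisy_study):
    _, study = small_noisy_study
    for p in build_pairs(study):
        assert p.delta == pytest.approx(p.cgm_value - p.ref.value, abs=1e-12)
        assert p.rel_delta == pytest.approx(p.delta / p.ref.value, abs=1e-15)


def test_scan_mode_only_on_fl(small_noisy_study):
    _, study = small_noisy_study
    for p in build_pairs(study):
        if p.pairing_mode is PairingMode.SCAN:
            assert p.system is System.FL_LIKE
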