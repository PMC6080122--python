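import dataclasses
import math

import numpy as np
import pytest
from scipy.stats import norm

from cgmeval.metrics import (
    MetricConfig,
    exceedance_table,
    mad_mard,
    pad_pard,
    round_half_up,
    stratify,
    thin_hourly,
    within_limits_table,
)
from cgmeval.study_model import Method, PairingMode, Phase, Site, BodyLocation, System
from cgmeval.synthetic import (
    ProfileParams,
    SensorErrorModel,
    StudyConfig,
    generate_study,
    simulate_profile,
    simulate_sensor,
)
from cgmeval.pairing import build_pairs

from conftest import T0, ZERO_MODELS, make_pair, minutes, zero_noise_config


def test_round_half_up():
    assert round_half_up(24.25) == 24.3
    assert round_half_up(24.249999) == 24.2
    assert round_half_up(0.05, 1) == 0.1
    assert round_half_up(85.835184, 1) == 85.8


# ---------------------------------------------------------------------------
# Exceedance
# ---------------------------------------------------------------------------


def test_absolute_difference_below_split_does_not_exceed_15():
    pairs = [make_pair(90.0, 104.0)]  # |delta| = 14
    table = exceedance_table(pairs)
    assert [r.n_exceeding for r in table.rows] == [0, 0, 0, 0]


def test_relative_difference_above_split():
    pairs = [make_pair(200.0, 262.0)]  # |rel| = 31%
    table = exceedance_table(pairs)
    exceeded = {r.threshold for r in table.rows if r.n_exceeding == 1}
    assert exceeded == {15.0, 20.0, 30.0}


def test_exceedance_is_strict():
    pairs = [make_pair(90.0, 105.0)]  # |delta| exactly 15
    table = exceedance_table(pairs)
    assert table.rows[0].n_exceeding == 0
    assert within_limits_table(pairs).rows[0].n_exceeding == 1  # complement


def test_exactly_100_uses_relative_stratum():
    pairs = [make_pair(100.0, 116.0)]  # rel 16% -> exceeds 15
    assert exceedance_table(pairs).rows[0].n_exceeding == 1
    # but as absolute it would also be 16 mg/dL; check stratum via MAD n
    assert mad_mard(pairs).mad.n == 0
    assert mad_mard(pairs).mard.n == 1


def test_under_over_shares_partition_exceeding_pairs():
    pairs = [make_pair(200.0, 140.0), make_pair(200.0, 270.0), make_pair(200.0, 300.0)]
    row = exceedance_table(pairs).rows[0]
    assert row.n_exceeding == 3
    assert row.pct_cgm_below + row.pct_cgm_above == pytest.approx(100.0)
    assert row.pct_cgm_below == pytest.approx(100.0 / 3.0)


def test_exceedance_monotone_in_threshold():
    rng = np.random.default_rng(0)
    pairs = [
        make_pair(150.0, 150.0 * (1 + e), group=f"G{i}")
        for i, e in enumerate(rng.normal(0, 0.2, 500))
        if 150.0 * (1 + e) > 1
    ]
    pcts = [r.percent for r in exceedance_table(pairs).rows]
    assert all(a >= b for a, b in zip(pcts, pcts[1:]))


def test_empty_input_defined():
    table = exceedance_table([])
    assert table.n_total == 0
    assert all(r.percent is None and r.n_exceeding == 0 for r in table.rows)


def test_gaussian_exceedance_matches_normal_tail():
    """15%-exceedance of N(0, 0.1) relative error ~ 2(1 - Phi(1.5))."""
    rng = np.random.default_rng(42)
    errors = rng.normal(0, 0.10, 100_000)
    pairs = [
        make_pair(150.0, 150.0 * (1 + e), group=f"G{i}") for i, e in enumerate(errors)
    ]
    row = exceedance_table(pairs).rows[0]
    expected = 200.0 * (1 - norm.cdf(1.5))
    assert row.percent == pytest.approx(expected, abs=0.5)


# ---------------------------------------------------------------------------
# MAD / MARD
# ---------------------------------------------------------------------------


def test_identical_pairs_zero():
    pairs = [make_pair(80.0, 80.0), make_pair(150.0, 150.0)]
    d = mad_mard(pairs)
    assert d.mad.mean == 0.0 and d.mard.mean == 0.0
    assert d.combined.mean == 0.0 and d.whole_range_mard.mean == 0.0


def test_single_low_pair():
    d = mad_mard([make_pair(80.0, 90.0)])
    assert d.mad.mean == pytest.approx(10.0) and d.mad.n == 1
    assert d.mard.mean is None and d.mard.n == 0
    assert d.combined.mean == pytest.approx(10.0)


def test_combined_mixes_scales():
    pairs = [make_pair(80.0, 90.0), make_pair(200.0, 220.0)]  # 10 mg/dL and 10%
    d = mad_mard(pairs)
    assert d.combined.mean == pytest.approx(10.0)
    assert d.combined.n == 2


def test_gaussian_mard_matches_half_normal_mean():
    """MARD of N(0, sigma) relative error ~ 100*sigma*sqrt(2/pi)."""
    rng = np.random.default_rng(7)
    sigma = 0.10
    errors = rng.normal(0, sigma, 100_000)
    pairs = [
        make_pair(150.0, 150.0 * (1 + e), group=f"G{i}") for i, e in enumerate(errors)
    ]
    d = mad_mard(pairs)
    assert d.mard.mean == pytest.approx(100 * sigma * math.sqrt(2 / math.pi), abs=0.15)


@pytest.mark.parametrize("sigma", [0.05, 0.10, 0.15])
def test_parameter_recovery_proportional_noise(sigma):
    """End-to-end: known proportional noise is recovered as MARD within 3 SE."""
    cfg = zero_noise_config(baseline=160.0, seed=int(sigma * 100))
    models = {
        s: SensorErrorModel(lag_tau_minutes=0, bias_mgdl=0, proportional_sd=sigma,
                            additive_sd_mgdl=0, dropout_prob=0)
        for s in System
    }
    study = generate_study(cfg, models)
    # displayed-value modes only: interpolation would average two noisy
    # samples and shrink the apparent noise
    pairs = [
        p for p in build_pairs(study) if p.pairing_mode is not PairingMode.INTERPOLATED
    ]
    d = mad_mard(pairs)
    expected = 100 * sigma * math.sqrt(2 / math.pi)
    se = d.mard.sd / math.sqrt(d.mard.n)
    assert abs(d.mard.mean - expected) < 3 * se + 1e-9


# ---------------------------------------------------------------------------
# Hourly thinning
# ---------------------------------------------------------------------------


def test_thin_hourly_keeps_one_per_hour():
    pairs = [
        make_pair(150.0, 150.0, t=T0.replace(minute=m), group=f"G{m}")
        for m in (0, 15, 30, 45)
    ]
    kept = thin_hourly(pairs)
    assert len(kept) == 1
    assert kept[0].ref.t.minute == 0  # earliest wins


def test_thin_hourly_noop_when_already_hourly():
    pairs = [
        make_pair(150.0, 150.0, t=T0 + minutes(60 * h), group=f"G{h}") for h in range(4)
    ]
    assert thin_hourly(pairs) == sorted(pairs, key=lambda p: p.ref.t)


def test_thin_hourly_key_includes_sensor():
    pairs = [
        make_pair(150.0, 150.0, t=T0, site=Site.LEFT, group="G1"),
        make_pair(150.0, 150.0, t=T0 + minutes(15), site=Site.RIGHT, group="G2"),
    ]
    assert len(thin_hourly(pairs)) == 2


# ---------------------------------------------------------------------------
# PAD / PARD
# ---------------------------------------------------------------------------


def _flat_profile_sensor(sigma, seed, n_minutes=120_000, baseline=160.0):
    cfg = StudyConfig(
        n_participants=1,
        n_days=math.ceil(n_minutes / 1440) + 1,
        visit_windows=((0, 1),),
        dynamic_days=(),
        seed=seed,
        profile=dataclasses.replace(ProfileParams.flat(), baseline_mgdl=baseline),
    )
    profile = simulate_profile(cfg, "P001")
    model = SensorErrorModel(lag_tau_minutes=0, bias_mgdl=0, proportional_sd=sigma,
                             additive_sd_mgdl=0, dropout_prob=0, seed=seed)
    return simulate_sensor(
        profile, model, System.DG5_LIKE, Site.LEFT, BodyLocation.ABDOMEN,
        cfg.start_date, cfg.start_date + minutes(n_minutes),
        cadence_minutes=1, warmup_minutes=0,
        rng=np.random.default_rng(seed),
    )


def test_identical_traces_zero_precision():
    a = _flat_profile_sensor(0.0, 1, n_minutes=600)
    b = dataclasses.replace(a, site=Site.RIGHT)
    p = pad_pard(a, b)
    assert p.pard.mean == 0.0
    assert p.pad.n == 0  # baseline 160 >= split


def test_pad_pard_symmetry():
    a = _flat_profile_sensor(0.05, 2, n_minutes=2000)
    b = dataclasses.replace(_flat_profile_sensor(0.05, 3, n_minutes=2000), site=Site.RIGHT)
    assert pad_pard(a, b) == pad_pard(b, a)


def test_pard_matches_folded_normal_mean():
    """Two independent sigma=0.10 sensors: PARD ~ 200*sigma/sqrt(pi)."""
    sigma = 0.10
    a = _flat_profile_sensor(sigma, 4)
    b = dataclasses.replace(_flat_profile_sensor(sigma, 5), site=Site.RIGHT)
    p = pad_pard(a, b)
    assert p.pard.n > 100_000
    assert p.pard.mean == pytest.approx(200 * sigma / math.sqrt(math.pi), abs=0.5)


def test_pad_pard_mismatched_sensors_rejected():
    a = _flat_profile_sensor(0.0, 1, n_minutes=600)
    b = dataclasses.replace(a, system=System.FL_LIKE, scans=[])
    with pytest.raises(ValueError, match="same system"):
        pad_pard(a, b)


# ---------------------------------------------------------------------------
# Stratification
# ---------------------------------------------------------------------------


def test_wear_day_from_wear_start():
    p = make_pair(150.0, 150.0, t=T0, wear_start=T0 - minutes(600))  # 10 h
    assert stratify([p], "wear_day") == {"0": [p]}
    p2 = make_pair(150.0, 150.0, t=T0, wear_start=T0 - minutes(60 * 30))  # 30 h
    assert "1" in stratify([p2], "wear_day")


def test_phase_groups_match_labels():
    pairs = [
        make_pair(150.0, 150.0, phase=Phase.IN_HOUSE, group="G1"),
        make_pair(150.0, 150.0, phase=Phase.DYNAMIC, group="G2"),
        make_pair(150.0, 150.0, phase=Phase.HOME_USE, group="G3"),
    ]
    groups = stratify(pairs, "phase")
    assert set(groups) == {"in_house", "dynamic", "home_use"}


def test_glucose_range_bins():
    pairs = [make_pair(v, v, group=f"G{v}") for v in (60.0, 120.0, 200.0)]
    groups = stratify(pairs, "glucose_range")
    assert set(groups) == {"<70", "70-180", ">180"}


def test_trend_classification():
    times = [T0 + minutes(15 * i) for i in range(5)]
    rising = [100.0, 120.0, 140.0, 160.0, 180.0]  # +1.33 mg/dL/min
    pairs = [
        make_pair(v, v, t=t, phase=Phase.DYNAMIC, group=f"G{i}")
        for i, (t, v) in enumerate(zip(times, rising))
    ]
    groups = stratify(pairs, "trend")
    assert set(groups["rising"]) == set(pairs[1:4])
    assert set(groups["unclassified"]) == {pairs[0], pairs[4]}  # no neighbors


def test_stratify_partitions_input(small_noisy_study):
    _, study = small_noisy_study
    pairs = build_pairs(study)
    for key in ("phase", "wear_day", "glucose_range", "therapeutic_decision",
                "reference_method", "trend"):
        groups = stratify(pairs, key)
        assert sum(len(g) for g in groups.values()) == len(pairs)


def test_unknown_key_rejected():
    with pytest.raises(ValueError, match="unknown stratification key"):
        stratify([], "bogus")


def test_zero_noise_stratified_groups_all_zero():
    cfg = zero_noise_config(seed=31)
    study = generate_study(cfg, ZERO_MODELS)
    pairs = build_pairs(study)
    for groups in (stratify(pairs, "phase"), stratify(pairs, "wear_day")):
        for g in groups.values():
            d = mad_mard(g)
            assert (d.whole_range_mard.mean or 0.0) == 0.0


# ---------------------------------------------------------------------------
# Aggregation consistency
# ---------------------------------------------------------------------------


def test_aggregated_mean_is_weighted_mean_of_sensor_means(small_noisy_study):
    _, study = small_noisy_study
    pairs = [
        p for p in build_pairs(study)
        if p.system is System.DG5_LIKE and p.pairing_mode is PairingMode.LOCF
    ]
    agg = mad_mard(pairs)
    by_sensor = {}
    for p in pairs:
        by_sensor.setdefault((p.site, p.sensor_seq), []).append(p)
    parts = [mad_mard(g) for g in by_sensor.values()]
    n_sum = sum(d.mard.n for d in parts)
    weighted = sum(d.mard.mean * d.mard.n for d in parts if d.mard.n) / n_sum
    assert n_sum == agg.mard.n
    assert weighted == pytest.approx(agg.mard.mean, abs=1e-9)
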