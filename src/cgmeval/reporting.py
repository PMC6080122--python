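"""Report assembly: exceedance and performance tables across evaluation
units and data sets, plus the end-to-end pipeline.

Reports are emitted as machine-readable JSON (the contract) and rendered
CSV tables (presentation). Cells with empty strata render as ``n.d.`` with
n = 0. Percent rounding happens here, at the reporting boundary.
"""

from __future__ import annotations

import enum
import hashlib
import json
from dataclasses import asdict, dataclass, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .error_grid import CEGSummary, ceg_summary
from .metrics import (
    DeviationSummary,
    ExceedanceSummary,
    MetricConfig,
    PrecisionSummary,
    Stat,
    exceedance_table,
    mad_mard,
    precision_diffs,
    precision_summary_from_diffs,
    round_half_up,
    thin_hourly,
)
from .pairing import DEFAULT_MODES, PairingConfig, build_pairs, write_pairs
from .study_model import (
    Method,
    PairedObservation,
    PairingMode,
    Phase,
    Study,
    System,
    write_study,
)
from .synthetic import SensorErrorModel, StudyConfig, generate_study


class EvaluationUnit(str, enum.Enum):
    AGGREGATED = "aggregated"
    SENSOR = "sensor"
    APPLICATION_SITE = "site"
    PARTICIPANT = "participant"


class DataSetSelector(str, enum.Enum):
    COMPLETE = "complete"
    IN_HOUSE = "in_house"
    HOME_USE = "home_use"
    DYNAMIC = "dynamic"
    THERAPEUTIC_DECISIONS = "therapeutic_decisions"


#: The four analysis modes of the headline tables.
MODE_SPECS: tuple[tuple[str, System, PairingMode], ...] = (
    ("DG5_INT", System.DG5_LIKE, PairingMode.INTERPOLATED),
    ("DG5_LOCF", System.DG5_LIKE, PairingMode.LOCF),
    ("FLcont_INT", System.FL_LIKE, PairingMode.INTERPOLATED),
    ("FLscan", System.FL_LIKE, PairingMode.SCAN),
)


def select_dataset(
    pairs: list[PairedObservation],
    selector: DataSetSelector | str,
    reference_method: Method = Method.BGMS_CAPILLARY,
) -> list[PairedObservation]:
    """Filter pairs to one of the analysis data sets.

    Dynamic is a sub-phase of in-house, so the in-house selector includes
    dynamic-phase pairs. Venous references exist only during dynamic
    phases; combining them with any other selector is a usage error.
    """
    selector = DataSetSelector(selector)
    if reference_method is Method.HK_VENOUS and selector is not DataSetSelector.DYNAMIC:
        raise ValueError("venous references are only available for the dynamic data set")
    out = [p for p in pairs if p.ref.method is reference_method]
    if selector is DataSetSelector.COMPLETE:
        return out
    if selector is DataSetSelector.IN_HOUSE:
        return [p for p in out if p.ref.phase in (Phase.IN_HOUSE, Phase.DYNAMIC)]
    if selector is DataSetSelector.HOME_USE:
        return [p for p in out if p.ref.phase is Phase.HOME_USE]
    if selector is DataSetSelector.DYNAMIC:
        return [p for p in out if p.ref.phase is Phase.DYNAMIC]
    return [p for p in out if p.ref.therapeutic_decision]


def group_pairs(
    pairs: list[PairedObservation], unit: EvaluationUnit | str
) -> dict[str, list[PairedObservation]]:
    """Group pairs by evaluation unit; keys are stable string labels."""
    unit = EvaluationUnit(unit)
    if unit is EvaluationUnit.AGGREGATED:
        return {"aggregated": list(pairs)}
    groups: dict[str, list[PairedObservation]] = {}
    for p in pairs:
        if unit is EvaluationUnit.SENSOR:
            key = f"{p.system.value}/{p.participant_id}/{p.site.value}/seq{p.sensor_seq}"
        elif unit is EvaluationUnit.APPLICATION_SITE:
            key = f"{p.system.value}/{p.participant_id}/{p.site.value}"
        else:
            key = p.participant_id
        groups.setdefault(key, []).append(p)
    return groups


# ---------------------------------------------------------------------------
# Serialization helpers
# ---------------------------------------------------------------------------


def _round(x: float | None, digits: int) -> float | None:
    return None if x is None else round_half_up(x, digits)


def stat_dict(s: Stat, digits: int = 1) -> dict:
    return {"mean": _round(s.mean, digits), "sd": _round(s.sd, digits), "n": s.n}


def deviation_dict(d: DeviationSummary, digits: int = 1) -> dict:
    return {
        "n_pairs": d.n_pairs,
        "mad_mgdl": stat_dict(d.mad, digits),
        "mard_pct": stat_dict(d.mard, digits),
        "combined_mad_mard": stat_dict(d.combined, digits),
        "whole_range_mard_pct": stat_dict(d.whole_range_mard, digits),
    }


def exceedance_dict(e: ExceedanceSummary, digits: int = 1) -> dict:
    return {
        "n_total": e.n_total,
        "thresholds": [
            {
                "threshold": r.threshold,
                "n_exceeding": r.n_exceeding,
                "percent": _round(r.percent, digits),
                "pct_cgm_below": _round(r.pct_cgm_below, digits),
                "pct_cgm_above": _round(r.pct_cgm_above, digits),
            }
            for r in e.rows
        ],
    }


def precision_dict(p: PrecisionSummary, digits: int = 1) -> dict:
    return {"pad_mgdl": stat_dict(p.pad, digits), "pard_pct": stat_dict(p.pard, digits)}


def ceg_dict(c: CEGSummary) -> dict:
    return {"n_total": c.n_total, "counts": c.counts, "percents": c.percents}


# ---------------------------------------------------------------------------
# Report builders
# ---------------------------------------------------------------------------


def _mode_pairs(
    pairs: list[PairedObservation], system: System, mode: PairingMode
) -> list[PairedObservation]:
    return [p for p in pairs if p.system is system and p.pairing_mode is mode]


def report_exceedance(
    study: Study,
    pairing_cfg: PairingConfig | None = None,
    metric_cfg: MetricConfig | None = None,
    pairs: list[PairedObservation] | None = None,
) -> dict:
    """Threshold-exceedance report at times of therapeutic decisions.

    One block per system using its displayed-value mode (LOCF for DG5-like,
    SCAN for FL-like), plus application-site-level percentage distributions
    (box-plot-ready, one value per site per threshold).
    """
    metric_cfg = metric_cfg or MetricConfig()
    if pairs is None:
        pairs = build_pairs(study, pairing_cfg)
    decisions = select_dataset(pairs, DataSetSelector.THERAPEUTIC_DECISIONS)

    out: dict = {"dataset": "therapeutic_decisions", "systems": {}}
    for label, system, mode in (("DG5_LOCF", System.DG5_LIKE, PairingMode.LOCF),
                                ("FLscan", System.FL_LIKE, PairingMode.SCAN)):
        subset = _mode_pairs(decisions, system, mode)
        table = exceedance_table(subset, metric_cfg)
        site_groups = group_pairs(subset, EvaluationUnit.APPLICATION_SITE)
        site_pct: dict[str, list] = {}
        for th in metric_cfg.thresholds:
            values = []
            for key in sorted(site_groups):
                t = exceedance_table(site_groups[key], metric_cfg)
                row = next(r for r in t.rows if r.threshold == th)
                values.append(
                    {"site": key, "percent": _round(row.percent, metric_cfg.round_digits)}
                )
            site_pct[f"{th:g}"] = values
        out["systems"][label] = {
            "system": system.value,
            "mode": mode.value,
            "exceedance": exceedance_dict(table, metric_cfg.round_digits),
            "site_percentages": site_pct,
        }
    return out


def _precision_pooled(
    study: Study, system: System, pairing_cfg: PairingConfig | None, cfg: MetricConfig
) -> PrecisionSummary:
    """PAD/PARD pooled over all same-participant sensor pairs of a system."""
    means_all, diffs_all = [], []
    by_pid: dict[str, list] = {}
    for tr in study.traces:
        if tr.system is system:
            by_pid.setdefault(tr.participant_id, []).append(tr)
    for pid in sorted(by_pid):
        traces = by_pid[pid]
        for i in range(len(traces)):
            for j in range(i + 1, len(traces)):
                a, b = traces[i], traces[j]
                if a.site is b.site:
                    continue  # precision compares the two application sites
                if a.active_start >= b.wear_end or b.active_start >= a.wear_end:
                    continue
                m, d = precision_diffs(a, b, pairing_cfg)
                if m.size:
                    means_all.append(m)
                    diffs_all.append(d)
    if not means_all:
        return precision_summary_from_diffs(np.empty(0), np.empty(0), cfg)
    return precision_summary_from_diffs(
        np.concatenate(means_all), np.concatenate(diffs_all), cfg
    )


def report_performance(
    study: Study,
    pairing_cfg: PairingConfig | None = None,
    metric_cfg: MetricConfig | None = None,
    pairs: list[PairedObservation] | None = None,
) -> dict:
    """MAD/MARD per mode and data set, CEG zone table, and PAD/PARD.

    In-house cells are thinned to at most one value per hour per sensor;
    dynamic cells are not.
    """
    pairing_cfg = pairing_cfg or PairingConfig()
    metric_cfg = metric_cfg or MetricConfig()
    if pairs is None:
        modes = {
            System.DG5_LIKE: (PairingMode.LOCF, PairingMode.INTERPOLATED),
            System.FL_LIKE: (PairingMode.SCAN, PairingMode.INTERPOLATED),
        }
        pairs = build_pairs(study, pairing_cfg, modes)
    digits = metric_cfg.round_digits

    out: dict = {"modes": {}, "precision": {}}
    for label, system, mode in MODE_SPECS:
        mp = _mode_pairs(pairs, system, mode)
        datasets = {
            "complete": mad_mard(select_dataset(mp, "complete"), metric_cfg),
            "in_house_hourly": mad_mard(
                thin_hourly(select_dataset(mp, "in_house")), metric_cfg
            ),
            "dynamic_capillary": mad_mard(select_dataset(mp, "dynamic"), metric_cfg),
            "dynamic_venous": mad_mard(
                select_dataset(mp, "dynamic", Method.HK_VENOUS), metric_cfg
            ),
            "home_use": mad_mard(select_dataset(mp, "home_use"), metric_cfg),
        }
        out["modes"][label] = {
            "system": system.value,
            "mode": mode.value,
            "mad_mard": {k: deviation_dict(v, digits) for k, v in datasets.items()},
            "ceg": ceg_dict(ceg_summary(select_dataset(mp, "complete"), cfg=metric_cfg)),
        }

    for system in (System.DG5_LIKE, System.FL_LIKE):
        out["precision"][system.value] = precision_dict(
            _precision_pooled(study, system, pairing_cfg, metric_cfg), digits
        )
    return out


# ---------------------------------------------------------------------------
# CSV rendering (presentation layer)
# ---------------------------------------------------------------------------


def _cell(stat: dict) -> str:
    if stat["n"] == 0 or stat["mean"] is None:
        return "n.d."
    return f"{stat['mean']} ± {stat['sd']} (n={stat['n']})"


def render_performance_csv(report: dict, path) -> None:
    rows = []
    for label, block in report["modes"].items():
        for dataset, dev in block["mad_mard"].items():
            rows.append(
                {
                    "mode": label,
                    "dataset": dataset,
                    "MAD_lt_split": _cell(dev["mad_mgdl"]),
                    "MARD_ge_split": _cell(dev["mard_pct"]),
                    "n_pairs": dev["n_pairs"],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def render_exceedance_csv(report: dict, path) -> None:
    rows = []
    for label, block in report["systems"].items():
        exc = block["exceedance"]
        for row in exc["thresholds"]:
            rows.append(
                {
                    "mode": label,
                    "threshold": row["threshold"],
                    "percent": "n.d." if row["percent"] is None else row["percent"],
                    "n_exceeding": row["n_exceeding"],
                    "pct_cgm_below": row["pct_cgm_below"],
                    "pct_cgm_above": row["pct_cgm_above"],
                    "n_total": exc["n_total"],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _config_digest(config: StudyConfig, models: dict[System, SensorErrorModel]) -> str:
    def encode(obj):
        if is_dataclass(obj):
            return {k: encode(v) for k, v in asdict(obj).items()}
        if isinstance(obj, dict):
            return {str(k): encode(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [encode(v) for v in obj]
        if hasattr(obj, "isoformat"):
            return obj.isoformat()
        return obj

    payload = json.dumps(
        {"study": encode(config), "models": {s.value: encode(m) for s, m in models.items()}},
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()


def run_pipeline(
    config: StudyConfig,
    out_dir,
    models: dict[System, SensorErrorModel] | None = None,
    pairing_cfg: PairingConfig | None = None,
    metric_cfg: MetricConfig | None = None,
    log=print,
) -> dict:
    """simulate -> pair -> evaluate -> report, with a manifest.

    Returns the manifest dict; all artifacts are written under ``out_dir``.
    Reruns with the same config and seeds produce identical outputs.
    """
    from .synthetic import DEFAULT_SENSOR_MODELS

    models = models or DEFAULT_SENSOR_MODELS
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn):
        log(f"[{name}] ...")
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-raise with stage name
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    study = stage("simulate", lambda: generate_study(config, models))
    stage("write-study", lambda: write_study(study, out / "study"))
    pairs = stage("pair", lambda: build_pairs(study, pairing_cfg))
    stage("write-pairs", lambda: write_pairs(pairs, out / "pairs.csv"))
    exc_report = stage(
        "exceedance", lambda: report_exceedance(study, pairing_cfg, metric_cfg, pairs=pairs)
    )
    perf_report = stage(
        "performance", lambda: report_performance(study, pairing_cfg, metric_cfg, pairs=pairs)
    )

    (out / "exceedance.json").write_text(json.dumps(exc_report, indent=2, sort_keys=True))
    (out / "performance.json").write_text(json.dumps(perf_report, indent=2, sort_keys=True))
    render_exceedance_csv(exc_report, out / "exceedance.csv")
    render_performance_csv(perf_report, out / "performance.csv")

    manifest = {
        "config_sha256": _config_digest(config, models),
        "seed": config.seed,
        "n_participants": config.n_participants,
        "n_days": config.n_days,
        "n_traces": len(study.traces),
        "n_reference_points": len(study.refs),
        "n_pairs": len(pairs),
        "version": __version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log(f"[done] wrote artifacts to {out}")
    return manifest


__all__ = [
    "EvaluationUnit",
    "DataSetSelector",
    "MODE_SPECS",
    "select_dataset",
    "group_pairs",
    "report_exceedance",
    "report_performance",
    "render_performance_csv",
    "render_exceedance_csv",
    "run_pipeline",
    "stat_dict",
    "deviation_dict",
    "exceedance_dict",
    "precision_dict",
    "ceg_dict",
]
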