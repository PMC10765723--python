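"""File readers/writers and the end-to-end pipeline runner."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .estimators import (
    DDFAThresholdEstimator,
    DFAAlpha1ThresholdEstimator,
    HRMaxThresholdEstimator,
    LactateThresholdEstimator,
    RRIPreprocessor,
)
from .series import RRISeries
from .thresholds import LactateCurve

logger = logging.getLogger("hrvthresh")

__all__ = [
    "read_rri",
    "write_rri_csv",
    "read_lactate",
    "run_pipeline",
    "report_row",
    "write_report",
]

REPORT_SCHEMA_VERSION = 1


def read_rri(path, dialect: str | None = None) -> RRISeries:
    """Read an RR-interval series.

    Dialects: ``txt-ms`` (one interval in ms per line) or ``csv-time-rr``
    (columns ``time_s, rr_ms``); auto-detected from the first line when not
    given.  Malformed lines raise with their line number.
    """
    path = Path(path)
    with open(path) as f:
        first = f.readline()
    if dialect is None:
        dialect = "csv-time-rr" if ("," in first or "rr_ms" in first) else "txt-ms"
    if dialect == "csv-time-rr":
        df = pd.read_csv(path)
        required = {"time_s", "rr_ms"}
        if not required <= set(df.columns):
            raise ValueError(f"{path}: expected columns {sorted(required)}")
        return RRISeries(
            intervals=df["rr_ms"].to_numpy(float),
            t_cum=df["time_s"].to_numpy(float),
        )
    if dialect != "txt-ms":
        raise ValueError(f"unknown dialect {dialect!r}")
    intervals = []
    with open(path) as f:
        for ln, line in enumerate(f, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                intervals.append(float(line))
            except ValueError:
                raise ValueError(f"{path}: unparseable RR value on line {ln}: {line!r}")
    if not intervals:
        raise ValueError(f"{path}: no data")
    return RRISeries.from_intervals(intervals)


def write_rri_csv(series: RRISeries, path, retained_only: bool = True) -> None:
    """Write a series as ``time_s, rr_ms`` CSV (retained beats by default)."""
    work = series.compact() if retained_only else series
    pd.DataFrame({"time_s": work.t_cum, "rr_ms": work.intervals}).to_csv(
        path, index=False
    )


def read_lactate(path) -> LactateCurve:
    """Read a lactate CSV with columns ``step_end_s, lactate_mmol_l, hr_bpm``."""
    df = pd.read_csv(path)
    required = {"step_end_s", "lactate_mmol_l", "hr_bpm"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    return LactateCurve(
        step_t=df["step_end_s"].to_numpy(float),
        lactate=df["lactate_mmol_l"].to_numpy(float),
        hr=df["hr_bpm"].to_numpy(float),
    )


def _result_block(est) -> dict:
    r = est.result_
    return {
        "method": r.method,
        "t1_bpm": r.t1_bpm,
        "t2_bpm": r.t2_bpm,
        "diagnostics": _jsonable(r.diagnostics),
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def run_pipeline(
    cfg: RunConfig,
    rri_path=None,
    lactate_path=None,
    hrmax: float | None = None,
    series: RRISeries | None = None,
    lactate: LactateCurve | None = None,
) -> dict:
    """Preprocess, analyse and estimate thresholds with every available method.

    Produces a JSON-serialisable report; per-method failures degrade to an
    absent block with a logged warning, never an aborted run.
    """
    if series is None:
        if rri_path is None:
            raise ValueError("need an RRI input")
        series = read_rri(rri_path)
    if lactate is None and lactate_path is not None:
        lactate = read_lactate(lactate_path)

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": cfg.to_dict(),
    }
    pre = RRIPreprocessor(
        lo=cfg.lo, hi=cfg.hi, kernel=cfg.kernel, frac=cfg.frac,
        manual_exclude=cfg.manual_exclude or None,
    )
    clean = pre.fit_transform(series).compact()
    report["preprocess"] = pre.report_.to_dict()
    logger.info("preprocessing removed %.2f%% of beats",
                100 * pre.report_.removed_fraction)

    methods: dict = {}
    try:
        ddfa_est = DDFAThresholdEstimator(
            scale_min=cfg.scale_min, scale_max=cfg.scale_max, n_scales=cfg.n_scales,
            segment_factor=cfg.segment_factor, hop=cfg.hop, centered=cfg.centered,
            baseline_bins=cfg.baseline_bins, smooth_kernel=cfg.smooth_kernel,
            run=cfg.run, level2=cfg.level2,
        ).fit(clean)
        methods["ddfa"] = _result_block(ddfa_est)
    except Exception as exc:  # degrade, never abort
        logger.warning("DDFA method failed: %s", exc)
    try:
        a1_est = DFAAlpha1ThresholdEstimator(
            step=cfg.a1_step, window=cfg.a1_window, lam=cfg.lam,
            order=cfg.order, band=cfg.band, gap_n=cfg.gap_n,
        ).fit(clean)
        methods["alpha1"] = _result_block(a1_est)
    except Exception as exc:
        logger.warning("DFA alpha1 method failed: %s", exc)
    if hrmax is not None:
        try:
            methods["hrmax"] = _result_block(
                HRMaxThresholdEstimator(p1=cfg.p1, p2=cfg.p2).fit(hrmax)
            )
        except Exception as exc:
            logger.warning("HRmax method failed: %s", exc)
    if lactate is not None:
        try:
            methods["lactate"] = _result_block(LactateThresholdEstimator().fit(lactate))
        except Exception as exc:
            logger.warning("lactate method failed: %s", exc)
    else:
        logger.warning("no lactate input; lactate block absent")
    report["methods"] = methods
    return report


def report_row(report: dict) -> pd.DataFrame:
    """Flatten a pipeline report into one table row of thresholds (BPM)."""
    names = {"lactate": "LT", "hrmax": "HRmaxT", "alpha1": "DFAa1T", "ddfa": "DDFAT"}
    row = {}
    for key, label in names.items():
        block = report["methods"].get(key)
        row[f"{label}1"] = block["t1_bpm"] if block else None
        row[f"{label}2"] = block["t2_bpm"] if block else None
    return pd.DataFrame([row])


def write_report(report: dict, path) -> None:
    with open(path, "w") as f:
        json.dump(report, f, indent=2, sort_keys=True)
        f.write("\n")
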