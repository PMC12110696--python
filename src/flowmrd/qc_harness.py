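"""Daily electronic QC, monitoring-log persistence and dashboard export.

The electronic QC run pushes a fixed test specimen through the full desk
pipeline — read, surrogate classification, correction overlay, drift score,
case call — serializes the result canonically and compares its cryptographic
digest against a reference digest frozen during validation. Any change in
the pipeline, its configuration or its numeric behaviour above the canonical
precision flips the digest and fails the run.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from datetime import date as _date
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from flowmrd import drift_monitor, error_analysis, synthcyto
from flowmrd.drift_monitor import DriftModel, DriftScore, alert_rate
from flowmrd.error_analysis import MonitoringRecord
from flowmrd.validation_stats import ConfusionCounts

__all__ = [
    "QCRecord",
    "MonitoringLog",
    "QCConfig",
    "canonical_json",
    "canonical_digest",
    "daily_qc",
    "dashboard_export",
]


@dataclass(frozen=True)
class QCConfig:
    """Every monitoring constant in one place, loadable from JSON."""

    lod_pct: float = error_analysis.LOD_PCT
    lloq_pct: float = error_analysis.LLOQ_PCT
    min_cluster: int = error_analysis.MIN_CLUSTER
    variance_target: float = 0.65
    n_sub: int = 10_000
    sd_multiplier: float = 3.0
    daily_rule_count: int = 5
    lot_size: int = 444
    acceptance_number: int = 1
    confidence: float = 0.95
    quality: float = 0.95
    review_periods: int = 6

    @classmethod
    def from_json(cls, path: str | Path) -> "QCConfig":
        return cls(**json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=1))
        return path


# ---------------------------------------------------------------------------
# canonical serialization and digest

def _canonicalize(obj):
    if isinstance(obj, float):
        if not np.isfinite(obj):
            raise TypeError(f"non-finite float {obj!r} not serializable")
        return float(f"{obj:.6g}")
    if isinstance(obj, (np.floating,)):
        return _canonicalize(float(obj))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (bool, int, str)) or obj is None:
        if isinstance(obj, str):
            return obj.replace("\r\n", "\n")
        return obj
    if isinstance(obj, _date):
        return obj.isoformat()
    if isinstance(obj, Mapping):
        return {str(k): _canonicalize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_canonicalize(v) for v in obj]
    raise TypeError(f"field of type {type(obj).__name__} not serializable")


def canonical_json(obj) -> str:
    """Canonical serialization: sorted keys, floats at 6 significant digits,
    newline-normalized strings."""
    return json.dumps(_canonicalize(obj), sort_keys=True,
                      separators=(",", ":"))


def canonical_digest(obj) -> str:
    """SHA-256 hex digest of the canonical serialization.

    Logically identical content digests identically regardless of key order
    or float-formatting noise below the canonical precision.
    """
    return hashlib.sha256(canonical_json(obj).encode("utf-8")).hexdigest()


# ---------------------------------------------------------------------------
# daily electronic QC

@dataclass(frozen=True)
class QCRecord:
    run_date: _date
    workstation_id: str
    digest: str
    reference_digest: str
    passed: bool
    note: str = ""


def run_pipeline(
    fcs_path: str | Path,
    model: DriftModel,
    correction_overlay: Mapping[int, str] | None = None,
    config: QCConfig | None = None,
    seed: int = 0,
) -> dict:
    """Full desk pipeline on one specimen file; returns the canonical output.

    Reads the FCS file with its label sidecar (the surrogate classifier
    stream), applies the stored correction overlay (event index -> corrected
    class, standing in for human review), scores drift and calls the case
    from the corrected labels.
    """
    config = config or QCConfig()
    matrix = synthcyto.read_fcs(fcs_path)
    auto = matrix.labels.copy()
    corrected = auto.copy()
    for idx, cls in (correction_overlay or {}).items():
        corrected[int(idx)] = cls
    counts, _ = error_analysis.event_confusion(auto, corrected)
    mrd = error_analysis.mrd_from_labels(
        corrected, lod=config.lod_pct, lloq=config.lloq_pct,
        min_cluster=config.min_cluster)
    score = drift_monitor.score_sample(model, matrix, n_sub=config.n_sub,
                                       seed=seed)
    return {
        "sample_id": matrix.sample_id,
        "n_events": matrix.n_events,
        "confusion": {"tp": counts.tp, "fp": counts.fp,
                      "fn": counts.fn, "tn": counts.tn},
        "mrd": {"clonal_events": mrd.clonal_events,
                "denominator_events": mrd.denominator_events,
                "percentage": mrd.percentage, "call": mrd.call},
        "drift": {"error": score.error, "alert": score.alert,
                  "direction": score.direction},
    }


def daily_qc(
    test_sample: str | Path,
    model: DriftModel,
    reference_digest: str,
    correction_overlay: Mapping[int, str] | None = None,
    config: QCConfig | None = None,
    run_date: _date | None = None,
    workstation_id: str = "workstation-1",
    seed: int = 0,
) -> QCRecord:
    """Hash-verified end-to-end QC run; never raises out of the pipeline.

    Any exception during processing yields a failing record carrying the
    error note, so a corrupted fixture surfaces as a QC failure rather than
    a silent crash.
    """
    run_date = run_date or _date.today()
    try:
        output = run_pipeline(test_sample, model, correction_overlay,
                              config, seed)
        digest = canonical_digest(output)
        note = ""
    except Exception as exc:  # noqa: BLE001 - QC must record, not crash
        digest = ""
        note = f"pipeline error: {exc}"
    return QCRecord(run_date=run_date, workstation_id=workstation_id,
                    digest=digest, reference_digest=reference_digest,
                    passed=bool(digest) and digest == reference_digest,
                    note=note)


# ---------------------------------------------------------------------------
# monitoring log (CSV-directory backend)

class MonitoringLog:
    """Append-only monitoring store backed by a directory of CSV files."""

    DRIFT = "drift_scores.csv"
    RECORDS = "monitoring_records.csv"
    QC = "qc_records.csv"

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)

    def _append(self, filename: str, row: dict) -> None:
        path = self.directory / filename
        df = pd.DataFrame([row])
        df.to_csv(path, mode="a", header=not path.exists(), index=False)

    def append_drift(self, score: DriftScore) -> None:
        self._append(self.DRIFT, {
            "sample_id": score.sample_id, "date": score.date.isoformat(),
            "error": score.error, "alert": score.alert,
            "direction": score.direction})

    def append_record(self, rec: MonitoringRecord) -> None:
        c = rec.event_confusion
        self._append(self.RECORDS, {
            "sample_id": rec.sample_id, "date": rec.date.isoformat(),
            "tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn,
            "dnn_pct": rec.dnn_pct, "corrected_pct": rec.corrected_pct,
            "dnn_call": rec.dnn_call, "corrected_call": rec.corrected_call,
            "flags": ";".join(sorted(rec.phenotype_flags))})

    def append_qc(self, rec: QCRecord) -> None:
        self._append(self.QC, {
            "run_date": rec.run_date.isoformat(),
            "workstation_id": rec.workstation_id, "digest": rec.digest,
            "reference_digest": rec.reference_digest,
            "passed": rec.passed, "note": rec.note})

    def drift_scores(self) -> list[DriftScore]:
        path = self.directory / self.DRIFT
        if not path.exists():
            return []
        df = pd.read_csv(path)
        return [DriftScore(sample_id=str(r.sample_id),
                           date=_date.fromisoformat(r.date),
                           error=float(r.error), alert=bool(r.alert),
                           direction=str(r.direction))
                for r in df.itertuples()]

    def monitoring_records(self) -> list[MonitoringRecord]:
        path = self.directory / self.RECORDS
        if not path.exists():
            return []
        df = pd.read_csv(path, keep_default_na=False)
        out = []
        for r in df.itertuples():
            flags = frozenset(f for f in str(r.flags).split(";") if f)
            out.append(MonitoringRecord(
                sample_id=str(r.sample_id),
                date=_date.fromisoformat(r.date),
                event_confusion=ConfusionCounts(int(r.tp), int(r.fp),
                                                int(r.fn), int(r.tn)),
                dnn_call=str(r.dnn_call), corrected_call=str(r.corrected_call),
                dnn_pct=float(r.dnn_pct), corrected_pct=float(r.corrected_pct),
                phenotype_flags=flags))
        return out

    def qc_records(self) -> list[QCRecord]:
        path = self.directory / self.QC
        if not path.exists():
            return []
        df = pd.read_csv(path, keep_default_na=False)
        return [QCRecord(run_date=_date.fromisoformat(r.run_date),
                         workstation_id=str(r.workstation_id),
                         digest=str(r.digest),
                         reference_digest=str(r.reference_digest),
                         passed=bool(r.passed), note=str(r.note))
                for r in df.itertuples()]


# ---------------------------------------------------------------------------
# dashboard export

def dashboard_export(
    log: MonitoringLog,
    start: _date,
    end: _date,
    out_dir: str | Path,
    model: DriftModel | None = None,
    plots: bool = False,
) -> dict:
    """Emit the monitoring bundle for a date range: drift time series with
    thresholds, alert summary, error-analysis metrics and QC pass/fail.

    Returns the bundle as a dict and writes CSV/JSON files under ``out_dir``.
    An empty range yields an empty bundle with a warning.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scores = [s for s in log.drift_scores() if start <= s.date <= end]
    records = [r for r in log.monitoring_records() if start <= r.date <= end]
    qc = [q for q in log.qc_records() if start <= q.run_date <= end]

    bundle: dict = {"schema_version": "1",
                    "period": {"start": start.isoformat(),
                               "end": end.isoformat()}}
    if not (scores or records or qc):
        warnings.warn("no monitoring data in the requested range")
        bundle["empty"] = True
        (out_dir / "summary.json").write_text(json.dumps(bundle, indent=1))
        return bundle

    drift_df = drift_monitor.scores_to_dataframe(scores)
    if model is not None and len(drift_df):
        drift_df["upper_threshold"] = model.upper_threshold
        drift_df["lower_threshold"] = model.lower_threshold
    drift_df.to_csv(out_dir / "drift_timeseries.csv", index=False)

    if scores:
        n_alerts, n_total, pct = alert_rate(scores)
        bundle["drift"] = {"n_alerts": n_alerts, "n_total": n_total,
                           "alert_pct": pct,
                           "events": [asdict(e) | {"date": e.date.isoformat()}
                                      for e in
                                      drift_monitor.detect_daily_drift(scores)]}
    if records:
        bundle["error_analysis"] = error_analysis.period_summary(records)
    if qc:
        qc_df = pd.DataFrame([{"run_date": q.run_date.isoformat(),
                               "workstation_id": q.workstation_id,
                               "passed": q.passed, "note": q.note}
                              for q in qc])
        qc_df.to_csv(out_dir / "qc_series.csv", index=False)
        bundle["qc"] = {"n_runs": len(qc),
                        "n_failures": int(sum(not q.passed for q in qc))}

    (out_dir / "summary.json").write_text(json.dumps(bundle, indent=1))

    if plots and scores:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 3))
        errs = [s.error for s in scores]
        colors = ["red" if s.alert else "black" for s in scores]
        ax.scatter(range(len(errs)), errs, c=colors, s=12)
        if model is not None:
            ax.axhline(model.upper_threshold, color="grey", ls="--")
            ax.axhline(model.lower_threshold, color="grey", ls="--")
        ax.set_xlabel("sample index")
        ax.set_ylabel("reconstruction error")
        fig.tight_layout()
        fig.savefig(out_dir / "drift_timeseries.png", dpi=100)
        plt.close(fig)
    return bundle
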