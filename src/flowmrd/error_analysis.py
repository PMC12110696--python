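"""Event-level error monitoring and case-level MRD calling.

The human-in-the-loop workflow yields two label streams per specimen: the
automated classifier's event labels and the technologist-corrected labels.
This module binarizes them (clonal vs everything else), accumulates confusion
counts, applies the case-level calling rule (>= 20-event clonal cluster and
the LOD/LLOQ bands) and summarizes missed cases by phenotype for the
monitoring dashboard.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from flowmrd.synthcyto import CLONAL_CLASSES, NON_VIABLE_CLASSES, EventMatrix
from flowmrd.validation_stats import (
    ConfusionCounts,
    Metric,
    binary_concordance,
    deming_fit,
)

__all__ = [
    "MRDResult",
    "MonitoringRecord",
    "PHENOTYPE_FLAGS",
    "event_confusion",
    "case_call",
    "mrd_from_labels",
    "missed_case_report",
    "period_summary",
]

#: Phenotype-flag vocabulary for missed-case review.
PHENOTYPE_FLAGS = (
    "CD5-negative", "CD5-positive", "non-CLL", "CD20-moderate",
    "CD22-moderate", "CD43-neg/partial", "CD45-not-dim",
    "light-chain-moderate", "CD200-negative", "CLL",
)

#: Default case-calling constants: LOD and LLOQ in percent of analyzed
#: white cells, and the minimum clonal cluster size for positivity.
LOD_PCT = 0.001
LLOQ_PCT = 0.002
MIN_CLUSTER = 20


@dataclass(frozen=True)
class MRDResult:
    clonal_events: int
    denominator_events: int
    percentage: float
    call: str  # {"positive", "equivocal", "negative"}


@dataclass(frozen=True)
class MonitoringRecord:
    sample_id: str
    date: _date
    event_confusion: ConfusionCounts
    dnn_call: str
    corrected_call: str
    dnn_pct: float
    corrected_pct: float
    phenotype_flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        unknown = self.phenotype_flags - set(PHENOTYPE_FLAGS)
        if unknown:
            raise ValueError(f"unknown phenotype flags: {sorted(unknown)}")


def _binarize(labels: np.ndarray) -> np.ndarray:
    return np.isin(np.asarray(labels, dtype=object), list(CLONAL_CLASSES))


def event_confusion(auto_labels: Sequence[str],
                    corrected_labels: Sequence[str]
                    ) -> tuple[ConfusionCounts, dict[str, Metric | None]]:
    """Clonal-vs-rest confusion between classifier and corrected labels.

    The corrected stream is the reference: an event the classifier called
    clonal that review reassigned to any normal class is a false positive,
    and vice versa for false negatives.
    """
    auto = np.asarray(auto_labels, dtype=object)
    corr = np.asarray(corrected_labels, dtype=object)
    if auto.shape != corr.shape:
        raise ValueError("label streams differ in length")
    a, c = _binarize(auto), _binarize(corr)
    counts = ConfusionCounts(
        tp=int(np.sum(a & c)), fp=int(np.sum(a & ~c)),
        fn=int(np.sum(~a & c)), tn=int(np.sum(~a & ~c)))
    return counts, binary_concordance(counts)


def case_call(clonal_events: int, denominator_events: int,
              lod: float = LOD_PCT, lloq: float = LLOQ_PCT,
              min_cluster: int = MIN_CLUSTER) -> MRDResult:
    """Case-level MRD call from clonal and denominator event counts.

    Positive requires a cluster of at least ``min_cluster`` clonal events AND
    a percentage at or above the LLOQ; an unquantifiable signal (percentage
    in the LOD band, or a sub-cluster clonal population) is equivocal;
    anything else is negative. ``lod``/``lloq`` are percentages.
    """
    if denominator_events <= 0:
        raise ValueError("denominator must be positive")
    if clonal_events < 0:
        raise ValueError("clonal_events must be nonnegative")
    pct = 100.0 * clonal_events / denominator_events
    if clonal_events >= min_cluster and pct >= lloq:
        call = "positive"
    elif pct >= lod or clonal_events > 0:
        # unquantifiable signal: LOD band, sub-cluster population, or a
        # cluster diluted below the LOD by a very large denominator
        call = "equivocal"
    else:
        call = "negative"
    return MRDResult(clonal_events=clonal_events,
                     denominator_events=denominator_events,
                     percentage=pct, call=call)


def mrd_from_labels(labels: Sequence[str], **call_kwargs) -> MRDResult:
    """MRD result from an event label stream.

    The denominator is viable white cells: all events except debris and
    doublets. Clonal events are any of the clonal population classes.
    """
    lab = np.asarray(labels, dtype=object)
    viable = ~np.isin(lab, list(NON_VIABLE_CLASSES))
    clonal = int(_binarize(lab).sum())
    return case_call(clonal, int(viable.sum()), **call_kwargs)


def missed_case_report(records: Sequence[MonitoringRecord]) -> pd.DataFrame:
    """Tally cases the classifier-only pass missed, overall and by phenotype.

    A miss is a case whose corrected call is positive but whose
    classifier-only call is not. Percentages are of all monitored cases.
    """
    n_total = len(records)
    missed = [r for r in records
              if r.corrected_call == "positive" and r.dnn_call != "positive"]
    if not missed:
        return pd.DataFrame(columns=["category", "count", "pct_of_cases"])
    rows = [{"category": "missed-total", "count": len(missed),
             "pct_of_cases": round(100.0 * len(missed) / n_total, 1)}]
    for flag in PHENOTYPE_FLAGS:
        k = sum(flag in r.phenotype_flags for r in missed)
        if k:
            rows.append({"category": flag, "count": k,
                         "pct_of_cases": round(100.0 * k / n_total, 1)})
    return pd.DataFrame(rows)


def period_summary(records: Sequence[MonitoringRecord],
                   deming_lambda: float = 1.0) -> dict:
    """Pooled event metrics plus a case-level method comparison for a period.

    Pools confusion counts over all records, computes the five monitoring
    metrics (accuracy, sensitivity, specificity, PPV, NPV), and fits a
    Deming line of classifier-only percentages on corrected percentages
    when enough distinct case pairs exist.
    """
    if not records:
        raise ValueError("no records")
    pooled = ConfusionCounts(0, 0, 0, 0)
    for r in records:
        pooled = pooled + r.event_confusion
    metrics = binary_concordance(pooled)
    out = {
        "n_cases": len(records),
        "pooled_confusion": {"tp": pooled.tp, "fp": pooled.fp,
                             "fn": pooled.fn, "tn": pooled.tn},
        "event_metrics": {
            name: (None if m is None else
                   {"percent": m.percent, "ci_low": 100 * m.ci_low,
                    "ci_high": 100 * m.ci_high,
                    "numerator": m.numerator, "denominator": m.denominator})
            for name, m in metrics.items()},
        "missed_cases": missed_case_report(records).to_dict("records"),
    }
    x = np.array([r.corrected_pct for r in records])
    y = np.array([r.dnn_pct for r in records])
    try:
        fit = deming_fit(x, y, lam=deming_lambda)
        out["case_comparison"] = {"slope": fit.slope,
                                  "intercept": fit.intercept,
                                  "r": fit.r, "n": fit.n}
    except ValueError:
        out["case_comparison"] = None
    return out
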