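"""Input-drift and out-of-distribution detection by PCA reconstruction error.

A reference cohort defines a preparation pipeline (median imputation,
frequency encoding of declared categorical metadata, standardization) and a
PCA basis retaining a target fraction of variance (default 65%). New samples
are scored by the mean Euclidean distance between their prepared events and
the inverse-PCA reconstruction; scores outside the reference mean ± 3 SD
raise an alert, and a formal drift event requires five or more same-day
alerts all in the same direction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from datetime import date as _date
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from flowmrd.synthcyto import EventMatrix

__all__ = [
    "DriftModel",
    "DriftScore",
    "DriftEvent",
    "fit_reference",
    "score_sample",
    "detect_daily_drift",
    "alert_rate",
    "scores_to_dataframe",
]

_SD_MULTIPLIER = 3.0


@dataclass
class DriftModel:
    """Preparation parameters, PCA basis and reference error distribution."""

    feature_names: tuple[str, ...]
    impute_values: np.ndarray          # per numeric feature (training median)
    freq_maps: dict[str, dict[str, float]]  # categorical feature -> level freq
    standardize_mean: np.ndarray
    standardize_sd: np.ndarray
    components: np.ndarray             # k x n_features, orthonormal rows
    k: int
    explained_fraction: float
    ref_error_mean: float
    ref_error_sd: float
    upper_threshold: float
    lower_threshold: float
    variance_target: float = 0.65
    n_sub: int = 10_000
    version: str = "1"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        gram = self.components @ self.components.T
        if not np.allclose(gram, np.eye(self.k), atol=1e-8):
            raise ValueError("PCA loadings are not orthonormal")

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "version": self.version,
            "feature_names": list(self.feature_names),
            "impute_values": self.impute_values.tolist(),
            "freq_maps": self.freq_maps,
            "standardize_mean": self.standardize_mean.tolist(),
            "standardize_sd": self.standardize_sd.tolist(),
            "components": self.components.tolist(),
            "k": self.k,
            "explained_fraction": self.explained_fraction,
            "ref_error_mean": self.ref_error_mean,
            "ref_error_sd": self.ref_error_sd,
            "upper_threshold": self.upper_threshold,
            "lower_threshold": self.lower_threshold,
            "variance_target": self.variance_target,
            "n_sub": self.n_sub,
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "DriftModel":
        d = json.loads(Path(path).read_text())
        return cls(
            feature_names=tuple(d["feature_names"]),
            impute_values=np.array(d["impute_values"]),
            freq_maps={k: dict(v) for k, v in d["freq_maps"].items()},
            standardize_mean=np.array(d["standardize_mean"]),
            standardize_sd=np.array(d["standardize_sd"]),
            components=np.array(d["components"]),
            k=int(d["k"]),
            explained_fraction=float(d["explained_fraction"]),
            ref_error_mean=float(d["ref_error_mean"]),
            ref_error_sd=float(d["ref_error_sd"]),
            upper_threshold=float(d["upper_threshold"]),
            lower_threshold=float(d["lower_threshold"]),
            variance_target=float(d["variance_target"]),
            n_sub=int(d["n_sub"]),
            version=str(d["version"]),
        )


@dataclass(frozen=True)
class DriftScore:
    sample_id: str
    date: _date
    error: float
    alert: bool
    direction: str  # {"above", "below", "none"}


@dataclass(frozen=True)
class DriftEvent:
    date: _date
    n_deviating: int
    direction: str  # {"above", "below"}


def _choose_k(explained_ratios: np.ndarray, target: float) -> int:
    """Smallest component count whose cumulative explained variance >= target."""
    cum = np.cumsum(explained_ratios)
    idx = np.searchsorted(cum, target - 1e-12)
    return int(min(idx, len(explained_ratios) - 1)) + 1


def _subsample(values: np.ndarray, n_sub: int,
               rng: np.random.Generator) -> np.ndarray:
    n = values.shape[0]
    if n <= n_sub:
        return values
    idx = rng.choice(n, size=n_sub, replace=False)
    return values[idx]


def _encode(matrix: EventMatrix, model_features: Sequence[str] | None,
            freq_maps: Mapping[str, Mapping[str, float]],
            metadata: Mapping[str, str] | None) -> tuple[np.ndarray, list[str]]:
    """Numeric channel block plus frequency-encoded categorical columns."""
    cols = list(matrix.channels)
    blocks = [matrix.values]
    names = cols[:]
    metadata = metadata or {}
    for feat, fmap in freq_maps.items():
        level = metadata.get(feat)
        if level is None or level not in fmap:
            if level is not None:
                warnings.warn(
                    f"unseen level {level!r} for categorical feature "
                    f"{feat!r}; encoded as frequency 0")
            val = 0.0 if level is not None else np.nan
        else:
            val = fmap[level]
        blocks.append(np.full((matrix.n_events, 1), val))
        names.append(feat)
    X = np.hstack(blocks)
    if model_features is not None:
        if list(names) != list(model_features):
            lookup = {n: i for i, n in enumerate(names)}
            try:
                X = X[:, [lookup[f] for f in model_features]]
            except KeyError as exc:
                raise ValueError(f"sample lacks model feature {exc}") from exc
            names = list(model_features)
    return X, names


def _prepare(X: np.ndarray, impute: np.ndarray, mean: np.ndarray,
             sd: np.ndarray) -> np.ndarray:
    X = np.where(np.isfinite(X), X, impute)
    return (X - mean) / sd


def _per_event_errors(Z: np.ndarray, components: np.ndarray) -> np.ndarray:
    scores = Z @ components.T
    recon = scores @ components
    return np.linalg.norm(Z - recon, axis=1)


def fit_reference(
    reference_samples: Sequence[EventMatrix],
    variance_target: float = 0.65,
    n_sub: int = 10_000,
    seed: int = 0,
    categorical_metadata: Mapping[str, Mapping[str, str]] | None = None,
) -> DriftModel:
    """Fit preparation parameters, PCA basis and reference error thresholds.

    One ``n_sub``-event subsample is drawn per reference sample; the pooled
    subsamples define medians (imputation), level frequencies (categorical
    encoding), standardization and the PCA basis. The per-sample errors of
    the reference subsamples, scored exactly as :func:`score_sample` scores
    new data, set the thresholds at mean ± 3 SD.

    ``categorical_metadata`` maps sample_id -> {feature: level} for declared
    categorical metadata features (e.g. specimen type, instrument).
    """
    if len(reference_samples) < 2:
        raise ValueError("need at least 2 reference samples")
    if not 0 < variance_target <= 1:
        raise ValueError("variance_target must be in (0, 1]")

    rng = np.random.default_rng(seed)
    cat_features: list[str] = []
    if categorical_metadata:
        cat_features = sorted({f for m in categorical_metadata.values()
                               for f in m})

    subs, metas = [], []
    for m in reference_samples:
        meta = (categorical_metadata or {}).get(m.sample_id, {})
        metas.append(meta)
        subs.append(_subsample(m.values, n_sub, rng))

    # level frequencies over training samples (one observation per sample)
    freq_maps: dict[str, dict[str, float]] = {}
    for feat in cat_features:
        levels = [meta.get(feat) for meta in metas if feat in meta]
        counts = pd.Series(levels).value_counts(normalize=True)
        freq_maps[feat] = {str(k): float(v) for k, v in counts.items()}

    blocks = []
    for m, sub, meta in zip(reference_samples, subs, metas):
        sub_matrix = EventMatrix(values=sub, channels=m.channels,
                                 labels=np.full(len(sub), "x", dtype=object),
                                 sample_id=m.sample_id)
        X, names = _encode(sub_matrix, None, freq_maps, meta)
        blocks.append(X)
    X_all = np.vstack(blocks)
    if X_all.shape[0] <= X_all.shape[1]:
        raise ValueError("pooled event count must exceed feature count")

    impute = np.nanmedian(X_all, axis=0)
    X_all = np.where(np.isfinite(X_all), X_all, impute)
    mean = X_all.mean(axis=0)
    sd = X_all.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"dropping constant feature(s): {dropped}")
        names = [n for n, k in zip(names, keep) if k]
        X_all, impute, mean, sd = (X_all[:, keep], impute[keep],
                                   mean[keep], sd[keep])
        blocks = [b[:, keep] for b in blocks]
        freq_maps = {f: v for f, v in freq_maps.items() if f in names}

    Z = (X_all - mean) / sd
    # PCA by SVD of the standardized pooled matrix; deterministic sign
    _, s, Vt = np.linalg.svd(Z, full_matrices=False)
    explained = s**2 / np.sum(s**2)
    k = _choose_k(explained, variance_target)
    comps = Vt[:k].copy()
    for row in comps:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1

    ref_errors = []
    for b in blocks:
        Zb = _prepare(b, impute, mean, sd)
        ref_errors.append(float(_per_event_errors(Zb, comps).mean()))
    ref_errors = np.array(ref_errors)
    mu, sigma = float(ref_errors.mean()), float(ref_errors.std(ddof=1))

    return DriftModel(
        feature_names=tuple(names),
        impute_values=impute,
        freq_maps=freq_maps,
        standardize_mean=mean,
        standardize_sd=sd,
        components=comps,
        k=k,
        explained_fraction=float(np.cumsum(explained)[k - 1]),
        ref_error_mean=mu,
        ref_error_sd=sigma,
        upper_threshold=mu + _SD_MULTIPLIER * sigma,
        lower_threshold=mu - _SD_MULTIPLIER * sigma,
        variance_target=variance_target,
        n_sub=n_sub,
    )


def score_sample(
    model: DriftModel,
    matrix: EventMatrix,
    n_sub: int | None = None,
    seed: int = 0,
    date: _date | None = None,
    metadata: Mapping[str, str] | None = None,
) -> DriftScore:
    """Reconstruction-error score for one sample against a fitted model.

    A without-replacement subsample of min(n_sub, n_events) events is
    prepared, projected onto the model's components and reconstructed; the
    score is the mean per-event Euclidean distance between prepared and
    reconstructed events.
    """
    if matrix.n_events == 0:
        raise ValueError("empty sample")
    n_sub = model.n_sub if n_sub is None else n_sub
    rng = np.random.default_rng(seed)
    sub = _subsample(matrix.values, n_sub, rng)
    sub_matrix = EventMatrix(values=sub, channels=matrix.channels,
                             labels=np.full(len(sub), "x", dtype=object),
                             sample_id=matrix.sample_id)
    X, _ = _encode(sub_matrix, model.feature_names, model.freq_maps, metadata)
    Z = _prepare(X, model.impute_values, model.standardize_mean,
                 model.standardize_sd)
    error = float(_per_event_errors(Z, model.components).mean())
    if error > model.upper_threshold:
        alert, direction = True, "above"
    elif error < model.lower_threshold:
        alert, direction = True, "below"
    else:
        alert, direction = False, "none"
    return DriftScore(sample_id=matrix.sample_id,
                      date=date or _date.today(),
                      error=error, alert=alert, direction=direction)


def detect_daily_drift(scores: Sequence[DriftScore],
                       min_count: int = 5) -> list[DriftEvent]:
    """Formal drift rule: >= ``min_count`` same-day alerts, all one direction."""
    events = []
    by_day: dict[_date, list[DriftScore]] = {}
    for s in scores:
        by_day.setdefault(s.date, []).append(s)
    for day in sorted(by_day):
        alerts = [s for s in by_day[day] if s.alert]
        if len(alerts) < min_count:
            continue
        directions = {s.direction for s in alerts}
        if len(directions) == 1:
            events.append(DriftEvent(date=day, n_deviating=len(alerts),
                                     direction=directions.pop()))
    return events


def alert_rate(scores: Sequence[DriftScore]) -> tuple[int, int, float]:
    """(n_alerts, n_total, percentage rounded to 2 decimals)."""
    if not scores:
        raise ValueError("no scores")
    n_alerts = sum(s.alert for s in scores)
    n_total = len(scores)
    return n_alerts, n_total, round(100.0 * n_alerts / n_total, 2)


def scores_to_dataframe(scores: Sequence[DriftScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"sample_id": s.sample_id, "date": s.date.isoformat(),
          "error": s.error, "alert": s.alert, "direction": s.direction}
         for s in scores])
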