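"""Synthetic 10-color cytometry simulator.

Generates event-level fluorescence data with the population structure a CLL
MRD panel sees: normal B cells (kappa / lambda polytypic), T cells,
hematogones, other white cells, debris and doublets, plus clonal B-cell
populations at configurable burden and phenotype (classic CLL, MCL-like,
CD5-negative, atypical). Intensities are drawn from a multivariate Gaussian
on the asinh scale per population and back-transformed to raw uncompensated
intensities, the standard noise shape for cytometry data.

Also provides the error models downstream modules consume (classifier label
flips, rater sensitivity/specificity draws), the crossed study-design
enumerators for precision/LLOQ studies, and minimal FCS 3.1 + CSV I/O.
"""

from __future__ import annotations

import csv
import struct
import warnings
from dataclasses import dataclass, field, replace
from datetime import date as _date
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FLUORO_CHANNELS",
    "SCATTER_CHANNELS",
    "CLONAL_CLASSES",
    "ChannelPanel",
    "PopulationTemplate",
    "SampleSpec",
    "EventMatrix",
    "RaterTable",
    "StudyDesign",
    "FCSParseError",
    "default_panel",
    "default_templates",
    "generate_sample",
    "generate_design",
    "simulate_classifier_labels",
    "simulate_rater_calls",
    "write_fcs",
    "read_fcs",
    "write_csv",
    "read_csv",
]

#: The 10 fluorescence channels of the single-tube CLL MRD panel.
FLUORO_CHANNELS = (
    "CD5", "CD19", "CD20", "CD22", "CD38",
    "CD43", "CD45", "CD200", "Kappa", "Lambda",
)
SCATTER_CHANNELS = ("FSC", "SSC")

#: Population classes treated as clonal (neoplastic) by downstream modules.
CLONAL_CLASSES = frozenset(
    {"clonal-CLL", "clonal-MCL-like", "clonal-CD5neg", "clonal-atypical"}
)

#: Classes excluded from the viable-WBC denominator when computing MRD %.
NON_VIABLE_CLASSES = frozenset({"debris", "doublet"})

#: asinh cofactor used to back-transform template intensities to raw scale.
ASINH_COFACTOR = 150.0


@dataclass(frozen=True)
class ChannelPanel:
    """Ordered acquisition channels: scatter plus fluorescence, arbitrary units."""

    names: tuple[str, ...] = SCATTER_CHANNELS + FLUORO_CHANNELS

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("channel names must be unique")

    @property
    def n_channels(self) -> int:
        return len(self.names)


def default_panel() -> ChannelPanel:
    return ChannelPanel()


@dataclass(frozen=True)
class PopulationTemplate:
    """Per-population intensity model on the asinh scale.

    ``location``/``spread`` give the per-channel center and dispersion;
    ``correlation`` is a single exchangeable channel–channel correlation,
    enough structure for PCA-based drift scoring to see multivariate shape.
    """

    name: str
    location: Mapping[str, float]
    spread: Mapping[str, float]
    correlation: float = 0.1

    def __post_init__(self) -> None:
        missing = [c for c in self.location if c not in self.spread]
        if missing:
            raise ValueError(f"spread missing for channels {missing}")
        if any(s <= 0 for s in self.spread.values()):
            raise ValueError("spreads must be positive")
        if not -0.2 <= self.correlation < 1:
            raise ValueError("correlation must be in [-0.2, 1)")

    def mean_vector(self, panel: ChannelPanel) -> np.ndarray:
        return np.array([self.location[c] for c in panel.names])

    def cov_matrix(self, panel: ChannelPanel) -> np.ndarray:
        s = np.array([self.spread[c] for c in panel.names])
        p = len(s)
        corr = np.full((p, p), self.correlation)
        np.fill_diagonal(corr, 1.0)
        return corr * np.outer(s, s)


def _tmpl(name: str, corr: float = 0.1, base_spread: float = 0.35,
          **levels: float) -> PopulationTemplate:
    panel = default_panel()
    loc = {c: levels.get(c, 0.5) for c in panel.names}
    spread = {c: base_spread for c in panel.names}
    return PopulationTemplate(name=name, location=loc, spread=spread,
                              correlation=corr)


# Intensity vocabulary (asinh units): negative ~0.5, dim ~2.0, moderate ~3.2,
# positive/bright ~4.2-4.8. Relative contrasts encode the phenotype axes that
# distinguish classic CLL (dim CD20/CD22, CD43+, CD200+, dim restricted light
# chain) from atypical / MCL-like / CD5-negative clones (moderate CD20/CD22,
# CD43 negative-or-partial, CD200 negative, moderate light chain). Absolute
# scales are arbitrary: no public reference intensities exist for this panel.
def default_templates() -> dict[str, PopulationTemplate]:
    t = [
        _tmpl("B-kappa", FSC=4.0, SSC=2.5, CD19=4.0, CD20=4.5, CD22=4.2,
              CD38=1.5, CD43=0.6, CD45=4.8, CD200=0.8, Kappa=4.2, Lambda=0.5),
        _tmpl("B-lambda", FSC=4.0, SSC=2.5, CD19=4.0, CD20=4.5, CD22=4.2,
              CD38=1.5, CD43=0.6, CD45=4.8, CD200=0.8, Kappa=0.5, Lambda=4.2),
        _tmpl("clonal-CLL", FSC=3.8, SSC=2.4, CD5=4.2, CD19=3.8, CD20=2.0,
              CD22=1.8, CD38=2.0, CD43=3.8, CD45=3.8, CD200=4.0,
              Kappa=2.0, Lambda=0.5),
        _tmpl("clonal-MCL-like", FSC=4.0, SSC=2.5, CD5=4.0, CD19=4.0,
              CD20=4.5, CD22=4.0, CD38=2.5, CD43=3.5, CD45=4.5, CD200=0.7,
              Kappa=0.5, Lambda=3.5),
        _tmpl("clonal-CD5neg", FSC=4.0, SSC=2.5, CD19=4.0, CD20=3.2,
              CD22=3.2, CD38=2.0, CD43=1.0, CD45=4.5, CD200=1.0,
              Kappa=3.2, Lambda=0.5),
        _tmpl("clonal-atypical", FSC=4.0, SSC=2.5, CD5=3.8, CD19=4.0,
              CD20=3.2, CD22=3.2, CD38=2.2, CD43=1.5, CD45=4.5, CD200=0.8,
              Kappa=3.2, Lambda=0.5),
        _tmpl("T", FSC=4.0, SSC=2.3, CD5=4.8, CD43=4.2, CD38=1.8,
              CD45=5.0, CD200=1.5),
        _tmpl("hematogone", FSC=3.5, SSC=2.0, CD19=4.2, CD20=2.2, CD22=3.0,
              CD38=5.0, CD43=1.2, CD45=3.2, CD200=2.5, Kappa=1.2, Lambda=1.2),
        _tmpl("other-WBC", FSC=4.5, SSC=4.5, CD38=2.5, CD43=3.0, CD45=4.5,
              Kappa=0.8, Lambda=0.8, CD22=0.8),
        _tmpl("debris", base_spread=0.6, FSC=1.0, SSC=1.0, CD45=1.0),
    ]
    return {x.name: x for x in t}


@dataclass(frozen=True)
class SampleSpec:
    """Recipe for one synthetic specimen acquisition."""

    sample_id: str
    specimen_type: str = "PB"  # {"BM", "PB"}
    n_events: int = 100_000
    mrd_fraction: float = 0.0
    clone_template: str = "clonal-CLL"
    acquisition_date: _date = _date(2024, 5, 1)
    instrument_id: str = "cytometer-1"
    operator_id: str = "op-1"
    seed: int = 0
    debris_fraction: float = 0.03
    doublet_fraction: float = 0.02

    def __post_init__(self) -> None:
        if self.specimen_type not in ("BM", "PB"):
            raise ValueError("specimen_type must be 'BM' or 'PB'")
        if self.n_events <= 0:
            raise ValueError("n_events must be positive")
        if not 0 <= self.mrd_fraction <= 1:
            raise ValueError("mrd_fraction must be in [0, 1]")
        total = self.mrd_fraction + self.debris_fraction + self.doublet_fraction
        if total > 1:
            raise ValueError("clone + debris + doublet fractions exceed 1")


@dataclass
class EventMatrix:
    """Per-event channel intensities and population labels for one specimen."""

    values: np.ndarray  # n_events x n_channels, raw intensities
    channels: tuple[str, ...]
    labels: np.ndarray  # n_events, population class strings
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.channels):
            raise ValueError("channel count mismatch")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("labels length must equal event count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite intensities")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.channels))
        df["label"] = self.labels
        return df


# Baseline cellular composition of the non-clonal, non-debris compartment.
# Bone marrows carry hematogones; peripheral bloods essentially do not.
_NORMAL_MIX = {
    "BM": {"T": 0.50, "B-kappa": 0.06, "B-lambda": 0.04,
           "hematogone": 0.04, "other-WBC": 0.36},
    "PB": {"T": 0.55, "B-kappa": 0.07, "B-lambda": 0.05,
           "hematogone": 0.002, "other-WBC": 0.328},
}


def _class_fractions(spec: SampleSpec) -> dict[str, float]:
    rest = 1.0 - spec.mrd_fraction - spec.debris_fraction - spec.doublet_fraction
    mix = _NORMAL_MIX[spec.specimen_type]
    frac = {name: rest * w for name, w in mix.items()}
    frac[spec.clone_template] = spec.mrd_fraction
    frac["debris"] = spec.debris_fraction
    frac["doublet"] = spec.doublet_fraction
    return frac


def _draw_population(rng: np.random.Generator, tmpl: PopulationTemplate,
                     panel: ChannelPanel, n: int) -> np.ndarray:
    mu = tmpl.mean_vector(panel)
    cov = tmpl.cov_matrix(panel)
    asinh_vals = rng.multivariate_normal(mu, cov, size=n,
                                         method="cholesky")
    return np.sinh(asinh_vals) * ASINH_COFACTOR


def generate_sample(
    spec: SampleSpec,
    templates: Mapping[str, PopulationTemplate] | None = None,
    panel: ChannelPanel | None = None,
) -> EventMatrix:
    """Draw one synthetic specimen.

    Event counts per population follow a multinomial draw with the fractions
    implied by ``spec``; intensities come from each template's Gaussian on the
    asinh scale, back-transformed to raw units. Doublets are sums of two
    random singlet events. Deterministic given ``spec.seed``.
    """
    panel = panel or default_panel()
    templates = dict(templates) if templates is not None else default_templates()
    fractions = _class_fractions(spec)
    needed = [c for c in fractions if c not in templates and c != "doublet"]
    if needed:
        raise KeyError(f"no template for population class(es): {needed}")

    classes = sorted(fractions)
    probs = np.array([fractions[c] for c in classes])
    probs = probs / probs.sum()
    rng = np.random.default_rng(spec.seed)
    counts = rng.multinomial(spec.n_events, probs)

    blocks: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    singlet_pool = ["T", "B-kappa", "B-lambda", "other-WBC"]
    for cls, n in zip(classes, counts):
        if n == 0:
            continue
        if cls == "doublet":
            # two singlets coincident in the laser: raw intensities add
            parts = rng.choice(singlet_pool, size=2 * n)
            vals = np.zeros((n, panel.n_channels))
            for pcls in singlet_pool:
                for half in (parts[:n], parts[n:]):
                    m = half == pcls
                    if m.any():
                        vals[m] += _draw_population(rng, templates[pcls],
                                                    panel, int(m.sum()))
        else:
            vals = _draw_population(rng, templates[cls], panel, int(n))
        blocks.append(vals)
        labels.append(np.full(n, cls, dtype=object))

    values = np.vstack(blocks) if blocks else np.empty((0, panel.n_channels))
    lab = np.concatenate(labels) if labels else np.empty(0, dtype=object)
    order = rng.permutation(len(lab))
    return EventMatrix(values=values[order], channels=panel.names,
                       labels=lab[order], sample_id=spec.sample_id)


# ---------------------------------------------------------------------------
# study designs


@dataclass
class StudyDesign:
    """Fully crossed study design: physical files plus analysis tasks."""

    kind: str
    specs: list[SampleSpec]
    tasks: pd.DataFrame

    @property
    def n_files(self) -> int:
        return len(self.specs)

    @property
    def n_tasks(self) -> int:
        return len(self.tasks)

    def replicates_per_sample(self) -> int:
        counts = self.tasks.groupby("sample_id").size()
        if counts.nunique() != 1:
            raise ValueError("unbalanced design")
        return int(counts.iloc[0])


def _check_levels(**levels: int) -> None:
    for name, v in levels.items():
        if v < 1:
            raise ValueError(f"factor {name!r} must have at least 1 level")


def generate_design(kind: str, **params) -> StudyDesign:
    """Enumerate a crossed validation-study design.

    ``quantitative_precision``: samples assayed in replicate on multiple
    instruments, each acquisition analyzed by every operator (default
    6 samples x 3 replicates x 2 instruments, 2 operators -> 36 files,
    72 analyses, 12 replicates per sample).

    ``qualitative_precision``: blinded replicate files each read by every
    rater (default 14 samples x 4 replicates, 4 raters -> 56 files,
    224 analyses).

    ``lloq``: dilution series per sample at target MRD percentages with
    per-level replicate counts (defaults 0.02% x1, 0.002% x3, 0.001% x3).
    """
    base = params.pop("base_spec", SampleSpec(sample_id="template"))
    seed0 = params.pop("seed", 0)

    if kind == "quantitative_precision":
        n_samples = params.pop("n_samples", 6)
        n_replicates = params.pop("n_replicates", 3)
        n_instruments = params.pop("n_instruments", 2)
        n_operators = params.pop("n_operators", 2)
        _check_levels(samples=n_samples, replicates=n_replicates,
                      instruments=n_instruments, operators=n_operators)
        specs, rows = [], []
        for s, r, i in product(range(n_samples), range(n_replicates),
                               range(n_instruments)):
            sid = f"Q{s + 1}"
            fid = f"{sid}_rep{r + 1}_inst{i + 1}"
            specs.append(replace(base, sample_id=fid,
                                 instrument_id=f"inst-{i + 1}",
                                 seed=seed0 + len(specs)))
            for o in range(n_operators):
                rows.append({"sample_id": sid, "file_id": fid,
                             "replicate": r + 1, "instrument": f"inst-{i + 1}",
                             "operator": f"op-{o + 1}"})
        return StudyDesign(kind, specs, pd.DataFrame(rows))

    if kind == "qualitative_precision":
        n_samples = params.pop("n_samples", 14)
        n_replicates = params.pop("n_replicates", 4)
        n_raters = params.pop("n_raters", 4)
        _check_levels(samples=n_samples, replicates=n_replicates,
                      raters=n_raters)
        specs, rows = [], []
        for s, r in product(range(n_samples), range(n_replicates)):
            sid = f"S{s + 1}"
            fid = f"{sid}_rep{r + 1}"
            specs.append(replace(base, sample_id=fid,
                                 seed=seed0 + len(specs)))
            for t in range(n_raters):
                rows.append({"sample_id": sid, "file_id": fid,
                             "replicate": r + 1, "rater": f"rater-{t + 1}"})
        return StudyDesign(kind, specs, pd.DataFrame(rows))

    if kind == "lloq":
        n_samples = params.pop("n_samples", 3)
        levels = params.pop("levels",
                            ((0.02, 1), (0.002, 3), (0.001, 3)))
        _check_levels(samples=n_samples)
        for _, reps in levels:
            _check_levels(replicates=reps)
        specs, rows = [], []
        for s in range(n_samples):
            sid = f"L{s + 1}"
            for pct, reps in levels:
                for r in range(reps):
                    fid = f"{sid}_{pct}pct_rep{r + 1}"
                    specs.append(replace(base, sample_id=fid,
                                         mrd_fraction=pct / 100.0,
                                         seed=seed0 + len(specs)))
                    rows.append({"sample_id": sid, "file_id": fid,
                                 "target_pct": pct, "replicate": r + 1})
        return StudyDesign(kind, specs, pd.DataFrame(rows))

    raise ValueError(f"unknown design kind {kind!r}")


# ---------------------------------------------------------------------------
# error models


def simulate_classifier_labels(
    matrix: EventMatrix,
    error_model: Mapping[str, Mapping[str, object]],
    seed: int,
) -> np.ndarray:
    """Corrupt the true labels with class-conditional flips.

    ``error_model`` maps a true class to ``{"rate": p, "to": target_class}``;
    each event of that class is independently relabeled with probability
    ``p``. Emulates an imperfect automated classifier whose miss rate may
    depend on phenotype (e.g. CD5-negative clones missed more often).
    """
    rng = np.random.default_rng(seed)
    out = matrix.labels.copy()
    for cls, model in error_model.items():
        rate = float(model["rate"])
        if not 0 <= rate <= 1:
            raise ValueError(f"rate for {cls!r} outside [0, 1]")
        target = str(model["to"])
        idx = np.flatnonzero(matrix.labels == cls)
        if idx.size:
            flip = rng.random(idx.size) < rate
            out[idx[flip]] = target
    return out


@dataclass
class RaterTable:
    """Binary calls indexed sample x replicate x rater, plus per-sample truth."""

    calls: np.ndarray  # bool, shape (n_samples, n_replicates, n_raters)
    truth: np.ndarray  # bool, shape (n_samples,)
    raters: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=bool)
        self.truth = np.asarray(self.truth, dtype=bool)
        if self.calls.ndim != 3:
            raise ValueError("calls must be sample x replicate x rater")
        if self.calls.shape[0] != len(self.truth):
            raise ValueError("truth length mismatch")
        if not self.raters:
            self.raters = tuple(f"rater-{i + 1}"
                                for i in range(self.calls.shape[2]))

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.calls.shape))

    def to_dataframe(self) -> pd.DataFrame:
        s, m, r = self.calls.shape
        rows = [{"sample_id": f"S{i + 1}", "replicate": j + 1,
                 "rater": self.raters[k], "call": bool(self.calls[i, j, k]),
                 "truth": bool(self.truth[i])}
                for i in range(s) for j in range(m) for k in range(r)]
        return pd.DataFrame(rows)


def simulate_rater_calls(
    truth: Sequence[bool],
    rater_profiles: Sequence[tuple[float, float]],
    replicates: int,
    seed: int,
) -> RaterTable:
    """Draw independent binary calls per (sample, replicate, rater).

    Each rater is a (sensitivity, specificity) pair: the probability of a
    correct call on a true-positive / true-negative sample respectively.
    """
    truth = np.asarray(truth, dtype=bool)
    for sens, spec_ in rater_profiles:
        if not (0 <= sens <= 1 and 0 <= spec_ <= 1):
            raise ValueError("sensitivity/specificity must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_s, n_r = len(truth), len(rater_profiles)
    calls = np.zeros((n_s, replicates, n_r), dtype=bool)
    for k, (sens, spec_) in enumerate(rater_profiles):
        p_call_pos = np.where(truth, sens, 1.0 - spec_)
        u = rng.random((n_s, replicates))
        calls[:, :, k] = u < p_call_pos[:, None]
    return RaterTable(calls=calls, truth=truth)


# ---------------------------------------------------------------------------
# FCS 3.1 and CSV I/O


class FCSParseError(ValueError):
    """Raised on a malformed FCS file; message carries the byte offset."""


_HEADER_LEN = 58


def write_fcs(matrix: EventMatrix, path: str | Path,
              write_labels: bool = True) -> Path:
    """Write a minimal FCS 3.1 file (float32 little-endian, list mode).

    Population labels go to a ``<stem>.labels.csv`` sidecar since the FCS
    standard has no label field.
    """
    path = Path(path)
    data = np.asarray(matrix.values, dtype="<f4").tobytes()
    n_events, n_par = matrix.values.shape

    def text_segment(begin_data: int, end_data: int) -> bytes:
        kw = [
            ("$BEGINANALYSIS", "0"), ("$ENDANALYSIS", "0"),
            ("$BEGINSTEXT", "0"), ("$ENDSTEXT", "0"),
            ("$BEGINDATA", f"{begin_data:>8d}"),
            ("$ENDDATA", f"{end_data:>8d}"),
            ("$BYTEORD", "1,2,3,4"), ("$DATATYPE", "F"), ("$MODE", "L"),
            ("$NEXTDATA", "0"),
            ("$PAR", str(n_par)), ("$TOT", str(n_events)),
        ]
        for i, name in enumerate(matrix.channels, start=1):
            kw += [(f"$P{i}N", name), (f"$P{i}B", "32"),
                   (f"$P{i}E", "0,0"), (f"$P{i}R", "262144")]
        body = "/" + "/".join(f"{k}/{v}" for k, v in kw) + "/"
        return body.encode("ascii")

    # TEXT length is stable because $BEGINDATA/$ENDDATA are fixed-width
    text = text_segment(0, 0)
    text_start = _HEADER_LEN
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + len(data) - 1
    text = text_segment(data_start, data_end)

    header = (
        b"FCS3.1    "
        + f"{text_start:>8d}{text_end:>8d}".encode()
        + f"{data_start:>8d}{data_end:>8d}".encode()
        + f"{0:>8d}{0:>8d}".encode()
    )
    assert len(header) == _HEADER_LEN
    path.write_bytes(header + text + data)
    if write_labels:
        _write_labels(matrix.labels, path.with_suffix(".labels.csv"))
    return path


def _write_labels(labels: np.ndarray, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label"])
        for lab in labels:
            w.writerow([lab])


def _read_labels(path: Path) -> np.ndarray:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    return np.array([r[0] for r in rows[1:]], dtype=object)


def read_fcs(path: str | Path, sample_id: str | None = None) -> EventMatrix:
    """Read a minimal FCS 3.1 file written by :func:`write_fcs`.

    Validates $TOT/$PAR against the DATA segment length and raises
    :class:`FCSParseError` with the offending byte offset on mismatch.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _HEADER_LEN or not raw[:6] == b"FCS3.1":
        raise FCSParseError("not an FCS 3.1 file (offset 0)")
    try:
        text_start = int(raw[10:18])
        text_end = int(raw[18:26])
        data_start = int(raw[26:34])
        data_end = int(raw[34:42])
    except ValueError as exc:
        raise FCSParseError(f"bad header offsets (offset 10): {exc}") from exc

    seg = raw[text_start:text_end + 1].decode("ascii", errors="replace")
    if not seg:
        raise FCSParseError(f"empty TEXT segment (offset {text_start})")
    delim = seg[0]
    parts = seg.strip(delim).split(delim)
    if len(parts) % 2:
        raise FCSParseError(
            f"odd keyword/value count in TEXT segment (offset {text_start})")
    kw = {parts[i].strip(): parts[i + 1].strip()
          for i in range(0, len(parts), 2)}

    try:
        n_par = int(kw["$PAR"])
        n_tot = int(kw["$TOT"])
    except (KeyError, ValueError) as exc:
        raise FCSParseError(
            f"missing or bad $PAR/$TOT (offset {text_start}): {exc}") from exc
    if kw.get("$DATATYPE") != "F":
        raise FCSParseError("only $DATATYPE=F supported")
    if kw.get("$BYTEORD") not in ("1,2,3,4",):
        raise FCSParseError("only little-endian $BYTEORD=1,2,3,4 supported")

    data = raw[data_start:data_end + 1]
    expect = n_tot * n_par * 4
    if len(data) != expect:
        raise FCSParseError(
            f"$TOT*$PAR*4 = {expect} bytes but DATA segment has "
            f"{len(data)} (offset {data_start})")
    values = np.frombuffer(data, dtype="<f4").reshape(n_tot, n_par)
    channels = tuple(kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1))

    label_path = path.with_suffix(".labels.csv")
    if label_path.exists():
        labels = _read_labels(label_path)
        if len(labels) != n_tot:
            raise FCSParseError("label sidecar length mismatch")
    else:
        labels = np.full(n_tot, "unlabeled", dtype=object)
    return EventMatrix(values=np.asarray(values, dtype=float),
                       channels=channels, labels=labels,
                       sample_id=sample_id or path.stem)


def write_csv(matrix: EventMatrix, path: str | Path) -> Path:
    """Bit-exact CSV export: header of channel names, one event per row."""
    path = Path(path)
    df = pd.DataFrame(matrix.values, columns=list(matrix.channels))
    # shortest round-trip repr keeps the export bit-exact on re-import
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))
    _write_labels(matrix.labels, path.with_suffix(".labels.csv"))
    return path


def read_csv(path: str | Path, sample_id: str | None = None) -> EventMatrix:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    label_path = path.with_suffix(".labels.csv")
    labels = (_read_labels(label_path) if label_path.exists()
              else np.full(len(df), "unlabeled", dtype=object))
    return EventMatrix(values=df.to_numpy(dtype=float),
                       channels=tuple(df.columns), labels=labels,
                       sample_id=sample_id or path.stem)
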