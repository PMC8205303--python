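"""The enhanced semi-naive Bayes (NSB) forecaster.

The model is an AODE-style super-parent Bayes classifier over windows of
difference symbols. For a window x = (x_1, …, x_d) with d = L−1 attributes,
each class y (a candidate next difference) is scored as

    P(y | x) ∝ Σ_{i=1}^{d} P̂(y, x_i) Π_{j=1}^{d} P̂(x_j | y, x_i)

where every attribute position i in turn plays the super-parent and the
inner product deliberately runs over all j including j = i (the standard
AODE formulation excludes j = i; this model does not — see the methods
note). Probabilities are Laplace-smoothed count ratios:

    P̂(y, x_i)       = (|D_{y,x_i}| + 1) / (|D| + N · N_i)
    P̂(x_j | y, x_i) = (|D_{y,x_i,x_j}| + 1) / (|D_{y,x_i}| + N_j)

with N the number of retained classes and N_i = N_j = A, the global
training-alphabet size (all positions share the one symbol set). Because
the model is nothing but integer count tables, it supports exact
incremental updating: adding counts from new samples is identical to
refitting on the concatenated data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import logsumexp

from .series import LevelSeries, discretize, first_difference, reconstruct
from .windowing import DiffSample, EmptyModelError, SampleSet

__all__ = [
    "CountTables",
    "NsbModel",
    "ForecastResult",
    "fit",
    "update",
    "laplace_joint",
    "laplace_conditional",
    "score",
    "log_scores",
    "predict_next",
    "forecast_series",
    "save_model",
    "load_model",
]

MODEL_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class CountTables:
    """Integer count tables backing the smoothed probability estimates.

    ``pair_counts[(y, i, x_i)]`` is |D_{y,x_i}|, the number of training
    samples with label y and symbol x_i at (1-based) attribute position i;
    ``triple_counts[(y, i, x_i, j, x_j)]`` is |D_{y,x_i,x_j}|. ``n_classes``
    is N, ``alphabet_size`` is A = N_i = N_j.
    """

    total: int
    class_counts: dict[float, int]
    pair_counts: dict[tuple[float, int, float], int]
    triple_counts: dict[tuple[float, int, float, int, float], int]
    n_classes: int
    alphabet_size: int


@dataclass(frozen=True)
class NsbModel:
    tables: CountTables
    window_length: int
    gamma: float
    decimals: int
    classes: frozenset[float]
    alphabet: frozenset[float]

    @property
    def n_attributes(self) -> int:
        return self.window_length - 1


def _count(samples: tuple[DiffSample, ...]) -> tuple[dict, dict, dict]:
    class_counts: dict[float, int] = {}
    pair: dict[tuple, int] = {}
    triple: dict[tuple, int] = {}
    for s in samples:
        y = s.label
        class_counts[y] = class_counts.get(y, 0) + 1
        for i, x_i in enumerate(s.attributes, start=1):
            key = (y, i, x_i)
            pair[key] = pair.get(key, 0) + 1
            for j, x_j in enumerate(s.attributes, start=1):
                tkey = (y, i, x_i, j, x_j)
                triple[tkey] = triple.get(tkey, 0) + 1
    return class_counts, pair, triple


def fit(samples: SampleSet, gamma: float = 0.0, decimals: int = 2) -> NsbModel:
    """Build the count tables from a (γ-filtered) sample set in one pass."""
    if len(samples) == 0:
        raise EmptyModelError("cannot fit on an empty sample set")
    class_counts, pair, triple = _count(samples.samples)
    alphabet = frozenset(samples.alphabet)
    tables = CountTables(
        total=len(samples),
        class_counts=class_counts,
        pair_counts=pair,
        triple_counts=triple,
        n_classes=len(class_counts),
        alphabet_size=len(alphabet),
    )
    return NsbModel(
        tables=tables,
        window_length=samples.window_length,
        gamma=float(gamma),
        decimals=int(decimals),
        classes=frozenset(class_counts),
        alphabet=alphabet,
    )


def update(model: NsbModel, new_samples: SampleSet) -> NsbModel:
    """Add counts from new samples; exactly equivalent to refitting on the union.

    Symbols outside the stored alphabet extend it (A grows, so smoothed
    probabilities shift accordingly). The window length must match.
    """
    if len(new_samples) == 0:
        return model
    if new_samples.window_length != model.window_length:
        raise ValueError(
            f"window length mismatch: model has L={model.window_length}, "
            f"new samples have L={new_samples.window_length}"
        )
    new_class, new_pair, new_triple = _count(new_samples.samples)
    class_counts = dict(model.tables.class_counts)
    for k, v in new_class.items():
        class_counts[k] = class_counts.get(k, 0) + v
    pair = dict(model.tables.pair_counts)
    for k, v in new_pair.items():
        pair[k] = pair.get(k, 0) + v
    triple = dict(model.tables.triple_counts)
    for k, v in new_triple.items():
        triple[k] = triple.get(k, 0) + v
    alphabet = model.alphabet | frozenset(new_samples.alphabet)
    tables = CountTables(
        total=model.tables.total + len(new_samples),
        class_counts=class_counts,
        pair_counts=pair,
        triple_counts=triple,
        n_classes=len(class_counts),
        alphabet_size=len(alphabet),
    )
    return replace(model, tables=tables, classes=frozenset(class_counts), alphabet=alphabet)


def laplace_joint(tables: CountTables, y: float, i: int, x_i: float) -> float:
    """Smoothed joint P̂(y, x_i) = (|D_{y,x_i}| + 1) / (|D| + N·N_i)."""
    count = tables.pair_counts.get((y, i, x_i), 0)
    return (count + 1) / (tables.total + tables.n_classes * tables.alphabet_size)


def laplace_conditional(
    tables: CountTables, y: float, i: int, x_i: float, j: int, x_j: float
) -> float:
    """Smoothed conditional P̂(x_j | y, x_i) = (|D_{y,x_i,x_j}| + 1) / (|D_{y,x_i}| + N_j)."""
    tcount = tables.triple_counts.get((y, i, x_i, j, x_j), 0)
    pcount = tables.pair_counts.get((y, i, x_i), 0)
    return (tcount + 1) / (pcount + tables.alphabet_size)


def _check_window(model: NsbModel, window) -> tuple[float, ...]:
    window = tuple(float(x) for x in window)
    if len(window) != model.n_attributes:
        raise ValueError(
            f"window must have L-1 = {model.n_attributes} symbols, got {len(window)}"
        )
    return window


def log_scores(model: NsbModel, window) -> dict[float, float]:
    """Unnormalized log posterior scores, one per retained class.

    Each super-parent term's inner product is accumulated in the log
    domain and the d terms are combined with log-sum-exp, so long windows
    cannot underflow.
    """
    window = _check_window(model, window)
    tables = model.tables
    out: dict[float, float] = {}
    for y in model.classes:
        terms = []
        for i, x_i in enumerate(window, start=1):
            t = math.log(laplace_joint(tables, y, i, x_i))
            for j, x_j in enumerate(window, start=1):
                t += math.log(laplace_conditional(tables, y, i, x_i, j, x_j))
            terms.append(t)
        out[y] = float(logsumexp(terms))
    return out


def score(model: NsbModel, window) -> dict[float, float]:
    """Posterior scores normalized to sum to 1 over the retained classes.

    Window symbols outside the training alphabet are allowed: they have
    zero counts everywhere and receive only smoothing mass.
    """
    logs = log_scores(model, window)
    classes = list(logs)
    arr = np.array([logs[y] for y in classes])
    norm = np.exp(arr - logsumexp(arr))
    return {y: float(p) for y, p in zip(classes, norm)}


def predict_next(model: NsbModel, window) -> float:
    """Argmax class under :func:`score` with a deterministic tie-break.

    Ties are broken by (1) larger training frequency of the class,
    (2) smaller absolute symbol value, (3) smaller signed value.
    """
    if not model.classes:
        raise EmptyModelError("model has no retained classes")
    scores = score(model, window)
    counts = model.tables.class_counts
    return min(scores, key=lambda y: (-scores[y], -counts.get(y, 0), abs(y), y))


@dataclass(frozen=True)
class ForecastResult:
    """One-step-ahead walk-forward forecast over a held-out level series."""

    timestamps: np.ndarray  # time of each forecast TARGET
    observed: np.ndarray  # true level at the target time
    predicted_diff: np.ndarray
    predicted_level: np.ndarray
    posterior: np.ndarray  # normalized score of the chosen class

    def __len__(self) -> int:
        return len(self.predicted_level)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "timestamp": self.timestamps,
                "observed": self.observed,
                "predicted_diff": self.predicted_diff,
                "predicted_level": self.predicted_level,
                "posterior_score": self.posterior,
            }
        )


def forecast_series(model: NsbModel, test_levels: LevelSeries) -> ForecastResult:
    """Walk-forward one-step forecasting of a held-out level series.

    At each step the window holds the last L−1 *observed* differences
    (discretized with the model's precision); the predicted difference is
    added to the current observed level. Predictions are never fed back.
    """
    L = model.window_length
    if len(test_levels) < L + 1:
        raise ValueError(
            f"test series needs at least L+1 = {L + 1} points, got {len(test_levels)}"
        )
    symbols = discretize(first_difference(test_levels), model.decimals)
    n = len(symbols)
    d = model.n_attributes
    pred_diffs = np.empty(n - d)
    posteriors = np.empty(n - d)
    for t in range(d, n):
        window = symbols[t - d : t]
        scores = score(model, window)
        counts = model.tables.class_counts
        y = min(scores, key=lambda c: (-scores[c], -counts.get(c, 0), abs(c), c))
        pred_diffs[t - d] = y
        posteriors[t - d] = scores[y]
    current_levels = test_levels.values[d : n]
    return ForecastResult(
        timestamps=np.asarray(test_levels.timestamps)[L:],
        observed=test_levels.values[L:],
        predicted_diff=pred_diffs,
        predicted_level=reconstruct(pred_diffs, current_levels),
        posterior=posteriors,
    )


# ---------------------------------------------------------------------------
# persistence: JSON with integer counts and fixed-precision symbol strings


def _sym_str(value: float, decimals: int) -> str:
    s = format(float(value), f".{decimals}f")
    # one symbol for both signs of zero
    return format(0.0, f".{decimals}f") if float(s) == 0.0 else s


def model_to_dict(model: NsbModel) -> dict:
    d = model.decimals
    return {
        "version": MODEL_SCHEMA_VERSION,
        "L": model.window_length,
        "gamma": model.gamma,
        "decimals": d,
        "alphabet": sorted(_sym_str(s, d) for s in model.alphabet),
        "classes": sorted(_sym_str(s, d) for s in model.classes),
        "total": model.tables.total,
        "class_counts": {
            _sym_str(y, d): c for y, c in sorted(model.tables.class_counts.items())
        },
        "pair_counts": {
            f"{_sym_str(y, d)}|{i}|{_sym_str(x, d)}": c
            for (y, i, x), c in sorted(model.tables.pair_counts.items())
        },
        "triple_counts": {
            f"{_sym_str(y, d)}|{i}|{_sym_str(xi, d)}|{j}|{_sym_str(xj, d)}": c
            for (y, i, xi, j, xj), c in sorted(model.tables.triple_counts.items())
        },
    }


def model_from_dict(payload: dict) -> NsbModel:
    if payload.get("version") != MODEL_SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema version: {payload.get('version')!r}")
    class_counts = {float(k): int(v) for k, v in payload["class_counts"].items()}
    pair = {}
    for key, c in payload["pair_counts"].items():
        y, i, x = key.split("|")
        pair[(float(y), int(i), float(x))] = int(c)
    triple = {}
    for key, c in payload["triple_counts"].items():
        y, i, xi, j, xj = key.split("|")
        triple[(float(y), int(i), float(xi), int(j), float(xj))] = int(c)
    alphabet = frozenset(float(s) for s in payload["alphabet"])
    classes = frozenset(float(s) for s in payload["classes"])
    tables = CountTables(
        total=int(payload["total"]),
        class_counts=class_counts,
        pair_counts=pair,
        triple_counts=triple,
        n_classes=len(classes),
        alphabet_size=len(alphabet),
    )
    return NsbModel(
        tables=tables,
        window_length=int(payload["L"]),
        gamma=float(payload["gamma"]),
        decimals=int(payload["decimals"]),
        classes=classes,
        alphabet=alphabet,
    )


def save_model(model: NsbModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_model(path) -> NsbModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))
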