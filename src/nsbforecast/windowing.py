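"""Sliding-window sample construction and frequency-threshold filtering.

A window of length L over the symbol sequence yields one training sample:
the first L−1 symbols are the attributes, the last is the class label to
predict. The threshold γ drops samples whose label is rare, limiting the
influence of low-probability difference categories (sensor outliers)
without modifying the underlying data.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

__all__ = ["DiffSample", "SampleSet", "EmptyModelError", "build_samples", "filter_by_frequency"]


class EmptyModelError(ValueError):
    """Raised when no samples (or classes) remain to build a model from."""


@dataclass(frozen=True)
class DiffSample:
    """One sliding-window instance: L−1 attribute symbols and a class label."""

    attributes: tuple[float, ...]
    label: float


@dataclass(frozen=True)
class SampleSet:
    """An ordered collection of window samples with its symbol alphabet.

    ``alphabet`` is the full set of distinct symbols seen in the source
    sequence; ``class_counts`` are label frequencies over the current
    samples (recomputed after filtering, while the alphabet is kept whole
    so rare symbols remain usable as attributes).
    """

    samples: tuple[DiffSample, ...]
    alphabet: frozenset[float]
    window_length: int
    class_counts: dict[float, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.class_counts is None:
            counts = dict(Counter(s.label for s in self.samples))
            object.__setattr__(self, "class_counts", counts)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def classes(self) -> frozenset[float]:
        return frozenset(self.class_counts)


def build_samples(symbols, window_length: int) -> SampleSet:
    """Slide a stride-1 window of length L over the symbol sequence.

    Window t contributes attributes ``symbols[t : t+L−1]`` and label
    ``symbols[t+L−1]``; a sequence of Z symbols yields Z − L + 1 samples.
    """
    symbols = [float(s) for s in np.asarray(symbols, dtype=float)]
    L = int(window_length)
    if L < 2:
        raise ValueError(f"window length must be >= 2, got {L}")
    if len(symbols) < L:
        raise ValueError(
            f"need at least {L} symbols for window length {L}, got {len(symbols)}"
        )
    samples = tuple(
        DiffSample(attributes=tuple(symbols[t : t + L - 1]), label=symbols[t + L - 1])
        for t in range(len(symbols) - L + 1)
    )
    return SampleSet(samples=samples, alphabet=frozenset(symbols), window_length=L)


def filter_by_frequency(samples: SampleSet, gamma: float) -> SampleSet:
    """Retain samples whose label frequency is strictly larger than γ.

    Frequencies are relative label counts measured on the *input* set
    (single-pass semantics); attributes are never filtered. Raises
    :class:`EmptyModelError` if nothing survives.
    """
    if not 0.0 <= gamma < 1.0:
        raise ValueError(f"gamma must be in [0, 1), got {gamma}")
    total = len(samples)
    if total == 0:
        raise EmptyModelError("cannot filter an empty sample set")
    retained = tuple(
        s for s in samples.samples if samples.class_counts[s.label] / total > gamma
    )
    if not retained:
        max_freq = max(samples.class_counts.values()) / total
        raise EmptyModelError(
            f"frequency threshold gamma={gamma} removed every sample "
            f"(maximum class frequency is {max_freq:.4f}); lower gamma"
        )
    return SampleSet(
        samples=retained,
        alphabet=samples.alphabet,
        window_length=samples.window_length,
    )
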