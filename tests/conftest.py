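"""Shared fixtures and the brute-force scoring oracle.

The oracle recomputes every count by looping over the raw sample list —
no tables, no caching — so it is an independent check of the table-driven
scorer.
"""

from __future__ import annotations

import numpy as np
import pytest

from nsbforecast import build_samples, fit


def brute_force_scores(samples, window, alphabet):
    """Score each class by direct enumeration over the raw samples.

    For class y: Σ_i P̂(y, x_i) Π_j P̂(x_j | y, x_i) with every |D_·|
    recounted from scratch; the result is normalized over classes.
    """
    raw_samples = [(s.attributes, s.label) for s in samples]
    total = len(raw_samples)
    classes = sorted({label for _, label in raw_samples})
    N = len(classes)
    A = len(alphabet)
    raw = {}
    for y in classes:
        acc = 0.0
        for i, x_i in enumerate(window):
            pair = sum(
                1 for attrs, label in raw_samples if label == y and attrs[i] == x_i
            )
            term = (pair + 1) / (total + N * A)
            for j, x_j in enumerate(window):
                triple = sum(
                    1
                    for attrs, label in raw_samples
                    if label == y and attrs[i] == x_i and attrs[j] == x_j
                )
                term *= (triple + 1) / (pair + A)
            acc += term
        raw[y] = acc
    z = sum(raw.values())
    return {y: v / z for y, v in raw.items()}


def random_toy_instance(rng: np.random.Generator):
    """A tiny random fitted model: alphabet ≤ 4, ≤ 8 samples, L ≤ 4.

    Returns (sample_set, model, window); the window may contain symbols
    outside the training alphabet.
    """
    pool = np.array([-0.2, -0.1, 0.0, 0.1])
    alphabet = rng.choice(pool, size=rng.integers(2, 5), replace=False)
    L = int(rng.integers(2, 5))
    n_samples = int(rng.integers(1, 9))
    symbols = rng.choice(alphabet, size=n_samples + L - 1)
    sample_set = build_samples(symbols, L)
    model = fit(sample_set)
    if rng.random() < 0.2:  # occasionally probe with an unseen symbol
        window = rng.choice(np.append(alphabet, 0.3), size=L - 1)
    else:
        window = rng.choice(alphabet, size=L - 1)
    return sample_set, model, tuple(float(x) for x in window)


@pytest.fixture
def toy_pair_samples():
    """The two-sample enumeration toy: symbols (a,b,c,d) → {(a,b→c), (b,c→d)}."""
    return build_samples([-0.2, -0.1, 0.1, 0.2], window_length=3)
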