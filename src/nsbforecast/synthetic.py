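"""Synthetic dissolved-oxygen-like series with known structure.

The generator emulates the regimes a coastal DO sensor record shows:
a diurnal sinusoidal cycle, a random-walk drift whose innovations live on
the difference scale (so first differences are Gaussian around the
cycle's slope), and occasional mean-reverting "mutation" spikes — an
abrupt jump that holds for a few steps and then reverts, with stable data
on both sides. A first-order Markov symbol generator provides ground
truth for accuracy-recovery tests, since its Bayes-optimal one-step
accuracy is computable from the transition matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import LevelSeries

__all__ = [
    "SyntheticConfig",
    "generate_sinusoidal",
    "generate_markov_diffs",
    "markov_bayes_accuracy",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the sinusoidal DO generator.

    Defaults describe a 5-minute coastal sensor: mean level 8.0 mg/L,
    diurnal amplitude 1.5 mg/L over a 288-sample day, Gaussian difference
    noise of 0.02 mg/L, and rare 1 mg/L spikes lasting six samples.
    ``quantize_decimals`` rounds the emitted levels to the sensor's
    reporting resolution (None keeps them continuous); a quantized
    noise-free cyclical series is exactly learnable because its
    differences live in the rounded symbol alphabet.
    """

    n: int = 2000
    base: float = 8.0
    amplitude: float = 1.5
    period: int = 288
    noise_sd: float = 0.02
    spike_prob: float = 0.002
    spike_magnitude: float = 1.0
    spike_duration: int = 6
    seed: int = 0
    quantize_decimals: int | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if self.period < 1:
            raise ValueError(f"period must be >= 1, got {self.period}")
        for name in ("amplitude", "noise_sd", "spike_prob", "spike_magnitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.spike_prob <= 1.0:
            raise ValueError(f"spike_prob must be in [0, 1], got {self.spike_prob}")
        if self.spike_duration < 1:
            raise ValueError(f"spike_duration must be >= 1, got {self.spike_duration}")
        if self.quantize_decimals is not None and self.quantize_decimals < 0:
            raise ValueError("quantize_decimals must be >= 0 or None")


def generate_sinusoidal(config: SyntheticConfig) -> LevelSeries:
    """Simulate a DO-like level series under ``config``.

    level_t = base + amplitude·sin(2πt/period) + W_t + S_t, where W_t is a
    random walk with N(0, noise_sd²) increments and S_t adds
    ±spike_magnitude for spike_duration steps after each spike onset, then
    reverts. Identical config (including seed) gives a bit-identical
    series. Timestamps are synthetic 5-minute intervals.
    """
    rng = np.random.default_rng(config.seed)
    t = np.arange(config.n)
    clean = config.base + config.amplitude * np.sin(2 * np.pi * t / config.period)

    if config.noise_sd > 0:
        walk = np.concatenate(
            [[0.0], np.cumsum(rng.normal(0.0, config.noise_sd, config.n - 1))]
        )
    else:
        walk = np.zeros(config.n)

    spikes = np.zeros(config.n)
    if config.spike_prob > 0 and config.spike_magnitude > 0:
        onsets = rng.random(config.n) < config.spike_prob
        signs = rng.choice([-1.0, 1.0], size=config.n)
        i = 0
        while i < config.n:
            if onsets[i]:
                stop = min(i + config.spike_duration, config.n)
                spikes[i:stop] += signs[i] * config.spike_magnitude
                i = stop  # spikes do not overlap; data revert before the next
            else:
                i += 1

    levels = clean + walk + spikes
    if config.quantize_decimals is not None:
        levels = np.round(levels, config.quantize_decimals)
    timestamps = pd.date_range("2020-01-01", periods=config.n, freq="5min").to_numpy()
    return LevelSeries(levels, timestamps)


def generate_markov_diffs(
    transition_matrix, symbols, n: int, seed: int = 0
) -> np.ndarray:
    """Sample a first-order Markov chain over difference symbols.

    Rows of ``transition_matrix`` must sum to 1. The initial state is
    drawn uniformly. Returns an array of n symbol values.
    """
    P = np.asarray(transition_matrix, dtype=float)
    symbols = np.asarray(symbols, dtype=float)
    k = len(symbols)
    if P.shape != (k, k):
        raise ValueError(f"transition matrix must be {k}x{k}, got {P.shape}")
    if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition matrix rows must be non-negative and sum to 1")
    if len(set(symbols.tolist())) != k:
        raise ValueError("symbols must be distinct")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    states = np.empty(n, dtype=np.intp)
    states[0] = rng.integers(k)
    for t in range(1, n):
        states[t] = rng.choice(k, p=P[states[t - 1]])
    return symbols[states]


def markov_bayes_accuracy(transition_matrix) -> float:
    """Bayes-optimal one-step prediction accuracy of a Markov chain.

    The optimal predictor maps each state s to argmax_t P[s, t]; its
    accuracy is Σ_s π_s max_t P[s, t] under the stationary distribution π.
    """
    P = np.asarray(transition_matrix, dtype=float)
    eigvals, eigvecs = np.linalg.eig(P.T)
    idx = int(np.argmin(np.abs(eigvals - 1.0)))
    pi = np.real(eigvecs[:, idx])
    pi = pi / pi.sum()
    return float(np.sum(pi * P.max(axis=1)))
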