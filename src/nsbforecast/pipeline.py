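"""High-level composition of the forecasting pipeline.

Ties the stages together: difference → discretize → window → γ-filter →
fit, and walk-forward evaluation on a held-out split. These are the
functions the CLI, the examples and the acceptance script call.
"""

from __future__ import annotations

import logging

from .metrics import MetricsReport, metrics_report
from .model import ForecastResult, NsbModel, fit, forecast_series
from .series import LevelSeries, discretize, first_difference, split_train_test
from .windowing import SampleSet, build_samples, filter_by_frequency

log = logging.getLogger("nsbforecast")

__all__ = ["prepare_samples", "fit_level_series", "evaluate_model", "evaluate_split"]


def prepare_samples(
    levels: LevelSeries, window_length: int, gamma: float, decimals: int
) -> SampleSet:
    """Difference, discretize, window and γ-filter a level series."""
    symbols = discretize(first_difference(levels), decimals)
    samples = build_samples(symbols, window_length)
    n_before = len(samples)
    if gamma > 0:
        samples = filter_by_frequency(samples, gamma)
    log.info(
        "prepared samples: alphabet size %d, %d windows, %d retained after gamma=%g "
        "(%d classes)",
        len(samples.alphabet), n_before, len(samples), gamma, len(samples.classes),
    )
    return samples


def fit_level_series(
    levels: LevelSeries, window_length: int, gamma: float = 0.0, decimals: int = 2
) -> NsbModel:
    """Fit an NSB model directly from a training level series."""
    samples = prepare_samples(levels, window_length, gamma, decimals)
    return fit(samples, gamma=gamma, decimals=decimals)


def evaluate_model(
    model: NsbModel, test_levels: LevelSeries
) -> tuple[ForecastResult, MetricsReport]:
    """Walk-forward forecast of a held-out series plus its metric report."""
    result = forecast_series(model, test_levels)
    return result, metrics_report(result.observed, result.predicted_level)


def evaluate_split(
    levels: LevelSeries,
    window_length: int,
    gamma: float = 0.0,
    decimals: int = 2,
    split_fraction: float = 0.9,
) -> tuple[NsbModel, ForecastResult, MetricsReport]:
    """Fit on the chronological head of a series, evaluate on the tail."""
    train, test = split_train_test(levels, split_fraction)
    model = fit_level_series(train, window_length, gamma, decimals)
    result, report = evaluate_model(model, test)
    return model, result, report
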