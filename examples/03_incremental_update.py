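"""Grow a fitted model with new data instead of refitting.

The model is nothing but integer count tables, so adding the counts of
new window samples is exactly equivalent to refitting on the
concatenated data — useful when a sensor streams new records.
"""

import numpy as np

from nsbforecast import build_samples, discretize, fit, update
from nsbforecast.windowing import SampleSet

rng = np.random.default_rng(5)
symbols = discretize(rng.normal(0, 0.03, 600), decimals=2)
full = build_samples(symbols, window_length=3)

half = len(full) // 2
first = SampleSet(samples=full.samples[:half], alphabet=full.alphabet, window_length=3)
second = SampleSet(samples=full.samples[half:], alphabet=full.alphabet, window_length=3)

incremental = update(fit(first), second)
batch = fit(full)

print(f"batch model:       {batch.tables.total} samples, "
      f"{len(batch.tables.pair_counts)} pair counts")
print(f"incremental model: {incremental.tables.total} samples, "
      f"{len(incremental.tables.pair_counts)} pair counts")
print(f"tables identical:  {incremental.tables == batch.tables}")
print("True: supplementing the original model equals regenerating it from scratch.")
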