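"""Recover the Bayes-optimal accuracy of a known Markov difference chain.

When the differences truly follow a first-order Markov chain, no
predictor can beat the chain's Bayes rate (predict the most likely next
state). With L = 2 the model conditions on exactly the previous
difference, so its accuracy should approach that rate.
"""

import numpy as np

from nsbforecast import (
    LevelSeries, build_samples, discretize, first_difference, fit,
    forecast_series, generate_markov_diffs, markov_bayes_accuracy,
    split_train_test,
)

P = np.array([[0.7, 0.2, 0.1], [0.15, 0.7, 0.15], [0.1, 0.25, 0.65]])
symbols = np.array([-0.1, 0.0, 0.1])
diffs = generate_markov_diffs(P, symbols, n=5000, seed=11)
levels = LevelSeries(8.0 + np.concatenate([[0.0], np.cumsum(diffs)]))

train, test = split_train_test(levels, 0.9)
model = fit(build_samples(discretize(first_difference(train), 1), window_length=2))
result = forecast_series(model, test)

observed = discretize(first_difference(test), 1)
accuracy = float(np.mean(result.predicted_diff == observed[1:]))
print(f"Bayes-optimal accuracy (from the transition matrix): "
      f"{markov_bayes_accuracy(P):.4f}")
print(f"NSB one-step symbol accuracy on held-out data:       {accuracy:.4f}")
print("The two agree to a few points: the model recovers the chain's predictable")
print("structure; the residual gap is finite-sample estimation noise.")
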