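"""Forecast a noisy diurnal dissolved-oxygen series one step ahead.

Simulates a realistic 5-minute DO sensor record (diurnal cycle, Gaussian
difference noise, occasional spikes), fits the semi-naive Bayes model on
the first 90%, and walk-forward forecasts the held-out 10%.
"""

from nsbforecast import SyntheticConfig, dm_test, evaluate_split, generate_sinusoidal
from nsbforecast import metrics_report, split_train_test

config = SyntheticConfig(n=4000, seed=1)
series = generate_sinusoidal(config)

model, result, report = evaluate_split(
    series, window_length=3, gamma=0.01, decimals=2, split_fraction=0.9
)
print(f"training samples: {model.tables.total}, "
      f"alphabet size: {model.tables.alphabet_size}, "
      f"retained classes: {model.tables.n_classes}")
print(f"NSB   MAE={report.mae:.5f} mg/L  RMSE={report.rmse:.5f} mg/L  "
      f"MAPE={report.mape:.5f}  WIA={report.wia:.5f}  (n={report.n})")

# persistence baseline: tomorrow equals today (predicted difference zero)
_, test = split_train_test(series, 0.9)
persistence_levels = test.values[model.n_attributes:-1]
persistence = metrics_report(result.observed, persistence_levels)
print(f"persistence MAE={persistence.mae:.5f} mg/L")

dm = dm_test(result.predicted_level - result.observed,
             persistence_levels - result.observed, loss="absolute")
print(f"DM-MAE statistic={dm.statistic:.3f}  p={dm.p_value:.2e}")
print("A negative DM statistic with a small p-value means the NSB forecast's")
print("absolute errors are significantly smaller than the persistence baseline's.")
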