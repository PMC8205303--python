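"""Count tables, Laplace smoothing, super-parent scoring and forecasting."""

import numpy as np
import pytest

from nsbforecast import (
    CountTables,
    EmptyModelError,
    LevelSeries,
    SampleSet,
    build_samples,
    discretize,
    first_difference,
    fit,
    forecast_series,
    laplace_conditional,
    laplace_joint,
    load_model,
    metrics_report,
    predict_next,
    save_model,
    score,
    update,
)
from nsbforecast.windowing import DiffSample

from conftest import brute_force_scores, random_toy_instance


A_, B_, C_, D_ = -0.2, -0.1, 0.1, 0.2  # the four toy symbols


class TestFit:
    def test_enumerated_counts(self, toy_pair_samples):
        model = fit(toy_pair_samples)
        t = model.tables
        assert t.total == 2
        assert t.pair_counts[(C_, 1, A_)] == 1
        assert t.triple_counts[(C_, 1, A_, 2, B_)] == 1
        assert t.n_classes == 2  # labels {C, D}
        assert t.alphabet_size == 4

    def test_duplicated_samples_double_every_count(self, toy_pair_samples):
        doubled = SampleSet(
            samples=toy_pair_samples.samples * 2,
            alphabet=toy_pair_samples.alphabet,
            window_length=3,
        )
        m1, m2 = fit(toy_pair_samples), fit(doubled)
        assert m2.tables.total == 2 * m1.tables.total
        for key, count in m1.tables.pair_counts.items():
            assert m2.tables.pair_counts[key] == 2 * count
        for key, count in m1.tables.triple_counts.items():
            assert m2.tables.triple_counts[key] == 2 * count

    def test_pair_counts_sum_to_total_per_position(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            _, model, _ = random_toy_instance(rng)
            t = model.tables
            for i in range(1, model.n_attributes + 1):
                assert (
                    sum(c for (y, pos, x), c in t.pair_counts.items() if pos == i)
                    == t.total
                )

    def test_triple_counts_marginalize_to_pairs(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            _, model, _ = random_toy_instance(rng)
            t = model.tables
            for (y, i, x_i), pcount in t.pair_counts.items():
                for j in range(1, model.n_attributes + 1):
                    total_j = sum(
                        c
                        for (yy, ii, xi, jj, xj), c in t.triple_counts.items()
                        if (yy, ii, xi, jj) == (y, i, x_i, j)
                    )
                    assert total_j == pcount

    def test_empty_sample_set_rejected(self):
        empty = SampleSet(samples=(), alphabet=frozenset(), window_length=2)
        with pytest.raises(EmptyModelError):
            fit(empty)


class TestLaplace:
    def test_empty_data_uniform(self):
        tables = CountTables(
            total=0, class_counts={}, pair_counts={}, triple_counts={},
            n_classes=3, alphabet_size=3,
        )
        assert laplace_joint(tables, 0.1, 1, 0.0) == pytest.approx(1 / 9)
        # empty condition: uniform over the alphabet
        assert laplace_conditional(tables, 0.1, 1, 0.0, 2, 0.1) == pytest.approx(1 / 3)

    def test_toy_hand_values(self, toy_pair_samples):
        model = fit(toy_pair_samples)
        # (|D_{y,x_i}|+1)/(|D|+N·N_i) = (1+1)/(2+2·4)
        assert laplace_joint(model.tables, C_, 1, A_) == pytest.approx(2 / 10)
        # (|D_{y,x_i,x_j}|+1)/(|D_{y,x_i}|+N_j) = (1+1)/(1+4)
        assert laplace_conditional(model.tables, C_, 1, A_, 2, B_) == pytest.approx(2 / 5)

    def test_joint_normalizes_over_classes_and_alphabet(self):
        """Σ_{y,x_i} P̂(y,x_i) = 1 at each position for every fitted model."""
        rng = np.random.default_rng(7)
        for _ in range(30):
            _, model, _ = random_toy_instance(rng)
            for i in range(1, model.n_attributes + 1):
                total = sum(
                    laplace_joint(model.tables, y, i, x)
                    for y in model.classes
                    for x in model.alphabet
                )
                assert total == pytest.approx(1.0, abs=1e-12)

    def test_conditional_normalizes_over_alphabet(self):
        """Σ_{x_j} P̂(x_j|y,x_i) = 1 for every condition."""
        rng = np.random.default_rng(8)
        for _ in range(30):
            _, model, _ = random_toy_instance(rng)
            for y in model.classes:
                for i in range(1, model.n_attributes + 1):
                    for x_i in model.alphabet:
                        for j in range(1, model.n_attributes + 1):
                            total = sum(
                                laplace_conditional(model.tables, y, i, x_i, j, x_j)
                                for x_j in model.alphabet
                            )
                            assert total == pytest.approx(1.0, abs=1e-12)


class TestScore:
    def test_matches_brute_force_oracle(self):
        """Table-driven scorer equals raw-sample enumeration to 1e−12."""
        rng = np.random.default_rng(12345)
        for _ in range(200):
            sample_set, model, window = random_toy_instance(rng)
            got = score(model, window)
            want = brute_force_scores(sample_set.samples, window, model.alphabet)
            assert set(got) == set(want)
            for y in want:
                assert got[y] == pytest.approx(want[y], abs=1e-12)

    def test_normalized(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            _, model, window = random_toy_instance(rng)
            scores = score(model, window)
            assert sum(scores.values()) == pytest.approx(1.0, abs=1e-12)
            assert all(v >= 0 for v in scores.values())

    def test_dominant_class(self):
        repeated = SampleSet(
            samples=(DiffSample((A_, B_), C_),) * 4,
            alphabet=frozenset([A_, B_, C_]),
            window_length=3,
        )
        model = fit(repeated)
        scores = score(model, (A_, B_))
        assert max(scores, key=scores.get) == C_

    def test_wrong_window_length(self, toy_pair_samples):
        model = fit(toy_pair_samples)
        with pytest.raises(ValueError, match="L-1"):
            score(model, (A_,))

    def test_unseen_symbols_get_smoothing_mass(self, toy_pair_samples):
        model = fit(toy_pair_samples)
        scores = score(model, (0.7, -0.7))
        assert sum(scores.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(0 < v < 1 for v in scores.values())

    def test_long_window_no_underflow(self):
        """Per-term log accumulation keeps 40-attribute products finite."""
        rng = np.random.default_rng(10)
        symbols = rng.choice([-0.1, 0.0, 0.1], size=120)
        model = fit(build_samples(symbols, window_length=41))
        scores = score(model, tuple(rng.choice([-0.1, 0.0, 0.1], size=40)))
        assert sum(scores.values()) == pytest.approx(1.0, abs=1e-9)


class TestPredict:
    def test_dominant_class(self):
        repeated = SampleSet(
            samples=(DiffSample((A_, B_), C_),) * 3,
            alphabet=frozenset([A_, B_, C_]),
            window_length=3,
        )
        assert predict_next(fit(repeated), (A_, B_)) == C_

    def test_tiebreak_smaller_signed_value(self):
        """Equal scores, equal frequency, |−0.1| = |0.1| → −0.1 wins."""
        symmetric = SampleSet(
            samples=(DiffSample((0.0,), 0.1), DiffSample((0.0,), -0.1)),
            alphabet=frozenset([-0.1, 0.0, 0.1]),
            window_length=2,
        )
        model = fit(symmetric)
        scores = score(model, (0.0,))
        assert scores[0.1] == pytest.approx(scores[-0.1], abs=1e-15)
        assert predict_next(model, (0.0,)) == -0.1

    def test_tiebreak_class_frequency(self):
        """An unseen window symbol gives every class identical smoothing-only
        scores; the more frequent training class must win."""
        samples = SampleSet(
            samples=(
                DiffSample((0.1,), 0.1),
                DiffSample((0.1,), 0.1),
                DiffSample((-0.1,), -0.1),
            ),
            alphabet=frozenset([-0.1, 0.1]),
            window_length=2,
        )
        model = fit(samples)
        scores = score(model, (0.3,))
        assert scores[0.1] == pytest.approx(scores[-0.1], abs=1e-15)
        assert predict_next(model, (0.3,)) == 0.1

    def test_repeating_pattern_fully_learned(self):
        """A period-3 diff pattern is a function of its 3 predecessors."""
        pattern = [0.1, 0.1, -0.2]
        symbols = np.array(pattern * 20)
        model = fit(build_samples(symbols, window_length=4))
        for start in range(3):
            window = tuple(symbols[start : start + 3])
            assert predict_next(model, window) == symbols[start + 3]


class TestUpdate:
    def test_empty_update_is_identity(self, toy_pair_samples):
        model = fit(toy_pair_samples)
        updated = update(
            model, SampleSet(samples=(), alphabet=frozenset(), window_length=3)
        )
        assert updated == model

    def test_update_equals_refit_on_union(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            symbols = rng.choice([-0.1, 0.0, 0.1, 0.2], size=rng.integers(8, 30))
            L = int(rng.integers(2, 5))
            full = build_samples(symbols, L)
            cut = int(rng.integers(1, len(full)))
            part1 = SampleSet(
                samples=full.samples[:cut],
                alphabet=frozenset(
                    {x for s in full.samples[:cut] for x in s.attributes}
                    | {s.label for s in full.samples[:cut]}
                ),
                window_length=L,
            )
            part2 = SampleSet(
                samples=full.samples[cut:],
                alphabet=frozenset(
                    {x for s in full.samples[cut:] for x in s.attributes}
                    | {s.label for s in full.samples[cut:]}
                ),
                window_length=L,
            )
            incremental = update(fit(part1), part2)
            refit = fit(
                SampleSet(
                    samples=full.samples,
                    alphabet=part1.alphabet | part2.alphabet,
                    window_length=L,
                )
            )
            assert incremental.tables == refit.tables
            assert incremental.alphabet == refit.alphabet

    def test_new_symbol_grows_alphabet_and_shifts_probabilities(self):
        """Adding a sample with a novel symbol changes A, hence denominators."""
        d1 = build_samples([-0.1, 0.0, -0.1], 2)  # samples (−0.1→0), (0→−0.1)
        model = fit(d1)
        assert model.tables.alphabet_size == 2
        # (|D_{0,−0.1}|+1)/(|D|+N·A) = (1+1)/(2+2·2)
        assert laplace_joint(model.tables, 0.0, 1, -0.1) == pytest.approx(2 / 6)
        d2 = build_samples([0.1, -0.1], 2)  # one sample (0.1 → −0.1)
        updated = update(model, d2)
        assert updated.tables.alphabet_size == 3
        assert updated.tables.total == 3
        # denominators now use |D|=3, A=3: (1+1)/(3+2·3)
        assert laplace_joint(updated.tables, 0.0, 1, -0.1) == pytest.approx(2 / 9)

    def test_window_length_mismatch(self, toy_pair_samples):
        model = fit(toy_pair_samples)
        other = build_samples([0.1, 0.2, 0.3], 2)
        with pytest.raises(ValueError, match="window length mismatch"):
            update(model, other)


class TestForecastSeries:
    def test_persistence_equivalent_model(self):
        """A model trained on constant diffs predicts 0 → lagged observations."""
        train = LevelSeries(np.full(30, 8.0))
        model = fit(build_samples(discretize(first_difference(train), 2), 3))
        test = LevelSeries(8.0 + 0.01 * np.arange(10.0))
        result = forecast_series(model, test)
        np.testing.assert_array_equal(result.predicted_diff, 0.0)
        np.testing.assert_allclose(result.predicted_level, test.values[2:-1])

    def test_alignment_arithmetic(self):
        rng = np.random.default_rng(13)
        test = LevelSeries(8 + np.cumsum(rng.choice([-0.1, 0.1], size=25)))
        train = LevelSeries(8 + np.cumsum(rng.choice([-0.1, 0.1], size=100)))
        for L in (2, 3, 5):
            model = fit(build_samples(discretize(first_difference(train), 1), L))
            result = forecast_series(model, test)
            assert len(result) == (len(test) - 1) - (L - 1)
            assert len(result.observed) == len(result.predicted_level)

    def test_deterministic_pattern_perfect_forecast(self):
        pattern = [0.1, 0.1, -0.2]
        levels = 8.0 + np.concatenate([[0.0], np.cumsum(pattern * 30)])
        train = LevelSeries(levels[:70])
        test = LevelSeries(levels[70:])
        model = fit(build_samples(discretize(first_difference(train), 2), 4))
        result = forecast_series(model, test)
        report = metrics_report(result.observed, result.predicted_level)
        assert report.mae == pytest.approx(0.0, abs=1e-12)
        assert report.wia == pytest.approx(1.0, abs=1e-12)

    def test_too_short_test_series(self, toy_pair_samples):
        model = fit(toy_pair_samples)
        with pytest.raises(ValueError, match="at least"):
            forecast_series(model, LevelSeries([8.0, 8.1, 8.2]))


class TestSerialization:
    def test_roundtrip_preserves_predictions(self, tmp_path):
        rng = np.random.default_rng(21)
        symbols = rng.choice([-0.1, 0.0, 0.1], size=60)
        model = fit(build_samples(symbols, 3), gamma=0.0, decimals=1)
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        assert loaded.tables == model.tables
        assert loaded.classes == model.classes
        probes = [tuple(rng.choice([-0.1, 0.0, 0.1], size=2)) for _ in range(20)]
        for window in probes:
            assert predict_next(loaded, window) == predict_next(model, window)
            got, want = score(loaded, window), score(model, window)
            for y in want:
                assert got[y] == pytest.approx(want[y], abs=1e-15)

    def test_file_is_deterministic(self, tmp_path):
        model = fit(build_samples([0.1, -0.1, 0.1, 0.0, 0.1], 2))
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        save_model(model, p1)
        save_model(model, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_bad_version_rejected(self, tmp_path):
        path = tmp_path / "model.json"
        path.write_text('{"version": 99}')
        with pytest.raises(ValueError, match="schema version"):
            load_model(path)
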