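import numpy as np
import pytest

from cuephys.decoding import (
    DecoderConfig,
    FeatureMatrix,
    build_feature_matrix,
    compare_groups,
    decode_once,
    repeated_decoding,
)
from cuephys.io import SessionBundle, UnitRecord
from cuephys.psth import BASELINE_BINS, align_and_bin
from cuephys.simulate import preset_config, simulate_session

from conftest import make_trials


def _single_unit_bundle():
    trials = make_trials([10.0, 50.0], ["DS+", "DS-"])
    spikes = np.sort(np.concatenate([
        10.0 + np.linspace(-0.95, 3.9, 40),   # trial 1 activity
        50.0 + np.linspace(-0.85, 3.8, 25),   # trial 2 activity
    ]))
    u = UnitRecord("u1", "ratA", "control", "day1", "dmPFC", spike_times=spikes)
    return SessionBundle([u], trials, "ratA", "control", "day1")


class TestFeatureMatrix:
    def test_single_unit_features_equal_normalized_rates(self):
        """With one unit the population average is that unit's own
        baseline-z rates."""
        bundle = _single_unit_bundle()
        fm = build_feature_matrix([bundle], "dmPFC")
        tensor = next(iter(align_and_bin(bundle).values()))
        rates = tensor.counts / 0.05
        base = rates[:, list(BASELINE_BINS)]
        expected = (rates - base.mean()) / base.std(ddof=0)
        np.testing.assert_allclose(fm.X, expected, atol=1e-12)
        np.testing.assert_array_equal(fm.y, [1, 0])

    def test_population_mean_recomputation(self, control_session):
        """Feature column 20 equals the hand-computed across-unit mean of
        normalized single-trial rates in bin 20."""
        bundle, _ = control_session
        area = "VTA"
        fm = build_feature_matrix([bundle], area)
        tensors = align_and_bin(bundle)
        cols = []
        for u in bundle.units_in(area):
            rates = tensors[u.unit_id].counts / 0.05
            base = rates[:, list(BASELINE_BINS)]
            mu, sd = base.mean(), base.std(ddof=0)
            if sd == 0:
                continue
            cols.append((rates[:, 20] - mu) / sd)
        np.testing.assert_allclose(fm.X[:, 20], np.mean(cols, axis=0), atol=1e-12)

    def test_no_units_rejected(self, control_session):
        bundle, _ = control_session
        empty = SessionBundle(
            units=bundle.units_in("dmPFC"), trials=bundle.trials,
            animal_id=bundle.animal_id, group=bundle.group, session=bundle.session,
        )
        with pytest.raises(ValueError):
            build_feature_matrix([empty], "VTA")


def _noise_features(rng, n_trials=100, n_feat=100):
    X = rng.normal(size=(n_trials, n_feat))
    y = np.r_[np.ones(n_trials // 2, int), np.zeros(n_trials // 2, int)]
    return FeatureMatrix(X=X, y=y, session_ids=np.full(n_trials, "s"))


class TestDecodeOnce:
    def test_separable_feature_found(self):
        rng = np.random.default_rng(5)
        fm = _noise_features(rng)
        fm.X[:, 50] = fm.y * 2.0 - 1.0 + rng.normal(0, 0.05, fm.y.size)
        res = decode_once(fm, DecoderConfig(), split_seed=11)
        assert res.accuracy == 1.0
        assert 50 in res.selected

    def test_null_accuracy_near_chance(self):
        rng = np.random.default_rng(6)
        fm = _noise_features(rng)
        cfg = DecoderConfig(n_repeats=20, seed=2)
        res = repeated_decoding(fm, cfg)
        acc = res.overall_accuracies
        se = max(acc.std(ddof=1) / np.sqrt(acc.size), 0.5 / np.sqrt(20 * acc.size))
        assert abs(acc.mean() - 0.5) < 3 * max(se, 0.03)


class TestRepeatedDecoding:
    def test_deterministic_under_master_seed(self):
        rng = np.random.default_rng(8)
        fm = _noise_features(rng, n_trials=60)
        cfg = DecoderConfig(n_repeats=5, seed=77)
        a = repeated_decoding(fm, cfg)
        b = repeated_decoding(fm, cfg)
        np.testing.assert_array_equal(a.selection_frequency, b.selection_frequency)
        for ep in a.epoch_accuracies:
            np.testing.assert_array_equal(
                a.epoch_accuracies[ep], b.epoch_accuracies[ep]
            )

    def test_planted_lever_signal_recovered(self):
        """Signal only in lever bins: Lever accuracy beats Tone accuracy and
        the top-10 lever features hit the planted bins."""
        rng = np.random.default_rng(9)
        fm = _noise_features(rng, n_trials=120)
        planted = list(range(84, 90))
        for b in planted:
            fm.X[:, b] += (fm.y * 2.0 - 1.0) * 1.5
        res = repeated_decoding(fm, DecoderConfig(n_repeats=15, seed=5))
        assert res.mean_epoch_accuracy["Lever"] > res.mean_epoch_accuracy["Tone"]
        assert set(res.top_features["Lever"]) & set(planted)


class TestGroupComparison:
    def test_identical_results_t_zero(self):
        rng = np.random.default_rng(10)
        fm = _noise_features(rng, n_trials=60)
        res = repeated_decoding(fm, DecoderConfig(n_repeats=4, seed=1))
        comp = compare_groups(res, res)
        for ep in comp:
            assert comp[ep].t == pytest.approx(0.0)
            assert comp[ep].df == 6

    def test_hand_computed_t_on_constructed_vectors(self):
        rng = np.random.default_rng(11)
        fm = _noise_features(rng, n_trials=60)
        a = repeated_decoding(fm, DecoderConfig(n_repeats=4, seed=1))
        b = repeated_decoding(fm, DecoderConfig(n_repeats=4, seed=1))
        # perturb one repeat of one epoch and compare against the closed form
        b.epoch_accuracies["Tone"] = a.epoch_accuracies["Tone"] + np.array(
            [0.1, 0.0, 0.0, 0.0]
        )
        x = a.epoch_accuracies["Tone"]
        y = b.epoch_accuracies["Tone"]
        n = 4
        sp = np.sqrt(((n - 1) * x.var(ddof=1) + (n - 1) * y.var(ddof=1)) / (2 * n - 2))
        t_ref = (x.mean() - y.mean()) / (sp * np.sqrt(2 / n))
        comp = compare_groups(a, b)
        assert comp["Tone"].t == pytest.approx(t_ref, abs=1e-10)

    def test_unequal_repeats_rejected(self):
        rng = np.random.default_rng(12)
        fm = _noise_features(rng, n_trials=60)
        a = repeated_decoding(fm, DecoderConfig(n_repeats=3, seed=1))
        b = repeated_decoding(fm, DecoderConfig(n_repeats=4, seed=1))
        with pytest.raises(ValueError):
            compare_groups(a, b)
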