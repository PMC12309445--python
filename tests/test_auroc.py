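import numpy as np
import pytest

from cuephys.auroc import (
    AuROCProfile,
    auroc_trace,
    binwise_auroc,
    compute_auroc_profile,
    epoch_selectivity,
    shuffle_null,
)
from cuephys.psth import align_and_bin
from cuephys.responsiveness import EPOCHS
from cuephys.simulate import AreaConfig, EpochEffect, SimConfig, simulate_session

from conftest import make_tensor


def threshold_sweep_auroc(a, b):
    """Independent oracle: trapezoidal integration of the empirical ROC curve
    swept over all distinct thresholds."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    thresholds = np.r_[np.inf, np.unique(np.concatenate([a, b]))[::-1], -np.inf]
    tpr = [(a >= t).mean() for t in thresholds]
    fpr = [(b >= t).mean() for t in thresholds]
    return float(np.trapezoid(tpr, fpr))


class TestBinwiseAuroc:
    def test_identical_distributions_half(self):
        assert binwise_auroc([1, 2, 3], [1, 2, 3]) == 0.5

    def test_full_separation_one(self):
        assert binwise_auroc([4, 5, 6], [1, 2, 3]) == 1.0

    def test_pair_enumeration_example(self):
        assert binwise_auroc([2, 3, 4], [1, 2, 3]) == pytest.approx(7 / 9)

    def test_matches_threshold_sweep_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n1, n2 = rng.integers(1, 12, 2)
            a = rng.integers(0, 6, n1)
            b = rng.integers(0, 6, n2)
            assert binwise_auroc(a, b) == pytest.approx(
                threshold_sweep_auroc(a, b), abs=1e-12
            )

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a = rng.poisson(1.0, 10)
            b = rng.poisson(2.0, 8)
            assert binwise_auroc(a, b) == pytest.approx(
                1 - binwise_auroc(b, a), abs=1e-12
            )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(8)
        a = rng.poisson(2.0, 12).astype(float)
        b = rng.poisson(1.0, 9).astype(float)
        assert binwise_auroc(np.exp(a), np.exp(b)) == pytest.approx(
            binwise_auroc(a, b), abs=1e-12
        )

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            binwise_auroc([], [1, 2])

    def test_trace_matches_scalar(self):
        rng = np.random.default_rng(9)
        plus = rng.poisson(1.0, (10, 5))
        minus = rng.poisson(0.5, (8, 5))
        trace = auroc_trace(plus, minus)
        for b in range(5):
            assert trace[b] == pytest.approx(
                binwise_auroc(plus[:, b], minus[:, b]), abs=1e-12
            )


class TestEpochSelectivity:
    def test_flat_trace_not_selective(self):
        prof = AuROCProfile("u", np.full(100, 0.5))
        sel = epoch_selectivity(prof, EPOCHS["ToneR"])
        assert not sel.selective and sel.degenerate
        assert sel.delta_auroc == 0.0

    def test_hand_arithmetic(self):
        """Baseline auROC alternating 0.45/0.55 (μ=0.5, SD 0.05); an epoch
        mean of 0.7 gives Z = 4 → selective, Δ = 0.2."""
        trace = np.full(100, 0.5)
        trace[0:20:2] = 0.45
        trace[1:20:2] = 0.55
        trace[list(EPOCHS["ToneR"].bins)] = 0.7
        sel = epoch_selectivity(AuROCProfile("u", trace), EPOCHS["ToneR"])
        assert sel.selective
        assert sel.delta_auroc == pytest.approx(0.2)
        assert sel.zscore == pytest.approx(4.0)

    def test_planted_lever_contrast_detected(self):
        """Strong DS+ lever gain with no DS− response: most units selective."""
        cfg = SimConfig(
            areas={
                "VTA": AreaConfig(
                    n_units=20, baseline_mean_hz=8.0, baseline_sd_hz=1e-9,
                    epochs={"Lever": EpochEffect(1.0, 0.0, 4.0)},
                    ds_minus_scale=0.0, da_fraction=0.5,
                )
            }
        )
        bundle, _ = simulate_session(cfg, "a", "control", "day1", seed=41)
        tensors = align_and_bin(bundle)
        hits = 0
        for t in tensors.values():
            prof = compute_auroc_profile(t)
            if epoch_selectivity(prof, EPOCHS["Lever"]).selective:
                hits += 1
        assert hits / len(tensors) >= 0.9


class TestShuffleNull:
    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        tensors = [
            make_tensor(
                rng.poisson(0.4, (40, 100)),
                np.array(["DS+"] * 20 + ["DS-"] * 20, dtype=object),
                unit_id=f"u{i}",
            )
            for i in range(5)
        ]
        a = shuffle_null(tensors, n_shuffles=10, seed=123)
        b = shuffle_null(tensors, n_shuffles=10, seed=123)
        assert a["per_shuffle"] == b["per_shuffle"]
        assert a["observed"] == b["observed"]

    def test_shuffled_delta_centered_at_zero(self):
        """Under label permutation the Δ auROC distribution is centered at 0."""
        rng = np.random.default_rng(6)
        counts = rng.poisson(0.5, (40, 100))
        cues = np.array(["DS+"] * 20 + ["DS-"] * 20, dtype=object)
        deltas = []
        for _ in range(500):
            t = make_tensor(counts, rng.permutation(cues))
            prof = compute_auroc_profile(t)
            deltas.append(
                epoch_selectivity(prof, EPOCHS["ToneR"]).delta_auroc
            )
        deltas = np.asarray(deltas)
        se = deltas.std(ddof=1) / np.sqrt(deltas.size)
        assert abs(deltas.mean()) < 3 * se
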