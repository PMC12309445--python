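import numpy as np
import pandas as pd
import pytest

from cuephys.psth import BASELINE_BINS, ZProfile, sliding_windows
from cuephys.responsiveness import (
    EPOCHS,
    classify_tensor,
    classify_unit_epoch,
    epoch_mean_activity,
    proportion_summary,
)
from cuephys.simulate import (
    AreaConfig,
    EpochEffect,
    SimConfig,
    gain_for_sd,
    simulate_session,
)
from cuephys.psth import align_and_bin

from conftest import make_tensor


def profile_from_z(z, baseline=BASELINE_BINS):
    z = np.asarray(z, float)
    return ZProfile(
        unit_id="u", cue_type="DS+", rate=z.copy(), baseline_bins=baseline,
        mu=0.0, sigma=1.0, z=z, windows=sliding_windows(z), degenerate=False,
        n_trials=10,
    )


class TestEpochGeometry:
    @pytest.mark.parametrize(
        "name,n_windows", [("ToneR", 5), ("ToneS", 47), ("Lever", 5)]
    )
    def test_windows_fully_inside_epoch(self, name, n_windows):
        assert len(EPOCHS[name].window_starts) == n_windows


class TestClassification:
    def test_zero_trace_is_none(self):
        lab = classify_unit_epoch(profile_from_z(np.zeros(100)), EPOCHS["ToneR"])
        assert lab.label == "none"

    def test_single_window_activation(self):
        """z = 3 over bins 20–23 gives one 200 ms window at W = 3 → activated
        under the ToneR one-window rule."""
        z = np.zeros(100)
        z[20:24] = 3.0
        lab = classify_unit_epoch(profile_from_z(z), EPOCHS["ToneR"])
        assert lab.label == "activated" and lab.n_sig_windows_pos >= 1

    @pytest.mark.parametrize("n_windows,expected", [(5, "none"), (6, "activated")])
    def test_sustained_six_window_boundary(self, n_windows, expected):
        """Exactly 6 suprathreshold sustained windows are required."""
        prof = profile_from_z(np.zeros(100))
        w = np.zeros(97)
        starts = list(EPOCHS["ToneS"].window_starts)[:n_windows]
        w[starts] = 2.5
        prof.windows = w
        assert classify_unit_epoch(prof, EPOCHS["ToneS"]).label == expected

    def test_tie_break_ambiguous(self):
        prof = profile_from_z(np.zeros(100))
        w = np.zeros(97)
        w[20] = 2.5
        w[22] = -2.5
        prof.windows = w
        assert classify_unit_epoch(prof, EPOCHS["ToneR"]).label == "ambiguous"

    def test_direction_with_more_windows_wins(self):
        prof = profile_from_z(np.zeros(100))
        w = np.zeros(97)
        w[[20, 21]] = 2.5
        w[23] = -2.5
        prof.windows = w
        assert classify_unit_epoch(prof, EPOCHS["ToneR"]).label == "activated"

    def test_baseline_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classify_unit_epoch(profile_from_z(np.zeros(100)), EPOCHS["Lever"])

    def test_threshold_monotonicity(self):
        """Raising the z threshold never turns more units activated."""
        rng = np.random.default_rng(17)
        profs = [profile_from_z(rng.normal(0, 1.5, 100)) for _ in range(50)]
        for epoch in EPOCHS.values():
            counts = []
            for thr in (1.5, 2.0, 2.5, 3.0):
                if epoch.name == "Lever":
                    ps = [profile_from_z(p.z, epoch.baseline) for p in profs]
                else:
                    ps = profs
                counts.append(
                    sum(
                        classify_unit_epoch(p, epoch, thr).label == "activated"
                        for p in ps
                    )
                )
            assert counts == sorted(counts, reverse=True)

    def test_trial_order_permutation_stability(self):
        rng = np.random.default_rng(23)
        counts = rng.poisson(0.4, (40, 100))
        cues = np.array(["DS+"] * 20 + ["DS-"] * 20, dtype=object)
        t1 = make_tensor(counts, cues)
        perm = rng.permutation(40)
        t2 = make_tensor(counts[perm], cues[perm])
        l1 = {k: v.label for k, v in classify_tensor(t1, "DS+").items()}
        l2 = {k: v.label for k, v in classify_tensor(t2, "DS+").items()}
        assert l1 == l2

    def test_degenerate_tensor_is_none(self):
        t = make_tensor(np.ones((6, 100), int), ["DS+"] * 6)
        labels = classify_tensor(t, "DS+")
        assert all(v.label == "none" and v.degenerate for v in labels.values())


class TestEpochMean:
    def test_values(self):
        assert epoch_mean_activity(profile_from_z(np.zeros(100)), EPOCHS["ToneS"]) == 0.0
        z = np.zeros(100)
        z[list(EPOCHS["ToneS"].bins)] = 1.0
        assert epoch_mean_activity(profile_from_z(z), EPOCHS["ToneS"]) == pytest.approx(1.0)
        z2 = np.zeros(100)
        bins = list(EPOCHS["ToneS"].bins)
        z2[bins[0::2]] = 2.0  # alternate 2, 0 over the 50 sustained bins
        assert epoch_mean_activity(profile_from_z(z2), EPOCHS["ToneS"]) == pytest.approx(1.0)


class TestProportions:
    def test_table_convention(self):
        """13 activated and 5 inhibited of 130 units print as 10% (4%)."""
        labels = pd.DataFrame(
            {
                "area": ["dmPFC"] * 130,
                "label": ["activated"] * 13 + ["inhibited"] * 5 + ["none"] * 112,
            }
        )
        out = proportion_summary(labels, by=["area"])
        assert out.loc[0, "pct_activated"] == 10
        assert out.loc[0, "pct_inhibited"] == 4

    def test_all_none(self):
        labels = pd.DataFrame({"area": ["VTA"] * 10, "label": ["none"] * 10})
        out = proportion_summary(labels, by=["area"])
        assert out.loc[0, "pct_activated"] == 0 and out.loc[0, "pct_inhibited"] == 0


class TestPlantedRecovery:
    def test_strong_gain_detected_with_high_probability(self):
        """Units with a ToneR rate step of 3 baseline SDs are flagged
        activated in ≥ 90% of cases at 50 trials per cue."""
        gain = gain_for_sd(6.0, 3.0)
        cfg = SimConfig(
            areas={
                "dmPFC": AreaConfig(
                    n_units=40, baseline_mean_hz=6.0, baseline_sd_hz=1e-9,
                    epochs={"ToneR": EpochEffect(1.0, 0.0, gain)},
                )
            }
        )
        bundle, truth = simulate_session(cfg, "a", "control", "day1", seed=99)
        tensors = align_and_bin(bundle)
        hits = sum(
            classify_tensor(tensors[u.unit_id], "DS+")["ToneR"].label == "activated"
            for u in bundle.units
        )
        assert hits / len(bundle.units) >= 0.9
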