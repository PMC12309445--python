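"""Binwise auROC cue selectivity of simulated VTA units vs the shuffle null.

For each unit the per-bin auROC compares DS+ and DS− firing-rate
distributions (0.5 = no discrimination).  A unit is selective in an epoch
when the epoch-mean auROC deviates from its baseline by > 2 baseline SDs;
the proportion of selective units is benchmarked against 10 label-shuffled
recomputations.
"""

from cuephys import align_and_bin, preset_config, shuffle_null, simulate_session

bundle, _ = simulate_session(
    preset_config("control"), "rat01", "control", "day1", seed=21
)
tensors = [
    align_and_bin(bundle)[u.unit_id] for u in bundle.units_in("VTA")
]
null = shuffle_null(tensors, n_shuffles=10, seed=3)

print(f"{len(tensors)} VTA units")
for epoch in ("ToneR", "ToneS", "Lever"):
    print(
        f"{epoch}: observed selective {null['observed'][epoch]:.0%} "
        f"vs shuffle mean {null['shuffle_mean'][epoch]:.0%}"
    )
# A large observed-vs-shuffle gap (typical for Lever, where the planted
# DS+/DS− contrast is strongest) indicates genuine cue discrimination;
# under the null both numbers agree.
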