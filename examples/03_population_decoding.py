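"""LASSO population decoding of cue value from simulated VTA activity.

Each trial contributes 100 features (per-bin population-average z rates);
repeated stratified splits with 5-fold CV-tuned L1 logistic regression give
held-out accuracies and per-feature selection frequencies; the 10 most
frequent features inside the Tone and Lever masks yield epoch accuracies.
"""

import numpy as np

from cuephys import (
    DecoderConfig,
    build_feature_matrix,
    preset_config,
    repeated_decoding,
    simulate_cohort,
)

cohort = simulate_cohort(preset_config("control"), "control", "day1", 3, seed=4)
features = build_feature_matrix([b for b, _ in cohort], "VTA")
print(f"feature matrix: {features.X.shape[0]} trials × {features.X.shape[1]} bins")

res = repeated_decoding(features, DecoderConfig(n_repeats=25, seed=12))
for epoch, accs in res.epoch_accuracies.items():
    print(
        f"{epoch}: accuracy {accs.mean():.2f} ± {accs.std(ddof=1):.2f} "
        f"(top features: bins {list(res.top_features[epoch])})"
    )
print("most-selected bins overall:", np.argsort(res.selection_frequency)[-5:][::-1])
# Accuracy near 0.5 = chance; the Lever epoch typically decodes best because
# the control condition plants its largest DS+/DS− contrast at lever
# presentation, and its top features cluster in bins 80–87 (3.0–3.4 s).
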