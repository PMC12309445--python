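"""Sliding-window responsiveness classification of units per task epoch.

Three epochs are analyzed relative to cue onset: the rapid tone response
(Tone^R, 0–0.4 s), the sustained tone response (Tone^S, 0.5–3 s) and the
lever presentation (Lever, 3–3.4 s).  A unit counts as activated (inhibited)
in an epoch if at least ``min_windows`` of the 200 ms sliding windows lying
fully inside the epoch have mean z above +2 (below −2).  Tone epochs are
referenced to the pre-cue baseline [−1, 0) s; the Lever epoch is referenced
to the late-tone baseline [2, 3) s, so its z trace is recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .psth import (
    AlignedTensor,
    BASELINE_BINS,
    DEFAULT_GRID,
    LEVER_BASELINE_BINS,
    WINDOW_BINS,
    ZProfile,
    zscore_profile,
)

__all__ = [
    "EpochSpec",
    "EPOCHS",
    "ResponseLabel",
    "classify_unit_epoch",
    "classify_tensor",
    "epoch_mean_activity",
    "proportion_summary",
]


@dataclass(frozen=True)
class EpochSpec:
    """Analysis window, baseline window and window-count criterion of an epoch."""

    name: str
    t_from: float
    t_to: float
    baseline: range
    min_windows: int

    @property
    def bins(self) -> range:
        return DEFAULT_GRID.bin_range(self.t_from, self.t_to)

    @property
    def window_starts(self) -> range:
        """Start bins of the 200 ms windows lying entirely inside the epoch."""
        b = self.bins
        return range(b.start, b.stop - WINDOW_BINS + 1)


EPOCHS: dict[str, EpochSpec] = {
    "ToneR": EpochSpec("ToneR", 0.0, 0.4, BASELINE_BINS, min_windows=1),
    "ToneS": EpochSpec("ToneS", 0.5, 3.0, BASELINE_BINS, min_windows=6),
    "Lever": EpochSpec("Lever", 3.0, 3.4, LEVER_BASELINE_BINS, min_windows=1),
}


@dataclass
class ResponseLabel:
    unit_id: str
    epoch: str
    cue_type: str
    label: str  # activated | inhibited | none | ambiguous
    n_sig_windows_pos: int
    n_sig_windows_neg: int
    degenerate: bool = False


def classify_unit_epoch(
    zprofile: ZProfile, epoch: EpochSpec, z_threshold: float = 2.0
) -> ResponseLabel:
    """Label one unit/cue type for one epoch from its z-trace windows.

    The profile must have been normalized against the epoch's own baseline
    (this matters for Lever).  If both the activated and the inhibited
    criterion are met, the direction with more significant windows wins;
    an exact tie is labeled ``ambiguous``.
    """
    if list(zprofile.baseline_bins) != list(epoch.baseline):
        raise ValueError(
            f"profile baseline {zprofile.baseline_bins} does not match "
            f"epoch {epoch.name} baseline {epoch.baseline}"
        )
    if zprofile.degenerate:
        return ResponseLabel(
            zprofile.unit_id, epoch.name, zprofile.cue_type,
            "none", 0, 0, degenerate=True,
        )
    w = zprofile.windows[list(epoch.window_starts)]
    n_pos = int(np.sum(w > z_threshold))
    n_neg = int(np.sum(w < -z_threshold))
    act = n_pos >= epoch.min_windows
    inh = n_neg >= epoch.min_windows
    if act and inh:
        if n_pos > n_neg:
            label = "activated"
        elif n_neg > n_pos:
            label = "inhibited"
        else:
            label = "ambiguous"
    elif act:
        label = "activated"
    elif inh:
        label = "inhibited"
    else:
        label = "none"
    return ResponseLabel(
        zprofile.unit_id, epoch.name, zprofile.cue_type, label, n_pos, n_neg
    )


def classify_tensor(
    tensor: AlignedTensor,
    cue_type: str,
    z_threshold: float = 2.0,
    epochs: dict[str, EpochSpec] = EPOCHS,
    sd_mode: str = "population",
) -> dict[str, ResponseLabel]:
    """Classify one unit for all epochs, recomputing z per epoch baseline."""
    profiles: dict[tuple[int, int], ZProfile] = {}
    out = {}
    for name, epoch in epochs.items():
        key = (epoch.baseline.start, epoch.baseline.stop)
        if key not in profiles:
            profiles[key] = zscore_profile(
                tensor, cue_type, baseline_bins=epoch.baseline, sd_mode=sd_mode
            )
        out[name] = classify_unit_epoch(profiles[key], epoch, z_threshold)
    return out


def epoch_mean_activity(zprofile: ZProfile, epoch: EpochSpec) -> float:
    """Mean z over the epoch's bins (the per-unit population-activity value)."""
    if list(zprofile.baseline_bins) != list(epoch.baseline):
        raise ValueError("profile baseline does not match epoch baseline")
    if zprofile.degenerate:
        raise ValueError(f"unit {zprofile.unit_id}: degenerate baseline")
    return float(zprofile.z[list(epoch.bins)].mean())


def proportion_summary(
    labels: pd.DataFrame,
    by: list[str],
    count_ambiguous: bool = False,
) -> pd.DataFrame:
    """Counts and integer-rounded percentages of activated/inhibited units.

    ``labels`` needs a ``label`` column plus the stratification columns.
    Ambiguous units (both criteria met, tied) are excluded from both the
    activated and inhibited counts unless ``count_ambiguous`` is set, in
    which case they add to both.
    """
    rows = []
    for key, g in labels.groupby(by, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        n = len(g)
        n_act = int((g["label"] == "activated").sum())
        n_inh = int((g["label"] == "inhibited").sum())
        n_amb = int((g["label"] == "ambiguous").sum())
        n_none = n - n_act - n_inh - n_amb
        if count_ambiguous:
            n_act += n_amb
            n_inh += n_amb
        rec = dict(zip(by, key))
        rec.update(
            n_units=n,
            n_activated=n_act,
            n_inhibited=n_inh,
            n_none=n_none,
            pct_activated=int(round(100 * n_act / n)) if n else 0,
            pct_inhibited=int(round(100 * n_inh / n)) if n else 0,
        )
        rows.append(rec)
    return pd.DataFrame(rows)
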