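"""Event-locked alignment, 50 ms binning, baseline z-scoring and basal rates.

Spike trains are aligned to cue onset and counted in 100 half-open 50 ms bins
spanning −1 s to +4 s.  Bin ``b`` covers ``[-1 + 0.05*b, -1 + 0.05*(b+1))``,
so bin 20 starts exactly at the cue.  The trial-averaged rate trace of each
unit is normalized to a z-score against the mean and SD of a baseline bin
range; 200 ms sliding windows (4 bins, advancing 1 bin) of that z trace feed
the responsiveness classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import SessionBundle, UnitRecord

__all__ = [
    "BinGrid",
    "AlignedTensor",
    "ZProfile",
    "align_unit",
    "align_and_bin",
    "zscore_profile",
    "sliding_windows",
    "basal_rate",
]

#: window width in bins (200 ms) and step (50 ms = 1 bin)
WINDOW_BINS = 4

#: default baseline: [-1, 0) s = bins 0..19
BASELINE_BINS = range(0, 20)
#: lever-event baseline: [2, 3) s = bins 60..79
LEVER_BASELINE_BINS = range(60, 80)


@dataclass(frozen=True)
class BinGrid:
    """The −1…+4 s, 50 ms peri-event bin grid (100 half-open bins)."""

    t_start: float = -1.0
    t_end: float = 4.0
    bin_width: float = 0.05

    def __post_init__(self) -> None:
        n = (self.t_end - self.t_start) / self.bin_width
        if abs(n - round(n)) > 1e-9:
            raise ValueError("bin width must divide the trace window")

    @property
    def n_bins(self) -> int:
        return int(round((self.t_end - self.t_start) / self.bin_width))

    @property
    def edges(self) -> np.ndarray:
        return self.t_start + self.bin_width * np.arange(self.n_bins + 1)

    @property
    def centers(self) -> np.ndarray:
        return self.edges[:-1] + self.bin_width / 2

    def bin_range(self, t_from: float, t_to: float) -> range:
        """Bins whose intervals tile [t_from, t_to); endpoints must align."""
        b0 = (t_from - self.t_start) / self.bin_width
        b1 = (t_to - self.t_start) / self.bin_width
        if abs(b0 - round(b0)) > 1e-9 or abs(b1 - round(b1)) > 1e-9:
            raise ValueError(f"[{t_from}, {t_to}) does not align to the bin grid")
        return range(int(round(b0)), int(round(b1)))


DEFAULT_GRID = BinGrid()


@dataclass
class AlignedTensor:
    """Per-unit trial × bin spike counts aligned to cue onset.

    ``counts[t, b]`` is the number of spikes of this unit in bin ``b`` of
    trial ``t``; ``cue_types[t]`` is the trial's label ("DS+" or "DS-").
    """

    unit_id: str
    counts: np.ndarray  # (n_trials, n_bins) int
    cue_types: np.ndarray  # (n_trials,) str
    grid: BinGrid = field(default_factory=BinGrid)

    @property
    def rates(self) -> np.ndarray:
        """Counts converted to instantaneous rates in spikes/s."""
        return self.counts / self.grid.bin_width

    def select(self, cue_type: str) -> np.ndarray:
        """Count matrix restricted to trials of one cue type."""
        return self.counts[self.cue_types == cue_type]


def align_unit(
    unit: UnitRecord, cue_onsets: np.ndarray, cue_types: np.ndarray,
    grid: BinGrid = DEFAULT_GRID,
) -> AlignedTensor:
    onsets = np.asarray(cue_onsets, float)
    counts = np.zeros((onsets.size, grid.n_bins), dtype=np.int64)
    # Half-open bins [edge_b, edge_{b+1}).  The 1e-9 guard keeps spike times
    # that are exact decimal multiples of the bin width (as in hand-written
    # fixtures) in the intended bin despite float subtraction error.
    for i, t0 in enumerate(onsets):
        idx = np.floor(
            (unit.spike_times - t0 - grid.t_start) / grid.bin_width + 1e-9
        ).astype(int)
        idx = idx[(idx >= 0) & (idx < grid.n_bins)]
        counts[i] = np.bincount(idx, minlength=grid.n_bins)
    return AlignedTensor(
        unit_id=unit.unit_id, counts=counts,
        cue_types=np.asarray(cue_types, dtype=object), grid=grid,
    )


def align_and_bin(
    bundle: SessionBundle, grid: BinGrid = DEFAULT_GRID,
    include_omissions: bool = True,
) -> dict[str, AlignedTensor]:
    """Align every unit of a session to cue onsets; returns {unit_id: tensor}."""
    trials = bundle.trials
    if not include_omissions:
        trials = trials[~trials["omission"]]
    onsets = trials["cue_onset_s"].to_numpy(float)
    cues = trials["cue_type"].to_numpy(object)
    return {u.unit_id: align_unit(u, onsets, cues, grid) for u in bundle.units}


@dataclass
class ZProfile:
    """Baseline-normalized trial-averaged rate trace of one unit/cue type."""

    unit_id: str
    cue_type: str
    rate: np.ndarray        # (n_bins,) trial-averaged rate, spikes/s
    baseline_bins: range
    mu: float               # baseline mean of the averaged trace
    sigma: float            # baseline SD of the averaged trace
    z: np.ndarray           # (n_bins,) z trace; NaN when degenerate
    windows: np.ndarray     # (n_bins - 3,) 200 ms sliding-window means of z
    degenerate: bool        # True when sigma == 0 (flat baseline)
    n_trials: int = 0


def sliding_windows(z: np.ndarray, width: int = WINDOW_BINS) -> np.ndarray:
    """Means of ``width`` consecutive bins, advancing one bin at a time."""
    kernel = np.ones(width) / width
    return np.convolve(z, kernel, mode="valid")


def zscore_profile(
    tensor: AlignedTensor,
    cue_type: str,
    baseline_bins: range = BASELINE_BINS,
    sd_mode: str = "population",
    z_mode: str = "baseline",
) -> ZProfile:
    """Trial-averaged rate trace z-scored against its baseline bins.

    ``sd_mode`` selects population (divide by n, default) or sample SD over
    the baseline bins; ``z_mode='full_trace'`` normalizes against all bins
    instead of the baseline range.  A flat reference (sigma = 0) marks the
    profile degenerate; its z trace is NaN and classification skips it.
    """
    counts = tensor.select(cue_type)
    if counts.shape[0] == 0:
        raise ValueError(f"no {cue_type} trials for unit {tensor.unit_id}")
    rate = counts.mean(axis=0) / tensor.grid.bin_width
    ref = rate if z_mode == "full_trace" else rate[list(baseline_bins)]
    ddof = 0 if sd_mode == "population" else 1
    mu = float(ref.mean())
    sigma = float(ref.std(ddof=ddof))
    degenerate = sigma == 0.0
    if degenerate:
        z = np.full_like(rate, np.nan)
    else:
        z = (rate - mu) / sigma
    return ZProfile(
        unit_id=tensor.unit_id, cue_type=cue_type, rate=rate,
        baseline_bins=baseline_bins, mu=mu, sigma=sigma, z=z,
        windows=sliding_windows(z), degenerate=degenerate,
        n_trials=counts.shape[0],
    )


def basal_rate(tensor: AlignedTensor, grid: BinGrid = DEFAULT_GRID) -> float:
    """Mean firing rate (Hz) over the 1 s before cue onset, all trials."""
    pre = grid.bin_range(-1.0, 0.0)
    window_s = len(pre) * grid.bin_width
    return float(tensor.counts[:, list(pre)].sum(axis=1).mean() / window_s)
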