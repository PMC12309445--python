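"""Synthetic DS-task sessions: inhomogeneous-Poisson units with planted effects.

The generator emulates the discriminative-stimulus reward task: 100 trials
per session (50 DS+ / 50 DS−, pseudorandom with at most 3 consecutive trials
of one cue), a 3 s tone followed by lever extension, and a 30 s intertrial
interval.  Each unit is a piecewise-constant-rate Poisson process: its
baseline rate is drawn from a lognormal matched to the recorded populations
(≈6 Hz dmPFC; ≈3.8 Hz putative-DA and higher non-DA in VTA), and responsive
units multiply that rate by an epoch gain inside the Tone-rapid [0, 0.4) s,
Tone-sustained [0.5, 3) s and Lever [3, 3.4) s windows.  DS− trials receive
a diluted version of the DS+ gain (the cue contrast).  Per-epoch responsive
fractions default to the observed control proportions; the ``isd_day1`` and
``isd_day15`` presets shift fractions and gains in the directions observed
after episodic social defeat (dmPFC down at both delays; VTA up at 1 d,
down at 15 d).  Every session ships with its ground truth for parameter-
recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import SessionBundle, UnitRecord

__all__ = [
    "EpochEffect",
    "AreaConfig",
    "SimConfig",
    "GroundTruth",
    "UnitTruth",
    "preset_config",
    "gain_for_sd",
    "make_trial_table",
    "simulate_session",
    "simulate_cohort",
]

#: gain windows relative to cue onset (start, stop) in seconds
EPOCH_WINDOWS = {"ToneR": (0.0, 0.4), "ToneS": (0.5, 3.0), "Lever": (3.0, 3.4)}

PRESETS = ("control", "isd_day1", "isd_day15")


@dataclass(frozen=True)
class EpochEffect:
    """Planted responsiveness of one epoch: fractions and DS+ gains."""

    frac_activated: float
    frac_inhibited: float
    gain_activated: float  # multiplicative rate factor on DS+ trials
    gain_inhibited: float = 0.25

    def __post_init__(self) -> None:
        if not (0 <= self.frac_activated + self.frac_inhibited <= 1):
            raise ValueError("epoch fractions must lie in [0, 1] and sum to <= 1")
        if self.gain_activated <= 0 or self.gain_inhibited <= 0:
            raise ValueError("gains must be positive")


@dataclass(frozen=True)
class AreaConfig:
    n_units: int
    baseline_mean_hz: float
    baseline_sd_hz: float
    epochs: dict[str, EpochEffect]
    #: DS− gain = 1 + (DS+ gain − 1) * ds_minus_scale
    ds_minus_scale: float = 0.4
    # VTA-only cell-type structure; ignored for dmPFC
    da_fraction: float | None = None
    da_rate_mean_hz: float = 3.8
    da_rate_sd_hz: float = 2.2
    da_waveform_ms: tuple[float, float] = (1.5, 0.12)  # mean, sd; wide spikes
    nonda_waveform_ms: tuple[float, float] = (0.8, 0.10)


@dataclass(frozen=True)
class SimConfig:
    areas: dict[str, AreaConfig]
    n_trials_per_cue: int = 50
    tone_to_lever_s: float = 3.0
    iti_s: float = 30.0
    trial_spacing_s: float = 35.0
    first_cue_s: float = 10.0
    max_run: int = 3  # pseudorandom constraint: <= 3 consecutive same-cue trials
    dsplus_press_prob: float = 0.96
    dsminus_press_prob: float = 0.27
    preset: str = "custom"


def gain_for_sd(
    baseline_hz: float, sd_units: float, n_trials: int = 50, bin_width: float = 0.05
) -> float:
    """Gain whose rate increment equals ``sd_units`` baseline SDs.

    The SD here is the sampling SD of a trial-averaged 50 ms bin rate of a
    Poisson unit, sqrt(b / (bin_width * n_trials)) — the scale against which
    the z-score classifier operates.
    """
    sd = np.sqrt(baseline_hz / (bin_width * n_trials))
    return 1.0 + sd_units * sd / baseline_hz


def _lognormal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    return rng.lognormal(mu, np.sqrt(sigma2), size)


# -- presets calibrated to the recorded control / post-stress populations ----

def _dmpfc_preset(name: str) -> AreaConfig:
    base = dict(n_units=35, baseline_mean_hz=6.0, baseline_sd_hz=4.5)
    if name == "control":
        epochs = {
            "ToneR": EpochEffect(0.10, 0.04, gain_activated=2.2),
            "ToneS": EpochEffect(0.13, 0.05, gain_activated=2.0, gain_inhibited=0.4),
            "Lever": EpochEffect(0.11, 0.08, gain_activated=2.2),
        }
    elif name == "isd_day1":
        base["baseline_mean_hz"] = 6.4
        epochs = {
            "ToneR": EpochEffect(0.01, 0.01, gain_activated=2.0),
            "ToneS": EpochEffect(0.03, 0.05, gain_activated=1.5, gain_inhibited=0.4),
            "Lever": EpochEffect(0.11, 0.07, gain_activated=2.2),
        }
    else:  # isd_day15: proportions near control, weaker sustained drive
        base["baseline_mean_hz"] = 6.1
        epochs = {
            "ToneR": EpochEffect(0.07, 0.04, gain_activated=2.0),
            "ToneS": EpochEffect(0.08, 0.04, gain_activated=1.5, gain_inhibited=0.4),
            "Lever": EpochEffect(0.09, 0.06, gain_activated=2.2),
        }
    return AreaConfig(epochs=epochs, **base)


def _vta_preset(name: str) -> AreaConfig:
    base = dict(
        n_units=9, baseline_mean_hz=6.4, baseline_sd_hz=5.0, da_fraction=0.7,
        ds_minus_scale=0.35,
    )
    if name == "control":
        epochs = {
            "ToneR": EpochEffect(0.34, 0.03, gain_activated=2.6),
            "ToneS": EpochEffect(0.22, 0.03, gain_activated=1.9, gain_inhibited=0.4),
            "Lever": EpochEffect(0.84, 0.03, gain_activated=3.0),
        }
    elif name == "isd_day1":
        base["baseline_mean_hz"] = 12.0  # non-DA rates rise after stress
        epochs = {
            "ToneR": EpochEffect(0.60, 0.04, gain_activated=3.0),
            "ToneS": EpochEffect(0.33, 0.01, gain_activated=1.9, gain_inhibited=0.4),
            "Lever": EpochEffect(0.74, 0.09, gain_activated=3.0),
        }
    else:  # isd_day15: near-control proportions, attenuated gains
        base["baseline_mean_hz"] = 14.0
        epochs = {
            "ToneR": EpochEffect(0.27, 0.03, gain_activated=1.7),
            "ToneS": EpochEffect(0.20, 0.04, gain_activated=1.4, gain_inhibited=0.6),
            "Lever": EpochEffect(0.75, 0.06, gain_activated=1.9),
        }
    return AreaConfig(epochs=epochs, **base)


def preset_config(name: str) -> SimConfig:
    """Named study condition: 'control', 'isd_day1' or 'isd_day15'."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    return SimConfig(
        areas={"dmPFC": _dmpfc_preset(name), "VTA": _vta_preset(name)},
        preset=name,
    )


# -- trial schedule ----------------------------------------------------------

def make_trial_table(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Pseudorandom 50+50 trial schedule with presses, omissions and timing."""
    n = cfg.n_trials_per_cue
    # constrained sequential draw: pick the next cue in proportion to the
    # remaining counts, but never extend a run beyond max_run; rare dead ends
    # (all remaining trials share one cue) restart the draw
    labels = None
    for _ in range(1000):
        remaining = {"DS+": n, "DS-": n}
        seq: list[str] = []
        run = 0
        ok = True
        while remaining["DS+"] + remaining["DS-"] > 0:
            choices = [c for c in ("DS+", "DS-") if remaining[c] > 0]
            if seq and run >= cfg.max_run:
                choices = [c for c in choices if c != seq[-1]]
            if not choices:
                ok = False
                break
            weights = np.array([remaining[c] for c in choices], float)
            pick = rng.choice(len(choices), p=weights / weights.sum())
            c = choices[pick]
            run = run + 1 if seq and c == seq[-1] else 1
            seq.append(c)
            remaining[c] -= 1
        if ok:
            labels = np.array(seq, dtype=object)
            break
    if labels is None:  # pragma: no cover - dead ends are rare
        raise RuntimeError("could not satisfy the pseudorandom run constraint")

    cue_onsets = cfg.first_cue_s + cfg.trial_spacing_s * np.arange(2 * n)
    lever_onsets = cue_onsets + cfg.tone_to_lever_s
    press, omit = [], []
    for i, cue in enumerate(labels):
        p = cfg.dsplus_press_prob if cue == "DS+" else cfg.dsminus_press_prob
        if rng.random() < p:
            lat = (
                max(0.2, rng.normal(0.9, 0.3))
                if cue == "DS+"
                else float(np.clip(rng.normal(3.8, 1.0), 0.3, 9.5))
            )
            press.append(lever_onsets[i] + lat)
            omit.append(False)
        else:
            press.append(np.nan)
            omit.append(True)
    return pd.DataFrame(
        {
            "trial_id": np.arange(2 * n),
            "cue_type": labels,
            "cue_onset_s": cue_onsets,
            "lever_onset_s": lever_onsets,
            "press_time_s": press,
            "omission": omit,
        }
    )


# -- units -------------------------------------------------------------------

@dataclass
class UnitTruth:
    unit_id: str
    area: str
    cell_type: str  # DA | nonDA | untyped (dmPFC)
    baseline_hz: float
    epoch_labels: dict[str, str]  # epoch -> activated | inhibited | none
    gains: dict[str, float]  # DS+ gain per epoch (1.0 when none)


@dataclass
class GroundTruth:
    animal_id: str
    group: str
    session: str
    preset: str
    seed: int
    units: list[UnitTruth]

    def planted_fraction(self, area: str, epoch: str, label: str = "activated") -> float:
        us = [u for u in self.units if u.area == area]
        return sum(u.epoch_labels[epoch] == label for u in us) / len(us)


def _draw_unit_params(
    area: str, cfg: AreaConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Baseline rates, waveform durations and true cell types for one area."""
    n = cfg.n_units
    if area == "VTA":
        is_da = rng.random(n) < (cfg.da_fraction if cfg.da_fraction is not None else 0.0)
        rates = np.where(
            is_da,
            np.clip(_lognormal(rng, cfg.da_rate_mean_hz, cfg.da_rate_sd_hz, n), 0.5, 11.0),
            np.clip(_lognormal(rng, cfg.baseline_mean_hz, cfg.baseline_sd_hz, n), 0.5, 45.0),
        )
        wf = np.where(
            is_da,
            np.clip(rng.normal(*cfg.da_waveform_ms, n), 1.25, 2.5),
            np.clip(rng.normal(*cfg.nonda_waveform_ms, n), 0.3, 1.15),
        )
        types = ["DA" if d else "nonDA" for d in is_da]
        return rates, wf, types
    rates = np.clip(_lognormal(rng, cfg.baseline_mean_hz, cfg.baseline_sd_hz, n), 0.5, 45.0)
    return rates, np.full(n, np.nan), ["untyped"] * n


def _spike_train(
    baseline_hz: float,
    gains: dict[str, float],
    trials: pd.DataFrame,
    ds_minus_scale: float,
    t_end: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Piecewise-constant-rate Poisson spikes over one whole session.

    Rate is baseline everywhere except inside the epoch windows of each
    trial, where it is baseline × gain; DS− trials use the diluted gain.
    """
    # segment breakpoints: [start, stop, rate]
    segs: list[tuple[float, float, float]] = []
    cursor = 0.0
    onsets = trials["cue_onset_s"].to_numpy(float)
    cues = trials["cue_type"].to_numpy(object)
    for t0, cue in zip(onsets, cues):
        for name, (w0, w1) in EPOCH_WINDOWS.items():
            g = gains.get(name, 1.0)
            if g == 1.0:
                continue
            if cue == "DS-":
                g = 1.0 + (g - 1.0) * ds_minus_scale
            a, b = t0 + w0, t0 + w1
            if a > cursor:
                segs.append((cursor, a, baseline_hz))
            segs.append((a, b, baseline_hz * g))
            cursor = b
    if t_end > cursor:
        segs.append((cursor, t_end, baseline_hz))

    times = []
    for a, b, rate in segs:
        k = rng.poisson(rate * (b - a))
        if k:
            times.append(rng.uniform(a, b, k))
    if not times:
        return np.empty(0)
    st = np.sort(np.concatenate(times))
    # strict ascent required by the data model; exact float duplicates from a
    # continuous-time draw are essentially impossible but cheap to drop
    return st[np.r_[True, np.diff(st) > 0]]


def simulate_session(
    cfg: SimConfig,
    animal_id: str,
    group: str,
    session: str,
    seed: int,
) -> tuple[SessionBundle, GroundTruth]:
    """One animal-session: trial table, all units' spike trains, ground truth."""
    rng = np.random.default_rng(seed)
    trials = make_trial_table(cfg, rng)
    t_end = float(trials["lever_onset_s"].iloc[-1] + 11.0)

    units: list[UnitRecord] = []
    truths: list[UnitTruth] = []
    for area, acfg in cfg.areas.items():
        rates, wfs, types = _draw_unit_params(area, acfg, rng)
        for i in range(acfg.n_units):
            labels: dict[str, str] = {}
            gains: dict[str, float] = {}
            for name in EPOCH_WINDOWS:
                eff = acfg.epochs.get(name)
                if eff is None:
                    labels[name] = "none"
                    gains[name] = 1.0
                    continue
                u = rng.random()
                if u < eff.frac_activated:
                    labels[name] = "activated"
                    gains[name] = eff.gain_activated
                elif u < eff.frac_activated + eff.frac_inhibited:
                    labels[name] = "inhibited"
                    gains[name] = eff.gain_inhibited
                else:
                    labels[name] = "none"
                    gains[name] = 1.0
            uid = f"{animal_id}-{area}-{i:03d}"
            st = _spike_train(
                rates[i], gains, trials, acfg.ds_minus_scale, t_end, rng
            )
            units.append(
                UnitRecord(
                    unit_id=uid, animal_id=animal_id, group=group,
                    session=session, area=area, spike_times=st,
                    waveform_ms=None if np.isnan(wfs[i]) else float(wfs[i]),
                )
            )
            truths.append(
                UnitTruth(uid, area, types[i], float(rates[i]), labels, gains)
            )
    bundle = SessionBundle(
        units=units, trials=trials, animal_id=animal_id, group=group, session=session
    )
    truth = GroundTruth(animal_id, group, session, cfg.preset, seed, truths)
    return bundle, truth


def simulate_cohort(
    cfg: SimConfig,
    group: str,
    session: str,
    n_animals: int,
    seed: int,
) -> list[tuple[SessionBundle, GroundTruth]]:
    """Independent animal-sessions with per-animal seeds fanned out from one
    master seed (SeedSequence spawning keeps the streams non-overlapping)."""
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_animals)
    out = []
    for i, child in enumerate(children):
        animal_seed = int(child.generate_state(1)[0] % (2**31))
        out.append(
            simulate_session(
                cfg, animal_id=f"{group}-{session}-rat{i:02d}", group=group,
                session=session, seed=animal_seed,
            )
        )
    return out
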