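"""Session data model and plain-text (TSV) bundle I/O.

A recording session is represented by a :class:`SessionBundle`: the spike
trains and metadata of all units recorded simultaneously in one animal on one
session day, plus the trial event table of that session.  Bundles are stored
as three UTF-8 tab-separated files (``spikes.tsv``, ``units.tsv``,
``events.tsv``) so that fixtures are diff-able and language-neutral.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "UnitRecord",
    "SessionBundle",
    "FormatError",
    "ValidationError",
    "validate_trials",
    "read_session_bundle",
    "write_session_bundle",
    "write_results",
]

GROUPS = ("control", "stress")
SESSIONS = ("day1", "day15")
AREAS = ("dmPFC", "VTA")
CUE_TYPES = ("DS+", "DS-")

#: seconds between cue onset and lever extension, fixed by the task design
TONE_TO_LEVER_S = 3.0

EVENT_COLUMNS = [
    "trial_id",
    "cue_type",
    "cue_onset_s",
    "lever_onset_s",
    "press_time_s",
    "omission",
]
UNIT_COLUMNS = ["unit_id", "animal_id", "group", "session", "area", "waveform_ms"]
SPIKE_COLUMNS = ["unit_id", "spike_time_s"]


class FormatError(ValueError):
    """A file does not conform to the expected column layout."""


class ValidationError(ValueError):
    """Data violate an invariant of the session model."""


@dataclass
class UnitRecord:
    """One isolated single unit: identity, metadata and its spike train.

    ``waveform_ms`` (peak-to-trough duration of the mean action potential) is
    only meaningful for VTA units, where it feeds putative-dopamine typing;
    it may be ``None`` for dmPFC units.
    """

    unit_id: str
    animal_id: str
    group: str
    session: str
    area: str
    spike_times: np.ndarray
    waveform_ms: float | None = None

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.group not in GROUPS:
            raise ValidationError(f"unit {self.unit_id}: unknown group {self.group!r}")
        if self.session not in SESSIONS:
            raise ValidationError(
                f"unit {self.unit_id}: unknown session {self.session!r}"
            )
        if self.area not in AREAS:
            raise ValidationError(f"unit {self.unit_id}: unknown area {self.area!r}")
        if self.spike_times.size:
            if self.spike_times[0] < 0:
                raise ValidationError(f"unit {self.unit_id}: negative spike times")
            if np.any(np.diff(self.spike_times) <= 0):
                raise ValidationError(
                    f"unit {self.unit_id}: spike times not strictly ascending"
                )
        if self.waveform_ms is not None and not self.waveform_ms > 0:
            raise ValidationError(
                f"unit {self.unit_id}: waveform duration must be > 0"
            )


def validate_trials(trials: pd.DataFrame, max_per_cue: int = 50) -> pd.DataFrame:
    """Validate a trial event table and return it with normalized dtypes.

    Enforced invariants: required columns present; cue onsets strictly
    ascending; lever extends exactly 3 s after the tone; omission trials have
    no press time; at most ``max_per_cue`` trials per cue type.
    """
    missing = [c for c in EVENT_COLUMNS if c not in trials.columns]
    if missing:
        raise FormatError(f"events table missing required column(s): {missing}")
    trials = trials.copy()
    trials["omission"] = trials["omission"].astype(int).astype(bool)
    bad_cues = set(trials["cue_type"]) - set(CUE_TYPES)
    if bad_cues:
        raise ValidationError(f"unknown cue types {sorted(bad_cues)}")
    onsets = trials["cue_onset_s"].to_numpy(float)
    if np.any(np.diff(onsets) <= 0):
        raise ValidationError("cue onsets are not strictly ascending")
    gap = trials["lever_onset_s"].to_numpy(float) - onsets
    if not np.allclose(gap, TONE_TO_LEVER_S, atol=1e-6):
        bad = trials["trial_id"].iloc[int(np.argmax(np.abs(gap - TONE_TO_LEVER_S)))]
        raise ValidationError(
            f"lever_onset must equal cue_onset + {TONE_TO_LEVER_S} s "
            f"(violated at trial {bad})"
        )
    omitted = trials["omission"].to_numpy()
    if np.any(omitted & trials["press_time_s"].notna().to_numpy()):
        raise ValidationError("omission trials must not carry a press time")
    counts = trials["cue_type"].value_counts()
    if (counts > max_per_cue).any():
        raise ValidationError(
            f"more than {max_per_cue} trials for cue type(s) "
            f"{list(counts[counts > max_per_cue].index)}"
        )
    return trials


@dataclass
class SessionBundle:
    """All units and trial events of one animal-session: the atomic input."""

    units: list[UnitRecord]
    trials: pd.DataFrame
    animal_id: str
    group: str
    session: str

    def __post_init__(self) -> None:
        self.trials = validate_trials(self.trials)
        for u in self.units:
            if u.animal_id != self.animal_id or u.session != self.session:
                raise ValidationError(
                    f"unit {u.unit_id} does not belong to animal "
                    f"{self.animal_id}/{self.session}"
                )
        for cue in CUE_TYPES:
            if not (self.trials["cue_type"] == cue).any():
                raise ValidationError(f"no {cue} trials in bundle")

    @property
    def areas(self) -> tuple[str, ...]:
        return tuple(sorted({u.area for u in self.units}))

    def units_in(self, area: str) -> list[UnitRecord]:
        return [u for u in self.units if u.area == area]


def read_session_bundle(
    spikes_path: str | Path, units_path: str | Path, events_path: str | Path
) -> SessionBundle:
    """Read a three-file TSV bundle from disk into a validated SessionBundle.

    Units listed in ``units.tsv`` without any row in ``spikes.tsv`` get an
    empty spike train (with a warning) rather than an error — silent units
    are legitimate.
    """
    spikes = pd.read_csv(spikes_path, sep="\t")
    units = pd.read_csv(units_path, sep="\t")
    events = pd.read_csv(events_path, sep="\t")
    for name, df, cols in (
        ("spikes", spikes, SPIKE_COLUMNS),
        ("units", units, UNIT_COLUMNS),
        ("events", events, EVENT_COLUMNS),
    ):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise FormatError(f"{name} file missing required column(s): {missing}")

    by_unit = {uid: g["spike_time_s"].to_numpy(float) for uid, g in spikes.groupby("unit_id")}
    records = []
    for row in units.itertuples(index=False):
        st = by_unit.get(row.unit_id)
        if st is None:
            warnings.warn(f"unit {row.unit_id} has no spikes; using empty train")
            st = np.empty(0)
        wf = None if pd.isna(row.waveform_ms) else float(row.waveform_ms)
        records.append(
            UnitRecord(
                unit_id=str(row.unit_id),
                animal_id=str(row.animal_id),
                group=str(row.group),
                session=str(row.session),
                area=str(row.area),
                spike_times=st,
                waveform_ms=wf,
            )
        )
    if not records:
        raise ValidationError("units file contains no units")
    animal_ids = {r.animal_id for r in records}
    sessions = {r.session for r in records}
    groups = {r.group for r in records}
    if len(animal_ids) != 1 or len(sessions) != 1 or len(groups) != 1:
        raise ValidationError(
            "bundle must contain exactly one animal/group/session; got "
            f"{animal_ids}/{groups}/{sessions}"
        )
    return SessionBundle(
        units=records,
        trials=events,
        animal_id=animal_ids.pop(),
        group=groups.pop(),
        session=sessions.pop(),
    )


def write_session_bundle(bundle: SessionBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write a bundle as spikes.tsv / units.tsv / events.tsv under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spikes = pd.DataFrame(
        {
            "unit_id": np.repeat(
                [u.unit_id for u in bundle.units],
                [u.spike_times.size for u in bundle.units],
            ),
            "spike_time_s": np.concatenate(
                [u.spike_times for u in bundle.units] or [np.empty(0)]
            ),
        }
    )
    units = pd.DataFrame(
        {
            "unit_id": [u.unit_id for u in bundle.units],
            "animal_id": [u.animal_id for u in bundle.units],
            "group": [u.group for u in bundle.units],
            "session": [u.session for u in bundle.units],
            "area": [u.area for u in bundle.units],
            "waveform_ms": [u.waveform_ms for u in bundle.units],
        }
    )
    events = bundle.trials.copy()
    events["omission"] = events["omission"].astype(int)
    paths = {
        "spikes": out / "spikes.tsv",
        "units": out / "units.tsv",
        "events": out / "events.tsv",
    }
    spikes.to_csv(paths["spikes"], sep="\t", index=False)
    units.to_csv(paths["units"], sep="\t", index=False)
    events.to_csv(paths["events"], sep="\t", index=False)
    return paths


def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    config: dict | None = None,
    seed: int | None = None,
) -> dict:
    """Write named result tables as TSV plus a JSON manifest.

    The manifest records the file list, a hash of the configuration snapshot
    and the master seed, which together are sufficient to reproduce a run.
    """
    if not tables:
        raise ValueError("no result tables to write")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, df in tables.items():
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        files[name] = path.name
    cfg_json = json.dumps(config or {}, sort_keys=True, default=str)
    manifest = {
        "files": files,
        "seed": seed,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "config": config or {},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
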