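"""End-to-end orchestration: simulate → classify → auROC → decode → stats.

``run_pipeline`` executes every analysis stage on simulated cohorts (or
bundles read from disk), writes one TSV per stage plus a JSON manifest, and
renders a markdown report assembled purely from the written tables.  A
single master seed fans out to per-stage and per-animal streams through
``numpy.random.SeedSequence`` spawning, so a rerun with the same
configuration and seed is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .auroc import compute_auroc_profile, epoch_selectivity, shuffle_null
from .celltype import CellTypeConfig, classify_cell_type
from .decoding import DecoderConfig, build_feature_matrix, compare_groups, repeated_decoding
from .io import SessionBundle, read_session_bundle, write_results
from .psth import align_and_bin, basal_rate, zscore_profile
from .responsiveness import EPOCHS, classify_tensor, epoch_mean_activity
from .simulate import preset_config, simulate_cohort
from .stats import chi_square, fisher_exact, phi_effect, t_tests

__all__ = ["PipelineConfig", "run_pipeline", "report", "analyze_bundles"]


@dataclass
class PipelineConfig:
    """Configuration of a full run; defaults mirror the study design
    (7 animals per group, two session days, both areas)."""

    sessions: tuple[str, ...] = ("day1", "day15")
    n_animals: int = 7
    areas: tuple[str, ...] = ("dmPFC", "VTA")
    z_threshold: float = 2.0
    n_shuffles: int = 10
    n_repeats: int = 100
    decode: bool = True
    include_omissions: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        for key in ("sessions", "areas"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg


def _classify_cell(
    bundles: list[SessionBundle], cfg: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-unit labels, basal rates / cell types, and epoch mean activities."""
    label_rows, unit_rows, act_rows = [], [], []
    ct_cfg = CellTypeConfig()
    for bundle in bundles:
        tensors = align_and_bin(bundle, include_omissions=cfg.include_omissions)
        for unit in bundle.units:
            tensor = tensors[unit.unit_id]
            rate = basal_rate(tensor)
            unit_rows.append(
                dict(
                    unit_id=unit.unit_id, animal_id=unit.animal_id,
                    group=unit.group, session=unit.session, area=unit.area,
                    basal_rate_hz=rate, waveform_ms=unit.waveform_ms,
                    cell_type=classify_cell_type(
                        rate, unit.waveform_ms, ct_cfg, area=unit.area
                    ),
                )
            )
            for cue in ("DS+", "DS-"):
                labels = classify_tensor(tensor, cue, cfg.z_threshold)
                for epoch_name, lab in labels.items():
                    label_rows.append(
                        dict(
                            unit_id=unit.unit_id, animal_id=unit.animal_id,
                            group=unit.group, session=unit.session,
                            area=unit.area, cue_type=cue, epoch=epoch_name,
                            label=lab.label, n_sig_pos=lab.n_sig_windows_pos,
                            n_sig_neg=lab.n_sig_windows_neg,
                            degenerate=lab.degenerate,
                        )
                    )
                # epoch mean activity for population comparisons (DS+ focus,
                # but both cue types are recorded)
                for epoch_name, epoch in EPOCHS.items():
                    prof = zscore_profile(tensor, cue, baseline_bins=epoch.baseline)
                    if prof.degenerate:
                        continue
                    act_rows.append(
                        dict(
                            unit_id=unit.unit_id, group=unit.group,
                            session=unit.session, area=unit.area,
                            cue_type=cue, epoch=epoch_name,
                            mean_z=epoch_mean_activity(prof, epoch),
                        )
                    )
    return pd.DataFrame(label_rows), pd.DataFrame(unit_rows), pd.DataFrame(act_rows)


def _selectivity_stage(
    bundles: list[SessionBundle], cfg: PipelineConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-unit epoch selectivity and the shuffle-null proportion table."""
    sel_rows, null_rows = [], []
    by_cell: dict[tuple[str, str, str], list] = {}
    meta: dict[str, dict] = {}
    for bundle in bundles:
        tensors = align_and_bin(bundle, include_omissions=cfg.include_omissions)
        for unit in bundle.units:
            key = (unit.area, unit.group, unit.session)
            by_cell.setdefault(key, []).append(tensors[unit.unit_id])
            meta[unit.unit_id] = dict(
                area=unit.area, group=unit.group, session=unit.session
            )
            prof = compute_auroc_profile(tensors[unit.unit_id])
            for epoch in EPOCHS.values():
                sel = epoch_selectivity(prof, epoch, cfg.z_threshold)
                sel_rows.append(
                    dict(
                        unit_id=unit.unit_id, area=unit.area, group=unit.group,
                        session=unit.session, epoch=epoch.name,
                        delta_auroc=sel.delta_auroc, zscore=sel.zscore,
                        selective=sel.selective, degenerate=sel.degenerate,
                    )
                )
    rng_seeds = np.random.SeedSequence(seed).spawn(len(by_cell))
    for (key, tensors), ss in zip(sorted(by_cell.items()), rng_seeds):
        null = shuffle_null(
            tensors, n_shuffles=cfg.n_shuffles,
            seed=np.random.default_rng(ss), z_threshold=cfg.z_threshold,
        )
        for epoch_name in EPOCHS:
            null_rows.append(
                dict(
                    area=key[0], group=key[1], session=key[2], epoch=epoch_name,
                    observed_prop=null["observed"][epoch_name],
                    shuffle_mean_prop=null["shuffle_mean"][epoch_name],
                    n_units=null["n_units"],
                )
            )
    return pd.DataFrame(sel_rows), pd.DataFrame(null_rows)


def _decode_stage(
    bundles: list[SessionBundle], cfg: PipelineConfig, seed: int
) -> tuple[pd.DataFrame, dict]:
    """LASSO decoding per (area, group, session) cell + group comparisons."""
    rows = []
    results: dict[tuple[str, str, str], object] = {}
    cells = sorted(
        {(a, b.group, b.session) for b in bundles for a in cfg.areas
         if b.units_in(a)}
    )
    seeds = np.random.SeedSequence(seed).spawn(len(cells))
    for (area, group, session), ss in zip(cells, seeds):
        cell_bundles = [
            b for b in bundles if b.group == group and b.session == session
        ]
        features = build_feature_matrix(cell_bundles, area)
        dcfg = DecoderConfig(
            n_repeats=cfg.n_repeats, seed=int(ss.generate_state(1)[0] % (2**31))
        )
        res = repeated_decoding(features, dcfg)
        results[(area, group, session)] = res
        for epoch, accs in res.epoch_accuracies.items():
            rows.append(
                dict(
                    area=area, group=group, session=session, epoch=epoch,
                    mean_accuracy=float(accs.mean()),
                    sd_accuracy=float(accs.std(ddof=1)),
                    top_features=",".join(map(str, res.top_features[epoch])),
                    n_trials=features.y.size,
                )
            )
    return pd.DataFrame(rows), results


def _stats_stage(
    labels: pd.DataFrame,
    activity: pd.DataFrame,
    decode_results: dict,
    areas: tuple[str, ...],
    sessions: tuple[str, ...],
) -> pd.DataFrame:
    """Control-vs-stress comparisons: unit proportions (chi-square / Fisher),
    population activity (t tests) and decoding accuracy (t tests)."""
    rows = []
    for area in areas:
        for session in sessions:
            for epoch in EPOCHS:
                sub = labels[
                    (labels.area == area) & (labels.session == session)
                    & (labels.epoch == epoch) & (labels.cue_type == "DS+")
                ]
                if sub.empty:
                    continue
                table = []
                for group in ("control", "stress"):
                    g = sub[sub.group == group]
                    table.append([
                        int((g.label == "activated").sum()),
                        int((g.label == "inhibited").sum()),
                        int((~g.label.isin(["activated", "inhibited"])).sum()),
                    ])
                obs = np.array(table)
                # drop all-zero columns (e.g. no inhibited units anywhere)
                obs = obs[:, obs.sum(axis=0) > 0]
                if obs.shape[1] < 2 or obs.shape[0] < 2:
                    continue
                if obs.shape == (2, 2) and obs.min() < 5:
                    # small-count convention: exact test instead of chi-square
                    p = fisher_exact(obs)
                    rows.append(
                        dict(
                            area=area, session=session, epoch=epoch,
                            comparison="proportion control vs stress",
                            test="fisher_exact", statistic=np.nan, df=np.nan,
                            p=p, effect=np.nan, effect_name="",
                        )
                    )
                else:
                    res = chi_square(obs)
                    rows.append(
                        dict(
                            area=area, session=session, epoch=epoch,
                            comparison="proportion control vs stress",
                            test="chi_square", statistic=res.chi2, df=res.df,
                            p=res.p, effect=phi_effect(res),
                            effect_name="phi_responsive",
                        )
                    )
                a = activity[
                    (activity.area == area) & (activity.session == session)
                    & (activity.epoch == epoch) & (activity.cue_type == "DS+")
                ]
                x = a[a.group == "control"]["mean_z"].to_numpy()
                y = a[a.group == "stress"]["mean_z"].to_numpy()
                if x.size > 1 and y.size > 1:
                    mode = "independent" if x.size == y.size else "welch"
                    t = t_tests(x, y, mode=mode)
                    rows.append(
                        dict(
                            area=area, session=session, epoch=epoch,
                            comparison="population activity control vs stress",
                            test=f"t_{mode}", statistic=t.t, df=t.df, p=t.p,
                            effect=t.d, effect_name="cohens_d",
                        )
                    )
            for epoch in ("Tone", "Lever"):
                key_c = (area, "control", session)
                key_s = (area, "stress", session)
                if key_c in decode_results and key_s in decode_results:
                    comp = compare_groups(
                        decode_results[key_c], decode_results[key_s]
                    )[epoch]
                    rows.append(
                        dict(
                            area=area, session=session, epoch=epoch,
                            comparison="decoding accuracy control vs stress",
                            test="t_independent", statistic=comp.t, df=comp.df,
                            p=comp.p, effect=comp.d, effect_name="cohens_d",
                        )
                    )
    return pd.DataFrame(rows)


def analyze_bundles(
    bundles: list[SessionBundle], cfg: PipelineConfig
) -> dict[str, pd.DataFrame]:
    """All analysis stages on in-memory bundles; returns the result tables."""
    from .responsiveness import proportion_summary

    ss = np.random.SeedSequence(cfg.seed).spawn(2)
    labels, units, activity = _classify_cell(bundles, cfg)
    proportions = proportion_summary(
        labels, by=["area", "group", "session", "cue_type", "epoch"]
    )
    selectivity, shuffle_props = _selectivity_stage(
        bundles, cfg, seed=int(ss[0].generate_state(1)[0] % (2**31))
    )
    tables = {
        "labels": labels,
        "units": units,
        "activity": activity,
        "proportions": proportions,
        "selectivity": selectivity,
        "selectivity_null": shuffle_props,
    }
    decode_results: dict = {}
    if cfg.decode:
        decoding, decode_results = _decode_stage(
            bundles, cfg, seed=int(ss[1].generate_state(1)[0] % (2**31))
        )
        tables["decoding"] = decoding
    tables["stats"] = _stats_stage(
        labels, activity, decode_results, cfg.areas, cfg.sessions
    )
    return tables


def run_pipeline(
    out_dir: str | Path,
    cfg: PipelineConfig | None = None,
    input_dirs: list[str | Path] | None = None,
) -> dict:
    """Full run on simulated cohorts (default) or bundles read from disk.

    Each ``input_dirs`` entry must hold spikes.tsv/units.tsv/events.tsv.
    Returns the manifest written alongside the TSV outputs.
    """
    cfg = cfg or PipelineConfig()
    if input_dirs is not None:
        if not input_dirs:
            raise ValueError("no input directories given")
        bundles = [
            read_session_bundle(
                Path(d) / "spikes.tsv", Path(d) / "units.tsv", Path(d) / "events.tsv"
            )
            for d in input_dirs
        ]
    else:
        bundles = []
        cells = [
            (group, session)
            for session in cfg.sessions
            for group in ("control", "stress")
        ]
        seeds = np.random.SeedSequence(cfg.seed).spawn(len(cells))
        for (group, session), ss in zip(cells, seeds):
            preset = "control" if group == "control" else f"isd_{session}"
            sim = simulate_cohort(
                preset_config(preset), group, session, cfg.n_animals,
                seed=int(ss.generate_state(1)[0] % (2**31)),
            )
            bundles.extend(b for b, _ in sim)
    tables = analyze_bundles(bundles, cfg)
    manifest = write_results(tables, out_dir, config=asdict(cfg), seed=cfg.seed)
    (Path(out_dir) / "report.md").write_text(report(out_dir))
    return manifest


def _fmt_table(df: pd.DataFrame) -> str:
    return df.to_string(index=False, float_format=lambda v: f"{v:.3f}")


def report(out_dir: str | Path) -> str:
    """Markdown summary assembled from the written stage TSVs (no numbers are
    recomputed here — every value traces to a table cell)."""
    out = Path(out_dir)
    sections = [
        ("Responsive-unit proportions", "proportions.tsv"),
        ("Cue selectivity (auROC) vs shuffle null", "selectivity_null.tsv"),
        ("Population decoding accuracy", "decoding.tsv"),
        ("Group statistics", "stats.tsv"),
    ]
    parts = ["# Session analysis report\n"]
    for title, fname in sections:
        path = out / fname
        if not path.exists():
            if fname == "decoding.tsv":
                continue  # decoding is optional
            raise FileNotFoundError(f"missing stage output: {fname}")
        df = pd.read_csv(path, sep="\t")
        parts.append(f"## {title}\n\n```\n{_fmt_table(df)}\n```\n")
    return "\n".join(parts)
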