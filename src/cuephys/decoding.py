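"""L1-penalized logistic (LASSO) population decoding of cue value.

Each trial is summarized by 100 features: the per-bin average, across the
simultaneously recorded units of that trial's session, of baseline-z
normalized single-trial firing rates.  Trials are pooled across animals of
one (area, group, session) cell and labeled 1 for DS+ / 0 for DS−.  One
decoding repeat draws a stratified 80/20 train/test split, picks the L1
strength by 5-fold cross-validated accuracy on the training set (ties go to
the stronger penalty), refits on the full training set, and records the
held-out accuracy and the features with nonzero coefficients.  Over 100
repeats the per-feature selection frequencies are tallied and the 10 most
frequent features per epoch mask (Tone, Lever) are reported.  Per-repeat
epoch accuracies come from restricted models refit on up to 10 of the
repeat's own train-side selected features, which keeps the accuracy
estimate free of selection leakage (gain-free data decodes at chance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler

from .io import SessionBundle
from .psth import AlignedTensor, BASELINE_BINS, DEFAULT_GRID, align_and_bin
from .stats import MeanComparisonResult, t_tests

__all__ = [
    "DecoderConfig",
    "FeatureMatrix",
    "RepeatResult",
    "DecodeResult",
    "build_feature_matrix",
    "decode_once",
    "repeated_decoding",
    "compare_groups",
]

log = logging.getLogger(__name__)

#: feature masks: Tone covers the cue period 0–3 s (bins 20–79),
#: Lever covers the lever second 3–4 s (bins 80–99)
EPOCH_MASKS: dict[str, range] = {"Tone": range(20, 80), "Lever": range(80, 100)}


@dataclass(frozen=True)
class DecoderConfig:
    n_repeats: int = 100
    train_fraction: float = 0.8
    n_folds: int = 5
    n_lambdas: int = 30
    lambda_ratio: float = 1e-3  # weakest penalty = lambda_max * ratio
    top_k: int = 10
    normalization: str = "baseline_z"  # or "raw"
    accuracy_mode: str = "epoch_topk"  # or "global"
    seed: int = 0


@dataclass
class FeatureMatrix:
    """Trials × 100 population-average features with binary cue labels."""

    X: np.ndarray  # (n_trials, n_bins)
    y: np.ndarray  # (n_trials,) 1 = DS+, 0 = DS−
    session_ids: np.ndarray  # (n_trials,) provenance of each trial


def _normalized_unit_rates(tensor: AlignedTensor, normalization: str) -> np.ndarray | None:
    """Per-trial, per-bin rates of one unit, optionally baseline z-scored.

    The z reference is the unit's own single-trial baseline-bin rates pooled
    over all trials (mean and population SD), so normalization is fixed per
    unit and cannot leak trial labels.  Units with a silent, flat baseline
    (SD = 0) carry no commensurable signal and are dropped with a log note.
    """
    rates = tensor.counts / tensor.grid.bin_width
    if normalization == "raw":
        return rates
    base = rates[:, list(BASELINE_BINS)]
    mu = base.mean()
    sigma = base.std(ddof=0)
    if sigma == 0.0:
        log.warning("unit %s: flat baseline, excluded from features", tensor.unit_id)
        return None
    return (rates - mu) / sigma


def build_feature_matrix(
    bundles: list[SessionBundle],
    area: str,
    normalization: str = "baseline_z",
    include_omissions: bool = True,
) -> FeatureMatrix:
    """Stack per-trial population-average features across sessions.

    Feature ``b`` of a trial is the mean over that session's ``area`` units
    of the normalized single-trial rate in bin ``b``; rows from all bundles
    are concatenated (trials pooled across animals).
    """
    X_rows, y_rows, sid_rows = [], [], []
    for bundle in bundles:
        units = bundle.units_in(area)
        if not units:
            log.warning("session %s has no %s units; skipped", bundle.animal_id, area)
            continue
        tensors = align_and_bin(bundle, include_omissions=include_omissions)
        per_unit = [
            _normalized_unit_rates(tensors[u.unit_id], normalization) for u in units
        ]
        per_unit = [r for r in per_unit if r is not None]
        if not per_unit:
            log.warning("session %s: no usable %s units; skipped", bundle.animal_id, area)
            continue
        pop = np.mean(per_unit, axis=0)  # (n_trials, n_bins)
        trials = bundle.trials
        if not include_omissions:
            trials = trials[~trials["omission"]]
        labels = (trials["cue_type"] == "DS+").to_numpy(int)
        X_rows.append(pop)
        y_rows.append(labels)
        sid_rows.append(np.full(len(labels), f"{bundle.animal_id}/{bundle.session}"))
    if not X_rows:
        raise ValueError(f"no sessions with {area} units")
    return FeatureMatrix(
        X=np.vstack(X_rows),
        y=np.concatenate(y_rows),
        session_ids=np.concatenate(sid_rows),
    )


def _lambda_grid(X_std: np.ndarray, y: np.ndarray, cfg: DecoderConfig) -> np.ndarray:
    """Descending L1-strength grid from the smallest all-zero penalty down.

    lambda_max = max_j |x_j'(y − ȳ)| / n is the smallest penalty for which
    the L1 logistic solution is fully sparse; the grid spans three decades
    below it (configurable).
    """
    n = y.size
    lam_max = np.abs(X_std.T @ (y - y.mean())).max() / n
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * cfg.lambda_ratio, cfg.n_lambdas)


def _fit_l1(X: np.ndarray, y: np.ndarray, lam: float) -> LogisticRegression:
    # sklearn's liblinear objective is ||w||_1 + C * sum(loss); the usual
    # per-sample penalty lambda corresponds to C = 1 / (n * lambda)
    C = 1.0 / (X.shape[0] * lam)
    model = LogisticRegression(
        l1_ratio=1.0, C=C, solver="liblinear", max_iter=2000, tol=1e-6
    )
    model.fit(X, y)
    return model


@dataclass
class RepeatResult:
    seed: int
    lam: float
    accuracy: float
    selected: np.ndarray  # nonzero-coefficient feature indices
    coef: np.ndarray  # full standardized coefficient vector
    train_idx: np.ndarray
    test_idx: np.ndarray


def decode_once(
    features: FeatureMatrix, cfg: DecoderConfig, split_seed: int
) -> RepeatResult:
    """One repeat: stratified split, CV-tuned L1 fit, held-out accuracy."""
    X, y = features.X, features.y
    seed = split_seed
    for attempt in range(10):
        idx_train, idx_test = train_test_split(
            np.arange(y.size),
            train_size=cfg.train_fraction,
            stratify=y,
            random_state=(seed + attempt) % (2**31),
        )
        if len(np.unique(y[idx_train])) == 2 and len(np.unique(y[idx_test])) == 2:
            break
        log.warning("degenerate split at seed %d; resampling", seed + attempt)
    X_tr, y_tr = X[idx_train], y[idx_train]
    X_te, y_te = X[idx_test], y[idx_test]

    scaler = StandardScaler().fit(X_tr)
    X_tr_s = scaler.transform(X_tr)
    X_te_s = scaler.transform(X_te)

    lambdas = _lambda_grid(X_tr_s, y_tr, cfg)
    cv = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=seed % (2**31))
    folds = list(cv.split(X_tr_s, y_tr))
    fold_acc = np.zeros((len(folds), lambdas.size))
    for f, (tr, va) in enumerate(folds):
        fold_scaler = StandardScaler().fit(X_tr[tr])
        Xf_tr = fold_scaler.transform(X_tr[tr])
        Xf_va = fold_scaler.transform(X_tr[va])
        for j, lam in enumerate(lambdas):
            m = _fit_l1(Xf_tr, y_tr[tr], lam)
            fold_acc[f, j] = (m.predict(Xf_va) == y_tr[va]).mean()
    cv_acc = fold_acc.mean(axis=0)
    # one-standard-error rule: strongest penalty whose CV accuracy is within
    # one SE of the best.  Lambdas descend, so the first qualifying index is
    # the sparsest model; this also breaks exact ties toward sparsity and
    # keeps label-free data at the empty (chance) model.
    best = int(np.argmax(cv_acc))
    se_best = fold_acc[:, best].std(ddof=1) / np.sqrt(len(folds))
    lam = float(lambdas[np.argmax(cv_acc >= cv_acc[best] - se_best)])

    model = _fit_l1(X_tr_s, y_tr, lam)
    selected = np.flatnonzero(model.coef_[0])
    accuracy = float((model.predict(X_te_s) == y_te).mean())
    return RepeatResult(
        seed=split_seed, lam=lam, accuracy=accuracy, selected=selected,
        coef=model.coef_[0].copy(), train_idx=idx_train, test_idx=idx_test,
    )


@dataclass
class DecodeResult:
    repeats: list[RepeatResult]
    selection_frequency: np.ndarray  # (n_features,) counts over repeats
    top_features: dict[str, np.ndarray]  # epoch -> top-k feature indices
    epoch_accuracies: dict[str, np.ndarray]  # epoch -> (n_repeats,) accuracies
    config: DecoderConfig

    @property
    def mean_epoch_accuracy(self) -> dict[str, float]:
        return {k: float(v.mean()) for k, v in self.epoch_accuracies.items()}

    @property
    def overall_accuracies(self) -> np.ndarray:
        return np.array([r.accuracy for r in self.repeats])


def _top_k_in_mask(
    freq: np.ndarray, mask: range, k: int
) -> np.ndarray:
    """Most frequently selected features inside a mask (ties → earlier bin)."""
    idx = np.array(list(mask))
    ever = idx[freq[idx] > 0]
    if ever.size < k:
        log.warning("only %d ever-selected features in mask; using all", ever.size)
        chosen = ever
    else:
        order = np.lexsort((ever, -freq[ever]))
        chosen = ever[order][:k]
    return np.sort(chosen)


def repeated_decoding(features: FeatureMatrix, cfg: DecoderConfig) -> DecodeResult:
    """Run the full repeated-split protocol and the top-k epoch accuracies.

    Deterministic for a fixed ``cfg.seed``: per-repeat split seeds are drawn
    from a seeded generator up front.
    """
    if cfg.n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    repeat_seeds = rng.integers(0, 2**31 - 1, size=cfg.n_repeats)
    repeats = [decode_once(features, cfg, int(s)) for s in repeat_seeds]

    n_feat = features.X.shape[1]
    freq = np.zeros(n_feat, dtype=int)
    for r in repeats:
        freq[r.selected] += 1

    top_features: dict[str, np.ndarray] = {}
    epoch_acc: dict[str, np.ndarray] = {}
    for name, mask in EPOCH_MASKS.items():
        if cfg.accuracy_mode == "global":
            top_features[name] = np.array(list(mask))
            epoch_acc[name] = np.array([r.accuracy for r in repeats])
            continue
        # the cross-repeat frequency ranking is the reported top-k set ...
        top_features[name] = _top_k_in_mask(freq, mask, cfg.top_k)
        # ... but each repeat's restricted accuracy uses only features that
        # repeat selected on its own training split (ranked by coefficient
        # magnitude), so held-out trials never influence the selection and
        # gain-free data decodes at chance
        mask_arr = np.array(list(mask))
        accs = np.empty(cfg.n_repeats)
        for i, r in enumerate(repeats):
            in_mask = r.selected[np.isin(r.selected, mask_arr)]
            order = np.argsort(-np.abs(r.coef[in_mask]), kind="stable")
            chosen = np.sort(in_mask[order[: cfg.top_k]])
            y_tr, y_te = features.y[r.train_idx], features.y[r.test_idx]
            if chosen.size == 0:
                # no epoch feature survived the penalty: majority-class rule
                majority = int(y_tr.mean() >= 0.5)
                accs[i] = (y_te == majority).mean()
                continue
            X_tr = features.X[r.train_idx][:, chosen]
            X_te = features.X[r.test_idx][:, chosen]
            scaler = StandardScaler().fit(X_tr)
            m = _fit_l1(scaler.transform(X_tr), y_tr, r.lam)
            accs[i] = (m.predict(scaler.transform(X_te)) == y_te).mean()
        epoch_acc[name] = accs
    return DecodeResult(
        repeats=repeats, selection_frequency=freq, top_features=top_features,
        epoch_accuracies=epoch_acc, config=cfg,
    )


def compare_groups(
    result_a: DecodeResult, result_b: DecodeResult
) -> dict[str, MeanComparisonResult]:
    """Independent t test per epoch on the per-repeat accuracy vectors
    (df = 2·n_repeats − 2) with Cohen's d."""
    out = {}
    for name in result_a.epoch_accuracies:
        a = result_a.epoch_accuracies[name]
        b = result_b.epoch_accuracies[name]
        if a.size != b.size:
            raise ValueError("groups must have equal repeat counts")
        out[name] = t_tests(a, b, mode="independent")
    return out
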