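"""End-to-end experiment drivers for the two evaluation protocols.

* Subject-dependent: one stratified session-level 80/10/10 split, heavily
  overlapping short windows, threshold calibrated on validation windows via
  Youden's J, reported at window level and (by mean-probability
  aggregation) at session level.
* Cross-subject: subject-grouped K-fold cross-validation, out-of-fold
  window probabilities aggregated to session scores, and one global
  threshold calibrated on the pooled out-of-fold session scores.

Drivers consume preprocessed records; feature extraction, windowing,
training and evaluation all happen here so a report is reproducible from a
config and a seed alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .. import features, windowing
from ..records import ConfigurationError, SessionRecord
from ..nn import (
    ABLATION_VARIANTS,
    ResNetSE,
    ResNetSESpec,
    ResTcnSEAttention,
    ResTcnSpec,
    TrainConfig,
    train_model,
)
from .metrics import (
    MetricsReport,
    aggregate_session_scores,
    classification_report,
    exact_binomial_test,
    roc_auc,
    wilson_interval,
    youden_threshold,
)
from .splits import FoldPlan, SplitPlan, grouped_folds, inner_validation_indices, osw_split


def _build_windows(records: list[SessionRecord], win_s: float, hop_s: float) -> dict:
    windows = [w for rec in records for w in windowing.segment_session(rec, win_s, hop_s)]
    packed = windowing.stack_windows(windows)
    packed["X"] = windowing.zscore_array(packed["X"])
    return packed


def _window_features(records: list[SessionRecord], win_s: float, hop_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Z-scored DWT and FEATS vectors aligned with ``_build_windows`` order."""
    dwt_rows, feats_rows = [], []
    for rec in records:
        for w in windowing.segment_session(rec, win_s, hop_s):
            wz = windowing.zscore_window(w)
            dwt_rows.append(features.dwt_features(wz))
            feats_rows.append(features.feats_vector(wz, rec.channel_names))
    return np.array(dwt_rows), np.array(feats_rows)


def _subset_indices(session_ids: np.ndarray, plan: SplitPlan) -> dict[str, np.ndarray]:
    return {
        name: np.array([i for i, s in enumerate(session_ids) if s in getattr(plan, name)], dtype=int)
        for name in ("train", "val", "test")
    }


def _standardize_features(train: np.ndarray, *others: np.ndarray) -> tuple[np.ndarray, ...]:
    mu = train.mean(axis=0, keepdims=True)
    sd = train.std(axis=0, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return tuple((a - mu) / sd for a in (train, *others))


def _make_model(name: str, win_samples: int, n_channels: int, spec=None, seed: int = 0,
                dwt_dim: int = 175, feats_dim: int = 167):
    if name == "resnet_se":
        return ResNetSE(win_samples, n_channels, spec or ResNetSESpec(), seed=seed)
    if name in ABLATION_VARIANTS:
        flags = ABLATION_VARIANTS[name]
        return ResTcnSEAttention(
            win_samples, n_channels, dwt_dim=dwt_dim, feats_dim=feats_dim,
            spec=spec or ResTcnSpec(), seed=seed, **flags,
        )
    raise ConfigurationError(f"unknown model {name!r}")


def _dump(payload: dict, out_dir: str | Path | None, name: str) -> None:
    if out_dir is None:
        return
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / name, "w") as fh:
        json.dump(payload, fh, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    return str(obj)


def run_subject_dependent(
    records: list[SessionRecord],
    model_name: str = "res_tcn_se_attention",
    model_spec=None,
    train_config: TrainConfig | None = None,
    win_s: float = 2.0,
    hop_s: float = 0.25,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict:
    """Session-disjoint 80/10/10 protocol; returns window- and session-level
    reports plus the validation-calibrated operating point."""
    train_config = train_config or TrainConfig(loss="bce", batch_size=128, mixup_alpha=0.0,
                                               schedule="cosine_restarts", seed=seed)
    plan = osw_split(records, seed=seed)
    packed = _build_windows(records, win_s, hop_s)
    idx = _subset_indices(packed["session"], plan)

    hybrid = model_name != "resnet_se"
    inputs: tuple[np.ndarray, ...]
    if hybrid:
        dwt, feats = _window_features(records, win_s, hop_s)
        d_tr, d_va, d_te = _standardize_features(dwt[idx["train"]], dwt[idx["val"]], dwt[idx["test"]])
        f_tr, f_va, f_te = _standardize_features(feats[idx["train"]], feats[idx["val"]], feats[idx["test"]])
        make_inputs = {
            "train": (packed["X"][idx["train"]], d_tr, f_tr),
            "val": (packed["X"][idx["val"]], d_va, f_va),
            "test": (packed["X"][idx["test"]], d_te, f_te),
        }
    else:
        make_inputs = {k: (packed["X"][idx[k]],) for k in idx}

    y = packed["y"]
    model = _make_model(model_name, packed["X"].shape[1], packed["X"].shape[2],
                        spec=model_spec, seed=seed)
    history = train_model(model, make_inputs["train"], y[idx["train"]],
                          make_inputs["val"], y[idx["val"]], train_config)

    val_probs = model.predict_proba(make_inputs["val"])
    op = youden_threshold(val_probs, y[idx["val"]], source="validation_windows")
    test_probs = model.predict_proba(make_inputs["test"])
    y_test = y[idx["test"]]
    window_report = classification_report(
        (test_probs >= op.threshold).astype(int), y_test, scores=test_probs, with_wilson=True
    )
    sessions = aggregate_session_scores(
        test_probs, packed["session"][idx["test"]], packed["subject"][idx["test"]], y_test
    )
    s_scores = np.array([s.score for s in sessions])
    s_labels = np.array([s.label for s in sessions])
    session_report = classification_report(
        (s_scores >= op.threshold).astype(int), s_labels,
        scores=s_scores if len(np.unique(s_labels)) == 2 else None, with_wilson=True,
    )
    result = {
        "protocol": "subject_dependent_osw",
        "model": model_name,
        "seed": seed,
        "split": {k: sorted(getattr(plan, k)) for k in ("train", "val", "test")},
        "operating_point": {"threshold": op.threshold, "source": op.source, "j": op.j_value},
        "window_report": window_report.to_dict(),
        "session_report": session_report.to_dict(),
        "session_scores": [vars(s) for s in sessions],
        "history_best_val_auc": history["best_val_auc"],
        "n_windows": {k: int(len(v)) for k, v in idx.items()},
    }
    _dump(result, out_dir, "subject_dependent_report.json")
    return result


def run_ablation(
    records: list[SessionRecord],
    variants: tuple[str, ...] = tuple(ABLATION_VARIANTS),
    seeds: tuple[int, ...] = (0, 1, 2),
    model_spec=None,
    train_config: TrainConfig | None = None,
    win_s: float = 2.0,
    hop_s: float = 0.25,
    split_seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict:
    """Structural ablation harness: retrain each variant across seeds on the
    same fixed split; report mean +- SD window and session accuracy."""
    table = {}
    for variant in variants:
        window_accs, session_accs = [], []
        for seed in seeds:
            cfg = train_config or TrainConfig(loss="bce", batch_size=128, mixup_alpha=0.0,
                                              schedule="cosine_restarts", seed=seed)
            cfg.seed = seed
            res = run_subject_dependent(
                records, model_name=variant, model_spec=model_spec, train_config=cfg,
                win_s=win_s, hop_s=hop_s, seed=split_seed,
            )
            window_accs.append(res["window_report"]["accuracy"])
            session_accs.append(res["session_report"]["accuracy"])
        table[variant] = {
            "window_acc_mean": float(np.mean(window_accs)),
            "window_acc_sd": float(np.std(window_accs)),
            "session_acc_mean": float(np.mean(session_accs)),
            "session_acc_sd": float(np.std(session_accs)),
            "seeds": list(seeds),
        }
    result = {"protocol": "subject_dependent_ablation", "variants": table}
    _dump(result, out_dir, "ablation_report.json")
    return result


def run_cross_subject(
    records: list[SessionRecord],
    model_name: str = "resnet_se",
    model_spec=None,
    train_config: TrainConfig | None = None,
    win_s: float = 3.0,
    hop_s: float = 0.25,
    n_folds: int = 5,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict:
    """Subject-grouped K-fold protocol with session aggregation and a single
    global Youden threshold on pooled out-of-fold session scores."""
    train_config = train_config or TrainConfig(loss="focal", batch_size=64,
                                               schedule="plateau", seed=seed)
    packed = _build_windows(records, win_s, hop_s)
    subjects = [rec.subject_id for rec in records]
    plan: FoldPlan = grouped_folds(subjects, k=n_folds, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xF01D)))

    oof_probs = np.full(packed["y"].shape, np.nan)
    fold_rows = []
    for fold_idx, fold in enumerate(plan.folds):
        is_test = np.isin(packed["subject"], sorted(fold.test_subjects))
        pool_idx = np.flatnonzero(~is_test)
        test_idx = np.flatnonzero(is_test)
        val_local = inner_validation_indices(len(pool_idx), plan.val_fraction, rng)
        val_mask = np.zeros(len(pool_idx), dtype=bool)
        val_mask[val_local] = True
        train_idx = pool_idx[~val_mask]
        val_idx = pool_idx[val_mask]

        cfg = TrainConfig(**{**vars(train_config), "seed": train_config.seed + fold_idx})
        model = _make_model(model_name, packed["X"].shape[1], packed["X"].shape[2],
                            spec=model_spec, seed=cfg.seed)
        history = train_model(
            model, (packed["X"][train_idx],), packed["y"][train_idx],
            (packed["X"][val_idx],), packed["y"][val_idx], cfg,
        )
        probs = model.predict_proba((packed["X"][test_idx],))
        oof_probs[test_idx] = probs
        y_fold = packed["y"][test_idx]
        fold_sessions = aggregate_session_scores(
            probs, packed["session"][test_idx], packed["subject"][test_idx], y_fold
        )
        fs = np.array([s.score for s in fold_sessions])
        fy = np.array([s.label for s in fold_sessions])
        fold_rows.append({
            "fold": fold_idx,
            "test_subjects": sorted(fold.test_subjects),
            "window_auc": roc_auc(probs, y_fold) if len(np.unique(y_fold)) == 2 else None,
            "session_auc": roc_auc(fs, fy) if len(np.unique(fy)) == 2 else None,
            "best_val_auc": history["best_val_auc"],
        })

    assert not np.isnan(oof_probs).any(), "every window must receive an out-of-fold score"
    sessions = aggregate_session_scores(
        oof_probs, packed["session"], packed["subject"], packed["y"]
    )
    s_scores = np.array([s.score for s in sessions])
    s_labels = np.array([s.label for s in sessions])
    op = youden_threshold(s_scores, s_labels, source="pooled_oof_sessions")
    preds = (s_scores >= op.threshold).astype(int)
    session_report = classification_report(preds, s_labels, scores=s_scores, with_wilson=True)

    k_correct = int((preds == s_labels).sum())
    fold_aucs = [r["session_auc"] for r in fold_rows if r["session_auc"] is not None]
    result = {
        "protocol": "cross_subject_grouped_cv",
        "model": model_name,
        "seed": seed,
        "n_folds": n_folds,
        "global_threshold": op.threshold,
        "threshold_source": op.source,
        "session_report": session_report.to_dict(),
        "session_scores": [vars(s) for s in sessions],
        "folds": fold_rows,
        "fold_session_auc_mean": float(np.mean(fold_aucs)) if fold_aucs else None,
        "fold_session_auc_sd": float(np.std(fold_aucs)) if fold_aucs else None,
        "pooled_session_auc": roc_auc(s_scores, s_labels),
        "binomial_p_vs_chance": exact_binomial_test(k_correct, len(s_labels)),
        "wilson_accuracy": wilson_interval(k_correct, len(s_labels)),
    }
    _dump(result, out_dir, "cross_subject_report.json")
    return result


def run_describe(records: list[SessionRecord], win_s: float = 2.0, hop_s: float = 1.0):
    """Descriptive quartile/effect-size summary on the 2.0 s / 1.0 s stream."""
    windows = [w for rec in records for w in windowing.segment_session(rec, win_s, hop_s)]
    table = features.desc_table(windows, records[0].channel_names)
    return features.band_power_summary(table), table
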