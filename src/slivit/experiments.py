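"""Experiment orchestration at desk scale.

Synthetic volumes are generated already intensity-calibrated, so the
experiment drivers default to ``stretch=False``; per-slice contrast
stretching is a scanner-normalization step for real acquisitions and would
erase the cross-slice intensity comparisons these tasks are built on.

Three designs are provided: a plain benchmark run (fine-tune, predict on the
held-out test split, bootstrap the metric), a training-fraction sweep
(subsample the train split, keep the test split fixed), and a
frame-permutation robustness study (train one model on the original slice
order and m models on shuffled copies, then rank and compare them on shared
bootstrap resamples). Simple 2D baselines — a logistic regression or ridge
regression on one slice's pixels — quantify how much of each synthetic task
is visible without 3D aggregation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import (PredictionSet, bonferroni_adjust, bootstrap_scores,
                         paired_bootstrap_test)
from .model import SlivitConfig, SlivitModel, compact_config, compact_integrator_config
from .synthetic import shuffle_copies
from .training import TrainConfig, finetune_3d, predict_volumes
from .volume_data import LabeledDataset, SplitAssignment, subsample_indices


@dataclass
class ExperimentReport:
    name: str
    rows: list = field(default_factory=list)      # per-run dicts
    pairwise: list = field(default_factory=list)  # comparison dicts
    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def save(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        payload = {"name": self.name, "rows": self.rows, "pairwise": self.pairwise,
                   "config": self.config, "seeds": self.seeds}
        (out_dir / f"{self.name}.json").write_text(json.dumps(payload, indent=2))
        self.to_frame().to_csv(out_dir / f"{self.name}.csv", index=False)


def _assert_test_isolation(train_ids, split: SplitAssignment) -> None:
    leak = set(train_ids) & set(split.test_ids)
    if leak:
        raise AssertionError(f"test ids leaked into training: {sorted(leak)[:5]}")


def desk_model(task: str, max_n: int = 64, seed: int = 0) -> SlivitModel:
    """Reduced-width model preset for CPU-scale experiments."""
    head = "binary" if task == "binary" else "regression"
    cfg = SlivitConfig(backbone=compact_config(),
                       integrator=compact_integrator_config(max_n=max_n),
                       head=head)
    return SlivitModel(cfg, seed=seed)


def _metrics_for(task: str) -> tuple:
    return ("roc_auc", "pr_auc") if task == "binary" else ("r2",)


def _score_model(model, dataset, task, label_column, B, eval_seed, stretch=True):
    y_true, y_score = predict_volumes(model, dataset, dataset.split.test_ids,
                                      label_column, task, stretch=stretch)
    preds = PredictionSet(list(dataset.split.test_ids), y_true, y_score, task)
    return preds, {m: bootstrap_scores(preds, m, B=B, seed=eval_seed)
                   for m in _metrics_for(task)}


def run_benchmark(dataset: LabeledDataset, task: str, label_column: str,
                  model: SlivitModel | None = None,
                  train_config: TrainConfig | None = None, B: int = 1000,
                  seed: int = 0, stretch: bool = False,
                  pretrained_backbone: dict | None = None,
                  out_dir=None) -> ExperimentReport:
    """Fine-tune on the train split, bootstrap metrics on the test split.

    ``pretrained_backbone`` (a backbone state dict, e.g. from
    :func:`slivit.training.pretrain_2d`) switches fine-tuning to the
    transferred initialization the protocol prescribes.
    """
    if dataset.split is None:
        raise ValueError("dataset must carry a split")
    model = model or desk_model("binary" if task == "binary" else "regression",
                                max_n=max(v.n_frames for v in dataset.volumes.values()),
                                seed=seed)
    train_config = train_config or TrainConfig(
        loss="bce_logits" if task == "binary" else "l1", seed=seed)
    _assert_test_isolation(dataset.split.train_ids, dataset.split)
    init = "random" if pretrained_backbone is None else "transferred"
    record = finetune_3d(model, dataset, task, label_column, init=init,
                         pretrained_backbone=pretrained_backbone,
                         config=train_config, stretch=stretch)
    preds, results = _score_model(model, dataset, task, label_column, B, seed,
                                  stretch)
    row = {"run": "benchmark", "best_epoch": record.best_epoch,
           "best_val_loss": record.best_val_loss, "base_lr": record.base_lr,
           "n_train": len(dataset.split.train_ids),
           "n_test": len(dataset.split.test_ids)}
    for m, res in results.items():
        row[m] = res.point_estimate
        row[f"{m}_ci_lower"], row[f"{m}_ci_upper"] = res.ci
    report = ExperimentReport(name=f"benchmark_{task}", rows=[row],
                              config={"train": asdict(train_config), "B": B},
                              seeds={"seed": seed})
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"id": preds.ids, "y_true": preds.y_true,
                      "y_score": preds.y_score}).to_csv(
            out_dir / "predictions.csv", index=False)
        report.save(out_dir)
    return report


def run_fraction_sweep(dataset: LabeledDataset, fractions, task: str,
                       label_column: str, model_seed: int = 0,
                       train_config: TrainConfig | None = None, B: int = 1000,
                       seed: int = 0, stretch: bool = False) -> ExperimentReport:
    """Train one model per train-split fraction; the test split stays fixed."""
    if dataset.split is None:
        raise ValueError("dataset must carry a split")
    train_config = train_config or TrainConfig(
        loss="bce_logits" if task == "binary" else "l1", seed=seed)
    max_n = max(v.n_frames for v in dataset.volumes.values())
    report = ExperimentReport(name=f"fraction_sweep_{task}",
                              config={"fractions": list(fractions)},
                              seeds={"seed": seed, "model_seed": model_seed})
    full_split = dataset.split
    metric = _metrics_for(task)[-1] if task != "binary" else "roc_auc"
    for frac in fractions:
        sub_ids = subsample_indices(full_split.train_ids, frac, seed=seed + 17)
        if len(sub_ids) < 2 * train_config.batch_size:
            report.rows.append({"fraction": frac, "skipped": True,
                                "n_train": len(sub_ids)})
            continue
        _assert_test_isolation(sub_ids, full_split)
        sub_split = SplitAssignment(train_ids=sub_ids, val_ids=full_split.val_ids,
                                    test_ids=full_split.test_ids,
                                    fractions=full_split.fractions,
                                    seed=full_split.seed)
        sub_ds = LabeledDataset(volumes=dataset.volumes, labels=dataset.labels,
                                split=sub_split, meta=dataset.meta)
        model = desk_model("binary" if task == "binary" else "regression",
                           max_n=max_n, seed=model_seed)
        # smaller subsets see fewer steps per epoch; scale the epoch cap so
        # every fraction gets a comparable optimization budget (early
        # stopping still governs the actual length)
        cap = min(2 * train_config.max_epochs,
                  math.ceil(train_config.max_epochs / frac))
        sub_config = replace(train_config, max_epochs=cap)
        record = finetune_3d(model, sub_ds, task, label_column,
                             config=sub_config, stretch=stretch)
        _, results = _score_model(model, sub_ds, task, label_column, B, seed,
                                  stretch)
        row = {"fraction": frac, "skipped": False, "n_train": len(sub_ids),
               "best_epoch": record.best_epoch}
        for m, res in results.items():
            row[m] = res.point_estimate
            row[f"{m}_ci_lower"], row[f"{m}_ci_upper"] = res.ci
        report.rows.append(row)
    report.config["metric"] = metric
    return report


def run_permutation_study(dataset: LabeledDataset, m: int, task: str,
                          label_column: str, model_seed: int = 0,
                          train_config: TrainConfig | None = None, B: int = 1000,
                          seed: int = 0, stretch: bool = False,
                          alpha: float = 1e-3) -> ExperimentReport:
    """Original-order model vs m shuffled-copy models on the same split.

    Reports each model's mean bootstrapped score, the original model's rank
    among the m+1 (rank 1 = best mean score), and paired significance tests
    of original vs each shuffled model on shared resample streams.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    train_config = train_config or TrainConfig(
        loss="bce_logits" if task == "binary" else "l1", seed=seed)
    max_n = max(v.n_frames for v in dataset.volumes.values())
    metric = "roc_auc" if task == "binary" else "r2"
    copies = shuffle_copies(dataset, m, seed=seed + 101)
    runs = [("original", dataset)] + [(f"shuffled_{i}", ds)
                                      for i, ds in enumerate(copies)]
    results = []
    for name, ds in runs:
        model = desk_model("binary" if task == "binary" else "regression",
                           max_n=max_n, seed=model_seed)
        record = finetune_3d(model, ds, task, label_column, config=train_config,
                             stretch=stretch)
        _, scored = _score_model(model, ds, task, label_column, B, seed, stretch)
        results.append((name, record, scored[metric]))
    means = [float(np.mean(res.scores)) for _, _, res in results]
    order = np.argsort(means)[::-1]
    rank_of = {int(i): int(r + 1) for r, i in enumerate(order)}
    report = ExperimentReport(name="permutation_study",
                              config={"m": m, "metric": metric, "B": B,
                                      "alpha": alpha},
                              seeds={"seed": seed, "model_seed": model_seed})
    p_values = []
    for i, (name, record, res) in enumerate(results):
        report.rows.append({"model": name, "mean_bootstrap_score": means[i],
                            "point": res.point_estimate,
                            "ci_lower": res.ci[0], "ci_upper": res.ci[1],
                            "rank": rank_of[i], "best_epoch": record.best_epoch})
        if i > 0:
            p = paired_bootstrap_test(results[0][2].scores, res.scores)
            p_values.append(p)
            report.pairwise.append({"a": "original", "b": name, "p_value": p})
    flags = bonferroni_adjust(p_values, alpha=alpha)
    for comp, flag in zip(report.pairwise, flags):
        comp["significant"] = bool(flag)
    report.config["original_rank"] = rank_of[0]
    return report


# ---------------------------------------------------------------------------
# Single-slice 2D baselines

def _slice_matrix(dataset, ids, label_column, frame_index, stride=2):
    X, y = [], []
    for vid in ids:
        vol = dataset.volumes[vid]
        idx = frame_index if frame_index is not None else vol.n_frames // 2
        X.append(vol.frames[idx, ::stride, ::stride].ravel())
        y.append(float(dataset.labels.table.loc[vid, label_column]))
    return np.stack(X), np.asarray(y)


def single_slice_baseline_auc(dataset: LabeledDataset, label_column: str = "label",
                              frame_index: int | None = None, seed: int = 0) -> float:
    """ROC AUC of a logistic regression on one slice's raw pixels."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import roc_auc_score

    Xtr, ytr = _slice_matrix(dataset, dataset.split.train_ids, label_column, frame_index)
    Xte, yte = _slice_matrix(dataset, dataset.split.test_ids, label_column, frame_index)
    clf = LogisticRegression(max_iter=2000, random_state=seed)
    clf.fit(Xtr, ytr)
    return float(roc_auc_score(yte, clf.predict_proba(Xte)[:, 1]))


def single_frame_baseline_r2(dataset: LabeledDataset, label_column: str = "target",
                             frame_index: int | None = None, seed: int = 0) -> float:
    """R^2 of a ridge regression on one frame's raw pixels."""
    from sklearn.linear_model import Ridge
    from sklearn.metrics import r2_score

    Xtr, ytr = _slice_matrix(dataset, dataset.split.train_ids, label_column, frame_index)
    Xte, yte = _slice_matrix(dataset, dataset.split.test_ids, label_column, frame_index)
    reg = Ridge(alpha=1.0, random_state=seed)
    reg.fit(Xtr, ytr)
    return float(r2_score(yte, reg.predict(Xte)))
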