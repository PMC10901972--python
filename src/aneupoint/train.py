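"""Training loop and data splitting.

Stratified 5-fold cross-validation (every fold preserves the cohort's
class proportion to within one sample), Adam with a cosine-annealing
warm-restarts learning-rate schedule, and per-epoch metric capture on the
training, internal-validation and (optionally) external-test splits.

The published training recipe is the default: batch size 20, 200 epochs,
initial learning rate 2e-5, weight decay 1e-4.  Scaled-down synthetic
studies override epochs and learning rate explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import evalreport
from .cloud import PointCloud
from .net import (Adam, NetConfig, PointCloudClassifier, build_plan,
                  loss, loss_grad, softmax)


@dataclass
class TrainConfig:
    """Optimizer/schedule hyper-parameters (defaults follow the recipe)."""

    batch_size: int = 20
    epochs: int = 200
    lr_init: float = 2e-5
    weight_decay: float = 1e-4
    t0: int = 10                # first restart cycle length (epochs)
    t_mult: int = 2             # cycle-length multiplier after each restart
    lr_min: float = 0.0
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("batch_size", "epochs", "lr_init", "t0", "t_mult"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.weight_decay < 0 or self.lr_min < 0:
            raise ValueError("weight_decay and lr_min must be >= 0")


@dataclass
class LabeledSample:
    """One case: its (normalized) cloud, rupture label, cohort and id."""

    cloud: PointCloud
    label: int
    cohort: str = "training"
    sample_id: str = ""


@dataclass
class FoldAssignment:
    """Train/validation id lists of one cross-validation fold."""

    fold_id: int
    train_ids: list
    val_ids: list

    def class_counts(self, labels: dict) -> dict:
        out = {}
        for side, ids in (("train", self.train_ids), ("val", self.val_ids)):
            arr = np.array([labels[i] for i in ids])
            out[side] = {0: int((arr == 0).sum()), 1: int((arr == 1).sum())}
        return out


def stratified_kfold(labels: dict, k: int = 5, seed: int = 42):
    """Stratified k-fold assignments over an id -> {0,1} label mapping."""
    ids = list(labels.keys())
    y = np.array([labels[i] for i in ids])
    for cls in (0, 1):
        if (y == cls).sum() < k:
            raise ValueError(f"class {cls} has fewer than k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for fi, (tr, va) in enumerate(skf.split(np.zeros(len(ids)), y), start=1):
        folds.append(FoldAssignment(
            fold_id=fi,
            train_ids=[ids[i] for i in tr],
            val_ids=[ids[i] for i in va]))
    return folds


def lr_schedule(epoch: int, config: TrainConfig) -> float:
    """Cosine annealing with warm restarts, closed form.

    Within a cycle of length ``t0 * t_mult**c`` the rate decays from
    ``lr_init`` to ``lr_min`` on a half-cosine and resets at each restart.
    """
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    t_cur = epoch
    t_i = config.t0
    while t_cur >= t_i:
        t_cur -= t_i
        t_i *= config.t_mult
    frac = t_cur / t_i
    return config.lr_min + (config.lr_init - config.lr_min) \
        * (1.0 + np.cos(np.pi * frac)) / 2.0


@dataclass
class FoldResult:
    """Per-epoch metrics and scores for one trained fold."""

    fold_id: int
    epoch_records: list           # list of dict split -> EpochMetrics
    epoch_scores: list            # list of dict split -> (scores, labels)
    best_weights: dict
    last_weights: dict
    best_epoch: int
    trained_ids: set              # ids that ever contributed a gradient


def _scores_for(clf, plans, batch: int = 64) -> np.ndarray:
    out = []
    for i in range(0, len(plans), batch):
        logits = clf.forward(plans[i:i + batch])
        out.append(softmax(logits)[:, 1])
    return np.concatenate(out)


def train_fold(fold: FoldAssignment, net_config: NetConfig,
               train_config: TrainConfig, data: dict,
               external: dict | None = None,
               progress: bool = False,
               plan_cache: dict | None = None) -> FoldResult:
    """Train one fold and record metrics for every epoch.

    ``data`` maps sample id -> :class:`LabeledSample`; ``external`` holds
    the held-out external cohort, scored every epoch but never trained on.
    Deterministic given the seeds (single-threaded NumPy arithmetic).
    """
    rng = np.random.default_rng(train_config.seed + fold.fold_id)
    clf = PointCloudClassifier(net_config)
    opt = Adam(clf.params, lr=train_config.lr_init,
               weight_decay=train_config.weight_decay)

    cache = plan_cache if plan_cache is not None else {}

    def plans_labels(ids, source):
        plans = []
        for i in ids:
            if i not in cache:
                cache[i] = build_plan(source[i].cloud.coords, net_config)
            plans.append(cache[i])
        labels = np.array([source[i].label for i in ids], dtype=np.intp)
        return plans, labels

    tr_plans, tr_labels = plans_labels(fold.train_ids, data)
    va_plans, va_labels = plans_labels(fold.val_ids, data)
    splits = {"train": (tr_plans, tr_labels),
              "internal_val": (va_plans, va_labels)}
    if external:
        ex_ids = list(external.keys())
        splits["external_test"] = plans_labels(ex_ids, external)

    n = len(tr_plans)
    records, scores_hist = [], []
    best_epoch, best_val_auc = 0, -np.inf
    best_weights = {k: v.copy() for k, v in clf.params.items()}
    trained_ids = set()
    for epoch in range(train_config.epochs):
        lr = lr_schedule(epoch, train_config)
        order = rng.permutation(n)
        for i in range(0, n, train_config.batch_size):
            sel = order[i:i + train_config.batch_size]
            logits = clf.forward([tr_plans[j] for j in sel],
                                 train=True, rng=rng)
            if not np.all(np.isfinite(logits)):
                raise FloatingPointError(
                    f"training diverged (non-finite loss) at epoch {epoch}")
            grads = clf.backward([tr_plans[j] for j in sel],
                                 loss_grad(logits, tr_labels[sel]))
            opt.step(clf.params, grads, lr=lr)
            trained_ids.update(fold.train_ids[j] for j in sel)

        rec, sc = {}, {}
        for split, (plans, labels) in splits.items():
            s = _scores_for(clf, plans)
            rec[split] = evalreport.compute_epoch_metrics(
                s, labels, split=split, epoch=epoch)
            sc[split] = (s, labels)
        records.append(rec)
        scores_hist.append(sc)
        if rec["internal_val"].auc > best_val_auc:
            best_val_auc = rec["internal_val"].auc
            best_epoch = epoch
            best_weights = {k: v.copy() for k, v in clf.params.items()}
        if progress:
            print(f"fold {fold.fold_id} epoch {epoch:3d} lr {lr:.2e} "
                  f"val_auc {rec['internal_val'].auc:.3f}")

    overlap = trained_ids & set(fold.val_ids)
    if external:
        overlap |= trained_ids & set(external.keys())
    if overlap:
        raise RuntimeError(f"leakage audit failed: {sorted(overlap)[:5]} "
                           "contributed gradients")
    return FoldResult(fold_id=fold.fold_id, epoch_records=records,
                      epoch_scores=scores_hist,
                      best_weights=best_weights,
                      last_weights={k: v.copy() for k, v in clf.params.items()},
                      best_epoch=best_epoch, trained_ids=trained_ids)


def run_cross_validation(samples: dict, net_config: NetConfig,
                         train_config: TrainConfig, k: int = 5,
                         external: dict | None = None,
                         progress: bool = False):
    """Stratified k-fold training; returns (folds, results)."""
    labels = {i: s.label for i, s in samples.items()}
    folds = stratified_kfold(labels, k=k, seed=train_config.seed)
    cache: dict = {}
    results = [train_fold(f, net_config, train_config, samples,
                          external=external, progress=progress,
                          plan_cache=cache)
               for f in folds]
    return folds, results
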