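"""Patient-level cross-validated training and evaluation.

Splitting is stratified by risk tier and performed strictly at the case
(patient) level, so no case contributes instances to both sides of a fold.
Models train with Adam (L2 weight decay), a linear learning-rate warmup,
and early stopping on validation loss; the best-epoch parameters are
restored. Metrics follow the standard multiclass conventions: accuracy,
per-class precision/recall/F1 with macro and support-weighted averages,
macro one-vs-rest AUC, and the confusion matrix; per-fold reports aggregate
as mean +/- sample SD.
"""

from __future__ import annotations

import copy
import dataclasses
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .abmil import Abmil, AbmilConfig
from .autodiff import Adam
from .bags import FeatureBag
from .clam import ClamSB, ClamConfig, clam_total_loss
from .losses import FocalParams, SmoothingParams, make_bag_loss
from .milboost import AttentionPool, BoostConfig, PoolConfig, enhanced_features, fit_boosted

MODEL_KINDS = ("clam_sb", "abmil", "milboost")


@dataclass
class TrainConfig:
    lr: float = 3e-5
    weight_decay: float = 1e-4
    max_epochs: int = 100
    warmup_epochs: int = 5
    early_stop_patience: int = 20
    loss_kind: str = "focal"  # focal | weighted_ce | ce | ce_smoothed
    alpha: tuple[float, ...] = (1.0, 3.0, 1.0)
    gamma: float = 2.0
    epsilon: float = 0.1  # label smoothing; 0 disables
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.warmup_epochs > self.max_epochs:
            raise ValueError("warmup_epochs must not exceed max_epochs")


def default_train_config(model_kind: str, **overrides) -> TrainConfig:
    """Per-model training defaults (CLAM: lr 3e-5 / 100 epochs focal+smoothing;
    ABMIL: lr 4e-4 / 20 epochs weighted CE; attention pool: focal)."""
    base = {
        "clam_sb": dict(lr=3e-5, max_epochs=100, early_stop_patience=20, loss_kind="focal"),
        "abmil": dict(lr=4e-4, max_epochs=20, early_stop_patience=5, loss_kind="weighted_ce", epsilon=0.0),
        "milboost": dict(lr=1e-3, max_epochs=30, early_stop_patience=5, loss_kind="focal", epsilon=0.0),
    }
    if model_kind not in base:
        raise ValueError(f"unknown model kind {model_kind!r}")
    cfg = base[model_kind] | overrides
    cfg.setdefault("warmup_epochs", min(5, cfg.get("max_epochs", 100)))
    return TrainConfig(**cfg)


@dataclass
class FoldSplit:
    fold_id: int
    train_ids: list[str]
    val_ids: list[str]

    def __post_init__(self):
        if set(self.train_ids) & set(self.val_ids):
            raise ValueError("train/val case overlap in fold")


def make_folds(
    cases: list[tuple[str, int]], k: int = 5, seed: int = 0, stratify_by_tier: bool = True
) -> list[FoldSplit]:
    """Stratified k-fold partition at the patient level, deterministic per seed."""
    ids = np.array([c for c, _ in cases])
    tiers = np.array([t for _, t in cases])
    if len(ids) < k:
        raise ValueError("cohort smaller than fold count")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate case ids")
    if stratify_by_tier:
        if np.any(np.bincount(tiers, minlength=3) == 0):
            raise ValueError("a tier has zero cases; cannot stratify")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(ids, tiers)
    else:
        from sklearn.model_selection import KFold

        split_iter = KFold(n_splits=k, shuffle=True, random_state=seed).split(ids)
    folds = []
    for fold_id, (tr, va) in enumerate(split_iter):
        folds.append(FoldSplit(fold_id, ids[tr].tolist(), ids[va].tolist()))
    return folds


def lr_at_epoch(epoch: int, config: TrainConfig) -> float:
    """Linear warmup: lr * (epoch + 1) / warmup_epochs, then constant lr."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    if config.warmup_epochs <= 0 or epoch >= config.warmup_epochs:
        return config.lr
    return config.lr * (epoch + 1) / config.warmup_epochs


def build_model(model_kind: str, input_dim: int, seed: int = 0):
    if model_kind == "clam_sb":
        return ClamSB(ClamConfig(input_dim=input_dim, seed=seed))
    if model_kind == "abmil":
        return Abmil(AbmilConfig(input_dim=input_dim, seed=seed))
    if model_kind == "milboost":
        return AttentionPool(PoolConfig(input_dim=input_dim, seed=seed))
    raise ValueError(f"unknown model kind {model_kind!r}")


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def predict_probs(model, bags: list[FeatureBag]) -> np.ndarray:
    """Eval-mode class probabilities, one simplex row per bag."""
    out = np.empty((len(bags), model.config.n_classes))
    for i, bag in enumerate(bags):
        logits = model.forward(bag, mode="eval")[0]
        out[i] = _softmax(logits.data)
    return out


def train_model(
    model, bags_by_id: dict[str, FeatureBag], split: FoldSplit, config: TrainConfig
) -> tuple[object, pd.DataFrame]:
    """Train one model on a fold; returns (best-epoch model, per-epoch history)."""
    train_bags = [bags_by_id[c] for c in split.train_ids]
    val_bags = [bags_by_id[c] for c in split.val_ids]
    if not train_bags or not val_bags:
        raise ValueError("empty train or validation split")

    smoothing = SmoothingParams(config.epsilon, len(config.alpha)) if config.epsilon > 0 else None
    bag_loss_fn = make_bag_loss(config.loss_kind, FocalParams(np.asarray(config.alpha), config.gamma), smoothing)
    opt = Adam(model.parameters(), lr=config.lr, weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)
    is_clam = isinstance(model, ClamSB)

    history_rows = []
    best_val, best_state, best_epoch, since_best = np.inf, None, -1, 0
    for epoch in range(config.max_epochs):
        opt.lr = lr_at_epoch(epoch, config)
        order = rng.permutation(len(train_bags))
        train_losses, train_correct = [], 0
        gate_means = []
        for i in order:
            bag = train_bags[i]
            out = model.forward(bag, mode="train")
            logits = out[0]
            loss = bag_loss_fn(logits, bag.tier)
            if is_clam:
                inst = model.instance_cluster_loss(out[1], out[2])
                loss = clam_total_loss(loss, inst, model.config.bag_weight)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, case {bag.case_id}: {loss.data}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            train_losses.append(float(loss.data))
            train_correct += int(np.argmax(logits.data) == bag.tier)
            if hasattr(model, "last_gate_mean"):
                gate_means.append(model.last_gate_mean)

        val_losses, val_correct = [], 0
        for bag in val_bags:
            logits = model.forward(bag, mode="eval")[0]
            val_losses.append(float(bag_loss_fn(logits, bag.tier).data))
            val_correct += int(np.argmax(logits.data) == bag.tier)
        val_loss = float(np.mean(val_losses))
        row = {
            "epoch": epoch,
            "lr": opt.lr,
            "train_loss": float(np.mean(train_losses)),
            "train_acc": train_correct / len(train_bags),
            "val_loss": val_loss,
            "val_acc": val_correct / len(val_bags),
        }
        if gate_means:
            row["gate_mean"] = float(np.mean(gate_means))
        history_rows.append(row)

        if val_loss < best_val:
            best_val, best_epoch, since_best = val_loss, epoch, 0
            best_state = copy.deepcopy(model.state_dict())
        else:
            since_best += 1
            if since_best >= config.early_stop_patience:
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    history = pd.DataFrame(history_rows)
    history.attrs["best_epoch"] = best_epoch
    return model, history


@dataclass
class MetricsReport:
    accuracy: float
    precision: np.ndarray  # per class
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    auc: float
    confusion: np.ndarray

    def scalars(self) -> dict[str, float]:
        out = {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "weighted_precision": self.weighted_precision,
            "weighted_recall": self.weighted_recall,
            "weighted_f1": self.weighted_f1,
            "auc": self.auc,
        }
        for c in range(len(self.f1)):
            out[f"precision_{c}"] = float(self.precision[c])
            out[f"recall_{c}"] = float(self.recall[c])
            out[f"f1_{c}"] = float(self.f1[c])
        return out


def metrics_from_precision_recall(precision, recall, support=None) -> tuple[np.ndarray, float]:
    """Per-class F1 = 2PR/(P+R) (0 when P+R=0) and the macro F1."""
    p = np.asarray(precision, dtype=float)
    r = np.asarray(recall, dtype=float)
    denom = p + r
    f1 = np.where(denom > 0, 2.0 * p * r / np.where(denom > 0, denom, 1.0), 0.0)
    return f1, float(f1.mean())


def evaluate(pred_probs: np.ndarray, tiers: np.ndarray, n_classes: int = 3) -> MetricsReport:
    """Full multiclass metrics from predicted probabilities and true tiers.

    Predicted class is the argmax (ties resolve to the lowest index). AUC is
    the unweighted mean of per-class one-vs-rest AUCs over classes present
    in ``tiers``; absent classes are excluded with a warning.
    """
    probs = np.asarray(pred_probs, dtype=float)
    tiers = np.asarray(tiers, dtype=int)
    if probs.ndim != 2 or probs.shape[0] != len(tiers):
        raise ValueError("pred_probs must be M x K aligned with tiers")
    preds = probs.argmax(axis=1)
    labels = np.arange(n_classes)
    prec, rec, f1, support = precision_recall_fscore_support(
        tiers, preds, labels=labels, zero_division=0
    )
    conf = confusion_matrix(tiers, preds, labels=labels)
    present = np.unique(tiers)
    if len(present) < n_classes:
        warnings.warn(
            f"classes {sorted(set(labels) - set(present))} absent from truth; excluded from macro AUC",
            stacklevel=2,
        )
    aucs = []
    for c in present:
        if len(present) < 2:
            break
        aucs.append(roc_auc_score((tiers == c).astype(int), probs[:, c]))
    auc = float(np.mean(aucs)) if aucs else float("nan")
    total = support.sum()
    weights = support / total
    return MetricsReport(
        accuracy=float((preds == tiers).mean()),
        precision=prec,
        recall=rec,
        f1=f1,
        support=support,
        macro_precision=float(prec.mean()),
        macro_recall=float(rec.mean()),
        macro_f1=float(f1.mean()),
        weighted_precision=float((prec * weights).sum()),
        weighted_recall=float((rec * weights).sum()),
        weighted_f1=float((f1 * weights).sum()),
        auc=auc,
        confusion=conf,
    )


def aggregate_folds(reports: list[MetricsReport] | list[dict]) -> dict[str, tuple[float, float]]:
    """Mean and sample SD (ddof=1) per scalar metric across fold reports."""
    if len(reports) < 2:
        raise ValueError("need at least two fold reports to aggregate")
    dicts = [r.scalars() if isinstance(r, MetricsReport) else dict(r) for r in reports]
    keys = dicts[0].keys()
    out = {}
    for key in keys:
        vals = np.array([d[key] for d in dicts], dtype=float)
        out[key] = (float(vals.mean()), float(vals.std(ddof=1)))
    return out


def majority_vote_baseline(patch_preds: dict[str, np.ndarray] | list[np.ndarray]) -> np.ndarray:
    """Modal patch class per slide; ties resolve to the lowest class index."""
    seqs = patch_preds.values() if isinstance(patch_preds, dict) else patch_preds
    votes = []
    for preds in seqs:
        preds = np.asarray(preds, dtype=int)
        if preds.size == 0:
            raise ValueError("slide with no patch predictions")
        counts = Counter(preds.tolist())
        top = max(counts.values())
        votes.append(min(c for c, n in counts.items() if n == top))
    return np.asarray(votes, dtype=int)


def patch_baseline_cv(
    bags: list[FeatureBag], k: int = 5, seed: int = 0
) -> tuple[list[MetricsReport], np.ndarray, np.ndarray]:
    """Non-MIL baseline: patch-level classifier + per-slide majority voting.

    Each instance inherits its slide's tier; a logistic-regression patch
    classifier is trained per fold and slide predictions are the modal patch
    class. Probabilities for AUC are mean patch probabilities per slide.
    """
    cases = [(b.case_id, b.tier) for b in bags]
    by_id = {b.case_id: b for b in bags}
    folds = make_folds(cases, k=k, seed=seed)
    reports, pooled_preds, pooled_tiers = [], [], []
    for split in folds:
        xs = np.concatenate([by_id[c].features for c in split.train_ids])
        ys = np.concatenate([np.full(by_id[c].n_instances, by_id[c].tier) for c in split.train_ids])
        clf = LogisticRegression(max_iter=500, random_state=seed)
        clf.fit(xs, ys)
        slide_probs, slide_preds, tiers = [], [], []
        for c in split.val_ids:
            patch_prob = clf.predict_proba(by_id[c].features)
            patch_pred = patch_prob.argmax(axis=1)
            slide_preds.append(patch_pred)
            slide_probs.append(patch_prob.mean(axis=0))
            tiers.append(by_id[c].tier)
        votes = majority_vote_baseline(slide_preds)
        probs = np.vstack(slide_probs)
        # score the vote, not the mean-probability argmax: overwrite argmax rows
        onehot = np.zeros_like(probs)
        onehot[np.arange(len(votes)), votes] = 1.0
        blended = 0.5 * probs + 0.5 * onehot  # keeps AUC informative, argmax = vote
        reports.append(evaluate(blended, np.asarray(tiers)))
        pooled_preds.extend(votes.tolist())
        pooled_tiers.extend(tiers)
    return reports, np.asarray(pooled_preds), np.asarray(pooled_tiers)


def cross_validate(
    model_kind: str,
    bags: list[FeatureBag],
    k: int = 5,
    seed: int = 0,
    train_config: TrainConfig | None = None,
    boost_config: BoostConfig | None = None,
) -> dict:
    """Patient-level k-fold CV of one model kind over a bag cohort.

    Returns a dict with per-fold reports, histories, pooled out-of-fold
    probabilities/tiers, and the fold splits.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    by_id = {b.case_id: b for b in bags}
    cases = [(b.case_id, b.tier) for b in bags]
    folds = make_folds(cases, k=k, seed=seed)
    input_dim = bags[0].dim
    reports, histories = [], []
    pooled_probs = np.zeros((len(bags), 3))
    pooled_tiers = np.zeros(len(bags), dtype=int)
    id_to_idx = {b.case_id: i for i, b in enumerate(bags)}
    for split in folds:
        base_config = train_config or default_train_config(model_kind)
        config = dataclasses.replace(base_config, seed=base_config.seed + split.fold_id)
        model = build_model(model_kind, input_dim, seed=seed * 1000 + split.fold_id)
        model, history = train_model(model, by_id, split, config)
        val_bags = [by_id[c] for c in split.val_ids]
        if model_kind == "milboost":
            train_bags = [by_id[c] for c in split.train_ids]
            feats_tr = np.vstack([enhanced_features(model.embed(b)) for b in train_bags])
            tiers_tr = np.array([b.tier for b in train_bags])
            bcfg = boost_config or BoostConfig(seed=seed)
            booster = fit_boosted(feats_tr, tiers_tr, bcfg)
            feats_va = np.vstack([enhanced_features(model.embed(b)) for b in val_bags])
            probs = booster.predict_proba(feats_va)
        else:
            probs = predict_probs(model, val_bags)
        tiers = np.array([b.tier for b in val_bags])
        reports.append(evaluate(probs, tiers))
        histories.append(history)
        for c, p in zip(split.val_ids, probs):
            pooled_probs[id_to_idx[c]] = p
            pooled_tiers[id_to_idx[c]] = by_id[c].tier
    return {
        "reports": reports,
        "last_model": model,
        "histories": histories,
        "pooled_probs": pooled_probs,
        "pooled_tiers": pooled_tiers,
        "folds": folds,
        "aggregate": aggregate_folds(reports),
    }


def fold_results_frame(reports: list[MetricsReport]) -> pd.DataFrame:
    """Per-fold scalar metrics as a tidy frame (one row per fold)."""
    return pd.DataFrame([{"fold": i, **r.scalars()} for i, r in enumerate(reports)])
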