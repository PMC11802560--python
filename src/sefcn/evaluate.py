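"""Leave-one-patient-out training and the evaluation metric suite.

The cross-validation protocol is patient-independent: with N patients,
each in turn is held out as the test set while a seeded random 20% of
the remaining patients' epochs forms the validation set and the other
80% trains the model.  Training runs with batch size 32 and the
checkpoint with the highest validation accuracy is the one evaluated.

Metrics: sensitivity TP/(TP+FN), specificity TN/(TN+FP), their
geometric mean, accuracy, the rank-statistic AUC, and per-event
detection latency.  Rates with a zero denominator are reported as NaN
("undefined"), never coerced to 0 or 1, so summaries are not silently
inflated.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .model import SEFCN, ModelConfig
from .preprocess import EpochSet
from . import nn

log = logging.getLogger(__name__)


# --------------------------------------------------------------------- splits
@dataclass(frozen=True)
class FoldSpec:
    test_patient: str
    train_patients: tuple[str, ...]
    validation_fraction: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.test_patient in self.train_patients:
            raise ValueError("test patient cannot appear among training patients")


def lopo_splits(
    patient_ids: list[str], validation_fraction: float = 0.20, seed: int = 0
) -> list[FoldSpec]:
    """One fold per patient; each patient is the test set exactly once."""
    ids = list(dict.fromkeys(patient_ids))
    if len(ids) < 2:
        raise ValueError(f"leave-one-patient-out needs >= 2 patients, got {len(ids)}")
    sub = np.random.SeedSequence(seed).generate_state(len(ids)) % (2**31)
    return [
        FoldSpec(
            test_patient=pid,
            train_patients=tuple(p for p in ids if p != pid),
            validation_fraction=validation_fraction,
            seed=int(sub[i]),
        )
        for i, pid in enumerate(ids)
    ]


def split_fold_epochs(
    fold: FoldSpec, epochs: EpochSet
) -> tuple[EpochSet, EpochSet, EpochSet]:
    """Partition an epoch set into (train, validation, test) for one fold.

    Validation is a seeded random fraction of the non-test patients'
    epochs, drawn by epoch as in the reference protocol.
    """
    pids = np.asarray(epochs.patient_ids)
    test_mask = pids == fold.test_patient
    pool_idx = np.flatnonzero(np.isin(pids, fold.train_patients))
    if len(pool_idx) == 0 or test_mask.sum() == 0:
        raise ValueError(f"fold {fold.test_patient}: empty train pool or test set")
    rng = np.random.default_rng(fold.seed)
    perm = rng.permutation(len(pool_idx))
    n_val = int(round(fold.validation_fraction * len(pool_idx)))
    val_idx = pool_idx[perm[:n_val]]
    train_idx = pool_idx[perm[n_val:]]
    return (
        epochs.subset(np.sort(train_idx)),
        epochs.subset(np.sort(val_idx)),
        epochs.subset(np.flatnonzero(test_mask)),
    )


# ------------------------------------------------------------------- training
@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train_loss) + 1),
                "train_loss": self.train_loss,
                "train_acc": self.train_acc,
                "val_loss": self.val_loss,
                "val_acc": self.val_acc,
            }
        )


def train_model(
    model: SEFCN,
    train: EpochSet,
    val: EpochSet,
    n_epochs: int = 100,
    batch_size: int = 32,
    lr: float = 1e-3,
    class_weights: np.ndarray | None = None,
    augment: bool = True,
    seed: int = 0,
) -> TrainHistory:
    """Mini-batch Adam training; restores the best-validation-accuracy state.

    The input scale is microvolts; epochs are standardized by the training
    set's global mean/std before entering the network (stored on the model
    so inference applies the same transform).

    ``augment`` applies two label-preserving transforms to each training
    batch: a random polarity flip (the sign of a bipolar derivation is a
    montage convention, not physiology) and a random circular time shift
    (epoch alignment is arbitrary under sliding-window segmentation).
    Both enforce invariances the detection task physically has and keep a
    small cohort from overfitting the discharge phase of individual
    training patients.
    """
    if train.labels is None or val.labels is None:
        raise ValueError("train/validation epoch sets must be labeled")
    classes = np.unique(train.labels)
    if len(classes) < 2:
        raise ValueError(
            f"training data contains a single class ({classes.tolist()}); "
            "cannot fit a binary classifier"
        )
    mu = float(train.epochs.mean())
    sd = float(train.epochs.std()) or 1.0
    model.input_mean, model.input_std = mu, sd

    x_train = (train.epochs - mu) / sd
    x_val = (val.epochs - mu) / sd
    y_train, y_val = train.labels, val.labels

    opt = nn.Adam(model.layers, lr=lr)
    rng = np.random.default_rng(seed)
    hist = TrainHistory()
    best_state, best_acc, best_loss = None, -np.inf, np.inf

    for _ in range(n_epochs):
        order = rng.permutation(len(x_train))
        losses, correct = [], 0
        for i in range(0, len(order), batch_size):
            idx = order[i : i + batch_size]
            xb = x_train[idx]
            if augment:
                xb = xb.copy()
                flip = rng.random(len(idx)) < 0.5
                xb[flip] *= -1.0
                shifts = rng.integers(0, xb.shape[2], len(idx))
                for j, sh in enumerate(shifts):
                    if sh:
                        xb[j] = np.roll(xb[j], int(sh), axis=-1)
            probs, _ = model.forward(xb, train=True)
            logits = np.log(probs + 1e-12)
            loss, dlogits = nn.cross_entropy_with_grad(logits, y_train[idx], class_weights)
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
            correct += int((probs.argmax(axis=1) == y_train[idx]).sum())
        hist.train_loss.append(float(np.mean(losses)))
        hist.train_acc.append(correct / len(order))

        val_probs = model.predict_proba(x_val)
        vloss, _ = nn.cross_entropy_with_grad(np.log(val_probs + 1e-12), y_val)
        vacc = float((val_probs.argmax(axis=1) == y_val).mean())
        hist.val_loss.append(vloss)
        hist.val_acc.append(vacc)
        # highest validation accuracy wins; ties go to the lower
        # validation loss (better-calibrated checkpoint)
        if vacc > best_acc or (vacc == best_acc and vloss < best_loss):
            best_acc, best_loss = vacc, vloss
            best_state = model.clone_state()
            hist.best_epoch = len(hist.val_acc) - 1

    if best_state is not None:
        model.set_state(best_state)
    return hist


def train_fold(
    fold: FoldSpec,
    epochs: EpochSet,
    config: ModelConfig = ModelConfig(),
    n_epochs: int = 100,
    batch_size: int = 32,
    lr: float = 1e-3,
) -> tuple[SEFCN, TrainHistory, EpochSet]:
    """Train one LOPO fold; returns (model, history, held-out test epochs)."""
    train, val, test = split_fold_epochs(fold, epochs)
    model = SEFCN(dataclasses.replace(config, seed=fold.seed))
    history = train_model(
        model, train, val, n_epochs=n_epochs, batch_size=batch_size, lr=lr,
        seed=fold.seed,
    )
    return model, history, test


def standardized(model: SEFCN, eps: EpochSet | np.ndarray) -> np.ndarray:
    """Apply the model's stored training-set standardization."""
    x = eps.epochs if isinstance(eps, EpochSet) else np.asarray(eps)
    mu = getattr(model, "input_mean", 0.0)
    sd = getattr(model, "input_std", 1.0)
    return (x - mu) / sd


# -------------------------------------------------------------------- metrics
@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(labels: np.ndarray, predictions: np.ndarray) -> ConfusionCounts:
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError(f"length mismatch: {labels.shape} vs {predictions.shape}")
    if labels.size == 0:
        raise ValueError("empty input")
    if set(np.unique(labels)) - {0, 1} or set(np.unique(predictions)) - {0, 1}:
        raise ValueError("labels and predictions must be binary 0/1")
    return ConfusionCounts(
        tp=int(((labels == 1) & (predictions == 1)).sum()),
        fp=int(((labels == 0) & (predictions == 1)).sum()),
        tn=int(((labels == 0) & (predictions == 0)).sum()),
        fn=int(((labels == 1) & (predictions == 0)).sum()),
    )


def _rate(num: int, den: int, name: str) -> float:
    if den == 0:
        log.warning("%s undefined: zero denominator", name)
        return float("nan")
    return num / den


def sen_spe_gmean_acc(counts: ConfusionCounts) -> tuple[float, float, float, float]:
    """Sensitivity, specificity, their geometric mean, and accuracy.

    sen = TP/(TP+FN); spe = TN/(TN+FP); gmean = sqrt(sen*spe);
    acc = (TP+TN)/total.  Undefined rates propagate as NaN.
    """
    sen = _rate(counts.tp, counts.tp + counts.fn, "sensitivity")
    spe = _rate(counts.tn, counts.tn + counts.fp, "specificity")
    gmean = float(np.sqrt(sen * spe))
    acc = _rate(counts.tp + counts.tn, counts.total, "accuracy")
    return sen, spe, gmean, acc


def auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Rank-statistic AUC: P(random positive outscores random negative).

    Ties count 1/2, i.e. the Mann-Whitney U statistic normalized by
    n_pos * n_neg.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape:
        raise ValueError("length mismatch between labels and scores")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        log.warning("AUC undefined: only one class present")
        return float("nan")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def detection_latency(
    labels_timeline: np.ndarray,
    preds_timeline: np.ndarray,
    epoch_len_s: float = 2.0,
) -> list[float]:
    """Per-seizure detection delay on aligned per-epoch timelines.

    Each contiguous run of 1-labels is a seizure event.  Its latency is
    the start time of the first predicted-positive epoch at or after the
    event's first epoch, minus the event's start; NaN when the event is
    never flagged before it ends.
    """
    labels = np.asarray(labels_timeline).astype(int)
    preds = np.asarray(preds_timeline).astype(int)
    if labels.shape != preds.shape:
        raise ValueError("timelines must be aligned (equal length)")
    latencies: list[float] = []
    edges = np.diff(np.concatenate([[0], labels, [0]]))
    onsets = np.flatnonzero(edges == 1)
    offsets = np.flatnonzero(edges == -1)
    for onset, offset in zip(onsets, offsets):
        hit = np.flatnonzero(preds[onset:offset] == 1)
        latencies.append(float(hit[0] * epoch_len_s) if len(hit) else float("nan"))
    return latencies


# -------------------------------------------------------------------- reports
PATIENT_COLUMNS = ["patient", "sen", "spe", "gmean", "acc", "auc", "latency_s"]


def evaluate_fold(model: SEFCN, test: EpochSet, threshold: float = 0.5) -> dict:
    """Epoch-level metrics of a trained model on one held-out patient."""
    x = standardized(model, test)
    probs = model.predict_proba(x)
    scores = probs[:, 1]
    preds = (scores >= threshold).astype(int)
    counts = confusion(test.labels, preds)
    sen, spe, gmean, acc = sen_spe_gmean_acc(counts)
    lat = detection_latency(test.labels, preds, test.window_s)
    lat_mean = float(np.nanmean(lat)) if lat and not np.all(np.isnan(lat)) else float("nan")
    return {
        "patient": str(test.patient_ids[0]),
        "sen": sen, "spe": spe, "gmean": gmean, "acc": acc,
        "auc": auc(test.labels, scores),
        "latency_s": lat_mean,
        "counts": counts,
        "scores": scores,
        "preds": preds,
    }


def summarize(per_patient: pd.DataFrame) -> pd.DataFrame:
    """Append a mean +/- SEM summary row to a per-patient metrics table.

    The summary G-Mean is the geometric mean of the mean sensitivity and
    mean specificity, sqrt(mean_sen * mean_spe) -- the convention used in
    published per-patient benchmark tables -- rather than the column mean.
    SEM = sd/sqrt(n) over patients, ignoring undefined entries.
    """
    if len(per_patient) < 2:
        raise ValueError("summary needs >= 2 patient rows")
    cols = [c for c in ("sen", "spe", "gmean", "acc", "auc", "latency_s")
            if c in per_patient.columns]
    means = {c: float(per_patient[c].mean()) for c in cols}
    sems = {
        c: float(per_patient[c].std(ddof=1) / np.sqrt(per_patient[c].notna().sum()))
        for c in cols
    }
    if "sen" in means and "spe" in means:
        means["gmean"] = float(np.sqrt(means["sen"] * means["spe"]))
    summary = per_patient.copy()
    mean_row = {"patient": "mean", **means}
    sem_row = {"patient": "sem", **sems}
    return pd.concat(
        [summary, pd.DataFrame([mean_row, sem_row])], ignore_index=True
    )


def run_lopo(
    epochs: EpochSet,
    config: ModelConfig = ModelConfig(),
    n_epochs: int = 100,
    batch_size: int = 32,
    lr: float = 1e-3,
    seed: int = 0,
    validation_fraction: float = 0.20,
) -> tuple[pd.DataFrame, dict[str, SEFCN]]:
    """Full leave-one-patient-out pass: per-patient metric rows + models."""
    patients = list(dict.fromkeys(np.asarray(epochs.patient_ids).tolist()))
    folds = lopo_splits(patients, validation_fraction, seed)
    rows, models = [], {}
    for fold in folds:
        model, history, test = train_fold(
            fold, epochs, config, n_epochs=n_epochs, batch_size=batch_size, lr=lr
        )
        res = evaluate_fold(model, test)
        res["best_epoch"] = history.best_epoch
        rows.append({k: res[k] for k in PATIENT_COLUMNS})
        models[fold.test_patient] = model
        log.info(
            "fold %s: sen=%.3f spe=%.3f gmean=%.3f",
            fold.test_patient, res["sen"], res["spe"], res["gmean"],
        )
    return pd.DataFrame(rows, columns=PATIENT_COLUMNS), models
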