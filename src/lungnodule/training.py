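"""Training loops and stratified evaluation.

Segmentation training follows the two-phase loss schedule: summed binary
cross entropy for the first ``bce_epochs`` epochs (a stabilizing warm-up
for the heavily class-imbalanced masks), then soft Dice loss for the
remainder.  The learning rate steps down twice over the run (1e-2 for
epochs 1..3/8, 1e-3 to 6/8, 1e-4 after), mirroring the published
64-epoch schedule.  For the optimizer step the BCE gradient is scaled by
the voxel count (mean rather than sum) so the step size is independent
of volume size; the logged loss is the summed form.

Classifier training minimizes mean negative log likelihood over one-hot
benign/malignant labels.  Both loops are deterministic given the config
seed.  Evaluation aggregates segmentation overlap per connected nodule
into the four diameter bins, and classification into a confusion matrix
with accuracy/recall/specificity and the ROC/AUC of the malignant-class
probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import losses, nn
from .metrics import (ConfusionMatrix, classification_metrics, dice_coefficient,
                      precision, recall, roc_auc)
from .phantom import equivalent_sphere_diameter_mm
from .preprocess import size_category
from .volume import SizeCategory


@dataclass
class SegTrainConfig:
    epochs: int = 64
    batch_size: int = 6
    lr: float = 1e-2
    lr_drops: tuple[float, float] = (1e-3, 1e-4)
    #: fractions of the run after which the rate drops (default 24/64, 48/64)
    lr_milestones: tuple[float, float] = (0.375, 0.75)
    bce_epochs: int = 3
    seed: int = 0

    def validate(self):
        if self.bce_epochs >= self.epochs:
            raise ValueError("bce_epochs must be < epochs")
        rates = (self.lr,) + tuple(self.lr_drops)
        if any(b >= a for a, b in zip(rates, rates[1:])):
            raise ValueError("learning-rate stages must be strictly decreasing")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if not (0 < self.lr_milestones[0] < self.lr_milestones[1] <= 1):
            raise ValueError("lr_milestones must be increasing fractions in (0, 1]")

    def lr_at(self, epoch: int) -> float:
        """Staged learning rate (1-based epoch)."""
        b1 = max(1, int(self.lr_milestones[0] * self.epochs))
        b2 = max(b1 + 1, int(self.lr_milestones[1] * self.epochs))
        if epoch <= b1:
            return self.lr
        if epoch <= b2:
            return self.lr_drops[0]
        return self.lr_drops[1]

    def active_loss(self, epoch: int) -> str:
        """Pure function of (epoch, bce_epochs); epoch is 1-based."""
        return "bce" if epoch <= self.bce_epochs else "dice"

    @classmethod
    def desk(cls, seed: int = 0) -> "SegTrainConfig":
        """CPU-sized configuration for small phantom cohorts.

        Small batches give the optimizer enough steps per epoch on a
        15-volume training set; the staged schedule holds the initial
        rate a little longer than the default thirds.
        """
        return cls(epochs=80, batch_size=2, lr=1e-2, lr_drops=(1e-3, 1e-4),
                   lr_milestones=(0.45, 0.75), bce_epochs=3, seed=seed)


@dataclass
class ClsTrainConfig:
    epochs: int = 52
    batch_size: int = 16
    lr: float = 1e-4
    seed: int = 0

    def validate(self):
        if self.epochs < 1 or self.batch_size < 1 or self.lr <= 0:
            raise ValueError("epochs, batch_size and lr must be positive")


def _batches(n, batch_size, rng):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def train_segmentation(model, dataset, config: SegTrainConfig):
    """Train on (grayscale volume in [0,1], binary mask) pairs.

    Returns (model, log) where log is one record per epoch:
    {"epoch", "loss_name", "loss", "lr"}.
    """
    config.validate()
    if not dataset:
        raise ValueError("empty dataset")
    vols = [np.asarray(v, dtype=np.float32) for v, _ in dataset]
    masks = [np.asarray(getattr(m, "values", m), dtype=np.float32) for _, m in dataset]
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model, lr=config.lr)
    log = []
    for epoch in range(1, config.epochs + 1):
        opt.lr = config.lr_at(epoch)
        loss_name = config.active_loss(epoch)
        epoch_losses = []
        for idx in _batches(len(vols), config.batch_size, rng):
            x = np.stack([vols[i] for i in idx])[:, None]
            t = np.stack([masks[i] for i in idx])[:, None]
            z = model.forward_logits(x)
            p = nn.sigmoid(z)
            nvox = p[0].size
            if loss_name == "bce":
                batch_loss = np.mean([losses.bce_loss(p[i], t[i])
                                      for i in range(len(idx))])
                # mean-per-voxel scaling keeps the step size volume-independent
                g_logits = (p - t) / (nvox * len(idx))
            else:
                batch_loss = np.mean([losses.dice_loss(p[i], t[i])
                                      for i in range(len(idx))])
                g_prob = np.stack([losses.dice_loss_grad(p[i], t[i])
                                   for i in range(len(idx))]) / len(idx)
                g_logits = g_prob * p * (1.0 - p)
            model.backward(g_logits.astype(np.float32))
            opt.step()
            epoch_losses.append(float(batch_loss))
        log.append({"epoch": epoch, "loss_name": loss_name,
                    "loss": float(np.mean(epoch_losses)), "lr": opt.lr})
    return model, log


def train_classifier(model, dataset, config: ClsTrainConfig):
    """Train on (ROI in [0,1], label) pairs; label 0 = benign, 1 = malignant."""
    config.validate()
    if not dataset:
        raise ValueError("empty dataset")
    rois = [np.asarray(v, dtype=np.float32) for v, _ in dataset]
    labels = np.array([int(l) for _, l in dataset])
    n_classes = model.spec.n_classes
    balance = {c: int((labels == c).sum()) for c in range(n_classes)}
    if len(set(labels.tolist())) < 2:
        import warnings

        warnings.warn(f"single-class dataset (balance {balance}); proceeding",
                      stacklevel=2)
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model, lr=config.lr)
    log = []
    for epoch in range(1, config.epochs + 1):
        epoch_losses = []
        for idx in _batches(len(rois), config.batch_size, rng):
            x = np.stack([rois[i] for i in idx])[:, None]
            onehot = np.eye(n_classes)[labels[idx]]
            logp = model.forward(x)
            epoch_losses.append(losses.nll_loss(np.exp(logp), onehot))
            g_logits = (np.exp(logp) - onehot) / len(idx)
            model.backward(g_logits.astype(np.float32))
            opt.step()
        log.append({"epoch": epoch, "loss": float(np.mean(epoch_losses)),
                    "class_balance": balance})
    return model, log


def _per_nodule_metrics(pred, truth, spacing_mm, pad_voxels=6):
    """Overlap per connected truth component, within its padded bbox."""
    lab, n = ndimage.label(np.asarray(getattr(truth, "values", truth), dtype=bool))
    pred = np.asarray(getattr(pred, "values", pred), dtype=bool)
    out = []
    for i in range(1, n + 1):
        comp = lab == i
        sl = ndimage.find_objects(comp.astype(np.int8))[0]
        sl = tuple(slice(max(0, s.start - pad_voxels), min(d, s.stop + pad_voxels))
                   for s, d in zip(sl, comp.shape))
        c, p = comp[sl], pred[sl]
        d_mm = equivalent_sphere_diameter_mm(int(comp.sum()), spacing_mm)
        try:
            dice = dice_coefficient(p, c)
        except ValueError:
            dice = float("nan")
        out.append({"diameter_mm": d_mm, "dice": dice,
                    "precision": precision(p, c), "recall": recall(p, c)})
    return out


def evaluate_segmentation(model, dataset, spacing_mm=(3.0, 1.5, 1.5),
                          threshold: float = 0.5, diameters=None):
    """Per-size-category mean Dice/precision/recall over connected nodules.

    ``dataset`` is (volume, truth mask) pairs; diameters default to the
    equivalent-sphere diameter of each truth component but can be given
    explicitly as a list-of-lists aligned with the components.
    """
    from .resunet3d import forward_segment, predict_mask

    rows = []
    for si, (vol, truth) in enumerate(dataset):
        prob = forward_segment(model, vol)
        pred = predict_mask(prob, threshold)
        per = _per_nodule_metrics(pred.values, truth, spacing_mm)
        if diameters is not None:
            for r, d in zip(per, diameters[si]):
                r["diameter_mm"] = d
        rows.extend(per)
    def _nanmean(vals):
        ok = [v for v in vals if not np.isnan(v)]
        return float(np.mean(ok)) if ok else float("nan")

    table = {}
    for cat in SizeCategory:
        sel = [r for r in rows if size_category(r["diameter_mm"]) is cat]
        if sel:
            table[cat.value] = {
                "n": len(sel),
                "dice": _nanmean([r["dice"] for r in sel]),
                "precision": _nanmean([r["precision"] for r in sel]),
                "recall": _nanmean([r["recall"] for r in sel]),
            }
    return table


def evaluate_classifier(model, dataset):
    """Confusion matrix at argmax, the three ratio metrics, and ROC/AUC."""
    from .resnet3d50 import classify_roi

    y_true, y_pred, scores = [], [], []
    for roi, label in dataset:
        cp = classify_roi(model, roi)
        y_true.append(int(label))
        y_pred.append(1 if cp.label == "malignant" else 0)
        scores.append(cp.p_malignant)
    if len(set(y_true)) < 2:
        raise ValueError("evaluation set must contain both classes")
    cm = ConfusionMatrix.from_predictions(y_true, y_pred)
    acc, rec, spec = classification_metrics(cm)
    fpr, tpr, auc = roc_auc(scores, y_true)
    return cm, {"accuracy": acc, "recall": rec, "specificity": spec}, (fpr, tpr), auc


def split_cohort(n: int, seed: int, fractions=(0.7, 0.15, 0.15)):
    """Deterministic train/val/test index split."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    return (order[:n_train].tolist(),
            order[n_train:n_train + n_val].tolist(),
            order[n_train + n_val:].tolist())
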