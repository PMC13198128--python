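"""Frozen-encoder downstream task heads, training recipes and metrics.

Six task heads consume embeddings from the pretrained encoders, which
stay completely frozen during fine-tuning (enforced by a cryptographic
digest of the encoder weights before and after every run):

* ``variant`` — pathogenic-missense classification over concatenated
  (wild-type, mutant) pooled sequence embeddings;
* ``thermostability`` — 5-class classification over pooled structure
  embeddings;
* ``acr`` — anti-CRISPR activity detection: a CNN over a stacked set of
  per-protein embeddings (query protein first, partner set after);
* ``peptide`` — bioactive-peptide binary classification: a CNN over the
  pooled sequence embedding viewed as a 1-D signal;
* ``mic`` — minimum-inhibitory-concentration regression (MLP);
* ``fitness`` — protein fitness regression over per-position sequence
  embeddings (convolution, mean over positions, linear read-out).

The metric suite (ACC, BACC, SN, SP, precision, recall, F1, MCC, AUC,
MSE, Spearman, Pearson, R^2) follows the definitional formulas, with a
rank-based, tie-corrected AUC.  ``run_task`` repeats head training over
seeds and reports mean +/- SD; ``paired_t_report`` compares two methods
with a two-sided paired t test on per-seed metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Sequence

import numpy as onp
import autograd.numpy as np
import pandas as pd
from scipy import stats as sps

from . import nn

__all__ = [
    "ConfusionSummary",
    "confusion_from",
    "auc_score",
    "compute_metrics",
    "UndefinedMetricError",
    "init_variant_head",
    "variant_forward",
    "init_thermo_head",
    "thermo_forward",
    "init_acr_head",
    "acr_forward",
    "init_peptide_head",
    "peptide_forward",
    "init_mic_head",
    "mic_forward",
    "init_fitness_head",
    "fitness_forward",
    "TaskSpec",
    "TaskReport",
    "train_head",
    "run_task",
    "aggregate_metrics",
    "paired_t_report",
    "validate_split_spec",
    "load_split_specs",
]


class UndefinedMetricError(ValueError):
    """A requested metric is undefined for the given inputs."""


# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class ConfusionSummary:
    """2x2 confusion counts with the derived classification metrics.

    Degenerate denominators follow the documented convention: a metric
    whose defining ratio is 0/0 evaluates to 0.0 (MCC likewise when any
    marginal is empty).
    """

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        for name in ("TP", "FP", "TN", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative count {name}")

    @staticmethod
    def _ratio(num, den):
        return num / den if den > 0 else 0.0

    @property
    def SN(self):  # sensitivity / recall
        return self._ratio(self.TP, self.TP + self.FN)

    @property
    def SP(self):  # specificity
        return self._ratio(self.TN, self.TN + self.FP)

    @property
    def ACC(self):
        return self._ratio(self.TP + self.TN, self.TP + self.TN + self.FP + self.FN)

    @property
    def BACC(self):
        return 0.5 * (self.SN + self.SP)

    @property
    def precision(self):
        return self._ratio(self.TP, self.TP + self.FP)

    @property
    def recall(self):
        return self.SN

    @property
    def F1(self):
        return self._ratio(2 * self.TP, 2 * self.TP + self.FP + self.FN)

    @property
    def MCC(self):
        den = (
            (self.TP + self.FP) * (self.TP + self.FN) * (self.TN + self.FP) * (self.TN + self.FN)
        )
        if den == 0:
            return 0.0
        return (self.TP * self.TN - self.FP * self.FN) / math.sqrt(den)


def confusion_from(y_true, y_pred) -> ConfusionSummary:
    y_true = onp.asarray(y_true).astype(int)
    y_pred = onp.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("truth and predictions must be equal-length and non-empty")
    return ConfusionSummary(
        TP=int(onp.sum((y_true == 1) & (y_pred == 1))),
        FP=int(onp.sum((y_true == 0) & (y_pred == 1))),
        TN=int(onp.sum((y_true == 0) & (y_pred == 0))),
        FN=int(onp.sum((y_true == 1) & (y_pred == 0))),
    )


def auc_score(y_true, scores) -> float:
    """Area under the ROC curve via the rank-sum (Mann-Whitney) form.

    Midranks handle ties, so tied scores contribute 1/2; all-tied
    scores give 0.5 exactly.
    """
    y_true = onp.asarray(y_true).astype(int)
    scores = onp.asarray(scores, dtype=float)
    n_pos = int(onp.sum(y_true == 1))
    n_neg = int(onp.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined: truth contains a single class")
    ranks = sps.rankdata(scores)
    r_pos = float(onp.sum(ranks[y_true == 1]))
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


_CLASSIFICATION = ("ACC", "BACC", "SN", "SP", "precision", "recall", "F1", "MCC")


def compute_metrics(y_true, predictions=None, scores=None, metrics: Sequence[str] = ("ACC",)) -> dict:
    """Compute requested metrics from truth plus predictions and/or scores.

    Classification metrics need hard ``predictions``; AUC needs
    ``scores``; regression metrics (MSE, Spearman, Pearson, R2) treat
    ``predictions`` as continuous estimates.
    """
    y_true = onp.asarray(y_true)
    if y_true.size == 0:
        raise ValueError("empty truth")
    out = {}
    conf = None
    for m in metrics:
        if m in _CLASSIFICATION:
            if predictions is None:
                raise ValueError(f"{m} needs hard predictions")
            if conf is None:
                conf = confusion_from(y_true, predictions)
            out[m] = float(getattr(conf, m))
        elif m == "AUC":
            if scores is None:
                raise ValueError("AUC needs scores")
            out[m] = float(auc_score(y_true, scores))
        elif m == "MSE":
            out[m] = float(onp.mean((onp.asarray(predictions, dtype=float) - y_true.astype(float)) ** 2))
        elif m == "Spearman":
            out[m] = float(sps.spearmanr(y_true, predictions).statistic)
        elif m == "Pearson":
            out[m] = float(sps.pearsonr(y_true.astype(float), onp.asarray(predictions, dtype=float)).statistic)
        elif m == "R2":
            y = y_true.astype(float)
            p = onp.asarray(predictions, dtype=float)
            ss_tot = float(onp.sum((y - y.mean()) ** 2))
            ss_res = float(onp.sum((y - p) ** 2))
            out[m] = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        else:
            raise ValueError(f"unknown metric {m!r}")
    return out


# ---------------------------------------------------------------------------
# heads


def init_variant_head(rng, d: int, hidden: int | None = None):
    """Binary MLP over concatenated (wild-type, mutant) embeddings.

    The full-scale recipe uses hidden width 1280 on 1280-wide
    embeddings; at other widths the hidden layer defaults to 2d.
    """
    hidden = hidden or 2 * d
    return {"fc1": nn.init_linear(rng, 2 * d, hidden), "fc2": nn.init_linear(rng, hidden, 2)}


def variant_forward(p, wt, mut, train: bool = False, rng=None, dropout: float = 0.5):
    """fc -> dropout(0.5) -> leaky ReLU -> fc -> softmax over 2 classes."""
    if mut is None:
        raise ValueError("variant head needs both wild-type and mutant embeddings")
    x = np.concatenate([wt, mut], axis=1)  # concatenation order is part of the contract
    h = nn.linear(p["fc1"], x)
    if train:
        h = h * nn.dropout_mask(rng, h.shape, dropout)
    h = nn.leaky_relu(h)
    return nn.softmax(nn.linear(p["fc2"], h), axis=1)


def init_thermo_head(rng, d: int, hidden: int = 128, classes: int = 5):
    return {
        "fc1": nn.init_linear(rng, d, hidden),
        "ln": nn.init_layer_norm(hidden),
        "fc2": nn.init_linear(rng, hidden, classes),
    }


def thermo_forward(p, x, modality: str = "structure"):
    """fc -> LayerNorm -> ReLU -> fc logits over the 5 thermostability bins."""
    if modality != "structure":
        raise ValueError(f"thermostability head expects structure embeddings, got {modality!r}")
    return nn.linear(p["fc2"], nn.relu(nn.layer_norm(p["ln"], nn.linear(p["fc1"], x))))


def init_acr_head(rng, d: int, channels: int = 4, hidden: int = 4, kernel: int = 7):
    return {
        "conv1": nn.init_conv1d(rng, d, channels, kernel),
        "bn1": nn.init_batchnorm(channels),
        "conv2": nn.init_conv1d(rng, channels, channels, kernel),
        "bn2": nn.init_batchnorm(channels),
        "fc1": nn.init_linear(rng, channels, hidden),
        "fc2": nn.init_linear(rng, hidden, 2),
    }


def _bn_block(p_bn, x, mask3, stats, collect):
    if stats is None:  # batch statistics (differentiable), over valid positions only
        if mask3 is None:
            mean = np.mean(x, axis=(0, 2))
            var = np.var(x, axis=(0, 2))
        else:
            denom = np.maximum(np.sum(mask3, axis=(0, 2)), 1.0)
            mean = np.sum(x * mask3, axis=(0, 2)) / denom
            var = np.sum(((x - mean[None, :, None]) ** 2) * mask3, axis=(0, 2)) / denom
        use = (mean, var)
    else:
        use = stats
    if collect is not None:
        collect.append((onp.asarray(use[0]), onp.asarray(use[1])))
    y = nn.batchnorm(p_bn, x, use)
    y = nn.relu(y)
    if mask3 is not None:
        y = y * mask3
    return y


def acr_forward(p, x, length_mask, train: bool = False, stats=None, collect=None, rng=None, dropout: float = 0.0):
    """Set-of-proteins classifier.

    x: (B, max_set, d) zero-padded stacked embeddings, query protein
    first; length_mask: (B, max_set).  Two 1-D convolutions (d -> 4 ->
    4 channels, kernel 7, stride 1, same padding), each followed by
    batch norm + ReLU and re-masked so padding rows contribute zero;
    masked mean over the set axis; two hidden-size-4 linear layers.
    """
    if x.shape[1] < 2:
        raise ValueError("acr head needs the query protein plus a non-empty partner set")
    sig = np.transpose(x, (0, 2, 1))  # (B, d, m)
    mask3 = length_mask[:, None, :]
    sig = sig * mask3
    s1, s2 = (None, None) if stats is None else stats
    h = conv = conv1d_masked(p["conv1"], sig)
    h = _bn_block(p["bn1"], h, mask3, s1, collect)
    h = conv1d_masked(p["conv2"], h)
    h = _bn_block(p["bn2"], h, mask3, s2, collect)
    denom = np.maximum(np.sum(length_mask, axis=1), 1.0)
    pooled = np.sum(h, axis=2) / denom[:, None]
    if train and dropout > 0.0:
        pooled = pooled * nn.dropout_mask(rng, pooled.shape, dropout)
    z = nn.relu(nn.linear(p["fc1"], pooled))
    if train and dropout > 0.0:
        z = z * nn.dropout_mask(rng, z.shape, dropout)
    return nn.linear(p["fc2"], z)


def conv1d_masked(p, sig):
    return nn.conv1d_same(p, sig)


def init_peptide_head(rng, d: int, channels: int = 32, hidden: int = 64, kernel: int = 3):
    L = d
    for _ in range(2):
        L = L + 2  # conv kernel 3, stride 1, padding 2
        L = (L + 2) // 2  # maxpool kernel 2, padding 1
    return {
        "conv1": nn.init_conv1d(rng, 1, channels, kernel),
        "bn1": nn.init_batchnorm(channels),
        "conv2": nn.init_conv1d(rng, channels, channels, kernel),
        "bn2": nn.init_batchnorm(channels),
        "fc1": nn.init_linear(rng, channels * L, hidden),
        "fc2": nn.init_linear(rng, hidden, 1),
    }


def peptide_forward(p, x, train: bool = False, rng=None, stats=None, collect=None, dropout: float = 0.15):
    """conv/BN/ReLU -> maxpool/dropout, twice; dense 64/ReLU/dropout; sigmoid."""
    sig = x[:, None, :]  # (B, 1, d): the pooled embedding as a 1-D signal
    s1, s2 = (None, None) if stats is None else stats
    h = nn.conv1d_same(p["conv1"], sig, padding=2)
    h = _bn_block(p["bn1"], h, None, s1, collect)
    h = nn.maxpool1d(h, kernel=2, padding=1)
    if train:
        h = h * nn.dropout_mask(rng, h.shape, dropout)
    h = nn.conv1d_same(p["conv2"], h, padding=2)
    h = _bn_block(p["bn2"], h, None, s2, collect)
    h = nn.maxpool1d(h, kernel=2, padding=1)
    if train:
        h = h * nn.dropout_mask(rng, h.shape, dropout)
    B = h.shape[0]
    flat = np.reshape(h, (B, -1))
    z = nn.relu(nn.linear(p["fc1"], flat))
    if train:
        z = z * nn.dropout_mask(rng, z.shape, dropout)
    return nn.sigmoid(nn.linear(p["fc2"], z))[:, 0]


def init_mic_head(rng, d: int, hidden: int = 256):
    return {"fc1": nn.init_linear(rng, d, hidden), "fc2": nn.init_linear(rng, hidden, 1)}


def mic_forward(p, x):
    """d -> 256 -> ReLU -> scalar regression output."""
    return nn.linear(p["fc2"], nn.relu(nn.linear(p["fc1"], x)))[:, 0]


def init_fitness_head(rng, d: int, kernel: int = 7):
    return {"conv": nn.init_conv1d(rng, d, d, kernel), "out": nn.init_linear(rng, d, 1)}


def fitness_forward(p, x, length_mask, train: bool = False, rng=None, dropout: float = 0.1):
    """Per-position embeddings (B, L, d) -> conv (same padding) ->
    dropout -> ReLU -> masked mean over positions -> linear scalar."""
    if x.shape[1] == 0:
        raise ValueError("fitness head needs at least one position")
    sig = np.transpose(x, (0, 2, 1))
    h = nn.conv1d_same(p["conv"], sig)
    if train:
        h = h * nn.dropout_mask(rng, h.shape, dropout)
    h = nn.relu(h)
    mask3 = length_mask[:, None, :]
    denom = np.maximum(np.sum(length_mask, axis=1), 1.0)
    pooled = np.sum(h * mask3, axis=2) / denom[:, None]
    return nn.linear(p["out"], pooled)[:, 0]


# ---------------------------------------------------------------------------
# losses


def _nll(probs, y, eps=1e-12):
    B = probs.shape[0]
    return -np.mean(np.log(probs[onp.arange(B), y] + eps))


def _ce_logits(logits, y):
    lse = nn.logsumexp(logits, axis=1)
    B = logits.shape[0]
    return np.mean(lse - logits[onp.arange(B), y])


def _bce(prob, y, eps=1e-12):
    return -np.mean(y * np.log(prob + eps) + (1 - y) * np.log(1 - prob + eps))


# ---------------------------------------------------------------------------
# training recipes


@dataclass(frozen=True)
class TaskSpec:
    """Identity, recipe and metric set of one downstream task run."""

    task: str
    modality: str
    metrics: tuple
    seeds: tuple = (0, 1, 2, 3, 4)
    epochs: int = 200
    batch_size: int = 32
    lr: float = 1e-4
    weight_decay: float = 0.0
    patience: int = 10
    extra: dict = field(default_factory=dict)


def _batches(rng, n, size):
    order = rng.permutation(n)
    for lo in range(0, n, size):
        yield order[lo : lo + size]


def _carve_val(rng, n, frac=0.1):
    order = rng.permutation(n)
    n_val = max(int(round(frac * n)), 1)
    return order[n_val:], order[:n_val]


def train_head(task: str, data: dict, seed: int, spec: TaskSpec):
    """Train one task head per its recipe; returns (params, aux).

    ``data`` carries the precomputed frozen-encoder embeddings; see the
    per-task branches for the expected keys.  Validation for early
    stopping is carved from the training set (10%, seed-dependent)
    where the recipe monitors validation performance.
    """
    rng = onp.random.default_rng(seed)
    if task == "variant":
        return _train_variant(rng, data, spec)
    if task == "thermostability":
        return _train_thermo(rng, data, spec)
    if task == "acr":
        return _train_acr(rng, data, spec)
    if task == "peptide":
        return _train_peptide(rng, data, spec)
    if task == "mic":
        return _train_mic(rng, data, spec)
    if task == "fitness":
        return _train_fitness(rng, data, spec)
    raise ValueError(f"unknown task {task!r}")


def _train_variant(rng, data, spec):
    Xw, Xm, y = data["wt"], data["mut"], data["y"]
    d = Xw.shape[1]
    p = init_variant_head(rng, d, hidden=spec.extra.get("hidden"))
    opt = nn.Adam(p, lr=spec.lr or 1e-4, weight_decay=spec.weight_decay or 1e-3)
    tr, va = _carve_val(rng, len(y))
    best, best_p, stale = onp.inf, p, 0
    for epoch in range(spec.epochs):
        for idx in _batches(rng, len(tr), spec.batch_size):
            rows = tr[idx]
            drop_rng = onp.random.default_rng(rng.integers(2**31 - 1))

            def obj(q):
                return _nll(variant_forward(q, Xw[rows], Xm[rows], train=True, rng=drop_rng), y[rows])

            loss, g = nn.value_and_grad(obj)(p)
            p = opt.step(p, g)
        val = float(_nll(variant_forward(p, Xw[va], Xm[va]), y[va]))
        if val < best - 1e-6:
            best, best_p, stale = val, p, 0
        else:
            stale += 1
            if stale >= spec.patience:
                break
    return best_p, {}


def _train_thermo(rng, data, spec):
    X, y = data["X"], data["y"]
    p = init_thermo_head(rng, X.shape[1])
    opt = nn.Adam(p, lr=spec.extra.get("lr", 1e-3))
    tr, va = _carve_val(rng, len(y))
    best, best_p, stale = onp.inf, p, 0
    for epoch in range(spec.epochs):
        for idx in _batches(rng, len(tr), spec.batch_size):
            rows = tr[idx]

            def obj(q):
                return _ce_logits(thermo_forward(q, X[rows]), y[rows])

            loss, g = nn.value_and_grad(obj)(p)
            p = opt.step(p, g)
        val = float(_ce_logits(thermo_forward(p, X[va]), y[va]))
        if val < best - 1e-6:
            best, best_p, stale = val, p, 0
        else:
            stale += 1
            if stale >= spec.patience:
                break
    return best_p, {}


def _train_acr(rng, data, spec):
    """Set-classifier recipe, including the swept dropout rate.

    The recipe sweeps dropout over [0.3, 0.5]; each candidate trains to
    the loss-plateau stop and the validation loss picks the winner.
    """
    X, M, y = data["X"], data["mask"], data["y"]
    tr, va = _carve_val(rng, len(y))
    epochs = spec.extra.get("epochs", 250)
    # the loss-plateau stop only engages after a burn-in, otherwise the
    # slow first epochs of a cold batch-norm stack trigger it spuriously
    min_epochs = spec.extra.get("min_epochs", 30)
    wd_start, wd_end = 0.01, 0.001

    def run(dropout, seed):
        local = onp.random.default_rng(seed)
        p = init_acr_head(local, X.shape[2])
        lr = spec.extra.get("lr", 3e-3)
        opt = nn.Adam(p, lr=lr)
        prev_epoch_loss, best_val, stale = None, onp.inf, 0
        for epoch in range(epochs):
            wd = wd_start + (wd_end - wd_start) * epoch / max(epochs - 1, 1)
            losses = []
            for idx in _batches(local, len(tr), spec.batch_size):
                rows = tr[idx]
                drop_rng = onp.random.default_rng(local.integers(2**31 - 1))

                def obj(q):
                    logits = acr_forward(q, X[rows], M[rows], train=True, rng=drop_rng, dropout=dropout)
                    return _ce_logits(logits, y[rows])

                loss, g = nn.value_and_grad(obj)(p)
                p = opt.step(p, g, lr=lr, weight_decay=wd)
                losses.append(float(loss))
            epoch_loss = float(onp.mean(losses))
            stats = _population_stats_acr(p, X[tr], M[tr])
            val = float(_ce_logits(acr_forward(p, X[va], M[va], stats=stats), y[va]))
            if val < best_val - 1e-6:
                best_val, stale = val, 0
            else:
                stale += 1
                if stale >= 10:
                    lr *= 0.9
                    stale = 0
            if (
                epoch + 1 >= min_epochs
                and prev_epoch_loss is not None
                and 0 <= prev_epoch_loss - epoch_loss < 0.005
            ):
                break
            prev_epoch_loss = epoch_loss
        return p, best_val

    candidates = spec.extra.get("dropout_sweep", (0.3, 0.4, 0.5))
    best = None
    for dropout in candidates:
        p, val = run(dropout, seed=int(rng.integers(2**31 - 1)))
        if best is None or val < best[1]:
            best = (p, val, dropout)
    p = best[0]
    stats = _population_stats_acr(p, X, M)
    return p, {"stats": stats, "dropout": best[2]}


def _population_stats_acr(p, X, M):
    collect: list = []
    acr_forward(p, X, M, collect=collect)
    return collect


def _population_stats_peptide(p, X):
    collect: list = []
    peptide_forward(p, X, collect=collect)
    return collect


def _train_peptide(rng, data, spec):
    X, y = data["X"], data["y"].astype(float)
    p = init_peptide_head(rng, X.shape[1])
    lr = spec.extra.get("lr", 1e-2)
    opt = nn.SGD(p, lr=lr, momentum=0.5)
    tr, va = _carve_val(rng, len(y))
    best_acc, best_p, best_stats, stale = -onp.inf, p, None, 0
    for epoch in range(spec.extra.get("epochs", 200)):
        lr_now = lr * (0.5 ** (epoch // 50))  # step decay
        for idx in _batches(rng, len(tr), spec.batch_size):
            rows = tr[idx]
            drop_rng = onp.random.default_rng(rng.integers(2**31 - 1))

            def obj(q):
                return _bce(peptide_forward(q, X[rows], train=True, rng=drop_rng), y[rows])

            loss, g = nn.value_and_grad(obj)(p)
            p = opt.step(p, g, lr=lr_now)
        stats = _population_stats_peptide(p, X[tr])
        val_pred = peptide_forward(p, X[va], stats=stats) > 0.5
        val_acc = float(onp.mean(val_pred == (y[va] > 0.5)))
        if val_acc > best_acc:
            best_acc, best_p, best_stats, stale = val_acc, p, stats, 0
        else:
            stale += 1
            if stale >= spec.extra.get("early_stop", 40):
                break
    if best_stats is None:
        best_stats = _population_stats_peptide(best_p, X)
    return best_p, {"stats": best_stats}


def _train_mic(rng, data, spec):
    X, y = data["X"], data["y"].astype(float)
    p = init_mic_head(rng, X.shape[1])
    lr0 = spec.extra.get("lr", 1e-4)
    lr_lambda: Callable[[int], float] = spec.extra.get("lr_lambda", lambda epoch: 1.0)
    opt = nn.Adam(p, lr=lr0)
    for epoch in range(spec.extra.get("epochs", 200)):
        lr_now = lr0 * lr_lambda(epoch)
        for idx in _batches(rng, len(y), spec.batch_size):
            rows = idx

            def obj(q):
                pred = mic_forward(q, X[rows])
                return np.mean((pred - y[rows]) ** 2)

            loss, g = nn.value_and_grad(obj)(p)
            p = opt.step(p, g, lr=lr_now)
    return p, {}


def _train_fitness(rng, data, spec):
    # full-scale recipe: AdamW 3e-4 for 10,000 steps; the desk default
    # runs a fifth of the steps and compensates with a higher rate
    X, M, y = data["X"], data["mask"], data["y"].astype(float)
    p = init_fitness_head(rng, X.shape[2])
    total_steps = spec.extra.get("steps", 2000)
    warmup = spec.extra.get("warmup", 100)
    base_lr = spec.extra.get("lr", 1e-3)
    opt = nn.AdamW(p, lr=base_lr, weight_decay=5e-2, betas=(0.9, 0.999))
    lr_at = nn.cosine_schedule(base_lr, total_steps, warmup=warmup)
    batch = spec.extra.get("batch", 64)
    n = len(y)
    for step in range(total_steps):
        rows = rng.choice(n, size=min(batch, n), replace=False)
        drop_rng = onp.random.default_rng(rng.integers(2**31 - 1))

        def obj(q):
            pred = fitness_forward(q, X[rows], M[rows], train=True, rng=drop_rng)
            return np.mean((pred - y[rows]) ** 2)

        loss, g = nn.value_and_grad(obj)(p)
        p = opt.step(p, g, lr=lr_at(step))
    return p, {}


# ---------------------------------------------------------------------------
# task running and reporting


@dataclass
class TaskReport:
    task: str
    per_seed: list  # list of metric dicts, one per seed
    mean: dict
    sd: dict
    seeds: tuple


def aggregate_metrics(per_seed: Sequence[dict]):
    keys = per_seed[0].keys()
    mean = {k: float(onp.mean([m[k] for m in per_seed])) for k in keys}
    sd = {k: float(onp.std([m[k] for m in per_seed], ddof=1)) if len(per_seed) > 1 else 0.0 for k in keys}
    return mean, sd


def evaluate_head(task: str, params, aux: dict, data: dict, metrics: Sequence[str]) -> dict:
    """Evaluation-mode predictions on the test split + metric map."""
    if task == "variant":
        probs = onp.asarray(variant_forward(params, data["wt"], data["mut"]))
        return compute_metrics(data["y"], probs.argmax(1), scores=probs[:, 1], metrics=metrics)
    if task == "thermostability":
        logits = onp.asarray(thermo_forward(params, data["X"]))
        return compute_metrics(data["y"], logits.argmax(1), metrics=metrics)
    if task == "acr":
        logits = onp.asarray(acr_forward(params, data["X"], data["mask"], stats=aux.get("stats")))
        probs = onp.asarray(nn.softmax(logits, axis=1))
        return compute_metrics(data["y"], probs.argmax(1), scores=probs[:, 1], metrics=metrics)
    if task == "peptide":
        prob = onp.asarray(peptide_forward(params, data["X"], stats=aux.get("stats")))
        return compute_metrics(data["y"], (prob > 0.5).astype(int), scores=prob, metrics=metrics)
    if task == "mic":
        pred = onp.asarray(mic_forward(params, data["X"]))
        return compute_metrics(data["y"], pred, metrics=metrics)
    if task == "fitness":
        pred = onp.asarray(fitness_forward(params, data["X"], data["mask"]))
        return compute_metrics(data["y"], pred, metrics=metrics)
    raise ValueError(f"unknown task {task!r}")


def run_task(spec: TaskSpec, train_data: dict, test_data: dict, encoder_params=None) -> TaskReport:
    """Train the head once per seed on frozen embeddings and report.

    When ``encoder_params`` is supplied, its digest is checked before
    and after every run; any mutation is a hard failure of the frozen
    contract.
    """
    digest_before = nn.tree_digest(encoder_params) if encoder_params is not None else None
    per_seed = []
    for seed in spec.seeds:
        params, aux = train_head(spec.task, train_data, seed, spec)
        per_seed.append(evaluate_head(spec.task, params, aux, test_data, spec.metrics))
        if digest_before is not None and nn.tree_digest(encoder_params) != digest_before:
            raise RuntimeError("frozen contract violated: encoder weights changed during fine-tuning")
    mean, sd = aggregate_metrics(per_seed)
    return TaskReport(task=spec.task, per_seed=per_seed, mean=mean, sd=sd, seeds=tuple(spec.seeds))


def paired_t_report(metrics_a: Sequence[float], metrics_b: Sequence[float], alpha: float = 0.05) -> dict:
    """Two-sided paired t test on per-seed metrics of two method variants."""
    a = onp.asarray(metrics_a, dtype=float)
    b = onp.asarray(metrics_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need equal-length per-seed metric lists (>= 2 seeds)")
    diffs = a - b
    if onp.allclose(diffs.std(ddof=1), 0.0):
        return {"t": float("nan"), "p": 1.0 if onp.allclose(diffs, 0.0) else float("nan"),
                "undefined_variance": True, "significant": False}
    res = sps.ttest_rel(a, b)
    return {"t": float(res.statistic), "p": float(res.pvalue), "undefined_variance": False,
            "significant": bool(res.pvalue < alpha)}


# ---------------------------------------------------------------------------
# bridging synthetic task datasets to frozen-encoder embeddings


def _embed_sequences(params, cfgs, sequences, batch_size=64, per_position=False):
    from .corpus_io import tokenize_sequence
    from .encoders import encode_sequence_batch, pad_token_batch

    pooled_rows, pos_rows, lengths = [], [], []
    toks = [tokenize_sequence(s) for s in sequences]
    for lo in range(0, len(toks), batch_size):
        chunk = toks[lo : lo + batch_size]
        ids, mask, _ = pad_token_batch(chunk)
        H, p = encode_sequence_batch(params["sequence"], cfgs["sequence"], ids, mask)
        pooled_rows.append(onp.asarray(p))
        if per_position:
            for j, t in enumerate(chunk):
                pos_rows.append(onp.asarray(H[j, 1 : len(t) - 1]))  # residue positions only
                lengths.append(len(t) - 2)
    pooled = onp.concatenate(pooled_rows)
    if not per_position:
        return pooled
    L = max(lengths)
    d = pooled.shape[1]
    X = onp.zeros((len(pos_rows), L, d))
    M = onp.zeros((len(pos_rows), L))
    for i, h in enumerate(pos_rows):
        X[i, : h.shape[0]] = h
        M[i, : h.shape[0]] = 1.0
    return X, M


def _embed_structures(params, cfgs, structures, batch_size=32):
    from .encoders import build_residue_graph, encode_structure_batch, pad_graph_batch

    rows = []
    for lo in range(0, len(structures), batch_size):
        graphs = pad_graph_batch(
            [build_residue_graph(s, k=cfgs["structure"].knn) for s in structures[lo : lo + batch_size]]
        )
        _, p = encode_structure_batch(params["structure"], cfgs["structure"], graphs)
        rows.append(onp.asarray(p))
    return onp.concatenate(rows)


def prepare_task_data(dataset, params, cfgs):
    """Embed a synthetic TaskDataset with frozen encoders.

    Returns (head_task_id, train_data, test_data) ready for
    :func:`train_head` / :func:`evaluate_head`.
    """

    def _arrays(split):
        if dataset.task == "pairwise_variant":
            wt = _embed_sequences(params, cfgs, [r.sequence for r, _, _ in split])
            mut = _embed_sequences(params, cfgs, [m for _, m, _ in split])
            y = onp.array([lab for _, _, lab in split], dtype=int)
            return {"wt": wt, "mut": mut, "y": y}
        if dataset.task == "five_class_thermo":
            X = _embed_structures(params, cfgs, [r.structure for r, _ in split])
            return {"X": X, "y": onp.array([lab for _, lab in split], dtype=int)}
        if dataset.task == "fitness":
            X, M = _embed_sequences(params, cfgs, [r.sequence for r, _ in split], per_position=True)
            return {"X": X, "mask": M, "y": onp.array([lab for _, lab in split], dtype=float)}
        if dataset.task == "pairing":
            sets = [tuple(r.sequence for r in recs) for recs, _ in split]
            flat = [s for group in sets for s in group]
            emb = _embed_sequences(params, cfgs, flat)
            d = emb.shape[1]
            m = max(len(g) for g in sets)
            X = onp.zeros((len(sets), m, d))
            M = onp.zeros((len(sets), m))
            pos = 0
            for i, g in enumerate(sets):
                X[i, : len(g)] = emb[pos : pos + len(g)]
                M[i, : len(g)] = 1.0
                pos += len(g)
            return {"X": X, "mask": M, "y": onp.array([lab for _, lab in split], dtype=int)}
        # pooled-sequence tasks
        X = _embed_sequences(params, cfgs, [r.sequence for r, _ in split])
        dtype = float if dataset.task == "regression_mic" else int
        return {"X": X, "y": onp.array([lab for _, lab in split], dtype=dtype)}

    head = {
        "binary_peptide": "peptide",
        "regression_mic": "mic",
        "five_class_thermo": "thermostability",
        "pairwise_variant": "variant",
        "fitness": "fitness",
        "pairing": "acr",
    }[dataset.task]
    return head, _arrays(dataset.train), _arrays(dataset.test)


# ---------------------------------------------------------------------------
# documented real-data split specifications


def load_split_specs() -> pd.DataFrame:
    with resources.files("trialign.data").joinpath("split_specs.csv").open() as fh:
        return pd.read_csv(fh)


def validate_split_spec(task: str, counts: dict) -> dict:
    """Check provided split counts against the recorded specification.

    Returns {"passed": bool, "mismatches": {cell: (expected, got)}}.
    Unknown task ids raise; missing or extra cells count as mismatches.
    """
    table = load_split_specs()
    rows = table[table["task"] == task]
    if rows.empty:
        raise ValueError(f"no recorded split specification for task {task!r}")
    expected = dict(zip(rows["cell"], rows["count"]))
    mismatches = {}
    for cell, exp in expected.items():
        got = counts.get(cell)
        if got != exp:
            mismatches[cell] = (int(exp), got)
    for cell in counts:
        if cell not in expected:
            mismatches[cell] = (None, counts[cell])
    return {"passed": not mismatches, "mismatches": mismatches}
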