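"""Sleep/wake dense segmentation model (scikit-learn style estimator).

:class:`SleepWakeSegmenter` maps preprocessed 128 Hz EEG+EOG signals to
per-cell sleep vs wakefulness-like probabilities at a configurable grid
resolution. The network is a 1-D U-Net over the sample axis with a
segment head (average pooling over ``resolution_s`` of samples followed
by a pointwise 2-class softmax). Training minimizes class-weighted
cross-entropy on randomly sampled windows with early stopping on
validation Cohen's kappa; transfer learning is participant-grouped
4-fold cross-validated fine-tuning of all weights at a reduced
learning rate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.model_selection import GroupKFold

from ._nn import Adam, UNet1d, weighted_cross_entropy
from .errors import ContractError
from .evaluation import cohen_kappa
from .hypnogram import WAKE_LIKE, GridLabels, ProbabilityTrack
from .signal_io import PsgRecord

logger = logging.getLogger(__name__)

EOG_PREFIXES = ("E1", "E2", "EOG", "LOC", "ROC")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture constants (all exposed, none hard-coded)."""

    depth: int = 2
    base_filters: int = 8
    kernel: int = 9
    resolution_s: int = 1
    fs: float = 128.0
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ContractError("depth must be >= 1")
        if self.kernel % 2 != 1:
            raise ContractError("kernel must be odd")
        if abs(self.resolution_s * self.fs - round(self.resolution_s * self.fs)) > 0:
            raise ContractError("resolution_s x fs must be a whole sample count")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol constants."""

    lr: float = 1e-3
    finetune_lr: float = 1e-4
    batch_size: int = 16
    window_s: int = 60
    max_epochs: int = 30
    finetune_epochs: int = 8
    patience: int = 5
    class_weight: str = "balanced"
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.finetune_lr > self.lr:
            raise ContractError("finetune_lr must be <= lr")
        if self.window_s % 30 != 0:
            raise ContractError("window_s must be a multiple of 30")


def available_pairs(record: PsgRecord) -> list[tuple[int, int]]:
    """All (EEG, EOG) channel-index pairs of a record.

    EOG channels are recognized by conventional name prefixes; when a
    record has no recognizable EEG/EOG split, the first two channels
    form the single pair.
    """
    names = record.channel_names
    eog = [i for i, n in enumerate(names) if n.upper().startswith(EOG_PREFIXES)]
    eeg = [i for i in range(len(names)) if i not in eog]
    if eog and eeg:
        return [(i, j) for i in eeg for j in eog]
    if len(names) >= 2:
        return [(0, 1)]
    raise ContractError("record needs at least one usable (EEG, EOG) pair")


def _as_array(x) -> np.ndarray:
    if isinstance(x, PsgRecord):
        n = min(c.samples.size for c in x.channels)
        return np.stack([c.samples[:n] for c in x.channels]).astype(np.float32)
    arr = np.asarray(x, dtype=np.float32)
    if arr.ndim != 2:
        raise ContractError(f"expected (channels, samples) array, got {arr.shape}")
    return arr


class SleepWakeSegmenter(BaseEstimator):
    """1-D U-Net sleep/wake-like segmenter.

    Parameters mirror :class:`ModelConfig` and :class:`TrainConfig`;
    see those for semantics. ``X`` passed to :meth:`fit` /
    :meth:`predict` is a sequence of preprocessed
    :class:`~somnoseg.signal_io.PsgRecord` at ``fs`` (or raw
    ``(channels, samples)`` arrays); ``y`` is a sequence of
    :class:`~somnoseg.hypnogram.GridLabels` at ``resolution_s``.

    Attributes (after fit)
    ----------------------
    net_ : the trained network
    history_ : per-epoch DataFrame (train_loss, val_kappa)
    class_weights_ : weights used in the loss
    best_val_kappa_ : early-stopping criterion value of the kept model
    """

    def __init__(self, depth: int = 2, base_filters: int = 8, kernel: int = 9,
                 resolution_s: int = 1, fs: float = 128.0,
                 lr: float = 1e-3, finetune_lr: float = 1e-4,
                 batch_size: int = 16, window_s: int = 60,
                 max_epochs: int = 30, finetune_epochs: int = 8,
                 patience: int = 5, class_weight: str = "balanced",
                 val_fraction: float = 0.2, block_s: int = 600,
                 random_state: int = 0):
        self.depth = depth
        self.base_filters = base_filters
        self.kernel = kernel
        self.resolution_s = resolution_s
        self.fs = fs
        self.lr = lr
        self.finetune_lr = finetune_lr
        self.batch_size = batch_size
        self.window_s = window_s
        self.max_epochs = max_epochs
        self.finetune_epochs = finetune_epochs
        self.patience = patience
        self.class_weight = class_weight
        self.val_fraction = val_fraction
        self.block_s = block_s
        self.random_state = random_state

    @classmethod
    def from_configs(cls, mcfg: ModelConfig, tcfg: TrainConfig
                     ) -> "SleepWakeSegmenter":
        return cls(depth=mcfg.depth, base_filters=mcfg.base_filters,
                   kernel=mcfg.kernel, resolution_s=mcfg.resolution_s,
                   fs=mcfg.fs, lr=tcfg.lr, finetune_lr=tcfg.finetune_lr,
                   batch_size=tcfg.batch_size, window_s=tcfg.window_s,
                   max_epochs=tcfg.max_epochs,
                   finetune_epochs=tcfg.finetune_epochs,
                   patience=tcfg.patience, class_weight=tcfg.class_weight,
                   val_fraction=tcfg.val_fraction, random_state=mcfg.seed)

    # -- internals --------------------------------------------------------

    @property
    def _cell_samples(self) -> int:
        cs = self.resolution_s * self.fs
        if cs != int(cs):
            raise ContractError("resolution_s x fs must be a whole sample count")
        return int(cs)

    def _validate_cfg(self) -> None:
        ModelConfig(self.depth, self.base_filters, self.kernel,
                    self.resolution_s, self.fs, 2, self.random_state)
        TrainConfig(self.lr, self.finetune_lr, self.batch_size, self.window_s,
                    self.max_epochs, self.finetune_epochs, self.patience,
                    self.class_weight, self.val_fraction, self.random_state)
        if self._cell_samples % (2 ** self.depth) != 0:
            raise ContractError(
                f"resolution of {self._cell_samples} samples is incompatible "
                f"with depth {self.depth} (needs divisibility by 2^depth)"
            )

    def build_net(self, in_channels: int = 2) -> UNet1d:
        """Construct the (untrained) network for this configuration."""
        self._validate_cfg()
        return UNet1d(in_channels, self.depth, self.base_filters, self.kernel,
                      self._cell_samples, 2, self.random_state)

    def _prepare(self, X, y):
        if len(X) == 0:
            raise ContractError("empty dataset")
        if len(X) != len(y):
            raise ContractError(f"len(X)={len(X)} != len(y)={len(y)}")
        cs = self._cell_samples
        items = []
        for rec, lab in zip(X, y):
            if lab.resolution_s != self.resolution_s:
                raise ContractError(
                    f"labels at {lab.resolution_s} s but model resolution is "
                    f"{self.resolution_s} s"
                )
            arr = _as_array(rec)
            pairs = (available_pairs(rec) if isinstance(rec, PsgRecord)
                     else [(0, 1)] if arr.shape[0] >= 2 else None)
            if pairs is None:
                raise ContractError("need >= 2 signal channels")
            n_cells = min(len(lab), arr.shape[1] // cs)
            if n_cells * cs < arr.shape[1]:
                arr = arr[:, :n_cells * cs]
            items.append((arr, lab.labels[:n_cells].astype(np.int64), pairs))
        return items

    def _class_weights(self, items) -> np.ndarray:
        counts = np.zeros(2)
        for _arr, lab, _p in items:
            counts += np.bincount(lab, minlength=2)
        if self.class_weight == "balanced" and counts.min() > 0:
            w = counts.sum() / (2.0 * counts)
        else:
            w = np.ones(2)
        return (w / w.mean()).astype(np.float64)

    def _epoch(self, net, opt, items, rng, win_cells, weights):
        cs = self._cell_samples
        total_cells = sum(lab.size for _a, lab, _p in items)
        steps = max(1, int(np.ceil(total_cells / (win_cells * self.batch_size))))
        losses = []
        eligible = [i for i, (_a, lab, _p) in enumerate(items)
                    if lab.size >= win_cells]
        if not eligible:
            raise ContractError(
                f"no recording is at least one {self.window_s} s window long"
            )
        for _ in range(steps):
            xb = np.empty((self.batch_size, 2, win_cells * cs), dtype=np.float32)
            yb = np.empty((self.batch_size, win_cells), dtype=np.int64)
            for b in range(self.batch_size):
                i = eligible[rng.integers(len(eligible))]
                arr, lab, pairs = items[i]
                s = int(rng.integers(lab.size - win_cells + 1))
                pi, pj = pairs[rng.integers(len(pairs))]
                xb[b, 0] = arr[pi, s * cs:(s + win_cells) * cs]
                xb[b, 1] = arr[pj, s * cs:(s + win_cells) * cs]
                yb[b] = lab[s:s + win_cells]
            logits = net.forward(xb, train=True)
            loss, dlogits = weighted_cross_entropy(logits, yb, weights)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: loss={loss} at optimizer step {opt.t}"
                )
            opt.zero_grad()
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
        return float(np.mean(losses))

    def _val_kappa(self, net, items) -> float:
        preds, refs = [], []
        for arr, lab, pairs in items:
            p = self._forward_array(net, arr, pairs)
            n = min(p.shape[1], lab.size)
            preds.append((p[WAKE_LIKE, :n] >= 0.5).astype(np.uint8))
            refs.append(lab[:n].astype(np.uint8))
        pred = GridLabels(np.concatenate(preds), self.resolution_s)
        ref = GridLabels(np.concatenate(refs), self.resolution_s)
        return cohen_kappa(pred, ref)

    def _forward_array(self, net, arr: np.ndarray, pairs) -> np.ndarray:
        """Pair-averaged class probabilities, shape (2, n_cells)."""
        cs = self._cell_samples
        n = arr.shape[1]
        n_cells = n // cs
        if n_cells * cs != n:
            logger.warning("dropping final partial cell (%d samples)",
                           n - n_cells * cs)
            n = n_cells * cs
        block = max(self.block_s // self.resolution_s, 1)  # cells per block
        halo = 30 // self.resolution_s if self.resolution_s <= 30 else 0
        acc = np.zeros((2, n_cells), dtype=np.float64)
        for pi, pj in pairs:
            x = np.stack([arr[pi, :n], arr[pj, :n]])[None, ...]
            for c0 in range(0, n_cells, block):
                c1 = min(c0 + block, n_cells)
                h0, h1 = max(0, c0 - halo), min(n_cells, c1 + halo)
                probs = net.predict_proba(x[:, :, h0 * cs:h1 * cs])[0]
                acc[:, c0:c1] += probs[:, c0 - h0:c0 - h0 + (c1 - c0)]
        return acc / len(pairs)

    def _train_loop(self, net, items, val_items, lr, max_epochs, rng):
        win_cells = self.window_s // self.resolution_s
        weights = self._class_weights(items)
        opt = Adam(net.params, lr=lr)
        history = []
        best_kappa, best_state, since_best = -np.inf, None, 0
        for epoch in range(max_epochs):
            loss = self._epoch(net, opt, items, rng, win_cells, weights)
            vk = self._val_kappa(net, val_items)
            history.append({"epoch": epoch, "train_loss": loss, "val_kappa": vk})
            if vk > best_kappa + 1e-6:
                best_kappa, since_best = vk, 0
                best_state = {k: v.copy() for k, v in net.state_arrays().items()}
            else:
                since_best += 1
                if since_best >= self.patience:
                    break
        if best_state is not None:
            net.load_state_arrays(best_state)
        return pd.DataFrame(history), best_kappa, weights

    # -- estimator API ----------------------------------------------------

    def fit(self, X, y, validation=None):
        """Train from random initialization.

        ``validation`` is an optional ``(X_val, y_val)`` pair; when
        omitted, ``val_fraction`` of the recordings is held out (the
        sets are disjoint). A single-recording dataset validates on
        itself (overfit/sanity mode).
        """
        self._validate_cfg()
        items = self._prepare(X, y)
        rng = np.random.default_rng(self.random_state)
        if validation is not None:
            val_items = self._prepare(*validation)
        elif len(items) == 1:
            logger.warning("single recording: validating on the training data")
            val_items = items
        else:
            n_val = max(1, int(round(self.val_fraction * len(items))))
            order = rng.permutation(len(items))
            val_items = [items[i] for i in order[:n_val]]
            items = [items[i] for i in order[n_val:]]
        net = self.build_net(in_channels=2)
        self.history_, self.best_val_kappa_, self.class_weights_ = \
            self._train_loop(net, items, val_items, self.lr, self.max_epochs, rng)
        self.net_ = net
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X) -> list[ProbabilityTrack]:
        """Per-recording WAKE_LIKE probability tracks (pair-averaged)."""
        self._check_fitted()
        out = []
        for rec in X:
            arr = _as_array(rec)
            pairs = (available_pairs(rec) if isinstance(rec, PsgRecord)
                     else [(0, 1)])
            onset = rec.start_offset_s if isinstance(rec, PsgRecord) else 0.0
            p = self._forward_array(self.net_, arr, pairs)
            out.append(ProbabilityTrack(p[WAKE_LIKE], self.resolution_s, onset))
        return out

    def predict(self, X) -> list[GridLabels]:
        """Hard labels: argmax of the probabilities, ties to WAKE_LIKE."""
        return [pt.argmax_labels() for pt in self.predict_proba(X)]

    def score(self, X, y) -> float:
        """Mean Cohen's kappa across recordings (sklearn scorer hook)."""
        ks = [cohen_kappa(p, GridLabels(r.labels, r.resolution_s, p.onset_s))
              for p, r in zip(self.predict(X), y)]
        return float(np.mean(ks))

    def finetune(self, X, y, groups, n_splits: int = 4):
        """Participant-grouped k-fold transfer learning.

        Recordings are partitioned into ``n_splits`` folds with no
        participant split across folds; each fold model fine-tunes all
        weights at ``finetune_lr`` on the other folds and validates on
        its own. Returns ``(best_estimator, report)`` where the best
        fold model is chosen by validation kappa and ``report`` holds
        per-fold pre/post kappa.
        """
        self._check_fitted()
        groups = np.asarray(groups)
        if len(groups) != len(X):
            raise ContractError("groups must parallel X")
        if len(np.unique(groups)) < n_splits:
            raise ContractError(
                f"need >= {n_splits} distinct participants, "
                f"got {len(np.unique(groups))}"
            )
        items = self._prepare(X, y)
        rng = np.random.default_rng(self.random_state + 1)
        rows, fold_nets = [], []
        gkf = GroupKFold(n_splits=n_splits)
        for fold, (tr, va) in enumerate(gkf.split(np.arange(len(items)),
                                                  groups=groups)):
            tr_items = [items[i] for i in tr]
            va_items = [items[i] for i in va]
            pre_kappa = self._val_kappa(self.net_, va_items)
            net = self.net_.clone()
            hist, post_kappa, _w = self._train_loop(
                net, tr_items, va_items, self.finetune_lr,
                self.finetune_epochs, rng)
            fold_nets.append(net)
            rows.append({
                "fold": fold, "n_train": len(tr), "n_val": len(va),
                "val_participants": sorted(set(groups[va])),
                "pre_kappa": pre_kappa, "post_kappa": post_kappa,
                "epochs_run": len(hist),
            })
        report = pd.DataFrame(rows)
        best = int(report["post_kappa"].idxmax())
        final = self._clone_with_net(fold_nets[best])
        final.finetune_report_ = report
        return final, report

    def _clone_with_net(self, net) -> "SleepWakeSegmenter":
        est = SleepWakeSegmenter(**self.get_params())
        est.net_ = net
        est.classes_ = np.array([0, 1])
        est.history_ = getattr(self, "history_", None)
        est.class_weights_ = getattr(self, "class_weights_", None)
        return est

    def _check_fitted(self) -> None:
        if not hasattr(self, "net_"):
            raise ContractError("model is not fitted; call fit() or load()")

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        self._check_fitted()
        meta = json.dumps({"params": self.get_params(),
                           "in_channels": self.net_.in_channels})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **self.net_.state_arrays())

    @classmethod
    def load(cls, path) -> "SleepWakeSegmenter":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            est = cls(**meta["params"])
            net = est.build_net(in_channels=meta["in_channels"])
            net.load_state_arrays({k: data[k] for k in data.files
                                   if k.startswith("p")})
        est.net_ = net
        est.classes_ = np.array([0, 1])
        return est
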