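"""Training loop and the four training / knowledge-transfer strategies.

Strategies
----------
DT
    direct training on the target species dataset only.
SP
    supervised pre-training: train on the annotated pre-training dataset
    only (and evaluate as-is on the target species).
GM
    general model: train once on the pre-training and species data pooled,
    with no fine-tuning stage.
TSTL
    two-stage transfer learning: train on the pre-training dataset, then
    fine-tune the checkpoint on the target species dataset (optionally with
    the GRU layers frozen).

Optimization is Adam on the class-weighted binary cross-entropy, with the
positive-class weight recomputed from the positive ratio of whichever set
is being trained on.  Model selection monitors validation AUPRC: the
learning rate is multiplied by ``plateau_factor`` after ``plateau_patience``
epochs without improvement, and training stops after
``early_stop_patience`` non-improving epochs.  The returned parameters are
the best-epoch checkpoint.  Runs are bit-reproducible from the seed on CPU.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import model as M
from .objectives import (LabeledScores, auprc, bce_grad_wrt_logits,
                         class_weight, evaluate, weighted_bce)
from .seqio import apportion
from .synthetic_data import LabeledFeatures

logger = logging.getLogger(__name__)

STRATEGIES = ("DT", "SP", "GM", "TSTL")


@dataclass
class TrainConfig:
    max_epochs: int = 200
    batch_size: int = 64
    initial_lr: float = 1e-3
    plateau_factor: float = 0.5
    plateau_patience: int = 5
    early_stop_patience: int = 10
    seed: int = 0
    strategy: str = "DT"
    freeze_gru: bool = False
    # model shape (repo defaults; not tuned values from any external source)
    n_layers: int = 6
    hidden: int = 32
    disc_hidden: int = 64
    # Adam moments
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.plateau_patience < 1 or self.early_stop_patience < 1:
            raise ValueError("patiences must be >= 1")
        if not 0.0 < self.plateau_factor < 1.0:
            raise ValueError("plateau_factor must be in (0, 1)")
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")


@dataclass
class TrainHistory:
    """Per-epoch trace of one training run."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_auprc: list[float] = field(default_factory=list)
    val_auc: list[float] = field(default_factory=list)
    val_bacc: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = -1  # 0-based index into the lists
    strategy: str = ""

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, self.n_epochs + 1),
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "val_auprc": self.val_auprc,
                "val_auc": self.val_auc,
                "val_bacc": self.val_bacc,
                "lr": self.lr,
            }
        )


@dataclass
class FeaturizedSplit:
    """Train/validation(/test) arrays for one featurized dataset."""

    X_train: np.ndarray
    y_train: np.ndarray
    X_val: np.ndarray
    y_val: np.ndarray
    X_test: Optional[np.ndarray] = None
    y_test: Optional[np.ndarray] = None
    name: str = ""

    @property
    def pos_ratio(self) -> float:
        return float(np.mean(self.y_train))


def split_features(
    data: LabeledFeatures,
    fractions: tuple[float, float, float] = (0.81, 0.09, 0.10),
    seed: int = 0,
) -> FeaturizedSplit:
    """Stratified train/validation/test split of a labeled feature set,
    using the same largest-remainder apportionment as the sequence splitter."""
    X, y = data.arrays()
    n = len(y)
    sizes = apportion(n, fractions)
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[], [], []]
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    pos_sizes = apportion(len(pos_idx), fractions)
    neg_sizes = [s - p for s, p in zip(sizes, pos_sizes)]
    if any(s < 0 for s in neg_sizes):
        neg_sizes = apportion(len(neg_idx), fractions)
    for idx, gsizes in ((pos_idx, pos_sizes), (neg_idx, neg_sizes)):
        perm = rng.permutation(len(idx))
        start = 0
        for k, gs in enumerate(gsizes):
            parts[k].extend(idx[perm[start : start + gs]])
            start += gs
    tr, va, te = (np.sort(np.array(p, dtype=int)) for p in parts)
    return FeaturizedSplit(
        X[tr], y[tr], X[va], y[va], X[te], y[te], name=data.name
    )


# --------------------------------------------------------------------------
# Adam
# --------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: M.ClassifierParams, cfg: TrainConfig) -> None:
        self.cfg = cfg
        self.t = 0
        self.m = M.zero_grads(params)
        self.v = M.zero_grads(params)

    def step(self, params: M.ClassifierParams, grads: dict, lr: float) -> None:
        c = self.cfg
        self.t += 1
        bc1 = 1.0 - c.beta1**self.t
        bc2 = 1.0 - c.beta2**self.t

        def update(target, name, g, m, v):
            m[name] = c.beta1 * m[name] + (1 - c.beta1) * g
            v[name] = c.beta2 * v[name] + (1 - c.beta2) * g * g
            mhat = m[name] / bc1
            vhat = v[name] / bc2
            cur = getattr(target, name)
            setattr(target, name, cur - lr * mhat / (np.sqrt(vhat) + c.adam_eps))

        for li, layer in enumerate(params.layers):
            if params.frozen_mask[li]:
                continue
            for name in layer.names():
                update(layer, name, grads["layers"][li][name],
                       self.m["layers"][li], self.v["layers"][li])
        d = params.discriminator
        for name in d.names():
            update(d, name, grads["disc"][name], self.m["disc"], self.v["disc"])


# --------------------------------------------------------------------------
# Training loop
# --------------------------------------------------------------------------

def _val_metrics(params: M.ClassifierParams, X: np.ndarray, y: np.ndarray, w: float):
    logits, p = M.forward(X, params, mode="eval")
    scores = LabeledScores(y, p)
    loss = weighted_bce(scores, w)
    rep = evaluate(scores)
    return loss, rep


def train(
    params: M.ClassifierParams,
    data: FeaturizedSplit,
    cfg: TrainConfig,
) -> tuple[M.ClassifierParams, TrainHistory]:
    """Optimize ``params`` on ``data`` per the configured schedule.

    Returns the best-epoch checkpoint (by validation AUPRC) and the full
    history.  ``params`` is not mutated.
    """
    if len(data.y_train) == 0 or len(data.y_val) == 0:
        raise ValueError("train and validation parts must be nonempty")
    if data.y_train.min() == data.y_train.max():
        raise ValueError("training part must contain both classes")
    if data.y_val.min() == data.y_val.max():
        raise ValueError("validation part must contain both classes")

    params = copy.deepcopy(params)
    w = class_weight(data.pos_ratio)
    logger.info(
        "training %s: n=%d (pos_ratio=%.4f, w=%.3f), val n=%d",
        data.name or "dataset", len(data.y_train), data.pos_ratio, w, len(data.y_val),
    )
    rng = np.random.default_rng(cfg.seed)
    opt = _Adam(params, cfg)
    history = TrainHistory(strategy=cfg.strategy)
    lr = cfg.initial_lr
    best_auprc = -np.inf
    best_params = copy.deepcopy(params)
    since_improve = 0
    since_plateau = 0
    n = len(data.y_train)

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            Xb, yb = data.X_train[idx], data.y_train[idx]
            cache: dict = {}
            logits, p = M.forward(Xb, params, mode="train", _cache=cache)
            scores = LabeledScores(yb, p)
            epoch_loss += weighted_bce(scores, w) * len(idx)
            dlogits = bce_grad_wrt_logits(scores.y, scores.p, w)
            grads = M.backward(dlogits, params, cache)
            opt.step(params, grads, lr)
        epoch_loss /= n

        val_loss, rep = _val_metrics(params, data.X_val, data.y_val, w)
        history.train_loss.append(epoch_loss)
        history.val_loss.append(val_loss)
        history.val_auprc.append(rep.auprc)
        history.val_auc.append(rep.auc)
        history.val_bacc.append(rep.bacc)
        history.lr.append(lr)

        if rep.auprc > best_auprc:
            best_auprc = rep.auprc
            best_params = copy.deepcopy(params)
            history.best_epoch = epoch
            since_improve = 0
            since_plateau = 0
        else:
            since_improve += 1
            since_plateau += 1
            if since_plateau >= cfg.plateau_patience:
                lr *= cfg.plateau_factor
                since_plateau = 0
                logger.info("epoch %d: plateau, lr -> %.2e", epoch + 1, lr)
            if since_improve >= cfg.early_stop_patience:
                logger.info("epoch %d: early stop (best epoch %d)",
                            epoch + 1, history.best_epoch + 1)
                break
    return best_params, history


def _pool(a: FeaturizedSplit, b: FeaturizedSplit) -> FeaturizedSplit:
    return FeaturizedSplit(
        np.concatenate([a.X_train, b.X_train]),
        np.concatenate([a.y_train, b.y_train]),
        np.concatenate([a.X_val, b.X_val]),
        np.concatenate([a.y_val, b.y_val]),
        b.X_test, b.y_test,
        name=f"{a.name}+{b.name}",
    )


def run_strategy(
    strategy: str,
    pretrain_data: Optional[FeaturizedSplit],
    species_data: FeaturizedSplit,
    cfg: TrainConfig,
    fine_tune_epochs: Optional[int] = None,
) -> tuple[M.ClassifierParams, TrainHistory]:
    """Run one training/transfer strategy and return its final model.

    ``fine_tune_epochs`` caps the TSTL fine-tuning stage (``None`` = the
    config's ``max_epochs``; 0 returns the pre-trained checkpoint as-is).
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    cfg = replace(cfg, strategy=strategy)
    d_in = species_data.X_train.shape[1]
    init = M.init_params(cfg.n_layers, d_in, cfg.hidden, cfg.disc_hidden, seed=cfg.seed)
    empty_pretrain = pretrain_data is None or len(pretrain_data.y_train) == 0

    if strategy == "DT":
        return train(init, species_data, cfg)
    if strategy == "SP":
        if empty_pretrain:
            raise ValueError("SP needs a nonempty pre-training dataset")
        return train(init, pretrain_data, cfg)
    if strategy == "GM":
        if empty_pretrain:
            logger.info("GM with empty pre-training data reduces to DT")
            return train(init, species_data, cfg)
        return train(init, _pool(pretrain_data, species_data), cfg)
    # TSTL
    if empty_pretrain:
        raise ValueError("TSTL needs a nonempty pre-training dataset")
    sp_params, sp_hist = train(init, pretrain_data, cfg)
    if fine_tune_epochs == 0:
        sp_hist.strategy = "TSTL"
        return sp_params, sp_hist
    ft_params = M.copy_and_freeze(sp_params, cfg.freeze_gru)
    ft_cfg = replace(cfg, max_epochs=fine_tune_epochs or cfg.max_epochs)
    return train(ft_params, species_data, ft_cfg)


def compare_strategies(
    pretrain_data: FeaturizedSplit,
    species_data: FeaturizedSplit,
    cfg: TrainConfig,
) -> pd.DataFrame:
    """Train all four strategies and evaluate each on the species test set.

    Returns a strategy x metric table (BACC, MCC, AUC, AUPRC)."""
    if species_data.X_test is None:
        raise ValueError("species data needs a test part")
    rows = []
    for strategy in STRATEGIES:
        params, _ = run_strategy(strategy, pretrain_data, species_data, cfg)
        _, p = M.forward(species_data.X_test, params, mode="eval")
        rep = evaluate(LabeledScores(species_data.y_test, p))
        rows.append(
            {"strategy": strategy, "bacc": rep.bacc, "mcc": rep.mcc,
             "auc": rep.auc, "auprc": rep.auprc}
        )
    return pd.DataFrame(rows).set_index("strategy")


def cross_domain_matrix(
    models: dict[str, M.ClassifierParams],
    testsets: dict[str, tuple[np.ndarray, np.ndarray]],
) -> pd.DataFrame:
    """AUPRC increments of cross-domain models over the in-domain model.

    Entry (a, b) = AUPRC(model_a on test_b) - AUPRC(model_b on test_b);
    the diagonal is 0 by construction.  Rows = training domain, columns =
    testing domain.
    """
    names = list(models)
    if set(names) != set(testsets):
        raise ValueError("models and testsets must cover the same domains")
    base = {}
    for b in names:
        Xb, yb = testsets[b]
        _, p = M.forward(Xb, models[b], mode="eval")
        base[b] = auprc(LabeledScores(yb, p))
    mat = np.zeros((len(names), len(names)))
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if a == b:
                continue
            Xb, yb = testsets[b]
            _, p = M.forward(Xb, models[a], mode="eval")
            mat[i, j] = auprc(LabeledScores(yb, p)) - base[b]
    return pd.DataFrame(mat, index=names, columns=names)
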