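"""Supervised training: loss, AdamW, stratified nested CV and the ensemble.

Training minimizes per-residue cross-entropy between the observed class
(orientation case collapsed: B/b -> B, H/h -> H) and the smoothed-softmax
output of the network; the Gaussian filter sits inside the trained graph but
the Viterbi decoder does not.  Models train for a fixed number of epochs
with AdamW (betas 0.9/0.999, decoupled weight decay on all trained tensors)
and an exponential learning-rate decay of 0.8 per epoch.

Model development uses a stratified five-fold nested cross-validation over
eight protein groups ({beta barrel, single-helix alpha, multi-helix alpha,
globular} x {signal peptide, none}): for each outer fold, hyperparameters
are selected by rotating a validation fold through the remaining four, the
best configuration is retrained on all four, and the held-out fold is
predicted by that model only.  The five outer models form the final
ensemble; at inference their smoothed class probabilities are averaged and
the mean is decoded by the Viterbi algorithm.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from memtop.decoder import StateMachine, build_state_machine, labels_to_segments, viterbi_decode
from memtop.io_formats import CLASS_INDEX, LabelSequence
from memtop.model_core import (
    ModelConfig,
    ModelParams,
    init_model,
    loss_and_gradients,
    predict_probabilities,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "Ensemble",
    "assign_group",
    "stratified_split",
    "targets_from_labels",
    "train_model",
    "grid_search",
    "nested_cross_validation",
    "ensemble_predict",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 15
    batch_size: int = 16
    lr0: float = 1e-3
    weight_decay: float = 1e-2
    betas: tuple[float, float] = (0.9, 0.999)
    lr_decay_factor: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 < self.lr_decay_factor <= 1.0:
            raise ValueError("lr_decay_factor must be in (0, 1]")

    def lr_at(self, epoch: int) -> float:
        """Learning rate used during epoch ``epoch`` (0-based)."""
        return self.lr0 * self.lr_decay_factor**epoch


@dataclass
class Ensemble:
    """The cross-validation ensemble: one member per outer fold."""

    members: list[ModelParams]
    fold_of: dict[str, int] = field(default_factory=dict)
    member_configs: list[TrainConfig] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# dataset bookkeeping

def assign_group(labels: LabelSequence | str) -> tuple[str, bool]:
    """Stratification group of a labeled protein.

    Beta barrel if the annotation holds any TMB segment (proteins with both
    strand and helix segments count as beta and are logged); otherwise
    single/multi-helix alpha by TMH count; otherwise globular.  Crossed with
    presence of a signal peptide.
    """
    segs = labels_to_segments(labels)
    kinds = [s.kind for s in segs]
    has_sp = "SP" in kinds
    n_b = kinds.count("TMB")
    n_h = kinds.count("TMH")
    if n_b:
        if n_h:
            logger.info("protein with both TMB and TMH segments assigned to beta group")
        kind = "beta"
    elif n_h == 1:
        kind = "alpha_single"
    elif n_h >= 2:
        kind = "alpha_multi"
    else:
        kind = "globular"
    return kind, has_sp


def stratified_split(groups: Mapping[str, tuple[str, bool]], k: int = 5,
                     seed: int = 0) -> dict[str, int]:
    """Deal each stratification group round-robin into k folds after a
    seeded shuffle; within every group the fold sizes differ by at most 1."""
    rng = np.random.default_rng(seed)
    folds: dict[str, int] = {}
    by_group: dict[tuple[str, bool], list[str]] = {}
    for pid in sorted(groups):
        by_group.setdefault(groups[pid], []).append(pid)
    for grp in sorted(by_group):
        ids = by_group[grp]
        if len(ids) < k:
            logger.info("group %s has only %d members for %d folds", grp, len(ids), k)
        rng.shuffle(ids)
        for j, pid in enumerate(ids):
            folds[pid] = j % k
    return folds


_COLLAPSE = {"B": "B", "b": "B", "H": "H", "h": "H", "S": "S", "i": "i", "o": "o"}


def targets_from_labels(labels: LabelSequence | str) -> np.ndarray:
    """Per-residue class indices with orientation case collapsed."""
    s = labels.labels if isinstance(labels, LabelSequence) else labels
    return np.array([CLASS_INDEX[_COLLAPSE[c]] for c in s], dtype=np.int64)


# ---------------------------------------------------------------------------
# optimization

class _AdamW:
    """Decoupled-weight-decay Adam over a ModelParams tensor dict."""

    def __init__(self, params: ModelParams, betas: tuple[float, float],
                 weight_decay: float, eps: float = 1e-8) -> None:
        self.params = params
        self.b1, self.b2 = betas
        self.wd = weight_decay
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: Mapping[str, np.ndarray], lr: float) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for key, p in self.params.items():
            g = grads[key]
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g**2
            mhat = self.m[key] / bc1
            vhat = self.v[key] / bc2
            p -= lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p)


def _dataset_loss(params: ModelParams, data: Sequence[tuple[np.ndarray, np.ndarray]]) -> float:
    """Mean per-residue cross-entropy over a dataset, dropout off."""
    total, n_res = 0.0, 0
    for x, y in data:
        loss, _ = loss_and_gradients(params, x, y, training=False)
        total += loss
        n_res += len(y)
    return total / max(n_res, 1)


def train_model(
    train: Sequence[tuple[np.ndarray, np.ndarray]],
    val: Sequence[tuple[np.ndarray, np.ndarray]],
    model_config: ModelConfig,
    train_config: TrainConfig,
) -> tuple[ModelParams, dict[str, list[float]]]:
    """Train one model; returns final-epoch params and the loss history.

    ``train``/``val`` are (feature matrix, collapsed target vector) pairs.
    Gradients are accumulated over each batch of proteins and averaged by the
    total residue count in the batch (unweighted mean over residues).  No
    early stopping: the final epoch's weights are returned.
    """
    if not train:
        raise ValueError("empty training set")
    dims = {x.shape[1] for x, _ in itertools.chain(train, val)}
    if dims != {model_config.input_dim}:
        raise ValueError(f"feature dims {dims} inconsistent with config D={model_config.input_dim}")
    params = init_model(model_config, train_config.seed)
    opt = _AdamW(params, train_config.betas, train_config.weight_decay)
    rng = np.random.default_rng(np.random.SeedSequence([train_config.seed, 0xBA7C4]))
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": [], "lr": []}

    n = len(train)
    for epoch in range(train_config.epochs):
        lr = train_config.lr_at(epoch)
        order = rng.permutation(n)
        epoch_loss, epoch_res = 0.0, 0
        for b0 in range(0, n, train_config.batch_size):
            batch = order[b0 : b0 + train_config.batch_size]
            acc: dict[str, np.ndarray] | None = None
            batch_res = 0
            for j in batch:
                x, y = train[j]
                dseed = int(rng.integers(2**31))
                loss, grads = loss_and_gradients(params, x, y, dropout_seed=dseed)
                epoch_loss += loss
                batch_res += len(y)
                if acc is None:
                    acc = grads
                else:
                    for key in acc:
                        acc[key] += grads[key]
            assert acc is not None
            for key in acc:
                acc[key] /= batch_res
            epoch_res += batch_res
            opt.step(acc, lr)
        history["train_loss"].append(epoch_loss / max(epoch_res, 1))
        history["val_loss"].append(_dataset_loss(params, val) if val else float("nan"))
        history["lr"].append(lr)
    return params, history


def grid_search(
    dev_sets: Sequence[Sequence[tuple[np.ndarray, np.ndarray]]],
    grid: Sequence[TrainConfig],
    model_config: ModelConfig,
) -> tuple[TrainConfig, dict]:
    """Pick the config with the lowest validation loss averaged over all
    leave-one-out rotations of the inner development folds."""
    if not grid:
        raise ValueError("empty hyperparameter grid")
    if len(dev_sets) < 2:
        raise ValueError("need at least 2 inner folds")
    results: list[tuple[float, int]] = []
    for ci, cfg in enumerate(grid):
        losses = []
        for vi in range(len(dev_sets)):
            tr = [p for j, s in enumerate(dev_sets) if j != vi for p in s]
            va = dev_sets[vi]
            _, hist = train_model(tr, va, model_config, cfg)
            losses.append(hist["val_loss"][-1])
        results.append((float(np.mean(losses)), ci))
    best_loss, best_ci = min(results)
    report = {"val_loss_per_config": [r[0] for r in sorted(results, key=lambda r: r[1])],
              "n_rotations": len(dev_sets)}
    return grid[best_ci], report


def nested_cross_validation(
    dataset: Mapping[str, tuple[np.ndarray, LabelSequence]],
    k: int = 5,
    grid: Sequence[TrainConfig] | None = None,
    seed: int = 0,
    model_config: ModelConfig | None = None,
    base_train_config: TrainConfig | None = None,
) -> tuple[Ensemble, dict[str, tuple[np.ndarray, LabelSequence]]]:
    """Stratified k-fold nested CV; returns the ensemble and per-protein
    held-out predictions (id -> (mean-able probabilities, decoded labels)).

    Every protein is predicted exactly once, by the single outer model whose
    training folds exclude it.
    """
    if model_config is None:
        some_x = next(iter(dataset.values()))[0]
        model_config = ModelConfig(input_dim=some_x.shape[1])
    base = base_train_config or TrainConfig()
    if grid is None:
        grid = [base]
    groups = {pid: assign_group(lab) for pid, (_, lab) in dataset.items()}
    fold_of = stratified_split(groups, k=k, seed=seed)
    prepared = {pid: (x, targets_from_labels(lab)) for pid, (x, lab) in dataset.items()}

    sm = build_state_machine()
    members: list[ModelParams] = []
    member_cfgs: list[TrainConfig] = []
    predictions: dict[str, tuple[np.ndarray, LabelSequence]] = {}
    for f in range(k):
        dev_folds = [j for j in range(k) if j != f]
        dev_sets = [[prepared[pid] for pid in sorted(prepared) if fold_of[pid] == j]
                    for j in dev_folds]
        if len(grid) > 1:
            best_cfg, _ = grid_search(dev_sets, grid, model_config)
        else:
            best_cfg = grid[0]
        best_cfg = replace(best_cfg, seed=seed * 1000 + f)
        dev_all = [p for s in dev_sets for p in s]
        params, _ = train_model(dev_all, [], model_config, best_cfg)
        members.append(params)
        member_cfgs.append(best_cfg)
        for pid in sorted(prepared):
            if fold_of[pid] != f:
                continue
            probs = predict_probabilities(params, prepared[pid][0])
            predictions[pid] = (probs, viterbi_decode(probs, sm).labels)
    return Ensemble(members, fold_of, member_cfgs), predictions


def ensemble_predict(ensemble: Ensemble, x: np.ndarray,
                     sm: StateMachine | None = None) -> tuple[np.ndarray, LabelSequence]:
    """Average the members' smoothed class probabilities, then Viterbi-decode
    the mean into a grammar-valid label string."""
    if not ensemble.members:
        raise ValueError("empty ensemble")
    probs = np.mean([predict_probabilities(m, x) for m in ensemble.members], axis=0)
    path = viterbi_decode(probs, sm or build_state_machine())
    return probs, path.labels
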