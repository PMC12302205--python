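"""Ensemble training of residual-correction models.

For each molecule the final prediction is the physics value plus the mean
correction of an ensemble of independently seeded members (or, in
DNN-alone mode, the mean network output itself).  Members are trained
with minibatch Adam on the mean-squared error of the combined prediction,
with early stopping on validation RMSE and reversion to the best epoch.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from ._autograd import Tensor
from .featurization import MolecularGraph
from .gnn_models import GraphBatch, init_model

logger = logging.getLogger("deltasolv.training")


@dataclass
class LabeledBatch:
    y_expt: np.ndarray
    y_phys: np.ndarray
    y_corr: np.ndarray

    def __post_init__(self):
        self.y_expt = np.asarray(self.y_expt, dtype=float)
        self.y_phys = np.asarray(self.y_phys, dtype=float)
        self.y_corr = np.asarray(self.y_corr, dtype=float)
        n = len(self.y_expt)
        if n < 1 or len(self.y_phys) != n or len(self.y_corr) != n:
            raise ValueError("y_expt, y_phys, y_corr must share length n >= 1")

    @property
    def n(self) -> int:
        return len(self.y_expt)


def residual_loss(batch: LabeledBatch) -> float:
    """Mean squared error of the combined prediction; equals RMSE**2."""
    resid = batch.y_expt - (batch.y_phys + batch.y_corr)
    return float(np.mean(resid * resid))


@dataclass
class TrainConfig:
    batch_size: int = 100
    learning_rate: float = 0.001
    patience: int = 20  # epochs; 20 for MPNN, 100 for GraphConv
    min_delta: float = 0.01  # kcal/mol improvement to reset patience
    max_epochs: int = 500
    ensemble_size: int = 20
    base_seed: int = 0
    mode: str = "residual"  # residual | dnn_alone

    def __post_init__(self):
        if self.patience < 1 or self.min_delta < 0 or self.ensemble_size < 1:
            raise ValueError("invalid training configuration")
        if self.mode not in ("residual", "dnn_alone"):
            raise ValueError(f"unknown mode {self.mode!r}")


DEFAULT_PATIENCE = {"mpnn": 20, "graphconv": 100}
DEFAULT_MAX_EPOCHS = {"mpnn": 500, "graphconv": 2000}


class EarlyStopper:
    """Stop when validation RMSE fails to improve by `min_delta` within
    `patience` epochs; remembers the best epoch for weight reversion."""

    def __init__(self, patience: int, min_delta: float):
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf  # strict minimum seen (weights revert here)
        self.best_epoch = -1
        self._anchor = np.inf  # last value that counted as an improvement
        self.epochs_since_improvement = 0

    def update(self, epoch: int, val_rmse: float) -> bool:
        """Record one epoch; returns True when training should stop."""
        if val_rmse < self.best:
            self.best = val_rmse
            self.best_epoch = epoch
        if val_rmse < self._anchor - self.min_delta:
            self._anchor = val_rmse
            self.epochs_since_improvement = 0
        else:
            self.epochs_since_improvement += 1
        return self.epochs_since_improvement >= self.patience


class Adam:
    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * p.grad
            self.v[k] = b2 * self.v[k] + (1 - b2) * p.grad * p.grad
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


@dataclass
class TrainingHistory:
    train_loss: list = field(default_factory=list)
    val_rmse: list = field(default_factory=list)
    best_epoch: int = -1
    best_val_rmse: float = np.inf
    stopped_epoch: int = -1


def _phys_values(graphs: Sequence[MolecularGraph], mode: str) -> np.ndarray:
    if mode == "dnn_alone":
        return np.zeros(len(graphs))
    vals = [g.y_phys for g in graphs]
    if any(v is None for v in vals):
        missing = [g.mol_id for g in graphs if g.y_phys is None]
        raise ValueError(f"residual mode needs physics predictions; missing for {missing}")
    return np.array(vals, dtype=float)


def _model_rmse(model, graphs, y_phys, batch_size=256) -> float:
    preds = predict_corrections(model, graphs, batch_size=batch_size)
    y = np.array([g.y for g in graphs])
    resid = y - (y_phys + preds)
    return float(np.sqrt(np.mean(resid * resid)))


def predict_corrections(model, graphs: Sequence[MolecularGraph], batch_size: int = 256) -> np.ndarray:
    """Deterministic (inference-mode) member outputs for a list of graphs."""
    out = []
    for lo in range(0, len(graphs), batch_size):
        batch = GraphBatch(graphs[lo:lo + batch_size])
        out.append(model.forward(batch, training=False).data)
    return np.concatenate(out)


def train_member(
    kind: str,
    train_graphs: Sequence[MolecularGraph],
    val_graphs: Sequence[MolecularGraph],
    config: TrainConfig,
    seed: int,
    model_config=None,
    log_fn: Optional[Callable[[str], None]] = None,
):
    """Train one ensemble member; returns (model, TrainingHistory)."""
    if not train_graphs or not val_graphs:
        raise ValueError("train and validation partitions must be nonempty")
    node_dim = train_graphs[0].node_features.shape[1]
    edge_dim = train_graphs[0].edge_features.shape[1] if train_graphs[0].edge_features.size else 0
    model = init_model(kind, node_dim=node_dim, edge_dim=edge_dim, seed=seed, config=model_config)
    rng = np.random.default_rng(seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    stopper = EarlyStopper(config.patience, config.min_delta)
    history = TrainingHistory()

    y_phys_train = _phys_values(train_graphs, config.mode)
    y_phys_val = _phys_values(val_graphs, config.mode)
    y_train = np.array([g.y for g in train_graphs])
    best_state = model.state_arrays()

    n = len(train_graphs)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss, n_seen = 0.0, 0
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            batch = GraphBatch([train_graphs[i] for i in idx])
            corr = model.forward(batch, training=True, rng=rng)
            resid = Tensor.const(y_train[idx] - y_phys_train[idx]) - corr
            loss = resid.square().mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
            n_seen += len(idx)
        epoch_loss /= n_seen
        val_rmse = _model_rmse(model, val_graphs, y_phys_val)
        history.train_loss.append(epoch_loss)
        history.val_rmse.append(val_rmse)
        improved = val_rmse < stopper.best
        stop = stopper.update(epoch, val_rmse)
        if improved:
            best_state = model.state_arrays()
        msg = (f"seed={seed} epoch={epoch} train_loss={epoch_loss:.4f} "
               f"val_rmse={val_rmse:.4f} best_epoch={stopper.best_epoch}")
        (log_fn or logger.debug)(msg)
        if stop:
            history.stopped_epoch = epoch
            break
    history.best_epoch = stopper.best_epoch
    history.best_val_rmse = float(stopper.best)
    model.load_state_arrays(best_state)
    return model, history


@dataclass
class EnsembleModel:
    members: list  # list of (model, TrainingHistory)
    config: TrainConfig
    kind: str
    physics_model_name: str = ""

    @property
    def member_seeds(self) -> list:
        return [m.seed for m, _ in self.members]

    def mean_correction(self, graphs: Sequence[MolecularGraph]) -> np.ndarray:
        outputs = np.stack([predict_corrections(m, graphs) for m, _ in self.members])
        return outputs.mean(axis=0)


def train_ensemble(
    kind: str,
    train_graphs: Sequence[MolecularGraph],
    val_graphs: Sequence[MolecularGraph],
    config: TrainConfig,
    model_config=None,
    physics_model_name: str = "",
    log_fn=None,
) -> EnsembleModel:
    """Train `ensemble_size` members on identical data, seeds base_seed+i."""
    members = []
    for i in range(config.ensemble_size):
        seed = config.base_seed + i
        member = train_member(kind, train_graphs, val_graphs, config, seed,
                              model_config=model_config, log_fn=log_fn)
        members.append(member)
    return EnsembleModel(members=members, config=config, kind=kind,
                         physics_model_name=physics_model_name)


def predict(ensemble: EnsembleModel, graphs: Sequence[MolecularGraph],
            y_phys: Optional[np.ndarray] = None) -> np.ndarray:
    """Final per-molecule predictions: physics + mean correction, or the
    mean network output alone in dnn_alone mode."""
    corr = ensemble.mean_correction(graphs)
    if ensemble.config.mode == "dnn_alone":
        return corr
    if y_phys is None:
        y_phys = _phys_values(graphs, "residual")
    return np.asarray(y_phys, dtype=float) + corr


@dataclass
class EvalReport:
    rmse: float
    rmse_physics_alone: float
    relative_improvement: float
    table: list  # rows: (id, y_expt, y_phys, correction, final, error)

    def to_json(self) -> str:
        return json.dumps({
            "rmse": self.rmse,
            "rmse_physics_alone": self.rmse_physics_alone,
            "relative_improvement": self.relative_improvement,
            "relative_improvement_pct": 100.0 * self.relative_improvement,
        })

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "y_expt", "y_phys", "correction", "final", "error"])
            writer.writerows(self.table)


def rmse(errors: np.ndarray) -> float:
    errors = np.asarray(errors, dtype=float)
    return float(np.sqrt(np.mean(errors * errors)))


def evaluate(ids: Sequence[str], y_expt: np.ndarray, final: np.ndarray,
             y_phys: np.ndarray) -> EvalReport:
    y_expt = np.asarray(y_expt, dtype=float)
    final = np.asarray(final, dtype=float)
    y_phys = np.asarray(y_phys, dtype=float)
    if len(ids) == 0:
        raise ValueError("cannot evaluate an empty set")
    model_rmse = rmse(y_expt - final)
    phys_rmse = rmse(y_expt - y_phys)
    rel = (phys_rmse - model_rmse) / phys_rmse if phys_rmse > 0 else 0.0
    table = [
        (ids[i], float(y_expt[i]), float(y_phys[i]),
         float(final[i] - y_phys[i]), float(final[i]), float(final[i] - y_expt[i]))
        for i in range(len(ids))
    ]
    return EvalReport(rmse=model_rmse, rmse_physics_alone=phys_rmse,
                      relative_improvement=rel, table=table)
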