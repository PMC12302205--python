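"""The two correction-regression architectures.

* GraphConv: two graph-convolution layers (sizes 53 and 38) with
  closed-neighborhood max pooling after each, an atom-level dense layer
  (size 27, rectifier), a sum||max graph gather, and a final linear head.
  Edge features are ignored.  Dropout 0.4 after every hidden layer during
  training.

* MPNN: linear node embedding to 64, three steps of edge-conditioned
  message passing (a two-layer edge network with hidden width 128 maps
  each edge feature vector to a 64x64 mixing matrix) with a shared gated
  recurrent update, then either a Set2Set readout (6 internal steps) or a
  plain node-sum readout, followed by a two-layer head.

Both are implemented on the package's NumPy autodiff core; weights are
plain named arrays with deterministic seeded initialization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np

from ._autograd import (
    Tensor, batched_matvec, concat, gather, segment_max, segment_softmax, segment_sum,
)
from .featurization import MolecularGraph


@dataclass
class GraphConvConfig:
    conv_sizes: tuple = (53, 38)
    dense_size: int = 27
    dropout: float = 0.4

    def __post_init__(self):
        if len(self.conv_sizes) != 2:
            raise ValueError("exactly two convolution layers")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class MPNNConfig:
    node_embed: int = 64
    edge_hidden: int = 128
    mp_steps: int = 3
    readout: str = "set2set"  # set2set | sum
    set2set_steps: int = 6
    head_hidden: int = 64
    dropout: float = 0.0

    def __post_init__(self):
        if self.mp_steps < 1:
            raise ValueError("mp_steps must be >= 1")
        if self.readout not in ("set2set", "sum"):
            raise ValueError(f"unknown readout {self.readout!r}")


class GraphBatch:
    """Disjoint union of molecular graphs for vectorized forward passes."""

    def __init__(self, graphs: Sequence[MolecularGraph]):
        self.n_graphs = len(graphs)
        self.sizes = np.array([g.n_nodes for g in graphs], dtype=int)
        offsets = np.concatenate([[0], np.cumsum(self.sizes)])
        self.n_nodes = int(offsets[-1])
        self.node_features = np.concatenate([g.node_features for g in graphs])
        self.batch_ids = np.repeat(np.arange(self.n_graphs), self.sizes)
        src, dst, efeat = [], [], []
        for g, off in zip(graphs, offsets):
            de = g.directed_edges()
            if len(de):
                src.append(de[:, 0] + off)
                dst.append(de[:, 1] + off)
                if g.edge_features.size:
                    efeat.append(np.vstack([g.edge_features, g.edge_features]))
        self.src = np.concatenate(src) if src else np.zeros(0, dtype=int)
        self.dst = np.concatenate(dst) if dst else np.zeros(0, dtype=int)
        self.edge_features = np.concatenate(efeat) if efeat else np.zeros((0, 0))
        self.ids = [g.mol_id for g in graphs]
        self.y = np.array([g.y if g.y is not None else np.nan for g in graphs])


def _uniform(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


def _linear_params(rng, name, d_in, d_out, params):
    params[f"{name}.W"] = Tensor.param(_uniform(rng, d_in, (d_in, d_out)))
    params[f"{name}.b"] = Tensor.param(_uniform(rng, d_in, (d_out,)))


def _linear(params, name, x: Tensor) -> Tensor:
    return x @ params[f"{name}.W"] + params[f"{name}.b"]


def _gru_params(rng, name, d_in, d_h, params):
    for gate in ("z", "r", "n"):
        params[f"{name}.W{gate}"] = Tensor.param(_uniform(rng, d_in, (d_in, d_h)))
        params[f"{name}.U{gate}"] = Tensor.param(_uniform(rng, d_h, (d_h, d_h)))
        params[f"{name}.b{gate}"] = Tensor.param(_uniform(rng, d_h, (d_h,)))


def _gru(params, name, x: Tensor, h: Tensor) -> Tensor:
    z = (x @ params[f"{name}.Wz"] + h @ params[f"{name}.Uz"] + params[f"{name}.bz"]).sigmoid()
    r = (x @ params[f"{name}.Wr"] + h @ params[f"{name}.Ur"] + params[f"{name}.br"]).sigmoid()
    n = (x @ params[f"{name}.Wn"] + (r * (h @ params[f"{name}.Un"])) + params[f"{name}.bn"]).tanh()
    return (1.0 - z) * n + z * h


def _lstm_params(rng, name, d_in, d_h, params):
    for gate in ("i", "f", "g", "o"):
        params[f"{name}.W{gate}"] = Tensor.param(_uniform(rng, d_in, (d_in, d_h)))
        params[f"{name}.U{gate}"] = Tensor.param(_uniform(rng, d_h, (d_h, d_h)))
        params[f"{name}.b{gate}"] = Tensor.param(_uniform(rng, d_h, (d_h,)))


def _lstm(params, name, x: Tensor, h: Tensor, c: Tensor):
    i = (x @ params[f"{name}.Wi"] + h @ params[f"{name}.Ui"] + params[f"{name}.bi"]).sigmoid()
    f = (x @ params[f"{name}.Wf"] + h @ params[f"{name}.Uf"] + params[f"{name}.bf"]).sigmoid()
    g = (x @ params[f"{name}.Wg"] + h @ params[f"{name}.Ug"] + params[f"{name}.bg"]).tanh()
    o = (x @ params[f"{name}.Wo"] + h @ params[f"{name}.Uo"] + params[f"{name}.bo"]).sigmoid()
    c_new = f * c + i * g
    h_new = o * c_new.tanh()
    return h_new, c_new


def _dropout(x: Tensor, p: float, training: bool, rng: Optional[np.random.Generator]) -> Tensor:
    if not training or p <= 0.0:
        return x
    if rng is None:
        raise ValueError("training-mode dropout needs an RNG")
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor.const(mask)


class _BaseModel:
    """Weight bookkeeping shared by both architectures."""

    kind = "base"

    def __init__(self):
        self.params: dict = {}
        self.seed: int = 0
        self.config = None
        self.dims: dict = {}

    def parameters(self):
        return self.params

    def state_arrays(self) -> dict:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_arrays(self, arrays: dict) -> None:
        for k, v in arrays.items():
            self.params[k].data = np.array(v, dtype=np.float64)

    def save(self, path) -> None:
        meta = json.dumps({
            "kind": self.kind,
            "seed": self.seed,
            "config": asdict(self.config),
            "dims": self.dims,
        })
        arrays = {k.replace(".", "__"): v.data for k, v in self.params.items()}
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @staticmethod
    def load(path) -> "_BaseModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            arrays = {k.replace("__", "."): data[k] for k in data.files if k != "__meta__"}
        if meta["kind"] == "graphconv":
            model = GraphConvModel(GraphConvConfig(**{**meta["config"],
                                   "conv_sizes": tuple(meta["config"]["conv_sizes"])}),
                                   node_dim=meta["dims"]["node_dim"], seed=meta["seed"])
        elif meta["kind"] == "mpnn":
            model = MPNNModel(MPNNConfig(**meta["config"]),
                              node_dim=meta["dims"]["node_dim"],
                              edge_dim=meta["dims"]["edge_dim"], seed=meta["seed"])
        else:
            raise ValueError(f"unknown model kind {meta['kind']!r}")
        model.load_state_arrays(arrays)
        return model


class GraphConvModel(_BaseModel):
    kind = "graphconv"

    def __init__(self, config: Optional[GraphConvConfig] = None, *, node_dim: int, seed: int = 0):
        super().__init__()
        self.config = config or GraphConvConfig()
        self.seed = int(seed)
        self.dims = {"node_dim": int(node_dim)}
        rng = np.random.default_rng(self.seed)
        c1, c2 = self.config.conv_sizes
        for name, d_in, d_out in [
            ("conv1.self", node_dim, c1), ("conv1.nbr", node_dim, c1),
            ("conv2.self", c1, c2), ("conv2.nbr", c1, c2),
            ("dense", c2, self.config.dense_size),
            ("head", 2 * self.config.dense_size, 1),
        ]:
            _linear_params(rng, name, d_in, d_out, self.params)

    def _conv(self, name, h: Tensor, batch: GraphBatch) -> Tensor:
        nbr_sum = segment_sum(gather(h, batch.src), batch.dst, batch.n_nodes)
        pre = (h @ self.params[f"{name}.self.W"]
               + nbr_sum @ self.params[f"{name}.nbr.W"]
               + self.params[f"{name}.self.b"])
        return pre.relu()

    @staticmethod
    def _pool(h: Tensor, batch: GraphBatch) -> Tensor:
        """Per-node max over the closed neighborhood."""
        src = np.concatenate([batch.src, np.arange(batch.n_nodes)])
        dst = np.concatenate([batch.dst, np.arange(batch.n_nodes)])
        return segment_max(gather(h, src), dst, batch.n_nodes)

    def forward(self, batch: GraphBatch, training: bool = False,
                rng: Optional[np.random.Generator] = None) -> Tensor:
        if batch.node_features.shape[1] != self.dims["node_dim"]:
            raise ValueError(
                f"feature dimension {batch.node_features.shape[1]} does not match "
                f"model node_dim {self.dims['node_dim']}")
        p = self.config.dropout
        h = Tensor.const(batch.node_features)
        h = _dropout(self._conv("conv1", h, batch), p, training, rng)
        h = self._pool(h, batch)
        h = _dropout(self._conv("conv2", h, batch), p, training, rng)
        h = self._pool(h, batch)
        h = _dropout(_linear(self.params, "dense", h).relu(), p, training, rng)
        g = concat([segment_sum(h, batch.batch_ids, batch.n_graphs),
                    segment_max(h, batch.batch_ids, batch.n_graphs)], axis=1)
        out = _linear(self.params, "head", g)
        return out.reshape(-1)


class MPNNModel(_BaseModel):
    kind = "mpnn"

    def __init__(self, config: Optional[MPNNConfig] = None, *, node_dim: int,
                 edge_dim: int, seed: int = 0):
        super().__init__()
        self.config = config or MPNNConfig()
        self.seed = int(seed)
        self.dims = {"node_dim": int(node_dim), "edge_dim": int(edge_dim)}
        if edge_dim < 1:
            raise ValueError("MPNN requires edge features")
        cfg = self.config
        d = cfg.node_embed
        rng = np.random.default_rng(self.seed)
        _linear_params(rng, "embed", node_dim, d, self.params)
        _linear_params(rng, "edge1", edge_dim, cfg.edge_hidden, self.params)
        _linear_params(rng, "edge2", cfg.edge_hidden, d * d, self.params)
        _gru_params(rng, "gru", d, d, self.params)
        if cfg.readout == "set2set":
            _lstm_params(rng, "s2s", 2 * d, d, self.params)
            head_in = 2 * d
        else:
            head_in = d
        _linear_params(rng, "head1", head_in, cfg.head_hidden, self.params)
        _linear_params(rng, "head2", cfg.head_hidden, 1, self.params)

    def _set2set(self, h: Tensor, batch: GraphBatch) -> Tensor:
        d = self.config.node_embed
        B = batch.n_graphs
        qstar = Tensor.const(np.zeros((B, 2 * d)))
        hh = Tensor.const(np.zeros((B, d)))
        cc = Tensor.const(np.zeros((B, d)))
        for _ in range(self.config.set2set_steps):
            hh, cc = _lstm(self.params, "s2s", qstar, hh, cc)
            scores = (h * gather(hh, batch.batch_ids)).sum(axis=1)
            attn = segment_softmax(scores, batch.batch_ids, B)
            weighted = h * attn.reshape(-1, 1)
            readout = segment_sum(weighted, batch.batch_ids, B)
            qstar = concat([hh, readout], axis=1)
        return qstar

    def forward(self, batch: GraphBatch, training: bool = False,
                rng: Optional[np.random.Generator] = None) -> Tensor:
        if np.any(batch.sizes < 2):
            bad = [batch.ids[i] for i in np.where(batch.sizes < 2)[0]]
            raise ValueError(f"MPNN cannot handle single-node graphs: {bad}")
        if batch.node_features.shape[1] != self.dims["node_dim"]:
            raise ValueError("node feature dimension mismatch")
        if batch.edge_features.shape[1] != self.dims["edge_dim"]:
            raise ValueError("edge feature dimension mismatch")
        cfg = self.config
        d = cfg.node_embed
        h = _linear(self.params, "embed", Tensor.const(batch.node_features))

        # categorical edge features repeat heavily; computing one mixing
        # matrix per distinct edge vector avoids materializing (E, d, d)
        unique_rows, inverse = np.unique(batch.edge_features, axis=0, return_inverse=True)
        grouped = len(unique_rows) <= 32 and len(batch.src) > 0
        if grouped:
            e = Tensor.const(unique_rows)
            groups = [(np.flatnonzero(inverse == t)) for t in range(len(unique_rows))]
        else:
            e = Tensor.const(batch.edge_features)
        mix = _linear(self.params, "edge2", _linear(self.params, "edge1", e).relu())
        for _ in range(cfg.mp_steps):
            if grouped:
                agg = None
                for t, idx in enumerate(groups):
                    A_t = gather(mix, [t]).reshape(d, d)
                    msg_t = gather(h, batch.src[idx]) @ A_t
                    part = segment_sum(msg_t, batch.dst[idx], batch.n_nodes)
                    agg = part if agg is None else agg + part
            elif len(batch.src) == 0:
                agg = Tensor.const(np.zeros((batch.n_nodes, d)))
            else:
                msg = batched_matvec(mix.reshape(-1, d, d), gather(h, batch.src))
                agg = segment_sum(msg, batch.dst, batch.n_nodes)
            agg = agg.relu()
            agg = _dropout(agg, cfg.dropout, training, rng)
            h = _gru(self.params, "gru", agg, h)
        if cfg.readout == "set2set":
            g = self._set2set(h, batch)
        else:
            g = segment_sum(h, batch.batch_ids, batch.n_graphs)
        out = _linear(self.params, "head2", _linear(self.params, "head1", g).relu())
        return out.reshape(-1)


def init_model(kind: str, node_dim: int, edge_dim: int = 0, seed: int = 0,
               config=None):
    """Factory: deterministic weights for the named architecture and seed."""
    if kind == "graphconv":
        return GraphConvModel(config, node_dim=node_dim, seed=seed)
    if kind == "mpnn":
        return MPNNModel(config, node_dim=node_dim, edge_dim=edge_dim, seed=seed)
    raise ValueError(f"unknown model kind {kind!r}")
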