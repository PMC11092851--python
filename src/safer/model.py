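"""Sub-hypergraph attention network with an FNN synergy head.

Each hypergraph (gene-set and drug) gets its own attention encoder.  An
encoder holds a learned per-node embedding table; hyperedge embeddings
start as the mean of their incident nodes.  Message passing alternates
for k layers:

* hyperedge update — softmax over the nodes of each edge of the scores
  ``c . tanh(W [h_node ; h_edge])`` followed by a ReLU-weighted sum;
* node update — the same scores renormalized across the edges containing
  each node, again ReLU-aggregated.

A subject (one drug-drug-cell-dose sample) selects the sub-hypergraph of
nodes where its dose-injected feature row F is nonzero; subgraph
attention scores node i as ``F_ji * (b . hV_i)`` and the subject
embedding is the ReLU of the attention-weighted node sum.  Cell and
drug-pair subject embeddings are concatenated with one-hot covariates
and passed through batch-norm and a two-layer ELU feed-forward head
(hidden width 200, dropout 0.2 after the subgraph layer and 0.3 in the
head) to a single synergy logit, trained with sigmoid binary
cross-entropy under Adam and a cosine learning-rate schedule.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .autodiff import Adam, Tensor, bce_with_logits, cosine_lr, masked_softmax
from .features import IncidenceHypergraph

__all__ = [
    "ModelConfig",
    "AttentionParams",
    "attention_state",
    "attention_scores",
    "hyperedge_attention",
    "node_attention",
    "layer_forward",
    "subgraph_embed",
    "HypergraphEncoder",
    "SynergySubjectBatch",
    "SynergyModel",
    "TrainHistory",
    "train",
]


@dataclass
class ModelConfig:
    """Hyperparameters; hidden width and dropout follow the tuned defaults."""

    embed_dim: int = 32  # node embedding / subject embedding width d
    hidden_dim: int = 200  # FNN hidden width
    n_layers: int = 2  # message-passing depth k
    dropout_subgraph: float = 0.2
    dropout_fnn: float = 0.3
    lr: float = 5e-3
    weight_decay: float = 1e-5
    epochs: int = 30
    batch_size: int = 256
    seed: int = 0


# ---------------------------------------------------------------------------
# Functional attention primitives (shared by the encoder and the oracle tests)


@dataclass
class AttentionParams:
    """One hypergraph's attention parameters: W = [W1 | W2], context c."""

    w_node: Tensor  # d x d, applied to the node embedding half
    w_edge: Tensor  # d x d, applied to the edge embedding half
    context: Tensor  # d x 1

    @classmethod
    def init(cls, dim: int, rng: np.random.Generator, scale: float | None = None) -> "AttentionParams":
        scale = scale if scale is not None else 1.0 / np.sqrt(dim)
        return cls(
            w_node=Tensor(rng.normal(0, scale, (dim, dim)), requires_grad=True),
            w_edge=Tensor(rng.normal(0, scale, (dim, dim)), requires_grad=True),
            context=Tensor(rng.normal(0, scale, (dim, 1)), requires_grad=True),
        )

    @property
    def tensors(self) -> list[Tensor]:
        return [self.w_node, self.w_edge, self.context]


def attention_state(node_emb: Tensor, edge_emb: Tensor, params: AttentionParams) -> Tensor:
    """Attention-ready state s = tanh(W . concat(node, edge)) for one pair."""
    return (node_emb @ params.w_node.T + edge_emb @ params.w_edge.T).tanh()


def attention_scores(hv: Tensor, he: Tensor, params: AttentionParams) -> Tensor:
    """Score matrix c . s(p, g) for every (node, edge) pair, |V| x |E|."""
    n_v, dim = hv.shape
    n_e = he.shape[0]
    u = hv @ params.w_node.T  # |V| x d
    q = he @ params.w_edge.T  # |E| x d
    s = (u.reshape(n_v, 1, dim) + q.reshape(1, n_e, dim)).tanh()
    return (s.reshape(n_v * n_e, dim) @ params.context).reshape(n_v, n_e)


def hyperedge_attention(scores: Tensor, incidence: np.ndarray) -> Tensor:
    """Per-edge softmax over incident nodes; columns sum to one."""
    if (np.asarray(incidence).sum(axis=0) == 0).any():
        raise ValueError("empty hyperedge")
    return masked_softmax(scores, np.asarray(incidence) > 0, axis=0)


def node_attention(scores: Tensor, incidence: np.ndarray) -> Tensor:
    """Per-node softmax over containing edges; rows sum to one."""
    if (np.asarray(incidence).sum(axis=1) == 0).any():
        raise ValueError("isolated node")
    return masked_softmax(scores, np.asarray(incidence) > 0, axis=1)


def layer_forward(
    hv: Tensor, he: Tensor, hg: IncidenceHypergraph, params: AttentionParams
) -> tuple[Tensor, Tensor]:
    """One dual-attention message-passing layer.

    New edge embeddings aggregate the previous nodes, new node embeddings
    aggregate the previous edges; both use the same pair scores, softmaxed
    along the appropriate axis, then ReLU.
    """
    scores = attention_scores(hv, he, params)
    a_edge = hyperedge_attention(scores, hg.incidence)  # |V| x |E|
    a_node = node_attention(scores, hg.incidence)
    he_new = (a_edge.T @ hv).relu()
    hv_new = (a_node @ he).relu()
    return hv_new, he_new


def subgraph_embed(
    f_rows: np.ndarray, hv: Tensor, bias: Tensor
) -> tuple[Tensor, Tensor]:
    """Subject embeddings from dose-injected features, with their attention.

    A subject's sub-hypergraph is the set of nodes where its feature row
    is nonzero; the attention score of node i is ``F_ji * (b . hV_i)``.
    Returns (embeddings n x d, attention weights n x |V|).
    """
    f_rows = np.atleast_2d(np.asarray(f_rows, dtype=float))
    support = f_rows != 0
    if (~support.any(axis=1)).any():
        raise ValueError("empty subgraph: a subject has an all-zero feature row")
    node_proj = (hv @ bias).reshape(1, -1)  # 1 x |V|
    scores = Tensor(f_rows) * node_proj
    attn = masked_softmax(scores, support, axis=1)
    emb = (attn @ hv).relu()
    return emb, attn


# ---------------------------------------------------------------------------
# Encoder and full model


class HypergraphEncoder:
    """Attention encoder for one hypergraph: embeddings + subgraph attention."""

    def __init__(self, hg: IncidenceHypergraph, dim: int, n_layers: int, rng: np.random.Generator):
        self.hg = hg
        self.n_layers = n_layers
        scale = 1.0 / np.sqrt(dim)
        self.node_table = Tensor(rng.normal(0, scale, (hg.n_nodes, dim)), requires_grad=True)
        self.attn = AttentionParams.init(dim, rng)
        self.bias = Tensor(rng.normal(0, scale, (dim, 1)), requires_grad=True)
        edge_sizes = hg.incidence.sum(axis=0)
        self._edge_mean = hg.incidence.T / edge_sizes[:, None]  # |E| x |V|

    @property
    def params(self) -> list[Tensor]:
        return [self.node_table, self.bias, *self.attn.tensors]

    def node_embeddings(self) -> Tensor:
        """Run k message-passing layers; returns final node embeddings hV^k."""
        hv = self.node_table
        he = Tensor(self._edge_mean) @ self.node_table  # hE^0: mean of incident nodes
        for _ in range(self.n_layers):
            hv, he = layer_forward(hv, he, self.hg, self.attn)
        return hv

    def subjects(self, f_rows: np.ndarray) -> tuple[Tensor, Tensor]:
        return subgraph_embed(f_rows, self.node_embeddings(), self.bias)


class _BatchNorm:
    """1-D batch normalization with running statistics for eval mode."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    @property
    def params(self) -> list[Tensor]:
        return [self.gamma, self.beta]

    def __call__(self, x: Tensor, train_mode: bool) -> Tensor:
        if train_mode:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=0, keepdims=True)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu.data.ravel()
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var.data.ravel()
        else:
            mu = Tensor(self.running_mean.reshape(1, -1))
            var = Tensor(self.running_var.reshape(1, -1))
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta


def _linear_init(rng: np.random.Generator, n_in: int, n_out: int) -> tuple[Tensor, Tensor]:
    w = Tensor(rng.normal(0, np.sqrt(2.0 / n_in), (n_in, n_out)), requires_grad=True)
    b = Tensor(np.zeros(n_out), requires_grad=True)
    return w, b


@dataclass
class SynergySubjectBatch:
    """Aligned model inputs for a set of subjects."""

    f_cell: np.ndarray  # n x |V_cell|
    f_drug: np.ndarray  # n x |V_drug|
    covariates: np.ndarray  # n x n_cov
    labels: np.ndarray  # n, in {0, 1}

    def __post_init__(self) -> None:
        n = len(self.labels)
        if not (len(self.f_cell) == len(self.f_drug) == len(self.covariates) == n):
            raise ValueError("batch arrays are not aligned")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx: np.ndarray) -> "SynergySubjectBatch":
        return SynergySubjectBatch(
            self.f_cell[idx], self.f_drug[idx], self.covariates[idx], self.labels[idx]
        )


class SynergyModel:
    """Two hypergraph encoders plus the batch-normalized ELU head."""

    def __init__(
        self,
        cell_hg: IncidenceHypergraph,
        drug_hg: IncidenceHypergraph,
        n_covariates: int,
        config: ModelConfig | None = None,
    ):
        self.config = config or ModelConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self.cell_encoder = HypergraphEncoder(cell_hg, cfg.embed_dim, cfg.n_layers, rng)
        self.drug_encoder = HypergraphEncoder(drug_hg, cfg.embed_dim, cfg.n_layers, rng)
        n_in = 2 * cfg.embed_dim + n_covariates
        self.bn = _BatchNorm(n_in)
        self.w1, self.b1 = _linear_init(rng, n_in, cfg.hidden_dim)
        self.w2, self.b2 = _linear_init(rng, cfg.hidden_dim, cfg.hidden_dim)
        self.w_out, self.b_out = _linear_init(rng, cfg.hidden_dim, 1)
        self._dropout_rng = np.random.default_rng(cfg.seed + 1)

    @property
    def params(self) -> list[Tensor]:
        return [
            *self.cell_encoder.params,
            *self.drug_encoder.params,
            *self.bn.params,
            self.w1,
            self.b1,
            self.w2,
            self.b2,
            self.w_out,
            self.b_out,
        ]

    def _dropout(self, x: Tensor, rate: float, train_mode: bool) -> Tensor:
        if not train_mode or rate <= 0:
            return x
        keep = self._dropout_rng.random(x.shape) >= rate
        return x * (keep.astype(float) / (1.0 - rate))

    def forward(self, batch: SynergySubjectBatch, train_mode: bool = False) -> Tensor:
        """Compute synergy logits for a batch; dropout only in train mode."""
        cfg = self.config
        cell_emb, _ = self.cell_encoder.subjects(batch.f_cell)
        drug_emb, _ = self.drug_encoder.subjects(batch.f_drug)
        cell_emb = self._dropout(cell_emb, cfg.dropout_subgraph, train_mode)
        drug_emb = self._dropout(drug_emb, cfg.dropout_subgraph, train_mode)
        x = Tensor.concat([cell_emb, drug_emb, Tensor(batch.covariates)], axis=1)
        x = self.bn(x, train_mode)
        x = (x @ self.w1 + self.b1).elu()
        x = self._dropout(x, cfg.dropout_fnn, train_mode)
        x = (x @ self.w2 + self.b2).elu()
        x = self._dropout(x, cfg.dropout_fnn, train_mode)
        return (x @ self.w_out + self.b_out).reshape(len(batch))

    def predict_scores(self, batch: SynergySubjectBatch) -> np.ndarray:
        """Predicted synergy probabilities (eval mode)."""
        logits = self.forward(batch, train_mode=False).data
        return 1.0 / (1.0 + np.exp(-logits))

    def subject_attention(self, batch: SynergySubjectBatch) -> tuple[np.ndarray, np.ndarray]:
        """Per-subject attention weights over cell and drug nodes (eval mode)."""
        _, cell_attn = self.cell_encoder.subjects(batch.f_cell)
        _, drug_attn = self.drug_encoder.subjects(batch.f_drug)
        return cell_attn.data, drug_attn.data

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params]

    def load_state_dict(self, state: Sequence[np.ndarray]) -> None:
        for p, arr in zip(self.params, state, strict=True):
            p.data = arr.copy()


@dataclass
class TrainHistory:
    """Per-epoch training loss and validation AUPRC."""

    train_loss: list[float] = field(default_factory=list)
    val_auprc: list[float] = field(default_factory=list)
    best_epoch: int = -1


def train(
    model: SynergyModel,
    train_batch: SynergySubjectBatch,
    val_batch: SynergySubjectBatch | None = None,
    config: ModelConfig | None = None,
) -> TrainHistory:
    """Minimize BCE-with-logits; returns history, best-validation weights kept.

    All randomness (shuffling, dropout) derives from ``config.seed``; the
    same seed reproduces the history bitwise.  A single-class training
    set cannot be fit with this loss and raises.
    """
    from .evaluation import auprc  # local import: evaluation also imports nothing from here

    cfg = config or model.config
    if len(np.unique(train_batch.labels)) < 2:
        raise ValueError("training fold contains a single class")
    rng = np.random.default_rng(cfg.seed + 2)
    model._dropout_rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model.params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    history = TrainHistory()
    best_state: list[np.ndarray] | None = None
    best_val = -np.inf
    n = len(train_batch)
    for epoch in range(cfg.epochs):
        lr = cosine_lr(cfg.lr, epoch, cfg.epochs)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            sub = train_batch.subset(idx)
            logits = model.forward(sub, train_mode=True)
            loss = bce_with_logits(logits, sub.labels)
            opt.zero_grad()
            loss.backward()
            opt.step(lr=lr)
            losses.append(float(loss.data))
        history.train_loss.append(float(np.mean(losses)))
        if val_batch is not None:
            scores = model.predict_scores(val_batch)
            val = auprc(scores, val_batch.labels)
            history.val_auprc.append(val)
            if val > best_val:
                best_val = val
                best_state = model.state_dict()
                history.best_epoch = epoch
    if best_state is not None:
        model.load_state_dict(best_state)
    return history
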