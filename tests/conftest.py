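"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately written with explicit Python loops and
no shared code with the package, so that agreement between the two
routes is evidence of correctness rather than tautology.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from safer.features import IncidenceHypergraph


# ---------------------------------------------------------------------------
# Brute-force oracles


def brute_average_precision(scores, labels) -> float:
    """Step-wise AP: sweep distinct thresholds descending, sum P * dR."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = labels.sum()
    ap = 0.0
    prev_recall = 0.0
    for t in sorted(set(scores), reverse=True):
        picked = scores >= t
        tp = int(labels[picked].sum())
        precision = tp / picked.sum()
        recall = tp / n_pos
        ap += precision * (recall - prev_recall)
        prev_recall = recall
    return ap


def brute_auroc(scores, labels) -> float:
    """Mann-Whitney AUROC by enumerating all positive/negative pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def brute_mannwhitney(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by enumerating all group assignments."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n = len(x)

    def u_stat(xs, ys):
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

    u_obs = u_stat(x, y)
    idxs = range(len(pooled))
    us = []
    for comb in itertools.combinations(idxs, n):
        rest = [i for i in idxs if i not in comb]
        us.append(u_stat(pooled[list(comb)], pooled[rest]))
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return float(u_obs), float(min(1.0, p))


def brute_bh(pvalues) -> np.ndarray:
    """BH step-up computed literally from the definition."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adjusted[i] = running_min
    return adjusted


def brute_layer_forward(hv, he, incidence, w_node, w_edge, c):
    """One message-passing layer with explicit loops over incident pairs."""
    n_v, d = hv.shape
    n_e = he.shape[0]
    scores = np.zeros((n_v, n_e))
    for i in range(n_v):
        for p in range(n_e):
            s = np.tanh(w_node @ hv[i] + w_edge @ he[p])
            scores[i, p] = float(c @ s)
    he_new = np.zeros_like(he)
    for p in range(n_e):
        members = [i for i in range(n_v) if incidence[i, p]]
        exps = np.array([np.exp(scores[i, p]) for i in members])
        weights = exps / exps.sum()
        agg = sum(w * hv[i] for w, i in zip(weights, members))
        he_new[p] = np.maximum(agg, 0.0)
    hv_new = np.zeros_like(hv)
    for i in range(n_v):
        edges = [p for p in range(n_e) if incidence[i, p]]
        exps = np.array([np.exp(scores[i, p]) for p in edges])
        weights = exps / exps.sum()
        agg = sum(w * he[p] for w, p in zip(weights, edges))
        hv_new[i] = np.maximum(agg, 0.0)
    return hv_new, he_new


def brute_subgraph_embed(f_row, hv, b):
    """Subject embedding by explicit softmax over the support."""
    support = [i for i in range(len(f_row)) if f_row[i] != 0]
    scores = np.array([f_row[i] * float(b @ hv[i]) for i in support])
    exps = np.exp(scores - scores.max())
    weights = exps / exps.sum()
    emb = sum(w * hv[i] for w, i in zip(weights, support))
    return np.maximum(emb, 0.0)


# ---------------------------------------------------------------------------
# Fixtures


def random_hypergraph(rng: np.random.Generator, n_nodes: int, n_edges: int) -> IncidenceHypergraph:
    """Random binary incidence with no empty edge and no isolated node."""
    while True:
        inc = (rng.random((n_nodes, n_edges)) < 0.5).astype(float)
        if inc.sum(axis=0).min() > 0 and inc.sum(axis=1).min() > 0:
            return IncidenceHypergraph(
                [f"n{i}" for i in range(n_nodes)],
                [f"e{j}" for j in range(n_edges)],
                inc,
            )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def toy_hypergraph() -> IncidenceHypergraph:
    return IncidenceHypergraph(
        node_names=["n0", "n1", "n2"],
        edge_names=["e0", "e1"],
        incidence=np.array([[1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]),
    )
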