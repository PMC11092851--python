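"""Differential attention-weight analysis between synergy and antagonism.

The model's per-subject subgraph attention, multiplied elementwise by
the dose-injected feature values, gives a weighted subgraph per sample.
For a pool of samples (the dose combinations of one triplet, or one drug
pair across cell lines) each gene-set node's weights are compared
between synergistic and antagonistic samples with a two-sided
Mann-Whitney U test; p-values are Benjamini-Hochberg adjusted and nodes
significant at FDR 0.05 are reported with their direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

__all__ = [
    "weighted_subgraph",
    "mannwhitney_test",
    "bh_adjust",
    "NodeResult",
    "DifferentialWeightReport",
    "pooled_analysis",
    "rank_triplets",
    "EXACT_TEST_MAX_N",
]

#: combined sample size at or below which the exact U distribution is used
EXACT_TEST_MAX_N = 20


def weighted_subgraph(attention: np.ndarray, features: np.ndarray) -> np.ndarray:
    """Elementwise product of attention weights and subject feature values.

    Zero features stay zero: the weighted subgraph lives on the subject's
    support only.
    """
    attention = np.asarray(attention, dtype=float)
    features = np.asarray(features, dtype=float)
    if attention.shape != features.shape:
        raise ValueError(f"shape mismatch: {attention.shape} vs {features.shape}")
    return attention * features


def mannwhitney_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U of x against y.

    U counts pairs with x > y (ties half).  The exact null distribution
    is used for combined samples of at most 20 without ties; otherwise
    the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty group in Mann-Whitney test")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if len(x) + len(y) <= EXACT_TEST_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    pvalues = np.asarray(pvalues, dtype=float)
    if len(pvalues) == 0:
        return pvalues
    if (pvalues < 0).any() or (pvalues > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvalues, method="fdr_bh")[1]


@dataclass(frozen=True)
class NodeResult:
    """Test result for one gene-set node within a pool."""

    node: str
    u_statistic: float
    p_value: float
    p_adjusted: float
    direction: str  # "higher_in_synergy" or "higher_in_antagonism"
    n_synergistic: int
    n_antagonistic: int


@dataclass
class DifferentialWeightReport:
    """All tested nodes of one pool, plus the significant subset."""

    pool: str
    results: list[NodeResult]
    alpha: float = 0.05

    @property
    def significant(self) -> list[NodeResult]:
        return [r for r in self.results if r.p_adjusted < self.alpha]

    def to_rows(self) -> list[dict]:
        return [
            {
                "node": r.node,
                "U": r.u_statistic,
                "p": r.p_value,
                "p_adj": r.p_adjusted,
                "direction": r.direction,
                "n_syn": r.n_synergistic,
                "n_ant": r.n_antagonistic,
            }
            for r in self.results
        ]


def pooled_analysis(
    weighted: np.ndarray,
    labels: np.ndarray,
    node_names: Sequence[str],
    pool: str = "by_dose",
    alpha: float = 0.05,
) -> DifferentialWeightReport:
    """Test every supported node's weights between the two label groups.

    ``weighted`` is the subjects x nodes weighted-subgraph matrix of the
    pool; only nodes with a nonzero weight in at least one pooled sample
    are tested.  Both labels must be present in the pool.
    """
    weighted = np.asarray(weighted, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if weighted.shape[0] != len(labels):
        raise ValueError("weighted matrix and labels are not aligned")
    syn = labels == 1
    ant = labels == 0
    if not syn.any() or not ant.any():
        raise ValueError(f"pool {pool!r} does not contain both labels")
    tested: list[tuple[str, float, float, str, int, int]] = []
    for j, name in enumerate(node_names):
        col = weighted[:, j]
        if not np.any(col != 0):
            continue
        x, y = col[syn], col[ant]
        u, p = mannwhitney_test(x, y)
        direction = "higher_in_synergy" if np.median(x) >= np.median(y) else "higher_in_antagonism"
        tested.append((name, u, p, direction, int(syn.sum()), int(ant.sum())))
    if not tested:
        return DifferentialWeightReport(pool=pool, results=[], alpha=alpha)
    adj = bh_adjust([t[2] for t in tested])
    results = [
        NodeResult(
            node=name,
            u_statistic=u,
            p_value=p,
            p_adjusted=float(q),
            direction=direction,
            n_synergistic=ns,
            n_antagonistic=na,
        )
        for (name, u, p, direction, ns, na), q in zip(tested, adj)
    ]
    results.sort(key=lambda r: (r.p_adjusted, r.p_value, r.node))
    return DifferentialWeightReport(pool=pool, results=results, alpha=alpha)


def rank_triplets(preds, top: int = 20) -> list[tuple[str, str, str]]:
    """Triplets ranked by per-triplet AUPRC (ties broken by sample count).

    Used to pick the triplets whose pools are worth interpreting: the
    analysis is most meaningful where the model actually separates the
    classes.
    """
    from .evaluation import UndefinedMetricError, auprc

    groups: dict[tuple[str, str, str], list[int]] = {}
    for i, t in enumerate(preds.triplets):
        groups.setdefault(t, []).append(i)
    ranked = []
    for triplet, idx in groups.items():
        idx = np.asarray(idx)
        try:
            score = auprc(preds.scores[idx], preds.labels[idx])
        except UndefinedMetricError:
            continue
        ranked.append((score, len(idx), triplet))
    ranked.sort(key=lambda t: (-t[0], -t[1], t[2]))
    return [t for _, _, t in ranked[:top]]
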