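"""Hypergraph construction and subject featurization.

Three representations feed the model:

* a gene-set hypergraph in which the retained gene sets (TFs or pathways)
  are nodes and individual genes are hyperedges tying together every set
  that contains them;
* a heterogeneous drug hypergraph in which drugs are hyperedges over two
  node types — k-mer SMILES substrings (chemical sub-structure) and the
  gene sets overlapping a drug's associated genes;
* dose-injected subject feature matrices F (subjects x nodes) that drive
  the per-subject subgraph attention: cell-line rows are ssGSEA
  normalized enrichment scores scaled by the summed dose, drug-pair rows
  are dose-scaled hyperedge memberships.

Raw concentrations are mapped to log10(dose + 1) before injection and
one-hot vocabulary construction, because screens span several orders of
magnitude and an untransformed sum would be dominated by the top dose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .curation import LabelledSample
from .io_formats import DrugRecord, ExpressionMatrix, GeneSetCollection

__all__ = [
    "IncidenceHypergraph",
    "SubjectFeatureMatrix",
    "NESMatrix",
    "CellAnnotation",
    "CovariateVocab",
    "transform_dose",
    "ssgsea",
    "build_geneset_hypergraph",
    "build_drug_hypergraph",
    "dose_inject_cell",
    "dose_inject_drugpair",
    "kmer_tokenize",
    "build_subject_features",
]


@dataclass(frozen=True)
class IncidenceHypergraph:
    """Named nodes and hyperedges with a binary |V| x |E| incidence matrix."""

    node_names: list[str]
    edge_names: list[str]
    incidence: np.ndarray

    def __post_init__(self) -> None:
        inc = np.asarray(self.incidence, dtype=float)
        object.__setattr__(self, "incidence", inc)
        if inc.shape != (len(self.node_names), len(self.edge_names)):
            raise ValueError("incidence shape does not match node/edge axes")
        if len(set(self.node_names)) != len(self.node_names):
            raise ValueError("duplicate node names")
        if len(set(self.edge_names)) != len(self.edge_names):
            raise ValueError("duplicate edge names")
        if not np.isin(inc, (0.0, 1.0)).all():
            raise ValueError("incidence must be binary")
        if inc.shape[1] and (inc.sum(axis=0) == 0).any():
            empty = [self.edge_names[j] for j in np.flatnonzero(inc.sum(axis=0) == 0)]
            raise ValueError(f"empty hyperedges: {empty}")
        if inc.shape[0] and (inc.sum(axis=1) == 0).any():
            isolated = [self.node_names[i] for i in np.flatnonzero(inc.sum(axis=1) == 0)]
            raise ValueError(f"isolated nodes: {isolated}")

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    @property
    def n_edges(self) -> int:
        return len(self.edge_names)

    def edge_column(self, edge: str) -> np.ndarray:
        return self.incidence[:, self.edge_names.index(edge)]


@dataclass(frozen=True)
class SubjectFeatureMatrix:
    """Subjects x nodes feature matrix F, aligned to a hypergraph's nodes."""

    subject_ids: list
    node_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != (len(self.subject_ids), len(self.node_names)):
            raise ValueError("feature matrix shape does not match axes")
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite subject features")


@dataclass(frozen=True)
class NESMatrix:
    """Cell-lines x gene-sets normalized enrichment scores."""

    cells: list[str]
    set_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != (len(self.cells), len(self.set_names)):
            raise ValueError("NES matrix shape does not match axes")
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite NES values")

    def row(self, cell: str) -> np.ndarray:
        return self.values[self.cells.index(cell)]


def transform_dose(dose: float | np.ndarray) -> float | np.ndarray:
    """Map a raw concentration to the log10(dose + 1) injection scale."""
    return np.log10(np.asarray(dose, dtype=float) + 1.0)


# ---------------------------------------------------------------------------
# ssGSEA


def ssgsea(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    weight: float = 0.25,
    sample_norm: str = "rank",
) -> NESMatrix:
    """Single-sample gene-set enrichment with min-max normalized scores.

    Per sample the genes are rank-normalized (average ranks, scaled to
    ``10000 * rank / n_genes``) and ordered by decreasing value; the
    enrichment score of a set is the summed difference between the
    weighted in-set running CDF (step ``|v|^weight``, normalized over the
    set) and the uniform out-of-set running CDF.  The NES divides every
    ES by the range (max - min) of the whole ES matrix, matching the
    conventional single-sample GSEA implementation.

    Sets with no gene present in ``expr`` are dropped with a warning.

    Parameters
    ----------
    weight:
        Rank-weighting exponent; 0.25 is the conventional default.
    sample_norm:
        ``"rank"`` (default) or ``"none"`` to use the raw values as the
        ranking metric.
    """
    if sample_norm == "rank":
        # average ranks, ascending, so the highest expression gets rank n
        order = expr.values.argsort(axis=0, kind="stable")
        from scipy.stats import rankdata

        ranks = rankdata(expr.values, method="average", axis=0)
        norm = 10000.0 * ranks / expr.values.shape[0]
    elif sample_norm == "none":
        norm = expr.values.astype(float)
    else:
        raise ValueError(f"unknown sample_norm {sample_norm!r}")

    gene_index = {g: i for i, g in enumerate(expr.genes)}
    kept_names: list[str] = []
    memberships: list[np.ndarray] = []
    for name, genes in sets.sets.items():
        mask = np.zeros(len(expr.genes), dtype=bool)
        hit = [gene_index[g] for g in genes if g in gene_index]
        if not hit:
            warnings.warn(f"gene set {name!r} has no gene in the expression matrix; dropped")
            continue
        mask[hit] = True
        kept_names.append(name)
        memberships.append(mask)
    if not kept_names:
        raise ValueError("no gene set overlaps the expression matrix")

    n_genes, n_samples = norm.shape
    es = np.empty((n_samples, len(kept_names)))
    for j in range(n_samples):
        vals = norm[:, j]
        order = np.argsort(-vals, kind="stable")
        sorted_vals = vals[order]
        for k, mask in enumerate(memberships):
            hit = mask[order]
            wv = np.abs(sorted_vals) ** weight * hit
            n_out = n_genes - hit.sum()
            cdf_in = np.cumsum(wv) / wv.sum()
            cdf_out = np.cumsum(~hit) / n_out if n_out else np.zeros(n_genes)
            es[j, k] = float((cdf_in - cdf_out).sum())

    spread = es.max() - es.min()
    nes = es / spread if spread > 0 else np.zeros_like(es)
    return NESMatrix(cells=list(expr.samples), set_names=kept_names, values=nes)


# ---------------------------------------------------------------------------
# Hypergraph builders


def build_geneset_hypergraph(
    sets: GeneSetCollection, sets_as_nodes: bool = True
) -> IncidenceHypergraph:
    """Build the gene-set hypergraph: sets are nodes, genes are hyperedges.

    A gene's hyperedge connects every set containing it; genes unique to
    one set form singleton hyperedges.  ``sets_as_nodes=False`` transposes
    the construction (genes as nodes, sets as hyperedges).
    """
    set_names = sorted(sets.sets)
    genes = sorted({g for gs in sets.sets.values() for g in gs})
    inc = np.zeros((len(set_names), len(genes)))
    gene_index = {g: j for j, g in enumerate(genes)}
    for i, name in enumerate(set_names):
        for g in sets.sets[name]:
            inc[i, gene_index[g]] = 1.0
    if sets_as_nodes:
        return IncidenceHypergraph(node_names=set_names, edge_names=genes, incidence=inc)
    return IncidenceHypergraph(node_names=genes, edge_names=set_names, incidence=inc.T)


def kmer_tokenize(smiles: str, k: int) -> set[str]:
    """Unique length-k sliding-window substrings of a SMILES string.

    A string shorter than k yields itself as the single token.
    """
    if not smiles:
        raise ValueError("empty SMILES string")
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(smiles) < k:
        return {smiles}
    return {smiles[i : i + k] for i in range(len(smiles) - k + 1)}


def build_drug_hypergraph(
    drugs: Sequence[DrugRecord], sets: GeneSetCollection, k: int = 9
) -> IncidenceHypergraph:
    """Heterogeneous drug hypergraph: drugs are hyperedges over two node types.

    Nodes are (a) every k-mer token of any drug's SMILES and (b) every
    gene-set whose members overlap at least one drug's associated genes.
    A drug is incident to its own tokens and to the sets its genes touch.
    """
    token_sets = {d.name: kmer_tokenize(d.smiles, k) for d in drugs}
    tokens = sorted(set().union(*token_sets.values())) if drugs else []
    overlapping = sorted(
        name
        for name, genes in sets.sets.items()
        if any(set(genes) & d.associated_genes for d in drugs)
    )
    collision = set(tokens) & set(overlapping)
    if collision:
        raise ValueError(f"gene-set names collide with k-mer tokens: {sorted(collision)}")
    node_names = tokens + overlapping
    node_index = {n: i for i, n in enumerate(node_names)}
    edge_names = [d.name for d in drugs]
    inc = np.zeros((len(node_names), len(edge_names)))
    for j, d in enumerate(drugs):
        for t in token_sets[d.name]:
            inc[node_index[t], j] = 1.0
        for name in overlapping:
            if set(sets.sets[name]) & d.associated_genes:
                inc[node_index[name], j] = 1.0
    return IncidenceHypergraph(node_names=node_names, edge_names=edge_names, incidence=inc)


# ---------------------------------------------------------------------------
# Dose injection


def dose_inject_cell(nes_row: np.ndarray, dose_a: float, dose_b: float) -> np.ndarray:
    """Cell-line subject features: (dose_a + dose_b) x NES, elementwise."""
    nes_row = np.asarray(nes_row, dtype=float)
    if dose_a == 0 and dose_b == 0:
        warnings.warn("both doses zero: subject row is all-zero")
    return (dose_a + dose_b) * nes_row


def dose_inject_drugpair(
    hg: IncidenceHypergraph, drug_a: str, drug_b: str, dose_a: float, dose_b: float
) -> np.ndarray:
    """Drug-pair subject features: each drug's dose on its own nodes.

    A node shared by both drugs receives the sum of the two doses.
    """
    for d in (drug_a, drug_b):
        if d not in hg.edge_names:
            raise KeyError(f"drug {d!r} is not a hyperedge of the drug hypergraph")
    return dose_a * hg.edge_column(drug_a) + dose_b * hg.edge_column(drug_b)


# ---------------------------------------------------------------------------
# One-hot covariates


@dataclass(frozen=True)
class CellAnnotation:
    """Phenotype of a cell line used as one-hot covariates."""

    tissue: str
    gender: str
    age: float


def _age_bin(age: float) -> int:
    return int(age // 10)


@dataclass(frozen=True)
class CovariateVocab:
    """Category dictionaries for the one-hot blocks, built on training data.

    Blocks: dose_a, dose_b (distinct tested concentrations on the
    injection scale), tissue, gender, age decade.  Categories unseen at
    build time encode to an all-zero block.
    """

    doses_a: tuple[float, ...]
    doses_b: tuple[float, ...]
    tissues: tuple[str, ...]
    genders: tuple[str, ...]
    age_bins: tuple[int, ...]
    cell_info: Mapping[str, CellAnnotation] = field(default_factory=dict)

    @classmethod
    def build(
        cls,
        samples: Sequence[LabelledSample],
        cell_info: Mapping[str, CellAnnotation] | None = None,
    ) -> "CovariateVocab":
        cell_info = dict(cell_info or {})
        doses_a = tuple(sorted({float(transform_dose(s.record.dose_a)) for s in samples}))
        doses_b = tuple(sorted({float(transform_dose(s.record.dose_b)) for s in samples}))
        annos = [cell_info[s.record.cell] for s in samples if s.record.cell in cell_info]
        return cls(
            doses_a=doses_a,
            doses_b=doses_b,
            tissues=tuple(sorted({a.tissue for a in annos})),
            genders=tuple(sorted({a.gender for a in annos})),
            age_bins=tuple(sorted({_age_bin(a.age) for a in annos})),
            cell_info=cell_info,
        )

    @property
    def size(self) -> int:
        return (
            len(self.doses_a)
            + len(self.doses_b)
            + len(self.tissues)
            + len(self.genders)
            + len(self.age_bins)
        )

    def encode(self, sample: LabelledSample) -> np.ndarray:
        def block(categories: Sequence, value) -> np.ndarray:
            vec = np.zeros(len(categories))
            if value in categories:
                vec[list(categories).index(value)] = 1.0
            return vec

        da = float(transform_dose(sample.record.dose_a))
        db = float(transform_dose(sample.record.dose_b))
        anno = self.cell_info.get(sample.record.cell)
        parts = [
            block(self.doses_a, da),
            block(self.doses_b, db),
            block(self.tissues, anno.tissue if anno else None),
            block(self.genders, anno.gender if anno else None),
            block(self.age_bins, _age_bin(anno.age) if anno else None),
        ]
        return np.concatenate(parts)


# ---------------------------------------------------------------------------
# End-to-end featurization


def build_subject_features(
    samples: Sequence[LabelledSample],
    nes: NESMatrix,
    cell_hg: IncidenceHypergraph,
    drug_hg: IncidenceHypergraph,
    vocab: CovariateVocab,
) -> tuple[SubjectFeatureMatrix, SubjectFeatureMatrix, np.ndarray, np.ndarray]:
    """Assemble aligned model inputs for a list of curated samples.

    Returns the cell-line feature matrix (aligned to the gene-set
    hypergraph nodes), the drug-pair feature matrix (aligned to the drug
    hypergraph nodes), the covariate matrix and the label vector.  Doses
    are transformed to the injection scale here.
    """
    if list(cell_hg.node_names) != list(nes.set_names):
        raise ValueError("gene-set hypergraph nodes must match NES columns")
    f_cell = np.empty((len(samples), cell_hg.n_nodes))
    f_drug = np.empty((len(samples), drug_hg.n_nodes))
    cov = np.empty((len(samples), vocab.size))
    labels = np.empty(len(samples), dtype=int)
    for i, s in enumerate(samples):
        da = float(transform_dose(s.record.dose_a))
        db = float(transform_dose(s.record.dose_b))
        f_cell[i] = dose_inject_cell(nes.row(s.record.cell), da, db)
        f_drug[i] = dose_inject_drugpair(drug_hg, s.record.drug_a, s.record.drug_b, da, db)
        cov[i] = vocab.encode(s)
        labels[i] = s.label
    ids = list(range(len(samples)))
    return (
        SubjectFeatureMatrix(ids, list(cell_hg.node_names), f_cell),
        SubjectFeatureMatrix(ids, list(drug_hg.node_names), f_drug),
        cov,
        labels,
    )
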