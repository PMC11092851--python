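"""Hypergraph builders, ssGSEA, dose injection and covariate encoding."""

import numpy as np
import pytest

from safer.curation import LabelledSample
from safer.features import (
    CellAnnotation,
    CovariateVocab,
    IncidenceHypergraph,
    build_drug_hypergraph,
    build_geneset_hypergraph,
    dose_inject_cell,
    dose_inject_drugpair,
    kmer_tokenize,
    ssgsea,
    transform_dose,
)
from safer.io_formats import DrugRecord, ExpressionMatrix, GeneSetCollection, SynergyRecord


class TestIncidenceInvariants:
    def test_empty_hyperedge_rejected(self):
        with pytest.raises(ValueError, match="empty hyperedges"):
            IncidenceHypergraph(["n0"], ["e0", "e1"], np.array([[1.0, 0.0]]))

    def test_isolated_node_rejected(self):
        with pytest.raises(ValueError, match="isolated nodes"):
            IncidenceHypergraph(["n0", "n1"], ["e0"], np.array([[1.0], [0.0]]))


class TestSsgsea:
    def test_hand_computed_running_sum(self):
        # one sample with values (4, 3, 2, 1); sets = top-2 and bottom-2 genes.
        # Weighted KS sums (w = 0.25): ES_top = 4^.25/(4^.25+3^.25) + 1 + 0.5
        # = 2.0179723833, ES_bottom = -1.9567863831; NES divides by the range.
        expr = ExpressionMatrix(
            genes=["G1", "G2", "G3", "G4"],
            samples=["c1"],
            values=np.array([[4.0], [3.0], [2.0], [1.0]]),
        )
        sets = GeneSetCollection({"TOP": ["G1", "G2"], "BOTTOM": ["G3", "G4"]})
        nes = ssgsea(expr, sets, sample_norm="none")
        assert nes.values[0, nes.set_names.index("TOP")] == pytest.approx(0.5076968193188184)
        assert nes.values[0, nes.set_names.index("BOTTOM")] == pytest.approx(-0.4923031806811817)

    def test_gene_row_permutation_invariance(self, rng):
        genes = [f"G{i}" for i in range(30)]
        values = rng.lognormal(size=(30, 4))
        sets = GeneSetCollection({"S1": genes[:7], "S2": genes[10:20]})
        base = ssgsea(ExpressionMatrix(genes, ["a", "b", "c", "d"], values), sets)
        perm = rng.permutation(30)
        shuffled = ssgsea(
            ExpressionMatrix([genes[i] for i in perm], ["a", "b", "c", "d"], values[perm]), sets
        )
        np.testing.assert_allclose(base.values, shuffled.values, atol=1e-12)

    def test_matches_reference_implementation(self, rng):
        gseapy = pytest.importorskip("gseapy")
        import pandas as pd

        genes = [f"G{i}" for i in range(50)]
        cells = [f"c{i}" for i in range(4)]
        values = rng.lognormal(size=(50, 4))
        sets = {"S1": genes[:10], "S2": genes[15:27], "S3": genes[30:38]}
        ours = ssgsea(
            ExpressionMatrix(genes, cells, values), GeneSetCollection(sets), weight=0.25
        )
        ref = gseapy.ssgsea(
            data=pd.DataFrame(values, index=genes, columns=cells),
            gene_sets=sets,
            outdir=None,
            sample_norm_method="rank",
            weight=0.25,
            min_size=1,
            no_plot=True,
            threads=1,
        ).res2d
        for _, row in ref.iterrows():
            got = ours.values[ours.cells.index(row["Name"]), ours.set_names.index(row["Term"])]
            assert got == pytest.approx(float(row["NES"]), abs=1e-6)

    def test_zero_overlap_set_dropped_with_warning(self):
        expr = ExpressionMatrix(["G1", "G2"], ["c1"], np.array([[1.0], [2.0]]))
        sets = GeneSetCollection({"OK": ["G1"], "MISSING": ["ZZZ"]})
        with pytest.warns(UserWarning, match="MISSING"):
            nes = ssgsea(expr, sets)
        assert nes.set_names == ["OK"]


class TestGenesetHypergraph:
    def test_shared_gene_bridges_sets(self):
        hg = build_geneset_hypergraph(GeneSetCollection({"S1": ["A", "B"], "S2": ["B", "C"]}))
        assert hg.node_names == ["S1", "S2"]
        assert hg.edge_names == ["A", "B", "C"]
        np.testing.assert_array_equal(hg.edge_column("B"), [1.0, 1.0])

    def test_disjoint_sets_block_diagonal(self):
        hg = build_geneset_hypergraph(GeneSetCollection({"S1": ["A", "B"], "S2": ["C", "D"]}))
        np.testing.assert_array_equal(
            hg.incidence, [[1.0, 1.0, 0.0, 0.0], [0.0, 0.0, 1.0, 1.0]]
        )

    def test_column_sums_equal_membership_counts(self, rng):
        genes = [f"G{i}" for i in range(12)]
        sets = {
            f"S{i}": sorted(rng.choice(genes, size=rng.integers(2, 6), replace=False))
            for i in range(5)
        }
        hg = build_geneset_hypergraph(GeneSetCollection(sets))
        for j, gene in enumerate(hg.edge_names):
            expected = sum(gene in members for members in sets.values())
            assert hg.incidence[:, j].sum() == expected

    def test_transpose_flag(self):
        hg = build_geneset_hypergraph(
            GeneSetCollection({"S1": ["A", "B"], "S2": ["B"]}), sets_as_nodes=False
        )
        assert hg.node_names == ["A", "B"] and hg.edge_names == ["S1", "S2"]


class TestKmer:
    def test_sliding_window(self):
        assert kmer_tokenize("ABCD", 3) == {"ABC", "BCD"}

    def test_short_string_single_token(self):
        assert kmer_tokenize("CCO", 9) == {"CCO"}

    def test_empty_string_rejected(self):
        with pytest.raises(ValueError):
            kmer_tokenize("", 3)

    def test_window_count_before_dedup(self, rng):
        alphabet = list("CcON1()")
        for _ in range(50):
            n = int(rng.integers(1, 30))
            k = int(rng.integers(1, 12))
            s = "".join(rng.choice(alphabet, size=n))
            windows = [s[i : i + k] for i in range(max(1, n - k + 1))] if n >= k else [s]
            assert len(windows) == max(1, n - k + 1)
            assert kmer_tokenize(s, k) == set(windows)


class TestDrugHypergraph:
    drugs = [
        DrugRecord("d1", "CCOCC", frozenset({"G1"})),
        DrugRecord("d2", "CCOCC", frozenset()),
        DrugRecord("d3", "NNCON", frozenset({"G9"})),
    ]
    sets = GeneSetCollection({"S1": ["G1", "G2"], "S2": ["G3"]})

    def test_gene_overlap_makes_incidence(self):
        hg = build_drug_hypergraph(self.drugs, self.sets, k=3)
        assert hg.incidence[hg.node_names.index("S1"), hg.edge_names.index("d1")] == 1.0
        assert "S2" not in hg.node_names  # no drug touches S2

    def test_identical_smiles_share_token_columns(self):
        hg = build_drug_hypergraph(self.drugs, self.sets, k=3)
        token_rows = [i for i, n in enumerate(hg.node_names) if n not in self.sets.sets]
        col1 = hg.incidence[token_rows, hg.edge_names.index("d1")]
        col2 = hg.incidence[token_rows, hg.edge_names.index("d2")]
        np.testing.assert_array_equal(col1, col2)

    def test_node_count_is_tokens_plus_overlapping_sets(self):
        hg = build_drug_hypergraph(self.drugs, self.sets, k=3)
        tokens = set()
        for d in self.drugs:
            tokens |= kmer_tokenize(d.smiles, 3)
        assert hg.n_nodes == len(tokens) + 1  # only S1 overlaps


class TestDoseInjection:
    def test_cell_injection_formula(self):
        np.testing.assert_allclose(dose_inject_cell(np.array([0.5]), 2.0, 3.0), [2.5])

    def test_zero_doses_warn_and_zero_row(self):
        with pytest.warns(UserWarning):
            row = dose_inject_cell(np.array([0.5, -0.2]), 0.0, 0.0)
        np.testing.assert_array_equal(row, [0.0, 0.0])

    def test_linearity_in_dose(self, rng):
        nes = rng.normal(size=6)
        np.testing.assert_allclose(
            dose_inject_cell(nes, 4.0, 6.0), 2 * dose_inject_cell(nes, 2.0, 3.0)
        )

    def test_drugpair_injection(self):
        hg = IncidenceHypergraph(
            ["only_a", "both", "only_b"],
            ["da", "db"],
            np.array([[1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]),
        )
        row = dose_inject_drugpair(hg, "da", "db", 2.0, 3.0)
        np.testing.assert_allclose(row, [2.0, 5.0, 3.0])

    def test_unknown_drug_rejected(self, toy_hypergraph):
        with pytest.raises(KeyError):
            dose_inject_drugpair(toy_hypergraph, "e0", "nope", 1.0, 1.0)


def _sample(dose_a=1.0, dose_b=10.0, cell="c1", loewe=15.0):
    return LabelledSample(
        record=SynergyRecord("a", "b", cell, dose_a, dose_b, 20.0, 12.0, 12.0, loewe, 12.0, "s"),
        label=1,
    )


class TestCovariates:
    info = {"c1": CellAnnotation("lung", "F", 54.0)}

    def test_dose_block_one_hot(self):
        samples = [_sample(1.0, 10.0), _sample(10.0, 100.0), _sample(100.0, 1.0)]
        vocab = CovariateVocab.build(samples, self.info)
        vec = vocab.encode(_sample(10.0, 1.0))
        # dose_a block has categories t(1) < t(10) < t(100); 10 is the middle
        np.testing.assert_array_equal(vec[:3], [0.0, 1.0, 0.0])

    def test_unseen_dose_encodes_zero_block(self):
        vocab = CovariateVocab.build([_sample(1.0, 1.0)], self.info)
        vec = vocab.encode(_sample(55.0, 1.0))
        assert vec[0] == 0.0  # single dose_a category, not matched

    def test_length_is_sum_of_vocab_sizes(self):
        samples = [_sample(1.0, 10.0), _sample(10.0, 1.0)]
        vocab = CovariateVocab.build(samples, self.info)
        assert len(vocab.encode(samples[0])) == vocab.size
        assert vocab.size == 2 + 2 + 1 + 1 + 1

    def test_dose_transform_monotone_log(self):
        assert transform_dose(0.0) == 0.0
        assert transform_dose(9.0) == pytest.approx(1.0)
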