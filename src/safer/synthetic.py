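"""Seeded toy data with a planted dose-dependent synergy signal.

The generator emits every input the tool consumes — gene sets, a
log-scale expression matrix, a drug table with SMILES-like strings,
a dose-level response table, an IC50 table and cell-line phenotypes — at
a scale where end-to-end training runs in minutes.  A designated subset
of gene sets is causal: the noise-free synergy logit of a sample is

    effect_size * meanNES_causal(cell) * (t(dose_a) + t(dose_b) - center)

with ``t`` the log10(dose + 1) injection transform and ``center`` the
grid-average dose sum.  Centering makes the signal change sign along the
dose axis, so a triplet genuinely switches between synergy and
antagonism with dose, which is the regime the model is built for.  The
Loewe score is ``10 x logit`` so the +/-10 label thresholds correspond
to |logit| = 1, and the other three synergy scores are noisy copies.
Configurable fractions of records are overwritten as additive,
non-inhibitory-synergistic, non-cancer or replicated to exercise every
curation rule.

This is not a biological simulator: expression is i.i.d. log-normal,
SMILES strings are random and only the monotone dose structure of real
screens is retained.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .curation import filter_gene_sets
from .features import CellAnnotation, ssgsea, transform_dose
from .io_formats import DrugRecord, ExpressionMatrix, GeneSetCollection, SynergyRecord

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate", "worked_pipeline_fixture"]

_SMILES_ALPHABET = "CcON1()"


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    n_genes: int = 120
    n_sets: int = 30
    n_cells: int = 10
    n_drugs: int = 12
    dose_levels: int = 4  # square dose grid, e.g. 4 -> 4x4
    k_mer: int = 9
    n_causal: int = 3
    effect_size: float = 15.0  # logit shift per unit dose-weighted NES
    noise_sd: float = 0.3
    frac_additive: float = 0.05  # records overwritten as additive
    frac_noninhibitory: float = 0.02
    frac_noncancer: float = 0.02
    frac_replicated: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sets < 2 or self.n_genes < 10 or self.n_drugs < 2 or self.n_cells < 1:
            raise ValueError("degenerate synthetic spec")
        if self.dose_levels < 2:
            raise ValueError("need at least a 2x2 dose grid")
        if self.n_causal < 1:
            raise ValueError("need at least one causal set")


@dataclass
class SyntheticDataset:
    """Generated inputs plus the ground truth they were built from."""

    spec: SyntheticSpec
    gene_sets: GeneSetCollection
    expression: ExpressionMatrix
    drugs: list[DrugRecord]
    records: list[SynergyRecord]
    ic50: dict[tuple[str, str], float]
    cell_info: dict[str, CellAnnotation]
    causal_sets: list[str]
    #: noise-free logit per record; None for rows overwritten by a filter case
    true_logits: list[float | None]

    @property
    def true_labels(self) -> list[int | None]:
        """Noise-free sign labels: 1 above zero logit, 0 below, None if corrupted."""
        return [
            None if lg is None else (1 if lg > 0 else 0) for lg in self.true_logits
        ]


def _random_smiles(rng: np.random.Generator) -> str:
    length = int(rng.integers(12, 41))
    return "".join(rng.choice(list(_SMILES_ALPHABET), size=length))


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate a full synthetic study; the seed fixes every draw."""
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:03d}" for i in range(spec.n_genes)]
    cells = [f"CELL{i:02d}" for i in range(spec.n_cells)]

    # gene sets with sizes straddling the one-sd size filter: a core of
    # moderate sets plus a minority of large outliers that the filter drops
    sets: dict[str, list[str]] = {}
    for i in range(spec.n_sets):
        if rng.random() < 0.15:
            size = int(rng.integers(spec.n_genes // 3, max(spec.n_genes // 2, spec.n_genes // 3 + 2)))
        else:
            size = int(rng.integers(5, 16))
        members = rng.choice(genes, size=size, replace=False)
        sets[f"SET{i:02d}"] = sorted(members)
    collection = GeneSetCollection(sets)
    retained = filter_gene_sets(collection)
    causal = sorted(retained.sets)[: spec.n_causal]

    expression = ExpressionMatrix(
        genes=genes,
        samples=cells,
        values=np.log2(rng.lognormal(mean=3.0, sigma=1.0, size=(spec.n_genes, spec.n_cells)) + 1.0),
    )

    drugs = []
    for i in range(spec.n_drugs):
        n_assoc = int(rng.integers(1, 5))
        assoc = frozenset(rng.choice(genes, size=n_assoc, replace=False))
        drugs.append(DrugRecord(name=f"DRUG{i:02d}", smiles=_random_smiles(rng), associated_genes=assoc))

    tissues = ["lung", "breast", "colon", "skin"]
    cell_info = {
        c: CellAnnotation(
            tissue=tissues[int(rng.integers(len(tissues)))],
            gender=["F", "M"][int(rng.integers(2))],
            age=float(rng.integers(20, 80)),
        )
        for c in cells
    }

    # planted signal lives on the causal sets' enrichment
    nes = ssgsea(expression, retained)
    causal_idx = [nes.set_names.index(s) for s in causal]
    mean_nes = {c: float(nes.row(c)[causal_idx].mean()) for c in cells}

    doses = np.logspace(-1, 2, spec.dose_levels)  # 0.1 .. 100 concentration units
    tdose = transform_dose(doses)
    center = float(2 * np.mean(tdose))

    ic50 = {
        (d.name, c): float(10 ** rng.uniform(-0.5, 1.7))
        for d in drugs
        for c in cells
    }

    records: list[SynergyRecord] = []
    true_logits: list[float | None] = []

    def emit(rec: SynergyRecord, logit: float | None) -> None:
        records.append(rec)
        true_logits.append(logit)

    for (da_drug, db_drug), cell in itertools.product(
        itertools.combinations(drugs, 2), cells
    ):
        for dose_a, dose_b in itertools.product(doses, doses):
            signal = spec.effect_size * mean_nes[cell] * (
                float(transform_dose(dose_a)) + float(transform_dose(dose_b)) - center
            )
            logit = signal + rng.normal(0, spec.noise_sd)
            loewe = 10.0 * logit
            others = loewe + rng.normal(0, 3.0, size=3)
            inhibition = 30.0 + 5.0 * logit + rng.normal(0, 5.0)
            study = "synthetic-screen"
            u = rng.random()
            rec = SynergyRecord(
                drug_a=da_drug.name,
                drug_b=db_drug.name,
                cell=cell,
                dose_a=float(dose_a),
                dose_b=float(dose_b),
                inhibition=float(inhibition),
                bliss=float(others[0]),
                hsa=float(others[1]),
                loewe=float(loewe),
                zip=float(others[2]),
                study=study,
            )
            if u < spec.frac_additive:
                band = rng.uniform(-9.5, 9.5, size=4)
                rec = SynergyRecord(
                    rec.drug_a, rec.drug_b, rec.cell, rec.dose_a, rec.dose_b,
                    inhibition=float(rec.inhibition),
                    bliss=float(band[0]), hsa=float(band[1]),
                    loewe=float(band[2]), zip=float(band[3]), study=study,
                )
                emit(rec, None)
            elif u < spec.frac_additive + spec.frac_noninhibitory:
                high = rng.uniform(11.0, 25.0, size=4)
                rec = SynergyRecord(
                    rec.drug_a, rec.drug_b, rec.cell, rec.dose_a, rec.dose_b,
                    inhibition=float(rng.uniform(-30.0, -1.0)),
                    bliss=float(high[0]), hsa=float(high[1]),
                    loewe=float(high[2]), zip=float(high[3]), study=study,
                )
                emit(rec, None)
            elif u < spec.frac_additive + spec.frac_noninhibitory + spec.frac_noncancer:
                rec = SynergyRecord(
                    rec.drug_a, rec.drug_b, rec.cell, rec.dose_a, rec.dose_b,
                    inhibition=rec.inhibition, bliss=rec.bliss, hsa=rec.hsa,
                    loewe=rec.loewe, zip=rec.zip, study="malaria",
                )
                emit(rec, None)
            else:
                emit(rec, float(signal))
                if rng.random() < spec.frac_replicated:
                    jitter = rng.normal(0, 0.5, size=4)
                    emit(
                        SynergyRecord(
                            rec.drug_a, rec.drug_b, rec.cell, rec.dose_a, rec.dose_b,
                            inhibition=float(rec.inhibition + rng.normal(0, 1.0)),
                            bliss=float(rec.bliss + jitter[0]),
                            hsa=float(rec.hsa + jitter[1]),
                            loewe=float(rec.loewe + jitter[2]),
                            zip=float(rec.zip + jitter[3]),
                            study=study,
                        ),
                        float(signal),
                    )

    return SyntheticDataset(
        spec=spec,
        gene_sets=collection,
        expression=expression,
        drugs=drugs,
        records=records,
        ic50=ic50,
        cell_info=cell_info,
        causal_sets=causal,
        true_logits=true_logits,
    )


def worked_pipeline_fixture() -> tuple[list[SynergyRecord], list[DrugRecord]]:
    """The fixed five-record curation table with exactly two survivors.

    Rows 1 and 2 are replicates averaging to Loewe 15 (one synergistic
    sample), row 3 is additive, row 4 is fully-synergistic but
    non-inhibitory, and row 5 is antagonistic (the second survivor).
    """
    drugs = [
        DrugRecord(name="DRUG-A", smiles="CCOCCOCCN"),
        DrugRecord(name="DRUG-B", smiles="CCNCC(C)O"),
    ]
    records = [
        SynergyRecord("DRUG-A", "DRUG-B", "CELL-1", 1.0, 2.0, 30.0, 12.0, 15.0, 20.0, 11.0, "s1"),
        SynergyRecord("DRUG-B", "DRUG-A", "CELL-1", 2.0, 1.0, 32.0, 14.0, 13.0, 10.0, 12.0, "s2"),
        SynergyRecord("DRUG-A", "DRUG-B", "CELL-1", 10.0, 10.0, 25.0, 3.0, -2.0, 5.0, 8.0, "s1"),
        SynergyRecord("DRUG-A", "DRUG-B", "CELL-2", 1.0, 1.0, -5.0, 12.0, 14.0, 11.0, 13.0, "s1"),
        SynergyRecord("DRUG-A", "DRUG-B", "CELL-2", 10.0, 1.0, 10.0, -12.0, -14.0, -20.0, -11.0, "s1"),
    ]
    return records, drugs
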