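"""Sample-inclusion pipeline: raw dose-level records -> labelled samples.

The pipeline, in order: unify drug names by SMILES, average experimental
replicates, drop non-cancer studies, drop additive samples (all four
synergy scores inside [-10, 10]), drop fully-synergistic samples that do
not inhibit growth, binarize the Loewe score at +/-10.  Every removal is
attributed to exactly one named rule and the stage counts in the report
reconcile.

A companion rule filters gene-set collections to sizes within one
standard deviation of the mean set size.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import DrugRecord, GeneSetCollection, SynergyRecord

__all__ = [
    "ADDITIVE_BAND",
    "LOEWE_THRESHOLD",
    "DEFAULT_NONCANCER_STUDIES",
    "LabelledSample",
    "CurationReport",
    "unify_drugs",
    "average_replicates",
    "filter_noncancer",
    "filter_additive",
    "filter_noninhibitory_synergy",
    "binarize",
    "curate",
    "filter_gene_sets",
    "canonical_triplet",
]

#: closed interval on every synergy score inside which a sample is additive
ADDITIVE_BAND = (-10.0, 10.0)
#: |LOEWE| threshold for the binary synergy/antagonism label
LOEWE_THRESHOLD = 10.0
#: study/disease tags treated as non-cancer screens
DEFAULT_NONCANCER_STUDIES = frozenset({"MALARIA", "SARS-COV-2"})


@dataclass(frozen=True)
class LabelledSample:
    """A curated dose-combination sample with its binary synergy label."""

    record: SynergyRecord
    label: int  # 1 = synergistic (LOEWE > 10), 0 = antagonistic (LOEWE < -10)

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")

    @property
    def triplet(self) -> tuple[str, str, str]:
        return self.record.triplet

    @property
    def doses(self) -> tuple[float, float]:
        return (self.record.dose_a, self.record.dose_b)


@dataclass
class CurationReport:
    """Stage counts plus an excluded-record log; counts are non-increasing."""

    input: int = 0
    after_drug_unification: int = 0
    after_replicate_averaging: int = 0
    after_noncancer_filter: int = 0
    after_additive_filter: int = 0
    after_noninhibitory_filter: int = 0
    after_label_binarization: int = 0
    exclusions: list[tuple[str, tuple]] = field(default_factory=list)

    def log(self, rule: str, record: SynergyRecord) -> None:
        self.exclusions.append((rule, (record.drug_a, record.drug_b, record.cell,
                                       record.dose_a, record.dose_b)))

    def stage_counts(self) -> list[int]:
        return [
            self.input,
            self.after_drug_unification,
            self.after_replicate_averaging,
            self.after_noncancer_filter,
            self.after_additive_filter,
            self.after_noninhibitory_filter,
            self.after_label_binarization,
        ]

    def to_dict(self) -> dict:
        return {
            "stages": {
                "input": self.input,
                "after_drug_unification": self.after_drug_unification,
                "after_replicate_averaging": self.after_replicate_averaging,
                "after_noncancer_filter": self.after_noncancer_filter,
                "after_additive_filter": self.after_additive_filter,
                "after_noninhibitory_filter": self.after_noninhibitory_filter,
                "after_label_binarization": self.after_label_binarization,
            },
            "exclusions": [
                {"rule": rule, "record": list(key)} for rule, key in self.exclusions
            ],
        }


def canonical_triplet(drug_a: str, drug_b: str, cell: str) -> tuple[str, str, str]:
    """Order the drug pair lexicographically so (a, b) and (b, a) coincide."""
    if drug_b < drug_a:
        drug_a, drug_b = drug_b, drug_a
    return (drug_a, drug_b, cell)


def unify_drugs(
    records: Sequence[SynergyRecord],
    drugs: Sequence[DrugRecord],
    report: CurationReport | None = None,
) -> list[SynergyRecord]:
    """Map drug names sharing a SMILES to one canonical id and order pairs.

    Different vendor labels for the same molecule become one id (the
    lexicographically first name with that SMILES), which prevents the
    same pair leaking across folds under two spellings.  Records naming
    a drug absent from the drug table are dropped and logged.
    """
    by_smiles: dict[str, list[str]] = defaultdict(list)
    for d in drugs:
        by_smiles[d.smiles].append(d.name)
    canon: dict[str, str] = {}
    for smiles, names in by_smiles.items():
        rep = min(names)
        for name in names:
            canon[name] = rep

    out: list[SynergyRecord] = []
    for rec in records:
        if rec.drug_a not in canon or rec.drug_b not in canon:
            if report is not None:
                report.log("unknown-drug", rec)
            continue
        a, b = canon[rec.drug_a], canon[rec.drug_b]
        da, db = rec.dose_a, rec.dose_b
        if b < a:
            a, b = b, a
            da, db = db, da
        out.append(replace(rec, drug_a=a, drug_b=b, dose_a=da, dose_b=db))
    return out


def average_replicates(records: Sequence[SynergyRecord]) -> list[SynergyRecord]:
    """Collapse replicate groups (same triplet and dose pair) to their mean.

    All four synergy scores and the inhibition are replaced by arithmetic
    means; study tags of the group are merged (sorted, ';'-joined).
    Output order follows first appearance of each group.
    """
    groups: dict[tuple, list[SynergyRecord]] = {}
    for rec in records:
        key = (rec.drug_a, rec.drug_b, rec.cell, rec.dose_a, rec.dose_b)
        groups.setdefault(key, []).append(rec)
    out = []
    for key, grp in groups.items():
        first = grp[0]
        if len(grp) == 1:
            out.append(first)
            continue
        studies = sorted({g.study for g in grp if g.study})
        out.append(
            replace(
                first,
                inhibition=float(np.mean([g.inhibition for g in grp])),
                bliss=float(np.mean([g.bliss for g in grp])),
                hsa=float(np.mean([g.hsa for g in grp])),
                loewe=float(np.mean([g.loewe for g in grp])),
                zip=float(np.mean([g.zip for g in grp])),
                study=";".join(studies),
            )
        )
    return out


def filter_noncancer(
    records: Sequence[SynergyRecord],
    blacklist: Iterable[str] = DEFAULT_NONCANCER_STUDIES,
    report: CurationReport | None = None,
) -> list[SynergyRecord]:
    """Drop records whose study tag matches a non-cancer screen."""
    bl = {b.upper() for b in blacklist}
    out = []
    for rec in records:
        tags = {t.strip().upper() for t in rec.study.split(";")}
        if tags & bl:
            if report is not None:
                report.log("non-cancer-study", rec)
            continue
        out.append(rec)
    return out


def is_additive(rec: SynergyRecord) -> bool:
    lo, hi = ADDITIVE_BAND
    return all(lo <= s <= hi for s in rec.scores)


def filter_additive(
    records: Sequence[SynergyRecord], report: CurationReport | None = None
) -> list[SynergyRecord]:
    """Remove samples with all four synergy scores within the additive band.

    The band is the closed interval [-10, 10]: a score exactly on the
    boundary still counts as additive.
    """
    out = []
    for rec in records:
        if is_additive(rec):
            if report is not None:
                report.log("additive", rec)
            continue
        out.append(rec)
    return out


def filter_noninhibitory_synergy(
    records: Sequence[SynergyRecord], report: CurationReport | None = None
) -> list[SynergyRecord]:
    """Remove fully-synergistic samples that do not kill cells.

    "Full agreement" means every one of the four scores exceeds +10; such
    a sample is excluded when its %inhibition is negative (the combination
    grew cells relative to the untreated control).
    """
    out = []
    for rec in records:
        if all(s > LOEWE_THRESHOLD for s in rec.scores) and rec.inhibition < 0:
            if report is not None:
                report.log("noninhibitory-synergy", rec)
            continue
        out.append(rec)
    return out


def binarize(
    records: Sequence[SynergyRecord], report: CurationReport | None = None
) -> list[LabelledSample]:
    """Label LOEWE > 10 as synergistic (1) and LOEWE < -10 as antagonistic (0).

    Records whose LOEWE lies inside [-10, 10] (possible when another score
    carried them past the additive filter) are excluded as indeterminate.
    """
    out = []
    for rec in records:
        if rec.loewe > LOEWE_THRESHOLD:
            out.append(LabelledSample(record=rec, label=1))
        elif rec.loewe < -LOEWE_THRESHOLD:
            out.append(LabelledSample(record=rec, label=0))
        elif report is not None:
            report.log("loewe-indeterminate", rec)
    return out


def curate(
    records: Sequence[SynergyRecord],
    drugs: Sequence[DrugRecord],
    noncancer_studies: Iterable[str] = DEFAULT_NONCANCER_STUDIES,
) -> tuple[list[LabelledSample], CurationReport]:
    """Run the full inclusion pipeline and return samples plus the report."""
    report = CurationReport(input=len(records))
    recs = unify_drugs(records, drugs, report)
    report.after_drug_unification = len(recs)
    recs = average_replicates(recs)
    report.after_replicate_averaging = len(recs)
    recs = filter_noncancer(recs, noncancer_studies, report)
    report.after_noncancer_filter = len(recs)
    recs = filter_additive(recs, report)
    report.after_additive_filter = len(recs)
    recs = filter_noninhibitory_synergy(recs, report)
    report.after_noninhibitory_filter = len(recs)
    samples = binarize(recs, report)
    report.after_label_binarization = len(samples)
    return samples, report


def filter_gene_sets(collection: GeneSetCollection) -> GeneSetCollection:
    """Keep gene sets whose size is within one sd of the mean set size.

    The sd is the sample standard deviation (n-1 denominator) over all
    set sizes; the interval is closed, so with equal-sized sets (sd = 0)
    everything is retained.  Requires at least two sets.
    """
    sizes = np.array([len(g) for g in collection.sets.values()], dtype=float)
    if len(sizes) < 2:
        raise ValueError("need at least 2 gene sets to size-filter")
    mean = sizes.mean()
    sd = sizes.std(ddof=1)
    kept = {
        name: genes
        for name, genes in collection.sets.items()
        if mean - sd <= len(genes) <= mean + sd
    }
    return GeneSetCollection(kept)
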