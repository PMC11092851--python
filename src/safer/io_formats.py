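"""Readers and writers for the file formats the tool touches.

Gene sets travel as GMT, expression matrices as TSV (genes x cell lines,
log2(TPM+1) scale), and drug / synergy-response / IC50 tables as CSV in a
DrugComb-export-like dialect.  All readers validate strictly and return a
parse report whenever rows can legitimately be dropped, so that
``kept + dropped == total`` always reconciles.

Gene symbols are upper-cased at ingest: upstream sources mix symbol cases
and silent case mismatches would otherwise drop genes from enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneSetCollection",
    "ExpressionMatrix",
    "DrugRecord",
    "SynergyRecord",
    "ParseReport",
    "FormatError",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "read_synergy_table",
    "write_synergy_table",
    "read_drug_table",
    "write_drug_table",
    "read_ic50_table",
    "write_ic50_table",
    "SYNERGY_COLUMNS",
]


class FormatError(ValueError):
    """A file violates the expected dialect or a field invariant."""


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (TF-target or pathway collections).

    ``sets`` maps a unique set name to an ordered, duplicate-free list of
    upper-case gene symbols.  Empty sets are rejected.
    """

    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise FormatError(f"gene set {name!r} has duplicate genes")
            if any(not g for g in genes):
                raise FormatError(f"gene set {name!r} has an empty gene symbol")

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def sizes(self) -> dict[str, int]:
        return {name: len(genes) for name, genes in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x cell-lines expression, log2(TPM+1) scale."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.genes), len(self.samples)):
            raise FormatError("expression matrix shape does not match axes")
        if len(set(self.genes)) != len(self.genes):
            raise FormatError("duplicate gene symbols in expression matrix")
        if len(set(self.samples)) != len(self.samples):
            raise FormatError("duplicate sample ids in expression matrix")
        if not np.all(np.isfinite(values)):
            raise FormatError("non-finite expression values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    def sample_values(self, sample: str) -> np.ndarray:
        return self.values[:, self.samples.index(sample)]


@dataclass(frozen=True)
class DrugRecord:
    """A drug: name, SMILES string and (possibly empty) associated genes."""

    name: str
    smiles: str
    associated_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.smiles:
            raise FormatError(f"drug {self.name!r} has an empty SMILES")
        object.__setattr__(
            self, "associated_genes", frozenset(g.upper() for g in self.associated_genes)
        )


@dataclass(frozen=True)
class SynergyRecord:
    """One dose-level combination measurement.

    ``inhibition`` is % growth inhibition relative to the untreated
    control; the four synergy scores follow the reference models of
    non-interaction (positive = synergy, negative = antagonism).
    """

    drug_a: str
    drug_b: str
    cell: str
    dose_a: float
    dose_b: float
    inhibition: float
    bliss: float
    hsa: float
    loewe: float
    zip: float
    study: str = ""

    def __post_init__(self) -> None:
        if self.dose_a < 0 or self.dose_b < 0:
            raise FormatError(
                f"negative dose for ({self.drug_a}, {self.drug_b}, {self.cell})"
            )

    @property
    def scores(self) -> tuple[float, float, float, float]:
        return (self.bliss, self.hsa, self.loewe, self.zip)

    @property
    def triplet(self) -> tuple[str, str, str]:
        return (self.drug_a, self.drug_b, self.cell)


@dataclass
class ParseReport:
    """Accounting of rows seen vs. kept while parsing a table."""

    total: int = 0
    kept: int = 0
    dropped: int = 0
    drop_reasons: dict[str, int] = field(default_factory=dict)

    def drop(self, reason: str, n: int = 1) -> None:
        self.dropped += n
        self.drop_reasons[reason] = self.drop_reasons.get(reason, 0) + n

    def reconciles(self) -> bool:
        return self.kept + self.dropped == self.total


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: ``name TAB description TAB gene1 TAB ...`` per line.

    Duplicate genes within a set are deduplicated preserving first
    occurrence; duplicate set names or empty sets raise :class:`FormatError`.
    """
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs name, description, genes")
        name = parts[0]
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
        genes = list(dict.fromkeys(g.upper() for g in parts[2:] if g))
        if not genes:
            raise FormatError(f"{path}:{lineno}: set {name!r} is empty")
        sets[name] = genes
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *genes])
        for name, genes in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Expression TSV


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression matrix: first column gene symbols, header cells.

    Any non-numeric or missing cell and any duplicate gene row raise
    :class:`FormatError`.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene rows {dups}")
    try:
        values = df.to_numpy(dtype=str).astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression cell ({exc})") from exc
    if not np.all(np.isfinite(values)):
        raise FormatError(f"{path}: non-finite expression value")
    return ExpressionMatrix(
        genes=[str(g).upper() for g in df.index],
        samples=[str(c) for c in df.columns],
        values=values,
    )


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# Synergy response CSV (DrugComb-export dialect)

#: canonical field name -> default column name in the CSV
SYNERGY_COLUMNS: dict[str, str] = {
    "drug_a": "drug_a",
    "drug_b": "drug_b",
    "cell": "cell",
    "dose_a": "dose_a",
    "dose_b": "dose_b",
    "inhibition": "inhibition",
    "bliss": "bliss",
    "hsa": "hsa",
    "loewe": "loewe",
    "zip": "zip",
    "study": "study",
}

_SCORE_FIELDS = ("bliss", "hsa", "loewe", "zip")


def read_synergy_table(
    path: str | Path, columns: Mapping[str, str] | None = None
) -> tuple[list[SynergyRecord], ParseReport]:
    """Read a dose-level response table.

    ``columns`` remaps canonical field names to the file's column names
    (the export dialect varies between database versions).  Rows missing
    any of the four synergy scores are dropped and counted in the report;
    a missing mandatory column is a format error.
    """
    colmap = dict(SYNERGY_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path)
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory columns {missing}")
    report = ParseReport(total=len(df))
    records: list[SynergyRecord] = []
    for _, row in df.iterrows():
        scores = [row[colmap[f]] for f in _SCORE_FIELDS]
        if any(pd.isna(s) for s in scores) or pd.isna(row[colmap["inhibition"]]):
            report.drop("missing-score")
            continue
        records.append(
            SynergyRecord(
                drug_a=str(row[colmap["drug_a"]]),
                drug_b=str(row[colmap["drug_b"]]),
                cell=str(row[colmap["cell"]]),
                dose_a=float(row[colmap["dose_a"]]),
                dose_b=float(row[colmap["dose_b"]]),
                inhibition=float(row[colmap["inhibition"]]),
                bliss=float(row[colmap["bliss"]]),
                hsa=float(row[colmap["hsa"]]),
                loewe=float(row[colmap["loewe"]]),
                zip=float(row[colmap["zip"]]),
                study="" if pd.isna(row[colmap["study"]]) else str(row[colmap["study"]]),
            )
        )
        report.kept += 1
    return records, report


def write_synergy_table(records: Iterable[SynergyRecord], path: str | Path) -> None:
    rows = [
        {
            "drug_a": r.drug_a,
            "drug_b": r.drug_b,
            "cell": r.cell,
            "dose_a": r.dose_a,
            "dose_b": r.dose_b,
            "inhibition": r.inhibition,
            "bliss": r.bliss,
            "hsa": r.hsa,
            "loewe": r.loewe,
            "zip": r.zip,
            "study": r.study,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(SYNERGY_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Drug table / IC50 table CSV


def read_drug_table(path: str | Path) -> list[DrugRecord]:
    """Read ``name,smiles,genes`` CSV; genes semicolon-separated, upper-cased."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("name", "smiles", "genes"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if df["name"].duplicated().any():
        raise FormatError(f"{path}: duplicate drug names")
    drugs = []
    for _, row in df.iterrows():
        genes = frozenset(g.strip().upper() for g in row["genes"].split(";") if g.strip())
        drugs.append(DrugRecord(name=row["name"], smiles=row["smiles"], associated_genes=genes))
    return drugs


def write_drug_table(drugs: Iterable[DrugRecord], path: str | Path) -> None:
    rows = [
        {"name": d.name, "smiles": d.smiles, "genes": ";".join(sorted(d.associated_genes))}
        for d in drugs
    ]
    pd.DataFrame(rows, columns=["name", "smiles", "genes"]).to_csv(path, index=False)


def read_ic50_table(path: str | Path) -> dict[tuple[str, str], float]:
    """Read ``drug,cell,ic50`` CSV into a ``(drug, cell) -> IC50`` map.

    IC50 must be strictly positive (it is a concentration); duplicate
    (drug, cell) rows are a format error.
    """
    df = pd.read_csv(path)
    for col in ("drug", "cell", "ic50"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if df.duplicated(subset=["drug", "cell"]).any():
        raise FormatError(f"{path}: duplicate (drug, cell) IC50 rows")
    out: dict[tuple[str, str], float] = {}
    for _, row in df.iterrows():
        ic50 = float(row["ic50"])
        if not ic50 > 0:
            raise FormatError(f"{path}: IC50 must be > 0, got {ic50} for {row['drug']}")
        out[(str(row["drug"]), str(row["cell"]))] = ic50
    return out


def write_ic50_table(ic50: Mapping[tuple[str, str], float], path: str | Path) -> None:
    rows = [{"drug": d, "cell": c, "ic50": v} for (d, c), v in ic50.items()]
    pd.DataFrame(rows, columns=["drug", "cell", "ic50"]).to_csv(path, index=False)
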