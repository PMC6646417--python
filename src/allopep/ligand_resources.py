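"""Experimental HLA class I ligand resources.

Parses an IEDB-style ligand assay export and a published minor
histocompatibility antigen (mHA) table into allele-keyed databases of
9-mer peptides, and reports how well a cohort's HLA alleles are covered
by a database.

IEDB rows are kept when the epitope originates from *H. sapiens*, the
assay's qualitative measure is "positive" or "positive-high"
(case-insensitive) and an HLA allele is given.  Entries longer than nine
residues are dropped by default (the database is used as a set of 9-mer
class I ligands); mHA peptides, in contrast, are expanded into all their
9-mer frames.  Allele names are normalised to two-field resolution
(e.g. ``A*01:01``) before keying.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

#: Default column names for an IEDB assay export.
IEDB_COLUMNS = {
    "peptide": "Description",
    "allele": "Allele Name",
    "qualitative_measure": "Qualitative Measure",
    "host_organism": "Host Organism Name",
}

#: Default column names for a published-mHA table.
MHA_COLUMNS = {"peptide": "peptide", "allele": "allele", "gene": "gene"}

ACCEPTED_MEASURES = frozenset({"positive", "positive-high"})

_ALLELE_RE = re.compile(
    r"^(?:HLA-)?([A-Z]+[0-9]*)\*?(\d+)(?::(\d+))?(?::\d+)*[A-Z]?$"
)


class LigandTableError(ValueError):
    """Missing columns or unusable ligand table."""


def normalize_allele(name: str) -> str | None:
    """Normalise an HLA allele name to two-field resolution, e.g.
    ``HLA-A*01:01:02`` -> ``A*01:01``.  Returns None if unparseable or
    the second field is absent."""
    m = _ALLELE_RE.match(str(name).strip().replace(" ", ""))
    if not m:
        return None
    locus, f1, f2 = m.group(1), m.group(2), m.group(3)
    if f2 is None:
        return None
    return f"{locus}*{int(f1):02d}:{int(f2):02d}"


def allele_locus(allele: str) -> str:
    return allele.split("*")[0]


@dataclass(frozen=True)
class LigandDatabase:
    """Allele-keyed sets of experimental 9-mer HLA class I ligands."""

    kind: str  # "iedb" or "mha"
    ligands: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def alleles(self) -> set[str]:
        return set(self.ligands)

    def pooled(self, alleles) -> set[str]:
        """Union of ligand sets over the given alleles (absent keys ignored)."""
        out: set[str] = set()
        for a in alleles:
            out |= self.ligands.get(a, frozenset())
        return out


def nine_merize_peptide(peptide: str, k: int = 9) -> set[str]:
    """All length-9 frames of a peptide; peptides shorter than 9 are
    dropped with a warning (they cannot contribute class I 9-mers)."""
    if len(peptide) < k:
        logger.warning("peptide %r shorter than %d residues; dropped", peptide, k)
        return set()
    return {peptide[i : i + k] for i in range(len(peptide) - k + 1)}


def _read_table(path, columns: dict[str, str], required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [columns[c] for c in required if columns[c] not in df.columns]
    if missing:
        raise LigandTableError(f"{path}: missing required column(s) {missing}")
    return df


def parse_iedb_table(
    path,
    *,
    columns: dict[str, str] | None = None,
    ninemerize: bool = False,
) -> LigandDatabase:
    """Parse an IEDB-style assay export into a 9-mer ligand database.

    With ``ninemerize`` longer entries are expanded into 9-mer frames
    instead of being dropped.
    """
    cols = {**IEDB_COLUMNS, **(columns or {})}
    df = _read_table(
        path, cols, ["peptide", "allele", "qualitative_measure", "host_organism"]
    )
    ligands: dict[str, set[str]] = {}
    n_kept = 0
    for _, row in df.iterrows():
        host = str(row[cols["host_organism"]])
        if "homo sapiens" not in host.lower():
            continue
        measure = str(row[cols["qualitative_measure"]]).strip().lower()
        if measure not in ACCEPTED_MEASURES:
            continue
        allele = normalize_allele(row[cols["allele"]])
        if allele is None:
            continue
        peptide = str(row[cols["peptide"]]).strip().upper()
        if len(peptide) == 9:
            frames = {peptide}
        elif ninemerize and len(peptide) > 9:
            frames = nine_merize_peptide(peptide)
        else:
            continue
        ligands.setdefault(allele, set()).update(frames)
        n_kept += 1
    logger.info(
        "IEDB table %s: %d / %d rows kept over %d alleles",
        path, n_kept, len(df), len(ligands),
    )
    return LigandDatabase(
        kind="iedb", ligands={a: frozenset(s) for a, s in ligands.items()}
    )


def parse_mha_table(path, *, columns: dict[str, str] | None = None) -> LigandDatabase:
    """Parse a published-mHA table; peptides are expanded to 9-mer frames
    under their restricting allele and deduplicated."""
    cols = {**MHA_COLUMNS, **(columns or {})}
    df = _read_table(path, cols, ["peptide", "allele"])
    if df.empty:
        logger.warning("mHA table %s is empty", path)
    ligands: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        allele = normalize_allele(row[cols["allele"]])
        if allele is None:
            continue
        peptide = str(row[cols["peptide"]]).strip().upper()
        frames = nine_merize_peptide(peptide)
        if frames:
            ligands.setdefault(allele, set()).update(frames)
    return LigandDatabase(
        kind="mha", ligands={a: frozenset(s) for a, s in ligands.items()}
    )


def write_ligand_tsv(db: LigandDatabase, path) -> None:
    """Round-trippable TSV export (peptide, allele)."""
    with open(path, "w") as fh:
        fh.write("peptide\tallele\n")
        for allele in sorted(db.ligands):
            for pep in sorted(db.ligands[allele]):
                fh.write(f"{pep}\t{allele}\n")


def read_ligand_tsv(path, kind: str) -> LigandDatabase:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"peptide", "allele"} <= set(df.columns):
        raise LigandTableError(f"{path}: expected columns peptide, allele")
    ligands: dict[str, set[str]] = {}
    for pep, allele in zip(df["peptide"], df["allele"]):
        norm = normalize_allele(allele)
        if norm is None:
            continue
        ligands.setdefault(norm, set()).add(str(pep).upper())
    return LigandDatabase(
        kind=kind, ligands={a: frozenset(s) for a, s in ligands.items()}
    )


def allele_coverage(
    cohort_alleles: set[str], db: LigandDatabase, *, locus: str | None = None
) -> float:
    """Percentage of cohort alleles with at least one ligand in the database,
    optionally restricted to one locus."""
    alleles = {normalize_allele(a) for a in cohort_alleles}
    alleles.discard(None)
    if locus is not None:
        alleles = {a for a in alleles if allele_locus(a) == locus}
    if not alleles:
        raise ValueError("empty cohort allele set")
    covered = sum(1 for a in alleles if db.ligands.get(a))
    return 100.0 * covered / len(alleles)
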