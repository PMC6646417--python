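"""Alloreactivity estimation from recipient-unique peptides.

The recipient-unique peptide set U of a donor-recipient pair is reduced
to four per-pair count estimates of HLA-presented mismatching:

* M1 — |U ∩ IEDB ligands| pooled over the recipient's class I alleles;
* M2 — |F ∩ IEDB ligands|, where F is U after the immunogenicity and
  tissue-expression filters;
* M3 — |U ∩ published 9-mer mHAs| over the recipient's alleles;
* M4 — number of peptides in F predicted to bind one of the recipient's
  HLA-A/-B alleles at a consensus percentile rank at or below the cutoff.

The immunogenicity filter scores each 9-mer as a position-weighted sum
of amino-acid log-enrichment weights (anchor positions 1, 2 and the
C-terminus masked when run without HLA specification) and keeps peptides
scoring strictly above 0.2.  The expression filter keeps peptides whose
source gene (or transcript, when transcript-level records exist) is
annotated with supportive reliability in skin, intestine, lung, liver or
bone marrow — the tissues where epithelial/hematopoietic presentation is
relevant for graft-versus-host disease.

Binding-affinity prediction is a pluggable contract: any object with a
``supported_alleles``/``predict`` pair works.  Shipped implementations
are a precomputed-rank TSV reader and a deterministic toy
position-specific scoring matrix predictor for tests and simulations.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from typing import Protocol

import numpy as np
import pandas as pd
from scipy.stats import norm

from .ligand_resources import LigandDatabase, allele_locus, normalize_allele
from .peptide_mismatch import MismatchedPeptide

logger = logging.getLogger(__name__)

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: GvHD-relevant target tissues for the expression filter.
DEFAULT_TISSUES = frozenset({"skin", "intestine", "lung", "liver", "bone marrow"})

DEFAULT_RELIABILITY = "supportive"
DEFAULT_IMMUNOGENICITY_THRESHOLD = 0.2

CLASS_I_LOCI = ("A", "B", "C")


class ScoringError(ValueError):
    """Missing inputs for alloreactivity scoring."""


# ---------------------------------------------------------------------------
# Immunogenicity model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImmunogenicityModel:
    """Position-weighted amino-acid enrichment model of T-cell immunogenicity.

    ``residue_log_enrichment`` holds one dimensionless log-enrichment
    weight per standard residue; ``position_weights`` one importance
    weight per peptide position; ``masked_positions`` (1-based) are
    forced to contribute zero — by default the class I anchor positions
    1, 2 and the C-terminus, the model's behaviour when no HLA allele is
    specified.
    """

    residue_log_enrichment: dict[str, float]
    position_weights: tuple[float, ...]
    masked_positions: frozenset[int] = frozenset({1, 2, 9})
    threshold: float = DEFAULT_IMMUNOGENICITY_THRESHOLD
    version: str = "1.1"

    def __post_init__(self) -> None:
        missing = set(STANDARD_RESIDUES) - set(self.residue_log_enrichment)
        if missing:
            raise ValueError(f"no enrichment weight for residues {sorted(missing)}")

    @classmethod
    def load_default(cls, threshold: float = DEFAULT_IMMUNOGENICITY_THRESHOLD):
        """Load the packaged version-1.1 weight tables."""
        text = (
            importlib_resources.files("allopep.data")
            .joinpath("immunogenicity_v1_1.json")
            .read_text()
        )
        data = json.loads(text)
        return cls(
            residue_log_enrichment=data["residue_log_enrichment"],
            position_weights=tuple(data["position_weights"]),
            masked_positions=frozenset(data["masked_positions"]),
            threshold=threshold,
            version=data["version"],
        )

    @property
    def effective_weights(self) -> tuple[float, ...]:
        return tuple(
            0.0 if (i + 1) in self.masked_positions else w
            for i, w in enumerate(self.position_weights)
        )


def immunogenicity_score(peptide: str, model: ImmunogenicityModel) -> float:
    """Σ_i w_i · e(peptide_i) over unmasked positions."""
    if len(peptide) != len(model.position_weights):
        raise ScoringError(
            f"peptide {peptide!r} length {len(peptide)} does not match the "
            f"model's {len(model.position_weights)} positions"
        )
    total = 0.0
    for residue, w in zip(peptide, model.effective_weights):
        try:
            e = model.residue_log_enrichment[residue]
        except KeyError:
            raise ScoringError(
                f"peptide {peptide!r} contains non-standard residue {residue!r}"
            ) from None
        total += w * e
    return total


def filter_by_immunogenicity(
    peptides: set[MismatchedPeptide], model: ImmunogenicityModel
) -> set[MismatchedPeptide]:
    """Keep peptides with score strictly greater than the model threshold."""
    return {
        p for p in peptides if immunogenicity_score(p.sequence, model) > model.threshold
    }


# ---------------------------------------------------------------------------
# Tissue-expression filter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionRecord:
    """One tissue-reliability annotation for a gene (optionally transcript)."""

    gene_id: str
    tissue: str
    reliability: str
    transcript_id: str | None = None


def read_expression_tsv(path) -> list[ExpressionRecord]:
    """Read an HPA-style expression reliability table
    (columns: gene, transcript, tissue, reliability)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    needed = {"gene", "tissue", "reliability"}
    if not needed <= set(df.columns):
        raise ScoringError(f"{path}: expected columns {sorted(needed)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            ExpressionRecord(
                gene_id=row["gene"],
                transcript_id=row.get("transcript") or None,
                tissue=row["tissue"],
                reliability=row["reliability"],
            )
        )
    return records


def filter_by_expression(
    peptides: set[MismatchedPeptide],
    table: list[ExpressionRecord],
    tissues: frozenset[str] = DEFAULT_TISSUES,
    required_reliability: str = DEFAULT_RELIABILITY,
) -> set[MismatchedPeptide]:
    """Keep peptides with at least one source gene/transcript annotated at
    the required reliability in at least one target tissue.

    Matching is at gene level, overridden by transcript-level records when
    any exist for a source transcript.  An empty expression table raises —
    absent data is not the same as no peptide passing.
    """
    if not table:
        raise ScoringError("empty expression table: cannot distinguish "
                           "missing data from a failed filter")
    tissues_lc = {t.lower() for t in tissues}
    rel_lc = required_reliability.lower()

    def passes(r: ExpressionRecord) -> bool:
        return r.reliability.lower() == rel_lc and r.tissue.lower() in tissues_lc

    by_transcript: dict[str, list[ExpressionRecord]] = {}
    by_gene: dict[str, list[ExpressionRecord]] = {}
    for r in table:
        if r.transcript_id:
            by_transcript.setdefault(r.transcript_id, []).append(r)
        by_gene.setdefault(r.gene_id, []).append(r)

    passing_transcripts = {t for t, rs in by_transcript.items() if any(map(passes, rs))}
    passing_genes = {g for g, rs in by_gene.items() if any(map(passes, rs))}

    kept = set()
    for p in peptides:
        ok = False
        for t in p.source_transcripts:
            if t in by_transcript:
                ok = ok or t in passing_transcripts
            else:
                ok = ok or any(g in passing_genes for g in p.source_genes)
        if ok:
            kept.add(p)
    return kept


# ---------------------------------------------------------------------------
# HLA typing and affinity prediction
# ---------------------------------------------------------------------------

HLA_LOCI = ("A", "B", "C", "DRB1", "DQB1", "DPB1")


@dataclass(frozen=True)
class HLATyping:
    """Two alleles (two-field resolution) at each of the six classical loci."""

    sample_id: str
    alleles: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        missing = set(HLA_LOCI) - set(self.alleles)
        if missing:
            raise ValueError(
                f"{self.sample_id}: typing incomplete, missing loci {sorted(missing)}"
            )

    def distinct_alleles(self, loci=HLA_LOCI) -> set[str]:
        out = set()
        for locus in loci:
            out.update(self.alleles[locus])
        return out

    def class_i_alleles(self) -> set[str]:
        return self.distinct_alleles(CLASS_I_LOCI)


def read_hla_typings(path) -> dict[str, HLATyping]:
    """Read a typing TSV: sample_id then <locus>_1/<locus>_2 columns."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    typings = {}
    for _, row in df.iterrows():
        alleles = {}
        for locus in HLA_LOCI:
            pair = tuple(
                normalize_allele(row[f"{locus}_{i}"]) for i in (1, 2)
            )
            if None in pair:
                raise ValueError(
                    f"{row['sample_id']}: unparseable allele at locus {locus}"
                )
            alleles[locus] = pair
        typings[row["sample_id"]] = HLATyping(row["sample_id"], alleles)
    return typings


def write_hla_typings(typings: dict[str, HLATyping], path) -> None:
    cols = ["sample_id"] + [f"{l}_{i}" for l in HLA_LOCI for i in (1, 2)]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for sid in sorted(typings):
            t = typings[sid]
            row = [sid]
            for locus in HLA_LOCI:
                row.extend(t.alleles[locus])
            fh.write("\t".join(row) + "\n")


@dataclass(frozen=True)
class AffinityConfig:
    """Consensus percentile-rank cutoff and loci used for prediction."""

    rank_cutoff: float = 4.0
    loci: tuple[str, ...] = ("A", "B")

    def __post_init__(self) -> None:
        if not (0 < self.rank_cutoff <= 100):
            raise ValueError("rank_cutoff must be in (0, 100]")


class AffinityPredictor(Protocol):
    """Contract for percentile-rank binding predictors."""

    def supported_alleles(self, alleles: set[str]) -> set[str]:
        """Subset of the requested alleles the predictor can score."""
        ...

    def predict(self, peptides: set[str], alleles: set[str]) -> dict[tuple[str, str], float]:
        """Percentile rank in (0, 100] for every (peptide, supported allele)."""
        ...


class PrecomputedRankTable:
    """Affinity predictor backed by a TSV of precomputed percentile ranks
    (columns: peptide, allele, percentile_rank)."""

    def __init__(self, path):
        df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "allele": str})
        needed = {"peptide", "allele", "percentile_rank"}
        if not needed <= set(df.columns):
            raise ScoringError(f"{path}: expected columns {sorted(needed)}")
        self._ranks: dict[tuple[str, str], float] = {}
        self._alleles: set[str] = set()
        for pep, allele, rank in zip(
            df["peptide"], df["allele"], df["percentile_rank"]
        ):
            norm_allele = normalize_allele(allele)
            if norm_allele is None:
                continue
            self._ranks[(str(pep), norm_allele)] = float(rank)
            self._alleles.add(norm_allele)

    def supported_alleles(self, alleles: set[str]) -> set[str]:
        return self._alleles & set(alleles)

    def predict(self, peptides, alleles):
        supported = self.supported_alleles(set(alleles))
        return {
            (p, a): self._ranks[(p, a)]
            for p in peptides
            for a in supported
            if (p, a) in self._ranks
        }


class ToyPSSMPredictor:
    """Deterministic position-specific scoring matrix predictor.

    Each allele gets a 9x20 matrix drawn from a generator seeded by a
    stable hash of (seed, allele); a peptide's percentile rank is the
    upper-tail normal probability of its standardised matrix score, so
    ranks fall in (0, 100] and lower means stronger predicted binding.
    This is a stand-in scoring model for tests and simulations, not a
    trained binding predictor.
    """

    def __init__(self, seed: int = 0, k: int = 9):
        self.seed = seed
        self.k = k

    def _matrix(self, allele: str) -> np.ndarray:
        digest = hashlib.sha256(f"{self.seed}:{allele}".encode()).digest()
        rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
        return rng.normal(size=(self.k, len(STANDARD_RESIDUES)))

    def supported_alleles(self, alleles: set[str]) -> set[str]:
        return {a for a in alleles if allele_locus(a) in ("A", "B", "C")}

    def predict(self, peptides, alleles):
        index = {aa: i for i, aa in enumerate(STANDARD_RESIDUES)}
        out: dict[tuple[str, str], float] = {}
        for allele in self.supported_alleles(set(alleles)):
            m = self._matrix(allele)
            for pep in peptides:
                if len(pep) != self.k or any(aa not in index for aa in pep):
                    continue
                score = sum(m[i, index[aa]] for i, aa in enumerate(pep))
                z = score / np.sqrt(self.k)
                out[(pep, allele)] = float(100.0 * norm.sf(z)) or 1e-9
        return out


def predict_percentile_ranks(
    peptides: set[str], alleles: set[str], predictor: AffinityPredictor
) -> tuple[dict[tuple[str, str], float], set[str]]:
    """Run the predictor; returns (rank map, unsupported alleles).

    Unsupported alleles are surfaced, never silently skipped.
    """
    supported = predictor.supported_alleles(set(alleles))
    unsupported = set(alleles) - supported
    if unsupported:
        logger.warning("predictor does not support alleles: %s", sorted(unsupported))
    ranks = predictor.predict(set(peptides), supported)
    for (pep, allele), r in ranks.items():
        if not (0 < r <= 100):
            raise ScoringError(
                f"rank {r} for ({pep}, {allele}) outside (0, 100]"
            )
    return ranks, unsupported


def count_high_affinity(
    rank_map: dict[tuple[str, str], float],
    recipient: HLATyping,
    config: AffinityConfig = AffinityConfig(),
) -> int:
    """Distinct peptides with rank <= cutoff for >=1 recipient allele at the
    configured loci (HLA-A and -B by default)."""
    alleles = recipient.distinct_alleles(config.loci)
    peptides = {
        pep
        for (pep, allele), rank in rank_map.items()
        if allele in alleles and rank <= config.rank_cutoff
    }
    return len(peptides)


# ---------------------------------------------------------------------------
# Per-pair method counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MismatchEstimate:
    """Per-pair alloreactivity estimates M1-M4 and the underlying totals.

    The filter-dependent fields (m2, m4, total_filtered) are None when no
    expression table was available, so the filter-free methods M1/M3 can
    still be produced and the filtered methods fail downstream with an
    explicit error instead of a silent zero.
    """

    pair_id: str
    m1: int
    m2: int | None
    m3: int
    m4: int | None
    total_mismatched: int
    total_filtered: int | None

    def __post_init__(self) -> None:
        values = [self.m1, self.m2, self.m3, self.m4,
                  self.total_mismatched, self.total_filtered]
        if min(v for v in values if v is not None) < 0:
            raise ValueError("counts must be >= 0")
        if self.m2 is not None and self.m2 > self.m1:
            raise ValueError(f"{self.pair_id}: m2 exceeds m1")
        if (self.total_filtered is not None
                and self.total_filtered > self.total_mismatched):
            raise ValueError(f"{self.pair_id}: inconsistent subset counts")


def compute_method_counts(
    pair_id: str,
    peptides: set[MismatchedPeptide],
    *,
    recipient_typing: HLATyping,
    iedb: LigandDatabase,
    mha: LigandDatabase,
    immunogenicity: ImmunogenicityModel,
    expression: list[ExpressionRecord],
    predictor: AffinityPredictor,
    affinity: AffinityConfig = AffinityConfig(),
    restrict_to_recipient_hla: bool = True,
) -> MismatchEstimate:
    """Compute M1-M4 for one donor-recipient pair.

    Ligand databases are pooled over the recipient's own class I alleles
    before intersecting (allele-aware matching); with
    ``restrict_to_recipient_hla=False`` the whole database is pooled
    instead.

    Without an expression table (``expression`` empty) the filter-free
    estimates M1/M3 are still computed and the filter-dependent fields are
    returned as None.
    """
    if recipient_typing is None:
        raise ScoringError(f"{pair_id}: recipient HLA typing missing")

    u_seqs = {p.sequence for p in peptides}
    if expression:
        filtered = filter_by_expression(
            filter_by_immunogenicity(peptides, immunogenicity), expression
        )
        f_seqs = {p.sequence for p in filtered}
    else:
        logger.warning(
            "%s: no expression table; filtered estimates M2/M4 unavailable",
            pair_id,
        )
        f_seqs = None

    if restrict_to_recipient_hla:
        iedb_pool = iedb.pooled(recipient_typing.class_i_alleles())
        mha_pool = mha.pooled(recipient_typing.class_i_alleles())
    else:
        iedb_pool = iedb.pooled(iedb.alleles)
        mha_pool = mha.pooled(mha.alleles)

    if f_seqs is not None:
        prediction_alleles = recipient_typing.distinct_alleles(affinity.loci)
        rank_map, _ = predict_percentile_ranks(f_seqs, prediction_alleles, predictor)
        m2 = len(f_seqs & iedb_pool)
        m4 = count_high_affinity(rank_map, recipient_typing, affinity)
        total_filtered = len(f_seqs)
    else:
        m2 = m4 = total_filtered = None

    return MismatchEstimate(
        pair_id=pair_id,
        m1=len(u_seqs & iedb_pool),
        m2=m2,
        m3=len(u_seqs & mha_pool),
        m4=m4,
        total_mismatched=len(u_seqs),
        total_filtered=total_filtered,
    )


def write_estimates_tsv(estimates: list[MismatchEstimate], path) -> None:
    cols = ["pair_id", "m1", "m2", "m3", "m4", "total_mismatched", "total_filtered"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for e in sorted(estimates, key=lambda e: e.pair_id):
            fh.write(
                "\t".join(
                    "NA" if getattr(e, c) is None else str(getattr(e, c))
                    for c in cols
                )
                + "\n"
            )


def read_estimates_tsv(path) -> list[MismatchEstimate]:
    df = pd.read_csv(path, sep="\t", dtype={"pair_id": str}, na_values=["NA"])

    def _opt(v):
        return None if pd.isna(v) else int(v)

    return [
        MismatchEstimate(
            pair_id=row.pair_id,
            m1=int(row.m1), m2=_opt(row.m2), m3=int(row.m3), m4=_opt(row.m4),
            total_mismatched=int(row.total_mismatched),
            total_filtered=_opt(row.total_filtered),
        )
        for row in df.itertuples()
    ]
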