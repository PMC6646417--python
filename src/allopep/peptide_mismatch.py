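"""Recipient-unique 9-mer extraction.

Donor and recipient in-silico proteomes are compared transcript by
transcript; transcripts whose protein sets differ are split into 9-mer
peptides by a sliding window, and the peptides present in the recipient
but absent from the donor form the candidate alloantigen set.  Each
peptide keeps provenance (source transcripts and genes) so downstream
tissue-expression filtering can map it back to the genome annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .proteome_builder import IndividualProteome

logger = logging.getLogger(__name__)


class MismatchError(ValueError):
    """Proteomes not comparable (different reference)."""


@dataclass(frozen=True)
class PeptideConfig:
    """Peptide window length in residues (class I ligands: 9)."""

    k: int = 9

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("peptide length k must be >= 1")


@dataclass(frozen=True)
class MismatchedPeptide:
    """A recipient-unique peptide with its source transcripts and genes."""

    sequence: str
    source_transcripts: frozenset[str]
    source_genes: frozenset[str]


def extract_nine_mers(protein: str, config: PeptideConfig = PeptideConfig()) -> set[str]:
    """All length-k substrings (step-1 sliding window), deduplicated.

    Windows containing X (unknown residue) are dropped: a peptide of
    undetermined sequence cannot be matched against ligand databases.
    """
    k = config.k
    return {
        protein[i : i + k]
        for i in range(len(protein) - k + 1)
        if "X" not in protein[i : i + k]
    }


def differing_transcripts(
    donor: IndividualProteome, recipient: IndividualProteome
) -> set[str]:
    """Transcripts whose protein sets differ between donor and recipient."""
    if donor.proteins.keys() != recipient.proteins.keys():
        only = donor.proteins.keys() ^ recipient.proteins.keys()
        raise MismatchError(
            "donor and recipient proteomes cover different transcripts "
            f"(must share a reference); unmatched: {sorted(only)[:5]}"
        )
    return {
        t
        for t in donor.proteins
        if donor.proteins[t] != recipient.proteins[t]
    }


def _peptides_with_provenance(
    proteome: IndividualProteome, transcripts: set[str], config: PeptideConfig
) -> dict[str, set[str]]:
    """Map peptide -> set of source transcript ids, over the given transcripts."""
    out: dict[str, set[str]] = {}
    for t in transcripts:
        for protein in proteome.proteins[t]:
            for pep in extract_nine_mers(protein, config):
                out.setdefault(pep, set()).add(t)
    return out


def recipient_unique_peptides(
    donor: IndividualProteome,
    recipient: IndividualProteome,
    config: PeptideConfig = PeptideConfig(),
    *,
    strict_donor_subtraction: bool = False,
) -> set[MismatchedPeptide]:
    """Peptides present in the recipient but not the donor.

    Identical proteins are excluded first; the differing transcripts are
    split into k-mers; the donor's k-mer union D is subtracted from the
    recipient's union R.  By default D is built from the differing
    transcripts only (matching the order exclude-split-subtract); with
    ``strict_donor_subtraction`` D is the donor's whole-proteome k-mer
    union, which additionally removes recipient peptides that happen to
    occur elsewhere in the donor proteome.
    """
    diff = differing_transcripts(donor, recipient)
    recip = _peptides_with_provenance(recipient, diff, config)
    donor_transcripts = set(donor.proteins) if strict_donor_subtraction else diff
    donor_peps: set[str] = set()
    for t in donor_transcripts:
        for protein in donor.proteins[t]:
            donor_peps |= extract_nine_mers(protein, config)

    result = set()
    for pep, transcripts in recip.items():
        if pep in donor_peps:
            continue
        result.add(
            MismatchedPeptide(
                sequence=pep,
                source_transcripts=frozenset(transcripts),
                source_genes=frozenset(
                    recipient.genes[t] for t in transcripts
                ),
            )
        )
    logger.info(
        "pair %s/%s: %d differing transcripts, %d recipient-unique peptides",
        donor.sample_id, recipient.sample_id, len(diff), len(result),
    )
    return result


def write_peptides_tsv(peptides: set[MismatchedPeptide], path) -> None:
    """TSV export: peptide, comma-joined source transcripts and genes."""
    with open(path, "w") as fh:
        fh.write("peptide\tsource_transcripts\tsource_genes\n")
        for p in sorted(peptides, key=lambda p: p.sequence):
            fh.write(
                f"{p.sequence}\t{','.join(sorted(p.source_transcripts))}\t"
                f"{','.join(sorted(p.source_genes))}\n"
            )


def read_peptides_tsv(path) -> set[MismatchedPeptide]:
    out = set()
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("peptide"):
            raise MismatchError(f"unexpected peptide TSV header in {path}")
        for line in fh:
            seq, transcripts, genes = line.rstrip("\n").split("\t")
            out.add(
                MismatchedPeptide(
                    sequence=seq,
                    source_transcripts=frozenset(transcripts.split(",")),
                    source_genes=frozenset(genes.split(",")),
                )
            )
    return out
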