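"""Per-individual in-silico proteome construction.

Each subject's quality-filtered non-synonymous variants are applied to the
reference coding sequences and translated, yielding one or two protein
sequences per transcript.

Genotype phase is unknown, so two deterministic pseudo-haplotypes are
built per transcript:

* H1 carries the alternate alleles of homozygous-alt variants only;
* H2 carries the alternate alleles of every non-missing carried variant
  (homozygous and heterozygous alike).

This needs no phasing, and guarantees that whenever any heterozygous
variant exists the reference-allele product (up to homozygous edits)
survives on H1.  With no heterozygous variant the two haplotypes
coincide and the protein set has size 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio.Seq import Seq

from .reference_and_variants import AnnotatedVariant, CodingTranscript

logger = logging.getLogger(__name__)


class ProteomeError(ValueError):
    """Inconsistent variant/reference combination."""


@dataclass(frozen=True)
class IndividualProteome:
    """Per-subject protein sequences, keyed by transcript.

    ``proteins`` maps transcript_id -> frozenset of amino-acid strings
    (standard 20-letter alphabet plus X for residues derived from N bases).
    """

    sample_id: str
    proteins: dict[str, frozenset[str]]
    genes: dict[str, str]  # transcript_id -> gene_id


def apply_variants_to_cds(
    transcript: CodingTranscript, variants: list[AnnotatedVariant]
) -> str:
    """Apply one haplotype's variants to the reference CDS.

    Variants are applied in descending CDS position so that earlier
    coordinates stay valid after indels.  Reference alleles must match the
    CDS and no two variants may overlap.
    """
    ordered = sorted(variants, key=lambda v: v.cds_pos, reverse=True)
    for earlier, later in zip(ordered[1:], ordered):
        if earlier.end_pos >= later.cds_pos:
            raise ProteomeError(
                f"{transcript.transcript_id}: overlapping variants at CDS "
                f"positions {earlier.cds_pos} and {later.cds_pos}"
            )
    cds = transcript.cds
    for v in ordered:
        start = v.cds_pos - 1
        end = start + len(v.ref_allele)
        if end > len(cds):
            raise ProteomeError(
                f"{transcript.transcript_id}:{v.cds_pos}: reference allele "
                f"extends past the CDS end"
            )
        observed = transcript.cds[start:end]
        if observed != v.ref_allele:
            raise ProteomeError(
                f"{transcript.transcript_id}:{v.cds_pos}: reference allele "
                f"mismatch (CDS has {observed!r}, variant says {v.ref_allele!r})"
            )
        cds = cds[:start] + v.alt_allele + cds[end:]
    return cds


def translate_cds(cds: str) -> str:
    """Translate from position 1 with the standard genetic code.

    Translation stops at the first stop codon (excluded from the output);
    a trailing incomplete codon is dropped; codons containing N yield X.
    """
    trimmed = cds[: len(cds) - len(cds) % 3]
    if not trimmed:
        return ""
    return str(Seq(trimmed).translate(to_stop=True))


def _haplotype_variants(
    variants: list[AnnotatedVariant], sample_id: str
) -> tuple[list[AnnotatedVariant], list[AnnotatedVariant]]:
    h1, h2 = [], []
    for v in variants:
        g = v.genotypes.get(sample_id)
        if g is None or g.missing or g.dosage == 0:
            continue
        if g.dosage == 2:
            h1.append(v)
        h2.append(v)
    return h1, h2


def build_individual_proteome(
    sample_id: str,
    reference: dict[str, CodingTranscript],
    variants: list[AnnotatedVariant],
) -> IndividualProteome:
    """Build the subject's protein set over every reference transcript.

    Transcripts with no carried variant yield the reference protein only;
    the H1/H2 products are deduplicated per transcript.
    """
    by_transcript: dict[str, list[AnnotatedVariant]] = {}
    for v in variants:
        if v.transcript_id not in reference:
            raise ProteomeError(
                f"variant references unknown transcript {v.transcript_id!r}"
            )
        by_transcript.setdefault(v.transcript_id, []).append(v)

    proteins: dict[str, frozenset[str]] = {}
    genes: dict[str, str] = {}
    for transcript_id, transcript in reference.items():
        genes[transcript_id] = transcript.gene_id
        carried = by_transcript.get(transcript_id, [])
        h1, h2 = _haplotype_variants(carried, sample_id)
        if not h2:  # no carried variant at all
            proteins[transcript_id] = frozenset({translate_cds(transcript.cds)})
            continue
        seqs = {
            translate_cds(apply_variants_to_cds(transcript, h1)),
            translate_cds(apply_variants_to_cds(transcript, h2)),
        }
        proteins[transcript_id] = frozenset(seqs)
    return IndividualProteome(sample_id=sample_id, proteins=proteins, genes=genes)


def write_proteome_fasta(proteome: IndividualProteome, path) -> None:
    """Debug export; header: sample|transcript|index within the protein set."""
    with open(path, "w") as fh:
        for transcript_id in sorted(proteome.proteins):
            for i, seq in enumerate(sorted(proteome.proteins[transcript_id])):
                gene = proteome.genes.get(transcript_id, transcript_id)
                fh.write(
                    f">{proteome.sample_id}|{transcript_id}|{i} gene:{gene}\n"
                )
                fh.write(seq + "\n")


def read_proteome_fasta(path) -> IndividualProteome:
    """Read a proteome written by :func:`write_proteome_fasta`."""
    from Bio import SeqIO

    proteins: dict[str, set[str]] = {}
    genes: dict[str, str] = {}
    sample_id = None
    for record in SeqIO.parse(str(path), "fasta"):
        sample, transcript_id, _ = record.id.split("|")
        if sample_id is None:
            sample_id = sample
        elif sample != sample_id:
            raise ProteomeError(f"mixed samples in proteome FASTA {path}")
        for token in record.description.split():
            if token.startswith("gene:"):
                genes[transcript_id] = token[5:]
        proteins.setdefault(transcript_id, set()).add(str(record.seq))
    if sample_id is None:
        raise ProteomeError(f"empty proteome FASTA {path}")
    return IndividualProteome(
        sample_id=sample_id,
        proteins={k: frozenset(v) for k, v in proteins.items()},
        genes=genes,
    )
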