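"""Coding-sequence reference and annotated-variant input.

Reads an Ensembl-style CDS FASTA and per-pair annotated VCFs into
transcript-space variant calls, and applies the hard genotype-quality
filter (read depth DP and genotype quality GQ) and the non-synonymous
effect whitelist that gate all downstream proteome construction.

Variant records are expected to carry a pipe-delimited consequence
annotation in the INFO field (key ``PCSQ`` by default)::

    PCSQ=transcript_id|effect|cds_pos|cds_ref|cds_alt[,...]

with one comma-separated entry per affected transcript.  ``cds_pos`` is
the 1-based position of ``cds_ref`` in the transcript's coding sequence
(VCF-style left-anchored representation for indels).  A mapping from
snpEff ``ANN`` / VEP ``CSQ`` fields to this dialect is documented in
``docs/methods.md``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pysam
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Effect classes accepted as non-synonymous protein-altering events.
ALLOWED_EFFECTS = frozenset(
    {"missense", "insertion", "deletion", "frameshift", "stop_gained"}
)

#: Nucleotide alphabet accepted in reference coding sequences.
CDS_ALPHABET = frozenset("ACGTN")

#: Default INFO key carrying the transcript-level consequence annotation.
ANNOTATION_KEY = "PCSQ"

DEFAULT_MIN_CDS_LEN = 50
DEFAULT_DP_MIN = 15
DEFAULT_GQ_MIN = 20


class ReferenceError(ValueError):
    """Malformed or inconsistent coding-sequence reference."""


class VariantError(ValueError):
    """Malformed variant input or sample mismatch."""


@dataclass(frozen=True)
class CodingTranscript:
    """A single protein-coding transcript's CDS."""

    transcript_id: str
    gene_id: str
    cds: str

    def __post_init__(self) -> None:
        bad = set(self.cds) - CDS_ALPHABET
        if bad:
            raise ReferenceError(
                f"{self.transcript_id}: CDS contains non-ACGTN characters {sorted(bad)}"
            )


@dataclass(frozen=True)
class QualityThresholds:
    """Hard genotype-level cutoffs on read depth and genotype quality."""

    dp_min: int = DEFAULT_DP_MIN
    gq_min: int = DEFAULT_GQ_MIN

    def __post_init__(self) -> None:
        if self.dp_min < 0 or self.gq_min < 0:
            raise ValueError("quality thresholds must be >= 0")


@dataclass(frozen=True)
class Genotype:
    """Per-sample call for one variant: alt-allele dosage plus QC fields."""

    dosage: int  # 0, 1 or 2 alt alleles
    dp: int | None
    gq: int | None
    missing: bool = False


@dataclass(frozen=True)
class AnnotatedVariant:
    """One coding variant in transcript space with per-sample genotypes."""

    transcript_id: str
    cds_pos: int  # 1-based position in the CDS
    ref_allele: str
    alt_allele: str
    effect_class: str
    genotypes: dict[str, Genotype] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.cds_pos < 1:
            raise VariantError(f"{self.transcript_id}: cds_pos must be >= 1")
        if self.effect_class not in ALLOWED_EFFECTS:
            raise VariantError(
                f"{self.transcript_id}:{self.cds_pos}: effect class "
                f"{self.effect_class!r} not in {sorted(ALLOWED_EFFECTS)}"
            )

    @property
    def end_pos(self) -> int:
        """Last CDS position covered by the reference allele (inclusive)."""
        return self.cds_pos + len(self.ref_allele) - 1


def _parse_fasta_header(record) -> tuple[str, str]:
    """Ensembl CDS header: first token is the transcript id; a 'gene:<id>'
    token supplies the gene id when present (falls back to transcript id)."""
    transcript_id = record.id
    gene_id = transcript_id
    for token in record.description.split():
        if token.startswith("gene:"):
            gene_id = token[len("gene:"):]
            break
    return transcript_id, gene_id


def read_cds_fasta(
    path,
    *,
    min_cds_len: int = DEFAULT_MIN_CDS_LEN,
    require_atg: bool = True,
) -> dict[str, CodingTranscript]:
    """Read a CDS FASTA, keeping records that start with the canonical ATG
    and are at least ``min_cds_len`` nucleotides long.

    Returns a mapping transcript_id -> :class:`CodingTranscript`.  Raises
    :class:`ReferenceError` on duplicate transcript ids.
    """
    kept: dict[str, CodingTranscript] = {}
    n_seen = 0
    for record in SeqIO.parse(str(path), "fasta"):
        n_seen += 1
        transcript_id, gene_id = _parse_fasta_header(record)
        if transcript_id in kept:
            raise ReferenceError(f"duplicate transcript id {transcript_id!r}")
        cds = str(record.seq).upper()
        if require_atg and not cds.startswith("ATG"):
            continue
        if len(cds) < min_cds_len:
            continue
        kept[transcript_id] = CodingTranscript(transcript_id, gene_id, cds)
    if n_seen == 0:
        logger.warning("no FASTA records found in %s", path)
    logger.info(
        "CDS reference %s: kept %d / %d records", path, len(kept), n_seen
    )
    return kept


def write_cds_fasta(transcripts, path) -> None:
    """Write transcripts back out in the Ensembl-style header dialect."""
    items = sorted(transcripts.values(), key=lambda t: t.transcript_id)
    with open(path, "w") as fh:
        for t in items:
            fh.write(f">{t.transcript_id} cds gene:{t.gene_id}\n")
            for i in range(0, len(t.cds), 60):
                fh.write(t.cds[i : i + 60] + "\n")


def _parse_annotation(value: str) -> list[tuple[str, str, int, str, str]]:
    entries = []
    for chunk in value.split(","):
        parts = chunk.split("|")
        if len(parts) != 5:
            raise VariantError(f"malformed consequence entry {chunk!r}")
        transcript_id, effect, pos, ref, alt = parts
        entries.append((transcript_id, effect, int(pos), ref.upper(), alt.upper()))
    return entries


def read_annotated_vcf(
    path,
    samples: list[str],
    *,
    annotation_key: str = ANNOTATION_KEY,
) -> list[AnnotatedVariant]:
    """Read an annotated VCF into per-transcript :class:`AnnotatedVariant`.

    One variant is emitted per (record, transcript annotation); entries whose
    effect class is outside the non-synonymous whitelist are dropped, and
    records lacking the annotation field are skipped with a warning.
    """
    variants: list[AnnotatedVariant] = []
    n_dropped_effect = 0
    with pysam.VariantFile(str(path)) as vcf:
        header_samples = list(vcf.header.samples)
        for sample in samples:
            if sample not in header_samples:
                raise VariantError(
                    f"sample {sample!r} absent from VCF header of {path} "
                    f"(has {header_samples})"
                )
        for rec in vcf:
            ann = rec.info.get(annotation_key)
            if ann is None:
                logger.warning(
                    "%s:%s lacks %s annotation; record skipped",
                    rec.chrom, rec.pos, annotation_key,
                )
                continue
            if isinstance(ann, tuple):
                ann = ",".join(ann)
            genotypes = {}
            for sample in samples:
                call = rec.samples[sample]
                alleles = call.get("GT") or (None, None)
                if any(a is None for a in alleles):
                    genotypes[sample] = Genotype(0, None, None, missing=True)
                else:
                    dosage = sum(1 for a in alleles if a and a > 0)
                    genotypes[sample] = Genotype(
                        dosage, call.get("DP"), call.get("GQ")
                    )
            for transcript_id, effect, pos, ref, alt in _parse_annotation(ann):
                if effect not in ALLOWED_EFFECTS:
                    n_dropped_effect += 1
                    continue
                variants.append(
                    AnnotatedVariant(
                        transcript_id=transcript_id,
                        cds_pos=pos,
                        ref_allele=ref,
                        alt_allele=alt,
                        effect_class=effect,
                        genotypes=genotypes,
                    )
                )
    logger.info(
        "VCF %s: %d coding variants kept, %d annotations outside the "
        "non-synonymous whitelist dropped", path, len(variants), n_dropped_effect,
    )
    return variants


def _fails(g: Genotype, thresholds: QualityThresholds) -> bool:
    if g.missing:
        return True
    if g.dp is None or g.dp < thresholds.dp_min:
        return True
    if g.gq is None or g.gq < thresholds.gq_min:
        return True
    return False


def genotype_quality_filter(
    variants: list[AnnotatedVariant], thresholds: QualityThresholds
) -> list[AnnotatedVariant]:
    """Set genotypes failing the DP/GQ hard cutoff to missing; drop variants
    whose genotypes are all missing.  Missing DP or GQ counts as failing."""
    out: list[AnnotatedVariant] = []
    for v in variants:
        genotypes = {
            s: replace(g, missing=True) if _fails(g, thresholds) else g
            for s, g in v.genotypes.items()
        }
        if all(g.missing for g in genotypes.values()):
            continue
        out.append(replace(v, genotypes=genotypes))
    return out


def select_nonsynonymous(variants) -> list[AnnotatedVariant]:
    """Explicit whitelist gate for adapters that loosen the effect-class type.

    :class:`AnnotatedVariant` already enforces the whitelist, so for inputs
    built through this module the call is the identity; loosely-typed records
    (e.g. plain objects from another reader) with an unknown ``effect_class``
    are dropped with a warning.
    """
    out = []
    for v in variants:
        if v.effect_class in ALLOWED_EFFECTS:
            out.append(v)
        else:
            logger.warning(
                "dropping variant %s:%s with unknown effect %r",
                v.transcript_id, v.cds_pos, v.effect_class,
            )
    return out
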