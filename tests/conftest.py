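"""Shared fixtures: tiny hand-built references, VCF writers and typings."""

from __future__ import annotations

import textwrap

import pytest

from allopep.reference_and_variants import (
    AnnotatedVariant,
    CodingTranscript,
    Genotype,
)
from allopep.alloreactivity_scoring import HLA_LOCI, HLATyping


def make_variant(
    transcript_id="T1",
    cds_pos=5,
    ref="C",
    alt="A",
    effect="missense",
    genotypes=None,
):
    return AnnotatedVariant(
        transcript_id=transcript_id,
        cds_pos=cds_pos,
        ref_allele=ref,
        alt_allele=alt,
        effect_class=effect,
        genotypes=genotypes or {},
    )


def gt(dosage, dp=40, gq=90, missing=False):
    return Genotype(dosage, dp, gq, missing)


def make_typing(sample_id="S1", **overrides) -> HLATyping:
    base = {
        "A": ("A*01:01", "A*02:01"),
        "B": ("B*07:02", "B*08:01"),
        "C": ("C*04:01", "C*07:01"),
        "DRB1": ("DRB1*01:01", "DRB1*03:01"),
        "DQB1": ("DQB1*02:01", "DQB1*06:02"),
        "DPB1": ("DPB1*04:01", "DPB1*02:01"),
    }
    base.update(overrides)
    assert set(base) == set(HLA_LOCI)
    return HLATyping(sample_id, base)


def write_vcf(path, records, samples=("D1", "R1")):
    """Write a minimal two-sample VCF; records are dicts with keys
    chrom, pos, ref, alt, info, and per-sample GT:DP:GQ strings."""
    contigs = sorted({r["chrom"] for r in records})
    header = textwrap.dedent(
        """\
        ##fileformat=VCFv4.2
        ##INFO=<ID=PCSQ,Number=.,Type=String,Description="consequence">
        ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
        ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
        ##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Quality">
        """
    )
    with open(path, "w") as fh:
        fh.write(header)
        for c in contigs:
            fh.write(f"##contig=<ID={c},length=10000>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for r in records:
            calls = "\t".join(r["calls"])
            fh.write(
                f"{r['chrom']}\t{r['pos']}\t.\t{r['ref']}\t{r['alt']}\t.\t"
                f"PASS\t{r.get('info', '.')}\tGT:DP:GQ\t{calls}\n"
            )
    return path


@pytest.fixture
def tiny_reference() -> dict[str, CodingTranscript]:
    # T1: MAIW*, T2: MKLE*
    return {
        "T1": CodingTranscript("T1", "G1", "ATGGCTATTTGGTAA"),
        "T2": CodingTranscript("T2", "G2", "ATGAAACTGGAGTAA"),
    }
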