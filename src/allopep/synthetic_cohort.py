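"""Synthetic transplant-cohort generator.

Emits a complete synthetic study — coding-sequence reference, paired
donor/recipient annotated VCFs, HLA typings, ligand/mHA/expression/rank
tables, and clinical outcomes drawn from a known logistic model — in
exactly the file formats the pipeline consumes.  Because the generating
truth (variant rates, ligand-overlap fractions, effect sizes) is known,
every pipeline stage and the association suite can be validated end to
end without access to patient data.

Each generator stage draws from its own child random stream, so changing
one configuration knob perturbs only that stage's output.  Two runs with
the same configuration and seed produce byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .reference_and_variants import (
    CodingTranscript,
    write_cds_fasta,
)
from .proteome_builder import translate_cds
from .peptide_mismatch import MismatchedPeptide
from .alloreactivity_scoring import (
    HLA_LOCI,
    STANDARD_RESIDUES,
    HLATyping,
    write_hla_typings,
)
from .association import PairCovariates, OutcomeRecord, write_outcomes_tsv

logger = logging.getLogger(__name__)

_STOPS = {"TAA", "TAG", "TGA"}
_NON_STOP_CODONS = sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
)

#: Built-in HLA allele pool with population frequencies per locus.  Alleles
#: are synthetic labels in realistic nomenclature; frequencies sum to 1.
DEFAULT_ALLELE_POOL: dict[str, list[tuple[str, float]]] = {
    "A": [("A*01:01", 0.30), ("A*02:01", 0.35), ("A*03:01", 0.20), ("A*24:02", 0.15)],
    "B": [("B*07:02", 0.30), ("B*08:01", 0.25), ("B*15:01", 0.25), ("B*27:05", 0.20)],
    "C": [("C*04:01", 0.35), ("C*07:01", 0.35), ("C*03:04", 0.30)],
    "DRB1": [("DRB1*01:01", 0.40), ("DRB1*03:01", 0.35), ("DRB1*15:01", 0.25)],
    "DQB1": [("DQB1*02:01", 0.45), ("DQB1*06:02", 0.30), ("DQB1*03:01", 0.25)],
    "DPB1": [("DPB1*04:01", 0.55), ("DPB1*02:01", 0.45)],
}

DEFAULT_EFFECT_WEIGHTS = {
    "missense": 0.82,
    "insertion": 0.05,
    "deletion": 0.05,
    "frameshift": 0.05,
    "stop_gained": 0.03,
}

DEFAULT_TISSUE_CYCLE = ("skin", "intestine", "lung", "liver", "bone marrow")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the scale and structure of an HLA-matched sibling
    transplant cohort: 157 pairs, mostly HLA-identical, cGvHD grades
    split roughly half "no", one sixth "limited", one third "extensive",
    and a positive ligand-count effect of 0.6 log-odds per SD.
    """

    n_pairs: int = 157
    n_transcripts: int = 40
    cds_length_range: tuple[int, int] = (300, 720)  # nucleotides, incl. stop
    per_transcript_variant_rate: float = 0.6
    shared_variant_fraction: float = 0.85  # siblings share most variants
    het_fraction: float = 0.67
    low_quality_fraction: float = 0.02
    effect_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_WEIGHTS)
    )
    allele_pool: dict[str, list[tuple[str, float]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_ALLELE_POOL.items()}
    )
    hla_mismatch_fraction: float = 0.06  # pairs not fully 12/12 matched
    ligand_db_size: int = 150  # decoy peptides per allele (IEDB-like table)
    mha_db_size: int = 8  # decoy mHA peptides per class I allele
    planted_overlap: float = 0.25  # recipient-unique peptides planted in IEDB table
    mha_planted_overlap: float = 0.03
    expression_supportive_fraction: float = 0.7
    rank_distribution: tuple[float, float] = (0.0, 100.0)  # uniform bounds
    effect_on: str = "m1"
    effect_beta: float = 0.6  # log-odds per SD of the ligand count
    covariate_betas: dict[str, float] = field(
        default_factory=lambda: {
            "donor_age": 0.3,
            "f_to_m": -0.8,
            "hla_freq_sum": -0.4,
            "n_unique_hla": 0.15,
            "tr_year": 0.1,
            "hla_match_count": 0.25,
        }
    )
    intercept: float = -0.5
    limited_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")
        for name in ("shared_variant_fraction", "planted_overlap",
                     "mha_planted_overlap", "limited_fraction",
                     "expression_supportive_fraction", "het_fraction",
                     "low_quality_fraction", "hla_mismatch_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        for locus, pool in self.allele_pool.items():
            if sum(f for _, f in pool) > 1 + 1e-9:
                raise ValueError(f"allele frequencies at {locus} sum above 1")


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(5)
    names = ("reference", "variants", "typings", "resources", "outcomes")
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def pair_sample_ids(pair_id: str) -> tuple[str, str]:
    """(donor sample id, recipient sample id) for a pair."""
    return f"{pair_id}-D", f"{pair_id}-R"


# ---------------------------------------------------------------------------
# Reference
# ---------------------------------------------------------------------------

def generate_reference(
    config: SimulationConfig, rng: np.random.Generator
) -> dict[str, CodingTranscript]:
    """ATG-initiated CDSs of in-range length divisible by 3, with a terminal
    stop codon and no internal stop (codons drawn uniformly from the 61
    non-stop codons)."""
    transcripts: dict[str, CodingTranscript] = {}
    lo, hi = config.cds_length_range
    for i in range(config.n_transcripts):
        n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
        n_internal = max(n_codons - 2, 0)  # minus start and stop
        body = "".join(
            _NON_STOP_CODONS[j]
            for j in rng.integers(0, len(_NON_STOP_CODONS), size=n_internal)
        )
        cds = "ATG" + body + "TAA"
        tid = f"ENST{i:08d}"
        transcripts[tid] = CodingTranscript(tid, f"ENSG{i:08d}", cds)
    return transcripts


# ---------------------------------------------------------------------------
# Variants and VCF emission
# ---------------------------------------------------------------------------

@dataclass
class _SimVariant:
    transcript_id: str
    cds_pos: int
    ref: str
    alt: str
    effect: str
    donor_dosage: int
    recipient_dosage: int
    donor_dp: int
    donor_gq: int
    recipient_dp: int
    recipient_gq: int


def _mutate_codon_base(cds: str, pos: int, rng) -> tuple[str, str]:
    """Substitution at 1-based pos that changes the encoded residue when a
    base choice allows it."""
    ref = cds[pos - 1]
    codon_start = (pos - 1) // 3 * 3
    codon = cds[codon_start : codon_start + 3]
    offset = (pos - 1) % 3
    choices = [b for b in "ACGT" if b != ref]
    rng.shuffle(choices)
    for alt in choices:
        new_codon = codon[:offset] + alt + codon[offset + 1 :]
        if new_codon in _STOPS:
            continue
        if translate_cds(new_codon) != translate_cds(codon):
            return ref, alt
    return ref, choices[0]


def _draw_variant(transcript: CodingTranscript, pos: int, effect: str, rng) -> tuple[int, str, str]:
    """(cds_pos, ref, alt) realising the requested effect class at ~pos."""
    cds = transcript.cds
    if effect == "missense":
        ref, alt = _mutate_codon_base(cds, pos, rng)
        return pos, ref, alt
    if effect == "insertion":  # in-frame
        ins = "".join(rng.choice(list("ACGT"), size=3))
        return pos, cds[pos - 1], cds[pos - 1] + ins
    if effect == "frameshift":
        ins = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 3))))
        return pos, cds[pos - 1], cds[pos - 1] + ins
    if effect == "deletion":  # in-frame deletion of one codon
        if pos + 3 > len(cds) - 3:
            pos = len(cds) - 7
        return pos, cds[pos - 1 : pos + 3], cds[pos - 1]
    if effect == "stop_gained":
        codon_start = ((pos - 1) // 3) * 3 + 1  # 1-based codon start
        return codon_start, cds[codon_start - 1 : codon_start + 2], "TAA"
    raise ValueError(f"unknown effect {effect!r}")


def _qc_values(config: SimulationConfig, rng) -> tuple[int, int]:
    if rng.random() < config.low_quality_fraction:
        return int(rng.integers(0, 10)), int(rng.integers(0, 15))
    return int(40 + rng.integers(-10, 20)), int(rng.integers(60, 100))


def generate_pair_variants(
    reference: dict[str, CodingTranscript],
    config: SimulationConfig,
    rng: np.random.Generator,
    n_pairs: int | None = None,
) -> dict[str, list[_SimVariant]]:
    """Per pair, Poisson-many variants per transcript; a variant is shared
    donor/recipient (identical genotype) with probability
    ``shared_variant_fraction``, else private to one subject."""
    n_pairs = config.n_pairs if n_pairs is None else n_pairs
    effects = sorted(config.effect_weights)
    weights = np.array([config.effect_weights[e] for e in effects], dtype=float)
    weights /= weights.sum()
    out: dict[str, list[_SimVariant]] = {}
    for p in range(n_pairs):
        pair_id = f"P{p:03d}"
        variants: list[_SimVariant] = []
        for tid in sorted(reference):
            transcript = reference[tid]
            n = int(rng.poisson(config.per_transcript_variant_rate))
            if n == 0:
                continue
            # keep variants >= 8 bases apart so ref alleles never overlap
            usable = np.arange(5, len(transcript.cds) - 8)
            chosen: list[int] = []
            for pos in rng.permutation(usable):
                if len(chosen) == n:
                    break
                if all(abs(pos - c) >= 8 for c in chosen):
                    chosen.append(int(pos))
            for pos in sorted(chosen):
                effect = effects[int(rng.choice(len(effects), p=weights))]
                cds_pos, ref, alt = _draw_variant(transcript, pos, effect, rng)
                dosage = 1 if rng.random() < config.het_fraction else 2
                shared = rng.random() < config.shared_variant_fraction
                if shared:
                    d_dos = r_dos = dosage
                else:
                    if rng.random() < 0.5:
                        d_dos, r_dos = dosage, 0
                    else:
                        d_dos, r_dos = 0, dosage
                d_dp, d_gq = _qc_values(config, rng)
                r_dp, r_gq = _qc_values(config, rng)
                variants.append(
                    _SimVariant(
                        transcript_id=tid, cds_pos=cds_pos, ref=ref, alt=alt,
                        effect=effect, donor_dosage=d_dos, recipient_dosage=r_dos,
                        donor_dp=d_dp, donor_gq=d_gq,
                        recipient_dp=r_dp, recipient_gq=r_gq,
                    )
                )
        out[pair_id] = variants
    return out


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=PCSQ,Number=.,Type=String,Description="Transcript consequence: transcript_id|effect|cds_pos|cds_ref|cds_alt">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Approximate read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
"""


def write_pair_vcf(
    pair_id: str,
    variants: list[_SimVariant],
    reference: dict[str, CodingTranscript],
    path,
) -> None:
    """Write one pair's variants as a two-sample VCF in transcript space
    (CHROM = transcript id, POS = CDS position)."""
    donor_id, recipient_id = pair_sample_ids(pair_id)
    gt = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for tid in sorted(reference):
            fh.write(
                f"##contig=<ID={tid},length={len(reference[tid].cds)}>\n"
            )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{donor_id}\t{recipient_id}\n"
        )
        for v in sorted(variants, key=lambda v: (v.transcript_id, v.cds_pos)):
            info = f"PCSQ={v.transcript_id}|{v.effect}|{v.cds_pos}|{v.ref}|{v.alt}"
            fh.write(
                f"{v.transcript_id}\t{v.cds_pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
                f"{info}\tGT:DP:GQ\t"
                f"{gt[v.donor_dosage]}:{v.donor_dp}:{v.donor_gq}\t"
                f"{gt[v.recipient_dosage]}:{v.recipient_dp}:{v.recipient_gq}\n"
            )


# ---------------------------------------------------------------------------
# HLA typings
# ---------------------------------------------------------------------------

def generate_hla_typings(
    config: SimulationConfig, rng: np.random.Generator, n_pairs: int | None = None
) -> dict[str, HLATyping]:
    """Sibling pairs, HLA-identical by default; a configurable fraction of
    pairs carries 1-3 allele mismatches introduced on the donor side."""
    n_pairs = config.n_pairs if n_pairs is None else n_pairs
    typings: dict[str, HLATyping] = {}
    loci = sorted(config.allele_pool)
    missing = set(HLA_LOCI) - set(loci)
    if missing:
        raise ValueError(f"allele pool missing loci {sorted(missing)}")
    for p in range(n_pairs):
        pair_id = f"P{p:03d}"
        donor_id, recipient_id = pair_sample_ids(pair_id)
        alleles: dict[str, tuple[str, str]] = {}
        for locus in HLA_LOCI:
            names = [a for a, _ in config.allele_pool[locus]]
            freqs = np.array([f for _, f in config.allele_pool[locus]])
            freqs = freqs / freqs.sum()
            a1, a2 = rng.choice(names, size=2, p=freqs)
            alleles[locus] = (str(a1), str(a2))
        donor_alleles = {k: v for k, v in alleles.items()}
        if rng.random() < config.hla_mismatch_fraction:
            n_mm = int(rng.integers(1, 4))
            for locus in rng.choice(HLA_LOCI, size=n_mm, replace=False):
                names = [a for a, _ in config.allele_pool[locus]]
                freqs = np.array([f for _, f in config.allele_pool[locus]])
                freqs = freqs / freqs.sum()
                new = str(rng.choice(names, p=freqs))
                donor_alleles[locus] = (donor_alleles[locus][0], new)
        typings[recipient_id] = HLATyping(recipient_id, alleles)
        typings[donor_id] = HLATyping(donor_id, donor_alleles)
    return typings


# ---------------------------------------------------------------------------
# Resources (ligand DB, mHA table, expression, affinity ranks)
# ---------------------------------------------------------------------------

def _random_peptide(rng, k: int = 9) -> str:
    return "".join(
        STANDARD_RESIDUES[j] for j in rng.integers(0, len(STANDARD_RESIDUES), size=k)
    )


def generate_resources(
    peptide_sets: dict[str, set[MismatchedPeptide]],
    typings: dict[str, HLATyping],
    reference: dict[str, CodingTranscript],
    config: SimulationConfig,
    rng: np.random.Generator,
    outdir,
) -> dict[str, Path]:
    """Write the four resource tables.

    The IEDB-like ligand table contains ``planted_overlap`` of each pair's
    recipient-unique peptides (assigned to alleles that recipient carries)
    plus random decoys per allele; the mHA table is built the same way at
    its own rate; the expression table marks a fraction of genes as
    supportive in one of the GvHD target tissues; the rank table assigns
    each (pooled peptide, A/B allele) a percentile rank drawn uniformly.
    """
    outdir = Path(outdir)
    paths = {
        "iedb": outdir / "iedb_ligands.tsv",
        "mha": outdir / "mha_table.tsv",
        "expression": outdir / "expression.tsv",
        "ranks": outdir / "affinity_ranks.tsv",
    }

    class_i_alleles = sorted(
        {a for locus in ("A", "B", "C") for a, _ in config.allele_pool[locus]}
    )
    ab_alleles = sorted(
        {a for locus in ("A", "B") for a, _ in config.allele_pool[locus]}
    )

    # IEDB-like assay table and mHA table with planted recipient peptides.
    iedb_rows: list[tuple[str, str]] = []
    mha_rows: list[tuple[str, str, str]] = []
    for pair_id in sorted(peptide_sets):
        _, recipient_id = pair_sample_ids(pair_id)
        rec_alleles = sorted(typings[recipient_id].class_i_alleles())
        for pep in sorted(peptide_sets[pair_id], key=lambda p: p.sequence):
            if rng.random() < config.planted_overlap:
                allele = rec_alleles[int(rng.integers(0, len(rec_alleles)))]
                iedb_rows.append((pep.sequence, allele))
            if rng.random() < config.mha_planted_overlap:
                allele = rec_alleles[int(rng.integers(0, len(rec_alleles)))]
                gene = sorted(pep.source_genes)[0]
                mha_rows.append((pep.sequence, allele, gene))
    for allele in class_i_alleles:
        for _ in range(config.ligand_db_size):
            iedb_rows.append((_random_peptide(rng), allele))
        for _ in range(config.mha_db_size):
            mha_rows.append((_random_peptide(rng), allele, "DECOY"))

    with open(paths["iedb"], "w") as fh:
        fh.write("Description\tAllele Name\tQualitative Measure\tHost Organism Name\n")
        for pep, allele in iedb_rows:
            fh.write(f"{pep}\tHLA-{allele}\tPositive\tHomo sapiens\n")
    with open(paths["mha"], "w") as fh:
        fh.write("peptide\tallele\tgene\n")
        for pep, allele, gene in mha_rows:
            fh.write(f"{pep}\t{allele}\t{gene}\n")

    # Expression reliability table over all reference genes.
    tissues = DEFAULT_TISSUE_CYCLE
    with open(paths["expression"], "w") as fh:
        fh.write("gene\ttranscript\ttissue\treliability\n")
        for i, tid in enumerate(sorted(reference)):
            gene = reference[tid].gene_id
            tissue = tissues[i % len(tissues)]
            supportive = rng.random() < config.expression_supportive_fraction
            reliability = "Supportive" if supportive else "Uncertain"
            fh.write(f"{gene}\t\t{tissue}\t{reliability}\n")

    # Percentile-rank table over the pooled recipient-unique peptides.
    pooled = sorted(
        {p.sequence for peps in peptide_sets.values() for p in peps}
    )
    lo, hi = config.rank_distribution
    with open(paths["ranks"], "w") as fh:
        fh.write("peptide\tallele\tpercentile_rank\n")
        for pep in pooled:
            for allele in ab_alleles:
                rank = float(rng.uniform(lo, hi))
                rank = min(max(rank, 1e-6), 100.0)
                fh.write(f"{pep}\t{allele}\t{rank:.4f}\n")
    return paths


# ---------------------------------------------------------------------------
# Outcomes
# ---------------------------------------------------------------------------

def generate_pair_metadata(
    config: SimulationConfig, rng: np.random.Generator, n_pairs: int | None = None
) -> dict[str, dict]:
    """Donor age, transplantation year and female-to-male direction."""
    n_pairs = config.n_pairs if n_pairs is None else n_pairs
    out = {}
    for p in range(n_pairs):
        pair_id = f"P{p:03d}"
        out[pair_id] = {
            "donor_age": float(np.clip(rng.normal(40, 12), 18, 70)),
            "tr_year": float(rng.integers(2001, 2016)),
            "f_to_m": bool(rng.random() < 0.2),
        }
    return out


def _safe_scale(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1) if x.size > 1 else 0.0
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def generate_outcomes(
    ligand_counts: dict[str, float],
    covariates: dict[str, PairCovariates],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[OutcomeRecord]:
    """Draw cGvHD grades from the planted logistic model.

    P(extensive) = logistic(intercept + effect_beta x scaled ligand count
    + Σ covariate_betas x scaled covariates); the grade "limited" is then
    assigned independently to a configurable fraction of pairs so the
    association stage's exclusion rule is exercised.
    """
    pair_ids = sorted(ligand_counts)
    counts = _safe_scale([ligand_counts[p] for p in pair_ids])
    eta = config.intercept + config.effect_beta * counts
    for name, beta in config.covariate_betas.items():
        vals = np.array([getattr(covariates[p], name) for p in pair_ids], float)
        if name == "f_to_m":
            eta = eta + beta * vals
        else:
            eta = eta + beta * _safe_scale(vals)
    prob = 1.0 / (1.0 + np.exp(-eta))
    extensive = rng.random(len(pair_ids)) < prob
    limited = rng.random(len(pair_ids)) < config.limited_fraction
    out = []
    for pid, ext, lim in zip(pair_ids, extensive, limited):
        grade = "limited" if lim else ("extensive" if ext else "no")
        cov = covariates[pid]
        out.append(
            OutcomeRecord(
                pair_id=pid,
                cgvhd_grade=grade,
                donor_age=cov.donor_age,
                tr_year=cov.tr_year,
                f_to_m=cov.f_to_m,
                agvhd_grade=int(rng.integers(0, 5)),
                relapse=bool(rng.random() < 0.3),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Full bundle
# ---------------------------------------------------------------------------

def simulate(config: SimulationConfig, outdir) -> dict[str, object]:
    """Generate the full input bundle into ``outdir``.

    Runs the proteome/mismatch stages internally (the planted ligand
    overlap and outcome model are defined relative to each pair's
    realised recipient-unique peptide set), then writes reference FASTA,
    per-pair VCFs, typing/ligand/mHA/expression/rank/outcome tables and a
    config snapshot.  The pipeline consumes the directory unchanged.
    """
    # local imports: the pipeline stages double as the simulator's forward model
    from .reference_and_variants import (
        QualityThresholds, genotype_quality_filter, read_annotated_vcf,
    )
    from .proteome_builder import build_individual_proteome
    from .peptide_mismatch import recipient_unique_peptides
    from .alloreactivity_scoring import read_hla_typings  # noqa: F401  (round-trip checkable)
    from .association import compute_hla_covariates, count_hla_matches
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "pairs").mkdir(exist_ok=True)
    streams = _streams(config.seed)

    reference = generate_reference(config, streams["reference"])
    write_cds_fasta(reference, outdir / "reference.fasta")

    pair_variants = generate_pair_variants(reference, config, streams["variants"])
    vcf_paths = {}
    for pair_id, variants in pair_variants.items():
        path = outdir / "pairs" / f"{pair_id}.vcf"
        write_pair_vcf(pair_id, variants, reference, path)
        vcf_paths[pair_id] = path

    typings = generate_hla_typings(config, streams["typings"])
    write_hla_typings(typings, outdir / "hla_typings.tsv")

    # Forward model: recipient-unique peptide sets per pair.
    thresholds = QualityThresholds()
    peptide_sets: dict[str, set[MismatchedPeptide]] = {}
    for pair_id in sorted(pair_variants):
        donor_id, recipient_id = pair_sample_ids(pair_id)
        variants = read_annotated_vcf(vcf_paths[pair_id], [donor_id, recipient_id])
        variants = genotype_quality_filter(variants, thresholds)
        donor = build_individual_proteome(donor_id, reference, variants)
        recipient = build_individual_proteome(recipient_id, reference, variants)
        peptide_sets[pair_id] = recipient_unique_peptides(donor, recipient)

    generate_resources(
        peptide_sets, typings, reference, config, streams["resources"], outdir
    )

    # Covariates and outcomes; the planted effect acts on the realised
    # intersection count of the configured method.
    metadata = generate_pair_metadata(config, streams["outcomes"])
    recipients = [typings[pair_sample_ids(p)[1]] for p in sorted(peptide_sets)]
    covariates: dict[str, PairCovariates] = {}
    for pair_id in sorted(peptide_sets):
        donor_id, recipient_id = pair_sample_ids(pair_id)
        freq_sum, n_unique = compute_hla_covariates(recipients, typings[recipient_id])
        covariates[pair_id] = PairCovariates(
            pair_id=pair_id,
            hla_freq_sum=freq_sum,
            n_unique_hla=n_unique,
            tr_year=metadata[pair_id]["tr_year"],
            donor_age=metadata[pair_id]["donor_age"],
            f_to_m=metadata[pair_id]["f_to_m"],
            hla_match_count=count_hla_matches(
                typings[donor_id], typings[recipient_id]
            ),
        )

    ligand_counts = _planted_method_counts(peptide_sets, typings, outdir, config)
    outcomes = generate_outcomes(
        ligand_counts, covariates, config, streams["outcomes"]
    )
    write_outcomes_tsv(outcomes, outdir / "outcomes.tsv")

    snapshot = asdict(config)
    snapshot["cds_length_range"] = list(config.cds_length_range)
    with open(outdir / "simulation_config.yaml", "w") as fh:
        yaml.safe_dump(snapshot, fh, sort_keys=True)

    return {
        "reference": reference,
        "typings": typings,
        "peptide_sets": peptide_sets,
        "covariates": covariates,
        "outcomes": outcomes,
        "ligand_counts": ligand_counts,
        "outdir": outdir,
    }


def _planted_method_counts(
    peptide_sets, typings, outdir, config
) -> dict[str, float]:
    """Realised per-pair count of the method the outcome model acts on."""
    from .ligand_resources import parse_iedb_table, parse_mha_table
    from .alloreactivity_scoring import (
        AffinityConfig, ImmunogenicityModel, MismatchEstimate,
        PrecomputedRankTable, compute_method_counts, read_expression_tsv,
    )

    iedb = parse_iedb_table(outdir / "iedb_ligands.tsv")
    mha = parse_mha_table(outdir / "mha_table.tsv")
    expression = read_expression_tsv(outdir / "expression.tsv")
    predictor = PrecomputedRankTable(outdir / "affinity_ranks.tsv")
    model = ImmunogenicityModel.load_default()
    counts = {}
    for pair_id in sorted(peptide_sets):
        _, recipient_id = pair_sample_ids(pair_id)
        est: MismatchEstimate = compute_method_counts(
            pair_id,
            peptide_sets[pair_id],
            recipient_typing=typings[recipient_id],
            iedb=iedb,
            mha=mha,
            immunogenicity=model,
            expression=expression,
            predictor=predictor,
            affinity=AffinityConfig(),
        )
        counts[pair_id] = float(getattr(est, config.effect_on))
    return counts
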