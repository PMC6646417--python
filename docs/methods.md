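# Methods

This note documents the models, conventions and numerical choices
behind `allopep`, and what the synthetic cohort does and does not
emulate.

## Variant input and quality control

Variants are consumed in *transcript space*: each VCF record carries a
pipe-delimited consequence annotation, `PCSQ=transcript_id|effect|
cds_pos|cds_ref|cds_alt` (one comma-separated entry per affected
transcript), with 1-based CDS coordinates and VCF-style left-anchored
indels. This removes the need for a genome→CDS projection engine and
maps directly onto snpEff `ANN` / VEP `CSQ` output: take
`Feature_ID`/`Feature` as the transcript, classify
`missense_variant`→missense, `inframe_insertion`→insertion,
`inframe_deletion`→deletion, `frameshift_variant`→frameshift,
`stop_gained`→stop_gained, and take the CDS-relative ref/alt from
`HGVS.c`/`CDS_position`. Records annotated with any other effect
(synonymous, intronic, UTR, start/stop-loss …) are excluded by the
non-synonymous whitelist.

Genotypes failing the hard depth/quality cutoff (defaults DP < 15 or
GQ < 20, configurable; missing DP/GQ counts as failing) are set to
missing; a variant whose genotypes are all missing is dropped. The
filter is idempotent and monotone in the thresholds. The default
values are ordinary exome-QC practice; the method only requires that
*some* hard cutoff exists.

## Personal proteomes and phasing

Reference coding sequences are kept when they begin with ATG and are at
least 50 nt long. Sequences may contain N; N-containing codons
translate to X, and any 9-mer window containing X is discarded
downstream (an undetermined peptide cannot be matched against a ligand
database).

Genotype phase is unknown, so each transcript is realised as two
deterministic pseudo-haplotypes: H1 carries alternate alleles of
homozygous-alt variants only, H2 of every non-missing carried variant.
This needs no phasing, is reproducible, and guarantees that when any
heterozygous site exists the (homozygous-edited) reference product
survives on H1. The cost is that multiple heterozygous variants in one
transcript are always treated as co-located (cis); with typical
per-transcript variant counts ≤1 this rarely matters, but it is an
assumption, not an inference. Variants are applied in descending CDS
position so indels do not invalidate upstream coordinates; overlapping
variants and reference-allele mismatches are hard errors.

Translation uses the standard genetic code, stops at the first stop
codon (frameshifts therefore naturally yield truncated or read-through
products), and drops a trailing partial codon. Proteins shorter than 9
residues simply contribute no windows.

## Recipient-unique peptides

The comparison follows exclude–split–subtract order: transcripts whose
protein *sets* are identical between donor and recipient are excluded;
the differing transcripts' proteins are split into 9-mer sliding
windows; and the donor's window union (over those same transcripts) is
subtracted from the recipient's. Peptide sequences are deduplicated
across transcripts, with provenance (source transcripts and genes)
merged so the expression filter can act on any source. An optional
strict mode subtracts the donor's *whole-proteome* window union
instead; it is off by default because the narrower subtraction matches
the stated processing order, but the flag makes the other reading
testable. The window length k = 9 reflects HLA class I peptide
presentation; other lengths (and class II) are out of scope.

## Ligand resources

The IEDB-style assay table is filtered to human-origin entries with a
qualitative measure of "positive" or "positive-high" (case-insensitive)
and an HLA allele present. Entries longer than nine residues are
dropped by default — the database is used as a set of 9-mer class I
ligands — while the published-mHA table *is* expanded into all 9-mer
frames; a config switch (`ninemerize`) applies frame expansion to the
IEDB table too. Allele names are normalised to two-field resolution
(`A*01:01`) before keying; higher-resolution names are truncated.
Cohort coverage is reported as the percentage of (optionally per-locus)
cohort alleles with at least one stored ligand.

## Immunogenicity model

The T-cell immunogenicity score of a 9-mer is a position-weighted sum
of per-residue log-enrichment weights,
score(p) = Σᵢ wᵢ·e(pᵢ), with the anchor positions 1, 2 and the
C-terminus masked (wᵢ = 0) when run without HLA specification — the
configuration used throughout this pipeline; allele-specific masking is
deliberately not implemented. The weight tables are packaged as a
versioned JSON (`data/immunogenicity_v1_1.json`) transcribed from the
public version-1.1 distribution of the model, so any future constant
revision is traceable. Peptides are kept when the score is strictly
greater than 0.2; a score of exactly 0.2 is excluded.

## Expression filter

A peptide passes when at least one source gene (or source transcript,
when transcript-level records exist for it — transcript records
override the gene default) is annotated at "supportive" reliability in
at least one of skin, intestine, lung, liver or bone marrow — the
epithelial and hematopoietic tissues relevant for GvHD target-organ
presentation. An *empty* expression table is an error rather than an
all-fail filter, so missing data cannot masquerade as biology; when no
table is configured at all, the pipeline still produces the filter-free
estimates M1/M3 and reports M2/M4 as unavailable.

## Affinity prediction

Binding prediction is a pluggable contract (`supported_alleles` +
`predict`, percentile ranks in (0, 100], lower = stronger). Shipped
implementations: a precomputed-rank TSV reader (the normal production
path: run any external consensus predictor once, save
peptide/allele/percentile_rank) and a deterministic toy PSSM predictor
(per-allele random score matrix from a seeded hash; rank = upper-tail
normal probability of the standardised score) used in tests and
simulations. The toy predictor is a scoring stand-in, not a trained
binding model. M4 counts distinct filtered peptides with rank ≤ 4
(cutoff ≤ 6 as a robustness alternative) at the recipient's HLA-A/-B
alleles only; unsupported alleles are surfaced in the run report, never
silently skipped.

## M1–M4 and HLA restriction

Database intersections are allele-aware by default: ligand sets are
pooled over the recipient's own class I alleles before intersecting,
which is what makes the HLA-frequency covariates and allele-coverage
reporting meaningful. `restrict_to_recipient_hla=false` gives the
unrestricted (whole-database) reading; both modes are tested. The
estimators obey, by construction, m2 ≤ m1, m2 ≤ total_filtered ≤
total_mismatched, m4 ≤ total_filtered, and m4 is monotone
non-decreasing in the rank cutoff.

## Association model

Pairs graded "limited" are excluded; the outcome is extensive (1) vs
no (0) cGvHD. Each method gets its own logistic model whose mismatch
covariate matches the method's filtering depth: the raw recipient-
mismatched total for M1/M3, the filtered total for M2/M4. HLA
covariates: the allele match count over the six classical loci
(multiset intersection per locus, 0–12), the number of distinct alleles
a recipient carries, and the sum over those alleles of their cohort
frequency. "Frequency" defaults to carrier frequency (fraction of
cohort recipients carrying the allele); allele-count frequency is
available via `hla_freq.mode` because the definition is genuinely
ambiguous. Numerical predictors are centred and scaled to unit sample
SD (so coefficients are per-SD and comparable across methods);
the binary female-to-male indicator enters unscaled. A covariate that
is constant in the analysed subset (e.g. the match count in a fully
HLA-identical cohort) is dropped from the design with a warning — it
carries no information and would otherwise abort the fit; the
`scale_center` primitive itself still treats zero spread as an error.

Fitting is maximum-likelihood logistic regression (statsmodels Logit;
Newton iterations, cap 100, tolerance 1e-8) with Wald z = β̂/SE and
two-sided normal p-values. Non-convergence, separation, or exploding
standard errors raise a per-method error that is recorded while the
remaining methods continue. Benjamini–Hochberg step-up adjustment is
applied jointly to the four ligand-count p-values only; covariate
p-values are reported unadjusted. Exact BH on the published nominal
method p-values (0.00976, 0.0234, 0.0366, 0.36) gives
(0.03904, 0.0468, 0.0488, 0.36); the corresponding published adjusted
values (0.04, 0.046, 0.0493, 0.36) differ in the third decimal,
consistent with rounding of the nominal p-values before adjustment —
the worked-example test therefore asserts two-decimal agreement on the
smallest value and exact agreement on the largest.

## Synthetic cohort

The generator emulates the *structure* of an HLA-matched sibling
transplant study at desk scale, with defaults chosen once:

- 157 pairs (the cohort scale), 40 transcripts of 300–720 nt —
  computation in minutes rather than the exome's ~20k transcripts; the
  per-pair peptide totals (~25) are therefore ~4 orders of magnitude
  below a real exome's (~9×10⁵), which rescales counts but not the
  pipeline's set algebra or the association model.
- Poisson(0.6) variants per transcript per pair, 85% shared between the
  siblings with identical genotype, 67% of carried variants
  heterozygous, 2% of genotypes low-quality (to exercise QC); effect
  classes 82% missense, 5% each in-frame insertion/deletion/frameshift,
  3% stop-gained. Codons are drawn uniformly from the 61 non-stop
  codons so internal stops occur only where a test plants them.
- A 4/4/3-allele class I pool (plus class II loci) with realistic
  two-field names; sibling pairs HLA-identical except a 6% mismatch
  fraction carrying 1–3 donor-side replacements, mirroring a
  147/3/2/5-style 12/11/10/≤9 match-count spread.
- Ligand tables: 25% of each pair's realised recipient-unique peptides
  planted under alleles that recipient carries, plus 150 random decoy
  9-mers per class I allele; the mHA table analogously at 3% with 8
  decoys per allele. 70% of genes "supportive" in one target tissue.
  Affinity ranks uniform on (0, 100], so ~8% of filtered peptides fall
  under the rank ≤ 4 cutoff at some A/B allele.
- Outcomes: P(extensive) = logistic(−0.5 + 0.6·z(M1) + Σβ·z(covariates))
  with covariate effects matching the observed direction pattern
  (donor age +0.3, female-to-male −0.8, HLA-frequency sum −0.4, …);
  "limited" is then assigned independently to 15% of pairs to exercise
  the exclusion rule. This yields roughly 50/15/35% no/limited/
  extensive.

Each generator stage draws from its own child stream of a single
`SeedSequence`, so the bundle is a pure function of (config, seed) —
two runs are byte-identical — and changing one knob perturbs only its
stage. What the simulator does **not** emulate: linkage and real human
allele-frequency spectra, per-gene mutation-rate variation, realistic
ligand-database allele bias, measured binding affinities, and exome
scale. Passing tests therefore demonstrate correctness of the set
algebra, filters, counting and inference under known truth — not
clinical effect sizes.

## Validation design

- Proteome construction, peptide extraction and M1–M4 are checked
  exactly against brute-force enumeration (character-by-character
  haplotype rebuild, substring sets, manual filter sums) on 200
  randomized micro-instances.
- The logistic fitter is checked to 1e-6 against an independent
  hand-written IRLS implementation on a fixed 40-row dataset.
- Parameter recovery: with the planted 0.6 log-odds effect at n = 150,
  100 outcome replicates give a mean fitted coefficient within 0.1 of
  truth and ~95% Wald-CI coverage; under the null the pooled fraction
  of BH-adjusted ligand p-values below 0.05 stays within binomial noise
  of the nominal level. Replicates regenerate outcomes over one fixed
  cohort realisation — the standard conditional design that fixes the
  design matrix X and isolates the inference step from peptide-level
  Monte Carlo noise. Conditional on X the maximum-likelihood estimate
  retains a realisation-dependent finite-sample bias: with ~35–50
  extensive cases against nine parameters (4–6 events per parameter)
  and a right-skewed count covariate, the fitted effect is overestimated
  on average across design realisations, occasionally substantially.
  This regime matches real cohorts of this size and is a property of
  unpenalised logistic regression there, not of the pipeline;
  penalised (e.g. Firth-type) fitting is deliberately out of scope.
- Degenerate cohorts (zero variant rate, or all variants shared) must
  produce exactly zero for every count end to end.

## Known limitations

- The two-pseudo-haplotype rule is an explicit phase-free assumption.
- Only 9-mers and HLA class I are modelled; proteasomal cleavage and
  TAP transport are not.
- The built-in predictor is a deterministic stand-in; production use
  requires precomputed ranks from a real consensus predictor.
- Count scales in the synthetic cohort are far below exome scale (see
  above), so absolute count summaries are not comparable to a real
  cohort's.
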