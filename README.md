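# allopep

Estimation of HLA-presented donor–recipient mismatching and its
association with chronic graft-versus-host disease (cGvHD) in
HLA-matched allogeneic hematopoietic stem-cell transplantation
(allo-HSCT) cohorts.

Even with full HLA identity, donor T cells can recognise recipient
peptides arising from non-synonymous coding variants the donor does not
carry — minor histocompatibility antigens (mHAs). `allopep` implements
the full computational chain from paired donor/recipient annotated
variant calls to cohort-level inference:

1. **Personal proteomes.** Coding sequences (Ensembl-CDS-style FASTA,
   records starting with the canonical ATG and ≥50 nt) are edited with
   each subject's quality-filtered (DP/GQ) non-synonymous variants
   (missense, insertion, deletion, frameshift, stop-gained; transcript-
   space annotation) and translated on two unphased pseudo-haplotypes.
2. **Recipient-unique 9-mers.** Transcripts with identical protein sets
   in donor and recipient are excluded; the rest are split into sliding
   9-mer windows and the donor's peptides are subtracted, leaving the
   candidate alloantigen set U for each pair.
3. **Four alloreactivity estimators** per pair (F = U filtered by a
   position-weighted T-cell immunogenicity score > 0.2 and by
   supportive tissue expression in skin, intestine, lung, liver or bone
   marrow):

   | method | definition |
   |--------|------------|
   | M1 | \|U ∩ IEDB 9-mer class I ligands\| over the recipient's HLA-A/B/C alleles |
   | M2 | \|F ∩ IEDB 9-mer class I ligands\| |
   | M3 | \|U ∩ published 9-mer mHAs\| |
   | M4 | peptides in F with predicted HLA-A/B binding percentile rank ≤ 4 |

4. **Association.** Per method, logistic regression of cGvHD "no" vs
   "extensive" (grade "limited" excluded) on the scaled ligand count,
   adjusted for the method-matched total mismatch count, the sum of
   cohort frequencies of the recipient's HLA alleles, the number of
   unique HLA alleles, transplantation year, donor age, female-to-male
   direction, and the 0–12 HLA allele match count; Wald tests, with the
   four ligand-count p-values jointly Benjamini–Hochberg adjusted.

Because real transplant-cohort genotypes are not redistributable, the
package ships a synthetic-cohort generator (`allopep.synthetic_cohort`)
that emits every input file format with configurable variant rates,
allele frequencies, ligand-overlap fractions and a known logistic
outcome model, so the whole pipeline is testable end to end.

## Worked example

Generate a 157-pair synthetic cohort and run the full pipeline:

```sh
allopep simulate --out runs/demo --seed 7 --n-pairs 157
allopep all --bundle runs/demo --out runs/demo-out
```

(`allopep proteomes` / `mismatch` / `score` / `associate` run the same
stages one at a time and produce bit-identical outputs.)

`runs/demo-out/summary.json` then contains, for this seed:

```
counts (mean [2.5–97.5 percentile]):
  total_mismatched  22.6  [0 – 60.5]
  total_filtered     2.3  [0 – 11.0]
  m1                 5.8  [0 – 15.2]     m2  0.56  [0 – 3.0]
  m3                 0.83 [0 – 4.0]      m4  0.30  [0 – 2.0]
outcomes: no 97, limited 23, extensive 37
ligand-count log-odds:  m1 0.671  m2 0.428  m3 0.174  m4 -0.071
nominal p:              m1 0.164  m2 0.229  m3 0.456  m4 0.796
BH-adjusted p:          m1 0.458  m2 0.458  m3 0.608  m4 0.796
```

The counts are the per-pair distribution of recipient-unique peptides
and their M1–M4 reductions; the log-odds are the per-SD effect of each
ligand-count estimate on the odds of extensive cGvHD in the adjusted
model. The generator's default planted effect (0.6 log-odds per SD on
M1) is positive but, at a single 157-pair cohort, not always
significant after adjustment — exactly the power regime the design
targets. `runs/demo-out/association.tsv` holds the full per-covariate
coefficient table and `manifest.json` the config hash and input
checksums.

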