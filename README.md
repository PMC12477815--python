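# nmdeff

Estimation of **individual-level nonsense-mediated mRNA decay efficiency
(iNMDeff)** from bulk RNA-seq derived count tables, with the surrounding
machinery needed to study how that efficiency varies across tissues, tumors
and individuals.

Nonsense-mediated decay (NMD) degrades transcripts carrying premature
termination codons (PTCs) and a sizable fraction of the unmutated
transcriptome. How efficiently it does so differs between tissues and between
people, with consequences for genetic disease severity, tumor evolution and
immunotherapy response. `nmdeff` provides a tested, reusable implementation of
the quantitative toolkit for this question, aimed at computational biologists
working with transcript-level counts, allele-specific expression (ASE) tables
and gene-level copy-number (CNA) matrices.

## What it computes

**Two orthogonal per-individual estimators.** Both model raw counts with a
negative-binomial regression (log link) and report iNMDeff as the sign-flipped
coefficient of the NMD-target indicator:

```
RawCount ~ NegBin(mu, theta)
log mu = b0 + b1 * NMDtarget + geneID [+ b_len * transcriptLength]
iNMDeff = -b1
```

* **ETG** (endogenous target genes): NMD-target transcripts paired with
  same-gene featureless control transcripts; `exp(-iNMDeff)` is the modeled
  target/control expression ratio.
* **ASE** (allele-specific expression): mutant vs wild-type RNA counts at
  germline PTC loci; `exp(-iNMDeff)` is the modeled MUT/WT allele ratio.

Ratios above 1 (iNMDeff below 0) mean *lower* NMD efficiency.

**Supporting machinery**, each a spec'd module with its own tests:

* NMD-feature annotation (uORFs in the 5'UTR; 3'UTR exon junctions more than
  50 nt past the stop codon; 3'UTR GC), target/control pair selection, and
  PTC prediction from nonsense SNVs and indels with classification into
  NMD-triggering / -evading (last-exon, 55 nt, start-proximal rules, long-exon
  variant with buffer zone, 3'UTR-EJC override);
* the per-method filtering cascades (cohort prevalence, coverage, MAF, LOEUF
  constraint, positive selection, co-occurring somatic events, minimum-unit
  and subsampling rules);
* per-PTC efficiency `pNMDeff = -log2(MUT/WT)` and permutation tests for
  inter-/intra-individual variability;
* tissue-level randomization statistics — ITNVD (inter-tissue variability
  deviation) and TND (per-tissue deviation) with the `(count + 1) / n_iter`
  p-value and the empirical-FDR calibration ratio — plus an OLS delta-R²
  variance decomposition;
* sparse-PCA CNA signatures on the duplicated gain/loss dosage matrix, tuned
  by genomic lag-1 autocorrelation, with a discovery (ASE) → validation (ETG)
  association step, gene-wise focal-amplification score tracks and candidate
  prioritization;
* a synthetic-data module that generates every input from scratch (toy
  genome/GTF, NB counts, ASE tables, multi-tissue cohorts, CNA matrices) with
  a ground-truth manifest.

## Worked example

`examples/` holds one short script per capability. `examples/etg_estimation.py`
simulates a cohort whose NMD-target transcripts are attenuated by a known
per-sample factor `exp(-eta)`, then re-estimates eta:

```
sample     true eta  iNMDeff     SE  pairs
S0000         1.199    1.141  0.063     40
S0001         1.605    1.559  0.049     40
S0002         1.171    1.288  0.047     40
...
mean |error| = 0.076
```

An iNMDeff of 1 means NMD-target transcripts are degraded to `exp(-1) ~ 37%`
of their paired controls. `examples/tissue_variability.py` plants two
low-efficiency tissues among ten and recovers them:

```
ITNVD = 0.116 (observed SD of tissue medians 0.150 vs null median 0.034), p = 0.0005
tissue           TND         p
brain         -0.362    0.0005
testis        -0.284    0.0005
tissue_0       0.014      0.26
...
```

The two planted tissues sit at the permutation floor `p = 1/2000 = 5e-4` with
negative TND (less efficient than chance). `examples/cna_signatures.py` plants
an arm-level gain that lowers carrier efficiency by 0.3 and recovers a single
sparse component over exactly the planted genes whose association replicates
across both estimators (betas −0.32 / −0.29).

A thin CLI mirrors the library (`nmdeff simulate|annotate|classify-ptc|etg|
ase|pnmdeff|tissue-test`).

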