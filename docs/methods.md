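# Methods

This note records the models implemented in `nmdeff`, the choices made where
the design was genuinely open, and what the synthetic cohorts do and do not
establish about real data.

## The efficiency model

Both estimators reduce to the same contrast: a set of count observations in
which half the rows are expected to be attenuated by NMD, the other half not,
with a grouping factor absorbing between-unit level differences.

For the endogenous-target-gene (ETG) method the rows are transcripts pooled
across an individual's selected target/control pairs:

    RawTranscriptExp ~ NegBin(mu, theta)
    log mu = b0 + b1 * NMDtarget + geneID + b_len * transcriptLength

and for the allele-specific (ASE) method the rows are the two alleles of each
germline PTC variant:

    RawAlleleExp ~ NegBin(mu, theta)
    log mu = b0 + b1 * NMDtarget + geneID

iNMDeff is `-b1`, so larger values mean stronger decay of the NMD-target arm;
`exp(-iNMDeff)` is the modeled target/control (or MUT/WT) ratio. The gene —
not the transcript or variant — is the blocking factor: variants sharing a
gene share one effect. A consequence worth knowing: with per-gene intercepts
and Poisson-like counts, `b1` behaves as a pooled (count-weighted) log ratio,
so a locus-level depth change is absorbed exactly only when the locus allelic
ratio matches the pooled ratio; the test suite exercises exactly that case.

**Fitting.** The reference analyses that motivated this package fit these
models as Bayesian GLMs with diffuse priors; `nmdeff` instead fits the
maximum-likelihood NB GLM — IRLS (statsmodels, NB2 family) alternated with a
bounded 1-D profile-likelihood search over log(1/theta) — and reports Wald
standard errors. With diffuse priors the posterior mode coincides with the
MLE, and on every simulated cohort the two give indistinguishable point
estimates at a fraction of the cost. This is the package's single intentional
methodological substitution. The dispersion loop declares convergence when
the profiled dispersion settles (relative change < 1e-4) or collapses into
the effectively-Poisson regime (alpha < 1e-6), where its exact value no
longer moves the coefficients.

`transcriptLength` enters in raw nucleotides (a log-length switch exists).
Zero-count rows are retained — the NB likelihood handles them — and a
degenerate all-zero arm surfaces as non-convergence or an extreme coefficient
with `converged=False`, never silently.

## Feature annotation and PTC rules

Internal coordinates are 0-based half-open; GTF input (1-based closed) is
converted at parse time, and CDS coordinates include the stop codon. Feature
definitions:

* **uORF**: AUG-initiated ORF in the 5'UTR whose stop codon lies strictly
  before the CDS start ("does not overlap the CDS" read strictly), length
  ≥ 30 nt including the stop. Overlapping uORFs count individually. Target
  selection requires ≥ 2 qualifying uORFs when no 3'UTR junction is present.
* **3'UTR EJC**: an exon-exon junction strictly more than 50 nt downstream
  of the first nt after the stop codon. A junction at exactly 50 nt does not
  qualify; the generator includes 40/50/60 nt boundary fixtures.
* **3'UTR GC** is recorded and used only for tie-breaking among qualifying
  targets (highest GC wins; exact ties broken by transcript id).

Target/control pair selection: targets need a complete ORF, median log(TPM)
≥ 1 (natural log as printed; the base is configurable) and a feature; controls
need median log(TPM) ≥ 3 and no feature; the pair is kept only when the
target/control TPM ratio is ≤ 0.9 (inclusive), optionally also requiring a
wild-type cell-line expression ratio ≤ 0.9 when such a table is supplied.

PTC classification (`classify_ptc_nmd`) applies, in order: start-proximal
evasion (PTC within the first 200 nt of the spliced transcript — measured on
transcript, not CDS, coordinates, the more common reading of "of the
transcript"; 250 nt in the strict preset), last-exon evasion, and the 55 nt
rule (within the final 55 nt of the penultimate exon, inclusive). A 3'UTR EJC
flips last-exon/55 nt evasion back to triggering — the extra junction's
complex survives termination. The strict (`dnds`) preset adds long-exon
evasion (≥ 1000 nt), a 500–1000 nt buffer zone that is excluded from both
classes, and restricts triggering calls to exons ≤ 500 nt. Indel PTCs are
predicted by editing the spliced sequence and scanning the (possibly shifted)
frame from the variant codon for the first stop, which may fall beyond the
CDS; positions are mapped back through the exon structure to genomic
coordinates. Variants outside the CDS raise a dedicated error, distinct from
"no downstream PTC".

## Filtering cascades

ETG, per individual and gene set: cohort prevalence (pair dropped only when
*both* members have log2(raw) ≥ 1 in fewer than half of the individual's
tissue cohort; the whole cohort serves as fallback when tissue labels are
absent), non-coding exclusion, per-individual exclusion of transcripts
overlapping truncating variants or CNAs (interval overlap is resolved by the
annotation layer; the filter itself consumes transcript-id sets), a minimum
of 2 surviving pairs, and a 50-pair cap by seeded subsampling for every set
except the consensus set. Per-individual subsampling seeds derive from the
global seed plus a CRC of the individual id, so cohort composition changes
never reshuffle other individuals.

ASE, per individual and variant set: PASS heterozygous variants; total
coverage ≥ 5 for nonsense/synonymous and ≥ 2 for indels; population MAF
≤ 20% (exclusion is *strictly greater*, following the more precise of the two
printed phrasings); single-exon and non-coding transcripts dropped; genes
under positive selection dropped; the most constrained LOEUF bin dropped —
the printed threshold conflates "first percentile" with "10% most
constrained", so the cutoff is a parameter defaulting to the most constrained
decile; variants co-occurring with somatic truncating events or CNAs dropped;
set-specific rules (triggering keeps triggering PTCs and requires frameshifts
to have a predicted PTC; evading symmetric; synonymous excludes all NMD-All
genes); multi-tissue designs can drop variants seen in a single tissue; a
minimum of 3 variants; a 100-variant seeded cap.

pNMDeff applies the seven printed exclusions (no downstream PTC, co-occurring
truncating/CNA events, single-exon without extra 3'UTR junctions, LOEUF first
decile or positive selection, homozygosity, DNA VAF > 20%, median TPM < 5 or
expression CV > 0.5).

## Randomization statistics

`pNMDeff = -log2(MUT/WT)`: 0 means no degradation, 1 a halved mutant allele,
+infinity complete degradation (MUT = 0); WT = 0 is undefined and excluded.
Variability tests compare an observed statistic — mean Spearman correlation
of sampled PTC pairs, or mean within-group variance over groups with enough
members (≥ 2 for correlation, ≥ 3 for variance) — against a baseline that
permutes pNMDeff values over the whole table (one exchangeable null).
Infinite records are excluded before either metric, matching the variance
metric's domain; a switch retains them for rank statistics. Excess variance
is randomized minus observed. P-values come from the permutation tail with
the `(count + 1) / n_iter` formula (lower tail for variance, upper for
correlation); an F-type approximation was considered and rejected in favor of
the tail the permutation scheme defines. Pair sampling is without replacement
within an iteration and independent across iterations.

ITNVD: observed SD over tissues of the tissue-median iNMDeff, minus the
median of that SD under `n_iter = 2000` random sample-to-tissue reassignments
(sizes preserved). TND: one tissue's observed median minus the median of its
randomized medians. Permutation is at the sample level (a donor-level option
exists for designs with repeated donors, off by default). The printed p
formula is upper-tail with strict inequality and a +1 numerator, giving a
floor of `1/n_iter` (5e-4 at 2000 iterations); TND uses the tail matching the
deviation's sign, the minimal reading consistent with reporting significant
negative deviations. Ties never count as exceedances.

Empirical FDR = (randomized hit rate) / (observed hit rate). The displayed
equation in the source material is inverted relative to its own worked
example (3 randomized vs 10 observed hits → ~30%); the worked example wins,
and `empirical_fdr_details` exposes the inverse ratio for audit. Zero
observed hits is an error, not a zero.

The delta-R² decomposition fits the full OLS model, then refits leaving out
one covariate at a time; collinear covariates raise an error naming the pair.

## CNA signatures

The gene × sample GISTIC-style score matrix is split into amplification rows
(negatives zeroed) and deletion rows (positives zeroed); their sum
reconstructs the input exactly. Rows are ordered amp-block-then-del-block,
each in genomic order, so an arm-level event is one contiguous run — ordering
amp/del interleaved per gene would destroy the lag-1 autocorrelation signal
the tuning relies on.

Sparse PCA uses scikit-learn's elastic-net-penalized decomposition with the
deterministic LARS solver (SVD warm start, fixed iteration cap): identical
inputs give identical loadings with no seed. Components are ranked by sample
score variance; "effective" means any nonzero loading. Tuning evaluates an
(alpha, k) grid by the median lag-1 Pearson autocorrelation of the leading
ceil(1%) of effective components — leading, because arm-scale structure
concentrates in the highest-variance components; a trailing option exists
since the source phrasing ("lowest 1% percentile") is ambiguous. The global
score maximizer is selected subject to a closeness-to-1 threshold (default
0.9); if no grid point reaches it the best is returned with a warning rather
than an error, since a noise-only matrix is a legitimate input.

Associations fit a linear model per signature (iNMDeff ~ score + covariates),
discover on ASE estimates with BH-FDR over signatures (default 10%), validate
discoveries on ETG estimates, and call a signature replicated only when both
pass and the signs agree. Focal events are contiguous altered runs spanning
less than a configurable fraction (default 25%) of their chromosome's genes —
the source distinguishes focal from arm-level without defining the cutoff.
Candidate genes must show expression anti-correlated with iNMDeff below a
negative threshold *and* expression correlated with their own CNA dosage
above a positive one.

## Synthetic cohorts

The generator inverts the estimation model: control transcript counts are
NB(baseline_g · depth · lib, theta) with log-normal gene baselines, target
counts multiply the mean by `exp(-eta_sample)`; ASE wild-type counts are
NB(depth · lib, theta) with the mutant mean attenuated the same way for
triggering PTCs and unattenuated for evading/synonymous variants. Per-sample
eta composes a base level, a tissue shift and a normal individual effect, all
recorded in the manifest alongside every seed, pairing, class label and
planted CNA segment — every expected estimate is computable analytically from
the manifest. Library size is a per-sample log-normal factor (sd 0 by
default so oracle expectations stay exact; positive values exercise the
internal-control invariants). One global seed fans out to fixed per-component
child streams (annotation=1, etg=2, ase=3, cna=4, cohort=5 via
`SeedSequence(seed, spawn_key=(k,))`), so adding a component never perturbs
existing streams, and generated files are byte-identical across runs.

Default study conditions used by the test suite: ETG recovery at 200
individuals × 50 pairs, depth 100 reads/transcript, theta = 10, eta ~
U(0, 2); ASE recovery at 200 individuals × 10 variants at ~30× coverage; null
ITNVD calibration on 20 tissues × 100 samples with 2000 permutations; the
planted-CNA pipeline on 400 genes × 300 samples with a 200-gene gain in 30%
of carriers and a −0.3 eta decrement. These sizes were chosen as the smallest
cohorts at which the estimators' asymptotics visibly hold (recovery bands
0.1/0.2, type-I error 4–7% at p ≤ 0.05).

What the synthetic cohorts do **not** emulate: mapping bias and duplicate
reads in ASE counts, isoform quantification uncertainty, correlated gene
baselines, splice-isoform switching, tumor purity and subclonality, and
GC-dependent degradation beyond bookkeeping. Passing recovery tests therefore
demonstrates correctness of the estimators under their own model, not
robustness to those real-data artifacts — the filtering cascades exist
precisely because the real data violate the clean model.

## Numerical details and limitations

* Dispersion search bounds: alpha = 1/theta in [1e-8, 1e3], optimized in log
  space (xatol 1e-8); design matrices are checked for full rank before
  fitting.
* Autocorrelation of a constant loading vector is defined as 0 (flagged),
  since the Pearson correlation is undefined there.
* GC tie-breaks, subsampling and permutations are all seeded or
  deterministic; fixed seeds give bit-identical results including null
  distributions.
* The ETG prevalence filter needs a tissue cohort of reasonable size; with
  very small cohorts the 50% threshold is coarse.
* `pNMDeff` records with MUT = 0 are +infinity and excluded from moment-based
  statistics; a rank-based treatment that retains them is available but off
  by default so the correlation and variance metrics see the same records.
* The NB profile likelihood can be flat in theta when gene effects absorb
  most variance; the estimate of theta is then reported as large (near-
  Poisson) and should not be interpreted, though iNMDeff itself is stable.
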