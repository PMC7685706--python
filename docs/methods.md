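# Methods

This note describes what each stage of `promvar` computes and why, in the
package's own terms. Coordinates are 1-based inclusive unless stated
otherwise; "BY" denotes the reference allele and "RM" the alternative.

## Library design (`promvar.design`)

**TSS libraries.** For a gene with TSS position `t`, the assayed window is
the 144 bp immediately upstream: positions `t−144 … t−1` on the plus strand,
or `t+1 … t+144` reverse-complemented for minus-strand genes. For the `k`
variants falling in the window, the block contains the all-BY oligo, each
single-RM oligo, and the all-RM oligo; duplicate inserts are removed, so
`k = 1` gives two oligos and `k = 2` gives four (the full 2² combination
set, which also enables the interaction test). Allele substitution splices
alternative alleles right-to-left so indel length changes never shift the
coordinates of substitutions still to be applied.

**Upstream libraries.** A variant outside a TSS window is assayed in a
144-bp window centered on it (start `pos − 72` on the BY reference), as a
BY/RM oligo pair. RM insertions lengthen the RM insert; the window always
holds 144 BY reference bases.

**Filtering and synthesis strand.** Any block containing an oligo whose
insert matches a restriction site used in cloning (on either strand, IUPAC
codes allowed) or whose full synthesis sequence exceeds 200 nt is dropped
whole, since a partial block breaks the paired comparisons. Oligos with
strictly more A than T in the full sequence are synthesized as the reverse
complement (synthesis yield is worse on A-rich strands); the flip is
recorded and undone by the PCR orientation at annotation time.

**Barcodes.** Random 20-mers with composition constraints that avoid
synthesis and sequencing artifacts: position 1 ∈ {C, T}; positions 2–4 and
every even position from 6 on exclude G; odd positions from 5 on are free.
The space holds 2 × 3¹¹ × 4⁸ ≈ 2.3 × 10¹⁰ sequences, so rejection sampling
of distinct barcodes is cheap.

## Barcode annotation (`promvar.annotate`)

Merged association reads are parsed by exact anchor matching: the constant
sequence 5′ of the insert and the library-specific constant between insert
and barcode must each occur exactly once; the barcode is the 20 bases after
the between-anchor and the observed oligo is the sequence between anchors.
Reads failing any condition are rejected with a reason code.

Each barcode's **primary oligo** is the modal observed oligo sequence
across its reads; ties are discarded as unresolvable. A barcode enters the
dictionary only if its primary sequence perfectly matches a designed
insert, it has at least the minimum read support, and (optionally) its
primary fraction is high enough. Barcodes are never collapsed by sequence
similarity: with ~2.3 × 10¹⁰ possible barcodes, near-identical pairs are
far more likely to be sequencing errors than distinct clones.

## Quantification (`promvar.quantify`)

Sample demultiplexing allows at most one mismatch to a sample index and
requires the hit to be unique. Barcode counting is exact-match against the
dictionary; technical replicates are summed, and barcode counts are summed
to oligos through the dictionary.

RNA samples lacking a matched DNA sample can borrow one by policy:
`same_batch` copies the DNA column of a same-batch replicate, `sum_all`
uses the element-wise sum of all DNA columns, `annotation` uses the
association-library DNA counts, `drop` removes the RNA sample. The
provenance is recorded.

Activity per oligo and replicate is `log2((RNA_cpm + c) / (DNA_cpm + c))`
with counts-per-million normalization per sample and pseudocount
`c = 0.5`. Oligos must be observed (nonzero DNA and RNA) in **every**
replicate; partial observation is excluded rather than imputed.

## Allelic testing (`promvar.testing`)

Each variant is tested by a paired t-test on per-replicate activity
differences between its RM oligo and the matched BY oligo; positive log2
fold-change means RM drives higher expression. With moderation on
(default), per-variant variances are shrunk toward a global prior fitted by
method of moments on log sample variances (a scaled inverse-chi-square
prior; the prior df comes from inverting the trigamma function by Newton's
method). The moderated statistic uses
`s²_post = (d0·s0² + df·s²) / (d0 + df)` on `df + d0` degrees of freedom,
stabilizing estimates when replicates are few. With moderation off the test
is exactly the classical paired t-test.

Multiple testing uses Benjamini–Hochberg q-values. When a variant was
assayed in several contexts (both libraries, both strands), the
smallest-p record is carried forward, ties broken by larger |logFC|. The
fraction of true effects is estimated as π1 = 1 − π0 with
π0(λ) = #{p > λ} / (m(1 − λ)) at λ = 0.5 (optionally a cubic smoother over
a λ grid). Variants are labelled **causal** (q ≤ 0.05), **non-causal**
(raw p > 0.2) or **excluded** (in between) — the wide gap keeps the
non-causal class clean for downstream feature association.

## Epistasis and LD (`promvar.epistasis`)

For promoters with exactly two variants, the four-combination TSS block
supports the interaction model `y = β0 + β1x1 + β2x2 + β3x1x2` fitted by
OLS on per-replicate activities; the interaction p-value is the t-test on
β3 (equivalent to the F-test of the nested comparison). A missing allele
combination makes the design rank-deficient and is an error, not a silent
NaN.

Pairwise linkage disequilibrium over an isolate panel drops heterozygous
and missing calls, reduces each marker to its two most frequent alleles,
and reports `D = p_AB − p_A·p_B`, `D′ = |D| / D_max` (with the standard
sign-dependent `D_max`) and `r² = D² / (p_A(1−p_A)p_B(1−p_B))`.

## Variant features (`promvar.features`)

**TFBS features.** For each TF's position weight matrix (length L, score
cutoff defining "strong" sites), every L-length window overlapping the
variant span in 1-bp steps is scored on both alleles, in three strand
contexts (plus, minus = reverse complement, strand-agnostic = union). Per
TF and context, five metrics compare alleles: |Δ best| and |Δ mean| over
strong windows, |Δ count| of strong windows, and |Δ best| and |Δ mean| over
weak windows — 15 features per TF; empty strong/weak sets on either allele
define the best/mean differences as 0. Across the TF panel, 27 aggregates
summarize the block: the summed strong-site-count change per context (3)
plus the max and average across TFs of each best/mean metric per strength
and context (24).

**Non-TF features.** TATA-box consensus `TATA(A/T)A(A/T)(A/G)` counts
(overlapping), ATG counts, SNV/indel class and indel length, nucleosome
occupancy (within ±72 bp of a mapped nucleosome center, closed interval),
and derived-allele frequency (the derived allele is the one absent from an
outgroup isolate; ambiguous calls give a missing value). All features are
Z-scored with the population SD across variants; constant columns are
excluded.

## Association models (`promvar.models`)

Each feature's association with causality is tested by logistic regression
of the causal/non-causal label on the feature plus two covariates (library
and baseline expression), with a likelihood-ratio χ²(1) p-value against the
covariate-only model and BH q-values across features. Perfect separation
falls back to a weakly ridge-penalized fit and is flagged.

Prediction uses a deterministic registry of 112 models, each defined by
flags: include non-TF features, a subset of strand contexts, a subset of
strengths (strong/weak), include the 27 aggregates, and restrict to
individually significant features. Classification models are logistic
regressions selected by mean Cohen's Kappa under repeated stratified
10-fold cross-validation (5 repeats) on a stratified 90% split and reported
by AUC on the held-out 10%; regression models (predicting |logFC|) use RMSE
for selection and held-out Spearman ρ plus full-data R². Features with any
missing value are excluded from modeling.

## eQTL comparison (`promvar.eqtl`)

Per-gene aggregates of variant effects (sum over all variants, sum over
significant ones, and the most/second-most significant variant's logFC) are
compared with local-eQTL effect estimates by Spearman correlation with a
Fisher-z confidence interval using the rank-adjusted variance
`1.06/(n−3)`, overall and within strata. Directional agreement (sign
concordance) and enrichment of causal-variant genes among genes with
significant allele-specific expression are tested by two-sided Fisher's
exact tests reporting the conditional-MLE odds ratio.

## Synthetic data (`promvar.simulate`)

The generator builds one 600-bp contig per gene (TSS at 400 for plus-strand
genes, 200 for minus), Poisson-many variants per window (capped at 4, at
least 25 bp apart) with a configurable SNV/indel mix, and plants a log2
effect on a configurable fraction of variants (Gaussian or fixed-magnitude
random-sign). Barcode counts are negative binomial: DNA around a common
mean, RNA around `dna_mean · 2^(baseline + Σ effects + interaction)`, each
scaled by log-normal replicate size factors; gene baselines are Gaussian in
log2. A gene-level eQTL table adds Gaussian noise to the true summed cis
effect with a LOD proxy. Every draw derives from a single seed, so tests
can assert exact reproducibility.

## Validation strategy

The test-suite checks every numerical routine against an independent
implementation where one exists: scipy's paired t-test for the unmoderated
allelic test, hand-computed BH and LD cases, exhaustive enumeration of all
small haplotype tables, brute-force enumerate-and-sum TFBS scoring,
hypergeometric summation for Fisher p-values, and cell-mean contrasts for
the interaction coefficient. Statistical behaviour (type-I error, power,
π1 recovery, end-to-end sensitivity and FDR) is validated on the
ground-truth-known generator with fixed seeds and 3σ Monte-Carlo bands.
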