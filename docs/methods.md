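# Methods

## Second-order association ("gene behaviour") networks

The engine works in two stages. First order: Spearman rank correlation
(average ranks at ties) of all gene pairs across samples, giving a matrix C
in [−1, 1] with unit diagonal. Rank correlation makes the result invariant
to any per-gene monotone transform of the abundance unit, so counts-derived
and FPKM-derived TPM behave identically. Second order: for a pair (i, j),
the Pearson correlation of profile rows C<sub>i·</sub> and C<sub>j·</sub>
after deleting columns i and j from both. Removing the self-columns keeps
the trivial C<sub>ii</sub> = 1 entries from inflating the profile
similarity; the diagonal of the output is *defined* as 1 rather than
computed. The implementation is closed-form — row sums, squared row sums
and the Gram matrix CCᵀ give every pair's censored covariance at once — and
is tested to agree with an explicit per-pair double loop to 1e−10.

Degenerate inputs are hard errors rather than silent NaN: constant genes
(undefined correlation) abort with the offending gene ids, as do constant
profiles after column removal. Values are clipped to [−1, 1] and the matrix
symmetrised to absorb float round-off (≤ 1e−15).

The *coalescence score* of a gene set is the mean off-diagonal association
among its members: 1 for identical behaviour, ≈ 0 for unrelated genes.
Gene clustering uses distance 1 − association with average linkage;
sample clustering uses Euclidean distance on z-scored expression. The 2-D
embedding is UMAP on association-profile rows with a fixed seed
(n_neighbors capped at n_genes − 1); tests assert neighbourhood properties
only, never coordinates.

## Unit conversions and preprocessing

counts → TPM divides by effective transcript length, normalises each sample
to rate share, and scales to 10⁶; FPKM → TPM is the pure within-sample
rescaling. "log" means natural log with a +1 pseudocount throughout.
Duplicate gene ids are suffixed ".1", ".2" in file order (never summed);
all-zero genes can be dropped with `filter_zero_genes`. TPM columns sum to
10⁶ within 1e−6 relative after any conversion.

## Scoring and stratification

The sum-log score is Σ ln(TPM+1) over the set; 0–100 scaling is min-max
across the cohort (error on constant scores). The mean-z score standardises
each gene across samples (ddof = 1) and averages within the set. Cuts use
type-7 (linearly interpolated) quantiles with *strict* above/below
membership. This convention is pinned because it uniquely reproduces both
extreme-group sizes of a 208-sample cohort: 52 above the 75th percentile
and 21 above the 90th. Ties lying exactly on a cut raise an error listing
the tied samples — reproducibility over convenience. Four-way groups
combine two independent HIGH/LOW calls at the same percentile (default
extreme quartiles); any MID call makes the sample UNASSIGNED. All
stratifications are invariant to strictly monotone transforms of the
scores.

## Statistics

Correlations come from scipy (Spearman default; Pearson by flag), with
BH-FDR (statsmodels step-up) applied within one analysis family at a time —
one matrix's upper triangle, one DE run — never pooled across families.
Mann-Whitney uses exact enumeration when both groups are ≤ 20 and tie-free,
the tie-corrected normal approximation otherwise. Differential expression
contrasts extreme-quartile groups: logFC is log₂ of (mean TPM + 1) ratios
(base-2 with pseudocount 1 is the field convention and is stable at zero
expression), p per gene by Mann-Whitney, q by BH over all genes, and the
significance flag applies q < 0.001 and |logFC| > 1.5. Ranks order genes by
signed −log₁₀(q), logFC breaking ties. The separate "−log₁₀ FDR > 20"
display cut is a plotting filter, not a correctness rule, and is exposed as
an optional threshold only.

## Enrichment

The enrichment score is the signed extremum of the weighted KS running sum:
+|stat|ʷ/Σ<sub>hits</sub>|stat|ʷ at set members, −1/(N−N<sub>hits</sub>)
elsewhere, with weight w = 1 by default (w = 0 gives the unweighted
statistic). If all hit statistics are exactly zero the hit increments fall
back to 1/N<sub>hits</sub>. The leading edge is the set members at or
before (after, for negative ES) the extremum. The permutation null is
either random same-size gene sets on a fixed ranking (preranked input) or
label permutations with per-permutation re-ranking by the signal-to-noise
statistic (expression + two-group input; sd floored at max(0.2·|mean|,
0.2)). NES divides each ES by the mean |permuted ES| of matching sign; FDR
is the classic ratio of same-sign tail fractions of pooled permuted NES
versus observed NES, capped at 1. Runs are bit-identical for a fixed seed.

## Survival

Real-world OS from claims: day 0 is treatment initiation; a gap of
*strictly more than* 100 days between the last claim and the data cutoff
imputes death at the last claim date, otherwise the patient is censored at
the last claim. Both the strict boundary and the death-at-last-claim
convention are pinned choices. Months are days/30.44. Kaplan-Meier, the
log-rank test and Cox regression are backed by lifelines; the median OS is
the first time survival reaches ≤ 0.5 and is reported as not reached (None)
otherwise. Cox uses Efron tie handling — the only method lifelines
implements, and the more accurate one with monthly-resolution ties; no
Breslow option is offered. Group comparisons are univariate by design
(subset-and-refit per biopsy site, histology or hormone status); no
multivariable adjustment is attempted.

## Synthetic cohorts

Expression is a Gaussian copula: a latent normal with block target
correlation — module block (rho 0.1/0.4/0.8 across benign/primary/
metastatic), SHR block (within 0.5; cross to module 0.1/0.3/0.5, scaling
with stage because a flat 0.5 cross is not PSD against a 0.1 module
block), AR block (within 0.5, cross 0 by default), and a weak equicorrelated
background (rho 0.2) emulating the global co-expression programs of real
transcriptomes — exponentiated to log-normal and closed to TPM. Targets are
eigenvalue-checked at config construction; invalid combinations fail fast.
Per-gene log-means are N(2, 1) and the latent log-sd is 1. The log-mean
spread is deliberately moderate: in a closed panel of a few dozen genes a
single very abundant gene dominates the TPM denominator and injects
compositional correlation that real 20k-gene transcriptomes do not show.
Stage sample sizes default to 245/493/208, mirroring typical public
benign/primary/metastatic cohorts.

Because exp() is monotone, latent correlations survive as Spearman
correlations (attenuated slightly, ≈ (6/π)·asin(ρ/2)); tests therefore use
a ±0.07 tolerance at n = 500. Known limitations: no batch effects, no
tumour purity, no heavy-tailed marginal shapes beyond log-normal, and the
TPM closure of a small panel leaves a small positive association offset
among all genes (vanishing by ~150 genes) — so passing tests demonstrate
method correctness on realistic covariance structure, not distributional
realism of any specific dataset.

Survival generation: exponential death times per group at monthly hazards
whose medians (ln 2/rate) default to 40.4, 21.3 and 9.4 months for the
protective (module-high/AR-low), adverse (module-low/AR-high) and
neuroendocrine groups, with 30 months for the remaining groups; uniform
accrual over 36 months and a cutoff 84 months later; claims every 30 days.
The recorded (os, event) are the *claims-rule view* of the latent death
time: a repository cannot observe a death within the 100-day gap of its
cutoff, so such patients are recorded as censored at last contact, exactly
as in real claims data. This makes the imputation round-trip exact by
construction while keeping the latent hazard structure visible to Cox and
log-rank (the boundary affects only deaths in the final 100 days of
follow-up). Pure parameter-recovery simulations (`simulate_survival`) use
latent times directly with independent exponential censoring tuned to the
requested censored fraction.

## Problem sizes in tests and the acceptance script

Desk-scale sizes are used throughout: association oracles on ≤ 12 genes ×
≤ 15 samples (50 fixtures), staged module recovery on 30 genes × 300
samples over 20 (tests) or 10 (script) generator seeds, GSEA on a
1,000-gene ranking with 1,000 permutations, Cox recovery at 1,000 per arm
over 20 replicates, and log-rank calibration over 500 (tests) or 200
(script) null replicates. These sizes give Monte-Carlo error comfortably
inside the asserted tolerances.
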