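# Methods

This note records the models, numerical choices, and limitations behind
each var2func module, and what the synthetic generators do and do not
emulate.

## Linkage disequilibrium (`ldproxy`)

For two biallelic loci with "1"-allele frequencies p_A, p_B and joint
haplotype frequency p_AB, r² = D²/(p_A(1−p_A)p_B(1−p_B)) with
D = p_AB − p_A·p_B. From phased haplotypes all quantities are plug-in
sample frequencies. From unphased 0/1/2 genotypes the four haplotype
frequencies are estimated by EM: only double heterozygotes are
phase-ambiguous, and the E-step splits them between the coupling (11/00)
and repulsion (10/01) resolutions in proportion to f11·f00 vs f10·f01.
Convergence tolerance is 1e-10 on the max frequency change, at most 1000
iterations; non-convergence returns the last iterate with a flag rather
than raising. A sample consisting entirely of double heterozygotes is
non-identifiable (the likelihood is symmetric in coupling/repulsion); the
result is flagged `identifiable=False`. On phase-unambiguous data
(no double heterozygotes) the EM solution equals the phased answer
exactly, which is the basis of the oracle test.

Proxy selection uses a strict inequality (r² > threshold, default 0.8),
with an `inclusive` flag for ≥. Monomorphic sites in a region scan get
NaN r² and a warning instead of an error, so one bad site does not abort
a scan.

## Chromatin evidence (`chromatin`)

Variants are 1-based genomic positions; peaks are 0-based half-open BED
intervals; a variant overlaps a peak iff start ≤ pos−1 < end. The
conversion lives in exactly one function (`overlaps`) so the off-by-one
convention cannot drift. Overlap queries go through an interval tree per
experiment and chromosome; a naive all-pairs scan is kept in the test
suite as an oracle and the two must agree exactly. Intervals within an
experiment are merged on construction; merging never changes any
variant's overlap flag. Experiments from the same cell line count
separately in support totals.

The ranking key — total support desc, then ATAC support, then TF-ChIP
support, then genomic position asc — is an explicit, recomputable
stand-in for narrative prioritisation; all counts it sorts on are
returned, so a user can re-rank with any other key.

## Motif scoring (`motif`)

A PWM column probability vector gets a pseudocount of 0.01 added to every
entry and is renormalised before taking log₂ odds against the background
(uniform by default, overridable), so no cell is −∞. A window's score is
the sum of per-position log-odds; scanning takes the maximum over all
windows of both strands. `N` bases contribute 0 (the background score).
The normalised affinity of a score s is a = (s − s_min)/(s_max − s_min),
where s_min/s_max are the PWM's attainable per-column minimum/maximum
sums; the allele effect is delta = a_alt − a_ref ∈ [−1, 1], classified as
loss (≤ −0.1), gain (≥ +0.1), or neutral. Each allele is scored by its own
best window — the motif need not stay anchored at the variant. This
normalisation is this package's own scheme; only the sign and the
thresholded classification are comparable to affinity scores produced by
other tools, never the magnitude.

Enrichment uses an empirical null of n_perm (default 10,000) windows
sampled uniformly from background sequences, with the add-one p-value
(1 + #{null ≥ obs})/(n_perm + 1), which is never zero and is monotone
non-increasing in the observed score. A permutation null was chosen over
a parametric background model because it makes no distributional
assumption and its calibration is directly testable (the suite checks the
type-I error at 0.05 over 200 null replicates against the binomial 99%
band).

## Association and meta-analysis (`assoc`)

HWE is the 1-df goodness-of-fit chi-square against expected counts
(np², 2npq, nq²) at the estimated allele frequency; monomorphic input is
trivially in equilibrium (p = 1, warning). The allelic OR uses the 2×2
cross-product with Woolf SE √(Σ 1/cell), applying the Haldane-Anscombe
+0.5 to all cells only when some cell is zero. Printed-summary inputs are
reconstructed as round(2·N·MAF) minor-allele counts; this rounding is the
source of last-digit differences from published ORs (a published OR also
reflects covariate adjustment on the real genotypes, which reconstructed
counts cannot reproduce). CIs use z = 1.959964 rather than 1.96 so that
CI → SE → CI round-trips printed values to more digits.

Logistic association fits status ~ dosage + covariates by Newton-type
iterations (statsmodels, tol 1e-8, ≤ 100 iterations); under within-group
Hardy-Weinberg sampling the dosage log-OR equals the allelic log-OR, which
links the two estimators in tests. Complete separation yields a flagged
non-converged result; constant or collinear covariates are dropped with a
warning. Meta-analysis is fixed-effect IVW only (β̂ = Σwβ/Σw,
SE = 1/√Σw, w = 1/se²); Cochran's Q and I² are reported for inspection
but no random-effects model is fitted.

## eQTL (`eqtl`)

The Wilcoxon-Mann-Whitney test uses the exact U null distribution when
both groups have ≤ 12 observations and no cross-group ties, otherwise the
normal approximation with tie and continuity corrections. The default
contrast set is {0 vs 2, 0 vs 1, 1 vs 2, 0 vs 1∪2} with group medians
reported; no multiple-testing correction is applied across contrasts of a
single gene (a flag in downstream code can add one; the design here
reports all contrasts transparently).

## Hi-C interaction calling (`hic`)

Contacts are stored as canonical i ≤ j triplets at fixed resolution
(default 10 kb). The expected count at distance d (in bins) is the
per-distance mean where at least `min_pairs_per_distance` (default 10)
pairs exist, and otherwise comes from a log-log linear fit
count ≈ c·d^(−α) over the well-populated distances; α is reported. P-values
are upper-tail Poisson, P(X ≥ obs) at the expected mean, BH-adjusted
across all tested (stored, off-diagonal) pairs; significance requires
q ≤ 0.05 and observed/expected ≥ 2, each rule independently switchable
since studies apply them separately. The Poisson likelihood is a
deliberate simplification of spline-prior binomial callers: its contract
here is planted-signal recovery on synthetic decay matrices (checked over
50 seeds), not concordance with any external caller. Matrix balancing,
TAD calling, and binary matrix formats are out of scope; the synthetic
generator produces uniform coverage, so raw counts are comparable.

## Lipidomics (`lipidomics`)

Missing values are imputed as 1/5 of the lipid's minimum observed
positive value (the convention of common metabolomics suites), then
log₁₀-transformed and Pareto-scaled ((x − mean)/√sd per lipid) for the
multivariate analysis. Univariate tests and fold changes operate on raw
imputed concentrations: log₂FC = log₂(mean treated/mean control) is
therefore invariant to the scaling. Test routing runs the
D'Agostino-Pearson omnibus test on each group and uses Welch's t only
when both groups pass at α = 0.05; the omnibus statistic is undefined
below n = 8 per group, so smaller designs — including the four-replicate
default, which mirrors a typical targeted-lipidomics design — are routed
to Welch's t deliberately rather than guessing a different intent.

The BKY two-stage FDR runs BH at q′ = Q/(1+Q); with 0 < r1 < m rejections
it reruns BH at q′·m/(m−r1). The implementation is independent of
statsmodels' `fdr_tsbky`, which serves as a cross-check oracle in the
tests. Volcano significance is p < 0.05 and |log₂FC| > 0.58 (≈1.5-fold).
Class totals sum imputed concentrations per class per sample and use
Welch's t. PLS-DA VIP comes from a NIPALS PLS1 fit against the centred
binary group indicator with unit-norm weight vectors;
VIP_j = √(p·Σ_a SSY_a·w²_aj / Σ_a SSY_a) where SSY_a = q²_a·t_aᵀt_a, so
mean(VIP²) = 1 identically. Components whose weight norm or score
variance falls below 1e-12 terminate extraction.

## Synthetic generators (`synth`)

Every generator draws from `numpy.random.default_rng([offset, seed])`
with a fixed per-generator offset, so identical arguments give
byte-identical outputs and adding a generator never perturbs the others'
streams.

Defaults are the study conditions of the worked scenario: cohort sizes
2101/4202 with MAFs 0.46/0.41, a (29 ATAC, 5 H3K27ac)-of-(30, 6) planted
chromatin support profile, 50-bp allelic windows around a planted motif,
an 89-subject eQTL cohort, a 200-bin 10-kb contact matrix with decay
exponent 1 and a fivefold loop, and a 543-lipid panel (AC 40, Cer 38,
CE 22, DG 44, FA 10, glycerophospholipids 98 split as LPC 14 / PCaa 49 /
PCae 35, HexCer 34, SM 15, TG 242) with four replicates per group at
CV 0.1. The glycerophospholipid split across its three subclasses is a
package choice (only the class total is externally fixed). Case ages are
uniform integers 0-10 years and sex is balanced, drawn independently of
genotype; real cohort demographics are not modelled.

What the generators deliberately do **not** emulate: read-level
sequencing, realistic LD structure from population panels, batch or
plate effects, peak-width/signal distributions, non-MCAR missingness, and
correlated lipid co-regulation. Passing tests on these inputs therefore
demonstrate correctness of the estimators and calibration under the
stated models, not robustness to every artefact of real data.

Expression values are intercept (10) + β·dosage + Gaussian noise, clipped
at zero to keep FPKM-like non-negativity; with the default intercept the
clip is essentially never active, and the WMW test is invariant to it as
a monotone transform.

## Problem sizes in the test and acceptance runs

The suite verifies calibration and recovery at sizes chosen to keep the
whole run fast while leaving comfortable statistical margins: enrichment
calibration over 200 null replicates at 499 permutations, Hi-C loop
recovery over 50 seeds (20 in the acceptance script), BKY null FDR over
1000 simulations of 500 p-values, logistic recovery over 200 simulated
cohorts at full 6303-subject size, and lipid planted-effect recovery over
200 seeds (50 in the acceptance script). Larger sizes change none of the
conclusions; all thresholds are the ones stated with each property.

## Known limitations

- The EM r² returns a point estimate only; no CI or LD pruning.
- The logistic fit does not implement Firth correction, so separated
  designs produce flagged results rather than penalised estimates.
- The Hi-C caller tests only stored pairs; truly unobserved (zero-count)
  pairs at a distance are not imputed into the FDR universe.
- PLS-DA VIP is computed for two classes (PLS1); multi-class designs are
  out of scope.
- Printed-summary reconstruction cannot recover covariate-adjusted ORs
  exactly; agreement is to rounding, as documented in `assoc`.
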