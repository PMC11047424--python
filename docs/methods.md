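# Methods

This note records the statistical model behind `targetmr`, the defaults and
why they were chosen, what the simulator does and does not emulate, and the
design decisions taken where the underlying conventions are genuinely open.

## Generating model of the simulator

All simulation happens on the standardized-genotype scale: genotypes are
treated as having unit variance, so a marginal regression of a trait on one
SNP in a cohort of size n has standard error 1/√n, and sparse causal
effects **b** over a region with LD correlation matrix **R** induce true
marginal effects **Rb**. One cohort's observed effect vector is a single
draw

  β̂ ~ MVN(Rb, R/n),

the standard asymptotic distribution of marginal GWAS estimates under LD.
LD is AR(1): r(i, j) = ρ^|i−j|, with SNPs on a uniform 1-based grid over a
200 kb cis region by default. A study bundle ties three independent cohorts
(two-sample design; no sample overlap) into the chain

  exposure →a→ mediator →b→ outcome, plus a direct exposure→outcome path,

so the total exposure effect is θ = direct + a·b by construction, and the
mediator additionally has its own causal variants (default: one SNP at
index 3m/4 with effect 0.15) placed far enough from the exposure's causal
SNP (index m/4) that AR(1) decay makes them effectively uncorrelated.
Mediator-specific effects reach the outcome multiplied by b, as the chain
requires.

Default study conditions: m = 50 SNPs, ρ = 0.5, one exposure causal SNP
with effect 0.3, n = 10⁴ per cohort. These were chosen so the selected
instrument has F ≈ (0.3·√n)² ≈ 900 — comfortably a "strong instrument"
regime — while a per-SNP z of 0.3·√n/√n·... remains realistic for cis-QTL
of expression traits. Colocalization scenarios use m = 100 and a causal
effect z_target/√n with z_target = 8, a clearly genome-wide-significant
signal.

What the simulator deliberately does **not** emulate: case-control outcomes
are generated on the linear (liability) scale and only *labeled*
case_control — the label selects the colocalization prior SD; there is no
logistic sampling, so the closed-form truth θ survives to the recovery
tests. There is no allele-frequency-dependent power (se = 1/√n for every
SNP), no haplotype or recombination structure beyond AR(1), no sample
overlap, and no winner's-curse correction. Passing recovery tests therefore
demonstrates correctness of the estimators under their own asymptotic
model, not robustness to the additional messiness of real GWAS
(stratification, imputation error, mismatched LD reference panels).

## Instrument selection

F = (β/se)² is the squared z of the SNP–exposure association; instruments
with F < 10 are excluded (F = 10 itself passes). All p-value thresholds are
strict inequalities. eQTL panels contribute exactly one instrument — the
most significant cis-SNP below 1×10⁻⁴, ties broken by smaller position then
lexicographic id — so LD clumping does not apply to them. pQTL panels are
thresholded at p < 0.05 and clumped greedily: repeatedly promote the
remaining SNP with the smallest p to index SNP and discard SNPs within the
window (default 10,000 kb, the conventional clumping default) whose r² with
it exceeds 0.001. Greedy clumping by ascending p is the standard semantics;
the output is pairwise r² ≤ cutoff by construction and invariant to input
row order, and both properties are asserted in tests against an
independently formulated oracle (walk SNPs in p order, keep one unless it
conflicts with an already-kept SNP — an equivalent but differently computed
characterization).

The lenient pQTL threshold is implemented exactly as stated upstream, with
the F filter as the only additional guard. The confounder screen emulates a
PhenoScanner query from a lookup table: any recorded association with an
outcome disorder at p < 5×10⁻⁸ removes the instrument, with the phenotype
logged.

## Harmonization

Records match on snp_id. Swapped effect/other alleles negate the outcome
beta. Palindromic SNPs (A/T, C/G) cannot be oriented by labels; they are
oriented by allele frequency when both eafs are informative (outside
[0.42, 0.58], the common ambiguity window) and dropped otherwise — also
when either eaf is missing, the conservative choice. Incompatible allele
sets are dropped with a warning. Harmonization is idempotent, and all MR
estimates are invariant (to 1e-12) under relabeling either input's alleles
with negated betas.

## Estimation

Wald ratio: β = β_y/β_x, se = se_y/|β_x| — the first-order delta
approximation, which ignores var(β_x) and is anti-conservative at low
instrument strength; the F ≥ 10 gate is what keeps it adequate (tests check
it against the Monte-Carlo sd of the ratio at F > 100, and the acceptance
suite checks 95% CI coverage lands in [0.92, 0.98] at the default
conditions — it sits near 0.93–0.95, the small deficit being exactly the
ignored var(β_x) term). IVW is fixed-effect: with so few instruments per
target a random-effects variance estimate would be noise; the fixed-effect
choice is recorded as the default and is algebraically identical to WLS of
β_y on β_x through the origin with weights 1/se_y² (tested against
statsmodels). P-values are two-sided normal, floored at 1e-300 rather than
truncated to zero. ORs and CIs are exp-transformed from the log scale, so
the OR is always the geometric mean of its CI bounds; the Bonferroni
threshold is α divided by the product of the multiplicity counts.

## Colocalization

Per-SNP log ABFs use the Gaussian-prior closed form ½[log(1−r) + r·z²],
r = W/(W+V), equal to the log ratio of the marginal likelihood N(β̂; 0,
V+W) to N(β̂; 0, V); the tests verify this against numerical quadrature of
the Bayes-factor integrand to 6 significant figures. Prior effect SDs are
0.15 (quantitative) and 0.2 (log-OR, case-control) — the defaults of the
established ABF colocalization method — with association priors p1 = p2 =
1×10⁻⁴ and p12 = 1×10⁻⁵. Hypothesis masses are assembled entirely in log
space with log-sum-exp; H3 (two distinct variants) uses the exact identity
Σ_{i≠j} = exp(L1+L2) − exp(L12) computed as a log-difference and clamped to
zero mass when numerically non-positive — with a single shared SNP this
yields PP.H3 = 0 exactly. The window is the ±100 kb neighbourhood
(inclusive on both ends, positions 1-based) of the top SNP of trait 1,
which is the disorder GWAS; anchoring on the GWAS top SNP matches the
trait-ordering convention adopted throughout and is flagged here because
the alternative (anchoring on the QTL) is equally defensible. The p12
sensitivity table recomputes posteriors over a log-spaced grid reusing
cached ABFs; only the H4 mass scales with p12, so PP.H4 is monotone in it.

## Mediation

The indirect effect is the product of coefficients a·b with delta-method
SE √(a²se_b² + b²se_a²); the product form is the standard two-step MR
estimator and, unlike the difference method, is directly testable by
recovery against the simulator's known a·b. Mediator instruments are
selected at genome-wide significance (5×10⁻⁸) with the same clumping
machinery — a conventional choice, since upstream criteria for mediator
instruments are typically unstated. Step 2 additionally removes mediator
SNPs in LD (r² above the clumping cutoff) with the exposure's instruments:
under the simulated chain the exposure's causal locus produces a
genome-wide-significant signal in the mediator GWAS whose mediator→outcome
ratio is θ/a rather than b, and admitting it biases the step-2 estimate
upward (to roughly 80% proportion mediated under the default chain, against
a true 66.7%). Excluding exposure-correlated SNPs is the two-step analogue
of guarding against exposure-driven pleiotropy and restores centered
recovery. Proportions are reported unclamped — they may be negative
(suppression) or exceed 100% — and the mediating/suppressing/
not_significant label (both steps p < 0.05 required) carries the
interpretation.

## Pipeline

Colocalization and mediation run only for MR results passing the
configured Bonferroni threshold (a `force_all` flag overrides). Failures
are isolated per combination: a degenerate panel logs an error and is
skipped. All stage seeds derive deterministically from the single config
seed via seed-sequence spawning, so identical configs produce byte-identical
output TSVs. The run log records the seed, every threshold, and per-stage
record counts, which are non-increasing along the filter chain.

## Numerical choices and degenerate inputs

- LD matrices are symmetrized by averaging when asymmetry ≤ 1e-8 and
  rejected beyond that; diagonals must be within 1e-6 of 1.
- Cholesky factorization of R adds a 1e-10 ridge for positive-definiteness
  at high ρ.
- Ties in p-value selection always break by (position, snp_id) so every
  selection is deterministic.
- A zero exposure beta invalidates a Wald ratio; IVW excludes such pairs
  with a warning and errors only when none remain.
- Summary-statistics files are UTF-8 TSV with `.` for missing and
  shortest-repr floats, so write→read is a lossless identity (property
  tested).

## Problem sizes in the validation suite

Recovery and calibration checks run at the study conditions stated above:
500 replicates for CI coverage and type-I error, 200 replicates for
mediation recovery and for the null-chain gate, 1000 random panels of ≤ 8
SNPs for the clumping oracle, and an 84-point (β, se, W) grid for the ABF
quadrature check. The full test suite completes in well under a minute on
one CPU.

## Known limitations

No MR-Egger, weighted-median, Steiger filtering or heterogeneity
statistics; no multivariable MR (the mediation decomposition is strictly
two-step univariable); no multi-causal-variant colocalization (the
single-causal-variant assumption is inherited from the ABF framework); no
VCF/BGEN parsing, liftover, or reference-panel LD estimation — LD arrives
as a precomputed correlation matrix. Case-control traits are handled on
the log-OR scale throughout; no liability-scale conversion is attempted.
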