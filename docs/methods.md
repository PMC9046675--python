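# Methods

This note records the statistical model behind `metasynopsis`, the
conventions and thresholds it fixes, what the synthetic-data generator
does and does not emulate, and the numerical choices a maintainer would
want to know about.

## Effect harmonization

Every study contributes a point estimate θ and standard error on a common
scale: the log odds ratio per copy of the designated effect (minor)
allele for binary outcomes, or a standardized mean difference (SMD) for
quantitative traits. Four input forms are resolved, in priority order:

1. a reported (θ, SE) pair — used as-is;
2. a ratio with 95% CI — θ = ln OR, SE = (ln U − ln L)/(2z), z = 1.959964.
   The z quantile is pinned to six decimals so CI-derived SEs reproduce
   identically across platforms. A point estimate outside its own CI is
   tolerated with a warning (the CI defines the SE);
3. genotype counts — alleles are counted (dose-2 homozygotes contribute
   two), the cross-product OR is formed on the 2×2 allele table, and
   SE = √(1/a + 1/b + 1/c + 1/d), with a 0.5 continuity correction added
   to every cell when any cell is zero. Allele counting is the additive
   model's estimator and is exactly consistent with the generator's
   multiplicative per-allele odds (see below);
4. per-genotype means — Cohen's d with the df-weighted pooled SD and
   SE(d) = √((n₁+n₀)/(n₁n₀) + d²/(2(n₁+n₀))). The Hedges small-sample
   correction exists behind a flag but is off by default, since plain SMD
   is the convention in the synopses this package reproduces. Co-dominant
   contrasts (dose 2 vs 0, dose 1 vs 0) are both available; the hom
   contrast is the default.

Orientation to the effect allele negates θ, inverts ratios with swapped
CI bounds, and dose-reverses genotype counts and group stats; it is an
involution and preserves |θ|, SE, p and totals exactly. Which allele is
"minor" is configuration (a per-variant map), not recomputed from data:
minor-allele frequency is population knowledge that study rows cannot be
trusted to agree on.

## Pooling and heterogeneity

Fixed effect: θ̂ = Σwθ/Σw, w = 1/SE², SE(θ̂) = (Σw)^(−1/2).
Cochran's Q = Σw(θ − θ̂)², df = k − 1, I² = max(0, (Q − df)/Q)·100 (the
Higgins form, not the df-scaled variant). DerSimonian–Laird:
τ̂² = max(0, (Q − df)/C), C = Σw − Σw²/Σw; random-effects weights
1/(SE² + τ̂²). Q, df and I² are always reported from the fixed-effect
weights regardless of the selected model.

Model selection follows the synopsis rule: random effects when I² ≥ 50%
(boundary inclusive), fixed effects below. Pooled p-values are Wald-type
normal approximations, 2(1 − Φ(|θ̂|/SE)), with no Knapp–Hartung
adjustment; CIs are exponentiated for ratio scales. Meta-analysis
requires at least three analyzable datasets; smaller collections are
retained but flagged ineligible. A single pre-pooled record (e.g. a GWAS
consortium estimate) passes through labelled `not_pooled` with no
heterogeneity statistics.

## Bias tests and sensitivity analyses

Egger's test regresses θᵢ/SEᵢ on 1/SEᵢ by OLS (statsmodels) and tests the
intercept with a t distribution on k − 2 df. Begg's test forms deviates
vᵢ = (θᵢ − θ̂_FE)/√(SEᵢ² − SE(θ̂_FE)²) — always against the fixed-effect
pooled value, the standard construction — and correlates them with the
variances by Kendall's τ (scipy), using the exact pair-permutation
distribution for k ≤ 8 without ties and the normal approximation
otherwise; ties fall back to τ-b and are flagged. Both tests need k ≥ 3
and are read at two-tailed p < 0.10. All-equal deviates (a constant
effect) short-circuit to τ = 0, p = 1.

The sensitivity suite re-pools k leave-one-out subsets, the subset
without the flagged first positive report, and the subset without studies
whose control genotypes violate HWE at p < 0.05 (configurable). An
association is *robust* when every evaluable re-analysis stays
significant with an unchanged direction; arms that cannot be evaluated
(no flag carried, or fewer than two records left) are noted and excluded
from the verdict rather than counted either way. Studies whose exclusion
destroys significance are named as drivers.

## Evidence grading

Venice letters: *amount of evidence* is graded on the total effect-allele
count among cases and controls (A above 1 000, B from 100, C below),
taken from genotype counts when present or 2·MAF·N otherwise;
*replication* on I² (A below 25% with ≥ 3 datasets, B to 50%, C above);
*protection from bias* is C when either bias test fires at 0.10 or the
sensitivity verdict is fragile, A when both tests are computable and
clean and the suite is robust, B in between. Any axis without usable
input is left ungraded and rendered "-"; an ungraded axis blocks
*strong* (which needs three A's) but does not force *weak* (which needs
a C). All thresholds live in configuration; the letter → category map is
strong = AAA, weak = any C, moderate otherwise.

FPRP = α(1 − π)/(α(1 − π) + (1 − β)π) with prior π = 0.05. Power is the
two-tailed Wald power to detect OR₁ at the *observed* α:
1 − β = Φ(|ln OR₁|/SE − z_{1−α/2}) + Φ(−|ln OR₁|/SE − z_{1−α/2}), with
z computed via the survival-function inverse so that extremely small α
(GWAS-scale p-values) stay finite. Only |ln OR₁| enters, so the
reciprocal convention for protective effects is automatic. OR₁ defaults
to 1.2: of the conventional targets, 1.2 is the one under which the
packaged tables' printed FPRP values reproduce from their printed inputs
(1.5 does not), and it is configurable. The observed α can be the
reported pooled p (`reported_p`, default) or the CI-implied level
2(1 − Φ(|ln OR|/SE)) (`ci_implied`); both are supported because printed
p-values are rounded. Categories: FPRP < 0.05 strong, < 0.20 moderate,
otherwise weak, with boundary values assigned to the less-noteworthy
side (the published rule uses open inequalities that leave boundaries
undefined). The final label shifts the Venice category up one level for
strong FPRP evidence, down one for weak, saturating at the ends — so the
final label never moves more than one level from the Venice category.

Grading runs only for associations with pooled p < 0.05; non-significant
rows keep their meta-analysis block only.

Two rows of the packaged tables carry printed cumulative labels that the
stated combination rule cannot produce (rs7529229/atrial fibrillation,
printed Weak where the rule gives Moderate; rs2228145/fibrinogen, printed
Moderate where the rule gives Strong). They are preserved verbatim and
reported as anomalies; the replay test asserts 39/41 agreement rather
than papering over them. Similarly, the printed FPRPs for two further
rows (rs2228145 with rheumatoid arthritis and with type-1 diabetes) are
not reproducible from their printed OR/CI/p under either α convention
and are excluded from numerical FPRP checks.

## Phenome-wide stage and LD pruning

The phenome-wide scan is offline: it consumes a pre-extracted summary
table and flags rows with p below FWER/m (m = table size); with the
packaged 778-phenotype configuration and FWER 0.05 the threshold is
6.43×10⁻⁵. LD pruning thresholds the r² matrix strictly above the cutoff
(default 0.80), takes connected components (scipy), and reports clusters
in input order with the first member as representative (a named variant
can be forced to the front). Strict inequality and first-in-order
representation make the operation deterministic and
permutation-invariant up to relabeling.

## Synthetic-data generator

For study i: θᵢ ~ Normal(θ, τ²); control genotypes are multinomial with
HWE proportions ((1−q)², 2q(1−q), q²) at minor-allele frequency q; case
genotype probabilities are the HWE weights tilted by exp(θᵢ·dose). Under
this multiplicative model the case allele odds are exactly exp(θᵢ) times
the control odds, so the allele-count OR is a consistent estimator of the
generative per-allele OR — verified at n = 10⁶ within 1%. Genotype
counts, the derived (θ, SE), and the control HWE p are all written into
each record, so the pipeline exercises the same conversion path as
published counts.

Defaults are chosen once to mirror the study census of the synopsized
literature (about five datasets per meta-analysis; case counts from
tens to tens of thousands with mean in the low thousands; control counts
up to the hundreds of thousands; MAFs 0.35–0.45): k = 5, q = 0.35, cases
uniform on [100, 10 000], controls on [500, 50 000], θ = 0, τ² = 0.

Small-study bias is injected by *suppression of null small studies*: in
the top tercile of SEs, a study that is not one-sided significant at 0.05
in the true direction is, with probability γ, replaced by redraws of the
same-size study until it is. γ = 0 is the identity; γ = 1 with a wide
funnel (k = 20, θ = 0.1, case/control counts on [25, 2 500]) drives
Egger rejection above 60% while clean collections stay near the nominal
10% — the power scenario the test suite measures. Suppressing only
sign-contradicting estimates was considered and rejected: it produces
too little asymmetry for any test to detect reliably at k = 20.

The quantitative generator shifts genotype-group means by SMD·σ/2 per
allele dose (so the hom-vs-wild contrast equals the configured SMD),
draws observed means with σ/√n noise and observed SDs from the scaled
χ² sampling distribution. Tiny genotype groups are floored at n = 2 so
every group has a defined variance.

What the generator does **not** emulate: covariate adjustment and
confounding, population stratification or ancestry mixtures, LD between
variants, genotyping error (HWE violations arise only by sampling), and
outcome misclassification. Passing tests therefore demonstrate that the
estimators recover the truth under the model's own assumptions — not
robustness to the failure modes of real literatures.

## Problem sizes and numerical conventions

Monte-Carlo checks in the test suite use 2 000 replicates for null
calibration of the pooled test (type-I error within [0.03, 0.07]), 500
replicates at k = 20 for recovery of θ = 0.2 and τ² = 0.03 (means within
±0.01), 500 + 500 replicates for Egger power/size, and 1 000 draws for
the generator's HWE rejection rate — sizes at which the whole suite runs
in well under a minute while Monte-Carlo standard errors stay a factor
of several below the asserted tolerances.

Other conventions: probabilities are clamped to [0, 1] where discrete
enumeration can overshoot by float epsilon; the exact HWE test uses the
likelihood-ordering (Wigginton-style) two-sided definition, validated
against the published worked value 0.593, and is the default below 200
subjects with chi-square above; duplicate (study, variant, outcome) keys
are a hard error listing the collisions; and report generation is pure —
identical inputs and configuration produce byte-identical TSV/JSON.
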