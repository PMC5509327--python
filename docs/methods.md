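# Methods

This note documents the statistical model, the defaults and the design
choices behind `genemeta`, and what the synthetic-data generator does and
does not emulate.

## Data model

Input is study-level, never subject-level. A case-control record carries
sample sizes, the named risk allele with its frequency, optional genotype
count triples ordered (hom-risk, het, hom-other), and an optional reported
OR with 95% CI (typically covariate-adjusted in the source study). A
quantitative-trait record carries the sample size, optional per-genotype
(n, mean, SD) trait summaries and/or a per-allele slope β with exactly one
of {SE, CI, p}. Records may name several variants (a study characterized
for two SNPs stays one record); tables filter by variant membership.

Validation is two-tiered. Structural invariants are hard errors: genotype
counts must sum to the stated n, CIs must bracket their point estimates,
SDs must be positive, frequencies must lie in [0, 1], study ids must be
unique. Whether a record carries *any* usable effect pathway is a soft
warning instead: published characteristics tables legitimately contain
rows whose effect estimates appear only in figures, and the pipeline logs
such rows as pathway "none" rather than refusing the table. The packaged
*G6PC2* tables are exactly of this kind — their per-study effects were
printed only as forest plots, so the fixtures support accounting,
subgroup membership, frequency pooling and attributable risk, but not
re-pooling of the published estimates.

The single frequency printed per case-control study is stored as the
control-group frequency. This is a documented ambiguity of such tables,
not a resolved fact; the optional `raf_case` column exists because
Hardy-Weinberg reconstruction of a 2×2 needs both group frequencies.

## Effect derivation

Pathway precedence for case-control records: reported OR/CI first (it
preserves the original adjustment), then genotype counts, then
HWE-reconstruction from case and control frequencies. Reconstructed
expected counts n·(f², 2f(1−f), (1−f)²) are kept fractional — rounding
would break exact recovery of f by allele counting. The per-study pathway
is logged so a mixed-pathway pool is always auditable.

Collapsed 2×2 tables with a zero cell receive the Haldane–Anscombe 0.5
added to every cell (configurable off; disabled it raises on degenerate
margins). The "additive" case-control contrast is the crude per-allele OR
from the allele-count 2×2 — no logistic dose model is fitted, matching
how crude per-allele ORs are derived from reconstructed frequencies in
this literature.

SMD defaults to Cohen's d; Hedges' g (J = 1 − 3/(4(n₁+n₀−2)−1), SE scaled
by J) is selectable. SE recovery uses the exact normal quantile
(1.959964… at 95%), not 1.96. The HWE χ² test has 1 df and no continuity
correction; monomorphic samples return χ² = 0, p = 1 with a flag.

## Pooling and heterogeneity

τ² is the DerSimonian–Laird moment estimator truncated at zero — the
default of the standard tool chains this package mirrors; no REML or
Paule–Mandel alternative in this version. ORs pool on the log scale, β and
SMD on the raw scale; CIs back-transform for reporting. Whenever Q ≤ df
the random-effects fit reduces exactly to the fixed-effect fit.

I² confidence intervals use the test-based interval on ln H with H
truncated at 1: SE(ln H) = ½(ln Q − ln df)/(√(2Q) − √(2df−1)) for
Q > df + 1, else √(1/(2(df−1))·(1 − 1/(3(df−1)²))) for df ≥ 2; for df = 1
with small Q neither form applies and the vacuous (0, 100) is reported.
Endpoints clamp to [0, 100]. This choice reproduces the interval shapes
customary in the applied literature (e.g. an upper bound near 90% for
three homogeneous studies).

H² is reported in two variants because both circulate under the same name:
the excess form max(0, (Q−df)/df), consistent with I²/(100−I²), is the
headline; the classical Q/df is always alongside. Printed H² columns in
source papers are occasionally inconsistent with their own I² under either
convention; the package computes, it does not imitate.

Single-study "subgroups" pass through with their own SE and undefined
heterogeneity. Subgroup output distinguishes k (records in the level) from
k_used (records that yielded an effect), so membership accounting works
even for characteristics-only tables. Pooled allele frequencies use
inverse-variance weights w = 2n/(f(1−f)) (binomial allele-count variance;
monomorphic studies excluded) or the unweighted mean.

Two-sided normal p-values throughout; no multiple-testing adjustment
across variants or genetic models, matching field practice for this kind
of analysis (noted, not endorsed).

## Bias diagnostics

Egger's test is the classic unweighted regression of the standardized
effect on precision; the intercept is tested against t(k−2). It requires
varying SEs — equal SEs make the predictor constant and raise a
degenerate-design error rather than returning a meaningless p. Begg's test
uses Kendall's τ between variance-stabilized deviations from the
fixed-effect pool and the study variances, with the continuity-corrected
normal approximation by default and exact permutation available for
k ≤ 8 (the exact path matches R metafor's `ranktest`). Variances
numerically at or below the pooled variance are floored at 1e-12. The
conventional p > 0.1 screening threshold is an annotation
(`suggests_bias`), never a filter.

## Attributable risk and power

PAR = (X−1)/X with X = (1+f(γ−1))², valid when the named allele is the
risk allele. When a pooled OR is protective (γ < 1) the complementary
allele is the risk allele: `orient_risk_allele` inverts γ and complements
f, and reports record the flip. For PAR the default pooled frequency is
the unweighted mean of study frequencies (the inverse-variance pool is
computed and reported alongside); with strongly varying study sizes the
two can differ materially, so both appear in the output.

Power uses closed forms, not likelihood machinery: for case-control
designs, expected case/control allele frequencies under HWE and
multiplicative penetrance at the stated prevalence (case frequency
fγ/(1+f(γ−1)); controls depleted of the risk allele as unaffecteds),
then the normal-approximation power of the allele-count log-OR Wald test;
for quantitative traits, the noncentral χ²(1, λ) tail with
λ = n·2f(1−f)·β²/σ². These are transparent approximations; agreement with
specific power programs' printed decimals is out of scope.

## Synthetic data

The generator emulates the random-effects structure the pipeline assumes:
per-study true effects θᵢ ~ N(μ, τ²), study frequencies and sizes uniform
on configurable ranges, genotypes under HWE.

*Case-control*: case genotype frequencies are population HWE frequencies
tilted by γ^dose (which is again HWE at fγ/(1+f(γ−1)); the prevalence
normalization cancels). Controls default to the population distribution
(`control_source="population"`), making the study-level allele-count
log-OR equal θᵢ exactly in expectation — the property the recovery tests
rely on. `control_source="unaffected"` instead samples disease-free
controls at the stated prevalence, as in a classic case-control design;
this is more literal but biases the allele OR upward relative to γ (about
+0.03 on the log scale at γ = 1.5), which matters only if γ is far from 1.

*Quantitative*: genotype counts are multinomial under HWE; per-genotype
sample means and SDs are drawn from their exact sampling distributions
(Normal, scaled χ²) around baseline + θᵢ·dose with residual SD σ. The
emitted per-allele slope and SE are algebraically identical to the
subject-level OLS fit on allele dose (verified in tests against
statsmodels on reconstructed subject data). When any genotype class has
fewer than 2 subjects — routine at frequencies near 0.97 — or σ = 0, the
study is emitted beta-only, since per-class SDs are then undefined;
resampling is not attempted because the rare-homozygote class is empty
with high probability and the rule must terminate.

Defaults: baseline trait 5.0 mmol/l (a typical normoglycemic fasting
glucose), residual SD 0.8 mmol/l, prevalence 8.8%. Presets: A
"g6pc2-fg-like" (k = 32, μ = 0.07 mmol/l per allele, τ = 0.01,
frequencies 0.6–0.97, n 500–5000) mirrors the shape of the large
rs560887/FG collection; B "null-symmetric" (μ = τ = 0, k = 15) supplies
the symmetric-funnel null for type-I-error checks of the bias tests; C
"hetero-or" (k = 15, μ = ln 0.96, τ = 0.05, per-group n 1000–4000)
mirrors a modest protective per-allele OR with real heterogeneity.
Scenario sizes were chosen so the full stochastic suite (200-replicate
coverage, 500-replicate type-I error) completes in seconds.

One integer seed determines everything; study i draws from the substream
keyed (seed, i), so increasing k extends a table without reshuffling
earlier studies, and identical seeds give byte-identical written tables.

What passing tests do *not* show: the generator has no publication-bias
selection mechanism (a censoring hook is out of scope), no linkage
between variants, no covariate structure behind "adjusted" ORs, no
population stratification, and uniform (not empirical) frequency/size
distributions. Recovery and coverage results therefore validate the
estimators under their own assumptions, not robustness to the ways real
study collections violate them.

## Orchestration

The pipeline derives effects per study (logging pathways), pools overall
and within the subgroup field, runs leave-one-out (flagging omitted
studies whose own estimate lies outside the parent CI), Egger/Begg and
funnel export, and optional PAR, per SNP × table × model cell; a failing
cell is recorded and skipped. Studies flagged as HWE-failing are retained
by default (matching how published collections handle them) with a config
switch to exclude. Outputs are plain CSVs plus a JSON manifest carrying
the config, its hash, the seed and the package version; reruns with the
same config are byte-identical (no timestamps anywhere in outputs).

## Known limitations

- DL confidence intervals use normal quantiles; for small k with large τ²
  they undercover somewhat (the k = 15 Gaussian check sits near 93–95%).
  Hartung–Knapp adjustment is deliberately out of scope.
- The packaged tables cannot reproduce published pooled effects (per-study
  estimates were printed only as figures); accounting, membership, pooled
  frequencies and PAR are what they support.
- Reported ORs with different adjustment sets are pooled as exchangeable,
  as is standard and as the source analyses did.
- Power formulas are approximations; no attempt is made to match any
  specific program's output digit-for-digit.
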