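# Methods

## Scope and data model

`metacred` synthesizes case-control genetic-association literatures at the
study level. The unit of input is one study's contribution to one
variant-cancer association: genotype counts `(common-homozygote,
heterozygote, rare-homozygote)` for cases and controls, or — when a source
publication reported only a summary — an odds ratio with its 95% CI. The
minor allele is the test allele throughout; a microsatellite allele is
represented as biallelic carrier/non-carrier counts. Records carry
publication year (for cumulative and first-published analyses), ethnicity
(African / Asian / Caucasian / other, for subgrouping) and a GWAS-replication
flag consumed by the bias grade.

When both genotype counts and a reported OR are available the pipeline
prefers the count-derived estimate (`prefer="counts"`, configurable),
because counts allow the allele-level and per-genotype contrasts, the HWE
test and the Harbord score to be computed consistently; reported-OR rows are
pooled via SE = (ln CI_high − ln CI_low)/(2·z₀.₉₇₅) and are excluded from
count-based procedures (Harbord, model-free, evidence amount), with the
exclusion counted and reported.

## Estimation and pooling

Per-study log ORs use the Woolf variance; the Haldane–Anscombe correction
(0.5 to all four cells when any cell is zero) is the default continuity
rule, matching the long-standing default of the meta-analysis software
family this workflow descends from. The fixed-effect estimator is
inverse-variance on the log-OR scale (a Mantel–Haenszel pooled OR is
available as an alternative); the random-effects estimator is
DerSimonian–Laird with the moment τ², no Knapp–Hartung adjustment —
deliberately matching the era of the catalogues this pipeline targets
rather than the newer REML/Paule–Mandel estimators.

Model selection is an explicit, manifest-recorded policy: random effects
when I² > 50% or Q-p < 0.10, fixed otherwise. Both thresholds are
configuration because published synopses typically state only that the model
was chosen "based on heterogeneity".

Single-study "pools" return the study itself with Q reported as 0 and
Q-p = 1 (Q is undefined at k = 1); I² is truncated at 0; τ² at 0. p-values
are floored at the smallest positive double to keep downstream logs finite.

The Hardy–Weinberg test defaults to the 1-df chi-square without continuity
correction; an exact conditional test (full enumeration of heterozygote
counts given allele counts, two-sided by cumulative probability of tables as
extreme or more) is available by flag. The HWE-violation threshold for
sensitivity exclusion is p < 0.05, configurable.

## Sensitivity, small-study bias, meta-regression

The sensitivity suite re-pools (i) leaving each study out, (ii) dropping the
first-published study (ties broken by year, then author, then study id),
(iii) dropping control-arm HWE violators. `stable` requires every variant to
keep the full-analysis direction and, when the full CI excludes 1, to keep
excluding 1.

The Harbord test regresses Z/√V on √V by unweighted OLS with the residual
variance estimated from the fit (t, k−2 df), per the test's original
formulation; it is skipped below `min_k = 3` studies with counts. The
threshold for declaring bias in the Venice bias grade is p < 0.10,
configurable. Meta-regression is weighted least squares of θ̂ᵢ on one
covariate with weights 1/(SEᵢ² + τ²_null) and scale fixed at 1
(normal-theory p), implemented directly on the normal equations.

## FPRP

α is the observed two-sided p (not a fixed 0.05); power is evaluated on the
log-OR scale against the two-sided normal rejection region at level α, for a
target OR of 1.5 (1/1.5 when the pooled OR is protective; on the log scale
only the magnitude matters). The prior grid is {0.25, 0.1, 0.05, 0.01,
0.001} with headline prior 0.05. These are mandatory, logged configuration:
published synopses using FPRP rarely state the exact prior and target behind
their printed categories, so the packaged catalogue's categories are treated
as inputs, never as values to re-derive. Categories use the inclusive middle
band: < 0.05, 0.05 ≤ FPRP ≤ 0.20, > 0.20.

## Venice grading

Amount: A > 1000 test alleles among cases and controls, B for 100–1000
(both boundaries inclusive), C < 100. Replication: A for I² < 25%, B for
25 ≤ I² ≤ 50, C above. The boundary conventions at exactly 100/1000 and
25/50 follow the inclusive phrasing of the published rule; no printed value
exercises them, so they are flagged here as conventions.

Protection from bias is judgment-laden in the original framework; it is
mechanized as an explicit decision table so grade differences are auditable:

- **C** when the Harbord p is below threshold, or the sensitivity suite is
  unstable, or max(OR, 1/OR) < 1.15 without GWAS replication (the smallness
  rule is applied symmetrically because protective associations are graded
  too);
- **A** when none of those fire and the Harbord test actually ran
  (no observable bias);
- **B** otherwise — bias could be present, typically because the Harbord
  test could not be run for lack of counts.

Composite: strong iff AAA, moderate iff all grades in {A, B}, weak iff any
C. The FPRP upgrade is modeled as "one level up when FPRP < 0.05" — the
minimal rule consistent with every published transition in the packaged
catalogue (moderate→strong and weak→moderate both occur; strong stays
strong). Every fired rule is recorded in the credibility record's rationale.

Grading applies only to nominally significant associations (p < 0.05, no
multiplicity correction — the synopsis convention); grading a
non-significant association is refused explicitly rather than silently
returning a grade.

## Genetic model-free analysis

OR₁ and OR₂ are pooled independently by DerSimonian–Laird and
λ = ln OR₁/ln OR₂ estimated from the pooled pair. The within-study
correlation induced by the shared common-homozygote reference cell is
handled empirically by a studywise nonparametric bootstrap (resample
studies, re-pool both contrasts, recompute λ; percentile CI; default 2 000
resamples, seed mandatory) rather than by the bivariate likelihood of the
original method — a deliberate approximation chosen for robustness and
testability. λ is declared undetermined when |pooled ln OR₂| ≤ 0.10 (the
ratio would be noise-dominated). The classification bands — recessive when
the CI lies in (−0.25, 0.25), additive/codominant in (0.25, 0.75), dominant
in (0.75, 1.25), beyond-range when the CI excludes [0, 1] — are package
conventions; the underlying method treats λ as continuous.

## Synthetic-data generator

The generator emulates exactly the structure the estimators assume: control
genotypes from HWE at the configured MAF (an inbreeding coefficient of 0.15
distorts HWE when requested); per-study ln OR₂ drawn N(ln OR₂, τ²) with
OR₁ = OR₂^λ; case genotype probabilities obtained by odds-weighting the
control distribution with (1, OR₁, OR₂) and renormalizing — a logistic
disease model under the rare-disease approximation, which makes the
generating ORs exactly the estimands (with λ = 0.5 the allele-level OR is
exactly OR₂^½, so a target allele OR of r is produced by or2 = r²).
Publication selection retains a study with probability π(p) applied to its
allele-OR p-value; the default rule is π = 1 for p < 0.05 and 0.25
otherwise — crude but monotone, sufficient to power bias-test checks. Each
study draws from the substream `default_rng([seed, study_index])` (selection
from `[seed, study_index, 1]`), so catalogues extend without reshuffling
history and toggling selection never changes the genotype draws.

What the generator does **not** emulate: covariates and confounding,
population stratification, linkage disequilibrium between variants,
genotyping error, or directional (one-sided) selection. Passing calibration
tests therefore demonstrates internal statistical correctness of the
estimators under their own assumptions, not robustness to the failure modes
of real literatures.

## Calibration checks and problem sizes

The full-scale suite (tests/test_acceptance.py) runs:

- **CI coverage**: 2 000 simulated meta-analyses, k = 10, true allele OR
  1.3, τ² = 0, 2 000 per arm; the fixed-effect 95% CI must cover the truth
  in 93.5–96.5% of replicates (observed during development: 95.3%).
- **Harbord calibration**: 2 000 replicates, k = 20, study sizes uniform on
  100–2 000 per arm, true allele OR 1.3. Without selection the rejection
  rate at α = 0.10 must lie in [0.08, 0.12]; with the default selection rule
  on the same grid it must strictly exceed the null rate. The grid uses a
  non-null true OR because two-sided p-selection under a null effect prunes
  both funnel flanks symmetrically and produces almost no asymmetry; with a
  true effect, selection preferentially retains inflated small studies,
  which is the asymmetry the test exists to detect (observed during
  development: 0.09 null vs 0.18 under selection).
- **λ recovery**: 200 replicates per generating λ ∈ {0, 0.5, 1}, k = 15,
  1 500 per arm, MAF 0.3, OR₂ = 2; the mean λ̂ must land within 0.1 of the
  truth.
- **Estimator oracle**: on random k ≤ 4 instances, pooled estimates, Q, I²
  and τ² must match a brute-force re-derivation of the weight formulas to
  1e-12 relative error (the DL estimator was additionally cross-checked
  against an independent R implementation during development and agreed to
  10 decimals).
- **FPRP closed forms**: power = α at zero effect; FPRP = 0.5 when
  α = power at prior 0.5; strict monotonicity; agreement of the power
  formula with numerical integration of the rejection region to 1e-8.

Smaller-replicate versions of the stochastic checks run in the per-module
tests for fast iteration.

## Known limitations and open points

- The packaged catalogue transcribes printed values verbatim, including one
  CI printed asymmetrically around its OR (rs6983267/colorectal,
  1.17, CI 1.08–1.19), and records 27 distinct variant labels although the
  source synopsis states 28 variants were evaluated — one label is not
  enumerable from the printed lists. Neither is re-derived.
- Whether adjusted or crude ORs were pooled when sources offered both is not
  recoverable from a summary table; the pipeline's counts-first preference
  is configurable for this reason.
- No network/multivariate meta-analysis, no Egger/Begg/trim-and-fill
  variants, no Bayesian false-discovery alternatives: the implemented tests
  are exactly the synopsis workflow's, and adding neighbours would invite
  silent divergence from it.
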