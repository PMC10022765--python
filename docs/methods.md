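# Methods

This note documents the statistical models implemented in `rqit`, the
defaults chosen where the design was genuinely open, and what the synthetic
generators do and do not emulate.

## Scoring and uncertainty propagation

A profile's score is the sum of its elements' utilities. The packaged
ANZMUSC-RQIT table stores the published integer utilities and
standard errors together with the published correlation matrix of the
utility *estimates* (estimation error, not respondent heterogeneity). The
profile standard error is the quadratic form

    SE² = Σ_e Σ_e' ρ_{e,e'} σ_e σ_e'

over all ordered pairs of the profile's elements, i.e. the elements'
estimation errors are treated as jointly normal. No respondent-level
uncertainty is added: the score's SE describes uncertainty in the scale
itself. Recomputing the published worked example (A4,B1,C3,D3,E1) from the
printed, rounded table entries gives SE ≈ 12.44; the published value 13.46
evidently used unrounded internal covariances, so exact agreement from the
printed tables is not attainable — the package reproduces the printed score
(582) exactly and the SE to the precision the rounded inputs allow. The
printed correlation matrix is marginally non-positive-definite (smallest
eigenvalue ≈ −9·10⁻⁴), a rounding artifact; the propagation formula is
unaffected, and the Monte-Carlo oracle used in tests clips the negative
eigenvalues before sampling.

## Choice-task design

The design module enumerates *anti-chain* triples: per dimension pair, every
way of choosing three levels on each side, paired in opposite order, so that
within a task no option dominates another coordinate-wise. For the
(4,3,4,3,4) structure this yields 73 tasks covering every element. The
published survey used 86 tasks from an unpublished catalogue; the task count
here is surfaced as metadata, and the design rule is pluggable. Dimensions
with only two levels cannot supply three distinct levels, so the rule then
permits one repeated level on that side (logged). Block allocation draws the
common tasks and partitions the remainder disjointly across blocks by
default (86 = 2 + 3×28 is the motivating case); option order is shuffled per
block from the seed, standard practice to neutralize position effects.

## Thurstone paired-comparison fitting

A best-worst answer on three options implies the full ranking best > middle
> worst, hence three paired comparisons (two when only one end was
answered). Each comparison contributes

    −log Φ( (U_w − U_l) / (s_r · √(2(1 − c))) )

to the negative log-likelihood, where `U` sums the option's two element
utilities. The two options' perception errors are independent normals by
default (difference variance 2s²); a between-option error correlation `c`
is exposed as an option but defaults to 0 since the published model's
correlation structure is unspecified.

Identifiability: the likelihood is invariant to adding a constant to all
elements of one dimension (both options of a task share the same dimension
pair) and to rescaling utilities and SEMs jointly. Model 2a anchors each
dimension's lowest element at 0 with common SEM fixed at 1; Model 2b uses
the within-dimension sum-to-zero basis (same model, different
parameterization), which places all elements on equal footing so that
standard errors from the inverse observed information are directly
comparable; Model 1 additionally estimates per-respondent SEMs, with the
scale fixed by normalizing their geometric mean to 1 (parameterized as
centered log-dispersions).

Optimization is quasi-Newton (L-BFGS-B, analytic gradient, three seeded
starts, convergence at mean-NLL gradient ∞-norm < 10⁻⁶, with a BFGS polish
if needed). The observed information is obtained by central differences of
the analytic gradient and mapped to element space through the
parameterization basis. If an element appears only on winning or only on
losing sides (separation), a ridge penalty 10⁻⁴·Σu² keeps estimates finite
and the affected elements are flagged in the result.

Rescaling to the reporting scale subtracts each dimension's lowest-level
utility and multiplies by the constant that makes the maximal profile sum
to exactly 1000; standard errors scale by the same constant (translation
leaves them unchanged) and correlations are untouched. Utilities are kept
at full precision so the 0/1000 anchors are exact; the packaged published
table stores the printed integers.

## Reliability statistics

ICC(2,1) and ICC(2,k) follow the two-way random-effects, absolute-agreement
formulas from the subject × rater ANOVA mean squares, with F-based
confidence intervals (Satterthwaite degrees of freedom) and Spearman–Brown
mapping of the single-measure bounds for the average case. Raters with any
missing rating are dropped listwise, matching the complete-data restriction
used for average and committee analyses. Committee reliability partitions
the complete raters at random (seeded) into committees of stated sizes,
averages each committee's ratings per subject, and reports the
single-measure ICC of the committee means without a CI — the partition is a
resampling device, not an estimator with a standard distribution theory.

Gwet's AC2 uses weighted observed agreement over rater pairs and Gwet's
chance-agreement term; default weights are quadratic ordinal
(w = 1 − (i−j)²/(K−1)²), switchable to nominal, under which the statistic
is AC1. Missing ratings are handled pairwise (subjects keep their observed
raters; subjects with fewer than two raters are excluded and counted). The
variance is a subject-level jackknife with a t-based CI; the published
analysis did not state its weighting or CI method, so both are options.

Modal percent agreement is the mean over subjects of the modal category's
share of that subject's raters (ties take the tied maximum count).

## Delphi machinery

The disagreement index follows the RAND/UCLA appropriateness method on the
1–9 scale: IPR = P70 − P30, IPRAS = 2.35 + 1.5·|5 − IPRCP| with IPRCP the
midpoint of the two percentiles, DI = IPR/IPRAS. The constants come from
the RAND/UCLA manual. Percentiles use linear interpolation by default but
the convention is switchable, because DI near the 1.0 boundary is sensitive
to it. Items are re-rated when the median is 4–6 or DI > 1, with the
triggering rule recorded. Theme contributions sum the medians of items at
or above the rating floor (default 7) per theme and report each theme's
percentage of the grand total to one decimal.

## Validity analytics

The unweighted instrument sum maps each dimension's ordinal level linearly
onto [0, 3] and adds them (0–18 for six dimensions). Cramér's V is
√(χ²/(n·min(r−1, c−1))) with the Pearson χ² p-value, replaced by Fisher's
exact test for 2×2 tables with any expected count below 5; the `min` term
sits inside the denominator so V lies in [0, 1]. Tertile logistic
regression cuts scores at the empirical 1/3 and 2/3 quantiles
(right-closed; boundaries shift to the next distinct value under heavy
ties), regresses the binary outcome on tertile indicators and reports odds
ratios with Wald CIs, the likelihood-ratio model χ² and Nagelkerke R².
Citation regression standardizes both ln(citations + 1) and the score, so
the reported coefficient is the standardized slope; the +1 offset makes
zero counts usable and is documented as a choice.

## Synthetic generators

The best-worst generator draws each respondent-task's perceived option
utilities as truth plus normal noise and reports the perceived extremes.
Defaults emulate the published survey's conditions: 41 respondents, 0.6%
single-ended answers, common SEM 1, and true latent utilities equal to the
published table × 0.006. That scale factor was calibrated a priori so that
a survey of roughly the published size (~3000 comparisons) yields element
standard errors of the order the published table reports (≈5–8 points on
the 0–1000 scale) — i.e. the generator reproduces the information level of
the real survey rather than an arbitrarily easy or hard one. Per-respondent
SEMs, when enabled, are log-normal (positive support, heavy enough tail to
distinguish the model variants).

The ratings generator discretizes latent subject effect + rater noise into
K categories at equal-probability cutpoints; the latent ICC
σ²_subject/(σ²_subject + σ²_noise) is recorded in the metadata. Note that
discretization attenuates the ordinal-scale ICC below the latent value
(e.g. latent 0.75 → ≈0.68 at K = 4); tests therefore compare simulation
means against a bivariate-normal discretization oracle, not the latent
value. The article generator draws profiles uniformly per dimension,
assigns journal group by a logistic model on weighted-score tertiles and
citations log-normally with a chosen standardized effect; stratified mode
balances the groups exactly.

What the generators do **not** emulate: real stakeholder-pool composition
and subgroup heterogeneity, respondent learning/fatigue across tasks,
rater-specific severity effects in the ratings grids, and the selection
processes behind real bibliometric samples. Passing recovery tests
therefore demonstrates correctness of the estimators under their assumed
models, not robustness to these real-data features.

## Problem sizes and numerical choices

The end-to-end recovery check uses 20 replicates of 200 respondents × the
full 73-task design (~44,000 comparisons each), a size at which estimates
are precise enough that rank recovery is expected under the generator's
information level; it completes in well under a minute thanks to the
vectorized likelihood. Monte-Carlo SE oracles use 10⁵ multivariate-normal
draws. Agreement oracle checks use 50 random small matrices. Convergence
and tolerance constants: gradient ∞-norm 10⁻⁶ (mean NLL), ridge 10⁻⁴,
sum-to-zero satisfied to 10⁻⁹, ICC/AC2 oracle agreement to 10⁻⁶.

## Known limitations

- The published 86-task catalogue and the unrounded covariance internals
  behind the published profile SE are not public; the package reproduces
  the published scores exactly and the SEs to rounded-input precision.
- Model 1's per-respondent SEMs are point estimates without shrinkage;
  with few tasks per respondent they are noisy (the common-SEM model is
  the default for inference, as in the published analysis).
- The AC2 jackknife CI is asymptotic in the number of subjects; with very
  few subjects it should be read qualitatively.
- No D-efficiency optimization of designs, no hierarchical-Bayes
  heterogeneity modelling, and no stakeholder-subgroup comparisons.
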