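# Methods

## From interval annotations to state sequences

A coded session is a set of half-open intervals `[onset, offset)` in
seconds on three channels (auditory, visual, tactile). On construction,
events are validated (positive duration, known channel), clipped to the
session duration with a warning (not rejected), and same-channel
overlaps or abutments are merged — the channel is simply *on* throughout.
Sessions shorter than a configurable minimum (default 420 s, the common
exclusion threshold for free-play recordings) are flagged in metadata,
never silently dropped.

The combined-signal state at time *t* is the 3-bit mask of channels
active at *t* (bit 0 auditory, bit 1 visual, bit 2 tactile; 0 = no
signal). The state sequence is built by **exact change-point
construction**: pool all interval endpoints, evaluate the mask on each
segment between consecutive endpoints, and run-length deduplicate so
consecutive states are always distinct. The initial state is the mask at
t = 0 (state 0 counts — the no-signal configuration is one of the
eight). An empty session yields the single state `[0]`.

Coding systems with a fixed sampling clock are emulated by an optional
fixed-bin mode (`bin_width` in seconds) that samples the mask on a grid;
it converges to the exact construction as the bin shrinks and is
verified against it in the tests. No gap-bridging is applied: an offset
immediately followed by an onset on the same channel is a continuous
signal only if the intervals actually touch.

## Entropy rate

Transitions between distinct states form a first-order Markov chain with
structurally zero diagonal. From a sequence with N transitions:

- counts `c[i,j]` = number of consecutive pairs (i, j);
- probabilities `p[i,j] = c[i,j] / Σ_j c[i,j]` on visited rows
  (optional additive smoothing is opt-in, default 0, and applied only to
  the off-diagonal cells of visited rows);
- stationary weights `π_i = Σ_j c[i,j] / N` — the empirical
  distribution of transition *sources*. This maximum-likelihood plug-in
  is the default because the estimated chain on a short session may be
  reducible, where an eigenvector is ill-defined; an eigenvector mode
  (leading left eigenvector of the estimated matrix restricted to
  visited states) is available via `stationary="eigen"` and agrees with
  the empirical mode on long ergodic sequences.

The entropy rate is `H = Σ_i π_i · h_i` with
`h_i = −Σ_j p[i,j] log₂ p[i,j]`, using `0·log 0 = 0`; unvisited states
carry π = 0 and contribute nothing. Base-2 logarithms are forced by the
measure's stated ceiling: with self-transitions excluded, H ∈
[0, log₂(k−1)], i.e. [0, 2.807] for k = 8. Self-transitions are
excluded by construction — the 2.807 maximum is attainable only over
seven admissible successors, and a "transition" is defined as a change
of combination.

The plug-in estimator is consistent (within ±0.01 of the generator
entropy at 10⁵ transitions, verified across the full unpredictability
range) but biased downward at session-scale lengths (~100 transitions),
like any entropy plug-in; estimates from fewer than 10 transitions
(configurable) are flagged `few_transitions`. The entropy rate is
empirically uncorrelated with the raw number of transitions when
unpredictability is varied independently of sequence length — they are
distinct constructs, and the test suite checks this as a property.

## Extreme-group cut-offs

`classify_unpredictability` labels values strictly above the empirical
85th percentile as `high`, the rest `low_moderate`. The percentile uses
linear interpolation between order statistics; ties at the cut go to
`low_moderate`. Both choices are recorded in the cut-off report
(cut value, rule, group sizes, per-group ranges) because percentile
conventions differ across software and the tie rule is otherwise
invisible. At n = 133 this yields a high group of 20.

## Synthetic sessions

The session generator uses a one-parameter transition family
`P(α) = (1−α)·C + α·U` — C a deterministic cycle permutation, U uniform
off-diagonal. Its entropy rate is continuous and nondecreasing in α and
spans the full range [0, log₂(k−1)] with one knob; by symmetry its
stationary law is uniform, so the closed-form entropy is just the row
entropy. A sampled state path is dressed with i.i.d. exponential dwell
times (default mean 2 s, a realistic signal-bout timescale) and
converted to per-channel events via the bitmask. The round trip —
simulate, rebuild the state sequence — is exact, which is what makes the
change-point code oracle-testable. The generator does not model dwell
autocorrelation, infant behavior, or dyadic feedback; it exists to give
sessions with *known* entropy.

## Synthetic cohorts

The cohort generator produces one row per mother–child dyad with
exposure (entropy rate), five maternal covariates, child sex, and the
child outcome (effortful control, 1–7). Defaults reproduce the
distributional structure typical of mother–infant free-play cohorts:

| quantity | default |
|---|---|
| entropy rate | truncated normal, mean .89, SD .17 on [0, 2.807] |
| economic satisfaction | trunc. normal 6.15 (2.31) on [0, 10], target r with outcome .126 |
| maternal effortful control | 4.64 (.76) on [1, 7], target r .136 |
| maternal sensitivity | 5.34 (1.40) on [1, 7], target r .128 |
| maternal anxiety / depression | 4.63 (5.81) on [0, 40] / 5.19 (4.97) on [0, 30], target r 0 |
| child sex | Bernoulli, P(female) = .474 |
| outcome | mean 5.46, SD .74, clipped to [1, 7] |
| sex effect | Cohen's d = .62, females higher |
| sex-specific exposure slopes | stratified r: males −.289, females −.007 |

Construction: covariates are mutually independent truncated normals,
standardized with their exact truncated moments; the outcome is

y = μ_sex + b_sex·(H − μ_H) + Σ_j c_j·z_j + ε_sex,  then clipped to [1, 7].

Calibration is analytic, from the variance decomposition of this linear
model:

- within-sex SD: σ_w = σ_y / √(1 + p_f p_m d²), and the sex means are
  separated by d·σ_w around the marginal mean;
- slopes b_sex = r_sex·σ_w / σ_H hit the stratified correlations;
- loadings c_j = r_j·σ_y hit the marginal covariate–outcome
  correlations (covariates are independent of sex and exposure);
- residual SDs solve σ²_ε,sex = σ_w²(1 − r_sex²) − Σ c_j². A negative
  solution means the requested structure is not positive semi-definite
  and construction fails with a message naming the offending
  combination.

Clipping the outcome at 7 censors roughly 2–3% of female draws and
attenuates moments and correlations by well under the recovery
tolerances; the effect is visible only as a slight shrinkage of the
covariate correlations (≈.119 observed vs .126 targeted at n = 10⁵).
The truncated-normal exposure is an assumption — whether real maternal
entropy is unimodal on [0, 2.807] is unknown; observed samples have
been confined to roughly [0.4, 1.35].

What passing recovery tests shows: the pipeline's estimators are
unbiased and correctly wired at scale, and directionally stable at study
scale (n = 133). What they do not show: anything about real coded video,
real covariate interdependence (here zero by design), missingness
mechanisms, or measurement error in the questionnaire scales.

## Analysis pipeline

- **Screening.** A candidate confounder enters the covariate set iff
  |r| with the outcome is *strictly* greater than .10 (at least a small
  effect) or p < .05; two-level categorical candidates are screened by
  the significance of a pooled t-test. The boundary r = .10 exactly is
  excluded — the rule is documented this way in the screening report.
- **Correlations.** Pearson r, two-sided p from the t distribution, and
  a Fisher-z interval `tanh(arctanh r ± z*/√(n−3))`.
- **Hierarchical regression.** "Stepwise" here means fixed ordered
  blocks refit cumulatively by OLS — never automatic variable selection.
  Standardized β = β·sd(x)/sd(y), i.e. every column z-scored, dummy
  variables included (conventions for standardizing dummies differ;
  this one is stated in the table metadata). CIs and p-values attach to
  the unstandardized coefficients; both are printed. Adjusted R² per
  step. Rank deficiency raises an error naming the collinear terms.
- **Moderation.** Covariates → main effects → interaction (mean-centered
  exposure × moderator dummy), probed by moderator-stratified
  correlations; strata with n < 4 or constant values are omitted with a
  warning. Sex coding: female = reference, the male dummy carries the
  contrast; the opposite coding only flips signs and is noted in
  metadata.
- **Extreme group.** High (top 15%) vs rest: pooled-variance Student's t
  (df = n − 2, matching how such contrasts are conventionally reported;
  Welch by flag), Cohen's d on the pooled SD, CI for the mean
  difference, then an OLS model of the outcome on the group indicator
  plus covariates. Maternal sensitivity can be entered as a low-vs-rest
  indicator at its *lowest* 15th percentile — the mirror-image
  dichotomization at the other tail — rather than as a low-vs-high
  extreme-pair contrast; the low-vs-rest reading matches how the
  continuous analyses treat the rest of the sample and is the
  implemented choice. An optional group × sex interaction model reports
  its interaction p.
- Missing data: listwise deletion with a warned count (no imputation).
  No multiple-testing correction is applied; the run metadata says so.

All p-values are two-sided; all intervals 95% unless configured.

## Problem sizes in the test suite

Oracle equivalence uses 1000 random sessions against a 1 ms
rasterization oracle; estimator consistency uses 10⁵-transition
sessions at five α values; cohort recovery uses n = 10⁵ with one
fitted `CohortStudy`; directional stability uses 500 replicates at
n = 133. The full suite runs in well under a minute on one CPU.
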