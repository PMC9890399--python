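# Methods

## Model

Responses are modelled with the graded response model (GRM): for a
4-category item with discrimination *a* > 0 and strictly increasing
thresholds *b₁ < b₂ < b₃* (latent-trait units), the cumulative category
probabilities are logistic in *a*(θ − *bₖ*) and category probabilities are
adjacent differences. The GRM is the natural choice for ordered 0–3 Likert
items and is the standard model in adaptive-testing frameworks for such
instruments. Item parameters are *inputs* (a calibrated bank, or the
synthetic generator's); `srscat` deliberately contains no calibration
routine.

Item Fisher information is Σₖ (∂P(X=k|θ)/∂θ)² / P(X=k|θ); categories with
numerically zero probability contribute zero (their derivative vanishes at
the same rate), which keeps the sum finite in the tails.

## Latent-trait estimation

EAP scores are posterior means over a fixed quadrature grid: equally spaced
nodes on [−6, 6], 121 nodes, rectangle weights, with the posterior assembled
in log space and normalized after subtracting the maximum (an explicit
underflow error is raised if every node underflows). The default grid
resolves posteriors from full 65-item administrations: against a
10,001-node trapezoid oracle the EAP and SE agree to 10⁻⁴ (tested). Node
count and bounds are configurable.

Two priors are provided: a diffuse normal with SD 10 (default — effectively
flat over the grid, so the posterior is dominated by the responses, matching
an administration engine that should "barely inform" the score) and the
standard normal for population-scaled scoring. The empirical reliability
attached to a posterior is 1 − SE², clipped to [0, 1]; it is interpretable
on a unit-variance latent metric.

A calibration note: when the scoring prior matches the generating
distribution of θ, the mean squared EAP error equals the mean posterior
variance *exactly* (law of total variance). The test suite checks this
identity two ways — exactly by full enumeration of all response patterns on
a 3-item bank, and by simulation at full-bank scale where the RMSE/rms-SE
ratio must sit in a Monte-Carlo band around 1. The reported SEs are
therefore honest error estimates, neither conservative nor optimistic.

## Adaptive administration

The engine selects, at each step, the unadministered item with maximum
Fisher information at the current EAP (ties → lowest item id; the first item
is chosen at the prior mean). Stopping is evaluated after every item:

1. never stop before `min_items` (default 10);
2. then stop with reason `reliability` if SE < 0.3 (equivalently, with the
   `reliability` parameterization, 1 − SE² > threshold);
3. else stop with reason `equilibrium` if the latest |ΔEAP| < 0.05 (defined
   from the second item on);
4. else stop with reason `max_items` at the item cap (default 65 = bank
   exhaustion; the observed 10–20 item range emerges from the rules, not
   from a cap).

When both precision and equilibrium hold at the same step the recorded
reason is `reliability`; the stop step itself is unaffected. Note the pair
(SE < 0.3, reliability > 0.90) is not an exact algebraic match — reliability
0.90 corresponds to SE 0.3162 — so the SE rule is the marginally stricter
one; SE < 0.3 certifies reliability 0.91 > 0.90, and the exactly matched
pair (0.3, 0.91) stops identically (tested).

The final EAP is converted to the expected test score over the full bank,
Σᵢ E[Xᵢ|θ̂] ∈ (0, 195), evaluated at the EAP point estimate (the conversion
used to report adaptive scores on the raw metric). A posterior-integrated
variant would be possible but the point-estimate convention is the one the
reporting pipeline expects; it is strictly increasing in θ̂.

Reverse-coded items: providers (recorded vectors or simulated examinees)
speak *raw* orientation; the engine re-keys reverse-masked items before the
likelihood, and the raw-total scorer does the same (k → 3 − k).

## Equating

Short (0–48) raw scores are placed on the full (0–195) metric by
equipercentile equating: integer scores are continuized as uniform ±0.5
intervals of the cumulative distribution, source-score mid-percentile ranks
(100·(F(x−1) + ½f(x))/N) are matched by inverting the target's piecewise
linear CDF, and results are clipped to the target scale. Runs of zero
frequency are collapsed to their interval midpoint before inversion, so
interior empty cells inherit interpolated cumulative values and the inverse
is single-valued; self-equating with full support is the exact identity
(tested to 10⁻⁹). No presmoothing is applied — with the analysis-scale
samples used here the raw frequencies are adequate, and smoothing choices
would be invisible to every downstream statistic except at sparse tails.
By default the equating reference is the study's own two randomized arms
(short-arm short totals vs full-arm full totals); any pair of reference
distributions, including paired single-group data, can be supplied instead.
POMP (percent of maximum possible) is the secondary, distribution-free
rescaling.

## Comparison battery

- Cohen's *d*: pooled SD with n−1 weights.
- ROC/AUC: tie-corrected rank (Mann–Whitney) estimator; variance from the
  placement-value decomposition var(V₁₀)/m + var(V₀₁)/n. The threshold
  sweep comes from scikit-learn's `roc_curve`; higher score = positive.
- AUC comparison: z = ΔAUC/SE reported as z² against χ²₁. Across
  randomized arms the comparison is unpaired (variances sum); a paired mode
  subtracts placement covariances for within-person designs. Type-I error
  calibration at n = 70 per arm is tested (2,000 null replicates, level
  within [0.035, 0.065]).
- Cut-offs: per-threshold sensitivity/specificity with the Youden-optimal
  cutoff (ties → lower cutoff).
- Bland–Altman: limits are mean ± 2·SD of paired differences (the wording
  "within 2 standard deviations" taken literally rather than ±1.96);
  `pct_within` counts pairs strictly inside the limits, with the degenerate
  all-identical case defined as 100%.
- Descriptives: per-group n, median, IQR, mean, SD; single-respondent cells
  are suppressed (flagged, statistics withheld) as privacy practice for
  small strata.
- Density shifts: mean difference in pooled-SD units plus the equal-variance
  normal overlap coefficient 2Φ(−|d|/2), matching normal-density
  visualisations of score distributions.

## Synthetic data

The generator reproduces the statistical structure the analysis assumes, not
any real cohort:

- **Design margins** (defaults): 154 clinical / 201 general enrollees; ASD
  prevalence 0.84 vs 0.02; male fraction 0.72 vs 0.34; preschool-form
  probability 0.63 vs 0.005; permuted-block randomization in blocks of
  three, so 201 general enrollees split exactly 67/67/67. An optional
  `two_arm_first_n` reproduces an initial enrollment period with only the
  full/short arms (off by default).
- **Latent traits**: θ = site baseline + 0.15·male + 2.0·ASD + N(0, 1).
  Both site baselines default to 0 so that the configured case/non-case
  separation of 2 SD is what the data exhibit and site-level score
  differences emerge from case mix alone; a positive clinical baseline is
  available to model referral skew. The male shift of 0.15 SD produces the
  mild male-right-shift seen in trait measures without materially moving
  the case separation.
- **Item bank**: 65 four-category items; discriminations log-normal with
  median 1.5 (σ = 0.3) — typical of well-calibrated social-communication
  items; item locations normal with mean 0.75, SD 0.9, so a general
  population centred at θ = 0 mostly scores low; within-item threshold
  spacings uniform on [0.5, 1.0], making thresholds strictly increasing by
  construction. The short form is the 16 most-discriminating items
  (short forms select high-loading items); the reverse mask defaults to
  empty (synthetic responses are generated in keyed orientation) and any
  nonzero mask causes the generator to store un-keyed raw responses that
  scoring re-keys. Optional per-group threshold offsets (`dif_sd`) emulate
  differential item functioning by form/sex.
- **Protocol**: every respondent gets a complete latent 65-item vector; the
  arm decides what is recorded. The adaptive arm is driven by that same
  vector, so replaying the recorded responses through the engine reproduces
  the administration deterministically. At the general site the shortened
  arms record all 65 items (remaining-items protocol), which is what makes
  within-person short/CAT vs full comparisons possible.
- True parameters live only in the truth record, which analysis code never
  reads; oracle tests may.

What the generator does *not* emulate: rater/informant error beyond the GRM,
mode effects (paper vs remote administration), comorbidity structure among
non-ASD diagnoses, race/ethnicity score differences, or item-level content.
Passing tests therefore demonstrate the *machinery* — scoring, adaptive
logic, equating, statistics — under the assumed data-generating model, not
the field behaviour of any real instrument.

## Problem sizes and determinism

The test suite and the acceptance script run the simulations at sizes chosen
to make Monte-Carlo error small relative to the assertions: 500
administrations for stopping-rule behaviour, 1,000 respondents for paired
agreement, 2,000 replicates for test calibration, n = 10,000 per group for
the binormal AUC link, and the full n = 355 study for the end-to-end run.
Every stochastic step draws from `numpy.random.default_rng` streams spawned
from a single seed, so identical configurations reproduce byte-identical
outputs (tested by hashing a re-run report directory).

## Known limitations

- Item-parameter calibration, IRT true-score equating, T-score norms and
  content balancing/exposure control are out of scope by design.
- The chi-squared AUC comparison is the large-sample z² form; very small
  strata (a handful of cases) push it beyond its asymptotic comfort zone,
  as with any DeLong-style test.
- The equipercentile map is only as good as its reference distributions;
  with sparse arms the tails of the concordance table flatten (no
  presmoothing by default).
- Group-specific (form × sex) parameter sets fall back to the default set
  with a warning when a requested group was never calibrated.
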