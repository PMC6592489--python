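# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `wbtraj`, and what the test suite does and does not
establish about behavior on real cohorts.

## Data model and inclusion

A cohort is long-format: one assessment record per participant × day
(LS 5–35, AB −40–40, CES-D 0–60; day 0 is each participant's own
pretest) plus weekly usage records (days-per-week of exercise use summed
over assigned exercises, and a binary adherence report). Two study
designs are bundled: Sample 1 assesses LS/AB on days {0, 7, 37, 97}
(posttest day 7), Sample 2 on days {0, 42, 72, 132} (posttest day 42)
with weekly usage assessments during its up-to-six-week intervention.
Designs are configuration, never hard-coded; any schedule whose window
endpoints are planned days is accepted.

Participants enter the analysis only with ≥ 4 non-missing observations
in *both* LS and AB (`min_points`, default 4). By default the rule
counts observations inside the modeled window (pretest → 3-month
follow-up), because only that span is modeled; a `within_window=False`
switch counts all recorded days instead, for schedules whose later
follow-ups should qualify participants. All missingness is handled by
pairwise deletion: each analysis assembles its own complete-case view
and nothing is ever imputed.

CES-D ≥ 16 flags elevated depression risk; a missing score propagates
as missing rather than collapsing to "not at risk".

## Trajectory fitting

Each outcome series is summarised by OLS on the centered monomial basis
`[1, u, …, u^m]`, `u = day − posttest_day`, with degree
`m = min(n_obs − 2, 4)` computed per outcome from that outcome's own
non-missing in-window count (floor 1, so 3 points fit a line). The
`n_obs − 2` rule keeps fits precise but unsaturated; the cap at 4
preserves that property on denser schedules. Centered monomials (rather
than an orthogonal basis) are used deliberately: windows are ≤ 132 days
and degrees ≤ 4, so conditioning is unproblematic, and coefficients
remain directly interpretable as value/slope/curvature at posttest.
Time is in integer days and is not rescaled — the distance below is
invariant to shifts, and magnitudes are handled there.

## Shape distance and clustering

The distance between two trajectories integrates the Euclidean norm of
the difference of their derivative vectors over the modeled window:

    D(A, B) = ∫ √( (LS_A′ − LS_B′)² + (AB_A′ − AB_B′)² ) dt.

Intercepts never enter, so D measures curve *shape* only and is a
pseudometric (distinct curves differing by constants are at distance
zero). The integrand is the square root of a polynomial and has no
closed form in general; it is integrated by fixed-node Gauss–Legendre
quadrature (default 64 nodes, configurable). Fixed nodes keep distances
deterministic, fast and smooth in the coefficients; with degree ≤ 4
polynomials the 64-node rule agrees with a 10⁶-step Riemann sum to
better than 1e−5 relative (tested), and is exact for constant-gap
integrands.

The modified K-means:

* **Initialisation** — K distinct member trajectories drawn at random
  (intercepts zeroed). "Random prototypes within the observation
  window" is underspecified for function-valued prototypes; seeding from
  members is deterministic given the seed and always starts inside the
  data's shape distribution. Default 20 restarts; the lowest-objective
  restart wins.
* **Assignment** — nearest prototype under D; ties break to the lowest
  cluster index.
* **Update** — each prototype becomes the coefficient-wise mean of its
  members' polynomials (zero-padded to the cluster's max degree,
  intercept re-pinned to 0). The coefficient mean is the natural
  function-valued centroid, but it minimises the *squared* derivative
  criterion, not the integral distance itself, so monotone descent is
  not guaranteed in theory. A descent guard therefore keeps the
  previous prototypes and stops the restart if an update would raise
  the objective; reported objective traces are monotone by
  construction.
* **Empty clusters** — reseeded to the trajectory farthest from its
  currently assigned prototype.
* **Termination** — assignments unchanged, objective improvement below
  `tol` (1e−6), the descent guard, or `max_iter` (100).

Clustering runs separately within each sample over that sample's own
window; no cross-sample distance is ever computed. Window-length
normalisation is available but off by default, since within-sample
clustering makes it moot.

### Choosing K

`scree_select` runs K = 1…10 and picks the elbow of W(K). The default
rule is the **chord criterion**: the interior K whose objective lies
farthest below the straight line joining the first and last points of
the W(K) curve — the operational equivalent of finding, by eye, where
the curve levels off into scree. A raw second-difference rule
(`method="second_difference"`) is also provided but is not the default:
when the drops W(K−1) − W(K) decay roughly geometrically (which they do
whenever one dominant split exists, e.g. a large flat "nondistressed"
mass versus everyone else), the second difference is maximised at the
smallest interior K no matter how much structure remains, so it cannot
level-detect a four-cluster solution. On default synthetic cohorts the
chord rule selects K = 4 in ≥ 9/10 seeds; the full table is retained so
neighbouring solutions can be compared descriptively.

### Naming K = 4 clusters

Clusters are named from observed member means (not prototypes) of LS at
baseline L₀, mid-window L_mid (the interior design day nearest the
window midpoint) and window end L_end, with threshold δ (default 2 LS
points): *nondistressed* if L₀ is the cross-cluster maximum and
|L_end − L₀| ≤ δ; *lasting benefit* if the mid-window rise exceeds δ and
persists; *hedonic adaptation* if the rise exceeds δ but the curve
returns to baseline; else *residual*. The same rule on AB (δ scaled by
the AB/LS range ratio 8/3, i.e. default 16/3) must agree, otherwise the
cluster falls back to *residual* with a warning. For K ≠ 4, indices are
reported without names. For plotting, a display intercept anchors each
zero-intercept prototype at its members' mean observed (LS, AB) at the
centering day; anchoring never changes a distance.

## Interpretation statistics

* **Mixed 4×4 ANOVA** (timepoint within, cluster between): univariate
  split-plot decomposition without sphericity correction, so the F
  degrees of freedom are (T−1, (N−G)(T−1)) for within effects and
  (G−1, N−G) between. Participants missing any of the four timepoints
  are dropped for that ANOVA only. η² = SS_effect / SS_total. The
  decomposition is exact for any group sizes because every retained
  participant has all T timepoints. Degenerate zero-variance data
  report F = 0, p = 1 rather than NaN so pipelines survive pathological
  toys. The implementation is cross-checked against
  `pingouin.mixed_anova` in the tests.
* **Post-hocs**: pooled-variance two-sample t per cluster pair per
  timepoint; Bonferroni adjustment `min(1, p·m)` where the family m
  defaults to all pairs × timepoints within a sample and outcome.
* **Cross-sample epoch ANOVA**: observations pooled into early
  ({0, 7}), middle ({37, 42}) and late ({72, 97, 132}) day groups;
  two-way cluster × sample ANOVA with Type-3 SS via effect-coded OLS
  (statsmodels), reporting the interaction as the similarity check
  between samples.
* **Correlations**: product-moment r on pairwise-deleted observation
  pairs, Fisher-z 95% CI.
* **Attrition comparison**: Welch t per baseline outcome between
  included and excluded participants plus a χ² test (no continuity
  correction) on the retention × sample table.

## Usage models

Frequency-of-use sums are z-scored within groups defined by the number
of assigned exercises (sample SD, pooled over assessment days; constant
groups get zeros with a warning), time is centered at the grand mean
day over the modeled records (recomputed from data, not fixed), and
adherence enters as a binary indicator: the usage record stores one
weekly yes/no per participant (adhered to the assigned exercises that
week), so a summed-and-standardized adherence variant has no basis in
the stored data model and is not offered. Each post-posttest assessment
contributes one analysis row, so n is observations, not participants.

The GLM is a fixed-effects logistic regression fitted by IRLS
(statsmodels) for lasting benefit (1) versus hedonic adaptation (0).
Backward elimination starts from
freq × adh × time with all lower-order terms and at each step removes
the best removable highest-order term, never dropping a main effect
while an interaction containing it remains. Two stopping criteria are
implemented: AIC improvement (default, since the selection table
reports AIC) and likelihood-ratio p > α (α = 0.05). They differ in
false-retention behavior — AIC keeps a truly null single-df interaction
with probability P(χ²₁ > 2) ≈ 0.16 versus 0.05 for the LRT — so exact
term-set recovery rates are higher under the LRT criterion, and the
acceptance checks of selection consistency exercise that mode.
Standardized coefficients are reported as b × SD(predictor) with the
outcome left on the logit scale. Pseudo-R²: Cox–Snell
1 − exp(2(ll₀ − ll₁)/n), Nagelkerke (Cox–Snell rescaled by its
maximum), McFadden 1 − ll₁/ll₀; all three are reported without forcing
agreement, because published pseudo-R² intervals and McFadden values
frequently presuppose different null models.

## Synthetic cohorts

The generator emulates the latent structure the pipeline assumes, with
defaults fixed once to the emulated study's conditions:

* **Archetypes** (mixture 0.528 / 0.180 / 0.142 / 0.150 —
  nondistressed, lasting benefit, hedonic adaptation, residual):
  piecewise-linear mean curves anchored at the design's four assessment
  days. Nondistressed is flat and high (LS 27, AB 22, CES-D 7.93);
  distressed archetypes start low (LS 17–18, AB 5–6, CES-D 26.74 — the
  reported distressed/nondistressed baseline CES-D means) and then
  rise-and-hold, rise-and-return, or dip without an early benefit.
  Published sources give these shapes only qualitatively, so the levels
  are free parameters chosen inside the reported pooled baseline
  means/SDs; they are part of the package's study conditions, not a
  tuning dial.
* **Between-person structure**: a standard-normal distress factor loads
  +2.6 on LS, +3.0 on AB and −6.0 on CES-D; a second, orthogonal
  hedonic-level factor loads +1.0 on LS and +3.5 on AB only. Two
  factors are needed because the LS–AB correlation (target 0.62) is
  *weaker* than the CES-D pairs (−0.70, −0.75): a single common factor
  plus the archetype separation would over-correlate LS with AB.
  Idiosyncratic person intercepts (SD 4.9 / 5.4 / 2.0) complete the
  between-person variance. Loadings were calibrated once, by
  simulation at n = 5000, against the target correlation triple.
* **Within-person noise** (SD 1.0 / 1.75 / 2.0 per observation) is
  deliberately smaller than the between-person SDs: momentary
  fluctuation around a person's trajectory, consistent with the high
  short-term test-retest stability of these scales. Only this noise
  affects curve shapes (intercept terms cancel in the distance), so it
  is what limits archetype recovery.
* Scores are rounded to integers (scale sums are integers) and clipped
  into range.
* **Attrition**: a discrete hazard acts at each post-baseline
  assessment day with base hazards (0.45, 0.12, 0.10) — most dropout
  between the first two assessments — and log-odds decreasing by 0.5
  per SD of a baseline well-being composite, so completers are
  better-off at baseline. Overall retention lands near 42%.
* **Usage**: non-benefit archetypes draw exchangeable usage (latent
  z-frequency N(0,1), adherence Bernoulli(0.6)). For lasting-benefit
  and hedonic-adaptation participants, usage is drawn from
  label-conditional distributions obtained by Bayes inversion of the
  configured logistic law (default slopes: freq −0.20, adh 0.11,
  freq × adh 0.65, freq × time 0.01 on the z-freq/binary/centered-day
  scale), via accept-reject with acceptance probability σ(η) or
  1 − σ(η). This guarantees the conditional log-odds of lasting benefit
  given usage reproduce the configured slopes exactly (the intercept
  absorbs mixture normalisation). Latent frequency maps to a weekly
  count with mean 3.5 and SD 1.5 per assigned exercise, rounded and
  clipped to [0, 7 × n_assigned]; downstream z-scoring recovers it up
  to discretisation.
* **Reproducibility**: one RNG substream per participant, seeded by
  (cohort seed, sample index, participant index), so identical configs
  give byte-identical CSVs regardless of generation order.

What the generator does *not* emulate: condition-specific intervention
effects (none are planted), item-level response processes, floor/ceiling
response styles beyond clipping, non-ignorable missingness within
completers, or the 6/12-month assessments. Passing recovery tests
therefore show the pipeline is correct and well-calibrated under the
assumed latent structure — clean archetypes, Gaussian person effects,
hazard-type attrition — not that four clusters exist in any real
cohort.

## Problem sizes and runtimes

The test suite and acceptance script size their simulations to run
comfortably on one CPU: archetype recovery uses 10 cohorts of n = 400
(median ARI and scree-K reported), correlation calibration one cohort
of n = 5000, GLM recovery 50 replicates at n = 2000, and null
calibration 300–400 replicates at n = 500. The full suite runs in
about a minute; the acceptance script in under 30 seconds.

## Known limitations

* With only 4 planned assessments, any dropout excludes a participant
  under the ≥ 4-points rule, so the synthetic included set is exactly
  the completers; real six-assessment designs admit partial completers,
  which the rule (and `within_window`) supports but the default designs
  cannot exercise.
* Attrition skews the included mixture toward nondistressed relative to
  the generating weights, as in real cohorts; generating weights are
  therefore not recovered among completers.
* The mean-update K-means minimises a surrogate of the integral
  distance; the descent guard trades a (rarely triggered) early stop
  for a monotonicity guarantee.
* The scree elbow is a heuristic; on cohorts without clear shape
  structure the chord rule still returns *some* K, and small samples
  (included n ≲ 150) can elbow at 3. The labeling stage then reports
  indices and downstream stages skip gracefully.
* Logistic models are fixed-effects at the observation level; repeated
  observations within participants are not modeled as random effects,
  so standard errors are anti-conservative under strong within-person
  dependence.
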