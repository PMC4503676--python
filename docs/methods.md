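# Methods notes

This note records the statistical models implemented in `antgrad`, the
defaults and why they were chosen, what the synthetic generators do and
do not emulate, and the numerical decisions that were genuinely open.

## Study design assumed by the package

The package targets a six-site precipitation gradient (94–662 mm mean
annual rainfall) sampled in two consecutive years. Generalist foragers
are surveyed in three 20 × 15 m plots per site with 20 food baits per
plot; *Messor* seed specialists are additionally mapped in one
100 × 100 m plot per site. Colony density is the number of active nests
per plot after merging; foraging activity per colony is the maximum
worker count over four sampling periods (two nocturnal, two diurnal).
Plot exclusions (e.g. baits destroyed by scavengers in one year) are
declared in the run configuration, not hard-coded, so a reduced design
— two plots instead of three at three sites in the first year — is
reproduced by the packaged demo config.

## Preprocessing

Nest entrances of the same species closer than 1 m are counted as one
nest. The pairwise rule is closed transitively (union-find) and the
closure is **iterated to a fixed point** on cluster centroids: merging
two entrance clusters can place their centroid within 1 m of a third,
and a single union-find pass over the original points would then return
a map that still contains sub-threshold pairs, violating idempotence.
The fixed-point version guarantees that the output has no same-species
pair closer than the threshold, is order-independent, and agrees with
the single pass on all typical configurations (chains, pairs). Merged
coordinates are the centroid of the original entrances; merged forager
counts are element-wise maxima over sampling periods, consistent with
the maximum-count measurement rule. The threshold is strict (`< 1 m`);
entrances exactly 1 m apart remain separate.

## C-score null model

`C_ij = (r_i − S_ij)(r_j − S_ij)` counts bait pairs held exclusively by
each species of a pair; the C-score averages over unordered pairs. The
null keeps row (species) sums fixed and treats columns (baits) as
equiprobable — each species re-placed on `r_i` baits drawn uniformly
without replacement — which is appropriate when sampling units are
standardized and interchangeable, as identical baits are. Column sums
are free to vary, so the average number of species per bait is
preserved only in expectation.

Decisions:

- **SES** uses the sample (n−1) sd of the simulated C-scores. Tests
  against exhaustive enumeration convert between population and sample
  sd accordingly.
- **p-values** are add-one randomization p's,
  `(1 + #{sim ≥ obs}) / (1 + n_rand)`; ties count toward both tails
  (conservative). The defaults report both tails; segregation is the
  upper one.
- A **degenerate null** (sd = 0, e.g. all rows full) flags the result
  and reports p-values without an SES.
- **Inclusion filters**: species occurring on fewer than 5% of the
  site-year's baits (inclusive threshold, evaluated after any bait
  exclusions) are dropped; then species that share no plot with another
  retained species are dropped. Fewer than two survivors aborts that
  site-year with a logged reason. Baits are pooled across a site's
  plots into one matrix per site-year; the bait → plot mapping keeps
  per-plot analysis possible.
- `n_rand` defaults to 5000.

The enumeration oracle (`enumerate_null_distribution`) walks every
combination of row placements — `prod_i C(b, r_i)` outcomes — and is
the ground truth for small matrices. Because the null depends on the
observed matrix only through `(n_baits, row sums)`, a sweep over
row-sum configurations covers all small matrices. Monte-Carlo checks
against it use a 3-SE bound per configuration with one independent
re-draw allowed: across ~200 simultaneous ~N(0,1) deviations an
isolated chance exceedance is expected, while a real bias fails twice.

## Dispersion test

The observed statistic is the plot mean of per-colony nearest-neighbor
distances, species pooled (a per-species analysis is available by
filtering the colony map). The null is Monte-Carlo CSR **conditioned on
the observed number of colonies** (binomial, not Poisson) in the actual
plot rectangle, 5000 patterns by default;
`Z = (NND_obs − NND_sim) / sd NND_sim` with the sample sd. No analytic
edge correction is applied — observed and simulated means carry the
same edge bias by construction, which is the point of simulating the
null in the true geometry. Site-year summaries average per-plot Z (and
NND); a summary is flagged heterogeneous when plot Z's disagree in sign
by more than the significance width, since a mean near zero would then
hide real but opposing structure.

Validation anchors: the n = 2 unit-square null mean equals the expected
distance between two uniform points (0.521405…); for dense patterns the
null mean approaches the edge-free CSR expectation `1/(2√(n/A))` from
above, matching Donnelly's edge-corrected form
`0.5√(A/n) + (0.0514 + 0.041/√n)·P/n` to ~1%; CSR inputs give
approximately standard-normal Z. Calibration experiments share one
simulated null per geometry across replicates — legitimate because the
null depends only on `(n, W, H)` — which keeps them fast without
changing what is being tested.

## Gradient statistics

Simple OLS with F reported on (1, n−2) df; a constant response returns
the null fit (slope 0, r² 0, F 0, p 1) rather than an error, since a
flat response is a meaningful field outcome. `log10_y` transforms the
response only (used for forager numbers, which are right-skewed);
nonpositive responses under the transform are an error naming the rows.
The ANCOVA fits `y ~ group + x + group:x` and tests the interaction
with F = t² on (1, n−4) df; per-group slopes and SEs come from separate
per-group fits, matching how per-group regression lines are reported
alongside a pooled interaction test. Spearman uses midranks with the
two-tailed t-approximation `t = ρ√((n−2)/(1−ρ²))` — the convention of
the major statistics packages, and the one that reproduces the printed
p-values of the study's covariate table (ρ = 0.94, p = 0.005 at n = 6);
an exact permutation mode exists for n ≤ 8. |ρ| = 1 is reported with
p = 0.0 (print as "< 0.001"). No multiple-testing correction is applied
anywhere, consistent with reporting each regression on its own.

Forager-number responses are aggregated as the mean over colonies of
the per-colony maximum, per species per site-year
(`aggregate_forager_numbers`); worker counts from multiple foraging
trails of one colony are assumed summed per period upstream of the
package.

## Synthetic generators

- **Point patterns**: CSR (uniform); hard-core by simple sequential
  inhibition (dart throwing) with a retry budget of 1000·n proposals —
  chosen over Matérn II thinning because conditioning on an exact point
  count is what the dispersion null and the test fixtures need; cluster
  processes with uniform parents and truncated-Gaussian offspring.
  Feasibility of a hard-core spec is screened by disc-packing fraction
  (< 0.5 of plot area).
- **Occupancy matrices**: per-bait equicorrelated Gaussian copula
  thresholded at each species' marginal probability. The `segregation`
  coefficient is the latent correlation: negative values deplete joint
  occupancy below the product of marginals (checkerboard excess),
  positive values enrich it. Equicorrelation bounds feasibility at
  ρ ≥ −1/(s−1); infeasible specs are rejected rather than silently
  clipped. The copula was chosen because no mechanistic generative
  model of bait-level segregation exists; any mechanism with controlled
  pairwise depletion serves, and the copula makes the strength a single
  interpretable knob.
- **Gradients**: `response = intercept + slope·x + N(0, σ)` per site,
  optionally with per-group slopes and a shared intercept — exactly the
  design the ANCOVA assumes.

The demo pipeline config encodes the study's qualitative structure as
generator settings: generalist colonies per 20 × 15 m plot declining
with precipitation (intercept 16.41, slope −0.011 mm⁻¹), specialist
colonies per 100 × 100 m plot increasing (10 + 0.02·x, hard-core
min_dist 7 m — nearest-neighbor spacing of mature *Messor* mounds),
log-log forager-number slopes steeper for specialists than generalists,
and bait-segregation fading from the arid end (ρ = −0.12 at 94 mm)
toward zero at the mesic end.

What the generators do **not** emulate: observation error in species
identification, bait-level detection failure, temporal autocorrelation
between years, within-plot habitat heterogeneity, and any true
behavioral mechanism of competition. Passing the closed-loop tests
therefore shows that the estimators recover the structure they assume,
not that the field data satisfy those assumptions.

## Problem sizes used in validation

Calibration experiments run at the study's own design sizes: 8 species
× 60 baits (three pooled 20-bait plots) for the SES type-I experiment
(1000 trials of 1000 randomizations); 20 colonies in 20 × 15 m for the
dispersion calibration (1000 replicates against a 5000-pattern null);
10⁶ replicates for the n = 2 closed form; 1000 replicates of the 6-site
× 2-group equal-slope ANCOVA. The enumeration sweep covers all 103
(2–3 species, 2–5 baits) row-sum configurations at 50 000
randomizations each.

## Known limitations

- The equiprobable-columns null is the only randomization algorithm
  offered; a fixed-fixed swap null is deliberately out of scope.
- The hard-core generator is sequential inhibition, whose realized
  patterns are slightly less regular than a Gibbs hard-core process at
  the same packing fraction; adequate for generating over-dispersed
  test patterns, not for fitting real point patterns (no Ripley's K
  inference is provided).
- Site-year Z summaries average plot-level Z scores; they are a
  descriptive summary, not a combined test statistic.
- The six-site regressions have n = 6; their F tests are exact under
  normality but have little power, which is inherent to the design, not
  to the implementation.
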