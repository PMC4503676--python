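# antgrad

Statistics for ground-dwelling ant assemblages sampled along a
productivity (precipitation) gradient: null-model co-occurrence at food
baits, Monte-Carlo nearest-neighbor dispersion of colonies, and
site-level gradient regressions with a slope-heterogeneity ANCOVA —
plus synthetic-data generators so every stage can be tested in a closed
loop without field data.

The package is aimed at community ecologists analyzing bait-occupancy
and colony-mapping surveys: the kind of design where colony density,
foraging activity and indirect measures of interference competition are
compared across sites that differ in resource supply.

## Methods in brief

**Co-occurrence (C-score / SES).** For a binary species × bait matrix
with row totals `r_i` and pairwise shared-bait counts `S_ij`, the
C-score is the mean number of checkerboard units over species pairs,

    C = mean_{i<j} (r_i − S_ij)(r_j − S_ij).

The null model holds row sums fixed and treats columns as equiprobable:
each species is re-placed on `r_i` baits drawn uniformly without
replacement (the recommended algorithm for bait/sample data). With
`n_rand` randomizations the result is reported as a standardized effect
size `SES = (C_obs − mean C_null) / sd C_null` and add-one randomization
p-values; `SES > 1.96` flags segregation (interference at baits),
`SES < −1.96` aggregation. Species must occur on ≥ 5% of a site's baits
and share a plot with another retained species to enter the analysis.

**Dispersion (Clark–Evans Z).** Per plot, the mean nearest-neighbor
distance over colonies (all species pooled, same-species nest entrances
< 1 m apart merged first) is standardized against complete spatial
randomness: `Z = (NND_obs − NND_sim) / sd NND_sim`, with the null
simulated in the actual plot rectangle (edge effects reproduced by
construction). `Z > 1.96` means over-dispersed (uniform, territorial)
colonies, `Z < −1.96` clumped.

**Gradient statistics.** Site-level responses (colony density, mean
forager number per species — the maximum worker count over four
sampling periods per colony) are regressed on mean annual precipitation
by OLS, optionally log10-transformed; differences in slope between
generalist foragers and *Messor* seed specialists are tested by the
group × precipitation interaction of an ANCOVA. Spearman (midrank) and
Pearson correlations cover the covariate cross-checks.

All three stages are exposed both as scikit-learn-style estimators
(`CScoreNullModel`, `ClarkEvansTest`, `GradientRegression`,
`SlopeAncova`) and as plain functions (`null_model_test`,
`clark_evans_z`, `linear_fit`, `ancova_slopes`, ...).

## Worked example

```python
import numpy as np
import antgrad as ag

# six-site covariate table (precipitation 94-662 mm)
sites = ag.table1_fixture()
precip = [s.precip_mean for s in sites]
rho, p = ag.spearman(precip, [s.biomass_mean for s in sites])
print(round(rho, 2), round(p, 3))            # 0.94 0.005

# C-score null-model test of a perfectly segregated 2x3 matrix
mat = ag.OccupancyMatrix(["A", "B"], ["b1", "b2", "b3"],
                         [[1, 0, 0], [0, 1, 0]])
res = ag.null_model_test(mat, n_rand=5000, rng=np.random.default_rng(42))
print(res.stat_obs, round(res.null_mean, 3), round(res.ses, 3))
# 1.0 0.66 0.718

# dispersion of an over-dispersed synthetic colony pattern
spec = ag.PointProcessSpec("hardcore", 15, 20.0, 15.0, min_dist=2.0, seed=4)
cmap = ag.simulate_point_pattern(spec)
d = ag.clark_evans_z(cmap, n_rand=5000, rng=np.random.default_rng(1))
print(round(d.z, 2), d.classification)       # 2.19 segregated
```

The first block reproduces the rank correlation between mean annual
precipitation and herbaceous biomass across the six sites. The second
shows the worked checkerboard example: the observed C-score 1.0 sits
0.72 null standard deviations above the exhaustive null mean 2/3 — far
from the ±1.96 significance band, as expected for a 2 × 3 matrix. The
third generates a hard-core (inhibited) colony pattern whose observed
mean NND of 3.36 m exceeds the CSR null mean 2.53 ± 0.38 m, giving
Z = 2.19: correctly classified as segregated.

The same analyses run from the shell:

```sh
antgrad simulate --spec examples/point_pattern.yaml --out colonies.csv
antgrad dispersion --colonies colonies.csv --plot-width 20 --plot-height 15 \
    --n-rand 5000 --seed 1
antgrad cooccur --matrix occupancy.csv --n-rand 5000 --seed 1
antgrad pipeline --demo --out antgrad_out    # full multi-stage synthetic run
```

`antgrad pipeline` writes `cooccurrence.csv`, `dispersion.csv`,
`gradient.csv` and a `run.log`; identical config + seed gives
byte-identical outputs.

## Layout

- `src/antgrad/data.py` — domain containers and result records
- `src/antgrad/io.py` — CSV readers/writers, nest merging
- `src/antgrad/simulate.py` — point-process, occupancy and gradient generators
- `src/antgrad/cooccurrence.py` — C-score, randomization null, SES, filters
- `src/antgrad/dispersion.py` — NND statistic and Monte-Carlo Clark–Evans test
- `src/antgrad/gradient.py` — OLS regressions, ANCOVA, correlations
- `src/antgrad/pipeline.py`, `src/antgrad/cli.py` — orchestration and CLI
- `docs/methods.md` — modeling assumptions, parameter choices, limitations
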