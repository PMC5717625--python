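# desertsem

Piecewise structural equation modelling of a desert food web, with
negative-binomial climate/wildfire scenario simulation and a 100-year
projection of the vegetation–rodent–predator cascade under
predator-removal scenarios.

The package is aimed at ecologists and biostatisticians who work with
long-term trapping, camera-trap and vegetation monitoring data from arid
systems and want to (i) quantify bottom-up (rainfall → vegetation →
consumers) and top-down (predator → prey) pathways jointly, and (ii)
push fitted pathways forward under climate-change driver scenarios.
Because such long-term datasets are rarely public, the package ships a
first-class synthetic-data generator that emulates the study design of a
multi-decade Simpson Desert monitoring programme (9 sites, 2–12 pitfall
grids per site, 36 traps per grid, quarterly trips, daily station
rainfall, per-grid years-since-wildfire, and a 2-year camera window for
dingo, feral cat and red fox), with known ground-truth coefficients so
every stage is testable end to end.

## The model

The food web is a directed graph of nine locally estimated submodels
(26 directed effects): insectivorous dasyurids, spinifex cover, spinifex
seed, rodents, mulgara, feral cat, red fox, dingo and reptiles. Each
node is a GLMM fitted by maximum likelihood with a Laplace approximation
for a single trip-level random intercept:

* count nodes: `y ~ Poisson(exp(X b + log E + u))`, effort offset `E`
  in trap-nights or camera-nights, `u ~ N(0, s²)` per sampling occasion;
* vegetation nodes: grid-averaged scores as binomial-logit, cover out of
  100 (%), seed index out of 5.

Count covariates enter as effort-standardised rates (captures per 100
trap-nights, photographs per camera-night). Per-node fit is the
percentage of null-model deviance explained; effect sizes are
standardized path coefficients — the change in predicted response from a
predictor's observed minimum to its maximum (others at their means,
random effect zero), divided by the observed response range. Paths with
two-sided Wald p < 0.05 are flagged significant.

Climate scenarios draw eight-month cumulative rainfall (NB, µ: 152 → 419
mm, size 1.57) and years-since-wildfire (NB, µ: 21 → 10 yr, size 3.34)
over 12 linear steps spanning 100 years, 2000 draws per step. The
projection feeds each draw through cover, then seed, then rodents (342
runs for the rodent node), under three predator regimes: all predators,
introduced cat + fox removed, all mammalian predators removed.

See `docs/methods.md` for assumptions, parameter defaults and numerical
choices.

## Worked example

```python
import desertsem as d
from desertsem import cli_io

design = d.generate_design(9, seed=1)          # 9 sites, 2-12 grids each
truth  = d.default_ground_truth()
tables = d.simulate_dataset(design, truth, seed=42)

graph  = d.canonical_graph()                   # 9 nodes, 26 effects
frames = cli_io.build_node_frames(tables, graph)
fits   = {s.name: d.fit_node(s, frames[s.name]) for s in graph.nodes}
sem    = d.assemble(fits, graph, frames)
print(f"{sem.n_significant()} of {len(sem.paths)} paths significant")

rod = sem.fits["rodents"]
for term in ("seed_index", "cat_per_cn", "fox_per_cn", "dingo_per_cn"):
    print(f"  {term:14s} std = {d.standardized_coefficient(rod, term):+.3f}")

cfg    = cli_io.RunConfig(out_dir="out", seed=3)
bundle = d.run_full_projection(sem, frames["cat"], cfg)
for line in bundle["summary_lines"]:
    print(line)
```

prints

```
19 of 26 paths significant
  seed_index     std = +0.349
  cat_per_cn     std = -0.081
  fox_per_cn     std = -0.014
  dingo_per_cn   std = +0.057
rodent capture change, introduced predators removed: +77.9%
rodent capture change, all predators removed: +34.1%
```

Reading the output: on this synthetic realisation 19 of the 26
hypothesised pathways are significant. Rodent captures rise with the
spinifex seed index and dingo activity and fall with feral-cat and
red-fox activity (the standardized coefficients are fractions of the
observed rodent-rate range moved across each predictor's observed
range). Removing only the introduced predators raises projected rodent
captures substantially more than removing all mammalian predators —
zeroing the dingo forfeits its positive path — while projected spinifex
cover declines from 30.7 % to 26.5 % across the 100-year
rainfall/wildfire drift. The magnitudes are properties of the synthetic
ground truth; the sign and ordering structure is the scientific content.

The same pipeline is scriptable from a shell:

```sh
desertsem synth   --config config.yaml      # tables + ground truth
desertsem fit     --config config.yaml      # paths.csv, fit_summaries.csv
desertsem project --config config.yaml      # projection.csv + figure
desertsem report  --config config.yaml      # significant-path network
```

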