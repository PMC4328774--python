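# phenodiet

Analysis of carbon-substrate utilization surveys of microbial isolates on
96-well phenotype-microarray plates (Biolog PM1 + PM2A, 190 carbon
substrates), aimed at quantitative-genetic questions: how broad is the
diet of a wild population, how much standing genetic variation does it
carry, are there trade-offs between substrate categories, and does
substrate use diverge geographically?

It is written for microbial ecologists and evolutionary biologists who
survey panels of near-clonal isolates (wild yeasts, bacteria) on plate
arrays with replicate plates and an uninoculated blank, and who want the
chain from raw optical densities to population-level statistics to be
scripted, testable, and reproducible.

## The quantities it computes

For isolate *i* on substrate *s*, with OD read at 590 nm after 72 h,

```
yield(i, s)      = OD_inoculated(i, s) − OD_blank(s)
std. yield(i, s) = yield(i, s) − mean over substrates of yield(i, ·)
```

The top 50 % of substrates by grand mean yield are retained; the **core
diet** is the retained subset on which *every* isolate at *every* site
has positive standardized yield, the rest is the **ancillary diet**.
Downstream statistics:

- **Genetic variance** per substrate and site from a one-way
  random-effects ANOVA over isolates with replicate plates as error:
  `V_G = max(0, (MS_among − MS_within)/n₀)`, genetic SD `√V_G`, genetic
  coefficient of variation `CV_G = √V_G / mean yield`, and the
  standardized variance `SV_A = CV_G²` (by the fundamental theorem of
  natural selection, the proportional fitness gain per generation if
  yield were fitness).
- **Genetic correlations** `r(s, t)` = Pearson correlation of
  isolate-mean yields across isolates, with a permutation null that
  shuffles each substrate's values independently across isolates (the
  "house-car" control), and six category contrasts (core/core,
  ancillary/ancillary, core/ancillary, pentose/pentose, hexose/hexose,
  pentose/hexose) with permutation p-values. Negative between-category
  means are the trade-off signature.
- **Geographic divergence**: PCA of standardized profiles, one-way ANOVA
  of PC1 on site, leave-one-out linear-discriminant classification of
  site or race on leading PC scores, and within-site Mantel tests of
  great-circle geographic distance against Euclidean profile distance
  (isolation by distance).

A calibrated synthetic-survey generator (`phenodiet.synthetic`)
reproduces the full data structure — two sites of 22 + 23 isolates, 2
replicate plate pairs, factor-structured genetic covariance producing
core/ancillary and pentose/hexose trade-offs, site divergence, a spatial
field, replicate noise — with known ground truth, so every stage is
verifiable.

## Worked example

```
$ python examples/01_diet_classification.py
survey: 45 isolates over sites MSH (22 isolates), Silwood (23 isolates); ...
utilized by at least one isolate: 188 / 190 substrates
retained after top-50% filter: 95
core diet (10): Acetic acid, D-Fructose, D-Galactose, D-Mannose, Palatinose,
  Pyruvic acid, Sucrose, Turanose, a-D-Glucose, a-Methyl-D-Glucoside
ancillary yield declines ~linearly with rank: r^2 = 0.99
```

188 of 190 substrates support growth of at least one isolate; half the
panel is used efficiently; exactly the ten designated sugars and derived
metabolites are preferred by every isolate at both sites.  The other
examples print the variance components (mean genetic CV 0.191 / 0.150 at
the two sites, hence SV_A 0.036 / 0.023), the six contrasts (core/core
+0.30, core/ancillary −0.10, pentose/pentose +0.75, pentose/hexose
−0.12, all with permutation p < 0.01), and the geography results (100 %
site classification, Mantel r +0.14 / +0.31 within sites).

The same chain is available as a command-line tool:

```
phenodiet simulate-analyze --preset paper_like --seed 1 -o out/
phenodiet analyze --od plates.csv --map platemap.csv --meta isolates.csv -o out/
```

which writes tidy CSV tables (yields, diet, variance, correlations,
contrasts, ordination, Mantel) and a `report.md` summarizing the run.

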