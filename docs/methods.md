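# Methods

This note documents the statistical model behind each stage, the
parameters that matter, what the synthetic-survey generator does and
does not emulate, and the numerical conventions the implementation
fixes.

## Data model

A survey consists of inoculated 96-well plates (two plate types, PM1 and
PM2A; 95 carbon wells and one water well each), one uninoculated blank
plate per plate type, a plate map, and isolate metadata.  OD is stored
for 24/48/72 h but all statistics use the 72 h endpoint; the earlier
timepoints are pass-through.  OD is dimensionless; no path-length or dye
correction is applied (the tetrazolium comparison is a validation
analysis, not a correction).  Well addresses are canonicalized to
`A1..H12`; the water well sits at A1 on both plates, following the
common convention for these plates.

## Yields and the diet rules

Yield is per-well blank subtraction at 72 h; negative yields are kept
(truncation would bias the variance components upward).  Yields are
computed per replicate and averaged to isolate means; variance
components consume the replicate-level values, everything else the
isolate means.

Utilization: a substrate counts as utilizable if for at least one
isolate a one-sided Welch t-test of that isolate's replicate yields
against the pooled water-well yields of the matching plate type is
significant at testwise α = 0.01.  With two replicates per isolate the
per-isolate test is underpowered, so pooling the water wells across all
plates of a type is essential; even so, the testwise convention admits
roughly `1 − 0.99^n_isolates` false positives per truly inert substrate,
which the report does not correct for (matching the survey convention
the package emulates).

The top-50 % filter ranks substrates by grand mean yield pooled over all
isolates of all sites and keeps the top ⌈n/2⌉; ties break
lexicographically by substrate name so integer-valued fixtures are
deterministic.  Standardization (row-centering) is computed over the
retained set by default, because the poorly utilized half is excluded
from all further analysis; a flag allows centering over the full carbon
panel.

Core diet: a retained substrate is core iff every isolate at every site
has positive standardized isolate-mean yield on it.  This
universal-preference rule is exact and testable, unlike a "shoulder"
detector on the rank plot, and it coincides by construction with the
substrates whose per-site preference counts equal the site sample
sizes.

## Variance components

One-way random-effects decomposition per substrate and site (sites are
never pooled here): `V_G = max(0, (MS_among − MS_within)/n₀)` with the
standard unequal-n coefficient `n₀ = (N − Σnᵢ²/N)/(a − 1)`.
Method-of-moments rather than REML: it is exactly testable against a
hand computation, adequate for a balanced two-replicate design, and
negative estimates are truncated at zero with the truncation counted.
Note the estimator convention: for two isolates with replicate means 10
and 20 and no within-variance, `V_G = 50` (the ddof = 1 variance of the
group means), not the population variance 25 of the two realized means.
The genetic CV divides `√V_G` by the site-specific mean yield of the
substrate; `SV_A = CV²`.  Since averaging and squaring do not commute,
the mean of per-substrate `CV²` exceeds the squared mean CV (Jensen);
summaries report the mean CV and square it afterwards, and the
per-substrate table is retained so users can do either.

Significance is summarized at two conventions: testwise P < 0.05 for the
site classification (both / one site / neither), and testwise P < 0.001,
whose Bonferroni product with ~95 retained substrates gives an
experiment-wise level near 0.1, for conservative flagging.

## Correlations and trade-offs

Genetic correlations are Pearson correlations of isolate-mean yields
across isolates, pooled over both sites by default (per-site matrices
are also available).  Pooling two diverged sites inflates correlations
between substrates that share site effects; this is deliberate — the
headline category contrasts are defined on the pooled panel — and the
generator's calibration accounts for it (below).

The overall mean pairwise correlation is referred to a null obtained by
independently permuting each substrate's column across isolates, which
destroys between-substrate association while preserving marginals.
Category contrasts permute all substrates of the second-listed category
(a flag selects the first or both).  All permutation p-values are
two-sided with the add-one convention (`p = (1 + #extreme)/(1 + B)`),
never exactly zero, and bit-reproducible for a fixed seed.

## Geography

PCA operates on the centered, unscaled standardized-yield matrix
(substrates share the OD unit); each component's largest-|loading| is
made positive so ordinations are deterministic.  Classification is
leave-one-out LDA on the leading PC scores covering ≥ 90 % of variance —
a raw LDA is singular with more substrates than isolates.  Mantel tests
correlate upper-triangle entries of the great-circle (haversine,
R = 6 371 000 m) and Euclidean-profile distance matrices; the p-value
permutes rows/columns of one matrix jointly and is one-sided for
positive association, because isolation by distance is a directional
hypothesis; 999 permutations by default.

## The synthetic-survey generator

The generator's defaults are the emulated survey's design: 22 + 23
isolates at two sites, 190 carbon substrates, two replicate plate
pairs, one blank per plate type, and optional dye/no-dye validation
pairs.

**Means.** Core substrates sit at 2.0 OD; the 85 ancillary means decline
linearly from 0.95 to 0.30 in a fixed (lexicographic) rank order; the
background half declines from 0.06 to ~0, with five substrates exactly
at zero.  Site divergence adds fixed boosts: the six pentoses (+0.35)
and maltose (+0.45) at the first site; the galactose- and
alanine-pathway substrates (+0.35) and the pentose-interconversion
polyols (+0.25) at the second.  These magnitudes are part of the
preset's definition: they make the two sites cleanly separable by
LOO-LDA while leaving the core diet's universality intact.

**Genetic covariance.** Per-isolate deviations follow a three-factor
model — overall vigor, a core-vs-ancillary bipolar factor, a
pentose-vs-hexose bipolar factor — plus independent residuals.  Loadings
are expressed as *fractions* of each substrate's total among-isolate SD,
so the implied correlation structure depends only on the fractions and
is available in closed form; positive semidefiniteness is guaranteed by
construction.  Each substrate's total SD is set to a target genetic CV
times the site mean: CV 0.07 for core substrates (weak core variation is
what makes universal preference possible, and it concentrates
significant variance in the ancillary diet) and a solved ancillary CV
such that the retained-set mean CV is 0.20 at site 1 and 0.16 at site 2.

**Calibration.** `calibrate_loadings` solves the six loading fractions
by deterministic least squares so that the *pooled* category-mean
correlations implied by the model — including the between-site mean
divergence, the spatial and race variance shares, and replicate-noise
attenuation of isolate means — hit the targets (core/core 0.37,
core/ancillary −0.13, pentose/pentose 0.77, pentose/hexose −0.16, with
ancillary/ancillary 0.04 and hexose/hexose 0.06 as soft targets, since
they share parameters with the other four).  The solved preset attains
the four primary targets to better than 0.02.

**Space and race.** Isolate coordinates are uniform in a ~2 km
(site 1) / ~1 km (site 2) bounding box.  A Gaussian field with
exponential covariance (range 400 m) modulates profiles along a random
substrate direction carrying 15 % of the among-isolate variance; the
range is a free parameter — the emulated study reports only Mantel
summaries, no variogram — and the default puts the within-site Mantel r
near 0.2.  Site 1 carries a two-race contrast (races split along the
longitude median, i.e. aligned with geography) worth 10 % of variance.

**Measurement.** OD = blank baseline (0.18) + yield + replicate noise
(SD 0.08), floored at zero after noise — a plate reader cannot report
negative OD — with flooring counted (< 1 % of wells under the
paper-like preset).  Blanks carry SD 0.01 noise.  No-dye validation
plates equal the dye plates plus independent noise whose SD (0.292) was
chosen from the closed-form attenuation `R² = var_signal /
(var_signal + σ²)` to sit near R² 0.76 for a typical plate's across-well
variance.  Inoculum densities are drawn at 5465 ± 2462 cells/mL and
subtract a small per-isolate offset from all yields (slope −1.8·10⁻⁶ OD
per cell/mL), giving the weak negative density-yield relation the
analysis checks for.

All randomness derives from a single seed through named
`SeedSequence.spawn` streams, so fixed-seed runs are byte-identical.

**What the generator does not emulate:** growth dynamics (lag/rate;
only the 72 h endpoint is modeled), batch or edge-well artifacts,
non-Gaussian replicate error, any genealogy behind the isolates, and
substrate-availability differences between habitats.  Passing tests
therefore show that the *estimators* recover known structure of this
form, not that real plate data are this well behaved.

## Problem sizes and numerical conventions

Replicate-survey checks (contrast and CV recovery) use 20 simulated
surveys of the full 45-isolate design — large enough that Monte-Carlo
error on category means is ≈ 0.01–0.02, small enough to run on a
laptop in seconds.  Zero-variance substrates are excluded pairwise from
correlation matrices with a warning; degenerate (constant) regressions
report r² = 0 with a warning rather than raising; empty permutation
categories are skipped.  CSV round-trips are lossless (`repr` floats on
write, round-trip float parsing on read).

## Known limitations

- The utilization call is sensitive to the water-well pooling choice;
  with two replicates there is no well-powered per-isolate alternative.
- Method-of-moments variance components can truncate at zero for
  low-variance substrates, which biases the mean genetic CV slightly
  near zero variance; the truncation count is reported.
- LDA on PC scores depends mildly on the variance threshold (default
  90 %); raw-feature LDA is not offered because it is singular at
  realistic survey sizes.
- The mean-correlation permutation null holds marginals fixed but not
  the isolates' overall-vigor structure; it answers "is there more
  between-substrate association than chance", not "which factor causes
  it".
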