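# Methods

## Model and assumptions

The pipeline treats per-cytosine DNA-modification density as the fraction of
bisulfite-protected reads at a site, estimated as methylated/total reads and
trusted only where depth exceeds 30 reads (strictly; a 30-read cell is
excluded).  The unit of biological replication throughout is the mouse: every
statistical contrast operates on per-mouse densities or per-mouse region
means, never on pooled reads (a pooled-read two-proportion variant exists
behind `test="proportion"` for sensitivity analysis).

Association with expression assumes an approximately linear relation between
a cytosine's density and relative mRNA across the 9-segment design, tested by
Pearson correlation with the two-sided p-value from the t transform at n-2
degrees of freedom.  Normality at individual cytosines is summarised by a
Shapiro–Wilk statistic that is advisory only — it annotates, and never
filters, results.  Family-wise error is controlled by Bonferroni over the
testing universe m, defined as the number of sites that actually pass the
coverage and missingness filters in the analysis at hand: sites that were
never tested cannot inflate the family.  m is logged on every run.

Cluster calls are maximal chains of significant cytosines in which each
consecutive pair lies within 500 bp and shares a correlation sign; chains
with at least 3 members become calls.  Non-significant cytosines (including
the dense CpH background) are not members and neither bridge nor sever a
chain; the alternative reading in which the whole cluster span is capped at
500 bp is available via `span_cap_bp`.  Mixed-sign chains are split at sign
changes, so every call has a single direction.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `min_reads` | 30 | reads | density kept only at depth strictly above this |
| `alpha` | 0.01 | — | significance after Bonferroni |
| `min_size` / `max_gap` | 3 / 500 | sites / bp | cluster chaining rule |
| `saturation` | 0.90 | fraction | sites above this group mean carry no deviation; applied before diet contrasts only |
| `min_sample_fraction` | 0.75 | fraction | a site must be non-missing in this share of each compared group |
| `loess_span` / degree | 0.3 / 1 | fraction / — | positional smoothing window; degree-1 local fits |
| SLP cap | 300 | — | underflow guard for p = 0 |

The saturation filter uses the analysis-group mean; a global-mean variant
would differ only for sites saturated in one group but not the other, and the
group-wise choice is the conservative one for contrasts.

## Synthetic data: what it emulates and what it does not

`synthetic_data` emulates the processed output of a targeted bisulfite
experiment: 609 CpG and 6,971 CpH cytosines over a 100 kb locus, read totals
drawn negative-binomially (mean 200, dispersion 5) with 5% of cells forced to
5–30 reads so the coverage filter is exercised, and methylated reads drawn
binomially at the planted density.  Biological noise is a per-sample
(mouse x segment) Gaussian offset of sd 0.02 added to all sites of that
sample and truncated to keep densities in [0,1]; mRNA noise is multiplicative
with the same relative sd.  Mice are shared across segments (6 mice x 9
segments for the gradient design) so repeated-measures analyses are
well-posed; the diet design uses 6 and 7 mice per arm over 5 segments,
reproducing the 2x5 factorial with 55 residual degrees of freedom.  CpH
sites are simulated at density 0.01, reflecting their lack of signal in this
cell type.

Planted constants are scenario definitions, not fitted values: the GRAD-1
mRNA shape (peak at segment 3, decline both ways) is a declared 9-vector,
and its affine density link sends the mRNA peak to 34.7% and the trough to
77.1% cluster density.  AGE-1 plants a uniform 0.45 infant cluster density
with adult gains of +0.30/+0.18/+0.12 at segments 7/1/3; DIET-1 plants
lactose-arm decreases of 0.052/0.047/0.036/0.064 at its three clusters.

The generator does **not** model read-level artifacts (bisulfite conversion
failure, mapping bias, strand asymmetries), linkage between neighbouring
cytosines beyond cluster co-membership, per-site baseline heterogeneity, or
batch effects.  Passing recovery tests therefore demonstrates that the
statistics recover planted effects under idealised sampling noise — not that
the pipeline is robust to every artifact of real libraries.

## Numerical choices

* Per-site correlation and Welch statistics are computed vectorised with
  masked (NaN-aware) sums; p-values use `scipy.stats.t`.  |r| is clipped to 1
  before the t transform; r = ±1 maps to p = 0 and SLP hits the ±300 cap.
* Degenerate inputs: a site with fewer than 4 complete pairs or zero variance
  is flagged, excluded from m, and carries NaN statistics.  In group
  contrasts a zero-variance pair with equal means yields p = 1 (and p = 0
  when means differ), matching the limiting t.
* LOESS uses the ceil(span·n) nearest neighbours (never fewer than
  degree + 2), tricube weights with the window's maximum distance as scale,
  and a local-coordinate weighted polyfit for conditioning; the farthest
  neighbour's zero weight is floored at 1e-9 to keep the design full rank,
  which leaves polynomial reproduction exact.  No robustness iterations.
* Factorial ANOVA uses Type II sums of squares (statsmodels OLS/anova_lm) so
  unbalanced arms do not create ordering artifacts; RM-ANOVA (statsmodels
  AnovaRM) requires complete mice — incomplete mice are dropped with a
  warning and fewer than 3 complete mice is an error; the F is uncorrected
  for sphericity by default.
* ΔΔCt normalises on the Ct (log2) scale, so the reference group's geometric
  mean fold is exactly 1; amplification efficiency is fixed at 2.
* Percent input shifts the input-aliquot Ct by log2(1/f) to the full-input
  scale; IgG subtraction is on the percent-input scale, floored at 0.
* All randomness flows through one `numpy.random.Generator` per simulation;
  identical (scenario, config, seed) gives byte-identical tables.

## Problem sizes used in the shipped checks

Recovery checks simulate the full-scale locus (7,580 sites x 53–65 samples):
50 seeds for gradient cluster recovery, 100 seeds at 609 CpGs for null
calibration, and 10 seeds for aging/diet shift recovery and for the reported
effect-size estimates — enough to push Monte-Carlo error well below the
±2-percentage-point recovery bands.

## Known limitations

* The density–mRNA link is affine and noise Gaussian; heteroscedastic or
  sigmoidal links are not modelled.
* Bonferroni is the only multiplicity control (no FDR or permutation nulls).
* Pairing of a sample's density with its own mouse's mRNA falls back to the
  segment mean only through the expression table supplied; cross-study
  calibrator designs for ΔΔCt (age-group or pooled references) are supported
  but untested against real calibrators.
* P90 is handled as a further group label in contrasts, not as a
  longitudinal model.
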