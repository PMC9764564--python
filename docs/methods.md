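# Methods

This note documents the model and the numerical/design choices behind
`costnet`, in the order the pipeline applies them.

## Network construction

A subject's connectivity matrix holds Pearson correlations between all pairs
of regional time series; the diagonal is hard-zeroed (self-connections are
not edges, and the AAL-90 pair count is N(N−1)/2 = 4005).

**Cost thresholding.** At cost s the K = round(s · 4005) strongest positive
correlations are retained as weighted edges.  The motivating literature is
silent on how negative correlations enter weighted thresholding; excluding
them is the dominant convention for weighted efficiency analyses and
guarantees non-negative weights so that 1/w is a valid edge length.  An
`edge_sign: absolute` option ranks and weights by |r| for sensitivity
analyses.  Ties at the cost boundary are broken deterministically by lowest
(i, j) pair — reproducibility over arbitrariness.  The grid 0.05…0.40 in
steps of 0.01 (36 values) is generated by integer arithmetic to avoid
floating-point drift in the grid length.  Because thresholding slices a
single ranking, the 36 edge sets are nested by construction, which implies
global efficiency is non-decreasing in cost (adding edges never lengthens a
shortest path).

## Graph metrics

All shortest paths use edge length 1/weight (strong correlation = short
functional distance).  Unreachable pairs contribute 0 to efficiencies (the
harmonic convention), so disconnected graphs — common at cost 0.05 — need no
special casing.  Characteristic path length Lp, by contrast, averages over
*connected* ordered pairs only and is NaN when no pair is connected; the AUC
stage refuses NaN curves and excludes such subjects with a logged reason
rather than imputing.

* Degree is the binary count of incident edges, not strength.
* Local efficiency of node i is the global efficiency of the subgraph
  induced by i's neighbours, keeping the original inter-neighbour weights
  (no incident-weight rescaling); nodes with fewer than two neighbours
  contribute 0.
* Betweenness uses Brandes' algorithm with fractional splitting over
  equal-length shortest paths, normalised by (N−1)(N−2)/2.
* Weighted clustering is the Onnela form, with weights rescaled by the
  maximum edge weight; the chosen variant is recorded in the run metadata
  (`metrics_meta.json`) because several inequivalent conventions circulate.

**Null models.** Small-world indices are normalised against ensembles of
degree-preserving Maslov–Sneppen rewirings (at least 10 × E successful
double-edge swaps per null, 100 nulls by default, mandatory seed).  The
empirical weight multiset is reassigned uniformly at random to the rewired
topology; whether the original analyses used weight-preserving or
topology-only nulls is not recoverable, so the convention is recorded in the
output metadata rather than asserted as fact.  σ is reported per cost like
every other global metric.

**Exactness and speed.** Distances come from Dijkstra
(`scipy.sparse.csgraph`), betweenness from igraph's C implementation, and
local efficiency from a compiled Floyd–Warshall kernel over all
neighbourhood subgraphs (numba), with a pure-numpy batched Floyd–Warshall as
fallback.  The test suite checks all three routes against exhaustive
simple-path enumeration on ~200 random graphs of up to 8 nodes, and the
kernel against the numpy fallback on larger graphs.

## AUC integration

Metric-versus-cost curves are reduced by the trapezoidal rule — the standard
reading of "area under the curve" on a discrete grid; a left-Riemann sum
would differ by O(step) and is not convention-stable.  AUC is linear and
monotone in the curve, which the suite asserts as properties.

## Motion QC

Framewise displacement follows the Power convention:
FD_t = |Δx|+|Δy|+|Δz| + r(|Δα|+|Δβ|+|Δγ|) with head radius r = 50 mm and
rotations in radians (FD_1 = 0; the mean is over frames 2…T).  "Relative
RMS" is implemented as the RMS of frame-to-frame translation-delta norms:
the rigorous matrix-based RMS needs the full affine transforms, which plain
realignment-parameter tables do not carry; the choice is recorded in the run
metadata.  The inclusion gate fails a subject whose cumulative translation
exceeds 2.5 mm on any axis or whose rotation exceeds 2.5° (inclusive
bounds); rotation limits are interpreted in degrees, the SPM convention.
Which motion summary enters the covariate set is ambiguous in the motivating
description (relative RMS vs FD); the config selects one (`motion_measure`,
default `rms`) and the choice is echoed in the manifest.

## Group inference

The omnibus test is a linear model `auc ~ intercept + 2 group indicators +
covariates` with a partial (extra-sum-of-squares) F test of the group
indicators; with an empty covariate list it reduces exactly to one-way
ANOVA, which the suite cross-checks against scipy and statsmodels.  The
abstract-level description of the original workflow says ANOVA while the
methods say ANCOVA with age, sex and motion as covariates; the
covariate-adjusted model is primary here.  Post-hoc pairwise comparisons
regress the covariates out of the *full* sample once and apply pooled
two-sample t-tests to the residuals (Welch by flag); this emulates the
two-sample-t-on-adjusted-values behaviour of the original toolchain, which
is otherwise unspecified.  The Bonferroni family is 90 nodes within each
nodal metric and the three group pairs for global metrics, mirroring how
per-metric corrected p-values are conventionally tabulated; the family size
is recorded on every output row.  Sex enters as a single indicator; no
interactions.  α = 0.05 two-sided throughout.

Degenerate cases are explicit: a response with no residual variance and no
group difference reports F = 0 (not NaN); a rank-deficient design names the
offending column; a constant clinical scale within a group flags the
correlation as not-computable instead of failing the run.

## Synthetic cohorts

The generator produces the *statistical structure the analysis assumes*, not
realistic BOLD physiology:

* **Template.** One Watts–Strogatz topology (N = 90, k = 8 ring neighbours,
  rewiring p = 0.10 — the canonical small-world regime) shared by all
  groups, edge weights ~ Normal(0.30, 0.03) (jitter chosen small so the
  planted multipliers dominate edge ranking).  Group structure enters only
  through multipliers: ×0.85 on every edge in both patient groups, and in
  the depressed group ×0.6 per endpoint on putamen/pallidum/right-STG-like
  nodes (indices 73–76, 82) and ×1.4 per endpoint on right
  SPG/ORBsup/ORBsupmed-like nodes (60, 6, 26).  An edge between two planted
  nodes receives both endpoint multipliers.  These values are configuration
  for detectability at n = 24/20/20 under Bonferroni-90, not claims about
  true effect sizes in disease.
* **Covariance.** Σ_g = template_g + d·I with one shared loading d chosen so
  the smallest eigenvalue across *all* group templates is 0.05.  Sharing d
  is essential: correlations are scale-invariant, so a per-group loading
  would cancel the global ×0.85 attenuation and erase the planted
  efficiency deficit; a shared fixed floor preserves the template weight
  *ratios* into correlation space.
* **Time series.** T = 190 draws (200 volumes minus 10 dummies) from
  N(0, Σ_g) via Cholesky, plus white measurement noise with sd
  0.2·√d (noise_sd = 0.2: visible attenuation without drowning the
  planted structure); an optional AR(1) coefficient on the latents defaults
  to 0 because the analysis consumes second-order structure only.
* **Phenotypes.** Independent Gaussian draws per group around the published
  cohort's means/SDs (age, education, duration, MMSE, HAMD, depression-NPI,
  motion summaries), clipped to valid scale ranges; sex counts match the
  published margins (17/7, 10/10, 11/9).  No age–group confound is planted
  by default; a confound can be introduced through the cohort spec, precisely to
  test that covariate adjustment reacts.
* **Motion.** Mean-reverting (AR(1), ρ = 0.9) six-parameter traces over
  200 frames, translation deltas scaled to hit the subject's drawn relative
  RMS exactly and rotation deltas scaled to absorb the remaining FD target;
  mean reversion mimics a head returning toward rest and keeps excursions
  inside the 2.5 mm / 2.5° gate (extreme draws are redrawn, then damped).

What passing recovery tests shows — and does not show.  Within-group
variability here comes only from correlation sampling noise at T = 190;
real cohorts add between-subject topology differences, haemodynamic and
physiological noise, and registration error, so the power observed on
synthetic cohorts is an upper bound, and recovered significance thresholds
do not transfer to real data.

## Problem sizes in the shipped checks

The test suite runs the full 36-cost grid throughout.  Oracle equivalence
uses 200 random graphs of 4–8 nodes (exhaustive enumeration); small-world
checks use 100 nulls; calibration uses 1000 simulated omnibus tests and 200
Bonferroni-90 replicates; parameter recovery analyses 20 complete default
cohorts (64 subjects each); determinism runs a reduced grid with small null
ensembles, chosen so a complete run stays comfortably within a normal CI
budget on one CPU.

## Known limitations

* The AAL-90 fixture's MNI coordinates are approximate centroids for
  reports and plots; no computation consumes them.
* Lp is averaged over connected pairs only; comparisons of Lp-derived
  quantities across very sparse graphs with different component structure
  should prefer the efficiency metrics (harmonic convention).
* The rewiring null keeps the degree sequence but not the weight-topology
  coupling; σ therefore inherits the usual caveats of weight-shuffled
  nulls.
* Statistical-significance-based edge thresholds, FDR alternatives,
  modularity/rich-club metrics and network-based statistics are out of
  scope.
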