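# Methods

## The redundancy measure

The pipeline operationalizes brain functional redundancy as a *time
proportion*. For each session, sliding windows of `window_volumes` (default
50, step 1) produce Pearson correlation matrices over the parcellated
regional timeseries. Each matrix is proportionally thresholded on a density
grid (default 0.05–0.95 in 0.05 steps, 19 graphs per window): the
`round(d · P)` strongest of the `P = n(n−1)/2` region pairs are kept as
binary edges, rounding half away from zero, ranking by signed correlation,
with exact ties broken by lexicographic node-pair order. Scanning densities
upward, `d₁` is the first density whose graph is one-connected and `d₂` the
first whose graph is two-connected; the window is redundant iff
`d₂ = d₁`. BFR is the mean label across all windows of all sessions,
concatenated in session order.

"Independent pathways" means internally vertex-disjoint paths. By Menger's
theorem the all-pairs condition "≥ k disjoint paths" is equivalent to
connectivity (k = 1) and biconnectivity (k = 2), which the production code
checks in linear time; an explicit max-flow path counter on the
split-node transform exists alongside it and the test suite asserts the
two routes agree on hundreds of random graphs. An edge-disjoint variant
(`path_mode="edge"`) and absolute-value edge ranking
(`rank_mode="absolute"`) are available for sensitivity analyses; defaults
are vertex-disjoint and signed ranking, the common choices for
proportionally thresholded functional connectomes.

Three consequences of the fixed ranking are load-bearing and are asserted
at run time: edge sets are nested across the grid, so k-connectedness is
monotone in density; therefore `d₂ ≥ d₁` always, and the k = 2 scan may
start at `d₁` without changing results. A window that never reaches
one-connectedness by the top grid density is labeled 0 and counted in an
aggregated warning (one line per session, never per window).

### Degenerate windows

A region that is constant within a window has no defined correlation; this
raises an error naming the region rather than propagating NaNs, because a
NaN would silently corrupt the threshold rank order.

## Window parameters

Windows are specified in volumes; duration in seconds (`window × TR`) is
reported as metadata. The 50-volume default at TR = 3 s spans 150 s,
enough to capture the slowest BOLD frequencies of interest (~0.01 Hz); a
100-volume window is reachable by configuration for sensitivity reruns. A
204-volume session loses 4 pre-steady-state volumes and yields
`floor((200 − 50)/1) + 1 = 151` windows. The same formula applied to a
196-volume retained session gives 147 windows; sessions of unequal length
are handled by the formula with no padding. (Published descriptions of
this design sometimes quote 151 windows for every session regardless of
acquisition length; the count formula is authoritative here.)

## Synthetic data: what it emulates and what it does not

The generator produces per-subject, per-session regional timeseries whose
windows have known redundancy ground truth, plus subject tables, cognitive
batteries, and moderated outcomes. All randomness flows from explicit
seeds; identical calls are bit-identical.

### Redundant and fragile covariance states

Both states are exact factor models (`Σ = B Bᵀ + diag(noise)`), sampled as
`X = Z Bᵀ + ε`. The `snr` parameter sets per-region noise variance to
`structural_variance / snr`, so within-community correlation is
`snr/(snr+1)` (0.91 at the default snr = 10).

*Redundant state.* Two equal communities of regions, each driven by a
single shared factor, plus a weak homotopic-style coupling (variance 0.25)
pairing every region with one partner in the opposite community. The tied
within-community correlations occupy the density grid up to just below
50%; the first grid density whose edge quota exceeds the within-community
edge count (`≈ n²/4`) admits roughly `n/4` cross-community edges at once.
At that density the graph jumps from two internally biconnected components
straight to a biconnected whole — so it is two-connected at the same
density at which it first becomes one-connected, and windows are labeled
redundant. The homotopic matching exists because correlated factor-noise
otherwise concentrates the first cross edges on single "hub" regions
(a cut vertex); matched pairs are vertex-disjoint by construction and
their deterministic correlation advantage (≈ 0.19 at snr 10) outweighs the
hub noise. This design was chosen over ring-with-chords constructions,
which proved unreliable at 50-volume windows: in any nested edge process
connectivity precedes biconnectivity unless both transitions land inside
one 5% grid step, and correlation sampling noise (sd ≈ 0.14 at 50 volumes)
kept splitting them.

*Fragile state.* A uniformly random spanning tree with maximum degree 3,
one latent factor per edge, so every tree-edge correlation is at least
`1/(3(1+1/snr))`. The tree connects at a low density, but its leaves gain
second pathways only through weak noise edges much later, so `d₂ ≫ d₁`
and windows are labeled non-redundant. The degree cap keeps hub regions
from diluting edge correlations (a star's edges would fall to ≈ 0.2 and
below the noise floor).

At n = 20 regions and snr = 10 these designs label ≥ 95% of pure windows
correctly (measured across seeds); reliability degrades below ~12 regions,
where the density-grid arithmetic loses its safety margin. State changes
occur at block boundaries; windows straddling a boundary mix covariances
and carry no ground-truth label.

What the generator does **not** emulate: hemodynamic response functions,
scanner drift and physiological noise spectra, head-motion artifacts
within timeseries, spatial autocorrelation of real parcellations, or
site-specific acquisition differences beyond a binary site covariate.
Passing tests therefore demonstrate that the *algorithmic chain* recovers
known structure, not that real resting-state data contains such structure.

### Subject table

Age is uniform on [18, 89] years. Cortical thickness (mm), the cortical
GM volume fraction, and brain age (years) are linear in age with Gaussian
noise (thickness ≈ 2.75 − 0.006·(age−18) ± 0.07; GM fraction ≈ 0.42 −
0.0012·(age−18) ± 0.012 of a TIV ≈ 1.45 × 10⁶ ± 1.1 × 10⁵ mm³; brain age
= age ± 5), magnitudes in the range structural pipelines report for
healthy adults. Maximum displacement is log-normal (median ≈ 0.67 mm,
σ_log = 0.75), so a 2.5 mm cut excludes a small right tail (~3–4%). Sex
and site are fair Bernoulli 0/1 codes.

### Cognitive battery

Scores are `factors · loadingsᵀ + noise` for 13 tests and 3 latent domain
factors. The default loading matrix encodes a realistic battery: six
episodic tests with communalities 0.60–0.85 on a dominant episodic/general
dimension, three semantic (vocabulary/reading) tests on a second dimension
with a slight negative tilt on the first, three executive tests
cross-loading on the first and loading modestly on a third, and a Trail
Making test that is almost entirely unique variance (0.98). Three clean
block-diagonal factors were rejected as defaults: after z-scoring they
produce a flat-topped scree with a cliff, and the line-distance elbow rule
then selects four components. The chosen structure yields a population
scree of ≈ 40/16/8% with a gently declining tail and a stable
three-component elbow at n = 260 (200/200 seeded cohorts), and its
component pattern (episodic-dominant PC1, semantic PC2, executive PC3,
Trail-Making-dominated PC4) mirrors what such batteries empirically show.

### Moderated outcomes and full cohorts

`gen_moderated_outcome` is the literal linear model `y = β₀ + β_bc·bc +
β_bfr·bfr + β_int·bc·bfr + β_site·site + β_sex·sex + ε`. Cohort defaults
use the episodic-model coefficient set (β_bc = 14.39, β_bfr = −0.03,
β_int = −0.15, β_site = −0.74, β_sex = 1.02) with residual SD 1.71 and
n = 260 — the conditions at which the calibration simulations run. In
`gen_cohort`, a per-subject redundancy propensity drives the per-block
state sequence (so true BFR varies across subjects), the episodic factor
is generated from the moderation model with cortical thickness as the
brain change, and the other two factors are independent; the truth record
retains every parameter needed to recompute expected effects.

## Cognitive PCA

Complete cases are selected before z-scoring, so column means and SDs
describe the analyzed sample. Columns are standardized with the n−1
denominator and decomposed by PCA (correlation-scale, since the input is
z-scored). Loadings are sign-fixed so each component's largest-magnitude
coefficient is positive; signs carry no statistical meaning. The retained
count is the 1-based index maximizing perpendicular distance to the chord
from the first to the last scree point, in (index, variance-%) coordinates
without axis normalization; ties within floating-point noise take the
earliest point. Retained components are labeled by the domain whose own
tests have the highest mean |loading| (size-normalized); an exact tie is
an error prompting a manual label. Trail Making enters as-is with no
reversal for its lower-is-better scale — no transformation is applied to
any test.

## Moderation models

Each brain-change definition gets one model: the retained components are
regressed on {BC, BFR, BC × BFR, site, sex}, plus chronological age for
the brain-age model only (to absorb the chronological-age bias of brain-age
predictions); flags allow adding age to the other two for sensitivity
reruns. GM volume is first normalized by total intracranial volume.
Predictors enter uncentered, matching the plain regression formula; note
that an uncentered product term is strongly collinear with its main
effects, which inflates the interaction's standard error — a property of
the design, not an estimation problem (a `center` flag exists for
conditioning comparisons only, as centering reparameterizes the main
effects). The multivariate fit is per-outcome OLS on the shared design —
point estimates identical to a joint multivariate fit; the joint residual
covariance is reported, but no multivariate test statistic is computed.
p-values are two-sided from the t distribution and uncorrected. A
condition-number guard (10¹⁰) rejects collinear designs, and fits require
at least ten more observations than predictors.

Sex and site reference categories are the 0 codes; which level is coded 0
is configurable upstream of the model and documented in the subject table.

Display splits: `mean_split` assigns values at or above the mean to
"high"; `threshold_split` cuts BFR at a fixed fraction (default 0.30) with
values at the cut going "high", and reports per-group simple slopes of
outcome on brain change.

## Numerical choices

- Edge quota rounding: half away from zero (`floor(x + 0.5)`), matching
  common proportional-threshold implementations.
- Tie-break for equal correlations: lexicographic (i, j); this fixes the
  nested-edge-set property and run-to-run determinism even when every
  off-diagonal entry is identical.
- Correlation matrices are symmetrized and clipped to [−1, 1] after
  computation to suppress floating-point asymmetry (< 1e−12).
- Elbow ties: resolved to the earliest index within a 1e−12 relative
  tolerance.
- TSV/CSV numeric text uses 17 significant digits and round-trip float
  parsing, so write→read is bit-exact.

## Problem sizes

The test suite and the acceptance script run on desk-scale versions of the
study conditions: 12–20 regions (the real parcellation has ~167; the
redundancy arithmetic is identical, and the two-community design is in
fact *more* robust at larger n), 20–40 subjects for end-to-end runs, the
full n = 260 for PCA and regression calibration, 20 seeds for state
separation, and 200/500 replicates for the interaction calibration. These
sizes were chosen so the whole suite exercises every stage at full
statistical fidelity while remaining quick on a laptop.

## Known limitations

- The redundancy labeler's behavior at the grid's edge (a window never
  one-connected by 0.95) is a package decision (label 0, warn); published
  descriptions of the scan do not state a fallback.
- Whether signed or absolute-value ranking, vertex- or edge-disjoint
  paths, and which rounding rule the original toolbox used are not
  documented in the sources this design follows; all are configurable, and
  the defaults are the field-standard choices.
- The synthetic generators define ground truth only for windows fully
  inside one state block.
- With uncentered predictors, single-draw interaction estimates at the
  default effect size are noisy (see the calibration simulations for the
  replicate-level behavior); this mirrors the modeling choice, not a bug.
- BFR's empirical distribution in real cohorts is not characterized here;
  generator defaults are chosen for state separability, not to match an
  observed BFR histogram.
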