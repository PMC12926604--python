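# Methods

## Pipeline model

The analysis treats each participant's brain as an undirected network whose
nodes are parcellation regions and whose edges are absolute Pearson
correlations between regional BOLD time series. The fixed processing order
is bandpass filtering → nuisance regression → frame censoring → correlation;
censored frames are simply removed before correlating (no interpolation),
so correlating after censoring equals correlating the retained submatrix
directly.

Temporal QC conventions:

* **Filter** — 4th-order Butterworth, applied forward–backward
  (`scipy.signal.sosfiltfilt`) for zero phase; the band (default
  0.009–0.08 Hz) and order are config-exposed. Only the band is dictated by
  the analysis design; the order is standard resting-state practice.
* **FD** — sum of absolute backward differences of the three translations
  plus 50 mm times the same for the three rotations (arc-length
  conversion); FD at frame 0 is 0 by convention. Threshold 0.5 mm.
* **DVARS** — RMS over regions of the frame-to-frame signal difference,
  computed on the raw-intensity series rescaled to a global median of 1000
  so the conventional threshold of 5 has meaning; both the normalization
  and the threshold are config parameters, since only the threshold value
  is fixed by the design. The pipeline computes DVARS before filtering
  because bandpassing removes the intensity baseline the normalization
  refers to.
* **Minimum duration** — participants with fewer than 270 s (4.5 min) of
  retained data are excluded; the boundary passes (≥).
* Only flagged frames are censored; no neighbor augmentation.

Network construction: all matrix values are absolute correlations (strong
negative couplings count as strong edges); the diagonal is zeroed
everywhere. Absolute thresholding keeps edges with |r| ≥ t (non-strict
boundary, config-exposed). Proportional thresholding keeps exactly
k = round-half-away(p·N(N−1)/2) strongest edges, with ties broken by
descending weight then ascending (i, j) order so repeat runs are identical.
Default sweeps are t ∈ [0.10, 0.65] and p ∈ [0.25, 0.65] in steps of 0.05;
`validate_sweep_bounds` reports per-threshold mean/median component counts
so a study can restrict the range to where networks stay essentially
connected (mean and median below 2). The synthetic demo cohort fragments
above t ≈ 0.35, so its end-to-end runs use the admissible range
[0.10, 0.35]; the package defaults are unchanged.

## Graph metrics

All 13 measures are implemented directly (no graph library at run time):

* Weighted path length uses the connection-length convention
  (length = 1/weight); binary distances are BFS hop counts, weighted
  distances Dijkstra. Average path length on disconnected networks is taken
  over reachable pairs only, which keeps sigma defined at sparse
  thresholds.
* Weighted clustering and transitivity use the Onnela
  geometric-mean-of-triangle-weights form on weights rescaled by the
  network maximum, normalized by binary degree.
* Betweenness is raw (unnormalized) Brandes accumulation — any fixed
  normalization cancels in the cross-participant standardization. For
  binary graphs the accumulation is evaluated level-synchronously for all
  sources at once as matrix products over BFS levels (algebraically
  identical to per-source Brandes).
* Eigenvector centrality is power iteration on A + I (the shift breaks the
  ±λ tie on bipartite graphs without changing eigenvectors), nonnegative,
  unit Euclidean norm, relative tolerance 1e-10.
* Assortativity is the Pearson correlation of endpoint degrees (weighted:
  strengths) over directed edge instances; regular graphs have zero
  endpoint variance and are reported undefined.
* Communities come from Louvain-style greedy modularity maximization with
  aggregation, best of n_restarts (default 10) under a seeded generator;
  the participation coefficient uses that partition.
* Small-world sigma uses Maslov–Sneppen degree-preserving rewiring
  (default 10 nulls, 10·|E| attempted swaps each); weighted networks rewire
  the binary topology and shuffle the weight multiset over the rewired
  edges. When no swap is possible (complete or star-like graphs) the nulls
  equal the observed network and sigma is exactly 1, with a warning.
* Undefined values (assortativity on regular graphs, eigenvector
  centrality and modularity on edgeless graphs, sigma when clustering is
  zero) propagate as NaN and are dropped complete-case downstream, never
  silently zeroed.

## Group analysis

Metrics are z-scored across participants within each
(scheme, threshold, region, metric) cell (sample-SD convention;
zero-variance cells become missing with a warning), then averaged per
region and metric across the sweep; a participant's summary is kept only
when more than half of the thresholds are present. The weighted scheme has
a single "threshold" and passes through.

The screen fits ordinary least squares per (scheme, region, metric) and
per test: Score ~ Age + Sex + CHD + GraphMeasure + CHD×GraphMeasure, with
CHD and sex coded {0, 1} (control/female = 0), age in years uncentered
(scores are age-corrected standard scores, so age acts as a residual
covariate), complete-case per test, at least 10 complete cases, and a fixed
two-sided p < 0.001 on the interaction with no multiplicity correction (a
Benjamini–Hochberg mode exists but is off by default and labelled an
extension). Rank-deficient designs are flagged unestimable rather than
dropped silently.

Age stratification assigns a participant to bin [lo, hi] iff
lo ≤ floor(age) ≤ hi (default bins 8–11 and 12+); participants outside all
bins are excluded with a log entry.

System segregation for the 14-label AALv3 DMN set is
(Z̄_w − Z̄_b)/Z̄_w with Z̄_w the mean absolute correlation over unordered
within-DMN pairs and Z̄_b the mean over DMN–external pairs, on the same
absolute-valued matrix the networks use (the segregation literature often
uses signed Fisher-z values; the choice is config-visible by passing a
different matrix). Z̄_w = 0 is undefined and flagged.

## Synthetic cohort: what it emulates, and what it does not

The generator reproduces the study design knobs that matter downstream:
two groups (default 47 CHD / 75 controls), ages uniform on 6–25 years, sex
Bernoulli(0.5), TR 2 s with 150 frames (300 s, above the 270 s floor),
community-structured coupling (default within 0.35 / between 0.10 across 6
communities at 90 regions), and motion with FD spikes (rate 0.05/frame,
1.0 mm) over a sub-threshold baseline. BOLD series are Gaussian AR(1)
(lag-1 coefficient 0.3) with the cross-sectional covariance imposed
exactly through a Cholesky factor, placed on a raw-intensity scale
(baseline 1000, fluctuation SD 2) so the DVARS convention behaves as on
real data. A full-scale atlas parcellation is approximated with 90 regions;
reduced-scale runs pass smaller values explicitly.

Individual variability is modelled by drawing each participant's
correlation matrix from a Wishart distribution around the group matrix,
rescaled to unit diagonal (`participant_dof`, default 150; smaller = more
heterogeneity). This is exactly the distribution of a sample correlation
matrix estimated from `dof` frames of the group process, is positive
definite by construction, and induces the realistic property that edges
sharing a region co-vary across participants.

A planted group effect shifts couplings incident to the configured effect
regions; by default the shift is **mean-preserving** — the remaining edges
receive the small compensating opposite shift — so the planted effect is a
local reallocation of connectivity rather than a global connectivity
difference, matching cohorts in which average connectivity does not differ
between groups while local organization does. For interaction studies,
each participant additionally receives an independent scalar coupling
offset at the effect regions (`coupling_jitter_sd`, default 0.08); this
offset is the ground-truth "GraphMeasure" from which cognitive scores are
generated via score = β₀ + β₁·age + β₂·sex + β₃·CHD + β₄·m + β₅·CHD·m + ε
with m the standardized offset (plus group shift) and ε Gaussian. Planting
at the coupling level, upstream of all metrics, mirrors how real group
differences would arise; recovery tests therefore tolerate attenuation
from metric-estimation noise.

What the generator does **not** emulate: hemodynamics (no balloon model),
voxel-level images, scanner artifacts beyond motion spikes, physiological
noise, spatial autocorrelation within regions, or non-Gaussian score
distributions (instrument ceilings, skewed parent ratings). Passing tests
demonstrate the pipeline's statistical machinery — construction, metrics,
standardization, screening — is correct and calibrated under a faithful
covariance-level model; they do not validate image-level preprocessing
choices against real scanner data.

### The planted-effect detection study

The end-to-end demonstration plants one region's coupling (region 20 of
30, 150 frames, dof 100, jitter SD 0.08, group shift 0.05 kept small so
the CHD×metric term is not collinear with CHD) and generates scores with
β₅ = 25 and noise SD 10 — set by power analysis targeting a minimum
per-scheme interaction t of about 5 after attenuation (pilot attenuation
r ≈ 0.7–0.9 between the threshold-averaged degree and the true offset).
The planted pair is (region 20, degree): the scores derive from coupling
strength, whose direct graph counterpart is degree/strength. Spatial
specificity is assessed within the planted metric's rows; metrics that
aggregate a node's whole neighborhood — weighted local efficiency or
clustering on a complete weighted graph — respond to any coupling
reallocation at every node by construction and carry no per-region ground
truth in this design. The absolute sweep for this cohort is restricted to
[0.10, 0.35] by the component-count rule.

The attenuation r is itself a random property of each cohort draw (the
Wishart background and the PD-driven shrinkage of extreme offsets vary), so
the probability of detecting the planted pair at p < 0.001 under all three
schemes simultaneously varies between roughly 0.6 and 0.95 across seed
families; null-region specificity is stable (~98% of null regions absent on
average).

## Numerical choices and degenerate inputs

* Proportional-threshold ties: descending weight, then ascending (i, j);
  k = 0 after rounding is rejected as degenerate.
* Exact symmetry is enforced after `corrcoef` (which is symmetric only to
  floating tolerance).
* Constant regions make the correlation undefined and raise an error
  naming the region.
* A planted offset that would break positive definiteness is halved until
  admissible, and the applied value is what the scores are generated from.
* Louvain ties: a node stays in its community unless the gain exceeds it
  by more than 1e-12; partitions are relabelled by first occurrence.
* Sigma with zero swaps (rewire factor 0, or no valid swap) returns the
  observed C and L for the nulls, making σ = 1 exact rather than
  accumulating mean-of-identical-floats rounding.

## Known limitations

* OLS p-values are exact under Gaussian errors; with heavy-tailed metric
  distributions (betweenness at sparse thresholds) the fixed p < 0.001
  screen can be mildly anti-conservative — the screening design
  deliberately forgoes multiplicity correction, so findings are screening
  candidates, not confirmatory results.
* Louvain is a greedy heuristic; restarts make small-graph optima reliable
  but give no guarantee at scale.
* The weighted scheme operates on complete graphs, where
  neighborhood-aggregating metrics have little spatial specificity (see
  above).
* Segregation uses absolute-valued correlations; signed conventions will
  differ where negative couplings are informative.
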