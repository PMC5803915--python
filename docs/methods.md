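# Methods

This note documents the modelling choices behind each pipeline stage, the
defaults and their rationale, and what the synthetic cohorts can and
cannot establish.

## Region table and node sets

The packaged parcellation (`data/regions_table1.tsv`) lists 76
hemisphere-resolved parcels of the rat brain; the 54 parcels containing
grey matter double as functional-network nodes (pure white-matter tracts
carry no usable BOLD signal and are excluded). Each network fixes its
matrix convention through a `NodeSet`: nodes are ordered by ascending
1-based table index and given contiguous 0-based ids, so files stay
1-based as published while matrices are 0-based.

The fixture's region volumes are **synthetic** (seeded uniform draws,
4–45 mm³): the published source table prints none, and the fiber-density
weight needs positive volumes. Real analyses must supply their own
volumes; all volume-dependent results on the fixture are internally
consistent but not anatomical.

## Structural connectome

Streamlines are undirected: tractography assigns start/end arbitrarily,
and all graph metrics downstream assume symmetry, so the unordered pair
defines the connection and the matrix is symmetric by construction.
Self-loops are dropped. Edge FA is the unweighted mean of per-streamline
FA (length weighting is a defensible alternative; the unweighted mean is
the simpler reading and is what the tests pin down). Fiber density is

    FD = (1 / (V_i V_j)) Σ_s 1/l(s)

with lengths in mm and volumes in mm³; no unit rescaling is applied —
only within-cohort comparability matters for group statistics. Endpoints
outside the declared node set are a hard parse error, surfacing
parcellation/tractography mismatches instead of silently dropping data.

## Functional preprocessing

Per-region pipeline, in order: linear detrend → band-pass 0.01–0.1 Hz →
nuisance regression → z-score. The band-pass is a hard rFFT mask: the
band alone defines the filter, and the operation is reproducible
bit-for-bit across platforms (an IIR/FIR design would add order/ripple
choices the analysis does not need). Nuisance regressors (motion, mean
WM and CSF signals) are detrended and band-passed like the data before
OLS residualisation, so regression cannot reintroduce out-of-band
signal; a consequence used by the tests is that a regressor identical to
a region's series zeroes it exactly, which is then reported as a
constant-series error naming the region.

Two numerical caveats are deliberate:

- *Near-idempotence.* On a finite window a linear ramp is not orthogonal
  to the Fourier basis, so re-running the pipeline on its own output
  shifts values by ~1e-2 SD units (a second detrend finds a small slope
  in band-limited data). The invariant we enforce is material
  equivalence (max deviation < 0.05 SD, per-row correlation > 0.999),
  not bitwise idempotence.
- *Constant series* at any stage are an error, not a silent drop: a flat
  region cannot enter a correlation matrix.

## Partial-correlation network

Edge weights are full-conditioning partial correlations from the inverse
sample correlation matrix, pcorr(i,j) = −P_ij/√(P_ii P_jj). With the
default dimensions (54 regions, 600 samples) the problem is well-posed;
if the condition number exceeds 1e10 a ridge term λI (λ = 1e-6·trace/N)
is added, and `ridge=0` turns the guard into an error. Negative partial
correlations are excluded *before* the Fisher z-transform; since
arctanh preserves sign, thresholding before or after the transform is
equivalent, and pre-transform keeps the weights finite by construction.

## Graph metrics

- Distances use edge length 1/weight — the standard inverse mapping in
  weighted brain networks. This choice affects every weighted
  integration metric and is therefore stated prominently.
- Global efficiency: mean of 1/d over ordered pairs, 1/∞ = 0, so
  disconnected networks are summarised, not rejected.
- Nodal efficiency: global efficiency of the subgraph induced by the
  node's neighbours (node excluded), i.e. the fault-tolerance reading of
  per-node efficiency. The closeness-style alternative (mean inverse
  distance from the node) is available as
  `closeness_efficiency` but is not the default and feeds no summary.
- Clustering: binary triangle fraction; weighted form is the Onnela
  geometric-mean triangle intensity on max-normalised weights, the
  dominant convention in the connectomics literature. With all weights
  equal it reduces exactly to the binary value.
- Degree counts any strictly positive weight; no threshold is applied,
  matching how the binary connectome is derived from the weighted one.

All metrics are checked against independent brute-force oracles
(Floyd–Warshall relaxation, neighbour-subgraph materialisation, triangle
enumeration, networkx's Onnela implementation) exhaustively on all
graphs with up to 5 nodes and on seeded random families to 30 nodes; the
exhaustive family is capped at 5 nodes because the 6-node enumeration
(32,768 graphs) adds runtime without adding coverage beyond the sampled
6-node check.

## Statistics

- Kruskal–Wallis on midranks with tie correction; p from the χ²(1)
  reference. An exact permutation mode (feasible to ~8 per group)
  enumerates group assignments and is used by the test suite to validate
  the approximation at the study's sample sizes.
- The age-adjusted model is a Gaussian GLM with identity link,
  `value ~ intercept + group + age`; the group coefficient's two-sided p
  uses the t reference with n−3 degrees of freedom. With constant age
  the model collapses to the two-sample comparison; group perfectly
  collinear with age is an identifiability error. Age matters because
  the cohort design scans each animal right after it finishes
  behavioural testing, so slower-learning (transgenic) animals are
  scanned older.
- FDR is Benjamini–Hochberg, applied per (connectome kind, metric)
  family across regions by default; a pooled mode corrects across all
  regional tests at once. Global metrics are few and reported
  uncorrected.
- The behaviour screen reports Spearman r per (metric, outcome) pair and
  flags |r| strictly greater than 0.7, with no multiplicity correction —
  it is a screen, not a confirmatory test.

## Synthetic cohorts

The generator emulates the four input kinds at the study's conditions:
9 animals per group; 76/54 regions; 600 volumes at TR 2 s; age at scan
~N(151.11, 12.06²) days for controls and ~N(181, 32.6²) for transgenics
(truncated at 40 days), reproducing the group–age confound.

- *Streamlines*: regions get seeded 3-D positions in a rat-brain-sized
  box; connection probability decays exponentially with distance
  (scaled to a target edge density, default 0.30); connected pairs get
  1 + Poisson(6) streamlines with lengths proportional to inter-region
  distance (log-normal spread) and per-streamline FA ~N(pair mean, 0.04)
  with pair means uniform on 0.30–0.60. The transgenic group's FA is
  multiplied by (1 − fa_effect), default 0.15 — large enough for a 9+9
  rank test to detect reliably, small enough that single small cohorts
  can miss it.
- *Time series*: white Gaussian noise with covariance inverse to a
  seeded sparse SPD precision matrix, plus a linear trend, motion
  random walks and band-limited WM/CSF signals mixed in through random
  loadings, so every preprocessing step has real work to do. A filter
  common to all channels preserves cross-channel correlation structure,
  so sample partial correlations converge to the planted precision.
- *Behaviour*: training-session and DNMS trial counts follow per-group
  count models (transgenic slower to learn, fewer trials); one named
  outcome is tied to one named network metric (global or regional)
  through a Gaussian copula on ranks with latent Pearson
  ρ = 2 sin(πρ_s/6), so the Spearman target is exact in expectation.
  Default coupling: FD-weighted average strength vs total training
  sessions at ρ_s = −0.72, the magnitude regime of the whole-brain
  correlations the pipeline is built to screen for.
- A ground-truth manifest records every planted effect; regional
  effects (`plant_regional_effect`) multiply FA or length on one
  region's incident streamlines in the transgenic group only.

What the synthetic data do **not** emulate: anatomy (region geometry is
random), realistic streamline-count or FA distributions (none are
published for this design), BOLD autocorrelation and physiological
noise spectra, learning dynamics within the behavioural task, and any
coupling between structural and functional networks of the same
subject. Passing tests therefore establish correctness of the
computations and calibration of the statistics under known ground
truth — not biological fidelity of any particular effect size.

## Simulation sizes

Replicate-based checks run at reduced dimensions chosen to keep the
whole suite fast while leaving the statistics meaningful: 30 structural
regions, structural modality only and mean 3+1 streamlines per connected
pair for the 200-replicate FA-effect recovery; 1,000 simulated 9+9
cohorts for the GLM null-calibration; a 20-region cohort at 9+9 for the
planted-coupling screen. The study-scale defaults (76/54 regions, 600
samples) are exercised once per run by the schema-conformance and
pipeline tests.

## Known limitations

- The fiber-density scale depends on the synthetic fixture volumes;
  absolute FD values are not comparable across region tables.
- The partial-correlation estimator assumes T comfortably above N; the
  ridge guard keeps small-T experiments running but biases edge weights
  toward zero.
- The exact Kruskal–Wallis mode enumerates combinations and is
  intentionally refused above ~200,000 assignments.
- `Connectome.from_csv` reconstructs node provenance from labels and
  assigns sequential source indexes; round-trips preserve matrices and
  labels, not original table indexes.
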