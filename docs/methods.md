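# Methods

## Model and procedure

The pipeline assumes per-patient tables of single-cell measurement vectors
x ∈ ℝ^P with a binary patient-level class label, where the class-mean
difference is small compared with the within-class cell spread.  Its steps:

1. **Supercell construction.**  A supercell of size N is the arithmetic
   mean of N randomly selected cells from one patient.  K independent
   draws give that patient's supercell cloud.  For i.i.d. cells with
   finite per-measurement variance σᵢ², the CLT gives supercell marginals
   with the same means and SDs σᵢ/√N, increasingly Gaussian in N.  No
   distributional assumption is made about the cells themselves; skewed
   inputs are handled by the same averaging.  Cells are never pooled
   across patients, so patient identity is preserved as a point cloud.
2. **Classification.**  A soft-margin SVM with a linear kernel is fitted
   to the pooled supercells of all training patients in z-scored space.
   The unit normal to the hyperplane (the amplitude vector) weighs each
   measurement's contribution to class separation; signed Euclidean
   distance from the hyperplane is the working coordinate downstream.
   The first class of the cohort's ordered class pair sits on the
   positive side.
3. **Ranking and the (N, M) tradeoff.**  Measurements are ordered by
   decreasing |amplitude| from the all-measurements fit at the working
   supercell size (the ranking is size-dependent for small N and
   stabilizes for large N).  Refitting on the top-M prefix for each (N, M)
   pair yields the accuracy grid: more cells averaged can substitute for
   fewer markers measured, and vice versa.
4. **Jackknife diagnosis.**  Each patient is held out in turn; the
   boundary is fitted on the remaining patients and the held-out cloud is
   called for a class only when at least θ of its K supercells lies on
   that side (abstaining otherwise).  Cohort outcomes are percentages of
   patients correct / unclassified / incorrect per M.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `size_n` (N) | — | cells averaged per supercell; SD shrinks ∝ 1/√N |
| `count_k` (K) | 100 | supercells per patient; resolution of the cloud fraction (1/K) |
| `replacement` | `never` | cells distinct within a supercell; clouds drawn independently, so different supercells may share cells |
| `margin_cost` (C) | 1000 | soft-margin cost; ≈ hard margin on separable supercell clouds, still defined on overlapping single-cell input |
| `threshold_theta` (θ) | 0.95 | abstention band; must exceed 0.5 so at most one class can claim a cloud; comparison is ≥ (a cloud exactly at θ is classified) |
| `ranking_scope` | `per_fold` | re-rank within each training fold (no leakage); `global` reproduces a single cohort-wide ranking |
| `evaluation` | `held_out` | accuracy grids split each patient's cells in half before building fit and evaluation supercells; `training` is the resubstitution protocol |

## Design choices

- **Sampling scheme.**  "Random subsets of N cells" leaves open whether
  subsets may share cells.  Default: no repeats within one supercell,
  independent subsets across supercells.  Disjoint partitioning would cap
  K at (cells/N), which contradicts drawing K=100 clouds of N=500 from
  ~10⁵ gated cells, so it is not offered.  Plain i.i.d. draws
  (`within_supercell_allowed`) are available; no finite-population
  correction is applied when comparing with 1/√N.
- **Seeding.**  Each patient's draw stream is derived from the master seed
  plus a CRC-32 of the sample id (plus the config), so adding or removing
  one patient never perturbs another patient's supercells, and the same K
  test supercells are reused across M within a jackknife fold — M-curves
  differ only by measurement set, not by sampling noise.
- **Standardization.**  z-scoring is fitted on the training supercells at
  the working N; amplitudes are reported in standardized space so markers
  with arbitrary intensity scales are comparable, and any positive
  rescaling of a raw column leaves amplitudes, rankings and accuracies
  unchanged.  Note that at large N the pooled supercell SD is dominated by
  the between-class separation, which compresses the z-space amplitudes of
  strongly separating markers toward one another; the unstandardized fit
  (`standardize=False`) recovers the raw geometric normal.
- **Zero-variance measurements** are dropped with a warning and recorded
  on the fitted boundary (amplitude exactly 0); missing or non-finite
  input values are hard errors everywhere — the method averages raw
  vectors, and silent imputation would corrupt supercell statistics.
- **Gating** thresholds are user-supplied (none are inferred): positive
  gates are strict (>), negative gates are (≤), so the two directions at
  one threshold partition the cells exactly.  Gating is conjunctive, hence
  idempotent and order-insensitive.
- **Ties** in the amplitude ranking break by original column order
  (stable sort), for reproducibility.
- **θ boundary case.**  A cloud exactly at the threshold is classified
  (≥), fixed here because prose descriptions of such bands are routinely
  inconsistent about the boundary case.
- **Minimal-measure / minimal-size searches** return `None` when no M or N
  meets the criterion: an unattainable criterion is a result, not an
  exception.
- **Degenerate inputs.**  Single-class training sets, folds that lose a
  class, supercell sizes exceeding a patient's cell count, empty gates and
  zero-spread width ratios all raise typed errors (`supercells.exceptions`).

## Synthetic cohorts

`generate_cohort` draws cells as
`class mean + patient offset + (subpopulation offset) + cell noise`, with
class shifts, patient-effect SDs and subpopulation offsets all expressed in
units of the per-measurement cell SD.  Defaults emulate a small clinical
flow-cytometry cohort: 8 + 14 patients, 16 measurements of which 5 carry a
0.3-SD class shift (pooled shift ≈ 0.67 SD, single-cell accuracy ≈ 0.63 —
heavily overlapping — while supercells of a few hundred cells separate
cleanly), 2000 cells per patient, patient offsets of 0.05 SD, Gaussian
noise with an optional moment-matched log-normal skew transform.

Patient effects are additive mean shifts only — the minimal structure that
makes leave-one-patient-out prediction nontrivial.  Mixture structure is
shared between classes and centered so class means are unchanged; the
`subpop_weight_jitter_sd` control lets the mixture proportions vary between
patients, which is the mechanism by which well-defined cell subpopulations
actually degrade averaging-based phenotyping (with fixed proportions,
averaging removes multimodality and a variance-matched unimodal cohort
behaves identically).

What the generator does **not** emulate: cytometry artifacts (spillover,
autofluorescence, doublets), patient-specific covariance structure,
non-stationary acquisition effects, or realistic marker correlation
patterns.  Passing tests on synthetic cohorts therefore validate the
statistical machinery — CLT narrowing, ranking, abstention accounting,
leakage-free evaluation — not robustness to instrument artifacts.

The closed-form oracle `expected_accuracy_1d(δ, σ, n) = Φ(√n·δ/(2σ))` is
the accuracy of the midpoint rule between two equal-variance Gaussians
after averaging n cells; the full pipeline is tested against it across
N ∈ {1, 10, 30, 100}.

## Numerical notes and problem sizes

The SVM fit is delegated to a linear-kernel SVC (libsvm); amplitudes are
the normalized coefficient vector, and `margin_` = 1/‖w‖ is the geometric
half-margin, checked against an exhaustive 2-D max-margin search to 1e-6 on
small point sets.  On near-separable clouds the hard-margin normal is
support-vector dominated and noticeably noisy at small cohort sizes; tests
that probe the *direction* of the normal (shift-direction recovery, the
minimal-measure construction) therefore use a moderate margin cost (0.1–1),
which anchors the fit to the cloud bulk.  CSV round-trips are bit-exact
(shortest-repr floats, round-trip parsing); the Excel adapter is exact to
the 16 significant digits spreadsheets store.

Simulation sizes in the test-suite and acceptance script (10,000 cells and
10,000 supercells for the narrowing factor; cohorts of 4–22 patients with
400–4000 cells each elsewhere) were chosen so Monte-Carlo standard errors
sit well below the asserted tolerances while a full run stays in the
minutes range on one core.

## Known limitations

- Binary classification only; no probabilistic calibration or ROC analysis.
- Linear boundaries only; distribution moments beyond the mean and
  nonlinear kernels are out of scope.
- FCS files are not read directly; convert to the canonical long CSV (the
  package applies no spectral compensation or fluorescence transform in
  any case, and gating thresholds are the user's responsibility).
- With strongly patient-varying subpopulation structure the supercell
  signal itself degrades (see above); identify subpopulations first and
  apply the pipeline within each.
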