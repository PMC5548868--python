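# Methods

This note documents the statistical machinery, the defaults and why they
are set where they are, what the synthetic cohorts do and do not emulate,
and the numerical choices a maintainer would want to know about.

## Pipeline model

The pipeline treats a participant as a triple (ROI time series S ∈
ℝ^{T×R}, motion trace M ∈ ℝ^{T×6}, tissue nuisance signals N ∈ ℝ^{T×3})
plus an attribute row (diagnosis, age, sex, handedness, three medication
flags, optional symptom severity). Processing order is fixed: band-pass →
nuisance regression (with band-passed tissue regressors) → correlation
over scrubbed frames. Filtering and regression always see the full
series; scrubbing only removes frames from the correlation, so filter
transients and regression fits are not distorted by missing frames.

### Connectivity stage

- **Band-pass** 0.008–0.1 Hz: 4th-order Butterworth applied
  forward-backward (zero phase). One octave beyond each band edge the
  two-pass attenuation exceeds 40 dB, comfortably beyond the 20 dB
  contract asserted in tests. The filter choice is ours; rs-fMRI pipelines
  conventionally use zero-phase Butterworth filters. Note that the
  forward-backward pass has a long edge transient at the 0.008 Hz pole
  (time constant ≈ 20 s); tests that measure tone amplitudes therefore use
  an FFT oracle at the driven frequency rather than peak amplitude.
- **Frame displacement** is the sum of |Δp| over the six motion
  parameters per transition. Rotation units are mandatory metadata
  (`mm`, `radians`, `degrees`); angular rotations are converted to arc
  length at a 50 mm head radius. There is no silent default for angular
  traces — an undeclared unit is an error.
- **Scrubbing convention.** The transition t → t+1 with FD above 0.5 mm
  flags frame t+1 ("the associated frame"); the flagged frame is removed
  together with the previous frame and the two subsequent frames, i.e.
  frames {t, t+1, t+2, t+3} clipped to range. The alignment of the window
  is a convention (the verbal rule is ambiguous about indexing); it is
  documented here and enumeration-tested, including overlapping windows.
- **Zero-variance ROI exclusion** uses tolerance 1e-12 on the
  retained-frame variance: exact-zero comparisons are fragile after
  filtering and regression in floating point. An ROI flat in any single
  participant is dropped for the whole cohort and the edge index rebuilt.

### Reduction

PCA is center-only (no per-edge rescaling: edges already share the
correlation scale) via SVD, keeping all min(n−1, p) components. A
deterministic sign convention (each component's largest-magnitude loading
is positive, first index on ties) makes downstream sparse selections
reproducible across BLAS implementations. By default the PCA is fitted
once on the whole internal cohort — the convention of the analysis this
package implements — with a strictly per-fold option
(`pca_scope: per_fold`) for leakage-sensitivity studies.

### Sparse CCA selection

The penalized matrix decomposition form: maximize uᵀ M v, M = ZᵀA, subject
to ‖u‖₂, ‖v‖₂ ≤ 1, ‖u‖₁ ≤ c_u, ‖v‖₁ ≤ c_v, by alternating
soft-thresholded power steps. Implementation details:

- The thresholding level for each update is solved **exactly**: the ratio
  ‖S(a,Δ)‖₁/‖S(a,Δ)‖₂ is piecewise smooth and non-increasing in Δ, so the
  level meeting the budget is the root of a per-segment quadratic
  (bisection remains as a numerical fallback). Entries below 1e-10 of the
  largest are snapped to exact zero, since support sets feed exact-zero
  rules downstream.
- Budgets are parameterized as fractions: c = f·√dim clipped below at the
  minimum feasible budget 1, so small fractions reach the fully sparse
  single-nonzero regime exactly. The default grid is f ∈ {0.1, …, 0.9} on
  both sides with one canonical pair per attribute column.
- Initialization is the leading singular pair of the (deflated) M —
  deterministic, no random restarts. Convergence: objective change
  < 1e-6 or 200 iterations (non-convergence warns and keeps the best
  iterate).
- **Projection deflation.** Successive pairs operate on
  M ← (I − uuᵀ) M (I − vvᵀ). This matters for confounded attributes: with
  the Witten-style subtraction M −= d·uvᵀ, a medication flag whose entire
  association with the connectome is mediated by diagnosis would re-load
  the already-extracted diagnosis PCs and (under the selection rule below)
  veto the true diagnostic features. Projection deflation removes the
  extracted component from both sides, so only genuinely residual
  structure can form later pairs.

**Diagnosis-specific selection.** Within one grid cell, a pair is
*diagnosis-only* if v is nonzero at the diagnosis column and within
`nv_tolerance` (default exactly 0) of zero at every nuisance column, and
*NV-related* if any nuisance weight exceeds the tolerance. The cell
contributes (PCs of diagnosis-only pairs) − (PCs of NV-related pairs); the
selection is the union of these per-cell sets. The subtraction implements
"related to the diagnosis label only": a PC that some canonical variable
ties to age or medication is not diagnosis-specific, even if another pair
ties it to the label. Deflation residue — pairs whose |canonical
correlation| is below `scca_min_corr_fraction` (default 0.5) of the
cell's strongest pair — is ignored by the rule; such pairs exist only
because a fixed number of pairs is extracted per cell and would otherwise
randomly veto true features. An empty selection is a reported outcome
(the classifier then falls back to bias-only with a warning), not an
error.

### ARD sparse logistic regression

P(y=1|ẑ;w) = 1/(1+exp(−wᵀẑ)) with ẑ = [zᵀ, 1]ᵀ. Each feature weight has a
zero-mean Gaussian prior with its own precision α_i; estimation alternates
a Laplace approximation at fixed α (damped Newton with step halving; one
Cholesky factorization yields the step, the posterior covariance and its
log-determinant) with the MacKay fixed-point update α_i ← γ_i/μ_i²,
γ_i = 1 − α_i Σ_ii. Numerical policy:

- Feature i is pruned (weight exactly zero) when α_i > 1e8; convergence
  when the max relative α change over surviving features is < 1e-4, cap
  500 evidence updates. All thresholds are config-exposed.
- The bias is exempt from relevance determination: its precision is fixed
  at 1e-6 (effectively unpenalized) and it is never pruned. Letting the
  bias precision follow the MacKay update oscillates near the clipping
  bound on weakly informative data and roughly triples iteration counts
  without changing fits.
- Perfect separation is caught by an ∞-norm weight cap (1e3) with a
  warning rather than divergence.
- The per-iteration Laplace evidence is recorded in `fit_log`. The MacKay
  update is a fixed-point heuristic, not an ascent method: individual
  steps can lower the evidence slightly, although the net change over a
  fit is positive in practice.  The trace is a diagnostic; tests assert
  net increase, not stepwise monotonicity.
- WLS = 0 (a measure-zero event) is classified as control and flagged.

### Evaluation

LOOCV refits selection (per fold by default; `selection_scope: pooled`
available — note the pooled variant sees the held-out label through the
selection) and the classifier per fold. The permutation test shuffles the
diagnosis column only, re-runs the entire selection + fit + scoring
cascade per replicate (freezing the selection is available behind
`permutation_freeze_selection`), and reports the add-one p-value
p = (1 + #{null ≥ observed})/(1 + n_perm), which is never zero and lies in
[1/(1+n_perm), 1]. The permutation statistic is AUC by default (accuracy
via config). External validation applies frozen artifacts — PCA transform,
selection, weights — and verifies by content hash that nothing mutated.

Two null-behavior facts worth knowing, both visible in the test suite:

- **Label shuffling tests exchangeability of the diagnosis column.** If
  an attribute is coupled to diagnosis by design (medication exists only
  in the patient group), the observed and permuted pipelines see the
  attribute matrix differently through the selection stage even when the
  connectome carries no signal, and the p-value becomes grossly
  conservative. Null-calibration experiments therefore decouple
  medication (`p_medicated=0`).
- **The bias-only fallback anti-learns in LOOCV.** With an empty
  selection the classifier reduces to its bias, which in a balanced
  leave-one-out design always points at the training-fold majority — the
  opposite of the held-out label — producing an accuracy/AUC atom at 0.
  Under the null this makes the accuracy distribution bimodal (atom at 0
  plus a ≈0.6 mode from noise-feature models; mean ≈ 0.44 at the tested
  scale) and the permutation p conservative through ties at the atom.
  This is a structural property of cross-validated pipelines with
  data-dependent feature selection, reported as measured.

Subgroup machinery mirrors the standard reporting tests: Pearson
chi-squared on 2×2 tables (1 df, no continuity correction), two-sample
pooled-variance t-tests accepting raw values or (mean, sd, n) summaries.

### Interpretation

c_j = Σ_{k∈selection} w_k V_{k,j} (bias excluded). The linearity identity
WLS(x) = bias + Σ_j c_j (x_j − mean_j) holds to machine precision for
internal and external participants and is asserted at 1e-10. Ranking is
by |c_j| with ties broken by edge index; "contribution" as the absolute
effective weight is our operationalization of "contributed most to the
WLS" (a participant-weighted variant would be possible; the absolute
weight is the reading consistent with a fixed linear discriminant). The
18-label network atlas ships as an editable TSV mapping; synthetic
cohorts use a round-robin assignment. Contributions are computed from a
final refit on the full training cohort by default; aggregating across
folds is possible by calling the same function per fold.

## Synthetic cohorts

The generator emulates exactly the statistical structure the analysis
assumes, nothing more:

- Two groups share a baseline ROI correlation matrix (off-diagonals ~
  N(0, base_density²), default 0.15); the patient group's matrix differs
  by `effect_delta` on the planted edges before positive-definiteness
  repair (eigenvalue clipping at 1e-6, reconstruction, unit-diagonal
  rescale; max entry distortion reported; shifts that leave (−1, 1) name
  the offending edges and fail).
- Nuisance-linked edges add attribute-proportional shifts per participant
  (age enters as (age−31)/10, binary attributes as 0/1) before a
  per-participant repair.
- Frames are drawn from a stationary AR(1) Gaussian process whose
  marginal covariance equals the (repaired) target exactly; the default
  AR coefficient 0.3 stands in for BOLD autocorrelation without modeling
  hemodynamics.
- Tissue nuisance signals are low-frequency sinusoid + noise mixtures
  leaked into the ROI series with gain 0.5, so the regression stage has a
  measurable effect to remove.
- Motion traces are Gaussian jitter (sd 0.02 mm) plus isolated 1 mm
  single-frame spikes whose adjacent transitions exceed the 0.5 mm scrub
  threshold by construction; spike frames are recorded in the ground
  truth. Rotations are stored mm-equivalent.
- Attributes mirror a realistic adult case–control cohort: age ~
  N(31, 9) clipped to [18, 65], balanced sex, 93% right-handedness,
  symptom severity ~ N(21.1, 6.3) in patients only, and medication only
  in the patient group at rate 16/56 by default (antidepressants most
  common, antipsychotics and anxiolytics at their observed relative
  rates). The realistic strength of the medication–diagnosis coupling is
  a user choice (`p_medicated`); it is deliberately severe by default —
  every medicated participant is a patient — because that is the hard
  case for nuisance-robust selection.
- The external cohort keeps the same correlation structure
  (`structure_seed`) and planted edges but resamples participants under a
  second-scanner profile: TR 2.411 s instead of 2.0 s, plus white site
  noise (`site_noise_sd`, default 0.5 when built via `external_spec`).

What passing tests on these cohorts do **not** show: robustness to
hemodynamic variability, spatially structured artifacts, atlas
misregistration, non-Gaussian BOLD noise, site effects beyond white noise
and TR, or real-data effect sizes — planted deltas of 0.4 at 200 frames
are far cleaner than clinical group differences, which is why recovery
accuracies here saturate at 1.0 while real cohorts of this design land
near 0.7–0.8.

## Problem sizes used by the test suite and acceptance script

Chosen so the whole suite runs comfortably on one CPU: recovery uses
cohorts of 40 participants × 30 ROIs × 200 frames (10 seeds); the
null-calibration experiment uses 100 replicates of 12 participants × 8
ROIs with 99 permutations each, pooled single-cell selection and an SLR
iteration cap of 150 — the permutation p is valid at any fixed pipeline
configuration because observed and null runs share it exactly. The
acceptance script repeats the same computations at 30 null replicates.

## Known limitations

- The SCCA grid, the selection's correlation gate and the per-cell
  subtraction rule are this package's operationalization of a verbal
  description; other readings exist (see the config's `--explain-config`
  provenance tags for which defaults are published constants and which
  are choices).
- MacKay updates give no monotonicity guarantee (above); fits on strongly
  collinear selected PCs can oscillate before pruning resolves them.
- `exclude_zero_variance_rois` requires identical ROI lists across
  participants; heterogeneous atlases must be reconciled upstream.
- The permutation test at default `n_perm=1000` re-runs the full cascade
  and is the most expensive operation in the package; freeze the
  selection or reduce the grid for exploratory runs.
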