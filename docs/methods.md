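# Methods

## Overview

`ieegnet` analyzes interictal intracranial EEG (iEEG) to ask whether the
functional-network footprint of surgically removed tissue predicts seizure
outcome. The pipeline per patient:

1. **Alignment.** Recording channels are matched to the contact table by
   exact id; contacts flagged as artifactual (identified upstream by visual
   inspection) are dropped.
2. **Signal conditioning.** Common-average rereference, 50 Hz notch (IIR,
   Q = 50, 4th order), 1–70 Hz Butterworth bandpass (4th order), both applied
   forward–backward ("zero phase"). The two filters are LTI, so they are
   realized as one stacked second-order-section cascade in a single
   forward–backward pass; this equals sequential application up to edge
   padding (tested).
3. **Network.** Pearson correlation on consecutive non-overlapping 2-second
   windows, averaged entrywise over windows. Correlations are signed and
   averaged raw; an absolute-value variant exists only as a sensitivity
   option.
4. **Spatial normalization.** Pairwise Euclidean contact distances (mm) and a
   cohort-level baseline f(d) = (p1·d + p2)/(d + q1) — the degree-1/degree-1
   rational function ("rat11") — fitted by unweighted nonlinear least squares
   to (distance, correlation) pairs pooled from *spared* contacts of
   *good-outcome* (ILAE class 1) patients, i.e. presumed non-epileptogenic
   tissue. Every matrix entry is replaced by its residual to this curve.
5. **D_RS.** Node strength = mean off-diagonal connectivity per contact.
   D_RS = the normalized Mann–Whitney U statistic (AUC) of spared vs removed
   node strengths: 1 when every spared contact out-ranks every removed one,
   0 in the opposite case, 0.5 for no separation. Being rank-based it is
   invariant to monotone transforms, so mean- vs sum-based node strength are
   interchangeable (tested exactly).
6. **Cohort statistics.** Outcome discrimination = AUC of D_RS for poor
   (ILAE ≥ 2) vs good (class 1) patients, with a Hanley–McNeil standard
   error mapped through the logit for the 95% CI, and a two-sided rank-sum
   test. Scans over minimum per-compartment coverage n_x (1…40), segment
   length (4 s…10 min), separate segments, and a leave-one-patient-out
   cross-validated AUC (Youden-J threshold per fold, ties broken at the
   midpoint of tied thresholds) complete the analysis.

## Numerical choices

- **rat11 fitting.** Multi-start over q1 ∈ {5, 10, 20, 50, 100} mm with a
  linear least-squares initialization of (p1, p2) given q1 (the model is
  linear in them), then trust-region refinement; best residual wins; the
  start list is fixed, so the fit is deterministic. Zero-distance pairs
  (coincident contacts, a data error) are excluded — they sit next to the
  pole and dominate its leverage. The pole is constrained to q1 > 0.
- **AUC / D_RS exactness.** The statistic is computed from doubled midranks
  as integers, arranged as 0.5 ± Δ so that auc(x,y) + auc(y,x) == 1 holds
  *exactly* in floating point, ties included.
- **Rank-sum p-values.** Exact enumeration of all C(n+m, n) label
  assignments for n+m ≤ 12 (handles ties; the two-sided p is the mass at
  least as far from nm/2 as observed). The large-sample path uses an
  Edgeworth expansion around the tie-aware normal: variance, skewness and
  kurtosis of the midrank sum have closed forms in the midrank power sums
  (finite-population sampling moments), and the two-term expansion with
  continuity correction has worst-case error ~5·10⁻⁴ against enumeration at
  n₁ = n₂ = 8, versus ~10⁻² for the plain normal.
- **CI at boundary AUCs.** An AUC of exactly 0 or 1 is pulled in by half a
  pair-count unit, 1/(2·n₁·n₂), before the logit so the interval is defined;
  the reported interval is widened to include the boundary value itself.
- **Degenerate windows.** A zero-variance channel within a window gets
  correlation 0 to all others in that window (logged); bandpassed real data
  are never exactly constant.
- **Filter edges.** Forward–backward filtering uses reflection padding of
  3 s (three periods of the 1 Hz band edge). Attenuation contracts are
  steady-state statements; the first/last second of a filtered segment
  carries edge transients, which are negligible for the long segments the
  analysis windows.
- **Re-filtering.** Because zero-phase application squares the magnitude
  response, re-running the chain on already-filtered broadband data changes
  it by ≈ 15% RMS (band-edge attenuation), exactly as the design response
  predicts; the test asserts that prediction rather than idempotence.

## The synthetic cohort generator

No public raw recordings exist for this analysis, so the package ships a
generator that emulates the statistical structure the method relies on; it
is first-class, tested code.

**Target correlation.** C_ij = f_true(d_ij) + δ·1[i, j both epileptogenic],
unit diagonal, then eigenvalue-clipped and rescaled to the nearest valid
correlation matrix (the repair distance is checked; configurations needing
more than 0.05 of repair, clipping included, are rejected as infeasible).
Defaults: f_true = (0.015·d + 1.6)/(d + 10) — a modest broadband correlation
level, ~0.16 at touching contacts decaying through ~0.05 at 30 mm — and
δ = 0.1 on a spatially contiguous 5-contact epileptogenic cluster.

**Montage and outcome.** Each patient gets a subdural grid with dimensions,
pitch and resection extent drawn per patient (6–8 × 6–10 contacts, 7–12 mm,
12–32 resected contacts): cross-patient implantation variability is exactly
the spatial-sampling confound the normalization targets. The resection is a
contiguous cluster at a random location. Good outcome: the epileptogenic
cluster sits fully inside the resection (overlap 1 → ILAE class 1). Poor
outcome: it is placed among spared contacts (overlap 0 → class 3). Labels
follow overlap deterministically; a `label_noise` option can flip them.

**Signals.** Stationary zero-mean Gaussian channels realizing the target
matrix via its eigendecomposition, deterministic per seed (per-patient
streams spawned from the master seed). Optional common-mode 50 Hz line
contamination exercises the notch/rereference stages. Signals are white in
time: windowed Pearson correlation sees only the instantaneous covariance,
so oscillatory structure would change effective degrees of freedom but not
the quantities under test.

**Channel amplitudes.** Real iEEG amplitudes vary severalfold between
contacts, and this heterogeneity matters: after common-average
rereferencing, the covariance of every channel with the montage sums to
zero identically, so with perfectly homogeneous amplitudes node strength
would collapse to a constant and carry no information — a property of the
rereference itself, for any data. The generator therefore models amplitudes
as a lognormal electrode-coupling gain times (local coherence)^(−γ/2)
(γ = 6 by default), encoding the empirically observed anti-correlation
between recorded amplitude and local synchrony; in particular,
hypersynchronous epileptogenic cortex presents an attenuated background.
Because local coherence includes the planted δ, the epileptogenic amplitude
signature scales with δ and vanishes at δ = 0: null cohorts carry no
signature of any kind and yield chance-level discrimination (tested).

**What passing tests do and do not show.** The generator reproduces the
*premises* of the analysis — distance decay, a hypersynchronous cluster
whose removal tracks outcome, implantation variability — under stationary
Gaussian assumptions. Passing tests show the pipeline correctly extracts
planted structure of realistic magnitude under those premises; they cannot
certify performance on real recordings, which add nonstationarity, 1/f
spectra, state (vigilance) effects and imperfect labels.

## Problem sizes

Test and demonstration cohorts are desk-scale by design: 20 + 20 patients at
60 s per recording for discrimination and coverage experiments, and 6 + 6
patients at 256 Hz with 600 s "hour-equivalent" segments for the temporal
analyses (full-scale 512 Hz × 1 h cohorts are byte-identical in structure,
only longer). The windowed estimator's sampling error shrinks as
1/√(windows), so these sizes leave comfortable margins for every effect
studied; all sizes are stated in the tests that use them.

## Known limitations

- With a montage-wide common average reference, residual-based spatial
  normalization operates on correlation matrices whose covariance row sums
  are constrained to zero; the normalization then leaves a small
  resection-contiguity offset in every patient's D_RS (~0.05–0.1 on small
  grids). The offset is common to both outcome groups and cancels from all
  group-level statistics, but individual D_RS values should not be read as
  absolute deviations from 0.5.
- The rat11 baseline describes the pooled decay; per-montage vertical
  offsets (different grids see different mean correlation levels) appear as
  extra scatter around it and are not modeled per patient.
- The LOO cross-validation threshold rule (Youden's J, midpoint tie-break)
  is one reasonable choice among several; it is isolated in a single
  function so alternates can be swapped.
- No band-specific networks, no coherence/phase metrics, no automatic
  artifact detection, no electrode localization — these are inputs or
  out of scope by design.
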