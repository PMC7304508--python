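# Methods

## The measure

Inter-subject phase synchronization (ISPS) asks, voxel by voxel and TR by
TR, how tightly aligned the instantaneous phases of the BOLD signal are
across a group of participants who experienced the same stimulus sequence.
Each prepared voxel time series x_s(t) (subject s) is extended to its
analytic signal x_s(t) + i·H[x_s(t)] via the discrete Hilbert transform;
the angle θ_s(t) of that complex series is the instantaneous phase.  Across
N subjects the synchronization at (v, t) is the mean resultant length

    R(t) = | (1/N) Σ_s exp(i θ_s(t)) | = 1 − circular variance,

which is 1 when all subjects share a phase and ~N^(−1/2) under uniform
phase dispersion (E[R] = √π / (2√N) for uniform phases, ≈ 0.18 at N = 24).
A single group-level resultant is used rather than the average pairwise
angular distance of earlier work; the pairwise statistic is retained only
as a test oracle through the exact identity
R² = 1/N + ((N−1)/N)·mean_{s≠s′} cos(θ_s − θ_s′).

Phase, not amplitude, carries the signal here: scaling any subject's series
leaves its phase — and hence every synchronization value — unchanged.

## Preparation

Per subject and per voxel: discard the first 10 of 218 acquired volumes
(TR = 2 s), then band-limit to 0.01–0.1 Hz and remove linear drift, then
z-transform (population denominator).  The default filter is an ideal
(rectangular) mask on the discrete real spectrum, zero-phase by
construction; detrending and filtering are applied as one orthogonal
projection (the drift basis is itself filtered before being regressed out),
which makes the preparation exactly idempotent — re-preparing prepared data
is a no-op to machine precision.  A forward–backward Butterworth filter is
available behind `bandpass_method="butterworth"` for users who prefer a
smooth roll-off; that route is sequential and only approximately
idempotent.  Voxels that are flat before or after filtering are excluded
and reported; group analyses intersect exclusions so every subject
contributes every analysed voxel.  Hilbert edge effects are kept (no
samples are masked by default) so correlation counts refer to the full 208
analysed TRs.

## The task design and reference functions

The blocked paradigm has four conditions (physical pain, affective pain,
and their controls), sixteen 16 s blocks (four per condition) separated by
jittered 8/10/12 s rest gaps, 436 s in total.  The published pseudorandom
block order is not available, so `build_default_design` ships a fixed
seeded surrogate (20 s lead-in covering the discarded volumes, five gaps of
each length, 10 s tail); every downstream statistic is order-agnostic given
the design object, and arbitrary orders can be loaded from a BIDS-style
events TSV.

Reference functions are boxcars convolved with a haemodynamic response
kernel on a 0.2 s grid and sampled at volume onsets.  Synchronization time
courses have no post-peak undershoot, so their references use a
single-gamma kernel (mean lag 6 s, SD 3 s — the common gamma-regressor
default); the GLM baseline uses the canonical double-gamma (peak 6 s,
undershoot 16 s, ratio 6).  Kernels are unit-sum, so plateaus sit at the
boxcar height.  Eight reference condition sets are used for association:
the four single conditions plus the physical/affective/pain/control
unions — the natural completion of a 2×2 design into "eight conditions".

## Decomposition

The voxels × time synchronization matrix is decomposed by spatial ICA:
voxels are treated as samples, so the independent sources are spatial maps
and the mixing columns are component synchronization time courses (the
degree of group phase alignment attributed to a network at each TR).  The
estimator is fixed-point negentropy ICA (logcosh contrast) after PCA
whitening to the model order; the one-at-a-time (deflation) update is used
because the symmetric update frequently fails to converge on desk-scale
synchronization matrices, while deflation converges within a few hundred
iterations.  Up to five seed-derived restarts are attempted before an error
is raised.  Maps are z-scored empirically and sign-fixed so spatial
skewness is nonnegative (components read as clusters of unusually high
synchronization); requesting more components than the matrix rank reduces
the order with a warning.

Model order is selected by split-half replicability: subjects are randomly
halved (n_splits = 10 by default), the synchronization matrix and ICA are
recomputed per half, components are matched across halves by Hungarian
assignment on |spatial correlation|, and the order maximizing the mean
matched |r| wins.  The replicability metric itself is a design choice; the
Hungarian-matched mean |r| is one defensible definition, not a community
standard.  Components whose suprathreshold (z > 2.3) voxels fall more than
50% inside white matter / CSF / brain-edge masks are labelled unclassified;
the 50% cut-off operationalizes a qualitative rule and is configurable.

## Association statistics

Component time course vs reference: Pearson r with a two-sided p from the t
distribution (n − 2 df) and Bonferroni correction over conditions ×
components (8 × 10 = 80 by default on a 10-component solution; m is
configurable).  Condition specificity uses the independent-samples Fisher
r-to-z test, Z = (atanh r₁ − atanh r₂) / √(1/(n₁−3) + 1/(n₂−3)), with
Cohen's q = |atanh r₁ − atanh r₂|.  The independent-samples form is the
default because it reproduces published statistics of this design to ~0.01
from the printed correlations at n = 208; a dependent-correlations variant
is deliberately not offered as default.  These p-values are calibrated for
serially uncorrelated time courses; band-limited synchronization time
courses are autocorrelated, so raw p-values from real pipelines are
anticonservative and should be read as descriptive rankings, not exact
error rates.

## The synthetic generator

`simulate` builds multi-subject 4D series on a 12×12×12 grid (24 subjects,
218 volumes by default): three disjoint 4×4×4 networks locked to physical
pain, affective pain and physical control, each adding
amplitude × (1 + η_s) × reference(t; δ_s) inside its mask, plus per-voxel
AR(1) Gaussian noise (stationary SD 1, lag-1 coefficient 0.3 — a realistic
amount of temporal smoothness for 2 s sampling).  Heterogeneity is
per-subject: a response-latency shift δ_s ~ N(0, σ_latency) applied to all
block onsets and an amplitude factor η_s ~ N(0, 0.1).  Signal amplitude
defaults to 1.0, i.e. a response-to-noise amplitude ratio of 1.  Everything
is deterministic given the seed, and a ground-truth object records masks
and realized subject factors for recovery tests.

What the generator emulates: condition-locked network signals shared across
subjects, subject-level response heterogeneity, and temporally
autocorrelated noise.  What it does not: spatial noise correlations,
physiological and motion artifacts, anatomy, non-stationary arousal
effects.  Passing recovery tests therefore shows the pipeline's statistics
behave as designed under the stated model, not that real fMRI of this
paradigm would yield the same components.

### A quantitative limit of latency jitter

Latency jitter attenuates phase alignment by roughly exp(−(ωσ)²/2) at
angular frequency ω.  The condition-locked response energy of this design
lives at ~0.0024–0.04 Hz, so σ = 4 s yields only 0.06–1.0 rad of phase
dispersion: in-mask synchronization declines measurably and monotonically
(0.2990 → 0.2829 over σ ∈ {0,1,2,4} s at the default fixture), but the
matched component–reference correlation only drops from ~0.77 to ~0.72 and
remains overwhelmingly significant, while the GLM group-t in-mask excess is
essentially untouched (~9.6).  Driving the association below a Bonferroni
threshold (|r| ≈ 0.23 at n = 208, m = 80) would require σ ≈ 1/ω ≈ 13 s.
Per-subject latency jitter of a few seconds is therefore *not* a
sufficient mechanism for a synchronization null in a slow blocked design;
a full ISPS-null/GLM-positive dissociation needs heterogeneity that breaks
within-condition response consistency itself (e.g. variable per-block
engagement), which this generator intentionally does not model.

## Numerical conventions

Voxels are linearized x-fastest (Fortran order) inside the mask everywhere
(matrices, serialized maps, run-length-encoded truth masks).  Analytic
phases are wrapped to (−π, π]; `analytic_phase` rejects rows that are not
zero-mean (tolerance 1e−6 relative) or constant.  Synchronization values
are clipped to [0, 1] against floating-point rounding.  Ties in Hungarian
matching are resolved by the assignment solver's deterministic ordering.
Zero-variance rows raise in low-level ops and are excluded-and-reported in
`prepare`.  All stochastic steps take explicit integer seeds; rerunning a
pipeline with the same config and seed reproduces every numeric output
bit-for-bit.

## Problem sizes

Default test and acceptance runs use the desk-scale fixture (1,728 voxels,
24 subjects, 208 analysed TRs, 3 planted networks), 10-component ICA,
3–10 split-half repetitions, and 2,000-draw nulls — sizes chosen so a full
pipeline runs in seconds and the entire suite in minutes on a single core
while keeping every statistic comfortably away from small-sample artifacts.
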