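# Methods

This note documents the models, statistics and numerical conventions
implemented in `olivemap`, the choices made where the procedure was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Stimulus protocol

A protocol is an ordered list of contiguous stimulus epochs, each with
a stationary *pre* phase (the baseline), a *moving* phase (the response
window) and a stationary *post* phase. Defaults follow the standard
paradigm for this preparation: 6 s / 10 s / 5.4 s phases at a 345.6 ms
frame period, which rounds per phase to 17 + 29 + 16 = 62 frames per
stimulus (phase frame counts are rounded to the nearest frame
independently). Each block presents gratings in eight directions
(0°–315° in 45° steps) in a seeded random order, followed by CW and
CCW windmill rotation. The monocular paradigm adds three blocks in the
fixed order left, right, binocular; converging/diverging rotations
appear only in the binocular block; and the first stimulus of each
block is presented twice with the first presentation flagged `discard`
(a stimulus-onset control) and excluded from every statistic. Epochs
are assumed contiguous; inter-stimulus gaps are not modeled.

Direction convention throughout: 0° forward, 90° rightward,
180° backward, −90° leftward; angles are reported in (−180°, 180°].

## Response extraction

For each stimulus, dF/F₀ is computed per frame as (F − F₀)/F₀ with F₀
the mean raw fluorescence over the pre phase; F₀ ≤ 0 is a degenerate
baseline and an error. The response is the mean dF/F₀ over the moving
phase, averaged across however many repetitions the neuron has
(repetition counts may differ between neurons). Missing frames are NaN
and are skipped in all window means.

**The 2-SD criterion.** A neuron responds to a stimulus when its
response strictly exceeds the baseline mean + 2 SD. The source of the
SD is underdetermined by the verbal rule; here both moments are taken
over the per-frame baseline dF/F₀ values pooled across repetitions of
that stimulus (sample SD, ddof = 1), i.e. the criterion measures the
response against frame-to-frame noise. The pooled baseline mean is ~0
by construction of dF/F₀. *Active* = responding to at least one
stimulus of the set, evaluated per stimulation block in the monocular
paradigm.

## Direction selectivity

DSI and PD come from the rectified vector sum of the eight
direction-labeled mean responses: rᵢ = max(responseᵢ, 0),
DSI = |Σ rᵢ u(θᵢ)| / Σ rᵢ, PD = atan2 of the summed vector. Rectifying
negative means (which arise from noise) is what guarantees the
documented anchors — DSI ∈ [0, 1], a single-stimulus responder at
exactly 1 — and is applied consistently to observed and shuffled data.
A neuron whose rectified responses are all zero has undefined tuning
and is excluded from the DS analysis (logged).

**Shuffle test.** Direction labels are permuted across individual
presentations (not across repetition-averaged values), preserving the
repetition structure under the null; repetition means and the DSI are
recomputed per shuffle (1,000 by default). The verdict is
observed DSI > empirical 95th percentile of the null, with the
quantile computed by linear interpolation of the order statistics and
a strict comparison. Because every shuffle reuses the same response
multiset, the null is defined exactly when the observed DSI is. With
fewer than two distinct response values the null is degenerate and the
neuron is ruled not selective with a warning. The empirical type-I
error of this rule on simulated direction-uniform neurons is ~5%
(recomputed by `scripts/acceptance.py`).

Selective neurons are classed by their rotation responding flags:
DS (neither), DS+CW, DS+CCW, or DS+CW+CCW. Forward/backward splits use
the sign of cos PD; cos PD = 0 (exactly sideways, a measure-zero event)
belongs to neither group and is logged.

## Binocular integration

The monocular index is (mean_contra − mean_ipsi)/(mean_contra +
mean_ipsi), with the means taken across repetitions and the eight
translational directions only (rotation stimuli carry no direction
label). Negative window means are kept as-is; consequences: a
non-positive denominator leaves the index undefined (the neuron is
excluded and logged, not assigned 0), and a slightly negative
noise-only mean in one eye can push the ratio marginally past ±1, in
which case it is clipped back onto the index's defined range [−1, 1].

Per-eye tuning applies the full DSI + shuffle machinery independently
to the left, right and binocular blocks; a neuron may be selective in
one block only. Neurons selective in both monocular blocks are grouped
by the quadrant of (sign cos PD_left, sign cos PD_right): (+,+) and
(−,−) are similar-PD neurons; (+,−) and (−,+) are the opposing-PD
(CW-type and CCW-type) rotation substrates.

## Voxelwise analysis

Labeled voxels are those whose time-averaged brightness strictly
exceeds a background estimate plus 2 camera gray values. The pipeline
estimates the background as the median brightness of the volume, a
robust stand-in for a manual estimate; both the estimate and the
offset are configurable. Per-voxel per-stimulus responses are
(F − F₀)/F₀ from the phase windows, computed per repetition and then
averaged. The voxelwise PD uses the same rectified vector-sum
estimator as the neuron-level DSI, applied to the eight per-voxel
direction responses.

Category rules (all comparisons strict, thresholds in dF/F₀):

- forward: cos PD > 0 and mean over the three forward-component
  stimuli {−45°, 0°, +45°} > 0.5;
- backward: cos PD < 0 and mean over {135°, 180°, 225°} > 0.25 (the
  lower threshold reflects the weaker backward responses);
- rotation: > 0.75 to one rotational direction and < 0.25 to the other;
- left/right: mean > 0.25 over the two stimuli with a left ({−90°,
  −45°}) or right ({90°, 45°}) component, assigned to the stronger
  side; exact ties are left unassigned and logged.

Forward and backward categories are disjoint by the exclusive cosine
sign. Projection maps count category voxels along one axis; with
`split_halves` the two image halves (projection vs soma territory) are
normalized independently to their own maxima, with the split at the
image midline by default and configurable because the anatomical
boundary need not be central. Display percentiles (top 1% / next 4% /
rest) use the Weibull plotting position (ranks i/(n+1)) with strict
exceedance, so ties at a threshold fall into the lower group and tiny
samples produce empty top groups.

## Overlap statistics

Point sets are pooled across the brain midline by reflecting one side
onto the other (idempotent, size-preserving) and analyzed in 2D — a
z-projection for the cerebellar terminal fields, a lateral projection
for the IO. Axon-terminal locations are the endpoints of rasterized
neuron skeletons: pixels of the 1-px skeleton with at most one
8-connected neighbor (an isolated pixel is its own endpoint); thick
input is thinned first with a warning.

Densities are isotropic Gaussian KDEs, kernel SD 10 px (7.8 µm at the
reference pixel pitch of 0.78 µm/px, configurable), evaluated exactly
(separable Gaussians, no histogram binning and no kernel truncation)
on a shared grid of 1 px spacing covering the joint bounding box plus
a 4-SD margin, then renormalized to integrate to 1 on the grid — the
renormalization absorbs the edge truncation. Exact evaluation keeps
the implementation verifiable against a direct per-point, per-cell
oracle to 10⁻⁸ at desk scale, where it costs the same as a truncated
kernel would.

MS(p, q) = Σ min(p, q) · cell area, symmetric and in [0, 1]. For two
anatomical classes (A₁, A₂) and two functional classes (F₁, F₂),
MI = (MS(A₁,F₁) + MS(A₂,F₂))/2 − (MS(A₁,F₂) + MS(A₂,F₁))/2.

**Bootstrap null.** Per iterate, the two classes are pooled within
each modality (anatomy and function separately, preserving each
modality's marginal spatial structure), pseudo-classes of the original
sizes are drawn with replacement, and the MI is recomputed on the same
grid; both modalities are resampled per iterate. The default is 10,000
iterates. The threshold is the empirical 100·(1 − α/6) = 99.1667th
percentile (reported rounded as 99.17; linear interpolation), the test
one-tailed with strict exceedance, and a pairing claim requires
significance in both the soma and the terminal region.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with ground truth for recovery tests. The expected moving-phase drive
of a neuron is, per eye, amplitude · exp(κ(cos(θ − PD_eye) − 1)) — a
peak-normalized von Mises tuning curve, the standard circular choice;
κ = 0 gives a direction-uniform response. Eye contributions are
weighted (w_contra, w_ipsi) and summed for binocular stimuli, so
weights summing to 1 leave the binocular plateau at the configured
amplitude; rotation stimuli drive per-label gains weighted the same
way. The drive is convolved with a causal exponential kernel
(τ = 0.7 s by default, a single-decay stand-in for fast-GCaMP
kinetics — sufficient for window-mean statistics), scaled onto the
baseline fluorescence (default 100), and i.i.d. Gaussian noise is
added to the raw signal (default SD 3, i.e. 0.03 dF/F₀ units). All
randomness flows through one seeded generator; no global state.

Default population (109 neurons): forward-preferring (40, rostral),
backward-preferring (25, caudal), CW-substrate (12, rostral-right,
left-eye-forward/right-eye-backward per-eye PDs, high CW gain),
CCW-substrate (12, mirror image), and direction-uniform active neurons
(20). PDs are wrapped-normal draws about the class mean (SD 25°)
rejected into the class's cosine half-plane; κ ~ U(2, 4); amplitudes
~ U(0.4, 0.8) dF/F₀ (U(0.2, 0.4) for the untuned class); eye weights
0.65/0.35 (contralateral bias). Anatomy: unipolar somata (16,
ventral-rostral) with medial cerebellar terminals, multipolar somata
(19, caudal-dorsal) with lateral terminals; the default functional
terminal clusters are colocated with them, making the default dataset
a positive control for the matching analysis. Class counts, centres,
spreads and tuning ranges are all configurable; the defaults are
chosen so that at three repetitions the shuffle test flags tuned
neurons with near-unit power and median PD recovery error well under
10°, the operating regime the analysis was designed for.

Volumes render each neuron as an isotropic Gaussian blob (SD 3 µm) of
its closed-form expected window-mean response per stimulus, on a 2 µm
voxel grid, with per-repetition response noise and a brightness
channel above a configurable background. Skeletons are parent-pointer
trees with a jittered path from the soma to a branch point and one
branch per requested terminal, leaves exactly at the terminals;
rasterization draws Bresenham lines in a chosen 2D projection.

**What the generator does not emulate** — and hence what passing tests
do not certify about real data: optics and PSF blur, motion artifacts
and registration error, indicator nonlinearity and saturation,
correlated or signal-dependent noise (noise is i.i.d. Gaussian on raw
fluorescence), behavioral state, and nonlinear binocular interactions
(interocular inhibition exists only as rotation-gain bookkeeping, not
as a mechanistic model). Conclusions about real recordings require the
analysis assumptions — window-mean sufficiency, baseline stationarity,
Gaussian-ish noise — to hold there too.

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale: the
shuffle-test calibration uses 2,000 simulated neurons × 1,000
shuffles; matching-index topography checks use the 109-neuron default
population with 2,000 bootstrap iterates (the analysis default remains
10,000); KDE oracles use ≤ 5-point sets on coarse grids. Pipelines are
deterministic given the config seed: stage seeds are derived from it,
and identical config + seed reproduce every CSV byte-for-byte.

## Known limitations

- The vector-sum PD estimator is biased toward the stimulus grid for
  very peaked tuning (only 8 samples of the tuning curve); at κ ≤ 4
  the bias is well below the 10° recovery criterion.
- The monocular index is undefined (not 0) for neurons unresponsive to
  both eyes, and clipped at ±1 when noise makes one block's mean
  slightly negative; strongly negative responses (suppression) are
  outside the index's intended domain.
- The bootstrap null resamples both modalities per iterate; resampling
  only one side would give a slightly different (narrower) null.
- `percentile_partition` conventions matter only for display
  groupings, not for any significance decision.
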