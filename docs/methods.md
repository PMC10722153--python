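# Methods

This note documents the models, rules and numerical choices implemented in
`graspmvpa`, and what the synthetic validation does and does not establish.

## Experimental layout

The design object encodes an event-related session: TR 2 s, 198 volumes per
run, 10 runs of 16 trials, 10 participants, 8 trial settings
(4 action conditions × 2 orientations), 20 repetitions of each setting.
A trial lasts 24 s: instruction 1 s, wait 5 s, action 4 s, wait 8 s,
judgment 2 s, inter-trial fixation 4 s.  Sixteen such trials fill 384 s =
192 volumes; the remaining 6 volumes (12 s) are modelled as **lead-in
baseline** at the start of each run, since some pre-event baseline is
required for percent signal change and the placement of the slack is not
otherwise constrained.  The lead-in length is configurable.

Trial order is randomized per run with exact per-run balance (two trials of
each setting per run).  An unconstrained shuffle of the session-level
multiset would leave some run without one setting with probability ≈ 0.11
per run × setting, making leave-one-run-out folds ill-defined; per-run
balance is also the standard practice for event-related designs and keeps
the two classes exactly balanced in every fold (hence no class weighting in
the classifier).  When the per-run trial count is not a multiple of the
number of settings (only possible in reduced layouts), the generator falls
back to a global shuffle.

Volume indexing is 0-based and half-open; a phase onset maps to
`floor(onset / TR)`.

## Synthetic BOLD model

Each ROI × run is a voxels × volumes matrix

```
signal = baseline · (1 + (universal + orientation)/100) + AR(1) noise + drift
```

* **Evoked responses.** Every measured phase (instruction, action,
  judgment) of every trial contributes a boxcar of the phase duration
  convolved with a double-gamma HRF (gamma shapes 6 and 16 at unit scale,
  undershoot ratio 6; peak ≈ 5 s, consistent with the 6 s hemodynamic lag
  the analysis rules assume).  Each convolved shape is normalized to unit
  peak so a programmed amplitude *a* (in percent of baseline) produces a
  peak evoked change of *a* percent regardless of phase duration.  The
  convolution grid is dt = 0.01 s.
* **Universal response** (default 2% of baseline): identical in every voxel
  and condition; this is what univariate percent signal change and the
  selection contrast detect.
* **Orientation information**: a ground-truth table maps
  (ROI, condition, phase) to an amplitude and a pattern id; the pattern
  bank holds one unit-norm voxel vector per id.  +45° trials add
  `+a·pattern`, −45° trials `−a·pattern` (antisymmetric coding — the
  simplest structure a linear decoder can exploit, with decodability
  governed by a single amplitude per cell).  Two cells share decodable
  structure **iff** they share a pattern id; to make that biconditional
  exact, distinct ids within an ROI are drawn mutually orthogonal
  (independent random high-dimensional vectors would retain a
  ~1/√n_voxels overlap, which a high amplitude turns into spurious
  transfer).  A per-(ROI, condition) sign flips the action-phase pattern
  relative to the instruction-phase pattern to model anti-correlated
  phase coding.
* **Noise**: stationary AR(1) per voxel (coefficient 0.3, marginal SD 1.0
  signal unit = 1% of the 100-unit baseline) plus linear + quadratic
  Legendre drift with N(0, 1) coefficients per voxel — a minimal but
  realistic low-frequency fMRI noise model; the source analysis gives no
  noise model because it used real data.
* **Sizes**: 300 voxels per ROI so the 250-voxel selection cap binds, with
  POIPS at 180 voxels to exercise the use-all-voxels branch.
* **Default orientation amplitude 2%** = 2 × noise SD: calibrated so the
  `effect_structure` scenario reproduces the qualitative significance pattern
  (group-level decoding ≈ 74% in active cells, chance elsewhere), not any
  particular accuracy value.
* **Motion**: smoothed random-walk traces rescaled to a per-run peak in
  [0.2, 1.5] mm/deg for clean runs and [2.3, 3.5] on one axis for
  contaminated ones; the first volume is the zero reference.
* **Behavior**: judgments correct with probability 0.95 and unanswered with
  probability 0.02 — near-ceiling performance with occasional misses, as
  expected from an easy two-alternative judgment.

Seeding: participant *i* of a dataset uses master seed + *i*; within a
participant, the trial table uses that seed directly and noise/motion/
behavior use streams spawned from it, so any participant regenerates in
isolation and a fixed master seed yields a byte-identical serialized
dataset.

Built-in scenarios: `null` (no orientation information anywhere — the
false-positive guard), `effect_structure` (information exactly in the cells the
same-type analysis is expected to flag, each with its own pattern),
`shared_DG_UG` (one shared DG/UG action pattern in V2/V3v/VIPS/DIPS,
independent DG and UG patterns in V1/V3d as the no-transfer control), and
`antiphase` (instruction/action patterns shared but sign-flipped for
DG/AG/NG in early areas, driving cross-phase decoding below chance).

## Preprocessing rules

* **Run exclusion**: a run is dropped iff max |translation| > 2 mm **or**
  max |rotation| > 2°, strictly greater (a run exactly at threshold is
  kept).  Fewer than two retained runs is an error because
  leave-one-run-out is then undefined.
* **Baseline volumes**: the lead-in plus the final volume of each
  inter-trial interval (the volume farthest from the preceding judgment
  response).  The baseline is still partially contaminated by late
  hemodynamic tails — unavoidable in this densely packed design — which is
  why percent-signal-change recovery is validated against a convolution
  oracle that models the same contamination, rather than against the raw
  programmed amplitude.
* **Univariate windows**: every phase window is lagged by 3 volumes (6 s)
  and averages 3 volumes.  Windows that would run past the end of the run
  (the judgment phase of a run's final trial) are dropped from the average.
* **Pattern windows** (deliberately separate from the univariate rule,
  since both rules exist independently): instruction/judgment use the
  single volume 4 s after onset; action uses the mean of the volumes 8 s
  and 10 s after onset.
* **Voxel selection** is computed once per participant × ROI on all
  retained runs, from the orientation-pooled stimulus-versus-baseline
  contrast.  Pooling both orientations makes the score independent of the
  decoded labels, so selecting before cross-validation does not bias it —
  enforced by a dedicated null-calibration test.  Ties at the cutoff are
  broken by ascending voxel id; zero-variance voxels score 0 with a logged
  warning.
* **Z-scoring** is fold-wise: means/SDs from the training portion only,
  applied to both portions; constant training features map to 0.  The
  scope of the original z-scoring (run, session or fold) is not specified
  in the source analysis; fold-wise is the only choice that provably
  avoids train/test leakage.

## Decoding

A linear soft-margin SVM (cost C = 1.0, configurable; results on
well-separated synthetic data are insensitive to C) yields a weight vector
and bias; prediction is the sign of the decision value, with an exact zero
resolved to the first label seen in training so repeated runs are
bit-reproducible.  Same-type accuracy is the mean over leave-one-run-out
folds; transfer and cross-phase accuracies average the two train/test
directions (per-direction values are retained in the result rows for
inspection).

## Group statistics

Per-cell accuracies are tested across participants with a two-tailed
one-sample *t* against 50%; a zero-variance sample away from the null is
reported as t = ±inf, p = 0 (a saturated decoder) rather than crashing the
table.  Benjamini–Hochberg FDR runs at q = 0.05; the default family is all
cells of one analysis kind — "number of ROIs × number of tests" — with a
per-(analysis, phase) panel family available in the configuration.
Percent signal change is tested against zero with the stricter default
threshold p < 0.0005 used for the univariate figure-level claim.
Behavioral accuracy is correct/answered with unanswered trials excluded
from the denominator.

## Validation scale and what it shows

The acceptance-level tests run at the study's native size: a 20-repetition
null calibration (108 cells, checked against a simultaneous 95% sampling
band — a per-cell two-standard-error rule across 108 cells would reject
spuriously with near certainty), an effect-structure recovery run on the
action-phase panel, transfer and cross-phase scenario runs, and oracle
equivalence of the numeric primitives (SVM vs. an explicit quadratic
program, BH vs. step-up enumeration, *t* p-values vs. the incomplete-beta
closed form to 1e−10).  The no-transfer control pools three ground-truth
draws because per-participant transfer accuracy under orthogonal patterns
is unbiased but widely dispersed (one fitted weight vector makes a
participant's test decisions strongly dependent).

Passing these tests shows the pipeline is unbiased, label-leakage-free and
faithful to its stated rules **on data matching the generator's
assumptions**.  The generator deliberately omits spatial voxel correlation,
physiological (cardiac/respiratory) noise, between-participant amplitude
variability, hemodynamic latency variation and non-antisymmetric orientation
codes; real-data accuracies and significance maps may differ for those
reasons, and nothing here validates the neuroscientific interpretation of
any particular ROI.  Real per-ROI matrices can be analyzed through the same
staged CLI, bypassing the generator.
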