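# graspmvpa

ROI-based multivoxel pattern analysis (MVPA) of object **orientation during
grasping without online visual feedback**, packaged as a fully tested
pipeline over a synthetic event-related BOLD generator with known ground
truth.

## The scientific problem

In the underlying experimental paradigm, participants see (or, in one
condition, do not see) a cylindrical object at +45° or −45° roll and then
grasp it, pantomime the grasp, or withhold it, in four action conditions:

| condition | visual instruction | grasp executed | object touched |
|-----------|--------------------|----------------|----------------|
| DG (direct grasp)    | yes | yes | yes |
| AG (air grasp)       | yes | yes | no  |
| NG (non grasp)       | yes | no  | no  |
| UG (uninformed grasp)| no  | yes | yes |

Each of 10 participants completes 10 runs × 16 trials (TR = 2 s, 198
volumes/run); every trial has instruction, action and judgment phases
(1 + 5 + 4 + 8 + 2 + 4 s including waits and inter-trial fixation).  The
question is whether the two orientations evoke discriminable voxel
patterns in nine visual/parietal regions of interest (V1, V2, V3d, V3v,
V3A, V7, VIPS, POIPS, DIPS), and whether those patterns are shared across
conditions and phases.

## The analysis

For every participant × ROI:

1. **Run exclusion** — drop any run whose head motion exceeds 2 mm
   translation or 2° rotation relative to the run's first volume.
2. **Voxel selection** — per-voxel two-sample *t* contrast of lagged
   stimulus volumes versus fixation-baseline volumes (orientations pooled,
   so the score is orthogonal to the decoded labels); keep the top 250
   voxels, or all of them in smaller ROIs.
3. **Pattern extraction** — instruction/judgment: the single volume 4 s
   after phase onset; action: the mean of the volumes 8 s and 10 s after
   onset (the grasp itself takes 4 s).
4. **Decoding** — linear soft-margin SVM on fold-wise z-scored features
   (training statistics applied to the test set):
   * *same-type*: leave-one-run-out within a condition;
   * *transfer-type*: train on one condition, test on another (both
     directions averaged) — above-chance accuracy implies a shared pattern;
   * *cross-phase*: train on instruction-phase patterns, test on
     action-phase patterns and vice versa — **below**-chance accuracy
     implies anti-correlated phase coding.
5. **Group inference** — two-tailed one-sample *t*-test of per-participant
   accuracies against the 50% chance level, Benjamini–Hochberg FDR at
   q = 0.05 across the ROI × test family.  A separate univariate check
   reports percent signal change, `100·(window − baseline)/baseline`, with
   a 3-volume (6 s) hemodynamic lag.

Because the corresponding human dataset is not deposited, the package
ships a **synthetic generator** that emulates the study's statistical
structure: double-gamma HRF responses for every trial phase, a universal
evoked amplitude plus per-(ROI, condition, phase) orientation patterns
with antisymmetric ±45° coding, AR(1) noise, slow drift, motion traces and
judgment responses.  Built-in ground-truth scenarios (`null`,
`effect_structure`, `shared_DG_UG`, `antiphase`) make every pipeline stage
verifiable against a known answer.

## Worked example

```python
import graspmvpa as g
from graspmvpa.pipeline import PipelineConfig

cfg = PipelineConfig.from_dict({
    "seed": 7,
    "scenario": "effect_structure",      # orientation information only in selected cells
    "rois": ["V1", "V3d", "V3v"],
    "phases": ["action"],
    "transfer_pairs": [["DG", "UG"]],
    "cross_phase_conditions": [],
})
result = g.run_pipeline(cfg)
print(g.make_report(result))
```

prints (abridged):

```
== same decoding, phase: action ==
ROI          AG          DG          NG          UG
V1         68.0%*      75.2%*      49.0%       50.8%
V3d        46.8%       76.8%*      54.2%       74.2%*
V3v        76.0%*      46.5%       48.3%       76.2%*

== transfer decoding, phase: action ==
ROI        DG&UG
V1         49.5%
V3d        47.9%
V3v        47.4%

behavioral judgment accuracy: group mean 95.2%
```

Read it as: decoding accuracy is the group mean over the 10 simulated
participants; `*` marks cells significant after FDR correction.  The
generator put action-phase orientation information into DG for V1/V3d, AG
for V1/V3v and UG for V3d/V3v — and exactly those cells are recovered
above the 50% chance line, while NG (no action executed) stays at chance
everywhere.  Each cell's pattern is independent here, so DG→UG transfer
stays at chance; the `shared_DG_UG` scenario makes it succeed.

The same pipeline is scriptable from the shell
(`graspmvpa run -c config.json -o results/`), and the staged subcommands
`simulate` / `preprocess` / `decode` / `stats` / `report` exchange plain
TSV + JSON files, which is also the import path for real per-ROI
voxel × time matrices.

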