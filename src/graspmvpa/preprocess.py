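"""Run exclusion, percent signal change, voxel selection, pattern extraction.

All window arithmetic is in 0-based volume indices at the design's TR.
Two separate timing rules coexist on purpose:

* the *univariate* rule lags every phase window by 3 volumes (6 s) to allow
  for hemodynamic latency and averages 3 volumes, used by percent signal
  change and by the voxel-selection contrast; and
* the *pattern* rule samples a single volume 4 s after instruction or
  judgment onset and the mean of the two volumes 8 s and 10 s after action
  onset (the action itself lasts 4 s), used to build classifier samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .design import ExperimentDesign, TrialEvent, phase_volume_index
from .synth import MotionTrace, RoiTimeSeries

logger = logging.getLogger(__name__)

TRANSLATION_THRESHOLD_MM = 2.0
ROTATION_THRESHOLD_DEG = 2.0
DEFAULT_LAG_VOLUMES = 3
DEFAULT_N_SELECT = 250


class PreprocessError(ValueError):
    """Raised for undefined preprocessing requests (bad windows, baselines...)."""


# ---------------------------------------------------------------------------
# Run exclusion
# ---------------------------------------------------------------------------

def exclude_runs(traces: Mapping[int, Sequence[MotionTrace]],
                 translation_mm: float = TRANSLATION_THRESHOLD_MM,
                 rotation_deg: float = ROTATION_THRESHOLD_DEG,
                 ) -> dict[int, tuple[int, ...]]:
    """Retained run indices per participant.

    A run is excluded iff its maximal absolute head translation exceeds
    ``translation_mm`` OR its maximal absolute rotation exceeds
    ``rotation_deg`` (strictly greater than; a run at exactly the threshold
    is retained).  Fewer than two retained runs leaves leave-one-run-out
    undefined and raises.
    """
    retained: dict[int, tuple[int, ...]] = {}
    for pid, runs in traces.items():
        keep = tuple(tr.run_index for tr in runs
                     if tr.max_translation() <= translation_mm
                     and tr.max_rotation() <= rotation_deg)
        dropped = len(runs) - len(keep)
        if dropped:
            logger.info("participant %s: excluded %d run(s) for motion", pid, dropped)
        if len(keep) < 2:
            raise PreprocessError(
                f"participant {pid} retains {len(keep)} run(s); "
                "leave-one-run-out needs at least 2")
        retained[pid] = keep
    return retained


# ---------------------------------------------------------------------------
# Baseline definition and percent signal change
# ---------------------------------------------------------------------------

def baseline_volume_indices(design: ExperimentDesign,
                            events: Sequence[TrialEvent]) -> np.ndarray:
    """Baseline volumes of one run: the lead-in plus the final volume of
    each inter-trial interval (the volume farthest from the preceding
    judgment response)."""
    idx = list(range(design.lead_in_volumes))
    iti_dur = design.phase_durations_seconds["iti"]
    for ev in events:
        end = ev.phase_onsets_seconds["iti"] + iti_dur
        last = int(np.floor(end / design.tr_seconds)) - 1
        if 0 <= last < design.volumes_per_run:
            idx.append(last)
    return np.unique(np.asarray(idx, dtype=int))


def _lagged_window(design: ExperimentDesign, event: TrialEvent, phase: str,
                   lag_volumes: int, n_volumes: int = 3) -> np.ndarray | None:
    v = phase_volume_index(event, phase, design)
    window = np.arange(v + lag_volumes, v + lag_volumes + n_volumes)
    if window[-1] >= design.volumes_per_run:
        return None
    return window


@dataclass
class PscResult:
    """Percent signal change of one ROI/run/contrast."""

    roi_name: str
    participant_id: int
    contrast: str
    value: float
    n_events: int


def percent_signal_change(ts: RoiTimeSeries, events: Sequence[TrialEvent],
                          phase: str, design: ExperimentDesign,
                          lag_volumes: int = DEFAULT_LAG_VOLUMES,
                          contrast: str | None = None,
                          baseline_events: Sequence[TrialEvent] | None = None,
                          ) -> PscResult:
    """Mean percent signal change of *phase* versus the fixation baseline.

    For every event, the 3 volumes starting ``lag_volumes`` after the phase
    onset volume are averaged; the result is
    ``100 * (window mean - baseline mean) / baseline mean`` averaged over
    voxels and events.  Events whose lagged window runs past the end of the
    run are dropped (this affects the judgment phase of the final trial).
    ``baseline_events`` lets a condition-restricted contrast keep the
    run-wide baseline definition.
    """
    base_idx = baseline_volume_indices(
        design, events if baseline_events is None else baseline_events)
    baseline = float(ts.matrix[:, base_idx].mean())
    if baseline <= 0:
        raise PreprocessError(f"non-positive baseline mean ({baseline:g}) "
                              f"for ROI {ts.roi_name!r}")
    windows = []
    for ev in events:
        w = _lagged_window(design, ev, phase, lag_volumes)
        if w is None:
            logger.debug("dropping trial %d run %d: %s window beyond run",
                         ev.trial_index_in_run, ev.run_index, phase)
            continue
        windows.append(w)
    if not windows:
        raise PreprocessError(f"no in-range events for phase {phase!r}")
    window_mean = float(np.mean([ts.matrix[:, w].mean() for w in windows]))
    value = 100.0 * (window_mean - baseline) / baseline
    return PscResult(ts.roi_name, ts.participant_id,
                     contrast or f"{phase}_vs_baseline", value, len(windows))


# ---------------------------------------------------------------------------
# Voxel selection
# ---------------------------------------------------------------------------

def selection_contrast(ts_by_run: Mapping[int, RoiTimeSeries],
                       events_by_run: Mapping[int, Sequence[TrialEvent]],
                       design: ExperimentDesign,
                       lag_volumes: int = DEFAULT_LAG_VOLUMES,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel stimulus-versus-baseline t score, pooled over runs.

    Pools the lagged instruction-phase (stimulus) volumes of every trial --
    all conditions and both orientations together, which keeps the score
    orthogonal to the orientation labels -- against the baseline volumes,
    and returns a two-sample t statistic per voxel plus the voxel ids.
    Zero-variance voxels score 0 (with a warning).
    """
    if len(ts_by_run) < 2:
        raise PreprocessError("selection_contrast needs at least 2 retained runs")
    stim_cols, base_cols = [], []
    voxel_ids = None
    for run, ts in sorted(ts_by_run.items()):
        events = events_by_run[run]
        if voxel_ids is None:
            voxel_ids = ts.voxel_ids
        base_cols.append(ts.matrix[:, baseline_volume_indices(design, events)])
        for ev in events:
            w = _lagged_window(design, ev, "instruction", lag_volumes)
            if w is not None:
                stim_cols.append(ts.matrix[:, w])
    stim = np.hstack(stim_cols)
    base = np.hstack(base_cols)
    import warnings
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant voxels
        t, _ = sps.ttest_ind(stim, base, axis=1)
    bad = ~np.isfinite(t)
    if bad.any():
        logger.warning("%d zero-variance voxel(s) scored 0 in selection contrast",
                       int(bad.sum()))
        t = np.where(bad, 0.0, t)
    return t, voxel_ids


@dataclass
class VoxelSelection:
    """Top-scoring voxels of one participant/ROI."""

    roi_name: str
    participant_id: int
    voxel_ids: np.ndarray
    scores: np.ndarray  # scores of the selected voxels, same order


def select_voxels(scores: np.ndarray, voxel_ids: np.ndarray,
                  k: int = DEFAULT_N_SELECT, *, roi_name: str = "",
                  participant_id: int = -1) -> VoxelSelection:
    """Top ``k`` voxels by contrast score (all voxels if fewer than ``k``).

    Ties at the selection boundary are broken by ascending voxel id, so the
    output is deterministic and stable across calls.
    """
    scores = np.asarray(scores, dtype=float)
    voxel_ids = np.asarray(voxel_ids)
    if scores.size == 0:
        raise PreprocessError("cannot select voxels from an empty ROI")
    if not np.all(np.isfinite(scores)):
        raise PreprocessError("selection scores must be finite")
    order = np.lexsort((voxel_ids, -scores))
    take = order[: min(k, scores.size)]
    take = take[np.argsort(voxel_ids[take])]  # stable presentation order
    return VoxelSelection(roi_name, participant_id, voxel_ids[take], scores[take])


# ---------------------------------------------------------------------------
# Pattern extraction and fold-wise normalization
# ---------------------------------------------------------------------------

@dataclass
class PatternSample:
    """One (pre-z-scoring) feature vector with its labels."""

    features: np.ndarray
    orientation: int
    condition: str
    phase: str
    run_index: int
    trial_index: int
    participant_id: int
    roi_name: str


#: Sampling offsets of the pattern rule, in seconds after phase onset.
PATTERN_WINDOW_OFFSETS_S: dict[str, tuple[float, ...]] = {
    "instruction": (4.0,),
    "judgment": (4.0,),
    "action": (8.0, 10.0),
}


def extract_patterns(ts: RoiTimeSeries, selection: VoxelSelection,
                     events: Sequence[TrialEvent], phase: str,
                     design: ExperimentDesign) -> list[PatternSample]:
    """One sample per trial: the phase's feature volume(s) restricted to the
    selected voxels (single volume at +4 s for instruction/judgment, mean of
    the +8 s and +10 s volumes for action)."""
    if phase not in PATTERN_WINDOW_OFFSETS_S:
        raise PreprocessError(f"no pattern window defined for phase {phase!r}")
    offsets = PATTERN_WINDOW_OFFSETS_S[phase]
    rows = np.searchsorted(ts.voxel_ids, selection.voxel_ids)
    if not np.array_equal(ts.voxel_ids[rows], selection.voxel_ids):
        raise PreprocessError("selection voxel ids not present in time series")
    samples = []
    for ev in events:
        v = phase_volume_index(ev, phase, design)
        vols = [v + int(round(off / design.tr_seconds)) for off in offsets]
        if vols[-1] >= design.volumes_per_run:
            raise PreprocessError(
                f"pattern window for trial {ev.trial_index_in_run} of run "
                f"{ev.run_index} (phase {phase!r}) exceeds the run length")
        feats = ts.matrix[np.ix_(rows, vols)].mean(axis=1)
        samples.append(PatternSample(feats, ev.orientation, ev.condition, phase,
                                     ev.run_index, ev.trial_index_in_run,
                                     ev.participant_id, ts.roi_name))
    return samples


def zscore_fold(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score features using training-set statistics only.

    The per-feature mean and SD are estimated on ``train`` and applied to
    both sets (no train/test leakage).  Features constant in the training
    set map to 0 everywhere.
    """
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    safe = np.where(sd == 0, 1.0, sd)
    ztr = (train - mean) / safe
    zte = (test - mean) / safe
    if np.any(sd == 0):
        const = sd == 0
        ztr[:, const] = 0.0
        zte[:, const] = 0.0
    return ztr, zte
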