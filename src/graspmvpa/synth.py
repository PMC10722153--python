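"""Synthetic event-related BOLD generator with known orientation structure.

Each region of interest (ROI) is simulated as a voxels x volumes matrix:

``signal = baseline * (1 + (universal + orientation) / 100) + AR(1) noise + drift``

where, per trial and per measured phase (instruction / action / judgment),
a phase-duration boxcar convolved with a double-gamma hemodynamic response
(normalized to unit peak) is scaled by

* a *universal* evoked amplitude (percent of baseline, identical in every
  voxel and condition) -- this is what univariate percent-signal-change and
  contrast-based voxel selection see; and
* an *orientation* amplitude (percent of baseline) times a unit-norm voxel
  pattern, signed +1 for +45 deg trials and -1 for -45 deg trials
  (antisymmetric coding) -- this is what a linear decoder can exploit.

Which (ROI, condition, phase) cells carry orientation information, whether
two cells share a pattern (supporting transfer decoding), and whether the
action-phase pattern is flipped relative to the instruction-phase pattern
(producing below-chance cross-phase decoding) are all spelled out in a
:class:`GroundTruth`, so every downstream result can be checked against a
known answer.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.signal import lfilter

from .design import (MEASURED_PHASES, ExperimentDesign, TrialEvent, TrialTable,
                     build_trial_table, orientation_label)

logger = logging.getLogger(__name__)

DEFAULT_ROI_NAMES: tuple[str, ...] = (
    "V1", "V2", "V3d", "V3v", "V3A", "V7", "VIPS", "POIPS", "DIPS")

#: 300 voxels per ROI so the top-250 selection cap binds; POIPS is smaller
#: to exercise the use-all-voxels branch.
DEFAULT_N_VOXELS: dict[str, int] = {roi: 300 for roi in DEFAULT_ROI_NAMES}
DEFAULT_N_VOXELS["POIPS"] = 180

SCENARIOS = ("null", "effect_structure", "shared_DG_UG", "antiphase")


class SynthError(ValueError):
    """Raised for invalid ground-truth or simulation requests."""


# ---------------------------------------------------------------------------
# Hemodynamic response
# ---------------------------------------------------------------------------

@lru_cache(maxsize=16)
def _hrf_peak_value(peak: float, undershoot: float, ratio: float) -> float:
    t = np.arange(0.0, 32.0, 0.01)
    h = sps.gamma.pdf(t, peak + 1.0) - sps.gamma.pdf(t, undershoot + 1.0) / ratio
    return float(h.max())


def canonical_hrf(time_seconds, peak: float = 5.0, undershoot: float = 15.0,
                  ratio: float = 6.0) -> np.ndarray:
    """Double-gamma hemodynamic impulse response, unit peak height.

    Gamma densities with unit scale peak at (shape - 1), so the response
    peaks near ``peak`` seconds (default 5 s) with an undershoot near
    ``undershoot`` seconds, attenuated by ``ratio``.
    """
    t = np.asarray(time_seconds, dtype=float)
    if np.any(t < 0):
        raise SynthError("canonical_hrf requires a non-negative time grid")
    h = sps.gamma.pdf(t, peak + 1.0) - sps.gamma.pdf(t, undershoot + 1.0) / ratio
    return h / _hrf_peak_value(peak, undershoot, ratio)


@lru_cache(maxsize=64)
def _event_shape(duration: float, dt: float = 0.01, span: float = 40.0) -> tuple:
    """Unit-peak response to a ``duration``-second boxcar, on a fine grid.

    Normalizing per duration makes the simulated percent signal change at
    the response peak equal the programmed amplitude regardless of how long
    the phase lasts.
    """
    t = np.arange(0.0, span, dt)
    box = (t < duration).astype(float)
    conv = np.convolve(box, canonical_hrf(t))[: t.size] * dt
    conv /= conv.max()
    return t, conv


def _sampled_regressor(onset_seconds: float, duration_seconds: float,
                       volume_times: np.ndarray) -> np.ndarray:
    t, shape = _event_shape(float(duration_seconds))
    return np.interp(volume_times - onset_seconds, t, shape, left=0.0, right=0.0)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Complete description of the signal structure driving the simulator.

    ``orientation_patterns`` maps ``(roi, condition, phase)`` to
    ``(amplitude, pattern_id)``; an absent cell or zero amplitude means no
    decodable orientation information there.  ``pattern_bank`` holds one
    unit-norm voxel-space vector per pattern id; two cells that reference
    the same id share decodable structure.  ``cross_phase_sign`` multiplies
    the action-phase pattern of an (roi, condition) relative to its
    instruction-phase pattern (-1 models anti-correlated phase coding).
    """

    roi_names: tuple[str, ...]
    n_voxels_per_roi: dict[str, int]
    baseline_level: float = 100.0
    universal_response_amplitude: float = 2.0
    orientation_patterns: dict[tuple[str, str, str], tuple[float, str]] = field(default_factory=dict)
    pattern_bank: dict[str, np.ndarray] = field(default_factory=dict)
    cross_phase_sign: dict[tuple[str, str], int] = field(default_factory=dict)
    noise_sd: float = 1.0
    ar1_coefficient: float = 0.3
    drift_amplitude: float = 1.0

    def validate(self) -> None:
        if self.baseline_level <= 0:
            raise SynthError("baseline_level must be positive")
        for (roi, cond, phase), (amp, pid) in self.orientation_patterns.items():
            if roi not in self.n_voxels_per_roi:
                raise SynthError(f"pattern cell references unknown ROI {roi!r}")
            if amp < 0:
                raise SynthError(f"amplitude for {(roi, cond, phase)} is negative")
            if amp > 0:
                vec = self.pattern_bank.get(pid)
                if vec is None:
                    raise SynthError(f"pattern id {pid!r} missing from pattern_bank")
                if vec.shape != (self.n_voxels_per_roi[roi],):
                    raise SynthError(f"pattern {pid!r} length does not match ROI {roi!r}")
                if not np.isclose(np.linalg.norm(vec), 1.0, atol=1e-8):
                    raise SynthError(f"pattern {pid!r} is not unit norm")
        for key, s in self.cross_phase_sign.items():
            if s not in (-1, 1):
                raise SynthError(f"cross_phase_sign[{key}] must be +1 or -1")

    def amplitude(self, roi: str, condition: str, phase: str) -> float:
        cell = self.orientation_patterns.get((roi, condition, phase))
        return cell[0] if cell else 0.0

    def cell(self, roi: str, condition: str, phase: str):
        """(amplitude, effective pattern vector) for a cell; (0, None) if silent."""
        entry = self.orientation_patterns.get((roi, condition, phase))
        if not entry or entry[0] == 0.0:
            return 0.0, None
        amp, pid = entry
        vec = self.pattern_bank[pid]
        if phase == "action":
            vec = self.cross_phase_sign.get((roi, condition), 1) * vec
        return amp, vec

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "roi_names": list(self.roi_names),
            "n_voxels_per_roi": dict(self.n_voxels_per_roi),
            "baseline_level": self.baseline_level,
            "universal_response_amplitude": self.universal_response_amplitude,
            "orientation_patterns": {
                "|".join(k): [amp, pid]
                for k, (amp, pid) in self.orientation_patterns.items()
            },
            "pattern_bank": {pid: vec.tolist() for pid, vec in self.pattern_bank.items()},
            "cross_phase_sign": {"|".join(k): s for k, s in self.cross_phase_sign.items()},
            "noise_sd": self.noise_sd,
            "ar1_coefficient": self.ar1_coefficient,
            "drift_amplitude": self.drift_amplitude,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GroundTruth":
        truth = cls(
            roi_names=tuple(d["roi_names"]),
            n_voxels_per_roi={k: int(v) for k, v in d["n_voxels_per_roi"].items()},
            baseline_level=float(d["baseline_level"]),
            universal_response_amplitude=float(d["universal_response_amplitude"]),
            orientation_patterns={
                tuple(k.split("|")): (float(v[0]), str(v[1]))
                for k, v in d["orientation_patterns"].items()
            },
            pattern_bank={k: np.asarray(v, dtype=float) for k, v in d["pattern_bank"].items()},
            cross_phase_sign={tuple(k.split("|")): int(v)
                              for k, v in d["cross_phase_sign"].items()},
            noise_sd=float(d["noise_sd"]),
            ar1_coefficient=float(d["ar1_coefficient"]),
            drift_amplitude=float(d["drift_amplitude"]),
        )
        truth.validate()
        return truth

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls.from_dict(json.loads(Path(path).read_text()))


# Cells with decodable orientation information in the effect-structure
# scenario, per (phase, condition) -> ROIs.
EFFECT_STRUCTURE_CELLS: dict[str, dict[str, tuple[str, ...]]] = {
    "instruction": {
        "DG": ("V1", "V2", "V3d"),
        "AG": ("V1", "V2", "V3d"),
        "NG": ("V1", "V2", "V3d"),
        "UG": (),
    },
    "action": {
        "DG": ("V1", "V2", "V3d", "V7", "VIPS", "POIPS", "DIPS"),
        "AG": ("V1", "V2", "V3v", "V3A"),
        "NG": (),
        "UG": ("V3d", "V3v"),
    },
    "judgment": {
        "DG": ("V1", "V2", "V3d"),
        "AG": ("V1", "V2", "V3d", "V3A"),
        "NG": (),
        "UG": ("V3v",),
    },
}

#: ROIs whose action-phase pattern is shared between DG and UG in the
#: shared-subspace scenario.
SHARED_DG_UG_ROIS: tuple[str, ...] = ("V2", "V3v", "VIPS", "DIPS")
#: ROIs given *independent* DG and UG action-phase patterns in the same
#: scenario, as the no-transfer control.
INDEPENDENT_DG_UG_ROIS: tuple[str, ...] = ("V1", "V3d")

#: Cells given anti-correlated instruction/action patterns in the
#: "antiphase" scenario, per condition -> ROIs.
ANTIPHASE_CELLS: dict[str, tuple[str, ...]] = {
    "DG": ("V1", "V2", "V3d"),
    "AG": ("V1", "V2", "V3d", "V3v"),
    "NG": ("V1", "V2", "V3d"),
}


def make_ground_truth(scenario: str | Mapping = "effect_structure", seed: int = 0, *,
                      amplitude: float = 2.0,
                      baseline_level: float = 100.0,
                      universal_response_amplitude: float = 2.0,
                      noise_sd: float = 1.0,
                      ar1_coefficient: float = 0.3,
                      drift_amplitude: float = 1.0,
                      roi_names: Sequence[str] | None = None,
                      n_voxels_per_roi: Mapping[str, int] | None = None) -> GroundTruth:
    """Build a :class:`GroundTruth` from a named scenario or an explicit map.

    Built-in scenarios:

    ``"null"``
        No orientation information anywhere (all amplitudes zero).
    ``"effect_structure"``
        Orientation information exactly in the (ROI, condition) cells the
        same-type decoding analysis is expected to flag, per phase; every
        cell has its own independent pattern.
    ``"shared_DG_UG"``
        Action-phase information for DG and UG sharing one pattern in
        V2/V3v/VIPS/DIPS and using independent patterns in V1/V3d.
    ``"antiphase"``
        Instruction- and action-phase information sharing a pattern but
        with the action-phase pattern negated (cross_phase_sign -1) for
        DG/AG/NG in early visual areas.

    An explicit mapping ``{(roi, condition, phase): (amplitude, pattern_id)}``
    may be passed instead of a name; pattern vectors are then drawn here.
    ``amplitude`` sets the orientation amplitude (percent of baseline) used
    for every active cell of a named scenario.
    """
    rois = tuple(roi_names) if roi_names is not None else DEFAULT_ROI_NAMES
    n_vox = dict(n_voxels_per_roi) if n_voxels_per_roi is not None else {
        roi: DEFAULT_N_VOXELS.get(roi, 300) for roi in rois}
    cells: dict[tuple[str, str, str], tuple[float, str]] = {}
    signs: dict[tuple[str, str], int] = {}

    if isinstance(scenario, Mapping):
        cells = {tuple(k): (float(v[0]), str(v[1])) for k, v in scenario.items()}
    elif scenario == "null":
        pass
    elif scenario == "effect_structure":
        for phase, by_cond in EFFECT_STRUCTURE_CELLS.items():
            for cond, cell_rois in by_cond.items():
                for roi in cell_rois:
                    if roi in rois:
                        cells[(roi, cond, phase)] = (amplitude, f"{roi}:{cond}:{phase}")
    elif scenario == "shared_DG_UG":
        for roi in SHARED_DG_UG_ROIS:
            if roi in rois:
                for cond in ("DG", "UG"):
                    cells[(roi, cond, "action")] = (amplitude, f"{roi}:DG+UG")
        for roi in INDEPENDENT_DG_UG_ROIS:
            if roi in rois:
                for cond in ("DG", "UG"):
                    cells[(roi, cond, "action")] = (amplitude, f"{roi}:{cond}")
    elif scenario == "antiphase":
        for cond, cell_rois in ANTIPHASE_CELLS.items():
            for roi in cell_rois:
                if roi in rois:
                    pid = f"{roi}:{cond}"
                    cells[(roi, cond, "instruction")] = (amplitude, pid)
                    cells[(roi, cond, "action")] = (amplitude, pid)
                    signs[(roi, cond)] = -1
    else:
        raise SynthError(f"unknown scenario {scenario!r}; known: {SCENARIOS}")

    # one ROI per pattern id; vectors drawn in sorted id order for determinism
    pattern_roi: dict[str, str] = {}
    for (roi, _c, _p), (amp, pid) in cells.items():
        if amp == 0:
            continue
        if pattern_roi.setdefault(pid, roi) != roi:
            raise SynthError(f"pattern id {pid!r} reused across ROIs")
    # Distinct pattern ids within an ROI are drawn mutually orthogonal so
    # that "different id" really means no shared decodable structure (random
    # high-dimensional vectors would retain a ~1/sqrt(n_voxels) overlap).
    rng = np.random.default_rng(seed)
    bank: dict[str, np.ndarray] = {}
    drawn_per_roi: dict[str, list[np.ndarray]] = {}
    for pid in sorted(pattern_roi):
        roi = pattern_roi[pid]
        vec = rng.standard_normal(n_vox[roi])
        for prev in drawn_per_roi.get(roi, []):
            vec -= (vec @ prev) * prev
        vec /= np.linalg.norm(vec)
        bank[pid] = vec
        drawn_per_roi.setdefault(roi, []).append(vec)

    truth = GroundTruth(
        roi_names=rois,
        n_voxels_per_roi=n_vox,
        baseline_level=baseline_level,
        universal_response_amplitude=universal_response_amplitude,
        orientation_patterns=cells,
        pattern_bank=bank,
        cross_phase_sign=signs,
        noise_sd=noise_sd,
        ar1_coefficient=ar1_coefficient,
        drift_amplitude=drift_amplitude,
    )
    truth.validate()
    return truth


# ---------------------------------------------------------------------------
# Time-series simulation
# ---------------------------------------------------------------------------

@dataclass
class RoiTimeSeries:
    """Voxels x volumes signal matrix for one ROI of one run."""

    participant_id: int
    run_index: int
    roi_name: str
    matrix: np.ndarray
    voxel_ids: np.ndarray

    def validate(self, design: ExperimentDesign) -> None:
        if self.matrix.shape != (len(self.voxel_ids), design.volumes_per_run):
            raise SynthError("matrix shape does not match voxel_ids / volumes_per_run")
        if not np.all(np.isfinite(self.matrix)):
            raise SynthError("matrix contains non-finite values")


@dataclass
class MotionTrace:
    """Per-volume rigid-body motion relative to the run's first volume."""

    participant_id: int
    run_index: int
    translation_mm: np.ndarray  # volumes x 3
    rotation_deg: np.ndarray    # volumes x 3

    def max_translation(self) -> float:
        return float(np.abs(self.translation_mm).max())

    def max_rotation(self) -> float:
        return float(np.abs(self.rotation_deg).max())


def simulate_roi_run(design: ExperimentDesign, trials: Sequence[TrialEvent],
                     truth: GroundTruth, roi: str,
                     seed: int | np.random.Generator) -> RoiTimeSeries:
    """Simulate one ROI of one run given its trials.

    Deterministic for a fixed seed; random draws happen in a fixed order
    (AR(1) innovations first, then drift coefficients).
    """
    if roi not in truth.n_voxels_per_roi:
        raise SynthError(f"ROI {roi!r} absent from ground truth")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_vox = truth.n_voxels_per_roi[roi]
    n_vol = design.volumes_per_run
    vol_t = np.arange(n_vol) * design.tr_seconds

    universal = np.zeros(n_vol)
    orient = np.zeros((n_vox, n_vol))
    for ev in trials:
        if ev.trial_onset_seconds >= design.run_duration_seconds:
            raise SynthError(f"trial onset {ev.trial_onset_seconds:g} s beyond run")
        sign = 1.0 if ev.orientation > 0 else -1.0
        for phase in MEASURED_PHASES:
            r = _sampled_regressor(ev.phase_onsets_seconds[phase],
                                   design.phase_durations_seconds[phase], vol_t)
            universal += truth.universal_response_amplitude * r
            amp, pattern = truth.cell(roi, ev.condition, phase)
            if pattern is not None:
                orient += np.outer((sign * amp) * pattern, r)

    signal = truth.baseline_level * (1.0 + (universal[None, :] + orient) / 100.0)

    if truth.noise_sd > 0:
        rho = truth.ar1_coefficient
        innov_sd = truth.noise_sd * np.sqrt(1.0 - rho ** 2)
        e = rng.normal(0.0, innov_sd, (n_vox, n_vol))
        e[:, 0] = rng.normal(0.0, truth.noise_sd, n_vox)  # stationary start
        signal = signal + lfilter([1.0], [1.0, -rho], e, axis=1)
    if truth.drift_amplitude > 0:
        tn = np.linspace(-1.0, 1.0, n_vol)
        coef = rng.normal(0.0, truth.drift_amplitude, (n_vox, 2))
        signal = signal + coef[:, :1] * tn + coef[:, 1:] * (3.0 * tn ** 2 - 1.0) / 2.0

    return RoiTimeSeries(trials[0].participant_id if trials else -1,
                         trials[0].run_index if trials else -1,
                         roi, signal, np.arange(n_vox))


def simulate_motion(design: ExperimentDesign, seed: int | np.random.Generator,
                    contaminated_runs: Iterable[int] = (),
                    participant_id: int = 0) -> list[MotionTrace]:
    """Smooth motion traces for one participant; first volume is zero.

    Clean runs stay strictly below 2 mm translation and 2 deg rotation;
    runs listed in ``contaminated_runs`` exceed at least one threshold on
    one randomly chosen axis.
    """
    contaminated = set(contaminated_runs)
    bad = contaminated - set(range(design.n_runs))
    if bad:
        raise SynthError(f"contaminated_runs {sorted(bad)} outside run range")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    traces = []
    for run in range(design.n_runs):
        steps = rng.normal(0.0, 1.0, (design.volumes_per_run - 1, 6))
        path = np.vstack([np.zeros(6), np.cumsum(steps, axis=0)])
        targets = rng.uniform(0.2, 1.5, 6)
        if run in contaminated:
            targets[rng.integers(0, 6)] = rng.uniform(2.3, 3.5)
        peak = np.abs(path).max(axis=0)
        peak[peak == 0] = 1.0
        path = path * (targets / peak)
        traces.append(MotionTrace(participant_id, run, path[:, :3], path[:, 3:]))
    return traces


def simulate_behavior(design: ExperimentDesign, table: TrialTable,
                      rng: np.random.Generator, p_correct: float = 0.95,
                      p_unanswered: float = 0.02) -> pd.DataFrame:
    """Per-trial judgment responses: chosen orientation or unanswered."""
    rows = []
    for ev in table:
        if rng.random() < p_unanswered:
            response, correct = np.nan, np.nan
        else:
            ok = rng.random() < p_correct
            response = ev.orientation if ok else -ev.orientation
            correct = float(ok)
        rows.append({"participant": ev.participant_id, "run": ev.run_index,
                     "trial": ev.trial_index_in_run, "condition": ev.condition,
                     "orientation": ev.orientation, "response": response,
                     "correct": correct})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Whole datasets
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    """All simulated material for one experiment."""

    design: ExperimentDesign
    truth: GroundTruth
    seed: int
    trial_tables: dict[int, TrialTable]
    timeseries: dict[tuple[int, int, str], RoiTimeSeries]
    motion: dict[int, list[MotionTrace]]
    behavior: pd.DataFrame

    @property
    def rois(self) -> tuple[str, ...]:
        return self.truth.roi_names


def simulate_dataset(design: ExperimentDesign, truth: GroundTruth, seed: int, *,
                     p_correct: float = 0.95, p_unanswered: float = 0.02,
                     contaminated_runs: Mapping[int, Iterable[int]] | None = None,
                     rois: Sequence[str] | None = None) -> SimulatedDataset:
    """Simulate the full experiment: one ROI matrix per participant x run x ROI.

    Participant ``i`` uses seed ``seed + i``; within a participant the trial
    table is built from that seed directly and the remaining randomness
    (noise, motion, behavior) is drawn from independent streams spawned from
    it, so any participant can be regenerated in isolation.
    """
    design.validate()
    truth.validate()
    use_rois = tuple(rois) if rois is not None else truth.roi_names
    unknown = set(use_rois) - set(truth.roi_names)
    if unknown:
        raise SynthError(f"requested ROIs {sorted(unknown)} absent from ground truth")
    contaminated = dict(contaminated_runs or {})

    tables: dict[int, TrialTable] = {}
    series: dict[tuple[int, int, str], RoiTimeSeries] = {}
    motion: dict[int, list[MotionTrace]] = {}
    behavior_frames = []
    for pid in range(design.n_participants):
        pseed = seed + pid
        tables[pid] = build_trial_table(design, pseed, pid)
        streams = np.random.SeedSequence(pseed).spawn(3)
        ts_rng = np.random.default_rng(streams[0])
        for run in range(design.n_runs):
            trials = tables[pid].for_run(run)
            for roi in use_rois:
                series[(pid, run, roi)] = simulate_roi_run(design, trials, truth, roi, ts_rng)
        motion[pid] = simulate_motion(design, np.random.default_rng(streams[1]),
                                      contaminated.get(pid, ()), pid)
        behavior_frames.append(simulate_behavior(design, tables[pid],
                                                 np.random.default_rng(streams[2]),
                                                 p_correct, p_unanswered))
    return SimulatedDataset(design, truth, seed, tables, series, motion,
                            pd.concat(behavior_frames, ignore_index=True))


# ---------------------------------------------------------------------------
# On-disk format (delimited text + JSON manifest)
# ---------------------------------------------------------------------------

def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> None:
    """Write a dataset as plain text: design/truth JSON, events TSV, one
    matrix TSV per participant/run/ROI, motion and behavior TSVs."""
    out = Path(outdir)
    for sub in ("events", "func", "motion", "behavior"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    design = dataset.design
    design.to_json(out / "design.json")
    dataset.truth.to_json(out / "ground_truth.json")
    files = []
    for pid, table in dataset.trial_tables.items():
        table.to_tsv(out / "events" / f"sub-{pid:02d}_events.tsv", design)
    for (pid, run, roi), ts in dataset.timeseries.items():
        name = f"sub-{pid:02d}_run-{run:02d}_roi-{roi}.tsv"
        pd.DataFrame(ts.matrix, index=ts.voxel_ids).to_csv(
            out / "func" / name, sep="\t", header=False, float_format="%.8g")
        files.append(name)
    for pid, traces in dataset.motion.items():
        for tr in traces:
            frame = pd.DataFrame(
                np.hstack([tr.translation_mm, tr.rotation_deg]),
                columns=["tx_mm", "ty_mm", "tz_mm", "rx_deg", "ry_deg", "rz_deg"])
            frame.to_csv(out / "motion" / f"sub-{pid:02d}_run-{tr.run_index:02d}_motion.tsv",
                         sep="\t", index=False, float_format="%.8g")
    dataset.behavior.to_csv(out / "behavior" / "behavior.tsv", sep="\t",
                            index=False, float_format="%.8g")
    manifest = {
        "seed": dataset.seed,
        "participants": sorted(dataset.trial_tables),
        "rois": list({roi for (_p, _r, roi) in dataset.timeseries}),
        "n_func_files": len(files),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def load_dataset(path: str | Path) -> SimulatedDataset:
    """Load a dataset written by :func:`write_dataset`.

    The same layout is the supported import path for real per-ROI data:
    ``design.json``, ``events/sub-XX_events.tsv`` and
    ``func/sub-XX_run-RR_roi-NAME.tsv`` matrices are required;
    ``ground_truth.json`` (used only to name ROIs and voxel counts),
    motion and behavior tables are optional.
    """
    root = Path(path)
    design = ExperimentDesign.from_json(root / "design.json")
    manifest = json.loads((root / "manifest.json").read_text())
    truth_file = root / "ground_truth.json"
    tables = {}
    for pid in manifest["participants"]:
        tables[pid] = TrialTable.from_tsv(root / "events" / f"sub-{pid:02d}_events.tsv", design)
    series = {}
    for f in sorted((root / "func").glob("sub-*_run-*_roi-*.tsv")):
        stem = f.stem  # sub-00_run-00_roi-V1
        parts = dict(p.split("-", 1) for p in stem.split("_"))
        pid, run, roi = int(parts["sub"]), int(parts["run"]), parts["roi"]
        raw = pd.read_csv(f, sep="\t", header=None, index_col=0)
        series[(pid, run, roi)] = RoiTimeSeries(pid, run, roi, raw.to_numpy(float),
                                                raw.index.to_numpy(int))
    rois = sorted({roi for (_p, _r, roi) in series})
    if truth_file.exists():
        truth = GroundTruth.from_json(truth_file)
    else:  # real data: minimal truth carrying only layout
        n_vox = {roi: series[next(k for k in series if k[2] == roi)].matrix.shape[0]
                 for roi in rois}
        truth = GroundTruth(tuple(rois), n_vox, noise_sd=0.0, drift_amplitude=0.0)
    motion: dict[int, list[MotionTrace]] = {}
    for f in sorted((root / "motion").glob("sub-*_run-*_motion.tsv")) if (root / "motion").exists() else []:
        parts = dict(p.split("-", 1) for p in f.stem.split("_") if "-" in p)
        pid, run = int(parts["sub"]), int(parts["run"])
        arr = pd.read_csv(f, sep="\t").to_numpy(float)
        motion.setdefault(pid, []).append(MotionTrace(pid, run, arr[:, :3], arr[:, 3:]))
    behavior_file = root / "behavior" / "behavior.tsv"
    behavior = (pd.read_csv(behavior_file, sep="\t") if behavior_file.exists()
                else pd.DataFrame())
    return SimulatedDataset(design, truth, int(manifest.get("seed", 0)), tables,
                            series, motion, behavior)
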