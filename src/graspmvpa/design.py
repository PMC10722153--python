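"""Experimental design: conditions, orientations, trial timing, and trial tables.

The experiment is an event-related grasping study.  Each trial shows (or, in
the uninformed condition, withholds) an oriented object, asks the participant
to grasp / pantomime / withhold, and ends with a two-alternative orientation
judgment.  Four action conditions (DG direct grasp, AG air grasp, NG non
grasp, UG uninformed grasp) are crossed with two object orientations
(+45 deg / -45 deg roll), giving eight trial settings.

This module encodes the layout constants (TR, run/trial counts, phase
durations) and converts trial events into second and volume coordinates.
Volume indexing is 0-based and half-open throughout.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

CONDITIONS: tuple[str, ...] = ("DG", "AG", "NG", "UG")
ORIENTATIONS: tuple[int, ...] = (45, -45)

#: Trial phases in temporal order.  "wait1"/"wait2" are the fixation waits
#: between phases, "iti" the inter-trial fixation.
PHASE_ORDER: tuple[str, ...] = ("instruction", "wait1", "action", "wait2", "judgment", "iti")

#: Phases with an evoked response that the analysis samples.
MEASURED_PHASES: tuple[str, ...] = ("instruction", "action", "judgment")

DEFAULT_PHASE_DURATIONS: dict[str, float] = {
    "instruction": 1.0,
    "wait1": 5.0,
    "action": 4.0,
    "wait2": 8.0,
    "judgment": 2.0,
    "iti": 4.0,
}


class DesignError(ValueError):
    """Raised when design parameters violate a structural invariant."""


def orientation_label(orientation: int) -> str:
    return f"+{orientation}" if orientation > 0 else str(orientation)


@dataclass(frozen=True)
class ExperimentDesign:
    """Timing and layout constants of the study.

    Defaults reproduce the study layout: TR 2 s, 198 volumes per run,
    10 runs of 16 trials, 10 participants, 20 repetitions of each of the
    8 trial settings, and a 24 s trial (1 + 5 + 4 + 8 + 2 + 4 s phases).
    The stated trial timings fill 192 volumes; the remaining 12 s are
    modelled as lead-in baseline volumes at the start of each run.
    """

    tr_seconds: float = 2.0
    volumes_per_run: int = 198
    n_runs: int = 10
    trials_per_run: int = 16
    n_participants: int = 10
    repetitions_per_setting: int = 20
    conditions: tuple[str, ...] = CONDITIONS
    orientations: tuple[int, ...] = ORIENTATIONS
    phase_durations_seconds: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHASE_DURATIONS)
    )
    lead_in_volumes: int = 6

    # -- derived quantities -------------------------------------------------

    @property
    def settings(self) -> list[tuple[str, int]]:
        """All (condition, orientation) trial settings, in canonical order."""
        return [(c, o) for c in self.conditions for o in self.orientations]

    @property
    def n_settings(self) -> int:
        return len(self.conditions) * len(self.orientations)

    @property
    def total_trials(self) -> int:
        return self.n_runs * self.trials_per_run

    @property
    def trial_duration_seconds(self) -> float:
        return float(sum(self.phase_durations_seconds[p] for p in PHASE_ORDER))

    @property
    def lead_in_seconds(self) -> float:
        return self.lead_in_volumes * self.tr_seconds

    @property
    def run_duration_seconds(self) -> float:
        return self.volumes_per_run * self.tr_seconds

    def phase_onset_in_trial(self, phase: str) -> float:
        """Onset of *phase* in seconds from trial onset."""
        if phase not in PHASE_ORDER:
            raise DesignError(f"unknown phase {phase!r}; expected one of {PHASE_ORDER}")
        onset = 0.0
        for p in PHASE_ORDER:
            if p == phase:
                return onset
            onset += self.phase_durations_seconds[p]
        raise AssertionError("unreachable")

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.tr_seconds <= 0:
            raise DesignError("tr_seconds must be positive")
        for name in ("volumes_per_run", "n_runs", "trials_per_run",
                     "n_participants", "repetitions_per_setting"):
            if getattr(self, name) <= 0:
                raise DesignError(f"{name} must be positive")
        if self.lead_in_volumes < 0:
            raise DesignError("lead_in_volumes must be non-negative")
        missing = [p for p in PHASE_ORDER if p not in self.phase_durations_seconds]
        if missing:
            raise DesignError(f"phase_durations_seconds missing phases {missing}")
        if any(self.phase_durations_seconds[p] <= 0 for p in PHASE_ORDER):
            raise DesignError("phase durations must be positive")
        if len(set(self.conditions)) != len(self.conditions):
            raise DesignError("conditions must be unique")
        if len(set(self.orientations)) != len(self.orientations) or len(self.orientations) != 2:
            raise DesignError("orientations must be two distinct values")
        if self.total_trials != self.n_settings * self.repetitions_per_setting:
            raise DesignError(
                "trial_count_balance violated: n_runs * trials_per_run "
                f"({self.total_trials}) != settings * repetitions_per_setting "
                f"({self.n_settings * self.repetitions_per_setting})"
            )
        needed = self.lead_in_seconds + self.trials_per_run * self.trial_duration_seconds
        if needed > self.run_duration_seconds + 1e-9:
            raise DesignError(
                "run_capacity violated: lead-in + trials need "
                f"{needed:g} s but the run holds {self.run_duration_seconds:g} s"
            )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "tr_seconds": self.tr_seconds,
            "volumes_per_run": self.volumes_per_run,
            "n_runs": self.n_runs,
            "trials_per_run": self.trials_per_run,
            "n_participants": self.n_participants,
            "repetitions_per_setting": self.repetitions_per_setting,
            "conditions": list(self.conditions),
            "orientations": list(self.orientations),
            "phase_durations_seconds": dict(self.phase_durations_seconds),
            "lead_in_volumes": self.lead_in_volumes,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExperimentDesign":
        return build_design(**dict(d))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ExperimentDesign":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_design(**overrides) -> ExperimentDesign:
    """Build a validated :class:`ExperimentDesign` (study defaults + overrides)."""
    if "conditions" in overrides:
        overrides["conditions"] = tuple(overrides["conditions"])
    if "orientations" in overrides:
        overrides["orientations"] = tuple(int(o) for o in overrides["orientations"])
    if "phase_durations_seconds" in overrides:
        durs = dict(DEFAULT_PHASE_DURATIONS)
        durs.update(overrides["phase_durations_seconds"])
        overrides["phase_durations_seconds"] = durs
    design = ExperimentDesign(**overrides)
    design.validate()
    return design


@dataclass(frozen=True)
class TrialEvent:
    """One trial of one run, with phase onsets in seconds from run start."""

    participant_id: int
    run_index: int
    trial_index_in_run: int
    condition: str
    orientation: int
    trial_onset_seconds: float
    phase_onsets_seconds: Mapping[str, float]

    @classmethod
    def make(cls, design: ExperimentDesign, participant_id: int, run_index: int,
             trial_index_in_run: int, condition: str, orientation: int) -> "TrialEvent":
        onset = design.lead_in_seconds + trial_index_in_run * design.trial_duration_seconds
        phases = {p: onset + design.phase_onset_in_trial(p) for p in PHASE_ORDER}
        return cls(participant_id, run_index, trial_index_in_run,
                   condition, orientation, onset, phases)


def phase_volume_index(event: TrialEvent, phase: str, design: ExperimentDesign) -> int:
    """0-based volume index containing the onset of *phase* of *event*."""
    if phase not in event.phase_onsets_seconds:
        raise DesignError(f"unknown phase {phase!r}")
    onset = event.phase_onsets_seconds[phase]
    if onset >= design.run_duration_seconds:
        raise DesignError(
            f"phase {phase!r} onset {onset:g} s is beyond the run "
            f"({design.run_duration_seconds:g} s)"
        )
    return int(math.floor(onset / design.tr_seconds))


@dataclass
class TrialTable:
    """Ordered trial events spanning all runs of one participant."""

    participant_id: int
    events: list[TrialEvent]

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[TrialEvent]:
        return iter(self.events)

    def for_run(self, run_index: int) -> list[TrialEvent]:
        return [e for e in self.events if e.run_index == run_index]

    def setting_counts(self) -> dict[tuple[str, int], int]:
        counts: dict[tuple[str, int], int] = {}
        for e in self.events:
            key = (e.condition, e.orientation)
            counts[key] = counts.get(key, 0) + 1
        return counts

    def validate(self, design: ExperimentDesign) -> None:
        for run in range(design.n_runs):
            if len(self.for_run(run)) != design.trials_per_run:
                raise DesignError(f"run {run} does not hold {design.trials_per_run} trials")
        for setting, n in self.setting_counts().items():
            if n != design.repetitions_per_setting:
                raise DesignError(
                    f"setting {setting} occurs {n} times, expected "
                    f"{design.repetitions_per_setting}"
                )

    # -- BIDS-style events table -------------------------------------------

    def to_frame(self, design: ExperimentDesign) -> pd.DataFrame:
        rows = [
            {
                "onset": e.trial_onset_seconds,
                "duration": design.trial_duration_seconds,
                "trial_type": f"{e.condition}_{orientation_label(e.orientation)}",
                "run": e.run_index,
                "participant": e.participant_id,
            }
            for e in self.events
        ]
        return pd.DataFrame(rows, columns=["onset", "duration", "trial_type", "run", "participant"])

    def to_tsv(self, path: str | Path, design: ExperimentDesign) -> None:
        self.to_frame(design).to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, design: ExperimentDesign) -> "TrialTable":
        events: list[TrialEvent] = []
        per_run_counter: dict[int, int] = {}
        for _, row in frame.iterrows():
            cond, orient = str(row["trial_type"]).rsplit("_", 1)
            run = int(row["run"])
            idx = per_run_counter.get(run, 0)
            per_run_counter[run] = idx + 1
            events.append(TrialEvent.make(design, int(row["participant"]), run,
                                          idx, cond, int(orient)))
        pid = events[0].participant_id if events else 0
        return cls(pid, events)

    @classmethod
    def from_tsv(cls, path: str | Path, design: ExperimentDesign) -> "TrialTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"), design)


def build_trial_table(design: ExperimentDesign, seed: int,
                      participant_id: int = 0) -> TrialTable:
    """Randomized trial order for one participant, balanced per run.

    When the per-run trial count is a multiple of the number of settings,
    each run holds an equal number of every setting, shuffled independently
    per run (the standard event-related layout; it also guarantees that
    every leave-one-run-out fold sees both orientations of every condition).
    Otherwise the full per-participant multiset of settings is shuffled
    jointly and cut into runs.
    """
    design.validate()
    rng = np.random.default_rng(seed)
    settings = design.settings
    events: list[TrialEvent] = []
    if design.trials_per_run % design.n_settings == 0:
        per_run = design.trials_per_run // design.n_settings
        for run in range(design.n_runs):
            block = settings * per_run
            order = rng.permutation(len(block))
            for idx, j in enumerate(order):
                cond, orient = block[j]
                events.append(TrialEvent.make(design, participant_id, run, idx, cond, orient))
    else:
        block = settings * design.repetitions_per_setting
        order = rng.permutation(len(block))
        for k, j in enumerate(order):
            run, idx = divmod(k, design.trials_per_run)
            cond, orient = block[j]
            events.append(TrialEvent.make(design, participant_id, run, idx, cond, orient))
    table = TrialTable(participant_id, events)
    table.validate(design)
    return table
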