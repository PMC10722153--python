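"""Pipeline orchestration: simulate -> preprocess -> decode -> group stats.

A single :class:`PipelineConfig` (JSON-serializable, master seed mandatory)
drives the whole analysis deterministically and yields tidy result tables
plus a manifest recording the configuration hash and seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .decoding import (DEFAULT_MARGIN_PENALTY, cross_phase_accuracy,
                       loro_accuracy, transfer_accuracy)
from .design import MEASURED_PHASES, ExperimentDesign, build_design
from .preprocess import (DEFAULT_LAG_VOLUMES, DEFAULT_N_SELECT, exclude_runs,
                         extract_patterns, percent_signal_change,
                         select_voxels, selection_contrast)
from .stats import (DEFAULT_ALPHA, DEFAULT_CHANCE, DEFAULT_PSC_ALPHA, DEFAULT_Q,
                    behavioral_accuracy, group_accuracy_table, psc_group_test)
from .synth import SimulatedDataset, make_ground_truth, simulate_dataset

logger = logging.getLogger(__name__)

#: The six condition pairs cross-decoded in the action phase.
DEFAULT_TRANSFER_PAIRS: tuple[tuple[str, str], ...] = (
    ("DG", "AG"), ("DG", "UG"), ("AG", "UG"),
    ("AG", "NG"), ("DG", "NG"), ("UG", "NG"))

PSC_CONTRASTS: tuple[tuple[str, str, str | None], ...] = (
    ("stimuli_vs_baseline", "instruction", None),
    ("grasping_vs_baseline", "action", None),
    ("judgment_vs_baseline", "judgment", None),
    ("UG_instruction_vs_baseline", "instruction", "UG"),
    ("NG_action_vs_baseline", "action", "NG"),
)


class ConfigError(ValueError):
    """Raised when a pipeline configuration does not validate."""


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one full analysis."""

    seed: int
    scenario: str = "effect_structure"
    design: dict = field(default_factory=dict)          # ExperimentDesign overrides
    truth: dict = field(default_factory=dict)           # make_ground_truth keyword overrides
    rois: list[str] | None = None                       # subset of truth ROIs
    phases: list[str] = field(default_factory=lambda: list(MEASURED_PHASES))
    same_conditions: list[str] | None = None            # default: all design conditions
    transfer_pairs: list[list[str]] = field(
        default_factory=lambda: [list(p) for p in DEFAULT_TRANSFER_PAIRS])
    transfer_phase: str = "action"
    cross_phase_conditions: list[str] | None = None     # default: all design conditions
    cross_phase_pair: list[str] = field(default_factory=lambda: ["instruction", "action"])
    margin_penalty: float = DEFAULT_MARGIN_PENALTY
    n_select: int = DEFAULT_N_SELECT
    lag_volumes: int = DEFAULT_LAG_VOLUMES
    chance: float = DEFAULT_CHANCE
    alpha: float = DEFAULT_ALPHA
    q: float = DEFAULT_Q
    psc_alpha: float = DEFAULT_PSC_ALPHA
    fdr_family: str = "analysis"
    p_correct: float = 0.95
    p_unanswered: float = 0.02
    contaminated_runs: dict = field(default_factory=dict)  # participant -> [runs]

    def validate(self) -> ExperimentDesign:
        if self.seed is None:
            raise ConfigError("a master seed is mandatory")
        design = build_design(**self.design)
        conds = set(design.conditions)
        for pair in self.transfer_pairs:
            if len(pair) != 2 or not set(pair) <= conds:
                raise ConfigError(f"transfer pair {pair} not drawn from {sorted(conds)}")
        for c in (self.same_conditions or []):
            if c not in conds:
                raise ConfigError(f"unknown condition {c!r} in same_conditions")
        for c in (self.cross_phase_conditions or []):
            if c not in conds:
                raise ConfigError(f"unknown condition {c!r} in cross_phase_conditions")
        for ph in list(self.phases) + [self.transfer_phase] + list(self.cross_phase_pair):
            if ph not in MEASURED_PHASES:
                raise ConfigError(f"unknown phase {ph!r}")
        if len(self.cross_phase_pair) != 2:
            raise ConfigError("cross_phase_pair must name two phases")
        return design

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        if "seed" not in d:
            raise ConfigError("a master seed is mandatory")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(d))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Result bundle of one pipeline run (tidy tables + manifest)."""

    config: PipelineConfig
    decoding: pd.DataFrame       # per participant x cell accuracies
    group: pd.DataFrame          # group stats with FDR flags
    psc: pd.DataFrame            # per participant x roi x contrast PSC
    psc_group: pd.DataFrame      # group PSC tests
    behavior: pd.DataFrame       # per-participant judgment accuracy
    manifest: dict

    _TABLES = ("decoding", "group", "psc", "psc_group", "behavior")

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name in self._TABLES:
            getattr(self, name).to_csv(out / f"{name}.tsv", sep="\t", index=False,
                                       float_format="%.10g")
        (out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True) + "\n")
        (out / "report.txt").write_text(make_report(self))


# ---------------------------------------------------------------------------
# Decoding over a dataset
# ---------------------------------------------------------------------------

def decode_dataset(dataset: SimulatedDataset, *,
                   retained: Mapping[int, Sequence[int]] | None = None,
                   rois: Sequence[str] | None = None,
                   phases: Sequence[str] = MEASURED_PHASES,
                   same_conditions: Sequence[str] | None = None,
                   transfer_pairs: Sequence[Sequence[str]] = (),
                   transfer_phase: str = "action",
                   cross_phase_conditions: Sequence[str] = (),
                   cross_phase_pair: Sequence[str] = ("instruction", "action"),
                   margin_penalty: float = DEFAULT_MARGIN_PENALTY,
                   n_select: int = DEFAULT_N_SELECT,
                   lag_volumes: int = DEFAULT_LAG_VOLUMES) -> pd.DataFrame:
    """Voxel selection, pattern extraction and all decoding analyses.

    Returns a tidy frame with one row per participant x ROI x analysis cell:
    columns ``participant, roi, analysis, phase, condition, accuracy,
    n_folds, fold_accuracies, directions``.
    """
    design = dataset.design
    use_rois = tuple(rois) if rois is not None else dataset.rois
    conds = tuple(same_conditions) if same_conditions is not None else design.conditions
    participants = sorted(dataset.trial_tables)
    if retained is None:
        retained = {pid: tuple(range(design.n_runs)) for pid in participants}
    need_phases = set(phases)
    if transfer_pairs:
        need_phases.add(transfer_phase)
    if cross_phase_conditions:
        need_phases.update(cross_phase_pair)

    rows = []
    for pid in participants:
        runs = tuple(retained[pid])
        table = dataset.trial_tables[pid]
        events_by_run = {r: table.for_run(r) for r in runs}
        for roi in use_rois:
            ts_by_run = {r: dataset.timeseries[(pid, r, roi)] for r in runs}
            scores, vids = selection_contrast(ts_by_run, events_by_run, design,
                                              lag_volumes)
            sel = select_voxels(scores, vids, n_select, roi_name=roi,
                                participant_id=pid)
            patterns = {
                ph: [s for r in runs
                     for s in extract_patterns(ts_by_run[r], sel,
                                               events_by_run[r], ph, design)]
                for ph in sorted(need_phases)
            }

            def by_cond(phase: str, cond: str):
                return [s for s in patterns[phase] if s.condition == cond]

            for ph in phases:
                for cond in conds:
                    res = loro_accuracy(by_cond(ph, cond), margin_penalty)
                    rows.append(_result_row(res, n_voxels=len(sel.voxel_ids)))
            for pair in transfer_pairs:
                a, b = pair
                res = transfer_accuracy(by_cond(transfer_phase, a),
                                        by_cond(transfer_phase, b), margin_penalty)
                rows.append(_result_row(res, n_voxels=len(sel.voxel_ids)))
            for cond in cross_phase_conditions:
                res = cross_phase_accuracy(by_cond(cross_phase_pair[0], cond),
                                           by_cond(cross_phase_pair[1], cond),
                                           margin_penalty)
                rows.append(_result_row(res, n_voxels=len(sel.voxel_ids)))
    return pd.DataFrame(rows)


def _result_row(res, n_voxels: int) -> dict:
    phase = res.phase if isinstance(res.phase, str) else "+".join(res.phase)
    cond = res.condition if isinstance(res.condition, str) else "&".join(res.condition)
    return {"participant": res.participant_id, "roi": res.roi_name,
            "analysis": res.kind, "phase": phase, "condition": cond,
            "accuracy": res.accuracy, "n_folds": len(res.fold_accuracies),
            "fold_accuracies": ",".join(f"{a:.6g}" for a in res.fold_accuracies),
            "directions": ";".join(f"{k}={v:.6g}" for k, v in res.directions.items()),
            "n_voxels": n_voxels}


def compute_psc_table(dataset: SimulatedDataset,
                      retained: Mapping[int, Sequence[int]],
                      rois: Sequence[str],
                      lag_volumes: int = DEFAULT_LAG_VOLUMES) -> pd.DataFrame:
    """Per participant x ROI x contrast percent signal change (runs averaged)."""
    design = dataset.design
    rows = []
    for pid, runs in sorted(retained.items()):
        table = dataset.trial_tables[pid]
        for roi in rois:
            for contrast, phase, cond in PSC_CONTRASTS:
                per_run = []
                for r in runs:
                    all_events = table.for_run(r)
                    events = (all_events if cond is None
                              else [e for e in all_events if e.condition == cond])
                    if not events:
                        continue
                    res = percent_signal_change(dataset.timeseries[(pid, r, roi)],
                                                events, phase, design, lag_volumes,
                                                contrast, baseline_events=all_events)
                    per_run.append(res.value)
                rows.append({"participant": pid, "roi": roi, "contrast": contrast,
                             "psc": float(np.mean(per_run)), "n_runs": len(per_run)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full simulate -> preprocess -> decode -> stats pipeline.

    Fully deterministic given the configuration content; every stage logs
    its counts and timing at INFO level.
    """
    t0 = time.perf_counter()
    design = config.validate()
    truth = make_ground_truth(config.scenario, config.seed, **config.truth)
    rois = tuple(config.rois) if config.rois else truth.roi_names

    dataset = simulate_dataset(
        design, truth, config.seed, p_correct=config.p_correct,
        p_unanswered=config.p_unanswered,
        contaminated_runs={int(k): v for k, v in config.contaminated_runs.items()},
        rois=rois)
    logger.info("simulate: %d ROI matrices in %.1fs", len(dataset.timeseries),
                time.perf_counter() - t0)

    t1 = time.perf_counter()
    retained = exclude_runs(dataset.motion)
    n_excluded = sum(design.n_runs - len(v) for v in retained.values())
    logger.info("exclude_runs: %d run(s) excluded", n_excluded)

    decoding = decode_dataset(
        dataset, retained=retained, rois=rois, phases=config.phases,
        same_conditions=config.same_conditions,
        transfer_pairs=config.transfer_pairs, transfer_phase=config.transfer_phase,
        cross_phase_conditions=(config.cross_phase_conditions
                                if config.cross_phase_conditions is not None
                                else design.conditions),
        cross_phase_pair=config.cross_phase_pair,
        margin_penalty=config.margin_penalty, n_select=config.n_select,
        lag_volumes=config.lag_volumes)
    logger.info("decode: %d result rows in %.1fs", len(decoding),
                time.perf_counter() - t1)

    group = group_accuracy_table(decoding, chance=config.chance, alpha=config.alpha,
                                 q=config.q, fdr_family=config.fdr_family)

    psc = compute_psc_table(dataset, retained, rois, config.lag_volumes)
    psc_rows = []
    for (roi, contrast), grp in psc.groupby(["roi", "contrast"], sort=True):
        gs = psc_group_test(grp["psc"].to_numpy(), roi_name=roi, contrast=contrast,
                            alpha=config.psc_alpha)
        psc_rows.append({"roi": roi, "contrast": contrast, "n": gs.n,
                         "mean_psc": gs.mean, "t": gs.t, "p": gs.p,
                         "significant": gs.significant_uncorrected})
    psc_group = pd.DataFrame(psc_rows)

    acc = behavioral_accuracy(dataset.behavior)
    behavior = acc.rename("accuracy").reset_index()

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "n_participants": design.n_participants,
        "rois": list(rois),
        "runs_retained": {str(k): list(v) for k, v in retained.items()},
        "n_decoding_rows": int(len(decoding)),
        "elapsed_seconds": round(time.perf_counter() - t0, 2),
    }
    logger.info("pipeline done in %.1fs", time.perf_counter() - t0)
    return PipelineResult(config, decoding, group, psc, psc_group, behavior, manifest)


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

def make_report(result: PipelineResult) -> str:
    """Human-readable per-panel summary of the serialized group table.

    One table per (analysis kind x phase); the chance level is 50%;
    ``*`` marks cells significant after FDR correction.  No number is
    recomputed here -- every value is read from the group table.
    """
    group = result.group
    lines = [f"graspmvpa report (config {result.manifest['config_hash']})",
             "chance level: 50%; '*' = significant after FDR (q < "
             f"{result.config.q:g}); accuracies are group means (n = "
             f"{result.manifest['n_participants']})", ""]
    if group.empty:
        lines.append("(no decoding panels)")
    for (analysis, phase), panel in group.groupby(["analysis", "phase"], sort=True):
        lines.append(f"== {analysis} decoding, phase: {phase} ==")
        conds = sorted(panel["condition"].unique())
        header = "ROI".ljust(8) + "".join(c.center(12) for c in conds)
        lines.append(header)
        for roi, sub in panel.groupby("roi", sort=True):
            cells = []
            for c in conds:
                row = sub[sub["condition"] == c]
                if row.empty:
                    cells.append("-".center(12))
                else:
                    r = row.iloc[0]
                    mark = "*" if r["significant_fdr"] else " "
                    cells.append(f"{100 * r['mean']:5.1f}%{mark}".center(12))
            lines.append(roi.ljust(8) + "".join(cells))
        lines.append("")
    if not result.psc_group.empty:
        lines.append("== percent signal change (group mean, t-test vs 0) ==")
        for _, r in result.psc_group.iterrows():
            mark = "*" if r["significant"] else " "
            lines.append(f"{r['roi']:<8}{r['contrast']:<28}"
                         f"{r['mean_psc']:7.3f}%{mark}  (p={r['p']:.2e})")
        lines.append("")
    if not result.behavior.empty:
        mean_acc = result.behavior["accuracy"].mean()
        lines.append(f"behavioral judgment accuracy: group mean {100 * mean_acc:.1f}%")
    return "\n".join(lines) + "\n"
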