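"""Group-level inference for decoding accuracies, signal change and behavior.

Per-cell decoding accuracies are tested across participants with a
two-tailed one-sample t-test against the 50% chance level; multiple
comparisons are handled with Benjamini-Hochberg false-discovery-rate
control at q = 0.05.  By default one FDR family spans all cells of one
analysis kind (the number of ROIs times the number of tests performed with
them); a per-(phase, analysis) family is available for figure-panel-style
correction.  Percent-signal-change values are tested against zero, and
behavioral judgment accuracy excludes unanswered trials from the
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

DEFAULT_ALPHA = 0.05
DEFAULT_Q = 0.05
DEFAULT_CHANCE = 0.5
#: Group PSC significance threshold (the univariate analysis uses a much
#: stricter printed threshold than the decoding tests).
DEFAULT_PSC_ALPHA = 0.0005


class StatsError(ValueError):
    """Raised for undefined statistical requests."""


def group_ttest(values: Sequence[float], null_mean: float) -> tuple[float, float, int]:
    """Two-tailed one-sample t-test of *values* against *null_mean*.

    Returns ``(t, p, df)`` with ``df = n - 1``.  A zero-variance sample is
    degenerate: if its mean equals the null the test is trivially null
    (t = 0, p = 1); otherwise t is undefined and an error is raised.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise StatsError("group_ttest needs at least 2 values")
    if not np.all(np.isfinite(x)):
        raise StatsError("group_ttest values must be finite")
    n = x.size
    mean = x.mean()
    sd = x.std(ddof=1)
    if sd == 0:
        if mean == null_mean:
            return 0.0, 1.0, n - 1
        raise StatsError("zero variance with mean != null_mean: t undefined")
    t = (mean - null_mean) / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return float(t), float(p), n - 1


def fdr_bh(p_values: Sequence[float], q: float = DEFAULT_Q
           ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure at level ``q``.

    Returns ``(significant flags, adjusted p-values)``; adjusted values are
    monotone in rank.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise StatsError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


@dataclass
class GroupStats:
    """Group-level summary of one cell (ROI x analysis identifiers)."""

    roi_name: str
    analysis: str
    phase: str
    condition: str
    n: int
    mean: float
    t: float
    p: float
    significant_uncorrected: bool
    p_adjusted: float = float("nan")
    significant_fdr: bool = False


def group_accuracy_table(accuracies: pd.DataFrame, *,
                         chance: float = DEFAULT_CHANCE,
                         alpha: float = DEFAULT_ALPHA,
                         q: float = DEFAULT_Q,
                         fdr_family: str = "analysis") -> pd.DataFrame:
    """Group statistics for a tidy per-participant accuracy table.

    ``accuracies`` needs columns ``participant, roi, analysis, phase,
    condition, accuracy``.  Each (analysis, phase, condition, roi) cell is
    t-tested across participants against ``chance``; FDR correction is
    applied within families given by ``fdr_family``: ``"analysis"`` (all
    cells of one analysis kind jointly, the default) or ``"panel"``
    (one family per analysis x phase).

    A cell in which every participant reaches the same accuracy away from
    chance (a saturated decoder) is reported with ``t = +/-inf, p = 0``.
    """
    rows = []
    keys = ["analysis", "phase", "condition", "roi"]
    for (analysis, phase, condition, roi), grp in accuracies.groupby(keys, sort=True):
        vals = grp["accuracy"].to_numpy(float)
        try:
            t, p, _df = group_ttest(vals, chance)
        except StatsError:
            t = np.inf if vals.mean() > chance else -np.inf
            p = 0.0
        rows.append({"analysis": analysis, "phase": phase, "condition": condition,
                     "roi": roi, "n": vals.size, "mean": vals.mean(), "t": t, "p": p})
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["significant_uncorrected"] = table["p"] < alpha
    if fdr_family == "analysis":
        family_cols = ["analysis"]
    elif fdr_family == "panel":
        family_cols = ["analysis", "phase"]
    else:
        raise StatsError(f"unknown fdr_family {fdr_family!r}")
    table["p_adjusted"] = np.nan
    table["significant_fdr"] = False
    for _, idx in table.groupby(family_cols).groups.items():
        reject, p_adj = fdr_bh(table.loc[idx, "p"].to_numpy(), q)
        table.loc[idx, "p_adjusted"] = p_adj
        table.loc[idx, "significant_fdr"] = reject
    return table


def psc_group_test(psc_values: Sequence[float], *, roi_name: str = "",
                   contrast: str = "", alpha: float = DEFAULT_PSC_ALPHA) -> GroupStats:
    """One-sample t-test of per-participant percent signal change against 0."""
    vals = np.asarray(psc_values, dtype=float)
    t, p, _df = group_ttest(vals, 0.0)
    return GroupStats(roi_name, "psc", "", contrast, vals.size, float(vals.mean()),
                      t, p, p < alpha)


def behavioral_accuracy(responses: pd.DataFrame) -> pd.Series:
    """Proportion of correct orientation judgments per participant.

    Unanswered trials (``correct`` missing) are excluded from the
    denominator; a participant with no answered trials is reported missing.
    """
    if "participant" not in responses or "correct" not in responses:
        raise StatsError("responses need 'participant' and 'correct' columns")

    def _acc(grp: pd.DataFrame) -> float:
        answered = grp["correct"].dropna()
        if answered.empty:
            return np.nan
        return float(answered.mean())

    return responses.groupby("participant").apply(_acc, include_groups=False)
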