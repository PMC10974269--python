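"""Dyad-level task comparison: one-sided rank-sum grid with Bonferroni control.

Per-window mean normalized bispectrum values from two task conditions
(collaboration vs competition) are compared per dyad, band and channel
combination with the two-sample Wilcoxon rank sum (Mann-Whitney) test — the
samples are unpaired window populations, not paired differences. Both tails
are computed for every cell; with d dyads, b bands and c combinations the
family holds m = d*b*c cells per tail and a cell is flagged significant when
its p-value falls below the Bonferroni-corrected level alpha/m.

The p-value is exact (full enumeration of rankings) when the combined sample
size is at most 12 and tie-free, and otherwise uses the normal approximation
with mid-rank tie correction and continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from .errors import B2BError, IncompleteDyadError, InsufficientDataError

#: Combined-sample-size cutoff below which the exact null distribution is used.
EXACT_MAX_N = 12


@dataclass
class TaskSeries:
    """Per-window band/combination values for one dyad under one task label."""

    dyad_id: str
    task: str
    data: dict[tuple[str, str], np.ndarray]  # (band, combination) -> values

    def __post_init__(self) -> None:
        for key, v in self.data.items():
            if len(v) == 0:
                raise InsufficientDataError(
                    f"dyad {self.dyad_id} task {self.task}: empty series for {key}"
                )

    @property
    def keys(self) -> set[tuple[str, str]]:
        return set(self.data)


def rank_sum_one_sided(x: np.ndarray, y: np.ndarray, tail: str) -> float:
    """One-sided Wilcoxon rank sum (Mann-Whitney) p-value.

    ``tail="right"`` tests whether x is stochastically greater than y,
    ``tail="left"`` the reverse. Exact when len(x)+len(y) <= 12 without ties;
    normal approximation with tie and continuity corrections otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InsufficientDataError("rank sum test requires non-empty samples")
    if tail not in ("right", "left"):
        raise ValueError(f"tail must be 'right' or 'left', got {tail!r}")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= EXACT_MAX_N and tie_free) else "asymptotic"
    alternative = "greater" if tail == "right" else "less"
    res = scipy.stats.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    return float(res.pvalue)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test level alpha/m controlling the family-wise error rate."""
    if not 0 < alpha < 1:
        raise B2BError(f"alpha must lie in (0, 1), got {alpha}")
    if m < 1:
        raise B2BError(f"test count m must be >= 1, got {m}")
    return alpha / m


@dataclass
class ComparisonGrid:
    """dyad x band x combination grid of one-sided p-values with flags.

    ``table`` columns: dyad, band, combination, p_right, p_left, sig_right,
    sig_left. The right tail tests collaboration > competition.
    """

    table: pd.DataFrame
    alpha: float
    m: int
    threshold: float

    def fraction_significant(self, tail: str) -> float:
        col = {"right": "sig_right", "left": "sig_left"}[tail]
        return float(self.table[col].sum()) / self.m

    def n_significant(self, tail: str) -> int:
        col = {"right": "sig_right", "left": "sig_left"}[tail]
        return int(self.table[col].sum())

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False, float_format="%.10g")


def compare_tasks(
    pairs: list[tuple[TaskSeries, TaskSeries]], alpha: float = 0.05
) -> ComparisonGrid:
    """Build the comparison grid from (first-task, second-task) series pairs.

    The first series of each pair is the x sample (collaboration in the
    reference protocol); p_right small means x stochastically greater. All
    dyads must share one (band, combination) key set; rows are emitted
    sorted by (dyad, band, combination) so the grid is invariant to the
    order dyads are supplied in.
    """
    if not pairs:
        raise IncompleteDyadError("no dyads supplied")
    rows = []
    key_sets = set()
    for first, second in pairs:
        if first.dyad_id != second.dyad_id:
            raise IncompleteDyadError(
                f"pair mixes dyads {first.dyad_id!r} and {second.dyad_id!r}"
            )
        if first.keys != second.keys:
            missing = first.keys ^ second.keys
            raise IncompleteDyadError(
                f"dyad {first.dyad_id}: tasks disagree on cells {sorted(missing)}"
            )
        key_sets.add(frozenset(first.keys))
        for band, combo in sorted(first.keys):
            x, y = first.data[(band, combo)], second.data[(band, combo)]
            rows.append(
                {
                    "dyad": first.dyad_id,
                    "band": band,
                    "combination": combo,
                    "p_right": rank_sum_one_sided(x, y, "right"),
                    "p_left": rank_sum_one_sided(x, y, "left"),
                }
            )
    if len(key_sets) > 1:
        raise IncompleteDyadError("dyads have differing (band, combination) grids")
    table = (
        pd.DataFrame(rows)
        .sort_values(["dyad", "band", "combination"])
        .reset_index(drop=True)
    )
    m = len(table)
    threshold = bonferroni_threshold(alpha, m)
    table["sig_right"] = table["p_right"] < threshold
    table["sig_left"] = table["p_left"] < threshold
    return ComparisonGrid(table=table, alpha=alpha, m=m, threshold=threshold)


# -- adapters from session outputs -----------------------------------------


def task_series_from_bands(
    bands: pd.DataFrame, dyad_id: str, task: str
) -> TaskSeries:
    """Build a TaskSeries from a band-summary table (bands.csv layout)."""
    required = {"window_index", "band", "combination", "value"}
    if not required <= set(bands.columns):
        raise B2BError(
            f"band summary table missing columns {sorted(required - set(bands.columns))}"
        )
    data = {}
    for (band, combo), grp in bands.groupby(["band", "combination"], sort=True):
        data[(str(band), str(combo))] = grp.sort_values("window_index")[
            "value"
        ].to_numpy()
    return TaskSeries(dyad_id=dyad_id, task=task, data=data)


def task_series_from_session_dir(
    session_dir: str | Path, dyad_id: str, task: str
) -> TaskSeries:
    """Read bands.csv from a session output directory."""
    path = Path(session_dir) / "bands.csv"
    if not path.exists():
        raise B2BError(f"no bands.csv in session directory {session_dir}")
    return task_series_from_bands(pd.read_csv(path), dyad_id, task)


def task_series_from_record(
    record, dyad_id: str, segments: list[tuple[str, float, float]]
) -> dict[str, TaskSeries]:
    """Split one session's band summaries into per-task series by start time.

    ``segments`` is a list of (label, start_s, end_s); a task window belongs
    to the segment containing its start time. Returns label -> TaskSeries
    (labels with no windows are omitted).
    """
    from .session import band_summary_frame  # local import avoids a cycle

    frame = band_summary_frame(record.band_summaries)
    out = {}
    for label, start, end in segments:
        sub = frame[(frame["start_time_s"] >= start) & (frame["start_time_s"] < end)]
        if len(sub):
            out[label] = task_series_from_bands(sub, dyad_id, label)
    return out
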