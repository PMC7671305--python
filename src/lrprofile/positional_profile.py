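"""Sliding-window error-rate distributions along reads.

Every alignment column is assigned to a 1-based read position (in original
read orientation).  Deletion columns carry no read base, so each one
inherits the read position of the next non-deletion column in the script
(or the previous one when the deletion is terminal).  Window rates are
computed per read and then averaged across reads, with the sample standard
deviation reported per window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .io_formats import EditScript

logger = logging.getLogger(__name__)

__all__ = [
    "WindowGrid",
    "WindowStat",
    "WindowDistribution",
    "assign_read_positions",
    "per_read_window_rates",
    "window_distribution",
    "distribution_to_tsv",
]

ERROR_TYPES = ("sub", "ins", "del")


@dataclass(frozen=True)
class WindowGrid:
    """Overlapping window layout over read positions 1..region_end."""

    window_length: int = 1000
    step: int = 500
    region_end: int = 7500
    min_read_length: int = 7500

    def __post_init__(self) -> None:
        if not (0 < self.step <= self.window_length <= self.region_end):
            raise ValueError("require 0 < step <= window_length <= region_end")

    def windows(self) -> list[tuple[int, int]]:
        """Inclusive (start, end) pairs: starts 1, 1+step, ... while the
        window still fits inside region_end."""
        out = []
        start = 1
        while start + self.window_length - 1 <= self.region_end:
            out.append((start, start + self.window_length - 1))
            start += self.step
        return out


def assign_read_positions(script: EditScript) -> np.ndarray:
    """Read position (original orientation) assigned to every column.

    Non-deletion columns use their own ``read_pos``; deletion columns take
    the position of the next non-deletion column in script order, falling
    back to the previous one for a terminal deletion run.
    """
    n = len(script.columns)
    pos = np.empty(n, dtype=np.int64)
    pending: list[int] = []
    last = -1
    for idx, col in enumerate(script.columns):
        if col.op == "del":
            pending.append(idx)
        else:
            for j in pending:
                pos[j] = col.read_pos
            pending.clear()
            pos[idx] = col.read_pos
            last = col.read_pos
    if pending:
        if last < 0:
            raise ValueError(f"{script.read_name}: deletion-only edit script")
        for j in pending:
            pos[j] = last
    return pos


def per_read_window_rates(
    script: EditScript, grid: WindowGrid
) -> dict[str, np.ndarray]:
    """Per-window rates (percent) of each error type for one read.

    The rate of a type in a window is the number of that type's columns
    assigned to the window divided by *all* columns assigned to the window.
    Windows with no assigned columns yield NaN.
    """
    pos = assign_read_positions(script)
    ops = np.array([c.op for c in script.columns])
    windows = grid.windows()
    totals = np.zeros(len(windows))
    per_type = {t: np.zeros(len(windows)) for t in ERROR_TYPES}
    for w, (start, end) in enumerate(windows):
        in_win = (pos >= start) & (pos <= end)
        totals[w] = in_win.sum()
        for t in ERROR_TYPES:
            per_type[t][w] = np.count_nonzero(in_win & (ops == t))
    with np.errstate(invalid="ignore", divide="ignore"):
        return {
            t: np.where(totals > 0, 100.0 * per_type[t] / totals, np.nan)
            for t in ERROR_TYPES
        }


@dataclass
class WindowStat:
    window_start: int
    window_end: int
    n_reads: int
    mean_pct: float
    stddev_pct: Optional[float]


@dataclass
class WindowDistribution:
    """Mean +/- sample stddev of per-read window rates, per error type."""

    grid: WindowGrid
    per_type: dict[str, list[WindowStat]] = field(default_factory=dict)
    n_reads: int = 0
    n_skipped_short: int = 0


def window_distribution(
    scripts: Iterable[EditScript], grid: Optional[WindowGrid] = None
) -> WindowDistribution:
    """Aggregate per-read window rates over a read set.

    Reads shorter than ``grid.min_read_length`` are filtered (tallied in
    ``n_skipped_short``).  Standard deviations use the n-1 denominator and
    are None when fewer than two reads qualify.
    """
    if grid is None:
        grid = WindowGrid()
    rates: dict[str, list[np.ndarray]] = {t: [] for t in ERROR_TYPES}
    n_reads = 0
    n_skipped = 0
    for script in scripts:
        if script.read_length < grid.min_read_length:
            n_skipped += 1
            continue
        per_read = per_read_window_rates(script, grid)
        for t in ERROR_TYPES:
            rates[t].append(per_read[t])
        n_reads += 1

    dist = WindowDistribution(grid=grid, n_reads=n_reads, n_skipped_short=n_skipped)
    windows = grid.windows()
    if n_reads == 0:
        logger.warning("no reads of length >= %d; empty distribution", grid.min_read_length)
        for t in ERROR_TYPES:
            dist.per_type[t] = [
                WindowStat(s, e, 0, float("nan"), None) for s, e in windows
            ]
        return dist
    if n_reads < 2:
        logger.warning("fewer than 2 qualifying reads; stddev unavailable")
    for t in ERROR_TYPES:
        mat = np.vstack(rates[t])  # n_reads x n_windows
        means = np.nanmean(mat, axis=0)
        stds = np.nanstd(mat, axis=0, ddof=1) if n_reads >= 2 else None
        dist.per_type[t] = [
            WindowStat(
                s,
                e,
                n_reads,
                float(means[w]),
                float(stds[w]) if stds is not None else None,
            )
            for w, (s, e) in enumerate(windows)
        ]
    return dist


def distribution_to_tsv(label: str, dist: WindowDistribution) -> str:
    lines = ["dataset\terror_type\twindow_start\twindow_end\tn_reads\tmean_pct\tstddev_pct"]
    for t in ERROR_TYPES:
        for ws in dist.per_type[t]:
            std = "NA" if ws.stddev_pct is None else f"{ws.stddev_pct:.4f}"
            lines.append(
                f"{label}\t{t}\t{ws.window_start}\t{ws.window_end}\t"
                f"{ws.n_reads}\t{ws.mean_pct:.4f}\t{std}"
            )
    return "\n".join(lines) + "\n"
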