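"""Error decomposition of edit scripts and read-set level aggregation.

Rates are *pooled*: percentages are computed from summed column counts over
the whole read set, with the total number of alignment columns
(match + sub + ins + del + ambiguous) as the denominator, so the per-type
percentages add up to the total error percentage by construction.

Columns touching an N base (on either side) are tallied as ``ambiguous``
and excluded from the error classes; they still occupy a column and break
perfect-match runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .io_formats import EditScript

logger = logging.getLogger(__name__)

__all__ = [
    "ErrorCounts",
    "ErrorProfile",
    "SubstitutionMatrix",
    "count_errors",
    "longest_perfect_run",
    "aggregate_profile",
    "substitution_matrix",
    "profiles_to_tsv",
    "profile_to_json",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def _is_ambiguous(col) -> bool:
    return col.ref_base == "N" or col.read_base == "N"


@dataclass
class ErrorCounts:
    """Per-column tallies for one or more alignments."""

    n_match: int = 0
    n_sub: int = 0
    n_ins: int = 0
    n_del: int = 0
    n_ambiguous: int = 0

    @property
    def n_columns(self) -> int:
        return self.n_match + self.n_sub + self.n_ins + self.n_del + self.n_ambiguous

    def __add__(self, other: "ErrorCounts") -> "ErrorCounts":
        return ErrorCounts(
            self.n_match + other.n_match,
            self.n_sub + other.n_sub,
            self.n_ins + other.n_ins,
            self.n_del + other.n_del,
            self.n_ambiguous + other.n_ambiguous,
        )

    def __iadd__(self, other: "ErrorCounts") -> "ErrorCounts":
        self.n_match += other.n_match
        self.n_sub += other.n_sub
        self.n_ins += other.n_ins
        self.n_del += other.n_del
        self.n_ambiguous += other.n_ambiguous
        return self


def count_errors(script: EditScript) -> ErrorCounts:
    """Classify every column of ``script`` exactly once."""
    c = ErrorCounts()
    for col in script.columns:
        if _is_ambiguous(col):
            c.n_ambiguous += 1
        elif col.op == "match":
            c.n_match += 1
        elif col.op == "sub":
            c.n_sub += 1
        elif col.op == "ins":
            c.n_ins += 1
        elif col.op == "del":
            c.n_del += 1
        else:  # pragma: no cover - EditScript enforces the op domain
            raise ValueError(f"unknown op {col.op!r}")
    return c


def longest_perfect_run(script: EditScript) -> int:
    """Length of the longest contiguous run of unambiguous match columns."""
    best = run = 0
    for col in script.columns:
        if col.op == "match" and not _is_ambiguous(col):
            run += 1
            if run > best:
                best = run
        else:
            run = 0
    return best


@dataclass
class ErrorProfile:
    """Pooled error metrics for one read set (one row of a report table)."""

    n_reads_total: int
    n_reads_aligned: int
    counts: ErrorCounts
    aligned_pct: Optional[float]
    sub_pct: Optional[float]
    ins_pct: Optional[float]
    del_pct: Optional[float]
    total_pct: Optional[float]
    longest_perfect_match: int
    longest_alignment: int
    max_stretch_pct: Optional[float]


def aggregate_profile(
    scripts: Iterable[EditScript],
    n_reads_total: int,
    n_reads_aligned: Optional[int] = None,
) -> ErrorProfile:
    """Pool edit scripts into an :class:`ErrorProfile`.

    ``n_reads_aligned`` defaults to the number of scripts (one primary
    alignment per aligned read); pass it explicitly when that does not hold.
    Rates are pooled counts over the whole set, not means of per-read rates.
    """
    totals = ErrorCounts()
    n_scripts = 0
    longest_match = 0
    longest_aln = 0
    stretch_pct: Optional[float] = None
    for script in scripts:
        n_scripts += 1
        totals += count_errors(script)
        run = longest_perfect_run(script)
        if run > longest_match:
            longest_match = run
        if script.ref_span > longest_aln:
            longest_aln = script.ref_span
            if script.read_span > 0:
                stretch_pct = 100.0 * (script.ref_span - script.read_span) / script.read_span
    if n_reads_aligned is None:
        n_reads_aligned = n_scripts

    if totals.n_columns == 0:
        logger.warning("no aligned columns; returning empty profile")
        return ErrorProfile(
            n_reads_total=n_reads_total,
            n_reads_aligned=n_reads_aligned,
            counts=totals,
            aligned_pct=(100.0 * n_reads_aligned / n_reads_total) if n_reads_total else None,
            sub_pct=None,
            ins_pct=None,
            del_pct=None,
            total_pct=None,
            longest_perfect_match=0,
            longest_alignment=0,
            max_stretch_pct=None,
        )

    denom = totals.n_columns
    sub_pct = 100.0 * totals.n_sub / denom
    ins_pct = 100.0 * totals.n_ins / denom
    del_pct = 100.0 * totals.n_del / denom
    return ErrorProfile(
        n_reads_total=n_reads_total,
        n_reads_aligned=n_reads_aligned,
        counts=totals,
        aligned_pct=(100.0 * n_reads_aligned / n_reads_total) if n_reads_total else None,
        sub_pct=sub_pct,
        ins_pct=ins_pct,
        del_pct=del_pct,
        total_pct=sub_pct + ins_pct + del_pct,
        longest_perfect_match=longest_match,
        longest_alignment=longest_aln,
        max_stretch_pct=stretch_pct,
    )


@dataclass
class SubstitutionMatrix:
    """4x4 (ref base x read base) counts over aligned columns.

    The diagonal holds match counts.  ``rate(X, Y)`` is the conditional rate
    count(X->Y) / (aligned columns with reference base X).  Transition and
    transversion rates are pooled over all aligned columns.
    """

    counts: np.ndarray  # shape (4, 4), int64, ACGT order

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4, 4):
            raise ValueError("substitution matrix must be 4x4")

    @property
    def rates(self) -> np.ndarray:
        """Off-diagonal conditional rates; diagonal entries are zero."""
        row_totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(row_totals > 0, self.counts / row_totals, 0.0)
        np.fill_diagonal(r, 0.0)
        return r

    @property
    def _transition_count(self) -> int:
        i = _BASE_INDEX
        c = self.counts
        return int(
            c[i["A"], i["G"]] + c[i["G"], i["A"]] + c[i["C"], i["T"]] + c[i["T"], i["C"]]
        )

    @property
    def _sub_count(self) -> int:
        return int(self.counts.sum() - np.trace(self.counts))

    @property
    def transition_rate(self) -> float:
        """Pooled A<->G + C<->T rate over all aligned columns."""
        total = int(self.counts.sum())
        return self._transition_count / total if total else 0.0

    @property
    def transversion_rate(self) -> float:
        total = int(self.counts.sum())
        return (self._sub_count - self._transition_count) / total if total else 0.0

    @property
    def transition_share(self) -> Optional[float]:
        """Fraction of substitutions that are transitions (None if no subs)."""
        subs = self._sub_count
        return self._transition_count / subs if subs else None

    def partner_pairs_by_rate(self) -> list[tuple[str, float]]:
        """Unordered base pairs ranked by pooled substitution count, descending."""
        i = _BASE_INDEX
        pairs = []
        for a_idx, a in enumerate(BASES):
            for b in BASES[a_idx + 1 :]:
                n = int(self.counts[i[a], i[b]] + self.counts[i[b], i[a]])
                pairs.append((f"{a}<->{b}", n))
        total = sum(n for _, n in pairs)
        pairs.sort(key=lambda p: (-p[1], p[0]))
        return [(name, n / total if total else 0.0) for name, n in pairs]

    def to_tsv(self) -> str:
        lines = ["\t" + "\t".join(BASES)]
        for a in BASES:
            row = [a] + [str(int(self.counts[_BASE_INDEX[a], _BASE_INDEX[b]])) for b in BASES]
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"


def substitution_matrix(scripts: Iterable[EditScript]) -> SubstitutionMatrix:
    """Accumulate match/sub columns into a :class:`SubstitutionMatrix`.

    Bases are taken as stored in the SAM record, i.e. in reference-forward
    orientation for both strands; N columns are skipped.
    """
    counts = np.zeros((4, 4), dtype=np.int64)
    for script in scripts:
        for col in script.columns:
            if col.op not in ("match", "sub"):
                continue
            ri = _BASE_INDEX.get(col.ref_base)
            qi = _BASE_INDEX.get(col.read_base)
            if ri is None or qi is None:
                continue
            counts[ri, qi] += 1
    return SubstitutionMatrix(counts)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_PROFILE_COLUMNS = [
    "dataset",
    "n_reads",
    "aligned_pct",
    "sub_pct",
    "ins_pct",
    "del_pct",
    "total_pct",
    "longest_perfect_match_bp",
    "longest_alignment_bp",
    "max_stretch_pct",
]


def _fmt(value: Optional[float]) -> str:
    return "NA" if value is None else f"{value:.2f}"


def profiles_to_tsv(profiles: Sequence[tuple[str, ErrorProfile]]) -> str:
    """One row per (label, profile); percentages to two decimals."""
    lines = ["\t".join(_PROFILE_COLUMNS)]
    for label, p in profiles:
        lines.append(
            "\t".join(
                [
                    label,
                    str(p.n_reads_total),
                    _fmt(p.aligned_pct),
                    _fmt(p.sub_pct),
                    _fmt(p.ins_pct),
                    _fmt(p.del_pct),
                    _fmt(p.total_pct),
                    str(p.longest_perfect_match),
                    str(p.longest_alignment),
                    _fmt(p.max_stretch_pct),
                ]
            )
        )
    return "\n".join(lines) + "\n"


def profile_to_json(label: str, profile: ErrorProfile, **extra) -> str:
    """Lossless JSON serialization (raw counts preserved)."""
    payload = {
        "dataset": label,
        "n_reads_total": profile.n_reads_total,
        "n_reads_aligned": profile.n_reads_aligned,
        "aligned_pct": profile.aligned_pct,
        "counts": asdict(profile.counts),
        "n_columns": profile.counts.n_columns,
        "sub_pct": profile.sub_pct,
        "ins_pct": profile.ins_pct,
        "del_pct": profile.del_pct,
        "total_pct": profile.total_pct,
        "longest_perfect_match_bp": profile.longest_perfect_match,
        "longest_alignment_bp": profile.longest_alignment,
        "max_stretch_pct": profile.max_stretch_pct,
    }
    payload.update(extra)
    return json.dumps(payload, indent=2, sort_keys=False) + "\n"
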