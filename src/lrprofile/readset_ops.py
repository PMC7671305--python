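"""Read-set census, length filtering, and seeded coverage downsampling."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_formats import ReadRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ReadSetStats",
    "readset_stats",
    "filter_min_length",
    "exclude_by_name",
    "downsample_to_coverage",
]


@dataclass
class ReadSetStats:
    n_reads: int
    total_bases: int
    mean_length: int  # nearest bp
    max_length: int
    coverage: float  # total_bases / genome_length
    bin_width: int
    histogram: list[tuple[int, int, int]]  # (bin_start, bin_end, count)

    def to_json(self, label: str = "") -> str:
        payload = {
            "dataset": label,
            "n_reads": self.n_reads,
            "total_bases": self.total_bases,
            "mean_length_bp": self.mean_length,
            "max_length_bp": self.max_length,
            "coverage": self.coverage,
        }
        return json.dumps(payload, indent=2) + "\n"

    def histogram_tsv(self) -> str:
        lines = ["bin_start\tbin_end\tcount"]
        for start, end, count in self.histogram:
            lines.append(f"{start}\t{end}\t{count}")
        return "\n".join(lines) + "\n"


def readset_stats(
    reads: Sequence[ReadRecord], genome_length: int, bin_width: int = 1000
) -> ReadSetStats:
    """Census of a read set: counts, lengths, fold coverage, length histogram.

    Histogram bins are ``[i*bin_width, (i+1)*bin_width - 1]``; their counts
    sum to ``n_reads``.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be > 0")
    lengths = np.array([len(r) for r in reads], dtype=np.int64)
    if lengths.size == 0:
        logger.warning("empty read set")
        return ReadSetStats(0, 0, 0, 0, 0.0, bin_width, [])
    total = int(lengths.sum())
    n_bins = int(lengths.max() // bin_width) + 1
    counts = np.bincount(lengths // bin_width, minlength=n_bins)
    histogram = [
        (i * bin_width, (i + 1) * bin_width - 1, int(c)) for i, c in enumerate(counts)
    ]
    return ReadSetStats(
        n_reads=int(lengths.size),
        total_bases=total,
        mean_length=int(round(total / lengths.size)),
        max_length=int(lengths.max()),
        coverage=total / genome_length,
        bin_width=bin_width,
        histogram=histogram,
    )


def filter_min_length(
    reads: Iterable[ReadRecord], min_len: int = 200
) -> list[ReadRecord]:
    """Keep reads strictly longer than ``min_len``; order preserved."""
    reads = list(reads)
    kept = [r for r in reads if len(r) > min_len]
    removed = len(reads) - len(kept)
    if removed:
        logger.info("length filter (> %d bp) removed %d of %d reads", min_len, removed, len(reads))
    if not kept:
        logger.warning("length filter removed every read")
    return kept


def exclude_by_name(
    reads: Iterable[ReadRecord], names: Iterable[str]
) -> list[ReadRecord]:
    """Drop reads whose name appears in ``names`` (e.g. region exclude lists)."""
    names = set(names)
    reads = list(reads)
    kept = [r for r in reads if r.name not in names]
    logger.info("exclude list removed %d of %d reads", len(reads) - len(kept), len(reads))
    return kept


def downsample_to_coverage(
    reads: Sequence[ReadRecord],
    genome_length: int,
    target_cov: float,
    seed: int,
) -> list[ReadRecord]:
    """Seeded downsampling to a target fold coverage.

    Reads are permuted with a seeded generator and taken in permuted order
    until cumulative bases reach ``target_cov * genome_length``; the read
    crossing the threshold is included.  Deterministic for fixed inputs and
    seed.  If total coverage is below target, all reads are returned with a
    warning.
    """
    if target_cov <= 0:
        raise ValueError("target_cov must be > 0")
    target_bases = target_cov * genome_length
    total = sum(len(r) for r in reads)
    if total < target_bases:
        logger.warning(
            "available coverage %.2fx below target %.2fx; returning all reads",
            total / genome_length,
            target_cov,
        )
        return list(reads)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(reads))
    out: list[ReadRecord] = []
    acc = 0
    for i in order:
        out.append(reads[i])
        acc += len(reads[i])
        if acc >= target_bases:
            break
    return out
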