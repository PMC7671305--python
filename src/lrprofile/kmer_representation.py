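"""K-mer counting and over/under-representation statistics.

References are counted circularly (k-mers bridging the end/start of the
linear string included) on both strands, so the table total is exactly
``2 * genome_length`` per sequence.  Read sets are counted as linear
sequences.  The representation difference of a k-mer is the *relative*
frequency difference ``(f_reads - f_ref) / f_ref``; outliers are k-mers
whose difference exceeds three sample standard deviations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .io_formats import revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "KmerCountTable",
    "KmerRepresentationRow",
    "LogoMatrix",
    "count_kmers",
    "representation_diff",
    "rank_represented",
    "logo_matrix",
    "frequency_change",
    "representation_to_tsv",
]

_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i

#: dense count arrays up to 4^10 entries; larger k falls back to a dict
_DENSE_K_MAX = 10


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_to_index(kmer: str) -> int:
    idx = 0
    for b in kmer:
        c = _CODE[ord(b)]
        if c > 3:
            raise ValueError(f"k-mer {kmer!r} contains non-ACGT base")
        idx = idx * 4 + int(c)
    return idx


def index_to_kmer(idx: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[idx % 4])
        idx //= 4
    return "".join(reversed(out))


@dataclass
class KmerCountTable:
    """Counts of all 4^k k-mers from one or more sequences."""

    k: int
    counts: np.ndarray  # dense, length 4^k
    total: int
    source: str  # 'reference_circular' | 'reads_linear' | free-form
    n_skipped: int = 0  # windows containing N

    def count_of(self, kmer: str) -> int:
        return int(self.counts[kmer_to_index(kmer)])

    def frequency_of(self, kmer: str) -> float:
        return self.count_of(kmer) / self.total if self.total else 0.0

    @property
    def frequencies(self) -> np.ndarray:
        if self.total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / self.total


def _scan(codes: np.ndarray, k: int, counts: np.ndarray) -> int:
    """Accumulate k-mer window counts into ``counts``; returns #N-windows."""
    n = len(codes)
    if n < k:
        return 0
    idx = np.zeros(n - k + 1, dtype=np.int64)
    invalid = np.zeros(n - k + 1, dtype=bool)
    for j in range(k):
        window = codes[j : n - k + 1 + j]
        bad = window > 3
        invalid |= bad
        idx = idx * 4 + np.where(bad, 0, window)
    valid = idx[~invalid]
    counts += np.bincount(valid, minlength=len(counts))
    return int(invalid.sum())


def count_kmers(
    seqs: Sequence[str],
    k: int,
    circular: bool = False,
    both_strands: bool = True,
    source: Optional[str] = None,
) -> KmerCountTable:
    """Count k-mers over sequences.

    Circular mode appends the first k-1 bases before scanning, for the
    forward and (when requested) reverse-complement strands independently.
    Windows containing N are skipped and tallied in ``n_skipped``;
    sequences shorter than k contribute nothing.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > _DENSE_K_MAX:
        raise ValueError(f"k > {_DENSE_K_MAX} is not supported by the dense table")
    counts = np.zeros(4**k, dtype=np.int64)
    n_skipped = 0
    for seq in seqs:
        strands = [seq]
        if both_strands:
            strands.append(revcomp(seq))
        for s in strands:
            if circular and len(s) >= 1:
                s = s + s[: k - 1]
            n_skipped += _scan(_encode(s), k, counts)
    if source is None:
        source = "reference_circular" if circular else "reads_linear"
    return KmerCountTable(
        k=k, counts=counts, total=int(counts.sum()), source=source, n_skipped=n_skipped
    )


@dataclass
class KmerRepresentationRow:
    kmer: str
    count_ref: int
    count_reads: int
    f_ref: float
    f_reads: float
    diff: Optional[float]  # (f_reads - f_ref) / f_ref; None when f_ref == 0
    is_homopolymer: bool
    is_outlier: bool = False


def representation_diff(
    ref_table: KmerCountTable, reads_table: KmerCountTable
) -> tuple[list[KmerRepresentationRow], float]:
    """Per-k-mer relative representation difference and its spread.

    Returns one row per k-mer (all 4^k) and ``sigma``, the sample standard
    deviation of the differences over k-mers present in the reference.
    Outlier flags mark |diff| > 3*sigma.
    """
    if ref_table.k != reads_table.k:
        raise ValueError(f"k mismatch: {ref_table.k} vs {reads_table.k}")
    k = ref_table.k
    f_ref = ref_table.frequencies
    f_reads = reads_table.frequencies
    present = ref_table.counts > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        diffs = np.where(present, (f_reads - f_ref) / np.where(present, f_ref, 1.0), np.nan)
    vals = diffs[present]
    sigma = float(np.std(vals, ddof=1)) if vals.size >= 2 else 0.0

    rows: list[KmerRepresentationRow] = []
    for idx in range(4**k):
        kmer = index_to_kmer(idx, k)
        d = float(diffs[idx]) if present[idx] else None
        rows.append(
            KmerRepresentationRow(
                kmer=kmer,
                count_ref=int(ref_table.counts[idx]),
                count_reads=int(reads_table.counts[idx]),
                f_ref=float(f_ref[idx]),
                f_reads=float(f_reads[idx]),
                diff=d,
                is_homopolymer=len(set(kmer)) == 1,
                is_outlier=(d is not None and abs(d) > 3 * sigma),
            )
        )
    return rows, sigma


def rank_represented(
    rows: Iterable[KmerRepresentationRow],
    n: int,
    direction: str = "over",
    exclude_homopolymers: bool = False,
) -> list[KmerRepresentationRow]:
    """Top-n rows by representation difference.

    ``direction='over'`` sorts by diff descending, ``'under'`` ascending;
    ties break lexicographically on the k-mer.  Rows without a defined diff
    are dropped; homopolymers are removed before truncation when requested.
    """
    if direction not in ("over", "under"):
        raise ValueError("direction must be 'over' or 'under'")
    pool = [r for r in rows if r.diff is not None]
    if exclude_homopolymers:
        pool = [r for r in pool if not r.is_homopolymer]
    sign = -1.0 if direction == "over" else 1.0
    pool.sort(key=lambda r: (sign * r.diff, r.kmer))
    if n > len(pool):
        logger.warning("requested top %d but only %d rows available", n, len(pool))
    return pool[:n]


@dataclass
class LogoMatrix:
    """Column-stochastic per-position base frequencies of a k-mer list."""

    matrix: np.ndarray  # shape (4, k), rows A,C,G,T

    @property
    def k(self) -> int:
        return self.matrix.shape[1]

    def to_tsv(self) -> str:
        lines = ["base\t" + "\t".join(f"pos{j + 1}" for j in range(self.k))]
        for i, b in enumerate("ACGT"):
            lines.append(b + "\t" + "\t".join(f"{v:.4f}" for v in self.matrix[i]))
        return "\n".join(lines) + "\n"


def logo_matrix(kmers: Sequence[str]) -> LogoMatrix:
    """Position frequency matrix ('frequency plot' logo) of uniform-length k-mers."""
    if not kmers:
        raise ValueError("empty k-mer list")
    k = len(kmers[0])
    if any(len(km) != k for km in kmers):
        raise ValueError("k-mers must have uniform length")
    mat = np.zeros((4, k))
    for km in kmers:
        codes = _encode(km)
        if (codes > 3).any():
            raise ValueError(f"k-mer {km!r} contains non-ACGT base")
        for j, c in enumerate(codes):
            mat[c, j] += 1
    return LogoMatrix(mat / len(kmers))


@dataclass
class FrequencyChangeRow:
    kmer: str
    diff_raw: Optional[float]
    diff_corrected: Optional[float]
    delta: Optional[float]  # diff_corrected - diff_raw


def frequency_change(
    raw_rows: Sequence[KmerRepresentationRow],
    corrected_rows: Sequence[KmerRepresentationRow],
    top_n: Optional[int] = None,
) -> list[FrequencyChangeRow]:
    """Change in representation difference between two read sets.

    Both row lists must cover the same k-mer universe.  With ``top_n`` the
    result is restricted to the k-mers with the largest |delta| (ties
    lexicographic); otherwise all rows are returned in k-mer order.
    """
    by_kmer = {r.kmer: r for r in corrected_rows}
    if set(by_kmer) != {r.kmer for r in raw_rows}:
        raise ValueError("raw and corrected rows cover different k-mer universes")
    out: list[FrequencyChangeRow] = []
    for raw in raw_rows:
        corr = by_kmer[raw.kmer]
        delta = (
            corr.diff - raw.diff if raw.diff is not None and corr.diff is not None else None
        )
        out.append(FrequencyChangeRow(raw.kmer, raw.diff, corr.diff, delta))
    if top_n is not None:
        defined = [r for r in out if r.delta is not None]
        defined.sort(key=lambda r: (-abs(r.delta), r.kmer))
        out = defined[:top_n]
    return out


def representation_to_tsv(rows: Iterable[KmerRepresentationRow]) -> str:
    lines = ["kmer\tcount_ref\tcount_reads\tf_ref\tf_reads\tdiff\tis_homopolymer\tis_outlier"]
    for r in rows:
        diff = "NA" if r.diff is None else f"{r.diff:.6f}"
        lines.append(
            f"{r.kmer}\t{r.count_ref}\t{r.count_reads}\t{r.f_ref:.6e}\t"
            f"{r.f_reads:.6e}\t{diff}\t{int(r.is_homopolymer)}\t{int(r.is_outlier)}"
        )
    return "\n".join(lines) + "\n"
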