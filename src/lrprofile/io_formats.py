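"""Reading of FASTA/FASTQ/SAM and reconstruction of per-column edit scripts.

The central data structure is :class:`EditScript`: the fully expanded,
per-column description of one read-to-reference alignment, obtained from
CIGAR plus either the MD tag or the reference sequence.  All downstream
error statistics are computed from edit scripts.

Coordinate conventions
----------------------
* Reference positions are 0-based half-open internally (``ref_start``) and
  1-based in :class:`EditColumn.ref_pos`.
* Read positions (:class:`EditColumn.read_pos`) are 1-based in the
  *original read orientation*, i.e. position 1 is the 5' end of the read as
  sequenced.  For reverse-strand alignments the stored-orientation position
  is flipped via ``read_length - pos_stored + 1``.
* Hard-clipped bases count towards ``read_length`` so the flip stays exact.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Optional, Union

import pysam
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ValidationError",
    "ReferenceGenome",
    "ReadRecord",
    "AlignmentRecord",
    "EditColumn",
    "EditScript",
    "SamCounters",
    "read_fasta",
    "read_fastq",
    "write_fastq",
    "parse_alignments",
    "expand_edit_script",
    "revcomp",
]


class FormatError(ValueError):
    """A file or record violates the expected format."""


class ValidationError(ValueError):
    """Internally inconsistent inputs (e.g. MD disagrees with the reference)."""


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# IUPAC ambiguity codes other than N collapse to N (lower case handled by
# upstream uppercasing).
_AMBIG_TO_N = str.maketrans("RYSWKMBDHV", "N" * 10)

_MD_DIALECT = re.compile(r"^[0-9]+(([A-Z]|\^[A-Z]+)[0-9]+)*$")
_MD_TOKEN = re.compile(r"(\d+)|(\^[A-Z]+)|([A-Z])")

#: CIGAR operations that consume query bases.
QUERY_OPS = frozenset("MIS=X")
#: CIGAR operations that consume reference bases.
REF_OPS = frozenset("MD=X")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over ``{A,C,G,T,N}``."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ReferenceGenome:
    """A (possibly circular) reference sequence."""

    name: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"reference {self.name!r} has an empty sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise FormatError(
                f"reference {self.name!r} contains invalid characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def base_at(self, pos: int) -> str:
        """Base at 0-based ``pos``; wraps around for circular genomes."""
        if self.circular:
            return self.sequence[pos % len(self.sequence)]
        return self.sequence[pos]


@dataclass
class ReadRecord:
    """A sequencing read with optional Sanger-scaled qualities."""

    name: str
    sequence: str
    qualities: Optional[str] = None

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise FormatError(
                f"read {self.name!r}: quality length {len(self.qualities)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AlignmentRecord:
    """One mapped SAM record, in stored (reference-forward) orientation.

    ``read_length`` is the full original read length including hard-clipped
    bases; ``seq`` is the sequence exactly as stored in the SAM record
    (reverse-complemented relative to the original read when ``strand`` is
    ``'-'``).
    """

    read_name: str
    read_length: int
    ref_name: str
    ref_start: int
    strand: str  # '+' or '-'
    cigar: list[tuple[str, int]]
    md: Optional[str] = None
    seq: Optional[str] = None
    is_primary: bool = True
    #: reference length from the SAM header; lets wrap-around alignments on
    #: circular genomes report wrapped 1-based positions without the sequence
    ref_length: Optional[int] = None

    def __post_init__(self) -> None:
        if self.ref_start < 0:
            raise FormatError(f"{self.read_name}: negative reference start")
        if self.strand not in "+-":
            raise FormatError(f"{self.read_name}: strand must be '+' or '-'")
        if self.seq is not None:
            qlen = sum(n for op, n in self.cigar if op in QUERY_OPS)
            if qlen != len(self.seq):
                raise FormatError(
                    f"{self.read_name}: CIGAR query length {qlen} != "
                    f"sequence length {len(self.seq)}"
                )


class EditColumn(NamedTuple):
    """One column of an expanded alignment.

    ``read_pos`` is None for deletions, ``ref_pos`` is None for insertions;
    both are 1-based (read positions in original read orientation).
    A NamedTuple rather than a dataclass: edit scripts routinely hold
    millions of columns and construction cost dominates.
    """

    op: str  # 'match' | 'sub' | 'ins' | 'del'
    read_pos: Optional[int]
    ref_pos: Optional[int]
    ref_base: Optional[str]
    read_base: Optional[str]


@dataclass
class EditScript:
    """Per-column expansion of a single alignment."""

    columns: list[EditColumn]
    read_span: int
    ref_span: int
    read_name: str = ""
    read_length: int = 0
    strand: str = "+"

    def __post_init__(self) -> None:
        n_read = n_ref = 0
        for c in self.columns:
            if c.op != "del":
                n_read += 1
            if c.op != "ins":
                n_ref += 1
        if n_read != self.read_span or n_ref != self.ref_span:
            raise ValidationError(
                f"{self.read_name}: span identities violated "
                f"(read {n_read}!={self.read_span}, ref {n_ref}!={self.ref_span})"
            )


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def read_fasta(
    path: Union[str, Path], circular: bool = False
) -> list[ReferenceGenome]:
    """Read a FASTA file into :class:`ReferenceGenome` records.

    Sequences are uppercased; IUPAC ambiguity codes other than N are mapped
    to N with a logged warning.  ``circular`` applies to every record.
    """
    genomes: list[ReferenceGenome] = []
    with open(path) as handle:
        for header, seq in SimpleFastaParser(handle):
            name = header.split()[0] if header.split() else header
            seq = seq.upper()
            mapped = seq.translate(_AMBIG_TO_N)
            n_mapped = sum(1 for a, b in zip(seq, mapped) if a != b)
            if n_mapped:
                logger.warning(
                    "%s: mapped %d IUPAC ambiguity bases to N", name, n_mapped
                )
            genomes.append(ReferenceGenome(name=name, sequence=mapped, circular=circular))
    if not genomes:
        raise FormatError(f"{path}: no FASTA records found")
    return genomes


def read_fastq(path: Union[str, Path]) -> list[ReadRecord]:
    """Read 4-line FASTQ records; names are truncated at the first whitespace."""
    reads: list[ReadRecord] = []
    with open(path) as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                name = title.split()[0]
                reads.append(ReadRecord(name=name, sequence=seq.upper(), qualities=qual))
        except ValueError as exc:  # biopython names the offending record
            raise FormatError(str(exc)) from exc
    return reads


def write_fastq(reads: Iterable[ReadRecord], path: Union[str, Path]) -> None:
    with open(path, "w") as out:
        for r in reads:
            qual = r.qualities if r.qualities is not None else "I" * len(r.sequence)
            out.write(f"@{r.name}\n{r.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------


@dataclass
class SamCounters:
    """Record-level tallies accumulated while parsing a SAM file."""

    n_records: int = 0
    n_unmapped: int = 0
    n_secondary: int = 0
    n_supplementary: int = 0
    n_missing_cigar: int = 0
    n_kept: int = 0
    primary_read_names: set = field(default_factory=set)


_CIGAR_OPS = "MIDNSHP=XB"


def parse_alignments(
    path: Union[str, Path],
    primary_only: bool = True,
    counters: Optional[SamCounters] = None,
) -> Iterator[AlignmentRecord]:
    """Iterate mapped records of a SAM file as :class:`AlignmentRecord`.

    Unmapped records are skipped but counted; with ``primary_only``
    secondary and supplementary records are dropped (and counted).  Mapped
    records without a CIGAR are skipped with a warning.  Pass a
    :class:`SamCounters` to retrieve the tallies.
    """
    if counters is None:
        counters = SamCounters()
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            counters.n_records += 1
            if rec.is_unmapped:
                counters.n_unmapped += 1
                continue
            if rec.is_secondary:
                counters.n_secondary += 1
                if primary_only:
                    continue
            if rec.is_supplementary:
                counters.n_supplementary += 1
                if primary_only:
                    continue
            if rec.cigartuples is None:
                counters.n_missing_cigar += 1
                logger.warning("%s: mapped record without CIGAR, skipped", rec.query_name)
                continue
            cigar = [(_CIGAR_OPS[op], n) for op, n in rec.cigartuples]
            md = rec.get_tag("MD") if rec.has_tag("MD") else None
            seq = rec.query_sequence
            is_primary = not (rec.is_secondary or rec.is_supplementary)
            if is_primary:
                counters.primary_read_names.add(rec.query_name)
            counters.n_kept += 1
            yield AlignmentRecord(
                read_name=rec.query_name,
                read_length=rec.infer_read_length(),
                ref_name=rec.reference_name,
                ref_start=rec.reference_start,
                strand="-" if rec.is_reverse else "+",
                cigar=cigar,
                md=str(md) if md is not None else None,
                seq=seq.upper() if seq else None,
                is_primary=is_primary,
                ref_length=sam.get_reference_length(rec.reference_name),
            )


# ---------------------------------------------------------------------------
# Edit-script expansion
# ---------------------------------------------------------------------------


class _MdStream:
    """Sequential consumer for an MD tag string.

    Yields one reference base classification per aligned (M/=/X) column and
    one reference base per deleted column, enforcing the dialect
    ``[0-9]+(([A-Z]|\\^[A-Z]+)[0-9]+)*``.
    """

    def __init__(self, md: str, context: str = "") -> None:
        if not _MD_DIALECT.match(md):
            raise FormatError(f"{context}: malformed MD tag {md!r}")
        self._events: list[tuple[str, str | int]] = []
        for m in _MD_TOKEN.finditer(md):
            if m.group(1) is not None:
                self._events.append(("run", int(m.group(1))))
            elif m.group(2) is not None:
                self._events.append(("del", m.group(2)[1:]))
            else:
                self._events.append(("sub", m.group(3)))
        self._i = 0
        self._run_left = 0
        self._del_left = ""
        self._context = context

    def _advance(self) -> None:
        while self._run_left == 0 and not self._del_left and self._i < len(self._events):
            kind, val = self._events[self._i]
            self._i += 1
            if kind == "run":
                self._run_left = val  # may be 0
            elif kind == "del":
                self._del_left = val
            else:
                self._pending_sub = val
                return

    _pending_sub: Optional[str] = None

    def next_aligned(self, read_base: str) -> tuple[str, str]:
        """Consume one M-column; returns (op, ref_base)."""
        if self._run_left > 0:
            self._run_left -= 1
            return "match", read_base
        self._pending_sub = None
        self._advance()
        if self._pending_sub is not None:
            return "sub", self._pending_sub
        if self._run_left > 0:
            self._run_left -= 1
            return "match", read_base
        raise FormatError(f"{self._context}: MD tag exhausted before CIGAR")

    def next_deleted(self) -> str:
        """Consume one deleted reference base."""
        if not self._del_left:
            self._pending_sub = None
            self._advance()
            if self._pending_sub is not None or not self._del_left:
                raise FormatError(
                    f"{self._context}: CIGAR deletion not mirrored in MD tag"
                )
        base, self._del_left = self._del_left[0], self._del_left[1:]
        return base

    def finish(self) -> None:
        self._pending_sub = None
        self._advance()
        if self._run_left or self._del_left or self._pending_sub or self._i < len(self._events):
            raise FormatError(f"{self._context}: MD tag longer than CIGAR")


def expand_edit_script(
    aln: AlignmentRecord, ref: Optional[ReferenceGenome] = None
) -> EditScript:
    """Expand CIGAR (+ MD and/or reference) into a per-column edit script.

    At least one of ``aln.md`` and ``ref`` must be available for M columns;
    when both are given they must agree (``ValidationError`` otherwise).
    ``=``/``X`` operators are accepted as pre-split match/sub columns.
    """
    if aln.seq is None:
        raise FormatError(f"{aln.read_name}: sequence required for edit-script expansion")
    md = _MdStream(aln.md, aln.read_name) if aln.md is not None else None
    has_md = md is not None
    has_ref = ref is not None

    columns: list[EditColumn] = []
    q = 0  # index into stored sequence
    r = 0  # reference offset from aln.ref_start
    lead_hard = aln.cigar[0][1] if aln.cigar and aln.cigar[0][0] == "H" else 0
    reverse = aln.strand == "-"
    read_length = aln.read_length
    rps = -1 if reverse else 1  # read-position step per stored base

    # Modulus for reporting wrapped 1-based positions of circular alignments.
    if has_ref:
        mod_len = len(ref) if ref.circular else None
    else:
        mod_len = aln.ref_length

    def read_pos(stored_index: int) -> int:
        pos_stored = stored_index + 1 + lead_hard
        return read_length - pos_stored + 1 if reverse else pos_stored

    def ref_pos(offset: int) -> int:
        pos0 = aln.ref_start + offset
        if mod_len is not None:
            pos0 %= mod_len
        return pos0 + 1

    def ref_base_at(offset: int) -> str:
        pos0 = aln.ref_start + offset
        if not ref.circular and pos0 >= len(ref):
            raise ValidationError(
                f"{aln.read_name}: alignment overruns linear reference {ref.name!r}"
            )
        return ref.base_at(pos0)

    def ref_segment(offset: int, length: int) -> str:
        """Reference bases for offsets [offset, offset+length), with wrap."""
        p0 = aln.ref_start + offset
        L = len(ref)
        if not ref.circular:
            if p0 + length > L:
                raise ValidationError(
                    f"{aln.read_name}: alignment overruns linear reference {ref.name!r}"
                )
            return ref.sequence[p0 : p0 + length]
        p0 %= L
        if p0 + length <= L:
            return ref.sequence[p0 : p0 + length]
        if length <= L:
            return ref.sequence[p0:] + ref.sequence[: p0 + length - L]
        return "".join(ref.base_at(p0 + t) for t in range(length))

    def bulk_match(chunk: int) -> None:
        """Append ``chunk`` match columns taking bases from the stored seq."""
        nonlocal q, r
        seg = aln.seq[q : q + chunk]
        rp0 = read_pos(q)
        p0 = aln.ref_start + r
        if mod_len is not None:
            columns.extend(
                EditColumn("match", rp0 + t * rps, (p0 + t) % mod_len + 1, b, b)
                for t, b in enumerate(seg)
            )
        else:
            columns.extend(
                EditColumn("match", rp0 + t * rps, p0 + t + 1, b, b)
                for t, b in enumerate(seg)
            )
        q += chunk
        r += chunk

    def aligned_column(op: str) -> None:
        """Slow path: classify a single M/=/X column."""
        nonlocal q, r
        read_base = aln.seq[q]
        col_op: Optional[str] = None
        ref_b: Optional[str] = None
        if has_md:
            col_op, ref_b = md.next_aligned(read_base)
        if has_ref:
            rb = ref_base_at(r)
            if has_md and ref_b != rb:
                raise ValidationError(
                    f"{aln.read_name}: MD ref base {ref_b!r} disagrees with "
                    f"reference base {rb!r} at offset {r}"
                )
            ref_b = rb
            col_op = "match" if rb == read_base else "sub"
        if col_op is None:
            # =/X without MD or reference still classify; plain M cannot.
            if op == "=":
                col_op, ref_b = "match", read_base
            elif op == "X":
                col_op, ref_b = "sub", None
            else:
                raise FormatError(
                    f"{aln.read_name}: M columns need an MD tag or a reference"
                )
        elif op == "=" and col_op != "match":
            raise ValidationError(f"{aln.read_name}: '=' column classified as sub")
        elif op == "X" and col_op != "sub":
            raise ValidationError(f"{aln.read_name}: 'X' column classified as match")
        columns.append(EditColumn(col_op, read_pos(q), ref_pos(r), ref_b, read_base))
        q += 1
        r += 1

    for op, n in aln.cigar:
        if op == "S":
            q += n
        elif op == "H":
            pass
        elif op == "M" or op == "=" or op == "X":
            remaining = n
            while remaining:
                if op == "M" and has_md and md._run_left > 0:
                    # Fast path: consume a whole MD match run at once.
                    chunk = min(md._run_left, remaining)
                    if has_ref and ref_segment(r, chunk) != aln.seq[q : q + chunk]:
                        raise ValidationError(
                            f"{aln.read_name}: MD match run disagrees with reference"
                        )
                    md._run_left -= chunk
                    bulk_match(chunk)
                    remaining -= chunk
                elif op == "M" and not has_md and has_ref:
                    # Fast path: bulk-compare against the reference segment.
                    seg = ref_segment(r, remaining)
                    qseg = aln.seq[q : q + remaining]
                    if seg == qseg:
                        bulk_match(remaining)
                        remaining = 0
                    else:
                        first_diff = next(
                            i for i, (a, b) in enumerate(zip(seg, qseg)) if a != b
                        )
                        if first_diff:
                            bulk_match(first_diff)
                            remaining -= first_diff
                        aligned_column(op)
                        remaining -= 1
                else:
                    aligned_column(op)
                    remaining -= 1
        elif op == "I":
            for _ in range(n):
                columns.append(EditColumn("ins", read_pos(q), None, None, aln.seq[q]))
                q += 1
        elif op == "D":
            for _ in range(n):
                if has_md:
                    ref_b = md.next_deleted()
                    if has_ref:
                        rb = ref_base_at(r)
                        if ref_b != rb:
                            raise ValidationError(
                                f"{aln.read_name}: MD deleted base {ref_b!r} disagrees "
                                f"with reference base {rb!r} at offset {r}"
                            )
                elif has_ref:
                    ref_b = ref_base_at(r)
                else:
                    raise FormatError(
                        f"{aln.read_name}: D columns need an MD tag or a reference"
                    )
                columns.append(EditColumn("del", None, ref_pos(r), ref_b, None))
                r += 1
        else:
            raise FormatError(f"{aln.read_name}: unsupported CIGAR operation {op!r}")

    if has_md:
        md.finish()

    read_span = sum(1 for c in columns if c.op in ("match", "sub", "ins"))
    ref_span = sum(1 for c in columns if c.op in ("match", "sub", "del"))
    return EditScript(
        columns=columns,
        read_span=read_span,
        ref_span=ref_span,
        read_name=aln.read_name,
        read_length=read_length,
        strand=aln.strand,
    )
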