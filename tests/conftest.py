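"""Shared fixtures and tiny builders used across the test suite."""

from __future__ import annotations

import pytest

from lrprofile.io_formats import (
    AlignmentRecord,
    EditColumn,
    EditScript,
    ReferenceGenome,
)


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    out = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            out.append((ch, int(num)))
            num = ""
    return out


def make_alignment(
    cigar: str,
    seq: str,
    md: str | None = None,
    strand: str = "+",
    ref_start: int = 0,
    read_length: int | None = None,
    name: str = "r",
    ref_name: str = "g",
    ref_length: int | None = None,
) -> AlignmentRecord:
    ops = parse_cigar(cigar)
    if read_length is None:
        read_length = sum(n for op, n in ops if op in "MIS=XH")
    return AlignmentRecord(
        read_name=name,
        read_length=read_length,
        ref_name=ref_name,
        ref_start=ref_start,
        strand=strand,
        cigar=ops,
        md=md,
        seq=seq,
        is_primary=True,
        ref_length=ref_length,
    )


def match_script(n: int, read_length: int | None = None, base: str = "A") -> EditScript:
    """An all-match script of n columns at read positions 1..n."""
    cols = [EditColumn("match", i + 1, i + 1, base, base) for i in range(n)]
    return EditScript(
        columns=cols,
        read_span=n,
        ref_span=n,
        read_name="perfect",
        read_length=read_length if read_length is not None else n,
    )


def script_from_ops(ops: str, read_length: int | None = None) -> EditScript:
    """Build a script from a compact op string: M=match, S=sub, I=ins, D=del.

    Read and reference positions advance per SAM semantics; bases are
    arbitrary but consistent (ref A, sub read G, ins read C).
    """
    cols = []
    rp = 0
    fp = 0
    for ch in ops:
        if ch == "M":
            rp += 1
            fp += 1
            cols.append(EditColumn("match", rp, fp, "A", "A"))
        elif ch == "S":
            rp += 1
            fp += 1
            cols.append(EditColumn("sub", rp, fp, "A", "G"))
        elif ch == "I":
            rp += 1
            cols.append(EditColumn("ins", rp, None, None, "C"))
        elif ch == "D":
            fp += 1
            cols.append(EditColumn("del", None, fp, "A", None))
        else:
            raise ValueError(ch)
    return EditScript(
        columns=cols,
        read_span=rp,
        ref_span=fp,
        read_name="ops",
        read_length=read_length if read_length is not None else rp,
    )


@pytest.fixture
def toy_genome() -> ReferenceGenome:
    return ReferenceGenome(name="toy", sequence="ACGTACGGTTCA", circular=True)
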