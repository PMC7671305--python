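"""Synthetic genomes and long reads with exact truth alignments.

The generator walks a reference span in *read orientation* (so 5'-end noise
lands on the read's own 5' end regardless of strand) and emits, per
reference position, an optional insertion run before the position, then
either a deletion or a read base (substituted or matching).  The truth
CIGAR and MD tag are constructed alongside, in SAM stored orientation, so
``io_formats.expand_edit_script`` on the truth record reproduces the truth
columns exactly.

Rate calibration
----------------
``p_sub``/``p_ins``/``p_del`` are *per-column* target rates: the expected
fraction of alignment columns of each type.  The internal per-position draw
probabilities are derived from them::

    q_ins = p_ins * (1 - p_ext) / (1 - p_ins)      # insertion event/position
    q_del = p_del / (1 - p_ins)                     # deletion/position
    q_sub = p_sub / (1 - p_ins - p_del)             # substitution | no deletion

so that pooled column rates recovered from the output equal the configured
values in expectation (insertions occupy columns that consume no reference,
which inflates the denominator; a naive draw at the nominal rates would
under-produce every type).  Within the 5'-noise region the *targets* are
multiplied by ``multiplier`` before calibration, making windowed rates in
that region a clean multiple of the plateau.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, TextIO, Union

import numpy as np

from .alignment_errors import ErrorCounts, count_errors
from .io_formats import (
    AlignmentRecord,
    EditColumn,
    EditScript,
    ReadRecord,
    ReferenceGenome,
    revcomp,
)

logger = logging.getLogger(__name__)

__all__ = [
    "HomopolymerModel",
    "FivePrimeNoise",
    "ReadLengthModel",
    "SimulationConfig",
    "SimulatedRead",
    "ont_like",
    "pacbio_like",
    "generate_genome",
    "simulate_read",
    "simulate_readset",
    "write_readset",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class HomopolymerModel:
    """Run-length perturbation of reference homopolymers.

    On entering a reference run of at least ``min_run`` identical bases the
    run length is changed by +1 (probability ``p_expand``, a truth
    insertion of the run base) or -1 (``p_contract``, a truth deletion).
    """

    enabled: bool = False
    min_run: int = 4
    p_expand: float = 0.0
    p_contract: float = 0.0

    def validate(self) -> None:
        if not 0 <= self.p_expand <= 1 or not 0 <= self.p_contract <= 1:
            raise ValueError("homopolymer probabilities must be in [0, 1]")
        if self.p_expand + self.p_contract > 1:
            raise ValueError("p_expand + p_contract must be <= 1")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")


@dataclass(frozen=True)
class FivePrimeNoise:
    """Error-rate multiplier applied to the first ``n5`` emitted read bases."""

    n5: int = 1000
    multiplier: float = 1.0

    def validate(self) -> None:
        if self.multiplier < 1:
            raise ValueError("5' multiplier must be >= 1")
        if self.n5 < 0:
            raise ValueError("n5 must be >= 0")


@dataclass(frozen=True)
class ReadLengthModel:
    """Lognormal read lengths truncated to [min_len, max_len]."""

    mu: float = 9.1
    sigma: float = 0.45
    min_len: int = 500
    max_len: int = 100_000

    def validate(self) -> None:
        if not 1 <= self.min_len <= self.max_len:
            raise ValueError("require 1 <= min_len <= max_len")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def draw(self, rng: np.random.Generator) -> int:
        for _ in range(1000):
            length = int(round(rng.lognormal(self.mu, self.sigma)))
            if self.min_len <= length <= self.max_len:
                return length
        raise RuntimeError("read-length truncation window rejects everything")


def _uniform_sub_pref() -> np.ndarray:
    m = np.full((4, 4), 1.0 / 3.0)
    np.fill_diagonal(m, 0.0)
    return m


@dataclass
class SimulationConfig:
    """Generative error model for long-read simulation.

    ``p_sub``/``p_ins``/``p_del`` are target per-column rates (see module
    docstring); ``sub_pref`` is a row-stochastic 4x4 replacement-base
    distribution with zero diagonal, rows/columns in ACGT order.
    ``p_ins_ext`` is the geometric insertion-extension probability (an
    insertion run has length 1 + Geometric(p_ins_ext)).
    """

    p_sub: float = 0.0
    p_ins: float = 0.0
    p_del: float = 0.0
    sub_pref: np.ndarray = field(default_factory=_uniform_sub_pref)
    ins_base_dist: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    p_ins_ext: float = 0.0
    homopolymer: HomopolymerModel = field(default_factory=HomopolymerModel)
    five_prime: FivePrimeNoise = field(default_factory=FivePrimeNoise)
    read_length: ReadLengthModel = field(default_factory=ReadLengthModel)
    seed: int = 0

    def __post_init__(self) -> None:
        self.sub_pref = np.asarray(self.sub_pref, dtype=float)
        self.ins_base_dist = np.asarray(self.ins_base_dist, dtype=float)
        self.validate()

    def validate(self) -> None:
        for name in ("p_sub", "p_ins", "p_del"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.p_sub + self.p_ins + self.p_del >= 1:
            raise ValueError("p_sub + p_ins + p_del must be < 1")
        if not 0 <= self.p_ins_ext < 1:
            raise ValueError("p_ins_ext must be in [0, 1)")
        if self.sub_pref.shape != (4, 4):
            raise ValueError("sub_pref must be 4x4")
        if np.any(np.diag(self.sub_pref) != 0):
            raise ValueError("sub_pref diagonal must be zero")
        if self.p_sub > 0 and not np.allclose(self.sub_pref.sum(axis=1), 1.0):
            raise ValueError("sub_pref rows must sum to 1")
        if self.ins_base_dist.shape != (4,) or not np.isclose(self.ins_base_dist.sum(), 1.0):
            raise ValueError("ins_base_dist must be a length-4 distribution")
        self.homopolymer.validate()
        self.five_prime.validate()
        self.read_length.validate()
        m = self.five_prime.multiplier
        if m * (self.p_sub + self.p_ins + self.p_del) >= 1:
            raise ValueError("5' multiplier pushes total error rate to >= 1")

    def draw_probs(self, multiplier: float = 1.0) -> tuple[float, float, float]:
        """Calibrated (q_ins, q_del, q_sub) for a given rate multiplier."""
        s = multiplier * self.p_sub
        i = multiplier * self.p_ins
        d = multiplier * self.p_del
        q_ins = i * (1.0 - self.p_ins_ext) / (1.0 - i)
        q_del = d / (1.0 - i)
        q_sub = s / (1.0 - i - d)
        if not (0 <= q_ins < 1 and 0 <= q_del < 1 and 0 <= q_sub < 1):
            raise ValueError("calibrated draw probabilities out of range")
        return q_ins, q_del, q_sub


def _preference_matrix(favored: dict[str, str], weight: float) -> np.ndarray:
    """Row-stochastic matrix putting ``weight`` on each base's favored partner."""
    m = np.zeros((4, 4))
    for a in BASES:
        others = [b for b in BASES if b != a]
        for b in others:
            m[_BASE_INDEX[a], _BASE_INDEX[b]] = (
                weight if favored[a] == b else (1.0 - weight) / 2.0
            )
    return m


def ont_like(seed: int = 0, **overrides) -> SimulationConfig:
    """Nanopore-style preset: ~4% of each error type, transition-heavy
    substitutions (A<->G, C<->T favored), homopolymer model off by default."""
    cfg = SimulationConfig(
        p_sub=0.0433,
        p_ins=0.0369,
        p_del=0.0454,
        sub_pref=_preference_matrix({"A": "G", "G": "A", "C": "T", "T": "C"}, 0.7),
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def pacbio_like(seed: int = 0, **overrides) -> SimulationConfig:
    """PacBio-style preset: insertion-dominated errors, transversion-leaning
    substitutions (A<->C, G<->T favored)."""
    cfg = SimulationConfig(
        p_sub=0.0168,
        p_ins=0.0804,
        p_del=0.0316,
        sub_pref=_preference_matrix({"A": "C", "C": "A", "G": "T", "T": "G"}, 0.7),
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


PRESETS = {"ont-like": ont_like, "pacbio-like": pacbio_like}


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------


def generate_genome(
    length: int,
    gc: float = 0.5,
    seed: int = 0,
    circular: bool = True,
    name: str = "sim_genome",
) -> ReferenceGenome:
    """Random i.i.d. genome with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 <= gc <= 1:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    codes = rng.choice(4, size=length, p=probs)
    seq = "".join(BASES[c] for c in codes)
    return ReferenceGenome(name=name, sequence=seq, circular=circular)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedRead:
    read: ReadRecord
    truth_alignment: AlignmentRecord
    truth_counts: ErrorCounts
    truth_columns: EditScript
    ref_start: int
    strand: str


def _template(genome: ReferenceGenome, start: int, span: int, strand: str) -> str:
    G = len(genome)
    if not 0 <= start < G:
        raise ValueError(f"start {start} outside genome of length {G}")
    if span < 1:
        raise ValueError("span must be >= 1")
    if start + span <= G:
        tmpl = genome.sequence[start : start + span]
    elif genome.circular:
        n_wraps, tail = divmod(start + span, G)
        tmpl = genome.sequence[start:] + genome.sequence * (n_wraps - 1) + genome.sequence[:tail]
    else:
        raise ValueError("span overruns a linear reference")
    return revcomp(tmpl) if strand == "-" else tmpl


def _run_starts(tmpl: str, min_run: int) -> dict[int, str]:
    """Start offsets of homopolymer runs with length >= min_run."""
    out: dict[int, str] = {}
    n = len(tmpl)
    j = 0
    while j < n:
        end = j + 1
        while end < n and tmpl[end] == tmpl[j]:
            end += 1
        if end - j >= min_run:
            out[j] = tmpl[j]
        j = end
    return out


def _draw_from(cum: np.ndarray, u: float) -> int:
    return int(np.searchsorted(cum, u, side="right"))


def simulate_read(
    genome: ReferenceGenome,
    start: int,
    span: int,
    strand: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    name: str = "sim_read",
) -> SimulatedRead:
    """Simulate one read over ``span`` reference bases starting at ``start``.

    The error process runs in read orientation; all truth artifacts (CIGAR,
    MD, edit script) are emitted in SAM stored orientation with read
    positions flipped back to the original read.
    """
    tmpl = _template(genome, start, span, strand)
    G = len(genome)

    q_base = config.draw_probs(1.0)
    m5 = config.five_prime.multiplier
    n5 = config.five_prime.n5 if m5 > 1.0 else 0
    q_noise = config.draw_probs(m5) if n5 else q_base
    p_ext = config.p_ins_ext

    sub_cum = np.cumsum(config.sub_pref, axis=1)
    ins_cum = np.cumsum(config.ins_base_dist)

    hp = config.homopolymer
    runs = _run_starts(tmpl, hp.min_run) if hp.enabled else {}

    u_ins = rng.random(span)
    u_del = rng.random(span)
    u_sub = rng.random(span)
    u_hp = rng.random(span) if runs else None

    # Segments in read orientation.  Match runs stay collapsed so the common
    # case costs O(#error events), not O(span):
    #   ("run", j0, L) | ("sub", j, read_base) | ("del", j) | ("ins", read_base)
    segments: list[tuple] = []
    read_parts: list[str] = []
    e = 0  # read bases emitted so far

    def handle_event(j: int, q_ins: float, q_del: float, q_sub: float) -> None:
        """Full per-position logic for position ``j`` (may still be a match)."""
        nonlocal e
        if u_ins[j] < q_ins:
            while True:
                b = BASES[_draw_from(ins_cum, rng.random())]
                segments.append(("ins", b))
                read_parts.append(b)
                e += 1
                if p_ext <= 0 or rng.random() >= p_ext:
                    break
        forced_del = False
        if j in runs:
            u = u_hp[j]
            if u < hp.p_expand:
                b = runs[j]
                segments.append(("ins", b))
                read_parts.append(b)
                e += 1
            elif u < hp.p_expand + hp.p_contract:
                forced_del = True
        ref_b = tmpl[j]
        if forced_del or u_del[j] < q_del:
            segments.append(("del", j))
        elif u_sub[j] < q_sub and ref_b in _BASE_INDEX:
            b = BASES[_draw_from(sub_cum[_BASE_INDEX[ref_b]], rng.random())]
            segments.append(("sub", j, b))
            read_parts.append(b)
            e += 1
        else:
            if segments and segments[-1][0] == "run" and segments[-1][1] + segments[-1][2] == j:
                segments[-1] = ("run", segments[-1][1], segments[-1][2] + 1)
            else:
                segments.append(("run", j, 1))
            read_parts.append(ref_b)
            e += 1

    # Scalar walk while the 5'-noise multiplier is active (rate depends on
    # the number of emitted read bases), then a vectorized scan of the rest.
    j = 0
    while j < span and e < n5:
        handle_event(j, *q_noise)
        j += 1
    if j < span:
        q_ins, q_del, q_sub = q_base
        event = (u_ins[j:] < q_ins) | (u_del[j:] < q_del) | (u_sub[j:] < q_sub)
        if runs:
            for rj in runs:
                if rj >= j:
                    event[rj - j] = True
        prev = j
        for idx in np.flatnonzero(event):
            pos = j + int(idx)
            if pos > prev:
                segments.append(("run", prev, pos - prev))
                read_parts.append(tmpl[prev:pos])
                e += pos - prev
            handle_event(pos, q_ins, q_del, q_sub)
            prev = pos + 1
        if prev < span:
            segments.append(("run", prev, span - prev))
            read_parts.append(tmpl[prev:span])
            e += span - prev

    read_seq = "".join(read_parts)
    read_length = len(read_seq)
    reverse = strand == "-"
    stored_seq = revcomp(read_seq) if reverse else read_seq

    # Stored (reference-forward) orientation: rebuild columns, CIGAR and MD.
    cigar: list[tuple[str, int]] = []
    md_parts: list[str] = []
    md_run = 0
    columns: list[EditColumn] = []
    q = 0  # stored read index (0-based)

    def add_cigar(cig_op: str, length: int) -> None:
        if cigar and cigar[-1][0] == cig_op:
            cigar[-1] = (cig_op, cigar[-1][1] + length)
        else:
            cigar.append((cig_op, length))

    seg_iter = reversed(segments) if reverse else iter(segments)
    last_was_del = False
    for seg in seg_iter:
        kind = seg[0]
        if kind == "run":
            _, j0, L = seg
            if reverse:
                off0 = span - 1 - (j0 + L - 1)
                bases = revcomp(tmpl[j0 : j0 + L])
            else:
                off0 = j0
                bases = tmpl[j0 : j0 + L]
            add_cigar("M", L)
            md_run += L
            rp0 = read_length - q if reverse else q + 1
            rstep = -1 if reverse else 1
            p0 = start + off0
            columns.extend(
                EditColumn("match", rp0 + t * rstep, (p0 + t) % G + 1, b, b)
                for t, b in enumerate(bases)
            )
            q += L
            last_was_del = False
        elif kind == "sub":
            _, sj, sb = seg
            off = span - 1 - sj if reverse else sj
            rb = tmpl[sj].translate(_COMP) if reverse else tmpl[sj]
            qb = sb.translate(_COMP) if reverse else sb
            add_cigar("M", 1)
            md_parts.append(str(md_run))
            md_parts.append(rb)
            md_run = 0
            read_pos = read_length - q if reverse else q + 1
            columns.append(EditColumn("sub", read_pos, (start + off) % G + 1, rb, qb))
            q += 1
            last_was_del = False
        elif kind == "del":
            _, dj = seg
            off = span - 1 - dj if reverse else dj
            rb = tmpl[dj].translate(_COMP) if reverse else tmpl[dj]
            add_cigar("D", 1)
            if last_was_del:
                md_parts[-1] += rb
            else:
                md_parts.append(str(md_run))
                md_parts.append("^" + rb)
                md_run = 0
            columns.append(EditColumn("del", None, (start + off) % G + 1, rb, None))
            last_was_del = True
        else:  # ins
            _, ib = seg
            qb = ib.translate(_COMP) if reverse else ib
            add_cigar("I", 1)
            read_pos = read_length - q if reverse else q + 1
            columns.append(EditColumn("ins", read_pos, None, None, qb))
            q += 1
            last_was_del = False
    md_parts.append(str(md_run))
    md = "".join(md_parts)

    truth_aln = AlignmentRecord(
        read_name=name,
        read_length=read_length,
        ref_name=genome.name,
        ref_start=start,
        strand=strand,
        cigar=cigar,
        md=md,
        seq=stored_seq,
        is_primary=True,
        ref_length=G,
    )
    script = EditScript(
        columns=columns,
        read_span=read_length,
        ref_span=span,
        read_name=name,
        read_length=read_length,
        strand=strand,
    )
    return SimulatedRead(
        read=ReadRecord(name=name, sequence=read_seq, qualities="I" * read_length),
        truth_alignment=truth_aln,
        truth_counts=count_errors(script),
        truth_columns=script,
        ref_start=start,
        strand=strand,
    )


_COMP = str.maketrans("ACGTN", "TGCAN")


def simulate_readset(
    genome: ReferenceGenome,
    coverage: float,
    config: SimulationConfig,
    name_prefix: str = "sim",
) -> Iterator[SimulatedRead]:
    """Yield simulated reads until cumulative read bases reach
    ``coverage * genome_length``.

    Start positions are uniform over the circle, strands Bernoulli(0.5),
    lengths from the configured distribution.  Deterministic per seed.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    G = len(genome)
    rng = np.random.default_rng(config.seed)
    target = coverage * G
    acc = 0
    i = 0
    while acc < target:
        span = config.read_length.draw(rng)
        start = int(rng.integers(G))
        strand = "+" if rng.random() < 0.5 else "-"
        if not genome.circular and start + span > G:
            span = G - start
        sr = simulate_read(
            genome, start, span, strand, config, rng, name=f"{name_prefix}_{i:06d}"
        )
        acc += len(sr.read)
        i += 1
        yield sr


def write_readset(
    sim_reads: Iterable[SimulatedRead],
    genome: ReferenceGenome,
    config: SimulationConfig,
    fastq: Union[str, TextIO],
    sam: Union[str, TextIO],
    summary: Union[str, TextIO, None] = None,
) -> tuple[int, ErrorCounts]:
    """Stream a simulated read set to FASTQ + truth SAM (+ summary TSV).

    Returns ``(n_reads, pooled_truth_counts)``.  Output is byte-stable for a
    fixed config; the seed is recorded in the SAM header and in each FASTQ
    title line for provenance.
    """

    def _open(x, mode="w"):
        return open(x, mode) if isinstance(x, (str, bytes)) else x

    fq = _open(fastq)
    sm = _open(sam)
    tsv = _open(summary) if summary is not None else None
    own = [h for h, orig in ((fq, fastq), (sm, sam), (tsv, summary)) if h is not orig]

    sm.write("@HD\tVN:1.6\tSO:unknown\n")
    sm.write(f"@SQ\tSN:{genome.name}\tLN:{len(genome)}\n")
    sm.write(f"@PG\tID:lrprofile-simulate\tPN:lrprofile\n")
    sm.write(f"@CO\tseed={config.seed}\n")
    if tsv is not None:
        tsv.write(
            "read\tlength\tstrand\tref_start\tn_match\tn_sub\tn_ins\tn_del\tn_ambiguous\n"
        )

    pooled = ErrorCounts()
    n = 0
    try:
        for sr in sim_reads:
            n += 1
            pooled += sr.truth_counts
            r = sr.read
            fq.write(
                f"@{r.name} ref={genome.name} start={sr.ref_start} "
                f"strand={sr.strand} seed={config.seed}\n"
                f"{r.sequence}\n+\n{r.qualities}\n"
            )
            aln = sr.truth_alignment
            flag = 16 if aln.strand == "-" else 0
            cig = "".join(f"{ln}{op}" for op, ln in aln.cigar)
            c = sr.truth_counts
            nm = c.n_sub + c.n_ins + c.n_del
            sm.write(
                f"{aln.read_name}\t{flag}\t{aln.ref_name}\t{aln.ref_start + 1}\t60\t"
                f"{cig}\t*\t0\t0\t{aln.seq}\t{'I' * len(aln.seq)}\t"
                f"NM:i:{nm}\tMD:Z:{aln.md}\n"
            )
            if tsv is not None:
                tsv.write(
                    f"{r.name}\t{len(r)}\t{sr.strand}\t{sr.ref_start}\t"
                    f"{c.n_match}\t{c.n_sub}\t{c.n_ins}\t{c.n_del}\t{c.n_ambiguous}\n"
                )
    finally:
        for h in own:
            h.close()
    return n, pooled
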