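"""Two-species consensus hybrid sequences.

Each homologous window pair is aligned semi-globally (free end gaps, since
flank truncation can leave the two windows unequally trimmed) and collapsed
to a single consensus string: columns where the two species agree keep the
base, every disagreement - substitution or gap - becomes a lowercase 'n'
(an unknown base).  Per-column source bases are preserved so that primer
design can later place the two-fold IUPAC code covering both species.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align


@dataclass(frozen=True)
class ConsensusColumn:
    base_a: str  # '-' for a gap
    base_b: str
    consensus_char: str


@dataclass(frozen=True)
class ConsensusSequence:
    columns: tuple[ConsensusColumn, ...]
    repeat_span: tuple[int, int]  # consensus coordinates, half-open

    @property
    def sequence(self) -> str:
        return "".join(c.consensus_char for c in self.columns)

    @property
    def n_count(self) -> int:
        return sum(1 for c in self.columns if c.consensus_char == "n")

    def __len__(self) -> int:
        return len(self.columns)


def _semiglobal_aligner(
    match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0
) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap
    al.extend_gap_score = gap
    # free end gaps on both sequences
    al.open_left_insertion_score = 0
    al.extend_left_insertion_score = 0
    al.open_right_insertion_score = 0
    al.extend_right_insertion_score = 0
    al.open_left_deletion_score = 0
    al.extend_left_deletion_score = 0
    al.open_right_deletion_score = 0
    al.extend_right_deletion_score = 0
    return al


def align_global(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> tuple[float, str, str]:
    """Semi-global alignment (free end gaps); returns (score, gapped_a, gapped_b)."""
    if not a or not b:
        raise ValueError("empty sequence")
    al = _semiglobal_aligner(match, mismatch, gap)
    aln = al.align(a, b)[0]
    ga, gb = _gapped(aln, a, b)
    return aln.score, ga, gb


def _gapped(aln, a: str, b: str) -> tuple[str, str]:
    ta, qa = aln.aligned
    pa, pb = [], []
    pos_a = pos_b = 0
    for (ts, te), (qs, qe) in zip(ta, qa):
        if ts > pos_a:
            pa.append(a[pos_a:ts])
            pb.append("-" * (ts - pos_a))
        if qs > pos_b:
            pa.append("-" * (qs - pos_b))
            pb.append(b[pos_b:qs])
        pa.append(a[ts:te])
        pb.append(b[qs:qe])
        pos_a, pos_b = te, qe
    if pos_a < len(a):
        pa.append(a[pos_a:])
        pb.append("-" * (len(a) - pos_a))
    if pos_b < len(b):
        pa.append("-" * (len(b) - pos_b))
        pb.append(b[pos_b:])
    return "".join(pa), "".join(pb)


def build_consensus(
    aligned_a: str, aligned_b: str, repeat_span_a: tuple[int, int]
) -> ConsensusSequence:
    """Collapse a gapped alignment into a consensus hybrid sequence.

    ``repeat_span_a`` gives the repeat tract in ungapped coordinates of
    sequence A; it is mapped through the alignment into consensus
    coordinates (which equal alignment-column coordinates).
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned strings differ in length")
    cols = []
    a_pos = 0
    span_start = span_end = None
    rs, re_ = repeat_span_a
    for i, (x, y) in enumerate(zip(aligned_a, aligned_b)):
        cons = x if (x == y and x != "-") else "n"
        cols.append(ConsensusColumn(x, y, cons))
        if x != "-":
            if a_pos == rs:
                span_start = i
            a_pos += 1
            if a_pos == re_:
                span_end = i + 1
    if span_start is None or span_end is None:
        raise ValueError("repeat_span_a outside aligned sequence A")
    return ConsensusSequence(tuple(cols), (span_start, span_end))


def consensus_of_pair(pair, repeat_span_a: tuple[int, int] | None = None):
    """Convenience: semi-globally align a LocusPair's windows and build the
    consensus, locating the repeat via the window coordinates of locus A."""
    la = pair.locus_a
    if repeat_span_a is None:
        repeat_span_a = (
            la.start - la.window_start,
            la.end - la.window_start,
        )
    _, ga, gb = align_global(la.window, pair.locus_b.window)
    return build_consensus(ga, gb, repeat_span_a)
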