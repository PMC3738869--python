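"""Cross-species pairing of microsatellite windows.

Homology between the flanked repeat windows of the two genomes is scored by
local (Smith-Waterman) alignment under BLAST-like +1/-3 scoring with affine
gaps, converted to a Karlin-Altschul expectation E = K*m*n*exp(-lambda*S).
Retained pairs must meet the E-value threshold (default 1e-59, inclusive:
"E-59 or better"), carry at least ``min_units_both`` uninterrupted repeat
units in BOTH species (default 8), and (by default) share the same motif
class.  Multi-hits are resolved to reciprocal best hits.

The E-value machinery reproduces the thresholding logic of a BLAST search,
not any particular BLAST build: lambda and K are configuration with
documented defaults for the ungapped +1/-3 scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio import Align

from .miner import RepeatLocus


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme plus Karlin-Altschul constants.

    Gap penalties are positive costs in the BLAST convention: a gap of
    length k costs gap_open + k * gap_extend.
    """

    match_score: float = 1.0
    mismatch_score: float = -3.0
    gap_open: float = 5.0
    gap_extend: float = 2.0
    ka_lambda: float = 1.374
    ka_k: float = 0.711
    search_space_mode: str = "pairwise"  # or "database"

    def __post_init__(self):
        if not (self.match_score > 0 > self.mismatch_score):
            raise ValueError("need match_score > 0 > mismatch_score")
        if self.ka_lambda <= 0 or self.ka_k <= 0:
            raise ValueError("Karlin-Altschul constants must be positive")
        if self.search_space_mode not in ("pairwise", "database"):
            raise ValueError("search_space_mode must be pairwise or database")

    def aligner(self, mode: str = "local") -> Align.PairwiseAligner:
        al = Align.PairwiseAligner()
        al.mode = mode
        al.match_score = self.match_score
        al.mismatch_score = self.mismatch_score
        # Biopython charges open on the first gapped position.
        al.open_gap_score = -(self.gap_open + self.gap_extend)
        al.extend_gap_score = -self.gap_extend
        return al


@dataclass(frozen=True)
class PairingConfig:
    e_threshold: float = 1e-59
    min_units_both: int = 8
    require_same_class: bool = True

    def __post_init__(self):
        if self.e_threshold <= 0:
            raise ValueError("e_threshold must be positive")
        if self.min_units_both < 1:
            raise ValueError("min_units_both must be >= 1")


@dataclass(frozen=True)
class LocusPair:
    locus_a: RepeatLocus
    locus_b: RepeatLocus
    aln_score: float
    e_value: float
    aligned_a: str
    aligned_b: str

    @property
    def motif_class(self) -> str:
        return self.locus_a.motif_class


def align_local(
    a: str, b: str, params: AlignmentParams | None = None
) -> tuple[float, str, str]:
    """Optimal local alignment score and one optimal gapped alignment."""
    if not a or not b:
        raise ValueError("empty sequence")
    params = params or AlignmentParams()
    al = params.aligner("local")
    alns = al.align(a, b)
    best = alns[0]
    ga, gb = _gapped_strings(best)
    return best.score, ga, gb


def _gapped_strings(aln) -> tuple[str, str]:
    # Rebuild gapped strings from the aligned-block coordinates.
    a_parts, b_parts = [], []
    (ta, qa) = aln.aligned
    prev_t = prev_q = None
    target = aln.target
    query = aln.query
    for (ts, te), (qs, qe) in zip(ta, qa):
        if prev_t is not None:
            a_parts.append(target[prev_t:ts])
            b_parts.append("-" * (ts - prev_t))
            a_parts.append("-" * (qs - prev_q))
            b_parts.append(query[prev_q:qs])
        a_parts.append(target[ts:te])
        b_parts.append(query[qs:qe])
        prev_t, prev_q = te, qe
    return "".join(a_parts), "".join(b_parts)


def evalue(score: float, m: int, n: int, params: AlignmentParams | None = None) -> float:
    """Karlin-Altschul expectation for a raw score in an m x n search space."""
    if score <= 0:
        raise ValueError("score must be positive")
    if m <= 0 or n <= 0:
        raise ValueError("search space dimensions must be positive")
    params = params or AlignmentParams()
    # exp() underflows for strong scores; work in log space.
    log_e = math.log(params.ka_k) + math.log(m) + math.log(n) - params.ka_lambda * score
    return math.exp(log_e) if log_e > -745 else 0.0


def pair_conserved_loci(
    loci_a: list[RepeatLocus],
    loci_b: list[RepeatLocus],
    params: AlignmentParams | None = None,
    cfg: PairingConfig | None = None,
) -> list[LocusPair]:
    """All-vs-all window comparison, reciprocal-best-hit selection, then the
    conservation filters (E-value, repeat units in both, same class)."""
    params = params or AlignmentParams()
    cfg = cfg or PairingConfig()
    if not loci_a or not loci_b:
        return []
    db_n = sum(len(l.window) for l in loci_b)
    al = params.aligner("local")

    scores: dict[tuple[int, int], tuple[float, float]] = {}
    for i, la in enumerate(loci_a):
        for j, lb in enumerate(loci_b):
            if cfg.require_same_class and la.motif_class != lb.motif_class:
                continue
            s = al.score(la.window, lb.window)
            if s <= 0:
                continue
            m = len(la.window)
            n = len(lb.window) if params.search_space_mode == "pairwise" else db_n
            e = evalue(s, m, n, params)
            if e <= cfg.e_threshold:
                scores[(i, j)] = (s, e)

    def best_for(idx: int, axis: int):
        hits = [(ij, se) for ij, se in scores.items() if ij[axis] == idx]
        if not hits:
            return None
        # higher score first; ties by lexicographic opposing locus id
        hits.sort(
            key=lambda h: (
                -h[1][0],
                (loci_b[h[0][1]] if axis == 0 else loci_a[h[0][0]]).locus_id,
            )
        )
        return hits[0][0]

    pairs: list[LocusPair] = []
    for (i, j), (s, e) in sorted(scores.items()):
        if best_for(i, 0) != (i, j) or best_for(j, 1) != (i, j):
            continue  # not reciprocal best
        la, lb = loci_a[i], loci_b[j]
        if min(la.longest_run, lb.longest_run) < cfg.min_units_both:
            continue
        score, ga, gb = align_local(la.window, lb.window, params)
        pairs.append(
            LocusPair(
                locus_a=la,
                locus_b=lb,
                aln_score=score,
                e_value=e,
                aligned_a=ga,
                aligned_b=gb,
            )
        )
    pairs.sort(key=lambda p: (p.locus_a.seq_id, p.locus_a.start))
    return pairs
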