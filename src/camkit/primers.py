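"""Degenerate cross-species primer design on consensus hybrid sequences.

Candidate primers are enumerated exhaustively over position and length in
the repeat-flanking portions of the consensus, never overlapping the repeat
tract.  At every interspecies mismatch column the two-fold IUPAC code
covering both source bases is emitted; columns where one species has a gap
disqualify the candidate.  Constraints follow standard microsatellite
primer practice: melting temperature 57-63 degC, forward/reverse Tm within
1 degC, at most two degenerate bases per primer and three per pair.

Two melting-temperature quantities are computed:

* ``nominal_tm`` - a nearest-neighbour Tm in which an unknown or degenerate
  position contributes the average over its allowed resolutions (the
  convention primer-design software applies to 'n' bases).
* ``degeneracy_tm_range`` - the min/max deviation of the true Tm from the
  nominal one once each degenerate position is resolved to a concrete base,
  using fixed per-base offsets (defaults: G +2.18, C +0.88, A -0.55,
  T -2.41 degC).  With two fully-unknown positions this spans -4.82 to
  +4.36 degC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

from Bio.SeqUtils import MeltingTemp as _mt

from ._seq import (
    IUPAC_SETS,
    SET_TO_CODE,
    degeneracy,
    degenerate_positions,
    expand_degenerate,
    revcomp,
)
from .consensus import ConsensusSequence

log = logging.getLogger("camkit")


@dataclass(frozen=True)
class DesignConstraints:
    tm_min: float = 57.0
    tm_max: float = 63.0
    max_pair_tm_diff: float = 1.0  # recommended-practice value: 0.5
    max_unknown_per_primer: int = 2
    max_degen_per_pair: int = 3
    primer_len_range: tuple[int, int] = (18, 25)
    product_len_range: tuple[int, int] = (80, 600)
    flank_search: int = 200  # how far from the repeat candidates may start

    def __post_init__(self):
        if self.tm_min >= self.tm_max:
            raise ValueError("tm_min must be below tm_max")
        if min(self.max_unknown_per_primer, self.max_degen_per_pair) < 0:
            raise ValueError("degeneracy budgets must be >= 0")


@dataclass(frozen=True)
class TmOffsets:
    """True-Tm deviation of a resolved base relative to the averaged
    unknown-base Tm, in degC."""

    offset_g: float = 2.18
    offset_c: float = 0.88
    offset_a: float = -0.55
    offset_t: float = -2.41

    def of(self, base: str) -> float:
        return {
            "G": self.offset_g,
            "C": self.offset_c,
            "A": self.offset_a,
            "T": self.offset_t,
        }[base]


@dataclass(frozen=True)
class PrimerPair:
    forward: str
    reverse: str
    dye: str | None = None
    nominal_tm_f: float = 0.0
    nominal_tm_r: float = 0.0
    degeneracy_count_pair: int = 0
    tm_deviation_range_f: tuple[float, float] = (0.0, 0.0)
    tm_deviation_range_r: tuple[float, float] = (0.0, 0.0)
    f_start: int = 0  # consensus coordinate of forward 5' end
    r_end: int = 0  # consensus coordinate one past the reverse primer's site
    identity_per_species: dict = field(default_factory=dict)
    expected_product_len: dict = field(default_factory=dict)
    min_expected_allele: dict = field(default_factory=dict)

    @property
    def consensus_product_len(self) -> int:
        return self.r_end - self.f_start

    @property
    def n_combinations(self) -> int:
        """Concrete forward x reverse sequence combinations after expanding
        every degenerate code (2^d for d two-fold codes)."""
        return degeneracy(self.forward) * degeneracy(self.reverse)


def nominal_tm(
    primer: str,
    na_mM: float = 50.0,
    primer_nM: float = 50.0,
) -> float:
    """Nearest-neighbour melting temperature; degenerate/unknown positions
    contribute the average over all their resolutions."""
    p = primer.upper()
    if len(p) < 8:
        raise ValueError("primer too short for a meaningful Tm (< 8 nt)")
    if not set(p) <= set(IUPAC_SETS):
        raise ValueError(f"invalid characters in primer {primer!r}")
    if degeneracy(p) > 256:
        raise ValueError("too many degenerate positions to enumerate")
    tms = [
        _mt.Tm_NN(s, nn_table=_mt.DNA_NN3, Na=na_mM, dnac1=primer_nM, dnac2=0)
        for s in expand_degenerate(p)
    ]
    return sum(tms) / len(tms)


def degeneracy_tm_range(
    primer: str, offsets: TmOffsets | None = None
) -> tuple[float, float]:
    """Min/max total true-Tm deviation over all resolutions of the
    degenerate/unknown positions; restricted codes only range over their
    allowed bases."""
    offsets = offsets or TmOffsets()
    p = primer.upper()
    if not set(p) <= set(IUPAC_SETS):
        raise ValueError(f"invalid characters in primer {primer!r}")
    lo = hi = 0.0
    for i in degenerate_positions(p):
        devs = [offsets.of(b) for b in IUPAC_SETS[p[i]]]
        lo += min(devs)
        hi += max(devs)
    return (round(lo, 10), round(hi, 10))


def assign_degenerate_codes(
    consensus: ConsensusSequence, window: tuple[int, int]
) -> str:
    """IUPAC primer text for a consensus window: agreements keep the base,
    mismatch columns get the two-fold code covering both species.  Windows
    containing a gap column are rejected, as are windows that overlap the
    repeat tract."""
    s, e = window
    rs, re_ = consensus.repeat_span
    if s < 0 or e > len(consensus) or s >= e:
        raise ValueError("window outside consensus")
    if not (e <= rs or s >= re_):
        raise ValueError("primer window overlaps the repeat tract")
    out = []
    for col in consensus.columns[s:e]:
        if col.base_a == "-" or col.base_b == "-":
            raise ValueError("gap column inside primer window")
        if col.base_a == col.base_b:
            out.append(col.base_a)
        else:
            out.append(SET_TO_CODE[frozenset((col.base_a, col.base_b))])
    return "".join(out)


def _round_half_up(x: float) -> int:
    import math

    return math.floor(x + 0.5)


def primer_species_identity(
    primer: str, species_window: str, binding_site: int | None = None
) -> tuple[int, int]:
    """Percent identity (rounded half-up) and mismatch count of a primer at
    its binding site in one species' sequence.

    A degenerate position matches if the species base is in the code's set.
    If ``binding_site`` is not given the best-matching ungapped offset is
    used; an alignment worse than 60% identity is treated as not found.
    """
    p = primer.upper()
    w = species_window.upper()
    L = len(p)
    if L > len(w):
        raise ValueError("primer longer than species window")
    sets = [IUPAC_SETS[c] for c in p]

    def matches_at(off: int) -> int:
        return sum(1 for k in range(L) if w[off + k] in sets[k])

    if binding_site is None:
        best_off, best_m = None, -1
        for off in range(len(w) - L + 1):
            m = matches_at(off)
            if m > best_m:
                best_off, best_m = off, m
        off, m = best_off, best_m
    else:
        if not (0 <= binding_site <= len(w) - L):
            raise ValueError("binding site outside window")
        off, m = binding_site, matches_at(binding_site)
    pct = 100 * m / L
    if pct < 60:
        raise ValueError("primer binding site not found in species window")
    return _round_half_up(pct), L - m


def _find_exact(pattern: str, text: str) -> list[int]:
    """Degenerate-aware full-match positions of pattern in text."""
    sets = [IUPAC_SETS[c] for c in pattern.upper()]
    L = len(sets)
    hits = []
    for off in range(len(text) - L + 1):
        if all(text[off + k] in sets[k] for k in range(L)):
            hits.append(off)
    return hits


def product_size_prediction(
    forward: str,
    reverse: str,
    species_window: str,
    repeat_struct_len: int,
) -> tuple[int, int]:
    """Expected amplicon length in one species and the minimum expected
    allele size (the product if the annotated repeat structure were fully
    lost: expected length minus the repeat-structure length)."""
    w = species_window.upper()
    f_hits = _find_exact(forward, w)
    r_site = revcomp(reverse)
    r_hits = _find_exact(r_site, w)
    if not f_hits or not r_hits:
        raise ValueError("primer not locatable in species window")
    if len(f_hits) > 1 or len(r_hits) > 1:
        warnings.warn("primer multiply locatable; using outermost sites")
    f = f_hits[0]
    r = max(r_hits)
    if r + len(r_site) <= f:
        raise ValueError("reverse primer site lies before the forward site")
    expected = r + len(r_site) - f
    return expected, expected - repeat_struct_len


def design_pairs(
    consensus: ConsensusSequence,
    constraints: DesignConstraints | None = None,
    offsets: TmOffsets | None = None,
    dye: str | None = None,
    max_results: int = 50,
) -> list[PrimerPair]:
    """Enumerate and rank primer pairs flanking the repeat tract.

    Candidate enumeration is exhaustive over position and length within the
    bounded flank; ranking prefers fewer degenerate bases in the pair, then
    the smaller forward/reverse Tm difference, then the shorter product,
    then the leftmost forward position, deterministically.  Only the
    ``max_results`` best-ranked pairs are materialised.  Returns an empty
    list when no candidate satisfies every constraint.
    """
    cons = constraints or DesignConstraints()
    offsets = offsets or TmOffsets()
    rs, re_ = consensus.repeat_span
    lmin, lmax = cons.primer_len_range

    def candidates(lo: int, hi: int):
        """Feasible single primers fully inside consensus columns [lo, hi)."""
        found = []
        for start in range(max(0, lo), hi):
            for L in range(lmin, lmax + 1):
                if start + L > hi:
                    break
                try:
                    seq = assign_degenerate_codes(consensus, (start, start + L))
                except ValueError:
                    continue
                nd = len(degenerate_positions(seq))
                if nd > cons.max_unknown_per_primer:
                    continue
                # cheap GC-rule prescreen before the NN model; the margins
                # cover the empirical spread between the two estimates on
                # 18-25-mers with a safety buffer
                gc = sum(
                    len(IUPAC_SETS[c] & frozenset("GC")) / len(IUPAC_SETS[c])
                    for c in seq
                )
                rough = 64.9 + 41 * (gc - 16.4) / L
                if not (cons.tm_min - 9 <= rough <= cons.tm_max + 5):
                    continue
                try:
                    tm = nominal_tm(seq)
                except ValueError:
                    continue
                if cons.tm_min <= tm <= cons.tm_max:
                    found.append((start, L, seq, nd, tm))
        return found

    fwd = candidates(rs - cons.flank_search, rs)
    rev_sites = candidates(re_, min(len(consensus), re_ + cons.flank_search))
    if not fwd or not rev_sites:
        side = "forward" if not fwd else "reverse"
        log.info(
            "no feasible %s primer: Tm window %.1f-%.1f, <=%d unknowns, "
            "lengths %d-%d",
            side, cons.tm_min, cons.tm_max,
            cons.max_unknown_per_primer, lmin, lmax,
        )
        return []
    rev_by_tm = sorted(rev_sites, key=lambda c: c[4])
    rev_tms = [c[4] for c in rev_by_tm]

    from bisect import bisect_left, bisect_right

    ranked = []
    for fs, fl, fseq, fnd, ftm in fwd:
        lo = bisect_left(rev_tms, ftm - cons.max_pair_tm_diff)
        hi = bisect_right(rev_tms, ftm + cons.max_pair_tm_diff)
        for rstart, rl, rsite, rnd, rtm in rev_by_tm[lo:hi]:
            # the reverse primer is the reverse complement of its site and
            # shares the duplex Tm computed for the site
            if fnd + rnd > cons.max_degen_per_pair:
                continue
            plen = rstart + rl - fs
            if not (cons.product_len_range[0] <= plen <= cons.product_len_range[1]):
                continue
            ranked.append(
                (fnd + rnd, abs(ftm - rtm), plen, fs, rstart + rl, fseq, rsite, ftm, rtm)
            )
    ranked.sort()
    out = []
    for degen, tmdiff, plen, fs, rend, fseq, rsite, ftm, rtm in ranked[:max_results]:
        rseq = revcomp(rsite)
        out.append(
            PrimerPair(
                forward=fseq,
                reverse=rseq,
                dye=dye,
                nominal_tm_f=ftm,
                nominal_tm_r=rtm,
                degeneracy_count_pair=degen,
                tm_deviation_range_f=degeneracy_tm_range(fseq, offsets),
                tm_deviation_range_r=degeneracy_tm_range(rseq, offsets),
                f_start=fs,
                r_end=rend,
            )
        )
    return out


def annotate_pair(
    pair: PrimerPair,
    species_windows: dict[str, str],
    repeat_struct_lens: dict[str, int],
) -> PrimerPair:
    """Fill per-species identity and product-size predictions for a pair."""
    ident, exp, mins = {}, {}, {}
    for sp, win in species_windows.items():
        fid = primer_species_identity(pair.forward, win)
        w_rc = revcomp(win)
        rid = primer_species_identity(pair.reverse, w_rc)
        ident[sp] = {"forward": fid, "reverse": rid}
        try:
            e, m = product_size_prediction(
                pair.forward, pair.reverse, win, repeat_struct_lens.get(sp, 0)
            )
            exp[sp], mins[sp] = e, m
        except ValueError:
            pass
    return replace(
        pair,
        identity_per_species=ident,
        expected_product_len=exp,
        min_expected_allele=mins,
    )
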