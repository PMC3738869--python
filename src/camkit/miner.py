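"""Dinucleotide microsatellite mining.

Detects dinucleotide repeat tracts in genome sequences under three criteria:
more than a configurable number of repeat units (default >10, i.e. at least
11 consistent units), at least 90% purity, and a minimum tract length of
19 bp.  A fixed-length flank (default 200 bp, truncated at contig ends) is
extracted around every retained tract for downstream homology search.

Purity is defined over a phase-consistent region: consistent bases are those
covered by copies of the seed dimer occurring at a fixed phase (even spacing
from the region start), and purity = consistent bases / region length.
Regions are grown by forward greedy chaining: the next phase-consistent copy
of the dimer is absorbed if and only if the purity of the extended region
stays at or above the threshold; a region always starts and ends on a
consistent dimer.  N bases never match a dimer and therefore count as
impurities and break runs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._seq import normalize, revcomp

#: Canonical motif classes, closed under reverse complement and phase rotation.
MOTIF_CLASSES = ("AT/TA", "CA/GT", "GA/CT", "GC/CG")

HETERODIMERS = tuple(
    a + b for a in "ACGT" for b in "ACGT" if a != b
)  # 12 of them


def canonical_motif_class(dimer: str) -> str:
    """Map a dinucleotide to its canonical class.

    The class is closed under phase rotation (CA = AC) and reverse
    complement (CA = TG), giving four classes: AT/TA, CA/GT, GA/CT, GC/CG.
    Homodimers are rejected (they are mononucleotide runs, not dinucleotide
    motifs), as is anything outside the A/C/G/T alphabet.
    """
    d = dimer.upper()
    if len(d) != 2 or not set(d) <= set("ACGT"):
        raise ValueError(f"not a DNA dinucleotide: {dimer!r}")
    if d[0] == d[1]:
        raise ValueError(f"homodimer {dimer!r} is a mononucleotide motif")
    variants = {d, d[::-1], revcomp(d), revcomp(d)[::-1]}
    for cls in MOTIF_CLASSES:
        if cls[:2] in variants:
            return cls
    raise AssertionError("unreachable: heterodimer outside all classes")


#: dimer -> class lookup for the scan loop
_CLASS_OF = {d: canonical_motif_class(d) for d in HETERODIMERS}


def _dimer_rank(d: str) -> int:
    """Strand-neutral preference between phase-shifted twin candidates of
    the same class: rank 0 for the reverse-complement-closed pair that
    contains the alphabetically first class member.  Because the pairs are
    closed under reverse complement, the preference is identical on both
    strands."""
    members = [x for x in HETERODIMERS if _CLASS_OF[x] == _CLASS_OF[d]]
    first_pair = {min(members), revcomp(min(members))}
    return 0 if d in first_pair else 1


_RANK = {d: _dimer_rank(d) for d in HETERODIMERS}


@dataclass(frozen=True)
class GenomeSequence:
    """One FASTA record: ``species_tag`` labels the genome it came from."""

    species_tag: str
    seq_id: str
    residues: str

    def __post_init__(self):
        object.__setattr__(self, "residues", normalize(self.residues))
        if not self.residues:
            raise ValueError("empty sequence")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class MinerConfig:
    """Mining criteria.

    min_units counts all phase-consistent dimer copies in the region
    (default 11, i.e. "more than ten repeats"); min_region_len is the
    minimum tract length in bp; flank_len is the sequence extracted on
    either side of the tract.
    """

    min_units: int = 11
    min_purity: float = 0.90
    min_region_len: int = 19
    flank_len: int = 200
    allowed_classes: frozenset[str] = frozenset(MOTIF_CLASSES)

    def __post_init__(self):
        if not (0 < self.min_purity <= 1):
            raise ValueError("min_purity must be in (0, 1]")
        if self.flank_len < 0:
            raise ValueError("flank_len must be >= 0")
        if self.min_units < 1:
            raise ValueError("min_units must be >= 1")
        bad = set(self.allowed_classes) - set(MOTIF_CLASSES)
        if bad:
            raise ValueError(f"unknown motif classes: {sorted(bad)}")


@dataclass(frozen=True)
class RepeatLocus:
    """A mined microsatellite tract (0-based half-open coordinates)."""

    species_tag: str
    seq_id: str
    start: int
    end: int
    motif_class: str
    observed_motif: str
    units: int
    purity: float
    longest_run: int
    window: str = ""
    window_start: int = 0
    window_end: int = 0

    @property
    def repeat_struct_len(self) -> int:
        return self.end - self.start

    @property
    def locus_id(self) -> str:
        return f"{self.species_tag}|{self.seq_id}|{self.start}-{self.end}"


def longest_uninterrupted_run(region: str, motif_class: str) -> int:
    """Longest run of consecutive, phase-consistent copies of any dimer
    in the class within ``region``.
    """
    if not region:
        raise ValueError("empty region")
    s = normalize(region)
    dimers = [d for d in HETERODIMERS if _CLASS_OF[d] == motif_class]
    if not dimers:
        raise ValueError(f"unknown motif class {motif_class!r}")
    best = 0
    for d in dimers:
        for i in range(len(s) - 1):
            run = 0
            j = i
            while s[j : j + 2] == d:
                run += 1
                j += 2
            if run > best:
                best = run
    return best


def _chain_positions(pos: np.ndarray, min_purity: float):
    """Regions grown bidirectionally from seed runs of phase-consistent
    dimer positions.

    Seeds are maximal uninterrupted runs; each seed absorbs the nearest
    consistent dimer on either side whenever the extended region's purity
    stays at or above min_purity, iterating to a fixpoint.  The rule is
    symmetric under sequence reversal.  Yields unique (start, end, units).
    """
    n = len(pos)
    if n == 0:
        return
    pos = [int(p) for p in pos]
    # seed runs: maximal stretches of consecutive (step 2) positions
    seeds = []
    i0 = 0
    for i in range(1, n + 1):
        if i == n or pos[i] != pos[i - 1] + 2:
            seeds.append((i0, i - 1))
            i0 = i
    seen = set()
    for lo0, hi0 in seeds:
        lo, hi = lo0, hi0
        units = hi - lo + 1
        while True:
            moved = False
            if hi + 1 < n and 2 * (units + 1) / (pos[hi + 1] + 2 - pos[lo]) >= min_purity:
                hi += 1
                units += 1
                moved = True
            if lo - 1 >= 0 and 2 * (units + 1) / (pos[hi] + 2 - pos[lo - 1]) >= min_purity:
                lo -= 1
                units += 1
                moved = True
            if not moved:
                break
        region = (pos[lo], pos[hi] + 2, units)
        if region not in seen:
            seen.add(region)
            yield region


def find_dinucleotide_repeats(
    genome: GenomeSequence, cfg: MinerConfig | None = None
) -> list[RepeatLocus]:
    """Scan one sequence for dinucleotide microsatellites.

    All 12 heterodimers are scanned at both phases on the forward strand;
    because motif classes are closed under reverse complement, mining the
    reverse complement yields the mirror-image locus set.  Overlapping
    candidates of the same class are merged (best by units, purity, length,
    leftmost); across classes the higher-purity, then longer, then leftmost
    candidate wins.  Output is sorted by (seq_id, start).
    """
    cfg = cfg or MinerConfig()
    s = genome.residues
    n = len(s)
    if n < cfg.min_region_len:
        return []
    arr = np.frombuffer(s.encode(), dtype="S1")
    candidates: list[RepeatLocus] = []
    for d in HETERODIMERS:
        cls = _CLASS_OF[d]
        if cls not in cfg.allowed_classes:
            continue
        m = (arr[:-1] == d[0].encode()) & (arr[1:] == d[1].encode())
        pos = np.nonzero(m)[0]
        if len(pos) < cfg.min_units:
            continue
        for parity in (0, 1):
            pp = pos[pos % 2 == parity]
            for start, end, units in _chain_positions(pp, cfg.min_purity):
                purity = 2 * units / (end - start)
                if (
                    units >= cfg.min_units
                    and purity >= cfg.min_purity
                    and end - start >= cfg.min_region_len
                ):
                    candidates.append(
                        RepeatLocus(
                            species_tag=genome.species_tag,
                            seq_id=genome.seq_id,
                            start=start,
                            end=end,
                            motif_class=cls,
                            observed_motif=d,
                            units=units,
                            purity=purity,
                            longest_run=0,
                        )
                    )
    loci = _resolve_overlaps(candidates)
    out = []
    for loc in sorted(loci, key=lambda l: (l.seq_id, l.start)):
        run = longest_uninterrupted_run(s[loc.start : loc.end], loc.motif_class)
        win, ws, we = _window(s, loc.start, loc.end, cfg.flank_len)
        out.append(
            replace(loc, longest_run=run, window=win, window_start=ws, window_end=we)
        )
    return out


def _resolve_overlaps(cands: list[RepeatLocus]) -> list[RepeatLocus]:
    # same-class merge: best by units desc, purity desc, length desc, leftmost
    by_class: dict[str, list[RepeatLocus]] = {}
    for c in cands:
        by_class.setdefault(c.motif_class, []).append(c)
    survivors: list[RepeatLocus] = []
    for group in by_class.values():
        group.sort(
            key=lambda c: (
                -c.units,
                -c.purity,
                -(c.end - c.start),
                _RANK[c.observed_motif],
                c.start,
            )
        )
        kept: list[RepeatLocus] = []
        for c in group:
            if all(c.end <= k.start or c.start >= k.end for k in kept):
                kept.append(c)
        survivors.extend(kept)
    # cross-class: higher purity, then longer, then leftmost
    survivors.sort(
        key=lambda c: (-c.purity, -(c.end - c.start), c.start, c.motif_class)
    )
    final: list[RepeatLocus] = []
    for c in survivors:
        if all(c.end <= k.start or c.start >= k.end for k in final):
            final.append(c)
    return final


def _window(s: str, start: int, end: int, flank_len: int):
    ws = max(0, start - flank_len)
    we = min(len(s), end + flank_len)
    return s[ws:we], ws, we


def extract_window(
    genome: GenomeSequence, locus: RepeatLocus, flank_len: int = 200
) -> str:
    """Repeat tract plus up to ``flank_len`` bp on each side, truncated at
    sequence ends (truncation is visible via the returned length)."""
    if not (0 <= locus.start < locus.end <= len(genome)):
        raise ValueError(
            f"locus {locus.start}-{locus.end} outside sequence of length {len(genome)}"
        )
    win, _, _ = _window(genome.residues, locus.start, locus.end, flank_len)
    return win
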