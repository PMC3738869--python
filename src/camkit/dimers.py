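"""Primer-dimer and hairpin screening.

Scores the cross-hybridisation potential of two primers as the maximum,
over all ungapped antiparallel offsets, of (matches - mismatches) in the
overlap - a conservative integer score in the style of simple dimer
screens; the default flagging threshold is 7.  Degenerate positions are
scored leniently by default (any resolution may pair; the strict policy
requires every resolution to pair, which for two-fold codes means only
exact one-base complements count).
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seq import COMPLEMENT, IUPAC_SETS, revcomp


@dataclass(frozen=True)
class CheckerConfig:
    threshold_score: int = 7
    degenerate_policy: str = "lenient"  # or "strict"
    min_hairpin_loop: int = 3

    def __post_init__(self):
        if self.threshold_score < 1:
            raise ValueError("threshold_score must be >= 1")
        if self.degenerate_policy not in ("lenient", "strict"):
            raise ValueError("degenerate_policy must be lenient or strict")


@dataclass(frozen=True)
class DimerFlag:
    name1: str
    name2: str
    kind: str  # "dimer" or "hairpin"
    score: int
    offset: int


def _pair_fn(policy: str):
    if policy == "lenient":
        return lambda s1, s2: bool(s1 & s2)
    return lambda s1, s2: s1 == s2 and len(s1) == 1


def _dimer_scan(p1: str, p2: str, cfg: CheckerConfig) -> tuple[int, int]:
    a = p1.upper()
    b = revcomp(p2.upper())
    if min(len(a), len(b)) < 6:
        raise ValueError("primers shorter than 6 nt")
    pair_ok = _pair_fn(cfg.degenerate_policy)
    sa = [IUPAC_SETS[c] for c in a]
    sb = [IUPAC_SETS[c] for c in b]
    best = -min(len(a), len(b))
    best_off = 0
    for off in range(-len(b) + 1, len(a)):
        score = 0
        for i in range(max(0, off), min(len(a), off + len(b))):
            score += 1 if pair_ok(sa[i], sb[i - off]) else -1
        if score > best:
            best, best_off = score, off
    return best, best_off


def dimer_score(p1: str, p2: str, cfg: CheckerConfig | None = None) -> int:
    """Best ungapped (matches - mismatches) of p1 against the reverse
    complement of p2 over all relative offsets.  Symmetric in its
    arguments and never exceeds the shorter primer's length."""
    return _dimer_scan(p1, p2, cfg or CheckerConfig())[0]


def hairpin_score(p: str, cfg: CheckerConfig | None = None) -> int:
    """Best stem score (matches - mismatches) of any self-fold keeping at
    least ``min_hairpin_loop`` unpaired bases in the loop."""
    cfg = cfg or CheckerConfig()
    s = p.upper()
    n = len(s)
    if n < 6:
        raise ValueError("primer shorter than 6 nt")
    pair_ok = _pair_fn(cfg.degenerate_policy)
    sets = [IUPAC_SETS[c] for c in s]
    comp = [IUPAC_SETS[c.translate(COMPLEMENT)] for c in s]
    best = 0
    for i0 in range(n):
        for j0 in range(i0 + cfg.min_hairpin_loop + 1, n):
            score = 0
            i, j = i0, j0
            while j - i - 1 >= cfg.min_hairpin_loop:
                score += 1 if pair_ok(sets[i], comp[j]) else -1
                if score > best:
                    best = score
                i += 1
                j -= 1
    return best


def flag_incompatible(
    primers: dict[str, str], cfg: CheckerConfig | None = None
) -> list[DimerFlag]:
    """Screen a named primer panel for self-dimers, cross-dimers and
    hairpins scoring at or above the threshold."""
    cfg = cfg or CheckerConfig()
    if not primers:
        raise ValueError("empty primer panel")
    names = sorted(primers)
    flags: list[DimerFlag] = []
    for i, n1 in enumerate(names):
        hp = hairpin_score(primers[n1], cfg)
        if hp >= cfg.threshold_score:
            flags.append(DimerFlag(n1, n1, "hairpin", hp, 0))
        for n2 in names[i:]:
            sc, off = _dimer_scan(primers[n1], primers[n2], cfg)
            if sc >= cfg.threshold_score:
                flags.append(DimerFlag(n1, n2, "dimer", sc, off))
    flags.sort(key=lambda f: (-f.score, f.name1, f.name2))
    return flags
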