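"""Independent reference implementations used only as test oracles.

Everything here is deliberately naive (plain-Python dynamic programming,
string slicing, from-scratch recounts) and kept separate from the library
code paths it checks.
"""

from __future__ import annotations


def gotoh_local(a: str, b: str, match=1.0, mismatch=-3.0, open_=5.0, ext=2.0):
    """Plain Smith-Waterman with affine gaps: a gap of length k costs
    open_ + k * ext.  Returns the optimal local score."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - (open_ + ext), E[i][j - 1] - ext)
            F[i][j] = max(H[i - 1][j] - (open_ + ext), F[i - 1][j] - ext)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def semiglobal_linear(a: str, b: str, match=1.0, mismatch=-1.0, gap=-2.0):
    """Semi-global alignment score with linear gaps and free end gaps."""
    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1] + s, M[i - 1][j] + gap, M[i][j - 1] + gap)
    return max(max(M[n]), max(M[i][m] for i in range(n + 1)))


_HETERODIMERS = [x + y for x in "ACGT" for y in "ACGT" if x != y]
_CLASS = {}
for d in _HETERODIMERS:
    comp = d.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    variants = {d, d[::-1], comp, comp[::-1]}
    for name in ("AT/TA", "CA/GT", "GA/CT", "GC/CG"):
        if name[:2] in variants:
            _CLASS[d] = name


def mine_bruteforce(seq: str, min_units=11, min_purity=0.9, min_region_len=19):
    """Naive re-implementation of the mining rule: per dimer and phase,
    forward greedy chaining with purity recomputed from scratch by string
    counting; then the same overlap-resolution policy applied naively.
    Returns a set of (start, end, motif_class)."""
    cands = []
    for d in _HETERODIMERS:
        positions = [i for i in range(len(seq) - 1) if seq[i : i + 2] == d]
        for parity in (0, 1):
            pp = [p for p in positions if p % 2 == parity]
            # seed runs of uninterrupted copies
            seeds, cur = [], []
            for p in pp:
                if cur and p != cur[-1] + 2:
                    seeds.append(cur)
                    cur = []
                cur.append(p)
            if cur:
                seeds.append(cur)
            regions = set()
            for seed in seeds:
                start, end = seed[0], seed[-1] + 2
                while True:
                    grown = False
                    nxt = [p for p in pp if p >= end]
                    if nxt and _purity_of(seq, d, start, nxt[0] + 2) >= min_purity:
                        end = nxt[0] + 2
                        grown = True
                    prv = [p for p in pp if p < start]
                    if prv and _purity_of(seq, d, prv[-1], end) >= min_purity:
                        start = prv[-1]
                        grown = True
                    if not grown:
                        break
                regions.add((start, end))
            for start, end in regions:
                region = seq[start:end]
                units = sum(
                    1
                    for i in range(0, len(region) - 1, 2)
                    if region[i : i + 2] == d
                )
                purity = 2 * units / (end - start)
                if (
                    units >= min_units
                    and purity >= min_purity
                    and end - start >= min_region_len
                ):
                    cands.append((start, end, _CLASS[d], units, purity, d))
    # same-class best-candidate resolution, naively
    kept = []
    for cls in ("AT/TA", "CA/GT", "GA/CT", "GC/CG"):
        group = sorted(
            [c for c in cands if c[2] == cls],
            key=lambda c: (-c[3], -c[4], -(c[1] - c[0]), _rank(c[5]), c[0]),
        )
        chosen = []
        for c in group:
            if all(c[1] <= k[0] or c[0] >= k[1] for k in chosen):
                chosen.append(c)
        kept.extend(chosen)
    kept.sort(key=lambda c: (-c[4], -(c[1] - c[0]), c[0], c[2]))
    final = []
    for c in kept:
        if all(c[1] <= k[0] or c[0] >= k[1] for k in final):
            final.append(c)
    return {(c[0], c[1], c[2]) for c in final}


def _rank(d: str) -> int:
    """Twin-candidate preference: the revcomp-closed dimer pair containing
    the alphabetically first class member ranks first."""
    comp = lambda x: x.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    members = [x for x in _HETERODIMERS if _CLASS[x] == _CLASS[d]]
    return 0 if d in {min(members), comp(min(members))} else 1


def _purity_of(seq: str, d: str, start: int, end: int) -> float:
    region = seq[start:end]
    units = sum(1 for i in range(0, len(region) - 1, 2) if region[i : i + 2] == d)
    return 2 * units / len(region)


def longest_run_bruteforce(region: str, dimers: list[str]) -> int:
    best = 0
    for d in dimers:
        for i in range(len(region)):
            k = 0
            while region[i + 2 * k : i + 2 * k + 2] == d:
                k += 1
            best = max(best, k)
    return best


def dimer_bruteforce(p1: str, p2: str) -> int:
    """All-offset ungapped matches-minus-mismatches of p1 against the
    reverse complement of p2, by direct string comparison."""
    comp = p2.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    best = -min(len(p1), len(comp))
    for off in range(-len(comp) + 1, len(p1)):
        sc = 0
        for i, ch in enumerate(p1):
            j = i - off
            if 0 <= j < len(comp):
                sc += 1 if ch == comp[j] else -1
        best = max(best, sc)
    return best


def chisq_2x2(a, b, c, d) -> float:
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


def ols_slope_f(x, y):
    """Normal-equations simple regression slope and F statistic."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((xi - mx) ** 2 for xi in x)
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    beta = sxy / sxx
    alpha = my - beta * mx
    ss_res = sum((yi - alpha - beta * xi) ** 2 for xi, yi in zip(x, y))
    ss_tot = sum((yi - my) ** 2 for yi in y)
    ss_reg = ss_tot - ss_res
    f = ss_reg / (ss_res / (n - 2))
    return beta, f
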