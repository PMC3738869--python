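"""Shared DNA-string helpers: complements, IUPAC codes, validation."""

from __future__ import annotations

COMPLEMENT = str.maketrans("ACGTRYMKWSNacgtrymkwsn", "TGCAYRKMWSNtgcayrkmwsn")

# IUPAC degenerate codes restricted to what a two-species consensus can emit,
# plus N for fully-unknown positions.
IUPAC_SETS = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "M": frozenset("AC"),
    "K": frozenset("GT"),
    "W": frozenset("AT"),
    "S": frozenset("CG"),
    "N": frozenset("ACGT"),
}

SET_TO_CODE = {v: k for k, v in IUPAC_SETS.items()}


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def is_dna(seq: str, alphabet: str = "ACGTN") -> bool:
    return bool(seq) and set(seq) <= set(alphabet)


def normalize(seq: str) -> str:
    """Uppercase a raw sequence and validate the A/C/G/T/N alphabet."""
    s = seq.upper()
    if not is_dna(s):
        bad = sorted(set(s) - set("ACGTN"))
        raise ValueError(f"non-DNA characters in sequence: {bad}")
    return s


def expand_degenerate(seq: str) -> list[str]:
    """All concrete resolutions of an IUPAC string, in lexicographic order."""
    out = [""]
    for ch in seq:
        try:
            bases = sorted(IUPAC_SETS[ch])
        except KeyError:
            raise ValueError(f"invalid IUPAC code {ch!r}") from None
        out = [p + b for p in out for b in bases]
    return out


def degeneracy(seq: str) -> int:
    """Number of concrete sequences an IUPAC string expands to."""
    d = 1
    for ch in seq:
        d *= len(IUPAC_SETS[ch])
    return d


def degenerate_positions(seq: str) -> list[int]:
    return [i for i, ch in enumerate(seq) if len(IUPAC_SETS[ch]) > 1]
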