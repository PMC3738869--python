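"""Packaged reference tables for the 24 published CAM markers.

Transcriptions of the published marker tables: genome-wide motif counts in
the zebra finch and chicken genomes, the 24 primer pairs with their
degenerate codes and percent identity to chicken, the repeat structures
and longest uninterrupted runs in both species, and the 12-species utility
summary with DNA-DNA hybridisation distances.  Files are integrity-checked
with SHA-256 on load.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import pandas as pd

_CHECKSUMS = {
    "table1_motif_counts.tsv": "00c4bac56bb48917203754ffb6000f5d8de1576b147c2a69d4193b4109b84c05",
    "table2_primers.tsv": "4707889c3333cd71dd7d9c87d18fd59fe428367541bfccd3b273ae62bcf3cdca",
    "table3_repeats.tsv": "52e9c19962b4fe74981deddf27c4b2b29c37a66cd91d4147326bc0387b25d9bf",
    "table4_species.tsv": "02ece05c47d7fc2d7504356de92b7a87c25eee98d3399f185a2ce43f9cb7f3f3",
}


@dataclass(frozen=True)
class FixtureBundle:
    motif_counts: pd.DataFrame  # genome-wide motif class counts per species
    primers: pd.DataFrame  # 24 markers: F/R IUPAC sequences, dyes, %ID
    repeats: pd.DataFrame  # repeat structures, longest runs, product sizes
    species: pd.DataFrame  # 12 species: distances, group, utility percent

    def primer_panel(self) -> dict[str, str]:
        """All 48 primers as a name -> IUPAC sequence mapping
        (names like CAM-01F / CAM-01R)."""
        panel = {}
        for _, row in self.primers.iterrows():
            panel[row.marker + "F"] = row.f_seq
            panel[row.marker + "R"] = row.r_seq
        return panel

    def chicken_positions(self) -> dict[str, tuple[str, int]]:
        """Marker -> (chicken chromosome, bp position)."""
        return {
            row.marker: (row.ch_chrom, int(row.ch_pos))
            for _, row in self.primers.iterrows()
        }

    def longest_runs(self) -> tuple[list[int], list[int]]:
        """Zebra finch and chicken longest uninterrupted run vectors,
        in marker order."""
        r = self.repeats.sort_values("marker")
        return list(r.zf_longest), list(r.ch_longest)


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("camkit") / "data" / name
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise RuntimeError(f"fixture {name} corrupted (checksum mismatch)")
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), sep="\t")


def load_paper_fixtures() -> FixtureBundle:
    return FixtureBundle(
        motif_counts=_read("table1_motif_counts.tsv"),
        primers=_read("table2_primers.tsv"),
        repeats=_read("table3_repeats.tsv"),
        species=_read("table4_species.tsv"),
    )


def repeat_struct_len(struct: str) -> int:
    """Length in bp of a printed repeat-structure string such as
    '(A)3(CA)18' (the '&' separator between disjoint repeat regions is
    ignored; interleaving non-repeat sequence is not part of the string)."""
    import re

    total = 0
    for unit, count, plain in re.findall(r"\(([A-Z]+)\)(\d+)|([A-Z]+)", struct):
        if unit:
            total += len(unit) * int(count)
        else:
            total += len(plain.replace("&", ""))
    return total
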