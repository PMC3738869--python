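"""FASTA and table I/O built on Biopython/pandas."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .miner import GenomeSequence, RepeatLocus

log = logging.getLogger("camkit")


def read_fasta(path, species_tag: str | None = None) -> list[GenomeSequence]:
    """Read a (multi-record) FASTA into GenomeSequence records.

    Sequences are normalized to uppercase (a note is logged when lowercase
    input is seen); the species tag defaults to the file stem.
    """
    path = Path(path)
    tag = species_tag if species_tag is not None else path.stem
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        if raw != raw.upper():
            log.info("record %s: lowercase bases normalized to uppercase", rec.id)
        out.append(GenomeSequence(tag, rec.id, raw))
    return out


def write_fasta(records: list[GenomeSequence], path) -> None:
    seqs = [
        SeqRecord(Seq(r.residues), id=r.seq_id, description="")
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def loci_to_frame(loci: list[RepeatLocus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species": l.species_tag,
                "seq_id": l.seq_id,
                "start": l.start,
                "end": l.end,
                "motif_class": l.motif_class,
                "observed_motif": l.observed_motif,
                "units": l.units,
                "purity": round(l.purity, 4),
                "longest_run": l.longest_run,
            }
            for l in loci
        ]
    )


def write_locus_table(loci: list[RepeatLocus], path) -> None:
    loci_to_frame(loci).to_csv(path, sep="\t", index=False)


def write_locus_bed(loci: list[RepeatLocus], path) -> None:
    """BED6: name = class:motif, score = purity scaled to 0-1000."""
    with open(path, "w") as fh:
        for l in loci:
            fh.write(
                f"{l.seq_id}\t{l.start}\t{l.end}\t"
                f"{l.motif_class.replace('/', '_')}:{l.observed_motif}\t"
                f"{int(round(1000 * l.purity))}\t+\n"
            )


def write_consensus_columns(entries: list[tuple[str, "object"]], path) -> None:
    """Per-pair consensus column table: one row per alignment column with
    both source bases; the repeat span is recorded on every row."""
    rows = []
    for name, cons in entries:
        rs, re_ = cons.repeat_span
        for i, col in enumerate(cons.columns):
            rows.append(
                {
                    "pair": name,
                    "column": i,
                    "base_a": col.base_a,
                    "base_b": col.base_b,
                    "consensus": col.consensus_char,
                    "repeat_start": rs,
                    "repeat_end": re_,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_consensus_columns(path) -> list[tuple[str, "object"]]:
    from .consensus import ConsensusColumn, ConsensusSequence

    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for name, sub in df.groupby("pair", sort=False):
        sub = sub.sort_values("column")
        cols = tuple(
            ConsensusColumn(r.base_a, r.base_b, r.consensus)
            for r in sub.itertuples()
        )
        span = (int(sub.repeat_start.iloc[0]), int(sub.repeat_end.iloc[0]))
        out.append((name, ConsensusSequence(cols, span)))
    return out


def write_consensus_fasta(entries, path) -> None:
    """Consensus sequences with lowercase n at disagreement columns."""
    with open(path, "w") as fh:
        for name, cons in entries:
            fh.write(f">{name} repeat={cons.repeat_span[0]}-{cons.repeat_span[1]}\n")
            seq = cons.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_expanded_primer_fasta(panel: dict[str, str], path) -> None:
    """Concrete (degeneracy-expanded) primer sequences as FASTA."""
    from ._seq import expand_degenerate

    with open(path, "w") as fh:
        for name in sorted(panel):
            for k, concrete in enumerate(expand_degenerate(panel[name])):
                fh.write(f">{name}.{k}\n{concrete}\n")


def write_window_fasta(loci: list[RepeatLocus], path) -> None:
    with open(path, "w") as fh:
        for l in loci:
            fh.write(f">{l.species_tag}|{l.seq_id}|{l.start}-{l.end}\n")
            for i in range(0, len(l.window), 70):
                fh.write(l.window[i : i + 70] + "\n")
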