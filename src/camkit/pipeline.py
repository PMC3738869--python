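"""End-to-end marker development workflow: mine -> pair -> consensus ->
design -> dimer screen, with a per-stage run log."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .consensus import consensus_of_pair
from .dimers import CheckerConfig, flag_incompatible
from .homology import AlignmentParams, PairingConfig, pair_conserved_loci
from .miner import GenomeSequence, MinerConfig, find_dinucleotide_repeats
from .primers import DesignConstraints, TmOffsets, annotate_pair, design_pairs

log = logging.getLogger("camkit")


@dataclass(frozen=True)
class PipelineConfig:
    miner: MinerConfig = field(default_factory=MinerConfig)
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    pairing: PairingConfig = field(default_factory=PairingConfig)
    design: DesignConstraints = field(default_factory=DesignConstraints)
    tm_offsets: TmOffsets = field(default_factory=TmOffsets)
    checker: CheckerConfig = field(default_factory=CheckerConfig)
    max_pairs_per_locus: int = 1  # best-ranked primer pair reported per locus

    def to_dict(self) -> dict:
        import dataclasses

        def plain(v):
            if isinstance(v, frozenset):
                return sorted(v)
            if isinstance(v, tuple):
                return list(v)
            return v

        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if dataclasses.is_dataclass(v):
                out[f.name] = {
                    g.name: plain(getattr(v, g.name)) for g in dataclasses.fields(v)
                }
            else:
                out[f.name] = plain(v)
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        """Build from a plain (JSON-compatible) dict; unknown keys at any
        level are rejected."""
        import dataclasses

        sections = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(d) - set(sections)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for name, val in d.items():
            f = sections[name]
            sub_cls = f.default_factory if f.default_factory is not dataclasses.MISSING else None
            if sub_cls is not None and dataclasses.is_dataclass(sub_cls):
                sub_fields = {g.name: g for g in dataclasses.fields(sub_cls)}
                bad = set(val) - set(sub_fields)
                if bad:
                    raise ValueError(f"unknown keys in [{name}]: {sorted(bad)}")
                coerced = {}
                for k, v in val.items():
                    current = getattr(sub_cls(), k)
                    if isinstance(current, frozenset):
                        v = frozenset(v)
                    elif isinstance(current, tuple):
                        v = tuple(v)
                    coerced[k] = v
                kwargs[name] = sub_cls(**coerced)
            else:
                kwargs[name] = val
        return cls(**kwargs)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        import json
        from pathlib import Path

        return cls.from_dict(json.loads(Path(path).read_text()))

    def save(self, path) -> None:
        import json
        from pathlib import Path

        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


@dataclass
class PipelineResult:
    loci_a: list
    loci_b: list
    pairs: list
    markers: pd.DataFrame
    dimer_flags: list
    counts: dict

    def funnel(self) -> dict:
        return dict(self.counts)


def run_pipeline(
    genomes_a: list[GenomeSequence],
    genomes_b: list[GenomeSequence],
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full marker-development funnel on two genomes.

    Returns the mined loci, conserved pairs, a marker report with one
    ranked primer pair per conserved locus (where design succeeded), and
    the dimer screen of the designed panel.
    """
    cfg = config or PipelineConfig()
    loci_a: list = []
    loci_b: list = []
    for g in genomes_a:
        loci_a.extend(find_dinucleotide_repeats(g, cfg.miner))
    for g in genomes_b:
        loci_b.extend(find_dinucleotide_repeats(g, cfg.miner))
    log.info("mined %d + %d loci", len(loci_a), len(loci_b))

    pairs = pair_conserved_loci(loci_a, loci_b, cfg.alignment, cfg.pairing)
    log.info("%d conserved pairs pass E <= %g", len(pairs), cfg.pairing.e_threshold)

    rows = []
    panel: dict[str, str] = {}
    n_consensus = 0
    for k, pair in enumerate(pairs):
        cons = consensus_of_pair(pair)
        n_consensus += 1
        cands = design_pairs(cons, cfg.design, cfg.tm_offsets)
        if not cands:
            continue
        best = cands[0]
        best = annotate_pair(
            best,
            {
                "a": pair.locus_a.window,
                "b": pair.locus_b.window,
            },
            {
                "a": pair.locus_a.repeat_struct_len,
                "b": pair.locus_b.repeat_struct_len,
            },
        )
        marker_id = f"MRK-{k + 1:02d}"
        panel[marker_id + "F"] = best.forward
        panel[marker_id + "R"] = best.reverse
        rows.append(
            {
                "marker": marker_id,
                "locus_a": pair.locus_a.locus_id,
                "locus_b": pair.locus_b.locus_id,
                "motif_class": pair.motif_class,
                "e_value": pair.e_value,
                "forward": best.forward,
                "reverse": best.reverse,
                "tm_f": round(best.nominal_tm_f, 2),
                "tm_r": round(best.nominal_tm_r, 2),
                "degen_pair": best.degeneracy_count_pair,
                "product_len_a": best.expected_product_len.get("a"),
                "product_len_b": best.expected_product_len.get("b"),
                "min_allele_a": best.min_expected_allele.get("a"),
                "min_allele_b": best.min_expected_allele.get("b"),
            }
        )
    markers = pd.DataFrame(rows)
    flags = flag_incompatible(panel, cfg.checker) if panel else []
    counts = {
        "loci_mined_a": len(loci_a),
        "loci_mined_b": len(loci_b),
        "conserved_pairs": len(pairs),
        "consensus_built": n_consensus,
        "markers_designed": len(markers),
        "dimer_flags": len(flags),
    }
    log.info("funnel: %s", counts)
    return PipelineResult(loci_a, loci_b, pairs, markers, flags, counts)
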