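"""Seeded synthetic data: genome pairs with planted conserved
microsatellites, and genotype panels with configurable null alleles and
sex-linked loci.

The genome generator emulates the input situation of a two-species
conserved-marker search: homologous loci share flanking sequence (mutated
at a configurable per-base divergence, with optional small indels) but
carry species-specific repeat counts; decoy loci occur in only one
species.  Exact planted coordinates are recorded in a truth table so that
precision and recall of every pipeline stage can be computed.

The panel generator emulates a genotyping screen: diploid draws under
Hardy-Weinberg proportions per species x locus, with optional null
alleles (heterozygote-with-null becomes an apparent homozygote,
null homozygote becomes an amplification failure), Z-linked loci
(hemizygous females) and W-product loci (all females share one allele
size absent from males).

All generators are pure functions of their seed and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .miner import GenomeSequence
from .panel import GenotypePanel

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GenomeSimParams:
    n_planted_conserved: int = 10
    n_decoys_per_species: int = 5
    repeat_units_range_a: tuple[int, int] = (12, 25)
    repeat_units_range_b: tuple[int, int] = (12, 25)
    motifs: tuple[str, ...] = ("CA", "GA", "AT")
    flank_len: int = 200
    flank_divergence: float = 0.05
    indel_rate: float = 0.002
    repeat_interruption_rate: float = 0.0
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    loci_per_contig: int = 2
    pad_range: tuple[int, int] = (60, 160)
    seed: int = 0

    def __post_init__(self):
        for p in (self.flank_divergence, self.indel_rate, self.repeat_interruption_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if abs(sum(self.base_composition) - 1) > 1e-9:
            raise ValueError("base_composition must sum to 1")


def _random_dna(rng, n: int, comp) -> str:
    return "".join(rng.choice(_BASES, size=n, p=comp))


def _mutate(rng, seq: str, sub_rate: float, indel_rate: float, comp) -> str:
    out = []
    for ch in seq:
        r = rng.random()
        if r < indel_rate / 2:
            continue  # deletion
        if r < indel_rate:
            out.append(_random_dna(rng, rng.integers(1, 4), comp))  # insertion
        if rng.random() < sub_rate:
            choices = [b for b in "ACGT" if b != ch]
            out.append(choices[rng.integers(0, 3)])
        else:
            out.append(ch)
    return "".join(out)


def _repeat_tract(rng, motif: str, units: int, interruption_rate: float) -> str:
    tract = motif * units
    if interruption_rate <= 0:
        return tract
    out = []
    for i in range(0, len(tract), 2):
        out.append(tract[i : i + 2])
        if rng.random() < interruption_rate:
            out.append(_random_dna(rng, 1, (0.25,) * 4))
    return "".join(out)


def generate_genome_pair(
    params: GenomeSimParams | None = None,
) -> tuple[list[GenomeSequence], list[GenomeSequence], pd.DataFrame]:
    """Two synthetic genomes plus the truth table of planted loci."""
    params = params or GenomeSimParams()
    rng = np.random.default_rng(params.seed)
    comp = params.base_composition

    cassettes_a: list[tuple[str, dict]] = []
    cassettes_b: list[tuple[str, dict]] = []
    truth_rows = []

    def make_cassette(kind: str, idx: int):
        motif = str(rng.choice(list(params.motifs)))
        left = _random_dna(rng, params.flank_len, comp)
        right = _random_dna(rng, params.flank_len, comp)
        ua = int(rng.integers(*params.repeat_units_range_a, endpoint=True))
        ub = int(rng.integers(*params.repeat_units_range_b, endpoint=True))
        tract_a = _repeat_tract(rng, motif, ua, params.repeat_interruption_rate)
        info = {"kind": kind, "motif": motif, "units_a": ua, "units_b": ub}
        if kind in ("conserved", "decoy_a"):
            cassettes_a.append((left + tract_a + right, dict(info, which="a", idx=idx)))
        if kind == "conserved":
            lb = _mutate(rng, left, params.flank_divergence, params.indel_rate, comp)
            rb = _mutate(rng, right, params.flank_divergence, params.indel_rate, comp)
            tract_b = _repeat_tract(rng, motif, ub, params.repeat_interruption_rate)
            cassettes_b.append((lb + tract_b + rb, dict(info, which="b", idx=idx)))
        if kind == "decoy_b":
            tract_b = _repeat_tract(rng, motif, ub, params.repeat_interruption_rate)
            cassettes_b.append(
                (left + tract_b + right, dict(info, which="b", idx=idx))
            )

    for i in range(params.n_planted_conserved):
        make_cassette("conserved", i)
    for i in range(params.n_decoys_per_species):
        make_cassette("decoy_a", 1000 + i)
        make_cassette("decoy_b", 2000 + i)

    def lay_out(cassettes, species_tag):
        records = []
        coords = {}
        per = max(1, params.loci_per_contig)
        for c0 in range(0, len(cassettes), per):
            chunk = cassettes[c0 : c0 + per]
            seq_id = f"{species_tag}_contig{c0 // per}"
            parts = []
            pos = 0
            for cass, info in chunk:
                pad = _random_dna(rng, int(rng.integers(*params.pad_range)), comp)
                parts.append(pad)
                pos += len(pad)
                coords[info["idx"], info["which"]] = (seq_id, pos, pos + len(cass), info)
                parts.append(cass)
                pos += len(cass)
            parts.append(_random_dna(rng, int(rng.integers(*params.pad_range)), comp))
            records.append(GenomeSequence(species_tag, seq_id, "".join(parts)))
        return records, coords

    recs_a, coords_a = lay_out(cassettes_a, "A")
    recs_b, coords_b = lay_out(cassettes_b, "B")

    seen = sorted({idx for idx, _ in list(coords_a) + list(coords_b)})
    for idx in seen:
        ca = coords_a.get((idx, "a"))
        cb = coords_b.get((idx, "b"))
        info = (ca or cb)[3]
        truth_rows.append(
            {
                "idx": idx,
                "kind": info["kind"],
                "motif": info["motif"],
                "units_a": info["units_a"] if ca else np.nan,
                "units_b": info["units_b"] if cb else np.nan,
                "contig_a": ca[0] if ca else "",
                "cassette_start_a": ca[1] if ca else np.nan,
                "cassette_end_a": ca[2] if ca else np.nan,
                "contig_b": cb[0] if cb else "",
                "cassette_start_b": cb[1] if cb else np.nan,
                "cassette_end_b": cb[2] if cb else np.nan,
            }
        )
    return recs_a, recs_b, pd.DataFrame(truth_rows)


@dataclass(frozen=True)
class PanelSimParams:
    n_species: int = 3
    n_loci: int = 10
    n_individuals: int = 20
    allele_count_range: tuple[int, int] = (2, 6)
    allele_size_base: int = 150
    allele_step: int = 2
    null_allele_freq: float = 0.0
    amplification_failure_rate: float = 0.0
    z_linked_loci: tuple[int, ...] = ()
    w_product_loci: tuple[int, ...] = ()
    genetic_distances: tuple[float, ...] = ()
    monomorphic_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for p in (self.null_allele_freq, self.amplification_failure_rate, self.monomorphic_rate):
            if not 0 <= p <= 1:
                raise ValueError("frequencies must be in [0, 1]")


def generate_genotype_panel(
    params: PanelSimParams | None = None,
) -> tuple[GenotypePanel, pd.DataFrame]:
    """Genotype panel plus per (species, locus) truth labels."""
    params = params or PanelSimParams()
    rng = np.random.default_rng(params.seed)
    rows = []
    truth = []
    for s in range(params.n_species):
        species = f"sp{s:02d}"
        for l in range(params.n_loci):
            locus = f"L{l:02d}"
            z_linked = l in params.z_linked_loci
            w_product = l in params.w_product_loci
            k = int(rng.integers(*params.allele_count_range, endpoint=True))
            if rng.random() < params.monomorphic_rate:
                k = 1
            base = params.allele_size_base + 40 * l
            sizes = [base + params.allele_step * j for j in range(k)]
            freqs = rng.dirichlet(np.ones(k))
            w_size = base - 20
            locus_fails = rng.random() < params.amplification_failure_rate
            truth.append(
                {
                    "species": species,
                    "locus": locus,
                    "n_alleles": k,
                    "null_freq": params.null_allele_freq,
                    "z_linked": z_linked,
                    "w_product": w_product,
                    "amplification_failed": locus_fails,
                }
            )
            for i in range(params.n_individuals):
                sex = "M" if i % 2 == 0 else "F"
                a1 = a2 = np.nan
                if not locus_fails:
                    if w_product and sex == "F":
                        a1 = a2 = w_size
                    elif z_linked and sex == "F":
                        a1 = a2 = int(rng.choice(sizes, p=freqs))
                    else:
                        draw = _draw_diploid(
                            rng, sizes, freqs, params.null_allele_freq
                        )
                        if draw is not None:
                            a1, a2 = draw
                rows.append(
                    {
                        "species": species,
                        "locus": locus,
                        "individual": f"{species}_ind{i:03d}",
                        "sex": sex,
                        "allele1": a1,
                        "allele2": a2,
                    }
                )
    return GenotypePanel(pd.DataFrame(rows)), pd.DataFrame(truth)


def _draw_diploid(rng, sizes, freqs, null_freq):
    """One HWE draw with a possible null allele."""
    probs = np.append(np.asarray(freqs) * (1 - null_freq), null_freq)
    idx = rng.choice(len(probs), size=2, p=probs)
    null_i = len(probs) - 1
    visible = [sizes[i] for i in idx if i != null_i]
    if not visible:
        return None  # null homozygote: amplification failure
    if len(visible) == 1:
        return visible[0], visible[0]  # apparent homozygote
    return tuple(sorted(visible))
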