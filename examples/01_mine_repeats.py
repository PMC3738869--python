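"""Mine dinucleotide microsatellites from a small sequence.

Builds a 600-bp contig with a planted (CA)14 tract, runs the miner with
the standard criteria (>10 units, >=90% purity, >18 bp) and prints the
locus table: coordinates, motif class, total consistent units, purity and
the longest uninterrupted run (the variability proxy used to select
marker candidates).
"""

import numpy as np

from camkit import GenomeSequence, find_dinucleotide_repeats

rng = np.random.default_rng(1)
background = "".join(rng.choice(list("ACGT"), size=600))
contig = background[:300] + "CA" * 14 + background[300:]

genome = GenomeSequence("demo", "contig1", contig)
for locus in find_dinucleotide_repeats(genome):
    print(
        f"{locus.seq_id}:{locus.start}-{locus.end}  class={locus.motif_class}  "
        f"motif={locus.observed_motif}  units={locus.units}  "
        f"purity={locus.purity:.2f}  longest_run={locus.longest_run}"
    )
    print(f"window: {len(locus.window)} bp (repeat plus up to 200 bp flanks)")
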