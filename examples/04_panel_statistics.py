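"""Marker-set statistics from the packaged published tables.

Recomputes the headline numbers of the conserved-marker study: motif
spectrum heterogeneity between the two source genomes, the paired
comparison of longest uninterrupted repeat runs, the decline of percent
polymorphic loci with DNA-DNA hybridisation distance, and the group
utility means.
"""

from camkit import (
    heterogeneity_chisq,
    load_paper_fixtures,
    paired_t,
    regress_vs_distance,
    utility_group_means,
)

fx = load_paper_fixtures()

t = fx.motif_counts.set_index("motif_class")
rows = ["AT/TA", "CA/GT", "GA/CT"]
res = heterogeneity_chisq([list(t.loc[rows, "zf_n"]), list(t.loc[rows, "ch_n"])])
print(f"motif spectrum ZF vs CH: chi2={res.statistic:.1f}, df={res.df[0]}, p={res.p:.2g}")
print("  (the two genomes favour different dinucleotide classes)")

zf, ch = fx.longest_runs()
res = paired_t(zf, ch)
print(f"longest runs ZF vs CH: t={res.statistic:.2f}, df={res.df[0]}, p={res.p:.2f}")
print("  (repeats are on average longer in the finch than in chicken)")

sp = fx.species[fx.species.exclude_poly == 0]
res = regress_vs_distance(sp.pct_poly, sp.dist_zf)
print(
    f"% polymorphic ~ distance: F={res.statistic:.2f}, df={res.df}, "
    f"adj R2={res.extra['adj_r_squared']:.2f}, p={res.p:.4f}, "
    f"slope={res.extra['slope']:.2f} %/distance-unit"
)
print("  (marker variability decays with genetic distance from the source species)")

print("group means:", utility_group_means(fx.species))
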