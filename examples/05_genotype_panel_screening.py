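"""Simulate and evaluate a cross-species genotype panel.

Generates a 3-species x 10-locus panel (20 individuals each) in which
locus L03 is Z-linked, locus L07 amplifies a W product in females, and
null alleles segregate at 10% frequency, then runs the screening a
marker developer would: utility summary, Hardy-Weinberg exact tests,
null-allele estimates and sex-linkage classification.
"""

from camkit import (
    hwe_exact_test,
    infer_sex_linkage,
    null_allele_freq,
    summarize_panel,
)
from camkit.simulate import PanelSimParams, generate_genotype_panel

panel, truth = generate_genotype_panel(
    PanelSimParams(
        n_species=3,
        n_loci=10,
        n_individuals=20,
        null_allele_freq=0.10,
        z_linked_loci=(3,),
        w_product_loci=(7,),
        seed=7,
    )
)

print(summarize_panel(panel).to_string(index=False))
print()
sp = panel.species[0]
for locus in panel.loci:
    g = panel.genotypes(sp, locus)
    alleles = [a for _, a in g]
    hwe = hwe_exact_test(alleles, seed=1)
    null = null_allele_freq(alleles)
    link = infer_sex_linkage(g)
    hwe_p = f"{hwe.p:.3f}" if hwe else "n/a"
    null_r = f"{null.estimate:+.3f}" if null else "n/a"
    print(f"{sp} {locus}: HWE p={hwe_p}  null-allele r={null_r}  linkage={link}")
print()
print("Loci with HWE rejection and positive null estimates mirror the planted")
print("10% null-allele frequency; L03/L07 show their planted sex linkage.")
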