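"""Utility summaries and the marker-set statistics, checked against the
published tables and independent oracles."""

import numpy as np
import pandas as pd
import pytest

from camkit.panel import (
    GenotypePanel,
    SpeciesMeta,
    flag_linked_loci,
    heterogeneity_chisq,
    hwe_exact_test,
    infer_sex_linkage,
    null_allele_freq,
    paired_t,
    regress_vs_distance,
    summarize_panel,
    utility_group_means,
)
from camkit.simulate import PanelSimParams, _draw_diploid, generate_genotype_panel
from oracles import chisq_2x2, ols_slope_f


# --- chi-square --------------------------------------------------------------


def test_genome_motif_count_heterogeneity(fixtures):
    """The zebra finch and chicken genome-wide motif spectra differ
    (chi2 = 381.6, df 2, GC/CG class excluded as near-empty)."""
    t = fixtures.motif_counts.set_index("motif_class")
    table = [
        list(t.loc[["AT/TA", "CA/GT", "GA/CT"], "zf_n"]),
        list(t.loc[["AT/TA", "CA/GT", "GA/CT"], "ch_n"]),
    ]
    res = heterogeneity_chisq(table)
    assert round(res.statistic, 1) == 381.6
    assert res.df == (2,)
    assert res.p < 0.0001


def test_identical_row_proportions_give_zero():
    res = heterogeneity_chisq([[10, 20, 30], [20, 40, 60]])
    assert res.statistic == pytest.approx(0.0, abs=1e-12)


def test_2x2_matches_closed_form(rng):
    for _ in range(20):
        a, b, c, d = (int(x) for x in rng.integers(5, 100, size=4))
        res = heterogeneity_chisq([[a, b], [c, d]])
        assert res.statistic == pytest.approx(chisq_2x2(a, b, c, d))
        assert res.df == (1,)


def test_zero_marginal_rejected():
    with pytest.raises(ValueError):
        heterogeneity_chisq([[0, 0], [1, 2]])


# --- paired t ----------------------------------------------------------------


def test_longest_run_paired_t(fixtures):
    """Zebra finch repeats are longer than their chicken homologues on
    average (t = 2.18, df 23, P = 0.04)."""
    zf, ch = fixtures.longest_runs()
    res = paired_t(zf, ch)
    assert round(res.statistic, 2) == 2.18
    assert res.df == (23,)
    assert round(res.p, 2) == 0.04


def test_run_direction_tallies(fixtures):
    """15 loci have fewer repeats in chicken, six more, three the same."""
    zf, ch = fixtures.longest_runs()
    diffs = np.array(zf) - np.array(ch)
    assert (diffs > 0).sum() == 15
    assert (diffs < 0).sum() == 6
    assert (diffs == 0).sum() == 3
    assert max(zf) == 27 and max(ch) == 20
    assert min(min(zf), min(ch)) == 8


def test_identical_vectors_rejected():
    with pytest.raises(ValueError):
        paired_t([1, 2, 3], [1, 2, 3])


def test_paired_t_type_one_error(rng):
    """Under the null (paired normals), rejection at alpha = 0.05 happens
    at the nominal rate within Monte-Carlo error."""
    n_rep, n = 2000, 12
    rej = 0
    for _ in range(n_rep):
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        if paired_t(x, y).p <= 0.05:
            rej += 1
    se = (0.05 * 0.95 / n_rep) ** 0.5
    assert abs(rej / n_rep - 0.05) <= 3 * se


# --- regression --------------------------------------------------------------


def test_polymorphism_distance_regression(fixtures):
    """Percent polymorphic declines with hybridisation distance from the
    source species (F = 27.55, df (1, 9), adjusted R2 = 0.73, chicken
    excluded)."""
    t = fixtures.species[fixtures.species.exclude_poly == 0]
    res = regress_vs_distance(t.pct_poly, t.dist_zf)
    assert round(res.statistic, 2) == 27.55
    assert res.df == (1, 9)
    assert round(res.extra["adj_r_squared"], 2) == 0.73
    assert round(res.p, 4) == 0.0005
    assert res.extra["slope"] < 0


def test_collinear_data_r2_one():
    x = [1.0, 2.0, 3.0, 4.0]
    y = [3.0, 5.0, 7.0, 9.0]
    res = regress_vs_distance(y, x)
    assert res.extra["r_squared"] == pytest.approx(1.0)


def test_regression_matches_normal_equations(rng):
    for _ in range(10):
        x = rng.uniform(0, 30, size=12)
        y = 80 - 1.5 * x + rng.normal(scale=8, size=12)
        res = regress_vs_distance(y, x)
        beta, f = ols_slope_f(list(x), list(y))
        assert res.extra["slope"] == pytest.approx(beta)
        assert res.statistic == pytest.approx(f)


def test_constant_predictor_rejected():
    with pytest.raises(ValueError):
        regress_vs_distance([1, 2, 3], [5, 5, 5])


# --- panel summaries ---------------------------------------------------------


def _panel_from_rows(rows):
    return GenotypePanel(pd.DataFrame(rows))


def test_twenty_three_of_twenty_four_rounds_to_96():
    rows = []
    for i in range(24):
        amp = i != 0  # one locus fails
        rows.append(
            {
                "species": "sp",
                "locus": f"L{i:02d}",
                "individual": "ind0",
                "sex": "F",
                "allele1": 100 if amp else np.nan,
                "allele2": 100 if amp else np.nan,
            }
        )
    s = summarize_panel(_panel_from_rows(rows))
    assert int(s.pct_amplified.iloc[0]) == 96


def test_uniform_homozygotes_are_monomorphic():
    rows = [
        {
            "species": "sp",
            "locus": "L0",
            "individual": f"i{k}",
            "sex": "M",
            "allele1": 120,
            "allele2": 120,
        }
        for k in range(8)
    ]
    s = summarize_panel(_panel_from_rows(rows))
    assert int(s.pct_polymorphic.iloc[0]) == 0


def test_summary_matches_direct_recount(rng):
    panel, _ = generate_genotype_panel(
        PanelSimParams(
            n_species=3,
            n_loci=12,
            n_individuals=6,
            amplification_failure_rate=0.15,
            monomorphic_rate=0.3,
            seed=21,
        )
    )
    s = summarize_panel(panel).set_index("species")
    for sp in panel.species:
        amp = poly = 0
        for locus in panel.loci:
            sizes = {a for _, al in panel.genotypes(sp, locus) for a in al}
            if sizes:
                amp += 1
                if len(sizes) > 1:
                    poly += 1
        assert s.loc[sp, "n_amplifying"] == amp
        assert s.loc[sp, "n_polymorphic"] == poly
        assert poly <= amp  # polymorphic loci are a subset of amplifying


def test_group_utility_means(fixtures):
    """Passerines average 68% polymorphic and 94% amplified; non-passerines
    42% polymorphic (source species and chicken excluded)."""
    means = utility_group_means(fixtures.species)
    assert means["passerine_mean_pct_polymorphic"] == 68
    assert means["passerine_mean_pct_amplified"] == 94
    assert means["non_passerine_mean_pct_polymorphic"] == 42


def test_species_meta_validation():
    with pytest.raises(ValueError):
        SpeciesMeta("x", -1, 28, "passerine")
    with pytest.raises(ValueError):
        SpeciesMeta("x", 0, 28, "waterfowl")


# --- Hardy-Weinberg ----------------------------------------------------------


def test_hwe_proportions_not_rejected():
    g = [(1, 1)] * 25 + [(1, 2)] * 50 + [(2, 2)] * 25
    res = hwe_exact_test(g)
    assert res.p > 0.9


def test_all_heterozygotes_rejected():
    g = [(1, 2)] * 20
    res = hwe_exact_test(g)
    assert res.p < 0.05


def test_monomorphic_not_applicable():
    assert hwe_exact_test([(1, 1)] * 10) is None


def test_multiallelic_monte_carlo_is_seeded(rng):
    g = [tuple(sorted(rng.integers(1, 5, size=2))) for _ in range(30)]
    r1 = hwe_exact_test(g, n_mc=2000, seed=7)
    r2 = hwe_exact_test(g, n_mc=2000, seed=7)
    assert r1.p == r2.p


def test_hwe_type_one_error_calibrated(rng):
    """Rejection rate under true Hardy-Weinberg sampling is at the nominal
    alpha within Monte-Carlo error plus the conservatism inherent to a
    discrete exact test."""
    n_rep, n = 3000, 100
    rej = 0
    for _ in range(n_rep):
        p = rng.uniform(0.2, 0.8)
        g = [
            tuple(sorted((1 if rng.random() < p else 2, 1 if rng.random() < p else 2)))
            for _ in range(n)
        ]
        res = hwe_exact_test(g)
        if res is not None and res.p <= 0.05:
            rej += 1
    rate = rej / n_rep
    se = (0.05 * 0.95 / n_rep) ** 0.5
    assert rate <= 0.05 + 3 * se
    assert rate >= 0.05 - (3 * se + 0.01)  # exact tests are conservative


# --- null alleles ------------------------------------------------------------


def test_balanced_heterozygosity_gives_zero():
    # Ho = 0.5 and He = 0.5 exactly: estimator returns 0
    g = [(1, 1)] * 25 + [(1, 2)] * 50 + [(2, 2)] * 25
    est = null_allele_freq(g)
    assert est.estimate == pytest.approx(0.0)
    assert not est.negative


def test_heterozygote_excess_reported_negative():
    g = [(1, 2)] * 18 + [(1, 1)] * 1 + [(2, 2)] * 1
    est = null_allele_freq(g)
    assert est.estimate < 0
    assert est.negative


def test_monomorphic_null_na():
    assert null_allele_freq([(1, 1)] * 10) is None


def test_null_frequency_recovery(rng):
    """The heterozygote-deficit estimator recovers a planted null-allele
    frequency of 0.2 to within 0.05 in the mean (n = 30 per panel)."""
    ests = []
    for _ in range(1000):
        sizes = [100, 102, 104, 106]
        freqs = rng.dirichlet(np.ones(4))
        g = []
        for _ in range(30):
            d = _draw_diploid(rng, sizes, freqs, 0.2)
            if d is not None:
                g.append(d)
        e = null_allele_freq(g)
        if e is not None:
            ests.append(e.estimate)
    assert abs(np.mean(ests) - 0.2) <= 0.05


# --- sex linkage -------------------------------------------------------------


def test_w_product_pattern_classified():
    """All females share a single 113-bp product absent from males while
    males segregate 134-145-bp alleles: a W-linked product over a Z
    locus."""
    g = [("F", (113,))] * 8 + [
        ("M", (134, 136)),
        ("M", (136, 138)),
        ("M", (145, 145)),
        ("M", (134, 145)),
        ("M", (138, 138)),
    ]
    assert infer_sex_linkage(g) == "Z-plus-W-product"


def test_heterozygous_female_means_autosomal():
    g = [("F", (100, 102)), ("M", (100, 102)), ("F", (102, 102))]
    assert infer_sex_linkage(g) == "autosomal"


def test_hemizygous_females_heterozygous_males():
    g = [("F", (100,)), ("F", (104,)), ("M", (100, 104)), ("M", (104, 104))]
    assert infer_sex_linkage(g) == "Z-linked"


def test_single_sex_inconclusive():
    assert infer_sex_linkage([("F", (100,))]) == "inconclusive"


def test_z_linkage_classifier_accuracy():
    """On simulated Z-linked panels with 20 individuals per sex the
    classifier is at least 99% correct."""
    correct = 0
    n_rep = 400
    for i in range(n_rep):
        panel, _ = generate_genotype_panel(
            PanelSimParams(
                n_species=1,
                n_loci=1,
                n_individuals=40,
                z_linked_loci=(0,),
                allele_count_range=(3, 6),
                seed=50000 + i,
            )
        )
        if infer_sex_linkage(panel.genotypes("sp00", "L00")) == "Z-linked":
            correct += 1
    assert correct / n_rep >= 0.99


# --- physical linkage --------------------------------------------------------


def test_published_chicken_positions_group_as_reported(fixtures):
    """Loci under 5 Mb apart on the same chicken chromosome chain into the
    two pairs and one triplet reported."""
    groups = flag_linked_loci(fixtures.chicken_positions())
    as_sets = {frozenset(g) for g in groups}
    assert frozenset({"CAM-02", "CAM-03"}) in as_sets
    assert frozenset({"CAM-05", "CAM-06", "CAM-07"}) in as_sets
    assert frozenset({"CAM-13", "CAM-23"}) in as_sets
    assert len(as_sets) == 3


def test_six_megabases_not_grouped():
    pos = {"a": ("chr1", 1_000_000), "b": ("chr1", 7_000_001)}
    assert flag_linked_loci(pos) == []


def test_linkage_groups_match_component_oracle(rng):
    for _ in range(20):
        pos = {
            f"L{i}": (f"chr{int(rng.integers(1, 4))}", float(rng.integers(0, 30_000_000)))
            for i in range(12)
        }
        groups = {frozenset(g) for g in flag_linked_loci(pos)}
        # independent oracle: connected components of the <=5 Mb graph
        names = list(pos)
        adj = {n: set() for n in names}
        for i, n1 in enumerate(names):
            for n2 in names[i + 1 :]:
                if pos[n1][0] == pos[n2][0] and abs(pos[n1][1] - pos[n2][1]) <= 5e6:
                    adj[n1].add(n2)
                    adj[n2].add(n1)
        seen, comps = set(), []
        for n in names:
            if n in seen:
                continue
            comp, stack = set(), [n]
            while stack:
                c = stack.pop()
                if c in comp:
                    continue
                comp.add(c)
                stack.extend(adj[c] - comp)
            seen |= comp
            if len(comp) > 1:
                comps.append(frozenset(comp))
        assert groups == set(comps)
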