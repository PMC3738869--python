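"""Cross-species marker utility statistics.

Summarises genotype panels (which loci amplify and which are polymorphic
per species), and implements the statistics used to characterise a
conserved marker set: heterogeneity chi-square tests on motif-count
tables, a paired t-test on longest uninterrupted repeat runs, OLS
regression of percent-polymorphic on DNA-DNA hybridisation distance,
a Hardy-Weinberg exact test, a heterozygote-deficit null-allele
estimator, sex-linkage inference from genotype/sex patterns, and a
<5 Mb physical-linkage flag.

A locus is "amplifying" in a species if at least one individual yields at
least one allele, and "polymorphic" if at least two distinct allele sizes
are observed across individuals - no frequency cutoff, matching usage on
small (4-individual) screening panels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class SpeciesMeta:
    name: str
    genetic_distance_zf: float
    genetic_distance_ch: float
    group: str  # "passerine" | "non-passerine"
    excluded_from_poly_stats: bool = False

    def __post_init__(self):
        if self.genetic_distance_zf < 0 or self.genetic_distance_ch < 0:
            raise ValueError("genetic distances must be >= 0")
        if self.group not in ("passerine", "non-passerine"):
            raise ValueError("group must be passerine or non-passerine")


@dataclass(frozen=True)
class StatResult:
    method: str
    statistic: float
    df: tuple[int, ...]
    p: float
    extra: dict = field(default_factory=dict)


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


class GenotypePanel:
    """Long-format allele-size calls: one row per (species, locus,
    individual) with allele1/allele2 (NaN = amplification failure) and the
    individual's sex (M/F/unknown)."""

    REQUIRED = ("species", "locus", "individual", "sex", "allele1", "allele2")

    def __init__(self, df: pd.DataFrame):
        missing = set(self.REQUIRED) - set(df.columns)
        if missing:
            raise ValueError(f"panel missing columns: {sorted(missing)}")
        self.df = df.reset_index(drop=True)

    @property
    def species(self) -> list[str]:
        return sorted(self.df["species"].unique())

    @property
    def loci(self) -> list[str]:
        return sorted(self.df["locus"].unique())

    def genotypes(self, species: str, locus: str) -> list[tuple]:
        sub = self.df[(self.df.species == species) & (self.df.locus == locus)]
        out = []
        for _, row in sub.iterrows():
            alleles = tuple(
                int(a) for a in (row.allele1, row.allele2) if pd.notna(a)
            )
            out.append((row.sex, alleles))
        return out

    @classmethod
    def read_tsv(cls, path) -> "GenotypePanel":
        """Read the wide interchange format: one row per individual with
        species and sex, then <locus>.1/<locus>.2 allele columns (blank =
        no amplification)."""
        wide = pd.read_csv(path, sep="\t")
        return cls.from_wide(wide)

    @classmethod
    def from_wide(cls, wide: pd.DataFrame) -> "GenotypePanel":
        locus_cols = [c for c in wide.columns if c.endswith(".1")]
        rows = []
        for _, r in wide.iterrows():
            for c1 in locus_cols:
                locus = c1[:-2]
                rows.append(
                    {
                        "species": r["species"],
                        "locus": locus,
                        "individual": r["individual"],
                        "sex": r.get("sex", "unknown"),
                        "allele1": r[c1],
                        "allele2": r.get(locus + ".2", np.nan),
                    }
                )
        return cls(pd.DataFrame(rows))

    def to_wide(self) -> pd.DataFrame:
        idx_cols = ["species", "individual", "sex"]
        w = self.df.pivot_table(
            index=idx_cols,
            columns="locus",
            values=["allele1", "allele2"],
            aggfunc="first",
        )
        w.columns = [f"{locus}.{1 if v == 'allele1' else 2}" for v, locus in w.columns]
        return w[sorted(w.columns)].reset_index()


def summarize_panel(panel: GenotypePanel) -> pd.DataFrame:
    """Per-species utility summary: % of loci amplifying, % of amplifying
    loci polymorphic, and mean alleles per polymorphic locus.  Percentages
    are rounded half-up to integers (printed-table precision)."""
    records = []
    for sp in panel.species:
        n_tested = n_amp = n_poly = 0
        allele_counts = []
        for locus in panel.loci:
            calls = [a for _, a in panel.genotypes(sp, locus)]
            if not calls:
                continue
            n_tested += 1
            sizes = sorted({s for a in calls for s in a})
            if sizes:
                n_amp += 1
                if len(sizes) >= 2:
                    n_poly += 1
                    allele_counts.append(len(sizes))
        if n_tested == 0:
            continue
        records.append(
            {
                "species": sp,
                "n_loci_tested": n_tested,
                "n_amplifying": n_amp,
                "n_polymorphic": n_poly,
                "pct_amplified": _round_half_up(100 * n_amp / n_tested),
                "pct_polymorphic": (
                    _round_half_up(100 * n_poly / n_amp) if n_amp else 0
                ),
                "mean_alleles_per_polymorphic_locus": (
                    float(np.mean(allele_counts)) if allele_counts else float("nan")
                ),
            }
        )
    return pd.DataFrame(records)


def utility_group_means(table: pd.DataFrame) -> dict:
    """Group means of the printed utility percentages.

    Polymorphism means exclude the source species (whose primers match it
    by construction) and any species flagged ``exclude_poly``; the
    amplification mean covers non-source passerines.  Values are rounded
    half-up, matching printed-table precision.
    """
    t = table.copy()
    pas = t[(t.group == "passerine") & (t.is_source == 0)]
    non = t[(t.group == "non-passerine") & (t.exclude_poly == 0)]
    return {
        "passerine_mean_pct_polymorphic": _round_half_up(
            pas[pas.exclude_poly == 0].pct_poly.mean()
        ),
        "passerine_mean_pct_amplified": _round_half_up(pas.pct_amp.mean()),
        "non_passerine_mean_pct_polymorphic": _round_half_up(non.pct_poly.mean()),
    }


def heterogeneity_chisq(table) -> StatResult:
    """Pearson chi-square (no continuity correction) on an r x c count
    table; df = (r-1)(c-1)."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    chi2, p, dof, expected = sps.chi2_contingency(t, correction=False)
    if (expected <= 0).any():
        raise ValueError("expected count of zero")
    return StatResult("pearson-chi2", float(chi2), (int(dof),), float(p))


def paired_t(x, y) -> StatResult:
    """Two-sided paired t-test; df = n - 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length vectors, n >= 2")
    d = x - y
    if np.allclose(d.std(ddof=1), 0):
        raise ValueError("zero variance of differences; t undefined")
    t, p = sps.ttest_rel(x, y)
    return StatResult("paired-t", float(t), (len(x) - 1,), float(p))


def regress_vs_distance(y, x, exclude: list[int] | None = None) -> StatResult:
    """OLS of y on x (slope F-test with df (1, n-2)); reports both multiple
    and adjusted R-squared."""
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if exclude:
        keep = [i for i in range(len(x)) if i not in set(exclude)]
        x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.allclose(x.std(), 0):
        raise ValueError("constant predictor")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return StatResult(
        "ols-slope-F",
        float(res.fvalue),
        (1, int(res.df_resid)),
        float(res.f_pvalue),
        extra={
            "slope": float(res.params[1]),
            "intercept": float(res.params[0]),
            "r_squared": float(res.rsquared),
            "adj_r_squared": float(res.rsquared_adj),
        },
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg and null alleles


def _diploid_calls(genotypes) -> list[tuple[int, int]]:
    calls = []
    for g in genotypes:
        alleles = g[1] if isinstance(g, tuple) and len(g) == 2 and isinstance(g[0], str) else g
        if len(alleles) == 1:
            calls.append((alleles[0], alleles[0]))
        elif len(alleles) == 2:
            calls.append(tuple(sorted(alleles)))
    return calls


def _log_table_prob(het: int, geno_counts: dict, allele_counts: dict, n: int) -> float:
    """Log conditional probability of a genotype table given allele counts
    (the classical exact-test measure)."""
    lg = math.lgamma
    val = lg(n + 1) + het * math.log(2)
    for a in allele_counts.values():
        val += lg(a + 1)
    val -= lg(2 * n + 1)
    for c in geno_counts.values():
        val -= lg(c + 1)
    return val


def hwe_exact_test(
    genotypes, n_mc: int = 10000, seed: int = 0
) -> StatResult | None:
    """Exact test of Hardy-Weinberg proportions.

    Two alleles: complete enumeration of heterozygote counts conditional on
    allele counts; p is the summed probability of all tables no more likely
    than the observed one.  More than two alleles: Monte-Carlo permutation
    of the allele vector with a fixed seed.  Returns None (not applicable)
    for a monomorphic locus.
    """
    calls = _diploid_calls(genotypes)
    if len(calls) < 5:
        raise ValueError("need at least 5 diploid genotypes")
    alleles = sorted({a for c in calls for a in c})
    if len(alleles) < 2:
        return None
    n = len(calls)
    geno_counts: dict = {}
    for c in calls:
        geno_counts[c] = geno_counts.get(c, 0) + 1
    allele_counts: dict = {a: 0 for a in alleles}
    for a, b in calls:
        allele_counts[a] += 1
        allele_counts[b] += 1
    obs_het = sum(v for (a, b), v in geno_counts.items() if a != b)

    if len(alleles) == 2:
        a1, a2 = alleles
        n1 = allele_counts[a1]
        lp_obs = _log_table_prob(obs_het, geno_counts, allele_counts, n)
        p = 0.0
        h = n1 % 2
        while h <= min(n1, 2 * n - n1):
            n11 = (n1 - h) // 2
            n22 = (2 * n - n1 - h) // 2
            if n11 >= 0 and n22 >= 0:
                gc = {(a1, a1): n11, (a1, a2): h, (a2, a2): n22}
                lp = _log_table_prob(h, gc, allele_counts, n)
                if lp <= lp_obs + 1e-9:
                    p += math.exp(lp)
            h += 2
        return StatResult("hwe-exact", float(obs_het), (1,), min(1.0, p))

    rng = np.random.default_rng(seed)
    pool = np.array([a for c in calls for a in c])
    lp_obs = _log_table_prob(obs_het, geno_counts, allele_counts, n)
    hits = 0
    for _ in range(n_mc):
        rng.shuffle(pool)
        gc: dict = {}
        het = 0
        for i in range(n):
            g = (pool[2 * i], pool[2 * i + 1])
            g = (min(g), max(g))
            gc[g] = gc.get(g, 0) + 1
            if g[0] != g[1]:
                het += 1
        if _log_table_prob(het, gc, allele_counts, n) <= lp_obs + 1e-9:
            hits += 1
    p = (hits + 1) / (n_mc + 1)
    return StatResult("hwe-exact-mc", float(obs_het), (1,), p, {"n_mc": n_mc})


@dataclass(frozen=True)
class NullAlleleEstimate:
    estimate: float
    negative: bool  # heterozygote excess; estimate reported as-is


def null_allele_freq(genotypes) -> NullAlleleEstimate | None:
    """Heterozygote-deficit null-allele estimator r = (He - Ho)/(He + Ho),
    where He is the expected heterozygosity from apparent allele
    frequencies.  None for a monomorphic locus."""
    calls = _diploid_calls(genotypes)
    if not calls:
        return None
    alleles = [a for c in calls for a in c]
    uniq = sorted(set(alleles))
    if len(uniq) < 2:
        return None
    n = len(calls)
    ho = sum(1 for a, b in calls if a != b) / n
    freqs = np.array([alleles.count(a) for a in uniq], dtype=float)
    freqs /= freqs.sum()
    he = 1.0 - float((freqs**2).sum())
    r = (he - ho) / (he + ho)
    return NullAlleleEstimate(r, r < 0)


# ---------------------------------------------------------------------------
# Sex linkage and physical linkage


def infer_sex_linkage(genotypes) -> str:
    """Classify a locus from genotype/sex patterns in a ZW system
    (females ZW, males ZZ).

    Returns "Z-linked" when no female shows two alleles while at least one
    male is heterozygous; "Z-plus-W-product" when additionally every female
    shares a single allele size that never appears in males (a W-linked
    product amplified in preference to the female's Z allele);
    "autosomal" otherwise; "inconclusive" if either sex is missing.
    """
    females = [a for s, a in genotypes if s == "F" and a]
    males = [a for s, a in genotypes if s == "M" and a]
    if not females or not males:
        return "inconclusive"
    female_two = any(len(set(a)) == 2 for a in females)
    male_het = any(len(set(a)) == 2 for a in males)
    if female_two or not male_het:
        return "autosomal"
    female_sizes = {a[0] for a in females if len(set(a)) == 1}
    male_sizes = {s for a in males for s in a}
    if len(female_sizes) == 1 and not (female_sizes & male_sizes):
        return "Z-plus-W-product"
    return "Z-linked"


def flag_linked_loci(
    positions: dict[str, tuple[str, float]], max_dist: float = 5_000_000
) -> list[list[str]]:
    """Groups of loci on the same chromosome within ``max_dist`` bp of a
    neighbour (single-linkage chaining).  Only groups of two or more loci
    are reported."""
    by_chrom: dict[str, list[tuple[float, str]]] = {}
    for name, (chrom, pos) in positions.items():
        by_chrom.setdefault(chrom, []).append((float(pos), name))
    groups = []
    for chrom in sorted(by_chrom):
        entries = sorted(by_chrom[chrom])
        cur = [entries[0]]
        for prev, nxt in zip(entries, entries[1:]):
            if nxt[0] - prev[0] <= max_dist:
                cur.append(nxt)
            else:
                if len(cur) > 1:
                    groups.append([n for _, n in cur])
                cur = [nxt]
        if len(cur) > 1:
            groups.append([n for _, n in cur])
    return groups
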