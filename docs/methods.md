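# Methods

This note documents the models and procedures implemented in camkit, the
parameter defaults and why they were chosen, the numerical decisions taken
where the underlying publications leave details open, and what the
synthetic-data tests do and do not establish.

## Repeat mining

A dinucleotide microsatellite is reported when a phase-consistent region
satisfies three criteria: more than ten consistent repeat units (default
`min_units = 11`), purity ≥ 0.90, and length > 18 bp (`min_region_len =
19`). Purity is defined as (bases covered by copies of the seed dimer at a
fixed phase) / (region length). The classic SSR-search tools state their
thresholds but not their extension algorithm, so camkit defines one
explicitly:

* **Seeds** are maximal uninterrupted runs of one dimer at one phase.
* **Extension** is bidirectional: a region absorbs the nearest consistent
  dimer on either side whenever the extended region's purity stays at or
  above the threshold, iterating to a fixpoint. A region always starts and
  ends on a consistent dimer.
* **Symmetry.** A forward-only greedy rule turned out to be strand
  asymmetric (segmentation depended on scan direction). The bidirectional
  rule, plus a reverse-complement-closed preference between phase-shifted
  twin candidates (e.g. the `GT`-phase and `TG`-phase readings of one
  tract), makes mining exactly mirror-symmetric: mining the reverse
  complement yields the mirrored locus set. This invariant is tested.
* Overlap resolution: same-class candidates keep the one with more units,
  then higher purity, then longer, then the preferred phase twin, then
  leftmost; across classes higher purity, then longer, then leftmost wins.
  `N` bases match no dimer, so they break runs and count as impurities.

Two unit counts serve different filters: `units` (all consistent dimers in
the region) drives the >10-unit mining criterion, while `longest_run`
(maximal consecutive phase-consistent copies) drives the ≥8-unit
conservation filter — interrupted tracts can pass the first and fail the
second.

Windows are the repeat tract plus up to 200 bp of flank per side,
truncated at contig ends (`flank_len = 200`).

## Conserved-pair selection

Windows are compared all-vs-all by Smith–Waterman local alignment with
match +1, mismatch −3, and affine gaps costing 5 + 2k (BLAST-style
defaults). Significance uses the Karlin–Altschul expectation
E = K·m·n·e^(−λS) with the documented ungapped +1/−3 constants λ = 1.374,
K = 0.711, and m·n the product of the two window lengths (pairwise mode; a
database mode summing the opposing window set is available). Reproducing
any particular BLAST build bit-for-bit is a non-goal: the *thresholding
logic* is the method, and λ, K and the threshold are configuration. The
threshold (default 1e−59) is inclusive — "E-59 or better" retains an exact
hit at the boundary.

Pairs must additionally carry ≥ 8 uninterrupted repeat units in *both*
loci and (by default) the same motif class; multi-hits resolve to
reciprocal best hits with ties broken by score then locus id. Repeat
tracts are not masked before alignment.

Under these constants the retention boundary sits at raw score ≈ 108 for
430-bp windows. Simulated window pairs at 5% flank divergence always pass;
by 30% divergence they always fail; 20% divergence straddles the boundary
(scores ≈ 95–130), so the test suite probes the separation at 5% vs 30%.

Alignment (both local here and semi-global below) is executed by
Biopython's `PairwiseAligner`; an independent plain-Python Gotoh dynamic
program in the test suite verifies scores on random sequences. Traceback
ties are resolved by the aligner's deterministic first-alignment rule
rather than a hand-specified diagonal-first order — only the score enters
any downstream decision, so this choice affects at most which of several
equally-optimal gap placements is displayed.

## Consensus hybrids

Each retained pair is aligned semi-globally (free end gaps, match +1,
mismatch −1, gap −2; end gaps are free because flank truncation can leave
the windows unequally trimmed). Every disagreement column — substitution
or gap — becomes a lowercase `n` (one `n` per gap column, so consensus
length equals alignment length; the conservative reading of replacing
gaps with an unknown base). Per-column source bases are preserved and the
repeat span is mapped through the alignment into consensus coordinates.

## Primer design

Candidates are enumerated exhaustively over start position and length
(18–25 nt) within a bounded flank (200 bp) on each side of the repeat;
a primer may never overlap the repeat span or a gap column. At each
mismatch column the two-fold IUPAC code covering the two source bases is
emitted; only two-species consensi are supported, so codes are always
two-fold.

Constraints (defaults): nominal Tm 57–63 °C, forward/reverse difference
≤ 1.0 °C (0.5 °C is the recommended-practice value and is configurable),
≤ 2 unknown positions per primer, ≤ 3 per pair, product length 80–600 bp.
Ranking prefers fewer degenerate bases, then smaller pair-Tm difference,
then shorter product, then leftmost position; only the 50 best-ranked
pairs are materialised. A cheap GC-count prescreen (margins −9/+5 °C,
covering the measured spread between the GC rule and the NN model on
18–25-mers with a buffer) avoids evaluating the NN model on hopeless
candidates; it cannot exclude a feasible one.

**Nominal Tm** uses the nearest-neighbour model (Allawi & SantaLucia
parameter set, 50 mM monovalent salt, 50 nM primer) with an unknown or
degenerate position contributing the average over its allowed resolutions
— the convention primer-design software applies to `n` bases. **True-Tm
deviation** of a resolved degenerate position is tracked separately with
fixed per-base offsets relative to that average: G +2.18, C +0.88,
A −0.55, T −2.41 °C. The mapping of the published "0.88/2.18 (G/C)" and
"0.55/2.41 (A/T)" pairs to individual bases is fixed by the published
worked extremes (two unknowns: −4.82 = 2×(−2.41) for T×2, +4.36 = 2×2.18
for G×2), leaving C = +0.88 and A = −0.55 as the only consistent
assignment; the offsets are configurable. Decoupling the offsets from the
NN model means the deviation analysis is reproduced regardless of NN
parameter-set choice.

Per-species identity counts a degenerate position as a match when the
species base is in the code's set, and is rounded half-up to integers
(matching printed precision, e.g. 18/21 → 86%). The expected product
length is the amplicon span located by degenerate-aware exact search; the
*minimum expected allele* is that length minus the annotated
repeat-structure length (the size if the repeat structure were fully
lost) — the definition that reproduces the published per-marker values.
Alternative degenerate resolutions are not re-checked against the design
criteria by default (the combinations expand as 2^d, at most 8 with the
three-code budget).

## Compatibility screen

Dimer potential of two primers is the maximum over all ungapped
antiparallel offsets of (matches − mismatches) in the overlap; hairpins
use the same scoring over self-folds with a minimum loop of 3 nt. This is
a documented stand-in for the published screening tool's scheme, which is
not restated in the literature; the conservative flagging threshold of 7
is retained. Degenerate positions score leniently by default (any
resolution may pair — degenerate bases are effectively unknowns), with a
strict all-resolutions policy available. On the packaged 24-marker panel
at threshold 7 the screen flags the three published combinations
(CAM-02R–CAM-15R, CAM-03R–CAM-20F, CAM-05R–CAM-06R, among six flags) and
finds no hairpins, matching the published screen qualitatively.

## Panel statistics

* A locus **amplifies** in a species when ≥ 1 individual yields ≥ 1
  allele; it is **polymorphic** when ≥ 2 distinct allele sizes occur. No
  frequency cutoff is applied — appropriate for the 4-individual screening
  panels the definition is used on. Percentages are rounded half-up to
  integers before group means, matching printed-table precision.
* Group means exclude the source species from polymorphism and
  amplification averages (its primers match it by construction) and the
  chicken from polymorphism statistics (backcross pedigree individuals,
  and the primers were engineered toward chicken).
* Heterogeneity tests are Pearson χ² without continuity correction on
  r×c count tables; the GC/CG class is excluded where empty. The published
  2×2 polymorphism contrasts (6.42 / 7.81 / 11.77) are *not* pinned: their
  exact pooling is not reconstructible from the printed tables.
* The regression of % polymorphic on ΔTm hybridisation distance is OLS
  with the slope F-test on df (1, n−2); both multiple and adjusted R² are
  reported. The published R² = 0.73 matches the **adjusted** value
  (multiple R² = 0.754), so the adjusted value is the pinned one.
* **Hardy–Weinberg**: exact test conditional on allele counts — complete
  enumeration of heterozygote counts for two alleles, seeded Monte-Carlo
  permutation of the allele vector (default 10,000 shuffles) for more. The
  test is conservative by discreteness: simulated type-I error at n = 100
  is ≈ 0.043 at α = 0.05, and the calibration test allows exactly this
  conservatism (α − 3·MC-s.e. − 0.01 lower bound).
* **Null alleles**: the heterozygote-deficit estimator
  r = (He − Ho)/(He + Ho) with He = 1 − Σp̂² from apparent allele
  frequencies. Under the null-allele model (heterozygote-with-null appears
  homozygous, null homozygote fails) this estimator's expectation is
  exactly the null frequency — apparent allele frequencies renormalise to
  q̂ᵢ = pᵢ/(1−r) and observed heterozygosity scales by (1−r)/(1+r), so the
  ratio telescopes to r. Negative estimates (heterozygote excess) are
  reported as-is with a flag. No multiple-testing correction is applied
  across loci by default.
* **Sex linkage** (ZW system: females ZW, males ZZ): a locus is Z-linked
  when no female shows two alleles while ≥ 1 male is heterozygous;
  additionally, when all females share one allele size absent from every
  male, the female product is classified as W-linked over a Z locus
  (a W product out-competing the Z allele in females). Single-sex panels
  are inconclusive.
* **Physical linkage**: loci on one chromosome chain into a group when
  consecutive positions are ≤ 5 Mb apart (single-linkage); such groups may
  show linkage disequilibrium.

## Synthetic data

The genome generator plants conserved cassettes — shared flanks (200 bp
per side) mutated in the second species at an i.i.d. per-base divergence
(default 5%, with 0.2% indels of 1–3 bp), around species-specific repeat
counts drawn uniformly from 12–25 units — plus species-specific decoy
cassettes, laid out two per contig with 60–160 bp pads. Repeats are
planted pure; a separate interruption parameter exists for purity stress
tests, so divergence, repeat count and purity can be varied independently.
Unit counts start at 12 so planted loci always pass the >10-unit mining
criterion; divergence 5% keeps conserved pairs safely inside the E-value
threshold (see above). Truth tables carry exact cassette coordinates, so
precision and recall of each stage are computable exactly.

The panel generator draws diploid genotypes under Hardy–Weinberg within
species × locus, with configurable allele counts (2–6 by default, 2-bp
ladder), null-allele frequency, whole-locus amplification failure,
Z-linked loci (hemizygous females) and W-product loci (all females share
one off-ladder size). All generators are pure functions of seed and
parameters.

**What passing tests show — and not.** The synthetic genomes have uniform
base composition, i.i.d. substitutions and pure planted repeats; real
genomes have compositional heterogeneity, repeat families, low-complexity
flanks and assembly artefacts, so the ≥95% planted-locus recovery measured
here bounds pipeline correctness, not field performance on real
assemblies. Likewise the genotype generator draws unlinked loci under
exact HWE; real panels add genotyping error, allele-size homoplasy and
population structure.

## Problem sizes and determinism

All stochastic tests run from fixed seeds. Documented scales: miner vs
brute-force scanner on 100 sequences of 1–1.2 kb (unit + acceptance
layers); aligner vs reference DP on ~360 random pairs of 10–50 nt;
planted-locus recovery over 20 seeded replicates at 5% divergence; HWE
calibration on 5,000 two-allele panels of n = 100 across the suite
(2,000 + 3,000); null-allele recovery over 2 × 1,000 panels of n = 30;
sex-linkage classification over 800 simulated Z-linked panels of 20
individuals per sex. These sizes keep the full suite fast while holding
Monte-Carlo error small relative to the tested margins.

## Known limitations

* E-values are desk-scale Karlin–Altschul arithmetic on extracted windows,
  not a seeded genome-scale search; genome-scale mining of real assemblies
  works but is memory- and time-naive.
* The dimer screen is a complementarity count, not a free-energy model.
* Consensus construction supports exactly two species.
* The Monte-Carlo HWE test uses the conditional-probability orderings of
  the classical exact test; mid-p variants are not implemented.
* `GC/CG` repeats are retained as a class but are expected to be
  essentially absent in avian genomes (one chicken locus, none in zebra
  finch, in the published counts).
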