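# Methods

## Coordinates and overlap semantics

All intervals are 0-based, half-open, BED-native; 1-based conventions
(SNP positions in association tables) are converted at the reader boundary.
Two intervals overlap iff they share at least one base (`a.start < b.end and
b.start < a.end`); there is no minimum-overlap-fraction option, because the
scientific question is whether an element touches a region at all.
Book-ended intervals do **not** overlap for counting but **are** unioned by
`merge_intervals` — the first is standard half-open semantics, the second is
the convenient convention when assembling disjoint query regions from
adjacent SNP windows.

Elements are deduplicated by id, not by coordinates: annotation databases
contain coordinate-identical distinct records, and each is a real element.
An element spanning two query regions counts once — the databases behind
published analyses do not disclose the alternative, and counting per touched
region would make the statistic depend on how the query happens to be split
by merging. Overlap is strand-blind.

The overlap index is a sorted-array search: query regions are merged to a
disjoint, sorted array, and an element hits iff the last region starting
before the element's end also ends after the element's start (disjoint
sorted regions have increasing ends, so that region carries the running
maximum end). This is exact and O(N log M) vectorised; an all-pairs
brute-force oracle and a pyranges cross-check pin it in the test suite.

## Building query regions from SNPs

Association outputs give point positions. How published analyses turned
suggestive SNPs into "genomic regions" (LD blocks? fixed windows?) is not
disclosed, so the package makes an explicit modelling choice: each SNP with
p < `p_max` (strict inequality, default 5×10⁻⁴) becomes a symmetric window
`[pos−1−flank, pos+flank)`, clipped to the chromosome, and windows within
`merge_gap` (default 0) are merged. The default flank of 75 kb makes a
singleton SNP yield a ~150 kb region — the scale of the published mean
region length — but this is a stand-in, not a reconstruction. Raising
`p_max` can only add covered bases (monotonicity, property-tested).

Region summaries report count, mean width (kb), total width (Mb) and width
SD (kb, sample n−1 denominator), each to one decimal as such tables print
them. SD of fewer than two regions is NaN; an empty set has NaN mean.

## The width/count-matched null

Each random set places one interval per query-region width, uniformly at
random among admissible starts: fully inside the chromosome, outside any
exclusion zone, and disjoint from intervals already placed in the same set.
Disjointness mirrors the query (merged association regions are disjoint) and
avoids double-covering bases; `allow_overlap` relaxes it. Widths are
preserved *exactly* as a multiset — the stated matching rule taken
literally.

Placement is rejection sampling with a per-region attempt cap (default
10,000); exhausting the cap raises an error naming the offending width,
never silently altering it. At the densities of interest (~9.3 Mb of
regions on a ~155 Mb chromosome, ~6% occupancy) rejection rates are
negligible. Within one set, widths are placed in descending order — a
deterministic order that keeps the cap unreachable in practice at much
higher packing densities; since every accepted configuration still draws
each start uniformly over its admissible set, single-interval start
positions are exactly uniform (chi-squared-tested).

Reproducibility: member *i* of an ensemble draws its generator from
`SeedSequence(seed, spawn_key=(i,))`, making it a pure function of
`(seed, i)`; any subset of iterations can be materialised independently and
bit-exactly matches a full run.

## Empirical p and the reporting convention

With k of N null iterations reaching a same-or-larger count, `p = k/N` and
the percentage is `100·k/N`. The comparison includes equality, so an
observed count of 0 gives p = 1. One shared null ensemble serves all
tracks: per iteration every track is evaluated against the same random set,
so per-track null vectors are comparable across element classes.

Published enrichment tables print p-values that equal the printed
percentages divided by 100 (24.5 → 0.25, 46.5 → 0.47), which implies k/N
rounded with **ties away from zero on the exact rational**: 0.245 in binary
floating point is slightly below 0.245 and bankers' rounding would print
0.24. `format_p` therefore recovers the rational (a `Fraction`, or the
nearest small-denominator rational behind a float) and rounds it half away
from zero. The conservative estimator (k+1)/(N+1), which cannot return 0,
is available behind `conservative=True` and off by default because the k/N
convention is what the reported tables use.

The null SD uses the sample (n−1) denominator — the statistical default,
noted in output metadata since published tables do not specify it. No
multiple-testing correction is applied across tracks; raw per-class
empirical p-values are reported.

## Gene-set bootstrap

Observed statistic: |candidates ∩ curated| after case-normalisation and
deduplication; genes outside the universe are dropped with a warning. Each
iteration draws |candidates| genes from the universe *without* replacement
(resampling of set membership); with-replacement draws sit behind a flag
because the term "bootstrapping" is ambiguous in this context. Without
replacement the null overlap is hypergeometric, and the Monte-Carlo p
converges to the tail P(X ≥ observed) — asserted in tests against exhaustive
subset enumeration at small sizes. The universe is user-supplied: no
default universe ships, because enrichment against an unstated universe is
not a well-posed question. The nine-gene curated methylation list is
packaged as a data file.

## Synthetic scenarios

The generator emulates the study conditions: a 155 Mb X-scale chromosome;
62 query regions totalling exactly 9.3 Mb (lognormal widths with CV 0.78,
rescaled to the exact total with the residual applied to the last region);
four annotation tracks whose default element counts (lncRNA 300, circRNA
2900, miRNA 160, superenhancer 5000) put the expected null in-query counts
near the published random-set means; an association table of uniform
background p-values plus tight (≤ 50 kb) signal clusters below the 5×10⁻⁴
threshold; and gene lists with an exactly planted candidate/curated overlap
(defaults: universe 800 ≈ the chrX gene count, curated 9, candidates 45,
overlap 3 — a configuration whose hypergeometric tail sits near 0.01, the
scale of the reported gene enrichment).

Planted truths are exact, not expected — region count, total width, element
count and gene overlap are enforced — so downstream tests can assert
equalities. Enrichment is planted by reweighting the element *midpoint*
density (weight `enrichment_fold` inside query regions, 1 outside), giving
a closed-form expected in-query midpoint fraction `f·W/((L−W)+f·W)` used in
the calibration tests; fold 0 plants strict depletion, with straddling
elements clipped back to the flanking gap. Element widths are uniform in
class-typical ranges (miRNA 22–100 bp, circRNA 0.2–5 kb, lncRNA 0.2–20 kb,
superenhancer 10–50 kb).

What the generator does **not** emulate: real annotation-database coordinate
distributions (clustering of genes, CpG islands, repeat structure), LD
between SNPs, GC- or gene-density covariates of element placement, and
assembly-gap structure (exclusions default to none but can be planted or
supplied as BED). Passing calibration and power tests therefore show the
*statistical machinery* is correct and well-calibrated under the stated
null — they do not show that a uniform-placement null is the right null for
any particular real annotation class, which is a scientific judgement the
user must make (e.g. by supplying exclusion zones or a different null
upstream).

## Problem sizes used in the test suite

Calibration uses 500 scenario replicates at 200 iterations each with a
2,000-element track; power uses 100 replicates at 1,000 iterations with a
10-fold planted circRNA enrichment at full study geometry; the gene
bootstrap convergence check uses 10⁵ draws on a 10-gene worked example with
the exact tail from all 252 subset enumerations. These sizes give
comfortable statistical resolution (3-SE bands, KS at α = 0.01) while the
whole suite runs in a few minutes on one CPU.

## Known limitations

- The region-construction flank/merge scheme is a modelling stand-in for an
  undisclosed procedure; conclusions sensitive to region boundaries should
  be checked across flank choices.
- The sampler preserves widths exactly; published random-set summaries hint
  at a sampler that re-merged colliding regions (mean random width slightly
  above the query mean). This package does not emulate that behaviour.
- Empirical p has resolution 1/N; at N = 1000 the smallest nonzero p is
  0.001 and p = 0 means only "none of N iterations qualified" (the
  conservative flag gives a strictly positive bound instead).
- Single-chromosome by design: no multi-chromosome or genome-wide sampling.
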