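# xregenrich

Permutation enrichment of non-coding annotation elements in chromosome-X
disease-associated regions.

## The problem

X-chromosome association studies of primary biliary cholangitis (PBC) yield
a set of genomic regions around suggestively associated SNPs (nominal
p < 5×10⁻⁴). Two questions follow:

1. Do these regions carry **more non-coding elements** — lncRNAs, circRNAs,
   miRNAs, superenhancers — than equally sized random stretches of the same
   chromosome?
2. Are the genes pinpointed by the association signals **enriched in a
   curated list of differentially methylated PBC genes**?

`xregenrich` implements both tests as a reusable, fully tested pipeline for
anyone running region-level annotation enrichment on a single chromosome,
plus a synthetic-data generator so that every stage can be exercised and
calibrated without any external download.

## The statistics

**Region test.** Let the query be regions R₁…Rₙ with widths w₁…wₙ on a
chromosome of length L. The null is a *width/count-matched* randomization:
each of N random sets (default N = 1000) places n disjoint intervals with
exactly the widths {wᵢ} uniformly at random on the chromosome, avoiding any
exclusion zones. For each annotation track the test statistic is the number
of elements sharing ≥ 1 base with ≥ 1 query region (each element counted
once). With k = #{random sets with a same-or-larger count}, the empirical
p-value is

&nbsp;&nbsp;&nbsp;&nbsp;p = k / N

reported together with the null mean and SD (n−1 denominator) and the
percentage 100·k/N. One shared ensemble of random sets is used for all
tracks. Reported p-values are rounded on the exact rational k/N with ties
away from zero (245/1000 → 0.25), matching the convention used in published
enrichment tables. A conservative (k+1)/(N+1) estimator is available behind
a flag.

**Gene test.** With candidate genes C, curated genes M and a universe U,
the observed statistic is |C ∩ M|; each bootstrap iteration draws |C| genes
from U without replacement and p is the fraction of draws with a
same-or-larger overlap — converging to the hypergeometric tail P(X ≥ |C ∩ M|).
The nine-gene curated methylation list ships with the package
(`load_pbc_methylation_genes()`).

## Worked example

```python
import xregenrich as x

# a synthetic X-scale study: 62 query regions totalling 9.3 Mb on a 155 Mb
# chromosome, with four null annotation tracks
sc = x.SyntheticScenario(seed=7)
model = x.make_chromosome(sc)
query = x.make_query_regions(sc, model)
tracks = [x.make_annotation_track(sc, model, query, s, stream=i)
          for i, s in enumerate(sc.track_specs)]

res = x.RegionEnrichment(query, tracks, model).fit(n_iter=1000, seed=7)
print(res.summary())
```

prints

```
Region enrichment vs width/count-matched random sets
chromosome: chrX (155,000,000 bp, 0 exclusion(s)); n_iter=1000, seed=7, p = k/n, null SD: sample (n-1)
          Set Regions (n) Regions (kb) DNA content (Mb) lncRNA (n) circRNA (n) miRNA (n) superenhancer (n)
        query          62        150.0              9.3         14         188        11               349
  random mean        62.0        150.0              9.3       19.2       177.1       9.7             360.2
    random SD           -            -                -        4.2        12.7       3.1              17.7
% >= observed           -            -                -       91.7        19.5      36.5              74.9
      p value           -            -                -       0.92        0.20      0.37              0.75
```

Row by row: the query geometry (62 regions, mean 150 kb, 9.3 Mb of DNA);
the random sets reproduce that geometry exactly (widths are preserved, only
placement varies); then per track the observed element count, the null mean
and SD over 1000 random sets, the percentage of random sets with a
same-or-larger count, and the empirical p. Here all four tracks were
generated under the null, and indeed none is significant.

The gene-set bootstrap on the same scenario's synthetic gene lists:

```python
universe, curated, candidates = x.make_gene_universe(sc)
g = x.GeneSetEnrichment(candidates, curated, universe).fit(n_iter=10_000, seed=7)
print(g.summary())
```

```
Gene-set bootstrap enrichment
universe=800, curated=9, candidates=45
observed overlap: 3
null overlap mean: 0.497
p (overlap >= observed, 10000 draws, seed 7): 0.0101
```

Three of the 45 candidates sit in the 9-gene curated list, against a null
expectation of ~0.5 — a significant enrichment at this planted effect size.

The same analyses are available from the shell:

```sh
xregenrich simulate --preset table3 --seed 7 --out-dir sim/
xregenrich regions  --snps sim/snps.tsv --chrom-model sim/chromosome.tsv --out sim/regions.bed
xregenrich tracks   --query sim/query.bed --track circRNA=sim/track_circRNA.bed \
                    --chrom-model sim/chromosome.tsv --n-iter 1000 --seed 7 \
                    --out table.tsv --json-out run.json
xregenrich genes    --candidates sim/genes_candidates.txt \
                    --universe sim/genes_universe.txt --n-iter 10000 --seed 7
```

`run.json` is a sidecar with the full null-count vectors and run metadata
(seed, versions), so any reported p can be recounted from the stored null.

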