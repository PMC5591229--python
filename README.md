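# vocnet

Classify plant species by the volatile organic compounds (VOCs) they emit,
using bipartite-network projections and multi-algorithm community detection.

Leaf emissions measured by PTR-ToF-MS arrive as a species × protonated-mass
matrix of intensities in normalized counts per second (ncps). The series are
strongly non-Gaussian: mostly zeros, a low flat plateau, and rare large
spikes — a compound is typically emitted in quantity by only a few species.
`vocnet` turns such a matrix into networks of species (and of compounds) and
groups the species into communities that share emission chemistry. It is
aimed at ecologists and metabolomics groups who want a reproducible,
statistics-first alternative to eyeballing heatmaps.

## Method

1. **Binarize.** The emission matrix becomes a binary incidence matrix
   *A*(*p*, *f*): *a*ᵢⱼ = 1 iff species *i* emits mass *j* above threshold.
   Two schemes: a fixed intensity cutoff (e.g. 1 ncps), or the per-VOC
   third-quartile rule (only emissions strictly above that compound's Q₃
   across species count — a far more severe pruning under which
   non-emitting species become isolated).
2. **Project.** *A* defines a two-layer plant–VOC graph. The species graph
   is the one-mode projection with weights *w*ᵢⱼ = number of shared VOCs
   (off-diagonal of *AAᵀ*); the compound graph uses *AᵀA* (plants emitting
   both).
3. **Measure.** Density *D* = 2*E*/(*N*(*N*−1)), degree *k*ᵢ, strength
   *s*ᵢ = Σⱼ *a*ᵢⱼ*w*ᵢⱼ, the Barrat weighted clustering coefficient
   *c*ᵢʷ = 1/(*s*ᵢ(*k*ᵢ−1)) Σⱼₕ ((*w*ᵢⱼ+*w*ᵢₕ)/2) *a*ᵢⱼ*a*ᵢₕ*a*ⱼₕ,
   and CCDFs of degree and strength.
4. **Cluster.** Weighted modularity
   *Q* = (1/2*m*) Σᵥw [*A*ᵥw − *k*ᵥ*k*w/(2*m*)] δ(*c*ᵥ, *c*w)
   is optimised by four independent algorithms — Louvain (BL), fast greedy
   agglomeration (FG), walktrap random walks (WT), label propagation (LP) —
   across a sweep of edge-weight filters. Only clusterings on which the
   algorithms agree (pairwise adjusted Rand index) are treated as robust.
5. **Characterize.** Each cluster is reported with its family composition,
   member list, most-shared ("clustering") VOCs and top-strength species.

A synthetic-data generator reproduces the zero-inflated, spike-dominated
structure of real emission matrices with a planted block partition, so the
whole pipeline can be validated against a known truth.

## Worked example

```bash
vocnet synth --seed 5 --out-dir data
vocnet detect --matrix data/matrix.csv --algorithm all --seed 0 --out part.json
vocnet sweep  --matrix data/matrix.csv --sweep-thresholds 0,0.3,0.6,1 --out sweep.tsv
vocnet report --partition part.json --matrix data/matrix.csv \
              --families data/families.tsv --voc-classes data/voc_classes.tsv \
              --out report.md
```

which prints

```
min pairwise ARI 0.762 (robust); retained walktrap with Q=0.3150
wrote 4-row sweep to sweep.tsv
top-strength species: sp032 (s=312), sp027 (s=286), sp006 (s=272), ...
```

and `sweep.tsv` holds the filtering sweep (community counts per algorithm,
surviving edges E, non-isolated nodes N, connectivity):

```
FG  WT  BL  LP  w_resc  E     N   is.connected
31  31  31  31  0.0     2124  81  True
37  37  37  37  0.3     755   75  True
65  63  64  63  0.6     289   49  False
100 104 100 101 1.0     11    11  True
```

At no filtering all four algorithms find 31 communities: the three planted
emission blocks plus 28 singleton species that emit nothing above
threshold (the "isolated" pseudo-cluster, 25.7% of species). `report.md`
then shows, e.g., that cluster 1 (37 species, 33.9%) is held together by
terpene-fragment masses emitted by 22–27 of its members, while cluster 2
aggregates around sulfur-compound masses — the chemistry planted by the
generator, recovered from the emissions alone.

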