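# dgcd — directed graphlet correlation distance for bipartite networks

Ecologists routinely pool bipartite species interaction networks (plant–
pollinator, host–parasite, seed-dispersal …) that were created by different
research teams, and then read topological patterns off the pooled
collection. Much of the topology spread in such collections can come from
*how* each team built its networks rather than from ecology. This package
quantifies that spread — **topological heterogeneity** — for any collection
of bipartite unweighted networks, and lets you contrast the dispersion of
networks grouped by domain, subgroup, or the publication that produced
them.

## Method

Each network is made directed by orienting every edge from one node set to
the other (a pure convention; all distances are invariant to flipping it —
this is a tested property). For every node the package counts how often it
occupies each of the 13 automorphism **orbits** of the six directed
graphlets on 2–3 nodes (single edge G0, directed path G1, in-star G2,
out-star G3, cycle G4, feed-forward triangle G5). Graphlets are *induced*
subgraphs; in a uniformly oriented bipartite graph only G0, G2 and G3 can
occur, so their 6 orbits carry all the signal and the remaining 7 orbit
columns are identically zero.

A network's **directed graphlet correlation matrix** (DGCM) holds the
Spearman rank correlation between every pair of per-node orbit-count
vectors. The distance between networks *K_i* and *K_j* is

> DGCD(K_i, K_j) = sqrt( Σ_{n<m} ( DGCM_{K_i}(n,m) − DGCM_{K_j}(n,m) )² ),

the Euclidean distance between the strict upper triangles — over all 13
orbits (**DGCD-13**) or over the 6 bipartite-realizable orbits
(**DGCD-6**). Identically zero orbit columns are handled by appending one
pseudo-node with count 1 in every orbit before ranking, so two empty
columns correlate at exactly +1 and add nothing to any distance.

Heterogeneity of a group of networks is the mean (and median) of its
within-group pairwise distances; the publication contrast compares the
network-count-weighted mean of per-publication dispersions with the mean
distance among networks that are each the sole product of their
publication. Collections are visualized by metric MDS (SMACOF) on the
distance matrix.

A synthetic corpus generator produces bipartite networks from a weighted
random model (log-normal node weights, tunable connectance and degree
skew) with a two-level "publication effect": publications draw their own
topology parameters around a base configuration, and their networks jitter
those again, so between- and within-publication heterogeneity can be
dialed independently and recovered by the pipeline.

## Worked example

```python
from dgcd import (PublicationEffectConfig, generate_publication_collection,
                  pairwise_dgcd, publication_weighted_mean,
                  between_group_mean, embed_mds)

cfg = PublicationEffectConfig(n_publications=4, networks_per_publication=6,
                              between_sd=0.5, within_sd=0.1, seed=11)
records = generate_publication_collection(cfg)

d13 = pairwise_dgcd(records)                      # 24 x 24 DGCD-13 matrix
pubs = {r.id: r.publication_id for r in records}
print(f"within-publication weighted mean DGCD-13:  "
      f"{publication_weighted_mean(d13, pubs):.3f}")
print(f"between-publication mean DGCD-13:          "
      f"{between_group_mean(d13, pubs):.3f}")
print(f"2-D metric MDS stress: {embed_mds(d13, dims=2, seed=0).stress:.3f}")
```

prints

```
within-publication weighted mean DGCD-13:  0.362
between-publication mean DGCD-13:          0.450
2-D metric MDS stress: 0.898
```

Networks from the same publication are on average closer to each other
(0.362) than to networks from other publications (0.450): the generator's
publication effect (`between_sd=0.5 > within_sd=0.1`) shows up directly in
the dispersion statistics. The stress value is the raw SMACOF residual of
squeezing the 24-network distance matrix into the plane.

The same pipeline runs from the shell:

```sh
dgcd simulate --out corpus --n-publications 6 --networks-per-publication 10
dgcd run --networks-dir corpus/networks --metadata corpus/metadata.csv \
         --out results --variant both
```

writing distance matrices (`dgcd13.csv`, `dgcd6.csv`), dispersion tables
per domain/subgroup/publication, MDS coordinates and an embedding plot.
Real corpora are consumed the same way: a directory of incidence-matrix
CSVs (row labels = one node set, column labels = the other, cells
binarized at > 0) plus a metadata CSV with columns
`network_id,domain,subgroup,publication_id`.

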