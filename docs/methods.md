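# Methods

## Scope and model

The package measures topological heterogeneity in collections of bipartite
unweighted networks. Every input is reduced to edge presence (cells > 0),
restricted to its giant (largest weakly connected) component, and required
to keep at least `min_side = 5` nodes on **each** side — small fragments
are hard to classify and would inflate apparent heterogeneity. The giant
component is extracted *before* the size filter so that a network whose
usable component is tiny cannot slip through on its raw node counts. Ties
between equal-size components break to the component containing the
lexicographically smallest node label, purely for determinism.

Edges are oriented uniformly: one whole node set is the "from" side, the
other the "to" side (`cols_to_rows` by default for incidence matrices,
i.e. column species point at row species). The choice is conventional:
flipping the orientation of every network simultaneously permutes orbit
columns identically in all networks and leaves every pairwise distance
unchanged. This invariance is asserted by a dedicated test rather than
assumed.

## Orbits and counting

The six directed graphlets on 2–3 nodes carry 13 automorphism orbits,
numbered G0 = {0 source, 1 target}, G1 (directed path) = {2, 3, 4},
G2 (in-star) = {5 periphery, 6 center}, G3 (out-star) = {7 center,
8 periphery}, G4 (cycle) = {9}, G5 (feed-forward) = {10, 11, 12}. Which of
the two stars is "G2" is a labeling choice with no observable consequence:
any orbit relabeling applied uniformly to all networks leaves every
distance unchanged, because distances compare matched matrix entries. The
in-star/out-star assignment used here keeps the star whose center is a
*target* node at the lower orbit pair, consistent with counting a target
node at orbit 6.

Graphlets are induced subgraphs, so for uniformly oriented bipartite
inputs closed forms hold and counting is O(Σ deg²): a source u with
out-degree d⁺ contributes d⁺ to orbit 0, C(d⁺, 2) to orbit 7, and
Σ_{v∈out(u)} (d⁻(v) − 1) to orbit 5; symmetrically for targets (orbits 1,
6, 8). The brute-force counter used as the test oracle instead enumerates
every 2- and 3-node subset and classifies the induced subgraph by its
multiset of within-subgraph (in, out) degree pairs; that classification is
itself verified exhaustively against VF2 isomorphism over all digraphs on
2–3 labeled nodes, so the oracle shares no code path or combinatorial
identity with the production counter.

## DGCM and DGCD

The DGCM is the matrix of Spearman correlations (average ranks on ties —
ties are pervasive because most counts are zero) between orbit-count
columns, taken across nodes. Seven of the 13 columns are identically zero
for bipartite inputs, leaving the correlation undefined. Default remedy:
append one pseudo-node whose count is 1 in every orbit before ranking.
Two all-zero columns then correlate at exactly +1 in every network and
contribute exactly 0 to every distance, so DGCD-13 and DGCD-6 order
collections identically up to the small cross terms between zero and
non-zero columns. The alternative `zero_correlation` policy defines any
correlation involving a zero-variance column as 0 instead; it exists so
results can be matched against conventions of other implementations. If a
column is constant even after the pseudo-node (every node tied at count
1 — impossible for connected bipartite inputs, but reachable for exotic
hand-built count matrices) its correlations are set to 0.

DGCD is the Euclidean distance between strict upper triangles of two
DGCMs, square root included — "Euclidean distance" is taken as the
operative definition. Pairwise computation stacks each network's upper
triangle into a vector and uses Euclidean `pdist`, which makes the
pseudometric axioms (symmetry, zero diagonal, triangle inequality)
structural rather than numerical accidents. DGCD-13 ≥ DGCD-6 holds
pairwise because the 13-orbit triangle strictly contains the 6-orbit one.
Tolerances used in tests: 1e-9 absolute on DGCM entries, 1e-8 on
distances.

## Dispersion statistics

Within-group dispersion is the mean (and median) over the C(n, 2)
unordered within-group pairs; groups with one network have no pairs and
are excluded with a warning, not counted as zero-dispersion. The
publication contrast reports (a) the mean of per-publication mean
distances over publications with ≥ 2 networks, weighted by the number of
networks each contributed (a `pairs` weighting is available as the natural
sensitivity variant), and (b) the mean pairwise distance among networks
that are each the sole network of their publication. The whole-domain
dispersion row is reported even when the domain forms no coherent
subgrouping, so a collection-wide heterogeneity number always exists.

## MDS

Metric MDS uses SMACOF stress majorization implemented in-package:
4 random restarts seeded from one master seed, Guttman transform updates,
convergence when the relative stress change drops below 1e-6 or after 300
iterations, best (lowest raw stress) restart kept, coordinates centered.
Raw stress Σ_{i<j} (d̂_ij − d_ij)² is reported. The implementation is
in-package because the analysis asserts two properties an off-the-shelf
call does not expose: the per-iteration stress trace (majorization
guarantees it is non-increasing, and a test asserts it) and bit-level
determinism for a fixed seed; `sklearn.manifold.smacof` serves as an
independent cross-check in the test suite. Distance matrices exactly
realizable in the plane (e.g. a 3-4-5 triangle) are recovered at stress
≤ 1e-6.

## Synthetic corpora

One network: sources and targets receive i.i.d. log-normal weights with
sigma = `degree_skew` (0 = Erdős–Rényi-like homogeneity; larger = heavier
degree tails, the dominant topological axis in real bipartite ecological
webs), and edge (u, v) appears independently with probability
`connectance · w_u x_v / (w̄ x̄)` capped at 1, so expected connectance
matches the knob. The giant component is extracted and the 5-per-side
filter enforced by resampling, at most 100 attempts before an explicit
generation error. Defaults — 25 × 25 species, connectance 0.15,
degree_skew 0.75 — describe a mid-sized field-observed interaction web.

Collections: publication p draws its own connectance (log-normal
multiplicative jitter, clipped to [0.01, 1]), degree skew (additive,
floored at 0) and side-size multipliers from the base configuration with
spread `between_sd`; each of its networks re-jitters those with
`within_sd`. Defaults `between_sd = 0.5`, `within_sd = 0.1` encode a
strong publication effect: same-publication networks are much more alike
than cross-publication ones, which the pipeline's dispersion statistics
recover (and fail to find when both spreads are 0). The generator emulates
only the *topological signature* of construction differences — parameter
dispersion — not species identities, abundances or sampling processes; a
pass on synthetic corpora therefore demonstrates that the statistics
detect parameter-level heterogeneity, not that any particular ecological
mechanism produced it in real data.

## Problem sizes

The test suite and the acceptance script run on desk-scale corpora chosen
as the package's own defaults: oracle equivalence on 200 random graphs
with 5–12 nodes per side, pseudometric and invariance checks on
50-network collections, publication-effect recovery on 20 replicate
corpora of 6 publications × 10 networks, and an 80-network corpus
(60 multi-publication + 20 singleton) for the end-to-end reproduction
script.

## Known limitations

- Only 2–3-node graphlets; the 4-node extension (129 orbits) is out of
  scope, as are weighted and bidirectional-edge graphlets.
- Spearman is the only correlation offered; no graphlet-degree-
  distribution agreement metrics and no motif/null-model analysis.
- Dispersion statistics are descriptive; no inferential test compares
  group dispersions.
- The generator does not produce nested or modular structure beyond what
  degree heterogeneity induces, and it is not fitted to any real corpus.
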