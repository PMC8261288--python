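# Methods

## Model and assumptions

The package operates on simple, unweighted, undirected graphs with opaque
string node identifiers. Communities are modelled as *covers*: lists of
node sets that may share nodes and need not span the graph. The detection
pipeline is edge-based — the primary clustering objects are edges, and the
node cover is derived from the edge assignment — because edge clustering
makes overlapping nodes emerge naturally rather than by post-hoc
assignment.

All neighborhoods are open: `N(u)` never contains `u`. This matters for
the similarity `sim(u,v) = |N(u)∩N(v)| / |N(u)∪N(v)|`; with open
neighborhoods two endpoints of an isolated edge have similarity 0, and the
worked fixture value `sim(8,13) = 1/3` comes out as stated.

## Seed selection

The influence `F(u)` multiplies each neighbor interaction
`D(u)D(v)/(1−sim)²` by `(1+C(u))(1+C(v))`, boosting nodes whose
neighborhoods are internally well-knit. Selection proceeds against a
*working* copy of `F`:

- a node is a candidate when its working F beats every neighbor's working
  F, with exact ties broken in favor of the node that precedes the other
  in canonical id order (`(len, str)` key, which orders decimal labels
  numerically and is total on arbitrary strings);
- repeatedly, the strongest candidate is accepted unless its similarity to
  an already-accepted seed exceeds `alpha` (the test is `≤ alpha` passes,
  i.e. the boundary value is accepted), in which case it is permanently
  rejected;
- on acceptance, the seed's neighbors' working F is multiplied by
  `min(GF, 1/GF)` where `GF` defaults to `|E|/|V|`. Taking the min ensures
  the "magnetic interference" always *reduces* neighbor candidacy even
  when the edge/node ratio exceeds 1.

Evaluating candidacy against the working (damped) influence, rather than
freezing the candidate list up-front, is a deliberate design choice: it is
the only reading under which the structural test cases behave sensibly —
a complete graph yields exactly one seed for *any* `alpha`, two triangles
joined by a bridge yield one seed per triangle despite their influence
values being exactly tied by symmetry, and each well-separated planted
community obtains its own seed even when its local maximum is initially
dominated by a neighbor in an adjacent community. Rejected candidates keep
their undamped working F and continue to suppress their neighbors; a
rejected candidate is by construction a near-duplicate of an accepted
seed, so its surroundings belong to an already-seeded community.

A consequence worth knowing: every connected component containing at least
one edge produces at least one seed (its working-F maximum is always a
candidate, and cross-component similarity is 0 ≤ alpha), so uncovered
nodes arise only from isolated nodes.

## Central edge sets

Seed `u` claims incident edges with `sim(u,v)` strictly above its mean
neighbor similarity. Degenerate case: if every neighbor similarity is
equal (e.g. a star hub, all sims 0) the strict rule selects nothing, and
the maximum-similarity edges are taken instead — a seed must nucleate a
nonempty community. Seeds are processed in acceptance order and an edge
already claimed stays with its first claimant; allowing shared central
edges would change the denominators of the mean distance below.

## Edge distance and non-central clustering

`Dis(a,b) = Jacard(a,b) × link(a,b)` with:

- `link`: 0 for identical edges, else `1 + d(x,y)` minimized over endpoint
  pairs (adjacent edges are at 1, reserving 0 for identity), `inf` across
  components;
- `Jacard`: Jaccard *distance* between closed edge neighborhoods
  (endpoints plus all their neighbors). Closed neighborhoods make the
  distance 0 exactly for structurally twin edges.

A non-central edge joins the central edge set minimizing the mean
`Dis`; ties go to the lowest community index; an edge at infinite distance
from every set (a component with no central edges — constructible by API,
not produced by the full pipeline) stays unassigned and is reported as
such, lowering the coverage rate rather than being force-assigned.

The older baseline distance (`ces_baseline.dnc` over the neighborhood
similarity `elc`) is included for the comparison demo only. Note its
`DNC(e, CE) = Σ x_j(S−x_j)/S` is *identically zero* when `|CE| = 1`, and
zero whenever `e` is ≥ 3 hops from every edge of `CE` — the blind spot
that motivates the combined distance. The self-similarity `ELC(e,e)` is
*not* 1 in general (it is 1 only when the endpoints are twins); the
formula is implemented literally and no unit-self-similarity is assumed.

## Overlap pruning

Per pass, with a snapshot of memberships: for each overlapping node `n`
(canonical order) and each of its communities `j`, the connection ratio
`con(n, core_j) / Σ_k con(n, core_k)` is computed, where `core_j` is the
set of nodes belonging only to `j`. Memberships with ratio below `prune`
are dropped; if *all* ratios fall below the threshold the node keeps only
the best-ratio community (ties to the lowest index). Guards: communities
below `min_prune_size` (default 3) are never pruned — their sizes are
tracked live within a pass, which also guarantees no community is ever
emptied; a zero denominator (no reachable cores) keeps all memberships; a
node never ends with zero memberships. Passes repeat to a fixed point with
a 100-iteration cap (in practice 1–3 passes suffice).

## Parameters

| name | default | meaning |
|------|---------|---------|
| `alpha` | 0.1 | seed similarity cap in [0,1]; larger admits more, finer-grained communities |
| `prune` | 0.3 | membership ratio threshold in [0,1]; larger prunes overlaps harder |
| `gf` | `|E|/|V|` | CMI coefficient; applied as the damping factor `min(gf, 1/gf)` |
| `min_prune_size` | 3 | communities smaller than this are pruning-exempt |
| `max_prune_iters` | 100 | fixed-point cap |

`alpha` and `prune` are data-dependent (sparse social networks like the
karate club want small `alpha` ≈ 0.1–0.3); the CLI therefore requires them
explicitly rather than promising a universal default. The monotone effect
of `prune` on the overlapping rate is a tested invariant.

## Numerical choices

- The `(1−sim)⁻²` singularity for twin nodes (sim = 1) is handled by
  capping sim at `1 − 1e−9`; influence stays finite and monotone in
  similarity.
- All tie-breaks (seed order, community argmin/argmax) use the canonical
  `(len, str)` node key or the lowest community index; the pipeline is
  bit-deterministic for a fixed graph and parameter set.
- Extended modularity sums over ordered node pairs within each community,
  including `v = w` with `A_vv = 0`; uncovered nodes are excluded from all
  sums. The whole graph as one community scores exactly 0.
- Overlapping NMI uses the LFK construction with log base 2; the
  admissibility condition `h(P11)+h(P00) ≥ h(P01)+h(P10)` guards against
  spurious anti-correlated matches, falling back to `H(X_k)`; communities
  with zero entropy (whole universe) contribute 0 to the normalized sum,
  the continuity limit.

## Synthetic benchmark

`generate_planted` emulates the LFR parameter surface (`n`, `k_avg`,
`mu`, `on`, `om`, `n_comm`) with a Bernoulli planted partition: round-robin
equal-size base communities, `on` nodes (spread one per stride) with
`om − 1` extra memberships, and per-pair edge probabilities `p_in` /
`p_out` calibrated so the expected degree is `k_avg` with an expected
outside-community share of `mu`. What it deliberately does **not**
emulate: LFR's power-law degree and community-size distributions, degree
cutoffs (`maxk`), or the realized edge counts of any particular LFR draw.
Recovery results on these graphs therefore demonstrate correctness of the
pipeline under homogeneous community structure, not performance on
heavy-tailed real PPI topology. Test problem sizes (n = 80–500, ≤ 20
replicate seeds) keep exact ground truth and sub-second runs while still
covering the benchmark parameter regime used in the recovery properties.

When `(1−mu)·k_avg` equals or exceeds the within-community partner count
the internal probability saturates at 1 (communities become cliques) and
the realized mean degree lands above target; the generator warns and the
self-checks use a ±15–20% degree tolerance.

## Known limitations

- Dense graphs: distance computation is quadratic in edges in the worst
  case; the implementation BFS-caches from central-edge endpoints, fine up
  to tens of thousands of edges, not for million-edge networks.
- Weighted or directed interactions are out of scope, as are dynamic
  updates.
- The pruning reconstruction ("iterate to fixed point, live sizes for the
  small-community guard") is one consistent reading of a procedure whose
  original pseudocode is not fully specified; alternatives (single pass,
  snapshot sizes) differ only on contrived inputs.
- Functional enrichment (GO/KEGG) of detected protein communities requires
  external annotation databases and is intentionally not part of the
  package.
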