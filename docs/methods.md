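# Methods

## Model

`allmpr` reconciles a rooted binary host phylogeny *H* (n vertices) with a
rooted binary parasite phylogeny *P* (m vertices) under the
duplication–transfer–loss (DTL) event model. The input association
φ: leaves(P) → leaves(H) records which extant parasite inhabits which
extant host; a *reconciliation* extends φ to a total map
γ: V(P) → V(H) subject to two constraints: no vertex maps to a proper
ancestor of its parent's image, and every internal parasite vertex has at
least one child mapping inside the subtree of its own image.

The event of an internal vertex v with image h = γ(v) and child images
u₁, u₂ is read off the positions of u₁, u₂ relative to h:

- **cospeciation** — u₁ and u₂ lie in the two different child subtrees of
  h (h must be internal);
- **duplication** — both lie in the subtree of h but not on different
  sides (one may coincide with h);
- **host switch** — exactly one stays in the subtree of h, the other
  lands on a vertex *incomparable* to h.

These three regions partition the admissible placements, so a placement
uniquely determines its event. Losses are counted on descending path
segments: with d(·,·) the topological (edge-count) distance, a
cospeciation contributes d(h,u₁)−1 + d(h,u₂)−1 losses, a duplication
d(h,u₁) + d(h,u₂), and a switch d(h,u_stay) on the staying side and zero
on the jumping side (the jumped child's image *is* the landing site).
This is the only loss convention consistent with zero-loss event vectors
that combine cospeciations and switches across non-adjacent host lineages,
and it is the convention the exhaustive-search oracle shares — deliberately,
since it is a modelling choice, not an algorithmic one.

Given a cost vector ⟨c_c, c_d, c_s, c_l⟩ of arbitrary reals (negative
values permitted), the cost of a reconciliation is the linear form
c_c·#c + c_d·#d + c_s·#s + c_l·#l, and the All-MPR problem asks for *all*
reconciliations of minimum cost. The k-bounded variant additionally caps
every switch's takeoff-to-landing host distance at k edges; k equal to
the host diameter is provably identical to unbounded, and the suite
asserts exact solution-set equality there.

## Dynamic program and solution DAG

`fill_dp` fills an m×n matrix D in postorder of both trees: D(p,h) is the
optimal cost of embedding the subtree of P rooted at p with p mapped to h.
Leaf cells are 0 at φ(p) and +∞ elsewhere. For internal p with children
p₁,p₂, writing g_i(u) = D(p_i,u) + c_l·d(h,u) for the staying cost of
child i at u, the three event terms are minimized over their placement
regions:

- cospeciation: c_c + min over orientations of g₁(L)+g₂(R) − 2c_l with
  L, R the two child subtrees of h;
- duplication: c_d + the minimum over the region
  ({h}×S) ∪ (S×{h}) ∪ (L×L) ∪ (R×R), S = subtree(h) — decomposed this
  way precisely so that different-side pairs, which are cospeciations by
  definition, are never mis-costed as duplications;
- switch: c_s + min over orientations of g_stay(S) + D(jump, x) with x
  ranging over the vertices incomparable to h within distance k.

Each region minimum is computed with its full argmin list, and the cell's
alternative set is the union of argmin products of the terms that attain
the cell optimum — deduplicated, then sorted by (event kind, child host
ids) so downstream iteration order is fully deterministic. Cells at +∞
store no alternatives. Worst-case storage is O(n²) alternatives per cell,
O(n³m) overall; the per-cell fill is O(n) per region scan plus the
materialized argmin products.

Arithmetic is exact (Python ints) whenever the cost vector is
all-integer, which makes tie detection exact — the case that matters for
enumeration correctness. Non-integral vectors fall back to floats with an
absolute tie tolerance of 1e-9.

The filled table *is* the solution DAG: nodes are cells reachable from
the optimal root cells, edges the alternatives. Because a cell's children
always involve parasite vertices with smaller postorder ids, ascending
cell order is a topological order; both the exact count (sum over
alternatives of products of child counts, arbitrary-precision integers)
and the minimax k_start (below) are single passes in that order.

## Enumeration

`enumerate_optimal` walks the DAG with a mixed-radix odometer: one digit
per internal parasite vertex in parasite-tree preorder, the digit being
the index into that vertex's current cell's alternative list. A digit's
radix depends only on digits before it (the ancestors fix its cell), so
advancing the deepest incrementable digit and resetting deeper ones
visits every solution exactly once, in a deterministic order, rebuilding
γ in O(m) per solution with O(m) state beyond the table. Root hosts are
scanned in postorder-id order. A `max_solutions` cap supports streaming
on instances whose counts are astronomical (the count-only path handles
those exactly regardless).

## Time feasibility

A switch asserts that the donor edge (above takeoff h) and recipient edge
(above landing l) coexisted. With t(x) the speciation time of internal
host vertex x (ancestors strictly earlier; leaves never speciate), the
edge above x spans the open interval (t(parent(x)), t(x)), and two open
intervals overlap iff each lower end precedes the other's upper end.
Each switch therefore adds t(parent(h)) < t(l) (dropped when h is the
root or l is a leaf — a leaf's upper end is +∞) and t(parent(l)) < t(h)
(dropped when h is a leaf; l is never the root). These edges join the
host ancestry digraph on internal vertices; the reconciliation is
time-feasible iff the combined digraph is acyclic (one DFS over an
O(n²)-edge graph). The encoding is validated against an independent
oracle that tries every total ordering of internal host vertices on all
small-battery solutions.

## Bounded-switch sweeps

`compute_k_start` finds the smallest over optimal solutions of the
largest in-solution switch distance without enumerating: per cell, the
minimum over alternatives of the maximum of the child values and the
alternative's own switch distance. Min distributes over the choice, so
this equals the enumeration minimax (asserted on the whole battery).

`find_kA` serves instances whose unbounded optima are all cyclic: it
decrements k from k_start, re-solving at each bound, until some bounded
optimum is time-feasible; the cost at that bound is an upper bracket on
the best acyclic cost. If a bound yields no solution at all the scan
stops (shrinking k only removes options). `find_kprime` serves the
opposite regime — too many acyclic optima — scanning upward from k_start
for the nearest bound that keeps the unbounded optimal cost while still
containing an acyclic solution, shrinking the set without losing
optimality. Both re-run the DP per k (bounds move by single steps in
practice) and respect a solution cap (default 10⁶), reporting the
affected bound as undetermined rather than guessing.

`select_root` handles unrooted parasite trees (gene trees, typically):
every edge of the unrooted binary tree is tried as a root position, the
DP is run per rooting, and the minimum-cost rooting is returned with ties
broken toward the smallest edge index in a deterministic edge order.

## Synthetic data and what the tests show

`random_instance` draws uniform random labelled rooted binary topologies
by iterative leaf attachment (each new leaf attaches to a uniformly
chosen edge or above the root — (2k−1) positions at k leaves, giving
every (2n−3)!! shape equal probability; 1000 draws realize all 105
five-leaf shapes) and a uniformly random leaf association. Sizes for the
oracle battery are 1–6 leaves per tree with cost components drawn from
{−1, 0, 1, 2, 3} and k ∈ {1, 2, ∞}: small enough for the exhaustive
oracle (at most 11⁵ candidate mappings), wide enough to hit negative and
zero costs, switch-free and switch-heavy regimes, and degenerate
single-leaf trees. The battery holds 200 such instances.

The generator emulates topology and association randomness only; it does
not model cospeciation-biased coevolution, branch lengths, or realistic
host–parasite tree-size ratios. Passing the oracle gates therefore
establishes algorithmic correctness (optimality, completeness of
enumeration, exact counting, feasibility verdicts) on arbitrary small
topologies — not biological realism of any particular reconciliation.

The >2⁶⁴ counting check uses a constructed family (caterpillar host with
24 leaves, balanced parasite with 32 leaves, every parasite leaf on one
host leaf, costs ⟨0,1,1,0⟩), whose exact count has magnitude ~10³².

## Numerical and degenerate-input choices

- +∞ is `math.inf`; any arithmetic with it stays infinite; infinite
  cells carry no alternatives.
- Single-vertex trees are legal; the 1-leaf/1-leaf instance reconciles
  uniquely at cost 0, keeping every recursion base total.
- A valid instance always has a finite optimum under any k ≥ 1 (mapping
  every internal parasite vertex to the LCA of its leaves' images is
  always a valid switch-free reconciliation), so "no solution" paths
  exist for API completeness but are unreachable for well-formed input.
- Branch lengths in Newick input are parsed and discarded; all distances
  are edge counts.
- Ties: exact for integer cost vectors, 1e-9 absolute tolerance
  otherwise (documented above).

## Problem sizes

The default suite runs the 200-instance oracle battery (seconds), the
constructed counting family (~0.2 s), and a 20+20-leaf enumeration smoke
test streaming 10⁴ of ~2.4×10⁶ solutions. The acceptance script repeats
the battery and counting family from a caller-supplied seed.

## Known limitations

- Strictly binary trees only; no polytomies, no dated trees, no
  branch-length-weighted switch distances.
- No sub-optimal enumeration within a cost slack and no uniform sampling
  of optima.
- The bounded-switch DP re-solves per k rather than updating
  incrementally.
- `find_kA` asserts the maximality of the returned bound only within the
  scanned range k_start…1, mirroring the decrementing procedure it
  implements.
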