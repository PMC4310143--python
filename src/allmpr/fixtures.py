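"""Random instance generation and the exhaustive-search oracle.

``random_instance`` draws uniform random binary leaf-labelled topologies
(by iterative attachment of each new leaf to a uniformly chosen edge,
including the position above the root, which yields every labelled rooted
binary shape with equal probability) plus a uniform random leaf
association.  ``brute_force_optimal`` enumerates *every* candidate mapping
of internal parasite vertices to host vertices, filters by validity and
the switch-distance bound, and returns the exact optimum and all argmin
mappings — the independent oracle against which the dynamic program and
the enumeration are validated.  The oracle deliberately shares the event
classification and costing (a modelling convention) but not the dynamic
program (the algorithm under test).
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass
from .core import CostVector, Event, Reconciliation, classify_events
from .trees import LeafMapping, PhyloTree, parse_newick

__all__ = [
    "InstanceSpec",
    "random_instance",
    "random_tree",
    "brute_force_optimal",
    "total_order_feasible",
    "BruteForceGuardError",
]

BRUTE_FORCE_GUARD = 10**7


class BruteForceGuardError(ValueError):
    """The exhaustive search space exceeds the safety guard."""


@dataclass(frozen=True)
class InstanceSpec:
    """Parameters of one random instance; generation is a pure function of
    ``seed``."""

    n_host_leaves: int
    n_parasite_leaves: int
    seed: int
    cost_values: tuple = (-1, 0, 1, 2, 3)
    k: int | None = None

    def __post_init__(self):
        if self.n_host_leaves < 1 or self.n_parasite_leaves < 1:
            raise ValueError("trees need at least one leaf")


def random_tree(n_leaves: int, rng: random.Random, prefix: str) -> PhyloTree:
    """Uniform random rooted binary topology with leaves
    ``{prefix}1 .. {prefix}{n}`` via iterative random edge attachment."""
    if n_leaves == 1:
        return parse_newick(f"{prefix}1;")
    # grow a nested-list representation; each attachment point is an edge
    # of the current tree or the slot above its root
    shape: list = [f"{prefix}1", f"{prefix}2"]

    def edges(node, out, parent_slot):
        # collect (container, index) slots whose content can be split
        for i, child in enumerate(node):
            out.append((node, i))
            if isinstance(child, list):
                edges(child, out, (node, i))

    root_holder: list = [shape]
    for i in range(3, n_leaves + 1):
        slots: list = [(root_holder, 0)]
        edges(root_holder[0], slots, None)
        container, idx = rng.choice(slots)
        container[idx] = [container[idx], f"{prefix}{i}"]

    def to_newick(node) -> str:
        if isinstance(node, str):
            return node
        return "(" + ",".join(to_newick(c) for c in node) + ")"

    return parse_newick(to_newick(root_holder[0]) + ";")


def random_instance(
    spec: InstanceSpec,
) -> tuple[PhyloTree, PhyloTree, LeafMapping]:
    """Reproducible random (host, parasite, association) triple."""
    rng = random.Random(spec.seed)
    host = random_tree(spec.n_host_leaves, rng, "h")
    parasite = random_tree(spec.n_parasite_leaves, rng, "p")
    host_leaves = host.leaf_labels()
    pairs = {
        lab: rng.choice(host_leaves) for lab in parasite.leaf_labels()
    }
    phi = LeafMapping.from_labels(host, parasite, pairs)
    return host, parasite, phi


def total_order_feasible(
    recon: Reconciliation, host: PhyloTree, parasite: PhyloTree
) -> bool:
    """Time-feasibility by exhaustive search over total orderings.

    Tries every total order of the internal host vertices and accepts the
    reconciliation iff some order respects ancestry (ancestors speciate
    first) and makes the donor and recipient edges of every host switch
    contemporaneous: the edge above a vertex ``x`` spans the open interval
    from its parent's speciation to its own (leaves never speciate), and
    two intervals overlap iff each lower end precedes the other's upper
    end.  Independent of the constraint-graph encoding under test; meant
    for hosts with at most ~7 internal vertices.
    """
    internal = host.internal_vertices()
    switches = []
    for v, ev in recon.events.items():
        if ev is not Event.HOST_SWITCH:
            continue
        h = recon.gamma[v]
        c1, c2 = parasite.children(v)
        u1, u2 = recon.gamma[c1], recon.gamma[c2]
        landing = u2 if host.is_ancestor(h, u1) else u1
        switches.append((h, landing))
    if not switches:
        return True
    for perm in itertools.permutations(internal):
        pos = {v: i for i, v in enumerate(perm)}
        ok = True
        for u in internal:
            for c in host.children(u):
                if not host.is_leaf(c) and pos[u] > pos[c]:
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        for h, l in switches:
            ph, pl = host.parent(h), host.parent(l)
            if ph is not None and not host.is_leaf(l) and pos[ph] >= pos[l]:
                ok = False
                break
            if pl is not None and not host.is_leaf(h) and pos[pl] >= pos[h]:
                ok = False
                break
        if ok:
            return True
    return False


def brute_force_optimal(
    host: PhyloTree,
    parasite: PhyloTree,
    phi: LeafMapping,
    costs: CostVector,
    k: int | None = None,
) -> tuple[float, list[Reconciliation]]:
    """Exact optimum and all optimal reconciliations by exhaustive search.

    Iterates every total extension of the leaf association over internal
    parasite vertices (mixed-radix counter in postorder), keeps the valid
    ones whose switch distances respect ``k``, and returns the minimum
    cost with all minimizers.  Guarded to small instances.
    """
    internal = parasite.internal_vertices()
    n = host.n_vertices
    if n ** len(internal) > BRUTE_FORCE_GUARD:
        raise BruteForceGuardError(
            f"{n}^{len(internal)} candidate mappings exceed the guard"
        )
    dist = host.distance_table()
    base = dict(phi.assoc)
    if not internal:
        recon = Reconciliation.from_gamma(host, parasite, phi, base, costs)
        return recon.cost, [recon]

    best_cost: float | None = None
    best: list[Reconciliation] = []
    digits = [0] * len(internal)
    while True:
        gamma = dict(base)
        for v, d in zip(internal, digits):
            gamma[v] = d
        result = classify_events(host, parasite, phi, gamma)
        if result.valid:
            ok = True
            if k is not None:
                for v, ev in result.events.items():
                    if ev is Event.HOST_SWITCH:
                        h = gamma[v]
                        c1, c2 = parasite.children(v)
                        u1, u2 = gamma[c1], gamma[c2]
                        landing = u2 if host.is_ancestor(h, u1) else u1
                        if dist[h][landing] > k:
                            ok = False
                            break
            if ok:
                recon = Reconciliation.from_gamma(
                    host, parasite, phi, gamma, costs
                )
                if best_cost is None or recon.cost < best_cost:
                    best_cost = recon.cost
                    best = [recon]
                elif recon.cost == best_cost:
                    best.append(recon)
        # advance the mixed-radix counter
        j = len(digits) - 1
        while j >= 0 and digits[j] + 1 >= n:
            digits[j] = 0
            j -= 1
        if j < 0:
            break
        digits[j] += 1
    if best_cost is None:
        return float("inf"), []
    return best_cost, best
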