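"""Event-class grouping, bounded-switch sweeps, and parasite-root selection.

Solutions are grouped into classes by their event vector ``<#c,#d,#s,#l>``
— solutions with identical counts of cospeciations, duplications, host
switches and losses form one class, a far smaller summary than the raw
solution list.

The bounded-switch machinery revolves around three quantities, all
relative to a fixed instance and cost vector.  ``k_start`` is the smallest
over all optimal solutions of the longest switch distance within a
solution: the tightest bound at which the unbounded optimal cost is still
attained.  When no unbounded optimal solution is time-feasible, ``find_kA``
decrements the bound from ``k_start`` looking for the largest ``k`` whose
optimal solution set contains an acyclic member (the cost may rise as the
bound shrinks, giving an upper bracket on the best acyclic cost).  When
acyclic optima do exist but are too numerous, ``find_kprime`` searches
upward from ``k_start`` for the nearest bound that preserves the unbounded
optimal cost while still admitting at least one acyclic solution, thereby
shrinking the solution set without losing optimality.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import dendropy

from .core import CostVector, DPTable, Event, Reconciliation, fill_dp
from .enumeration import count_optimal, enumerate_optimal
from .feasibility import split_by_feasibility
from .trees import LeafMapping, PhyloTree, PolytomyError, parse_newick

__all__ = [
    "ClassTable",
    "KPoint",
    "KSweepResult",
    "SolutionCapExceeded",
    "event_vector",
    "class_table",
    "class_table_rows",
    "max_switch_distance",
    "compute_k_start",
    "find_kA",
    "find_kprime",
    "RootSelection",
    "select_root",
]

DEFAULT_SWEEP_CAP = 10**6

ClassTable = Counter  # event_vector tuple -> number of solutions


class SolutionCapExceeded(RuntimeError):
    """A sweep step would require enumerating more solutions than the cap;
    the affected bound is reported as undetermined."""

    def __init__(self, k: int, count: int, cap: int):
        super().__init__(
            f"bound k={k} has {count} optimal solutions, exceeding the "
            f"cap of {cap}; result undetermined at this k"
        )
        self.k = k
        self.count = count
        self.cap = cap


def event_vector(recon: Reconciliation) -> tuple[int, int, int, int]:
    return recon.event_vector


def class_table(solutions: Iterable[Reconciliation]) -> ClassTable:
    """Count solutions per distinct event vector."""
    table: ClassTable = Counter()
    for recon in solutions:
        table[recon.event_vector] += 1
    return table


def class_table_rows(
    table: ClassTable,
) -> list[tuple[tuple[int, int, int, int], int]]:
    """Deterministic (lexicographically sorted) rows of a class table."""
    return sorted(table.items())


def max_switch_distance(
    recon: Reconciliation, host: PhyloTree, parasite: PhyloTree
) -> int:
    """Longest takeoff-to-landing distance among the solution's switches
    (0 when the solution has no switch)."""
    dist = host.distance_table()
    best = 0
    for v, ev in recon.events.items():
        if ev is not Event.HOST_SWITCH:
            continue
        h = recon.gamma[v]
        c1, c2 = parasite.children(v)
        u1, u2 = recon.gamma[c1], recon.gamma[c2]
        landing = u2 if host.is_ancestor(h, u1) else u1
        best = max(best, dist[h][landing])
    return best


def compute_k_start(table: DPTable) -> int:
    """Smallest over all optimal solutions of the longest switch distance.

    Computed without enumeration: a minimax dynamic program over the
    solution DAG — per cell, the minimum over alternatives of the maximum
    of the two child values and, for a switch alternative, its own switch
    distance.  Min distributes over the alternative choice, so this equals
    the enumeration-based value.
    """
    if table.opt == float("inf"):
        raise ValueError("instance has no solution; k_start undefined")
    parasite = table.parasite
    dist = table.host.distance_table()
    memo: dict[tuple[int, int], int] = {}

    seen: set[tuple[int, int]] = set()
    root = parasite.root
    stack = [(root, h) for h in table.opt_roots]
    while stack:
        cell = stack.pop()
        if cell in seen:
            continue
        seen.add(cell)
        p, h = cell
        if not parasite.is_leaf(p):
            p1, p2 = parasite.children(p)
            for alt in table.alts[(p, h)]:
                stack.append((p1, alt.left_host))
                stack.append((p2, alt.right_host))

    # ascending parasite postorder id is a topological order of the DAG
    for cell in sorted(seen):
        p, h = cell
        if parasite.is_leaf(p):
            memo[cell] = 0
            continue
        p1, p2 = parasite.children(p)
        best: int | None = None
        for alt in table.alts[cell]:
            val = max(memo[(p1, alt.left_host)], memo[(p2, alt.right_host)])
            if alt.event is Event.HOST_SWITCH:
                landing = (
                    alt.right_host
                    if table.host.is_ancestor(h, alt.left_host)
                    else alt.left_host
                )
                val = max(val, dist[h][landing])
            if best is None or val < best:
                best = val
        memo[cell] = best  # type: ignore[assignment]
    return min(memo[(root, h)] for h in table.opt_roots)


@dataclass
class KPoint:
    """One step of a bounded-switch scan."""

    k: int
    opt: float
    total: int
    acyclic: int | None  # None = not computed (cap exceeded)


@dataclass
class KSweepResult:
    """Outcome of a ``find_kA`` / ``find_kprime`` scan."""

    k: int
    opt: float
    total: int
    acyclic: int
    solutions: list[Reconciliation] = field(default_factory=list)
    trace: list[KPoint] = field(default_factory=list)
    k_start: int = 0


def _solutions_at(
    host: PhyloTree,
    parasite: PhyloTree,
    phi: LeafMapping,
    costs: CostVector,
    k: int,
    cap: int,
) -> tuple[DPTable, int, list[Reconciliation], list[Reconciliation]]:
    table = fill_dp(host, parasite, phi, costs, k=k)
    if table.opt == float("inf"):
        return table, 0, [], []
    total = count_optimal(table)
    if total > cap:
        raise SolutionCapExceeded(k, total, cap)
    acyclic, cyclic = split_by_feasibility(
        enumerate_optimal(table), host, parasite
    )
    return table, total, acyclic, cyclic


def find_kA(
    host: PhyloTree,
    parasite: PhyloTree,
    phi: LeafMapping,
    costs: CostVector,
    max_solutions: int = DEFAULT_SWEEP_CAP,
) -> KSweepResult | None:
    """Decrement the switch bound from ``k_start`` until some optimal
    solution under the bound is time-feasible.

    Returns the first such bound with its optimal cost and acyclic
    solutions, or None when no bound down to 1 yields one.  Raises
    :class:`SolutionCapExceeded` when a step cannot be checked within the
    solution cap.
    """
    unbounded = fill_dp(host, parasite, phi, costs, k=None)
    if unbounded.opt == float("inf"):
        return None
    k_start = compute_k_start(unbounded)
    trace: list[KPoint] = []
    for k in range(max(k_start, 1), 0, -1):
        table = fill_dp(host, parasite, phi, costs, k=k)
        if table.opt == float("inf"):
            # shrinking k only removes switch options, so smaller bounds
            # cannot recover a solution
            trace.append(KPoint(k, float("inf"), 0, 0))
            break
        total = count_optimal(table)
        if total > max_solutions:
            raise SolutionCapExceeded(k, total, max_solutions)
        acyclic, _ = split_by_feasibility(
            enumerate_optimal(table), host, parasite
        )
        trace.append(KPoint(k, table.opt, total, len(acyclic)))
        if acyclic:
            return KSweepResult(
                k=k,
                opt=table.opt,
                total=total,
                acyclic=len(acyclic),
                solutions=acyclic,
                trace=trace,
                k_start=k_start,
            )
    return None


def find_kprime(
    host: PhyloTree,
    parasite: PhyloTree,
    phi: LeafMapping,
    costs: CostVector,
    max_solutions: int = DEFAULT_SWEEP_CAP,
) -> KSweepResult | None:
    """Smallest bound ``k' >= k_start`` that preserves the unbounded
    optimal cost while admitting at least one time-feasible solution.

    Useful when the unbounded acyclic solution set is unmanageably large:
    ``|S(k')| <= |S(unbounded)|`` while optimality is untouched.  Returns
    None when even the unbounded problem has no acyclic optimal solution.
    """
    unbounded = fill_dp(host, parasite, phi, costs, k=None)
    if unbounded.opt == float("inf"):
        return None
    k_start = compute_k_start(unbounded)
    diameter = host.diameter()
    trace: list[KPoint] = []
    for k in range(max(k_start, 1), max(diameter, 1) + 1):
        table = fill_dp(host, parasite, phi, costs, k=k)
        total = count_optimal(table)
        if total > max_solutions:
            raise SolutionCapExceeded(k, total, max_solutions)
        acyclic, _ = split_by_feasibility(
            enumerate_optimal(table), host, parasite
        )
        trace.append(KPoint(k, table.opt, total, len(acyclic)))
        same_cost = table.opt == unbounded.opt
        if same_cost and acyclic:
            return KSweepResult(
                k=k,
                opt=table.opt,
                total=total,
                acyclic=len(acyclic),
                solutions=acyclic,
                trace=trace,
                k_start=k_start,
            )
    return None


# ---------------------------------------------------------- root selection


@dataclass
class RootSelection:
    """A chosen rooting of an unrooted parasite tree."""

    tree: PhyloTree
    opt: float
    edge_index: int
    candidate_costs: list[float] = field(default_factory=list)


def _unrooted_graph(text: str) -> tuple[dict[int, list[int]], dict[int, str]]:
    """Adjacency of an unrooted binary tree parsed from Newick.

    A basal bifurcation (rooted-style input) is suppressed; every internal
    node must then have degree 3 and every leaf degree 1.
    """
    tree = dendropy.Tree.get(
        data=text, schema="newick", suppress_internal_node_taxa=True
    )
    nodes = list(tree.postorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    adj: dict[int, list[int]] = {i: [] for i in range(len(nodes))}
    labels: dict[int, str] = {}
    for nd in nodes:
        i = index[id(nd)]
        if not nd.child_nodes():
            lab = nd.taxon.label if nd.taxon else nd.label
            if lab is None:
                raise PolytomyError("unrooted tree has an unlabelled leaf")
            labels[i] = lab
        for child in nd.child_nodes():
            j = index[id(child)]
            adj[i].append(j)
            adj[j].append(i)
    seed = index[id(tree.seed_node)]
    if len(adj[seed]) == 2:  # artificial root of a rooted-style file
        a, b = adj[seed]
        adj[a] = [x if x != seed else b for x in adj[a]]
        adj[b] = [x if x != seed else a for x in adj[b]]
        del adj[seed]
    for i, nbrs in adj.items():
        deg = len(nbrs)
        if (i in labels and deg != 1) or (i not in labels and deg != 3):
            raise PolytomyError(
                f"unrooted tree is not binary at vertex {labels.get(i, i)}"
            )
    return adj, labels


def _root_on_edge(
    adj: dict[int, list[int]], labels: dict[int, str], a: int, b: int
) -> PhyloTree:
    def newick(v: int, come_from: int) -> str:
        nbrs = [x for x in sorted(adj[v]) if x != come_from]
        if not nbrs:
            return labels[v]
        return "(" + ",".join(newick(x, v) for x in nbrs) + ")"

    return parse_newick(f"({newick(a, b)},{newick(b, a)});")


def select_root(
    parasite_unrooted: str,
    host: PhyloTree,
    phi_labels: dict[str, str],
    costs: CostVector,
    k: int | None = None,
) -> RootSelection:
    """Root an unrooted parasite tree on the edge minimizing the optimal
    reconciliation cost.

    ``parasite_unrooted`` is a Newick string (a basal trifurcation, or a
    rooted-style basal bifurcation which is first suppressed);
    ``phi_labels`` maps parasite leaf labels to host leaf labels.  Every
    edge is tried in a deterministic order; ties break toward the smallest
    edge index.
    """
    adj, labels = _unrooted_graph(parasite_unrooted)
    if len(labels) < 2:
        raise ValueError("unrooted parasite tree needs at least 2 leaves")
    edges = sorted(
        {(min(u, v), max(u, v)) for u, nbrs in adj.items() for v in nbrs}
    )
    best: RootSelection | None = None
    candidate_costs: list[float] = []
    for idx, (a, b) in enumerate(edges):
        rooted = _root_on_edge(adj, labels, a, b)
        phi = LeafMapping.from_labels(host, rooted, phi_labels)
        table = fill_dp(host, rooted, phi, costs, k=k)
        candidate_costs.append(table.opt)
        if best is None or table.opt < best.opt:
            best = RootSelection(tree=rooted, opt=table.opt, edge_index=idx)
    assert best is not None
    best.candidate_costs = candidate_costs
    return best
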