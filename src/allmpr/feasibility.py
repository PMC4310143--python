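"""Time-feasibility (acyclicity) testing for reconciliations.

A host switch asserts that the donor lineage (the host-tree edge above the
takeoff vertex) and the recipient lineage (the edge above the landing
vertex) existed at the same moment.  Writing ``t(x)`` for the (unknown)
speciation time of internal host vertex ``x`` — leaves live forever,
ancestors speciate before descendants — the edge above ``x`` spans
``(t(parent(x)), t(x))``, and two open intervals overlap iff each one's
lower end precedes the other's upper end.  A switch from takeoff ``h`` to
landing ``l`` therefore imposes

* ``t(parent(h)) < t(l)``   (skipped when ``h`` is the root or ``l`` a leaf),
* ``t(parent(l)) < t(h)``   (skipped when ``h`` is a leaf; ``l`` is never
  the root since it is incomparable to ``h``).

These strict precedences, together with the host tree's own ancestry
order, form a digraph on the internal host vertices; the reconciliation is
time-feasible iff that digraph is acyclic.  With O(n^2) possible edges and
a single DFS-based cycle check the test runs in O(n^2).
"""

from __future__ import annotations

from typing import Iterable

import networkx as nx

from .core import Event, Reconciliation
from .trees import PhyloTree

__all__ = [
    "temporal_graph",
    "is_time_feasible",
    "split_by_feasibility",
    "temporal_graph_dot",
]


def _switch_pairs(recon: Reconciliation, host: PhyloTree, parasite: PhyloTree):
    """(takeoff, landing) host-vertex pairs of all host-switch events."""
    for v, ev in recon.events.items():
        if ev is not Event.HOST_SWITCH:
            continue
        h = recon.gamma[v]
        c1, c2 = parasite.children(v)
        u1, u2 = recon.gamma[c1], recon.gamma[c2]
        landing = u2 if host.is_ancestor(h, u1) else u1
        yield h, landing


def temporal_graph(
    recon: Reconciliation, host: PhyloTree, parasite: PhyloTree
) -> nx.DiGraph:
    """The precedence digraph on internal host vertices induced by the host
    tree's ancestry plus the reconciliation's switch constraints."""
    g = nx.DiGraph()
    internal = set(host.internal_vertices())
    g.add_nodes_from(internal)
    for v in internal:
        for c in host.children(v):
            if c in internal:
                g.add_edge(v, c)
    for h, l in _switch_pairs(recon, host, parasite):
        ph = host.parent(h)
        pl = host.parent(l)
        if ph is not None and not host.is_leaf(l):
            g.add_edge(ph, l)
        if pl is not None and not host.is_leaf(h):
            g.add_edge(pl, h)
    return g


def is_time_feasible(
    recon: Reconciliation, host: PhyloTree, parasite: PhyloTree
) -> bool:
    """True iff the switches admit a consistent temporal ordering of host
    speciations (the precedence digraph has no directed cycle)."""
    g = temporal_graph(recon, host, parasite)
    # a self-loop (t(x) < t(x)) is already a cycle
    if any(u == v for u, v in g.edges):
        return False
    return nx.is_directed_acyclic_graph(g)


def split_by_feasibility(
    solutions: Iterable[Reconciliation], host: PhyloTree, parasite: PhyloTree
) -> tuple[list[Reconciliation], list[Reconciliation]]:
    """Partition solutions into (acyclic, cyclic) lists, preserving order."""
    acyclic: list[Reconciliation] = []
    cyclic: list[Reconciliation] = []
    for recon in solutions:
        (acyclic if is_time_feasible(recon, host, parasite) else cyclic).append(
            recon
        )
    return acyclic, cyclic


def temporal_graph_dot(
    recon: Reconciliation, host: PhyloTree, parasite: PhyloTree
) -> str:
    """GraphViz DOT rendering of the precedence digraph (debugging aid)."""
    g = temporal_graph(recon, host, parasite)
    lines = ["digraph temporal {"]
    for v in sorted(g.nodes):
        lines.append(f'  n{v} [label="{host.name(v)}"];')
    for u, v in sorted(g.edges):
        lines.append(f"  n{u} -> n{v};")
    lines.append("}")
    return "\n".join(lines)
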