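"""Dynamic-programming engine for DTL cophylogeny reconciliation.

Model
-----
A reconciliation maps every parasite vertex ``p`` to a host vertex
``gamma(p)``, extending the leaf association ``phi``.  Each internal
parasite vertex is assigned exactly one event, determined by where its two
children map relative to ``h = gamma(p)``:

* **cospeciation** — the children map into the two *different* child
  subtrees of ``h`` (requires ``h`` internal);
* **duplication** — both children map inside the subtree of ``h`` but not
  on different sides (one may sit on ``h`` itself);
* **host switch** — exactly one child stays inside the subtree of ``h``;
  the other jumps to a host vertex *incomparable* to ``h``.

Losses are counted on descending host-path segments: a cospeciation at
``h`` with child images ``u1, u2`` contributes ``d(h,u1)-1 + d(h,u2)-1``
losses, a duplication ``d(h,u1) + d(h,u2)``, and a host switch ``d(h,u)``
on the staying side only (the jumped child's image is the landing site, so
the jump branch contributes none).  ``d`` is the topological edge distance.

Given a cost vector ``<c_c, c_d, c_s, c_l>`` (any reals, negatives
allowed), ``fill_dp`` computes for every cell ``(p, h)`` the minimum cost
``D(p,h)`` of a sub-reconciliation mapping ``p`` to ``h``, together with
*all* minimizing child placements — the solution DAG from which counting
and enumeration proceed.  A switch-distance bound ``k`` restricts host
switches to landings within ``k`` edges of the takeoff.
"""

from __future__ import annotations

import enum
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .trees import LeafMapping, PhyloTree

__all__ = [
    "Event",
    "CostVector",
    "Alternative",
    "DPTable",
    "Reconciliation",
    "Classification",
    "INFINITY",
    "classify_events",
    "cost_of",
    "fill_dp",
]

INFINITY = math.inf

#: absolute tolerance for cost-tie detection with non-integral cost vectors
FLOAT_TIE_TOL = 1e-9


class Event(enum.IntEnum):
    """Event kinds, ordered for deterministic alternative sorting."""

    COSPECIATION = 0
    DUPLICATION = 1
    HOST_SWITCH = 2

    @property
    def code(self) -> str:
        return {"COSPECIATION": "C", "DUPLICATION": "D", "HOST_SWITCH": "S"}[
            self.name
        ]


@dataclass(frozen=True)
class CostVector:
    """Event costs ``<c_c, c_d, c_s, c_l>``; any real values are allowed."""

    cospeciation: float
    duplication: float
    host_switch: float
    loss: float

    @classmethod
    def from_string(cls, text: str) -> "CostVector":
        parts = [s.strip() for s in text.split(",")]
        if len(parts) != 4:
            raise ValueError(
                f"cost vector needs 4 comma-separated values, got {text!r}"
            )
        vals = [float(s) if "." in s or "e" in s.lower() else int(s) for s in parts]
        return cls(*vals)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.cospeciation, self.duplication, self.host_switch, self.loss)

    @property
    def exact(self) -> bool:
        """True when all four costs are integers, making all DP arithmetic
        exact and tie detection a matter of equality."""
        return all(isinstance(c, int) for c in self.as_tuple())

    def total(self, event_vector: Sequence[int]) -> float:
        nc, nd, ns, nl = event_vector
        return (
            self.cospeciation * nc
            + self.duplication * nd
            + self.host_switch * ns
            + self.loss * nl
        )


@dataclass(frozen=True)
class Alternative:
    """One optimal placement of the two children of a parasite vertex.

    ``left_host``/``right_host`` are the host images of the first/second
    child (in the parasite tree's stored child order).  The event is fully
    determined by the two positions relative to the cell's host vertex.
    """

    event: Event
    left_host: int
    right_host: int

    def sort_key(self) -> tuple[int, int, int]:
        return (int(self.event), self.left_host, self.right_host)


@dataclass
class Classification:
    """Outcome of event determination for a candidate mapping."""

    valid: bool
    events: dict[int, Event] = field(default_factory=dict)
    losses: Counter = field(default_factory=Counter)
    offending_vertex: int | None = None
    reason: str | None = None


@dataclass
class Reconciliation:
    """A full reconciliation: the mapping, its events, losses and cost."""

    gamma: dict[int, int]
    events: dict[int, Event]
    losses: Counter
    cost: float
    event_vector: tuple[int, int, int, int]

    def gamma_key(self) -> tuple[tuple[int, int], ...]:
        """Hashable canonical form of the mapping (for set comparisons)."""
        return tuple(sorted(self.gamma.items()))

    @classmethod
    def from_gamma(
        cls,
        host: PhyloTree,
        parasite: PhyloTree,
        phi: LeafMapping,
        gamma: Mapping[int, int],
        costs: CostVector,
    ) -> "Reconciliation":
        cls_result = classify_events(host, parasite, phi, gamma)
        if not cls_result.valid:
            raise ValueError(
                f"invalid reconciliation at parasite vertex "
                f"{cls_result.offending_vertex}: {cls_result.reason}"
            )
        ev = cls_result.events
        nc = sum(1 for e in ev.values() if e is Event.COSPECIATION)
        nd = sum(1 for e in ev.values() if e is Event.DUPLICATION)
        ns = sum(1 for e in ev.values() if e is Event.HOST_SWITCH)
        nl = sum(cls_result.losses.values())
        vec = (nc, nd, ns, nl)
        return cls(
            gamma=dict(gamma),
            events=ev,
            losses=cls_result.losses,
            cost=costs.total(vec),
            event_vector=vec,
        )


def classify_events(
    host: PhyloTree,
    parasite: PhyloTree,
    phi: LeafMapping,
    gamma: Mapping[int, int],
) -> Classification:
    """Determine the event of every internal parasite vertex and the loss
    multiset, or report why the mapping is invalid.

    Invalidity is a *verdict*, not an exception, so that exhaustive search
    can use this as its validity filter.
    """
    for leaf in parasite.leaves():
        if gamma.get(leaf) != phi.assoc[leaf]:
            return Classification(
                False,
                offending_vertex=leaf,
                reason="leaf mapping disagrees with the leaf association",
            )
    events: dict[int, Event] = {}
    losses: Counter = Counter()

    def descend_losses(top: int, bottom: int, skip_top: bool) -> None:
        # losses at each vertex on the path top..bottom, excluding bottom
        # (and excluding top itself for cospeciation's post-split walk)
        v = bottom
        path = []
        while v != top:
            v = host.parent(v)  # type: ignore[assignment]
            path.append(v)
        # path holds top..parent(bottom) in ascending order; drop `top`?
        for w in path:
            if skip_top and w == top:
                continue
            losses[w] += 1

    for v in parasite.internal_vertices():
        h = gamma[v]
        c1, c2 = parasite.children(v)
        u1, u2 = gamma[c1], gamma[c2]
        in1 = host.is_ancestor(h, u1)
        in2 = host.is_ancestor(h, u2)
        # constraint (a): a child image may never be a proper ancestor of h
        for c, u in ((c1, u1), (c2, u2)):
            if host.is_ancestor(u, h) and u != h:
                return Classification(
                    False,
                    offending_vertex=c,
                    reason="child maps to a proper ancestor of its "
                    "parent's image",
                )
        if not (in1 or in2):
            # constraint (b): one child must stay in the subtree of h
            return Classification(
                False,
                offending_vertex=v,
                reason="neither child maps into the subtree of the "
                "parent's image",
            )
        if in1 and in2:
            hcs = host.children(h)
            if hcs and (
                (host.is_ancestor(hcs[0], u1) and host.is_ancestor(hcs[1], u2))
                or (host.is_ancestor(hcs[1], u1) and host.is_ancestor(hcs[0], u2))
            ):
                events[v] = Event.COSPECIATION
                descend_losses(h, u1, skip_top=True)
                descend_losses(h, u2, skip_top=True)
            else:
                events[v] = Event.DUPLICATION
                descend_losses(h, u1, skip_top=False)
                descend_losses(h, u2, skip_top=False)
        else:
            events[v] = Event.HOST_SWITCH
            u_stay = u1 if in1 else u2
            descend_losses(h, u_stay, skip_top=False)
    return Classification(True, events=events, losses=losses)


def cost_of(recon: Reconciliation, costs: CostVector) -> float:
    """Total cost ``c_c*#c + c_d*#d + c_s*#s + c_l*#l``."""
    return costs.total(recon.event_vector)


@dataclass
class DPTable:
    """Filled DP matrix with per-cell optimal alternatives (solution DAG).

    ``D[p][h]`` is the optimal sub-cost of mapping parasite vertex ``p`` to
    host vertex ``h`` (``math.inf`` if impossible); ``alts[(p, h)]`` lists
    every optimal child placement for internal ``p`` at finite cells, in
    deterministic order.  ``opt`` is the global optimum and ``opt_roots``
    the host vertices achieving it for the parasite root.
    """

    host: PhyloTree
    parasite: PhyloTree
    phi: LeafMapping
    costs: CostVector
    k: int | None
    D: list[list[float]]
    alts: dict[tuple[int, int], list[Alternative]]
    opt: float
    opt_roots: list[int]

    @property
    def unbounded(self) -> bool:
        return self.k is None

    def switch_distance(self, h: int, landing: int) -> int:
        return self.host.distance_table()[h][landing]


def _collect_min(
    candidates: Iterable[tuple[float, int]], exact: bool
) -> tuple[float, list[int]]:
    """Minimum value and all argmins over (value, id) pairs."""
    best = INFINITY
    arg: list[int] = []
    tol = 0.0 if exact else FLOAT_TIE_TOL
    for val, idx in candidates:
        if val is INFINITY or val == INFINITY:
            continue
        if val < best - tol:
            best = val
            arg = [idx]
        elif abs(val - best) <= tol:
            arg.append(idx)
    return best, arg


def fill_dp(
    host: PhyloTree,
    parasite: PhyloTree,
    phi: LeafMapping,
    costs: CostVector,
    k: int | None = None,
) -> DPTable:
    """Fill the reconciliation DP matrix under switch-distance bound ``k``.

    ``k=None`` means unbounded.  Returns a :class:`DPTable` whose ``alts``
    hold *all* cost-minimizing child placements per cell, so counting and
    enumeration downstream are exact.
    """
    if k is not None and k < 1:
        raise ValueError("switch-distance bound k must be >= 1 (or None)")
    phi.validate(host, parasite)
    n = host.n_vertices
    m = parasite.n_vertices
    dist = host.distance_table()
    exact = costs.exact
    tol = 0.0 if exact else FLOAT_TIE_TOL
    c_c, c_d, c_s, c_l = costs.as_tuple()

    # per host vertex: child-subtree vertex lists and k-reachable
    # incomparable landings
    sub_left: list[list[int]] = [[] for _ in range(n)]
    sub_right: list[list[int]] = [[] for _ in range(n)]
    landings: list[list[int]] = [[] for _ in range(n)]
    for h in range(n):
        hcs = host.children(h)
        if hcs:
            sub_left[h] = host.subtree_vertices(hcs[0])
            sub_right[h] = host.subtree_vertices(hcs[1])
        landings[h] = [
            x
            for x in range(n)
            if not host.are_comparable(h, x)
            and (k is None or dist[h][x] <= k)
        ]

    D: list[list[float]] = [[INFINITY] * n for _ in range(m)]
    alts: dict[tuple[int, int], list[Alternative]] = {}

    for p in parasite.postorder():
        if parasite.is_leaf(p):
            D[p][phi.assoc[p]] = 0.0 if not exact else 0
            continue
        p1, p2 = parasite.children(p)
        row1, row2 = D[p1], D[p2]
        for h in range(n):
            dh = dist[h]
            L, R = sub_left[h], sub_right[h]

            # stay-side values with losses: D(child, u) + c_l * d(h, u)
            def region_min(row: list[float], region: list[int]):
                return _collect_min(
                    ((row[u] + c_l * dh[u], u) for u in region), exact
                )

            minL1, argL1 = region_min(row1, L)
            minR1, argR1 = region_min(row1, R)
            minL2, argL2 = region_min(row2, L)
            minR2, argR2 = region_min(row2, R)
            valA1, valA2 = row1[h], row2[h]
            # stay-anywhere-in-subtree minimum (A ∪ L ∪ R)
            minS1 = min(valA1, minL1, minR1)
            minS2 = min(valA2, minL2, minR2)
            out1, argO1 = _collect_min(
                ((row1[x], x) for x in landings[h]), exact
            )
            out2, argO2 = _collect_min(
                ((row2[x], x) for x in landings[h]), exact
            )

            cosp = (
                c_c + min(minL1 + minR2, minR1 + minL2) - 2 * c_l
                if L and (minL1 + minR2 < INFINITY or minR1 + minL2 < INFINITY)
                else INFINITY
            )
            dup_terms = (
                valA1 + minS2,
                minS1 + valA2,
                minL1 + minL2,
                minR1 + minR2,
            )
            dup_best = min(dup_terms)
            dup = c_d + dup_best if dup_best < INFINITY else INFINITY
            sw_terms = (minS1 + out2, out1 + minS2)
            sw_best = min(sw_terms)
            sw = c_s + sw_best if sw_best < INFINITY else INFINITY

            best = min(cosp, dup, sw)
            if best == INFINITY:
                continue
            D[p][h] = best

            cell_alts: set[Alternative] = set()

            def close(a: float, b: float) -> bool:
                if a == INFINITY or b == INFINITY:
                    return a == b
                return abs(a - b) <= tol

            if close(cosp, best):
                if close(minL1 + minR2, cosp - c_c + 2 * c_l):
                    for x in argL1:
                        for y in argR2:
                            cell_alts.add(
                                Alternative(Event.COSPECIATION, x, y)
                            )
                if close(minR1 + minL2, cosp - c_c + 2 * c_l):
                    for x in argR1:
                        for y in argL2:
                            cell_alts.add(
                                Alternative(Event.COSPECIATION, x, y)
                            )
            if close(dup, best):
                target = dup - c_d
                argS1 = (
                    ([h] if close(valA1, minS1) else [])
                    + (argL1 if close(minL1, minS1) else [])
                    + (argR1 if close(minR1, minS1) else [])
                )
                argS2 = (
                    ([h] if close(valA2, minS2) else [])
                    + (argL2 if close(minL2, minS2) else [])
                    + (argR2 if close(minR2, minS2) else [])
                )
                if close(valA1 + minS2, target):
                    for y in argS2:
                        cell_alts.add(Alternative(Event.DUPLICATION, h, y))
                if close(minS1 + valA2, target):
                    for x in argS1:
                        cell_alts.add(Alternative(Event.DUPLICATION, x, h))
                if close(minL1 + minL2, target):
                    for x in argL1:
                        for y in argL2:
                            cell_alts.add(Alternative(Event.DUPLICATION, x, y))
                if close(minR1 + minR2, target):
                    for x in argR1:
                        for y in argR2:
                            cell_alts.add(Alternative(Event.DUPLICATION, x, y))
            if close(sw, best):
                target = sw - c_s
                argS1 = (
                    ([h] if close(valA1, minS1) else [])
                    + (argL1 if close(minL1, minS1) else [])
                    + (argR1 if close(minR1, minS1) else [])
                )
                argS2 = (
                    ([h] if close(valA2, minS2) else [])
                    + (argL2 if close(minL2, minS2) else [])
                    + (argR2 if close(minR2, minS2) else [])
                )
                if close(minS1 + out2, target):
                    for x in argS1:
                        for y in argO2:
                            cell_alts.add(Alternative(Event.HOST_SWITCH, x, y))
                if close(out1 + minS2, target):
                    for x in argO1:
                        for y in argS2:
                            cell_alts.add(Alternative(Event.HOST_SWITCH, x, y))
            alts[(p, h)] = sorted(cell_alts, key=Alternative.sort_key)

    root = parasite.root
    opt, opt_roots = _collect_min(
        ((D[root][h], h) for h in range(n)), exact
    )
    return DPTable(
        host=host,
        parasite=parasite,
        phi=phi,
        costs=costs,
        k=k,
        D=D,
        alts=alts,
        opt=opt,
        opt_roots=sorted(opt_roots),
    )
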