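"""Exact counting and polynomial-delay enumeration of optimal reconciliations.

Both operations walk the solution DAG implicit in a filled
:class:`~allmpr.core.DPTable`: nodes are the table cells reachable from the
optimal root cells, and each internal cell carries its ordered list of
optimal child placements.  Shared sub-solutions are represented once, so
counting is a memoized product-sum over cells (arbitrary-precision Python
integers) and enumeration advances an explicit choice vector — an
"odometer" of one alternative index per internal parasite vertex, in
parasite-tree preorder — rebuilding the embedded mapping in O(m) per
solution.
"""

from __future__ import annotations

import json
from typing import IO, Iterator

from .core import DPTable, Reconciliation

__all__ = [
    "count_optimal",
    "enumerate_optimal",
    "first_solution",
    "NoSolutionError",
    "write_solutions_text",
    "write_solutions_jsonl",
]


class NoSolutionError(RuntimeError):
    """The instance admits no valid reconciliation under the given bound."""


def count_optimal(table: DPTable) -> int:
    """Exact number of optimal reconciliations, without enumerating them.

    ``N(cell)`` is 1 for leaf cells and the sum over alternatives of the
    product of the two child-cell counts otherwise; the result is the sum
    of ``N`` over the optimal root cells.  Python integers keep counts of
    any magnitude exact.
    """
    if table.opt == float("inf"):
        return 0
    parasite = table.parasite
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

    # child cells carry parasite vertices with smaller postorder ids than
    # their parent's, so ascending parasite id is a topological order
    for cell in sorted(seen):
        p, h = cell
        if parasite.is_leaf(p):
            memo[cell] = 1
        else:
            p1, p2 = parasite.children(p)
            memo[cell] = sum(
                memo[(p1, a.left_host)] * memo[(p2, a.right_host)]
                for a in table.alts[cell]
            )
    return sum(memo[(root, h)] for h in table.opt_roots)


def enumerate_optimal(
    table: DPTable, max_solutions: int | None = None
) -> Iterator[Reconciliation]:
    """Yield every optimal reconciliation exactly once, deterministically.

    Order: optimal root hosts in postorder-id order; within a root, the
    odometer over per-cell alternative lists with the *last* internal
    parasite vertex (in preorder) varying fastest.  Memory beyond the
    table is O(m); successive solutions are produced in O(m) each.
    """
    if table.opt == float("inf"):
        return
    parasite = table.parasite
    emitted = 0
    for root_host in table.opt_roots:
        for gamma in _assignments(table, root_host):
            if max_solutions is not None and emitted >= max_solutions:
                return
            yield Reconciliation.from_gamma(
                table.host, table.parasite, table.phi, gamma, table.costs
            )
            emitted += 1


def _assignments(table: DPTable, root_host: int) -> Iterator[dict[int, int]]:
    parasite = table.parasite
    root = parasite.root
    if parasite.is_leaf(root):
        yield {root: root_host}
        return
    # internal parasite vertices in preorder: digit j's radix (the length
    # of its cell's alternative list) depends only on digits < j, so a
    # mixed-radix odometer visits every combination exactly once
    order = [v for v in parasite.preorder() if not parasite.is_leaf(v)]
    idx = [0] * len(order)
    while True:
        gamma: dict[int, int] = {root: root_host}
        cells: list[tuple[int, int]] = []
        for j, v in enumerate(order):
            cell = (v, gamma[v])
            cells.append(cell)
            alt = table.alts[cell][idx[j]]
            c1, c2 = parasite.children(v)
            gamma[c1] = alt.left_host
            gamma[c2] = alt.right_host
        yield gamma
        # advance the deepest digit with an unexhausted alternative and
        # reset all deeper ones
        j = len(order) - 1
        while j >= 0 and idx[j] + 1 >= len(table.alts[cells[j]]):
            j -= 1
        if j < 0:
            return
        idx[j] += 1
        for jj in range(j + 1, len(order)):
            idx[jj] = 0


def first_solution(table: DPTable) -> Reconciliation:
    """Head of the enumeration stream (the streaming mode for instances
    whose full solution set is astronomically large)."""
    for recon in enumerate_optimal(table, max_solutions=1):
        return recon
    raise NoSolutionError("instance has no valid reconciliation")


# ------------------------------------------------------------- serialization


def _solution_rows(
    table: DPTable, recon: Reconciliation
) -> list[tuple[str, str, str]]:
    parasite, host = table.parasite, table.host
    rows = []
    for p in parasite.postorder():
        h = recon.gamma[p]
        ev = recon.events.get(p)
        rows.append(
            (parasite.name(p), host.name(h), ev.code if ev else "leaf")
        )
    return rows


def write_solutions_text(
    table: DPTable, solutions, out: IO[str]
) -> int:
    """Write one block per solution: ``parasite TAB host TAB event`` rows,
    a losses line, and the event vector.  Returns the number written."""
    n = 0
    for i, recon in enumerate(solutions):
        out.write(f"# solution {i}\n")
        for prow, hrow, ev in _solution_rows(table, recon):
            out.write(f"{prow}\t{hrow}\t{ev}\n")
        loss_names = sorted(
            name
            for h, mult in recon.losses.items()
            for name in [table.host.name(h)] * mult
        )
        out.write("losses\t" + (",".join(loss_names) or "-") + "\n")
        nc, nd, ns, nl = recon.event_vector
        out.write(f"events\t{nc},{nd},{ns},{nl}\n\n")
        n += 1
    return n


def write_solutions_jsonl(table: DPTable, solutions, out: IO[str]) -> int:
    """JSON-lines variant of the solution stream (one object per line,
    deterministic field order)."""
    n = 0
    for recon in solutions:
        obj = {
            "gamma": [
                [table.parasite.name(p), table.host.name(h)]
                for p, h in sorted(recon.gamma.items())
            ],
            "events": [
                [table.parasite.name(p), ev.code]
                for p, ev in sorted(recon.events.items())
            ],
            "losses": sorted(
                name
                for h, mult in recon.losses.items()
                for name in [table.host.name(h)] * mult
            ),
            "event_vector": list(recon.event_vector),
            "cost": recon.cost,
        }
        out.write(json.dumps(obj, separators=(",", ":")) + "\n")
        n += 1
    return n
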