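"""Rooted binary phylogenetic trees and host--parasite instance I/O.

The central object is :class:`PhyloTree`, a fully binary rooted tree with
labelled leaves.  Vertices are integers numbered in postorder (children
before parents, root last); that numbering is the canonical iteration and
tie-breaking order used throughout the package.  Branch lengths present in
Newick input are accepted and discarded: all distances are topological
edge counts.

Instances (host tree, parasite tree, leaf association) can be read from a
Nexus file in the Jane/CoRe-PA host--parasite dialect or from a pair of
Newick files plus a tab-separated leaf-mapping file.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy

logger = logging.getLogger(__name__)

__all__ = [
    "PhyloTree",
    "LeafMapping",
    "TreeError",
    "NewickParseError",
    "PolytomyError",
    "DuplicateLeafError",
    "UnknownVertexError",
    "MappingError",
    "IncompleteMappingError",
    "UnknownLeafError",
    "parse_newick",
    "parse_instance",
    "read_nexus",
    "read_newick_pair",
    "write_nexus",
    "write_newick_pair",
]


class TreeError(ValueError):
    """Base class for tree construction and query errors."""


class NewickParseError(TreeError):
    """Malformed Newick text (message includes line/column when known)."""


class PolytomyError(TreeError):
    """A vertex with out-degree other than 0 or 2 was encountered."""


class DuplicateLeafError(TreeError):
    """Two leaves of one tree carry the same label."""


class UnknownVertexError(TreeError):
    """A vertex id outside the tree was used in a query."""


class MappingError(ValueError):
    """Base class for leaf-association errors."""


class IncompleteMappingError(MappingError):
    """A parasite leaf has no host image."""


class UnknownLeafError(MappingError):
    """The association references a leaf label absent from the tree."""


class PhyloTree:
    """Rooted binary tree with labelled leaves and postorder integer vertices.

    Vertices are ``0 .. n_vertices - 1`` in postorder; the root is always
    ``n_vertices - 1``.  Internal vertices without an explicit name get a
    deterministic auto-name: the lexicographically smallest leaf label of
    each child subtree, joined by ``"+"``.
    """

    def __init__(
        self,
        children: Sequence[tuple[int, ...]],
        labels: Sequence[str | None],
        names: Sequence[str | None] | None = None,
    ):
        n = len(children)
        self._children: list[tuple[int, ...]] = [tuple(c) for c in children]
        self._parent: list[int] = [-1] * n
        for v, cs in enumerate(self._children):
            if len(cs) not in (0, 2):
                raise PolytomyError(
                    f"vertex {names[v] if names and names[v] else v} has "
                    f"{len(cs)} children; trees must be strictly binary"
                )
            for c in cs:
                self._parent[c] = v
        roots = [v for v in range(n) if self._parent[v] == -1]
        if len(roots) != 1:
            raise TreeError(f"expected exactly one root, found {len(roots)}")
        self._root = roots[0]

        self._label: list[str | None] = list(labels)
        seen: set[str] = set()
        for v in range(n):
            if not self._children[v]:
                lab = self._label[v]
                if lab is None:
                    raise TreeError(f"leaf vertex {v} has no label")
                if lab in seen:
                    raise DuplicateLeafError(f"duplicate leaf label {lab!r}")
                seen.add(lab)

        # depths and subtree leaf sets drive auto-naming and queries
        self._depth = [0] * n
        self._min_leaf: list[str] = [""] * n
        order = self.postorder()
        for v in order:
            cs = self._children[v]
            if cs:
                self._min_leaf[v] = min(self._min_leaf[c] for c in cs)
            else:
                self._min_leaf[v] = self._label[v]  # type: ignore[assignment]
        for v in reversed(order):
            for c in self._children[v]:
                self._depth[c] = self._depth[v] + 1

        self._name: list[str] = [""] * n
        for v in range(n):
            cs = self._children[v]
            explicit = names[v] if names is not None else None
            if explicit:
                self._name[v] = explicit
            elif cs:
                self._name[v] = "+".join(sorted(self._min_leaf[c] for c in cs))
            else:
                self._name[v] = self._label[v]  # type: ignore[assignment]

        # Euler intervals for O(1) ancestor tests
        self._tin = [0] * n
        self._tout = [0] * n
        clock = 0
        stack: list[tuple[int, bool]] = [(self._root, False)]
        while stack:
            v, done = stack.pop()
            if done:
                self._tout[v] = clock
                clock += 1
            else:
                self._tin[v] = clock
                clock += 1
                stack.append((v, True))
                for c in reversed(self._children[v]):
                    stack.append((c, False))

        self._by_label = {
            self._label[v]: v for v in range(n) if not self._children[v]
        }
        self._dist: list[list[int]] | None = None

    # ---------------------------------------------------------------- basic
    @property
    def n_vertices(self) -> int:
        return len(self._children)

    @property
    def root(self) -> int:
        return self._root

    def _check(self, v: int) -> None:
        if not (0 <= v < len(self._children)):
            raise UnknownVertexError(f"vertex {v} not in tree")

    def children(self, v: int) -> tuple[int, ...]:
        self._check(v)
        return self._children[v]

    def parent(self, v: int) -> int | None:
        self._check(v)
        p = self._parent[v]
        return None if p < 0 else p

    def is_leaf(self, v: int) -> bool:
        self._check(v)
        return not self._children[v]

    def leaf_label(self, v: int) -> str:
        self._check(v)
        if self._children[v]:
            raise TreeError(f"vertex {v} is internal and has no leaf label")
        return self._label[v]  # type: ignore[return-value]

    def name(self, v: int) -> str:
        self._check(v)
        return self._name[v]

    def depth(self, v: int) -> int:
        self._check(v)
        return self._depth[v]

    def vertex_by_label(self, label: str) -> int:
        try:
            return self._by_label[label]
        except KeyError:
            raise UnknownLeafError(f"no leaf labelled {label!r}") from None

    def leaves(self) -> list[int]:
        return [v for v in range(self.n_vertices) if not self._children[v]]

    def leaf_labels(self) -> list[str]:
        return [self._label[v] for v in self.leaves()]  # type: ignore[misc]

    def internal_vertices(self) -> list[int]:
        return [v for v in range(self.n_vertices) if self._children[v]]

    def postorder(self) -> list[int]:
        """Vertices in postorder.  Ids are assigned in postorder at
        construction, so this is simply ``0..n-1``."""
        return list(range(self.n_vertices))

    def preorder(self) -> list[int]:
        out: list[int] = []
        stack = [self._root]
        while stack:
            v = stack.pop()
            out.append(v)
            for c in reversed(self._children[v]):
                stack.append(c)
        return out

    # -------------------------------------------------------------- queries
    def is_ancestor(self, u: int, v: int) -> bool:
        """True iff ``u`` is an ancestor of ``v`` (reflexively: u of u)."""
        self._check(u)
        self._check(v)
        return self._tin[u] <= self._tin[v] and self._tout[v] <= self._tout[u]

    def are_comparable(self, u: int, v: int) -> bool:
        return self.is_ancestor(u, v) or self.is_ancestor(v, u)

    def lca(self, u: int, v: int) -> int:
        self._check(u)
        self._check(v)
        while not self.is_ancestor(u, v):
            u = self._parent[u]
        return u

    def distance(self, u: int, v: int) -> int:
        """Number of edges on the undirected path between ``u`` and ``v``."""
        if self._dist is not None:
            self._check(u)
            self._check(v)
            return self._dist[u][v]
        a = self.lca(u, v)
        return self._depth[u] + self._depth[v] - 2 * self._depth[a]

    def distance_table(self) -> list[list[int]]:
        """All-pairs topological distances, computed once and cached."""
        if self._dist is None:
            n = self.n_vertices
            d = [[0] * n for _ in range(n)]
            for u in range(n):
                for v in range(u + 1, n):
                    a = self.lca(u, v)
                    duv = self._depth[u] + self._depth[v] - 2 * self._depth[a]
                    d[u][v] = d[v][u] = duv
            self._dist = d
        return self._dist

    def subtree_vertices(self, u: int) -> list[int]:
        """All vertices of the subtree rooted at ``u`` (including ``u``),
        in increasing (postorder) id order."""
        self._check(u)
        return [
            v
            for v in range(self.n_vertices)
            if self._tin[u] <= self._tin[v] and self._tout[v] <= self._tout[u]
        ]

    def diameter(self) -> int:
        """Longest topological path (in edges) between any two vertices."""
        d = self.distance_table()
        return max((max(row) for row in d), default=0)

    # ------------------------------------------------------------------ I/O
    def to_newick(self, include_internal_names: bool = False) -> str:
        def rec(v: int) -> str:
            if not self._children[v]:
                return _quote_newick(self._label[v])  # type: ignore[arg-type]
            inner = ",".join(rec(c) for c in self._children[v])
            name = _quote_newick(self._name[v]) if include_internal_names else ""
            return f"({inner}){name}"

        return rec(self._root) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PhyloTree({self.to_newick()!r})"


_NEWICK_UNQUOTED = re.compile(r"^[^\s()\[\]{}/\\,;:=*'\"`<>]+$")


def _quote_newick(label: str) -> str:
    if _NEWICK_UNQUOTED.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


@dataclass(frozen=True)
class LeafMapping:
    """Total association of parasite leaves to host leaves.

    ``assoc`` maps parasite leaf vertex ids to host leaf vertex ids.  Every
    parasite leaf has exactly one image; a host leaf may have any number of
    pre-images (including none).
    """

    assoc: Mapping[int, int]

    @classmethod
    def from_labels(
        cls, host: PhyloTree, parasite: PhyloTree, pairs: Mapping[str, str]
    ) -> "LeafMapping":
        assoc: dict[int, int] = {}
        for p_lab, h_lab in pairs.items():
            p = parasite.vertex_by_label(p_lab)
            h = host.vertex_by_label(h_lab)
            assoc[p] = h
        missing = [
            parasite.leaf_label(v) for v in parasite.leaves() if v not in assoc
        ]
        if missing:
            raise IncompleteMappingError(
                f"parasite leaves with no host image: {sorted(missing)}"
            )
        return cls(assoc=assoc)

    def validate(self, host: PhyloTree, parasite: PhyloTree) -> None:
        for v in parasite.leaves():
            if v not in self.assoc:
                raise IncompleteMappingError(
                    f"parasite leaf {parasite.leaf_label(v)!r} has no host image"
                )
        for p, h in self.assoc.items():
            if not parasite.is_leaf(p):
                raise MappingError(f"mapping source {p} is not a parasite leaf")
            if not host.is_leaf(h):
                raise MappingError(f"mapping image {h} is not a host leaf")

    def as_label_pairs(
        self, host: PhyloTree, parasite: PhyloTree
    ) -> list[tuple[str, str]]:
        return sorted(
            (parasite.leaf_label(p), host.leaf_label(h))
            for p, h in self.assoc.items()
        )


# ------------------------------------------------------------------ parsing


def _from_dendropy(tree: dendropy.Tree) -> PhyloTree:
    """Convert a dendropy tree to a postorder-indexed :class:`PhyloTree`."""
    nodes = list(tree.postorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    children: list[tuple[int, ...]] = []
    labels: list[str | None] = []
    names: list[str | None] = []
    for nd in nodes:
        kids = nd.child_nodes()
        if len(kids) not in (0, 2):
            who = nd.taxon.label if nd.taxon else (nd.label or f"#{index[id(nd)]}")
            raise PolytomyError(
                f"vertex {who!r} has {len(kids)} children; "
                "only strictly binary trees are supported"
            )
        children.append(tuple(index[id(k)] for k in kids))
        if kids:
            labels.append(None)
            names.append(nd.label or (nd.taxon.label if nd.taxon else None))
        else:
            lab = nd.taxon.label if nd.taxon else nd.label
            if lab is None:
                raise NewickParseError("leaf without a label")
            labels.append(lab)
            names.append(None)
    return PhyloTree(children, labels, names)


def parse_newick(text: str) -> PhyloTree:
    """Parse a single rooted, strictly binary Newick description.

    Branch lengths are accepted and ignored.  Polytomies raise
    :class:`PolytomyError`; duplicate leaf labels raise
    :class:`DuplicateLeafError`; malformed text raises
    :class:`NewickParseError` carrying dendropy's line/column diagnosis.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
        )
    except dendropy.utility.error.DataParseError as exc:
        msg = str(exc)
        if "Duplicate taxon labels" in msg or "Multiple occurrences" in msg:
            raise DuplicateLeafError(msg) from exc
        raise NewickParseError(msg) from exc
    return _from_dendropy(tree)


# ------------------------------------------------- Nexus host--parasite files

_BLOCK_RE = re.compile(
    r"begin\s+(\w+)\s*;(.*?)end\s*;", re.IGNORECASE | re.DOTALL
)
_TREE_RE = re.compile(r"tree\s+[^=]*=\s*(.*?;)", re.IGNORECASE | re.DOTALL)
_RANGE_RE = re.compile(r"range\s+(.*?);", re.IGNORECASE | re.DOTALL)


def read_nexus(path: str | Path) -> tuple[PhyloTree, PhyloTree, LeafMapping]:
    """Read the Jane/CoRe-PA Nexus host--parasite dialect.

    Expected blocks: ``BEGIN HOST;`` and ``BEGIN PARASITE;``, each with one
    ``TREE`` statement, and ``BEGIN DISTRIBUTION;`` with
    ``RANGE p1:h1, p2:h2, ...;``.  Matching is case-insensitive and
    whitespace-tolerant; unknown blocks are skipped with a logged warning.
    """
    text = Path(path).read_text(encoding="utf-8")
    host_nwk = parasite_nwk = None
    range_body = None
    for m in _BLOCK_RE.finditer(text):
        kind = m.group(1).lower()
        body = m.group(2)
        if kind == "host":
            tm = _TREE_RE.search(body)
            if not tm:
                raise NewickParseError(f"{path}: HOST block has no TREE statement")
            host_nwk = tm.group(1)
        elif kind == "parasite":
            tm = _TREE_RE.search(body)
            if not tm:
                raise NewickParseError(
                    f"{path}: PARASITE block has no TREE statement"
                )
            parasite_nwk = tm.group(1)
        elif kind == "distribution":
            rm = _RANGE_RE.search(body)
            if not rm:
                raise MappingError(
                    f"{path}: DISTRIBUTION block has no RANGE statement"
                )
            range_body = rm.group(1)
        else:
            logger.warning("%s: skipping unknown Nexus block %r", path, kind)
    if host_nwk is None or parasite_nwk is None or range_body is None:
        raise TreeError(
            f"{path}: need HOST, PARASITE and DISTRIBUTION blocks "
            f"(found host={host_nwk is not None}, "
            f"parasite={parasite_nwk is not None}, "
            f"distribution={range_body is not None})"
        )
    host = parse_newick(host_nwk)
    parasite = parse_newick(parasite_nwk)
    pairs: dict[str, str] = {}
    for entry in range_body.split(","):
        entry = entry.strip()
        if not entry:
            continue
        if ":" not in entry:
            raise MappingError(f"{path}: malformed RANGE entry {entry!r}")
        p_lab, h_lab = (s.strip() for s in entry.split(":", 1))
        pairs[p_lab] = h_lab
    phi = LeafMapping.from_labels(host, parasite, pairs)
    return host, parasite, phi


def read_newick_pair(
    host_path: str | Path, parasite_path: str | Path, mapping_path: str | Path
) -> tuple[PhyloTree, PhyloTree, LeafMapping]:
    """Read an instance given as two Newick files plus a two-column TSV
    (parasite leaf TAB host leaf, no header)."""
    host = parse_newick(Path(host_path).read_text(encoding="utf-8"))
    parasite = parse_newick(Path(parasite_path).read_text(encoding="utf-8"))
    pairs: dict[str, str] = {}
    for ln, line in enumerate(
        Path(mapping_path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip():
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) != 2:
            raise MappingError(
                f"{mapping_path}:{ln}: expected two tab-separated columns"
            )
        pairs[cols[0].strip()] = cols[1].strip()
    phi = LeafMapping.from_labels(host, parasite, pairs)
    return host, parasite, phi


def parse_instance(
    path: str | Path | Sequence[str | Path], format: str = "nexus"
) -> tuple[PhyloTree, PhyloTree, LeafMapping]:
    """Dispatch to :func:`read_nexus` or :func:`read_newick_pair`.

    For ``format="newick-pair"``, ``path`` is the triple
    ``(host, parasite, mapping)``.
    """
    if format == "nexus":
        return read_nexus(path)  # type: ignore[arg-type]
    if format == "newick-pair":
        host_p, para_p, map_p = path  # type: ignore[misc]
        return read_newick_pair(host_p, para_p, map_p)
    raise ValueError(f"unknown instance format {format!r}")


def write_nexus(
    path: str | Path, host: PhyloTree, parasite: PhyloTree, phi: LeafMapping
) -> None:
    buf = io.StringIO()
    buf.write("#NEXUS\n\n")
    buf.write("BEGIN HOST;\n")
    buf.write(f"TREE HOST = {host.to_newick()}\n")
    buf.write("END;\n\n")
    buf.write("BEGIN PARASITE;\n")
    buf.write(f"TREE PARASITE = {parasite.to_newick()}\n")
    buf.write("END;\n\n")
    buf.write("BEGIN DISTRIBUTION;\n")
    entries = ", ".join(
        f"{p}:{h}" for p, h in phi.as_label_pairs(host, parasite)
    )
    buf.write(f"RANGE {entries};\n")
    buf.write("END;\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def write_newick_pair(
    host_path: str | Path,
    parasite_path: str | Path,
    mapping_path: str | Path,
    host: PhyloTree,
    parasite: PhyloTree,
    phi: LeafMapping,
) -> None:
    Path(host_path).write_text(host.to_newick() + "\n", encoding="utf-8")
    Path(parasite_path).write_text(parasite.to_newick() + "\n", encoding="utf-8")
    lines = [
        f"{p}\t{h}" for p, h in phi.as_label_pairs(host, parasite)
    ]
    Path(mapping_path).write_text("\n".join(lines) + "\n", encoding="utf-8")
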