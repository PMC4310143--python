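"""Tree model, Newick/Nexus/TSV readers, and ancestry/distance queries."""

import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allmpr.fixtures import InstanceSpec, random_instance, random_tree
from allmpr.trees import (
    DuplicateLeafError,
    IncompleteMappingError,
    LeafMapping,
    NewickParseError,
    PolytomyError,
    UnknownLeafError,
    UnknownVertexError,
    parse_instance,
    parse_newick,
    read_newick_pair,
    read_nexus,
    write_newick_pair,
    write_nexus,
)


class TestParseNewick:
    def test_smallest_binary_tree(self):
        t = parse_newick("(A,B);")
        assert t.n_vertices == 3
        assert sorted(t.leaf_label(c) for c in t.children(t.root)) == ["A", "B"]

    def test_five_vertices(self):
        t = parse_newick("((A,B),C);")
        assert t.n_vertices == 5
        assert sorted(t.leaf_labels()) == ["A", "B", "C"]

    def test_polytomy_rejected(self):
        with pytest.raises(PolytomyError):
            parse_newick("(A,B,C);")

    def test_duplicate_leaf_rejected(self):
        with pytest.raises(DuplicateLeafError):
            parse_newick("(A,A);")

    def test_malformed_reports_position(self):
        with pytest.raises(NewickParseError, match="column"):
            parse_newick("((A,B;")

    def test_single_leaf_tree(self):
        t = parse_newick("A;")
        assert t.n_vertices == 1
        assert t.is_leaf(t.root)

    def test_branch_lengths_ignored(self):
        t = parse_newick("((A:1.5,B:0.2):3,C:1);")
        assert t.n_vertices == 5

    def test_auto_names_are_min_leaf_joins(self):
        t = parse_newick("((B,D),(A,C));")
        assert t.name(t.root) == "A+B"

    def test_postorder_root_last(self):
        t = parse_newick("((A,B),(C,D));")
        order = t.postorder()
        assert len(order) == t.n_vertices
        assert order[-1] == t.root
        # children always precede parents
        for v in order:
            for c in t.children(v):
                assert c < v


class TestQueries:
    def test_distance_identity_and_siblings(self):
        t = parse_newick("((A,B),C);")
        a, b, c = (t.vertex_by_label(x) for x in "ABC")
        assert t.distance(a, a) == 0
        assert t.distance(a, b) == 2
        assert t.distance(a, c) == 3

    def test_distance_matches_bfs_oracle(self):
        t = parse_newick("((A,B),C);")
        # adjacency BFS over the 5-vertex undirected graph
        adj = {v: set() for v in range(t.n_vertices)}
        for v in range(t.n_vertices):
            for c in t.children(v):
                adj[v].add(c)
                adj[c].add(v)
        for src in range(t.n_vertices):
            seen = {src: 0}
            frontier = [src]
            while frontier:
                nxt = []
                for u in frontier:
                    for w in adj[u]:
                        if w not in seen:
                            seen[w] = seen[u] + 1
                            nxt.append(w)
                frontier = nxt
            for dst in range(t.n_vertices):
                assert t.distance(src, dst) == seen[dst]

    def test_root_is_ancestor_of_all(self):
        t = parse_newick("((A,B),(C,D));")
        assert all(t.is_ancestor(t.root, v) for v in range(t.n_vertices))

    def test_lca_of_siblings(self):
        t = parse_newick("((A,B),C);")
        a, b = t.vertex_by_label("A"), t.vertex_by_label("B")
        assert t.lca(a, b) == t.parent(a)
        assert t.lca(a, b) == t.lca(b, a)

    def test_unknown_vertex_rejected(self):
        t = parse_newick("(A,B);")
        with pytest.raises(UnknownVertexError):
            t.distance(0, 99)

    @given(st.integers(min_value=0, max_value=500))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_ancestry_matches_subtree_membership(self, seed):
        t = random_tree(random.Random(seed).randint(1, 6), random.Random(seed), "x")
        for u, v in itertools.product(range(t.n_vertices), repeat=2):
            assert t.is_ancestor(u, v) == (v in set(t.subtree_vertices(u)))

    @given(st.integers(min_value=0, max_value=500))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_distance_is_a_metric(self, seed):
        t = random_tree(random.Random(seed).randint(1, 6), random.Random(seed), "x")
        n = t.n_vertices
        for u, v in itertools.product(range(n), repeat=2):
            assert t.distance(u, v) == t.distance(v, u)
            assert (t.distance(u, v) == 0) == (u == v)
        for u, v, w in itertools.product(range(n), repeat=3):
            assert t.distance(u, w) <= t.distance(u, v) + t.distance(v, w)

    def test_comparability_dichotomy(self):
        t = parse_newick("((A,B),(C,D));")
        for u, v in itertools.product(range(t.n_vertices), repeat=2):
            comparable = t.is_ancestor(u, v) or t.is_ancestor(v, u)
            assert comparable == t.are_comparable(u, v)


NEXUS_TOY = """#NEXUS
begin host;
tree host = (h1,h2);
end;
Begin Parasite;
TREE PARASITE = (p1,p2);
End;
BEGIN DISTRIBUTION;
RANGE p1:h1, p2:h2;
END;
"""


class TestInstanceIO:
    def test_nexus_two_leaf_instance(self, tmp_path):
        f = tmp_path / "toy.nex"
        f.write_text(NEXUS_TOY)
        host, parasite, phi = read_nexus(f)
        assert sorted(host.leaf_labels()) == ["h1", "h2"]
        assert sorted(parasite.leaf_labels()) == ["p1", "p2"]
        assert phi.as_label_pairs(host, parasite) == [
            ("p1", "h1"),
            ("p2", "h2"),
        ]

    def test_nexus_unknown_block_skipped(self, tmp_path, caplog):
        f = tmp_path / "toy.nex"
        f.write_text(
            NEXUS_TOY + "\nBEGIN TAXA;\nwhatever;\nEND;\n"
        )
        host, _, _ = read_nexus(f)
        assert host.n_vertices == 3

    def test_incomplete_mapping_rejected(self, tmp_path):
        h = tmp_path / "h.nwk"
        p = tmp_path / "p.nwk"
        m = tmp_path / "m.tsv"
        h.write_text("(h1,h2);")
        p.write_text("(p1,p2);")
        m.write_text("p1\th1\n")
        with pytest.raises(IncompleteMappingError):
            read_newick_pair(h, p, m)

    def test_unknown_leaf_rejected(self, tmp_path):
        h = tmp_path / "h.nwk"
        p = tmp_path / "p.nwk"
        m = tmp_path / "m.tsv"
        h.write_text("(h1,h2);")
        p.write_text("(p1,p2);")
        m.write_text("p1\th1\np2\thX\n")
        with pytest.raises(UnknownLeafError):
            read_newick_pair(h, p, m)

    @pytest.mark.parametrize("fmt", ["nexus", "newick-pair"])
    def test_round_trip_both_formats(self, tmp_path, fmt):
        host, parasite, phi = random_instance(InstanceSpec(5, 4, seed=7))
        if fmt == "nexus":
            f = tmp_path / "inst.nex"
            write_nexus(f, host, parasite, phi)
            h2, p2, phi2 = parse_instance(f, format="nexus")
        else:
            paths = (
                tmp_path / "h.nwk",
                tmp_path / "p.nwk",
                tmp_path / "m.tsv",
            )
            write_newick_pair(*paths, host, parasite, phi)
            h2, p2, phi2 = parse_instance(paths, format="newick-pair")
        assert h2.to_newick() == host.to_newick()
        assert p2.to_newick() == parasite.to_newick()
        assert phi2.as_label_pairs(h2, p2) == phi.as_label_pairs(
            host, parasite
        )

    def test_mapping_totality_validated(self):
        host = parse_newick("(h1,h2);")
        parasite = parse_newick("(p1,p2);")
        with pytest.raises(IncompleteMappingError):
            LeafMapping.from_labels(host, parasite, {"p1": "h1"})
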