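"""Shared fixtures: toy instances, tree builders, and the seeded random
battery that anchors the oracle-equivalence suite."""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import pytest

from allmpr import (
    CostVector,
    DPTable,
    LeafMapping,
    PhyloTree,
    Reconciliation,
    enumerate_optimal,
    fill_dp,
    parse_newick,
)
from allmpr.fixtures import InstanceSpec, brute_force_optimal, random_instance

BATTERY_SEED = 1234
BATTERY_SIZE = 200
COST_VALUES = (-1, 0, 1, 2, 3)
K_CHOICES = (1, 2, None)


def caterpillar(n: int, prefix: str) -> PhyloTree:
    s = f"{prefix}1"
    for i in range(2, n + 1):
        s = f"({s},{prefix}{i})"
    return parse_newick(s + ";")


def balanced(n: int, prefix: str) -> PhyloTree:
    labs = [f"{prefix}{i}" for i in range(1, n + 1)]

    def build(ls):
        if len(ls) == 1:
            return ls[0]
        m = len(ls) // 2
        return "(" + build(ls[:m]) + "," + build(ls[m:]) + ")"

    return parse_newick(build(labs) + ";")


@dataclass
class BatteryCase:
    """One random instance with the DP result, the enumerated solution
    list, and the brute-force oracle's answer."""

    seed: int
    host: PhyloTree
    parasite: PhyloTree
    phi: LeafMapping
    costs: CostVector
    k: int | None
    table: DPTable
    solutions: list[Reconciliation]
    oracle_opt: float
    oracle_solutions: list[Reconciliation]


def make_battery(
    base_seed: int = BATTERY_SEED, size: int = BATTERY_SIZE
) -> list[BatteryCase]:
    rng = random.Random(base_seed)
    cases = []
    for i in range(size):
        nh = rng.randint(1, 6)
        np_ = rng.randint(1, 6)
        seed = base_seed * 1000 + i
        host, parasite, phi = random_instance(InstanceSpec(nh, np_, seed=seed))
        costs = CostVector(*(rng.choice(COST_VALUES) for _ in range(4)))
        k = rng.choice(K_CHOICES)
        oracle_opt, oracle_sols = brute_force_optimal(
            host, parasite, phi, costs, k
        )
        table = fill_dp(host, parasite, phi, costs, k=k)
        solutions = (
            list(enumerate_optimal(table))
            if table.opt != float("inf")
            else []
        )
        cases.append(
            BatteryCase(
                seed=seed,
                host=host,
                parasite=parasite,
                phi=phi,
                costs=costs,
                k=k,
                table=table,
                solutions=solutions,
                oracle_opt=oracle_opt,
                oracle_solutions=oracle_sols,
            )
        )
    return cases


@pytest.fixture(scope="session")
def battery() -> list[BatteryCase]:
    return make_battery()


@pytest.fixture
def congruent3():
    """Host and parasite congruent 3-leaf trees with the matched mapping."""
    host = parse_newick("((A,B),C);")
    parasite = parse_newick("((a,b),c);")
    phi = LeafMapping.from_labels(
        host, parasite, {"a": "A", "b": "B", "c": "C"}
    )
    return host, parasite, phi


@pytest.fixture
def crossed_switch():
    """Two reciprocal host switches whose donor lineages must each predate
    the other — no temporal ordering of host speciations exists."""
    host = parse_newick("((a,b),(c,d));")
    parasite = parse_newick("((pa1,(pc1,pd1)),(pc2,(pa2,pb2)));")
    phi = LeafMapping.from_labels(
        host,
        parasite,
        {
            "pa1": "a",
            "pc1": "c",
            "pd1": "d",
            "pc2": "c",
            "pa2": "a",
            "pb2": "b",
        },
    )
    host_by_name = {host.name(v): v for v in range(host.n_vertices)}
    para_by_name = {
        parasite.name(v): v for v in range(parasite.n_vertices)
    }
    gamma = {p: h for p, h in phi.assoc.items()}
    gamma[para_by_name["pc1+pd1"]] = host_by_name["c+d"]
    gamma[para_by_name["pa1+pc1"]] = host.vertex_by_label("a")
    gamma[para_by_name["pa2+pb2"]] = host_by_name["a+b"]
    gamma[para_by_name["pa2+pc2"]] = host.vertex_by_label("c")
    gamma[parasite.root] = host.root
    recon = Reconciliation.from_gamma(
        host, parasite, phi, gamma, CostVector(0, 1, 1, 1)
    )
    return host, parasite, recon
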