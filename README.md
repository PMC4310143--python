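# allmpr

Exact enumeration of **all** most-parsimonious cophylogeny
reconciliations under the duplication–transfer–loss (DTL) event model —
for researchers studying host–parasite coevolution, gene-tree/species-tree
association, or any other pair of dependently evolving phylogenies.

## The problem

Given a rooted binary host tree *H*, a rooted binary parasite tree *P*,
an association φ from parasite leaves to host leaves, and a cost vector
⟨c_c, c_d, c_s, c_l⟩ for the four events — **c**ospeciation,
**d**uplication, host **s**witch (transfer), **l**oss — a reconciliation
is a map γ: V(P) → V(H) extending φ, with one event per internal parasite
vertex and a derived loss multiset; its cost is
c_c·#c + c_d·#d + c_s·#s + c_l·#l. Under most cost vectors the optimum
is attained by *many* reconciliations (counts beyond 10³⁰ occur on trees
of modest size), and some of them are biologically impossible: their
switches imply a cyclic temporal ordering of host speciations. Any
downstream interpretation needs the whole optimal set, or at least honest
summaries of it.

`allmpr` provides, with no restriction on cost signs (negative
cospeciation costs are fine):

- the optimal cost and **exact** solution count (arbitrary precision,
  never enumerated) via a dynamic program whose cells store *all*
  optimal child placements — a solution DAG;
- deterministic enumeration of all optimal reconciliations with O(m)
  delay per solution (m = parasite tree size);
- a time-feasibility (acyclicity) test for each solution and
  acyclic/cyclic splits;
- grouping of solutions into event classes ⟨#c, #d, #s, #l⟩;
- the distance-bounded switch variant: optimal reconciliations whose
  switches land within k edges of their takeoff, with sweep procedures
  (`k_start`, `find_kA`, `find_kprime`) that locate useful bounds
  automatically;
- rooting of an unrooted parasite/gene tree by minimum reconciliation
  cost over all edges.

Inputs are a Nexus file in the Jane/CoRe-PA host–parasite dialect, or two
Newick files plus a tab-separated leaf mapping.

## Worked example

`example.nex`:

```
#NEXUS
BEGIN HOST;
TREE HOST = (((h1,h2),h3),h4);
END;
BEGIN PARASITE;
TREE PARASITE = ((p1,p2),(p3,p4));
END;
BEGIN DISTRIBUTION;
RANGE p1:h1, p2:h3, p3:h2, p4:h4;
END;
```

```sh
allmpr --input example.nex --costs 0,1,1,1 --classes
```

prints (provenance fields elided):

```json
{
  "acyclic": "2",
  "classes": [
    {"count": 1, "event_vector": [1, 0, 2, 0]},
    {"count": 1, "event_vector": [2, 0, 1, 1]}
  ],
  "cyclic": "0",
  "k_start": 4,
  "mode": "classes",
  "optimal_cost": 2,
  "total": "2"
}
```

Reading: under costs ⟨0,1,1,1⟩ the optimum costs 2 and is attained by
exactly two reconciliations, both time-feasible, falling into two event
classes — one explains the data with 1 cospeciation and 2 host switches
(no losses), the other with 2 cospeciations, 1 switch and 1 loss.
`k_start = 4` says every optimal solution needs some switch spanning 4
host-tree edges; re-running with `-k 3` would trade cost for shorter
switches. Counts are serialized as decimal strings because exact counts
routinely exceed 64-bit (and double) range.

The same pipeline is available as a library:

```python
from allmpr import (CostVector, fill_dp, count_optimal, enumerate_optimal,
                    split_by_feasibility, read_nexus)

host, parasite, phi = read_nexus("example.nex")
table = fill_dp(host, parasite, phi, CostVector(0, 1, 1, 1))
print(table.opt, count_optimal(table))          # 2 2
acyclic, cyclic = split_by_feasibility(
    enumerate_optimal(table), host, parasite)
```

Other CLI modes: `--count`, `--enumerate [--acyclic-only] [--json]`,
`--sweep-ka`, `--sweep-kprime`, `--select-root`, with `-k INT|unbounded`
and `--max-solutions` caps; see `allmpr --help`. The default mode reports
the exact count plus the first solution and its feasibility verdict,
which is the practical workflow for instances with astronomical counts.

Documentation of the model, algorithms and design choices is in
[`docs/methods.md`](docs/methods.md).

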