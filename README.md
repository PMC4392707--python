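# splitdiv — split-diversity conservation prioritization by exact ILP

`splitdiv` selects conservation units — protected areas or taxa — so that the
selected set retains as much **split diversity (SD)** as possible, using exact
integer linear programming (HiGHS via `scipy.optimize.milp`).

## Background

Faith's phylogenetic diversity (PD) of a taxon subset is the total branch
length of the smallest subtree connecting the subset — but it is defined on a
single tree. Real phylogenetic analyses produce *collections* of trees
(bootstrap replicates, posterior samples) that rarely agree on one topology.

A **split system** `(Σ, λ)` sidesteps this. A split `σ` is a bipartition of
the taxon set into two non-empty sides; every branch of every tree induces
one. Pooling the splits of a tree collection (weights averaged, summed, or
replaced by frequencies) gives a weighted split system, and the **split
diversity** of a subset `W` is

```
SD(W) = Σ over splits σ that separate at least two taxa of W of λ(σ)
```

where "separates" means both sides of `σ` intersect `W`. On the split system
of a single tree, SD equals PD for every subset — so SD is a strict
generalization of PD to conflicting tree collections.

`splitdiv` solves three exact optimization problems on split systems:

1. **Reserve selection** — find the cheapest set of areas whose combined taxa
   retain at least `p%` of total SD. Costs are area acquisition cost plus an
   optional fencing term `β × perimeter` of the selected reserve
   (boundary-length matrix `b`).
2. **Viable taxon selection** — choose at most `k` taxa maximizing SD, subject
   to food-web viability: every selected predator must have at least one
   selected prey (or, with diet proportions, selected prey making up at least
   `d%` of its diet).
3. **Economic sweep** — re-solve reserve selection along a grid of urban/rural
   land-price ratios, recover the piecewise-linear optimal-cost curve, and
   locate the accumulated-cost break-even point between an early
   (urban-containing) and a late (rural-only) optimal reserve.

All solutions are exact optima, not heuristics, and each solver re-verifies
its answer with independent predicate checks before returning it.

## Worked example

The tree `((A:1,B:2):1,(C:3,D:4):2);` yields five splits. The two parallel
root edges induce the same bipartition `AB|CD`, so their lengths merge into
one split of weight 3:

| split | weight |
|---|---|
| `A \| BCD` | 1 |
| `B \| ACD` | 2 |
| `AB \| CD` | 3 |
| `C \| ABD` | 3 |
| `D \| ABC` | 4 |

```python
from splitdiv import Tree, TaxonSet, splits_from_tree, sd_score

tree = Tree.from_newick("((A:1,B:2):1,(C:3,D:4):2);", TaxonSet(["A", "B", "C", "D"]))
system = splits_from_tree(tree)
sd_score(system, [0, 1])   # SD(A,B) = 3.0  (splits A|BCD, B|ACD)
sd_score(system, [0, 2])   # SD(A,C) = 7.0  (A|BCD, AB|CD, C|ABD)
system.total_weight()      # 13.0 — the tree's total branch length
```

Both values equal the PD of the same subsets on the tree, as they must.

## Command line

The `splitdiv` command exposes the whole stack. A complete session on a
synthetic instance:

```
$ splitdiv synth --seed 7 --n-taxa 10 --n-trees 20 --grid 4 --out-dir demo
instance written to demo

$ splitdiv sd --trees demo/trees.nwk --subset t01,t02,t03,t04
10.4645364

$ splitdiv reserve --trees demo/trees.nwk --presence demo/presence.csv \
      --boundary demo/boundary.csv --costs demo/costs.csv --p 90 --beta 0.5
optimal: 3 areas, cost 8, SD 92.5796%

$ splitdiv taxonsel --trees demo/trees.nwk --foodweb demo/foodweb.tsv --k 5
optimal: 5 taxa, SD 15.9797 (92.5405% of total)
```

`splitdiv sweep` runs the cost-ratio analysis; `--out file.json` on any
subcommand writes the full machine-readable result. Infeasible instances
(e.g. a forced predator whose every potential prey is absent) exit with
status 3 and a certificate naming the cause.

Input formats: Newick tree files (one or many trees), NEXUS `SPLITS` blocks
(SplitsTree-style), presence / boundary / cost CSV matrices, and a
predator–prey TSV with optional diet proportions. See `docs/methods.md` for
the exact conventions.

## Layout

- `src/splitdiv/splits.py` — taxon sets, splits, split systems, trees, SD/PD
- `src/splitdiv/foodweb.py` — food webs, diet matrices, viability predicates
- `src/splitdiv/ilp.py` — ILP model layer over `scipy.optimize.milp`, plus
  brute-force enumeration oracles
- `src/splitdiv/reserve.py` — landscapes, reserve selection, minimum
  representation, cost-ratio sweep and break-even analysis
- `src/splitdiv/taxa.py` — (d%-)viable taxon selection
- `src/splitdiv/io.py` — readers/writers for all file formats
- `src/splitdiv/cli.py` — the `splitdiv` command
- `src/splitdiv/synth.py` — seeded synthetic instance generators

`docs/methods.md` documents the mathematical models, ILP formulations,
numerical choices, and generator assumptions in full.
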