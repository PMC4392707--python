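"""Seeded synthetic instances with the statistical structure the methods
assume: bootstrap-like tree collections, grid landscapes with geometric
boundary matrices and clustered species ranges, and layered acyclic food
webs with Dirichlet diet compositions.

Everything is driven by a single integer seed; the same seed yields a
bit-identical instance.
"""
from __future__ import annotations

import random
from dataclasses import dataclass

import dendropy
import numpy as np

from .foodweb import DietMatrix, FoodWeb
from .reserve import Landscape
from .splits import TaxonSet, Tree

__all__ = [
    "SynthSpec",
    "gen_tree_collection",
    "gen_landscape",
    "gen_strip_landscape",
    "gen_foodweb",
]


@dataclass
class SynthSpec:
    """Knobs of the synthetic-instance generators.

    Defaults emulate a moderately sized study: a 100-replicate bootstrap-like
    collection over 20 taxa, a 6x6 grid landscape with clustered rectangular
    ranges, and a 3-layer food web of intermediate connectance with uniform
    Dirichlet diets.
    """

    seed: int = 0
    n_taxa: int = 20
    # tree collection
    n_trees: int = 100
    nni_moves: int = 2           # topology perturbation strength per replicate
    length_jitter_sigma: float = 0.3  # lognormal sigma for branch-length noise
    # landscape
    grid: int = 6
    occupancy: float = 0.8       # per-cell occupancy inside a species' rectangle
    max_range: int = 3           # max rectangle side (cells)
    urban_block: int = 2         # urban corner block side (cells)
    unit_price: float = 1.0      # cost per unit cell area
    # food web
    layers: int = 3
    connectance: float = 0.5     # prob. of each possible cross-layer prey link
    diet_concentration: float = 1.0  # symmetric Dirichlet parameter


def _taxon_labels(n: int) -> list[str]:
    width = len(str(n))
    return [f"t{str(i + 1).zfill(width)}" for i in range(n)]


def _random_topology(labels: list[str], rng: random.Random) -> dendropy.Tree:
    """Yule-style topology: grow by repeatedly bifurcating a random leaf."""
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    leaves = []
    for _ in range(2):
        child = tree.seed_node.new_child()
        leaves.append(child)
    while len(leaves) < len(labels):
        node = leaves.pop(rng.randrange(len(leaves)))
        for _ in range(2):
            leaves.append(node.new_child())
    order = labels[:]
    rng.shuffle(order)
    for leaf, lab in zip(leaves, order):
        leaf.taxon = tns.require_taxon(label=lab)
    return tree


def _assign_exponential_lengths(
    tree: dendropy.Tree, rng: random.Random, mean: float = 1.0
) -> None:
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None:
            edge.length = rng.expovariate(1.0 / mean)


def _random_nni(tree: dendropy.Tree, rng: random.Random) -> None:
    """One nearest-neighbour-interchange on a random internal edge."""
    internal = [
        nd for nd in tree.preorder_node_iter()
        if nd.parent_node is not None and not nd.is_leaf()
    ]
    if not internal:
        return
    v = internal[rng.randrange(len(internal))]
    u = v.parent_node
    siblings = [c for c in u.child_nodes() if c is not v]
    if not siblings or not v.child_nodes():
        return
    s = siblings[rng.randrange(len(siblings))]
    a = v.child_nodes()[rng.randrange(len(v.child_nodes()))]
    # swap subtree a (below v) with sibling s (beside v)
    u.remove_child(s)
    v.remove_child(a)
    u.add_child(a)
    v.add_child(s)


def gen_tree_collection(spec: SynthSpec) -> list[Tree]:
    """A bootstrap-like tree collection over a shared taxon set.

    A base Yule topology receives exponential branch lengths; each replicate
    applies ``nni_moves`` random NNI rearrangements and multiplies every
    branch length by lognormal noise.  With ``nni_moves=0`` and
    ``length_jitter_sigma=0`` every replicate equals the base tree.
    """
    if spec.n_taxa < 3:
        raise ValueError("need at least 3 taxa for a tree collection")
    rng = random.Random(spec.seed)
    labels = _taxon_labels(spec.n_taxa)
    taxa = TaxonSet(labels)
    base = _random_topology(labels, rng)
    _assign_exponential_lengths(base, rng)
    base_newick = base.as_string(schema="newick")
    out = []
    for _ in range(spec.n_trees):
        rep = dendropy.Tree.get(
            data=base_newick, schema="newick", preserve_underscores=True
        )
        for _ in range(spec.nni_moves):
            _random_nni(rep, rng)
        if spec.length_jitter_sigma > 0:
            for edge in rep.preorder_edge_iter():
                if edge.head_node.parent_node is not None and edge.length:
                    edge.length *= rng.lognormvariate(
                        0.0, spec.length_jitter_sigma
                    )
        out.append(Tree(rep, taxa))
    return out


def gen_landscape(spec: SynthSpec, taxa: TaxonSet) -> Landscape:
    """A g x g grid landscape with 4-neighbourhood boundaries.

    Cells are unit squares: perimeter 4, shared edges of length 1.  Every
    taxon occupies cells of a random rectangle (each cell independently with
    probability ``occupancy``; regenerated up to 50 times if the draw leaves
    the range empty).  A corner block of cells is flagged urban.  Costs are
    cell area times the unit price.
    """
    g = spec.grid
    if g < 2:
        raise ValueError("grid must be at least 2x2")
    rng = random.Random(spec.seed + 1)
    m = g * g
    areas = [f"a{r}_{c}" for r in range(g) for c in range(g)]

    def cell(r: int, c: int) -> int:
        return r * g + c

    boundary = np.zeros((m, m))
    np.fill_diagonal(boundary, 4.0)
    for r in range(g):
        for c in range(g):
            if r + 1 < g:
                boundary[cell(r, c), cell(r + 1, c)] = 1.0
                boundary[cell(r + 1, c), cell(r, c)] = 1.0
            if c + 1 < g:
                boundary[cell(r, c), cell(r, c + 1)] = 1.0
                boundary[cell(r, c + 1), cell(r, c)] = 1.0
    presence = np.zeros((m, taxa.n), dtype=np.int8)
    max_range = min(spec.max_range, g)
    for j in range(taxa.n):
        for attempt in range(50):
            h = rng.randint(1, max_range)
            w = rng.randint(1, max_range)
            r0 = rng.randint(0, g - h)
            c0 = rng.randint(0, g - w)
            cells = [
                cell(r, c)
                for r in range(r0, r0 + h)
                for c in range(c0, c0 + w)
                if rng.random() < spec.occupancy
            ]
            if cells:
                presence[cells, j] = 1
                break
        else:
            raise RuntimeError(
                f"taxon {taxa.labels[j]} drew an empty range 50 times "
                f"(seed {spec.seed}, occupancy {spec.occupancy})"
            )
    ub = min(spec.urban_block, g)
    urban = [r < ub and c < ub for r in range(g) for c in range(g)]
    costs = np.full(m, spec.unit_price)  # unit cell area x unit price
    return Landscape(areas, presence, costs, boundary, beta=0.0, urban=urban)


def gen_strip_landscape(
    seed: int,
    m: int,
    taxa: TaxonSet,
    beta: float = 0.0,
    integer_costs: bool = True,
) -> Landscape:
    """m unit-cell areas in a row (perimeter 4, neighbours share an edge of
    length 1) with clustered presence; every taxon is guaranteed coverable.

    A deliberately small geometry used for exhaustive cross-checks against
    enumeration, where the number of areas must stay low.
    """
    rng = np.random.default_rng(seed)
    presence = np.zeros((m, taxa.n), dtype=np.int8)
    for j in range(taxa.n):
        start = int(rng.integers(0, m))
        width = int(rng.integers(1, min(3, m) + 1))
        cells = [c for c in range(start, min(start + width, m))
                 if rng.random() < 0.8]
        if not cells:
            cells = [start]
        presence[cells, j] = 1
    costs = (rng.integers(1, 10, m).astype(float) if integer_costs
             else rng.random(m) * 9 + 1)
    boundary = np.zeros((m, m))
    np.fill_diagonal(boundary, 4.0)
    for i in range(m - 1):
        boundary[i, i + 1] = boundary[i + 1, i] = 1.0
    return Landscape([f"a{i}" for i in range(m)], presence, costs, boundary,
                     beta=beta)


def gen_foodweb(spec: SynthSpec, taxa: TaxonSet) -> tuple[FoodWeb, DietMatrix]:
    """A layered (hence acyclic) food web with Dirichlet diet rows.

    Taxa are dealt round-robin into ``layers`` trophic layers; layer-0 taxa
    are basal.  Every consumer preys on each strictly-lower-layer taxon with
    probability ``connectance`` and always on at least one (a random
    lower-layer taxon is forced when the Bernoulli draws all miss).  Diet
    rows are drawn from a symmetric Dirichlet, so they sum to 1 exactly.
    """
    if spec.layers < 2:
        raise ValueError("need at least 2 layers")
    rng = random.Random(spec.seed + 2)
    np_rng = np.random.default_rng(spec.seed + 2)
    n = taxa.n
    if n < spec.layers:
        raise ValueError("need at least one taxon per layer")
    layer_of = [i % spec.layers for i in range(n)]
    arrows: list[tuple[str, str]] = []
    diet_rows: dict[int, dict[int, float]] = {}
    for j in range(n):
        if layer_of[j] == 0:
            continue
        lower = [i for i in range(n) if layer_of[i] < layer_of[j]]
        prey = [i for i in lower if rng.random() < spec.connectance]
        if not prey:
            prey = [lower[rng.randrange(len(lower))]]
        prey = sorted(prey)
        props = np_rng.dirichlet([spec.diet_concentration] * len(prey))
        # renormalize away any accumulated float error so rows sum to 1 exactly
        props = props / props.sum()
        diet_rows[j] = {i: float(p) for i, p in zip(prey, props)}
        arrows.extend((taxa.labels[j], taxa.labels[i]) for i in prey)
    web = FoodWeb(taxa, arrows)
    diets = DietMatrix(web, diet_rows)
    return web, diets
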