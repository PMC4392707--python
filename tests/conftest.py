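import numpy as np
import pytest

from splitdiv import (
    DietMatrix,
    FoodWeb,
    Landscape,
    TaxonSet,
    Tree,
    splits_from_tree,
)


@pytest.fixture
def toy_tree() -> Tree:
    """Four-taxon tree whose split weights are easy to enumerate by hand:
    A|BCD 1, B|ACD 2, C|ABD 3, D|ABC 4, AB|CD 3 (two root edges merged)."""
    return Tree.from_newick("((A:1,B:2):1,(C:3,D:4):2);")


@pytest.fixture
def toy_system(toy_tree):
    return splits_from_tree(toy_tree)


@pytest.fixture
def chain_web():
    """Three-taxon chain: Q eats only H, H eats only P, P basal."""
    taxa = TaxonSet(["P", "H", "Q"])
    web = FoodWeb(taxa, [("Q", "H"), ("H", "P")])
    diets = DietMatrix(web, {taxa.index("Q"): {taxa.index("H"): 1.0},
                             taxa.index("H"): {taxa.index("P"): 1.0}})
    return taxa, web, diets


@pytest.fixture
def pq_web():
    """P basal; H eats P; Q eats H (80%) and P (20%)."""
    taxa = TaxonSet(["P", "H", "Q"])
    web = FoodWeb(taxa, [("H", "P"), ("Q", "H"), ("Q", "P")])
    diets = DietMatrix(
        web,
        {
            taxa.index("H"): {taxa.index("P"): 1.0},
            taxa.index("Q"): {taxa.index("H"): 0.8, taxa.index("P"): 0.2},
        },
    )
    return taxa, web, diets


def grid_landscape_2x2(presence, costs=None, beta=0.0, urban=None):
    """2x2 unit-cell landscape with 4-neighbour boundaries."""
    areas = ["a00", "a01", "a10", "a11"]
    boundary = np.array(
        [
            [4.0, 1.0, 1.0, 0.0],
            [1.0, 4.0, 0.0, 1.0],
            [1.0, 0.0, 4.0, 1.0],
            [0.0, 1.0, 1.0, 4.0],
        ]
    )
    presence = np.asarray(presence)
    if costs is None:
        costs = np.ones(4)
    return Landscape(areas, presence, costs, boundary, beta, urban)
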