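"""Reserve selection: model, special cases, sweep, crossover."""
import numpy as np
import pytest

from splitdiv import (
    CostLine,
    TaxonSet,
    accumulated_cost_crossover,
    brute_force_reserve,
    cost_ratio_sweep,
    minimum_representation,
    solve_reserve,
    aggregate_trees,
    splits_from_tree,
)
from splitdiv.reserve import Landscape
from splitdiv.splits import SplitSystem
from splitdiv.synth import SynthSpec, gen_landscape, gen_tree_collection

from conftest import grid_landscape_2x2


def all_trivial_system(taxa: TaxonSet, weights=None) -> SplitSystem:
    system = SplitSystem(taxa)
    for j in range(taxa.n):
        memb = [0] * taxa.n
        memb[j] = 1
        system.add(memb, 1.0 if weights is None else weights[j])
    return system


class TestSolveReserve:
    def test_p0_selects_nothing(self, toy_system):
        presence = np.eye(4, dtype=int)
        landscape = grid_landscape_2x2(presence)
        sol = solve_reserve(landscape, toy_system, p=0)
        assert sol.optimal and sol.selected == [] and sol.total_cost == 0.0

    def test_both_sides_of_only_split_needed(self):
        """A single split with its sides in two disjoint areas forces both
        areas at p = 100."""
        taxa = TaxonSet(["A", "B"])
        system = SplitSystem(taxa)
        system.add([0, 1], 5.0)
        presence = np.array([[1, 0], [0, 1], [0, 0], [0, 0]])
        landscape = grid_landscape_2x2(presence)
        sol = solve_reserve(landscape, system, p=100)
        assert sol.optimal and sol.selected == [0, 1]

    def test_single_area_holding_everything(self, toy_system):
        presence = np.zeros((4, 4), dtype=int)
        presence[2] = 1
        landscape = grid_landscape_2x2(presence)
        sol = solve_reserve(landscape, toy_system, p=100)
        assert sol.optimal and sol.selected == [2]

    def test_sd_recomputed_meets_target(self, toy_system):
        rng = np.random.default_rng(7)
        presence = (rng.random((4, 4)) < 0.6).astype(int)
        presence[0] = 1  # guarantee coverability
        landscape = grid_landscape_2x2(presence, beta=0.5)
        sol = solve_reserve(landscape, toy_system, p=95)
        assert sol.optimal
        assert sol.sd_percent >= 95 - 1e-6

    def test_uncoverable_taxon_at_p100_is_infeasible(self, toy_system):
        presence = np.zeros((4, 4), dtype=int)
        presence[:, :3] = 1  # taxon 3 occurs nowhere
        landscape = grid_landscape_2x2(presence)
        sol = solve_reserve(landscape, toy_system, p=100)
        assert sol.status == "infeasible"
        assert sol.infeasible_taxa == [3]

    def test_matches_oracle_on_grid(self):
        trees = gen_tree_collection(SynthSpec(seed=21, n_taxa=6, n_trees=3))
        system = aggregate_trees(trees)
        landscape = gen_landscape(SynthSpec(seed=21, grid=3), trees[0].taxa)
        landscape.beta = 1.0
        for p in (50, 80, 95, 100):
            sol = solve_reserve(landscape, system, p)
            _best, obj = brute_force_reserve(landscape, system, p)
            assert sol.optimal
            assert sol.total_cost == pytest.approx(obj, abs=1e-6)

    def test_cost_monotone_in_p(self):
        trees = gen_tree_collection(SynthSpec(seed=22, n_taxa=6, n_trees=3))
        system = aggregate_trees(trees)
        landscape = gen_landscape(SynthSpec(seed=22, grid=3), trees[0].taxa)
        costs = [
            solve_reserve(landscape, system, p).total_cost
            for p in (0, 25, 50, 75, 100)
        ]
        assert costs == sorted(costs)

    def test_fence_identity_adjacent_pair(self):
        """Selecting two adjacent unit cells shares one edge: the fence is
        2 * 4 - 2 * 1."""
        landscape = grid_landscape_2x2(np.ones((4, 1), dtype=int))
        assert landscape.fence_length([0]) + landscape.fence_length([1]) \
            - landscape.fence_length([0, 1]) == pytest.approx(2 * 1.0)
        assert landscape.fence_length([0, 1]) == pytest.approx(6.0)

    def test_boundary_beta_prefers_contiguous(self, toy_system):
        """With a fencing cost, a contiguous pair beats a diagonal pair of
        equal area cost."""
        # taxa split across {a00, a01} and also across {a00, a11}
        presence = np.array(
            [[1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 0, 0], [0, 0, 1, 1]]
        )
        landscape = grid_landscape_2x2(presence, beta=1.0)
        sol = solve_reserve(landscape, toy_system, p=100)
        assert sol.optimal
        assert sol.selected == [0, 1]  # adjacent, not the diagonal 0/3


class TestMinimumRepresentation:
    def test_identity_presence_takes_all_areas(self):
        landscape = grid_landscape_2x2(np.eye(4, dtype=int))
        sol = minimum_representation(landscape)
        assert sol.optimal and sol.total_cost == pytest.approx(4.0)

    def test_single_covering_area(self):
        presence = np.zeros((4, 3), dtype=int)
        presence[1] = 1
        landscape = grid_landscape_2x2(presence, costs=[5, 2, 5, 5])
        sol = minimum_representation(landscape)
        assert sol.optimal and sol.selected == [1] and sol.total_cost == 2.0

    def test_uncoverable_taxon_named(self):
        presence = np.zeros((4, 2), dtype=int)
        presence[:, 0] = 1
        landscape = grid_landscape_2x2(presence)
        sol = minimum_representation(landscape)
        assert sol.status == "infeasible" and sol.infeasible_taxa == [1]

    @pytest.mark.parametrize("seed", range(4))
    def test_random_instances_match_set_cover_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        m, n = 6, 8
        presence = (rng.random((m, n)) < 0.4).astype(int)
        presence[0] = 1
        costs = rng.integers(1, 10, m).astype(float)
        landscape = Landscape(
            [f"a{i}" for i in range(m)], presence, costs, np.zeros((m, m))
        )
        sol = minimum_representation(landscape)
        # exhaustive set-cover oracle
        best = min(
            (
                float(costs[list(s)].sum()) if s else 0.0
                for s in _powerset(m)
                if presence[list(s)].any(axis=0).all() or not n
            ),
            default=None,
        )
        assert sol.optimal and sol.total_cost == pytest.approx(best)

    def test_equals_reserve_p100_beta0_with_trivial_splits(self):
        trees = gen_tree_collection(SynthSpec(seed=23, n_taxa=6, n_trees=1))
        taxa = trees[0].taxa
        landscape = gen_landscape(SynthSpec(seed=23, grid=3), taxa)
        system = all_trivial_system(taxa)
        mr = minimum_representation(landscape)
        rs = solve_reserve(landscape, system, p=100)
        assert mr.optimal and rs.optimal
        assert mr.total_cost == pytest.approx(rs.total_cost)


def _powerset(m):
    import itertools

    for r in range(m + 1):
        yield from (set(c) for c in itertools.combinations(range(m), r))


def three_area_urban_instance():
    """Urban area A holds all four taxa; rural B and C each hold half.
    At low ratios {A} is optimal; once rho > 2 the rural pair {B, C} wins."""
    taxa = TaxonSet(["t1", "t2", "t3", "t4"])
    system = all_trivial_system(taxa)
    presence = np.array([[1, 1, 1, 1], [1, 1, 0, 0], [0, 0, 1, 1]])
    landscape = Landscape(
        ["A", "B", "C"],
        presence,
        costs=[1.0, 1.0, 1.0],
        boundary=np.zeros((3, 3)),
        beta=0.0,
        urban=[True, False, False],
    )
    return landscape, system


class TestSweep:
    def test_no_urban_areas_flat_line(self):
        landscape, system = three_area_urban_instance()
        landscape = Landscape(
            landscape.areas, landscape.presence, landscape.costs,
            landscape.boundary, 0.0, [False] * 3,
        )
        intervals = cost_ratio_sweep(
            landscape, system, p=100, ratios=[1.0, 2.0, 3.0]
        )
        assert len(intervals) == 1
        assert intervals[0].cost_line.slope == 0.0

    def test_change_point_computable_by_hand(self):
        """{A} costs rho, {B,C} costs 2: the optimum switches at rho = 2."""
        landscape, system = three_area_urban_instance()
        grid = [round(1.0 + 0.25 * i, 10) for i in range(17)]  # 1 .. 5
        intervals = cost_ratio_sweep(landscape, system, p=100, ratios=grid)
        assert len(intervals) == 2
        first, last = intervals
        assert first.selected == frozenset({0})
        assert first.cost_line.slope == pytest.approx(1.0)
        assert last.selected == frozenset({1, 2})
        assert last.cost_line.slope == 0.0
        assert last.cost_line.intercept == pytest.approx(2.0)
        # the hand-computed intersection of the two cost lines
        assert first.ratio_hi <= 2.0 <= last.ratio_lo

    def test_slopes_non_increasing(self):
        landscape, system = three_area_urban_instance()
        intervals = cost_ratio_sweep(
            landscape, system, p=100,
            ratios=[round(1 + 0.5 * i, 10) for i in range(9)],
        )
        slopes = [iv.cost_line.slope for iv in intervals]
        assert slopes == sorted(slopes, reverse=True)


class TestCrossover:
    def test_identical_lines_never_cross(self):
        line = CostLine(3.0, 1.0)
        traj = [1 + 0.1 * i for i in range(50)]
        assert accumulated_cost_crossover(line, line, traj) is None
        assert accumulated_cost_crossover(line, line, traj, "analytic") is None

    def test_cheap_now_steep_later_crosses(self):
        """A starts cheaper but climbs; B is flat: accumulated costs must
        cross, and the step-summation and closed-form roots agree to within
        one grid step."""
        a = CostLine(0.0, 1.0)   # cost rho
        b = CostLine(2.0, 0.0)   # flat 2
        step = 0.1
        traj = [round(1 + step * i, 10) for i in range(200)]
        disc = accumulated_cost_crossover(a, b, traj, "discrete")
        ana = accumulated_cost_crossover(a, b, traj, "analytic")
        assert disc is not None and ana is not None
        assert abs(disc - ana) <= step + 1e-9
        # sanity: per-period costs are equal at rho=2, so accumulated costs
        # cross later than that
        assert ana > 2.0

    def test_bad_trajectory_rejected(self):
        with pytest.raises(ValueError):
            accumulated_cost_crossover(
                CostLine(0, 1), CostLine(1, 0), [2.0, 1.0]
            )
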