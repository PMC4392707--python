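"""Spatial reserve selection under a split-diversity target.

Given m candidate areas with per-area conservation costs c_i, a symmetric
boundary-length matrix B (b_ii = perimeter of area i, b_ij = boundary shared
by adjacent areas i and j) and a fencing price beta per unit boundary, the
problem is to choose the cheapest set of areas whose resident taxa retain at
least p% of the total split diversity.  The quadratic fencing term is
linearized with one auxiliary variable z_ij per adjacent pair: the fence
around a selection W has length sum_{i in W} b_ii - 2 sum_{i<j in W} b_ij,
because shared boundaries between co-selected areas are internal and need no
fence.

The classical minimum representation problem (cover every taxon at least
once, at minimum cost) is the special case p = 100, beta = 0 on a split
system containing all trivial splits.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .ilp import ILPModel, SolveResult, solve
from .splits import SplitSystem, sd_score_mask

logger = logging.getLogger(__name__)

WEIGHT_SCALE = 10 ** 6  # scaled-integer split weights for exact p% thresholds

__all__ = [
    "Landscape",
    "ReserveSolution",
    "CostLine",
    "SweepInterval",
    "build_reserve_model",
    "solve_reserve",
    "minimum_representation",
    "cost_ratio_sweep",
    "accumulated_cost_crossover",
]


class Landscape:
    """A reserve-selection instance: areas, presence matrix, costs, boundaries.

    Parameters
    ----------
    areas
        Ordered identifiers of the m candidate areas.
    presence
        m x n binary matrix; presence[i, j] = 1 iff taxon j occurs in area i.
    costs
        Per-area conservation cost (cost units).
    boundary
        Symmetric m x m matrix of boundary lengths; diagonal = perimeters.
    beta
        Fencing cost per unit boundary length.
    urban
        Optional boolean flags marking areas under urban economic pressure.
    """

    def __init__(
        self,
        areas: Sequence[str],
        presence: np.ndarray,
        costs: Sequence[float],
        boundary: np.ndarray,
        beta: float = 0.0,
        urban: Sequence[bool] | None = None,
    ):
        self.areas = list(map(str, areas))
        m = len(self.areas)
        if len(set(self.areas)) != m:
            raise ValueError("duplicate area identifiers")
        presence = np.asarray(presence)
        if presence.shape[0] != m:
            raise ValueError("presence matrix row count != number of areas")
        if not np.isin(presence, (0, 1)).all():
            raise ValueError("presence matrix entries must be 0/1")
        self.presence = presence.astype(np.int8)
        self.costs = np.asarray(costs, dtype=float)
        if self.costs.shape != (m,):
            raise ValueError("cost vector length != number of areas")
        boundary = np.asarray(boundary, dtype=float)
        if boundary.shape != (m, m):
            raise ValueError("boundary matrix must be m x m")
        if not np.allclose(boundary, boundary.T):
            raise ValueError("boundary matrix must be symmetric")
        if (boundary < 0).any():
            raise ValueError("boundary lengths must be non-negative")
        off = boundary.sum(axis=1) - np.diag(boundary)
        bad = np.nonzero(np.diag(boundary) + 1e-9 < off)[0]
        if bad.size:
            logger.warning(
                "areas %s have shared boundary exceeding their perimeter "
                "(geometric consistency b_ii >= sum b_ij violated)",
                [self.areas[i] for i in bad],
            )
        self.boundary = boundary
        self.beta = float(beta)
        if urban is None:
            urban = [False] * m
        self.urban = np.asarray(urban, dtype=bool)
        if self.urban.shape != (m,):
            raise ValueError("urban flag vector length != number of areas")

    @property
    def m(self) -> int:
        return len(self.areas)

    @property
    def n_taxa(self) -> int:
        return self.presence.shape[1]

    def adjacent_pairs(self) -> list[tuple[int, int]]:
        """Area index pairs (i < j) sharing positive boundary."""
        m = self.m
        return [
            (i, j)
            for i in range(m)
            for j in range(i + 1, m)
            if self.boundary[i, j] > 0
        ]

    def area_taxon_masks(self) -> list[int]:
        """Per-area bitmask of resident taxa."""
        out = []
        for i in range(self.m):
            mask = 0
            for j in np.nonzero(self.presence[i])[0]:
                mask |= 1 << int(j)
            out.append(mask)
        return out

    def covered_taxa(self, members: Iterable[int]) -> frozenset[int]:
        members = list(members)
        if not members:
            return frozenset()
        cov = self.presence[members].any(axis=0)
        return frozenset(int(j) for j in np.nonzero(cov)[0])

    def fence_length(self, members: Iterable[int]) -> float:
        members = sorted(set(members))
        total = sum(self.boundary[i, i] for i in members)
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                total -= 2 * self.boundary[members[a], members[b]]
        return float(total)

    def selection_cost(self, members: Iterable[int]) -> float:
        members = list(members)
        return float(
            self.costs[members].sum() + self.beta * self.fence_length(members)
        )

    def with_urban_ratio(self, ratio: float) -> "Landscape":
        """Copy with urban per-area costs scaled by the urban/rural ratio."""
        costs = self.costs.copy()
        costs[self.urban] *= float(ratio)
        return Landscape(
            self.areas, self.presence, costs, self.boundary, self.beta, self.urban
        )


@dataclass
class ReserveSolution:
    status: str
    selected: list[int] = field(default_factory=list)
    selected_areas: list[str] = field(default_factory=list)
    covered_taxa: frozenset[int] = frozenset()
    total_cost: float = float("nan")
    area_cost: float = float("nan")
    fence_length: float = float("nan")
    sd: float = float("nan")
    sd_percent: float = float("nan")
    split_indicators: list[int] = field(default_factory=list)
    infeasible_taxa: list[int] = field(default_factory=list)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def _split_side_area_cover(
    landscape: Landscape, system: SplitSystem
) -> list[tuple[list[int], list[int]]]:
    """For each split, the areas containing at least one taxon of each side."""
    masks = landscape.area_taxon_masks()
    out = []
    for sp, _w in system:
        a_side = [i for i, mk in enumerate(masks) if mk & sp.mask0]
        b_side = [i for i, mk in enumerate(masks) if mk & sp.mask1]
        out.append((a_side, b_side))
    return out


def build_reserve_model(
    landscape: Landscape,
    system: SplitSystem,
    p: float,
    exact_thresholds: bool = True,
    strict_z: bool = False,
) -> ILPModel:
    """ILP for reserve selection preserving >= p% of total SD.

    Variables: x_i per area, z_ij per adjacent pair, y_sigma per split.
    Objective: minimize  sum c_i x_i + beta (sum b_ii x_i - 2 sum b_ij z_ij).
    Constraints: z_ij <= x_i, z_ij <= x_j (the lower bound
    z_ij >= x_i + x_j - 1 is redundant here because z carries a negative
    objective coefficient in a minimization; ``strict_z`` adds it anyway);
    y_sigma <= sum of x over areas covering each side of sigma;
    sum lambda(sigma) y_sigma >= (p/100) sum lambda(sigma).

    With ``exact_thresholds`` the split weights in the p% constraint are
    scaled by 10^6 and rounded to integers so the percentage threshold is not
    eroded by floating-point representation.
    """
    if not (0.0 <= p <= 100.0):
        raise ValueError(f"p must be in [0, 100], got {p}")
    model = ILPModel("min")
    m = landscape.m
    for i in range(m):
        model.add_var(f"x{i}")
    pairs = landscape.adjacent_pairs()
    for i, j in pairs:
        model.add_var(f"z{i}_{j}")
    for s in range(len(system)):
        model.add_var(f"y{s}")
    obj: dict[str, float] = {}
    for i in range(m):
        obj[f"x{i}"] = landscape.costs[i] + landscape.beta * landscape.boundary[i, i]
    for i, j in pairs:
        obj[f"z{i}_{j}"] = -2.0 * landscape.beta * landscape.boundary[i, j]
    model.set_objective(obj)
    for i, j in pairs:
        z = f"z{i}_{j}"
        model.add_constraint({z: 1.0, f"x{i}": -1.0}, "<=", 0.0, f"zub_{i}_{j}a")
        model.add_constraint({z: 1.0, f"x{j}": -1.0}, "<=", 0.0, f"zub_{i}_{j}b")
        if strict_z:
            model.add_constraint(
                {z: 1.0, f"x{i}": -1.0, f"x{j}": -1.0}, ">=", -1.0,
                f"zlb_{i}_{j}",
            )
    side_cover = _split_side_area_cover(landscape, system)
    uncoverable_splits = []
    for s, (a_side, b_side) in enumerate(side_cover):
        if not a_side or not b_side:
            uncoverable_splits.append(s)
            model.fix(f"y{s}", 0)
            continue
        model.add_constraint(
            {f"y{s}": 1.0, **{f"x{i}": -1.0 for i in a_side}}, "<=", 0.0,
            f"splitA_{s}",
        )
        model.add_constraint(
            {f"y{s}": 1.0, **{f"x{i}": -1.0 for i in b_side}}, "<=", 0.0,
            f"splitB_{s}",
        )
    if uncoverable_splits:
        logger.warning(
            "%d splits have a side with no resident taxa in any area and can "
            "never count toward the SD target", len(uncoverable_splits),
        )
    weights = system.weights
    if exact_thresholds:
        iw = np.rint(weights * WEIGHT_SCALE).astype(np.int64)
        total = int(iw.sum())
        # integer lhs, so the p% threshold rounds up to the next attainable
        # integer weight; the small slack guards against float dust in p*total
        rhs = math.ceil(p * total / 100.0 - 1e-6)
        model.add_constraint(
            {f"y{s}": float(iw[s]) for s in range(len(system))}, ">=",
            float(rhs), "sd_target",
        )
    else:
        total = float(weights.sum())
        model.add_constraint(
            {f"y{s}": float(weights[s]) for s in range(len(system))}, ">=",
            (p / 100.0) * total - 1e-9, "sd_target",
        )
    return model


def _uncoverable_taxa(landscape: Landscape) -> list[int]:
    return [int(j) for j in np.nonzero(~landscape.presence.any(axis=0))[0]]


def solve_reserve(
    landscape: Landscape,
    system: SplitSystem,
    p: float,
    exact_thresholds: bool = True,
    time_limit: float | None = None,
) -> ReserveSolution:
    """Build and solve the reserve-selection ILP; verify the solution.

    The SD of the covered taxa is recomputed independently of the solver's y
    variables, and the p% target is asserted against that independent value.
    """
    if p >= 100.0 - 1e-12:
        bad = _uncoverable_taxa(landscape)
        if bad:
            bad_mask = 0
            for j in bad:
                bad_mask |= 1 << j
            # a split with one side entirely uncoverable can never be counted,
            # so p = 100% is infeasible as soon as such a split has weight
            if any(
                w > 0 and (
                    sp.mask0 & ~bad_mask == 0 or sp.mask1 & ~bad_mask == 0
                )
                for sp, w in system
            ):
                return ReserveSolution(status="infeasible", infeasible_taxa=bad)
    model = build_reserve_model(landscape, system, p, exact_thresholds)
    res = solve(model, time_limit=time_limit)
    if not res.optimal:
        return ReserveSolution(status=res.status)
    members = sorted(
        int(v[1:]) for v in res.selected("x")
    )
    covered = landscape.covered_taxa(members)
    mask = 0
    for j in covered:
        mask |= 1 << j
    sd = sd_score_mask(system, mask)
    total = system.total_weight()
    sd_pct = 100.0 * sd / total if total > 0 else 100.0
    if sd_pct < p - 1e-6:
        raise AssertionError(
            f"solver selection attains {sd_pct:.6f}% SD < target {p}%"
        )
    # solver y-values can only claim splits actually separated by the cover
    claimed = sum(
        w for s, (sp, w) in enumerate(system)
        if res.assignment.get(f"y{s}", 0) == 1
    )
    if claimed > sd + 1e-6:
        raise AssertionError("solver split indicators overcount attained SD")
    indicators = [
        1 if (mask & sp.mask1) and (mask & sp.mask0) else 0 for sp, _ in system
    ]
    fence = landscape.fence_length(members)
    area_cost = float(landscape.costs[members].sum()) if members else 0.0
    return ReserveSolution(
        status="optimal",
        selected=members,
        selected_areas=[landscape.areas[i] for i in members],
        covered_taxa=covered,
        total_cost=area_cost + landscape.beta * fence,
        area_cost=area_cost,
        fence_length=fence,
        sd=sd,
        sd_percent=sd_pct,
        split_indicators=indicators,
    )


def minimum_representation(landscape: Landscape) -> ReserveSolution:
    """Cheapest area set covering every taxon at least once (set cover)."""
    bad = _uncoverable_taxa(landscape)
    if bad:
        return ReserveSolution(status="infeasible", infeasible_taxa=bad)
    model = ILPModel("min")
    m, n = landscape.m, landscape.n_taxa
    for i in range(m):
        model.add_var(f"x{i}")
    model.set_objective({f"x{i}": float(landscape.costs[i]) for i in range(m)})
    for j in range(n):
        rows = [int(i) for i in np.nonzero(landscape.presence[:, j])[0]]
        model.add_constraint(
            {f"x{i}": 1.0 for i in rows}, ">=", 1.0, f"cover_t{j}"
        )
    res = solve(model)
    if not res.optimal:
        return ReserveSolution(status=res.status)
    members = sorted(int(v[1:]) for v in res.selected("x"))
    covered = landscape.covered_taxa(members)
    fence = landscape.fence_length(members)
    area_cost = float(landscape.costs[members].sum()) if members else 0.0
    return ReserveSolution(
        status="optimal",
        selected=members,
        selected_areas=[landscape.areas[i] for i in members],
        covered_taxa=covered,
        total_cost=area_cost,
        area_cost=area_cost,
        fence_length=fence,
        sd=float("nan"),
        sd_percent=float("nan"),
    )


# ---------------------------------------------------------------------------
# Economic-pressure sweep


@dataclass(frozen=True)
class CostLine:
    """Optimal cost of a fixed selection as a linear function of the
    urban/rural cost ratio rho: cost(rho) = intercept + slope * rho."""

    intercept: float
    slope: float

    def __call__(self, ratio: float) -> float:
        return self.intercept + self.slope * ratio


@dataclass
class SweepInterval:
    ratio_lo: float
    ratio_hi: float
    selected: frozenset[int]
    selected_areas: list[str]
    cost_line: CostLine
    n_urban: int


def cost_ratio_sweep(
    landscape: Landscape,
    system: SplitSystem,
    p: float,
    ratios: Sequence[float],
    exact_thresholds: bool = True,
) -> list[SweepInterval]:
    """Solve reserve selection along an ascending urban/rural cost-ratio grid.

    For each ratio rho the cost of every urban area is its base cost times
    rho.  Grid points at which the optimal selection coincides are merged
    into intervals; within an interval the optimal cost is exactly linear in
    rho with slope = total base cost of the selected urban areas.
    """
    ratios = list(ratios)
    if not ratios:
        raise ValueError("ratio grid must contain at least one value")
    if any(b <= a for a, b in zip(ratios, ratios[1:])):
        raise ValueError("ratio grid must be strictly ascending")
    intervals: list[SweepInterval] = []
    for rho in ratios:
        scaled = landscape.with_urban_ratio(rho)
        sol = solve_reserve(scaled, system, p, exact_thresholds)
        if not sol.optimal:
            raise RuntimeError(f"sweep solve failed at ratio {rho}: {sol.status}")
        sel = frozenset(sol.selected)
        if intervals and intervals[-1].selected == sel:
            intervals[-1].ratio_hi = rho
            continue
        members = sorted(sel)
        urban_members = [i for i in members if landscape.urban[i]]
        slope = float(landscape.costs[urban_members].sum()) if urban_members else 0.0
        rural_members = [i for i in members if not landscape.urban[i]]
        intercept = (
            (float(landscape.costs[rural_members].sum()) if rural_members else 0.0)
            + landscape.beta * landscape.fence_length(members)
        )
        intervals.append(
            SweepInterval(
                ratio_lo=rho,
                ratio_hi=rho,
                selected=sel,
                selected_areas=[landscape.areas[i] for i in members],
                cost_line=CostLine(intercept, slope),
                n_urban=len(urban_members),
            )
        )
    return intervals


def accumulated_cost_crossover(
    line_a: CostLine,
    line_b: CostLine,
    trajectory: Sequence[float],
    mode: str = "discrete",
) -> float | None:
    """Break-even ratio at which set A's accumulated cost first exceeds B's.

    The trajectory models the urban/rural cost ratio rising over time; each
    step incurs that period's conservation cost, so the accumulated cost of a
    linear cost line grows quadratically.  ``discrete`` sums step by step over
    the given trajectory; ``analytic`` integrates the cost difference
    continuously from the trajectory start and solves the resulting quadratic
    for its positive root.  Returns None when the accumulated curves never
    cross within the trajectory.
    """
    traj = [float(r) for r in trajectory]
    if not traj or any(b <= a for a, b in zip(traj, traj[1:])):
        raise ValueError("trajectory must be a non-empty ascending sequence")
    if mode == "discrete":
        cum_a = cum_b = 0.0
        for rho in traj:
            cum_a += line_a(rho)
            cum_b += line_b(rho)
            if cum_a > cum_b + 1e-9:
                return rho
        return None
    if mode == "analytic":
        rho0 = traj[0]
        d0 = line_a.intercept - line_b.intercept
        d1 = line_a.slope - line_b.slope
        # cumulative difference from rho0 to rho:
        #   D(rho) = d0 (rho - rho0) + d1 (rho^2 - rho0^2) / 2
        if abs(d1) < 1e-15:
            return None  # parallel lines: one side dominates forever (or ties)
        # D(rho) = 0  =>  d1/2 rho^2 + d0 rho - (d0 rho0 + d1 rho0^2 / 2) = 0
        a, b, c = d1 / 2.0, d0, -(d0 * rho0 + d1 * rho0 ** 2 / 2.0)
        disc = b * b - 4 * a * c
        if disc < 0:
            return None
        roots = [(-b + math.sqrt(disc)) / (2 * a), (-b - math.sqrt(disc)) / (2 * a)]

        def cum_diff(rho: float) -> float:
            return d0 * (rho - rho0) + d1 * (rho ** 2 - rho0 ** 2) / 2.0

        # accept a root at the trajectory start (lines tying at rho0) as long
        # as A's accumulated cost actually exceeds B's just beyond it
        candidates = sorted(
            max(r, rho0) for r in roots
            if r >= rho0 - 1e-9 and cum_diff(max(r, rho0) + 1e-6) > 0
        )
        if not candidates:
            return None
        rho_star = candidates[0]
        if rho_star > traj[-1] + 1e-9:
            return None
        return rho_star
    raise ValueError(f"unknown crossover mode {mode!r}")
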