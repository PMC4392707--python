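"""Viable and d%-viable taxon selection maximizing split diversity.

Pick at most k taxa maximizing SD subject to food-web viability: every
selected predator must retain at least one prey in the selection (plain
viability) or at least d% of its diet composition (d%-viability).  Both are
solved exactly as 0/1 ILPs with one variable v_i per taxon and one split
indicator y_sigma per split; forced taxa (e.g. aggregate trophic groups that
anchor the base of a web) are pinned to 1.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

from .foodweb import (
    DietMatrix,
    FoodWeb,
    diet_score,
    is_d_viable,
    is_viable,
    unselectable_predators,
)
from .ilp import ILPModel, solve
from .splits import SplitSystem, sd_score

logger = logging.getLogger(__name__)

__all__ = [
    "TaxonProblem",
    "TaxonSolution",
    "build_taxon_model",
    "solve_taxon",
    "unconstrained_gap",
]


@dataclass
class TaxonProblem:
    """One (d%-)viable taxon-selection instance.

    ``d`` is a percentage; when None the plain one-prey viability constraint
    applies.  Forced taxa are always selected and count toward k unless
    ``forced_exempt_from_k`` is set.
    """

    system: SplitSystem
    web: FoodWeb | None = None
    diets: DietMatrix | None = None
    k: int = 0
    d: float | None = None
    forced: frozenset[int] = frozenset()
    forced_exempt_from_k: bool = False

    def __post_init__(self):
        n = self.system.taxa.n
        self.forced = frozenset(int(i) for i in self.forced)
        if any(i < 0 or i >= n for i in self.forced):
            raise ValueError("forced taxon index out of range")
        if not self.forced_exempt_from_k and len(self.forced) > self.k:
            raise ValueError("forced set larger than k")
        if self.d is not None:
            if not (0.0 < self.d <= 100.0):
                raise ValueError(f"d must be in (0, 100], got {self.d}")
            if self.diets is None:
                raise ValueError("d%-viability requires a DietMatrix")


@dataclass
class TaxonSolution:
    status: str
    selected: frozenset[int] = frozenset()
    selected_taxa: list[str] = field(default_factory=list)
    sd: float = float("nan")
    relative_sd: float = float("nan")
    prey_counts: dict[int, int] = field(default_factory=dict)
    diet_scores: dict[int, float] = field(default_factory=dict)
    unselectable: list[int] = field(default_factory=list)
    infeasibility_certificate: str = ""

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def build_taxon_model(problem: TaxonProblem) -> ILPModel:
    """ILP for (d%-)viable taxon selection.

    maximize   sum lambda(sigma) y_sigma
    subject to sum v_i <= k;
               y_sigma <= sum_{i in A} v_i and y_sigma <= sum_{i in B} v_i
                 for the two sides A, B of each split;
               v_j <= sum_{i in C_j} v_i             (plain viability), or
               sum_{i in C_j} w_ji v_i >= (d/100) v_j (d%-viability),
                 for every non-basal predator j;
               v_j = 1 for forced taxa.
    """
    system = problem.system
    n = system.taxa.n
    model = ILPModel("max")
    for i in range(n):
        model.add_var(f"v{i}")
    for s in range(len(system)):
        model.add_var(f"y{s}")
    model.set_objective(
        {f"y{s}": float(w) for s, (_sp, w) in enumerate(system)}
    )
    budget = {f"v{i}": 1.0 for i in range(n)}
    k = problem.k
    if problem.forced_exempt_from_k:
        k = k + len(problem.forced)
    model.add_constraint(budget, "<=", float(k), "budget")
    for s, (sp, _w) in enumerate(system):
        a_side = [i for i in range(n) if not (sp.mask1 >> i & 1)]
        b_side = [i for i in range(n) if sp.mask1 >> i & 1]
        model.add_constraint(
            {f"y{s}": 1.0, **{f"v{i}": -1.0 for i in a_side}}, "<=", 0.0,
            f"splitA_{s}",
        )
        model.add_constraint(
            {f"y{s}": 1.0, **{f"v{i}": -1.0 for i in b_side}}, "<=", 0.0,
            f"splitB_{s}",
        )
    if problem.web is not None:
        for j, preyset in problem.web.prey.items():
            if not preyset:
                continue
            if problem.d is None:
                model.add_constraint(
                    {f"v{j}": 1.0, **{f"v{i}": -1.0 for i in preyset}},
                    "<=", 0.0, f"viab_{j}",
                )
            else:
                thr = problem.d / 100.0
                if thr < 1e-6:
                    # below solver feasibility tolerance the weighted form is
                    # numerically vacuous; for positive diet weights d -> 0+
                    # is exactly the one-prey constraint on supported prey
                    support = [
                        i for i in preyset if problem.diets.weight(j, i) > 0
                    ]
                    model.add_constraint(
                        {f"v{j}": 1.0, **{f"v{i}": -1.0 for i in support}},
                        "<=", 0.0, f"diet_{j}",
                    )
                else:
                    model.add_constraint(
                        {
                            f"v{j}": -thr,
                            **{
                                f"v{i}": problem.diets.weight(j, i)
                                for i in preyset
                            },
                        },
                        ">=", 0.0, f"diet_{j}",
                    )
    for i in problem.forced:
        model.fix(f"v{i}", 1)
    return model


def solve_taxon(
    problem: TaxonProblem, time_limit: float | None = None
) -> TaxonSolution:
    """Build and solve; independently re-verify viability and SD.

    The SD of the returned set is recomputed from the split system (not read
    off the solver's y variables), and the set is re-checked against the
    module-independent viability predicates.
    """
    unsel: list[int] = []
    if problem.d is not None and problem.web is not None:
        unsel = unselectable_predators(problem.web, problem.diets, problem.d)
        bad_forced = sorted(set(unsel) & problem.forced)
        if bad_forced:
            labels = [problem.system.taxa.labels[i] for i in bad_forced]
            return TaxonSolution(
                status="infeasible",
                unselectable=unsel,
                infeasibility_certificate=(
                    f"forced predators {labels} have total in-web diet below "
                    f"{problem.d}% and can never be d%-viable"
                ),
            )
    model = build_taxon_model(problem)
    res = solve(model, time_limit=time_limit)
    if not res.optimal:
        cert = ""
        if res.status == "infeasible" and problem.web is not None:
            missing = {
                j: sorted(problem.web.prey_of(j) - problem.forced)
                for j in problem.forced
                if not problem.web.is_basal(j)
            }
            cert = (
                "forced set cannot be completed to a viable set within k; "
                f"forced predators and their candidate prey: {missing}"
            )
        return TaxonSolution(
            status=res.status, unselectable=unsel,
            infeasibility_certificate=cert,
        )
    selected = frozenset(int(v[1:]) for v in res.selected("v"))
    if problem.web is not None:
        if problem.d is None:
            assert is_viable(problem.web, selected), \
                "solver returned a set violating the viability predicate"
        else:
            assert is_d_viable(problem.web, problem.diets, selected, problem.d), \
                "solver returned a set violating d%-viability"
    sd = sd_score(problem.system, selected)
    total = problem.system.total_weight()
    prey_counts = {}
    diet_scores = {}
    if problem.web is not None:
        for j in selected:
            if problem.web.is_basal(j):
                continue
            prey_counts[j] = len(problem.web.prey_of(j) & selected)
            if problem.diets is not None:
                diet_scores[j] = diet_score(
                    problem.web, problem.diets, j, selected
                )
    return TaxonSolution(
        status="optimal",
        selected=selected,
        selected_taxa=[problem.system.taxa.labels[i] for i in sorted(selected)],
        sd=sd,
        relative_sd=100.0 * sd / total if total > 0 else 100.0,
        prey_counts=prey_counts,
        diet_scores=diet_scores,
        unselectable=unsel,
    )


@dataclass
class GapReport:
    constrained: TaxonSolution
    unconstrained: TaxonSolution
    sd_gap: float
    relative_sd_gap: float
    preyless_in_unconstrained: list[str]


def unconstrained_gap(problem: TaxonProblem) -> GapReport:
    """Quantify what viability costs: solve with and without the food web.

    Reports the SD difference and the predators left without any selected
    prey in the unconstrained optimum (the taxa whose viability the
    constrained problem has to 'repair').
    """
    constrained = solve_taxon(problem)
    free = TaxonProblem(
        system=problem.system, web=None, diets=None, k=problem.k,
        d=None, forced=problem.forced,
        forced_exempt_from_k=problem.forced_exempt_from_k,
    )
    unconstrained = solve_taxon(free)
    preyless: list[str] = []
    if problem.web is not None and unconstrained.optimal:
        s = unconstrained.selected
        for j in sorted(s):
            if not problem.web.is_basal(j) and not (problem.web.prey_of(j) & s):
                preyless.append(problem.system.taxa.labels[j])
    sd_gap = (
        unconstrained.sd - constrained.sd
        if constrained.optimal and unconstrained.optimal else float("nan")
    )
    rel_gap = (
        unconstrained.relative_sd - constrained.relative_sd
        if constrained.optimal and unconstrained.optimal else float("nan")
    )
    return GapReport(
        constrained=constrained,
        unconstrained=unconstrained,
        sd_gap=sd_gap,
        relative_sd_gap=rel_gap,
        preyless_in_unconstrained=preyless,
    )
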