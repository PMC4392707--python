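"""Food webs, viability, and diet-based (d%) viability of taxon subsets.

A food web is a directed graph over the taxon set with an arrow from each
predator to each of its prey.  A taxon subset S is *viable* when every member
is either basal (no prey at all) or retains at least one prey inside S.  With
diet-composition weights w_ji (the proportion of prey i in predator j's diet,
summing to 1 per predator), S is *d%-viable* when every non-basal member
retains at least d% of its diet among the selected prey.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .splits import TaxonSet

logger = logging.getLogger(__name__)

DIET_SUM_TOL = 1e-6
# comparison slack; must stay well below EPSILON_D / 100 so the d -> 0+
# reduction to plain viability is not erased by the slack itself
D_VIABLE_SLACK = 1e-12
#: the d value at which d%-viability reduces to plain viability on webs with
#: strictly positive diet weights
EPSILON_D = 1e-7

__all__ = [
    "FoodWeb",
    "DietMatrix",
    "WebReport",
    "validate_web",
    "is_viable",
    "diet_score",
    "is_d_viable",
    "EPSILON_D",
]


class FoodWeb:
    """Directed predator -> prey graph over a TaxonSet.

    Prey sets C_i and the basal set (taxa without prey) are derived at
    construction.  Self-loops are rejected; cycles are permitted (see
    validate_web) unless ``strict_dag`` is set.
    """

    def __init__(
        self,
        taxa: TaxonSet,
        arrows: Iterable[tuple[str, str]],
        strict_dag: bool = False,
    ):
        self.taxa = taxa
        self.prey: dict[int, frozenset[int]] = {}
        seen: dict[int, set[int]] = {i: set() for i in range(taxa.n)}
        for pred, prey in arrows:
            if pred not in taxa:
                raise ValueError(f"arrow references unknown predator {pred!r}")
            if prey not in taxa:
                raise ValueError(f"arrow references unknown prey {prey!r}")
            if pred == prey:
                raise ValueError(f"self-loop on taxon {pred!r}")
            seen[taxa.index(pred)].add(taxa.index(prey))
        self.prey = {i: frozenset(s) for i, s in seen.items()}
        self.basal = frozenset(i for i, s in self.prey.items() if not s)
        if strict_dag:
            cycles = self.find_cycles()
            if cycles:
                raise ValueError(f"food web contains cycles: {cycles[:3]}")

    @property
    def n(self) -> int:
        return self.taxa.n

    def arrows(self) -> list[tuple[int, int]]:
        return [(j, i) for j, s in self.prey.items() for i in sorted(s)]

    def prey_of(self, j: int) -> frozenset[int]:
        return self.prey[j]

    def is_basal(self, j: int) -> bool:
        return j in self.basal

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.arrows())
        return g

    def find_cycles(self) -> list[list[int]]:
        g = self.to_digraph()
        try:
            cyc = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return []
        return [[u for u, _ in cyc]]

    def __repr__(self) -> str:
        n_arrows = sum(len(s) for s in self.prey.values())
        return (
            f"FoodWeb(n_taxa={self.n}, n_arrows={n_arrows}, "
            f"n_basal={len(self.basal)})"
        )


class DietMatrix:
    """Diet proportions w_ji: share of prey i in predator j's diet.

    Support must match the web's prey sets; each non-basal row sums to 1
    within ``DIET_SUM_TOL`` (checked by validate_web, not at construction, so
    that defective inputs can be loaded and reported).
    """

    def __init__(self, web: FoodWeb, rows: Mapping[int, Mapping[int, float]]):
        self.web = web
        self.rows: dict[int, dict[int, float]] = {}
        for j, row in rows.items():
            for i, w in row.items():
                if not (0.0 <= w <= 1.0 + DIET_SUM_TOL):
                    raise ValueError(
                        f"diet proportion w[{j},{i}]={w} outside [0, 1]"
                    )
                if i not in web.prey_of(j):
                    raise ValueError(
                        f"diet entry for non-arrow pair predator {j} prey {i}"
                    )
            self.rows[j] = {i: float(w) for i, w in row.items()}

    @classmethod
    def uniform(cls, web: FoodWeb) -> "DietMatrix":
        """Equal share 1/|C_j| for every prey of every predator."""
        rows = {
            j: {i: 1.0 / len(s) for i in s}
            for j, s in web.prey.items() if s
        }
        return cls(web, rows)

    def weight(self, j: int, i: int) -> float:
        return self.rows.get(j, {}).get(i, 0.0)

    def row_sum(self, j: int) -> float:
        return sum(self.rows.get(j, {}).values())


@dataclass
class WebReport:
    """Structural diagnostics produced by validate_web."""

    cycles: list[list[int]] = field(default_factory=list)
    empty_diet_rows: list[int] = field(default_factory=list)
    diet_sum_violations: dict[int, float] = field(default_factory=dict)
    unreachable_from_basal: list[int] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not (
            self.cycles
            or self.empty_diet_rows
            or self.diet_sum_violations
            or self.unreachable_from_basal
        )


def validate_web(web: FoodWeb, diets: DietMatrix | None = None) -> WebReport:
    """Check structural soundness of a (weighted) food web.

    Cycles are reported as warnings rather than errors: the viability
    constraints are purely local (each predator needs a prey, not an acyclic
    support chain), so the optimization remains well-defined on webs with
    omnivory loops.
    """
    report = WebReport()
    report.cycles = web.find_cycles()
    if report.cycles:
        logger.warning("food web contains cycles: %s", report.cycles[:3])
    if diets is not None:
        for j, preyset in web.prey.items():
            if not preyset:
                continue
            row = diets.rows.get(j, {})
            if not row:
                report.empty_diet_rows.append(j)
                continue
            s = sum(row.values())
            if abs(s - 1.0) > DIET_SUM_TOL:
                report.diet_sum_violations[j] = s
    # reachability: a consumer is supported if some chain of prey links leads
    # to a basal taxon
    g = web.to_digraph()
    reach_basal = set(web.basal)
    # iterate to a fixed point (handles cycles without blowing up)
    changed = True
    while changed:
        changed = False
        for j, preyset in web.prey.items():
            if j not in reach_basal and preyset & reach_basal:
                reach_basal.add(j)
                changed = True
    report.unreachable_from_basal = sorted(set(range(web.n)) - reach_basal)
    return report


def is_viable(web: FoodWeb, subset: Iterable[int]) -> bool:
    """True iff every member of the subset is basal or has prey in the subset.

    The empty set is vacuously viable.
    """
    s = frozenset(int(i) for i in subset)
    for j in s:
        if j in web.basal:
            continue
        if not (web.prey_of(j) & s):
            return False
    return True


def diet_score(
    web: FoodWeb, diets: DietMatrix, j: int, subset: Iterable[int]
) -> float:
    """delta(s_j | S): total diet proportion of predator j covered by S."""
    if web.is_basal(j):
        warnings.warn(f"diet_score of basal taxon {j} is defined as 1")
        return 1.0
    s = frozenset(int(i) for i in subset)
    return sum(w for i, w in diets.rows.get(j, {}).items() if i in s)


def is_d_viable(
    web: FoodWeb, diets: DietMatrix, subset: Iterable[int], d: float
) -> bool:
    """True iff every non-basal member retains >= d% of its diet in the subset.

    ``d`` is a percentage (d=30 means 30% of the diet); comparisons carry a
    1e-9 slack so exact thresholds are not lost to floating-point noise.
    As d -> 0+ this reduces to is_viable on webs with strictly positive diet
    weights.
    """
    if not (0.0 < d <= 100.0):
        raise ValueError(f"d must be in (0, 100], got {d}")
    s = frozenset(int(i) for i in subset)
    thr = d / 100.0
    for j in s:
        if j in web.basal:
            continue
        score = sum(w for i, w in diets.rows.get(j, {}).items() if i in s)
        if score < thr - D_VIABLE_SLACK:
            return False
    return True


def unselectable_predators(
    web: FoodWeb, diets: DietMatrix, d: float
) -> list[int]:
    """Predators whose total in-web diet falls short of d% even if every prey
    is selected; these can never belong to a d%-viable set."""
    thr = d / 100.0
    return [
        j for j, preyset in web.prey.items()
        if preyset and diets.row_sum(j) < thr - D_VIABLE_SLACK
    ]
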