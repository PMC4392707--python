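"""Solver-agnostic 0/1 ILP models, an exact solve contract, and brute-force
oracles used to cross-check every optimization problem on small instances.

The solve backend is the HiGHS branch-and-bound exposed through
``scipy.optimize.milp``, which proves optimality; an ``optimal`` status is a
guarantee, and infeasibility is reported as such, never as an empty optimum.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.optimize import LinearConstraint, milp
from scipy.sparse import csr_matrix

from .foodweb import DietMatrix, FoodWeb, is_d_viable, is_viable
from .splits import SplitSystem, sd_score_mask

__all__ = [
    "ILPModel",
    "SolveResult",
    "SolverUnavailableError",
    "solve",
    "brute_force_taxon",
    "brute_force_reserve",
]

_OPS = ("<=", ">=", "==")


class SolverUnavailableError(RuntimeError):
    """No exact MILP backend could be imported."""


@dataclass
class _Constraint:
    coeffs: dict[str, float]
    op: str
    rhs: float
    name: str = ""


class ILPModel:
    """A 0/1 integer linear program: binary variables, linear objective,
    linear constraints with <=, >= or == comparators."""

    def __init__(self, sense: str = "min"):
        if sense not in ("min", "max"):
            raise ValueError(f"sense must be 'min' or 'max', got {sense!r}")
        self.sense = sense
        self.variables: list[str] = []
        self._var_index: dict[str, int] = {}
        self.objective: dict[str, float] = {}
        self.constraints: list[_Constraint] = []
        self.fixed: dict[str, int] = {}

    def add_var(self, name: str) -> str:
        if name in self._var_index:
            raise ValueError(f"duplicate variable {name!r}")
        self._var_index[name] = len(self.variables)
        self.variables.append(name)
        return name

    def set_objective(self, coeffs: Mapping[str, float]) -> None:
        self._check_known(coeffs)
        self.objective = dict(coeffs)

    def add_constraint(
        self, coeffs: Mapping[str, float], op: str, rhs: float, name: str = ""
    ) -> None:
        if op not in _OPS:
            raise ValueError(f"comparator must be one of {_OPS}, got {op!r}")
        self._check_known(coeffs)
        if not all(np.isfinite(v) for v in coeffs.values()) or not np.isfinite(rhs):
            raise ValueError(f"non-finite coefficient in constraint {name!r}")
        self.constraints.append(_Constraint(dict(coeffs), op, float(rhs), name))

    def fix(self, name: str, value: int) -> None:
        """Pin a binary variable to 0 or 1."""
        if name not in self._var_index:
            raise ValueError(f"unknown variable {name!r}")
        self.fixed[name] = int(value)

    def _check_known(self, coeffs: Mapping[str, float]) -> None:
        unknown = [v for v in coeffs if v not in self._var_index]
        if unknown:
            raise ValueError(f"constraint references undeclared variables {unknown}")

    def objective_value(self, assignment: Mapping[str, int]) -> float:
        return sum(c * assignment.get(v, 0) for v, c in self.objective.items())

    # -- LP file export (debugging aid) ------------------------------------

    def to_lp(self) -> str:
        """Render the model in the standard LP file dialect."""
        def term_str(coeffs: Mapping[str, float]) -> str:
            parts = []
            for v, c in coeffs.items():
                sign = "+" if c >= 0 else "-"
                parts.append(f"{sign} {abs(c):.12g} {v}")
            s = " ".join(parts) if parts else "0"
            return s.lstrip("+ ").strip() or "0"

        lines = ["Minimize" if self.sense == "min" else "Maximize"]
        lines.append(" obj: " + term_str(self.objective))
        lines.append("Subject To")
        for i, con in enumerate(self.constraints):
            op = {"<=": "<=", ">=": ">=", "==": "="}[con.op]
            nm = con.name or f"c{i}"
            lines.append(f" {nm}: {term_str(con.coeffs)} {op} {con.rhs:.12g}")
        for v, val in self.fixed.items():
            lines.append(f" fix_{v}: {v} = {val}")
        lines.append("Binary")
        lines.append(" " + " ".join(self.variables))
        lines.append("End")
        return "\n".join(lines) + "\n"


@dataclass
class SolveResult:
    status: str  # optimal | infeasible | limit-reached
    assignment: dict[str, int] = field(default_factory=dict)
    objective: float | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def selected(self, prefix: str) -> list[str]:
        """Names of variables with the given prefix set to 1."""
        return [
            v for v, val in self.assignment.items()
            if val == 1 and v.startswith(prefix)
        ]


def solve(
    model: ILPModel, time_limit: float | None = None, seed: int | None = None
) -> SolveResult:
    """Solve a 0/1 ILP to proven optimality.

    ``seed`` is accepted for interface stability; the HiGHS backend is
    deterministic for a fixed model, so it has no effect on the result.
    """
    try:
        from scipy.optimize import milp as _milp  # noqa: F401
    except ImportError as exc:  # pragma: no cover
        raise SolverUnavailableError(
            "scipy.optimize.milp (HiGHS) is required as the exact MILP backend"
        ) from exc
    nv = len(model.variables)
    idx = model._var_index
    c = np.zeros(nv)
    for v, coef in model.objective.items():
        c[idx[v]] = coef
    if model.sense == "max":
        c = -c
    rows, cols, data, lb, ub = [], [], [], [], []
    for r, con in enumerate(model.constraints):
        for v, coef in con.coeffs.items():
            rows.append(r)
            cols.append(idx[v])
            data.append(coef)
        if con.op == "<=":
            lb.append(-np.inf)
            ub.append(con.rhs)
        elif con.op == ">=":
            lb.append(con.rhs)
            ub.append(np.inf)
        else:
            lb.append(con.rhs)
            ub.append(con.rhs)
    var_lb = np.zeros(nv)
    var_ub = np.ones(nv)
    for v, val in model.fixed.items():
        var_lb[idx[v]] = val
        var_ub[idx[v]] = val
    constraints = []
    if model.constraints:
        a = csr_matrix((data, (rows, cols)), shape=(len(model.constraints), nv))
        constraints = [LinearConstraint(a, np.array(lb), np.array(ub))]
    # tight feasibility tolerances: viability thresholds like 0.3 must not be
    # undercut by the backend's default 1e-6 slack
    options = {
        "mip_feasibility_tolerance": 1e-9,
        "primal_feasibility_tolerance": 1e-9,
    }
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    from scipy.optimize import Bounds

    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="Unrecognized options", category=RuntimeWarning
        )
        res = milp(
            c,
            constraints=constraints,
            integrality=np.ones(nv),
            bounds=Bounds(var_lb, var_ub),
            options=options,
        )
    if res.status == 0:
        x = np.rint(res.x).astype(int)
        assignment = {v: int(x[idx[v]]) for v in model.variables}
        obj = model.objective_value(assignment)
        return SolveResult("optimal", assignment, obj)
    if res.status == 2:
        return SolveResult("infeasible")
    if res.status == 1:
        return SolveResult("limit-reached")
    return SolveResult("infeasible" if "infeasible" in str(res.message).lower()
                       else "limit-reached")


# ---------------------------------------------------------------------------
# Brute-force oracles


def brute_force_taxon(
    system: SplitSystem,
    web: FoodWeb | None,
    diets: DietMatrix | None,
    k: int,
    d: float | None = None,
    forced: Iterable[int] = (),
) -> tuple[frozenset[int], float]:
    """Exhaustive oracle for (d%-)viable taxon selection.

    Enumerates all subsets of size <= k containing the forced taxa, keeps
    those passing the viability predicate, and returns the one maximizing SD.
    Guarded at n <= 20 to stay combinatorially honest.
    """
    n = system.taxa.n
    if n > 20:
        raise ValueError(f"brute force refuses n={n} > 20 taxa")
    forced = frozenset(int(i) for i in forced)
    if len(forced) > k:
        raise ValueError("forced set larger than k")
    free = sorted(set(range(n)) - forced)
    best_set: frozenset[int] | None = None
    best_sd = -1.0
    base_mask = 0
    for i in forced:
        base_mask |= 1 << i
    for extra in range(0, k - len(forced) + 1):
        for combo in itertools.combinations(free, extra):
            subset = forced | frozenset(combo)
            if web is not None:
                if d is None:
                    if not is_viable(web, subset):
                        continue
                elif not is_d_viable(web, diets, subset, d):
                    continue
            mask = base_mask
            for i in combo:
                mask |= 1 << i
            sd = sd_score_mask(system, mask)
            if sd > best_sd + 1e-12:
                best_sd = sd
                best_set = subset
    if best_set is None:
        raise ValueError("no feasible subset (forced set cannot be made viable)")
    return best_set, best_sd


def brute_force_reserve(
    landscape, system: SplitSystem, p: float
) -> tuple[frozenset[int], float]:
    """Exhaustive oracle for reserve selection under an SD target.

    Enumerates all area subsets, keeps those whose covered taxa attain at
    least p% of the total SD, and returns the subset minimizing
    cost + beta * fence length.  Guarded at m <= 15 areas.
    """
    m = len(landscape.areas)
    if m > 15:
        raise ValueError(f"brute force refuses m={m} > 15 areas")
    target = (p / 100.0) * system.total_weight() - 1e-9
    area_masks = landscape.area_taxon_masks()
    best_set: frozenset[int] | None = None
    best_obj = np.inf
    for bits in range(1 << m):
        members = [i for i in range(m) if bits >> i & 1]
        cover = 0
        for i in members:
            cover |= area_masks[i]
        if sd_score_mask(system, cover) < target:
            continue
        obj = landscape.selection_cost(members)
        if obj < best_obj - 1e-12:
            best_obj = obj
            best_set = frozenset(members)
    if best_set is None:
        raise ValueError("no area subset attains the SD target")
    return best_set, float(best_obj)
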