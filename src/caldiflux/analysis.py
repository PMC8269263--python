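"""Flux analysis core: FBA, FVA, and MOMA on stoichiometric models.

All linear programs are solved with scipy's HiGHS backend under a fixed
lexicographic row/column ordering, so repeated runs give bit-stable
objective values.  Degenerate optima are expected: only objective values are
contractually reproducible; flux vectors are reported but should be
interrogated through FVA envelopes.

The :class:`FluxProblem` class caches the stoichiometric matrix of a model so
that thousands of feasibility/optimality solves (as in the minimal-network
study) only pay the matrix construction cost once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from scipy import optimize, sparse as sp

from .model import MediumSpec, Model, stoichiometric_matrix

__all__ = [
    "FluxSolution",
    "FluxRange",
    "LinearCoupling",
    "ConstrainedModel",
    "FluxProblem",
    "fba",
    "fva",
    "moma",
    "moma_linear",
]

#: Mass-balance equality tolerance.
EPS_EQ = 1e-9
#: Flux comparison tolerance used by callers/tests.
EPS_FLUX = 1e-6


@dataclass
class FluxSolution:
    """Outcome of a single optimization.

    ``status`` is one of ``optimal | infeasible | unbounded``; numeric junk is
    never propagated — ``objective_value`` and ``fluxes`` are only populated
    for optimal solves.
    """

    status: str
    objective_value: Optional[float] = None
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass(frozen=True)
class FluxRange:
    min_flux: float
    max_flux: float


@dataclass(frozen=True)
class LinearCoupling:
    """An extra linear constraint  lower <= sum(coef * v_rxn) <= upper."""

    coefficients: Mapping[str, float]
    lower: float
    upper: float


@dataclass
class ConstrainedModel:
    """A model plus side constraints (e.g., product-ratio calibration)."""

    model: Model
    constraints: Sequence[LinearCoupling] = ()


AnyModel = Union[Model, ConstrainedModel]


def _split(modelish: AnyModel) -> tuple[Model, Sequence[LinearCoupling]]:
    if isinstance(modelish, ConstrainedModel):
        return modelish.model, tuple(modelish.constraints)
    return modelish, ()


class FluxProblem:
    """Reusable LP scaffold for one model (fixed stoichiometry).

    Bounds may be perturbed per-solve through the ``overrides`` argument,
    which maps reaction id -> (lower, upper); this is how knockout
    tentatives, medium changes, and objective-fraction constraints are
    expressed without rebuilding the matrix.
    """

    def __init__(
        self,
        model: AnyModel,
        medium: Optional[MediumSpec] = None,
    ) -> None:
        model, couplings = _split(model)
        if medium is not None:
            model = medium.apply(model)
        self.model = model
        S, species, rxn_ids = stoichiometric_matrix(model)
        self.rxn_ids: list[str] = rxn_ids
        self.index: dict[str, int] = {rid: j for j, rid in enumerate(rxn_ids)}
        n = len(rxn_ids)
        self.lb = np.array([model.reactions[r].lower_bound for r in rxn_ids])
        self.ub = np.array([model.reactions[r].upper_bound for r in rxn_ids])

        eq_rows, eq_rhs = [S], [np.zeros(S.shape[0])]
        ub_rows, ub_rhs = [], []
        for c in couplings:
            row = np.zeros((1, n))
            for rid, coef in c.coefficients.items():
                row[0, self.index[rid]] = coef
            if c.lower == c.upper:
                eq_rows.append(sp.csr_matrix(row))
                eq_rhs.append(np.array([c.lower]))
            else:
                if np.isfinite(c.upper):
                    ub_rows.append(sp.csr_matrix(row))
                    ub_rhs.append(np.array([c.upper]))
                if np.isfinite(c.lower):
                    ub_rows.append(sp.csr_matrix(-row))
                    ub_rhs.append(np.array([-c.lower]))
        self.A_eq = sp.vstack(eq_rows, format="csr")
        self.b_eq = np.concatenate(eq_rhs)
        self.A_ub = sp.vstack(ub_rows, format="csr") if ub_rows else None
        self.b_ub = np.concatenate(ub_rhs) if ub_rows else None

    # -- internals ----------------------------------------------------------

    def _bounds(self, overrides: Optional[Mapping[str, tuple]] = None):
        lb, ub = self.lb, self.ub
        if overrides:
            lb, ub = lb.copy(), ub.copy()
            for rid, (lo, hi) in overrides.items():
                j = self.index[rid]
                lb[j], ub[j] = lo, hi
        return lb, ub

    def solve(
        self,
        objective: Optional[Mapping[str, float]] = None,
        maximize: bool = True,
        overrides: Optional[Mapping[str, tuple]] = None,
    ) -> FluxSolution:
        """Solve max/min c.v subject to the steady-state constraints."""

        n = len(self.rxn_ids)
        c = np.zeros(n)
        if objective:
            for rid, coef in objective.items():
                c[self.index[rid]] = coef
        if maximize:
            c = -c
        lb, ub = self._bounds(overrides)
        if np.any(lb > ub):
            return FluxSolution(status="infeasible")
        res = optimize.linprog(
            c,
            A_eq=self.A_eq,
            b_eq=self.b_eq,
            A_ub=self.A_ub,
            b_ub=self.b_ub,
            bounds=np.column_stack([lb, ub]),
            method="highs",
        )
        if res.status == 2:
            return FluxSolution(status="infeasible")
        if res.status == 3:
            return FluxSolution(status="unbounded")
        if not res.success:  # pragma: no cover - solver hiccup
            return FluxSolution(status="infeasible")
        value = -res.fun if maximize else res.fun
        fluxes = {rid: float(res.x[j]) for j, rid in enumerate(self.rxn_ids)}
        return FluxSolution(status="optimal", objective_value=float(value), fluxes=fluxes)

    def feasible(self, overrides: Optional[Mapping[str, tuple]] = None) -> bool:
        return self.solve(objective=None, maximize=False, overrides=overrides).optimal


# ---------------------------------------------------------------------------
# FBA / FVA
# ---------------------------------------------------------------------------


def fba(
    model: AnyModel,
    objective: str,
    medium: Optional[MediumSpec] = None,
    maximize: bool = True,
) -> FluxSolution:
    """Flux balance analysis: optimize one reaction's flux.

    Solves max (or min) v_obj subject to S.v = 0 and bounds.  The objective
    value is unique up to LP tolerance even when the flux vector is
    degenerate.
    """

    problem = FluxProblem(model, medium=medium)
    if objective not in problem.index:
        raise KeyError(f"objective reaction {objective!r} not in model")
    return problem.solve(objective={objective: 1.0}, maximize=maximize)


def fva(
    model: AnyModel,
    objective: str,
    fraction: float = 1.0,
    medium: Optional[MediumSpec] = None,
    reactions: Optional[Iterable[str]] = None,
) -> Union[dict, FluxSolution]:
    """Flux variability analysis at a given objective fraction.

    First maximizes ``objective``; then, with the objective constrained to at
    least ``fraction`` of its optimum, minimizes and maximizes every reaction
    in ``reactions`` (default: all).  Returns a dict of
    reaction id -> :class:`FluxRange`; if the base problem is not optimal the
    :class:`FluxSolution` carrying the status is returned instead.
    """

    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    problem = FluxProblem(model, medium=medium)
    base = problem.solve(objective={objective: 1.0}, maximize=True)
    if not base.optimal:
        return base
    opt = base.objective_value
    # Constrain the objective reaction from below.  For negative optima the
    # fraction is interpreted on the distance from zero, keeping the
    # constraint a relaxation of "at the optimum".
    floor = fraction * opt if opt >= 0 else opt / fraction
    j = problem.index[objective]
    overrides = {objective: (max(problem.lb[j], floor), problem.ub[j])}

    targets = list(reactions) if reactions is not None else list(problem.rxn_ids)
    ranges: dict[str, FluxRange] = {}
    for rid in targets:
        lo_sol = problem.solve({rid: 1.0}, maximize=False, overrides=overrides)
        hi_sol = problem.solve({rid: 1.0}, maximize=True, overrides=overrides)
        if not (lo_sol.optimal and hi_sol.optimal):  # pragma: no cover
            return FluxSolution(status=lo_sol.status if not lo_sol.optimal else hi_sol.status)
        ranges[rid] = FluxRange(
            min_flux=lo_sol.objective_value, max_flux=hi_sol.objective_value
        )
    return ranges


# ---------------------------------------------------------------------------
# MOMA
# ---------------------------------------------------------------------------


def moma(
    edited: AnyModel,
    reference_fluxes: Mapping[str, float],
    medium: Optional[MediumSpec] = None,
) -> FluxSolution:
    """Minimization of metabolic adjustment (quadratic objective).

    Finds the flux vector of the edited model closest (in squared Euclidean
    distance) to a wild-type reference distribution.  The returned
    ``objective_value`` is the achieved distance; fluxes carry the mutant
    prediction.  Reactions present in the edited model but missing from the
    reference are treated as reference flux 0.
    """

    problem = FluxProblem(edited, medium=medium)
    n = len(problem.rxn_ids)
    v_ref = np.array([reference_fluxes.get(rid, 0.0) for rid in problem.rxn_ids])
    lb, ub = problem.lb, problem.ub
    if np.any(lb > ub):
        return FluxSolution(status="infeasible")
    if not problem.feasible():
        return FluxSolution(status="infeasible")

    A, c_lo, c_hi = _constraint_rows(problem)
    # Fast path: the reference is already feasible (distance 0).
    v0 = np.clip(v_ref, lb, ub)
    if (
        np.allclose(v0, v_ref)
        and np.all(np.abs(A @ v_ref - np.clip(A @ v_ref, c_lo, c_hi)) < EPS_EQ)
    ):
        return FluxSolution(
            status="optimal",
            objective_value=0.0,
            fluxes={rid: float(v_ref[j]) for j, rid in enumerate(problem.rxn_ids)},
        )

    fun = lambda v: float(np.sum((v - v_ref) ** 2))
    jac = lambda v: 2.0 * (v - v_ref)
    # The raw mass-balance system carries linearly dependent rows (conserved
    # moieties), which breaks SLSQP's LSQ subproblem; replace the equality
    # block with an orthogonal, full-rank equivalent from its SVD.
    A_eq_red, b_eq_red = _reduce_equalities(
        problem.A_eq.toarray(), problem.b_eq
    )
    constraints = [optimize.LinearConstraint(A_eq_red, b_eq_red, b_eq_red)]
    if problem.A_ub is not None:
        constraints.append(
            optimize.LinearConstraint(
                problem.A_ub.toarray(),
                np.full(problem.A_ub.shape[0], -np.inf),
                problem.b_ub,
            )
        )
    bounds = optimize.Bounds(lb, ub)
    start = _feasible_start(problem, v_ref)
    res = optimize.minimize(
        fun,
        start,
        jac=jac,
        bounds=bounds,
        constraints=constraints,
        method="SLSQP",
        options={"maxiter": 1000, "ftol": 1e-14},
    )
    residual = lambda v: float(
        np.max(np.abs(A @ v - np.clip(A @ v, c_lo, c_hi)), initial=0.0)
    )
    if not res.success or residual(res.x) > 1e-6:
        res = optimize.minimize(  # pragma: no cover - fallback path
            fun,
            start,
            jac=jac,
            bounds=bounds,
            constraints=constraints,
            method="trust-constr",
            options={"maxiter": 3000, "gtol": 1e-10, "xtol": 1e-12},
        )
    v = np.asarray(res.x)
    if residual(v) > 1e-6:  # pragma: no cover - keep contracts honest
        v = start  # the L1 warm start is feasible; fall back to it
    return FluxSolution(
        status="optimal",
        objective_value=float(np.sum((v - v_ref) ** 2)),
        fluxes={rid: float(v[j]) for j, rid in enumerate(problem.rxn_ids)},
    )


def _feasible_start(problem: FluxProblem, v_ref: np.ndarray) -> np.ndarray:
    """Project the reference toward feasibility with one L1 LP (warm start)."""

    sol = _l1_closest(problem, v_ref)
    if sol is not None:
        return sol
    zero = problem.solve(objective=None, maximize=False)
    return np.array([zero.fluxes[r] for r in problem.rxn_ids])


def _reduce_equalities(A: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Replace A v = b by an equivalent full-rank orthogonal system."""

    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    tol = max(A.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    keep = s > tol
    return Vt[keep], (U.T @ b)[keep] / s[keep]


def _constraint_rows(problem: FluxProblem):
    """All side constraints of a problem as (matrix, lower, upper) arrays."""

    mats = [problem.A_eq]
    lo = [problem.b_eq]
    hi = [problem.b_eq]
    if problem.A_ub is not None:
        mats.append(problem.A_ub)
        lo.append(np.full(problem.A_ub.shape[0], -np.inf))
        hi.append(problem.b_ub)
    A = sp.vstack(mats, format="csr").toarray()
    return A, np.concatenate(lo), np.concatenate(hi)


def _l1_closest(problem: FluxProblem, v_ref: np.ndarray) -> Optional[np.ndarray]:
    """Minimize sum |v - v_ref| subject to the problem constraints (an LP)."""

    n = len(problem.rxn_ids)
    m_eq = problem.A_eq.shape[0]
    # Variables: [v, t]; minimize 1.t with  v - t <= v_ref,  -v - t <= -v_ref.
    c = np.concatenate([np.zeros(n), np.ones(n)])
    I = sp.identity(n, format="csr")
    A_eq = sp.hstack([problem.A_eq, sp.csr_matrix((m_eq, n))], format="csr")
    ub_rows = [sp.hstack([I, -I]), sp.hstack([-I, -I])]
    b_ub = [v_ref, -v_ref]
    if problem.A_ub is not None:
        ub_rows.insert(
            0, sp.hstack([problem.A_ub, sp.csr_matrix((problem.A_ub.shape[0], n))])
        )
        b_ub.insert(0, problem.b_ub)
    res = optimize.linprog(
        c,
        A_eq=A_eq,
        b_eq=problem.b_eq,
        A_ub=sp.vstack(ub_rows, format="csr"),
        b_ub=np.concatenate(b_ub),
        bounds=[(lo, hi) for lo, hi in zip(problem.lb, problem.ub)]
        + [(0, None)] * n,
        method="highs",
    )
    if not res.success:
        return None
    return np.asarray(res.x[:n])


def moma_linear(
    edited: AnyModel,
    reference_fluxes: Mapping[str, float],
    medium: Optional[MediumSpec] = None,
) -> FluxSolution:
    """L1 (linear-programming) variant of MOMA for solver-free environments.

    Minimizes the sum of absolute flux deviations from the reference instead
    of the squared deviation; objective_value is the achieved L1 distance.
    """

    problem = FluxProblem(edited, medium=medium)
    v_ref = np.array([reference_fluxes.get(rid, 0.0) for rid in problem.rxn_ids])
    if np.any(problem.lb > problem.ub) or not problem.feasible():
        return FluxSolution(status="infeasible")
    v = _l1_closest(problem, v_ref)
    if v is None:  # pragma: no cover
        return FluxSolution(status="infeasible")
    return FluxSolution(
        status="optimal",
        objective_value=float(np.sum(np.abs(v - v_ref))),
        fluxes={rid: float(v[j]) for j, rid in enumerate(problem.rxn_ids)},
    )
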