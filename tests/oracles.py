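"""Independent test oracles.

These deliberately avoid the package's LP machinery: the vertex enumerator
works straight from dense linear algebra over basic solutions, and the
two-pathway fixture oracle is pure boolean logic.  They exist so that FBA
and the minimal-network study can be checked against something that shares
no code path with the implementation.
"""

from __future__ import annotations

import itertools

import numpy as np


def vertex_enumerate_optimum(S, lb, ub, c, tol=1e-9):
    """Maximum of c.v over {v : S v = 0, lb <= v <= ub} by brute force.

    Enumerates candidate vertices: every subset of variables fixed at a
    bound whose complementary columns of S have full column rank, solving
    the remaining equality system exactly.  Suitable only for tiny problems
    (n <= ~8).  Returns the best objective, or None if no feasible vertex
    exists (the fixtures are always bounded polytopes, where the optimum is
    attained at a vertex).
    """

    S = np.asarray(S, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    c = np.asarray(c, dtype=float)
    n = S.shape[1]
    best = None
    for k in range(n + 1):
        for fixed in itertools.combinations(range(n), k):
            free = [j for j in range(n) if j not in fixed]
            S_free = S[:, free]
            if free and np.linalg.matrix_rank(S_free) < len(free):
                continue  # not a unique basic solution
            for pattern in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
                v = np.zeros(n)
                for j, val in zip(fixed, pattern):
                    v[j] = val
                rhs = -S[:, fixed] @ np.array(pattern) if fixed else np.zeros(S.shape[0])
                if free:
                    sol, *_ = np.linalg.lstsq(S_free, rhs, rcond=None)
                    v[free] = sol
                if np.max(np.abs(S @ v)) > tol:
                    continue
                if np.any(v < lb - tol) or np.any(v > ub + tol):
                    continue
                value = float(c @ v)
                if best is None or value > best:
                    best = value
    return best


# ---------------------------------------------------------------------------
# Two-pathway fixture: boolean feasibility oracle
# ---------------------------------------------------------------------------

#: Deletable reactions of the 12-reaction two-pathway fixture.
TWO_PATHWAY_DELETABLE = (
    "T1",
    "P1a", "P1b", "P2a", "P2b",
    "Q1", "Q2a", "Q2b",
    "R1",
    "D1", "D2", "X1",
)


def two_pathway_feasible(subset) -> bool:
    """Feasibility (flux >= 1 from A to Z) of a reaction subset, by logic.

    The fixture routes A -> Z either through B (P1a|P1b then P2a|P2b),
    through C (Q1 then Q2a|Q2b), or through the B->C crosslink
    (P1a|P1b then R1 then Q2a|Q2b).  T1 (uptake transport) is always
    required; D1/D2/X1 lead to a dead end and never matter.
    """

    s = set(subset)
    if "T1" not in s:
        return False
    via_b = ("P1a" in s or "P1b" in s) and ("P2a" in s or "P2b" in s)
    via_c = "Q1" in s and ("Q2a" in s or "Q2b" in s)
    via_cross = ("P1a" in s or "P1b" in s) and "R1" in s and ("Q2a" in s or "Q2b" in s)
    return via_b or via_c or via_cross


def two_pathway_minimal_networks() -> list[frozenset]:
    """All 1-minimal feasible subsets, by exhaustive enumeration (2^12)."""

    minimal = []
    universe = TWO_PATHWAY_DELETABLE
    for bits in itertools.product((0, 1), repeat=len(universe)):
        subset = frozenset(r for r, b in zip(universe, bits) if b)
        if not two_pathway_feasible(subset):
            continue
        if all(not two_pathway_feasible(subset - {r}) for r in subset):
            minimal.append(subset)
    return minimal


def two_pathway_classification() -> tuple[frozenset, frozenset, frozenset]:
    """Ground-truth (core, conditional, nonessential) over the universe."""

    nets = two_pathway_minimal_networks()
    universe = frozenset(TWO_PATHWAY_DELETABLE)
    core = frozenset.intersection(*nets)
    union = frozenset.union(*nets)
    return core, union - core, universe - union
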