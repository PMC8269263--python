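"""Randomized minimal-network analysis.

A *minimal network* is a subset of reactions from which no single deletable
reaction can be removed without making the imposed constraints (a minimum
biomass flux and an ethanol-production level) infeasible.  Replicate minimal
networks are found by greedy pruning in a seeded uniform-random reaction
order; classifying each reaction by its occurrence across replicates yields
three sets:

* **core-essential** — present in every minimal network,
* **conditionally essential** — present in some but not all,
* **nonessential** — present in none.

The per-replicate trace of the three set sizes supports a convergence
diagnostic (sizes unchanged over a trailing window).

Ethanol levels follow the study protocol: 0 (production forced to zero),
0.5 (at least half the maximum), and 0.9999 (at least 99.99% of the
maximum — the slack absorbs LP solver tolerance).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .analysis import FluxProblem
from .model import MediumSpec, Model

__all__ = [
    "SparseConstraints",
    "MinimalNetwork",
    "ClassificationResult",
    "SparseStudyResult",
    "ETHANOL_LEVELS",
    "deletable_reactions",
    "find_minimal_network",
    "classify",
    "convergence",
    "run_sparse_study",
]

#: Named ethanol production levels: fraction of the model's maximum.
ETHANOL_LEVELS = {"none": 0.0, "half": 0.5, "max": 0.9999}

#: Reaction kinds never pruned (media and objectives are not network choices).
PROTECTED_KINDS = ("exchange", "biomass", "sink")


@dataclass(frozen=True)
class SparseConstraints:
    """Feasibility constraints maintained during pruning.

    ``ethanol_level`` is a fraction of the maximum ethanol flux (computed
    under the biomass constraint); level 0 pins production to zero.
    ``biomass_min`` is an absolute flux floor on the biomass reaction.
    """

    biomass_min: float = 0.0
    ethanol_level: float = 0.0
    ethanol_exchange: str = "EX_etoh"
    protected_reactions: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.biomass_min < 0:
            raise ValueError("biomass_min must be nonnegative")
        if not 0.0 <= self.ethanol_level <= 1.0:
            raise ValueError("ethanol_level must be in [0, 1]")


@dataclass(frozen=True)
class MinimalNetwork:
    retained: frozenset[str]
    seed: int
    order: tuple[str, ...]


@dataclass
class ClassificationResult:
    core_essential: frozenset[str]
    conditionally_essential: frozenset[str]
    nonessential: frozenset[str]
    #: (core size, conditional size, nonessential size) after each network.
    trace: list[tuple[int, int, int]] = field(default_factory=list)


@dataclass
class SparseStudyResult:
    level: float
    biomass_min: float
    ethanol_target: float
    networks: list[MinimalNetwork]
    classification: ClassificationResult
    converged: bool
    convergence_iteration: Optional[int]
    seeds: list[int]
    occurrence: dict[str, int]


def deletable_reactions(
    model: Model, protected: Iterable[str] = ()
) -> list[str]:
    """Reactions eligible for pruning: everything but boundary pseudo-
    reactions and an explicit protected set."""

    protected = set(protected)
    return sorted(
        rid
        for rid, rxn in model.reactions.items()
        if rxn.kind not in PROTECTED_KINDS and rid not in protected
    )


def _ethanol_bounds(
    problem: FluxProblem, constraints: SparseConstraints
) -> dict[str, tuple[float, float]]:
    """Translate the study constraints into bound overrides on the problem."""

    overrides: dict[str, tuple[float, float]] = {}
    biomass = problem.model.biomass_id
    if biomass is not None and constraints.biomass_min > 0:
        j = problem.index[biomass]
        overrides[biomass] = (constraints.biomass_min, problem.ub[j])
    ex = constraints.ethanol_exchange
    if ex in problem.index:
        j = problem.index[ex]
        if constraints.ethanol_level == 0.0:
            overrides[ex] = (0.0, 0.0)
        else:
            base = problem.solve({ex: 1.0}, maximize=True, overrides=overrides)
            if not base.optimal:
                raise RuntimeError(
                    f"cannot establish maximum ethanol: {base.status}"
                )
            target = constraints.ethanol_level * base.objective_value
            overrides[ex] = (target, problem.ub[j])
    return overrides


def find_minimal_network(
    model: Model,
    constraints: SparseConstraints,
    seed: int,
    medium: Optional[MediumSpec] = None,
) -> MinimalNetwork:
    """Greedy random-order pruning to a 1-minimal constraint-feasible set.

    Deletable reactions are visited in a seeded uniform permutation; each is
    tentatively blocked and stays blocked iff the biomass/ethanol constraints
    remain feasible.  The result is 1-minimal by construction: every retained
    deletable reaction was tested against the final network's predecessors
    and, because blocking decisions are monotone (a reaction infeasible to
    remove early can only stay infeasible as more reactions are blocked),
    cannot be removed from the final set either.
    """

    problem = FluxProblem(model, medium=medium)
    base_overrides = _ethanol_bounds(problem, constraints)
    if not problem.feasible(base_overrides):
        raise RuntimeError("constraints are infeasible on the full model")

    candidates = deletable_reactions(model, constraints.protected_reactions)
    rng = np.random.default_rng(seed)
    order = tuple(np.array(candidates)[rng.permutation(len(candidates))])

    overrides = dict(base_overrides)
    removed: set[str] = set()
    for rid in order:
        if rid in base_overrides:
            continue
        saved = overrides.get(rid)
        overrides[rid] = (0.0, 0.0)
        if problem.feasible(overrides):
            removed.add(rid)
        else:
            if saved is None:
                del overrides[rid]
            else:  # pragma: no cover - defensive
                overrides[rid] = saved
    retained = frozenset(model.reactions) - removed
    return MinimalNetwork(retained=retained, seed=seed, order=order)


def classify(
    networks: Sequence[MinimalNetwork], universe: Iterable[str]
) -> ClassificationResult:
    """Occurrence-based partition of the deletable universe.

    ``universe`` is the deletable reaction set; reactions outside it
    (exchanges, biomass, sinks) are never classified.
    """

    if not networks:
        raise ValueError("classification requires at least one network")
    universe = frozenset(universe)
    inter: Optional[set[str]] = None
    union: set[str] = set()
    trace: list[tuple[int, int, int]] = []
    for net in networks:
        present = set(net.retained) & universe
        inter = set(present) if inter is None else inter & present
        union |= present
        trace.append(
            (len(inter), len(union - inter), len(universe - union))
        )
    return ClassificationResult(
        core_essential=frozenset(inter or set()),
        conditionally_essential=frozenset(union - (inter or set())),
        nonessential=frozenset(universe - union),
        trace=trace,
    )


def convergence(
    trace: Sequence[tuple[int, int, int]], window: int = 100
) -> tuple[bool, Optional[int]]:
    """Converged iff all three set sizes are unchanged for ``window``
    consecutive additions; returns the first iteration (1-based) at which the
    stable window completes."""

    if window <= 0:
        raise ValueError("window must be positive")
    if window > len(trace):
        return False, None
    for end in range(window, len(trace) + 1):
        chunk = trace[end - window : end]
        if all(t == chunk[0] for t in chunk):
            return True, end
    return False, None


def run_sparse_study(
    model: Model,
    level: Union[str, float],
    n: int,
    base_seed: int,
    biomass_min: float = 0.0,
    ethanol_exchange: str = "EX_etoh",
    medium: Optional[MediumSpec] = None,
    window: int = 100,
    protected: Iterable[str] = (),
) -> SparseStudyResult:
    """Run ``n`` seeded minimal-network replicates and classify.

    Replicate seeds are ``base_seed .. base_seed + n - 1`` (recorded in the
    result for audit); identical ``base_seed`` gives bit-identical results.
    """

    if n < 1:
        raise ValueError("need at least one replicate")
    frac = ETHANOL_LEVELS[level] if isinstance(level, str) else float(level)
    constraints = SparseConstraints(
        biomass_min=biomass_min,
        ethanol_level=frac,
        ethanol_exchange=ethanol_exchange,
        protected_reactions=frozenset(protected),
    )
    # Record the absolute ethanol target for the manifest.
    problem = FluxProblem(model, medium=medium)
    overrides = _ethanol_bounds(problem, constraints)
    target = overrides.get(ethanol_exchange, (0.0, 0.0))[0]

    seeds = list(range(base_seed, base_seed + n))
    networks = [
        find_minimal_network(model, constraints, seed, medium=medium)
        for seed in seeds
    ]
    universe = deletable_reactions(model, constraints.protected_reactions)
    result = classify(networks, universe)
    converged, iteration = convergence(result.trace, window=window)
    occurrence = {
        rid: sum(1 for net in networks if rid in net.retained)
        for rid in universe
    }
    return SparseStudyResult(
        level=frac,
        biomass_min=biomass_min,
        ethanol_target=target,
        networks=networks,
        classification=result,
        converged=converged,
        convergence_iteration=iteration,
        seeds=seeds,
        occurrence=occurrence,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def study_table(study: SparseStudyResult) -> pd.DataFrame:
    """Per-reaction classification table (id, class, occurrence, n)."""

    cls = study.classification
    rows = []
    for rid in sorted(study.occurrence):
        if rid in cls.core_essential:
            label = "core-essential"
        elif rid in cls.conditionally_essential:
            label = "conditionally-essential"
        else:
            label = "nonessential"
        rows.append(
            {
                "reaction": rid,
                "class": label,
                "occurrence": study.occurrence[rid],
                "n": len(study.networks),
            }
        )
    return pd.DataFrame(rows)


def write_study(study: SparseStudyResult, directory: Union[str, Path]) -> None:
    """Write the classification TSV and a JSON run manifest."""

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    study_table(study).to_csv(directory / "classification.tsv", sep="\t", index=False)
    manifest = {
        "level": study.level,
        "biomass_min": study.biomass_min,
        "ethanol_target": study.ethanol_target,
        "n": len(study.networks),
        "seeds": study.seeds,
        "converged": study.converged,
        "convergence_iteration": study.convergence_iteration,
        "class_sizes": {
            "core_essential": len(study.classification.core_essential),
            "conditionally_essential": len(
                study.classification.conditionally_essential
            ),
            "nonessential": len(study.classification.nonessential),
        },
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
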