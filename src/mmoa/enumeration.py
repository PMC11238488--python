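"""iMAT-style consensus MILP and partial enumeration of alternative optima.

The consensus problem asks for a steady-state flux distribution that
maximizes agreement with the trinary expression calls: each a-priori
active reaction (RH) scores a point when it carries flux at or above the
activation threshold epsilon, each a-priori inactive reaction (RL) scores
a point when it carries none. Because expression constrains only part of
the network, the optimum is massively degenerate: many distinct activity
patterns reach the same score. The enumeration strategies below sample
that optimal set:

* ``reaction_enum`` re-solves the MILP once per reaction with that
  reaction forced into the state opposite its baseline state, keeping
  every solution that still attains the optimal score;
* ``systematic_sample`` thins an ordered solution list to a fraction by
  drawing one solution per contiguous batch;
* ``diversity_enum`` starts from sampled solutions and repeatedly
  maximizes the Hamming distance of the activity vector to everything
  found so far, with the optimal score held as a hard constraint, pushing
  the search toward the far edges of the optimal set.

Every reaction carries explicit activity indicators (a forward binary,
plus a backward binary when reversible) with exact linking: indicator on
implies |v| >= epsilon, indicator off implies v = 0. Solutions are
therefore binary activity patterns, directly comparable across runs. The
MILP backend is GLPK through optlang, which is deterministic.
"""

from __future__ import annotations

import itertools
from contextlib import contextmanager
from dataclasses import dataclass, field

import numpy as np
from optlang.glpk_interface import Constraint, Model, Objective, Variable
from scipy.optimize import linprog

from .expression import CoreSets, GeneCategorization, derive_core_sets
from .model_io import MetabolicModel
from .solutions import BinarySolution, SolutionSet

__all__ = [
    "ImatProblem",
    "ImatMilp",
    "EnumParams",
    "solve_imat",
    "reaction_enum",
    "systematic_sample",
    "diversity_enum",
    "enumerate_condition",
    "verify_pattern",
]


@dataclass
class ImatProblem:
    """The consensus problem: a model, its core sets, and the threshold."""

    model: MetabolicModel
    core: CoreSets
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        rxns = set(self.model.reactions)
        stray = (self.core.rh | self.core.rl) - rxns
        if stray:
            raise ValueError(f"core sets reference unknown reactions: {sorted(stray)}")


class ImatMilp:
    """The consensus MILP with helpers for enumeration.

    Holds one optlang/GLPK model that is mutated in place (temporary
    constraints, swapped objectives) by the enumeration strategies; all
    mutations are scoped by context managers so the object can be reused.
    """

    def __init__(self, problem: ImatProblem):
        self.problem = problem
        model = problem.model
        eps = problem.epsilon
        self.reactions = list(model.reactions)
        self._v: dict[str, Variable] = {}
        self._af: dict[str, Variable] = {}
        self._ab: dict[str, Variable] = {}
        constraints = []
        for rid in self.reactions:
            rxn = model.reactions[rid]
            lb, ub = rxn.lower_bound, rxn.upper_bound
            v = Variable(f"v_{rid}", lb=lb, ub=ub)
            af = Variable(f"af_{rid}", type="binary")
            self._v[rid], self._af[rid] = v, af
            act = af
            # af=1 => v >= eps (af=0 relaxes to v >= lb)
            constraints.append(Constraint(v - (eps - lb) * af, lb=lb, name=f"fwd_{rid}"))
            if rxn.reversible:
                ab = Variable(f"ab_{rid}", type="binary")
                self._ab[rid] = ab
                act = af + ab
                # ab=1 => v <= -eps
                constraints.append(Constraint(v - (-eps - ub) * ab, ub=ub, name=f"bwd_{rid}"))
                constraints.append(Constraint(af + ab, ub=1, name=f"dir_{rid}"))
            # both indicators off => v = 0
            constraints.append(Constraint(v - ub * act, ub=0, name=f"cap_{rid}"))
            constraints.append(Constraint(v - min(lb, 0.0) * act, lb=0, name=f"floor_{rid}"))
        for mid in model.metabolites:
            terms = [
                rxn.stoichiometry[mid] * self._v[rxn.id]
                for rxn in model.reactions.values()
                if mid in rxn.stoichiometry and rxn.stoichiometry[mid] != 0
            ]
            if terms:
                constraints.append(Constraint(sum(terms), lb=0, ub=0, name=f"mass_{mid}"))
        self._milp = Model(name="imat")
        self._milp.add(constraints)
        self._consensus = sum(self._activity_expr(r) for r in sorted(problem.core.rh)) - sum(
            self._activity_expr(r) for r in sorted(problem.core.rl)
        )
        if isinstance(self._consensus, int):  # both core sets empty
            self._consensus = 0 * next(iter(self._v.values()))
        self.set_consensus_objective()
        self._optimum: int | None = None

    def _activity_expr(self, rid: str):
        if rid in self._ab:
            return self._af[rid] + self._ab[rid]
        return self._af[rid]

    def set_consensus_objective(self) -> None:
        self._milp.objective = Objective(self._consensus, direction="max")

    def set_distance_objective(self, patterns: list[tuple[int, ...]]) -> None:
        """Maximize summed Hamming distance of the activity vector to ``patterns``."""
        n = len(patterns)
        ones = np.sum(np.asarray(patterns, dtype=int), axis=0)
        expr = sum(
            (n - 2 * int(ones[i])) * self._activity_expr(rid)
            for i, rid in enumerate(self.reactions)
        )
        self._milp.objective = Objective(expr, direction="max")

    def solve(self) -> BinarySolution | None:
        """Solve with the current objective/constraints; None if infeasible."""
        status = self._milp.optimize()
        if status != "optimal":
            return None
        pattern = tuple(
            int(round(self._af[r].primal + (self._ab[r].primal if r in self._ab else 0.0)))
            for r in self.reactions
        )
        return BinarySolution(pattern, self.score_of(pattern))

    def score_of(self, pattern: tuple[int, ...]) -> int:
        """Consensus score of an activity pattern (no solving involved)."""
        idx = {r: i for i, r in enumerate(self.reactions)}
        core = self.problem.core
        return sum(pattern[idx[r]] for r in core.rh) + sum(1 - pattern[idx[r]] for r in core.rl)

    def optimum(self) -> int:
        if self._optimum is None:
            sol = self.solve()
            if sol is None:
                raise RuntimeError("consensus MILP is infeasible")
            self._optimum = sol.objective_score
        return self._optimum

    @contextmanager
    def forced_state(self, rid: str, active: bool):
        """Temporarily force one reaction active (|v|>=eps) or blocked (v=0)."""
        expr = self._activity_expr(rid)
        c = Constraint(expr, lb=1, name=f"force_{rid}") if active else Constraint(
            expr, ub=0, name=f"force_{rid}"
        )
        self._milp.add([c])
        try:
            yield
        finally:
            self._milp.remove([c])

    @contextmanager
    def fixed_score(self, score: int):
        """Temporarily pin the consensus score to an exact value."""
        rl_size = len(self.problem.core.rl)
        c = Constraint(self._consensus, lb=score - rl_size, ub=score - rl_size, name="fix_score")
        self._milp.add([c])
        try:
            yield
        finally:
            self._milp.remove([c])


def solve_imat(problem: ImatProblem, seed: int = 0) -> BinarySolution:
    """Solve the consensus MILP once and return one optimal activity pattern.

    GLPK is deterministic, so ``seed`` does not change the result; it is
    accepted for interface symmetry with the stochastic enumeration steps.
    """
    del seed
    sol = ImatMilp(problem).solve()
    if sol is None:
        raise RuntimeError("consensus MILP is infeasible; check bounds and biomass constraint")
    return sol


def reaction_enum(problem: ImatProblem, milp: ImatMilp | None = None) -> SolutionSet:
    """Enumerate alternative optima by flipping each reaction's baseline state.

    For every reaction the MILP is re-solved with the reaction forced to
    the state opposite its state in the baseline optimum (active ->
    blocked, inactive -> forced active). Solutions that still reach the
    unconstrained optimal score are kept; forced-infeasible iterations are
    skipped. The baseline solution is always included and the result is
    duplicate-free, in discovery order.
    """
    milp = milp or ImatMilp(problem)
    milp.set_consensus_objective()
    baseline = milp.solve()
    if baseline is None:
        raise RuntimeError("consensus MILP is infeasible")
    opt = baseline.objective_score
    milp._optimum = opt
    rows = [baseline.activities]
    scores = [opt]
    idx = {r: i for i, r in enumerate(milp.reactions)}
    for rid in milp.reactions:
        was_active = baseline.activities[idx[rid]] == 1
        with milp.forced_state(rid, active=not was_active):
            sol = milp.solve()
        if sol is not None and sol.objective_score == opt:
            rows.append(sol.activities)
            scores.append(sol.objective_score)
    return SolutionSet.from_rows(milp.reactions, rows, scores=scores)


def systematic_sample(solutions: SolutionSet, fraction: float = 0.01, seed: int = 0) -> SolutionSet:
    """Draw one random solution per contiguous batch of ceil(1/fraction).

    Keeps roughly ``fraction`` of the ordered solution list while touching
    every stretch of it, so the thinned set stays representative of the
    whole enumeration order. Deterministic for a given seed.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = len(solutions)
    if n == 0:
        return SolutionSet(solutions.reactions, np.empty((0, len(solutions.reactions))),
                           condition=solutions.condition)
    batch = int(np.ceil(1.0 / fraction))
    rng = np.random.default_rng(seed)
    rows = list(solutions)
    picked = [rows[start + int(rng.integers(min(batch, n - start)))]
              for start in range(0, n, batch)]
    return SolutionSet.from_rows(solutions.reactions, picked, condition=solutions.condition)


def diversity_enum(
    problem: ImatProblem,
    start_solutions: SolutionSet,
    iterations_per_start: int = 5,
    seed: int = 0,
    milp: ImatMilp | None = None,
) -> SolutionSet:
    """Walk away from each start by maximizing Hamming distance at fixed score.

    For each start solution the MILP is re-solved with (a) the optimal
    consensus score as an equality constraint and (b) an objective that
    maximizes the summed Hamming distance between the activity vector and
    all solutions found so far for that start. The walk stops after
    ``iterations_per_start`` rounds or as soon as it revisits a known
    solution. The returned set is the union of all walks and the starts.
    The solver is deterministic; ``seed`` is accepted for interface
    symmetry.
    """
    del seed
    milp = milp or ImatMilp(problem)
    if start_solutions.reactions and start_solutions.reactions != milp.reactions:
        raise ValueError("start solutions are indexed over a different reaction list")
    milp.set_consensus_objective()
    opt = milp.optimum()
    for pattern in start_solutions:
        if milp.score_of(pattern) != opt:
            raise ValueError("start solution is not optimal for this problem")
    rows = list(start_solutions)
    with milp.fixed_score(opt):
        for start in start_solutions:
            found = [start]
            for _ in range(iterations_per_start):
                milp.set_distance_objective(found)
                sol = milp.solve()
                if sol is None or sol.activities in found:
                    break
                found.append(sol.activities)
            rows.extend(found[1:])
    milp.set_consensus_objective()
    return SolutionSet.from_rows(start_solutions.reactions or milp.reactions, rows,
                                 condition=start_solutions.condition)


@dataclass
class EnumParams:
    """Knobs of the per-condition enumeration pipeline."""

    epsilon: float = 1.0
    fraction: float = 0.01
    iterations_per_start: int = 5
    seed: int = 0


def enumerate_condition(
    model: MetabolicModel,
    categorizations: dict[str, GeneCategorization],
    params: EnumParams | None = None,
    condition: str = "",
) -> SolutionSet:
    """Run the full enumeration for one condition and pool its replicates.

    Per replicate sample: derive core sets from its trinary calls, run
    reaction-enum, thin the result by systematic sampling, extend it with
    diversity-enum from the sampled starts, and union the two. Replicate
    solution sets are then merged and deduplicated under one condition
    label.
    """
    if not categorizations:
        raise ValueError("need at least one replicate categorization")
    params = params or EnumParams()
    merged: SolutionSet | None = None
    for i, (sample, cat) in enumerate(sorted(categorizations.items())):
        core = derive_core_sets(model, cat)
        problem = ImatProblem(model, core, epsilon=params.epsilon)
        milp = ImatMilp(problem)
        renum = reaction_enum(problem, milp=milp)
        starts = systematic_sample(renum, fraction=params.fraction, seed=params.seed + i)
        denum = diversity_enum(problem, starts, params.iterations_per_start,
                               seed=params.seed + i, milp=milp)
        replicate = renum.union(denum)
        merged = replicate if merged is None else merged.union(replicate)
    merged.condition = condition
    return merged


def verify_pattern(model: MetabolicModel, reactions: list[str], pattern: tuple[int, ...],
                   epsilon: float = 1.0, max_reversible: int = 12) -> bool:
    """LP feasibility check: can the activity pattern carry a steady state?

    Inactive reactions are pinned to zero flux; active irreversible ones
    to [max(lb, eps), ub]; active reversible ones must reach |v| >= eps in
    one of the two orientations, so orientations are searched exhaustively
    (bounded by ``max_reversible`` active reversible reactions).
    """
    mets = list(model.metabolites)
    met_idx = {m: i for i, m in enumerate(mets)}
    n = len(reactions)
    a_eq = np.zeros((len(mets), n))
    for j, rid in enumerate(reactions):
        for m, c in model.reactions[rid].stoichiometry.items():
            a_eq[met_idx[m], j] = c
    rev_active = [j for j, rid in enumerate(reactions)
                  if pattern[j] == 1 and model.reactions[rid].reversible]
    if len(rev_active) > max_reversible:
        raise ValueError("too many active reversible reactions for exhaustive orientation search")
    base_bounds: list[tuple[float, float]] = []
    for j, rid in enumerate(reactions):
        rxn = model.reactions[rid]
        if pattern[j] == 0:
            base_bounds.append((0.0, 0.0))
        elif rxn.reversible:
            base_bounds.append((rxn.lower_bound, rxn.upper_bound))  # refined per orientation
        else:
            base_bounds.append((max(rxn.lower_bound, epsilon), rxn.upper_bound))
    for signs in itertools.product((1, -1), repeat=len(rev_active)):
        bounds = list(base_bounds)
        for s, j in zip(signs, rev_active):
            rxn = model.reactions[reactions[j]]
            bounds[j] = (epsilon, rxn.upper_bound) if s == 1 else (rxn.lower_bound, -epsilon)
        res = linprog(np.zeros(n), A_eq=a_eq, b_eq=np.zeros(len(mets)), bounds=bounds,
                      method="highs")
        if res.status == 0:
            return True
    return False
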