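"""Structured cultural transmission on a toroidal lattice.

A binary cultural variant (wild vs mutant) spreads through a population
of agents arranged on a width x height lattice wrapped on a torus.  Each
agent interacts only with its eight closest neighbours, split into two
classes: the four orthogonally adjacent cells ("friends", direct
contacts) and the four diagonal cells ("friends-of-friends", indirect
contacts).  Per generation, synchronously and reading the previous
generation's states, each agent keeps its variant with probability
b_self, or else imitates from the direct class (probability b_direct) or
the indirect class (b_indirect); the three biases sum to one.

Imitation follows the classic cultural-inheritance bias form: if q is
the mutant fraction among the sampled cultural parents, the agent adopts
the mutant with probability q + beta*q*(1-q).  With the default beta=0
this reduces to copying one uniformly chosen parent (unbiased vertical
transmission); beta>0 models a directional bias favouring the mutant.
Mutation occurs only at seeding, so all-wild and all-mutant states are
absorbing: a run ends in extinction, full penetrance, or censoring at
the generation cap.

A mean-field variant drops the spatial constraint and draws n_parents
cultural parents uniformly from the whole population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "LatticeConfig",
    "BiasVector",
    "SimResult",
    "EnsembleResult",
    "neighbours",
    "step",
    "step_mean_field",
    "run",
    "run_mean_field",
    "ensemble",
]


@dataclass(frozen=True)
class LatticeConfig:
    """Geometry and run-control of the transmission simulator."""

    width: int = 100
    height: int = 100
    n_parents: int = 8
    max_generations: int = 500
    seed_count: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 3 or self.height < 3:
            raise ValueError("lattice must be at least 3x3 (neighbour classes collide)")
        if self.n_parents < 1:
            raise ValueError("n_parents must be >= 1")
        if not 1 <= self.seed_count <= self.n_agents:
            raise ValueError("seed_count must be in 1..width*height")
        if self.max_generations < 0:
            raise ValueError("max_generations must be >= 0")

    @property
    def n_agents(self) -> int:
        return self.width * self.height


@dataclass(frozen=True)
class BiasVector:
    """Retention / direct-imitation / indirect-imitation probabilities."""

    b_self: float
    b_direct: float
    b_indirect: float

    def __post_init__(self) -> None:
        vals = (self.b_self, self.b_direct, self.b_indirect)
        if any(not 0 <= v <= 1 for v in vals):
            raise ValueError("bias components must lie in [0, 1]")
        if abs(sum(vals) - 1.0) > 1e-12:
            raise ValueError(f"bias components must sum to 1, got {sum(vals)!r}")


Outcome = Literal["extinct", "penetrant", "censored"]


@dataclass(frozen=True)
class SimResult:
    """Outcome of a single transmission run."""

    outcome: Outcome
    generations: int
    final_mutants: int
    trajectory: tuple[int, ...] | None = None


@dataclass(frozen=True)
class EnsembleResult:
    """Aggregate over independent replicate runs."""

    n_reps: int
    extinction_fraction: float
    penetrant_fraction: float
    censored_fraction: float
    penetrance_time_quantiles: dict[str, float]
    results: tuple[SimResult, ...] = field(repr=False, default=())


def neighbours(
    config: LatticeConfig, x: int, y: int
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Direct (orthogonal) and indirect (diagonal) neighbours of a cell.

    Coordinates wrap on the torus; the eight cells are distinct for any
    lattice of at least 3x3.
    """
    if not (0 <= x < config.width and 0 <= y < config.height):
        raise ValueError(f"cell ({x}, {y}) outside the {config.width}x{config.height} lattice")
    w, h = config.width, config.height
    direct = [((x + dx) % w, (y + dy) % h) for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1))]
    indirect = [((x + dx) % w, (y + dy) % h) for dx, dy in ((1, 1), (1, -1), (-1, 1), (-1, -1))]
    return direct, indirect


_DIRECT_SHIFTS = ((1, 0), (-1, 0), (0, 1), (0, -1))
_INDIRECT_SHIFTS = ((1, 1), (1, -1), (-1, 1), (-1, -1))


def _class_fractions(state: np.ndarray, shifts) -> np.ndarray:
    """Mutant fraction among the 4 neighbours of each cell, per class."""
    acc = np.zeros(state.shape, dtype=float)
    for dx, dy in shifts:
        acc += np.roll(state, shift=(dx, dy), axis=(0, 1))
    return acc / len(shifts)


def _adopt_probability(q: np.ndarray, beta: float) -> np.ndarray:
    return q + beta * q * (1.0 - q)


def step(
    state: np.ndarray, bias: BiasVector, rng: np.random.Generator, beta: float = 0.0
) -> np.ndarray:
    """One synchronous generation on the torus.

    ``state`` is a boolean (height, width) array, True = mutant.  All
    agents read the previous generation.  Retention keeps the own
    variant; imitation adopts the mutant with probability
    ``q + beta*q*(1-q)`` where q is the mutant fraction in the chosen
    neighbour class (at beta=0, exactly copying one uniform neighbour).
    """
    if state.ndim != 2:
        raise ValueError("state must be a 2-D lattice array")
    if not 0 <= beta <= 1:
        raise ValueError("beta must lie in [0, 1]")
    s = state.astype(bool)
    u = rng.random(s.shape)
    retain = u < bias.b_self
    use_direct = (~retain) & (u < bias.b_self + bias.b_direct)
    use_indirect = ~(retain | use_direct)
    q_dir = _adopt_probability(_class_fractions(s, _DIRECT_SHIFTS), beta)
    q_ind = _adopt_probability(_class_fractions(s, _INDIRECT_SHIFTS), beta)
    draws = rng.random(s.shape)
    new = np.where(
        retain, s, np.where(use_direct, draws < q_dir, draws < q_ind)
    )
    return new.astype(bool)


def step_mean_field(
    state: np.ndarray,
    bias: BiasVector,
    rng: np.random.Generator,
    n_parents: int = 8,
    beta: float = 0.0,
) -> np.ndarray:
    """One synchronous panmictic generation.

    Imitating agents (probability ``1 − b_self``) each draw ``n_parents``
    cultural parents uniformly (with replacement) from the whole
    previous-generation population and adopt the mutant with probability
    ``q + beta*q*(1-q)``, q being the mutant fraction among their
    parents.  The direct/indirect split is irrelevant without structure.
    """
    s = np.asarray(state).astype(bool).ravel()
    n = s.size
    x = s.mean()
    u = rng.random(n)
    retain = u < bias.b_self
    m = rng.binomial(n_parents, x, size=n)
    q = _adopt_probability(m / n_parents, beta)
    new = np.where(retain, s, rng.random(n) < q)
    return new.astype(bool).reshape(np.asarray(state).shape)


def _seed_state(config: LatticeConfig, rng: np.random.Generator) -> np.ndarray:
    state = np.zeros((config.height, config.width), dtype=bool)
    flat = rng.choice(config.n_agents, size=config.seed_count, replace=False)
    state.ravel()[flat] = True
    return state


def _iterate(
    config: LatticeConfig,
    bias: BiasVector,
    rng: np.random.Generator,
    advance,
    record_trajectory: bool,
) -> SimResult:
    state = _seed_state(config, rng)
    n = config.n_agents
    traj = [int(state.sum())] if record_trajectory else None
    gen = 0
    while 0 < state.sum() < n and gen < config.max_generations:
        state = advance(state, rng)
        gen += 1
        if record_trajectory:
            traj.append(int(state.sum()))
    count = int(state.sum())
    if count == 0:
        outcome: Outcome = "extinct"
    elif count == n:
        outcome = "penetrant"
    else:
        outcome = "censored"
    return SimResult(
        outcome=outcome,
        generations=gen,
        final_mutants=count,
        trajectory=tuple(traj) if record_trajectory else None,
    )


def run(
    config: LatticeConfig,
    bias: BiasVector,
    beta: float = 0.0,
    rng: np.random.Generator | None = None,
    record_trajectory: bool = False,
) -> SimResult:
    """Seed mutants uniformly at random and iterate lattice generations.

    Stops at extinction (no mutants), full penetrance (all mutants) or
    the generation cap (censored).
    """
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    return _iterate(
        config, bias, rng, lambda s, r: step(s, bias, r, beta=beta), record_trajectory
    )


def run_mean_field(
    config: LatticeConfig,
    bias: BiasVector,
    beta: float = 0.0,
    rng: np.random.Generator | None = None,
    record_trajectory: bool = False,
) -> SimResult:
    """Identical dynamics with panmictic parent sampling."""
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    return _iterate(
        config,
        bias,
        rng,
        lambda s, r: step_mean_field(s, bias, r, n_parents=config.n_parents, beta=beta),
        record_trajectory,
    )


def ensemble(
    config: LatticeConfig,
    bias: BiasVector,
    n_reps: int,
    beta: float = 0.0,
    mean_field: bool = False,
    quantiles: Sequence[float] = (0.25, 0.5, 0.75),
    keep_results: bool = True,
) -> EnsembleResult:
    """Aggregate independent replicate runs.

    Each replicate uses its own RNG substream spawned from
    ``config.rng_seed``, so the ensemble is reproducible and replicates
    are independent.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    seeds = np.random.SeedSequence(config.rng_seed).spawn(n_reps)
    runner = run_mean_field if mean_field else run
    results = [
        runner(config, bias, beta=beta, rng=np.random.default_rng(ss)) for ss in seeds
    ]
    outcomes = [r.outcome for r in results]
    pen_times = [r.generations for r in results if r.outcome == "penetrant"]
    qdict = {}
    for q in quantiles:
        key = f"q{int(round(100 * q))}"
        qdict[key] = float(np.quantile(pen_times, q)) if pen_times else float("nan")
    return EnsembleResult(
        n_reps=n_reps,
        extinction_fraction=outcomes.count("extinct") / n_reps,
        penetrant_fraction=outcomes.count("penetrant") / n_reps,
        censored_fraction=outcomes.count("censored") / n_reps,
        penetrance_time_quantiles=qdict,
        results=tuple(results) if keep_results else (),
    )
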