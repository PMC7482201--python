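"""Toroidal cultural-transmission simulator against exact small-chain oracles."""

import numpy as np
import pytest

from dunbargraph import (
    BiasVector,
    LatticeConfig,
    ensemble,
    run,
    run_mean_field,
)
from dunbargraph.lattice_sim import neighbours, step, step_mean_field

from _oracles import (
    mean_field_drift,
    poisson_binomial_pmf,
    torus3_node_probs,
)


def test_neighbour_classes_distinct_and_wrapped():
    config = LatticeConfig(width=100, height=100)
    direct, indirect = neighbours(config, 50, 50)
    assert len(direct) == len(indirect) == 4
    assert len(set(direct + indirect)) == 8
    d0, i0 = neighbours(config, 0, 0)
    assert (99, 99) in i0
    assert (99, 0) in d0 and (0, 99) in d0


def test_three_by_three_neighbourhood_covers_lattice():
    config = LatticeConfig(width=3, height=3)
    direct, indirect = neighbours(config, 1, 1)
    assert len(set(direct + indirect)) == 8
    assert (1, 1) not in direct + indirect


def test_tiny_lattice_rejected():
    with pytest.raises(ValueError):
        LatticeConfig(width=2, height=5)


def test_bias_vector_validation():
    with pytest.raises(ValueError):
        BiasVector(0.5, 0.5, 0.5)
    with pytest.raises(ValueError):
        BiasVector(-0.1, 0.6, 0.5)


def test_pure_retention_is_identity(rng):
    state = rng.random((6, 6)) < 0.4
    out = step(state, BiasVector(1.0, 0.0, 0.0), rng)
    assert np.array_equal(out, state)


def test_all_mutant_state_absorbing(rng):
    state = np.ones((5, 5), dtype=bool)
    out = step(state, BiasVector(0.1, 0.6, 0.3), rng)
    assert out.all()
    out_mf = step_mean_field(state, BiasVector(0.1, 0.6, 0.3), rng)
    assert out_mf.all()


def test_one_step_count_distribution_matches_enumeration(rng):
    """On the 3x3 torus with pure direct copying, the one-generation
    mutant-count distribution equals the exact Poisson-binomial law of
    the per-node adoption probabilities."""
    bias = BiasVector(0.0, 1.0, 0.0)
    # fixed two-mutant start state (cells 0 and 4 of the flattened grid)
    state = np.zeros(9, dtype=bool)
    state[[0, 4]] = True
    z = int(sum(1 << i for i in np.flatnonzero(state)))
    node_p = torus3_node_probs((0.0, 1.0, 0.0))[z]
    exact = poisson_binomial_pmf(node_p)

    n_draws = 40_000
    counts = np.zeros(10)
    grid = state.reshape(3, 3)
    for _ in range(n_draws):
        counts[int(step(grid, bias, rng).sum())] += 1
    observed = counts / n_draws
    se = np.sqrt(exact * (1 - exact) / n_draws)
    assert np.all(np.abs(observed - exact) <= 4 * se + 1e-4)


def test_full_seeding_is_immediately_penetrant():
    config = LatticeConfig(width=4, height=4, seed_count=16, rng_seed=1)
    res = run(config, BiasVector(0.2, 0.6, 0.2))
    assert res.outcome == "penetrant" and res.generations == 0
    res_mf = run_mean_field(config, BiasVector(0.2, 0.6, 0.2))
    assert res_mf.outcome == "penetrant" and res_mf.generations == 0


def test_pure_retention_run_is_censored():
    config = LatticeConfig(width=4, height=4, seed_count=1, max_generations=20, rng_seed=2)
    res = run(config, BiasVector(1.0, 0.0, 0.0), record_trajectory=True)
    assert res.outcome == "censored"
    assert res.trajectory == (1,) * 21


def test_mean_field_neutral_copying_is_martingale(rng):
    """Unbiased copying leaves the expected mutant fraction unchanged."""
    n = 400
    x0 = 0.3
    state = np.zeros(n, dtype=bool)
    state[:120] = True
    after = [
        step_mean_field(state, BiasVector(0.4, 0.4, 0.2), rng, n_parents=8).mean()
        for _ in range(3000)
    ]
    se = np.std(after) / np.sqrt(len(after))
    assert abs(np.mean(after) - x0) < 4 * se + 1e-4


def test_mean_field_trajectory_tracks_drift_recursion(rng):
    """With a directional bias the mean trajectory follows the exact
    one-step drift recursion for the first generations."""
    bias = BiasVector(0.2, 0.5, 0.3)
    beta, n_parents, n, gens, reps = 0.5, 8, 100, 5, 1000
    start = np.zeros(n, dtype=bool)
    start[:10] = True
    # conditional check: E[x_{t+1} | x_t] = drift(x_t) exactly, so the
    # mean one-step residual over replicates is zero up to MC error
    residuals = np.zeros(gens)
    for _ in range(reps):
        s = start.copy()
        for g in range(gens):
            predicted = mean_field_drift(s.mean(), bias.b_self, beta, n_parents)
            s = step_mean_field(s, bias, rng, n_parents=n_parents, beta=beta)
            residuals[g] += s.mean() - predicted
    residuals /= reps
    # per-generation sd of x_{t+1} is < 0.06, so MC se < 0.002
    assert np.all(np.abs(residuals) < 0.006)


def test_ensemble_aggregates_and_reproducibility():
    config = LatticeConfig(width=4, height=4, seed_count=16, max_generations=10, rng_seed=7)
    res = ensemble(config, BiasVector(0.2, 0.6, 0.2), n_reps=10)
    assert res.penetrant_fraction == 1.0
    assert res.penetrance_time_quantiles["q50"] == 0.0
    config2 = LatticeConfig(width=5, height=5, seed_count=2, max_generations=50, rng_seed=11)
    a = ensemble(config2, BiasVector(0.1, 0.5, 0.4), n_reps=20, keep_results=True)
    b = ensemble(config2, BiasVector(0.1, 0.5, 0.4), n_reps=20, keep_results=True)
    assert [r.generations for r in a.results] == [r.generations for r in b.results]
    assert a.extinction_fraction + a.penetrant_fraction + a.censored_fraction == pytest.approx(1.0)


def test_pure_retention_ensemble_all_censored():
    config = LatticeConfig(width=3, height=3, seed_count=1, max_generations=5, rng_seed=0)
    res = ensemble(config, BiasVector(1.0, 0.0, 0.0), n_reps=5)
    assert res.extinction_fraction == 0.0
    assert res.censored_fraction == 1.0
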