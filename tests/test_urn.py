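"""Layer-allocation urn model: probabilities, pmf, shape transition."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dunbargraph import (
    AllocationModel,
    allocation_pmf,
    classify_shape,
    expected_occupancy,
    layer_probs,
)


def compositions(total, parts):
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in compositions(total - first, parts - 1):
            yield (first, *rest)


def test_uniform_at_mu_zero():
    model = AllocationModel(s=(1, 2, 3, 4), mu=0.0, L=100)
    assert layer_probs(model) == pytest.approx([0.25] * 4)


def test_two_layer_closed_form():
    model = AllocationModel(s=(1, 2), mu=math.log(2), L=10)
    assert layer_probs(model) == pytest.approx([2 / 3, 1 / 3])


def test_negative_mu_reverses_order():
    model = AllocationModel(s=(1, 2, 3, 4), mu=-0.7, L=10)
    p = layer_probs(model)
    assert np.all(np.diff(p) > 0)


@given(st.floats(-5, 5), st.floats(-100, 100))
def test_shift_invariance_of_layer_probs(mu, shift):
    base = AllocationModel(s=(1.0, 2.5, 4.0), mu=mu)
    shifted = AllocationModel(s=(1.0 + shift, 2.5 + shift, 4.0 + shift), mu=mu)
    assert layer_probs(shifted) == pytest.approx(layer_probs(base), abs=1e-12)


def test_extreme_mu_is_numerically_stable():
    p = layer_probs(AllocationModel(s=(1, 2, 3), mu=500.0))
    assert np.all(np.isfinite(p)) and p.sum() == pytest.approx(1.0)
    assert p[0] == pytest.approx(1.0)


@pytest.mark.parametrize("L,r,mu", [(3, 3, 0.0), (4, 2, 0.8), (6, 4, -0.5), (5, 3, 1.7)])
def test_pmf_normalizes_over_all_compositions(L, r, mu):
    model = AllocationModel(s=tuple(range(1, r + 1)), mu=mu, L=L)
    total = sum(allocation_pmf(model, c) for c in compositions(L, r))
    assert total == pytest.approx(1.0)


def test_small_enumeration_at_mu_zero():
    model = AllocationModel(s=(1, 2), mu=0.0, L=2)
    assert allocation_pmf(model, (2, 0)) == pytest.approx(0.25)
    assert allocation_pmf(model, (1, 1)) == pytest.approx(0.5)
    assert allocation_pmf(model, (0, 2)) == pytest.approx(0.25)


def test_empty_network_pmf():
    model = AllocationModel(s=(1, 2, 3), mu=1.0, L=0)
    assert allocation_pmf(model, (0, 0, 0)) == 1.0


def test_pmf_rejects_wrong_total():
    model = AllocationModel(s=(1, 2), mu=0.0, L=3)
    with pytest.raises(ValueError):
        allocation_pmf(model, (1, 1))


def test_expected_occupancy_uniform():
    model = AllocationModel(s=(1, 2, 3, 4, 5), mu=0.0, L=150)
    assert expected_occupancy(model) == pytest.approx([30.0] * 5)


def test_expected_occupancy_matches_multinomial_sampling(rng):
    model = AllocationModel(s=(1, 2, 3), mu=0.6, L=50)
    p = layer_probs(model)
    draws = rng.multinomial(model.L, p, size=100_000)
    mean = draws.mean(axis=0)
    se = np.sqrt(model.L * p * (1 - p) / 100_000)
    assert np.all(np.abs(mean - expected_occupancy(model)) < 3 * se + 1e-9)


@pytest.mark.parametrize("s", [(1, 2, 3, 4), (0.5, 1.7, 2.0), (1, 4, 9, 16, 25)])
def test_shape_flips_exactly_at_mu_zero(s):
    assert classify_shape(AllocationModel(s=s, mu=1e-6)) == "convex"
    assert classify_shape(AllocationModel(s=s, mu=-1e-6)) == "concave"
    assert classify_shape(AllocationModel(s=s, mu=0.0)) == "degenerate"


def test_conventional_and_inverted_shapes():
    assert classify_shape(AllocationModel(s=(1, 2, 3, 4), mu=1.0)) == "convex"
    assert classify_shape(AllocationModel(s=(1, 2, 3, 4), mu=-1.0)) == "concave"


def test_shape_requires_monotone_costs():
    with pytest.raises(ValueError):
        classify_shape(AllocationModel(s=(1, 3, 2), mu=1.0))
    with pytest.raises(ValueError):
        classify_shape(AllocationModel(s=(1, 2), mu=1.0))


def test_monotonicity_of_probs_in_cost():
    p_pos = layer_probs(AllocationModel(s=(1, 2, 3, 4), mu=0.9))
    p_neg = layer_probs(AllocationModel(s=(1, 2, 3, 4), mu=-0.9))
    assert np.all(np.diff(p_pos) < 0)
    assert np.all(np.diff(p_neg) > 0)


def test_model_validation():
    with pytest.raises(ValueError):
        AllocationModel(s=(), mu=0.0)
    with pytest.raises(ValueError):
        AllocationModel(s=(1, 2), mu=0.0, L=10, N=5)
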