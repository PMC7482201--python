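"""Layer-scheme containers and descriptive statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dunbargraph import (
    EffortProfile,
    GroupSizeTable,
    LayerScheme,
    cumulative_effort,
    cumulative_to_annuli,
    default_effort_profile,
    mean_scaling_ratio,
    scaling_ratios,
    summarize_group_sizes,
)
from dunbargraph import datasets


increasing_sizes = st.lists(
    st.floats(0.1, 1e6, allow_nan=False), min_size=1, max_size=10, unique=True
).map(sorted)


@pytest.mark.parametrize(
    "cumulative, expected",
    [
        ([5, 15, 50, 150], [5, 10, 35, 100]),
        ([2.9, 7.4, 17.7, 43.0, 134.3], [2.9, 4.5, 10.3, 25.3, 91.3]),
        ([7], [7]),
    ],
)
def test_cumulative_to_annuli(cumulative, expected):
    annuli = cumulative_to_annuli(LayerScheme(tuple(cumulative)))
    assert annuli == pytest.approx(expected)


@given(increasing_sizes)
def test_annuli_sum_to_outermost_size(sizes):
    scheme = LayerScheme(tuple(sizes))
    annuli = cumulative_to_annuli(scheme)
    assert len(annuli) == scheme.n_layers
    assert sum(annuli) == pytest.approx(sizes[-1])


def test_non_increasing_sizes_rejected():
    with pytest.raises(ValueError):
        LayerScheme((5, 5, 50))
    with pytest.raises(ValueError):
        LayerScheme((15, 5))
    with pytest.raises(ValueError):
        LayerScheme(())


@given(st.floats(1.5, 10), st.integers(2, 8), st.floats(0.5, 100))
def test_geometric_scheme_has_constant_ratio(r, n, base):
    sizes = tuple(base * r**i for i in range(n))
    ratios = scaling_ratios(LayerScheme(sizes))
    assert ratios == pytest.approx([r] * (n - 1))
    assert mean_scaling_ratio(LayerScheme(sizes)) == pytest.approx(r)


@pytest.mark.parametrize(
    "dataset, expected_1dp",
    [
        ("personal_network_average", 3.0),
        ("multilevel_mammals", 2.5),
        ("primate_group_sizes", 2.2),
    ],
)
def test_published_layer_rows_scaling_ratio(dataset, expected_1dp):
    scheme = LayerScheme(datasets.LAYER_SIZE_ROWS[dataset])
    assert round(mean_scaling_ratio(scheme), 1) == expected_1dp


def test_single_layer_has_no_ratios():
    with pytest.raises(ValueError):
        scaling_ratios(LayerScheme((7,)))


def test_effort_sixty_percent_to_inner_fifteen(four_layer_scheme):
    profile = EffortProfile((0.40, 0.20, 0.25, 0.15))
    assert cumulative_effort(profile, four_layer_scheme, 1) == pytest.approx(0.60)
    assert cumulative_effort(profile, four_layer_scheme, 3) == pytest.approx(1.0)


def test_uniform_effort_shares(four_layer_scheme):
    profile = EffortProfile((0.25,) * 4)
    assert cumulative_effort(profile, four_layer_scheme, 0) == pytest.approx(0.25)


def test_cumulative_effort_nondecreasing(canonical_scheme):
    profile = default_effort_profile(canonical_scheme)
    values = [
        cumulative_effort(profile, canonical_scheme, i)
        for i in range(canonical_scheme.n_layers)
    ]
    assert all(b >= a for a, b in zip(values, values[1:]))
    assert values[-1] == pytest.approx(1.0)
    assert values[1] == pytest.approx(0.60, abs=1e-9)


def test_default_effort_profile_decays_per_capita(canonical_scheme):
    profile = default_effort_profile(canonical_scheme)
    per_capita = np.asarray(profile.annulus_shares) / np.asarray(
        cumulative_to_annuli(canonical_scheme)
    )
    assert np.all(np.diff(per_capita) < 0)


def test_effort_profile_must_normalize():
    with pytest.raises(ValueError):
        EffortProfile((0.5, 0.4))
    with pytest.raises(ValueError):
        cumulative_effort(EffortProfile((1.0,)), LayerScheme((5, 15)), 0)
    with pytest.raises(IndexError):
        cumulative_effort(EffortProfile((0.6, 0.4)), LayerScheme((5, 15)), 2)


def test_community_size_summary_midpoint():
    mean, sd = summarize_group_sizes(datasets.community_size_table())
    assert round(mean, 1) == 158.0
    assert round(sd, 1) == 28.7


def test_range_policies_shift_the_mean():
    table = GroupSizeTable((("a", 100), ("b", (100, 200))))
    assert summarize_group_sizes(table, "low")[0] == pytest.approx(100.0)
    assert summarize_group_sizes(table, "midpoint")[0] == pytest.approx(125.0)
    assert summarize_group_sizes(table, "high")[0] == pytest.approx(150.0)


def test_identical_sizes_have_zero_sd():
    table = GroupSizeTable((("a", 150), ("b", 150), ("c", 150)))
    assert summarize_group_sizes(table)[1] == 0.0


def test_empty_or_singleton_table_rejected():
    with pytest.raises(ValueError):
        summarize_group_sizes(GroupSizeTable(()))
    with pytest.raises(ValueError):
        GroupSizeTable((("bad", (200, 100)),))


def test_scheme_json_roundtrip(four_layer_scheme):
    again = LayerScheme.from_dict(four_layer_scheme.to_dict())
    assert again.cumulative_sizes == four_layer_scheme.cumulative_sizes
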