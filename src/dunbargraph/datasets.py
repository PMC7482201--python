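"""Published layer-size and grouping-size tables bundled as inputs.

These are the printed summary rows from the comparative literature on
layered social organisation: mean cumulative layer sizes per dataset
(personal networks, top-down community structure, multilevel mammal
societies and primate group sizes) and estimates of natural human
grouping sizes.  They are inputs for the descriptive statistics in
:mod:`dunbargraph.layer_model`, not outputs of this package.
"""

from __future__ import annotations

from .layer_model import GroupSizeTable, LayerScheme

__all__ = [
    "LAYER_SIZE_ROWS",
    "personal_network_average",
    "community_structure_average",
    "multilevel_mammal_layers",
    "primate_group_sizes",
    "community_size_table",
    "egocentric_network_size_table",
]

#: Mean cumulative layer sizes per source dataset (inner to outer).
LAYER_SIZE_ROWS: dict[str, tuple[float, ...]] = {
    # personal (egocentric) networks
    "cellphone_europe_call_frequency": (2.9, 7.4, 17.7, 43.0, 134.3),
    "cellphone_china": (2.1, 7.3, 20.4, 54.2, 141.4),
    "facebook_1": (1.7, 5.3, 14.9, 40.9),
    "facebook_2": (1.5, 4.3, 10.7, 27.0),
    "coauthor_networks": (2.0, 6.3, 15.8, 37.9, 116.8),
    "personal_network_average": (2.0, 5.8, 15.8, 34.6, 148.3),
    # top-down community structure
    "hunter_gatherer_2": (4.5, 15.6, 53.5, 165.7, 837.1),
    "communities_of_practice": (4.0, 11.0, 30.2, 112.2, 389.0, 1737.8),
    "twitter_communities": (1.6, 4.5, 11.2, 28.3, 88.3),
    "community_structure_average": (1.6, 4.6, 12.8, 45.5, 154.4, 369.5, 1350.4),
    # comparative
    "multilevel_mammals": (3.1, 6.9, 19.8, 47.3),
    "primate_group_sizes": (2.3, 6.2, 15.6, 31.3, 53.1),
}


def _scheme(key: str) -> LayerScheme:
    return LayerScheme(LAYER_SIZE_ROWS[key], label=key)


def personal_network_average() -> LayerScheme:
    """Average cumulative layer sizes over personal-network datasets."""
    return _scheme("personal_network_average")


def community_structure_average() -> LayerScheme:
    """Average cumulative layer sizes over community-structure datasets
    (military unit series excluded from the published average)."""
    return _scheme("community_structure_average")


def multilevel_mammal_layers() -> LayerScheme:
    """Mean layer sizes of multilevel mammal societies (elephant, orca,
    gelada, hamadryas baboon)."""
    return _scheme("multilevel_mammals")


def primate_group_sizes() -> LayerScheme:
    """Clustered mean group sizes across 215 primate species."""
    return _scheme("primate_group_sizes")


#: Published community-size estimates; ranges stay as (low, high) pairs.
_COMMUNITY_ROWS: tuple[tuple[str, float | tuple[float, float]], ...] = (
    ("Domesday Book village size", 150),
    ("C18th English villages", 160),
    ("Italian alpine communities", 176),
    ("tribal societies", 148),
    ("hunter-gatherer clans", 165),
    ("E. Tennessee rural community", 197),
    ("Hutterite farming communities", 107),
    ("'Nebraska' Amish parishes", 113),
    ("church congregations (ideal)", 200),
    ("WW2 army company", 180),
    ("academic research specialities", (100, 200)),
    ("Twitter networks", (100, 200)),
)

#: Published egocentric network-size estimates.  The printed average for
#: this block (153.6) is not reproducible from these rows under any
#: simple range convention; it is kept for reference only.
_EGOCENTRIC_ROWS: tuple[tuple[str, float | tuple[float, float]], ...] = (
    ("small world experiments", 134),
    ("Christmas card distribution list", 153.5),
    ("women's egocentric networks", 171.8),
    ("egocentric network survey", 174.9),
    ("cellphone calling network (Europe)", 134.3),
    ("cellphone calling network (China)", 141.4),
    ("US wedding guest lists", 143.7),
    ("e-mail networks", 250),
    ("Facebook friends (mode)", (150, 250)),
    ("Facebook friends (UK)", 169),
    ("co-author networks", 116.8),
)


def community_size_table() -> GroupSizeTable:
    """The twelve published community-size estimates."""
    return GroupSizeTable(_COMMUNITY_ROWS)


def egocentric_network_size_table() -> GroupSizeTable:
    """The eleven published egocentric network-size estimates."""
    return GroupSizeTable(_EGOCENTRIC_ROWS)
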