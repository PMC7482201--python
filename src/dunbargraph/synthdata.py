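"""Synthetic egocentric contact data and demo community graphs.

The ego-contact generator emulates the statistical signature of layered
contact-rate data: alters fall into annuli of configurable cumulative
size, per-alter contact rates drop by a constant factor per layer
(default 3, mirroring the empirical layer-size scaling ratio), and rates
are jittered by log-normal noise (log10 scale).  The generator is
bit-reproducible under a fixed seed, and a generate-then-detect loop
recovers the configured layer count.

The community-graph generator builds a small weighted graph in which
every node carries an ego-layer structure; it is a demo substrate for
diffusion experiments, not a fitted model of any empirical network.
"""

from __future__ import annotations

from dataclasses import dataclass
import networkx as nx
import numpy as np

from .layer_detect import ContactTable
from .layer_model import (
    EffortProfile,
    LayerScheme,
    cumulative_to_annuli,
    default_effort_profile,
)

__all__ = ["EgoGeneratorConfig", "gen_ego_contacts", "gen_community_graph"]


@dataclass(frozen=True)
class EgoGeneratorConfig:
    """Layered contact-rate generator settings.

    ``rate_innermost`` is the mean contact rate (events/day) of the
    innermost annulus; successive layers divide it by
    ``layer_rate_ratio``; ``log10_noise_sd`` jitters each alter's rate
    on the log10 scale.
    """

    cumulative_sizes: tuple[float, ...] = (5, 15, 50, 150)
    rate_innermost: float = 1.0
    layer_rate_ratio: float = 3.0
    log10_noise_sd: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        LayerScheme(self.cumulative_sizes)  # validates monotonicity
        if self.rate_innermost <= 0:
            raise ValueError("rate_innermost must be positive")
        if self.layer_rate_ratio < 1:
            raise ValueError("layer_rate_ratio must be >= 1")
        if self.log10_noise_sd < 0:
            raise ValueError("log10_noise_sd must be >= 0")

    @property
    def scheme(self) -> LayerScheme:
        return LayerScheme(self.cumulative_sizes, label="generator")


def gen_ego_contacts(config: EgoGeneratorConfig) -> ContactTable:
    """Generate one ego's contact table with geometric layer structure.

    Layer ``j`` (0-based, innermost first) contributes annulus-many
    alters at base rate ``rate_innermost / layer_rate_ratio**j``, each
    multiplied by ``10**eps`` with ``eps ~ Normal(0, log10_noise_sd)``.
    """
    rng = np.random.default_rng(config.rng_seed)
    annuli = [int(round(a)) for a in cumulative_to_annuli(config.scheme)]
    rates: list[float] = []
    for j, count in enumerate(annuli):
        base = config.rate_innermost / config.layer_rate_ratio**j
        noise = rng.normal(0.0, config.log10_noise_sd, size=count)
        rates.extend((base * 10.0**noise).tolist())
    ids = tuple(f"alter_{i:04d}" for i in range(len(rates)))
    return ContactTable(alter_ids=ids, contact_rates=tuple(rates))


def gen_community_graph(
    n: int = 150,
    scheme: LayerScheme | None = None,
    tie_weight_profile: EffortProfile | None = None,
    rng_seed: int = 0,
) -> nx.Graph:
    """Small weighted community graph with per-node layer structure.

    Nodes are placed on a ring (a stand-in for social distance) and each
    pair is assigned to a layer by its ring distance, so both endpoints
    agree on the tie's layer; the edge weight is the layer's per-capita
    effort share.  Only pairs within the outermost layer are connected,
    and the ring ordering keeps the graph connected by construction.
    """
    scheme = LayerScheme((5, 15, 50, 150)) if scheme is None else scheme
    if n < scheme.cumulative_sizes[0]:
        raise ValueError("community must be at least as large as the innermost layer")
    profile = (
        default_effort_profile(scheme) if tie_weight_profile is None else tie_weight_profile
    )
    annuli = np.asarray(cumulative_to_annuli(scheme))
    per_capita = np.asarray(profile.annulus_shares) / annuli
    rng = np.random.default_rng(rng_seed)
    pos = rng.permutation(n)  # random placement on the ring

    # A node's two ring-neighbours at distance d occupy closeness ranks
    # 2(d-1) and 2(d-1)+1; the pair's layer is read off the earlier rank
    # so both endpoints agree and edge weights are symmetric by
    # construction.  Odd layer boundaries therefore round up by one.
    outer = min(int(scheme.cumulative_sizes[-1]), n - 1)
    boundaries = [min(int(c), n - 1) for c in scheme.cumulative_sizes]

    def layer_of(rank: int) -> int:
        for j, c in enumerate(boundaries):
            if rank < c:
                return j
        return len(boundaries) - 1

    g = nx.Graph()
    g.add_nodes_from(range(n))
    for u in range(n):
        for v in range(u + 1, n):
            delta = abs(int(pos[u]) - int(pos[v]))
            d = min(delta, n - delta)
            rank = 2 * (d - 1)
            if rank >= outer:
                continue
            g.add_edge(u, v, weight=float(per_capita[layer_of(rank)]))
    return g
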