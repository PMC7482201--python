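"""Bayesian urn model of layer allocation under a resource constraint.

Each of Ego's L relationships is assigned to one of r layers; a
relationship in layer k costs s_k units of the limited social resource
(time).  Maximum-entropy allocation under the total-resource constraint
gives each relationship an independent layer distribution

    p_k = exp(-mu * s_k) / sum_j exp(-mu * s_j),

with mu the Lagrange multiplier of the resource constraint, so that
conditional on L the occupancy vector (l_1, ..., l_r) is multinomial.
The sign of mu controls the network's shape: mu > 0 yields the
conventional few-expensive/many-cheap structure, mu < 0 the inverted
structure, with a phase transition exactly at mu = 0.  The prior over L
itself (the B(L, L/N, N) prefactor) is not modelled; every operation
here conditions on L.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.stats import multinomial

__all__ = [
    "AllocationModel",
    "layer_probs",
    "allocation_pmf",
    "expected_occupancy",
    "classify_shape",
]


@dataclass(frozen=True)
class AllocationModel:
    """Cost schedule and constraint parameters of the layer-allocation urn.

    ``s`` is the per-relationship cost (time investment) of each of the
    r layers; ``mu`` the Lagrange multiplier of the resource constraint;
    ``L`` the total network size; ``N`` the available population.  The
    total budget ``S`` enters only through ``mu`` and is informational.
    """

    s: tuple[float, ...]
    mu: float = 1.0
    L: int = 150
    N: int | None = None
    S: float | None = None

    def __post_init__(self) -> None:
        s = tuple(float(v) for v in self.s)
        if len(s) == 0:
            raise ValueError("cost schedule must have at least one layer")
        if any(not np.isfinite(v) for v in s):
            raise ValueError("layer costs must be finite")
        if not np.isfinite(self.mu):
            raise ValueError("mu must be finite")
        if self.L < 0:
            raise ValueError("network size L must be >= 0")
        if self.N is not None and self.N < self.L:
            raise ValueError("population N must be at least L")
        object.__setattr__(self, "s", s)

    @property
    def n_layers(self) -> int:
        return len(self.s)


def layer_probs(model: AllocationModel) -> np.ndarray:
    """Per-relationship layer probabilities p_k ∝ exp(−mu·s_k).

    Computed with a max-shifted exponent for stability at large
    ``|mu·s|``; invariant to adding a constant to all costs.
    """
    z = -model.mu * np.asarray(model.s)
    z -= z.max()
    w = np.exp(z)
    return w / w.sum()


def allocation_pmf(model: AllocationModel, occupancy: Sequence[int]) -> float:
    """Probability of an occupancy vector, conditional on network size L.

    Conditional on L the urn is exactly multinomial(L; p) with p from
    :func:`layer_probs`; evaluated in log space.
    """
    ell = np.asarray(occupancy)
    if ell.shape != (model.n_layers,):
        raise ValueError(f"occupancy must have one entry per layer ({model.n_layers})")
    if np.any(ell < 0) or not np.all(ell == np.round(ell)):
        raise ValueError("occupancies must be nonnegative integers")
    if int(ell.sum()) != model.L:
        raise ValueError(f"occupancies must sum to L={model.L}, got {int(ell.sum())}")
    if model.L == 0:
        return 1.0
    p = layer_probs(model)
    return float(np.exp(multinomial.logpmf(ell, n=model.L, p=p)))


def expected_occupancy(model: AllocationModel) -> np.ndarray:
    """Expected alters per layer, L·p_k."""
    return model.L * layer_probs(model)


Shape = Literal["concave", "convex", "degenerate"]


def classify_shape(model: AllocationModel, atol: float = 1e-12) -> Shape:
    """Shape of the cumulative occupancy curve across cost-ranked layers.

    Layers are ranked from most to least costly and the expected
    cumulative proportional occupancy is accumulated along that ranking.
    Conventional networks (mu > 0) place few alters in costly layers and
    many in cheap ones, so the curve starts shallow and steepens:
    convex.  Inverted networks (mu < 0) load the costly layers, giving a
    concave curve.  At mu = 0 occupancy is uniform and the curve is
    linear ("degenerate").  The classification flips exactly at mu = 0
    for any strictly monotone cost schedule.
    """
    if model.n_layers < 3:
        raise ValueError("shape classification needs at least three layers")
    s = np.asarray(model.s)
    diffs = np.diff(s)
    if np.all(diffs > 0):
        order = np.argsort(-s)  # most costly first
    elif np.all(diffs < 0):
        order = np.argsort(-s)
    else:
        raise ValueError("cost schedule must be strictly monotone to classify shape")
    p = layer_probs(model)[order]
    cumulative = np.cumsum(p)
    second = np.diff(cumulative, n=2)
    if np.all(np.abs(second) <= atol):
        return "degenerate"
    if np.all(second >= -atol):
        return "convex"
    if np.all(second <= atol):
        return "concave"
    # mixed curvature cannot arise from a monotone softmax, but guard anyway
    raise ValueError("cumulative occupancy curve has mixed curvature")
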