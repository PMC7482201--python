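"""Layered egocentric network structure and its descriptive statistics.

An egocentric ("Dunbar graph") network is a set of nested layers of
cumulative size roughly 5, 15, 50, 150 (and, including weaker ties,
500, 1500 and 5000): contact frequency and emotional closeness decline
from the innermost layer outward.  The members of a layer that do not
belong to any inner layer form its *annulus* (the 50-layer annulus holds
35 alters).  This module holds the layer-scheme container and the
descriptive statistics built on it: annulus sizes, successive scaling
ratios, cumulative social-effort shares and grouping-size summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "CANONICAL_CUMULATIVE_SIZES",
    "LayerScheme",
    "EffortProfile",
    "GroupSizeTable",
    "cumulative_to_annuli",
    "scaling_ratios",
    "mean_scaling_ratio",
    "cumulative_effort",
    "summarize_group_sizes",
    "default_effort_profile",
]

#: Canonical cumulative layer sizes of a full human egocentric network.
CANONICAL_CUMULATIVE_SIZES: tuple[float, ...] = (5, 15, 50, 150, 500, 1500, 5000)


@dataclass(frozen=True)
class LayerScheme:
    """Cumulative layer sizes of an egocentric network, inner to outer.

    Parameters
    ----------
    cumulative_sizes
        Strictly increasing positive layer sizes, innermost first.
        Layer ``i`` *contains* all inner layers, so sizes are cumulative.
    label
        Free-text description of where the scheme comes from.
    """

    cumulative_sizes: tuple[float, ...] = CANONICAL_CUMULATIVE_SIZES
    label: str = ""

    def __post_init__(self) -> None:
        sizes = tuple(float(s) for s in self.cumulative_sizes)
        if len(sizes) == 0:
            raise ValueError("a layer scheme needs at least one layer")
        if any(not np.isfinite(s) or s <= 0 for s in sizes):
            raise ValueError("cumulative layer sizes must be positive and finite")
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError(f"cumulative layer sizes must be strictly increasing, got {sizes}")
        object.__setattr__(self, "cumulative_sizes", sizes)

    @property
    def n_layers(self) -> int:
        return len(self.cumulative_sizes)

    def annuli(self) -> list[float]:
        """Per-annulus member counts (layer minus all inner layers)."""
        return cumulative_to_annuli(self)

    def to_dict(self) -> dict:
        return {"cumulative_sizes": list(self.cumulative_sizes), "label": self.label}

    @classmethod
    def from_dict(cls, d: dict) -> "LayerScheme":
        return cls(tuple(d["cumulative_sizes"]), d.get("label", ""))


@dataclass(frozen=True)
class EffortProfile:
    """Fraction of total social effort directed to each annulus.

    Empirically about 40% of social time goes to the innermost 5 alters
    and a further 20% to the next 10, so 60% of effort reaches only 15
    people; shares must sum to one.
    """

    annulus_shares: tuple[float, ...]

    def __post_init__(self) -> None:
        shares = tuple(float(s) for s in self.annulus_shares)
        if len(shares) == 0:
            raise ValueError("effort profile must have at least one share")
        if any(s < 0 or s > 1 for s in shares):
            raise ValueError("effort shares must lie in [0, 1]")
        if abs(sum(shares) - 1.0) > 1e-9:
            raise ValueError(f"effort shares must sum to 1, got {sum(shares)!r}")
        object.__setattr__(self, "annulus_shares", shares)

    def to_dict(self) -> dict:
        return {"annulus_shares": list(self.annulus_shares)}

    @classmethod
    def from_dict(cls, d: dict) -> "EffortProfile":
        return cls(tuple(d["annulus_shares"]))


@dataclass(frozen=True)
class GroupSizeTable:
    """Rows of (label, size estimate) where a size may be an (low, high) range."""

    rows: tuple[tuple[str, float | tuple[float, float]], ...]

    def __post_init__(self) -> None:
        rows = []
        for label, size in self.rows:
            if isinstance(size, (tuple, list)):
                low, high = float(size[0]), float(size[1])
                if not (0 < low < high):
                    raise ValueError(f"range for {label!r} must satisfy 0 < low < high")
                rows.append((str(label), (low, high)))
            else:
                size = float(size)
                if size <= 0:
                    raise ValueError(f"size for {label!r} must be positive")
                rows.append((str(label), size))
        object.__setattr__(self, "rows", tuple(rows))

    def __len__(self) -> int:
        return len(self.rows)


def cumulative_to_annuli(scheme: LayerScheme) -> list[float]:
    """Convert cumulative layer sizes to per-annulus member counts.

    The first annulus equals the innermost layer; annulus ``i`` is the
    difference of successive cumulative sizes.  Annuli sum back to the
    outermost cumulative size.

    >>> cumulative_to_annuli(LayerScheme((5, 15, 50, 150)))
    [5.0, 10.0, 35.0, 100.0]
    """
    sizes = np.asarray(scheme.cumulative_sizes, dtype=float)
    return [float(sizes[0]), *np.diff(sizes).tolist()]


def scaling_ratios(scheme: LayerScheme) -> list[float]:
    """Successive ratios of cumulative layer sizes (outer / inner).

    Human egocentric layers scale by a remarkably constant factor of
    about three: each layer is roughly three times the size of the layer
    immediately inside it.
    """
    if scheme.n_layers < 2:
        raise ValueError("scaling ratios require at least two layers")
    sizes = np.asarray(scheme.cumulative_sizes, dtype=float)
    return (sizes[1:] / sizes[:-1]).tolist()


def mean_scaling_ratio(scheme: LayerScheme) -> float:
    """Arithmetic mean of the successive layer-size ratios."""
    return float(np.mean(scaling_ratios(scheme)))


def cumulative_effort(profile: EffortProfile, scheme: LayerScheme, upto_layer: int) -> float:
    """Total effort share reaching alters up to (and including) a layer.

    ``upto_layer`` is a zero-based layer index.  With the default 40%/20%
    inner shares, the cumulative effort at layer index 1 (the 15-layer)
    is 0.60: sixty percent of social time is devoted to just 15 people.
    """
    if len(profile.annulus_shares) != scheme.n_layers:
        raise ValueError(
            f"profile has {len(profile.annulus_shares)} shares but the scheme "
            f"has {scheme.n_layers} annuli"
        )
    if not 0 <= upto_layer < scheme.n_layers:
        raise IndexError(f"layer index {upto_layer} out of range 0..{scheme.n_layers - 1}")
    return float(sum(profile.annulus_shares[: upto_layer + 1]))


RangePolicy = Literal["midpoint", "low", "high"]


def _resolve_size(size: float | tuple[float, float], policy: RangePolicy) -> float:
    if isinstance(size, tuple):
        low, high = size
        if policy == "midpoint":
            return 0.5 * (low + high)
        if policy == "low":
            return low
        if policy == "high":
            return high
        raise ValueError(f"unknown range policy {policy!r}")
    return size


def summarize_group_sizes(
    table: GroupSizeTable, range_policy: RangePolicy = "midpoint"
) -> tuple[float, float]:
    """Mean and sample (n-1) standard deviation of grouping sizes.

    Sizes given as ranges ("100-200") are resolved per ``range_policy``
    before averaging; the default takes the midpoint.
    """
    if len(table) == 0:
        raise ValueError("cannot summarize an empty group-size table")
    if len(table) < 2:
        raise ValueError("need at least two rows for a sample standard deviation")
    values = np.array([_resolve_size(size, range_policy) for _, size in table.rows])
    return float(values.mean()), float(values.std(ddof=1))


def default_effort_profile(scheme: LayerScheme) -> EffortProfile:
    """Default effort shares: 40%/20% to the two inner annuli, remainder outward.

    The two innermost annuli receive the empirical 40% and 20% shares.
    The remaining 40% is spread over the outer annuli with per-capita
    effort decaying geometrically from the second annulus's per-capita
    level; the decay factor is solved so the shares sum to one.  For a
    scheme with fewer than three layers the known shares are truncated
    and renormalized.
    """
    from scipy.optimize import brentq

    annuli = np.asarray(cumulative_to_annuli(scheme), dtype=float)
    r = len(annuli)
    if r == 1:
        return EffortProfile((1.0,))
    if r == 2:
        return EffortProfile((0.40 / 0.60, 0.20 / 0.60))
    inner = np.array([0.40, 0.20])
    remainder = 1.0 - inner.sum()
    per_capita_2 = inner[1] / annuli[1]

    def excess(f: float) -> float:
        shares = annuli[2:] * per_capita_2 * f ** np.arange(1, r - 1)
        return shares.sum() - remainder

    # per-capita effort must keep decaying outward, so f is in (0, 1)
    if excess(1.0 - 1e-12) < 0:
        # outer annuli too small to absorb the remainder at decaying
        # per-capita effort: fall back to flat per-capita outer shares
        outer = annuli[2:] * per_capita_2
        shares = np.concatenate([inner, outer])
        return EffortProfile(tuple((shares / shares.sum()).tolist()))
    factor = brentq(excess, 1e-9, 1.0 - 1e-12)
    outer = annuli[2:] * per_capita_2 * factor ** np.arange(1, r - 1)
    shares = np.concatenate([inner, outer])
    shares = shares / shares.sum()
    return EffortProfile(tuple(shares.tolist()))
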