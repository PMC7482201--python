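"""Layer detection in scalar contact-rate data.

Egocentric layer structure is detected the way the large cellphone,
Facebook and co-author analyses detect it: the per-alter contact rates
are partitioned into contiguous classes on the (log) rate scale by Jenks
natural breaks — the globally optimal contiguous partition minimizing
within-class squared deviation, which for one-dimensional data coincides
with the exact k-means optimum — and the number of layers is chosen by
maximizing the mean silhouette over a candidate range.

The dynamic program is exact and deterministic (O(k·n²) over runs of
tied values), so both "Jenks"-labelled and "k-means"-labelled analyses
map onto the same core.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import silhouette_score

from .layer_model import LayerScheme, mean_scaling_ratio

__all__ = [
    "ContactTable",
    "LayerFit",
    "optimal_breaks",
    "select_num_layers",
    "detect_layers",
]


@dataclass(frozen=True)
class ContactTable:
    """Per-alter contact rates for a single ego.

    ``contact_rate`` is in events per day; rates must be positive and
    alter identifiers unique.
    """

    alter_ids: tuple
    contact_rates: tuple[float, ...]

    def __post_init__(self) -> None:
        ids = tuple(self.alter_ids)
        rates = tuple(float(r) for r in self.contact_rates)
        if len(ids) != len(rates):
            raise ValueError("alter_ids and contact_rates must have equal length")
        if len(set(ids)) != len(ids):
            raise ValueError("alter identifiers must be unique")
        if any(not np.isfinite(r) or r <= 0 for r in rates):
            raise ValueError("contact rates must be positive and finite")
        object.__setattr__(self, "alter_ids", ids)
        object.__setattr__(self, "contact_rates", rates)

    def __len__(self) -> int:
        return len(self.alter_ids)


@dataclass(frozen=True)
class LayerFit:
    """Result of clustering contact rates into layers.

    ``breaks`` are the k−1 thresholds on the rate scale separating
    layers; ``layer_sizes_cumulative`` counts alters from the
    highest-rate (innermost) layer outward; ``within_class_ssd`` is the
    partition's total within-class sum of squared deviations on the
    scale the partition was computed on.
    """

    k: int
    breaks: tuple[float, ...]
    layer_sizes_cumulative: tuple[int, ...]
    within_class_ssd: float
    selection_scores: dict = field(default_factory=dict)
    mean_scaling_ratio: float | None = None

    def __post_init__(self) -> None:
        sizes = self.layer_sizes_cumulative
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("cumulative layer sizes must be strictly increasing")
        if len(sizes) != self.k:
            raise ValueError("one cumulative size per layer required")

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "breaks": list(self.breaks),
            "cumulative_sizes": list(self.layer_sizes_cumulative),
            "within_class_ssd": self.within_class_ssd,
            "mean_scaling_ratio": self.mean_scaling_ratio,
            "selection_scores": {str(k): v for k, v in self.selection_scores.items()},
        }


def _blocks(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique sorted values and their multiplicities."""
    return np.unique(values, return_counts=True)


def _dp_partition(uniq: np.ndarray, counts: np.ndarray, k: int) -> tuple[list[int], float]:
    """Exact minimum-SSD contiguous partition of weighted sorted points.

    Returns the list of block indices starting each class and the total
    within-class sum of squared deviations.  Tied observations live in
    one block, so they are never split across classes.
    """
    b = len(uniq)
    w = counts.astype(float)
    cw = np.concatenate([[0.0], np.cumsum(w)])
    cwx = np.concatenate([[0.0], np.cumsum(w * uniq)])
    cwx2 = np.concatenate([[0.0], np.cumsum(w * uniq**2)])

    # SSD[i, j] = within-class SSD of blocks i..j-1 (half-open); upper triangle
    n_mat = cw[None, 1:] - cw[:-1, None]
    s_mat = cwx[None, 1:] - cwx[:-1, None]
    s2_mat = cwx2[None, 1:] - cwx2[:-1, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        ssd_mat = s2_mat - s_mat**2 / n_mat
    ssd_mat = np.where(n_mat > 0, np.maximum(ssd_mat, 0.0), np.inf)

    INF = float("inf")
    # cost[j]: best SSD of splitting blocks 0..j-1 into m classes
    cost = np.full(b + 1, INF)
    cost[0] = 0.0
    back = np.zeros((k + 1, b + 1), dtype=int)
    for m in range(1, k + 1):
        # candidate split points i (end of the first m-1 classes)
        total = cost[:-1, None] + ssd_mat  # total[i, j-1]
        back[m, 1:] = np.argmin(total, axis=0)
        new_cost = np.full(b + 1, INF)
        new_cost[1:] = np.min(total, axis=0)
        new_cost[:m] = INF
        cost = new_cost
    starts = []
    j = b
    for m in range(k, 0, -1):
        i = int(back[m][j])
        starts.append(i)
        j = i
    starts.reverse()
    return starts, float(cost[b])


def optimal_breaks(values: Sequence[float], k: int) -> LayerFit:
    """Globally optimal partition of scalar values into ``k`` contiguous classes.

    This is Jenks natural breaks, computed by exact dynamic programming,
    and equivalently the exact 1-D k-means solution.  ``breaks`` are the
    midpoints between adjacent class boundary values, and the cumulative
    layer sizes count from the largest values (innermost layer) outward.

    Raises if ``k`` exceeds the number of observations or of distinct
    values (tied values are never split across classes).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("values must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite (no NaN/inf)")
    if not 1 <= k <= len(x):
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={len(x)}")
    uniq, counts = _blocks(x)
    if k > len(uniq):
        raise ValueError(
            f"k={k} exceeds the {len(uniq)} distinct values; tied values are co-clustered"
        )
    starts, total_ssd = _dp_partition(uniq, counts, k)
    boundaries = starts[1:]  # block index starting classes 2..k
    breaks = tuple(
        float(0.5 * (uniq[i - 1] + uniq[i])) for i in boundaries
    )
    # class sizes in ascending-value order → innermost layer = top values
    edges = [0, *boundaries, len(uniq)]
    class_counts = [int(counts[a:b].sum()) for a, b in zip(edges, edges[1:])]
    cumulative = tuple(np.cumsum(class_counts[::-1]).tolist())
    return LayerFit(
        k=k,
        breaks=breaks,
        layer_sizes_cumulative=cumulative,
        within_class_ssd=total_ssd,
    )


def labels_from_fit(values: Sequence[float], fit: LayerFit) -> np.ndarray:
    """Class label (0 = lowest-value class) for each observation."""
    x = np.asarray(values, dtype=float)
    return np.searchsorted(np.asarray(fit.breaks), x)


def select_num_layers(
    values: Sequence[float],
    k_range: Sequence[int] = range(2, 9),
    transform: str | None = "log10",
) -> tuple[int, dict[int, float]]:
    """Choose the number of layers by maximal mean silhouette.

    For each candidate ``k`` the exact optimal partition of the
    (optionally log10-transformed) values is scored by the mean
    silhouette coefficient; ties go to the smaller ``k``.  Degenerate
    inputs with a single distinct value return ``k=1`` with a warning.

    Returns ``(k, scores)`` with the silhouette score per candidate.
    """
    x = np.asarray(values, dtype=float)
    if transform == "log10":
        if np.any(x <= 0):
            raise ValueError("log10 transform requires positive values")
        x = np.log10(x)
    elif transform is not None:
        raise ValueError(f"unknown transform {transform!r}")
    uniq = np.unique(x)
    if len(uniq) == 1:
        warnings.warn("all values identical; returning a single layer", stacklevel=2)
        return 1, {}
    ks = sorted(set(int(k) for k in k_range))
    if any(k < 2 for k in ks):
        raise ValueError("candidate layer counts must be >= 2")
    if len(x) < max(ks):
        raise ValueError("need at least max(k_range) observations")
    scores: dict[int, float] = {}
    for k in ks:
        if k > len(uniq):
            continue
        fit = optimal_breaks(x, k)
        labels = labels_from_fit(x, fit)
        scores[k] = float(silhouette_score(x.reshape(-1, 1), labels))
    if not scores:
        warnings.warn("no feasible candidate layer count; returning a single layer", stacklevel=2)
        return 1, {}
    best = max(scores, key=lambda k: (scores[k], -k))
    return best, scores


def detect_layers(
    table: ContactTable,
    k_range: Sequence[int] = range(2, 9),
    transform: str | None = "log10",
) -> LayerFit:
    """Detect the layer structure of an ego's contact-rate distribution.

    Selects the layer count by silhouette, computes the optimal breaks
    on the same scale, and reports cumulative layer sizes from the
    highest-rate (innermost) layer outward together with the mean
    scaling ratio of the recovered cumulative sizes.  Break thresholds
    are mapped back to the raw events/day scale.
    """
    if len(table) < 4:
        raise ValueError("layer detection requires at least four alters")
    rates = np.asarray(table.contact_rates, dtype=float)
    k_range = [k for k in k_range if k <= len(rates)]
    k, scores = select_num_layers(rates, k_range or [2], transform=transform)
    if k == 1:
        return LayerFit(
            k=1,
            breaks=(),
            layer_sizes_cumulative=(len(rates),),
            within_class_ssd=0.0,
            selection_scores=scores,
            mean_scaling_ratio=None,
        )
    x = np.log10(rates) if transform == "log10" else rates
    fit = optimal_breaks(x, k)
    breaks_raw = tuple(
        float(10**b) if transform == "log10" else float(b) for b in fit.breaks
    )
    ratio = (
        mean_scaling_ratio(LayerScheme(fit.layer_sizes_cumulative))
        if fit.k >= 2
        else None
    )
    return LayerFit(
        k=fit.k,
        breaks=breaks_raw,
        layer_sizes_cumulative=fit.layer_sizes_cumulative,
        within_class_ssd=fit.within_class_ssd,
        selection_scores=scores,
        mean_scaling_ratio=ratio,
    )
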