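"""Layered information-acquisition ("reach") model.

The chance that Ego hears about an innovation through face-to-face
contact is modelled layer by layer: an annulus with n_i members, each
carrying the trait with probability r_K and each contacted with
probability c_i, contributes n_i * r_K * c_i, and contributions are
summed over annuli from the innermost outward.  The literal sum is an
expected number of informative contacts and may exceed one; a strict
probability variant (one minus the product of per-dyad miss
probabilities) is provided alongside it.

The optimal community size for information transmission is read off the
saturating reach-versus-community-size curve as the point where the
curve has closed all but 1/e of the gap between its baseline and its
asymptote.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .layer_model import (
    EffortProfile,
    LayerScheme,
    cumulative_to_annuli,
    default_effort_profile,
)

__all__ = [
    "AnnulusProfile",
    "ReachCurve",
    "reach",
    "reach_complement",
    "reach_curve",
    "inflection_point",
    "optimal_layer",
    "contact_probabilities_from_effort",
]


@dataclass(frozen=True)
class AnnulusProfile:
    """Per-annulus inputs of the reach model.

    ``n_i`` members per annulus, ``c_i`` per-dyad contact probability
    per annulus, and ``r_K`` the prevalence of the trait among community
    members (the fraction initially seeded, e.g. 0.01 for 1%).
    """

    n_i: tuple[float, ...]
    c_i: tuple[float, ...]
    r_K: float

    def __post_init__(self) -> None:
        n = tuple(float(v) for v in self.n_i)
        c = tuple(float(v) for v in self.c_i)
        if len(n) != len(c):
            raise ValueError("n_i and c_i must have equal length")
        if len(n) == 0:
            raise ValueError("profile must have at least one annulus")
        if any(not np.isfinite(v) or v < 0 for v in n + c):
            raise ValueError("annulus sizes and contact probabilities must be finite and >= 0")
        if not 0 <= self.r_K <= 1:
            raise ValueError("trait prevalence r_K must lie in [0, 1]")
        object.__setattr__(self, "n_i", n)
        object.__setattr__(self, "c_i", c)

    @property
    def n_annuli(self) -> int:
        return len(self.n_i)


@dataclass(frozen=True)
class ReachCurve:
    """Reach evaluated at increasing community sizes."""

    community_sizes: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        x = tuple(float(v) for v in self.community_sizes)
        y = tuple(float(v) for v in self.values)
        if len(x) != len(y) or len(x) < 2:
            raise ValueError("curve needs >= 2 (community_size, value) pairs")
        if any(b <= a for a, b in zip(x, x[1:])):
            raise ValueError("community sizes must be strictly increasing")
        object.__setattr__(self, "community_sizes", x)
        object.__setattr__(self, "values", y)


def _check_index(profile: AnnulusProfile, upto_layer: int) -> None:
    if not 0 <= upto_layer < profile.n_annuli:
        raise IndexError(
            f"layer index {upto_layer} out of range 0..{profile.n_annuli - 1}"
        )


def reach(profile: AnnulusProfile, upto_layer: int) -> float:
    """Expected informative contacts summed over annuli up to a layer.

    The literal additive model: sum over annuli 1..i of
    ``n_i * r_K * c_i``.  Being an expected count it is linear in r_K
    and can exceed one.
    """
    _check_index(profile, upto_layer)
    n = np.asarray(profile.n_i[: upto_layer + 1])
    c = np.asarray(profile.c_i[: upto_layer + 1])
    return float(np.sum(n * profile.r_K * c))


def reach_complement(profile: AnnulusProfile, upto_layer: int) -> float:
    """Strict probability of at least one informative contact.

    ``1 − Π_i (1 − r_K·c_i)^{n_i}``: each dyad independently misses with
    probability ``1 − r_K·c_i``.  Bounded by [0, 1] and never exceeds
    the literal additive reach; the two agree to first order when every
    ``r_K·c_i`` is small.
    """
    _check_index(profile, upto_layer)
    if any(c > 1 for c in profile.c_i):
        raise ValueError("contact probabilities must lie in [0, 1] for the strict variant")
    n = np.asarray(profile.n_i[: upto_layer + 1])
    c = np.asarray(profile.c_i[: upto_layer + 1])
    log_miss = np.sum(n * np.log1p(-np.clip(profile.r_K * c, 0.0, 1.0 - 1e-300)))
    return float(-np.expm1(log_miss))


def contact_probabilities_from_effort(
    scheme: LayerScheme, profile: EffortProfile | None = None
) -> tuple[float, ...]:
    """Per-annulus contact probabilities calibrated from effort shares.

    Per-capita contact is taken proportional to per-capita effort
    (annulus effort share divided by annulus size), scaled so the
    innermost annulus has contact probability one.  This is a
    calibration from the 40%/20% effort allocation, not a measured
    contact schedule.
    """
    if profile is None:
        profile = default_effort_profile(scheme)
    annuli = np.asarray(cumulative_to_annuli(scheme))
    shares = np.asarray(profile.annulus_shares)
    if len(shares) != len(annuli):
        raise ValueError("effort profile and scheme must have the same number of annuli")
    per_capita = shares / annuli
    c = per_capita / per_capita[0]
    return tuple(float(v) for v in c)


def reach_curve(
    scheme: LayerScheme,
    c_i: Sequence[float] | None = None,
    r_K: float = 0.01,
    community_sizes: Sequence[float] | None = None,
    strict: bool = False,
) -> ReachCurve:
    """Reach as a function of community size, evaluated layer by layer.

    Community sizes default to the scheme's cumulative layer sizes; each
    requested size must coincide with a layer boundary at or beyond the
    innermost layer.  ``strict`` switches to the probability variant.
    """
    if c_i is None:
        c_i = contact_probabilities_from_effort(scheme)
    annuli = cumulative_to_annuli(scheme)
    profile = AnnulusProfile(tuple(annuli), tuple(c_i), r_K)
    cum = list(scheme.cumulative_sizes)
    if community_sizes is None:
        community_sizes = cum
    fn = reach_complement if strict else reach
    xs, ys = [], []
    for size in community_sizes:
        if size < cum[0]:
            raise ValueError(
                f"community size {size} is below the innermost layer ({cum[0]})"
            )
        try:
            idx = cum.index(float(size))
        except ValueError:
            raise ValueError(
                f"community size {size} is not a layer boundary of the scheme"
            ) from None
        xs.append(float(size))
        ys.append(fn(profile, idx))
    return ReachCurve(tuple(xs), tuple(ys))


def inflection_point(
    curve: ReachCurve,
    baseline: float | None = None,
    slope_tolerance: float = 1e-3,
) -> float:
    """Community size where the curve closes 1 − 1/e of its rise.

    The asymptote is estimated as the final curve value; the curve must
    be saturating, i.e. its final segment's slope must be below
    ``slope_tolerance`` times the mean slope over the whole curve.  The
    crossing of ``baseline + (1 − 1/e)·(asymptote − baseline)`` is found
    by linear interpolation between samples.  For a curve
    ``A·(1 − exp(−x/λ))`` sampled densely from a zero baseline the
    returned point is λ.
    """
    x = np.asarray(curve.community_sizes)
    y = np.asarray(curve.values)
    if baseline is None:
        baseline = float(y[0])
    asymptote = float(y[-1])
    rise = asymptote - baseline
    if rise <= 0:
        raise ValueError("curve does not rise above its baseline; no asymptote")
    mean_slope = (y[-1] - y[0]) / (x[-1] - x[0])
    last_slope = (y[-1] - y[-2]) / (x[-1] - x[-2])
    if mean_slope <= 0 or last_slope > slope_tolerance * mean_slope:
        raise ValueError(
            "curve has not saturated (final slope above tolerance); no asymptote"
        )
    target = baseline + (1.0 - math.exp(-1.0)) * rise
    for i in range(len(x) - 1):
        y0, y1 = y[i], y[i + 1]
        if (y0 < target <= y1) or (i == 0 and y0 >= target):
            if y0 >= target:
                return float(x[0])
            t = (target - y0) / (y1 - y0)
            return float(x[i] + t * (x[i + 1] - x[i]))
    return float(x[-1])


def optimal_layer(curve: ReachCurve, scheme: LayerScheme, **kwargs) -> float:
    """Layer boundary nearest (in log size) to the 1/e inflection point.

    Snaps the interpolated inflection community size onto the scheme's
    cumulative layer sizes, which is the natural resolution of a curve
    sampled only at layer boundaries.
    """
    x_star = inflection_point(curve, **kwargs)
    sizes = np.asarray(scheme.cumulative_sizes)
    idx = int(np.argmin(np.abs(np.log(sizes) - np.log(x_star))))
    return float(sizes[idx])
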