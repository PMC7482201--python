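"""Independent brute-force oracles used by the test suite.

These are deliberately naive and share no code with the package: an
exhaustive contiguous-partition search for the 1-D clustering DP, an
exact 512-state absorbing Markov chain for the 3x3 torus simulator, a
Poisson-binomial convolution for one-step mutant counts, and the exact
mean-field drift recursion.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def brute_force_min_ssd(values, k):
    """Minimum within-class SSD over all contiguous k-partitions of sorted values."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    best = np.inf
    for cuts in combinations(range(1, n), k - 1):
        edges = [0, *cuts, n]
        total = 0.0
        for a, b in zip(edges, edges[1:]):
            seg = x[a:b]
            total += float(((seg - seg.mean()) ** 2).sum())
        best = min(best, total)
    return best


def _torus3_neighbour_masks():
    """Direct and indirect neighbour index lists for every cell of a 3x3 torus."""
    direct, indirect = [], []
    for y in range(3):
        for x in range(3):
            d = [((y + dy) % 3) * 3 + (x + dx) % 3 for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1))]
            i = [((y + dy) % 3) * 3 + (x + dx) % 3 for dx, dy in ((1, 1), (1, -1), (-1, 1), (-1, -1))]
            direct.append(d)
            indirect.append(i)
    return direct, indirect


def torus3_node_probs(bias, beta=0.0):
    """Per-state per-node next-generation mutant probabilities on the 3x3 torus.

    Returns a (512, 9) array: entry [z, i] is the probability node i is
    mutant next generation given current state bitmask z.
    """
    b_self, b_direct, b_indirect = bias
    direct, indirect = _torus3_neighbour_masks()
    states = np.array([[(z >> i) & 1 for i in range(9)] for z in range(512)], dtype=float)
    probs = np.empty((512, 9))
    for i in range(9):
        q_d = states[:, direct[i]].mean(axis=1)
        q_i = states[:, indirect[i]].mean(axis=1)
        a_d = q_d + beta * q_d * (1 - q_d)
        a_i = q_i + beta * q_i * (1 - q_i)
        probs[:, i] = b_self * states[:, i] + b_direct * a_d + b_indirect * a_i
    return probs


def torus3_transition_matrix(bias, beta=0.0):
    """Exact 512x512 synchronous-update transition matrix on the 3x3 torus."""
    probs = torus3_node_probs(bias, beta)
    states = np.array([[(z >> i) & 1 for i in range(9)] for z in range(512)], dtype=float)
    T = np.empty((512, 512))
    for z in range(512):
        p = probs[z]
        T[z] = np.prod(states * p + (1 - states) * (1 - p), axis=1)
    return T


def torus3_extinction_probability(bias, beta=0.0, n_seeds=1):
    """Exact extinction probability from a uniformly seeded 3x3 start.

    Averages the absorbing-chain hitting probability of the all-wild
    state over all starting states with ``n_seeds`` mutants.
    """
    T = torus3_transition_matrix(bias, beta)
    transient = [z for z in range(512) if z not in (0, 511)]
    Q = T[np.ix_(transient, transient)]
    r0 = T[transient, 0]  # one-step absorption into all-wild
    h = np.linalg.solve(np.eye(len(transient)) - Q, r0)
    ext = {z: v for z, v in zip(transient, h)}
    ext[0], ext[511] = 1.0, 0.0
    starts = [z for z in range(512) if bin(z).count("1") == n_seeds]
    return float(np.mean([ext[z] for z in starts]))


def torus3_mean_absorption_time(bias, beta=0.0, n_seeds=1):
    """Exact expected generations to absorption from a uniform seeding."""
    T = torus3_transition_matrix(bias, beta)
    transient = [z for z in range(512) if z not in (0, 511)]
    Q = T[np.ix_(transient, transient)]
    t = np.linalg.solve(np.eye(len(transient)) - Q, np.ones(len(transient)))
    times = {z: v for z, v in zip(transient, t)}
    times[0] = times[511] = 0.0
    starts = [z for z in range(512) if bin(z).count("1") == n_seeds]
    return float(np.mean([times[z] for z in starts]))


def poisson_binomial_pmf(probs):
    """Exact pmf of a sum of independent Bernoulli(p_i) variables."""
    pmf = np.array([1.0])
    for p in probs:
        pmf = np.convolve(pmf, [1 - p, p])
    return pmf


def mean_field_drift(x, bias_self, beta, n_parents):
    """Exact one-generation expected mutant fraction under panmixia.

    E[x'] = x + (1-b_self) * beta * x(1-x) * (1 - 1/n_parents), from
    E[q + beta q(1-q)] with q = Binomial(n_parents, x)/n_parents.
    """
    return x + (1 - bias_self) * beta * x * (1 - x) * (1 - 1 / n_parents)
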