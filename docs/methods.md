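# Methods

`dunbargraph` implements a family of models built around one empirical
regularity: egocentric social networks are organised in nested layers of
cumulative size roughly 5, 15, 50 and 150 (extending to 500, 1500 and
5000 when acquaintances and nameable faces are included), with contact
frequency and emotional closeness falling sharply from one layer to the
next and successive layers scaling by a factor of about three. This note
records the models, their assumptions, the parameter choices that were
genuinely open, and what the synthetic data does and does not emulate.

## Layer schemes and descriptive statistics

A `LayerScheme` stores strictly increasing cumulative layer sizes; the
*annulus* of layer *i* is the difference of successive cumulative sizes
(the 50-layer annulus holds 35 alters). The scaling ratio between layers
*i* and *i+1* is the ratio of cumulative sizes, and the mean scaling
ratio is their arithmetic mean — this is the statistic reported for
published layer-size series, and it reproduces the printed values for
personal networks (3.0), top-down community structure (3.11),
multilevel mammal societies (2.49) and primate group sizes (2.23).

Grouping-size tables may contain ranges ("100–200"); these are resolved
to their midpoint by default (policies `low` and `high` are exposed
because the original averaging convention is unstated). Midpoint
resolution reproduces the published community-size mean of 158.0 and
sample (n−1) standard deviation of 28.7 exactly. The corresponding
egocentric average (153.6 ± 46.0) is *not* reproducible from its
printed rows under any of the three conventions (midpoint gives
162.7 ± 37.3); the rows are bundled for reference but no statistic is
claimed for them.

### Effort profile

Empirically ~40% of social effort goes to the innermost 5 alters and a
further 20% to the next 10. The default `EffortProfile` fixes those two
shares and spreads the remaining 40% over the outer annuli with
per-capita effort decaying geometrically from the second annulus's
level; the decay factor is solved numerically (Brent's method) so the
shares sum to one. For the canonical 7-layer scheme this gives a
per-capita decay of ≈4.6× per layer. Outer-layer shares are a
calibration, not a measured quantity: only the 40/20/60 structure is
empirical.

## Layer detection

Contact rates are scalar, so layer detection is 1-D optimal
partitioning: Jenks natural breaks, computed by exact dynamic
programming over blocks of tied values (O(k·B²) with B distinct
values). The contiguous minimum-SSD partition of sorted scalars is also
the global 1-D k-means optimum, so one core serves analyses labelled
either way. Tied observations are never split across classes; requesting
more classes than distinct values is an error.

The number of layers is chosen by maximal mean silhouette over
candidate k (default 2–8) on log10-transformed rates, ties toward
smaller k. Whether the original analyses clustered raw or log rates is
unstated; log10 is the default because rates span orders of magnitude,
and a raw-scale flag is provided. Degenerate inputs (a single distinct
value) return k = 1 with a warning, since the silhouette is undefined
there.

**Known limitation.** Layer recovery depends on the ratio of
between-layer separation to within-layer spread. With a 3× rate drop
per layer (log10 gap 0.477), recovery of all four layers from a single
ego's 150 rates requires within-layer log10 spread ≲ 0.1. At spread
0.3 the adjacent-layer Bayes misclassification rate is ~21% and no
selection criterion we evaluated (silhouette, Calinski–Harabasz,
Davies–Bouldin, gap statistic, jump, elbow, Gaussian-mixture BIC)
modally recovers four layers — the structure is statistically
unidentifiable at that noise level, not merely hard to find. The
synthetic generator's default noise (0.3, below) sits in this
unidentifiable regime, so the generate-then-detect loop at defaults
modally returns 2; the detection machinery itself is validated against
an exhaustive-search oracle and recovers planted structure whenever it
is identifiable.

## Information reach and the 1/e optimum

The chance that Ego hears about an innovation via face-to-face contact
is accumulated layer by layer: annulus *i* with *n_i* members, trait
prevalence *r_K* (default 0.01 — 1% of the community seeded) and
per-dyad contact probability *c_i* contributes *n_i·r_K·c_i*. The
literal sum is an expected number of informative contacts; because it
is sometimes read as a probability even though it can exceed one, a
strict variant 1 − Π(1 − r_K·c_i)^{n_i} is provided separately. The two
agree to first order as r_K·c_i → 0, and the strict value never exceeds
the literal one. Fidelity to the additive form comes first; the
product-complement is the package's own correctness variant.

Default contact probabilities are *not* empirical: they are calibrated
from the effort profile (per-capita effort per annulus, scaled so the
innermost annulus has c = 1) and fully configurable. Under this
calibration each annulus's contribution is proportional to its effort
share, so the reach curve inherits the 40/20 structure.

The optimal community size is the point where a saturating reach curve
has closed 1 − 1/e of the gap between its baseline and its asymptote
(estimated as the final value), located by linear interpolation between
sampled community sizes. A non-saturating curve is rejected: the final
segment's slope must be below `slope_tolerance` (default 1e-3) times
the curve's mean slope. The effort-calibrated default curve saturates
only approximately over seven layer-boundary samples (final relative
slope ≈ 0.08), so analyses of that curve pass the exposed tolerance
explicitly (0.1); the strict default is kept for densely sampled
curves. `optimal_layer` snaps the interpolated crossing to the nearest
layer boundary in log size — the natural resolution of a curve sampled
only at boundaries — and lands on the 50-layer for the default
calibration.

## The allocation urn

Each of L relationships is assigned independently to one of r layers
with probability p_k ∝ exp(−µ·s_k), where s_k is the per-relationship
time cost of layer k and µ the Lagrange multiplier of the total-time
constraint; conditional on L the occupancy vector is multinomial(L, p).
The prior over L itself (a prefactor B(L, L/N, N) in the full posterior)
is never evaluated — its functional form is not specified — so every
operation conditions on L, where the law is exact. The total budget S
enters only through µ. Log-space arithmetic with a max-shifted exponent
keeps the probabilities stable for |µ·s| up to hundreds.

Network *shape* is classified from the expected cumulative proportional
occupancy accumulated over layers ranked from most to least costly:
conventional networks (µ > 0) put few alters in costly (intimate)
layers and many in cheap ones, giving a convex curve; inverted networks
(µ < 0) give a concave curve; µ = 0 is uniform (linear, "degenerate").
The cost-ranked convention is used because the source descriptions of
which curve is "conventional" are internally inconsistent; under this
convention the classification is mathematically well defined and flips
exactly at µ = 0 for any strictly monotone cost schedule, which is the
substantive claim (the migrant/host phase transition).

## Cultural transmission on a torus

10 000 agents (default 100×100, configurable) sit on a torus and
interact only with their eight closest neighbours, split into four
orthogonal "friends" (direct) and four diagonal "friends-of-friends"
(indirect). The update is synchronous and generational, reading the
previous generation: each agent retains its variant with probability
`b_self`, otherwise imitates from the direct class with probability
`b_direct` or the indirect class with `b_indirect` (the three sum to 1).
An ambiguity in the original description of which four cells are
"direct" is resolved by the standard Moore decomposition
(orthogonal = direct, diagonal = indirect).

Imitation uses the classic cultural-inheritance bias form: with q the
mutant fraction among the sampled parent class, the agent adopts the
mutant with probability q + β·q·(1−q). At the default β = 0 this is
exactly copying one uniformly chosen neighbour; β > 0 is a directional
bias favouring the novel variant, exposed because neutral single-seed
spread almost never fixes (fixation probability 1/N) and the published
penetrance-time bands presuppose some bias steepness, whose value was
never printed. β is never applied silently.

The variant space is binary and mutation occurs only at seeding
(default one node, an occurrence probability of 10⁻⁴ on the default
lattice); thereafter dynamics are pure imitation, so all-wild and
all-mutant are absorbing and every run ends extinct, penetrant, or
censored at the generation cap. A mean-field variant draws `n_parents`
(default 8) cultural parents uniformly from the whole population,
applying the same bias form to their mutant fraction; at β = 0 the
expected mutant fraction is a martingale, and the exact one-step drift
E[x′] = x + (1−b_self)·β·x(1−x)·(1−1/n_parents) serves as a test
oracle. Ensembles run replicates on independent substreams spawned from
one seed and report extinction/penetrant/censored fractions and
penetrance-time quantiles.

Correctness is anchored on a 3×3 torus, where the full 512-state
transition matrix is enumerable: simulated extinction probabilities and
mean absorption times are required to match the exact absorbing-chain
solution within three Monte-Carlo standard errors at 10⁴ replicates.
Directional claims — structure slows penetrance relative to panmixia —
are tested as paired ensembles at 20×20 (200 replicates per arm), a
size chosen to keep the full suite fast while leaving the effect
unambiguous (median 47 vs 30 generations under the default bias). The
published figures of 44–60% extinction and 75–150 (mean-field) vs
150–300 (structured) generations to penetrance depend on unprinted
bias-steepness settings and are treated as calibration bands, not
targets; for reference, the reproduction script's 100×100 single-seed
ensembles at β = 0.5 happen to land at ~47% extinction and ~200
structured generations.

## Synthetic data

`gen_ego_contacts` emulates exactly the signature the layer models
assume: annulus-many alters per layer, a constant contact-rate ratio
between layers (default 3, mirroring the size scaling ratio, since the
published per-layer contact frequencies exist only as a figure), and
log-normal within-layer noise (default log10 sd 0.3). It does not
emulate heavy-tailed individual variation, reciprocity, churn, or
call-duration marginals, so passing recovery tests show the detector
works on cleanly layered rate data, not that real cellphone records
are this clean. `gen_community_graph` places nodes on a ring and
assigns each pair a layer by ring distance (both endpoints agree by
construction, so weights are symmetric; odd layer boundaries round up
by one) with weights equal to per-capita effort shares — a demo
substrate for diffusion, not a fitted social network.

## Numerical choices and problem sizes

- Clustering DP: exact, deterministic; ties in sorted values are
  co-clustered by construction; breaks are midpoints between adjacent
  class extremes on the clustering scale.
- Silhouette ties go to smaller k (parsimony).
- Urn pmf normalisation is verified exhaustively for L ≤ 6, r ≤ 4;
  multinomial evaluation is delegated to scipy in log space.
- Markov-oracle checks use 10⁴ replicates (3×3) and 200 paired
  replicates (20×20); the reproduction script uses 60 replicates per
  arm at 100×100 and 60 synthetic egos for the layer-recovery
  experiment. These sizes keep the whole suite under a couple of
  minutes while holding Monte-Carlo error well below the effects
  tested.
- RNG: `numpy.random.Generator` throughout; ensembles spawn
  per-replicate substreams from a single `SeedSequence`, so results are
  bit-reproducible under a fixed seed and replicates are independent.
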