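# Methods

## The model

`cheatnet` simulates bipartite plant–pollinator communities under a
generalized Lotka–Volterra model with saturating, interference-laden
functional responses. The community is obligately mutualistic: every
basal growth rate is negative, so no species persists without partners.
Pollinators may divert part of their interaction effort into cheating
(nectar robbing): a cheater escapes the mutualism cost on its cheating
interactions, while the robbed plant gains nothing and still pays it.

Four parameters control the cheating pattern:

| parameter | meaning | default grid |
|---|---|---|
| Δ̄ | proportion of pollinator species cheating | 0.1 … 1.0 step 0.1 |
| Ω | cheating frequency of each cheater | 0 … 1 step 0.1 |
| Ψ | innovative fraction of cheating (vs. conservative) | 0 … 1 step 0.1 |
| Λ | per-interaction cost of mutualism (time⁻¹) | 0, 0.15, 0.3 |

and the fixed functional-response parameters are α = 1.5
(per-interaction benefit; Λ/α = 0.1 or 0.2 for the two nonzero costs),
β = 1 (handling time), c = 1 (within-guild interference; optionally 0
for pollinators to probe the role of interference),
competition-for-space matrices equal to the identity. Communities hold
20 plants and 20 pollinators (10+10 in the small-community variant) at
backbone connectance φ ∈ {0.2, 0.3, 0.4}. Initial abundances are 1 for
every species.

Cheater identity follows one of two scenarios: the Δ̄·n_A pollinators
with the fewest (specialist scenario) or the most (generalist scenario)
mutualistic partners cheat, with ties broken by a seeded permutation.

## Synthetic-community ingredients chosen here

Several ingredients of the community generator are this package's own
design choices, made once and documented rather than tuned:

* **Backbone from trait matching.** Each species carries one
  standard-normal morphological trait; plant i and pollinator j link
  iff |t_i − t_j| ≤ d, with d bisected so realized connectance is
  closest to φ. Species left isolated get their nearest-trait partner;
  if realized connectance still misses φ by more than 0.05, traits are
  redrawn (≤ 50 times). Trait-distance rules are the standard way to
  obtain nested networks from continuous traits.
* **Growth rates.** Per community, two beta shape parameters are drawn
  uniformly from [0.5, 5]; Beta(a, b) draws are mapped affinely onto
  [−0.5, −0.001]. Redrawing the shapes per community samples a wide
  variety of growth-rate vectors (skewed, u-shaped, bell-shaped).
* **Niche similarity.** The interference weights are cosine
  similarities of interaction-strength profiles: Π between rows of M
  (plants sharing pollinators), Υ between rows of C (plants sharing
  cheaters), Θ between columns of M + C (all interactions, legitimate
  or not, compete for plants). Cosine similarity is symmetric, lies in
  [0, 1], is 1 for identical niches and 0 for disjoint ones — the
  properties the model requires. The diagonal is 1, so self-interference
  is included.

## Integration and stopping

The ODE system is integrated with LSODA (rtol 1e−8, atol 1e−10) and
sampled at unit time steps. A run stops when the per-species abundance
variance over the trailing 10 samples falls below 1e−14, or after
8,000 steps. Any abundance dipping below 1e−9 is clamped to zero
between samples — extinction is absorbing in a multiplicative model,
and the clamp prevents resurrection through floating-point noise.
Stability of the final state is verified on the surviving-species
subsystem (abundance > 1e−5) by a complex-step Jacobian: stable iff
every eigenvalue has real part below 1e−8. A state with every species
extinct is classified stable (all growth rates are negative).
Persistence is the percentage of all species strictly above 1e−5.

Across 1,000 simulations with parameters sampled uniformly from the
grids above, the stopping rule ends in a Jacobian-verified stable
state in ≥ 99.9% of runs (measured by `scripts/acceptance.py` and the
test suite at every run; typically 100%).

## Sweep design

Every cheating run is differenced against the no-cheating baseline of
the same community: one Ω = 0 integration per (seed, φ, Λ), reused
across scenarios and the (Δ̄, Ψ) axes, where Ω = 0 makes the dynamics
identical. Jobs are pure functions of (seed, combination), so any
execution order yields identical tables. The production design —
500 seeds × 3,630 combinations × 2 scenarios × 3 connectances =
10,890,000 jobs — is enumerable via `SweepGrid()`; the analyses here
execute stratified sub-grids (25–50 seeds, selected parameter windows)
that finish in minutes on one CPU. The problem sizes used by each
driver and by the acceptance script are stated in their headers.

The variance decomposition reports 1 − V_g/V, where V is the variance
of the effect over all runs and V_g the variance of group-mean-centered
effects (groups = parameter × scenario combinations). The residual
effect is regressed by OLS on mean growth rates, connectance, and
nestedness/modularity centered within connectance class (centering
breaks their correlation with connectance). Grouping is exposed as a
parameter since the production figure's exact grouping (with or
without connectance and size variants) is not pinned down.

## Network metrics

NODF follows the standard binary paired-overlap definition with the
decreasing-fill condition, averaged over row and column pairs and
scaled 0–100; it matches an explicit brute-force implementation and
R's `vegan::nestednodf` on random matrices. Bipartite modularity is
Barber's Q optimized by greedy label propagation across guilds plus
module agglomeration (in the style of the LPAwb+ algorithm), best of
20 seeded restarts; on small matrices it matches exhaustive search
over all row partitions with exactly optimized column labels.

## Synthetic field data

The generator emulates a camera-trap survey of plant–hummingbird
networks: 17 sites along a 100–3,500 m elevation gradient, 10–18
plants and 7–14 birds per site, per-plant sampling effort of 100–400 h,
flower traits (log-normal corolla length around 18 mm, a 0–60
curvature score) and bird bill lengths (log-normal around 22 mm).
Birds reach flowers with corolla ≤ bill + 4 mm and curvature ≤ 45;
legitimate visit rates decay exponentially with trait mismatch.
A fraction Δ̄_true = 0.8 of birds cheat — preferentially the ones with
few reachable partners — at a logit-linear frequency decreasing with
log partner diversity (slope −1.2) and scaled elevation (slope −2.0),
with Ψ_true = 0.9 of the cheating mass placed on plants outside the
convex hull of the bird's legitimate partners in trait space
(preferring plants far from the niche centroid) and the rest on
legitimate partners proportionally to visit rates. Counts are negative
binomial (size 2.0; camera-trap counts are overdispersed) and
converted to interactions·day⁻¹ as counts/hours × 24. A bird whose
reachable set covers every plant cannot cheat innovatively; its
innovative mass reverts to conservative placement, and the generator
errors only if no bird anywhere can cheat innovatively while
Ψ_true > 0.

What the generator does **not** emulate: temporal (monthly) structure,
observer error, phylogenetic signal in traits, plant abundance
variation, or cross-site bird identity. Passing recovery tests
therefore show that the estimators are consistent for data with this
generative structure, not that the field estimates from any real
survey are unbiased.

## Estimators

Per site: the proportion of cheaters (birds with ≥ 1 illegitimate
interaction among observed birds) and the overall cheating level
(illegitimate over total frequency, summed over all pairs — the
site-level Δ̄×Ω). Per bird and site: cheating frequency (illegitimate
over total frequency summed over partners) and partner diversity
(plants with ≥ 1 legitimate interaction). The innovative proportion of
a bird is 1 minus the overlap (mass under the pointwise minimum) of
two weighted 2D Gaussian-kernel densities over (corolla length,
curvature) — one weighted by legitimate, one by illegitimate
frequencies — each normalized to sum to 1 on a shared 100×100 grid
spanning the union of the supporting points padded 10% per side.
Bandwidths follow Silverman's rule per dimension on the weighted
points (σ_d · n_eff^(−1/6), Kish effective sample size); both grid and
bandwidths are configurable since no canonical choice exists. Plants
with missing traits are dropped before the density step.

Trends are fitted with logit-link GLMs via statsmodels: quasibinomial
(binomial IRLS with Pearson-dispersion-scaled covariance) for the two
site-level proportions against elevation, binomial for per-bird
cheating frequency against log partner diversity, with total
interaction frequency as weights and Wald χ² per term. Random site
and bird intercepts are deliberately out of scope; the fixed-effects
fit recovers the generator's slopes, and mixed-effects variants are
routine in external statistics tools.

## Empirical parameterization

A field network is converted to a backbone: I_ij = 1 where the pair
ever interacted legitimately, C_ij = illegitimate/total frequency
(pairs with only illegitimate records keep I = 0, C = 1 and feed the
cheating matrix only — a documented toggle), M_ij = I_ij(1 − C_ij).
The effect of observed cheating is the persistence difference between
paired runs (observed C vs. C = 0) sharing growth-rate vectors, over
a grid of α ∈ {1, …, 2}, Λ ∈ {0, 0.05, 0.1, 0.15, 0.3}, c ∈ {0.5, 1}
(60 combinations). Randomized null patterns keep the multiset of
positive C values and their count of cheating birds, re-drawing the
cheater set and the placements uniformly over the new cheaters' pairs
(I = 1 placements become conservative, I = 0 innovative), which
preserves total cheating mass exactly. Comparisons use z-scores of
logit-transformed persistence (0 and 1 adjusted to 0.01 and 0.99);
zero null standard deviation with a zero numerator gives z = 0, a
sign-definite infinity clamps to ±5, and finite scores are clipped to
the same range.

On the synthetic field networks, observed cheating patterns score
above their randomized nulls on average at low benefit and low cost
(site-mean z > 0), while the mean persistence effect of observed
cheating is near zero to slightly negative across the grid — the
synthetic networks are sparser and smaller than the communities where
indirect facilitation accumulates, so the paired effect is weaker
than in the theoretical sweep.

## Numerical and degenerate-input conventions

* round() uses half-away-from-zero (platform-independent cheater
  counts).
* Zero-valued rows in similarity computations get similarity 0
  off-diagonal and 1 on the diagonal.
* `variance_explained` returns NaN when total variance is zero;
  the residual regression raises a descriptive error naming collinear
  columns on rank deficiency.
* All randomness descends from a single named seed per run through
  `numpy` SeedSequence spawning; identical configurations and seeds
  give byte-identical outputs across processes.

## Known limitations

* The trait→backbone rule, growth-rate hyperparameters and similarity
  definitions are this package's documented stand-ins; quantitative
  results that depend on them (notably the exact ceiling of the
  positive cheating effect, measured here around +1.5 to +2.5 points depending on the seed set)
  carry that uncertainty, while the sign structure of the effect over
  the parameter space is robust in our experiments.
* "Iteration" in the stopping rule is one unit-time sample of a
  continuous adaptive integration, not a solver step.
* No evolutionary dynamics: Δ, Ω, Ψ are fixed during a run.
* Only pollinators cheat; plant-side cheating is out of scope.
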