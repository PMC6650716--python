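# Methods

`bainet` infers nested ("hierarchically modular") social structure from
*covisit* data: records of which social units — gorilla groups and solitary
males in the motivating system — were present at a shared resource hotspot
(a forest clearing, or bai) on each observation day.  The package treats
units as atomic network nodes and one calendar day as the sampling period.
This note documents the models, the numerical choices, and what the
synthetic benchmark does and does not establish.

## Data model

All stages run on a binary units × days presence matrix.  Days with zero
attendance remain as columns: the number of observation days `T` is the
length of the monitored interval, not the number of attended days, and the
input is expected to contain only monitored days.  Duplicate unit-day rows
collapse silently (with a logged count) because association is defined at
day resolution.  Units seen fewer than `min_visits = 8` times in a study
period are removed before index computation; the default matches the
analysis plan the package reproduces, where a unit seen fewer than eight
times in a two-year window carries too little information for a stable
index.

## Association indices

**Simple ratio (SR).**  `SR_ij = x / (x + y_i + y_j)` with `x` the number of
days both units visited and `y_i`, `y_j` the days only one did — the Jaccard
index of the two visit-day sets.  It is the standard gambit-of-the-group
index but can assign spuriously high values to rarely seen units.

**Binomial probability (BP).**  The upper-tail probability of the observed
covisit count under independent visiting:

    p_ij = P(X >= k_ij),   X ~ Binomial(T, (v_i / T)(v_j / T)),

where `v_i` is unit *i*'s visit count.  The tail is computed by exact
summation (`scipy.stats.binom.sf`).  Small `p_ij` means the pair covisits
far more often than their marginal rates explain; the association value is
stored as `1 − p_ij` so both indices read "bigger = closer", and the raw
tail is kept alongside because the clustering stage consumes it as a
distance.  The tail is one-sided upper: avoidance (covisiting less than
chance) is not scored as association.

A **rate-adjusted** mode corrects for fluctuation in overall visitation
(seasonality): with `s_t` the day-*t* attendance divided by mean attendance,
the per-day covisit probability becomes `q_t ∝ p0 · s_t²` (both members of a
pair are more likely to be present by chance on busy days), normalised so
`mean(q_t) = p0`, clamped at 1 with a logged count.  The tail then comes
from the exact Poisson-binomial distribution, evaluated by a dynamic-
programming convolution truncated at `k` (O(T·k) per pair).  With constant
attendance this reproduces plain mode to machine precision, which is tested.

## Null models

*SR*: data-stream permutation of the presence matrix by checkerboard swaps —
pick two units and two days forming a `[[1,0],[0,1]]` pattern and flip it —
preserving every unit's visit count and every day's attendance.  The chain
counts **trial** swaps: a rejected proposal is still a chain step.  This
matters: a chain that steps only on successful swaps has stationary
distribution proportional to the number of available checkerboards in each
matrix, not uniform; the trial-swap chain (symmetric proposal over ordered
pairs of occupied cells, self-loops otherwise) is uniform over the
fixed-margin class, which the tests verify by exhaustive enumeration on a
small matrix.  Ensembles use one sequential chain with a thinning interval
(default 500 steps) and burn-in (default 2× thinning); both are exposed in
configuration because no canonical values exist for them.

*BP*: each unit's visit days are redrawn as a uniform random subset of its
observed size.  The BP index conditions on unit visit counts only — that is
its own null hypothesis — so its null frees the day margins.

Empirical p-values use the add-one convention, `(1 + #{nulls ≥ obs}) /
(1 + n)`, so they are never exactly zero and ties count against the
observed value.

## Tier detection

**First tier (clustering).**  The BP tail, transformed as `d = p^(2/3)`, is
the clustering distance; UPGMA (average linkage, via
`scipy.cluster.hierarchy`) builds the dendrogram.  The 2/3-power transform
is chosen because it makes the cumulative count of dendrogram joins
approximately linear in `d` under the null (verified on null ensembles with
R² > 0.9), so a change of gradient in the observed curve signals a
transition between organisational scales.  The *knot* is located by
scanning every split of the local-gradient series — gradients taken between
consecutive distinct merge heights, ties contributing one step — with at
least 5 gradients per side, scoring each split with a two-sided two-sample
Wilcoxon rank-sum test (exact when both sides have ≤ 25 gradients, normal
approximation with tie correction otherwise) and keeping the most
significant split.  The reported `w` is the rank-sum of the below-knot
sample.  The scan's minimum p-value is used without multiplicity
correction, mirroring the procedure it reproduces; the null calibration of
the knot test is therefore approximate and the `significant` flag should be
read descriptively.  Cutting the dendrogram strictly below the knot height
(merges at exactly the knot height are cut) yields the tier-1 partition.

**Second tier (modularity).**  Louvain multi-level optimisation
(python-igraph) of weighted modularity with resolution γ,

    Q(γ) = Σ_c [ w_c / W − γ (s_c / 2W)² ].

The observed partition takes the best of 10 restarts, each with a shuffled
vertex order; igraph's internal randomness is re-seeded per run so results
are reproducible given the seed.  Significance is the empirical p of the
observed Q against the null ensemble re-optimised at the same γ (one
restart per null matrix; Q values are stable on these small dense graphs).
The resolution sweep covers γ = 0…2 in steps of 0.01 by default, reusing a
single null ensemble across the grid; troughs of the p-curve (local minima
after collapsing plateaus, retained if p < α) mark scales at which the data
are more modular than chance.

**Consistency.**  Agreement between the two routes is a binomial GLM over
all unordered unit pairs, predicting same-tier-2-module from
same-tier-1-cluster.  Complete separation — which is the *expected* outcome
when recovery is perfect, since every tier-1 pair then shares a module — is
flagged rather than fitted.  Dyadic observations are not independent; the
Wald p is anti-conservative and reported as published practice, not as a
calibrated test (no MRQAP correction is attempted).

## Scaling and kinship

Social levels are numbered 1–7: individuals, mother–offspring units, family
units (groups/solitaries), first-tier associations, second-tier
associations, sub-population, population.  Levels 1 and 3–5 come from the
pipeline (3–5 as mean individuals per unit, weighted by unit size); levels
2, 6 and 7 cannot be derived from covisit streams and enter only as
explicit configuration — omitted with a warning otherwise, never silently
invented.  The scaling ratio is `exp(slope)` of the OLS fit of `ln(size)`
on level.  For several populations, the default first averages sizes per
level and fits the means; a pooled mode with per-population intercepts
(shared slope) is also available.

Kinship is consumed as given binary data (1 = estimated relatedness ≥ 0.2,
i.e. half-siblings or closer): a logistic regression of pairwise module
co-membership on relatedness of the units' silverbacks, with the same
separation handling and the same dyadic-dependence caveat as above.

## Synthetic generator

The generator emulates the empirical regime: `n_units = 48` (≈ 44%
solitary), `T = 730` days, group sizes `2 + Poisson(5)` (mean 7
individuals), per-unit rate multipliers lognormal with σ = 0.4 and mean 1
around a base rate of 0.05 visits/day, seasonal factor
`s_t = 1 + 0.3 sin(2πt/365)`.  Planted structure is literal: tier-2 modules
of near-even size around 8 units are partitioned into tier-1 clusters of
`1 + Poisson(1)` units (mean 2), and covisit correlation arises from shared
latent daily *excursion* events — each cluster fires with probability 0.15
per day, each module with 0.25, and a unit's visit probability is
multiplied by 6 when its cluster fired and 5 when its module fired
(clamped at 1).  Module sizes are near-even rather than Poisson because the
second-tier associations the generator emulates are of similar size; a
heavy-tailed size distribution would plant one- and two-unit "modules" that
no detection method could in principle recover.  Silverback kinship is
Bernoulli: probability 0.25 of relatedness within a module, 0.04 between.

With both boosts at 1 the units visit independently — exactly the null
hypothesis of the inference — so the same generator drives the type-I
calibration.  What the generator does *not* emulate: demographic turnover
(groups forming or dissolving mid-stream), unmonitored days, multi-day
excursions with temporal autocorrelation, and observation error in unit
identification.  Passing recovery tests therefore show the chain is correct
and well-powered under its own assumptions, not that real bai data meet
those assumptions.

## Problem sizes and numerical choices

The test suite and the acceptance script scale simulations to single-CPU
runs: calibration uses 200 structureless replicates of 20 units × 365 days
with 200 permutations each (thinning 100, burn-in 200 — under the null the
chain starts at a draw from its stationary class, so short thinning does
not bias the test); recovery uses 20 replicates at the full default regime
(48 units × 730 days); the scripted resolution sweep uses a 0.02 γ-step
with 100 nulls.  UPGMA tie-breaking follows scipy's nearest-neighbor-chain
order; merge ties only arise on exactly equal distances, which have measure
zero for BP tails on real or simulated data.  Mantel tests use Pearson
correlation of off-diagonal upper triangles with simultaneous row/column
relabeling, one-sided (Z′ ≥ Z), add-one; an exact mode enumerates all
relabelings for ≤ 8 shared units.  All stochastic operations take explicit
seeds, and ensembles record seed and method.

## Known limitations

- The BP formulation here is a reconstruction pinned by its stated purpose
  (tail probability of the covisit count given average visit rates, with a
  daily-rate adjustment for visitation fluctuation); variant forms could
  differ in detail.
- The knot scan's candidate-set and sidedness choices are likewise pinned
  reconstructions; the minimum-p scan is not multiplicity-corrected.
- GLM p-values ignore dyadic non-independence (see above).
- Louvain is a greedy heuristic; optimality is only guaranteed on the small
  enumerable fixtures where the tests compare it with brute force.
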