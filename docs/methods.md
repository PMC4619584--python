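# Methods

This note documents the models and conventions behind every number the
package produces: the estimators, the null models, the heuristics with
their failure modes, and the choices made where the literature leaves the
definition open.

## 1. From visit records to the consumption matrix

A visit record is (plant, frugivore, duration in minutes, focal counts,
focal interval). Focal counts are fruits manipulated during short fixed
windows — 30 s is the convention for primates, 10 s for birds, and the
package refuses mixed interval lengths within one frugivore species
because a pooled mean across intervals of different lengths is not a
rate.

The cell estimate for a (plant, frugivore) pair is

    X = (Σ duration) × mean(focal counts) × 60 / interval_s

with the focal counts **pooled across all visits of the pair** before
averaging (each focal window counts equally). A `per_visit_rates=True`
flag averages per-visit means instead (each visit counts equally); the
pooled default is what makes the estimator additive over arbitrary
splits of the log. Pairs with positive feeding time but no focal sample
raise an error naming the pair rather than silently dropping fruit.

**Group reallocation.** When an external study provides better-sampled
relative consumption within a species group (e.g. the monkeys at a site
with long-term behavioural data), `reallocate_group` keeps each plant's
group total fixed and redistributes it by the supplied per-plant
proportions (validated to sum to 1 within 1e-6). Non-members are
untouched; conservation is exact.

**Scales.** Matrices carry a `counts`/`percent` flag. Row-normalization
to percentages (each plant row summing to 100) is idempotent and leaves
the binary skeleton, degree family and effective partners unchanged;
indices that depend on column marginals (SS, d, d′, H2′) do change, so
analyses state which scale they consumed. Binarization thresholds at
weight > 0 with no minimum-percentage cutoff.

## 2. Species-level indices

For a focal level with S species and m potential partners:

- **D, ND** — partner count and D/m.
- **NR (nested rank)** — rank in the degree-sorted matrix mapped to
  [0, 1]; ties broken by total weight, then label, so output is
  deterministic. The level mean is exactly 0.5.
- **WB, WC** — betweenness and closeness on the weighted one-mode
  projection. Projection edge weight is the co-use product
  w_ik = Σ_j X_ij·X_kj (a `min`-overlap alternative is exposed);
  path distance is 1/w. Both are rescaled to sum to 1 across the level,
  which makes the level mean 1/S by construction. Mutually unreachable
  pairs contribute ten times the largest finite distance to closeness;
  isolated species score 0.
- **SS (species strength)** — sum of the partners' dependencies on the
  focal species; across plants the strengths sum exactly to the number
  of non-empty frugivore columns.
- **EP (effective partners)** — exp of the Shannon entropy of the
  species' weights; 1 ≤ EP ≤ D.
- **SSP (species specificity)** — population CV of the species' weights
  over all m potential partners (zeros included), divided by √(m−1),
  its maximum when all weight sits on one partner; 0 = perfectly even.
- **d, d′** — Kullback–Leibler divergence of the species' partner use
  p′_ij from availability q_j = A_j/M. The standardization range is
  heuristic: d_max concentrates the species' total on the scarcest
  partners without exceeding their observed totals; d_min redistributes
  it proportionally to availability, in integer units on the counts
  scale (largest-remainder rounding) and continuously otherwise. When
  the range collapses (d_max = d_min), every allocation compatible with
  the marginals has the same divergence: d′ is defined as 1 when that
  forced divergence is positive (the web pins the species at maximal
  specialization, e.g. an equal-count perfect matching) and 0 when it
  is zero (a single partner on offer). An exhaustive-enumeration test
  confirms the heuristic bounds bracket the truth on all small webs.
- **G (generality)** — reported at network level as the level mean of
  EP. A per-species "generality" column distinct from EP is not well
  defined and is deliberately not invented.
- **Core/periphery** — G_c = (k − k̄)/σ_k with the population SD, core
  at G_c ≥ 1. The population SD makes G_c provably monotone in the
  species' own degree (z² ≤ n−1), so gaining partners can never demote
  a core species.

Converted variants 1−d, 1−d′, 1−NR, 1−SSP are stored alongside the raw
values so that "larger = more central/generalist" holds across every
column of the summary table.

## 3. Network-level statistics and nulls

**NODF.** For each ordered pair within rows (and within columns) where
the richer member has strictly larger fill, the pair scores
100 × shared/fill(poorer); NODF averages over all pairs. The
implementation is validated cell-for-cell against an independent
set-based re-derivation on every 3×3 binary matrix and agrees with
`vegan::nestednodf` to 5 decimals on a frozen fixture.

**Binary nulls.** ER draws every cell Bernoulli(F/(n_r·n_c)); CE uses
the mean of row and column fill probabilities, (f_i/n_c + g_j/n_r)/2.
Empty rows and columns are retained — they shape CE's probabilities.

**Weighted null (`vaznull` scheme).** The skeleton is drawn cell by cell
with probability proportional to the product of relative marginal
totals, in two phases (cover every row, then every column) followed by
fill-up to exactly F cells; the remaining M − F interaction units fall
multinomially on the filled cells. M and F are conserved exactly and
every margin is non-empty. The two-phase scheme needs F ≥ n_r + n_c − 1,
which is raised as an explicit error otherwise; empty margins are
dropped with a warning first.

**H2′.** H2 is the Shannon entropy of the joint interaction
distribution. H2max is the exact upper bound Σ marginal entropies
(product allocation). H2min comes from greedy concentration — repeatedly
committing min(remaining row, remaining column) to the cell pairing the
largest remainders — **with the observed allocation included in the
candidate set**: the greedy ordering is occasionally beaten by the
observed matrix itself (found by the package's own random-matrix
invariant test), and taking the minimum of the two keeps
H2min ≤ H2 ≤ H2max for every input. H2′ = (H2max − H2)/(H2max − H2min),
clamped to [0, 1]; a single row or column leaves it undefined (NaN).

**Significance.** Empirical one-tailed p with the +1 correction,
p = (1 + #{null ≥ obs})/(R + 1), so p is never exactly 0 and a result
beyond every null reports 1/(R+1). z = (obs − null mean)/null SD.
Replicate seeds derive from the master seed by counter. ER/CE with H2′
is rejected (those nulls destroy the weights); NODF against the weighted
null is allowed with a warning.

## 4. Robustness

Removal orders are uniformly random permutations of the active
(degree > 0) species at one level; after each removal, species at the
other level with no remaining partners are secondarily extinct. The
curve starts at (0, 1), ends at (1, 0), and R is its trapezoidal area.
Species with no partners at the outset are excluded from both the
removal sequence and the survivor denominator — this is what makes the
one-plant-ablation experiment well defined when deleting a plant strands
a frugivore as a structural zero column. Direction naming: "plant-level
R" is the robustness of the plant level when frugivores are removed.
Default 100 random orders; per-order seeds spawn from the master seed.
The implementation matches exhaustive hand simulation on every web up to
3+3 species and every removal order.

## 5. Phylogenetic assemblage structure

Cophenetic distances are patristic path sums on the input newick
(dendropy); trees must carry branch lengths, or `missing_lengths="unit"`
substitutes 1. MPD is the mean over unordered pairs, MNTD the mean
nearest-neighbour distance; both presence-based (no abundance
weighting — a weighted variant is deliberately out of scope because the
classification criteria are defined on the unweighted statistics).

The null randomizes the **community matrix**, not tip draws: sequential
checkerboard swaps preserving every row and column total (independent
swap), burn-in 10 × fill attempts, thinning fill attempts between the
`runs` samples of one chain (defaults; both overridable). This removes
species-richness and frequency artefacts from the standardized effect
sizes. NRI = −(MPD_obs − mean)/SD over the null samples; NTI likewise
with MNTD. Classification is two-tailed on the null quantiles at alpha
(default 0.05) — aggregated below the alpha/2 quantile, dispersed above
1 − alpha/2 — rather than a fixed |index| > 1.96 cutoff, which is not
robust to the skewed nulls that small assemblages produce. Degenerate
nulls (no checkerboard, assemblage = full pool, or SD numerically zero)
classify as random with NaN indices and a warning; the SD test uses a
relative tolerance because a constant null sequence accumulates
~1e-16 floating-point scatter.

## 6. Synthetic data: what it emulates and what it does not

`gen_matrix` mixes a deterministic skeleton (strict threshold structure
for nestedness, one-to-one matching for specialization; the larger dial
wins) with Bernoulli noise whose base rate keeps expected fill constant
across dial settings; weights are rounded log-normal (σ = 1, floor 1 on
realised links) and every margin is forced non-empty. The dials are
calibrated in distribution, not by value: mean NODF (H2′) rises
monotonically in the nestedness (specialization) level — Spearman ρ ≈
0.9 over 5 levels × 50 matrices, checked in the test suite. A perfect
matching with unequal level sizes, or both dials at 1, is refused.

`gen_visit_log` inverts the matrix construction: Poisson(hours) visits
per non-zero cell, exponential durations, ≥ 1 Poisson focal counts per
visit with the cell's latent rate. Because the pooled focal mean is an
unbiased rate estimate independent of the durations, the expectation of
`fruits_handled(gen_visit_log(X))` equals X cell-wise (verified within
3 Monte-Carlo SEs over 200 logs).

`gen_phylogeny` is a Yule pure-birth tree (dendropy's constant-rate
birth–death sampler with death rate 0); `gen_assemblage` draws clustered
(focal tip + nearest neighbours by cophenetic distance), dispersed
(greedy maximin) or uniform-random tip sets. Clustered/dispersed are
defined on cophenetic distance, not topology, to match what MPD/MNTD
measure.

What the generator does **not** emulate: taxonomic identity (primates
vs birds beyond an optional label), observation-effort heterogeneity
across plants, temporal structure within the study period, and
phylogenetic signal in interaction weights. Passing the recovery tests
therefore shows the estimators work under the stated sampling model,
not that any field community satisfies that model.

## 7. Keystone flow and regression screens

Pulp flow = consumption rate (fruits·h⁻¹·tree⁻¹) × active hours ×
dry pulp mass per fruit (g) × density (trees·ha⁻¹), in g·ha⁻¹·day⁻¹.
Active hours default to 12 (a daylight day); crop duration enters only
through an optional `annualize` toggle (× duration/12) because no
standard combining formula exists for it — absolute flow magnitudes
therefore depend on these conventions and only orderings and overlaps
are treated as comparable across studies. Flow is exactly
multiplicatively separable in its factors. Rankings sort descending
with label tie-breaks; list overlap matches on normalized labels
(whitespace and cf./aff. unified). A published pair of top-20 lists for
a western Amazonian forest (flow-based vs scarcity-period production)
ships as a data fixture for the overlap comparison; the scarcity-period
index is consumed as given, never computed.

The regression screens are ordinary least squares (scipy):
visit time ~ frugivore abundance per plant (reporting R² and slope
sign, with the community summary = fraction of plants with positive
slope), and the seven-prediction battery regressing pulp lipid content
on crop duration, seed width, frugivore size, crop size, visitation
rate, visitor richness and recruitment below parents, with expected
signs (+, +, +, −, −, −, −). Under independence R² ~ Beta(1/2, (n−2)/2),
which the null tests use as their oracle. Missing predictors are
reported as untested rows, not errors; a constant response leaves all
rows undefined.

## 8. Problem sizes and numerical conventions

Validation runs use webs of 10–30 species per level, 64-tip trees, 999
swap samples and 100–1000 null replicates — sizes at which every check
runs in seconds while the binomial/Monte-Carlo error bands quoted in the
tests are already narrow. The phylogenetic recovery experiment averages
over 4 independent trees × (50 clustered + 50 random) assemblages
because single-tree detection rates vary with the tree realisation
(SD ≈ 0.07). Tolerances: exact conservation laws are asserted with
array equality; entropy and area identities at 1e-9; stochastic
recoveries within 3–4 standard errors of their oracle value. All
randomness flows from explicit integer seeds through
`numpy.random.default_rng` (one named stream per generator; child seeds
drawn by counter), so every result in the README and the acceptance
JSON is bit-reproducible given the seed.

## Known limitations

- The d_min/d_max and H2min standardization ranges are heuristic; d′
  and H2′ are guaranteed to lie in [0, 1] and to bracket the enumerable
  truth on small webs, but are not certified optima on large ones.
- The weighted null requires F ≥ n_r + n_c − 1; extremely sparse webs
  (near-perfect matchings) cannot be tested against it.
- Betweenness/closeness depend on the chosen one-mode projection
  weighting; both the product and min conventions are offered, and
  values are only comparable within one convention.
- NRI/NTI classifications inherit the independent-swap null's
  conditioning: with few assemblages or a community matrix dominated by
  one structure type, the null itself absorbs part of that structure
  and power drops.
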