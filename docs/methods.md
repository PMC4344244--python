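# Methods

## Data model

The unit record is a *feeding episode*: species, year, month, diet item,
foraging location, plus filter metadata (lowland/highland altitude band,
bird-feeder flag, free-text site note).  Diet items and locations are
closed vocabularies; the standard schema has 11 diet items (10 identified
plus "unidentified") and 10 locations.  The two "unidentified" labels are
treated asymmetrically, and this asymmetry is the central design decision
of the package:

- an unidentified **item** is missing data and is imputed by the model;
- an unidentified **location** is an observable reporting outcome (the
  observer saw only handling, not the catch) and participates as an
  ordinary tenth location category, i.e. as a column of the
  location-given-item law.  This keeps a single likelihood for every
  episode.

Exclusion filters: feeder records, non-lowland records, and records with
neither item nor location information are dropped.  Episodes with an
unidentified item but a known location are *retained* — they carry the
signal the imputation model uses.  Lowland filtering relies on a
precomputed altitude band column; no geospatial computation is performed.
Reports describing several items/locations at once are split into separate
episodes, pairing parallel lists elementwise or broadcasting a single
location over all items.

All estimators consume one sufficient statistic: the per-species counts
tensor `counts[month, item, location]`, pooled across years.  Months with
no episodes are kept as zero slices because the seasonal smoother needs the
full 12-month cycle.

## Estimators

**ROP.** `compute_rop` divides monthly item counts by the monthly episode
total, unidentified included; `rop_identified_only` renormalises over
identified items.  Months with zero support are *undefined* (NaN rows),
never silently zero, so downstream comparisons skip them explicitly.

**Seasonal tests.** 2x2 contingency tables of identified episodes split by
season — breeding (April–September) versus wintering (October–March) — and
by animal versus non-animal item (or ground versus non-ground location).
"Animal" means invertebrate, fish, amphibian and reptile, bird, mammal;
man-made food counts as non-animal.  The statistic is the Pearson
chi-square without continuity correction (scipy's `chi2_contingency`); the
one-sided p-value is the standard halving construction, `p/2` when the
observed shift points in the hypothesised direction and `1 - p/2`
otherwise.  Degenerate margins yield a flagged-undefined result.  The test
uses identified episodes only; including unidentified episodes as
non-animal would be the main alternative and is not implemented.

**CP.** Stomach-content count proportions pool raw item counts across
studies within a species-month (no study weighting), after removing
bird-month cells with fewer than five specimens (threshold configurable;
boundary: five kept, four dropped).  Plant items are counted in parts,
animal items in individuals, uncountable material as one — properties of
the input tables, not of this code.

**RMSD.** Root mean square difference between a monitoring table
(identified-only ROP or MOP) and the CP table for one item, over bird-month
cells defined in both, computed on the percentage scale (0–100).  The
percentage scale is used because composition gaps are conventionally
reported in percentage points; values above 1 would be impossible on the
fraction scale.  Cells are pooled across species per item rather than
averaged per species.

## The imputation model

Parameterisation (per species, fitted independently):

- `n[m,k] ~ Poisson(λ[m,k])` for the complete (identified + latent) count
  of item `k` in month `m`.  Conditional on the monthly totals this is
  exactly the multinomial item-choice model; the Poisson form makes the
  Metropolis updates one-dimensional.
- `θ[k,·]`, the location law given item `k`, is month-invariant and shared
  by identified and unidentified episodes — the identifying assumption:
  missingness of the item depends on the episode only through its location,
  so data are missing at random given location.
- `log λ[·,k]` has a circular first-order Gaussian random-walk prior over
  the 12 months with precision `τ[k]`; a single precision per item, i.e.
  the strength of seasonal autocorrelation does not vary over the year.
  The 12-cycle Laplacian has rank 11, so the `τ` full conditional is
  `Gamma(a + 11/2, b + SS/2)` with `SS` the circular sum of squared
  increments.  The intrinsic random walk leaves the level free; a
  `Normal(μ0, s0²)` prior on the per-item *mean* log level makes the prior
  proper.

Priors (defaults, all exposed in `MopModelSpec`): `θ[k] ~ Dirichlet(1)`;
`τ[k] ~ Gamma(2, 0.5)` (prior mean precision 4, a mild smoothing
preference on the log scale); `μ0 = log(mean monthly identified count per
item + 0.5)` and `s0 = 2`, centring the level near the data scale while
staying diffuse.  These are weakly informative, proper choices that
stabilise months with zero counts.

Gibbs blocks per sweep:

1. **Latent reallocation** — the `u[m,l]` unidentified episodes of a cell
   are multinomially split over items with `P(k|m,l) ∝ π[m,k]·θ[k,l]`.
   Episodes are exchangeable within a cell, so counts, not per-episode
   labels, are tracked; this is exactly equivalent and vectorises the step.
2. **θ update** — conjugate Dirichlet with the complete location counts.
3. **λ, τ update** — single-site Gaussian random-walk Metropolis over the
   12 months, vectorised across items (items are conditionally
   independent), followed by the conjugate Gamma draw of `τ`.  Months with
   zero episodes contribute no likelihood; their `log λ` is interpolated by
   the prior.  A NaN acceptance ratio raises immediately rather than
   corrupting the chain.

Sampler defaults: 3 chains, 20 000 iterations, 10 000 burn-in, thinning 10,
proposal sd 0.3 (acceptance ≈ 0.6 on study-scale data).  Per-chain streams
are spawned from one master seed, so a fit is bitwise reproducible.
Split-R̂ and effective sample size are computed per scalar via ArviZ; R̂
above 1.1 triggers a warning, never a failure.

**MOP.**  The posterior-mean complete count of each item-month is rounded
half-away-from-zero to an integer and renormalised within the month.
Rounding is applied to complete counts, not to `λ`: the estimated
frequencies being integerised are most naturally the episode counts
themselves.  Consequences worth knowing: with no unidentified episodes the
complete counts are constant across draws and the MOP equals the
identified-only ROP *exactly*, and months whose rounded counts are all zero
are flagged undefined.

## Synthetic data

The generator draws, per month, items from a smooth seasonal truth
(`log λ[m,k] = c + A_k sin(2π(m − φ_k)/12)`, matching the prior family),
locations from item-specific rows of a Dirichlet-sampled `θ` (concentration
0.8 by default, giving each item a pronounced location preference — the
regime in which locations are informative), then hides the item with a
location-dependent probability.  The default study scale is 12 months x 4
identified items x 3 locations with 40 episodes per month and missingness
rising from 10% to 60% across locations.  An optional per-item multiplier
on the missingness probability creates a controlled violation of the
missing-at-random-given-location assumption for robustness experiments.
Stomach tables are simulated from the same monthly truth: Poisson item
totals per specimen (default mean 8, 8 specimens per month) with
multinomial item identities.

What the generator does *not* emulate: observer heterogeneity and
expertise, reporting preference for rare items, item-size effects on
detectability, and spatial structure.  Passing recovery tests therefore
demonstrate correctness of the inference under the model's own missingness
mechanism, not robustness to every bias of real volunteer data.

## Problem sizes and numerical choices

The test suite and the acceptance script run the recovery study at the
default study scale with 20 replicate datasets and a scaled-down sampler
(1 chain, 2 500 iterations, 1 000 burn-in, thinning 3) — enough for the
integer-rounded MOPs to stabilise at this data size, as the multi-chain
diagnostics of the worked example indicate, while keeping a full run in
tens of seconds.  Composition rows are validated to sum to 1 within 1e-6
(1e-9 in tests for exact constructions); undefined months propagate as NaN
everywhere.  Ties in rounding cannot occur at half-integers systematically
because posterior means are Monte-Carlo averages; `floor(x + 0.5)` is used
regardless.

## Known limitations

- The identifying assumption is untestable from monitoring data alone;
  item-dependent missingness (e.g. small items being harder to identify
  anywhere) biases MOPs, which is why the generator can simulate it.
- `θ` is month-invariant; species that shift foraging microhabitat within
  a location category across seasons violate this silently.
- Species are fitted independently; no pooling of location laws across
  species.
- The published-tally dataset contains summary rows only; episode-level
  reanalysis of the original monitoring data requires the original
  (non-public) episode table.
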