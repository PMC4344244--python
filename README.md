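# avidiet

Monthly diet compositions of bird species estimated from episodic foraging
observations, with hierarchical Bayesian imputation of unidentified diet
items.

## The problem

Volunteer (citizen-science) monitoring programmes accumulate large numbers
of *feeding episodes*: one-off reports that a bird of some species was seen
consuming a diet item (seed, fleshy fruit, invertebrate, ...) at a foraging
location (ground, tree, bush, in the air, ...).  Two obstacles stand
between such data and a monthly diet composition:

1. in many episodes the observer could not identify what was being eaten,
   and identifiability varies strongly with the foraging location — a bird
   gleaning inside a tree canopy is much harder to score than one picking
   seeds off open ground — so simply dropping unidentified episodes biases
   the composition;
2. observation effort is uneven over the year, so months with few episodes
   give noisy proportions.

`avidiet` computes three estimators and the machinery to compare them:

- **ROP** (raw observation proportion): the monthly fraction of episodes
  per diet category, with "unidentified" kept as its own category (or
  renormalised over identified items only);
- **MOP** (model-aided observation proportion): monthly proportions after
  Bayesian imputation of the unidentified items;
- **CP** (count proportion): the monthly fraction of each item among all
  items counted in historical stomach-content studies, the benchmark the
  monitoring estimates are validated against (root mean square difference
  over matched bird–month cells, in percentage points).

## The model

For a species, let `y[m,k,l]` count identified episodes in month `m` with
item `k` at location `l`, and `u[m,l]` the unidentified episodes at
location `l`.  The hierarchy is

- `n[m,k] ~ Poisson(λ[m,k])` — expected foraging frequencies; conditional
  on monthly totals this is the multinomial item-choice model;
- `location | item k ~ Multinomial(θ[k,·])`, one month-invariant law per
  item shared by identified and unidentified episodes, so an unidentified
  episode's location is evidence about its item:
  `P(item k | m, l) ∝ π[m,k]·θ[k,l]` with `π[m,·] ∝ λ[m,·]`;
- `log λ[·,k]` follows a circular first-order Gaussian random walk over the
  12-month cycle (December adjacent to January) with per-item precision
  `τ[k] ~ Gamma(a, b)` — seasonal autocorrelation that stabilises sparse
  months — plus a Normal prior on the mean log level;
- `θ[k] ~ Dirichlet(α)`.

Inference is Gibbs sampling: multinomial reallocation of unidentified
episodes, conjugate Dirichlet updates of `θ`, Metropolis-within-Gibbs
updates of `log λ` and a conjugate Gamma update of `τ`.  MOPs are the
posterior-mean complete counts (identified + imputed), rounded to integers
and renormalised per month.

## Worked example

```python
import numpy as np
from avidiet import (MopModelSpec, default_truth, generate_episodes, tally,
                     fit_mop, rop_identified_only, total_variation)

truth = default_truth(seed=7)              # 12 months x 4 items x 3 locations,
episodes, _ = generate_episodes(truth)     # 40 episodes/month, 10-60%
counts = tally(episodes, truth.species, truth.schema)  # location-dependent missingness

spec = MopModelSpec(chains=2, iterations=4000, burn_in=1500, thinning=5, seed=7)
res = fit_mop(counts, spec)
print(res.summary())
print("TV(MOP, truth)       =", round(total_variation(res.mop(), truth.pi_true), 4))
print("TV(ROP_ident, truth) =", round(total_variation(rop_identified_only(counts), truth.pi_true), 4))
```

prints

```
Diet imputation model
============================================================
species:              synthetic species
episodes:             480 (160 unidentified, 33.3%)
items x locations:    4 x 3
chains/iter/burn/thin: 2/4000/1500/5
MH acceptance rate:   0.636
max split-R-hat:      1.017   min ESS: 197

Model-aided observation proportions (MOP):
       item1  item2  item3  item4  support
month
1      0.150  0.175  0.125  0.550       40
2      0.205  0.077  0.128  0.590       39
...
12     0.200  0.025  0.325  0.450       40

TV(MOP, truth)       = 0.1177
TV(ROP_ident, truth) = 0.1836
```

A third of the episodes had their item hidden, preferentially at
high-missingness locations; the imputed MOP sits markedly closer to the
true monthly diet (mean total-variation distance 0.118) than the
identified-only ROP (0.184), which is biased by the location-dependent
missingness.

The same analysis runs from the shell:

```bash
avidiet simulate --outdir sim --seed 7         # episodes.csv, stomach.csv, truth.json
avidiet report --config run.yaml               # full pipeline: tallies, ROPs,
                                               # MOPs, seasonal tests, RMSDs
```

where `run.yaml` points at the episode/stomach files and an output
directory and sets the master seed.

`avidiet.datasets` additionally ships the published per-species summary
tallies of the Kanagawa volunteer monitoring study of 15 resident birds
(episode totals, identified totals, monthly counts), which parameterise
realistic examples and the summary arithmetic.

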