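# Methods

## The model

`littsim` is a forward-time, individual-based simulator of ecological
speciation in the Galician *Littorina saxatilis* system: two shore
ecotypes (an upper-shore "Crab" form and a lower-shore "Wave" form)
that meet and hybridise in a narrow mid-shore band.  The shore is a
one-dimensional array of 26 demes in three habitats — 20 upper
(sheltered) demes, 2 intermediate demes forming the hybrid zone, and 4
lower (wave-exposed) demes.  Each deme `d` has an ecological optimum
`theta_d` (1, 0.5, 0 for upper, intermediate, lower) and a carrying
capacity `K_d` (3,750 for upper/intermediate, 15,000 for lower demes).
A `symmetric` control landscape equalises deme counts (12 + 2 + 12) and
uses a uniform per-deme K of 3,750; it exists to isolate the effect of
the Galician asymmetry in habitat extent and density.

Individuals are diploid with separate sexes and discrete,
non-overlapping generations.  Each carries:

- an **ecological magic trait** `x` in [0, 1]: L unlinked bi-allelic
  additive loci (alleles 0/1), phenotype = allele sum / 2L.  `x` sets
  viability in the local habitat *and* is the target of male mate
  choice;
- a **mating trait** `c` in [0, 1], same architecture, expressed in
  males as the preference `C = 2c - 1` (|C| is choosiness; C > 0
  positive assortment, C < 0 negative, C = 0 random mating);
- 8 neutral **microsatellite** loci under the stepwise mutation model.

There is no environmental variance; genotype and phenotype coincide.

The life cycle runs birth → viability → mating → migration →
reproduction → mutation:

1. **Viability.** A juvenile with trait `x` in deme `d` survives with
   probability `V = 1 / (1 + (b/2 - 1) N / (w K_d))`, where
   `w = exp(-(x - theta_d)^2 / (2 sigma_s^2))` is Gaussian fitness,
   `N` is the deme's juvenile count and `b` the mean brood size.
   In the *neutral-middle* scenario `w = 1` in the two intermediate
   demes.  At the Beverton–Holt fixed point with `w = 1`, the juvenile
   census settles at `K` and the adult census at `2K/b` (4% of K for
   b = 50).
2. **Mating.** Males choose within their deme.  Each male evaluates
   `N_f = 10` females sampled without replacement (all of them if fewer)
   through the FND preference
   `Psi = exp(-C^2 D^2 / (2 sigma_a^2 D_max^2))` for `C > 0`
   (with `(D - D_max)^2` for `C < 0`, and `Psi = 1` for `C = 0`), where
   `D = |x_male - x_female|` and `D_max = 1`.  Without cost, every male
   mates with exactly one candidate drawn with probability
   `Psi_j / sum(Psi)`; if every `Psi` underflows the choice is uniform,
   since the no-cost male mates unconditionally.  With cost, the male
   visits his candidates in random order and mates with probability
   `Psi` at each encounter; if all fail he stays unmated — the cost to
   choosiness.
3. **Migration.** Only mated (pregnant) females move: 0, 1 or 2 demes
   with probability 0.75 / 0.15 / 0.10, direction 50:50, one draw per
   female per generation.  A draw that would leave the shore is
   cancelled (the female stays); this keeps the "no move" mass intact
   at the shore ends instead of creating reflection currents.
4. **Reproduction.** Each mated pair contributes an independent
   Poisson(b = 50) brood born in the female's destination deme, with
   free segregation at every locus.  Females chosen by several males
   produce one brood per pair.
5. **Mutation.** Newborn trait alleles flip 0 <-> 1 at `mu` per copy;
   microsatellites mutate at `mu0` per copy, stepping ±1 with equal
   probability.

A replicate starts from the brood of a single immigrant female in the
most upper deme: 50 juveniles, homozygous at every trait locus with
`x = 1` (the local optimum) and `c = 0.5` exactly (half the mating loci
fixed for allele 1, half for 0; one heterozygous locus if L is odd),
and heterozygous at every microsatellite for two fixed starting states
(100/101 — the SMM only uses relative steps).  Sexes are independent
Bernoulli(1/2) throughout; the snail has separate sexes and no sex ratio
is imposed beyond the fair coin.

## Parameters

| name | meaning | default |
|---|---|---|
| `T` | generations | 20,000 |
| `b` | mean brood per mated pair | 50 |
| `N_f` | females evaluated per male | 10 |
| `sigma_s` | inverse selection strength | 0.45 (grid: 0.15, 0.45, 1) |
| `sigma_a` | mating-preference tolerance | 0.1 (grid: 0.05, 0.1) |
| `L` | loci per trait | 4 (grid: 4, 8) |
| `mu` | trait mutation rate / copy | 1e-5 |
| `mu0` | microsatellite rate / copy | 1e-3 |
| `middle_selective` | hybrid-zone selection | True |
| `cost` | cost to choosiness | False |
| `scale` | uniform multiplier on all K | 1.0 |
| `thin` | snapshot interval | 100 |

The grid of the factorial screen crosses `sigma_s`, `sigma_a`, `L` and
`middle_selective` (24 cells; 48 with the cost dimension), 20 replicates
per cell, seeds `base_seed + cell * replicates + replicate`.

## Desk-scale preset and its rescaling model

Full-scale runs cost hours per replicate, so the package ships a
desk-scale preset (`littsim.experiment.DESK_SCALE_PRESET`): `scale =
0.1` (all K shrunk tenfold) and `T = 2,000`.  This compresses both
population size and duration tenfold, which distorts the two slow
processes of the model unless rates are rescaled:

- the **trait mutation rate** is raised to `mu = 1e-3`
  (`mu / (scale * T_desk/T_full)` = 100x) so that the *total* adaptive
  mutational input of the compressed run — mutants per generation times
  generations — matches the full-scale experiment.  Adaptation here is
  mutation-limited (founders carry no trait variation), and total drift
  `T / N` is automatically preserved by the joint compression, so this
  is the coherent diffusion-style rescaling; selection and migration
  act on much shorter timescales than `T` and need no adjustment.
  Without it, nothing adapts within the compressed horizon at
  `scale = 0.1`.
- the **microsatellite rate** is raised to `mu0 = 1e-2` (10x), which
  preserves the standing neutral diversity `theta ~ 4 N mu0` that F_ST
  is computed from.  Neutral markers are observational, so the right
  invariant is diversity, not event totals.

What desk-scale runs preserve: the qualitative phase behaviour (fast
colonisation and adaptation under `sigma_s` in {0.45, 1}, the
asymmetric pull of the Galician middle habitat toward the exposed-shore
optimum, the symmetric control sitting near 0.5, high Q_ST with much
lower F_ST after adaptation).  What they distort: per-generation
mutation load and segregation variance are 100x the full-scale values,
which inflates within-habitat trait variance; means in mixture habitats
shift a few hundredths toward 0.5, drift is lumpier, and adaptation
waiting times are relatively more variable.  Quantitative desk-scale
results should therefore be read with roughly ±0.05 trait-unit
generosity relative to full-scale expectations; full-scale spot checks
(scale 1, `mu = 1e-5`) reproduce adaptation by ~400–1,000 generations,
a Galician middle-habitat mean `x` of ~0.15–0.25 and a neutral-middle
Q_ST of ~0.74.

## Statistics

All per-habitat summaries (mean `x`, mean `c`, mean choosiness, census,
mean fitness) are computed on the *juvenile cohort* of the recorded
generation — the population as born, whose census equilibrates at K.
The mating correlation `r` is the Pearson correlation of `x` between
partners over the mated pairs that produced that cohort, grouped by the
deme where the mating took place; it is defined as 0 when either
partner series is (near-)fixed and undefined below two pairs.

Differentiation between the three shore levels:

- `F_ST = 1 - mean(H_shore) / H_total` over the microsatellites, with
  expected heterozygosity `H = 1 - sum p_a^2` averaged over loci
  (observed-heterozygote H available behind a flag); empty shores are
  excluded and negative sampling estimates clamp to 0.
- `Q_ST = V_between / (V_between + 2 V_within)` for the ecological
  trait, with `V_between` the population variance of the three
  unweighted habitat means and `V_within` the unweighted mean of the
  within-habitat population variances.  The unweighted convention makes
  the toy cases exact and, at full scale, reproduces the neutral-middle
  value ~0.74; census-weighting `V_within` was evaluated and rejected
  because it cannot reproduce that value.

Outcome classifiers at the final generation: *adapted* when the
lower-shore mean `x` < 0.25; mate-choice class per habitat negative /
random / positive for mean `c` below 0.45 / inside the band / above
0.55; *ecological speciation* when the middle-shore mean `c` >= 0.9
jointly with `Q_ST >= 0.9`.  Time to adaptation is the first recorded
generation with lower-shore mean `x` < 0.25 (resolution = the thinning
interval).

## The factorial screen

`eta_squared_anova` fits a fixed-effects OLS with all main effects and
all two-way interactions of the four factors (statsmodels, type-II sums
of squares; the design is balanced by construction and unbalanced
tables are refused).  Each term's partial eta-squared
`SS_term / (SS_term + SS_error)` is normalised to % of the summed etas
so screens of different responses are comparable; significance is
flagged at 0.001.  The two largest interactions can be pulled out with
`top_interactions`.  The screen is exploratory — a variance-accounting
device, not hypothesis testing.

## Numerical choices

- One `numpy` PCG64 generator per replicate, seeded from `SimParams`;
  a replicate is a pure function of (params, landscape, seed).
- Mutation uses the exact Bernoulli-per-copy law, realised either as a
  dense mask or as a Binomial total with uniformly drawn distinct
  positions, switched on the expected event count.
- Males with exactly `C = 0` shortcut to uniform female choice, which
  is distributionally identical to evaluating candidates with
  `Psi == 1`; candidate subsets are drawn by key-ordering (uniform
  subset in uniform visiting order).
- In the no-cost scheme a candidate row whose `Psi` sum underflows to
  zero falls back to a uniform choice (the no-cost male must mate).
- The with-cost scheme uses sequential independent Bernoulli encounters;
  the additive "1 - sum(Psi)" description of the failure probability is
  its small-`Psi` approximation, and the sequential form keeps
  probabilities in [0, 1] when `sum(Psi) > 1`.
- `viability_mode="prefactor"` switches the survival formula to
  `V = w / (1 + (b/2 - 1) N / K)` for sensitivity analysis; the default
  reading lets fitness rescale the effective capacity, which makes
  survival increase with fitness at any density.
- Extinction (no juveniles anywhere, or no mating at all) terminates a
  replicate with the partial series kept and all classifiers false.

## Problem sizes used by the shipped tests and acceptance script

Unit and property tests run on toy populations and single demes within
seconds.  The acceptance script and the stochastic acceptance tests use
the desk-scale preset: 20 replicates per landscape for the
symmetric-vs-Galician middle-habitat comparison and a handful of
replicates for the adaptation-signature checks, about 10–15 minutes in
total on one CPU.  The full Table-scale grid (24 cells x 20 replicates
x 20,000 generations) is supported by `littsim grid` and
`FULL_SCALE_PRESET` but takes CPU-days; its headline aggregates
(colonisation and speciation percentages, Table-4-style choosiness
means, Q_ST by middle scenario) are recomputable from the persisted
records CSV with `littsim report`.

## Known limitations

- No linkage, recombination map or inversions; loci segregate freely.
- One-dimensional shore, kernel limited to ±2 demes, no homeward
  migration bias.
- Female choice, sperm pooling and multiple paternity per brood are not
  modelled; each mating pair contributes an independent brood.
- The desk-scale preset is a rescaled model, not a miniature of the
  full model; see the scaling section for what it does and does not
  preserve.
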