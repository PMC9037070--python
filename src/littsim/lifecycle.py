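"""The per-generation engine: viability, mating, migration, reproduction.

Generations are discrete and non-overlapping, with events in the order
birth, viability, mating, migration, reproduction, mutation.  A cohort of
juveniles born into each deme first passes Gaussian viability selection
combined with Beverton-Holt density regulation,

    w_i = exp(-(x_i - theta)^2 / (2 sigma_s^2)),
    V_i = 1 / (1 + (b/2 - 1) N / (w_i K)),

where N is the local juvenile count and K the deme's carrying capacity
(at the Beverton-Holt fixed point with w = 1 the juvenile census settles
at K and the adult census at 2K/b).  Survivors become the adults; males
then choose mates within their deme through the FND preference function

    Psi = exp(-C^2 D^2 / (2 sigma_a^2 D_max^2))          if C > 0,
          1                                               if C = 0,
          exp(-C^2 (D - D_max)^2 / (2 sigma_a^2 D_max^2)) if C < 0,

with C = 2c - 1 and D = |x_male - x_female|.  Without cost every male
mates with exactly one of the N_f females he samples, with probability
proportional to Psi; with cost each encounter succeeds with probability
Psi itself and a choosy male may stay unmated.  Mated (pregnant) females
may then migrate 0-2 demes, each mated pair contributes a Poisson(b)
brood born in the female's destination deme, and newborns mutate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import stats as _stats
from .genetics import (Cohort, gametes_from_parents, make_founder_brood,
                       mutate_microsats, mutate_trait_alleles)
from .landscape import (HABITAT_LABELS, Landscape, MigrationKernel,
                        build_landscape, migrate_females)

__all__ = [
    "SimParams",
    "SimState",
    "ReplicateResult",
    "fitness",
    "survival_probability",
    "viability_survival",
    "psi_fnd",
    "choice_probabilities",
    "unmated_probability",
    "sample_candidates",
    "mate_deme_no_cost",
    "mate_deme_with_cost",
    "reproduce_pair",
    "generation_step",
    "run_replicate",
]


@dataclass(frozen=True)
class SimParams:
    """All model parameters plus scenario flags and the RNG seed.

    Defaults follow the full-scale Galician configuration: 20,000
    generations, Poisson mean brood b = 50, N_f = 10 females evaluated
    per male, trait/microsatellite mutation rates 1e-5 / 1e-3, and the
    (0.75, 0.15, 0.10) migration kernel.
    """

    T: int = 20_000
    b: float = 50.0
    N_f: int = 10
    sigma_s: float = 0.45
    sigma_a: float = 0.1
    mu: float = 1e-5
    mu0: float = 1e-3
    L: int = 4
    n_msat: int = 8
    middle_selective: bool = True
    cost: bool = False
    landscape_kind: str = "galician"
    scale: float = 1.0
    seed: int = 0
    founder_n: int = 50
    thin: int = 100
    kernel: MigrationKernel = field(default_factory=MigrationKernel)
    viability_mode: str = "capacity"  # or "prefactor"

    def __post_init__(self) -> None:
        if self.T < 0 or self.b < 0 or self.N_f < 1 or self.L < 1:
            raise ValueError("T, b must be >= 0; N_f, L must be >= 1")
        if self.sigma_s <= 0 or self.sigma_a <= 0:
            raise ValueError("sigma_s and sigma_a must be positive")
        for rate in (self.mu, self.mu0):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("mutation rates must lie in [0, 1]")
        if self.viability_mode not in ("capacity", "prefactor"):
            raise ValueError("viability_mode must be 'capacity' or 'prefactor'")

    def make_landscape(self) -> Landscape:
        return build_landscape(self.landscape_kind, self.scale, self.middle_selective)


# ----------------------------------------------------------------------
# kernels


def fitness(x, theta, sigma_s):
    """Gaussian stabilising fitness around the local optimum (w = 1 at
    x = theta; sigma_s is the inverse selection strength)."""
    if np.any(np.asarray(sigma_s) <= 0):
        raise ValueError("sigma_s must be positive")
    x = np.asarray(x, dtype=float)
    d = x - theta
    return np.exp(-(d * d) / (2.0 * sigma_s ** 2))


def survival_probability(w, N, b, K, mode: str = "capacity"):
    """Beverton-Holt juvenile survival probability.

    ``capacity`` (default): V = 1 / (1 + (b/2 - 1) N / (w K)) — fitness
    rescales the effective capacity.  ``prefactor``: V = w / (1 +
    (b/2 - 1) N / K), kept for sensitivity analysis.  w = 0 gives V = 0.
    """
    w = np.asarray(w, dtype=float)
    N = np.asarray(N, dtype=float)
    crowd = (b / 2.0 - 1.0) * N / np.asarray(K, dtype=float)
    if mode == "capacity":
        with np.errstate(divide="ignore"):
            v = 1.0 / (1.0 + crowd / w)
        return np.where(w > 0.0, v, 0.0)
    if mode == "prefactor":
        return w / (1.0 + crowd)
    raise ValueError("mode must be 'capacity' or 'prefactor'")


def viability_survival(w, N, b, K, rng: np.random.Generator, mode: str = "capacity"):
    """Bernoulli survival draw(s) at the Beverton-Holt probability."""
    if np.any(np.asarray(N) < 1):
        raise ValueError("N counts all local juveniles including self; must be >= 1")
    v = survival_probability(w, N, b, K, mode)
    return rng.random(np.shape(v) if np.ndim(v) else None) < v


def psi_fnd(c, D, sigma_a, D_max: float = 1.0):
    """FND mating preference of a male with trait c for a partner at
    ecological distance D = |x_m - x_f| (see module docstring).

    Broadcasts over c and D; returns values in [0, 1] with Psi = 1 for a
    random mater (C = 0), for a maximally positive-assortative male at
    D = 0 and for a maximally negative-assortative male at D = D_max.
    """
    if sigma_a <= 0:
        raise ValueError("sigma_a must be positive")
    c = np.asarray(c, dtype=float)
    D = np.asarray(D, dtype=float)
    if np.any(c < 0) or np.any(c > 1):
        raise ValueError("mating trait c must lie in [0, 1]")
    if np.any(D < 0) or np.any(D > D_max):
        raise ValueError("distance D must lie in [0, D_max]")
    C = 2.0 * c - 1.0
    denom = 2.0 * sigma_a ** 2 * D_max ** 2
    C2 = C * C
    pos = np.exp(-C2 * D * D / denom)
    neg = np.exp(-C2 * (D - D_max) ** 2 / denom)
    out = np.where(C > 0, pos, np.where(C < 0, neg, 1.0))
    return out if out.ndim else float(out)


def choice_probabilities(psi: np.ndarray) -> np.ndarray:
    """No-cost choice: probabilities proportional to Psi across the
    sampled candidates (uniform if every Psi underflows to zero, since a
    male without cost always mates)."""
    psi = np.asarray(psi, dtype=float)
    total = psi.sum()
    if total == 0.0:
        return np.full(psi.shape, 1.0 / psi.size)
    return psi / total


def unmated_probability(psi: np.ndarray) -> float:
    """With-cost mating: probability that every encounter fails when each
    succeeds independently with probability Psi."""
    psi = np.asarray(psi, dtype=float)
    return float(np.prod(1.0 - psi))


# ----------------------------------------------------------------------
# within-deme mating


def sample_candidates(n_males: int, n_females: int, N_f: int,
                      rng: np.random.Generator) -> np.ndarray:
    """For each male, a uniform random sample (without replacement, in
    random order) of min(N_f, n_females) female indices."""
    k = min(N_f, n_females)
    keys = rng.random((n_males, n_females))
    if k == n_females:
        return np.argsort(keys, axis=1, kind="stable")
    # uniform k-subset via smallest keys, then order the k by key so the
    # visiting order is itself uniformly random
    part = np.argpartition(keys, k - 1, axis=1)[:, :k]
    order = np.argsort(np.take_along_axis(keys, part, axis=1), axis=1)
    return np.take_along_axis(part, order, axis=1)


def _psi_matrix(c_m: np.ndarray, D: np.ndarray, sigma_a: float) -> np.ndarray:
    C = 2.0 * c_m[:, None] - 1.0
    denom = 2.0 * sigma_a ** 2
    C2 = C * C
    pos = np.exp(-C2 * D * D / denom)
    neg = np.exp(-C2 * (D - 1.0) ** 2 / denom)
    return np.where(C > 0, pos, np.where(C < 0, neg, 1.0))


def mate_deme_no_cost(x_m, c_m, x_f, sigma_a: float, N_f: int,
                      rng: np.random.Generator):
    """Mate every male in a deme under the no-cost scheme.

    Each male samples min(N_f, #females) candidates and mates with
    exactly one, chosen with probability Psi_j / sum(Psi); if the sum
    underflows to zero the choice is uniform.  Returns (male_idx,
    female_idx) index arrays into the deme's male/female lists; every
    male appears once.
    """
    x_m = np.asarray(x_m, float); c_m = np.asarray(c_m, float)
    x_f = np.asarray(x_f, float)
    n_m, n_f = x_m.size, x_f.size
    if n_f == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    fem = np.empty(n_m, dtype=np.int64)
    # a random mater (C = 0) has Psi = 1 for every candidate, so his
    # choice is uniform over the deme's females -- no need to sample
    choosy = np.flatnonzero(c_m != 0.5)
    random_maters = c_m == 0.5
    if random_maters.any():
        fem[random_maters] = rng.integers(0, n_f, int(random_maters.sum()))
    if choosy.size:
        cand = sample_candidates(choosy.size, n_f, N_f, rng)
        D = np.abs(x_m[choosy, None] - x_f[cand])
        psi = _psi_matrix(c_m[choosy], D, sigma_a)
        totals = psi.sum(axis=1)
        zero = totals == 0.0
        if zero.any():
            psi[zero] = 1.0
            totals = psi.sum(axis=1)
        cum = np.cumsum(psi, axis=1)
        u = rng.random(choosy.size) * totals
        j = np.minimum((u[:, None] >= cum).sum(axis=1), cand.shape[1] - 1)
        fem[choosy] = cand[np.arange(choosy.size), j]
    return np.arange(n_m, dtype=np.int64), fem


def mate_deme_with_cost(x_m, c_m, x_f, sigma_a: float, N_f: int,
                        rng: np.random.Generator):
    """Mate the deme's males under the cost-to-choosiness scheme.

    Each male visits his sampled candidates in random order and mates
    with probability Psi at each encounter, stopping at the first
    success; males whose every encounter fails stay unmated.  Returns
    (male_idx, female_idx) for the successful males only.
    """
    x_m = np.asarray(x_m, float); c_m = np.asarray(c_m, float)
    x_f = np.asarray(x_f, float)
    n_m, n_f = x_m.size, x_f.size
    if n_f == 0 or n_m == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    fem = np.empty(n_m, dtype=np.int64)
    mated = np.zeros(n_m, dtype=bool)
    # random maters (Psi = 1) succeed at the first encounter, which is a
    # uniform female
    random_maters = c_m == 0.5
    if random_maters.any():
        mated[random_maters] = True
        fem[random_maters] = rng.integers(0, n_f, int(random_maters.sum()))
    choosy = np.flatnonzero(~random_maters)
    if choosy.size:
        cand = sample_candidates(choosy.size, n_f, N_f, rng)
        D = np.abs(x_m[choosy, None] - x_f[cand])
        psi = _psi_matrix(c_m[choosy], D, sigma_a)
        success = rng.random(psi.shape) < psi
        ok = success.any(axis=1)
        first = success.argmax(axis=1)
        mated[choosy] = ok
        fem[choosy[ok]] = cand[ok, first[ok]]
    males = np.flatnonzero(mated)
    return males, fem[males]


# ----------------------------------------------------------------------
# reproduction


def reproduce_pair(male_parts, female_parts, b: float, rng: np.random.Generator,
                   deme: int = 0):
    """Brood of a single mated pair: Poisson(b) offspring, each formed
    from one independent gamete of each parent.  ``*_parts`` are
    (eco, mate, msat) diploid arrays of the parent.  Returns a Cohort.
    """
    n_off = int(rng.poisson(b))
    return _make_brood(male_parts, female_parts,
                       np.zeros(n_off, np.int64), np.zeros(n_off, np.int64),
                       np.full(n_off, deme, np.int64), rng)


def _make_brood(father_arrays, mother_arrays, father_idx, mother_idx, demes,
                rng: np.random.Generator) -> Cohort:
    f_eco, f_mate, f_msat = father_arrays
    m_eco, m_mate, m_msat = mother_arrays
    if f_eco.ndim == 2:  # single-parent convenience (L, 2) -> (1, L, 2)
        f_eco, f_mate, f_msat = f_eco[None], f_mate[None], f_msat[None]
        m_eco, m_mate, m_msat = m_eco[None], m_mate[None], m_msat[None]
    eco = np.stack([gametes_from_parents(f_eco, father_idx, rng),
                    gametes_from_parents(m_eco, mother_idx, rng)], axis=2)
    mate = np.stack([gametes_from_parents(f_mate, father_idx, rng),
                     gametes_from_parents(m_mate, mother_idx, rng)], axis=2)
    msat = np.stack([gametes_from_parents(f_msat, father_idx, rng),
                     gametes_from_parents(m_msat, mother_idx, rng)], axis=2)
    sex = rng.integers(0, 2, size=father_idx.size).astype(np.uint8)
    return Cohort(eco, mate, msat, sex, demes)


# ----------------------------------------------------------------------
# the generation engine


@dataclass
class Matings:
    """The pairs that produced the current juvenile cohort."""

    x_male: np.ndarray
    x_female: np.ndarray
    deme: np.ndarray  # deme where the mating took place


@dataclass
class SimState:
    """Juvenile cohort at the start of a generation."""

    cohort: Cohort
    generation: int = 0
    matings: Optional[Matings] = None
    extinct: bool = False


def generation_step(state: SimState, params: SimParams, landscape: Landscape,
                    rng: np.random.Generator) -> SimState:
    """Advance one full life cycle: viability -> mating -> migration ->
    reproduction -> mutation.  Returns the next generation's state."""
    juv = state.cohort
    if juv.n == 0:
        return SimState(juv, state.generation + 1, None, extinct=True)

    # --- viability: Gaussian selection x Beverton-Holt regulation
    x = juv.x
    theta_d = landscape.theta[juv.deme]
    w = np.where(landscape.selective[juv.deme],
                 fitness(x, theta_d, params.sigma_s), 1.0)
    counts = np.bincount(juv.deme, minlength=landscape.n_demes)
    v = survival_probability(w, counts[juv.deme], params.b,
                             landscape.K[juv.deme], params.viability_mode)
    alive = rng.random(juv.n) < v
    adults = juv.subset(alive)
    if adults.n == 0:
        return SimState(Cohort.empty(params.L, params.n_msat),
                        state.generation + 1, None, extinct=True)
    x_a = adults.x
    c_a = adults.c

    # --- within-deme mate choice (males choose)
    mate_fn = mate_deme_with_cost if params.cost else mate_deme_no_cost
    male_pool: list[np.ndarray] = []
    female_pool: list[np.ndarray] = []
    order = np.argsort(adults.deme, kind="stable")
    deme_sorted = adults.deme[order]
    starts = np.searchsorted(deme_sorted, np.arange(landscape.n_demes + 1))
    for d in range(landscape.n_demes):
        members = order[starts[d]:starts[d + 1]]
        if members.size == 0:
            continue
        males = members[adults.sex[members] == 0]
        females = members[adults.sex[members] == 1]
        if males.size == 0 or females.size == 0:
            continue
        mi, fi = mate_fn(x_a[males], c_a[males], x_a[females],
                         params.sigma_a, params.N_f, rng)
        male_pool.append(males[mi])
        female_pool.append(females[fi])
    if not male_pool:
        return SimState(Cohort.empty(params.L, params.n_msat),
                        state.generation + 1, None, extinct=True)
    sires = np.concatenate(male_pool)
    dams = np.concatenate(female_pool)
    matings = Matings(x_male=x_a[sires], x_female=x_a[dams],
                      deme=adults.deme[sires].copy())

    # --- migration: each pregnant female draws one destination
    uniq_dams, inv = np.unique(dams, return_inverse=True)
    dest_uniq = migrate_females(adults.deme[uniq_dams], params.kernel,
                                landscape.n_demes, rng)
    pair_dest = dest_uniq[inv]

    # --- reproduction: Poisson(b) brood per mated pair
    brood = rng.poisson(params.b, size=sires.size)
    rep = np.repeat(np.arange(sires.size), brood)
    if rep.size == 0:
        return SimState(Cohort.empty(params.L, params.n_msat),
                        state.generation + 1, matings, extinct=True)
    sire_idx, dam_idx = sires[rep], dams[rep]
    both = np.concatenate([sire_idx, dam_idx])
    n_off = rep.size
    # both traits share one gather, and both parents one call
    traits_par = np.concatenate([adults.eco, adults.mate], axis=1)
    tg = gametes_from_parents(traits_par, both, rng)
    traits = np.stack([tg[:n_off], tg[n_off:]], axis=2)
    mg = gametes_from_parents(adults.msat, both, rng)
    msat = np.stack([mg[:n_off], mg[n_off:]], axis=2)

    # --- mutation on the newborn cohort
    mutate_trait_alleles(traits, params.mu, rng, inplace=True)
    mutate_microsats(msat, params.mu0, rng, inplace=True)

    sex = rng.integers(0, 2, size=rep.size).astype(np.uint8)
    newborn = Cohort(traits[:, :params.L, :], traits[:, params.L:, :],
                     msat, sex, pair_dest[rep])
    return SimState(newborn, state.generation + 1, matings)


# ----------------------------------------------------------------------
# replicate runner


@dataclass
class ReplicateResult:
    params: SimParams
    summary: _stats.ReplicateSummary
    series: pd.DataFrame
    final: SimState


_SHORT = {"upper_sheltered": "upper", "intermediate": "middle",
          "lower_exposed": "lower"}


def _snapshot_row(state: SimState, params: SimParams, landscape: Landscape) -> dict:
    cohort = state.cohort
    row: dict = {"generation": state.generation, "total_census": cohort.n}
    x = cohort.x
    c = cohort.c
    hab_of_deme = landscape.habitat
    hab = hab_of_deme[cohort.deme] if cohort.n else np.empty(0, np.int8)
    theta_d = landscape.theta[cohort.deme] if cohort.n else np.empty(0)
    sel_d = landscape.selective[cohort.deme] if cohort.n else np.empty(0, bool)
    w = np.where(sel_d, fitness(x, theta_d, params.sigma_s), 1.0) if cohort.n else np.empty(0)
    groups_x = []
    msat_by_shore = []
    for code, label in enumerate(HABITAT_LABELS):
        s = _SHORT[label]
        mask = hab == code
        n_hab = int(mask.sum())
        row[f"N_{s}"] = n_hab
        if n_hab:
            row[f"x_{s}"] = float(x[mask].mean())
            row[f"c_{s}"] = float(c[mask].mean())
            row[f"choosiness_{s}"] = float(np.abs(2.0 * c[mask] - 1.0).mean())
            row[f"w_{s}"] = float(w[mask].mean())
            groups_x.append(x[mask])
            msat_by_shore.append(cohort.msat[mask])
        else:
            row[f"x_{s}"] = np.nan
            row[f"c_{s}"] = np.nan
            row[f"choosiness_{s}"] = np.nan
            row[f"w_{s}"] = np.nan
        if state.matings is not None:
            pm = hab_of_deme[state.matings.deme] == code
            row[f"r_{s}"] = (_stats.mating_correlation(state.matings.x_male[pm],
                                                       state.matings.x_female[pm])
                             if pm.sum() >= 2 else np.nan)
        else:
            row[f"r_{s}"] = np.nan
    row["fst"] = _stats.fst_microsat(msat_by_shore) if msat_by_shore else np.nan
    row["qst"] = _stats.qst_trait(groups_x) if len(groups_x) >= 2 else np.nan
    return row


def _summarise(series: pd.DataFrame, final_row: dict, extinct: bool,
               generations_run: int) -> _stats.ReplicateSummary:
    habitats = {}
    for label in HABITAT_LABELS:
        s = _SHORT[label]
        habitats[label] = _stats.HabitatSummary(
            habitat=label, mean_x=final_row[f"x_{s}"], mean_c=final_row[f"c_{s}"],
            mean_choosiness=final_row[f"choosiness_{s}"], census=final_row[f"N_{s}"],
            mating_r=final_row[f"r_{s}"], mean_fitness=final_row[f"w_{s}"])
    summary = _stats.ReplicateSummary(
        habitats=habitats, fst=final_row["fst"], qst=final_row["qst"],
        extinct=extinct, generations_run=generations_run,
        time_to_adaptation=_stats.time_to_adaptation(
            series["generation"].to_numpy(), series["x_lower"].to_numpy()))
    return _stats.classify_outcomes(summary)


def run_replicate(params: SimParams, landscape: Optional[Landscape] = None,
                  rng: Optional[np.random.Generator] = None) -> ReplicateResult:
    """Run one replicate: founder brood in the most upper sheltered deme,
    T generations, thinned per-habitat time series and a final summary.

    A replicate is a pure function of (params, landscape, seed): the same
    seed reproduces bit-identical output.
    """
    if landscape is None:
        landscape = params.make_landscape()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    state = SimState(make_founder_brood(params.founder_n, params.L, rng,
                                        params.n_msat, deme=0))
    rows = [_snapshot_row(state, params, landscape)]
    extinct = False
    for t in range(1, params.T + 1):
        state = generation_step(state, params, landscape, rng)
        if state.extinct:
            extinct = True
            rows.append(_snapshot_row(state, params, landscape))
            break
        if t % params.thin == 0 or t == params.T:
            rows.append(_snapshot_row(state, params, landscape))
    series = pd.DataFrame(rows)
    summary = _summarise(series, rows[-1], extinct, state.generation)
    return ReplicateResult(params=params, summary=summary, series=series,
                           final=state)
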