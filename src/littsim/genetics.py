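"""Genomes, phenotypes, gamete formation and mutation.

Individuals are diploid with two additive quantitative traits — an
ecological magic trait ``x`` (the target of both viability selection and
male mate choice) and a male mating trait ``c`` — each encoded by ``L``
unlinked bi-allelic loci with allelic values 0/1, plus a panel of neutral
microsatellite loci evolving under the stepwise mutation model (SMM).
There is no environmental variance: genotypic and phenotypic values
coincide, and a trait value is the allele sum scaled into [0, 1].

Populations are held as a :class:`Cohort`, a struct-of-arrays container
(one row per individual) so that the per-generation engine can operate on
whole cohorts with vectorised numpy.  :class:`Individual` is a light
per-row view used by fixtures and small tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TraitArchitecture",
    "IndividualGenome",
    "Individual",
    "Cohort",
    "Choosiness",
    "compute_trait_value",
    "choosiness",
    "make_gamete",
    "gametes_from_parents",
    "mutate_trait_alleles",
    "mutate_microsats",
    "make_founder_brood",
    "write_population",
    "read_population",
]

MALE = 0
FEMALE = 1

#: Founder microsatellite heterozygote states.  The SMM only cares about
#: relative repeat steps, so the absolute values are arbitrary constants.
FOUNDER_MSAT_STATES = (100, 101)


@dataclass(frozen=True)
class TraitArchitecture:
    """Number of loci behind each trait and the microsatellite panel size."""

    loci_per_trait: int = 4
    microsat_loci: int = 8

    def __post_init__(self) -> None:
        if self.loci_per_trait < 1:
            raise ValueError("loci_per_trait must be >= 1")
        if self.microsat_loci < 1:
            raise ValueError("microsat_loci must be >= 1")


@dataclass
class IndividualGenome:
    """Diploid allele matrices for one individual.

    ``eco`` and ``mate`` are (L, 2) binary matrices; ``msat`` is an
    (M, 2) integer matrix of repeat counts.
    """

    eco: np.ndarray
    mate: np.ndarray
    msat: np.ndarray

    def __post_init__(self) -> None:
        self.eco = _validate_binary(np.asarray(self.eco))
        self.mate = _validate_binary(np.asarray(self.mate))
        self.msat = np.asarray(self.msat)
        if self.msat.ndim != 2 or self.msat.shape[1] != 2:
            raise ValueError("msat must be an (M, 2) matrix")
        if np.any(self.msat <= 0):
            raise ValueError("microsatellite states must be positive integers")


@dataclass
class Individual:
    """One diploid individual: genome, sex and derived phenotypes."""

    genome: IndividualGenome
    sex: int
    deme: int = 0

    @property
    def x(self) -> float:
        return float(compute_trait_value(self.genome.eco))

    @property
    def c(self) -> float:
        return float(compute_trait_value(self.genome.mate))


class Cohort:
    """A population slice stored column-wise for vectorised processing.

    Arrays (first axis = individuals):

    - ``eco``:  (n, L, 2) uint8 ecological-trait alleles
    - ``mate``: (n, L, 2) uint8 mating-trait alleles
    - ``msat``: (n, M, 2) int32 microsatellite repeat states
    - ``sex``:  (n,) uint8, 0 = male, 1 = female
    - ``deme``: (n,) int32 deme of residence
    """

    __slots__ = ("eco", "mate", "msat", "sex", "deme")

    def __init__(self, eco, mate, msat, sex, deme):
        self.eco = np.asarray(eco, dtype=np.uint8)
        self.mate = np.asarray(mate, dtype=np.uint8)
        self.msat = np.asarray(msat, dtype=np.int32)
        self.sex = np.asarray(sex, dtype=np.uint8)
        self.deme = np.asarray(deme, dtype=np.int32)
        n = self.eco.shape[0]
        if not (self.mate.shape[0] == self.msat.shape[0] == self.sex.shape[0] == self.deme.shape[0] == n):
            raise ValueError("all cohort arrays must share the first dimension")

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return int(self.eco.shape[0])

    def __len__(self) -> int:
        return self.n

    @property
    def x(self) -> np.ndarray:
        """Ecological trait values, recomputed from the genome."""
        return compute_trait_value(self.eco, validate=False)

    @property
    def c(self) -> np.ndarray:
        """Mating trait values, recomputed from the genome."""
        return compute_trait_value(self.mate, validate=False)

    def subset(self, index) -> "Cohort":
        return Cohort(self.eco[index], self.mate[index], self.msat[index],
                      self.sex[index], self.deme[index])

    @classmethod
    def empty(cls, L: int, n_msat: int = 8) -> "Cohort":
        return cls(np.empty((0, L, 2), np.uint8), np.empty((0, L, 2), np.uint8),
                   np.empty((0, n_msat, 2), np.int32), np.empty(0, np.uint8),
                   np.empty(0, np.int32))

    @classmethod
    def concatenate(cls, cohorts: Sequence["Cohort"]) -> "Cohort":
        return cls(np.concatenate([c.eco for c in cohorts]),
                   np.concatenate([c.mate for c in cohorts]),
                   np.concatenate([c.msat for c in cohorts]),
                   np.concatenate([c.sex for c in cohorts]),
                   np.concatenate([c.deme for c in cohorts]))

    def individuals(self) -> Iterable[Individual]:
        for i in range(self.n):
            yield Individual(
                IndividualGenome(self.eco[i].copy(), self.mate[i].copy(), self.msat[i].copy()),
                sex=int(self.sex[i]), deme=int(self.deme[i]))

    @classmethod
    def from_individuals(cls, inds: Sequence[Individual]) -> "Cohort":
        return cls(np.stack([i.genome.eco for i in inds]),
                   np.stack([i.genome.mate for i in inds]),
                   np.stack([i.genome.msat for i in inds]),
                   np.array([i.sex for i in inds]),
                   np.array([i.deme for i in inds]))


# ----------------------------------------------------------------------
# phenotypes


def _validate_binary(alleles: np.ndarray) -> np.ndarray:
    if not np.isin(alleles, (0, 1)).all():
        raise ValueError("trait alleles must be 0 or 1")
    return alleles


def compute_trait_value(alleles, validate: bool = True):
    """Additive trait value: allele sum over all 2L copies, divided by 2L.

    Accepts a single (L, 2) genotype or a stacked (n, L, 2) batch; returns
    a scalar or an (n,) float array in [0, 1], quantised in steps of
    1/(2L).
    """
    a = np.asarray(alleles)
    if validate:
        _validate_binary(a)
    if a.ndim == 2:
        return a.sum(dtype=np.float64) / a.size
    if a.ndim == 3:
        two_l = a.shape[1] * a.shape[2]
        return a.sum(axis=(1, 2), dtype=np.float64) / two_l
    raise ValueError("alleles must be (L, 2) or (n, L, 2)")


@dataclass(frozen=True)
class Choosiness:
    C: float
    choosiness: float
    regime: str  # "negative" | "random" | "positive"


def choosiness(c: float) -> Choosiness:
    """Map the mating-trait phenotype c onto preference sign and strength.

    C = 2c - 1; its absolute value is the choosiness and its sign the
    mating regime: C = 0 random mating, C > 0 positive assortment
    (preference for similar x), C < 0 negative assortment.
    """
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"mating trait c must lie in [0, 1], got {c}")
    C = 2.0 * c - 1.0
    regime = "random" if C == 0 else ("positive" if C > 0 else "negative")
    return Choosiness(C=C, choosiness=abs(C), regime=regime)


# ----------------------------------------------------------------------
# gametes


def make_gamete(genome: IndividualGenome, rng: np.random.Generator):
    """Form one haploid gamete by free segregation at every locus.

    Each trait locus and each microsatellite independently transmits one
    of its two allele copies with probability 1/2 (no linkage).  Returns
    ``(eco, mate, msat)`` haploid arrays.
    """
    eco = _segregate(genome.eco, rng)
    mate = _segregate(genome.mate, rng)
    msat = _segregate(genome.msat, rng)
    return eco, mate, msat


def _segregate(diploid: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    picks = rng.integers(0, 2, size=diploid.shape[0])
    return diploid[np.arange(diploid.shape[0]), picks]


def gametes_from_parents(alleles: np.ndarray, parent_idx: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    """Batched free segregation: one gamete per entry of ``parent_idx``.

    ``alleles`` is the parental (n_par, L, 2) array; returns (n_off, L)
    haploid picks, each locus drawn independently.
    """
    n_off = parent_idx.shape[0]
    n_loci = alleles.shape[1]
    picks = _random_bits(n_off, n_loci, rng)
    flat = np.ascontiguousarray(alleles).reshape(-1)
    locus_offset = np.arange(n_loci) * 2
    return flat[(parent_idx * (2 * n_loci))[:, None] + locus_offset[None, :] + picks]


def _random_bits(n_rows: int, n_cols: int, rng: np.random.Generator) -> np.ndarray:
    """(n_rows, n_cols) iid fair bits, drawn bytewise for speed."""
    n_bytes = (n_cols + 7) // 8
    raw = rng.integers(0, 256, size=(n_rows, n_bytes), dtype=np.uint8)
    return np.unpackbits(raw, axis=1)[:, :n_cols]


# ----------------------------------------------------------------------
# mutation

# Below this expected event count, mutations are placed by drawing the
# Binomial total and distinct uniform positions (same law, far fewer draws).
_SPARSE_EVENT_LIMIT = 256.0


def _bernoulli_sites(n_sites: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Flat indices of sites hit by an independent Bernoulli(rate) process."""
    if rate * n_sites <= _SPARSE_EVENT_LIMIT and rate < 0.1:
        k = rng.binomial(n_sites, rate)
        if k == 0:
            return np.empty(0, dtype=np.int64)
        return rng.choice(n_sites, size=k, replace=False)
    return np.flatnonzero(rng.random(n_sites) < rate)


def mutate_trait_alleles(alleles: np.ndarray, mu: float, rng: np.random.Generator,
                         inplace: bool = False) -> np.ndarray:
    """Flip each of the allele copies 0<->1 independently with probability mu."""
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mutation rate must lie in [0, 1]")
    out = alleles if inplace else alleles.copy()
    if mu == 0.0 or out.size == 0:
        return out
    if not out.flags.c_contiguous:  # reshape would silently copy
        out = np.ascontiguousarray(out)
    flat = out.reshape(-1)
    sites = _bernoulli_sites(flat.size, mu, rng)
    flat[sites] ^= 1
    if out is not alleles and inplace:
        alleles[...] = out
        return alleles
    return out


def mutate_microsats(msat: np.ndarray, mu0: float, rng: np.random.Generator,
                     inplace: bool = False) -> np.ndarray:
    """Stepwise mutation model: each allele copy mutates with probability
    mu0, changing its repeat count by +1 or -1 with equal probability."""
    if not 0.0 <= mu0 <= 1.0:
        raise ValueError("mutation rate must lie in [0, 1]")
    out = msat if inplace else msat.copy()
    if mu0 == 0.0 or out.size == 0:
        return out
    if not out.flags.c_contiguous:
        out = np.ascontiguousarray(out)
    flat = out.reshape(-1)
    sites = _bernoulli_sites(flat.size, mu0, rng)
    if sites.size:
        steps = rng.integers(0, 2, size=sites.size).astype(np.int32) * 2 - 1
        flat[sites] += steps
    if out is not msat and inplace:
        msat[...] = out
        return msat
    return out


# ----------------------------------------------------------------------
# founder population


def make_founder_brood(n: int, L: int, rng: np.random.Generator,
                       n_msat: int = 8, deme: int = 0) -> Cohort:
    """The brood of the single colonising female: n juveniles in the most
    upper sheltered deme.

    Every individual is homozygous 1/1 at all ecological loci (x = 1, the
    sheltered-habitat optimum) and homozygous at the mating loci with half
    of them fixed for 1 and half for 0, so that c = 0.5 exactly (random
    mating).  For odd L one mating locus is made heterozygous to keep
    c = 0.5 exact.  Every microsatellite locus is heterozygous for the two
    fixed starting states.  Sexes are independent Bernoulli(1/2).
    """
    if n < 1:
        raise ValueError("founder brood size must be >= 1")
    eco = np.ones((n, L, 2), dtype=np.uint8)
    mate = np.zeros((n, L, 2), dtype=np.uint8)
    half = L // 2
    mate[:, :half, :] = 1
    if L % 2 == 1:
        mate[:, half, 0] = 1  # heterozygous middle locus keeps c at 1/2
    msat = np.empty((n, n_msat, 2), dtype=np.int32)
    msat[:, :, 0] = FOUNDER_MSAT_STATES[0]
    msat[:, :, 1] = FOUNDER_MSAT_STATES[1]
    sex = rng.integers(0, 2, size=n).astype(np.uint8)
    deme_arr = np.full(n, deme, dtype=np.int32)
    return Cohort(eco, mate, msat, sex, deme_arr)


# ----------------------------------------------------------------------
# tab-separated fixture interchange


def write_population(path, cohort: Cohort) -> None:
    """Write a cohort as tab-separated text (one row per individual)."""
    with open(path, "w") as fh:
        fh.write("id\tdeme\tsex\teco_h1\teco_h2\tmate_h1\tmate_h2\tmsat\n")
        for i in range(cohort.n):
            eco_h = ["".join(map(str, cohort.eco[i, :, j])) for j in (0, 1)]
            mate_h = ["".join(map(str, cohort.mate[i, :, j])) for j in (0, 1)]
            msat = "|".join(f"{a}/{b}" for a, b in cohort.msat[i])
            fh.write(f"{i}\t{cohort.deme[i]}\t{cohort.sex[i]}\t"
                     f"{eco_h[0]}\t{eco_h[1]}\t{mate_h[0]}\t{mate_h[1]}\t{msat}\n")


def read_population(path) -> Cohort:
    """Read a cohort previously written by :func:`write_population`."""
    eco, mate, msat, sex, deme = [], [], [], [], []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("id\t"):
            raise ValueError("not a population table")
        for line in fh:
            _, d, s, e1, e2, m1, m2, ms = line.rstrip("\n").split("\t")
            deme.append(int(d))
            sex.append(int(s))
            eco.append(np.stack([[int(ch) for ch in e1], [int(ch) for ch in e2]], axis=1))
            mate.append(np.stack([[int(ch) for ch in m1], [int(ch) for ch in m2]], axis=1))
            msat.append([[int(a) for a in pair.split("/")] for pair in ms.split("|")])
    return Cohort(np.array(eco), np.array(mate), np.array(msat), sex, deme)
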