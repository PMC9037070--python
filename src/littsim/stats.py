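"""Summary statistics, differentiation indices and outcome classifiers.

Differentiation between shore levels is measured two ways: neutrally,
with F_ST over the microsatellite panel,

    F_ST = 1 - mean(H_shore) / H_total,

where H is expected heterozygosity (1 - sum p_a^2, averaged over loci)
computed per shore and on the pooled sample; and for the ecological
trait, with its quantitative analogue

    Q_ST = V_between / (V_between + 2 V_within),

where V_between is the variance of the (unweighted) habitat means and
V_within the mean within-habitat variance, both with the population
(divide-by-n) convention.  Local adaptation under gene flow shows up as
high Q_ST with low F_ST.

Outcome classifiers follow fixed thresholds: adaptation to the exposed
shore when its mean x drops below 0.25; non-random mate choice when mean
c leaves the [0.45, 0.55] band; ecological speciation when middle-shore
mean c >= 0.9 jointly with Q_ST >= 0.9.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "HabitatSummary",
    "ReplicateSummary",
    "expected_heterozygosity",
    "fst_microsat",
    "qst_trait",
    "mating_correlation",
    "choice_class",
    "classify_outcomes",
    "time_to_adaptation",
    "ADAPTATION_THRESHOLD",
    "CHOICE_BAND",
    "SPECIATION_C",
    "SPECIATION_QST",
]

ADAPTATION_THRESHOLD = 0.25
CHOICE_BAND = (0.45, 0.55)
SPECIATION_C = 0.9
SPECIATION_QST = 0.9


# ----------------------------------------------------------------------
# heterozygosity and F_ST


def expected_heterozygosity(msat: np.ndarray) -> float:
    """Expected heterozygosity of a microsatellite sample.

    ``msat`` is an (n, M, 2) genotype array.  Per locus
    H = 1 - sum_a p_a^2 from the pooled allele frequencies; the result is
    averaged over the M loci.
    """
    msat = np.asarray(msat)
    if msat.ndim != 3 or msat.shape[0] < 1:
        raise ValueError("need an (n, M, 2) genotype array with n >= 1")
    hs = []
    for locus in range(msat.shape[1]):
        alleles = msat[:, locus, :].reshape(-1)
        _, counts = np.unique(alleles, return_counts=True)
        p = counts / counts.sum()
        hs.append(1.0 - np.square(p).sum())
    return float(np.mean(hs))


def observed_heterozygosity(msat: np.ndarray) -> float:
    """Fraction of heterozygous genotypes, averaged over loci."""
    msat = np.asarray(msat)
    if msat.ndim != 3 or msat.shape[0] < 1:
        raise ValueError("need an (n, M, 2) genotype array with n >= 1")
    return float((msat[:, :, 0] != msat[:, :, 1]).mean())


def fst_microsat(populations: Sequence[np.ndarray],
                 observed: bool = False) -> float:
    """F_ST over shore levels: 1 - mean within-shore H / pooled H.

    ``populations`` holds one (n, M, 2) microsatellite array per shore;
    empty shores are excluded.  Returns 0 when the pooled sample is
    monomorphic, and negative sampling-noise estimates are clamped to 0.
    """
    pops = [np.asarray(p) for p in populations if np.asarray(p).shape[0] > 0]
    if not pops:
        raise ValueError("all shore samples are empty")
    h_fun = observed_heterozygosity if observed else expected_heterozygosity
    h_within = float(np.mean([h_fun(p) for p in pops]))
    h_total = expected_heterozygosity(np.concatenate(pops, axis=0))
    if h_total == 0.0:
        return 0.0
    return float(min(1.0, max(0.0, 1.0 - h_within / h_total)))


# ----------------------------------------------------------------------
# Q_ST


def qst_trait(groups: Sequence[np.ndarray]) -> float:
    """Quantitative differentiation of trait values across habitats.

    V_between is the population variance of the unweighted habitat means;
    V_within is the mean of the within-habitat population variances.
    Returns 0 when both variances vanish; habitats without individuals
    are excluded and at least two must remain.
    """
    vals = [np.asarray(g, dtype=float) for g in groups if np.asarray(g).size > 0]
    if len(vals) < 2:
        raise ValueError("Q_ST needs at least two non-empty habitats")
    means = np.array([v.mean() for v in vals])
    v_between = float(np.var(means))
    v_within = float(np.mean([np.var(v) for v in vals]))
    denom = v_between + 2.0 * v_within
    if denom == 0.0:
        return 0.0
    return float(min(1.0, max(0.0, v_between / denom)))


# ----------------------------------------------------------------------
# mating correlation


def mating_correlation(x_male: np.ndarray, x_female: np.ndarray) -> float:
    """Pearson r of the ecological trait among mated partners.

    Defined as 0 when either partner series has zero variance (a
    near-fixed trait cannot show assortment); NaN with fewer than two
    pairs.
    """
    xm = np.asarray(x_male, dtype=float)
    xf = np.asarray(x_female, dtype=float)
    if xm.shape != xf.shape:
        raise ValueError("partner series must have equal length")
    if xm.size < 2:
        return float("nan")
    if np.ptp(xm) == 0.0 or np.ptp(xf) == 0.0:
        return 0.0
    return float(np.corrcoef(xm, xf)[0, 1])


# ----------------------------------------------------------------------
# classifiers


def choice_class(mean_c: float) -> str:
    """Mate-choice regime from a habitat's mean c, with a noise band
    around random mating: negative below 0.45, positive above 0.55."""
    if np.isnan(mean_c):
        return "undefined"
    if mean_c < CHOICE_BAND[0]:
        return "negative"
    if mean_c > CHOICE_BAND[1]:
        return "positive"
    return "random"


@dataclass
class HabitatSummary:
    """Final-generation summary of one shore level."""

    habitat: str
    mean_x: float = float("nan")
    mean_c: float = float("nan")
    mean_choosiness: float = float("nan")
    census: int = 0
    mating_r: float = float("nan")
    mean_fitness: float = float("nan")


@dataclass
class ReplicateSummary:
    """Outcome of one replicate run."""

    habitats: dict[str, HabitatSummary] = field(default_factory=dict)
    fst: float = float("nan")
    qst: float = float("nan")
    time_to_adaptation: Optional[int] = None
    colonized: bool = False
    adapted: bool = False
    choice_classes: dict[str, str] = field(default_factory=dict)
    speciation: bool = False
    extinct: bool = False
    generations_run: int = 0

    def to_dict(self) -> dict:
        """Flatten to one record row (habitat fields suffixed by level)."""
        short = {"upper_sheltered": "upper", "intermediate": "middle",
                 "lower_exposed": "lower"}
        row: dict = {
            "fst": self.fst, "qst": self.qst,
            "time_to_adaptation": self.time_to_adaptation,
            "colonized": self.colonized, "adapted": self.adapted,
            "speciation": self.speciation, "extinct": self.extinct,
            "generations_run": self.generations_run,
        }
        for label, h in self.habitats.items():
            s = short.get(label, label)
            row.update({f"x_{s}": h.mean_x, f"c_{s}": h.mean_c,
                        f"choosiness_{s}": h.mean_choosiness,
                        f"N_{s}": h.census, f"r_{s}": h.mating_r,
                        f"w_{s}": h.mean_fitness,
                        f"choice_{s}": self.choice_classes.get(label, "undefined")})
        return row


def classify_outcomes(summary: ReplicateSummary) -> ReplicateSummary:
    """Fill in the adaptation / choice / speciation classifiers in place.

    Adapted: lower-shore mean x < 0.25.  Choice class per habitat from
    mean c against the 0.45/0.55 band.  Speciation: middle-shore mean
    c >= 0.9 jointly with Q_ST >= 0.9.  Extinct replicates classify as
    not adapted, not speciated, choice undefined.
    """
    if summary.extinct:
        summary.adapted = False
        summary.colonized = False
        summary.speciation = False
        summary.choice_classes = {label: "undefined" for label in summary.habitats}
        return summary
    lower = summary.habitats.get("lower_exposed")
    summary.colonized = bool(lower is not None and lower.census > 0)
    summary.adapted = bool(lower is not None and not np.isnan(lower.mean_x)
                           and lower.mean_x < ADAPTATION_THRESHOLD)
    summary.choice_classes = {label: choice_class(h.mean_c)
                              for label, h in summary.habitats.items()}
    middle = summary.habitats.get("intermediate")
    summary.speciation = bool(
        middle is not None and not np.isnan(middle.mean_c)
        and middle.mean_c >= SPECIATION_C
        and not np.isnan(summary.qst) and summary.qst >= SPECIATION_QST)
    return summary


def time_to_adaptation(generations: np.ndarray, lower_mean_x: np.ndarray) -> Optional[int]:
    """First recorded generation with lower-shore mean x < 0.25, else None."""
    gens = np.asarray(generations)
    xs = np.asarray(lower_mean_x, dtype=float)
    if gens.shape != xs.shape:
        raise ValueError("series must have equal length")
    below = ~np.isnan(xs) & (xs < ADAPTATION_THRESHOLD)
    if not below.any():
        return None
    return int(gens[np.argmax(below)])
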