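"""Shore geometry, habitat optima, carrying capacities and migration.

The shore is a one-dimensional array of demes in three habitats: the
upper sheltered shore (ecological optimum theta = 1), a two-deme
intermediate hybrid zone (theta = 0.5, optionally neutral) and the lower
wave-exposed shore (theta = 0).  The Galician layout is asymmetric — 20
upper demes and 4 lower demes, with the lower shore four times denser —
while the symmetric control layout equalises deme counts and densities.

Only pregnant (mated) females migrate, moving 0, 1 or 2 demes per
generation; a drawn move that would leave the shore is cancelled and the
female stays where she is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Habitat",
    "Landscape",
    "MigrationKernel",
    "build_landscape",
    "migrate_female",
    "migrate_females",
    "destination_pmf",
    "UPPER", "INTERMEDIATE", "LOWER",
    "HABITAT_LABELS",
]

UPPER, INTERMEDIATE, LOWER = 0, 1, 2
HABITAT_LABELS = ("upper_sheltered", "intermediate", "lower_exposed")
_THETA = {UPPER: 1.0, INTERMEDIATE: 0.5, LOWER: 0.0}


@dataclass(frozen=True)
class Habitat:
    """One habitat band: label, ecological optimum and selectivity flag."""

    label: str
    theta: float
    selective: bool = True


@dataclass(frozen=True)
class MigrationKernel:
    """Probabilities of a pregnant female moving 0, 1 or 2 demes."""

    p0: float = 0.75
    p1: float = 0.15
    p2: float = 0.10

    def __post_init__(self) -> None:
        probs = (self.p0, self.p1, self.p2)
        if any(p < 0 for p in probs) or not np.isclose(sum(probs), 1.0):
            raise ValueError("kernel probabilities must be >= 0 and sum to 1")

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum([self.p0, self.p1, self.p2])


class Landscape:
    """Ordered deme array with per-deme habitat, optimum and capacity."""

    def __init__(self, habitat_codes, K, selective=None):
        self.habitat = np.asarray(habitat_codes, dtype=np.int8)
        self.K = np.asarray(K, dtype=np.float64)
        if self.habitat.shape != self.K.shape:
            raise ValueError("habitat and K must have equal length")
        if np.any(self.K <= 0):
            raise ValueError("carrying capacities must be positive")
        self.theta = np.array([_THETA[h] for h in self.habitat])
        if selective is None:
            selective = np.ones(self.n_demes, dtype=bool)
        self.selective = np.asarray(selective, dtype=bool)

    @property
    def n_demes(self) -> int:
        return int(self.habitat.shape[0])

    @property
    def total_capacity(self) -> float:
        return float(self.K.sum())

    def demes_of(self, habitat_code: int) -> np.ndarray:
        return np.flatnonzero(self.habitat == habitat_code)

    def habitats(self) -> list[Habitat]:
        out = []
        for code in (UPPER, INTERMEDIATE, LOWER):
            idx = self.demes_of(code)
            out.append(Habitat(HABITAT_LABELS[code], _THETA[code],
                               bool(self.selective[idx].all()) if idx.size else True))
        return out

    def to_frame(self) -> pd.DataFrame:
        """Tabular view (deme, habitat, theta, K, selective) for logging."""
        return pd.DataFrame({
            "deme": np.arange(self.n_demes),
            "habitat": [HABITAT_LABELS[h] for h in self.habitat],
            "theta": self.theta,
            "K": self.K,
            "selective": self.selective,
        })


def build_landscape(kind: str = "galician", scale: float = 1.0,
                    middle_selective: bool = True) -> Landscape:
    """Construct the shore.

    ``galician``: 26 demes = 20 upper + 2 intermediate + 4 lower, with
    per-deme K = 3,750 for upper/intermediate and K = 15,000 for the
    lower exposed demes.  ``symmetric``: same total deme count with equal
    upper/lower deme numbers (12 + 2 + 12) and uniform per-deme K = 3,750.

    ``scale`` multiplies every K uniformly so reduced-capacity runs keep
    all rates untouched; ``middle_selective=False`` makes the two
    intermediate demes ecologically neutral (fitness 1 for every x).
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if kind == "galician":
        codes = [UPPER] * 20 + [INTERMEDIATE] * 2 + [LOWER] * 4
        K = [3750.0] * 22 + [15000.0] * 4
    elif kind == "symmetric":
        codes = [UPPER] * 12 + [INTERMEDIATE] * 2 + [LOWER] * 12
        K = [3750.0] * 26
    else:
        raise ValueError(f"unknown landscape kind: {kind!r}")
    K = np.asarray(K) * scale
    selective = np.array([middle_selective if c == INTERMEDIATE else True for c in codes])
    return Landscape(codes, K, selective)


# ----------------------------------------------------------------------
# migration


def migrate_females(demes: np.ndarray, kernel: MigrationKernel, n_demes: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Destination demes for a batch of pregnant females.

    Distance 0/1/2 is drawn from the kernel; a nonzero move goes left or
    right with probability 1/2; a move that would leave the shore is
    cancelled (the female stays).
    """
    demes = np.asarray(demes, dtype=np.int64)
    dist = np.searchsorted(kernel.cumulative, rng.random(demes.shape[0]), side="right")
    dist = np.minimum(dist, 2)  # guard against u == 1.0 edge
    sign = rng.integers(0, 2, size=demes.shape[0]) * 2 - 1
    dest = demes + dist * sign
    off = (dest < 0) | (dest >= n_demes)
    dest[off] = demes[off]
    return dest


def migrate_female(deme: int, kernel: MigrationKernel, n_demes: int,
                   rng: np.random.Generator) -> int:
    """Single-female convenience wrapper around :func:`migrate_females`."""
    if not 0 <= deme < n_demes:
        raise ValueError("deme index out of range")
    return int(migrate_females(np.array([deme]), kernel, n_demes, rng)[0])


def destination_pmf(deme: int, kernel: MigrationKernel, n_demes: int) -> np.ndarray:
    """Exact destination distribution for one female, by enumeration.

    Returns an (n_demes,) probability vector.  Interior demes get mass
    (p0; p1/2 at +-1; p2/2 at +-2); cancelled boundary moves fold back
    onto the origin.
    """
    if not 0 <= deme < n_demes:
        raise ValueError("deme index out of range")
    pmf = np.zeros(n_demes)
    moves = [(0, kernel.p0), (1, kernel.p1 / 2), (-1, kernel.p1 / 2),
             (2, kernel.p2 / 2), (-2, kernel.p2 / 2)]
    for step, p in moves:
        dest = deme + step
        pmf[dest if 0 <= dest < n_demes else deme] += p
    return pmf
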