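"""Bead-in-droplet occupancy statistics.

Bead loading into monodisperse droplets follows a Poisson law with mean
``lam`` beads per droplet, so the occupied fraction is ``1 - exp(-lam)``
and working at <= 30% occupancy leaves >= 70% of droplets empty while
keeping most occupied droplets monoclonal.  Magnetic beads can also
aggregate; aggregation is modeled as geometric clumps, the simplest
overdispersion mechanism that preserves the mean loading rate.

The same arithmetic calibrates template-per-droplet loading during clonal
bead amplification (DNA dilute enough to give 10-30% positive beads).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class LoadingModel:
    """Mean beads per droplet plus an optional clumping parameter.

    ``clump_p`` is the continuation probability of a geometric clump-size
    distribution: 0 means independent single beads; larger values make
    beads arrive in aggregates while the mean beads per droplet stays
    ``lam``.
    """

    lam: float
    clump_p: float = 0.0

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if not 0.0 <= self.clump_p < 1.0:
            raise ValueError("clump_p must be in [0, 1)")


def occupancy_fraction(lam: float) -> float:
    """Fraction of droplets with at least one bead: ``1 - exp(-lam)``."""
    if lam < 0:
        raise ValueError("lam must be >= 0")
    return -math.expm1(-lam)


def lambda_for_occupancy(target: float) -> float:
    """Mean loading rate that yields a target occupied fraction.

    Inverse of :func:`occupancy_fraction`: ``-log(1 - target)``.
    """
    if not 0.0 < target < 1.0:
        raise ValueError("target occupancy must be in (0, 1)")
    return -math.log1p(-target)


def monoclonal_fraction(lam: float) -> float:
    """P(exactly one bead | at least one bead) = ``lam e^-lam / (1 - e^-lam)``."""
    if lam <= 0:
        raise ValueError("lam must be > 0")
    return lam * math.exp(-lam) / -math.expm1(-lam)


def bead_pgf(model: LoadingModel, s: float) -> float:
    """Probability generating function E[s^K] of the bead count K.

    Closed form for the clumped-Poisson loading model; ``bead_pgf(m, 0)``
    is the empty-droplet fraction.  Useful to predict how often a
    droplet contains at least one bead of a type present at a given
    pool fraction (thinning: evaluate at 1 - fraction).
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError("s must be in [0, 1]")
    if model.clump_p == 0.0:
        return math.exp(model.lam * (s - 1.0))
    mu = model.lam * (1.0 - model.clump_p)
    g = (1.0 - model.clump_p) * s / (1.0 - model.clump_p * s)
    return math.exp(mu * (g - 1.0))


def sample_bead_counts(
    n_droplets: int,
    model: LoadingModel,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw per-droplet bead counts.

    With ``clump_p = 0`` counts are i.i.d. Poisson(lam).  Otherwise the
    number of clumps per droplet is Poisson(lam * (1 - clump_p)) and each
    clump holds Geometric(clump_p) beads (support >= 1, mean
    ``1/(1-clump_p)``), so the mean beads per droplet is preserved at
    ``lam`` while the variance grows.
    """
    if n_droplets < 1:
        raise ValueError("n_droplets must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if model.clump_p == 0.0:
        return rng.poisson(model.lam, size=n_droplets)
    clump_rate = model.lam * (1.0 - model.clump_p)
    clumps = rng.poisson(clump_rate, size=n_droplets)
    counts = clumps.copy()
    occupied = clumps > 0
    if occupied.any():
        # Sum of k geometric(>=1) sizes = k + NegBin(k) extra beads.
        extras = rng.negative_binomial(clumps[occupied], 1.0 - model.clump_p)
        counts[occupied] += extras
    return counts
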