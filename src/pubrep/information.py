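"""Entropy and the information lost by discretization and coarse-graining.

Spectratyping and continuous density-of-states approximations both reduce
the resolution at which a repertoire is described.  For a continuous trait
density discretized into ``B`` bins of width ``Delta`` the loss is

    L(Delta) = | (S_p - log Delta) - H_q |

where ``S_p`` is the differential entropy and ``H_q`` the entropy of the
binned masses; subtracting ``log Delta`` removes the divergent part of
``H_q`` as ``Delta -> 0`` (the limiting-density correction).  For an
already-discrete distribution coarse-grained by grouping ``ceil(Omega/B)``
consecutive traits per bin, the loss is the entropy difference
``H_p - H_q >= 0``.

Entropies are in nats throughout; ``to_bits`` rescales outputs only.
"""

from __future__ import annotations

import math
from collections.abc import Callable
from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .errors import InvalidInputError
from .repertoire import CloneProbabilities, discretize_density

#: Tolerance on the normalization of a continuous density.
DENSITY_NORM_TOL = 1e-6

#: Quadrature tolerance for differential entropy.
ENTROPY_QUAD_TOL = 1e-8

LOG2 = math.log(2.0)


@dataclass(frozen=True)
class BinnedDistribution:
    """Probability masses over consecutive bins.

    ``bin_width`` carries the trait-space width for continuous
    discretizations; ``bin_size`` carries the number of original traits
    per bin for discrete coarse-graining.  Either may be absent.
    """

    mass: np.ndarray
    bin_width: float | None = None
    bin_size: int | None = None

    def __post_init__(self) -> None:
        mass = np.asarray(self.mass, dtype=float)
        if mass.ndim != 1 or mass.size < 1:
            raise InvalidInputError("mass must be a non-empty 1-D vector")
        if np.any(mass < 0):
            raise InvalidInputError("bin masses must be non-negative")
        if abs(mass.sum() - 1.0) > 1e-9:
            raise InvalidInputError("bin masses must sum to 1 within 1e-9")
        object.__setattr__(self, "mass", mass)

    @property
    def num_bins(self) -> int:
        return int(self.mass.size)


def from_probabilities(probs: CloneProbabilities) -> BinnedDistribution:
    """View a clone probability vector as a one-trait-per-bin distribution."""
    return BinnedDistribution(probs.probs, bin_size=1)


def discrete_entropy(dist: BinnedDistribution) -> float:
    """Shannon entropy ``-sum q log q`` in nats, with 0 log 0 := 0."""
    q = dist.mass[dist.mass > 0]
    return float(-np.sum(q * np.log(q)))


def differential_entropy(
    density: Callable[[float], float],
    a: float,
    b: float,
) -> float:
    """``S_p = -int_a^b p log p`` by adaptive quadrature; may be negative."""
    if not b > a:
        raise InvalidInputError("interval must satisfy b > a")
    norm, _ = integrate.quad(
        density, a, b, epsabs=ENTROPY_QUAD_TOL, epsrel=ENTROPY_QUAD_TOL,
        limit=200,
    )
    if abs(norm - 1.0) > DENSITY_NORM_TOL:
        raise InvalidInputError(
            f"density integrates to {norm:.8g}, not 1 within {DENSITY_NORM_TOL:g}"
        )

    def integrand(x: float) -> float:
        p = density(x)
        if p <= 0.0:
            return 0.0
        return -p * math.log(p)

    value, _ = integrate.quad(
        integrand, a, b, epsabs=ENTROPY_QUAD_TOL, epsrel=ENTROPY_QUAD_TOL,
        limit=200,
    )
    return float(value)


def information_loss_continuous(
    density: Callable[[float], float],
    a: float,
    b: float,
    num_bins: int,
) -> float:
    """Loss of discretizing a continuous density into ``num_bins`` bins.

    ``|(S_p - log Delta) - H_q|``; zero for the uniform density at any
    bin count, and decreasing as the number of bins grows.
    """
    s_p = differential_entropy(density, a, b)
    q = discretize_density(density, a, b, num_bins)
    h_q = discrete_entropy(BinnedDistribution(q.probs))
    delta = (b - a) / num_bins
    return abs((s_p - math.log(delta)) - h_q)


def coarse_grain(
    dist: BinnedDistribution, target_bins: int
) -> BinnedDistribution:
    """Group ``ceil(Omega/B)`` consecutive traits into each of B bins.

    The final bin may hold fewer traits, or none (zero mass): the rule
    deliberately mirrors spectratype-style grouping, including the
    plateaus it produces as B varies.  Total mass is conserved exactly.
    """
    if target_bins < 1:
        raise InvalidInputError("target_bins must be >= 1")
    omega = dist.num_bins
    if target_bins > omega:
        raise InvalidInputError("target_bins cannot exceed current bins")
    size = math.ceil(omega / target_bins)
    mass = np.zeros(target_bins)
    for b in range(target_bins):
        chunk = dist.mass[b * size : (b + 1) * size]
        mass[b] = chunk.sum()
    return BinnedDistribution(mass, bin_size=size)


def information_loss_discrete(
    original: BinnedDistribution, coarse: BinnedDistribution
) -> float:
    """Entropy difference ``H_p - H_q`` of a coarse-graining; >= 0.

    For a uniform distribution over Omega traits grouped into an exact
    divisor B of Omega this equals ``-log(B/Omega)``.
    """
    loss = discrete_entropy(original) - discrete_entropy(coarse)
    if loss < -1e-12:
        raise InvalidInputError(
            "coarse distribution has higher entropy than the original; "
            "was it produced by coarse_grain?"
        )
    return max(loss, 0.0)


def to_bits(nats: float) -> float:
    """Rescale an entropy or loss from nats to bits."""
    return nats / LOG2


def truncated_sqrt_density(x: float) -> float:
    """``exp(-x) / (sqrt(x) gamma(1/2, 1))`` on (0, 1], zero elsewhere.

    A normalized truncated power law with an integrable singularity at
    zero: few high-abundance clones and many low-abundance ones, the
    shape typical of receptor-sequence rank abundances.  The
    normalization is the lower incomplete gamma function at (1/2, 1).
    """
    from scipy.special import gamma, gammainc

    norm = gammainc(0.5, 1.0) * gamma(0.5)
    if x <= 0.0 or x > 1.0:
        return 0.0
    return math.exp(-x) / (math.sqrt(x) * norm)
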