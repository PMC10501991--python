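"""M-overlap (publicness), privateness, and the per-clone sharing spectrum.

The M-overlap ``K^(M)`` is the number of clones present in *all* of M
individuals.  Its moments under the multinomial model are

    E[K]   = sum_i prod_m rho_i^(m)
    E[K^2] = E[K] + sum_{i!=j} prod_m rho_ij^(m)

The number of individuals ``M_i`` that carry clone i follows a Poisson
binomial distribution over the per-member occurrence probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _pairsum
from .errors import InvalidInputError
from .repertoire import Cohort
from .richness import MomentSummary, richness_observed


@dataclass(frozen=True)
class DiscretePMF:
    """Probability mass function on integer support ``0..K_max``."""

    support: np.ndarray
    mass: np.ndarray

    def __post_init__(self) -> None:
        support = np.asarray(self.support, dtype=np.int64)
        mass = np.asarray(self.mass, dtype=float)
        if support.shape != mass.shape or support.ndim != 1:
            raise InvalidInputError("support and mass must be equal-length 1-D")
        if np.any(mass < -1e-12):
            raise InvalidInputError("pmf mass must be non-negative")
        if abs(mass.sum() - 1.0) > 1e-10:
            raise InvalidInputError("pmf mass must sum to 1 within 1e-10")
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "mass", np.maximum(mass, 0.0))

    @property
    def mean(self) -> float:
        return float(np.dot(self.support, self.mass))

    @property
    def variance(self) -> float:
        return float(np.dot(self.support**2, self.mass) - self.mean**2)


def overlap_observed(cohort: Cohort) -> int:
    """Number of clones with ``n_i^(m) >= 1`` in every member."""
    cohort.require_n_representation()
    if cohort.num_members == 1:
        return richness_observed(cohort.members[0])
    stacked = np.vstack([m.counts for m in cohort.members])
    return int(np.count_nonzero(np.all(stacked >= 1, axis=0)))


def _member_occurrence(cohort: Cohort, exponents: list[int]) -> np.ndarray:
    """Matrix of rho_i^(m) = 1-(1-p_i^(m))^{E_m}, shape (M, Omega)."""
    rows = []
    for member, e in zip(cohort.members, exponents):
        rows.append(-np.expm1(_pairsum.log_absent(member.probs, e, False)))
    return np.vstack(rows)


def overlap_moments_p(
    cohort: Cohort,
    chunk_size: int | None = None,
) -> MomentSummary:
    """Moments of the M-overlap in the p-representation (whole organisms)."""
    cohort.require_p_representation()
    exponents = list(cohort.population_sizes)
    rho = _member_occurrence(cohort, exponents)
    mean = float(rho.prod(axis=0).sum())
    pair = _pairsum.pair_sum_overlap(
        [m.probs for m in cohort.members], exponents, chunk_size
    )
    return MomentSummary.from_moments(mean, mean + pair)


def privateness_expected(
    cohort: Cohort,
    chunk_size: int | None = None,
) -> float:
    """Expected M-privateness ``Omega - E[K^(M)]``.

    Counts clones expected to be absent from at least one of the M
    individuals (i.e. carried by at most M-1 of them).
    """
    cohort.require_p_representation()
    exponents = list(cohort.population_sizes)
    rho = _member_occurrence(cohort, exponents)
    return float(cohort.num_clones - rho.prod(axis=0).sum())


def poisson_binomial_pmf(success_probs: np.ndarray) -> DiscretePMF:
    """Exact Poisson-binomial pmf by dynamic-programming convolution.

    The distribution of the number of successes among independent
    Bernoulli trials with heterogeneous probabilities.  The DP costs
    O(n^2) instead of the 2^n subset enumeration of the defining sum.
    """
    probs = np.asarray(success_probs, dtype=float)
    if probs.ndim != 1:
        raise InvalidInputError("success_probs must be a 1-D vector")
    if np.any(probs < 0) or np.any(probs > 1):
        raise InvalidInputError("success probabilities must lie in [0, 1]")
    n = probs.size
    mass = np.zeros(n + 1)
    mass[0] = 1.0
    for k, p in enumerate(probs):
        # After trial k+1 the support grows by one: shift-and-add.
        mass[1 : k + 2] = mass[1 : k + 2] * (1.0 - p) + mass[: k + 1] * p
        mass[0] *= 1.0 - p
    return DiscretePMF(np.arange(n + 1), mass)


def sharing_spectrum(
    clone_index: int,
    cohort: Cohort,
) -> tuple[DiscretePMF, float]:
    """Distribution of ``M_i``: how many members carry clone i at all.

    Returns the Poisson-binomial pmf over 0..M together with the mean
    sharing frequency ``E[M_i]/M``.
    """
    cohort.require_p_representation()
    if not 0 <= clone_index < cohort.num_clones:
        raise InvalidInputError("clone index out of range")
    rho = _member_occurrence(cohort, list(cohort.population_sizes))
    successes = rho[:, clone_index]
    pmf = poisson_binomial_pmf(successes)
    return pmf, pmf.mean / cohort.num_members
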