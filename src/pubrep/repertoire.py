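"""Core repertoire data types and the multinomial population model.

A repertoire is described on a shared clone index ``i = 1..Omega`` either by
integer cell counts ``n_i`` (the *n-representation*) or by occurrence
probabilities ``p_i`` (the *p-representation*).  A :class:`Cohort` collects
``M`` such descriptions on a common index, together with the population
sizes ``N^(m)`` and, optionally, the sample sizes ``S^(m)`` drawn from each
individual.

The statistical model throughout the package treats each individual as an
independent multinomial draw of ``N^(m)`` cells from its probability vector
``p^(m)``: every new cell is of clone ``i`` with probability ``p_i^(m)``.
"""

from __future__ import annotations

from collections.abc import Callable, Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate
from scipy.special import gammaln

from .errors import (
    ConfigurationError,
    EmptyRepertoireError,
    InvalidInputError,
)

#: Normalization slack accepted for probability vectors.
PROB_TOLERANCE = 1e-9

#: Absolute tolerance for adaptive quadrature in :func:`discretize_density`.
QUADRATURE_TOL = 1e-10


@dataclass(frozen=True)
class CloneAbundance:
    """Integer cell counts per clone for one individual.

    Parameters
    ----------
    counts
        Length-``Omega`` vector of cell counts ``n_i >= 0``.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 1 or counts.size < 1:
            raise InvalidInputError("counts must be a non-empty 1-D vector")
        if np.any(counts < 0):
            raise InvalidInputError("cell counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        """Total cell count ``N = sum_i n_i``."""
        return int(self.counts.sum())

    @property
    def num_clones(self) -> int:
        """Number of clone slots ``Omega`` (including zero-count slots)."""
        return int(self.counts.size)


@dataclass(frozen=True)
class CloneProbabilities:
    """Normalized clone occurrence probabilities for one individual."""

    probs: np.ndarray
    tolerance: float = PROB_TOLERANCE

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 1 or probs.size < 1:
            raise InvalidInputError("probs must be a non-empty 1-D vector")
        if np.any(probs < 0) or np.any(probs > 1):
            raise InvalidInputError("probabilities must lie in [0, 1]")
        if abs(probs.sum() - 1.0) > self.tolerance:
            raise InvalidInputError(
                f"probabilities sum to {probs.sum():.12g}, "
                f"outside tolerance {self.tolerance:g} of 1"
            )
        object.__setattr__(self, "probs", probs)

    @property
    def num_clones(self) -> int:
        return int(self.probs.size)


Member = CloneAbundance | CloneProbabilities


@dataclass(frozen=True)
class Cohort:
    """``M`` individuals described on a shared clone index.

    All members must use the same representation and the same number of
    clone slots ``Omega``.  ``population_sizes`` are the whole-organism
    cell counts ``N^(m)``; for abundance members they default to the count
    totals.  ``sample_sizes`` are the subsample sizes ``S^(m)`` and are
    required only by the subsampling operations.
    """

    members: tuple[Member, ...]
    population_sizes: tuple[int, ...] = ()
    sample_sizes: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        members = tuple(self.members)
        if len(members) < 1:
            raise InvalidInputError("a cohort needs at least one member")
        omegas = {m.num_clones for m in members}
        if len(omegas) > 1:
            raise InvalidInputError("all members must share the same Omega")
        kinds = {type(m) for m in members}
        if len(kinds) > 1:
            raise InvalidInputError(
                "cohort members must all be abundances or all probabilities"
            )
        pop = tuple(int(n) for n in self.population_sizes)
        if not pop:
            if isinstance(members[0], CloneAbundance):
                pop = tuple(m.total for m in members)
            else:
                raise ConfigurationError(
                    "population_sizes are required for probability members"
                )
        if len(pop) != len(members):
            raise InvalidInputError("one population size per member required")
        if any(n < 0 for n in pop):
            raise InvalidInputError("population sizes must be non-negative")
        for m, n in zip(members, pop):
            if isinstance(m, CloneAbundance) and m.total != n:
                raise InvalidInputError(
                    "population size must equal the abundance total"
                )
        if self.sample_sizes is not None:
            ss = tuple(int(s) for s in self.sample_sizes)
            if len(ss) != len(members):
                raise InvalidInputError("one sample size per member required")
            if any(s < 0 for s in ss):
                raise InvalidInputError("sample sizes must be non-negative")
            if any(s > n for s, n in zip(ss, pop)):
                raise InvalidInputError("sample sizes cannot exceed N^(m)")
            object.__setattr__(self, "sample_sizes", ss)
        object.__setattr__(self, "members", members)
        object.__setattr__(self, "population_sizes", pop)

    @property
    def num_members(self) -> int:
        return len(self.members)

    @property
    def num_clones(self) -> int:
        return self.members[0].num_clones

    @property
    def is_n_representation(self) -> bool:
        return isinstance(self.members[0], CloneAbundance)

    def require_n_representation(self) -> None:
        if not self.is_n_representation:
            raise InvalidInputError("operation requires abundance members")

    def require_p_representation(self) -> None:
        if self.is_n_representation:
            raise InvalidInputError("operation requires probability members")

    def require_sample_sizes(self) -> tuple[int, ...]:
        if self.sample_sizes is None:
            raise ConfigurationError("sample sizes S^(m) are not set")
        return self.sample_sizes

    def subset(self, member_indices: Sequence[int]) -> "Cohort":
        """Cohort restricted to the given 0-based member indices."""
        idx = list(member_indices)
        return Cohort(
            members=tuple(self.members[i] for i in idx),
            population_sizes=tuple(self.population_sizes[i] for i in idx),
            sample_sizes=(
                None
                if self.sample_sizes is None
                else tuple(self.sample_sizes[i] for i in idx)
            ),
        )


@dataclass(frozen=True)
class CloneCountSpectrum:
    """Clone counts by size: ``c_k`` = number of clones with exactly k cells.

    The ``k = 0`` entry records unseen clone slots, so ``Omega`` is always
    recoverable as ``sum_k c_k``.
    """

    counts_by_size: dict[int, int] = field(default_factory=dict)

    @property
    def total_cells(self) -> int:
        return sum(k * c for k, c in self.counts_by_size.items())

    @property
    def observed_richness(self) -> int:
        return sum(c for k, c in self.counts_by_size.items() if k >= 1)

    @property
    def num_clones(self) -> int:
        return sum(self.counts_by_size.values())


def clone_count_spectrum(abundance: CloneAbundance) -> CloneCountSpectrum:
    """Tally clones by abundance: ``c_k = #{i : n_i = k}``.

    The spectrum conserves cells (``sum_k k c_k = N``) and clones
    (``sum_{k>=1} c_k`` equals the observed richness).
    """
    sizes, counts = np.unique(abundance.counts, return_counts=True)
    return CloneCountSpectrum(
        {int(k): int(c) for k, c in zip(sizes, counts)}
    )


def probability_binned_spectrum(
    probs: CloneProbabilities, delta: float
) -> CloneCountSpectrum:
    """Clone counts by binned probability: ``c_k = #{i : k*delta <= p_i < (k+1)*delta}``.

    This is the probability-binning alternative to the integer-abundance
    tally; the integer form (:func:`clone_count_spectrum`) is the default
    used by the rest of the package.
    """
    if delta <= 0:
        raise InvalidInputError("delta must be positive")
    bins = np.floor(probs.probs / delta).astype(np.int64)
    sizes, counts = np.unique(bins, return_counts=True)
    return CloneCountSpectrum(
        {int(k): int(c) for k, c in zip(sizes, counts)}
    )


def empirical_probabilities(abundance: CloneAbundance) -> CloneProbabilities:
    """Maximum-likelihood point estimate ``p_hat_i = n_i / N``."""
    total = abundance.total
    if total == 0:
        raise EmptyRepertoireError("empty repertoire: N = 0")
    return CloneProbabilities(abundance.counts / total)


def discretize_density(
    density: Callable[[float], float],
    a: float,
    b: float,
    num_bins: int,
) -> CloneProbabilities:
    """Discretize a trait density on ``[a, b]`` into equal-width bins.

    Bin ``i`` (half-open ``[a+(i-1)*D, a+i*D)`` with ``D=(b-a)/num_bins``)
    receives the integral of ``density`` over the bin; the masses are then
    renormalized to sum to one.  Integrable endpoint singularities are
    handled by the adaptive quadrature.
    """
    if num_bins < 1:
        raise InvalidInputError("num_bins must be >= 1")
    if not b > a:
        raise InvalidInputError("interval must satisfy b > a")
    edges = np.linspace(a, b, num_bins + 1)
    masses = np.empty(num_bins)
    for i in range(num_bins):
        val, _ = integrate.quad(
            density, edges[i], edges[i + 1],
            epsabs=QUADRATURE_TOL, epsrel=QUADRATURE_TOL, limit=200,
        )
        if val < -QUADRATURE_TOL * max(1.0, abs(val)):
            raise InvalidInputError("density is negative on a bin")
        masses[i] = max(val, 0.0)
    total = masses.sum()
    if total <= 0:
        raise InvalidInputError("density has zero total mass on [a, b]")
    return CloneProbabilities(masses / total)


def multinomial_loglikelihood(
    abundance: CloneAbundance, probs: CloneProbabilities
) -> float:
    """Log-probability of a count configuration under the multinomial model.

    ``log P(n | p, N) = log N! + sum_i [n_i log p_i - log n_i!]``,
    evaluated through log-gamma.  Returns ``-inf`` when a clone with zero
    probability carries a positive count.
    """
    n = abundance.counts
    p = probs.probs
    if n.size != p.size:
        raise InvalidInputError("abundance and probabilities length mismatch")
    impossible = (n > 0) & (p == 0)
    if np.any(impossible):
        return float("-inf")
    mask = n > 0
    loglik = gammaln(abundance.total + 1) - gammaln(n[mask] + 1).sum()
    loglik += float(np.sum(n[mask] * np.log(p[mask])))
    return float(loglik)
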