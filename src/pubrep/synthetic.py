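"""Seeded generators for synthetic cohorts.

Three kinds of inputs exercise every operation in the package:

* a deterministic shifted-uniform cohort — M individuals each holding the
  same number of equally sized clones, with consecutive individuals offset
  by a fixed shift along the clone index, so pairwise and group overlaps
  are exact interval intersections;
* multinomial cohorts drawn from arbitrary or power-law probability
  vectors (the package's population model);
* multivariate-hypergeometric subsamples (one-shot draws without
  replacement) from known abundances.

Every stochastic generator takes an explicit integer seed; there is no
hidden global RNG state.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .powerlaw import PowerLawSpec, powerlaw_probabilities
from .repertoire import CloneAbundance, CloneProbabilities, Cohort
from .sampling import SampleConfiguration


@dataclass(frozen=True)
class ShiftedUniformSpec:
    """Parameters of the shifted-uniform cohort.

    Defaults describe three individuals of 1000 clones x 100 cells each
    (N = 1e5) with a shift of 250 clone indices between consecutive
    individuals, giving a group richness of 1500, pairwise overlaps of
    750 (consecutive) and 500 (outermost), and a triple overlap of 500.
    The shift is the one value consistent with those overlap maxima.
    """

    num_members: int = 3
    clones_per_member: int = 1000
    copies_per_clone: int = 100
    shift: int = 250

    def __post_init__(self) -> None:
        if self.num_members < 1 or self.clones_per_member < 1:
            raise InvalidInputError("need at least one member and one clone")
        if self.copies_per_clone < 1 or self.shift < 0:
            raise InvalidInputError("copies >= 1 and shift >= 0 required")

    @property
    def num_clones(self) -> int:
        return self.clones_per_member + (self.num_members - 1) * self.shift


def shifted_uniform_cohort(
    spec: ShiftedUniformSpec = ShiftedUniformSpec(),
    sample_sizes: Sequence[int] | None = None,
) -> Cohort:
    """Deterministic shifted-uniform cohort (no RNG involved)."""
    members = []
    for m in range(spec.num_members):
        counts = np.zeros(spec.num_clones, dtype=np.int64)
        start = m * spec.shift
        counts[start : start + spec.clones_per_member] = spec.copies_per_clone
        members.append(CloneAbundance(counts))
    return Cohort(
        members=tuple(members),
        sample_sizes=None if sample_sizes is None else tuple(sample_sizes),
    )


def multinomial_cohort(
    probs_per_member: Sequence[CloneProbabilities],
    N_per_member: Sequence[int],
    seed: int,
) -> Cohort:
    """Independent multinomial draw of each member's cell population."""
    if len(probs_per_member) != len(N_per_member):
        raise InvalidInputError("one population size per member required")
    rng = np.random.default_rng(seed)
    members = tuple(
        CloneAbundance(rng.multinomial(int(n), p.probs))
        for p, n in zip(probs_per_member, N_per_member)
    )
    return Cohort(members=members)


def hypergeometric_subsample(
    abundance: CloneAbundance, S: int, seed: int
) -> SampleConfiguration:
    """One-shot draw of S cells without replacement from known counts."""
    if S > abundance.total:
        raise InvalidInputError("cannot sample more cells than exist")
    if S < 0:
        raise InvalidInputError("S must be >= 0")
    rng = np.random.default_rng(seed)
    counts = rng.multivariate_hypergeometric(abundance.counts, int(S))
    return SampleConfiguration(counts, parent_size=abundance.total)


def subsampled_cohort(
    cohort: Cohort, sample_sizes: Sequence[int], seed: int
) -> Cohort:
    """Subsample every member of an abundance cohort, as its own cohort.

    Member m's subsample uses an independent child seed derived from
    ``seed`` so members stay independent but reproducible.
    """
    cohort.require_n_representation()
    seeds = np.random.SeedSequence(seed).spawn(cohort.num_members)
    members = []
    for member, S, child in zip(cohort.members, sample_sizes, seeds):
        rng = np.random.default_rng(child)
        counts = rng.multivariate_hypergeometric(member.counts, int(S))
        members.append(CloneAbundance(counts))
    return Cohort(members=tuple(members))


def powerlaw_cohort(
    spec: PowerLawSpec, M: int, N: int, seed: int
) -> Cohort:
    """M iid multinomial draws from one truncated power law."""
    if M < 1:
        raise InvalidInputError("M must be >= 1")
    probs = powerlaw_probabilities(spec)
    return multinomial_cohort([probs] * M, [N] * M, seed)


def sonia_like_cohort(
    M: int = 3,
    num_sequences: int = 2000,
    seed: int = 0,
) -> Cohort:
    """Synthetic stand-in for a generation-model (SONIA-style) cohort.

    Emulates the size-frequency profile of V(D)J generation-probability
    sampling — the vast majority of sequences at abundance 1, a few above
    5 — by drawing each member's cells from a common heavy-tailed
    probability vector over a clone space comparable to the cell count.
    It reproduces the qualitative shape only, not any particular
    generation model's output.
    """
    rng = np.random.default_rng(seed)
    omega = 4 * num_sequences
    # Heavy-tailed weights: most clones tiny, a few orders larger.
    weights = rng.pareto(1.5, size=omega) + 1.0
    probs = CloneProbabilities(weights / weights.sum())
    seeds = np.random.SeedSequence(seed).spawn(M)
    members = tuple(
        CloneAbundance(
            np.random.default_rng(child).multinomial(num_sequences, probs.probs)
        )
        for child in seeds
    )
    return Cohort(members=members)
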