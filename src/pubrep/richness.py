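"""Richness of single repertoires and of pooled multi-individual groups.

Richness ``R`` counts the distinct clones with at least one cell.  In the
n-representation it is a deterministic tally; in the p-representation it
is a random variable of the multinomial draw, with

    E[R]   = sum_i rho_i,            rho_i  = 1 - (1-p_i)^N
    E[R^2] = E[R] + sum_{i!=j} rho_ij

where ``rho_ij`` is the pairwise joint-occurrence probability.  Group
(pooled) richness over ``M`` individuals replaces ``rho`` with the
any-member occurrence probabilities ``rho~``.
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np

from . import _pairsum
from .errors import InvalidInputError
from .repertoire import CloneAbundance, CloneProbabilities, Cohort

#: Tolerance below which a negative variance is treated as round-off.
VARIANCE_TOL = 1e-9


@dataclass(frozen=True)
class MomentSummary:
    """First two moments of a count statistic plus derived dispersion.

    ``fano`` (variance/mean) and ``cv_squared`` (variance/mean^2) are NaN
    when the mean is zero.
    """

    mean: float
    second_moment: float
    variance: float
    fano: float
    cv_squared: float

    @classmethod
    def from_moments(cls, mean: float, second_moment: float) -> "MomentSummary":
        variance = second_moment - mean * mean
        if variance < -VARIANCE_TOL * max(1.0, mean * mean):
            raise InvalidInputError(
                f"second moment {second_moment!r} below mean^2"
            )
        variance = max(variance, 0.0)
        if mean == 0.0:
            fano = cv2 = float("nan")
        else:
            fano = variance / mean
            cv2 = variance / (mean * mean)
        return cls(mean, second_moment, variance, fano, cv2)


def richness_observed(abundance: CloneAbundance) -> int:
    """Number of clones with at least one cell."""
    return int(np.count_nonzero(abundance.counts))


def occurrence_probability(p_i: float, N: int) -> float:
    """``rho_i = 1 - (1-p_i)^N``: clone i appears at all among N cells."""
    if not 0.0 <= p_i <= 1.0:
        raise InvalidInputError("p_i must lie in [0, 1]")
    if N < 0:
        raise InvalidInputError("N must be >= 0")
    if N == 0:
        return 0.0
    if p_i == 1.0:
        return 1.0
    return -math.expm1(N * math.log1p(-p_i))


def joint_occurrence_probability(p_subset: Sequence[float], N: int) -> float:
    """Joint occurrence of two or three clones in one multinomial draw.

    Inclusion-exclusion over the absence events: for two clones
    ``rho_ij = 1 + (1-p_i-p_j)^N - (1-p_i)^N - (1-p_j)^N`` and the
    analogous alternating sum for three.
    """
    p = [float(x) for x in p_subset]
    if len(p) not in (2, 3):
        raise InvalidInputError("p_subset must contain 2 or 3 probabilities")
    if any(x < 0 or x > 1 for x in p):
        raise InvalidInputError("probabilities must lie in [0, 1]")
    if sum(p) > 1.0 + 1e-9:
        raise InvalidInputError("probabilities of disjoint clones exceed 1")
    if N < 0:
        raise InvalidInputError("N must be >= 0")

    def absent(total: float) -> float:
        total = min(total, 1.0)
        if total >= 1.0:
            return 0.0 if N >= 1 else 1.0
        return math.exp(N * math.log1p(-total))

    if len(p) == 2:
        value = 1.0 + absent(p[0] + p[1]) - absent(p[0]) - absent(p[1])
    else:
        value = (
            1.0
            - absent(p[0] + p[1] + p[2])
            - sum(absent(x) for x in p)
            + absent(p[0] + p[1])
            + absent(p[0] + p[2])
            + absent(p[1] + p[2])
        )
    return _pairsum.clamp_probability(value)


def _moments_from_absent(
    ps: list[np.ndarray],
    exponents: list[int],
    chunk_size: int | None,
    approx_exp: bool,
) -> MomentSummary:
    """Shared group-richness moment evaluation.

    With per-member absence probabilities ``A_i^(m) = (1-p_i^(m))^{E_m}``:
    ``mean = sum_i (1 - prod_m A_i^(m))`` and the pair term expands to
    ``Om(Om-1) - 2(Om-1) sum_i GA_i + sum_{i!=j} GB_ij`` with
    ``GA_i = prod_m A_i^(m)`` and ``GB_ij`` the joint pair absence.
    """
    omega = ps[0].size
    log_ga = np.zeros(omega)
    for p, e in zip(ps, exponents):
        log_ga += _pairsum.log_absent(p, e, approx_exp)
    ga = np.exp(log_ga)
    mean = float(np.sum(-np.expm1(log_ga)))
    sum_gb = _pairsum.pair_sum_group_absent(ps, exponents, chunk_size, approx_exp)
    pair = omega * (omega - 1) - 2.0 * (omega - 1) * float(ga.sum()) + sum_gb
    return MomentSummary.from_moments(mean, mean + pair)


def richness_moments_p(
    probs: CloneProbabilities,
    N: int,
    chunk_size: int | None = None,
) -> MomentSummary:
    """Mean, second moment and dispersion of single-individual richness."""
    if N < 0:
        raise InvalidInputError("N must be >= 0")
    return _moments_from_absent([probs.probs], [N], chunk_size, approx_exp=False)


def group_richness_observed(cohort: Cohort) -> int:
    """Pooled richness: clones with at least one cell in any member."""
    cohort.require_n_representation()
    stacked = np.vstack([m.counts for m in cohort.members])
    return int(np.count_nonzero(stacked.sum(axis=0)))


def group_occurrence(
    probs_per_member: Sequence[CloneProbabilities],
    N_per_member: Sequence[int],
    clone_indices: Sequence[int],
) -> float:
    """Any-member occurrence ``rho~_i`` or pairwise ``rho~_ij`` (0-based index).

    ``rho~_i = 1 - prod_m (1-p_i^(m))^{N^(m)}`` is the probability that
    clone i appears in at least one of the M individuals; it always
    dominates the all-member product ``prod_m rho_i^(m)``.
    """
    idx = [int(i) for i in clone_indices]
    if len(idx) not in (1, 2):
        raise InvalidInputError("clone_indices must hold one or two indices")
    if len(probs_per_member) != len(N_per_member):
        raise InvalidInputError("one population size per member required")
    ps = [m.probs for m in probs_per_member]
    ns = [int(n) for n in N_per_member]

    def log_absent_at(i: int) -> float:
        out = 0.0
        for p, n in zip(ps, ns):
            if p[i] >= 1.0:
                return -math.inf if n >= 1 else 0.0
            out += n * math.log1p(-p[i])
        return out

    if len(idx) == 1:
        return -math.expm1(log_absent_at(idx[0]))
    i, j = idx
    log_pair = 0.0
    for p, n in zip(ps, ns):
        s = p[i] + p[j]
        if s > 1.0 + 1e-9:
            raise InvalidInputError("p_i + p_j > 1 for a member")
        s = min(s, 1.0)
        if s >= 1.0:
            log_pair = -math.inf if n >= 1 else log_pair
        else:
            log_pair += n * math.log1p(-s)
    value = (
        1.0
        - math.exp(log_absent_at(i))
        - math.exp(log_absent_at(j))
        + math.exp(log_pair)
    )
    return _pairsum.clamp_probability(value)


def group_richness_moments_p(
    cohort: Cohort,
    chunk_size: int | None = None,
    approx_exp: bool = False,
) -> MomentSummary:
    """Moments of the pooled richness of all cohort members.

    ``approx_exp`` switches every ``(1-p)^N`` to the Poisson limit
    ``exp(-pN)`` (accurate for p << 1, N >> 1); it is never applied
    silently.
    """
    cohort.require_p_representation()
    ps = [m.probs for m in cohort.members]
    return _moments_from_absent(
        ps, list(cohort.population_sizes), chunk_size, approx_exp
    )
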