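"""Statistics of subsampled repertoires.

A sequencing experiment draws ``S^(m) << N^(m)`` cells without replacement
from individual m, yielding counts ``s_i^(m)``.  Under one-shot uniform
subsampling the per-clone occurrence probabilities are hypergeometric:

    sigma_i  = 1 - C(N-n_i, S) / C(N, S)

and all richness/overlap moments keep their whole-organism form with
``sigma`` in place of ``rho``.  Binomial-coefficient ratios are evaluated
through the stable product form

    C(N-n, S) / C(N, S) = prod_{l=1..n} (1 - S / (N - n + l))

in log space, which never forms a factorial and is safe for N ~ 1e8.

In the p-representation, hypergeometric subsampling of a multinomial
population is again multinomial with S draws (conjugacy), so the sampled
moments reuse the whole-organism formulas with exponent S.
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np

from . import _pairsum
from .errors import InvalidInputError
from .overlap import DiscretePMF, poisson_binomial_pmf
from .repertoire import CloneAbundance, CloneProbabilities, Cohort
from .richness import MomentSummary


@dataclass(frozen=True)
class SampleConfiguration:
    """Observed subsample counts ``s_i`` from a parent population of size N."""

    counts: np.ndarray
    parent_size: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 1 or counts.size < 1:
            raise InvalidInputError("counts must be a non-empty 1-D vector")
        if np.any(counts < 0):
            raise InvalidInputError("sample counts must be non-negative")
        if counts.sum() > self.parent_size:
            raise InvalidInputError("sample size exceeds parent population")
        object.__setattr__(self, "counts", counts)

    @property
    def sample_size(self) -> int:
        return int(self.counts.sum())


def log_binomial_ratio(N: int, n_i: int, S: int) -> float:
    """``log [C(N-n_i, S) / C(N, S)]`` via the product form.

    Returns ``-inf`` when ``S > N - n_i`` (the sample cannot avoid clone
    i's cells entirely).
    """
    if not 0 <= n_i <= N:
        raise InvalidInputError("need 0 <= n_i <= N")
    if not 0 <= S <= N:
        raise InvalidInputError("need 0 <= S <= N")
    if n_i == 0 or S == 0:
        return 0.0
    if S > N - n_i:
        return -math.inf
    j = np.arange(N - n_i + 1, N + 1, dtype=float)
    return float(np.log1p(-S / j).sum())


def _log_r_table(N: int, S: int, n_max: int) -> np.ndarray:
    """``T[n] = log C(N-n, S)/C(N, S)`` for n = 0..n_max, via suffix sums."""
    n_max = min(n_max, N)
    j = np.arange(N, N - n_max, -1, dtype=float)
    with np.errstate(divide="ignore"):
        terms = np.where(j > S, np.log1p(-S / np.maximum(j, 1.0)), -np.inf)
    return np.concatenate([[0.0], np.cumsum(terms)])


def _r_table(member: CloneAbundance, S: int, pair: bool = True) -> np.ndarray:
    """Avoidance ratios ``r(n)`` tabulated up to 2*max(n_i) (for pair sums)."""
    n_max = int(member.counts.max(initial=0)) * (2 if pair else 1)
    with np.errstate(invalid="ignore"):
        return np.exp(_log_r_table(member.total, S, n_max))


def sample_occurrence(
    context: tuple[int, int],
    clone_sizes: Sequence[int] | int,
) -> float:
    """``sigma_i`` (one clone) or ``sigma_ij`` (two clones) for one sample.

    ``context`` is ``(N, S)``; ``clone_sizes`` the parent counts of the
    clone(s) of interest.
    """
    N, S = context
    sizes = [int(clone_sizes)] if np.isscalar(clone_sizes) else [int(x) for x in clone_sizes]
    if len(sizes) == 1:
        return -math.expm1(log_binomial_ratio(N, sizes[0], S))
    if len(sizes) == 2:
        ni, nj = sizes
        if ni + nj > N:
            raise InvalidInputError("n_i + n_j cannot exceed N")
        value = (
            1.0
            + math.exp(log_binomial_ratio(N, ni + nj, S))
            - math.exp(log_binomial_ratio(N, ni, S))
            - math.exp(log_binomial_ratio(N, nj, S))
        )
        return _pairsum.clamp_probability(value)
    raise InvalidInputError("clone_sizes must hold one or two counts")


def group_sample_occurrence(
    cohort: Cohort,
    clone_indices: Sequence[int] | int,
) -> float:
    """Any-sample occurrence ``sigma~_i`` or pairwise ``sigma~_ij`` (0-based).

    The probability that the clone (or both clones) shows up in at least
    one of the M subsamples.
    """
    cohort.require_n_representation()
    samples = cohort.require_sample_sizes()
    idx = [int(clone_indices)] if np.isscalar(clone_indices) else [int(x) for x in clone_indices]
    if len(idx) not in (1, 2):
        raise InvalidInputError("clone_indices must hold one or two indices")

    def log_avoid(sizes_fn) -> float:
        out = 0.0
        for member, N, S in zip(
            cohort.members, cohort.population_sizes, samples
        ):
            out += log_binomial_ratio(N, sizes_fn(member), S)
        return out

    if len(idx) == 1:
        i = idx[0]
        return -math.expm1(log_avoid(lambda m: int(m.counts[i])))
    i, j = idx
    value = (
        1.0
        + math.exp(log_avoid(lambda m: int(m.counts[i] + m.counts[j])))
        - math.exp(log_avoid(lambda m: int(m.counts[i])))
        - math.exp(log_avoid(lambda m: int(m.counts[j])))
    )
    return _pairsum.clamp_probability(value)


def _pair_sum_r(
    counts: list[np.ndarray],
    tables: list[np.ndarray],
    chunk: int,
) -> float:
    """``sum_{i != j} prod_m r_m(n_i^(m) + n_j^(m))`` chunked over rows."""
    omega = counts[0].size
    total = 0.0
    for start in range(0, omega, chunk):
        rows = slice(start, min(start + chunk, omega))
        block = np.ones((rows.stop - rows.start, omega))
        for n, table in zip(counts, tables):
            # Diagonal (i == i) indices may exceed the table range; the
            # entries are discarded below, so clipping them is safe.
            idx = np.minimum(n[rows, None] + n[None, :], table.size - 1)
            block *= table[idx]
        _pairsum._fill_diagonal_block(block, rows, 0.0)
        total += float(block.sum())
    return total


def sampled_richness_moments_n(
    cohort: Cohort,
    group: bool = False,
    chunk_size: int | None = None,
) -> MomentSummary:
    """Moments of sampled richness from known counts.

    With ``group=False`` the cohort must have a single member and the
    result describes ``R_s``; with ``group=True`` it describes the pooled
    sampled richness ``R_s^(M)`` built from the any-sample probabilities.
    """
    cohort.require_n_representation()
    samples = cohort.require_sample_sizes()
    if not group and cohort.num_members != 1:
        raise InvalidInputError(
            "individual sampled richness needs a single-member cohort; "
            "pass group=True for the pooled quantity"
        )
    omega = cohort.num_clones
    chunk = _pairsum.resolve_chunk(omega, chunk_size)
    counts = [m.counts for m in cohort.members]
    tables = [
        _r_table(m, S) for m, S in zip(cohort.members, samples)
    ]
    # prod_m r_m(n_i^(m)): probability clone i is missed by every sample.
    ga = np.ones(omega)
    for n, table in zip(counts, tables):
        ga *= table[n]
    mean = float((1.0 - ga).sum())
    sum_gb = _pair_sum_r(counts, tables, chunk)
    pair = omega * (omega - 1) - 2.0 * (omega - 1) * float(ga.sum()) + sum_gb
    return MomentSummary.from_moments(mean, mean + pair)


def _overlap_support(cohort: Cohort) -> np.ndarray:
    """Clones with at least one cell in every member.

    ``sigma_i^(m)`` and ``sigma_ij^(m)`` vanish whenever the member lacks
    the clone, so restricting the overlap sums to this support is exact.
    """
    stacked = np.vstack([m.counts for m in cohort.members])
    return np.flatnonzero(np.all(stacked >= 1, axis=0))


def sampled_overlap_moments_n(
    cohort: Cohort,
    chunk_size: int | None = None,
) -> MomentSummary:
    """Moments of the sampled M-overlap ``K_s^(M)`` from known counts."""
    cohort.require_n_representation()
    samples = cohort.require_sample_sizes()
    support = _overlap_support(cohort)
    if support.size == 0:
        return MomentSummary.from_moments(0.0, 0.0)
    chunk = _pairsum.resolve_chunk(support.size, chunk_size)
    counts = [m.counts[support] for m in cohort.members]
    tables = [_r_table(m, S) for m, S in zip(cohort.members, samples)]
    sigma = np.ones(support.size)
    for n, table in zip(counts, tables):
        sigma *= 1.0 - table[n]
    mean = float(sigma.sum())
    pair = 0.0
    for start in range(0, support.size, chunk):
        rows = slice(start, min(start + chunk, support.size))
        block = np.ones((rows.stop - rows.start, support.size))
        for n, table in zip(counts, tables):
            idx = np.minimum(n[rows, None] + n[None, :], table.size - 1)
            sigma_ij = (
                1.0
                + table[idx]
                - table[n[rows, None]]
                - table[n[None, :]]
            )
            _pairsum._check_clamp(sigma_ij, rows)
            block *= sigma_ij
        _pairsum._fill_diagonal_block(block, rows, 0.0)
        pair += float(block.sum())
    return MomentSummary.from_moments(mean, mean + pair)


def sampled_overlap_success_probs(cohort: Cohort) -> np.ndarray:
    """Per-clone success ``prod_m sigma_i^(m)`` on the all-member support."""
    cohort.require_n_representation()
    samples = cohort.require_sample_sizes()
    support = _overlap_support(cohort)
    sigma = np.ones(support.size)
    for member, S in zip(cohort.members, samples):
        table = _r_table(member, S, pair=False)
        sigma *= 1.0 - table[member.counts[support]]
    return sigma


def sampled_overlap_pmf(cohort: Cohort) -> DiscretePMF:
    """Distribution of the sampled M-overlap, clone presences independent.

    Poisson-binomial over per-clone success probabilities
    ``prod_m sigma_i^(m)``.  The multinomial/hypergeometric constraint
    couples clones weakly (negatively), so this pmf is exact in its mean
    but slightly overstates the variance; the moments from
    :func:`sampled_overlap_moments_n`, which carry the exact pairwise
    ``sigma_ij`` term, are authoritative for the variance.
    """
    return poisson_binomial_pmf(sampled_overlap_success_probs(cohort))


def sampled_occurrence_p(
    probs_per_member: Sequence[float | tuple[float, float]],
    sample_sizes: Sequence[int] | int,
    group: bool = False,
) -> float:
    """Sampled occurrence probabilities in the p-representation.

    By multinomial conjugacy these are the whole-organism forms with S in
    place of N: ``rho_i(S)``, ``rho_ij(S)`` for a single member, and the
    any-member ``rho~_i(S)``, ``rho~_ij(S)`` with ``group=True``.
    """
    entries = list(probs_per_member)
    sizes = [int(sample_sizes)] if np.isscalar(sample_sizes) else [int(s) for s in sample_sizes]
    if len(sizes) != len(entries):
        raise InvalidInputError("one sample size per member required")
    if any(s < 0 for s in sizes):
        raise InvalidInputError("sample sizes must be >= 0")
    if not group and len(entries) != 1:
        raise InvalidInputError("non-group form takes a single member")
    is_pair = not np.isscalar(entries[0])

    def log_miss(total: float, S: int) -> float:
        if not 0.0 <= total <= 1.0 + 1e-9:
            raise InvalidInputError("probabilities must lie in [0, 1]")
        total = min(total, 1.0)
        if total >= 1.0:
            return -math.inf if S >= 1 else 0.0
        return S * math.log1p(-total)

    if not is_pair:
        total_log = sum(log_miss(float(p), s) for p, s in zip(entries, sizes))
        return -math.expm1(total_log)
    log_i = log_j = log_ij = 0.0
    for (pi, pj), s in zip(entries, sizes):
        if pi + pj > 1.0 + 1e-9:
            raise InvalidInputError("p_i + p_j > 1 for a member")
        log_i += log_miss(float(pi), s)
        log_j += log_miss(float(pj), s)
        log_ij += log_miss(min(float(pi) + float(pj), 1.0), s)
    value = 1.0 - math.exp(log_i) - math.exp(log_j) + math.exp(log_ij)
    return _pairsum.clamp_probability(value)


def sampled_moments_p(
    cohort: Cohort,
    statistic: str,
    chunk_size: int | None = None,
) -> MomentSummary:
    """Sampled moments in the p-representation for a given statistic.

    ``statistic`` is one of ``"richness"`` (single member), or
    ``"group_richness"`` / ``"overlap"`` over all members.  Each is the
    whole-organism formula with exponents ``S^(m)`` instead of
    ``N^(m)``.
    """
    from . import overlap as overlap_mod
    from . import richness as richness_mod

    cohort.require_p_representation()
    samples = cohort.require_sample_sizes()
    sampled = Cohort(
        members=cohort.members,
        population_sizes=samples,
        sample_sizes=samples,
    )
    if statistic == "richness":
        if cohort.num_members != 1:
            raise InvalidInputError("richness statistic needs one member")
        return richness_mod.richness_moments_p(
            cohort.members[0], samples[0], chunk_size
        )
    if statistic == "group_richness":
        return richness_mod.group_richness_moments_p(sampled, chunk_size)
    if statistic == "overlap":
        return overlap_mod.overlap_moments_p(sampled, chunk_size)
    raise InvalidInputError(
        "statistic must be 'richness', 'group_richness' or 'overlap'"
    )


def posterior_expected_richness(
    sample: SampleConfiguration,
    probs: CloneProbabilities,
    N: int,
) -> float:
    """Posterior mean whole-organism richness given a sampled configuration.

    With the multinomial prior, the unsampled ``N - S`` cells are again a
    multinomial draw, so ``E[R | s] = Omega - sum_{j: s_j=0} (1-p_j)^{N-S}``:
    only the sample-absent clones remain uncertain.
    """
    if sample.counts.size != probs.num_clones:
        raise InvalidInputError("sample and probabilities length mismatch")
    S = sample.sample_size
    if S > N:
        raise InvalidInputError("sample size exceeds N")
    absent = probs.probs[sample.counts == 0]
    with np.errstate(divide="ignore"):
        missing = np.exp((N - S) * np.log1p(-np.minimum(absent, 1.0)))
    missing[absent >= 1.0] = 0.0 if N - S >= 1 else 1.0
    return float(probs.num_clones - missing.sum())
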