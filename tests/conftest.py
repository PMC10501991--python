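"""Shared brute-force oracles for the test suite.

These enumerate tiny state spaces exactly (multinomial compositions,
hypergeometric subsets, Bernoulli subsets) and are deliberately
independent of the library's own evaluation paths.
"""

from __future__ import annotations

import itertools
import math
from math import comb

import numpy as np
import pytest


def compositions(total: int, parts: int):
    """All non-negative integer vectors of given length summing to total."""
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in compositions(total - first, parts - 1):
            yield (first, *rest)


def multinomial_pmf(counts, probs) -> float:
    prob = math.factorial(sum(counts))
    for n, p in zip(counts, probs):
        if n > 0 and p == 0:
            return 0.0
        prob *= p**n / math.factorial(n)
    return prob


def hypergeometric_pmf(sample, parent, S) -> float:
    N = sum(parent)
    prob = 1.0 / comb(N, S)
    for s, n in zip(sample, parent):
        if s > n:
            return 0.0
        prob *= comb(n, s)
    return prob


def exact_cohort_moments(ps, Ns, statistic: str) -> tuple[float, float]:
    """Exact mean and second moment of richness/overlap by joint enumeration.

    ``ps`` is a list of per-member probability vectors, ``Ns`` per-member
    draw sizes.  Enumerates every joint configuration of all members'
    multinomial draws; feasible for Omega <= 3, N <= 5, M <= 2-3.
    """
    omega = len(ps[0])
    member_outcomes = []
    for p, n in zip(ps, Ns):
        outcomes = [
            (c, multinomial_pmf(c, p)) for c in compositions(n, omega)
        ]
        member_outcomes.append([(c, w) for c, w in outcomes if w > 0])
    mean = second = 0.0
    for joint in itertools.product(*member_outcomes):
        weight = math.prod(w for _, w in joint)
        counts = np.array([c for c, _ in joint])
        if statistic == "richness":
            value = int(np.count_nonzero(counts[0]))
        elif statistic == "group_richness":
            value = int(np.count_nonzero(counts.sum(axis=0)))
        elif statistic == "overlap":
            value = int(np.count_nonzero(np.all(counts >= 1, axis=0)))
        else:
            raise ValueError(statistic)
        mean += weight * value
        second += weight * value * value
    return mean, second


def exact_sampled_moments(counts_list, Ss, statistic: str) -> tuple[float, float]:
    """Exact sampled richness/overlap moments by hypergeometric enumeration."""
    omega = len(counts_list[0])
    member_outcomes = []
    for n, S in zip(counts_list, Ss):
        outcomes = [
            (s, hypergeometric_pmf(s, n, S))
            for s in compositions(S, omega)
        ]
        member_outcomes.append([(s, w) for s, w in outcomes if w > 0])
    mean = second = 0.0
    for joint in itertools.product(*member_outcomes):
        weight = math.prod(w for _, w in joint)
        samples = np.array([s for s, _ in joint])
        if statistic == "richness":
            value = int(np.count_nonzero(samples[0]))
        elif statistic == "group_richness":
            value = int(np.count_nonzero(samples.sum(axis=0)))
        elif statistic == "overlap":
            value = int(np.count_nonzero(np.all(samples >= 1, axis=0)))
        else:
            raise ValueError(statistic)
        mean += weight * value
        second += weight * value * value
    return mean, second


def subset_poisson_binomial(probs) -> np.ndarray:
    """2^n enumeration of the Poisson binomial pmf."""
    n = len(probs)
    mass = np.zeros(n + 1)
    for bits in itertools.product([0, 1], repeat=n):
        weight = math.prod(
            p if b else 1.0 - p for p, b in zip(probs, bits)
        )
        mass[sum(bits)] += weight
    return mass


def random_probability_vector(rng, omega: int) -> np.ndarray:
    return rng.dirichlet(np.ones(omega))


@pytest.fixture
def rng():
    return np.random.default_rng(20230914)
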