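"""Richness and overlap under truncated power-law clone probabilities.

Ranked clone probabilities ``p_i = i^(-nu) / H_nu(Omega)`` (truncated at
rank Omega, normalized by the generalized harmonic number) are a good
description of measured rank-abundance curves of T-cell repertoires.
For these single-parameter families the expected richness, its coefficient
of variation, and the expected sampled M-overlap admit closed forms in the
large-Omega limit, expressed through the exponential integral

    E(x, y) = int_1^inf t^(-x) exp(-y t) dt = y^(x-1) Gamma(1-x, y)

and the Riemann zeta function.  The closed forms exist on specific
exponent branches (nu = 0, 1/2, 1, and nu > 1 for richness); in between,
direct summation is the supported method and is exposed everywhere as
``method="exact_sum"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import mpmath
import numpy as np
from scipy.special import expn, zeta

from . import _pairsum
from .errors import InvalidInputError, UnsupportedBranchError
from .repertoire import CloneProbabilities
from .richness import MomentSummary

#: Ranks are summed directly up to this bound; an Euler-Maclaurin tail
#: covers the remainder (relative error well below 1e-10).
DIRECT_SUM_LIMIT = 10_000_000

#: Empirical validity gate for the large-nu overlap asymptotic.
NU_ASYMPTOTIC_MIN = 0.7

#: Block size for chunked sums over ranks.
RANK_CHUNK = 5_000_000


def harmonic_number(nu: float, omega: int) -> float:
    """Generalized harmonic number ``H_nu(Omega) = sum_{j=1..Omega} j^-nu``."""
    if omega < 1:
        raise InvalidInputError("omega must be >= 1")
    if nu < 0:
        raise InvalidInputError("nu must be >= 0")
    head = min(omega, DIRECT_SUM_LIMIT)
    total = 0.0
    for start in range(1, head + 1, RANK_CHUNK):
        j = np.arange(start, min(start + RANK_CHUNK, head + 1), dtype=float)
        total += float(np.sum(j**-nu))
    if omega > head:
        # Euler-Maclaurin for the tail sum_{j=head+1..omega} j^-nu.
        a, b = float(head), float(omega)
        f = lambda x: x**-nu
        fp = lambda x: -nu * x ** (-nu - 1.0)
        integral = (
            math.log(b / a) if nu == 1.0
            else (b ** (1.0 - nu) - a ** (1.0 - nu)) / (1.0 - nu)
        )
        total += integral + (f(a) + f(b)) / 2.0 + (fp(b) - fp(a)) / 12.0 - f(a)
    return total


@dataclass(frozen=True)
class PowerLawSpec:
    """Truncated power law ``p_i = i^-nu / H_nu(Omega)``, i = 1..Omega."""

    nu: float
    omega: int

    def __post_init__(self) -> None:
        if self.nu < 0:
            raise InvalidInputError("nu must be >= 0")
        if self.omega < 1:
            raise InvalidInputError("omega must be >= 1")
        object.__setattr__(self, "omega", int(self.omega))

    @property
    def harmonic_norm(self) -> float:
        return harmonic_number(self.nu, self.omega)

    def rank_probabilities(self, ranks: np.ndarray) -> np.ndarray:
        return ranks**-self.nu / self.harmonic_norm


def powerlaw_probabilities(spec: PowerLawSpec) -> CloneProbabilities:
    """Materialize the full descending probability vector."""
    ranks = np.arange(1, spec.omega + 1, dtype=float)
    return CloneProbabilities(spec.rank_probabilities(ranks))


def exponential_integral(x: float, y: float) -> float:
    """``E(x, y) = int_1^inf t^-x exp(-y t) dt`` for y > 0.

    Integer orders use scipy's ``expn``; general orders go through the
    upper-incomplete-gamma relation evaluated in arbitrary precision.
    """
    if y <= 0:
        raise InvalidInputError("y must be positive")
    if x == round(x) and x >= 0:
        return float(expn(int(round(x)), y))
    with mpmath.workdps(30):
        val = mpmath.power(y, x - 1.0) * mpmath.gammainc(1.0 - x, y)
    return float(val)


def _sum_over_ranks(spec: PowerLawSpec, term) -> float:
    """Chunked ``sum_i term(p_i)`` over ranks 1..Omega."""
    total = 0.0
    H = spec.harmonic_norm
    for start in range(1, spec.omega + 1, RANK_CHUNK):
        ranks = np.arange(
            start, min(start + RANK_CHUNK, spec.omega + 1), dtype=float
        )
        total += float(np.sum(term(ranks**-spec.nu / H)))
    return total


def expected_richness_powerlaw(
    spec: PowerLawSpec,
    N: int,
    method: str = "exact_sum",
) -> float:
    """Expected richness of one individual with N cells.

    ``exact_sum`` evaluates the occupancy sum ``sum_i (1 - exp(-N p_i))``
    directly; ``closed_form`` evaluates the large-Omega branch for
    nu in {0, 1/2, 1} or nu > 1.
    """
    if N < 1:
        raise InvalidInputError("N must be >= 1")
    if method == "exact_sum":
        return _sum_over_ranks(spec, lambda p: -np.expm1(-N * p))
    if method != "closed_form":
        raise InvalidInputError("method must be 'exact_sum' or 'closed_form'")
    nu, omega = spec.nu, spec.omega
    if nu == 0.0:
        x = omega / N
        return N * x * -math.expm1(-1.0 / x)
    if nu == 0.5:
        x = omega / N
        return N * x * (1.0 - 2.0 * exponential_integral(3.0, 1.0 / (2.0 * x)))
    if nu == 1.0:
        return N * (
            1.0
            - math.log(N) / math.log(omega)
            + math.log(math.log(omega)) / math.log(omega)
        )
    if nu > 1.0:
        x = omega / N ** (1.0 / nu)
        arg = x**-nu / float(zeta(nu))
        return (
            N ** (1.0 / nu)
            * x
            * (1.0 - exponential_integral(1.0 + 1.0 / nu, arg) / nu)
        )
    raise UnsupportedBranchError(
        f"no closed-form richness branch at nu={nu}; use method='exact_sum'"
    )


def variance_closed_form(spec: PowerLawSpec, N: int) -> float:
    """Exponential-integral approximation to var[R] (nu > 0 branches)."""
    nu, omega = spec.nu, spec.omega
    if nu == 0.0:
        q = math.exp(-N / omega)
        return omega * q * (1.0 - q)
    H = spec.harmonic_norm
    scale = H * omega**nu
    return (omega / nu) * (
        exponential_integral(1.0 + 1.0 / nu, N / scale)
        - exponential_integral(1.0 + 1.0 / nu, 2.0 * N / scale)
    )


def cv2_closed_form(spec: PowerLawSpec, N: int) -> float:
    """Squared coefficient of variation of richness, closed-form branch."""
    nu, omega = spec.nu, spec.omega
    if nu == 0.0:
        x = omega / N
        q = math.exp(-1.0 / x)
        return q / (x * (1.0 - q)) / N
    if nu == 0.5:
        x = omega / N
        e_half = exponential_integral(3.0, 0.5 / x)
        e_full = exponential_integral(3.0, 1.0 / x)
        return (2.0 / x) * (e_half - e_full) / (1.0 - 2.0 * e_half) ** 2 / N
    if nu == 1.0:
        lo = math.log(omega)
        lol = math.log(omega * lo)
        return lo * (lol - math.log(4.0 * N)) / (lol - math.log(N)) ** 2 / N
    if nu > 1.0:
        x = omega / N ** (1.0 / nu)
        z = float(zeta(nu))
        e1 = exponential_integral(1.0 + 1.0 / nu, x**-nu / z)
        e2 = exponential_integral(1.0 + 1.0 / nu, 2.0 * x**-nu / z)
        return (e1 - e2) / (nu * x) / (1.0 - e1 / nu) ** 2 / N ** (1.0 / nu)
    raise UnsupportedBranchError(
        f"no closed-form CV^2 branch at nu={nu}; use richness_dispersion_powerlaw"
    )


def richness_dispersion_powerlaw(
    spec: PowerLawSpec,
    N: int,
    method: str = "exact_sum",
) -> MomentSummary:
    """Mean, variance and CV^2 of single-individual richness.

    ``exact_sum`` uses the direct sums ``mean = sum_i (1 - exp(-p_i N))``
    and ``var = sum_i exp(-p_i N)(1 - exp(-p_i N))``; ``closed_form``
    uses the exponential-integral approximations on the supported
    branches.
    """
    if N < 1:
        raise InvalidInputError("N must be >= 1")
    if method == "exact_sum":
        mean = _sum_over_ranks(spec, lambda p: -np.expm1(-N * p))
        var = _sum_over_ranks(
            spec, lambda p: np.exp(-N * p) * -np.expm1(-N * p)
        )
    elif method == "closed_form":
        mean = expected_richness_powerlaw(spec, N, method="closed_form")
        var = variance_closed_form(spec, N)
    else:
        raise InvalidInputError("method must be 'exact_sum' or 'closed_form'")
    return MomentSummary.from_moments(mean, var + mean * mean)


def expected_overlap_powerlaw(
    spec: PowerLawSpec,
    S: int,
    M: int,
    method: str = "exact_sum",
    approx_exp: bool = False,
) -> float:
    """Expected sampled M-overlap with identical p and S across members.

    ``exact_sum`` evaluates ``sum_i (1 - (1-p_i)^S)^M`` (log1p-based
    powers; ``approx_exp`` swaps in ``exp(-p_i S)``).  ``asymptotic``
    evaluates the nu = 0 line or the large-S line valid for
    nu >= NU_ASYMPTOTIC_MIN.
    """
    if S < 1 or M < 1:
        raise InvalidInputError("need S >= 1 and M >= 1")
    nu, omega = spec.nu, spec.omega
    if method == "exact_sum":
        if approx_exp:
            term = lambda p: (-np.expm1(-S * p)) ** M
        else:
            term = lambda p: (-np.expm1(S * np.log1p(-p))) ** M
        return _sum_over_ranks(spec, term)
    if method != "asymptotic":
        raise InvalidInputError("method must be 'exact_sum' or 'asymptotic'")
    if nu == 0.0:
        return omega * (-math.expm1(-S / omega)) ** M
    if nu >= NU_ASYMPTOTIC_MIN:
        if M < 2:
            raise InvalidInputError("asymptotic overlap branch needs M >= 2")
        H = spec.harmonic_norm
        return (-math.expm1(-S / H)) ** M * (S / (H * math.log(M))) ** (1.0 / nu)
    raise UnsupportedBranchError(
        f"no asymptotic overlap branch for 0 < nu < {NU_ASYMPTOTIC_MIN}; "
        "use method='exact_sum'"
    )


def overlap_variance_powerlaw(
    spec: PowerLawSpec,
    S: int,
    M: int,
    method: str = "binomial",
    chunk_size: int | None = None,
) -> float:
    """Variance of the sampled M-overlap.

    ``binomial`` approximates the overlap as Omega Bernoulli trials at
    the mean rate (accurate for large S and modest nu); ``exact``
    evaluates the pairwise second-moment sum and is quadratic in Omega.
    """
    mean = expected_overlap_powerlaw(spec, S, M, method="exact_sum")
    if method == "binomial":
        q = mean / spec.omega
        return spec.omega * q * (1.0 - q)
    if method != "exact":
        raise InvalidInputError("method must be 'binomial' or 'exact'")
    p = powerlaw_probabilities(spec).probs
    pair = _pairsum.pair_sum_overlap([p] * M, [S] * M, chunk_size)
    second = mean + pair
    return second - mean * mean
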