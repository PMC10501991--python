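"""Chunked evaluation of the O(Omega^2) pair sums behind second moments.

Second moments of richness and overlap all contain a sum over ordered
clone pairs ``i != j`` of pairwise occurrence probabilities.  These sums
are evaluated blockwise with NumPy so memory stays bounded, and they are
guarded: above :data:`PAIR_SUM_LIMIT` clone slots the caller must opt in
by passing an explicit ``chunk_size``.

All ``(1-q)^E`` powers are taken in log space via ``log1p`` so that the
tiny per-clone probabilities typical of repertoires (p ~ 1e-8, N ~ 1e8)
do not lose precision.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidInputError, ResourceGuardError

#: Largest Omega for which pair sums run without an explicit chunk_size.
PAIR_SUM_LIMIT = 50_000

#: Default row-block size for chunked evaluation.
DEFAULT_CHUNK = 4096

#: Inclusion-exclusion results outside [-CLAMP_TOL, 1+CLAMP_TOL] raise.
CLAMP_TOL = 1e-12


#: Upper bound on elements per row block (keeps blocks under ~0.5 GiB).
MAX_BLOCK_ELEMENTS = 64_000_000


def resolve_chunk(omega: int, chunk_size: int | None) -> int:
    if chunk_size is not None:
        if chunk_size < 1:
            raise InvalidInputError("chunk_size must be >= 1")
        chunk = int(chunk_size)
    else:
        if omega > PAIR_SUM_LIMIT:
            raise ResourceGuardError(
                f"pair sum over {omega}^2 ordered pairs exceeds the guard "
                f"limit ({PAIR_SUM_LIMIT}); pass an explicit chunk_size to "
                "enable chunked evaluation"
            )
        chunk = min(omega, DEFAULT_CHUNK)
    return max(1, min(chunk, MAX_BLOCK_ELEMENTS // max(omega, 1)))


def log_absent(p: np.ndarray, exponent: int, approx_exp: bool) -> np.ndarray:
    """``log (1-p_i)^E`` elementwise, or its Poisson approximation ``-E p``."""
    if exponent == 0:
        return np.zeros_like(p)
    if approx_exp:
        return -float(exponent) * p
    with np.errstate(divide="ignore"):
        return float(exponent) * np.log1p(-p)


def _pair_exponent_block(
    p: np.ndarray,
    exponent: int,
    rows: slice,
    approx_exp: bool,
) -> np.ndarray:
    """``(1 - p_i - p_j)^E`` for a row block; diagonal left as computed.

    Raises when ``p_i + p_j`` exceeds one beyond round-off for any
    off-diagonal pair (impossible under a normalized multinomial, so an
    excursion signals inconsistent input).
    """
    s = p[rows, None] + p[None, :]
    offdiag_max = _offdiag_max(s, rows)
    if offdiag_max > 1.0 + 1e-9:
        raise InvalidInputError("p_i + p_j > 1 for a clone pair")
    np.clip(s, 0.0, 1.0, out=s)
    if exponent == 0:
        return np.ones_like(s)
    if approx_exp:
        return np.exp(-float(exponent) * s)
    with np.errstate(divide="ignore"):
        return np.exp(float(exponent) * np.log1p(-s))


def _offdiag_max(s: np.ndarray, rows: slice) -> float:
    s = s.copy()
    _fill_diagonal_block(s, rows, -np.inf)
    return float(s.max()) if s.size else -np.inf


def _fill_diagonal_block(mat: np.ndarray, rows: slice, value: float) -> None:
    start = rows.start or 0
    nrow, ncol = mat.shape
    for r in range(nrow):
        j = start + r
        if 0 <= j < ncol:
            mat[r, j] = value


def pair_sum_group_absent(
    ps: list[np.ndarray],
    exponents: list[int],
    chunk_size: int | None = None,
    approx_exp: bool = False,
) -> float:
    """``sum_{i != j} prod_m (1 - p_i^(m) - p_j^(m))^{E_m}``.

    This is the only quadratic piece of the group-richness second moment:
    the pairwise joint-absence probability of clones i and j across all
    members.
    """
    omega = ps[0].size
    chunk = resolve_chunk(omega, chunk_size)
    total = 0.0
    for start in range(0, omega, chunk):
        rows = slice(start, min(start + chunk, omega))
        block = np.ones((rows.stop - rows.start, omega))
        for p, e in zip(ps, exponents):
            block *= _pair_exponent_block(p, e, rows, approx_exp)
        _fill_diagonal_block(block, rows, 0.0)
        total += float(block.sum())
    return total


def pair_sum_overlap(
    ps: list[np.ndarray],
    exponents: list[int],
    chunk_size: int | None = None,
    approx_exp: bool = False,
) -> float:
    """``sum_{i != j} prod_m rho_ij^(m)`` with inclusion-exclusion per member.

    ``rho_ij^(m) = 1 - (1-p_i)^E - (1-p_j)^E + (1-p_i-p_j)^E`` is the
    probability that both clones appear in member m's draw.
    """
    omega = ps[0].size
    chunk = resolve_chunk(omega, chunk_size)
    absent = [np.exp(log_absent(p, e, approx_exp)) for p, e in zip(ps, exponents)]
    total = 0.0
    for start in range(0, omega, chunk):
        rows = slice(start, min(start + chunk, omega))
        block = np.ones((rows.stop - rows.start, omega))
        for p, e, a in zip(ps, exponents, absent):
            both_absent = _pair_exponent_block(p, e, rows, approx_exp)
            rho_ij = 1.0 - a[rows, None] - a[None, :] + both_absent
            _check_clamp(rho_ij, rows)
            block *= rho_ij
        _fill_diagonal_block(block, rows, 0.0)
        total += float(block.sum())
    return total


def _check_clamp(mat: np.ndarray, rows: slice) -> None:
    """Clamp round-off excursions of probabilities into [0, 1] in place."""
    _fill_diagonal_block(mat, rows, 0.5)  # diagonal is discarded later
    from .errors import NumericalConsistencyError

    lo, hi = float(mat.min()), float(mat.max())
    if lo < -CLAMP_TOL or hi > 1.0 + CLAMP_TOL:
        raise NumericalConsistencyError(
            f"pairwise probability left [0,1]: range [{lo:.3e}, {hi:.3e}]"
        )
    np.clip(mat, 0.0, 1.0, out=mat)


def clamp_probability(value: float, tol: float = CLAMP_TOL) -> float:
    """Clamp a scalar probability to [0, 1]; raise beyond ``tol``."""
    from .errors import NumericalConsistencyError

    if value < -tol or value > 1.0 + tol:
        raise NumericalConsistencyError(
            f"probability {value!r} outside [0, 1] beyond tolerance"
        )
    return min(max(value, 0.0), 1.0)
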