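"""Penalized matrix decomposition (PMD) of the HSIC matrix.

Finds sparse, non-negative, L2-normalized singular vector pairs (eta, mu)
maximizing ``eta^T M mu`` subject to ``||eta||_1 <= c1`` and
``||mu||_1 <= c2``, by alternating soft-thresholded power iterations; further
components are extracted after rank-1 deflation ``M <- M - d eta mu^T``.

The L1 budgets live in ``[1, sqrt(dim)]``: at 1 the unit-L2 constraint forces
a single nonzero coordinate, at ``sqrt(dim)`` the constraint is vacuous
(Cauchy-Schwarz) and the decomposition coincides with the dense SVD restricted
to the non-negative orthant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConvergenceError, DegenerateVectorError, InvalidInputError
from .hsic import HsicMatrix

__all__ = ["soft_threshold", "l1_bound_delta", "pmd_rank1", "pmd_decompose", "SingularPair"]

_BISECT_TOL = 1e-8
_BISECT_MAX_ITER = 200


@dataclass(frozen=True)
class SingularPair:
    """One sparse singular component of the HSIC matrix."""

    eta: np.ndarray  # left weights, length M_x, >= 0, unit L2
    mu: np.ndarray  # right weights, length M_z, >= 0, unit L2
    d: float  # singular value eta^T M mu
    index: int = 0
    p_value: float | None = None
    n_iter: int = 0


def soft_threshold(a: np.ndarray, c: float) -> np.ndarray:
    """Element-wise ``sign(a) (|a| - c)_+``, the proximal map of the L1 norm."""
    if c < 0:
        raise InvalidInputError("soft threshold must be non-negative")
    a = np.asarray(a, dtype=float)
    return np.sign(a) * np.maximum(np.abs(a) - c, 0.0)


def _clamp_normalize(a: np.ndarray) -> np.ndarray:
    """Project onto the non-negative orthant, then the unit L2 sphere."""
    a = np.maximum(a, 0.0)
    nrm = np.linalg.norm(a)
    if nrm == 0.0:
        raise DegenerateVectorError("iterate collapsed to the zero vector")
    return a / nrm


def l1_bound_delta(a: np.ndarray, c: float) -> float:
    """Smallest threshold so the normalized soft-thresholded vector fits in c.

    Returns the smallest ``delta >= 0`` (bisection on ``[0, max|a|]``, to
    within 1e-8) such that ``u = S(a, delta)/||S(a, delta)||_2`` satisfies
    ``||u||_1 <= c``; 0 when the untresholded unit vector already does.
    """
    a = np.asarray(a, dtype=float)
    if c < 1:
        raise InvalidInputError("an L1 budget below 1 is infeasible for a unit vector")
    if not np.any(a):
        raise DegenerateVectorError("cannot threshold an all-zero vector")
    scale = float(np.abs(a).max())  # work on O(1) magnitudes (underflow-safe)
    a = a / scale

    def l1_of(delta: float) -> float:
        s = soft_threshold(a, delta)
        nrm = np.linalg.norm(s)
        return np.inf if nrm == 0.0 else float(np.abs(s).sum() / nrm)

    if l1_of(0.0) <= c * (1 + 1e-12):  # tolerate exact-boundary round-off
        return 0.0
    lo, hi = 0.0, 1.0
    for _ in range(_BISECT_MAX_ITER):
        mid = (lo + hi) / 2
        if l1_of(mid) > c:
            lo = mid
        else:
            hi = mid
        if hi - lo < _BISECT_TOL:
            break
    return hi * scale


def _sparse_unit(a: np.ndarray, c: float) -> np.ndarray:
    """One PMD half-update: clamp, threshold to the L1 budget, L2-normalize."""
    a = np.maximum(np.asarray(a, dtype=float), 0.0)
    if not np.any(a):
        raise DegenerateVectorError("update direction is entirely non-positive")
    delta = l1_bound_delta(a, c)
    s = soft_threshold(a, delta)
    nrm = np.linalg.norm(s)
    if nrm == 0.0 or np.abs(s).sum() / nrm > c + 1e-6:
        # exact ties at the maximum make the budget unattainable by
        # thresholding; break toward the lowest-index coordinate vector
        out = np.zeros_like(a)
        out[int(np.argmax(a))] = 1.0
        return out
    return s / nrm


def _svd_init(m: np.ndarray) -> np.ndarray:
    """Non-negative start: leading left singular vector, sign-flipped, clamped."""
    u = np.linalg.svd(m, full_matrices=False)[0][:, 0]
    if u.sum() < 0:
        u = -u
    u = np.maximum(u, 0.0)
    if not np.any(u):  # perfectly sign-balanced vector; fall back to magnitudes
        u = np.abs(np.linalg.svd(m, full_matrices=False)[0][:, 0])
    return u / np.linalg.norm(u)


def pmd_rank1(
    m: HsicMatrix | np.ndarray,
    c1: float,
    c2: float,
    init: np.ndarray | None = None,
    max_iter: int = 1000,
    tol: float = 1e-6,
    index: int = 0,
) -> SingularPair:
    """Leading sparse non-negative singular pair of ``m``.

    Alternates ``mu <- sparse_unit(M^T eta, c2)`` and
    ``eta <- sparse_unit(M mu, c1)`` from an SVD start until the largest
    change in either vector falls below ``tol``.  Deterministic given ``m``.
    """
    values = m.values if isinstance(m, HsicMatrix) else np.asarray(m, dtype=float)
    if values.size == 0 or not np.any(values):
        raise InvalidInputError("cannot decompose an empty or all-zero matrix")
    if not (1 <= c1 <= np.sqrt(values.shape[0]) + 1e-9):
        raise InvalidInputError(f"c1={c1} outside [1, sqrt({values.shape[0]})]")
    if not (1 <= c2 <= np.sqrt(values.shape[1]) + 1e-9):
        raise InvalidInputError(f"c2={c2} outside [1, sqrt({values.shape[1]})]")

    eta = _svd_init(values) if init is None else _clamp_normalize(np.asarray(init, float))
    mu = np.zeros(values.shape[1])
    try:
        for it in range(1, max_iter + 1):
            mu_new = _sparse_unit(values.T @ eta, c2)
            eta_new = _sparse_unit(values @ mu_new, c1)
            delta = max(
                float(np.abs(eta_new - eta).max()), float(np.abs(mu_new - mu).max())
            )
            eta, mu = eta_new, mu_new
            if delta < tol:
                break
    except DegenerateVectorError as err:
        raise ConvergenceError(
            f"rank-1 update collapsed (c1={c1}, c2={c2}); the residual matrix "
            "may be dominated by negative entries"
        ) from err
    d = float(eta @ values @ mu)
    return SingularPair(eta=eta, mu=mu, d=d, index=index, n_iter=it)


def pmd_decompose(
    m: HsicMatrix | np.ndarray,
    c1: float,
    c2: float,
    n_components: int = 1,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> list[SingularPair]:
    """Successive sparse singular pairs via rank-1 deflation.

    Stops early (returning fewer pairs) once the residual matrix norm drops
    below 1e-12.  Deflation subtracts ``d eta mu^T`` from the residual; the
    residual may go negative — non-negativity applies to the vectors only.
    """
    values = np.array(m.values if isinstance(m, HsicMatrix) else m, dtype=float)
    if n_components > min(values.shape):
        raise InvalidInputError(
            f"{n_components} components requested from a {values.shape} matrix"
        )
    pairs: list[SingularPair] = []
    residual = values
    for i in range(n_components):
        if np.linalg.norm(residual) < 1e-12:
            break
        pair = pmd_rank1(residual, c1, c2, max_iter=max_iter, tol=tol, index=i)
        pairs.append(pair)
        residual = residual - pair.d * np.outer(pair.eta, pair.mu)
    return pairs
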