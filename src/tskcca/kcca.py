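"""Second stage: regularized kernel CCA on the combined, weighted kernels.

For combined kernels ``Kx`` and ``Kz`` the dual problem maximizes
``alpha^T Kx Kz beta`` subject to ``alpha^T (Kx + N kappa/2 I)^2 alpha = 1``
and the analogous constraint on ``beta``.  Substituting
``u = (Kx + c I) alpha`` turns this into the ordinary SVD of the whitened
cross-operator ``R = (Kx + c I)^{-1} Kx Kz (Kz + c I)^{-1}`` — an N x N
problem instead of the raw 2N x 2N generalized eigenproblem, and numerically
better behaved.  The ridge ``kappa`` keeps full-rank kernels from producing
trivial perfect correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .errors import ConditioningError, InvalidInputError, UndefinedCorrelationError

__all__ = ["fit_kcca", "canonical_variables", "test_correlation", "KccaModel"]

DEFAULT_KAPPA = 0.02  # recommended ridge for Gaussian-kernel CCA


@dataclass(frozen=True)
class KccaModel:
    """Fitted dual coefficients for one canonical component."""

    alpha: np.ndarray  # length N
    beta: np.ndarray  # length N
    kappa: float
    rho_train: float  # Pearson correlation of the training canonical variables
    component_index: int = 0
    eta: np.ndarray | None = field(default=None, repr=False)  # first-stage weights
    mu: np.ndarray | None = field(default=None, repr=False)


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    su, sv = u.std(), v.std()
    if su < 1e-300 or sv < 1e-300:
        raise UndefinedCorrelationError("a canonical variable has zero variance")
    return float(np.dot(u - u.mean(), v - v.mean()) / (len(u) * su * sv))


def fit_kcca(
    kx: np.ndarray,
    kz: np.ndarray,
    kappa: float = DEFAULT_KAPPA,
    component_index: int = 0,
    eta: np.ndarray | None = None,
    mu: np.ndarray | None = None,
) -> KccaModel:
    """Leading regularized kernel-CCA pair for combined kernels ``kx``, ``kz``."""
    kx = np.asarray(kx, dtype=float)
    kz = np.asarray(kz, dtype=float)
    if kx.shape != kz.shape or kx.ndim != 2 or kx.shape[0] != kx.shape[1]:
        raise InvalidInputError(f"kernel shapes {kx.shape}, {kz.shape} do not match")
    if not (np.isfinite(kx).all() and np.isfinite(kz).all()):
        raise InvalidInputError("non-finite combined kernel")
    if kappa <= 0:
        raise InvalidInputError("kappa must be positive")
    n = kx.shape[0]
    ridge = n * kappa / 2.0
    eye = np.eye(n)
    try:
        fx = cho_factor(kx + ridge * eye)
        fz = cho_factor(kz + ridge * eye)
    except LinAlgError as err:  # kernels so indefinite the ridge cannot fix them
        raise ConditioningError("regularized kernel matrix is not SPD") from err
    sx = cho_solve(fx, kx)  # (Kx + cI)^{-1} Kx, symmetric up to round-off
    sz = cho_solve(fz, kz)
    r = sx @ sz.T
    u, _, vt = np.linalg.svd(r)
    alpha = cho_solve(fx, u[:, 0])
    beta = cho_solve(fz, vt[0])
    fx_scores = kx @ alpha
    gz_scores = kz @ beta
    rho = _pearson(fx_scores, gz_scores)
    if rho < 0:  # orient the pair so the leading correlation is non-negative
        beta = -beta
        rho = -rho
    return KccaModel(
        alpha=alpha,
        beta=beta,
        kappa=kappa,
        rho_train=rho,
        component_index=component_index,
        eta=None if eta is None else np.asarray(eta, float),
        mu=None if mu is None else np.asarray(mu, float),
    )


def canonical_variables(
    cross_kernels: list[np.ndarray], weights: np.ndarray, dual: np.ndarray
) -> np.ndarray:
    """Scores ``(sum_m w_m K_test^(m)) dual`` for out-of-sample points."""
    weights = np.asarray(weights, dtype=float)
    dual = np.asarray(dual, dtype=float)
    if len(cross_kernels) != len(weights):
        raise InvalidInputError(
            f"{len(weights)} weights for {len(cross_kernels)} cross-kernels"
        )
    n_test, n_train = cross_kernels[0].shape
    if dual.shape != (n_train,):
        raise InvalidInputError("dual vector does not match the training sample count")
    scores = np.zeros(n_test)
    for w, k in zip(weights, cross_kernels):
        if k.shape != (n_test, n_train):
            raise InvalidInputError("cross-kernels have inconsistent shapes")
        if w != 0.0:
            scores += w * (k @ dual)
    return scores


def test_correlation(
    model: KccaModel,
    cross_kernels_x: list[np.ndarray],
    cross_kernels_z: list[np.ndarray],
    eta: np.ndarray | None = None,
    mu: np.ndarray | None = None,
) -> float:
    """Held-out canonical correlation of one fitted component.

    Pearson correlation between ``sum_m eta_m K_x,test^(m) alpha`` and
    ``sum_l mu_l K_z,test^(l) beta``; the cross-kernels must come from banks
    built with the training bandwidths and normalizations.
    """
    eta = model.eta if eta is None else eta
    mu = model.mu if mu is None else mu
    if eta is None or mu is None:
        raise InvalidInputError("first-stage weights required for test correlation")
    fx = canonical_variables(cross_kernels_x, eta, model.alpha)
    gz = canonical_variables(cross_kernels_z, mu, model.beta)
    return _pearson(fx, gz)
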