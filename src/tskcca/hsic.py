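"""Empirical Hilbert-Schmidt Independence Criterion (HSIC) between kernels.

The plug-in estimator ``Tr(Kx H Kz H) / (N-1)^2`` with the centering matrix
``H = I - 11^T/N`` measures statistical dependence between the two views as
seen through a pair of kernels.  Stacking it over two sub-kernel banks gives
the matrix ``M`` with ``M[m, l] = HSIC(Kx^(m), Kz^(l))``, whose sparse
singular vectors are the kernel weights of the first stage: the dependence of
the combined kernels is the bilinear form ``eta^T M mu``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateBankError, InvalidInputError
from .kernels import Source, SubKernelBank

__all__ = ["centering_matrix", "center_gram", "hsic", "hsic_matrix", "HsicMatrix"]


def centering_matrix(n: int) -> np.ndarray:
    """The idempotent centering matrix ``H = I - 11^T/n``."""
    return np.eye(n) - np.full((n, n), 1.0 / n)


def center_gram(gram: np.ndarray) -> np.ndarray:
    """``H K H`` without forming H: subtract row/column means, add grand mean."""
    row = gram.mean(axis=0, keepdims=True)
    col = gram.mean(axis=1, keepdims=True)
    return gram - row - col + gram.mean()


@dataclass(frozen=True)
class HsicMatrix:
    """Pairwise HSIC values between two banks, with source metadata."""

    values: np.ndarray  # (M_x, M_z)
    row_sources: list[Source]
    col_sources: list[Source]
    n: int  # sample count the estimates were computed on

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def hsic(kx: np.ndarray, kz: np.ndarray) -> float:
    """Empirical HSIC ``Tr(Kx H Kz H) / (N-1)^2`` of two N x N kernels."""
    kx = np.asarray(kx, dtype=float)
    kz = np.asarray(kz, dtype=float)
    if kx.shape != kz.shape or kx.ndim != 2 or kx.shape[0] != kx.shape[1]:
        raise InvalidInputError(f"kernel shapes {kx.shape} and {kz.shape} do not match")
    n = kx.shape[0]
    if n < 2:
        raise InvalidInputError("HSIC needs at least 2 samples")
    # Tr(Kx H Kz H) = <H Kx H, Kz> elementwise for symmetric kernels
    return float(np.sum(center_gram(kx) * kz)) / (n - 1) ** 2


def centered_stack(bank: SubKernelBank) -> np.ndarray:
    """``H K H`` for every kernel in the bank, stacked to ``(M, N, N)``."""
    grams = bank.grams()
    row = grams.mean(axis=1, keepdims=True)
    col = grams.mean(axis=2, keepdims=True)
    grand = grams.mean(axis=(1, 2), keepdims=True)
    return grams - row - col + grand


def hsic_matrix(bank_x: SubKernelBank, bank_z: SubKernelBank) -> HsicMatrix:
    """The M_x x M_z matrix of pairwise HSIC values between two banks.

    Computed by centering each sub-kernel once and taking Frobenius inner
    products, which is algebraically identical to evaluating the estimator
    per pair.
    """
    if len(bank_x) == 0 or len(bank_z) == 0:
        raise DegenerateBankError("cannot build an HSIC matrix from an empty bank")
    if bank_x.n != bank_z.n:
        raise InvalidInputError("banks were built on different sample counts")
    n = bank_x.n
    cx = centered_stack(bank_x).reshape(len(bank_x), -1)
    # H Kz H is symmetric, so <H Kx H, Kz> = <(H Kx H), (H Kz H)> after one
    # more (idempotent) centering; centering both sides keeps it symmetric.
    cz = centered_stack(bank_z).reshape(len(bank_z), -1)
    values = cx @ cz.T / (n - 1) ** 2
    return HsicMatrix(
        values=values,
        row_sources=bank_x.sources,
        col_sources=bank_z.sources,
        n=n,
    )
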