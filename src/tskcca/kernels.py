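"""Sub-kernel banks for multiple kernel learning.

Each view (an ``N x d`` sample-by-feature matrix) is expanded into a bank of
Gaussian sub-kernels, one per feature (``K[n,n'] = exp{-g (x_nm - x_n'm)^2}``)
and optionally one per unordered feature pair (a Gaussian kernel on the
2-dimensional input ``(x_.m, x_.m')``).  Banks are normalized to unit variance
in the reproducing kernel Hilbert space so that weight coefficients learned
downstream are comparable across sub-kernels of different scales.

Bandwidths follow the median heuristic: ``g = 1 / median(pairwise Euclidean
distances)`` of the inputs feeding the sub-kernel, applied inside
``exp{-g * squared distance}``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence, Union

import numpy as np
from scipy.spatial.distance import pdist, squareform, cdist

from .errors import DegenerateBankError, InvalidInputError

logger = logging.getLogger(__name__)

#: below this, a median distance or an RKHS variance is treated as zero
DEGENERATE_TOL = 1e-12

Source = Union[int, tuple[int, int]]

GammaPolicy = Union[str, float]  # "median_per_kernel" | "median_per_view" | fixed float


@dataclass(frozen=True)
class ViewMatrix:
    """One view: samples in rows, features in columns."""

    values: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise InvalidInputError("view must be a 2-D samples-by-features matrix")
        if values.shape[0] < 2:
            raise InvalidInputError("a view needs at least 2 samples")
        if not np.isfinite(values).all():
            raise InvalidInputError("view contains non-finite values")
        object.__setattr__(self, "values", values)
        names = list(self.feature_names) or [f"f{j + 1}" for j in range(values.shape[1])]
        if len(names) != values.shape[1]:
            raise InvalidInputError(
                f"{len(names)} feature names for {values.shape[1]} columns"
            )
        object.__setattr__(self, "feature_names", names)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def source_name(self, source: Source) -> str:
        if isinstance(source, tuple):
            return f"{self.feature_names[source[0]]}*{self.feature_names[source[1]]}"
        return self.feature_names[source]


@dataclass(frozen=True)
class SubKernel:
    """An ``N x N`` Gram matrix restricted to one feature or feature pair."""

    gram: np.ndarray
    source: Source
    bandwidth: float
    variance: float | None = None  # RKHS variance of the *unnormalized* kernel
    degenerate: bool = False

    @property
    def n(self) -> int:
        return self.gram.shape[0]


@dataclass(frozen=True)
class SubKernelBank:
    """Ordered collection of sub-kernels sharing a sample set."""

    kernels: list[SubKernel]
    view_label: str = ""
    normalized: bool = False
    gamma_policy: GammaPolicy = "median_per_kernel"

    def __len__(self) -> int:
        return len(self.kernels)

    @property
    def n(self) -> int:
        return self.kernels[0].n

    @property
    def sources(self) -> list[Source]:
        return [k.source for k in self.kernels]

    def source_names(self, view: ViewMatrix) -> list[str]:
        return [view.source_name(k.source) for k in self.kernels]

    def grams(self) -> np.ndarray:
        """Stacked Gram matrices, shape ``(len(bank), N, N)``."""
        return np.stack([k.gram for k in self.kernels])


def median_bandwidth(inputs: np.ndarray) -> float:
    """Median-heuristic bandwidth for a Gaussian kernel.

    ``inputs`` is the ``N x d`` block of features feeding one sub-kernel
    (``d = 1`` feature-wise, ``d = 2`` pair-wise).  Returns
    ``g = 1 / median(pairwise Euclidean distances)``; a (near-)constant input,
    whose median distance falls below :data:`DEGENERATE_TOL`, gets the
    fallback ``g = 1``.
    """
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
    if inputs.shape[0] == 1 and inputs.shape[1] > 1:  # 1-D vector passed flat
        inputs = inputs.T
    if inputs.shape[0] < 2:
        raise InvalidInputError("median heuristic needs at least 2 samples")
    if not np.isfinite(inputs).all():
        raise InvalidInputError("non-finite values in kernel input")
    med = float(np.median(pdist(inputs)))
    if med < DEGENERATE_TOL:
        logger.warning("degenerate (constant) kernel input; falling back to gamma=1")
        return 1.0
    return 1.0 / med


def _is_degenerate(inputs: np.ndarray) -> bool:
    return float(np.median(pdist(np.atleast_2d(inputs)))) < DEGENERATE_TOL


def _gaussian_gram(columns: np.ndarray, gamma: float) -> np.ndarray:
    sq = squareform(pdist(columns, "sqeuclidean"))
    return np.exp(-gamma * sq)


def _resolve_gamma(columns: np.ndarray, gamma: GammaPolicy, view_gamma: float | None) -> float:
    if isinstance(gamma, (int, float)):
        if gamma <= 0:
            raise InvalidInputError("fixed bandwidth must be positive")
        return float(gamma)
    if gamma == "median_per_kernel":
        return median_bandwidth(columns)
    if gamma == "median_per_view":
        assert view_gamma is not None
        return view_gamma
    raise InvalidInputError(f"unknown gamma policy {gamma!r}")


def feature_wise_bank(
    view: ViewMatrix, gamma: GammaPolicy = "median_per_kernel", view_label: str = ""
) -> SubKernelBank:
    """One Gaussian sub-kernel per feature (bank size = number of features)."""
    view_gamma = (
        median_bandwidth(view.values) if gamma == "median_per_view" else None
    )
    kernels = []
    for m in range(view.n_features):
        col = view.values[:, m : m + 1]
        g = _resolve_gamma(col, gamma, view_gamma)
        kernels.append(
            SubKernel(
                gram=_gaussian_gram(col, g),
                source=m,
                bandwidth=g,
                degenerate=_is_degenerate(col),
            )
        )
    return SubKernelBank(kernels, view_label=view_label, gamma_policy=gamma)


def pair_wise_bank(
    view: ViewMatrix,
    gamma: GammaPolicy = "median_per_kernel",
    include_features: bool = True,
    view_label: str = "",
) -> SubKernelBank:
    """Sub-kernels on all unordered feature pairs, lexicographic in (m, m').

    By default the single-feature kernels are included first, giving
    ``d + d(d-1)/2`` sub-kernels, which lets the decomposition pick either a
    marginal effect or a cross-feature interaction for each feature.
    """
    if view.n_features < 2:
        raise InvalidInputError("pair-wise kernels need at least 2 features")
    view_gamma = (
        median_bandwidth(view.values) if gamma == "median_per_view" else None
    )
    kernels: list[SubKernel] = []
    if include_features:
        kernels.extend(feature_wise_bank(view, gamma, view_label).kernels)
    for m in range(view.n_features):
        for m2 in range(m + 1, view.n_features):
            cols = view.values[:, [m, m2]]
            g = _resolve_gamma(cols, gamma, view_gamma)
            kernels.append(
                SubKernel(
                    gram=_gaussian_gram(cols, g),
                    source=(m, m2),
                    bandwidth=g,
                    degenerate=_is_degenerate(cols),
                )
            )
    return SubKernelBank(kernels, view_label=view_label, gamma_policy=gamma)


def build_bank(
    view: ViewMatrix,
    mode: str = "feature",
    gamma: GammaPolicy = "median_per_kernel",
    view_label: str = "",
) -> SubKernelBank:
    """Build a bank by mode: ``feature``, ``feature+pair``, or ``pair``."""
    if mode == "feature":
        return feature_wise_bank(view, gamma, view_label)
    if mode == "feature+pair":
        return pair_wise_bank(view, gamma, include_features=True, view_label=view_label)
    if mode == "pair":
        return pair_wise_bank(view, gamma, include_features=False, view_label=view_label)
    raise InvalidInputError(f"unknown kernel mode {mode!r}")


def rkhs_variance(kernel: SubKernel | np.ndarray) -> float:
    """Variance of the kernel feature map: ``mean(diag K) - mean(K)``.

    This is the empirical variance of ``phi(x_n)`` around its mean in the
    RKHS; it is non-negative for PSD kernels and is clamped at 0 against
    round-off.
    """
    gram = kernel.gram if isinstance(kernel, SubKernel) else np.asarray(kernel, float)
    return max(float(gram.trace() / gram.shape[0] - gram.mean()), 0.0)


def normalize_bank(bank: SubKernelBank) -> SubKernelBank:
    """Scale every sub-kernel to unit RKHS variance (``K -> K / sigma^2``).

    Zero-variance kernels (constant inputs) are dropped with a warning so the
    L2-normalized weight vectors downstream stay well defined.  Idempotent.
    """
    if bank.normalized:
        return bank
    kept = []
    for kernel in bank.kernels:
        s2 = rkhs_variance(kernel)
        if s2 < DEGENERATE_TOL:
            logger.warning(
                "dropping zero-variance sub-kernel (source=%s) from bank %r",
                kernel.source,
                bank.view_label,
            )
            continue
        kept.append(replace(kernel, gram=kernel.gram / s2, variance=s2))
    if not kept:
        raise DegenerateBankError(
            f"all sub-kernels in bank {bank.view_label!r} had zero variance"
        )
    return SubKernelBank(
        kept, view_label=bank.view_label, normalized=True, gamma_policy=bank.gamma_policy
    )


def combine(bank: SubKernelBank, weights: np.ndarray) -> np.ndarray:
    """Weighted sum of the bank's Gram matrices, ``K = sum_m w_m K^(m)``."""
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (len(bank),):
        raise InvalidInputError(
            f"{weights.shape} weights for a bank of {len(bank)} kernels"
        )
    if (weights < 0).any():
        raise InvalidInputError("kernel weights must be non-negative")
    n = bank.n
    out = np.zeros((n, n))
    for w, kernel in zip(weights, bank.kernels):
        if w != 0.0:
            out += w * kernel.gram
    return out


def cross_bank(
    train_view: ViewMatrix, test_view: ViewMatrix, bank: SubKernelBank
) -> list[np.ndarray]:
    """Cross-kernels ``K_test^(m)`` (``N_test x N_train``) for a fitted bank.

    Each matrix re-evaluates the training sub-kernel between test and
    training samples, reusing the training bandwidth and, for a normalized
    bank, the training RKHS variance; nothing is re-estimated from test data.
    """
    if test_view.feature_names != train_view.feature_names:
        raise InvalidInputError("test view features do not match the training view")
    out = []
    for kernel in bank.kernels:
        idx = list(kernel.source) if isinstance(kernel.source, tuple) else [kernel.source]
        sq = cdist(test_view.values[:, idx], train_view.values[:, idx], "sqeuclidean")
        cross = np.exp(-kernel.bandwidth * sq)
        if bank.normalized:
            assert kernel.variance is not None
            cross = cross / kernel.variance
        out.append(cross)
    return out
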