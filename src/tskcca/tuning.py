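"""Permutation testing and sparsity-budget selection.

Significance of a canonical component is judged against the null hypothesis
that the two views are statistically independent: the sample order of one
view is permuted B times, the full two-stage pipeline (HSIC matrix, sparse
decomposition at a fixed budget, kernel CCA) is re-run on each permuted copy,
and the observed training canonical correlation is ranked among the null
ones with the add-one estimator ``p = (1 + #{null >= observed}) / (B + 1)``.

The L1 budgets (c1, c2) are selected on a grid by running this test for the
first component at every grid point and keeping the pair with the lowest
p-value.  Permutation p-values are discrete and frequently tie at their
minimum ``1/(B+1)``; tied grid points resolve toward the sparser budget
(smaller ``c1 + c2``), which keeps the selected supports minimal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, TskccaError
from .hsic import centered_stack, hsic_matrix, HsicMatrix
from .kcca import DEFAULT_KAPPA, fit_kcca
from .kernels import build_bank, normalize_bank, GammaPolicy, SubKernelBank, ViewMatrix
from .pmd import pmd_decompose, SingularPair

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationResult",
    "GridSearchResult",
    "permutation_test",
    "permutation_pvalue",
    "grid_search",
    "default_grid",
]


@dataclass(frozen=True)
class PermutationResult:
    """Permutation test outcome for one component at one budget."""

    p_value: float
    b: int  # number of permutations
    observed: float  # training canonical correlation on intact data
    nulls: np.ndarray  # length-b null statistics (+inf marks a failed replicate)
    component_index: int  # 1-based
    c1: float
    c2: float
    n_failures: int = 0


@dataclass(frozen=True)
class GridSearchResult:
    """Selected budget and the per-grid-point first-component tests."""

    c1: float
    c2: float
    result: PermutationResult
    table: list[PermutationResult]


@dataclass(frozen=True)
class PreparedViews:
    """Normalized banks and cached centered kernels for one paired dataset."""

    bank_x: SubKernelBank
    bank_z: SubKernelBank
    grams_x: np.ndarray  # (M_x, N, N) normalized Gram stack
    grams_z: np.ndarray
    m: HsicMatrix
    centered_x_flat: np.ndarray  # (M_x, N*N)
    centered_z: np.ndarray  # (M_z, N, N)


def prepare_views(
    x: ViewMatrix | np.ndarray,
    z: ViewMatrix | np.ndarray,
    kernel_mode: str = "feature",
    gamma: GammaPolicy = "median_per_kernel",
) -> PreparedViews:
    """Build, normalize, and center the sub-kernel banks for both views."""
    vx = x if isinstance(x, ViewMatrix) else ViewMatrix(np.asarray(x, float))
    vz = z if isinstance(z, ViewMatrix) else ViewMatrix(np.asarray(z, float))
    if vx.n_samples != vz.n_samples:
        raise InvalidInputError(
            f"views are not sample-aligned ({vx.n_samples} vs {vz.n_samples} rows)"
        )
    bank_x = normalize_bank(build_bank(vx, kernel_mode, gamma, view_label="x"))
    bank_z = normalize_bank(build_bank(vz, kernel_mode, gamma, view_label="z"))
    cx = centered_stack(bank_x)
    cz = centered_stack(bank_z)
    n = bank_x.n
    m_values = cx.reshape(len(bank_x), -1) @ cz.reshape(len(bank_z), -1).T / (n - 1) ** 2
    m = HsicMatrix(m_values, bank_x.sources, bank_z.sources, n)
    return PreparedViews(
        bank_x=bank_x,
        bank_z=bank_z,
        grams_x=bank_x.grams(),
        grams_z=bank_z.grams(),
        m=m,
        centered_x_flat=cx.reshape(len(bank_x), -1),
        centered_z=cz,
    )


def _combine_stack(weights: np.ndarray, grams: np.ndarray) -> np.ndarray:
    """Weighted sum of a Gram stack, touching only the nonzero weights."""
    idx = np.flatnonzero(weights)
    if idx.size == 0:
        return np.zeros(grams.shape[1:])
    return np.tensordot(weights[idx], grams[idx], axes=1)


def _stage_rhos(
    m_values: np.ndarray,
    grams_x: np.ndarray,
    grams_z: np.ndarray,
    c1: float,
    c2: float,
    n_components: int,
    kappa: float,
) -> tuple[list[SingularPair], np.ndarray]:
    """Both stages: sparse decomposition, then one KCCA fit per component."""
    pairs = pmd_decompose(m_values, c1, c2, n_components)
    rhos = np.full(n_components, -np.inf)
    for i, pair in enumerate(pairs):
        kx = _combine_stack(pair.eta, grams_x)
        kz = _combine_stack(pair.mu, grams_z)
        rhos[i] = fit_kcca(kx, kz, kappa, component_index=i + 1).rho_train
    return pairs, rhos


def _permutations(n: int, b: int, seed: int) -> list[np.ndarray]:
    """B sample-order permutations from independent child streams of seed."""
    children = np.random.SeedSequence(seed).spawn(b)
    return [np.random.default_rng(c).permutation(n) for c in children]


def permutation_test(
    x: ViewMatrix | np.ndarray,
    z: ViewMatrix | np.ndarray,
    c1: float,
    c2: float,
    n_components: int = 1,
    b: int = 100,
    seed: int = 0,
    kernel_mode: str = "feature",
    gamma: GammaPolicy = "median_per_kernel",
    kappa: float = DEFAULT_KAPPA,
    prepared: PreparedViews | None = None,
) -> list[PermutationResult]:
    """Permutation p-values for the first ``n_components`` components.

    All components share the same B permutations of the z-view sample order;
    each permuted replicate repeats the full first stage (including deflation)
    and the second-stage fit.  A replicate that fails inside a stage is
    counted as a null at least as large as the observed statistic
    (conservative) and logged.
    """
    if b < 1:
        raise InvalidInputError("need at least one permutation")
    prep = prepared or prepare_views(x, z, kernel_mode, gamma)
    n = prep.bank_x.n
    pairs, observed = _stage_rhos(
        prep.m.values, prep.grams_x, prep.grams_z, c1, c2, n_components, kappa
    )
    nulls = np.full((b, n_components), np.inf)
    failures = np.zeros(n_components, dtype=int)
    scale = (n - 1) ** 2
    for i, perm in enumerate(_permutations(n, b, seed)):
        cz_perm = prep.centered_z[:, perm][:, :, perm].reshape(len(prep.bank_z), -1)
        m_perm = prep.centered_x_flat @ cz_perm.T / scale
        grams_z_perm = prep.grams_z[:, perm][:, :, perm]
        try:
            _, nulls[i] = _stage_rhos(
                m_perm, prep.grams_x, grams_z_perm, c1, c2, n_components, kappa
            )
        except TskccaError as err:
            failures += 1
            logger.warning("permutation %d failed (%s); counted against rejection", i, err)
    results = []
    for i in range(n_components):
        n_ge = int(np.sum(nulls[:, i] >= observed[i]))
        results.append(
            PermutationResult(
                p_value=(1 + n_ge) / (b + 1),
                b=b,
                observed=float(observed[i]),
                nulls=nulls[:, i].copy(),
                component_index=i + 1,
                c1=c1,
                c2=c2,
                n_failures=int(failures[i]),
            )
        )
    return results


def permutation_pvalue(
    x: ViewMatrix | np.ndarray,
    z: ViewMatrix | np.ndarray,
    c1: float,
    c2: float,
    component: int = 1,
    b: int = 100,
    seed: int = 0,
    **kwargs,
) -> PermutationResult:
    """Permutation test for a single (1-based) component index."""
    if component < 1:
        raise InvalidInputError("component indices are 1-based")
    return permutation_test(
        x, z, c1, c2, n_components=component, b=b, seed=seed, **kwargs
    )[component - 1]


def default_grid(
    m_x: int,
    m_z: int,
    n_grid: int = 10,
    tie_budgets: bool = False,
    c1_max: float | None = None,
    c2_max: float | None = None,
) -> list[tuple[float, float]]:
    """Equally spaced budget grid within ``[1, sqrt(M_x)] x [1, sqrt(M_z)]``.

    With ``tie_budgets`` a single axis with ``c1 = c2`` is used (the protocol
    for symmetric simulation designs).
    """
    hi1 = math.sqrt(m_x) if c1_max is None else c1_max
    hi2 = math.sqrt(m_z) if c2_max is None else c2_max
    if not (1 <= hi1 <= math.sqrt(m_x) + 1e-9 and 1 <= hi2 <= math.sqrt(m_z) + 1e-9):
        raise InvalidInputError("grid bounds outside [1, sqrt(bank size)]")
    if tie_budgets:
        hi = min(hi1, hi2)
        return [(c, c) for c in np.linspace(1.0, hi, n_grid)]
    axis1 = np.linspace(1.0, hi1, n_grid)
    axis2 = np.linspace(1.0, hi2, n_grid)
    return [(c1, c2) for c1 in axis1 for c2 in axis2]


def grid_search(
    x: ViewMatrix | np.ndarray,
    z: ViewMatrix | np.ndarray,
    grid: list[tuple[float, float]] | None = None,
    b: int = 100,
    seed: int = 0,
    kernel_mode: str = "feature",
    gamma: GammaPolicy = "median_per_kernel",
    kappa: float = DEFAULT_KAPPA,
    n_grid: int = 10,
    tie_budgets: bool = False,
    c1_max: float | None = None,
    c2_max: float | None = None,
) -> GridSearchResult:
    """Select (c1, c2) by the first component's permutation p-value.

    The same B permutations are reused across grid points, so p-values are
    comparable and the search is deterministic given the seed.  Ranking is
    lexicographic: smallest p-value, then smallest ``c1 + c2`` (sparser),
    then smallest ``c1``.
    """
    prep = prepare_views(x, z, kernel_mode, gamma)
    if grid is None:
        grid = default_grid(
            len(prep.bank_x), len(prep.bank_z), n_grid, tie_budgets, c1_max, c2_max
        )
    if not grid:
        raise InvalidInputError("empty budget grid")

    observed = np.empty(len(grid))
    for g, (c1, c2) in enumerate(grid):
        _, rhos = _stage_rhos(prep.m.values, prep.grams_x, prep.grams_z, c1, c2, 1, kappa)
        observed[g] = rhos[0]

    n = prep.bank_x.n
    scale = (n - 1) ** 2
    nulls = np.full((b, len(grid)), np.inf)
    failures = np.zeros(len(grid), dtype=int)
    for i, perm in enumerate(_permutations(n, b, seed)):
        cz_perm = prep.centered_z[:, perm][:, :, perm].reshape(len(prep.bank_z), -1)
        m_perm = prep.centered_x_flat @ cz_perm.T / scale
        grams_z_perm = prep.grams_z[:, perm][:, :, perm]
        for g, (c1, c2) in enumerate(grid):
            try:
                _, rhos = _stage_rhos(m_perm, prep.grams_x, grams_z_perm, c1, c2, 1, kappa)
                nulls[i, g] = rhos[0]
            except TskccaError as err:
                failures[g] += 1
                logger.warning(
                    "permutation %d failed at budget %s (%s)", i, (c1, c2), err
                )

    table = []
    for g, (c1, c2) in enumerate(grid):
        n_ge = int(np.sum(nulls[:, g] >= observed[g]))
        table.append(
            PermutationResult(
                p_value=(1 + n_ge) / (b + 1),
                b=b,
                observed=float(observed[g]),
                nulls=nulls[:, g].copy(),
                component_index=1,
                c1=float(c1),
                c2=float(c2),
                n_failures=int(failures[g]),
            )
        )
    best = min(
        range(len(grid)),
        key=lambda g: (table[g].p_value, grid[g][0] + grid[g][1], grid[g][0]),
    )
    return GridSearchResult(
        c1=float(grid[best][0]), c2=float(grid[best][1]), result=table[best], table=table
    )
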