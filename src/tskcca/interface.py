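"""End-to-end pipeline, configuration, and delimited-text / JSON I/O.

``run_tskcca`` wires the stages together: sub-kernel banks are built and
normalized for both views, the HSIC matrix between them is decomposed into
sparse non-negative singular pairs (with the L1 budgets either fixed or
selected on a grid by permutation test), and each pair's weighted kernels are
passed to regularized kernel CCA; optional held-out views give test
correlations and an optional permutation test gives per-component p-values.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .kcca import fit_kcca, test_correlation, KccaModel
from .kernels import cross_bank, GammaPolicy, ViewMatrix
from .pmd import pmd_decompose, SingularPair
from .tuning import grid_search, permutation_test, prepare_views

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ComponentResult", "ResultBundle", "run_tskcca",
           "read_view", "write_results"]


@dataclass
class RunConfig:
    """Everything needed to replay a run; echoed into every result file."""

    kernel_mode: str = "feature"  # "feature" | "feature+pair" | "pair"
    gamma: GammaPolicy = "median_per_kernel"
    kappa: float = 0.02
    c1: float | None = None  # fixed budgets; None triggers the grid search
    c2: float | None = None
    n_components: int = 10
    b_grid: int = 100  # permutations per grid point during budget selection
    b_significance: int = 0  # per-component permutation test; 0 skips it
    n_grid: int = 10
    tie_budgets: bool = False
    c1_max: float | None = None
    c2_max: float | None = None
    seed: int = 0
    standardize: bool = False
    zero_tol: float = 1e-8
    x_path: str | None = None
    z_path: str | None = None

    def validate(self) -> None:
        if self.kernel_mode not in ("feature", "feature+pair", "pair"):
            raise InvalidInputError(f"unknown kernel mode {self.kernel_mode!r}")
        if self.kappa <= 0:
            raise InvalidInputError("kappa must be positive")
        if (self.c1 is None) != (self.c2 is None):
            raise InvalidInputError("set both budgets or neither")
        if self.n_components < 1:
            raise InvalidInputError("need at least one component")
        if self.b_grid < 1:
            raise InvalidInputError("need at least one permutation for the grid")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class ComponentResult:
    """One extracted component with its weights and correlations."""

    index: int  # 1-based extraction order
    eta: dict[str, float]  # nonzero left weights keyed by source name
    mu: dict[str, float]
    d: float  # singular value of the HSIC matrix
    rho_train: float
    p_value: float | None = None
    rho_test: float | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class ResultBundle:
    """Full pipeline output: components, selected budgets, config echo."""

    components: list[ComponentResult]
    c1: float
    c2: float
    config: RunConfig
    sources_x: list[str]
    sources_z: list[str]
    pairs: list[SingularPair] = field(repr=False, default_factory=list)
    models: list[KccaModel] = field(repr=False, default_factory=list)

    def to_dict(self) -> dict:
        return {
            "c1": self.c1,
            "c2": self.c2,
            "components": [c.to_dict() for c in self.components],
            "sources_x": self.sources_x,
            "sources_z": self.sources_z,
            "config": self.config.to_dict(),
        }


def _maybe_standardize(view: ViewMatrix, on: bool) -> ViewMatrix:
    if not on:
        return view
    values = view.values
    sd = values.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return ViewMatrix((values - values.mean(axis=0)) / sd, view.feature_names)


def run_tskcca(
    config: RunConfig,
    x: ViewMatrix | np.ndarray | None = None,
    z: ViewMatrix | np.ndarray | None = None,
    x_test: ViewMatrix | None = None,
    z_test: ViewMatrix | None = None,
) -> ResultBundle:
    """Run the full two-stage pipeline under one configuration.

    Views may be passed in memory or read from ``config.x_path`` /
    ``config.z_path``.  Deterministic given the config (all randomness flows
    from ``config.seed``).
    """
    config.validate()
    if x is None or z is None:
        if config.x_path is None or config.z_path is None:
            raise InvalidInputError("provide views in memory or via config paths")
        x = read_view(config.x_path)
        z = read_view(config.z_path)
    if not isinstance(x, ViewMatrix):
        x = ViewMatrix(np.asarray(x, float))
    if not isinstance(z, ViewMatrix):
        z = ViewMatrix(np.asarray(z, float))
    if x.n_samples != z.n_samples:
        raise InvalidInputError(
            f"views are not sample-aligned ({x.n_samples} vs {z.n_samples} rows)"
        )
    x = _maybe_standardize(x, config.standardize)
    z = _maybe_standardize(z, config.standardize)

    c1, c2 = config.c1, config.c2
    if c1 is None:
        search = grid_search(
            x, z,
            b=config.b_grid,
            seed=config.seed,
            kernel_mode=config.kernel_mode,
            gamma=config.gamma,
            kappa=config.kappa,
            n_grid=config.n_grid,
            tie_budgets=config.tie_budgets,
            c1_max=config.c1_max,
            c2_max=config.c2_max,
        )
        c1, c2 = search.c1, search.c2
        logger.info("grid search selected c1=%.4g c2=%.4g (p=%.4g)",
                    c1, c2, search.result.p_value)

    prep = prepare_views(x, z, config.kernel_mode, config.gamma)
    n_components = min(config.n_components, *prep.m.shape)
    pairs = pmd_decompose(prep.m, c1, c2, n_components)

    p_values: list[float | None] = [None] * len(pairs)
    if config.b_significance > 0:
        results = permutation_test(
            x, z, c1, c2,
            n_components=len(pairs),
            b=config.b_significance,
            seed=config.seed,
            kernel_mode=config.kernel_mode,
            gamma=config.gamma,
            kappa=config.kappa,
            prepared=prep,
        )
        p_values = [r.p_value for r in results]

    cross_x = cross_z = None
    if x_test is not None and z_test is not None:
        cross_x = cross_bank(x, x_test, prep.bank_x)
        cross_z = cross_bank(z, z_test, prep.bank_z)

    names_x = prep.bank_x.source_names(x)
    names_z = prep.bank_z.source_names(z)
    components, models = [], []
    for pair, p_val in zip(pairs, p_values):
        kx = prep.grams_x[np.flatnonzero(pair.eta)]
        kz = prep.grams_z[np.flatnonzero(pair.mu)]
        model = fit_kcca(
            np.tensordot(pair.eta[np.flatnonzero(pair.eta)], kx, axes=1),
            np.tensordot(pair.mu[np.flatnonzero(pair.mu)], kz, axes=1),
            config.kappa,
            component_index=pair.index + 1,
            eta=pair.eta,
            mu=pair.mu,
        )
        rho_test = None
        if cross_x is not None:
            rho_test = test_correlation(model, cross_x, cross_z)
        models.append(model)
        components.append(
            ComponentResult(
                index=pair.index + 1,
                eta={n: float(w) for n, w in zip(names_x, pair.eta)
                     if w > config.zero_tol},
                mu={n: float(w) for n, w in zip(names_z, pair.mu)
                    if w > config.zero_tol},
                d=pair.d,
                rho_train=model.rho_train,
                p_value=p_val,
                rho_test=rho_test,
            )
        )
    return ResultBundle(
        components=components,
        c1=float(c1),
        c2=float(c2),
        config=config,
        sources_x=names_x,
        sources_z=names_z,
        pairs=pairs,
        models=models,
    )


def read_view(
    path: str | Path,
    sep: str | None = None,
    no_header: bool = False,
    sample_id_col: str | None = None,
) -> ViewMatrix:
    """Read a delimited numeric matrix (header row of feature names).

    The separator is inferred from the extension (``.tsv`` -> tab, else
    comma) unless given.  With ``no_header`` the features are auto-named
    ``f1..fd``.  ``sample_id_col`` names a non-numeric identifier column to
    drop after recording it (used only for alignment checks by callers).
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        frame = pd.read_csv(
            path, sep=sep, header=None if no_header else 0,
            float_precision="round_trip",
        )
    except pd.errors.ParserError as err:
        raise InvalidInputError(f"{path}: malformed delimited text ({err})") from err
    if sample_id_col is not None and sample_id_col in frame.columns:
        frame = frame.drop(columns=[sample_id_col])
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().values.any() and not frame.isna().values.any():
        row, col = np.argwhere(numeric.isna().values)[0]
        raise InvalidInputError(
            f"{path}: non-numeric value at row {row + 1}, column {frame.columns[col]!r}"
        )
    if numeric.isna().values.any():
        row, col = np.argwhere(numeric.isna().values)[0]
        raise InvalidInputError(
            f"{path}: missing value at row {row + 1}, column {frame.columns[col]!r}"
        )
    names = [f"f{j + 1}" for j in range(frame.shape[1])] if no_header else [
        str(c) for c in frame.columns
    ]
    return ViewMatrix(numeric.to_numpy(dtype=float), names)


def write_view(view: ViewMatrix, path: str | Path, sep: str = ",") -> None:
    """Write a view as delimited text at full precision (lossless round-trip)."""
    pd.DataFrame(view.values, columns=view.feature_names).to_csv(
        path, sep=sep, index=False, float_format="%.17g"
    )


def write_results(bundle: ResultBundle, path: str | Path) -> None:
    """Serialize a result bundle to JSON (sorted keys, reproducible bytes)."""
    Path(path).write_text(json.dumps(bundle.to_dict(), indent=2, sort_keys=True))
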