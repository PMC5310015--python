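"""Synthetic paired-view benchmarks with known relevant features.

Three generative designs exercise the method's claims:

1. a single nonlinear (quadratic) association ``z1 = x1^2 + noise``,
   invisible to linear CCA because ``corr(x1, x1^2) = 0`` on symmetric
   support;
2. three simultaneous additive nonlinear associations
   (``z1 = x1 + exp(-x4^2)``, ``z2 = x2^2 + sin(pi x5 / 2)``,
   ``z3 = |x3| + sigmoid(5 x6)``, each plus N(0, 0.1^2) noise) hidden among
   22 pure-noise response columns, testing multi-component recovery;
3. a pure multiplicative interaction ``z1 = x1 x2 + noise``, detectable only
   through pair-wise kernels.

All background features are i.i.d. uniform on [-0.5, 0.5].  Each generator
can also emit an independent test split drawn from the same process, and
records the ground-truth relevant features (or feature pairs) so selections
can be scored by precision and recall.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import InvalidInputError
from .kernels import ViewMatrix
from .pmd import SingularPair

__all__ = [
    "SyntheticDataset",
    "SelectionScore",
    "generate_dataset1",
    "generate_dataset2",
    "generate_dataset3",
    "score_selection",
]


@dataclass(frozen=True)
class SyntheticDataset:
    """Paired views plus ground-truth relevance metadata."""

    x: ViewMatrix
    z: ViewMatrix
    relevant_x: frozenset[str]  # feature names, or "xa*xb" for a pair
    relevant_z: frozenset[str]
    noise_sd: float
    seed: int
    x_test: ViewMatrix | None = None
    z_test: ViewMatrix | None = None

    @property
    def relevant(self) -> frozenset[str]:
        return self.relevant_x | self.relevant_z

    def to_dict(self) -> dict:
        return {
            "relevant_x": sorted(self.relevant_x),
            "relevant_z": sorted(self.relevant_z),
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "n": self.x.n_samples,
            "d_x": self.x.n_features,
            "d_z": self.z.n_features,
        }


@dataclass(frozen=True)
class SelectionScore:
    """Precision/recall of a retrieved feature set against ground truth."""

    precision: float | None  # None when nothing was retrieved
    recall: float
    retrieved: frozenset[str] = field(default_factory=frozenset)


def _names(prefix: str, d: int) -> list[str]:
    return [f"{prefix}.{j + 1}" for j in range(d)]


def _uniform(rng: np.random.Generator, n: int, d: int) -> np.ndarray:
    return rng.uniform(-0.5, 0.5, size=(n, d))


def _draw_dataset1(rng: np.random.Generator, n: int, d: int, s: float):
    x = _uniform(rng, n, d)
    z = _uniform(rng, n, d)
    z[:, 0] = x[:, 0] ** 2 + rng.normal(0.0, s, size=n)
    return x, z


def generate_dataset1(
    n: int = 100, d: int = 10, s: float = 0.05, seed: int = 0, n_test: int = 0
) -> SyntheticDataset:
    """Single quadratic association: ``z.1 = x.1^2 + N(0, s^2)``."""
    if n < 2 or d < 1 or s < 0:
        raise InvalidInputError("need n >= 2, d >= 1, s >= 0")
    rng = np.random.default_rng(seed)
    x, z = _draw_dataset1(rng, n, d, s)
    xt = zt = None
    if n_test:
        xt_arr, zt_arr = _draw_dataset1(rng, n_test, d, s)
        xt = ViewMatrix(xt_arr, _names("x", d))
        zt = ViewMatrix(zt_arr, _names("z", d))
    return SyntheticDataset(
        x=ViewMatrix(x, _names("x", d)),
        z=ViewMatrix(z, _names("z", d)),
        relevant_x=frozenset({"x.1"}),
        relevant_z=frozenset({"z.1"}),
        noise_sd=s,
        seed=seed,
        x_test=xt,
        z_test=zt,
    )


def _draw_dataset2(rng: np.random.Generator, n: int, d: int, s: float):
    x = _uniform(rng, n, d)
    z = _uniform(rng, n, d)
    eps = rng.normal(0.0, s, size=(n, 3))
    z[:, 0] = x[:, 0] + np.exp(-x[:, 3] ** 2) + eps[:, 0]
    z[:, 1] = x[:, 1] ** 2 + np.sin(np.pi * x[:, 4] / 2) + eps[:, 1]
    z[:, 2] = np.abs(x[:, 2]) + 1.0 / (1.0 + np.exp(-5.0 * x[:, 5])) + eps[:, 2]
    return x, z


def generate_dataset2(n: int = 100, seed: int = 0, n_test: int = 0) -> SyntheticDataset:
    """Three additive nonlinear associations among 25+25 features.

    The design is fixed at 25 features per view with noise sd 0.1; only the
    sample size is free (the training size is a choice of this package, with
    100 as the default).
    """
    if n < 2:
        raise InvalidInputError("need n >= 2")
    d, s = 25, 0.1
    rng = np.random.default_rng(seed)
    x, z = _draw_dataset2(rng, n, d, s)
    xt = zt = None
    if n_test:
        xt_arr, zt_arr = _draw_dataset2(rng, n_test, d, s)
        xt = ViewMatrix(xt_arr, _names("x", d))
        zt = ViewMatrix(zt_arr, _names("z", d))
    return SyntheticDataset(
        x=ViewMatrix(x, _names("x", d)),
        z=ViewMatrix(z, _names("z", d)),
        relevant_x=frozenset({f"x.{j}" for j in range(1, 7)}),
        relevant_z=frozenset({f"z.{j}" for j in range(1, 4)}),
        noise_sd=s,
        seed=seed,
        x_test=xt,
        z_test=zt,
    )


def _draw_dataset3(rng: np.random.Generator, n: int, d: int, s: float):
    x = _uniform(rng, n, d)
    z = _uniform(rng, n, d)
    z[:, 0] = x[:, 0] * x[:, 1] + rng.normal(0.0, s, size=n)
    return x, z


def generate_dataset3(
    n: int = 100, d: int = 5, seed: int = 0, n_test: int = 0
) -> SyntheticDataset:
    """Multiplicative interaction: ``z.1 = x.1 x.2 + N(0, 0.1^2)``."""
    if n < 2 or d < 2:
        raise InvalidInputError("need n >= 2 and d >= 2")
    s = 0.1
    rng = np.random.default_rng(seed)
    x, z = _draw_dataset3(rng, n, d, s)
    xt = zt = None
    if n_test:
        xt_arr, zt_arr = _draw_dataset3(rng, n_test, d, s)
        xt = ViewMatrix(xt_arr, _names("x", d))
        zt = ViewMatrix(zt_arr, _names("z", d))
    return SyntheticDataset(
        x=ViewMatrix(x, _names("x", d)),
        z=ViewMatrix(z, _names("z", d)),
        relevant_x=frozenset({"x.1*x.2"}),
        relevant_z=frozenset({"z.1"}),
        noise_sd=s,
        seed=seed,
        x_test=xt,
        z_test=zt,
    )


def score_selection(
    pairs: SingularPair | Iterable[SingularPair],
    sources_x: Sequence[str],
    sources_z: Sequence[str],
    truth: SyntheticDataset,
    zero_tol: float = 1e-8,
) -> SelectionScore:
    """Precision/recall of the sub-kernels retrieved by one or more components.

    ``sources_x`` / ``sources_z`` are the feature (or ``"a*b"`` pair) names of
    the bank entries, aligned with the weight vectors.  A sub-kernel is
    retrieved when its weight exceeds ``zero_tol`` in any supplied component.
    """
    if isinstance(pairs, SingularPair):
        pairs = [pairs]
    retrieved: set[str] = set()
    for pair in pairs:
        if len(pair.eta) != len(sources_x) or len(pair.mu) != len(sources_z):
            raise InvalidInputError("weight vectors do not match the source lists")
        retrieved.update(
            name for w, name in zip(pair.eta, sources_x) if w > zero_tol
        )
        retrieved.update(name for w, name in zip(pair.mu, sources_z) if w > zero_tol)
    relevant = set(truth.relevant)
    hits = len(retrieved & relevant)
    precision = hits / len(retrieved) if retrieved else None
    recall = hits / len(relevant)
    return SelectionScore(
        precision=precision, recall=recall, retrieved=frozenset(retrieved)
    )
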