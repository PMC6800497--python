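"""Phenotype, environmental target, metabolic error and fitness.

Each functional protein contributes a triangle
``x -> e * h * max(0, 1 - |x - m| / w)`` on the trait axis [0, 1].  The
phenotype sums activation (h > 0) and inhibition (h < 0) separately, caps
each at 1, and floors their difference at 0, yielding a [0,1] -> [0,1]
piecewise-linear function.  The environment is the optimal phenotypic
function: a clipped sum of three Gaussians.  The metabolic error ``g`` is
the integral of the absolute difference between phenotype and target
(trapezoidal rule on a uniform grid), and fitness is ``exp(-k * g)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotation import Annotation, AnnotationParams, DEFAULT_PARAMS, Protein, annotate
from .genome import Genome

__all__ = [
    "N_INTERVALS",
    "DEFAULT_GAUSSIANS",
    "CurveGrid",
    "PhenotypicTarget",
    "Individual",
    "Evaluator",
    "compute_phenotype",
    "metabolic_error",
    "fitness",
]

#: Default number of uniform intervals on [0, 1] (301 grid points).
N_INTERVALS = 300

#: (height, mean, sd) of the three Gaussians of the fixed environment.
DEFAULT_GAUSSIANS: tuple[tuple[float, float, float], ...] = (
    (1.2, 0.5, 0.12),
    (-1.4, 0.52, 0.07),
    (0.3, 0.8, 0.03),
)

#: Default selection intensity k in fitness = exp(-k * g).
DEFAULT_K = 1000.0


@dataclass(frozen=True)
class CurveGrid:
    """A [0,1] -> R function sampled on a uniform grid."""

    values: np.ndarray
    x: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        x = self.x if self.x is not None else np.linspace(0.0, 1.0, v.size)
        object.__setattr__(self, "x", np.asarray(x, dtype=float))
        if self.x.size != v.size:
            raise ValueError("grid and values size mismatch")

    @property
    def n_points(self) -> int:
        return self.values.size


def grid_x(n_intervals: int = N_INTERVALS) -> np.ndarray:
    return np.linspace(0.0, 1.0, n_intervals + 1)


class PhenotypicTarget:
    """Clipped Gaussian-sum environmental target on a uniform grid."""

    def __init__(
        self,
        gaussians: Sequence[tuple[float, float, float]] = DEFAULT_GAUSSIANS,
        n_intervals: int = N_INTERVALS,
    ):
        self.gaussians = tuple(tuple(map(float, g)) for g in gaussians)
        x = grid_x(n_intervals)
        self.curve = CurveGrid(np.clip(self.raw(x), 0.0, 1.0), x)

    def raw(self, x: np.ndarray) -> np.ndarray:
        """Unclipped Gaussian sum, evaluated anywhere."""
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for h, mu, sd in self.gaussians:
            out += h * np.exp(-((x - mu) ** 2) / (2.0 * sd**2))
        return out

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return np.clip(self.raw(x), 0.0, 1.0)


def compute_phenotype(
    proteins: Sequence[Protein], n_intervals: int = N_INTERVALS
) -> CurveGrid:
    """Triangle-sum phenotype on the grid.

    Activation ``A = min(1, sum of h>0 triangles)`` and inhibition
    ``I = min(1, sum of |h<0 triangles|)`` are capped separately; the
    phenotype is ``max(0, A - I)`` (traits more inhibited than activated
    are set to 0).
    """
    x = grid_x(n_intervals)
    act = np.zeros_like(x)
    inh = np.zeros_like(x)
    for p in proteins:
        if not p.is_functional:
            continue
        tri = p.e * p.h * np.maximum(0.0, 1.0 - np.abs(x - p.m) / p.w)
        if p.h > 0:
            act += tri
        else:
            inh += -tri
    P = np.maximum(0.0, np.minimum(1.0, act) - np.minimum(1.0, inh))
    return CurveGrid(P, x)


def metabolic_error(P: CurveGrid, target: PhenotypicTarget | CurveGrid) -> float:
    """Integral of |phenotype - target| over [0, 1] (trapezoidal rule)."""
    T = target.curve if isinstance(target, PhenotypicTarget) else target
    if P.n_points != T.n_points:
        raise ValueError(
            f"grid mismatch: phenotype has {P.n_points} points, target {T.n_points}"
        )
    return float(np.trapezoid(np.abs(P.values - T.values), P.x))


def fitness(g: float, k: float = DEFAULT_K) -> float:
    """Exponential fitness exp(-k*g); strictly decreasing in g, always > 0."""
    if g < 0:
        raise ValueError("metabolic error must be >= 0")
    if k <= 0:
        raise ValueError("selection intensity k must be > 0")
    return float(np.exp(-k * g))


class Individual:
    """A genome with its cached annotation, phenotype, error and fitness."""

    def __init__(
        self,
        genome: Genome,
        target: PhenotypicTarget | None = None,
        params: AnnotationParams = DEFAULT_PARAMS,
        k: float = DEFAULT_K,
    ):
        self.genome = genome
        self.params = params
        self.k = k
        self.target = target if target is not None else PhenotypicTarget()
        self._annotation: Annotation | None = None
        self._phenotype: CurveGrid | None = None
        self._g: float | None = None

    @property
    def annotation(self) -> Annotation:
        if self._annotation is None:
            self._annotation = annotate(self.genome, self.params)
        return self._annotation

    @property
    def phenotype(self) -> CurveGrid:
        if self._phenotype is None:
            self._phenotype = compute_phenotype(
                self.annotation.proteins, self.target.curve.n_points - 1
            )
        return self._phenotype

    @property
    def g(self) -> float:
        if self._g is None:
            self._g = metabolic_error(self.phenotype, self.target)
        return self._g

    @property
    def fitness(self) -> float:
        return fitness(self.g, self.k)


class Evaluator:
    """Genome -> metabolic error pipeline with a content-addressed cache.

    Clonal populations re-evaluate identical genomes constantly; caching
    on the raw bit string makes the generation loop scale with the number
    of *distinct* mutated offspring rather than with population size.
    """

    def __init__(
        self,
        target: PhenotypicTarget | None = None,
        params: AnnotationParams = DEFAULT_PARAMS,
        k: float = DEFAULT_K,
        max_cache: int = 50_000,
    ):
        self.target = target if target is not None else PhenotypicTarget()
        self.params = params
        self.k = k
        self.max_cache = max_cache
        self._cache: dict[bytes, float] = {}

    def error_of(self, genome: Genome) -> float:
        key = genome.tobytes()
        g = self._cache.get(key)
        if g is None:
            ann = annotate(genome, self.params)
            P = compute_phenotype(ann.proteins, self.target.curve.n_points - 1)
            g = metabolic_error(P, self.target)
            if len(self._cache) >= self.max_cache:
                self._cache.clear()
            self._cache[key] = g
        return g

    def fitness_of(self, genome: Genome) -> float:
        return fitness(self.error_of(genome), self.k)
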