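"""Synthetic validation scenarios: point clouds from tree-structured complexes.

Each scenario models a cohort of tumors evolving along one of two branches of
a common evolutionary tree.  The latent cell-population profiles are global
vertices in a high-dimensional "gene" space; each tumor belongs to one
branch (subsimplex) and is a random convex combination of that branch's
vertices, plus per-dimension Gaussian measurement noise.  Four named
scenarios cover the qualitative ways two branches can share ancestry:

- A: two line segments joined at a point (3 vertices),
- B: two tetrahedra joined at a point (7 vertices),
- C: two triangles joined at a point (5 vertices),
- D: two triangles sharing an edge (4 vertices).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix

__all__ = ["ScenarioSpec", "GroundTruth", "make_scenario", "scenario_catalog"]

_NAMED_STRUCTURES: dict[str, list[list[int]]] = {
    "A_two_lines_point": [[0, 1], [0, 2]],
    "B_two_tetrahedra_point": [[0, 1, 2, 3], [0, 4, 5, 6]],
    "C_two_triangles_point": [[0, 1, 2], [0, 3, 4]],
    "D_two_triangles_edge": [[0, 1, 2], [0, 1, 3]],
}


@dataclass
class ScenarioSpec:
    """Generative description of one validation scenario.

    noise_level is expressed in units of the per-dimension standard
    deviation of the noiseless mixed data (0.1 steps mirror the validation
    grid, but any value in [0, 1] is accepted).
    """

    name: str = "custom"
    subsimplex_vertex_sets: list[list[int]] = field(default_factory=list)
    n_samples: int = 400
    ambient_dim: int = 25000
    noise_level: float = 0.0
    vertex_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name in _NAMED_STRUCTURES and not self.subsimplex_vertex_sets:
            self.subsimplex_vertex_sets = [
                list(s) for s in _NAMED_STRUCTURES[self.name]
            ]
        if not self.subsimplex_vertex_sets:
            raise ValueError("a custom scenario needs subsimplex_vertex_sets")
        if any(len(s) < 2 for s in self.subsimplex_vertex_sets):
            raise ValueError("every subsimplex needs at least 2 vertices")
        if not (0 <= self.noise_level):
            raise ValueError("noise_level must be nonnegative")
        if self.ambient_dim < 2:
            raise ValueError("ambient_dim must be at least 2")
        if self.vertex_scale <= 0:
            raise ValueError("vertex_scale must be positive")
        if self.n_samples < self.total_vertices:
            raise ValueError("n_samples must be at least the total vertex count")

    @property
    def total_vertices(self) -> int:
        return len({v for s in self.subsimplex_vertex_sets for v in s})

    @property
    def n_subsimplices(self) -> int:
        return len(self.subsimplex_vertex_sets)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


@dataclass
class GroundTruth:
    """True components, fractions and branch labels behind a scenario draw."""

    C_true: np.ndarray  # vertices x ambient_dim
    F_true: np.ndarray  # vertices x n_samples
    subsimplex_label: np.ndarray  # per-sample branch index
    noiseless_X: np.ndarray  # ambient_dim x n_samples, before noise

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.C_true).to_csv(outdir / "C_true.tsv", sep="\t")
        pd.DataFrame(self.F_true).to_csv(outdir / "F_true.tsv", sep="\t")
        pd.DataFrame({"subsimplex": self.subsimplex_label}).to_csv(
            outdir / "labels.tsv", sep="\t"
        )


def make_scenario(spec: ScenarioSpec) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw one data set from a scenario.

    Vertices are i.i.d. spherical Gaussian of scale ``vertex_scale`` in the
    ambient space; each sample picks a branch uniformly, draws flat
    Dirichlet(1,...,1) fractions over that branch's vertices, and receives
    additive Gaussian noise with per-dimension sd equal to ``noise_level``
    times the per-dimension sd of the noiseless mixed data.  Fully
    deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.total_vertices
    g = spec.ambient_dim
    n = spec.n_samples
    C = rng.normal(scale=spec.vertex_scale, size=(k, g))
    labels = rng.integers(0, spec.n_subsimplices, size=n)
    F = np.zeros((k, n))
    for j in range(n):
        support = spec.subsimplex_vertex_sets[labels[j]]
        F[support, j] = rng.dirichlet(np.ones(len(support)))
    noiseless = C.T @ F  # g x n
    if spec.noise_level > 0:
        sd = noiseless.std(axis=1, ddof=1, keepdims=True)
        noise = rng.normal(size=(g, n)) * (spec.noise_level * sd)
        values = noiseless + noise
    else:
        values = noiseless.copy()
    em = ExpressionMatrix(
        values=values,
        gene_ids=[f"g{i}" for i in range(g)],
        sample_ids=[f"s{j}" for j in range(n)],
    )
    truth = GroundTruth(
        C_true=C, F_true=F, subsimplex_label=labels, noiseless_X=noiseless
    )
    return em, truth


def scenario_catalog(
    n_samples: int = 400,
    ambient_dim: int = 25000,
    noise_level: float = 0.0,
    vertex_scale: float = 1.0,
    seed: int = 0,
) -> list[ScenarioSpec]:
    """The four named scenarios with default parameters, in A-D order."""
    return [
        ScenarioSpec(
            name=name,
            n_samples=n_samples,
            ambient_dim=ambient_dim,
            noise_level=noise_level,
            vertex_scale=vertex_scale,
            seed=seed,
        )
        for name in _NAMED_STRUCTURES
    ]
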