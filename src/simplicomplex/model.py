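"""End-to-end unmixing as a model/results pair.

:class:`SimplicialComplexModel` holds the data and hyperparameters;
``fit(seed)`` runs the full pipeline — per-gene Z-scoring, PCA reduction,
geodesic k-medoids clustering, per-cluster bootstrap simplex fitting, vertex
merging into a simplicial complex, per-sample fraction refitting against the
merged vertices, and back-projection of the merged vertices to gene space —
and returns a :class:`UnmixResults` carrying estimates, uncertainties and a
``summary()`` table.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .cluster import ClusterAssignment, geodesic_distances, kmedoids_cluster
from .merge import (
    BootstrapEnsemble,
    PhylogenyTree,
    SimplicialComplex,
    bootstrap_fit,
    build_complex,
    phylogeny_mst,
)
from .preprocess import (
    ExpressionMatrix,
    GeneSpaceComponents,
    ReducedRepresentation,
    backproject,
    load_expression,
    pca_reduce,
    zscore_rows,
)
from .simplexfit import ObjectiveConfig, estimate_num_vertices, solve_fractions

__all__ = ["PipelineConfig", "SimplicialComplexModel", "UnmixResults", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All pipeline stage parameters in one place.

    Defaults follow the reference choices: 10 principal components,
    gamma=10, p=1, MST penalty, 10 bootstrap replicates; the per-cluster
    vertex counts default to the eigenvalue-spectrum heuristic with a 0.05
    variance-share threshold.
    """

    n_pcs: int = 10
    k_clusters: int = 2
    n_vertices: int | list[int] | str = "auto"
    eigen_threshold: float = 0.05
    gamma: float = 10.0
    p: int = 1
    penalty: str = "mst"
    B: int = 10
    n_restarts: int = 20
    max_iter: int = 30
    tol: float = 1e-6
    constant_gene_policy: str = "drop"

    def objective_config(self, seed: int = 0) -> ObjectiveConfig:
        return ObjectiveConfig(
            gamma=self.gamma,
            p=self.p,
            penalty=self.penalty,
            max_iter=self.max_iter,
            tol=self.tol,
            seed=seed,
        )


class SimplicialComplexModel:
    """Simplicial-complex mixed-membership model of a genes x samples matrix.

    Parameters
    ----------
    data : ExpressionMatrix, DataFrame (genes x samples) or ndarray
    config : PipelineConfig, optional
        Stage parameters; keyword overrides are applied on top.
    """

    def __init__(self, data, config: PipelineConfig | None = None, **overrides):
        if isinstance(data, ExpressionMatrix):
            self.data = data
        elif isinstance(data, pd.DataFrame):
            self.data = ExpressionMatrix(
                values=data.to_numpy(dtype=float),
                gene_ids=[str(i) for i in data.index],
                sample_ids=[str(c) for c in data.columns],
            )
        else:
            self.data = ExpressionMatrix(values=np.asarray(data, dtype=float))
        cfg = config or PipelineConfig()
        if overrides:
            cfg = PipelineConfig(**{**asdict(cfg), **overrides})
        self.config = cfg

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, orientation: str = "genes_by_samples",
                       **kwargs) -> "SimplicialComplexModel":
        if orientation == "samples_by_genes":
            df = df.T
        return cls(df, **kwargs)

    @classmethod
    def from_file(cls, path, dialect: str = "tsv",
                  orientation: str = "genes_by_samples", **kwargs) -> "SimplicialComplexModel":
        return cls(load_expression(path, dialect=dialect, orientation=orientation), **kwargs)

    def fit(self, seed: int = 0, verbose: bool = False) -> "UnmixResults":
        cfg = self.config
        t0 = time.perf_counter()
        log: list[dict] = []

        def stage(name: str, **info) -> None:
            entry = {"stage": name, "elapsed_s": round(time.perf_counter() - t0, 3)}
            entry.update(info)
            log.append(entry)
            if verbose:
                print(json.dumps(entry))

        try:
            Z = zscore_rows(self.data, cfg.constant_gene_policy)
            stage("zscore", genes=Z.n_genes, samples=Z.n_samples)
            n_pcs = min(cfg.n_pcs, Z.n_genes, Z.n_samples - 1)
            reduced = pca_reduce(Z, n_pcs)
            stage("pca", n_components=n_pcs)
            coords = reduced.coords
            D = geodesic_distances(coords)
            assign = kmedoids_cluster(
                D, coords, cfg.k_clusters, n_restarts=cfg.n_restarts, seed=seed
            )
            sizes = np.bincount(assign.labels, minlength=cfg.k_clusters)
            stage("cluster", k=cfg.k_clusters, sizes=sizes.tolist())

            seedseq = np.random.SeedSequence(seed)
            child_seeds = [
                int(s.generate_state(1)[0] % (2**31 - 1))
                for s in seedseq.spawn(cfg.k_clusters)
            ]
            ensembles: list[BootstrapEnsemble] = []
            m_per_cluster: list[int] = []
            for c in range(cfg.k_clusters):
                pts = coords[assign.labels == c]
                m = self._vertices_for_cluster(c, pts)
                m = min(m, pts.shape[0])
                if m < 2:
                    m = 2
                m_per_cluster.append(m)
                ocfg = cfg.objective_config(seed=child_seeds[c])
                ens = bootstrap_fit(pts, m, ocfg, B=cfg.B, seed=child_seeds[c])
                ensembles.append(ens)
                stage(
                    "unmix",
                    cluster=c,
                    m=m,
                    objective=round(ens.fit.objective, 6) if ens.fit else None,
                    max_vertex_sd=round(float(ens.vertex_sd.max()), 6),
                )
            cx = build_complex(ensembles)
            stage("merge", merged_vertices=cx.n_vertices,
                  subsimplices=[len(s) for s in cx.subsimplices])
            tree = phylogeny_mst(cx) if cx.n_vertices >= 2 else PhylogenyTree(
                nodes=list(range(cx.n_vertices))
            )

            # the merge moves vertices, so per-sample fractions are re-solved
            # against the sample's own (merged) subsimplex; components outside
            # that subsimplex are structural zeros
            n = coords.shape[0]
            F = np.zeros((cx.n_vertices, n))
            for c in range(cfg.k_clusters):
                members = np.flatnonzero(assign.labels == c)
                sub = cx.subsimplices[c]
                if len(sub) == 1:
                    F[sub[0], members] = 1.0
                    continue
                K_sub = cx.vertices[sub]
                F_sub = solve_fractions(K_sub, coords[members], cfg.p)
                F[np.ix_(sub, members)] = F_sub
            stage("refit_fractions", components=cx.n_vertices)

            component_ids = [f"v{i}" for i in range(cx.n_vertices)]
            components = backproject(
                cx.vertices, reduced, component_ids=component_ids,
                gene_ids=list(Z.gene_ids),
            )
            stage("backproject")
        except Exception as err:
            raise RuntimeError(
                f"pipeline failed at stage {log[-1]['stage'] if log else 'start'}: {err}"
            ) from err

        return UnmixResults(
            model=self,
            components=components,
            fractions=F,
            complex_=cx,
            tree=tree,
            reduced=reduced,
            zmatrix=Z,
            cluster_assignment=assign,
            ensembles=ensembles,
            m_per_cluster=m_per_cluster,
            seed=seed,
            log=log,
        )

    def _vertices_for_cluster(self, c: int, pts: np.ndarray) -> int:
        nv = self.config.n_vertices
        if isinstance(nv, str):
            if nv != "auto":
                raise ValueError(f"unknown n_vertices setting {nv!r}")
            return estimate_num_vertices(pts, self.config.eigen_threshold)
        if isinstance(nv, int):
            return nv
        return int(nv[c])


@dataclass
class UnmixResults:
    """Fitted components, fractions, complex and tree, with provenance."""

    model: SimplicialComplexModel
    components: GeneSpaceComponents
    fractions: np.ndarray  # merged components x samples
    complex_: SimplicialComplex
    tree: PhylogenyTree
    reduced: ReducedRepresentation
    zmatrix: ExpressionMatrix
    cluster_assignment: ClusterAssignment
    ensembles: list[BootstrapEnsemble]
    m_per_cluster: list[int]
    seed: int
    log: list[dict] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.complex_.n_vertices

    def fractions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.fractions,
            index=self.components.component_ids,
            columns=self.zmatrix.sample_ids,
        )

    def summary(self) -> str:
        cx = self.complex_
        k = self.model.config.k_clusters
        lines = [
            "Simplicial complex unmixing results",
            "=" * 51,
            f"samples: {self.zmatrix.n_samples}   genes: {self.zmatrix.n_genes}"
            f"   PCs: {self.reduced.n_components}   seed: {self.seed}",
            f"clusters: {k}   vertices per cluster: {self.m_per_cluster}"
            f"   merged components: {cx.n_vertices}",
            "",
            f"{'component':>10} {'cluster(s)':>12} {'sd':>10} {'mean fraction':>14}",
            "-" * 51,
        ]
        for i in range(cx.n_vertices):
            in_clusters = [c for c, sub in enumerate(cx.subsimplices) if i in sub]
            lines.append(
                f"{'v' + str(i):>10} {','.join(map(str, in_clusters)):>12} "
                f"{cx.vertex_sd[i]:>10.4f} {self.fractions[i].mean():>14.4f}"
            )
        lines.append("-" * 51)
        for c, ens in enumerate(self.ensembles):
            obj = ens.fit.objective if ens.fit else float("nan")
            lines.append(
                f"cluster {c}: n={int((self.cluster_assignment.labels == c).sum())}"
                f"  objective={obj:.4f}  B={ens.B}"
            )
        shared = [
            i
            for i in range(cx.n_vertices)
            if sum(i in sub for sub in cx.subsimplices) > 1
        ]
        lines.append(f"shared vertices: {shared if shared else 'none'}")
        if self.tree.edges:
            lines.append("tree (MST): " + self.tree.to_newick())
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> None:
        """Write components.tsv, fractions.tsv, complex.json, tree.nwk,
        tree_edges.tsv and report.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.components.to_frame().to_csv(outdir / "components.tsv", sep="\t")
        self.fractions_frame().to_csv(outdir / "fractions.tsv", sep="\t")
        self.complex_.save(outdir / "complex.json")
        (outdir / "tree.nwk").write_text(self.tree.to_newick() + "\n")
        pd.DataFrame(self.tree.to_edge_table()).to_csv(
            outdir / "tree_edges.tsv", sep="\t", index=False
        )
        report = {
            "seed": self.seed,
            "package_version": _pkg_version,
            "config": asdict(self.model.config),
            "m_per_cluster": self.m_per_cluster,
            "merged_components": self.n_components,
            "cluster_sizes": np.bincount(
                self.cluster_assignment.labels,
                minlength=self.model.config.k_clusters,
            ).tolist(),
            "stages": self.log,
        }
        (outdir / "report.json").write_text(json.dumps(report, indent=1))


def run_pipeline(M: ExpressionMatrix, cfg: PipelineConfig | None = None,
                 seed: int = 0, verbose: bool = False) -> UnmixResults:
    """Functional wrapper: build the model and fit it."""
    return SimplicialComplexModel(M, config=cfg).fit(seed=seed, verbose=verbose)
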