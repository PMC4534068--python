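"""Loading, Z-scoring and linear dimensionality reduction of expression matrices.

The unmixing pipeline works on a genes x samples matrix of genomic
measurements (RNA expression, copy number, ...).  Each gene is normalised to
a Z score across samples, the sample cloud is reduced to a small number of
principal components, and inferred simplex vertices are eventually mapped
back to gene space through the stored PCA basis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ReducedRepresentation",
    "GeneSpaceComponents",
    "load_expression",
    "zscore_rows",
    "pca_reduce",
    "backproject",
]


@dataclass
class ExpressionMatrix:
    """A genes x samples numeric matrix with identifiers.

    Parameters
    ----------
    values : ndarray of shape (g, s)
        Measurement for each gene (row) in each sample (column).
    gene_ids : list of str
        Unique row identifiers.
    sample_ids : list of str
        Unique column identifiers.
    """

    values: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        g, s = self.values.shape
        if not self.gene_ids:
            self.gene_ids = [f"g{i}" for i in range(g)]
        if not self.sample_ids:
            self.sample_ids = [f"s{j}" for j in range(s)]
        if len(self.gene_ids) != g or len(self.sample_ids) != s:
            raise ValueError("identifier lengths do not match matrix shape")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite entry at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class ReducedRepresentation:
    """PCA embedding of the samples plus everything needed to invert it.

    ``coords`` holds the samples in the reduced space (s x g'), ``basis`` the
    orthonormal principal axes (g' x g) and ``offset`` the per-gene mean that
    was subtracted before projection, so that a reduced point ``y`` maps back
    to gene space as ``y @ basis + offset``.
    """

    coords: np.ndarray
    basis: np.ndarray
    offset: np.ndarray
    explained_variance: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.basis = np.asarray(self.basis, dtype=float)
        self.offset = np.asarray(self.offset, dtype=float)
        self.explained_variance = np.asarray(self.explained_variance, dtype=float)
        if not self.sample_ids:
            self.sample_ids = [f"s{j}" for j in range(self.coords.shape[0])]
        gram = self.basis @ self.basis.T
        if not np.allclose(gram, np.eye(self.basis.shape[0]), atol=1e-8):
            raise ValueError("basis rows are not orthonormal")
        if np.any(np.diff(self.explained_variance) > 1e-12):
            raise ValueError("explained_variance must be non-increasing")

    @property
    def n_components(self) -> int:
        return self.basis.shape[0]

    def save(self, outdir: str | Path, prefix: str = "reduced") -> None:
        """Write coords as TSV and the basis/offset bundle as JSON + TSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            self.coords,
            index=self.sample_ids,
            columns=[f"PC{i + 1}" for i in range(self.n_components)],
        ).to_csv(outdir / f"{prefix}_coords.tsv", sep="\t")
        pd.DataFrame(self.basis).to_csv(
            outdir / f"{prefix}_basis.tsv", sep="\t", header=False, index=False
        )
        with open(outdir / f"{prefix}_meta.json", "w") as fh:
            json.dump(
                {
                    "offset": self.offset.tolist(),
                    "explained_variance": self.explained_variance.tolist(),
                    "n_components": int(self.n_components),
                },
                fh,
            )


@dataclass
class GeneSpaceComponents:
    """Inferred pure-population profiles, components x genes, in Z-score units."""

    values: np.ndarray
    component_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 1:
            raise ValueError("components must form a non-empty 2-D matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("components contain non-finite entries")
        if not self.component_ids:
            self.component_ids = [f"c{i}" for i in range(self.values.shape[0])]
        if not self.gene_ids:
            self.gene_ids = [f"g{i}" for i in range(self.values.shape[1])]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.component_ids, columns=self.gene_ids
        )


def _check_unique(ids: list[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for x in ids:
        seen[x] = seen.get(x, 0) + 1
    dups = sorted({x for x, c in seen.items() if c > 1})
    if dups:
        raise ValueError(f"duplicate {what} identifiers: {', '.join(map(str, dups))}")


def load_expression(
    path: str | Path,
    dialect: str = "tsv",
    orientation: str = "genes_by_samples",
) -> ExpressionMatrix:
    """Read a delimited matrix with a header row and an identifier column.

    Parameters
    ----------
    path : str or Path
    dialect : {'tsv', 'csv'}
    orientation : {'genes_by_samples', 'samples_by_genes'}
        How the file is laid out; the result is always genes x samples.
    """
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if orientation not in ("genes_by_samples", "samples_by_genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = "\t" if dialect == "tsv" else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty matrix in {path}")
    if orientation == "samples_by_genes":
        df = df.T
    _check_unique([str(x) for x in df.index], "gene")
    _check_unique([str(x) for x in df.columns], "sample")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[np.argmax(bad.to_numpy())]
                raise ValueError(
                    f"non-numeric cell at row {row!r}, column {col!r}"
                )
        values = df.apply(pd.to_numeric).to_numpy()
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"missing value at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    em = ExpressionMatrix(
        values=values.astype(float),
        gene_ids=[str(x) for x in df.index],
        sample_ids=[str(x) for x in df.columns],
    )
    if em.n_genes < 2 or em.n_samples < 3:
        raise ValueError(
            f"matrix too small ({em.n_genes} genes x {em.n_samples} samples); "
            "need at least 2 genes and 3 samples"
        )
    return em


def zscore_rows(M: ExpressionMatrix, constant_gene_policy: str = "drop") -> ExpressionMatrix:
    """Z-score each gene across samples (mean 0, sample sd 1).

    Genes with zero variance have no Z score; they are removed
    (``constant_gene_policy='drop'``) or set to all zeros (``'zero'``).
    """
    if constant_gene_policy not in ("drop", "zero"):
        raise ValueError(f"unknown constant_gene_policy {constant_gene_policy!r}")
    if M.n_samples < 2:
        raise ValueError("Z-scoring requires at least 2 samples")
    vals = M.values
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    constant = sd[:, 0] <= 0
    if constant_gene_policy == "drop":
        keep = ~constant
        if not keep.any():
            raise ValueError("all genes are constant; nothing left after dropping")
        z = (vals[keep] - mean[keep]) / sd[keep]
        gene_ids = [g for g, k in zip(M.gene_ids, keep) if k]
    else:
        sd_safe = np.where(constant[:, None], 1.0, sd)
        z = (vals - mean) / sd_safe
        z[constant] = 0.0
        gene_ids = list(M.gene_ids)
    return ExpressionMatrix(values=z, gene_ids=gene_ids, sample_ids=list(M.sample_ids))


def pca_reduce(Z: ExpressionMatrix, n_components: int) -> ReducedRepresentation:
    """Project samples onto the top principal axes of the gene space.

    Samples are observations, genes features; the per-gene mean is removed
    (stored as the offset) and no further scaling is applied.  Axis signs are
    fixed so each basis row's largest-magnitude entry is positive, making
    runs reproducible.
    """
    g, s = Z.values.shape
    max_rank = min(g, s - 1)
    if not (1 <= n_components <= max_rank):
        raise ValueError(
            f"n_components={n_components} out of range [1, {max_rank}] "
            f"for {g} genes x {s} samples"
        )
    X = Z.values.T  # s x g, samples as rows
    offset = X.mean(axis=0)
    Xc = X - offset
    # economy SVD; deterministic up to sign, which we then fix
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    basis = Vt[:n_components]
    coords = U[:, :n_components] * S[:n_components]
    signs = np.sign(basis[np.arange(n_components), np.argmax(np.abs(basis), axis=1)])
    signs[signs == 0] = 1.0
    basis = basis * signs[:, None]
    coords = coords * signs[None, :]
    explained = S[:n_components] ** 2 / (s - 1)
    return ReducedRepresentation(
        coords=coords,
        basis=basis,
        offset=offset,
        explained_variance=explained,
        sample_ids=list(Z.sample_ids),
    )


def backproject(K: np.ndarray, R: ReducedRepresentation,
                component_ids: list[str] | None = None,
                gene_ids: list[str] | None = None) -> GeneSpaceComponents:
    """Map reduced-space vertices back to gene space: ``K @ basis + offset``."""
    K = np.atleast_2d(np.asarray(K, dtype=float))
    if K.shape[1] != R.n_components:
        raise ValueError(
            f"vertex dimension {K.shape[1]} does not match the "
            f"{R.n_components}-component reduction"
        )
    values = K @ R.basis + R.offset
    return GeneSpaceComponents(
        values=values,
        component_ids=component_ids or [],
        gene_ids=gene_ids or [],
    )
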