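"""Scoring reconstructions against ground truth, plus comparison baselines.

Vertex error is the RMSD per matched vertex per ambient dimension after a
minimum-cost assignment between estimated and true components.  Fraction
error is reported either directly on the fraction matrices or — the default,
since fractions live on k components while the headline metric is per
ambient dimension — on the reconstructions ``C_true^T F`` they imply.

Two baselines are provided: a Gaussian mixture model fit by EM on the
reduced data (means as "vertices", responsibilities as "fractions") and the
single-simplex method (one simplex fit to the whole cloud, no clustering or
merging).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from scipy.stats import chi2_contingency
from sklearn.mixture import GaussianMixture

from .simplexfit import ObjectiveConfig, SimplexModel, fit_simplex

__all__ = [
    "vertex_rmsd",
    "fraction_rmsd",
    "gmm_baseline",
    "single_simplex_baseline",
    "contingency_chi2",
]


def vertex_rmsd(C_est: np.ndarray, C_true: np.ndarray) -> tuple[float, dict[int, int]]:
    """RMSD per matched vertex per dimension, with the optimal matching.

    Estimated and true vertices are paired by minimum-total-Euclidean-cost
    assignment; surplus vertices on either side are left unmatched and not
    scored.  Returns ``(rmsd, matching)`` with matching mapping estimated to
    true indices.
    """
    C_est = np.atleast_2d(np.asarray(C_est, dtype=float))
    C_true = np.atleast_2d(np.asarray(C_true, dtype=float))
    if C_est.size == 0 or C_true.size == 0:
        raise ValueError("empty vertex sets")
    if C_est.shape[1] != C_true.shape[1]:
        raise ValueError("vertex sets live in different spaces")
    cost = cdist(C_est, C_true)
    rows, cols = linear_sum_assignment(cost)
    g = C_est.shape[1]
    sq = float(((C_est[rows] - C_true[cols]) ** 2).sum())
    rmsd = np.sqrt(sq / (len(rows) * g))
    matching = {int(r): int(c) for r, c in zip(rows, cols)}
    return rmsd, matching


def fraction_rmsd(
    F_est: np.ndarray,
    F_true: np.ndarray,
    matching: dict[int, int],
    mode: str = "reconstruction",
    C_true: np.ndarray | None = None,
) -> float:
    """Mixture-fraction error under a component matching.

    mode='fractions': RMSD between the aligned fraction matrices, per point
    per component.  mode='reconstruction' (default): RMSD between the
    implied mixed profiles ``C_true^T F``, per point per ambient dimension.
    Estimated components with no matched true component are scored against
    zero rows (fractions mode) or contribute missing mass (reconstruction).
    """
    F_est = np.atleast_2d(np.asarray(F_est, dtype=float))
    F_true = np.atleast_2d(np.asarray(F_true, dtype=float))
    if F_est.shape[1] != F_true.shape[1]:
        raise ValueError("fraction matrices disagree on sample count")
    n = F_true.shape[1]
    m_true = F_true.shape[0]
    unmatched = [i for i in range(F_est.shape[0]) if i not in matching]
    used_unmatched = [i for i in unmatched if np.abs(F_est[i]).max() > 0]
    if used_unmatched:
        warnings.warn(
            f"{len(used_unmatched)} unmatched estimated component(s) with "
            "nonzero usage scored against zero"
        )
    aligned = np.zeros((m_true, n))
    for i, t in matching.items():
        aligned[t] = F_est[i]
    if mode == "fractions":
        extra = F_est[used_unmatched] if used_unmatched else np.zeros((0, n))
        diff_sq = ((aligned - F_true) ** 2).sum() + (extra**2).sum()
        m_scored = m_true + len(used_unmatched)
        return float(np.sqrt(diff_sq / (n * m_scored)))
    if mode == "reconstruction":
        if C_true is None:
            raise ValueError("reconstruction mode requires C_true")
        C_true = np.atleast_2d(np.asarray(C_true, dtype=float))
        g = C_true.shape[1]
        recon_est = C_true.T @ aligned
        recon_true = C_true.T @ F_true
        return float(np.sqrt(((recon_est - recon_true) ** 2).sum() / (n * g)))
    raise ValueError(f"unknown mode {mode!r}")


def gmm_baseline(
    X: np.ndarray, k: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Full-covariance Gaussian mixture fit by EM on the reduced data.

    Returns ``(means, responsibilities)`` with means of shape (k, d) and
    responsibilities (k, n); responsibilities act as the GMM method's
    fraction estimates when scoring.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if k > X.shape[0]:
        raise ValueError("more components than points")
    gm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        reg_covar=1e-6,
        random_state=seed,
        n_init=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gm.fit(X)
    resp = gm.predict_proba(X).T
    return gm.means_, resp


def single_simplex_baseline(
    X: np.ndarray, m: int, cfg: ObjectiveConfig | None = None
) -> SimplexModel:
    """The earlier single-simplex method: one simplex around the whole cloud."""
    return fit_simplex(X, m, cfg or ObjectiveConfig())


def contingency_chi2(labels_a, labels_b) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence on the cross-tabulation.

    Zero-margin rows/columns are dropped (with a warning) before testing;
    no continuity correction is applied.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape[0] != b.shape[0]:
        raise ValueError("label vectors must have equal length")
    cats_a, ia = np.unique(a, return_inverse=True)
    cats_b, ib = np.unique(b, return_inverse=True)
    table = np.zeros((len(cats_a), len(cats_b)))
    np.add.at(table, (ia, ib), 1)
    keep_rows = table.sum(axis=1) > 0
    keep_cols = table.sum(axis=0) > 0
    if not keep_rows.all() or not keep_cols.all():
        warnings.warn("dropping zero-margin rows/columns from contingency table")
        table = table[keep_rows][:, keep_cols]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least 2 categories per margin after drops")
    chi2, p, dof, _ = chi2_contingency(table, correction=False)
    return float(chi2), int(dof), float(p)
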