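"""Ordination and permutation statistics for DOM composition tables.

Normalized intensity tables are Hellinger-transformed (square root of row
proportions), pairwise Bray-Curtis dissimilarities are computed, and
principal coordinate analysis (classical scaling) embeds the samples.
Environmental variables are related to the ordination by least-squares
vector fitting with permutation p-values, and single formulas are screened
against environmental parameters by permutation Spearman rank correlation.

Permutation p-values use the (1 + exceedances) / (n_perm + 1) convention,
so p = 0 is impossible and results are reproducible under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .datamodel import FormulaTable

__all__ = [
    "Ordination",
    "VectorFit",
    "hellinger",
    "bray_curtis",
    "bray_curtis_matrix",
    "pcoa",
    "fit_env_vectors",
    "spearman_screen",
]


def hellinger(table: FormulaTable | pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform: sqrt of row-relative abundances.

    Rows of squared entries sum to 1; zeros stay zeros.
    """
    values = table.values if isinstance(table, FormulaTable) else table
    arr = values.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("Hellinger transform requires non-negative values")
    sums = arr.sum(axis=1)
    if (sums == 0).any():
        bad = list(values.index[sums == 0])
        raise ValueError(f"all-zero rows: {bad}")
    return pd.DataFrame(np.sqrt(arr / sums[:, None]), index=values.index,
                        columns=values.columns)


def bray_curtis(a, b) -> float:
    """Bray-Curtis dissimilarity sum|a-b| / sum(a+b) in [0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("Bray-Curtis requires non-negative vectors")
    denom = (a + b).sum()
    if denom == 0:
        raise ValueError("both vectors are all-zero")
    return float(np.abs(a - b).sum() / denom)


def bray_curtis_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities between rows (samples)."""
    d = squareform(pdist(values.to_numpy(dtype=float), metric="braycurtis"))
    return pd.DataFrame(d, index=values.index, columns=values.index)


@dataclass
class Ordination:
    """PCoA result: sample scores, eigenvalues, explained fractions.

    Axes are ordered by decreasing eigenvalue and scores are centered.
    Negative eigenvalues are reported as-is (no correction); explained
    fractions are computed over positive eigenvalues only.
    """

    scores: pd.DataFrame
    eigenvalues: np.ndarray
    explained_fraction: np.ndarray


def pcoa(d: pd.DataFrame | np.ndarray, k: int | None = None) -> Ordination:
    """Classical scaling (principal coordinate analysis) of a dissimilarity matrix.

    Gower double-centering of -D**2/2 followed by eigendecomposition; scores
    are eigenvectors scaled by the square roots of the positive eigenvalues.
    """
    index = d.index if isinstance(d, pd.DataFrame) else None
    D = np.asarray(d, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > max(eigval.max(), 0) * 1e-12
    n_axes = int(pos.sum()) if k is None else min(k, int(pos.sum()))
    scores = eigvec[:, :n_axes] * np.sqrt(eigval[:n_axes])
    explained = np.where(pos, eigval, 0.0) / eigval[pos].sum()
    cols = [f"PC{i+1}" for i in range(n_axes)]
    scores_df = pd.DataFrame(scores, columns=cols)
    if index is not None:
        scores_df.index = index
    return Ordination(scores=scores_df, eigenvalues=eigval,
                      explained_fraction=explained[: len(eigval)])


@dataclass
class VectorFit:
    """One environmental variable fitted to the first two ordination axes."""

    variable: str
    direction: np.ndarray | None  # unit vector on (PC1, PC2)
    r2: float | None
    p_perm: float | None


def _fit_r2(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares fit of y on centered scores; returns (coefs, R^2)."""
    yc = y - y.mean()
    coef, *_ = np.linalg.lstsq(scores, yc, rcond=None)
    fitted = scores @ coef
    ss_tot = float(yc @ yc)
    r2 = float(fitted @ fitted) / ss_tot
    return coef, r2


def fit_env_vectors(
    ordination: Ordination,
    env: pd.DataFrame,
    n_perm: int = 9999,
    seed: int | None = None,
    n_axes: int = 2,
) -> list[VectorFit]:
    """envfit-style vector fitting of environmental variables to PCoA scores.

    Each variable is regressed on the first ``n_axes`` score axes; R^2 is
    the coefficient of determination and the permutation p-value counts
    permuted R^2 values at least as large as the observed one. Constant
    variables are reported with missing r2/p.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    scores = ordination.scores.to_numpy()[:, :n_axes]
    env = env.loc[ordination.scores.index]
    rng = np.random.default_rng(seed)
    # scores are centered, so R^2 with intercept is the squared norm of the
    # projection onto the score column space
    q, _ = np.linalg.qr(scores)
    results = []
    for name in env.columns:
        y = env[name].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            results.append(VectorFit(name, None, None, None))
            continue
        coef, r2 = _fit_r2(scores, y)
        norm = np.linalg.norm(coef)
        direction = coef / norm if norm > 0 else coef
        yc = y - y.mean()
        perms = np.stack([rng.permutation(yc) for _ in range(n_perm)])
        null_r2 = np.square(perms @ q).sum(axis=1) / float(yc @ yc)
        count = int((null_r2 >= r2 - 1e-12).sum())
        p = (1 + count) / (n_perm + 1)
        results.append(VectorFit(name, direction, r2, p))
    return results


def spearman_screen(
    table: FormulaTable | pd.DataFrame,
    env: pd.DataFrame,
    n_perm: int = 9999,
    alpha: float = 0.001,
    seed: int | None = None,
) -> pd.DataFrame:
    """Permutation Spearman screening of formulas against environmental variables.

    For every (formula, variable) pair, Spearman's rho (average ranks for
    ties) is tested against its two-sided permutation null; only pairs with
    p < alpha are returned. Columns: formula, variable, rho, p_perm.
    """
    values = table.values if isinstance(table, FormulaTable) else table
    if values.shape[0] < 3:
        raise ValueError("need at least 3 samples for rank correlation")
    env = env.loc[values.index]
    rng = np.random.default_rng(seed)

    X = np.apply_along_axis(rankdata, 0, values.to_numpy(dtype=float))
    Xc = X - X.mean(axis=0)
    Xn = np.linalg.norm(Xc, axis=0)
    ok = Xn > 0
    n = X.shape[0]

    rows = []
    for name in env.columns:
        y = rankdata(env[name].to_numpy(dtype=float))
        yc = y - y.mean()
        yn = np.linalg.norm(yc)
        if yn == 0:
            continue
        rho = np.full(X.shape[1], np.nan)
        rho[ok] = (yc @ Xc[:, ok]) / (yn * Xn[ok])
        # permutations of the sample labels, vectorized over formulas
        perms = np.stack([rng.permutation(yc) for _ in range(n_perm)])  # n_perm x n
        null = (perms @ Xc[:, ok]) / (yn * Xn[ok])  # n_perm x formulas
        exceed = (np.abs(null) >= np.abs(rho[ok]) - 1e-12).sum(axis=0)
        p = np.full(X.shape[1], np.nan)
        p[ok] = (1 + exceed) / (n_perm + 1)
        for j, col in enumerate(values.columns):
            if np.isfinite(p[j]) and p[j] < alpha:
                rows.append({"formula": col, "variable": name,
                             "rho": float(rho[j]), "p_perm": float(p[j])})
    return pd.DataFrame(rows, columns=["formula", "variable", "rho", "p_perm"])
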