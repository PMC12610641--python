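"""Ordination and clustering of sensory and chemical profiles.

Provides Z-score row normalization, PCA by explicit eigendecomposition of
the covariance/correlation matrix (tiny matrices; no iterative SVD, no
convergence nondeterminism), a joint sensory+chemical PCA on column-wise
Z-scored blocks, loading-vector co-localization geometry (angle in the
leading component plane plus Pearson correlation across samples), and
hierarchical cluster ordering for heatmaps.

Sign convention: within each loading column the largest-magnitude element is
made positive, so results are reproducible across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "PCAResult",
    "ColocalizationResult",
    "ClusterHeatmap",
    "zscore_rows",
    "run_pca",
    "joint_pca",
    "colocalize",
    "hcluster",
    "cluster_heatmap",
]


def zscore_rows(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Per-row (x - mean)/sd with sd on n-1; constant rows become zeros.

    Returns the Z-scored matrix and the list of constant (flagged) row
    labels.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 columns to Z-score rows")
    x = matrix.astype(float)
    mu = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    constant = list(x.index[sd == 0])
    safe = sd.replace(0, np.nan)
    z = x.sub(mu, axis=0).div(safe, axis=0).fillna(0.0)
    return z, constant


@dataclass
class PCAResult:
    scores: pd.DataFrame  # sample x component
    loadings: pd.DataFrame  # variable x component, unit-norm eigenvector columns
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    preprocessing: str  # "center" | "zscore"
    data: pd.DataFrame  # the raw input (sample x variable), for correlations
    blocks: pd.Series | None = None  # variable -> block label (joint PCA)
    constant_variables: list = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def _zscore_columns(x: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    constant = list(x.columns[sd == 0])
    z = x.sub(mu, axis=1).div(sd.replace(0, np.nan), axis=1).fillna(0.0)
    return z, constant


def run_pca(
    matrix: pd.DataFrame,
    preprocessing: str = "center",
    n_components: int | None = None,
) -> PCAResult:
    """PCA via eigendecomposition of the covariance (``center``) or
    correlation (``zscore``) structure of a sample x variable matrix.

    Components are ordered by decreasing variance; loadings are unit-norm
    eigenvectors with the deterministic sign convention described in the
    module docstring.
    """
    x = matrix.astype(float)
    n, p = x.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    if p < 2:
        raise ValueError("PCA needs at least 2 variables")
    if preprocessing == "center":
        xp = x - x.mean(axis=0)
        constant = []
    elif preprocessing == "zscore":
        xp, constant = _zscore_columns(x)
    else:
        raise ValueError(f"unknown preprocessing {preprocessing!r}")
    cov = xp.T.to_numpy() @ xp.to_numpy() / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # sign convention: largest-magnitude element of each column positive
    for j in range(evecs.shape[1]):
        k = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]
    if n_components is None:
        n_components = p
    n_components = min(n_components, p)
    evals = evals[:n_components]
    evecs = evecs[:, :n_components]
    total = float(np.trace(cov))
    ratio = evals / total if total > 0 else np.zeros_like(evals)
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    loadings = pd.DataFrame(evecs, index=x.columns, columns=comp_names)
    scores = pd.DataFrame(xp.to_numpy() @ evecs, index=x.index, columns=comp_names)
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance=evals,
        explained_variance_ratio=ratio,
        preprocessing=preprocessing,
        data=x,
        constant_variables=constant,
    )


def joint_pca(
    sensory_means: pd.DataFrame,
    compound_means: pd.DataFrame,
    preprocessing: str = "zscore",
) -> PCAResult:
    """PCA of column-concatenated sensory-attribute and compound blocks.

    Both blocks must cover the identical sample set.  Every variable is
    Z-scored across samples before decomposition so the two blocks are
    commensurable; the result carries a block label per variable.
    """
    s = sensory_means.astype(float)
    c = compound_means.astype(float)
    if set(s.index) != set(c.index):
        raise ValueError("sensory and compound blocks cover different sample sets")
    c = c.reindex(s.index)
    overlap = set(s.columns) & set(c.columns)
    if overlap:
        raise ValueError(f"variable names shared between blocks: {sorted(overlap)}")
    joint = pd.concat([s, c], axis=1)
    result = run_pca(joint, preprocessing=preprocessing)
    result.blocks = pd.Series(
        ["sensory"] * s.shape[1] + ["compound"] * c.shape[1], index=joint.columns
    )
    return result


@dataclass
class ColocalizationResult:
    pairs: pd.DataFrame  # columns: variable_a, variable_b, theta_degrees, pearson_r,
    #          n_samples, co_localized, small_n
    theta_max: float
    r_min: float
    n_components: int

    def co_localized_pairs(self) -> list[tuple[str, str]]:
        f = self.pairs[self.pairs["co_localized"]]
        return list(zip(f["variable_a"], f["variable_b"]))


def loading_angle(result: PCAResult, var_a: str, var_b: str, n_components: int = 2) -> float:
    """Angle (degrees, in [0, 180]) between two variables' loading-plot
    vectors restricted to the first ``n_components`` components.

    Vectors are the eigenvector entries scaled by the square root of each
    component's variance — the standard variable-correlation plot geometry,
    under which the angle between two arrows encodes their correlation
    (cos theta equals the inter-variable correlation when the retained
    components capture the full variance).
    """
    if n_components > result.n_components:
        raise ValueError("more components requested than available")
    scale = np.sqrt(result.explained_variance[:n_components])
    va = result.loadings.loc[var_a].to_numpy()[:n_components] * scale
    vb = result.loadings.loc[var_b].to_numpy()[:n_components] * scale
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        zero = var_a if na == 0 else var_b
        raise ValueError(f"variable {zero!r} has a zero loading vector in the chosen components")
    return float(math.degrees(math.acos(np.clip(va @ vb / (na * nb), -1.0, 1.0))))


def colocalize(
    result: PCAResult,
    pairs: list[tuple[str, str]],
    n_components: int = 2,
    theta_max: float = 10.0,
    r_min: float = 0.9,
    data: pd.DataFrame | None = None,
) -> ColocalizationResult:
    """Loading-vector co-localization of variable pairs.

    For each (a, b) pair: theta is the angle between the two loading vectors
    in the leading ``n_components``-dimensional plane; r is the Pearson
    correlation of the two variables' raw values across samples (undefined —
    reported NaN, never flagged — when either variable is constant).  The
    pair is flagged ``co_localized`` when theta < theta_max AND r > r_min.
    A ``small_n`` caveat flag is set when fewer than 5 samples support r.
    """
    if data is None:
        data = result.data
    rows = []
    for a, b in pairs:
        theta = loading_angle(result, a, b, n_components=n_components)
        xa = data[a].to_numpy(dtype=float)
        xb = data[b].to_numpy(dtype=float)
        if np.std(xa) == 0 or np.std(xb) == 0:
            r = float("nan")
        else:
            r = float(np.corrcoef(xa, xb)[0, 1])
        flag = bool(theta < theta_max and np.isfinite(r) and r > r_min)
        rows.append(
            {
                "variable_a": a,
                "variable_b": b,
                "theta_degrees": theta,
                "pearson_r": r,
                "n_samples": len(xa),
                "co_localized": flag,
                "small_n": len(xa) < 5,
            }
        )
    return ColocalizationResult(pd.DataFrame(rows), theta_max, r_min, n_components)


def hcluster(
    matrix: pd.DataFrame,
    axis: int = 0,
    linkage: str = "average",
    metric: str = "euclidean",
) -> tuple[np.ndarray, np.ndarray]:
    """Agglomerative clustering of rows (axis=0) or columns (axis=1).

    Returns (leaf order as positional indices, scipy linkage matrix).  Leaf
    order is deterministic: scipy's tie handling follows input index order.
    """
    x = matrix.to_numpy(dtype=float)
    if axis == 1:
        x = x.T
    if x.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    d = pdist(x, metric=metric)
    if not np.isfinite(d).all():
        raise ValueError("non-finite distances between items")
    Z = hierarchy.linkage(d, method=linkage)
    order = hierarchy.leaves_list(Z)
    return order, Z


@dataclass
class ClusterHeatmap:
    """Z-scored matrix with hierarchical row/column orderings."""

    zmatrix: pd.DataFrame  # variable x sample
    row_order: np.ndarray
    col_order: np.ndarray
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    constant_rows: list = field(default_factory=list)

    def reordered(self) -> pd.DataFrame:
        return self.zmatrix.iloc[self.row_order, self.col_order]


def cluster_heatmap(
    matrix: pd.DataFrame,
    linkage: str = "average",
    metric: str = "euclidean",
) -> ClusterHeatmap:
    """Z-score each row (variable) then cluster rows and columns."""
    z, constant = zscore_rows(matrix)
    row_order, row_Z = hcluster(z, axis=0, linkage=linkage, metric=metric)
    col_order, col_Z = hcluster(z, axis=1, linkage=linkage, metric=metric)
    return ClusterHeatmap(z, row_order, col_order, row_Z, col_Z, constant)
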