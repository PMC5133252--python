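"""Donor-mean PCA with a permutation control, and Minkowski clustering.

Repertoire features (gene/family usage frequencies or CDR3 property
means) are first averaged per donor x subset; the resulting matrix is
analysed by PCA and by agglomerative clustering under the Minkowski
power-4 distance, which emphasizes the largest coordinate differences.
Whether the subsets separate beyond chance is assessed by re-running the
whole donor-means -> PCA pipeline on label-shuffled data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "DonorMeanMatrix",
    "PcaResult",
    "donor_means",
    "run_pca",
    "separation_statistic",
    "randomization_control",
    "minkowski_cluster",
    "MinkowskiDendrogram",
]


@dataclass
class DonorMeanMatrix:
    """(donor, subset)-indexed feature matrix with provenance."""

    values: pd.DataFrame  # MultiIndex (donor_id, subset) x feature columns
    provenance: str = ""

    @property
    def subsets(self) -> np.ndarray:
        return self.values.index.get_level_values("subset").to_numpy()


@dataclass
class PcaResult:
    scores: pd.DataFrame  # rows x components
    loadings: pd.DataFrame  # features x components
    explained_variance_ratio: np.ndarray
    separation_stat: float
    separation_p: float | None = None

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": [f"PC{i+1}" for i in range(len(self.explained_variance_ratio))],
                "explained_variance_ratio": self.explained_variance_ratio,
            }
        )


def donor_means(
    upstream,
    feature_cols: list[str] | None = None,
) -> DonorMeanMatrix:
    """Average features per donor x subset.

    Accepts a :class:`~bcelldev.usage.UsageTable` (frequencies are pivoted
    to a wide matrix; absent keys 0-filled) or a per-clonotype property
    DataFrame with ``donor_id``/``subset`` columns (arithmetic mean per
    cell; rows with missing values dropped).
    """
    if hasattr(upstream, "wide"):  # UsageTable
        wide = upstream.wide()
        return DonorMeanMatrix(values=wide, provenance=f"usage:{upstream.axis}")
    df = upstream
    if feature_cols is None:
        feature_cols = [
            c for c in df.columns
            if c not in ("clonotype_id", "donor_id", "subset", "chain")
            and pd.api.types.is_numeric_dtype(df[c])
        ]
    means = (
        df.dropna(subset=feature_cols)
        .groupby(["donor_id", "subset"], observed=True)[feature_cols]
        .mean()
        .sort_index()
    )
    return DonorMeanMatrix(values=means, provenance="properties")


def separation_statistic(scores: np.ndarray, labels: np.ndarray, n_dims: int = 2) -> float:
    """Between-group share of dispersion in the first PC dimensions.

    Sum over groups of n_g ||centroid_g - grand||^2 divided by the total
    sum of squares around the grand centroid, computed on the first
    ``n_dims`` score columns. Invariant to feature reordering and to
    orthogonal rotations of the score plane; 0 when group centroids
    coincide, 1 when groups collapse onto their centroids.
    """
    s = np.asarray(scores)[:, :n_dims]
    grand = s.mean(axis=0)
    total = ((s - grand) ** 2).sum()
    if total <= 0:
        return 0.0
    between = 0.0
    for g in np.unique(labels):
        sub = s[labels == g]
        between += len(sub) * ((sub.mean(axis=0) - grand) ** 2).sum()
    return float(between / total)


def run_pca(
    m: DonorMeanMatrix,
    center: bool = True,
    scale: bool = False,
) -> PcaResult:
    """SVD-based PCA of the donor-mean matrix.

    Deterministic up to component sign; the sign is fixed so the
    largest-magnitude loading of each component is positive. With
    ``center`` on (default) the scores reconstruct the centered data
    exactly through the loadings.
    """
    X = m.values.to_numpy(float)
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need at least 3 rows and 2 features")
    if np.ptp(X) == 0:
        raise ValueError("zero variance: constant matrix")
    mu = X.mean(axis=0) if center else np.zeros(X.shape[1])
    Xc = X - mu
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    scores = U * S
    var = S**2 / max(1, X.shape[0] - 1)
    evr = var / var.sum() if var.sum() > 0 else var
    comp_names = [f"PC{i+1}" for i in range(len(S))]
    labels = m.subsets
    stat = separation_statistic(scores, labels)
    return PcaResult(
        scores=pd.DataFrame(scores, index=m.values.index, columns=comp_names),
        loadings=pd.DataFrame(Vt.T, index=m.values.columns, columns=comp_names),
        explained_variance_ratio=evr,
        separation_stat=stat,
    )


def _pipeline_stat(df: pd.DataFrame, feature_cols: list[str]) -> float:
    m = donor_means(df, feature_cols=feature_cols)
    try:
        res = run_pca(m)
    except ValueError:
        return 0.0
    return res.separation_stat


def randomization_control(
    records: pd.DataFrame,
    feature_cols: list[str],
    n_perm: int = 199,
    seed: int = 0,
    within_donor: bool = True,
) -> tuple[float, float, np.ndarray]:
    """Permutation p-value for subset separation in donor-mean PCA.

    Subset labels are shuffled across sequences (within each donor by
    default, preserving subset sizes); the donor-means -> PCA ->
    separation-statistic pipeline is recomputed per permutation and
    ``p = (1 + #{perm >= observed}) / (n_perm + 1)``. Returns
    (observed statistic, p, permuted statistics).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if records["subset"].nunique() < 2:
        raise ValueError("need at least 2 subsets to randomize")
    rng = np.random.default_rng(seed)
    df = records.reset_index(drop=True)
    observed = _pipeline_stat(df, feature_cols)
    perm_stats = np.empty(n_perm)
    subset_values = df["subset"].to_numpy()
    donor_values = df["donor_id"].to_numpy()
    for i in range(n_perm):
        shuffled = subset_values.copy()
        if within_donor:
            for donor in np.unique(donor_values):
                idx = np.flatnonzero(donor_values == donor)
                shuffled[idx] = shuffled[rng.permutation(idx)]
        else:
            shuffled = shuffled[rng.permutation(len(shuffled))]
        perm = df.copy()
        perm["subset"] = shuffled
        perm_stats[i] = _pipeline_stat(perm, feature_cols)
    p = (1.0 + np.sum(perm_stats >= observed)) / (n_perm + 1.0)
    return observed, float(p), perm_stats


@dataclass
class MinkowskiDendrogram:
    linkage_matrix: np.ndarray
    labels: list[str]
    newick: str

    def root_partition(self) -> tuple[set[str], set[str]]:
        """Leaf-label sets of the two children of the root merge."""
        tree = hierarchy.to_tree(self.linkage_matrix)
        left = {self.labels[i] for i in tree.get_left().pre_order()}
        right = {self.labels[i] for i in tree.get_right().pre_order()}
        return left, right

    def isolates_group(self, group_labels: set[str]) -> bool:
        """True when one side of the root split is exactly this label set."""
        left, right = self.root_partition()
        return left == set(group_labels) or right == set(group_labels)


def _to_newick(node, labels, parent_height: float) -> str:
    length = max(0.0, parent_height - node.dist)
    if node.is_leaf():
        name = labels[node.id].replace(" ", "_").replace(",", "_")
        return f"{name}:{length:.6g}"
    left = _to_newick(node.get_left(), labels, node.dist)
    right = _to_newick(node.get_right(), labels, node.dist)
    return f"({left},{right}):{length:.6g}"


def minkowski_cluster(
    m: DonorMeanMatrix,
    power: float = 4.0,
    linkage: str = "complete",
) -> MinkowskiDendrogram:
    """Agglomerative clustering under the Minkowski L^p distance.

    ``power`` defaults to 4, which weights the largest coordinate
    differences more heavily than Euclidean distance; merge heights
    become Newick branch lengths.
    """
    if power < 1:
        raise ValueError("Minkowski power must be >= 1 (otherwise not a metric)")
    X = m.values.to_numpy(float)
    labels = [f"{d}|{s}" for d, s in m.values.index]
    dists = pdist(X, metric="minkowski", p=power)
    Z = hierarchy.linkage(dists, method=linkage)
    root = hierarchy.to_tree(Z)
    newick = f"({_to_newick(root.get_left(), labels, root.dist)},{_to_newick(root.get_right(), labels, root.dist)});"
    return MinkowskiDendrogram(linkage_matrix=Z, labels=labels, newick=newick)
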