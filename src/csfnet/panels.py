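"""Discriminative biomarker panels: top-k differentially abundant proteins,
PCA with group centroids, and two-way hierarchical clustering with a
two-class sample cut."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from ._util import zscore_rows
from .differential import DAPTable


@dataclass(frozen=True)
class PanelParams:
    k: int = 12
    distance: str = "euclidean"
    linkage: str = "average"

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("panel size k must be >= 2")


def select_top_daps(dap: DAPTable, params: PanelParams = PanelParams()) -> list[str]:
    """Top-k proteins by ascending ANOVA p; ties broken by larger |log2_diff|.

    Selection is a pure function of the DAP table (no abundance access), so
    re-runs reproduce the panel byte-for-byte.
    """
    tested = dap.table.loc[dap.table["p"].notna()].copy()
    if len(tested) < params.k:
        raise ValueError(
            f"only {len(tested)} tested proteins; need {params.k} for the panel"
        )
    tested["_abs_diff"] = tested["log2_diff"].abs()
    tested = tested.sort_values(
        by=["p", "_abs_diff"], ascending=[True, False], kind="mergesort"
    )
    return list(tested.index[: params.k])


def _panel_submatrix(
    matrix: pd.DataFrame, panel: list[str]
) -> tuple[np.ndarray, list[str], list[str]]:
    """Z-scored panel rows; samples missing more than half the panel are
    excluded and reported."""
    missing = [p for p in panel if p not in matrix.index]
    if missing:
        raise KeyError(f"panel proteins absent from matrix: {missing}")
    sub = matrix.loc[panel]
    frac_missing = sub.isna().mean(axis=0)
    keep = frac_missing <= 0.5
    dropped = list(sub.columns[~keep])
    sub = sub.loc[:, keep]
    if sub.shape[1] < 3:
        raise ValueError("fewer than 3 samples retain enough panel coverage")
    Z = zscore_rows(sub.to_numpy(dtype=float))
    return Z, list(sub.columns), dropped


@dataclass
class PanelPCA:
    scores: pd.DataFrame  # sample x (PC1, PC2)
    var_explained: np.ndarray  # per component, nonincreasing
    centroids: pd.DataFrame  # group x (PC1, PC2, PC1_se, PC2_se, n)
    excluded_samples: list[str]


def panel_pca(
    matrix: pd.DataFrame, panel: list[str], traits: pd.DataFrame
) -> PanelPCA:
    """PCA of samples on the z-scored panel submatrix; first two components
    with per-group centroids (mean score) and standard errors (SD/sqrt(n))."""
    Z, samples, dropped = _panel_submatrix(matrix, panel)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    var = s**2 / np.sum(s**2)
    scores = pd.DataFrame(
        (s[:2, None] * Vt[:2]).T, index=samples, columns=["PC1", "PC2"]
    )
    tr = traits.set_index("sample_id").reindex(samples)
    rows = []
    for grp, sub in scores.groupby(tr["group"].to_numpy()):
        n = len(sub)
        rows.append({
            "group": grp,
            "PC1": sub["PC1"].mean(), "PC2": sub["PC2"].mean(),
            "PC1_se": sub["PC1"].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
            "PC2_se": sub["PC2"].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
            "n": n,
        })
    centroids = pd.DataFrame(rows).set_index("group")
    scores.index.name = "sample_id"
    return PanelPCA(scores=scores, var_explained=var, centroids=centroids,
                    excluded_samples=dropped)


def _to_newick(Z: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def rec(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        return f"({rec(node.left)},{rec(node.right)}):{node.dist:.4g}"

    return rec(tree) + ";"


@dataclass
class PanelClustering:
    sample_classes: pd.Series  # sample -> 1 or 2
    class_composition: pd.DataFrame  # class x group counts
    sample_newick: str
    protein_newick: str
    excluded_samples: list[str]


def panel_cluster(
    matrix: pd.DataFrame,
    panel: list[str],
    traits: pd.DataFrame,
    params: PanelParams = PanelParams(),
) -> PanelClustering:
    """Two-way hierarchical clustering of the z-scored panel submatrix;
    the sample dendrogram is cut into exactly 2 classes and each class's
    diagnosis-group composition is tabulated."""
    Z, samples, dropped = _panel_submatrix(matrix, panel)
    # stable sample order: clustering is order-invariant because distances are
    link_s = hierarchy.linkage(Z.T, method=params.linkage, metric=params.distance)
    link_p = hierarchy.linkage(Z, method=params.linkage, metric=params.distance)
    classes = hierarchy.fcluster(link_s, t=2, criterion="maxclust")
    sample_classes = pd.Series(classes, index=samples, name="class")
    tr = traits.set_index("sample_id").reindex(samples)
    comp = pd.crosstab(sample_classes, tr["group"])
    comp.index.name = "class"
    return PanelClustering(
        sample_classes=sample_classes,
        class_composition=comp,
        sample_newick=_to_newick(link_s, samples),
        protein_newick=_to_newick(link_p, list(panel)),
        excluded_samples=dropped,
    )
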