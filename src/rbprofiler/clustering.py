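"""Clustering of differentially expressed RBPs and function-class summaries.

Differentially expressed RBPs are row-z-scored, clustered
agglomeratively across subsets, and each cluster is summarised by its
distribution over the five RNA-process classes (splicing, stability,
transport, modification, translation), with Fisher-exact
overrepresentation tests per class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, ClusterMixin

from .catalog import FUNCTION_CLASSES, RBPCatalog
from .de import adjust_bh

__all__ = [
    "zscore_rows",
    "ClusterAssignment",
    "GeneHierarchicalClustering",
    "hierarchical_cluster",
    "class_distribution",
    "fisher_enrichment",
    "enrich_classes",
]

DISTANCES = ("euclidean", "correlation")
LINKAGES = ("complete", "average", "ward")


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each row to mean 0, sample sd 1 (ddof=1).

    Constant rows cannot be scaled; they come back as all zeros with
    a warning (standard heatmap scaling behaviour).
    """
    X = matrix.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("row z-scoring needs at least 2 columns")
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant row(s) z-scored to all zeros",
            stacklevel=2,
        )
    sd = np.where(sd == 0, 1.0, sd)
    return pd.DataFrame((X - mean) / sd, index=matrix.index, columns=matrix.columns)


@dataclass
class ClusterAssignment:
    """Gene-to-cluster labels with the linkage that produced them."""

    labels: pd.Series  # gene -> cluster id, 1..k
    linkage: np.ndarray  # scipy linkage record (merge heights)
    k: int
    scaling: str = "zscore_rows"

    def __post_init__(self) -> None:
        ids = sorted(self.labels.unique())
        if ids != list(range(1, self.k + 1)):
            raise ValueError(f"cluster ids must be contiguous 1..{self.k}, got {ids}")

    def genes_in(self, cluster_id: int) -> set[str]:
        return set(self.labels.index[self.labels == cluster_id])


class GeneHierarchicalClustering(BaseEstimator, ClusterMixin):
    """Agglomerative clustering of gene rows, cut at ``n_clusters``.

    Rows are optionally z-scored first (the heatmap convention).
    Deterministic: cluster ids are renumbered 1..k in order of first
    appearance along the row index, so the labelling never depends on
    library internals.

    Parameters
    ----------
    n_clusters : int
    distance : "euclidean" or "correlation"
    linkage : "complete", "average" or "ward" (ward requires
        euclidean distance)
    scale_rows : bool, z-score rows before clustering (default True)

    Attributes
    ----------
    labels_ : ndarray of cluster ids (1..k) per row of X.
    linkage_ : scipy linkage matrix.
    """

    def __init__(
        self,
        n_clusters: int = 3,
        distance: str = "euclidean",
        linkage: str = "complete",
        scale_rows: bool = True,
    ):
        self.n_clusters = n_clusters
        self.distance = distance
        self.linkage = linkage
        self.scale_rows = scale_rows

    def fit(self, X, y=None):
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.distance not in DISTANCES:
            raise ValueError(f"distance must be one of {DISTANCES}")
        if self.linkage not in LINKAGES:
            raise ValueError(f"linkage must be one of {LINKAGES}")
        if self.linkage == "ward" and self.distance != "euclidean":
            raise ValueError("ward linkage requires euclidean distance")
        X = pd.DataFrame(X)
        if self.n_clusters > X.shape[0]:
            raise ValueError("n_clusters exceeds the number of genes")
        Z = zscore_rows(X) if self.scale_rows else X
        dist = pdist(Z.to_numpy(dtype=float), metric=self.distance)
        link = hierarchy.linkage(dist, method=self.linkage)
        raw = hierarchy.fcluster(link, t=self.n_clusters, criterion="maxclust")
        # renumber clusters by first appearance for determinism
        remap: dict[int, int] = {}
        labels = np.empty_like(raw)
        for i, c in enumerate(raw):
            if c not in remap:
                remap[c] = len(remap) + 1
            labels[i] = remap[c]
        self.labels_ = labels
        self.linkage_ = link
        return self


def hierarchical_cluster(
    matrix: pd.DataFrame,
    k: int,
    distance: str = "euclidean",
    linkage: str = "complete",
    scale_rows: bool = True,
) -> ClusterAssignment:
    """Cluster gene rows of ``matrix`` into ``k`` clusters."""
    est = GeneHierarchicalClustering(
        n_clusters=k, distance=distance, linkage=linkage, scale_rows=scale_rows
    ).fit(matrix)
    labels = pd.Series(est.labels_, index=matrix.index, name="cluster")
    n_found = len(set(est.labels_))
    return ClusterAssignment(
        labels,
        est.linkage_,
        k=n_found,
        scaling="zscore_rows" if scale_rows else "none",
    )


def class_distribution(
    clusters: ClusterAssignment,
    catalog: RBPCatalog,
) -> pd.DataFrame:
    """Per-cluster distribution over the five RNA-process classes.

    For each cluster: total genes, genes annotated for at least one
    class, genes annotated for two or more, and per-class counts and
    percentages. Percentages use the annotated genes as denominator
    (multi-class genes count once per class, so percentages can sum
    above 100). Clusters with no annotated gene report 0 percentages
    and ``n_annotated = 0``.
    """
    classes = sorted(FUNCTION_CLASSES)
    rows = []
    for cid in range(1, clusters.k + 1):
        genes = sorted(clusters.genes_in(cid))
        ann = {
            g: catalog[g].function_classes if g in catalog else frozenset()
            for g in genes
        }
        annotated = [g for g in genes if ann[g]]
        n_ann = len(annotated)
        row: dict[str, float | int] = {
            "cluster": cid,
            "n_genes": len(genes),
            "n_annotated": n_ann,
            "n_multi": sum(len(ann[g]) >= 2 for g in annotated),
        }
        for cls in classes:
            cnt = sum(cls in ann[g] for g in annotated)
            row[f"n_{cls}"] = cnt
            row[f"pct_{cls}"] = 100.0 * cnt / n_ann if n_ann else 0.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("cluster")


def fisher_enrichment(
    cluster_genes: Iterable[str],
    class_genes: Iterable[str],
    background: Iterable[str],
) -> tuple[float, float]:
    """Two-sided Fisher exact test for class overrepresentation.

    2x2 table over ``background``: in-cluster/in-class vs the three
    complements. Returns (odds_ratio, p); the odds ratio uses a
    Haldane correction (+0.5 to every cell) when any cell is zero.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    cluster = set(cluster_genes) & bg
    cls = set(class_genes) & bg
    if set(cluster_genes) - bg or set(class_genes) - bg:
        raise ValueError("cluster and class genes must be subsets of background")
    a = len(cluster & cls)
    b = len(cluster - cls)
    c = len(cls - cluster)
    d = len(bg) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(p)


def enrich_classes(
    cluster_genes: Iterable[str],
    class_table: Mapping[str, Iterable[str]],
    background: Iterable[str],
) -> pd.DataFrame:
    """Fisher enrichment of one gene set against each function class,
    BH-adjusted across the classes tested."""
    rows = []
    for cls in sorted(class_table):
        odds, p = fisher_enrichment(cluster_genes, class_table[cls], background)
        rows.append({"class": cls, "odds_ratio": odds, "p": p})
    df = pd.DataFrame(rows).set_index("class")
    df["padj"] = adjust_bh(df["p"].to_numpy())
    return df
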