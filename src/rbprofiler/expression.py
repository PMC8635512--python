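"""Bulk RNA and protein abundance matrices and their summaries.

Holds genes x samples abundance tables (raw counts, TPM, protein copy
numbers or log2 LFQ intensities) together with per-sample metadata
(cell type, differentiation subset, donor), and implements the
catalogue-level summaries: TPM normalisation, per-cell-type averaging,
detection calling, expression ranking, set overlaps, RNA-protein
concordance and PCA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

UNITS = ("counts", "tpm", "cn", "lfq_log2")

#: Default detection thresholds by unit (strict ">" comparison).
DETECTION_THRESHOLDS = {"tpm": 0.1, "cn": 1.0}


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance matrix with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol, one column per sample.
    sample_meta
        DataFrame indexed by sample name with columns ``cell_type``,
        ``subset``, ``donor`` (extra columns allowed).
    unit
        One of ``counts``, ``tpm``, ``cn``, ``lfq_log2``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if not self.values.index.is_unique:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dupes[:5])}")
        if len(self.sample_meta) != self.values.shape[1]:
            raise ValueError(
                f"sample_meta has {len(self.sample_meta)} rows for "
                f"{self.values.shape[1]} sample columns"
            )
        if not self.sample_meta.index.equals(self.values.columns):
            self.sample_meta = self.sample_meta.loc[self.values.columns]
        if self.unit != "lfq_log2" and (self.values.to_numpy() < 0).any():
            raise ValueError(f"negative values not allowed for unit {self.unit!r}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def samples_of(self, cell_type: str) -> list[str]:
        mask = self.sample_meta["cell_type"] == cell_type
        return list(self.sample_meta.index[mask])

    def cell_type_means(self, cell_type: str) -> pd.Series:
        cols = self.samples_of(cell_type)
        if not cols:
            raise KeyError(f"no samples with cell_type {cell_type!r}")
        return self.values[cols].mean(axis=1)


@dataclass
class DetectionResult:
    """Per-cell-type sets of detected genes."""

    detected: dict[str, set[str]]
    threshold: float
    aggregation: str
    unit: str

    def union(self) -> set[str]:
        out: set[str] = set()
        for s in self.detected.values():
            out |= s
        return out


def compute_tpm(
    counts: ExpressionMatrix,
    effective_lengths: Mapping[str, float] | pd.Series,
) -> ExpressionMatrix:
    """Convert raw gene counts to TPM.

    TPM corrects for library depth and transcript length:
    ``rate_g = count_g / efflen_g``; ``tpm_g = 1e6 * rate_g / sum(rate)``
    per sample, so every non-degenerate column sums to 1e6. All-zero
    columns stay all-zero.
    """
    if counts.unit != "counts":
        raise ValueError(f"expected counts, got {counts.unit!r}")
    lens = pd.Series(effective_lengths, dtype=float)
    missing = counts.genes.difference(lens.index)
    if len(missing):
        raise ValueError(f"missing effective length for gene(s): {list(missing[:5])}")
    lens = lens.loc[counts.genes]
    bad = lens.index[lens <= 0]
    if len(bad):
        raise ValueError(f"non-positive effective length for gene(s): {list(bad[:5])}")
    rate = counts.values.div(lens, axis=0)
    total = rate.sum(axis=0)
    scale = total.where(total > 0, other=1.0)  # keep all-zero columns zero
    tpm = rate.div(scale, axis=1) * 1e6
    return ExpressionMatrix(tpm, counts.sample_meta.copy(), unit="tpm")


def average_subsets(
    matrix: ExpressionMatrix,
    group_by: Sequence[str] = ("cell_type", "donor"),
) -> ExpressionMatrix:
    """Average sample columns within metadata groups.

    Used to collapse differentiation subsets to one column per
    (cell type, donor) before cell-type-level comparisons. Output has
    one column per group (arithmetic mean of the member columns);
    metadata keeps the grouping keys and any column constant within
    the group.
    """
    group_by = list(group_by)
    for key in group_by:
        if key not in matrix.sample_meta.columns:
            raise KeyError(f"sample metadata has no column {key!r}")
    groups = matrix.sample_meta.groupby(group_by, sort=True, observed=True)
    cols, meta_rows = {}, []
    for name, sub in groups:
        if len(sub) == 0:
            raise ValueError(f"empty group {name!r}")
        if not isinstance(name, tuple):
            name = (name,)
        label = "_".join(str(v) for v in name)
        cols[label] = matrix.values[sub.index].mean(axis=1)
        row = {k: v for k, v in zip(group_by, name)}
        for col in matrix.sample_meta.columns:
            if col in group_by:
                continue
            uniq = sub[col].unique()
            row[col] = uniq[0] if len(uniq) == 1 else "mixed"
        meta_rows.append((label, row))
    values = pd.DataFrame(cols)
    meta = pd.DataFrame({k: r for k, r in meta_rows}).T
    meta.index.name = "sample"
    return ExpressionMatrix(values, meta, unit=matrix.unit)


def detect_expressed(
    matrix: ExpressionMatrix,
    threshold: float | None = None,
    aggregation: str = "mean",
) -> DetectionResult:
    """Call genes detected per cell type.

    Under ``mean`` aggregation (default) a gene is detected in a cell
    type iff its mean abundance across that cell type's samples is
    strictly above the threshold (0.1 for TPM, 1 for protein copy
    number). ``any`` calls a gene detected if any single sample
    exceeds the threshold.
    """
    if matrix.unit not in DETECTION_THRESHOLDS:
        raise ValueError(f"detection undefined for unit {matrix.unit!r}")
    if aggregation not in ("mean", "any"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    if threshold is None:
        threshold = DETECTION_THRESHOLDS[matrix.unit]
    detected = {}
    for cell_type in pd.unique(matrix.sample_meta["cell_type"]):
        sub = matrix.values[matrix.samples_of(cell_type)]
        if aggregation == "mean":
            hits = sub.mean(axis=1) > threshold
        else:
            hits = (sub > threshold).any(axis=1)
        detected[cell_type] = set(matrix.genes[hits])
    return DetectionResult(detected, threshold, aggregation, matrix.unit)


def overlap_sets(named_sets: Mapping[str, Iterable]) -> dict[tuple[str, ...], int]:
    """Exact region counts of the inclusion-exclusion partition.

    For 1-4 named sets, returns ``{(names of sets containing the
    region): count}`` for every non-empty region of the Venn
    partition. Region counts sum to the size of the union.
    """
    names = list(named_sets)
    if not 1 <= len(names) <= 4:
        raise ValueError("overlap_sets supports 1-4 sets")
    sets = {n: set(named_sets[n]) for n in names}
    union = set().union(*sets.values())
    regions: dict[tuple[str, ...], int] = {}
    for element in union:
        members = tuple(n for n in names if element in sets[n])
        regions[members] = regions.get(members, 0) + 1
    return regions


def rank_expression(
    matrix: ExpressionMatrix,
    cell_type: str,
    highlight: Iterable[str] = (),
) -> pd.DataFrame:
    """Rank genes by mean abundance in one cell type.

    Descending abundance, alphabetical tie-break, 1-based dense ranks.
    ``highlight`` flags rows (e.g. the top differentially expressed
    RBPs on an expression-rank plot).
    """
    means = matrix.cell_type_means(cell_type)
    order = sorted(means.index, key=lambda g: (-means[g], g))
    highlight = set(highlight)
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(order) + 1),
            "symbol": order,
            "abundance": means.loc[order].to_numpy(),
            "highlighted": [g in highlight for g in order],
        }
    )


def rna_protein_concordance(
    rna: ExpressionMatrix,
    protein: ExpressionMatrix,
    groups: Mapping[str, str],
    cell_type: str,
    pseudocount: float = 1.0,
    rna_threshold: float = 0.1,
    protein_threshold: float = 1.0,
) -> dict[str, dict[str, float | int | None]]:
    """Per-group Pearson correlation of RNA vs protein abundance.

    For the chosen cell type, genes co-detected in both matrices
    (mean TPM > ``rna_threshold`` and mean copy number >
    ``protein_threshold``) are split by ``groups`` (e.g. ``rbp`` vs
    ``other``) and the correlation of log10(TPM+1) vs log10(CN+1) is
    computed per group. Groups with fewer than 3 co-detected genes
    report ``r=None``.
    """
    rna_mean = rna.cell_type_means(cell_type)
    prot_mean = protein.cell_type_means(cell_type)
    shared = rna_mean.index.intersection(prot_mean.index)
    co = [
        g
        for g in shared
        if rna_mean[g] > rna_threshold and prot_mean[g] > protein_threshold
    ]
    out: dict[str, dict[str, float | int | None]] = {}
    for group in sorted(set(groups.values())):
        genes = [g for g in co if groups.get(g) == group]
        if len(genes) < 3:
            out[group] = {"r": None, "n": len(genes)}
            continue
        x = np.log10(rna_mean.loc[genes].to_numpy() + pseudocount)
        y = np.log10(prot_mean.loc[genes].to_numpy() + pseudocount)
        r = float(stats.pearsonr(x, y).statistic)
        out[group] = {"r": r, "n": len(genes)}
    return out


def pca_embed(
    matrix: ExpressionMatrix,
    n_components: int = 2,
    gene_subset: Iterable[str] | None = None,
    n_top_genes: int = 500,
    log_transform: bool | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on the most variable genes.

    Works on log2(x+1) abundances (for counts/TPM/CN; log2 LFQ is
    already log scale), restricted to ``gene_subset`` if given (e.g.
    the RBP catalogue), then to the ``n_top_genes`` most variable
    genes. Columns are centred per gene; samples are projected onto
    the top right-singular directions.

    Returns (samples x components coordinates, variance fractions).
    """
    from sklearn.decomposition import PCA

    values = matrix.values
    if gene_subset is not None:
        keep = values.index.intersection(pd.Index(sorted(set(gene_subset))))
        values = values.loc[keep]
    if log_transform is None:
        log_transform = matrix.unit != "lfq_log2"
    X = np.log2(values.to_numpy(dtype=float) + 1.0) if log_transform else (
        values.to_numpy(dtype=float)
    )
    n_samples = X.shape[1]
    if n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    if n_components >= min(X.shape):
        raise ValueError("n_components must be < min(n_genes, n_samples)")
    var = X.var(axis=1)
    if not (var > 0).any():
        raise ValueError("no variance: constant matrix")
    top = np.argsort(-var, kind="stable")[: min(n_top_genes, X.shape[0])]
    X = X[top].T  # samples x genes
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    coords = pd.DataFrame(
        coords,
        index=values.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return coords, pca.explained_variance_ratio_
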