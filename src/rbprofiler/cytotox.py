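"""Single-cell cytotoxicity analysis of T cells.

The stage that links RBP expression to cytotoxic potential: naive
T cells (high CCR7/LEF1/SELL) are excluded, a cytotoxicity signature
is built by taking the genes most correlated with the anchor FGFBP2,
each cell gets a cytotoxic score (mean of the signature genes'
Z-scored log-normalized expression), cells are binned into bottom-10%
(low), middle and top-10% (high) score groups, and a two-part hurdle
model tests genes between the low and high bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .de import adjust_bh

__all__ = [
    "SingleCellMatrix",
    "lognormalize",
    "exclude_naive",
    "select_signature",
    "cytotoxic_score",
    "bin_by_score",
    "HurdleDE",
    "hurdle_de_test",
    "shared_de",
    "CytotoxicScorer",
]

NAIVE_MARKERS = ("CCR7", "LEF1", "SELL")
DEFAULT_ANCHOR = "FGFBP2"


@dataclass
class SingleCellMatrix:
    """Genes x cells integer count matrix with cell metadata.

    The log-normalized layer ``log2(1 + 1e4 * count / cell_total)``
    is computed on demand and cached.
    """

    counts: pd.DataFrame
    cell_meta: pd.DataFrame = None
    _lognorm: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        X = self.counts.to_numpy()
        if (X < 0).any():
            raise ValueError("negative counts")
        if not np.allclose(X, np.round(X)):
            raise ValueError("counts must be integers")
        totals = X.sum(axis=0)
        if (totals <= 0).any():
            n = int((totals <= 0).sum())
            raise ValueError(f"{n} cell(s) have zero total counts; filter them first")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=self.counts.columns)
        elif not self.cell_meta.index.equals(self.counts.columns):
            self.cell_meta = self.cell_meta.loc[self.counts.columns]

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def cells(self) -> pd.Index:
        return self.counts.columns

    @property
    def lognorm(self) -> pd.DataFrame:
        if self._lognorm is None:
            self._lognorm = lognormalize(self.counts)
        return self._lognorm

    def subset_cells(self, cells: Sequence[str]) -> "SingleCellMatrix":
        cells = pd.Index(cells)
        return SingleCellMatrix(
            self.counts[cells].copy(), self.cell_meta.loc[cells].copy()
        )


def lognormalize(counts: pd.DataFrame, scale: float = 1e4) -> pd.DataFrame:
    """Depth-normalize and log-transform: log2(1 + scale*c/total)."""
    totals = counts.sum(axis=0)
    return np.log2(1.0 + scale * counts.div(totals, axis=1))


def _two_means_1d(x: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact 1-D two-means: split point minimising within-cluster SSE.

    Deterministic (no initialisation); returns (boolean mask of the
    higher-mean cluster, gap between cluster means).
    """
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = xs.size
    csum = np.cumsum(xs)
    total = csum[-1]
    ks = np.arange(1, n)  # split: first k in low cluster
    mean_lo = csum[:-1] / ks
    mean_hi = (total - csum[:-1]) / (n - ks)
    csq = np.cumsum(xs**2)
    sse = (csq[:-1] - ks * mean_lo**2) + ((csq[-1] - csq[:-1]) - (n - ks) * mean_hi**2)
    k = int(ks[np.argmin(sse)])
    hi_mask = np.zeros(n, dtype=bool)
    hi_mask[order[k:]] = True
    gap = float(mean_hi[k - 1] - mean_lo[k - 1])
    return hi_mask, gap


def exclude_naive(
    sc: SingleCellMatrix,
    markers: Sequence[str] = NAIVE_MARKERS,
    min_separation: float = 4.0,
) -> tuple[SingleCellMatrix, pd.Series]:
    """Exclude cells expressing high levels of naive T-cell markers.

    Each cell's naive score is the mean of the available markers'
    per-gene Z-scores (on log-normalized expression). Cells are split
    by exact two-means on the score; the higher-mean partition is
    excluded iff the between-mean gap exceeds ``min_separation``
    pooled within-cluster standard deviations, otherwise nothing is
    excluded and a warning is emitted. The threshold is scale-free:
    splitting a unimodal score yields a gap near 2.7 within-cluster
    sds whatever the score spread, while a genuinely bimodal naive
    population scores far higher, so the default of 4 separates the
    two regimes and makes the operation idempotent. Returns
    (filtered matrix, per-cell excluded flags).
    """
    present = [m for m in markers if m in sc.genes]
    if not present:
        raise ValueError(f"none of the naive markers {tuple(markers)} are present")
    ln = sc.lognorm.loc[present]
    sd = ln.std(axis=1, ddof=1)
    usable = sd > 0
    flags = pd.Series(False, index=sc.cells, name="naive_excluded")
    if not usable.any():
        warnings.warn("naive markers are constant; nothing excluded", stacklevel=2)
        return sc, flags
    z = ln.loc[usable.index[usable]].sub(ln.mean(axis=1), axis=0).div(sd, axis=0)
    score = z.mean(axis=0).to_numpy()
    if np.allclose(score, score[0]):
        warnings.warn("naive scores are constant; nothing excluded", stacklevel=2)
        return sc, flags
    hi_mask, gap = _two_means_1d(score)
    lo_vals, hi_vals = score[~hi_mask], score[hi_mask]
    dof = max(1, score.size - 2)
    pooled_var = (
        (lo_vals.size - 1) * (lo_vals.var(ddof=1) if lo_vals.size > 1 else 0.0)
        + (hi_vals.size - 1) * (hi_vals.var(ddof=1) if hi_vals.size > 1 else 0.0)
    ) / dof
    separation = gap / np.sqrt(pooled_var) if pooled_var > 0 else np.inf
    if separation <= min_separation:
        warnings.warn(
            f"naive-score partitions separated by only {separation:.2f} "
            f"within-cluster sds (<= {min_separation}); nothing excluded",
            stacklevel=2,
        )
        return sc, flags
    flags[:] = hi_mask
    kept = sc.cells[~hi_mask]
    return sc.subset_cells(kept), flags


def select_signature(
    sc: SingleCellMatrix,
    anchor: str = DEFAULT_ANCHOR,
    n_top: int = 7,
) -> tuple[list[str], pd.Series]:
    """Anchor-based cytotoxic signature selection.

    Computes the Pearson correlation of every other gene's
    log-normalized expression with the anchor's across all scored
    cells, and returns (signature, correlations) where the signature
    is the anchor followed by the ``n_top`` most correlated genes
    (ties broken alphabetically).
    """
    if anchor not in sc.genes:
        raise ValueError(f"anchor gene {anchor!r} not present")
    ln = sc.lognorm
    a = ln.loc[anchor].to_numpy()
    if a.std(ddof=1) == 0:
        raise ValueError(f"anchor gene {anchor!r} has zero variance")
    X = ln.to_numpy()
    ac = a - a.mean()
    Xc = X - X.mean(axis=1, keepdims=True)
    denom = np.sqrt((Xc**2).sum(axis=1)) * np.sqrt((ac**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (Xc @ ac) / denom, np.nan)
    cors = pd.Series(r, index=sc.genes, name="pearson_r").drop(anchor)
    ranked = sorted(
        cors.dropna().index, key=lambda g: (-cors[g], g)
    )
    signature = [anchor] + ranked[: int(n_top)]
    return signature, cors


def cytotoxic_score(sc: SingleCellMatrix, signature: Sequence[str]) -> pd.Series:
    """Per-cell cytotoxic score: mean of signature-gene Z-scores.

    Each signature gene's log-normalized expression is Z-scored
    across all scored cells (sample sd, ddof=1); a cell's score is
    the mean over the available genes. Zero-variance signature genes
    are dropped with a warning.
    """
    present = [g for g in signature if g in sc.genes]
    if not present:
        raise ValueError("no signature gene present in the matrix")
    ln = sc.lognorm.loc[present]
    sd = ln.std(axis=1, ddof=1)
    dropped = [g for g in present if sd[g] == 0]
    if dropped:
        warnings.warn(
            f"dropping zero-variance signature gene(s): {dropped}", stacklevel=2
        )
    kept = [g for g in present if sd[g] > 0]
    if not kept:
        raise ValueError("all signature genes are constant")
    z = ln.loc[kept].sub(ln.loc[kept].mean(axis=1), axis=0).div(sd[kept], axis=0)
    return pd.Series(z.mean(axis=0), index=sc.cells, name="cytotoxic_score")


def bin_by_score(scores: pd.Series) -> pd.Series:
    """Bin cells by cytotoxic score into low / intermediate / high.

    By rank: the ``floor(0.1*n)`` lowest-ranked cells are ``low``,
    the same number highest-ranked are ``high``, the rest
    ``intermediate``. Score ties are broken by cell identifier for
    determinism.
    """
    n = len(scores)
    if n < 10:
        raise ValueError("binning needs at least 10 cells")
    vals = scores.to_numpy()
    if np.allclose(vals, vals[0]):
        raise ValueError("degenerate score distribution: all scores identical")
    n_ext = n // 10
    order = sorted(scores.index, key=lambda c: (scores[c], str(c)))
    bins = pd.Series("intermediate", index=scores.index, name="bin")
    bins[order[:n_ext]] = "low"
    bins[order[-n_ext:]] = "high"
    return bins


def _binom_ll(k: int, n: int, p: float) -> float:
    if n == 0:
        return 0.0
    ll = 0.0
    if k > 0:
        ll += k * np.log(p)
    if n - k > 0:
        ll += (n - k) * np.log1p(-p)
    return ll


class HurdleDE(BaseEstimator):
    """Two-part hurdle test between two cell groups (MAST-style).

    Per gene, two components are fitted and combined by likelihood
    ratio:

    * detection: Bernoulli model of expressed/not with a group
      effect, tested against the pooled rate (closed-form binomial
      LR, 1 df when 0 < pooled detection < all cells);
    * continuous: Gaussian model of the positive log-normalized
      values with a group mean effect and shared variance, tested
      against a common mean (1 df when both groups contain positive
      cells and the values are not degenerate).

    Combined LR = LR_detection + LR_continuous ~ chi2 with df = number
    of identifiable components. The reported log2 fold change is the
    difference of mean log-normalized expression over all cells
    (group2 - group1). Genes undetected in both groups are skipped
    (p = 1, lfc = 0) and left out of the BH family.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        lfc_threshold: float = 0.5,
        reference: str | None = None,
    ):
        self.alpha = alpha
        self.lfc_threshold = lfc_threshold
        self.reference = reference

    def fit(self, X, y):
        from .de import _as_two_groups

        X = pd.DataFrame(X)  # cells x genes, log-normalized
        y, levels = _as_two_groups(y, self.reference)
        g1 = np.asarray(y) == levels[0]
        g2 = np.asarray(y) == levels[1]
        n1, n2 = int(g1.sum()), int(g2.sum())
        if n1 == 0 or n2 == 0:
            raise ValueError("both groups must contain cells")

        vals = X.to_numpy(dtype=float)
        A, B = vals[g1], vals[g2]  # cells x genes per group
        n_genes = vals.shape[1]
        lr = np.zeros(n_genes)
        dfs = np.zeros(n_genes, dtype=int)
        lfc = B.mean(axis=0) - A.mean(axis=0)

        detA = A > 0
        detB = B > 0
        kA, kB = detA.sum(axis=0), detB.sum(axis=0)
        k = kA + kB
        n = n1 + n2
        tested = k > 0

        for j in np.nonzero(tested)[0]:
            # detection component
            if 0 < k[j] < n:
                p1, p2, pp = kA[j] / n1, kB[j] / n2, k[j] / n
                lr_det = 2.0 * (
                    _binom_ll(kA[j], n1, p1)
                    + _binom_ll(kB[j], n2, p2)
                    - _binom_ll(k[j], n, pp)
                )
                lr[j] += max(0.0, lr_det)
                dfs[j] += 1
            # continuous component on positive values
            a = A[detA[:, j], j]
            b = B[detB[:, j], j]
            m = a.size + b.size
            if a.size >= 1 and b.size >= 1 and m >= 3:
                pooled = np.concatenate([a, b])
                rss_null = float(((pooled - pooled.mean()) ** 2).sum())
                rss_full = float(((a - a.mean()) ** 2).sum()) + float(
                    ((b - b.mean()) ** 2).sum()
                )
                if rss_full > 0 and rss_null > 0:
                    lr[j] += max(0.0, m * np.log(rss_null / rss_full))
                    dfs[j] += 1

        p = np.ones(n_genes)
        has_df = dfs > 0
        p[has_df] = stats.chi2.sf(lr[has_df], dfs[has_df])
        lfc = np.where(tested, lfc, 0.0)

        padj = np.ones(n_genes)
        fam = tested.nonzero()[0]
        if fam.size:
            padj[fam] = adjust_bh(p[fam])
        de_flag = (np.abs(lfc) > self.lfc_threshold) & (padj < self.alpha)

        self.contrast_ = (levels[1], levels[0])
        self.results_ = pd.DataFrame(
            {
                "lr": lr,
                "df": dfs,
                "lfc_raw": lfc,
                "lfc_shrunk": lfc,
                "se": np.nan,
                "p": p,
                "padj": padj,
                "de_flag": de_flag,
            },
            index=X.columns,
        )
        self.results_.index.name = "symbol"
        return self


def hurdle_de_test(
    sc: SingleCellMatrix,
    groups: pd.Series | Mapping[str, str],
    alpha: float = 0.05,
    lfc_threshold: float = 0.5,
    reference: str | None = None,
    min_cells: int = 20,
) -> pd.DataFrame:
    """Hurdle DE between two cell bins (e.g. low vs high score).

    ``groups`` maps a subset of cells to two labels; only those cells
    enter the test, and each group must contain at least
    ``min_cells`` cells.
    """
    groups = pd.Series(groups)
    cells = [c for c in sc.cells if c in groups.index]
    g = groups.loc[cells]
    counts = g.value_counts()
    if len(counts) != 2:
        raise ValueError(f"expected 2 groups, got {list(counts.index)}")
    if (counts < min_cells).any():
        raise ValueError(f"each group needs >= {min_cells} cells, got {dict(counts)}")
    X = sc.lognorm[cells].T  # cells x genes
    est = HurdleDE(alpha=alpha, lfc_threshold=lfc_threshold, reference=reference).fit(
        X, g.to_numpy()
    )
    return est.results_


def shared_de(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    lfc_col: str = "lfc_raw",
) -> tuple[set[str], set[str]]:
    """Genes DE with consistent direction in both tables.

    Returns (shared_high, shared_low): significant (``de_flag``) in
    both with positive LFC in both, respectively negative in both.
    Direction conflicts appear in neither set.
    """
    out_high: set[str] = set()
    out_low: set[str] = set()
    common = de_a.index[de_a["de_flag"]].intersection(de_b.index[de_b["de_flag"]])
    for gene in common:
        la, lb = de_a.at[gene, lfc_col], de_b.at[gene, lfc_col]
        if la > 0 and lb > 0:
            out_high.add(gene)
        elif la < 0 and lb < 0:
            out_low.add(gene)
    return out_high, out_low


class CytotoxicScorer(BaseEstimator):
    """End-to-end per-cell cytotoxicity scoring.

    ``fit`` runs naive-marker exclusion, anchor-based signature
    selection and per-cell scoring on a :class:`SingleCellMatrix`;
    ``transform`` (or the fitted attributes) expose the scores and
    low/intermediate/high bins.

    Attributes
    ----------
    signature_ : list of gene symbols, anchor first.
    correlations_ : Series of anchor correlations per gene.
    scores_ : Series per scored (non-excluded) cell.
    bins_ : Series of bin labels per scored cell.
    naive_excluded_ : boolean Series over the input cells.
    """

    def __init__(
        self,
        anchor: str = DEFAULT_ANCHOR,
        n_top: int = 7,
        naive_markers: Sequence[str] = NAIVE_MARKERS,
        min_separation: float = 4.0,
        exclude_naive_cells: bool = True,
    ):
        self.anchor = anchor
        self.n_top = n_top
        self.naive_markers = naive_markers
        self.min_separation = min_separation
        self.exclude_naive_cells = exclude_naive_cells

    def fit(self, X: SingleCellMatrix, y=None):
        sc = X
        if self.exclude_naive_cells:
            sc, flags = exclude_naive(
                sc, markers=self.naive_markers, min_separation=self.min_separation
            )
        else:
            flags = pd.Series(False, index=sc.cells, name="naive_excluded")
        self.naive_excluded_ = flags
        self.scored_ = sc
        self.signature_, self.correlations_ = select_signature(
            sc, anchor=self.anchor, n_top=self.n_top
        )
        self.scores_ = cytotoxic_score(sc, self.signature_)
        self.bins_ = bin_by_score(self.scores_)
        return self

    def transform(self, X=None) -> pd.DataFrame:
        """Return the per-cell table (score, bin, naive flag)."""
        df = pd.DataFrame(
            {
                "score": self.scores_,
                "bin": self.bins_,
            }
        )
        df["naive_excluded"] = False
        excluded = self.naive_excluded_[self.naive_excluded_].index
        if len(excluded):
            ex = pd.DataFrame(
                {"score": np.nan, "bin": "excluded", "naive_excluded": True},
                index=excluded,
            )
            df = pd.concat([df, ex])
        df.index.name = "cell"
        return df

    def fit_transform(self, X: SingleCellMatrix, y=None) -> pd.DataFrame:
        return self.fit(X).transform()
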