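"""Differential-expression statistics for bulk RNA and protein data.

Transparent re-implementations of the standard two-group tests used on
lymphocyte expression panels:

* :class:`NegativeBinomialWaldDE` — per-gene negative-binomial Wald
  test on raw counts, with median-of-ratios size factors,
  method-of-moments dispersion, and normal-prior shrinkage of the
  log2 fold changes (pulling noisy low-count estimates toward zero).
* :class:`ModeratedTDE` — empirical-Bayes moderated t-test on log2
  protein intensities (limma-style variance moderation with
  moment-matched prior df).

Both are scikit-learn style estimators: ``fit(X, y)`` with ``X`` of
shape (n_samples, n_genes) and a two-level group label vector ``y``;
the per-gene table lands in ``results_``. Exact numeric parity with
the reference R packages is a non-goal; thresholding semantics
(|LFC| > 0.5, BH-adjusted p below 0.01 for RNA / 0.05 for protein,
both strict) and shrinkage direction are the contract.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator

__all__ = [
    "estimate_size_factors",
    "adjust_bh",
    "shrink_lfc",
    "NegativeBinomialWaldDE",
    "ModeratedTDE",
    "nb_wald_test",
    "moderated_t_test",
    "filter_de_rbps",
]

_LN2 = np.log(2.0)


def estimate_size_factors(
    counts: pd.DataFrame | np.ndarray,
    pseudo_reference: bool = False,
) -> pd.Series:
    """Median-of-ratios library-size factors (genes x samples input).

    ``sf_j = median_g(count_gj / geomean_g)`` over genes with nonzero
    counts in every sample. With ``pseudo_reference=True`` the
    geometric mean is computed on counts+0.5 over all genes instead,
    for sparse matrices where no gene is ubiquitously expressed.
    """
    df = pd.DataFrame(counts)
    X = df.to_numpy(dtype=float)
    if pseudo_reference:
        logX = np.log(X + 0.5)
        log_geomean = logX.mean(axis=1)
        usable = np.ones(X.shape[0], dtype=bool)
    else:
        usable = (X > 0).all(axis=1)
        if not usable.any():
            raise ValueError(
                "no gene has nonzero counts in every sample; pass "
                "pseudo_reference=True to use a pseudo-reference sample"
            )
        logX = np.zeros_like(X)
        logX[usable] = np.log(X[usable])
        log_geomean = np.zeros(X.shape[0])
        log_geomean[usable] = logX[usable].mean(axis=1)
    log_ratios = logX[usable] - log_geomean[usable, None]
    sf = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(sf, index=df.columns, name="size_factor")


def adjust_bh(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    # step-up: running minimum from the largest p downward
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def shrink_lfc(
    lfc_raw: np.ndarray | Sequence[float],
    se: np.ndarray | Sequence[float],
    prior_variance: float | None = None,
) -> np.ndarray:
    """Normal-prior shrinkage of per-gene log fold changes.

    Posterior mean under LFC_g ~ N(0, tau^2) observed with variance
    se_g^2: ``lfc * tau^2 / (tau^2 + se^2)``. When ``prior_variance``
    is None, tau^2 is estimated across genes by moments:
    ``max(eps, var(lfc) - mean(se^2))``. Shrinkage is strictly toward
    zero, never across it, and genes with large standard errors
    shrink more.
    """
    lfc = np.asarray(lfc_raw, dtype=float)
    se = np.asarray(se, dtype=float)
    if (se <= 0).any():
        raise ValueError("standard errors must be positive")
    if prior_variance is None:
        if lfc.size < 2:
            return lfc.copy()
        tau2 = max(1e-8, float(np.var(lfc, ddof=1) - np.mean(se**2)))
    else:
        tau2 = float(prior_variance)
    return lfc * tau2 / (tau2 + se**2)


def _as_two_groups(y: Sequence, reference: str | None) -> tuple[np.ndarray, list]:
    y = np.asarray(y)
    levels = list(pd.unique(y))
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 group levels, got {levels}")
    if reference is not None:
        if reference not in levels:
            raise ValueError(f"reference level {reference!r} not in {levels}")
        levels = [reference] + [l for l in levels if l != reference]
    return y, levels


class NegativeBinomialWaldDE(BaseEstimator):
    """Two-group negative-binomial Wald test on raw gene counts.

    Model: normalized counts for gene g in group k are NB with mean
    mu_gk and dispersion alpha_g. Per gene:

    * size-factor normalisation (median-of-ratios),
    * dispersion by method of moments on normalized counts:
      ``alpha_g = max(0, (s^2 - mean) / mean^2)`` with pooled
      within-group variance, moderated across genes by flooring each
      estimate at the across-gene median (small-sample per-gene
      estimates truncate at zero and would otherwise understate the
      variance, inflating the Wald statistic),
    * LFC = log2((mu_2 + eps) / (mu_1 + eps)) with a small pseudo-mean
      ``eps`` guarding all-zero groups,
    * ``Var(ln mu_k) ~ (1/mu_k + alpha_g) / n_k``; Wald
      z = delta_ln / SE with a two-sided normal p,
    * BH adjustment across all tested genes, normal-prior LFC
      shrinkage, and the strict DE call
      ``|lfc| > lfc_threshold and padj < alpha``.

    Parameters
    ----------
    alpha : float
        Adjusted-p cutoff for the DE flag (0.01 for RNA panels).
    lfc_threshold : float
        Absolute log2-fold-change cutoff (strict).
    use_shrunk : bool
        Apply the DE-flag LFC cutoff to the shrunken LFC (default)
        rather than the raw one.
    zero_mean_epsilon : float
        Pseudo-mean (normalized counts) added to group means for the
        fold change and its variance.
    moderate_dispersion : bool
        Floor per-gene dispersions at the across-gene median
        (default True).
    reference : str or None
        Group level treated as denominator; default: first level in
        order of appearance in ``y``.

    Attributes
    ----------
    results_ : DataFrame indexed by gene with columns ``base_mean``,
        ``lfc_raw``, ``lfc_shrunk``, ``se`` (natural-log scale),
        ``p``, ``padj``, ``de_flag``.
    size_factors_ : Series per sample.
    dispersion_ : ndarray of per-gene dispersion estimates.
    """

    def __init__(
        self,
        alpha: float = 0.01,
        lfc_threshold: float = 0.5,
        use_shrunk: bool = True,
        zero_mean_epsilon: float = 0.5,
        moderate_dispersion: bool = True,
        reference: str | None = None,
        size_factors: pd.Series | None = None,
    ):
        self.alpha = alpha
        self.lfc_threshold = lfc_threshold
        self.use_shrunk = use_shrunk
        self.zero_mean_epsilon = zero_mean_epsilon
        self.moderate_dispersion = moderate_dispersion
        self.reference = reference
        self.size_factors = size_factors

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y, levels = _as_two_groups(y, self.reference)
        if len(y) != X.shape[0]:
            raise ValueError("len(y) must equal the number of sample rows in X")
        g1 = np.asarray(y) == levels[0]
        g2 = np.asarray(y) == levels[1]
        n1, n2 = int(g1.sum()), int(g2.sum())
        if n1 < 2 or n2 < 2:
            raise ValueError("each group needs at least 2 samples")

        counts = X.to_numpy(dtype=float).T  # genes x samples
        if self.size_factors is not None:
            sf = pd.Series(self.size_factors, index=X.index).to_numpy(dtype=float)
        else:
            try:
                sf = estimate_size_factors(pd.DataFrame(counts, columns=X.index))
            except ValueError:
                sf = estimate_size_factors(
                    pd.DataFrame(counts, columns=X.index), pseudo_reference=True
                )
            sf = sf.to_numpy()
        self.size_factors_ = pd.Series(sf, index=X.index, name="size_factor")

        q = counts / sf  # normalized counts
        m1 = q[:, g1].mean(axis=1)
        m2 = q[:, g2].mean(axis=1)
        mu = q.mean(axis=1)
        # pooled within-group variance, ddof adjusted
        v1 = q[:, g1].var(axis=1, ddof=1)
        v2 = q[:, g2].var(axis=1, ddof=1)
        s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            disp = np.where(mu > 0, (s2 - mu) / mu**2, 0.0)
        disp = np.clip(disp, 0.0, None)
        self.dispersion_genewise_ = disp.copy()
        if self.moderate_dispersion and disp.size:
            expressed = mu > 1.0
            pool = disp[expressed] if expressed.any() else disp
            disp = np.maximum(disp, float(np.median(pool)))
        self.dispersion_ = disp

        eps = self.zero_mean_epsilon
        delta_ln = np.log(m2 + eps) - np.log(m1 + eps)
        var_ln = (1.0 / (m1 + eps) + disp) / n1 + (1.0 / (m2 + eps) + disp) / n2
        se_ln = np.sqrt(var_ln)
        z = delta_ln / se_ln
        p = 2.0 * stats.norm.sf(np.abs(z))

        all_zero = (counts[:, g1].sum(axis=1) == 0) & (counts[:, g2].sum(axis=1) == 0)
        p = np.where(all_zero, 1.0, p)
        delta_ln = np.where(all_zero, 0.0, delta_ln)

        lfc_raw = delta_ln / _LN2
        se_log2 = se_ln / _LN2
        lfc_shrunk = shrink_lfc(lfc_raw, se_log2)
        padj = adjust_bh(p)
        lfc_used = lfc_shrunk if self.use_shrunk else lfc_raw
        de_flag = (np.abs(lfc_used) > self.lfc_threshold) & (padj < self.alpha)

        self.contrast_ = (levels[1], levels[0])
        self.results_ = pd.DataFrame(
            {
                "base_mean": mu,
                "lfc_raw": lfc_raw,
                "lfc_shrunk": lfc_shrunk,
                "se": se_ln,
                "p": p,
                "padj": padj,
                "de_flag": de_flag,
            },
            index=X.columns,
        )
        self.results_.index.name = "symbol"
        return self


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton, monotone decreasing)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-8 * x:
            break
    return float(x)


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match the scaled-F prior of gene variances (limma style).

    Returns (d0, s0_squared): prior degrees of freedom and prior
    variance such that s2_g ~ s0^2 * F(df, d0) marginally. d0 may be
    inf (variances effectively exchangeable).
    """
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) if e.size > 1 else 0.0
    resid = e_var - float(special.polygamma(1, df / 2.0))
    if resid <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(resid)
    s0_sq = float(
        np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    )
    return d0, s0_sq


class ModeratedTDE(BaseEstimator):
    """Empirical-Bayes moderated two-sample t-test on log2 intensities.

    Per protein: ordinary two-sample t statistics are moderated by
    replacing the sample variance with the posterior
    ``s2_post = (d0*s0^2 + d*s2_g) / (d0 + d)`` where the prior
    (d0, s0^2) is moment-matched on the distribution of log sample
    variances across proteins; t is referred to d0 + d degrees of
    freedom. The log2 fold change is the difference of group means
    (intensities are already log2). DE call: ``padj < alpha`` and
    ``|lfc| > lfc_threshold`` (both strict).
    """

    def __init__(
        self,
        alpha: float = 0.05,
        lfc_threshold: float = 0.5,
        reference: str | None = None,
        prior_df: float | None = None,
        prior_var: float | None = None,
    ):
        self.alpha = alpha
        self.lfc_threshold = lfc_threshold
        self.reference = reference
        self.prior_df = prior_df  # None -> moment-matched; 0 -> ordinary t
        self.prior_var = prior_var

    def fit(self, X, y):
        X = pd.DataFrame(X)
        vals = X.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("intensities must be finite (impute upstream)")
        y, levels = _as_two_groups(y, self.reference)
        g1 = np.asarray(y) == levels[0]
        g2 = np.asarray(y) == levels[1]
        n1, n2 = int(g1.sum()), int(g2.sum())
        if n1 < 2 or n2 < 2:
            raise ValueError("each group needs at least 2 samples")
        df_resid = n1 + n2 - 2
        if df_resid <= 0:
            raise ValueError("zero residual degrees of freedom")

        A = vals[g1].T  # proteins x samples
        B = vals[g2].T
        m1, m2 = A.mean(axis=1), B.mean(axis=1)
        s2 = ((n1 - 1) * A.var(axis=1, ddof=1) + (n2 - 1) * B.var(axis=1, ddof=1)) / (
            df_resid
        )
        if self.prior_df is None:
            d0, s0_sq = _fit_f_dist(s2, df_resid)
        else:
            d0 = float(self.prior_df)
            s0_sq = float(self.prior_var) if self.prior_var is not None else (
                float(np.median(s2))
            )
        self.prior_df_, self.prior_var_ = d0, s0_sq
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
            df_total = np.inf
        elif d0 == 0:
            s2_post = s2.copy()
            df_total = df_resid
        else:
            s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
            df_total = d0 + df_resid
        self.s2_post_ = s2_post

        lfc = m2 - m1  # log2 scale already
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, lfc / se, 0.0)
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
        padj = adjust_bh(p)
        de_flag = (np.abs(lfc) > self.lfc_threshold) & (padj < self.alpha)

        self.contrast_ = (levels[1], levels[0])
        self.results_ = pd.DataFrame(
            {
                "base_mean": vals.mean(axis=0),
                "lfc_raw": lfc,
                "lfc_shrunk": lfc,  # no LFC shrinkage for the moderated t
                "se": se * _LN2,  # natural-log scale, for interface parity
                "p": p,
                "padj": padj,
                "de_flag": de_flag,
            },
            index=X.columns,
        )
        self.results_.index.name = "symbol"
        return self


# -- thin functional wrappers ------------------------------------------------


def nb_wald_test(
    counts,
    groups,
    size_factors: pd.Series | None = None,
    alpha: float = 0.01,
    lfc_threshold: float = 0.5,
    use_shrunk: bool = True,
    reference: str | None = None,
) -> pd.DataFrame:
    """Run :class:`NegativeBinomialWaldDE` on a genes x samples frame.

    ``counts`` may be an :class:`~rbprofiler.expression.ExpressionMatrix`
    (unit counts) or a genes x samples DataFrame; ``groups`` maps
    samples to two levels (dict or aligned sequence).
    """
    from .expression import ExpressionMatrix

    if isinstance(counts, ExpressionMatrix):
        if counts.unit != "counts":
            raise ValueError("nb_wald_test expects raw counts")
        counts = counts.values
    X = counts.T  # samples x genes
    y = _align_groups(groups, X.index)
    est = NegativeBinomialWaldDE(
        alpha=alpha,
        lfc_threshold=lfc_threshold,
        use_shrunk=use_shrunk,
        reference=reference,
        size_factors=size_factors,
    ).fit(X, y)
    return est.results_


def moderated_t_test(
    log_intensity,
    groups,
    alpha: float = 0.05,
    lfc_threshold: float = 0.5,
    reference: str | None = None,
) -> pd.DataFrame:
    """Run :class:`ModeratedTDE` on a proteins x samples log2 frame."""
    from .expression import ExpressionMatrix

    if isinstance(log_intensity, ExpressionMatrix):
        log_intensity = log_intensity.values
    X = log_intensity.T
    y = _align_groups(groups, X.index)
    est = ModeratedTDE(
        alpha=alpha, lfc_threshold=lfc_threshold, reference=reference
    ).fit(X, y)
    return est.results_


def _align_groups(groups, samples: pd.Index) -> np.ndarray:
    if isinstance(groups, Mapping):
        missing = [s for s in samples if s not in groups]
        if missing:
            raise KeyError(f"no group label for sample(s) {missing[:5]}")
        return np.asarray([groups[s] for s in samples])
    groups = np.asarray(list(groups))
    if len(groups) != len(samples):
        raise ValueError("group labels must align with samples")
    return groups


def filter_de_rbps(
    de: pd.DataFrame,
    catalog,
    lfc_threshold: float = 0.5,
    padj_threshold: float = 0.01,
    use_shrunk: bool = True,
    top_n: int = 20,
) -> pd.DataFrame:
    """Filter a DE table down to curated-catalogue RBPs.

    Re-applies the strict thresholds (|LFC| > ``lfc_threshold``,
    padj < ``padj_threshold``) on the chosen LFC column, keeps genes
    present in the curated catalogue, and flags the ``top_n`` rows by
    absolute LFC (ties broken alphabetically) in a ``top20`` column.
    Multiple-testing adjustment is expected to have been done over all
    tested genes upstream; only the filtering happens here.
    """
    lfc_col = "lfc_shrunk" if use_shrunk else "lfc_raw"
    rbp_symbols = catalog.curated().symbols if hasattr(catalog, "curated") else set(
        catalog
    )
    rbp_symbols = {str(s).strip().upper() for s in rbp_symbols}
    normalized = pd.Index([str(g).strip().upper() for g in de.index])
    keep = (
        (de[lfc_col].abs() > lfc_threshold)
        & (de["padj"] < padj_threshold)
        & normalized.isin(rbp_symbols)
    )
    out = de.loc[keep].copy()
    out["is_rbp"] = True
    order = sorted(out.index, key=lambda g: (-abs(out.at[g, lfc_col]), g))
    top = set(order[:top_n])
    out["top20"] = [g in top for g in out.index]
    return out.loc[order]
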