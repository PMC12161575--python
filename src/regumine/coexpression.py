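"""Count normalization and bias-corrected gene-gene co-expression.

The stack mirrors a standard bulk RNA-seq co-expression recipe for a small
bacterial sample set: low-expression filtering, trimmed-mean-of-M-values (TMM)
library normalization, an asinh-based log2 transform (which needs no additive
pseudocount and maps zero counts to zero), removal of the first principal
component (a dominant technical factor correlated with expression level),
all-to-all Pearson correlations with Student-t p-values, and spatial quantile
normalization (spqn) of the correlation matrix to equalize mean-expression-
dependent broadening of the correlation distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats


@dataclass
class CorrelationResult:
    """Symmetric gene-gene Pearson correlations with p-values.

    ``pcc``/``pvalues`` are genes x genes DataFrames sharing one index;
    ``mean_expression`` is the per-gene mean of the expression matrix the
    correlations were computed from. Zero-variance genes carry NaN rows and
    columns rather than being dropped, keeping gene indexing stable.
    """

    pcc: pd.DataFrame
    pvalues: pd.DataFrame
    n_samples: int
    mean_expression: pd.Series

    @property
    def genes(self) -> pd.Index:
        return self.pcc.index

    def correlation(self, a: str, b: str) -> float:
        return float(self.pcc.at[a, b])


def filter_low_expression(
    counts: pd.DataFrame, min_count: int = 5, min_fraction: float = 0.5
) -> pd.DataFrame:
    """Keep genes with >= min_count reads in >= min_fraction of samples.

    The sample threshold is ceil(min_fraction * n_samples), so a gene passing
    in exactly half of an even sample count is kept.
    """
    n_samples = counts.shape[1]
    needed = math.ceil(min_fraction * n_samples)
    keep = (counts >= min_count).sum(axis=1) >= needed
    if not keep.any():
        raise ValueError("low-expression filter removed every gene")
    return counts.loc[keep]


def tmm_factors(
    counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, one per sample.

    The reference sample is the one whose upper quartile of positive,
    library-size-scaled counts is closest to the mean of those quartiles.
    Per sample, M (log ratio) and A (log abundance) values against the
    reference are computed over genes expressed in both; after trimming the
    most extreme ``trim_m`` of M and ``trim_a`` of A on each side (by rank),
    the factor is 2 to the precision-weighted mean M, with weights from the
    binomial (delta-method) variance of M. Factors are rescaled to have zero
    mean log so they are depth corrections, not depth estimates.
    """
    mat = counts.to_numpy(float)
    lib = mat.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("every sample must have a positive total count")
    uq = np.array(
        [np.quantile(col[col > 0] / n, 0.75) for col, n in zip(mat.T, lib)]
    )
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    yr, nr = mat[:, ref], lib[ref]

    log_factors = np.zeros(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == ref:
            continue
        yk, nk = mat[:, j], lib[j]
        both = (yk > 0) & (yr > 0)
        if not both.any():
            raise ValueError(f"sample {counts.columns[j]} shares no expressed genes with reference")
        pk, pr = yk[both] / nk, yr[both] / nr
        m = np.log2(pk / pr)
        a = 0.5 * np.log2(pk * pr)
        # delta-method asymptotic variance of M; inverse used as weight
        v = (nk - yk[both]) / (nk * yk[both]) + (nr - yr[both]) / (nr * yr[both])
        n = m.size
        lo_m, hi_m = math.floor(n * trim_m) + 1, n + 1 - (math.floor(n * trim_m) + 1)
        lo_a, hi_a = math.floor(n * trim_a) + 1, n + 1 - (math.floor(n * trim_a) + 1)
        rank_m = scipy.stats.rankdata(m)
        rank_a = scipy.stats.rankdata(a)
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if keep.any() and v[keep].sum() > 0:
            w = 1.0 / v[keep]
            log_factors[j] = float((w * m[keep]).sum() / w.sum())
        else:  # fully trimmed (tiny or degenerate input): fall back to no scaling
            log_factors[j] = 0.0
    log_factors -= log_factors.mean()
    return pd.Series(2.0 ** log_factors, index=counts.columns, name="tmm_factor")


def normalize_transform(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Effective-library CPM followed by the asinh transform in log2 units.

    x = 1e6 * count / (library size * factor); y = log2(x + sqrt(x^2 + 1)).
    y(0) = 0, and y approaches log2(2x) for large x, so no additive
    pseudocount constant is needed.
    """
    if (factors <= 0).any():
        raise ValueError("normalization factors must be positive")
    lib = counts.sum(axis=0)
    x = counts / (lib * factors.loc[counts.columns]) * 1e6
    return np.log2(x + np.sqrt(x * x + 1.0))


def remove_pc1(expression: pd.DataFrame) -> pd.DataFrame:
    """Regress the first principal component out of a genes x samples matrix.

    Genes are centered, the projection of each gene onto the first right
    singular vector of the centered matrix is removed, and gene means are
    added back. Removes one dominant shared factor (technical or otherwise)
    at the cost of one effective degree of freedom per gene.
    """
    if expression.shape[1] < 3:
        raise ValueError("need at least 3 samples to estimate a principal component")
    x = expression.to_numpy(float)
    means = x.mean(axis=1, keepdims=True)
    xc = x - means
    if not (xc != 0).any():
        raise ValueError("expression matrix is constant; no component to remove")
    # v1: first right singular vector over samples
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    v1 = vt[0]
    resid = xc - np.outer(xc @ v1, v1)
    return pd.DataFrame(resid + means, index=expression.index, columns=expression.columns)


def correlation_with_pvalues(expression: pd.DataFrame) -> CorrelationResult:
    """All-to-all Pearson correlations with two-sided Student-t p-values.

    t = r sqrt(n-2) / sqrt(1-r^2) on n-2 degrees of freedom. Genes with zero
    variance get NaN correlations/p-values (flagged, not dropped).
    """
    n = expression.shape[1]
    if n < 4:
        raise ValueError("need at least 4 samples for correlation p-values")
    x = expression.to_numpy(float)
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    degenerate = sd == 0
    r[degenerate, :] = np.nan
    r[:, degenerate] = np.nan
    r = np.clip(r, -1.0, 1.0)
    pvals = correlation_pvalue(r, n)
    np.fill_diagonal(r, np.where(degenerate, np.nan, 1.0))
    np.fill_diagonal(pvals, np.where(degenerate, np.nan, 0.0))
    genes = expression.index
    return CorrelationResult(
        pcc=pd.DataFrame(r, index=genes, columns=genes),
        pvalues=pd.DataFrame(pvals, index=genes, columns=genes),
        n_samples=n,
        mean_expression=expression.mean(axis=1),
    )


def correlation_pvalue(r: np.ndarray, n_samples: int) -> np.ndarray:
    """Two-sided Student p-value for Pearson r at the given sample count."""
    df = n_samples - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.abs(r) * np.sqrt(df / np.maximum(1.0 - r * r, 0.0))
    return 2.0 * scipy.stats.t.sf(t, df)


def critical_pcc(n_samples: int, alpha: float = 0.05, n_components_removed: int = 1) -> float:
    """Minimum |r| reaching two-sided significance alpha at this sample size.

    r* = t* / sqrt(t*^2 + df) with t* the two-sided Student quantile. The
    degrees of freedom are n - 2 - n_components_removed: by default one
    principal component has been regressed out of the expression matrix
    upstream, which consumes one additional df (with 22 samples this yields
    the 0.43 threshold the pipeline quotes; the plain n - 2 value would be
    0.42). Pass n_components_removed=0 for correlations of raw expression.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    df = n_samples - 2 - n_components_removed
    if df < 1:
        raise ValueError("too few samples for the requested degrees of freedom")
    t_star = scipy.stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(t_star / math.sqrt(t_star * t_star + df))


# ---------------------------------------------------------------------------
# Spatial quantile normalization


def spatial_quantile_normalize(
    corr: CorrelationResult,
    ngrp: int = 20,
    size_grp: int | None = None,
    ref_grp: int = 18,
) -> CorrelationResult:
    """Equalize mean-expression-dependent spread of the correlation matrix.

    Genes are ranked by mean expression and split into ``ngrp`` equal bins,
    tiling the correlation matrix into an ngrp x ngrp grid. For every cell the
    empirical correlation distribution is estimated from an enlarged window of
    ``size_grp`` x ``size_grp`` genes centered on the cell (windows near the
    matrix border are shifted inward, keeping the estimation sample constant),
    and the cell's off-diagonal values are quantile-mapped onto the
    distribution of the reference cell (ref_grp, ref_grp) — by convention a
    high-expression bin whose correlations are least compressed. The result is
    symmetrized and the diagonal restored to 1; p-values are recomputed from
    the mapped correlations with the same Student formula.
    """
    n = corr.pcc.shape[0]
    if not 0 <= ref_grp < ngrp:
        raise ValueError("ref_grp must index one of the ngrp bins")
    if ngrp > n:
        raise ValueError("more bins than genes")
    if size_grp is None:
        # estimation windows must stay well-populated relative to the matrix:
        # at desk-scale gene counts a window of half the genes keeps the
        # source and reference tail estimates mutually consistent, so no
        # single co-regulated module can dominate either distribution
        size_grp = min(n, max(n // 2, n // ngrp, 10))
    if size_grp > n:
        raise ValueError("size_grp cannot exceed the number of genes")

    order = np.argsort(corr.mean_expression.to_numpy(), kind="stable")
    m = corr.pcc.to_numpy(float)[np.ix_(order, order)]
    bins = np.array_split(np.arange(n), ngrp)
    if min(len(b) for b in bins) == 0:
        raise ValueError("degenerate empty expression bin")
    windows = [_centered_window(b, size_grp, n) for b in bins]

    ref_lo, ref_hi = windows[ref_grp]
    ref_vals = _window_values(m, ref_lo, ref_hi, ref_lo, ref_hi)
    ref_sorted = np.sort(ref_vals)

    out = np.array(m)
    for i in range(ngrp):
        wi = windows[i]
        for j in range(ngrp):
            est = _window_values(m, *windows[i], *windows[j])
            est_sorted = np.sort(est)
            rows, cols = np.ix_(bins[i], bins[j])
            block = m[rows, cols]
            mapped = _quantile_map(block.ravel(), est_sorted, ref_sorted)
            mapped = mapped.reshape(block.shape)
            if i == j:  # keep the structural diagonal out of the mapping
                sub = np.diag_indices(len(bins[i]))
                mapped[sub] = block[sub]
            out[rows, cols] = mapped
    out = (out + out.T) / 2.0
    np.fill_diagonal(out, np.diag(m))

    inverse = np.empty(n, dtype=int)
    inverse[order] = np.arange(n)
    restored = out[np.ix_(inverse, inverse)]
    genes = corr.pcc.index
    restored = np.clip(restored, -1.0, 1.0)
    pvals = correlation_pvalue(restored, corr.n_samples)
    np.fill_diagonal(pvals, 0.0)
    return CorrelationResult(
        pcc=pd.DataFrame(restored, index=genes, columns=genes),
        pvalues=pd.DataFrame(pvals, index=genes, columns=genes),
        n_samples=corr.n_samples,
        mean_expression=corr.mean_expression,
    )


def _centered_window(bin_idx: np.ndarray, size: int, n: int) -> tuple[int, int]:
    center = int(round(bin_idx.mean()))
    lo = center - size // 2
    lo = max(0, min(lo, n - size))
    return lo, lo + size


def _window_values(m: np.ndarray, r0: int, r1: int, c0: int, c1: int) -> np.ndarray:
    """Values of a window excluding structural-diagonal entries."""
    block = m[r0:r1, c0:c1]
    rows = np.arange(r0, r1)[:, None]
    cols = np.arange(c0, c1)[None, :]
    keep = rows != cols
    return block[keep]


def _quantile_map(values: np.ndarray, src_sorted: np.ndarray, ref_sorted: np.ndarray) -> np.ndarray:
    """Monotone map of values through src's empirical CDF onto ref's quantiles."""
    if src_sorted.size < 2 or ref_sorted.size < 2:
        return values
    src_q = np.linspace(0.0, 1.0, src_sorted.size)
    ref_q = np.linspace(0.0, 1.0, ref_sorted.size)
    u = np.interp(values, src_sorted, src_q)
    return np.interp(u, ref_q, ref_sorted)


def bin_density_diagnostic(
    corr: CorrelationResult, n_bins: int = 10
) -> pd.DataFrame:
    """Quartiles of within-bin correlations across mean-expression bins.

    Genes are sorted by mean expression and split into ``n_bins`` equal bins
    (remainders spread over the first bins); all-to-all correlations within
    each bin are summarised. In unbiased data every bin's distribution is
    centered near zero; a mean-expression-linked confounder shows up as bin
    medians drifting with bin index.
    """
    n = corr.pcc.shape[0]
    order = np.argsort(corr.mean_expression.to_numpy(), kind="stable")
    m = corr.pcc.to_numpy(float)[np.ix_(order, order)]
    bins = np.array_split(np.arange(n), n_bins)
    rows = []
    for i, b in enumerate(bins):
        vals = _window_values(m, b[0], b[-1] + 1, b[0], b[-1] + 1)
        vals = vals[~np.isnan(vals)]
        q1, q2, q3 = np.percentile(vals, [25, 50, 75]) if vals.size else (np.nan,) * 3
        rows.append(
            {
                "bin": i,
                "n_genes": len(b),
                "n_pairs": vals.size // 2,
                "q1": q1,
                "median": q2,
                "q3": q3,
            }
        )
    return pd.DataFrame(rows)


def plot_bin_densities(diagnostics: dict[str, pd.DataFrame], path) -> None:
    """Ridgeline-style comparison of bin medians/quartiles across pipeline stages."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(len(diagnostics), 1, figsize=(6, 2.5 * len(diagnostics)),
                             sharex=True, squeeze=False)
    for ax, (label, diag) in zip(axes[:, 0], diagnostics.items()):
        ax.axvline(0, color="k", linestyle="--", linewidth=0.8)
        ax.errorbar(
            diag["median"], diag["bin"],
            xerr=[diag["median"] - diag["q1"], diag["q3"] - diag["median"]],
            fmt="o", capsize=2,
        )
        ax.set_ylabel(f"{label}\nexpression bin")
    axes[-1, 0].set_xlabel("within-bin Pearson correlation")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Full stack


def coexpression_pipeline(
    counts: pd.DataFrame,
    min_count: int = 5,
    min_fraction: float = 0.5,
    spqn_ngrp: int = 20,
    spqn_size: int | None = None,
    spqn_ref: int = 18,
    spqn_passes: int = 1,
    n_diag_bins: int = 10,
) -> tuple[CorrelationResult, dict[str, pd.DataFrame]]:
    """Filter -> TMM -> asinh-log2 -> PC1 removal -> PCC -> spqn.

    Returns the corrected correlation result plus bin diagnostics captured
    before any correction, after PC1 removal, and after spqn.
    """
    filtered = filter_low_expression(counts, min_count, min_fraction)
    factors = tmm_factors(filtered)
    expr = normalize_transform(filtered, factors)
    raw_corr = correlation_with_pvalues(expr)
    resid = remove_pc1(expr)
    corr = correlation_with_pvalues(resid)
    diagnostics = {
        "normalized": bin_density_diagnostic(raw_corr, n_diag_bins),
        "pc1_removed": bin_density_diagnostic(corr, n_diag_bins),
    }
    for _ in range(spqn_passes):
        corr = spatial_quantile_normalize(corr, spqn_ngrp, spqn_size, spqn_ref)
    diagnostics["spqn"] = bin_density_diagnostic(corr, n_diag_bins)
    return corr, diagnostics
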