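"""Two-group negative-binomial differential expression.

The model is the standard RNA-seq NB GLM with a log link: counts for gene i in
sample j are NB with mean s_j * mu_{i,g(j)} and variance mu + alpha * mu^2,
where s_j is a median-of-ratios size factor and g(j) the sample's group. The
two group means are fitted by maximum likelihood (Newton on the log scale),
the log2 fold change is their log ratio, and a Wald z-test on the log-ratio
with BH correction gives adjusted p-values. Dispersion is estimated per gene
by method of moments on normalized counts (no trend shrinkage by default).

Also provides the two transforms used downstream: a variance-stabilizing
log transform for PCA/clustering and TPM for expression-level display.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

ALPHA_MIN = 1e-8

RESULT_COLUMNS = ["gene_id", "baseMean", "log2FoldChange", "lfcSE", "stat", "pvalue", "padj"]


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors against the geometric-mean pseudo-reference.

    For each sample j the factor is the median over genes (restricted to genes
    with strictly positive counts in every sample) of count_ij / geomean_i.
    """
    arr = counts.to_numpy(dtype=float)
    if arr.ndim != 2 or arr.shape[1] == 0:
        raise ValueError("count matrix must be genes x samples with >= 1 sample")
    all_positive = (arr > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError("no gene has positive counts in every sample; "
                         "size factors are undefined")
    logs = np.log(arr[all_positive])
    log_geomean = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geomean, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def estimate_dispersion(
    counts: pd.DataFrame,
    factors: pd.Series,
    groups: dict[str, list[str]] | list[list[str]],
) -> pd.Series:
    """Per-gene NB dispersion by method of moments on normalized counts.

    Within each group the moment relation Var(q) ~= mu * E[1/s] + alpha * mu^2
    (q = count / size factor) is solved for alpha; group estimates are pooled
    with df weights and floored at ALPHA_MIN.
    """
    if isinstance(groups, dict):
        group_lists = list(groups.values())
    else:
        group_lists = list(groups)
    for g in group_lists:
        if len(g) < 2:
            raise ValueError("dispersion estimation needs >= 2 samples per group")
    n_genes = counts.shape[0]
    num = np.zeros(n_genes)
    den = np.zeros(n_genes)
    for g in group_lists:
        s = factors.loc[g].to_numpy(dtype=float)
        q = counts[g].to_numpy(dtype=float) / s
        mu = q.mean(axis=1)
        var = q.var(axis=1, ddof=1)
        xi = np.mean(1.0 / s)
        with np.errstate(divide="ignore", invalid="ignore"):
            a_g = (var - mu * xi) / mu**2
        w = len(g) - 1
        ok = mu > 0
        num[ok] += w * a_g[ok]
        den[ok] += w
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / np.maximum(den, 1), 0.0)
    alpha = np.maximum(alpha, ALPHA_MIN)
    return pd.Series(alpha, index=counts.index, name="dispersion")


def _fit_group_mean(y: np.ndarray, s: np.ndarray, alpha: np.ndarray,
                    n_iter: int = 50, tol: float = 1e-10):
    """MLE of per-gene NB mean mu for one group, with offsets s and known alpha.

    Newton iteration on b = log(mu); returns (mu_hat, fisher_info_b). Genes
    whose group total is zero get mu floored at a half-count equivalent so the
    Wald statistic stays defined (huge SE, p near 1).
    """
    s = s[None, :]
    total = y.sum(axis=1)
    floor = 0.5 / s.sum()
    mu0 = np.maximum(total / s.sum(), floor)
    b = np.log(mu0)
    a = alpha[:, None]
    for _ in range(n_iter):
        mu = np.exp(b)[:, None]
        denom = 1.0 + a * s * mu
        score = ((y - s * mu) / denom).sum(axis=1)
        # expected information for b: sum s*mu/(1 + a*s*mu)
        info = (s * mu / denom).sum(axis=1)
        step = score / np.maximum(info, 1e-300)
        step = np.clip(step, -5.0, 5.0)
        b = b + step
        if np.max(np.abs(step)) < tol:
            break
    b = np.maximum(b, np.log(floor))
    mu = np.exp(b)[:, None]
    info = (s * mu / (1.0 + a * s * mu)).sum(axis=1)
    return np.exp(b), info


def wald_test_two_group(
    counts: pd.DataFrame,
    factors: pd.Series,
    alpha: pd.Series,
    group_a: list[str],
    group_b: list[str],
) -> pd.DataFrame:
    """NB Wald test of group B vs group A (positive LFC = higher in B).

    The Wald statistic is the log fold change over its standard error from
    the expected Fisher information; the reference distribution is Student t
    with n_A + n_B - 2 degrees of freedom (indistinguishable from normal at
    cohort scale, calibrated at small n). Genes with all-zero counts across
    both groups get NA p-values and are excluded from the BH denominator.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    ya = counts[group_a].to_numpy(dtype=float)
    yb = counts[group_b].to_numpy(dtype=float)
    sa = factors.loc[group_a].to_numpy(dtype=float)
    sb = factors.loc[group_b].to_numpy(dtype=float)
    al = alpha.loc[counts.index].to_numpy(dtype=float)

    mu_a, info_a = _fit_group_mean(ya, sa, al)
    mu_b, info_b = _fit_group_mean(yb, sb, al)

    beta = np.log(mu_b) - np.log(mu_a)              # natural-log fold change
    se = np.sqrt(1.0 / info_a + 1.0 / info_b)
    stat = beta / se
    # t reference with n_A + n_B - 2 df: accounts for the plug-in dispersion
    # estimate, which would otherwise inflate small-sample type-I error
    df = max(len(group_a) + len(group_b) - 2, 1)
    pvalue = 2.0 * stats.t.sf(np.abs(stat), df)

    all_zero = (ya.sum(axis=1) + yb.sum(axis=1)) == 0
    pvalue[all_zero] = np.nan
    stat[all_zero] = np.nan
    beta[all_zero] = np.nan
    se[all_zero] = np.nan

    norm_all = np.concatenate([ya / sa, yb / sb], axis=1)
    ln2 = np.log(2.0)
    res = pd.DataFrame({
        "gene_id": counts.index,
        "baseMean": norm_all.mean(axis=1),
        "log2FoldChange": beta / ln2,
        "lfcSE": se / ln2,
        "stat": stat,
        "pvalue": pvalue,
    })
    res["padj"] = bh_adjust(res["pvalue"].to_numpy())
    return res


def bh_adjust(p_values: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaN propagated, excluded from m."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[mask] = res
    return out


def vst_counts(counts: pd.DataFrame, factors: pd.Series,
               pseudocount: float = 4.0) -> pd.DataFrame:
    """Variance-stabilizing log transform of normalized counts.

    log2(q + c) with c = 4 by default: for NB data with common dispersion the
    per-gene SD of the transform is ~sqrt(alpha)/ln 2 for large means,
    decoupling variance from mean well enough for PCA and clustering.
    """
    q = counts.to_numpy(dtype=float) / factors.loc[counts.columns].to_numpy(dtype=float)
    return pd.DataFrame(np.log2(q + pseudocount), index=counts.index,
                        columns=counts.columns)


def tpm_normalize(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million given per-gene transcript lengths in bp.

    Columns sum to 1e6 whenever any count is positive; an all-zero sample
    stays an all-zero column.
    """
    L = lengths.loc[counts.index].to_numpy(dtype=float)
    if (L <= 0).any():
        bad = counts.index[np.argwhere(L <= 0)[0][0]]
        raise ValueError(f"non-positive transcript length for gene {bad!r}")
    rate = counts.to_numpy(dtype=float) / (L[:, None] / 1e3)
    colsum = rate.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tpm = np.where(colsum > 0, 1e6 * rate / colsum, 0.0)
    return pd.DataFrame(tpm, index=counts.index, columns=counts.columns)


def write_de_results(res: pd.DataFrame, path) -> None:
    res[RESULT_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")
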