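"""Regulatory windows, peak overlap counting, and TF enrichment.

A gene's regulatory region is the window from 5 kb upstream to 2 kb
downstream of its TSS, oriented by transcription (upstream means 5'), clipped
at the chromosome start. Per-TF enrichment in a foreground gene set relative
to the all-lncRNA background is a one-tailed (greater) Fisher exact test on
the binary has-a-binding-site indicator, BH-corrected across TFs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust
from .io import PeakSet

logger = logging.getLogger(__name__)

UPSTREAM = 5_000
DOWNSTREAM = 2_000


def regulatory_regions(models: pd.DataFrame, upstream: int = UPSTREAM,
                       downstream: int = DOWNSTREAM, stranded: bool = True) -> pd.DataFrame:
    """Half-open TSS windows per gene, strand-mirrored for minus-strand genes.

    + strand: [tss - upstream, tss + downstream)
    - strand: [tss - downstream + 1, tss + upstream + 1)
    With stranded=False every gene uses the + strand convention.
    """
    tss = models["tss"].to_numpy(dtype=np.int64)
    plus = (models["strand"].to_numpy() == "+") | (not stranded)
    start = np.where(plus, tss - upstream, tss - downstream + 1)
    end = np.where(plus, tss + downstream, tss + upstream + 1)
    start = np.maximum(start, 0)
    return pd.DataFrame({
        "gene_id": models["gene_id"].to_numpy(),
        "chrom": models["chrom"].to_numpy(),
        "start": start,
        "end": end,
        "strand": models["strand"].to_numpy(),
    })


def count_overlaps(regions: pd.DataFrame, peaks: PeakSet) -> pd.Series:
    """Number of peaks overlapping each region by >= 1 bp (half-open semantics).

    Sorted-array bisection per chromosome: a peak [ps, pe) overlaps region
    [rs, re) iff ps < re and pe > rs. Regions on chromosomes absent from the
    peak set count zero (logged once).
    """
    counts = np.zeros(len(regions), dtype=np.int64)
    by_chrom = {c: df for c, df in peaks.intervals.groupby("chrom", sort=False)}
    missing = set()
    for chrom, idx in regions.groupby("chrom", sort=False).groups.items():
        sub = by_chrom.get(chrom)
        if sub is None:
            missing.add(chrom)
            continue
        starts = np.sort(sub["start"].to_numpy())
        ends = np.sort(sub["end"].to_numpy())
        rs = regions.loc[idx, "start"].to_numpy()
        re_ = regions.loc[idx, "end"].to_numpy()
        n_start_before_end = np.searchsorted(starts, re_, side="left")
        n_end_before_start = np.searchsorted(ends, rs, side="right")
        counts[regions.index.get_indexer(idx)] = n_start_before_end - n_end_before_start
    if missing:
        logger.info("no %s peaks on chromosome(s) %s; counted as zero overlap",
                    peaks.tf_name, sorted(missing))
    return pd.Series(counts, index=regions["gene_id"].to_numpy(), name=peaks.tf_name)


def binding_matrix(regions: pd.DataFrame, peaks_by_tf: dict[str, PeakSet]) -> pd.DataFrame:
    """Genes x TFs matrix of peak counts within each gene's regulatory window."""
    cols = {tf: count_overlaps(regions, ps) for tf, ps in peaks_by_tf.items()}
    return pd.DataFrame(cols)


def fisher_one_tailed_p(a: int, b: int, c: int, d: int) -> float:
    """Upper-tail (enrichment) Fisher p for the 2x2 table [[a, b], [c, d]].

    Equals the hypergeometric tail P(X >= a | N = a+b+c+d, K = a+c, n = a+b).
    """
    return float(stats.hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))


def fisher_enrichment(binding: pd.DataFrame, foreground: set[str] | list[str],
                      padj_threshold: float = 0.15) -> pd.DataFrame:
    """Per-TF enrichment of binding sites in the foreground vs the background.

    The background is every gene in the binding matrix; the 2x2 table uses the
    binary (>= 1 site) reading of the counts. One tailed, direction =
    enrichment; BH across TFs; enriched means padj < padj_threshold.
    """
    fg = set(foreground)
    if not fg:
        raise ValueError("foreground gene set is empty")
    missing = fg - set(binding.index)
    if missing:
        raise ValueError(f"foreground genes missing from binding matrix: {sorted(missing)[:5]}")
    is_fg = binding.index.isin(fg)
    bound = binding.to_numpy() >= 1
    a = bound[is_fg].sum(axis=0)
    b = is_fg.sum() - a
    c = bound[~is_fg].sum(axis=0)
    d = (~is_fg).sum() - c
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = np.where((b * c) > 0, (a * d) / (b * c), np.inf)
        odds = np.where((a * d) == 0, np.where((b * c) > 0, 0.0, np.nan), odds)
    p = np.array([fisher_one_tailed_p(int(ai), int(bi), int(ci), int(di))
                  for ai, bi, ci, di in zip(a, b, c, d)])
    res = pd.DataFrame({
        "tf_name": binding.columns,
        "a": a, "b": b, "c": c, "d": d,
        "odds_ratio": odds,
        "p_one_tailed": p,
    })
    res["p_adjusted"] = bh_adjust(res["p_one_tailed"].to_numpy())
    res["enriched"] = res["p_adjusted"] < padj_threshold
    return res


def arbs_summary(candidate_genes: list[str], regions: pd.DataFrame,
                 tumor_peaks: PeakSet, normal_peaks: PeakSet) -> tuple[pd.DataFrame, dict]:
    """Tumor- vs normal-specific AR binding sites in candidate windows.

    Returns per-gene counts plus the headline summary: the fraction of
    candidates with at least one site of each class, the total site counts,
    and the tumor/normal total ratio.
    """
    sub = regions[regions["gene_id"].isin(candidate_genes)].reset_index(drop=True)
    tumor = count_overlaps(sub, tumor_peaks)
    normal = count_overlaps(sub, normal_peaks)
    per_gene = pd.DataFrame({
        "gene_id": sub["gene_id"].to_numpy(),
        "tumor_arbs": tumor.to_numpy(),
        "normal_arbs": normal.to_numpy(),
    })
    n = len(per_gene)
    tot_t = int(per_gene["tumor_arbs"].sum())
    tot_n = int(per_gene["normal_arbs"].sum())
    summary = {
        "n_candidates": n,
        "fraction_with_tumor_arbs": float((per_gene["tumor_arbs"] >= 1).mean()) if n else 0.0,
        "fraction_with_normal_arbs": float((per_gene["normal_arbs"] >= 1).mean()) if n else 0.0,
        "total_tumor_arbs": tot_t,
        "total_normal_arbs": tot_n,
        "tumor_to_normal_ratio": (tot_t / tot_n) if tot_n else float("inf") if tot_t else np.nan,
    }
    return per_gene, summary


def tf_expression_summary(counts: pd.DataFrame, lengths: pd.Series,
                          tf_gene_ids: list[str]) -> pd.DataFrame:
    """TPM-based expression rank of each TF among all genes.

    Percentile is the fraction of genes with mean TPM <= the TF's, times 100;
    TFs above the 75th percentile are flagged top-quartile.
    """
    from .de import tpm_normalize

    missing = set(tf_gene_ids) - set(counts.index)
    if missing:
        raise ValueError(f"unknown TF gene id(s): {sorted(missing)}")
    tpm = tpm_normalize(counts, lengths)
    mean_tpm = tpm.mean(axis=1)
    sorted_vals = np.sort(mean_tpm.to_numpy())
    rows = []
    for g in tf_gene_ids:
        v = mean_tpm.loc[g]
        pct = 100.0 * np.searchsorted(sorted_vals, v, side="right") / len(sorted_vals)
        rows.append((g, float(v), float(pct), pct > 75.0))
    return pd.DataFrame(rows, columns=["gene_id", "mean_tpm", "percentile", "top_quartile"])
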