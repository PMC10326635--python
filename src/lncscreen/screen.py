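"""The four-stage metastasis-specificity screen for lncRNAs.

Stage 1 calls differential expression between metastases and primary tumors
(relaxed padj < 0.15 by design, to feed the later filters). Stage 2 removes
candidates whose signal could come from the tissue of origin, using three
control comparisons against non-prostate normal tissues and BPH prostate.
Stage 3 removes candidates whose per-patient primary-vs-metastasis direction
contradicts the cohort-level call in more than two patients. Stage 4 flags
candidates that overlap a protein-coding gene or pseudogene on the same
strand for manual curation (an optional decision file resolves the flags).
Every stage records a machine-readable drop reason per gene.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import de

logger = logging.getLogger(__name__)

DROP_COLUMNS = ["gene_id", "reason", "comparison", "tissue", "padj", "lfc", "detail"]


@dataclasses.dataclass
class ScreenConfig:
    stage1_padj: float = 0.15
    stage2_padj: float = 0.01
    pairwise_max_opposite: int = 2
    stage2_rule: str = "same-sign-drop"   # or "opposite-sign-drop"
    masking_biotypes: tuple[str, ...] = ("protein_coding", "pseudogene")

    def __post_init__(self):
        if not (0 <= self.stage1_padj < 1) or not (0 < self.stage2_padj < 1):
            raise ValueError("padj thresholds must lie in (0, 1)")
        if self.pairwise_max_opposite < 0:
            raise ValueError("pairwise_max_opposite must be >= 0")
        if self.stage2_rule not in ("same-sign-drop", "opposite-sign-drop"):
            raise ValueError(f"unknown stage2_rule {self.stage2_rule!r}")


@dataclasses.dataclass
class StageReport:
    stage: str
    input_genes: list[str]
    survivors: list[str]
    drops: pd.DataFrame  # DROP_COLUMNS

    def __post_init__(self):
        assert set(self.survivors) <= set(self.input_genes)
        dropped = set(self.input_genes) - set(self.survivors)
        recorded = set(self.drops["gene_id"]) if len(self.drops) else set()
        assert dropped == recorded, f"audit gap in {self.stage}"

    def to_frame(self) -> pd.DataFrame:
        if len(self.drops) == 0:
            return pd.DataFrame(columns=DROP_COLUMNS)
        return self.drops[DROP_COLUMNS]


def _empty_drops() -> pd.DataFrame:
    return pd.DataFrame(columns=DROP_COLUMNS)


def _two_group_de(counts: pd.DataFrame, group_a: list[str], group_b: list[str]) -> pd.DataFrame:
    sub = counts[group_a + group_b]
    factors = de.size_factors_median_of_ratios(sub)
    alpha = de.estimate_dispersion(sub, factors, [group_a, group_b])
    return de.wald_test_two_group(sub, factors, alpha, group_a, group_b)


def stage1_de(counts: pd.DataFrame, samples: pd.DataFrame, models: pd.DataFrame,
              config: ScreenConfig) -> tuple[pd.DataFrame, StageReport]:
    """Metastasis vs primary Wald test over lncRNA genes; survivors pass
    padj strictly below the stage-1 threshold, with their LFC sign recorded."""
    primaries = samples.loc[samples["cancer_status"] == "primary", "sample_id"].tolist()
    mets = samples.loc[samples["cancer_status"] == "metastasis", "sample_id"].tolist()
    if not primaries or not mets:
        raise ValueError("stage 1 needs >= 1 primary and >= 1 metastasis sample")
    lnc = models.loc[models["biotype"] == "lncRNA", "gene_id"]
    lnc = [g for g in lnc if g in counts.index]
    res = _two_group_de(counts.loc[lnc], primaries, mets)
    keep = res["padj"] < config.stage1_padj
    keep = keep.fillna(False)
    survivors = res.loc[keep, "gene_id"].tolist()
    dropped = res.loc[~keep]
    drops = pd.DataFrame({
        "gene_id": dropped["gene_id"],
        "reason": "stage1_not_significant",
        "comparison": "metastasis_vs_primary",
        "tissue": "NA",
        "padj": dropped["padj"],
        "lfc": dropped["log2FoldChange"],
        "detail": np.where(dropped["padj"].isna(), "all-zero or untested",
                           f"padj >= {config.stage1_padj}"),
    })
    report = StageReport("stage1_de", list(res["gene_id"]), survivors, drops)
    return res, report


def stage2_tissue_filters(counts: pd.DataFrame, samples: pd.DataFrame,
                          survivors: list[str], directions: pd.Series,
                          config: ScreenConfig) -> StageReport:
    """Three tissue-specific control comparisons.

    (a) primaries vs each non-prostate normal tissue separately;
    (b) primaries vs all non-prostate normals pooled;
    (c) BPH vs all non-prostate normals pooled.
    Control LFC is oriented control-minus-reference. Under the default rule a
    survivor with metastasis direction d is dropped when a control comparison
    is significant (padj < stage-2 threshold) with sign(LFC) == d, i.e. the
    control tissue deviates in the direction that could explain the
    metastasis signal.

    Each control comparison is a full differential-expression run over every
    gene in the matrix (so normalization and the BH denominator rest on the
    whole transcriptome, not the handful of survivors); survivor rows are
    then read off the result.
    """
    if not survivors:
        return StageReport("stage2_tissue_filters", [], [], _empty_drops())
    primaries = samples.loc[samples["cancer_status"] == "primary", "sample_id"].tolist()
    normals = samples[samples["cancer_status"] == "normal"]
    bph = samples.loc[samples["cancer_status"] == "bph", "sample_id"].tolist()

    comparisons: list[tuple[str, str, list[str], list[str]]] = []
    sites_done = []
    for site, grp in normals.groupby("tissue_site"):
        ids = grp["sample_id"].tolist()
        if len(ids) >= 2:
            comparisons.append(("filter_a", site, primaries, ids))
            sites_done.append(site)
        else:
            logger.warning("filter (a): skipping %s (fewer than 2 normal samples)", site)
    all_normals = normals["sample_id"].tolist()
    if len(all_normals) >= 2:
        comparisons.append(("filter_b", "all_normals", primaries, all_normals))
    else:
        logger.warning("filters (a)/(b) skipped: no non-prostate normal samples")
    if len(bph) >= 2 and len(all_normals) >= 2:
        comparisons.append(("filter_c", "all_normals_vs_bph", bph, all_normals))
    else:
        logger.warning("filter (c) skipped: needs >= 2 BPH and >= 2 normal samples")

    sign_drop = +1 if config.stage2_rule == "same-sign-drop" else -1
    drop_rows = []
    for name, tissue, ref, ctrl in comparisons:
        res = _two_group_de(counts, ref, ctrl).set_index("gene_id")
        for g in survivors:
            padj, lfc = res.at[g, "padj"], res.at[g, "log2FoldChange"]
            if np.isnan(padj) or padj >= config.stage2_padj or lfc == 0:
                continue
            if np.sign(lfc) == sign_drop * directions.loc[g]:
                drop_rows.append((g, "stage2_tissue_specific", name, tissue,
                                  padj, lfc, "control deviation explains signal"))
    drops = pd.DataFrame(drop_rows, columns=DROP_COLUMNS)
    surviving = [g for g in survivors if g not in set(drops["gene_id"])]
    return StageReport("stage2_tissue_filters", survivors, surviving, drops)


def stage3_pairwise(counts: pd.DataFrame, factors: pd.Series, samples: pd.DataFrame,
                    survivors: list[str], directions: pd.Series,
                    config: ScreenConfig) -> StageReport:
    """Per-patient direction check in patients with paired primary/metastasis.

    For each paired patient, a gene's direction is the sign of (mean
    normalized expression over that patient's metastases) minus (mean over
    the patient's primaries). A gene is removed when more than
    `pairwise_max_opposite` patients contradict its cohort-level direction;
    exact zero differences count as consistent.
    """
    if not survivors:
        return StageReport("stage3_pairwise", [], [], _empty_drops())
    has_pri = samples[samples["cancer_status"] == "primary"].groupby("patient_id").size()
    has_met = samples[samples["cancer_status"] == "metastasis"].groupby("patient_id").size()
    paired = sorted(set(has_pri.index) & set(has_met.index))
    if not paired:
        logger.warning("stage 3: no patients with paired primary and metastasis; passing all")
        return StageReport("stage3_pairwise", survivors, list(survivors), _empty_drops())

    norm = counts.loc[survivors] / factors.loc[counts.columns]
    n_opposite = pd.Series(0, index=survivors)
    for pid in paired:
        pri = samples.loc[(samples["patient_id"] == pid) &
                          (samples["cancer_status"] == "primary"), "sample_id"]
        met = samples.loc[(samples["patient_id"] == pid) &
                          (samples["cancer_status"] == "metastasis"), "sample_id"]
        diff = norm[met].mean(axis=1) - norm[pri].mean(axis=1)
        opposite = np.sign(diff) == -directions.loc[survivors]
        n_opposite += opposite.astype(int)
    removed = n_opposite[n_opposite > config.pairwise_max_opposite].index.tolist()
    drops = pd.DataFrame({
        "gene_id": removed,
        "reason": "stage3_inconsistent_across_patients",
        "comparison": "patient_pairwise",
        "tissue": "NA",
        "padj": np.nan,
        "lfc": np.nan,
        "detail": [f"opposite in {int(n_opposite[g])} of {len(paired)} paired patients"
                   for g in removed],
    })
    surviving = [g for g in survivors if g not in set(removed)]
    return StageReport("stage3_pairwise", survivors, surviving, drops)


def stage4_overlap_filter(survivors: list[str], models: pd.DataFrame,
                          directions: pd.Series, config: ScreenConfig,
                          curation: dict[str, str] | None = None,
                          ) -> tuple[pd.DataFrame, StageReport]:
    """Same-strand >= 1 bp overlap with coding genes / pseudogenes.

    Overlapping candidates are flagged needs_curation but kept, unless a
    curation decision file marks them "drop". Returns the candidate set
    (gene_id, direction, curation_flag) and the stage report.
    """
    idx = models.set_index("gene_id")
    missing = [g for g in survivors if g not in idx.index]
    if missing:
        raise ValueError(f"survivor missing from annotation: {missing[0]!r}")
    masks = models[models["biotype"].isin(config.masking_biotypes)]
    rows, drop_rows = [], []
    for g in survivors:
        m = idx.loc[g]
        hits = masks[(masks["chrom"] == m["chrom"]) & (masks["strand"] == m["strand"]) &
                     (masks["start"] < m["end"]) & (masks["end"] > m["start"])]
        flag = "needs_curation" if len(hits) else "clean"
        decision = (curation or {}).get(g)
        if flag == "needs_curation" and decision == "drop":
            drop_rows.append((g, "stage4_curated_out", "overlap_curation",
                              "NA", np.nan, np.nan,
                              f"overlaps {hits['gene_id'].iloc[0]}; curated drop"))
            continue
        rows.append((g, int(directions.loc[g]), flag))
    candidates = pd.DataFrame(rows, columns=["gene_id", "direction", "curation_flag"])
    drops = pd.DataFrame(drop_rows, columns=DROP_COLUMNS)
    report = StageReport("stage4_overlap", survivors, candidates["gene_id"].tolist(), drops)
    return candidates, report


def run_screen(counts: pd.DataFrame, samples: pd.DataFrame, models: pd.DataFrame,
               config: ScreenConfig | None = None,
               curation: dict[str, str] | None = None,
               ) -> tuple[pd.DataFrame, list[StageReport]]:
    """Execute stages 1-4 in order; returns (candidates, stage reports)."""
    config = config or ScreenConfig()
    de_res, rep1 = stage1_de(counts, samples, models, config)
    directions = pd.Series(np.sign(de_res.set_index("gene_id")["log2FoldChange"]))
    rep2 = stage2_tissue_filters(counts, samples, rep1.survivors, directions, config)
    factors = de.size_factors_median_of_ratios(counts)
    rep3 = stage3_pairwise(counts, factors, samples, rep2.survivors, directions, config)
    candidates, rep4 = stage4_overlap_filter(rep3.survivors, models, directions,
                                             config, curation)
    reports = [rep1, rep2, rep3, rep4]
    logger.info("screen funnel: %s", " -> ".join(
        f"{r.stage}:{len(r.survivors)}" for r in reports))
    return candidates, reports


def audit_dict(reports: list[StageReport]) -> dict:
    """Machine-readable audit trail of the full funnel."""
    return {
        "funnel": [{"stage": r.stage, "n_input": len(r.input_genes),
                    "n_survivors": len(r.survivors)} for r in reports],
        "drops": {r.stage: r.to_frame().to_dict(orient="records") for r in reports},
    }


def write_screen_outputs(candidates: pd.DataFrame, reports: list[StageReport],
                         outdir: str | Path) -> None:
    outdir = Path(outdir)
    (outdir / "stage_reports").mkdir(parents=True, exist_ok=True)
    candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    for r in reports:
        r.to_frame().to_csv(outdir / "stage_reports" / f"{r.stage}.tsv",
                            sep="\t", index=False, na_rep="NA")
    with open(outdir / "audit.json", "w") as fh:
        json.dump(audit_dict(reports), fh, indent=2, default=str)
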