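"""Synthetic cohorts with planted ground truth.

The generator emulates the statistical structure of a multi-site autopsy
cohort of metastatic castration-resistant prostate cancer: a handful of
patients with primary tumors, many metastases spread over several tissue
sites, normal-tissue controls per site, and BPH prostate controls. Counts are
negative binomial on a log-scale linear predictor

    log2 mean = baseline + patient effect + metastasis effect + site effect

where patient effects are gene-block-shared shifts (so they survive
library-size normalization and dominate sample clustering, as in real
cohorts), planted metastasis genes carry a fixed log2 fold change in every
metastasis, and tissue-specific genes are elevated in a site's normal tissue
AND in metastases at that site — the confound the tissue filters exist to
remove. Companions generate gene models with same-strand overlaps, TF peak
sets enriched near planted genes, and survival cohorts with known hazards.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GeneModel, PeakSet, models_to_frame
from .tf import regulatory_regions

DEFAULT_SITES = ("liver", "bone", "lymph_node", "adrenal", "subdural")


@dataclasses.dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults emulate the autopsy-cohort scale
    (six patients with primaries, one of them with two, ~80 metastases over
    five sites) with realistic NB dispersion and strong lncRNA tissue
    specificity."""

    n_patients: int = 25
    n_primaries_per_patient: int | Sequence[int] | None = None  # default: 5x1 + 1x2
    mets_per_patient: int | Sequence[int] = 3
    tissue_sites: Sequence[str] = DEFAULT_SITES
    # relative met burden per site, aligned with tissue_sites; the default
    # mirrors a real autopsy series (lymph node >> bone > liver > adrenal,
    # subdural) — the unevenness matters, because site-specific genes only
    # reach the cohort-level DE stage when their site carries enough mets
    site_weights: Sequence[float] = (12, 18, 40, 7, 6)
    n_normals_per_site: int = 10
    n_bph: int = 4
    n_genes: int = 2500
    fraction_lncRNA: float = 0.8
    n_planted_met_genes: int = 20
    planted_lfc: float = 3.0
    n_tissue_specific_genes: int = 6   # per site
    tissue_lfc: float = 5.0
    # genes that differ between a site's normal tissue and everything else but
    # carry no signal in metastases: real tissue-vs-tumor comparisons involve
    # thousands of such genes, and they set the BH denominator the stage-2
    # control filters actually face
    n_background_tissue_genes: int = 50   # per site
    background_tissue_lfc_range: tuple[float, float] = (2.0, 6.0)
    patient_effect_sd: float = 1.0
    n_patient_effect_blocks: int = 10
    dispersion: float = 0.2
    baseline_log_mean_range: tuple[float, float] = (2.0, 9.0)
    fraction_overlapping_lncRNA: float = 0.05
    n_tfs: int = 20
    n_enriched_tfs: int = 3
    fg_peak_prob: float = 0.9
    bg_peak_prob: float = 0.1
    peak_width: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.n_primaries_per_patient is None:
            self.n_primaries_per_patient = [1] * 5 + [2] + [0] * (self.n_patients - 6)
        if self.n_patients <= 0 or self.n_genes < 10:
            raise ValueError("n_patients must be positive and n_genes >= 10")
        if not 0 <= self.fraction_lncRNA <= 1:
            raise ValueError("fraction_lncRNA must be in [0, 1]")
        if not 0 <= self.fraction_overlapping_lncRNA <= 1:
            raise ValueError("fraction_overlapping_lncRNA must be in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be strictly positive")
        if self.patient_effect_sd < 0:
            raise ValueError("patient_effect_sd must be non-negative")
        prim = self._per_patient(self.n_primaries_per_patient)
        mets = self._per_patient(self.mets_per_patient)
        if any(p < 0 for p in prim) or any(m < 0 for m in mets):
            raise ValueError("per-patient sample counts must be non-negative")
        if all(m == 0 for m in mets):
            raise ValueError("cohort must contain at least one metastasis")
        if len(self.site_weights) != len(self.tissue_sites):
            raise ValueError("site_weights must align with tissue_sites")
        if any(w < 0 for w in self.site_weights) or sum(self.site_weights) <= 0:
            raise ValueError("site_weights must be non-negative with positive sum")
        n_lnc = int(round(self.n_genes * self.fraction_lncRNA))
        need = self.n_planted_met_genes + (
            self.n_tissue_specific_genes + self.n_background_tissue_genes
        ) * len(self.tissue_sites)
        if need > n_lnc:
            raise ValueError("more planted + tissue-specific genes than lncRNAs")

    def _per_patient(self, value) -> list[int]:
        if isinstance(value, (int, np.integer)):
            return [int(value)] * self.n_patients
        value = list(value)
        if len(value) != self.n_patients:
            raise ValueError("per-patient list length must equal n_patients")
        return [int(v) for v in value]

    @property
    def n_lncRNA(self) -> int:
        return int(round(self.n_genes * self.fraction_lncRNA))


@dataclasses.dataclass
class SyntheticTruth:
    """Planted ground truth: which genes carry which signal."""

    planted_met_genes: dict[str, int]           # gene_id -> +1 / -1
    tissue_specific_genes: dict[str, set[str]]  # site -> gene ids
    overlapping_lncRNAs: set[str] = dataclasses.field(default_factory=set)
    peak_enriched_tfs: set[str] = dataclasses.field(default_factory=set)
    # tissue-variable background (site normals only, no metastasis signal)
    background_tissue_genes: dict[str, set[str]] = dataclasses.field(default_factory=dict)

    def all_tissue_specific(self) -> set[str]:
        out: set[str] = set()
        for genes in self.tissue_specific_genes.values():
            out |= genes
        return out


def _rng_streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def gene_ids(config: SimulationConfig) -> tuple[list[str], list[str], list[str]]:
    """Deterministic gene id lists: (lncRNAs, protein-coding, pseudogenes)."""
    n_lnc = config.n_lncRNA
    n_other = config.n_genes - n_lnc
    n_coding = int(round(n_other * 0.7))
    lnc = [f"LNC{i:05d}" for i in range(n_lnc)]
    coding = [f"PCG{i:05d}" for i in range(n_coding)]
    pseudo = [f"PSG{i:05d}" for i in range(n_other - n_coding)]
    return lnc, coding, pseudo


def assign_truth_genes(config: SimulationConfig) -> SyntheticTruth:
    """Choose planted metastasis genes and per-site tissue-specific genes.

    Selection uses a dedicated child seed so every generator sees the same
    assignment. Roughly three quarters of the planted genes go up in
    metastases, the rest down. The categories are disjoint by construction.
    """
    rng = _rng_streams(config.seed, 4)[0]
    lnc, _, _ = gene_ids(config)
    n_plant = config.n_planted_met_genes
    n_tissue = config.n_tissue_specific_genes * len(config.tissue_sites)
    n_bg = config.n_background_tissue_genes * len(config.tissue_sites)
    chosen = rng.choice(len(lnc), size=n_plant + n_tissue + n_bg, replace=False)
    planted_ids = [lnc[i] for i in chosen[:n_plant]]
    n_up = int(np.ceil(0.75 * n_plant))
    planted = {g: (+1 if k < n_up else -1) for k, g in enumerate(planted_ids)}
    tissue: dict[str, set[str]] = {}
    pos = n_plant
    for site in config.tissue_sites:
        tissue[site] = {lnc[i] for i in chosen[pos:pos + config.n_tissue_specific_genes]}
        pos += config.n_tissue_specific_genes
    background: dict[str, set[str]] = {}
    for site in config.tissue_sites:
        background[site] = {lnc[i]
                            for i in chosen[pos:pos + config.n_background_tissue_genes]}
        pos += config.n_background_tissue_genes
    return SyntheticTruth(planted_met_genes=planted, tissue_specific_genes=tissue,
                          background_tissue_genes=background)


def _met_site_sequence(config: SimulationConfig, n_mets: int,
                       rng: np.random.Generator) -> list[str]:
    """Per-met site labels honoring the site weights (largest remainder),
    shuffled so patients carry mets at mixed sites."""
    w = np.asarray(config.site_weights, dtype=float)
    w = w / w.sum()
    base = np.floor(w * n_mets).astype(int)
    remainder = w * n_mets - base
    for i in np.argsort(-remainder)[: n_mets - base.sum()]:
        base[i] += 1
    seq = [site for site, k in zip(config.tissue_sites, base) for _ in range(k)]
    rng.shuffle(seq)
    return seq


def _sample_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    prim = config._per_patient(config.n_primaries_per_patient)
    mets = config._per_patient(config.mets_per_patient)
    site_seq = _met_site_sequence(config, sum(mets), rng)
    site_cursor = 0
    for p in range(config.n_patients):
        pid = f"P{p + 1:02d}"
        for k in range(prim[p]):
            rows.append((f"{pid}_PRI{k + 1}", pid, "primary", "prostate"))
        for k in range(mets[p]):
            site = site_seq[site_cursor]
            site_cursor += 1
            rows.append((f"{pid}_MET{k + 1}", pid, "metastasis", site))
    for site in config.tissue_sites:
        for k in range(config.n_normals_per_site):
            pid = f"N_{site}_{k + 1}"
            rows.append((f"{pid}_NOR", pid, "normal", site))
    for k in range(config.n_bph):
        pid = f"B{k + 1:02d}"
        rows.append((f"{pid}_BPH", pid, "bph", "prostate"))
    return pd.DataFrame(rows, columns=["sample_id", "patient_id", "cancer_status", "tissue_site"])


def simulate_cohort_counts(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate (counts, sample table, truth) for the full cohort.

    Counts are NB with Var = mu + alpha * mu^2. Patient effects are drawn per
    (patient, gene block) — including the control pseudo-patients — so
    patient-to-patient variability dominates the covariance structure without
    being removable by size factors.
    """
    truth = assign_truth_genes(config)
    rng = _rng_streams(config.seed, 4)[1]
    samples = _sample_table(config, rng)
    lnc, coding, pseudo = gene_ids(config)
    genes = lnc + coding + pseudo
    n_genes, n_samples = len(genes), len(samples)

    baseline = rng.uniform(*config.baseline_log_mean_range, size=n_genes)

    blocks = np.arange(n_genes) % config.n_patient_effect_blocks
    patients = samples["patient_id"].unique()
    pat_effect = rng.normal(0.0, config.patient_effect_sd,
                            size=(len(patients), config.n_patient_effect_blocks))
    pat_index = {p: i for i, p in enumerate(patients)}
    sample_pat = samples["patient_id"].map(pat_index).to_numpy()

    log2mu = baseline[:, None] + pat_effect[sample_pat][:, blocks].T

    gene_index = {g: i for i, g in enumerate(genes)}
    is_met = (samples["cancer_status"] == "metastasis").to_numpy()
    for g, d in truth.planted_met_genes.items():
        log2mu[gene_index[g], is_met] += d * config.planted_lfc
    for site, site_genes in truth.tissue_specific_genes.items():
        at_site = (samples["tissue_site"] == site).to_numpy()
        for g in site_genes:
            log2mu[gene_index[g], at_site] += config.tissue_lfc
    is_normal = (samples["cancer_status"] == "normal").to_numpy()
    lo, hi = config.background_tissue_lfc_range
    for site, site_genes in truth.background_tissue_genes.items():
        normal_at_site = is_normal & (samples["tissue_site"] == site).to_numpy()
        for g in sorted(site_genes):
            effect = rng.uniform(lo, hi) * (1 if rng.random() < 0.5 else -1)
            log2mu[gene_index[g], normal_at_site] += effect

    mu = np.exp2(log2mu)
    a = config.dispersion
    counts = rng.negative_binomial(n=1.0 / a, p=1.0 / (1.0 + a * mu))
    counts_df = pd.DataFrame(counts.astype(np.int64), index=pd.Index(genes, name="gene_id"),
                             columns=samples["sample_id"].to_list())
    return counts_df, samples, truth


def simulate_gene_models(config: SimulationConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Lay gene models on one chromosome; a configurable fraction of the
    unplanted lncRNAs is placed to overlap a coding or pseudogene on the same
    strand (>= 1 bp), feeding the screen's overlap filter."""
    truth = assign_truth_genes(config)
    rng = _rng_streams(config.seed, 4)[2]
    lnc, coding, pseudo = gene_ids(config)

    special = set(truth.planted_met_genes) | truth.all_tissue_specific()
    for genes in truth.background_tissue_genes.values():
        special |= genes
    eligible = [g for g in lnc if g not in special]
    n_overlap = int(round(config.fraction_overlapping_lncRNA * len(lnc)))
    n_overlap = min(n_overlap, len(eligible), len(coding) + len(pseudo))
    overlap_ids = set(rng.choice(eligible, size=n_overlap, replace=False)) if n_overlap else set()
    truth.overlapping_lncRNAs = overlap_ids

    partners = coding + pseudo
    partner_for = {g: partners[i % len(partners)]
                   for i, g in enumerate(sorted(overlap_ids))}

    models: list[GeneModel] = []
    positions: dict[str, tuple[int, int, str]] = {}
    cursor = 10_000
    plain = [g for g in lnc if g not in overlap_ids] + coding + pseudo
    order = list(plain)
    rng.shuffle(order)
    for g in order:
        length = int(rng.integers(500, 5001))
        strand = "+" if rng.random() < 0.5 else "-"
        start = cursor
        end = start + length
        biotype = ("lncRNA" if g.startswith("LNC")
                   else "protein_coding" if g.startswith("PCG") else "pseudogene")
        models.append(GeneModel(g, "chr1", start, end, strand, biotype,
                                transcript_length=length))
        positions[g] = (start, end, strand)
        cursor = end + int(rng.integers(10_000, 30_001))
    for g in sorted(overlap_ids):
        ps, pe, pstrand = positions[partner_for[g]]
        length = int(rng.integers(500, 5001))
        # start inside the partner so the overlap is >= 1 bp on the same strand
        start = int(rng.integers(ps, pe))
        models.append(GeneModel(g, "chr1", start, start + length, pstrand, "lncRNA",
                                transcript_length=length))
    return models_to_frame(models), truth


def simulate_peaks(
    config: SimulationConfig, models: pd.DataFrame,
    truth: SyntheticTruth | None = None,
) -> dict[str, PeakSet]:
    """Per-TF peak sets over the lncRNA regulatory windows.

    The first `n_enriched_tfs` TFs drop a peak into a planted metastasis
    gene's window with probability `fg_peak_prob`, everywhere else with
    `bg_peak_prob`; background TFs use `bg_peak_prob` throughout.
    """
    if models.empty:
        raise ValueError("gene models must be non-empty")
    if truth is None:
        truth = assign_truth_genes(config)
    rng = _rng_streams(config.seed, 4)[3]
    lnc_models = models[models["biotype"] == "lncRNA"]
    regions = regulatory_regions(lnc_models)
    planted = set(truth.planted_met_genes)
    enriched = [f"TF_ENR{i + 1:02d}" for i in range(config.n_enriched_tfs)]
    background = [f"TF_BG{i + 1:03d}" for i in range(config.n_tfs - config.n_enriched_tfs)]
    truth.peak_enriched_tfs = set(enriched)

    out: dict[str, PeakSet] = {}
    starts = regions["start"].to_numpy()
    ends = regions["end"].to_numpy()
    fg = regions["gene_id"].isin(planted).to_numpy()
    for tf in enriched + background:
        p = np.where(fg, config.fg_peak_prob, config.bg_peak_prob) if tf in set(enriched) \
            else np.full(len(regions), config.bg_peak_prob)
        hit = rng.random(len(regions)) < p
        centers = rng.integers(starts, ends)
        half = config.peak_width // 2
        peak_start = np.maximum(centers[hit] - half, 0)
        peak_end = peak_start + config.peak_width
        df = pd.DataFrame({"chrom": regions["chrom"].to_numpy()[hit],
                           "start": peak_start, "end": peak_end})
        out[tf] = PeakSet(tf_name=tf, intervals=df)
    return out


def simulate_study(config: SimulationConfig):
    """Convenience wrapper: counts + samples + gene models + peaks + one truth."""
    counts, samples, truth = simulate_cohort_counts(config)
    models, truth_m = simulate_gene_models(config)
    truth.overlapping_lncRNAs = truth_m.overlapping_lncRNAs
    peaks = simulate_peaks(config, models, truth)
    return counts, samples, models, peaks, truth


# ---------------------------------------------------------------------------
# survival cohort

PSA_CATEGORIES = ("psa_low", "psa_intermediate", "psa_high")

DEFAULT_COVARIATE_LOG_HRS: Mapping[str, float] = {
    "psa_intermediate": 0.2,
    "psa_high": 0.8,
    "age_high": 0.3,
    "pt_high": 0.4,
}


def simulate_survival_cohort(
    n: int,
    hr_expression: float,
    censor_rate: float = 0.3,
    seed: int = 0,
    covariate_log_hrs: Mapping[str, float] = DEFAULT_COVARIATE_LOG_HRS,
    gs_baseline_ratio: float = 1.5,
) -> pd.DataFrame:
    """Exponential progression times with a known expression-group hazard ratio.

    The high-expression group is the top quartile of a log-normal expression
    marker; its hazard is multiplied by `hr_expression`. Clinical covariates
    (age, PSA, Gleason, pT) follow realistic categorical distributions and
    contribute the given log hazard ratios; the Gleason category scales the
    baseline hazard only (so Gleason is a stratification variable, not a
    modeled covariate). Censoring is independent with the requested marginal
    probability; censor_rate=0 means every subject progresses.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    if hr_expression <= 0:
        raise ValueError("hr_expression must be positive")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    expression = rng.lognormal(mean=2.0, sigma=1.0, size=n)
    q3 = np.quantile(expression, 0.75)
    high = expression > q3

    age = np.clip(rng.normal(62, 8, size=n), 40, 90)
    psa = rng.lognormal(mean=2.2, sigma=0.8, size=n)
    gleason = rng.choice([6, 7, 8, 9], size=n, p=[0.25, 0.45, 0.2, 0.1])
    pt = rng.choice([2, 3, 4, 5, 6], size=n, p=[0.3, 0.3, 0.15, 0.15, 0.1])

    log_h = np.log(1e-2) * np.ones(n)
    log_h += np.log(hr_expression) * high
    log_h += covariate_log_hrs.get("psa_intermediate", 0.0) * ((psa >= 10) & (psa < 20))
    log_h += covariate_log_hrs.get("psa_high", 0.0) * (psa >= 20)
    log_h += covariate_log_hrs.get("age_high", 0.0) * (age > 62)
    log_h += covariate_log_hrs.get("pt_high", 0.0) * (pt >= 5)
    gs_stratum = np.where(gleason < 7, 0, np.where(gleason == 7, 1, 2))
    log_h += np.log(gs_baseline_ratio) * gs_stratum

    h = np.exp(log_h)
    event_time = rng.exponential(1.0 / h)
    if censor_rate > 0:
        c = h * censor_rate / (1.0 - censor_rate)
        censor_time = rng.exponential(1.0 / c)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    return pd.DataFrame({
        "sample_id": [f"S{i + 1:04d}" for i in range(n)],
        "time": np.maximum(time, 1e-9),
        "event": event,
        "age": age,
        "psa": psa,
        "gleason": gleason,
        "pt": pt,
        "expression": expression,
    })
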