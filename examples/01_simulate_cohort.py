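"""Generate a synthetic multi-site metastasis cohort with planted truth.

Builds the default cohort — 25 patients, 6 of them with primary tumors (one
with two), ~80 metastases spread unevenly over five tissue sites, per-site
normal controls and BPH prostate controls — and prints what was planted.
"""

from lncscreen import simulate as sim

config = sim.SimulationConfig(seed=1)
counts, samples, models, peaks, truth = sim.simulate_study(config)

print(f"count matrix: {counts.shape[0]} genes x {counts.shape[1]} samples")
print("samples by status:", samples["cancer_status"].value_counts().to_dict())
print("metastases by site:",
      samples.loc[samples.cancer_status == "metastasis", "tissue_site"]
      .value_counts().to_dict())

n_up = sum(d > 0 for d in truth.planted_met_genes.values())
print(f"planted metastasis genes: {len(truth.planted_met_genes)} "
      f"({n_up} up, {len(truth.planted_met_genes) - n_up} down), |log2FC| = "
      f"{config.planted_lfc}")
print(f"tissue-specific confounders: "
      f"{sum(len(v) for v in truth.tissue_specific_genes.values())} "
      f"({config.n_tissue_specific_genes} per site, log2FC = {config.tissue_lfc})")
print(f"lncRNAs overlapping a coding/pseudogene: {len(truth.overlapping_lncRNAs)}")
print(f"TFs planted as enriched near metastasis genes: "
      f"{sorted(truth.peak_enriched_tfs)}")
# The confounders mimic tissue-of-origin expression: they are elevated in a
# site's normal tissue AND in metastases growing at that site, so a naive
# metastasis-vs-primary comparison mistakes them for metastasis genes.
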