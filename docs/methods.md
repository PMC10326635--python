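# Methods

## Count model and differential expression

All expression testing rests on the standard RNA-seq negative-binomial model:
counts `y_ij ~ NB(mean = s_j * mu_ig, Var = mu + alpha_i * mu^2)` with a
log link, where `s_j` is a per-sample size factor, `g` indexes the two
groups of a comparison and `alpha_i` is a per-gene dispersion.

- **Size factors** are classical median-of-ratios: per sample, the median
  over genes (restricted to genes positive in every sample) of the count
  divided by the gene's geometric mean. They are equivariant (scaling one
  sample's counts scales its factor) and undefined only when no gene is
  positive everywhere, which is an error.
- **Dispersion** is per-gene method of moments on normalized counts:
  within each group, `Var(y/s) ≈ mu * E[1/s] + alpha * mu^2` is solved for
  `alpha`; group estimates are pooled with degree-of-freedom weights and
  floored at `1e-8` (a constant gene hits the floor). No trend or shrinkage
  is applied by default — the screen's decisions depend on directions and
  threshold crossings, not on exact dispersion values — and the estimator
  recovers the truth well at moderate group sizes (median within 3% of a
  simulated alpha = 0.2 at 50 per group).
- **The Wald test** fits the two group means by Newton iteration on the
  log scale (score equations with size-factor offsets and known alpha;
  an all-zero group is floored at half a normalized count so the statistic
  stays defined and conservative). The statistic is the log fold change over
  its standard error from expected Fisher information. The reference
  distribution is Student t with `n_A + n_B - 2` degrees of freedom rather
  than normal: with a noisy plug-in dispersion the normal reference is
  visibly anticonservative at small n (measured type-I ~0.069 at 0.05
  nominal, 10 vs 10), while the t reference restores ~0.053; at cohort scale
  the two are numerically identical. This is the same small-sample logic
  that quasi-likelihood F-tests use. Genes with all-zero counts in a
  comparison report NA and are excluded from the BH denominator.
- **BH adjustment** is the classical step-up, validated in tests against the
  brute-force definition `padj_(i) = min_{j>=i} min(1, m p_(j)/j)`.
- **VST** is `log2(normalized count + 4)`: for NB data the transformed SD
  approaches `sqrt(alpha)/ln 2` for large means, flat enough in the mean for
  PCA and clustering (the SD-on-mean slope contract |slope| <= 0.1 is
  tested). **TPM** divides by transcript length in kb and rescales columns
  to 1e6; all-zero samples stay all-zero.

## The four-stage screen

Stage thresholds: adjusted p < 0.15 at stage 1 (relaxed on purpose — the
later filters, not the DE cutoff, provide specificity), < 0.01 for the
stage-2 control comparisons, "more than 2 opposite patients" at stage 3.
All comparisons are strict inequalities.

The stage-2 keep/drop rule had to be formalized from prose: each control
comparison is oriented control-minus-reference (non-prostate normals vs
primaries for filters a/b, other normals vs BPH for filter c), and a
survivor with metastasis direction `d` is dropped when any control
comparison is significant with LFC sign equal to `d` — the control tissue
deviates in the direction that could explain the metastasis signal. Genes
whose control deviation opposes `d` are kept. The opposite reading is one
config switch away (`stage2_rule="opposite-sign-drop"`). Each control
comparison is a full DE run over every gene in the matrix, so normalization
and the BH denominator reflect the whole transcriptome rather than the few
dozen survivors (normalizing over survivors only measurably biases the
control fold changes, because tissue-elevated genes dominate such a small
gene set).

Stage 3 uses size-factor-normalized counts (not VST) so direction semantics
match stage 1; exact-zero per-patient differences count as consistent, since
only genuine opposition is evidence against a gene. Stage 4 treats manual
IGV curation as external: overlapping candidates are kept but flagged, and
an optional decision file (gene -> keep/drop) resolves the worklist
reproducibly. Dispersion for every comparison is estimated from that
comparison's two groups only.

## Regulatory regions and TF enrichment

Windows span 5,000 bp upstream to 2,000 bp downstream of the TSS, oriented
by transcription (for a minus-strand gene at TSS t the half-open window is
`[t-1999, t+5001)`), clipped at position 0; an unstranded mode reproduces
the naive reading. Overlap counting is half-open with a >= 1 bp rule,
implemented by sorted-array bisection and tested exhaustively against the
quadratic all-pairs oracle. Enrichment uses the binary has-a-site reading
per gene, a one-tailed (greater) Fisher exact test of foreground vs
background-minus-foreground with the all-lncRNA annotation as background,
and BH across the tested TFs with enrichment declared at adjusted p < 0.15.
Depletion is not tested.

## Survival analysis

Expression is dichotomized at the third quartile (linear-interpolation
type-7 quantile; a value exactly at Q3 is "low", so "high" is the strict top
quartile). Covariate categories: age <= 62 / > 62; PSA <= 10, (10, 20),
>= 20 ng/mL (20.0 exactly is "high"); pT codes 2-4 vs 5-6; Gleason < 7,
= 7, > 7. Kaplan-Meier curves, the log-rank test, the Cox partial-likelihood
fit (Breslow tie handling) and the Grambsch-Therneau scaled-Schoenfeld
proportional-hazards test are delegated to lifelines; the Cox model includes
expression group, PSA, age and pT categories as dummies against the
reference levels above, with Gleason as a stratification variable only
(stratum-specific baseline hazards), because Gleason violates proportional
hazards in this setting. Constant covariates are dropped with a warning;
fewer than five events makes the PH test NA.

## The synthetic cohort generator

The generator emulates the statistical structure of a multi-site autopsy
cohort, with defaults at that study scale: 25 patients, six with primary
tumors (one contributing two primaries), three metastases per patient
(~75 total) distributed over five sites with the uneven burden real autopsy
series show (lymph node >> bone > liver > adrenal, subdural; configurable
`site_weights`), ten normals per non-prostate site, four BPH prostate
controls, 2,500 genes of which 80% are lncRNAs.

The log2 mean of each count is `baseline + patient + status + site`:

- **baseline** ~ U(2, 9) per gene (means ~4-512);
- **patient effects** ~ N(0, 1) per patient per block of genes (10 blocks,
  including pseudo-patients behind normal/BPH samples). Sharing the shift
  within a gene block — rather than drawing it per gene or per sample —
  makes patient identity dominate sample clustering without being absorbed
  by size factors, reproducing the patient-dominant PCA structure of real
  cohorts (tested);
- **status effect**: 20 planted metastasis genes carry ±3 log2 units in
  every metastasis (three quarters up);
- **site effects**: 6 tissue-specific confounders per site carry +5 log2
  units in that site's normal tissue AND in metastases at that site —
  tissue-of-origin admixture, the exact confound stage 2 exists to remove —
  while 50 background tissue-variable genes per site carry ±U(2, 6) in that
  site's normals only. The background genes carry no metastasis signal; they
  exist because real tissue-vs-tumor comparisons involve hundreds of
  strongly tissue-specific lncRNAs, and it is these that set the BH
  denominator the stage-2 filters actually face. Without them the control
  comparisons would be unrealistically starved of significant genes.

Dispersion is a constant alpha = 0.2 (typical bulk RNA-seq); counts are NB
draws. Gene models go on one chromosome with a configurable 5% of unplanted
lncRNAs placed to overlap a coding gene or pseudogene on the same strand.
Peak sets drop one peak per window with probability 0.9 (planted-enriched
TFs over planted genes) or 0.1 (background). Survival cohorts draw
exponential event times whose hazard multiplies `hr_expression` for the top
expression quartile, with categorical covariate effects and a Gleason-
scaled baseline; censoring is independent with the exact requested marginal
probability. All generators are bit-reproducible from the config seed via
independent child streams.

What the generator does *not* emulate — and hence what passing tests cannot
show about real data: isoform structure, GC/length biases, zero inflation
beyond NB, correlated TF binding, admixture fractions varying by sample,
informative censoring, and real LNCipedia/Ensembl annotation geometry.

## Problem sizes and numerical choices

The validation suite runs the full screen at the default cohort scale
(2,500 genes x ~136 samples, seconds per run), null DE calibration at 2,000
genes and 10 vs 10, the exact Fisher sweep over all 2x2 tables with N <= 60,
1,000 random overlap fixtures, and 100 Cox replicates at n = 1,000 — sizes
chosen so the whole suite completes in a couple of minutes while leaving
Monte-Carlo error well inside the asserted bands. Newton fits run 50
iterations with step clipping at ±5 log units and converge in far fewer;
ties, zeros and degenerate groups are handled as described per module.

## Known limitations

Stage-1 sensitivity at the default scale is limited by the seven primary
samples and unit-SD patient effects: individual planted genes occasionally
miss the relaxed stage-1 cutoff (measured sensitivity across seeds ~0.93-1.0
with the planted |LFC| = 3). The per-gene MoM dispersion is noisy at small
group sizes; the t reference compensates for calibration but not power. The
screen tests lncRNAs one comparison at a time and has no multi-factor
design, continuous covariates, or outlier filtering.
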