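# Methods

## The analysis

`stromasig` operationalizes a prognostic-signature workflow for gastric
cancer built on one biological premise: the fraction of stromal
(fibroblast-rich) tissue in a tumor is a latent axis that simultaneously
drives a block of co-expressed genes and the patient's hazard of death.

**Discovery.** Each gene's log-scale expression enters a univariate Cox
proportional-hazards model per discovery cohort, fit by Newton–Raphson on
the partial likelihood with the Efron tie correction (50 iterations
maximum, step-halving, tolerance 1e-9 on the log-partial-likelihood
change; Breslow available). Expression is *not* standardized before the
screen, so hazard ratios are per log2-expression unit. Genes are ranked by
two-sided Wald p-value within each cohort (rank 1 = smallest; ties receive
the average rank), the two ranks are summed, genes whose hazard ratio
falls on opposite sides of 1 in the two cohorts are excluded, and the k
genes with the smallest rank sum form the signature. Rank-sum ties break
by the smaller minimum single-cohort p-value, then lexicographic gene id.
The concordance filter is applied after ranking over the full screen; the
selection depends on p-value ranks only and is therefore invariant to any
monotone transformation of the p-values, and symmetric in the two cohorts.

**Classification.** Signature rows are standardized per gene to mean 0 and
sample (n−1) SD; samples are clustered by complete-linkage agglomeration
on Euclidean distances (scipy). Cutting the tree into its two (or three)
major branches — removing the one (two) highest merges — and ordering
branches by mean standardized signature expression yields SU (highest),
SD (lowest), and SI (middle, three-way cut). This formalizes as an
explicit rule what is usually read off a clustered heatmap: the branches
separate tumors with concerted high vs low signature expression. EMT
status uses mean standardized epithelial (sE) and mesenchymal (sM) marker
scores: E if sE > t and sM < −t, M for the mirror image, otherwise I
(t = 0 by default, an explicit operationalization of reading the two
major marker branches). The stromal score is a single-sample rank
statistic: walking a sample's genes from highest to lowest expression, an
in-set running fraction weighted by (within-sample rank)^0.25 minus a
uniform out-of-set running fraction, summed over all positions and
divided by the gene count. It depends only on within-sample ranks, so any
strictly increasing per-sample transform leaves it unchanged. The score's
median defines ST-H (strictly above) vs ST-L.

**Survival statistics.** Kaplan–Meier estimation and the log-rank test are
delegated to lifelines behind the module interface; Cox fits (univariate
and multivariate, categorical covariates expanded against an explicit
reference level) use the package's own engine so the screen and the
downstream models share one implementation. The median survival
convention is the smallest time with S(t) ≤ 0.5; a curve that never
reaches 0.5 has an undefined median ("longer than follow-up", reported
as infinity). The multiple-cutoff log-rank scan dichotomizes a numeric
score at each grid quantile (default: percentiles 10–90 in steps of 5),
reporting the log-rank p and univariate Cox HR per cutoff; cutoffs
leaving a group under 10% of samples are flagged and skipped. The scan is
exploratory and applies no multiplicity correction.

**Wet-lab formulas.** Primer efficiency is (10^(−1/slope) − 1) × 100 from
an ordinary least-squares fit of mean Ct on log10 concentration over a
two-fold dilution series, with a 90–110% acceptance window. ΔΔCt
normalizes the target Ct by the arithmetic mean of the reference-gene Cts
(the log2 of the geometric mean of reference quantities — GAPDH and B2M
by default) and then by one explicitly named reference tumor sample,
whose relative quantity is exactly 1; RQ = 2^(−ΔΔCt). The simplified
H-score is percentage of positive cells × intensity (0–3), range 0–300;
the five-protein sum is split at its median with at-median samples
assigned "low" so "high" strictly exceeds the median. MMR status: any of
MLH1/PMS2/MSH2/MSH6 lost → dMMR; all present → pMMR; otherwise (an
equivocal stain, or an explicit override) → eqMMR.

## The synthetic generator

`SimConfig` encodes the study conditions; `generate_cohort` draws, from a
single seeded stream in fixed order (bit-for-bit reproducible):

- a latent stromal fraction sᵢ ∈ [0, 1] per tumor from an equal-weight
  two-component Beta mixture, Beta(3, 17) and Beta(17, 3) (modes ≈ 0.15
  and 0.85). The mixture emulates the empirically bimodal structure of
  stromal-signature expression — clustered heatmaps of real cohorts show
  two clearly separated blocks, not a continuum — and it is what makes a
  two-branch dendrogram cut a meaningful classifier. A unimodal fraction
  is available via config (set the mixing weight to 0), but with a
  unimodal latent axis the per-gene survival signal at the default effect
  sizes is too weak for any top-20 screen to find, and a median split of
  a unimodal axis is not a natural two-class truth.
- gene expression: per-gene baseline ~ N(7, 1) (log2-intensity scale)
  plus N(0, noise_sd²) noise; the 20 stromal genes add
  `expression_loading`·sᵢ (default 2 log2 units per unit fraction);
  mesenchymal/epithelial markers add ±`marker_loading`·sᵢ (default 0.5 —
  markers track the stromal axis more weakly than the dedicated stromal
  block, so they inform EMT calls without dominating the prognostic
  screen; EMT-recovery checks raise it explicitly).
- survival: time-to-event from a Weibull model (shape 1 = exponential
  default) with hazard `baseline_hazard`·exp(`stromal_effect`·sᵢ)
  (defaults 0.02 events/month and log-HR 1.5 per unit fraction — a
  median survival of a few years in the stroma-poor stratum and an
  SU-vs-SD hazard ratio near the 2–3 range reported for real cohorts),
  censored by an independent Uniform(0, 120] months draw (~10-year
  follow-up; roughly 20–25% censoring at the defaults).

Which gene slots carry the stromal/marker roles is a property of the
simulated gene panel, drawn from a separate `gene_role_seed`: cohorts
generated with different `seed` but one `gene_role_seed` share planted
gene identities, as two patient cohorts profiled on one platform would —
without this, cross-cohort rank-sum discovery would have nothing to
aggregate.

Companion generators produce primer dilution series (Ct from the inverse
efficiency formula plus optional noise), Ct tables derived from cohort
expression (Ct falls one cycle per expression doubling; constant-quantity
reference genes), and IHC tables (percentages, intensities, MMR flags
with ~15% dMMR tumors).

**What the generator does not emulate:** probe-level microarray artifacts,
batch effects, platform differences, non-proportional hazards, correlated
censoring, immune infiltration as a second axis, and count-level
single-cell structure. Passing tests therefore demonstrate that the
pipeline recovers the structure it assumes when that structure is present
— not that real cohorts satisfy those assumptions.

## Numerical choices and degenerate inputs

- Log base 2 wherever a log scale is unspecified; quantile normalization
  averages per-rank sorted values with ties receiving the mean of the
  quantile values they span, and is idempotent to 1e-12.
- The low-count filter keeps genes whose zero fraction is strictly below
  the threshold (default 0.90); median-of-ratios size factors use only
  genes nonzero in every sample and the linear-scale median.
- Duplicate probesets collapse to the symbol with the highest mean
  expression; genes with any missing value are excluded from clustering
  and screening; constant genes are dropped with a warning.
- Cox: non-converged or diverging (|β| > 15, separation-like) genes are
  flagged and excluded from the screen, never silent NaN; multivariate
  fits raise on rank-deficient designs naming the collinear columns.
- Dendrogram cuts use scipy's `cut_tree`, equivalent to removing the
  n_groups − 1 highest merges; a resulting group smaller than 2 warns but
  still labels. Sample-order invariance holds for tie-free data.
- The stromal-score walk breaks within-sample rank ties by gene position
  for determinism; all-equal scores label every sample ST-L with a
  warning.

## Scale of the shipped checks

The test suite and acceptance script measure recovery at the conditions
above: 20 discovery-cohort pairs (n = 300, 2,000 genes each), five
held-out cohorts for classifier fidelity, 100 effect-free cohorts
(n = 200, 45 genes) for null calibration of the subtype log-rank test,
and small fixtures for the brute-force oracle comparisons. These sizes
were chosen as the smallest at which the binomial/KS checks have useful
power; everything regenerates from code at run time.

## Known limitations

- The published signature's 20th probeset is not in the shipped default
  list (only the 19 named genes are); users may supply the full panel.
- The stromal score is an enrichment statistic on an arbitrary unitless
  scale; only its within-cohort ordering (and median split) is meaningful,
  and the ESTIMATE stromal gene list must be supplied by the user.
- The multiple-cutoff scan inherits the exploratory character of such
  graphs: its minimum p-value is optimistically biased and should not be
  reported as a single hypothesis test.
- Real-cohort reproduction of published hazard ratios and medians
  requires the original GEO/TCGA matrices, which this package reads
  (tab-delimited and series-matrix dialects) but does not download.
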