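# stromasig

Stromal prognostic-signature discovery and tumor subtyping for gastric-cancer
expression cohorts.

Gastric tumors with a stroma-rich, mesenchymal phenotype carry a markedly
worse prognosis. `stromasig` implements the full analysis pipeline that
identifies and exploits this axis from bulk transcriptomic cohorts with
matched survival data:

- **Signature discovery** — per-gene univariate Cox proportional-hazards
  screening in two discovery cohorts, p-value ranking, cross-cohort
  **rank-sum** aggregation, hazard-direction concordance filtering, and
  top-*k* selection (default 20 genes). The 19 named genes of the published
  gastric-cancer stromal signature (ACTA2, CALD1, HEYL, TAGLN, TPM2, …)
  ship as a default list.
- **Subtype classification** — per-gene standardization
  (x − mean)/SD, hierarchical clustering (Euclidean distance, complete
  linkage), and a two- or three-branch cut ordered by mean standardized
  signature expression: **Stromal-UP (SU)** / **Stromal-DOWN (SD)** (/
  **SI**). Also E/I/M epithelial–mesenchymal calls from marker scores and
  an ssGSEA-style rank-based **stromal score** with a median ST-H/ST-L
  split.
- **Survival statistics** — Kaplan–Meier curves and medians, log-rank
  tests, univariate/multivariate Cox models (own Newton–Raphson partial
  likelihood engine, Efron ties), and a multiple-cutoff log-rank scan.
- **Wet-lab quantification** — qPCR primer efficiency
  ((10^(−1/slope) − 1) × 100), ΔΔCt relative quantification against the
  geometric mean of reference genes, simplified IHC H-scores
  (% positive × intensity 0–3) with a five-protein summed median split,
  and MMR status calls (dMMR/pMMR/eqMMR).
- **Synthetic cohorts** — a generator that plants a latent per-sample
  stromal fraction driving both a correlated stromal gene block and a
  proportional-hazards survival link, so the entire pipeline is testable
  end-to-end without downloads.

The model at the core: for gene *g* with log expression *x*, the screen
fits the hazard λ(t) = λ₀(t)·exp(β·x) per cohort and ranks genes by the
Wald p-value of β̂; the rank sum over the two cohorts is the selection
criterion, with HR = e^β > 1 read as a poor-prognosis association.

## Worked example

```python
from stromasig import SimConfig, generate_cohort, classify_su_sd
from stromasig.discovery import discover

a = generate_cohort(SimConfig(seed=1))   # 2,000 genes x 300 tumors
b = generate_cohort(SimConfig(seed=2))
signature = discover(a.cohort, b.cohort, endpoint="os", k=20)
len(set(signature.genes) & set(a.truth.stromal_genes))   # 19 of 20 planted
```

Running `python examples/04_survival_analysis.py` prints:

```
SU (n=125): median survival 9.0 months
SD (n=175): median survival 30.8 months
log-rank chi-square 52.49 (df=1), p = 4.3e-13
SU vs SD hazard ratio 2.70, Wald p = 2.4e-12
cutoff scan: smallest p 5.1e-12 at the 65% score percentile (HR 2.58)
```

The SU group — tumors over-expressing the stromal signature in concert —
has a far shorter median survival and a hazard ratio near the planted
effect; the cutoff scan shows the split is not knife-edge dependent on
the median. Each script in `examples/` demonstrates one capability
(simulation, discovery, classification, survival, wet-lab formulas) and
ends with a line on what the numbers mean.

A thin CLI wraps the same library calls:

```bash
stromasig simulate --seed 1 --out cohA
stromasig discover --cohort-a cohA --cohort-b cohB --k 20 --out signature.tsv
stromasig classify --cohort cohA --signature signature.tsv --out labels.tsv
stromasig survive --labels labels.tsv --clinical cohA/clinical.tsv --out results.json
```

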