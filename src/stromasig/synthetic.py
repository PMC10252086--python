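"""Synthetic cohorts with planted stromal/prognostic structure.

The generator emulates the statistical skeleton of a bulk gastric-cancer
expression cohort: each tumor carries a latent stromal fraction s ∈ [0, 1]
drawn from a two-component Beta mixture — a stroma-poor mode near 0.15
and a stroma-rich mode near 0.85 — reproducing the two clearly separated
expression blocks that stromal-signature heatmaps show; a block of
"stromal" genes whose log expression shifts by ``expression_loading``·s;
mesenchymal markers sharing that loading sign and epithelial markers the
opposite sign; all other genes pure noise; and survival times from a
proportional-hazards model whose log hazard increases by
``stromal_effect``·s over baseline, with independent uniform censoring.
Companion generators produce qPCR dilution series, Ct tables derived from
cohort expression, and IHC score tables.

All draws come from one ``numpy`` Generator seeded once, consumed in a
fixed order, so a (config, seed) pair reproduces its cohort bit-for-bit
and no sub-table can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Cohort, write_clinical, write_expression
from .wetlab import IHCRecord, MMR_PROTEINS, IHC_PANEL, CtTable, PrimerDilutionSeries


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults are the conditions the discovery analysis assumes: 300 tumors,
    2,000 genes with 20 planted stromal genes, a log-hazard ratio of 1.5
    per unit stromal fraction, an expression loading of 2 log2 units
    against unit noise, a baseline hazard of 0.02 events/month (median
    survival of a few years in the low-stroma stratum) and a 120-month
    follow-up window.
    """

    n_samples: int = 300
    n_genes: int = 2000
    n_stromal_genes: int = 20
    n_epithelial_markers: int = 10
    n_mesenchymal_markers: int = 10
    stromal_effect: float = 1.5        # log-HR per unit stromal fraction
    expression_loading: float = 2.0    # log2-expression shift per unit fraction
    #: loading of the epithelial/mesenchymal marker blocks; markers track
    #: the stromal axis more weakly than the dedicated stromal block, so
    #: they inform EMT calls without dominating the prognostic screen
    marker_loading: float = 0.5
    noise_sd: float = 1.0              # log2-expression units
    baseline_hazard: float = 0.02      # events per month
    censor_horizon: float = 120.0      # months
    weibull_shape: float = 1.0         # 1.0 = exponential survival
    #: Beta parameters of the stroma-poor and stroma-rich components and
    #: the stroma-rich mixing weight. Weight 0 collapses to a single Beta.
    stromal_low_beta: tuple[float, float] = (3.0, 17.0)
    stromal_high_beta: tuple[float, float] = (17.0, 3.0)
    stromal_high_weight: float = 0.5
    seed: int = 0
    #: Which genes are stromal/markers is a property of the simulated gene
    #: panel, not of one cohort draw: cohorts generated with different
    #: ``seed`` but the same ``gene_role_seed`` share planted gene
    #: identities, as two patient cohorts profiled on one platform would.
    gene_role_seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_samples": self.n_samples, "n_genes": self.n_genes,
            "n_stromal_genes": self.n_stromal_genes,
            "n_epithelial_markers": self.n_epithelial_markers,
            "n_mesenchymal_markers": self.n_mesenchymal_markers,
        }
        for name, v in counts.items():
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
        reserved = (self.n_stromal_genes + self.n_epithelial_markers
                    + self.n_mesenchymal_markers)
        if reserved > self.n_genes:
            raise ValueError(
                f"stromal genes + markers ({reserved}) exceed n_genes "
                f"({self.n_genes})"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.censor_horizon <= 0:
            raise ValueError("censor_horizon must be > 0")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.weibull_shape <= 0:
            raise ValueError("weibull_shape must be > 0")
        if not 0.0 <= self.stromal_high_weight <= 1.0:
            raise ValueError("stromal_high_weight must lie in [0, 1]")


@dataclass
class CohortTruth:
    """Ground truth planted into a synthetic cohort."""

    stromal_fraction: pd.Series           # per sample, in [0, 1]
    stromal_genes: list[str]
    epithelial_markers: list[str]
    mesenchymal_markers: list[str]


@dataclass
class SyntheticCohort:
    expression: pd.DataFrame
    clinical: pd.DataFrame
    truth: CohortTruth
    config: SimConfig = field(repr=False, default=None)

    @property
    def cohort(self) -> Cohort:
        return Cohort(expression=self.expression, clinical=self.clinical,
                      name=f"synthetic_seed{self.config.seed}"
                      if self.config else "synthetic")


BASELINE_MEAN = 7.0   # typical log2 microarray intensity
BASELINE_SD = 1.0     # between-gene spread of baselines


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Draw one cohort under the proportional-hazards stromal model."""
    rng = np.random.default_rng(config.seed)
    n, g = config.n_samples, config.n_genes

    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    gene_ids = [f"G{j + 1:05d}" for j in range(g)]

    # latent stromal fraction: stroma-poor vs stroma-rich tumor mixture
    rich = rng.uniform(size=n) < config.stromal_high_weight
    lo = rng.beta(*config.stromal_low_beta, size=n)
    hi = rng.beta(*config.stromal_high_beta, size=n)
    s = np.where(rich, hi, lo)

    # planted roles: disjoint random slots, fixed by gene_role_seed so that
    # independently drawn cohorts share one planted panel
    roles = np.random.default_rng(config.gene_role_seed).permutation(g)
    k_s = config.n_stromal_genes
    k_e = config.n_epithelial_markers
    k_m = config.n_mesenchymal_markers
    stromal_idx = roles[:k_s]
    epi_idx = roles[k_s:k_s + k_e]
    mes_idx = roles[k_s + k_e:k_s + k_e + k_m]

    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=g)
    expr = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(g, n))
    expr[stromal_idx] += config.expression_loading * s[None, :]
    expr[mes_idx] += config.marker_loading * s[None, :]
    expr[epi_idx] -= config.marker_loading * s[None, :]

    # survival: hazard = baseline_hazard * exp(stromal_effect * s),
    # Weibull(shape) time via inverse transform; shape 1 = exponential
    rate = config.baseline_hazard * np.exp(config.stromal_effect * s)
    u = rng.uniform(size=n)
    t_event = (-np.log(u) / rate) ** (1.0 / config.weibull_shape)
    c = rng.uniform(0.0, config.censor_horizon, size=n)
    c = np.nextafter(c, np.inf)  # censoring on (0, horizon]
    os_time = np.minimum(t_event, c)
    os_event = (t_event <= c).astype(int)

    expression = pd.DataFrame(expr, index=gene_ids, columns=sample_ids)
    expression.index.name = "gene_id"
    clinical = pd.DataFrame(
        {"os_time": os_time, "os_event": os_event},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = CohortTruth(
        stromal_fraction=pd.Series(s, index=sample_ids, name="stromal_fraction"),
        stromal_genes=[gene_ids[j] for j in np.sort(stromal_idx)],
        epithelial_markers=[gene_ids[j] for j in np.sort(epi_idx)],
        mesenchymal_markers=[gene_ids[j] for j in np.sort(mes_idx)],
    )
    return SyntheticCohort(expression=expression, clinical=clinical,
                           truth=truth, config=config)


def write_cohort(cohort: SyntheticCohort, directory) -> None:
    """Write expression/clinical in the formats cohort_io reads, plus truth."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_expression(cohort.expression, directory / "expression.tsv")
    write_clinical(cohort.clinical, directory / "clinical.tsv")
    truth = pd.DataFrame({
        "stromal_fraction": cohort.truth.stromal_fraction,
        "is_stromal_gene_target": "",
    })
    truth[["stromal_fraction"]].to_csv(directory / "truth_samples.tsv", sep="\t")
    genes = pd.DataFrame({
        "gene_id": (cohort.truth.stromal_genes
                    + cohort.truth.epithelial_markers
                    + cohort.truth.mesenchymal_markers),
        "role": (["stromal"] * len(cohort.truth.stromal_genes)
                 + ["epithelial_marker"] * len(cohort.truth.epithelial_markers)
                 + ["mesenchymal_marker"] * len(cohort.truth.mesenchymal_markers)),
    })
    genes.to_csv(directory / "truth_genes.tsv", sep="\t", index=False)


def generate_dilution_series(true_efficiency: float, n_points: int = 5,
                             seed: int = 0, noise_sd: float = 0.0,
                             primer_id: str = "primer") -> PrimerDilutionSeries:
    """Standard-curve Ct values for a primer of known efficiency.

    Dilution steps are two-fold (1:2, 1:4, … as used on a pooled cDNA
    standard curve). Mean Ct follows the inverse of the efficiency formula:
    slope = −1/log10(1 + E/100) on a log10-concentration axis, plus
    optional Gaussian noise.
    """
    if not 50.0 < true_efficiency <= 150.0:
        raise ValueError("true_efficiency must be in (50, 150] percent")
    if n_points < 3:
        raise ValueError("need at least 3 dilution points for the regression")
    rng = np.random.default_rng(seed)
    conc = 0.5 ** np.arange(1, n_points + 1)   # 1/2, 1/4, 1/8, ...
    slope = -1.0 / np.log10(1.0 + true_efficiency / 100.0)
    intercept = 20.0
    ct = intercept + slope * np.log10(conc)
    if noise_sd > 0:
        ct = ct + rng.normal(0.0, noise_sd, size=n_points)
    return PrimerDilutionSeries(concentrations=conc, mean_ct=ct,
                                primer_id=primer_id)


def generate_ct_table(cohort: SyntheticCohort, targets: list[str],
                      reference_sample: str | None = None,
                      noise_sd: float = 0.1, seed: int = 0) -> CtTable:
    """Derive a qPCR Ct table from a cohort's (log2) expression values.

    Ct falls one cycle per doubling of transcript: Ct = offset − log2
    expression value, plus technical noise. Reference genes (GAPDH, B2M)
    are constant-quantity housekeepers.
    """
    rng = np.random.default_rng(seed)
    missing = [t for t in targets if t not in cohort.expression.index]
    if missing:
        raise ValueError(f"targets not in cohort expression: {missing}")
    samples = list(cohort.expression.columns)
    offset = 35.0
    data = {}
    for t in targets:
        data[t] = offset - cohort.expression.loc[t].to_numpy() \
            + rng.normal(0.0, noise_sd, size=len(samples))
    for ref in ("GAPDH", "B2M"):
        data[ref] = 18.0 + rng.normal(0.0, noise_sd, size=len(samples))
    values = pd.DataFrame(data, index=pd.Index(samples, name="sample_id"))
    return CtTable(values=values, reference_genes=("GAPDH", "B2M"),
                   reference_sample=reference_sample or samples[0])


def generate_ihc_table(n: int, seed: int = 0,
                       force_percentage: float | None = None,
                       force_intensity: int | None = None) -> list[IHCRecord]:
    """Random IHC score table for the five-protein panel plus MMR flags.

    Percentages lie in [0, 100], intensities in {0, 1, 2, 3}; MMR proteins
    are mostly present with occasional loss (dMMR tumors) or equivocal
    stains. ``force_percentage``/``force_intensity`` pin every stain for
    boundary-case testing.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    compartments = ("neoplastic", "stromal", "inflammatory")
    for i in range(n):
        stains = {}
        for protein in IHC_PANEL:
            for comp in compartments:
                pct = (force_percentage if force_percentage is not None
                       else float(np.round(rng.uniform(0, 100), 0)))
                inten = (force_intensity if force_intensity is not None
                         else int(rng.integers(0, 4)))
                stains[(protein, comp)] = (pct, inten)
        mmr = {}
        for protein in MMR_PROTEINS:
            r = rng.uniform()
            # ~15% dMMR tumors overall, occasional equivocal stains
            mmr[protein] = ("lost" if r < 0.04
                            else "equivocal" if r < 0.065 else "present")
        tumor_pct = float(np.round(rng.uniform(20, 90), 0))
        stroma_pct = float(np.round(rng.uniform(0, 100 - tumor_pct), 0))
        records.append(IHCRecord(
            sample_id=f"T{i + 1:03d}", stains=stains, mmr=mmr,
            tumor_pct=tumor_pct, stroma_pct=stroma_pct,
        ))
    return records
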