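"""Ex-vivo quantification: qPCR efficiency and ΔΔCt, IHC H-scores, MMR calls.

The formulas here mirror routine molecular-pathology practice: primer
efficiency from a standard-curve regression of mean Ct on log10
concentration; relative quantification by the ΔΔCt method against the
geometric mean of two reference genes (GAPDH, B2M) and one explicitly
chosen reference tumor sample; a simplified H-score (percentage of positive
cells × intensity 0–3, range 0–300) summed over a five-protein panel with a
median split; and mismatch-repair status from the four canonical MMR
proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MMR_PROTEINS = ("MLH1", "PMS2", "MSH2", "MSH6")
IHC_PANEL = ("HEYL", "ACTA2", "TPM2", "CALD1", "TAGLN")
EFFICIENCY_WINDOW = (90.0, 110.0)


@dataclass
class PrimerDilutionSeries:
    """Standard-curve data: mean Ct at each dilution of a cDNA pool."""

    concentrations: np.ndarray   # relative concentrations, e.g. 1/2 … 1/32
    mean_ct: np.ndarray          # cycles
    primer_id: str = "primer"

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.mean_ct = np.asarray(self.mean_ct, dtype=float)
        if len(self.concentrations) != len(self.mean_ct):
            raise ValueError("concentrations and Ct vectors differ in length")
        if len(self.concentrations) < 3:
            raise ValueError("a standard curve needs at least 3 dilution points")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")


@dataclass
class EfficiencyResult:
    efficiency: float       # percent
    slope: float            # cycles per log10 concentration
    r_squared: float
    passes: bool            # inside the 90–110% acceptance window


def primer_efficiency(series: PrimerDilutionSeries) -> EfficiencyResult:
    """Amplification efficiency (%) from the standard-curve slope.

    Ordinary least squares of mean Ct on log10(concentration); efficiency
    = (10^(−1/slope) − 1) × 100. A perfect doubling chemistry has slope
    −1/log10(2) ≈ −3.32 and efficiency 100%.
    """
    x = np.log10(series.concentrations)
    fit = stats.linregress(x, series.mean_ct)
    if not np.isfinite(fit.slope) or abs(fit.slope) < 1e-12:
        raise ValueError("degenerate standard curve: zero/undefined slope")
    eff = (10.0 ** (-1.0 / fit.slope) - 1.0) * 100.0
    lo, hi = EFFICIENCY_WINDOW
    return EfficiencyResult(efficiency=float(eff), slope=float(fit.slope),
                            r_squared=float(fit.rvalue ** 2),
                            passes=bool(lo <= eff <= hi))


@dataclass
class CtTable:
    """qPCR cycle-threshold values, samples × targets.

    ``values`` must contain a column per reference gene for every sample;
    ``reference_sample`` is the tumor sample all RQs are expressed against.
    """

    values: pd.DataFrame
    reference_genes: tuple[str, ...] = ("GAPDH", "B2M")
    reference_sample: str = ""

    def __post_init__(self) -> None:
        if not self.reference_sample:
            raise ValueError(
                "a reference sample must be named explicitly for ΔΔCt"
            )
        if self.reference_sample not in self.values.index:
            raise ValueError(
                f"reference sample {self.reference_sample!r} not in table"
            )
        missing = [g for g in self.reference_genes
                   if g not in self.values.columns]
        if missing:
            raise ValueError(f"reference genes missing from table: {missing}")
        if (self.values <= 0).any().any():
            raise ValueError("Ct values must be positive cycles")


def delta_delta_ct(table: CtTable, target: str) -> pd.Series:
    """Relative quantity of ``target`` per sample by the ΔΔCt method.

    ΔCt = Ct_target − mean(reference Cts); the arithmetic mean of reference
    Cts is the log2 of the geometric mean of reference quantities.
    ΔΔCt = ΔCt_sample − ΔCt_reference-sample; RQ = 2^(−ΔΔCt). The reference
    sample's RQ is exactly 1.
    """
    if target not in table.values.columns:
        raise ValueError(f"target {target!r} not in Ct table")
    ref_ct = table.values[list(table.reference_genes)]
    bad = ref_ct.isna().any(axis=1)
    if bad.any():
        raise ValueError(
            f"missing reference Ct for sample(s) {list(table.values.index[bad])}"
        )
    d_ct = table.values[target] - ref_ct.mean(axis=1)
    dd_ct = d_ct - d_ct.loc[table.reference_sample]
    rq = np.power(2.0, -dd_ct)
    rq.name = f"RQ_{target}"
    return rq


def h_score(percentage: float, intensity: int) -> float:
    """Simplified H-score: % positive cells × intensity (0–3), range 0–300."""
    if not 0 <= percentage <= 100:
        raise ValueError(f"percentage {percentage} outside [0, 100]")
    if intensity not in (0, 1, 2, 3):
        raise ValueError(f"intensity {intensity} not in {{0,1,2,3}}")
    return float(percentage) * int(intensity)


@dataclass
class IHCRecord:
    """One tumor core's immunohistochemistry read-out.

    ``stains`` maps (protein, compartment) to (percentage positive,
    intensity); compartments are 'neoplastic', 'stromal', 'inflammatory'.
    ``mmr`` maps each MMR protein to 'present' | 'lost' | 'equivocal'.
    """

    sample_id: str
    stains: dict = field(default_factory=dict)
    mmr: dict = field(default_factory=dict)
    tumor_pct: float = np.nan
    stroma_pct: float = np.nan
    mmr_equivocal_override: bool = False

    def __post_init__(self) -> None:
        for (protein, compartment), (pct, inten) in self.stains.items():
            h_score(pct, inten)  # range validation
        if (np.isfinite(self.tumor_pct) and np.isfinite(self.stroma_pct)
                and self.tumor_pct + self.stroma_pct > 100 + 1e-9):
            raise ValueError(
                f"{self.sample_id}: tumor% + stroma% exceeds 100"
            )


def summed_h_score(records: list[IHCRecord],
                   proteins: tuple[str, ...] = IHC_PANEL,
                   compartment: str = "stromal") -> pd.DataFrame:
    """Per-sample sum of H-scores over the panel, with a median-split label.

    Samples strictly above the median sum are 'high'; at or below, 'low'.
    """
    rows = {}
    for rec in records:
        total = 0.0
        for protein in proteins:
            key = (protein, compartment)
            if key not in rec.stains:
                raise ValueError(
                    f"{rec.sample_id}: no {compartment} stain for {protein}"
                )
            pct, inten = rec.stains[key]
            total += h_score(pct, inten)
        rows[rec.sample_id] = total
    sums = pd.Series(rows, name="summed_h_score")
    med = sums.median()
    labels = pd.Series(np.where(sums > med, "high", "low"), index=sums.index,
                       name="label")
    return pd.DataFrame({"summed_h_score": sums, "label": labels})


def mmr_status(flags: dict, equivocal_override: bool = False) -> str:
    """MMR status from per-protein expression flags.

    Any protein lost → 'dMMR'; all four present → 'pMMR'; otherwise (an
    equivocal stain with nothing lost, or an explicit override) → 'eqMMR'.
    """
    missing = [p for p in MMR_PROTEINS if p not in flags]
    if missing:
        raise ValueError(f"missing MMR flags for {missing}")
    vals = [flags[p] for p in MMR_PROTEINS]
    bad = [v for v in vals if v not in ("present", "lost", "equivocal")]
    if bad:
        raise ValueError(f"invalid MMR flag value(s) {bad}")
    if any(v == "lost" for v in vals):
        return "dMMR"
    if equivocal_override or any(v == "equivocal" for v in vals):
        return "eqMMR"
    return "pMMR"


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need equal-length vectors with at least 4 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
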