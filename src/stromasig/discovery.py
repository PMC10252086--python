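"""Prognostic signature discovery by cross-cohort rank-sum aggregation.

The selection procedure: fit a univariate Cox proportional-hazards model
(expression on the log scale, untransformed) per gene in each of two
discovery cohorts; rank genes within each cohort by Wald p-value (rank 1 =
smallest, ties averaged); sum the two ranks; drop genes whose hazard-ratio
direction disagrees between cohorts; and take the k genes (default 20)
with the smallest rank sum. Genes whose expression is associated with
shorter survival in both cohorts carry HR > 1 ("poor" direction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._coxph import cox_univariate_screen
from .io import Cohort

logger = logging.getLogger(__name__)

#: The 19 named genes of the published gastric-cancer stromal signature.
#: Strongly enriched for cancer-associated-fibroblast / extracellular-matrix
#: biology. A user-supplied list (e.g. the full 20-probeset panel) may be
#: substituted anywhere a signature is accepted.
DEFAULT_SIGNATURE_GENES = (
    "ACTA2", "CALD1", "HEYL", "TAGLN", "TPM2", "IGFBP7", "TUBB6", "LAMC1",
    "RAI14", "ITGB5", "MXRA7", "AKAP12", "MATN3", "LAYN", "TGFB2", "LOXL4",
    "RASSF8", "NALCN", "NREP",
)


def cox_screen(cohort: Cohort, endpoint: str = "os",
               ties: str = "efron") -> pd.DataFrame:
    """Univariate Cox screen of every gene against a survival endpoint.

    Returns a DataFrame indexed by gene_id with columns ``hazard_ratio``,
    ``cox_p`` (two-sided Wald) and ``log_hr``. Constant genes are skipped
    with a warning; non-converged genes are excluded, never silent NaN.
    """
    endpoint = endpoint.lower()
    if endpoint not in ("os", "dfs"):
        raise ValueError("endpoint must be 'os' or 'dfs'")
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    if tcol not in cohort.clinical.columns or ecol not in cohort.clinical.columns:
        raise ValueError(f"cohort lacks {tcol}/{ecol} columns")
    times = cohort.clinical[tcol].to_numpy(dtype=float)
    events = cohort.clinical[ecol].to_numpy(dtype=float)
    if events.sum() < 2:
        raise ValueError("need at least 2 events to screen")

    expr = cohort.expression
    complete = expr.notna().all(axis=1)
    if not complete.all():
        logger.warning("excluding %d genes with missing values",
                       int((~complete).sum()))
        expr = expr.loc[complete]
    X = expr.to_numpy(dtype=float).T          # samples × genes
    nonconst = X.std(axis=0) > 0
    if not nonconst.all():
        logger.warning("skipping %d constant genes", int((~nonconst).sum()))
    gene_ids = expr.index[nonconst]
    res = cox_univariate_screen(X[:, nonconst], times, events, ties=ties)
    ok = res["converged"]
    if not ok.all():
        logger.warning("excluding %d non-converged genes: %s",
                       int((~ok).sum()), list(gene_ids[~ok])[:10])
    out = pd.DataFrame(
        {
            "log_hr": res["coef"][ok],
            "hazard_ratio": np.exp(res["coef"][ok]),
            "cox_p": res["p"][ok],
        },
        index=gene_ids[ok],
    )
    out.index.name = "gene_id"
    return out


def rank_by_p(screen: pd.DataFrame) -> pd.DataFrame:
    """Attach p-value ranks: rank 1 = smallest p, tied p-values averaged."""
    if screen.empty:
        raise ValueError("cannot rank an empty screen")
    out = screen.copy()
    out["rank"] = stats.rankdata(out["cox_p"].to_numpy(), method="average")
    return out


@dataclass
class Signature:
    """An ordered prognostic gene list with per-gene direction tags."""

    genes: list[str]
    direction: dict               # gene_id -> "poor" (HR>1) | "good" (HR<1)
    table: pd.DataFrame = None    # full selection ledger

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


def rank_sum_select(screen_a: pd.DataFrame, screen_b: pd.DataFrame,
                    k: int = 20) -> Signature:
    """Select the k genes with the smallest cross-cohort rank sum.

    Only genes screened in both cohorts are considered; genes whose hazard
    ratio falls on opposite sides of 1 in the two cohorts are excluded as
    discordant before selection. Ties on the rank sum are broken by the
    smaller minimum single-cohort p-value, then lexicographic gene id.
    """
    for df, which in ((screen_a, "A"), (screen_b, "B")):
        if "rank" not in df.columns:
            raise ValueError(f"screen {which} is unranked; call rank_by_p first")
    shared = screen_a.index.intersection(screen_b.index)
    merged = pd.DataFrame({
        "hr_a": screen_a.loc[shared, "hazard_ratio"],
        "p_a": screen_a.loc[shared, "cox_p"],
        "rank_a": screen_a.loc[shared, "rank"],
        "hr_b": screen_b.loc[shared, "hazard_ratio"],
        "p_b": screen_b.loc[shared, "cox_p"],
        "rank_b": screen_b.loc[shared, "rank"],
    })
    merged["rank_sum"] = merged["rank_a"] + merged["rank_b"]
    merged["concordant"] = (np.sign(np.log(merged["hr_a"]))
                            == np.sign(np.log(merged["hr_b"])))
    concordant = merged[merged["concordant"]].copy()
    if len(concordant) < k:
        raise ValueError(
            f"only {len(concordant)} concordant genes shared by both screens; "
            f"cannot select k={k} (achievable k={len(concordant)})"
        )
    concordant["min_p"] = concordant[["p_a", "p_b"]].min(axis=1)
    concordant["_gene"] = concordant.index
    chosen = concordant.sort_values(
        ["rank_sum", "min_p", "_gene"], kind="stable"
    ).head(k).drop(columns="_gene")
    direction = {
        g: ("poor" if chosen.loc[g, "hr_a"] > 1 else "good")
        for g in chosen.index
    }
    chosen = chosen.assign(
        direction=[direction[g] for g in chosen.index]
    )
    return Signature(genes=list(chosen.index), direction=direction,
                     table=chosen)


def discover(cohort_a: Cohort, cohort_b: Cohort, endpoint: str = "os",
             k: int = 20, ties: str = "efron") -> Signature:
    """End-to-end discovery: screen both cohorts, rank, and rank-sum select."""
    sa = rank_by_p(cox_screen(cohort_a, endpoint=endpoint, ties=ties))
    sb = rank_by_p(cox_screen(cohort_b, endpoint=endpoint, ties=ties))
    return rank_sum_select(sa, sb, k=k)
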