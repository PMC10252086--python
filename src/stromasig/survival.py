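"""Survival statistics: Kaplan–Meier, log-rank, Cox models, cutoff scans.

Kaplan–Meier estimation and the log-rank test are delegated to lifelines
behind this module's interface; Cox models run on the package's own
partial-likelihood engine (Newton–Raphson, Efron ties by default) so that
the per-gene screen and the multivariate fits share one implementation.
The median survival convention is the smallest time at which the survival
curve reaches 0.5 or below; if the curve never does, the median is
undefined (reported as ``inf`` — longer than follow-up).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from ._coxph import CoxModel, cox_newton


@dataclass
class KMCurve:
    """Product-limit survival estimate."""

    times: np.ndarray            # event-time grid (months)
    survival: np.ndarray         # S(t) at each grid time
    at_risk: np.ndarray          # number at risk entering each grid time
    median: float                # months; inf if never reaches 0.5

    @property
    def median_defined(self) -> bool:
        return np.isfinite(self.median)


def km_estimate(times, events) -> KMCurve:
    """Kaplan–Meier estimate with median survival."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if times.size == 0:
        raise ValueError("empty survival data")
    if np.any(times <= 0):
        raise ValueError("survival times must be > 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    grid = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(grid).to_numpy()
    at_risk = table["at_risk"].to_numpy()
    median = float(kmf.median_survival_time_)
    return KMCurve(times=grid, survival=surv, at_risk=at_risk, median=median)


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p: float


def logrank(groups: list[tuple]) -> LogRankResult:
    """Log-rank test across ≥2 groups of (times, events).

    Standard observed-minus-expected chi-square with hypergeometric
    variance; degrees of freedom = number of groups − 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    all_t, all_e, all_g = [], [], []
    for gid, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=float)
        if t.size == 0:
            raise ValueError(f"group {gid} has no observations")
        all_t.append(t)
        all_e.append(e)
        all_g.append(np.full(t.shape, gid))
    t = np.concatenate(all_t)
    e = np.concatenate(all_e)
    g = np.concatenate(all_g)
    if e.sum() < 1:
        raise ValueError("need at least one event overall")
    res = multivariate_logrank_test(t, g, e)
    return LogRankResult(statistic=float(res.test_statistic),
                         df=len(groups) - 1, p=float(res.p_value))


def logrank_by_label(labels: pd.Series, clinical: pd.DataFrame,
                     endpoint: str = "os") -> LogRankResult:
    """Log-rank test between label groups, aligned on shared samples."""
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    shared = labels.index.intersection(clinical.index)
    lab = labels.loc[shared]
    groups = [
        (clinical.loc[shared[lab == name], tcol].to_numpy(),
         clinical.loc[shared[lab == name], ecol].to_numpy())
        for name in sorted(lab.unique())
    ]
    return logrank(groups)


def cox_fit(covariates: pd.DataFrame, times, events, ties: str = "efron",
            reference_levels: dict | None = None) -> CoxModel:
    """Cox proportional-hazards fit with Wald tests per covariate.

    Categorical (string/categorical dtype) columns are expanded to
    indicator columns against a reference level — the explicitly supplied
    one, else the lexicographically first level. A rank-deficient design
    raises an error naming the collinear columns.
    """
    if covariates.empty:
        raise ValueError("no covariates")
    reference_levels = reference_levels or {}
    pieces, names = [], []
    for col in covariates.columns:
        series = covariates[col]
        if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
            levels = sorted(series.astype(str).unique())
            ref = str(reference_levels.get(col, levels[0]))
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} absent from {col!r}")
            for lev in levels:
                if lev == ref:
                    continue
                pieces.append((series.astype(str) == lev).astype(float).to_numpy())
                names.append(f"{col}[{lev} vs {ref}]")
        else:
            pieces.append(series.to_numpy(dtype=float))
            names.append(col)
    X = np.column_stack(pieces)
    if np.isnan(X).any():
        raise ValueError("covariates contain missing values")
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X]))
    if rank < X.shape[1] + 1:
        corr = np.corrcoef(X, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        pairs = [
            f"{names[i]} ~ {names[j]}"
            for i in range(len(names)) for j in range(i + 1, len(names))
            if abs(corr[i, j]) > 0.999
        ]
        const = [names[i] for i in range(X.shape[1]) if X[:, i].std() == 0]
        raise ValueError(
            "rank-deficient design; collinear/constant columns: "
            f"{pairs + const or names}"
        )
    return cox_newton(X, np.asarray(times, dtype=float),
                      np.asarray(events, dtype=float), ties=ties, names=names)


def cox_fit_by_label(labels: pd.Series, clinical: pd.DataFrame,
                     endpoint: str = "os", reference: str | None = None,
                     ties: str = "efron") -> CoxModel:
    """Univariate Cox HR of label groups (e.g. SU vs SD), reference = SD-like.

    ``reference`` defaults to the lexicographically first label.
    """
    shared = labels.index.intersection(clinical.index)
    cov = pd.DataFrame({"group": labels.loc[shared].astype(str)})
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    return cox_fit(cov, clinical.loc[shared, tcol],
                   clinical.loc[shared, ecol], ties=ties,
                   reference_levels={"group": reference} if reference else None)


@dataclass
class CutoffScanPoint:
    quantile: float
    cutoff: float
    p: float
    hazard_ratio: float
    n_high: int
    n_low: int
    skipped: bool = False


def multi_cutoff_logrank(score, times, events,
                         quantile_grid=None,
                         min_group_fraction: float = 0.10,
                         ties: str = "efron") -> list[CutoffScanPoint]:
    """Log-rank p and Cox HR for a grid of dichotomizing score cutoffs.

    Default grid: the 10th–90th percentiles in steps of 5. At each grid
    quantile the score is split at that cutoff (high = above); cutoffs
    leaving either group below ``min_group_fraction`` of the samples are
    flagged skipped, not computed. Exploratory: no multiplicity correction.
    """
    score = np.asarray(score, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if np.ptp(score) == 0:
        raise ValueError("constant score cannot be dichotomized")
    if quantile_grid is None:
        quantile_grid = np.arange(0.10, 0.901, 0.05)
    quantile_grid = np.asarray(quantile_grid, dtype=float)
    if np.any((quantile_grid <= 0) | (quantile_grid >= 1)):
        raise ValueError("quantile grid must lie strictly inside (0, 1)")
    n = len(score)
    out = []
    for q in quantile_grid:
        cut = float(np.quantile(score, q))
        high = score > cut
        n_high, n_low = int(high.sum()), int((~high).sum())
        if min(n_high, n_low) < min_group_fraction * n:
            out.append(CutoffScanPoint(quantile=float(q), cutoff=cut,
                                       p=np.nan, hazard_ratio=np.nan,
                                       n_high=n_high, n_low=n_low,
                                       skipped=True))
            continue
        lr = logrank([(times[~high], events[~high]),
                      (times[high], events[high])])
        model = cox_newton(high.astype(float), times, events, ties=ties)
        out.append(CutoffScanPoint(
            quantile=float(q), cutoff=cut, p=lr.p,
            hazard_ratio=float(np.exp(model.coef[0])),
            n_high=n_high, n_low=n_low,
        ))
    return out
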