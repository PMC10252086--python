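"""Reading, writing, normalizing and aligning expression cohorts.

Expression matrices are pandas DataFrames with gene identifiers as the
index and sample identifiers as columns, holding log-scale values.
Clinical tables are DataFrames indexed by sample identifier with at least
``os_time`` (months) and ``os_event`` (0/1) columns; ``dfs_time`` and
``dfs_event`` are optional, as are arbitrary covariate columns.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_CLINICAL_COLUMNS = ("os_time", "os_event")

_SERIES_MATRIX_BEGIN = "!series_matrix_table_begin"
_SERIES_MATRIX_END = "!series_matrix_table_end"


@dataclass
class Cohort:
    """An expression matrix and clinical table over the same ordered samples."""

    expression: pd.DataFrame
    clinical: pd.DataFrame
    name: str = "cohort"

    def __post_init__(self) -> None:
        if list(self.expression.columns) != list(self.clinical.index):
            raise ValueError(
                f"cohort {self.name!r}: expression samples and clinical "
                "samples must be identical and identically ordered"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expression.columns)

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]


def read_expression(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    """Read a gene × sample expression matrix.

    ``dialect="tsv"``: plain tab-delimited table, header row of sample ids,
    first column gene ids. ``dialect="geo_series_matrix"``: GEO
    series-matrix flavour — ``!``-prefixed metadata lines are skipped and
    only the block between the table markers is parsed; quoted identifiers
    are unquoted. Missing values stay missing (NaN), never zero.
    """
    path = Path(path)
    if dialect == "tsv":
        header = path.open().readline().rstrip("\n").split("\t")[1:]
        if len(set(header)) != len(header):
            dups = sorted({h for h in header if header.count(h) > 1})
            raise ValueError(f"{path}: duplicate sample ids {dups}")
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    elif dialect == "geo_series_matrix":
        lines: list[str] = []
        in_table = None
        for line in path.read_text().splitlines():
            low = line.strip().lower()
            if low.startswith(_SERIES_MATRIX_BEGIN):
                in_table = True
                continue
            if low.startswith(_SERIES_MATRIX_END):
                in_table = False
                continue
            if line.startswith("!"):
                continue
            if in_table is False:
                continue
            if line.strip():
                lines.append(line)
        if not lines:
            raise ValueError(f"{path}: no data table found in series-matrix file")
        header = [h.strip('"') for h in lines[0].rstrip("\n").split("\t")[1:]]
        if len(set(header)) != len(header):
            dups = sorted({h for h in header if header.count(h) > 1})
            raise ValueError(f"{path}: duplicate sample ids {dups}")
        from io import StringIO

        raw = pd.read_csv(StringIO("\n".join(lines)), sep="\t", index_col=0,
                          dtype=str)
        raw.index = raw.index.str.strip('"')
        raw.columns = raw.columns.str.strip('"')
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if raw.columns.duplicated().any():
        dups = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample ids {dups}")
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col].str.strip('"') if raw[col].dtype == object
                                  else raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna() & (raw[col].astype(str).str.strip() != "")
        bad &= ~raw[col].astype(str).str.upper().isin(("NA", "NAN", "NULL"))
        if bad.any():
            row = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"{path}: unparseable numeric value at gene {row!r}, sample {col!r}"
            )
        values[col] = converted
    values.index.name = "gene_id"
    return values


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a matrix in the tab-delimited dialect ``read_expression`` reads."""
    out = matrix.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited clinical table (``sample_id`` + endpoints).

    Samples with non-positive or missing OS time, or a missing event
    indicator, are dropped: only patients with usable nonzero survival data
    enter analysis.
    """
    tab = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in ("sample_id", *REQUIRED_CLINICAL_COLUMNS)
               if c not in tab.columns]
    if missing:
        raise ValueError(f"{path}: clinical table lacks columns {missing}")
    if tab["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids in clinical table")
    tab = tab.set_index("sample_id")
    usable = (tab["os_time"] > 0) & tab["os_event"].isin((0, 1))
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info("dropped %d samples without usable survival data", n_dropped)
    tab = tab[usable]
    tab["os_event"] = tab["os_event"].astype(int)
    return tab


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    out = clinical.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize samples so every column shares one distribution.

    The target distribution is the mean of the per-sample sorted value
    vectors; ties within a sample receive the mean of the quantile values
    they span. Missing values are not supported here (filter first).
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    if matrix.isna().any().any():
        raise ValueError("quantile normalization requires a complete matrix")
    vals = matrix.to_numpy(dtype=float)
    sorted_vals = np.sort(vals, axis=0)
    target = sorted_vals.mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        order = np.argsort(col, kind="stable")
        ranked = np.empty_like(target)
        ranked[order] = target
        # ties: average the target quantiles the tied block spans
        uniq, inv, counts = np.unique(col, return_inverse=True,
                                      return_counts=True)
        if (counts > 1).any():
            sums = np.bincount(inv, weights=ranked)
            ranked = (sums / counts)[inv]
        out[:, j] = ranked
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def filter_low_count_genes(counts: pd.DataFrame,
                           zero_fraction_max: float = 0.90) -> pd.DataFrame:
    """Keep genes whose fraction of zero-count samples is < the threshold.

    The default drops genes that are zero in 90% or more of samples.
    """
    arr = counts.to_numpy()
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    zero_frac = (arr == 0).mean(axis=1)
    keep = zero_frac < zero_fraction_max
    return counts.loc[keep]


def median_ratio_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Median-of-ratios count normalization, returned on the log2 scale.

    Per-sample size factor = median over reference genes (nonzero in every
    sample) of count / geometric-mean count across samples; output values
    are log2(count / size_factor + 1).
    """
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    all_nonzero = (arr > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; filter genes first"
        )
    ref = arr[all_nonzero]
    geo_mean = np.exp(np.mean(np.log(ref), axis=1))
    sf = np.median(ref / geo_mean[:, None], axis=0)
    norm = np.log2(arr / sf[None, :] + 1.0)
    return pd.DataFrame(norm, index=counts.index, columns=counts.columns)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (the scaling used by median_ratio_normalize)."""
    arr = counts.to_numpy(dtype=float)
    all_nonzero = (arr > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError("no gene has nonzero counts in every sample")
    ref = arr[all_nonzero]
    geo_mean = np.exp(np.mean(np.log(ref), axis=1))
    sf = np.median(ref / geo_mean[:, None], axis=0)
    return pd.Series(sf, index=counts.columns)


def collapse_probesets(matrix: pd.DataFrame,
                       probe_to_symbol: pd.Series) -> pd.DataFrame:
    """Collapse probesets to gene symbols keeping the highest-mean probe."""
    mapped = matrix.loc[matrix.index.isin(probe_to_symbol.index)].copy()
    symbols = probe_to_symbol.loc[mapped.index]
    means = mapped.mean(axis=1)
    best = (
        pd.DataFrame({"symbol": symbols.values, "mean": means.values},
                     index=mapped.index)
        .sort_values("mean", ascending=False)
        .drop_duplicates("symbol")
    )
    out = mapped.loc[best.index]
    out.index = best["symbol"].values
    out.index.name = "gene_id"
    return out.sort_index()


def align(expression: pd.DataFrame, clinical: pd.DataFrame,
          name: str = "cohort") -> Cohort:
    """Restrict both tables to their shared samples, in expression order."""
    shared = [s for s in expression.columns if s in clinical.index]
    if not shared:
        raise ValueError("expression and clinical tables share no samples")
    n_dropped = (expression.shape[1] - len(shared)) + (len(clinical) - len(shared))
    if n_dropped:
        logger.info("align: dropped %d unmatched samples", n_dropped)
    return Cohort(expression=expression[shared],
                  clinical=clinical.loc[shared], name=name)


def drop_incomplete_genes(matrix: pd.DataFrame) -> pd.DataFrame:
    """Drop genes with any missing value (required before clustering/Cox)."""
    keep = matrix.notna().all(axis=1)
    n_drop = int((~keep).sum())
    if n_drop:
        warnings.warn(f"dropping {n_drop} genes with missing values",
                      stacklevel=2)
    return matrix.loc[keep]


def write_cdt(matrix: pd.DataFrame, path: str | Path,
              gene_order: list | None = None,
              sample_order: list | None = None) -> None:
    """Write a Treeview-compatible ``.cdt`` clustered-data table."""
    out = matrix.copy()
    if gene_order is not None:
        out = out.loc[gene_order]
    if sample_order is not None:
        out = out[sample_order]
    with open(path, "w") as fh:
        fh.write("GID\tNAME\tGWEIGHT\t" + "\t".join(map(str, out.columns)) + "\n")
        fh.write("EWEIGHT\t\t\t" + "\t".join(["1"] * out.shape[1]) + "\n")
        for gid, row in out.iterrows():
            vals = "\t".join(f"{v:.6g}" for v in row.to_numpy())
            fh.write(f"GENE_{gid}\t{gid}\t1\t{vals}\n")


def read_cohort_dir(directory: str | Path, name: str | None = None) -> Cohort:
    """Load ``expression.tsv`` + ``clinical.tsv`` from a cohort directory."""
    directory = Path(directory)
    expr = read_expression(directory / "expression.tsv")
    clin = read_clinical(directory / "clinical.tsv")
    return align(expr, clin, name=name or directory.name)
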