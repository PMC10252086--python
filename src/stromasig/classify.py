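"""Tumor subtyping from a prognostic signature.

The clustering recipe: per-gene standardization (value − mean)/SD, then
agglomerative hierarchical clustering of samples (and optionally genes)
with Euclidean distance and complete linkage. Cutting the sample tree into
its two (or three) major branches and ordering branches by mean
standardized signature expression yields the Stromal-UP (SU), Stromal-DOWN
(SD) and, for a three-way cut, Stromal-INTERMEDIATE (SI) labels; SU tumors
over-express the signature in concert and carry the poor prognosis.

EMT status (Epithelial / Intermediate / Mesenchymal) comes from mean
standardized epithelial and mesenchymal marker scores, and a rank-based
single-sample enrichment statistic over a stromal gene set gives an
ESTIMATE-style stromal score with a median ST-H/ST-L split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import rankdata


def standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scores: (value − mean) / SD, with the n−1 sample SD.

    Constant genes (zero variance) are dropped with a warning.
    """
    vals = matrix.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("matrix contains missing values; filter genes first")
    sd = vals.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant genes before "
                      "standardization", stacklevel=2)
    vals = vals[keep]
    z = (vals - vals.mean(axis=1, keepdims=True)) / sd[keep][:, None]
    return pd.DataFrame(z, index=matrix.index[keep], columns=matrix.columns)


@dataclass
class Dendrogram:
    """A binary merge tree over samples or genes (complete linkage)."""

    linkage: np.ndarray          # scipy linkage matrix
    items: list[str]             # leaf identifiers, input order
    axis: str                    # "samples" or "genes"

    @property
    def leaf_order(self) -> list[str]:
        return [self.items[i] for i in hierarchy.leaves_list(self.linkage)]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def hcluster(matrix: pd.DataFrame, axis: str = "samples") -> Dendrogram:
    """Hierarchical clustering: Euclidean distance, complete linkage."""
    if axis == "samples":
        data = matrix.to_numpy(dtype=float).T
        items = list(matrix.columns)
    elif axis == "genes":
        data = matrix.to_numpy(dtype=float)
        items = list(matrix.index)
    else:
        raise ValueError("axis must be 'samples' or 'genes'")
    if np.isnan(data).any():
        raise ValueError(
            "matrix contains missing values; drop incomplete genes first "
            "(see stromasig.io.drop_incomplete_genes)"
        )
    if len(items) < 2:
        raise ValueError("need at least 2 items to cluster")
    Z = hierarchy.linkage(pdist(data, metric="euclidean"), method="complete")
    return Dendrogram(linkage=Z, items=items, axis=axis)


@dataclass
class SubtypeLabels:
    """Per-sample categorical calls under one labelling scheme."""

    labels: pd.Series                  # sample_id -> label
    scheme: str                        # "SU/SD", "SU/SI/SD", "E/I/M", "ST-H/ST-L"
    mean_signature_z: pd.Series = field(default=None)

    def counts(self) -> pd.Series:
        return self.labels.value_counts()


def cut_and_label(dend: Dendrogram, standardized_signature: pd.DataFrame,
                  n_groups: int = 2) -> SubtypeLabels:
    """Cut the sample dendrogram into its major branches and name them.

    Removing the n_groups − 1 highest merges leaves n_groups branches;
    branches are ordered by their mean standardized signature expression:
    highest → SU, lowest → SD, middle (three-way cut) → SI.
    """
    if dend.axis != "samples":
        raise ValueError("cut_and_label requires a sample dendrogram")
    if n_groups not in (2, 3):
        raise ValueError("n_groups must be 2 or 3")
    if n_groups > len(dend.items):
        raise ValueError("more groups than leaves")
    assign = hierarchy.cut_tree(dend.linkage, n_clusters=n_groups).ravel()
    samples = pd.Index(dend.items)
    mean_z = standardized_signature[samples].mean(axis=0)
    group_means = pd.Series(
        [mean_z[samples[assign == gid]].mean() for gid in range(n_groups)]
    )
    order = group_means.sort_values(ascending=False).index  # high → low
    if n_groups == 2:
        names = {order[0]: "SU", order[1]: "SD"}
    else:
        names = {order[0]: "SU", order[1]: "SI", order[2]: "SD"}
    labels = pd.Series([names[gid] for gid in assign], index=samples,
                       name="label")
    sizes = labels.value_counts()
    if (sizes < 2).any():
        warnings.warn(f"subtype group(s) of size < 2: {sizes.to_dict()}",
                      stacklevel=2)
    return SubtypeLabels(labels=labels,
                         scheme="SU/SD" if n_groups == 2 else "SU/SI/SD",
                         mean_signature_z=mean_z)


def classify_su_sd(matrix: pd.DataFrame, signature_genes,
                   n_groups: int = 2) -> SubtypeLabels:
    """Standardize the signature rows, cluster samples, and label SU/SD."""
    present = [g for g in signature_genes if g in matrix.index]
    if len(present) < 2:
        raise ValueError("fewer than 2 signature genes present in matrix")
    z = standardize(matrix.loc[present])
    dend = hcluster(z, axis="samples")
    return cut_and_label(dend, z, n_groups=n_groups)


def classify_emt(matrix: pd.DataFrame, epithelial_markers,
                 mesenchymal_markers, threshold: float = 0.0) -> SubtypeLabels:
    """Epithelial / Intermediate / Mesenchymal calls from marker scores.

    Per sample: sE = mean standardized epithelial-marker expression, sM
    likewise for mesenchymal markers. E if sE > t and sM < −t; M if sM > t
    and sE < −t; otherwise I. The default t = 0 is an explicit
    operationalization of reading the two major marker branches.
    """
    epithelial = [g for g in epithelial_markers if g in matrix.index]
    mesenchymal = [g for g in mesenchymal_markers if g in matrix.index]
    overlap = set(epithelial) & set(mesenchymal)
    if overlap:
        raise ValueError(f"markers in both lists: {sorted(overlap)}")
    if len(epithelial) < 5 or len(mesenchymal) < 5:
        raise ValueError("need at least 5 markers of each class in the matrix")
    z = standardize(matrix.loc[epithelial + mesenchymal])
    s_e = z.loc[[g for g in epithelial if g in z.index]].mean(axis=0)
    s_m = z.loc[[g for g in mesenchymal if g in z.index]].mean(axis=0)
    t = threshold
    call = np.where((s_e > t) & (s_m < -t), "E",
                    np.where((s_m > t) & (s_e < -t), "M", "I"))
    labels = pd.Series(call, index=matrix.columns, name="label")
    return SubtypeLabels(labels=labels, scheme="E/I/M")


@dataclass
class StromalScore:
    """Per-sample rank-based enrichment of a stromal gene set."""

    scores: pd.Series
    gene_set: list[str]


def stromal_score(matrix: pd.DataFrame, stromal_gene_set,
                  weight_exponent: float = 0.25) -> StromalScore:
    """Single-sample enrichment score for a stromal gene set.

    For each sample, genes are ranked by expression within the sample
    (1 = lowest). Walking the genes from highest to lowest expression, an
    in-set running fraction weighted by rank^0.25 and an out-of-set uniform
    running fraction are accumulated; the score is the sum of their
    differences over all positions, divided by the number of genes. Higher
    scores mean the stromal genes concentrate at the top of the sample's
    expression ranking. The statistic depends on within-sample ranks only.
    """
    present = [g for g in stromal_gene_set if g in matrix.index]
    if len(present) < 10:
        raise ValueError(
            f"only {len(present)} stromal genes present in matrix; need >= 10"
        )
    genes = matrix.index
    in_set = genes.isin(present)
    n_genes, n_out = len(genes), int((~in_set).sum())
    if n_out == 0:
        raise ValueError("stromal gene set covers the whole matrix")
    scores = {}
    vals = matrix.to_numpy(dtype=float)
    for j, sample in enumerate(matrix.columns):
        x = vals[:, j]
        ranks = rankdata(x, method="average")          # 1 = lowest
        # descending expression; stable index tie-break for determinism
        order = np.lexsort((np.arange(n_genes), -ranks))
        hit = in_set[order]
        w = ranks[order] ** weight_exponent
        w_hit = np.where(hit, w, 0.0)
        p_in = np.cumsum(w_hit) / w_hit.sum()
        p_out = np.cumsum(~hit) / n_out
        scores[sample] = float(np.sum(p_in - p_out) / n_genes)
    return StromalScore(scores=pd.Series(scores, name="stromal_score"),
                        gene_set=present)


def median_split(score: StromalScore) -> SubtypeLabels:
    """ST-H/ST-L labels: strictly above the median score → ST-H, else ST-L."""
    s = score.scores
    if len(s) < 2:
        raise ValueError("need at least 2 samples for a median split")
    med = s.median()
    if s.nunique() == 1:
        warnings.warn("all stromal scores equal; every sample labelled ST-L",
                      stacklevel=2)
    labels = pd.Series(np.where(s > med, "ST-H", "ST-L"), index=s.index,
                       name="label")
    return SubtypeLabels(labels=labels, scheme="ST-H/ST-L")
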