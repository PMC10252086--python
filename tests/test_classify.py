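"""Standardization, clustering, SU/SD, EMT and stromal-score labelling."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from stromasig import SimConfig, generate_cohort
from stromasig.classify import (
    classify_emt,
    classify_su_sd,
    cut_and_label,
    hcluster,
    median_split,
    standardize,
    stromal_score,
)


def mat(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestStandardize:
    def test_arithmetic_sequence_maps_to_unit_steps(self):
        out = standardize(mat([[1, 2, 3]]))
        np.testing.assert_allclose(out.to_numpy(), [[-1, 0, 1]])

    def test_constant_gene_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = standardize(mat([[5, 5, 5], [1, 2, 3]]))
        assert list(out.index) == ["g1"]

    def test_row_moments(self):
        rng = np.random.default_rng(0)
        out = standardize(mat(rng.normal(size=(20, 50))))
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-10)


def naive_complete_linkage(points):
    """O(n^3) agglomeration oracle: returns partition after each merge."""
    clusters = {i: frozenset([i]) for i in range(len(points))}
    partitions, heights = [], []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            d = max(
                np.linalg.norm(points[i] - points[j])
                for i in clusters[a] for j in clusters[b]
            )
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        merged = clusters.pop(a) | clusters.pop(b)
        clusters[max(clusters, default=0) + len(points) + 1] = merged
        heights.append(d)
        partitions.append(frozenset(clusters.values()))
    return partitions, heights


def scipy_partitions(Z, n):
    """Partition after each merge step, reconstructed from a linkage matrix."""
    members = {i: frozenset([i]) for i in range(n)}
    partitions = []
    for step, (a, b, _, _) in enumerate(Z):
        members[n + step] = members.pop(int(a)) | members.pop(int(b))
        partitions.append(frozenset(members.values()))
    return partitions


class TestHcluster:
    def test_identical_samples_merge_first_at_height_zero(self):
        m = mat([[1, 1, 5], [2, 2, 9]], samples=["a", "b", "c"])
        dend = hcluster(m, axis="samples")
        assert dend.linkage[0, 2] == 0.0
        assert {int(dend.linkage[0, 0]), int(dend.linkage[0, 1])} == {0, 1}

    def test_merge_sequence_matches_naive_oracle_on_6_items(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(6, 4))
        m = mat(pts.T, samples=[f"s{i}" for i in range(6)])
        dend = hcluster(m, axis="samples")
        oracle_parts, oracle_heights = naive_complete_linkage(list(pts))
        np.testing.assert_allclose(dend.linkage[:, 2], oracle_heights,
                                   rtol=1e-12)
        assert scipy_partitions(dend.linkage, 6) == oracle_parts

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(3)
        dend = hcluster(mat(rng.normal(size=(5, 12))), axis="samples")
        assert (np.diff(dend.heights) >= -1e-12).all()

    def test_two_separated_blobs_split_at_root(self):
        rng = np.random.default_rng(11)
        blob = np.r_[rng.normal(0, 0.3, size=(10, 3)),
                     rng.normal(8, 0.3, size=(10, 3))]
        m = mat(blob.T)
        dend = hcluster(m, axis="samples")
        from scipy.cluster.hierarchy import cut_tree
        cut = cut_tree(dend.linkage, 2).ravel()
        assert len(set(cut[:10])) == 1 and len(set(cut[10:])) == 1
        assert cut[0] != cut[-1]

    def test_missing_values_rejected_with_guidance(self):
        m = mat([[1, np.nan], [2, 3]])
        with pytest.raises(ValueError, match="drop_incomplete_genes"):
            hcluster(m, axis="samples")

    def test_gene_axis(self):
        rng = np.random.default_rng(5)
        dend = hcluster(mat(rng.normal(size=(8, 10))), axis="genes")
        assert len(dend.items) == 8


class TestCutAndLabel:
    def make_blobs(self, shifts, n_per=8, seed=0):
        rng = np.random.default_rng(seed)
        cols = []
        for shift in shifts:
            cols.append(rng.normal(shift, 0.4, size=(10, n_per)))
        values = np.concatenate(cols, axis=1)
        return mat(values)

    def test_high_blob_labelled_su(self):
        m = self.make_blobs([+2, -2])
        z = standardize(m)
        dend = hcluster(z, axis="samples")
        labels = cut_and_label(dend, z, n_groups=2)
        assert (labels.labels.iloc[:8] == "SU").all()
        assert (labels.labels.iloc[8:] == "SD").all()
        su_mean = labels.mean_signature_z[labels.labels == "SU"].mean()
        sd_mean = labels.mean_signature_z[labels.labels == "SD"].mean()
        assert su_mean > sd_mean

    def test_three_groups_monotone_ordering(self):
        m = self.make_blobs([+3, 0, -3])
        z = standardize(m)
        dend = hcluster(z, axis="samples")
        labels = cut_and_label(dend, z, n_groups=3)
        assert (labels.labels.iloc[:8] == "SU").all()
        assert (labels.labels.iloc[8:16] == "SI").all()
        assert (labels.labels.iloc[16:] == "SD").all()

    def test_invariant_to_sample_order(self):
        m = self.make_blobs([+2, -2], seed=4)
        rng = np.random.default_rng(9)
        perm = rng.permutation(m.shape[1])
        shuffled = m.iloc[:, perm]
        for matrix in (m, shuffled):
            z = standardize(matrix)
            labels = cut_and_label(hcluster(z, axis="samples"), z)
            if matrix is m:
                base = labels.labels
            else:
                assert (labels.labels.loc[base.index] == base).all()

    def test_labels_depend_only_on_signature_rows(self, small_cohort):
        sig = small_cohort.truth.stromal_genes
        a = classify_su_sd(small_cohort.expression, sig)
        noisy = small_cohort.expression.copy()
        rng = np.random.default_rng(0)
        other = [g for g in noisy.index if g not in sig]
        noisy.loc[other] = rng.normal(size=(len(other), noisy.shape[1]))
        b = classify_su_sd(noisy, sig)
        assert (a.labels == b.labels).all()

    def test_synthetic_agreement_with_true_median_split(self, small_cohort):
        labels = classify_su_sd(small_cohort.expression,
                                small_cohort.truth.stromal_genes)
        s = small_cohort.truth.stromal_fraction
        true = np.where(s > s.median(), "SU", "SD")
        assert (labels.labels.to_numpy() == true).mean() >= 0.90

    def test_subset_robustness_mirrors_platform_gene_loss(self, small_cohort):
        """Labels barely move when only 13 of 20 signature genes are used."""
        full = classify_su_sd(small_cohort.expression,
                              small_cohort.truth.stromal_genes)
        rng = np.random.default_rng(2)
        for _ in range(3):
            subset = list(rng.choice(small_cohort.truth.stromal_genes, 13,
                                     replace=False))
            part = classify_su_sd(small_cohort.expression, subset)
            assert (part.labels != full.labels).mean() < 0.10


class TestClassifyEMT:
    def test_clear_profiles(self):
        rng = np.random.default_rng(0)
        epi = [f"E{i}" for i in range(5)]
        mes = [f"M{i}" for i in range(5)]
        n = 20
        half = n // 2
        values = {}
        for g in epi:
            values[g] = np.r_[np.full(half, 8.0), np.full(half, 4.0)] \
                + rng.normal(0, 0.1, n)
        for g in mes:
            values[g] = np.r_[np.full(half, 4.0), np.full(half, 8.0)] \
                + rng.normal(0, 0.1, n)
        m = pd.DataFrame(values).T
        m.columns = [f"s{j}" for j in range(n)]
        labels = classify_emt(m, epi, mes)
        assert (labels.labels.iloc[:half] == "E").all()
        assert (labels.labels.iloc[half:] == "M").all()

    def test_ambiguous_sample_is_intermediate(self):
        rng = np.random.default_rng(1)
        epi = [f"E{i}" for i in range(5)]
        mes = [f"M{i}" for i in range(5)]
        m = pd.DataFrame(rng.normal(5, 1, size=(10, 12)),
                         index=epi + mes,
                         columns=[f"s{j}" for j in range(12)])
        labels = classify_emt(m, epi, mes, threshold=5.0)
        assert (labels.labels == "I").all()  # huge threshold: nothing clears

    def test_marker_overlap_rejected(self):
        m = mat(np.random.default_rng(0).normal(size=(10, 6)))
        with pytest.raises(ValueError, match="both lists"):
            classify_emt(m, list(m.index[:5]), list(m.index[4:9]))

    def test_synthetic_em_calls_match_planted_loadings(self):
        cfg = SimConfig(n_samples=200, n_genes=100, n_epithelial_markers=10,
                        n_mesenchymal_markers=10, marker_loading=2.0,
                        noise_sd=1.0, seed=19)
        c = generate_cohort(cfg)
        labels = classify_emt(c.expression, c.truth.epithelial_markers,
                              c.truth.mesenchymal_markers)
        s = c.truth.stromal_fraction
        truth = np.where(s > s.median(), "M", "E")
        called = labels.labels.isin(["E", "M"])
        agree = (labels.labels[called] == pd.Series(truth, index=s.index)[called])
        assert agree.mean() >= 0.90


def literal_running_sum_score(matrix, gene_set, exponent=0.25):
    """Independent literal ssGSEA-style oracle (per-sample loop over genes)."""
    out = {}
    for sample in matrix.columns:
        col = matrix[sample]
        ranks = pd.Series(rankdata(col.to_numpy()), index=col.index)
        ordered = sorted(matrix.index,
                         key=lambda g: (-ranks[g], list(matrix.index).index(g)))
        in_set = set(gene_set)
        w_total = sum(ranks[g] ** exponent for g in ordered if g in in_set)
        n_out = sum(1 for g in ordered if g not in in_set)
        p_in = p_out = 0.0
        es = 0.0
        for g in ordered:
            if g in in_set:
                p_in += ranks[g] ** exponent / w_total
            else:
                p_out += 1.0 / n_out
            es += p_in - p_out
        out[sample] = es / len(ordered)
    return pd.Series(out)


class TestStromalScore:
    def fixture_20x5(self):
        rng = np.random.default_rng(23)
        return mat(rng.normal(6, 2, size=(20, 5))), \
            [f"g{i}" for i in range(0, 20, 2)]  # 10 genes

    def test_matches_literal_oracle(self):
        m, gene_set = self.fixture_20x5()
        score = stromal_score(m, gene_set)
        oracle = literal_running_sum_score(m, gene_set)
        np.testing.assert_allclose(score.scores.to_numpy(),
                                   oracle[score.scores.index].to_numpy(),
                                   atol=1e-12)

    def test_top_ranked_set_attains_permutation_maximum(self):
        genes = [f"g{i}" for i in range(20)]
        gene_set = genes[:10]
        rng = np.random.default_rng(1)
        base = np.arange(20, dtype=float)
        # sample 0: set genes occupy exactly the top ranks
        top = np.r_[base[10:], base[:10]]
        best = stromal_score(mat(top[:, None], genes=genes,
                                 samples=["s0"]), gene_set).scores["s0"]
        for _ in range(50):
            perm = rng.permutation(base)
            other = stromal_score(mat(perm[:, None], genes=genes,
                                      samples=["s0"]), gene_set).scores["s0"]
            assert other <= best + 1e-12

    def test_invariant_under_monotone_transform(self):
        m, gene_set = self.fixture_20x5()
        a = stromal_score(m, gene_set).scores
        b = stromal_score(np.exp(m / 3.0), gene_set).scores
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)

    def test_fewer_than_10_genes_rejected(self):
        m, _ = self.fixture_20x5()
        with pytest.raises(ValueError, match=">= 10"):
            stromal_score(m, ["g0", "g2"])

    def test_synthetic_st_h_group_has_higher_true_fraction(self, small_cohort):
        score = stromal_score(small_cohort.expression,
                              small_cohort.truth.stromal_genes)
        st = median_split(score)
        s = small_cohort.truth.stromal_fraction
        assert s[st.labels == "ST-H"].mean() > s[st.labels == "ST-L"].mean()


class TestMedianSplit:
    def test_scores_above_median_are_high(self):
        from stromasig.classify import StromalScore
        score = StromalScore(
            scores=pd.Series([1.0, 2.0, 3.0, 4.0],
                             index=["a", "b", "c", "d"]),
            gene_set=["x"] * 10)
        st = median_split(score)
        assert st.labels.tolist() == ["ST-L", "ST-L", "ST-H", "ST-H"]

    def test_all_equal_scores_all_low_with_warning(self):
        from stromasig.classify import StromalScore
        score = StromalScore(scores=pd.Series([2.0, 2.0, 2.0],
                                              index=list("abc")),
                             gene_set=["x"] * 10)
        with pytest.warns(UserWarning, match="equal"):
            st = median_split(score)
        assert (st.labels == "ST-L").all()
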