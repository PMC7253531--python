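"""PCA, k-means and the group → LF/IF/HF mapping."""

import itertools

import numpy as np
import pandas as pd
import pytest

from capheno import phenotype_clustering as pc
from capheno.burst_features import FEATURE_NAMES
from capheno.errors import InputError, ParameterError


def random_features(rng, n):
    return rng.normal(0, 1, (n, 9)) + rng.uniform(1, 5, 9)


class TestImputeMedian:
    def test_nan_replaced_with_column_median(self):
        x = np.array([[1.0, np.nan], [3.0, 4.0], [5.0, 8.0]])
        out = pc.impute_median(x)
        assert out[0, 1] == 6.0
        assert np.array_equal(out[:, 0], x[:, 0])

    def test_all_nan_column_becomes_zero(self):
        x = np.array([[np.nan, 1.0], [np.nan, 2.0]])
        out = pc.impute_median(x)
        assert np.all(out[:, 0] == 0.0)

    def test_input_not_mutated(self):
        x = np.array([[np.nan, 1.0], [2.0, 3.0]])
        pc.impute_median(x)
        assert np.isnan(x[0, 0])


class TestFitPCA:
    def test_single_varying_feature_dominates_pc1(self):
        rng = np.random.default_rng(0)
        x = np.zeros((50, 3))
        x[:, 1] = rng.normal(0, 2, 50)
        x[:, 0] = 5.0 + rng.normal(0, 1e-6, 50)
        x[:, 2] = rng.normal(0, 1e-6, 50)
        model, _ = pc.fit_pca(x, standardize=False)
        contrib = pc.pc_contributions(model, 0)
        assert contrib[1] > 99.9

    def test_loadings_match_eigh_of_correlation(self):
        rng = np.random.default_rng(1)
        x = random_features(rng, 200) @ rng.normal(0, 1, (9, 9))
        model, _ = pc.fit_pca(x, standardize=True)
        z = (x - x.mean(0)) / x.std(0, ddof=1)
        corr = z.T @ z / (len(x) - 1)
        w, v = np.linalg.eigh(corr)
        order = np.argsort(w)[::-1]
        v = v[:, order]
        for j in range(9):
            i = int(np.argmax(np.abs(v[:, j])))
            if v[i, j] < 0:
                v[:, j] *= -1
        np.testing.assert_allclose(model.loadings, v, atol=1e-6)

    def test_explained_variance_ratios_sum_to_one(self):
        rng = np.random.default_rng(2)
        model, _ = pc.fit_pca(random_features(rng, 60))
        assert model.explained_variance_ratio.sum() == pytest.approx(1.0)
        assert np.all(np.diff(model.explained_variance_ratio) <= 1e-12)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(3)
        x = random_features(rng, 40)
        model, scores = pc.fit_pca(x)
        z = (x - model.mean) / model.scale
        np.testing.assert_allclose(model.inverse_transform(scores), z, atol=1e-9)

    def test_transform_matches_fit_scores(self):
        rng = np.random.default_rng(4)
        x = random_features(rng, 40)
        model, scores = pc.fit_pca(x)
        np.testing.assert_allclose(model.transform(x), scores, atol=1e-9)

    def test_contributions_sum_to_100(self):
        rng = np.random.default_rng(5)
        model, _ = pc.fit_pca(random_features(rng, 30))
        for j in range(model.n_components):
            assert pc.pc_contributions(model, j).sum() == pytest.approx(100.0)
        with pytest.raises(IndexError):
            pc.pc_contributions(model, model.n_components)

    def test_constant_data_rejected(self):
        with pytest.raises(ParameterError):
            pc.fit_pca(np.ones((10, 4)))

    def test_nan_rejected(self):
        x = np.ones((10, 3)) + np.arange(10)[:, None]
        x[0, 0] = np.nan
        with pytest.raises(InputError):
            pc.fit_pca(x)


class TestKMeans:
    def test_k_equals_n_zero_inertia(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, (6, 2))
        out = pc.kmeans_cluster(x, k=6, n_restarts=10, seed=0)
        assert out.inertia == pytest.approx(0.0, abs=1e-12)
        assert sorted(out.labels) == [1, 2, 3, 4, 5, 6]

    @pytest.mark.parametrize("seed", range(10))
    def test_recovers_separated_blobs(self, seed):
        rng = np.random.default_rng(seed)
        centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        truth = np.repeat([0, 1, 2], 30)
        x = centers[truth] + rng.normal(0, 0.5, (90, 2))
        out = pc.kmeans_cluster(x, k=3, n_restarts=20, seed=seed)
        # perfect recovery up to label permutation
        for g in (1, 2, 3):
            assert len(set(truth[out.labels == g])) == 1

    def test_matches_exhaustive_optimum_small_case(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, (8, 2))
        out = pc.kmeans_cluster(x, k=2, n_restarts=50, seed=0)
        best = np.inf
        idx = np.arange(8)
        for r in range(1, 8):
            for a in itertools.combinations(idx, r):
                mask = np.zeros(8, bool)
                mask[list(a)] = True
                inert = sum(
                    ((x[m] - x[m].mean(0)) ** 2).sum() for m in (mask, ~mask)
                )
                best = min(best, inert)
        assert out.inertia == pytest.approx(best, rel=1e-9)

    def test_inertia_monotone_in_k(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, (60, 3))
        inertias = [
            pc.kmeans_cluster(x, k=k, n_restarts=20, seed=0).inertia
            for k in (2, 4, 8)
        ]
        assert inertias[0] >= inertias[1] >= inertias[2]

    def test_labels_one_based(self):
        rng = np.random.default_rng(9)
        out = pc.kmeans_cluster(rng.normal(0, 1, (20, 2)), k=4, seed=0)
        assert out.labels.min() == 1 and out.labels.max() == 4

    def test_too_few_points_rejected(self):
        with pytest.raises(ParameterError):
            pc.kmeans_cluster(np.zeros((3, 2)), k=8)


def _features_frame(rows):
    """Build a features DataFrame from (n_spikes, n_bursts, ibi_s) triples."""
    data = {name: [] for name in FEATURE_NAMES}
    for ns, b, ibi in rows:
        data["n_spikes"].append(ns)
        data["firing_rate_hz"].append(ns / 600.0)
        data["isi_mean_s"].append(1.0)
        data["isi_sd_s"].append(0.5)
        data["n_bursts"].append(b)
        data["spikes_per_burst"].append(3.0 if b else np.nan)
        data["isi_in_burst_s"].append(0.3 if b else np.nan)
        data["ibi_s"].append(ibi)
        data["burst_length_s"].append(0.6 if b else np.nan)
    return pd.DataFrame(data)


def _assign(labels, k):
    labels = np.asarray(labels)
    return pc.ClusterAssignment(
        labels=labels, k=k, centroids=np.zeros((k, 2)), inertia=0.0, seed=0
    )


class TestClassifyGroups:
    def test_threshold_examples(self):
        # group 1: 50 bursts, IBI 12 s -> HF; group 2: 3 bursts, IBI 55 s -> LF;
        # group 3: 12 bursts, IBI 37 s -> IF
        rows = [(400, 50, 12.0)] * 3 + [(20, 3, 55.0)] * 3 + [(100, 12, 37.0)] * 3
        feats = _features_frame(rows)
        report = pc.classify_groups(_assign([1] * 3 + [2] * 3 + [3] * 3, 3), feats)
        assert report.group_class == {1: "HF", 2: "LF", 3: "IF"}
        assert report.class_fractions == {
            "LF": pytest.approx(1 / 3),
            "IF": pytest.approx(1 / 3),
            "HF": pytest.approx(1 / 3),
        }

    def test_hf_checked_before_lf(self):
        # median burst count 45 (HF) with IBI 50 s (would be LF): HF wins
        feats = _features_frame([(400, 45, 50.0)] * 4)
        report = pc.classify_groups(_assign([1] * 4, 1), feats)
        assert report.group_class == {1: "HF"}

    def test_boundary_values(self):
        cases = [
            ((300, 40, 20.0), "HF"),   # bursts exactly 40
            ((300, 20, 16.0), "HF"),   # IBI exactly 16 s
            ((50, 7, 30.0), "LF"),     # bursts exactly 7
            ((50, 10, 40.0), "IF"),    # IBI exactly 40 s is not LF
            ((50, 10, 40.5), "LF"),    # IBI above 40 s
        ]
        for row, expected in cases:
            report = pc.classify_groups(_assign([1] * 4, 1), _features_frame([row] * 4))
            assert report.group_class[1] == expected, row

    def test_no_burst_group_tertile_fallback(self):
        rows = (
            [(5, 0, np.nan)] * 4 + [(50, 0, np.nan)] * 4 + [(200, 0, np.nan)] * 4
        )
        feats = _features_frame(rows)
        report = pc.classify_groups(_assign([1] * 4 + [2] * 4 + [3] * 4, 3), feats)
        assert report.group_class == {1: "LF", 2: "IF", 3: "HF"}

    def test_fractions_sum_to_one(self):
        rows = [(400, 50, 12.0)] * 5 + [(20, 3, 55.0)] * 7
        report = pc.classify_groups(
            _assign([1] * 5 + [2] * 7, 2), _features_frame(rows)
        )
        assert sum(report.class_fractions.values()) == pytest.approx(1.0)
        assert report.class_fractions["HF"] == pytest.approx(5 / 12)

    def test_size_mismatch_rejected(self):
        with pytest.raises(InputError):
            pc.classify_groups(_assign([1, 1], 1), _features_frame([(10, 2, 20.0)]))

    def test_report_json_has_group_stats(self):
        rows = [(400, 50, 12.0)] * 4 + [(20, 3, 55.0)] * 4
        report = pc.classify_groups(
            _assign([1] * 4 + [2] * 4, 2), _features_frame(rows)
        )
        import json

        doc = json.loads(report.to_json())
        assert doc["class_fractions"]["HF"] == pytest.approx(0.5)
        assert set(doc["group_class"]) == {"1", "2"}
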