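import math

import numpy as np
import pandas as pd
import pytest

import cawave.model as cwm
from cawave.model import (
    CardiacActivityModel,
    compute_metrics,
    correlation_tables,
    ecfp_features,
    loco_cv,
    multi_peak_enrichment,
    pca_projection,
    point_biserial,
    replicate_distance_analysis,
    select_features,
)


class TestPointBiserial:
    def test_feature_equal_to_label_is_one(self):
        y = np.array([0, 1, 0, 1, 1, 0])
        assert point_biserial(y.astype(float), y) == pytest.approx(1.0)

    def test_identity_with_scipy_oracle(self):
        from scipy.stats import pointbiserialr

        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.normal(size=50)
            y = rng.integers(0, 2, size=50)
            if y.min() == y.max():
                continue
            assert point_biserial(x, y) == pytest.approx(
                pointbiserialr(y, x).statistic, abs=1e-12
            )

    def test_null_correlation_is_small(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=10_000)
        y = rng.integers(0, 2, size=10_000)
        assert abs(point_biserial(x, y)) < 0.05

    def test_single_class_and_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            point_biserial(np.arange(5.0), np.ones(5))
        with pytest.raises(ValueError):
            point_biserial(np.ones(6), np.array([0, 1, 0, 1, 0, 1]))


class TestSelectFeatures:
    def _tables(self, n_params=35, n=60, seed=0, signal=()):
        rng = np.random.default_rng(seed)
        y = np.tile([0, 1], n // 2)
        X = pd.DataFrame(
            rng.normal(size=(n, n_params)),
            columns=[f"p{i:02d}" for i in range(n_params)],
        )
        for name in signal:
            X[name] = X[name] + 3.0 * y
        corrs, inter = correlation_tables(X, y)
        return corrs, inter

    def test_default_k_returns_25(self):
        corrs, inter = self._tables()
        assert len(select_features(corrs, inter, k=25)) == 25

    def test_duplicated_feature_pruned(self):
        rng = np.random.default_rng(1)
        y = np.tile([0, 1], 30)
        X = pd.DataFrame({"a": rng.normal(size=60)})
        X["b"] = X["a"]  # exact duplicate
        X["c"] = rng.normal(size=60)
        corrs, inter = correlation_tables(X, y)
        with pytest.warns(UserWarning, match="survive"):
            selected = select_features(corrs, inter, k=3)
        assert len(selected) == 2
        assert len({"a", "b"} & set(selected)) == 1

    def test_planted_signal_ranks_top(self):
        signal = [f"p{i:02d}" for i in range(5)]
        corrs, inter = self._tables(signal=signal)
        top5 = select_features(corrs, inter, k=5)
        assert set(top5) == set(signal)

    def test_k_larger_than_survivors_warns(self):
        corrs, inter = self._tables(n_params=10)
        with pytest.warns(UserWarning):
            assert len(select_features(corrs, inter, k=25)) == 10


class TestPCAProjection:
    def test_collinear_data_pc1_explains_all(self):
        x = np.linspace(0, 1, 20)
        coords, evr = pca_projection(np.column_stack([x, 2 * x]))
        assert evr[0] == pytest.approx(1.0, abs=1e-12)

    def test_rank2_distances_preserved(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(15, 2)) @ rng.normal(size=(2, 6))
        coords, _ = pca_projection(X)
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(pdist(coords), pdist(X), atol=1e-9)

    def test_matches_covariance_eigensolver_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 5))
        _, evr = pca_projection(X)
        Xc = X - X.mean(axis=0)
        eig = np.sort(np.linalg.eigvalsh(np.cov(Xc.T)))[::-1]
        np.testing.assert_allclose(evr, eig[:2] / eig.sum(), atol=1e-12)


class TestECFP:
    def test_vector_length_2048(self):
        assert ecfp_features("CCO").shape == (2048,)

    def test_methane_sets_at_least_one_bit(self):
        assert ecfp_features("C").sum() >= 1

    def test_deterministic(self):
        a = ecfp_features("CC(=O)Oc1ccccc1C(=O)O")
        b = ecfp_features("CC(=O)Oc1ccccc1C(=O)O")
        np.testing.assert_array_equal(a, b)

    def test_invalid_smiles_rejected(self):
        with pytest.raises(ValueError, match="SMILES"):
            ecfp_features("not-a-molecule(((")


class TestComputeMetrics:
    def test_perfect_predictions(self):
        p = np.array([1.0, 1.0, 0.0, 0.0])
        y = np.array([1, 1, 0, 0])
        metrics, _ = compute_metrics(p, y)
        assert all(v == 1.0 for v in metrics.values())

    def test_uninformative_probabilities(self):
        p = np.full(8, 0.5)
        y = np.array([1, 0] * 4)
        metrics, _ = compute_metrics(p, y)
        assert metrics["auc"] == pytest.approx(0.5)

    def test_hand_built_compound_table(self):
        # 4 compounds x 2 samples; compound means: A .8(1) B .3(1) C .6(0) D .2(0)
        compounds = list("AABBCCDD")
        p = np.array([0.9, 0.7, 0.4, 0.2, 0.5, 0.7, 0.1, 0.3])
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        metrics, _ = compute_metrics(p, y, compounds, mode="compound_wise")
        # confusion at 0.5: TP=1 (A), FN=1 (B), FP=1 (C), TN=1 (D)
        assert metrics["accuracy"] == pytest.approx(0.5)
        assert metrics["precision"] == pytest.approx(0.5)
        assert metrics["recall"] == pytest.approx(0.5)
        # ranks: A(.8) > C(.6) > B(.3) > D(.2) -> 3 of 4 active/inactive pairs ordered
        assert metrics["auc"] == pytest.approx(0.75)

    def test_single_class_auc_signalled(self):
        with pytest.raises(ValueError, match="single-class"):
            compute_metrics(np.array([0.2, 0.8]), np.array([1, 1]))

    def test_conflicting_compound_labels_rejected(self):
        with pytest.raises(ValueError, match="conflicting"):
            compute_metrics(
                np.array([0.1, 0.9]), np.array([0, 1]), ["A", "A"],
                mode="compound_wise",
            )


def _toy_dataset(n_compounds=8, replicates=3, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_compounds):
        label = i % 2
        for r in range(replicates):
            feats = rng.normal(size=6) + 4.0 * label
            rows.append({"compound": f"C{i}", "label": label, "feats": feats})
    X = pd.DataFrame([r["feats"] for r in rows],
                     columns=[f"f{j}" for j in range(6)])
    return X, [r["compound"] for r in rows], [r["label"] for r in rows]


class TestLocoCV:
    def test_separable_data_perfect_auc(self):
        X, comp, y = _toy_dataset()
        report = loco_cv(X, comp, y, n_features=4, seed=1)
        assert report.metrics_compound_wise["auc"] == 1.0

    def test_heldout_compound_never_in_training(self, monkeypatch):
        X, comp, y = _toy_dataset()
        X = X.copy()
        X["code"] = pd.factorize(np.asarray(comp))[0].astype(float)
        seen = {}
        real_fit = cwm.RandomForestClassifier.fit

        def spy(self, Xt, yt):
            seen[len(seen)] = np.unique(np.asarray(Xt)[:, -1])
            return real_fit(self, Xt, yt)

        monkeypatch.setattr(cwm.RandomForestClassifier, "fit", spy)
        loco_cv(X, comp, y, select=False, seed=1)
        codes = pd.factorize(np.asarray(comp))[0]
        held_out = sorted(set(codes))
        for fold, train_codes in zip(held_out, seen.values()):
            assert fold not in train_codes

    def test_single_class_training_fold_aborts(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(4, 3)))
        with pytest.raises(ValueError, match="single-class"):
            loco_cv(X, ["A", "A", "B", "B"], [1, 1, 0, 0], select=False, seed=0)

    def test_fixed_seed_reproducible(self):
        X, comp, y = _toy_dataset()
        a = loco_cv(X, comp, y, select=False, seed=7)
        b = loco_cv(X, comp, y, select=False, seed=7)
        pd.testing.assert_frame_equal(a.sample_predictions, b.sample_predictions)

    def test_compound_probability_is_mean_of_samples(self):
        X, comp, y = _toy_dataset()
        report = loco_cv(X, comp, y, select=False, seed=1)
        merged = report.sample_predictions.groupby("compound")["probability"].mean()
        for _, row in report.compound_predictions.iterrows():
            assert row["probability"] == pytest.approx(merged[row["compound"]])


class TestReplicateDistances:
    def test_identical_replicates_have_zero_distance(self):
        X = pd.DataFrame([[1.0, 2.0]] * 3 + [[5.0, 5.0]] * 3)
        comp = ["A"] * 3 + ["B"] * 3
        conc = [10.0] * 6
        labels = [1] * 6
        out = replicate_distance_analysis(X, comp, conc, labels)
        assert np.all(out[("replicate", "active")] == 0.0)
        assert np.all(out[("non_replicate", "active")] > 0)

    def test_mixed_label_pairs_excluded(self):
        X = pd.DataFrame([[0.0], [1.0]])
        out = replicate_distance_analysis(X, ["A", "B"], [1.0, 1.0], [0, 1])
        assert all(len(v) == 0 for v in out.values())

    def test_replicates_tighter_than_non_replicates(self, benchmark_artifacts):
        from cawave.parameters import DEFAULT_REGISTRY

        mod = benchmark_artifacts["modeling"]
        active = mod[mod["cardiac_active"] == 1]
        out = replicate_distance_analysis(
            active[DEFAULT_REGISTRY.analysis_names()],
            active["compound_id"],
            active["std_concentration"],
            active["cardiac_active"],
        )
        rep = out[("replicate", "active")]
        non = out[("non_replicate", "active")]
        assert np.median(rep) < np.median(non)


class TestMultiPeakEnrichment:
    def test_zero_observed_gives_one(self):
        assert multi_peak_enrichment(0, 6, 0.094) == 1.0

    def test_matches_exhaustive_enumeration(self):
        # paper-style background: 11/116 vehicle controls with multi-peaks
        p0 = 11 / 116
        n, k = 6, 5
        exact = sum(
            math.comb(n, j) * p0**j * (1 - p0) ** (n - j) for j in range(k, n + 1)
        )
        assert multi_peak_enrichment(k, n, p0) == pytest.approx(exact, abs=1e-15)

    def test_monotone_decreasing_in_observed_count(self):
        ps = [multi_peak_enrichment(k, 10, 0.1) for k in range(11)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError):
            multi_peak_enrichment(1, 0, 0.1)


class TestModelResultsObjects:
    def test_from_dataframe_and_summary(self):
        X, comp, y = _toy_dataset()
        df = X.copy()
        df["compound_id"] = comp
        df["cardiac_active"] = y
        model = CardiacActivityModel.from_dataframe(
            df, feature_columns=X.columns, conc_col=None, smiles_col=None,
            n_features=4,
        )
        results = model.fit(seed=3)
        text = results.summary()
        assert "auc" in text and "compound-wise" in text
        assert results.metrics("compound_wise")["auc"] == 1.0
        assert set(results.sample_predictions.columns) == {
            "compound", "label", "probability"
        }

    def test_fingerprint_baseline_requires_smiles(self):
        X, comp, y = _toy_dataset()
        model = CardiacActivityModel(X, comp, y)
        with pytest.raises(ValueError, match="SMILES"):
            model.fit_fingerprint_baseline()
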