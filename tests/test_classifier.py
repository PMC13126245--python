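"""Classifier pipeline: feature selection, clustering, training, attribution."""

import numpy as np
import pandas as pd
import pytest

from bcl3meth import classifier as clf
from bcl3meth import synth

SMALL_CONFIG = dict(n_variable=500, k_clusters=50, n_trees=100, seed=0)


@pytest.fixture(scope="module")
def trained(cohort_small_module):
    beta, sheet = cohort_small_module
    labels = clf.labels_from_sheet(sheet)
    config = clf.ClassifierConfig(**SMALL_CONFIG)
    fitted, metrics = clf.train_classifier(beta, labels, config)
    return beta, labels, fitted, metrics


@pytest.fixture(scope="module")
def cohort_small_module():
    ann = synth.generate_annotation(2000, seed=1)
    cfg = synth.CohortConfig(
        n_cases=20, n_controls=10, n_cpgs=2000, n_hypo=196, n_hyper=4,
        delta_beta=0.35, precision=80.0, purity_range=(0.8, 1.0), seed=7,
    )
    beta, sheet, _ = synth.generate_cohort(cfg, ann)
    return beta, sheet


class TestVariableSelection:
    def test_constant_cpg_ranked_last(self):
        beta = pd.DataFrame(
            {"s1": [0.1, 0.9, 0.5], "s2": [0.9, 0.1, 0.5], "s3": [0.5, 0.5, 0.5]},
            index=["cgA", "cgB", "cgC"],
        )
        order = clf.select_variable_cpgs(beta, 3)
        assert order[-1] == "cgC"

    def test_descending_variance_order(self):
        beta = pd.DataFrame(
            {
                "s1": [0.0, 0.4, 0.5],
                "s2": [0.4, 0.5, 0.5],
                "s3": [0.8, 0.6, 0.5],
            },
            index=["cgA", "cgB", "cgC"],
        )
        assert clf.select_variable_cpgs(beta, 2) == ["cgA", "cgB"]

    def test_equal_variance_ties_lexicographic(self):
        beta = pd.DataFrame(
            {"s1": [0.2, 0.2, 0.2], "s2": [0.6, 0.6, 0.6]},
            index=["cgZ", "cgA", "cgM"],
        )
        assert clf.select_variable_cpgs(beta, 3) == ["cgA", "cgM", "cgZ"]

    def test_n_too_large_rejected(self):
        beta = pd.DataFrame({"s1": [0.1], "s2": [0.3]}, index=["cgA"])
        with pytest.raises(ValueError):
            clf.select_variable_cpgs(beta, 2)


class TestClusterRepresentatives:
    def test_k_equals_n_identity(self):
        rng = np.random.default_rng(0)
        beta = pd.DataFrame(rng.uniform(size=(6, 8)), index=[f"cg{i}" for i in range(6)])
        reps = clf.cluster_representatives(beta, list(beta.index), k=6, seed=0)
        assert sorted(reps) == sorted(beta.index)

    def test_two_separated_groups_one_rep_each(self):
        rng = np.random.default_rng(1)
        lo = 0.05 + rng.normal(0, 0.01, size=(5, 10))
        hi = 0.95 + rng.normal(0, 0.01, size=(5, 10))
        beta = pd.DataFrame(
            np.clip(np.vstack([lo, hi]), 0, 1),
            index=[f"lo{i}" for i in range(5)] + [f"hi{i}" for i in range(5)],
        )
        reps = clf.cluster_representatives(beta, list(beta.index), k=2, seed=3)
        assert len(reps) == 2
        assert {r[:2] for r in reps} == {"lo", "hi"}

    def test_seed_determinism(self, cohort_small_module):
        beta, _ = cohort_small_module
        cpgs = list(beta.index[:300])
        a = clf.cluster_representatives(beta, cpgs, 20, seed=5)
        b = clf.cluster_representatives(beta, cpgs, 20, seed=5)
        assert a == b


class TestTraining:
    def test_strong_planted_effect_perfect_separation(self, trained):
        _, _, _, metrics = trained
        assert metrics.auroc == pytest.approx(1.0)

    def test_pipeline_containment(self, trained):
        beta, labels, fitted, _ = trained
        assert set(fitted.feature_ids) <= set(fitted.variable_cpgs)
        sig, _ = clf.extract_signature(fitted, beta, labels)
        assert set(sig.cpg_ids) <= set(fitted.feature_ids)

    def test_null_labels_auroc_near_chance(self, cohort_small_module):
        beta, sheet = cohort_small_module
        labels = clf.labels_from_sheet(sheet)
        aurocs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            shuffled = pd.Series(
                rng.permutation(labels.to_numpy()), index=labels.index
            )
            config = clf.ClassifierConfig(
                n_variable=200, k_clusters=20, n_trees=50, test_fraction=0.3, seed=seed
            )
            _, metrics = clf.train_classifier(beta, shuffled, config)
            aurocs.append(metrics.auroc)
        assert 0.3 <= float(np.median(aurocs)) <= 0.7

    def test_signal_ablation_collapses_to_chance(self, cohort_small_module):
        ann = synth.generate_annotation(2000, seed=1)
        cfg = synth.CohortConfig(
            n_cases=20, n_controls=10, n_cpgs=2000, n_hypo=196, n_hyper=4,
            delta_beta=0.35, precision=80.0, purity_range=(0.8, 1.0), seed=7,
        )
        beta, sheet, truth = synth.generate_cohort(cfg, ann)
        ablated = beta.drop(index=list(truth["cpg_id"]))
        labels = clf.labels_from_sheet(sheet)
        config = clf.ClassifierConfig(**SMALL_CONFIG)
        _, metrics = clf.train_classifier(ablated, labels, config)
        assert abs(metrics.auroc - 0.5) <= 0.35

    def test_determinism_across_runs(self, cohort_small_module):
        beta, sheet = cohort_small_module
        labels = clf.labels_from_sheet(sheet)
        config = clf.ClassifierConfig(**SMALL_CONFIG)
        f1, m1 = clf.train_classifier(beta, labels, config)
        f2, m2 = clf.train_classifier(beta, labels, config)
        assert m1.to_dict() == m2.to_dict()
        assert f1.feature_ids == f2.feature_ids
        s1, _ = clf.extract_signature(f1, beta, labels)
        s2, _ = clf.extract_signature(f2, beta, labels)
        assert s1.cpg_ids == s2.cpg_ids
        assert s1.directions == s2.directions

    def test_small_class_rejected(self, cohort_small_module):
        beta, sheet = cohort_small_module
        labels = clf.labels_from_sheet(sheet).iloc[:22]  # 20 cases, 2 others
        with pytest.raises(ValueError):
            clf.train_classifier(beta, labels, clf.ClassifierConfig(**SMALL_CONFIG))


class TestAttribution:
    def test_local_accuracy(self, trained):
        beta, labels, fitted, _ = trained
        X = beta.loc[fitted.feature_ids, list(labels.index)].T
        base, contrib = clf.attribute(fitted, X)
        recon = base + contrib.sum(axis=1).to_numpy()
        proba = fitted.case_proba(X.to_numpy())
        np.testing.assert_allclose(recon, proba, atol=1e-6)

    def test_unused_feature_attribution_zero(self):
        rng = np.random.default_rng(4)
        n = 40
        X = pd.DataFrame(
            {
                "informative": np.r_[rng.uniform(0.0, 0.3, n // 2), rng.uniform(0.7, 1.0, n // 2)],
                "constant": np.full(n, 0.5),
            },
            index=[f"s{i}" for i in range(n)],
        )
        y = pd.Series(["case"] * (n // 2) + ["other"] * (n // 2), index=X.index)
        from sklearn.ensemble import RandomForestClassifier

        model = RandomForestClassifier(n_estimators=20, random_state=0).fit(X, y)
        fitted = clf.FittedClassifier(
            model=model, feature_ids=list(X.columns), train_ids=list(X.index),
            test_ids=[], config=clf.ClassifierConfig(n_variable=2, k_clusters=2, n_signature=2),
        )
        _, contrib = clf.attribute(fitted, X)
        assert (contrib["constant"] == 0).all()
        assert contrib["informative"].abs().sum() > 0

    def test_single_stump_puts_all_mass_on_split_feature(self):
        X = pd.DataFrame(
            {"f1": [0.1, 0.2, 0.8, 0.9], "f2": [0.5, 0.5, 0.5, 0.5]},
            index=["a", "b", "c", "d"],
        )
        y = pd.Series(["case", "case", "other", "other"], index=X.index)
        from sklearn.ensemble import RandomForestClassifier

        model = RandomForestClassifier(
            n_estimators=1, max_depth=1, max_features=None, random_state=0, bootstrap=False
        ).fit(X, y)
        fitted = clf.FittedClassifier(
            model=model, feature_ids=["f1", "f2"], train_ids=list(X.index),
            test_ids=[], config=clf.ClassifierConfig(n_variable=2, k_clusters=2, n_signature=2),
        )
        base, contrib = clf.attribute(fitted, X)
        assert (contrib["f2"] == 0).all()
        np.testing.assert_allclose(
            base + contrib["f1"].to_numpy(), fitted.case_proba(X.to_numpy()), atol=1e-12
        )


class TestSignatureAndClassify:
    def test_signature_of_all_features(self, trained):
        beta, labels, fitted, _ = trained
        sig, _ = clf.extract_signature(fitted, beta, labels, n=len(fitted.feature_ids))
        assert sorted(sig.cpg_ids) == sorted(fitted.feature_ids)

    def test_hypo_dominated_effects_give_low_directions(self, trained):
        beta, labels, fitted, _ = trained
        sig, _ = clf.extract_signature(fitted, beta, labels)
        n_low = sum(1 for d in sig.directions.values() if d == clf.LOW)
        assert n_low > len(sig.cpg_ids) / 2

    def test_reduced_model_close_to_full(self, trained):
        beta, labels, fitted, metrics = trained
        sig, _ = clf.extract_signature(fitted, beta, labels)
        assert abs(sig.metrics.auroc - metrics.auroc) <= 0.02

    def test_classify_batch_order_invariant(self, trained):
        beta, labels, fitted, _ = trained
        sig, _ = clf.extract_signature(fitted, beta, labels)
        sub = beta[list(labels.index[:8])]
        fwd = clf.classify(sig, sub)
        rev = clf.classify(sig, sub[list(reversed(sub.columns))])
        pd.testing.assert_frame_equal(fwd.loc[rev.index], rev)

    def test_training_case_classified_as_case(self, trained):
        beta, labels, fitted, _ = trained
        sig, _ = clf.extract_signature(fitted, beta, labels)
        case_id = labels.index[labels == "case"][0]
        out = clf.classify(sig, beta[case_id])
        assert out["label"].iloc[0] == "case"

    def test_probability_boundary_is_case(self):
        sig = clf.SignatureModel(
            cpg_ids=["cgA"], directions={"cgA": clf.LOW},
            model=clf._JSONForest([{  # single stump with leaf prob exactly 0.5
                "children_left": [1, -1, -1], "children_right": [2, -1, -1],
                "feature": [0, -2, -2], "threshold": [0.5, -2.0, -2.0],
                "case_prob": [0.5, 0.5, 0.7],
            }]),
        )
        beta = pd.DataFrame({"s": [0.2]}, index=["cgA"])
        out = clf.classify(sig, beta)
        assert out["probability"].iloc[0] == pytest.approx(0.5)
        assert out["label"].iloc[0] == "case"

    def test_missing_signature_cpgs_listed(self, trained):
        beta, labels, fitted, _ = trained
        sig, _ = clf.extract_signature(fitted, beta, labels)
        with pytest.raises(ValueError, match=sig.cpg_ids[0]):
            clf.classify(sig, beta.drop(index=sig.cpg_ids[0]))

    def test_json_round_trip_preserves_predictions(self, trained):
        beta, labels, fitted, _ = trained
        sig, _ = clf.extract_signature(fitted, beta, labels)
        restored = clf.SignatureModel.from_json(sig.to_json())
        sub = beta[list(labels.index[:6])]
        np.testing.assert_allclose(
            clf.classify(sig, sub)["probability"],
            clf.classify(restored, sub)["probability"],
            atol=1e-9,
        )
        assert restored.directions == sig.directions


class TestModelResultsSurface:
    def test_fit_returns_summary_and_predictions(self, cohort_small_module):
        beta, sheet = cohort_small_module
        labels = clf.labels_from_sheet(sheet)
        model = clf.TranslocationClassifier(beta, labels, clf.ClassifierConfig(**SMALL_CONFIG))
        res = model.fit()
        text = res.summary()
        assert "AUROC" in text and "signature" in text
        preds = res.predict(beta[list(labels.index[:5])])
        assert set(preds.columns) == {"probability", "label"}
        assert len(res.signature.cpg_ids) == res.config.n_signature
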