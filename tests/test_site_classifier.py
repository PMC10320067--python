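"""AdaBoost stump ensemble: training mechanics, prediction, evaluation.

The hand-check values come from running one AdaBoost round on paper:
four equally weighted points with one misclassified by the best stump
give e_1 = 1/4 and alpha_1 = 0.5*ln(3).  sklearn's AdaBoostClassifier
serves as an independent cross-check oracle on a generated table.
"""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import AdaBoostClassifier
from sklearn.metrics import roc_auc_score
from sklearn.tree import DecisionTreeClassifier

from allomap.errors import (
    ConsistencyError,
    EmptyProfileError,
    FeatureValidationError,
    TrainingError,
)
from allomap.fixtures import make_feature_table
from allomap.pocket_finder import Pocket, PocketDescriptors
from allomap.rae_profile import RaeProfile
from allomap.site_classifier import (
    SiteFeatureVector,
    Stump,
    TrainedEnsemble,
    evaluate,
    extract_features,
    load_model,
    predict_sites,
    read_feature_table,
    save_model,
    train_adaboost,
    write_feature_table,
)
from allomap.structure_io import ResidueId


def _rows(xs, labels):
    return [
        SiteFeatureVector(pocket_id=i, hydrophobicity=float(x), flexibility=0.0,
                          rae=0.0, label=bool(l))
        for i, (x, l) in enumerate(zip(xs, labels))
    ]


class TestExtractFeatures:
    def _pocket(self, pid=0):
        return Pocket(pid, frozenset([ResidueId("A", 1, "", "ALA")]),
                      np.zeros((1, 3)))

    def test_pass_through(self):
        v = extract_features(
            self._pocket(),
            PocketDescriptors(hydrophobicity=1.2, flexibility=-0.3),
            RaeProfile(0, [ResidueId("A", 1, "", "ALA")], np.array([0.6])),
        )
        assert (v.hydrophobicity, v.flexibility, v.rae) == (1.2, -0.3, 0.6)

    def test_pocket_id_mismatch_rejected(self):
        with pytest.raises(ConsistencyError):
            extract_features(
                self._pocket(0),
                PocketDescriptors(0.0, 0.0),
                RaeProfile(1, [ResidueId("A", 1, "", "ALA")], np.array([0.6])),
            )


class TestTraining:
    def test_separable_toy_perfect_after_one_round(self):
        model = train_adaboost(_rows([0, 1, 2, 3], [0, 0, 1, 1]), n_rounds=1)
        preds = predict_sites(model, _rows([0, 1, 2, 3], [0, 0, 1, 1]))
        calls = {p.pocket_id: p.is_allosteric for p in preds}
        assert calls == {0: False, 1: False, 2: True, 3: True}

    def test_hand_computed_first_round(self):
        # points (0,+), (2,+), (1,-), (3,-): the best stump misclassifies
        # exactly one of four equally weighted points
        model = train_adaboost(_rows([0, 2, 1, 3], [1, 1, 0, 0]), n_rounds=1)
        alpha = model.stumps[0].alpha
        assert alpha == pytest.approx(0.5 * math.log(3.0), abs=1e-9)
        # alpha = 0.5*ln((1-e)/e) with e = 0.25

    def test_single_class_rejected(self):
        with pytest.raises(TrainingError):
            train_adaboost(_rows([0, 1], [1, 1]))

    def test_non_finite_features_rejected(self):
        rows = _rows([0, np.nan, 2, 3], [0, 0, 1, 1])
        with pytest.raises(FeatureValidationError):
            train_adaboost(rows)

    def test_all_alphas_positive(self):
        # every completed round must have weighted error < 0.5, i.e. alpha > 0
        table = make_feature_table(n=200, seed=3)
        model = train_adaboost(table, n_rounds=50, seed=3)
        assert all(s.alpha > 0 for s in model.stumps)
        assert all(np.isfinite(s.alpha) for s in model.stumps)

    def test_label_flip_negates_decision_function(self):
        table = make_feature_table(n=120, seed=9)
        flipped = table.assign(label=1 - table["label"])
        m1 = train_adaboost(table, n_rounds=10, balance_classes=False)
        m2 = train_adaboost(flipped, n_rounds=10, balance_classes=False)
        x = make_feature_table(n=40, seed=10)[
            ["hydrophobicity", "flexibility", "rae"]
        ].to_numpy()
        assert np.allclose(m1.decision_function(x), -m2.decision_function(x),
                           atol=1e-9)

    def test_feature_shift_invariance(self):
        # adding a constant to a feature is absorbed by refitted scaling
        table = make_feature_table(n=150, seed=4)
        shifted = table.assign(rae=table["rae"] + 100.0)
        m1 = train_adaboost(table, n_rounds=15)
        m2 = train_adaboost(shifted, n_rounds=15)
        x = make_feature_table(n=30, seed=5)[
            ["hydrophobicity", "flexibility", "rae"]
        ].to_numpy()
        x_shift = x.copy()
        x_shift[:, 2] += 100.0
        assert np.allclose(m1.decision_function(x),
                           m2.decision_function(x_shift), atol=1e-9)


class TestPrediction:
    def test_empty_rows_empty_output(self):
        model = train_adaboost(_rows([0, 1, 2, 3], [0, 0, 1, 1]))
        assert predict_sites(model, []) == []

    def test_zero_margin_maps_to_half_confidence(self):
        model = TrainedEnsemble(
            stumps=[Stump(0, 0.0, 1, 1.0), Stump(0, 0.0, -1, 1.0)],
            n_rounds=2, scale_mean=np.zeros(3), scale_std=np.ones(3),
        )
        pred = predict_sites(model, [SiteFeatureVector(0, 5.0, 0.0, 0.0)])[0]
        assert pred.confidence == pytest.approx(0.5)
        assert pred.is_allosteric  # threshold is inclusive at 0.5

    def test_output_sorted_by_confidence(self):
        table = make_feature_table(n=100, seed=6)
        model = train_adaboost(table, n_rounds=20)
        preds = predict_sites(model, table)
        confs = [p.confidence for p in preds]
        assert confs == sorted(confs, reverse=True)

    def test_heldout_auc_on_planted_signal(self):
        train = make_feature_table(n=500, seed=11)
        test = make_feature_table(n=500, seed=12)
        model = train_adaboost(train, n_rounds=50)
        conf = [p.confidence for p in predict_sites(model, test)]
        order = {p.pocket_id: p.confidence for p in predict_sites(model, test)}
        y = test["label"].to_numpy()
        scores = np.array([order[i] for i in test["pocket_id"]])
        assert roc_auc_score(y, scores) > 0.9

    def test_agrees_with_sklearn_adaboost_oracle(self):
        table = make_feature_table(n=300, seed=13)
        x = table[["hydrophobicity", "flexibility", "rae"]].to_numpy()
        y = table["label"].to_numpy()
        ours = train_adaboost(table, n_rounds=30, balance_classes=False)
        ref = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1), n_estimators=30,
            random_state=0,
        ).fit(x, y)
        auc_ours = roc_auc_score(y, ours.decision_function(x))
        auc_ref = roc_auc_score(y, ref.decision_function(x))
        assert abs(auc_ours - auc_ref) < 0.05


class TestEvaluate:
    def _table(self):
        # 2 proteins, 5 pockets; hand-set features so calls are forced by
        # a single-stump model thresholding the rae feature at 0
        return pd.DataFrame({
            "protein_id": ["p1", "p1", "p1", "p2", "p2"],
            "pocket_id": [0, 1, 2, 3, 4],
            "hydrophobicity": [0.0] * 5,
            "flexibility": [0.0] * 5,
            "rae": [5.0, -5.0, -5.0, -5.0, -5.0],
            "label": [1, 1, 0, 1, 0],
        })

    def _threshold_model(self):
        return TrainedEnsemble(
            stumps=[Stump(2, 0.0, 1, 1.0)], n_rounds=1,
            scale_mean=np.zeros(3), scale_std=np.ones(3),
        )

    def test_hand_counted_confusion(self):
        # positives: pockets 0,1 (p1) and 3 (p2); only pocket 0 is called
        # positive -> site recall 1/3, protein recall 1/2
        m = evaluate(self._threshold_model(), self._table())
        assert m["site_recall"] == pytest.approx(1 / 3)
        assert m["protein_recall"] == pytest.approx(1 / 2)

    def test_perfect_classifier(self):
        table = self._table().assign(rae=[5.0, 5.0, -5.0, 5.0, -5.0])
        m = evaluate(self._threshold_model(), table)
        assert m["site_recall"] == 1.0
        assert m["protein_recall"] == 1.0
        assert m["roc_auc"] == 1.0

    def test_no_positive_labels_rejected(self):
        table = self._table().assign(label=0)
        with pytest.raises(EmptyProfileError):
            evaluate(self._threshold_model(), table)

    def test_random_confidence_auc_near_half(self):
        # permutation null: scoring by noise gives AUC ~ 0.5 across seeds
        aucs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            y = np.repeat([0, 1], 100)
            scores = rng.random(200)
            aucs.append(roc_auc_score(y, scores))
        assert abs(np.mean(aucs) - 0.5) < 0.05


class TestPersistence:
    def test_model_roundtrip(self, tmp_path):
        table = make_feature_table(n=100, seed=2)
        model = train_adaboost(table, n_rounds=10, seed=2)
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        x = table[["hydrophobicity", "flexibility", "rae"]].to_numpy()
        assert np.allclose(model.decision_function(x),
                           loaded.decision_function(x))

    def test_table_roundtrip(self, tmp_path):
        table = make_feature_table(n=50, seed=1)
        path = tmp_path / "table.tsv"
        write_feature_table(table, path)
        again = read_feature_table(path)
        pd.testing.assert_frame_equal(table, again)
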