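import numpy as np
import pytest

from lhseg.classify import (
    BONA_FIDE,
    TrainingSet,
    TreeModel,
    bona_fide,
    classify,
    train,
)
from lhseg.zlink import Object3D


def _ts(rows, labels, names):
    return TrainingSet(
        features=[dict(zip(names, r)) for r in rows], labels=list(labels)
    )


NAMES2 = ["f0", "f1"]


class TestTrain:
    def test_linearly_separable_depth_one(self):
        rows = [(0.1, 5), (0.3, 7), (0.9, 4), (0.8, 6)]
        labels = ["HSC1", "HSC1", "FALSE", "FALSE"]
        model = train(_ts(rows, labels, NAMES2), cv_folds=2, feature_names=NAMES2)
        assert model.selected_features() == ["f0"]
        preds = [model.predict_one(dict(zip(NAMES2, r))) for r in rows]
        assert preds == labels

    def test_relative_margin_breaks_ties_toward_wider_gap(self):
        # both features split perfectly; f0 has a wide relative gap,
        # f1 a sliver -- the tree must pick f0
        rows = [(0.0, 0.49), (0.1, 0.50), (0.9, 0.51), (1.0, 0.52)]
        labels = ["HSC1", "HSC1", "FALSE", "FALSE"]
        model = train(_ts(rows, labels, NAMES2), cv_folds=2, feature_names=NAMES2)
        assert model.selected_features() == ["f0"]

    def test_contradictory_duplicates_majority_leaf(self):
        rows = [(1.0, 0.0)] * 5
        labels = ["HSC2", "HSC2", "FALSE", "FALSE", "FALSE"]
        model = train(_ts(rows, labels, NAMES2), cv_folds=2, feature_names=NAMES2)
        assert model.predict_one({"f0": 1.0, "f1": 0.0}) == "FALSE"

    def test_exact_tie_resolves_by_class_order(self):
        rows = [(1.0, 0.0)] * 4
        labels = ["HSC1", "HSC1", "FALSE", "FALSE"]
        model = train(_ts(rows, labels, NAMES2), cv_folds=2, feature_names=NAMES2)
        assert model.predict_one({"f0": 1.0, "f1": 0.0}) == "HSC1"

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            _ts([(1, 2)], ["HSC1"], NAMES2)

    def test_determinism(self):
        rng = np.random.default_rng(0)
        rows = rng.normal(size=(20, 2))
        labels = ["HSC1" if r[0] + 0.2 * r[1] > 0 else "FALSE" for r in rows]
        m1 = train(_ts(rows, labels, NAMES2), seed=3, feature_names=NAMES2)
        m2 = train(_ts(rows, labels, NAMES2), seed=3, feature_names=NAMES2)
        assert m1.to_json() == m2.to_json()

    def test_serialization_roundtrip(self):
        rows = [(0.1, 5), (0.9, 4), (0.5, 9), (0.4, 1)]
        labels = ["HSC1", "FALSE", "HSC2", "HSC1"]
        model = train(_ts(rows, labels, NAMES2), cv_folds=2, feature_names=NAMES2)
        back = TreeModel.from_json(model.to_json())
        assert back.root == model.root
        assert back.feature_names == model.feature_names

    def test_cross_check_against_reference_cart(self):
        """On cleanly separated clusters, held-out predictions agree
        with an independent CART implementation."""
        from sklearn.tree import DecisionTreeClassifier

        rng = np.random.default_rng(1)
        a = rng.normal([0, 0], 0.3, (15, 2))
        b = rng.normal([3, 3], 0.3, (15, 2))
        X = np.vstack([a, b])
        y = ["HSC1"] * 15 + ["FALSE"] * 15
        mine = train(_ts(X, y, NAMES2), cv_folds=3, feature_names=NAMES2)
        ref = DecisionTreeClassifier(criterion="gini", random_state=0).fit(X, y)
        test = rng.normal([1.5, 1.5], 2.0, (50, 2))
        mine_pred = [mine.predict_one(dict(zip(NAMES2, r))) for r in test]
        ref_pred = list(ref.predict(test))
        agree = np.mean([m == r for m, r in zip(mine_pred, ref_pred)])
        assert agree >= 0.9


class TestClassify:
    def _obj(self, feats, oid=0):
        o = Object3D(id=oid, members=[])
        o.features = feats
        return o

    def test_empty_list(self):
        rows = [(0.1, 5), (0.9, 4)]
        model = train(
            _ts(rows, ["HSC1", "FALSE"], NAMES2), cv_folds=2, feature_names=NAMES2
        )
        assert classify(model, []) == []

    def test_memorized_point_and_bona_fide_filter(self):
        rows = [(0.1, 5), (0.9, 4), (0.5, 9)]
        labels = ["HSC1", "FALSE", "HSC2"]
        model = train(_ts(rows, labels, NAMES2), cv_folds=2, feature_names=NAMES2)
        objs = [
            self._obj({"f0": 0.1, "f1": 5}, 0),
            self._obj({"f0": 0.9, "f1": 4}, 1),
        ]
        classify(model, objs)
        assert objs[0].label == "HSC1"
        assert objs[1].label == "FALSE"
        assert [o.id for o in bona_fide(objs)] == [0]
        assert set(BONA_FIDE) == {"HSC1", "HSC2"}

    def test_missing_feature_errors(self):
        rows = [(0.1, 5), (0.9, 4)]
        model = train(
            _ts(rows, ["HSC1", "FALSE"], NAMES2), cv_folds=2, feature_names=NAMES2
        )
        o = self._obj({"f1": 4})
        with pytest.raises(KeyError):
            classify(model, [o])

    def test_unfeaturized_object_errors(self):
        rows = [(0.1, 5), (0.9, 4)]
        model = train(
            _ts(rows, ["HSC1", "FALSE"], NAMES2), cv_folds=2, feature_names=NAMES2
        )
        with pytest.raises(ValueError):
            classify(model, [Object3D(id=0, members=[])])


def test_archetype_training_set_fits_perfectly():
    """The curated 2/5/11 synthetic archetypes must be fully separated
    by the trained tree (resubstitution accuracy 1)."""
    from lhseg.benchmark import classifier_benchmark

    cb = classifier_benchmark(seed=0)
    assert cb["resubstitution_accuracy"] == 1.0
    assert len(cb["model"].selected_features()) >= 1
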