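import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from phasesep import classifier as clf
from phasesep.fixtures import make_labeled_features

DESK_HP = clf.Hyperparameters(n_estimators=60, max_depth=4)


@pytest.fixture(scope="module")
def separable():
    return make_labeled_features(50, 120, effect_size=3.0, seed=42)


class TestSplit:
    def _positives(self, n_id=10, n_noid=10):
        return pd.DataFrame(
            {
                "protein_id": [f"P{i}" for i in range(n_id + n_noid)],
                "label": ["ID-PSP"] * n_id + ["noID-PSP"] * n_noid,
            }
        )

    def _negatives(self, n=20):
        return pd.DataFrame(
            {"protein_id": [f"N{i}" for i in range(n)], "label": ["non-PSP"] * n}
        )

    def test_even_split(self):
        out = clf.split_dataset(self._positives(), self._negatives())
        for label in ("ID-PSP", "noID-PSP"):
            sub = out[out["label"] == label]
            assert (sub["split"] == "train").sum() == 5
            assert (sub["split"] == "test").sum() == 5

    def test_reserved_in_train(self):
        reserved = [f"P{i}" for i in range(4)]
        out = clf.split_dataset(self._positives(), self._negatives(), reserved_ids=reserved)
        assert (out[out["protein_id"].isin(reserved)]["split"] == "train").all()

    def test_deterministic(self):
        a = clf.split_dataset(self._positives(), self._negatives(), seed=42)
        b = clf.split_dataset(self._positives(), self._negatives(), seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_tiny_stratum_errors(self):
        pos = pd.DataFrame({"protein_id": ["P0"], "label": ["ID-PSP"]})
        with pytest.raises(ValueError, match="fewer than 2"):
            clf.split_dataset(pos, self._negatives())


class TestScaler:
    def test_affine_map(self):
        train = pd.DataFrame({"x": [0.0, 10.0]})
        params = clf.fit_scaler(train)
        out = clf.apply_scaler(params, pd.DataFrame({"x": [5.0]}))
        assert out["x"].iloc[0] == pytest.approx(0.5)

    def test_constant_column(self):
        params = clf.fit_scaler(pd.DataFrame({"x": [3.0, 3.0]}))
        out = clf.apply_scaler(params, pd.DataFrame({"x": [3.0, 7.0]}))
        assert (out["x"] == 0.0).all()

    def test_no_clipping(self):
        params = clf.fit_scaler(pd.DataFrame({"x": [0.0, 10.0]}))
        out = clf.apply_scaler(params, pd.DataFrame({"x": [12.0]}))
        assert out["x"].iloc[0] == pytest.approx(1.2)

    def test_missing_stays_missing(self):
        params = clf.fit_scaler(pd.DataFrame({"x": [0.0, np.nan, 10.0]}))
        out = clf.apply_scaler(params, pd.DataFrame({"x": [np.nan]}))
        assert np.isnan(out["x"].iloc[0])


class TestClassWeights:
    def test_equal_counts(self):
        w = clf.class_weights(["ID-PSP"] * 10 + ["noID-PSP"] * 10 + ["non-PSP"] * 10)
        assert len(set(w.tolist())) == 1

    def test_inverse_frequency(self):
        labels = ["ID-PSP"] * 10 + ["noID-PSP"] * 5 + ["non-PSP"] * 85
        w = clf.class_weights(labels)
        assert w[0] == pytest.approx(100 / 10)
        assert w[10] == pytest.approx(100 / 5)
        assert w[15] == pytest.approx(100 / 85)

    def test_equal_class_mass(self):
        labels = ["ID-PSP"] * 7 + ["noID-PSP"] * 3 + ["non-PSP"] * 40
        w = clf.class_weights(labels)
        masses = {
            cls: sum(wi for wi, l in zip(w, labels) if l == cls)
            for cls in set(labels)
        }
        assert len({round(m, 9) for m in masses.values()}) == 1


class TestSampleNegatives:
    def test_size(self):
        subset = clf.sample_negatives([f"N{i}" for i in range(100)], 10, 0)
        assert len(subset) == 20
        assert len(set(subset)) == 20

    def test_deterministic(self):
        pool = [f"N{i}" for i in range(100)]
        assert clf.sample_negatives(pool, 10, 3) == clf.sample_negatives(pool, 10, 3)

    def test_rounds_differ(self):
        pool = [f"N{i}" for i in range(200)]
        draws = {tuple(clf.sample_negatives(pool, 10, r)) for r in range(10)}
        assert len(draws) == 10

    def test_pool_too_small(self):
        with pytest.raises(ValueError, match="pool"):
            clf.sample_negatives(["N0", "N1"], 5, 0)


class TestEnsemble:
    def test_determinism(self, separable):
        m1 = clf.train_ensemble(separable, hp=DESK_HP, seed=42)
        m2 = clf.train_ensemble(separable, hp=DESK_HP, seed=42)
        probe = make_labeled_features(10, 10, effect_size=1.0, seed=7)
        s1, _ = clf.predict(m1, probe)
        s2, _ = clf.predict(m2, probe)
        assert np.array_equal(s1, s2)

    def test_separable_auroc(self, separable):
        model = clf.train_ensemble(separable, hp=DESK_HP, seed=42)
        held = make_labeled_features(50, 120, effect_size=3.0, seed=1)
        scores, _ = clf.predict(model, held)
        y = held["label"].isin(clf.POSITIVE_LABELS).astype(int)
        assert roc_auc_score(y, scores) >= 0.95

    def test_identical_subsets_equal_single_model(self):
        # a pool of exactly 2x positives forces every round onto the same rows
        df = make_labeled_features(20, 40, effect_size=2.0, seed=3)
        model = clf.train_ensemble(df, hp=DESK_HP, seed=42)
        probe = make_labeled_features(10, 10, effect_size=2.0, seed=9)
        scores, stds = clf.predict(model, probe)
        assert np.allclose(stds, 0.0)
        single = model.members[0]
        X = clf.apply_scaler(model.scaler, probe[model.schema]).to_numpy()
        assert np.allclose(scores, single.predict_proba(X)[:, 1])

    def test_default_ensemble_has_ten_members(self, separable):
        model = clf.train_ensemble(separable, hp=DESK_HP, seed=42)
        assert len(model.members) == clf.N_MEMBERS == 10

    def test_mean_bounds(self, separable):
        model = clf.train_ensemble(separable, hp=DESK_HP, seed=42)
        probe = make_labeled_features(15, 15, effect_size=1.0, seed=11)
        X = clf.apply_scaler(model.scaler, probe[model.schema]).to_numpy()
        member_scores = np.stack([m.predict_proba(X)[:, 1] for m in model.members])
        scores, _ = clf.predict(model, probe)
        assert (scores >= member_scores.min(axis=0) - 1e-12).all()
        assert (scores <= member_scores.max(axis=0) + 1e-12).all()

    def test_schema_mismatch(self, separable):
        model = clf.train_ensemble(separable, hp=DESK_HP, seed=42)
        probe = make_labeled_features(10, 10, effect_size=1.0, seed=7).drop(
            columns=["sticker_ssup"]
        )
        with pytest.raises(ValueError, match="schema"):
            clf.predict(model, probe)

    def test_save_load_round_trip(self, separable, tmp_path):
        model = clf.train_ensemble(separable, hp=DESK_HP, seed=42)
        model.save(tmp_path / "archive")
        loaded = clf.EnsembleModel.load(tmp_path / "archive")
        probe = make_labeled_features(10, 10, effect_size=1.0, seed=5)
        s1, _ = clf.predict(model, probe)
        s2, _ = clf.predict(loaded, probe)
        assert np.array_equal(s1, s2)


class TestTuning:
    def test_single_trial_returns_its_config(self, separable):
        best, history = clf.tune_hyperparameters(
            separable, n_trials=1, seed=42, n_members=2
        )
        assert len(history) == 1
        assert best == history[0][0]

    def test_argmax_property(self, separable):
        best, history = clf.tune_hyperparameters(
            separable, n_trials=3, seed=42, n_members=2
        )
        best_objective = max(h[1] for h in history)
        assert any(h[0] == best and h[1] == best_objective for h in history)
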