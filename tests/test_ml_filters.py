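import numpy as np
import pytest

from svlr.clustering import SignatureCluster
from svlr.ml_filters import (CLUSTER_MATRIX_ROWS, FilterModelBundle,
                             augment_low_depth, build_cluster_matrix,
                             cnn_filter, compute_bounds, generate_labels,
                             normalize, rf_filter, train_cnn, train_rf)
from svlr.ml_filters.cnn import CNN_CLASSES, ClusterFeatureMatrix
from svlr.models import Signature
from svlr.signatures import INTRA_FEATURES
from svlr.synthetic_data import (TruthSV, separable_cluster_matrices,
                                 separable_inter_vectors)

N = len(INTRA_FEATURES)


def _cluster(n, t="DEL", start=1000, rng=None):
    rng = rng or np.random.default_rng(0)
    members = []
    for i in range(n):
        s = start + int(rng.integers(-20, 21))
        sig = Signature(t=t, c="chr1", s=s, e=s + 100, read_name=f"r{i}",
                        source="intra", length=100,
                        features=rng.uniform(0, 10, N))
        members.append(sig)
    members.sort(key=lambda m: m.s)
    cl = SignatureCluster(t=t, c="chr1", members=members)
    cl.consensus_s = start
    cl.consensus_e = start + 100
    cl.length = 100
    return cl


BOUNDS = np.vstack([np.zeros(N), np.full(N, 10.0)])


class TestMatrix:
    def test_zero_filling(self):
        m = build_cluster_matrix(_cluster(40), BOUNDS)
        assert m.values.shape == (100, 25)
        assert m.depth == 40
        assert np.any(m.values[:40] != 0)
        assert np.all(m.values[40:] == 0)

    def test_min_max_formula(self):
        bounds = np.vstack([np.full(N, 2.0), np.full(N, 10.0)])
        cl = _cluster(1)
        cl.members[0].features = np.full(N, 6.0)
        m = build_cluster_matrix(cl, bounds)
        np.testing.assert_allclose(m.values[0], 0.5)

    def test_constant_feature_maps_to_zero_and_clipping(self):
        bounds = np.vstack([np.full(N, 3.0), np.full(N, 3.0)])
        x = np.full((2, N), 7.0)
        out = normalize(x, bounds)
        assert np.all(out == 0.0)
        wide = compute_bounds(np.array([[0.0] * N, [1.0] * N]))
        assert np.all(normalize(np.full((1, N), 9.9), wide) == 1.0)

    def test_oversized_cluster_keeps_nearest_members(self):
        rng = np.random.default_rng(5)
        cl = _cluster(130, rng=rng)
        m = build_cluster_matrix(cl, BOUNDS)
        assert m.depth == CLUSTER_MATRIX_ROWS
        devs = sorted(abs(mm.s - cl.consensus_s) for mm in cl.members)
        kept_max = devs[CLUSTER_MATRIX_ROWS - 1]
        # the kept rows are exactly those within the 100th-smallest deviation
        assert all(d <= kept_max for d in devs[:CLUSTER_MATRIX_ROWS])


class TestAugmentation:
    def test_counts_and_window_sizes(self):
        mats = augment_low_depth(_cluster(8), BOUNDS, rng_seed=1)
        assert len(mats) == 8
        assert all(m.depth < 8 for m in mats)

    def test_depth_one_is_identity(self):
        cl = _cluster(1)
        mats = augment_low_depth(cl, BOUNDS, rng_seed=1)
        np.testing.assert_array_equal(
            mats[0].values, build_cluster_matrix(cl, BOUNDS).values)

    def test_deterministic_under_seed(self):
        cl = _cluster(12)
        a = augment_low_depth(cl, BOUNDS, rng_seed=9)
        b = augment_low_depth(cl, BOUNDS, rng_seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.values, y.values)

    def test_rejects_high_depth(self):
        with pytest.raises(ValueError):
            augment_low_depth(_cluster(30), BOUNDS, rng_seed=0)


class TestLabels:
    TRUTH = [TruthSV("a", "DEL", "chr1", 10_000, 10_500, 500, "0/1"),
             TruthSV("b", "DUP", "chr1", 50_000, 51_000, 1000, "1/1")]

    def test_matching_rule(self):
        near = _cluster(3, start=10_005)
        near.consensus_e = near.consensus_s + 475
        near.length = 475  # ratio 0.95
        assert generate_labels([near], self.TRUTH) == ["DEL"]

    def test_far_item_is_false(self):
        far = _cluster(3, start=15_000)
        assert generate_labels([far], self.TRUTH) == ["false"]

    def test_type_taken_from_truth(self):
        ins = Signature(t="INS", c="chr1", s=50_010, e=51_010,
                        read_name="r", source="inter", length=1000)
        assert generate_labels([ins], self.TRUTH) == ["DUP"]

    def test_empty_truth_labels_all_false(self):
        assert generate_labels([_cluster(2)], []) == ["false"]


class TestRandomForest:
    def test_separable_data_high_f1_and_determinism(self):
        X, y = separable_inter_vectors(120, seed=2)
        a = train_rf(X, y, seed=2)
        b = train_rf(X, y, seed=2)
        assert a.heldout_macro_f1 >= 0.9
        assert a.best_params == b.best_params
        assert a.heldout_macro_f1 == b.heldout_macro_f1

    def test_filter_drops_false_and_relabels(self):
        X, y = separable_inter_vectors(120, seed=2)
        rf = train_rf(X, y, seed=2)
        sigs = []
        # craft one vector per class from the class means
        for cls in ("DEL", "INS", "false"):
            Xc = X[[i for i, lab in enumerate(y) if lab == cls][:1]]
            sigs.append(Signature(t="INS", c="chr1", s=100, e=150,
                                  read_name=cls, source="inter", length=50,
                                  features=Xc[0]))
        out = rf_filter(sigs, rf)
        names = {s.read_name: s.t for s in out}
        assert "false" not in names               # false prediction removed
        assert names.get("DEL") == "DEL"          # INS relabeled to DEL
        assert names.get("INS") == "INS"

    def test_single_class_rejected(self):
        X, _ = separable_inter_vectors(30, seed=0)
        with pytest.raises(ValueError):
            train_rf(X, ["DEL"] * len(X), seed=0)


class TestCNN:
    def test_separable_data_learns_and_is_deterministic(self):
        mats = separable_cluster_matrices(200, seed=4)
        a = train_cnn(mats, seed=4, batch_size=64)
        b = train_cnn(mats, seed=4, batch_size=64)
        assert a.heldout_accuracy >= 0.9
        assert a.final_loss == pytest.approx(b.final_loss, abs=1e-4)

    def test_zero_matrices_random_labels_give_chance(self):
        rng = np.random.default_rng(6)
        mats = [ClusterFeatureMatrix(values=np.zeros((100, N)), depth=5,
                                     label=CNN_CLASSES[int(rng.integers(0, 3))])
                for _ in range(300)]
        model = train_cnn(mats, seed=6, epochs=3)
        assert model.heldout_accuracy < 0.6

    def test_single_class_rejected(self):
        mats = separable_cluster_matrices(10, seed=0)
        for m in mats:
            m.label = "DEL"
        with pytest.raises(ValueError):
            train_cnn(mats, seed=0)

    def test_filter_semantics(self):
        mats = separable_cluster_matrices(80, seed=4)
        model = train_cnn(mats, seed=4, epochs=5)
        # a DUP cluster passes through untouched regardless of the model
        dup = _cluster(5, t="DUP")
        for m in dup.members:
            m.source = "inter"
        out = cnn_filter([dup], model, BOUNDS)
        assert out == [dup]


class TestBundle:
    def test_save_load_round_trip(self, tmp_path):
        X, y = separable_inter_vectors(120, seed=2)
        rf = train_rf(X, y, seed=2)
        mats = separable_cluster_matrices(60, seed=2)
        cnn = train_cnn(mats, seed=2, epochs=4)
        bundle = FilterModelBundle(rf=rf, cnn=cnn, cnn_bounds=BOUNDS, seed=2)
        path = bundle.save(str(tmp_path / "bundle"))
        back = FilterModelBundle.load(path)
        np.testing.assert_array_equal(rf.predict(X[:50]),
                                      back.rf.predict(X[:50]))
        stack = np.stack([m.values for m in mats[:20]])
        np.testing.assert_allclose(cnn.predict_proba(stack),
                                   back.cnn.predict_proba(stack), atol=1e-6)

    def test_schema_mismatch_refuses_to_load(self, tmp_path):
        import json, os
        X, y = separable_inter_vectors(60, seed=1)
        bundle = FilterModelBundle(rf=train_rf(X, y, seed=1))
        path = bundle.save(str(tmp_path / "bundle"))
        meta = json.load(open(os.path.join(path, "meta.json")))
        meta["inter_hash"] = "deadbeefdeadbeef"
        json.dump(meta, open(os.path.join(path, "meta.json"), "w"))
        from svlr.ml_filters.bundle import SchemaMismatchError
        with pytest.raises(SchemaMismatchError):
            FilterModelBundle.load(path)
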