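"""Autoencoders, the unified loss, end-to-end training, and checkpointing."""

import math

import numpy as np
import pandas as pd
import pytest

from driversig.neural_model import (
    Autoencoder,
    AutoencoderSpec,
    Batch,
    DrugResponseModel,
    FeatureSet,
    TrainConfig,
    bce,
    build_autoencoder,
    grid_search,
    predict_pairs,
    pretrain_autoencoder,
    train_end_to_end,
    unified_loss,
)
from driversig.neural_model import _eval_loss


def make_model(signature_size=4, mut_dim=12, drug_dim=16, seed=0):
    return DrugResponseModel.build(
        [f"p{i}" for i in range(signature_size)],
        AutoencoderSpec(mut_dim, 8, 6, 4),
        AutoencoderSpec(drug_dim, 10, 6, 4),
        seed=seed,
    )


def random_batch(rng, n=20, signature_size=4, mut_dim=12, drug_dim=16):
    return Batch(
        a=rng.standard_normal((n, signature_size)),
        r_c=(rng.random((n, mut_dim)) < 0.3).astype(float),
        r_d=(rng.random((n, drug_dim)) < 0.2).astype(float),
        s=rng.standard_normal(n),
    )


class TestSpecs:
    def test_width_ordering_enforced(self):
        with pytest.raises(ValueError, match="widths"):
            AutoencoderSpec(10, 12, 6, 3)
        with pytest.raises(ValueError, match="widths"):
            AutoencoderSpec(10, 8, 3, 6)

    def test_parameter_count_closed_form(self):
        spec = AutoencoderSpec(534, 300, 100, 30)
        ae = build_autoencoder(spec, seed=0)
        actual = sum(p.value.size for p in ae.parameters())
        # batchnorm running statistics are state but not trainable parameters
        assert actual == spec.n_parameters

    def test_predictor_input_dim_from_reference_widths(self):
        # 38 signature pathways + two 30-dim bottlenecks -> 98-unit input layer
        model = DrugResponseModel.build(
            [f"p{i}" for i in range(38)],
            AutoencoderSpec(534, 300, 100, 30),
            AutoencoderSpec(1024, 300, 100, 30),
            seed=0,
        )
        assert model.predictor.spec.input_dim == 98
        assert model.predictor.spec.hidden == (98, 98)


class TestAutoencoder:
    def test_seeded_init_identical(self):
        spec = AutoencoderSpec(20, 12, 8, 4)
        a = build_autoencoder(spec, seed=3)
        b = build_autoencoder(spec, seed=3)
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.value, pb.value)

    def test_reconstruction_in_unit_interval(self, rng):
        ae = build_autoencoder(AutoencoderSpec(20, 12, 8, 4), seed=0)
        x = (rng.random((6, 20)) < 0.3).astype(float)
        out = ae.reconstruct(x)
        assert np.all((out > 0) & (out < 1))

    def test_overfits_memorizable_set(self, rng):
        x = (rng.random((50, 64)) < 0.25).astype(float)
        ae = build_autoencoder(AutoencoderSpec(64, 32, 16, 8), seed=0)
        from driversig.neural_model import _train_autoencoder

        # full-batch Adam: batch statistics match inference statistics
        _train_autoencoder(ae, x, epochs=500, lr=1e-2, batch_size=50,
                           rng=np.random.default_rng(0))
        assert bce(ae.reconstruct(x), x) < 0.05


class TestUnifiedLoss:
    def test_matches_scalar_loop_oracle(self, rng):
        for _ in range(5):
            n, dc, dd = 7, 5, 6
            s = rng.standard_normal(n)
            sp = rng.standard_normal(n)
            rc = (rng.random((n, dc)) < 0.5).astype(float)
            rd = (rng.random((n, dd)) < 0.5).astype(float)
            pc = rng.uniform(0.01, 0.99, (n, dc))
            pd_ = rng.uniform(0.01, 0.99, (n, dd))
            lc, ld = 0.7, 1.3
            got = unified_loss(s, sp, rc, pc, rd, pd_, lc, ld).total

            mse = sum((si - pi) ** 2 for si, pi in zip(s, sp)) / n
            def loop_bce(p, y):
                tot = 0.0
                for i in range(p.shape[0]):
                    for j in range(p.shape[1]):
                        tot += -(y[i, j] * math.log(p[i, j])
                                 + (1 - y[i, j]) * math.log(1 - p[i, j]))
                return tot / p.size
            want = mse + lc * loop_bce(pc, rc) + ld * loop_bce(pd_, rd)
            assert abs(got - want) < 1e-10

    def test_half_probability_gives_ln2_per_bit(self):
        y = np.array([[0.0, 1.0], [1.0, 0.0]])
        p = np.full_like(y, 0.5)
        assert bce(p, y) == pytest.approx(math.log(2), abs=1e-12)

    def test_perfect_prediction_leaves_reconstruction_terms(self, rng):
        s = rng.standard_normal(5)
        rc = np.zeros((5, 3))
        pc = np.full((5, 3), 0.4)
        loss = unified_loss(s, s, rc, pc, rc, pc)
        assert loss.mse == 0.0
        assert loss.total == pytest.approx(loss.bce_c + loss.bce_d)

    def test_probabilities_outside_unit_interval_rejected(self):
        y = np.zeros((2, 2))
        bad = np.array([[0.5, 1.5], [0.5, 0.5]])
        with pytest.raises(ValueError, match="outside"):
            bce(bad, y)


class TestForward:
    def test_batched_order_preserving(self, rng):
        model = make_model()
        b = random_batch(rng, n=11)
        preds = model.predict(b.a, b.r_c, b.r_d, chunk=4)
        whole = model.forward(b.a, b.r_c, b.r_d)["s_pred"]
        assert np.array_equal(preds, whole)

    def test_dimension_mismatch_names_block(self, rng):
        model = make_model()
        b = random_batch(rng)
        with pytest.raises(ValueError, match="mutation block"):
            model.forward(b.a, b.r_c[:, :5], b.r_d)
        with pytest.raises(ValueError, match="fingerprint block"):
            model.forward(b.a, b.r_c, b.r_d[:, :5])
        with pytest.raises(ValueError, match="activity block"):
            model.forward(b.a[:, :2], b.r_c, b.r_d)


class TestTraining:
    def test_history_deterministic_given_seed(self, rng):
        train = random_batch(rng, n=40)
        val = random_batch(rng, n=12)
        cfg = TrainConfig(batch_size=8, max_epochs=5, patience=5, seed=9)
        h1 = train_end_to_end(make_model(seed=2), train, val, cfg).history
        h2 = train_end_to_end(make_model(seed=2), train, val, cfg).history
        assert h1 == h2

    def test_returned_state_is_best_validation_state(self, rng):
        train = random_batch(rng, n=40)
        val = random_batch(rng, n=12)
        cfg = TrainConfig(batch_size=8, max_epochs=15, patience=3, seed=0)
        model = train_end_to_end(make_model(seed=1), train, val, cfg)
        final_val, _ = _eval_loss(model, val, cfg.lambda_c, cfg.lambda_d)
        best_recorded = min(h["val_loss"] for h in model.history)
        assert final_val == pytest.approx(best_recorded, abs=1e-12)

    def test_patience_counts_consecutive_non_improvements(self, rng):
        train = random_batch(rng, n=30)
        val = random_batch(rng, n=10)
        cfg = TrainConfig(batch_size=8, max_epochs=50, patience=1, seed=0)
        model = train_end_to_end(make_model(seed=1), train, val, cfg)
        # with patience 1, training stops on the first non-improving epoch
        monitored = [h["val_loss"] for h in model.history]
        assert all(b < a for a, b in zip(monitored[:-2], monitored[1:-1]))
        assert monitored[-1] >= monitored[-2]

    def test_empty_sets_rejected(self, rng):
        b = random_batch(rng, n=10)
        empty = b.subset(np.array([], dtype=int))
        with pytest.raises(ValueError, match="non-empty"):
            train_end_to_end(make_model(), empty, b, TrainConfig())


class TestPretrain:
    def test_single_combination_grid_returned(self, rng):
        x = (rng.random((30, 20)) < 0.3).astype(float)
        grid = {"hidden1": (12,), "hidden2": (8,), "bottleneck": (4,)}
        best, results = pretrain_autoencoder(x, grid, epochs=3, seed=0)
        assert (best.hidden1, best.hidden2, best.bottleneck) == (12, 8, 4)
        assert len(results) == 1

    def test_non_binary_features_rejected(self, rng):
        with pytest.raises(ValueError, match="binary"):
            pretrain_autoencoder(rng.standard_normal((10, 8)),
                                 {"hidden1": (4,), "hidden2": (3,), "bottleneck": (2,)})

    def test_infeasible_widths_rejected(self, rng):
        x = (rng.random((10, 8)) < 0.3).astype(float)
        with pytest.raises(ValueError, match="combination"):
            pretrain_autoencoder(x, {"hidden1": (300,), "hidden2": (100,),
                                     "bottleneck": (30,)})


class TestGridSearch:
    def test_single_combination_returned(self, rng):
        train = random_batch(rng, n=30)
        val = random_batch(rng, n=10)
        test = random_batch(rng, n=10)
        best, results = grid_search(
            train, val, test, lambda seed: make_model(seed=seed),
            lrs=(1e-3,), batch_sizes=(8,), epochs=2,
        )
        assert best.learning_rate == 1e-3 and best.batch_size == 8
        assert len(results) == 1
        assert {"rmse", "pcc"} <= set(results.columns)


class TestCheckpoint:
    def test_round_trip_bitwise(self, tmp_path, rng):
        model = make_model(seed=5)
        train = random_batch(rng, n=30)
        val = random_batch(rng, n=10)
        train_end_to_end(model, train, val,
                         TrainConfig(batch_size=8, max_epochs=3, patience=3))
        path = tmp_path / "ckpt.npz"
        model.save(path)
        clone = DrugResponseModel.load(path)
        b = random_batch(rng, n=7)
        assert np.array_equal(
            model.predict(b.a, b.r_c, b.r_d), clone.predict(b.a, b.r_c, b.r_d)
        )
        assert clone.signature == model.signature
        assert clone.history == model.history


class TestPredictPairs:
    def make_features(self, rng, cells=("c1", "c2", "c3"), drugs=("d1", "d2")):
        return FeatureSet(
            activities=pd.DataFrame(rng.standard_normal((4, len(cells))),
                                    index=[f"p{i}" for i in range(4)], columns=cells),
            mutations=pd.DataFrame((rng.random((12, len(cells))) < 0.3).astype(int),
                                   index=[f"g{i}" for i in range(12)], columns=cells),
            fingerprints=pd.DataFrame((rng.random((16, len(drugs))) < 0.2).astype(int),
                                      index=range(16), columns=drugs),
        )

    def test_permuted_pairs_get_permuted_predictions(self, rng):
        model = make_model()
        features = self.make_features(rng)
        pairs = pd.DataFrame({
            "cell_id": ["c1", "c2", "c3", "c1"],
            "drug_id": ["d1", "d2", "d1", "d2"],
            "ln_ic50": [0.0, 1.0, 2.0, 3.0],
        })
        fwd, _ = predict_pairs(model, features, pairs)
        rev, _ = predict_pairs(model, features, pairs.iloc[::-1].reset_index(drop=True))
        assert np.allclose(fwd["s_pred"].to_numpy(), rev["s_pred"].to_numpy()[::-1])

    def test_missing_features_reported_not_dropped_silently(self, rng):
        model = make_model()
        features = self.make_features(rng)
        pairs = pd.DataFrame({
            "cell_id": ["c1", "cX"],
            "drug_id": ["d1", "d1"],
            "ln_ic50": [0.0, 0.0],
        })
        preds, rejects = predict_pairs(model, features, pairs)
        assert len(preds) == 1
        assert rejects["reason"].tolist() == ["missing cell features"]

    def test_no_predictable_pair_is_error(self, rng):
        model = make_model()
        features = self.make_features(rng)
        pairs = pd.DataFrame({"cell_id": ["cX"], "drug_id": ["dX"], "ln_ic50": [0.0]})
        with pytest.raises(ValueError, match="no pair"):
            predict_pairs(model, features, pairs)
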