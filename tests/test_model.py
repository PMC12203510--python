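"""Synergy model: encoder contracts, prediction head, masking, training loop."""

import numpy as np
import pytest

from synfuse.drug_features import DrugFeaturizer
from synfuse.model import (
    ModelConfig,
    SynergyModel,
    encode_combination,
    loss,
    mask_features,
)
from synfuse.nn import TransformerBlock
from synfuse.records import DrugRecord, EmbeddingTable, ValidationError

TINY = dict(h=2, d=16, n_layers=1, cell_dim=4, head_widths=(8, 4),
            dropout=0.0, batch_size=8, max_epochs=5, seed=0)


def _model(**over):
    return SynergyModel(ModelConfig(**{**TINY, **over}))


class TestEncodeCombination:
    def test_flatten_length_is_8d(self, rng):
        blocks = [TransformerBlock(16, 2, rng)]
        fd = encode_combination(rng.standard_normal((8, 16)), blocks)
        assert fd.shape == (8 * 16,)

    def test_flatten_reshape_inverse(self, rng):
        blocks = [TransformerBlock(16, 2, rng)]
        tokens = rng.standard_normal((8, 16))
        out = blocks[0].forward(tokens[None])[0]
        fd = encode_combination(tokens, blocks)
        np.testing.assert_array_equal(fd.reshape(8, 16), out)

    def test_no_attention_encoder_is_raw_flatten(self, rng):
        # disabling the attention module must leave the raw combination
        # feature, bit-exact
        model = _model(use_attention=False)
        tokens = rng.standard_normal((3, 8, 16))
        cells = rng.standard_normal((3, 4))
        model.forward(tokens, cells)
        np.testing.assert_array_equal(model._fd, tokens.reshape(3, -1))

    def test_permutation_equivariance_of_encoder(self, rng):
        model = _model()
        tokens = rng.standard_normal((1, 8, 16))
        perm = rng.permutation(8)
        cells = np.zeros((1, 4))
        model.forward(tokens, cells)
        fd = model._fd.reshape(8, 16).copy()
        model.forward(tokens[:, perm], cells)
        fd_perm = model._fd.reshape(8, 16)
        np.testing.assert_allclose(fd_perm, fd[perm], atol=1e-10)


class TestPredictHead:
    def test_eval_mode_deterministic_despite_dropout(self, rng):
        model = _model(dropout=0.5)
        tokens = rng.standard_normal((4, 8, 16))
        cells = rng.standard_normal((4, 4))
        np.testing.assert_array_equal(model.predict(tokens, cells),
                                      model.predict(tokens, cells))

    def test_zero_weights_give_zero_and_half(self, rng):
        tokens = rng.standard_normal((3, 8, 16))
        cells = rng.standard_normal((3, 4))
        for task, expected in (("regression", 0.0), ("classification", 0.5)):
            model = _model(task=task, use_attention=False)
            for p in model.head.params():
                p.value[...] = 0.0
            np.testing.assert_allclose(model.predict(tokens, cells),
                                       np.full(3, expected), atol=1e-12)

    def test_forward_matches_layer_by_layer_oracle(self, rng):
        model = _model(use_attention=False)
        tokens = rng.standard_normal((5, 8, 16))
        cells = rng.standard_normal((5, 4))
        out = model.predict(tokens, cells)
        x = np.hstack([tokens.reshape(5, -1), cells])
        for layer in model.head.layers:
            name = type(layer).__name__
            if name == "Dense":
                x = x @ layer.W.value + layer.b.value
            elif name == "BatchNorm1d":
                x = (layer.gamma.value * (x - layer.running_mean)
                     / np.sqrt(layer.running_var + layer.eps) + layer.beta.value)
            elif name == "ReLU":
                x = np.maximum(x, 0.0)
            # dropout is identity in eval mode
        np.testing.assert_allclose(out, x.ravel(), atol=1e-5)

    def test_symmetrized_prediction_order_invariant(self, rng):
        model = _model()
        t_ab = rng.standard_normal((6, 8, 16))
        t_ba = t_ab[:, [4, 5, 6, 7, 0, 1, 2, 3]]
        cells = rng.standard_normal((6, 4))
        fwd = model.predict_symmetric(t_ab, t_ba, cells)
        rev = model.predict_symmetric(t_ba, t_ab, cells)
        np.testing.assert_array_equal(fwd, rev)


class TestLoss:
    def test_zero_when_equal(self):
        y = np.array([1.0, -2.0, 3.0])
        assert loss(y, y) == 0.0

    def test_hand_arithmetic(self):
        assert loss(np.array([0.0, 2.0]), np.array([1.0, 1.0])) == 1.0

    def test_matches_loop_oracle(self, rng):
        y = rng.standard_normal(100)
        y_hat = rng.standard_normal(100)
        oracle = sum((a - b) ** 2 for a, b in zip(y, y_hat)) / 100
        assert loss(y, y_hat) == pytest.approx(oracle, abs=1e-12)

    def test_bce_matches_formula(self, rng):
        y = rng.integers(0, 2, size=50).astype(float)
        p = rng.uniform(0.01, 0.99, size=50)
        oracle = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert loss(y, p, task="classification") == pytest.approx(oracle, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            loss(np.array([]), np.array([]))


class TestModelGradient:
    def test_backprop_matches_finite_difference(self, rng):
        model = _model(dropout=0.0)
        tokens = rng.standard_normal((6, 8, 16))
        cells = rng.standard_normal((6, 4))
        y = rng.standard_normal(6)
        # freeze batch-norm running-stat updates for a clean comparison
        for bn in model._bn_layers():
            bn.momentum = 0.0
        for p in model.parameters():
            p.grad[...] = 0.0
        model.loss_and_grads(tokens, cells, y, training=True)
        analytic = [p.grad.copy() for p in model.parameters()]
        checked = 0
        eps = 1e-6
        param_rng = np.random.default_rng(0)
        for p, grad in zip(model.parameters(), analytic):
            flat = p.value.ravel()
            for idx in param_rng.choice(flat.size, size=min(3, flat.size),
                                        replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                hi = model.loss_and_grads(tokens, cells, y, training=True)
                flat[idx] = orig - eps
                lo = model.loss_and_grads(tokens, cells, y, training=True)
                flat[idx] = orig
                num = (hi - lo) / (2 * eps)
                got = grad.ravel()[idx]
                if abs(num) > 1e-6:  # below this FD noise dominates
                    assert abs(got - num) / abs(num) < 1e-4
                    checked += 1
        assert checked > 10


def _toy_training_data(rng, n=120):
    tokens = rng.standard_normal((n, 8, 16))
    cells = rng.standard_normal((n, 4))
    pairs = [(f"D{i % 10}", f"E{i % 12}") for i in range(n)]
    return tokens, cells, pairs


class TestTraining:
    def test_same_seed_same_result(self, rng):
        tokens, cells, pairs = _toy_training_data(rng)
        y = tokens[:, 0, 0] + cells[:, 0]
        runs = []
        for _ in range(2):
            model = _model(max_epochs=10, dropout=0.3, seed=5)
            h = model.fit(tokens, cells, y, pairs)
            runs.append((h.train_loss, h.val_loss,
                         model.predict(tokens[:5], cells[:5]).tolist()))
        assert runs[0] == runs[1]

    def test_early_stop_triggers_on_pure_noise(self, rng):
        tokens, cells, pairs = _toy_training_data(rng)
        y = rng.standard_normal(len(pairs))
        model = _model(max_epochs=200, patience=10, lr=1e-3)
        h = model.fit(tokens, cells, y, pairs)
        # stopped within patience (+1 for the triggering epoch) of the best
        assert h.n_epochs <= h.best_epoch + 10 + 1
        assert h.n_epochs < 200

    def test_learns_planted_linear_signal(self, rng):
        tokens, cells, pairs = _toy_training_data(rng, n=200)
        y = 2.0 * tokens[:, 0, 0] - cells[:, 1]
        model = _model(max_epochs=150, patience=150, lr=3e-3)
        h = model.fit(tokens, cells, y, pairs)
        assert min(h.val_loss) < 0.5 * h.val_loss[0]

    def test_single_pair_rejected(self, rng):
        tokens = rng.standard_normal((3, 8, 16))
        cells = rng.standard_normal((3, 4))
        with pytest.raises(ValidationError):
            _model().fit(tokens, cells, np.zeros(3), [("A", "B")] * 3)


class TestMaskFeatures:
    @pytest.fixture
    def featurizer(self, rng):
        table = EmbeddingTable({f"P{i}": rng.standard_normal(8) for i in range(6)})
        drugs = {
            "A": DrugRecord("A", target_ids={"P0", "P1"}, pathway_ids={"PW0"}),
            "B": DrugRecord("B", target_ids={"P2"}, pathway_ids={"PW1"}),
        }
        fps = {"A": (rng.random(16) < 0.3).astype(float),
               "B": (rng.random(16) < 0.3).astype(float)}
        return DrugFeaturizer(drugs, table, {"PW0": {"P4"}, "PW1": {"P5"}},
                              fingerprints=fps, n_bits=16, d=16), table

    def test_empty_drop_is_noop(self, featurizer):
        fz, _ = featurizer
        np.testing.assert_array_equal(mask_features(fz, "A", "B").tokens,
                                      fz.combination("A", "B").tokens)

    def test_drop_only_target_zeroes_token(self, featurizer):
        fz, _ = featurizer
        cf = mask_features(fz, "A", "B", drop_targets={"P2"})
        np.testing.assert_array_equal(cf.tokens[6], np.zeros(16))  # drug B d^t
        base = fz.combination("A", "B").tokens
        np.testing.assert_array_equal(cf.tokens[:6], base[:6])
        np.testing.assert_array_equal(cf.tokens[7], base[7])

    def test_drop_one_of_two_targets_recomputes_mean(self, featurizer):
        fz, table = featurizer
        cf = mask_features(fz, "A", "B", drop_targets={"P1"})
        np.testing.assert_allclose(cf.tokens[2, :8], table["P0"], atol=1e-12)
        base = fz.combination("A", "B").tokens
        changed = [i for i in range(8)
                   if not np.array_equal(cf.tokens[i], base[i])]
        assert changed == [2]

    def test_unannotated_id_warns_and_noops(self, featurizer, caplog):
        fz, _ = featurizer
        import logging
        with caplog.at_level(logging.WARNING):
            cf = mask_features(fz, "A", "B", drop_targets={"P9"})
        assert "P9" in caplog.text
        np.testing.assert_array_equal(cf.tokens,
                                      fz.combination("A", "B").tokens)
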