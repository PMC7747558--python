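"""Embedding, aggregation, LSTM forward/backward, loss and ranking."""

import copy
import math

import numpy as np
import pytest
from icuseq.model import (
    Adam,
    ModelConfig,
    aggregate_hour,
    embed,
    forward,
    forward_batch,
    importance_ranking,
    init_params,
    load_checkpoint,
    loss,
    loss_and_grads,
    pack_stays,
    save_checkpoint,
)
from icuseq.tokenization import TokenizedStay, build_vocabulary


def make_stay(hour_lists, outcome=1, window=6, stay_id="S1"):
    hours = [np.asarray(h, dtype=np.int64) for h in hour_lists]
    hours += [np.empty(0, dtype=np.int64)] * (window - len(hours))
    return TokenizedStay(stay_id=stay_id, outcome=outcome, hours=hours)


@pytest.fixture
def small_setup():
    cfg = ModelConfig(embedding_dim=16, hidden_units=32, embedding_dropout=0.0,
                      window=6)
    rng = np.random.default_rng(0)
    params = init_params(cfg, vocab_size=9, rng=rng)
    return cfg, params


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"embedding_dim": 17},
            {"hidden_units": 33},
            {"embedding_dropout": 1.0},
            {"architecture": "transformer"},
            {"aggregation": "max"},
        ],
    )
    def test_enumerations_validated(self, kwargs):
        with pytest.raises(ValueError):
            ModelConfig(**kwargs)


class TestEmbed:
    def test_lookup_identity_and_order(self, small_setup):
        _, params = small_setup
        out = embed([3, 5, 3], params.E)
        assert np.array_equal(out[0], params.E[3])
        assert np.array_equal(out[1], params.E[5])
        assert np.array_equal(out[2], params.E[3])

    def test_pad_row_is_zero(self, small_setup):
        _, params = small_setup
        assert np.array_equal(embed([0], params.E)[0], np.zeros(16))

    def test_out_of_range_fatal(self, small_setup):
        _, params = small_setup
        with pytest.raises(IndexError):
            embed([9], params.E)


class TestAggregateHour:
    def test_single_token_identity(self, small_setup):
        _, params = small_setup
        out = aggregate_hour([4], params.E, params.w)
        assert np.allclose(out, params.E[4], atol=1e-15)

    def test_equal_weights_symmetric_mean(self, small_setup):
        _, params = small_setup
        params.w[:] = 0.7
        out = aggregate_hour([2, 5], params.E, params.w)
        assert np.allclose(out, (params.E[2] + params.E[5]) / 2, atol=1e-12)

    def test_hand_computed_softmax(self, small_setup):
        """w = (ln1, ln2, ln3) gives weights 1/6, 2/6, 3/6 exactly."""
        _, params = small_setup
        params.w[2], params.w[3], params.w[4] = math.log(1), math.log(2), math.log(3)
        out = aggregate_hour([2, 3, 4], params.E, params.w)
        expected = (1 * params.E[2] + 2 * params.E[3] + 3 * params.E[4]) / 6
        assert np.allclose(out, expected, atol=1e-12)

    def test_empty_hour_zero_vector(self, small_setup):
        _, params = small_setup
        assert np.array_equal(aggregate_hour([], params.E, params.w), np.zeros(16))

    def test_permutation_invariance(self, small_setup):
        _, params = small_setup
        rng = np.random.default_rng(1)
        params.w[:] = rng.normal(size=9)
        for _ in range(100):
            idx = rng.integers(1, 9, size=rng.integers(1, 8))
            perm = rng.permutation(idx)
            assert np.allclose(
                aggregate_hour(idx, params.E, params.w),
                aggregate_hour(perm, params.E, params.w),
                atol=1e-12,
            )

    def test_convex_combination_norm_bound(self, small_setup):
        _, params = small_setup
        rng = np.random.default_rng(2)
        for _ in range(50):
            idx = rng.integers(1, 9, size=rng.integers(1, 8))
            out = aggregate_hour(idx, params.E, params.w)
            max_norm = max(np.linalg.norm(params.E[i]) for i in idx)
            assert np.linalg.norm(out) <= max_norm + 1e-12

    def test_mean_aggregation_equals_equal_weights(self, small_setup):
        cfg, params = small_setup
        rng = np.random.default_rng(3)
        params.w[:] = 1.234  # all equal
        for _ in range(20):
            idx = rng.integers(1, 9, size=rng.integers(1, 8))
            assert np.allclose(
                aggregate_hour(idx, params.E, params.w, "learned-weights"),
                aggregate_hour(idx, params.E, params.w, "mean"),
                atol=1e-12,
            )


class TestForward:
    def test_all_empty_stay_valid_probs(self, small_setup):
        cfg, params = small_setup
        traj = forward(make_stay([], window=6), params, cfg)
        assert traj.probs.shape == (6,)
        assert np.all((traj.probs > 0) & (traj.probs < 1))

    def test_deterministic_without_dropout(self, small_setup):
        cfg, params = small_setup
        stay = make_stay([[1, 2], [3], [], [4, 5, 6]], window=6)
        p1 = forward(stay, params, cfg).probs
        p2 = forward(stay, params, cfg).probs
        assert np.array_equal(p1, p2)

    def test_matches_scalar_lstm_oracle(self, small_setup):
        """Step-by-step scalar recurrence reproduces the batched forward."""
        cfg, params = small_setup
        stay = make_stay([[1, 2], [3], [], [4, 5, 6], [7], [8]], window=6)
        probs = forward(stay, params, cfg).probs

        h = np.zeros(32)
        c = np.zeros(32)
        hu = 32
        for t in range(6):
            x = aggregate_hour(stay.hours[t], params.E, params.w)
            z = x @ params.Wx + h @ params.Wh + params.b
            i = 1 / (1 + np.exp(-z[:hu]))
            f = 1 / (1 + np.exp(-z[hu:2 * hu]))
            g = np.tanh(z[2 * hu:3 * hu])
            o = 1 / (1 + np.exp(-z[3 * hu:]))
            c = f * c + i * g
            h = o * np.tanh(c)
            p = 1 / (1 + np.exp(-(h @ params.head_w + params.head_b)))
            assert abs(p - probs[t]) < 1e-10

    def test_causality_under_future_mutation(self, small_setup):
        cfg, params = small_setup
        stay = make_stay([[1], [2], [3], [4], [5], [6]], window=6)
        base = forward(stay, params, cfg).probs
        mutated = copy.deepcopy(stay)
        mutated.hours[4] = np.array([7, 8], dtype=np.int64)
        mutated.hours[5] = np.empty(0, dtype=np.int64)
        changed = forward(mutated, params, cfg).probs
        assert np.array_equal(base[:4], changed[:4])
        assert not np.array_equal(base[4:], changed[4:])

    def test_mlp_baseline_is_per_hour(self, small_setup):
        """The ablation scores each hour independently of all other hours."""
        _, params16 = small_setup
        cfg = ModelConfig(embedding_dim=16, hidden_units=32, embedding_dropout=0.0,
                          window=6, architecture="mlp-baseline", mlp_depth=2)
        params = init_params(cfg, vocab_size=9, rng=np.random.default_rng(4))
        stay = make_stay([[1], [2], [3]], window=6)
        base = forward(stay, params, cfg).probs
        mutated = copy.deepcopy(stay)
        mutated.hours[1] = np.array([8], dtype=np.int64)
        changed = forward(mutated, params, cfg).probs
        assert base[1] != changed[1]
        unchanged = [t for t in range(6) if t != 1]
        assert np.array_equal(base[unchanged], changed[unchanged])


class TestLoss:
    def test_uniform_half_probability_closed_form(self):
        p = np.full((1, 48), 0.5)
        assert loss(p, [1]) == pytest.approx(48 * math.log(2), rel=1e-12)

    def test_two_hour_hand_computation(self):
        p = np.array([[0.9, 0.8]])
        assert loss(p, [1]) == pytest.approx(-(math.log(0.9) + math.log(0.8)),
                                             rel=1e-12)

    def test_perfect_prediction_near_zero(self):
        p = np.full((3, 5), 1.0)
        assert loss(p, [1, 1, 1]) < 1e-5
        assert loss(np.zeros((2, 5)), [0, 0]) < 1e-5

    def test_nonnegative(self):
        rng = np.random.default_rng(6)
        p = rng.random((4, 7))
        assert loss(p, [0, 1, 0, 1]) >= 0

    def test_nonbinary_outcome_fatal(self):
        with pytest.raises(ValueError):
            loss(np.full((1, 2), 0.5), [2])


class TestGradients:
    def test_finite_difference_gradcheck(self, small_setup):
        """Backprop through aggregation + LSTM + head matches numeric grads."""
        cfg, params = small_setup
        stays = [
            make_stay([[1, 2], [3], [], [4, 5, 6]], outcome=1, window=6),
            make_stay([[7], [], [8, 1]], outcome=0, window=6, stay_id="S2"),
        ]
        tokens, seg, y = pack_stays(stays, cfg.window)
        _, grads = loss_and_grads(tokens, seg, y, params, cfg, training_mode=False)

        rng = np.random.default_rng(7)
        eps = 1e-6
        arrs = params.arrays()
        for name in ["E", "w", "Wx", "Wh", "b", "head_w", "head_b"]:
            a = arrs[name]
            flat = a.reshape(-1)
            for _ in range(5):
                j = int(rng.integers(flat.size))
                if name == "E" and j < a.shape[1] if a.ndim == 2 else False:
                    continue  # PAD row is pinned
                orig = flat[j]
                flat[j] = orig + eps
                Lp, _ = loss_and_grads(tokens, seg, y, params, cfg, training_mode=False)
                flat[j] = orig - eps
                Lm, _ = loss_and_grads(tokens, seg, y, params, cfg, training_mode=False)
                flat[j] = orig
                num = (Lp - Lm) / (2 * eps)
                ana = grads[name].reshape(-1)[j]
                assert ana == pytest.approx(num, rel=1e-4, abs=1e-8), name

    def test_mlp_gradcheck(self):
        cfg = ModelConfig(embedding_dim=16, hidden_units=32, embedding_dropout=0.0,
                          window=4, architecture="mlp-baseline", mlp_depth=2)
        params = init_params(cfg, vocab_size=6, rng=np.random.default_rng(8))
        noise = np.random.default_rng(88)
        for i, (W, b) in enumerate(params.mlp):
            # keep every ReLU pre-activation away from its kink so the
            # central difference is valid
            b += noise.normal(0.05, 0.02, size=b.shape)
        stays = [make_stay([[1, 2], [3]], outcome=1, window=4)]
        tokens, seg, y = pack_stays(stays, cfg.window)
        _, grads = loss_and_grads(tokens, seg, y, params, cfg, training_mode=False)
        rng = np.random.default_rng(9)
        eps = 1e-6
        arrs = params.arrays()
        for name in ["mlp_W0", "mlp_b0", "mlp_W1", "head_w", "E", "w"]:
            flat = arrs[name].reshape(-1)
            for _ in range(4):
                j = int(rng.integers(flat.size))
                orig = flat[j]
                flat[j] = orig + eps
                Lp, _ = loss_and_grads(tokens, seg, y, params, cfg, training_mode=False)
                flat[j] = orig - eps
                Lm, _ = loss_and_grads(tokens, seg, y, params, cfg, training_mode=False)
                flat[j] = orig
                num = (Lp - Lm) / (2 * eps)
                ana = grads[name].reshape(-1)[j]
                if abs(num) < 1e-12 and abs(ana) < 1e-12:
                    continue
                assert ana == pytest.approx(num, rel=1e-4, abs=1e-8), name

    def test_single_adam_step_decreases_batch_loss(self, small_setup):
        cfg, params = small_setup
        stays = [make_stay([[1, 2], [3], [4]], outcome=1, window=6),
                 make_stay([[5], [6, 7]], outcome=0, window=6, stay_id="S2")]
        tokens, seg, y = pack_stays(stays, cfg.window)
        L0, grads = loss_and_grads(tokens, seg, y, params, cfg, training_mode=False)
        Adam(params, lr=1e-4).step(params, grads)
        L1, _ = loss_and_grads(tokens, seg, y, params, cfg, training_mode=False)
        assert L1 < L0

    def test_params_stay_finite_and_pad_pinned(self, small_setup):
        cfg, params = small_setup
        stays = [make_stay([[1, 2], [3]], outcome=1, window=6)]
        tokens, seg, y = pack_stays(stays, cfg.window)
        opt = Adam(params)
        rng = np.random.default_rng(10)
        for _ in range(20):
            _, grads = loss_and_grads(tokens, seg, y, params, cfg,
                                      training_mode=True, rng=rng)
            opt.step(params, grads)
        assert params.all_finite()
        assert np.array_equal(params.E[0], np.zeros(16))


class TestDropout:
    def test_zero_dropout_bitwise_deterministic(self, small_setup):
        cfg, params = small_setup
        stays = [make_stay([[1, 2, 3], [4]], window=6)]
        tokens, seg, _ = pack_stays(stays, cfg.window)
        p1, _ = forward_batch(tokens, seg, 1, params, cfg, training_mode=True,
                              rng=np.random.default_rng(0))
        p2, _ = forward_batch(tokens, seg, 1, params, cfg, training_mode=True,
                              rng=np.random.default_rng(99))
        assert np.array_equal(p1, p2)

    def test_dropout_renormalizes_over_survivors(self, small_setup):
        """With all but one token dropped, the hour equals that embedding."""
        cfg, params = small_setup
        cfg = ModelConfig(embedding_dim=16, hidden_units=32,
                          embedding_dropout=0.5, window=6)
        stays = [make_stay([[1, 2]], window=6)]
        tokens, seg, _ = pack_stays(stays, cfg.window)
        seen = set()
        for s in range(40):
            rng = np.random.default_rng(s)
            _, cache = forward_batch(tokens, seg, 1, params, cfg,
                                     training_mode=True, rng=rng)
            a = cache["agg"]["a"]
            seen.add(tuple(np.round(a, 12)))
            assert a.sum() == pytest.approx(1.0, abs=1e-12) or a.sum() == 0.0
        assert len(seen) > 1  # both survival patterns actually occur


class TestImportanceRanking:
    def test_unique_maximum_first_and_reserved_excluded(self):
        vocab = build_vocabulary(["alpha", "beta", "gamma"])
        w = np.array([9.0, 9.0, 0.1, 5.0, 0.2])  # PAD/UNK large but excluded
        ranked = importance_ranking(w, vocab)
        assert ranked[0] == ("beta", 5.0)
        assert all(tok not in ("<PAD>", "<UNK>") for tok, _ in ranked)

    def test_ties_break_lexicographically(self):
        vocab = build_vocabulary(["zeta", "eta", "theta"])
        w = np.array([0.0, 0.0, 1.0, 1.0, 1.0])
        ranked = importance_ranking(w, vocab)
        assert [t for t, _ in ranked] == ["eta", "theta", "zeta"]

    def test_top_k_truncates(self):
        vocab = build_vocabulary(["a", "b", "c"])
        ranked = importance_ranking(np.zeros(5), vocab, top_k=2)
        assert len(ranked) == 2


class TestCheckpoint:
    def test_roundtrip(self, small_setup, tmp_path):
        cfg, params = small_setup
        vocab = build_vocabulary([f"t{i}" for i in range(7)])
        save_checkpoint(tmp_path / "cp", params, cfg, vocab)
        loaded, loaded_cfg = load_checkpoint(tmp_path / "cp", expected_vocab_size=9)
        assert loaded_cfg == cfg
        for k, v in params.arrays().items():
            assert np.array_equal(v, loaded.arrays()[k])

    def test_vocab_size_mismatch_rejected(self, small_setup, tmp_path):
        cfg, params = small_setup
        save_checkpoint(tmp_path / "cp", params, cfg)
        with pytest.raises(ValueError):
            load_checkpoint(tmp_path / "cp", expected_vocab_size=100)
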