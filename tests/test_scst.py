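"""Losses, decoding, toy-policy gradients and the two-phase trainer."""

import math

import numpy as np
import pytest

from simplerl.scst import (
    Rollout,
    RolloutPair,
    SequencePair,
    TrainingConfig,
    encode_corpus,
    greedy_decode,
    load_checkpoint,
    make_toy_policy,
    mle_loss,
    pg_loss,
    sample_decode,
    save_checkpoint,
    scst_loss,
    total_loss,
    train,
    train_step,
    vocab_from_texts,
)

VOCAB = tuple("abcdefg") + (".", "</s>")


@pytest.fixture
def model():
    return make_toy_policy(VOCAB, embedding_dim=8, seed=3)


@pytest.fixture
def pair(model):
    return SequencePair(model.encode(("a", "b", "c")), model.encode(("d", "e", "</s>")))


def _rollout(logprobs, reward=None, mode="sampled", weights=None):
    return Rollout(
        tokens=tuple(range(len(logprobs))),
        per_token_logprob=np.array(logprobs, dtype=float),
        mode=mode,
        reward=reward,
        reward_weights=weights,
    )


class TestLosses:
    def test_mle_loss_zero_for_perfect_model(self):
        class Perfect:
            def sequence_logprobs(self, source, tokens):
                return np.zeros(len(tokens))

        assert mle_loss(Perfect(), SequencePair((0,), (1, 2))) == 0.0

    def test_mle_loss_uniform_model(self, model):
        # force uniform by zeroing the weights: -2*ln(1/V) over 2 target tokens
        model.set_params(np.zeros_like(model.get_params()))
        p = SequencePair(model.encode(("a",)), model.encode(("b", "c")))
        assert mle_loss(model, p) == pytest.approx(2 * math.log(len(VOCAB)))

    def test_mle_loss_single_halfprob_token(self):
        class Half:
            def sequence_logprobs(self, source, tokens):
                return np.full(len(tokens), math.log(0.5))

        assert mle_loss(Half(), SequencePair((0,), (1,))) == pytest.approx(math.log(2))

    def test_mle_loss_rejects_out_of_vocab(self, model):
        with pytest.raises(ValueError, match="outside vocabulary"):
            mle_loss(model, SequencePair((0,), (99,)))

    @pytest.mark.parametrize(
        "logprobs, reward, baseline, expected",
        [
            ([-1.0, -1.0], 0.7, 0.7, 0.0),
            ([-1.0, -1.0], 1.0, 0.0, 1.0),
            ([-1.0, -1.0], 0.0, 1.0, -1.0),
        ],
    )
    def test_pg_loss_sign_convention(self, logprobs, reward, baseline, expected):
        assert pg_loss(_rollout(logprobs, reward), baseline) == pytest.approx(expected)

    def test_scst_loss_uses_greedy_reward_as_baseline(self):
        sampled = _rollout([-0.5, -0.5], reward=0.9, weights=(1, 1, 1))
        greedy = _rollout([-0.1], reward=0.5, mode="greedy", weights=(1, 1, 1))
        rp = RolloutPair(sampled=sampled, greedy=greedy)
        assert rp.advantage == pytest.approx(0.4)
        assert scst_loss(rp) == pytest.approx(0.2)  # -(-0.5)*0.4

    def test_scst_loss_zero_at_equal_rewards(self):
        rp = RolloutPair(_rollout([-2.0], reward=0.5), _rollout([-1.0], reward=0.5, mode="greedy"))
        assert scst_loss(rp) == 0.0

    def test_scst_loss_negative_advantage(self):
        rp = RolloutPair(_rollout([-0.5, -0.5], reward=0.1), _rollout([-1.0], reward=0.5, mode="greedy"))
        assert scst_loss(rp) == pytest.approx(-0.2)

    def test_scst_loss_rejects_mismatched_weights(self):
        rp = RolloutPair(
            _rollout([-1.0], reward=0.5, weights=(1, 0, 0)),
            _rollout([-1.0], reward=0.5, mode="greedy", weights=(0, 1, 0)),
        )
        with pytest.raises(ValueError, match="weights"):
            scst_loss(rp)

    @pytest.mark.parametrize(
        "gamma, lpg, lml, expected",
        [(0.0, 2.0, 4.0, 4.0), (1.0, 2.0, 4.0, 2.0), (0.5, 2.0, 4.0, 3.0)],
    )
    def test_total_loss_convex_mixture(self, gamma, lpg, lml, expected):
        assert total_loss(lpg, lml, gamma) == pytest.approx(expected)

    def test_total_loss_endpoints_on_random_values(self):
        rng = np.random.default_rng(0)
        for lpg, lml in rng.normal(size=(20, 2)):
            assert total_loss(lpg, lml, 0.0) == pytest.approx(lml)
            assert total_loss(lpg, lml, 1.0) == pytest.approx(lpg)

    def test_total_loss_rejects_gamma_outside_unit_interval(self):
        for gamma in (-0.1, 1.1):
            with pytest.raises(ValueError):
                total_loss(1.0, 1.0, gamma)


class TestDecoding:
    def test_normalized_at_every_step(self, model):
        src = model.encode(("a", "b"))
        for prefix in [(), (0,), (0, 1)]:
            lp = model.token_logprobs(src, prefix)
            assert np.logaddexp.reduce(lp) == pytest.approx(0.0, abs=1e-12)

    def test_greedy_is_deterministic(self, model):
        src = model.encode(("a", "b", "c"))
        r1 = greedy_decode(model, src, 10)
        r2 = greedy_decode(model, src, 10)
        assert r1.tokens == r2.tokens
        assert np.array_equal(r1.per_token_logprob, r2.per_token_logprob)

    def test_greedy_tie_breaks_to_lowest_id(self, model):
        model.set_params(np.zeros_like(model.get_params()))  # uniform: all tied
        rollout = greedy_decode(model, model.encode(("a",)), 5)
        assert rollout.tokens[0] == 0

    def test_greedy_stops_at_eos(self, model):
        rollout = greedy_decode(model, model.encode(("a",)), 50)
        if model.eos_id in rollout.tokens:
            assert rollout.tokens.index(model.eos_id) == len(rollout.tokens) - 1
        else:
            assert len(rollout.tokens) == 50

    def test_sampling_reproducible_from_seed(self, model):
        src = model.encode(("a", "b"))
        r1 = sample_decode(model, src, 12, seed=99)
        r2 = sample_decode(model, src, 12, seed=99)
        assert r1.tokens == r2.tokens
        assert r1.seed == 99

    def test_deterministic_policy_sampling_equals_greedy(self, model):
        # a huge logit on one path makes the distribution effectively a delta
        params = np.zeros_like(model.get_params()).reshape(len(VOCAB), -1)
        params[model.eos_id, :] = 1e3
        model.set_params(params.ravel())
        src = model.encode(("a",))
        greedy = greedy_decode(model, src, 5)
        for seed in (0, 1, 2):
            assert sample_decode(model, src, 5, seed).tokens == greedy.tokens

    def test_sampling_frequency_matches_distribution(self, model):
        """First-token frequencies over many seeded draws track the softmax."""
        src = model.encode(("a", "b"))
        probs = np.exp(model.token_logprobs(src, ()))
        rng = np.random.default_rng(123)
        n = 4000
        draws = rng.choice(len(probs), size=n, p=probs)  # oracle sampler
        first = [sample_decode(model, src, 1, seed=s).tokens[0] for s in range(n)]
        for tok in range(len(VOCAB)):
            expected = probs[tok]
            se = math.sqrt(expected * (1 - expected) / n)
            assert np.mean(np.array(first) == tok) == pytest.approx(expected, abs=5 * se + 1e-3)
            assert np.mean(draws == tok) == pytest.approx(expected, abs=5 * se + 1e-3)


class TestToyPolicyGradients:
    def test_same_seed_same_parameters(self):
        m1 = make_toy_policy(VOCAB, embedding_dim=8, seed=7)
        m2 = make_toy_policy(VOCAB, embedding_dim=8, seed=7)
        assert np.array_equal(m1.get_params(), m2.get_params())

    def test_vocab_too_small_rejected(self):
        with pytest.raises(ValueError):
            make_toy_policy(("</s>",))

    def test_sequence_logprobs_consistent_with_stepwise(self, model, pair):
        seq = model.sequence_logprobs(pair.source_tokens, pair.target_tokens)
        step = [
            model.token_logprobs(pair.source_tokens, pair.target_tokens[:t])[
                pair.target_tokens[t]
            ]
            for t in range(len(pair.target_tokens))
        ]
        np.testing.assert_allclose(seq, step, rtol=1e-12)

    def _fd_grad(self, model, loss_fn, indices, eps=1e-6):
        p0 = model.get_params()
        grads = {}
        for i in indices:
            p = p0.copy()
            p[i] += eps
            model.set_params(p)
            up = loss_fn()
            p = p0.copy()
            p[i] -= eps
            model.set_params(p)
            down = loss_fn()
            grads[i] = (up - down) / (2 * eps)
        model.set_params(p0)
        return grads

    def test_mle_gradient_matches_finite_differences(self, model, pair):
        _, grad_logp = model.sequence_logprob_grad(pair.source_tokens, pair.target_tokens)
        analytic = -grad_logp  # loss = -sum logp
        rng = np.random.default_rng(5)
        idx = rng.choice(analytic.size, size=6, replace=False)
        fd = self._fd_grad(model, lambda: mle_loss(model, pair), idx)
        for i in idx:
            assert analytic[i] == pytest.approx(fd[i], abs=1e-5)

    def test_scst_gradient_matches_finite_differences(self, model, pair):
        """Gradient of -(mean logp)*advantage with the advantage held fixed."""
        sampled_tokens = model.encode(("b", "a", "</s>"))
        advantage = 0.37

        def loss():
            lp = model.sequence_logprobs(pair.source_tokens, sampled_tokens)
            return -float(lp.mean()) * advantage

        _, grad_logp = model.sequence_logprob_grad(pair.source_tokens, sampled_tokens)
        analytic = -(advantage / len(sampled_tokens)) * grad_logp
        rng = np.random.default_rng(8)
        idx = rng.choice(analytic.size, size=6, replace=False)
        fd = self._fd_grad(model, loss, idx)
        for i in idx:
            assert analytic[i] == pytest.approx(fd[i], abs=1e-5)


class TestTraining:
    @pytest.fixture
    def tiny(self, vocab, small_corpus, scorer):
        pairs = small_corpus[:10]
        toks = vocab_from_texts([p.source for p in pairs] + [p.reference for p in pairs])
        model = make_toy_policy(toks, embedding_dim=16, seed=2)
        corpus = encode_corpus(pairs, model)
        return model, corpus

    def test_zero_epochs_is_a_no_op(self, tiny, scorer):
        model, corpus = tiny
        before = model.get_params()
        trace = train(model, corpus, scorer, TrainingConfig(mle_epochs=0, rl_epochs=0))
        assert trace.records == []
        assert np.array_equal(model.get_params(), before)

    def test_zero_learning_rate_keeps_parameters(self, tiny, scorer):
        model, corpus = tiny
        before = model.get_params()
        train_step(model, corpus[:4], scorer, TrainingConfig(learning_rate=0.0))
        assert np.array_equal(model.get_params(), before)

    def test_same_seed_reproduces_trace_exactly(self, tiny, scorer):
        _, corpus = tiny
        cfg = TrainingConfig(seed=4, mle_epochs=1, rl_epochs=2, learning_rate=0.1)
        traces = []
        for _ in range(2):
            model = make_toy_policy(tiny[0].vocab, embedding_dim=16, seed=2)
            traces.append(train(model, corpus, scorer, cfg))
        assert traces[0].records == traces[1].records

    def test_gamma_zero_step_equals_pure_mle_step(self, tiny, scorer):
        model_a, corpus = tiny
        model_b = make_toy_policy(model_a.vocab, embedding_dim=16, seed=2)
        cfg = TrainingConfig(learning_rate=0.1, gamma=0.0)
        train_step(model_a, corpus[:4], scorer, cfg, gamma=0.0)
        # manual MLE step on the same batch
        grad = np.zeros_like(model_b.get_params())
        for p in corpus[:4]:
            _, g = model_b.sequence_logprob_grad(p.source_tokens, p.target_tokens)
            grad += -g
        model_b.set_params(model_b.get_params() - 0.1 * grad / 4)
        np.testing.assert_allclose(model_a.get_params(), model_b.get_params(), rtol=1e-12)

    def test_zero_advantage_with_pure_rl_keeps_parameters(self, scorer):
        """With gamma=1 and a forced deterministic policy, sampled == greedy,
        the advantage is 0, and the update must leave parameters unchanged."""
        model = make_toy_policy(VOCAB, embedding_dim=8, seed=3)
        params = np.zeros_like(model.get_params()).reshape(len(VOCAB), -1)
        params[model.eos_id, :] = 1e3  # delta distribution on eos
        model.set_params(params.ravel())
        before = model.get_params()
        batch = [SequencePair(model.encode(("a",)), model.encode(("b", "</s>")))]
        train_step(model, batch, scorer, TrainingConfig(learning_rate=0.5), gamma=1.0)
        assert np.array_equal(model.get_params(), before)

    def test_positive_advantage_raises_sampled_sequence_probability(self, tiny, scorer):
        """One gamma=1 SGD step along the SCST gradient must increase the
        probability of an above-baseline sampled sequence (finite check)."""
        model, corpus = tiny
        pair = corpus[0]
        sampled_tokens = pair.target_tokens[:5]
        advantage = 0.5
        logp_before, grad = model.sequence_logprob_grad(pair.source_tokens, sampled_tokens)
        step = -(advantage / len(sampled_tokens)) * grad  # d(loss)/d(params)
        model.set_params(model.get_params() - 0.1 * step)
        logp_after = model.sequence_logprobs(pair.source_tokens, sampled_tokens)
        assert logp_after.sum() > logp_before.sum()

    def test_two_phase_trace_structure(self, tiny, scorer):
        model, corpus = tiny
        cfg = TrainingConfig(seed=1, mle_epochs=2, rl_epochs=3, learning_rate=0.1)
        trace = train(model, corpus, scorer, cfg)
        assert [r.phase for r in trace.records] == ["mle"] * 2 + ["rl"] * 3
        assert all(math.isnan(r.sampled_reward) for r in trace.records[:2])
        assert all(not math.isnan(r.sampled_reward) for r in trace.records[2:])
        assert all(r.lml >= 0 for r in trace.records)

    def test_trace_csv_round_trip(self, tiny, scorer, tmp_path):
        model, corpus = tiny
        trace = train(model, corpus, scorer, TrainingConfig(mle_epochs=1, rl_epochs=1))
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        lines = path.read_text().splitlines()
        assert lines[0].split(",")[:3] == ["epoch", "phase", "lml"]
        assert len(lines) == 3


class TestCheckpoint:
    def test_round_trip_preserves_behavior(self, tmp_path):
        model = make_toy_policy(VOCAB, embedding_dim=8, seed=3)
        model.set_params(model.get_params() + 0.25)
        path = tmp_path / "policy.ckpt"
        save_checkpoint(model, path)
        loaded = load_checkpoint(path)
        assert loaded.vocab == model.vocab
        np.testing.assert_array_equal(loaded.get_params(), model.get_params())
        src = model.encode(("a", "b"))
        np.testing.assert_allclose(
            loaded.token_logprobs(src, (0,)), model.token_logprobs(src, (0,)), rtol=1e-12
        )

    def test_rejects_foreign_files(self, tmp_path):
        path = tmp_path / "junk.txt"
        path.write_text('{"format": "something-else"}\n')
        with pytest.raises(ValueError):
            load_checkpoint(path)
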