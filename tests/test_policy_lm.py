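"""Causal policy: chunking, cross-entropy, SFT and nucleus sampling."""

import math

import numpy as np
import pytest

from molppo import policy_lm
from molppo.chem_data import TokenVocabulary
from molppo.nn import Tensor, no_grad
from molppo.policy_lm import (CausalPolicy, PolicyConfig, chunk_corpus,
                              cross_entropy_loss, evaluate_lm_loss, generate,
                              sft_train)

TINY = PolicyConfig(n_layers=1, n_heads=2, embed_dim=16, ff_mult=2,
                    context_window=32, learning_rate=3e-3, epochs=4)


def make_policy(vocab_size=7, seed=0, config=TINY):
    return CausalPolicy(vocab_size, config, seed=seed)


class TestChunking:
    def test_merges_and_splits(self):
        chunks = chunk_corpus([[1] * 5, [2] * 7], window=6)
        assert [len(c) for c in chunks] == [6, 6]
        assert sum(chunks, []) == [1] * 5 + [2] * 7

    def test_identity_on_exact_window(self):
        seq = [1, 2, 3, 4, 5, 6]
        assert chunk_corpus([seq], window=6) == [seq]

    def test_keeps_short_final_chunk(self):
        chunks = chunk_corpus([[1] * 3, [2] * 3, [3] * 3], window=4)
        assert [len(c) for c in chunks] == [4, 4, 1]

    def test_token_conservation(self, rng):
        seqs = [list(rng.integers(0, 9, rng.integers(1, 30)))
                for _ in range(20)]
        chunks = chunk_corpus(seqs, window=8)
        assert sum(chunks, []) == sum((list(s) for s in seqs), [])

    def test_window_too_small(self):
        with pytest.raises(ValueError):
            chunk_corpus([[1, 2]], window=1)


class TestCrossEntropy:
    def test_certain_model_zero_loss(self):
        # logits put (numerically) all mass on the target
        logits = Tensor(np.eye(4)[None] * 50.0)
        targets = np.arange(4)[None]
        loss = cross_entropy_loss(logits, targets, np.ones((1, 4)))
        assert loss.item() == pytest.approx(0.0, abs=1e-8)

    def test_uniform_model(self):
        logits = Tensor(np.zeros((1, 3, 4)))
        loss = cross_entropy_loss(logits, np.zeros((1, 3), dtype=int),
                                  np.ones((1, 3)))
        assert loss.item() == pytest.approx(math.log(4))

    def test_half_probability_single_position(self):
        logits = np.full((1, 1, 2), 0.0)
        # p(correct) = 0.5 at the only position
        loss = cross_entropy_loss(Tensor(logits), np.array([[0]]),
                                  np.ones((1, 1)))
        assert loss.item() == pytest.approx(math.log(2))

    def test_mask_excludes_positions(self):
        logits = Tensor(np.zeros((1, 2, 4)))
        mask = np.array([[1.0, 0.0]])
        loss = cross_entropy_loss(logits, np.zeros((1, 2), dtype=int), mask)
        assert loss.item() == pytest.approx(math.log(4))

    def test_loss_is_log_perplexity(self, rng):
        """exp(mean NLL) equals the geometric-mean inverse token probability,
        computed independently from the softmax outputs."""
        policy = make_policy().eval()
        seq = [1] + list(rng.integers(3, 7, 8))
        loss = evaluate_lm_loss(policy, [seq])
        ids = np.array([seq])
        with no_grad():
            logits, _ = policy.forward(ids[:, :-1])
        from molppo.nn import softmax
        probs = softmax(logits, axis=-1).data[0]
        token_p = [probs[t, seq[t + 1]] for t in range(len(seq) - 1)]
        perplexity = np.prod([1.0 / p for p in token_p]) ** (1.0 / len(token_p))
        assert math.exp(loss) == pytest.approx(perplexity, rel=1e-9)


def test_policy_distribution_sums_to_one(rng):
    policy = make_policy().eval()
    ids = rng.integers(0, 7, size=(2, 5))
    with no_grad():
        logits, values = policy.forward(ids)
    from molppo.nn import softmax
    probs = softmax(logits, axis=-1).data
    assert np.allclose(probs.sum(axis=-1), 1.0)
    assert values.shape == (2, 5)


def test_policy_is_causal(rng):
    policy = make_policy().eval()
    ids = rng.integers(0, 7, size=(1, 6))
    with no_grad():
        base, _ = policy.forward(ids)
    ids2 = ids.copy()
    ids2[0, 4] = (ids2[0, 4] + 1) % 7
    with no_grad():
        pert, _ = policy.forward(ids2)
    assert np.allclose(base.data[0, :4], pert.data[0, :4])


class TestSFT:
    def test_memorizes_single_molecule(self):
        vocab = TokenVocabulary(["[C]", "[O]"])
        seq = [vocab.bos_id, 3, 4, 3, vocab.eos_id]
        cfg = PolicyConfig(n_layers=1, n_heads=2, embed_dim=16, ff_mult=2,
                           context_window=16, learning_rate=1e-2, epochs=30)
        policy = CausalPolicy(vocab.size, cfg, seed=0)
        policy, history = sft_train(policy, [seq] * 8, [seq], cfg, seed=0)
        assert history["eval_loss"].iloc[-1] < 0.05

    def test_deterministic_history(self, rng):
        seqs = [[1] + list(rng.integers(3, 7, 6)) + [2] for _ in range(10)]
        cfg = PolicyConfig(n_layers=1, n_heads=2, embed_dim=8, ff_mult=2,
                           context_window=16, epochs=2)
        h1 = sft_train(CausalPolicy(7, cfg, seed=1), seqs, seqs[:3], cfg,
                       seed=1)[1]
        h2 = sft_train(CausalPolicy(7, cfg, seed=1), seqs, seqs[:3], cfg,
                       seed=1)[1]
        assert h1.equals(h2)

    def test_eval_loss_decreases_on_learnable_corpus(self, rng):
        base = [1, 3, 4, 5, 6, 3, 4, 2]
        seqs = [base[:] for _ in range(16)]
        cfg = PolicyConfig(n_layers=1, n_heads=2, embed_dim=16, ff_mult=2,
                           context_window=16, learning_rate=3e-3, epochs=5)
        _, history = sft_train(CausalPolicy(7, cfg, seed=0), seqs, seqs[:4],
                               cfg, seed=0)
        assert history["eval_loss"].iloc[-1] < history["eval_loss"].iloc[0]

    def test_chunked_and_padded_both_run(self, rng):
        seqs = [[1] + list(rng.integers(3, 7, rng.integers(3, 10))) + [2]
                for _ in range(12)]
        cfg = PolicyConfig(n_layers=1, n_heads=2, embed_dim=8, ff_mult=2,
                           context_window=16, epochs=1)
        results = policy_lm.sft_compare(7, seqs, seqs[:3], cfg, seed=0)
        assert {"chunked", "padded", "best"} <= set(results)
        assert results["best"] in ("chunked", "padded")


class TestGeneration:
    def eos_policy(self, eos_id=2, vocab_size=5):
        """Hand-set parameters: all probability mass on eos everywhere."""
        policy = make_policy(vocab_size)
        policy.load_state_arrays([np.zeros_like(a)
                                  for a in policy.state_arrays()])
        policy.ln_f.gamma.data[:] = 1.0
        for block in policy.blocks:
            block.ln1.gamma.data[:] = 1.0
            block.ln2.gamma.data[:] = 1.0
        policy.lm_head.bias.data[eos_id] = 100.0
        return policy.eval()

    def test_immediate_eos(self):
        policy = self.eos_policy()
        out = generate(policy, [[1]], eos_id=2, top_p=1.0, seed=0)
        assert out == [[1, 2]]

    def test_small_top_p_is_greedy(self, rng):
        policy = make_policy().eval()
        a = generate(policy, [[1]], eos_id=2, top_p=1e-9, max_len=12, seed=0)
        b = generate(policy, [[1]], eos_id=2, top_p=1e-9, max_len=12, seed=99)
        assert a == b  # the nucleus degenerates to the argmax

    def test_seed_determinism(self):
        policy = make_policy().eval()
        a = generate(policy, [[1], [1]], eos_id=2, top_p=1.0, max_len=15,
                     seed=7)
        b = generate(policy, [[1], [1]], eos_id=2, top_p=1.0, max_len=15,
                     seed=7)
        assert a == b

    def test_respects_max_len(self):
        policy = make_policy().eval()
        out = generate(policy, [[1]], eos_id=-1, top_p=1.0, max_len=9, seed=0)
        assert len(out[0]) <= 9

    def test_invalid_top_p(self):
        with pytest.raises(ValueError):
            generate(make_policy(), [[1]], eos_id=2, top_p=0.0)


def test_checkpoint_round_trip(tmp_path):
    vocab = TokenVocabulary(["[C]", "[O]"])
    policy = make_policy(vocab.size)
    policy.vocabulary = vocab
    path = tmp_path / "p.ckpt"
    policy_lm.save_checkpoint(policy, path)
    loaded = policy_lm.load_checkpoint(path)
    ids = np.array([[1, 3, 4]])
    with no_grad():
        a, _ = policy.forward(ids)
        b, _ = loaded.forward(ids)
    assert np.allclose(a.data, b.data)
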