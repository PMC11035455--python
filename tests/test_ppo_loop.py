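"""PPO primitives (KL, clipping, GAE) and the training loop contracts."""

import math

import numpy as np
import pytest

from molppo import pipeline, ppo_loop
from molppo.chem_data import TokenVocabulary
from molppo.policy_lm import CausalPolicy, PolicyConfig
from molppo.ppo_loop import (PPOConfig, clipped_ratio, compute_advantages,
                             kl_divergence, make_prompts, ppo_train,
                             score_rollouts)
from molppo.qsar_reward import QSARConfig, QSARModel, predict, train_qsar


class TestKLDivergence:
    def test_identity(self):
        assert kl_divergence([0.3, 0.7], [0.3, 0.7]) == pytest.approx(0.0)

    def test_point_mass_vs_uniform(self):
        assert kl_divergence([1.0, 0.0], [0.5, 0.5]) == pytest.approx(
            math.log(2))

    def test_known_value(self):
        # 0.5 ln 2 + 0.5 ln(2/3) = 0.14384...
        assert kl_divergence([0.5, 0.5], [0.25, 0.75]) == pytest.approx(
            0.1438, abs=1e-4)

    def test_asymmetric(self):
        assert kl_divergence([0.5, 0.5], [0.25, 0.75]) != pytest.approx(
            kl_divergence([0.25, 0.75], [0.5, 0.5]))

    def test_support_violation(self):
        with pytest.raises(ValueError):
            kl_divergence([1.0, 0.0], [0.0, 1.0])

    def test_nonnegative_and_zero_iff_equal(self, rng):
        for _ in range(1000):
            n = int(rng.integers(2, 8))
            p = rng.dirichlet(np.ones(n))
            q = rng.dirichlet(np.ones(n))
            assert kl_divergence(p, q) >= 0.0
            assert kl_divergence(p, p) == pytest.approx(0.0, abs=1e-12)


class TestClippedRatio:
    def test_equal_logprobs(self):
        assert clipped_ratio(-1.0, -1.0, 0.2) == pytest.approx(1.0)

    def test_upper_clip(self):
        assert clipped_ratio(math.log(2.0), 0.0, 0.2) == pytest.approx(1.2)

    def test_lower_clip(self):
        assert clipped_ratio(math.log(0.5), 0.0, 0.2) == pytest.approx(0.8)

    def test_containment(self, rng):
        new = rng.normal(size=500)
        old = rng.normal(size=500)
        r = clipped_ratio(new, old, 0.2)
        assert np.all(r >= 0.8) and np.all(r <= 1.2)


def gae_reference(rewards, values, gamma, lam):
    """Independent O(T^2) forward-sum GAE (oracle for the recursion)."""
    T = len(rewards)
    deltas = [rewards[t] + gamma * (values[t + 1] if t + 1 < T else 0.0)
              - values[t] for t in range(T)]
    return np.array([
        sum((gamma * lam) ** l * deltas[t + l] for l in range(T - t))
        for t in range(T)])


class TestAdvantages:
    def test_telescoping_limit(self):
        est = compute_advantages(np.zeros(4), terminal_reward=5.0,
                                 kl_penalties=np.zeros(4), gamma=1.0, lam=1.0)
        assert np.allclose(est.advantages, 5.0)

    def test_constant_kl_stream(self):
        c = 0.3
        est = compute_advantages(np.zeros(3), terminal_reward=0.0,
                                 kl_penalties=np.full(3, c), gamma=1.0,
                                 lam=1.0)
        assert np.allclose(est.advantages, [-3 * c, -2 * c, -c])

    def test_matches_brute_force(self, rng):
        for _ in range(50):
            T = int(rng.integers(1, 11))
            values = rng.normal(size=T)
            kl = rng.normal(size=T) * 0.1
            reward = float(rng.normal())
            gamma = float(rng.uniform(0.9, 1.0))
            lam = float(rng.uniform(0.8, 1.0))
            rewards = -kl.copy()
            rewards[-1] += reward
            est = compute_advantages(values, reward, kl, gamma, lam)
            ref = gae_reference(rewards, values, gamma, lam)
            assert np.allclose(est.advantages, ref, atol=1e-10)
            assert np.allclose(est.returns, ref + values, atol=1e-10)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compute_advantages(np.zeros(3), 1.0, np.zeros(2))


class TestPrompts:
    def test_fraction_and_range(self, rng):
        seqs = [list(range(3, 20))] * 10
        cfg = PPOConfig(rollout_batch_size=400, fraction_from_scratch=0.5)
        prompts = make_prompts(seqs, cfg, bos_id=1, rng=rng)
        bare = [p for p in prompts if p == [1]]
        prefixed = [p for p in prompts if len(p) > 1]
        assert 0.4 < len(bare) / 400 < 0.6
        for p in prefixed:
            assert p[0] == 1
            assert 2 <= len(p) - 1 <= 8


@pytest.fixture(scope="module")
def reward_setup(small_dataset_module):
    dataset = small_dataset_module
    cfg = QSARConfig(hidden_size=8, embed_dim=4, dropout=0.0, max_epochs=2)
    model, _ = train_qsar(dataset, cfg, seed=0)
    return dataset, model


@pytest.fixture(scope="module")
def small_dataset_module():
    from molppo import chem_data, synthetic_data
    table, _ = synthetic_data.simulate_table(
        60, seed=21, oracle=synthetic_data.OracleSpec(noise_sd=0.1))
    rows = [(s, chem_data.ic50_to_pic50(v))
            for s, v in zip(table["smiles"], table["ic50_nM"])]
    return chem_data.prepare_dataset(rows, seed=21)


class TestScoring:
    def test_training_molecule_scores_like_eval_path(self, reward_setup):
        dataset, model = reward_setup
        vocab = dataset.vocabulary
        record = dataset.records[0]
        ids = vocab.encode(record.selfies_tokens)
        response = [vocab.bos_id] + ids + [vocab.eos_id]
        rewards, valid = score_rollouts([response], model, vocab)
        expected = predict(model, [ids],
                           dataset.normalized_matrix[:1])
        assert valid[0]
        assert rewards[0] == pytest.approx(expected[0], abs=1e-9)

    def test_batch_equals_sequential(self, reward_setup):
        dataset, model = reward_setup
        vocab = dataset.vocabulary
        responses = [[vocab.bos_id] + vocab.encode(r.selfies_tokens)
                     + [vocab.eos_id] for r in dataset.records[:6]]
        batch, _ = score_rollouts(responses, model, vocab)
        single = np.array([score_rollouts([r], model, vocab)[0][0]
                           for r in responses])
        assert np.allclose(batch, single)

    def test_constant_model_constant_rewards(self, reward_setup):
        dataset, _ = reward_setup
        vocab = dataset.vocabulary
        cfg = QSARConfig(hidden_size=4, embed_dim=2, dropout=0.0)
        const = QSARModel(vocab.size, dataset.normalized_matrix.shape[1],
                          cfg, seed=0)
        const.load_state_arrays([np.zeros_like(a)
                                 for a in const.state_arrays()])
        const.head.bias.data[:] = 6.5
        const.vocabulary = vocab
        const.scaler = dataset.scaler
        const.descriptor_names = dataset.descriptor_names
        const.eval()
        responses = [[vocab.bos_id] + vocab.encode(r.selfies_tokens)
                     + [vocab.eos_id] for r in dataset.records[:5]]
        rewards, _ = score_rollouts(responses, const, vocab)
        assert np.allclose(rewards, 6.5)

    def test_empty_response_gets_floor(self, reward_setup):
        dataset, model = reward_setup
        vocab = dataset.vocabulary
        rewards, valid = score_rollouts([[vocab.bos_id, vocab.eos_id]],
                                        model, vocab, floor_reward=-1.0)
        assert rewards[0] == -1.0 and not valid[0]

    def test_vocabulary_mismatch_rejected(self, reward_setup):
        _, model = reward_setup
        other = TokenVocabulary(["[C]"])
        with pytest.raises(ValueError):
            score_rollouts([[1, 3, 2]], model, other)


class TestPPOTraining:
    def ppo_setup(self, reward_setup, ppo_config, seed=0):
        dataset, reward_model = reward_setup
        vocab = dataset.vocabulary
        cfg = PolicyConfig(n_layers=1, n_heads=2, embed_dim=16, ff_mult=2,
                           context_window=32, epochs=1)
        policy = CausalPolicy(vocab.size, cfg, seed=seed)
        policy.vocabulary = vocab
        ref = CausalPolicy(vocab.size, cfg, seed=seed)
        ref.vocabulary = vocab
        ref.copy_from(policy)
        seqs = [vocab.encode(r.selfies_tokens) for r in dataset.records[:20]]
        return policy, ref, reward_model, seqs

    def test_history_deterministic(self, reward_setup):
        cfg = PPOConfig(epochs=2, batches_per_epoch=1, inner_epochs=1,
                        rollout_batch_size=4, max_len=16, learning_rate=1e-3)
        h = []
        for _ in range(2):
            policy, ref, rm, seqs = self.ppo_setup(reward_setup, cfg)
            _, hist = ppo_train(policy, ref, rm, seqs, cfg, seed=3)
            h.append(hist)
        assert h[0].equals(h[1])

    def test_huge_kl_coefficient_freezes_policy(self, reward_setup):
        cfg = PPOConfig(epochs=2, batches_per_epoch=2, inner_epochs=2,
                        rollout_batch_size=8, max_len=16,
                        kl_coefficient=1e5, adaptive_kl=False)
        policy, ref, rm, seqs = self.ppo_setup(reward_setup, cfg)
        before = [a.copy() for a in policy.state_arrays()]
        _, hist = ppo_train(policy, ref, rm, seqs, cfg, seed=1)
        # the penalty dominates: the policy barely moves from the reference
        assert hist["mean_kl"].abs().iloc[-1] < 0.05
        drift = max(np.abs(a - b).max()
                    for a, b in zip(policy.state_arrays(), before))
        assert drift < 0.05

    def test_validity_is_total_at_every_epoch(self, reward_setup):
        cfg = PPOConfig(epochs=2, batches_per_epoch=2, inner_epochs=1,
                        rollout_batch_size=8, max_len=16, learning_rate=1e-3)
        policy, ref, rm, seqs = self.ppo_setup(reward_setup, cfg)
        _, hist = ppo_train(policy, ref, rm, seqs, cfg, seed=2)
        assert (hist["valid_fraction"] == 1.0).all()
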