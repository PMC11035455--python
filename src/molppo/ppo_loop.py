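"""Proximal policy optimization of the token policy against the QSAR reward.

The feedback loop per rollout batch: build prompts (bare begin-of-sequence
or the first 2-8 tokens of a training molecule), sample continuations with
top-p = 1.0, decode and score each molecule with the reward model, subtract
a per-token KL penalty against the frozen supervised-fine-tuned reference,
estimate per-token advantages with GAE, and maximize the clipped surrogate
objective plus a value-head regression loss.

The KL coefficient can adapt toward a target KL via a proportional
controller, or stay fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import codec
from .chem_data import TokenVocabulary, apply_scaler, compute_descriptors
from .nn import Adam, Tensor, log_softmax, no_grad
from .policy_lm import CausalPolicy, generate, pad_sequences
from .qsar_reward import QSARModel, predict as qsar_predict


# ---------------------------------------------------------------------------
# config and containers
# ---------------------------------------------------------------------------

@dataclass
class PPOConfig:
    epochs: int = 14
    learning_rate: float = 1.41e-5
    clip_epsilon: float = 0.2
    kl_coefficient: float = 0.2
    adaptive_kl: bool = True
    kl_target: float = 6.0          # target KL per sequence for the controller
    kl_horizon: float = 10000.0
    rollout_batch_size: int = 16
    batches_per_epoch: int = 4
    inner_epochs: int = 4           # optimization passes per rollout batch
    prompt_token_range: tuple[int, int] = (2, 8)
    fraction_from_scratch: float = 0.5
    value_loss_weight: float = 0.1
    value_grad_to_body: bool = False  # value loss perturbs shared body if True
    gamma: float = 1.0
    lam: float = 0.95
    top_p: float = 1.0
    max_len: int = 64
    whiten_advantages: bool = True
    floor_reward: float = 0.0       # reward for undecodable/unscorable output
    reward_clip: tuple[float, float] = (0.0, 12.0)  # plausible pIC50 range
    kl_ceiling: float = 10.0        # mean nats/token; beyond this, early stop

    def __post_init__(self):
        if not 0.0 < self.clip_epsilon < 1.0:
            raise ValueError("clip_epsilon must be in (0, 1)")
        if self.kl_coefficient < 0:
            raise ValueError("kl_coefficient must be >= 0")


@dataclass
class RolloutBatch:
    queries: list[list[int]]
    responses: list[list[int]]      # full sequences (prompt + continuation)
    rewards: np.ndarray             # one scalar per sequence
    old_logprobs: np.ndarray        # (B, T-1), gen positions only meaningful
    ref_logprobs: np.ndarray
    values: np.ndarray              # (B, T-1)
    gen_mask: np.ndarray            # 1 where a column is a generated action


@dataclass
class AdvantageEstimate:
    advantages: np.ndarray
    values: np.ndarray
    returns: np.ndarray


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------

def kl_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """D_KL(P || Q) = sum_i P(i) log(P(i)/Q(i)) for discrete distributions."""
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError("distributions must have equal length")
    if not (math.isclose(p.sum(), 1.0, abs_tol=1e-8)
            and math.isclose(q.sum(), 1.0, abs_tol=1e-8)):
        raise ValueError("inputs must sum to 1")
    if np.any((p > 0) & (q <= 0)):
        raise ValueError("support violation: P > 0 where Q = 0")
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def clipped_ratio(logp_new: np.ndarray, logp_old: np.ndarray,
                  epsilon: float) -> np.ndarray:
    """clip(exp(logp_new - logp_old), 1 - eps, 1 + eps)."""
    ratio = np.exp(np.asarray(logp_new) - np.asarray(logp_old))
    return np.clip(ratio, 1.0 - epsilon, 1.0 + epsilon)


def compute_advantages(values: np.ndarray, terminal_reward: float,
                       kl_penalties: np.ndarray, gamma: float = 1.0,
                       lam: float = 0.95) -> AdvantageEstimate:
    """Generalized advantage estimation over one generated episode.

    Per-token rewards are the negative KL penalties, with the scalar
    molecule reward added at the final token.  With gamma = lam = 1 and zero
    values, every advantage equals the total reward (telescoping check).
    """
    values = np.asarray(values, dtype=np.float64)
    kl_penalties = np.asarray(kl_penalties, dtype=np.float64)
    if values.shape != kl_penalties.shape:
        raise ValueError("values and kl_penalties must have equal length")
    T = len(values)
    rewards = -kl_penalties.copy()
    rewards[-1] += terminal_reward
    advantages = np.zeros(T)
    gae = 0.0
    for t in reversed(range(T)):
        next_value = values[t + 1] if t + 1 < T else 0.0
        delta = rewards[t] + gamma * next_value - values[t]
        gae = delta + gamma * lam * gae
        advantages[t] = gae
    return AdvantageEstimate(advantages=advantages, values=values,
                             returns=advantages + values)


def whiten(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    return (x - x.mean()) / (x.std() + 1e-8)


def make_prompts(sequences: list[list[int]], config: PPOConfig,
                 bos_id: int, rng: np.random.Generator) -> list[list[int]]:
    """Sample rollout prompts from the tokenized training set.

    A configured fraction are a bare [bos]; the rest are [bos] plus the
    first k tokens of a random training molecule, k uniform in the
    configured range (truncated to the molecule's length).
    """
    lo, hi = config.prompt_token_range
    prompts = []
    for _ in range(config.rollout_batch_size):
        if rng.random() < config.fraction_from_scratch or not sequences:
            prompts.append([bos_id])
        else:
            seq = sequences[rng.integers(0, len(sequences))]
            k = min(int(rng.integers(lo, hi + 1)), len(seq))
            prompts.append([bos_id] + list(seq[:k]))
    return prompts


def score_rollouts(responses: list[list[int]], reward_model: QSARModel,
                   vocabulary: TokenVocabulary,
                   floor_reward: float = 0.0
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Predicted pIC50 per generated sequence, via the reward model.

    Special tokens are stripped, the remaining tokens are decoded to SMILES,
    descriptors are computed and normalized with the reward model's stored
    train scaler, and the (tokens, descriptors) pair goes through the same
    forward pass used at evaluation time.  The sequence branch reads the
    *canonical* re-encoding of the decoded molecule (falling back to the
    generated spelling if the canonical one leaves the vocabulary), so the
    reward is a function of the molecule rather than of its token spelling —
    otherwise the policy can inflate rewards by re-spelling molecules.
    Sequences that decode to nothing or whose descriptors fail receive
    `floor_reward`.  Returns (rewards, valid mask).
    """
    if reward_model.vocabulary.content_hash() != vocabulary.content_hash():
        raise ValueError("reward model vocabulary does not match policy")
    specials = {vocabulary.pad_id, vocabulary.bos_id, vocabulary.eos_id}
    rewards = np.full(len(responses), float(floor_reward))
    valid = np.zeros(len(responses), dtype=bool)
    seqs, descs, keep = [], [], []
    for i, resp in enumerate(responses):
        ids = [t for t in resp if t not in specials]
        if not ids:
            continue
        smiles = codec.decode(vocabulary.decode(ids))
        if not smiles:
            continue
        try:
            _, vec = compute_descriptors(smiles)
        except ValueError:
            continue
        try:
            ids = vocabulary.encode(codec.encode(smiles))
        except (ValueError, KeyError):
            pass  # canonical spelling not representable; keep generated ids
        seqs.append(ids)
        descs.append(apply_scaler(vec, reward_model.scaler))
        keep.append(i)
        valid[i] = True
    if keep:
        preds = qsar_predict(reward_model, seqs, np.vstack(descs))
        rewards[keep] = preds
    return rewards, valid


# ---------------------------------------------------------------------------
# tensor-side helpers for the surrogate loss
# ---------------------------------------------------------------------------

def _tensor_clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """clip with straight-through zero gradient outside [lo, hi]."""
    inside = ((x.data >= lo) & (x.data <= hi)).astype(np.float64)
    clipped_const = np.clip(x.data, lo, hi) * (1.0 - inside)
    return x * Tensor(inside) + Tensor(clipped_const)


def _tensor_min(a: Tensor, b: Tensor) -> Tensor:
    take_a = (a.data <= b.data).astype(np.float64)
    return a * Tensor(take_a) + b * Tensor(1.0 - take_a)


def _gather_logprobs(logits: Tensor, targets: np.ndarray) -> Tensor:
    logp = log_softmax(logits, axis=-1)
    B, T = targets.shape
    b_idx, t_idx = np.meshgrid(np.arange(B), np.arange(T), indexing="ij")
    return logp[b_idx.ravel(), t_idx.ravel(), targets.ravel()].reshape(B, T)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _collect_rollout(policy: CausalPolicy, ref_policy: CausalPolicy,
                     reward_model: QSARModel, sequences: list[list[int]],
                     config: PPOConfig, vocab: TokenVocabulary,
                     rng: np.random.Generator) -> RolloutBatch:
    prompts = make_prompts(sequences, config, vocab.bos_id, rng)
    responses = generate(policy, prompts, vocab.eos_id, top_p=config.top_p,
                         max_len=config.max_len,
                         seed=int(rng.integers(0, 2 ** 31)))
    rewards, _valid = score_rollouts(responses, reward_model, vocab,
                                     config.floor_reward)
    rewards = np.clip(rewards, *config.reward_clip)
    ids, mask = pad_sequences(responses)
    inp, tgt = ids[:, :-1], ids[:, 1:]
    pad_mask = np.asarray(inp != vocab.pad_id, dtype=np.int64)
    # column c holds the action producing token ids[:, c+1]
    gen_mask = np.zeros_like(tgt, dtype=np.float64)
    for i, (prompt, resp) in enumerate(zip(prompts, responses)):
        gen_mask[i, len(prompt) - 1:len(resp) - 1] = 1.0
    with no_grad():
        logits, values = policy.forward(inp, pad_mask=pad_mask)
        old_logp = _gather_logprobs(logits, tgt).data
        ref_logits, _ = ref_policy.forward(inp, pad_mask=pad_mask)
        ref_logp = _gather_logprobs(ref_logits, tgt).data
    return RolloutBatch(queries=prompts, responses=responses, rewards=rewards,
                        old_logprobs=old_logp, ref_logprobs=ref_logp,
                        values=values.data, gen_mask=gen_mask)


def ppo_train(policy: CausalPolicy, ref_policy: CausalPolicy,
              reward_model: QSARModel, sequences: list[list[int]],
              config: PPOConfig, seed: int = 0
              ) -> tuple[CausalPolicy, pd.DataFrame]:
    """Optimize the policy against the reward model; returns per-epoch history.

    `sequences` are tokenized training molecules without special tokens
    (prompt material).  `ref_policy` stays frozen and provides the KL
    reference.  History columns: mean reward, mean KL per generated token
    versus the reference, fraction of valid decodes, and the KL coefficient.
    """
    vocab = policy.vocabulary
    if vocab is None:
        raise ValueError("policy has no attached vocabulary")
    optimizer = Adam(policy.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(seed)
    kl_coef = config.kl_coefficient
    history = {"epoch": [], "mean_reward": [], "mean_kl": [],
               "valid_fraction": [], "kl_coef": [], "policy_loss": [],
               "value_loss": []}
    stop = False
    for epoch in range(config.epochs):
        ep_rewards, ep_kls, ep_valid, ep_ploss, ep_vloss = [], [], [], [], []
        for _ in range(config.batches_per_epoch):
            batch = _collect_rollout(policy, ref_policy, reward_model,
                                     sequences, config, vocab, rng)
            gen_mask = batch.gen_mask
            n_gen = gen_mask.sum()
            if n_gen == 0:
                continue
            kl_tok = (batch.old_logprobs - batch.ref_logprobs) * gen_mask
            mean_kl = float(kl_tok.sum() / n_gen)
            # per-sequence GAE on the generated region
            advantages = np.zeros_like(gen_mask)
            returns = np.zeros_like(gen_mask)
            for i in range(gen_mask.shape[0]):
                cols = np.nonzero(gen_mask[i])[0]
                if len(cols) == 0:
                    continue
                est = compute_advantages(batch.values[i, cols],
                                         float(batch.rewards[i]),
                                         kl_coef * kl_tok[i, cols],
                                         gamma=config.gamma, lam=config.lam)
                advantages[i, cols] = est.advantages
                returns[i, cols] = est.returns
            if config.whiten_advantages:
                flat = advantages[gen_mask > 0]
                advantages[gen_mask > 0] = whiten(flat)
            ids, _ = pad_sequences(batch.responses)
            inp, tgt = ids[:, :-1], ids[:, 1:]
            pad_mask = np.asarray(inp != vocab.pad_id, dtype=np.int64)
            adv_t = Tensor(advantages * gen_mask)
            mask_t = Tensor(gen_mask)
            for _ in range(config.inner_epochs):
                logits, values = policy.forward(
                    inp, pad_mask=pad_mask,
                    detach_values=not config.value_grad_to_body)
                new_logp = _gather_logprobs(logits, tgt)
                ratio = (new_logp - Tensor(batch.old_logprobs)).clip_exp()
                unclipped = ratio * adv_t
                clipped = _tensor_clip(ratio, 1.0 - config.clip_epsilon,
                                       1.0 + config.clip_epsilon) * adv_t
                policy_loss = -(_tensor_min(unclipped, clipped) * mask_t
                                ).sum() / n_gen
                v_err = (values - Tensor(returns)) * mask_t
                value_loss = (v_err * v_err).sum() / n_gen
                loss = policy_loss + config.value_loss_weight * value_loss
                if not np.isfinite(loss.item()):
                    raise RuntimeError(f"PPO diverged at epoch {epoch}")
                optimizer.zero_grad()
                loss.backward()
                optimizer.step()
            ep_rewards.append(float(batch.rewards.mean()))
            ep_kls.append(mean_kl)
            ep_valid.append(float(np.mean(
                [1.0 if r else 0.0 for r in _decode_ok(batch.responses, vocab)])))
            ep_ploss.append(policy_loss.item())
            ep_vloss.append(value_loss.item())
            if config.adaptive_kl:
                error = np.clip(mean_kl * n_gen / gen_mask.shape[0]
                                / config.kl_target - 1.0, -0.2, 0.2)
                kl_coef *= 1.0 + error * (config.rollout_batch_size
                                          / config.kl_horizon)
        history["epoch"].append(epoch)
        history["mean_reward"].append(float(np.mean(ep_rewards)))
        history["mean_kl"].append(float(np.mean(ep_kls)))
        history["valid_fraction"].append(float(np.mean(ep_valid)))
        history["kl_coef"].append(kl_coef)
        history["policy_loss"].append(float(np.mean(ep_ploss)))
        history["value_loss"].append(float(np.mean(ep_vloss)))
        if abs(history["mean_kl"][-1]) > config.kl_ceiling:
            stop = True
        if stop:
            break
    policy.eval()
    return policy, pd.DataFrame(history)


def _decode_ok(responses: list[list[int]],
               vocab: TokenVocabulary) -> list[bool]:
    specials = {vocab.pad_id, vocab.bos_id, vocab.eos_id}
    out = []
    for resp in responses:
        ids = [t for t in resp if t not in specials]
        smiles = codec.decode(vocab.decode(ids)) if ids else ""
        out.append(codec.canonical_smiles(smiles) is not None)
    return out
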