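"""End-to-end desk-scale pipeline: synthesize data, train reward model,
supervised-fine-tune the policy, run PPO, and sample molecules.

The default configurations here are the package's scaled-down study
conditions: a ~500-molecule synthetic dataset, a compact reward model and
policy, 10 SFT epochs and up to 14 PPO epochs with rollout batches of 16 at
top-p 1.0.  Every stage is seeded from a single integer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import chem_data, codec, synthetic_data
from .policy_lm import CausalPolicy, PolicyConfig, generate, sft_train
from .ppo_loop import PPOConfig, ppo_train, score_rollouts
from .qsar_reward import QSARConfig, QSARModel, train_qsar


def desk_qsar_config() -> QSARConfig:
    return QSARConfig(hidden_size=64, embed_dim=32, n_recurrent_layers=2,
                      dropout=0.1, max_epochs=30, batch_size=16)


def desk_policy_config() -> PolicyConfig:
    return PolicyConfig(n_layers=2, n_heads=2, embed_dim=64, ff_mult=2,
                        context_window=64, learning_rate=1e-3,
                        batch_size=16, epochs=10)


def desk_ppo_config() -> PPOConfig:
    return PPOConfig(epochs=14, learning_rate=1e-3, batches_per_epoch=16,
                     inner_epochs=4, rollout_batch_size=16, max_len=48,
                     fraction_from_scratch=0.75, kl_coefficient=0.05,
                     value_loss_weight=0.25)


@dataclass
class PipelineResult:
    dataset: chem_data.EfficacyDataset
    oracle: synthetic_data.OracleSpec
    reward_model: QSARModel
    sft_policy: CausalPolicy
    ppo_policy: CausalPolicy
    sft_history: object
    ppo_history: object


def tokenized_split(dataset: chem_data.EfficacyDataset
                    ) -> tuple[list[list[int]], list[list[int]]]:
    """([bos] + tokens + [eos]) id sequences for the train and eval splits."""
    vocab = dataset.vocabulary
    seqs = [[vocab.bos_id] + vocab.encode(r.selfies_tokens) + [vocab.eos_id]
            for r in dataset.records]
    train = [seqs[i] for i in dataset.train_idx]
    evals = [seqs[i] for i in dataset.eval_idx]
    return train, evals


def make_dataset(n_molecules: int = 500, seed: int = 0,
                 oracle: synthetic_data.OracleSpec | None = None
                 ) -> tuple[chem_data.EfficacyDataset, synthetic_data.OracleSpec]:
    table, oracle = synthetic_data.simulate_table(n_molecules, seed=seed,
                                                  oracle=oracle)
    rows = [(s, chem_data.ic50_to_pic50(v))
            for s, v in zip(table["smiles"], table["ic50_nM"])]
    return chem_data.prepare_dataset(rows, seed=seed), oracle


def sample_sequences(policy: CausalPolicy, n: int, seed: int = 0,
                     top_p: float = 1.0, max_len: int = 48,
                     batch_size: int = 64) -> list[list[int]]:
    """Sample n token sequences from bare [bos] prompts."""
    vocab = policy.vocabulary
    out: list[list[int]] = []
    for start in range(0, n, batch_size):
        count = min(batch_size, n - start)
        prompts = [[vocab.bos_id]] * count
        out.extend(generate(policy, prompts, vocab.eos_id, top_p=top_p,
                            max_len=max_len, seed=seed + start))
    return out


def decode_sequences(sequences: list[list[int]], vocab) -> list[str]:
    specials = {vocab.pad_id, vocab.bos_id, vocab.eos_id}
    return [codec.decode(vocab.decode([t for t in seq if t not in specials]))
            for seq in sequences]


def sample_smiles(policy: CausalPolicy, n: int, seed: int = 0,
                  top_p: float = 1.0, max_len: int = 48,
                  batch_size: int = 64) -> list[str]:
    """Sample n molecules from bare [bos] prompts and decode to SMILES."""
    seqs = sample_sequences(policy, n, seed=seed, top_p=top_p, max_len=max_len,
                            batch_size=batch_size)
    return decode_sequences(seqs, policy.vocabulary)


def predict_pic50(reward_model: QSARModel, policy_vocab,
                  sequences_or_smiles: list, floor_reward: float = 0.0
                  ) -> np.ndarray:
    """Reward-model pIC50 per item (floor for unscorable/empty decodes).

    Accepts either generated token-id sequences (scored exactly as in the
    PPO loop) or SMILES strings (canonically re-encoded first).
    """
    responses = []
    for item in sequences_or_smiles:
        if isinstance(item, str):
            try:
                responses.append(
                    policy_vocab.encode(codec.encode(item)) if item else [])
            except (ValueError, KeyError):
                responses.append([])
        else:
            responses.append(list(item))
    rewards, _ = score_rollouts(responses, reward_model, policy_vocab,
                                floor_reward=floor_reward)
    return rewards


def run_pipeline(n_molecules: int = 500, seed: int = 0,
                 qsar_config: QSARConfig | None = None,
                 policy_config: PolicyConfig | None = None,
                 ppo_config: PPOConfig | None = None,
                 oracle: synthetic_data.OracleSpec | None = None
                 ) -> PipelineResult:
    """Synthetic data -> QSAR reward -> SFT -> PPO, all from one seed."""
    qsar_config = qsar_config or desk_qsar_config()
    policy_config = policy_config or desk_policy_config()
    ppo_config = ppo_config or desk_ppo_config()

    dataset, oracle = make_dataset(n_molecules, seed=seed, oracle=oracle)
    reward_model, _ = train_qsar(dataset, qsar_config, seed=seed)

    train_seqs, eval_seqs = tokenized_split(dataset)
    policy = CausalPolicy(dataset.vocabulary.size, policy_config, seed=seed)
    policy.vocabulary = dataset.vocabulary
    policy, sft_history = sft_train(policy, train_seqs, eval_seqs,
                                    policy_config, seed=seed)

    ref_policy = CausalPolicy(dataset.vocabulary.size, policy_config, seed=seed)
    ref_policy.vocabulary = dataset.vocabulary
    ref_policy.copy_from(policy)
    ref_policy.eval()

    prompt_material = [dataset.vocabulary.encode(r.selfies_tokens)
                       for r in (dataset.records[i] for i in dataset.train_idx)]
    policy, ppo_history = ppo_train(policy, ref_policy, reward_model,
                                    prompt_material, ppo_config, seed=seed)
    return PipelineResult(dataset=dataset, oracle=oracle,
                          reward_model=reward_model, sft_policy=ref_policy,
                          ppo_policy=policy, sft_history=sft_history,
                          ppo_history=ppo_history)
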