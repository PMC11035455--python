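"""Decoder-only autoregressive token policy over SELFIES-style tokens.

A small causal transformer trained from scratch: token + learned positional
embeddings, pre-norm blocks, a language-model head, and a scalar value head
(used by PPO).  Supervised fine-tuning minimizes masked next-token
cross-entropy with AdamW; preprocessing can either pad each molecule to the
batch maximum or chunk the concatenated corpus into fixed windows, and a
comparison harness reports both eval losses.  Sampling is inclusive nucleus
(top-p) with per-sequence eos stopping.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .chem_data import TokenVocabulary
from .nn import (Adam, Embedding, LayerNorm, Linear, Module, Tensor,
                 TransformerBlock, log_softmax, no_grad)


@dataclass
class PolicyConfig:
    n_layers: int = 4
    n_heads: int = 4
    embed_dim: int = 128
    ff_mult: int = 4
    context_window: int = 256   # must cover the longest dataset sequence
    learning_rate: float = 7e-5
    weight_decay: float = 0.01
    batch_size: int = 16
    epochs: int = 10
    chunking: bool = False


class CausalPolicy(Module):
    """pi_theta(a_t | s_t) over the token vocabulary, plus V(s_t)."""

    def __init__(self, vocab_size: int, config: PolicyConfig, seed: int = 0):
        super().__init__()
        self.config = config
        self.vocab_size = vocab_size
        rng = np.random.default_rng(seed)
        D = config.embed_dim
        self.tok_emb = Embedding(vocab_size, D, rng)
        self.pos_emb = Embedding(config.context_window, D, rng)
        self.blocks = [TransformerBlock(D, config.n_heads, config.ff_mult, rng)
                       for _ in range(config.n_layers)]
        self.ln_f = LayerNorm(D)
        self.lm_head = Linear(D, vocab_size, rng)
        # two-layer value head: expressive enough even when it reads
        # gradient-stopped hidden states (see forward)
        self.value_fc = Linear(D, D, rng)
        self.value_out = Linear(D, 1, rng)
        self.vocabulary: TokenVocabulary | None = None

    def forward(self, ids: np.ndarray, pad_mask: np.ndarray | None = None,
                detach_values: bool = False) -> tuple[Tensor, Tensor]:
        """ids (B, T) -> (logits (B, T, V), values (B, T)).

        With `detach_values` the value head reads a gradient-stopped copy of
        the hidden states, so value-regression error cannot perturb the
        policy distribution.
        """
        B, T = ids.shape
        if T > self.config.context_window:
            raise ValueError("sequence longer than context window")
        x = self.tok_emb(ids) + self.pos_emb(np.arange(T)[None, :])
        for block in self.blocks:
            x = block(x, pad_mask)
        x = self.ln_f(x)
        v_in = x.detach() if detach_values else x
        values = self.value_out(self.value_fc(v_in).relu()).reshape(B, T)
        return self.lm_head(x), values


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

def chunk_corpus(sequences: list[list[int]], window: int) -> list[list[int]]:
    """Concatenate all sequences and re-split into fixed-length windows.

    All chunks have length `window` except possibly the last, which is kept
    short (it is padded at batch time) so no tokens are discarded.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    flat: list[int] = [t for seq in sequences for t in seq]
    return [flat[i:i + window] for i in range(0, len(flat), window)]


def pad_sequences(seqs: list[list[int]],
                  pad_id: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Right-pad to the batch max; returns (ids, attention mask)."""
    T = max(len(s) for s in seqs)
    ids = np.full((len(seqs), T), pad_id, dtype=np.int64)
    mask = np.zeros((len(seqs), T), dtype=np.int64)
    for i, s in enumerate(seqs):
        ids[i, :len(s)] = s
        mask[i, :len(s)] = 1
    return ids, mask


def cross_entropy_loss(logits: Tensor, targets: np.ndarray,
                       mask: np.ndarray) -> Tensor:
    """Mean over unmasked positions of -log q(correct next token)."""
    logp = log_softmax(logits, axis=-1)
    B, T = targets.shape
    b_idx, t_idx = np.meshgrid(np.arange(B), np.arange(T), indexing="ij")
    picked = logp[b_idx.ravel(), t_idx.ravel(), targets.ravel()].reshape(B, T)
    mask = np.asarray(mask, dtype=np.float64)
    total = mask.sum()
    if total == 0:
        raise ValueError("all positions masked")
    return -(picked * Tensor(mask)).sum() / total


def _lm_batch(rows: list[list[int]], pad_id: int = 0):
    """Shift a padded batch into (input ids, target ids, target mask)."""
    ids, mask = pad_sequences(rows, pad_id)
    return ids[:, :-1], ids[:, 1:], mask[:, 1:] * mask[:, :-1]


def evaluate_lm_loss(policy: CausalPolicy, sequences: list[list[int]],
                     batch_size: int = 32, pad_id: int = 0) -> float:
    """Token-weighted eval cross-entropy (== ln perplexity)."""
    policy.eval()
    total_nll = total_tok = 0.0
    with no_grad():
        for start in range(0, len(sequences), batch_size):
            rows = sequences[start:start + batch_size]
            inp, tgt, m = _lm_batch(rows, pad_id)
            logits, _ = policy.forward(inp, pad_mask=np.asarray(inp != pad_id,
                                                                dtype=np.int64))
            loss = cross_entropy_loss(logits, tgt, m)
            total_nll += loss.item() * m.sum()
            total_tok += m.sum()
    return total_nll / total_tok


# ---------------------------------------------------------------------------
# supervised fine-tuning
# ---------------------------------------------------------------------------

def sft_train(policy: CausalPolicy, train_sequences: list[list[int]],
              eval_sequences: list[list[int]], config: PolicyConfig,
              seed: int = 0) -> tuple[CausalPolicy, pd.DataFrame]:
    """Masked next-token cross-entropy training with AdamW.

    `train_sequences` are full molecules ([bos] ... [eos]); with
    ``config.chunking`` the corpus is chunked to the context window first.
    Eval loss is always computed on the untouched held-out molecules so the
    chunked and padded variants are comparable.
    """
    rows = (chunk_corpus(train_sequences, config.context_window)
            if config.chunking else list(train_sequences))
    optimizer = Adam(policy.parameters(), lr=config.learning_rate,
                     weight_decay=config.weight_decay)
    rng = np.random.default_rng(seed)
    history = {"epoch": [], "train_loss": [], "eval_loss": []}
    for epoch in range(config.epochs):
        policy.train()
        order = rng.permutation(len(rows))
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = [rows[i] for i in order[start:start + config.batch_size]]
            batch = [r for r in batch if len(r) >= 2]
            if not batch:
                continue
            inp, tgt, m = _lm_batch(batch)
            logits, _ = policy.forward(
                inp, pad_mask=np.asarray(inp != 0, dtype=np.int64))
            loss = cross_entropy_loss(logits, tgt, m)
            if not np.isfinite(loss.item()):
                raise RuntimeError(f"SFT diverged at epoch {epoch}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(loss.item())
        history["epoch"].append(epoch)
        history["train_loss"].append(float(np.mean(losses)))
        history["eval_loss"].append(evaluate_lm_loss(policy, eval_sequences))
    policy.eval()
    return policy, pd.DataFrame(history)


def sft_compare(vocab_size: int, train_sequences: list[list[int]],
                eval_sequences: list[list[int]], config: PolicyConfig,
                seed: int = 0) -> dict:
    """Train once with chunking and once with padding; keep the lower eval loss."""
    results = {}
    for chunking in (True, False):
        cfg = PolicyConfig(**{**asdict(config), "chunking": chunking})
        policy = CausalPolicy(vocab_size, cfg, seed=seed)
        policy, history = sft_train(policy, train_sequences, eval_sequences,
                                    cfg, seed=seed)
        results["chunked" if chunking else "padded"] = {
            "policy": policy, "history": history,
            "eval_loss": history["eval_loss"].iloc[-1]}
    best = min(results, key=lambda k: results[k]["eval_loss"])
    results["best"] = best
    return results


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _nucleus_sample(probs: np.ndarray, top_p: float,
                    rng: np.random.Generator) -> int:
    """Inclusive nucleus sampling from one probability vector."""
    order = np.argsort(-probs)
    sorted_p = probs[order]
    cum = np.cumsum(sorted_p)
    cut = min(int(np.searchsorted(cum, top_p, side="left")) + 1, len(sorted_p))
    kept = sorted_p[:cut] / sorted_p[:cut].sum()
    return int(order[rng.choice(cut, p=kept)])


def generate(policy: CausalPolicy, prompts: list[list[int]], eos_id: int,
             top_p: float = 1.0, max_len: int = 64,
             seed: int = 0) -> list[list[int]]:
    """Ancestral top-p sampling; each output is prompt + continuation.

    Stops a sequence at eos or when it reaches `max_len` tokens.  Sampling is
    batched; the per-sequence draw order is fixed so results are a function
    of (parameters, prompts, seed) only.
    """
    if not 0.0 < top_p <= 1.0:
        raise ValueError("top_p must be in (0, 1]")
    policy.eval()
    rng = np.random.default_rng(seed)
    seqs = [list(p) for p in prompts]
    done = [False] * len(seqs)
    for i, s in enumerate(seqs):
        if len(s) >= max_len:
            done[i] = True
    with no_grad():
        while not all(done):
            ids, mask = pad_sequences(seqs)
            logits, _ = policy.forward(ids, pad_mask=mask)
            logp = log_softmax(logits, axis=-1).data
            for i, seq in enumerate(seqs):
                if done[i]:
                    continue
                probs = np.exp(logp[i, len(seq) - 1])
                probs /= probs.sum()
                token = _nucleus_sample(probs, top_p, rng)
                seq.append(token)
                if token == eos_id or len(seq) >= max_len:
                    done[i] = True
    return seqs


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(policy: CausalPolicy, path) -> None:
    meta = {"config": asdict(policy.config), "vocab_size": policy.vocab_size,
            "vocabulary": policy.vocabulary.to_json(),
            "vocabulary_hash": policy.vocabulary.content_hash()}
    arrays = {f"param_{i}": a for i, a in enumerate(policy.state_arrays())}
    with open(path, "wb") as fh:
        np.savez(fh, meta=json.dumps(meta), **arrays)


def load_checkpoint(path) -> CausalPolicy:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        policy = CausalPolicy(meta["vocab_size"], PolicyConfig(**meta["config"]))
        n = len(policy.parameters())
        policy.load_state_arrays([data[f"param_{i}"] for i in range(n)])
    policy.vocabulary = TokenVocabulary.from_json(meta["vocabulary"])
    policy.eval()
    return policy
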