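"""Hybrid sequence + descriptor QSAR regressor (the PPO reward model).

The model reads a molecule twice: as a token sequence (embedding -> stacked
LSTM, read out at the last real position) and as a z-scored RDKit descriptor
vector (dense branch).  The two branch outputs are concatenated and passed
through a fusion layer to a single output neuron predicting pIC50.  Training
minimizes MSE with Adam and a reduce-on-plateau schedule; the epoch with the
best evaluation MSE is kept.

Also provides the agreement metrics (MSE and Lin's concordance correlation
coefficient), the data-efficiency experiment over nested training subsets,
and the SELFIES-vs-SMILES representation comparison.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import chem_data
from .chem_data import EfficacyDataset, ScalerParams, TokenVocabulary
from .nn import (Adam, Embedding, LSTM, Linear, Module, ReduceLROnPlateau,
                 Tensor, concat, dropout, no_grad)


@dataclass
class QSARConfig:
    hidden_size: int = 256
    n_recurrent_layers: int = 2
    embed_dim: int = 128
    n_descriptor_dense_layers: int = 1
    learning_rate: float = 1e-3
    dropout: float = 0.3
    batch_size: int = 16
    max_epochs: int = 100
    adam_betas: tuple[float, float] = (0.9, 0.999)
    plateau_factor: float = 0.5
    plateau_patience: int = 5
    use_descriptors: bool = True   # False = sequence-only ablation
    use_sequence: bool = True      # False = descriptor-only ablation
    descriptor_clip: float = 10.0  # clamp |z| of descriptor inputs

    def __post_init__(self):
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (self.use_descriptors or self.use_sequence):
            raise ValueError("at least one input branch must be enabled")


class QSARModel(Module):
    """Fig-style two-branch regressor; forward maps a batch to predicted pIC50."""

    def __init__(self, vocab_size: int, n_descriptors: int, config: QSARConfig,
                 seed: int = 0):
        super().__init__()
        self.config = config
        self.vocab_size = vocab_size
        self.n_descriptors = n_descriptors
        rng = np.random.default_rng(seed)
        H = config.hidden_size
        fusion_in = 0
        if config.use_sequence:
            self.embedding = Embedding(vocab_size, config.embed_dim, rng)
            self.lstm = LSTM(config.embed_dim, H, config.n_recurrent_layers,
                             rng, dropout_p=config.dropout)
            fusion_in += H
        if config.use_descriptors:
            self.desc_layers = []
            d_in = n_descriptors
            for _ in range(config.n_descriptor_dense_layers):
                self.desc_layers.append(Linear(d_in, H, rng))
                d_in = H
            fusion_in += H
        self.fusion = Linear(fusion_in, H, rng)
        self.head = Linear(H, 1, rng)
        # attached after training so the checkpoint is self-contained
        self.vocabulary: TokenVocabulary | None = None
        self.scaler: ScalerParams | None = None
        self.descriptor_names: list[str] | None = None
        self.representation: str = "selfies"

    def forward(self, ids: np.ndarray, lengths: np.ndarray,
                descriptors: np.ndarray,
                rng: np.random.Generator | None = None) -> Tensor:
        """ids (B, T) padded with 0; lengths (B,); descriptors (B, D) z-scored."""
        cfg = self.config
        parts = []
        if cfg.use_sequence:
            if ids.max(initial=0) >= self.vocab_size:
                raise ValueError("token id out of vocabulary range")
            x = self.embedding(ids)
            outs = self.lstm(x, rng=rng)            # (B, T, H)
            B = ids.shape[0]
            h_last = outs[np.arange(B), lengths - 1, :]  # true last position
            parts.append(dropout(h_last, cfg.dropout, rng, self.training))
        if cfg.use_descriptors:
            # z-scores far outside the train range carry no calibrated
            # signal; clamping keeps predictions bounded off-distribution
            d = Tensor(np.clip(descriptors, -cfg.descriptor_clip,
                               cfg.descriptor_clip))
            for layer in self.desc_layers:
                d = dropout(layer(d).relu(), cfg.dropout, rng, self.training)
            parts.append(d)
        h = parts[0] if len(parts) == 1 else concat(parts, axis=1)
        h = dropout(self.fusion(h).relu(), cfg.dropout, rng, self.training)
        return self.head(h).reshape(-1)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def mse(pred: np.ndarray, true: np.ndarray) -> float:
    pred, true = np.asarray(pred, float), np.asarray(true, float)
    if pred.shape != true.shape or pred.size < 2:
        raise ValueError("mse needs two equal-length vectors of size >= 2")
    return float(np.mean((pred - true) ** 2))


def ccc(pred: np.ndarray, true: np.ndarray) -> float:
    """Lin's concordance correlation coefficient with population moments.

    CCC = 2 cov(x, y) / (var x + var y + (mean x - mean y)^2); defined as 0
    when both vectors are constant.
    """
    x, y = np.asarray(pred, float), np.asarray(true, float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("ccc needs two equal-length vectors of size >= 2")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = ((x - mx) * (y - my)).mean()
    denom = vx + vy + (mx - my) ** 2
    if denom == 0.0:
        return 0.0
    return float(2.0 * cov / denom)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _sequences_for(dataset: EfficacyDataset,
                   representation: str) -> tuple[list[list[int]], TokenVocabulary]:
    if representation == "selfies":
        vocab = dataset.vocabulary
        seqs = [vocab.encode(r.selfies_tokens) for r in dataset.records]
    elif representation == "smiles":
        token_lists = [chem_data.tokenize_smiles_chars(r.smiles)
                       for r in dataset.records]
        vocab = TokenVocabulary.from_corpus(token_lists)
        seqs = [vocab.encode(toks) for toks in token_lists]
    else:
        raise ValueError(f"unknown representation {representation!r}")
    return seqs, vocab


def _pad_batch(seqs: list[list[int]], pad_id: int = 0) -> tuple[np.ndarray, np.ndarray]:
    lengths = np.array([max(len(s), 1) for s in seqs])
    T = int(lengths.max())
    ids = np.full((len(seqs), T), pad_id, dtype=np.int64)
    for i, s in enumerate(seqs):
        ids[i, :len(s)] = s
    return ids, lengths


def predict(model: QSARModel, seqs: list[list[int]], descriptors: np.ndarray,
            batch_size: int = 64) -> np.ndarray:
    model.eval()
    out = []
    with no_grad():
        for start in range(0, len(seqs), batch_size):
            sl = slice(start, start + batch_size)
            ids, lengths = _pad_batch(seqs[sl])
            out.append(model.forward(ids, lengths, descriptors[sl]).data)
    return np.concatenate(out) if out else np.empty(0)


def train_qsar(dataset: EfficacyDataset, config: QSARConfig, seed: int = 0,
               representation: str = "selfies",
               train_idx: np.ndarray | None = None
               ) -> tuple[QSARModel, pd.DataFrame]:
    """Fit the regressor; returns (best-eval-MSE checkpoint, per-epoch history)."""
    seqs, vocab = _sequences_for(dataset, representation)
    train_idx = dataset.train_idx if train_idx is None else np.asarray(train_idx)
    eval_idx = dataset.eval_idx
    y = dataset.pic50s()
    X = dataset.normalized_matrix

    model = QSARModel(vocab.size, X.shape[1], config, seed=seed)
    optimizer = Adam(model.parameters(), lr=config.learning_rate,
                     betas=config.adam_betas)
    scheduler = ReduceLROnPlateau(optimizer, factor=config.plateau_factor,
                                  patience=config.plateau_patience)
    rng = np.random.default_rng(seed + 1)
    eval_seqs = [seqs[i] for i in eval_idx]

    history = {"epoch": [], "train_mse": [], "eval_mse": [], "lr": []}
    best_eval = math.inf
    best_state: list[np.ndarray] | None = None
    for epoch in range(config.max_epochs):
        model.train()
        order = rng.permutation(train_idx)
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            if len(batch) < 2:
                continue
            ids, lengths = _pad_batch([seqs[i] for i in batch])
            pred = model.forward(ids, lengths, X[batch], rng=rng)
            err = pred - Tensor(y[batch])
            loss = (err * err).mean()
            if not np.isfinite(loss.item()):
                raise RuntimeError(f"training diverged at epoch {epoch}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_losses.append(loss.item())
        eval_pred = predict(model, eval_seqs, X[eval_idx])
        eval_mse = mse(eval_pred, y[eval_idx])
        scheduler.step(eval_mse)
        history["epoch"].append(epoch)
        history["train_mse"].append(float(np.mean(epoch_losses)))
        history["eval_mse"].append(eval_mse)
        history["lr"].append(optimizer.lr)
        if eval_mse < best_eval:
            best_eval = eval_mse
            best_state = [a.copy() for a in model.state_arrays()]
    if best_state is not None:
        model.load_state_arrays(best_state)
    model.eval()
    model.vocabulary = vocab
    model.scaler = dataset.scaler
    model.descriptor_names = dataset.descriptor_names
    model.representation = representation
    return model, pd.DataFrame(history)


def evaluate_qsar(model: QSARModel, dataset: EfficacyDataset,
                  representation: str | None = None) -> dict[str, float]:
    """Eval-split MSE and CCC of a trained model."""
    representation = representation or model.representation
    seqs, _ = _sequences_for(dataset, representation)
    idx = dataset.eval_idx
    pred = predict(model, [seqs[i] for i in idx], dataset.normalized_matrix[idx])
    y = dataset.pic50s()[idx]
    return {"mse": mse(pred, y), "ccc": ccc(pred, y)}


def data_efficiency_experiment(dataset: EfficacyDataset, sizes: list[int],
                               config: QSARConfig, seed: int = 0
                               ) -> pd.DataFrame:
    """Retrain at several training-set sizes against one fixed eval split.

    Subsets are nested (each smaller one is a prefix of the larger) to reduce
    between-size variance; the eval set never changes.
    """
    if any(s > len(dataset.train_idx) for s in sizes):
        raise ValueError("requested size exceeds available training set")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(dataset.train_idx)
    rows = []
    for size in sizes:
        model, _ = train_qsar(dataset, config, seed=seed,
                              train_idx=np.sort(perm[:size]))
        metrics = evaluate_qsar(model, dataset)
        rows.append({"size": size, **metrics})
    return pd.DataFrame(rows)


def compare_representations(dataset: EfficacyDataset, config: QSARConfig,
                            seed: int = 0) -> pd.DataFrame:
    """Same architecture trained on SELFIES tokens vs SMILES characters."""
    rows = []
    for representation in ("selfies", "smiles"):
        model, _ = train_qsar(dataset, config, seed=seed,
                              representation=representation)
        metrics = evaluate_qsar(model, dataset, representation)
        rows.append({"representation": representation,
                     "vocab_size": model.vocab_size, **metrics})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: QSARModel, path) -> None:
    meta = {
        "config": asdict(model.config),
        "vocab_size": model.vocab_size,
        "n_descriptors": model.n_descriptors,
        "vocabulary": model.vocabulary.to_json(),
        "vocabulary_hash": model.vocabulary.content_hash(),
        "scaler": model.scaler.to_json(),
        "descriptor_names": model.descriptor_names,
        "representation": model.representation,
    }
    arrays = {f"param_{i}": a for i, a in enumerate(model.state_arrays())}
    with open(path, "wb") as fh:
        np.savez(fh, meta=json.dumps(meta), **arrays)


def load_checkpoint(path) -> QSARModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        cfg = meta["config"]
        cfg["adam_betas"] = tuple(cfg["adam_betas"])
        model = QSARModel(meta["vocab_size"], meta["n_descriptors"],
                          QSARConfig(**cfg))
        n = len(model.parameters())
        model.load_state_arrays([data[f"param_{i}"] for i in range(n)])
    model.vocabulary = TokenVocabulary.from_json(meta["vocabulary"])
    model.scaler = ScalerParams.from_json(meta["scaler"])
    model.descriptor_names = meta["descriptor_names"]
    model.representation = meta["representation"]
    model.eval()
    return model
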