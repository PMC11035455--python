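"""Ingestion and preprocessing of BindingDB-style activity tables.

Turns a delimited table of (SMILES, IC50) rows into a deduplicated,
tokenized, descriptor-annotated dataset ready for QSAR training and policy
fine-tuning: IC50 -> pIC50 conversion, canonical-SMILES dedup with
arithmetic-mean averaging of repeated measurements, SELFIES-style
tokenization, vocabulary construction, RDKit descriptor computation with
train-set z-scoring, and a seeded 80/20 split.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors
from sklearn.preprocessing import StandardScaler

from . import codec

logger = logging.getLogger(__name__)

#: accepted IC50 unit tags and their molar conversion factors
UNIT_TO_MOLAR = {"nM": 1e-9, "uM": 1e-6, "µM": 1e-6, "M": 1.0}

PAD, BOS, EOS = "[pad]", "[bos]", "[eos]"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class MoleculeRecord:
    """One unique ligand after dedup-averaging."""
    smiles: str                     # canonical SMILES
    selfies_tokens: list[str]       # round-trips to `smiles`
    pic50: float                    # -log10 of molar IC50
    n_measurements: int = 1


class TokenVocabulary:
    """token <-> id map shared by the policy and the QSAR sequence encoder.

    Ids are contiguous from 0 with the special tokens first:
    ``[pad]=0, [bos]=1, [eos]=2``.
    """

    def __init__(self, tokens: list[str]):
        specials = [PAD, BOS, EOS]
        body = sorted(set(tokens) - set(specials))
        self.id_to_token: list[str] = specials + body
        self.token_to_id: dict[str, int] = {
            t: i for i, t in enumerate(self.id_to_token)}

    @classmethod
    def from_corpus(cls, corpus: list[list[str]]) -> "TokenVocabulary":
        if not corpus:
            raise ValueError("empty corpus")
        tokens: set[str] = set()
        for seq in corpus:
            tokens.update(seq)
        return cls(sorted(tokens))

    @property
    def size(self) -> int:
        return len(self.id_to_token)

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD]

    @property
    def bos_id(self) -> int:
        return self.token_to_id[BOS]

    @property
    def eos_id(self) -> int:
        return self.token_to_id[EOS]

    def encode(self, tokens: list[str]) -> list[int]:
        return [self.token_to_id[t] for t in tokens]

    def decode(self, ids: list[int]) -> list[str]:
        return [self.id_to_token[i] for i in ids]

    def content_hash(self) -> str:
        payload = "\x00".join(self.id_to_token).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def to_json(self) -> dict:
        return {"id_to_token": self.id_to_token}

    @classmethod
    def from_json(cls, obj: dict) -> "TokenVocabulary":
        vocab = cls.__new__(cls)
        vocab.id_to_token = list(obj["id_to_token"])
        vocab.token_to_id = {t: i for i, t in enumerate(vocab.id_to_token)}
        return vocab


@dataclass
class ScalerParams:
    """Per-descriptor location/scale fitted on the training rows only."""
    mean: np.ndarray
    scale: np.ndarray            # 1.0 for zero-variance columns
    train_col_means: np.ndarray  # imputation values for NaN descriptors

    def to_json(self) -> dict:
        return {"mean": self.mean.tolist(), "scale": self.scale.tolist(),
                "train_col_means": self.train_col_means.tolist()}

    @classmethod
    def from_json(cls, obj: dict) -> "ScalerParams":
        return cls(np.asarray(obj["mean"]), np.asarray(obj["scale"]),
                   np.asarray(obj["train_col_means"]))


@dataclass
class EfficacyDataset:
    """Deduplicated records plus descriptors, split and scaler."""
    records: list[MoleculeRecord]
    descriptor_names: list[str]
    descriptor_matrix: np.ndarray          # raw values, NaN-imputed
    normalized_matrix: np.ndarray          # z-scores under train scaler
    train_idx: np.ndarray
    eval_idx: np.ndarray
    scaler: ScalerParams
    vocabulary: TokenVocabulary
    seed: int = 0

    @property
    def n(self) -> int:
        return len(self.records)

    def pic50s(self) -> np.ndarray:
        return np.array([r.pic50 for r in self.records])

    def canonical_set(self) -> set[str]:
        return {r.smiles for r in self.records}


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def ic50_to_pic50(ic50: float, unit: str = "nM") -> float:
    """pIC50 = -log10(IC50 in molar); e.g. 100 nM -> 7.0."""
    if unit not in UNIT_TO_MOLAR:
        raise ValueError(f"unknown IC50 unit {unit!r}")
    if ic50 is None or not math.isfinite(ic50) or ic50 <= 0:
        raise ValueError(f"IC50 must be positive and finite, got {ic50!r}")
    return -math.log10(ic50 * UNIT_TO_MOLAR[unit])


def deduplicate_and_average(
        rows: list[tuple[str, float]]) -> tuple[list[MoleculeRecord], int]:
    """Group rows by canonical SMILES and average their pIC50 values.

    Returns (records sorted by canonical SMILES, number of dropped rows).
    Rows whose SMILES cannot be parsed or tokenized are dropped and counted.
    """
    groups: dict[str, list[float]] = {}
    dropped = 0
    for smiles, pic50 in rows:
        canonical = codec.canonical_smiles(smiles)
        if canonical is None:
            logger.warning("dropping unparseable SMILES %r", smiles)
            dropped += 1
            continue
        groups.setdefault(canonical, []).append(float(pic50))
    records = []
    for canonical in sorted(groups):
        try:
            tokens = codec.encode(canonical)
        except ValueError as exc:
            logger.warning("dropping %r: %s", canonical, exc)
            dropped += len(groups[canonical])
            continue
        values = groups[canonical]
        records.append(MoleculeRecord(
            smiles=canonical, selfies_tokens=tokens,
            pic50=float(np.mean(values)), n_measurements=len(values)))
    return records, dropped


def split_dataset(n: int, train_frac: float = 0.8,
                  seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Single seeded shuffle into train/eval; |train| = floor(train_frac * n)."""
    if n < 2:
        raise ValueError("need at least 2 records to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(math.floor(train_frac * n))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def smiles_to_selfies(smiles: str) -> list[str]:
    return codec.encode(smiles)


def selfies_to_smiles(tokens: list[str]) -> str:
    return codec.decode(tokens)


def build_vocabulary(corpus: list[list[str]]) -> TokenVocabulary:
    return TokenVocabulary.from_corpus(corpus)


_DESCRIPTOR_NAMES: list[str] | None = None


def descriptor_names() -> list[str]:
    """The full numeric RDKit descriptor panel, sorted for determinism."""
    global _DESCRIPTOR_NAMES
    if _DESCRIPTOR_NAMES is None:
        _DESCRIPTOR_NAMES = sorted(name for name, _ in Descriptors._descList)
    return _DESCRIPTOR_NAMES


def compute_descriptors(smiles: str) -> tuple[list[str], np.ndarray]:
    """RDKit descriptor vector; failures become NaN (imputed downstream)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    values = Descriptors.CalcMolDescriptors(mol, missingVal=np.nan, silent=True)
    names = descriptor_names()
    vec = np.array([float(values[name]) for name in names])
    vec[~np.isfinite(vec)] = np.nan
    return names, vec


def compute_descriptor_matrix(smiles_list: list[str]) -> tuple[list[str], np.ndarray]:
    rows = [compute_descriptors(s)[1] for s in smiles_list]
    return descriptor_names(), np.vstack(rows) if rows else np.empty((0, 0))


def normalize_descriptors(
        matrix: np.ndarray,
        train_idx: np.ndarray) -> tuple[np.ndarray, ScalerParams]:
    """Column z-scores with location/scale fitted on training rows only.

    NaN entries are imputed with the train-column mean first; zero-variance
    columns map to all zeros.
    """
    matrix = np.asarray(matrix, dtype=np.float64).copy()
    train_means = np.nanmean(matrix[train_idx], axis=0)
    train_means = np.where(np.isfinite(train_means), train_means, 0.0)
    nan_mask = ~np.isfinite(matrix)
    if nan_mask.any():
        matrix[nan_mask] = np.broadcast_to(train_means, matrix.shape)[nan_mask]
    scaler = StandardScaler()
    scaler.fit(matrix[train_idx])
    normalized = (matrix - scaler.mean_) / scaler.scale_
    params = ScalerParams(mean=scaler.mean_.copy(), scale=scaler.scale_.copy(),
                          train_col_means=train_means)
    return normalized, params


def apply_scaler(vec: np.ndarray, params: ScalerParams) -> np.ndarray:
    vec = np.asarray(vec, dtype=np.float64).copy()
    bad = ~np.isfinite(vec)
    if bad.any():
        vec[bad] = params.train_col_means[bad]
    return (vec - params.mean) / params.scale


_SMILES_TOKEN_RE = re.compile(r"Cl|Br|.")


def tokenize_smiles_chars(smiles: str) -> list[str]:
    """Character-level SMILES tokens with two-character element handling."""
    return _SMILES_TOKEN_RE.findall(smiles)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def load_table(path: str | Path, smiles_col: str = "smiles",
               ic50_col: str = "ic50_nM", unit: str = "nM",
               sep: str | None = None) -> list[tuple[str, float]]:
    """Read a delimited table into (smiles, pic50) rows; invalid IC50s dropped."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    if smiles_col not in df.columns or ic50_col not in df.columns:
        raise ValueError(f"table must have columns {smiles_col!r}, {ic50_col!r}")
    rows = []
    for smiles, ic50 in zip(df[smiles_col], df[ic50_col]):
        try:
            rows.append((str(smiles), ic50_to_pic50(float(ic50), unit)))
        except (TypeError, ValueError) as exc:
            logger.warning("rejecting row (%r, %r): %s", smiles, ic50, exc)
    return rows


def prepare_dataset(rows: list[tuple[str, float]], train_frac: float = 0.8,
                    seed: int = 0) -> EfficacyDataset:
    """Full preprocessing: dedup, tokenize, descriptors, z-score, split."""
    records, _ = deduplicate_and_average(rows)
    if len(records) < 2:
        raise ValueError("need at least 2 unique molecules")
    vocab = build_vocabulary([r.selfies_tokens for r in records])
    names, matrix = compute_descriptor_matrix([r.smiles for r in records])
    train_idx, eval_idx = split_dataset(len(records), train_frac, seed)
    normalized, scaler = normalize_descriptors(matrix, train_idx)
    # store imputed raw matrix alongside z-scores
    raw = np.asarray(matrix, dtype=np.float64).copy()
    bad = ~np.isfinite(raw)
    if bad.any():
        raw[bad] = np.broadcast_to(scaler.train_col_means, raw.shape)[bad]
    return EfficacyDataset(records=records, descriptor_names=names,
                           descriptor_matrix=raw, normalized_matrix=normalized,
                           train_idx=train_idx, eval_idx=eval_idx,
                           scaler=scaler, vocabulary=vocab, seed=seed)


def save_dataset(dataset: EfficacyDataset, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = pd.DataFrame({
        "smiles": [r.smiles for r in dataset.records],
        "pic50": [r.pic50 for r in dataset.records],
        "n_measurements": [r.n_measurements for r in dataset.records],
    })
    table.to_csv(out / "dataset.tsv", sep="\t", index=False)
    sidecar = {
        "seed": dataset.seed,
        "vocabulary": dataset.vocabulary.to_json(),
        "scaler": dataset.scaler.to_json(),
        "descriptor_names": dataset.descriptor_names,
        "train_idx": dataset.train_idx.tolist(),
        "eval_idx": dataset.eval_idx.tolist(),
    }
    (out / "dataset.json").write_text(json.dumps(sidecar))


def load_dataset(out_dir: str | Path) -> EfficacyDataset:
    out = Path(out_dir)
    table = pd.read_csv(out / "dataset.tsv", sep="\t")
    sidecar = json.loads((out / "dataset.json").read_text())
    records = []
    for smiles, pic50, n in zip(table["smiles"], table["pic50"],
                                table["n_measurements"]):
        records.append(MoleculeRecord(smiles=smiles,
                                      selfies_tokens=codec.encode(smiles),
                                      pic50=float(pic50), n_measurements=int(n)))
    scaler = ScalerParams.from_json(sidecar["scaler"])
    names, matrix = compute_descriptor_matrix([r.smiles for r in records])
    raw = matrix.copy()
    bad = ~np.isfinite(raw)
    if bad.any():
        raw[bad] = np.broadcast_to(scaler.train_col_means, raw.shape)[bad]
    normalized = np.vstack([apply_scaler(row, scaler) for row in matrix])
    return EfficacyDataset(
        records=records, descriptor_names=sidecar["descriptor_names"],
        descriptor_matrix=raw, normalized_matrix=normalized,
        train_idx=np.asarray(sidecar["train_idx"]),
        eval_idx=np.asarray(sidecar["eval_idx"]),
        scaler=scaler,
        vocabulary=TokenVocabulary.from_json(sidecar["vocabulary"]),
        seed=int(sidecar["seed"]))
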