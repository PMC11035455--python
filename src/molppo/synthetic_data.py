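"""Synthetic BindingDB-shaped datasets with a known efficacy oracle.

Real activity tables pair ligand SMILES with IC50 measurements whose
underlying structure–activity relationship is unknown.  This module builds
the same shape with a *known* relationship: molecules are drawn as random
token strings over the robust codec alphabet (hence always valid), and a
deterministic oracle maps a molecule's RDKit descriptors through a weighted
z-score and a sigmoid squash onto a pIC50 range.  Because the oracle is an
explicit descriptor function, the hybrid QSAR model can represent it exactly
(identifiability tests), and PPO has a verifiable reward landscape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem
from rdkit.Chem import Descriptors

from . import codec

#: tokens used for random molecule generation: common organic atoms, single
#: and double bonds, one-digit branches and rings — descriptors never fail
GENERATOR_TOKENS = ["[C]", "[C]", "[C]", "[C]", "[=C]", "[N]", "[=N]", "[O]",
                    "[=O]", "[F]", "[S]", "[Cl]", "[Br]",
                    "[Branch1]", "[Branch1]", "[Ring1]", "[Ring1]"]


@dataclass
class OracleSpec:
    """Ground-truth efficacy: pic50 = low + (high-low)·sigmoid(w·z) + noise.

    `z` is the vector of named RDKit descriptors standardized by the fixed
    (center, scale) pairs below — constants typical of drug-like molecules,
    so the oracle is a pure function of the molecule, not of any dataset.
    """
    weights: dict[str, float] = field(default_factory=lambda: {
        "MolWt": 1.0, "MolLogP": 0.7, "TPSA": -0.5,
        "NumHDonors": -0.3, "RingCount": 0.4})
    centers: dict[str, float] = field(default_factory=lambda: {
        "MolWt": 250.0, "MolLogP": 2.0, "TPSA": 60.0,
        "NumHDonors": 1.5, "RingCount": 2.0})
    scales: dict[str, float] = field(default_factory=lambda: {
        "MolWt": 100.0, "MolLogP": 1.5, "TPSA": 40.0,
        "NumHDonors": 1.2, "RingCount": 1.2})
    pic50_low: float = 4.0
    pic50_high: float = 9.0
    noise_sd: float = 0.3

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump({
            "weights": self.weights, "centers": self.centers,
            "scales": self.scales, "pic50_low": self.pic50_low,
            "pic50_high": self.pic50_high, "noise_sd": self.noise_sd}))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "OracleSpec":
        obj = yaml.safe_load(Path(path).read_text())
        return cls(**obj)


@dataclass
class SyntheticDatasetSpec:
    """Shape of the emitted activity table."""
    n_unique: int = 1032
    duplicate_rate: float = 0.25   # Poisson mean of extra measurements per ligand
    max_tokens: int = 40
    seed: int = 0


def generate_molecules(n: int, max_tokens: int = 40, seed: int = 0,
                       attempt_cap: int = 500) -> list[str]:
    """Draw `n` unique valid canonical SMILES from random token strings.

    Raises RuntimeError after `attempt_cap * n` decode attempts (the token
    subset is rich enough that this only triggers for absurd requests).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    out: list[str] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > attempt_cap * n:
            raise RuntimeError(
                f"could not generate {n} unique molecules in {attempts} attempts")
        length = int(rng.integers(8, max_tokens + 1))
        toks = [GENERATOR_TOKENS[i]
                for i in rng.integers(0, len(GENERATOR_TOKENS), length)]
        smiles = codec.decode(toks)
        if not smiles or smiles in seen:
            continue
        seen.add(smiles)
        out.append(smiles)
    return out


def oracle_efficacy(smiles: str, spec: OracleSpec,
                    rng: np.random.Generator | None = None) -> float:
    """Ground-truth pIC50 of a molecule; deterministic when noise_sd == 0."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    score = 0.0
    for name, w in spec.weights.items():
        value = getattr(Descriptors, name)(mol)
        score += w * (value - spec.centers[name]) / spec.scales[name]
    squashed = spec.pic50_low + (spec.pic50_high - spec.pic50_low) / (
        1.0 + np.exp(-score))
    if spec.noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        squashed += rng.normal(0.0, spec.noise_sd)
    return float(squashed)


def oracle_admits_high_efficacy(spec: OracleSpec, threshold: float = 7.0,
                                n_samples: int = 200, seed: int = 0,
                                max_tokens: int = 40) -> bool:
    """Rejection-sampling check that molecules above `threshold` exist."""
    molecules = generate_molecules(n_samples, max_tokens=max_tokens, seed=seed)
    noiseless = OracleSpec(weights=spec.weights, centers=spec.centers,
                           scales=spec.scales, pic50_low=spec.pic50_low,
                           pic50_high=spec.pic50_high, noise_sd=0.0)
    return any(oracle_efficacy(s, noiseless) > threshold for s in molecules)


def make_bindingdb_like_table(molecules: list[str], oracle: OracleSpec,
                              spec: SyntheticDatasetSpec) -> pd.DataFrame:
    """Emit (smiles, ic50_nM) rows with per-ligand repeated measurements.

    Each measurement scatters around the noiseless oracle pIC50 with
    sd = oracle.noise_sd, then converts to nM via IC50 = 10^(9 - pIC50).
    """
    rng = np.random.default_rng(spec.seed)
    noiseless = OracleSpec(weights=oracle.weights, centers=oracle.centers,
                           scales=oracle.scales, pic50_low=oracle.pic50_low,
                           pic50_high=oracle.pic50_high, noise_sd=0.0)
    rows = []
    for smiles in molecules:
        true_pic50 = oracle_efficacy(smiles, noiseless)
        k = 1 + int(rng.poisson(spec.duplicate_rate))
        for _ in range(k):
            observed = true_pic50 + (rng.normal(0.0, oracle.noise_sd)
                                     if oracle.noise_sd > 0 else 0.0)
            rows.append({"smiles": smiles,
                         "ic50_nM": float(10.0 ** (9.0 - observed))})
    return pd.DataFrame(rows)


def simulate_table(n_unique: int = 1032, seed: int = 0,
                   oracle: OracleSpec | None = None,
                   duplicate_rate: float = 0.25,
                   max_tokens: int = 40) -> tuple[pd.DataFrame, OracleSpec]:
    """Convenience wrapper: molecules + oracle + table in one call."""
    oracle = oracle or OracleSpec()
    spec = SyntheticDatasetSpec(n_unique=n_unique, duplicate_rate=duplicate_rate,
                                max_tokens=max_tokens, seed=seed)
    molecules = generate_molecules(n_unique, max_tokens=max_tokens, seed=seed)
    return make_bindingdb_like_table(molecules, oracle, spec), oracle
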