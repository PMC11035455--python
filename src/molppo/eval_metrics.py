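"""Post-hoc evaluation of generated molecule sets.

Validity (parseable SMILES), novelty (absence from the training + evaluation
dataset by canonical SMILES), the high-efficacy fraction (predicted
pIC50 > 7), the linear-scale IC50 fold change between dataset and generated
molecules, and an overlaid property-distribution report (molecular weight,
logP, TPSA, H-bond donors/acceptors, ring count) with kernel-density plots
and distributional distances.

All efficacy values for generated molecules are model-predicted (reward
model output), not experimental.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors
from scipy import stats

from . import codec

#: property panel reported for generated-vs-dataset comparison
PROPERTY_PANEL = {
    "MolWt": Descriptors.MolWt,
    "MolLogP": Descriptors.MolLogP,
    "TPSA": Descriptors.TPSA,
    "NumHDonors": Descriptors.NumHDonors,
    "NumHAcceptors": Descriptors.NumHAcceptors,
    "RingCount": Descriptors.RingCount,
}


@dataclass
class GenerationReport:
    n_generated: int
    validity: float
    novelty: float
    uniqueness: float
    pic50_values: np.ndarray
    fraction_above_7: float
    ic50_fold_change: float
    ic50_fold_change_geometric: float
    property_table: pd.DataFrame
    property_distances: dict = field(default_factory=dict)

    def to_json(self) -> dict:
        return {
            "n_generated": self.n_generated,
            "validity": self.validity,
            "novelty": self.novelty,
            "uniqueness": self.uniqueness,
            "fraction_above_7": self.fraction_above_7,
            "ic50_fold_change": self.ic50_fold_change,
            "ic50_fold_change_geometric": self.ic50_fold_change_geometric,
            "pic50_values": [float(v) for v in self.pic50_values],
            "pic50_source": "model-predicted",
            "property_distances": self.property_distances,
        }


def validity(smiles_list: list[str]) -> float:
    """Fraction of strings RDKit can parse."""
    if not smiles_list:
        raise ValueError("empty input")
    ok = sum(Chem.MolFromSmiles(s) is not None for s in smiles_list)
    return ok / len(smiles_list)


def novelty(smiles_list: list[str], dataset_smiles: set[str] | list[str]) -> float:
    """Fraction of generated sequences absent from the dataset.

    Comparison is by canonical SMILES over the union of train and eval
    molecules; each generated sequence counts once (duplicates are not
    collapsed — a separate uniqueness metric covers that).
    """
    if not smiles_list:
        raise ValueError("empty input")
    reference = {codec.canonical_smiles(s) for s in dataset_smiles}
    hits = 0
    for s in smiles_list:
        canonical = codec.canonical_smiles(s)
        if canonical is not None and canonical not in reference:
            hits += 1
    return hits / len(smiles_list)


def uniqueness(smiles_list: list[str]) -> float:
    """Fraction of distinct canonical SMILES among generated sequences."""
    if not smiles_list:
        raise ValueError("empty input")
    canon = [codec.canonical_smiles(s) for s in smiles_list]
    return len(set(canon)) / len(smiles_list)


def fraction_above_threshold(pic50s: np.ndarray, threshold: float = 7.0) -> float:
    """Fraction with pIC50 strictly greater than the threshold."""
    pic50s = np.asarray(pic50s, dtype=np.float64)
    if pic50s.size == 0:
        raise ValueError("empty input")
    return float(np.mean(pic50s > threshold))


def ic50_fold_change(dataset_pic50s: np.ndarray,
                     generated_pic50s: np.ndarray) -> float:
    """mean(IC50 dataset) / mean(IC50 generated), on the linear molar scale.

    Values above 1 mean the generated molecules are more potent on average.
    """
    d = 10.0 ** -np.asarray(dataset_pic50s, dtype=np.float64)
    g = 10.0 ** -np.asarray(generated_pic50s, dtype=np.float64)
    if d.size == 0 or g.size == 0:
        raise ValueError("empty input")
    return float(d.mean() / g.mean())


def ic50_fold_change_geometric(dataset_pic50s: np.ndarray,
                               generated_pic50s: np.ndarray) -> float:
    """Geometric-mean variant: 10^(mean generated pIC50 - mean dataset pIC50)."""
    d = np.asarray(dataset_pic50s, dtype=np.float64)
    g = np.asarray(generated_pic50s, dtype=np.float64)
    if d.size == 0 or g.size == 0:
        raise ValueError("empty input")
    return float(10.0 ** (g.mean() - d.mean()))


def property_table(smiles_list: list[str]) -> pd.DataFrame:
    rows = []
    for s in smiles_list:
        mol = Chem.MolFromSmiles(s)
        if mol is None or mol.GetNumAtoms() == 0:
            continue
        rows.append({"smiles": s,
                     **{name: fn(mol) for name, fn in PROPERTY_PANEL.items()}})
    return pd.DataFrame(rows)


def property_report(smiles_list: list[str], reference_list: list[str],
                    out_dir: str | Path | None = None
                    ) -> tuple[pd.DataFrame, dict]:
    """Property panel for generated molecules plus distances to a reference.

    Per property: Wasserstein distance and the two-sample KS statistic
    between the generated and reference distributions.  With `out_dir`,
    writes normalized KDE overlay plots (scipy's rule-of-thumb bandwidth,
    recorded in the metadata).
    """
    gen = property_table(smiles_list)
    ref = property_table(reference_list)
    distances: dict = {"kde_bandwidth": "scott"}
    for name in PROPERTY_PANEL:
        g, r = gen[name].to_numpy(float), ref[name].to_numpy(float)
        if len(g) < 2 or len(r) < 2:
            continue
        distances[name] = {
            "wasserstein": float(stats.wasserstein_distance(g, r)),
            "ks_statistic": float(stats.ks_2samp(g, r).statistic),
        }
    if out_dir is not None:
        _plot_kde_overlays(gen, ref, Path(out_dir))
    return gen, distances


def _plot_kde_overlays(gen: pd.DataFrame, ref: pd.DataFrame,
                       out_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir.mkdir(parents=True, exist_ok=True)
    for name in PROPERTY_PANEL:
        fig, ax = plt.subplots(figsize=(4, 3))
        plotted = False
        for label, values in (("generated", gen[name]), ("dataset", ref[name])):
            v = values.to_numpy(float)
            if len(np.unique(v)) < 2:
                continue
            kde = stats.gaussian_kde(v)  # Scott's rule bandwidth
            xs = np.linspace(v.min(), v.max(), 200)
            ax.plot(xs, kde(xs), label=label)
            plotted = True
        ax.set_xlabel(name)
        ax.set_ylabel("density")
        if plotted:
            ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(out_dir / f"kde_{name}.svg")
        plt.close(fig)


def build_report(generated_smiles: list[str], generated_pic50s: np.ndarray,
                 dataset_smiles: list[str], dataset_pic50s: np.ndarray,
                 out_dir: str | Path | None = None) -> GenerationReport:
    """Assemble the full evaluation report for a generation batch."""
    table, distances = property_report(generated_smiles, dataset_smiles,
                                       out_dir=out_dir)
    report = GenerationReport(
        n_generated=len(generated_smiles),
        validity=validity(generated_smiles),
        novelty=novelty(generated_smiles, dataset_smiles),
        uniqueness=uniqueness(generated_smiles),
        pic50_values=np.asarray(generated_pic50s, dtype=np.float64),
        fraction_above_7=fraction_above_threshold(generated_pic50s, 7.0),
        ic50_fold_change=ic50_fold_change(dataset_pic50s, generated_pic50s),
        ic50_fold_change_geometric=ic50_fold_change_geometric(
            dataset_pic50s, generated_pic50s),
        property_table=table,
        property_distances=distances,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report.to_json(), indent=1))
    return report
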