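"""Hybrid QSAR regressor: metrics, forward pass, training behavior."""

import numpy as np
import pytest

from molppo import qsar_reward
from molppo.nn import no_grad
from molppo.qsar_reward import (QSARConfig, QSARModel, ccc, mse, predict,
                                train_qsar)


def lin_ccc_reference(x, y):
    """Brute-force Lin's formula with explicit loops (independent oracle)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    vx = sum((xi - mx) ** 2 for xi in x) / n
    vy = sum((yi - my) ** 2 for yi in y) / n
    cov = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y)) / n
    denom = vx + vy + (mx - my) ** 2
    return 0.0 if denom == 0 else 2 * cov / denom


class TestMetrics:
    def test_ccc_known_value(self):
        # shifted-by-one line: 2*var / (2*var + 1) with var([1,2,3]) = 2/3
        assert ccc([1, 2, 3], [2, 3, 4]) == pytest.approx(4 / 7)

    def test_ccc_identity_and_constants(self):
        assert ccc([1.0, 2.0, 5.0], [1.0, 2.0, 5.0]) == pytest.approx(1.0)
        assert ccc([3.0, 3.0, 3.0], [1.0, 2.0, 3.0]) == 0.0
        assert ccc([3.0, 3.0], [3.0, 3.0]) == 0.0

    def test_ccc_matches_brute_force(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 21))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            assert ccc(x, y) == pytest.approx(lin_ccc_reference(x, y),
                                              abs=1e-10)

    def test_ccc_bounded_by_pearson(self, rng):
        for _ in range(100):
            x = rng.normal(size=15)
            y = rng.normal(size=15)
            assert abs(ccc(x, y)) <= abs(np.corrcoef(x, y)[0, 1]) + 1e-12

    def test_mse(self):
        assert mse([1.0, 2.0], [1.0, 4.0]) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            mse([1.0], [1.0])


class TestForward:
    def make_model(self, **kwargs):
        cfg = QSARConfig(hidden_size=4, embed_dim=3, n_recurrent_layers=1,
                         dropout=0.0, **kwargs)
        return QSARModel(vocab_size=5, n_descriptors=2, config=cfg, seed=0)

    def test_zero_parameters_give_bias(self):
        model = self.make_model().eval()
        model.load_state_arrays([np.zeros_like(a)
                                 for a in model.state_arrays()])
        model.head.bias.data[:] = 1.25
        with no_grad():
            out = model.forward(np.array([[1, 2, 3]]), np.array([3]),
                                np.zeros((1, 2)))
        assert out.data == pytest.approx([1.25])

    def test_batch_permutation_equivariance(self, rng):
        model = self.make_model().eval()
        ids = rng.integers(0, 5, size=(6, 4))
        lengths = np.full(6, 4)
        desc = rng.normal(size=(6, 2))
        with no_grad():
            out = model.forward(ids, lengths, desc).data
            perm = np.array([3, 1, 5, 0, 2, 4])
            out_perm = model.forward(ids[perm], lengths[perm],
                                     desc[perm]).data
        assert np.allclose(out[perm], out_perm)

    def test_out_of_vocab_id_rejected(self):
        model = self.make_model().eval()
        with pytest.raises(ValueError):
            model.forward(np.array([[9]]), np.array([1]), np.zeros((1, 2)))

    def test_hand_computed_descriptor_only_forward(self):
        """Descriptor branch with hand-set weights against pencil arithmetic."""
        cfg = QSARConfig(hidden_size=1, embed_dim=1, n_recurrent_layers=1,
                         dropout=0.0, use_sequence=False)
        model = QSARModel(vocab_size=3, n_descriptors=2, config=cfg, seed=0)
        model.desc_layers[0].weight.data = np.array([[2.0], [-1.0]])
        model.desc_layers[0].bias.data = np.array([0.5])
        model.fusion.weight.data = np.array([[3.0]])
        model.fusion.bias.data = np.array([-1.0])
        model.head.weight.data = np.array([[0.5]])
        model.head.bias.data = np.array([0.25])
        model.eval()
        # d = relu(2*1 - 1*2 + 0.5) = 0.5 ; f = relu(3*0.5 - 1) = 0.5
        # out = 0.5*0.5 + 0.25 = 0.5
        with no_grad():
            out = model.forward(np.array([[0]]), np.array([1]),
                                np.array([[1.0, 2.0]]))
        assert out.data == pytest.approx([0.5])


class TestTraining:
    CFG = dict(hidden_size=32, embed_dim=12, dropout=0.1, max_epochs=20)

    def test_learns_noiseless_oracle(self, noiseless_dataset):
        dataset, _ = noiseless_dataset
        model, history = train_qsar(dataset, QSARConfig(**self.CFG), seed=0)
        metrics = qsar_reward.evaluate_qsar(model, dataset)
        assert metrics["ccc"] > 0.6
        assert history["eval_mse"].iloc[-1] < history["eval_mse"].iloc[0]

    def test_shuffled_labels_destroy_signal(self, noiseless_dataset):
        dataset, _ = noiseless_dataset
        rng = np.random.default_rng(3)
        shuffled = [dict(vars(r)) for r in dataset.records]
        perm = rng.permutation(dataset.n)
        import copy
        ds = copy.copy(dataset)
        ds.records = [copy.copy(r) for r in dataset.records]
        for rec, j in zip(ds.records, perm):
            rec.pic50 = dataset.records[j].pic50
        model, _ = train_qsar(ds, QSARConfig(**self.CFG), seed=0)
        metrics = qsar_reward.evaluate_qsar(model, ds)
        assert abs(metrics["ccc"]) < 0.35

    def test_deterministic_history(self, small_dataset):
        dataset, _ = small_dataset
        cfg = QSARConfig(hidden_size=8, embed_dim=4, dropout=0.1, max_epochs=3)
        _, h1 = train_qsar(dataset, cfg, seed=5)
        _, h2 = train_qsar(dataset, cfg, seed=5)
        assert h1.equals(h2)

    def test_predictions_not_collapsed(self, noiseless_dataset):
        dataset, _ = noiseless_dataset
        model, _ = train_qsar(dataset, QSARConfig(**self.CFG), seed=0)
        seqs = [dataset.vocabulary.encode(r.selfies_tokens)
                for r in dataset.records]
        preds = predict(model, [seqs[i] for i in dataset.train_idx],
                        dataset.normalized_matrix[dataset.train_idx])
        assert preds.std() > 0.1


class TestExperiments:
    def test_data_efficiency_table(self, small_dataset):
        dataset, _ = small_dataset
        cfg = QSARConfig(hidden_size=8, embed_dim=4, dropout=0.1, max_epochs=2)
        table = qsar_reward.data_efficiency_experiment(
            dataset, [20, 40], cfg, seed=0)
        assert list(table["size"]) == [20, 40]
        assert set(table.columns) >= {"size", "mse", "ccc"}

    def test_data_efficiency_rejects_oversize(self, small_dataset):
        dataset, _ = small_dataset
        with pytest.raises(ValueError):
            qsar_reward.data_efficiency_experiment(
                dataset, [10_000], QSARConfig(max_epochs=1), seed=0)

    def test_compare_representations(self, small_dataset):
        dataset, _ = small_dataset
        cfg = QSARConfig(hidden_size=8, embed_dim=4, dropout=0.1, max_epochs=2)
        table = qsar_reward.compare_representations(dataset, cfg, seed=0)
        assert set(table["representation"]) == {"selfies", "smiles"}
        assert (table["vocab_size"] > 3).all()


def test_checkpoint_round_trip(small_dataset, tmp_path):
    dataset, _ = small_dataset
    cfg = QSARConfig(hidden_size=8, embed_dim=4, dropout=0.1, max_epochs=2)
    model, _ = train_qsar(dataset, cfg, seed=1)
    path = tmp_path / "qsar.ckpt"
    qsar_reward.save_checkpoint(model, path)
    loaded = qsar_reward.load_checkpoint(path)
    seqs = [dataset.vocabulary.encode(r.selfies_tokens)
            for r in dataset.records[:5]]
    desc = dataset.normalized_matrix[:5]
    assert np.allclose(predict(model, seqs, desc), predict(loaded, seqs, desc))
    assert loaded.vocabulary.content_hash() == dataset.vocabulary.content_hash()
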