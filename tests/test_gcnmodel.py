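"""Model construction, exact gradients, invariances, checkpointing."""

import numpy as np
import pytest

from pocketgcn import curate, featurize, gcnmodel, metrics, pocket, synthdata
from pocketgcn.gcnmodel import ModelConfig, TrainConfig


def _subset(pairs, n, seed=0):
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(pairs))[:n]
    return [pairs[i] for i in idx]


class TestConstruction:
    def test_bc_scores_in_unit_interval(self, tiny_model, small_bc_pairs):
        pairs, _ = small_bc_pairs
        scores = gcnmodel.predict_batch(tiny_model, _subset(pairs, 30))
        assert np.all((scores > 0) & (scores < 1))

    def test_rg_scores_finite_unconstrained(self, small_bc_pairs):
        pairs, _ = small_bc_pairs
        cfg = ModelConfig(pocket_widths=(8,), ligand_widths=(8,), fc_widths=(8,), head="rg")
        model = gcnmodel.build_model(
            cfg, pairs[0].pocket.node_features.shape[1],
            pairs[0].ligand.node_features.shape[1], seed=0,
        )
        scores = gcnmodel.predict_batch(model, _subset(pairs, 30))
        assert np.all(np.isfinite(scores))

    def test_seeded_init_reproducible(self, small_bc_pairs):
        pairs, _ = small_bc_pairs
        dims = (pairs[0].pocket.node_features.shape[1],
                pairs[0].ligand.node_features.shape[1])
        m1 = gcnmodel.build_model(ModelConfig(), *dims, seed=11)
        m2 = gcnmodel.build_model(ModelConfig(), *dims, seed=11)
        assert set(m1.params) == set(m2.params)
        for k in m1.params:
            assert np.array_equal(m1.params[k], m2.params[k])

    def test_feature_dim_mismatch_rejected(self, tiny_model, small_bc_pairs):
        pairs, _ = small_bc_pairs
        batch_l = gcnmodel.pack_graphs([pairs[0].ligand])
        with pytest.raises(ValueError, match="dimension"):
            tiny_model.forward(batch_l, batch_l)


class TestGradients:
    @pytest.mark.parametrize("head", ["bc", "rg"])
    def test_backprop_matches_finite_differences(self, head, small_bc_pairs):
        """Analytic gradients agree with central finite differences for
        every parameter tensor (spot-checked entries), both heads."""
        pairs, _ = small_bc_pairs
        batch = _subset(pairs, 6, seed=2)
        cfg = ModelConfig(pocket_widths=(5, 4), ligand_widths=(6,), fc_widths=(7, 5),
                          head=head, dropout=0.0)
        model = gcnmodel.build_model(
            cfg, batch[0].pocket.node_features.shape[1],
            batch[0].ligand.node_features.shape[1], seed=1,
        )
        pockets, ligands, labels = gcnmodel.collate(batch)
        labels = labels if head == "bc" else labels + 5.0
        loss_fn = gcnmodel.bce_loss if head == "bc" else gcnmodel.mse_loss

        def total_loss():
            return loss_fn(model.forward(pockets, ligands), labels)[0]

        scores, cache = model.forward(pockets, ligands, return_cache=True)
        _, d_scores = loss_fn(scores, labels)
        d_logits = (scores - labels) / len(labels) if head == "bc" else d_scores
        grads = model.backward(pockets, ligands, cache, d_logits)
        rng = np.random.default_rng(0)
        h = 1e-6
        for name, g in grads.items():
            flat = g.ravel()
            for idx in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = model.params[name].ravel()[idx]
                model.params[name].ravel()[idx] = orig + h
                up = total_loss()
                model.params[name].ravel()[idx] = orig - h
                down = total_loss()
                model.params[name].ravel()[idx] = orig
                numeric = (up - down) / (2 * h)
                assert numeric == pytest.approx(flat[idx], rel=1e-4, abs=1e-7), name


class TestForwardInvariances:
    def test_eval_mode_deterministic(self, tiny_model, small_bc_pairs):
        pairs, _ = small_bc_pairs
        batch = _subset(pairs, 10)
        s1 = gcnmodel.predict_batch(tiny_model, batch)
        s2 = gcnmodel.predict_batch(tiny_model, batch)
        assert np.array_equal(s1, s2)

    def test_node_permutation_invariance(self, tiny_model, small_bc_pairs):
        pairs, _ = small_bc_pairs
        pair = pairs[5]
        rng = np.random.default_rng(1)
        perm = rng.permutation(pair.pocket.n_nodes)
        inv = np.argsort(perm)
        permuted = pocket.PocketGraph(
            node_features=pair.pocket.node_features[perm],
            edges=[(int(inv[i]), int(inv[j])) for i, j in pair.pocket.edges],
        )
        s0 = gcnmodel.forward_pair(tiny_model, pair.pocket, pair.ligand)
        s1 = gcnmodel.forward_pair(tiny_model, permuted, pair.ligand)
        assert s1 == pytest.approx(s0, abs=1e-5)

    def test_batch_matches_single_forward(self, tiny_model, small_bc_pairs):
        pairs, _ = small_bc_pairs
        batch = _subset(pairs, 40, seed=3)
        batched = gcnmodel.predict_batch(tiny_model, batch)
        single = np.array(
            [gcnmodel.forward_pair(tiny_model, p.pocket, p.ligand) for p in batch]
        )
        assert np.max(np.abs(batched - single)) <= 1e-6

    def test_shuffled_batch_scores_permute(self, tiny_model, small_bc_pairs):
        pairs, _ = small_bc_pairs
        batch = _subset(pairs, 20, seed=4)
        scores = gcnmodel.predict_batch(tiny_model, batch)
        perm = np.random.default_rng(0).permutation(len(batch))
        shuffled = gcnmodel.predict_batch(tiny_model, [batch[i] for i in perm])
        assert np.allclose(shuffled, scores[perm], atol=1e-9)

    def test_untrained_model_null_auc_band(self):
        """An untrained classifier scores a balanced labeled set at
        chance level: AUC within [0.4, 0.6] at n=500."""
        rng = np.random.default_rng(12)
        lib = synthdata.make_ligand_library(40, seed=2)
        table = featurize.default_embedding_table(lib, seed=0, epochs=3)
        graphs = [featurize.ligand_to_graph(
            __import__("pocketgcn").chemio.parse_ligand(s)) for s in lib]
        pdb, _ = synthdata.make_toy_structure(12, seed=0)
        from pocketgcn import chemio

        s = chemio.read_structure(pdb)
        res = pocket.extract_pocket(s, s.hetero_coords("LIG"), cutoff_nm=0.8)
        pg = pocket.build_pocket_graph(res, table)
        labels_perm = rng.permutation([0.0] * 250 + [1.0] * 250)
        pairs = [
            curate.LabeledPair("P0", f"L{i}", pg, graphs[i % len(graphs)],
                               float(labels_perm[i]), "binary")
            for i in range(500)
        ]
        cfg = ModelConfig(pocket_widths=(8, 8), ligand_widths=(8, 8), fc_widths=(16, 8))
        model = gcnmodel.build_model(cfg, 30, graphs[0].node_features.shape[1], seed=9)
        scores = gcnmodel.predict_batch(model, pairs)
        labels = np.array([p.label for p in pairs])
        auc = metrics.classification_metrics(scores, labels)["auc"]
        assert 0.4 <= auc <= 0.6


class TestTraining:
    @pytest.fixture(scope="class")
    def trained(self, small_bc_pairs, tmp_path_factory):
        pairs, _ = small_bc_pairs
        split = curate.split_dataset(pairs, level="pair", fraction=0.25, seed=0)
        tr = [pairs[i] for i in split.train_ids]
        te = [pairs[i] for i in split.test_ids]
        cfg = ModelConfig(pocket_widths=(12, 12), ligand_widths=(12, 12),
                          fc_widths=(24, 12))
        model = gcnmodel.build_model(
            cfg, 30, tr[0].ligand.node_features.shape[1], seed=0
        )
        ckpt_dir = tmp_path_factory.mktemp("ckpts")
        tc = TrainConfig(lr=0.005, epochs=200, checkpoint_interval=100,
                         batch_size=64, seed=0)
        history = gcnmodel.train(model, tr, te, tc, checkpoint_dir=ckpt_dir)
        return model, history, ckpt_dir, te

    def test_checkpoints_at_interval(self, trained):
        _, history, ckpt_dir, _ = trained
        assert history["checkpoints"] == [100, 200]
        assert (ckpt_dir / "checkpoint_epoch00100.npz").exists()
        assert (ckpt_dir / "checkpoint_epoch00200.npz").exists()

    def test_validation_metrics_recorded_each_epoch(self, trained):
        _, history, _, _ = trained
        assert len(history["val"]) == 200
        assert all("loss" in v for v in history["val"])

    def test_training_loss_decreases_over_windows(self, trained):
        """Mean training loss over successive 50-epoch windows is
        non-increasing (non-strict)."""
        _, history, _, _ = trained
        loss = np.array(history["train_loss"])
        windows = loss.reshape(4, 50).mean(axis=1)
        assert np.all(np.diff(windows) <= 1e-6)

    def test_checkpoint_reload_bitwise_identical(self, trained, small_bc_pairs):
        model, _, ckpt_dir, te = trained
        reloaded, meta = gcnmodel.GCNModel.load(ckpt_dir / "checkpoint_epoch00200.npz")
        assert meta["epoch"] == 200
        s1 = gcnmodel.predict_batch(model, te)
        s2 = gcnmodel.predict_batch(reloaded, te)
        assert np.array_equal(s1, s2)

    def test_seeded_training_reproducible(self, small_bc_pairs):
        pairs, _ = small_bc_pairs
        split = curate.split_dataset(pairs, level="pair", fraction=0.25, seed=1)
        tr = [pairs[i] for i in split.train_ids]
        te = [pairs[i] for i in split.test_ids]
        outs = []
        for _ in range(2):
            cfg = ModelConfig(pocket_widths=(8,), ligand_widths=(8,), fc_widths=(8,))
            model = gcnmodel.build_model(cfg, 30, tr[0].ligand.node_features.shape[1], seed=5)
            gcnmodel.train(model, tr, te, TrainConfig(lr=0.005, epochs=20,
                           checkpoint_interval=10, batch_size=64, seed=5))
            outs.append(gcnmodel.predict_batch(model, te))
        assert np.max(np.abs(outs[0] - outs[1])) <= 1e-6

    def test_mismatched_loss_rejected(self, tiny_model, small_bc_pairs):
        pairs, _ = small_bc_pairs
        with pytest.raises(ValueError, match="loss"):
            gcnmodel.train(tiny_model, pairs[:10], pairs[10:12],
                           TrainConfig(epochs=1, checkpoint_interval=1, loss="mse"))

    def test_empty_validation_rejected(self, tiny_model, small_bc_pairs):
        pairs, _ = small_bc_pairs
        with pytest.raises(ValueError, match="validation"):
            gcnmodel.train(tiny_model, pairs[:10], [],
                           TrainConfig(epochs=1, checkpoint_interval=1))
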