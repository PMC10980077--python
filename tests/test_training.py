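"""Training loops: batching, schedules, clipping, dual-phase, ridge heads."""

import numpy as np
import pandas as pd
import pytest

from mutenc.model import ModelConfig, TargetModel, build_model, encode_sequences, predict
from mutenc.preprocess import clean_attribute_table, drop_excluded_terms, standardize_attributes
from mutenc.simulate import make_experimental_dataset, score_variants
from mutenc.training import (
    TrainingError,
    _pdb_batches,
    finetune_config,
    finetune_dual_phase,
    fit_ridge_head,
    multitask_loss,
    pretrain,
    pretrain_config,
)
from mutenc.variants import sample_subvariants


@pytest.fixture(scope="module")
def mini_cfg():
    return ModelConfig(
        embed_dim=16, n_layers=2, n_heads=2, ff_dim=24, dropout=0.1,
        rpe_mode="3d", rpe_clip=3, n_tasks=55, head_hidden=8,
    )


@pytest.fixture(scope="module")
def std_table(toy_structure, sim_params):
    vs = sample_subvariants(toy_structure.sequence, 300, max_subs=3, seed=0, base_id=toy_structure.id)
    t = score_variants(toy_structure, sim_params, vs, noise=False, seed=0)
    clean, _ = clean_attribute_table(t, seed=0)
    clean = drop_excluded_terms(clean)
    perm = np.random.default_rng(0).permutation(len(clean))
    splits = {"train": perm[:240], "val": perm[240:270], "test": perm[270:]}
    std, _ = standardize_attributes(clean, splits["train"])
    return std, splits


@pytest.fixture(scope="module")
def tiny_dataset(toy_structure, additive_params):
    return make_experimental_dataset(
        toy_structure, additive_params, 120, max_subs=2, assay_noise=0.0, seed=1
    )


class TestConfigYaml:
    def test_roundtrip(self, tmp_path):
        from mutenc.training import config_from_yaml, config_to_yaml

        cfg = finetune_config(epochs=7, seed=3)
        path = tmp_path / "cfg.yaml"
        config_to_yaml(cfg, path)
        assert config_from_yaml(path) == cfg

    def test_unknown_field_raises(self, tmp_path):
        from mutenc.training import config_from_yaml

        path = tmp_path / "cfg.yaml"
        path.write_text("momentum: 0.9\n")
        with pytest.raises(TrainingError, match="unknown"):
            config_from_yaml(path)


class TestBatchSampler:
    def test_batches_single_pdb_and_cover_all_rows(self, toy_structure, sim_params):
        vs1 = sample_subvariants(toy_structure.sequence, 40, max_subs=2, seed=0, base_id="a")
        t1 = score_variants(toy_structure, sim_params, vs1, noise=False)
        t2 = t1.copy()
        t1["base_pdb"], t2["base_pdb"] = "a", "b"
        table = pd.concat([t1, t2], ignore_index=True)
        ids = np.arange(len(table))
        batches = _pdb_batches(table, ids, batch_size=16, rng=np.random.default_rng(0))
        seen = []
        for b in batches:
            assert table.loc[b, "base_pdb"].nunique() == 1
            seen.extend(b)
        assert sorted(seen) == list(ids)


class TestPretrain:
    def test_rejects_unstandardized_table(self, toy_structure, sim_params, mini_cfg):
        vs = sample_subvariants(toy_structure.sequence, 60, max_subs=2, seed=0, base_id=toy_structure.id)
        t = score_variants(toy_structure, sim_params, vs, noise=False)
        t = drop_excluded_terms(t)
        m = build_model(mini_cfg, structure=toy_structure, seed=0)
        with pytest.raises(TrainingError, match="standardized"):
            pretrain(m, t, {"train": np.arange(40), "val": np.arange(40, 50)},
                     pretrain_config(epochs=1, batch_size=16), toy_structure)

    def test_loss_zero_for_exact_predictor(self):
        pred = np.random.default_rng(0).normal(size=(8, 3))
        from mutenc.nn import Tensor

        assert float(multitask_loss(Tensor(pred), pred).data) == 0.0

    def test_short_pretraining_decreases_loss_and_clips(self, std_table, toy_structure, mini_cfg):
        std, splits = std_table
        m = build_model(mini_cfg, structure=toy_structure, seed=0)
        cfg = pretrain_config(epochs=8, batch_size=64, seed=0)
        m, hist = pretrain(m, std, splits, cfg, toy_structure)
        assert hist.train_losses[-1] < hist.train_losses[0]
        assert len(hist.val_losses) == 8
        # every post-clip global gradient norm respects the 0.5 bound
        assert max(hist.grad_norms_postclip) <= 0.5 + 1e-9

    def test_deterministic_under_seed(self, std_table, toy_structure, mini_cfg):
        std, splits = std_table
        cfg = pretrain_config(epochs=2, batch_size=64, seed=3)
        _, h1 = pretrain(build_model(mini_cfg, structure=toy_structure, seed=0),
                         std, splits, cfg, toy_structure)
        _, h2 = pretrain(build_model(mini_cfg, structure=toy_structure, seed=0),
                         std, splits, cfg, toy_structure)
        np.testing.assert_allclose(h1.train_losses, h2.train_losses, rtol=1e-12)

    def test_accumulation_chunking_equivalence(self, std_table, toy_structure):
        """Gradient accumulation reproduces full-batch steps (dropout off)."""
        std, splits = std_table
        cfg0 = ModelConfig(16, 1, 2, 24, 0.0, "3d", 3, 55, 8)
        histories = []
        for chunks in (1, 4):
            m = build_model(cfg0, structure=toy_structure, seed=0)
            cfg = pretrain_config(epochs=1, batch_size=80, seed=3, accum_chunks=chunks)
            _, h = pretrain(m, std, splits, cfg, toy_structure)
            histories.append(h.train_losses[-1])
        assert histories[0] == pytest.approx(histories[1], rel=1e-9)


class TestDualPhase:
    def make_target(self, toy_structure, seed=0, n_tasks=55):
        cfg = ModelConfig(16, 1, 2, 24, 0.1, "3d", 3, n_tasks, 8)
        return TargetModel(build_model(cfg, structure=toy_structure, seed=seed),
                           rng=np.random.default_rng(seed))

    def test_backbone_bit_identical_through_phase1(self, toy_structure, tiny_dataset):
        """Phase 1 must not touch the backbone; with a zero phase-2 learning
        rate the whole run leaves backbone weights bit-identical, while the
        head does move."""
        tm = self.make_target(toy_structure)
        before = {k: v.copy() for k, v in tm.state_dict().items()}
        cfg = finetune_config(epochs=3, lr_phase2=0.0, seed=0)
        split = {"train": np.arange(40), "val": np.arange(40, 50)}
        tm, hist = finetune_dual_phase(tm, tiny_dataset, split, cfg, selection_threshold=10**9)
        after = tm.state_dict()
        for k in before:
            if k.startswith("backbone."):
                np.testing.assert_array_equal(before[k], after[k], err_msg=k)
        assert not np.array_equal(before["head.weight"], after["head.weight"])
        assert hist.selection_rule == "last-epoch"

    def test_phase2_updates_backbone(self, toy_structure, tiny_dataset):
        tm = self.make_target(toy_structure)
        before = {k: v.copy() for k, v in tm.state_dict().items()}
        cfg = finetune_config(epochs=2, seed=0)
        split = {"train": np.arange(40), "val": np.arange(40, 50)}
        tm, _ = finetune_dual_phase(tm, tiny_dataset, split, cfg, selection_threshold=10**9)
        after = tm.state_dict()
        changed = [
            k for k in before
            if k.startswith("backbone.") and not np.array_equal(before[k], after[k])
        ]
        assert changed

    def test_selection_threshold_rule(self, toy_structure, tiny_dataset):
        cfg = finetune_config(epochs=2, seed=0)
        split_small = {"train": np.arange(60), "val": np.arange(60, 76)}  # 16 rows
        split_large = {"train": np.arange(60), "val": np.arange(60, 92)}  # 32 rows
        tm = self.make_target(toy_structure)
        _, hist_small = finetune_dual_phase(tm, tiny_dataset, split_small, cfg, selection_threshold=32)
        assert hist_small.selection_rule == "last-epoch"
        assert hist_small.selected_epoch == 2 * cfg.epochs - 1
        tm = self.make_target(toy_structure)
        _, hist_large = finetune_dual_phase(tm, tiny_dataset, split_large, cfg, selection_threshold=32)
        assert hist_large.selection_rule == "best-validation"
        assert hist_large.selected_epoch == int(np.argmin(hist_large.val_losses))

    def test_empty_train_raises(self, toy_structure, tiny_dataset):
        tm = self.make_target(toy_structure)
        with pytest.raises(TrainingError):
            finetune_dual_phase(tm, tiny_dataset, {"train": [], "val": []},
                                finetune_config(epochs=1))

    def test_overlapping_split_raises(self, toy_structure, tiny_dataset):
        tm = self.make_target(toy_structure)
        with pytest.raises(TrainingError):
            finetune_dual_phase(tm, tiny_dataset, {"train": [0, 1], "val": [1, 2]},
                                finetune_config(epochs=1))


class TestRidgeHead:
    def test_matches_normal_equations_oracle(self, toy_structure, tiny_dataset):
        tm = TestDualPhase().make_target(toy_structure)
        split = {"train": np.arange(80), "val": np.arange(80, 100)}
        tm = fit_ridge_head(tm, tiny_dataset, split, alpha=1.0)
        from mutenc.training import _backbone_features

        tokens = encode_sequences(tiny_dataset.sequences())
        X = _backbone_features(tm, tokens)[split["train"]]
        y = tiny_dataset.scores()[split["train"]]
        # normal equations with centered intercept handling
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        w = np.linalg.solve(Xc.T @ Xc + 1.0 * np.eye(X.shape[1]), Xc.T @ yc)
        b = y.mean() - X.mean(axis=0) @ w
        pred_oracle = X @ w + b
        pred_model = predict(tm, [tiny_dataset.sequences()[i] for i in split["train"]])
        np.testing.assert_allclose(pred_model, pred_oracle, atol=1e-8)

    def test_duplicated_rows_match_oracle_on_duplicated_design(self, toy_structure, tiny_dataset):
        tm = TestDualPhase().make_target(toy_structure)
        ids = np.concatenate([np.arange(40), np.arange(40)])  # duplicated rows
        from mutenc.training import _backbone_features

        tokens = encode_sequences(tiny_dataset.sequences())
        X = _backbone_features(tm, tokens)[ids]
        y = tiny_dataset.scores()[ids]
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        w = np.linalg.solve(Xc.T @ Xc + np.eye(X.shape[1]), Xc.T @ yc)
        b = y.mean() - X.mean(axis=0) @ w
        from sklearn.linear_model import Ridge

        r = Ridge(alpha=1.0, solver="cholesky").fit(X, y)
        np.testing.assert_allclose(r.coef_, w, atol=1e-8)
        np.testing.assert_allclose(r.intercept_, b, atol=1e-8)

    def test_huge_alpha_shrinks_to_intercept(self, toy_structure, tiny_dataset):
        tm = TestDualPhase().make_target(toy_structure)
        split = {"train": np.arange(80), "val": []}
        tm = fit_ridge_head(tm, tiny_dataset, split, alpha=1e12)
        y = tiny_dataset.scores()[:80]
        pred = predict(tm, [tiny_dataset.sequences()[i] for i in range(80)])
        np.testing.assert_allclose(pred, y.mean(), atol=1e-4)
        assert np.abs(tm.head.weight.data).max() < 1e-6
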