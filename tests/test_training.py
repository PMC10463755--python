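"""Loss oracle, schedule, training loop contracts and grid search."""

import math
from dataclasses import replace

import numpy as np
import pytest

from mcldti.network import ModelConfig
from mcldti.training import (
    GridSpec,
    TrainConfig,
    bce_loss,
    build_pipeline,
    grid_search,
    load_checkpoint,
    lr_at,
    prepare_arrays,
    save_checkpoint,
    train_model,
)


class TestBceLoss:
    def test_near_perfect_prediction_near_zero_loss(self):
        assert bce_loss([1 - 1e-9], [1]) < 1e-6

    def test_uniform_prediction_gives_ln_two(self):
        assert abs(bce_loss([0.5, 0.5], [1, 0]) - math.log(2)) < 1e-9

    def test_permutation_invariance(self):
        p = [0.2, 0.7, 0.9]
        y = [0, 1, 1]
        assert bce_loss(p, y) == bce_loss(p[::-1], y[::-1])

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            bce_loss([], [])

    def test_boundary_probabilities_are_clamped_finite(self):
        assert np.isfinite(bce_loss([0.0, 1.0], [1, 0]))


class TestLrSchedule:
    CFG = TrainConfig(lr=1e-3, lr_decay=0.8, decay_every=10)

    def test_initial_epoch_uses_base_lr(self):
        assert lr_at(0, self.CFG) == 1e-3

    def test_two_decades_of_decay(self):
        assert abs(lr_at(20, self.CFG) - 6.4e-4) < 1e-12

    def test_no_decay_when_coefficient_is_one(self):
        cfg = TrainConfig(lr=1e-3, lr_decay=1.0)
        assert lr_at(57, cfg) == 1e-3

    def test_monotone_non_increasing(self):
        lrs = [lr_at(e, self.CFG) for e in range(50)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))


class TestTrainModel:
    def test_same_seed_reproduces_first_epoch_loss(self, tiny_model_config,
                                                   tiny_dataset):
        tc = TrainConfig(epochs=1, batch_size=8, seed=3)
        a = train_model(tiny_model_config, tc, tiny_dataset)
        b = train_model(tiny_model_config, tc, tiny_dataset)
        assert abs(a.history[0]["train_loss"] - b.history[0]["train_loss"]) < 1e-6

    def test_history_length_equals_epochs(self, tiny_model_config, tiny_dataset):
        tc = TrainConfig(epochs=3, batch_size=8, seed=0)
        result = train_model(tiny_model_config, tc, tiny_dataset)
        assert len(result.history) == 3

    def test_checkpoint_is_argmax_of_valid_auc(self, tiny_model_config,
                                               tiny_dataset):
        tc = TrainConfig(epochs=3, batch_size=8, seed=1)
        result = train_model(tiny_model_config, tc, tiny_dataset[:12],
                             tiny_dataset[12:])
        aucs = [h["valid_roc_auc"] for h in result.history]
        assert aucs[result.best_epoch] == max(aucs)

    def test_empty_train_set_rejected(self, tiny_model_config):
        with pytest.raises(ValueError, match="empty"):
            train_model(tiny_model_config, TrainConfig(), [])

    def test_loss_decreases_over_early_epochs(self, tiny_model_config,
                                              tiny_dataset):
        tc = TrainConfig(epochs=5, batch_size=8, seed=0)
        result = train_model(tiny_model_config, tc, tiny_dataset)
        assert (result.history[4]["train_loss"]
                < result.history[0]["train_loss"])

    def test_predictions_deterministic_after_training(self, tiny_model_config,
                                                      tiny_dataset):
        tc = TrainConfig(epochs=1, batch_size=8, seed=0)
        result = train_model(tiny_model_config, tc, tiny_dataset)
        np.testing.assert_array_equal(result.predict(tiny_dataset),
                                      result.predict(tiny_dataset))

    def test_checkpoint_round_trip_preserves_predictions(
            self, tiny_model_config, tiny_dataset, tmp_path):
        tc = TrainConfig(epochs=1, batch_size=8, seed=0)
        result = train_model(tiny_model_config, tc, tiny_dataset)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, result)
        restored = load_checkpoint(path)
        np.testing.assert_allclose(restored.predict(tiny_dataset),
                                   result.predict(tiny_dataset), atol=1e-7)

    def test_ddi_variant_trains_and_predicts(self, tiny_model_config):
        from mcldti.synthetic import SyntheticSpec, gen_ddi_dataset

        data = gen_ddi_dataset(SyntheticSpec(n_examples=16, seed=2))
        cfg = replace(tiny_model_config, task="ddi")
        result = train_model(cfg, TrainConfig(epochs=1, batch_size=8, seed=0),
                             data)
        scores = result.predict(data)
        assert scores.shape == (16,)
        assert np.all((scores > 0) & (scores < 1))

    def test_vocabularies_come_from_training_split_only(self, tiny_model_config,
                                                        tiny_dataset):
        pipe = build_pipeline(tiny_dataset[:8], tiny_model_config)
        size_before = len(pipe.vocab_tgt)
        prepare_arrays(tiny_dataset[8:], pipe)  # encoding must not grow vocab
        assert len(pipe.vocab_tgt) == size_before


class TestGridSearch:
    def _sets(self, tiny_dataset):
        return tiny_dataset[:12], tiny_dataset[12:]

    def test_single_cell_grid_returns_that_config(self, tiny_model_config,
                                                  tiny_dataset):
        grid = GridSpec(lr=(1e-3,), lr_decay=(0.8,), batch_size=(8,),
                        dropout=(0.1,))
        train, valid = self._sets(tiny_dataset)
        best_tc, best_mc, log = grid_search(grid, tiny_model_config, train,
                                            valid, search_epochs=1)
        assert (best_tc.lr, best_tc.batch_size) == (1e-3, 8)
        assert best_mc.dropout == 0.1
        assert len(log) == 2  # one cell per phase

    def test_two_phase_cell_count(self, tiny_model_config, tiny_dataset):
        grid = GridSpec(lr=(1e-2, 1e-3), lr_decay=(0.8, 0.9),
                        batch_size=(8,), dropout=(0.1,))
        train, valid = self._sets(tiny_dataset)
        _, _, log = grid_search(grid, tiny_model_config, train, valid,
                                search_epochs=1)
        assert sum(r["phase"] == 1 for r in log) == 2   # lr x batch
        assert sum(r["phase"] == 2 for r in log) == 2   # dropout x decay

    def test_empty_candidate_list_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(lr=())

    def test_full_default_grid_replay_evaluates_45_cells(self, monkeypatch,
                                                         tiny_model_config,
                                                         tiny_dataset):
        """The default two-phase search scans 5 lrs x 4 batch sizes,
        then 5 dropouts x 5 decays: 45 cells in total."""
        import mcldti.training as tr

        class _Stub:
            def predict(self, examples, batch_size=64):
                # perfect ranking: every cell ties at ROC-AUC 1.0
                return np.array([ex.label for ex in examples], float)

        monkeypatch.setattr(tr, "train_model",
                            lambda *args, **kwargs: _Stub())
        train, valid = tiny_dataset[:12], tiny_dataset[12:]
        best_tc, _, log = tr.grid_search(GridSpec(), tiny_model_config,
                                         train, valid, search_epochs=1)
        assert sum(r["phase"] == 1 for r in log) == 20
        assert sum(r["phase"] == 2 for r in log) == 25
        # all cells tie, so the documented tie-break applies
        assert best_tc.lr == 1e-5
        assert best_tc.batch_size == 32
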