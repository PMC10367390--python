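"""Loss algebra, FGM contracts, fit behaviour and the self-training loop."""

import logging

import numpy as np
import pytest

from lexner.model import DualBranchNER, ModelConfig
from lexner.training import (SelfTrainConfig, TrainConfig, fgm_perturbation,
                             joint_loss, pseudo_label, semisupervised_loss)


class TestJointLoss:
    def test_single_branch_weights(self):
        assert joint_loss(2.0, 0.5, 1.0, 0.0) == 2.0
        assert joint_loss(2.0, 0.5, 0.0, 1.0) == 0.5

    def test_weighted_sum(self):
        assert joint_loss(2.0, 0.5, 1.0, 1.0) == 2.5

    def test_homogeneity(self):
        base = joint_loss(1.3, 0.7, 0.4, 0.9)
        assert np.isclose(joint_loss(1.3, 0.7, 0.8, 1.8), 2.0 * base)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            joint_loss(1.0, 1.0, -0.1, 1.0)
        with pytest.raises(ValueError):
            joint_loss(1.0, 1.0, 0.0, 0.0)


class TestSemisupervisedLoss:
    def test_theta_zero_is_labeled_loss_exactly(self):
        assert semisupervised_loss(1.234, 99.0, 0.0) == 1.234

    def test_convex_combination_bounds(self):
        for theta in (0.0, 0.3, 0.7, 0.99):
            lo, hi = sorted((0.4, 2.0))
            val = semisupervised_loss(0.4, 2.0, theta)
            assert lo - 1e-12 <= val <= hi + 1e-12

    def test_invalid_theta_rejected(self):
        for theta in (-0.1, 1.0, 1.5):
            with pytest.raises(ValueError):
                semisupervised_loss(1.0, 1.0, theta)


class TestFgm:
    def test_perturbation_norm_equals_epsilon(self):
        g = np.random.default_rng(0).normal(size=(7, 3))
        r = fgm_perturbation(g, 0.25)
        assert np.isclose(np.linalg.norm(r), 0.25)

    def test_zero_gradient_skips_perturbation(self):
        assert fgm_perturbation(np.zeros((4, 4)), 0.5) is None

    def test_epsilon_zero_leaves_loss_unchanged(self, tiny_dataset, tiny_model):
        model = tiny_model
        batch = model.make_batches(tiny_dataset.train[:4], 4)[0]
        lb, lf = model.loss_batch(batch, train_mode=False)
        clean = joint_loss(lb, lf)
        clean.backward()
        r = fgm_perturbation(model.enc.E_c.grad, 0.0)
        if r is not None:
            model.enc.E_c.data += r
        lb2, lf2 = model.loss_batch(batch, train_mode=False)
        assert joint_loss(lb2, lf2).item() == clean.item()
        for p in model.parameters():
            p.grad = None

    def test_embedding_restored_after_adversarial_cycle(self, tiny_dataset):
        ds = tiny_dataset
        model = DualBranchNER.from_corpus(ds.train, ds.dictionary,
                                          ds.radical_table, ModelConfig(), seed=9)
        before = model.enc.E_c.data.copy()
        model.fit(ds.train[:16], ds.dev,
                  TrainConfig(epochs=1, seed=0, fgm_enabled=True,
                              fgm_epsilon=0.3, dev_fraction=0.0))
        # weights moved by the optimizer, but no residual perturbation is
        # left behind: a second clean forward is reproducible
        a = model.evaluate(ds.dev)["f1"]
        b = model.evaluate(ds.dev)["f1"]
        assert a == b
        assert model.enc.E_c.data.shape == before.shape


class TestSupervisedFit:
    def test_loss_decreases_on_tiny_corpus(self, tiny_dataset):
        ds = tiny_dataset
        model = DualBranchNER.from_corpus(ds.train[:2], ds.dictionary,
                                          ds.radical_table, ModelConfig(), seed=1)
        res = model.fit(ds.train[:2], None,
                        TrainConfig(epochs=25, batch_size=2, seed=0,
                                    dev_fraction=0.0))
        first = res.history[0]["loss_B"] + res.history[0]["loss_F"]
        last = res.history[-1]["loss_B"] + res.history[-1]["loss_F"]
        assert last < first

    def test_same_seed_reproduces_metric_log(self, tiny_dataset):
        ds = tiny_dataset

        def run():
            model = DualBranchNER.from_corpus(ds.train, ds.dictionary,
                                              ds.radical_table, ModelConfig(),
                                              seed=5)
            res = model.fit(ds.train, ds.dev, TrainConfig(epochs=2, seed=5))
            return res.history

        assert run() == run()

    def test_empty_corpus_rejected(self, tiny_dataset, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.fit([], None, TrainConfig(epochs=1))

    def test_summary_reports_history(self, tiny_dataset):
        ds = tiny_dataset
        model = DualBranchNER.from_corpus(ds.train, ds.dictionary,
                                          ds.radical_table, ModelConfig(), seed=2)
        res = model.fit(ds.train[:8], ds.dev[:4],
                        TrainConfig(epochs=1, seed=0, dev_fraction=0.0))
        text = res.summary()
        assert "best dev F1" in text and "epoch" in text


class TestPseudoLabel:
    def test_threshold_one_selects_nothing_from_untrained_model(
            self, tiny_dataset, tiny_model):
        assert pseudo_label(tiny_model, tiny_dataset.unlabeled, 1.0) == []

    def test_threshold_zero_selects_everything(self, tiny_dataset, tiny_model):
        out = pseudo_label(tiny_model, tiny_dataset.unlabeled, 0.0)
        assert len(out) == len(tiny_dataset.unlabeled)

    def test_duplicate_sentences_get_identical_labels_and_confidence(
            self, tiny_dataset, tiny_model):
        sent = tiny_dataset.unlabeled[0]
        out = pseudo_label(tiny_model, [sent, list(sent)], 0.0)
        (c1, l1, conf1), (c2, l2, conf2) = out
        assert l1 == l2 and conf1 == conf2

    def test_confidences_are_probabilities(self, tiny_dataset, tiny_model):
        for _s, _l, conf in pseudo_label(tiny_model, tiny_dataset.unlabeled, 0.0):
            assert 0.0 <= conf <= 1.0


class TestSelfTrain:
    def test_pool_grows_and_unlabeled_shrinks_conservatively(self, tiny_dataset):
        ds = tiny_dataset
        model = DualBranchNER.from_corpus(ds.train, ds.dictionary,
                                          ds.radical_table, ModelConfig(), seed=4)
        res = model.fit_semisupervised(
            ds.train[:20], ds.unlabeled,
            SelfTrainConfig(tau=0.5, theta=0.3, max_rounds=2, round_epochs=1,
                            per_round_cap=0.5),
            TrainConfig(epochs=3, seed=0), ds.dev)
        pool_sizes = [r["pool_size"] for r in res.rounds]
        u_sizes = [r["u_size"] for r in res.rounds]
        assert pool_sizes == sorted(pool_sizes)
        assert u_sizes == sorted(u_sizes, reverse=True)
        for r in res.rounds:
            assert r["pool_size"] + r["u_size"] == len(ds.unlabeled)

    def test_empty_unlabeled_degenerates_to_supervised(self, tiny_dataset, caplog):
        ds = tiny_dataset
        model = DualBranchNER.from_corpus(ds.train, ds.dictionary,
                                          ds.radical_table, ModelConfig(), seed=4)
        with caplog.at_level(logging.WARNING):
            res = model.fit_semisupervised(ds.train[:12], [],
                                           SelfTrainConfig(max_rounds=1,
                                                           round_epochs=1),
                                           TrainConfig(epochs=1, seed=0), ds.dev)
        assert res.rounds == []
        assert any("unlabeled" in r.message for r in caplog.records)

    def test_smaller_unlabeled_pool_warns(self, tiny_dataset, caplog):
        ds = tiny_dataset
        model = DualBranchNER.from_corpus(ds.train, ds.dictionary,
                                          ds.radical_table, ModelConfig(), seed=4)
        with caplog.at_level(logging.WARNING):
            model.fit_semisupervised(ds.train[:20], ds.unlabeled[:3],
                                     SelfTrainConfig(tau=1.0, max_rounds=1,
                                                     round_epochs=1),
                                     TrainConfig(epochs=1, seed=0), ds.dev)
        assert any("not larger" in r.message for r in caplog.records)

    def test_unreachable_threshold_stops_after_empty_selection(self, tiny_dataset):
        ds = tiny_dataset
        model = DualBranchNER.from_corpus(ds.train, ds.dictionary,
                                          ds.radical_table, ModelConfig(), seed=4)
        res = model.fit_semisupervised(ds.train[:20], ds.unlabeled,
                                       SelfTrainConfig(tau=1.0, max_rounds=3,
                                                       round_epochs=1),
                                       TrainConfig(epochs=1, seed=0), ds.dev)
        assert len(res.rounds) == 1
        assert res.rounds[0]["selected"] == 0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SelfTrainConfig(tau=0.0)
        with pytest.raises(ValueError):
            SelfTrainConfig(theta=1.0)
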