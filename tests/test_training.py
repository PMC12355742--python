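"""Training harness: autoencoder fitting, classifier training, regime
freezing, model selection, suite structure."""

import numpy as np
import pytest

from neurofuse import nn, volumes
from neurofuse.networks import AutoencoderSpec, ResNetSpec, build
from neurofuse.training import (ExperimentSpec, SuiteConfig, TrainingError,
                                check_no_leakage, results_table, run_suite,
                                select_best_image_model, train_autoencoder,
                                train_image_model, train_linear_head)
from neurofuse.tabular import phantom_schema


@pytest.fixture(scope="module")
def tiny_volumes(small_batch):
    return small_batch.data[:20]


class TestExperimentSpec:
    def test_clinical_arm_rejects_branch(self):
        with pytest.raises(ValueError):
            ExperimentSpec(arm="clinical", branch="resnet")

    def test_image_arm_requires_branch(self):
        with pytest.raises(ValueError):
            ExperimentSpec(arm="image")

    def test_learning_rate_defaults_by_regime(self):
        assert ExperimentSpec(arm="clinical").resolved_lr == 0.01
        ft = ExperimentSpec(arm="image", branch="resnet", regime="FT")
        assert ft.resolved_lr == 0.001 and ft.resolved_scheduler
        sc = ExperimentSpec(arm="image", branch="resnet", regime="scratch")
        assert sc.resolved_lr == 0.1 and sc.resolved_scheduler
        assert not ExperimentSpec(arm="clinical").resolved_scheduler


class TestAutoencoderTraining:
    def test_reconstruction_loss_decreases(self, tiny_volumes):
        spec = AutoencoderSpec(grid_shape=tiny_volumes.shape[2:],
                               channels=(2, 4), latent_dim=8)
        _, hist = train_autoencoder(tiny_volumes, spec, epochs=6,
                                    batch_size=4, seed=0)
        assert min(hist["train_loss"]) < hist["train_loss"][0]

    def test_zero_epochs_returns_initialization(self, tiny_volumes):
        spec = AutoencoderSpec(grid_shape=tiny_volumes.shape[2:],
                               channels=(2,), latent_dim=4)
        model, hist = train_autoencoder(tiny_volumes, spec, epochs=0, seed=5)
        fresh = build(spec, seed=5)
        assert nn.parameter_hash(model) == nn.parameter_hash(fresh)
        assert hist["train_loss"] == []

    def test_constant_zero_volumes_reach_near_zero_loss(self):
        zeros = np.zeros((8, 1, 8, 8, 8))
        spec = AutoencoderSpec(grid_shape=(8, 8, 8), channels=(2,), latent_dim=3)
        model, hist = train_autoencoder(zeros, spec, epochs=15, batch_size=4,
                                        seed=0)
        assert min(hist["train_loss"]) < 1e-3
        recon = model.forward(zeros[:2])
        assert np.abs(recon).max() < 0.1


class TestClassifierTraining:
    def test_separable_features_reach_perfect_validation_auprc(self):
        rng = np.random.default_rng(0)
        y = np.array([0, 1] * 40)
        X = np.hstack([(y * 2 - 1)[:, None] * 3.0 + rng.normal(0, .1, (80, 1)),
                       rng.normal(size=(80, 3))])
        spec = ExperimentSpec(arm="clinical", epochs=40, seed=0)
        _, hist = train_linear_head(X[:60], y[:60], X[60:], y[60:], spec)
        assert max(hist["val_auprc"]) == pytest.approx(1.0)

    def test_single_class_training_fold_aborts(self):
        X = np.zeros((10, 2))
        with pytest.raises(TrainingError):
            train_linear_head(X, np.zeros(10), X, np.zeros(10),
                              ExperimentSpec(arm="clinical"))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 4))
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        spec = ExperimentSpec(arm="clinical", epochs=10, seed=9)
        m1, _ = train_linear_head(X[:30], y[:30], X[30:], y[30:], spec)
        m2, _ = train_linear_head(X[:30], y[:30], X[30:], y[30:], spec)
        assert nn.parameter_hash(m1) == nn.parameter_hash(m2)


class TestFreezing:
    def test_transfer_learning_leaves_backbone_bit_identical(self, tiny_volumes):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, size=len(tiny_volumes))
        y[:2] = [0, 1]
        rspec = ResNetSpec(widths=(2, 4, 4, 4))
        pretrained = nn.state_arrays(build(rspec, seed=11, tab_dim=0).backbone)
        xspec = ExperimentSpec(arm="image", branch="resnet", regime="TL",
                               use_ehr=False, epochs=2, batch_size=4,
                               patience=5, seed=0)
        model, _ = train_image_model(tiny_volumes[:12], y[:12],
                                     tiny_volumes[12:], y[12:], rspec, xspec,
                                     pretrained_state=pretrained)
        after = nn.state_arrays(model.backbone)
        for name, arr in pretrained.items():
            if "running" in name:
                continue  # batch-norm statistics are not parameters
            assert np.array_equal(arr, after[name]), name

    def test_scheduler_trace_non_increasing(self, tiny_volumes):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, size=len(tiny_volumes))
        y[:2] = [0, 1]
        rspec = ResNetSpec(widths=(2, 4, 4, 4))
        xspec = ExperimentSpec(arm="image", branch="resnet", regime="scratch",
                               use_ehr=False, lr=1e-2, epochs=4, batch_size=4,
                               patience=10, seed=0)
        _, hist = train_image_model(tiny_volumes[:12], y[:12],
                                    tiny_volumes[12:], y[12:], rspec, xspec)
        lrs = hist["lr"]
        assert all(b <= a for a, b in zip(lrs, lrs[1:]))


class TestModelSelection:
    def test_single_candidate_selected(self):
        c = {"label": "FT", "regime": "FT", "val_auprc": [0.4, 0.5, 0.45]}
        assert select_best_image_model([c]) is c

    def test_higher_mean_wins(self):
        a = {"label": "TL", "regime": "TL", "val_auprc": [0.40, 0.40, 0.40]}
        b = {"label": "FT", "regime": "FT", "val_auprc": [0.44, 0.44, 0.44]}
        assert select_best_image_model([a, b]) is b

    def test_equal_means_lower_sd_wins(self):
        a = {"label": "FT", "regime": "FT", "val_auprc": [0.41, 0.44, 0.47]}
        b = {"label": "scratch", "regime": "scratch",
             "val_auprc": [0.43, 0.44, 0.45]}
        assert select_best_image_model([a, b]) is b

    def test_full_tie_breaks_on_regime_order(self):
        a = {"label": "scratch", "regime": "scratch", "val_auprc": [0.4, 0.4]}
        b = {"label": "TL", "regime": "TL", "val_auprc": [0.4, 0.4]}
        assert select_best_image_model([a, b]) is b

    def test_incomparable_fold_sets_rejected(self):
        a = {"label": "TL", "regime": "TL", "val_auprc": [0.4, 0.4]}
        b = {"label": "FT", "regime": "FT", "val_auprc": [0.4]}
        with pytest.raises(ValueError):
            select_best_image_model([a, b])


@pytest.fixture(scope="module")
def suite_result(small_cohort, small_batch):
    config = SuiteConfig(outcomes=("los",), epochs_ae=3, epochs_image=2,
                         epochs_clf=10, resnet_widths=(2, 4, 4, 4),
                         ae_channels=(2, 4), latent_dim=8, seed=0)
    return run_suite(small_cohort.table, small_batch.data,
                     phantom_schema(), config), config


class TestSuite:

    def test_all_thirteen_rows_emitted(self, suite_result):
        result, _ = suite_result
        table = results_table(result, "los")
        assert len(table) == 13
        assert list(table.columns) == ["Experiment", "AUC", "AUPRC", "Recall",
                                       "Specificity", "F1-Score"]

    def test_disabling_image_arms_leaves_clinical_rows_only(self, small_cohort,
                                                            small_batch):
        config = SuiteConfig(outcomes=("los",), arms=("clinical",),
                             epochs_clf=5, seed=0)
        result = run_suite(small_cohort.table, small_batch.data,
                           phantom_schema(), config)
        assert set(result.reports["los"]) == {"Clinical/EHR",
                                              "Clinical/EHR w/IDF",
                                              "Clinical/IDF"}

    def test_no_holdout_leakage_into_any_run(self, suite_result):
        result, _ = suite_result
        assert check_no_leakage(result)

    def test_every_record_carries_the_plan_hash(self, suite_result):
        result, _ = suite_result
        expect = result.plans["los"].plan_hash
        assert result.records
        assert all(rec.split_hash == expect for rec in result.records)
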