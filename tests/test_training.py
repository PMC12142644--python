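"""Gradient policy mechanics and the training loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from secondgram.data import Cohort, SplitCohorts, split_cohort
from secondgram.diffusion import make_schedule
from secondgram.network import DenoiserConfig, UNet1D
from secondgram.selfcond import build_training_set
from secondgram.simulate import SyntheticConfig, generate_cohort
from secondgram.training import (GradientPolicy, TrainConfig, calibrate_thresholds,
                                 grad_norm, manipulate_gradient,
                                 policy_from_norms, train)

from conftest import make_tiny_cohort

SMALL_NET = DenoiserConfig(d=4, n_labels=2, down_sizes=(16, 12, 8), embed_dim=8)


class TestGradNorm:
    def test_worked_examples(self):
        assert grad_norm([np.array([3.0]), np.array([4.0])]) == 5.0
        assert grad_norm([np.zeros((2, 3))]) == 0.0
        assert grad_norm({"w": np.array([-2.5])}) == 2.5

    def test_non_finite_errors(self):
        with pytest.raises(FloatingPointError):
            grad_norm([np.array([1.0, np.nan])])


class TestManipulateGradient:
    def test_pass_branch(self):
        g = {"a": np.array([0.1]), "b": np.array([0.2])}
        out = manipulate_gradient(g, GradientPolicy())
        assert out is g  # G ~ 0.224 <= 0.3: unchanged

    def test_clip_branch_rescales_to_delta_max(self):
        g = {"a": np.array([0.3]), "b": np.array([0.4])}
        out = manipulate_gradient(g, GradientPolicy())
        np.testing.assert_allclose(out["a"], [0.18])
        np.testing.assert_allclose(out["b"], [0.24])
        assert grad_norm(out) == pytest.approx(0.3)

    def test_skip_branch_zeroes(self):
        g = [np.array([0.6]), np.array([0.8])]
        out = manipulate_gradient(g, GradientPolicy())
        assert all(np.all(v == 0) for v in out)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.01, 2.0), st.floats(1.1, 5.0))
    def test_output_norm_bounded_or_zero(self, seed, dmax, ratio):
        rng = np.random.default_rng(seed)
        g = {f"p{i}": rng.standard_normal(rng.integers(1, 5))
             * 10.0 ** rng.integers(-2, 2) for i in range(3)}
        policy = GradientPolicy(delta_max=dmax, delta_err=dmax * ratio)
        out = manipulate_gradient(g, policy)
        G = grad_norm(out)
        assert G <= policy.delta_max * (1 + 1e-12) or G == 0.0

    def test_clip_preserves_direction(self):
        rng = np.random.default_rng(0)
        g = {"w": rng.standard_normal(20)}
        G = grad_norm(g)
        policy = GradientPolicy(delta_max=G / 2, delta_err=2 * G)
        out = manipulate_gradient(g, policy)
        cos = float(g["w"] @ out["w"] /
                    (np.linalg.norm(g["w"]) * np.linalg.norm(out["w"])))
        assert cos == pytest.approx(1.0, abs=1e-9)


class TestCalibration:
    def test_mean_and_three_times_max(self):
        p = policy_from_norms([1.0, 2.0, 3.0])
        assert (p.delta_max, p.delta_err) == (2.0, 9.0)
        p = policy_from_norms([0.5])
        assert (p.delta_max, p.delta_err) == (0.5, 1.5)

    def test_equal_norms_keep_ordering(self):
        p = policy_from_norms([0.7, 0.7, 0.7])
        assert p.delta_max == pytest.approx(0.7)
        assert p.delta_err == pytest.approx(2.1)
        assert p.delta_max < p.delta_err

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            policy_from_norms([])

    def test_calibration_pass_does_not_update_weights(self, schedule):
        cohort = make_tiny_cohort(4, 12, d=4)
        net = UNet1D(SMALL_NET, seed=0)
        before = net.copy_params()
        samples = build_training_set(cohort, schedule, 5,
                                     np.random.default_rng(0))
        policy = calibrate_thresholds(net, samples, schedule,
                                      GradientPolicy(mode="calibrated"),
                                      batch_size=8, seed=1)
        for k in before:
            np.testing.assert_array_equal(net.params[k], before[k])
        assert policy.delta_max < policy.delta_err
        assert policy.mode == "calibrated"

    def test_fixed_mode_rejected(self, schedule):
        with pytest.raises(ValueError):
            calibrate_thresholds(UNet1D(SMALL_NET, seed=0), [], schedule,
                                 GradientPolicy(mode="fixed"))


class TestPolicyInvariants:
    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            GradientPolicy(delta_max=0.8, delta_err=0.5)


def small_splits(seed=0, n_paired=24, n_unpaired=60, d=4):
    cohort = make_tiny_cohort(n_paired, n_unpaired, d=d, seed=seed)
    return split_cohort(cohort, seed=seed)


class TestTrainLoop:
    def test_all_skipped_leaves_parameters_at_initialization(self, schedule):
        splits = small_splits()
        cfg = TrainConfig(epochs=3, patience=3, batch_size=16, seed=42)
        policy = GradientPolicy(delta_max=1e-12, delta_err=2e-12)
        net, hist = train(splits, SMALL_NET, cfg, policy, schedule)
        # reconstruct the initialization net exactly as train() does
        rng = np.random.default_rng(cfg.seed)
        init = UNet1D(SMALL_NET, seed=int(rng.integers(2**31)))
        for k in init.params:
            np.testing.assert_array_equal(net.params[k], init.params[k])
        n_batches = int(np.ceil(len(splits.train) / cfg.batch_size))
        assert sum(hist.n_skipped) == hist.n_epochs * n_batches

    def test_loss_decreases_on_toy_problem(self):
        cfg = SyntheticConfig(d=16, n_patients=500, paired_fraction=0.3,
                              missing_rate=0.0, seed=9)
        cohort, _ = generate_cohort(cfg)
        splits = split_cohort(cohort, seed=9)
        dcfg = DenoiserConfig(d=16, n_labels=4, down_sizes=(32, 24, 16),
                              embed_dim=16)
        tcfg = TrainConfig(epochs=200, patience=200, batch_size=128, seed=3)
        net, hist = train(splits, dcfg, tcfg,
                          GradientPolicy(mode="calibrated"), make_schedule())
        assert hist.n_epochs == 200
        first = np.median(hist.train_loss[:10])
        last = np.median(hist.train_loss[-10:])
        assert last < first

    def test_early_stopping_at_patience(self, schedule):
        splits = small_splits(seed=1)
        # vanishing learning rate: the validation score never improves
        cfg = TrainConfig(epochs=50, patience=2, batch_size=32, seed=0,
                          learning_rate=1e-30)
        net, hist = train(splits, SMALL_NET, cfg,
                          GradientPolicy(mode="calibrated"), schedule)
        assert hist.best_epoch == 0
        assert hist.n_epochs == 3  # best epoch plus `patience` flat epochs

    def test_ablation_without_self_conditioning_uses_paired_only(self, schedule):
        splits = small_splits(seed=2)
        n_paired_train = sum(r.has_followup for r in splits.train)
        cfg = TrainConfig(epochs=2, patience=2, batch_size=16, seed=1,
                          self_conditioning=False)
        _, hist = train(splits, SMALL_NET, cfg,
                        GradientPolicy(mode="calibrated"), schedule)
        assert hist.n_samples == [n_paired_train] * 2
        assert hist.n_self_conditioned == [0, 0]

    def test_ablation_without_gradient_manipulation_never_clips(self, schedule):
        splits = small_splits(seed=3)
        cfg = TrainConfig(epochs=2, patience=2, batch_size=16, seed=1,
                          gradient_manipulation=False)
        # thresholds that would otherwise skip everything
        policy = GradientPolicy(delta_max=1e-12, delta_err=2e-12)
        net, hist = train(splits, SMALL_NET, cfg, policy, schedule)
        assert sum(hist.n_clipped) == 0 and sum(hist.n_skipped) == 0
        rng = np.random.default_rng(cfg.seed)
        init = UNet1D(SMALL_NET, seed=int(rng.integers(2**31)))
        assert any(not np.array_equal(net.params[k], init.params[k])
                   for k in init.params)  # updates actually applied

    def test_no_longitudinal_validation_errors(self, schedule):
        cohort = make_tiny_cohort(4, 10, d=4)
        splits = split_cohort(cohort, seed=0)
        empty_val = Cohort([r for r in splits.validation if not r.has_followup],
                           cohort.feature_names, cohort.label_names,
                           cohort.feature_ranges, True)
        bad = SplitCohorts(splits.train, empty_val, splits.test)
        with pytest.raises(ValueError, match="longitudinal"):
            train(bad, SMALL_NET, TrainConfig(epochs=1, patience=1, seed=0),
                  GradientPolicy(), schedule)
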