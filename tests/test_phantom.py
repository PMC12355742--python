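"""Synthetic lesion-phantom generator: geometry, outcomes, calibration."""

import numpy as np
import pytest

from neurofuse import phantom
from neurofuse.phantom import (CalibrationError, PhantomConfig, PlacementError,
                               SchemaError, SizingError, calibrate_intercept,
                               generate_brain_volume, generate_cohort,
                               generate_outcomes, implant_lesion)


def _cfg(**kw):
    base = dict(n_subjects=5, grid_shape=(16, 16, 16), voxel_volume=64.0,
                lesion_axis_range=(1.0, 3.0), seed=1)
    base.update(kw)
    return PhantomConfig(**base)


class TestBrainVolume:
    def test_noise_free_limit_all_brain_voxels_equal_base(self):
        vol = generate_brain_volume(_cfg(background_noise_sd=0.0),
                                    np.random.default_rng(0))
        inside = vol.brain_mask.astype(bool)
        assert np.all(vol.image[inside] == _cfg().base_intensity)

    def test_voxels_outside_brain_are_exactly_zero(self):
        vol = generate_brain_volume(_cfg(background_noise_sd=0.5),
                                    np.random.default_rng(0))
        assert np.all(vol.image[~vol.brain_mask.astype(bool)] == 0.0)

    def test_brain_covers_30_to_60_percent_of_grid(self):
        for seed in range(5):
            vol = generate_brain_volume(_cfg(), np.random.default_rng(seed))
            frac = vol.brain_mask.mean()
            assert 0.30 <= frac <= 0.60

    def test_same_seed_gives_bit_identical_volumes(self):
        a = generate_brain_volume(_cfg(), np.random.default_rng(5))
        b = generate_brain_volume(_cfg(), np.random.default_rng(5))
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.brain_mask, b.brain_mask)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(SizingError):
            generate_brain_volume(
                PhantomConfig(grid_shape=(4, 16, 16)), np.random.default_rng(0))


class TestImplantLesion:
    def test_lesion_voxel_count_matches_ellipsoid_volume(self):
        # deep spherical lesion, radius 5 voxels: (4/3) pi 125 ~ 523.6
        cfg = _cfg(grid_shape=(32, 32, 32), voxel_volume=8.0)
        vol = generate_brain_volume(cfg, np.random.default_rng(0))
        vol = implant_lesion(vol, (15, 15, 15), (5, 5, 5), contrast=1.0)
        count = int(vol.lesion_mask.sum())
        expect = 4 / 3 * np.pi * 125
        assert abs(count - expect) / expect < 0.10
        assert vol.lesion_volume_cm3 == pytest.approx(count * 8.0 / 1000.0)

    def test_subvoxel_lesion_is_single_center_voxel(self):
        vol = generate_brain_volume(_cfg(), np.random.default_rng(0))
        vol = implant_lesion(vol, (8, 8, 8), (0.5, 0.5, 0.5), contrast=1.0)
        assert vol.lesion_mask.sum() == 1
        assert vol.lesion_mask[8, 8, 8] == 1

    def test_zero_contrast_leaves_image_unchanged_but_records_mask(self):
        base = generate_brain_volume(_cfg(), np.random.default_rng(0))
        out = implant_lesion(base, (8, 8, 8), (2, 2, 2), contrast=0.0)
        assert np.array_equal(out.image, base.image)
        assert out.lesion_mask.sum() > 0

    def test_center_outside_brain_rejected(self):
        vol = generate_brain_volume(_cfg(), np.random.default_rng(0))
        with pytest.raises(PlacementError):
            implant_lesion(vol, (0, 0, 0), (2, 2, 2), contrast=1.0)

    def test_lesion_mask_clipped_to_brain(self):
        vol = generate_brain_volume(_cfg(), np.random.default_rng(0))
        out = implant_lesion(vol, (8, 8, 8), (20, 20, 20), contrast=1.0)
        assert not (out.lesion_mask & ~out.brain_mask.astype(bool)).any()


class TestOutcomes:
    @staticmethod
    def _table(n=100, seed=0):
        rng = np.random.default_rng(seed)
        import pandas as pd

        return pd.DataFrame({"lesion_volume_cm3": rng.uniform(0, 5, n),
                             "age": rng.normal(60, 10, n)})

    def test_zero_model_gives_half_probability(self):
        t = self._table()
        _, probs = generate_outcomes(t, {"lesion_volume_cm3": 0.0}, 0.0,
                                     np.random.default_rng(0))
        assert np.all(probs == 0.5)

    def test_large_coefficient_approaches_step_function(self):
        t = self._table()
        intercept = -50 * 2.5  # crossing at lesion volume 2.5
        labels, _ = generate_outcomes(t, {"lesion_volume_cm3": 50.0},
                                      intercept, np.random.default_rng(0))
        lv = t["lesion_volume_cm3"].to_numpy()
        clear = np.abs(lv - 2.5) > 0.1
        assert np.array_equal(labels[clear], (lv[clear] > 2.5).astype(int))

    def test_unknown_predictor_rejected(self):
        with pytest.raises(SchemaError):
            generate_outcomes(self._table(), {"no_such_column": 1.0}, 0.0,
                              np.random.default_rng(0))

    def test_calibrated_prevalence_on_large_sample(self):
        t = self._table(n=5000, seed=3)
        coefs = {"lesion_volume_cm3": 1.0, "age": 0.02}
        b = calibrate_intercept(t, coefs, 0.1891)
        # outcome rng independent of the covariate rng
        labels, probs = generate_outcomes(t, coefs, b,
                                          np.random.default_rng(99))
        assert probs.mean() == pytest.approx(0.1891, abs=1e-4)
        assert labels.mean() == pytest.approx(0.1891, abs=0.015)


class TestCalibrateIntercept:
    def test_zero_coefficients_target_half_gives_zero(self):
        t = TestOutcomes._table()
        assert calibrate_intercept(t, {"age": 0.0}, 0.5) == pytest.approx(
            0.0, abs=1e-3)

    def test_zero_coefficients_closed_form_logit(self):
        t = TestOutcomes._table()
        b = calibrate_intercept(t, {"age": 0.0}, 0.1891)
        assert b == pytest.approx(np.log(0.1891 / 0.8109), abs=1e-3)

    def test_monotone_in_target(self):
        t = TestOutcomes._table()
        coefs = {"lesion_volume_cm3": 1.0}
        assert calibrate_intercept(t, coefs, 0.6) > calibrate_intercept(
            t, coefs, 0.3)

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            calibrate_intercept(TestOutcomes._table(), {"age": 0.0}, 1.5)


class TestCohort:
    def test_recorded_idf_volume_exact(self, small_cohort):
        for vol, row_vol in zip(small_cohort.volumes,
                                small_cohort.table.lesion_volume_cm3):
            assert row_vol == vol.lesion_mask.sum() * vol.voxel_volume / 1000.0

    def test_one_row_per_volume_and_truth_lengths(self, small_cohort):
        n = len(small_cohort.volumes)
        assert len(small_cohort.table) == n
        for rec in small_cohort.generating_truth["outcomes"].values():
            assert len(rec["probabilities"]) == n
            assert len(rec["labels"]) == n

    def test_missing_rate_bound_enforced(self):
        with pytest.raises(ValueError):
            _cfg(missing_rate=0.25).validate()

    def test_labels_consistent_with_continuous_outcomes(self, small_cohort):
        t = small_cohort.table
        truth = small_cohort.generating_truth["outcomes"]
        assert np.array_equal((t.los_days > 8).astype(int),
                              np.asarray(truth["los"]["labels"]))
        assert np.array_equal((t.mrs_90day > 2).astype(int),
                              np.asarray(truth["mrs"]["labels"]))

    def test_write_cohort_deterministic_bytes(self, tmp_path):
        import hashlib

        cfg = _cfg(n_subjects=3)
        sums = []
        for run in range(2):
            out = tmp_path / f"run{run}"
            phantom.write_cohort(generate_cohort(cfg), out)
            digest = hashlib.sha256()
            for p in sorted(out.iterdir()):
                digest.update(p.name.encode())
                digest.update(p.read_bytes())
            sums.append(digest.hexdigest())
        assert sums[0] == sums[1]


class TestCalibrationInvariants:
    def test_prevalence_within_band_across_seeds(self):
        """Empirical prevalence within +/-0.02 of each calibration target."""
        for outcome, target in (("los", 0.1891), ("mrs", 0.3850)):
            for seed in (0, 1, 2):
                cfg = _cfg(n_subjects=2000, seed=seed)
                cohort = generate_cohort(cfg)
                labels = np.asarray(
                    cohort.generating_truth["outcomes"][outcome]["labels"])
                assert labels.mean() == pytest.approx(target, abs=0.02), \
                    (outcome, seed)

    def test_generating_signs_recoverable_by_logistic_regression(self):
        """Coefficient signs recovered at n=2000 in at least 2 of 3 seeds."""
        from sklearn.linear_model import LogisticRegression

        hits = 0
        for seed in (0, 1, 2):
            cohort = generate_cohort(_cfg(n_subjects=2000, seed=seed,
                                          missing_rate=0.0))
            t = cohort.table
            coefs = cohort.generating_truth["outcomes"]["los"]["coefficients"]
            X = t[list(coefs)].to_numpy(dtype=float)
            y = np.asarray(cohort.generating_truth["outcomes"]["los"]["labels"])
            fit = LogisticRegression(max_iter=2000).fit(X, y)
            hits += all(np.sign(fit.coef_[0]) == np.sign(list(coefs.values())))
        assert hits >= 2
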