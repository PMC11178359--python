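import numpy as np
import pytest

from socialgrid.glm import QuadratureBetas
from socialgrid.grid import (
    GridConsistency,
    QuadratureFilterGLM,
    classify_alignment,
    covariate_test,
    estimate_orientation,
    group_test,
    sphere_roi,
    voxelwise_orientations,
)
from socialgrid.simulate import BoldRun, SimConfig, simulate_subject


def _betas(b_cos, b_sin, fold=6):
    return QuadratureBetas(np.atleast_1d(b_cos), np.atleast_1d(b_sin), fold)


class TestOrientationEstimate:
    @pytest.mark.parametrize(
        "b_cos, b_sin, fold, phi",
        [(1.0, 0.0, 6, 0.0), (0.0, 1.0, 6, 15.0), (-1.0, 0.0, 6, 30.0), (0.0, 1.0, 4, 22.5)],
    )
    def test_atan2_worked_values(self, b_cos, b_sin, fold, phi):
        est = estimate_orientation(_betas(b_cos, b_sin, fold))
        assert est.phi_deg == pytest.approx(phi)
        assert 0.0 <= est.phi_deg < 360.0 / fold

    def test_zero_resultant_flagged_low_confidence(self):
        est = estimate_orientation(_betas(0.0, 0.0))
        assert est.low_confidence

    def test_monte_carlo_recovery_from_noisy_voxel_betas(self):
        # oracle: 100 voxels with betas ω(cos6φ, sin6φ) + N(0, 0.1), φ=20°
        rng = np.random.default_rng(8)
        phi = np.deg2rad(6 * 20.0)
        bc = np.cos(phi) + rng.normal(0, 0.1, 100)
        bs = np.sin(phi) + rng.normal(0, 0.1, 100)
        est = estimate_orientation(_betas(bc, bs))
        err = abs(est.phi_deg - 20.0)
        assert min(err, 60 - err) < 2.0

    def test_estimator_equivariance_under_rotation(self):
        # rotating the generating orientation by Δ shifts the estimate by Δ
        rng = np.random.default_rng(9)
        for delta in (7.0, 23.0, 41.0):
            base = np.deg2rad(6 * 12.0)
            rot = np.deg2rad(6 * (12.0 + delta))
            e0 = estimate_orientation(
                _betas(np.cos(base) + rng.normal(0, 0.01, 50), np.sin(base) + rng.normal(0, 0.01, 50))
            )
            e1 = estimate_orientation(
                _betas(np.cos(rot) + rng.normal(0, 0.01, 50), np.sin(rot) + rng.normal(0, 0.01, 50))
            )
            shift = (e1.phi_deg - e0.phi_deg) % 60.0
            assert shift == pytest.approx(delta % 60.0, abs=1.0)


class TestAlignmentClassification:
    @pytest.mark.parametrize(
        "theta, phi, fold, aligned",
        [
            (10.0, 0.0, 6, True),
            (30.0, 0.0, 6, False),
            (196.0, 0.0, 6, False),
            (45.0, 0.0, 4, False),
            (90.0, 0.0, 4, True),
            (62.0, 2.0, 6, True),
        ],
    )
    def test_worked_examples(self, theta, phi, fold, aligned):
        _, flag = classify_alignment(theta, phi, fold)
        assert bool(flag) == aligned

    def test_matches_brute_force_nearest_center(self):
        rng = np.random.default_rng(10)
        fold = 6
        centers = np.arange(2 * fold) * 360.0 / (2 * fold)
        for theta in rng.uniform(0, 360, 200):
            idx, _ = classify_alignment(theta, 13.0, fold)
            offs = (theta - 13.0) % 360.0
            d = np.abs((offs - centers + 180.0) % 360.0 - 180.0)
            assert centers[int(idx)] == pytest.approx(centers[np.argmin(d)])


class TestVoxelwiseOrientations:
    def test_shared_betas_give_identical_orientations(self):
        phi = voxelwise_orientations(_betas([0.0, 0.0], [1.0, 1.0]))
        assert np.allclose(phi, 15.0)

    def test_atan2_branches_fold_into_domain(self):
        phi = voxelwise_orientations(_betas([1.0, -1.0], [0.0, 0.0]))
        assert np.allclose(sorted(phi), [0.0, 30.0])

    def test_requires_two_voxels(self):
        with pytest.raises(ValueError):
            voxelwise_orientations(_betas(1.0, 0.0))


class TestLeaveOneRunOut:
    def test_recovers_true_orientation_and_positive_contrast(self, small_subject):
        roi = np.where(small_subject.truth["voxel_kinds"] == "grid")[0]
        model = GridConsistency(6).fit(small_subject.runs, small_subject.trials, roi)
        phi_true = small_subject.truth["phi_true_deg"]
        for ori in model.orientations_.values():
            err = abs(ori.phi_deg - phi_true) % 60.0
            assert min(err, 60.0 - err) < 10.0
        assert model.contrast_ > 0
        assert len(model.result_.per_run) == 4
        assert model.result_.contrast == pytest.approx(
            model.result_.per_run["contrast"].mean()
        )

    def test_orientation_never_uses_held_out_run(self, small_subject):
        """Cross-validation honesty: perturbing the held-out run leaves its
        estimating-set orientation unchanged."""
        roi = np.where(small_subject.truth["voxel_kinds"] == "grid")[0]
        base = GridConsistency(6).fit(small_subject.runs, small_subject.trials, roi)
        perturbed_runs = list(small_subject.runs)
        rng = np.random.default_rng(0)
        perturbed_runs[2] = BoldRun(
            small_subject.runs[2].data + rng.normal(0, 5.0, small_subject.runs[2].data.shape),
            small_subject.runs[2].repetition_time,
            run=2,
        )
        pert = GridConsistency(6).fit(perturbed_runs, small_subject.trials, roi)
        assert pert.orientations_[2].phi_deg == pytest.approx(
            base.orientations_[2].phi_deg
        )
        assert pert.orientations_[0].phi_deg != pytest.approx(
            base.orientations_[0].phi_deg
        )

    def test_needs_at_least_two_runs(self, small_subject):
        with pytest.raises(ValueError):
            GridConsistency(6).fit(small_subject.runs[:1], small_subject.trials)


class TestGroupAndCovariateTests:
    def test_degenerate_equal_contrasts(self):
        res = group_test([0.5, 0.5, 0.5])
        assert res.degenerate and np.isinf(res.t)

    def test_symmetric_contrasts_give_zero_t(self):
        res = group_test([-1.0, 1.0, -2.0, 2.0], alternative="two-sided")
        assert res.t == pytest.approx(0.0)

    def test_paired_difference(self):
        res = group_test([1.0, 1.2, 0.9, 1.1], paired_with=[0.1, 0.2, 0.0, 0.3])
        assert res.p < 0.01

    def test_covariate_identity_gives_perfect_correlation(self):
        y = np.array([0.1, 0.5, 0.3, 0.9, 0.7])
        table = covariate_test(y, {"self": y})
        assert table["r"].iloc[0] == pytest.approx(1.0)

    def test_covariate_slope_recovery(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=40)
        y = 0.5 + 2.0 * x + rng.normal(0, 0.01, 40)
        table = covariate_test(y, {"x": x})
        assert table["slope"].iloc[0] == pytest.approx(2.0, abs=0.02)

    def test_permuted_covariate_centers_on_zero(self):
        rng = np.random.default_rng(12)
        y = rng.normal(size=24)
        x = rng.normal(size=24)
        rs = [
            covariate_test(y, {"x": rng.permutation(x)})["r"].iloc[0]
            for _ in range(200)
        ]
        assert abs(np.mean(rs)) < 0.05

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            covariate_test([1.0, 2.0, 3.0], {"c": [5.0, 5.0, 5.0]})

    def test_fdr_column_present(self):
        rng = np.random.default_rng(13)
        y = rng.normal(size=20)
        table = covariate_test(
            y, {f"x{i}": rng.normal(size=20) for i in range(4)}
        )
        assert np.all(table["p_fdr"] >= table["p"] - 1e-12)


def test_sphere_roi_contains_center_and_respects_radius():
    vox = sphere_roi((5, 5, 5), (2, 2, 2), 1.0)
    grid = np.indices((5, 5, 5)).reshape(3, -1).T
    assert np.all(np.linalg.norm(grid[vox] - 2.0, axis=1) <= 1.0)
    assert len(vox) == 7  # center + 6 face neighbours


def test_fold_specific_contrast_null_at_control_fold(small_subject):
    """A sixfold signal should not produce consistent fourfold alignment."""
    roi = np.where(small_subject.truth["voxel_kinds"] == "grid")[0]
    c6 = GridConsistency(6).fit(small_subject.runs, small_subject.trials, roi).contrast_
    c4 = GridConsistency(4).fit(small_subject.runs, small_subject.trials, roi).contrast_
    assert c6 > abs(c4)
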