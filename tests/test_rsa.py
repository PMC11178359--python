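import numpy as np
import pandas as pd
import pytest

from socialgrid.grid import OrientationEstimate, group_test
from socialgrid.rsa import (
    TrialPatterns,
    loo_orientations_from_patterns,
    lss_estimates,
    model_dsm,
    neural_dsm,
    rsa_orientation_dependent,
    rsa_orientation_independent,
)
from socialgrid.simulate import BoldRun, SimConfig, simulate_trial_patterns


def _two_event_run(amplitudes, n_scans=60, tr=2.0):
    from socialgrid.design import make_regressor

    onsets = [10.0, 70.0]
    sig = np.zeros(n_scans)
    for o, a in zip(onsets, amplitudes):
        sig += make_regressor([o], 2.0, a, n_scans, tr)
    trials = pd.DataFrame(
        {
            "onset": onsets,
            "duration": 2.0,
            "choice_onset": [14.0, 74.0],
            "choice_duration": 2.0,
            "theta_deg": [0.0, 90.0],
        }
    )
    return BoldRun(np.vstack([sig, 2 * sig]), tr), trials


class TestLssEstimates:
    def test_noiseless_unit_amplitudes_recovered(self):
        run, trials = _two_event_run([1.0, 1.0])
        pats = lss_estimates(run, trials, drift_cutoff=None)
        assert np.allclose(pats.patterns[:, 0], 1.0, atol=1e-6)

    def test_amplitude_ratio_preserved(self):
        run, trials = _two_event_run([1.0, 2.0])
        pats = lss_estimates(run, trials, drift_cutoff=None)
        ratio = pats.patterns[1, 0] / pats.patterns[0, 0]
        assert ratio == pytest.approx(2.0, abs=1e-6)

    def test_row_order_follows_trial_order(self):
        run, trials = _two_event_run([1.0, 2.0])
        shuffled = trials.iloc[[1, 0]].reset_index(drop=True)
        a = lss_estimates(run, trials, drift_cutoff=None).patterns[:, 0]
        b = lss_estimates(run, shuffled, drift_cutoff=None).patterns[:, 0]
        assert np.allclose(sorted(a), sorted(b), atol=1e-6)
        assert b[0] == pytest.approx(a[1], abs=1e-6)

    def test_single_trial_rejected(self):
        run, trials = _two_event_run([1.0, 1.0])
        with pytest.raises(ValueError):
            lss_estimates(run, trials.iloc[:1])


class TestDsms:
    def test_model_dsm_worked_values(self):
        d = model_dsm([10.0, 70.0, 40.0, 0.0, 100.0], fold=6)
        assert d[0, 1] == pytest.approx(0.0)  # one folded period apart
        assert d[0, 2] == pytest.approx(30.0)  # maximal folded difference
        assert d[3, 4] == pytest.approx(20.0)  # 100 mod 60 = 40 -> folded 20
        assert np.all(d >= 0) and np.all(d <= 30.0)

    def test_model_dsm_invariant_to_direction_shift(self):
        th = np.random.default_rng(0).uniform(0, 360, 30)
        assert np.allclose(model_dsm(th, 6), model_dsm(th + 17.3, 6))

    def test_neural_dsm_shape_symmetry_and_bounds(self):
        pats, meta = simulate_trial_patterns(n_runs=4, n_trials=80, rng_seed=1)
        dsm = neural_dsm(TrialPatterns(pats, meta))
        assert dsm.shape == (320, 320)
        assert np.allclose(dsm, dsm.T)
        assert np.allclose(np.diag(dsm), 0.0)

    def test_identical_and_anticorrelated_rows(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        dsm = neural_dsm(np.vstack([base, base, -base]))
        assert dsm[0, 1] == pytest.approx(0.0)
        assert dsm[0, 2] == pytest.approx(2.0)

    def test_zero_variance_row_rejected_with_trial_named(self):
        with pytest.raises(ValueError, match="\\[1\\]"):
            neural_dsm(np.array([[1.0, 2.0], [3.0, 3.0]]))


class TestOrientationIndependent:
    def test_model_against_itself_gives_rho_one(self):
        th = np.random.default_rng(2).uniform(0, 360, 40)
        m = model_dsm(th, 6)
        rho, _ = rsa_orientation_independent(m, m)
        assert rho == pytest.approx(1.0)

    def test_noise_patterns_center_on_zero(self):
        rhos = []
        for seed in range(15):
            pats, meta = simulate_trial_patterns(
                n_runs=2, n_trials=40, omega=0.0, rng_seed=seed
            )
            rho, _ = rsa_orientation_independent(
                neural_dsm(TrialPatterns(pats, meta)),
                model_dsm(meta["theta_deg"].to_numpy(), 6),
            )
            rhos.append(rho)
        assert group_test(rhos, alternative="two-sided").p > 0.01

    def test_hexadirectional_patterns_give_positive_rho(self):
        fzs = []
        for seed in range(10):
            pats, meta = simulate_trial_patterns(rng_seed=seed)
            _, fz = rsa_orientation_independent(
                neural_dsm(TrialPatterns(pats, meta)),
                model_dsm(meta["theta_deg"].to_numpy(), 6),
            )
            fzs.append(fz)
        res = group_test(fzs)
        assert res.mean > 0 and res.p < 0.05

    def test_size_mismatch_and_constant_dsm_rejected(self):
        m = model_dsm([0.0, 10.0, 20.0], 6)
        with pytest.raises(ValueError):
            rsa_orientation_independent(m, model_dsm([0.0, 10.0], 6))
        with pytest.raises(ValueError, match="constant"):
            rsa_orientation_independent(np.zeros((3, 3)), m)


class TestOrientationDependent:
    def _patterns(self, thetas, rows):
        meta = pd.DataFrame({"run": 0, "theta_deg": thetas})
        return TrialPatterns(np.asarray(rows, dtype=float), meta)

    def test_identical_aligned_orthogonal_misaligned(self):
        rng = np.random.default_rng(3)
        aligned_pattern = rng.normal(size=24)
        pats = self._patterns(
            [0.0, 60.0, 120.0, 30.0, 90.0],
            [
                aligned_pattern,
                aligned_pattern,
                aligned_pattern,
                rng.normal(size=24),
                rng.normal(size=24),
            ],
        )
        diff = rsa_orientation_dependent(pats, OrientationEstimate(0.0, 6), 6)
        assert diff == pytest.approx(1.0, abs=0.4)

    def test_all_identical_patterns_give_zero_difference(self):
        row = np.arange(8.0)
        pats = self._patterns([0.0, 60.0, 30.0, 90.0], [row, row, row, row])
        diff = rsa_orientation_dependent(pats, OrientationEstimate(0.0, 6), 6)
        assert diff == pytest.approx(0.0, abs=1e-12)

    def test_empty_class_rejected(self):
        row = np.arange(8.0)
        pats = self._patterns([0.0, 60.0], [row, row + 1])
        with pytest.raises(ValueError):
            rsa_orientation_dependent(pats, OrientationEstimate(0.0, 6), 6)

    def test_generative_patterns_give_positive_group_effect(self):
        diffs = []
        for seed in range(10):
            pats, meta = simulate_trial_patterns(rng_seed=seed)
            tp = TrialPatterns(pats, meta)
            ori = loo_orientations_from_patterns(tp, 6)
            diffs.append(rsa_orientation_dependent(tp, ori, 6))
        res = group_test(diffs)
        assert res.mean > 0 and res.p < 0.05


def test_permuted_directions_center_both_statistics_on_zero():
    rng = np.random.default_rng(4)
    pats, meta = simulate_trial_patterns(n_runs=2, n_trials=40, rng_seed=5)
    tp = TrialPatterns(pats, meta)
    dsm = neural_dsm(tp)
    rhos = []
    for _ in range(30):
        perm = rng.permutation(len(meta))
        rho, _ = rsa_orientation_independent(
            dsm, model_dsm(meta["theta_deg"].to_numpy()[perm], 6)
        )
        rhos.append(rho)
    assert abs(np.mean(rhos)) < 0.02


def test_loo_orientations_recover_truth_at_pattern_level():
    pats, meta = simulate_trial_patterns(noise_sd=0.2, phi_deg=35.0, rng_seed=6)
    ori = loo_orientations_from_patterns(TrialPatterns(pats, meta), 6)
    for est in ori.values():
        err = abs(est.phi_deg - 35.0) % 60.0
        assert min(err, 60.0 - err) < 3.0
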