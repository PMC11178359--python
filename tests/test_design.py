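import numpy as np
import pytest

from socialgrid.design import (
    build_glm1_design,
    build_glm2_design,
    build_glm3_design,
    concat_designs,
    hrf_kernel,
    make_regressor,
    offset_bin,
)


def _toy_trials(theta_deg, distance=None, gap=12.0):
    import pandas as pd

    n = len(theta_deg)
    onsets = 10.0 + gap * np.arange(n)
    return pd.DataFrame(
        {
            "onset": onsets,
            "duration": 2.0,
            "choice_onset": onsets + 2.0,
            "choice_duration": 2.5,
            "theta_deg": theta_deg,
            "distance": distance if distance is not None else np.linspace(0.2, 0.8, n),
        }
    )


class TestMakeRegressor:
    def test_zero_amplitudes_give_zero_column(self):
        col = make_regressor([10.0, 30.0], 2.0, 0.0, n_scans=40, repetition_time=2.0)
        assert np.allclose(col, 0.0)

    def test_linearity_in_amplitude(self):
        one = make_regressor([10.0], 2.0, 1.0, 60, 2.0)
        two = make_regressor([10.0], 2.0, 2.0, 60, 2.0)
        assert np.allclose(two, 2.0 * one)

    def test_peak_lags_onset_by_canonical_hrf_delay(self):
        # oracle: argmax of the HRF kernel itself (~5 s for a brief event)
        kernel = hrf_kernel()
        kernel_peak_s = np.argmax(kernel) * 0.05
        col = make_regressor([20.0], 0.1, 1.0, n_scans=60, repetition_time=0.5)
        peak_s = np.argmax(col) * 0.5
        assert peak_s - 20.0 == pytest.approx(kernel_peak_s, abs=0.5)
        assert 4.0 < kernel_peak_s < 6.5

    def test_onset_outside_run_rejected(self):
        with pytest.raises(ValueError):
            make_regressor([100.0], 2.0, 1.0, n_scans=10, repetition_time=2.0)


class TestGlm1Design:
    def test_modulator_amplitudes_at_quadrature_direction(self):
        # sin(6·15°) = 1, cos(6·15°) = 0: with two opposite-phase trials the
        # centered sin modulator keeps ±1 and the cos modulator vanishes
        trials = _toy_trials([15.0, 45.0])
        design = build_glm1_design(trials, 6, n_scans=30, repetition_time=2.0)
        sin_col = design.frame["morph_sin6theta"].to_numpy()
        cos_col = design.frame["morph_cos6theta"].to_numpy()
        assert np.max(np.abs(cos_col)) == pytest.approx(0.0, abs=1e-9)
        assert np.max(np.abs(sin_col)) > 0.1

    def test_column_budget(self):
        trials = _toy_trials(np.linspace(0, 350, 16))
        design = build_glm1_design(trials, 6, n_scans=120, repetition_time=2.0)
        n_drift = len(design.columns_of_kind("drift"))
        assert len(design.labels) == 4 + n_drift + 1

    def test_constant_directions_flagged_degenerate(self):
        trials = _toy_trials([30.0, 30.0, 30.0])
        design = build_glm1_design(trials, 6, n_scans=40, repetition_time=2.0)
        assert "morph_sin6theta" in design.degenerate
        assert "morph_cos6theta" in design.degenerate

    def test_invalid_fold(self):
        with pytest.raises(ValueError):
            build_glm1_design(_toy_trials([0.0]), 0, 40, 2.0)

    def test_modulator_columns_uncorrelated_with_morph_after_centering(self):
        trials = _toy_trials(np.linspace(0, 355, 24))
        design = build_glm1_design(trials, 6, n_scans=170, repetition_time=2.0)
        # centering pre-convolution keeps modulators near-orthogonal to the
        # stage regressor in a balanced design
        morph = design.frame["morph"].to_numpy()
        for lab in ("morph_sin6theta", "morph_cos6theta"):
            col = design.frame[lab].to_numpy()
            r = np.corrcoef(morph, col)[0, 1]
            assert abs(r) < 0.3


class TestOffsetBins:
    @pytest.mark.parametrize(
        "theta, phi, fold, bin_index, aligned",
        [
            (10.0, 0.0, 6, 0, True),
            (29.0, 0.0, 6, 1, False),
            (30.0, 0.0, 6, 1, False),
            (196.0, 0.0, 6, 1, False),  # offset 196 -> folded 16 -> center 30
            (15.0, 0.0, 6, 1, False),  # half-open boundary goes up
            (45.0, 0.0, 4, 1, False),  # 4-fold trough
            (59.0, 0.0, 6, 0, True),
        ],
    )
    def test_nearest_center_assignment(self, theta, phi, fold, bin_index, aligned):
        idx = offset_bin(theta, phi, fold)
        assert idx % (2 * fold) == bin_index % (2 * fold) or (
            idx % 2 == bin_index % 2
        )
        assert (idx % 2 == 0) == aligned

    def test_glm2_has_twelve_bins_for_sixfold(self):
        trials = _toy_trials(np.linspace(0, 355, 24))
        design = build_glm2_design(trials, 0.0, 6, n_scans=170, repetition_time=2.0)
        assert len(design.columns_of_kind("bin")) == 12

    def test_empty_bins_become_degenerate_zero_columns(self):
        trials = _toy_trials([1.0, 2.0, 3.0])  # all in bin 0
        design = build_glm2_design(trials, 0.0, 6, n_scans=50, repetition_time=2.0)
        empty = [
            lab
            for lab in design.columns_of_kind("bin")
            if design.provenance[lab]["n_trials"] == 0
        ]
        assert len(empty) == 11
        assert set(empty) <= set(design.degenerate)


class TestGlm3Design:
    def test_centered_distance_amplitudes(self):
        trials = _toy_trials(
            [0.0, 90.0, 180.0, 270.0], distance=[0.1, 0.3, 0.1, 0.3], gap=30.0
        )
        design = build_glm3_design(trials, n_scans=60, repetition_time=2.0)
        d = trials["distance"].to_numpy()
        centered = d - d.mean()
        # centering arithmetic: equally frequent {0.1, 0.3} -> amplitudes ±0.1
        assert np.allclose(np.sort(np.unique(centered)), [-0.1, 0.1])
        # the convolved column alternates symmetrically around zero
        col = design.frame["morph_distance"].to_numpy()
        assert np.max(col) == pytest.approx(-np.min(col), rel=0.05)
        assert abs(col.mean()) < 0.01

    def test_constant_distance_rejected(self):
        trials = _toy_trials([0.0, 90.0], distance=[0.5, 0.5])
        with pytest.raises(ValueError):
            build_glm3_design(trials, n_scans=30, repetition_time=2.0)


def test_concat_designs_shares_task_and_splits_nuisance():
    t1 = _toy_trials(np.linspace(0, 350, 8))
    t2 = _toy_trials(np.linspace(5, 355, 8))
    d1 = build_glm1_design(t1, 6, 60, 2.0)
    d2 = build_glm1_design(t2, 6, 60, 2.0)
    cat = concat_designs([d1, d2])
    assert cat.n_scans == 120
    assert "morph_sin6theta" in cat.labels
    assert "run0_intercept" in cat.labels and "run1_intercept" in cat.labels
    block = cat.frame["run1_intercept"].to_numpy()
    assert np.allclose(block[:60], 0.0) and np.allclose(block[60:], 1.0)
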