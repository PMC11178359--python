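"""Grid-orientation estimation and the leave-one-run-out consistency test.

The putative grid orientation of a region is φ = atan2(β̄_sin, β̄_cos)/f,
where β̄_sin and β̄_cos are the ROI-averaged quadrature-modulator betas
from the estimating runs. Consistency is tested out-of-sample: for every
held-out run, φ is estimated from the remaining runs, trials of the
held-out run are binned by their direction's offset from φ (2f bins of
360°/(2f)), one regressor per bin is fitted and the contrast
mean(aligned bins) − mean(misaligned bins) — renormalised over occupied
bins — is the run's consistency effect. The subject-level effect is the
mean over held-out runs. Folds 4, 5, 7 and 8 serve as specificity
controls for the hexadirectional f = 6.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .design import build_glm1_design, build_glm2_design, concat_designs, offset_bin
from .glm import GlmFit, QuadratureBetas, fit_ols, quadrature_betas, quadrature_f_test
from .simulate import BoldRun

__all__ = [
    "OrientationEstimate",
    "ConsistencyResult",
    "QuadratureFilterGLM",
    "GridConsistency",
    "estimate_orientation",
    "classify_alignment",
    "loo_consistency",
    "control_periodicities",
    "voxelwise_orientations",
    "group_test",
    "covariate_test",
    "sphere_roi",
]


@dataclass
class OrientationEstimate:
    """Putative grid orientation φ of an ROI for one fold.

    φ lives on the fold's fundamental domain [0°, 360°/f).
    ``low_confidence`` flags a near-zero mean resultant (both ROI-mean
    betas ≈ 0), where the direction is ill-determined.
    """

    phi_deg: float
    fold: int
    source_runs: tuple[int, ...] = ()
    roi: str = ""
    low_confidence: bool = False
    voxel_phi_deg: np.ndarray | None = None


@dataclass
class ConsistencyResult:
    """Aligned-vs-misaligned contrast of one subject at one fold."""

    fold: int
    per_run: pd.DataFrame  # run, phi_deg, aligned_mean, misaligned_mean, contrast
    contrast: float = field(init=False)

    def __post_init__(self) -> None:
        self.contrast = float(self.per_run["contrast"].mean())


def estimate_orientation(
    betas: QuadratureBetas,
    roi_voxels: np.ndarray | None = None,
    fold: int | None = None,
    source_runs: tuple[int, ...] = (),
    roi: str = "",
) -> OrientationEstimate:
    """ROI grid orientation from ROI-averaged quadrature betas."""
    fold = fold if fold is not None else betas.fold
    sel = slice(None) if roi_voxels is None else np.asarray(roi_voxels)
    b_sin = np.mean(betas.beta_sin[sel])
    b_cos = np.mean(betas.beta_cos[sel])
    amp = np.hypot(b_sin, b_cos)
    phi = np.rad2deg(np.arctan2(b_sin, b_cos)) / fold % (360.0 / fold)
    return OrientationEstimate(
        phi_deg=float(phi),
        fold=fold,
        source_runs=source_runs,
        roi=roi,
        low_confidence=bool(amp < 1e-12),
    )


def classify_alignment(theta_deg, phi_deg: float, fold: int = 6):
    """(bin index, aligned flag) of directions relative to orientation φ.

    The offset is mapped to the nearest of the 2f bin centers k·360°/(2f);
    a bin is aligned iff its center ≡ 0 (mod 360°/f).
    """
    idx = offset_bin(theta_deg, phi_deg, fold)
    return idx, idx % 2 == 0


def voxelwise_orientations(betas: QuadratureBetas, fold: int | None = None) -> np.ndarray:
    """Per-voxel putative orientations φ_v = atan2(β_sin, β_cos)/f (degrees)."""
    fold = fold if fold is not None else betas.fold
    if betas.beta_sin.size < 2:
        raise ValueError("need at least 2 voxels for voxelwise orientations")
    phi = np.rad2deg(np.arctan2(betas.beta_sin, betas.beta_cos)) / fold
    return phi % (360.0 / fold)


class QuadratureFilterGLM(BaseEstimator):
    """Quadrature-filter (GLM1) analysis of one subject's runs.

    Fits morph/choice regressors with sin(fθ) and cos(fθ) parametric
    modulators, either per run or on all runs jointly (shared task
    columns, run-specific drift/intercept), and exposes per-voxel
    quadrature betas, the joint F-statistic of the directional modulation
    and its normal-quantile Z.

    Parameters
    ----------
    fold : int
        Periodicity f of the directional modulation (6 = hexadirectional).
    drift_cutoff : float or None
        High-pass cutoff (s) of the discrete-cosine drift basis.

    Attributes (after ``fit``)
    --------------------------
    betas_ : QuadratureBetas
    F_, z_ : per-voxel joint F statistic and Z transform
    orientation_ : OrientationEstimate over all fitted runs
    fit_ : the underlying GlmFit
    """

    def __init__(self, fold: int = 6, drift_cutoff: float | None = 128.0):
        self.fold = fold
        self.drift_cutoff = drift_cutoff

    def fit(self, runs: list[BoldRun], events: pd.DataFrame, roi_voxels=None, designs=None):
        runs = [runs] if isinstance(runs, BoldRun) else list(runs)
        if designs is None:
            designs = []
            for r in runs:
                tr_tab = events[events["run"] == r.run] if "run" in events else events
                designs.append(
                    build_glm1_design(
                        tr_tab, self.fold, r.n_scans, r.repetition_time, self.drift_cutoff
                    )
                )
        design = concat_designs(list(designs))
        data = np.concatenate([r.data for r in runs], axis=1)
        self.fit_ = fit_ols(BoldRun(data, runs[0].repetition_time), design)
        self.betas_ = quadrature_betas(self.fit_, self.fold)
        self.F_, self.z_ = quadrature_f_test(self.fit_, self.fold)
        self.orientation_ = estimate_orientation(
            self.betas_,
            roi_voxels,
            self.fold,
            source_runs=tuple(r.run for r in runs),
        )
        return self


def _glm2_contrast(fit: GlmFit, design) -> tuple[float, float]:
    """Renormalised aligned/misaligned bin-beta means from a GLM2 fit."""
    aligned, misaligned = [], []
    for lab in design.columns_of_kind("bin"):
        if lab in design.degenerate:
            continue
        b = float(np.mean(fit.beta(lab)))
        (aligned if design.provenance[lab]["aligned"] else misaligned).append(b)
    if not aligned or not misaligned:
        raise ValueError("held-out run has no occupied aligned or misaligned bins")
    return float(np.mean(aligned)), float(np.mean(misaligned))


class GridConsistency(BaseEstimator):
    """Leave-one-run-out grid-orientation consistency analysis.

    Every run serves once as the testing set: the orientation is estimated
    from the other runs (GLM1 on the ROI average), the held-out run is
    fitted with the bin design (GLM2) and the aligned−misaligned contrast
    of ROI-mean bin betas is recorded. The subject-level consistency
    effect is the mean contrast over held-out runs.

    Attributes (after ``fit``)
    --------------------------
    result_ : ConsistencyResult
    contrast_ : float, subject-level mean contrast
    orientations_ : dict run -> OrientationEstimate used for that run
    """

    def __init__(self, fold: int = 6, drift_cutoff: float | None = 128.0):
        self.fold = fold
        self.drift_cutoff = drift_cutoff

    def fit(self, runs: list[BoldRun], events: pd.DataFrame, roi_voxels=None):
        runs = list(runs)
        if len(runs) < 2:
            raise ValueError("leave-one-run-out needs at least 2 runs")
        glm1_designs = {
            r.run: build_glm1_design(
                events[events["run"] == r.run] if "run" in events else events,
                self.fold,
                r.n_scans,
                r.repetition_time,
                self.drift_cutoff,
            )
            for r in runs
        }
        rows = []
        self.orientations_ = {}
        for held in runs:
            estimating = [r for r in runs if r is not held]
            glm1 = QuadratureFilterGLM(self.fold, self.drift_cutoff).fit(
                estimating,
                events,
                roi_voxels,
                designs=[glm1_designs[r.run] for r in estimating],
            )
            ori = glm1.orientation_
            self.orientations_[held.run] = ori
            test_trials = events[events["run"] == held.run] if "run" in events else events
            design = build_glm2_design(
                test_trials,
                ori.phi_deg,
                self.fold,
                held.n_scans,
                held.repetition_time,
                self.drift_cutoff,
            )
            roi_data = held.data if roi_voxels is None else held.data[np.asarray(roi_voxels)]
            fit = fit_ols(BoldRun(roi_data, held.repetition_time), design)
            try:
                a, m = _glm2_contrast(fit, design)
            except ValueError as err:
                warnings.warn(f"run {held.run} excluded: {err}")
                continue
            rows.append(
                {
                    "run": held.run,
                    "phi_deg": ori.phi_deg,
                    "aligned_mean": a,
                    "misaligned_mean": m,
                    "contrast": a - m,
                }
            )
        if not rows:
            raise ValueError("no run yielded a valid aligned/misaligned contrast")
        self.result_ = ConsistencyResult(self.fold, pd.DataFrame(rows))
        self.contrast_ = self.result_.contrast
        return self


def loo_consistency(
    subject_runs: list[BoldRun],
    trials: pd.DataFrame,
    roi_voxels=None,
    fold: int = 6,
    drift_cutoff: float | None = 128.0,
) -> ConsistencyResult:
    """Functional wrapper over :class:`GridConsistency`."""
    return GridConsistency(fold, drift_cutoff).fit(subject_runs, trials, roi_voxels).result_


def control_periodicities(
    subject_runs: list[BoldRun],
    trials: pd.DataFrame,
    roi_voxels=None,
    folds: tuple[int, ...] = (4, 5, 7, 8),
    drift_cutoff: float | None = 128.0,
) -> dict[int, ConsistencyResult]:
    """The consistency pipeline repeated at each control periodicity."""
    return {
        f: loo_consistency(subject_runs, trials, roi_voxels, f, drift_cutoff)
        for f in folds
    }


@dataclass
class GroupTestResult:
    t: float
    p: float
    mean: float
    n: int
    degenerate: bool = False


def group_test(
    contrasts,
    popmean: float = 0.0,
    alternative: str = "greater",
    paired_with=None,
) -> GroupTestResult:
    """Second-level one-sample t-test of per-subject contrasts (optionally a
    paired t against a second condition)."""
    x = np.asarray(contrasts, dtype=float)
    if paired_with is not None:
        x = x - np.asarray(paired_with, dtype=float)
    if x.size < 2:
        raise ValueError("group test needs n >= 2")
    if np.allclose(x, x[0]):
        m = float(x.mean() - popmean)
        sign = np.sign(m) if m else 0.0
        return GroupTestResult(
            t=float(sign * np.inf) if sign else 0.0,
            p=0.0 if sign else 1.0,
            mean=float(x.mean()),
            n=x.size,
            degenerate=True,
        )
    res = stats.ttest_1samp(x, popmean, alternative=alternative)
    return GroupTestResult(float(res.statistic), float(res.pvalue), float(x.mean()), x.size)


def covariate_test(
    contrasts,
    covariates: dict[str, np.ndarray] | np.ndarray,
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Simple regressions of subject contrasts on each covariate, with
    Benjamini–Hochberg FDR over the tested covariates.

    Returns a table (covariate, slope, r, p, p_fdr, significant).
    """
    y = np.asarray(contrasts, dtype=float)
    if not isinstance(covariates, dict):
        covariates = {"covariate": np.asarray(covariates)}
    rows = []
    for name, x in covariates.items():
        x = np.asarray(x, dtype=float)
        if x.size != y.size:
            raise ValueError(f"covariate {name!r} length mismatch")
        if x.size < 3:
            raise ValueError("covariate test needs n >= 3")
        if np.allclose(x, x[0]):
            raise ValueError(f"covariate {name!r} is constant")
        res = stats.linregress(x, y)
        rows.append(
            {"covariate": name, "slope": res.slope, "r": res.rvalue, "p": res.pvalue}
        )
    table = pd.DataFrame(rows)
    reject, p_fdr, *_ = multipletests(table["p"], alpha=fdr_q, method="fdr_bh")
    table["p_fdr"] = p_fdr
    table["significant"] = reject
    return table


def sphere_roi(shape: tuple[int, int, int], center, radius: float) -> np.ndarray:
    """Flat voxel indices of a sphere (voxel units) in a 3D grid — utility
    replacing peak-centered sphere masks."""
    grid = np.indices(shape).reshape(3, -1).T
    d = np.linalg.norm(grid - np.asarray(center, dtype=float), axis=1)
    return np.where(d <= radius)[0]
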