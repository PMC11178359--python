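"""Representational similarity analyses of trial-wise activity patterns.

Single-trial patterns are estimated with the least-squares-separate (LSS)
approach: for each trial, a GLM with one target regressor for that trial's
morph stage and one nuisance regressor for all other morph events (plus
choice, drift, intercept); the target beta is the trial's pattern row.

Two tests for hexadirectional pattern structure:

* orientation-independent — Spearman correlation between the neural
  trial × trial dissimilarity matrix (1 − Pearson r) and a model DSM
  proportional to the angular difference of trial directions folded by
  360°/f;
* orientation-dependent — mean pattern similarity among trials aligned to
  a (cross-validated) grid orientation minus the mean similarity between
  aligned and misaligned trials (AA − AM).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignMatrix, cosine_drift, make_regressor
from .glm import fit_ols
from .grid import OrientationEstimate, classify_alignment
from .simulate import BoldRun

__all__ = [
    "TrialPatterns",
    "lss_estimates",
    "neural_dsm",
    "model_dsm",
    "rsa_orientation_independent",
    "rsa_orientation_dependent",
    "fisher_z",
]


@dataclass
class TrialPatterns:
    """Trial × voxel matrix of LSS betas with per-trial metadata."""

    patterns: np.ndarray
    trials: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.patterns) != len(self.trials):
            raise ValueError("pattern rows must match trial metadata rows")

    @staticmethod
    def concatenate(parts: list["TrialPatterns"]) -> "TrialPatterns":
        return TrialPatterns(
            np.vstack([p.patterns for p in parts]),
            pd.concat([p.trials for p in parts], ignore_index=True),
        )


def lss_estimates(
    run: BoldRun,
    trials: pd.DataFrame,
    drift_cutoff: float | None = 128.0,
) -> TrialPatterns:
    """Least-squares-separate single-trial pattern estimation for one run."""
    trials = trials.reset_index(drop=True)
    n = len(trials)
    if n < 2:
        raise ValueError("LSS needs at least 2 trials (nuisance regressor undefined)")
    tr = run.repetition_time
    n_scans = run.n_scans
    m_on = trials["onset"].to_numpy(dtype=float)
    m_dur = trials["duration"].to_numpy(dtype=float)
    single = np.column_stack(
        [make_regressor([m_on[i]], [m_dur[i]], 1.0, n_scans, tr) for i in range(n)]
    )
    total = single.sum(axis=1)
    choice = make_regressor(
        trials["choice_onset"], trials["choice_duration"], 1.0, n_scans, tr
    )
    drift = cosine_drift(n_scans, tr, drift_cutoff) if drift_cutoff else np.empty((n_scans, 0))
    betas = np.zeros((n, run.n_voxels))
    frame_times = np.arange(n_scans) * tr
    for i in range(n):
        cols = {
            "target": single[:, i],
            "nuisance": total - single[:, i],
            "choice": choice,
        }
        prov = {
            "target": {"kind": "stage"},
            "nuisance": {"kind": "stage"},
            "choice": {"kind": "stage"},
        }
        for k in range(drift.shape[1]):
            cols[f"drift_{k + 1}"] = drift[:, k]
            prov[f"drift_{k + 1}"] = {"kind": "drift"}
        cols["intercept"] = np.ones(n_scans)
        prov["intercept"] = {"kind": "intercept"}
        design = DesignMatrix(pd.DataFrame(cols), frame_times, prov)
        fit = fit_ols(run, design)
        betas[i] = fit.beta("target")
    return TrialPatterns(betas, trials)


def neural_dsm(patterns: TrialPatterns | np.ndarray) -> np.ndarray:
    """Trial × trial dissimilarity matrix, 1 − Pearson r between pattern rows."""
    mat = patterns.patterns if isinstance(patterns, TrialPatterns) else np.asarray(patterns)
    if mat.shape[1] < 2:
        raise ValueError("correlation distance needs at least 2 voxels")
    sd = mat.std(axis=1)
    if np.any(sd == 0):
        bad = np.where(sd == 0)[0].tolist()
        raise ValueError(f"zero-variance pattern rows for trials {bad}")
    dsm = 1.0 - np.corrcoef(mat)
    np.fill_diagonal(dsm, 0.0)
    return dsm


def model_dsm(theta_deg, fold: int = 6) -> np.ndarray:
    """Model DSM: angular difference of trial directions folded by 360°/f.

    Entries lie in [0°, 180°/f]; pairs one folded period apart are
    identical (0°).
    """
    if fold < 1:
        raise ValueError("fold must be >= 1")
    th = np.asarray(theta_deg, dtype=float)
    period = 360.0 / fold
    delta = np.mod(np.abs(th[:, None] - th[None, :]), period)
    return np.minimum(delta, period - delta)


def _upper(mat: np.ndarray) -> np.ndarray:
    return mat[np.triu_indices_from(mat, k=1)]


def fisher_z(r):
    """Fisher's variance-stabilising transform arctanh(r)."""
    return np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))


def rsa_orientation_independent(
    neural: np.ndarray,
    model: np.ndarray,
    exclude_within_run: pd.Series | np.ndarray | None = None,
):
    """Spearman ρ between neural and model DSM over off-diagonal pairs.

    Returns (ρ, Fisher-Z). ``exclude_within_run``: per-trial run labels;
    when given, within-run pairs are dropped (robustness toggle).
    Group-level inference is a one-sample t-test across subjects on the
    Fisher-Z values (see :func:`socialgrid.grid.group_test`).
    """
    neural = np.asarray(neural, dtype=float)
    model = np.asarray(model, dtype=float)
    if neural.shape != model.shape:
        raise ValueError("neural and model DSM sizes differ")
    nv, mv = _upper(neural), _upper(model)
    if exclude_within_run is not None:
        runs = np.asarray(exclude_within_run)
        keep = _upper(runs[:, None] != runs[None, :]).astype(bool)
        nv, mv = nv[keep], mv[keep]
    if np.allclose(nv, nv[0]) or np.allclose(mv, mv[0]):
        raise ValueError("constant DSM; rank correlation undefined")
    rho = stats.spearmanr(nv, mv).statistic
    return float(rho), float(fisher_z(rho))


def loo_orientations_from_patterns(
    patterns: TrialPatterns,
    fold: int = 6,
) -> dict[int, OrientationEstimate]:
    """Leave-one-run-out orientations estimated at the pattern level.

    For every run, the remaining runs' patterns are regressed on
    [1, cos(fθ), sin(fθ)] per voxel; the ROI-averaged quadrature betas
    give the orientation used to classify that run's trials — mirroring
    the univariate cross-validation procedure when trial patterns rather
    than time series are in hand.
    """
    from .glm import QuadratureBetas
    from .grid import estimate_orientation

    trials = patterns.trials
    runs = trials["run"].to_numpy() if "run" in trials else np.zeros(len(trials), int)
    theta = np.deg2rad(trials["theta_deg"].to_numpy(dtype=float))
    out: dict[int, OrientationEstimate] = {}
    for r in np.unique(runs):
        est = runs != r
        X = np.column_stack(
            [np.ones(est.sum()), np.cos(fold * theta[est]), np.sin(fold * theta[est])]
        )
        coef, *_ = np.linalg.lstsq(X, patterns.patterns[est], rcond=None)
        betas = QuadratureBetas(beta_cos=coef[1], beta_sin=coef[2], fold=fold)
        out[int(r)] = estimate_orientation(betas, fold=fold)
    return out


def rsa_orientation_dependent(
    patterns: TrialPatterns,
    orientations: dict[int, OrientationEstimate] | OrientationEstimate,
    fold: int = 6,
    exclude_within_run: bool = False,
):
    """AA − AM pattern-similarity difference.

    Trials are classified aligned/misaligned using the leave-one-run-out
    orientation of their own run (pass the ``GridConsistency``
    ``orientations_`` mapping, or a single estimate). Similarity is the
    Pearson correlation between trial patterns; the statistic is the mean
    similarity among aligned pairs minus the mean similarity between
    aligned and misaligned pairs, pooled over runs by default.
    """
    trials = patterns.trials
    runs = trials["run"].to_numpy() if "run" in trials else np.zeros(len(trials), int)
    aligned = np.zeros(len(trials), dtype=bool)
    for r in np.unique(runs):
        if isinstance(orientations, dict):
            ori = orientations[int(r)]
        else:
            ori = orientations
        sel = runs == r
        _, al = classify_alignment(
            trials.loc[sel, "theta_deg"].to_numpy(), ori.phi_deg, fold
        )
        aligned[sel] = al
    if not aligned.any() or aligned.all():
        raise ValueError("need both aligned and misaligned trials")
    sim = np.corrcoef(patterns.patterns)
    iu = np.triu_indices_from(sim, k=1)
    both_aligned = aligned[iu[0]] & aligned[iu[1]]
    cross = aligned[iu[0]] ^ aligned[iu[1]]
    keep = np.ones(len(iu[0]), dtype=bool)
    if exclude_within_run:
        keep = runs[iu[0]] != runs[iu[1]]
    vals = sim[iu]
    aa = vals[both_aligned & keep]
    am = vals[cross & keep]
    if aa.size == 0 or am.size == 0:
        raise ValueError("empty AA or AM pair class")
    return float(aa.mean() - am.mean())
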