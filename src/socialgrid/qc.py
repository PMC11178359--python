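"""Temporal signal-to-noise quality control and its relation to the
hexadirectional-modulation statistic."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .rsa import fisher_z
from .simulate import BoldRun

__all__ = ["TsnrResult", "tsnr", "tsnr_modulation_relation"]


@dataclass
class TsnrResult:
    """Per-voxel tSNR = μ/σ, averaged across runs.

    Voxels with σ = 0 in any run are flagged undefined (NaN) and excluded
    from ROI aggregates.
    """

    per_voxel: np.ndarray
    per_run: np.ndarray  # run × voxel

    def roi_mean(self, roi_voxels=None) -> float:
        vals = self.per_voxel if roi_voxels is None else self.per_voxel[np.asarray(roi_voxels)]
        return float(np.nanmean(vals))


def tsnr(runs: BoldRun | list[BoldRun], detrend: bool = False) -> TsnrResult:
    """Voxelwise temporal SNR, mean over runs of per-run μ/σ.

    σ is computed on the raw series by default, matching the plain μ/σ
    definition; ``detrend=True`` removes a linear trend first.
    """
    runs = [runs] if isinstance(runs, BoldRun) else list(runs)
    per_run = []
    for r in runs:
        if r.n_scans < 2:
            raise ValueError("tSNR needs at least 2 scans")
        data = r.data
        if detrend:
            t = np.arange(r.n_scans)
            slope = np.polyfit(t, data.T, 1)
            data = data - np.outer(slope[0], t)
        mu = r.data.mean(axis=1)  # μ always from the raw series
        sd = data.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            snr = np.where(sd > 0, mu / sd, np.nan)
        per_run.append(snr)
    per_run = np.asarray(per_run)
    return TsnrResult(per_run.mean(axis=0), per_run)


def tsnr_modulation_relation(
    tsnr_by_subject: np.ndarray,
    z_by_subject: np.ndarray,
) -> dict:
    """Relation between tSNR and the hexadirectional-modulation Z.

    ``tsnr_by_subject`` / ``z_by_subject``: subject × voxel arrays.
    Across subjects: Pearson r between subject-mean tSNR and subject-mean
    Z. Within subjects: per-subject voxelwise r, Fisher-Z transformed,
    tested against zero with a two-sided Wilcoxon signed-rank test.
    """
    tsnr_mat = np.asarray(tsnr_by_subject, dtype=float)
    z_mat = np.asarray(z_by_subject, dtype=float)
    if tsnr_mat.shape != z_mat.shape:
        raise ValueError("tSNR and Z arrays must have matching shape")
    if tsnr_mat.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    mean_t = np.nanmean(tsnr_mat, axis=1)
    mean_z = np.nanmean(z_mat, axis=1)
    for arr, name in ((mean_t, "tSNR"), (mean_z, "Z")):
        if np.allclose(arr, arr[0]):
            raise ValueError(f"constant subject-mean {name}")
    across = stats.pearsonr(mean_t, mean_z)
    within_r = np.empty(tsnr_mat.shape[0])
    for s in range(tsnr_mat.shape[0]):
        ok = np.isfinite(tsnr_mat[s]) & np.isfinite(z_mat[s])
        if ok.sum() < 3 or np.allclose(tsnr_mat[s, ok], tsnr_mat[s, ok][0]):
            raise ValueError(f"subject {s}: degenerate voxelwise input")
        within_r[s] = stats.pearsonr(tsnr_mat[s, ok], z_mat[s, ok]).statistic
    fz = fisher_z(within_r)
    wil = stats.wilcoxon(fz, alternative="two-sided")
    return {
        "across_r": float(across.statistic),
        "across_p": float(across.pvalue),
        "within_r": within_r,
        "within_fisher_z": fz,
        "wilcoxon_stat": float(wil.statistic),
        "wilcoxon_p": float(wil.pvalue),
    }
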