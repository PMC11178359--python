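"""Mass-univariate OLS fitting, contrasts and the quadrature F→Z statistic."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .design import DesignMatrix
from .simulate import BoldRun

__all__ = ["GlmFit", "fit_ols", "t_contrast", "quadrature_f_test", "QuadratureBetas"]

#: |Z| ceiling used when the F cumulative probability saturates.
Z_CLIP = 8.2


@dataclass
class GlmFit:
    """Per-voxel OLS estimates for one design.

    ``betas`` is voxel × regressor over the *fitted* (non-degenerate)
    columns listed in ``labels``; degenerate design columns are recorded
    but carry no estimate.
    """

    betas: np.ndarray
    labels: list[str]
    residual_variance: np.ndarray
    df: int
    design: DesignMatrix
    xtx_inv: np.ndarray

    def beta(self, label: str) -> np.ndarray:
        """Per-voxel beta for one column label."""
        return self.betas[:, self.labels.index(label)]


def fit_ols(run: BoldRun | np.ndarray, design: DesignMatrix) -> GlmFit:
    """Fit the design to every voxel's time series by ordinary least squares.

    Degenerate (all-zero) columns are dropped before fitting; a
    rank-deficient remaining design raises with the offending columns
    named.
    """
    data = run.data if isinstance(run, BoldRun) else np.asarray(run, dtype=float)
    if data.ndim == 1:
        data = data[None, :]
    if data.shape[1] != design.n_scans:
        raise ValueError(
            f"data has {data.shape[1]} scans but design has {design.n_scans} rows"
        )
    labels = [c for c in design.labels if c not in design.degenerate]
    X = design.frame[labels].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify collinear columns via tiny R diagonal of a pivoted QR
        r = np.abs(np.diag(np.linalg.qr(X, mode="r")))
        bad = [labels[i] for i in np.where(r < 1e-10 * r.max())[0]]
        raise ValueError(f"rank-deficient design; collinear columns: {bad or labels}")
    df = design.n_scans - rank
    if df <= 0:
        raise ValueError("non-positive residual degrees of freedom")
    xtx_inv = np.linalg.inv(X.T @ X)
    betas = data @ X @ xtx_inv  # voxel × regressor
    resid = data - betas @ X.T
    rss = np.einsum("vt,vt->v", resid, resid)
    return GlmFit(betas, labels, rss / df, df, design, xtx_inv)


def t_contrast(fit: GlmFit, weights: dict[str, float]):
    """Per-voxel contrast estimate, t statistic and two-sided p.

    ``weights`` maps column labels to contrast weights; labels absent from
    the fit (degenerate columns) are rejected.
    """
    c = np.zeros(len(fit.labels))
    for lab, w in weights.items():
        if lab not in fit.labels:
            raise ValueError(f"contrast names unfitted column {lab!r}")
        c[fit.labels.index(lab)] = w
    est = fit.betas @ c
    var = fit.residual_variance * float(c @ fit.xtx_inv @ c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = est / np.sqrt(var)
    p = 2.0 * stats.t.sf(np.abs(t), fit.df)
    return est, t, p


@dataclass
class QuadratureBetas:
    """Per-voxel (β_cos fθ, β_sin fθ) estimates for one fold."""

    beta_cos: np.ndarray
    beta_sin: np.ndarray
    fold: int


def quadrature_betas(fit: GlmFit, fold: int) -> QuadratureBetas:
    try:
        return QuadratureBetas(
            beta_cos=fit.beta(f"morph_cos{fold}theta"),
            beta_sin=fit.beta(f"morph_sin{fold}theta"),
            fold=fold,
        )
    except ValueError as err:
        raise ValueError(
            f"fit does not contain fold-{fold} quadrature modulator columns"
        ) from err


def quadrature_f_test(fit: GlmFit, fold: int = 6):
    """Joint F-test of β_cos = β_sin = 0 and its normal-quantile Z.

    F has (2, df) degrees of freedom. Z = Φ⁻¹(P(F' ≤ F)), the one-sided
    normal quantile of the F cumulative probability, computed through the
    survival function for tail accuracy and clipped to ±``Z_CLIP``.
    """
    sin_lab = f"morph_sin{fold}theta"
    cos_lab = f"morph_cos{fold}theta"
    for lab in (sin_lab, cos_lab):
        if lab not in fit.labels:
            raise ValueError(f"fit is missing modulator column {lab!r}")
    idx = [fit.labels.index(cos_lab), fit.labels.index(sin_lab)]
    C = np.zeros((2, len(fit.labels)))
    C[0, idx[0]] = 1.0
    C[1, idx[1]] = 1.0
    mid = np.linalg.inv(C @ fit.xtx_inv @ C.T)
    cb = fit.betas @ C.T  # voxel × 2
    num = np.einsum("vi,ij,vj->v", cb, mid, cb) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        F = num / fit.residual_variance
    F = np.where(np.isfinite(F), F, 0.0)
    return F, f_to_z(F, d1=2, d2=fit.df)


def f_to_z(F, d1: int, d2: int):
    """Map F statistics to standard-normal quantiles of their cumulative
    probability, with clipping of saturated tails."""
    F = np.asarray(F, dtype=float)
    sf = stats.f.sf(F, d1, d2)
    with np.errstate(divide="ignore"):
        z = stats.norm.isf(sf)
    # where sf underflows, fall back on the cdf route before clipping
    low = stats.norm.ppf(np.clip(stats.f.cdf(F, d1, d2), 1e-300, 1.0))
    z = np.where(np.isfinite(z), z, low)
    return np.clip(z, -Z_CLIP, Z_CLIP)
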