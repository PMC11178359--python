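"""Mass-univariate design-matrix construction.

Three first-level models are used throughout:

* GLM1 ("quadrature filter"): morph-stage regressor plus sin(fθ) and
  cos(fθ) parametric modulators of the morph stage — a joint F-test on the
  two modulators detects f-fold directional modulation regardless of the
  (unknown) grid orientation φ.
* GLM2 ("consistency"): one morph regressor per offset bin of the
  trajectory direction relative to a putative orientation φ (2f bins of
  width 360°/(2f); for f=6, 12 bins of 30°).
* GLM3 ("distance"): traveled Euclidean distance as a parametric modulator
  of the morph stage.

All stage regressors are boxcars whose duration matches the modelled
stage, convolved with a canonical double-gamma HRF. Parametric modulators
are mean-centered per run *before* convolution; no serial
orthogonalisation is applied. Slow drifts are modelled with a discrete
cosine basis (default 128 s cutoff) plus an intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from nilearn.glm.first_level.hemodynamic_models import glover_hrf

__all__ = [
    "DesignMatrix",
    "hrf_kernel",
    "make_regressor",
    "cosine_drift",
    "build_glm1_design",
    "build_glm2_design",
    "build_glm3_design",
    "concat_designs",
    "offset_bin",
]

_DT = 0.05  # oversampled resolution (s) for event trains before convolution


@lru_cache(maxsize=8)
def _hrf_kernel_cached(dt: float, time_length: float) -> np.ndarray:
    h = glover_hrf(t_r=dt, oversampling=1, time_length=time_length)
    return h / h.max()


def hrf_kernel(dt: float = _DT, time_length: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at resolution ``dt``, peak-normalised."""
    return _hrf_kernel_cached(float(dt), float(time_length))


@dataclass
class DesignMatrix:
    """A scan × regressor design with per-column provenance.

    ``provenance`` maps column label -> dict with at least ``kind`` (one of
    ``stage``, ``modulator``, ``bin``, ``drift``, ``intercept``) and, for
    bins, ``bin_index`` / ``bin_center_deg`` / ``aligned``. ``degenerate``
    lists columns that are identically zero (e.g. empty bins or constant
    modulators) and must be excluded from fitting/contrasts.
    """

    frame: pd.DataFrame
    frame_times: np.ndarray
    provenance: dict[str, dict] = field(default_factory=dict)
    degenerate: list[str] = field(default_factory=list)

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def labels(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n_scans(self) -> int:
        return len(self.frame)

    def columns_of_kind(self, kind: str) -> list[str]:
        return [c for c, p in self.provenance.items() if p.get("kind") == kind]


def make_regressor(
    onsets,
    durations,
    amplitudes,
    n_scans: int,
    repetition_time: float,
    hrf: np.ndarray | None = None,
) -> np.ndarray:
    """Boxcar event train scaled by ``amplitudes``, HRF-convolved, sampled
    at frame times ``k·TR``."""
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    durations = np.broadcast_to(
        np.atleast_1d(np.asarray(durations, dtype=float)), onsets.shape
    )
    amplitudes = np.broadcast_to(
        np.atleast_1d(np.asarray(amplitudes, dtype=float)), onsets.shape
    )
    if np.any(durations <= 0):
        raise ValueError("durations must be positive")
    run_end = n_scans * repetition_time
    if np.any(onsets < 0) or np.any(onsets >= run_end):
        raise ValueError("event onset outside the run")
    if hrf is None:
        hrf = hrf_kernel()
    n_hi = int(np.ceil(run_end / _DT))
    train = np.zeros(n_hi)
    for o, d, a in zip(onsets, durations, amplitudes):
        i0 = int(round(o / _DT))
        i1 = min(int(round((o + d) / _DT)), n_hi)
        train[i0:i1] += a
    # Riemann-scaled discrete convolution: a unit-amplitude event of ~2 s
    # yields an O(1) peak response (kernel is peak-normalised)
    conv = np.convolve(train, hrf)[:n_hi] * _DT
    frame_idx = np.round(np.arange(n_scans) * repetition_time / _DT).astype(int)
    return conv[frame_idx]


def cosine_drift(n_scans: int, repetition_time: float, cutoff: float = 128.0) -> np.ndarray:
    """Discrete-cosine drift basis (periods longer than ``cutoff`` seconds).

    Returns an ``n_scans × K`` array, K = floor(2·duration/cutoff); may be
    empty for short runs.
    """
    duration = n_scans * repetition_time
    order = int(np.floor(2.0 * duration / cutoff))
    t = (np.arange(n_scans) + 0.5) / n_scans
    return np.column_stack(
        [np.cos(np.pi * k * t) for k in range(1, order + 1)]
    ) if order >= 1 else np.empty((n_scans, 0))


def _assemble(
    task_cols: dict[str, np.ndarray],
    task_prov: dict[str, dict],
    n_scans: int,
    repetition_time: float,
    drift_cutoff: float | None,
) -> DesignMatrix:
    cols = dict(task_cols)
    prov = dict(task_prov)
    if drift_cutoff is not None:
        drift = cosine_drift(n_scans, repetition_time, drift_cutoff)
        for k in range(drift.shape[1]):
            lab = f"drift_{k + 1}"
            cols[lab] = drift[:, k]
            prov[lab] = {"kind": "drift"}
    cols["intercept"] = np.ones(n_scans)
    prov["intercept"] = {"kind": "intercept"}
    frame = pd.DataFrame(cols)
    degenerate = [c for c in frame.columns if np.allclose(frame[c].to_numpy(), 0.0)]
    frame_times = np.arange(n_scans) * repetition_time
    return DesignMatrix(frame, frame_times, prov, degenerate)


def _stage_events(trials: pd.DataFrame):
    morph_on = trials["onset"].to_numpy(dtype=float)
    morph_dur = trials["duration"].to_numpy(dtype=float)
    choice_on = trials["choice_onset"].to_numpy(dtype=float)
    choice_dur = trials["choice_duration"].to_numpy(dtype=float)
    return morph_on, morph_dur, choice_on, choice_dur


def build_glm1_design(
    trials: pd.DataFrame,
    fold: int,
    n_scans: int,
    repetition_time: float = 2.0,
    drift_cutoff: float | None = 128.0,
    hrf: np.ndarray | None = None,
) -> DesignMatrix:
    """Quadrature-filter design: morph, morph×sin(fθ), morph×cos(fθ), choice."""
    if fold < 1:
        raise ValueError("fold must be >= 1")
    morph_on, morph_dur, choice_on, choice_dur = _stage_events(trials)
    theta = np.deg2rad(trials["theta_deg"].to_numpy(dtype=float))
    sin_mod = np.sin(fold * theta)
    cos_mod = np.cos(fold * theta)
    sin_mod = sin_mod - sin_mod.mean()
    cos_mod = cos_mod - cos_mod.mean()
    cols = {
        "morph": make_regressor(morph_on, morph_dur, 1.0, n_scans, repetition_time, hrf),
        f"morph_sin{fold}theta": make_regressor(
            morph_on, morph_dur, sin_mod, n_scans, repetition_time, hrf
        ),
        f"morph_cos{fold}theta": make_regressor(
            morph_on, morph_dur, cos_mod, n_scans, repetition_time, hrf
        ),
        "choice": make_regressor(choice_on, choice_dur, 1.0, n_scans, repetition_time, hrf),
    }
    prov = {
        "morph": {"kind": "stage", "stage": "morph"},
        f"morph_sin{fold}theta": {"kind": "modulator", "modulator": "sin", "fold": fold},
        f"morph_cos{fold}theta": {"kind": "modulator", "modulator": "cos", "fold": fold},
        "choice": {"kind": "stage", "stage": "choice"},
    }
    return _assemble(cols, prov, n_scans, repetition_time, drift_cutoff)


def offset_bin(theta_deg, phi_deg: float, fold: int):
    """Bin index of a trial direction's offset from orientation φ.

    The offset (θ−φ) mod 360° is mapped to the nearest of the 2f bin
    centers ``k·360°/(2f)`` (half-open bins [center−w/2, center+w/2),
    w = 360°/(2f)). Even bin indices (centers ≡ 0 mod 360°/f) are aligned,
    odd indices misaligned.
    """
    if fold < 1:
        raise ValueError("fold must be >= 1")
    width = 360.0 / (2 * fold)
    offset = np.mod(np.asarray(theta_deg, dtype=float) - phi_deg, 360.0)
    idx = np.mod(np.floor(offset / width + 0.5).astype(int), 2 * fold)
    return idx


def build_glm2_design(
    trials: pd.DataFrame,
    phi_deg: float,
    fold: int,
    n_scans: int,
    repetition_time: float = 2.0,
    drift_cutoff: float | None = 128.0,
    hrf: np.ndarray | None = None,
) -> DesignMatrix:
    """Consistency design: one morph regressor per direction-offset bin.

    For f=6 this yields 12 bins of 30°; bins with no trials produce
    all-zero columns, flagged degenerate and excluded from contrasts.
    """
    morph_on, morph_dur, choice_on, choice_dur = _stage_events(trials)
    bins = offset_bin(trials["theta_deg"].to_numpy(dtype=float), phi_deg, fold)
    n_bins = 2 * fold
    cols: dict[str, np.ndarray] = {}
    prov: dict[str, dict] = {}
    for b in range(n_bins):
        lab = f"bin_{b:02d}"
        sel = bins == b
        if np.any(sel):
            col = make_regressor(
                morph_on[sel], morph_dur[sel], 1.0, n_scans, repetition_time, hrf
            )
        else:
            col = np.zeros(n_scans)
        cols[lab] = col
        prov[lab] = {
            "kind": "bin",
            "bin_index": b,
            "bin_center_deg": b * 360.0 / n_bins,
            "aligned": b % 2 == 0,
            "n_trials": int(sel.sum()),
        }
    cols["choice"] = make_regressor(choice_on, choice_dur, 1.0, n_scans, repetition_time, hrf)
    prov["choice"] = {"kind": "stage", "stage": "choice"}
    return _assemble(cols, prov, n_scans, repetition_time, drift_cutoff)


def build_glm3_design(
    trials: pd.DataFrame,
    n_scans: int,
    repetition_time: float = 2.0,
    drift_cutoff: float | None = 128.0,
    hrf: np.ndarray | None = None,
) -> DesignMatrix:
    """Distance design: morph, morph×distance (mean-centered), choice."""
    morph_on, morph_dur, choice_on, choice_dur = _stage_events(trials)
    d = trials["distance"].to_numpy(dtype=float)
    if np.allclose(d, d[0]):
        raise ValueError("all traveled distances are equal; distance modulator degenerate")
    d_mod = d - d.mean()
    cols = {
        "morph": make_regressor(morph_on, morph_dur, 1.0, n_scans, repetition_time, hrf),
        "morph_distance": make_regressor(
            morph_on, morph_dur, d_mod, n_scans, repetition_time, hrf
        ),
        "choice": make_regressor(choice_on, choice_dur, 1.0, n_scans, repetition_time, hrf),
    }
    prov = {
        "morph": {"kind": "stage", "stage": "morph"},
        "morph_distance": {"kind": "modulator", "modulator": "distance"},
        "choice": {"kind": "stage", "stage": "choice"},
    }
    return _assemble(cols, prov, n_scans, repetition_time, drift_cutoff)


def concat_designs(designs: list[DesignMatrix]) -> DesignMatrix:
    """Stack run designs sharing task columns, with run-specific drift and
    intercept blocks.

    Columns whose provenance kind is ``stage``, ``modulator`` or ``bin``
    are shared (stacked vertically); drift and intercept columns become
    block-diagonal per run. Used for multi-run fits so that a single
    (β_sin, β_cos) pair is estimated across the estimating set.
    """
    if len(designs) == 1:
        return designs[0]
    task_kinds = {"stage", "modulator", "bin"}
    task_labels = [c for c in designs[0].labels if designs[0].provenance[c]["kind"] in task_kinds]
    for d in designs[1:]:
        other = [c for c in d.labels if d.provenance[c]["kind"] in task_kinds]
        if other != task_labels:
            raise ValueError("designs have mismatched task columns")
    n_total = sum(d.n_scans for d in designs)
    cols: dict[str, np.ndarray] = {}
    prov: dict[str, dict] = {}
    for lab in task_labels:
        cols[lab] = np.concatenate([d.frame[lab].to_numpy() for d in designs])
        prov[lab] = dict(designs[0].provenance[lab])
        if prov[lab]["kind"] == "bin":
            prov[lab]["n_trials"] = sum(d.provenance[lab]["n_trials"] for d in designs)
    offset = 0
    for r, d in enumerate(designs):
        nuis = [c for c in d.labels if d.provenance[c]["kind"] in ("drift", "intercept")]
        for lab in nuis:
            full = np.zeros(n_total)
            full[offset : offset + d.n_scans] = d.frame[lab].to_numpy()
            new_lab = f"run{r}_{lab}"
            cols[new_lab] = full
            prov[new_lab] = dict(d.provenance[lab])
        offset += d.n_scans
    frame = pd.DataFrame(cols)
    degenerate = [c for c in frame.columns if np.allclose(frame[c].to_numpy(), 0.0)]
    times = np.concatenate([d.frame_times for d in designs])
    return DesignMatrix(frame, times, prov, degenerate)
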