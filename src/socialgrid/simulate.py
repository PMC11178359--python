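"""Ground-truth task and BOLD simulation.

Emulates the scanner recall task — 4 runs × 80 trials, each trial a
trajectory (direction θ, distance d) through the unit-square social value
map, with directions sampled one per equal-width bin of [0, 2π) and half
of the trajectories terminating on avatar locations — and a BOLD signal
model in which "grid" voxels respond to the morph stage with amplitude
baseline + ω·cos(f(θ−φ_v)), "distance" voxels with baseline + slope·d and
"noise" voxels carry no task signal. Neural event trains are convolved
with a canonical HRF, sampled at the repetition time and corrupted with
additive Gaussian (optionally AR(1)) noise.

Per-voxel grid phases φ_v are drawn von Mises around the subject's true
orientation φ (concentration ``phase_kappa`` on the folded angle f·φ),
emulating the assumption that neighbouring grid cells share similar
orientations while leaving enough dispersion for multivariate pattern
structure.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import hrf_kernel, make_regressor
from .space import Avatar, SocialSpace, expected_profit, sample_avatar_layout

__all__ = [
    "SimConfig",
    "BoldRun",
    "SubjectData",
    "hexadirectional_response",
    "sample_recall_block",
    "simulate_run",
    "simulate_subject",
    "simulate_behavior",
]

#: Noise standard deviation calibrated (by simulation, with ω = 1 and the
#: default 80-trial design) so that a single grid voxel's quadrature Z is
#: ≈ 2 — the per-voxel contrast-to-noise regime the analyses are
#: validated at. See docs/methods.md.
CALIBRATED_NOISE_SD = 12.0


@dataclass(frozen=True)
class SimConfig:
    """Study-design and signal-model parameters for one simulated subject."""

    repetition_time: float = 2.0
    n_runs: int = 4
    n_trials: int = 80  # per run/block
    morph_duration: float = 2.0  # 1 s visible morph + 1 s imagination
    choice_duration: float = 2.5
    iti_range: tuple[float, float] = (2.0, 6.0)
    distance_range: tuple[float, float] = (0.2, 0.8)
    initial_pad: float = 10.0
    final_pad: float = 10.0
    fold: int = 6
    n_grid_voxels: int = 50
    n_distance_voxels: int = 20
    n_noise_voxels: int = 30
    grid_amplitude: float = 1.0  # ω
    grid_orientation_deg: float | None = None  # None -> drawn U[0°, 360°/f)
    phase_kappa: float = 4.0  # von Mises concentration of f·φ_v around f·φ
    morph_amplitude: float = 2.0  # baseline morph-stage response
    choice_amplitude: float = 1.5
    distance_slope: float = 2.0
    signal_offset: float = 100.0
    noise_sd: float = CALIBRATED_NOISE_SD
    ar1_coef: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_amplitude < 0:
            raise ValueError("grid amplitude ω must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise sd must be positive")
        if self.fold < 1:
            raise ValueError("fold must be >= 1")
        if self.grid_orientation_deg is not None:
            if not (0.0 <= self.grid_orientation_deg < 360.0 / self.fold):
                raise ValueError("grid orientation must lie in [0°, 360°/fold)")

    @property
    def n_voxels(self) -> int:
        return self.n_grid_voxels + self.n_distance_voxels + self.n_noise_voxels


@dataclass
class BoldRun:
    """A voxel × time BOLD matrix with repetition-time metadata."""

    data: np.ndarray
    repetition_time: float
    run: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("BoldRun.data must be a voxel × time matrix")
        if np.any(~np.isfinite(self.data)):
            raise ValueError("BoldRun.data contains non-finite values")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_scans(self) -> int:
        return self.data.shape[1]


@dataclass
class SubjectData:
    """One simulated subject: BOLD runs, trial table and ground truth."""

    runs: list[BoldRun]
    trials: pd.DataFrame  # all runs, column 'run' distinguishes
    truth: dict = field(default_factory=dict)

    def run_trials(self, run: int) -> pd.DataFrame:
        return self.trials[self.trials["run"] == run].reset_index(drop=True)


def hexadirectional_response(theta_deg, phi_deg, omega: float, fold: int = 6):
    """Directional-modulation amplitude ω·cos(f(θ−φ)); angles in degrees."""
    if fold < 1:
        raise ValueError("fold must be >= 1")
    if omega < 0:
        raise ValueError("omega must be non-negative")
    rad = np.deg2rad(np.asarray(theta_deg, dtype=float) - phi_deg)
    return omega * np.cos(fold * rad)


def _max_backward_distance(end: np.ndarray, theta: float) -> float:
    """Largest d with start = end − d·(cosθ, sinθ) still in the unit square."""
    u = np.array([np.cos(theta), np.sin(theta)])
    dmax = np.inf
    for k in range(2):
        if u[k] > 1e-12:
            dmax = min(dmax, end[k] / u[k])
        elif u[k] < -1e-12:
            dmax = min(dmax, (end[k] - 1.0) / u[k])
    return float(dmax)


def sample_recall_block(
    space: SocialSpace,
    avatars: list[Avatar],
    n_trials: int = 80,
    rng_seed: int | np.random.Generator = 0,
    config: SimConfig | None = None,
) -> pd.DataFrame:
    """Generate one recall-task block as a trial table.

    Directions are sampled one per equal-width bin of [0, 2π) (n_trials
    bins); a random half of the trials is constructed to terminate exactly
    on an avatar location (the start is back-computed from the avatar
    position); onsets follow morph → choice → jittered ITI scheduling.

    Columns: onset, duration, choice_onset, choice_duration, theta_deg,
    distance, on_avatar, correct_option, start_x, start_y, end_x, end_y.
    """
    if n_trials % 2 != 0:
        raise ValueError("n_trials must be even (half terminate on avatars)")
    cfg = config or SimConfig(n_trials=n_trials)
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    d_lo, d_hi = cfg.distance_range

    # one direction per bin, then shuffle presentation order
    bin_width = 2.0 * np.pi / n_trials
    theta = (np.arange(n_trials) + rng.uniform(size=n_trials)) * bin_width
    order = rng.permutation(n_trials)
    theta = theta[order]
    on_avatar = np.zeros(n_trials, dtype=bool)
    on_avatar[rng.choice(n_trials, size=n_trials // 2, replace=False)] = True

    avatar_pos = np.array([a.location for a in avatars])
    starts = np.zeros((n_trials, 2))
    ends = np.zeros((n_trials, 2))
    dist = np.zeros(n_trials)
    av_cycle = rng.permutation(np.resize(np.arange(len(avatars)), n_trials // 2))
    ai = 0
    for i in range(n_trials):
        th = theta[i]
        if on_avatar[i]:
            end = avatar_pos[av_cycle[ai]]
            ai += 1
            dmax = _max_backward_distance(end, th)
            if dmax <= 1e-3:
                raise RuntimeError(
                    f"no admissible distance for trial direction {np.rad2deg(th):.1f} deg"
                )
            hi = min(d_hi, 0.98 * dmax)
            lo = d_lo if d_lo < hi else 0.5 * hi
            d = rng.uniform(lo, hi)
            start = end - d * np.array([np.cos(th), np.sin(th)])
        else:
            u = np.array([np.cos(th), np.sin(th)])
            for attempt in range(200):
                d = rng.uniform(d_lo, d_hi)
                x_lo, x_hi = max(0.0, -d * u[0]), min(1.0, 1.0 - d * u[0])
                y_lo, y_hi = max(0.0, -d * u[1]), min(1.0, 1.0 - d * u[1])
                if x_lo >= x_hi or y_lo >= y_hi:
                    continue
                start = np.array([rng.uniform(x_lo, x_hi), rng.uniform(y_lo, y_hi)])
                end = start + d * u
                if np.min(np.linalg.norm(avatar_pos - end, axis=1)) > space.popout_radius:
                    break
            else:
                raise RuntimeError("could not place a non-avatar trajectory")
        starts[i], ends[i], dist[i] = start, end, d

    onsets = np.zeros(n_trials)
    choice_onsets = np.zeros(n_trials)
    t = cfg.initial_pad
    for i in range(n_trials):
        onsets[i] = t
        choice_onsets[i] = t + cfg.morph_duration
        t = choice_onsets[i] + cfg.choice_duration + rng.uniform(*cfg.iti_range)

    return pd.DataFrame(
        {
            "onset": onsets,
            "duration": cfg.morph_duration,
            "choice_onset": choice_onsets,
            "choice_duration": cfg.choice_duration,
            "theta_deg": np.rad2deg(theta) % 360.0,
            "distance": dist,
            "on_avatar": on_avatar,
            "correct_option": rng.integers(0, 3, size=n_trials),
            "start_x": starts[:, 0],
            "start_y": starts[:, 1],
            "end_x": ends[:, 0],
            "end_y": ends[:, 1],
        }
    )


def _draw_voxel_population(cfg: SimConfig, phi_true_deg: float, rng: np.random.Generator):
    kinds = np.array(
        ["grid"] * cfg.n_grid_voxels
        + ["distance"] * cfg.n_distance_voxels
        + ["noise"] * cfg.n_noise_voxels
    )
    psi = rng.vonmises(
        np.deg2rad(cfg.fold * phi_true_deg), cfg.phase_kappa, size=cfg.n_voxels
    )
    phi_v = np.rad2deg(psi) % 360.0 / cfg.fold
    phi_v[kinds != "grid"] = np.nan
    return kinds, phi_v


def simulate_run(
    trials: pd.DataFrame,
    config: SimConfig,
    voxel_kinds: np.ndarray | None = None,
    voxel_phases_deg: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    run: int = 0,
) -> BoldRun:
    """Simulate one run's voxel × time BOLD matrix from a trial table.

    The per-trial morph-stage neural amplitude of each voxel kind follows
    the closed-form signal model (see module docstring); amplitudes of
    overlapping events sum. Reproducible for a fixed generator state.
    """
    cfg = config
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if voxel_kinds is None or voxel_phases_deg is None:
        phi_true = (
            cfg.grid_orientation_deg
            if cfg.grid_orientation_deg is not None
            else rng.uniform(0.0, 360.0 / cfg.fold)
        )
        voxel_kinds, voxel_phases_deg = _draw_voxel_population(cfg, phi_true, rng)

    last = (trials["choice_onset"] + trials["choice_duration"]).max()
    n_scans = int(np.ceil((last + cfg.final_pad) / cfg.repetition_time))
    if n_scans <= 0:
        raise ValueError("run has non-positive number of scans")

    hrf = hrf_kernel()
    theta = np.deg2rad(trials["theta_deg"].to_numpy())
    d = trials["distance"].to_numpy()
    m_on = trials["onset"].to_numpy()
    m_dur = trials["duration"].to_numpy()
    c_on = trials["choice_onset"].to_numpy()
    c_dur = trials["choice_duration"].to_numpy()

    def reg(on, dur, amp):
        return make_regressor(on, dur, amp, n_scans, cfg.repetition_time, hrf)

    # shared signal components; per-voxel signals are linear combinations
    morph = reg(m_on, m_dur, 1.0)
    cos_c = reg(m_on, m_dur, np.cos(cfg.fold * theta))
    sin_c = reg(m_on, m_dur, np.sin(cfg.fold * theta))
    dist_c = reg(m_on, m_dur, d)
    choice = reg(c_on, c_dur, 1.0)

    n_vox = len(voxel_kinds)
    signal = np.full((n_vox, n_scans), cfg.signal_offset)
    for v in range(n_vox):
        kind = voxel_kinds[v]
        if kind == "grid":
            fphi = np.deg2rad(cfg.fold * voxel_phases_deg[v])
            signal[v] += (
                cfg.morph_amplitude * morph
                + cfg.grid_amplitude * (np.cos(fphi) * cos_c + np.sin(fphi) * sin_c)
                + cfg.choice_amplitude * choice
            )
        elif kind == "distance":
            signal[v] += (
                cfg.morph_amplitude * morph
                + cfg.distance_slope * dist_c
                + cfg.choice_amplitude * choice
            )
        elif kind != "noise":
            raise ValueError(f"unknown voxel kind {kind!r}")

    noise = rng.normal(0.0, cfg.noise_sd, size=(n_vox, n_scans))
    if cfg.ar1_coef:
        a = cfg.ar1_coef
        w = noise * np.sqrt(1.0 - a * a)
        noise = np.empty_like(w)
        noise[:, 0] = w[:, 0] / np.sqrt(1.0 - a * a)
        for t in range(1, n_scans):
            noise[:, t] = a * noise[:, t - 1] + w[:, t]
    return BoldRun(signal + noise, cfg.repetition_time, run=run)


def simulate_subject(config: SimConfig | None = None, seed: int | None = None) -> SubjectData:
    """Simulate a full subject: avatar layout, 4 run blocks and BOLD runs.

    Ground truth (true orientation, voxel kinds, per-voxel phases, avatar
    layout) is recorded in ``SubjectData.truth``.
    """
    cfg = config or SimConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    root = np.random.SeedSequence(cfg.seed)
    ss = root.spawn(2 + cfg.n_runs)
    rng_layout = np.random.default_rng(ss[0])
    space = SocialSpace()
    avatars = sample_avatar_layout(space, rng_layout)

    rng_vox = np.random.default_rng(ss[1])
    phi_true = (
        cfg.grid_orientation_deg
        if cfg.grid_orientation_deg is not None
        else float(rng_vox.uniform(0.0, 360.0 / cfg.fold))
    )
    kinds, phi_v = _draw_voxel_population(cfg, phi_true, rng_vox)

    runs: list[BoldRun] = []
    tables: list[pd.DataFrame] = []
    for r in range(cfg.n_runs):
        rng_run = np.random.default_rng(ss[2 + r])
        block = sample_recall_block(space, avatars, cfg.n_trials, rng_run, cfg)
        block.insert(0, "run", r)
        runs.append(simulate_run(block, cfg, kinds, phi_v, rng_run, run=r))
        tables.append(block)
    trials = pd.concat(tables, ignore_index=True)
    truth = {
        "phi_true_deg": float(phi_true),
        "fold": cfg.fold,
        "voxel_kinds": kinds,
        "voxel_phases_deg": phi_v,
        "avatars": avatars,
        "space": space,
        "config": cfg,
    }
    return SubjectData(runs, trials, truth)


def simulate_trial_patterns(
    n_runs: int = 4,
    n_trials: int = 80,
    n_voxels: int = 50,
    omega: float = 1.0,
    phi_deg: float | None = None,
    fold: int = 6,
    phase_kappa: float = 4.0,
    baseline_sd: float = 1.0,
    noise_sd: float = 1.0,
    rng_seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Generatively hexadirectional trial × voxel patterns.

    Pattern of trial i in voxel v: baseline_v + ω·cos(f(θ_i − φ_v)) + ε,
    with per-voxel phases φ_v von Mises around φ (concentration
    ``phase_kappa`` on the folded angle) and white pattern noise of sd
    ``noise_sd`` — the direct pattern-level counterpart of the BOLD
    signal model, for validating the representational-similarity tests.

    Returns (patterns, trial metadata with run and theta_deg columns).
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    if phi_deg is None:
        phi_deg = float(rng.uniform(0.0, 360.0 / fold))
    psi_v = rng.vonmises(np.deg2rad(fold * phi_deg), phase_kappa, size=n_voxels)
    bin_width = 360.0 / n_trials
    theta, runs = [], []
    for r in range(n_runs):
        t = (np.arange(n_trials) + rng.uniform(size=n_trials)) * bin_width
        theta.append(rng.permutation(t))
        runs.append(np.full(n_trials, r))
    theta = np.concatenate(theta)
    runs = np.concatenate(runs)
    baseline = rng.normal(0.0, baseline_sd, size=n_voxels)
    signal = omega * np.cos(
        fold * np.deg2rad(theta)[:, None] - psi_v[None, :]
    )
    noise = rng.normal(0.0, noise_sd, size=(len(theta), n_voxels))
    patterns = baseline[None, :] + signal + noise
    meta = pd.DataFrame({"run": runs, "theta_deg": theta})
    meta.attrs["phi_true_deg"] = phi_deg
    return patterns, meta


def simulate_behavior(
    avatars: list[Avatar],
    rt_slope: float = 0.5,
    acc_slope: float = 5.0,
    rt_intercept: float = 0.3,
    acc_intercept: float = 0.5,
    rt_noise_sd: float = 0.1,
    n_explore: int = 2000,
    explore_avatar_weight: float = 0.4,
    n_collect: int = 30,
    collect_angle_sd_deg: float = 5.0,
    collect_response_sd: float = 0.005,
    collect_mean_transitions: float = 2.0,
    n_compare_reps: int = 4,
    investment: float = 1.0,
    n_recall: int = 80,
    p_recall_correct: float = 0.85,
    space: SocialSpace | None = None,
    rng_seed: int | np.random.Generator = 0,
) -> dict[str, pd.DataFrame]:
    """Generate one participant's behavioral tables.

    Returns a dict with keys ``explore`` (location samples drawn from a
    mixture concentrated at avatars vs uniform over the map), ``collect``
    (first-transition direction, final response, transition count),
    ``compare`` (per-pair accuracy and response time with
    log RT = intercept − slope·distance + noise and accuracy logistic in
    the task-relevant distance), and ``recall`` (correct/incorrect
    responses).
    """
    if rt_noise_sd <= 0:
        raise ValueError("noise sd must be positive")
    if not np.isfinite(rt_slope) or not np.isfinite(acc_slope):
        raise ValueError("slopes must be finite")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    space = space or SocialSpace()
    pos = np.array([a.location for a in avatars])

    # --- explore: mixture of at-avatar and uniform samples -----------------
    at_avatar = rng.uniform(size=n_explore) < explore_avatar_weight
    idx = rng.integers(0, len(avatars), size=n_explore)
    ang = rng.uniform(0, 2 * np.pi, size=n_explore)
    rad = space.popout_radius * 0.99 * np.sqrt(rng.uniform(size=n_explore))
    near = pos[idx] + np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
    uni = rng.uniform(0, 1, size=(n_explore, 2))
    xy = np.where(at_avatar[:, None], near, uni)
    xy = np.clip(xy, 0.0, 1.0)
    explore = pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1]})

    # --- collect -----------------------------------------------------------
    targets = np.resize(np.arange(len(avatars)), n_collect)
    rows = []
    for t in targets:
        target = pos[t]
        start = rng.uniform(0.05, 0.95, size=2)
        ideal = np.rad2deg(np.arctan2(target[1] - start[1], target[0] - start[0]))
        first = ideal + rng.normal(0.0, collect_angle_sd_deg)
        resp = np.clip(target + rng.normal(0.0, collect_response_sd, size=2), 0, 1)
        rows.append(
            {
                "target": t,
                "start_x": start[0],
                "start_y": start[1],
                "first_transition_deg": first % 360.0,
                "response_x": resp[0],
                "response_y": resp[1],
                "n_transitions": 1 + rng.poisson(max(collect_mean_transitions - 1, 0.0)),
            }
        )
    collect = pd.DataFrame(rows)

    # --- compare -----------------------------------------------------------
    pairs = [(i, j) for i in range(len(avatars)) for j in range(i + 1, len(avatars))]
    rows = []
    for block in ("competence", "trustworthiness", "cooperation"):
        for i, j in pairs:
            if block == "competence":
                dist = abs(avatars[i].competence - avatars[j].competence)
            elif block == "trustworthiness":
                dist = abs(avatars[i].trustworthiness - avatars[j].trustworthiness)
            else:
                dist = abs(
                    expected_profit(investment, avatars[i].competence, avatars[i].trustworthiness)
                    - expected_profit(investment, avatars[j].competence, avatars[j].trustworthiness)
                )
            for _ in range(n_compare_reps):
                log_rt = rt_intercept - rt_slope * dist + rng.normal(0.0, rt_noise_sd)
                p_acc = 1.0 / (1.0 + np.exp(-(acc_intercept + acc_slope * dist)))
                rows.append(
                    {
                        "block": block,
                        "pair_i": i,
                        "pair_j": j,
                        "distance": dist,
                        "log_rt": log_rt,
                        "rt": float(np.exp(log_rt)),
                        "accuracy": int(rng.uniform() < p_acc),
                    }
                )
    compare = pd.DataFrame(rows)

    # --- recall ------------------------------------------------------------
    recall = pd.DataFrame(
        {"correct": (rng.uniform(size=n_recall) < p_recall_correct).astype(int)}
    )
    return {"explore": explore, "collect": collect, "compare": compare, "recall": recall}
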