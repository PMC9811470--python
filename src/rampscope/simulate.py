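"""Synthetic L-maze sessions with known ground truth.

Forward model, in order:

1. a trajectory on the linearized maze path (alternating left/right trials,
   smooth speed jitter, pauses at the wells, optional turn-back trials),
   with the five ground-truth event markers recorded during generation;
2. a population of neurons with assigned tuning classes whose firing rates
   are functions of movement phase, position, speed, and session incline;
3. inhomogeneous-Poisson spikes, convolved with a fast-rise / slow-decay
   calcium-indicator kernel plus Gaussian noise to give ΔF/F₀ traces;
4. a rendered one-photon movie: small round interneuron footprints and large
   striped Purkinje-cell footprints on a background with vessel shadows.

Every stage takes an explicit seed and is bit-reproducible; nothing touches
global random state.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .behavior import PhaseThresholds, label_phases
from .extraction import FluorMovie
from .maze import MazeModel

logger = logging.getLogger(__name__)

CELL_CLASSES = (
    "uphill",
    "downhill",
    "both",
    "flat",
    "quiescent",
    "phase_change_pre_up",
    "phase_change_post_up",
    "phase_change_peak",
    "phase_change_post_down",
    "reward",
    "speed_coupled",
    "pc_like",
)

__all__ = [
    "SimConfig",
    "GroundTruthPopulation",
    "CELL_CLASSES",
    "make_population",
    "simulate_trajectory",
    "simulate_rates_and_spikes",
    "spikes_to_fluorescence",
    "kernel_peak_time",
    "kernel_peak_factor",
    "make_background",
    "render_movie",
    "default_sim_thresholds",
    "simulate_session",
]


@dataclass(frozen=True)
class SimConfig:
    """Session-level simulation parameters.

    Defaults encode the study conditions: 30-Hz acquisition, 16.7 cm/s
    (10 m/min) mean running speed, and a GCaMP6s-like transient kernel
    (0.1-s rise, 1.0-s decay).
    """

    n_trials: int = 20
    frame_rate: float = 30.0          # Hz
    mean_run_speed: float = 16.7      # cm/s
    pause_duration: float = 3.0       # s at the well (consumption + turn)
    speed_jitter: float = 0.15        # relative SD of the smoothed speed noise
    jitter_smooth_s: float = 0.3      # temporal smoothing of the speed noise
    uphill_speed_factor: float = 0.65   # climbing is slower than level walking
    downhill_speed_factor: float = 0.85  # descending slightly slower too
    incomplete_fraction: float = 0.0  # probability a trial turns back mid-maze
    base_event_rate: float = 0.3      # events/s outside the preferred condition
    phase_gain: float = 5.0           # rate multiplier in the preferred condition
    incline_gain: float = 0.0         # signed modulation of gain vs session angle
    kernel_rise_tau: float = 0.1      # s
    kernel_decay_tau: float = 1.0     # s
    transient_amplitude: float = 1.0  # kernel multiplier, ΔF/F0 units
    noise_sd: float = 0.05            # trace noise SD, ΔF/F0 units
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.mean_run_speed <= 0:
            raise ValueError("mean_run_speed must be positive")
        if self.kernel_rise_tau <= 0 or self.kernel_decay_tau <= 0:
            raise ValueError("kernel taus must be positive")
        if self.kernel_rise_tau >= self.kernel_decay_tau:
            raise ValueError("kernel_rise_tau must be smaller than kernel_decay_tau")
        if self.base_event_rate < 0 or self.noise_sd < 0:
            raise ValueError("rates and noise must be non-negative")
        if self.n_trials < 0:
            raise ValueError("n_trials must be non-negative")
        if self.uphill_speed_factor <= 0 or self.downhill_speed_factor <= 0:
            raise ValueError("speed factors must be positive")


@dataclass
class GroundTruthPopulation:
    """Ground-truth neurons: tuning class, gain, and footprint geometry."""

    classes: list[str]
    gains: np.ndarray                  # per-neuron rate multiplier
    centers: np.ndarray                # (n, 2) pixel coordinates (row, col)
    shapes: list[str]                  # 'round_small' | 'striped_large'
    angles: np.ndarray                 # stripe orientation, radians (PC only)
    frame_shape: tuple[int, int]
    pixel_size: float = 1.3            # µm/px of the rendered movie

    def __post_init__(self) -> None:
        for c in self.classes:
            if c not in CELL_CLASSES:
                raise ValueError(f"unknown cell class {c!r}")
        h, w = self.frame_shape
        if np.any(self.centers < 0) or np.any(self.centers[:, 0] >= h) or np.any(
            self.centers[:, 1] >= w
        ):
            raise ValueError("footprint center outside frame bounds")

    @property
    def n(self) -> int:
        return len(self.classes)


def make_population(
    counts: dict[str, int],
    frame_shape: tuple[int, int] = (64, 64),
    pixel_size: float = 1.3,
    seed: int = 0,
    gain: float | dict[str, float] = 5.0,
    min_separation_px: float = 0.0,
    margin_px: int = 6,
) -> GroundTruthPopulation:
    """Build a ground-truth population with random footprint centers.

    ``counts`` maps class names to neuron counts.  With
    ``min_separation_px > 0`` centers are rejection-sampled to be pairwise
    separated (used for spatially disjoint planted sources).
    """
    rng = np.random.default_rng(seed)
    classes: list[str] = []
    gains: list[float] = []
    for cls, cnt in counts.items():
        if cls not in CELL_CLASSES:
            raise ValueError(f"unknown cell class {cls!r}")
        g = gain[cls] if isinstance(gain, dict) else gain
        classes.extend([cls] * cnt)
        gains.extend([g] * cnt)

    h, w = frame_shape
    centers: list[tuple[int, int]] = []
    for _ in classes:
        for _try in range(10_000):
            r = int(rng.integers(margin_px, h - margin_px))
            c = int(rng.integers(margin_px, w - margin_px))
            if not centers or min_separation_px <= 0:
                break
            d = np.hypot(
                np.array([p[0] for p in centers]) - r,
                np.array([p[1] for p in centers]) - c,
            )
            if d.min() >= min_separation_px:
                break
        else:
            raise ValueError("could not place footprints with the requested separation")
        centers.append((r, c))

    shapes = ["striped_large" if c == "pc_like" else "round_small" for c in classes]
    angles = rng.uniform(0, math.pi, size=len(classes))
    return GroundTruthPopulation(
        classes=classes,
        gains=np.asarray(gains, dtype=float),
        centers=np.asarray(centers, dtype=int).reshape(-1, 2),
        shapes=shapes,
        angles=angles,
        frame_shape=frame_shape,
        pixel_size=pixel_size,
    )


# ---------------------------------------------------------------------------
# Trajectory
# ---------------------------------------------------------------------------

def simulate_trajectory(
    maze: MazeModel,
    config: SimConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a session of alternating left/right trials.

    Returns ``(track, trials)``: the behavior track (``t_s, x_cm, y_cm,
    path_cm, arm``) and the ground-truth trial table with the five marker
    times per trial (markers other than the start are NaN for turn-back
    trials).  The mouse starts resting at the horizontal-arm well, so the
    first trial runs left.
    """
    if seed is None:
        seed = config.rng_seed
    rng = np.random.default_rng(seed)
    fr = config.frame_rate
    dt = 1.0 / fr
    total = maze.total_path_length
    n_pause = int(round(config.pause_duration * fr))

    path_frames: list[float] = []
    rows: list[dict] = []

    pos = 0.0  # start at the horizontal-arm well
    path_frames.extend([pos] * max(n_pause, 1))

    sigma_frames = max(config.jitter_smooth_s * fr, 1e-6)

    for trial_id in range(config.n_trials):
        direction = "left" if pos < total / 2 else "right"
        sign = 1.0 if direction == "left" else -1.0
        target = total if direction == "left" else 0.0
        turn_back = rng.random() < config.incomplete_fraction
        turn_at = np.nan
        if turn_back:
            lo, hi = sorted([pos + sign * 2.0, maze.apex_path - sign * 1.0])
            turn_at = rng.uniform(lo, hi)

        # Smooth multiplicative speed jitter for this trial.
        est = int(3 * total / config.mean_run_speed * fr) + 200
        if config.speed_jitter > 0:
            noise = gaussian_filter1d(rng.standard_normal(est), sigma_frames)
            noise *= config.speed_jitter / max(noise.std(), 1e-12)
        else:
            noise = np.zeros(est)

        markers = dict(
            trial_id=trial_id,
            direction=direction,
            t_trial_start=len(path_frames) * dt,
            t_up_start=np.nan,
            t_peak=np.nan,
            t_down_end=np.nan,
            t_reward=np.nan,
            complete=not turn_back,
        )
        cur_sign = sign
        prev = pos
        for k in range(est):
            v = config.mean_run_speed * max(1.0 + noise[k], 0.05)
            # Slower on the ramp: the slope being climbed depends on heading.
            if maze.ramp_path_start <= prev < maze.ramp_path_end:
                below_apex = prev < maze.apex_path
                climbing = below_apex if cur_sign > 0 else not below_apex
                v *= (config.uphill_speed_factor if climbing
                      else config.downhill_speed_factor)
            pos = float(np.clip(prev + cur_sign * v * dt, 0.0, total))
            path_frames.append(pos)
            t_now = (len(path_frames) - 1) * dt
            if not turn_back:
                _record_crossings(markers, prev, pos, sign, maze, t_now,
                                  total, config, rz=1.0)
                if (direction == "left" and pos >= total) or (
                    direction == "right" and pos <= 0.0
                ):
                    break
            else:
                if cur_sign == sign and (pos - turn_at) * sign >= 0:
                    cur_sign = -sign  # turn around mid-maze
                elif cur_sign == -sign and (
                    (sign > 0 and pos <= 0.0) or (sign < 0 and pos >= total)
                ):
                    break
            prev = pos
        else:
            raise RuntimeError("trial did not terminate; check speed configuration")

        rows.append(markers)
        path_frames.extend([pos] * n_pause)

    path = np.asarray(path_frames, dtype=float)
    if config.n_trials == 0:
        path = np.asarray([], dtype=float)
    t = np.arange(len(path)) * dt
    if len(path):
        x, y = maze.path_to_xy(path)
        arm = maze.arm_of_path(path)
    else:
        x = y = np.asarray([], dtype=float)
        arm = np.asarray([], dtype="<U10")
    track = pd.DataFrame({"t_s": t, "x_cm": x, "y_cm": y, "path_cm": path, "arm": arm})
    trials = pd.DataFrame(
        rows,
        columns=[
            "trial_id", "direction", "t_trial_start", "t_up_start",
            "t_peak", "t_down_end", "t_reward", "complete",
        ],
    )
    return track, trials


def _record_crossings(markers, prev, pos, sign, maze, t_now, total, config, rz):
    """Record ramp/reward marker times when the path crosses a landmark."""
    def crossed(level):
        return (prev - level) * sign < 0 <= (pos - level) * sign

    if sign > 0:  # left trial: path increasing
        if np.isnan(markers["t_up_start"]) and crossed(maze.ramp_path_start):
            markers["t_up_start"] = t_now
        if np.isnan(markers["t_peak"]) and crossed(maze.apex_path):
            markers["t_peak"] = t_now
        if np.isnan(markers["t_down_end"]) and crossed(maze.ramp_path_end):
            markers["t_down_end"] = t_now
        if np.isnan(markers["t_reward"]) and crossed(total - rz):
            markers["t_reward"] = t_now
    else:  # right trial: path decreasing
        if np.isnan(markers["t_up_start"]) and crossed(maze.ramp_path_end):
            markers["t_up_start"] = t_now
        if np.isnan(markers["t_peak"]) and crossed(maze.apex_path):
            markers["t_peak"] = t_now
        if np.isnan(markers["t_down_end"]) and crossed(maze.ramp_path_start):
            markers["t_down_end"] = t_now
        if np.isnan(markers["t_reward"]) and crossed(rz):
            markers["t_reward"] = t_now


# ---------------------------------------------------------------------------
# Rates and spikes
# ---------------------------------------------------------------------------

def incline_factor(incline_deg: float | None, incline_gain: float) -> float:
    """Multiplicative gain modulation for a session's ramp angle.

    Linear in the angle, anchored at 1.0 for the 45° standard configuration
    and scaled so the 15°–45° range spans ``incline_gain`` in units of the
    gain: factor = 1 + incline_gain * (angle − 45)/30, clipped at 0.
    """
    if incline_deg is None or incline_gain == 0:
        return 1.0
    return max(0.0, 1.0 + incline_gain * (incline_deg - 45.0) / 30.0)


def _transition_frames(phases: np.ndarray) -> dict[str, np.ndarray]:
    p = np.asarray(phases)
    up = (p == "uphill").astype(int)
    down = (p == "downhill").astype(int)
    up_starts = np.flatnonzero(np.diff(up) == 1) + 1
    peaks = np.flatnonzero((np.diff(up) == -1) & (np.diff(down) == 1)) + 1
    down_ends = np.flatnonzero(np.diff(down) == -1) + 1
    return {"up_start": up_starts, "peak": peaks, "down_end": down_ends}


def simulate_rates_and_spikes(
    pop: GroundTruthPopulation,
    phases: np.ndarray,
    speed: np.ndarray,
    config: SimConfig,
    seed: int | None = None,
    trials: pd.DataFrame | None = None,
    incline_deg: float | None = None,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Inhomogeneous-Poisson spikes from each neuron's class rate function.

    Returns ``(spike_times, rates)``: per-neuron sorted spike-time arrays (s)
    and the underlying (n, T) rate series in events/s.  Phase-tuned classes
    elevate their rate by the neuron's gain only in the matching frames;
    phase-change classes in short (0.5-s) windows around the matching phase
    transitions; speed-coupled neurons scale linearly with speed.
    """
    if len(phases) != len(speed):
        raise ValueError("phases and speed must share the time base")
    fr = config.frame_rate
    dt = 1.0 / fr
    T = len(phases)
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    trans = _transition_frames(phases)
    half_win = int(round(0.25 * fr))
    win = int(round(0.5 * fr))
    ifac = incline_factor(incline_deg, config.incline_gain)

    reward_frames = np.asarray([], dtype=int)
    if trials is not None and len(trials):
        comp = trials[trials["complete"].astype(bool)]
        reward_frames = np.round(comp["t_reward"].to_numpy(float) * fr).astype(int)

    phase_masks = {
        "uphill": phases == "uphill",
        "downhill": phases == "downhill",
        "flat": phases == "flat",
        "quiescent": phases == "quiescent",
    }

    def window_mask(frames: np.ndarray, lo: int, hi: int) -> np.ndarray:
        m = np.zeros(T, dtype=bool)
        for f in frames:
            m[max(0, f + lo): min(T, f + hi)] = True
        return m

    rates = np.empty((pop.n, T), dtype=float)
    spikes: list[np.ndarray] = []
    warned = False
    for i, (cls, g) in enumerate(zip(pop.classes, pop.gains)):
        rate = np.full(T, config.base_event_rate)
        if cls in ("uphill", "downhill", "flat", "quiescent"):
            mask = phase_masks[cls]
        elif cls == "both":
            mask = phase_masks["uphill"] | phase_masks["downhill"]
        elif cls == "pc_like":
            mask = phase_masks["quiescent"]
        elif cls == "phase_change_pre_up":
            mask = window_mask(trans["up_start"], -win, 0)
        elif cls == "phase_change_post_up":
            mask = window_mask(trans["up_start"], 0, win)
        elif cls == "phase_change_peak":
            mask = window_mask(trans["peak"], -half_win, half_win)
        elif cls == "phase_change_post_down":
            mask = window_mask(trans["down_end"], 0, win)
        elif cls == "reward":
            if trials is None:
                raise ValueError("reward-tuned neurons need the trial table")
            mask = window_mask(reward_frames, 0, int(round(fr)))
        elif cls == "speed_coupled":
            rate = config.base_event_rate * (
                1.0 + (g - 1.0) * np.asarray(speed) / config.mean_run_speed
            )
            mask = None
        else:  # pragma: no cover - guarded by GroundTruthPopulation
            raise ValueError(f"unknown cell class {cls!r}")
        if mask is not None:
            rate = np.where(mask, config.base_event_rate * g * ifac, rate)
        if np.any(rate < 0):
            if not warned:
                logger.warning("negative rates clipped to 0")
                warned = True
            rate = np.clip(rate, 0.0, None)
        rates[i] = rate
        counts = rng.poisson(rate * dt)
        times = np.repeat(np.arange(T) * dt, counts) + rng.uniform(
            0, dt, size=int(counts.sum())
        )
        spikes.append(np.sort(times))
    return spikes, rates


# ---------------------------------------------------------------------------
# Fluorescence forward model
# ---------------------------------------------------------------------------

def kernel_peak_time(rise_tau: float, decay_tau: float) -> float:
    """Closed-form argmax of the double-exponential kernel, seconds."""
    return rise_tau * math.log(1.0 + decay_tau / rise_tau)

def kernel_peak_factor(rise_tau: float, decay_tau: float) -> float:
    """Kernel value at its peak for a unit amplitude multiplier."""
    tp = kernel_peak_time(rise_tau, decay_tau)
    return (1.0 - math.exp(-tp / rise_tau)) * math.exp(-tp / decay_tau)


def spikes_to_fluorescence(
    spike_times: np.ndarray,
    n_frames: int,
    config: SimConfig,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """ΔF/F₀ trace from a spike train via the calcium-indicator kernel.

    Each spike adds ``A·(1 − e^(−t/τ_rise))·e^(−t/τ_decay)`` for t past the
    spike time (linear superposition).  Returns ``(noisy, clean)`` traces;
    the clean trace is the ground truth before Gaussian noise.
    """
    fr = config.frame_rate
    dt = 1.0 / fr
    tau_r, tau_d = config.kernel_rise_tau, config.kernel_decay_tau
    support = int(math.ceil((tau_r + 6.0 * tau_d) * fr))
    clean = np.zeros(n_frames, dtype=float)
    t_grid = np.arange(support) * dt
    for ts in np.asarray(spike_times, dtype=float):
        i0 = int(math.ceil(ts * fr))
        if i0 >= n_frames:
            continue
        offs = t_grid[: n_frames - i0] + (i0 * dt - ts)
        clean[i0: i0 + len(offs)] += config.transient_amplitude * (
            1.0 - np.exp(-offs / tau_r)
        ) * np.exp(-offs / tau_d)
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.rng_seed if seed is None else seed)
        noisy = clean + rng.normal(0.0, config.noise_sd, size=n_frames)
    else:
        noisy = clean.copy()
    return noisy, clean


# ---------------------------------------------------------------------------
# Movie rendering
# ---------------------------------------------------------------------------

def make_background(
    frame_shape: tuple[int, int],
    seed: int = 0,
    base_level: float = 100.0,
    n_vessels: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Static background with smooth intensity structure and vessel shadows.

    Returns ``(background, vessel_mask)``; vessels are dark meandering lines
    (50% attenuation), mimicking the shadows cast by surface blood vessels.
    """
    rng = np.random.default_rng(seed)
    h, w = frame_shape
    bg = base_level + 10.0 * gaussian_filter(rng.standard_normal((h, w)), 6.0)
    vessel = np.zeros((h, w), dtype=bool)
    for _ in range(n_vessels):
        row = float(rng.uniform(0.2 * h, 0.8 * h))
        drift = gaussian_filter1d(rng.standard_normal(w), 8.0) * 6.0
        for c in range(w):
            r = int(round(row + drift[c]))
            vessel[max(0, r - 1): min(h, r + 2), c] = True
    bg = np.where(vessel, 0.5 * bg, bg)
    return bg, vessel


def _footprint(
    shape: str, center: tuple[int, int], frame_shape: tuple[int, int],
    angle: float, mli_sigma_px: float, pc_sigma_px: tuple[float, float],
) -> np.ndarray:
    h, w = frame_shape
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    dr, dc = rr - center[0], cc - center[1]
    if shape == "round_small":
        fp = np.exp(-(dr**2 + dc**2) / (2.0 * mli_sigma_px**2))
    elif shape == "striped_large":
        u = dr * math.cos(angle) + dc * math.sin(angle)
        v = -dr * math.sin(angle) + dc * math.cos(angle)
        sa, sb = pc_sigma_px
        fp = np.exp(-(u**2) / (2 * sa**2) - (v**2) / (2 * sb**2))
    else:
        raise ValueError(f"unknown footprint shape {shape!r}")
    fp[fp < 1e-4] = 0.0
    return fp


def render_movie(
    pop: GroundTruthPopulation,
    traces: np.ndarray,
    background: np.ndarray | None = None,
    seed: int = 0,
    pixel_noise_sd: float = 1.0,
    amplitude_scale: float = 50.0,
    mli_sigma_px: float = 2.0,
    pc_sigma_px: tuple[float, float] = (8.0, 1.2),
) -> tuple[FluorMovie, np.ndarray, np.ndarray]:
    """Render a movie: background + Σ footprint·trace + pixel noise.

    ``traces`` is (n, T) in ΔF/F₀ units; ``amplitude_scale`` converts trace
    units to camera counts.  Returns ``(movie, vessel_mask, footprints)``;
    the vessel mask and the (n, H, W) ground-truth footprints feed QC tests.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if traces.shape[0] != pop.n:
        raise ValueError("traces row count must match the population size")
    rng = np.random.default_rng(seed)
    if background is None:
        background, vessel = make_background(pop.frame_shape, seed=seed)
    else:
        vessel = np.zeros(pop.frame_shape, dtype=bool)
    if background.shape != pop.frame_shape:
        raise ValueError("background shape must match the population frame shape")

    fps = np.stack(
        [
            _footprint(s, tuple(c), pop.frame_shape, a, mli_sigma_px, pc_sigma_px)
            for s, c, a in zip(pop.shapes, pop.centers, pop.angles)
        ]
    )
    movie = np.tensordot(traces.T, fps, axes=1) * amplitude_scale
    movie += background[None, :, :]
    if pixel_noise_sd > 0:
        movie += rng.normal(0.0, pixel_noise_sd, size=movie.shape)
    movie = np.clip(movie, 0.0, None).astype(np.float32)
    return (
        FluorMovie(frames=movie, frame_rate=30.0, pixel_size=pop.pixel_size),
        vessel,
        fps,
    )


# ---------------------------------------------------------------------------
# Convenience: a full synthetic session
# ---------------------------------------------------------------------------

def default_sim_thresholds(config: SimConfig) -> PhaseThresholds:
    """Phase thresholds matched to a simulated session's speed scale.

    The locomotion-onset threshold is set to 30% of the configured mean run
    speed so trial-start detection fires on simulated accelerations.
    """
    return PhaseThresholds(locomotion_onset_cms=0.3 * config.mean_run_speed)


@dataclass
class SyntheticSession:
    """Bundle of a fully simulated session and its ground truth."""

    maze: MazeModel
    config: SimConfig
    track: pd.DataFrame
    trials: pd.DataFrame
    phases: np.ndarray
    speed: np.ndarray
    population: GroundTruthPopulation
    spikes: list[np.ndarray]
    rates: np.ndarray
    traces: np.ndarray          # (n, T) noisy ΔF/F0
    clean_traces: np.ndarray    # (n, T) noiseless ground truth
    thresholds: PhaseThresholds = field(default_factory=PhaseThresholds)


def simulate_session(
    maze: MazeModel,
    config: SimConfig,
    counts: dict[str, int],
    seed: int = 0,
    incline_deg: float | None = None,
    thresholds: PhaseThresholds | None = None,
) -> SyntheticSession:
    """Run the full forward model through fluorescence traces.

    Seeds for the trajectory, population, spiking, and trace noise are all
    derived from ``seed`` through independent fixed offsets.
    """
    from .behavior import compute_speed

    if thresholds is None:
        thresholds = default_sim_thresholds(config)
    track, trials = simulate_trajectory(maze, config, seed=seed)
    speed = compute_speed(track)
    phases = label_phases(track, trials, maze, thresholds, speed=speed)
    pop = make_population(counts, seed=seed + 1, gain=config.phase_gain)
    spikes, rates = simulate_rates_and_spikes(
        pop, phases, speed, config, seed=seed + 2, trials=trials,
        incline_deg=incline_deg,
    )
    T = len(track)
    traces = np.empty((pop.n, T))
    clean = np.empty((pop.n, T))
    for i, st in enumerate(spikes):
        traces[i], clean[i] = spikes_to_fluorescence(
            st, T, config, seed=seed + 10_000 + i
        )
    return SyntheticSession(
        maze=maze, config=config, track=track, trials=trials, phases=phases,
        speed=speed, population=pop, spikes=spikes, rates=rates,
        traces=traces, clean_traces=clean, thresholds=thresholds,
    )
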