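"""Behavioral preprocessing: speed, trial events, movement phases, spatial bins.

Positions arrive as a *behavior track* — a :class:`pandas.DataFrame` with
columns ``t_s`` (uniformly sampled time), ``x_cm``, ``y_cm`` (top view) and
``path_cm`` (linearized coordinate along the maze, see :mod:`rampscope.maze`).

A session decomposes into trials bounded by visits to the two food wells.
Five event markers describe each complete trial, in strict temporal order:
trial start (locomotion onset after turning), uphill start (entering the ramp),
peak (apex crossing), downhill end (leaving the ramp), and reward (arrival at
the opposite well).  Trials where the animal turns back mid-maze are flagged
incomplete and excluded from every downstream computation.

Movement phases per frame:

- ``uphill``    — between uphill start and peak of a complete trial;
- ``downhill``  — between peak and downhill end;
- ``flat``      — moving on the vertical arm (flat walking is scored only
  there, to keep it uncontaminated by ramp approach/departure);
- ``quiescent`` — still period between the end of reward consumption and the
  next trial start;
- ``other``     — everything else (turning, reward consumption, horizontal
  flat segments).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .maze import MazeModel

logger = logging.getLogger(__name__)

PHASES = ("uphill", "downhill", "flat", "quiescent", "other")

__all__ = [
    "PhaseThresholds",
    "SpatialBinning",
    "compute_speed",
    "detect_trial_events",
    "label_phases",
    "linearize_and_bin",
    "assign_windows",
    "window_roles",
    "trial_direction_per_frame",
    "PHASES",
]


@dataclass(frozen=True)
class PhaseThresholds:
    """Thresholds for event detection and phase labeling.

    Notes
    -----
    ``locomotion_onset_cms`` defaults to 30 cm/s (0.3 m/s) and
    ``quiescence_cms`` to 0.5 cm/s (0.3 m/min).  The two defaults come from
    differently-unitted conventions (m/s vs m/min) and are deliberately kept
    as independent keys; see docs/methods.md for the discussion.  Sessions
    whose running speeds never reach 30 cm/s need a lower onset threshold for
    trial-start detection to fire.
    """

    locomotion_onset_cms: float = 30.0
    quiescence_cms: float = 0.5
    reward_zone_cm: float = 1.0      # food wells sit 1 cm from the arm ends
    reward_duration_s: float = 1.0   # consumption window after reward arrival


def compute_speed(track: pd.DataFrame, smooth_win: float = 0.2) -> np.ndarray:
    """Path speed in cm/s: central differences, boxcar-smoothed.

    Parameters
    ----------
    track : DataFrame
        Behavior track with ``t_s`` and ``path_cm`` columns.
    smooth_win : float
        Boxcar window in seconds; edges are padded with the nearest value.
    """
    if len(track) < 2:
        raise ValueError("need at least 2 samples to compute speed")
    t = track["t_s"].to_numpy(float)
    path = track["path_cm"].to_numpy(float)
    speed = np.abs(np.gradient(path, t))
    dt = float(np.median(np.diff(t)))
    win = max(1, int(round(smooth_win / dt)))
    if win > 1:
        padded = np.concatenate(
            [np.full(win, speed[0]), speed, np.full(win, speed[-1])]
        )
        kernel = np.ones(win) / win
        speed = np.convolve(padded, kernel, mode="same")[win:-win]
    return speed


def _first_crossing(path: np.ndarray, idx: np.ndarray, level: float, rising: bool) -> int | None:
    """First frame (absolute index) in `idx` where path crosses `level`."""
    vals = path[idx]
    hit = vals >= level if rising else vals <= level
    if not hit.any():
        return None
    return int(idx[int(np.argmax(hit))])


def detect_trial_events(
    track: pd.DataFrame,
    speed: np.ndarray,
    maze: MazeModel,
    thresholds: PhaseThresholds = PhaseThresholds(),
) -> pd.DataFrame:
    """Segment a session into trials and locate the five event markers.

    A trial is an excursion between the two reward zones (the final
    ``reward_zone_cm`` of each arm).  Returns one row per excursion with
    columns ``trial_id, direction, t_trial_start, t_up_start, t_peak,
    t_down_end, t_reward, complete``.  Excursions that return to the starting
    zone are incomplete: marker times other than the trial start are NaN.
    """
    t = track["t_s"].to_numpy(float)
    path = track["path_cm"].to_numpy(float)
    n = len(track)
    total = maze.total_path_length
    rz = thresholds.reward_zone_cm

    zone = np.zeros(n, dtype=int)  # 0 none, 1 horizontal well, 2 vertical well
    zone[path <= rz] = 1
    zone[path >= total - rz] = 2

    rows = []
    if n == 0 or not (zone != 0).any():
        logger.warning("track never reaches a reward zone; returning empty trial table")
        return _empty_trial_table()

    vel = np.gradient(path, t) if n > 1 else np.zeros(n)

    # Runs of in-zone frames; excursions live between consecutive zone runs.
    in_zone = zone != 0
    changes = np.flatnonzero(np.diff(in_zone.astype(int)))
    starts = [0] + (changes + 1).tolist()
    ends = changes.tolist() + [n - 1]
    runs = [(s, e, zone[s]) for s, e in zip(starts, ends) if in_zone[s]]

    trial_id = 0
    for (s0, e0, z0), (s1, _e1, z1) in zip(runs[:-1], runs[1:]):
        direction = "left" if z0 == 1 else "right"  # outbound away from z0
        complete = z1 != z0
        out_sign = 1.0 if z0 == 1 else -1.0

        # Trial start: locomotion onset in the outbound direction after the
        # previous reward (searched from the start of the resting zone run).
        search = np.arange(s0, s1)
        moving = (speed[search] > thresholds.locomotion_onset_cms) & (
            np.sign(vel[search]) == out_sign
        )
        if moving.any():
            i_start = int(search[int(np.argmax(moving))])
        else:
            i_start = e0 + 1 if e0 + 1 < n else e0
            logger.info(
                "trial %d: no frame exceeded the onset threshold; "
                "falling back to zone exit", trial_id
            )

        t_up = t_peak = t_down = t_reward = np.nan
        if complete:
            exc = np.arange(e0 + 1, s1)
            rising = direction == "left"
            if rising:
                i_up = _first_crossing(path, exc, maze.ramp_path_start, True)
                i_pk = _first_crossing(path, exc, maze.apex_path, True)
                i_dn = _first_crossing(path, exc, maze.ramp_path_end, True)
            else:
                i_up = _first_crossing(path, exc, maze.ramp_path_end, False)
                i_pk = _first_crossing(path, exc, maze.apex_path, False)
                i_dn = _first_crossing(path, exc, maze.ramp_path_start, False)
            if None in (i_up, i_pk, i_dn):
                complete = False  # never actually crossed the ramp
            else:
                t_up, t_peak, t_down = t[i_up], t[i_pk], t[i_dn]
                t_reward = t[s1]

        rows.append(
            dict(
                trial_id=trial_id,
                direction=direction,
                t_trial_start=t[i_start],
                t_up_start=t_up,
                t_peak=t_peak,
                t_down_end=t_down,
                t_reward=t_reward,
                complete=complete,
            )
        )
        trial_id += 1

    if not rows:
        logger.warning("no excursions between reward zones detected")
        return _empty_trial_table()
    return pd.DataFrame(rows)


def _empty_trial_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "trial_id",
            "direction",
            "t_trial_start",
            "t_up_start",
            "t_peak",
            "t_down_end",
            "t_reward",
            "complete",
        ]
    )


def label_phases(
    track: pd.DataFrame,
    trials: pd.DataFrame,
    maze: MazeModel,
    thresholds: PhaseThresholds = PhaseThresholds(),
    speed: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame movement-phase labels (see module docstring for definitions).

    Only complete trials contribute uphill/downhill/flat labels; the
    quiescent label fills still frames between the end of one trial's reward
    consumption and the next trial's start.
    """
    t = track["t_s"].to_numpy(float)
    path = track["path_cm"].to_numpy(float)
    if speed is None:
        speed = compute_speed(track)
    labels = np.full(len(track), "other", dtype="<U9")

    comp = trials[trials["complete"].astype(bool)].sort_values("t_trial_start")
    starts = comp["t_trial_start"].to_numpy(float)
    rewards = comp["t_reward"].to_numpy(float)
    if len(comp) > 1 and np.any(starts[1:] < rewards[:-1]):
        raise ValueError("overlapping trials")

    on_vertical = path >= maze.horizontal_path_length
    moving = speed > thresholds.quiescence_cms

    for _, tr in comp.iterrows():
        in_trial = (t >= tr.t_trial_start) & (t < tr.t_reward)
        labels[(t >= tr.t_up_start) & (t < tr.t_peak)] = "uphill"
        labels[(t >= tr.t_peak) & (t < tr.t_down_end)] = "downhill"
        labels[in_trial & on_vertical & moving & (labels == "other")] = "flat"

    # Quiescence: still frames from reward-consumption end to the next start.
    still = speed < thresholds.quiescence_cms
    bounds = []
    if len(comp):
        bounds.append((t[0], starts[0]))  # pause before the first trial
        for i in range(len(comp) - 1):
            bounds.append((rewards[i] + thresholds.reward_duration_s, starts[i + 1]))
        bounds.append((rewards[-1] + thresholds.reward_duration_s, t[-1] + 1e-9))
    for lo, hi in bounds:
        sel = (t >= lo) & (t < hi) & still & (labels == "other")
        labels[sel] = "quiescent"
    return labels


@dataclass(frozen=True)
class SpatialBinning:
    """Division of the linearized path into spatial bins and eight windows.

    The horizontal-arm walked path (slope surfaces included) is tiled by
    ``n_bins_horizontal`` bins and the vertical arm by ``n_bins_vertical``
    (defaults 90 + 40 = 130).  Bin indices are 1-based in a fixed spatial
    frame, ordered along the travel direction of right trials.

    Windows w1..w8 are contiguous path segments: w1/w2 tile the vertical arm,
    w3/w4 the flat stretch between corner and ramp, w5/w6 the two ramp slopes
    (w5 = the slope climbed in right trials), w7/w8 the flat stretch from ramp
    to the horizontal-arm end.  Their uphill/downhill meaning flips with
    travel direction (see :func:`window_roles`).
    """

    n_bins_horizontal: int = 90
    n_bins_vertical: int = 40

    def __post_init__(self) -> None:
        if self.n_bins_horizontal < 1 or self.n_bins_vertical < 1:
            raise ValueError("bin counts must be positive")

    @property
    def total_bins(self) -> int:
        return self.n_bins_horizontal + self.n_bins_vertical

    def edges(self, maze: MazeModel) -> np.ndarray:
        """Bin edges along the path, length ``total_bins + 1``."""
        h = np.linspace(0.0, maze.horizontal_path_length, self.n_bins_horizontal + 1)
        v = np.linspace(
            maze.horizontal_path_length, maze.total_path_length, self.n_bins_vertical + 1
        )
        return np.concatenate([h, v[1:]])

    def bin_centers(self, maze: MazeModel) -> np.ndarray:
        e = self.edges(maze)
        return 0.5 * (e[:-1] + e[1:])

    def window_of_bins(self, maze: MazeModel) -> np.ndarray:
        """Window label ('w1'..'w8') of each bin, by bin center."""
        centers = self.bin_centers(maze)
        off = maze.ramp_path_start
        apex = maze.apex_path
        rend = maze.ramp_path_end
        hp = maze.horizontal_path_length
        vmid = hp + maze.vertical_arm_length / 2.0
        mid34 = (rend + hp) / 2.0
        mid78 = off / 2.0

        labels = np.empty(len(centers), dtype="<U2")
        labels[centers >= vmid] = "w1"
        labels[(centers >= hp) & (centers < vmid)] = "w2"
        labels[(centers >= mid34) & (centers < hp)] = "w3"
        labels[(centers >= rend) & (centers < mid34)] = "w4"
        labels[(centers >= apex) & (centers < rend)] = "w5"
        labels[(centers >= off) & (centers < apex)] = "w6"
        labels[(centers >= mid78) & (centers < off)] = "w7"
        labels[centers < mid78] = "w8"
        return labels


def linearize_and_bin(
    track: pd.DataFrame, maze: MazeModel, binning: SpatialBinning = SpatialBinning()
) -> np.ndarray:
    """Map each frame to a 1-based spatial bin index along the path."""
    path = track["path_cm"].to_numpy(float)
    if np.any(path < -1e-9) or np.any(path > maze.total_path_length + 1e-9):
        raise ValueError("path coordinate outside the maze")
    edges = binning.edges(maze)
    idx = np.searchsorted(edges, path, side="right")
    return np.clip(idx, 1, binning.total_bins).astype(int)


def assign_windows(
    bins: np.ndarray,
    direction: str,
    binning: SpatialBinning,
    maze: MazeModel,
) -> np.ndarray:
    """Window label ('w1'..'w8') per frame from its spatial bin.

    Window geometry is fixed in space; ``direction`` does not move the
    boundaries (flipping it only swaps the uphill/downhill *meaning* of the
    two slope windows — see :func:`window_roles`).
    """
    if direction not in ("left", "right"):
        raise ValueError(f"direction must be 'left' or 'right', got {direction!r}")
    bin_windows = binning.window_of_bins(maze)
    bins = np.asarray(bins, dtype=int)
    if np.any(bins < 1) or np.any(bins > binning.total_bins):
        raise ValueError("bin index out of range")
    return bin_windows[bins - 1]


def window_roles(direction: str) -> dict[str, str]:
    """Uphill/downhill semantics of the slope windows for a travel direction.

    In right trials w5 is the uphill slope and w6 the downhill slope; in left
    trials the roles are reversed.
    """
    if direction == "right":
        return {"w5": "uphill", "w6": "downhill"}
    if direction == "left":
        return {"w5": "downhill", "w6": "uphill"}
    raise ValueError(f"direction must be 'left' or 'right', got {direction!r}")


def trial_direction_per_frame(trials: pd.DataFrame, t: np.ndarray) -> np.ndarray:
    """Direction label of the complete trial each frame belongs to ('' outside)."""
    t = np.asarray(t, dtype=float)
    out = np.full(len(t), "", dtype="<U5")
    comp = trials[trials["complete"].astype(bool)]
    for _, tr in comp.iterrows():
        out[(t >= tr.t_trial_start) & (t < tr.t_reward)] = tr.direction
    return out
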