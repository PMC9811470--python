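"""Neuron tuning analysis: peri-event alignment, classification, spatial maps.

Activity here is either a ΔF/F₀ trace per neuron or a Ca²⁺ event series; the
classification default follows the event-rate convention (events per second
within a phase).  All trial-resolved computations use complete trials only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import PhaseThresholds

logger = logging.getLogger(__name__)

__all__ = [
    "PeriEventTensor",
    "NeuronClass",
    "PhaseShape",
    "ActivityBinMap",
    "InclineProfile",
    "align_average_sort",
    "speed_correlation",
    "trial_phase_activity",
    "classify_neuron",
    "classify_phase_shape",
    "bin_activity_maps",
    "incline_modulation",
]


# ---------------------------------------------------------------------------
# Peri-event alignment
# ---------------------------------------------------------------------------

@dataclass
class PeriEventTensor:
    """Trial-averaged activity around one event marker, peak-time sorted."""

    marker: str
    lags_s: np.ndarray       # (L,)
    mean: np.ndarray         # (n_neurons, L) trial average
    order: np.ndarray        # neuron permutation by peak-activation time


def align_average_sort(
    activity: np.ndarray,
    marker_times: np.ndarray,
    frame_rate: float,
    window_s: float = 5.0,
    marker: str = "",
) -> PeriEventTensor:
    """Align activity to marker times, average across trials, sort neurons.

    ``activity`` is (n_neurons, T); ``marker_times`` are the marker's times
    (s) in complete trials.  Snippets extending past the session edges are
    NaN-padded and averaged with ``nanmean``.  Neurons are ordered by the
    argmax lag of their averaged series (ties broken by neuron id).
    """
    activity = np.atleast_2d(np.asarray(activity, dtype=float))
    times = np.asarray(marker_times, dtype=float)
    times = times[np.isfinite(times)]
    if times.size == 0:
        raise ValueError("marker missing in all trials")
    n, T = activity.shape
    w = int(round(window_s * frame_rate))
    lags = np.arange(-w, w + 1)
    snippets = np.full((len(times), n, len(lags)), np.nan)
    for k, t0 in enumerate(times):
        i0 = int(round(t0 * frame_rate))
        lo, hi = i0 - w, i0 + w + 1
        src_lo, src_hi = max(0, lo), min(T, hi)
        if src_lo >= src_hi:
            continue
        snippets[k, :, src_lo - lo: src_hi - lo] = activity[:, src_lo:src_hi]
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(snippets, axis=0)
    peak_lag = np.nanargmax(np.where(np.isnan(mean), -np.inf, mean), axis=1)
    order = np.argsort(peak_lag, kind="stable")
    return PeriEventTensor(marker=marker, lags_s=lags / frame_rate,
                           mean=mean, order=order)


def speed_correlation(
    activity: np.ndarray,
    speed: np.ndarray,
    mode: str = "full_session",
    marker_times: np.ndarray | None = None,
    window_s: float = 1.0,
    frame_rate: float = 30.0,
) -> np.ndarray | float:
    """Pearson correlation between activity and locomotion speed.

    ``mode='peri_event'`` restricts samples to ±``window_s`` around the given
    marker times (the peri-event convention is 1 s before to 1 s after).
    Zero-variance inputs give NaN.  Returns a scalar for 1-D activity, else
    one r per neuron.
    """
    act = np.atleast_2d(np.asarray(activity, dtype=float))
    speed = np.asarray(speed, dtype=float)
    if act.shape[1] != len(speed):
        raise ValueError("activity and speed lengths differ")
    if act.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if mode == "peri_event":
        if marker_times is None:
            raise ValueError("peri_event mode needs marker_times")
        mask = np.zeros(len(speed), dtype=bool)
        w = int(round(window_s * frame_rate))
        for t0 in np.asarray(marker_times, dtype=float):
            if np.isfinite(t0):
                i0 = int(round(t0 * frame_rate))
                mask[max(0, i0 - w): min(len(speed), i0 + w + 1)] = True
    elif mode == "full_session":
        mask = np.ones(len(speed), dtype=bool)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    s = speed[mask]
    out = np.full(act.shape[0], np.nan)
    if s.std() > 0:
        for i, row in enumerate(act):
            r = row[mask]
            if r.std() > 0:
                out[i] = float(np.corrcoef(r, s)[0, 1])
    if np.isnan(out).any():
        logger.info("speed_correlation: %d neurons with undefined r "
                    "(zero variance)", int(np.isnan(out).sum()))
    return float(out[0]) if np.asarray(activity).ndim == 1 else out


# ---------------------------------------------------------------------------
# Tuning classification
# ---------------------------------------------------------------------------

def trial_phase_activity(
    activity: np.ndarray,
    phases: np.ndarray,
    trials: pd.DataFrame,
    frame_rate: float,
    speed: np.ndarray | None = None,
    thresholds: PhaseThresholds = PhaseThresholds(),
    measure: str = "event_rate",
    baseline_s: float = 2.0,
) -> pd.DataFrame:
    """Per-trial activity in each movement phase plus a still baseline.

    ``activity`` is either event start frames (1-D int array, for
    ``measure='event_rate'``: events/s within the phase) or a ΔF/F₀ trace
    (for ``measure='trace_mean'``).  The baseline is the last ``baseline_s``
    seconds of low-movement (quiescent) frames preceding each trial start.
    Returns a DataFrame indexed by trial id with columns
    ``uphill, downhill, flat, quiescent, baseline`` (NaN where a phase was
    not visited in that trial).
    """
    phases = np.asarray(phases)
    T = len(phases)
    t = np.arange(T) / frame_rate
    if measure == "event_rate":
        ev = np.zeros(T)
        starts = np.asarray(activity, dtype=int)
        np.add.at(ev, starts[(starts >= 0) & (starts < T)], 1.0)
    elif measure == "trace_mean":
        ev = np.asarray(activity, dtype=float)
        if len(ev) != T:
            raise ValueError("trace and phases lengths differ")
    else:
        raise ValueError(f"unknown measure {measure!r}")

    def agg(mask: np.ndarray) -> float:
        k = int(mask.sum())
        if k == 0:
            return np.nan
        if measure == "event_rate":
            return float(ev[mask].sum() / (k / frame_rate))
        return float(ev[mask].mean())

    comp = trials[trials["complete"].astype(bool)].sort_values("t_trial_start")
    rewards = comp["t_reward"].to_numpy(float)
    rows = []
    prev_bound = 0.0
    for k, (_, tr) in enumerate(comp.iterrows()):
        in_trial = (t >= tr.t_trial_start) & (t < tr.t_reward)
        row = {"trial_id": int(tr.trial_id)}
        for ph in ("uphill", "downhill", "flat"):
            row[ph] = agg(in_trial & (phases == ph))
        q_mask = (t >= tr.t_reward) & (phases == "quiescent")
        if k + 1 < len(comp):
            q_mask &= t < comp["t_trial_start"].to_numpy(float)[k + 1]
        row["quiescent"] = agg(q_mask)
        pre = (t >= prev_bound) & (t < tr.t_trial_start) & (phases == "quiescent")
        idx = np.flatnonzero(pre)
        n_bl = int(round(baseline_s * frame_rate))
        bl = np.zeros(T, dtype=bool)
        if idx.size:
            bl[idx[-n_bl:]] = True
        row["baseline"] = agg(bl)
        rows.append(row)
        prev_bound = tr.t_reward
    return pd.DataFrame(rows).set_index("trial_id")


@dataclass
class NeuronClass:
    """Tuning class of one neuron with the comparisons behind it."""

    label: str                        # uphill|downhill|flat|quiescent|other
    means: dict[str, float]
    p_values: dict[str, float]
    reason: str = ""


def _paired_p(a: np.ndarray, b: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 2:
        return np.nan
    if np.allclose(a[ok], b[ok]):
        return 1.0
    return float(stats.ttest_rel(a[ok], b[ok]).pvalue)


def classify_neuron(
    phase_activity: pd.DataFrame,
    alpha: float = 0.05,
    min_trials: int = 5,
    paired: bool = True,
) -> NeuronClass:
    """Assign a tuning class from per-trial phase activity.

    A neuron is *uphill* when its uphill activity significantly exceeds both
    the still baseline and the downhill activity (paired t-test across
    trials, p < alpha) and its uphill mean is strictly the highest across
    all maze locations; downhill and flat are symmetric (flat must beat both
    ramp phases).  *Quiescent* neurons are maximal during quiescence with
    significance against every movement phase.  Anything else — including
    exact ties — is *other*.
    """
    df = phase_activity
    need = ["uphill", "downhill", "flat", "quiescent", "baseline"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"missing phase columns: {missing}")
    n_ok = int(df[need].notna().all(axis=1).sum())
    means = {c: float(np.nanmean(df[c])) for c in need}
    if len(df) < min_trials:
        return NeuronClass("other", means, {}, reason=f"only {len(df)} trials")

    def p(a: str, b: str) -> float:
        if paired:
            return _paired_p(df[a].to_numpy(float), df[b].to_numpy(float))
        x = df[a].dropna().to_numpy(float)
        y = df[b].dropna().to_numpy(float)
        if len(x) < 2 or len(y) < 2:
            return np.nan
        return float(stats.ttest_ind(x, y, equal_var=False).pvalue)

    pv: dict[str, float] = {}

    def sig_greater(a: str, b: str) -> bool:
        key = f"{a}_vs_{b}"
        pv[key] = p(a, b)
        return bool(np.isfinite(pv[key]) and pv[key] < alpha and means[a] > means[b])

    locs = ("uphill", "downhill", "flat")

    def is_max(ph: str, competitors: tuple[str, ...]) -> bool:
        return all(means[ph] > means[c] for c in competitors if c != ph)

    if is_max("uphill", locs + ("quiescent",)) and \
            sig_greater("uphill", "baseline") and sig_greater("uphill", "downhill"):
        return NeuronClass("uphill", means, pv)
    if is_max("downhill", locs + ("quiescent",)) and \
            sig_greater("downhill", "baseline") and sig_greater("downhill", "uphill"):
        return NeuronClass("downhill", means, pv)
    if is_max("flat", locs + ("quiescent",)) and sig_greater("flat", "baseline") and \
            sig_greater("flat", "uphill") and sig_greater("flat", "downhill"):
        return NeuronClass("flat", means, pv)
    if is_max("quiescent", locs) and all(
        sig_greater("quiescent", ph) for ph in locs
    ):
        return NeuronClass("quiescent", means, pv)
    reason = "no phase passed the significance and maximality rules"
    if n_ok < min_trials:
        reason = f"only {n_ok} trials with all phases sampled"
    return NeuronClass("other", means, pv, reason=reason)


# ---------------------------------------------------------------------------
# Phase-shape classification (phase-specific vs phase-change)
# ---------------------------------------------------------------------------

@dataclass
class PhaseShape:
    """Temporal shape of a neuron's ramp response."""

    kind: str        # phase_specific | phase_change | other
    subtype: str     # uphill|downhill|both | pre_uphill|post_uphill|peak|post_downhill | ''
    span_s: float    # duration of the activation used for the call


def _longest_run(active: np.ndarray) -> tuple[int, int] | None:
    """(start, end) inclusive of the longest True run, or None."""
    if not active.any():
        return None
    padded = np.concatenate([[False], active, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    k = int(np.argmax(ends - starts))
    return int(starts[k]), int(ends[k])


def classify_phase_shape(
    peri_peak: np.ndarray,
    frame_rate: float,
    peri_up_start: np.ndarray | None = None,
    peri_down_end: np.ndarray | None = None,
    span_specific_s: float = 2.0,
    span_change_s: float = 1.0,
    near_s: float = 0.5,
    sd_mult: float = 1.0,
    threshold_mode: str = "baseline_plus_sd",
) -> PhaseShape:
    """Phase-specific vs phase-change call from trial-averaged traces.

    ``peri_peak`` is the 10-s trial-averaged trace centered on the ramp-peak
    marker (lag 0 at the middle frame); ``peri_up_start`` / ``peri_down_end``
    are the analogous alignments to uphill start and downhill end.
    Activation = the longest contiguous stretch of the averaged trace above
    the SD-based threshold.  The default level is the trace's baseline (its
    10th percentile) plus ``sd_mult`` × SD, which stays valid for nonzero
    baseline activity and for activations filling most of the window.
    ``threshold_mode='sd'`` uses the SD as an absolute level (appropriate
    when baseline event activity is essentially zero) and
    ``'mean_plus_sd'`` the classical mean offset — note the latter cannot
    flag activations filling more than ~half the window.
    A ≥ 2-s activation confined before the peak is a phase-specific uphill
    neuron (2 s ≈ 2/3 of the average uphill duration); after the peak,
    downhill; spanning both sides, "both".  A < 1-s activation centered
    within ``near_s`` of the peak (or of uphill start / downhill end on
    those alignments) is a phase-change neuron of the matching transition
    subtype.
    """
    def call(trace: np.ndarray | None):
        if trace is None:
            return None
        trace = np.asarray(trace, dtype=float)
        sd = np.nanstd(trace)
        if not np.isfinite(sd) or sd < 1e-12:
            return None
        if threshold_mode == "baseline_plus_sd":
            thr = np.nanpercentile(trace, 10) + sd_mult * sd
        elif threshold_mode == "sd":
            thr = sd_mult * sd
        elif threshold_mode == "mean_plus_sd":
            thr = np.nanmean(trace) + sd_mult * sd
        else:
            raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
        run = _longest_run(np.nan_to_num(trace, nan=-np.inf) > thr)
        if run is None:
            return None
        a, b = run
        center = len(trace) // 2
        span = (b - a + 1) / frame_rate
        return a, b, center, span

    tol = int(round(0.25 * frame_rate))
    near = near_s * frame_rate

    res = call(peri_peak)
    if res is not None:
        a, b, c, span = res
        if span >= span_specific_s:
            if b <= c + tol:
                return PhaseShape("phase_specific", "uphill", span)
            if a >= c - tol:
                return PhaseShape("phase_specific", "downhill", span)
            return PhaseShape("phase_specific", "both", span)
        if span < span_change_s and abs((a + b) / 2.0 - c) <= near:
            return PhaseShape("phase_change", "peak", span)

    res = call(peri_up_start)
    if res is not None:
        a, b, c, span = res
        mid = (a + b) / 2.0
        if span < span_change_s and -near <= mid - c < 0:
            return PhaseShape("phase_change", "pre_uphill", span)
        if span < span_change_s and 0 <= mid - c <= near:
            return PhaseShape("phase_change", "post_uphill", span)

    res = call(peri_down_end)
    if res is not None:
        a, b, c, span = res
        if span < span_change_s and abs((a + b) / 2.0 - c) <= near:
            return PhaseShape("phase_change", "post_downhill", span)

    return PhaseShape("other", "", 0.0)


# ---------------------------------------------------------------------------
# Spatial bin maps
# ---------------------------------------------------------------------------

@dataclass
class ActivityBinMap:
    """Occupancy-averaged activity per spatial bin, split by direction."""

    right: np.ndarray       # (n_neurons, n_bins), NaN where unvisited
    left: np.ndarray
    difference: np.ndarray  # right − left, NaN where either side unvisited
    order: np.ndarray       # neurons sorted by difference-map peak location


def bin_activity_maps(
    activity: np.ndarray,
    bins: np.ndarray,
    directions: np.ndarray,
    n_bins: int = 130,
) -> ActivityBinMap:
    """Project activity onto spatial bins per trial direction and subtract.

    ``bins`` holds the 1-based spatial bin of each frame and ``directions``
    the direction label ('left'/'right'/'' outside trials) of the trial each
    frame belongs to.  The per-bin value is the occupancy-weighted mean of
    the activity over the frames spent in the bin; the difference map is
    right − left.  Neurons are sorted by the location of the difference
    map's peak (ties and all-NaN maps by neuron id, at the end).
    """
    act = np.atleast_2d(np.asarray(activity, dtype=float))
    bins = np.asarray(bins, dtype=int)
    directions = np.asarray(directions)
    if act.shape[1] != len(bins) or len(bins) != len(directions):
        raise ValueError("activity, bins, and directions must share the time base")

    maps = {}
    for d in ("right", "left"):
        sel = directions == d
        if not sel.any():
            logger.warning("no frames in %s trials; difference map undefined", d)
        sums = np.zeros((act.shape[0], n_bins))
        counts = np.zeros(n_bins)
        b = bins[sel] - 1
        np.add.at(counts, b, 1.0)
        for i in range(act.shape[0]):
            np.add.at(sums[i], b, act[i, sel])
        with np.errstate(invalid="ignore"):
            maps[d] = np.where(counts > 0, sums / counts, np.nan)
    diff = maps["right"] - maps["left"]

    peak = np.full(act.shape[0], n_bins + 1, dtype=float)
    for i in range(act.shape[0]):
        row = diff[i]
        if np.isfinite(row).any():
            peak[i] = np.nanargmax(row)
    order = np.argsort(peak, kind="stable")
    return ActivityBinMap(right=maps["right"], left=maps["left"],
                          difference=diff, order=order)


# ---------------------------------------------------------------------------
# Incline modulation
# ---------------------------------------------------------------------------

@dataclass
class InclineProfile:
    """Activity of one neuron (one phase) across the three ramp angles."""

    means: dict[float, float]
    modulation: str             # increasing | decreasing | similar | other
    p_extreme: float            # smallest vs largest angle comparison
    stable: bool | None = None  # same tuning class at all angles (set by caller)


def incline_modulation(
    samples: dict[float, np.ndarray],
    alpha: float = 0.05,
) -> InclineProfile:
    """Classify how activity changes across slope angles (15°, 30°, 45°).

    ``samples`` maps each angle to its per-trial activity values.
    *increasing*: means rise monotonically with angle and the extreme pair
    differs significantly (Welch t-test); *decreasing*: symmetric;
    *similar*: no pair differs significantly; *other*: anything else.
    """
    angles = sorted(samples)
    if len(angles) != 3:
        raise ValueError("need activity at exactly three angles")
    vals = [np.asarray(samples[a], dtype=float) for a in angles]
    for a, v in zip(angles, vals):
        if len(v) < 2:
            raise ValueError(f"angle {a}: need >= 2 trials")
    means = {float(a): float(np.nanmean(v)) for a, v in zip(angles, vals)}
    m = [means[float(a)] for a in angles]

    def p(i: int, j: int) -> float:
        if np.allclose(vals[i], vals[i][0]) and np.allclose(vals[j], vals[j][0]) \
                and np.isclose(vals[i][0], vals[j][0]):
            return 1.0
        return float(stats.ttest_ind(vals[i], vals[j], equal_var=False).pvalue)

    p01, p12, p02 = p(0, 1), p(1, 2), p(0, 2)
    if m[0] < m[1] < m[2] and p02 < alpha:
        mod = "increasing"
    elif m[0] > m[1] > m[2] and p02 < alpha:
        mod = "decreasing"
    elif all(q >= alpha for q in (p01, p12, p02)):
        mod = "similar"
    else:
        mod = "other"
    return InclineProfile(means=means, modulation=mod, p_extreme=p02)
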