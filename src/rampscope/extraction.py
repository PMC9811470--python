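"""Movie-to-events chain for one-photon miniscope recordings.

Stages: spatial downsampling → per-pixel ΔF/F₀ against the session-mean
baseline F₀ → skewness-seeking PCA-ICA demixing into components (paired
spatial filter + temporal signal) → automated component QC (temporal
skewness, vessel overlap, soma size/shape) → per-cell trace extraction
(3×3-spot with background-median subtraction for interneurons;
truncated-filter projection for Purkinje cells) → rising-phase Ca²⁺ event
detection on the derivative of ΔF/F₀.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import convolve1d
from skimage.measure import label as cc_label, regionprops
from sklearn.decomposition import PCA, FastICA

logger = logging.getLogger(__name__)

__all__ = [
    "FluorMovie",
    "DffMovie",
    "Component",
    "QCThresholds",
    "spatial_downsample",
    "compute_dff",
    "pca_ica",
    "qc_components",
    "extract_trace_mli",
    "extract_trace_pc",
    "detect_events",
    "event_phase_stats",
    "robust_sd",
]


@dataclass
class FluorMovie:
    """Fluorescence movie: (T, H, W) intensities at a given frame rate."""

    frames: np.ndarray
    frame_rate: float = 30.0
    pixel_size: float = 1.3  # µm/px

    def __post_init__(self) -> None:
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a non-empty (T, H, W) array")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape


@dataclass
class DffMovie:
    """ΔF/F₀ movie with its per-pixel baseline and validity mask."""

    values: np.ndarray        # (T, H, W), dimensionless
    f0: np.ndarray            # (H, W)
    valid: np.ndarray         # (H, W) bool, False where F0 <= eps
    frame_rate: float = 30.0
    pixel_size: float = 1.3


@dataclass
class Component:
    """One PCA-ICA component: paired spatial filter and temporal signal."""

    spatial_filter: np.ndarray   # (H, W)
    temporal_signal: np.ndarray  # (T,)
    skewness: float
    component_id: int = 0
    equivalent_diameter_um: float = float("nan")
    elongation: float = float("nan")
    vessel_overlap: float = float("nan")
    cell_class: str = "unclassified"  # MLI | PC | artifact | unclassified
    accepted: bool = False
    qc_log: list[str] = field(default_factory=list)


def spatial_downsample(movie: FluorMovie, factor: int = 4) -> FluorMovie:
    """Block-mean spatial pooling by an integer factor.

    Trailing rows/columns that do not fill a block are cropped (logged).
    The pixel size scales by the factor.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return movie
    T, H, W = movie.frames.shape
    h, w = H // factor, W // factor
    if h * factor != H or w * factor != W:
        logger.info("cropping trailing edge: (%d, %d) -> (%d, %d)",
                    H, W, h * factor, w * factor)
    cropped = movie.frames[:, : h * factor, : w * factor]
    pooled = cropped.reshape(T, h, factor, w, factor).mean(axis=(2, 4))
    return FluorMovie(
        frames=pooled, frame_rate=movie.frame_rate,
        pixel_size=movie.pixel_size * factor,
    )


def compute_dff(movie: FluorMovie, eps: float = 1e-9) -> DffMovie:
    """ΔF/F₀ with F₀ = per-pixel temporal mean over the whole session.

    Pixels whose baseline is ≤ eps are masked invalid (their ΔF/F₀ is set
    to 0).  ``F₀·(1 + ΔF/F₀)`` reconstructs the input on valid pixels.
    """
    if movie.frames.shape[0] < 2:
        raise ValueError("need at least 2 frames for a baseline")
    f = movie.frames.astype(float)
    f0 = f.mean(axis=0)
    valid = f0 > eps
    if not valid.any():
        logger.warning("all pixels have zero baseline; output fully masked")
    dff = np.zeros_like(f)
    np.divide(f - f0[None], f0[None], out=dff, where=valid[None])
    return DffMovie(values=dff, f0=f0, valid=valid,
                    frame_rate=movie.frame_rate, pixel_size=movie.pixel_size)


# ---------------------------------------------------------------------------
# PCA-ICA demixing
# ---------------------------------------------------------------------------

def pca_ica(
    dff: DffMovie,
    n_ics: int,
    n_pcs: int | None = None,
    spatiotemporal_weight: float = 0.5,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-5,
) -> list[Component]:
    """Demix a ΔF/F₀ movie into independent spatiotemporal components.

    PCA reduces the (T × pixels) matrix to ``n_pcs`` components (default
    1.5 × n_ics, rounded); ICA then rotates them to maximize
    non-Gaussianity with the cube nonlinearity, i.e. seeking skewed sources
    — the signature of sparse calcium transients.  ICA runs on the joint
    representation concatenating each PC's spatial map (weighted by
    ``spatiotemporal_weight`` µ) and temporal score (weighted by 1 − µ),
    so µ = 1 is purely spatial and µ = 0 purely temporal ICA.

    Each component's sign is fixed so its temporal skewness is ≥ 0, and the
    list is ordered by decreasing temporal skewness.  Deterministic for a
    fixed seed.
    """
    if not 0.0 <= spatiotemporal_weight <= 1.0:
        raise ValueError("spatiotemporal_weight must be in [0, 1]")
    T = dff.values.shape[0]
    flat = dff.values.reshape(T, -1)
    valid = dff.valid.ravel()
    X = flat[:, valid]
    if X.shape[1] == 0:
        raise ValueError("no valid pixels")
    if n_pcs is None:
        n_pcs = int(round(1.5 * n_ics))
    n_pcs = min(n_pcs, T, X.shape[1])
    if n_ics > n_pcs:
        raise ValueError(f"n_ics ({n_ics}) must be <= n_pcs ({n_pcs})")

    pca = PCA(n_components=n_pcs, svd_solver="randomized", random_state=seed)
    scores = pca.fit_transform(X)            # (T, k)
    if np.any(pca.explained_variance_ < 1e-15):
        bad = int(np.argmax(pca.explained_variance_ < 1e-15))
        raise ValueError(f"degenerate covariance: principal component {bad} "
                         "has (near-)zero variance")
    loadings = pca.components_               # (k, P_valid)

    # Joint spatiotemporal representation, each part scaled to unit RMS.
    mu = spatiotemporal_weight
    sp = loadings / max(np.sqrt(np.mean(loadings**2)), 1e-15)
    tp = scores.T / max(np.sqrt(np.mean(scores**2)), 1e-15)
    Z = np.hstack([mu * sp, (1.0 - mu) * tp])  # (k, P_valid + T)

    ica = FastICA(
        n_components=n_ics, fun="cube", whiten="unit-variance",
        random_state=seed, max_iter=max_iter, tol=tol,
    )
    sources = ica.fit_transform(Z.T).T       # (n_ics, P_valid + T)

    P_valid = sp.shape[1]
    comps: list[Component] = []
    H, W = dff.valid.shape
    for i, src in enumerate(sources):
        smap = np.zeros(H * W)
        smap[valid] = src[:P_valid]
        tsig = src[P_valid:].copy()
        sk = float(stats.skew(tsig))
        if sk < 0:
            smap, tsig, sk = -smap, -tsig, -sk
        comps.append(Component(
            spatial_filter=smap.reshape(H, W), temporal_signal=tsig,
            skewness=sk, component_id=i,
        ))
    comps.sort(key=lambda c: -c.skewness)
    for i, c in enumerate(comps):
        c.component_id = i
    return comps


@dataclass(frozen=True)
class QCThresholds:
    """Automated component QC in place of visual inspection."""

    skewness_min: float = 1.0          # reject components with lower skewness
    vessel_overlap_max: float = 0.5    # filter-support fraction over vessels
    mli_diameter_um: tuple[float, float] = (3.0, 12.0)  # round-soma range
    elongation_max: float = 3.0        # above this, striped -> Purkinje cell
    support_level: float = 0.5         # filter support = > level * max


def _filter_support(filt: np.ndarray, level: float) -> np.ndarray:
    m = filt.max()
    if m <= 0:
        return np.zeros_like(filt, dtype=bool)
    return filt > level * m


def qc_components(
    components: list[Component],
    vessel_mask: np.ndarray | None,
    pixel_size: float,
    thresholds: QCThresholds = QCThresholds(),
) -> list[Component]:
    """Set ``cell_class`` and ``accepted`` on each component, in place.

    Rules: reject temporal skewness below the minimum; reject filters whose
    support overlaps vessel shadows beyond the threshold (blood-flow
    artifacts); classify the remainder by footprint geometry — small round
    somata are interneurons (MLI), large or elongated/striped footprints are
    Purkinje cells.  The MLI pipeline accepts only MLI components; every
    decision is appended to the component's ``qc_log``.
    """
    for comp in components:
        support = _filter_support(comp.spatial_filter, thresholds.support_level)
        area = int(support.sum())
        comp.equivalent_diameter_um = (
            2.0 * math.sqrt(area / math.pi) * pixel_size if area else 0.0
        )
        comp.elongation = 1.0
        if area:
            lbl = cc_label(support)
            props = max(regionprops(lbl), key=lambda p: p.area)
            if props.axis_minor_length > 0:
                comp.elongation = props.axis_major_length / props.axis_minor_length
            elif props.axis_major_length > 0:
                comp.elongation = float("inf")
        if vessel_mask is not None and area:
            comp.vessel_overlap = float((support & vessel_mask).sum()) / area
        else:
            comp.vessel_overlap = 0.0

        comp.accepted = False
        if comp.skewness < thresholds.skewness_min:
            comp.cell_class = "artifact"
            comp.qc_log.append(
                f"rejected: skewness {comp.skewness:.2f} < {thresholds.skewness_min}"
            )
            continue
        if comp.vessel_overlap > thresholds.vessel_overlap_max:
            comp.cell_class = "artifact"
            comp.qc_log.append(
                f"rejected: vessel overlap {comp.vessel_overlap:.2f}"
            )
            continue
        lo, hi = thresholds.mli_diameter_um
        if comp.equivalent_diameter_um > hi or comp.elongation > thresholds.elongation_max:
            comp.cell_class = "PC"
            comp.qc_log.append(
                f"classified PC (diameter {comp.equivalent_diameter_um:.1f} µm, "
                f"elongation {comp.elongation:.1f}); rejected from MLI set"
            )
            continue
        if comp.equivalent_diameter_um < lo:
            comp.cell_class = "artifact"
            comp.qc_log.append(
                f"rejected: footprint too small ({comp.equivalent_diameter_um:.1f} µm)"
            )
            continue
        comp.cell_class = "MLI"
        comp.accepted = True
        comp.qc_log.append("accepted as MLI")
    return components


# ---------------------------------------------------------------------------
# Trace extraction
# ---------------------------------------------------------------------------

def extract_trace_mli(
    dff: DffMovie,
    component: Component,
    background_mask: np.ndarray | None = None,
    support_level: float = 0.5,
) -> np.ndarray:
    """MLI ΔF/F₀ trace: 3×3 spot mean minus per-frame background median.

    The cell location is the brightest pixel of the spatial filter; the
    trace is the mean ΔF/F₀ over the 3×3 window centered there, minus the
    median over the background area (valid pixels outside the cell body, or
    outside all accepted filters when ``background_mask`` is supplied).
    """
    filt = component.spatial_filter
    r, c = np.unravel_index(int(np.argmax(filt)), filt.shape)
    H, W = filt.shape
    r0, r1 = max(0, r - 1), min(H, r + 2)
    c0, c1 = max(0, c - 1), min(W, c + 2)
    if r1 - r0 < 3 or c1 - c0 < 3:
        logger.info("3x3 window clipped at frame border (peak at %d, %d)", r, c)
    if background_mask is None:
        background_mask = dff.valid & ~_filter_support(filt, support_level)
    else:
        background_mask = background_mask & dff.valid
    if not background_mask.any():
        raise ValueError("empty background region")
    spot = dff.values[:, r0:r1, c0:c1].mean(axis=(1, 2))
    bg = np.median(dff.values[:, background_mask], axis=1)
    return spot - bg


def extract_trace_pc(dff: DffMovie, component: Component) -> np.ndarray:
    """Purkinje-cell trace via the truncated spatial filter.

    Pixel weights below (mean + 2·SD) of the filter are zeroed; the trace is
    the weight-normalized projection of each ΔF/F₀ frame onto the truncated
    filter.  Scale-invariant in the filter.
    """
    w = component.spatial_filter.astype(float).copy()
    thr = w.mean() + 2.0 * w.std()
    w[w <= thr] = 0.0  # keep only pixels above mean + 2 SD
    total = w.sum()
    if total <= 0:
        raise ValueError("truncation left an empty filter (degenerate filter)")
    T = dff.values.shape[0]
    return dff.values.reshape(T, -1) @ (w.ravel() / total)


# ---------------------------------------------------------------------------
# Event detection
# ---------------------------------------------------------------------------

def robust_sd(x: np.ndarray) -> float:
    """Robust SD: 1.4826 × median absolute deviation."""
    x = np.asarray(x, dtype=float)
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


def _moving_slope(trace: np.ndarray, window: int, frame_rate: float) -> np.ndarray:
    """Least-squares slope of the trace over a centered moving window, 1/s."""
    i = np.arange(window) - (window - 1) / 2.0
    denom = (i**2).sum() / frame_rate  # Σ(t−t̄)² with t in seconds
    weights = i[::-1] / denom          # convolution reverses the kernel
    return convolve1d(trace, weights, mode="nearest")


def detect_events(
    trace: np.ndarray,
    frame_rate: float,
    baseline_frames: np.ndarray | None = None,
    deriv_window_s: float = 0.2,
    deriv_sd_mult: float = 5.0,
    peak_sd_mult: float = 3.0,
    deriv_gate_on_trace: bool = False,
) -> pd.DataFrame:
    """Detect the rising phases of Ca²⁺ events in a ΔF/F₀ trace.

    The 1st derivative is the least-squares slope over a ``deriv_window_s``
    moving window (6 frames at 30 Hz).  A candidate rise starts where the
    derivative crosses 0 upward, ends at its next downward zero-crossing,
    and is kept only if (a) the derivative within the rise exceeds
    ``deriv_sd_mult`` × the baseline SD of the derivative and (b) the peak
    ΔF/F₀ within the rise exceeds ``peak_sd_mult`` × the baseline SD of the
    trace above the baseline median.  Baseline fluctuation is the robust SD
    (1.4826·MAD) over ``baseline_frames`` (e.g. quiescent-phase frames), or
    over the whole trace when not supplied.  Events never overlap.

    Returns a DataFrame with ``rise_start_frame, rise_end_frame, peak_dff,
    duration_s`` (one row per event).
    """
    trace = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace must be finite")
    window = max(2, int(round(deriv_window_s * frame_rate)))
    if baseline_frames is None:
        bl = np.ones(len(trace), dtype=bool)
    else:
        bl = np.asarray(baseline_frames)
        if bl.dtype != bool:
            mask = np.zeros(len(trace), dtype=bool)
            mask[bl] = True
            bl = mask
    if bl.sum() < 2 * window:
        raise ValueError("baseline shorter than twice the derivative window")

    deriv = _moving_slope(trace, window, frame_rate)
    sd_deriv = robust_sd(deriv[bl])
    sd_trace = robust_sd(trace[bl])
    med_trace = float(np.median(trace[bl]))
    deriv_gate = deriv_sd_mult * (sd_trace if deriv_gate_on_trace else sd_deriv)
    peak_gate = peak_sd_mult * sd_trace

    events = []
    T = len(trace)
    i = 1
    while i < T:
        if deriv[i] > 0 and deriv[i - 1] <= 0:
            j = i + 1
            while j < T and deriv[j] >= 0:
                j += 1
            end = j - 1  # last frame before the derivative falls below 0
            seg = slice(i, end + 1)
            if deriv[seg].max() > deriv_gate:
                # Zero-crossings of the smoothed derivative delimit the
                # candidate; the reported rise is the trace's own minimum-to-
                # maximum stretch inside it, which removes the half-window
                # timing bias of the centered slope estimate.
                i_peak = i + int(np.argmax(trace[seg]))
                pre = trace[i: i_peak + 1]
                below = np.flatnonzero(pre <= med_trace + 2.0 * sd_trace)
                if below.size:  # onset = last sub-baseline frame before the peak
                    i_rise = i + int(below[-1])
                else:  # riding on a previous tail: last minimum before the peak
                    i_rise = i + int(len(pre) - 1 - np.argmin(pre[::-1]))
                peak = float(trace[i_peak])
                if peak - med_trace > peak_gate:
                    events.append(dict(
                        rise_start_frame=i_rise,
                        rise_end_frame=i_peak,
                        peak_dff=peak - med_trace,
                        duration_s=(i_peak - i_rise) / frame_rate,
                    ))
            i = j + 1
        else:
            i += 1
    return pd.DataFrame(
        events,
        columns=["rise_start_frame", "rise_end_frame", "peak_dff", "duration_s"],
    )


def event_phase_stats(
    events: pd.DataFrame,
    phases: np.ndarray,
    frame_rate: float,
) -> pd.DataFrame:
    """Per-phase event frequency, intensity, and duration.

    Frequency = events whose rise start falls in the phase ÷ total phase
    time; intensity = mean peak ΔF/F₀; duration = mean rise duration.  A
    phase with zero events has frequency 0 and undefined (NaN) intensity and
    duration; a phase never visited has all three undefined.
    """
    from .behavior import PHASES

    phases = np.asarray(phases)
    rows = []
    starts = events["rise_start_frame"].to_numpy(int) if len(events) else np.array([], int)
    for ph in PHASES:
        mask = phases == ph
        t_total = mask.sum() / frame_rate
        in_phase = mask[starts] if len(starts) else np.array([], bool)
        n_ev = int(in_phase.sum())
        rows.append(dict(
            phase=ph,
            time_s=t_total,
            n_events=n_ev,
            frequency_hz=(n_ev / t_total) if t_total > 0 else np.nan,
            intensity_dff=float(events.loc[in_phase, "peak_dff"].mean()) if n_ev else np.nan,
            duration_s=float(events.loc[in_phase, "duration_s"].mean()) if n_ev else np.nan,
        ))
    return pd.DataFrame(rows).set_index("phase")
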