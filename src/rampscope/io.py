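"""File I/O: behavior CSV, trial tables, movies (TIFF), HDF5 bundles, configs.

All writers round-trip: reading back reproduces the values to 1e-9.
Behavior CSV columns are ``t_s, x_cm, y_cm, path_cm``; event CSVs carry
``rise_start_frame, rise_end_frame, peak_dff, duration_s``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .extraction import Component, FluorMovie
from .simulate import SimConfig

logger = logging.getLogger(__name__)

__all__ = [
    "write_behavior_csv", "read_behavior_csv",
    "write_trials", "read_trials",
    "write_phases_csv", "read_phases_csv",
    "write_movie_tiff", "read_movie_tiff",
    "write_traces_csv", "read_traces_csv",
    "write_events_csv", "read_events_csv",
    "write_components_h5", "read_components_h5",
    "write_ground_truth_h5",
    "load_sim_config", "save_sim_config",
    "write_provenance",
]


def write_behavior_csv(track: pd.DataFrame, path: str | Path) -> None:
    cols = ["t_s", "x_cm", "y_cm", "path_cm"]
    track[cols].to_csv(path, index=False, float_format="%.10g")

def read_behavior_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(trials.to_json(orient="records", double_precision=12))
    else:
        trials.to_csv(path, index=False, float_format="%.10g")

def read_trials(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".json":
        return pd.read_json(path, orient="records")
    return pd.read_csv(path)


def write_phases_csv(phases: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"frame": np.arange(len(phases)), "phase": phases}).to_csv(
        path, index=False
    )

def read_phases_csv(path: str | Path) -> np.ndarray:
    return pd.read_csv(path)["phase"].to_numpy(dtype="<U9")


def write_movie_tiff(movie: FluorMovie, path: str | Path) -> None:
    """Multi-page TIFF, uint16, frame-major; clipped to the uint16 range."""
    data = np.clip(np.round(movie.frames), 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(path, data.astype(np.uint16), metadata={
        "frame_rate_hz": movie.frame_rate, "pixel_size_um": movie.pixel_size,
    })

def read_movie_tiff(
    path: str | Path, frame_rate: float = 30.0, pixel_size: float = 1.3
) -> FluorMovie:
    frames = tifffile.imread(path).astype(float)
    if frames.ndim == 2:
        frames = frames[None]
    return FluorMovie(frames=frames, frame_rate=frame_rate, pixel_size=pixel_size)


def write_traces_csv(traces: np.ndarray, path: str | Path) -> None:
    """(n_neurons, T) traces; one column per neuron."""
    traces = np.atleast_2d(traces)
    pd.DataFrame(traces.T, columns=[f"n{i}" for i in range(traces.shape[0])]).to_csv(
        path, index=False, float_format="%.10g"
    )

def read_traces_csv(path: str | Path) -> np.ndarray:
    return pd.read_csv(path).to_numpy(float).T


def write_events_csv(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, index=False, float_format="%.10g")

def read_events_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_components_h5(components: list[Component], path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        for comp in components:
            g = f.create_group(f"component_{comp.component_id:04d}")
            g.create_dataset("spatial_filter", data=comp.spatial_filter)
            g.create_dataset("temporal_signal", data=comp.temporal_signal)
            g.attrs.update(
                skewness=comp.skewness,
                equivalent_diameter_um=comp.equivalent_diameter_um,
                elongation=comp.elongation,
                vessel_overlap=comp.vessel_overlap,
                cell_class=comp.cell_class,
                accepted=comp.accepted,
                qc_log="\n".join(comp.qc_log),
            )

def read_components_h5(path: str | Path) -> list[Component]:
    comps = []
    with h5py.File(path, "r") as f:
        for i, key in enumerate(sorted(f)):
            g = f[key]
            comps.append(Component(
                spatial_filter=g["spatial_filter"][()],
                temporal_signal=g["temporal_signal"][()],
                skewness=float(g.attrs["skewness"]),
                component_id=i,
                equivalent_diameter_um=float(g.attrs["equivalent_diameter_um"]),
                elongation=float(g.attrs["elongation"]),
                vessel_overlap=float(g.attrs["vessel_overlap"]),
                cell_class=str(g.attrs["cell_class"]),
                accepted=bool(g.attrs["accepted"]),
                qc_log=str(g.attrs["qc_log"]).splitlines(),
            ))
    return comps


def write_ground_truth_h5(session, path: str | Path) -> None:
    """Ground truth of a synthetic session: spikes, traces, labels, footprint geometry."""
    with h5py.File(path, "w") as f:
        f.create_dataset("clean_traces", data=session.clean_traces)
        f.create_dataset("noisy_traces", data=session.traces)
        f.create_dataset("rates", data=session.rates)
        f.create_dataset("class_labels",
                         data=np.asarray(session.population.classes, dtype="S"))
        f.create_dataset("footprint_centers", data=session.population.centers)
        f.create_dataset("phases", data=session.phases.astype("S"))
        g = f.create_group("spikes")
        for i, st in enumerate(session.spikes):
            g.create_dataset(f"neuron_{i:04d}", data=st)


def load_sim_config(path: str | Path) -> SimConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return SimConfig(**raw)

def save_sim_config(config: SimConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config)))


def write_provenance(path: str | Path, config=None, seed: int | None = None,
                     extra: dict | None = None) -> None:
    """Run provenance: config hash, seed, and library versions."""
    import sklearn

    from . import __version__

    info: dict = {
        "rampscope": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit_learn": sklearn.__version__,
        "seed": seed,
    }
    if config is not None:
        blob = yaml.safe_dump(dataclasses.asdict(config)).encode()
        info["config"] = dataclasses.asdict(config)
        info["config_sha256"] = hashlib.sha256(blob).hexdigest()
    if extra:
        info.update(extra)
    Path(path).write_text(json.dumps(info, indent=2, default=str))
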