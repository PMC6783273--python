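"""File formats, configuration and run manifests.

All interchange formats are plain delimited text (tab-separated with a
header row; ``#`` lines before the header carry ``key = value`` metadata).
Times are seconds at every interface; the simulator's internal minutes and
per-day rates are converted at the boundary.  Vendor MEA formats are out of
scope — an import adapter producing the spike-table layout below is the
designated extension point.

Spike table::

    # duration_s = 600
    # div = 14
    electrode_id<TAB>spike_time_s
    e01<TAB>0.534
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .growth_model import ModelParams, Trajectory
from .network_metrics import PointPattern
from .spike_analysis import SBEvent, SpikeRecording

__all__ = [
    "ParseError",
    "RunManifest",
    "read_config",
    "read_spike_table",
    "write_spike_table",
    "read_point_table",
    "write_point_table",
    "read_weight_matrix",
    "write_weight_matrix",
    "read_ca_pairs",
    "write_ca_pairs",
    "write_trajectory",
    "write_sbe_table",
    "write_stats_table",
    "write_manifest",
]

logger = logging.getLogger("neurogrowth")


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-exactly."""

    command: str
    parameters: dict
    seed: Optional[int]
    inputs: List[str] = field(default_factory=list)
    outputs: List[str] = field(default_factory=list)
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.UTC).isoformat()
    )


def write_manifest(manifest: RunManifest, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(manifest), fh, indent=2, default=str)
        fh.write("\n")


def read_config(path) -> ModelParams:
    """Load simulator parameters from a flat YAML key-value file; keys
    mirror ModelParams field names, unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: config must be a flat key-value mapping")
    return ModelParams.from_dict(raw)


def _parse_metadata(line: str, meta: dict) -> None:
    body = line.lstrip("#").strip()
    if "=" in body:
        key, _, value = body.partition("=")
        meta[key.strip()] = value.strip()


def _split_row(line: str) -> List[str]:
    return line.split(",") if "," in line else line.split()


def read_spike_table(path) -> SpikeRecording:
    """Read a delimited spike table (see module docstring).

    Rows are sorted per electrode on load.  Missing duration metadata falls
    back to the latest spike time (logged as a warning); malformed rows
    raise :class:`ParseError` naming the line.
    """
    meta: dict = {}
    trains: Dict[str, list] = {}
    header_seen = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                _parse_metadata(line, meta)
                continue
            parts = _split_row(line)
            if not header_seen:
                if len(parts) < 2:
                    raise ParseError(f"{path}:{lineno}: expected a two-column header")
                header_seen = True
                continue
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected two columns")
            el = parts[0].strip()
            try:
                t = float(parts[1])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: spike time {parts[1]!r} is not a number"
                ) from None
            if t < 0:
                raise ParseError(f"{path}:{lineno}: negative spike time")
            trains.setdefault(el, []).append(t)
    if not header_seen and not meta:
        raise ParseError(f"{path}: empty spike table without metadata")
    duration = None
    for key in ("duration_s", "duration"):
        if key in meta:
            duration = float(meta[key])
            break
    max_t = max((max(v) for v in trains.values() if v), default=0.0)
    if duration is None:
        duration = max_t
        logger.warning(
            "%s: no duration metadata; using latest spike time %.3f s", path, duration
        )
    div = float(meta["div"]) if "div" in meta else None
    spikes = {el: np.sort(np.asarray(v, dtype=float)) for el, v in trains.items()}
    return SpikeRecording(spikes, duration=duration, div=div)


def write_spike_table(rec: SpikeRecording, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# duration_s = {float(rec.duration)!r}\n")
        if rec.div is not None:
            fh.write(f"# div = {float(rec.div)!r}\n")
        fh.write("electrode_id\tspike_time_s\n")
        for el in rec.electrodes:
            for t in rec.spikes[el]:
                fh.write(f"{el}\t{float(t)!r}\n")


def read_point_table(path) -> PointPattern:
    meta: dict = {}
    rows = []
    header_seen = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                _parse_metadata(line, meta)
                continue
            if not header_seen:
                header_seen = True
                continue
            parts = _split_row(line)
            try:
                rows.append([float(parts[-2]), float(parts[-1])])
            except (ValueError, IndexError):
                raise ParseError(f"{path}:{lineno}: expected numeric x y") from None
    if "domain_side_um" not in meta:
        raise ParseError(f"{path}: missing '# domain_side_um = ...' metadata")
    return PointPattern(
        np.asarray(rows, dtype=float),
        domain_side=float(meta["domain_side_um"]),
        d_min=float(meta.get("d_min_um", 0.0)),
    )


def write_point_table(pattern: PointPattern, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# domain_side_um = {float(pattern.domain_side)!r}\n")
        fh.write(f"# d_min_um = {float(pattern.d_min)!r}\n")
        fh.write("point_id\tx_um\ty_um\n")
        for i, (x, y) in enumerate(pattern.points):
            fh.write(f"{i}\t{float(x)!r}\t{float(y)!r}\n")


def read_weight_matrix(path) -> np.ndarray:
    w = np.loadtxt(path)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ParseError(f"{path}: weight matrix must be square")
    return w


def write_weight_matrix(w: np.ndarray, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, np.asarray(w, dtype=float), delimiter="\t")


def read_ca_pairs(path) -> np.ndarray:
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    cols = list(df.columns)
    if len(cols) < 2:
        raise ParseError(f"{path}: expected columns pfr_hz, amplitude_dff")
    arr = df[cols[:2]].to_numpy(dtype=float)
    return arr


def write_ca_pairs(pairs: np.ndarray, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(np.asarray(pairs), columns=["pfr_hz", "amplitude_dff"])
    df.to_csv(path, sep="\t", index=False)


def write_trajectory(traj: Trajectory, out_dir) -> List[Path]:
    """Write the time-series table and one snapshot table per recorded
    state (neuron_id, x_um, y_um, radius_um, state_x)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    series = pd.DataFrame({"t_min": traj.times, **traj.series})
    ts_path = out / "timeseries.tsv"
    series.to_csv(ts_path, sep="\t", index=False)
    written.append(ts_path)
    for t_min, state in traj.snapshots:
        snap = pd.DataFrame(
            {
                "neuron_id": np.arange(state.n),
                "x_um": state.positions[:, 0],
                "y_um": state.positions[:, 1],
                "radius_um": state.radii,
                "state_x": state.x,
            }
        )
        p = out / f"snapshot_t{int(round(t_min)):07d}min.tsv"
        snap.to_csv(p, sep="\t", index=False)
        written.append(p)
    return written


def write_sbe_table(sbes: List[SBEvent], path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "sbe_id": i,
            "core_start_s": e.core_start,
            "core_end_s": e.core_end,
            "ext_start_s": e.ext_start,
            "ext_end_s": e.ext_end,
            "n_sites": e.n_sites,
            "n_spikes": e.n_spikes,
        }
        for i, e in enumerate(sbes)
    ]
    pd.DataFrame(
        rows,
        columns=[
            "sbe_id", "core_start_s", "core_end_s", "ext_start_s",
            "ext_end_s", "n_sites", "n_spikes",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_stats_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
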