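"""Result serialization: stable CSV/JSON writers and reproducibility records."""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import SimulationConfig
from .dynamics import TrajectorySet
from .spatial import InteractionNetwork, NetworkStats

__all__ = ["RunRecord", "write_results", "trajectories_frame", "edge_list_frame"]


@dataclass(frozen=True)
class RunRecord:
    """Manifest of one run: config echo, seed, version, file checksums."""

    config: dict
    seed: int
    version: str
    started: str
    finished: str
    manifest: dict[str, str]  # path -> sha256 of contents

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def trajectories_frame(trajs: TrajectorySet) -> pd.DataFrame:
    """Tidy (time, individual_id, x) table of the measurement window."""
    n_t, n_i = trajs.values.shape
    return pd.DataFrame(
        {
            "time": np.repeat(np.arange(n_t), n_i),
            "individual_id": np.tile(np.arange(n_i), n_t),
            "x": trajs.values.ravel(),
        }
    )


def edge_list_frame(net: InteractionNetwork) -> pd.DataFrame:
    """Directed edge list with distances and reciprocity flags."""
    return pd.DataFrame(
        {
            "source_id": net.src,
            "target_id": net.dst,
            "distance": net.dist,
            "reciprocal_flag": net.reciprocal.astype(int),
        }
    )


def _stats_frame(stats: NetworkStats) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "n_leaders": stats.n_leaders,
                "n_followers": stats.n_followers,
                "leaders_per_follower": stats.leaders_per_follower,
                "reciprocal_per_participant": stats.reciprocal_per_participant,
                "n_central_followers": stats.n_central_followers,
                "n_components": len(stats.component_sizes),
                "largest_component": max(stats.component_sizes, default=0),
            }
        ]
    )


def write_results(
    tables: pd.DataFrame | TrajectorySet | NetworkStats | dict[str, pd.DataFrame],
    destination: str | Path,
    config: SimulationConfig | None = None,
    stem: str = "results",
) -> RunRecord:
    """Write CSV payload(s) plus a JSON run-metadata record.

    Accepts a tidy DataFrame, a :class:`TrajectorySet` (written as a
    trajectory CSV and an edge-list CSV), a :class:`NetworkStats`, or a
    dict of named DataFrames.  Column order is stable and floats are
    written with full ``repr`` precision, so re-running an identical
    config + seed reproduces byte-identical files.
    """
    destination = Path(destination)
    destination.mkdir(parents=True, exist_ok=True)
    started = _dt.datetime.now(_dt.timezone.utc).isoformat()

    frames: dict[str, pd.DataFrame]
    if isinstance(tables, TrajectorySet):
        frames = {
            f"{stem}_trajectories": trajectories_frame(tables),
            f"{stem}_edges": edge_list_frame(tables.network),
        }
        if config is None:
            config = tables.config
    elif isinstance(tables, NetworkStats):
        frames = {stem: _stats_frame(tables)}
    elif isinstance(tables, pd.DataFrame):
        frames = {stem: tables}
    else:
        frames = dict(tables)

    manifest: dict[str, str] = {}
    for name, frame in frames.items():
        path = destination / f"{name}.csv"
        frame.to_csv(path, index=False)
        manifest[path.name] = _sha256(path)

    record = RunRecord(
        config=config.to_dict() if config is not None else {},
        seed=config.seed if config is not None else -1,
        version=__version__,
        started=started,
        finished=_dt.datetime.now(_dt.timezone.utc).isoformat(),
        manifest=manifest,
    )
    meta_path = destination / f"{stem}_meta.json"
    meta_path.write_text(record.to_json() + "\n")
    return record
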