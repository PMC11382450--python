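"""Delimited-text table I/O and run manifests.

All tables are plain delimited text (TSV by default, CSV supported via the
``.csv`` extension), with a mandatory header row. Angles are serialized in
degrees with 6 decimal places and times in milliseconds. Vibrotactile-only
trials carry the explicit ``NA`` sentinel in the ``uncertainty_deg`` column.
Trajectories are stored long-format (trajectory_id, t_ms, x_mm, y_mm); a
one-file-per-trial directory layout is also readable.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path
from typing import Dict, Iterable, Optional

import numpy as np
import pandas as pd

from . import __version__
from .simulate import Trajectory

__all__ = [
    "write_table", "read_table", "write_trial_table", "read_trial_table",
    "write_trajectory_store", "read_trajectory_store", "read_trajectory_dir",
    "write_manifest", "file_checksum",
]

_FLOAT_FMT = "%.6f"


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_sep_for(path), index=False, float_format=_FLOAT_FMT,
              na_rep="NA")
    return path


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep=_sep_for(path), na_values=["NA"], **kwargs)


def write_trial_table(trials: pd.DataFrame, path: str | Path) -> Path:
    return write_table(trials, path)


def read_trial_table(path: str | Path) -> pd.DataFrame:
    df = read_table(path, dtype={"bar_angles_deg": str, "motor_pattern": str})
    for col in ("bar_angles_deg", "motor_pattern"):
        if col in df:
            df[col] = df[col].fillna("")
    return df


def write_trajectory_store(trajectories: Iterable[Trajectory], path: str | Path) -> Path:
    frames = [t.to_frame() for t in trajectories]
    table = (pd.concat(frames, ignore_index=True) if frames
             else pd.DataFrame(columns=["trajectory_id", "t_ms", "x_mm", "y_mm"]))
    return write_table(table, path)


def _store_from_long(table: pd.DataFrame) -> Dict[str, Trajectory]:
    out: Dict[str, Trajectory] = {}
    for tid, g in table.groupby("trajectory_id", sort=False):
        g = g.sort_values("t_ms")
        out[str(tid)] = Trajectory(str(tid), g["t_ms"].to_numpy(float),
                                   g["x_mm"].to_numpy(float),
                                   g["y_mm"].to_numpy(float))
    return out


def read_trajectory_store(path: str | Path) -> Dict[str, Trajectory]:
    """Read a long-format trajectory table into a trajectory_id -> Trajectory map."""
    return _store_from_long(read_table(path))


def read_trajectory_dir(directory: str | Path) -> Dict[str, Trajectory]:
    """Read a directory of one-file-per-trial trajectory tables.

    Each file holds t_ms, x_mm, y_mm columns; the trajectory id is the stem.
    """
    out: Dict[str, Trajectory] = {}
    for path in sorted(Path(directory).glob("*.[tc]sv")):
        g = read_table(path)
        out[path.stem] = Trajectory(path.stem, g["t_ms"].to_numpy(float),
                                    g["x_mm"].to_numpy(float),
                                    g["y_mm"].to_numpy(float))
    return out


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: str | Path, config: dict, seed: Optional[int],
                   stage: str, files: Iterable[str | Path]) -> Path:
    """Write/extend the run manifest with config snapshot, seed, package
    version, stage timestamp and output checksums."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.json"
    manifest = {}
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
    manifest.setdefault("package_version", __version__)
    manifest.setdefault("config", config)
    if seed is not None:
        manifest["seed"] = seed
    stages = manifest.setdefault("stages", {})
    stages[stage] = {
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "files": {str(Path(f).name): file_checksum(f) for f in files},
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path
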