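"""Output writers: timeseries CSV, summary/fit JSON, manifests, grid snapshots."""

from __future__ import annotations

import json
import platform
import time
from pathlib import Path
from typing import Any, Dict, Sequence

import numpy as np
import pandas as pd

from .config import config_to_dict
from .engine import ScenarioConfig, SimulationResult

__all__ = [
    "write_timeseries",
    "write_summary",
    "write_manifest",
    "write_snapshot",
    "read_measurements",
    "write_measurements",
]


def write_timeseries(result: SimulationResult, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    result.timeseries.to_csv(path, index=False)
    return path


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_summary(summary: Dict[str, Any], path: str | Path) -> Path:
    """Experiment summary JSON (replicate result objects are not serialised)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    clean = {k: _jsonable(v) for k, v in summary.items() if k != "results"}
    path.write_text(json.dumps(clean, indent=2))
    return path


def write_manifest(
    config: ScenarioConfig,
    base_seed: int,
    replicate_seeds: Sequence[int],
    outputs: Sequence[str],
    path: str | Path,
) -> Path:
    """Run manifest: enough to regenerate every output file exactly."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest = {
        "code_version": __version__,
        "base_seed": int(base_seed),
        "replicate_seeds": [int(s) for s in replicate_seeds],
        "config": _jsonable(config_to_dict(config)),
        "outputs": list(outputs),
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "platform": platform.platform(),
    }
    path.write_text(json.dumps(manifest, indent=2))
    return path


def write_snapshot(grid: np.ndarray, meta: Dict[str, Any], path: str | Path) -> Path:
    """Plain-text grid snapshot (one count per site) with a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, grid, fmt="%d")
    Path(str(path) + ".json").write_text(json.dumps(_jsonable(meta), indent=2))
    return path


def read_measurements(path: str | Path):
    """Caliper measurement CSV -> list of GrowthMeasurement (columns day, diameter_mm)."""
    from .tumor_growth import GrowthMeasurement

    df = pd.read_csv(path)
    missing = {"day", "diameter_mm"} - set(df.columns)
    if missing:
        raise ValueError(f"measurement CSV must have columns day, diameter_mm; missing {missing}")
    return [GrowthMeasurement(time=float(r.day), diameter=float(r.diameter_mm)) for r in df.itertuples()]


def write_measurements(series, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"day": [m.time for m in series], "diameter_mm": [m.diameter for m in series]}).to_csv(
        path, index=False
    )
    return path
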