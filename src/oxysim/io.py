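"""Plain-text I/O: spike-time files, CSV tables and run manifests.

Spike trains are newline-delimited seconds with 6 decimal places
(microsecond resolution); ``#``-prefixed comment lines are allowed.
"""

from __future__ import annotations

import json
import platform
import sys
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Any, Union

import numpy as np
import pandas as pd

from .spiking import SpikeTrain

__all__ = [
    "write_spike_train",
    "read_spike_train",
    "write_csv",
    "write_manifest",
]


def write_spike_train(train: SpikeTrain, path: Union[str, Path]) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# spike times in seconds, duration={train.duration:.6f}\n")
        for t in train.times:
            fh.write(f"{t:.6f}\n")


def read_spike_train(path: Union[str, Path],
                     duration: float | None = None) -> SpikeTrain:
    """Read a spike-time file; duration defaults to the header value or
    the last spike time."""
    path = Path(path)
    times = []
    header_duration = None
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "duration=" in line and header_duration is None:
                try:
                    header_duration = float(line.split("duration=")[1])
                except ValueError:
                    pass
            continue
        times.append(float(line))
    arr = np.asarray(times)
    if duration is None:
        duration = header_duration if header_duration is not None else \
            (float(arr[-1]) if arr.size else 0.0)
    return SpikeTrain(times=arr, duration=duration)


def write_csv(frame: pd.DataFrame, path: Union[str, Path]) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format="%.6g")


def _jsonable(obj: Any) -> Any:
    if is_dataclass(obj) and not isinstance(obj, type):
        return asdict(obj)
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_manifest(path: Union[str, Path], *, command: str,
                   seed: int | None, config: dict) -> None:
    """Record the effective configuration of a run next to its outputs."""
    from . import __version__

    payload = {
        "command": command,
        "seed": seed,
        "config": {k: _jsonable(v) for k, v in config.items()},
        "versions": {
            "oxysim": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "platform": platform.platform(),
        },
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable)
                          + "\n")
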