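"""Plain-text readers and writers for the pipeline's tables.

Waveform families travel as delimited tables (column 1 ``time_s``, one
column per flash named ``dark_-5.01``, ``light_2.72``, ...) with a JSON
sidecar holding acquisition metadata. Thickness grids use a long-form table
(x_mm, y_mm, layer, thickness_um). Results serialize to JSON with full
provenance.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .ergsim import ERGWaveform, FlashStimulus, Timebase, WaveformFamily
from .errors import ProtocolError
from .octthick import LAYERS, ThicknessGrid


def _flash_column(stim: FlashStimulus) -> str:
    return f"{stim.adaptation}_{stim.log_energy:g}"


def write_waveform_table(family: WaveformFamily, path: str | Path,
                         metadata: dict | None = None) -> None:
    """Write a family as CSV plus a ``<path>.meta.json`` sidecar."""
    path = Path(path)
    tb = family.timebase
    table = {"time_s": tb.times()}
    for wave in family:
        table[_flash_column(wave.stimulus)] = wave.samples
    pd.DataFrame(table).to_csv(path, index=False)
    meta = {"sampling_rate": tb.sampling_rate, "duration": tb.duration,
            "onset_index": tb.onset_index}
    if metadata:
        meta.update(metadata)
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2, default=_jsonable))


def read_waveform_table(path: str | Path) -> WaveformFamily:
    path = Path(path)
    table = pd.read_csv(path)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        tb = Timebase(meta["sampling_rate"], meta["duration"],
                      meta["onset_index"])
    else:  # fall back to the time column
        dt = float(np.median(np.diff(table["time_s"])))
        tb = Timebase(1.0 / dt, dt * len(table), 0)
    waves = []
    for column in table.columns:
        if column == "time_s":
            continue
        try:
            adaptation, log_e = column.rsplit("_", 1)
            stim = FlashStimulus(float(log_e), adaptation)
        except ValueError as exc:
            raise ProtocolError(f"cannot parse flash column {column!r}") from exc
        waves.append(ERGWaveform(tb, stim, table[column].to_numpy()))
    return WaveformFamily(waves)


def write_thickness_grid(grid: ThicknessGrid, path: str | Path) -> None:
    xx, yy = np.meshgrid(grid.x, grid.y)
    frames = []
    for layer, values in grid.layers.items():
        frames.append(pd.DataFrame({
            "x_mm": xx.ravel(), "y_mm": yy.ravel(),
            "layer": layer, "thickness_um": values.ravel()}))
    pd.concat(frames).to_csv(path, index=False)


def read_thickness_grid(path: str | Path) -> ThicknessGrid:
    table = pd.read_csv(path)
    x = np.unique(table["x_mm"])
    y = np.unique(table["y_mm"])
    layers = {}
    for layer, sub in table.groupby("layer"):
        grid = (sub.pivot_table(index="y_mm", columns="x_mm",
                                values="thickness_um")
                .reindex(index=y, columns=x))
        layers[layer] = grid.to_numpy()
    return ThicknessGrid(x, y, layers)


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="index"))
    if isinstance(obj, dict):
        return {str(k): v for k, v in obj.items()}
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def dump_json(obj: Any, path: str | Path) -> None:
    """Serialize results (dataclasses, arrays, frames) to pretty JSON."""
    Path(path).write_text(json.dumps(_sanitize(obj), indent=2, default=_jsonable))


def _sanitize(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {(k if isinstance(k, str) else "_".join(map(str, np.atleast_1d(k)))):
                _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj
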