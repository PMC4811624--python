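"""Reading and writing GAW files, peak tables, reports and frame stacks."""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np

from .errors import ConfigError, ParseError
from .peaks import Peak
from .signal import GAWSignal

__all__ = ["read_gaw", "write_gaw", "write_peaks", "write_json",
           "read_frames", "write_frames"]

_SPLIT = re.compile(r"[,;\t ]+")
#: tolerated relative jitter of the sampling interval
_MAX_JITTER = 0.01


def read_gaw(path, fps: float | None = None) -> GAWSignal:
    """Read a GAW from delimited text.

    Two numeric columns are interpreted as (time_ms, area) with the frame
    rate inferred from the median sampling interval; one column is the bare
    area and requires ``fps``.  A header line is skipped if present.
    """
    path = Path(path)
    times, areas = [], []
    ncol = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = [f for f in _SPLIT.split(line.strip()) if f]
            if not fields or line.lstrip().startswith("#"):
                continue
            try:
                vals = [float(f) for f in fields]
            except ValueError:
                if lineno == 1:   # header
                    continue
                raise ParseError(f"non-numeric row in {path.name}", line=lineno)
            if ncol is None:
                ncol = len(vals)
            elif len(vals) != ncol:
                raise ParseError(f"inconsistent column count in {path.name}", line=lineno)
            if ncol == 1:
                areas.append(vals[0])
            elif ncol == 2:
                times.append(vals[0])
                areas.append(vals[1])
            else:
                raise ParseError(f"expected 1 or 2 columns, got {ncol}", line=lineno)
    if not areas:
        raise ParseError(f"no data rows in {path}")

    if ncol == 2:
        dt = np.diff(np.asarray(times))
        med = float(np.median(dt))
        if med <= 0:
            raise ParseError("time column is not increasing")
        if np.max(np.abs(dt - med)) > _MAX_JITTER * med:
            raise ParseError("nonuniform sampling: interval jitter exceeds 1%")
        inferred = 1000.0 / med     # time column in ms
        fps = fps if fps is not None else inferred
    elif fps is None:
        raise ConfigError("a 1-column GAW file requires an explicit fps")
    return GAWSignal(np.asarray(areas), fps)


def write_gaw(path, gaw: GAWSignal) -> None:
    """Write (time_ms, area) as CSV."""
    arr = np.column_stack([gaw.times_ms, gaw.values])
    np.savetxt(path, arr, fmt="%.6f", delimiter=",", header="time_ms,area", comments="")


def write_peaks(path, peaks: list[Peak]) -> None:
    with Path(path).open("w") as fh:
        fh.write("time_ms\tamplitude\tpreceded_by_closure\n")
        for p in peaks:
            fh.write(f"{p.time_ms:.6f}\t{p.amplitude:.6f}\t{int(p.preceded_by_closure)}\n")


def write_json(path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def read_frames(path) -> np.ndarray:
    """Read a frame stack from a directory of PNG/TIFF files or a multi-page TIFF."""
    import imageio.v3 as iio

    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".png", ".tif", ".tiff"))
        if not files:
            raise ParseError(f"no PNG/TIFF frames in {path}")
        return np.stack([iio.imread(f) for f in files])
    frames = iio.imread(path)
    return frames if frames.ndim == 3 else frames[None]


def write_frames(outdir, frames: np.ndarray) -> None:
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(frames):
        iio.imwrite(outdir / f"frame_{i:06d}.png", frame)
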