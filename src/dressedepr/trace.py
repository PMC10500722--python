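"""The ``Trace`` container and its plain-text file format.

A trace is a uniformly or non-uniformly sampled time-domain signal (a
dressed-echo modulation curve or a relaxation decay) together with the
metadata needed to regenerate it.  Files are two-column ASCII (time,
amplitude; optional third column for an imaginary part) with ``#``-prefixed
header lines carrying a JSON metadata object, e.g.::

    # dressedepr-trace {"schema": 1, "units": {"time": "us", "amplitude": "a.u."}, ...}
    0.000000e+00 1.000000e+00
    ...

Legacy bare two-column files are accepted with warned defaults (µs,
dimensionless).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

__all__ = ["Trace", "TraceParseError", "read_trace", "write_trace"]

_MAGIC = "dressedepr-trace"
_SCHEMA = 1


class TraceParseError(ValueError):
    """Raised when a trace file cannot be parsed; carries the line number."""


@dataclass
class Trace:
    """A sampled time-domain signal with axis metadata.

    ``time`` is in µs (strictly increasing); ``amplitude`` is real or
    complex, dimensionless unless metadata says otherwise.  ``meta`` holds
    generating parameters, units and seeds.
    """

    time: np.ndarray
    amplitude: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.amplitude = np.asarray(self.amplitude)
        if self.time.ndim != 1 or self.amplitude.shape != self.time.shape:
            raise ValueError("time and amplitude must be 1-D arrays of equal length")
        if self.time.size >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time axis must be strictly increasing")
        self.meta.setdefault("units", {"time": "us", "amplitude": "a.u."})

    @property
    def dt(self) -> float:
        """Grid spacing; raises if the grid is not uniform to 1 ppm."""
        steps = np.diff(self.time)
        if steps.size == 0:
            raise ValueError("trace has fewer than two points")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=0.0):
            raise ValueError("time grid is not uniform")
        return float(steps[0])

    def normalized(self) -> "Trace":
        """Amplitude scaled so the first point is 1 (complex-safe)."""
        a0 = self.amplitude[0]
        if a0 == 0:
            raise ValueError("cannot normalize: first amplitude is zero")
        return Trace(self.time.copy(), self.amplitude / a0, dict(self.meta))


def write_trace(trace: Trace, path: str | Path) -> None:
    """Write a trace losslessly (17 significant digits) with JSON header."""
    path = Path(path)
    meta = dict(trace.meta)
    meta["schema"] = _SCHEMA
    is_complex = np.iscomplexobj(trace.amplitude)
    meta["columns"] = (["time", "real", "imag"] if is_complex
                       else ["time", "amplitude"])
    lines = [f"# {_MAGIC} {json.dumps(meta, sort_keys=True)}"]
    for i, t in enumerate(trace.time):
        a = trace.amplitude[i]
        if is_complex:
            lines.append(f"{t:.17e} {a.real:.17e} {a.imag:.17e}")
        else:
            lines.append(f"{t:.17e} {float(a):.17e}")
    path.write_text("\n".join(lines) + "\n")


def read_trace(path: str | Path) -> Trace:
    """Read a trace file; bare two-column files get warned defaults."""
    path = Path(path)
    meta: dict[str, Any] | None = None
    times: list[float] = []
    cols: list[list[float]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith(_MAGIC):
                payload = body[len(_MAGIC):].strip()
                try:
                    meta = json.loads(payload)
                except json.JSONDecodeError as exc:
                    raise TraceParseError(
                        f"{path}:{lineno}: malformed JSON header: {exc}") from exc
                if "units" not in meta:
                    raise TraceParseError(
                        f"{path}:{lineno}: header missing required 'units'")
            continue
        parts = line.split()
        if len(parts) not in (2, 3):
            raise TraceParseError(
                f"{path}:{lineno}: expected 2 or 3 numeric columns, got {len(parts)}")
        try:
            vals = [float(p) for p in parts]
        except ValueError as exc:
            raise TraceParseError(f"{path}:{lineno}: non-numeric value") from exc
        times.append(vals[0])
        cols.append(vals[1:])
    if not times:
        raise TraceParseError(f"{path}: no data rows")
    if meta is None:
        warnings.warn(
            f"{path}: no metadata header; assuming time in us, amplitude dimensionless",
            stacklevel=2)
        meta = {"units": {"time": "us", "amplitude": "a.u."}, "schema": _SCHEMA}
    ncols = {len(c) for c in cols}
    if len(ncols) != 1:
        raise TraceParseError(f"{path}: inconsistent column counts {sorted(ncols)}")
    arr = np.asarray(cols, dtype=float)
    amp = arr[:, 0] + 1j * arr[:, 1] if arr.shape[1] == 2 else arr[:, 0]
    meta.pop("columns", None)
    return Trace(np.asarray(times), amp, meta)
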