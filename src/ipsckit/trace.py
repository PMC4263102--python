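"""Uniformly sampled current traces and their on-disk formats.

A :class:`Trace` is the package's basic container: a current time series in
pA sampled at a fixed interval ``dt`` (ms).  The default acquisition
emulated throughout is 10 kHz sampling (``dt = 0.1`` ms) with a 3-kHz
low-pass front end.

Two interchange formats are supported:

* two-column delimited text ``time_ms<TAB>current_pA``;
* a compact binary container (magic ``IPTR``) with a fixed header holding
  ``dt``, ``t0``, sample count and a units tag, followed by float64 samples.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace

import numpy as np

_MAGIC = b"IPTR"
_HEADER = struct.Struct("<4sHddq8s")  # magic, version, dt, t0, n, units


@dataclass
class Trace:
    """Uniformly sampled signal: current (pA) or conductance (nS) vs time (ms)."""

    samples: np.ndarray
    dt: float = 0.1
    t0: float = 0.0
    units: str = "pA"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        """Span covered by the samples in ms."""
        return len(self.samples) * self.dt

    def time(self) -> np.ndarray:
        """Sample times in ms."""
        return self.t0 + self.dt * np.arange(len(self.samples))

    def copy(self) -> "Trace":
        return replace(self, samples=self.samples.copy())

    def index_at(self, t_ms: float) -> int:
        """Index of the sample nearest to time ``t_ms`` (clipped to range)."""
        i = int(round((t_ms - self.t0) / self.dt))
        return min(max(i, 0), len(self.samples) - 1)

    def segment(self, start_ms: float, stop_ms: float) -> "Trace":
        """Sub-trace covering [start_ms, stop_ms)."""
        i0 = self.index_at(start_ms)
        i1 = self.index_at(stop_ms)
        return Trace(self.samples[i0:i1 + 1].copy(), self.dt,
                     self.t0 + i0 * self.dt, self.units)


def write_trace_text(trace: Trace, path) -> None:
    """Write a trace as two-column delimited text (time_ms, value)."""
    data = np.column_stack([trace.time(), trace.samples])
    np.savetxt(path, data, fmt="%.9g", delimiter="\t",
               header=f"time_ms\t{trace.units}", comments="# ")


def read_trace_text(path, units: str = "pA") -> Trace:
    """Read a two-column text trace; dt is inferred and checked for uniformity."""
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("expected two columns (time, value)")
    t, y = data[:, 0], data[:, 1]
    if len(t) < 2:
        raise ValueError("need at least two samples to infer dt")
    dts = np.diff(t)
    dt = float(np.median(dts))
    if not np.allclose(dts, dt, rtol=1e-6, atol=1e-9 * max(dt, 1.0)):
        raise ValueError("time column is not uniformly sampled")
    return Trace(y, dt=dt, t0=float(t[0]), units=units)


def write_trace_bin(trace: Trace, path) -> None:
    """Write the compact binary container (header + float64 samples)."""
    units = trace.units.encode()[:8].ljust(8, b"\x00")
    header = _HEADER.pack(_MAGIC, 1, trace.dt, trace.t0, len(trace.samples), units)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(np.ascontiguousarray(trace.samples, dtype="<f8").tobytes())


def read_trace_bin(path) -> Trace:
    with open(path, "rb") as fh:
        header = fh.read(_HEADER.size)
        magic, version, dt, t0, n, units = _HEADER.unpack(header)
        if magic != _MAGIC:
            raise ValueError("not an IPTR trace file")
        if version != 1:
            raise ValueError(f"unsupported IPTR version {version}")
        samples = np.frombuffer(fh.read(8 * n), dtype="<f8", count=n)
    return Trace(samples.copy(), dt=dt, t0=t0, units=units.rstrip(b"\x00").decode())
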