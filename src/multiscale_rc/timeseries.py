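"""Uniformly sampled multivariate time series container.

The container deliberately stays thin: a ``(T, n)`` value matrix, a start
time, a fixed sampling step and optional column names.  CSV round-trips go
through :mod:`pandas`; binary round-trips use :func:`numpy.savez_compressed`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TimeSeries", "read_timeseries", "write_timeseries"]

_TIME_RTOL = 1e-6


@dataclass
class TimeSeries:
    """A uniformly sampled trajectory.

    Parameters
    ----------
    values : ndarray of shape (T, n)
        One row per sample, one column per state dimension.
    dt : float
        Sampling step in model time units; must be positive.
    t0 : float
        Time of the first row.
    names : list of str, optional
        Column labels; defaults to ``u1 ... un``.
    """

    values: np.ndarray
    dt: float
    t0: float = 0.0
    names: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.ndim != 2:
            raise ValueError("values must be a (T, n) matrix")
        if self.values.shape[0] == 1 and self.values.shape[1] > 1 and self.names is None:
            # a 1-D vector passed in: interpret as a single column
            self.values = self.values.T
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.values.shape[0] < 1:
            raise ValueError("a time series needs at least one sample")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")
        if self.names is None:
            self.names = [f"u{i + 1}" for i in range(self.values.shape[1])]
        if len(self.names) != self.values.shape[1]:
            raise ValueError("number of names does not match number of columns")

    # -- basic geometry -------------------------------------------------
    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def n_dim(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self))

    def window(self, start: int, stop: int) -> "TimeSeries":
        """Sub-series of rows ``start:stop`` with the time origin shifted."""
        if not (0 <= start < stop <= len(self)):
            raise IndexError(
                f"window [{start}, {stop}) outside series of length {len(self)}"
            )
        return TimeSeries(
            self.values[start:stop].copy(),
            dt=self.dt,
            t0=self.t0 + start * self.dt,
            names=list(self.names),
        )

    def column(self, i: int) -> np.ndarray:
        return self.values[:, i]

    # -- I/O -------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.names)
        frame.insert(0, "time", self.times)
        return frame

    def to_csv(self, path) -> None:
        # pandas' default float formatting is the shortest round-trippable
        # representation, so the CSV is lossless at double precision
        self.to_frame().to_csv(path, index=False)

    def to_npz(self, path) -> None:
        np.savez_compressed(
            path,
            values=self.values,
            dt=np.float64(self.dt),
            t0=np.float64(self.t0),
            names=np.array(self.names),
        )

    @classmethod
    def from_npz(cls, path) -> "TimeSeries":
        with np.load(path, allow_pickle=False) as payload:
            return cls(
                payload["values"],
                dt=float(payload["dt"]),
                t0=float(payload["t0"]),
                names=[str(s) for s in payload["names"]],
            )

    @classmethod
    def from_csv(cls, path, dt: float | None = None) -> "TimeSeries":
        frame = pd.read_csv(path, float_precision="round_trip")
        if frame.shape[0] < 1:
            raise ValueError(f"{path}: empty table")
        cols = list(frame.columns)
        if cols and cols[0].lower() == "time":
            t = frame.iloc[:, 0].to_numpy(dtype=float)
            if len(t) > 1:
                steps = np.diff(t)
                step = np.median(steps)
                bad = np.nonzero(~np.isclose(steps, step, rtol=_TIME_RTOL, atol=0))[0]
                if bad.size:
                    raise ValueError(
                        f"{path}: time column is not uniformly spaced "
                        f"(first offending row: {int(bad[0]) + 3})"
                    )
            else:
                step = dt if dt is not None else 1.0
            return cls(
                frame.iloc[:, 1:].to_numpy(dtype=float),
                dt=float(step),
                t0=float(t[0]),
                names=cols[1:],
            )
        # no time column: caller supplies dt (defaults to step counting)
        return cls(
            frame.to_numpy(dtype=float),
            dt=1.0 if dt is None else float(dt),
            t0=0.0,
            names=cols,
        )


def read_timeseries(path, fmt: str = "csv", dt: float | None = None) -> TimeSeries:
    if fmt == "csv":
        return TimeSeries.from_csv(path, dt=dt)
    if fmt == "binary":
        return TimeSeries.from_npz(path)
    raise ValueError(f"unknown time-series format: {fmt!r}")


def write_timeseries(series: TimeSeries, path, fmt: str = "csv"):
    if fmt == "csv":
        series.to_csv(path)
    elif fmt == "binary":
        series.to_npz(path)
    else:
        raise ValueError(f"unknown time-series format: {fmt!r}")
    return path
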