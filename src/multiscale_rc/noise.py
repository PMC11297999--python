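"""Separation of the fast-scale residual and sampleable noise models.

Once a slow-scale model is trained, the one-step teacher-forced
prediction error

.. math:: \\eta_{t+1} = u_{t+1} - \\tilde u_{t+1}

isolates the fast component of the signal.  For white (memoryless)
forcing the residual rows form an empirical pool that is resampled with
replacement during rolling prediction; for colored forcing a second
echo-state network is trained on the residual series itself and run
closed-loop to extrapolate the noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reservoir import EchoStateNetwork, ReservoirConfig
from .timeseries import TimeSeries

__all__ = [
    "NoiseModel",
    "separate_noise",
    "sample_noise",
    "fit_noise_reservoir",
    "calibrate_amplification",
]


@dataclass
class NoiseModel:
    """Sampleable model of the separated fast-scale residual.

    ``amplification`` rescales every draw; it compensates a separated
    noise intensity that is systematically lower or higher than the true
    fast-scale intensity (an imperfect slow model biases the residual
    scale).
    """

    mode: str                       # "empirical" | "reservoir"
    residuals: np.ndarray           # (M, n) stored residual rows
    amplification: float = 1.0
    noise_esn: EchoStateNetwork | None = None
    seed: int = 0

    def __post_init__(self):
        self.residuals = np.atleast_2d(np.asarray(self.residuals, dtype=float))
        if self.mode not in ("empirical", "reservoir"):
            raise ValueError(f"unknown noise-model mode: {self.mode!r}")
        if self.residuals.shape[0] < 1:
            raise ValueError("the residual pool must contain at least one row")
        if self.amplification <= 0:
            raise ValueError("amplification must be positive")
        if self.mode == "reservoir" and (
            self.noise_esn is None or not self.noise_esn.is_trained
        ):
            raise ValueError("reservoir mode requires a trained noise network")

    @property
    def n_dim(self) -> int:
        return self.residuals.shape[1]


def separate_noise(
    esn: EchoStateNetwork, series: TimeSeries
) -> tuple[TimeSeries, TimeSeries]:
    """Split ``series`` into slow-scale prediction and fast-scale residual.

    Teacher-forces the trained network over the whole series from the
    zero state; the one-step predictions form the smooth component on
    steps ``1..T`` and the residual is their exact elementwise
    complement, so ``smooth + residual`` reconstructs the input.
    """
    if not esn.is_trained:
        raise RuntimeError("separate_noise requires a trained network")
    if len(series) < 2:
        raise ValueError("series must contain at least two samples")
    R, _ = esn._drive(series.values[:-1])
    smooth_vals = (esn.W_out @ R).T
    resid_vals = series.values[1:] - smooth_vals
    smooth = TimeSeries(smooth_vals, dt=series.dt, t0=series.t0 + series.dt,
                        names=list(series.names))
    residual = TimeSeries(resid_vals, dt=series.dt, t0=series.t0 + series.dt,
                          names=list(series.names))
    return smooth, residual


def sample_noise(model: NoiseModel, n_draws: int, seed: int = 0) -> np.ndarray:
    """Draw whole residual rows i.i.d. with replacement, scaled by gamma.

    Rows (not individual coordinates) are resampled so that the
    instantaneous cross-dimensional dependence of the fast component is
    preserved in multivariate systems.
    """
    if model.mode != "empirical":
        raise ValueError("sample_noise requires an empirical noise model")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, model.residuals.shape[0], size=n_draws)
    return model.amplification * model.residuals[idx]


def fit_noise_reservoir(
    residual: TimeSeries,
    config: ReservoirConfig,
    window: tuple[int, int] | None = None,
    amplification: float = 1.0,
) -> NoiseModel:
    """Train a second reservoir on (a window of) the residual series.

    The network learns the residual one step ahead with the same
    pipeline as the slow-scale model; after training, its stored state
    continues the windowed residual autonomously.  The window is given
    in step indices of ``residual``; it defaults to the whole series.
    """
    if window is None:
        window = (0, len(residual))
    start, stop = window
    if not (0 <= start < stop <= len(residual)):
        raise IndexError(f"window {window} outside residual series of length {len(residual)}")
    segment = residual.window(start, stop)
    washout = (
        config.washout if config.washout is not None else min(100, (len(segment) - 1) // 10)
    )
    if len(segment) < washout + 2:
        raise ValueError("residual window too short for the configured washout")
    esn = EchoStateNetwork(config, n_inputs=residual.n_dim)
    esn.train(segment)
    return NoiseModel(
        mode="reservoir",
        residuals=segment.values,
        amplification=amplification,
        noise_esn=esn,
        seed=config.seed,
    )


def calibrate_amplification(series: TimeSeries, residual: TimeSeries) -> float:
    """Noise amplification factor from the one-step increment scale.

    For small sampling steps the one-step increments of the data are
    dominated by the fast component, so the ratio of the data's
    increment scale to the residual scale estimates how far the
    separated noise intensity deviates from the true one.  The returned
    factor rescales resampled residuals back to the data's fast-scale
    intensity.
    """
    inc = np.diff(series.values, axis=0)
    num = float(np.linalg.norm(inc.std(axis=0)))
    den = float(np.linalg.norm(residual.values.std(axis=0)))
    if den == 0:
        raise ValueError("residual has zero variance; nothing to calibrate")
    return num / den
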