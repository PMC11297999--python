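"""Closed-loop generation: autonomous runs, stochastic rolling prediction
and the dual-reservoir colored-noise forecast.

In every mode the network's own output is fed back as the next input.
The rolling prediction implements

.. math:: \\hat u_{s+1} = \\tilde u_{s+1} + \\gamma\\, \\eta_{s+1}

with :math:`\\eta` drawn from the separated noise pool (white noise) or
produced by the autonomous continuation of a second reservoir (colored
noise).  The noisy value — not the clean readout — is fed back, so the
generated path explores the state space the way the data does.

Fed-back inputs are confined to the training support of the slow-scale
model (elementwise clamping to the observed data range): beyond that
support the readout is an uncontrolled extrapolation, and a single large
noise draw could otherwise hand the closed loop to a spurious attractor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .noise import NoiseModel
from .reservoir import EchoStateNetwork
from .timeseries import TimeSeries

__all__ = [
    "ForecastResult",
    "predict_autonomous",
    "rolling_predict",
    "predict_colored",
    "run_ensemble",
]


@dataclass
class ForecastResult:
    """Prediction plus optional per-step noise draws and ensemble data."""

    prediction: TimeSeries
    noise_draws: TimeSeries | None = None
    ensemble: list[TimeSeries] = field(default_factory=list)
    mean_trajectory: TimeSeries | None = None
    abs_error: TimeSeries | None = None


def _sync_state(esn: EchoStateNetwork, u_start: np.ndarray, n_sync: int) -> np.ndarray:
    """Re-synchronise the reservoir by teacher forcing a constant input."""
    r = np.zeros(esn.config.n_nodes)
    for _ in range(n_sync):
        r = esn.step(r, u_start)
    return r


def _clamp(esn: EchoStateNetwork, u: np.ndarray, enabled: bool) -> np.ndarray:
    if enabled and esn.input_range is not None:
        return np.clip(u, esn.input_range[0], esn.input_range[1])
    return u


def _resolve_state(esn, u_start, r0, n_sync):
    u = np.atleast_1d(np.asarray(u_start, dtype=float))
    if r0 is not None:
        return u, r0.copy()
    return u, _sync_state(esn, u, n_sync)


def predict_autonomous(
    esn: EchoStateNetwork,
    u_start,
    n_steps: int,
    dt: float = 1.0,
    r0: np.ndarray | None = None,
    n_sync: int = 100,
    clamp: bool = True,
) -> TimeSeries:
    """Noise-free closed loop from ``u_start``.

    When no explicit reservoir state ``r0`` is given, the state is
    re-synchronised by teacher forcing ``n_sync`` repeats of the start
    value (the zero state would make the first readouts depend on an
    arbitrary initialisation).
    """
    if not esn.is_trained:
        raise RuntimeError("predict_autonomous requires a trained network")
    if n_steps == 0:
        return _empty_series(esn.n_inputs, dt)
    u, r = _resolve_state(esn, u_start, r0, n_sync)
    out = np.empty((n_steps, esn.n_inputs))
    for s in range(n_steps):
        r = esn.step(r, u)
        u = _clamp(esn, esn.readout(r), clamp)
        out[s] = u
    return TimeSeries(out, dt=dt, t0=dt)


def _empty_series(n_dim: int, dt: float) -> TimeSeries:
    ts = TimeSeries(np.zeros((1, n_dim)), dt=dt)
    ts.values = np.empty((0, n_dim))
    return ts


def rolling_predict(
    esn: EchoStateNetwork,
    noise: NoiseModel,
    u_start,
    n_steps: int,
    seed: int = 0,
    dt: float = 1.0,
    r0: np.ndarray | None = None,
    n_sync: int = 100,
    clamp: bool = True,
) -> ForecastResult:
    """Stochastic rolling prediction with empirically resampled noise."""
    if not esn.is_trained:
        raise RuntimeError("rolling_predict requires a trained network")
    if noise.mode != "empirical":
        raise ValueError("rolling_predict requires an empirical noise model")
    u, r = _resolve_state(esn, u_start, r0, n_sync)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, noise.residuals.shape[0], size=n_steps)
    draws = noise.amplification * noise.residuals[idx]
    out = np.empty((n_steps, esn.n_inputs))
    for s in range(n_steps):
        r = esn.step(r, u)
        u = _clamp(esn, esn.readout(r) + draws[s], clamp)
        out[s] = u
    prediction = TimeSeries(out, dt=dt, t0=dt)
    return ForecastResult(
        prediction=prediction,
        noise_draws=TimeSeries(draws, dt=dt, t0=dt),
    )


def predict_colored(
    esn_det: EchoStateNetwork,
    noise_model: NoiseModel,
    u_start,
    n_steps: int,
    dt: float = 1.0,
    r0_det: np.ndarray | None = None,
    n_sync: int = 100,
    clamp: bool = True,
) -> ForecastResult:
    """Dual-reservoir forecast for temporally correlated noise.

    The noise reservoir continues the residual series closed-loop from
    its post-training state; its output is added to the deterministic
    readout at every step and the sum is fed back.  Fully deterministic
    given the two trained networks.
    """
    if not esn_det.is_trained:
        raise RuntimeError("predict_colored requires a trained slow-scale network")
    if noise_model.mode != "reservoir" or noise_model.noise_esn is None:
        raise ValueError("predict_colored requires a reservoir-mode noise model")
    esn_noise = noise_model.noise_esn
    if not esn_noise.is_trained:
        raise RuntimeError("the noise reservoir is untrained")

    u, r_det = _resolve_state(esn_det, u_start, r0_det, n_sync)
    r_noise = esn_noise.r.copy()
    eta = noise_model.residuals[-1].copy()
    gamma = noise_model.amplification
    out = np.empty((n_steps, esn_det.n_inputs))
    draws = np.empty((n_steps, esn_det.n_inputs))
    for s in range(n_steps):
        r_det = esn_det.step(r_det, u)
        r_noise = esn_noise.step(r_noise, eta)
        eta = esn_noise.readout(r_noise)
        draws[s] = gamma * eta
        u = _clamp(esn_det, esn_det.readout(r_det) + gamma * eta, clamp)
        out[s] = u
    return ForecastResult(
        prediction=TimeSeries(out, dt=dt, t0=dt),
        noise_draws=TimeSeries(draws, dt=dt, t0=dt),
    )


def run_ensemble(
    pipeline,
    n_replicates: int,
    seeds=None,
    reference: TimeSeries | None = None,
) -> ForecastResult:
    """Repeat a train-and-predict pipeline over replicate seeds.

    ``pipeline(seed)`` must return a :class:`TimeSeries` prediction (it
    typically regenerates data, retrains and predicts).  When a
    reference trajectory is supplied, the pointwise ensemble mean and
    its absolute error against the reference are attached to the result.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if seeds is None:
        seeds = list(range(n_replicates))
    if len(seeds) != n_replicates:
        raise ValueError("number of seeds must equal n_replicates")
    members = [pipeline(seed) for seed in seeds]
    preds = [m.prediction if isinstance(m, ForecastResult) else m for m in members]
    lengths = {len(p) for p in preds}
    if len(lengths) != 1:
        raise ValueError("ensemble members have unequal lengths")
    result = ForecastResult(prediction=preds[0], ensemble=preds)
    stack = np.stack([p.values for p in preds])
    mean_vals = stack.mean(axis=0)
    proto = preds[0]
    result.mean_trajectory = TimeSeries(mean_vals, dt=proto.dt, t0=proto.t0,
                                        names=list(proto.names))
    if reference is not None:
        if len(reference) != len(proto):
            raise ValueError("reference length does not match predictions")
        err = np.abs(mean_vals - reference.values)
        result.abs_error = TimeSeries(err, dt=proto.dt, t0=proto.t0,
                                      names=list(proto.names))
    return result
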