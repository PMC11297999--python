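"""End-to-end experiment pipelines for the shipped example systems.

Each pipeline regenerates its data with the package's own simulators,
trains the slow-scale model with the shipped hyperparameter fixture,
separates the noise and produces predictions, so that every reported
statistic is recomputed from scratch for a given seed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

from .dynamics import DriftSpec, LorenzDriveParams, simulate_lorenz_driven, simulate_sde
from .forecasting import predict_colored, rolling_predict
from .noise import NoiseModel, calibrate_amplification, fit_noise_reservoir, separate_noise
from .reservoir import EchoStateNetwork, ReservoirConfig
from .timeseries import TimeSeries
from .transitions import (
    DEFAULT_PERSISTENCE,
    TransitionStats,
    detect_transitions,
    first_persistent_crossing,
)
from .tuning import StableStates, infer_stable_states

__all__ = [
    "load_config",
    "reservoir_config_from",
    "Example1Result",
    "run_example1",
    "Example2Result",
    "run_example2",
    "run_example3",
    "lorenz_transition_time",
    "train_slow_scale",
]

#: noise-reservoir training window and prediction-start margin for the
#: colored-noise pipeline, in sampling steps.  The window is the reference
#: 580 steps of noisy data immediately preceding the prediction start;
#: the start sits a short margin before the transition so that the
#: reservoir state carries the onset of the escape.
COLORED_WINDOW = 580
COLORED_MARGIN = 8
COLORED_STEPS = 300


def load_config(name: str) -> dict:
    """Load a shipped experiment fixture (``example1`` ... ``example4``)."""
    ref = importlib.resources.files("multiscale_rc.configs") / f"{name}.yaml"
    with ref.open("r") as handle:
        return yaml.safe_load(handle)


def reservoir_config_from(cfg: dict, seed: int = 0, **overrides) -> ReservoirConfig:
    """Build a :class:`ReservoirConfig` from a fixture dictionary."""
    r = dict(cfg["reservoir"])
    r.update(overrides)
    return ReservoirConfig(
        n_nodes=int(r["n_nodes"]),
        input_scaling=float(r["input_scaling"]),
        degree=float(r["degree"]),
        spectral_radius=float(r["spectral_radius"]),
        leak_rate=float(r["leak_rate"]),
        ridge_beta=float(r["ridge_beta"]),
        seed=seed,
        washout=r.get("washout"),
        input_jitter=float(r.get("input_jitter", 0.0)),
    )


def _simulate_from_config(cfg: dict, n_steps: int, seed: int) -> TimeSeries:
    sys = cfg["system"]
    dt = float(cfg["simulation"]["dt"])
    if sys["kind"] == "bistable_1d":
        drift = DriftSpec.bistable_1d(**sys["params"])
        eps = np.atleast_1d(np.asarray(sys["noise_eps"], dtype=float))
        amp = np.sqrt(2.0 * eps * sys["params"]["b"])
        return simulate_sde(drift, amp, sys["u0"], dt, n_steps, seed=seed)
    if sys["kind"] == "nongradient_2d":
        drift = DriftSpec.nongradient_2d(**sys["params"])
        eps = np.atleast_1d(np.asarray(sys["noise_eps"], dtype=float))
        amp = np.sqrt(2.0 * eps * sys["params"]["b"])
        return simulate_sde(drift, amp, sys["u0"], dt, n_steps, seed=seed)
    if sys["kind"] == "lorenz_driven":
        u0 = sys["u0"]
        params = LorenzDriveParams(
            u1_0=u0[0], x0=u0[1], y0=u0[2], z0=u0[3], **sys["params"]
        )
        return simulate_lorenz_driven(params, dt, n_steps)
    raise ValueError(f"cannot simulate system kind {sys['kind']!r}")


def train_slow_scale(
    series: TimeSeries, config: ReservoirConfig
) -> tuple[EchoStateNetwork, TimeSeries, TimeSeries]:
    """Train the slow-scale model and separate the residual.

    Returns ``(esn, smooth, residual)`` with the residual defined on
    steps ``1..T`` of the training series.
    """
    esn = EchoStateNetwork(config, n_inputs=series.n_dim)
    esn.train(series)
    smooth, residual = separate_noise(esn, series)
    return esn, smooth, residual


# ---------------------------------------------------------------------------
# Example 1 / Example 3: white-noise replicate protocols
# ---------------------------------------------------------------------------

@dataclass
class Example1Result:
    """Replicate statistics for a white-noise example."""

    predicted_counts: list[int] = field(default_factory=list)
    direct_counts: list[int] = field(default_factory=list)
    predicted_waits: list[float] = field(default_factory=list)
    direct_waits: list[float] = field(default_factory=list)

    @property
    def mean_predicted(self) -> float:
        return float(np.mean(self.predicted_counts))

    @property
    def mean_direct(self) -> float:
        return float(np.mean(self.direct_counts))


def _white_noise_replicate(
    cfg: dict, data_seed: int, reservoir_seed: int, prediction_seed: int
) -> tuple[TransitionStats, TransitionStats, StableStates]:
    """One train/predict replicate plus its paired direct simulation.

    A single long trajectory is generated; its first half trains the
    model, its second half is the direct-simulation reference for the
    same duration as the prediction.
    """
    sim = cfg["simulation"]
    n_train, n_predict = int(sim["n_train"]), int(sim["n_predict"])
    persistence = int(cfg.get("evaluation", {}).get("persistence", DEFAULT_PERSISTENCE))
    full = _simulate_from_config(cfg, n_train + n_predict, seed=data_seed)
    train = full.window(0, n_train + 1)
    direct = full.window(n_train, n_train + n_predict + 1)

    rc = reservoir_config_from(cfg, seed=reservoir_seed)
    esn, _, residual = train_slow_scale(train, rc)

    amp_setting = cfg.get("noise", {}).get("amplification", 1.0)
    if amp_setting == "auto":
        gamma = calibrate_amplification(train, residual)
    else:
        gamma = float(amp_setting)
    pool = NoiseModel(mode="empirical", residuals=residual.values, amplification=gamma)

    forecast = rolling_predict(
        esn, pool, train.values[-1], n_predict, seed=prediction_seed,
        dt=train.dt, r0=esn.r,
    )
    states = infer_stable_states(train)
    pred_stats = detect_transitions(forecast.prediction, states, persistence=persistence)
    direct_stats = detect_transitions(direct, states, persistence=persistence)
    return pred_stats, direct_stats, states


def _run_white_noise_example(
    cfg: dict, n_replicates: int, base_seed: int
) -> Example1Result:
    result = Example1Result()
    root = np.random.SeedSequence(base_seed)
    for child in root.spawn(n_replicates):
        data_seed, res_seed, pred_seed = (
            int(s.generate_state(1)[0] % (2 ** 31)) for s in child.spawn(3)
        )
        pred_stats, direct_stats, _ = _white_noise_replicate(
            cfg, data_seed, res_seed, pred_seed
        )
        result.predicted_counts.append(pred_stats.count)
        result.direct_counts.append(direct_stats.count)
        result.predicted_waits.extend(pred_stats.waiting_times.tolist())
        result.direct_waits.extend(direct_stats.waiting_times.tolist())
    return result


def run_example1(n_replicates: int = 20, base_seed: int = 0) -> Example1Result:
    """White-noise double well: replicate transition statistics."""
    return _run_white_noise_example(load_config("example1"), n_replicates, base_seed)


def run_example3(n_replicates: int = 10, base_seed: int = 0) -> Example1Result:
    """2-D non-gradient system: replicate transition statistics."""
    return _run_white_noise_example(load_config("example3"), n_replicates, base_seed)


# ---------------------------------------------------------------------------
# Example 2: colored-noise single-transition prediction
# ---------------------------------------------------------------------------

def lorenz_transition_time(
    persistence: int = DEFAULT_PERSISTENCE, dt: float = 0.01, n_steps: int = 8000
) -> float:
    """Time of the first persistent zero crossing of the driven well."""
    cfg = load_config("example2_set1")
    series = _simulate_from_config(cfg, n_steps, seed=0)
    idx = first_persistent_crossing(series.column(0), 0.0, persistence)
    if idx is None:
        raise RuntimeError("no persistent transition found in the simulated window")
    return idx * dt


@dataclass
class Example2Result:
    truth: TimeSeries
    predictions: list[np.ndarray]
    pred_start: int
    dt: float

    @property
    def mean_trajectory(self) -> np.ndarray:
        return np.mean(self.predictions, axis=0)

    @property
    def truth_window(self) -> np.ndarray:
        n = len(self.predictions[0])
        return self.truth.column(0)[self.pred_start + 1: self.pred_start + 1 + n]

    @property
    def mean_abs_error(self) -> float:
        return float(np.abs(self.mean_trajectory - self.truth_window).mean())

    def mean_crossing_time(self, persistence: int = DEFAULT_PERSISTENCE) -> float | None:
        idx = first_persistent_crossing(self.mean_trajectory, 0.0, persistence)
        if idx is None:
            return None
        return (self.pred_start + idx + 1) * self.dt


def run_example2(
    n_members: int = 50,
    base_seed: int = 0,
    margin: int = COLORED_MARGIN,
    window: int = COLORED_WINDOW,
    n_pred: int = COLORED_STEPS,
) -> Example2Result:
    """Dual-reservoir prediction of the single colored-noise transition.

    The target series is the deterministic Lorenz-driven trajectory.
    The prediction starts ``margin`` steps before its detected
    transition; the noise reservoir trains on the ``window`` residual
    steps preceding the start.  Every member refits both reservoirs
    with fresh seeds and the member average is the forecast.
    """
    cfg1 = load_config("example2_set1")
    cfg2 = load_config("example2_set2")
    sim = cfg1["simulation"]
    dt = float(sim["dt"])
    truth = _simulate_from_config(cfg1, int(sim["n_train"]), seed=0)
    slow = TimeSeries(truth.values[:, 0:1], dt=dt, names=["u1"])

    cross = first_persistent_crossing(slow.column(0), 0.0)
    if cross is None:
        raise RuntimeError("the target series contains no persistent transition")
    pred_start = cross - margin

    root = np.random.SeedSequence(base_seed)
    predictions = []
    for child in root.spawn(n_members):
        det_seed, noise_seed = (
            int(s.generate_state(1)[0] % (2 ** 31)) for s in child.spawn(2)
        )
        rc_det = reservoir_config_from(cfg1, seed=det_seed)
        esn, _, residual = train_slow_scale(slow, rc_det)
        # residual step t corresponds to series step t+1
        rc_noise = reservoir_config_from(cfg2, seed=noise_seed)
        noise_model = fit_noise_reservoir(
            residual,
            rc_noise,
            window=(pred_start - window - 1, pred_start - 1),
        )
        # deterministic reservoir synchronised on the data up to the start
        _, r_det = esn._drive(slow.values[:pred_start])
        forecast = predict_colored(
            esn, noise_model, slow.values[pred_start], n_pred, dt=dt, r0_det=r_det
        )
        predictions.append(forecast.prediction.column(0))
    return Example2Result(
        truth=slow, predictions=predictions, pred_start=pred_start, dt=dt
    )
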