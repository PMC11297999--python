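"""Hyperparameter diagnostics: stable-state convergence and PSD matching.

Two complementary acceptance checks for a trained slow-scale model:

1. *Convergence* — noise-free closed loops launched from points spread
   over the data range must relax onto the metastable centers inferred
   from the training data (centers come from segmenting the series at
   large jumps and averaging segments).
2. *Spectral match* — the power spectral density of a stochastic
   rolling prediction must match the training data's PSD; the distance
   is the mean squared difference of log10 power.

``grid_search`` formalises the manual trial-and-error loop over
candidate hyperparameter sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.cluster import hierarchy

from .forecasting import predict_autonomous, rolling_predict
from .noise import NoiseModel, separate_noise
from .reservoir import EchoStateNetwork, ReservoirConfig
from .timeseries import TimeSeries

__all__ = [
    "StableStates",
    "Spectrum",
    "infer_stable_states",
    "check_convergence",
    "estimate_psd",
    "psd_distance",
    "grid_search",
]


@dataclass
class StableStates:
    """Metastable centers inferred from a trajectory."""

    centers: np.ndarray          # (k, n)
    jump_threshold: float
    segment_count: int

    @property
    def k(self) -> int:
        return self.centers.shape[0]


def infer_stable_states(
    series: TimeSeries,
    jump_threshold: float | None = None,
    min_segment: int = 10,
    merge_fraction: float = 0.25,
    refine: bool = True,
) -> StableStates:
    """Centers from segmenting the series between large jumps.

    The series is cut wherever the Euclidean one-step increment exceeds
    ``jump_threshold`` (default: 2.5 times the median increment norm);
    segments shorter than ``min_segment`` steps are dropped, each
    remaining segment is averaged, and means closer than
    ``merge_fraction`` of the overall data range are merged.  With
    ``refine`` the merged centers are polished by a short mean-shift on
    the raw samples (segment means are diluted by barrier-crossing
    stretches; the density mode marks the stable state), and low-density
    modes are dropped.
    """
    if len(series) < 10:
        raise ValueError("need at least 10 samples to infer stable states")
    # discard a short burn-in: the deterministic approach from the initial
    # condition is not part of the metastable signal and would otherwise
    # seed a spurious center along the relaxation path
    burn = min(len(series) // 20, 500)
    if len(series) - burn >= 10:
        series = series.window(burn, len(series))
    steps = np.linalg.norm(np.diff(series.values, axis=0), axis=1)
    if jump_threshold is None:
        med = float(np.median(steps))
        jump_threshold = 2.5 * med if med > 0 else float(steps.max()) * 0.5
    cuts = np.nonzero(steps > jump_threshold)[0] + 1
    bounds = np.concatenate([[0], cuts, [len(series)]])
    means = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a >= min_segment:
            means.append(series.values[a:b].mean(axis=0))
    if not means:
        raise ValueError(
            "no segment of sufficient length survives; lower the jump threshold"
        )
    means = np.array(means)
    span = float(
        np.linalg.norm(series.values.max(axis=0) - series.values.min(axis=0))
    )
    tol = merge_fraction * span
    # agglomerate segment means with centroid linkage (resists chaining
    # through the sparse in-between means of transition-spanning segments)
    if len(means) > 1:
        Z = hierarchy.linkage(means, method="centroid")
        labels = hierarchy.fcluster(Z, t=tol, criterion="distance")
        centers = [means[labels == lab].mean(axis=0) for lab in np.unique(labels)]
    else:
        centers = [means[0]]
    if refine and len(centers) > 1:
        ctr = np.array(centers)
        samples = series.values
        # mean-shift polish: move each center to the mean of the samples
        # within half the merge radius; seeks the local density mode, which
        # marks the stable state better than occupation averages do
        bandwidth = 0.5 * tol
        for _ in range(5):
            new = []
            for c in ctr:
                near = samples[np.linalg.norm(samples - c, axis=1) <= bandwidth]
                new.append(near.mean(axis=0) if near.shape[0] else c)
            ctr = np.array(new)
        # refined centers may have migrated to the same mode: merge them,
        # then drop low-density modes (barrier stretches, initial transients)
        merged: list[np.ndarray] = []
        for c in ctr:
            for j, mc in enumerate(merged):
                if np.linalg.norm(c - mc) <= bandwidth:
                    merged[j] = 0.5 * (mc + c)
                    break
            else:
                merged.append(c)
        ctr = np.array(merged)
        density = np.array(
            [
                np.mean(np.linalg.norm(samples - c, axis=1) <= bandwidth)
                for c in ctr
            ]
        )
        keep = density >= 0.1 * density.max()
        centers = list(ctr[keep] if np.any(keep) else ctr)
    return StableStates(
        centers=np.array(sorted(centers, key=lambda c: c[0])),
        jump_threshold=float(jump_threshold),
        segment_count=len(means),
    )


def check_convergence(
    esn: EchoStateNetwork,
    states: StableStates,
    n_starts: int = 10,
    horizon: int = 2000,
    tol: float = 0.1,
    start_range: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """Fraction of noise-free closed loops ending near an inferred center.

    Starts are spread uniformly over the training range (or an explicit
    ``start_range``); a run counts as converged when its final point is
    within ``tol`` of the nearest center.
    """
    if not esn.is_trained:
        raise RuntimeError("check_convergence requires a trained network")
    if start_range is None:
        if esn.input_range is None:
            raise ValueError("no training range recorded; pass start_range")
        lo, hi = esn.input_range
    else:
        lo, hi = (np.atleast_1d(np.asarray(v, dtype=float)) for v in start_range)
    fracs = np.linspace(0.0, 1.0, n_starts)
    hits = 0
    for f in fracs:
        start = lo + f * (hi - lo)
        path = predict_autonomous(esn, start, horizon)
        end = path.values[-1]
        dist = np.min(np.linalg.norm(states.centers - end, axis=1))
        hits += dist <= tol
    return hits / n_starts


@dataclass
class Spectrum:
    """Averaged-periodogram PSD estimate with its estimator settings."""

    frequencies: np.ndarray
    power: np.ndarray            # (n_freq, n_dim)
    settings: dict

    def __post_init__(self):
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")


def estimate_psd(series: TimeSeries, nperseg: int | None = None) -> Spectrum:
    """Welch PSD per dimension (median-free, 50% overlap, Hann taper)."""
    T = len(series)
    if T < 256:
        raise ValueError("series too short for a stable PSD estimate (need >= 256)")
    if nperseg is None:
        nperseg = min(1024, T // 8)
    freqs, power = signal.welch(
        series.values, fs=1.0 / series.dt, nperseg=nperseg, axis=0,
        window="hann", noverlap=nperseg // 2, detrend=False,
    )
    return Spectrum(
        frequencies=freqs[1:],
        power=np.atleast_2d(power)[1:],
        settings={"nperseg": nperseg, "window": "hann", "overlap": 0.5,
                  "fs": 1.0 / series.dt},
    )


def psd_distance(a: Spectrum, b: Spectrum, floor: float = 1e-300) -> float:
    """Mean squared difference of log10 power, over bins and dimensions."""
    if a.frequencies.shape != b.frequencies.shape or not np.allclose(
        a.frequencies, b.frequencies
    ):
        raise ValueError("spectra live on different frequency grids")
    la = np.log10(np.maximum(a.power, floor))
    lb = np.log10(np.maximum(b.power, floor))
    return float(np.mean((la - lb) ** 2))


def grid_search(
    candidates: list[ReservoirConfig],
    training: TimeSeries,
    criterion: str = "convergence",
    prediction_steps: int | None = None,
    seed: int = 0,
) -> list[tuple[ReservoirConfig, float]]:
    """Train every candidate and rank by the chosen diagnostic.

    Scores are "higher is better": the convergence fraction, the
    negative PSD distance, or their lexicographic combination flattened
    as ``convergence - psd_distance``.  A candidate whose training
    fails receives ``-inf`` instead of aborting the search.
    """
    if not candidates:
        raise ValueError("grid_search needs at least one candidate")
    if criterion not in ("convergence", "psd", "combined"):
        raise ValueError(f"unknown criterion: {criterion!r}")
    states = infer_stable_states(training)
    ref_spectrum = estimate_psd(training) if criterion != "convergence" else None
    if prediction_steps is None:
        prediction_steps = len(training) - 1
    # convergence tolerance scales with the data: the inferred centers carry
    # a finite-sample offset of a few percent of the range themselves
    span = float(np.linalg.norm(training.values.max(axis=0) - training.values.min(axis=0)))
    conv_tol = 0.075 * span
    scored = []
    for config in candidates:
        try:
            esn = EchoStateNetwork(config, n_inputs=training.n_dim)
            esn.train(training)
            score = 0.0
            if criterion in ("convergence", "combined"):
                score += check_convergence(esn, states, tol=conv_tol)
            if criterion in ("psd", "combined"):
                _, residual = separate_noise(esn, training)
                pool = NoiseModel(mode="empirical", residuals=residual.values)
                fc = rolling_predict(
                    esn, pool, training.values[-1], prediction_steps, seed=seed,
                    dt=training.dt,
                )
                pred_spectrum = estimate_psd(
                    fc.prediction, nperseg=ref_spectrum.settings["nperseg"]
                )
                score -= psd_distance(pred_spectrum, ref_spectrum)
        except Exception:
            score = float("-inf")
        scored.append((config, float(score)))
    scored.sort(key=lambda pair: pair[1], reverse=True)
    return scored
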