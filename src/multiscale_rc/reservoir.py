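"""Leaky echo-state reservoir with a ridge-regression readout.

The reservoir follows the standard leaky-integrator update

.. math::

    r_{t+1} = (1 - \\alpha) r_t + \\alpha \\tanh(A r_t + W_{in} u_t),
    \\qquad \\tilde u_{t+1} = W_{out} r_{t+1},

where :math:`A` is a sparse Erdős–Rényi recurrent matrix rescaled to a
prescribed spectral radius, :math:`W_{in}` has entries uniform on
``[-K_in, K_in]`` and only :math:`W_{out}` is trained, by ridge
regression of one-step-ahead targets on collected states.

The leak rate :math:`\\alpha` is the pivotal knob: it sets the intrinsic
time scale of the reservoir, and choosing it to match the slow component
of a two-time-scale signal makes the trained readout a model of the slow
dynamics only, with the fast component left in the one-step residual.

Inputs are normalised per dimension to a fixed fraction of their training
range before entering the input layer (targets stay in original units),
so that reference input-scaling values keep the tanh preactivations in
their responsive range whatever the units of the data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve

from .timeseries import TimeSeries

__all__ = [
    "ReservoirConfig",
    "EchoStateNetwork",
    "fit_readout",
]

#: training data is mapped into [-TARGET_INPUT_RANGE, TARGET_INPUT_RANGE]
TARGET_INPUT_RANGE = 0.25

#: dense eigensolver is used up to this size (robust for very sparse A)
_DENSE_EIG_LIMIT = 3000


@dataclass(frozen=True)
class ReservoirConfig:
    """Hyperparameters of the echo-state network.

    Parameters
    ----------
    n_nodes : int
        Reservoir size ``N``.
    input_scaling : float
        Half-width ``K_in`` of the uniform distribution of input weights.
    degree : float
        Mean degree ``D`` of the Erdős–Rényi recurrent graph.
    spectral_radius : float
        Spectral radius ``rho`` imposed on the recurrent matrix.  Very
        small values (1e-3) are legitimate: they make the reservoir an
        almost memory-free nonlinear expansion of the leaky input filter.
    leak_rate : float
        Leak ``alpha`` in ``(0, 1]``; small values slow the reservoir.
    ridge_beta : float
        Tikhonov regularisation of the readout.
    seed : int
        Seed for the fixed random matrices.
    washout : int or None
        Initial state/target pairs discarded before the regression; when
        None, ``min(100, T // 10)`` is used.
    input_jitter : float
        Optional teacher-forcing regularisation: standard deviation (as
        a fraction of each dimension's maximum absolute training value)
        of Gaussian noise added to the *inputs* of the state-collection
        pass used for fitting the readout.  Stabilises the closed loop
        on smooth training data; 0 disables it.
    """

    n_nodes: int = 800
    input_scaling: float = 1.0
    degree: float = 4.0
    spectral_radius: float = 1e-3
    leak_rate: float = 0.2
    ridge_beta: float = 1e-8
    seed: int = 0
    washout: int | None = None
    input_jitter: float = 0.0

    def __post_init__(self):
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if self.degree > self.n_nodes:
            raise ValueError("degree cannot exceed the number of nodes")
        if not (0 < self.leak_rate <= 1):
            raise ValueError("leak_rate must lie in (0, 1]")
        if self.spectral_radius < 0:
            raise ValueError("spectral_radius must be >= 0")
        if self.ridge_beta < 0:
            raise ValueError("ridge_beta must be >= 0")
        if self.input_jitter < 0:
            raise ValueError("input_jitter must be >= 0")

    def with_seed(self, seed: int) -> "ReservoirConfig":
        return replace(self, seed=seed)


def _spectral_radius(A: sparse.spmatrix) -> float:
    n = A.shape[0]
    if n <= _DENSE_EIG_LIMIT:
        return float(np.abs(np.linalg.eigvals(A.toarray())).max())
    vals = sparse.linalg.eigs(A, k=1, return_eigenvectors=False, maxiter=20 * n)
    return float(np.abs(vals).max())


def _build_recurrent(n: int, degree: float, rho: float, seed: int) -> sparse.csr_matrix:
    """Sparse ER matrix with uniform[-1, 1] weights rescaled to radius rho."""
    for attempt in range(32):
        rs = np.random.RandomState(seed + attempt)
        A = sparse.random(
            n, n, density=min(degree / n, 1.0), random_state=rs,
            data_rvs=lambda k: rs.uniform(-1.0, 1.0, k), format="csr",
        )
        raw = _spectral_radius(A)
        if raw > 0:
            return A * (rho / raw)
    # all attempts nilpotent (conceivable only for extremely sparse graphs)
    raise RuntimeError("could not generate a recurrent matrix with nonzero spectral radius")


class EchoStateNetwork:
    """A reservoir plus (after training) its linear readout."""

    def __init__(self, config: ReservoirConfig, n_inputs: int):
        self.config = config
        self.n_inputs = int(n_inputs)
        rng = np.random.default_rng(config.seed)
        self.W_in = rng.uniform(
            -config.input_scaling, config.input_scaling, size=(config.n_nodes, n_inputs)
        )
        if config.spectral_radius == 0:
            self.A = sparse.csr_matrix((config.n_nodes, config.n_nodes))
        else:
            self.A = _build_recurrent(
                config.n_nodes, config.degree, config.spectral_radius, config.seed + 1
            )
        self.W_out: np.ndarray | None = None
        self.r = np.zeros(config.n_nodes)
        #: per-dimension divisor applied to inputs (set by fit/set_input_scale)
        self.input_scale = np.ones(n_inputs)
        #: observed training range, used to confine closed-loop feedback
        self.input_range: tuple[np.ndarray, np.ndarray] | None = None

    # -- input normalisation --------------------------------------------
    def set_input_scale(self, training_values: np.ndarray) -> None:
        peak = np.abs(training_values).max(axis=0)
        peak = np.where(peak > 0, peak, 1.0)
        self.input_scale = peak / TARGET_INPUT_RANGE
        self.input_range = (
            training_values.min(axis=0).copy(),
            training_values.max(axis=0).copy(),
        )

    # -- dynamics --------------------------------------------------------
    def step(self, r: np.ndarray, u: np.ndarray) -> np.ndarray:
        """One leaky-integrator update; does not mutate stored state."""
        a = self.config.leak_rate
        return (1.0 - a) * r + a * np.tanh(self.A @ r + self.W_in @ (u / self.input_scale))

    def _drive(self, inputs: np.ndarray, r0: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Run teacher forcing over ``inputs`` (T, n); returns (R, r_final).

        Column ``t`` of ``R`` is the state after absorbing ``inputs[t]``.
        """
        a = self.config.leak_rate
        n_nodes = self.config.n_nodes
        r = np.zeros(n_nodes) if r0 is None else r0.copy()
        T = inputs.shape[0]
        R = np.empty((n_nodes, T))
        drive = self.W_in @ (inputs / self.input_scale).T
        A = self.A
        for t in range(T):
            r = (1.0 - a) * r + a * np.tanh(A @ r + drive[:, t])
            R[:, t] = r
        return R, r

    def effective_washout(self, T: int) -> int:
        if self.config.washout is not None:
            return self.config.washout
        return min(100, T // 10)

    def collect_states(self, series: TimeSeries) -> tuple[np.ndarray, np.ndarray]:
        """Teacher-forced state/target pairs for one-step-ahead training.

        The state built after absorbing ``u_t`` is paired with the target
        ``u_{t+1}``; the first ``washout`` pairs are dropped.  The final
        reservoir state is stored on the network.
        """
        T = len(series) - 1
        washout = self.effective_washout(T)
        if T < washout + 1:
            raise ValueError(
                f"series of length {len(series)} too short for washout {washout}"
            )
        R, r_final = self._drive(series.values[:-1])
        self.r = r_final
        return R[:, washout:], series.values[1 + washout:].T

    def train(self, series: TimeSeries) -> "EchoStateNetwork":
        """Fit the readout on one-step-ahead pairs from ``series``.

        When ``input_jitter`` is active, the readout is regressed on a
        second teacher-forcing pass whose inputs carry Gaussian jitter;
        the targets are unchanged.  The jittered pass teaches the readout
        to map states just off the training manifold back onto it, which
        keeps noise-free closed loops within the learned attractor.
        """
        self.set_input_scale(series.values)
        cfg = self.config
        T = len(series) - 1
        washout = self.effective_washout(T)
        if T < washout + 1:
            raise ValueError(f"series of length {len(series)} too short for training")

        R_clean, r_final = self._drive(series.values[:-1])
        targets = series.values[1 + washout:].T
        if cfg.input_jitter > 0:
            rng = np.random.default_rng(cfg.seed + 7919)
            sigma = cfg.input_jitter * np.abs(series.values).max(axis=0)
            jittered = series.values[:-1] + sigma * rng.standard_normal(
                series.values[:-1].shape
            )
            R_fit, _ = self._drive(jittered)
        else:
            R_fit = R_clean
        self.W_out = fit_readout(R_fit[:, washout:], targets, cfg.ridge_beta)
        self.r = r_final
        return self

    @property
    def is_trained(self) -> bool:
        return self.W_out is not None

    def readout(self, r: np.ndarray) -> np.ndarray:
        if self.W_out is None:
            raise RuntimeError("readout requested from an untrained network")
        return self.W_out @ r

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        coo = self.A.tocoo()
        cfg = self.config
        np.savez_compressed(
            path,
            cfg=np.array(
                [
                    cfg.n_nodes, cfg.input_scaling, cfg.degree, cfg.spectral_radius,
                    cfg.leak_rate, cfg.ridge_beta, cfg.seed,
                    -1 if cfg.washout is None else cfg.washout, cfg.input_jitter,
                ]
            ),
            n_inputs=self.n_inputs,
            W_in=self.W_in,
            A_row=coo.row, A_col=coo.col, A_data=coo.data,
            W_out=np.empty((0, 0)) if self.W_out is None else self.W_out,
            r=self.r,
            input_scale=self.input_scale,
            has_range=self.input_range is not None,
            range_lo=np.zeros(self.n_inputs) if self.input_range is None else self.input_range[0],
            range_hi=np.zeros(self.n_inputs) if self.input_range is None else self.input_range[1],
        )

    @classmethod
    def load(cls, path) -> "EchoStateNetwork":
        with np.load(path, allow_pickle=False) as payload:
            c = payload["cfg"]
            config = ReservoirConfig(
                n_nodes=int(c[0]), input_scaling=float(c[1]), degree=float(c[2]),
                spectral_radius=float(c[3]), leak_rate=float(c[4]), ridge_beta=float(c[5]),
                seed=int(c[6]), washout=None if c[7] < 0 else int(c[7]),
                input_jitter=float(c[8]),
            )
            esn = cls.__new__(cls)
            esn.config = config
            esn.n_inputs = int(payload["n_inputs"])
            esn.W_in = payload["W_in"]
            n = config.n_nodes
            esn.A = sparse.csr_matrix(
                (payload["A_data"], (payload["A_row"], payload["A_col"])), shape=(n, n)
            )
            W_out = payload["W_out"]
            esn.W_out = None if W_out.size == 0 else W_out
            esn.r = payload["r"]
            esn.input_scale = payload["input_scale"]
            esn.input_range = (
                (payload["range_lo"], payload["range_hi"]) if payload["has_range"] else None
            )
        return esn


def fit_readout(R: np.ndarray, U: np.ndarray, beta: float) -> np.ndarray:
    """Ridge minimiser of ``sum_t ||u_t - W r_t||^2 + beta ||W||^2``.

    Solves ``(R R^T + beta I) W^T = R U^T`` by Cholesky factorisation;
    the inverse is never formed.  With ``beta = 0`` the Gram matrix must
    be positive definite, otherwise a rank error is raised.
    """
    if R.ndim != 2 or U.ndim != 2 or R.shape[1] != U.shape[1]:
        raise ValueError("R and U must be matrices with matching column counts")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    G = R @ R.T
    if beta > 0:
        G[np.diag_indices_from(G)] += beta
    try:
        factor = cho_factor(G, lower=True, check_finite=False)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "state Gram matrix is singular; use beta > 0"
        ) from err
    return cho_solve(factor, R @ U.T, check_finite=False).T
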