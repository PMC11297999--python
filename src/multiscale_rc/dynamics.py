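"""Synthetic generators for bistable stochastic dynamics.

Three families of test systems are provided:

* a one-dimensional bistable gradient system
  ``du/dt = -b(-u + u^3 + c) + sqrt(2*eps*b) * xi(t)``
  with Gaussian white noise, where ``b`` sets the relaxation speed,
  ``eps`` the noise strength and ``c`` tilts the double well;
* a two-dimensional bistable *non-gradient* extension whose
  antisymmetric coupling of strength ``a`` breaks detailed balance and
  adds a rotational component to the flow;
* the same 1-D double well driven deterministically by a fast Lorenz-63
  subsystem, which plays the role of temporally correlated (colored)
  noise.

White-noise trajectories are integrated with Euler--Maruyama at the
requested output step.  The Lorenz-driven system is deterministic but
stiff in its fast subsystem, so it is advanced with classical
fixed-step RK4 using a few internal substeps per recorded sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .timeseries import TimeSeries

__all__ = [
    "SimulationDiverged",
    "DriftSpec",
    "LorenzDriveParams",
    "drift_bistable_1d",
    "drift_nongradient_2d",
    "simulate_sde",
    "simulate_lorenz_driven",
]

#: states larger than this abort the integration
DIVERGENCE_BOUND = 1e6


class SimulationDiverged(RuntimeError):
    """Raised when an integration leaves the admissible state region."""

    def __init__(self, step: int):
        self.step = step
        super().__init__(f"simulation diverged at step {step} (|state| > {DIVERGENCE_BOUND:g})")


def drift_bistable_1d(u: float, b: float, c: float = 0.0) -> float:
    """Drift of the 1-D double well, ``-b(-u + u^3 + c)``."""
    return -b * (-u + u ** 3 + c)


def drift_nongradient_2d(u, a: float, b: float, c: float = 0.0) -> np.ndarray:
    """Drift of the 2-D bistable non-gradient system.

    The symmetric part is the double well acting on the first coordinate
    with linear relaxation of the second; the antisymmetric part of
    strength ``a`` rotates the flow, violating detailed balance.
    """
    u1, u2 = u
    g = -u1 + u1 ** 3 + c
    return np.array([-b * g - a * u2, a * g - b * u2])


@dataclass
class DriftSpec:
    """Parameterized deterministic vector field ``f(u)``."""

    kind: str
    params: dict = field(default_factory=dict)
    fn: Callable[[np.ndarray], np.ndarray] | None = None
    dim: int = 1

    @classmethod
    def bistable_1d(cls, b: float = 5.0, c: float = 0.0) -> "DriftSpec":
        return cls(kind="bistable_1d", params={"b": b, "c": c}, dim=1)

    @classmethod
    def nongradient_2d(cls, a: float = 5.0, b: float = 5.0, c: float = 0.0) -> "DriftSpec":
        return cls(kind="nongradient_2d", params={"a": a, "b": b, "c": c}, dim=2)

    @classmethod
    def custom(cls, fn: Callable[[np.ndarray], np.ndarray], dim: int) -> "DriftSpec":
        return cls(kind="custom", fn=fn, dim=dim)

    def __call__(self, u: np.ndarray) -> np.ndarray:
        if self.kind == "bistable_1d":
            return np.atleast_1d(drift_bistable_1d(u[0], **self.params))
        if self.kind == "nongradient_2d":
            return drift_nongradient_2d(u, **self.params)
        if self.kind == "custom":
            out = np.asarray(self.fn(u), dtype=float)
            if out.shape != np.shape(u):
                raise ValueError("custom drift changed the state dimension")
            return out
        raise ValueError(f"unknown drift kind: {self.kind!r}")


def simulate_sde(
    drift: DriftSpec,
    noise_amp,
    u0,
    dt: float,
    n_steps: int,
    seed: int = 0,
) -> TimeSeries:
    """Euler--Maruyama integration of ``du = f(u) dt + noise_amp dW``.

    ``noise_amp`` is the per-dimension amplitude multiplying independent
    standard Wiener increments; for the 1-D double well the physical
    choice is ``sqrt(2*eps*b)``.  The returned series has ``n_steps + 1``
    rows including the initial condition, and is bit-reproducible for a
    fixed seed.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be at least 1")
    if dt <= 0:
        raise ValueError("dt must be positive")
    u = np.atleast_1d(np.asarray(u0, dtype=float)).copy()
    n = u.shape[0]
    amp = np.broadcast_to(np.asarray(noise_amp, dtype=float), (n,)).copy()
    if np.any(amp < 0):
        raise ValueError("noise amplitudes must be non-negative")

    rng = np.random.default_rng(seed)
    increments = rng.standard_normal((n_steps, n)) if np.any(amp > 0) else None
    sqdt = np.sqrt(dt)

    out = np.empty((n_steps + 1, n))
    out[0] = u
    for k in range(n_steps):
        u = u + drift(u) * dt
        if increments is not None:
            u = u + amp * sqdt * increments[k]
        if not np.all(np.isfinite(u)) or np.any(np.abs(u) > DIVERGENCE_BOUND):
            raise SimulationDiverged(k + 1)
        out[k + 1] = u
    return TimeSeries(out, dt=dt, t0=0.0)


@dataclass
class LorenzDriveParams:
    """Double well driven by a fast Lorenz-63 subsystem.

    ``psi`` couples the Lorenz ``y`` variable into the slow coordinate;
    ``eps`` compresses the Lorenz time scale (the chaotic subsystem runs
    a factor ``1/eps**2`` faster than the well).
    """

    b: float = 1.0
    c: float = 0.0
    psi: float = 0.08
    eps: float = 0.5
    u1_0: float = -1.5
    x0: float = 1.0
    y0: float = 1.0
    z0: float = 1.0

    def __post_init__(self):
        if self.eps == 0:
            raise ValueError("eps must be nonzero")


def simulate_lorenz_driven(
    p: LorenzDriveParams,
    dt: float = 0.01,
    n_steps: int = 8000,
    substeps: int = 4,
) -> TimeSeries:
    """Integrate the Lorenz-driven double well; columns ``u1, x, y, z``.

    The integration is fully deterministic.  RK4 with ``substeps``
    internal stages per recorded sample keeps the fast Lorenz subsystem
    stable at the coarse recording step used throughout (``dt = 0.01``
    with ``eps = 0.5`` makes the effective Lorenz step four times the
    recording step's nominal accuracy budget).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be at least 1")
    if dt <= 0:
        raise ValueError("dt must be positive")
    b, c, psi, eps = p.b, p.c, p.psi, p.eps
    ie2 = 1.0 / eps ** 2

    def rhs(s):
        u, x, y, z = s
        return np.array(
            [
                -b * (-u + u ** 3 + c) + (psi / eps) * y,
                10.0 * ie2 * (y - x),
                ie2 * (28.0 * x - x * z - y),
                ie2 * (x * y - (8.0 / 3.0) * z),
            ]
        )

    h = dt / substeps
    s = np.array([p.u1_0, p.x0, p.y0, p.z0], dtype=float)
    out = np.empty((n_steps + 1, 4))
    out[0] = s
    for k in range(n_steps):
        for _ in range(substeps):
            k1 = rhs(s)
            k2 = rhs(s + 0.5 * h * k1)
            k3 = rhs(s + 0.5 * h * k2)
            k4 = rhs(s + h * k3)
            s = s + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not np.all(np.isfinite(s)) or np.any(np.abs(s) > DIVERGENCE_BOUND):
            raise SimulationDiverged(k + 1)
        out[k + 1] = s
    return TimeSeries(out, dt=dt, t0=0.0, names=["u1", "x", "y", "z"])
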