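"""Simulate a noisy double well and count its noise-induced transitions.

The system is du/dt = -b(-u + u^3) + sqrt(2*eps*b)*xi(t): two stable
states at u = +-1 separated by a barrier that only the noise can cross.
"""
import numpy as np

from multiscale_rc import DriftSpec, detect_transitions, simulate_sde
from multiscale_rc.tuning import StableStates

b, eps, dt = 5.0, 0.3, 0.01
series = simulate_sde(DriftSpec.bistable_1d(b=b), np.sqrt(2 * eps * b),
                      u0=1.5, dt=dt, n_steps=10000, seed=1)
wells = StableStates(centers=np.array([[-1.0], [1.0]]), jump_threshold=0.0,
                     segment_count=2)
stats = detect_transitions(series, wells, persistence=50)
print(f"simulated {len(series)} samples over t in [0, {len(series) * dt:.0f}]")
print(f"transitions: {stats.count}, mean waiting time: "
      f"{stats.waiting_times.mean():.2f} time units")
print("each transition is a persistent (50-step) crossing of the barrier at u=0;")
print("the waiting time is the interval between consecutive crossings.")
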