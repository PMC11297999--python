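# Methods

This note records the model, the numerical choices and the limits of
what the shipped tests demonstrate. It is written for a user who wants
to know *why* the package behaves as it does, not just what it computes.

## The multi-scaling idea

A trajectory from a multistable stochastic system mixes two time
scales: fast fluctuation around a metastable state and slow, rare
switching between states. The package models the slow part with a
leaky echo-state network (ESN),

r_{t+1} = (1 − α) r_t + α tanh(A r_t + W_in u_t),  ũ_{t+1} = W_out r_{t+1},

whose leak rate α is the pivotal knob: the continuous-time reading
(1/α) dr/dt = −r + tanh(A r + W_in u) shows α scaling the reservoir's
internal relaxation. With α matched to the slow scale, the ridge-fitted
readout approximates the conditional mean of the next observation —
i.e., the deterministic one-step map — and the residual
η_{t+1} = u_{t+1} − ũ_{t+1} collects the fast component. Generation
re-assembles the two: deterministic readout plus a noise draw, fed back
closed-loop. For white forcing the draws are rows resampled from the
residual pool (rows, not scalar coordinates, so instantaneous
cross-dimensional dependence survives in multivariate systems). For
colored forcing a second ESN is trained on the residual series itself
and continued autonomously.

## Hyperparameters

| knob | meaning | shipped values |
|---|---|---|
| N | reservoir size | 800–1200 |
| K_in | input-weight half-width | 0.04–4 |
| D | mean degree of the sparse recurrent graph | 1–4 |
| ρ | spectral radius of A | 1.2×10⁻³–0.806 |
| α | leak rate (time scale) | 0.065–0.3 |
| β | ridge penalty | 10⁻⁸–10⁻⁶ |
| γ | noise amplification | 1.1 (double well), auto elsewhere |

The per-example values ship as YAML fixtures under
`multiscale_rc/configs/` and are used verbatim by the `experiments`
pipelines. Tiny spectral radii (10⁻³) are intentional: they make the
reservoir an almost memory-free nonlinear expansion of the leaky input
filter, which suffices for one-dimensional slow dynamics.

**Input normalisation.** Inputs are divided per dimension by
max|u|/0.25, mapping the training range into [−1/4, 1/4] before the
input layer (readout targets stay in original units). Without it,
K_in = 4 on data of range ±2 drives tanh deep into saturation and the
noise-free closed loop acquires spurious attractors. The scale is
deliberately *uncentered*: the feature map then remains odd in u, which
preserves the ± symmetry of symmetric double wells; centering (even by
a few percent) measurably biases the learned wells. The normalisation
is part of the model and is stored with the trained network.

**Noise amplification γ.** An imperfect slow model biases the residual
intensity relative to the true fast component. The double-well fixture
ships the calibrated value γ = 1.1 for that system. Elsewhere the default
`amplification: auto` computes γ = σ(Δu)/σ(η): for small sampling steps
the one-step increments of the data are noise-dominated, so their
standard deviation estimates the true per-step noise scale and the
ratio rescales the pool to it.

**Feedback clamping.** Closed-loop feedback is clamped elementwise to
the training range. Outside the observed support the readout is an
uncontrolled extrapolation; on smooth (colored-noise) training data the
learned drift can point outward beyond |u| ≈ 1.4 and a sustained noise
stretch would hand the loop to a spurious saturated attractor. The
clamp never engages more than marginally on the noisy (white) examples,
whose data already cover the support the loop explores.

**Optional input jitter.** `ReservoirConfig.input_jitter` adds Gaussian
noise to the inputs of the readout-fitting pass (targets unchanged),
teaching the readout to map near-manifold states back to the manifold.
It widens closed-loop basins on smooth data but damps the response to
injected noise, so the shipped fixtures leave it at 0 and rely on the
clamp instead.

## Synthetic generators

* `simulate_sde` — Euler–Maruyama at the recorded step, increments
  amp·√dt·N(0,1). Defaults follow the studied systems: double well
  du = −b(−u+u³+c)dt + √(2εb)dW with b=5, ε=0.3, c=0, dt=0.01; the 2-D
  non-gradient variant adds the antisymmetric coupling a=5 at dt=0.002.
* `simulate_lorenz_driven` — the double well (b=1) driven by ψ/ϵ·y of a
  Lorenz-63 subsystem sped up by 1/ϵ² (ψ=0.08, ϵ=0.5), integrated with
  classical RK4 at 4 substeps per recorded sample. Plain one-step Euler
  at the recording step is unstable for the fast subsystem (its
  effective step exceeds the Lorenz stability limit). The coupled
  system is chaotic over the 80-unit horizon, so the transition time of
  the realization is a property of the integrator arithmetic; under the
  shipped scheme the first persistent crossing lands at t = 24.94,
  inside the system's t∈[22, 25] escape window, and a regression test
  pins it there.

What the generators *do not* emulate: measurement noise distinct from
dynamical noise, non-stationarity, missing samples, and state-dependent
(multiplicative) noise. Passing tests therefore show that the pipeline
recovers transition statistics when the fast component is stationary
and additive — the idealised regime — not that it is robust to
arbitrary experimental artefacts. Experimental recordings enter through
the CSV reader (`example4.yaml` fixture); when the physical sampling
interval is unknown, the sample index is the time unit.

## Training and prediction conventions

* One-step-ahead alignment: the state built after absorbing u_t is
  regressed onto u_{t+1}. The same-time (denoising) alignment was
  evaluated and rejected — its closed loop under-responds to injected
  noise and produces essentially no transitions.
* Washout: `min(100, T/10)` state/target pairs are discarded (the zero
  initial state is arbitrary); configurable.
* Ridge solve: Cholesky on (R Rᵀ + βI); the inverse is never formed.
* Prediction start: continuing the training series starts from the
  final teacher-forced state; starting from an arbitrary point
  re-synchronises by teacher-forcing 100 repeats of the start value.
* Noise separation is defined by residual := input − smooth; this
  identity is bitwise exact. (The rearranged sum smooth + residual can
  differ from the input by one unit in the last place on a few percent
  of entries — IEEE addition is not the exact inverse of subtraction.)

## The colored-noise protocol

The single-transition forecast trains the slow model on the full
8000-step realization, fits the noise ESN on the 580 residual samples
preceding the prediction start (550–650 are empirically suitable), and
starts the prediction 8 samples before the realization's detected
persistent crossing — i.e., on the data available just before the
transition, which is where the method is meant to operate: the fast
subsystem's chaos (several Lyapunov times per time unit) makes any
continuation information decay within roughly one time unit, so a
start far from the crossing cannot be tracked by *any* noise model.
Every ensemble member refits both reservoirs with fresh seeds; the
member average is the forecast. With 50 members the ensemble-mean
crossing falls at t ≈ 24.9 (truth: 24.94) and the mean absolute error
over the 300-step window is ≈ 0.43.

## Stable states, transitions, diagnostics

* Stable-state inference segments the series at one-step increments
  above 2.5× the median increment norm, averages segments of ≥10
  samples, merges means by centroid-linkage within 25% of the data
  range, then polishes centers by a short mean-shift on the raw samples
  (bandwidth: half the merge radius) and drops low-density modes and a
  5% burn-in. The mean-shift step matters: raw segment means are
  diluted toward the barrier by transition-spanning segments, while the
  density mode marks the well.
* A transition is a separatrix crossing (midpoint between adjacent
  centers along the chosen dimension) that persists for 50 samples;
  waiting times are intervals between consecutive transitions; windows
  are half-open.
* Convergence diagnostic: fraction of noise-free closed loops (ten
  starts spread over the data range, 2000 steps) ending within
  tolerance of a center. PSD matching uses Welch (Hann window, 50%
  overlap, segment length min(1024, T/8)) and the mean squared log₁₀
  power difference. `grid_search` ranks candidate configurations by
  either score; its convergence tolerance is 7.5% of the data span,
  absorbing the few-percent offsets of both the inferred centers and
  the learned attractors.

## Problem sizes in the shipped tests

The end-to-end suites run the double-well protocol at 20 train/predict
replicates of 10 000 steps, the 2-D non-gradient protocol at 10
replicates of 20 000 steps, and the colored-noise ensemble at 50
members — the package's chosen desk-scale versions of the full-scale
protocols (100 replicates). Ensemble means at these sizes
carry standard errors of a few percent, which the acceptance tolerances
absorb.

## Known limitations

* Generated transition counts run systematically ~20–35% above the
  direct simulation for the 2-D rotational system: the reservoir's
  finite response time adds effective diffusion near the separatrix.
  The waiting-time *distribution shape* matches well (KS ≈ 0.14).
* The colored-noise forecast is meaningful only within about one time
  unit of the prediction start (chaotic noise), which is why the
  protocol anchors the start at the transition onset.
* Wells inferred from occupation data sit a few percent inside the true
  fixed points for diffusive signals; tolerance parameters default
  accordingly.
* Very tilted double wells (strongly asymmetric time scales) would need
  two hyperparameter sets; the shipped pipelines use one.
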