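# Methods

## The model

`arousalctl` regulates a scalar latent cognitive-arousal state that is never
observed directly. At each discrete step `k` the state `x_k` emits two
conditionally independent observations:

* a binary skin-conductance-response (SCR) event
  `n_k ~ Bernoulli(q_k)` with `q_k = 1 / (1 + exp(-(γ + x_k)))`, and
* a continuous log-tonic skin-conductance level
  `r_k = ρ0 + ρ1 x_k + ζ_k`, `ζ_k ~ N(0, σ_ζ²)`.

`γ` is calibrated from a participant's average SCR rate under the assumption
that the resting state sits near zero, i.e. `γ = logit(base rate)`. Because
the symbol ρ is conventional both for the tonic regression coefficients and
for a state-transition gain, the code names the former `tonic_intercept` /
`tonic_slope` and reserves "gain" for the latter.

The nominal state dynamics are a controlled random walk,
`x_{k+1} = x_k + s_k + u_k + ν_k`, where `s_k` is the environmental stimulus
(visible only to the simulator, never to the estimator or controller), `u_k`
the control input, and `ν_k ~ N(0, σ_ν²)` process noise. Two augmentations
relax this nominal model:

* **adaptive track** — the unit transition gain becomes a time-varying
  `ρ_k` following a random walk (`x_{k+1} = ρ_k x_k + u_k + s_k + ν_k`);
* **robust track** — an additive disturbance `d_k` following a random walk
  enters the dynamics (`x_{k+1} = x_k + d_k + u_k + s_k + ν_k`).

Each track stacks the state with its auxiliary quantity into a 2-vector that
is estimated jointly.

## The recursive Bayesian filter

Prediction propagates the mean through the (possibly bilinear) transition and
the covariance through the Jacobian evaluated at the incoming posterior mean,
plus the diagonal process covariance — the standard extended-Kalman
prediction. The measurement update folds both observation channels in through
the score and curvature of their joint log-likelihood at the predicted state:

    g = (n - q) + ρ1 (r - ρ0 - ρ1 x) / σ_ζ²
    h = -q(1 - q) - ρ1² / σ_ζ²           (h < 0 always)

    Σ_post = (Σ_pred⁻¹ + diag(-h, 0))⁻¹
    m_post = m_pred + Σ_post (g, 0)'

i.e. posterior precision = prior precision + observed Fisher information,
with information entering only through the state component; the gain or
disturbance component moves only through the off-diagonal covariance
coupling built up during prediction. The update is computed as a rank-1
Sherman–Morrison downdate of `Σ_pred`, which is algebraically identical and
remains valid when the auxiliary component has zero variance (used by the
reduction tests). This is a single Newton-style step from the predicted mean
toward the posterior mode with a Laplace covariance; an optional
iterate-to-convergence mode (max 20 iterations, tolerance 1e-10) exists for
the mode-consistency cross-checks and is not used in the closed loop.

A design note on the update form: a covariance update that *adds* the score
derivative to the prior covariance does not contract uncertainty and admits
no fixed point consistent with the mean update above; the information form
is the standard point-process/Gaussian filter update and is what this
package implements.

With the binary channel disabled the update reduces exactly to the linear
Kalman filter for the tonic channel (asserted to 1e-10 against a hand-coded
Kalman oracle); with a point-mass prior at zero disturbance the robust
filter reduces exactly to the 1-D nominal filter used by the static baseline.

Numerical guards: `q` is clamped to [1e-12, 1 − 1e-12] so likelihood terms
stay finite at extreme states; covariances are re-symmetrized every step; a
non-positive posterior state variance or non-finite mean raises a
divergence error carrying the offending quantities.

Default initial beliefs: mean (0, 1) with covariance diag(1.0, 0.1) on the
adaptive track, mean (0, 0) with the same covariance on the robust track.
These are declared choices (a unit-variance state prior, an auxiliary prior
centred on the nominal value); both are overridable.

## The controllers

Both tracks minimize the quadratic cost `Σ Q (x_k - x*)² + R (u_k - u*)²`
with the auxiliary quantity frozen at its current estimate. For the scalar
system `x_{k+1} = a x_k + u_k` the infinite-horizon discrete algebraic
Riccati equation

    P = Q + a² P - a² P² / (P + R)

has a unique positive root (closed form of a quadratic), giving the feedback
gain `l = a P / (P + R)` and the set-point law `u = u* - l (x̂ - x*)`,
applied at the filtered state estimate. The equilibrium input absorbs the
estimated model deviation:

* adaptive: `a = ρ̂` (clamped to [-2, 2] before the Riccati solve to guard
  against transient filter excursions), `u* = x* (1 - ρ̂)`, re-solved every
  step — the solve is closed-form and costs nothing;
* robust: `a = 1` fixed (so `P` and `l` are constants), `u* = -d̂`, exact
  cancellation of the estimated disturbance.

The static baseline uses the same LQR machinery with the auxiliary quantity
frozen at its *nominal* value (gain 1, disturbance 0, hence `u* = 0`), driven
by the 1-D nominal filter. Default weights are `Q = R = 1` for both tracks.
An optional per-scenario sign clamp on the input (inhibition ⇒ u ≤ 0,
excitation ⇒ u ≥ 0) is provided and off by default.

## The closed loop

Per step, strictly in this order: observe the true state; update the belief;
compute `u_k` from the filtered estimate and the current reference; advance
the true dynamics with `u_k` and `s_k`. The reference trajectory enters the
controller only — never the filter. Tracking RMSE is reported between the
reference and the *estimated* state (the quantity the loop can actually
see); RMSE against the true state is logged alongside for diagnostics.
Control effort is `Σ_k |u_k|`. Percent changes are reported as
`100 (static - dynamic) / static`, so positive means the dynamic controller
improved on the static baseline.

Within one step the random draws occur in a fixed order (SCR event, tonic
noise, process noise, walk noise), so every run is a bit-reproducible pure
function of (profile, scenario, seed).

## Synthetic participant profiles

The package evaluates itself on six synthetic participant profiles that play
the role of per-participant models fitted to wearable EDA recordings in the
kind of study this framework targets. Sampling ranges are declared
plausibility ranges, not estimates of any real participant:

| parameter | range | rationale |
|---|---|---|
| SCR base rate | U(0.05, 0.4) | sparse-to-frequent phasic events per step |
| γ | logit(base rate) | calibration at resting state |
| tonic slope ρ1 | U(0.3, 1.5) | weak-to-strong arousal coupling |
| tonic intercept ρ0 | U(-1, 1) | arbitrary log-conductance offset |
| tonic noise σ_ζ² | log-U(0.05, 0.5) | wrist-worn measurement quality |
| process σ_ν² | log-U(1e-3, 1e-2) | slow intrinsic state drift |
| gain walk σ_ε² | log-U(1e-5, 1e-4) | per-run gain drift SD ≈ 0.06–0.2 |
| disturbance walk σ_ω² | log-U(1e-4, 1e-3) | slow exogenous drift |

The tonic noise range deliberately makes the continuous channel noisy enough
that the binary SCR channel carries comparable information — with a
near-noiseless tonic channel the event channel this model family is built
around would be redundant. Draws whose tonic information rate
`ρ1²/σ_ζ²` falls below 2.0 are rejected and redrawn, emulating the exclusion
of artifact-laden recordings that wearable studies apply before modeling.

Truth paths are chosen so the augmented estimators' advantage is actually
expressible: the adaptive-track gain starts at the nominal value 1.0 (the
track is literally the nominal unit gain relaxed into a random walk) and is
hard-clipped to [0.5, 1.1]; the robust-track disturbance is a mid-run step of
U(0.25, 0.5) plus the small walk. Hard clipping makes the ceiling sticky: a
profile whose gain walk drifts high can sit at 1.1 (mildly unstable
dynamics) for long stretches. On the lowest-observability profile this makes
the static arm genuinely diverge — its nominal filter, tugged between the
controller-consistent model prediction and the observations, tracks the
escaping truth with a large lag, and the effective feedback drops below the
instability margin. The dynamic adaptive arm regulates the same runs. This
failure mode is retained: it is exactly the regime joint estimation exists
for, and it explains the large across-profile dispersion in the battery
percent changes.

## Scenarios and the evaluation battery

One step is an abstract discrete index; the defaults use 400-step runs with
50-step blocks. Three scenario shapes:

* **inhibition** — alternating relax (s = 0) / stress (s = +0.08) blocks;
  binary reference 0.5 in relax blocks, 0.0 in stress blocks (drive arousal
  down against the stimulus);
* **excitation** — alternating neutral (s = 0) / calming (s = -0.05) blocks;
  binary reference 0.5 / 1.5 (drive arousal up against the stimulus);
* **multistep** — staircase reference 0 → 0.75 → 1.5 → 0.75 → 0 over five
  80-step plateaus with mild alternating stimulation.

The canonical battery crosses the six profiles (generation seeds 101–106)
with the three scenario shapes on both controller tracks, 20 paired
seeds per cell (static and dynamic arms share each seed's noise stream),
base seed 0. Seeds are averaged within a profile cell first; profiles are
then weighted equally in the across-profile mean ± SD. On this battery the
dynamic controller reduces tracking RMSE versus static in 35 of 36
profile × scenario × track cells; the adaptive track reduces both RMSE and
effort on the multi-step average, while the robust track trades a ~10%
effort increase for a ~65–70% RMSE reduction. That trade is structural: at
steady state both robust arms spend |d| per step (the static arm through
feedback against its offset, the dynamic arm through `u* = -d̂`), so the
dynamic arm's extra estimate chatter can only be repaid in accuracy, not in
effort.

## Parameter-recovery experiments

Two experiments back the filters' identifiability claims, each with 50
replicates at 2000 steps:

* constant true gain 0.85 under alternating 100-step excitation blocks
  (amplitude 0.1); filter walk variance 1e-4; the terminal gain estimate
  must land within ±0.1 of the truth. The gain is identifiable only while
  the state is away from zero, hence the sustained excitation.
* disturbance step 0 → 0.5 at mid-run with a compensating input −0.5 from
  the step onward (keeping the state bounded, and making the disturbance
  distinguishable from the known input); the terminal-quarter mean estimate
  must land within ±0.15.

## Known limitations

* The generator emulates per-step observation pairs, not raw EDA waveforms:
  there is no SCR deconvolution, no tonic/phasic decomposition, no sampling
  rate — those live upstream of this model family. Passing tests show the
  estimation-and-control machinery works under the stated model; they say
  nothing about model misfit to real skin-conductance data.
* Tonic regression coefficients are supplied (generated or configured), not
  fitted; offline EM estimation from recordings is out of scope.
* The control input is an abstract actuation channel: no latency,
  saturation, or intervention-specific dynamics.
* Step duration is abstract; block lengths and amplitudes are configuration,
  not physiological claims.
* The adaptive and robust designs are evaluated separately; no hybrid
  design is provided.
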