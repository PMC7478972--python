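# Methods

This note documents the models implemented in `halotaxis`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical decisions taken where the design was open.

## The physical picture

A haloarchaeal cell swims at v₀ ≈ 2 μm/s along a gently helical path,
reversing direction at Poisson-distributed intervals with mean
τ_run ≈ 12–15 s. Rotational Brownian motion randomises its heading with
diffusivity D_r ≈ 0.08 s⁻¹, i.e. a directional memory time
τ_r = 1/(2D_r) ≈ 6 s that is *shorter* than a typical run — the opposite
of the regime familiar from fast-swimming bacteria, where
τ_run ≪ τ_r. Chemotaxis is modelled as a weak modulation of the reversal
rate by the recent concentration history (a biased random walk), and the
central quantitative outputs are the chemotactic drift speed v_x up a
linear gradient, the fractional drift v_x/v₀, and the efficiency
ε = v_x/(γ v₀²) with γ the hydrodynamic friction coefficient.

## Synthetic trajectory generator (`synthetic`)

The swimmer is represented by a helix axis **h** (a unit vector), a
transported perpendicular frame (**e₁**, **e₂**), and a phase φ advancing
at the helix angular frequency ω. The instantaneous tangent is

    a = cos θ · h + sin θ (cos φ · e₁ + sin φ · e₂),

so the tangent keeps a fixed pitch angle θ to the axis and the implied
helix radius is r = v₀ sin θ/ω (≈ 0.19 μm at defaults — "small
amplitude"). With no axis diffusion the direction correlation is exactly
cos²θ + sin²θ cos(ωτ). Per frame (dt = 1/frame_rate, no sub-stepping):

1. possible reversal (Poisson probability dt/τ_run, chemotactically
   modulated if enabled): **h** → −**h**, **e₂** → −**e₂**, which keeps
   the frame right-handed and preserves helix handedness;
2. axis rotational diffusion: **h** ← normalize(**h** + ξ),
   ξ ~ N(0, 2 D_r dt I₃) — the isotropic-kick scheme, equivalent to
   per-axis angular increments to O(dt); **e₁** is parallel-transported
   (projected back to the tangent plane), **e₂** = **h** × **e₁**;
3. translation r ← r + v₀ a dt + N(0, 2 D_t dt I₃);
4. after the kinematics, i.i.d. Gaussian localisation noise is added per
   frame (σ_xy = 0.4 μm, σ_z = 0.5 μm).

Defaults are the measured reference conditions: v₀ = 1.9 μm/s,
τ_run = 14.7 s, D_r = 0.081 s⁻¹, 50 Hz. θ = 0.3 rad and ω = 3 rad/s are
representative modal values (only distributions are reported for these);
D_t = 0.15 μm²/s is the orientation-averaged Perrin value for the
effective cell ellipsoid (below).

What the generator does **not** emulate: between-cell speed
heterogeneity (each cell shares one v₀, so population speed spreads are
narrower than measured ones — only the mean is compared to data),
detection dropouts and track fragmentation, depth-dependent noise,
hydrodynamic wall effects, and cell–cell interactions. Passing tests
therefore demonstrate estimator correctness under the stated statistical
model, not robustness to every instrumental artefact.

At 50 Hz the per-frame displacement (0.038 μm) is an order of magnitude
below the localisation noise, so raw finite-difference speeds are
noise-dominated (~28 μm/s); all speed statistics in this package apply to
smoothed tracks.

## Track processing (`processing`)

**Smoothing.** Gaps of ≤ 5 missing frames are linearly interpolated;
longer gaps split the track; pieces shorter than 3 s are discarded. Each
coordinate is smoothed with a penalised cubic smoothing spline. The
penalty is *fixed* (λ = 1.0 μm²·s³) rather than chosen by residual
matching or GCV: calibration against synthetic ground truth showed that
residual-matched and GCV splines under-smooth for derivative estimation
(+15 % to +31 % speed bias at study conditions), whereas the fixed
penalty recovers generating speeds to −2 % with ~0.2 μm RMS deviation
from the noise-free path, and any value in [0.3, 3] stays within 10 %.
The smoothed-track residual RMS then comes out close to the localisation
noise, as it should.

**Motility classification.** Log-log MSD slope α on lags 1–5 s;
swimming if α ≥ 1.5. The window starts at 1 s because below the
smoothing scale even a diffuser's spline looks locally ballistic
(calibrated: smoothed swimmers give α = 1.6–1.9, smoothed diffusers
1.1–1.5 on this window).

**Reversal detection.** The statistic
Ξ(t) = |a(t)·a(t+1)|/Δt · [1 − v_t/⟨v⟩_t] spikes where the smoothed
trajectory folds back and the apparent speed dips. Two caveats,
quantified on synthetic ground truth: (i) the |a·a′| factor is ≈ 1 both
in runs and at reversals, so discrimination rests entirely on the speed
dip; an `angular` variant using arccos(a·a′)/Δt over a configurable
baseline is provided; (ii) for a 1.9 μm/s swimmer with 0.4 μm noise and
D_t ≈ 0.15 μm²/s, *single-event* detection is intrinsically marginal —
frame-accurate localisation is impossible (the cell moves 0.08 μm in two
frames) and isolated event peaks overlap the no-event background. The
default threshold (3 × median|Ξ| per track, with an absolute floor
requiring a ≥ 25 % speed dip, minimum event separation 1 s) was
calibrated so that the *rate* of detected events matches the programmed
rate: across seeds it recovers the event count to a few % and the mean
run duration within ~1 s.e. (individual events: ~70 % precision). On
noise-free tracks detection is exact to a frame or two. First and last
runs are censored (boundary-truncated) and excluded from duration fits,
which would otherwise be biased low.

**Fits.** Exponential run-duration MLE = sample mean, s.e. = mean/√n.
Speed distributions are summarised by a Gaussian (mean, s.d.) over pooled
instantaneous speeds.

## Orientation analysis (`orientation`)

The direction correlation C(τ) = ⟨a(t)·a(t+τ)⟩ is averaged over pairs
within the same run, excluding frames within 1 s of a detected reversal.
The lag grid is dense (every frame) up to 2 s and logarithmic beyond, to
bound cost on long tracks. The model

    C(τ) = exp(−2 D_r τ) [cos²θ + sin²θ cos(ωτ)]

is fitted by bounded least squares (weights √counts per lag), with 8
ω-starts log-spaced between one cycle per curve span and the lag-grid
Nyquist frequency — the objective has local minima in ω. θ = 0 reduces
the model to the pure-Brownian exponential exp(−2 D_r τ); fitting *that*
form to helical data overestimates D_r (the helical wobble is booked as
extra diffusion), which is the reason the full model exists. Populations
of per-track D_r are summarised by a log-normal MLE; its mode
exp(μ − σ²) is the reported central value.

## Chemotaxis assay (`assay`)

Runs are classified by the cosine between their mean direction and the
gradient: up if ≥ 0.5, down if ≤ −0.5 (60° cones; configurable), else
perpendicular (the internal control). The fractional drift estimator is

    v_x/v₀ = f · 2 (T⁺ − T⁻) / (T⁺ + T⁻).

The unprojected form (f = 1) applied to measured sector durations
overstates the drift measured directly by about a factor of three; a
geometric projection factor f = 1/3 — the scale of the mean direction
cosine of runs binned into broad cones, with runs spending much of their
time only partially aligned — reproduces the directly measured values
for both reference strains (20.7/14.6 s → 0.115 ≈ 0.11; 20.2/17.6 s →
0.046 ≈ 0.04). Both factors are available; 1/3 is the default. The
drift s.e.m. is first-order propagation from the sector s.e.m. values.

## Brownian-dynamics simulator (`simulate`, `response`, `friction`)

**Geometry and friction.** Cells are prolate spheroids; translational
and rotational frictions use the closed-form Perrin factors (validated
against numerical quadrature of the shape integrals, and reducing to
Stokes' law for a sphere). The default effective semi-axes (1.9, 0.35) μm
— the cell's width but roughly three times its body length, standing in
for the archaellum's stabilising contribution — give D_r ≈ 0.074 s⁻¹ in
the η = 1.82 mPa·s medium at 298 K, close to the measured 0.08 s⁻¹,
which the simulator sets explicitly. D_t defaults to the
orientation-averaged Perrin value (≈ 0.15 μm²/s); an anisotropic
parallel/perpendicular mode is available. Temperature is configurable
(the study does not state one; 298 K default).

**Response model.** The reorientation rate is
λ(t) = λ [1 − ∫ c(t′) R(t−t′) dt′] with
R(t) = W k e^{−kt}[1 − kt/2 − (kt/2)²] and memory 1/k = 2 s. ∫R dt = 0,
so constant concentrations never bias the rate (perfect adaptation); a
steady ramp of slope g gives a modulation 3Wg/(2k). Modes: `lengthen`
clips the rate at ≤ λ, `shorten` at ≥ λ, `bipolar` is unclipped; the
rate is always floored at 0 and flooring occurrences are counted as a
saturation audit.

The convolution uses three exponentially decaying accumulators (for the
e^{−kt}, t e^{−kt}, t² e^{−kt} components), updated in O(1) per step.
The per-sample weights are the *exact* integrals of R over each dt
interval, so perfect adaptation holds exactly in discrete time (by
telescoping of the antiderivative F(u) = Wku e^{−ku}(1 + ku/4)). This
matters: a rectangle-rule discretisation leaks an O(dt) bias
proportional to the absolute concentration, which grows without bound as
cells climb the linear field c = x. The memory is pre-filled with the
steady state for the starting concentration, so there is no onset
transient from the convolution's lower limit.

**Sensitivity calibration.** W is chosen so that the steady-state
modulation for a cell swimming straight up the gradient equals
β = 0.9: W = 2kβ/(3 v₀ |∇c|) — the largest response that cannot drive
the rate negative for any heading. With this choice the rate-flooring
audit stays below 0.01 % at reference conditions. The response
amplitude matters beyond a scale factor. At β = 0.9 the drift level is
v_x/v₀ ≈ 0.05, the bipolar and run-lengthening responses are optimised
by τ_run ≈ 10 s, the run-shortening response is statistically
indifferent between τ_run = 10 and 20 s, and the fractional drift is
nearly independent of swimming speed. Amplitudes 2–4× larger — which
incur substantial rate flooring — roughly double the drift level, shift
the run-shortening optimum toward 20 s, and introduce a low-speed
penalty (flooring driven by diffusive concentration noise, amplified by
W ∝ 1/v₀) that makes the fractional drift rise with v₀ before
saturating. Measurements quoted by this package use β = 0.9 throughout;
the amplitude-dependent statements above are reproducible with the
``saturation_fraction`` setting.

**Integration.** Per step (dt = 0.033 s): memory update and rate
evaluation; reversal (exact 180° flip) or tumble with probability
λ(t)·dt (a hard error if that product exceeds 1); direction
normalize-after-kick rotational diffusion; translation v₀ dt along the
heading plus diffusive displacement. Initial directions are equilibrated
by 60 s of pure rotational diffusion at zero chemotactic bias.
Correctness checks: reversal counts match T/τ_run; the mode-free
direction correlation decays at 2D_r + 2λ (parity flips at Poisson rate
λ compound with rotational diffusion); the long-time diffusivity matches
the Green–Kubo form v₀²/(3(2D_r + 2λ)); drift without chemotaxis is
statistically zero; halving dt leaves the drift unchanged within the
sampling resolution. The tumble preset (for fast run-and-tumble
comparisons: τ_run = 1 s, v₀ = 20 μm/s, lengthen-only) draws tumble
angles from a gamma distribution with mean 68°, the classic run–tumble
value, as the measured distribution is not published in usable form.

**Observables.** Drift velocity is a straight-line fit of the ensemble
mean position through the origin (its quoted standard error treats
saved samples as independent and is therefore optimistic; tests use the
spread of per-cell displacements instead). MSD along the gradient is
reported as ⟨x²(τ)⟩/τ — measured from the trajectory origin for
chemotactic ensembles (drift breaks stationarity) and with time-origin
averaging for unbiased ones. Efficiency is ε = v_x/(γ v₀²), and the
friction-scaled ε·γ = v_x/v₀² is reported alongside for
geometry-independent comparisons.

## Problem sizes used in tests and the acceptance script

Sweeps run 50 cells × 3000 s per condition (τ_run ∈ {2, 5, 10, 20, 40} s
for three response modes; v₀ ∈ {0.5, 1, 2, 4, 8} μm/s at τ_run = 14.7 s),
with four independent replicate ensembles averaged per grid point —
single ensembles leave neighbouring grid points within ~1 s.e. of each
other, so optimum locations estimated from one ensemble flip from seed
to seed. Transport-property checks use 100–200 cells × 400–3000 s; the
processing pipeline checks use 25–50 tracks of 60–120 s at 50 Hz. Even
with replicates, the run-shortening mode's 10 s vs 20 s comparison and
the speed-sweep argmax remain statistically tied at the β = 0.9 response
amplitude (see the calibration discussion above), and their measured
optima inherit that seed dependence; the bipolar/lengthening optimum at
10 s is resolved robustly.

## Known limitations

* Reversal detection is rate-calibrated, not event-exact, at realistic
  noise; downstream sector statistics inherit ~30 % event impurity.
* The ω (helix frequency) estimate degrades once smoothing suppresses
  the sub-noise helix amplitude; D_r is robust but ω distributions from
  heavily smoothed data should be treated with caution.
* The drift s.e. from the through-origin fit underestimates the true
  ensemble error (correlated residuals); use per-cell spreads for
  inference.
* Unbounded domain with a strictly linear attractant field; no walls,
  no nutrient consumption, no cell–cell interactions, no receptor-level
  signalling dynamics.
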