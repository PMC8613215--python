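# Methods

## Model

`vhisim` models body perception during the virtual-hand illusion as
inference over a one-degree-of-freedom arm: the elbow angle μ⁰ ∈ (−π/2, π/2)
rotating in the horizontal plane, with zero parallel to the sagittal plane
and positive rotation toward the body midline. The belief state comprises
the generalized coordinates (μ⁰, μ¹, μ²) — inferred angle, angular velocity
and acceleration — and the causal variable ν, the perceived horizontal
location of the virtual hand.

Four sensory channels contribute precision-weighted squared errors to the
free energy: the proprioceptive angle (s_p − μ⁰) and velocity (ṡ_p − μ¹),
the causal-binding error (ν − g_v(μ⁰)) between the perceived virtual hand
and the visually predicted own-hand position g_v(μ⁰) = L cos(μ⁰ − π/2) + b,
and the visual measurement error (s_v − ν). A dynamics prior treats the arm
as a mass-spring system expecting no action, f(μ) = [μ¹, −γμ⁰/m, 0];
under the embedding truncation μ³ ≡ 0 the only non-vanishing motion error
is e₂ = μ² + γμ⁰/m, since the first-order error μ¹ − f₁ = μ¹ − μ¹ is
identically zero.

All four updates are derived from the same objective:

- belief: μ̇ = [μ¹, μ², 0] − ∂F/∂μ, ν̇ = −∂F/∂ν;
- action: ȧ = −K_a Π_p (s_p − μ⁰), with ∂s_p/∂a taken as 1 and K_a
  absorbing all scaling. The action never moves the arm (it is physically
  locked); the reported lateral force is `force_scale · a`, positive toward
  the midline;
- precision: Π̇ = −½ ε² + Σ per channel (fixed point at ε² = 2Σ), floored
  at e for the two visual channels and e^0.1 for the two proprioceptive
  channels. The printed form of this precision rule mixes precision and
  variance symbols in the source literature; it is implemented exactly as
  stated, with the stated fixed point, and only its floors are treated as
  hard constraints.

The belief flow is an *exact* gradient flow: the motion-error term
−Π_μ e₂ is assigned to the μ²-row (the order that appears directly in e₂)
together with its chain-rule image −(γ/m) Π_μ e₂ on the μ⁰-row. This exact-
gradient reading is what makes the finite-difference oracle tests possible;
a transcription that places the motion-error components on shifted rows is
not the gradient of any objective and is not used.

### The causality parameter κ

κ ∈ [0, 1] is the believed probability that the visual event (ball bouncing
on the virtual hand) and the tactile event (vibration on the real hand)
share a common source; it is the model's proxy for illusory ownership. κ
enters as a linear weight on the causal-binding channel's precision, so it
scales that error's contribution in *both* the μ⁰-row of the belief update
and the ν update. This keeps the flow an exact gradient; a configuration
switch (`kappa_in_nu_update=False`) removes κ from the ν-row for users who
want the binding weighted asymmetrically, at the cost of exact gradient
correspondence. With κ = 0 the virtual hand decouples from the arm belief
entirely: no drift, no force.

Synchrony maps to κ through a two-anchor linear function of the mean
visuo-tactile delay: any mean delay within the 100 ms simultaneity window
saturates at κ = 1; the mean delay of an ideal fully-random asynchronous
train (uniform on 0.1–0.8 s, mean 0.45 s) maps to κ = 0; intermediate mean
delays interpolate linearly. The functional form is a transparency choice —
only the anchors and monotonicity carry substance — and the discrete
settings used in cohort simulations (κ = 1 synchronous, κ = 0.3
asynchronous, sweep values 0.3/0.6/0.9) are exposed as direct overrides.
The `weak_asynchronous` generator mixes a fraction of near-synchronous
pairs into an asynchronous train; its default fraction (0.26) was chosen so
the expected mean delay maps to κ ≈ 0.3, emulating an experimental
asynchronous mode in which the random vibration timing still allows
participants to bind the two streams.

## Units and numerical conditioning

Public interfaces use the field's conventions: angles in rad, horizontal
positions in cm (L ≈ 44.7 cm, condition offsets ±15 cm), forces in N.
Inside the free energy, positional errors are evaluated in **metres**. This
is a deliberate conditioning choice: the visual precision floor e then
means "visual position SD never worse than ~0.6 m", a physically sensible
bound, and the stiffness of the visual term, (∂g_v/∂μ⁰)² κ Π_c ≈ 0.45² ·
e ≈ 0.5 s⁻¹ at the floor, integrates stably with the 1 ms Euler step that
matches the 1 kHz force recording. Evaluating the same floors on cm²
variances would force the visual stiffness above 10³ s⁻¹ and make the
stated step size divergent. The conversion is a single constant applied at
the free-energy boundary; `free_energy_gradients` reports ν̇ back in cm/s.

Other numerical choices:

- explicit Euler, dt = 1 ms (configurable), all coupled updates evaluated
  from the same current state and applied simultaneously;
- μ⁰ clipped to (−π/2 + 10⁻⁶, π/2 − 10⁻⁶) to keep the visual map's domain;
- belief initialisation at the true locked angle, ν at the displayed
  virtual-hand position, action at 0;
- the windowed mean force uses the half-open interval [10 s, 15 s) — 5000
  samples at 1 kHz;
- degenerate zero-variance t-tests are resolved as limits: all-zero data
  gives t = 0, p = 1; constant nonzero differences give |t| = ∞ with p = 0
  when the direction matches the alternative and p = 1 otherwise.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| L | 44.7208 (sampled N(44.7208, 2.4807) per participant) | cm | forearm length in the visual map |
| b | 0 (sampled N(0, 4.2794) per participant) | cm | localisation bias of the predicted hand |
| σ_sp² | 1 (sampled N(1, 0.5), truncated > 0.05) | rad² | initial proprioceptive variance — individual precision differences |
| σ for velocity channel | 1 | (rad/s)² | fixed prior velocity uncertainty |
| σ for visual channels | e⁻² | m² | initial visual/binding variance (≈13.5 cm SD) |
| Σ_μ | (1, 1, 1) | — | dynamics-prior variances per order |
| m, γ | 1, 1 | model units | mass-spring prior; covered by fixed-point/symmetry tests, not absolute claims |
| K_a | 0.1 | — | action gain |
| κ | 1 / 0.3 | — | synchronous / asynchronous causal binding |
| force_scale | 0.16 | N per model unit | calibrated once so the default synchronous cohort's lateral windowed mean is ≈0.04 N, the order observed in humans |
| observation noise | 0.01 rad, 0.1 cm | per 1 kHz sample | zero-mean Gaussian on s_p and s_v |
| dt, duration | 1 ms, 40 s | s | integration and trial length |

The population distributions are read as (mean, SD); reading the second
argument as a variance would give, e.g., forearm lengths essentially
constant across people, which is implausible. σ_sp² draws are truncated
below at 0.05 to keep precisions finite.

Absolute simulated Newtons depend on the product of K_a, force_scale and
the precision trajectory and are calibration, not prediction: all scientific
claims (and tests) rest on signs, orderings across conditions and
monotonicity in κ.

## Experimental design generator

Each participant: 10 blocks × 12 trials, 4 per virtual-hand location
(Left −15 cm / Center 0 / Right +15 cm), 120 trials per participant, 1680
for the 14-participant study with alternating group assignment (7
synchronous / 7 asynchronous). Within a block, Center trials occupy fixed
positions so lateral stimulation is bracketed by the no-conflict condition;
since the protocol fixes Center "at the beginning, the middle and the end"
but each block holds four Center trials, the symmetric double-middle
placement (1, 6, 7, 12) is adopted, with the all-Left and all-Right runs of
four filling positions 2–5 and 8–11 in per-block random order.

## What the synthetic data emulates — and what it does not

The cohort simulator reproduces the *structure* of the human data: per-trial
windowed mean forces with participant-level heterogeneity (sampled σ_sp², b,
L), condition-dependent sign, and κ-dependent magnitude.
`synth_force_table` additionally generates human-*scale* tables (condition
mean shifts + participant intercepts + trial noise) on the exact schedule,
used for pipeline validation and power/null calibration. Neither captures:
drifts and saturation of attention over a session, musculoskeletal dynamics
or co-contraction, the emergence or decay of the ownership illusion itself
(κ is set, not inferred), within-trial nonstationarities of real force
traces beyond the model's own transient, or any subjective ownership
measure. Passing tests therefore demonstrate internal correctness and the
model's qualitative predictions, not quantitative fit to any particular
human dataset. Statistics on recorded data require the per-trial force
table to be supplied in the documented CSV schema.

## Problem sizes

Default test and acceptance runs use the study's sample sizes where cheap
(20 simulated participants, 10 per κ value, 14-participant synthetic
tables) and reduced trial counts per condition (2–4) elsewhere; trial
durations in unit tests are shortened to 5–15 s (the analysis window needs
15 s) since the belief transient settles within ~2 s. The κ-sweep and
attenuation comparisons reuse matched participant and noise seeds across κ
so differences are paired, not sampled.

## Known limitations

- One joint, one spatial axis: no shoulder/wrist redundancy, no depth.
- Truncated generalized coordinates (three orders) with μ³ ≡ 0.
- The precision dynamics follow the stated rule verbatim; its sign
  conventions admit other readings, and only the floors and the stated
  fixed point are relied upon.
- κ is a per-trial constant; real binding presumably evolves within trials.
- The synchrony → κ interpolation between anchors is a modelling choice;
  only its anchors and monotonicity are testable.
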