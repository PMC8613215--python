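# vhisim

Active-inference simulation and force analysis for the **virtual-hand
illusion** (VHI).

When people embody a rubber or virtual hand that is displaced from their
real, hidden hand, they do not only *perceive* their hand closer to the fake
one (proprioceptive drift) — they also *push* toward it, involuntarily, even
when instructed to stay still. `vhisim` implements a computational account
of this active component: perception and action are both cast as gradient
descent on a free-energy bound (precision-weighted prediction error), so
that a visuo-proprioceptive conflict simultaneously produces perceptual
drifts and a lateral force toward the virtual hand. The package is for
computational and experimental researchers in body representation who want
to generate the model's behavioural predictions, simulate whole cohorts
under the experimental protocol, and run the matching force-statistics
pipeline on simulated or recorded data — without any VR or robotic
hardware.

## The model

A single degree of freedom: the elbow angle of the (locked) left arm,
rotating in the horizontal plane. The agent holds a generalized-coordinate
belief μ = (μ⁰, μ¹, μ²) about the angle and its derivatives, plus a causal
variable ν — the perceived horizontal location of the virtual hand (cm,
positive toward the body midline). The generative model predicts

- proprioception: ŝ_p = μ⁰, ŝ̇_p = μ¹,
- vision: ŝ_v via g_v(μ⁰) = L·cos(μ⁰ − π/2) + b, with forearm length L and
  a participant-specific localisation bias b,
- dynamics: a mass-spring prior f(μ) = [μ¹, −γμ⁰/m, 0] that expects no
  action.

Beliefs evolve by the generalized shift plus the negative gradient of the
precision-weighted squared error F:

μ̇ = Dμ − ∂F/∂μ,  ν̇ = −∂F/∂ν

The binding error between the perceived virtual hand and the predicted hand
position, ν − g_v(μ⁰), is weighted by the **causality parameter κ ∈ [0, 1]**
— the believed probability that the visual (ball bouncing on the virtual
hand) and tactile (vibration on the real hand) events share a common
source. κ is driven by visuo-tactile synchrony: delays within 100 ms give
κ = 1, a fully random asynchronous train gives κ = 0. Sensory precisions
are themselves optimised online (floored at e for vision and e^0.1 for
proprioception), and the action follows the reflex-arc update

ȧ = −K_a · Σ_p⁻¹ · (s_p − μ⁰),

read out as a lateral force (N, positive toward the midline) while the arm
stays locked. With the virtual hand displaced, μ⁰ drifts toward it, the
proprioceptive error s_p − μ⁰ becomes nonzero, and the integrated action
pushes toward the virtual hand — attenuated as κ decreases.

## Worked example

```python
import vhisim as v

params = v.ModelParams()                      # population defaults, kappa = 1
trial = v.TrialConfig(offset=15.0)            # virtual hand 15 cm toward the midline
res = v.simulate_trial(params, trial, rng_seed=0)

print(f"windowed mean force (10-15 s): {v.window_mean(res):+.3f} N")
print(f"proprioceptive drift:          {res.proprio_drift:+.2f} cm")
print(f"visual drift:                  {res.visual_drift:+.2f} cm")

table = v.simulate_cohort(n_sync=10, n_async=10, trials_per_condition=4, rng_seed=0)
print(v.ForceStats(table).fit().summary())
```

prints

```
windowed mean force (10-15 s): +0.041 N
proprioceptive drift:          +1.68 cm
visual drift:                  -6.66 cm
Lateral-force statistics
============================================================
trials: 240   participants: 20

Condition means (N):
  Left    -0.0288 (SD 0.0094)
  Center   0.0022 (SD 0.0081)
  Right    0.0331 (SD 0.0151)

Trial-level ANOVA (location x mode):
  location     F(2, 234) = 1483.60, p = 1.19e-133
  mode         F(1, 234) = 73.09, p = 1.62e-15
  interaction  F(2, 234) = 140.23, p = 9.33e-41

Post-hoc t-tests (participant aggregates):
  Center vs 0     t(19) = 1.19, p = 0.25 (two-sided)
  Right > Center  t(19) = 13.98, p = 9.4e-12 (greater)
  Left < Center   t(19) = -13.89, p = 1.06e-11 (less)
```

Reading the output: a virtual hand 15 cm toward the midline draws the
inferred hand ~1.7 cm toward it while the perceived virtual hand shifts
~6.7 cm back toward the body, and the locked arm pushes ~0.04 N toward the
virtual hand. Across a 20-participant simulated cohort the force tracks the
virtual-hand location (Left negative, Right positive), the collocated
Center condition is compatible with zero force, and the asynchronous group
(κ = 0.3) shows attenuated forces — the significant mode effect and
interaction in the trial-level ANOVA.

The same machinery is available from the shell:

```bash
vhisim simulate --n-sync 10 --n-async 10 --seed 0 --out run/
vhisim analyze --table run/trial_table.csv --out run_stats/
vhisim sweep --kappa 0 --kappa 0.3 --kappa 0.6 --kappa 0.9 --seed 0
vhisim design --print-block
vhisim events --mode weak_asynchronous
```

A recorded per-trial force table (columns `pid, group, block, trial,
condition, mean_force_N`, adaptable via a column map) can be fed to
`vhisim analyze` / `vhisim.load_force_table` to run the identical pipeline
on human data.

## Layout

- `vhisim.core` — generative model, free-energy gradients, action and
  precision updates, trial integration
- `vhisim.stimulation` — visuo-tactile event trains and the synchrony → κ map
- `vhisim.cohort` — participant sampling and cohort/κ-sweep simulation
- `vhisim.design` — block/trial schedule of the human experiment
- `vhisim.analysis` — offset removal, windowed means, ANOVA and post-hoc
  t-tests, synthetic force tables, `ForceStats` facade
- `vhisim.cli` — `vhisim` command-line entry points
- `docs/methods.md` — modelling assumptions, parameter choices and
  numerical details
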