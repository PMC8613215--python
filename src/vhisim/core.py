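"""Generative model and coupled perception-action-precision updates.

The agent infers its elbow angle in generalized coordinates
``mu = (mu0, mu1, mu2)`` (position, velocity, acceleration) together with the
perceived horizontal location ``nu`` of the virtual hand, by descending the
gradient of a precision-weighted squared-error free energy.  Four sensory
channels enter the free energy:

====================  =========================  =====================
channel               observation                prediction
====================  =========================  =====================
proprioceptive angle  ``s_p``                    ``mu0``
proprioceptive vel.   ``s_p_dot``                ``mu1``
causal binding        ``nu``                     ``g_v(mu0)``
visual position       ``s_v``                    ``nu``
====================  =========================  =====================

with ``g_v(mu0) = L cos(mu0 - pi/2) + b`` the visual generative map.  The
causal-binding channel is weighted by the causality parameter ``kappa``
(the believed probability that visual and tactile events share a source), so
``kappa = 0`` severs the influence of the virtual hand on the arm belief.
A dynamics prior models the arm as a mass-spring system that expects no
action.  The action variable integrates the proprioceptive prediction error
(reflex arc); because the hand is physically locked the action never moves
the arm and is read out as a lateral force instead.

Angles are rad, horizontal positions cm at the interface (metres inside the
free energy; see :mod:`vhisim.params`).  Positive positions and forces point
toward the body midline.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np

from .params import (
    M_PER_CM,
    ModelParams,
    TrialConfig,
    clamp_precisions,
)

#: half-width of the admissible elbow-angle interval, minus the clamp margin.
_MU0_LIMIT = math.pi / 2 - 1e-6


@dataclass
class ArmBelief:
    """Generalized-coordinate belief about the arm plus the causal variable.

    ``mu0``/``mu1``/``mu2`` are the inferred elbow angle (rad), angular
    velocity and acceleration; ``nu`` is the perceived horizontal location of
    the virtual hand (cm).
    """

    mu0: float = 0.0
    mu1: float = 0.0
    mu2: float = 0.0
    nu: float = 0.0

    def __post_init__(self) -> None:
        for name in ("mu0", "mu1", "mu2", "nu"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"ArmBelief.{name} must be finite")
        if not -math.pi / 2 < self.mu0 < math.pi / 2:
            raise ValueError("mu0 must lie in (-pi/2, pi/2)")

    @property
    def mu(self) -> np.ndarray:
        return np.array([self.mu0, self.mu1, self.mu2])


@dataclass
class Sensations:
    """Observed proprioceptive angle/velocity (rad, rad/s) and virtual-hand
    position (cm).  With the arm locked, ``s_p`` stays at the true angle
    (plus observation noise) for the whole trial."""

    s_p: float = 0.0
    s_p_dot: float = 0.0
    s_v: float = 0.0


@dataclass
class Action:
    """Accumulated action variable and its calibration to Newtons.

    The lateral force reported by the model is ``force_scale * a``, positive
    when directed toward the body midline (torso)."""

    a: float = 0.0
    force_scale: float = 0.16

    def __post_init__(self) -> None:
        if not math.isfinite(self.a):
            raise ValueError("action variable must be finite")
        if self.force_scale <= 0:
            raise ValueError("force_scale must be positive")

    @property
    def force(self) -> float:
        return self.force_scale * self.a


@dataclass
class TrialResult:
    """Traces and summary drifts of one simulated stimulation trial."""

    time: np.ndarray          # s, 1 ms grid
    force: np.ndarray         # N, positive toward the midline
    mu0_trace: np.ndarray     # rad
    nu_trace: np.ndarray      # cm
    proprio_drift: float      # cm: g_v(mu0_final) - g_v(true angle)
    visual_drift: float       # cm: nu_final - s_v
    config: TrialConfig | None = None
    params: ModelParams | None = None

    def __post_init__(self) -> None:
        n = len(self.time)
        if not (len(self.force) == len(self.mu0_trace) == len(self.nu_trace) == n):
            raise ValueError("all traces must have equal length")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.time,
                "force_N": self.force,
                "mu0_rad": self.mu0_trace,
                "nu_cm": self.nu_trace,
            }
        )

    def to_csv(self, path) -> None:
        """Tidy CSV with a commented metadata header block."""
        buf = io.StringIO()
        meta = {
            "proprio_drift_cm": self.proprio_drift,
            "visual_drift_cm": self.visual_drift,
        }
        if self.config is not None:
            meta.update({f"trial.{k}": v for k, v in self.config.to_dict().items()})
        if self.params is not None:
            meta.update({f"model.{k}": v for k, v in self.params.to_dict().items()})
        for k, v in meta.items():
            buf.write(f"# {k}: {v}\n")
        self.to_frame().to_csv(buf, index=False)
        with open(path, "w") as fh:
            fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# generative model
# ---------------------------------------------------------------------------

def predict_visual(mu0, params: ModelParams):
    """Noise-free visual prediction of the hand position, cm.

    ``g_v(mu0) = L cos(mu0 - pi/2) + b``; at mu0 = 0 the arm is parallel to
    the sagittal plane and the (unbiased) projection is 0.
    """
    mu0 = np.asarray(mu0, dtype=float)
    if np.any(np.abs(mu0) >= math.pi / 2):
        raise ValueError("mu0 outside the admissible interval (-pi/2, pi/2)")
    return params.L * np.cos(mu0 - math.pi / 2) + params.b


def visual_jacobian(mu0, params: ModelParams):
    """d g_v / d mu0 in cm/rad: ``-L sin(mu0 - pi/2)``."""
    mu0 = np.asarray(mu0, dtype=float)
    if np.any(np.abs(mu0) > math.pi / 2):
        raise ValueError("mu0 outside the admissible interval [-pi/2, pi/2]")
    return -params.L * np.sin(mu0 - math.pi / 2)


def dynamics_model(belief: ArmBelief, params: ModelParams) -> np.ndarray:
    """Expected generalized motion of the mass-spring prior (no action):
    ``f(mu) = [mu1, -gamma*mu0/m, 0]``."""
    if params.m == 0:
        raise ValueError("arm mass m must be nonzero")
    return np.array([belief.mu1, -params.gamma * belief.mu0 / params.m, 0.0])


def free_energy(belief: ArmBelief, s: Sensations, params: ModelParams,
                precisions=None) -> float:
    """Precision-weighted squared-error objective (Laplace free energy).

    ``precisions`` are the four current sensory precisions; defaults to the
    floor-clamped inverse of ``params.sigma_s``.  Positional errors are
    evaluated in metres.  The causal-binding term is weighted by kappa, so
    its precision is effectively ``kappa * pi_c``.
    """
    pi = _precisions(params, precisions)
    pi_mu = 1.0 / np.asarray(params.sigma_mu)
    g_m = (params.L * math.sin(belief.mu0) + params.b) * M_PER_CM
    nu_m = belief.nu * M_PER_CM
    s_v_m = s.s_v * M_PER_CM
    e_p = s.s_p - belief.mu0
    e_pv = s.s_p_dot - belief.mu1
    e_c = nu_m - g_m
    e_v = s_v_m - nu_m
    # motion error of the second order: e2 = mu2 - f_2(mu); the first- and
    # third-order motion errors vanish identically under the truncation
    # mu^[3] = 0 (e1 = mu1 - mu1, e3 = 0 - 0).
    e2 = belief.mu2 + params.gamma * belief.mu0 / params.m
    return 0.5 * (
        pi[0] * e_p**2
        + pi[1] * e_pv**2
        + params.kappa * pi[2] * e_c**2
        + pi[3] * e_v**2
        + pi_mu[1] * e2**2
    )


def free_energy_gradients(belief: ArmBelief, s: Sensations, params: ModelParams,
                          precisions=None):
    """Right-hand side of the belief dynamics: ``(dmu, dnu)``.

    ``dmu`` (rad/s, rad/s^2, rad/s^3) is the generalized shift
    ``[mu1, mu2, 0]`` plus the negative free-energy gradient; ``dnu`` (cm/s)
    is the negative gradient with respect to the perceived virtual-hand
    location, taken in metre coordinates and converted.  ``nu`` therefore
    relaxes toward a precision-weighted compromise between the measured
    virtual-hand position ``s_v`` and the predicted hand position
    ``g_v(mu0)`` (the visual drift); with kappa = 0 the arm belief and the
    virtual hand decouple entirely.
    """
    pi = _precisions(params, precisions)
    pi_mu = 1.0 / np.asarray(params.sigma_mu)
    if np.any(pi <= 0) or np.any(pi_mu <= 0):
        raise ValueError("precisions must be positive")

    L_m = params.L * M_PER_CM
    g_m = L_m * math.sin(belief.mu0) + params.b * M_PER_CM
    dg_m = L_m * math.cos(belief.mu0)
    nu_m = belief.nu * M_PER_CM
    e_p = s.s_p - belief.mu0
    e_pv = s.s_p_dot - belief.mu1
    e_c = nu_m - g_m
    e_v = s.s_v * M_PER_CM - nu_m
    e2 = belief.mu2 + params.gamma * belief.mu0 / params.m

    grad0 = pi[0] * e_p + params.kappa * pi[2] * dg_m * e_c \
        - (params.gamma / params.m) * pi_mu[1] * e2
    grad1 = pi[1] * e_pv
    grad2 = -pi_mu[1] * e2
    dmu = np.array([belief.mu1 + grad0, belief.mu2 + grad1, grad2])

    k_nu = params.kappa if params.kappa_in_nu_update else 1.0
    dnu_m = pi[3] * e_v - k_nu * pi[2] * e_c
    return dmu, dnu_m / M_PER_CM


def action_update(a: Action, s: Sensations, belief: ArmBelief,
                  params: ModelParams, precisions=None, dt: float = 0.001) -> Action:
    """One Euler step of the action (reflex-arc) variable.

    ``da = -K_a * (ds_p/da) * pi_p * (s_p - mu0)`` with ``ds_p/da = 1`` (the
    action is expressed in units of the proprioceptive channel; ``K_a``
    absorbs all scaling).  The physical hand position is never updated: the
    arm is locked and the accumulated action is read out as force.
    """
    pi = _precisions(params, precisions)
    da = -params.K_a * pi[0] * (s.s_p - belief.mu0)
    return Action(a=a.a + dt * da, force_scale=a.force_scale)


def precision_update(params: ModelParams, s: Sensations, belief: ArmBelief,
                     precisions=None, dt: float = 0.001) -> np.ndarray:
    """One gradient step of the sensory precisions, then floor clamping.

    Follows the precision dynamics ``dPi = -(1/2) (s - g(mu))^2 + Sigma_s``
    per channel (fixed point at squared error equal to twice the variance),
    with the visual channels floored at exp(1) and the proprioceptive
    channels at exp(0.1).  Returns the updated 4-vector of precisions.
    """
    pi = _precisions(params, precisions)
    errs = _channel_errors(belief, s, params)
    new = pi + dt * (-0.5 * errs**2 + 1.0 / pi)
    return clamp_precisions(new, params)


def _channel_errors(belief: ArmBelief, s: Sensations, params: ModelParams) -> np.ndarray:
    g_m = (params.L * math.sin(belief.mu0) + params.b) * M_PER_CM
    return np.array([
        s.s_p - belief.mu0,
        s.s_p_dot - belief.mu1,
        belief.nu * M_PER_CM - g_m,
        (s.s_v - belief.nu) * M_PER_CM,
    ])


def _precisions(params: ModelParams, precisions) -> np.ndarray:
    if precisions is None:
        return params.initial_precisions
    pi = np.asarray(precisions, dtype=float)
    if pi.shape[-1] != 4:
        raise ValueError("expected 4 sensory precisions")
    return pi


# ---------------------------------------------------------------------------
# trial integration
# ---------------------------------------------------------------------------

def simulate_trial(profile_or_params, trial: TrialConfig | None = None,
                   rng_seed=None) -> TrialResult:
    """Integrate one stimulation trial with the physical hand locked.

    Parameters
    ----------
    profile_or_params
        A :class:`~vhisim.params.ModelParams` or any object with a
        ``to_params()`` method (e.g. a sampled participant profile).
    trial
        Trial configuration (condition offset, duration, step, noise).
    rng_seed
        Seed (int or numpy SeedSequence/Generator) for the observation noise.

    The virtual hand is displayed at the unbiased projection of the true
    angle plus the condition offset; the proprioceptive observation stays at
    the true (locked) angle.  Returns full 1 kHz traces plus the final
    proprioceptive and visual drifts derived through the visual map.
    """
    params = _as_params(profile_or_params)
    if trial is None:
        trial = TrialConfig()
    n = trial.n_steps
    rng = np.random.default_rng(rng_seed)
    if trial.noise and trial.noise_sd_proprio > 0:
        noise_p = rng.normal(0.0, trial.noise_sd_proprio, size=(1, n))
    else:
        noise_p = np.zeros((1, n))
    if trial.noise and trial.noise_sd_visual > 0:
        noise_v = rng.normal(0.0, trial.noise_sd_visual, size=(1, n))
    else:
        noise_v = np.zeros((1, n))

    arrays = batch_arrays([params], [trial])
    force, mu0_tr, nu_tr = integrate_batch(
        arrays, noise_p, noise_v, trial.dt, n, record_traces=True
    )
    time = np.arange(n) * trial.dt
    true_proj = params.L * math.sin(trial.true_angle)
    s_v_base = true_proj + trial.offset
    mu0_f = mu0_tr[0, -1]
    proprio_drift = params.L * (math.sin(mu0_f) - math.sin(trial.true_angle))
    visual_drift = nu_tr[0, -1] - s_v_base
    return TrialResult(
        time=time,
        force=force[0],
        mu0_trace=mu0_tr[0],
        nu_trace=nu_tr[0],
        proprio_drift=proprio_drift,
        visual_drift=visual_drift,
        config=trial,
        params=params,
    )


def _as_params(profile_or_params) -> ModelParams:
    if isinstance(profile_or_params, ModelParams):
        return profile_or_params
    if hasattr(profile_or_params, "to_params"):
        return profile_or_params.to_params()
    raise TypeError(
        "expected ModelParams or an object with to_params(), got "
        f"{type(profile_or_params).__name__}"
    )


def batch_arrays(params_list, trial_list) -> dict:
    """Pack per-trial model constants into flat arrays for lockstep
    integration of many trials."""
    if len(params_list) != len(trial_list):
        raise ValueError("params_list and trial_list must have equal length")
    get_p = lambda attr: np.array([getattr(p, attr) for p in params_list], float)
    get_t = lambda attr: np.array([getattr(t, attr) for t in trial_list], float)
    arr = {
        "L_m": get_p("L") * M_PER_CM,
        "b_m": get_p("b") * M_PER_CM,
        "gamma": get_p("gamma"),
        "m": get_p("m"),
        "K_a": get_p("K_a"),
        "kappa": get_p("kappa"),
        "force_scale": get_p("force_scale"),
        "pi0": np.stack([p.initial_precisions for p in params_list]),
        "pi_mu2": np.array([1.0 / p.sigma_mu[1] for p in params_list]),
        "floor_p": get_p("precision_floor_proprio"),
        "floor_v": get_p("precision_floor_visual"),
        "k_nu": np.array(
            [p.kappa if p.kappa_in_nu_update else 1.0 for p in params_list]
        ),
        "true_angle": get_t("true_angle"),
    }
    arr["s_v_base_m"] = (
        np.array([p.L for p in params_list]) * np.sin(arr["true_angle"])
        + get_t("offset")
    ) * M_PER_CM
    return arr


def integrate_batch(arr: dict, noise_p: np.ndarray, noise_v_cm: np.ndarray,
                    dt: float, n_steps: int, record_traces: bool = False):
    """Explicit-Euler integration of B trials in lockstep.

    All updates (belief, perceived virtual-hand location, action, precisions)
    are evaluated from the same current state and applied simultaneously.
    Returns ``(force, mu0_trace, nu_trace_cm)``; the traces are None unless
    ``record_traces``.
    """
    B = noise_p.shape[0]
    L_m, b_m = arr["L_m"], arr["b_m"]
    gamma, m_mass = arr["gamma"], arr["m"]
    kappa, k_nu = arr["kappa"], arr["k_nu"]
    K_a, force_scale = arr["K_a"], arr["force_scale"]
    pi_mu2 = arr["pi_mu2"]
    floor_p, floor_v = arr["floor_p"], arr["floor_v"]
    s_p_true = arr["true_angle"].copy()
    s_v_base = arr["s_v_base_m"]
    noise_v = noise_v_cm * M_PER_CM

    mu0 = s_p_true.copy()
    mu1 = np.zeros(B)
    mu2 = np.zeros(B)
    nu = s_v_base.copy()
    a = np.zeros(B)
    pi = arr["pi0"].copy()          # (B, 4)
    pi_p, pi_pv, pi_c, pi_v = (pi[:, i].copy() for i in range(4))

    force = np.empty((B, n_steps))
    mu0_tr = np.empty((B, n_steps)) if record_traces else None
    nu_tr = np.empty((B, n_steps)) if record_traces else None

    for k in range(n_steps):
        s_p = s_p_true + noise_p[:, k]
        s_v = s_v_base + noise_v[:, k]

        sin_mu0 = np.sin(mu0)
        g = L_m * sin_mu0 + b_m
        dg = L_m * np.cos(mu0)
        e_p = s_p - mu0
        e_pv = -mu1
        e_c = nu - g
        e_v = s_v - nu
        e2 = mu2 + gamma * mu0 / m_mass

        dmu0 = mu1 + pi_p * e_p + kappa * pi_c * dg * e_c \
            - (gamma / m_mass) * pi_mu2 * e2
        dmu1 = mu2 + pi_pv * e_pv
        dmu2 = -pi_mu2 * e2
        dnu = pi_v * e_v - k_nu * pi_c * e_c
        da = -K_a * pi_p * e_p

        mu0 = np.clip(mu0 + dt * dmu0, -_MU0_LIMIT, _MU0_LIMIT)
        mu1 = mu1 + dt * dmu1
        mu2 = mu2 + dt * dmu2
        nu = nu + dt * dnu
        a = a + dt * da

        pi_p = np.maximum(pi_p + dt * (-0.5 * e_p**2 + 1.0 / pi_p), floor_p)
        pi_pv = np.maximum(pi_pv + dt * (-0.5 * e_pv**2 + 1.0 / pi_pv), floor_p)
        pi_c = np.maximum(pi_c + dt * (-0.5 * e_c**2 + 1.0 / pi_c), floor_v)
        pi_v = np.maximum(pi_v + dt * (-0.5 * e_v**2 + 1.0 / pi_v), floor_v)

        force[:, k] = force_scale * a
        if record_traces:
            mu0_tr[:, k] = mu0
            nu_tr[:, k] = nu

    if record_traces:
        return force, mu0_tr, nu_tr / M_PER_CM
    return force, None, None
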