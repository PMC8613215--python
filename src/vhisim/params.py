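"""Model parameters for the 1-DOF active-inference arm.

The generative model sees the elbow angle (rad) and the horizontal position of
the virtual hand.  Horizontal positions are expressed in centimetres at every
public interface (forearm length ``L``, perceptual bias ``b``, virtual-hand
offsets); inside the free-energy computation positional prediction errors are
evaluated in metres so that the fixed precision floors ``exp(1)`` (visual) and
``exp(0.1)`` (proprioception) correspond to plausible maximum sensory
uncertainties and the gradient flow is well conditioned at a 1 ms Euler step.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Optional

import yaml

#: metres per centimetre — positional channels are converted once, internally.
M_PER_CM = 0.01

#: minimum precision of the visual channels (virtual-hand position and the
#: causal binding error), as stated for the model: exp(1).
PRECISION_FLOOR_VISUAL = math.e

#: minimum precision of the proprioceptive channels: exp(0.1).
PRECISION_FLOOR_PROPRIO = math.exp(0.1)


@dataclass
class ModelParams:
    """Constants of the generative model and its initial precisions.

    Parameters
    ----------
    L : float
        Forearm length in cm.  Cohort sampling draws it from N(44.7208, 2.4807).
    b : float
        Participant-specific localisation bias of the predicted hand position, cm.
    m : float
        Arm mass in model units (mass-spring dynamics prior).
    gamma : float
        Viscosity of the dynamics prior, model units.
    K_a : float
        Gain of the action (reflex-arc) update.
    kappa : float
        Causality weight in [0, 1]: the believed probability that the visual
        and tactile events share a common source.  It linearly scales the
        precision of the causal (virtual-hand binding) channel.
    sigma_s : tuple of float
        Initial sensory variances per channel
        ``(proprio angle [rad^2], proprio velocity [(rad/s)^2],
        causal binding [m^2], visual position [m^2])``.
    sigma_mu : tuple of float
        Dynamics (model) variances per generalized order.
    force_scale : float
        Calibration from accumulated-action model units to Newtons.  The
        default is set so that a default synchronous cohort produces lateral
        window-mean forces of ~0.04 N, the order of magnitude observed in
        human participants.
    kappa_in_nu_update : bool
        Whether kappa also weights the causal-channel term of the perceived
        virtual-hand-location update (default True, which makes the full
        update an exact gradient flow of the free energy).
    """

    L: float = 44.7208
    b: float = 0.0
    m: float = 1.0
    gamma: float = 1.0
    K_a: float = 0.1
    kappa: float = 1.0
    sigma_s: tuple = (1.0, 1.0, math.exp(-2.0), math.exp(-2.0))
    sigma_mu: tuple = (1.0, 1.0, 1.0)
    precision_floor_visual: float = PRECISION_FLOOR_VISUAL
    precision_floor_proprio: float = PRECISION_FLOOR_PROPRIO
    force_scale: float = 0.16
    kappa_in_nu_update: bool = True

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError(f"forearm length L must be positive, got {self.L}")
        if self.m <= 0:
            raise ValueError(f"arm mass m must be positive, got {self.m}")
        if self.gamma < 0:
            raise ValueError(f"viscosity gamma must be >= 0, got {self.gamma}")
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError(f"kappa must lie in [0, 1], got {self.kappa}")
        if self.force_scale <= 0:
            raise ValueError("force_scale must be positive")
        self.sigma_s = tuple(float(v) for v in self.sigma_s)
        self.sigma_mu = tuple(float(v) for v in self.sigma_mu)
        if len(self.sigma_s) != 4:
            raise ValueError("sigma_s must have 4 entries (s_p, s_p_dot, causal, visual)")
        if len(self.sigma_mu) != 3:
            raise ValueError("sigma_mu must have 3 entries (one per generalized order)")
        if any(v <= 0 for v in self.sigma_s) or any(v <= 0 for v in self.sigma_mu):
            raise ValueError("all variances must be positive")

    # -- convenience views -------------------------------------------------

    @property
    def initial_precisions(self):
        """Initial sensory precisions (inverse variances), floor-clamped."""
        import numpy as np

        pi = 1.0 / np.asarray(self.sigma_s, dtype=float)
        return clamp_precisions(pi, self)

    def replace(self, **kwargs) -> "ModelParams":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sigma_s"] = list(self.sigma_s)
        d["sigma_mu"] = list(self.sigma_mu)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown ModelParams fields: {sorted(unknown)}")
        return cls(**d)


def clamp_precisions(pi, params: ModelParams):
    """Apply the fixed precision floors to a 4-channel precision vector.

    Channels 0-1 (proprioception) are floored at exp(0.1); channels 2-3
    (causal binding and visual position) at exp(1).
    """
    import numpy as np

    pi = np.array(pi, dtype=float, copy=True)
    pi[..., 0] = np.maximum(pi[..., 0], params.precision_floor_proprio)
    pi[..., 1] = np.maximum(pi[..., 1], params.precision_floor_proprio)
    pi[..., 2] = np.maximum(pi[..., 2], params.precision_floor_visual)
    pi[..., 3] = np.maximum(pi[..., 3], params.precision_floor_visual)
    return pi


@dataclass
class TrialConfig:
    """Configuration of one 40 s visuo-tactile stimulation trial.

    The physical hand is locked at ``true_angle``; the virtual hand is shown
    at the unbiased projection of the true angle plus ``offset`` cm
    (Left = -15, Center = 0, Right = +15 by convention, increasing toward the
    body midline).
    """

    offset: float = 0.0
    true_angle: float = 0.0
    duration: float = 40.0
    dt: float = 0.001
    noise_sd_proprio: float = 0.01   # rad, per 1 kHz sample
    noise_sd_visual: float = 0.1     # cm, per 1 kHz sample
    noise: bool = True

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"trial duration must be positive, got {self.duration}")
        if self.dt <= 0:
            raise ValueError(f"integration step dt must be positive, got {self.dt}")
        if not -math.pi / 2 < self.true_angle < math.pi / 2:
            raise ValueError("true_angle must lie in (-pi/2, pi/2)")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


#: standard virtual-hand locations, cm relative to the real hand projection.
CONDITION_OFFSETS = {"Left": -15.0, "Center": 0.0, "Right": 15.0}


def load_config(path) -> dict:
    """Read a YAML/JSON run configuration into a plain dict."""
    with open(path) as fh:
        text = fh.read()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def params_from_config(cfg: dict) -> ModelParams:
    return ModelParams.from_dict(cfg.get("model", {}))


def trial_from_config(cfg: dict, offset: Optional[float] = None) -> TrialConfig:
    d = dict(cfg.get("trial", {}))
    if offset is not None:
        d["offset"] = offset
    return TrialConfig(**d)
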