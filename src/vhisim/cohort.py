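"""Virtual participants and simulated cohorts.

Individual differences are generated by sampling, per participant, the
initial proprioceptive variance sigma_sp^2 ~ N(1, 0.5) (truncated below at
0.05), the localisation bias b ~ N(0, 4.2794) cm and the forearm length
L ~ N(44.7208, 2.4807) cm; all other model constants are shared.  The
causality parameter follows the stimulation group (kappa = 1 synchronous,
0.3 asynchronous) unless overridden, e.g. for a kappa sweep.

Cohort runs produce the same per-trial table schema as the human experiment
(participant, group, block, trial, condition, windowed mean lateral force),
so the identical statistical pipeline applies to both.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import batch_arrays, integrate_batch
from .params import CONDITION_OFFSETS, ModelParams, TrialConfig

GROUP_KAPPA = {"synchronous": 1.0, "asynchronous": 0.3}

#: truncation floor for the sampled initial proprioceptive variance.
SIGMA_SP2_MIN = 0.05

# analysis window of the windowed mean force, s (10 s to 15 s of stimulation)
WINDOW = (10.0, 15.0)


@dataclass
class ParticipantProfile:
    """One virtual participant: sampled perceptual constants plus kappa."""

    pid: int
    group: str
    sigma_sp2: float
    b: float
    L: float
    kappa: float

    def __post_init__(self) -> None:
        if self.sigma_sp2 <= 0:
            raise ValueError("sigma_sp2 must be positive")
        if self.L <= 0:
            raise ValueError("forearm length must be positive")
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError("kappa must lie in [0, 1]")

    def to_params(self, base: Optional[ModelParams] = None) -> ModelParams:
        base = base if base is not None else ModelParams()
        sigma_s = (self.sigma_sp2,) + tuple(base.sigma_s[1:])
        return base.replace(L=self.L, b=self.b, kappa=self.kappa, sigma_s=sigma_s)


def sample_participant(group: str, rng_seed=None, pid: int = 0,
                       kappa: Optional[float] = None) -> ParticipantProfile:
    """Draw one participant from the population distributions.

    ``kappa`` defaults to the group's value (1.0 synchronous /
    0.3 asynchronous) and can be overridden for sweeps.
    """
    if group not in GROUP_KAPPA:
        raise ValueError(f"unknown group {group!r}; expected one of {tuple(GROUP_KAPPA)}")
    rng = np.random.default_rng(rng_seed)
    sigma_sp2 = rng.normal(1.0, 0.5)
    while sigma_sp2 <= SIGMA_SP2_MIN:
        sigma_sp2 = rng.normal(1.0, 0.5)
    b = rng.normal(0.0, 4.2794)
    L = rng.normal(44.7208, 2.4807)
    while L <= 0:  # pragma: no cover - ~18 sigma event
        L = rng.normal(44.7208, 2.4807)
    return ParticipantProfile(
        pid=pid,
        group=group,
        sigma_sp2=float(sigma_sp2),
        b=float(b),
        L=float(L),
        kappa=GROUP_KAPPA[group] if kappa is None else float(kappa),
    )


def _run_trials(profiles: Sequence[ParticipantProfile],
                specs: list[tuple],
                base_params: ModelParams,
                trial_template: TrialConfig,
                master_seed) -> pd.DataFrame:
    """Integrate a flat list of trial specs in one lockstep batch.

    ``specs`` rows are ``(profile_index, condition, trial_index)``.  Noise
    streams derive from ``(master_seed, pid, condition index, trial index)``
    so cohorts are reproducible and matched across kappa settings.
    """
    cond_index = {c: i for i, c in enumerate(CONDITION_OFFSETS)}
    params_list, trial_list, seeds = [], [], []
    for prof_i, cond, trial_i in specs:
        prof = profiles[prof_i]
        params_list.append(prof.to_params(base_params))
        trial_list.append(replace(trial_template, offset=CONDITION_OFFSETS[cond]))
        seeds.append(np.random.SeedSequence(
            [int(master_seed), int(prof.pid), cond_index[cond], int(trial_i)]
        ))

    n = trial_template.n_steps
    B = len(specs)
    noise_p = np.zeros((B, n))
    noise_v = np.zeros((B, n))
    if trial_template.noise:
        for i, ss in enumerate(seeds):
            rng = np.random.default_rng(ss)
            if trial_template.noise_sd_proprio > 0:
                noise_p[i] = rng.normal(0.0, trial_template.noise_sd_proprio, n)
            if trial_template.noise_sd_visual > 0:
                noise_v[i] = rng.normal(0.0, trial_template.noise_sd_visual, n)

    arrays = batch_arrays(params_list, trial_list)
    force, _, _ = integrate_batch(arrays, noise_p, noise_v,
                                  trial_template.dt, n, record_traces=False)
    i0 = int(round(WINDOW[0] / trial_template.dt))
    i1 = int(round(WINDOW[1] / trial_template.dt))
    mean_force = force[:, i0:i1].mean(axis=1)

    rows = []
    for (prof_i, cond, trial_i), f in zip(specs, mean_force):
        prof = profiles[prof_i]
        rows.append(
            (prof.pid, prof.group, prof.kappa, trial_i // 4 + 1, trial_i + 1,
             cond, float(f))
        )
    return pd.DataFrame(
        rows,
        columns=["pid", "group", "kappa", "block", "trial", "condition",
                 "mean_force_N"],
    )


def simulate_cohort(n_sync: int = 10, n_async: int = 10,
                    trials_per_condition: int = 4, rng_seed=0,
                    base_params: Optional[ModelParams] = None,
                    trial: Optional[TrialConfig] = None) -> pd.DataFrame:
    """Simulate a two-group cohort and return the per-trial force table.

    Each participant runs ``trials_per_condition`` trials in each of the
    Left/Center/Right conditions; the table records the 10-15 s windowed
    mean lateral force per trial.
    """
    if n_sync < 0 or n_async < 0 or n_sync + n_async < 1:
        raise ValueError("need at least one participant")
    if trials_per_condition < 1:
        raise ValueError("trials_per_condition must be >= 1")
    base_params = base_params if base_params is not None else ModelParams()
    trial = trial if trial is not None else TrialConfig()

    ss = np.random.SeedSequence(rng_seed)
    part_seeds = ss.spawn(n_sync + n_async)
    profiles = []
    for i in range(n_sync + n_async):
        group = "synchronous" if i < n_sync else "asynchronous"
        profiles.append(sample_participant(group, part_seeds[i], pid=i + 1))

    specs = [
        (i, cond, t)
        for i in range(len(profiles))
        for cond in CONDITION_OFFSETS
        for t in range(trials_per_condition)
    ]
    return _run_trials(profiles, specs, base_params, trial, rng_seed)


def kappa_sweep(kappas: Sequence[float], n_per_kappa: int = 10,
                trials_per_condition: int = 4, rng_seed=0,
                base_params: Optional[ModelParams] = None,
                trial: Optional[TrialConfig] = None) -> pd.DataFrame:
    """Run matched cohorts at each causality value.

    Participants and observation-noise streams are identical across kappa
    settings (only kappa differs), so per-kappa forces are directly
    comparable pairwise.  Group is labelled synchronous for bookkeeping.
    """
    kappas = [float(k) for k in kappas]
    if any(not 0.0 <= k <= 1.0 for k in kappas):
        raise ValueError("every kappa must lie in [0, 1]")
    if n_per_kappa < 1:
        raise ValueError("n_per_kappa must be >= 1")
    base_params = base_params if base_params is not None else ModelParams()
    trial = trial if trial is not None else TrialConfig()

    ss = np.random.SeedSequence(rng_seed)
    part_seeds = ss.spawn(n_per_kappa)
    tables = []
    for kap in kappas:
        profiles = [
            sample_participant("synchronous", part_seeds[i], pid=i + 1, kappa=kap)
            for i in range(n_per_kappa)
        ]
        specs = [
            (i, cond, t)
            for i in range(n_per_kappa)
            for cond in CONDITION_OFFSETS
            for t in range(trials_per_condition)
        ]
        tables.append(_run_trials(profiles, specs, base_params, trial, rng_seed))
    return pd.concat(tables, ignore_index=True)


def summarize_sweep(table: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD force per (kappa, condition): one summary row each."""
    out = (
        table.groupby(["kappa", "condition"], as_index=False)["mean_force_N"]
        .agg(mean_force_N="mean", sd_force_N="std", n_trials="count")
    )
    return out.sort_values(["kappa", "condition"], ignore_index=True)
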