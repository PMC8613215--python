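"""Synthetic visuo-tactile event trains and the synchrony-to-kappa map.

A stimulation trial shows a ball bouncing on the virtual hand roughly every
two seconds (the visual event) while a coin vibrator delivers the tactile
event on the real hand.  Synchronous stimulation keeps the two within 100 ms;
asynchronous stimulation delays the vibration by up to 800 ms.  The degree of
synchrony determines the causal-binding parameter kappa: the probability the
agent assigns to the visual and tactile events sharing a common source.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MODES = ("synchronous", "asynchronous", "weak_asynchronous")

#: pairs closer than this are perceived as simultaneous (s).
SYNC_WINDOW = 0.1
#: maximum visuo-tactile delay of the asynchronous generator (s).
ASYNC_MAX = 0.8
#: mean |offset| of an ideal fully-random asynchronous train, U(0.1, 0.8).
IDEAL_ASYNC_MEAN = (SYNC_WINDOW + ASYNC_MAX) / 2.0

#: default fraction of near-synchronous pairs in the weak-asynchronous mode,
#: chosen so its expected mean offset maps to kappa ~= 0.3 — the causality
#: level attributed to the experimental asynchronous stimulation, where the
#: vibration fell randomly along the ball trajectory and participants could
#: still bind the two streams.
WEAK_ASYNC_SYNC_FRACTION = 0.26


@dataclass
class VTEventTrain:
    """Paired visual (ball-contact) and tactile (vibration) event times, s."""

    visual_times: np.ndarray
    tactile_times: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        self.visual_times = np.asarray(self.visual_times, dtype=float)
        self.tactile_times = np.asarray(self.tactile_times, dtype=float)
        if self.visual_times.shape != self.tactile_times.shape:
            raise ValueError("visual and tactile trains must pair one-to-one")
        if self.mode not in MODES:
            raise ValueError(f"unknown VT mode {self.mode!r}; expected one of {MODES}")
        for name, t in (("visual", self.visual_times), ("tactile", self.tactile_times)):
            if np.any(np.diff(t) < 0):
                raise ValueError(f"{name} event times must be sorted ascending")

    def __len__(self) -> int:
        return len(self.visual_times)

    @property
    def offsets(self) -> np.ndarray:
        """Per-pair |tactile - visual| delays, s."""
        return np.abs(self.tactile_times - self.visual_times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "event_index": np.arange(len(self)),
                "visual_time_s": self.visual_times,
                "tactile_time_s": self.tactile_times,
                "mode": self.mode,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "VTEventTrain":
        df = pd.read_csv(path)
        mode = str(df["mode"].iloc[0]) if len(df) else "synchronous"
        return cls(
            visual_times=df["visual_time_s"].to_numpy(),
            tactile_times=df["tactile_time_s"].to_numpy(),
            mode=mode,
        )


def generate_events(mode: str, duration: float = 40.0, mean_interval: float = 2.0,
                    rng_seed=None, sync_fraction: float = WEAK_ASYNC_SYNC_FRACTION,
                    ) -> VTEventTrain:
    """Generate one trial's visuo-tactile event train.

    Visual events are spaced by ``mean_interval`` with +/-10% uniform jitter
    (a touch event roughly every two seconds over a 40 s trial).  Tactile
    offsets are drawn per mode: synchronous U(0, 0.1) s, asynchronous
    U(0.1, 0.8) s, weak_asynchronous a mixture with probability
    ``sync_fraction`` of a near-synchronous offset.  Pairs whose tactile
    event would fall outside the trial are dropped, so a very short trial may
    legitimately contain no events.
    """
    if mode not in MODES:
        raise ValueError(f"unknown VT mode {mode!r}; expected one of {MODES}")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if mean_interval <= 0:
        raise ValueError("mean_interval must be positive")
    if not 0.0 <= sync_fraction <= 1.0:
        raise ValueError("sync_fraction must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)

    visual = []
    t = 0.0
    while True:
        t += mean_interval * rng.uniform(0.9, 1.1)
        if t >= duration:
            break
        visual.append(t)
    visual = np.asarray(visual)

    if mode == "synchronous":
        offs = rng.uniform(0.0, SYNC_WINDOW, size=visual.size)
    elif mode == "asynchronous":
        offs = rng.uniform(SYNC_WINDOW, ASYNC_MAX, size=visual.size)
    else:  # weak_asynchronous
        near = rng.random(visual.size) < sync_fraction
        offs = np.where(
            near,
            rng.uniform(0.0, SYNC_WINDOW, size=visual.size),
            rng.uniform(SYNC_WINDOW, ASYNC_MAX, size=visual.size),
        )
    tactile = visual + offs
    keep = tactile <= duration
    return VTEventTrain(visual_times=visual[keep], tactile_times=tactile[keep],
                        mode=mode)


def kappa_from_synchrony(train: VTEventTrain) -> float:
    """Map a VT train's mean delay to the causality parameter kappa in [0, 1].

    Two-anchor linear map on the mean |tactile - visual| offset: any mean
    delay within the simultaneity window (<= 0.1 s) saturates at kappa = 1
    (synchronous stimulation, visual input attributed to one's own body);
    the ideal fully-random asynchronous train (uniform delays, mean 0.45 s)
    maps to kappa = 0 (no causal link).  Intermediate trains — e.g. the
    weak-asynchronous generator emulating the experimental asynchronous
    stimulation — interpolate linearly, landing near kappa ~= 0.3 for the
    default mixture.
    """
    if len(train) == 0:
        raise ValueError("cannot infer kappa from an empty event train")
    mean_off = float(np.mean(train.offsets))
    if mean_off <= SYNC_WINDOW:
        return 1.0
    kappa = (IDEAL_ASYNC_MEAN - mean_off) / (IDEAL_ASYNC_MEAN - SYNC_WINDOW)
    return float(np.clip(kappa, 0.0, 1.0))
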