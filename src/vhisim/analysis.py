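"""Force preprocessing and the statistical pipeline.

The pipeline mirrors the human study: per-block force offset removal, the
10-15 s windowed mean per trial, a trial-level two-way ANOVA of the windowed
mean force with virtual-hand location (within) and visuo-tactile stimulation
mode (between) plus their interaction, and per-participant post-hoc t-tests
(Center against zero, two-tailed; Right > Center and Left < Center, paired
one-tailed).  It applies identically to simulated cohorts and to a human
per-trial force table loaded from CSV.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

CONDITIONS = ("Left", "Center", "Right")
FORCE_COL = "mean_force_N"

REQUIRED_COLUMNS = ("pid", "group", "block", "trial", "condition", FORCE_COL)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def remove_block_offset(traces: pd.DataFrame, force_col: str = "force_N",
                        block_col: str = "block") -> pd.DataFrame:
    """Subtract each block's grand-mean force from every sample in the block.

    Emulates the offset removal applied to the recorded 9-min blocks so that
    slow shifts in limb posture do not bias the force values; the corrected
    data has exactly zero mean within every block.
    """
    for col in (force_col, block_col):
        if col not in traces.columns:
            raise ValueError(f"missing column {col!r}")
    if len(traces) == 0:
        raise ValueError("empty force data: no blocks to correct")
    out = traces.copy()
    out[force_col] = out[force_col] - out.groupby(block_col)[force_col].transform("mean")
    return out


def window_mean(trace, t0: float = 10.0, t1: float = 15.0) -> float:
    """Mean lateral force over the half-open analysis window [t0, t1) s.

    ``trace`` may be a TrialResult, a (time, force) pair of arrays, or a
    DataFrame with ``time_s``/``force_N`` columns.
    """
    if hasattr(trace, "time") and hasattr(trace, "force"):
        time, force = np.asarray(trace.time), np.asarray(trace.force)
    elif isinstance(trace, pd.DataFrame):
        time, force = trace["time_s"].to_numpy(), trace["force_N"].to_numpy()
    else:
        time, force = (np.asarray(a) for a in trace)
    if t1 <= t0:
        raise ValueError(f"empty analysis window [{t0}, {t1})")
    if time.size == 0 or t0 < time[0] or t1 > time[-1] + (time[1] - time[0] if time.size > 1 else 0):
        raise ValueError(f"window [{t0}, {t1}) not covered by the trace")
    mask = (time >= t0) & (time < t1)
    if not mask.any():
        raise ValueError(f"no samples inside window [{t0}, {t1})")
    return float(force[mask].mean())


def load_force_table(path, column_map: Optional[dict] = None) -> pd.DataFrame:
    """Read a per-trial force table (e.g. exported human data) from CSV.

    Expected columns after renaming through ``column_map``:
    pid, group (synchronous/asynchronous), block, trial, condition
    (Left/Center/Right), mean_force_N.
    """
    df = pd.read_csv(path, comment="#")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"force table missing columns: {missing}")
    bad = set(df["condition"].unique()) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown condition labels: {sorted(bad)}")
    return df


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass
class EffectF:
    """One ANOVA effect: F statistic, numerator/denominator df, p-value."""

    F: float
    df1: float
    df2: float
    p: float


@dataclass
class TTest:
    t: float
    df: int
    p: float
    tails: str  # "two-sided", "greater", "less"


@dataclass
class StatsReport:
    """Full output of the force-statistics pipeline."""

    anova: dict                     # effect name -> EffectF
    center_onesample: TTest
    paired_right: TTest
    paired_left: TTest
    condition_means: dict
    condition_sds: dict
    n_participants: int
    n_trials: int

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def summary(self) -> str:
        lines = [
            "Lateral-force statistics",
            "=" * 60,
            f"trials: {self.n_trials}   participants: {self.n_participants}",
            "",
            "Condition means (N):",
        ]
        for c in CONDITIONS:
            lines.append(
                f"  {c:<7} {self.condition_means[c]: .4f} "
                f"(SD {self.condition_sds[c]:.4f})"
            )
        lines += ["", "Trial-level ANOVA (location x mode):"]
        for name, eff in self.anova.items():
            lines.append(
                f"  {name:<12} F({eff.df1:g}, {eff.df2:g}) = {eff.F:.2f}, "
                f"p = {eff.p:.3g}"
            )
        lines += ["", "Post-hoc t-tests (participant aggregates):"]
        for label, tt in (
            ("Center vs 0", self.center_onesample),
            ("Right > Center", self.paired_right),
            ("Left < Center", self.paired_left),
        ):
            lines.append(
                f"  {label:<15} t({tt.df}) = {tt.t:.2f}, p = {tt.p:.3g} "
                f"({tt.tails})"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in ("condition", "group", FORCE_COL) if c not in table.columns]
    if missing:
        raise ValueError(f"force table missing columns: {missing}")


def anova_location_mode(table: pd.DataFrame, level: str = "trial") -> dict:
    """Two-way ANOVA of the windowed mean force.

    ``level='trial'`` (default) fits a fixed-effects OLS on individual trials
    (location, mode, interaction); on the full 14-participant data this
    yields the residual df of 1674 = 1680 - 6 cell means.  ``level='participant'``
    runs a repeated-measures mixed ANOVA on per-participant condition means
    (location within, mode between) instead.

    Returns ``{"location": EffectF, "mode": EffectF, "interaction": EffectF}``.
    """
    _check_table(table)
    cells = table.groupby(["condition", "group"]).size()
    for cond in CONDITIONS:
        for grp in table["group"].unique():
            n = cells.get((cond, grp), 0)
            if n < 2:
                raise ValueError(
                    f"cell (condition={cond}, group={grp}) has {n} trials; "
                    "need at least 2 per cell"
                )

    if level == "trial":
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        model = smf.ols(f"{FORCE_COL} ~ C(condition) * C(group)", data=table).fit()
        tab = anova_lm(model, typ=2)
        df_resid = float(tab.loc["Residual", "df"])

        def eff(row):
            return EffectF(
                F=float(tab.loc[row, "F"]),
                df1=float(tab.loc[row, "df"]),
                df2=df_resid,
                p=float(tab.loc[row, "PR(>F)"]),
            )

        return {
            "location": eff("C(condition)"),
            "mode": eff("C(group)"),
            "interaction": eff("C(condition):C(group)"),
        }

    if level == "participant":
        import pingouin as pg

        agg = (
            table.groupby(["pid", "group", "condition"], as_index=False)[FORCE_COL]
            .mean()
        )
        res = pg.mixed_anova(
            data=agg, dv=FORCE_COL, within="condition", subject="pid",
            between="group"
        )
        res = res.set_index("Source")

        p_col = "p_unc" if "p_unc" in res.columns else "p-unc"

        def eff2(row):
            return EffectF(
                F=float(res.loc[row, "F"]),
                df1=float(res.loc[row, "DF1"]),
                df2=float(res.loc[row, "DF2"]),
                p=float(res.loc[row, p_col]),
            )

        return {
            "location": eff2("condition"),
            "mode": eff2("group"),
            "interaction": eff2("Interaction"),
        }

    raise ValueError(f"unknown level {level!r}; expected 'trial' or 'participant'")


def _one_sample_t(x: np.ndarray, tails: str = "two-sided") -> TTest:
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    sd = x.std(ddof=1)
    if sd == 0.0:
        # zero-variance limit: certainty, strict acceptance/rejection
        m = x.mean()
        if m == 0.0:
            return TTest(t=0.0, df=n - 1, p=1.0, tails=tails)
        t = math.inf if m > 0 else -math.inf
        if tails == "two-sided":
            p = 0.0
        elif tails == "greater":
            p = 0.0 if m > 0 else 1.0
        else:
            p = 0.0 if m < 0 else 1.0
        return TTest(t=t, df=n - 1, p=p, tails=tails)
    res = stats.ttest_1samp(x, 0.0, alternative=tails)
    return TTest(t=float(res.statistic), df=n - 1, p=float(res.pvalue), tails=tails)


def posthoc_tests(table: pd.DataFrame, center_tails: str = "two-sided") -> StatsReport:
    """Participant-aggregated post-hoc tests plus descriptives.

    Forces are first averaged across trial repetitions per (participant,
    condition).  Center is tested against zero (two-tailed by default);
    Right - Center with the one-tailed alternative 'greater', Left - Center
    with 'less', matching the directional hypothesis that forces point
    toward the virtual hand.
    """
    _check_table(table)
    if "pid" not in table.columns:
        raise ValueError("force table missing columns: ['pid']")
    agg = table.groupby(["pid", "condition"])[FORCE_COL].mean().unstack()
    missing = agg.isna().any(axis=1)
    if missing.any():
        raise ValueError(
            f"participants missing a condition: {list(agg.index[missing])}"
        )
    for c in CONDITIONS:
        if c not in agg.columns:
            raise ValueError(f"no trials in condition {c}")
    n = len(agg)
    if n < 2:
        raise ValueError("need at least 2 participants")

    center = _one_sample_t(agg["Center"].to_numpy(), tails=center_tails)
    right = _one_sample_t(
        (agg["Right"] - agg["Center"]).to_numpy(), tails="greater")
    left = _one_sample_t(
        (agg["Left"] - agg["Center"]).to_numpy(), tails="less")

    anova = anova_location_mode(table) if _has_two_groups(table) else {}
    cond_stats = table.groupby("condition")[FORCE_COL]
    return StatsReport(
        anova=anova,
        center_onesample=center,
        paired_right=right,
        paired_left=left,
        condition_means={c: float(cond_stats.mean()[c]) for c in CONDITIONS},
        condition_sds={c: float(cond_stats.std()[c]) for c in CONDITIONS},
        n_participants=n,
        n_trials=len(table),
    )


def _has_two_groups(table: pd.DataFrame) -> bool:
    return table["group"].nunique() == 2


# ---------------------------------------------------------------------------
# synthetic human-scale table (stand-in for the supplementary force data)
# ---------------------------------------------------------------------------

def synth_force_table(effects: Sequence[float] = (-0.039, 0.0, 0.036),
                      n_participants: int = 14,
                      participant_sd: float = 0.03,
                      trial_sd: float = 0.1,
                      rng_seed=0) -> pd.DataFrame:
    """Synthetic per-trial force table with the experiment's structure.

    ``effects`` are the (Left, Center, Right) mean force shifts in N;
    participants receive a random force intercept (SD ``participant_sd``)
    shared across conditions, trials add Gaussian noise (SD ``trial_sd``).
    The schedule (10 blocks x 12 trials, alternating group assignment)
    comes from :mod:`vhisim.design`, so n = 14 gives 1680 rows.  This is a
    synthetic stand-in for the per-trial human force table.
    """
    from .design import generate_schedule

    if len(effects) != 3:
        raise ValueError("effects must give (Left, Center, Right) shifts")
    if participant_sd < 0 or trial_sd < 0:
        raise ValueError("noise SDs must be >= 0")
    rng = np.random.default_rng(rng_seed)
    shift = dict(zip(CONDITIONS, effects))
    sched = generate_schedule(n_participants, rng)
    intercepts = rng.normal(0.0, participant_sd, size=n_participants)
    cond_shift = sched["condition"].map(shift).to_numpy()
    pid_idx = sched["participant"].to_numpy() - 1
    force = (
        cond_shift
        + intercepts[pid_idx]
        + rng.normal(0.0, trial_sd, size=len(sched))
    )
    out = sched.rename(columns={"participant": "pid", "position": "trial"})
    out[FORCE_COL] = force
    return out[["pid", "group", "block", "trial", "condition", FORCE_COL]]


# ---------------------------------------------------------------------------
# model-style facade
# ---------------------------------------------------------------------------

class ForceStats:
    """Statistical model of a per-trial force table.

    Thin estimator-style wrapper over the pipeline: construct from a table
    (simulated cohort or loaded human data), ``fit()`` to obtain a
    :class:`StatsReport`-carrying results object with a ``summary()``.
    """

    def __init__(self, table: pd.DataFrame, center_tails: str = "two-sided"):
        _check_table(table)
        self.table = table
        self.center_tails = center_tails

    @classmethod
    def from_csv(cls, path, column_map: Optional[dict] = None) -> "ForceStats":
        return cls(load_force_table(path, column_map))

    def fit(self) -> "ForceStatsResults":
        return ForceStatsResults(self, posthoc_tests(self.table, self.center_tails))


class ForceStatsResults:
    def __init__(self, model: ForceStats, report: StatsReport):
        self.model = model
        self.report = report

    def summary(self) -> str:
        return self.report.summary()

    def to_json(self, path=None) -> str:
        return self.report.to_json(path)
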