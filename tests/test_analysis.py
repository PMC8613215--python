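import math

import numpy as np
import pandas as pd
import pytest

import vhisim as v
from vhisim.analysis import FORCE_COL, _one_sample_t


class TestRemoveBlockOffset:
    def test_constant_block_becomes_zero(self):
        df = pd.DataFrame({"block": 1, "force_N": np.full(100, 0.5)})
        out = v.remove_block_offset(df)
        np.testing.assert_allclose(out["force_N"], 0.0, atol=1e-15)

    def test_corrected_blocks_have_zero_mean(self, rng):
        df = pd.DataFrame({
            "block": np.repeat([1, 2, 3], 200),
            "force_N": rng.normal(0.2, 0.5, 600),
        })
        out = v.remove_block_offset(df)
        means = out.groupby("block")["force_N"].mean()
        np.testing.assert_allclose(means, 0.0, atol=1e-12)

    def test_pure_offsets_leave_identical_signals(self, rng):
        signal = rng.normal(0, 0.3, 150)
        signal -= signal.mean()
        df = pd.DataFrame({
            "block": np.repeat([1, 2], 150),
            "force_N": np.concatenate([signal + 0.2, signal - 0.2]),
        })
        out = v.remove_block_offset(df)
        b1 = out[out.block == 1]["force_N"].to_numpy()
        b2 = out[out.block == 2]["force_N"].to_numpy()
        np.testing.assert_allclose(b1, b2, atol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            v.remove_block_offset(pd.DataFrame({"block": [], "force_N": []}))


class TestWindowMean:
    def test_constant_trace(self):
        t = np.arange(0, 40, 0.001)
        assert v.window_mean((t, np.full_like(t, 0.04))) == pytest.approx(0.04)

    def test_linear_ramp_closed_form(self):
        # 0 -> 0.4 N over 40 s: mean over [10, 15) is 0.125 N
        t = np.arange(0, 40, 0.001)
        force = 0.01 * t
        assert v.window_mean((t, force)) == pytest.approx(0.125, abs=1e-4)

    def test_empty_window_rejected(self):
        t = np.arange(0, 40, 0.001)
        with pytest.raises(ValueError):
            v.window_mean((t, t), t0=10.0, t1=10.0)

    def test_window_outside_trace_rejected(self):
        t = np.arange(0, 5, 0.001)
        with pytest.raises(ValueError):
            v.window_mean((t, t))


def _toy_table(cell_values):
    """Balanced 2 (group) x 3 (condition) table from a dict of per-cell lists."""
    rows = []
    pid = {"synchronous": 1, "asynchronous": 2}
    for (grp, cond), ys in cell_values.items():
        for i, y in enumerate(ys):
            rows.append((pid[grp], grp, 1, i + 1, cond, y))
    return pd.DataFrame(
        rows, columns=["pid", "group", "block", "trial", "condition", FORCE_COL])


def _hand_anova(table):
    """Independent oracle: explicit sum-of-squares decomposition of the
    balanced two-way fixed-effects ANOVA with interaction."""
    y = table[FORCE_COL].to_numpy()
    grand = y.mean()
    conds = sorted(table["condition"].unique())
    grps = sorted(table["group"].unique())
    n_cell = len(table) // (len(conds) * len(grps))
    ss_a = sum(
        (table[table.condition == c][FORCE_COL].mean() - grand) ** 2
        for c in conds) * n_cell * len(grps)
    ss_b = sum(
        (table[table.group == g][FORCE_COL].mean() - grand) ** 2
        for g in grps) * n_cell * len(conds)
    ss_cells = 0.0
    ss_res = 0.0
    for c in conds:
        for g in grps:
            cell = table[(table.condition == c) & (table.group == g)][FORCE_COL]
            ss_cells += n_cell * (cell.mean() - grand) ** 2
            ss_res += ((cell - cell.mean()) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    df_a, df_b = len(conds) - 1, len(grps) - 1
    df_ab = df_a * df_b
    df_res = len(y) - len(conds) * len(grps)
    ms_res = ss_res / df_res
    return {
        "location": (ss_a / df_a / ms_res, df_a, df_res),
        "mode": (ss_b / df_b / ms_res, df_b, df_res),
        "interaction": (ss_ab / df_ab / ms_res, df_ab, df_res),
    }


class TestAnova:
    def test_matches_hand_computed_table(self):
        cells = {
            ("synchronous", "Left"): [-0.05, -0.03],
            ("synchronous", "Center"): [0.01, -0.01],
            ("synchronous", "Right"): [0.04, 0.06],
            ("asynchronous", "Left"): [-0.02, -0.04],
            ("asynchronous", "Center"): [0.00, 0.02],
            ("asynchronous", "Right"): [0.03, 0.01],
        }
        table = _toy_table(cells)
        got = v.anova_location_mode(table)
        want = _hand_anova(table)
        for name in ("location", "mode", "interaction"):
            F, df1, df2 = want[name]
            assert got[name].F == pytest.approx(F, abs=1e-10)
            assert got[name].df1 == df1
            assert got[name].df2 == df2

    def test_group_effect_reduces_to_two_sample_t(self, rng):
        """With condition effects exactly zero (each trial value replicated
        across the three conditions), the mode F equals 3 t^2 for the
        two-sample t on the unique per-replicate values — the classical
        F = t^2 identity under 3-fold replication."""
        from scipy import stats

        a = rng.normal(0.0, 1.0, 6)
        b = rng.normal(0.5, 1.0, 6)
        cells = {}
        for cond in ("Left", "Center", "Right"):
            cells[("synchronous", cond)] = list(a)
            cells[("asynchronous", cond)] = list(b)
        got = v.anova_location_mode(_toy_table(cells))
        t = stats.ttest_ind(a, b).statistic
        assert got["mode"].F == pytest.approx(3 * t**2, rel=1e-10)
        assert got["location"].F == pytest.approx(0.0, abs=1e-10)

    def test_trial_level_dfs_on_full_design(self):
        table = v.synth_force_table(n_participants=14, rng_seed=0)
        got = v.anova_location_mode(table)
        assert (got["location"].df1, got["location"].df2) == (2, 1674)
        assert (got["mode"].df1, got["interaction"].df1) == (1, 2)

    def test_participant_level_variant_runs(self):
        table = v.synth_force_table(n_participants=8, rng_seed=1)
        got = v.anova_location_mode(table, level="participant")
        assert got["location"].df1 == 2
        assert got["location"].df2 == 12  # (3-1) * (8-2)

    def test_missing_cell_error_names_the_cell(self):
        table = v.synth_force_table(n_participants=4, rng_seed=0)
        table = table[~((table.condition == "Right") &
                        (table.group == "asynchronous"))]
        with pytest.raises(ValueError, match="Right.*asynchronous"):
            v.anova_location_mode(table)

    def test_constant_shift_invariance(self):
        table = v.synth_force_table(n_participants=6, rng_seed=2)
        shifted = table.copy()
        shifted[FORCE_COL] = shifted[FORCE_COL] + 0.7
        a = v.anova_location_mode(table)
        b = v.anova_location_mode(shifted)
        for name in a:
            assert a[name].F == pytest.approx(b[name].F, rel=1e-9)


class TestPosthoc:
    def test_center_all_zero_gives_null_t(self):
        cells = {(g, c): [0.0, 0.0] for g in ("synchronous", "asynchronous")
                 for c in ("Left", "Center", "Right")}
        rep = v.posthoc_tests(_toy_table(cells))
        assert rep.center_onesample.t == 0.0
        assert rep.center_onesample.p == 1.0

    def test_constant_positive_differences_reject_strictly(self):
        rows = []
        for pid in range(1, 4):
            rows += [(pid, "synchronous", 1, 1, "Center", 0.0),
                     (pid, "synchronous", 1, 1, "Right", 0.05),
                     (pid, "synchronous", 1, 1, "Left", -0.05)]
        table = pd.DataFrame(
            rows, columns=["pid", "group", "block", "trial", "condition",
                           FORCE_COL])
        rep = v.posthoc_tests(table)
        assert rep.paired_right.p < 1e-6
        assert rep.paired_left.p < 1e-6

    def test_three_participant_hand_computed_t(self):
        center = np.array([0.01, -0.02, 0.03])
        right = np.array([0.05, 0.03, 0.08])
        rows = []
        for i in range(3):
            rows += [(i + 1, "synchronous", 1, 1, "Center", center[i]),
                     (i + 1, "synchronous", 1, 1, "Right", right[i]),
                     (i + 1, "synchronous", 1, 1, "Left", -right[i])]
        table = pd.DataFrame(
            rows, columns=["pid", "group", "block", "trial", "condition",
                           FORCE_COL])
        rep = v.posthoc_tests(table)

        def t_of(x):
            return x.mean() / (x.std(ddof=1) / math.sqrt(len(x)))

        assert rep.center_onesample.t == pytest.approx(t_of(center), abs=1e-12)
        assert rep.paired_right.t == pytest.approx(t_of(right - center), abs=1e-12)
        assert rep.paired_left.t == pytest.approx(t_of(-right - center), abs=1e-12)
        assert rep.paired_right.tails == "greater"
        assert rep.paired_left.tails == "less"

    def test_missing_condition_for_participant_rejected(self):
        table = v.synth_force_table(n_participants=4, rng_seed=0)
        table = table[~((table.pid == 2) & (table.condition == "Left"))]
        with pytest.raises(ValueError, match="missing a condition"):
            v.posthoc_tests(table)

    def test_report_serialises(self, tmp_path):
        table = v.synth_force_table(n_participants=4, rng_seed=3)
        rep = v.posthoc_tests(table)
        text = rep.to_json(tmp_path / "stats.json")
        assert (tmp_path / "stats.json").exists()
        assert '"anova"' in text
        assert "ANOVA" in rep.summary()


class TestSynthForceTable:
    def test_row_count_matches_design(self):
        table = v.synth_force_table(n_participants=14, rng_seed=0)
        assert len(table) == 1680
        assert table.groupby("pid").size().eq(120).all()

    def test_zero_effects_zero_noise_is_exactly_null(self):
        table = v.synth_force_table(effects=(0.0, 0.0, 0.0), n_participants=4,
                                    participant_sd=0.0, trial_sd=0.0, rng_seed=0)
        assert (table[FORCE_COL] == 0.0).all()
        rep = v.posthoc_tests(table)
        assert rep.center_onesample.t == 0.0
        assert rep.paired_right.t == 0.0
        assert rep.paired_left.t == 0.0

    def test_effects_recovered_with_small_noise(self):
        effects = (-0.039, 0.0, 0.036)
        table = v.synth_force_table(effects=effects, n_participants=14,
                                    participant_sd=0.01, trial_sd=0.02,
                                    rng_seed=4)
        agg = table.groupby(["pid", "condition"])[FORCE_COL].mean().unstack()
        for cond, true in zip(("Left", "Center", "Right"), effects):
            assert abs(agg[cond].mean() - true) <= 2 * agg[cond].sem()


class TestLoadForceTable:
    def test_round_trip_and_column_map(self, tmp_path):
        table = v.synth_force_table(n_participants=2, rng_seed=0)
        path = tmp_path / "forces.csv"
        table.rename(columns={"pid": "subject"}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="pid"):
            v.load_force_table(path)
        back = v.load_force_table(path, column_map={"subject": "pid"})
        pd.testing.assert_frame_equal(back, table)

    def test_bad_condition_labels_rejected(self, tmp_path):
        table = v.synth_force_table(n_participants=2, rng_seed=0)
        table.loc[0, "condition"] = "Middle"
        path = tmp_path / "forces.csv"
        table.to_csv(path, index=False)
        with pytest.raises(ValueError, match="Middle"):
            v.load_force_table(path)


class TestForceStatsFacade:
    def test_fit_returns_summary_results(self):
        table = v.synth_force_table(n_participants=6, rng_seed=5)
        res = v.ForceStats(table).fit()
        assert res.report.n_trials == len(table)
        assert "Post-hoc" in res.summary()


class TestZeroVarianceT:
    def test_directional_conventions(self):
        up = _one_sample_t(np.full(4, 0.2), tails="greater")
        assert up.p == 0.0 and up.t == math.inf
        down = _one_sample_t(np.full(4, 0.2), tails="less")
        assert down.p == 1.0
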