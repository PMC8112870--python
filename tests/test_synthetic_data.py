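"""Design grids, trial simulators, renewal intervals, bottleneck timeline."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats


from multidec.ddm_core import SolverConfig, first_passage_solve
from multidec.synthetic_data import (
    DesignError,
    DesignGrid,
    MultiSwitchSpec,
    TimelineSpec,
    bottleneck_timeline,
    draw_switch_intervals,
    generate_design,
    simulate_trials,
)


class TestDesign:
    @pytest.mark.parametrize(
        "levels,n_signed",
        [
            ((0, 0.032, 0.064, 0.128, 0.256, 0.512), 11),
            ((0, 0.032, 0.064, 0.128, 0.256), 9),
            ((0.256,), 2),
        ],
    )
    def test_signed_expansion(self, levels, n_signed):
        grid = DesignGrid(motion_levels=levels, color_levels=levels)
        assert len(grid.signed_motion) == n_signed

    def test_full_factorial_counts(self):
        six = (0, 0.032, 0.064, 0.128, 0.256, 0.512)
        five = (0, 0.032, 0.064, 0.128, 0.256)
        assert len(generate_design(DesignGrid(six, six))) == 121
        assert len(generate_design(DesignGrid(five, five))) == 81
        assert len(generate_design(DesignGrid((0.3,), (0.4,)))) == 4

    def test_empty_levels_rejected(self):
        with pytest.raises(DesignError):
            DesignGrid(motion_levels=(), color_levels=(0.1,))

    def test_deterministic_order_and_seeded_shuffle(self):
        grid = DesignGrid((0, 0.1, 0.3), (0, 0.2))
        a = generate_design(grid)
        b = generate_design(grid)
        pd.testing.assert_frame_equal(a, b)
        s1 = generate_design(grid, seed=5, shuffle=True)
        s2 = generate_design(grid, seed=5, shuffle=True)
        pd.testing.assert_frame_equal(s1, s2)
        assert not s1.equals(a)


class TestSwitchIntervals:
    def test_positive_and_mean(self):
        x = draw_switch_intervals(0.5, 200_000, seed=1)
        assert np.all(x > 0)
        assert x.mean() == pytest.approx(1.5 * 0.5, rel=0.01)

    def test_matches_order_statistic_density(self):
        """Empirical CDF matches F(t) = (1 - exp(-t/tau))^2."""
        tau = 0.7
        x = draw_switch_intervals(tau, 100_000, seed=2)
        ks = stats.kstest(x, lambda t: (1 - np.exp(-t / tau)) ** 2)
        assert ks.statistic < 0.01

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            draw_switch_intervals(0.0, 10)


class TestSimulateTrials:
    def test_seed_reproducibility(self, serial_gen_params, small_design):
        a = simulate_trials("serial", serial_gen_params, small_design, n=20, seed=9)
        b = simulate_trials("serial", serial_gen_params, small_design, n=20, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_strong_coherence_high_accuracy(self, serial_gen_params):
        grid = DesignGrid((0.512,), (0.758,))
        tt = simulate_trials("serial", serial_gen_params, grid, n=200, seed=3)
        strong = tt[(tt.s_m == 0.512) & (tt.s_c == 0.758)]
        assert (strong.R_m == 1).mean() > 0.97
        assert (strong.R_c == 1).mean() > 0.97

    def test_rt_exceeds_nondecision_floor(self, serial_gen_params, small_design):
        tt = simulate_trials("serial", serial_gen_params, small_design, n=30, seed=4)
        assert (tt.rt > 0).all()

    def test_choice_frequencies_match_solver(self, serial_gen_params):
        """Simulator choice frequencies agree with the Fokker-Planck
        probabilities within binomial error at n = 10^4."""
        grid = DesignGrid((0.128,), (0.25,))
        tt = simulate_trials(
            "serial", serial_gen_params, grid, n=2500, seed=11, sim_dt=1e-4
        )
        cfg = SolverConfig(dt=1e-3, t_max=5.0, n_grid=256)
        for sm in (-0.128, 0.128):
            fp = first_passage_solve(serial_gen_params["motion"], sm, cfg)
            emp = (tt[tt.s_m == sm].R_m == 1).mean()
            se = np.sqrt(0.25 / 2500)
            assert fp.prob_upper() == pytest.approx(emp, abs=3.5 * se)

    def test_parallel_rt_not_exceeding_serial_mean(self, serial_gen_params, small_design):
        ts = simulate_trials("serial", serial_gen_params, small_design, n=150, seed=5)
        tp = simulate_trials("parallel", serial_gen_params, small_design, n=150, seed=5)
        assert tp.rt.mean() < ts.rt.mean()

    def test_multiswitch_emits_ordered_bimanual_columns(self, serial_gen_params, small_design):
        params = dict(serial_gen_params)
        params["switch"] = MultiSwitchSpec(0.5, 0.8, 0.3)
        tt = simulate_trials("multiswitch", params, small_design, n=50, seed=6)
        assert {"rt_first", "rt_second", "first_dim"} <= set(tt.columns)
        assert (tt.rt_first <= tt.rt_second).all()
        assert set(tt.first_dim.unique()) <= {"motion", "color"}

    def test_multiswitch_large_tau_is_single_switch(self, serial_gen_params):
        """With tau_delta far above any decision time, the first response
        no longer depends on the other dimension's coherence."""
        grid = DesignGrid((0.512,), (0.064, 0.472))
        params = dict(serial_gen_params)
        params["switch"] = MultiSwitchSpec(1e4, 1.0, 0.3)
        tt = simulate_trials("multiswitch", params, grid, n=400, seed=7)
        first_m = tt[tt.first_dim == "motion"]
        means = first_m.groupby(first_m.s_c.abs())["rt_first"].mean()
        assert abs(means.iloc[0] - means.iloc[1]) < 0.02

    def test_unknown_architecture_rejected(self, serial_gen_params, small_design):
        with pytest.raises(ValueError):
            simulate_trials("quantum", serial_gen_params, small_design, n=5, seed=0)


class TestBottleneckTimeline:
    def test_first_updates_at_180_and_270_ms(self):
        """With 90 ms sampling and a 90 ms instruction delay, the motion
        decision variable is first updated 180 ms after stimulus onset
        and the color variable at 270 ms."""
        events = bottleneck_timeline(TimelineSpec(), t_dur=0.12)
        updates = [(t, d) for t, k, d in events if k == "update_received"]
        first_m = min(t for t, d in updates if d == "motion")
        first_c = min(t for t, d in updates if d == "color")
        assert first_m == pytest.approx(0.180)
        assert first_c == pytest.approx(0.270)

    def test_zero_instruction_delay_removes_deferral(self):
        events = bottleneck_timeline(TimelineSpec(tau_ins=0.0), t_dur=0.36)
        for dim in ("motion", "color"):
            ts = [t for t, k, d in events if k == "update_received" and d == dim]
            assert np.allclose(ts, np.arange(1, len(ts) + 1) * 0.09)

    def test_alternation_doubles_update_interval(self):
        """During alternation each dimension is updated at twice its solo
        interval."""
        both = bottleneck_timeline(TimelineSpec(), t_dur=1.0)
        solo = bottleneck_timeline(TimelineSpec(dims=("motion",)), t_dur=1.0)
        m_both = sorted(t for t, k, d in both if k == "update_received" and d == "motion")
        m_solo = sorted(t for t, k, d in solo if k == "update_received")
        assert np.diff(m_both)[1] == pytest.approx(2 * np.diff(m_solo)[1])

    def test_event_times_non_decreasing(self):
        events = bottleneck_timeline(TimelineSpec(), t_dur=0.6)
        ts = [t for t, _, _ in events]
        assert all(b >= a - 1e-12 for a, b in zip(ts, ts[1:]))

    def test_single_instruction_in_flight(self):
        """No instruction is sent while another is in flight."""
        events = bottleneck_timeline(TimelineSpec(), t_dur=1.0)
        sends = sorted(t for t, k, _ in events if k == "instruction_sent")
        assert np.all(np.diff(sends) >= 0.09 - 1e-12)
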