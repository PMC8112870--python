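"""Buffer-limited serial model for fixed-duration stimuli."""

import numpy as np
import pandas as pd
import pytest

from multidec.ddm_core import BoundSpec, DDMParams, SolverConfig
from multidec.duration_buffer import (
    BufferModelSpec,
    allocate_processing_time,
    choice_prob_table,
    default_buffer_grid,
    variable_duration_negloglik,
)
from multidec.synthetic_data import DesignGrid, simulate_trials


def _clipped(kappa, u=0.8, g=0.3, d=0.5, label="motion"):
    return DDMParams(kappa, 0.0, BoundSpec(form="clipped_exp", u=u, g=g, d=d), label)


@pytest.fixture(scope="module")
def buffer_spec():
    return BufferModelSpec(
        t_buf=0.08, p_m_first=0.85,
        motion=_clipped(14.0, u=0.7, g=0.25, d=0.4),
        color=_clipped(12.0, u=0.7, g=0.25, d=0.4, label="color"),
    )


@pytest.fixture(scope="module")
def dur_design():
    return DesignGrid(
        motion_levels=(0.06, 0.512), color_levels=(0.1, 0.758),
        durations=(0.12, 0.48, 1.2),
    )


class TestAllocateProcessingTime:
    @pytest.mark.parametrize(
        "t_buf,t_dur,t_m,expected",
        [
            (0.08, 0.5, 0.3, 0.28),   # termination in the serial phase
            (0.08, 0.06, None, 0.06),  # stimulus shorter than the buffer
            (0.08, 0.06, 0.05, 0.06),
            (0.08, 1.2, None, 0.08),   # no termination: buffer only
            (0.08, 0.5, 0.05, 0.5),    # termination in the parallel phase
        ],
    )
    def test_branches(self, t_buf, t_dur, t_m, expected):
        assert allocate_processing_time(t_buf, t_dur, t_m) == pytest.approx(expected)

    def test_absorption_after_stimulus_end_rejected(self):
        with pytest.raises(ValueError):
            allocate_processing_time(0.08, 0.5, 0.6)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            allocate_processing_time(-0.1, 0.5)


class TestChoiceProbabilities:
    def test_joint_probabilities_normalized(self, buffer_spec, dur_design):
        from multidec.synthetic_data import generate_design

        conds = generate_design(dur_design)
        table = choice_prob_table(buffer_spec, conds)
        total = table[["p_pp", "p_pn", "p_np", "p_nn"]].sum(axis=1)
        assert np.allclose(total, 1.0, atol=1e-9)

    def test_simulated_choices_match_solved_probabilities(self, buffer_spec, dur_design):
        trials = simulate_trials(
            "buffer", {"buffer": buffer_spec}, dur_design, n=1500, seed=7, sim_dt=2e-4
        )
        table = choice_prob_table(buffer_spec, trials).set_index(["s_m", "s_c", "t_dur"])
        emp = trials.groupby(["s_m", "s_c", "t_dur"]).agg(
            c_pos=("R_c", lambda r: (r == 1).mean()),
            m_pos=("R_m", lambda r: (r == 1).mean()),
            n=("R_c", "size"),
        )
        for key, row in emp.iterrows():
            se = np.sqrt(0.25 / row["n"])
            assert table.loc[key, "p_c_pos"] == pytest.approx(row["c_pos"], abs=4 * se + 5e-3)
            assert table.loc[key, "p_m_pos"] == pytest.approx(row["m_pos"], abs=4 * se + 5e-3)

    def test_large_buffer_is_parallel_limit(self, buffer_spec, dur_design):
        """t_buf at or above every duration: choices are the independent
        fixed-duration probabilities, regardless of prioritization."""
        from multidec.synthetic_data import generate_design

        conds = generate_design(dur_design)
        full = BufferModelSpec(
            t_buf=1.2, p_m_first=0.85, motion=buffer_spec.motion, color=buffer_spec.color
        )
        flipped = BufferModelSpec(
            t_buf=1.2, p_m_first=0.15, motion=buffer_spec.motion, color=buffer_spec.color
        )
        a = choice_prob_table(full, conds)
        b = choice_prob_table(flipped, conds)
        assert np.allclose(a["p_c_pos"], b["p_c_pos"], atol=1e-6)
        assert np.allclose(a["p_m_pos"], b["p_m_pos"], atol=1e-6)

    def test_zero_buffer_is_single_switch_serial(self, buffer_spec, dur_design):
        """t_buf = 0 with motion always first: at short durations the
        color dimension is squeezed whenever motion does not terminate."""
        from multidec.synthetic_data import generate_design

        conds = generate_design(dur_design)
        serial = BufferModelSpec(
            t_buf=0.0, p_m_first=1.0, motion=_clipped(6.0), color=buffer_spec.color
        )
        parallel = BufferModelSpec(
            t_buf=1.2, p_m_first=1.0, motion=_clipped(6.0), color=buffer_spec.color
        )
        a = choice_prob_table(serial, conds).set_index(["s_m", "s_c", "t_dur"])
        b = choice_prob_table(parallel, conds).set_index(["s_m", "s_c", "t_dur"])
        # hard motion, short duration: serial color accuracy is at chance
        key = (0.06, 0.758, 0.12)
        assert a.loc[key, "p_c_pos"] < b.loc[key, "p_c_pos"] - 0.2

    def test_negloglik_requires_durations(self, buffer_spec, serial_gen_params, small_design):
        trials = simulate_trials("serial", serial_gen_params, small_design, n=20, seed=1)
        with pytest.raises(ValueError):
            variable_duration_negloglik(trials, buffer_spec)

    def test_duration_beyond_horizon_rejected(self, buffer_spec):
        trials = pd.DataFrame(
            {"s_m": [0.1], "s_c": [0.1], "R_m": [1], "R_c": [1], "t_dur": [2.0]}
        )
        with pytest.raises(ValueError):
            variable_duration_negloglik(trials, buffer_spec)


class TestModelSignatures:
    def test_default_grid_matches_protocol(self):
        grid = default_buffer_grid()
        expected = np.array(
            [0, 40, 80, 120, 160, 200, 240, 360, 480, 600, 720, 840, 960, 1080, 1200]
        ) / 1000.0
        assert np.allclose(grid, expected)

    def test_interference_at_intermediate_durations_only(self):
        """With an 80 ms buffer and motion prioritized, color accuracy at
        intermediate durations is lower when motion is hard than when
        motion is easy; at the shortest duration the difference is
        negligible."""
        spec = BufferModelSpec(
            t_buf=0.08, p_m_first=1.0,
            motion=_clipped(8.0), color=_clipped(14.0, label="color"),
        )
        conds = pd.DataFrame(
            [
                (sm, 0.15, td)
                for sm in (0.04, 0.512)
                for td in (0.12, 0.48)
            ],
            columns=["s_m", "s_c", "t_dur"],
        )
        table = choice_prob_table(spec, conds).set_index(["s_m", "t_dur"])
        gap_short = (
            table.loc[(0.512, 0.12), "p_c_pos"] - table.loc[(0.04, 0.12), "p_c_pos"]
        )
        gap_mid = (
            table.loc[(0.512, 0.48), "p_c_pos"] - table.loc[(0.04, 0.48), "p_c_pos"]
        )
        assert gap_mid > 0.04
        assert abs(gap_short) < gap_mid / 3

    def test_sensitivity_grows_as_sqrt_time_before_termination(self):
        """Fixed-duration sensitivity of an unterminated accumulator
        improves as sqrt(t): d'(4t) = 2 d'(t)."""
        from scipy.stats import norm

        from multidec.ddm_core import first_passage_solve

        p = DDMParams(12.0, 0.0, BoundSpec.flat(5.0), "color")
        cfg = SolverConfig(dt=2e-3, t_max=1.0, n_grid=512)
        from multidec.duration_buffer import _fixed_dur_pos_prob

        fp = first_passage_solve(p, 0.1, cfg)
        probs = _fixed_dur_pos_prob(fp)
        dt = cfg.dt
        d1 = norm.ppf(probs[int(0.2 / dt)])
        d2 = norm.ppf(probs[int(0.8 / dt)])
        assert d2 / d1 == pytest.approx(2.0, rel=0.05)
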