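"""Serial/parallel composition of decision-time densities."""

import numpy as np
import pytest

from multidec.combine import (
    GridError,
    NonDecisionSpec,
    RTDensity,
    apply_nondecision,
    parallel_rt_density,
    parallel_rt_density_cdf,
    rt_summary,
    serial_rt_density,
)
from multidec.ddm_core import FirstPassage


def _delta_fp(t_up, times, mass_up=1.0):
    """A first-passage object with a point mass at t_up on the upper bound."""
    dt = times[1] - times[0]
    f_up = np.zeros_like(times)
    f_up[int(round(t_up / dt))] = mass_up / dt
    grid = np.linspace(-1, 1, 64)
    surv = np.zeros((len(times), len(grid)))
    return FirstPassage(times=times, f_upper=f_up, f_lower=np.zeros_like(times),
                        grid=grid, survivor=surv)


@pytest.fixture(scope="module")
def times():
    return np.arange(0, 4.0 + 1e-12, 2e-3)


class TestDeltaIdentities:
    def test_serial_deltas_sum(self, times):
        dt = times[1] - times[0]
        rt = serial_rt_density(_delta_fp(0.3, times), _delta_fp(0.5, times))
        d = rt.pair_density(1, 1)
        assert times[np.argmax(d)] == pytest.approx(0.8, abs=2 * dt)
        assert rt.pair_mass(1, 1) == pytest.approx(1.0, abs=1e-9)

    def test_parallel_deltas_max(self, times):
        dt = times[1] - times[0]
        rt = parallel_rt_density(_delta_fp(0.3, times), _delta_fp(0.5, times))
        d = rt.pair_density(1, 1)
        assert times[np.argmax(d)] == pytest.approx(0.5, abs=2 * dt)
        assert rt.pair_mass(1, 1) == pytest.approx(1.0, abs=1e-9)

    def test_mismatched_grids_rejected(self, fp_pair):
        fp_m, _ = fp_pair
        other = np.arange(0, 2.0 + 1e-12, 1e-3)
        with pytest.raises(GridError):
            serial_rt_density(fp_m, _delta_fp(0.3, other))


class TestSerialComposition:
    def test_mean_additivity(self, fp_pair):
        fp_m, fp_c = fp_pair
        rt = serial_rt_density(fp_m, fp_c)
        d = rt.pair_density(1, 1)
        mean = np.sum(rt.times * d) / np.sum(d)
        mean_m = fp_m.mean_time("upper")
        mean_c = fp_c.mean_time("upper")
        assert mean == pytest.approx(mean_m + mean_c, rel=5e-3)

    def test_matches_monte_carlo(self, fp_pair):
        """Serial density matches the histogram of summed simulated times."""
        rng = np.random.default_rng(7)
        fp_m, fp_c = fp_pair
        dt = fp_m.dt
        n = 100_000
        tm = rng.choice(fp_m.times, size=n, p=fp_m.f_upper / fp_m.f_upper.sum())
        tc = rng.choice(fp_c.times, size=n, p=fp_c.f_upper / fp_c.f_upper.sum())
        hist, edges = np.histogram(
            tm + tc, bins=np.arange(0, fp_m.times[-1] + dt, 0.05), density=True
        )
        rt = serial_rt_density(fp_m, fp_c)
        d = rt.pair_density(1, 1)
        d = d / (np.sum(d) * dt)
        centers = 0.5 * (edges[:-1] + edges[1:])
        model = np.interp(centers, rt.times, d)
        l1 = np.sum(np.abs(model - hist)) * 0.05
        assert l1 < 0.02


class TestParallelComposition:
    def test_sum_form_equals_cdf_derivative_form(self, fp_pair):
        fp_m, fp_c = fp_pair
        a = parallel_rt_density(fp_m, fp_c)
        b = parallel_rt_density_cdf(fp_m, fp_c)
        l1 = np.sum(np.abs(a.dens - b.dens)) * a.dt
        assert l1 < 1e-6

    def test_iid_exponential_max_mean(self, times):
        """E[max of two iid exponentials with mean tau] = 1.5 tau."""
        tau = 0.4
        dt = times[1] - times[0]
        f = np.exp(-times / tau) / tau
        f /= np.sum(f) * dt
        grid = np.linspace(-1, 1, 64)
        surv = np.zeros((len(times), len(grid)))
        zero = np.zeros_like(times)
        fp1 = FirstPassage(times, f, zero, grid, surv)
        fp2 = FirstPassage(times, f.copy(), zero, grid, surv)
        rt = parallel_rt_density(fp1, fp2)
        d = rt.pair_density(1, 1)
        mean = np.sum(times * d) / np.sum(d)
        assert mean == pytest.approx(1.5 * tau, rel=0.02)

    def test_serial_mean_exceeds_parallel_mean(self, fp_pair):
        fp_m, fp_c = fp_pair
        rs = serial_rt_density(fp_m, fp_c)
        rp = parallel_rt_density(fp_m, fp_c)
        ds, dp = rs.pair_density(1, 1), rp.pair_density(1, 1)
        mean_s = np.sum(rs.times * ds) / np.sum(ds)
        mean_p = np.sum(rp.times * dp) / np.sum(dp)
        assert mean_s > mean_p

    def test_marginal_choice_probabilities_rule_invariant(self, fp_pair):
        """Composition rule does not alter the marginal choice functions
        (no accuracy interference under either rule)."""
        fp_m, fp_c = fp_pair
        rs = serial_rt_density(fp_m, fp_c)
        rp = parallel_rt_density(fp_m, fp_c)
        for r in (1, -1):
            assert rs.marginal_motion(r) == pytest.approx(rp.marginal_motion(r), abs=1e-6)
            assert rs.marginal_color(r) == pytest.approx(rp.marginal_color(r), abs=1e-6)


class TestTailMass:
    def test_tail_mass_small_at_default_horizon(self, serial_gen_params):
        """Composed densities leave < 1e-4 mass beyond the 5 s horizon
        for representative parameters."""
        from multidec.ddm_core import SolverConfig, first_passage_solve

        cfg = SolverConfig(dt=2e-3, t_max=5.0, n_grid=128)
        fp_m = first_passage_solve(serial_gen_params["motion"], 0.128, cfg)
        fp_c = first_passage_solve(serial_gen_params["color"], 0.25, cfg)
        rt = serial_rt_density(fp_m, fp_c)
        assert rt.tail_mass_deficit() < 1e-4


class TestNonDecision:
    def test_zero_sigma_is_pure_shift(self, times):
        rt = serial_rt_density(_delta_fp(0.3, times), _delta_fp(0.5, times))
        shifted = apply_nondecision(rt, NonDecisionSpec(0.25, 0.0))
        d = shifted.pair_density(1, 1)
        assert times[np.argmax(d)] == pytest.approx(1.05, abs=2 * rt.dt)

    def test_mass_preserved_per_pair(self, fp_pair):
        fp_m, fp_c = fp_pair
        rt = serial_rt_density(fp_m, fp_c)
        out = apply_nondecision(rt, NonDecisionSpec(0.3, 0.05))
        for rm in (1, -1):
            for rc in (1, -1):
                assert out.pair_mass(rm, rc) == pytest.approx(
                    rt.pair_mass(rm, rc), abs=2e-3
                )

    def test_mean_and_variance_shift(self, times):
        rt = serial_rt_density(_delta_fp(0.4, times), _delta_fp(0.6, times))
        nd = NonDecisionSpec(0.3, 0.04)
        out = apply_nondecision(rt, nd)
        d = out.pair_density(1, 1)
        mass = np.sum(d) * out.dt
        mean = np.sum(out.times * d) * out.dt / mass
        var = np.sum((out.times - mean) ** 2 * d) * out.dt / mass
        assert mean == pytest.approx(1.0 + 0.3, abs=5e-3)
        assert var == pytest.approx(0.04**2, rel=0.1)


class TestRTSummary:
    def test_symmetric_driftless_pairs(self, serial_gen_params, coarse_cfg):
        from multidec.ddm_core import first_passage_solve

        fp_m = first_passage_solve(serial_gen_params["motion"], 0.0, coarse_cfg)
        fp_c = first_passage_solve(serial_gen_params["color"], 0.0, coarse_cfg)
        rt = serial_rt_density(fp_m, fp_c)
        summary = rt_summary(rt)
        for mass, _mean in summary.values():
            assert mass == pytest.approx(0.25, abs=5e-3)

    def test_correct_only_selects_matching_signs(self, fp_pair):
        fp_m, fp_c = fp_pair
        rt = serial_rt_density(fp_m, fp_c)
        summary = rt_summary(rt, s_m=0.128, s_c=0.25, correct_only=True)
        assert set(summary) == {(1, 1)}

    def test_shifted_delta_mean(self, times):
        rt = serial_rt_density(_delta_fp(0.3, times), _delta_fp(0.5, times))
        out = apply_nondecision(rt, NonDecisionSpec(0.2, 0.0))
        mass, mean = rt_summary(out)[(1, 1)]
        assert mean == pytest.approx(1.0, abs=2 * out.dt)


class TestSerialShiftInvariance:
    def test_stacked_vs_pinched_families(self, serial_gen_params, coarse_cfg):
        """Under the serial rule, hardening the color decision shifts the
        motion-conditioned mean RT by the same amount at every motion
        strength (stacked curves); under the parallel rule, the shift
        shrinks as motion gets harder (pinched curves)."""
        from multidec.ddm_core import first_passage_solve

        pm = serial_gen_params["motion"]
        pc = serial_gen_params["color"]
        s_motion = (0.064, 0.512)
        fp_c_easy = first_passage_solve(pc, 0.472, coarse_cfg)
        fp_c_hard = first_passage_solve(pc, 0.064, coarse_cfg)

        def mean_rt(rule_fn, fp_c, sm):
            fp_m = first_passage_solve(pm, sm, coarse_cfg)
            rt = rule_fn(fp_m, fp_c)
            d = rt.pair_density(1, 1)
            return np.sum(rt.times * d) / np.sum(d)

        serial_shifts = [
            mean_rt(serial_rt_density, fp_c_hard, sm)
            - mean_rt(serial_rt_density, fp_c_easy, sm)
            for sm in s_motion
        ]
        parallel_shifts = [
            mean_rt(parallel_rt_density, fp_c_hard, sm)
            - mean_rt(parallel_rt_density, fp_c_easy, sm)
            for sm in s_motion
        ]
        # serial: same shift for hard and easy motion (within tolerance)
        assert serial_shifts[0] == pytest.approx(serial_shifts[1], abs=0.015)
        # parallel: the shift depends on motion strength (pinched)
        assert abs(parallel_shifts[0] - parallel_shifts[1]) > 0.05
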