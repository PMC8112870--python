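"""Recovery and validation harnesses.

Self-contained study conditions for validating the package's estimators
on data simulated from known ground truth: serial-vs-parallel rule
recovery (diffusion-based and gamma-based), parameter recovery
(sensitivity kappa, buffer capacity, switch-interval and first-response
non-decision parameters), and the small closed-form checks (switch
interval expectation, accumulator variance, bottleneck timeline events).

Problem sizes are desk-scale: rule recovery uses an easy+hard 4x4 signed
design at 2304 trials per dataset (the free-response session count of
the reaching task) with warm-started refits; both candidate rules start
from the same point so neither is favored by initialization.
"""

from __future__ import annotations

import numpy as np

from .combine import NonDecisionSpec
from .ddm_core import BoundSpec, DDMParams
from .duration_buffer import BufferModelSpec, profile_buffer_grid
from .empirical_rt import GammaDecomposition, GammaSpec, fit_gamma_decomposition, simulate_from_gammas
from .fit_compare import fit_mle, log10_bayes_factor, pack_params
from .multiswitch import fit_multiswitch, simulate_first_response
from .synthetic_data import (
    DesignGrid,
    MultiSwitchSpec,
    TimelineSpec,
    bottleneck_timeline,
    draw_switch_intervals,
    simulate_trials,
)

__all__ = [
    "switch_interval_expectation",
    "unbounded_accumulator_variance",
    "timeline_first_updates",
    "diffusion_rule_recovery",
    "gamma_rule_recovery",
    "kappa_recovery",
    "buffer_capacity_recovery",
    "multiswitch_recovery",
]


def _seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------
# closed-form scale checks
# ---------------------------------------------------------------------------


def switch_interval_expectation(seed: int = 0, n: int = 1_000_000) -> float:
    """Mean inter-switch interval in multiples of tau_delta, estimated
    from n draws at tau_delta = 1 (closed form: 1.5)."""
    return float(draw_switch_intervals(1.0, n, seed=seed).mean())


def unbounded_accumulator_variance(
    seed: int = 0, n_paths: int = 100_000, dt: float = 1e-3, t: float = 1.0
) -> float:
    """Sample variance of the unbounded zero-drift decision variable at
    time t under step noise N(0, dt) (convention: unit variance per
    second)."""
    rng = np.random.default_rng(seed)
    n_steps = int(round(t / dt))
    v = np.zeros(n_paths)
    sdt = np.sqrt(dt)
    for _ in range(n_steps):
        v += rng.normal(0.0, sdt, size=n_paths)
    return float(np.var(v, ddof=1))


def timeline_first_updates() -> tuple[float, float]:
    """First motion and color update-receipt times (ms) in the bottleneck
    timeline with 90 ms sampling and a 90 ms instruction delay, motion
    first, strict alternation."""
    events = bottleneck_timeline(TimelineSpec(), t_dur=0.12)
    updates = [(t, d) for t, k, d in events if k == "update_received"]
    first_m = min(t for t, d in updates if d == "motion") * 1000
    first_c = min(t for t, d in updates if d == "color") * 1000
    return float(first_m), float(first_c)


# ---------------------------------------------------------------------------
# rule recovery
# ---------------------------------------------------------------------------

RECOVERY_DESIGN = DesignGrid(
    motion_levels=(0.064, 0.512), color_levels=(0.064, 0.472)
)
RECOVERY_N_PER_CELL = 144  # 16 signed conditions -> 2304 trials


def _recovery_gen_params() -> dict:
    return {
        "motion": DDMParams(
            11.0, 0.0, BoundSpec(form="logistic", u=0.9, a=1.2, d=1.5), "motion"
        ),
        "color": DDMParams(
            9.0, 0.0, BoundSpec(form="logistic", u=0.8, a=1.0, d=1.4), "color"
        ),
        "nd": NonDecisionSpec(0.32, 0.06),
    }


def diffusion_rule_recovery(
    n_datasets: int = 20, seed: int = 0, maxfev: int = 60
) -> dict:
    """Simulate datasets under each rule, fit both rules (warm-started
    at the generating parameters, identically for both candidates), and
    select by log10 Bayes factor.  Returns per-rule correct fractions
    and the Bayes factors."""
    params = _recovery_gen_params()
    x0 = pack_params(params["motion"], params["color"], params["nd"])
    out = {"serial": [], "parallel": []}
    seeds = _seeds(seed, 2 * n_datasets)
    for i, gen_rule in enumerate(("serial", "parallel")):
        for rep in range(n_datasets):
            s = seeds[i * n_datasets + rep]
            trials = simulate_trials(
                gen_rule, params, RECOVERY_DESIGN, n=RECOVERY_N_PER_CELL, seed=s
            )
            fit_s = fit_mle(trials, "serial", seed=s, n_starts=1, x0=x0, maxfev=maxfev)
            fit_p = fit_mle(trials, "parallel", seed=s, n_starts=1, x0=x0, maxfev=maxfev)
            out[gen_rule].append(log10_bayes_factor(fit_s, fit_p))
    return {
        "bf_serial_data": out["serial"],
        "bf_parallel_data": out["parallel"],
        "frac_correct_serial": float(np.mean(np.array(out["serial"]) > 0)),
        "frac_correct_parallel": float(np.mean(np.array(out["parallel"]) < 0)),
    }


def _gamma_truth():
    p_m = {-0.512: 0.02, -0.064: 0.25, 0.064: 0.75, 0.512: 0.98}
    p_c = {-0.512: 0.03, -0.064: 0.3, 0.064: 0.7, 0.512: 0.97}
    gam = {}
    for s, mean_corr in [(0.064, 0.55), (0.512, 0.25)]:
        for sign in (1, -1):
            for r in (1, -1):
                correct = sign == r
                gam[("m", sign * s, r)] = GammaSpec(
                    mean_corr if correct else 1.3 * mean_corr, 0.4 * mean_corr
                )
                gam[("c", sign * s, r)] = GammaSpec(
                    1.2 * mean_corr if correct else 1.5 * mean_corr, 0.45 * mean_corr
                )
    nd = {(r1, r2): GammaSpec(0.32, 0.06) for r1 in (1, -1) for r2 in (1, -1)}
    return p_m, p_c, gam, nd


def gamma_rule_recovery(n_datasets: int = 20, seed: int = 0, maxiter: int = 15) -> dict:
    """Rule recovery for the empirical gamma decomposition; both rules'
    fits warm-start from the generating cell values."""
    p_m, p_c, gam, nd = _gamma_truth()
    truth = GammaDecomposition(decision=gam, nondecision=nd, rule="serial")
    seeds = _seeds(seed + 1, 2 * n_datasets)
    margins = {"serial": [], "parallel": []}
    for i, gen_rule in enumerate(("serial", "parallel")):
        for rep in range(n_datasets):
            s = seeds[i * n_datasets + rep]
            trials = simulate_from_gammas(
                p_m, p_c, gam, nd, gen_rule, RECOVERY_N_PER_CELL, seed=s
            )
            ds = fit_gamma_decomposition(trials, "serial", x0=truth, maxiter=maxiter)
            dp = fit_gamma_decomposition(trials, "parallel", x0=truth, maxiter=maxiter)
            margins[gen_rule].append(ds.loglik - dp.loglik)
    return {
        "margin_serial_data": margins["serial"],
        "margin_parallel_data": margins["parallel"],
        "frac_correct_serial": float(np.mean(np.array(margins["serial"]) > 0)),
        "frac_correct_parallel": float(np.mean(np.array(margins["parallel"]) < 0)),
    }


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------


def kappa_recovery(seed: int = 0, maxfev: int = 900) -> dict:
    """Fit the serial model to 10^4 serial trials (kappa_m = 10,
    kappa_c = 12, flat-ish bounds) from generic multi-starts; returns the
    true and estimated sensitivities."""
    params = {
        "motion": DDMParams(
            10.0, 0.0, BoundSpec(form="logistic", u=0.8, a=0.3, d=3.0), "motion"
        ),
        "color": DDMParams(
            12.0, 0.0, BoundSpec(form="logistic", u=0.75, a=0.3, d=3.0), "color"
        ),
        "nd": NonDecisionSpec(0.3, 0.05),
    }
    design = DesignGrid(
        motion_levels=(0, 0.064, 0.256), color_levels=(0, 0.064, 0.256)
    )
    trials = simulate_trials("serial", params, design, n=400, seed=seed)
    fit = fit_mle(trials, "serial", seed=seed, n_starts=3, maxfev=maxfev)
    return {
        "kappa_m_true": 10.0,
        "kappa_c_true": 12.0,
        "kappa_m_est": fit.params["motion"].kappa,
        "kappa_c_est": fit.params["color"].kappa,
        "nll": fit.nll,
    }


BUFFER_VALIDATION_CAPACITY = 0.08  # s, the capacity used for validation


def _buffer_gen_spec() -> BufferModelSpec:
    # high color sensitivity makes 40 ms differences in available color
    # processing time measurable in choice accuracy; very hard motion
    # levels ensure the buffer often caps the color allocation
    return BufferModelSpec(
        t_buf=BUFFER_VALIDATION_CAPACITY,
        p_m_first=0.95,
        motion=DDMParams(
            10.0, 0.0, BoundSpec(form="clipped_exp", u=0.9, g=0.3, d=0.5), "motion"
        ),
        color=DDMParams(
            30.0, 0.0, BoundSpec(form="clipped_exp", u=1.1, g=0.3, d=0.5), "color"
        ),
    )


BUFFER_DESIGN = DesignGrid(
    motion_levels=(0.03, 0.06, 0.512),
    color_levels=(0.09, 0.15, 0.758),
    durations=tuple(np.round(np.arange(0.12, 1.21, 0.12), 3)),
    easy_easy_weight=0.2,
)


def buffer_capacity_recovery(
    seed: int = 0, maxfev: int = 120, n_repeats: int = 3
) -> dict:
    """Recover the buffer capacity by profile likelihood.

    Each repeat simulates ~3000 fixed-duration choice trials from the
    buffer model at the validation capacity and profiles the likelihood
    over the 0-240 ms grid (40 ms steps), refitting the remaining
    parameters at each grid value.  The reported capacity maximizes the
    profile summed over repeats (the validation protocol repeats the
    simulation rather than enlarging a single dataset).
    """
    gen = _buffer_gen_spec()
    grid = np.round(np.arange(0, 0.241, 0.04), 4)
    seeds = _seeds(seed + 11, n_repeats)
    profiles = []
    n_trials = 0
    for s in seeds:
        trials = simulate_trials(
            "buffer", {"buffer": gen}, BUFFER_DESIGN, n=9, seed=s, sim_dt=2.5e-4
        )
        n_trials = len(trials)
        profile, _ = profile_buffer_grid(
            trials, grid, seed=s, start=gen, maxfev=maxfev
        )
        profiles.append(profile.set_index("t_buf")["nll"])
    total = sum(profiles)
    best = float(total.idxmin())
    summed = total.reset_index().rename(columns={"nll": "nll"})
    summed["converged"] = True
    return {
        "capacity_true_ms": BUFFER_VALIDATION_CAPACITY * 1000,
        "capacity_est_ms": best * 1000,
        "profile": summed,
        "profiles": profiles,
        "n_trials": n_trials,
        "n_repeats": n_repeats,
    }


def multiswitch_recovery(seed: int = 0, n_per_cond: int = 250) -> dict:
    """Recover (tau_delta, p_m_first, tnd_first) from simulated bimanual
    first responses at tau_delta = 0.47 s (mean interval ~0.7 s)."""
    base = _recovery_gen_params()
    design = DesignGrid(
        motion_levels=(0.064, 0.256, 0.512), color_levels=(0.064, 0.25, 0.472)
    )
    true = MultiSwitchSpec(tau_delta=0.47, p_m_first=0.8, tnd_first=0.30)
    obs = simulate_first_response(base, true, design, n_per_cond=n_per_cond, seed=seed)
    fitted, sse, diag = fit_multiswitch(
        obs, base, design, seed=seed + 1, n_per_cond=n_per_cond, maxfev=120
    )
    return {
        "tau_delta_true": true.tau_delta,
        "tau_delta_est": fitted.tau_delta,
        "p_m_first_true": true.p_m_first,
        "p_m_first_est": fitted.p_m_first,
        "tnd_first_true": true.tnd_first,
        "tnd_first_est": fitted.tnd_first,
        "sse": sse,
        "diagnostics": diag,
    }
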