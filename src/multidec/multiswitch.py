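"""Multi-switch (time-multiplexed) serial model of the bimanual task.

The bimanual task yields two response times per trial, one per stimulus
dimension.  With a base serial fit (to the second response and the
choices) held fixed, three extra parameters explain the first response
time: the mean inter-switch exponential component tau_delta (switch
intervals are the max of two exponentials, expectation 1.5 tau_delta),
the probability p_m_first that motion is evaluated first, and the mean
non-decision time of the first report.  These parameters only affect the
first response: the second response time is the sum of the two decision
times regardless of the switching schedule.

Because the model has no closed form, fitting is by simulation with
common random numbers: the objective is the sum of squared errors of the
mean first-response times over four groupings (reported-first dimension
x own/other coherence), and is deterministic given (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .combine import NonDecisionSpec
from .ddm_core import DDMParams
from .synthetic_data import (
    MultiSwitchSpec,
    DesignGrid,
    _bound_array,
    _child_seed,
    _euler_free,
    _overlay_switch_schedule,
    generate_design,
)
from .ddm_core import drift_rate

__all__ = [
    "FirstResponseData",
    "simulate_first_response",
    "multiswitch_objective",
    "fit_multiswitch",
    "compute_groupings",
]

#: upper search bound for tau_delta (s); a fit at this bound is the
#: single-switch degenerate case
TAU_DELTA_MAX = 20.0

GROUPINGS = (
    ("motion", "own"),
    ("motion", "other"),
    ("color", "own"),
    ("color", "other"),
)


@dataclass
class FirstResponseData:
    """Trials with a first-response time and the four binned groupings.

    group_means maps (first_dim, own|other) -> Series of mean rt_first
    indexed by unsigned coherence of the own / other dimension.
    """

    trials: pd.DataFrame
    group_means: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.group_means:
            self.group_means = compute_groupings(self.trials)


def compute_groupings(trials: pd.DataFrame) -> dict:
    """Mean rt_first in the four groupings: split by the dimension
    reported first, binned by own-dimension or other-dimension unsigned
    coherence (bins are the design's strength levels)."""
    df = trials.copy()
    df["am"] = df["s_m"].abs()
    df["ac"] = df["s_c"].abs()
    out = {}
    for first in ("motion", "color"):
        sub = df[df["first_dim"] == first]
        own_col = "am" if first == "motion" else "ac"
        oth_col = "ac" if first == "motion" else "am"
        out[(first, "own")] = sub.groupby(own_col)["rt_first"].mean()
        out[(first, "other")] = sub.groupby(oth_col)["rt_first"].mean()
    return out


def _base_components(base_fit) -> tuple[DDMParams, DDMParams, NonDecisionSpec]:
    params = base_fit.params if hasattr(base_fit, "params") else base_fit
    return params["motion"], params["color"], params["nd"]


def simulate_first_response(
    base_fit,
    spec: MultiSwitchSpec,
    design: DesignGrid,
    n_per_cond: int = 1000,
    seed: int = 0,
    sim_dt: float = 5e-4,
    horizon: float = 5.0,
) -> FirstResponseData:
    """Simulate the bimanual task under the multi-switch schedule.

    base_fit supplies the two diffusions and the (second-response)
    non-decision spec; they are held fixed.  The switch schedule is
    overlaid on the evidence-time absorptions, so the three spec
    parameters only shape rt_first.
    """
    from .synthetic_data import simulate_trials

    pm, pc, nd = _base_components(base_fit)
    trials = simulate_trials(
        "multiswitch",
        {"motion": pm, "color": pc, "nd": nd, "switch": spec},
        design,
        n=n_per_cond,
        seed=seed,
        sim_dt=sim_dt,
        horizon=horizon,
    )
    return FirstResponseData(trials=trials)


def multiswitch_objective(sim: FirstResponseData, obs: FirstResponseData) -> float:
    """Sum of squared errors of mean rt_first over the four groupings.

    Bins present in only one of the two data sets are dropped from both
    (symmetric treatment of empty bins)."""
    sse = 0.0
    for key in GROUPINGS:
        a = sim.group_means.get(key)
        b = obs.group_means.get(key)
        if a is None or b is None:
            continue
        common = a.index.intersection(b.index)
        if len(common) == 0:
            continue
        diff = a.loc[common].to_numpy() - b.loc[common].to_numpy()
        sse += float(np.sum(diff**2))
    return sse


class _CRNSimulator:
    """Common-random-number simulator for the multi-switch objective.

    The evidence-time absorptions (t_m, t_c) do not depend on the three
    first-response parameters, so they are drawn once; each candidate
    parameter vector only re-runs the (seeded) switch-schedule overlay
    and adds the mean first-response non-decision time.
    """

    def __init__(self, base_fit, design: DesignGrid, n_per_cond: int,
                 seed: int, sim_dt: float = 5e-4, horizon: float = 5.0):
        pm, pc, nd = _base_components(base_fit)
        cond = generate_design(design)
        cond = cond.loc[cond.index.repeat(n_per_cond)].reset_index(drop=True)
        ss = np.random.SeedSequence(seed)
        mu_m = np.asarray(drift_rate(pm, cond["s_m"].to_numpy()))
        mu_c = np.asarray(drift_rate(pc, cond["s_c"].to_numpy()))
        b_m = _bound_array(pm, sim_dt, horizon)
        b_c = _bound_array(pc, sim_dt, horizon)
        _, self.t_m, _ = _euler_free(mu_m, b_m, sim_dt, _child_seed(ss))
        _, self.t_c, _ = _euler_free(mu_c, b_c, sim_dt, _child_seed(ss))
        self.overlay_seed = _child_seed(ss)
        self.s_m = cond["s_m"].to_numpy()
        self.s_c = cond["s_c"].to_numpy()

    def first_response(self, spec: MultiSwitchSpec) -> FirstResponseData:
        first_dim, t_first = _overlay_switch_schedule(
            self.t_m, self.t_c, spec.tau_delta, spec.p_m_first, self.overlay_seed
        )
        df = pd.DataFrame(
            {
                "s_m": self.s_m,
                "s_c": self.s_c,
                "first_dim": np.where(first_dim == 0, "motion", "color"),
                "rt_first": t_first + spec.tnd_first,
            }
        )
        return FirstResponseData(trials=df)


def fit_multiswitch(
    obs: FirstResponseData,
    base_fit,
    design: DesignGrid,
    bounds: dict | None = None,
    seed: int = 0,
    n_per_cond: int = 500,
    maxfev: int = 120,
    x0: MultiSwitchSpec | None = None,
) -> tuple[MultiSwitchSpec, float, dict]:
    """Fit (tau_delta, p_m_first, tnd_first) by simulation-based SSE.

    Uses common random numbers so the objective is deterministic given
    (parameters, seed).  Returns (spec, objective value, diagnostics);
    diagnostics["single_switch_degenerate"] is True when tau_delta ends
    at its upper bound (the schedule never switches before the first
    absorption, as for a single-switch observer).
    """
    b = {
        "tau_delta": (0.05, TAU_DELTA_MAX),
        "p_m_first": (0.01, 0.99),
        "tnd_first": (0.01, 1.0),
        **(bounds or {}),
    }
    sim = _CRNSimulator(base_fit, design, n_per_cond, seed)

    def unpack(x):
        return MultiSwitchSpec(
            tau_delta=float(np.exp(x[0])),
            p_m_first=float(1.0 / (1.0 + np.exp(-x[1]))),
            tnd_first=float(np.clip(x[2], *b["tnd_first"])),
        )

    def objective(x):
        spec = unpack(x)
        if not b["tau_delta"][0] <= spec.tau_delta <= b["tau_delta"][1]:
            return 1e9
        if not b["p_m_first"][0] <= spec.p_m_first <= b["p_m_first"][1]:
            return 1e9
        return multiswitch_objective(sim.first_response(spec), obs)

    if x0 is None:
        starts = [
            MultiSwitchSpec(tau_delta=0.5, p_m_first=0.7, tnd_first=0.3),
            # the single-switch regime is a separate basin: start one
            # search near the upper tau_delta bound
            MultiSwitchSpec(tau_delta=0.9 * TAU_DELTA_MAX, p_m_first=0.7, tnd_first=0.3),
            MultiSwitchSpec(tau_delta=0.15, p_m_first=0.5, tnd_first=0.3),
        ]
    else:
        starts = [x0]
    res = None
    for s0 in starts:
        start = np.array(
            [np.log(s0.tau_delta), np.log(s0.p_m_first / (1 - s0.p_m_first)), s0.tnd_first]
        )
        r = optimize.minimize(
            objective, start, method="Nelder-Mead",
            options={"maxfev": maxfev, "xatol": 1e-3, "fatol": 1e-6},
        )
        if res is None or r.fun < res.fun:
            res = r
    spec = unpack(res.x)
    degenerate = spec.tau_delta >= 0.8 * b["tau_delta"][1]
    diagnostics = {
        "single_switch_degenerate": bool(degenerate),
        "nfev": int(res.nfev),
        "converged": bool(res.success),
    }
    return spec, float(res.fun), diagnostics
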