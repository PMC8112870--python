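"""Synthetic experiment designs and trial-level data generators.

Generates factorial signed-coherence designs (e.g. the 9x9 and 11x11
grids of the free-response tasks), and simulates trial tables under four
double-decision architectures:

* ``serial``     RT = Tm + Tc + Tnd (one accumulator at a time)
* ``parallel``   RT = max(Tm, Tc) + Tnd (simultaneous accumulation)
* ``multiswitch``time-multiplexed serial accumulation with renewal
  switching; emits the first and second response times of a bimanual
  report
* ``buffer``     parallel acquisition for a buffer-capacity window, then
  serial prioritized processing of a fixed-duration stimulus (choices
  only)

Accumulators follow Euler-Maruyama increments ``dV = mu dt + N(0, dt)``
with symmetric, possibly collapsing bounds.  The module also produces the
deterministic discrete-event timeline of the sample/buffer/update
bottleneck schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from .combine import NonDecisionSpec
from .ddm_core import DDMParams, bound_height, drift_rate

__all__ = [
    "DesignGrid",
    "MultiSwitchSpec",
    "TimelineSpec",
    "DesignError",
    "generate_design",
    "simulate_trials",
    "draw_switch_intervals",
    "bottleneck_timeline",
    "EXP_DESIGNS",
]

SIM_DT = 2.5e-4  # Euler-Maruyama step (s); finer than the solver grid
SIM_HORIZON = 5.0  # censoring horizon (s), the task response deadline


class DesignError(ValueError):
    """Invalid experiment design."""


@dataclass(frozen=True)
class DesignGrid:
    """Factorial design over unsigned coherence levels.

    Each dimension's signed expansion is +/- each nonzero level, plus 0
    if 0 is listed; e.g. five unsigned levels including 0 give nine
    signed values and a 9x9 factorial.
    """

    motion_levels: tuple[float, ...]
    color_levels: tuple[float, ...]
    n_per_cell: int = 10
    durations: tuple[float, ...] | None = None
    #: weight applied to the trial count of easy-easy cells (both
    #: dimensions at their maximum level); the variable-duration task
    #: presents those combinations rarely (~2.4% of trials)
    easy_easy_weight: float = 1.0

    def __post_init__(self) -> None:
        for levels in (self.motion_levels, self.color_levels):
            if len(levels) == 0:
                raise DesignError("empty coherence level list")
            if any(not 0 <= lv <= 1 for lv in levels):
                raise DesignError(f"levels must be in [0, 1], got {levels}")

    @staticmethod
    def _signed(levels: Sequence[float]) -> np.ndarray:
        nonzero = sorted({lv for lv in levels if lv > 0})
        signed = [-lv for lv in reversed(nonzero)]
        if 0 in levels or 0.0 in levels:
            signed.append(0.0)
        signed.extend(nonzero)
        return np.array(signed)

    @property
    def signed_motion(self) -> np.ndarray:
        return self._signed(self.motion_levels)

    @property
    def signed_color(self) -> np.ndarray:
        return self._signed(self.color_levels)


#: experiment presets: unsigned coherence levels from the study designs
EXP_DESIGNS: dict[str, DesignGrid] = {
    # eye free-response task: 5 unsigned levels incl. 0 -> 9x9 signed
    "exp1_eye": DesignGrid(
        motion_levels=(0, 0.032, 0.064, 0.128, 0.256),
        color_levels=(0, 0.031, 0.062, 0.124, 0.245),
    ),
    # unimanual / bimanual tasks: 6 unsigned levels incl. 0 -> 11x11 signed
    "exp1_uni": DesignGrid(
        motion_levels=(0, 0.032, 0.064, 0.128, 0.256, 0.512),
        color_levels=(0, 0.064, 0.128, 0.250, 0.472, 0.758),
    ),
    "exp2_short": DesignGrid(
        motion_levels=(0, 0.064, 0.128, 0.256, 0.512),
        color_levels=(0, 0.124, 0.245, 0.462, 0.762),
        durations=(0.12,),
    ),
    # variable-duration task: 3 unsigned levels -> 6x6 signed, 120..1200 ms
    "exp3_duration": DesignGrid(
        motion_levels=(0.03, 0.063, 0.512),
        color_levels=(0.052, 0.104, 0.758),
        durations=tuple(np.round(np.arange(0.12, 1.21, 0.12), 3)),
    ),
    "exp4_bimanual": DesignGrid(
        motion_levels=(0, 0.032, 0.064, 0.128, 0.256, 0.512),
        color_levels=(0, 0.064, 0.128, 0.250, 0.472, 0.758),
    ),
}


@dataclass(frozen=True)
class MultiSwitchSpec:
    """Renewal-switching parameters of the time-multiplexed serial model.

    tau_delta : mean of each exponential component of the inter-switch
        interval (s); the interval is the max of two such draws, so its
        expectation is 1.5 * tau_delta.
    p_m_first : probability that motion is evaluated first.
    tnd_first : mean non-decision time of the first report (s).
    """

    tau_delta: float
    p_m_first: float
    tnd_first: float

    def __post_init__(self) -> None:
        if self.tau_delta <= 0:
            raise ValueError(f"tau_delta must be > 0, got {self.tau_delta}")
        if not 0 <= self.p_m_first <= 1:
            raise ValueError(f"p_m_first must be in [0, 1], got {self.p_m_first}")


@dataclass
class TimelineSpec:
    """Parameters of the discrete sample/buffer/update bottleneck schedule.

    tau_s : sampling interval (s); the buffers acquire their first samples
        at t = tau_s.
    tau_ins : instruction delay (s) from buffer clearance to receipt of the
        decision-variable update; only one instruction may be in flight.
    tau_v : decision-circuit time constant (s); annotation only.
    schedule : alternation policy; "alternate" = strict alternation among
        dimensions holding a buffered sample.
    first : dimension given priority for the first update.
    """

    tau_s: float = 0.09
    tau_ins: float = 0.09
    tau_v: float = 0.04
    schedule: str = "alternate"
    first: str = "motion"
    dims: tuple[str, ...] = ("motion", "color")

    def __post_init__(self) -> None:
        if self.tau_s <= 0:
            raise ValueError(f"tau_s must be > 0, got {self.tau_s}")
        if self.tau_ins < 0:
            raise ValueError(f"tau_ins must be >= 0, got {self.tau_ins}")


def generate_design(
    grid: DesignGrid, seed: int | None = None, shuffle: bool = False
) -> pd.DataFrame:
    """Full factorial of signed coherences (and durations, if present).

    Conditions are enumerated in deterministic (sorted) order; with
    ``shuffle=True`` the rows are then shuffled with the given seed.
    """
    s_m = grid.signed_motion
    s_c = grid.signed_color
    rows = []
    durations = grid.durations if grid.durations is not None else (np.nan,)
    for sm in s_m:
        for sc in s_c:
            for td in durations:
                rows.append((sm, sc, td))
    df = pd.DataFrame(rows, columns=["s_m", "s_c", "t_dur"])
    if grid.durations is None:
        df = df.drop(columns=["t_dur"])
    if shuffle:
        rng = np.random.default_rng(seed)
        df = df.sample(frac=1.0, random_state=rng).reset_index(drop=True)
    return df


def draw_switch_intervals(tau_delta: float, n: int, seed=None) -> np.ndarray:
    """Inter-switch intervals: iid max of two exponentials with mean
    tau_delta.  Density 2*lam*exp(-lam t)*(1 - exp(-lam t)), lam =
    1/tau_delta; expectation 1.5 * tau_delta."""
    if tau_delta <= 0:
        raise ValueError(f"tau_delta must be > 0, got {tau_delta}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = rng.exponential(tau_delta, size=n)
    b = rng.exponential(tau_delta, size=n)
    return np.maximum(a, b)


# ---------------------------------------------------------------------------
# Euler-Maruyama accumulators (numba kernels)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _euler_free(mus, bound, dt, seed):
    """Simulate paths to absorption (free response).

    Returns (side, t_dec, absorbed): side in {+1,-1} (sign of V at the
    horizon if censored), decision time (s), absorption flag.
    """
    np.random.seed(seed)
    n = mus.shape[0]
    n_steps = bound.shape[0] - 1
    side = np.zeros(n, np.int64)
    t_dec = np.empty(n)
    absorbed = np.zeros(n, np.bool_)
    sdt = np.sqrt(dt)
    for i in range(n):
        v = 0.0
        mu_dt = mus[i] * dt
        for k in range(1, n_steps + 1):
            v += mu_dt + np.random.normal() * sdt
            b = bound[k]
            if v >= b:
                side[i] = 1
                t_dec[i] = k * dt
                absorbed[i] = True
                break
            elif v <= -b:
                side[i] = -1
                t_dec[i] = k * dt
                absorbed[i] = True
                break
        if not absorbed[i]:
            side[i] = 1 if v > 0 else -1
            t_dec[i] = n_steps * dt
    return side, t_dec, absorbed


@njit(cache=True)
def _euler_fixed(mus, bound, n_steps_each, dt, seed):
    """Simulate paths for per-trial fixed processing times.

    Absorption at the (possibly collapsing) bound may occur before the
    per-trial step count n_steps_each[i]; otherwise the choice is the sign
    of the unabsorbed V.  Returns (side, t_dec, absorbed).
    """
    np.random.seed(seed)
    n = mus.shape[0]
    side = np.zeros(n, np.int64)
    t_dec = np.empty(n)
    absorbed = np.zeros(n, np.bool_)
    sdt = np.sqrt(dt)
    for i in range(n):
        v = 0.0
        mu_dt = mus[i] * dt
        m = n_steps_each[i]
        for k in range(1, m + 1):
            v += mu_dt + np.random.normal() * sdt
            b = bound[k]
            if v >= b:
                side[i] = 1
                t_dec[i] = k * dt
                absorbed[i] = True
                break
            elif v <= -b:
                side[i] = -1
                t_dec[i] = k * dt
                absorbed[i] = True
                break
        if not absorbed[i]:
            if v > 0:
                side[i] = 1
            elif v < 0:
                side[i] = -1
            else:
                side[i] = 1 if np.random.random() < 0.5 else -1
            t_dec[i] = m * dt
    return side, t_dec, absorbed


@njit(cache=True)
def _overlay_switch_schedule(t_m, t_c, tau_delta, p_m_first, seed):
    """Clock time of the first absorption under renewal alternation.

    t_m, t_c are the per-trial evidence (processing) times to absorption
    of the two accumulators.  During an epoch only the active dimension's
    evidence time advances; absorption interrupts the epoch in progress;
    after the first absorption the survivor runs without interruption.

    Returns (first_dim, t_first_clock): first_dim 0 = motion, 1 = color.
    """
    np.random.seed(seed)
    n = t_m.shape[0]
    first_dim = np.zeros(n, np.int64)
    t_first = np.empty(n)
    for i in range(n):
        rem = np.empty(2)
        rem[0] = t_m[i]
        rem[1] = t_c[i]
        active = 0 if np.random.random() < p_m_first else 1
        clock = 0.0
        while True:
            a = np.random.exponential(tau_delta)
            b = np.random.exponential(tau_delta)
            epoch = a if a > b else b
            if rem[active] <= epoch:
                clock += rem[active]
                first_dim[i] = active
                t_first[i] = clock
                break
            rem[active] -= epoch
            clock += epoch
            active = 1 - active
    return first_dim, t_first


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.spawn(1)[0].generate_state(1)[0] % (2**31 - 1))


def _bound_array(params: DDMParams, dt: float, horizon: float) -> np.ndarray:
    n_steps = int(round(horizon / dt))
    return np.asarray(bound_height(params.bound, np.arange(n_steps + 1) * dt))


def _draw_nd(rng: np.random.Generator, nd: NonDecisionSpec, n: int) -> np.ndarray:
    """Truncated-normal non-decision draws (resample below zero)."""
    out = rng.normal(nd.mu_nd, nd.sigma_nd, size=n) if nd.sigma_nd > 0 else np.full(n, nd.mu_nd)
    bad = out < 0
    while np.any(bad):
        out[bad] = rng.normal(nd.mu_nd, nd.sigma_nd, size=int(bad.sum()))
        bad = out < 0
    return out


def simulate_trials(
    architecture: str,
    params: dict,
    design: DesignGrid,
    n: int | None = None,
    seed: int = 0,
    sim_dt: float = SIM_DT,
    horizon: float = SIM_HORIZON,
) -> pd.DataFrame:
    """Simulate a trial table under the given architecture.

    params keys:
      serial/parallel : motion, color (DDMParams), nd (NonDecisionSpec)
      multiswitch     : additionally switch (MultiSwitchSpec)
      buffer          : buffer (an object with fields motion, color,
                        t_buf, p_m_first); design must carry durations

    n overrides design.n_per_cell (trials per condition cell).  Trials
    whose accumulation exceeds the horizon are flagged censored, not
    dropped.  Reproducible given seed.
    """
    if architecture not in ("serial", "parallel", "multiswitch", "buffer"):
        raise ValueError(f"unknown architecture {architecture!r}")
    n_per = int(n) if n is not None else design.n_per_cell
    cond = generate_design(design)
    reps = np.full(len(cond), n_per)
    if design.easy_easy_weight != 1.0:
        easy = (cond["s_m"].abs() == cond["s_m"].abs().max()) & (
            cond["s_c"].abs() == cond["s_c"].abs().max()
        )
        reps[easy.to_numpy()] = max(int(round(n_per * design.easy_easy_weight)), 1)
    cond = cond.loc[cond.index.repeat(reps)].reset_index(drop=True)
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])

    if architecture == "buffer":
        return _simulate_buffer(params["buffer"], cond, rng, ss, sim_dt, seed)

    pm: DDMParams = params["motion"]
    pc: DDMParams = params["color"]
    nd: NonDecisionSpec = params["nd"]
    mu_m = np.asarray(drift_rate(pm, cond["s_m"].to_numpy()))
    mu_c = np.asarray(drift_rate(pc, cond["s_c"].to_numpy()))
    b_m = _bound_array(pm, sim_dt, horizon)
    b_c = _bound_array(pc, sim_dt, horizon)
    side_m, t_dec_m, abs_m = _euler_free(mu_m, b_m, sim_dt, _child_seed(ss))
    side_c, t_dec_c, abs_c = _euler_free(mu_c, b_c, sim_dt, _child_seed(ss))
    nd_draw = _draw_nd(rng, nd, len(cond))
    censored = ~(abs_m & abs_c)

    out = pd.DataFrame(
        {
            "subject": "sim",
            "s_m": cond["s_m"].to_numpy(),
            "s_c": cond["s_c"].to_numpy(),
            "R_m": side_m,
            "R_c": side_c,
            "censored": censored,
        }
    )
    if architecture == "serial":
        out["task"] = "2D-RT"
        out["rt"] = t_dec_m + t_dec_c + nd_draw
    elif architecture == "parallel":
        out["task"] = "2D-RT"
        out["rt"] = np.maximum(t_dec_m, t_dec_c) + nd_draw
    else:  # multiswitch
        sw: MultiSwitchSpec = params["switch"]
        first_dim, t_first = _overlay_switch_schedule(
            t_dec_m, t_dec_c, sw.tau_delta, sw.p_m_first, _child_seed(ss)
        )
        nd_first = _draw_nd(
            rng, NonDecisionSpec(sw.tnd_first, nd.sigma_nd), len(cond)
        )
        rt_first = t_first + nd_first
        rt_second = t_dec_m + t_dec_c + nd_draw
        # the first report cannot follow the second; clipping rt_first
        # keeps rt_second independent of the first-response parameters
        rt_first = np.minimum(rt_first, rt_second)
        out["task"] = "bimanual"
        out["rt"] = rt_second
        out["rt_first"] = rt_first
        out["rt_second"] = rt_second
        out["first_dim"] = np.where(first_dim == 0, "motion", "color")
    out.attrs["seed"] = seed
    out.attrs["architecture"] = architecture
    return out


def _simulate_buffer(spec, cond, rng, ss, sim_dt, seed) -> pd.DataFrame:
    """Fixed-duration choices under the buffer-limited serial model."""
    from .duration_buffer import allocate_processing_time

    if "t_dur" not in cond.columns:
        raise DesignError("buffer architecture requires a design with durations")
    pm: DDMParams = spec.motion
    pc: DDMParams = spec.color
    n_tr = len(cond)
    mu_m = np.asarray(drift_rate(pm, cond["s_m"].to_numpy()))
    mu_c = np.asarray(drift_rate(pc, cond["s_c"].to_numpy()))
    t_dur = cond["t_dur"].to_numpy()
    max_dur = float(np.max(t_dur))
    b_m = _bound_array(pm, sim_dt, max_dur)
    b_c = _bound_array(pc, sim_dt, max_dur)
    m_first = rng.random(n_tr) < spec.p_m_first
    steps_dur = np.round(t_dur / sim_dt).astype(np.int64)

    # prioritized dimension processes the full stimulus duration
    mu_pri = np.where(m_first, mu_m, mu_c)
    b_pri_m = b_m
    b_pri_c = b_c
    side_pri = np.empty(n_tr, np.int64)
    t_pri = np.empty(n_tr)
    abs_pri = np.empty(n_tr, np.bool_)
    idx_m = np.where(m_first)[0]
    idx_c = np.where(~m_first)[0]
    for idx, b in ((idx_m, b_pri_m), (idx_c, b_pri_c)):
        if len(idx) == 0:
            continue
        s, t, a = _euler_fixed(
            mu_pri[idx], b, steps_dur[idx], sim_dt, _child_seed(ss)
        )
        side_pri[idx] = s
        t_pri[idx] = t
        abs_pri[idx] = a

    # other dimension gets the buffer-limited allocation
    t_other = np.array(
        [
            allocate_processing_time(
                spec.t_buf, t_dur[i], t_pri[i] if abs_pri[i] else None
            )
            for i in range(n_tr)
        ]
    )
    steps_other = np.round(t_other / sim_dt).astype(np.int64)
    mu_oth = np.where(m_first, mu_c, mu_m)
    side_oth = np.empty(n_tr, np.int64)
    for idx, b in ((idx_m, b_c), (idx_c, b_m)):
        if len(idx) == 0:
            continue
        s, _, _ = _euler_fixed(
            mu_oth[idx], b, steps_other[idx], sim_dt, _child_seed(ss)
        )
        side_oth[idx] = s

    out = pd.DataFrame(
        {
            "subject": "sim",
            "task": "2D-duration",
            "s_m": cond["s_m"].to_numpy(),
            "s_c": cond["s_c"].to_numpy(),
            "R_m": np.where(m_first, side_pri, side_oth),
            "R_c": np.where(m_first, side_oth, side_pri),
            "t_dur": t_dur,
            "censored": False,
        }
    )
    out.attrs["seed"] = seed
    out.attrs["architecture"] = "buffer"
    return out


def bottleneck_timeline(spec: TimelineSpec, t_dur: float) -> list[tuple[float, str, str]]:
    """Deterministic discrete-event schedule of buffered evidence updates.

    Each dimension's buffer acquires an (independent) evidence sample no
    sooner than tau_s after its previous acquisition, the first at
    t = tau_s; because the filtered evidence stream outlasts the stimulus
    by about one sampling interval, samples are available up to
    t_dur + tau_s.  Clearing a buffer issues an update instruction that
    takes tau_ins to be received; only one instruction can be in flight
    (the bottleneck).  Among dimensions holding a sample, clearance
    strictly alternates, starting with ``spec.first``.

    Returns the event log: ordered (time, event_kind, dimension) tuples
    with kinds "sample_acquired", "instruction_sent", "update_received".
    """
    if t_dur <= 0:
        raise ValueError(f"t_dur must be > 0, got {t_dur}")
    dims = list(spec.dims)
    deadline = t_dur + spec.tau_s
    events: list[tuple[float, str, str]] = []

    buffered_at: dict[str, float | None] = {d: None for d in dims}
    last_acq: dict[str, float] = {d: -np.inf for d in dims}
    exhausted: dict[str, bool] = {d: False for d in dims}
    channel_free = 0.0
    last_sent: str | None = None

    def try_acquire(dim: str, ready: float) -> None:
        if buffered_at[dim] is not None or exhausted[dim]:
            return
        t_acq = max(spec.tau_s, last_acq[dim] + spec.tau_s, ready)
        if t_acq > deadline + 1e-12:
            exhausted[dim] = True
            return
        buffered_at[dim] = t_acq
        last_acq[dim] = t_acq
        events.append((t_acq, "sample_acquired", dim))

    for d in dims:
        try_acquire(d, 0.0)

    while True:
        candidates = [d for d in dims if buffered_at[d] is not None]
        if not candidates:
            break
        if spec.schedule == "alternate" and last_sent is not None:
            order = [d for d in dims if d != last_sent] + [last_sent]
            candidates.sort(key=order.index)
        else:
            first_order = [spec.first] + [d for d in dims if d != spec.first]
            candidates.sort(key=first_order.index)
        dim = candidates[0]
        t_send = max(channel_free, buffered_at[dim])
        events.append((t_send, "instruction_sent", dim))
        events.append((t_send + spec.tau_ins, "update_received", dim))
        channel_free = t_send + spec.tau_ins
        buffered_at[dim] = None
        last_sent = dim
        try_acquire(dim, t_send)
        for d in dims:
            try_acquire(d, t_send)

    events.sort(key=lambda e: (e[0], e[1]))
    return events
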