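"""Buffer-limited serial model for experimenter-controlled durations.

For a fixed-duration stimulus the two dimensions are acquired in parallel
for a buffer-capacity window ``t_buf``; thereafter processing is serial,
with one dimension prioritized (motion with probability ``p_m_first``).
The prioritized dimension accumulates for the full stimulus duration (or
until its bound); the other dimension's maximum processing time is

    t_max_other = t_dur                      if t_dur <= t_buf or t_pri <= t_buf
                  t_buf + (t_dur - t_pri)    if t_pri > t_buf
                  t_buf                      if the prioritized process never
                                             terminates and t_dur > t_buf

where ``t_pri`` is the prioritized dimension's absorption time.  Setting
t_buf = 0 yields a purely serial single-switch model; t_buf at or above
the longest duration is effectively parallel.  Only choices are modeled
(no non-decision component); the likelihood is over the four choice pairs
per (coherence pair, duration) cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .ddm_core import (
    BoundSpec,
    DDMParams,
    FirstPassage,
    SolverConfig,
    first_passage_solve,
)

__all__ = [
    "BufferModelSpec",
    "allocate_processing_time",
    "variable_duration_negloglik",
    "profile_buffer_grid",
    "default_buffer_grid",
    "choice_prob_table",
]

LIK_FLOOR = 1e-10

#: solver used for fixed-duration likelihoods: horizon just past the
#: longest stimulus duration used in the variable-duration design
DUR_SOLVER = SolverConfig(dt=2.5e-3, t_max=1.25, n_grid=96)


@dataclass(frozen=True)
class BufferModelSpec:
    """Buffer capacity, prioritization, and the two 1D diffusions.

    The diffusions use clipped-exponential bounds and no non-decision
    component (choices only).
    """

    t_buf: float
    p_m_first: float
    motion: DDMParams
    color: DDMParams

    def __post_init__(self) -> None:
        if self.t_buf < 0:
            raise ValueError(f"t_buf must be >= 0, got {self.t_buf}")
        if not 0 <= self.p_m_first <= 1:
            raise ValueError(f"p_m_first must be in [0, 1], got {self.p_m_first}")


def allocate_processing_time(
    t_buf: float, t_dur: float, t_m: float | None = None
) -> float:
    """Maximum processing time available to the non-prioritized dimension.

    t_m is the prioritized dimension's absorption time, or None if it did
    not terminate within the stimulus.
    """
    if t_buf < 0 or t_dur < 0 or (t_m is not None and t_m < 0):
        raise ValueError("times must be >= 0")
    if t_m is not None and t_m > t_dur + 1e-12:
        raise ValueError(
            f"absorption time t_m={t_m} cannot postdate stimulus end t_dur={t_dur}"
        )
    if t_dur <= t_buf:
        return t_dur
    if t_m is None:
        return t_buf
    if t_m <= t_buf:
        return t_dur
    return t_buf + (t_dur - t_m)


def _pos_neg_mass(fp: FirstPassage) -> tuple[np.ndarray, np.ndarray]:
    """Unabsorbed mass with positive / negative sign at each time index."""
    pos_cols = fp.grid > 1e-12
    neg_cols = fp.grid < -1e-12
    pos = fp.survivor[:, pos_cols].sum(axis=1) * fp.dx
    neg = fp.survivor[:, neg_cols].sum(axis=1) * fp.dx
    on_zero = np.abs(fp.grid) <= 1e-12
    if np.any(on_zero):
        half = 0.5 * fp.survivor[:, on_zero].sum(axis=1) * fp.dx
        pos = pos + half
        neg = neg + half
    return pos, neg


def _fixed_dur_pos_prob(fp: FirstPassage) -> np.ndarray:
    """P(positive choice | processing time = t_k) for every grid time."""
    cum_up = np.cumsum(fp.f_upper) * fp.dt
    cum_lo = np.cumsum(fp.f_lower) * fp.dt
    pos, neg = _pos_neg_mass(fp)
    num = cum_up + pos
    den = cum_up + cum_lo + pos + neg
    return num / np.maximum(den, 1e-300)


def _pair_probs_one_direction(
    fp_pri: FirstPassage,
    p_pos_oth: np.ndarray,
    t_buf: float,
    t_dur: float,
) -> np.ndarray:
    """Joint choice-pair probabilities (pri x other) for one prioritization.

    Returns a (2, 2) array indexed [prioritized choice +/-, other choice
    +/-], integrating over the prioritized dimension's absorption time
    (and its survivor mass) to set the other dimension's processing time.
    """
    dt = fp_pri.dt
    k_dur = int(round(t_dur / dt))
    t = fp_pri.times[: k_dur + 1]
    # processing time of the other dimension given prioritized absorption at t
    tc = np.where(
        (t_dur <= t_buf) | (t <= t_buf), t_dur, t_buf + (t_dur - t)
    )
    j = np.clip(np.round(tc / dt).astype(int), 0, len(p_pos_oth) - 1)
    p_oth = p_pos_oth[j]

    w_up = fp_pri.f_upper[: k_dur + 1] * dt
    w_lo = fp_pri.f_lower[: k_dur + 1] * dt
    out = np.zeros((2, 2))
    out[0, 0] = np.sum(w_up * p_oth)
    out[0, 1] = np.sum(w_up * (1.0 - p_oth))
    out[1, 0] = np.sum(w_lo * p_oth)
    out[1, 1] = np.sum(w_lo * (1.0 - p_oth))

    # prioritized dimension unabsorbed at stimulus end
    pos, neg = _pos_neg_mass(fp_pri)
    tc_no = t_dur if t_dur <= t_buf else t_buf
    j_no = min(int(round(tc_no / dt)), len(p_pos_oth) - 1)
    p_oth_no = p_pos_oth[j_no]
    out[0, 0] += pos[k_dur] * p_oth_no
    out[0, 1] += pos[k_dur] * (1.0 - p_oth_no)
    out[1, 0] += neg[k_dur] * p_oth_no
    out[1, 1] += neg[k_dur] * (1.0 - p_oth_no)
    return out


def _solve_per_level(params: DDMParams, levels: np.ndarray, cfg: SolverConfig):
    return {s: first_passage_solve(params, s, cfg) for s in levels}


def choice_prob_table(
    spec: BufferModelSpec,
    conditions: pd.DataFrame,
    cfg: SolverConfig = DUR_SOLVER,
) -> pd.DataFrame:
    """Model choice-pair probabilities per (s_m, s_c, t_dur) condition.

    Returns the input conditions with columns p_pp, p_pn, p_np, p_nn
    (motion sign first) and the marginals p_m_pos, p_c_pos.
    """
    cond = conditions.drop_duplicates(["s_m", "s_c", "t_dur"]).reset_index(drop=True)
    fps_m = _solve_per_level(spec.motion, cond["s_m"].unique(), cfg)
    fps_c = _solve_per_level(spec.color, cond["s_c"].unique(), cfg)
    p_pos_m = {s: _fixed_dur_pos_prob(fp) for s, fp in fps_m.items()}
    p_pos_c = {s: _fixed_dur_pos_prob(fp) for s, fp in fps_c.items()}

    rows = []
    for sm, sc, td in cond[["s_m", "s_c", "t_dur"]].itertuples(index=False):
        pri_m = _pair_probs_one_direction(fps_m[sm], p_pos_c[sc], spec.t_buf, td)
        pri_c = _pair_probs_one_direction(fps_c[sc], p_pos_m[sm], spec.t_buf, td)
        # pri_c is indexed [color, motion]; transpose to [motion, color]
        joint = spec.p_m_first * pri_m + (1 - spec.p_m_first) * pri_c.T
        joint = np.clip(joint, 0.0, None)
        joint /= max(joint.sum(), 1e-300)
        rows.append(
            {
                "s_m": sm,
                "s_c": sc,
                "t_dur": td,
                "p_pp": joint[0, 0],
                "p_pn": joint[0, 1],
                "p_np": joint[1, 0],
                "p_nn": joint[1, 1],
                "p_m_pos": joint[0].sum(),
                "p_c_pos": joint[:, 0].sum(),
            }
        )
    return pd.DataFrame(rows)


def variable_duration_negloglik(
    trials: pd.DataFrame,
    spec: BufferModelSpec,
    cfg: SolverConfig = DUR_SOLVER,
) -> float:
    """Negative log-likelihood of the four choice pairs across durations."""
    if "t_dur" not in trials.columns:
        raise ValueError("variable-duration likelihood requires a t_dur column")
    if float(trials["t_dur"].max()) > cfg.t_max + 1e-9:
        raise ValueError(
            f"durations up to {trials['t_dur'].max()} exceed the solver "
            f"horizon {cfg.t_max}"
        )
    probs = choice_prob_table(spec, trials, cfg)
    counts = (
        trials.groupby(["s_m", "s_c", "t_dur", "R_m", "R_c"]).size().reset_index(name="n")
    )
    key = {(1, 1): "p_pp", (1, -1): "p_pn", (-1, 1): "p_np", (-1, -1): "p_nn"}
    counts["pair"] = [key[(rm, rc)] for rm, rc in zip(counts["R_m"], counts["R_c"])]
    merged = counts.merge(probs, on=["s_m", "s_c", "t_dur"], how="left", validate="m:1")
    p = merged[["p_pp", "p_pn", "p_np", "p_nn"]].to_numpy()[
        np.arange(len(merged)), merged["pair"].map({"p_pp": 0, "p_pn": 1, "p_np": 2, "p_nn": 3})
    ]
    return float(-np.sum(merged["n"].to_numpy() * np.log(np.maximum(p, LIK_FLOOR))))


def default_buffer_grid() -> np.ndarray:
    """Buffer-capacity grid (s): 0 to 240 ms in 40 ms steps, then 120 ms
    steps up to 1200 ms."""
    fine = np.arange(0, 0.241, 0.040)
    coarse = np.arange(0.360, 1.201, 0.120)
    return np.round(np.concatenate([fine, coarse]), 4)


def _pack(spec: BufferModelSpec) -> np.ndarray:
    vec = []
    for p in (spec.motion, spec.color):
        vec.extend([p.kappa, p.s0, p.bound.u, p.bound.g, p.bound.d])
    vec.append(spec.p_m_first)
    return np.array(vec)


def _unpack(vec: np.ndarray, t_buf: float) -> BufferModelSpec:
    def dim(v, label):
        kappa, s0, u, g, d = v
        return DDMParams(
            kappa=max(kappa, 1e-3),
            s0=float(np.clip(s0, -0.99, 0.99)),
            bound=BoundSpec(form="clipped_exp", u=max(u, 1e-3), g=max(g, 0.0), d=max(d, 1e-3)),
            dimension_label=label,
        )

    return BufferModelSpec(
        t_buf=t_buf,
        p_m_first=float(np.clip(vec[10], 0.0, 1.0)),
        motion=dim(vec[0:5], "motion"),
        color=dim(vec[5:10], "color"),
    )


def profile_buffer_grid(
    trials: pd.DataFrame,
    grid: np.ndarray | None = None,
    seed: int = 0,
    start: BufferModelSpec | None = None,
    cfg: SolverConfig = DUR_SOLVER,
    maxfev: int = 200,
) -> tuple[pd.DataFrame, float]:
    """Profile likelihood over a grid of buffer capacities.

    At each grid value of t_buf the remaining parameters (two diffusions
    and p_m_first) are refit by Nelder-Mead from the ``start`` spec (a
    common starting point for every grid value, so no capacity is favored
    by initialization).  Returns (profile table, argmax capacity in s).
    Grid points where the optimizer fails are recorded and excluded from
    the argmax.
    """
    if grid is None:
        grid = default_buffer_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty buffer grid")
    if start is None:
        start = BufferModelSpec(
            t_buf=0.0,
            p_m_first=0.8,
            motion=DDMParams(10.0, 0.0, BoundSpec(form="clipped_exp", u=0.8, g=0.3, d=0.5), "motion"),
            color=DDMParams(10.0, 0.0, BoundSpec(form="clipped_exp", u=0.8, g=0.3, d=0.5), "color"),
        )
    x0 = _pack(start)
    rows = []
    x_prev = None
    for t_buf in grid:
        def nll_of(vec, t_buf=t_buf):
            try:
                return variable_duration_negloglik(trials, _unpack(vec, t_buf), cfg)
            except (ValueError, RuntimeError):
                return 1e12

        # every grid point starts from the same common point; a second,
        # shorter continuation run from the previous point's optimum
        # keeps the profile smooth in t_buf
        best_res = optimize.minimize(
            nll_of, x0, method="Nelder-Mead",
            options={"maxfev": maxfev, "xatol": 1e-3, "fatol": 1e-3},
        )
        if x_prev is not None:
            res2 = optimize.minimize(
                nll_of, x_prev, method="Nelder-Mead",
                options={"maxfev": maxfev // 2, "xatol": 1e-3, "fatol": 1e-3},
            )
            if res2.fun < best_res.fun:
                best_res = res2
        ok = np.isfinite(best_res.fun) and best_res.fun < 1e11
        if ok:
            x_prev = best_res.x
        rows.append({"t_buf": t_buf, "nll": float(best_res.fun), "converged": bool(ok)})
    profile = pd.DataFrame(rows)
    valid = profile[profile["converged"]]
    if valid.empty:
        raise RuntimeError("optimizer failed at every buffer-grid point")
    best = float(valid.loc[valid["nll"].idxmin(), "t_buf"])
    return profile, best
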