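"""Same/different double-decision with a binary report.

Two patches of random dots move up or down; the observer reports whether
the dominant directions are the same or different.  Each patch drives a
proportional-rate drift-diffusion with flat (non-collapsing) bounds; the
same/different response is the comparison of the two direction
decisions.  The 1D (single patch, up/down report) and 2D tasks are fit
jointly, sharing the sensitivity kappa and the up/down bias, with
separate bound heights and non-decision times per task.  The 2D decision
time is the sum (serial) or max (parallel) of the two patch decision
times; correct-trial mean RTs are computed assuming a negligible
contribution of double errors.

The fit maximizes binomial choice likelihood plus Gaussian likelihood of
the per-condition mean RTs (standard errors taken from the data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .ddm_core import BoundSpec, DDMParams, SolverConfig, first_passage_solve
from .synthetic_data import _child_seed, _euler_free

__all__ = [
    "SameDiffSpec",
    "samediff_map",
    "fit_samediff_joint",
    "predict_samediff",
    "simulate_samediff_trials",
]

SD_SOLVER = SolverConfig(dt=5e-3, t_max=5.0, n_grid=96)

_UPDOWN = {"up": 1, "down": -1, 1: 1, -1: -1}


@dataclass(frozen=True)
class SameDiffSpec:
    """Shared-sensitivity model of the 1D direction and 2D same/different
    tasks: flat bounds b0_1d / b0_2d and mean non-decision times tnd_1d /
    tnd_2d; rule is how the two patch decision times combine in 2D."""

    kappa_m: float
    s_m0: float
    b0_1d: float
    b0_2d: float
    tnd_1d: float
    tnd_2d: float
    rule: str = "serial"

    def __post_init__(self) -> None:
        if self.b0_1d <= 0 or self.b0_2d <= 0:
            raise ValueError("bound heights must be > 0")
        if self.rule not in ("serial", "parallel"):
            raise ValueError(f"rule must be serial|parallel, got {self.rule!r}")

    def dim_params(self, task: str) -> DDMParams:
        b0 = self.b0_1d if task == "1D" else self.b0_2d
        return DDMParams(
            kappa=self.kappa_m, s0=self.s_m0, bound=BoundSpec.flat(b0),
            dimension_label="motion",
        )


def samediff_map(r_left, r_right) -> str:
    """Map two up/down direction decisions to the binary report."""
    a, b = _UPDOWN[r_left], _UPDOWN[r_right]
    return "same" if a == b else "different"


def _patch_stats(spec: SameDiffSpec, task: str, levels: np.ndarray, cfg: SolverConfig):
    """Per signed coherence: P(correct direction), decision-time density
    of the correct choice (normalized), and the shared time grid."""
    params = spec.dim_params(task)
    out = {}
    for s in levels:
        fp = first_passage_solve(params, float(s), cfg)
        p_up = fp.prob_upper()
        p_up = p_up / max(p_up + fp.prob_lower(), 1e-12)
        if s >= 0:
            p_corr, f = p_up, fp.f_upper
        else:
            p_corr, f = 1.0 - p_up, fp.f_lower
        mass = np.sum(f) * fp.dt
        dens = f / max(mass, 1e-300)
        out[float(s)] = (p_corr, dens)
    return out


def predict_samediff(
    spec: SameDiffSpec,
    conds_1d: np.ndarray,
    conds_2d: pd.DataFrame,
    cfg: SolverConfig = SD_SOLVER,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Model predictions for the 1D and 2D condition tables.

    conds_1d: signed coherences of the single-patch task.
    conds_2d: DataFrame with columns s_left, s_right (signed).
    Returns (pred_1d, pred_2d) with per-condition P(correct) and the
    predicted correct-trial mean RT.
    """
    times = cfg.times
    dt = cfg.dt
    stats_1d = _patch_stats(spec, "1D", np.unique(conds_1d), cfg)
    rows = [
        {"s": s, "p_correct": stats_1d[float(s)][0],
         "mean_rt": float(np.sum(times * stats_1d[float(s)][1]) * dt) + spec.tnd_1d}
        for s in np.unique(conds_1d)
    ]
    pred_1d = pd.DataFrame(rows)

    levels_2d = np.unique(np.concatenate([conds_2d["s_left"], conds_2d["s_right"]]))
    stats_2d = _patch_stats(spec, "2D", levels_2d, cfg)
    rows = []
    for sl, sr in conds_2d[["s_left", "s_right"]].drop_duplicates().itertuples(index=False):
        p1, f1 = stats_2d[float(sl)]
        p2, f2 = stats_2d[float(sr)]
        p_correct = p1 * p2 + (1 - p1) * (1 - p2)
        # correct-trial decision time, neglecting double errors: both
        # patches resolve correctly, with their conditional densities
        if spec.rule == "serial":
            n = len(times)
            conv = np.fft.irfft(
                np.fft.rfft(f1, 2 * n) * np.fft.rfft(f2, 2 * n), 2 * n
            )[:n] * dt
            dens = conv
        else:
            F1 = np.cumsum(f1) * dt
            F2 = np.cumsum(f2) * dt
            dens = f1 * (F2 - 0.5 * f2 * dt) + f2 * (F1 - 0.5 * f1 * dt)
        mass = max(np.sum(dens) * dt, 1e-300)
        mean_t = float(np.sum(times * dens) * dt / mass)
        rows.append(
            {"s_left": sl, "s_right": sr, "p_correct": p_correct,
             "mean_rt": mean_t + spec.tnd_2d}
        )
    return pred_1d, pd.DataFrame(rows)


def _summaries(trials_1d: pd.DataFrame, trials_2d: pd.DataFrame):
    t1 = trials_1d.copy()
    t1["correct"] = np.sign(t1["s"]) == np.sign(t1["R"])
    g1 = t1.groupby("s").agg(
        n=("correct", "size"), k=("correct", "sum"),
    )
    rt1 = t1[t1["correct"]].groupby("s")["rt"].agg(["mean", "sem", "size"])
    t2 = trials_2d.copy()
    truth = np.where(np.sign(t2["s_left"]) == np.sign(t2["s_right"]), 1, -1)
    t2["correct"] = t2["R_sd"].to_numpy() == truth
    g2 = t2.groupby(["s_left", "s_right"]).agg(n=("correct", "size"), k=("correct", "sum"))
    rt2 = t2[t2["correct"]].groupby(["s_left", "s_right"])["rt"].agg(["mean", "sem", "size"])
    return g1, rt1, g2, rt2


def fit_samediff_joint(
    trials_1d: pd.DataFrame,
    trials_2d: pd.DataFrame,
    rule: str,
    cfg: SolverConfig = SD_SOLVER,
    maxfev: int = 400,
    x0: SameDiffSpec | None = None,
) -> tuple[SameDiffSpec, float]:
    """Joint maximum-likelihood fit of the 1D and 2D tasks.

    trials_1d columns: s (signed coherence, positive = up), R (+1 up /
    -1 down), rt.  trials_2d columns: s_left, s_right, R_sd (+1 same /
    -1 different), rt.  Returns (spec, joint log-likelihood): binomial
    choice likelihood plus Gaussian likelihood of correct-trial mean RTs.
    """
    for df, cols in ((trials_1d, ("s", "R", "rt")), (trials_2d, ("s_left", "s_right", "R_sd", "rt"))):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns {missing}")
    g1, rt1, g2, rt2 = _summaries(trials_1d, trials_2d)
    if rt1["mean"].isna().any() or rt2["mean"].isna().any():
        raise ValueError("a condition cell has no correct trials")
    conds_1d = g1.index.to_numpy(dtype=float)
    conds_2d = g2.reset_index()[["s_left", "s_right"]]

    def loglik(vec) -> float:
        kappa, s0, b1, b2, t1_, t2_ = vec
        try:
            spec = SameDiffSpec(
                kappa_m=max(kappa, 1e-3), s_m0=float(np.clip(s0, -0.5, 0.5)),
                b0_1d=max(b1, 0.05), b0_2d=max(b2, 0.05),
                tnd_1d=max(t1_, 0.0), tnd_2d=max(t2_, 0.0), rule=rule,
            )
            p1, p2 = predict_samediff(spec, conds_1d, conds_2d, cfg)
        except (ValueError, RuntimeError):
            return -1e12
        ll = 0.0
        p1 = p1.set_index("s")
        for s, row in g1.iterrows():
            p = np.clip(p1.loc[s, "p_correct"], 1e-9, 1 - 1e-9)
            ll += row["k"] * np.log(p) + (row["n"] - row["k"]) * np.log(1 - p)
        for s, row in rt1.iterrows():
            se = max(row["sem"], 1e-3)
            ll += -0.5 * ((row["mean"] - p1.loc[s, "mean_rt"]) / se) ** 2 - np.log(se)
        p2 = p2.set_index(["s_left", "s_right"])
        for key, row in g2.iterrows():
            p = np.clip(p2.loc[key, "p_correct"], 1e-9, 1 - 1e-9)
            ll += row["k"] * np.log(p) + (row["n"] - row["k"]) * np.log(1 - p)
        for key, row in rt2.iterrows():
            se = max(row["sem"], 1e-3)
            ll += -0.5 * ((row["mean"] - p2.loc[key, "mean_rt"]) / se) ** 2 - np.log(se)
        return float(ll)

    if x0 is None:
        x0_vec = np.array([8.0, 0.0, 0.7, 0.7, 0.3, 0.35])
    else:
        x0_vec = np.array([x0.kappa_m, x0.s_m0, x0.b0_1d, x0.b0_2d, x0.tnd_1d, x0.tnd_2d])
    res = optimize.minimize(
        lambda v: -loglik(v), x0_vec, method="Nelder-Mead",
        options={"maxfev": maxfev, "xatol": 1e-3, "fatol": 1e-3},
    )
    kappa, s0, b1, b2, t1_, t2_ = res.x
    spec = SameDiffSpec(
        kappa_m=max(kappa, 1e-3), s_m0=float(np.clip(s0, -0.5, 0.5)),
        b0_1d=max(b1, 0.05), b0_2d=max(b2, 0.05),
        tnd_1d=max(t1_, 0.0), tnd_2d=max(t2_, 0.0), rule=rule,
    )
    return spec, float(-res.fun)


def simulate_samediff_trials(
    spec: SameDiffSpec,
    levels: tuple[float, ...],
    n_1d: int,
    n_2d: int,
    seed: int = 0,
    sim_dt: float = 2.5e-4,
    horizon: float = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the 1D direction task and the 2D same/different task.

    levels are unsigned coherences; signed conditions are +/- each level
    per patch.  n_1d / n_2d are trials per signed condition (1D) and per
    signed condition pair (2D).
    """
    rng = np.random.default_rng(seed)
    ss = np.random.SeedSequence(seed + 1)
    signed = np.array(sorted([-l for l in levels] + list(levels)))
    p1d = spec.dim_params("1D")
    p2d = spec.dim_params("2D")

    conds = np.repeat(signed, n_1d)
    mu = p1d.kappa * (conds + p1d.s0)
    n_steps = int(round(horizon / sim_dt))
    bound = np.full(n_steps + 1, p1d.bound.u)
    side, tdec, _ = _euler_free(mu, bound, sim_dt, _child_seed(ss))
    t1 = pd.DataFrame({"s": conds, "R": side, "rt": tdec + spec.tnd_1d})

    pairs = [(sl, sr) for sl in signed for sr in signed]
    sl = np.repeat([p[0] for p in pairs], n_2d)
    sr = np.repeat([p[1] for p in pairs], n_2d)
    bound2 = np.full(n_steps + 1, p2d.bound.u)
    side_l, t_l, _ = _euler_free(p2d.kappa * (sl + p2d.s0), bound2, sim_dt, _child_seed(ss))
    side_r, t_r, _ = _euler_free(p2d.kappa * (sr + p2d.s0), bound2, sim_dt, _child_seed(ss))
    t_dec = t_l + t_r if spec.rule == "serial" else np.maximum(t_l, t_r)
    r_sd = np.where(side_l == side_r, 1, -1)
    t2 = pd.DataFrame(
        {"s_left": sl, "s_right": sr, "R_sd": r_sd, "rt": t_dec + spec.tnd_2d}
    )
    return t1, t2
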