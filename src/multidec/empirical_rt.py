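"""Empirical decomposition of double-decision RT distributions.

Instead of diffusion models, the observed double-decision RT
distributions are explained as the serial (convolution) or parallel
(max) combination of latent one-dimensional decision-time distributions,
one gamma per (signed coherence, choice) cell of each dimension, plus a
gamma non-decision time per choice pair (Rm, Rc).  The participant's
choices are taken as ground truth; only RT is modeled.  For robustness,
only (strengths x choices) cells with more than 10 trials enter the fit.

A simplified variant (used for the same/different task) pools signed
coherences to unsigned levels, uses correct trials only, and fits a
single non-decision gamma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "GammaSpec",
    "GammaDecomposition",
    "fit_gamma_decomposition",
    "gamma_rt2d_density",
    "simulate_from_gammas",
    "EMP_GRID",
]

LIK_FLOOR = 1e-10
MIN_TRIALS_PER_CELL = 10  # cells need strictly more than this

#: shared time grid for the latent-density compositions
EMP_GRID = (5e-3, 5.0)  # (dt, t_max)


@dataclass(frozen=True)
class GammaSpec:
    """Gamma distribution parameterized by mean and SD (both seconds)."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.sd <= 0:
            raise ValueError(f"gamma mean and sd must be > 0, got {self}")

    @property
    def shape(self) -> float:
        return (self.mean / self.sd) ** 2

    @property
    def scale(self) -> float:
        return self.sd**2 / self.mean

    def density(self, times: np.ndarray) -> np.ndarray:
        return stats.gamma.pdf(times, a=self.shape, scale=self.scale)

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.gamma(self.shape, self.scale, size=n)


@dataclass
class GammaDecomposition:
    """Fitted latent gammas.

    decision   : {(dim, s_key, choice) -> GammaSpec}; dim in {"m", "c"};
                 s_key is the signed coherence (unsigned level in the
                 pooled variant, with choice fixed to +1).
    nondecision: {(Rm, Rc) -> GammaSpec}, or {("all",) -> GammaSpec} for
                 the single-gamma variant.
    """

    decision: dict
    nondecision: dict
    rule: str
    pooled: bool = False
    loglik: float = np.nan
    diagnostics: dict = field(default_factory=dict)


def _grid(dt: float = EMP_GRID[0], t_max: float = EMP_GRID[1]) -> np.ndarray:
    return np.arange(int(round(t_max / dt)) + 1) * dt


def _cell_keys(trials: pd.DataFrame, pooled: bool):
    """Map each trial to its motion/color/nondecision cell keys, after
    excluding joint cells with too few trials."""
    df = trials.copy()
    if pooled:
        df["_km"] = list(zip(["m"] * len(df), df["s_m"].abs(), [1] * len(df)))
        df["_kc"] = list(zip(["c"] * len(df), df["s_c"].abs(), [1] * len(df)))
        df["_knd"] = [("all",)] * len(df)
        df["s_m_abs"] = df["s_m"].abs()
        df["s_c_abs"] = df["s_c"].abs()
        joint = ["s_m_abs", "s_c_abs"]
    else:
        df["_km"] = list(zip(["m"] * len(df), df["s_m"], df["R_m"]))
        df["_kc"] = list(zip(["c"] * len(df), df["s_c"], df["R_c"]))
        df["_knd"] = list(zip(df["R_m"], df["R_c"]))
        joint = ["s_m", "s_c", "R_m", "R_c"]
    sizes = df.groupby(joint)[joint[0]].transform("size")
    df = df[sizes > MIN_TRIALS_PER_CELL]
    if df.empty:
        raise ValueError(
            f"no (strength x choice) cell has more than {MIN_TRIALS_PER_CELL} trials"
        )
    return df


def _pack_cells(df: pd.DataFrame):
    keys_m = sorted(df["_km"].unique())
    keys_c = sorted(df["_kc"].unique())
    keys_nd = sorted(df["_knd"].unique())
    return keys_m, keys_c, keys_nd


def _compose_cell_density(gm, gc, gnd, rule, times, fft_cache):
    dt = times[1] - times[0]
    nt = len(times)
    nfft = 2 * nt

    def dens_fft(spec):
        key = (round(spec.mean, 10), round(spec.sd, 10))
        if key not in fft_cache:
            d = spec.density(times)
            d[0] = 0.0  # the pole at t=0 (shape < 1) carries no mass
            d[~np.isfinite(d)] = 0.0
            m = d.sum() * dt
            if m <= 1e-300:
                d = np.zeros_like(d)
                d[1] = 1.0 / dt  # degenerate: all mass in the first bin
            else:
                d = d / m  # renormalize truncation to the grid
            fft_cache[key] = (d, np.fft.rfft(d, nfft))
        return fft_cache[key]

    dm, fm = dens_fft(gm)
    dc, fc = dens_fft(gc)
    dnd, fnd = dens_fft(gnd)
    if rule == "serial":
        out = np.fft.irfft(fm * fc * fnd, nfft)[:nt] * dt * dt
    else:
        cm = np.cumsum(dm) * dt
        cc = np.cumsum(dc) * dt
        pair = dm * (cc - 0.5 * dc * dt) + dc * (cm - 0.5 * dm * dt)
        out = np.fft.irfft(np.fft.rfft(pair, nfft) * fnd, nfft)[:nt] * dt
    np.maximum(out, 0.0, out=out)
    return out


def _nll_given_specs(df, spec_of, rule, times, fft_cache=None):
    dt = times[1] - times[0]
    nt = len(times)
    if fft_cache is None:
        fft_cache = {}
    elif len(fft_cache) > 4000:
        fft_cache.clear()
    nll = 0.0
    for (km, kc, knd), sub in df.groupby(["_km", "_kc", "_knd"], sort=False):
        dens = _compose_cell_density(
            spec_of[km], spec_of[kc], spec_of[knd], rule, times, fft_cache
        )
        pos = sub["rt"].to_numpy() / dt
        k = np.clip(np.floor(pos).astype(int), 0, nt - 2)
        frac = np.clip(pos - k, 0.0, 1.0)
        lik = dens[k] * (1 - frac) + dens[k + 1] * frac
        nll -= np.sum(np.log(np.maximum(lik, LIK_FLOOR)))
    return float(nll)


def _initial_specs(df, keys_m, keys_c, keys_nd):
    """Moment-based initialization: a fifth of the grand-mean RT for the
    non-decision time, the remainder split between the two dimensions."""
    out = {}
    grand = df["rt"].mean()
    nd0 = max(0.2 * grand, 0.05)
    for keys, col in ((keys_m, "_km"), (keys_c, "_kc")):
        for key in keys:
            sub = df[df[col] == key]["rt"]
            mean = max((sub.mean() - nd0) / 2.0, 0.05)
            sd = max(np.sqrt(max(sub.var(), 1e-4) / 3.0), 0.02)
            out[key] = GammaSpec(mean, sd)
    for key in keys_nd:
        out[key] = GammaSpec(nd0, max(0.3 * nd0, 0.02))
    return out


def fit_gamma_decomposition(
    trials: pd.DataFrame,
    rule: str,
    pooled: bool = False,
    x0: GammaDecomposition | None = None,
    maxiter: int = 200,
    dt: float = EMP_GRID[0],
    t_max: float = EMP_GRID[1],
) -> GammaDecomposition:
    """Maximum-likelihood latent gamma decomposition of 2D RTs.

    rule : "serial" (decision time = sum of latents) or "parallel" (max).
    pooled : the simplified variant (unsigned strengths, correct trials
        only, single non-decision gamma); the caller supplies
        correct-only trials.
    x0 : optional warm-start decomposition (cells matched by key).

    Optimization is bounded L-BFGS-B over the log means and log SDs of
    all cells, from a moment-based initialization.
    """
    if rule not in ("serial", "parallel"):
        raise ValueError(f"rule must be serial|parallel, got {rule!r}")
    # size the grid to the data: the composed densities are evaluated at
    # observed RTs only, so the horizon need not exceed the slowest trial
    t_max = min(t_max, float(np.ceil((trials["rt"].max() + 0.5) / 0.25) * 0.25))
    times = _grid(dt, t_max)
    df = _cell_keys(trials, pooled)
    keys_m, keys_c, keys_nd = _pack_cells(df)
    all_keys = list(keys_m) + list(keys_c) + list(keys_nd)
    init = _initial_specs(df, keys_m, keys_c, keys_nd)
    if x0 is not None:
        merged = {**x0.decision, **x0.nondecision}
        for key in all_keys:
            if key in merged:
                init[key] = merged[key]

    x_init = np.concatenate(
        [[np.log(init[k].mean), np.log(init[k].sd)] for k in all_keys]
    )
    bounds = [(np.log(5e-3), np.log(4.0)), (np.log(5e-3), np.log(2.0))] * len(all_keys)

    def specs_of(x):
        return {
            key: GammaSpec(np.exp(x[2 * i]), np.exp(x[2 * i + 1]))
            for i, key in enumerate(all_keys)
        }

    fft_cache: dict = {}

    def objective(x):
        try:
            val = _nll_given_specs(df, specs_of(x), rule, times, fft_cache)
        except (ValueError, FloatingPointError):
            return 1e12
        return val if np.isfinite(val) else 1e12

    res = optimize.minimize(
        objective, x_init, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-8},
    )
    specs = specs_of(res.x)
    decomp = GammaDecomposition(
        decision={k: specs[k] for k in list(keys_m) + list(keys_c)},
        nondecision={k: specs[k] for k in keys_nd},
        rule=rule,
        pooled=pooled,
        loglik=-float(res.fun),
        diagnostics={"n_cells": len(all_keys), "n_trials": len(df),
                     "converged": bool(res.success), "nit": int(res.nit)},
    )
    return decomp


def gamma_rt2d_density(
    decomp: GammaDecomposition,
    condition: tuple,
    dt: float = EMP_GRID[0],
    t_max: float = EMP_GRID[1],
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted 2D RT density for a condition.

    condition = (s_m, s_c, R_m, R_c), or (|s_m|, |s_c|) for the pooled
    variant.  Returns (times, density); raises KeyError for cells absent
    from the decomposition.
    """
    times = _grid(dt, t_max)
    if decomp.pooled:
        sm, sc = condition[:2]
        km, kc, knd = ("m", abs(sm), 1), ("c", abs(sc), 1), ("all",)
    else:
        sm, sc, rm, rc = condition
        km, kc, knd = ("m", sm, rm), ("c", sc, rc), (rm, rc)
    for key in (km, kc):
        if key not in decomp.decision:
            raise KeyError(f"cell {key} not present in the decomposition")
    if knd not in decomp.nondecision:
        raise KeyError(f"non-decision cell {knd} not present")
    dens = _compose_cell_density(
        decomp.decision[km], decomp.decision[kc], decomp.nondecision[knd],
        decomp.rule, times, {},
    )
    return times, dens


def simulate_from_gammas(
    choice_p_m: dict,
    choice_p_c: dict,
    gammas: dict,
    nd_gammas: dict,
    rule: str,
    n_per_cond: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate 2D free-response trials from known latent gammas.

    choice_p_m / choice_p_c map signed coherence -> P(positive choice);
    gammas maps (dim, s, choice) -> GammaSpec; nd_gammas maps (Rm, Rc)
    -> GammaSpec.  Used by the rule-recovery harnesses.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sm, p_m in choice_p_m.items():
        for sc, p_c in choice_p_c.items():
            rm = np.where(rng.random(n_per_cond) < p_m, 1, -1)
            rc = np.where(rng.random(n_per_cond) < p_c, 1, -1)
            tm = np.empty(n_per_cond)
            tc = np.empty(n_per_cond)
            tnd = np.empty(n_per_cond)
            for r in (1, -1):
                mask = rm == r
                tm[mask] = gammas[("m", sm, r)].draw(rng, int(mask.sum()))
                mask = rc == r
                tc[mask] = gammas[("c", sc, r)].draw(rng, int(mask.sum()))
            for r1 in (1, -1):
                for r2 in (1, -1):
                    mask = (rm == r1) & (rc == r2)
                    tnd[mask] = nd_gammas[(r1, r2)].draw(rng, int(mask.sum()))
            t2d = tm + tc if rule == "serial" else np.maximum(tm, tc)
            for i in range(n_per_cond):
                rows.append((sm, sc, rm[i], rc[i], t2d[i] + tnd[i]))
    df = pd.DataFrame(rows, columns=["s_m", "s_c", "R_m", "R_c", "rt"])
    df["subject"] = "sim"
    df["task"] = "2D-RT"
    return df
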