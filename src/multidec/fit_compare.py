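"""Likelihood fitting and serial-vs-parallel model comparison.

The double-decision likelihood is over (Rm, Rc, RT) triples: the two 1D
first-passage problems are solved per signed coherence, composed under
the serial (convolution) or parallel (max) rule, convolved with the
non-decision density, and evaluated at each trial's RT by linear
interpolation on the density grid.

Both rules carry the same 12 parameters (5 per stimulus dimension plus
the non-decision mean and SD), so models are compared directly by their
(held-out) log-likelihoods, reported as a log10 Bayes factor.  The
fit-on-strongest/predict-rest protocol fits all parameters on the
conditions where at least one dimension is at its maximum strength and
evaluates the likelihood of the remaining conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm_api
from scipy import optimize

from .combine import NonDecisionSpec
from .ddm_core import BoundSpec, DDMParams, SolverConfig, first_passage_solve

__all__ = [
    "FitResult",
    "SplitSpec",
    "LogisticInteractionResult",
    "FIT_SOLVER",
    "PARAM_NAMES",
    "DEFAULT_BOUNDS",
    "double_decision_negloglik",
    "fit_mle",
    "make_strongest_split",
    "predict_rt_densities",
    "split_fit_predict",
    "log10_bayes_factor",
    "interaction_logistic_bic",
    "pack_params",
    "unpack_params",
]

logger = logging.getLogger(__name__)

LIK_FLOOR = 1e-10

#: solver used inside likelihood evaluations; coarser than the desk-scale
#: default but within the grid-convergence envelope for smooth densities
FIT_SOLVER = SolverConfig(dt=5e-3, t_max=5.0, n_grid=96)

PARAM_NAMES = (
    "kappa_m", "s0_m", "u_m", "a_m", "d_m",
    "kappa_c", "s0_c", "u_c", "a_c", "d_c",
    "mu_nd", "sigma_nd",
)

DEFAULT_BOUNDS = {
    "kappa": (0.5, 40.0),
    "s0": (-0.3, 0.3),
    "u": (0.3, 3.0),
    "a": (0.0, 10.0),
    "d": (0.1, 5.0),
    "mu_nd": (0.05, 1.0),
    "sigma_nd": (0.005, 0.3),
}


def pack_params(motion: DDMParams, color: DDMParams, nd: NonDecisionSpec) -> np.ndarray:
    return np.array(
        [
            motion.kappa, motion.s0, motion.bound.u, motion.bound.a, motion.bound.d,
            color.kappa, color.s0, color.bound.u, color.bound.a, color.bound.d,
            nd.mu_nd, nd.sigma_nd,
        ]
    )


def unpack_params(vec: np.ndarray) -> dict:
    def dim(v, label):
        kappa, s0, u, a, d = v
        return DDMParams(
            kappa=max(float(kappa), 1e-3),
            s0=float(np.clip(s0, -0.99, 0.99)),
            bound=BoundSpec(form="logistic", u=max(float(u), 1e-3),
                            a=max(float(a), 0.0), d=max(float(d), 1e-3)),
            dimension_label=label,
        )

    return {
        "motion": dim(vec[0:5], "motion"),
        "color": dim(vec[5:10], "color"),
        "nd": NonDecisionSpec(max(float(vec[10]), 0.0), max(float(vec[11]), 0.0)),
    }


def _bounds_vector() -> tuple[np.ndarray, np.ndarray]:
    lo, hi = [], []
    for name in PARAM_NAMES:
        key = name.rsplit("_", 1)[0] if name not in ("mu_nd", "sigma_nd") else name
        b = DEFAULT_BOUNDS[key]
        lo.append(b[0])
        hi.append(b[1])
    return np.array(lo), np.array(hi)


@dataclass
class SplitSpec:
    """Masks over the signed design grid for fit and prediction sets."""

    fit_conditions: pd.DataFrame
    predict_conditions: pd.DataFrame

    def __post_init__(self) -> None:
        f = set(map(tuple, self.fit_conditions[["s_m", "s_c"]].to_numpy()))
        p = set(map(tuple, self.predict_conditions[["s_m", "s_c"]].to_numpy()))
        if f & p:
            raise ValueError("fit and predict condition sets overlap")


@dataclass
class FitResult:
    """Fitted double-decision model (12 parameters) and diagnostics."""

    rule: str
    params: dict  # motion: DDMParams, color: DDMParams, nd: NonDecisionSpec
    vector: np.ndarray
    nll: float
    n_trials: int
    data_hash: int
    holdout_nll: float | None = None
    holdout_n: int | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def loglik(self) -> float:
        return -self.nll

    @property
    def holdout_loglik(self) -> float | None:
        return None if self.holdout_nll is None else -self.holdout_nll


def _data_hash(trials: pd.DataFrame) -> int:
    cols = [c for c in ("s_m", "s_c", "R_m", "R_c", "rt") if c in trials.columns]
    return int(pd.util.hash_pandas_object(trials[cols], index=False).sum() % (2**63))


def predict_rt_densities(
    params: dict,
    rule: str,
    sm_levels: np.ndarray,
    sc_levels: np.ndarray,
    cfg: SolverConfig = FIT_SOLVER,
) -> tuple[np.ndarray, np.ndarray]:
    """Composed RT densities for all condition/choice-pair combinations.

    Returns (times, dens) with dens shaped (n_sm, n_sc, 2, 2, n_t);
    choice axes are ordered (+1, -1) for motion then color.
    """
    if rule not in ("serial", "parallel"):
        raise ValueError(f"rule must be serial|parallel, got {rule!r}")
    times = cfg.times
    nt = len(times)
    dt = cfg.dt

    def solve_dim(p: DDMParams, levels: np.ndarray) -> np.ndarray:
        out = np.empty((len(levels), 2, nt))
        for i, s in enumerate(levels):
            fp = first_passage_solve(p, float(s), cfg)
            out[i, 0] = fp.f_upper
            out[i, 1] = fp.f_lower
        return out

    am = solve_dim(params["motion"], sm_levels)  # (n_sm, 2, nt)
    ac = solve_dim(params["color"], sc_levels)  # (n_sc, 2, nt)
    nd_dens = params["nd"].density(times)

    nfft = 2 * nt
    fnd = np.fft.rfft(nd_dens, nfft)
    if rule == "serial":
        fm = np.fft.rfft(am, nfft, axis=-1)
        fc = np.fft.rfft(ac, nfft, axis=-1)
        prod = (
            fm[:, None, :, None, :]
            * fc[None, :, None, :, :]
            * fnd[None, None, None, None, :]
        )
        dens = np.fft.irfft(prod, nfft, axis=-1)[..., :nt] * dt * dt
    else:
        cm = np.cumsum(am, axis=-1) * dt
        cc = np.cumsum(ac, axis=-1) * dt
        # f_m(t) F_c(t^-) + f_c(t) F_m(t^-) per choice pair
        pair = am[:, None, :, None, :] * (cc - 0.5 * ac * dt)[None, :, None, :, :] + ac[
            None, :, None, :, :
        ] * (cm - 0.5 * am * dt)[:, None, :, None, :]
        fpair = np.fft.rfft(pair, nfft, axis=-1)
        dens = np.fft.irfft(fpair * fnd, nfft, axis=-1)[..., :nt] * dt
    np.maximum(dens, 0.0, out=dens)
    return times, dens


def _trial_indices(trials: pd.DataFrame, sm_levels, sc_levels):
    i_sm = np.searchsorted(sm_levels, trials["s_m"].to_numpy())
    i_sc = np.searchsorted(sc_levels, trials["s_c"].to_numpy())
    i_rm = np.where(trials["R_m"].to_numpy() == 1, 0, 1)
    i_rc = np.where(trials["R_c"].to_numpy() == 1, 0, 1)
    return i_sm, i_sc, i_rm, i_rc


def double_decision_negloglik(
    trials: pd.DataFrame,
    params: dict,
    rule: str,
    cfg: SolverConfig = FIT_SOLVER,
) -> float:
    """-log likelihood of observed (Rm, Rc, RT) under the composed model.

    Densities are floored at 1e-10; trials with RT beyond the solver
    horizon contribute the model's beyond-horizon tail mass for the
    condition (censored contribution, logged at debug level).
    """
    sm_levels = np.sort(trials["s_m"].unique())
    sc_levels = np.sort(trials["s_c"].unique())
    times, dens = predict_rt_densities(params, rule, sm_levels, sc_levels, cfg)
    dt = float(times[1] - times[0])
    nt = len(times)
    i_sm, i_sc, i_rm, i_rc = _trial_indices(trials, sm_levels, sc_levels)
    rt = trials["rt"].to_numpy()

    pos = rt / dt
    k = np.floor(pos).astype(int)
    in_grid = k < nt - 1
    frac = pos - k
    kk = np.clip(k, 0, nt - 2)
    d0 = dens[i_sm, i_sc, i_rm, i_rc, kk]
    d1 = dens[i_sm, i_sc, i_rm, i_rc, kk + 1]
    lik = d0 * (1 - frac) + d1 * frac

    if np.any(~in_grid):
        tail = 1.0 - dens.sum(axis=(2, 3, 4)) * dt  # per condition
        lik = np.where(in_grid, lik, np.maximum(tail[i_sm, i_sc], LIK_FLOOR))
        logger.debug(
            "%d trial(s) beyond the %.2f s horizon entered as censored mass",
            int(np.sum(~in_grid)), times[-1],
        )
    return float(-np.sum(np.log(np.maximum(lik, LIK_FLOOR))))


def fit_mle(
    trials: pd.DataFrame,
    rule: str,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
    seed: int = 0,
    n_starts: int = 8,
    x0: np.ndarray | None = None,
    maxfev: int = 600,
    cfg: SolverConfig = FIT_SOLVER,
    min_trials: int = 50,
) -> FitResult:
    """Maximum-likelihood fit by multi-start bounded Nelder-Mead.

    Starts are a fixed heuristic point (or ``x0`` if given) plus
    seeded quasi-random points inside the bounds; deterministic given
    seed.  Raises RuntimeError if every start fails.
    """
    if len(trials) < min_trials:
        raise ValueError(f"need >= {min_trials} trials, got {len(trials)}")
    lo, hi = bounds if bounds is not None else _bounds_vector()

    def nll_of(vec: np.ndarray) -> float:
        try:
            return double_decision_negloglik(trials, unpack_params(vec), rule, cfg)
        except (ValueError, RuntimeError):
            return 1e12

    rng = np.random.default_rng(seed)
    starts = []
    if x0 is not None:
        starts.append(np.clip(np.asarray(x0, dtype=float), lo, hi))
    else:
        starts.append(
            np.array([10.0, 0.0, 1.0, 1.0, 1.0, 10.0, 0.0, 1.0, 1.0, 1.0, 0.35, 0.08])
        )
    while len(starts) < n_starts:
        starts.append(lo + (hi - lo) * rng.random(len(lo)))

    best = None
    n_fail = 0
    for x_start in starts:
        res = optimize.minimize(
            nll_of, x_start, method="Nelder-Mead",
            bounds=list(zip(lo, hi)),
            options={"maxfev": maxfev, "xatol": 1e-3, "fatol": 1e-3},
        )
        if not np.isfinite(res.fun) or res.fun >= 1e11:
            n_fail += 1
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(
            f"all {len(starts)} optimizer starts failed for the {rule} fit"
        )
    params = unpack_params(best.x)
    return FitResult(
        rule=rule,
        params=params,
        vector=np.asarray(best.x),
        nll=float(best.fun),
        n_trials=len(trials),
        data_hash=_data_hash(trials),
        diagnostics={"n_starts": len(starts), "n_failed": n_fail,
                     "nfev": int(best.nfev), "converged": bool(best.success)},
    )


def make_strongest_split(trials: pd.DataFrame) -> SplitSpec:
    """Fit set: conditions where at least one dimension is at its maximum
    unsigned strength; predict set: the rest."""
    conds = trials[["s_m", "s_c"]].drop_duplicates().reset_index(drop=True)
    max_m = conds["s_m"].abs().max()
    max_c = conds["s_c"].abs().max()
    is_fit = (conds["s_m"].abs() == max_m) | (conds["s_c"].abs() == max_c)
    if not is_fit.any() or is_fit.all():
        raise ValueError("design has no usable maximum-strength split")
    return SplitSpec(
        fit_conditions=conds[is_fit].reset_index(drop=True),
        predict_conditions=conds[~is_fit].reset_index(drop=True),
    )


def split_fit_predict(
    trials: pd.DataFrame,
    rule: str,
    seed: int = 0,
    **fit_kwargs,
) -> FitResult:
    """Fit on the strongest-stimulus conditions; evaluate the held-out
    likelihood of the remaining conditions."""
    split = make_strongest_split(trials)
    fit_keys = set(map(tuple, split.fit_conditions.to_numpy()))
    in_fit = [
        (sm, sc) in fit_keys
        for sm, sc in trials[["s_m", "s_c"]].itertuples(index=False)
    ]
    in_fit = np.asarray(in_fit)
    fit_trials = trials[in_fit]
    pred_trials = trials[~in_fit]
    if pred_trials.empty:
        raise ValueError("empty predict set")
    result = fit_mle(fit_trials, rule, seed=seed, **fit_kwargs)
    result.holdout_nll = double_decision_negloglik(
        pred_trials, result.params, rule, fit_kwargs.get("cfg", FIT_SOLVER)
    )
    result.holdout_n = len(pred_trials)
    result.data_hash = _data_hash(trials)
    result.diagnostics["split"] = split
    return result


def log10_bayes_factor(fit_serial: FitResult, fit_parallel: FitResult) -> float:
    """log10 BF = (LL_serial - LL_parallel) / ln 10; positive favors the
    serial rule.  Uses held-out likelihoods when both fits carry them.
    Both fits must refer to the same data."""
    if fit_serial.data_hash != fit_parallel.data_hash:
        raise ValueError("fits refer to different data sets")
    if fit_serial.holdout_nll is not None and fit_parallel.holdout_nll is not None:
        ll_s, ll_p = -fit_serial.holdout_nll, -fit_parallel.holdout_nll
    else:
        ll_s, ll_p = fit_serial.loglik, fit_parallel.loglik
    return float((ll_s - ll_p) / np.log(10.0))


@dataclass
class LogisticInteractionResult:
    """Nested logistic-regression comparison for choice interference.

    delta_bic = BIC(full) - BIC(reduced); positive values support the
    reduced model without the interaction term (beta3 = 0)."""

    coef_full: np.ndarray
    coef_reduced: np.ndarray
    bic_full: float
    bic_reduced: float
    separation_flag: bool = False

    @property
    def delta_bic(self) -> float:
        return self.bic_full - self.bic_reduced

    @property
    def beta3(self) -> float:
        return float(self.coef_full[-1])


def _fit_logit(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Fit a logistic model; on (quasi-)separation fall back to a weak L2
    penalty while keeping the plain-likelihood BIC."""
    n, k = X.shape
    model = sm_api.Logit(y, X)
    flagged = False
    try:
        with np.errstate(all="ignore"):
            res = model.fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(res.params)) or np.abs(res.params).max() > 1e3:
            raise ValueError("diverged")
        coef = np.asarray(res.params)
        llf = float(res.llf)
    except Exception:
        flagged = True
        with np.errstate(all="ignore"):
            res = model.fit_regularized(alpha=1e-3, L1_wt=0.0, disp=0, maxiter=500)
        coef = np.asarray(res.params)
        llf = float(model.loglike(coef))
    bic = -2.0 * llf + k * np.log(n)
    return coef, bic, flagged


def interaction_logistic_bic(
    trials: pd.DataFrame,
    dimension: str,
    variant: str = "strength",
) -> LogisticInteractionResult:
    """BIC comparison of logistic choice models with and without an
    interaction term.

    variant="strength": within 2D trials, does the unsigned strength of
    the other dimension modulate sensitivity?
        logit p+ = b0 + b1*s + b2*|s_other| + b3*s*|s_other|
    fit per subject; BICs summed over subjects.

    variant="task": single vs double decisions (requires a ``task``
    column with 1D and 2D labels),
        logit p+ = b0 + b1*s + b2*I2D + b3*s*I2D + subject indicators.
    """
    if dimension not in ("motion", "color"):
        raise ValueError(f"dimension must be motion|color, got {dimension!r}")
    s_col, other_col, r_col = (
        ("s_m", "s_c", "R_m") if dimension == "motion" else ("s_c", "s_m", "R_c")
    )
    df = trials.dropna(subset=[r_col]).copy()
    y_all = (df[r_col].to_numpy() == 1).astype(float)

    if variant == "strength":
        bic_f = bic_r = 0.0
        coefs_f = coefs_r = None
        flagged = False
        subjects = df["subject"].unique() if "subject" in df.columns else ["all"]
        for subj in subjects:
            sub = df if subjects[0] == "all" and len(subjects) == 1 else df[df["subject"] == subj]
            y = (sub[r_col].to_numpy() == 1).astype(float)
            s = sub[s_col].to_numpy()
            o = np.abs(sub[other_col].to_numpy())
            X_full = np.column_stack([np.ones_like(s), s, o, s * o])
            X_red = X_full[:, :3]
            cf, bf, fl1 = _fit_logit(y, X_full)
            cr, br, fl2 = _fit_logit(y, X_red)
            bic_f += bf
            bic_r += br
            flagged |= fl1 or fl2
            coefs_f, coefs_r = cf, cr  # last subject's coefficients
        return LogisticInteractionResult(coefs_f, coefs_r, bic_f, bic_r, flagged)

    if variant == "task":
        if "task" not in df.columns:
            raise ValueError("task variant requires a 'task' column")
        s = df[s_col].to_numpy()
        is2d = df["task"].astype(str).str.startswith("2D").to_numpy().astype(float)
        cols = [np.ones_like(s), s, is2d, s * is2d]
        subjects = sorted(df["subject"].unique()) if "subject" in df.columns else []
        for subj in subjects[1:]:
            cols.append((df["subject"] == subj).to_numpy().astype(float))
        X_full = np.column_stack(cols)
        X_red = np.delete(X_full, 3, axis=1)
        cf, bf, fl1 = _fit_logit(y_all, X_full)
        cr, br, fl2 = _fit_logit(y_all, X_red)
        # keep the interaction coefficient last for .beta3
        cf = np.concatenate([np.delete(cf, 3), [cf[3]]])
        return LogisticInteractionResult(cf, cr, bf, br, fl1 or fl2)

    raise ValueError(f"unknown variant {variant!r}")
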