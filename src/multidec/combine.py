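"""Composition of two 1D decision processes into double-decision RTs.

A double decision reports both a motion choice ``Rm`` and a color choice
``Rc``.  Given the first-passage sub-densities of the two 1D processes,
the double-decision time is

* serial rule:   T = Tm + Tc      -> per choice pair, the convolution of
  the motion and color absorption sub-densities;
* parallel rule: T = max(Tm, Tc) -> per choice pair, the "ended-at-t
  times other-ended-before-t" sum, equivalently the derivative of the
  product of the two sub-CDFs.

Non-decision latencies (sensory and motor delays) are modeled as a normal
distribution, truncated at zero and renormalized, and convolved with the
double-decision time density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ddm_core import FirstPassage

__all__ = [
    "RTDensity",
    "NonDecisionSpec",
    "GridError",
    "serial_rt_density",
    "parallel_rt_density",
    "parallel_rt_density_cdf",
    "apply_nondecision",
    "rt_summary",
]

#: choice codes along each axis of RTDensity.dens
CHOICE_CODES = (1, -1)


class GridError(ValueError):
    """Time grids of the two processes do not match."""


@dataclass
class RTDensity:
    """Joint sub-densities of double-decision time per choice pair.

    dens[i, j] is the sub-density over ``times`` for motion choice
    CHOICE_CODES[i] and color choice CHOICE_CODES[j].  The total mass over
    all four pairs is <= 1 and approaches 1 as the horizon grows.
    """

    times: np.ndarray
    dens: np.ndarray  # shape (2, 2, n_t)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def pair_index(self, r_m: int, r_c: int) -> tuple[int, int]:
        return CHOICE_CODES.index(r_m), CHOICE_CODES.index(r_c)

    def pair_density(self, r_m: int, r_c: int) -> np.ndarray:
        i, j = self.pair_index(r_m, r_c)
        return self.dens[i, j]

    def pair_mass(self, r_m: int, r_c: int) -> float:
        return float(np.sum(self.pair_density(r_m, r_c)) * self.dt)

    def total_mass(self) -> float:
        return float(np.sum(self.dens) * self.dt)

    def marginal_motion(self, r_m: int) -> float:
        i = CHOICE_CODES.index(r_m)
        return float(np.sum(self.dens[i]) * self.dt)

    def marginal_color(self, r_c: int) -> float:
        j = CHOICE_CODES.index(r_c)
        return float(np.sum(self.dens[:, j]) * self.dt)

    def tail_mass_deficit(self) -> float:
        """Mass beyond the horizon: 1 - total mass on the grid."""
        return 1.0 - self.total_mass()


@dataclass(frozen=True)
class NonDecisionSpec:
    """Normal non-decision time, truncated at zero and renormalized."""

    mu_nd: float
    sigma_nd: float

    def __post_init__(self) -> None:
        if self.sigma_nd < 0:
            raise ValueError(f"sigma_nd must be >= 0, got {self.sigma_nd}")

    def density(self, times: np.ndarray) -> np.ndarray:
        """Truncated-normal density sampled on the time grid, normalized
        so its rectangle-rule mass is exactly 1."""
        dt = times[1] - times[0]
        if self.sigma_nd == 0:
            dens = np.zeros_like(times)
            k = int(round(self.mu_nd / dt))
            k = min(max(k, 0), len(times) - 1)
            dens[k] = 1.0 / dt
            return dens
        dens = stats.norm.pdf(times, loc=self.mu_nd, scale=self.sigma_nd)
        mass = np.sum(dens) * dt
        if mass <= 0:
            raise ValueError("non-decision density has no mass on the grid")
        return dens / mass


def _check_grids(fp_m: FirstPassage, fp_c: FirstPassage) -> None:
    if fp_m.times.shape != fp_c.times.shape or not np.allclose(
        fp_m.times, fp_c.times
    ):
        raise GridError("motion and color first-passage time grids differ")


def _sub_densities(fp: FirstPassage) -> dict[int, np.ndarray]:
    return {1: fp.f_upper, -1: fp.f_lower}


def _conv_same_grid(a: np.ndarray, b: np.ndarray, dt: float) -> np.ndarray:
    """Discrete convolution of two densities on a shared grid, truncated
    to the grid length; mass beyond the horizon is dropped (reported via
    RTDensity.tail_mass_deficit)."""
    n = len(a)
    full = np.fft.irfft(np.fft.rfft(a, 2 * n) * np.fft.rfft(b, 2 * n), 2 * n)
    out = full[:n] * dt
    np.maximum(out, 0.0, out=out)
    return out


def serial_rt_density(fp_m: FirstPassage, fp_c: FirstPassage) -> RTDensity:
    """Serial composition: T = Tm + Tc, density per choice pair is the
    convolution of the corresponding sub-densities."""
    _check_grids(fp_m, fp_c)
    dt = fp_m.dt
    fm, fc = _sub_densities(fp_m), _sub_densities(fp_c)
    dens = np.empty((2, 2, len(fp_m.times)))
    for i, rm in enumerate(CHOICE_CODES):
        for j, rc in enumerate(CHOICE_CODES):
            dens[i, j] = _conv_same_grid(fm[rm], fc[rc], dt)
    return RTDensity(times=fp_m.times.copy(), dens=dens)


def parallel_rt_density(fp_m: FirstPassage, fp_c: FirstPassage) -> RTDensity:
    """Parallel composition: T = max(Tm, Tc).

    Implements the sum of "ended at t while the other ended before t"
    terms: p(T) = f_m(T) F_c(T) + f_c(T) F_m(T) per choice pair, with F
    the sub-CDF.  Numerically equal to the derivative of the product of
    sub-CDFs (see parallel_rt_density_cdf).
    """
    _check_grids(fp_m, fp_c)
    dt = fp_m.dt
    fm, fc = _sub_densities(fp_m), _sub_densities(fp_c)
    dens = np.empty((2, 2, len(fp_m.times)))
    for i, rm in enumerate(CHOICE_CODES):
        for j, rc in enumerate(CHOICE_CODES):
            Fm = np.cumsum(fm[rm]) * dt
            Fc = np.cumsum(fc[rc]) * dt
            # subtract half the current bin so F is evaluated just before t
            dens[i, j] = fm[rm] * (Fc - 0.5 * fc[rc] * dt) + fc[rc] * (
                Fm - 0.5 * fm[rm] * dt
            )
    return RTDensity(times=fp_m.times.copy(), dens=dens)


def parallel_rt_density_cdf(fp_m: FirstPassage, fp_c: FirstPassage) -> RTDensity:
    """Parallel composition via the derivative of the product of the two
    sub-CDFs; internal cross-check for parallel_rt_density."""
    _check_grids(fp_m, fp_c)
    dt = fp_m.dt
    fm, fc = _sub_densities(fp_m), _sub_densities(fp_c)
    dens = np.empty((2, 2, len(fp_m.times)))
    for i, rm in enumerate(CHOICE_CODES):
        for j, rc in enumerate(CHOICE_CODES):
            Fm = np.cumsum(fm[rm]) * dt
            Fc = np.cumsum(fc[rc]) * dt
            prod = Fm * Fc
            d = np.empty_like(prod)
            d[0] = prod[0] / dt
            d[1:] = np.diff(prod) / dt
            dens[i, j] = d
    return RTDensity(times=fp_m.times.copy(), dens=dens)


def apply_nondecision(rt: RTDensity, nd: NonDecisionSpec) -> RTDensity:
    """Convolve each choice-pair sub-density with the non-decision density.

    The mean of each pair shifts by (approximately, because of the zero
    truncation) mu_nd; mass per pair is preserved up to the horizon.
    """
    nd_dens = nd.density(rt.times)
    dens = np.empty_like(rt.dens)
    for i in range(2):
        for j in range(2):
            dens[i, j] = _conv_same_grid(rt.dens[i, j], nd_dens, rt.dt)
    return RTDensity(times=rt.times.copy(), dens=dens)


def rt_summary(
    rt: RTDensity,
    s_m: float | None = None,
    s_c: float | None = None,
    correct_only: bool = False,
):
    """Per choice-pair mass and conditional mean RT.

    With ``correct_only=True`` the summary is restricted to the pairs
    whose choice signs match the signs of the signed coherences (s_m,
    s_c); at zero coherence on a dimension, either choice counts as
    correct (the plotting convention for mean-RT graphs).

    Returns a dict keyed by (r_m, r_c) with values (mass, mean_rt); the
    mean is None for pairs with no mass.
    """
    if correct_only and (s_m is None or s_c is None):
        raise ValueError("correct_only summary requires signed coherences")
    out = {}
    for rm in CHOICE_CODES:
        for rc in CHOICE_CODES:
            if correct_only:
                ok_m = s_m == 0 or np.sign(s_m) == rm
                ok_c = s_c == 0 or np.sign(s_c) == rc
                if not (ok_m and ok_c):
                    continue
            d = rt.pair_density(rm, rc)
            mass = float(np.sum(d) * rt.dt)
            mean = float(np.sum(rt.times * d) * rt.dt / mass) if mass > 1e-12 else None
            out[(rm, rc)] = (mass, mean)
    return out
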