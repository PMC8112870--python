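"""Random-dot color-motion movies and psychophysical reverse correlation.

The stimulus is a field of dots replotted every video frame.  A dot
shown on frame n reappears on frame n + lag (40 ms at 75 Hz with a
3-frame lag) displaced coherently with probability |motion coherence|
(sign = direction), otherwise at a random location.  Each dot is
independently colored blue with probability p_blue = color coherence / 2
+ 0.5.

Motion energy is extracted with parameterized opponent quadrature
spatiotemporal filters (an energy-model stand-in with configurable
spatial and temporal constants; the temporal impulse response spans
roughly 100-150 ms).  Color energy is the per-frame blue-minus-yellow
dot count convolved with the same temporal impulse response.  For
reverse correlation, single-trial energy traces are detrended by the
mean over all trials sharing the same signed coherence, and the
residuals are averaged conditional on the observer's choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "StimulusSpec",
    "MotionFilters",
    "DotMovie",
    "EnergyTraces",
    "generate_dot_movie",
    "stimulus_energy",
    "choice_conditioned_residuals",
    "temporal_impulse_response",
]


@dataclass(frozen=True)
class StimulusSpec:
    """Dynamic random-dot stimulus parameters.

    coherence_motion: signed probability of coherent displacement
    (positive = rightward).  coherence_color = 2 (p_blue - 0.5), positive
    = blue dominant.  The displacement size follows from the dot speed
    and the lag: dx = speed * lag / frame_rate.
    """

    frame_rate: float = 75.0
    aperture: float = 5.0  # width of the square field (deg)
    dot_density: float = 16.0  # dots / deg^2 / s
    lag_frames: int = 3
    speed: float = 5.0  # deg / s
    coherence_motion: float = 0.0
    coherence_color: float = 0.0
    duration: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        for c in (self.coherence_motion, self.coherence_color):
            if not -1 <= c <= 1:
                raise ValueError(f"coherences must be in [-1, 1], got {c}")
        if self.lag_frames < 1:
            raise ValueError("lag_frames must be >= 1")

    @property
    def p_blue(self) -> float:
        return self.coherence_color / 2.0 + 0.5

    @property
    def n_frames(self) -> int:
        return max(int(round(self.duration * self.frame_rate)), self.lag_frames)

    @property
    def dots_per_frame(self) -> int:
        return max(int(round(self.dot_density * self.aperture**2 / self.frame_rate)), 1)

    @property
    def displacement(self) -> float:
        return self.speed * self.lag_frames / self.frame_rate


@dataclass
class DotMovie:
    """Frame-wise dot coordinates (deg) and colors (True = blue)."""

    spec: StimulusSpec
    x: np.ndarray  # (n_frames, n_dots)
    y: np.ndarray
    blue: np.ndarray  # bool, (n_frames, n_dots)
    displaced: np.ndarray  # bool; True where the dot moved coherently

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.spec.n_frames) / self.spec.frame_rate


def generate_dot_movie(spec: StimulusSpec) -> DotMovie:
    """Generate one trial's dot movie, reproducible from spec.seed."""
    rng = np.random.default_rng(spec.seed)
    nf, nd = spec.n_frames, spec.dots_per_frame
    half = spec.aperture / 2.0
    x = np.empty((nf, nd))
    y = np.empty((nf, nd))
    displaced = np.zeros((nf, nd), dtype=bool)
    for f in range(nf):
        if f < spec.lag_frames:
            x[f] = rng.uniform(-half, half, nd)
            y[f] = rng.uniform(-half, half, nd)
        else:
            move = rng.random(nd) < abs(spec.coherence_motion)
            dx = np.sign(spec.coherence_motion) * spec.displacement
            newx = x[f - spec.lag_frames] + dx
            # wrap around the aperture
            newx = (newx + half) % spec.aperture - half
            x[f] = np.where(move, newx, rng.uniform(-half, half, nd))
            y[f] = np.where(move, y[f - spec.lag_frames], rng.uniform(-half, half, nd))
            displaced[f] = move
    blue = rng.random((nf, nd)) < spec.p_blue
    return DotMovie(spec=spec, x=x, y=y, blue=blue, displaced=displaced)


@dataclass(frozen=True)
class MotionFilters:
    """Opponent quadrature (x, t) filter bank.

    Space-time separable pairs combined into direction-selective filters
    (energy model); quadrature outputs are squared and summed, then
    pooled over space.  Defaults give a temporal impulse response
    spanning roughly 100-150 ms.
    """

    spatial_freq: float = 1.3  # cyc/deg
    spatial_sigma: float = 0.35  # deg
    tau: float = 0.018  # s, temporal low-pass constant
    n_fast: int = 3
    n_slow: int = 5
    x_step: float = 0.05  # deg, spatial sampling of the filter/field
    support_x: float = 1.2  # deg, half-width of spatial support
    support_t: float = 0.25  # s, temporal support

    def spatial(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        xs = np.arange(-self.support_x, self.support_x + 1e-9, self.x_step)
        env = np.exp(-(xs**2) / (2 * self.spatial_sigma**2))
        even = env * np.cos(2 * np.pi * self.spatial_freq * xs)
        odd = env * np.sin(2 * np.pi * self.spatial_freq * xs)
        return xs, even, odd

    def temporal(self, frame_rate: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        ts = np.arange(0.0, self.support_t, 1.0 / frame_rate)

        def tfilt(n):
            h = (ts / self.tau) ** n * np.exp(-ts / self.tau)
            return h / np.sqrt(np.sum(h**2) + 1e-300)

        return ts, tfilt(self.n_fast), tfilt(self.n_slow)


def temporal_impulse_response(
    filters: MotionFilters | None = None, frame_rate: float = 75.0
) -> tuple[np.ndarray, np.ndarray]:
    """The temporal impulse response used for the color stream (and as
    the temporal envelope of the motion filters)."""
    filters = filters or MotionFilters()
    ts, fast, slow = filters.temporal(frame_rate)
    h = fast + slow
    return ts, h / np.max(np.abs(h))


@dataclass
class EnergyTraces:
    """Frame-wise stimulus energies for one trial.

    R, L: rightward/leftward motion energy; net motion = R - L.
    color: blue-minus-yellow count filtered by the temporal impulse
    response.  Residuals (detrended within signed-coherence groups) are
    produced by choice_conditioned_residuals.
    """

    times: np.ndarray
    R: np.ndarray
    L: np.ndarray
    color: np.ndarray
    filters: MotionFilters

    @property
    def net_motion(self) -> np.ndarray:
        return self.R - self.L


def _dot_field(movie: DotMovie, filters: MotionFilters) -> np.ndarray:
    """Project dots onto a 1D spatial grid: (n_frames, nx) occupancy."""
    spec = movie.spec
    half = spec.aperture / 2.0
    edges = np.arange(-half, half + filters.x_step, filters.x_step)
    nf = spec.n_frames
    field_xt = np.empty((nf, len(edges) - 1))
    for f in range(nf):
        field_xt[f], _ = np.histogram(movie.x[f], bins=edges)
    return field_xt


def stimulus_energy(
    movie: DotMovie, filters: MotionFilters | None = None
) -> EnergyTraces:
    """Directional motion energies and filtered color signal.

    Motion: the dot field (pooled over y) is convolved with two
    quadrature pairs of oriented (x, t) filters; quadrature outputs are
    squared, summed and pooled over space to give R(t) and L(t).  Color:
    per-frame (n_blue - n_yellow) convolved with the temporal impulse
    response.  Movies shorter than the filter support are zero-padded.
    """
    filters = filters or MotionFilters()
    spec = movie.spec
    field_xt = _dot_field(movie, filters)
    _, s_even, s_odd = filters.spatial()
    _, t_fast, t_slow = filters.temporal(spec.frame_rate)

    def conv_xt(sx, st):
        kern = np.outer(st, sx)  # (nt, nx)
        full = signal.fftconvolve(field_xt, kern, mode="full")
        # causal in time, centered in space
        x0 = (len(sx) - 1) // 2
        return full[: field_xt.shape[0], x0 : x0 + field_xt.shape[1]]

    even_fast = conv_xt(s_even, t_fast)
    even_slow = conv_xt(s_even, t_slow)
    odd_fast = conv_xt(s_odd, t_fast)
    odd_slow = conv_xt(s_odd, t_slow)

    # n.b. convolution flips the spatial kernel, which swaps the naive
    # orientation pairing; these combinations are rightward-selective for
    # positive-displacement (rightward) apparent motion
    r1 = odd_fast - even_slow
    r2 = even_fast + odd_slow
    l1 = odd_fast + even_slow
    l2 = even_fast - odd_slow
    R = np.sum(r1**2 + r2**2, axis=1)
    L = np.sum(l1**2 + l2**2, axis=1)

    excess_blue = movie.blue.sum(axis=1) - (~movie.blue).sum(axis=1)
    _, h = temporal_impulse_response(filters, spec.frame_rate)
    color = signal.fftconvolve(excess_blue.astype(float), h, mode="full")[
        : len(excess_blue)
    ]
    return EnergyTraces(times=movie.times, R=R, L=L, color=color, filters=filters)


def choice_conditioned_residuals(
    traces: np.ndarray,
    coherence: np.ndarray,
    choice: np.ndarray,
    group_labels: np.ndarray | None = None,
) -> pd.DataFrame:
    """Choice-conditioned averages of detrended energy residuals.

    traces : (n_trials, n_t) single-trial energy time courses.
    coherence : signed coherence per trial; residuals are the traces
        minus the mean over all trials sharing the same signed coherence.
    choice : +1 / -1 per trial.
    group_labels : optional extra grouping (e.g. 1D vs 2D task).

    Returns a tidy frame with columns (group, choice, t_index, mean, sem,
    n).  Signed-coherence groups with fewer than 2 trials are excluded.
    """
    traces = np.asarray(traces, dtype=float)
    coherence = np.asarray(coherence)
    choice = np.asarray(choice)
    if group_labels is None:
        group_labels = np.repeat("all", len(choice))
    resid = np.full_like(traces, np.nan)
    for s in np.unique(coherence):
        mask = coherence == s
        if mask.sum() < 2:
            continue
        resid[mask] = traces[mask] - traces[mask].mean(axis=0, keepdims=True)
    keep = ~np.isnan(resid[:, 0])
    rows = []
    for g in np.unique(group_labels):
        for ch in np.unique(choice):
            mask = keep & (group_labels == g) & (choice == ch)
            if mask.sum() == 0:
                continue
            block = resid[mask]
            mean = block.mean(axis=0)
            sem = stats.sem(block, axis=0) if mask.sum() > 1 else np.zeros_like(mean)
            for k in range(traces.shape[1]):
                rows.append(
                    {"group": g, "choice": int(ch), "t_index": k,
                     "mean": mean[k], "sem": float(np.atleast_1d(sem)[k] if np.ndim(sem) else sem),
                     "n": int(mask.sum())}
                )
    return pd.DataFrame(rows)
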