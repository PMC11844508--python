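"""Gamma-parametrized integration windows and the window-estimation model.

A neural integration window is modelled as a Gamma density that is shifted
and scaled so that it is described by three interpretable parameters:

* ``width``  -- the smallest interval containing 75% of the window's mass,
* ``center`` -- the window's median, i.e. the overall stimulus-to-response
  delay,
* ``shape``  -- the Gamma shape, interpolating between exponential-like
  (shape 1) and more Gaussian-like (shape 5) windows.

The baseline (unshifted, unscaled) distribution is a Gamma with shape ``b``
and rate ``b`` (unit mean).  Its baseline width ``w_d`` and center ``c_d``
convert the user-facing (width, center) pair into the scale ``lam = w/w_d``
and shift ``delta = c - lam*c_d`` of the actual density
``h(t) = g((t - delta)/lam; b) / lam``.  Windows with ``delta < 0`` are
acausal and excluded from fitting.

The model predicts the cross-context correlation (CCC) of a neuron from the
relative overlap of its window with the shared segment versus the
surrounding context segments: with ``s(tau)`` the convolution of the window
with a (crossfade-tapered) segment boxcar,

    P_CCC(tau) = ceiling(tau) * s_shared(tau)^2
                 / (s_shared(tau)^2 + sum_n s_n,surround(tau)^2)

and the best window is the grid argmin of the summed squared prediction
error pooled over segment durations and lags.  `IntegrationWindowModel` /
`IntegrationWindowResults` expose this as a fit/results pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, signal, stats

__all__ = [
    "baseline_stats",
    "GammaWindow",
    "minimal_center",
    "segment_overlap",
    "predict_ccc",
    "WindowGrid",
    "IntegrationWindowModel",
    "IntegrationWindowResults",
    "fit_window",
]

#: internal fine grid step (seconds).  2^-10 s makes every dyadic segment
#: duration (500/2^k ms) and the 15.625 ms crossfade ramp an integer number
#: of samples, so surround-segment shifts in the prediction are exact.
FINE_DT = 2.0 ** -10

DEFAULT_RAMP = 0.015625
WIDTH_MASS = 0.75


@lru_cache(maxsize=None)
def baseline_stats(shape: int, mass: float = WIDTH_MASS) -> tuple[float, float]:
    """Baseline width ``w_d`` and center ``c_d`` of the unit-mean Gamma.

    The baseline distribution has shape ``shape`` and rate ``shape`` (mean
    1).  The center is its median.  The width is the length of the shortest
    interval containing ``mass`` of the probability; it is found by
    minimizing ``ppf(F + mass) - ppf(F)`` over the lower tail probability
    ``F`` (a coarse scan followed by bounded local refinement), so the mass
    of the returned interval is exact by construction.
    """
    if shape < 1:
        raise ValueError("shape must be a positive integer")
    dist = stats.gamma(a=shape, scale=1.0 / shape)
    c_d = float(dist.ppf(0.5))

    def interval_length(lo_prob: float) -> float:
        return float(dist.ppf(lo_prob + mass) - dist.ppf(lo_prob))

    grid = np.linspace(0.0, 1.0 - mass, 2001)
    lengths = dist.ppf(grid + mass) - dist.ppf(grid)
    k = int(np.argmin(lengths))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            interval_length, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-12},
        )
        best = min(res.x, 1.0 - mass)
        w_d = min(interval_length(best), lengths[k])
    else:  # pragma: no cover - degenerate bracket
        w_d = float(lengths[k])
    return float(w_d), c_d


def minimal_center(width: float, shape: int) -> float:
    """Smallest causal center for a window of the given width and shape.

    A window is causal when its shift ``delta = c - lam*c_d`` is
    nonnegative; the minimal center is therefore ``(w/w_d) * c_d``.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    w_d, c_d = baseline_stats(shape)
    return width / w_d * c_d


@dataclass(frozen=True)
class GammaWindow:
    """A shifted/scaled Gamma integration window.

    Parameters are the field-facing (width, center, shape); the scale and
    shift of the underlying density are derived.
    """

    width: float
    center: float
    shape: int = 2

    def __post_init__(self) -> None:
        if not (np.isfinite(self.width) and np.isfinite(self.center)):
            raise ValueError("window parameters must be finite")
        if self.width <= 0 or self.center <= 0:
            raise ValueError("width and center must be positive")
        if self.shape < 1:
            raise ValueError("shape must be a positive integer")

    @property
    def baseline(self) -> tuple[float, float]:
        return baseline_stats(self.shape)

    @property
    def lam(self) -> float:
        """Scale factor applied to the baseline distribution."""
        w_d, _ = self.baseline
        return self.width / w_d

    @property
    def delta(self) -> float:
        """Temporal shift of the scaled distribution (negative = acausal)."""
        _, c_d = self.baseline
        return self.center - self.lam * c_d

    @property
    def causal(self) -> bool:
        return self.delta >= -1e-12

    def scaled(self, factor: float) -> "GammaWindow":
        """Window with width and center multiplied by ``factor``."""
        return GammaWindow(self.width * factor, self.center * factor, self.shape)

    # -- discretization ---------------------------------------------------

    def _dist(self):
        return stats.gamma(a=self.shape, scale=self.lam / self.shape, loc=self.delta)

    def support(self, tail: float = 1e-12) -> float:
        """Upper lag beyond which the window mass is below ``tail``."""
        return float(self._dist().ppf(1.0 - tail))

    def density(self, lags: np.ndarray, dt: float | None = None) -> np.ndarray:
        """Bin-averaged density on a uniform lag grid.

        Computed from CDF differences over the bins centred at ``lags`` so
        that the discretized window integrates to the enclosed mass exactly
        (the pointwise pdf under-resolves the narrowest windows at 1 ms).
        """
        lags = np.asarray(lags, dtype=float)
        if dt is None:
            if lags.size < 2:
                raise ValueError("need dt or at least two lags")
            dt = float(lags[1] - lags[0])
        dist = self._dist()
        return (dist.cdf(lags + dt / 2) - dist.cdf(lags - dt / 2)) / dt

    def kernel(self, dt: float, tail: float = 1e-12) -> np.ndarray:
        """Discrete convolution kernel; tap k carries the mass of the bin
        centred on lag k*dt, so the discretized window is delay-unbiased.

        Truncated where the remaining tail mass is below ``tail``.
        """
        upper = self.support(tail)
        n = max(int(np.ceil(upper / dt)) + 2, 2)
        lags = np.arange(n) * dt
        return self.density(lags, dt) * dt

    def measured_stats(self, dt: float = 1e-4, mass: float = WIDTH_MASS) -> tuple[float, float]:
        """(width, center) re-measured from the discretized window.

        Round-trip check: these reproduce the nominal parameters within a
        grid step.
        """
        dist = self._dist()
        center = float(dist.ppf(0.5))
        grid = np.linspace(0.0, 1.0 - mass, 4001)
        lengths = dist.ppf(grid + mass) - dist.ppf(grid)
        return float(lengths.min()), center


def tapered_boxcar(duration: float, lags: np.ndarray, ramp: float = DEFAULT_RAMP) -> np.ndarray:
    """Segment indicator with raised-cosine tapered edges.

    The boxcar is 1 over the nominal segment [0, duration]; each edge is
    tapered with a raised-cosine ramp of ``ramp/2`` (~7.8 ms for the
    standard 15.625 ms crossfade) centred on the boundary, so adjacent
    tiled segments sum to 1.
    """
    lags = np.asarray(lags, dtype=float)
    half = ramp / 2.0
    out = np.zeros_like(lags)

    def rise(t: np.ndarray) -> np.ndarray:
        # raised cosine from 0 at -half/2 to 1 at +half/2
        return 0.5 * (1.0 - np.cos(np.pi * (t + half / 2) / half))

    core = (lags >= half / 2) & (lags <= duration - half / 2)
    out[core] = 1.0
    lead = (lags > -half / 2) & (lags < half / 2)
    out[lead] = rise(lags[lead])
    trail = (lags > duration - half / 2) & (lags < duration + half / 2)
    out[trail] = rise(duration - lags[trail])
    return out


def _overlap_fine(window: GammaWindow, duration: float, t_lo: float, t_hi: float,
                  ramp: float, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Overlap s(t) = (h * b)(t) on the fine grid, ignoring the shift.

    The window is evaluated with delta = 0 (shift handled by the caller as
    a lag translation), which keeps a single convolution reusable across
    the whole center grid.
    """
    base = GammaWindow(window.width, minimal_center(window.width, window.shape),
                       window.shape)
    kern = base.kernel(dt, tail=1e-10)
    n_lo = int(np.floor(t_lo / dt)) - 1
    n_hi = int(np.ceil(t_hi / dt)) + 1
    t = np.arange(n_lo, n_hi + 1) * dt
    # boxcar sampled on grid extended leftwards by the kernel length so the
    # causal convolution is valid over all requested t
    pad = len(kern)
    t_ext = np.arange(n_lo - pad, n_hi + 1) * dt
    b = tapered_boxcar(duration, t_ext, ramp)
    s = signal.fftconvolve(b, kern, mode="full")[pad: pad + len(t)]
    return t, np.clip(s, 0.0, 1.0)


def segment_overlap(window: GammaWindow, duration: float, lags: np.ndarray,
                    ramp: float = DEFAULT_RAMP, dt: float = FINE_DT) -> np.ndarray:
    """Overlap of the window with one segment as a function of lag.

    Implements the convolution of the discretized window with the tapered
    segment boxcar; values are in [0, 1] with 1 meaning the window is fully
    contained in the segment at that lag.
    """
    lags = np.asarray(lags, dtype=float)
    lo = float(lags.min()) - window.delta
    hi = float(lags.max()) - window.delta
    t, s = _overlap_fine(window, duration, lo - dt, hi + dt, ramp, dt)
    return np.interp(lags - window.delta, t, s, left=0.0, right=0.0)


def _ratio_fine(window: GammaWindow, duration: float, t_lo: float, t_hi: float,
                ramp: float, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Shared-overlap ratio q/(q + sum of surround q) on the fine grid.

    The surround layout tiles the lag axis with adjacent copies of the
    shared segment interval; their overlaps are lag-shifted copies of the
    shared overlap, so a single convolution serves all terms.
    """
    n_sur = int(np.ceil((window.support(1e-9) - window.delta + max(abs(t_lo), abs(t_hi)))
                        / duration)) + 1
    margin = (n_sur + 2) * dt
    t, s = _overlap_fine(window, duration, t_lo - n_sur * duration - margin,
                         t_hi + n_sur * duration + margin, ramp, dt)
    shift = int(round(duration / dt))
    lo = int(round((t_lo - t[0]) / dt))
    hi = lo + int(round((t_hi - t_lo) / dt))
    length = hi - lo + 1
    # zero-pad so that every surround shift indexes inside the array even
    # when the duration is not an exact grid multiple
    pad = n_sur * shift + length
    q = np.concatenate([np.zeros(pad), s * s, np.zeros(pad)])
    total = np.zeros(length)
    for n in range(-n_sur, n_sur + 1):
        a = pad + lo + n * shift
        total += q[a: a + length]
    q_sh = q[pad + lo: pad + hi + 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 1e-30, q_sh / np.maximum(total, 1e-30), 0.0)
    return t[lo: hi + 1], ratio


def predict_ccc(window: GammaWindow, duration: float, lags: np.ndarray,
                ceiling: np.ndarray | float | None = None,
                ramp: float = DEFAULT_RAMP, dt: float = FINE_DT) -> np.ndarray:
    """Predicted cross-context correlation for one segment duration.

    The prediction multiplies the noise ceiling by the squared-overlap
    ratio of the shared segment relative to all tiled segments; where every
    overlap is zero the ratio is defined as 0.
    """
    lags = np.asarray(lags, dtype=float)
    lo = float(lags.min()) - window.delta
    hi = float(lags.max()) - window.delta
    t, ratio = _ratio_fine(window, duration, lo - dt, hi + dt, ramp, dt)
    pred = np.interp(lags - window.delta, t, ratio, left=0.0, right=0.0)
    if ceiling is None:
        return pred
    return pred * np.asarray(ceiling, dtype=float)


# ---------------------------------------------------------------------------
# grid fitting


def _log_spaced(lo: float, hi: float, n: int) -> np.ndarray:
    return np.exp(np.linspace(math.log(lo), math.log(hi), n))


@dataclass(frozen=True)
class WindowGrid:
    """Search grid for the window fit.

    Defaults: 100 log-spaced widths in [1/128, 0.5] s, 100 log-spaced
    centers in [1 ms, 0.25] s (a strictly positive stand-in for the nominal
    (0, 0.25] range, which cannot be log-spaced from 0), shapes 1..5.
    """

    widths: tuple[float, ...] = tuple(_log_spaced(1.0 / 128, 0.5, 100))
    centers: tuple[float, ...] = tuple(_log_spaced(1e-3, 0.25, 100))
    shapes: tuple[int, ...] = (1, 2, 3, 4, 5)
    dt: float = FINE_DT

    @classmethod
    def coarse(cls, n_width: int = 40, n_center: int = 25,
               shapes: tuple[int, ...] = (2,)) -> "WindowGrid":
        """Reduced grid for quick exploratory fits."""
        return cls(widths=tuple(_log_spaced(1.0 / 128, 0.5, n_width)),
                   centers=tuple(_log_spaced(1e-3, 0.25, n_center)),
                   shapes=shapes)


class IntegrationWindowModel:
    """Estimate a neuron's integration window from its CCC profiles.

    Parameters
    ----------
    profiles : sequence of CCCProfile
        Cross-context correlation and noise ceiling versus lag, one per
        segment duration (see `tci.ccc`).  At least two durations with
        defined values are required.
    grid : WindowGrid, optional
        Parameter grid searched exhaustively; acausal combinations
        (delta < -dt/2) are excluded.
    ramp : float
        Crossfade ramp of the stimulus; sets the boxcar taper.
    ceiling_weighted : bool
        If True, weight each squared error by the noise ceiling (an option;
        the default pools unweighted squared errors across durations/lags).
    """

    def __init__(self, profiles: Sequence, grid: WindowGrid | None = None,
                 ramp: float = DEFAULT_RAMP, ceiling_weighted: bool = False):
        self.profiles = list(profiles)
        self.grid = grid or WindowGrid()
        self.ramp = ramp
        self.ceiling_weighted = ceiling_weighted
        self._data = []
        for p in self.profiles:
            lags = np.asarray(p.lags, dtype=float)
            ccc = np.asarray(p.ccc, dtype=float)
            ceil = np.asarray(p.ceiling, dtype=float)
            ok = np.isfinite(ccc) & np.isfinite(ceil)
            if ok.sum() == 0:
                continue
            self._data.append((float(p.duration), lags[ok], ccc[ok], ceil[ok]))
        if len({d for d, *_ in self._data}) < 2:
            raise ValueError("need CCC profiles for at least two segment durations")

    def fit(self) -> "IntegrationWindowResults":
        g = self.grid
        widths = np.asarray(g.widths)
        centers = np.asarray(g.centers)
        shapes = list(g.shapes)
        dt = g.dt
        loss = np.full((len(shapes), len(widths), len(centers)), np.inf)
        n_obs = sum(len(lags) for _, lags, _, _ in self._data)

        for bi, beta in enumerate(shapes):
            w_d, c_d = baseline_stats(beta)
            for wi, w in enumerate(widths):
                lam = w / w_d
                delta = centers - lam * c_d
                causal = delta >= -dt / 2
                if not causal.any():
                    continue
                acc = np.zeros(len(centers))
                base = GammaWindow(w, lam * c_d, beta)  # delta = 0
                for duration, lags, ccc, ceil in self._data:
                    lo = float(lags.min() - delta[causal].max()) - dt
                    hi = float(lags.max() - max(delta[causal].min(), 0.0)) + dt
                    t, ratio = _ratio_fine(base, duration, min(lo, -dt), hi,
                                           self.ramp, dt)
                    # all centers at once: prediction at lag - delta
                    query = lags[None, :] - delta[causal, None]
                    pred = np.interp(query.ravel(), t, ratio,
                                     left=0.0, right=0.0).reshape(query.shape)
                    resid = ccc[None, :] - ceil[None, :] * pred
                    if self.ceiling_weighted:
                        acc[causal] += np.sum(ceil[None, :] * resid ** 2, axis=1)
                    else:
                        acc[causal] += np.sum(resid ** 2, axis=1)
                loss[bi, wi, causal] = acc[causal]

        if not np.isfinite(loss).any():
            raise ValueError("no causal grid point could be evaluated")
        best_loss = loss.min()
        # ties broken by smaller width, then center, then shape
        cand = np.argwhere(loss == best_loss)
        order = np.lexsort((cand[:, 0], cand[:, 2], cand[:, 1]))
        bi, wi, ci = cand[order[0]]
        best = GammaWindow(float(widths[wi]), float(centers[ci]), int(shapes[bi]))
        return IntegrationWindowResults(self, best, float(best_loss), loss, n_obs)


@dataclass
class IntegrationWindowResults:
    """Results of an integration-window grid fit."""

    model: IntegrationWindowModel
    window: GammaWindow
    loss: float
    loss_grid: np.ndarray = field(repr=False)
    n_obs: int = 0

    @property
    def width(self) -> float:
        return self.window.width

    @property
    def center(self) -> float:
        return self.window.center

    @property
    def shape(self) -> int:
        return self.window.shape

    def predict(self, duration: float, lags: np.ndarray,
                ceiling: np.ndarray | float | None = None) -> np.ndarray:
        """Predicted CCC of the fitted window for one segment duration."""
        return predict_ccc(self.window, duration, np.asarray(lags, float),
                           ceiling=ceiling, ramp=self.model.ramp,
                           dt=self.model.grid.dt)

    def predicted_curves(self) -> list[dict]:
        """Per-duration predicted CCC curves at the fitted window."""
        out = []
        for duration, lags, ccc, ceil in self.model._data:
            pred = self.predict(duration, lags, ceiling=ceil)
            out.append({"duration": duration, "lags": lags, "ccc": ccc,
                        "ceiling": ceil, "predicted": pred})
        return out

    def width_interval(self, factor: float = 2.0) -> tuple[float, float]:
        """Range of widths whose best loss is within ``factor`` of the minimum.

        A simple grid-profile uncertainty band on the width estimate.
        """
        prof = self.loss_grid.min(axis=(0, 2))
        widths = np.asarray(self.model.grid.widths)
        ok = prof <= self.loss * factor + 1e-300
        return float(widths[ok].min()), float(widths[ok].max())

    def summary(self) -> str:
        lines = [
            "Integration window fit (grid search)",
            "=" * 44,
            f"width   {self.width * 1e3:8.2f} ms  (75%-mass interval)",
            f"center  {self.center * 1e3:8.2f} ms  (window median)",
            f"shape   {self.shape:8d}",
            f"delta   {self.window.delta * 1e3:8.2f} ms  (causal shift)",
            f"loss    {self.loss:10.4g}  (SSE over {self.n_obs} lag points)",
            "-" * 44,
        ]
        for c in self.predicted_curves():
            rms = float(np.sqrt(np.mean((c["ccc"] - c["predicted"]) ** 2)))
            lines.append(
                f"duration {c['duration'] * 1e3:7.2f} ms : RMS residual {rms:6.3f}"
                f" over {len(c['lags'])} lags")
        lo, hi = self.width_interval()
        lines.append(f"width band (loss < 2x min): {lo * 1e3:.1f}-{hi * 1e3:.1f} ms")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot measured CCC, ceiling and fitted prediction per duration."""
        import matplotlib.pyplot as plt

        curves = self.predicted_curves()
        if ax is None:
            _, axes = plt.subplots(1, len(curves), figsize=(3 * len(curves), 2.6),
                                   sharey=True, squeeze=False)
            axes = axes[0]
        else:
            axes = [ax] * len(curves)
        for a, c in zip(axes, curves):
            ms = c["lags"] * 1e3
            a.plot(ms, c["ceiling"], "k-", lw=1, label="ceiling")
            a.plot(ms, c["ccc"], "C0-", lw=1, label="CCC")
            a.plot(ms, c["predicted"], "C3--", lw=1, label="model")
            a.set_title(f"{c['duration'] * 1e3:.0f} ms")
            a.set_xlabel("lag (ms)")
        axes[0].set_ylabel("correlation")
        axes[0].legend(fontsize=7)
        return axes


def fit_window(profiles: Iterable, grid: WindowGrid | None = None,
               ramp: float = DEFAULT_RAMP,
               ceiling_weighted: bool = False) -> IntegrationWindowResults:
    """Convenience wrapper: fit an integration window to CCC profiles."""
    return IntegrationWindowModel(profiles, grid=grid, ramp=ramp,
                                  ceiling_weighted=ceiling_weighted).fit()
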