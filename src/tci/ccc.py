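"""Cross-context correlation, noise ceiling and group summaries.

The cross-context correlation (CCC) at lag tau is the Pearson correlation,
across shared segments, between the responses in the two contexts,
averaged over every ordered pair of repetitions from different contexts:

    CCC(tau) = (1/R^2) sum_{r1} sum_{r2} corr(M[:, tau, 1, r1], M[:, tau, 2, r2])

The noise ceiling replaces the cross-context comparison with a
cross-repetition comparison within the same context, averaged over the two
contexts, and bounds the CCC attainable given response variability:

    ceiling(tau) = (1/2) sum_c (1/(R(R-1))) sum_{r1 != r2} corr(M[:, tau, c, r1], M[:, tau, c, r2])

Raw correlation coefficients are averaged (no Fisher transform).  Missing
cells are pairwise-excluded; a column needs at least three segments and
nonzero variance on both sides to contribute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .responses import ResponseMatrixSet

__all__ = [
    "CCCProfile",
    "cross_context_correlation",
    "noise_ceiling",
    "compute_profile",
    "group_normalized_ccc",
    "profiles_to_frame",
]

MIN_SEGMENTS = 3


@dataclass
class CCCProfile:
    """CCC and noise ceiling versus lag for one unit and duration."""

    neuron_id: str
    duration: float
    lags: np.ndarray
    ccc: np.ndarray
    ceiling: np.ndarray
    n_segments: int
    n_reps: int
    context_types: tuple[str, ...] = ("random_random", "natural_random")
    n_dropped: int = 0           # zero-variance (tau, r1, r2) terms dropped


def _corr_terms(X: np.ndarray, Y: np.ndarray) -> tuple[float, int, int]:
    """Mean Pearson correlation over all column pairs of X and Y.

    X, Y: (segments, reps) for a single lag, rows already restricted to
    pairwise-complete segments.  Returns (mean corr, n terms used,
    n zero-variance terms dropped).
    """
    m = X.shape[0]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sx = X.std(axis=0)
    sy = Y.std(axis=0)
    C = Xc.T @ Yc / m
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = C / np.outer(sx, sy)
    valid = np.isfinite(corr)
    n_terms = int(valid.sum())
    if n_terms == 0:
        return float("nan"), 0, corr.size
    return float(corr[valid].mean()), n_terms, int(corr.size - n_terms)


def cross_context_correlation(mset: ResponseMatrixSet) -> tuple[np.ndarray, int]:
    """CCC(tau) for one response-matrix set.

    Returns the CCC vector over lags and the total count of zero-variance
    correlation terms dropped from the averages.
    """
    M = mset.M
    n_lags = M.shape[1]
    ccc = np.full(n_lags, np.nan)
    dropped = 0
    for k in range(n_lags):
        X = M[:, k, 0, :]
        Y = M[:, k, 1, :]
        rows = np.isfinite(X).all(axis=1) & np.isfinite(Y).all(axis=1)
        if rows.sum() < MIN_SEGMENTS:
            continue
        val, n_terms, n_drop = _corr_terms(X[rows], Y[rows])
        dropped += n_drop
        if n_terms:
            ccc[k] = val
    return ccc, dropped


def noise_ceiling(mset: ResponseMatrixSet) -> np.ndarray:
    """ceiling(tau): cross-repetition correlation averaged over contexts."""
    M = mset.M
    if mset.n_reps < 2:
        raise ValueError("noise ceiling requires at least two repetitions")
    n_lags = M.shape[1]
    ceiling = np.full(n_lags, np.nan)
    off_diag = ~np.eye(mset.n_reps, dtype=bool)
    for k in range(n_lags):
        per_context = []
        for c in (0, 1):
            X = M[:, k, c, :]
            rows = np.isfinite(X).all(axis=1)
            if rows.sum() < MIN_SEGMENTS:
                per_context.append(np.nan)
                continue
            val, n_terms = _corr_terms_offdiag(X[rows], off_diag)
            per_context.append(val if n_terms else np.nan)
        if np.all(np.isfinite(per_context)):
            ceiling[k] = float(np.mean(per_context))
    return ceiling


def _corr_terms_offdiag(X: np.ndarray, off_diag: np.ndarray) -> tuple[float, int]:
    m = X.shape[0]
    Xc = X - X.mean(axis=0)
    sx = X.std(axis=0)
    C = Xc.T @ Xc / m
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = C / np.outer(sx, sx)
    sel = off_diag & np.isfinite(corr)
    n = int(sel.sum())
    if n == 0:
        return float("nan"), 0
    return float(corr[sel].mean()), n


def compute_profile(mset: ResponseMatrixSet, neuron_id: str = "",
                    context_types: Sequence[str] | None = None) -> CCCProfile:
    """CCC and noise ceiling for one unit/duration, optionally restricted
    to a subset of context-pair types (random_random / natural_random)."""
    if context_types is not None:
        keep = [i for i, p in enumerate(mset.pairs)
                if p.context_type in context_types]
        mset = ResponseMatrixSet(duration=mset.duration, lags=mset.lags,
                                 M=mset.M[keep], pairs=[mset.pairs[i] for i in keep],
                                 bin_width=mset.bin_width,
                                 repetitions=mset.repetitions)
        types = tuple(context_types)
    else:
        types = tuple(sorted({p.context_type for p in mset.pairs}))
    ccc, dropped = cross_context_correlation(mset)
    if mset.n_reps >= 2:
        ceil = noise_ceiling(mset)
    else:
        ceil = np.full_like(ccc, np.nan)
    return CCCProfile(neuron_id=neuron_id, duration=mset.duration,
                      lags=mset.lags, ccc=ccc, ceiling=ceil,
                      n_segments=mset.n_segments, n_reps=mset.n_reps,
                      context_types=types, n_dropped=dropped)


def group_normalized_ccc(profiles: Sequence[CCCProfile],
                         min_ceiling: float = 0.05) -> dict[float, dict]:
    """Noise-normalized group CCC per duration.

    The median CCC over units is divided by the median noise ceiling over
    units, lag by lag; lags where the median ceiling falls below
    ``min_ceiling`` are masked (NaN).  Returns
    {duration: {lags, normalized, median_ccc, median_ceiling, n_units}}.
    """
    if not profiles:
        raise ValueError("empty profile group")
    by_dur: dict[float, list[CCCProfile]] = {}
    for p in profiles:
        by_dur.setdefault(float(p.duration), []).append(p)
    out = {}
    for dur, group in sorted(by_dur.items()):
        lags = group[0].lags
        ccc = np.nanmedian(np.vstack([p.ccc for p in group]), axis=0)
        ceil = np.nanmedian(np.vstack([p.ceiling for p in group]), axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = np.where(ceil >= min_ceiling, ccc / ceil, np.nan)
        out[dur] = {"lags": lags, "normalized": norm, "median_ccc": ccc,
                    "median_ceiling": ceil, "n_units": len(group)}
    return out


def profiles_to_frame(profiles: Iterable[CCCProfile]) -> pd.DataFrame:
    """Long-format table (neuron_id, duration_ms, lag_ms, ccc, ceiling,
    n_valid_segments) for CSV export."""
    rows = []
    for p in profiles:
        for lag, c, n in zip(p.lags, p.ccc, p.ceiling):
            rows.append({"neuron_id": p.neuron_id,
                         "duration_ms": p.duration * 1e3,
                         "lag_ms": lag * 1e3, "ccc": c, "ceiling": n,
                         "n_valid_segments": p.n_segments})
    return pd.DataFrame(rows)
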