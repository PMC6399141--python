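"""Activation and repolarization marker detection.

Four marker rules: electrogram AT (minimum dV/dt of the intrinsic
deflection), optical AT (maximum dF/dt of the upstroke), electrogram RT
(maximum dV/dt of the T-wave) and optical RT (minimum dF/dt), plus a
global-activation-field fit that estimates node activation times from
pairwise inter-electrogram delays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix, vstack as sp_vstack
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import lsmr

from ecgitank.errors import ComponentError
from ecgitank.electro import OpticalStack, SignalBlock, TimeMap

__all__ = [
    "MarkerSet",
    "at_from_egm",
    "at_from_optical",
    "rt_from_egm",
    "rt_from_optical",
    "at_map_from_egms",
    "rt_map_from_egms",
    "at_map_from_optical",
    "rt_map_from_optical",
    "global_activation_field",
    "fit_delay_field",
    "graph_laplacian",
]

RT_WINDOW_MS = (50.0, 450.0)


@dataclass
class MarkerSet:
    at: TimeMap
    rt: TimeMap
    method_tag: str
    windows: dict

    def to_csv(self, path) -> None:
        at_t = self.at.times.ravel()
        rt_t = self.rt.times.ravel()
        valid = (self.at.valid & self.rt.valid).ravel()
        pd.DataFrame(
            {
                "id": np.arange(at_t.size),
                "at_ms": at_t,
                "rt_ms": rt_t,
                "valid": valid.astype(int),
                "method_tag": self.method_tag,
            }
        ).to_csv(path, index=False)


def _derivative(trace: np.ndarray, rate: float) -> np.ndarray:
    """First central difference in units per ms."""
    return np.gradient(trace, axis=-1) * rate / 1000.0


def _window_indices(times_ms: np.ndarray, window_ms) -> np.ndarray:
    if window_ms is None:
        return np.arange(len(times_ms))
    lo, hi = window_ms
    return np.flatnonzero((times_ms >= lo) & (times_ms < hi))


def at_from_egm(
    trace: np.ndarray,
    rate: float,
    t0: float = 0.0,
    window_ms=None,
    noise_floor: float = 0.0,
):
    """AT = time of minimum derivative of the intrinsic deflection.

    Returns (time_ms, valid); flat traces (SD at or below the noise floor)
    are marked invalid.  Ties break to the earliest sample.
    """
    trace = np.asarray(trace, dtype=float)
    t = t0 + np.arange(len(trace)) * 1000.0 / rate
    idx = _window_indices(t, window_ms)
    if idx.size == 0 or np.std(trace[idx]) <= noise_floor:
        return np.nan, False
    d = _derivative(trace, rate)[idx]
    return float(t[idx[np.argmin(d)]]), True


def at_from_optical(
    trace: np.ndarray,
    rate: float,
    t0: float = 0.0,
    window_ms=None,
    noise_floor: float = 0.0,
):
    """AT = time of maximum dF/dt of the optical upstroke.

    Invalid when flat or when polarity is inverted (the steepest downslope
    exceeds the steepest upslope, which cannot happen for an upright action
    potential).
    """
    trace = np.asarray(trace, dtype=float)
    t = t0 + np.arange(len(trace)) * 1000.0 / rate
    idx = _window_indices(t, window_ms)
    if idx.size == 0 or np.std(trace[idx]) <= noise_floor:
        return np.nan, False
    d = _derivative(trace, rate)[idx]
    if d.max() <= 0 or -d.min() > d.max():
        return np.nan, False
    return float(t[idx[np.argmax(d)]]), True


def rt_from_egm(
    trace: np.ndarray,
    at_ms: float,
    rate: float,
    t0: float = 0.0,
    window_ms=RT_WINDOW_MS,
):
    """RT = time of maximum dV/dt within the T-wave window [AT+50, AT+450] ms."""
    trace = np.asarray(trace, dtype=float)
    t = t0 + np.arange(len(trace)) * 1000.0 / rate
    idx = _window_indices(t, (at_ms + window_ms[0], at_ms + window_ms[1]))
    if idx.size == 0:
        return np.nan, False
    d = _derivative(trace, rate)[idx]
    return float(t[idx[np.argmax(d)]]), True


def rt_from_optical(
    trace: np.ndarray,
    at_ms: float,
    rate: float,
    t0: float = 0.0,
    window_ms=RT_WINDOW_MS,
):
    """RT = time of minimum dF/dt within the repolarization window.

    Invalid when the trace never falls inside the window (no repolarization).
    """
    trace = np.asarray(trace, dtype=float)
    t = t0 + np.arange(len(trace)) * 1000.0 / rate
    idx = _window_indices(t, (at_ms + window_ms[0], at_ms + window_ms[1]))
    if idx.size == 0:
        return np.nan, False
    d = _derivative(trace, rate)[idx]
    if d.min() >= 0:
        return np.nan, False
    return float(t[idx[np.argmin(d)]]), True


# ---------------------------------------------------------------------------
# vectorized map helpers


def at_map_from_egms(egms: SignalBlock, window_ms=None, noise_floor: float = 0.0) -> TimeMap:
    times = np.full(egms.n_channels, np.nan)
    valid = np.zeros(egms.n_channels, dtype=bool)
    for i in range(egms.n_channels):
        if not egms.valid[i]:
            continue
        times[i], valid[i] = at_from_egm(
            egms.samples[i], egms.rate, egms.t0, window_ms, noise_floor
        )
    return TimeMap(times=times, valid=valid, domain_tag="sock_electrodes")


def rt_map_from_egms(egms: SignalBlock, at: TimeMap, window_ms=RT_WINDOW_MS) -> TimeMap:
    times = np.full(egms.n_channels, np.nan)
    valid = np.zeros(egms.n_channels, dtype=bool)
    for i in range(egms.n_channels):
        if not (egms.valid[i] and at.valid[i]):
            continue
        times[i], valid[i] = rt_from_egm(
            egms.samples[i], at.times[i], egms.rate, egms.t0, window_ms
        )
    return TimeMap(times=times, valid=valid, domain_tag="sock_electrodes")


def at_map_from_optical(stack: OpticalStack, mask: np.ndarray | None = None) -> TimeMap:
    """Per-pixel optical AT map (vectorized argmax dF/dt)."""
    if mask is None:
        mask = stack.mask
    d = np.gradient(stack.frames, axis=2) * stack.rate / 1000.0
    dmax = d.max(axis=2)
    dmin = d.min(axis=2)
    arg = d.argmax(axis=2)
    times = stack.t0 + arg * 1000.0 / stack.rate
    valid = mask & (dmax > 0) & (dmax >= -dmin)
    times = np.where(valid, times, np.nan)
    return TimeMap(times=times, valid=valid, domain_tag="optical_pixels")


def rt_map_from_optical(
    stack: OpticalStack, at: TimeMap, window_ms=RT_WINDOW_MS
) -> TimeMap:
    """Per-pixel optical RT map: argmin dF/dt in each pixel's T window."""
    d = np.gradient(stack.frames, axis=2) * stack.rate / 1000.0
    t = stack.times_ms[None, None, :]
    lo = at.times[:, :, None] + window_ms[0]
    hi = at.times[:, :, None] + window_ms[1]
    in_win = (t >= lo) & (t < hi)
    dmask = np.where(in_win, d, np.inf)
    arg = dmask.argmin(axis=2)
    minval = dmask.min(axis=2)
    valid = at.valid & np.isfinite(minval) & (minval < 0)
    times = np.where(valid, stack.t0 + arg * 1000.0 / stack.rate, np.nan)
    return TimeMap(times=times, valid=valid, domain_tag="optical_pixels")


# ---------------------------------------------------------------------------
# global activation field


def _edge_delay(di: np.ndarray, dj: np.ndarray, max_lag: int):
    """Lag (samples) maximizing normalized cross-correlation of two
    derivative traces, with the peak correlation value."""
    n = len(di)
    best_lag, best_c = 0, -np.inf
    di0 = di - di.mean()
    dj0 = dj - dj.mean()
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            a, b = di0[lag:], dj0[: n - lag]
        else:
            a, b = di0[: n + lag], dj0[-lag:]
        denom = np.sqrt((a @ a) * (b @ b))
        if denom <= 0:
            continue
        c = float(a @ b) / denom
        if c > best_c:
            best_c, best_lag = c, lag
    return best_lag, best_c


def global_activation_field(
    egms: SignalBlock,
    edges: np.ndarray,
    max_lag_ms: float = 30.0,
    cc_min: float = 0.5,
    mu: float = 1e-2,
) -> TimeMap:
    """Activation times fitted to pairwise inter-electrogram delays.

    For each mesh edge the delay is the lag maximizing the normalized
    cross-correlation of the two derivative traces (peak < ``cc_min`` drops
    the edge).  Node times then solve
    min sum w_ij (t_i - t_j - delta_ij)^2 + mu ||L t||^2 and the additive
    gauge is fixed by matching the mean of the per-node minimum-dV/dt
    estimates.
    """
    n = egms.n_channels
    raw = np.empty(n)
    for i in range(n):
        ti, ok = at_from_egm(egms.samples[i], egms.rate, egms.t0)
        raw[i] = ti if ok else np.nan
    if n == 1:
        return TimeMap(times=raw, valid=np.isfinite(raw), domain_tag="ecgi_nodes")

    d = _derivative(egms.samples, egms.rate)
    max_lag = int(round(max_lag_ms * egms.rate / 1000.0))
    rows, cols, dat, deltas, ws = [], [], [], [], []
    kept = []
    for k, (i, j) in enumerate(np.asarray(edges, dtype=int)):
        lag, c = _edge_delay(d[i], d[j], max_lag)
        if c < cc_min:
            continue
        kept.append((i, j))
        deltas.append(lag * 1000.0 / egms.rate)  # t_i - t_j estimate
        ws.append(c)
    if not kept:
        raise ComponentError("all delay edges dropped; no reliable correlations")
    kept = np.asarray(kept, dtype=int)
    t = fit_delay_field(
        kept,
        np.asarray(deltas),
        np.asarray(ws),
        n,
        laplacian_edges=np.asarray(edges, dtype=int),
        mu=mu,
        anchor=float(np.nanmean(raw)) if np.isfinite(np.nanmean(raw)) else None,
    )
    return TimeMap(times=t, valid=np.ones(n, dtype=bool), domain_tag="ecgi_nodes")


def graph_laplacian(edges: np.ndarray, n: int):
    """Unweighted graph Laplacian as a sparse matrix."""
    e = np.asarray(edges, dtype=int)
    A = coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n))
    A = ((A + A.T) > 0).astype(float)
    return coo_matrix(np.diag(np.asarray(A.sum(axis=1)).ravel())) - A


def fit_delay_field(
    edges: np.ndarray,
    deltas: np.ndarray,
    weights: np.ndarray,
    n: int,
    laplacian_edges: np.ndarray | None = None,
    mu: float = 1e-2,
    anchor: float | None = None,
) -> np.ndarray:
    """Weighted least-squares fit of node times to edge delays.

    Solves min sum_ij w_ij (t_i - t_j - delta_ij)^2 + mu ||L t||^2 where
    delta_ij estimates t_i - t_j; the additive gauge is fixed by shifting
    the mean to ``anchor`` (or zero).
    """
    edges = np.asarray(edges, dtype=int)
    if edges.size:
        adj = coo_matrix((np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(n, n))
        n_comp, _ = connected_components(adj + adj.T, directed=False)
        if n_comp > 1:
            raise ComponentError(
                f"delay graph split into {n_comp} components after edge dropping"
            )
    w = np.sqrt(np.asarray(weights, dtype=float))
    m = len(edges)
    inc = coo_matrix(
        (
            np.concatenate([w, -w]),
            (np.concatenate([np.arange(m), np.arange(m)]), np.concatenate([edges[:, 0], edges[:, 1]])),
        ),
        shape=(m, n),
    )
    L = graph_laplacian(laplacian_edges if laplacian_edges is not None else edges, n)
    system = sp_vstack([inc, np.sqrt(mu) * L]).tocsr()
    rhs = np.concatenate([w * np.asarray(deltas, dtype=float), np.zeros(n)])
    t = lsmr(system, rhs, atol=1e-14, btol=1e-14, maxiter=10000)[0]
    t = t - t.mean() + (anchor if anchor is not None else 0.0)
    return t
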