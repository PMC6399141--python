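"""Preprocessing of optical and electrical recordings.

Spatial/temporal uniform averaging, the 20%-amplitude data mask with
connected-component and morphological cleanup, multi-lead beat averaging,
camera-sync temporal alignment, and automated bad-channel screening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter
from skimage.measure import label
from skimage.morphology import closing as _closing, disk

from ecgitank.errors import (
    DataQualityError,
    EmptyMaskError,
    InsufficientBeatsError,
    InvalidParameterError,
    SyncError,
)
from ecgitank.electro import OpticalStack, SignalBlock

__all__ = [
    "DataMask",
    "spatial_average",
    "temporal_average",
    "compute_mask",
    "cleanup_mask",
    "beat_average",
    "detect_beat_starts",
    "sync_align",
    "decimate",
    "drop_bad_channels",
]


@dataclass
class DataMask:
    """Boolean pixel mask with the parameters that produced it."""

    grid: np.ndarray
    provenance: dict

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=bool)

    def to_csv(self, path) -> None:
        np.savetxt(path, self.grid.astype(int), fmt="%d", delimiter=",")

    @classmethod
    def from_csv(cls, path) -> "DataMask":
        grid = np.loadtxt(path, delimiter=",").astype(bool)
        return cls(grid=grid, provenance={"source": "csv"})

    def to_png(self, path) -> None:
        from PIL import Image

        Image.fromarray((self.grid * 255).astype(np.uint8)).save(path)


def spatial_average(stack: OpticalStack, kernel_mm: float = 2.1) -> OpticalStack:
    """Mask-restricted square-window spatial mean on every frame.

    Window side = round(kernel_mm / pixel_mm) pixels (3 px at 0.7 mm/px).
    Only in-mask pixels contribute and only in-mask pixels are replaced.
    """
    if kernel_mm <= 0:
        raise InvalidParameterError("kernel_mm must be positive")
    width = int(round(kernel_mm / stack.pixel_mm))
    if width <= 1:
        warnings.warn("spatial kernel smaller than one pixel; no-op", stacklevel=2)
        return stack.copy()
    out = stack.copy()
    m = stack.mask.astype(float)
    num = uniform_filter(stack.frames * m[:, :, None], size=(width, width, 1), mode="constant")
    den = uniform_filter(m, size=width, mode="constant")
    valid = den > 1e-12
    averaged = np.where(valid[:, :, None], num / np.where(valid, den, 1.0)[:, :, None], 0.0)
    out.frames = np.where(stack.mask[:, :, None], averaged, stack.frames)
    return out


def _odd_window(kernel_ms: float, rate: float) -> int:
    w = int(np.ceil(kernel_ms * rate / 1000.0))
    if w % 2 == 0:
        w += 1
    return max(w, 1)


def _moving_average(x: np.ndarray, w: int, axis: int) -> np.ndarray:
    """Uniform moving average with truncated windows at the edges."""
    x = np.moveaxis(x, axis, -1)
    kern = np.ones(w)
    num = np.apply_along_axis(lambda t: np.convolve(t, kern, mode="same"), -1, x)
    counts = np.convolve(np.ones(x.shape[-1]), kern, mode="same")
    return np.moveaxis(num / counts, -1, axis)


def temporal_average(signals, kernel_ms: float = 1.5):
    """Odd-length moving average spanning at least ``kernel_ms``.

    3 samples at 1 kHz for the 1.5 ms default; edges use truncated windows.
    Accepts a SignalBlock or an OpticalStack and returns the same type.
    """
    if kernel_ms <= 0:
        raise InvalidParameterError("kernel_ms must be positive")
    out = signals.copy()
    w = _odd_window(kernel_ms, signals.rate)
    if w <= 1:
        return out
    if isinstance(signals, OpticalStack):
        out.frames = _moving_average(signals.frames, w, axis=2)
    else:
        out.samples = _moving_average(signals.samples, w, axis=1)
    return out


def cleanup_mask(grid: np.ndarray, closing_radius: int = 1) -> np.ndarray:
    """Keep the largest 8-connected component, then morphological closing."""
    labels = label(grid, connectivity=2)
    if labels.max() == 0:
        return np.zeros_like(grid, dtype=bool)
    sizes = np.bincount(labels.ravel())[1:]
    keep = np.argmax(sizes) + 1
    grid = labels == keep
    if closing_radius > 0:
        grid = _closing(grid, disk(closing_radius)).astype(bool)
    return grid


def compute_mask(
    stack: OpticalStack, threshold_fraction: float = 0.2, closing_radius: int = 1
) -> DataMask:
    """Amplitude-based data mask: the 20% rule plus cleanup.

    Per-pixel amplitude is max-min over time; pixels below
    threshold_fraction of the global maximum amplitude are dropped, small
    components removed, and edges smoothed by dilation-erosion (closing).
    """
    if stack.n_frames == 0:
        raise InvalidParameterError("stack is empty")
    amplitude = stack.frames.max(axis=2) - stack.frames.min(axis=2)
    if amplitude.max() <= 0:
        raise EmptyMaskError("all pixels are flat; no signal to mask")
    grid = amplitude >= threshold_fraction * amplitude.max()
    if not grid.any():
        raise EmptyMaskError("no pixel exceeds the amplitude threshold")
    grid = cleanup_mask(grid, closing_radius)
    if not grid.any():
        raise EmptyMaskError("mask empty after cleanup")
    return DataMask(
        grid=grid,
        provenance={
            "threshold_fraction": threshold_fraction,
            "closing_radius": closing_radius,
        },
    )


# ---------------------------------------------------------------------------
# beat detection / averaging


def detect_beat_starts(signals: SignalBlock, cycle_samples: int | None = None):
    """Beat onsets on the cross-channel RMS trace.

    The cycle length comes from the dominant autocorrelation peak unless
    given; subsequent beats are aligned to the first by maximizing
    cross-correlation over integer lags within +/-10% of a cycle.
    Returns (starts, cycle_samples).
    """
    x = signals.samples[signals.valid]
    rms = np.sqrt(np.mean((x - x.mean(axis=1, keepdims=True)) ** 2, axis=0))
    n = len(rms)
    if cycle_samples is None:
        r = rms - rms.mean()
        ac = np.correlate(r, r, mode="full")[n - 1 :]
        min_lag = max(10, n // 20)
        if n - min_lag < 2:
            raise InsufficientBeatsError("recording too short for beat detection")
        cycle_samples = int(min_lag + np.argmax(ac[min_lag:]))
    n_beats = n // cycle_samples
    if n_beats < 1:
        raise InsufficientBeatsError("no full cycle in recording")
    first = rms[:cycle_samples]
    starts = [0]
    search = max(1, cycle_samples // 10)
    for k in range(1, n_beats):
        nominal = k * cycle_samples
        best_lag, best_c = 0, -np.inf
        for lag in range(-search, search + 1):
            s = nominal + lag
            if s < 0 or s + cycle_samples > n:
                continue
            c = float(first @ rms[s : s + cycle_samples])
            if c > best_c:
                best_c, best_lag = c, lag
        starts.append(nominal + best_lag)
    return np.array(starts, dtype=int), cycle_samples


def beat_average(signals: SignalBlock, n_beats: int, cycle_samples: int | None = None) -> SignalBlock:
    """Multi-lead signal averaging across aligned pacing cycles."""
    starts, cycle = detect_beat_starts(signals, cycle_samples)
    usable = [s for s in starts if s + cycle <= signals.n_samples]
    if len(usable) < n_beats:
        raise InsufficientBeatsError(f"detected {len(usable)} beats, need {n_beats}")
    acc = np.zeros((signals.n_channels, cycle))
    for s in usable[:n_beats]:
        acc += signals.samples[:, s : s + cycle]
    out = signals.copy()
    out.samples = acc / n_beats
    out.meta["beats_averaged"] = n_beats
    return out


# ---------------------------------------------------------------------------
# temporal sync and channel screening


def sync_align(electrical: SignalBlock, sync: np.ndarray, sync_rate: float | None = None):
    """Offset of the first camera-sync rising edge, and the re-referenced block.

    Threshold is half the sync amplitude; the electrical t0 is shifted so
    that optical frame 0 corresponds to electrical time ``offset``.
    Returns (offset_ms, shifted SignalBlock).
    """
    sync = np.asarray(sync, dtype=float)
    if sync_rate is None:
        sync_rate = electrical.rate
    lo, hi = sync.min(), sync.max()
    if hi - lo <= 0:
        raise SyncError("sync channel carries no edge")
    thr = (hi + lo) / 2.0
    above = sync >= thr
    edges = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if above[0]:
        edges = np.concatenate([[0], edges])
    if edges.size == 0:
        raise SyncError("no rising edge found in sync channel")
    offset_ms = float(edges[0] * 1000.0 / sync_rate)
    shifted = electrical.copy()
    shifted.t0 = electrical.t0 - offset_ms
    shifted.meta["sync_offset_ms"] = offset_ms
    return offset_ms, shifted


def decimate(signals: SignalBlock, factor: int = 2) -> SignalBlock:
    """Integer decimation to the optical timebase (no extra filtering:
    temporal averaging has already been applied upstream)."""
    out = signals.copy()
    out.samples = signals.samples[:, ::factor]
    out.rate = signals.rate / factor
    return out


def drop_bad_channels(signals: SignalBlock, sd_fraction: float = 0.01) -> SignalBlock:
    """Flag flatline and non-finite channels invalid.

    A channel is bad when its temporal SD is below ``sd_fraction`` of the
    median channel SD or it contains non-finite samples.  Raises when more
    than half the channels would be flagged.
    """
    sd = np.nanstd(signals.samples, axis=1)
    finite = np.all(np.isfinite(signals.samples), axis=1)
    med = np.median(sd[finite]) if finite.any() else 0.0
    bad = (~finite) | (sd < sd_fraction * med)
    if bad.sum() > 0.5 * signals.n_channels:
        raise DataQualityError(f"{bad.sum()} of {signals.n_channels} channels flagged bad")
    out = signals.copy()
    out.valid = signals.valid & ~bad
    return out
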