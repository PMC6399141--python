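"""Cross-domain map pairing and validation statistics.

Nearest-pixel pairing, Pearson correlation + RMSE map comparison,
distance-vs-time gradient profiles, paired t-tests, and mean +/- SD
summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ecgitank.camera import pair_points_to_mask
from ecgitank.errors import InvalidParameterError, PairingError, RoiError

__all__ = [
    "ComparisonResult",
    "GradientProfile",
    "pair_to_pixels",
    "compare_maps",
    "gradient_profile",
    "paired_ttest",
    "summarize",
]

PAIRING_CUTOFF_PX = 5.0


@dataclass
class ComparisonResult:
    cc: float | None
    rmse: float
    n_pairs: int
    pairs: list

    def __post_init__(self):
        if self.cc is not None and not -1.0 - 1e-12 <= self.cc <= 1.0 + 1e-12:
            raise InvalidParameterError("correlation outside [-1, 1]")
        if self.rmse < 0:
            raise InvalidParameterError("rmse must be non-negative")


@dataclass
class GradientProfile:
    roi: tuple
    ref_point: tuple
    samples: pd.DataFrame  # columns: distance_mm, time_ms, source

    def slope(self) -> float:
        """Least-squares slope of time vs distance (ms/mm)."""
        d = self.samples["distance_mm"].to_numpy()
        t = self.samples["time_ms"].to_numpy()
        return float(np.polyfit(d, t, 1)[0])


def pair_to_pixels(
    points_px: np.ndarray,
    mask: np.ndarray,
    visible: np.ndarray | None = None,
    cutoff_px: float = PAIRING_CUTOFF_PX,
):
    """Pair each visible projected point with its nearest in-mask pixel.

    Points farther than ``cutoff_px`` stay unpaired; ties break to the
    lowest (row, col).  Returns a list of (point_index, (row, col)).
    """
    points_px = np.atleast_2d(points_px)
    if visible is None:
        visible = np.all(np.isfinite(points_px), axis=1)
    if not np.asarray(mask, dtype=bool).any():
        raise PairingError("mask is empty")
    pairs = []
    idx = np.flatnonzero(visible)
    if idx.size:
        rc, dist = pair_points_to_mask(points_px[idx], mask, cutoff_px=cutoff_px)
        for k, i in enumerate(idx):
            if np.isfinite(dist[k]):
                pairs.append((int(i), (int(rc[k, 0]), int(rc[k, 1]))))
    if not pairs:
        raise PairingError("no point could be paired with an in-mask pixel")
    return pairs


def compare_maps(a, b, pairs=None) -> ComparisonResult:
    """Pearson correlation and RMSE between paired map values.

    ``a`` holds per-source values and ``b`` a per-pixel map when ``pairs``
    is given (as from :func:`pair_to_pixels`); with ``pairs=None`` both are
    flat arrays already in correspondence.  A constant input leaves the
    correlation undefined (None, with a warning); the RMSE is still
    returned.
    """
    if pairs is not None:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        src = np.array([p[0] for p in pairs])
        rc = np.array([p[1] for p in pairs])
        av = a[src]
        bv = b[rc[:, 0], rc[:, 1]]
        pair_list = list(pairs)
    else:
        av = np.asarray(a, dtype=float)
        bv = np.asarray(b, dtype=float)
        pair_list = list(zip(range(len(av)), range(len(bv))))
    ok = np.isfinite(av) & np.isfinite(bv)
    av, bv = av[ok], bv[ok]
    pair_list = [p for p, o in zip(pair_list, ok) if o]
    if len(av) < 3:
        raise InvalidParameterError("need at least 3 valid pairs")
    rmse = float(np.sqrt(np.mean((av - bv) ** 2)))
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        warnings.warn("constant map; correlation undefined", stacklevel=2)
        cc = None
    else:
        cc = float(stats.pearsonr(av, bv)[0])
    return ComparisonResult(cc=cc, rmse=rmse, n_pairs=len(av), pairs=pair_list)


def gradient_profile(
    times: np.ndarray,
    valid: np.ndarray,
    roi: tuple,
    ref_point: tuple,
    pixel_mm: float,
    source: str = "optical",
) -> GradientProfile:
    """Times of valid in-ROI pixels against distance from a reference pixel.

    ``roi`` is (row0, row1, col0, col1), half-open; ``ref_point`` is
    (row, col).  Samples are sorted by distance.
    """
    r0, r1, c0, c1 = roi
    sub_t = np.asarray(times, dtype=float)[r0:r1, c0:c1]
    sub_v = np.asarray(valid, dtype=bool)[r0:r1, c0:c1]
    rows, cols = np.nonzero(sub_v & np.isfinite(sub_t))
    if rows.size == 0:
        raise RoiError("region of interest contains no valid pixels")
    rr = rows + r0
    cc = cols + c0
    dist = pixel_mm * np.hypot(rr - ref_point[0], cc - ref_point[1])
    df = pd.DataFrame(
        {"distance_mm": dist, "time_ms": sub_t[rows, cols], "source": source}
    ).sort_values("distance_mm", kind="stable", ignore_index=True)
    return GradientProfile(roi=tuple(roi), ref_point=tuple(ref_point), samples=df)


def paired_ttest(x, y):
    """Classical paired t statistic with a two-sided p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidParameterError("paired samples must have equal length")
    if x.size < 2:
        raise InvalidParameterError("paired t-test requires n >= 2")
    diff = x - y
    if np.all(diff == 0):
        return 0.0, 1.0
    t, p = stats.ttest_rel(x, y)
    return float(t), float(p)


def summarize(values):
    """Arithmetic mean and sample (n-1) SD; SD is None for n < 2."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InvalidParameterError("cannot summarize an empty sequence")
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size >= 2 else None
    return mean, sd
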