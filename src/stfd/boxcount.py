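"""Box-counting (Minkowski-Bouligand) dimension estimation.

The dimension of a point cloud on [0, 1)^d is estimated as the least-squares
slope of log n(r) vs log r, where n(r) is the number of occupied cells of the
regular grid that divides each axis into r parts.  Counting uses a mixed-radix
integer key per point instead of allocating an r^d occupancy array.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .activation import PointCloud, SourceEpoch, binarize_epoch, cloud_4d, normalize_coords

__all__ = [
    "DEFAULT_RESOLUTIONS",
    "DEFAULT_FIT_RANGE",
    "BoxCountCurve",
    "FDSeries",
    "count_boxes",
    "fd_estimate",
    "fd_series",
]

logger = logging.getLogger(__name__)

#: Grid resolutions: powers of two from 1 to 128.
DEFAULT_RESOLUTIONS: Tuple[int, ...] = (1, 2, 4, 8, 16, 32, 64, 128)
#: Scaling range used for the log-log regression.
DEFAULT_FIT_RANGE: Tuple[int, int] = (8, 64)


@dataclass(frozen=True)
class BoxCountCurve:
    """Occupied-box counts across resolutions plus the fitted slope."""

    resolutions: Tuple[int, ...]
    counts: Tuple[int, ...]
    fit_range: Tuple[int, int]
    slope: float
    r2: float

    def to_tsv(self) -> str:
        lines = ["r\tn_r"]
        lines += [f"{r}\t{n}" for r, n in zip(self.resolutions, self.counts)]
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class FDSeries:
    """Per-window fractal-dimension estimates for one subject."""

    subject_id: str
    window_seconds: float
    values: Tuple[float, ...]

    @property
    def mean_fd(self) -> float:
        return float(np.mean(self.values))

    def to_tsv(self) -> str:
        lines = ["subject_id\twindow_index\tfd"]
        lines += [
            f"{self.subject_id}\t{i}\t{v:.6f}" for i, v in enumerate(self.values)
        ]
        return "\n".join(lines) + "\n"


def count_boxes(cloud: PointCloud, r: int) -> int:
    """Number of occupied cells of the r-per-axis grid on [0, 1)^dim."""
    if r < 1:
        raise ValueError("resolution r must be >= 1")
    if cloud.n_points == 0:
        raise ValueError("cannot count boxes of empty set")
    idx = (cloud.points * r).astype(np.int64)
    # coordinates live in [0, 1) so indices are already in [0, r); guard the
    # pathological float where p * r rounds up to r
    np.clip(idx, 0, r - 1, out=idx)
    key = idx[:, 0].copy()
    for axis in range(1, cloud.dim):
        key *= r
        key += idx[:, axis]
    return int(np.unique(key).size)


def _validate_resolutions(resolutions: Sequence[int]) -> Tuple[int, ...]:
    res = tuple(int(r) for r in resolutions)
    if len(res) < 2:
        raise ValueError("need at least two resolutions")
    for r in res:
        if r < 1 or (r & (r - 1)) != 0:
            raise ValueError(f"resolutions must be powers of two, got {r}")
    if any(b <= a for a, b in zip(res, res[1:])):
        raise ValueError("resolutions must be strictly ascending")
    return res


def fd_estimate(
    cloud: PointCloud,
    resolutions: Sequence[int] = DEFAULT_RESOLUTIONS,
    fit_range: Tuple[int, int] = DEFAULT_FIT_RANGE,
) -> BoxCountCurve:
    """Count boxes across ``resolutions`` and fit the log-log slope.

    The slope is fitted by unweighted least squares over the resolutions
    inside ``fit_range`` (inclusive endpoints, which must belong to
    ``resolutions`` and span at least 3 points).
    """
    res = _validate_resolutions(resolutions)
    r_min, r_max = fit_range
    if r_min not in res or r_max not in res:
        raise ValueError("fit_range endpoints must be members of resolutions")
    fit_res = [r for r in res if r_min <= r <= r_max]
    if len(fit_res) < 3:
        raise ValueError("fit range must contain at least 3 resolutions")
    if cloud.n_points == 0:
        raise ValueError("cannot estimate dimension of empty cloud")

    counts = tuple(count_boxes(cloud, r) for r in res)
    log_r = np.log([r for r in res if r in fit_res])
    log_n = np.log([n for r, n in zip(res, counts) if r in fit_res])
    if np.ptp(log_n) == 0.0:
        # flat curve (e.g. single point): dimension 0, perfect fit
        slope, r2 = 0.0, 1.0
    else:
        fit = stats.linregress(log_r, log_n)
        slope, r2 = float(fit.slope), float(fit.rvalue**2)
    return BoxCountCurve(
        resolutions=res,
        counts=counts,
        fit_range=(int(r_min), int(r_max)),
        slope=slope,
        r2=r2,
    )


def fd_series(
    epoch: SourceEpoch,
    window_seconds: float = 1.0,
    resolutions: Sequence[int] = DEFAULT_RESOLUTIONS,
    fit_range: Tuple[int, int] = DEFAULT_FIT_RANGE,
    bbox: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> FDSeries:
    """Per-window 4D fractal dimension of an epoch.

    The epoch is binarized once (threshold over all samples), coordinates are
    normalized once (per-subject bounding box unless an explicit ``bbox`` is
    supplied), and each consecutive non-overlapping window of
    ``round(fs * window_seconds)`` samples yields one FD estimate.  A trailing
    partial window is discarded.  An empty window gets FD = 0 with a warning
    so the series length stays fixed.
    """
    n_window = int(round(epoch.fs * window_seconds))
    if n_window < 1 or epoch.n_samples < n_window:
        raise ValueError("epoch shorter than one window")
    mask = binarize_epoch(epoch)
    norm, _ = normalize_coords(epoch.coords, bbox=bbox)
    n_windows = epoch.n_samples // n_window

    values = []
    for w in range(n_windows):
        cloud = cloud_4d(mask, norm, w * n_window, n_window)
        if cloud.n_points == 0:
            logger.warning(
                "subject %s window %d: no supra-threshold activations, FD set to 0",
                epoch.subject_id,
                w,
            )
            values.append(0.0)
            continue
        try:
            curve = fd_estimate(cloud, resolutions=resolutions, fit_range=fit_range)
        except ValueError as exc:
            raise ValueError(
                f"subject {epoch.subject_id} window {w}: {exc}"
            ) from exc
        values.append(curve.slope)
    return FDSeries(
        subject_id=epoch.subject_id,
        window_seconds=float(window_seconds),
        values=tuple(values),
    )
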