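"""Binarization of source epochs and construction of 3D/4D point clouds.

A source is considered *active* at a sample when the absolute value of its
current amplitude strictly exceeds that source's epoch-wide threshold
(mean + sample SD of the absolute amplitudes).  Active sources at a sample
define a 3D point cloud in normalized coordinates; stacking the clouds of a
window of samples along a normalized time axis yields a 4D cloud.
"""

from __future__ import annotations

from dataclasses import InitVar, dataclass
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "SourceEpoch",
    "ActivationMask",
    "PointCloud",
    "binarize_epoch",
    "normalize_coords",
    "cloud_3d",
    "cloud_4d",
]

#: Largest double below 1.0 — the top of every half-open [0, 1) axis.
_ONE_MINUS = np.nextafter(1.0, 0.0)


@dataclass(frozen=True)
class SourceEpoch:
    """A real-valued source-space epoch.

    Parameters
    ----------
    values : ndarray, shape (n_sources, n_samples)
        Source current amplitudes (arbitrary units).
    coords : ndarray, shape (n_sources, 3)
        3D source positions (mm).
    fs : float
        Sampling rate in Hz.
    subject_id : str
    group : str or None
        Cohort label, e.g. ``"groupA"`` / ``"groupB"``.
    """

    values: np.ndarray
    coords: np.ndarray
    fs: float
    subject_id: str = "subject"
    group: Optional[str] = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        coords = np.asarray(self.coords, dtype=float)
        if values.ndim != 2 or values.shape[0] < 1 or values.shape[1] < 1:
            raise ValueError("values must be a non-empty n_sources x n_samples matrix")
        if coords.ndim != 2 or coords.shape != (values.shape[0], 3):
            raise ValueError("coords must have shape (n_sources, 3)")
        if not np.isfinite(values).all():
            raise ValueError("values contains non-finite entries")
        if not np.isfinite(coords).all():
            raise ValueError("coords contains non-finite entries")
        if not (self.fs > 0):
            raise ValueError("fs must be positive")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "coords", coords)

    @property
    def n_sources(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        """Epoch duration in seconds."""
        return self.n_samples / self.fs


@dataclass(frozen=True)
class ActivationMask:
    """Boolean supra-threshold mask with its per-source thresholds."""

    mask: np.ndarray
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        thresholds = np.asarray(self.thresholds, dtype=float)
        if mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if thresholds.shape != (mask.shape[0],):
            raise ValueError("thresholds must have one entry per source")
        if (thresholds < 0).any():
            raise ValueError("thresholds must be non-negative")
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "thresholds", thresholds)

    @property
    def n_sources(self) -> int:
        return self.mask.shape[0]

    @property
    def n_samples(self) -> int:
        return self.mask.shape[1]


@dataclass(frozen=True)
class PointCloud:
    """A deduplicated set of points on the half-open unit hypercube.

    ``points`` is an (n, dim) array with every coordinate in [0, 1).
    ``assume_deduplicated`` skips the unique-rows pass for callers that
    construct provably duplicate-free point sets (e.g. lattices).
    """

    dim: int
    points: np.ndarray
    provenance: str = ""
    assume_deduplicated: InitVar[bool] = False

    def __post_init__(self, assume_deduplicated: bool) -> None:
        if self.dim < 1:
            raise ValueError("dim must be a positive integer")
        pts = np.asarray(self.points, dtype=float).reshape(-1, self.dim)
        if pts.size:
            if not np.isfinite(pts).all():
                raise ValueError("points contain non-finite coordinates")
            if (pts < 0).any() or (pts >= 1).any():
                raise ValueError("coordinates must lie in [0, 1)")
            if not assume_deduplicated:
                pts = np.unique(pts, axis=0)
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


def binarize_epoch(epoch: SourceEpoch) -> ActivationMask:
    """Threshold an epoch into a boolean activation mask.

    For each source the threshold is ``mean(|x|) + sd(|x|)`` computed over the
    *full* epoch (sample SD, N-1 denominator); a source is active at a sample
    iff its absolute amplitude is strictly greater than the threshold.
    """
    if epoch.n_samples < 2:
        raise ValueError("epoch too short for threshold estimation")
    absvals = np.abs(epoch.values)
    thresholds = absvals.mean(axis=1) + absvals.std(axis=1, ddof=1)
    mask = absvals > thresholds[:, None]
    return ActivationMask(mask=mask, thresholds=thresholds)


def normalize_coords(
    coords: np.ndarray,
    bbox: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> Tuple[np.ndarray, Tuple[np.ndarray, np.ndarray]]:
    """Affinely map coordinates onto the half-open unit cube.

    Each axis of the bounding box (computed from ``coords`` unless an explicit
    ``bbox = (lo, hi)`` is given, e.g. a cohort-level box) is mapped onto
    [0, 1); the maximum lands just below 1 so it falls in the last grid cell.
    A degenerate axis (zero extent) maps to 0.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 1:
        raise ValueError("need at least one coordinate row")
    if not np.isfinite(coords).all():
        raise ValueError("coordinates must be finite")
    if bbox is None:
        lo, hi = coords.min(axis=0), coords.max(axis=0)
    else:
        lo, hi = (np.asarray(b, dtype=float) for b in bbox)
    extent = hi - lo
    out = np.zeros_like(coords)
    live = extent > 0
    out[:, live] = (coords[:, live] - lo[live]) / extent[live]
    np.clip(out, 0.0, _ONE_MINUS, out=out)
    return out, (lo, hi)


def cloud_3d(mask: ActivationMask, norm_coords: np.ndarray, t: int) -> PointCloud:
    """Normalized 3D positions of the sources active at sample ``t``."""
    if not 0 <= t < mask.n_samples:
        raise IndexError(f"sample index {t} out of range [0, {mask.n_samples})")
    pts = norm_coords[mask.mask[:, t]]
    return PointCloud(dim=3, points=pts, provenance=f"t={t}")


def cloud_4d(
    mask: ActivationMask,
    norm_coords: np.ndarray,
    t0: int,
    n_window: int,
) -> PointCloud:
    """4D cloud for the half-open sample window [t0, t0 + n_window).

    Each active (source, sample) pair contributes the source's normalized 3D
    position plus the within-window time coordinate ``(t - t0) / n_window``,
    so the time axis spans [0, 1) like the spatial axes.
    """
    if n_window < 1:
        raise ValueError("window must contain at least one sample")
    if t0 < 0 or t0 + n_window > mask.n_samples:
        raise ValueError(
            f"window [{t0}, {t0 + n_window}) extends past epoch end "
            f"({mask.n_samples} samples)"
        )
    src, tt = np.nonzero(mask.mask[:, t0 : t0 + n_window])
    pts = np.column_stack([norm_coords[src], tt / n_window])
    return PointCloud(dim=4, points=pts, provenance=f"window=[{t0},{t0 + n_window})")
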