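"""Synthetic inputs: fractal validation clouds and two-group source epochs.

Two generators:

* :func:`make_fractal` builds point clouds whose box-counting dimension is
  known analytically (lines, planes, filled cubes, Cantor products, an
  extruded Sierpinski carpet) for estimator validation.
* :func:`simulate_epoch` / :func:`simulate_cohort` build source epochs with
  spatially clustered, temporally evolving activations; the two groups differ
  in the spatial dispersion of the clusters, so the patient-like group yields
  more diffuse supra-threshold sets and a higher spatio-temporal dimension.

The epoch generator targets the statistical structure the analysis assumes,
not biophysical realism: there is no forward or inverse modelling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterator, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats

from .activation import PointCloud, SourceEpoch

__all__ = [
    "FractalSpec",
    "CohortSpec",
    "analytic_dimension",
    "make_fractal",
    "simulate_epoch",
    "simulate_cohort",
    "simulate_scores",
]

_LOG2_LOG3 = math.log(2.0) / math.log(3.0)

FRACTAL_FAMILIES = (
    "uniform_hypercube",
    "line",
    "plane",
    "cantor_product",
    "sierpinski_carpet_extrusion",
)


@dataclass(frozen=True)
class FractalSpec:
    """Recipe for a validation point cloud of known dimension.

    ``grid`` requests a deterministic lattice (points per axis at cell
    centers) where the family supports it; ``n_points`` requests that many
    random samples from the set.  ``level`` is the construction depth of the
    Cantor / carpet families.
    """

    family: str
    dim: int = 3
    level: int = 7
    n_points: Optional[int] = None
    grid: Optional[int] = None
    seed: int = 0


def analytic_dimension(spec: FractalSpec) -> float:
    """Exact Hausdorff (= box-counting) dimension of the specified family."""
    if spec.family == "uniform_hypercube":
        return float(spec.dim)
    if spec.family == "line":
        return 1.0
    if spec.family == "plane":
        return 2.0
    if spec.family == "cantor_product":
        return spec.dim * _LOG2_LOG3
    if spec.family == "sierpinski_carpet_extrusion":
        return math.log(8.0) / math.log(3.0) + 1.0
    raise ValueError(f"unknown fractal family: {spec.family}")


def _cantor_axis_values(level: int) -> np.ndarray:
    """Left endpoints of the 2**level middle-thirds Cantor intervals."""
    vals = np.zeros(1)
    for k in range(1, level + 1):
        vals = np.concatenate([vals, vals + 2.0 * 3.0**-k])
    return np.sort(vals)


def _sample_cantor(rng: np.random.Generator, n: int, level: int) -> np.ndarray:
    digits = rng.integers(0, 2, size=(n, level)) * 2.0
    scales = 3.0 ** -np.arange(1, level + 1)
    return digits @ scales


def _sample_carpet(rng: np.random.Generator, n: int, level: int) -> np.ndarray:
    # the 8 retained sub-cells of the Sierpinski carpet (all but the center)
    cells = np.array([(i, j) for i in range(3) for j in range(3) if (i, j) != (1, 1)])
    choice = rng.integers(0, 8, size=(n, level))
    xy = np.zeros((n, 2))
    for k in range(level):
        xy += cells[choice[:, k]] * 3.0 ** -(k + 1)
    return xy


def make_fractal(spec: FractalSpec) -> Tuple[PointCloud, float]:
    """Build the point cloud and return it with its analytic dimension."""
    dim_value = analytic_dimension(spec)  # validates family
    if spec.dim < 2:
        raise ValueError("fractal clouds need dim >= 2")
    rng = np.random.default_rng(spec.seed)

    if spec.family == "uniform_hypercube":
        if spec.grid is not None:
            axes = [(np.arange(spec.grid) + 0.5) / spec.grid] * spec.dim
            mesh = np.meshgrid(*axes, indexing="ij")
            pts = np.stack([m.ravel() for m in mesh], axis=1)
            unique = True
        else:
            n = spec.n_points or 100_000
            pts = rng.random((n, spec.dim))
            unique = False
    elif spec.family == "line":
        n = spec.n_points or 10_000
        t = (np.arange(n) + 0.5) / n
        pts = np.tile(t[:, None], (1, spec.dim))
        unique = True
    elif spec.family == "plane":
        if spec.grid is not None:
            ax = (np.arange(spec.grid) + 0.5) / spec.grid
            u, v = np.meshgrid(ax, ax, indexing="ij")
            uv = np.stack([u.ravel(), v.ravel()], axis=1)
        else:
            uv = rng.random((spec.n_points or 100_000, 2))
        pts = np.full((len(uv), spec.dim), 0.5)
        pts[:, :2] = uv
        unique = False
    elif spec.family == "cantor_product":
        full_size = (2**spec.level) ** spec.dim
        if full_size <= 2**22:
            axis = _cantor_axis_values(spec.level)
            mesh = np.meshgrid(*([axis] * spec.dim), indexing="ij")
            pts = np.stack([m.ravel() for m in mesh], axis=1)
            unique = True
        else:
            n = spec.n_points or 2_000_000
            pts = np.stack(
                [_sample_cantor(rng, n, spec.level) for _ in range(spec.dim)], axis=1
            )
            unique = False
    elif spec.family == "sierpinski_carpet_extrusion":
        if spec.dim != 3:
            raise ValueError("sierpinski_carpet_extrusion is defined for dim=3 only")
        n = spec.n_points or 1_000_000
        xy = _sample_carpet(rng, n, spec.level)
        z = rng.random(n)
        pts = np.column_stack([xy, z])
        unique = False
    else:  # pragma: no cover - guarded by analytic_dimension
        raise ValueError(f"unknown fractal family: {spec.family}")

    cloud = PointCloud(
        dim=spec.dim,
        points=pts,
        provenance=f"{spec.family}(level={spec.level}, seed={spec.seed})",
        assume_deduplicated=unique,
    )
    return cloud, dim_value


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a two-group synthetic cohort.

    Desk-scale defaults keep a full cohort tractable on one CPU;
    :meth:`paper_scale` restores the original recording geometry
    (15,002 sources, 500 Hz, 120 s, 27 + 15 subjects).
    """

    n_groupA: int = 27
    n_groupB: int = 15
    n_sources: int = 2_000
    fs: float = 100.0
    epoch_seconds: float = 20.0
    dispersion_A: float = 25.0  # mm, spatial scale of groupA cluster bumps
    dispersion_B: float = 12.0
    n_clusters: int = 40
    temporal_jump_rate: float = 0.02  # relocation probability per sample
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_groupA, self.n_groupB, self.n_sources, self.n_clusters) < 1:
            raise ValueError("all counts must be >= 1")
        if self.dispersion_A <= 0 or self.dispersion_B <= 0:
            raise ValueError("dispersions must be positive")
        if not 0.0 <= self.temporal_jump_rate <= 1.0:
            raise ValueError("temporal_jump_rate must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.fs <= 0 or self.epoch_seconds <= 0:
            raise ValueError("fs and epoch_seconds must be positive")

    def paper_scale(self) -> "CohortSpec":
        return replace(self, n_sources=15_002, fs=500.0, epoch_seconds=120.0)

    @property
    def subject_ids(self) -> Tuple[str, ...]:
        a = tuple(f"A{i + 1:02d}" for i in range(self.n_groupA))
        b = tuple(f"B{i + 1:02d}" for i in range(self.n_groupB))
        return a + b

    def group_of(self, subject_id: str) -> str:
        return "groupA" if subject_id.startswith("A") else "groupB"


def _cortical_shell(n: int, rng: np.random.Generator) -> np.ndarray:
    """Source positions on a deformed spherical shell (mm)."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    radii = 70.0 + rng.normal(0.0, 3.0, size=n)
    coords = v * radii[:, None]
    coords[:, 0] *= 1.1  # slight antero-posterior elongation
    coords[:, 2] *= 0.8  # flattened inferior-superior axis
    return coords


def _ou_path(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary zero-mean AR(1) (discretized Ornstein-Uhlenbeck) path."""
    phi = math.exp(-1.0 / (0.25 * fs))  # 250 ms correlation time
    innov = rng.normal(0.0, math.sqrt(1.0 - phi * phi), size=n)
    innov[0] = rng.normal()
    return sp_signal.lfilter([1.0], [1.0, -phi], innov)


def simulate_epoch(spec: CohortSpec, subject_index: int) -> SourceEpoch:
    """Simulate one subject's source epoch.

    The subject RNG stream is derived from ``(spec.seed, subject_index)``,
    so each epoch is reproducible independently of generation order.  The
    signal is a sum of ``n_clusters`` Gaussian spatial bumps (scale = the
    group's dispersion) carrying Ornstein-Uhlenbeck amplitude paths; each
    cluster relocates to a random source with probability
    ``temporal_jump_rate`` per sample.  Because the per-source threshold rule
    is scale-invariant, essentially all variance must live at the cluster
    scale for the supra-threshold sets to be spatially coherent: the i.i.d.
    noise term is a small jitter (tie-breaking), not a competing signal.
    Larger dispersion produces more spatially diffuse excursion sets and a
    higher spatio-temporal dimension.
    """
    ids = spec.subject_ids
    if not 0 <= subject_index < len(ids):
        raise IndexError("subject_index out of range")
    subject_id = ids[subject_index]
    group = spec.group_of(subject_id)
    dispersion = spec.dispersion_A if group == "groupA" else spec.dispersion_B

    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, subject_index)))
    coords = _cortical_shell(spec.n_sources, rng)
    n_t = int(round(spec.fs * spec.epoch_seconds))

    if spec.noise_sd > 0:
        values = rng.normal(0.0, spec.noise_sd, size=(spec.n_sources, n_t))
    else:
        values = np.zeros((spec.n_sources, n_t))

    inv_two_sigma2 = 1.0 / (2.0 * dispersion * dispersion)
    for _ in range(spec.n_clusters):
        amp = _ou_path(n_t, spec.fs, rng)
        jumps = rng.random(n_t) < spec.temporal_jump_rate
        jumps[0] = True
        starts = np.flatnonzero(jumps)
        ends = np.append(starts[1:], n_t)
        for s, e in zip(starts, ends):
            center = coords[rng.integers(spec.n_sources)]
            d2 = np.sum((coords - center) ** 2, axis=1)
            bump = np.exp(-d2 * inv_two_sigma2)
            values[:, s:e] += bump[:, None] * amp[s:e][None, :]

    return SourceEpoch(
        values=values, coords=coords, fs=spec.fs, subject_id=subject_id, group=group
    )


def simulate_cohort(spec: CohortSpec) -> Iterator[SourceEpoch]:
    """Yield the epochs of the full cohort (groupA subjects first)."""
    for i in range(len(spec.subject_ids)):
        yield simulate_epoch(spec, i)


# ---------------------------------------------------------------------------
# clinical-score simulation
# ---------------------------------------------------------------------------

#: (column, sign, center, scale, lo, hi, step) for the latent-factor scores
_SCORE_LAYOUT = (
    ("updrs3", +1.0, 32.0, 14.0, 0.0, 132.0, 1.0),
    ("hoehn_yahr", +1.0, 2.0, 0.75, 1.0, 5.0, 0.5),
    ("moca", -1.0, 24.0, 3.0, 0.0, 30.0, 1.0),
    ("mmp", -1.0, 26.0, 3.2, 0.0, 32.0, 1.0),
)


def simulate_scores(
    summary: pd.DataFrame,
    correlation_with_fd: float = 0.0,
    loading: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Demographic and clinical columns for a cohort summary table.

    Clinical scores follow a one-factor model: each score loads with
    magnitude ``loading`` on a common latent severity factor, which in turn
    correlates with the normal scores of each subject's ``mean_fd`` so that
    the target score-FD correlation is approximately ``correlation_with_fd``
    (default 0: no association).  Scores are clipped to instrument bounds and
    rounded to instrument resolution; clinical columns are produced for
    groupA subjects only, demographics for everyone.
    """
    if not 0.0 < loading <= 1.0:
        raise ValueError("loading must lie in (0, 1]")
    if abs(correlation_with_fd) > loading:
        raise ValueError("correlation_with_fd magnitude cannot exceed loading")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x5C0)))
    out = summary.copy()
    n = len(out)
    out["age"] = np.round(rng.normal(67.0, 6.0, size=n)).clip(40, 90)
    out["education"] = np.round(rng.normal(12.0, 4.0, size=n)).clip(0, 22)
    out["sex"] = np.where(rng.random(n) < 0.5, "F", "M")

    is_a = (out["group"] == "groupA").to_numpy()
    n_a = int(is_a.sum())
    for col, *_ in _SCORE_LAYOUT:
        out[col] = np.nan
    out["disease_duration"] = np.nan
    if n_a == 0:
        return out

    fd = out.loc[is_a, "mean_fd"].to_numpy(dtype=float)
    # normal scores of the FD ranks: Spearman-faithful latent for the factor
    z = stats.norm.ppf((stats.rankdata(fd) - 0.5) / n_a)
    c = correlation_with_fd / loading
    factor = c * z + math.sqrt(max(0.0, 1.0 - c * c)) * rng.normal(size=n_a)
    resid = math.sqrt(max(0.0, 1.0 - loading * loading))
    for col, sign, center, scale, lo, hi, step in _SCORE_LAYOUT:
        raw = sign * loading * factor + resid * rng.normal(size=n_a)
        vals = center + scale * raw
        vals = np.round(vals / step) * step
        out.loc[is_a, col] = np.clip(vals, lo, hi)
    out.loc[is_a, "disease_duration"] = np.round(
        rng.normal(6.0, 3.0, size=n_a).clip(0.5, 20.0), 1
    )
    return out
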