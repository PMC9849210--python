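"""Seed-based resting-state functional connectivity (rsFC).

Operates on preprocessed 4-D BOLD volumes: steady-state trimming, motion
censoring, nuisance regression, spherical seed extraction, voxel-wise seed
correlation maps, Fisher r-to-z, and circuit-level (seed-to-cluster) rsFC
values.  Spatial preprocessing (registration, segmentation, smoothing) is
assumed done upstream; seed coordinates are given in the volumes' own
millimeter space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ConfigurationError,
    DegenerateDataError,
    DesignError,
    InsufficientDataError,
)

__all__ = [
    "Volume4D",
    "MotionTrace",
    "TissueMasks",
    "SeedSpec",
    "ConnectivityMap",
    "framewise_displacement",
    "trim_initial_volumes",
    "censor_frames",
    "build_confound_matrix",
    "nuisance_regress",
    "sphere_mask",
    "extract_roi_series",
    "seed_map",
    "fisher_z",
    "circuit_rsfc",
    "ATANH_CLIP",
]

# correlations are clipped to ±(1 - 1e-7) before atanh so self-correlations
# map to a large finite z instead of infinity
ATANH_CLIP = 1.0 - 1e-7


@dataclass
class Volume4D:
    """4-D BOLD series with a voxel-to-mm affine and repetition time."""

    data: np.ndarray  # (x, y, z, t)
    affine: np.ndarray  # 4x4 voxel index -> mm
    tr_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ConfigurationError(f"volume must be 4-D; got {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ConfigurationError("affine must be 4x4")
        if not np.all(np.isfinite(self.data)):
            raise ConfigurationError("volume contains non-finite values")
        if not self.tr_s > 0:
            raise ConfigurationError("tr_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_mm(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)


@dataclass
class MotionTrace:
    """Per-frame rigid-body motion: 3 translations (mm), 3 rotations (rad)."""

    params: np.ndarray  # (t, 6)

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ConfigurationError("motion params must be (t, 6)")

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]

    @property
    def derivatives(self) -> np.ndarray:
        """Frame-to-frame differences (first frame backfilled with zero)."""
        return np.diff(self.params, axis=0, prepend=self.params[:1])

    def displacement(self, rotation_radius_mm: float = 50.0) -> np.ndarray:
        return framewise_displacement(self.params, rotation_radius_mm)


@dataclass
class TissueMasks:
    """Boolean tissue masks on the volume grid."""

    wm: np.ndarray
    csf: np.ndarray
    brain: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wm = np.asarray(self.wm, dtype=bool)
        self.csf = np.asarray(self.csf, dtype=bool)
        if self.wm.shape != self.csf.shape:
            raise ConfigurationError("wm and csf masks must share a shape")
        if self.brain is not None:
            self.brain = np.asarray(self.brain, dtype=bool)


@dataclass
class SeedSpec:
    """Spherical seed: name, center in mm, radius in mm (default 10)."""

    name: str
    center: tuple[float, float, float]
    radius: float = 10.0

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ConfigurationError("seed radius must be positive")
        self.center = tuple(float(c) for c in self.center)
        if len(self.center) != 3:
            raise ConfigurationError("seed center must have 3 coordinates")


@dataclass
class ConnectivityMap:
    """Per-voxel seed correlation, either raw r or Fisher z."""

    values: np.ndarray
    kind: str  # "r" | "z"
    degenerate: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("r", "z"):
            raise ConfigurationError("kind must be 'r' or 'z'")
        if self.kind == "r" and np.any(np.abs(self.values) > 1 + 1e-9):
            raise ConfigurationError("r-kind map has values outside [-1, 1]")


def framewise_displacement(
    params: np.ndarray, rotation_radius_mm: float = 50.0
) -> np.ndarray:
    """Scalar per-frame motion: Euclidean norm of the frame-to-frame
    translation plus the rotation converted to arc length on a
    ``rotation_radius_mm`` sphere.  The first frame has zero displacement.
    """
    p = np.asarray(params, dtype=float)
    d = np.diff(p, axis=0, prepend=p[:1])
    return np.linalg.norm(d[:, :3], axis=1) + rotation_radius_mm * np.linalg.norm(
        d[:, 3:], axis=1
    )


def trim_initial_volumes(
    vol: Volume4D, n: int = 4, motion: MotionTrace | None = None
):
    """Drop the first ``n`` frames (magnetization steady state).

    Returns the trimmed volume, or ``(volume, motion)`` when a motion trace
    is supplied.
    """
    if n < 0:
        raise ConfigurationError("n must be non-negative")
    if vol.n_frames <= n:
        raise InsufficientDataError(
            f"cannot trim {n} of {vol.n_frames} frames"
        )
    out = Volume4D(vol.data[..., n:], vol.affine, vol.tr_s)
    if motion is None:
        return out
    if motion.n_frames != vol.n_frames:
        raise ConfigurationError("motion trace not aligned to volume")
    return out, MotionTrace(motion.params[n:])


def censor_frames(
    motion, threshold_mm: float = 0.2, min_retained: int = 8
) -> np.ndarray:
    """Indices of frames retained after motion censoring.

    Every frame whose displacement exceeds ``threshold_mm`` is censored
    together with its immediate temporal neighbors (one frame on either
    side).  Raises when fewer than ``min_retained`` frames survive.
    """
    disp = motion.displacement() if isinstance(motion, MotionTrace) else np.asarray(
        motion, dtype=float
    )
    bad = disp > threshold_mm
    censored = bad.copy()
    censored[:-1] |= bad[1:]
    censored[1:] |= bad[:-1]
    retained = np.flatnonzero(~censored)
    if retained.size < min_retained:
        raise InsufficientDataError(
            f"only {retained.size} frames retained after censoring (<{min_retained})"
        )
    return retained


def _mask_mean_series(data4d: np.ndarray, mask: np.ndarray) -> np.ndarray:
    if not mask.any():
        raise DegenerateDataError("empty mask")
    return data4d[mask].mean(axis=0)


def build_confound_matrix(
    motion: MotionTrace,
    wm_series: np.ndarray,
    csf_series: np.ndarray,
    frame_indices: np.ndarray | None = None,
) -> np.ndarray:
    """Nuisance design: intercept, linear trend, 6 motion parameters, their
    6 temporal derivatives, and the WM and CSF mean time courses.

    ``frame_indices`` selects the (original-timing) frames to keep; the
    trend column is built from those indices so censor-then-regress equals
    regression restricted to the retained frames.
    """
    t = motion.n_frames
    idx = np.arange(t) if frame_indices is None else np.asarray(frame_indices)
    trend = (idx - idx.mean()) / max(t - 1, 1)
    cols = [
        np.ones(idx.size),
        trend,
        motion.params[idx].T,
        motion.derivatives[idx].T,
        np.asarray(wm_series)[idx],
        np.asarray(csf_series)[idx],
    ]
    return np.column_stack([np.atleast_2d(c).reshape(-1, idx.size).T for c in cols])


def nuisance_regress(
    vol: Volume4D,
    motion: MotionTrace,
    masks: TissueMasks,
    retained: np.ndarray | None = None,
    cond_tol: float = 1e8,
) -> Volume4D:
    """Voxel-wise OLS against the nuisance design; residuals returned.

    The fit uses only the ``retained`` frames (all frames by default) and
    the returned volume contains exactly those frames.
    """
    if motion.n_frames != vol.n_frames:
        raise ConfigurationError("motion trace not aligned to volume")
    wm = _mask_mean_series(vol.data, masks.wm)
    csf = _mask_mean_series(vol.data, masks.csf)
    x = build_confound_matrix(motion, wm, csf, retained)
    if not np.all(np.isfinite(x)):
        raise DesignError("non-finite nuisance regressors")
    # condition check on standardized non-intercept columns
    xs = x[:, 1:].copy()
    sd = xs.std(axis=0)
    if np.any(sd == 0):
        raise DesignError("constant nuisance regressor (collinear with intercept)")
    xs = (xs - xs.mean(axis=0)) / sd
    if np.linalg.cond(np.column_stack([np.ones(len(xs)), xs])) > cond_tol:
        raise DesignError("nuisance design is ill conditioned")
    idx = np.arange(vol.n_frames) if retained is None else np.asarray(retained)
    y = vol.data[..., idx].reshape(-1, idx.size).T  # (frames, voxels)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = (y - x @ beta).T.reshape(vol.shape3d + (idx.size,))
    return Volume4D(resid, vol.affine, vol.tr_s)


def sphere_mask(
    shape3d: tuple[int, int, int], affine: np.ndarray, seed: SeedSpec
) -> np.ndarray:
    """Boolean mask of voxels whose center lies within the seed sphere.

    The test is Euclidean distance in mm between voxel centers (0-based
    indices mapped through the affine) and the seed center.
    """
    ii, jj, kk = np.indices(shape3d)
    idx = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1)
    mm = idx @ np.asarray(affine, dtype=float).T
    d = np.linalg.norm(mm[..., :3] - np.asarray(seed.center), axis=-1)
    return d <= seed.radius


def extract_roi_series(
    vol: Volume4D, seed: SeedSpec, exclude_masks: TissueMasks | None = None
) -> np.ndarray:
    """Mean time series over seed-sphere voxels, excluding WM/CSF voxels."""
    mask = sphere_mask(vol.shape3d, vol.affine, seed)
    if exclude_masks is not None:
        mask &= ~exclude_masks.wm
        mask &= ~exclude_masks.csf
    if not mask.any():
        raise DegenerateDataError(
            f"seed '{seed.name}' covers no voxels after exclusions"
        )
    return vol.data[mask].mean(axis=0)


def _pearson_vs_series(
    data2d: np.ndarray, series: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson r of ``data2d`` (V, t) against ``series`` (t,).

    Zero-variance rows get r = 0 and are flagged degenerate.
    """
    xc = data2d - data2d.mean(axis=1, keepdims=True)
    yc = series - series.mean()
    sy = np.sqrt((yc**2).sum())
    sx = np.sqrt((xc**2).sum(axis=1))
    degenerate = (sx == 0) | (sy == 0)
    denom = np.where(degenerate, 1.0, sx * sy)
    r = (xc @ yc) / denom
    r[degenerate] = 0.0
    return np.clip(r, -1.0, 1.0), degenerate


def seed_map(
    vol: Volume4D,
    seed_series: np.ndarray,
    retained: np.ndarray | None = None,
    min_frames: int = 8,
) -> ConnectivityMap:
    """Voxel-wise Pearson correlation with the seed series (kind ``r``)."""
    idx = np.arange(vol.n_frames) if retained is None else np.asarray(retained)
    if idx.size < min_frames:
        raise InsufficientDataError(f"need at least {min_frames} retained frames")
    series = np.asarray(seed_series, dtype=float)
    if series.size == vol.n_frames:
        series = series[idx]
    elif series.size != idx.size:
        raise ConfigurationError("seed series not aligned to retained frames")
    flat = vol.data[..., idx].reshape(-1, idx.size)
    r, degenerate = _pearson_vs_series(flat, series)
    return ConnectivityMap(
        r.reshape(vol.shape3d), "r", degenerate.reshape(vol.shape3d)
    )


def fisher_z(x):
    """Fisher r-to-z transform, ``z = atanh(r)``.

    Accepts a scalar/array of correlations or an r-kind ConnectivityMap
    (returning a z-kind map).  Values are clipped to ``±(1 - 1e-7)`` first,
    so perfect correlations map to a large finite z.  Transforming a map
    that is already z-kind is an error.
    """
    if isinstance(x, ConnectivityMap):
        if x.kind != "r":
            raise ConfigurationError("map is already Fisher z; double transform")
        z = np.arctanh(np.clip(x.values, -ATANH_CLIP, ATANH_CLIP))
        return ConnectivityMap(z, "z", x.degenerate)
    arr = np.clip(np.asarray(x, dtype=float), -ATANH_CLIP, ATANH_CLIP)
    out = np.arctanh(arr)
    return float(out) if np.isscalar(x) or out.ndim == 0 else out


def circuit_rsfc(
    vol: Volume4D,
    seed: SeedSpec,
    cluster_mask: np.ndarray,
    exclude_masks: TissueMasks | None = None,
    retained: np.ndarray | None = None,
) -> float:
    """Fisher z of the correlation between the seed-sphere mean series and
    the cluster-mean series — the subject-level circuit value consumed by
    the regression screen and the mediation model.
    """
    idx = np.arange(vol.n_frames) if retained is None else np.asarray(retained)
    a = extract_roi_series(vol, seed, exclude_masks)[idx]
    cluster_mask = np.asarray(cluster_mask, dtype=bool)
    if cluster_mask.shape != vol.shape3d:
        raise ConfigurationError("cluster mask shape mismatch")
    b = _mask_mean_series(vol.data, cluster_mask)[idx]
    r, degenerate = _pearson_vs_series(a[None, :], b)
    if degenerate[0]:
        raise DegenerateDataError("zero-variance series in circuit correlation")
    return float(fisher_z(float(r[0])))
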