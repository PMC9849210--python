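"""Synthetic resting-state BOLD volumes with planted ROI correlation
structure, motion spikes, and WM/CSF nuisance compartments.

Each ROI sphere shares a latent unit-variance signal; the latent signals
are drawn with a configurable target correlation matrix.  Voxel noise
inside an ROI is re-centered so the ROI-mean series equals the latent
exactly, hence empirical ROI-mean correlations converge to the target as
the number of frames grows.  Background voxels carry spatially smoothed
Gaussian noise (the volumes emulate data already smoothed during
preprocessing).  The motion trace is a small-amplitude random walk with
persistent translation jumps injected at spike frames so that
approximately ``motion_spike_rate`` of frames exceed the 0.2 mm censoring
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from ..errors import ConfigurationError
from ..rsfc import (
    MotionTrace,
    SeedSpec,
    TissueMasks,
    Volume4D,
    framewise_displacement,
    sphere_mask,
)

__all__ = [
    "FMRISimConfig",
    "FMRISubject",
    "generate_fmri_subject",
    "default_rois",
    "centered_affine",
    "nearest_correlation_psd",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def centered_affine(grid_dims: tuple[int, int, int], voxel_mm: float) -> np.ndarray:
    """Affine placing the grid center at the mm-space origin."""
    aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    aff[:3, 3] = -(np.asarray(grid_dims) - 1) / 2.0 * voxel_mm
    return aff


def default_rois() -> list[SeedSpec]:
    """Four well-separated spheres inside the default grid (synthetic
    stand-ins for auditory/frontal nodes; coordinates are not anatomical).
    """
    return [
        SeedSpec("l_stg", (-30.0, -20.0, 8.0), 8.0),
        SeedSpec("r_stg", (30.0, -20.0, 8.0), 8.0),
        SeedSpec("l_mpfc", (-8.0, 30.0, -10.0), 8.0),
        SeedSpec("l_prg", (-24.0, 12.0, 20.0), 8.0),
    ]


def nearest_correlation_psd(r: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Clip negative eigenvalues and restore the unit diagonal.

    One-step projection, adequate for mildly indefinite targets produced by
    transforming noisy Fisher-z values back to correlations.
    """
    r = 0.5 * (r + r.T)
    w, v = np.linalg.eigh(r)
    if w.min() >= 0:
        out = r.copy()
    else:
        out = (v * np.maximum(w, floor)) @ v.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


@dataclass
class FMRISimConfig:
    """Parameters of one synthetic resting-state acquisition."""

    grid_dims: tuple[int, int, int] = (24, 24, 16)
    voxel_mm: float = 4.0
    n_volumes: int = 444
    tr_s: float = 2.0
    roi_specs: list[SeedSpec] = field(default_factory=default_rois)
    roi_correlations: np.ndarray | None = None
    smooth_fwhm_mm: float = 4.0
    motion_spike_rate: float = 0.05
    roi_noise_sd: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_volumes <= 4:
            raise ConfigurationError("n_volumes must exceed 4")
        if not 0 <= self.motion_spike_rate < 1:
            raise ConfigurationError("motion_spike_rate must be in [0, 1)")
        if self.voxel_mm <= 0 or self.tr_s <= 0:
            raise ConfigurationError("voxel_mm and tr_s must be positive")
        k = len(self.roi_specs)
        if k == 0:  # template config; ROIs supplied later via replace()
            self.roi_correlations = np.zeros((0, 0))
            return
        if self.roi_correlations is None:
            r = np.full((k, k), 0.3)
            np.fill_diagonal(r, 1.0)
            self.roi_correlations = r
        self.roi_correlations = np.asarray(self.roi_correlations, dtype=float)
        r = self.roi_correlations
        if r.shape != (k, k):
            raise ConfigurationError("roi_correlations shape must match roi_specs")
        if not np.allclose(r, r.T, atol=1e-10):
            raise ConfigurationError("roi_correlations must be symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-10):
            raise ConfigurationError("roi_correlations must have a unit diagonal")
        if np.linalg.eigvalsh(r).min() < -1e-8:
            raise ConfigurationError("roi_correlations must be positive semidefinite")

    @property
    def affine(self) -> np.ndarray:
        return centered_affine(self.grid_dims, self.voxel_mm)

    @property
    def effective_fwhm_mm(self) -> float:
        """Gaussian-equivalent smoothness of the produced background noise,
        including the one-voxel sampling contribution of the discrete grid.
        """
        return float(np.sqrt(self.smooth_fwhm_mm**2 + self.voxel_mm**2))


class FMRISubject(NamedTuple):
    volume: Volume4D
    motion: MotionTrace
    masks: TissueMasks
    ground_truth: dict


def _tissue_masks(
    grid_dims: tuple[int, int, int], roi_union: np.ndarray
) -> TissueMasks:
    """WM = outer one-voxel shell in x/y, CSF = bottom slab; both disjoint
    from the ROI spheres and from each other."""
    wm = np.zeros(grid_dims, dtype=bool)
    wm[[0, -1], :, :] = True
    wm[:, [0, -1], :] = True
    csf = np.zeros(grid_dims, dtype=bool)
    csf[:, :, 0] = True
    csf &= ~wm
    wm &= ~roi_union
    csf &= ~roi_union
    brain = np.ones(grid_dims, dtype=bool) & ~wm & ~csf
    return TissueMasks(wm=wm, csf=csf, brain=brain)


def _motion_trace(
    rng: np.random.Generator, t: int, spike_rate: float
) -> tuple[MotionTrace, np.ndarray]:
    steps = np.zeros((t, 6))
    steps[1:, :3] = rng.normal(0.0, 0.02, (t - 1, 3))  # mm
    steps[1:, 3:] = rng.normal(0.0, 0.0002, (t - 1, 3))  # rad
    n_spikes = int(round(spike_rate * t))
    spikes = (
        rng.choice(np.arange(1, t), size=n_spikes, replace=False)
        if n_spikes
        else np.array([], dtype=int)
    )
    for s in spikes:
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        steps[s, :3] += direction * (0.25 + rng.exponential(0.15))
    params = np.cumsum(steps, axis=0)
    return MotionTrace(params), np.sort(spikes)


def generate_fmri_subject(config: FMRISimConfig) -> FMRISubject:
    """Generate one subject's 4-D volume, motion trace, and tissue masks.

    Returns a named tuple ``(volume, motion, masks, ground_truth)``; the
    ground-truth dict records the latent ROI signals, planted correlation
    matrix, spike frames, and smoothness so downstream tests can compare
    estimates against known values.
    """
    rng = np.random.default_rng(config.seed)
    dims, t = tuple(config.grid_dims), config.n_volumes
    affine = config.affine

    roi_masks = [sphere_mask(dims, affine, s) for s in config.roi_specs]
    union = np.zeros(dims, dtype=bool)
    for i, m in enumerate(roi_masks):
        if not m.any():
            raise ConfigurationError(
                f"ROI '{config.roi_specs[i].name}' intersects no voxels"
            )
        if (union & m).any():
            raise ConfigurationError("ROI spheres overlap")
        union |= m
    masks = _tissue_masks(dims, union)

    # latent ROI signals with the target correlation structure
    chol = np.linalg.cholesky(
        config.roi_correlations + 1e-10 * np.eye(len(roi_masks))
    )
    latents = rng.standard_normal((t, len(roi_masks))) @ chol.T  # (t, k)

    # background: spatially smoothed white noise, unit variance per voxel
    sigma_vox = config.smooth_fwhm_mm * FWHM_TO_SIGMA / config.voxel_mm
    noise = rng.standard_normal(dims + (t,))
    if sigma_vox > 0:
        noise = ndimage.gaussian_filter(noise, sigma=(sigma_vox,) * 3 + (0,))
        noise /= noise.std()
    data = noise

    # ROI voxels: latent + re-centered voxel noise (ROI mean == latent)
    for m, lat in zip(roi_masks, latents.T):
        block = rng.normal(0.0, config.roi_noise_sd, (int(m.sum()), t))
        block -= block.mean(axis=0, keepdims=True)
        data[m] = lat[None, :] + block

    # nuisance compartments carry their own slow signals
    for tissue_mask in (masks.wm, masks.csf):
        slow = ndimage.gaussian_filter1d(rng.standard_normal(t), sigma=3.0)
        data[tissue_mask] += 0.8 * slow[None, :]

    motion, spike_frames = _motion_trace(rng, t, config.motion_spike_rate)

    gt = {
        "roi_names": [s.name for s in config.roi_specs],
        "roi_correlations": config.roi_correlations,
        "latents": latents,
        "spike_frames": spike_frames,
        "smooth_fwhm_mm": config.smooth_fwhm_mm,
        "effective_fwhm_mm": config.effective_fwhm_mm,
        "displacement": framewise_displacement(motion.params),
        "seed": config.seed,
    }
    vol = Volume4D(data, affine, config.tr_s)
    return FMRISubject(vol, motion, masks, gt)
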