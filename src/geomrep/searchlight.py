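"""Volumetric searchlight RSA over per-run beta volumes.

A sphere of voxels (radius in voxel units, strict inequality: radius 3
gives 93 voxels) is swept across the brain mask; centers whose sphere
falls more than 50% outside the mask are discarded.  Within each sphere
a crossnobis RDM is computed across runs and compared to each model RDM
with a whitened (here plain-Pearson under identity entry precision)
correlation, yielding one scalar map per model.  Group maps can be
smoothed with a mask-aware Gaussian kernel; a cross-validated
subject-specific ROI estimator selects the top decile of voxels from one
run's contrast and reads responses from the remaining runs.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy import ndimage

from .rsa import RDM, pair_indices

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class BetaVolume:
    """Per-condition, per-run 3D coefficient grids with a brain mask.

    ``data`` is runs x X x Y x Z x conditions.
    """

    data: np.ndarray
    mask: np.ndarray
    condition_labels: list[str]
    voxel_size_mm: float = 2.0
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 5:
            raise ValueError("data must be runs x X x Y x Z x conditions")
        if self.data.shape[1:4] != self.mask.shape:
            raise ValueError("mask shape must match the spatial dimensions")
        if self.data.shape[0] < 2:
            raise ValueError("crossnobis needs at least 2 runs")
        if self.data.shape[4] != len(self.condition_labels):
            raise ValueError("condition label count mismatch")
        if self.affine is None:
            self.affine = np.diag([self.voxel_size_mm] * 3 + [1.0])

    @property
    def n_runs(self) -> int:
        return self.data.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.data.shape[4]


def sphere_offsets(radius_voxels: float = 3.0) -> np.ndarray:
    """Integer offsets with Euclidean norm strictly below the radius.

    The strict inequality reproduces the 93-voxel sphere at radius 3
    (center included); radius 1 keeps the center only.
    """
    if radius_voxels <= 0:
        raise ValueError("radius must be positive")
    r = int(np.ceil(radius_voxels))
    grid = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1].reshape(3, -1).T
    keep = (grid**2).sum(axis=1) < radius_voxels**2
    return grid[keep]


def valid_centers(
    mask: np.ndarray, offsets: np.ndarray, min_coverage: float = 0.5
) -> np.ndarray:
    """In-mask centers with strictly more than min_coverage of the sphere
    inside the mask (out-of-volume sphere voxels count as outside)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    kernel_r = int(np.abs(offsets).max())
    side = 2 * kernel_r + 1
    kernel = np.zeros((side, side, side))
    for off in offsets:
        kernel[tuple(off + kernel_r)] = 1.0
    counts = ndimage.convolve(mask.astype(float), kernel, mode="constant", cval=0.0)
    coverage = counts / len(offsets)
    return np.argwhere(mask & (coverage > min_coverage))


def _crossnobis_loo(patterns: np.ndarray) -> np.ndarray:
    """Leave-one-out crossnobis on conditions x folds x voxels (identity
    noise covariance, normalized by voxel count); vectorized fast path."""
    n_cond, n_fold, p = patterns.shape
    pairs = pair_indices(n_cond)
    deltas = np.stack([patterns[i] - patterns[j] for i, j in pairs])
    total = deltas.sum(axis=1)
    acc = np.zeros(len(pairs))
    for m in range(n_fold):
        rest = (total - deltas[:, m]) / (n_fold - 1)
        acc += np.einsum("kp,kp->k", deltas[:, m], rest)
    return acc / (n_fold * p)


def searchlight_rsa(
    betas: BetaVolume,
    models: list[RDM],
    radius_voxels: float = 3.0,
    min_coverage: float = 0.5,
) -> list[np.ndarray]:
    """Per-model correlation volume from sphere-wise crossnobis RDMs.

    Each valid center receives the whitened similarity between the
    sphere's crossnobis RDM and each model RDM; discarded centers and
    zero-variance spheres are NaN.
    """
    if betas.n_conditions < 3:
        raise ValueError("need at least 3 conditions")
    labels = list(betas.condition_labels)
    model_vecs = []
    for m in models:
        mv = m.subset(labels).values.astype(float)
        mc = mv - mv.mean()
        nrm = np.linalg.norm(mc)
        if nrm == 0:
            raise ValueError("constant model RDM")
        model_vecs.append(mc / nrm)

    offsets = sphere_offsets(radius_voxels)
    centers = valid_centers(betas.mask, offsets, min_coverage)
    shape = betas.mask.shape
    maps = [np.full(shape, np.nan) for _ in models]

    # runs x X x Y x Z x cond -> index by voxel triple
    data = betas.data
    mask = betas.mask
    dims = np.array(shape)
    for cx, cy, cz in centers:
        vox = offsets + np.array([cx, cy, cz])
        inside = np.all((vox >= 0) & (vox < dims), axis=1)
        vox = vox[inside]
        vox = vox[mask[vox[:, 0], vox[:, 1], vox[:, 2]]]
        if len(vox) == 0:
            continue
        # conditions x runs x voxels
        pat = data[:, vox[:, 0], vox[:, 1], vox[:, 2], :].transpose(2, 0, 1)
        vals = _crossnobis_loo(pat)
        vc = vals - vals.mean()
        nrm = np.linalg.norm(vc)
        if nrm == 0:
            continue  # zero-variance sphere: left missing
        vc /= nrm
        for k, mv in enumerate(model_vecs):
            maps[k][cx, cy, cz] = float(vc @ mv)
    return maps


def smooth_volume(
    volume: np.ndarray,
    fwhm_mm: float,
    voxel_size_mm: float = 2.0,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Mask-aware Gaussian smoothing (sigma = fwhm / (2 sqrt(2 ln 2))).

    Missing values (NaN or out-of-mask) are excluded from the kernels and
    the result is renormalized, so a constant map stays constant.
    """
    volume = np.asarray(volume, dtype=float)
    if fwhm_mm <= 0:
        return volume.copy()
    sigma = fwhm_mm * _FWHM_TO_SIGMA / voxel_size_mm
    valid = np.isfinite(volume)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    filled = np.where(valid, volume, 0.0)
    num = ndimage.gaussian_filter(filled, sigma=sigma, mode="constant", cval=0.0)
    den = ndimage.gaussian_filter(valid.astype(float), sigma=sigma, mode="constant", cval=0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(valid & (den > 0), num / den, np.nan)
    return out


def subject_specific_roi(
    contrast_maps: np.ndarray,
    roi_mask: np.ndarray,
    top_fraction: float = 0.10,
    response_maps: np.ndarray | None = None,
) -> dict:
    """Cross-validated subject-specific ROI response estimate.

    For each selection run, the ``top_fraction`` most responsive voxels
    inside ``roi_mask`` (by that run's contrast) are selected, and the
    mean response over those voxels is read from the *other* runs
    (``response_maps`` defaults to the contrast maps themselves).  The
    estimates are averaged over the selection-run loop, so selection and
    estimation data are always disjoint.
    """
    contrast_maps = np.asarray(contrast_maps, dtype=float)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if contrast_maps.ndim < 2 or contrast_maps.shape[0] < 2:
        raise ValueError("need runs x voxels (>= 2 runs)")
    if response_maps is None:
        response_maps = contrast_maps
    response_maps = np.asarray(response_maps, dtype=float)
    if response_maps.shape != contrast_maps.shape:
        raise ValueError("response maps must match contrast maps in shape")

    n_runs = contrast_maps.shape[0]
    flat_c = contrast_maps.reshape(n_runs, -1)[:, roi_mask.ravel()]
    flat_r = response_maps.reshape(n_runs, -1)[:, roi_mask.ravel()]
    n_roi = flat_c.shape[1]
    k = max(1, int(round(top_fraction * n_roi)))
    if n_roi < 10:
        warnings.warn(f"ROI has only {n_roi} voxels; top-{top_fraction:.0%} selection is degenerate")

    fold_estimates = []
    fold_selections = []
    for sel_run in range(n_runs):
        top = np.argsort(flat_c[sel_run])[::-1][:k]
        others = [r for r in range(n_runs) if r != sel_run]
        fold_estimates.append(float(flat_r[others][:, top].mean()))
        fold_selections.append(top)
    return {
        "estimate": float(np.mean(fold_estimates)),
        "fold_estimates": np.array(fold_estimates),
        "fold_selections": fold_selections,
        "n_selected": k,
    }
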