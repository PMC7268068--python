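"""Searchlight mapping of excess decoding accuracy over a masked voxel grid.

A sphere of fixed radius (default 5 mm, i.e. a 10 mm diameter light) is
centred on every in-mask voxel; the voxels inside the sphere-and-mask
intersection form the feature set for the same running-index SVM decoding used
in the region-of-interest analysis, including its permutation chance.  The
per-centre excess accuracy is written back to the centre voxel, yielding a map
of local association information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import TrialBetaMatrix, VolumeGrid
from .mvpa import ClassifierSpec, _encode_labels, _pooled_cv_accuracy

__all__ = ["SearchlightMap", "sphere_offsets", "run_searchlight", "smooth_map"]


@dataclass
class SearchlightMap:
    """Voxel maps of excess accuracy (NaN outside the mask) plus grid metadata."""

    excess: np.ndarray
    raw: np.ndarray
    chance: np.ndarray
    grid: VolumeGrid
    radius_mm: float

    def to_nifti(self, path, which: str = "excess") -> None:
        import nibabel as nib

        vol = getattr(self, which).astype(np.float32)
        nib.save(nib.Nifti1Image(vol, self.grid.affine), str(path))


def sphere_offsets(radius_mm: float, spacing_mm: float) -> np.ndarray:
    """Integer voxel offsets (i, j, k) with spacing * ||(i,j,k)|| <= radius.

    The centre (0, 0, 0) is always included; the boundary is inclusive.
    """
    if radius_mm < 0:
        raise ValueError("radius must be non-negative")
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    r_vox = int(np.floor(radius_mm / spacing_mm))
    rng = np.arange(-r_vox, r_vox + 1)
    i, j, k = np.meshgrid(rng, rng, rng, indexing="ij")
    offs = np.column_stack([i.ravel(), j.ravel(), k.ravel()])
    d2 = (offs**2).sum(axis=1) * spacing_mm**2
    return offs[d2 <= radius_mm**2 + 1e-9]


def run_searchlight(
    betas: TrialBetaMatrix,
    grid: VolumeGrid,
    labels,
    *,
    radius_mm: float = 5.0,
    n_perm: int = 100,
    spec: ClassifierSpec | None = None,
    rng: np.random.Generator | int | None = None,
    min_voxels: int = 1,
) -> SearchlightMap:
    """Decode at every in-mask centre using the voxels in sphere-and-mask.

    ``betas`` must carry ``voxel_coords`` matching in-mask voxels of ``grid``;
    ``labels`` are the stimulus identities of the (retained, chronological)
    trials.  Patterns should already be z-scored.  Each centre gets its own
    permutation chance with ``n_perm`` permutations (fold assignment follows
    the running-index rule throughout).  Centres whose neighbourhood has
    fewer than ``min_voxels`` voxels are left NaN; an isolated centre still
    decodes on its own voxel when ``min_voxels`` is 1.
    """
    spec = spec or ClassifierSpec()
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if grid.n_in_mask == 0:
        raise ValueError("mask is empty")
    if betas.voxel_coords is None:
        raise ValueError("betas.voxel_coords are required for searchlight mapping")
    if betas.voxel_coords.shape[0] != grid.n_in_mask:
        raise ValueError("betas columns must match the in-mask voxels of grid")

    X = np.ascontiguousarray(betas.data, dtype=np.float64)
    y01, _ = _encode_labels(labels)

    # voxel (i,j,k) -> column index lookup
    col_of = -np.ones(grid.shape, dtype=np.intp)
    coords = betas.voxel_coords
    col_of[coords[:, 0], coords[:, 1], coords[:, 2]] = np.arange(coords.shape[0])

    offs = sphere_offsets(radius_mm, grid.spacing)
    shape = np.array(grid.shape)

    raw = np.full(grid.shape, np.nan)
    chance = np.full(grid.shape, np.nan)
    n = len(y01)
    for c in coords:
        neigh = c + offs
        ok = np.all((neigh >= 0) & (neigh < shape), axis=1)
        cols = col_of[neigh[ok, 0], neigh[ok, 1], neigh[ok, 2]]
        cols = cols[cols >= 0]
        if len(cols) < min_voxels:
            continue
        Xs = np.ascontiguousarray(X[:, cols])
        raw[tuple(c)] = _pooled_cv_accuracy(Xs, y01, spec)
        null = 0.0
        for _ in range(n_perm):
            null += _pooled_cv_accuracy(Xs, y01[rng.permutation(n)], spec)
        chance[tuple(c)] = null / n_perm
    return SearchlightMap(
        excess=raw - chance, raw=raw, chance=chance, grid=grid, radius_mm=radius_mm
    )


def smooth_map(smap: SearchlightMap, fwhm_mm: float, which: str = "excess") -> np.ndarray:
    """Gaussian-smooth a map (mask-normalised), for group-level display.

    NaNs outside the mask are treated as missing: the map is smoothed with
    zeros filled in and renormalised by the smoothed mask, so in-mask values
    are a weighted average of in-mask neighbours only.
    """
    from scipy.ndimage import gaussian_filter

    vol = getattr(smap, which).copy()
    mask = np.isfinite(vol)
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)) * smap.grid.spacing)
    filled = np.where(mask, vol, 0.0)
    num = gaussian_filter(filled, sigma)
    den = gaussian_filter(mask.astype(float), sigma)
    out = np.full_like(vol, np.nan)
    nz = den > 1e-12
    out[nz & mask] = num[nz & mask] / den[nz & mask]
    return out
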