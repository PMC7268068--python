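"""Shared data containers: trial-wise beta matrices and volume grids."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TrialBetaMatrix", "VolumeGrid"]


@dataclass
class TrialBetaMatrix:
    """Trials x voxels response-amplitude estimates.

    ``data`` rows follow the chronological trial order of the generating
    design; ``trial_info`` is the matching events table (one row per trial).
    ``voxel_coords`` optionally carries integer grid coordinates (n_voxels, 3)
    for volume-based analyses such as the searchlight.
    """

    data: np.ndarray
    trial_info: pd.DataFrame | None = None
    participant: str | None = None
    hemisphere: str | None = None
    voxel_coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D trials x voxels array")
        if not np.isfinite(self.data).all():
            raise ValueError("beta matrix contains non-finite values")
        if self.trial_info is not None and len(self.trial_info) != self.data.shape[0]:
            raise ValueError(
                f"trial_info has {len(self.trial_info)} rows but data has "
                f"{self.data.shape[0]} trials"
            )
        if self.voxel_coords is not None:
            self.voxel_coords = np.asarray(self.voxel_coords)
            if self.voxel_coords.shape != (self.data.shape[1], 3):
                raise ValueError("voxel_coords must have shape (n_voxels, 3)")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def subset(self, rows) -> "TrialBetaMatrix":
        rows = np.asarray(rows)
        info = self.trial_info.iloc[rows].reset_index(drop=True) if self.trial_info is not None else None
        return TrialBetaMatrix(
            data=self.data[rows],
            trial_info=info,
            participant=self.participant,
            hemisphere=self.hemisphere,
            voxel_coords=self.voxel_coords,
        )

    def to_tsv(self, path) -> None:
        """Write the beta matrix as TSV with one voxel per column (v0, v1, ...)."""
        cols = [f"v{j}" for j in range(self.n_voxels)]
        pd.DataFrame(self.data, columns=cols).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, trial_info: pd.DataFrame | None = None) -> "TrialBetaMatrix":
        df = pd.read_csv(path, sep="\t")
        return cls(data=df.to_numpy(dtype=float), trial_info=trial_info)

    def to_nifti(self, grid: "VolumeGrid", path) -> None:
        """Write betas as a 4-D NIfTI stack (x, y, z, trial) on ``grid``.

        Requires ``voxel_coords``; out-of-mask voxels are zero.
        """
        import nibabel as nib

        if self.voxel_coords is None:
            raise ValueError("voxel_coords are required to write a NIfTI volume")
        vol = np.zeros(grid.shape + (self.n_trials,), dtype=np.float32)
        i, j, k = self.voxel_coords.T
        vol[i, j, k, :] = self.data.T
        nib.save(nib.Nifti1Image(vol, grid.affine), str(path))

    @classmethod
    def from_nifti(
        cls,
        path,
        grid: "VolumeGrid",
        trial_info: pd.DataFrame | None = None,
        participant: str | None = None,
        hemisphere: str | None = None,
    ) -> "TrialBetaMatrix":
        """Load per-trial beta images (a 4-D stack) restricted to the mask of ``grid``.

        This is the real-data entry point: per-trial beta NIfTI + ROI mask +
        events table feed the same decoding code paths as simulated data.
        """
        import nibabel as nib

        vol = np.asanyarray(nib.load(str(path)).dataobj)
        if vol.ndim != 4 or vol.shape[:3] != grid.shape:
            raise ValueError(
                f"expected a 4-D stack on grid {grid.shape}, got shape {vol.shape}"
            )
        coords = grid.mask_coords()
        data = vol[coords[:, 0], coords[:, 1], coords[:, 2], :].T
        return cls(
            data=data,
            trial_info=trial_info,
            participant=participant,
            hemisphere=hemisphere,
            voxel_coords=coords,
        )


@dataclass
class VolumeGrid:
    """A 3-D voxel grid with isotropic spacing, affine and a boolean mask."""

    shape: tuple[int, int, int]
    spacing: float = 1.5
    affine: np.ndarray | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3:
            raise ValueError("shape must be 3-D")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.affine is None:
            self.affine = np.diag([self.spacing] * 3 + [1.0])
        self.affine = np.asarray(self.affine, dtype=float)
        if self.mask is None:
            self.mask = np.ones(self.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.shape:
            raise ValueError("mask shape must equal grid shape")

    @property
    def n_in_mask(self) -> int:
        return int(self.mask.sum())

    def mask_coords(self) -> np.ndarray:
        """Integer (i, j, k) coordinates of in-mask voxels in C order."""
        return np.argwhere(self.mask)

    def to_nifti(self, path) -> None:
        import nibabel as nib

        nib.save(nib.Nifti1Image(self.mask.astype(np.uint8), self.affine), str(path))

    @classmethod
    def from_nifti(cls, path, spacing: float | None = None) -> "VolumeGrid":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        vox = float(np.abs(img.affine[0, 0])) if spacing is None else spacing
        return cls(shape=data.shape, spacing=vox, affine=img.affine, mask=data > 0)
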