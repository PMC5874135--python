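"""In-memory container for a voxelwise gray-matter volume dataset."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_PHENOTYPES = ("participant_id", "age", "sex", "scanner_tesla")


@dataclass
class GrayMatterDataset:
    """N participants x 3-D grid of modulated gray-matter volume.

    Attributes
    ----------
    volumes : ndarray, shape (N, nx, ny, nz)
        One co-registered volume per participant.
    mask : ndarray of bool, shape (nx, ny, nz)
        Analysis (brain) mask shared by all participants.
    affine : ndarray, shape (4, 4)
        Axis-aligned voxel-to-world (mm) map, RAS+ convention.
    participants : DataFrame
        Phenotypes with columns ``participant_id``, ``age`` (years), ``sex``
        ("M"/"F") and ``scanner_tesla`` (1.5 or 3.0), row-aligned to
        ``volumes``.
    ground_truth : object, optional
        Planted-pattern record attached by the simulator (see
        :mod:`seedpls.simulate`); absent for data read from disk without one.
    """

    volumes: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    participants: pd.DataFrame
    ground_truth: object | None = None
    _voxel_matrix: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.volumes.ndim != 4:
            raise ValueError(f"volumes must be 4-D (N,nx,ny,nz), got {self.volumes.shape}")
        if self.volumes.shape[1:] != self.mask.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match volume grid "
                f"{self.volumes.shape[1:]}"
            )
        missing = set(REQUIRED_PHENOTYPES) - set(self.participants.columns)
        if missing:
            raise ValueError(f"participants table missing columns {sorted(missing)}")
        if len(self.participants) != self.volumes.shape[0]:
            raise ValueError(
                f"{len(self.participants)} phenotype rows for "
                f"{self.volumes.shape[0]} volumes"
            )

    @property
    def n_participants(self) -> int:
        return self.volumes.shape[0]

    @property
    def n_voxels(self) -> int:
        """Number of voxels inside the mask."""
        return int(self.mask.sum())

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.volumes.shape[1:]

    @property
    def ages(self) -> np.ndarray:
        return self.participants["age"].to_numpy(dtype=float)

    @property
    def voxel_matrix(self) -> np.ndarray:
        """Masked N x V matrix of gray-matter values (cached)."""
        if self._voxel_matrix is None:
            self._voxel_matrix = self.volumes[:, self.mask]
        return self._voxel_matrix

    def unmask(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a V-length vector back onto the 3-D grid."""
        values = np.asarray(values)
        if values.shape != (self.n_voxels,):
            raise ValueError(f"expected ({self.n_voxels},) vector, got {values.shape}")
        out = np.full(self.mask.shape, fill, dtype=float)
        out[self.mask] = values
        return out
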