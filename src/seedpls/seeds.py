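"""Network seed tables and cubical ROI extraction.

Each of the six canonical neurocognitive networks (default, dorsal attention,
frontoparietal control, ventral attention, somatomotor, visual) is represented
by four seed coordinates in MNI space: the top two high-confidence seeds from
Yeo et al.'s 1,000-subject functional parcellation plus their contralateral
mirrors, obtained by negating the x coordinate.  The default network is the
exception: because it separates into anterior and posterior components, it is
represented by two midline seeds (medial prefrontal and posterior cingulate
cortex) and one bilateral inferior-parietal pair.

Gray-matter volume is read out from a cubical region of interest (10.5 mm
edge by default) centred on each seed and averaged across a network's four
seeds, yielding one scalar per participant per network — the seed vector Y
submitted to the PLS analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .errors import (
    EmptyROIError,
    MidlineSeedError,
    OutOfBoundsError,
    UnsupportedAffineError,
)

NETWORKS = (
    "default",
    "dorsal_attention",
    "frontoparietal",
    "ventral_attention",
    "somatomotor",
    "visual",
)

#: Default ROI edge length in mm.
DEFAULT_CUBE_EDGE_MM = 10.5


@dataclass(frozen=True)
class SeedSpec:
    """One network seed: MNI coordinate plus network membership.

    Laterality must be consistent with the sign of x ("L" for x < 0, "R" for
    x > 0); midline seeds (x == 0) are not used in the built-in table.
    """

    network: str
    x: float
    y: float
    z: float
    laterality: str
    label: str

    def __post_init__(self):
        if self.network not in NETWORKS:
            raise ValueError(f"unknown network {self.network!r}")
        if self.laterality not in ("L", "R"):
            raise ValueError(f"laterality must be 'L' or 'R', got {self.laterality!r}")
        if self.x < 0 and self.laterality != "L":
            raise ValueError(f"seed at x={self.x} must be labelled 'L'")
        if self.x > 0 and self.laterality != "R":
            raise ValueError(f"seed at x={self.x} must be labelled 'R'")

    @property
    def coord_mm(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


class SeedTable:
    """Ordered collection of :class:`SeedSpec` rows."""

    def __init__(self, seeds: Iterable[SeedSpec]):
        self.seeds: tuple[SeedSpec, ...] = tuple(seeds)

    def __len__(self) -> int:
        return len(self.seeds)

    def __iter__(self) -> Iterator[SeedSpec]:
        return iter(self.seeds)

    def __getitem__(self, i) -> SeedSpec:
        return self.seeds[i]

    @property
    def networks(self) -> tuple[str, ...]:
        seen = []
        for s in self.seeds:
            if s.network not in seen:
                seen.append(s.network)
        return tuple(seen)

    def network_seeds(self, network: str) -> tuple[SeedSpec, ...]:
        out = tuple(s for s in self.seeds if s.network == network)
        if not out:
            raise KeyError(f"network {network!r} not present in seed table")
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "network": s.network,
                    "x": s.x,
                    "y": s.y,
                    "z": s.z,
                    "laterality": s.laterality,
                    "label": s.label,
                }
                for s in self.seeds
            ]
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SeedTable":
        df = pd.read_csv(Path(path), sep="\t")
        required = {"network", "x", "y", "z", "laterality", "label"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"seed table {path} missing columns {sorted(missing)}")
        return cls(
            SeedSpec(
                network=row.network,
                x=float(row.x),
                y=float(row.y),
                z=float(row.z),
                laterality=str(row.laterality),
                label=str(row.label),
            )
            for row in df.itertuples()
        )


# Built-in 24-seed fixture: four seeds per network.  Non-midline pairs are
# exact x-sign mirrors of each other; the default network instead carries two
# midline seeds (anterior and posterior components) plus one bilateral pair.
_BUILTIN_ROWS = (
    ("default", -7, 49, 18, "L", "Medial prefrontal cortex"),
    ("default", -7, -52, 26, "L", "Posterior cingulate cortex"),
    ("default", -41, -60, 29, "L", "Inferior parietal lobule"),
    ("default", 41, -60, 29, "R", "Inferior parietal lobule"),
    ("dorsal_attention", -22, -8, 54, "L", "Frontal eye fields"),
    ("dorsal_attention", 22, -8, 54, "R", "Frontal eye fields"),
    ("dorsal_attention", -51, -64, -2, "L", "Middle temporal motion complex"),
    ("dorsal_attention", 51, -64, -2, "R", "Middle temporal motion complex"),
    ("frontoparietal", -40, 50, 7, "L", "Frontal pole"),
    ("frontoparietal", 40, 50, 7, "R", "Frontal pole"),
    ("frontoparietal", -43, -50, 46, "L", "Anterior inferior parietal lobule"),
    ("frontoparietal", 43, -50, 46, "R", "Anterior inferior parietal lobule"),
    ("ventral_attention", -5, 15, 32, "L", "Anterior cingulate cortex"),
    ("ventral_attention", 5, 15, 32, "R", "Anterior cingulate cortex"),
    ("ventral_attention", -31, 11, 8, "L", "Anterior insula"),
    ("ventral_attention", 31, 11, 8, "R", "Anterior insula"),
    ("somatomotor", -41, -20, 62, "L", "Precentral gyrus (hand)"),
    ("somatomotor", 41, -20, 62, "R", "Precentral gyrus (hand)"),
    ("somatomotor", -55, -4, 26, "L", "Precentral gyrus (tongue)"),
    ("somatomotor", 55, -4, 26, "R", "Precentral gyrus (tongue)"),
    ("visual", -3, -74, 23, "L", "Extrastriate visual cortex"),
    ("visual", 3, -74, 23, "R", "Extrastriate visual cortex"),
    ("visual", -16, -74, 7, "L", "Visual area 1"),
    ("visual", 16, -74, 7, "R", "Visual area 1"),
)


def builtin_seed_table() -> SeedTable:
    """Return the built-in 24-row seed table (six networks, four seeds each)."""
    return SeedTable(SeedSpec(*row) for row in _BUILTIN_ROWS)


def mirror_seed(seed: SeedSpec) -> SeedSpec:
    """Return the contralateral seed: x negated, laterality flipped.

    Raises :class:`MidlineSeedError` for midline seeds (x == 0), which have no
    distinct contralateral partner.
    """
    if seed.x == 0:
        raise MidlineSeedError(f"cannot mirror midline seed {seed.label!r} (x=0)")
    return replace(
        seed,
        x=-seed.x,
        laterality="R" if seed.laterality == "L" else "L",
    )


def _check_axis_aligned(affine: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Validate an axis-aligned scaling+translation affine; return voxel sizes."""
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise UnsupportedAffineError(f"affine must be 4x4, got {affine.shape}")
    rot = affine[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if np.max(np.abs(off_diag)) > tol:
        raise UnsupportedAffineError(
            "affine has rotation/shear components; only axis-aligned "
            "scaling+translation is supported"
        )
    scales = np.diag(rot)
    if np.any(np.abs(scales) <= tol):
        raise UnsupportedAffineError("affine has zero scaling on some axis")
    return scales


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero (grid independent)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def mm_to_voxel(
    affine: np.ndarray,
    coord_mm,
    grid_shape: tuple[int, int, int],
) -> tuple[int, int, int]:
    """Map a world (mm) coordinate to the nearest voxel index.

    The affine must be axis-aligned (diagonal scaling plus translation);
    rotated or sheared grids are rejected rather than resampled.  Coordinates
    whose nearest voxel falls outside ``grid_shape`` raise
    :class:`OutOfBoundsError`.
    """
    scales = _check_axis_aligned(affine)
    coord = np.asarray(coord_mm, dtype=float)
    idx_f = (coord - np.asarray(affine[:3, 3])) / scales
    idx = _round_half_away(idx_f).astype(int)
    shape = np.asarray(grid_shape, dtype=int)
    if np.any(idx < 0) or np.any(idx >= shape):
        raise OutOfBoundsError(
            f"coordinate {tuple(coord)} mm maps to voxel {tuple(idx)} outside "
            f"grid of shape {tuple(shape)}"
        )
    return tuple(int(i) for i in idx)


def _cube_slices(affine, center_mm, edge_mm, grid_shape):
    """Index ranges of voxels whose centers lie within the closed cube."""
    scales = _check_axis_aligned(affine)
    origin = np.asarray(affine[:3, 3], dtype=float)
    center = np.asarray(center_mm, dtype=float)
    half = edge_mm / 2.0
    slices = []
    for ax in range(3):
        s = scales[ax]
        # voxel index i has world coordinate origin + i*s on this axis
        lo_mm, hi_mm = center[ax] - half, center[ax] + half
        bounds = sorted(((lo_mm - origin[ax]) / s, (hi_mm - origin[ax]) / s))
        # closed interval; guard FP noise at the exact edge/2 boundary
        i_lo = int(np.ceil(bounds[0] - 1e-9))
        i_hi = int(np.floor(bounds[1] + 1e-9))
        i_lo = max(i_lo, 0)
        i_hi = min(i_hi, grid_shape[ax] - 1)
        if i_hi < i_lo:
            return None
        slices.append(slice(i_lo, i_hi + 1))
    return tuple(slices)


def extract_cube(
    volume: np.ndarray,
    affine: np.ndarray,
    center_mm,
    edge_mm: float = DEFAULT_CUBE_EDGE_MM,
    mask: np.ndarray | None = None,
) -> float:
    """Mean gray-matter value in a cubical ROI centred at ``center_mm``.

    A voxel enters the mean when its center lies within ``edge_mm / 2`` of the
    cube center along every axis (closed interval, world coordinates).  When a
    mask is given, only masked voxels contribute; a cube that intersects the
    grid but not the mask raises :class:`EmptyROIError`, and a cube partially
    clipped by the mask or grid edge is averaged over the available voxels
    with a warning.
    """
    if edge_mm <= 0:
        raise ValueError(f"edge_mm must be positive, got {edge_mm}")
    volume = np.asarray(volume)
    slices = _cube_slices(affine, center_mm, edge_mm, volume.shape)
    if slices is None:
        raise EmptyROIError(
            f"cube of edge {edge_mm} mm at {tuple(np.asarray(center_mm))} mm "
            "contains no voxel centers inside the grid"
        )
    block = volume[slices]
    scales = _check_axis_aligned(affine)
    n_expected = 1
    for ax in range(3):
        n_expected *= int(np.floor(edge_mm / 2.0 / abs(scales[ax]) + 1e-9)) * 2 + 1
    if mask is not None:
        mblock = np.asarray(mask, dtype=bool)[slices]
        n_in = int(mblock.sum())
        if n_in == 0:
            raise EmptyROIError(
                f"cube at {tuple(np.asarray(center_mm))} mm does not intersect the mask"
            )
        if n_in < n_expected:
            warnings.warn(
                f"cube at {tuple(np.asarray(center_mm))} mm only partially covered "
                f"({n_in}/{n_expected} voxels); averaging the masked intersection",
                stacklevel=2,
            )
        return float(block[mblock].mean())
    if block.size < n_expected:
        warnings.warn(
            f"cube at {tuple(np.asarray(center_mm))} mm clipped by the grid "
            f"({block.size}/{n_expected} voxels)",
            stacklevel=2,
        )
    return float(block.mean())


@dataclass
class NetworkSeedAverage:
    """Per-participant mean seed gray-matter volume for one network (vector Y)."""

    network: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("network seed averages contain non-finite values")


def network_seed_average(
    dataset,
    table: SeedTable,
    network: str,
    edge_mm: float = DEFAULT_CUBE_EDGE_MM,
) -> NetworkSeedAverage:
    """Average the per-seed cube extractions of one network over participants.

    Returns the N-length seed vector Y: for each participant, the unweighted
    mean over the network's seeds of the mean gray-matter value in the cubical
    ROI at each seed.
    """
    seeds = table.network_seeds(network)
    n = dataset.n_participants
    values = np.empty(n, dtype=float)
    for i in range(n):
        vol = dataset.volumes[i]
        per_seed = []
        for seed in seeds:
            try:
                per_seed.append(
                    extract_cube(vol, dataset.affine, seed.coord_mm, edge_mm, dataset.mask)
                )
            except EmptyROIError as exc:
                raise EmptyROIError(
                    f"seed {seed.label!r} ({seed.network}, {seed.coord_mm}): {exc}"
                ) from exc
        values[i] = float(np.mean(per_seed))
    return NetworkSeedAverage(network=network, values=values)
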