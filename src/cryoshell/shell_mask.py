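"""Distance-banded solvent-shell voxel masks around the reference RNA.

The comparison between predicted and experimental density is restricted to
voxels at a given distance band from the RNA heavy atoms (default
1.8-3.2 Å), with voxels nearest to poorly resolved residues excluded.
Growing shells, sliding 1 Å windows, and per-residue partitions of the
default shell support localization of the assessment.  All distances are to
the reference structure only, never to model frames.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree

from .ensemble_io import ReferenceStructure, coords_array
from .density_builder import DensityGrid, Lattice, write_mrc

DEFAULT_BAND = (1.8, 3.2)
#: poorly resolved residue ranges excluded from assessment by default
DEFAULT_EXCLUDED = "63-88,229-245,284-295,332-335,364-402"


@dataclass(frozen=True)
class DistanceField:
    """Per-voxel distance to the RNA and nearest-residue label on a lattice.

    ``nearest_residue`` is only resolved where ``distance <= d_max``
    (−1 elsewhere); ties in nearest-atom distance go to the lowest residue
    index.
    """

    lattice: Lattice
    distance: np.ndarray
    nearest_residue: np.ndarray
    d_max: float


def compute_distance_field(ref: ReferenceStructure, lattice: Lattice,
                           d_max: float = 5.0) -> DistanceField:
    """Distance of every voxel center to the nearest reference heavy atom."""
    xs, ys, zs = lattice.all_centers_1d()
    pts = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"),
                   axis=-1).reshape(-1, 3)
    heavy = [a for a in ref.atoms if a.is_heavy]
    tree = cKDTree(coords_array(heavy))
    dist, _ = tree.query(pts)
    nearest = np.full(len(pts), -1, dtype=int)
    inplay = np.nonzero(dist <= d_max)[0]
    if inplay.size:
        # exact tie-break: lowest residue index wins (first argmin in sorted order)
        by_res = ref.atoms_by_residue()
        residues = sorted(by_res)
        dmat = np.empty((len(residues), inplay.size))
        sub = pts[inplay]
        for row, res in enumerate(residues):
            rtree = cKDTree(coords_array([a for a in by_res[res]
                                          if a.is_heavy]))
            dmat[row], _ = rtree.query(sub)
        nearest[inplay] = np.asarray(residues)[np.argmin(dmat, axis=0)]
    shape = lattice.shape
    return DistanceField(lattice, dist.reshape(shape),
                         nearest.reshape(shape), d_max)


@dataclass
class ShellMask:
    """A set of lattice voxels in a half-open distance band [r_min, r_max)."""

    lattice: Lattice
    indices: np.ndarray          # (n, 3) int voxel indices
    distance: np.ndarray         # (n,) distance to RNA, Å
    nearest_residue: np.ndarray  # (n,) residue index labels
    band: tuple[float, float]

    def __len__(self) -> int:
        return int(self.indices.shape[0])

    @property
    def mask_id(self) -> str:
        return f"shell[{self.band[0]:.2f},{self.band[1]:.2f})"

    def extract(self, grid: DensityGrid) -> np.ndarray:
        """Pull the grid values at the mask voxels, in mask order."""
        if (tuple(grid.lattice.shape) != tuple(self.lattice.shape)
                or not np.allclose(grid.lattice.origin_a,
                                   self.lattice.origin_a, atol=1e-6)
                or not np.allclose(grid.lattice.spacing_a,
                                   self.lattice.spacing_a, atol=1e-9)):
            raise ValueError("grid lattice differs from mask lattice; "
                             "resample first")
        i = self.indices
        return grid.values[i[:, 0], i[:, 1], i[:, 2]]

    def voxel_set(self) -> set[tuple[int, int, int]]:
        return {tuple(row) for row in self.indices.tolist()}


def compute_shell(ref: ReferenceStructure, lattice: Lattice,
                  r_min: float = DEFAULT_BAND[0],
                  r_max: float = DEFAULT_BAND[1],
                  excluded: Iterable[int] | None = None,
                  field: DistanceField | None = None) -> ShellMask:
    """Voxels whose distance to the RNA lies in [r_min, r_max).

    Voxels whose nearest residue is in the exclusion set are dropped (not
    reassigned to the next-nearest residue).  ``excluded`` defaults to the
    reference structure's own exclusion set.
    """
    if r_min > r_max:
        raise ValueError(f"need r_min <= r_max, got [{r_min}, {r_max})")
    if field is None or field.d_max < r_max:
        field = compute_distance_field(ref, lattice, d_max=max(r_max, 5.0))
    if excluded is None:
        excluded = ref.excluded_residues
    excluded = frozenset(int(i) for i in excluded)
    sel = (field.distance >= r_min) & (field.distance < r_max)
    if excluded:
        sel &= ~np.isin(field.nearest_residue, sorted(excluded))
    idx = np.argwhere(sel)
    return ShellMask(lattice=lattice, indices=idx,
                     distance=field.distance[sel],
                     nearest_residue=field.nearest_residue[sel],
                     band=(r_min, r_max))


def growing_shells(ref: ReferenceStructure, lattice: Lattice,
                   excluded: Iterable[int] | None = None,
                   field: DistanceField | None = None) -> list[ShellMask]:
    """Nested shells [1.8, 1.9), [1.8, 2.0), ... up to [1.8, 5.0)."""
    if field is None:
        field = compute_distance_field(ref, lattice, d_max=5.0)
    outer = np.round(np.arange(1.9, 5.0 + 1e-9, 0.1), 10)
    return [compute_shell(ref, lattice, 1.8, float(r), excluded, field)
            for r in outer]


def distance_windows(ref: ReferenceStructure, lattice: Lattice,
                     excluded: Iterable[int] | None = None,
                     field: DistanceField | None = None) -> list[ShellMask]:
    """Sliding 1 Å windows [1.8, 2.8), [1.9, 2.9), ... up to [4.0, 5.0)."""
    if field is None:
        field = compute_distance_field(ref, lattice, d_max=5.0)
    inner = np.round(np.arange(1.8, 4.0 + 1e-9, 0.1), 10)
    return [compute_shell(ref, lattice, float(r), float(np.round(r + 1.0, 10)),
                          excluded, field)
            for r in inner]


def per_residue_regions(mask: ShellMask) -> dict[int, ShellMask]:
    """Partition a mask's voxels by their nearest RNA residue."""
    out: dict[int, ShellMask] = {}
    for res in np.unique(mask.nearest_residue):
        sel = mask.nearest_residue == res
        out[int(res)] = ShellMask(lattice=mask.lattice,
                                  indices=mask.indices[sel],
                                  distance=mask.distance[sel],
                                  nearest_residue=mask.nearest_residue[sel],
                                  band=mask.band)
    return out


def mask_to_mrc(mask: ShellMask, path: str | Path) -> None:
    """Export a mask as a binary MRC map (1 inside, 0 outside)."""
    values = np.zeros(mask.lattice.shape)
    i = mask.indices
    values[i[:, 0], i[:, 1], i[:, 2]] = 1.0
    write_mrc(DensityGrid(mask.lattice, values, "mask"), path)


def mask_to_csv(mask: ShellMask, path: str | Path) -> None:
    """Export a mask as a CSV voxel table (index, distance, nearest residue)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["i", "j", "k", "distance_to_rna", "nearest_residue"])
        for (i, j, k), d, r in zip(mask.indices.tolist(),
                                   mask.distance.tolist(),
                                   mask.nearest_residue.tolist()):
            writer.writerow([i, j, k, f"{d:.6f}", r])
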