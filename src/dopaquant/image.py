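"""Volumetric containers and NIfTI I/O.

The pipeline operates on co-registered, atlas-space volumes: a PET activity
map, a FLAIR MRI, and an integer label atlas encoding hemispheres (five
lobes + striatum each) and the pons. All three must share grid shape and
affine. Registration to the common space is an external precondition
(standard multi-step linear registration with any established toolkit, e.g.
ANTs/ITK/FSL); this package consumes its output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List

import nibabel as nib
import numpy as np

AFFINE_TOL_MM = 1e-4

SIDES = ("left", "right")

#: Canonical role names understood by the pipeline.
LOBE_ROLES = {
    side: tuple(f"lobe_{side}_{i}" for i in range(1, 6)) for side in SIDES
}
STRIATUM_ROLES = {side: f"striatum_{side}" for side in SIDES}
PONS_ROLE = "pons"


@dataclass
class VolumetricImage:
    """A 3D scalar grid in atlas space.

    Attributes
    ----------
    grid:
        3D float array of intensities. PET grids are activity concentrations
        in arbitrary but internally consistent units (ratios are what
        matter); FLAIR grids are arbitrary units.
    affine:
        4x4 voxel-to-world map (mm).
    modality:
        "PET" or "FLAIR".
    """

    grid: np.ndarray
    affine: np.ndarray
    modality: str

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.grid.ndim != 3:
            raise ValueError("grid must be 3D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.modality not in ("PET", "FLAIR"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError(f"{self.modality}: non-finite intensities")
        if self.modality == "PET" and np.any(self.grid < 0):
            raise ValueError("PET intensities must be >= 0")

    @property
    def shape(self) -> tuple:
        return self.grid.shape

    def voxel_to_world(self, idx: Iterable[int]) -> list:
        """World-mm coordinates of a 0-based voxel index."""
        hom = np.append(np.asarray(idx, dtype=float), 1.0)
        return list((self.affine @ hom)[:3])


@dataclass
class AtlasLabels:
    """Integer label volume with a legend mapping label -> anatomical role.

    Roles are ``lobe_{side}_{1..5}``, ``striatum_{side}`` and ``pons``;
    label 0 is background. Each hemisphere is the union of its five lobes
    and its striatum.
    """

    labels: np.ndarray
    legend: Dict[int, str]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")
        roles = list(self.legend.values())
        for side in SIDES:
            missing = [r for r in LOBE_ROLES[side] if r not in roles]
            if missing:
                raise ValueError(f"atlas legend missing lobes: {missing}")
            if STRIATUM_ROLES[side] not in roles:
                raise ValueError(f"atlas legend missing striatum_{side}")
        if PONS_ROLE not in roles:
            raise ValueError("atlas legend missing pons")
        present = set(np.unique(self.labels)) - {0}
        unknown = present - set(self.legend)
        if unknown:
            raise ValueError(f"labels without legend entry: {sorted(unknown)}")

    def _labels_for(self, roles: Iterable[str]) -> List[int]:
        wanted = set(roles)
        return [lab for lab, role in self.legend.items() if role in wanted]

    def mask_for_roles(self, roles: Iterable[str]) -> np.ndarray:
        return np.isin(self.labels, self._labels_for(roles))

    def hemisphere_mask(self, side: str) -> np.ndarray:
        return self.mask_for_roles(LOBE_ROLES[side] + (STRIATUM_ROLES[side],))

    def lobe_masks(self, side: str) -> List[np.ndarray]:
        return [self.mask_for_roles([r]) for r in LOBE_ROLES[side]]

    def striatum_mask(self, side: str) -> np.ndarray:
        return self.mask_for_roles([STRIATUM_ROLES[side]])

    def pons_mask(self) -> np.ndarray:
        return self.mask_for_roles([PONS_ROLE])

    def brain_mask(self) -> np.ndarray:
        """All labelled tissue (both hemispheres plus pons)."""
        return self.labels != 0


def read_volume(path: str | Path, modality: str) -> VolumetricImage:
    """Read a NIfTI-1 scalar volume as a :class:`VolumetricImage`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    grid = np.asanyarray(img.dataobj, dtype=np.float64)
    if grid.ndim == 4 and grid.shape[3] == 1:
        grid = grid[..., 0]
    return VolumetricImage(grid=grid, affine=img.affine, modality=modality)


def read_atlas(path: str | Path, legend: Dict[int, str]) -> AtlasLabels:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    labels = np.asanyarray(img.dataobj)
    labels = np.rint(labels).astype(np.int32)
    return AtlasLabels(labels=labels, legend=legend, affine=img.affine)


def write_volume(grid: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    grid = np.asarray(grid)
    if grid.dtype == bool:
        grid = grid.astype(np.uint8)
    nib.save(nib.Nifti1Image(grid, np.asarray(affine)), str(path))


def check_alignment(*volumes) -> None:
    """Require identical shape and affine (within tolerance) across a case.

    Accepts any mix of VolumetricImage / AtlasLabels.
    """
    shapes = []
    affines = []
    for v in volumes:
        arr = v.labels if isinstance(v, AtlasLabels) else v.grid
        shapes.append(arr.shape)
        affines.append(np.asarray(v.affine, dtype=float))
    ref_shape, ref_aff = shapes[0], affines[0]
    for shape, aff in zip(shapes[1:], affines[1:]):
        if shape != ref_shape:
            raise ValueError(f"grid mismatch: {shape} vs {ref_shape}")
        if np.max(np.abs(aff - ref_aff)) > AFFINE_TOL_MM:
            raise ValueError("affine mismatch beyond tolerance")
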