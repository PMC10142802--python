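"""Dual local-mean maxima of the candidate lesion volume.

Everything the reference stage did not claim (M_c = brain − M_n − M_s)
contains both the glioma and the striatum of the affected hemisphere, whose
physiological uptake is often comparable to the tumor's. Instead of a single
maximum, two are reported: m_in inside an inflated ipsilateral striatal mask
M_c,s and m_out in the remainder M_c,n. Each maximum is the largest mean
activity of a cubic (2l+1)^3 window centered inside the mask (windows are
averaged as-is, without clipping to the mask), because a single hottest
voxel is noise-prone while gliomas peak centrally and decline outward.

When m_out >= m_in the glioma clearly peaks outside the striatum and m_out
represents it. When m_in > m_out the basal ganglia involvement must be
judged: with evident infiltration m_in is the reliable marker, otherwise
m_out is still reported, flagged for clinician review.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .image import VolumetricImage

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)

REVIEW_FLAG = "clinician review required"


@dataclass
class LocalMaximum:
    value: float
    center_voxel: Tuple[int, int, int]
    center_world_mm: List[float]
    window_half: int


@dataclass
class SelectedMaximum:
    source: str                  # "m_in" | "m_out"
    maximum: LocalMaximum
    reason: str
    flags: List[str] = field(default_factory=list)

    @property
    def value(self) -> float:
        return self.maximum.value


def build_complement(brain: np.ndarray, m_n: np.ndarray,
                     m_s: np.ndarray) -> np.ndarray:
    """M_c: the brain voxels left after removing both reference masks."""
    if not (brain.shape == m_n.shape == m_s.shape):
        raise ValueError("masks on different grids")
    m_c = brain & ~m_n & ~m_s
    if not m_c.any():
        raise ValueError("no candidate lesion volume")
    return m_c


def inflate_striatal_mask(pet: np.ndarray, striatum_label: np.ndarray,
                          seed: np.ndarray, limit: np.ndarray,
                          rho_grow: float = 0.8, max_iter: int = 50,
                          ) -> Tuple[np.ndarray, List[str]]:
    """Grow the raw filter-discarded striatal seed until it encircles the
    atlas striatum of the affected hemisphere.

    Neighbors (26-connectivity) join while their activity reaches
    ``rho_grow`` times the current region mean, so the expansion follows the
    local intensity — and can legitimately incorporate contiguous affected
    tissue of similar uptake. The result is clipped to ``limit``
    (M_c restricted to the affected hemisphere) and always unioned with the
    atlas label there; hitting the iteration cap first is flagged.
    """
    if not striatum_label.any():
        raise ValueError("atlas striatum label empty on the affected side")
    flags: List[str] = []
    target = striatum_label & limit
    region = seed & limit
    if not region.any():
        region = target.copy()
        flags.append("empty_seed_grown_from_atlas_label")
    covered = bool(np.all(target <= region))
    for _ in range(max_iter):
        if covered:
            break
        frontier = ndimage.binary_dilation(region, _STRUCT26) & ~region & limit
        admit = frontier & (pet >= rho_grow * float(pet[region].mean()))
        if not admit.any():
            break
        region |= admit
        covered = bool(np.all(target <= region))
    if not covered:
        flags.append("incomplete striatal coverage")
        region |= target
    return region, flags


def local_mean_maximum(pet: VolumetricImage, mask: np.ndarray,
                       window_half: int) -> LocalMaximum:
    """Highest cubic-window mean over centers in the mask.

    Only centers whose window lies fully inside the grid are considered;
    ties resolve to the smallest lexicographic voxel index.
    """
    grid = pet.grid
    size = 2 * window_half + 1
    valid = np.zeros(grid.shape, dtype=bool)
    sl = tuple(slice(window_half, s - window_half) for s in grid.shape)
    if all(s.stop > s.start for s in sl):
        valid[sl] = True
    centers = mask & valid
    if not centers.any():
        raise ValueError("no window center fully inside the grid")
    means = ndimage.uniform_filter(grid, size=size, mode="constant")
    cand = np.where(centers, means, -np.inf)
    flat = int(np.argmax(cand))          # first max in C order = lexicographic
    idx = np.unravel_index(flat, grid.shape)
    return LocalMaximum(
        value=float(means[idx]),
        center_voxel=tuple(int(i) for i in idx),
        center_world_mm=pet.voxel_to_world(idx),
        window_half=window_half)


def select_representative(m_in: LocalMaximum, m_out: LocalMaximum,
                          infiltration_assumed: bool) -> SelectedMaximum:
    """Apply the selection rule between the two maxima."""
    if m_out.value >= m_in.value:
        return SelectedMaximum(
            source="m_out", maximum=m_out,
            reason="m_out >= m_in: glioma peak lies outside the striatum")
    if infiltration_assumed:
        return SelectedMaximum(
            source="m_in", maximum=m_in,
            reason="m_in > m_out with evident striatal infiltration")
    return SelectedMaximum(
        source="m_out", maximum=m_out,
        reason=("m_in > m_out but infiltration unclear; m_out retained as "
                "the representative value"),
        flags=[REVIEW_FLAG])
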