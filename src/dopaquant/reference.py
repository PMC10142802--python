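"""Data-driven reference regions via the quantile-histogram conformity filter.

The normal-tissue reference is found by comparing, at every brain voxel p,
the intensity distribution of a cubic window I(p) = (2l+1)^3 against the
distribution of a reference lobe V_i of the non-affected hemisphere,
summarized as K quantile bins. Conformity is measured by the chi-square-like
statistic

    Y = sum_j (o_j - e_j)^2 / e_j

where e_j is the reference proportion of bin j and o_j the proportion of
window voxels falling in bin j; p is accepted into the lobe mask M_i when
Y <= threshold. The five per-lobe masks are averaged into the normal-tissue
mask M_n (majority rule by default), whose mean activity c_n normalizes the
PET. The voxels the filter discards in the non-affected hemisphere around
the atlas striatum supply the striatal reference M_s and its mean c_s.

Notes on conventions
--------------------
* e_j is measured empirically from the reference voxels' own bin assignment.
  On continuous data the quantile construction makes e_j ~= 1/K; with heavy
  ties bins merge and e_j reflects the actual mass, keeping Y well defined.
* A fully degenerate reference (a single distinct value) switches to exact
  matching: a window conforms iff every voxel equals that value.
* Windows are evaluated only where fully inside the grid; centers closer
  than l to the boundary are excluded and counted.
* The published fixed threshold 1e-3 is available, but the default derives
  the threshold per reference histogram as the 95th percentile of Y under
  multinomial sampling at the window size (seeded simulation), since the
  sampling floor of Y at window size N is ~(K-1)/N, far above 1e-3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .config import PipelineConfig
from .image import AtlasLabels, VolumetricImage

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


# --------------------------------------------------------------------------
# Quantile histogram


@dataclass
class QuantileHistogram:
    """K-bin quantile description of a reference region's intensities."""

    edges: np.ndarray          # bin edges, length n_bins + 1, non-decreasing
    proportions: np.ndarray    # e_j, length n_bins, sums to 1, all > 0
    n_reference: int
    degenerate: bool = False   # single distinct reference value

    @property
    def n_bins(self) -> int:
        return len(self.proportions)

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Bin index for each value; out-of-range values are clipped into
        the extreme bins. Meaningless for degenerate histograms."""
        idx = np.searchsorted(self.edges, values, side="right") - 1
        return np.clip(idx, 0, self.n_bins - 1)


def quantile_reference(values: np.ndarray, n_bins: int) -> QuantileHistogram:
    """Summarize a reference region into quantile bins with empirical mass.

    Duplicate quantile edges (tied intensities) are merged, so the returned
    histogram may hold fewer than ``n_bins`` bins, each with positive mass.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size < n_bins:
        raise ValueError(
            f"reference region has {values.size} voxels, fewer than "
            f"{n_bins} quantile bins")
    vmin, vmax = values.min(), values.max()
    if vmin == vmax:
        return QuantileHistogram(
            edges=np.array([vmin, vmax]),
            proportions=np.array([1.0]),
            n_reference=values.size,
            degenerate=True)
    edges = np.unique(np.quantile(values, np.linspace(0.0, 1.0, n_bins + 1)))
    hist = QuantileHistogram(edges=edges,
                             proportions=np.empty(len(edges) - 1),
                             n_reference=values.size)
    counts = np.bincount(hist.assign(values), minlength=hist.n_bins)
    while np.any(counts == 0) and len(counts) > 1:
        j = int(np.flatnonzero(counts == 0)[0])  # merge empty bin leftward
        keep = j if j > 0 else 1
        edges = np.delete(edges, keep)
        hist = QuantileHistogram(edges=edges,
                                 proportions=np.empty(len(edges) - 1),
                                 n_reference=values.size)
        counts = np.bincount(hist.assign(values), minlength=hist.n_bins)
    hist.proportions = counts / values.size
    return hist


def y_statistic(observed: Sequence[float], expected: Sequence[float]) -> float:
    """Conformity statistic between two proportion vectors.

    Zero iff observed equals expected; grows with the squared per-bin
    discrepancy weighted by the reference mass.
    """
    o = np.asarray(observed, dtype=np.float64)
    e = np.asarray(expected, dtype=np.float64)
    if o.shape != e.shape:
        raise ValueError("observed/expected length mismatch")
    if np.any(e <= 0):
        raise ValueError("zero reference bin")
    if abs(o.sum() - 1.0) > 1e-9 or abs(e.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must each sum to 1")
    y = 0.0
    for j in range(len(o)):          # fixed order, matches the filter
        y += (o[j] - e[j]) ** 2 / e[j]
    return float(y)


def calibrated_threshold(hist: QuantileHistogram, window_volume: int,
                         seed: int, n_sim: int = 256,
                         quantile: float = 0.95) -> float:
    """q95 of Y under multinomial sampling of `window_volume` voxels from
    the reference distribution — the finite-window sampling floor."""
    if hist.degenerate:
        return 0.0
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(window_volume, hist.proportions, size=n_sim)
    o = draws / window_volume
    e = hist.proportions[None, :]
    ys = np.zeros(n_sim)
    for j in range(hist.n_bins):
        ys += (o[:, j] - e[0, j]) ** 2 / e[0, j]
    return float(np.quantile(ys, quantile))


# --------------------------------------------------------------------------
# Sliding-window filter


def _box_counts(indicator: np.ndarray, half: int) -> np.ndarray:
    """Exact integer counts of True voxels in every (2*half+1)^3 window,
    for all fully-inside window centers (integral-image method)."""
    w = 2 * half + 1
    padded = np.zeros(tuple(s + 1 for s in indicator.shape), dtype=np.int64)
    padded[1:, 1:, 1:] = indicator.astype(np.int64)
    for ax in range(3):
        np.cumsum(padded, axis=ax, out=padded)
    P = padded
    return (P[w:, w:, w:] - P[:-w, w:, w:] - P[w:, :-w, w:] - P[w:, w:, :-w]
            + P[:-w, :-w, w:] + P[:-w, w:, :-w] + P[w:, :-w, :-w]
            - P[:-w, :-w, :-w])


def _interior(shape: Tuple[int, ...], half: int) -> np.ndarray:
    valid = np.zeros(shape, dtype=bool)
    sl = tuple(slice(half, s - half) for s in shape)
    if all(s.stop > s.start for s in sl):
        valid[sl] = True
    return valid


def y_filter(grid: np.ndarray, hist: QuantileHistogram,
             search_mask: np.ndarray, l_ref: int,
             threshold: float) -> Tuple[np.ndarray, Dict]:
    """Accept every search-mask voxel whose window distribution conforms.

    Returns the accepted mask and diagnostics (boundary exclusions,
    acceptance rate, the per-voxel Y map over valid centers).
    """
    grid = np.asarray(grid, dtype=np.float64)
    w3 = (2 * l_ref + 1) ** 3
    valid = _interior(grid.shape, l_ref)
    core = tuple(slice(l_ref, s - l_ref) for s in grid.shape)

    if hist.degenerate:
        v = hist.edges[0]
        conform = _box_counts(grid == v, l_ref) == w3
        accepted = np.zeros(grid.shape, dtype=bool)
        accepted[core] = conform
        y_map = None
    else:
        bins = hist.assign(grid)
        y_core = np.zeros(tuple(s - 2 * l_ref for s in grid.shape))
        for j in range(hist.n_bins):        # sequential accumulation
            o_j = _box_counts(bins == j, l_ref) / w3
            y_core += (o_j - hist.proportions[j]) ** 2 / hist.proportions[j]
        accepted = np.zeros(grid.shape, dtype=bool)
        accepted[core] = y_core <= threshold
        y_map = y_core

    accepted &= search_mask
    n_boundary = int(np.count_nonzero(search_mask & ~valid))
    n_search = int(np.count_nonzero(search_mask & valid))
    diag = {
        "n_boundary_excluded": n_boundary,
        "acceptance_rate": (float(np.count_nonzero(accepted)) / n_search
                            if n_search else 0.0),
        "threshold": float(threshold),
        "degenerate_reference": hist.degenerate,
        "y_map_core": y_map,
    }
    return accepted, diag


def combine_reference_masks(masks: Sequence[np.ndarray],
                            threshold: float = 0.5) -> np.ndarray:
    """Average the per-lobe indicator masks; keep voxels whose mean
    indicator reaches the threshold (0.5 -> at least 3 of 5)."""
    if not masks:
        raise ValueError("no masks to combine")
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ValueError("masks on different grids")
    mean_ind = np.mean([m.astype(np.float64) for m in masks], axis=0)
    combined = mean_ind >= threshold
    if not combined.any():
        raise ValueError("no reference tissue found")
    return combined


# --------------------------------------------------------------------------
# Striatal reference


def striatal_component(pet: np.ndarray, rejected: np.ndarray,
                       striatum_label: np.ndarray, hemisphere: np.ndarray,
                       background_level: float) -> Tuple[np.ndarray, List[str]]:
    """Hyperintense discarded component(s) covering the striatum.

    The filter also discards a window-thick halo of background-level voxels
    around any hyperintense structure (their windows overlap it), so the
    raw discarded component would dilute the striatal mean. Components are
    therefore gated at the midpoint between the background level and the
    striatal estimate before extraction; the discarded voxels inside the
    atlas label are always kept.
    """
    flags: List[str] = []
    region = rejected & hemisphere
    seed = region & striatum_label
    if not seed.any():
        flags.append("striatal_fallback")
        return striatum_label & hemisphere, flags
    striatal_est = float(pet[seed].mean())
    gate = 0.5 * (background_level + striatal_est)
    gated = region & (pet >= gate)
    lab, n = ndimage.label(gated, structure=_STRUCT26)
    touching = np.unique(lab[gated & striatum_label])
    touching = touching[touching > 0]
    mask = np.isin(lab, touching) | seed
    return mask, flags


def extract_striatal_reference(pet: np.ndarray, rejected: np.ndarray,
                               striatum_label: np.ndarray,
                               hemisphere: np.ndarray,
                               background_level: float,
                               ) -> Tuple[np.ndarray, float, List[str]]:
    """Striatal mask M_s on the non-affected side and its mean activity c_s."""
    if not striatum_label.any():
        raise ValueError("atlas striatum label empty on the non-affected side")
    m_s, flags = striatal_component(pet, rejected, striatum_label,
                                    hemisphere, background_level)
    c_s = float(pet[m_s].mean())
    return m_s, c_s, flags


def normalize(image: VolumetricImage, c: float) -> VolumetricImage:
    """Divide every voxel by a positive normalization constant."""
    if not c > 0:
        raise ValueError("normalization constant must be > 0")
    return VolumetricImage(image.grid / c, image.affine, image.modality)


# --------------------------------------------------------------------------
# Orchestration over the five lobes


@dataclass
class ReferenceResult:
    """Everything the reference stage produces for one case."""

    lobe_masks: List[np.ndarray]     # M_i, accepted set per lobe reference
    accepted: np.ndarray             # combined accepted voxels (whole brain)
    rejected: np.ndarray             # brain minus accepted
    m_n: np.ndarray
    m_s: np.ndarray
    c_n: float
    c_s: float
    thresholds: List[float]
    flags: List[str] = field(default_factory=list)
    diagnostics: Dict = field(default_factory=dict)


def extract_references(pet: VolumetricImage, atlas: AtlasLabels,
                       unaffected_side: str, cfg: PipelineConfig,
                       ) -> ReferenceResult:
    """Run the conformity filter for the five contralateral lobes and build
    M_n, M_s, c_n, c_s.

    Each lobe of the non-affected hemisphere supplies one reference
    histogram; its filter runs over the whole brain (so the discarded set is
    defined on both sides), and the five accepted masks are combined by the
    averaging rule. M_n is the combined mask restricted to the non-affected
    hemisphere (or, with ``per_lobe_search``, the union of each lobe's
    accepted voxels within that lobe).
    """
    grid = pet.grid
    brain = atlas.brain_mask()
    hemi = atlas.hemisphere_mask(unaffected_side)
    flags: List[str] = []
    lobe_masks: List[np.ndarray] = []
    thresholds: List[float] = []
    per_lobe_diag = []
    lobes = atlas.lobe_masks(unaffected_side)
    for i, lobe in enumerate(lobes):
        hist = quantile_reference(grid[lobe], cfg.quantile_bins)
        if hist.degenerate:
            flags.append(f"degenerate_reference_lobe_{i + 1}")
        if cfg.y_threshold_mode == "calibrated":
            thr = calibrated_threshold(
                hist, (2 * cfg.l_ref + 1) ** 3,
                seed=cfg.seed + 7919 * (i + 1))
            thr = max(thr, cfg.y_threshold)
        else:
            thr = cfg.y_threshold
        accepted_i, diag = y_filter(grid, hist, brain, cfg.l_ref, thr)
        lobe_masks.append(accepted_i)
        thresholds.append(thr)
        diag.pop("y_map_core", None)
        per_lobe_diag.append(diag)

    accepted = combine_reference_masks(
        lobe_masks, cfg.mask_combination_threshold)
    rejected = brain & ~accepted

    if cfg.per_lobe_search:
        m_n = np.zeros_like(accepted)
        for m_i, lobe in zip(lobe_masks, lobes):
            m_n |= m_i & lobe
    else:
        m_n = accepted & hemi
    if not m_n.any():
        raise ValueError("no reference tissue found")
    c_n = float(grid[m_n].mean())

    m_s, c_s, s_flags = extract_striatal_reference(
        grid, rejected, atlas.striatum_mask(unaffected_side), hemi, c_n)
    flags.extend(s_flags)
    if (m_n & m_s).any():        # can only happen through the fallback path
        m_n = m_n & ~m_s
        c_n = float(grid[m_n].mean())
        flags.append("m_n_striatum_overlap_removed")

    return ReferenceResult(
        lobe_masks=lobe_masks, accepted=accepted, rejected=rejected,
        m_n=m_n, m_s=m_s, c_n=c_n, c_s=c_s, thresholds=thresholds,
        flags=flags, diagnostics={"per_lobe": per_lobe_diag})
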