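"""Synthetic PET+FLAIR+atlas phantoms with known ground truth.

The phantom emulates the imaging assumptions the automated procedure rests
on: a monolateral lesion with elevated tracer uptake and FLAIR
hyperintensity, bilaterally hyperintense striata, and smooth background
parenchyma with additive Gaussian noise — all already in a common
atlas-space grid. The "brain" is an ellipsoid split into two hemispheres,
each carrying five lobe labels and one striatum label, plus a pons; no real
anatomy is needed because the method only consumes this label logic.

The lesion has a flat plateau core (uptake declines from the center to the
periphery, as gliomas present) wider than the maxima window, so the local
window mean at the center equals the plateau value and the expected scores
are known in closed form: t_n = peak/background, t_s = peak/striatum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .image import AtlasLabels, VolumetricImage

# Label scheme of the synthetic atlas.
LEFT_LOBES = (1, 2, 3, 4, 5)
RIGHT_LOBES = (6, 7, 8, 9, 10)
STRIATUM_LEFT, STRIATUM_RIGHT, PONS = 11, 12, 13

LEGEND = {
    **{lab: f"lobe_left_{i}" for i, lab in enumerate(LEFT_LOBES, 1)},
    **{lab: f"lobe_right_{i}" for i, lab in enumerate(RIGHT_LOBES, 1)},
    STRIATUM_LEFT: "striatum_left",
    STRIATUM_RIGHT: "striatum_right",
    PONS: "pons",
}


@dataclass
class PhantomSpec:
    """Geometry and intensity parameters of one synthetic case.

    Defaults put a right-hemisphere lesion at twice the background uptake
    (plateau core 9 voxels across), striata at 2.5x background on both
    sides, and 5% Gaussian noise — a configuration representative of a
    clearly hyperintense glioma on a quiet parenchyma.
    """

    shape: Tuple[int, int, int] = (64, 64, 64)
    background_pet_mean: float = 1.0
    background_noise_sigma: float = 0.05
    striatum_pet_mean: float = 2.5
    lesion_pet_peak: float = 2.0
    lesion_flair_contrast: float = 1.5
    lesion_radius: float = 7.0
    lesion_plateau_radius: float = 4.0
    lesion_center: Optional[Tuple[float, float, float]] = None
    lesion_side: str = "right"
    lesion_touches_striatum: bool = False
    bilateral: bool = False
    maxima_window_half: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.background_pet_mean, self.striatum_pet_mean,
               self.lesion_pet_peak) <= 0:
            raise ValueError("all mean activities must be > 0")
        if self.background_noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.lesion_plateau_radius > self.lesion_radius:
            raise ValueError("plateau radius cannot exceed lesion radius")
        if 2 * self.lesion_plateau_radius + 1 < 2 * self.maxima_window_half + 1:
            warnings.warn(
                "lesion plateau narrower than the maxima window; exact "
                "peak recovery is not guaranteed", stacklevel=2)


@dataclass
class PhantomBundle:
    """A generated case plus its ground truth."""

    pet: VolumetricImage
    flair: VolumetricImage
    atlas: AtlasLabels
    truth: Dict = field(default_factory=dict)


def _sphere(shape, center, radius) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius ** 2


def _radial_profile(shape, center, radius, plateau_radius,
                    peak, background) -> np.ndarray:
    """Plateau at `peak` out to plateau_radius, linear decline to
    `background` at `radius`, background beyond."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r = np.sqrt(sum((g - c) ** 2.0 for g, c in zip(grids, center)))
    out = np.full(shape, background, dtype=np.float64)
    ramp = (r > plateau_radius) & (r <= radius)
    if radius > plateau_radius:
        frac = (radius - r[ramp]) / (radius - plateau_radius)
        out[ramp] = background + frac * (peak - background)
    out[r <= plateau_radius] = peak
    return out


def _build_atlas(shape) -> Tuple[AtlasLabels, Dict[str, np.ndarray], dict]:
    nx, ny, nz = shape
    cx, cy, cz = nx // 2, ny // 2, nz // 2 + 2
    semi = (0.41 * nx, 0.375 * ny, 0.3125 * nz)  # (26, 24, 20) at 64^3
    grids = np.ogrid[0:nx, 0:ny, 0:nz]
    brain = (sum(((g - c) / a) ** 2
                 for g, c, a in zip(grids, (cx, cy, cz), semi)) <= 1.0)

    geom = {
        "center": (cx, cy, cz),
        "striatum_radius": 0.078 * nx,  # 5 at 64^3
        "striatum_left": (cx - 0.1875 * nx, cy, cz),
        "striatum_right": (cx + 0.1875 * nx, cy, cz),
        "pons_center": (cx, cy + 0.125 * ny, max(cz - 0.28 * nz, 2)),
        "pons_radius": 0.0625 * nx,
    }
    striat = {
        "left": _sphere(shape, geom["striatum_left"], geom["striatum_radius"]) & brain,
        "right": _sphere(shape, geom["striatum_right"], geom["striatum_radius"]) & brain,
    }
    pons = _sphere(shape, geom["pons_center"], geom["pons_radius"]) & brain

    labels = np.zeros(shape, dtype=np.int32)
    x = np.arange(nx)[:, None, None]
    for side, lobes in (("left", LEFT_LOBES), ("right", RIGHT_LOBES)):
        hemi = brain & ((x < cx) if side == "left" else (x >= cx))
        hemi &= ~pons & ~striat["left"] & ~striat["right"]
        ys = np.nonzero(hemi)[1]
        # five antero-posterior slabs with near-equal voxel counts
        edges = np.quantile(ys, [0.2, 0.4, 0.6, 0.8])
        slab = np.digitize(np.arange(ny), edges)  # 0..4 per y index
        for i, lab in enumerate(lobes):
            labels[hemi & (slab[None, :, None] == i)] = lab
    labels[striat["left"]] = STRIATUM_LEFT
    labels[striat["right"]] = STRIATUM_RIGHT
    labels[pons] = PONS

    atlas = AtlasLabels(labels=labels, legend=dict(LEGEND))
    masks = {"brain": brain, "striatum_left": striat["left"],
             "striatum_right": striat["right"], "pons": pons}
    return atlas, masks, geom


def _default_lesion_center(spec: PhantomSpec, geom: dict):
    cx, cy, cz = geom["center"]
    sx = 1.0 if spec.lesion_side == "right" else -1.0
    if spec.lesion_touches_striatum:
        # just antero-dorsal to the striatum so the spheres overlap
        stri = geom["striatum_right" if spec.lesion_side == "right" else "striatum_left"]
        return (stri[0], stri[1] - 6.0, stri[2] + 4.0)
    return (cx + sx * 10.0, cy - 12.0, cz + 6.0)


def generate_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Build one deterministic phantom case from its spec."""
    shape = tuple(spec.shape)
    atlas, masks, geom = _build_atlas(shape)
    brain = masks["brain"]

    center = spec.lesion_center or _default_lesion_center(spec, geom)
    lesion = _sphere(shape, center, spec.lesion_radius)
    if np.any(lesion & ~brain):
        raise ValueError("lesion extends outside the brain")
    hemi = atlas.hemisphere_mask(spec.lesion_side)
    if not spec.bilateral and not np.all(
            (lesion & brain) <= (hemi | masks["pons"])):
        raise ValueError("lesion not contained in a single hemisphere")

    mu = spec.background_pet_mean
    pet = np.zeros(shape, dtype=np.float64)
    pet[brain] = mu
    for side in ("left", "right"):
        pet[masks[f"striatum_{side}"]] = spec.striatum_pet_mean

    flair = np.zeros(shape, dtype=np.float64)
    flair[brain] = 1.0

    centers = [center]
    if spec.bilateral:
        cx = geom["center"][0]
        centers.append((2 * cx - center[0], center[1], center[2]))
    lesion_mask = np.zeros(shape, dtype=bool)
    plateau_mask = np.zeros(shape, dtype=bool)
    for c in centers:
        prof = _radial_profile(shape, c, spec.lesion_radius,
                               spec.lesion_plateau_radius,
                               spec.lesion_pet_peak, mu)
        pet = np.where(brain, np.maximum(pet, prof), pet)
        fprof = _radial_profile(shape, c, spec.lesion_radius,
                                spec.lesion_plateau_radius,
                                spec.lesion_flair_contrast, 1.0)
        flair = np.where(brain, np.maximum(flair, fprof), flair)
        lesion_mask |= _sphere(shape, c, spec.lesion_radius) & brain
        plateau_mask |= _sphere(shape, c, spec.lesion_plateau_radius) & brain

    if spec.background_noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        pet[brain] += rng.normal(0.0, spec.background_noise_sigma,
                                 int(brain.sum()))
        flair[brain] += rng.normal(0.0, spec.background_noise_sigma,
                                   int(brain.sum()))
        np.clip(pet, 0.0, None, out=pet)
        np.clip(flair, 0.0, None, out=flair)

    affine = np.eye(4)
    affine[:3, 3] = -np.asarray(geom["center"], dtype=float)
    atlas.affine = affine
    bundle = PhantomBundle(
        pet=VolumetricImage(pet, affine, "PET"),
        flair=VolumetricImage(flair, affine, "FLAIR"),
        atlas=atlas,
        truth={
            "lesion_mask": lesion_mask,
            "plateau_mask": plateau_mask,
            "striatum_left": masks["striatum_left"],
            "striatum_right": masks["striatum_right"],
            "brain_mask": brain,
            "affected_side": None if spec.bilateral else spec.lesion_side,
            "spec": spec,
        },
    )
    t_n, t_s = ground_truth_scores(bundle)
    bundle.truth["expected_t_n"] = t_n
    bundle.truth["expected_t_s"] = t_s
    return bundle


def ground_truth_scores(bundle: PhantomBundle) -> Tuple[float, float]:
    """Analytic expected scores: plateau mean over background mean, and
    plateau mean over striatum mean."""
    spec: PhantomSpec = bundle.truth["spec"]
    t_n = spec.lesion_pet_peak / spec.background_pet_mean
    t_s = spec.lesion_pet_peak / spec.striatum_pet_mean
    return float(t_n), float(t_s)
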