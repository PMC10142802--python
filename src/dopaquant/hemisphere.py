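"""Lesion lateralization from FLAIR.

The FLAIR scan is parcelled into ~300 spatially compact districts by a
supervoxel K-means (SLIC: K-means over intensity and position with a
deterministic grid initialization, post-split into 26-connected
components). Each district is summarized by 14 intensity statistics and a
linear-margin SVM labels it healthy or pathological; the union of
pathological districts forms a coarse affected-tissue mask V_t whose
hemisphere overlap decides the affected side. Segmentation accuracy is
deliberately not a goal — any coarse V_t that lands mostly in the correct
hemisphere serves, because V_t is only a seed for choosing the reference
hemisphere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import joblib
import numpy as np
from scipy import stats as sstats
from skimage import measure, segmentation
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .config import PipelineConfig
from .image import AtlasLabels, VolumetricImage

HEALTHY, PATHOLOGICAL = 0, 1

#: Feature order is fixed: average, standard deviation, variance, mean and
#: median absolute deviation, skewness, kurtosis, maximum, minimum, median,
#: mode, range, interquartile range, entropy.
FEATURE_NAMES = (
    "mean", "std", "variance", "mean_abs_dev", "median_abs_dev",
    "skewness", "kurtosis", "max", "min", "median", "mode", "range",
    "iqr", "entropy",
)

_ENTROPY_BINS = 32


@dataclass
class District:
    """One connected parcel of the brain with its feature vector."""

    id: int
    indices: np.ndarray              # flat voxel indices into the grid
    features: Optional[np.ndarray] = None
    label: Optional[int] = None      # HEALTHY / PATHOLOGICAL

    @property
    def size(self) -> int:
        return int(self.indices.size)


def texture_features(values: np.ndarray) -> np.ndarray:
    """The 14 intensity statistics of one district.

    Conventions for the unnamed details: sample (n-1) standard deviation
    and variance; Fisher-Pearson moment skewness and Fisher (excess) moment
    kurtosis (defined for any district size >= 2, and 0 for a constant
    district); entropy is the Shannon entropy (bits) of a 32-bin histogram
    over the district's own range; the mode is the mean of the values in
    the most populated of those bins (smallest bin wins ties).
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size < 2:
        raise ValueError("district must contain at least 2 voxels")
    mean = v.mean()
    std = v.std(ddof=1)
    median = float(np.median(v))
    vmin, vmax = float(v.min()), float(v.max())
    constant = vmax == vmin
    if constant:
        skew = kurt = entropy = 0.0
        mode = mean
    else:
        skew = float(sstats.skew(v, bias=True))
        kurt = float(sstats.kurtosis(v, fisher=True, bias=True))
        counts, edges = np.histogram(v, bins=_ENTROPY_BINS, range=(vmin, vmax))
        p = counts[counts > 0] / v.size
        entropy = float(-(p * np.log2(p)).sum())
        modal = int(np.argmax(counts))   # argmax returns the smallest tie
        lo, hi = edges[modal], edges[modal + 1]
        in_bin = (v >= lo) & ((v < hi) if modal < _ENTROPY_BINS - 1 else (v <= hi))
        mode = float(v[in_bin].mean())
    q1, q3 = np.percentile(v, [25, 75])
    feats = np.array([
        mean, std, std ** 2,
        float(np.abs(v - mean).mean()),
        float(np.median(np.abs(v - median))),
        skew, kurt, vmax, vmin, median, mode,
        vmax - vmin, q3 - q1, entropy,
    ])
    if not np.all(np.isfinite(feats)):
        raise ValueError("non-finite texture features")
    return feats


def parcellate(flair: VolumetricImage, brain_mask: np.ndarray,
               cfg: PipelineConfig) -> List[District]:
    """Split the brain into ~k_districts compact districts.

    SLIC supervoxels on the min-max normalized FLAIR, then a
    26-connected-component split so every district is connected; components
    below 2 voxels are merged into their dominant neighbor. Deterministic.
    """
    grid = flair.grid
    vals = grid[brain_mask]
    if vals.size == 0:
        raise ValueError("empty brain mask")
    vmin, vmax = vals.min(), vals.max()
    if vmax == vmin:
        raise ValueError("degenerate parcellation: constant image")
    norm = np.zeros_like(grid)
    norm[brain_mask] = (vals - vmin) / (vmax - vmin)

    labels = segmentation.slic(
        norm, n_segments=cfg.k_districts, compactness=0.05,
        mask=brain_mask, channel_axis=None, start_label=1,
        enforce_connectivity=True)
    comps = measure.label(labels, background=0, connectivity=3)
    comps[~brain_mask] = 0

    # merge sub-minimal components into the neighbor with most contact
    sizes = np.bincount(comps.ravel())
    small = np.flatnonzero(sizes < 2)
    small = small[small > 0]
    if small.size:
        from scipy import ndimage
        for cid in small:
            vox = np.argwhere(comps == cid)
            neigh: Dict[int, int] = {}
            for p in vox:
                lo = np.maximum(p - 1, 0)
                hi = np.minimum(p + 2, comps.shape)
                block = comps[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
                for q in np.unique(block):
                    if q not in (0, cid):
                        neigh[q] = neigh.get(q, 0) + int((block == q).sum())
            if neigh:
                comps[comps == cid] = max(neigh, key=neigh.get)

    ids = np.unique(comps)
    ids = ids[ids > 0]
    flat = comps.ravel()
    order = np.argsort(flat, kind="stable")
    sorted_vals = flat[order]
    districts = []
    for did in ids:
        lo = np.searchsorted(sorted_vals, did, side="left")
        hi = np.searchsorted(sorted_vals, did, side="right")
        districts.append(District(id=int(did), indices=order[lo:hi]))
    n = len(districts)
    if not 0.5 * cfg.k_districts <= n <= 2 * cfg.k_districts:
        import logging
        logging.getLogger(__name__).warning(
            "district count %d outside [0.5, 2] x %d", n, cfg.k_districts)
    return districts


def compute_district_features(districts: Sequence[District],
                              flair: VolumetricImage) -> None:
    flat = flair.grid.ravel()
    for d in districts:
        d.features = texture_features(flat[d.indices])


def label_districts_from_mask(districts: Sequence[District],
                              lesion_mask: np.ndarray,
                              min_fraction: float = 0.5) -> None:
    """Assign PATHOLOGICAL to districts mostly inside a reference lesion
    mask (ground truth or expert drawing), HEALTHY otherwise."""
    flat = lesion_mask.ravel()
    for d in districts:
        frac = float(flat[d.indices].mean())
        d.label = PATHOLOGICAL if frac >= min_fraction else HEALTHY


@dataclass
class ClassifierModel:
    """Trained healthy/pathological district classifier.

    A linear-kernel SVM (C=1) over z-scored features; the published
    procedure names the classifier and features but no hyperparameters,
    so the simplest margin classifier is used.
    """

    pipeline: Pipeline
    n_training: int
    class_counts: Dict[int, int]
    training_accuracy: float

    def predict(self, features: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(features, dtype=np.float64))
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite feature vector")
        return self.pipeline.predict(X)

    def save(self, path: str | Path) -> None:
        joblib.dump(self, str(path))

    @staticmethod
    def load(path: str | Path) -> "ClassifierModel":
        model = joblib.load(str(path))
        if not isinstance(model, ClassifierModel):
            raise TypeError("not a ClassifierModel file")
        return model


def train_classifier(districts: Sequence[District],
                     seed: int = 0) -> ClassifierModel:
    """Fit the district classifier on labelled districts.

    Classes are balanced by random subsampling to the minority count before
    fitting (as the published procedure did with its 300-region balanced
    set); features are standardized on the training sample.
    """
    labelled = [d for d in districts if d.label is not None]
    if not labelled:
        raise ValueError("no labelled districts")
    X = np.stack([d.features for d in labelled])
    y = np.array([d.label for d in labelled])
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training set contains a single class")
    n_per_class = counts.min()
    rng = np.random.default_rng(seed)
    keep = np.concatenate([
        rng.choice(np.flatnonzero(y == c), size=n_per_class, replace=False)
        for c in classes])
    keep.sort()
    Xb, yb = X[keep], y[keep]
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(kernel="linear", C=1.0)),
    ])
    pipe.fit(Xb, yb)
    acc = float((pipe.predict(Xb) == yb).mean())
    return ClassifierModel(
        pipeline=pipe, n_training=int(len(yb)),
        class_counts={int(c): int((yb == c).sum()) for c in classes},
        training_accuracy=acc)


@dataclass
class HemisphereDecision:
    affected_side: str
    v_t: np.ndarray
    overlap_fractions: Dict[str, float]


def classify_and_lateralize(model: ClassifierModel,
                            districts: Sequence[District],
                            atlas: AtlasLabels,
                            tie_tolerance: float = 0.01,
                            ambiguity_fraction: float = 0.25,
                            ) -> HemisphereDecision:
    """Predict district labels, build V_t and pick the affected hemisphere.

    The affected side maximizes |V_t ∩ hemisphere| / |V_t|. The decision is
    refused as "ambiguous hemisphere" either on a near-tie (fraction
    difference below ``tie_tolerance``) or when the minority hemisphere
    still holds more than ``ambiguity_fraction`` of V_t — a district-level
    parcellation never splits a bilateral lesion exactly 50/50, so the
    minority-share bound is what enforces the monolaterality assumption in
    practice.
    """
    X = np.stack([d.features for d in districts])
    pred = model.predict(X)
    shape = atlas.labels.shape
    v_t = np.zeros(shape, dtype=bool).ravel()
    for d, p in zip(districts, pred):
        if p == PATHOLOGICAL:
            v_t[d.indices] = True
    v_t = v_t.reshape(shape)
    if not v_t.any():
        raise ValueError("no affected tissue detected")
    total = float(v_t.sum())
    fractions = {
        side: float((v_t & atlas.hemisphere_mask(side)).sum()) / total
        for side in ("left", "right")}
    diff = abs(fractions["left"] - fractions["right"])
    if diff < tie_tolerance or min(fractions.values()) > ambiguity_fraction:
        raise ValueError("ambiguous hemisphere")
    side = max(fractions, key=fractions.get)
    return HemisphereDecision(affected_side=side, v_t=v_t,
                              overlap_fractions=fractions)
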