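"""Quantile histogram, Y statistic and the sliding-window conformity filter.

The sliding-window implementation is checked voxel-by-voxel against a
brute-force oracle that recounts every window's bin occupancy and
re-evaluates the statistic independently.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dopaquant import (PipelineConfig, VolumetricImage,
                       combine_reference_masks, extract_references,
                       extract_striatal_reference, normalize,
                       quantile_reference, y_filter, y_statistic)
from dopaquant.reference import calibrated_threshold


# ---------------------------------------------------------------- histogram

def test_decile_bins_on_uniform_sequence():
    hist = quantile_reference(np.arange(1.0, 101.0), 10)
    assert hist.n_bins == 10
    np.testing.assert_allclose(hist.proportions, 0.1)
    np.testing.assert_allclose(hist.edges, np.quantile(np.arange(1, 101.0),
                                                       np.linspace(0, 1, 11)))


def test_median_split():
    hist = quantile_reference(np.array([1.0, 2.0, 3.0, 4.0]), 2)
    assert hist.n_bins == 2
    np.testing.assert_allclose(hist.proportions, [0.5, 0.5])


def test_degenerate_reference_flagged():
    hist = quantile_reference(np.full(50, 7.0), 10)
    assert hist.degenerate
    assert hist.proportions.tolist() == [1.0]


def test_too_few_voxels():
    with pytest.raises(ValueError, match="fewer"):
        quantile_reference(np.arange(5.0), 10)


def test_tied_values_merge_bins_with_positive_mass():
    values = np.array([1.0] * 40 + [2.0] * 40 + [3.0] * 20)
    hist = quantile_reference(values, 10)
    assert np.all(hist.proportions > 0)
    assert hist.proportions.sum() == pytest.approx(1.0)


# ---------------------------------------------------------------- statistic

def test_y_zero_iff_match():
    e = np.full(10, 0.1)
    assert y_statistic(e, e) == 0.0


def test_y_hand_computed_case():
    """One bin doubled, one emptied: Y = 0.1^2/0.1 * 2 = 0.2."""
    e = np.full(10, 0.1)
    o = np.array([0.2] + [0.1] * 8 + [0.0])
    assert y_statistic(o, e) == pytest.approx(0.2)


def test_y_fully_concentrated():
    """All mass in one decile: Y = 0.9^2/0.1 + 9 * 0.1^2/0.1 = 9.0."""
    e = np.full(10, 0.1)
    o = np.zeros(10)
    o[0] = 1.0
    assert y_statistic(o, e) == pytest.approx(9.0)


def test_y_input_validation():
    e = np.full(10, 0.1)
    with pytest.raises(ValueError, match="sum to 1"):
        y_statistic(np.full(10, 0.2), e)
    with pytest.raises(ValueError, match="zero reference"):
        y_statistic(e, np.array([0.0] + [1.0 / 9] * 9))


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.integers(min_value=0, max_value=50), min_size=2,
                max_size=12).filter(lambda c: sum(c) > 0))
def test_y_nonnegative_and_zero_only_at_match(counts):
    o = np.asarray(counts, float) / sum(counts)
    e = np.full(len(counts), 1.0 / len(counts))
    y = y_statistic(o, e)
    assert y >= 0.0
    assert (y == 0.0) == np.allclose(o, e)


# ------------------------------------------------------------------ filter

def _brute_force_filter(grid, hist, search, l, threshold):
    """Independent per-voxel recount of window bin occupancy."""
    out = np.zeros(grid.shape, bool)
    n = (2 * l + 1) ** 3
    for p in np.argwhere(search):
        lo = p - l
        hi = p + l + 1
        if np.any(lo < 0) or np.any(hi > grid.shape):
            continue
        window = grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].ravel()
        if hist.degenerate:
            out[tuple(p)] = np.all(window == hist.edges[0])
            continue
        counts = np.bincount(hist.assign(window), minlength=hist.n_bins)
        y = 0.0
        for j in range(hist.n_bins):
            y += (counts[j] / n - hist.proportions[j]) ** 2 / hist.proportions[j]
        out[tuple(p)] = y <= threshold
    return out


def test_filter_matches_brute_force_oracle():
    """Sliding-window mask identical to exhaustive recomputation, 20^3."""
    rng = np.random.default_rng(0)
    grid = rng.normal(1.0, 0.1, (20, 20, 20))
    grid[8:14, 8:14, 8:14] = rng.normal(2.0, 0.1, (6, 6, 6))  # hot cube
    search = np.ones(grid.shape, bool)
    hist = quantile_reference(grid[:, :, :8].ravel(), 10)
    for thr in (1e-3, 0.05, 0.5):
        fast, _ = y_filter(grid, hist, search, 3, thr)
        slow = _brute_force_filter(grid, hist, search, 3, thr)
        assert np.array_equal(fast, slow)


def test_degenerate_filter_matches_brute_force():
    grid = np.ones((20, 20, 20))
    grid[10:13, 10:13, 10:13] = 2.0
    hist = quantile_reference(np.ones(100), 10)
    search = np.ones(grid.shape, bool)
    fast, _ = y_filter(grid, hist, search, 3, 1e-3)
    slow = _brute_force_filter(grid, hist, search, 3, 1e-3)
    assert np.array_equal(fast, slow)
    # the hot cube and its window-reach halo are rejected
    assert not fast[10:13, 10:13, 10:13].any()
    assert fast[3:7, 3:7, 3:7].all()


def test_hot_sphere_rejected_homogeneous_accepted():
    """A 2x-hot sphere is rejected; conforming background accepted."""
    rng = np.random.default_rng(1)
    grid = rng.normal(1.0, 0.05, (30, 30, 30))
    z, y, x = np.ogrid[0:30, 0:30, 0:30]
    sphere = (z - 15) ** 2 + (y - 15) ** 2 + (x - 15) ** 2 <= 36
    grid[sphere] *= 2.0
    hist = quantile_reference(grid[:, :, :8].ravel(), 10)
    thr = calibrated_threshold(hist, 7 ** 3, seed=0)
    accepted, diag = y_filter(grid, hist, np.ones(grid.shape, bool), 3, thr)
    assert not accepted[sphere].any()
    interior = np.zeros(grid.shape, bool)
    interior[3:27, 3:27, 3:27] = True
    clean = interior & ~sphere
    # stay clear of the sphere by its radius plus the window reach
    clean[6:25, 6:25, 6:25] = False
    assert accepted[clean].mean() > 0.9


def test_infinite_threshold_keeps_eroded_search_mask():
    rng = np.random.default_rng(2)
    grid = rng.normal(1.0, 0.1, (16, 16, 16))
    search = np.ones(grid.shape, bool)
    hist = quantile_reference(grid.ravel(), 10)
    accepted, diag = y_filter(grid, hist, search, 3, np.inf)
    expected = np.zeros(grid.shape, bool)
    expected[3:13, 3:13, 3:13] = True
    assert np.array_equal(accepted, expected)
    assert diag["n_boundary_excluded"] == int(search.sum() - expected.sum())


def test_calibrated_threshold_tracks_sampling_floor():
    """q95 of Y at window size N sits near (K-1)/N, far above 1e-3."""
    hist = quantile_reference(np.random.default_rng(3).random(5000), 10)
    thr = calibrated_threshold(hist, 343, seed=0)
    assert 0.01 < thr < 0.1
    assert thr > 1e-3


# ------------------------------------------------------------- combination

def test_majority_combination_rule():
    shape = (4, 4, 4)
    masks = [np.zeros(shape, bool) for _ in range(5)]
    for m in masks:
        m[0, 0, 0] = True          # in all five
    for m in masks[:3]:
        m[1, 1, 1] = True          # in exactly three
    for m in masks[:2]:
        m[2, 2, 2] = True          # in exactly two
    combined = combine_reference_masks(masks, 0.5)
    assert combined[0, 0, 0] and combined[1, 1, 1]
    assert not combined[2, 2, 2]
    assert not combined[3, 3, 3]


def test_empty_combination_is_an_error():
    masks = [np.zeros((4, 4, 4), bool) for _ in range(5)]
    with pytest.raises(ValueError, match="no reference tissue"):
        combine_reference_masks(masks, 0.5)


# --------------------------------------------------------------- reference

def test_references_on_noiseless_phantom(noiseless_bundle, cfg):
    b = noiseless_bundle
    side = "left" if b.truth["affected_side"] == "right" else "right"
    ref = extract_references(b.pet, b.atlas, side, cfg)
    assert ref.c_n == b.truth["spec"].background_pet_mean
    assert ref.c_s == b.truth["spec"].striatum_pet_mean
    truth_striatum = b.truth[f"striatum_{side}"]
    assert np.array_equal(ref.m_s, truth_striatum)
    assert not (ref.m_n & ref.m_s).any()


def test_striatal_mask_covers_truth_on_noisy_phantom(noisy_bundle, cfg):
    b = noisy_bundle
    side = "left" if b.truth["affected_side"] == "right" else "right"
    ref = extract_references(b.pet, b.atlas, side, cfg)
    truth = b.truth[f"striatum_{side}"]
    coverage = (ref.m_s & truth).sum() / truth.sum()
    assert coverage >= 0.9
    assert ref.c_s == pytest.approx(b.truth["spec"].striatum_pet_mean,
                                    rel=0.05)


def test_striatal_fallback_when_striatum_conforms(cfg):
    """Striatum at background uptake: nothing rejected there, fallback."""
    from dopaquant.phantom import PhantomSpec, generate_phantom
    b = generate_phantom(PhantomSpec(striatum_pet_mean=1.0,
                                     background_noise_sigma=0.0, seed=4))
    side = "left" if b.truth["affected_side"] == "right" else "right"
    ref = extract_references(b.pet, b.atlas, side, cfg)
    assert "striatal_fallback" in ref.flags


def test_accepted_reference_is_mono_modal(noisy_result, noisy_bundle):
    """Intensities of M_n form a single-mode (kernel-smoothed) histogram."""
    from scipy.stats import gaussian_kde
    vals = noisy_bundle.pet.grid[noisy_result.masks["M_n"]]
    kde = gaussian_kde(vals)
    xs = np.linspace(vals.min(), vals.max(), 256)
    dens = kde(xs)
    maxima = np.flatnonzero((dens[1:-1] > dens[:-2])
                            & (dens[1:-1] > dens[2:]))
    assert len(maxima) == 1


# ---------------------------------------------------------- normalization

def test_normalize_identity_and_composition():
    img = VolumetricImage(np.arange(27.0).reshape(3, 3, 3) + 1.0,
                          np.eye(4), "PET")
    assert np.array_equal(normalize(img, 1.0).grid, img.grid)
    ab = normalize(normalize(img, 2.0), 3.0)
    direct = normalize(img, 6.0)
    np.testing.assert_allclose(ab.grid, direct.grid)
    with pytest.raises(ValueError):
        normalize(img, 0.0)


def test_normalized_mean_over_mn_is_one(noisy_result, noisy_bundle):
    p_n = normalize(noisy_bundle.pet, noisy_result.c_n)
    m_n = noisy_result.masks["M_n"]
    assert p_n.grid[m_n].mean() == pytest.approx(1.0, abs=1e-12)
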