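"""ROI statistics, the rotating-ROI search, and the CNR computation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acrcnr import (
    AngularProfile,
    DegenerateStatisticsError,
    GeometryError,
    SearchConfig,
    StatisticsError,
    angular_profile,
    auto_cnr,
    circular_roi_mask,
    image_from_array,
    locate_low_contrast_object,
    locate_object,
    measure_cnr,
    roi_stats,
)
from acrcnr.core import roi_center_at_angle
from acrcnr.synthetic import SyntheticPhantomConfig, generate_slice, generate_stack


# --- circular ROI geometry -------------------------------------------------

@pytest.mark.parametrize("diameter", [10.0, 15.0, 20.0, 25.0])
def test_roi_pixel_count_matches_analytic_area(noiseless_slice, diameter):
    image, truth = noiseless_slice
    mask = circular_roi_mask(image, truth.phantom_center_mm, diameter)
    expected = np.pi * (diameter / 2) ** 2 / (image.spacing_mm[0] ** 2)
    assert mask.sum() == pytest.approx(expected, rel=0.02)


def test_pixel_sized_circle_selects_one_pixel(flat_image):
    # centered exactly on the pixel at (10 mm, 10 mm), 1 mm pitch
    mask = circular_roi_mask(flat_image, (10.0, 10.0), 1.0)
    assert mask.sum() == 1
    assert mask[10, 10]


def test_mask_depends_only_on_geometry(flat_image):
    other = image_from_array(np.random.default_rng(0).normal(size=(64, 64)), (1.0, 1.0))
    m1 = circular_roi_mask(flat_image, (30.0, 30.0), 20.0)
    m2 = circular_roi_mask(other, (30.0, 30.0), 20.0)
    assert np.array_equal(m1, m2)


def test_circle_leaving_the_image_is_an_error(flat_image):
    with pytest.raises(GeometryError):
        circular_roi_mask(flat_image, (2.0, 30.0), 10.0)


# --- ROI statistics --------------------------------------------------------

def test_constant_region_stats(flat_image):
    vals = flat_image.values.copy()
    vals[:] = 90.0
    image = image_from_array(vals, (1.0, 1.0))
    stats = roi_stats(image, circular_roi_mask(image, (30.0, 30.0), 10.0))
    assert stats.mean_hu == 90.0
    assert stats.sd_hu == 0.0


def test_hand_computed_stats(flat_image):
    vals = flat_image.values.copy()
    mask = np.zeros_like(vals, dtype=bool)
    mask[5, 5], mask[5, 6], mask[5, 7] = True, True, True
    vals[5, 5:8] = [88.0, 90.0, 92.0]
    stats = roi_stats(image_from_array(vals, (1.0, 1.0)), mask)
    assert stats.mean_hu == pytest.approx(90.0)
    assert stats.sd_hu == pytest.approx(2.0)
    assert stats.n_pixels == 3


def test_single_pixel_mask_is_an_error(flat_image):
    mask = np.zeros((64, 64), dtype=bool)
    mask[3, 3] = True
    with pytest.raises(StatisticsError):
        roi_stats(flat_image, mask)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**16))
def test_roi_stats_equals_brute_force(seed):
    """Oracle: an explicit per-pixel loop over the selected values."""
    rng = np.random.default_rng(seed)
    image = image_from_array(rng.normal(90, 5, size=(64, 64)), (1.0, 1.0))
    mask = circular_roi_mask(image, (32.0, 32.0), float(rng.uniform(5, 30)))
    stats = roi_stats(image, mask)
    selected = [
        image.values[r, c]
        for r in range(64)
        for c in range(64)
        if mask[r, c]
    ]
    n = len(selected)
    mean = sum(selected) / n
    sd = (sum((v - mean) ** 2 for v in selected) / (n - 1)) ** 0.5
    assert stats.mean_hu == pytest.approx(mean, abs=1e-12)
    assert stats.sd_hu == pytest.approx(sd, rel=1e-12)
    assert stats.n_pixels == n


# --- angular profile and localization -------------------------------------

def test_profile_is_flat_on_uniform_phantom():
    cfg = SyntheticPhantomConfig(noise_sd_hu=0.0, contrast_hu=0.0)
    image, truth = generate_slice(cfg, 0)
    profile = angular_profile(image, truth.phantom_center_mm)
    assert profile.mean_hu.max() - profile.mean_hu.min() < 1e-9
    assert len(profile.angles_deg) == 180  # 360 / 2


def test_noiseless_object_found_at_ground_truth_angle(noiseless_slice):
    image, truth = noiseless_slice
    profile = angular_profile(image, truth.phantom_center_mm)
    assert profile.argmax_deg == pytest.approx(truth.object_angle_deg, abs=2.0)


def test_tie_break_takes_first_occurrence():
    angles = np.arange(0, 360, 2.0)
    means = np.zeros(180)
    means[10] = means[90] = 5.0  # equal maxima at 20° and 180°
    profile = AngularProfile(angles_deg=angles, mean_hu=means)
    loc = locate_low_contrast_object(profile, (0.0, 0.0))
    assert loc.angle_deg == 20.0


def test_detected_center_sits_on_the_search_circle(noisy_slice):
    image, truth = noisy_slice
    out = auto_cnr(image)
    r = np.hypot(
        out.location.center_mm[0] - out.centroid.center_mm[0],
        out.location.center_mm[1] - out.centroid.center_mm[1],
    )
    assert r == pytest.approx(55.0, abs=1e-9)


def test_roi_leaving_image_names_the_angle(noiseless_slice):
    image, _ = noiseless_slice
    cfg = SearchConfig(radius_mm=110.0)  # pushes ROIs past the image edge
    with pytest.raises(GeometryError, match="angle"):
        angular_profile(image, (20.0, 20.0), cfg)


@pytest.mark.parametrize("start", [10.0, 90.0])
def test_start_angle_multiple_of_step_changes_nothing(noiseless_slice, start):
    """The search covers the same absolute angles whatever the start, so
    the detected angle is identical when the offset is a multiple of the
    step — the initial ROI can be at any angle."""
    image, truth = noiseless_slice
    base, *_ = locate_object(image, SearchConfig())
    shifted, *_ = locate_object(image, SearchConfig(start_angle_deg=start))
    assert shifted.angle_deg == base.angle_deg


@pytest.mark.parametrize("start", [0.7, 33.3])
def test_arbitrary_start_angle_still_finds_the_object(noiseless_slice, start):
    image, truth = noiseless_slice
    loc, *_ = locate_object(image, SearchConfig(start_angle_deg=start))
    diff = abs((loc.angle_deg - truth.object_angle_deg + 180) % 360 - 180)
    assert diff <= 2.0


def test_misaligned_phantom_object_still_located():
    """10 mm misalignment: detected object center within 2 mm of truth."""
    cfg = SyntheticPhantomConfig(noise_sd_hu=0.0, offset_mm=(6.0, -8.0))
    image, truth = generate_slice(cfg, 0)
    loc, *_ = locate_object(image)
    err = np.hypot(
        loc.center_mm[0] - truth.object_center_mm[0],
        loc.center_mm[1] - truth.object_center_mm[1],
    )
    assert err < 2.0


# --- CNR -------------------------------------------------------------------

def test_same_center_gives_zero_contrast(noisy_slice):
    image, truth = noisy_slice
    res = measure_cnr(image, truth.phantom_center_mm, truth.phantom_center_mm)
    assert res.contrast_hu == 0.0
    assert res.cnr == 0.0


def test_noiseless_background_is_degenerate(noiseless_slice):
    image, truth = noiseless_slice
    with pytest.raises(DegenerateStatisticsError, match="CNR undefined"):
        measure_cnr(image, truth.object_center_mm, truth.phantom_center_mm)


def test_cnr_arithmetic_identity(noisy_slice):
    image, _ = noisy_slice
    res = auto_cnr(image).result
    assert res.cnr == res.contrast_hu / res.noise_hu  # exact, by construction
    assert res.cnr * res.noise_hu == pytest.approx(res.contrast_hu, rel=1e-14)
    assert res.noise_hu > 0


def test_doubling_noise_halves_mean_cnr():
    """CNR scales inversely with noise SD on matched synthetic stacks."""
    means = []
    for sd in (3.0, 6.0):
        cfg = SyntheticPhantomConfig(noise_sd_hu=sd, n_slices=6, seed=5)
        cnrs = [auto_cnr(im).result.cnr for im, _ in generate_stack(cfg)]
        means.append(np.mean(cnrs))
    assert means[0] / means[1] == pytest.approx(2.0, rel=0.10)


def test_uniform_phantom_without_object_gives_near_zero_cnr():
    cfg = SyntheticPhantomConfig(contrast_hu=0.0, noise_sd_hu=3.0)
    image, truth = generate_slice(cfg, 9)
    out = auto_cnr(image)  # must not crash despite there being no object
    assert abs(out.result.cnr) < 0.2


def test_roi_center_at_angle_convention():
    """0° is 12 o'clock (−y), 90° is 3 o'clock (+x), clockwise positive."""
    c = (0.0, 0.0)
    assert roi_center_at_angle(c, 55.0, 0.0) == pytest.approx((0.0, -55.0))
    assert roi_center_at_angle(c, 55.0, 90.0) == pytest.approx((55.0, 0.0))
    assert roi_center_at_angle(c, 55.0, 180.0) == pytest.approx((0.0, 55.0))
    assert roi_center_at_angle(c, 55.0, 270.0) == pytest.approx((-55.0, 0.0))
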