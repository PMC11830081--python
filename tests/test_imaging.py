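"""Center estimation and radial profiling on synthetic spheroid images."""

import numpy as np
import pytest

from spherowave import (
    PX_PER_MM,
    SpheroidImageSpec,
    estimate_center,
    generate_spheroid_image,
    radial_density_profile,
)
from spherowave.imaging import BIN_PX, MM_PER_PX, N_BINS, NoSpheroidError


@pytest.fixture(scope="module")
def full_frame_spec():
    return SpheroidImageSpec(noise_sigma=0.0, n_distractors=0)


@pytest.fixture(scope="module")
def full_frame_image(full_frame_spec):
    return generate_spheroid_image(full_frame_spec)


@pytest.fixture(scope="module")
def full_frame_center(full_frame_image):
    return estimate_center(full_frame_image)


def test_center_recovered_within_one_pixel(full_frame_spec, full_frame_center):
    c = full_frame_center
    assert abs(c.row - full_frame_spec.center[0]) < 1.0
    assert abs(c.col - full_frame_spec.center[1]) < 1.0
    assert 0.0 <= c.selected_object_eccentricity <= 1.0


def test_constant_image_has_no_spheroid():
    with pytest.raises(NoSpheroidError):
        estimate_center(np.full((128, 128), 0.5))


def test_round_object_beats_elongated_distractor():
    """The most-rounded large object wins even against an equal-area blob."""
    spec = SpheroidImageSpec(height=600, width=800, center=(300.0, 250.0),
                             core_radius=60, noise_sigma=0.0, n_distractors=1,
                             seed=2)
    im = generate_spheroid_image(spec)
    c = estimate_center(im)
    assert c.n_objects_considered >= 2
    assert abs(c.row - 300.0) < 1.5 and abs(c.col - 250.0) < 1.5


def test_translation_equivariance():
    base = SpheroidImageSpec(height=600, width=800, center=(280.0, 360.0),
                             core_radius=60, noise_sigma=0.0)
    shifted = SpheroidImageSpec(height=600, width=800, center=(310.0, 320.0),
                                core_radius=60, noise_sigma=0.0)
    c0 = estimate_center(generate_spheroid_image(base))
    c1 = estimate_center(generate_spheroid_image(shifted))
    assert abs((c1.row - c0.row) - 30.0) < 1.0
    assert abs((c1.col - c0.col) - (-40.0)) < 1.0


def test_integer_dtype_images_are_rescaled(full_frame_image, full_frame_center):
    im16 = (full_frame_image * 65535).astype(np.uint16)
    c = estimate_center(im16)
    assert abs(c.row - full_frame_center.row) < 1.0
    assert abs(c.col - full_frame_center.col) < 1.0


def test_pixel_scale_constants():
    assert PX_PER_MM == pytest.approx(1536 / 4.33)
    assert MM_PER_PX * 1000 == pytest.approx(2.819, abs=5e-3)  # um per px
    assert N_BINS * BIN_PX * MM_PER_PX == pytest.approx(3.38, abs=5e-3)


class TestRadialProfile:
    def test_annulus_profile_matches_generator_within_2pct(
        self, full_frame_spec, full_frame_image, full_frame_center
    ):
        prof = radial_density_profile(full_frame_image, full_frame_center)
        contrast = (
            full_frame_spec.background_intensity - full_frame_spec.core_intensity
        )
        base = 1.0 - full_frame_spec.background_intensity
        inside = prof.bin_centers_px < 1.5 * full_frame_spec.core_radius
        expected = base + contrast * full_frame_spec.radial_shape(
            prof.bin_centers_px[inside]
        )
        np.testing.assert_allclose(prof.y[inside], expected, rtol=0.02, atol=2e-3)

    def test_profile_is_flat_beyond_boundary(self, full_frame_image, full_frame_center):
        with pytest.warns(UserWarning):
            # noise-free profile is exactly flat outside: no sign change
            prof = radial_density_profile(full_frame_image, full_frame_center)
        assert np.all(prof.y_subtracted[prof.boundary_bin:] == 0.0)

    def test_background_offset_invariance(self, full_frame_image, full_frame_center):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            a = radial_density_profile(full_frame_image, full_frame_center)
            b = radial_density_profile(
                np.clip(full_frame_image - 0.05, 0, 1), full_frame_center
            )
        np.testing.assert_allclose(a.y_subtracted, b.y_subtracted, atol=1e-10)

    def test_constant_image_gives_zero_profile(self):
        im = np.full((400, 400), 0.6)
        from spherowave.imaging import CenterEstimate

        center = CenterEstimate(200.0, 200.0, 1, 0.0, 0.0)
        with pytest.warns(UserWarning):
            prof = radial_density_profile(im, center)
        assert np.ptp(prof.y) < 1e-12  # bin means only differ by float rounding
        assert np.all(np.abs(prof.y_subtracted) < 1e-12)
        assert np.all(prof.y_subtracted[prof.boundary_bin:] == 0.0)

    def test_noisy_image_boundary_detection(self):
        spec = SpheroidImageSpec(noise_sigma=0.01, seed=4)
        im = generate_spheroid_image(spec)
        c = estimate_center(im)
        prof = radial_density_profile(im, c)
        # boundary beyond the core-exclusion zone but before the frame edge
        assert 100 <= prof.boundary_bin < N_BINS - 1
        assert np.all(prof.y_subtracted[prof.boundary_bin:] == 0.0)
        # densities inside the object are positive after subtraction
        core_bins = prof.bin_centers_px < spec.core_radius
        assert prof.y_subtracted[core_bins].min() > 0

    def test_profile_csv_has_mm_scale(self, tmp_path, full_frame_image,
                                      full_frame_center):
        import warnings

        import pandas as pd

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            prof = radial_density_profile(full_frame_image, full_frame_center)
        out = tmp_path / "profile.csv"
        prof.to_csv(out)
        df = pd.read_csv(out)
        assert list(df.columns) == ["bin_center_mm", "density"]
        assert df["bin_center_mm"].iloc[-1] == pytest.approx(
            (N_BINS - 0.5) * BIN_PX * MM_PER_PX
        )
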