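"""Profile metrology: parabolic peaks, interpolated widths, slice averaging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import petrange as pr
from petrange.errors import DataError, ProfileTruncatedError
from petrange.profiles import (LineProfile, SIGMA_TO_FWHM, SIGMA_TO_FWTM,
                               parabolic_peak, width_at_fraction)


def gaussian_profile(sigma=1.0, step=0.05, half=6.0, mu=0.0):
    x = np.arange(-half, half + step / 2, step)
    return LineProfile(x, np.exp(-(x - mu) ** 2 / (2 * sigma ** 2)))


class TestExtractProfile:
    def test_length_and_values_along_axis(self):
        g = pr.centered_grid((8, 9, 10), 0.5)
        g.values[:, 4, 5] = np.arange(8)
        p = pr.extract_profile(g, "x", g.index_to_world((0, 4, 5)))
        assert p.positions.size == 8
        assert np.array_equal(p.intensities, np.arange(8))

    def test_delta_volume_single_nonzero(self):
        g = pr.centered_grid((9, 9, 9), 1.0)
        g.values[4, 4, 4] = 1.0
        p = pr.extract_profile(g, "z", (0, 0, 0))
        assert np.count_nonzero(p.intensities) == 1

    def test_gaussian_ridge_read_back_exactly(self):
        g = pr.centered_grid((41, 9, 9), 0.25)
        x = g.axis_coords(0)
        ridge = np.exp(-x ** 2 / 2)
        g.values[:] = ridge[:, None, None]
        p = pr.extract_profile(g, "x", (0, 0, 0))
        assert np.array_equal(p.intensities, ridge)

    def test_point_outside_grid(self):
        g = pr.centered_grid((9, 9, 9), 1.0)
        with pytest.raises(DataError):
            pr.extract_profile(g, "x", (99, 0, 0))


class TestParabolicPeak:
    def test_symmetric_three_points(self):
        p = LineProfile(np.arange(-1.0, 4.0), [0, 1, 2, 1, 0])
        fit = parabolic_peak(p)
        assert (fit.position, fit.value) == (1.0, 2.0)

    def test_exact_on_shifted_parabola(self):
        x = np.arange(-1.0, 4.0)
        y = np.maximum(4 - (x - 1.3) ** 2, 0)
        fit = parabolic_peak(LineProfile(x, y))
        assert fit.position == pytest.approx(1.3, abs=1e-12)
        assert fit.value == pytest.approx(4.0, abs=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(-0.49, 0.49), st.floats(0.01, 10), st.floats(0.1, 5))
    def test_exact_on_any_parabola(self, mu, extra, curv):
        x = np.arange(-2.0, 3.0)
        amp = curv * 6.5 + extra  # keep the parabola positive on the grid
        y = amp - curv * (x - mu) ** 2
        fit = parabolic_peak(LineProfile(x, y))
        assert fit.position == pytest.approx(mu, abs=1e-9)
        assert fit.value == pytest.approx(amp, rel=1e-9)

    def test_fine_gaussian_vertex(self):
        fit = parabolic_peak(gaussian_profile(sigma=1.0, step=0.1, mu=0.037))
        assert abs(fit.position - 0.037) < 1e-3

    def test_boundary_argmax_raises(self):
        p = LineProfile(np.arange(5.0), [5, 4, 3, 2, 1])
        with pytest.raises(ProfileTruncatedError):
            parabolic_peak(p)

    def test_collinear_three_points_fall_back_flagged(self):
        # zero-curvature neighbourhood: vertex fit degenerates to the
        # discrete maximum, with the degeneracy flagged
        from petrange.profiles import _parabola_vertex
        xv, yv, degen = _parabola_vertex(np.arange(3.0), np.ones(3))
        assert degen and (xv, yv) == (1.0, 1.0)


class TestWidthAtFraction:
    def test_triangle_widths(self):
        x = np.arange(-1.5, 1.51, 0.25)
        p = LineProfile(x, np.maximum(1 - np.abs(x), 0))
        peak = parabolic_peak(p)
        # parabola through (-.25, .75),(0,1),(.25,.75) has vertex 1.0
        assert width_at_fraction(p, peak, 0.5) == pytest.approx(1.0, rel=1e-9)
        assert width_at_fraction(p, peak, 0.1) == pytest.approx(1.8, rel=1e-9)

    def test_gaussian_closed_form(self):
        p = gaussian_profile(sigma=1.0, step=0.05)
        peak = parabolic_peak(p)
        assert width_at_fraction(p, peak, 0.5) == pytest.approx(SIGMA_TO_FWHM, rel=5e-3)
        assert width_at_fraction(p, peak, 0.1) == pytest.approx(SIGMA_TO_FWTM, rel=5e-3)

    def test_rectangle_width(self):
        x = np.arange(-3, 3.01, 0.25)
        y = np.where(np.abs(x) <= 1.0, 1.0, 0.0)
        y[np.argmax(y)] += 1e-9  # unique argmax, interior
        p = LineProfile(x, y)
        w = width_at_fraction(p, parabolic_peak(p), 0.5)
        assert w == pytest.approx(2.0, abs=0.25)

    def test_truncated_side_reported(self):
        x = np.arange(0, 3.01, 0.25)
        p = LineProfile(x, np.exp(-(x - 2.5) ** 2))
        # interior peak but the right tail never falls below half maximum
        with pytest.raises(ProfileTruncatedError, match="right"):
            width_at_fraction(p, parabolic_peak(p), 0.5)

    @settings(deadline=None, max_examples=30)
    @given(st.floats(-3, 3), st.floats(0.5, 3))
    def test_translation_invariance_and_dilation_scaling(self, shift, scale):
        base = gaussian_profile(sigma=1.0, step=0.05)
        w0 = width_at_fraction(base, parabolic_peak(base), 0.5)
        moved = LineProfile(base.positions * scale + shift, base.intensities)
        w1 = width_at_fraction(moved, parabolic_peak(moved), 0.5)
        assert w1 == pytest.approx(scale * w0, rel=1e-9)


class TestSliceAveraging:
    def _cylinder_volume(self, radius=1.0, sigma=0.6, voxel=0.25):
        import scipy.ndimage as ndi
        g = pr.centered_grid((81, 81, 9), voxel)
        x = g.axis_coords(0)
        disk = (x[:, None] ** 2 + x[None, :] ** 2 <= radius ** 2).astype(float)
        g.values[:] = disk[:, :, None]
        g.values = ndi.gaussian_filter(g.values, [sigma / voxel, sigma / voxel, 0])
        return g

    def test_identical_slices_zero_sd(self):
        g = self._cylinder_volume()
        m = pr.slice_averaged_metrics(g, "x", (0, 0, 0))
        assert m.fwhm_sd == 0.0
        assert m.fwhm_mean == pytest.approx(np.mean(m.fwhm_mm))
        assert m.n_slices_excluded == 0
        assert len(m.fwhm_mm) == 7

    def test_blurred_cylinder_against_convolution_oracle(self):
        radius, sigma = 1.0, 0.6
        g = self._cylinder_volume(radius, sigma)
        m = pr.slice_averaged_metrics(g, "x", (0, 0, 0))
        # dense oracle: the profile is a center row of the 2D-blurred disk,
        # so evaluate the 2D convolution on a much finer grid and read the
        # same row
        step = 0.02
        xx = np.arange(-4, 4, step)
        disk2d = (xx[:, None] ** 2 + xx[None, :] ** 2 <= radius ** 2).astype(float)
        import scipy.ndimage as ndi
        sm = ndi.gaussian_filter(disk2d, sigma / step)
        row = sm[:, sm.shape[1] // 2]
        peak = row.max()
        above = xx[row >= 0.5 * peak]
        oracle = above.max() - above.min()
        assert m.fwhm_mean == pytest.approx(oracle, rel=0.03)

    def test_center_slice_margin_enforced(self):
        g = self._cylinder_volume()
        with pytest.raises(DataError):
            pr.slice_averaged_metrics(g, "x", (0, 0, g.axis_coords(2)[0]))


class TestPercentChange:
    def test_examples(self):
        assert pr.percent_change(2.0, 1.0) == -50.0
        assert pr.percent_change(1.7, 1.7) == 0.0
        assert pr.percent_change(6.5, 2.6) == pytest.approx(-60.0)

    def test_domain_error(self):
        with pytest.raises(DataError):
            pr.percent_change(0.0, 1.0)
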