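import numpy as np
import pytest

from conftest import draw_quartic_inflections, make_quartic_profile
from sfxtriage.frame_store import FrameRef, open_stack, read_frame
from sfxtriage.profiling import (ROI, AutoLabelParams, IntensityProfile,
                                 ProfileError, auto_label_by_inflection,
                                 fit_profile_polynomial, vertical_projection)


def profile_with_inflections(r1, r2, source=None, length=101):
    return IntensityProfile(make_quartic_profile(r1, r2, length=length),
                            source=source)


class TestVerticalProjection:
    def test_constant_field(self):
        frame = np.full((12, 8), 3.5)
        prof = vertical_projection(frame, ROI.from_rect(2, 10, 1, 7))
        np.testing.assert_allclose(prof.values, 3.5)
        assert len(prof) == 8

    def test_row_indicator_field(self):
        frame = np.tile(np.arange(10.0)[:, None], (1, 6))
        prof = vertical_projection(frame, ROI.from_rect(0, 10, 0, 6))
        np.testing.assert_allclose(prof.values, np.arange(10.0))

    def test_matches_bruteforce_row_means(self):
        rng = np.random.default_rng(42)
        frame = rng.normal(size=(10, 8))
        roi = ROI.from_rect(1, 9, 2, 7)
        prof = vertical_projection(frame, roi)
        expected = [np.mean([frame[r, c] for c in range(2, 7)])
                    for r in range(1, 9)]
        np.testing.assert_allclose(prof.values, expected)

    def test_panel_roi_resolves_through_geometry(self, small_stack):
        stack = open_stack(small_stack.file_paths[0])
        frame = read_frame(stack, 0)
        prof = vertical_projection(frame, ROI.from_panel("p1"),
                                   small_stack.geometry)
        rec = small_stack.dump["geometry"]["panels"][1]
        expected = frame[rec["min_ss"]:rec["max_ss"] + 1,
                         rec["min_fs"]:rec["max_fs"] + 1].mean(axis=1)
        np.testing.assert_allclose(prof.values, expected)

    def test_empty_roi_rejected(self):
        with pytest.raises(ProfileError, match="empty"):
            vertical_projection(np.ones((5, 5)), ROI.from_rect(2, 2, 0, 5))

    def test_roi_outside_frame_rejected(self):
        with pytest.raises(ProfileError, match="outside"):
            vertical_projection(np.ones((5, 5)), ROI.from_rect(0, 9, 0, 5))


class TestPolynomialFit:
    def test_odd_cubic_single_inflection(self):
        x = np.arange(101.0)
        prof = IntensityProfile((x - 50.0) ** 3)
        fit = fit_profile_polynomial(prof, order=3)
        assert len(fit.inflections) == 1
        assert fit.inflections[0] == pytest.approx(50.0, abs=1e-6)

    @pytest.mark.parametrize("r1,r2", [(30.0, 70.0), (20.5, 25.0), (10.0, 90.0)])
    def test_quartic_inflections_recovered_exactly(self, r1, r2):
        """Noiseless quartics with analytically known curvature roots."""
        fit = fit_profile_polynomial(profile_with_inflections(r1, r2), order=4)
        assert fit.inflections == pytest.approx((r1, r2), abs=1e-6)

    def test_linear_profile_has_no_inflection(self):
        prof = IntensityProfile(2.0 * np.arange(50.0) + 1.0)
        fit = fit_profile_polynomial(prof, order=4)
        assert fit.inflections == ()

    @pytest.mark.parametrize("degree", [1, 2, 3, 4])
    def test_noiseless_polynomial_recovered(self, degree):
        rng = np.random.default_rng(degree)
        coef = rng.normal(size=degree + 1)
        x = np.arange(80.0)
        values = np.polynomial.polynomial.polyval(x, coef)
        prof = IntensityProfile(values)
        fit = fit_profile_polynomial(prof, order=4)
        scale = np.abs(values).max()
        assert fit.residual < 1e-8 * scale
        np.testing.assert_allclose(fit(x), values, atol=1e-8 * scale)

    @pytest.mark.parametrize("seed", range(5))
    def test_inflections_within_one_row_under_noise(self, seed):
        """1%-of-range Gaussian noise moves inflections < 1 row unit."""
        rng = np.random.default_rng(seed)
        r1, r2 = draw_quartic_inflections(rng)
        clean = make_quartic_profile(r1, r2)
        sigma = 0.01 * (clean.max() - clean.min())
        noisy = clean + rng.normal(0, sigma, size=clean.shape)
        fit = fit_profile_polynomial(IntensityProfile(noisy), order=4)
        assert len(fit.inflections) == 2
        assert abs(fit.inflections[0] - r1) < 1.0
        assert abs(fit.inflections[1] - r2) < 1.0

    def test_too_short_profile_rejected(self):
        with pytest.raises(ProfileError, match="length 4"):
            fit_profile_polynomial(IntensityProfile(np.arange(4.0)), order=4)

    def test_coefficients_reported_in_row_units(self):
        x = np.arange(60.0)
        values = 2.0 + 3.0 * x - 0.5 * x ** 2
        fit = fit_profile_polynomial(IntensityProfile(values), order=2)
        np.testing.assert_allclose(fit.coefficients, [2.0, 3.0, -0.5],
                                   atol=1e-8)


class TestAutoLabel:
    @staticmethod
    def cluster_profiles(signatures):
        return [profile_with_inflections(s, s + 5.0, source=FrameRef("x.h5", i))
                for i, s in enumerate(signatures)]

    def test_two_cluster_dominance(self):
        profiles = self.cluster_profiles([20.0] * 8 + [70.0] * 2)
        labelset, diag = auto_label_by_inflection(
            profiles, AutoLabelParams(bin_width=5.0))
        assert labelset.counts == {"good": 8, "bad": 2, "skip": 0}
        for i in range(8):
            assert labelset[FrameRef("x.h5", i)] == "good"
        assert diag.dominant_fraction == pytest.approx(0.8)
        assert not diag.warning

    def test_low_dominance_sets_warning(self):
        profiles = self.cluster_profiles(
            [20.0] * 4 + [50.0] * 3 + [80.0] * 3)
        labelset, diag = auto_label_by_inflection(
            profiles, AutoLabelParams(bin_width=5.0))
        assert diag.dominant_fraction == pytest.approx(0.4)
        assert diag.warning
        assert labelset.counts["good"] == 4

    def test_inflection_free_frames_are_skipped(self):
        profiles = self.cluster_profiles([20.0] * 3)
        profiles.append(IntensityProfile(np.arange(101.0),
                                         source=FrameRef("x.h5", 9)))
        labelset, diag = auto_label_by_inflection(
            profiles, AutoLabelParams(bin_width=5.0))
        assert labelset[FrameRef("x.h5", 9)] == "skip"
        assert diag.n_skipped == 1

    def test_all_inflection_free_is_error(self):
        profiles = [IntensityProfile(np.arange(101.0) * k,
                                     source=FrameRef("x.h5", k))
                    for k in (1, 2)]
        with pytest.raises(ProfileError, match="inflection"):
            auto_label_by_inflection(profiles)

    def test_order_invariance(self):
        profiles = self.cluster_profiles([20.0] * 6 + [70.0] * 4)
        fwd, _ = auto_label_by_inflection(profiles, AutoLabelParams(bin_width=5.0))
        rev, _ = auto_label_by_inflection(profiles[::-1],
                                          AutoLabelParams(bin_width=5.0))
        assert dict(fwd.labels) == dict(rev.labels)

    def test_needs_two_profiles(self):
        with pytest.raises(ProfileError, match="at least 2"):
            auto_label_by_inflection(self.cluster_profiles([20.0]))

    def test_generator_truth_recovered(self, clean_stack):
        """On a stack whose artefact shifts the inflection by >= 10 bin
        widths, auto-labelling matches the generator's truth exactly."""
        roi = ROI.from_panel("p1")
        profiles, sig_good, sig_bad = [], [], []
        for path in clean_stack.file_paths:
            stack = open_stack(path)
            for event in range(stack.n_events):
                prof = vertical_projection(read_frame(stack, event), roi,
                                           clean_stack.geometry)
                prof = IntensityProfile(prof.values,
                                        source=FrameRef(str(path), event))
                profiles.append(prof)
                sig = fit_profile_polynomial(prof).first_inflection
                truth = clean_stack.truth[prof.source]
                (sig_good if truth == "good" else sig_bad).append(sig)
        bin_width = 0.2
        shift = abs(np.mean(sig_bad) - np.mean(sig_good))
        assert shift >= 10 * bin_width  # the regime the rule is built for
        labelset, diag = auto_label_by_inflection(
            profiles, AutoLabelParams(bin_width=bin_width))
        assert diag.n_skipped == 0
        for ref, truth in clean_stack.truth.labels.items():
            assert labelset[ref] == truth


def test_profile_plot_renders():
    import matplotlib
    matplotlib.use("Agg")
    prof = IntensityProfile(make_quartic_profile(30.0, 70.0))
    fit = fit_profile_polynomial(prof, order=4)
    ax = prof.plot(fit=fit)
    assert len(ax.lines) >= 2
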