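"""Oriented contour cues: half-disc χ² gradients, mPb, sPb, combination."""

import numpy as np
import pytest

from fieldseg.cues import (
    CueConfig,
    CueExtractor,
    OrientedContourSignal,
    combine_with_fcn,
    gpb,
    half_disc_gradient,
    mpb,
    orientation_bins,
    spectral_globalization,
)
from fieldseg.fcn import BoundaryProbabilityMap
from fieldseg.grids import RasterGrid

FAST = CueConfig(use_texture=False, scales=(2, 4), n_eigenvectors=8)


def make_signal(strength):
    return OrientedContourSignal(
        grid=RasterGrid(width=strength.shape[2], height=strength.shape[1]),
        strength=strength,
    )


class TestHalfDisc:
    def test_constant_image_zero(self):
        g = half_disc_gradient(np.full((32, 32), 0.7), 4, 0.3)
        assert g.max() == pytest.approx(0.0, abs=1e-9)

    def test_radius_validation(self):
        with pytest.raises(ValueError):
            half_disc_gradient(np.zeros((32, 32)), 0, 0.0)
        with pytest.raises(ValueError):
            half_disc_gradient(np.zeros((10, 10)), 8, 0.0)

    def test_step_edge_maximal_at_edge_orientation(self):
        """Vertical step edge: the response at the edge is maximal over
        orientations at the vertical (π/2) bin — brute-force comparison."""
        img = np.zeros((32, 32))
        img[:, 16:] = 1.0
        responses = [
            half_disc_gradient(img, 4, th)[16, 16] for th in orientation_bins(8)
        ]
        assert int(np.argmax(responses)) == 4  # bins cover [0, π), bin 4 = π/2
        assert responses[4] == pytest.approx(1.0, abs=1e-6)

    def test_rotation_equivariance_quarter_turns(self, rng):
        """Rotating the image by 90° permutes the orientation axis."""
        img = rng.random((24, 24))
        for theta in orientation_bins(4):
            a = half_disc_gradient(img, 3, theta)
            b = half_disc_gradient(np.rot90(img), 3, (theta + np.pi / 2) % np.pi)
            # interior comparison: at the image border the clipped half-disc
            # validity is sensitive to fp noise in the area computation
            assert np.allclose(a[4:-4, 4:-4], np.rot90(b, -1)[4:-4, 4:-4], atol=1e-10)

    def test_affine_rescaling_invariance(self, rng):
        img = rng.random((24, 24))
        a = half_disc_gradient(img, 3, 0.5)
        b = half_disc_gradient(3.5 * img - 1.2, 3, 0.5)
        assert np.allclose(a, b, atol=1e-10)


class TestMPb:
    def test_constant_zero_signal(self):
        sig = mpb(np.full((32, 32), 0.4), FAST)
        assert sig.strength.max() == pytest.approx(0.0, abs=1e-9)

    def test_single_scale_single_channel_reduces_to_half_disc(self, rng):
        img = rng.random((32, 32))
        cfg = CueConfig(use_texture=False, scales=(3,), n_orientations=4)
        sig = mpb(img, cfg)
        raw = np.stack(
            [half_disc_gradient(img, 3, th) for th in orientation_bins(4)]
        )
        assert np.allclose(sig.strength, raw / raw.max(), atol=1e-9)

    def test_two_field_ridge_on_boundary(self, two_field_scene):
        _, truth = two_field_scene
        sig = mpb(truth.image, FAST)
        ridge = sig.max_over_orientations()
        # strongest responses should lie within 2 px of the true boundary
        from fieldseg.reference import select_candidates

        band = select_candidates(truth.boundary_lines, truth.image.grid, 1.0).mask
        strong = ridge > 0.7 * ridge.max()
        from scipy.ndimage import binary_dilation

        near = binary_dilation(band, iterations=2)
        assert (strong & ~near).sum() / max(strong.sum(), 1) < 0.2

    def test_weight_mismatch_rejected(self, rng):
        cfg = CueConfig(use_texture=False, channel_weights=(1.0, 2.0))
        with pytest.raises(ValueError):
            mpb(rng.random((16, 16)), cfg)


class TestGlobalization:
    def test_zero_signal_zero_contrast(self):
        sig = make_signal(np.zeros((4, 40, 40)))
        out = spectral_globalization(sig, FAST)
        assert out.strength.max() == pytest.approx(0.0, abs=1e-6)

    def test_output_normalized_non_negative(self, two_field_scene):
        _, truth = two_field_scene
        out = spectral_globalization(mpb(truth.image, FAST), FAST)
        assert out.strength.min() >= 0
        assert out.strength.max() <= 1 + 1e-6

    def test_bridges_masked_gaps(self, two_field_scene):
        """Globalization reconnects a ridge whose local signal has gaps."""
        from skimage.measure import label as cc_label

        _, truth = two_field_scene
        local = mpb(truth.image, FAST)
        s = local.strength.copy()
        rng = np.random.default_rng(0)
        ridge = local.max_over_orientations() > 0.3
        rr, cc = np.nonzero(ridge)
        drop = rng.random(len(rr)) < 0.2
        s[:, rr[drop], cc[drop]] = 0.0
        gapped = make_signal(s)
        glob = spectral_globalization(gapped, FAST)
        combined = make_signal(
            np.clip(s + glob.strength, 0, 1)
        )
        def n_components(sig_, t):
            return cc_label(sig_.max_over_orientations() > t, connectivity=2).max()

        # the same threshold fragments the gapped local signal more than
        # the globalization-augmented one
        assert n_components(combined, 0.3) <= n_components(gapped, 0.3)


class TestGPb:
    def test_zero_globalization_weight_reduces_to_mpb(self, two_field_scene):
        _, truth = two_field_scene
        cfg = CueConfig(use_texture=False, scales=(2, 4), spb_weight=0.0)
        a = gpb(truth.image, cfg)
        b = mpb(truth.image, cfg)
        assert np.array_equal(a.strength, b.strength)

    def test_in_unit_interval(self, two_field_scene):
        _, truth = two_field_scene
        sig = gpb(truth.image, FAST)
        assert sig.strength.min() >= 0 and sig.strength.max() <= 1 + 1e-6


class TestCombineWithFCN:
    def grid_and_prob(self, rng, n=32):
        grid = RasterGrid(width=n, height=n)
        prob = rng.random((n, n)).astype(np.float32)
        return grid, BoundaryProbabilityMap(grid=grid, prob=prob)

    def test_alpha_zero_identity(self, rng):
        grid, pm = self.grid_and_prob(rng)
        sig = make_signal(rng.random((8, 32, 32)))
        out = combine_with_fcn(sig, pm, 0.0, "replicate")
        assert np.allclose(out.strength, sig.strength)

    def test_alpha_one_replicate_equals_normalized_prob(self, rng):
        grid, pm = self.grid_and_prob(rng)
        sig = make_signal(np.zeros((8, 32, 32)))
        out = combine_with_fcn(sig, pm, 1.0, "replicate")
        expected = pm.prob / pm.prob.max()
        assert np.allclose(out.max_over_orientations(), expected, atol=1e-6)

    def test_intermediate_alpha_bounded_by_parents(self, rng):
        grid, pm = self.grid_and_prob(rng)
        sig = make_signal(rng.random((8, 32, 32)))
        out = combine_with_fcn(sig, pm, 0.4, "structure-tensor")
        parent_max = np.maximum(
            sig.max_over_orientations(), pm.prob / pm.prob.max()
        )
        assert (out.max_over_orientations() <= parent_max + 1e-6).all()

    def test_grid_mismatch_rejected(self, rng):
        grid, pm = self.grid_and_prob(rng, 32)
        sig = make_signal(rng.random((8, 16, 16)))
        with pytest.raises(ValueError):
            combine_with_fcn(sig, pm, 0.5)

    def test_invalid_alpha_rejected(self, rng):
        grid, pm = self.grid_and_prob(rng)
        sig = make_signal(rng.random((8, 32, 32)))
        with pytest.raises(ValueError):
            combine_with_fcn(sig, pm, 1.5)


def test_extractor_estimator_surface(two_field_scene):
    _, truth = two_field_scene
    ext = CueExtractor(use_texture=False, scales=(2, 4), n_eigenvectors=8)
    sig = ext.fit().transform(truth.image)
    assert sig.strength.shape[0] == 8
    assert 0 <= sig.strength.min() and sig.strength.max() <= 1 + 1e-6
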