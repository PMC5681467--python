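"""Filter bank correctness against brute-force per-pixel oracles."""

import numpy as np
import pytest
from scipy import ndimage

from tubuseg.features import (FeatureSpec, NEIGHBOR_DIRECTIONS,
                              build_feature_stack, entropy_features,
                              gaussian_blur, hessian_features,
                              neighbors_features, structure_features)


def seeded_slice(shape=(32, 32), seed=0, scale=1000.0):
    return np.random.default_rng(seed).random(shape) * scale


# ---------------------------------------------------------------- gaussian

class TestGaussianBlur:
    def test_constant_slice_unchanged(self):
        out = gaussian_blur(np.full((16, 16), 7.0), sigma=2.0)
        np.testing.assert_allclose(out, 7.0, rtol=1e-10)

    def test_impulse_response_sums_to_one(self):
        img = np.zeros((33, 33))
        img[16, 16] = 1.0
        out = gaussian_blur(img, sigma=2.0)
        assert abs(out.sum() - 1.0) <= 1e-6
        assert out[16, 16] == out.max()

    def test_matches_brute_force_convolution(self):
        img = seeded_slice((24, 24), seed=3)
        sigma = 1.5
        r = int(4.0 * sigma + 0.5)
        x = np.arange(-r, r + 1)
        k1 = np.exp(-0.5 * (x / sigma) ** 2)
        k1 /= k1.sum()
        kernel = np.outer(k1, k1)
        padded = np.pad(img, r, mode="reflect")
        ref = np.empty_like(img)
        for y in range(img.shape[0]):
            for x0 in range(img.shape[1]):
                ref[y, x0] = (padded[y:y + 2 * r + 1, x0:x0 + 2 * r + 1] * kernel).sum()
        np.testing.assert_allclose(gaussian_blur(img, sigma), ref, atol=1e-8 * 1000)

    def test_mean_preserved(self):
        # exact on constants (kernel normalisation); on arbitrary slices the
        # mirror boundary perturbs the mean only at O(perimeter/area)
        const = np.full((30, 30), 123.0)
        assert abs(gaussian_blur(const, 3.0).mean() - 123.0) / 123.0 <= 1e-6
        img = seeded_slice((40, 40), seed=1)
        out = gaussian_blur(img, 3.0)
        assert abs(out.mean() - img.mean()) / img.mean() <= 1e-3

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_blur(np.zeros((4, 4)), 0.0)


# --------------------------------------------------------------- neighbors

class TestNeighbors:
    def test_constant_slice_all_features_constant(self):
        out = neighbors_features(np.full((10, 10), 3.0), radii=(1, 2))
        assert out.shape == (10, 10, 16)
        np.testing.assert_array_equal(out, 3.0)

    def test_single_bright_pixel_north_shift(self):
        img = np.zeros((20, 20))
        img[10, 10] = 1.0
        out = neighbors_features(img, radii=(1,))
        north = out[..., 0]  # direction order starts with N
        assert north[11, 10] == 1.0
        assert north.sum() == 1.0

    def test_opposite_shifts_cancel_in_interior(self):
        img = seeded_slice((16, 16), seed=5)
        r = 2
        out1 = neighbors_features(img, radii=(r,))
        # N (idx 0) and S (idx 4) are opposite: shifting the N-feature south
        # restores the interior
        north = out1[..., 0]
        back = neighbors_features(north, radii=(r,))[..., 4]
        np.testing.assert_array_equal(back[r:-r, r:-r], img[r:-r, r:-r])

    def test_index_arithmetic_all_directions(self):
        img = seeded_slice((14, 14), seed=8)
        r = 2
        out = neighbors_features(img, radii=(r,))
        for di, (_, (dy, dx)) in enumerate(NEIGHBOR_DIRECTIONS):
            inner = out[r:-r, r:-r, di]
            expect = img[r + r * dy:14 - r + r * dy, r + r * dx:14 - r + r * dx]
            np.testing.assert_array_equal(inner, expect)


# ----------------------------------------------------------------- entropy

def brute_entropy(img, radius, bins):
    lo, hi = img.min(), img.max()
    if hi <= lo:
        return np.zeros_like(img, dtype=float)
    q = np.clip(((img - lo) / (hi - lo) * bins).astype(int), 0, bins - 1)
    padded = np.pad(q, radius, mode="reflect")
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    disc = yy ** 2 + xx ** 2 <= radius ** 2
    out = np.zeros(img.shape, dtype=float)
    for y in range(img.shape[0]):
        for x in range(img.shape[1]):
            window = padded[y:y + 2 * radius + 1, x:x + 2 * radius + 1][disc]
            counts = np.bincount(window, minlength=bins).astype(float)
            p = counts[counts > 0] / counts.sum()
            out[y, x] = -(p * np.log2(p)).sum()
    return out


class TestEntropy:
    def test_constant_slice_zero_entropy(self):
        out = entropy_features(np.full((12, 12), 5.0), radius=3, bins=16)
        np.testing.assert_array_equal(out, 0.0)

    def test_checkerboard_interior_near_one_bit(self):
        yy, xx = np.mgrid[0:24, 0:24]
        img = ((yy + xx) % 2).astype(float)
        out = entropy_features(img, radius=4, bins=8)
        # disc windows hold a near-even split of the two values
        assert np.abs(out[6:-6, 6:-6] - 1.0).max() <= 1e-2

    def test_matches_brute_force_oracle(self):
        img = seeded_slice((32, 32), seed=2)
        out = entropy_features(img, radius=3, bins=16)
        ref = brute_entropy(img, radius=3, bins=16)
        np.testing.assert_allclose(out, ref, atol=1e-5)

    def test_explicit_range_overrides_slice_range(self):
        img = seeded_slice((16, 16), seed=4, scale=10.0)
        a = entropy_features(img, 3, 8, value_range=(0.0, 10.0))
        b = entropy_features(img[:8, :8], 3, 8, value_range=(0.0, 10.0))
        np.testing.assert_allclose(a[3:5, 3:5], b[3:5, 3:5], atol=1e-12)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            entropy_features(np.zeros((4, 4)), radius=0, bins=8)
        with pytest.raises(ValueError):
            entropy_features(np.zeros((4, 4)), radius=2, bins=1)


# --------------------------------------------------------- structure tensor

class TestStructureTensor:
    def test_constant_slice_zero_eigenvalues(self):
        hi, lo = structure_features(np.full((16, 16), 9.0), 1.0, 1.0)
        np.testing.assert_allclose(hi, 0.0, atol=1e-10)
        np.testing.assert_allclose(lo, 0.0, atol=1e-10)

    def test_matches_per_pixel_eigendecomposition(self):
        img = seeded_slice((32, 32), seed=6)
        ds, si = 1.0, 2.0
        hi, lo = structure_features(img, ds, si)
        gy = ndimage.gaussian_filter(img, ds, order=(1, 0), mode="mirror")
        gx = ndimage.gaussian_filter(img, ds, order=(0, 1), mode="mirror")
        jxx = ndimage.gaussian_filter(gx * gx, si, mode="mirror")
        jyy = ndimage.gaussian_filter(gy * gy, si, mode="mirror")
        jxy = ndimage.gaussian_filter(gx * gy, si, mode="mirror")
        mats = np.stack([np.stack([jxx, jxy], -1), np.stack([jxy, jyy], -1)], -2)
        eigs = np.linalg.eigvalsh(mats)  # ascending
        np.testing.assert_allclose(lo, eigs[..., 0], atol=1e-5 * np.abs(eigs).max())
        np.testing.assert_allclose(hi, eigs[..., 1], atol=1e-5 * np.abs(eigs).max())

    def test_step_edge_ridge_and_anisotropy(self):
        img = np.zeros((32, 32))
        img[:, 16:] = 100.0
        hi, lo = structure_features(img, 1.0, 1.0)
        interior = slice(8, 24)
        edge_hi = hi[interior, 16]
        assert (edge_hi > hi[interior, 4]).all()
        # smallest eigenvalue is ~0 on a straight edge
        assert (lo[interior, 16] / edge_hi < 0.05).all()

    def test_rotation_equivariance(self):
        img = seeded_slice((32, 32), seed=9)
        hi, lo = structure_features(img, 1.0, 2.0)
        hi_r, lo_r = structure_features(np.rot90(img), 1.0, 2.0)
        b = 6  # exclude borders where mirror padding breaks the symmetry
        np.testing.assert_allclose(hi_r[b:-b, b:-b], np.rot90(hi)[b:-b, b:-b],
                                   atol=1e-5 * np.abs(hi).max())
        np.testing.assert_allclose(lo_r[b:-b, b:-b], np.rot90(lo)[b:-b, b:-b],
                                   atol=1e-5 * np.abs(hi).max())


# ------------------------------------------------------------------ hessian

class TestHessian:
    def test_constant_slice(self):
        hi, lo, theta = hessian_features(np.full((12, 12), 4.0), 1.0)
        np.testing.assert_allclose(hi, 0.0, atol=1e-10)
        np.testing.assert_allclose(lo, 0.0, atol=1e-10)
        np.testing.assert_array_equal(theta, 0.0)

    def test_bright_horizontal_ridge(self):
        img = np.zeros((32, 32))
        img[16, :] = 100.0
        hi, lo, theta = hessian_features(img, 1.0)
        centre = lo[16, 8:24]
        assert (centre < 0).all()
        assert centre.max() < -1.0
        # orientation of the strong (negative) eigenvalue's eigenvector is
        # the ridge normal, i.e. the y axis -> angle pi/2
        err = np.abs(theta[16, 8:24] - np.pi / 2)
        assert np.degrees(err.max()) < 5.0

    def test_matches_per_pixel_eigendecomposition(self):
        img = seeded_slice((32, 32), seed=12)
        s = 1.5
        hi, lo, _ = hessian_features(img, s)

        # independent oracle: build sampled-Gaussian derivative kernels
        # (unit-sum smoother, zero-DC even derivatives), dense 2D
        # convolution, then per-pixel symmetric eigendecomposition
        r = int(4.0 * s + 0.5)
        x = np.arange(-r, r + 1, dtype=float)
        g = np.exp(-0.5 * (x / s) ** 2)
        g /= g.sum()
        g1 = -x / s ** 2 * g
        g2 = (x ** 2 / s ** 4 - 1.0 / s ** 2) * g
        g2 = g2 - g2.mean()

        def conv2(image, ky, kx):
            kernel = np.outer(ky, kx)[::-1, ::-1]  # convolution, not correlation
            padded = np.pad(image, r, mode="reflect")
            out = np.empty_like(image)
            for yy in range(image.shape[0]):
                for xx in range(image.shape[1]):
                    out[yy, xx] = (padded[yy:yy + 2 * r + 1,
                                          xx:xx + 2 * r + 1] * kernel).sum()
            return out

        hyy = conv2(img, g2, g)
        hxx = conv2(img, g, g2)
        hxy = conv2(img, g1, g1)
        mats = np.stack([np.stack([hxx, hxy], -1), np.stack([hxy, hyy], -1)], -2)
        eigs = np.linalg.eigvalsh(mats)
        scale = np.abs(eigs).max()
        np.testing.assert_allclose(lo, eigs[..., 0], atol=1e-5 * scale)
        np.testing.assert_allclose(hi, eigs[..., 1], atol=1e-5 * scale)

    def test_orientation_range(self):
        img = seeded_slice((24, 24), seed=13)
        _, _, theta = hessian_features(img, 2.0)
        assert (theta >= 0).all() and (theta < np.pi).all()


# ------------------------------------------------------------- feature stack

class TestFeatureStack:
    def test_gaussian_only_spec_has_two_features(self):
        spec = FeatureSpec(gaussian_sigmas=(2.0,), enabled=("gaussian",))
        stack = build_feature_stack(np.zeros((8, 8)), spec)
        assert stack.n_features == 2
        assert stack.feature_names == ["raw", "gaussian_s2"]

    def test_default_spec_count_formula(self):
        spec = FeatureSpec()
        g = len(spec.gaussian_sigmas)
        n = 8 * len(spec.neighbors_radii)
        s = 2 * len(spec.structure_sigmas)
        h = 3 * len(spec.hessian_sigmas)
        assert spec.feature_count() == 1 + g + n + 1 + s + h == 37
        stack = build_feature_stack(np.zeros((8, 8)), spec)
        assert stack.data.shape == (8, 8, 37)
        assert len(stack.feature_names) == 37

    def test_raw_intensity_is_feature_zero(self):
        img = seeded_slice((10, 10), seed=1)
        stack = build_feature_stack(img, FeatureSpec())
        np.testing.assert_allclose(stack.data[..., 0], img, rtol=1e-6)

    def test_determinism(self):
        img = seeded_slice((16, 16), seed=3)
        spec = FeatureSpec()
        a = build_feature_stack(img, spec)
        b = build_feature_stack(img, spec)
        np.testing.assert_array_equal(a.data, b.data)
        assert a.spec_fingerprint == b.spec_fingerprint

    def test_3d_block_processed_slice_wise(self):
        rng = np.random.default_rng(0)
        block = rng.random((3, 12, 12))
        spec = FeatureSpec(gaussian_sigmas=(1.0,),
                           enabled=("gaussian", "hessian"),
                           hessian_sigmas=(1.0,))
        stack = build_feature_stack(block, spec)
        for z in range(3):
            per_slice = build_feature_stack(block[z], spec)
            np.testing.assert_array_equal(stack.data[z], per_slice.data)

    def test_translation_equivariance_interior(self):
        img = seeded_slice((40, 40), seed=21)
        spec = FeatureSpec(gaussian_sigmas=(1.0,), neighbors_radii=(1,),
                           entropy_radius=2, entropy_bins=8,
                           entropy_range=(0.0, 1000.0),
                           structure_sigmas=((1.0, 1.0),), hessian_sigmas=(1.0,))
        shifted = np.roll(img, (3, 5), axis=(0, 1))
        a = build_feature_stack(img, spec).data
        b = build_feature_stack(shifted, spec).data
        m = 12  # stay clear of wrap-around and boundary effects
        a_in = a[m:-m, m:-m]
        b_in = b[m + 3:-m + 3, m + 5:-m + 5]
        for f in range(a.shape[-1]):
            scale = max(np.abs(a_in[..., f]).max(), 1.0)
            np.testing.assert_allclose(b_in[..., f], a_in[..., f],
                                       atol=1e-5 * scale)

    def test_fingerprint_differs_between_specs(self):
        assert FeatureSpec().fingerprint() != \
            FeatureSpec(gaussian_sigmas=(1.0,)).fingerprint()

    def test_empty_spec_rejected(self):
        with pytest.raises(ValueError):
            FeatureSpec(enabled=())
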