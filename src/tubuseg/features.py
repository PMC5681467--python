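"""Per-voxel feature bank for trainable segmentation.

Vessel and airway walls in wax-embedded tissue appear as bright shells
around a lumen whose density matches the background wax, so the useful
evidence is edge- and texture-like rather than absolute intensity.  The
bank combines raw intensity with Gaussian blurs at several scales,
neighbour intensities (translated copies of the slice), local histogram
entropy, structure-tensor eigenvalues and Hessian eigenvalues/orientation.

Features are computed slice-wise in 2D along z.  Intensities are used as
acquired: no histogram normalisation or equalisation is applied anywhere,
because voxel values are proportional to X-ray absorption and rescaling
would destroy comparability between scans.

All filters use mirror-reflection boundary handling, matching the halo
padding of the block store, so blockwise and whole-volume computation agree
wherever the halo covers the filter footprint.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "FeatureSpec",
    "FeatureStack",
    "NEIGHBOR_DIRECTIONS",
    "gaussian_blur",
    "neighbors_features",
    "entropy_features",
    "structure_features",
    "hessian_features",
    "build_feature_stack",
]

# Compass directions as (dy, dx) with image y increasing downward; the
# feature for direction d at (y, x) is the intensity of the neighbour at
# (y + r*dy, x + r*dx).
NEIGHBOR_DIRECTIONS: tuple[tuple[str, tuple[int, int]], ...] = (
    ("N", (-1, 0)), ("NE", (-1, 1)), ("E", (0, 1)), ("SE", (1, 1)),
    ("S", (1, 0)), ("SW", (1, -1)), ("W", (0, -1)), ("NW", (-1, -1)),
)

_GROUPS = ("gaussian", "neighbors", "entropy", "structure", "hessian")


@dataclass(frozen=True)
class FeatureSpec:
    """Declarative configuration of the filter bank.

    Defaults span wall thicknesses of a few voxels at 8 um resolution.
    ``entropy_range`` fixes the quantisation range; when ``None`` the
    slice's own min-max range is used (note that this makes the entropy
    feature depend on the slice extent, so blockwise prediction with
    entropy enabled should pass an explicit range for exact seamlessness).
    """

    gaussian_sigmas: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0)
    neighbors_radii: tuple[int, ...] = (1, 2)
    entropy_radius: int = 4
    entropy_bins: int = 64
    entropy_range: tuple[float, float] | None = None
    structure_sigmas: tuple[tuple[float, float], ...] = ((1.0, 1.0), (1.0, 3.0), (2.0, 3.0))
    hessian_sigmas: tuple[float, ...] = (1.0, 2.0, 4.0)
    enabled: tuple[str, ...] = _GROUPS

    def __post_init__(self) -> None:
        bad = set(self.enabled) - set(_GROUPS)
        if bad:
            raise ValueError(f"unknown feature groups: {sorted(bad)}")
        if not self.enabled:
            raise ValueError("at least one feature group must be enabled")
        if any(s <= 0 for s in self.gaussian_sigmas):
            raise ValueError("gaussian sigmas must be positive")
        if any(r < 1 for r in self.neighbors_radii):
            raise ValueError("neighbour radii must be >= 1")
        if self.entropy_radius < 1 or self.entropy_bins < 2:
            raise ValueError("entropy radius must be >= 1 and bins >= 2")
        if any(a <= 0 or b <= 0 for a, b in self.structure_sigmas):
            raise ValueError("structure scales must be positive")
        if any(s <= 0 for s in self.hessian_sigmas):
            raise ValueError("hessian sigmas must be positive")

    def feature_names(self) -> list[str]:
        names = ["raw"]
        if "gaussian" in self.enabled:
            names += [f"gaussian_s{s:g}" for s in self.gaussian_sigmas]
        if "neighbors" in self.enabled:
            names += [f"neighbor_{d}_r{r}" for r in self.neighbors_radii
                      for d, _ in NEIGHBOR_DIRECTIONS]
        if "entropy" in self.enabled:
            names += [f"entropy_r{self.entropy_radius}_b{self.entropy_bins}"]
        if "structure" in self.enabled:
            for ds, si in self.structure_sigmas:
                names += [f"structure_max_d{ds:g}_i{si:g}",
                          f"structure_min_d{ds:g}_i{si:g}"]
        if "hessian" in self.enabled:
            for s in self.hessian_sigmas:
                names += [f"hessian_hi_s{s:g}", f"hessian_lo_s{s:g}",
                          f"hessian_orient_s{s:g}"]
        return names

    def feature_count(self) -> int:
        return len(self.feature_names())

    def fingerprint(self) -> str:
        payload = asdict(self)
        return hashlib.sha1(
            json.dumps(payload, sort_keys=True, default=list).encode()
        ).hexdigest()

    def max_footprint(self) -> int:
        """Largest spatial footprint radius (voxels) of any enabled filter;
        the minimum safe halo for blockwise application."""
        r = 0
        if "gaussian" in self.enabled and self.gaussian_sigmas:
            r = max(r, max(_gauss_radius(s) for s in self.gaussian_sigmas))
        if "neighbors" in self.enabled and self.neighbors_radii:
            r = max(r, max(self.neighbors_radii))
        if "entropy" in self.enabled:
            r = max(r, self.entropy_radius)
        if "structure" in self.enabled:
            for ds, si in self.structure_sigmas:
                r = max(r, _gauss_radius(ds) + _gauss_radius(si))
        if "hessian" in self.enabled and self.hessian_sigmas:
            r = max(r, max(_gauss_radius(s) for s in self.hessian_sigmas))
        return r


def _gauss_radius(sigma: float, truncate: float = 4.0) -> int:
    return int(truncate * sigma + 0.5)


def gaussian_derivative_kernel(sigma: float, order: int) -> np.ndarray:
    """1D sampled-Gaussian derivative kernel, truncated at 4 sigma.

    The plain Gaussian is normalised to unit sum; derivative kernels of
    even order are corrected to zero DC response so that constant inputs
    map exactly to zero (truncation otherwise leaves a small residual).
    Odd orders are antisymmetric and already sum to zero.
    """
    r = _gauss_radius(sigma)
    x = np.arange(-r, r + 1, dtype=np.float64)
    g = np.exp(-0.5 * (x / sigma) ** 2)
    g /= g.sum()
    if order == 0:
        return g
    if order == 1:
        return -x / sigma ** 2 * g
    if order == 2:
        k = (x ** 2 / sigma ** 4 - 1.0 / sigma ** 2) * g
        return k - k.mean()
    raise ValueError("order must be 0, 1 or 2")


def gaussian_derivative(img: np.ndarray, sigma: float,
                        order_y: int, order_x: int) -> np.ndarray:
    """Separable Gaussian-derivative filtering with mirror boundary."""
    img = np.asarray(img, dtype=np.float64)
    out = ndimage.correlate1d(img, gaussian_derivative_kernel(sigma, order_y)[::-1],
                              axis=0, mode="mirror")
    out = ndimage.correlate1d(out, gaussian_derivative_kernel(sigma, order_x)[::-1],
                              axis=1, mode="mirror")
    return out


@dataclass
class FeatureStack:
    """Per-voxel feature vectors for one slice or block (in memory only).

    ``data`` has shape (..., n_features); the trailing axis order matches
    ``feature_names`` and is stable across calls and machines.
    """

    data: np.ndarray
    feature_names: list[str]
    spec_fingerprint: str

    @property
    def n_features(self) -> int:
        return self.data.shape[-1]

    def as_matrix(self) -> np.ndarray:
        return self.data.reshape(-1, self.n_features)


def gaussian_blur(img: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing with mirror boundary; mean-preserving."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return ndimage.gaussian_filter(np.asarray(img, dtype=np.float64),
                                   sigma, mode="mirror")


def neighbors_features(img: np.ndarray, radii: Sequence[int]) -> np.ndarray:
    """Neighbour intensities: for each radius r and compass direction d the
    feature at (y, x) is the input at (y + r*dy, x + r*dx), mirror boundary.

    Returns an array of shape (H, W, 8 * len(radii)) ordered radius-major,
    direction order N, NE, E, SE, S, SW, W, NW.
    """
    if any(r < 1 for r in radii):
        raise ValueError("radii must be >= 1")
    img = np.asarray(img, dtype=np.float64)
    h, w = img.shape
    out = np.empty((h, w, 8 * len(radii)), dtype=np.float64)
    for ri, r in enumerate(radii):
        padded = np.pad(img, r, mode="reflect")
        for di, (_, (dy, dx)) in enumerate(NEIGHBOR_DIRECTIONS):
            out[..., 8 * ri + di] = padded[r + r * dy: r + r * dy + h,
                                           r + r * dx: r + r * dx + w]
    return out


def _disc_footprint(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return (yy * yy + xx * xx <= radius * radius).astype(np.float64)


def entropy_features(img: np.ndarray, radius: int, bins: int,
                     value_range: tuple[float, float] | None = None) -> np.ndarray:
    """Per-pixel Shannon entropy (base 2) of the local intensity histogram.

    Intensities are quantised to ``bins`` equal-width bins over
    ``value_range`` (default: the slice's min-max); the histogram is taken
    over the disc of the given radius with mirror boundary.  A degenerate
    range yields zero entropy everywhere.
    """
    if radius < 1 or bins < 2:
        raise ValueError("radius must be >= 1 and bins >= 2")
    img = np.asarray(img, dtype=np.float64)
    lo, hi = value_range if value_range is not None else (img.min(), img.max())
    if not hi > lo:
        return np.zeros(img.shape, dtype=np.float64)
    q = np.clip(((img - lo) / (hi - lo) * bins).astype(np.int64), 0, bins - 1)
    disc = _disc_footprint(radius)
    total = disc.sum()
    entropy = np.zeros(img.shape, dtype=np.float64)
    for b in range(bins):
        ind = (q == b).astype(np.float64)
        if not ind.any():
            continue
        cnt = ndimage.correlate(ind, disc, mode="mirror")
        cnt = np.round(cnt)  # counts are integers; kill FP dust
        p = cnt / total
        nz = p > 0
        entropy[nz] -= p[nz] * np.log2(p[nz])
    return entropy


def structure_features(img: np.ndarray, derivative_scale: float,
                       integration_scale: float) -> tuple[np.ndarray, np.ndarray]:
    """Largest and smallest eigenvalues of the 2D structure tensor.

    Gradients are Gaussian derivatives at ``derivative_scale``; their outer
    product is smoothed at ``integration_scale``.
    """
    if derivative_scale <= 0 or integration_scale <= 0:
        raise ValueError("scales must be positive")
    img = np.asarray(img, dtype=np.float64)
    gy = gaussian_derivative(img, derivative_scale, 1, 0)
    gx = gaussian_derivative(img, derivative_scale, 0, 1)
    jxx = ndimage.gaussian_filter(gx * gx, integration_scale, mode="mirror")
    jyy = ndimage.gaussian_filter(gy * gy, integration_scale, mode="mirror")
    jxy = ndimage.gaussian_filter(gx * gy, integration_scale, mode="mirror")
    tr = jxx + jyy
    disc = np.sqrt((jxx - jyy) ** 2 + 4.0 * jxy ** 2)
    return 0.5 * (tr + disc), 0.5 * (tr - disc)


def hessian_features(img: np.ndarray, sigma: float
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hessian eigenvalues and orientation at one Gaussian scale.

    Returns (eig_hi, eig_lo, orientation): the two eigenvalues of the
    Gaussian second-derivative Hessian ordered by signed value, and the
    angle in [0, pi) from the +x axis of the eigenvector belonging to the
    larger-magnitude eigenvalue (0 by convention at isotropic points).
    For a bright ridge the large-magnitude eigenvalue is strongly negative
    and its eigenvector points across the ridge.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    img = np.asarray(img, dtype=np.float64)
    hyy = gaussian_derivative(img, sigma, 2, 0)
    hxx = gaussian_derivative(img, sigma, 0, 2)
    hxy = gaussian_derivative(img, sigma, 1, 1)
    tr = hxx + hyy
    disc = np.sqrt((hxx - hyy) ** 2 + 4.0 * hxy ** 2)
    eig_hi = 0.5 * (tr + disc)
    eig_lo = 0.5 * (tr - disc)
    lam = np.where(np.abs(eig_hi) >= np.abs(eig_lo), eig_hi, eig_lo)
    # eigenvector of lam: (hxy, lam - hxx), or (lam - hyy, hxy) if degenerate
    vx = hxy
    vy = lam - hxx
    alt = np.abs(vx) + np.abs(vy) < np.abs(lam - hyy) + np.abs(hxy)
    vx = np.where(alt, lam - hyy, vx)
    vy = np.where(alt, hxy, vy)
    theta = np.mod(np.arctan2(vy, vx), np.pi)
    # isotropic points (eigenvalue tie, incl. numerical dust on constant
    # regions) have no defined orientation: set 0 by convention
    scale = float(np.abs(img).max())
    tied = disc <= 1e-9 * max(scale, 1e-300)
    theta = np.where(tied, 0.0, theta)
    theta = np.where(np.isclose(theta, np.pi), 0.0, theta)
    return eig_hi, eig_lo, theta


def _slice_stack(img: np.ndarray, spec: FeatureSpec) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    feats = [img]
    if "gaussian" in spec.enabled:
        feats += [gaussian_blur(img, s) for s in spec.gaussian_sigmas]
    if "neighbors" in spec.enabled:
        nb = neighbors_features(img, spec.neighbors_radii)
        feats += [nb[..., i] for i in range(nb.shape[-1])]
    if "entropy" in spec.enabled:
        feats.append(entropy_features(img, spec.entropy_radius,
                                      spec.entropy_bins, spec.entropy_range))
    if "structure" in spec.enabled:
        for ds, si in spec.structure_sigmas:
            lo_hi = structure_features(img, ds, si)
            feats += [lo_hi[0], lo_hi[1]]
    if "hessian" in spec.enabled:
        for s in spec.hessian_sigmas:
            feats += list(hessian_features(img, s))
    return np.stack(feats, axis=-1)


def build_feature_stack(block: np.ndarray, spec: FeatureSpec) -> FeatureStack:
    """Compute the full feature bank for a 2D slice or a 3D block.

    3D blocks are processed slice by slice along z.  Raw intensity is
    always feature 0; the remaining order follows ``spec.feature_names()``.
    """
    block = np.asarray(block)
    if block.ndim == 2:
        data = _slice_stack(block, spec)
    elif block.ndim == 3:
        data = np.stack([_slice_stack(block[z], spec)
                         for z in range(block.shape[0])], axis=0)
    else:
        raise ValueError(f"block must be 2D or 3D, got ndim {block.ndim}")
    return FeatureStack(data.astype(np.float32),
                        spec.feature_names(), spec.fingerprint())
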