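"""Synthetic micro-CT phantoms of wax-embedded lung tissue.

A rendered phantom reproduces the statistical scene of a real scan section:
a uniform wax background, darker air bubbles trapped in the wax, a textured
alveolar region, and tubular airways/vessels whose walls are brighter than
wax while their lumens — being wax-filled — match the background exactly.
Ground-truth wall and lumen masks are returned alongside the volume, so
every pipeline stage can be scored without any external data.

Intensities default to 16-bit-range values (wax 20000, wall 35000, bubble
8000) so 8/16/32-bit code paths are all exercised by casting.  Noise is
additive Gaussian, a simple proxy for reconstruction noise; beam hardening
and ring artifacts are not modelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .blockstore import Volume
from .trainseg import LabelSet

__all__ = [
    "Tube",
    "PhantomSpec",
    "render_phantom",
    "default_phantom",
    "make_labelset_from_truth",
]


@dataclass(frozen=True)
class Tube:
    """A tubular structure: a polyline centerline (linear interpolation
    between control points, (z, y, x) voxel coordinates), a lumen radius
    and a wall thickness, both in voxels."""

    points: tuple[tuple[float, float, float], ...]
    lumen_radius: float
    wall_thickness: float

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError("a tube needs at least two control points")
        if self.lumen_radius < 0:
            raise ValueError("lumen_radius must be >= 0")
        if self.wall_thickness < 1:
            raise ValueError("wall_thickness must be >= 1")


@dataclass(frozen=True)
class PhantomSpec:
    """Scene description for a phantom volume.

    Intensity ordering wall_level > wax_level > bubble_level is enforced:
    walls are X-ray dense, wax is intermediate, air is lucent.
    """

    dims: tuple[int, int, int] = (96, 96, 96)
    wax_level: float = 20000.0
    wall_level: float = 35000.0
    bubble_level: float = 8000.0
    tubes: tuple[Tube, ...] = ()
    bubbles: tuple[tuple[tuple[float, float, float], float], ...] = ()
    alveolar_box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]] | None = None
    alveolar_amplitude: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.wall_level > self.wax_level > self.bubble_level):
            raise ValueError(
                "intensity ordering wall_level > wax_level > bubble_level required")
        if any(d < 1 for d in self.dims):
            raise ValueError("dims must all be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _segment_distance(coords: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from each row of coords to the segment a-b."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(coords - a, axis=1)
    t = np.clip(((coords - a) @ ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(coords - proj, axis=1)


def _tube_distance(dims: tuple[int, int, int], tube: Tube) -> np.ndarray:
    zz, yy, xx = np.meshgrid(*[np.arange(d, dtype=np.float32) for d in dims],
                             indexing="ij")
    coords = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)
    pts = np.asarray(tube.points, dtype=np.float32)
    dist = np.full(coords.shape[0], np.inf, dtype=np.float32)
    for a, b in zip(pts[:-1], pts[1:]):
        np.minimum(dist, _segment_distance(coords, a, b), out=dist)
    return dist.reshape(dims)


def render_phantom(spec: PhantomSpec) -> tuple[Volume, np.ndarray, np.ndarray]:
    """Render a phantom volume with its ground-truth wall and lumen masks.

    Voxels within the lumen radius of a centerline take the wax level (the
    lumen is wax-filled); the shell out to lumen_radius + wall_thickness
    takes the wall level.  Bubbles override to the bubble level (and are
    excluded from the truth masks), noise is added last, and the truth
    masks are computed before noise so they are independent of it.
    """
    dims = spec.dims
    rng = np.random.default_rng(spec.seed)
    vol = np.full(dims, spec.wax_level, dtype=np.float32)

    if spec.alveolar_box is not None and spec.alveolar_amplitude > 0:
        (z0, z1), (y0, y1), (x0, x1) = spec.alveolar_box
        box_shape = (z1 - z0, y1 - y0, x1 - x0)
        tex = rng.standard_normal(box_shape).astype(np.float32)
        tex = ndimage.gaussian_filter(tex, 2.0)
        tex /= max(tex.std(), 1e-12)
        vol[z0:z1, y0:y1, x0:x1] += spec.alveolar_amplitude * tex

    wall_truth = np.zeros(dims, dtype=bool)
    lumen_truth = np.zeros(dims, dtype=bool)
    for tube in spec.tubes:
        outer = tube.lumen_radius + tube.wall_thickness
        pts = np.asarray(tube.points)
        if (pts < 0).any() or (pts >= np.asarray(dims)).any():
            warnings.warn("tube centerline leaves the volume; it will be clipped")
        dist = _tube_distance(dims, tube)
        lumen = dist <= tube.lumen_radius
        wall = (dist > tube.lumen_radius) & (dist <= outer)
        vol[lumen] = spec.wax_level
        vol[wall] = spec.wall_level
        lumen_truth |= lumen
        wall_truth |= wall
    # walls win over lumens where tubes overlap
    lumen_truth &= ~wall_truth

    bubble_mask = np.zeros(dims, dtype=bool)
    if spec.bubbles:
        zz, yy, xx = np.meshgrid(*[np.arange(d, dtype=np.float32) for d in dims],
                                 indexing="ij")
        for center, radius in spec.bubbles:
            cz, cy, cx = center
            sphere = ((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2
                      <= radius * radius)
            bubble_mask |= sphere
        vol[bubble_mask] = spec.bubble_level
        wall_truth &= ~bubble_mask
        lumen_truth &= ~bubble_mask

    if spec.noise_sigma > 0:
        vol = vol + rng.normal(0.0, spec.noise_sigma, size=dims).astype(np.float32)

    return Volume(vol.astype(np.float32)), wall_truth, lumen_truth


def default_phantom(seed: int = 1) -> PhantomSpec:
    """The package's standard test scene: a 96^3 volume with one airway
    (wide lumen, thicker wall), one blood vessel (narrow lumen, thin wall),
    three air bubbles and one textured alveolar box, with Gaussian noise at
    10% of the wall-to-wax contrast."""
    airway = Tube(points=((0, 48, 24), (48, 56, 48), (95, 48, 72)),
                  lumen_radius=7.0, wall_thickness=3.0)
    vessel = Tube(points=((0, 75, 75), (48, 70, 60), (95, 78, 40)),
                  lumen_radius=4.0, wall_thickness=2.0)
    return PhantomSpec(
        dims=(96, 96, 96),
        tubes=(airway, vessel),
        bubbles=(((20, 15, 20), 6.0), ((70, 20, 30), 5.0), ((85, 85, 12), 7.0)),
        alveolar_box=((10, 50), (8, 30), (55, 88)),
        alveolar_amplitude=3000.0,
        noise_sigma=0.10 * (35000.0 - 20000.0),
        seed=seed,
    )


def make_labelset_from_truth(wall_truth: np.ndarray, lumen_truth: np.ndarray,
                             n_slices: int = 2, seed: int = 0,
                             per_class: int = 200) -> LabelSet:
    """Sample a sparse training label set from ground-truth masks.

    Emulates manual annotation of a few slices: foreground labels are drawn
    from wall plus lumen (walls are annotated with their interior), and
    background labels from everything else on the same slices.  Slices
    without foreground are resampled with a warning.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    rng = np.random.default_rng(seed)
    fg = wall_truth | lumen_truth
    nz = fg.shape[0]
    candidates = [z for z in range(nz) if fg[z].any()]
    if not candidates:
        raise ValueError("truth masks contain no foreground on any slice")
    order = rng.permutation(nz)
    chosen: list[int] = []
    skipped = False
    for z in order:
        if len(chosen) == n_slices:
            break
        if fg[z].any():
            chosen.append(int(z))
        else:
            skipped = True
    if skipped:
        warnings.warn("some candidate slices had no foreground and were resampled")
    zs, ys, xs, cs = [], [], [], []
    for z in sorted(chosen):
        for class_id, m in ((1, fg[z]), (0, ~fg[z])):
            yy, xx = np.nonzero(m)
            n = min(per_class, len(yy))
            pick = rng.choice(len(yy), size=n, replace=False)
            zs.append(np.full(n, z))
            ys.append(yy[pick])
            xs.append(xx[pick])
            cs.append(np.full(n, class_id))
    return LabelSet(np.concatenate(zs), np.concatenate(ys),
                    np.concatenate(xs), np.concatenate(cs))
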