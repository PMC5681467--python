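"""Presentation of segmentation results: colorized overlays and 3D meshes.

Overlays blend mask colors over the grayscale section for visual QC; masks
are surfaced with marching cubes and written as binary STL for rendering or
3D printing.  Both stages are read-only with respect to the masks.  Mesh
smoothing is deliberately out of scope: the exported surface is the raw
iso-surface at the voxel scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import trimesh
from skimage import measure

__all__ = [
    "MeshModel",
    "EmptyMaskError",
    "overlay_masks",
    "write_overlay",
    "mask_to_mesh",
    "write_stl",
    "read_stl",
]


class EmptyMaskError(ValueError):
    """Surfacing was requested for a mask with no foreground voxels."""


@dataclass
class MeshModel:
    """A triangulated surface in physical coordinates (micrometres).

    ``vertices`` is (V, 3) float in (z, y, x) order scaled by the voxel
    size; ``faces`` is (F, 3) int.  ``provenance`` records which mask the
    mesh came from.
    """

    vertices: np.ndarray
    faces: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if len(self.faces) and (self.faces.min() < 0
                                or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def euler_characteristic(self) -> int:
        """V - E + F of the triangulation (2 for a closed genus-0 surface,
        <= 0 once the surface has handles, e.g. a tube wall)."""
        edges = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        n_edges = len(np.unique(edges, axis=0))
        return len(self.vertices) - n_edges + self.n_faces

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces,
                               process=False)


def overlay_masks(slice2d: np.ndarray,
                  masks: list[np.ndarray],
                  colors: list[tuple[int, int, int]],
                  alpha: float = 0.5) -> np.ndarray:
    """Alpha-blend mask colors over a grayscale slice.

    The grayscale base is scaled to 0..255 over the slice's own range.
    Masks are painted in list order, so where masks overlap the
    last-listed mask wins.  Pixels in no mask keep their grayscale value.
    Returns an (H, W, 3) uint8 image.
    """
    slice2d = np.asarray(slice2d, dtype=np.float64)
    if len(masks) != len(colors):
        raise ValueError("need one color per mask")
    if len(set(map(tuple, colors))) != len(colors):
        raise ValueError("mask colors must be distinct")
    lo, hi = slice2d.min(), slice2d.max()
    gray = np.zeros_like(slice2d) if hi <= lo else (slice2d - lo) / (hi - lo) * 255.0
    rgb = np.repeat(gray[..., None], 3, axis=2)
    for mask, color in zip(masks, colors):
        mask = np.asarray(mask).astype(bool)
        if mask.shape != slice2d.shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match slice {slice2d.shape}")
        for c in range(3):
            ch = rgb[..., c]
            ch[mask] = (1.0 - alpha) * ch[mask] + alpha * color[c]
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


def write_overlay(image: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), image)


def mask_to_mesh(mask: np.ndarray, voxel_size_um: float = 8.0,
                 provenance: str = "") -> MeshModel:
    """Surface a binary mask with marching cubes at the 0.5 iso-level.

    The mask is padded with one background layer first, so masks touching
    the volume boundary still yield closed (watertight) surfaces.  Vertex
    coordinates are in micrometres.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise EmptyMaskError("cannot surface an empty mask")
    padded = np.pad(mask, 1).astype(np.float32)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5)
    verts = (verts - 1.0) * voxel_size_um
    faces = faces[:, ::-1]  # outward-facing normals (positive enclosed volume)
    return MeshModel(verts, faces, provenance=provenance)


def write_stl(mesh: MeshModel, path: str | Path) -> None:
    """Write a binary STL; the declared triangle count equals the mesh's
    face count."""
    if mesh.n_faces == 0:
        raise EmptyMaskError("refusing to write an empty mesh")
    mesh.to_trimesh().export(Path(path), file_type="stl")


def read_stl(path: str | Path) -> MeshModel:
    tm = trimesh.load_mesh(Path(path), process=False)
    return MeshModel(np.asarray(tm.vertices), np.asarray(tm.faces))
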