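"""Out-of-core handling of large 3D volumes as grids of cubic blocks.

Micro-CT scans of wax-embedded tissue are tens of gigabytes; processing them
whole needs several times that in RAM.  The strategy here is the classic
ghost-cell one from parallel computing: the volume is partitioned into cubic
sub-volumes ("blocks"), each persisted as a loss-less TIFF, and any filter
with a bounded spatial footprint is applied block by block after borrowing a
halo of voxels from the neighbouring blocks.  Global intensity properties
(min / max / histogram) live in a JSON sidecar so that later stages can use
volume-wide statistics without ever loading the full array.

Conventions used throughout the package:

* arrays are indexed ``(z, y, x)``, 0-based, with half-open ranges;
* blocks enumerate in row-major order with the x-block index fastest;
* edge blocks are truncated, never padded, so the core blocks partition the
  volume exactly;
* out-of-volume voxels (needed when a halo sticks out of the scan) are
  filled by mirror reflection about the boundary voxel.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator, Sequence

import numpy as np
import tifffile

__all__ = [
    "Volume",
    "BlockGrid",
    "BlockRef",
    "VolumeMeta",
    "BlockStore",
    "IncompleteStoreError",
    "ContractViolationError",
    "plan_grid",
    "split_volume",
    "assemble_volume",
    "read_block_with_halo",
    "map_blocks",
    "compute_meta",
    "read_volume",
    "write_volume",
]

BLOCK_NAME = "block_{0:04d}_{1:04d}_{2:04d}.tif"
META_NAME = "meta.json"

_DTYPE_BITS = {np.dtype(np.uint8): 8, np.dtype(np.uint16): 16,
               np.dtype(np.float32): 32, np.dtype(np.int32): 32,
               np.dtype(np.uint32): 32}


class IncompleteStoreError(RuntimeError):
    """A block expected by the grid is missing from the store."""


class ContractViolationError(RuntimeError):
    """A user-supplied block operator broke the map_blocks contract."""


def _dtype_bits(dtype: np.dtype) -> int:
    dtype = np.dtype(dtype)
    if dtype in _DTYPE_BITS:
        return _DTYPE_BITS[dtype]
    return dtype.itemsize * 8


@dataclass
class Volume:
    """A 3D scalar intensity grid with voxel-size metadata.

    ``data`` is indexed (z, y, x).  ``voxel_size_um`` is the isotropic voxel
    edge in micrometres (8 um for the scanner settings this tool targets).
    """

    data: np.ndarray
    voxel_size_um: float = 8.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ValueError("all volume dimensions must be >= 1")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        if np.issubdtype(self.data.dtype, np.floating) and not np.isfinite(self.data).all():
            raise ValueError("volume intensities must be finite")

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    @property
    def dtype_bits(self) -> int:
        return _dtype_bits(self.data.dtype)


@dataclass(frozen=True)
class BlockRef:
    """One block of a grid: its index and voxel ranges in volume coordinates."""

    index: tuple[int, int, int]
    core: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    halo_extent: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

    @property
    def core_shape(self) -> tuple[int, int, int]:
        return tuple(hi - lo for lo, hi in self.core)  # type: ignore[return-value]

    def core_slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi) for lo, hi in self.core)  # type: ignore[return-value]


@dataclass(frozen=True)
class BlockGrid:
    """Ceiling-division partition of a volume into cubic blocks."""

    volume_dims: tuple[int, int, int]
    block_edge: int
    halo: int = 0

    def __post_init__(self) -> None:
        if self.block_edge < 1:
            raise ValueError("block_edge must be >= 1")
        if self.halo < 0:
            raise ValueError("halo must be >= 0")
        if any(d < 1 for d in self.volume_dims):
            raise ValueError("volume dims must all be >= 1")

    @property
    def counts(self) -> tuple[int, int, int]:
        return tuple(math.ceil(d / self.block_edge) for d in self.volume_dims)  # type: ignore[return-value]

    @property
    def n_blocks(self) -> int:
        cz, cy, cx = self.counts
        return cz * cy * cx

    def ref(self, index: tuple[int, int, int]) -> BlockRef:
        counts = self.counts
        for a in range(3):
            if not 0 <= index[a] < counts[a]:
                raise IndexError(f"block index {index} outside grid counts {counts}")
        core = tuple(
            (index[a] * self.block_edge,
             min((index[a] + 1) * self.block_edge, self.volume_dims[a]))
            for a in range(3)
        )
        halo_extent = tuple((lo - self.halo, hi + self.halo) for lo, hi in core)
        return BlockRef(tuple(index), core, halo_extent)  # type: ignore[arg-type]

    def indices(self) -> Iterator[tuple[int, int, int]]:
        """Row-major enumeration, x-block index fastest."""
        cz, cy, cx = self.counts
        for i in range(cz):
            for j in range(cy):
                for k in range(cx):
                    yield (i, j, k)

    def refs(self) -> Iterator[BlockRef]:
        for idx in self.indices():
            yield self.ref(idx)


def plan_grid(dims: Sequence[int], block_edge: int, halo: int = 0) -> BlockGrid:
    """Plan a block grid for a volume of the given (nz, ny, nx) dimensions."""
    return BlockGrid(tuple(int(d) for d in dims), int(block_edge), int(halo))  # type: ignore[arg-type]


@dataclass
class VolumeMeta:
    """Global properties of a split volume, persisted in the JSON sidecar."""

    dims: tuple[int, int, int]
    block_edge: int
    halo: int
    voxel_size_um: float
    dtype: str
    global_min: float | None = None
    global_max: float | None = None
    histogram_edges: list[float] = field(default_factory=list)
    histogram_counts: list[int] = field(default_factory=list)

    @property
    def dtype_bits(self) -> int:
        return _dtype_bits(np.dtype(self.dtype))

    @property
    def block_count(self) -> int:
        return BlockGrid(self.dims, self.block_edge, self.halo).n_blocks

    def to_dict(self) -> dict:
        return {
            "dims": list(self.dims),
            "block_edge": self.block_edge,
            "halo": self.halo,
            "voxel_size_um": self.voxel_size_um,
            "dtype": self.dtype,
            "dtype_bits": self.dtype_bits,
            "block_count": self.block_count,
            "global_min": self.global_min,
            "global_max": self.global_max,
            "histogram_edges": self.histogram_edges,
            "histogram_counts": self.histogram_counts,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VolumeMeta":
        return cls(
            dims=tuple(d["dims"]),
            block_edge=int(d["block_edge"]),
            halo=int(d["halo"]),
            voxel_size_um=float(d["voxel_size_um"]),
            dtype=str(d["dtype"]),
            global_min=d.get("global_min"),
            global_max=d.get("global_max"),
            histogram_edges=list(d.get("histogram_edges", [])),
            histogram_counts=[int(c) for c in d.get("histogram_counts", [])],
        )


class BlockStore:
    """A directory of per-block TIFFs plus the JSON metadata sidecar."""

    def __init__(self, path: str | os.PathLike, meta: VolumeMeta):
        self.path = Path(path)
        self.meta = meta

    @property
    def grid(self) -> BlockGrid:
        return BlockGrid(self.meta.dims, self.meta.block_edge, self.meta.halo)

    @classmethod
    def open(cls, path: str | os.PathLike) -> "BlockStore":
        path = Path(path)
        meta_path = path / META_NAME
        if not meta_path.exists():
            raise FileNotFoundError(f"no {META_NAME} sidecar in {path}")
        meta = VolumeMeta.from_dict(json.loads(meta_path.read_text()))
        return cls(path, meta)

    @classmethod
    def create(cls, path: str | os.PathLike, meta: VolumeMeta,
               overwrite: bool = False) -> "BlockStore":
        path = Path(path)
        if path.exists() and any(path.iterdir()) and not overwrite:
            raise FileExistsError(
                f"store path {path} exists and is non-empty; pass overwrite=True")
        path.mkdir(parents=True, exist_ok=True)
        store = cls(path, meta)
        store.write_meta()
        return store

    def block_path(self, index: tuple[int, int, int]) -> Path:
        return self.path / BLOCK_NAME.format(*index)

    def write_meta(self) -> None:
        (self.path / META_NAME).write_text(json.dumps(self.meta.to_dict(), indent=1))

    def write_block(self, index: tuple[int, int, int], data: np.ndarray) -> None:
        expected = self.grid.ref(index).core_shape
        if tuple(data.shape) != expected:
            raise ContractViolationError(
                f"block {index} has shape {data.shape}, expected core shape {expected}")
        tifffile.imwrite(self.block_path(index), np.ascontiguousarray(data),
                         photometric="minisblack")

    def read_block(self, index: tuple[int, int, int]) -> np.ndarray:
        p = self.block_path(index)
        if not p.exists():
            raise IncompleteStoreError(f"missing block {tuple(index)} ({p.name})")
        arr = tifffile.imread(p)
        if arr.ndim == 2:  # single-slice blocks collapse to 2D on disk
            arr = arr[None, ...]
        return arr

    def is_complete(self) -> bool:
        return all(self.block_path(i).exists() for i in self.grid.indices())

    def read_slice(self, z: int) -> np.ndarray:
        """Gather one full (y, x) plane at height z from the stored blocks."""
        nz, ny, nx = self.meta.dims
        if not 0 <= z < nz:
            raise IndexError(f"slice {z} outside volume depth {nz}")
        out = np.empty((ny, nx), dtype=np.dtype(self.meta.dtype))
        i = z // self.meta.block_edge
        cz, cy, cx = self.grid.counts
        for j in range(cy):
            for k in range(cx):
                ref = self.grid.ref((i, j, k))
                blk = self.read_block((i, j, k))
                (z0, _), (y0, y1), (x0, x1) = ref.core
                out[y0:y1, x0:x1] = blk[z - z0]
        return out


def read_volume(path: str | os.PathLike, voxel_size_um: float = 8.0) -> Volume:
    """Read a volume from a multi-page TIFF or a directory of per-slice TIFFs.

    Slice files in a directory are stacked in lexicographic filename order,
    which is taken to be the z order.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise FileNotFoundError(f"no TIFF slices in {path}")
        data = np.stack([tifffile.imread(f) for f in files], axis=0)
    else:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None, ...]
    return Volume(data, voxel_size_um=voxel_size_um)


def write_volume(volume: Volume, path: str | os.PathLike) -> None:
    """Write a volume as a single multi-page loss-less TIFF."""
    tifffile.imwrite(Path(path), np.ascontiguousarray(volume.data),
                     photometric="minisblack")


def split_volume(volume: Volume, grid: BlockGrid, store_path: str | os.PathLike,
                 overwrite: bool = False) -> BlockStore:
    """Split a volume into per-block TIFFs with a JSON sidecar.

    Only core regions are stored; halos are constructed on read.  No voxel
    value is altered.
    """
    if tuple(grid.volume_dims) != tuple(volume.dims):
        raise ValueError(
            f"grid planned for dims {grid.volume_dims}, volume has {volume.dims}")
    meta = VolumeMeta(
        dims=volume.dims, block_edge=grid.block_edge, halo=grid.halo,
        voxel_size_um=volume.voxel_size_um, dtype=str(volume.data.dtype),
    )
    store = BlockStore.create(store_path, meta, overwrite=overwrite)
    for ref in grid.refs():
        store.write_block(ref.index, volume.data[ref.core_slices()])
    return store


def assemble_volume(store: BlockStore) -> Volume:
    """Concatenate all core blocks back into a single volume (exact inverse
    of :func:`split_volume`)."""
    meta = store.meta
    out = np.empty(meta.dims, dtype=np.dtype(meta.dtype))
    for ref in store.grid.refs():
        blk = store.read_block(ref.index)
        if tuple(blk.shape) != ref.core_shape:
            raise ContractViolationError(
                f"block {ref.index} on disk has shape {blk.shape}, "
                f"expected {ref.core_shape}")
        out[ref.core_slices()] = blk
    return Volume(out, voxel_size_um=meta.voxel_size_um)


def _mirror_pad(arr: np.ndarray, widths: list[tuple[int, int]]) -> np.ndarray:
    """Mirror-reflect about the boundary voxel (no edge duplication); falls
    back to edge replication along axes too short to reflect."""
    if all(w == (0, 0) for w in widths):
        return arr
    safe = []
    for (lo, hi), n in zip(widths, arr.shape):
        # np.pad 'reflect' needs pad width <= n - 1 per side
        safe.append(n > max(lo, hi))
    if all(safe):
        return np.pad(arr, widths, mode="reflect")
    out = arr
    for ax, (lo, hi) in enumerate(widths):
        if lo == 0 and hi == 0:
            continue
        w = [(0, 0)] * out.ndim
        w[ax] = (lo, hi)
        mode = "reflect" if out.shape[ax] > max(lo, hi) else "edge"
        out = np.pad(out, w, mode=mode)
    return out


def read_block_with_halo(store: BlockStore, index: tuple[int, int, int],
                         halo: int) -> np.ndarray:
    """Read one block expanded by ``halo`` voxels per side.

    Interior faces are filled from neighbouring blocks; faces at the volume
    boundary are filled by mirror reflection.  Output shape is the core
    shape plus ``2 * halo`` along each axis.
    """
    if halo < 0:
        raise ValueError("halo must be >= 0")
    if halo > store.meta.block_edge:
        raise ValueError(
            f"halo {halo} exceeds block edge {store.meta.block_edge}")
    grid = store.grid
    ref = grid.ref(index)
    dims = store.meta.dims
    want = [(lo - halo, hi + halo) for lo, hi in ref.core]
    clipped = [(max(lo, 0), min(hi, d)) for (lo, hi), d in zip(want, dims)]
    gathered = np.empty([hi - lo for lo, hi in clipped],
                        dtype=np.dtype(store.meta.dtype))
    edge = store.meta.block_edge
    brange = [range(lo // edge, (hi - 1) // edge + 1) for lo, hi in clipped]
    for i in brange[0]:
        for j in brange[1]:
            for k in brange[2]:
                nref = grid.ref((i, j, k))
                blk = store.read_block((i, j, k))
                src, dst = [], []
                for a, ((c0, c1), (g0, g1)) in enumerate(zip(nref.core, clipped)):
                    lo = max(c0, g0)
                    hi = min(c1, g1)
                    src.append(slice(lo - c0, hi - c0))
                    dst.append(slice(lo - g0, hi - g0))
                gathered[tuple(dst)] = blk[tuple(src)]
    widths = [(c0 - w0, w1 - c1)
              for (w0, w1), (c0, c1) in zip(want, clipped)]
    return _mirror_pad(gathered, widths)


def map_blocks(store: BlockStore, voxel_op: Callable[[np.ndarray], np.ndarray],
               halo: int, out_path: str | os.PathLike,
               out_dtype: np.dtype | str | None = None,
               overwrite: bool = False) -> BlockStore:
    """Apply a shape-preserving voxel operator block by block.

    ``voxel_op`` must have a spatial footprint radius of at most ``halo``:
    under that condition the assembled result equals applying the operator
    to the unsplit volume.  The operator receives the halo-padded block and
    must return an array of identical shape; the halo is cropped on write.
    Blocks are independent, so processing order does not affect the result.
    """
    out: BlockStore | None = None
    for ref in store.grid.refs():
        padded = read_block_with_halo(store, ref.index, halo)
        result = voxel_op(padded)
        if result.shape != padded.shape:
            raise ContractViolationError(
                f"operator changed block shape {padded.shape} -> {result.shape} "
                f"at block {ref.index}")
        if out is None:
            if out_dtype is None:
                out_dtype = result.dtype
            meta = VolumeMeta(
                dims=store.meta.dims, block_edge=store.meta.block_edge,
                halo=store.meta.halo, voxel_size_um=store.meta.voxel_size_um,
                dtype=str(np.dtype(out_dtype)),
            )
            out = BlockStore.create(out_path, meta, overwrite=overwrite)
        core = result[tuple(slice(halo, halo + s) for s in ref.core_shape)]
        out.write_block(ref.index, core.astype(out_dtype, copy=False))
    assert out is not None
    return out


def compute_meta(store: BlockStore, bins: int = 256) -> VolumeMeta:
    """Aggregate global min / max and the intensity histogram over all
    blocks and persist them in the sidecar.

    The result is identical to computing the histogram on the unsplit
    volume with the same bin edges.
    """
    gmin = math.inf
    gmax = -math.inf
    dtype = None
    for idx in store.grid.indices():
        blk = store.read_block(idx)
        if dtype is None:
            dtype = blk.dtype
        elif blk.dtype != dtype:
            raise ValueError(
                f"inconsistent block dtypes: {dtype} vs {blk.dtype} at {idx}")
        gmin = min(gmin, float(blk.min()))
        gmax = max(gmax, float(blk.max()))
    if gmax > gmin:
        edges = np.linspace(gmin, gmax, bins + 1)
    else:
        edges = np.array([gmin, gmin + 1.0])  # degenerate range: one bin
    counts = np.zeros(len(edges) - 1, dtype=np.int64)
    for idx in store.grid.indices():
        blk = store.read_block(idx)
        c, _ = np.histogram(blk, bins=edges)
        counts += c
    meta = store.meta
    meta.global_min = gmin
    meta.global_max = gmax
    meta.histogram_edges = [float(e) for e in edges]
    meta.histogram_counts = [int(c) for c in counts]
    store.write_meta()
    return meta
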