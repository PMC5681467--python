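"""End-to-end segmentation pipeline and its configuration.

The pipeline chains the stages of the workflow — split into blocks, train
or load a classifier, predict per block, threshold, intensity-refine,
denoise, assemble, export — behind a single config object.  Every stage
logs its parameters and counts, and a JSON run manifest records the full
configuration so any run can be reproduced or restarted from an
intermediate store.
"""

from __future__ import annotations

import dataclasses
import json
import sys
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import blockstore as bs
from . import postprocess as pp
from .features import FeatureSpec
from .synthetic import default_phantom, make_labelset_from_truth, render_phantom
from .trainseg import (ClassifierModel, LabelSet, extract_training_set,
                       load_model, predict_block, save_model, train_classifier)

__all__ = ["PipelineConfig", "run_pipeline", "pick_test_block"]


@dataclass
class PipelineConfig:
    """All pipeline parameters; serialises losslessly to/from JSON.

    ``threshold`` converts the probability map to a mask; ``threshold2``
    is the intensity cut that strips wax-density voxels (pick it between
    the wax and wall modes of the global histogram — the ``meta``
    subcommand prints that histogram).
    """

    input_volume: str | None = None
    input_store: str | None = None
    workdir: str = "tubuseg_run"
    labels: str | None = None
    model: str | None = None
    block_edge: int = 256
    halo: int = 16
    feature_spec: FeatureSpec = field(default_factory=FeatureSpec)
    n_trees: int = 200
    seed: int = 17
    threshold: float = 0.5
    threshold2: float = 27500.0
    denoiser: str = "connected_regions"   # or "open_close" / "close_open_open2"
    min_size: int = 700
    connectivity: int = 26
    voxel_size_um: float = 8.0
    export_overlay: bool = True
    export_mesh: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        fs = d.get("feature_spec")
        if isinstance(fs, dict):
            fs = {k: (tuple(tuple(x) if isinstance(x, list) else x for x in v)
                      if isinstance(v, list) else v) for k, v in fs.items()}
            d["feature_spec"] = FeatureSpec(**fs)
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, default=list))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _log(stage: str, msg: str) -> None:
    print(f"[tubuseg:{stage}] {msg}", file=sys.stderr)


def pick_test_block(store: bs.BlockStore) -> tuple[int, int, int]:
    """Choose a representative block to trial a segmentation on.

    Returns the block whose intensity variance is closest to the
    volume-wide variance — a proxy for "looks like the volume at large"
    that reliably picks blocks containing structure rather than empty wax.
    Ties break to the lowest index in enumeration order.
    """
    indices = list(store.grid.indices())
    if not indices:
        raise ValueError("empty store")
    n_total = 0
    s1 = 0.0
    s2 = 0.0
    block_var = {}
    for idx in indices:
        blk = store.read_block(idx).astype(np.float64)
        n = blk.size
        n_total += n
        s1 += float(blk.sum())
        s2 += float((blk * blk).sum())
        block_var[idx] = float(blk.var())
    global_var = s2 / n_total - (s1 / n_total) ** 2
    best = min(indices, key=lambda i: (abs(block_var[i] - global_var), i))
    return best


def run_pipeline(config: PipelineConfig,
                 truth_wall: np.ndarray | None = None) -> dict:
    """Execute the full workflow described by ``config``.

    Stages: split (or open an existing store) -> train or load classifier
    -> predict per block with halos -> assemble probability map ->
    threshold -> intensity refine -> denoise -> export.  The probability
    stage is out-of-core; post-processing runs on the assembled volume
    because connected-region filtering is global.

    If ``truth_wall`` is given (phantom runs), the final Dice against it is
    reported in the manifest.  Returns a dict of artifacts including the
    final mask and all output paths.
    """
    t0 = time.time()
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {"workdir": str(workdir)}

    # --- split ---------------------------------------------------------
    if config.input_store:
        store = bs.BlockStore.open(config.input_store)
        _log("split", f"opened existing store {config.input_store} "
                      f"({store.meta.block_count} blocks)")
    else:
        if not config.input_volume:
            raise ValueError("config needs input_volume or input_store")
        volume = bs.read_volume(config.input_volume, config.voxel_size_um)
        grid = bs.plan_grid(volume.dims, config.block_edge, config.halo)
        store = bs.split_volume(volume, grid, workdir / "store_raw",
                                overwrite=True)
        _log("split", f"split {volume.dims} into {grid.n_blocks} blocks "
                      f"(edge {config.block_edge}, halo {config.halo})")
    if store.meta.global_min is None:
        bs.compute_meta(store)
    artifacts["store_raw"] = str(store.path)

    spec = config.feature_spec
    min_halo = spec.max_footprint()
    halo = config.halo
    if store.grid.n_blocks == 1:
        # a single block has no interior seams; mirror padding at its faces
        # already matches whole-volume boundary handling
        halo = 0
    elif halo < min_halo:
        warnings.warn(
            f"halo {halo} is below the maximum filter footprint; the minimum "
            f"safe halo for this feature spec is {min_halo} voxels")
        _log("predict", f"WARNING: halo {halo} < minimum safe halo {min_halo}")
        halo = min(min_halo, store.meta.block_edge)

    # --- train / load --------------------------------------------------
    if config.model and Path(config.model).exists() and not config.labels:
        model = load_model(config.model)
        _log("train", f"loaded model from {config.model}")
    else:
        if not config.labels:
            raise ValueError("config needs labels (for training) or a model file")
        labels = LabelSet.from_table(config.labels)
        label_slices = np.unique(labels.z)
        slice_stack = np.stack([store.read_slice(int(z)) for z in label_slices])
        # re-index label z onto the gathered slices
        zmap = {int(z): i for i, z in enumerate(label_slices)}
        relabeled = LabelSet(
            np.array([zmap[int(z)] for z in labels.z]),
            labels.y, labels.x, labels.class_id, classes=labels.classes)
        sub = bs.Volume(slice_stack, voxel_size_um=store.meta.voxel_size_um)
        X, y = extract_training_set(sub, relabeled, spec)
        model = train_classifier(X, y, n_trees=config.n_trees,
                                 seed=config.seed, spec=spec)
        _log("train", f"trained forest: {config.n_trees} trees, "
                      f"{len(y)} samples, classes {model.samples_per_class}")
        model_path = Path(config.model) if config.model else workdir / "model.joblib"
        save_model(model, model_path)
        artifacts["model"] = str(model_path)

    # --- predict (out-of-core) -----------------------------------------
    def op(block: np.ndarray) -> np.ndarray:
        return predict_block(block, model, spec).astype(np.float32)

    prob_store = bs.map_blocks(store, op, halo=halo,
                               out_path=workdir / "store_prob", overwrite=True)
    _log("predict", f"predicted {store.meta.block_count} blocks with halo {halo}")
    artifacts["store_prob"] = str(prob_store.path)

    # --- assemble + post-process ---------------------------------------
    prob = bs.assemble_volume(prob_store).data
    original = bs.assemble_volume(store).data
    mask_t = pp.threshold_probability(prob, config.threshold)
    _log("threshold", f"t={config.threshold}: {int(mask_t.sum())} voxels kept")
    mask_r = pp.refine_by_intensity(mask_t, original, config.threshold2)
    _log("refine", f"t2={config.threshold2}: {int(mask_r.sum())} voxels kept")
    if config.denoiser == "connected_regions":
        mask_d = pp.remove_small_regions(mask_r, config.min_size,
                                         config.connectivity)
    elif config.denoiser == "open_close":
        mask_d = pp.scheme_open_close(mask_r)
    elif config.denoiser == "close_open_open2":
        mask_d = pp.scheme_close_open_open2(mask_r)
    else:
        raise ValueError(f"unknown denoiser {config.denoiser!r}")
    _log("denoise", f"{config.denoiser}: {int(mask_d.sum())} voxels kept")

    mask_path = workdir / "final_mask.tif"
    bs.write_volume(bs.Volume((mask_d * 255).astype(np.uint8),
                              config.voxel_size_um), mask_path)
    artifacts["final_mask_path"] = str(mask_path)
    artifacts["final_mask"] = mask_d
    artifacts["probability_map"] = prob

    # --- export --------------------------------------------------------
    if config.export_overlay:
        from .export import overlay_masks, write_overlay
        z = original.shape[0] // 2
        img = overlay_masks(original[z], [mask_d[z].astype(bool)],
                            [(255, 64, 64)])
        overlay_path = workdir / f"overlay_z{z:04d}.png"
        write_overlay(img, overlay_path)
        artifacts["overlay"] = str(overlay_path)
    if config.export_mesh and mask_d.any():
        from .export import mask_to_mesh, write_stl
        mesh = mask_to_mesh(mask_d, config.voxel_size_um, provenance="final_mask")
        stl_path = workdir / "final_mask.stl"
        write_stl(mesh, stl_path)
        artifacts["stl"] = str(stl_path)
        _log("mesh", f"{mesh.n_faces} triangles -> {stl_path}")

    manifest = {
        "config": config.to_dict(),
        "final_voxels": int(mask_d.sum()),
        "runtime_s": round(time.time() - t0, 2),
    }
    if truth_wall is not None:
        manifest["dice_vs_truth"] = pp.dice(mask_d, truth_wall)
        artifacts["dice"] = manifest["dice_vs_truth"]
        _log("score", f"Dice vs truth = {manifest['dice_vs_truth']:.4f}")
    (workdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, default=list))
    artifacts["manifest"] = str(workdir / "manifest.json")
    return artifacts
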