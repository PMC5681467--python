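import numpy as np
import pytest

from tubuseg.pipeline import PipelineConfig, run_pipeline
from tubuseg.synthetic import (default_phantom, make_labelset_from_truth,
                               render_phantom)
from tubuseg import write_volume


@pytest.fixture(scope="session")
def phantom():
    """The default rendered phantom with its ground truth (seed 1)."""
    spec = default_phantom(seed=1)
    volume, wall, lumen = render_phantom(spec)
    return {"spec": spec, "volume": volume, "wall": wall, "lumen": lumen}


@pytest.fixture(scope="session")
def pipeline_run(phantom, tmp_path_factory):
    """One full end-to-end run on the default phantom, shared across tests.

    Trains on 2 annotated slices, predicts the 3D volume blockwise,
    thresholds at 0.5, intensity-refines, and removes small regions.
    """
    root = tmp_path_factory.mktemp("pipeline")
    write_volume(phantom["volume"], root / "phantom.tif")
    labels = make_labelset_from_truth(phantom["wall"], phantom["lumen"],
                                      n_slices=2, seed=1)
    labels.to_table(root / "labels.txt")
    config = PipelineConfig(
        input_volume=str(root / "phantom.tif"),
        workdir=str(root / "run"),
        labels=str(root / "labels.txt"),
        block_edge=96,
        halo=32,
    )
    artifacts = run_pipeline(config, truth_wall=phantom["wall"])
    artifacts["config"] = config
    artifacts["labels"] = labels
    return artifacts
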