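"""Segment and classify the simulated scene, then score it.

Runs the two-level pipeline (coarse objects -> level-1 land-cover split ->
fine objects within forest -> subtype rules -> shrubland extraction) on the
rasters written by 01_simulate_scene.py, reports every calibrated
threshold, and scores the map against the held-out validation points.
Writes the classified map (scratch/), the run report, the confusion matrix
and the accuracy table (results/).
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from obforest.accuracy import build_confusion, simple_accuracies
from obforest.classify import PipelineConfig, run_pipeline
from obforest.grids import (DEMRaster, ZoneMask, load_samples, read_bands,
                            read_label_raster, write_label_raster)
from obforest.scheme import CODE_TO_NAME, NAME_TO_CODE

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "scene"
RESULTS = ROOT / "results"


def main() -> None:
    meta = json.loads((RESULTS / "scene_meta.json").read_text())
    dates = [tuple(d) for d in meta["dates"]]
    from obforest.grids import read_scene_stack
    stack = read_scene_stack(
        [SCRATCH / f"scene_{d}.tif" for d in range(len(dates))], dates)
    grid, elev, _ = read_bands(SCRATCH / "dem.tif")
    dem = DEMRaster(grid=grid, elevation=elev)
    zgrid, zarr, _ = read_bands(SCRATCH / "zones.tif")
    zones = ZoneMask(grid=zgrid, zones=zarr.astype(np.int32))
    samples = load_samples(SCRATCH / "samples.csv", grid=stack.grid,
                           scheme=NAME_TO_CODE)

    label_map, report = run_pipeline(stack, dem, zones, samples,
                                     PipelineConfig(seed=meta["seed"]))
    write_label_raster(SCRATCH / "classified.tif", label_map)
    (RESULTS / "run_report.json").write_text(
        json.dumps(report, indent=2, default=float))

    cm = build_confusion(label_map, samples.subset("validation"))
    rep = simple_accuracies(cm)
    named = cm.counts.copy()
    named.index = [CODE_TO_NAME[c] for c in named.index]
    named.columns = [CODE_TO_NAME[c] for c in named.columns]
    named.to_csv(RESULTS / "confusion_matrix.csv")
    acc = pd.DataFrame({
        "class": [CODE_TO_NAME[c] for c in rep.users.index],
        "users_accuracy": rep.users.round(3).to_numpy(),
        "producers_accuracy": rep.producers.round(3).to_numpy(),
    })
    acc.to_csv(RESULTS / "accuracy.csv", index=False)

    print("calibrated thresholds:")
    for name, rec in report["thresholds"].items():
        print(f"  {name}: {rec['value']:.4f}")
    print(f"\noverall accuracy: {rep.overall:.3f} "
          f"on {cm.total} held-out points")
    print(acc.to_string(index=False))


if __name__ == "__main__":
    main()
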