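"""Cross-map comparison: published area tables and a synthetic grid demo.

First reproduces the provincial area arithmetic of the three products
(totals, subtype shares, relative differences).  Then demonstrates the
spatial comparison machinery on the simulated scene: the classified map and
a degraded variant are reduced to binary forest masks, aggregated to a
1500 m percentage grid (50 x 50 blocks of 30 m pixels), differenced and
binned, mirroring how maps of different provenance are compared.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from obforest import published as pub
from obforest.compare import (aggregate_percentage, fraction_in_range,
                              percent_difference, relative_difference, remap,
                              RemapTable)
from obforest.grids import LabelRaster, read_label_raster
from obforest.scheme import FOREST_SUBTYPES, LandCover as LC

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "scene"
RESULTS = ROOT / "results"


def published_area_comparison() -> pd.DataFrame:
    areas = pub.HJ1_PROVINCIAL_AREAS
    total = float(areas.to_numpy().sum())
    rows = [{"statistic": "hj1_total_forest_km2", "value": total}]
    for name, ref in pub.TOTAL_FOREST_AREA_KM2.items():
        rows.append({"statistic": f"hj1_vs_{name.lower()}_km2", "value": total - ref})
        rows.append({"statistic": f"hj1_vs_{name.lower()}_percent",
                     "value": relative_difference(total, ref)})
    rows.append({"statistic": "dbf_share_percent",
                 "value": round(100 * areas.loc['DBF'].sum() / total)})
    rows.append({"statistic": "mcd12q1_mixed_share_percent",
                 "value": round(100 * pub.MCD12Q1_MIXED_FOREST_KM2
                                / pub.TOTAL_FOREST_AREA_KM2['MCD12Q1'])})
    return pd.DataFrame(rows)


def synthetic_grid_comparison() -> pd.DataFrame | None:
    path = SCRATCH / "classified.tif"
    if not path.exists():
        print("no classified scene found; run 02_classify_scene.py first")
        return None
    fine = read_label_raster(path)
    # forest -> 1, non-forest -> 2 (0 stays reserved for nodata)
    to_binary = RemapTable({int(c): 1 for c in FOREST_SUBTYPES}
                           | {int(c): 2 for c in (LC.WATER, LC.SETTLEMENTS,
                                                  LC.OTHER_LAND, LC.CROPLAND,
                                                  LC.GRASSLAND, LC.WETLAND)}
                           | {int(LC.FOREST): 1})
    binary = remap(fine, to_binary)
    pct = aggregate_percentage(binary, block=50)

    # a coarsened stand-in product: majority label over 10x10 blocks loses
    # small forest patches, as a 300 m product would
    lab = fine.labels
    coarse = lab.copy()
    for r in range(0, lab.shape[0], 10):
        for c in range(0, lab.shape[1], 10):
            block = lab[r:r + 10, c:c + 10]
            vals, counts = np.unique(block, return_counts=True)
            coarse[r:r + 10, c:c + 10] = vals[np.argmax(counts)]
    coarse_binary = remap(LabelRaster(fine.grid, coarse, fine.nodata), to_binary)
    pct_coarse = aggregate_percentage(coarse_binary, block=50)

    diff, hist = percent_difference(pct, pct_coarse)
    hist.to_csv(RESULTS / "percent_difference_histogram.csv", index=False)
    summary = {
        "fine_forest_percent_mean": round(float(np.nanmean(pct.percent)), 2),
        "coarse_forest_percent_mean": round(float(np.nanmean(pct_coarse.percent)), 2),
        "cells_within_10_points": round(fraction_in_range(diff, -10, 10), 3),
        "cells_fine_higher_by_30plus": round(fraction_in_range(diff, 30, 100), 3),
    }
    (RESULTS / "grid_comparison.json").write_text(json.dumps(summary, indent=2))
    print("\nsynthetic 1500 m grid comparison (fine vs majority-coarsened):")
    for k, v in summary.items():
        print(f"  {k}: {v}")
    return hist


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    table = published_area_comparison()
    table.to_csv(RESULTS / "published_area_comparison.csv", index=False)
    print(table.to_string(index=False))
    synthetic_grid_comparison()


if __name__ == "__main__":
    main()
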