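"""Published validation counts and area tables for Northeast China forest maps.

These are inputs: the printed confusion matrices (with mapped-area
proportions W_i) and provincial area tables of the 2010 HJ-1-based forest
map of Northeast China and of the GlobCover 2009 / MCD12Q1 2009 products it
was compared against.  The accuracy and comparison modules recompute the
published accuracy and area statistics from them at run time.
"""

from __future__ import annotations

import pandas as pd

from .accuracy import ConfusionMatrix

# --- binary forest / non-forest validation counts per product -------------
# rows = mapped (forest, non-forest), columns = reference (forest, non-forest)
FOREST_NONFOREST_LABELS = ["forest", "non-forest"]

BINARY_CONFUSION = {
    "HJ-1": [[1169, 142], [359, 2303]],
    "MCD12Q1": [[520, 127], [1008, 2318]],
    "GlobCover": [[555, 275], [973, 2170]],
}

#: proportion of mapped area W_i per product (forest, non-forest)
BINARY_WEIGHTS = {
    "HJ-1": {"forest": 0.40, "non-forest": 0.60},
    "MCD12Q1": {"forest": 0.34, "non-forest": 0.66},
    "GlobCover": {"forest": 0.36, "non-forest": 0.64},
}

# --- forest-subtype validation counts of the HJ-1-based map ----------------
SUBTYPE_LABELS = ["ENF", "DNF", "DBF", "MF", "SRF"]

SUBTYPE_CONFUSION = [
    [84, 5, 12, 3, 1],
    [8, 100, 10, 6, 4],
    [12, 10, 213, 10, 8],
    [5, 13, 16, 82, 6],
    [1, 5, 3, 17, 31],
]

SUBTYPE_WEIGHTS = {"ENF": 0.03, "DNF": 0.20, "DBF": 0.68, "MF": 0.07, "SRF": 0.02}

# --- provincial forest areas (km^2) ---------------------------------------
PROVINCES = ["Heilongjiang", "Jilin", "Liaoning", "Inner Mongolia"]

HJ1_PROVINCIAL_AREAS = pd.DataFrame(
    {
        "Heilongjiang": [4277, 46731, 126400, 20116, 946],
        "Jilin": [4000, 2358, 67198, 9769, 1593],
        "Liaoning": [3911, 1854, 49135, 698, 5508],
        "Inner Mongolia": [2532, 47226, 102180, 2781, 3882],
    },
    index=["ENF", "DNF", "DBF", "MF", "SRF"],
)

#: total forest area (km^2) per product / reference
TOTAL_FOREST_AREA_KM2 = {
    "MCD12Q1": 425_267.0,
    "GlobCover": 449_856.0,
    "NSF": 498_057.0,  # national statistics of forest area
}

#: MCD12Q1 subtype areas quoted for the same region (km^2)
MCD12Q1_MIXED_FOREST_KM2 = 275_720.0
MCD12Q1_DECIDUOUS_BROADLEAF_KM2 = 55_381.0


def binary_confusion(product: str) -> ConfusionMatrix:
    return ConfusionMatrix.from_counts(BINARY_CONFUSION[product],
                                       FOREST_NONFOREST_LABELS)


def subtype_confusion() -> ConfusionMatrix:
    return ConfusionMatrix.from_counts(SUBTYPE_CONFUSION, SUBTYPE_LABELS)
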