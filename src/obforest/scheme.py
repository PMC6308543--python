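"""Land-cover class scheme: IPCC-style level-1 classes plus forest subtypes."""

from __future__ import annotations

from enum import IntEnum


class LandCover(IntEnum):
    """Integer class codes used in label rasters and sample tables."""

    WATER = 1
    SETTLEMENTS = 2
    OTHER_LAND = 3
    CROPLAND = 4
    GRASSLAND = 5
    WETLAND = 6
    FOREST = 10  # aggregate forest / level-1 forest candidate
    EVERGREEN_NEEDLELEAF = 11
    EVERGREEN_BROADLEAF = 12
    DECIDUOUS_NEEDLELEAF = 13
    DECIDUOUS_BROADLEAF = 14
    MIXED_FOREST = 15
    SHRUBLAND = 16


LEVEL1_CLASSES = (
    LandCover.WATER,
    LandCover.SETTLEMENTS,
    LandCover.OTHER_LAND,
    LandCover.CROPLAND,
    LandCover.GRASSLAND,
    LandCover.WETLAND,
    LandCover.FOREST,
)

FOREST_SUBTYPES = (
    LandCover.EVERGREEN_NEEDLELEAF,
    LandCover.EVERGREEN_BROADLEAF,
    LandCover.DECIDUOUS_NEEDLELEAF,
    LandCover.DECIDUOUS_BROADLEAF,
    LandCover.MIXED_FOREST,
    LandCover.SHRUBLAND,
)

NON_FOREST_VEGETATION = (
    LandCover.CROPLAND,
    LandCover.GRASSLAND,
    LandCover.WETLAND,
)

NON_VEGETATION = (LandCover.SETTLEMENTS, LandCover.OTHER_LAND)

#: name <-> code maps for sample CSVs and reports
NAME_TO_CODE = {c.name.lower(): int(c) for c in LandCover}
CODE_TO_NAME = {int(c): c.name.lower() for c in LandCover}

#: short field codes used in tables
SHORT = {
    LandCover.EVERGREEN_NEEDLELEAF: "ENF",
    LandCover.EVERGREEN_BROADLEAF: "EBF",
    LandCover.DECIDUOUS_NEEDLELEAF: "DNF",
    LandCover.DECIDUOUS_BROADLEAF: "DBF",
    LandCover.MIXED_FOREST: "MF",
    LandCover.SHRUBLAND: "SRF",
}


def is_forest(code: int) -> bool:
    return code == LandCover.FOREST or code in {int(c) for c in FOREST_SUBTYPES}
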