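"""Multiresolution region-merging segmentation.

Bottom-up merging from single-pixel objects under a combined spectral
("color") and shape heterogeneity criterion.  A merge of adjacent objects a
and b increases heterogeneity by

    cost = w_color * dh_color + (1 - w_color) * dh_shape
    dh_color = sum_k w_k * (n_ab s_ab - n_a s_a - n_b s_b)      (s = band std)
    dh_shape = w_compact * dh_cmp + (1 - w_compact) * dh_smooth
    h_cmp = l / sqrt(n)   h_smooth = l / b                      (l = perimeter,
                                                                 b = bbox perimeter)

with each dh_* computed as n_ab h_ab - n_a h_a - n_b h_b.  Merging proceeds
by local mutual best fitting: from a seed object the chain of best
neighbours is followed until two objects are each other's best partner, and
that pair is merged iff cost < scale**2.  The scan order of seeds is a
seeded permutation, and equal-cost candidates resolve to the lowest object
id, so runs are reproducible.

Objects are tracked with incremental accumulators (pixel count, per-band sum
and sum of squares, exposed-edge perimeter, bounding box) and a region
adjacency graph whose edges carry shared boundary length, so each merge is
O(degree).  Adjacency is 4-connected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt

import numpy as np

from .grids import GeoGrid

BACKGROUND = -1  # label of pixels outside the segmentation mask


class AdjacencyError(ValueError):
    """Operation requires two adjacent objects."""


@dataclass(frozen=True)
class SegParams:
    """Scale threshold and criterion weights for one segmentation level."""

    scale: float
    w_shape: float = 0.3
    w_compact: float = 0.6
    band_weights: tuple[float, ...] | None = None  # None -> 1.0 per band

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        for w in (self.w_shape, self.w_compact):
            if not 0.0 <= w <= 1.0:
                raise ValueError("weights must lie in [0, 1]")

    @property
    def w_color(self) -> float:
        return 1.0 - self.w_shape

    @property
    def w_smooth(self) -> float:
        return 1.0 - self.w_compact


#: Defaults for the two segmentation levels: a coarse level separating
#: forest from non-forest and a fine level for forest subtypes.
LEVEL1_PARAMS = SegParams(scale=30.0, w_shape=0.3, w_compact=0.6)
LEVEL2_PARAMS = SegParams(scale=10.0, w_shape=0.1, w_compact=0.6)


@dataclass
class SegmentMap:
    """Labelled partition of the grid plus per-object accumulators.

    ``labels`` holds the object id of every segmented pixel and
    ``BACKGROUND`` elsewhere.  ``stats`` maps object id to a dict with keys
    n, sum (per band), sumsq (per band), perimeter, bbox; ``adjacency`` maps
    object id to {neighbour id: shared boundary length}.
    """

    grid: GeoGrid
    labels: np.ndarray
    stats: dict[int, dict]
    adjacency: dict[int, dict[int, int]]
    merge_log: list[tuple[int, int, float]] = field(default_factory=list)

    def object_ids(self) -> list[int]:
        return sorted(self.stats)

    @property
    def n_objects(self) -> int:
        return len(self.stats)

    def check_consistency(self, planes: np.ndarray) -> None:
        """Recompute accumulators from the label raster; raise on mismatch."""
        planes = np.atleast_3d(planes) if planes.ndim == 2 else planes
        for oid, st in self.stats.items():
            sel = self.labels == oid
            n = int(sel.sum())
            if n != st["n"]:
                raise AssertionError(f"object {oid}: pixel count {n} != {st['n']}")
            for k in range(planes.shape[0]):
                s = float(planes[k][sel].sum())
                if abs(s - st["sum"][k]) > 1e-6 * max(1.0, abs(s)):
                    raise AssertionError(f"object {oid}: band {k} sum mismatch")
            if abs(_perimeter_of(sel) - st["perimeter"]) > 0:
                raise AssertionError(f"object {oid}: perimeter mismatch")


def _perimeter_of(sel: np.ndarray) -> int:
    p = 0
    padded = np.pad(sel, 1)
    for ax, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        p += int((sel & ~np.roll(padded, shift, axis=ax)[1:-1, 1:-1]).sum())
    return p


class _Merger:
    """Mutable region-merging state over flattened pixel indices."""

    def __init__(self, planes: np.ndarray, mask: np.ndarray, params: SegParams,
                 seed: int):
        self.params = params
        k, rows, cols = planes.shape
        self.k = k
        self.rows, self.cols = rows, cols
        wb = params.band_weights or tuple(1.0 for _ in range(k))
        if len(wb) != k:
            raise ValueError("band_weights length must match number of planes")
        self.wb = [float(w) for w in wb]

        idx = np.flatnonzero(mask.ravel())
        self.initial_ids = idx
        N = rows * cols
        self.active = np.zeros(N, dtype=bool)
        self.active[idx] = True
        self.parent = np.arange(N, dtype=np.int64)

        flat = planes.reshape(k, N)
        self.n = [0] * N
        self.bsum = [[0.0] * N for _ in range(k)]
        self.bsq = [[0.0] * N for _ in range(k)]
        self.sd = [[0.0] * N for _ in range(k)]
        self.perim = [0] * N
        self.r0 = [0] * N
        self.r1 = [0] * N
        self.c0 = [0] * N
        self.c1 = [0] * N
        self.nbrs: list[dict[int, int] | None] = [None] * N
        m = mask
        for i in idx:
            r, c = divmod(int(i), cols)
            self.n[i] = 1
            for b in range(k):
                v = float(flat[b, i])
                self.bsum[b][i] = v
                self.bsq[b][i] = v * v
            self.perim[i] = 4
            self.r0[i] = self.r1[i] = r
            self.c0[i] = self.c1[i] = c
            nb: dict[int, int] = {}
            if r > 0 and m[r - 1, c]:
                nb[i - cols] = 1
            if r < rows - 1 and m[r + 1, c]:
                nb[i + cols] = 1
            if c > 0 and m[r, c - 1]:
                nb[i - 1] = 1
            if c < cols - 1 and m[r, c + 1]:
                nb[i + 1] = 1
            self.nbrs[i] = nb

        rng = np.random.default_rng(seed)
        self.order = idx[rng.permutation(len(idx))]
        self.merge_log: list[tuple[int, int, float]] = []

    # -- criterion ---------------------------------------------------------

    def cost(self, a: int, b: int) -> float:
        p = self.params
        na, nb_ = self.n[a], self.n[b]
        nab = na + nb_
        color = 0.0
        for k in range(self.k):
            s = self.bsum[k][a] + self.bsum[k][b]
            ss = self.bsq[k][a] + self.bsq[k][b]
            mean = s / nab
            var = ss / nab - mean * mean
            sdab = sqrt(var) if var > 0.0 else 0.0
            color += self.wb[k] * (nab * sdab - na * self.sd[k][a] - nb_ * self.sd[k][b])
        if p.w_shape == 0.0:
            return p.w_color * color
        shared = self.nbrs[a].get(b)  # type: ignore[union-attr]
        if shared is None:
            raise AdjacencyError(f"objects {a} and {b} are not adjacent")
        la, lb = self.perim[a], self.perim[b]
        lab = la + lb - 2 * shared
        d_cmp = lab * sqrt(nab) - la * sqrt(na) - lb * sqrt(nb_)
        rr0 = min(self.r0[a], self.r0[b]); rr1 = max(self.r1[a], self.r1[b])
        cc0 = min(self.c0[a], self.c0[b]); cc1 = max(self.c1[a], self.c1[b])
        bb_ab = 2 * ((rr1 - rr0 + 1) + (cc1 - cc0 + 1))
        bb_a = 2 * ((self.r1[a] - self.r0[a] + 1) + (self.c1[a] - self.c0[a] + 1))
        bb_b = 2 * ((self.r1[b] - self.r0[b] + 1) + (self.c1[b] - self.c0[b] + 1))
        d_sm = nab * lab / bb_ab - na * la / bb_a - nb_ * lb / bb_b
        shape = p.w_compact * d_cmp + p.w_smooth * d_sm
        return p.w_color * color + p.w_shape * shape

    def best_neighbor(self, a: int) -> tuple[int, float]:
        best = -1
        bc = float("inf")
        for t in self.nbrs[a]:  # type: ignore[union-attr]
            c = self.cost(a, t)
            if c < bc or (c == bc and t < best):
                bc = c
                best = t
        return best, bc

    def merge(self, a: int, b: int, cost: float) -> int:
        """Merge b into a (a < b); returns the surviving id."""
        if b < a:
            a, b = b, a
        shared = self.nbrs[a].pop(b)  # type: ignore[union-attr]
        self.nbrs[b].pop(a)  # type: ignore[union-attr]
        na, nb_ = self.n[a], self.n[b]
        nab = na + nb_
        self.n[a] = nab
        for k in range(self.k):
            s = self.bsum[k][a] + self.bsum[k][b]
            ss = self.bsq[k][a] + self.bsq[k][b]
            self.bsum[k][a] = s
            self.bsq[k][a] = ss
            mean = s / nab
            var = ss / nab - mean * mean
            self.sd[k][a] = sqrt(var) if var > 0.0 else 0.0
        self.perim[a] = self.perim[a] + self.perim[b] - 2 * shared
        self.r0[a] = min(self.r0[a], self.r0[b])
        self.r1[a] = max(self.r1[a], self.r1[b])
        self.c0[a] = min(self.c0[a], self.c0[b])
        self.c1[a] = max(self.c1[a], self.c1[b])
        for t, sh in self.nbrs[b].items():  # type: ignore[union-attr]
            nt = self.nbrs[t]
            nt.pop(b)  # type: ignore[union-attr]
            na_t = self.nbrs[a]
            na_t[t] = na_t.get(t, 0) + sh  # type: ignore[index]
            nt[a] = na_t[t]  # type: ignore[index]
        self.nbrs[b] = None
        self.active[b] = False
        self.parent[b] = a
        self.merge_log.append((a, b, cost))
        return a

    def run(self) -> None:
        threshold = self.params.scale * self.params.scale
        active = self.active
        while True:
            merged_any = False
            for seed_id in self.order:
                cur = int(seed_id)
                if not active[cur]:
                    continue
                visited: set[int] = set()
                while True:
                    if not self.nbrs[cur]:
                        break
                    best, bc = self.best_neighbor(cur)
                    if bc >= threshold:
                        break
                    bb, _ = self.best_neighbor(best)
                    if bb == cur:
                        cur = self.merge(cur, best, bc)
                        merged_any = True
                        visited.clear()
                    else:
                        if best in visited:
                            break  # equal-cost cycle; leave for next pass
                        visited.add(cur)
                        cur = best
            if not merged_any:
                break

    def resolve_labels(self) -> np.ndarray:
        labels = np.full(self.rows * self.cols, BACKGROUND, dtype=np.int64)
        parent = self.parent
        for i in self.initial_ids:
            root = int(i)
            while parent[root] != root:
                root = int(parent[root])
            # path compression
            j = int(i)
            while parent[j] != root:
                parent[j], j = root, int(parent[j])
            labels[i] = root
        return labels.reshape(self.rows, self.cols)


def merge_cost(segments: SegmentMap, a: int, b: int, params: SegParams,
               planes: np.ndarray | None = None) -> float:
    """Heterogeneity increase of merging two adjacent objects of a SegmentMap."""
    if b not in segments.adjacency.get(a, {}):
        raise AdjacencyError(f"objects {a} and {b} are not adjacent")
    sa, sb = segments.stats[a], segments.stats[b]
    k = len(sa["sum"])
    wb = params.band_weights or tuple(1.0 for _ in range(k))
    na, nb_ = sa["n"], sb["n"]
    nab = na + nb_
    color = 0.0
    for i in range(k):
        s = sa["sum"][i] + sb["sum"][i]
        ss = sa["sumsq"][i] + sb["sumsq"][i]
        mean = s / nab
        var = ss / nab - mean * mean
        sdab = sqrt(var) if var > 0.0 else 0.0
        color += wb[i] * (nab * sdab - na * sa["sd"][i] - nb_ * sb["sd"][i])
    shared = segments.adjacency[a][b]
    la, lb = sa["perimeter"], sb["perimeter"]
    lab = la + lb - 2 * shared
    d_cmp = lab * sqrt(nab) - la * sqrt(na) - lb * sqrt(nb_)
    (ar0, ar1, ac0, ac1), (br0, br1, bc0, bc1) = sa["bbox"], sb["bbox"]
    bb_ab = 2 * ((max(ar1, br1) - min(ar0, br0) + 1) + (max(ac1, bc1) - min(ac0, bc0) + 1))
    bb_a = 2 * ((ar1 - ar0 + 1) + (ac1 - ac0 + 1))
    bb_b = 2 * ((br1 - br0 + 1) + (bc1 - bc0 + 1))
    d_sm = nab * lab / bb_ab - na * la / bb_a - nb_ * lb / bb_b
    shape = params.w_compact * d_cmp + params.w_smooth * d_sm
    return params.w_color * color + params.w_shape * shape


def _as_planes(planes) -> np.ndarray:
    arr = np.asarray(planes, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError("planes must be one or more 2-D rasters")
    return arr


def segment(planes, params: SegParams, seed: int = 0,
            grid: GeoGrid | None = None,
            mask: np.ndarray | None = None) -> SegmentMap:
    """Segment one or more co-registered raster planes.

    ``mask`` restricts segmentation to True pixels (used for the fine,
    within-forest level); everything else gets the ``BACKGROUND`` label.
    """
    arr = _as_planes(planes)
    k, rows, cols = arr.shape
    if rows * cols == 0:
        raise ValueError("empty raster")
    if mask is None:
        mask = np.ones((rows, cols), dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (rows, cols):
            raise ValueError("mask shape must match planes")
        if not mask.any():
            raise ValueError("segmentation mask is empty")
    if grid is None:
        grid = GeoGrid(rows, cols)

    merger = _Merger(arr, mask, params, seed)
    merger.run()
    labels = merger.resolve_labels()

    stats: dict[int, dict] = {}
    adjacency: dict[int, dict[int, int]] = {}
    for i in np.flatnonzero(merger.active):
        i = int(i)
        stats[i] = {
            "n": merger.n[i],
            "sum": [merger.bsum[b][i] for b in range(k)],
            "sumsq": [merger.bsq[b][i] for b in range(k)],
            "sd": [merger.sd[b][i] for b in range(k)],
            "perimeter": merger.perim[i],
            "bbox": (merger.r0[i], merger.r1[i], merger.c0[i], merger.c1[i]),
        }
        adjacency[i] = dict(merger.nbrs[i])  # type: ignore[arg-type]
    return SegmentMap(grid=grid, labels=labels, stats=stats,
                      adjacency=adjacency, merge_log=merger.merge_log)


def segment_within_mask(planes, mask: np.ndarray,
                        params: SegParams = LEVEL2_PARAMS,
                        seed: int = 0, grid: GeoGrid | None = None) -> SegmentMap:
    """Fine-level segmentation restricted to a candidate mask."""
    return segment(planes, params, seed=seed, grid=grid, mask=mask)
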