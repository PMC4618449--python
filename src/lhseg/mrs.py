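"""Per-slice multi-resolution segmentation by iterative pairwise region
merging (the Baatz-Schäpe scheme).

Every pixel starts as its own segment.  Adjacent segments merge while the
*fusion cost* -- the increase in weighted color + shape heterogeneity the
merge would cause -- stays below the square of the scale parameter
``alpha``.  Larger ``alpha`` admits costlier merges and yields fewer,
larger segments; the limit ``alpha -> inf`` collapses any image to one
segment.

Heterogeneity terms
-------------------
color
    ``sum_k w_k * [n_m * sigma_k(m) - (n_a * sigma_k(a) + n_b * sigma_k(b))]``
    where ``sigma_k`` is the population standard deviation of channel
    ``k`` over a segment's pixels and ``n`` its area.
shape
    a mix of compactness deviation ``l / sqrt(n)`` and smoothness
    deviation ``l / b`` (``l`` = perimeter in pixel edges, ``b`` =
    bounding-box perimeter), each area-weighted in the same
    ``n_m * h_m - (n_a * h_a + n_b * h_b)`` form and blended by
    ``compactness_weight``.

The total cost is ``(1 - shape_weight) * color + shape_weight * shape``.

Merge scheduling is *mutual best fitting*: in each pass, surviving
segments are visited in a seeded random permutation of their ascending
ids; a segment merges with its cheapest admissible neighbor only if it is
in turn that neighbor's cheapest neighbor (ties broken toward the lowest
neighbor id).  Passes repeat until no merge fires.  The procedure is a
deterministic function of (image, params).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["MrsParams", "Segment", "SegmentGraph", "fusion_cost", "segment_slice"]


@dataclass(frozen=True)
class MrsParams:
    """Parameters of the region-merging segmentation.

    scale
        The scale parameter alpha (> 0); a merge is admissible iff its
        fusion cost is below ``alpha**2``.
    shape_weight
        Weight of the shape term in [0, 1]; the color term gets
        ``1 - shape_weight``.
    compactness_weight
        Mix between compactness and smoothness inside the shape term.
    channel_weights
        Per-channel weights ``w_k`` of the color term.
    seed
        Seed of the per-pass scan permutation.
    """

    scale: float
    shape_weight: float = 0.1
    compactness_weight: float = 0.5
    channel_weights: tuple[float, ...] = (1.0,)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if not 0.0 <= self.shape_weight <= 1.0:
            raise ValueError("shape_weight must be in [0, 1]")
        if not 0.0 <= self.compactness_weight <= 1.0:
            raise ValueError("compactness_weight must be in [0, 1]")


@dataclass
class Segment:
    """One region of a slice partition.

    ``mean_intensity`` is per channel; ``perimeter`` counts exposed pixel
    edges (image borders included); ``bbox`` is inclusive
    ``(ymin, xmin, ymax, xmax)``.
    """

    id: int
    pixel_set: frozenset[tuple[int, int]]
    mean_intensity: tuple[float, ...]
    area: int
    perimeter: int
    bbox: tuple[int, int, int, int]
    # channel sums and sums of squares; carried so fusion_cost can be
    # evaluated without re-touching pixels
    sums: tuple[float, ...] = field(default=(), repr=False)
    sumsqs: tuple[float, ...] = field(default=(), repr=False)


@dataclass
class SegmentGraph:
    """Region-adjacency graph of one slice's partition.

    ``adjacency[i][j]`` is the shared-border length (pixel edges) between
    segments ``i`` and ``j``; it is symmetric and has no self entries.
    ``labels`` maps every pixel to its segment id (a complete partition).
    """

    slice_index: int
    segments: dict[int, Segment]
    adjacency: dict[int, dict[int, int]]
    labels: np.ndarray

    def neighbors(self, seg_id: int) -> dict[int, int]:
        return self.adjacency[seg_id]


def _shared_border(a: Segment, b: Segment) -> int:
    small, big = (a, b) if a.area <= b.area else (b, a)
    bigset = big.pixel_set
    border = 0
    for y, x in small.pixel_set:
        for ny, nx in ((y + 1, x), (y - 1, x), (y, x + 1), (y, x - 1)):
            if (ny, nx) in bigset:
                border += 1
    return border


def _cost_from_stats(
    na: int,
    sa: tuple[float, ...],
    qa: tuple[float, ...],
    pa: int,
    ba: tuple[int, int, int, int],
    nb: int,
    sb: tuple[float, ...],
    qb: tuple[float, ...],
    pb: int,
    bb: tuple[int, int, int, int],
    border: int,
    params: MrsParams,
) -> float:
    nm = na + nb
    color = 0.0
    for k, wk in enumerate(params.channel_weights):
        sm, qm = sa[k] + sb[k], qa[k] + qb[k]
        vm = qm / nm - (sm / nm) ** 2
        va = qa[k] / na - (sa[k] / na) ** 2
        vb = qb[k] / nb - (sb[k] / nb) ** 2
        color += wk * (
            nm * math.sqrt(vm if vm > 0 else 0.0)
            - na * math.sqrt(va if va > 0 else 0.0)
            - nb * math.sqrt(vb if vb > 0 else 0.0)
        )
    sw = params.shape_weight
    if sw == 0.0:
        return (1.0 - sw) * color
    pm = pa + pb - 2 * border
    y0 = min(ba[0], bb[0])
    x0 = min(ba[1], bb[1])
    y1 = max(ba[2], bb[2])
    x1 = max(ba[3], bb[3])
    bper_m = 2 * ((y1 - y0 + 1) + (x1 - x0 + 1))
    bper_a = 2 * ((ba[2] - ba[0] + 1) + (ba[3] - ba[1] + 1))
    bper_b = 2 * ((bb[2] - bb[0] + 1) + (bb[3] - bb[1] + 1))
    cmpct = (
        nm * pm / math.sqrt(nm) - na * pa / math.sqrt(na) - nb * pb / math.sqrt(nb)
    )
    smooth = nm * pm / bper_m - na * pa / bper_a - nb * pb / bper_b
    cw = params.compactness_weight
    shape = cw * cmpct + (1.0 - cw) * smooth
    return (1.0 - sw) * color + sw * shape


def fusion_cost(
    a: Segment, b: Segment, params: MrsParams, border: int | None = None
) -> float:
    """Heterogeneity increase caused by merging two adjacent segments.

    Symmetric in its arguments and >= 0 up to floating-point round-off.
    Raises ``ValueError`` for a non-adjacent pair.
    """
    if border is None:
        border = _shared_border(a, b)
    if border == 0:
        raise ValueError(f"segments {a.id} and {b.id} are not adjacent")
    if len(a.sums) != len(params.channel_weights):
        raise ValueError("segment channel count does not match channel_weights")
    return _cost_from_stats(
        a.area, a.sums, a.sumsqs, a.perimeter, a.bbox,
        b.area, b.sums, b.sumsqs, b.perimeter, b.bbox,
        border, params,
    )


def segment_slice(
    slice_image: np.ndarray, params: MrsParams, slice_index: int = 0
) -> SegmentGraph:
    """Partition one 2D slice into homogeneous segments.

    ``slice_image`` is ``(y, x)`` or ``(k, y, x)`` for multi-channel
    input; ``params.channel_weights`` must match the channel count.
    Returns a :class:`SegmentGraph` whose segments cover the slice
    disjointly, with final ids assigned in raster order of each segment's
    first pixel.
    """
    img = np.asarray(slice_image, dtype=np.float64)
    if img.ndim == 2:
        img = img[None]
    if img.ndim != 3 or img.shape[1] == 0 or img.shape[2] == 0:
        raise ValueError("slice_image must be a non-empty 2D or (k, y, x) array")
    nk, h, w = img.shape
    if nk != len(params.channel_weights):
        raise ValueError(
            f"{nk} channels but {len(params.channel_weights)} channel weights"
        )
    npx = h * w
    flat = img.reshape(nk, npx)

    # per-segment incremental state, indexed by segment id (init: flat pixel id)
    alive = bytearray([1]) * npx
    n = [1] * npx
    s = [list(flat[:, i]) for i in range(npx)]
    q = [[v * v for v in s[i]] for i in range(npx)]
    per = [4] * npx
    ymin = [i // w for i in range(npx)]
    ymax = list(ymin)
    xmin = [i % w for i in range(npx)]
    xmax = list(xmin)
    px = [[i] for i in range(npx)]
    nbr: list[dict[int, int]] = [dict() for _ in range(npx)]
    for i in range(npx):
        y, x = divmod(i, w)
        d = nbr[i]
        if x + 1 < w:
            d[i + 1] = 1
        if x > 0:
            d[i - 1] = 1
        if y + 1 < h:
            d[i + w] = 1
        if y > 0:
            d[i - w] = 1

    scale2 = params.scale * params.scale
    cw = params.channel_weights
    shape_w = params.shape_weight
    cmpct_w = params.compactness_weight

    def cost(a: int, b: int, border: int) -> float:
        na, nb_ = n[a], n[b]
        nm = na + nb_
        color = 0.0
        sa, sb = s[a], s[b]
        qa, qb = q[a], q[b]
        for k in range(nk):
            sm = sa[k] + sb[k]
            qm = qa[k] + qb[k]
            vm = qm / nm - (sm / nm) ** 2
            va = qa[k] / na - (sa[k] / na) ** 2
            vb = qb[k] / nb_ - (sb[k] / nb_) ** 2
            color += cw[k] * (
                nm * math.sqrt(vm if vm > 0 else 0.0)
                - na * math.sqrt(va if va > 0 else 0.0)
                - nb_ * math.sqrt(vb if vb > 0 else 0.0)
            )
        if shape_w == 0.0:
            return color
        pm = per[a] + per[b] - 2 * border
        y0 = ymin[a] if ymin[a] < ymin[b] else ymin[b]
        x0 = xmin[a] if xmin[a] < xmin[b] else xmin[b]
        y1 = ymax[a] if ymax[a] > ymax[b] else ymax[b]
        x1 = xmax[a] if xmax[a] > xmax[b] else xmax[b]
        bper_m = 2 * ((y1 - y0 + 1) + (x1 - x0 + 1))
        bper_a = 2 * ((ymax[a] - ymin[a] + 1) + (xmax[a] - xmin[a] + 1))
        bper_b = 2 * ((ymax[b] - ymin[b] + 1) + (xmax[b] - xmin[b] + 1))
        cmpct = (
            nm * pm / math.sqrt(nm)
            - na * per[a] / math.sqrt(na)
            - nb_ * per[b] / math.sqrt(nb_)
        )
        smooth = nm * pm / bper_m - na * per[a] / bper_a - nb_ * per[b] / bper_b
        shape = cmpct_w * cmpct + (1.0 - cmpct_w) * smooth
        return (1.0 - shape_w) * color + shape_w * shape

    def best(v: int) -> tuple[int, float]:
        bu, bc = -1, math.inf
        for u, border in nbr[v].items():
            c = cost(v, u, border)
            if c < bc or (c == bc and u < bu):
                bu, bc = u, c
        return bu, bc

    def merge(a: int, b: int) -> None:
        """Merge b into a (a < b assumed by caller)."""
        border = nbr[a][b]
        nm = n[a] + n[b]
        for k in range(nk):
            s[a][k] += s[b][k]
            q[a][k] += q[b][k]
        per[a] = per[a] + per[b] - 2 * border
        if ymin[b] < ymin[a]:
            ymin[a] = ymin[b]
        if xmin[b] < xmin[a]:
            xmin[a] = xmin[b]
        if ymax[b] > ymax[a]:
            ymax[a] = ymax[b]
        if xmax[b] > xmax[a]:
            xmax[a] = xmax[b]
        n[a] = nm
        # small-to-large pixel list union
        if len(px[a]) < len(px[b]):
            px[a], px[b] = px[b], px[a]
        px[a].extend(px[b])
        px[b] = []
        del nbr[a][b]
        del nbr[b][a]
        for u, bl in nbr[b].items():
            nbr[a][u] = nbr[a].get(u, 0) + bl
            d = nbr[u]
            del d[b]
            d[a] = nbr[a][u]
        nbr[b] = {}
        alive[b] = 0

    rng = np.random.default_rng(params.seed)
    while True:
        ids = [i for i in range(npx) if alive[i]]
        order = rng.permutation(len(ids))
        merged_any = False
        for oi in order:
            v = ids[oi]
            if not alive[v]:
                continue
            u, cu = best(v)
            if u < 0 or cu >= scale2:
                continue
            v2, _ = best(u)
            if v2 == v:
                a, b = (v, u) if v < u else (u, v)
                merge(a, b)
                merged_any = True
        if not merged_any:
            break

    # final relabeling in raster order of each segment's first pixel
    survivors = [i for i in range(npx) if alive[i]]
    survivors.sort(key=lambda i: min(px[i]))
    segments: dict[int, Segment] = {}
    old_to_new = {}
    labels = np.empty((h, w), dtype=np.int32)
    for new_id, old in enumerate(survivors):
        old_to_new[old] = new_id
        coords = frozenset((i // w, i % w) for i in px[old])
        for i in px[old]:
            labels[i // w, i % w] = new_id
        segments[new_id] = Segment(
            id=new_id,
            pixel_set=coords,
            mean_intensity=tuple(s[old][k] / n[old] for k in range(nk)),
            area=n[old],
            perimeter=per[old],
            bbox=(ymin[old], xmin[old], ymax[old], xmax[old]),
            sums=tuple(s[old]),
            sumsqs=tuple(q[old]),
        )
    adjacency: dict[int, dict[int, int]] = {i: {} for i in range(len(survivors))}
    for old in survivors:
        a = old_to_new[old]
        for u, bl in nbr[old].items():
            adjacency[a][old_to_new[u]] = bl
    return SegmentGraph(
        slice_index=slice_index,
        segments=segments,
        adjacency=adjacency,
        labels=labels,
    )
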