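"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity from first principles (naive data
structures, no incremental bookkeeping, no spatial indexes) so the
optimized implementations can be checked against it.
"""

from __future__ import annotations

import math

import numpy as np


def mrs_brute_force(image: np.ndarray, params) -> set[frozenset]:
    """Mutual-best-fitting region merging with all statistics recomputed
    from pixel sets at every evaluation.

    Shares only the algorithm definition (cost formula, scan rule, seed)
    with the production code; every number is derived fresh from the
    raw pixel sets.  Returns the final partition as a set of frozensets
    of flat pixel indices.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        img = img[None]
    nk, h, w = img.shape
    flat = img.reshape(nk, h * w)
    segs: dict[int, set[int]] = {i: {i} for i in range(h * w)}

    def shared_border(a: set[int], b: set[int]) -> int:
        count = 0
        for p in a:
            y, x = divmod(p, w)
            for q in (
                p + 1 if x + 1 < w else -1,
                p - 1 if x > 0 else -1,
                p + w if y + 1 < h else -1,
                p - w if y > 0 else -1,
            ):
                if q in b:
                    count += 1
        return count

    def perimeter(a: set[int]) -> int:
        total = 0
        for p in a:
            y, x = divmod(p, w)
            for ny, nx in ((y, x + 1), (y, x - 1), (y + 1, x), (y - 1, x)):
                if not (0 <= ny < h and 0 <= nx < w) or ny * w + nx not in a:
                    total += 1
        return total

    def cost(a: set[int], b: set[int], border: int) -> float:
        na, nb = len(a), len(b)
        nm = na + nb

        def pop_sd(s, q, n):
            v = q / n - (s / n) ** 2
            return math.sqrt(v) if v > 0 else 0.0

        ai, bi = sorted(a), sorted(b)
        color = 0.0
        for k, wk in enumerate(params.channel_weights):
            va = flat[k, ai]
            vb = flat[k, bi]
            sa, qa = float(va.sum()), float((va**2).sum())
            sb, qb = float(vb.sum()), float((vb**2).sum())
            color += wk * (
                nm * pop_sd(sa + sb, qa + qb, nm)
                - na * pop_sd(sa, qa, na)
                - nb * pop_sd(sb, qb, nb)
            )
        if params.shape_weight == 0.0:
            return color
        pa, pb = perimeter(a), perimeter(b)
        pm = pa + pb - 2 * border

        def bbox_perim(s):
            ys = [p // w for p in s]
            xs = [p % w for p in s]
            return 2 * ((max(ys) - min(ys) + 1) + (max(xs) - min(xs) + 1))

        cmpct = (
            nm * pm / math.sqrt(nm)
            - na * pa / math.sqrt(na)
            - nb * pb / math.sqrt(nb)
        )
        smooth = (
            nm * pm / bbox_perim(a | b)
            - na * pa / bbox_perim(a)
            - nb * pb / bbox_perim(b)
        )
        shape = params.compactness_weight * cmpct + (
            1 - params.compactness_weight
        ) * smooth
        return (1 - params.shape_weight) * color + params.shape_weight * shape

    def best(v: int) -> tuple[int, float]:
        bu, bc = -1, math.inf
        for u in segs:
            if u == v:
                continue
            border = shared_border(segs[v], segs[u])
            if border == 0:
                continue
            c = cost(segs[v], segs[u], border)
            if c < bc or (c == bc and u < bu):
                bu, bc = u, c
        return bu, bc

    scale2 = params.scale**2
    rng = np.random.default_rng(params.seed)
    while True:
        ids = sorted(segs)
        order = rng.permutation(len(ids))
        merged_any = False
        for oi in order:
            v = ids[oi]
            if v not in segs:
                continue
            u, cu = best(v)
            if u < 0 or cu >= scale2:
                continue
            v2, _ = best(u)
            if v2 == v:
                a, b = (v, u) if v < u else (u, v)
                segs[a] = segs[a] | segs[b]
                del segs[b]
                merged_any = True
        if not merged_any:
            break
    return {frozenset(s) for s in segs.values()}


def min_surface_distance_brute(
    pts_a: np.ndarray, pts_b: np.ndarray, sd: float
) -> float:
    """Exhaustive all-pairs anisotropic minimum distance between two
    (x, y, z) point sets."""
    best = math.inf
    for x1, y1, z1 in pts_a:
        for x2, y2, z2 in pts_b:
            d = math.sqrt(
                (x1 - x2) ** 2 + (y1 - y2) ** 2 + ((z1 - z2) * sd) ** 2
            )
            if d < best:
                best = d
    return best


def random_blob_volume(rng, shape, n_blobs=2) -> np.ndarray:
    """Label volume of a few random solid ellipsoids (possibly clipped)."""
    labels = np.zeros(shape, dtype=np.int32)
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    for i in range(1, n_blobs + 1):
        cz, cy, cx = (rng.uniform(0, s - 1) for s in shape)
        rz = rng.uniform(1, max(2.0, shape[0] / 3))
        ry = rng.uniform(1.5, shape[1] / 3)
        rx = rng.uniform(1.5, shape[2] / 3)
        mask = (
            ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
        ) <= 1.0
        labels[mask & (labels == 0)] = i
    return labels
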