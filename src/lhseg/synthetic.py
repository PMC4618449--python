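"""Ground-truthed synthetic 3D stacks emulating intravital bone-marrow
imaging.

A scene has three channels on an anisotropic voxel grid:

* a dye channel with bright roundish cells (some bearing a short uropod
  protrusion), irregular debris/aggregates whose protrusions exceed the
  object's own diameter, and background autofluorescence;
* an osteoblast channel with clusters of polygonal patches in three
  intensity tiers (bright / medium / dim), mimicking reporter-intensity
  heterogeneity within a cluster;
* a bone channel with a collagen slab containing ellipsoidal cavities.

Objects are rendered with sub-voxel partial-volume intensities: a voxel
straddling an object boundary carries the fraction of its volume inside
the object, so the 50% isophote coincides with the continuous object
surface, as in real sampled fluorescence.  The truth mask of an object
is the set of voxels whose *centers* lie inside the surface.  Signal
decays exponentially with imaging depth, Gaussian read noise (optionally
Poisson shot noise) is added last, and the image is clipped to the 8-bit
range.

Every scene is a deterministic function of its spec (same spec + seed =>
bit-identical stack and truth), and ships with per-channel truth label
masks plus a truth table holding each object's class, centroid, and
brute-force surface distances from each cell to the nearest osteoblast
and bone.

What this generator does *not* emulate: optical point-spread blurring,
scattering artifacts, cell doublets, and motion — real stacks are harder
than these scenes, so pipeline scores here bound, rather than estimate,
performance on real data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.draw import polygon as draw_polygon

from .stack import ChannelRole, VolumeStack, VoxelSpacing

__all__ = [
    "SceneSpec",
    "SceneTruth",
    "generate_scene",
    "generate_benchmark_suite",
    "render_single_object",
    "generate_object_set",
    "brute_force_surface_distance_um",
]

CLASS_HSC1 = "HSC1"
CLASS_HSC2 = "HSC2"
CLASS_FALSE = "FALSE"

_DEFAULT_SPACING = VoxelSpacing(dx=0.8, dy=0.8, sd=2.0)


@dataclass(frozen=True)
class SceneSpec:
    """Recipe of one synthetic scene.

    Intensities are on the 8-bit scale before attenuation and noise;
    ``brightness`` scales all signal (not the noise), emulating
    acquisition-setting variability between datasets.
    """

    shape: tuple[int, int, int] = (8, 96, 96)  # (z, y, x)
    spacing: VoxelSpacing = _DEFAULT_SPACING
    n_hsc1: int = 1
    n_hsc2: int = 1
    n_debris: int = 3
    n_osteoblast_clusters: int = 2
    osteoblast_tiers: tuple[float, float, float] = (200.0, 140.0, 80.0)
    hsc_intensity: float = 200.0
    bone_intensity: float = 150.0
    bone_thickness_px: int = 16
    n_bone_cavities: int = 2
    background: tuple[float, float, float] = (8.0, 5.0, 4.0)
    brightness: float = 1.0
    attenuation_per_um: float = 0.01
    noise_sd: float = 5.0
    poisson: bool = False
    touching_pair: bool = False
    seed: int = 0


@dataclass
class SceneTruth:
    """Ground truth accompanying a generated scene."""

    did_labels: np.ndarray
    osteoblast_labels: np.ndarray
    bone_labels: np.ndarray
    table: pd.DataFrame

    def labels_for(self, role: ChannelRole) -> np.ndarray:
        return {
            ChannelRole.DID: self.did_labels,
            ChannelRole.OSTEOBLAST: self.osteoblast_labels,
            ChannelRole.BONE: self.bone_labels,
        }[role]


# ------------------------------------------------- component rendering
#
# Every dye-labeled object is a union of ellipsoidal components
# (center_zyx in voxel coords, radii_zyx in voxels).  Rendering
# evaluates the union on a 3x3x3 sub-voxel grid to get partial-volume
# coverage; the truth mask uses the voxel centers only.

_SUB_OFFSETS = [
    (a / 3.0, b / 3.0, c / 3.0)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
]


def _inside_union(shape, comps, dz=0.0, dy=0.0, dx=0.0) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    out = np.zeros(shape, dtype=bool)
    for (cz, cy, cx), (rz, ry, rx) in comps:
        rz, ry, rx = max(rz, 0.51), max(ry, 0.51), max(rx, 0.51)
        out |= (
            ((zz + dz - cz) / rz) ** 2
            + ((yy + dy - cy) / ry) ** 2
            + ((xx + dx - cx) / rx) ** 2
        ) <= 1.0
    return out


def _render_components(shape, comps) -> tuple[np.ndarray, np.ndarray]:
    """(truth mask, partial-volume coverage) of a union of ellipsoids."""
    mask = _inside_union(shape, comps)
    cov = np.zeros(shape, dtype=np.float64)
    for dz, dy, dx in _SUB_OFFSETS:
        cov += _inside_union(shape, comps, dz, dy, dx)
    return mask, cov / len(_SUB_OFFSETS)


def _cell_comps(spacing, center, r_um, rng, squash=0.85):
    """Roundish cell: mildly anisotropic ellipsoid with random in-plane
    axis ratio."""
    ax = r_um * rng.uniform(0.9, 1.1)
    ay = r_um * rng.uniform(0.9, 1.1)
    az = r_um * squash
    return [(tuple(center), (az / spacing.sd, ay / spacing.dy, ax / spacing.dx))]


def _protrusion_comps(
    spacing, start_zyx, direction_yx, length_um, radius_um, tilt_z=0.0
):
    """Thin protrusion as a chain of overlapping small spheres.

    Mostly in-plane (that is where protrusions are resolved), with an
    optional moderate z tilt so protruding structures spread across
    slices as real 3D membrane extensions do.
    """
    comps = []
    step_um = max(radius_um * 0.6, 0.5)
    n_steps = max(2, int(length_um / step_um))
    dy, dx = direction_yx
    norm = math.hypot(dy, dx)
    dy, dx = dy / norm, dx / norm
    radii = (radius_um / spacing.sd, radius_um / spacing.dy, radius_um / spacing.dx)
    for i in range(n_steps + 1):
        t_um = i * length_um / n_steps
        comps.append(
            (
                (
                    start_zyx[0] + tilt_z * t_um / spacing.sd,
                    start_zyx[1] + dy * t_um / spacing.dy,
                    start_zyx[2] + dx * t_um / spacing.dx,
                ),
                radii,
            )
        )
    return comps


def _hsc1_comps(spacing, center, rng, r_um=None):
    if r_um is None:
        r_um = rng.uniform(3.4, 4.3)
    return _cell_comps(spacing, center, r_um, rng)


def _hsc2_comps(spacing, center, rng, r_um=None, uropod_frac=None):
    if r_um is None:
        r_um = rng.uniform(3.2, 4.0)
    if uropod_frac is None:
        uropod_frac = rng.uniform(0.45, 0.75)
    comps = _cell_comps(spacing, center, r_um, rng)
    theta = rng.uniform(0, 2 * math.pi)
    direction = (math.sin(theta), math.cos(theta))
    # uropod: shorter than the cell diameter
    length = uropod_frac * 2 * r_um
    start = (
        center[0],
        center[1] + direction[0] * r_um * 0.9 / spacing.dy,
        center[2] + direction[1] * r_um * 0.9 / spacing.dx,
    )
    comps += _protrusion_comps(
        spacing, start, direction, length, radius_um=1.1,
        tilt_z=rng.uniform(-0.3, 0.3),
    )
    return comps


def _debris_comps(spacing, center, rng, r_um=None, length_frac=None, n_prot=None):
    """Irregular aggregate: core with 1-2 protrusions longer than the
    core's own diameter.  Core sizes reach cell scale: the small-debris
    end is already removed by the area filter of the segmentation, and
    the aggregates that remain are the ones that genuinely resemble
    cells in size and brightness."""
    if r_um is None:
        r_um = rng.uniform(1.8, 2.8)
    if n_prot is None:
        n_prot = int(rng.integers(1, 3))
    comps = _cell_comps(spacing, center, r_um, rng, squash=0.9)
    for _ in range(n_prot):
        theta = rng.uniform(0, 2 * math.pi)
        direction = (math.sin(theta), math.cos(theta))
        lf = rng.uniform(1.6, 2.6) if length_frac is None else length_frac
        length = lf * 2 * r_um
        start = (
            center[0],
            center[1] + direction[0] * r_um * 0.8 / spacing.dy,
            center[2] + direction[1] * r_um * 0.8 / spacing.dx,
        )
        comps += _protrusion_comps(
            spacing, start, direction, length, radius_um=1.0,
            tilt_z=rng.uniform(-0.35, 0.35),
        )
    return comps


_COMP_BUILDERS = {
    CLASS_HSC1: _hsc1_comps,
    CLASS_HSC2: _hsc2_comps,
    CLASS_FALSE: _debris_comps,
}


def _patch_mask_cov(shape, center_zyx, rng, r_lo=5.0, r_hi=9.0, z_half=1):
    """Polygonal osteoblast patch extruded over a few slices, with 3x
    in-plane supersampled coverage."""
    n_vert = int(rng.integers(5, 8))
    angles = np.sort(rng.uniform(0, 2 * math.pi, n_vert))
    radii = rng.uniform(r_lo, r_hi, n_vert)
    ys = center_zyx[1] + radii * np.sin(angles)
    xs = center_zyx[2] + radii * np.cos(angles)

    up = 3
    rr, cc = draw_polygon(
        (ys + 0.5) * up - 0.5, (xs + 0.5) * up - 0.5,
        shape=(shape[1] * up, shape[2] * up),
    )
    fine = np.zeros((shape[1] * up, shape[2] * up), dtype=np.float64)
    fine[rr, cc] = 1.0
    cov2d = fine.reshape(shape[1], up, shape[2], up).mean(axis=(1, 3))

    rr1, cc1 = draw_polygon(ys, xs, shape=shape[1:])
    mask2d = np.zeros(shape[1:], dtype=bool)
    mask2d[rr1, cc1] = True

    mask = np.zeros(shape, dtype=bool)
    cov = np.zeros(shape, dtype=np.float64)
    z0 = max(0, int(center_zyx[0]) - z_half)
    z1 = min(shape[0], int(center_zyx[0]) + z_half + 1)
    mask[z0:z1] = mask2d
    cov[z0:z1] = cov2d
    return mask, cov


# ------------------------------------------------------- truth distances


_STRUCTURE_6 = np.array(
    [
        [[0, 0, 0], [0, 1, 0], [0, 0, 0]],
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]],
        [[0, 0, 0], [0, 1, 0], [0, 0, 0]],
    ],
    dtype=bool,
)


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    from scipy.ndimage import binary_erosion

    interior = binary_erosion(mask, structure=_STRUCTURE_6, border_value=0)
    return np.argwhere(mask & ~interior)  # (z, y, x)


def _touching(mask_a: np.ndarray, mask_b: np.ndarray) -> bool:
    from scipy.ndimage import binary_dilation

    return bool((binary_dilation(mask_a, structure=_STRUCTURE_6) & mask_b).any())


def brute_force_surface_distance_um(
    mask_a: np.ndarray, mask_b: np.ndarray, spacing: VoxelSpacing
) -> float:
    """Exhaustive all-pairs minimum surface distance in micrometers.

    The independent oracle for the distance machinery: no spatial index,
    just every surface-voxel pair.  Touching masks give exactly 0.
    """
    if _touching(mask_a, mask_b):
        return 0.0
    sa = _surface_voxels(mask_a).astype(np.float64)
    sb = _surface_voxels(mask_b).astype(np.float64)
    scale = np.array([spacing.z_factor, 1.0, 1.0])
    sa *= scale
    sb *= scale
    best = math.inf
    for row in sa:
        d2 = ((sb - row) ** 2).sum(axis=1).min()
        if d2 < best:
            best = d2
    return math.sqrt(best) * spacing.dx


# ------------------------------------------------------------ the scene


_INPLANE_CROSS = np.array(
    [[[0, 1, 0], [1, 1, 1], [0, 1, 0]]], dtype=bool
)
_Z_LINE = np.ones((3, 1, 1), dtype=bool)


def _clearance_zone(mask: np.ndarray, px: int = 2) -> np.ndarray:
    """Mask dilated by ``px`` in-plane and one slice in z: the region
    another object may not enter, so rendered objects never touch."""
    from scipy.ndimage import binary_dilation

    out = binary_dilation(mask, structure=_INPLANE_CROSS, iterations=px)
    return binary_dilation(out, structure=_Z_LINE)


def generate_scene(spec: SceneSpec) -> tuple[VolumeStack, SceneTruth]:
    """Render one scene with its truth masks and truth table."""
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    spacing = spec.spacing
    shape = spec.shape

    did = np.zeros(shape, dtype=np.float64)
    gfp = np.zeros(shape, dtype=np.float64)
    shg = np.zeros(shape, dtype=np.float64)
    did_labels = np.zeros(shape, dtype=np.int32)
    ob_labels = np.zeros(shape, dtype=np.int32)
    bone_labels = np.zeros(shape, dtype=np.int32)

    # ---- bone slab with cavities on the +x side of the field
    x_bone = nx - spec.bone_thickness_px
    bone = np.zeros(shape, dtype=bool)
    bone[:, :, x_bone:] = True
    bone_cov = bone.astype(np.float64)
    for _ in range(spec.n_bone_cavities):
        cz = rng.uniform(1, nz - 2)
        cy = rng.uniform(8, ny - 9)
        cx = rng.uniform(x_bone + 3, nx - 4)
        radii = (
            rng.uniform(2.5, 5.0) / spacing.sd,
            rng.uniform(4.0, 8.0) / spacing.dy,
            rng.uniform(3.0, 6.0) / spacing.dx,
        )
        cav_mask, cav_cov = _render_components(shape, [((cz, cy, cx), radii)])
        bone &= ~cav_mask
        bone_cov *= 1.0 - cav_cov
    shg = spec.bone_intensity * spec.brightness * bone_cov
    bone_labels[bone] = 1

    # ---- osteoblast clusters of tiered polygonal patches, endosteal side
    occupied_centers: list[tuple[float, float, float]] = []
    patch_id = 0
    for _ in range(spec.n_osteoblast_clusters):
        cz = rng.uniform(min(1.5, 0.25 * nz), max(nz - 2.5, 0.3 * nz))
        cy = rng.uniform(14, ny - 15)
        cx = rng.uniform(x_bone - 26, x_bone - 12)
        occupied_centers.append((cz, cy, cx))
        n_patches = int(rng.integers(2, 4))
        for _p in range(n_patches):
            ocy = cy + rng.uniform(-9, 9)
            ocx = cx + rng.uniform(-9, 9)
            ocz = min(max(cz + rng.uniform(-1.2, 1.2), 1), nz - 2)
            tier = spec.osteoblast_tiers[patch_id % len(spec.osteoblast_tiers)]
            patch, pcov = _patch_mask_cov(shape, (ocz, ocy, ocx), rng)
            allowed = ~bone
            patch &= allowed
            pcov = np.where(allowed, pcov, 0.0)
            if patch.sum() < 10:
                continue
            patch_id += 1
            gfp = np.maximum(gfp, tier * spec.brightness * pcov)
            ob_labels[patch] = patch_id

    # ---- dye-labeled objects in the marrow compartment; placement is
    # mask-based with a clearance zone so no two objects touch (touching
    # and doublet objects are out of scope except the explicit
    # touching-pair option below)
    kinds = (
        [CLASS_HSC1] * spec.n_hsc1
        + [CLASS_HSC2] * spec.n_hsc2
        + [CLASS_FALSE] * spec.n_debris
    )
    occupancy = bone | (ob_labels > 0)
    z_margin = min(1.8, 0.3 * nz)
    rows = []
    for i, kind in enumerate(kinds, start=1):
        placed = False
        for _attempt in range(400):
            center = (
                rng.uniform(z_margin, nz - 1 - z_margin),
                rng.uniform(9.0, ny - 10.0),
                rng.uniform(9.0, x_bone - 9.0),
            )
            comps = _COMP_BUILDERS[kind](spacing, center, rng)
            mask = _inside_union(shape, comps)
            if mask.sum() < 20:
                continue
            if (_clearance_zone(mask) & occupancy).any():
                continue
            placed = True
            break
        if not placed:
            raise RuntimeError("infeasible object placement; enlarge the scene")
        mask, cov = _render_components(shape, comps)
        intensity = spec.hsc_intensity * rng.uniform(0.9, 1.1) * spec.brightness
        did = np.maximum(did, intensity * cov)
        did_labels[mask] = i
        occupancy |= mask
        rows.append({"object_id": i, "class": kind})

    # ---- optional touching cell-osteoblast pair (distance-0 rule)
    if spec.touching_pair:
        did, gfp = _add_touching_pair(
            spec, rng, shape, spacing, did, gfp, did_labels, ob_labels, bone, rows
        )

    # ---- truth table with brute-force distances
    has_ob = ob_labels.max() > 0
    for row in rows:
        mask = did_labels == row["object_id"]
        zs, ys, xs = np.nonzero(mask)
        row["centroid_z"] = float(zs.mean())
        row["centroid_y"] = float(ys.mean())
        row["centroid_x"] = float(xs.mean())
        row["n_voxels"] = int(mask.sum())
        if row["class"] in (CLASS_HSC1, CLASS_HSC2):
            row["dist_osteoblast_um"] = (
                brute_force_surface_distance_um(mask, ob_labels > 0, spacing)
                if has_ob
                else math.nan
            )
            row["dist_bone_um"] = brute_force_surface_distance_um(
                mask, bone, spacing
            )
        else:
            row["dist_osteoblast_um"] = math.nan
            row["dist_bone_um"] = math.nan
    table = pd.DataFrame(
        rows,
        columns=[
            "object_id", "class", "centroid_z", "centroid_y", "centroid_x",
            "n_voxels", "dist_osteoblast_um", "dist_bone_um",
        ],
    )

    # ---- attenuation, noise, quantization
    stack_data = []
    for img, bg in zip((did, gfp, shg), spec.background):
        img = img + bg * spec.brightness
        depth_um = np.arange(nz) * spacing.sd
        atten = np.exp(-spec.attenuation_per_um * depth_um)[:, None, None]
        img = img * atten
        if spec.poisson:
            img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
        img = img + rng.normal(0.0, spec.noise_sd, size=shape)
        stack_data.append(np.clip(np.rint(img), 0, 255).astype(np.uint8))

    stack = VolumeStack(
        np.stack(stack_data),
        spacing,
        [ChannelRole.DID, ChannelRole.OSTEOBLAST, ChannelRole.BONE],
    )
    truth = SceneTruth(
        did_labels=did_labels,
        osteoblast_labels=ob_labels,
        bone_labels=bone_labels,
        table=table,
    )
    return stack, truth


def _add_touching_pair(
    spec, rng, shape, spacing, did, gfp, did_labels, ob_labels, bone, rows
):
    """Place one extra cell face-adjacent to a fresh osteoblast patch."""
    nz, ny, nx = shape
    cz = nz // 2
    cy = ny // 3
    cx = int(nx - spec.bone_thickness_px - 20)
    patch, pcov = _patch_mask_cov(shape, (cz, cy, cx), rng, r_lo=5.0, r_hi=7.0)
    allowed = ~bone
    patch &= allowed
    pcov = np.where(allowed, pcov, 0.0)
    pid = int(ob_labels.max()) + 1
    gfp = np.maximum(gfp, spec.osteoblast_tiers[0] * spec.brightness * pcov)
    ob_labels[patch] = pid

    comps = _cell_comps(spacing, (float(cz), float(cy), float(cx)), 3.6, rng)
    cell, ccov = _render_components(shape, comps)
    # slide the cell along -x until just before overlap: the last
    # non-overlapping offset leaves a face-adjacent voxel pair
    blocked = patch | bone
    while True:
        shifted = np.roll(cell, -1, axis=2)
        shifted[:, :, -1] = False
        if (shifted & blocked).any() or not shifted.any():
            break
        cell = shifted
        ccov = np.roll(ccov, -1, axis=2)
        ccov[:, :, -1] = 0.0
    ccov = np.where(blocked | (ob_labels > 0), 0.0, ccov)
    cell &= ~blocked
    oid = int(did_labels.max()) + 1
    did = np.maximum(did, spec.hsc_intensity * spec.brightness * ccov)
    did_labels[cell] = oid
    rows.append({"object_id": oid, "class": CLASS_HSC1})
    return did, gfp


def generate_benchmark_suite(
    seed: int = 0, n_scenes: int = 10
) -> list[tuple[VolumeStack, SceneTruth]]:
    """Scenes spanning the acquisition variability of real datasets:
    brightness, depth attenuation, z step (with matching slice count so
    total depth stays comparable), and debris load all vary."""
    rng = np.random.default_rng(seed)
    scenes = []
    for i in range(n_scenes):
        sd = float(rng.uniform(1.0, 5.0))
        nz = int(np.clip(round(16.0 / sd), 4, 12))
        spec = SceneSpec(
            shape=(nz, 96, 96),
            spacing=VoxelSpacing(dx=0.8, dy=0.8, sd=sd),
            n_hsc1=int(rng.integers(1, 3)),
            n_hsc2=int(rng.integers(1, 3)),
            n_debris=int(rng.integers(2, 7)),
            brightness=float(rng.uniform(0.7, 1.3)),
            attenuation_per_um=float(rng.uniform(0.005, 0.015)),
            seed=int(seed * 1009 + i) % (2**31 - 1),
        )
        scenes.append(generate_scene(spec))
    return scenes


# --------------------------------------- standalone objects (classifier)


def render_single_object(
    kind: str,
    seed: int,
    spacing: VoxelSpacing | None = None,
    shape: tuple[int, int, int] = (12, 48, 48),
    noise_sd: float = 5.0,
    intensity: float = 200.0,
    background: float = 8.0,
    **shape_params,
):
    """One dye-labeled object of the given class in a small private
    volume.  Returns ``(stack, truth_mask)`` with a single DID channel.
    Used to build classifier training/test archetypes; ``shape_params``
    pin class-specific shape parameters (size, protrusion length) that
    are otherwise drawn randomly.
    """
    if spacing is None:
        spacing = VoxelSpacing(dx=0.8, dy=0.8, sd=1.5)
    if kind not in _COMP_BUILDERS:
        raise ValueError(f"unknown object class {kind!r}")
    rng = np.random.default_rng(seed)
    center = (shape[0] / 2.0, shape[1] / 2.0, shape[2] / 2.0)
    comps = _COMP_BUILDERS[kind](spacing, center, rng, **shape_params)
    mask, cov = _render_components(shape, comps)
    img = intensity * rng.uniform(0.9, 1.1) * cov + background
    img = img + rng.normal(0.0, noise_sd, size=shape)
    data = np.clip(np.rint(img), 0, 255).astype(np.uint8)[None]
    stack = VolumeStack(data, spacing, [ChannelRole.DID])
    return stack, mask


def generate_object_set(
    seed: int, n_hsc1: int, n_hsc2: int, n_false: int
) -> list[tuple[str, VolumeStack, np.ndarray]]:
    """A labeled set of rendered single objects, deterministic in seed."""
    out = []
    base = int(seed) * 7919
    k = 0
    for kind, count in (
        (CLASS_HSC1, n_hsc1),
        (CLASS_HSC2, n_hsc2),
        (CLASS_FALSE, n_false),
    ):
        for _ in range(count):
            stack, mask = render_single_object(kind, seed=(base + k) % (2**31 - 1))
            out.append((kind, stack, mask))
            k += 1
    return out


def generate_training_archetypes(
    seed: int = 0,
) -> list[tuple[str, VolumeStack, np.ndarray]]:
    """The curated 2/5/11 training set.

    Annotators pick training objects *representative of the spectrum* of
    each class rather than at random, so the archetypes tile each
    class's shape-parameter range: cell sizes from small to large,
    uropods from the shortest to the longest that still qualify, debris
    protrusions from borderline to extreme, with both single- and
    double-protrusion aggregates.  Rendering noise stays random
    (seeded), only the shape parameters are pinned.
    """
    base = int(seed) * 104729
    items = []

    def add(kind, k, **params):
        stack, mask = render_single_object(
            kind, seed=(base + k) % (2**31 - 1), **params
        )
        items.append((kind, stack, mask))

    k = 0
    for r in (3.5, 4.2):
        add(CLASS_HSC1, k, r_um=r)
        k += 1
    for r, uf in ((3.3, 0.46), (3.5, 0.55), (3.7, 0.65), (3.9, 0.74), (3.5, 0.70)):
        add(CLASS_HSC2, k, r_um=r, uropod_frac=uf)
        k += 1
    for r, lf, npr in (
        (1.9, 1.65, 1), (1.9, 2.1, 2), (2.1, 1.8, 1), (2.2, 2.5, 2),
        (2.3, 1.65, 2), (2.4, 2.2, 1), (2.5, 1.7, 1), (2.6, 2.4, 2),
        (2.7, 1.65, 1), (2.7, 2.0, 2), (2.8, 2.55, 1),
    ):
        add(CLASS_FALSE, k, r_um=r, length_frac=lf, n_prot=npr)
        k += 1
    return items
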