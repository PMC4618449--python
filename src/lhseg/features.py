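"""Morphological, intensity, and textural features of 3D objects.

The three appearance classes of dye-labeled objects differ in shape:
quiescent cells are round and smooth; migratory cells carry a short
uropod protrusion (shorter than the cell diameter); debris and
aggregates are irregular, with protrusions that can exceed the main
diameter of the object.  The feature set below is chosen so each pair of
classes is separable along at least two axes (e.g. sphericity +
protrusion ratio, solidity + border roughness), leaving the decision
tree to pick the discriminative ones.

Physical features honor the anisotropic voxel spacing; texture is
gray-level co-occurrence computed per 2D slice (offset 1 px, four
directions averaged) and then volume-averaged, consistent with the
slice-wise design of the segmentation.

Degenerate conventions (fixed here so tiny objects never produce NaN):
a single-voxel object has sphericity 1, elongation 1, protrusion ratio
0, solidity 1, border roughness 1.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from skimage.feature import graycomatrix, graycoprops
from skimage.measure import marching_cubes, mesh_surface_area

from .stack import VolumeStack
from .zlink import Object3D

__all__ = ["FEATURE_NAMES", "compute_features", "features_table"]

# features offered to the classifier; n_slices is carried in the
# feature dict as metadata (single-slice objects are flagged downstream)
# but is an acquisition artifact, not a morphology descriptor
FEATURE_NAMES = [
    "volume_vox",
    "volume_um3",
    "surface_area_um2",
    "sphericity",
    "elongation",
    "max_protrusion_ratio",
    "compactness",
    "solidity",
    "border_roughness",
    "mean_intensity",
    "intensity_sd",
    "intensity_skew",
    "glcm_contrast",
    "glcm_homogeneity",
]


def _mask_and_origin(vox: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    origin = vox.min(axis=0)
    extent = vox.max(axis=0) - origin + 1
    mask = np.zeros(extent, dtype=bool)
    mask[tuple((vox - origin).T)] = True
    return mask, origin


def _surface_area_um2(mask: np.ndarray, sp_zyx: tuple[float, float, float]) -> float:
    padded = np.pad(mask, 1).astype(np.float64)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=sp_zyx)
    return float(mesh_surface_area(verts, faces))


def _solidity(coords_phys: np.ndarray, volume_um3: float) -> float:
    from scipy.spatial import ConvexHull, QhullError

    try:
        hull = ConvexHull(coords_phys)
        hull_vol = hull.volume
    except (QhullError, ValueError):
        return 1.0
    if hull_vol <= 0:
        return 1.0
    # hull of voxel centers slightly under-covers the voxelized body;
    # clamp so convex objects report exactly 1
    return float(min(1.0, volume_um3 / (hull_vol + 1e-12)))


def _glcm(mask: np.ndarray, patch: np.ndarray) -> tuple[float, float]:
    """Per-slice co-occurrence contrast/homogeneity, volume-averaged.

    Non-member pixels are zeroed so texture reflects the object itself.
    Intensities are quantized to 64 levels.
    """
    contrasts, homogs = [], []
    angles = [0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4]
    for z in range(mask.shape[0]):
        m = mask[z]
        if m.sum() < 4:
            continue
        img = np.where(m, patch[z], 0.0)
        q = np.clip(img / 4.0, 0, 63).astype(np.uint8)
        glcm = graycomatrix(q, distances=[1], angles=angles, levels=64, normed=True)
        contrasts.append(float(graycoprops(glcm, "contrast").mean()))
        homogs.append(float(graycoprops(glcm, "homogeneity").mean()))
    if not contrasts:
        return 0.0, 1.0
    return float(np.mean(contrasts)), float(np.mean(homogs))


def compute_features(obj: Object3D, stack: VolumeStack) -> dict[str, float]:
    """Deterministic feature vector of one 3D object.

    Intensities are taken from the stack channel matching the object's
    class.  Raises ``ValueError`` on an empty object.
    """
    vox = obj.voxels()
    if len(vox) == 0:
        raise ValueError("cannot featurize an empty object")
    sp = stack.spacing
    sp_zyx = (sp.sd, sp.dy, sp.dx)
    channel = stack.channel(obj.object_class).astype(np.float64)
    vals = channel[tuple(vox.T)]
    n = len(vox)
    volume_um3 = n * sp.voxel_volume_um3

    feats: dict[str, float] = {
        "volume_vox": float(n),
        "volume_um3": float(volume_um3),
        "mean_intensity": float(vals.mean()),
        "intensity_sd": float(vals.std()),
        "intensity_skew": float(sps.skew(vals)) if n > 2 and vals.std() > 0 else 0.0,
        "n_slices": float(len({int(z) for z, _, _ in vox})),
    }

    coords_phys = vox * np.asarray(sp_zyx)
    if n == 1:
        feats.update(
            surface_area_um2=float(
                2 * (sp.dx * sp.dy + sp.dx * sp.sd + sp.dy * sp.sd)
            ),
            sphericity=1.0,
            elongation=1.0,
            max_protrusion_ratio=0.0,
            compactness=1.0,
            solidity=1.0,
            border_roughness=1.0,
            glcm_contrast=0.0,
            glcm_homogeneity=1.0,
        )
        return feats

    mask, origin = _mask_and_origin(vox)
    area = _surface_area_um2(mask, sp_zyx)
    r_eq = (3.0 * volume_um3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    sphere_area = 4.0 * np.pi * r_eq**2
    feats["surface_area_um2"] = area
    feats["sphericity"] = float(min(1.0, sphere_area / area))
    feats["border_roughness"] = float(area / sphere_area)

    centered = coords_phys - coords_phys.mean(axis=0)
    cov = np.cov(centered.T)
    ev = np.sort(np.linalg.eigvalsh(np.atleast_2d(cov)))[::-1]
    ev = np.clip(ev, 1e-9, None)
    feats["elongation"] = float(np.sqrt(ev[0] / ev[-1]))

    radii = np.linalg.norm(centered, axis=1)
    # excursion beyond the volume-equivalent radius, in units of the
    # equivalent diameter: > 1 means a protrusion longer than the main
    # diameter of the object, the hallmark of debris
    feats["max_protrusion_ratio"] = float(
        max(0.0, radii.max() - r_eq) / (2.0 * r_eq)
    )

    bbox_vol = float(np.prod(mask.shape) * sp.voxel_volume_um3)
    feats["compactness"] = float(volume_um3 / bbox_vol)
    feats["solidity"] = _solidity(coords_phys, volume_um3)

    z0, y0, x0 = origin
    patch = channel[
        z0 : z0 + mask.shape[0], y0 : y0 + mask.shape[1], x0 : x0 + mask.shape[2]
    ]
    feats["glcm_contrast"], feats["glcm_homogeneity"] = _glcm(mask, patch)
    return feats


def features_table(objs: list[Object3D], stack: VolumeStack):
    """Features of many objects as a pandas DataFrame (one row per
    object, stable column order); also stores each vector on the object."""
    import pandas as pd

    rows = []
    for o in objs:
        f = compute_features(o, stack)
        o.features = f
        rows.append({"object_id": o.id, "object_class": o.object_class.value, **f})
    return pd.DataFrame(
        rows, columns=["object_id", "object_class", *FEATURE_NAMES, "n_slices"]
    )
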