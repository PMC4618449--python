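"""End-to-end pipeline: smoothing, per-slice segmentation, z-linking,
classification of dye-labeled objects, and 3D distance measurement.

The pipeline is a pure function of (stack, configuration, seeds): every
stochastic component (segmentation scan order, classifier training) is
seeded through the configuration, so a rerun is bit-identical.

Per-object-class parameters (scale, MDN threshold, neighborhood
distance, minimum area, foreground cutoff) follow the logic that small
bright dye-labeled cells need a tight neighborhood and a high contrast
threshold, while large heterogeneous osteoblast clusters and bone need a
wider neighborhood and a lower threshold.  The shipped defaults were
calibrated once on the synthetic benchmark suite and are plain data --
override any of them via the config file.
"""

from __future__ import annotations

import dataclasses
import functools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import (
    BONA_FIDE,
    TrainingSet,
    TreeModel,
    bona_fide as _bona_fide,
    classify as _classify_objects,
    train as _train_tree,
)
from .distance import DistanceRecord, measure_distances
from .features import features_table
from .mdn import MdnParams, Object2D, merge_by_mdn
from .mrs import MrsParams, segment_slice
from .preprocess import gaussian_smooth
from .stack import ChannelRole, VolumeStack
from .synthetic import generate_training_archetypes
from .zlink import Object3D, link_objects

logger = logging.getLogger(__name__)

__all__ = [
    "ClassConfig",
    "PipelineConfig",
    "PipelineResult",
    "default_config",
    "default_model",
    "run_pipeline",
    "segment_channel",
    "label_mask",
    "distances_dataframe",
]


@dataclass(frozen=True)
class ClassConfig:
    """Segmentation parameters for one object class."""

    mrs: MrsParams
    mdn: MdnParams


def default_config() -> "PipelineConfig":
    """Shipped parameter set (one set for all datasets, per class)."""
    return PipelineConfig(
        preprocess_sigma=0.4,
        classes={
            # small, bright, low-heterogeneity dye objects: higher MDN
            # threshold, tight object-adaptive neighborhood
            ChannelRole.DID: ClassConfig(
                mrs=MrsParams(scale=15.0, shape_weight=0.1, compactness_weight=0.5),
                mdn=MdnParams(
                    threshold=90.0,
                    distance_mode="auto",
                    min_object_area=5,
                    foreground_min_intensity=60.0,
                ),
            ),
            # large heterogeneous clusters: lower threshold, wider fixed
            # neighborhood
            ChannelRole.OSTEOBLAST: ClassConfig(
                mrs=MrsParams(scale=20.0, shape_weight=0.1, compactness_weight=0.5),
                mdn=MdnParams(
                    threshold=40.0,
                    distance_mode="fixed",
                    distance=8.0,
                    min_object_area=20,
                    foreground_min_intensity=30.0,
                ),
            ),
            ChannelRole.BONE: ClassConfig(
                mrs=MrsParams(scale=30.0, shape_weight=0.1, compactness_weight=0.5),
                mdn=MdnParams(
                    threshold=50.0,
                    distance_mode="fixed",
                    distance=12.0,
                    min_object_area=20,
                    foreground_min_intensity=40.0,
                ),
            ),
        },
    )


@dataclass
class PipelineConfig:
    preprocess_sigma: float = 0.8
    classes: dict[ChannelRole, ClassConfig] = field(default_factory=dict)
    zlink_overlap_fraction: float = 0.1
    zlink_max_gap: int = 0
    measure_to: tuple[ChannelRole, ...] = (ChannelRole.OSTEOBLAST, ChannelRole.BONE)
    classifier_seed: int = 0

    def to_dict(self) -> dict:
        return {
            "preprocess": {"sigma": self.preprocess_sigma},
            "zlink": {
                "overlap_fraction": self.zlink_overlap_fraction,
                "max_gap": self.zlink_max_gap,
            },
            "measure_to": [r.value for r in self.measure_to],
            "classifier_seed": self.classifier_seed,
            "classes": {
                role.value: {
                    "mrs": dataclasses.asdict(cc.mrs),
                    "mdn": dataclasses.asdict(cc.mdn),
                }
                for role, cc in self.classes.items()
            },
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        base = default_config()
        cfg = cls(
            preprocess_sigma=payload.get("preprocess", {}).get("sigma", 0.8),
            zlink_overlap_fraction=payload.get("zlink", {}).get(
                "overlap_fraction", 0.1
            ),
            zlink_max_gap=payload.get("zlink", {}).get("max_gap", 0),
            measure_to=tuple(
                ChannelRole(r)
                for r in payload.get("measure_to", ["osteoblast", "bone"])
            ),
            classifier_seed=payload.get("classifier_seed", 0),
        )
        classes = {}
        for role_name, block in payload.get("classes", {}).items():
            role = ChannelRole(role_name)
            defaults = base.classes.get(role)
            mrs_kwargs = dict(dataclasses.asdict(defaults.mrs)) if defaults else {}
            mdn_kwargs = dict(dataclasses.asdict(defaults.mdn)) if defaults else {}
            mrs_kwargs.update(block.get("mrs", {}))
            mdn_kwargs.update(block.get("mdn", {}))
            if "channel_weights" in mrs_kwargs:
                mrs_kwargs["channel_weights"] = tuple(mrs_kwargs["channel_weights"])
            classes[role] = ClassConfig(
                mrs=MrsParams(**mrs_kwargs), mdn=MdnParams(**mdn_kwargs)
            )
        cfg.classes = classes or base.classes
        return cfg

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class PipelineResult:
    objects: dict[ChannelRole, list[Object3D]]
    features: pd.DataFrame
    classifications: pd.DataFrame
    distances: pd.DataFrame
    shape_zyx: tuple[int, int, int]

    def label_masks(self) -> dict[ChannelRole, np.ndarray]:
        return {
            role: label_mask(objs, self.shape_zyx)
            for role, objs in self.objects.items()
        }

    def bona_fide(self) -> list[Object3D]:
        return _bona_fide(self.objects.get(ChannelRole.DID, []))


def label_mask(objs: list[Object3D], shape_zyx) -> np.ndarray:
    """Integer label volume of a set of 3D objects (0 = background,
    object ids offset by +1)."""
    out = np.zeros(shape_zyx, dtype=np.int32)
    for o in objs:
        for m in o.members:
            for y, x in m.pixel_set:
                out[m.slice_index, y, x] = o.id + 1
    return out


def segment_channel(
    stack: VolumeStack, role: ChannelRole, cfg: PipelineConfig
) -> list[Object3D]:
    """Smooth + segment + MDN-merge one channel slice-by-slice, then
    link the 2D objects across z."""
    cc = cfg.classes[role]
    smoothed = gaussian_smooth(stack, role, cfg.preprocess_sigma)
    channel = smoothed.channel(role)
    all_2d: list[Object2D] = []
    for z in range(stack.n_slices):
        graph = segment_slice(channel[z], cc.mrs, slice_index=z)
        all_2d.extend(merge_by_mdn(graph, cc.mdn, object_class=role))
    objs = link_objects(
        all_2d,
        stack.spacing,
        overlap_fraction=cfg.zlink_overlap_fraction,
        max_gap=cfg.zlink_max_gap,
    )
    logger.info("%s: %d 2D objects -> %d 3D objects", role.value, len(all_2d), len(objs))
    return objs


@functools.lru_cache(maxsize=8)
def default_model(seed: int = 0) -> TreeModel:
    """Classifier trained on the built-in synthetic archetypes
    (2 round cells / 5 uropod-bearing cells / 11 debris objects).

    The archetype renders are run through the segmentation pipeline and
    the resulting objects are featurized, so the model is trained on
    the same kind of (imperfect) masks it will classify -- training on
    ideal ground-truth masks would misstate the morphology of thin
    structures that segmentation inevitably erodes.
    """
    from .features import compute_features

    cfg = default_config()
    feats, labels = [], []
    false_pool = []
    for kind, stack, _mask in generate_training_archetypes(seed):
        objs = segment_channel(stack, ChannelRole.DID, cfg)
        if not objs:
            continue
        if kind == "FALSE":
            # debris segments into a core plus protrusion fragments;
            # all of them are non-specific signal worth annotating
            false_pool.extend((o, stack) for o in objs)
        else:
            obj = max(objs, key=lambda o: o.voxel_count)
            feats.append(compute_features(obj, stack))
            labels.append(kind)
    # keep 11 debris annotations spanning the size spectrum
    false_pool.sort(key=lambda t: t[0].voxel_count)
    n_false = 11
    if len(false_pool) > n_false:
        idx = np.linspace(0, len(false_pool) - 1, n_false).round().astype(int)
        false_pool = [false_pool[i] for i in idx]
    for o, stack in false_pool:
        feats.append(compute_features(o, stack))
        labels.append("FALSE")
    ts = TrainingSet(features=feats, labels=labels)
    return _train_tree(ts, cv_folds=3, seed=seed)


def run_pipeline(
    stack: VolumeStack,
    config: PipelineConfig | None = None,
    model: TreeModel | None = None,
) -> PipelineResult:
    """Run every stage on one stack.

    Channels without a config block are skipped.  Classification and
    distance measurement run only when a DID channel is present; missing
    target channels raise a clear error when distances to them were
    requested.
    """
    cfg = config or default_config()
    objects: dict[ChannelRole, list[Object3D]] = {}
    for role in cfg.classes:
        if stack.has_channel(role):
            objects[role] = segment_channel(stack, role, cfg)

    features = pd.DataFrame()
    classifications = pd.DataFrame()
    distances = pd.DataFrame()
    if ChannelRole.DID in objects:
        did_objs = objects[ChannelRole.DID]
        features = features_table(did_objs, stack)
        if model is None:
            model = default_model(cfg.classifier_seed)
        _classify_objects(model, did_objs)
        classifications = pd.DataFrame(
            {
                "object_id": [o.id for o in did_objs],
                "label": [o.label for o in did_objs],
                "bona_fide": [o.label in BONA_FIDE for o in did_objs],
            }
        )
        cells = _bona_fide(did_objs)
        targets = {}
        for role in cfg.measure_to:
            if not stack.has_channel(role):
                raise ValueError(
                    f"distances to {role.value!r} requested but the stack has "
                    f"no such channel"
                )
            targets[role] = objects.get(role, [])
        if cells and targets:
            records = measure_distances(cells, targets, stack.spacing)
            distances = distances_dataframe(records)
    return PipelineResult(
        objects=objects,
        features=features,
        classifications=classifications,
        distances=distances,
        shape_zyx=stack.shape_zyx,
    )


def distances_dataframe(records: list[DistanceRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "hsc_id": r.hsc_id,
                "target_class": r.target_class.value,
                "distance_px": r.distance_px,
                "distance_um": r.distance_um,
                "hsc_x": r.hsc_point[0] if r.hsc_point else None,
                "hsc_y": r.hsc_point[1] if r.hsc_point else None,
                "hsc_z": r.hsc_point[2] if r.hsc_point else None,
                "target_x": r.target_point[0] if r.target_point else None,
                "target_y": r.target_point[1] if r.target_point else None,
                "target_z": r.target_point[2] if r.target_point else None,
                "target_object_id": r.target_object_id,
            }
        )
    return pd.DataFrame(rows)


def merge_seam_objects(objects_2d: list[Object2D]) -> list[Object2D]:
    """Merge same-slice, same-class 2D objects whose pixel sets are
    4-adjacent -- the seam rule for tile-wise processing of large
    mosaics, where one cell can be split across tile borders."""
    objs = list(objects_2d)
    n = len(objs)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    by_slice: dict[int, list[int]] = {}
    for i, o in enumerate(objs):
        by_slice.setdefault(o.slice_index, []).append(i)
    for idxs in by_slice.values():
        for ai in range(len(idxs)):
            for bi in range(ai + 1, len(idxs)):
                a, b = objs[idxs[ai]], objs[idxs[bi]]
                if a.object_class != b.object_class:
                    continue
                touch = any(
                    (y + dy, x + dx) in b.pixel_set
                    for y, x in a.pixel_set
                    for dy, dx in ((0, 1), (0, -1), (1, 0), (-1, 0))
                )
                if touch:
                    ra, rb = find(idxs[ai]), find(idxs[bi])
                    if ra != rb:
                        parent[max(ra, rb)] = min(ra, rb)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    out = []
    for new_id, members in enumerate(sorted(groups.values(), key=min)):
        pixels = frozenset().union(*(objs[i].pixel_set for i in members))
        tot = sum(objs[i].mean_intensity * objs[i].area for i in members)
        out.append(
            Object2D(
                id=new_id,
                slice_index=objs[members[0]].slice_index,
                pixel_set=pixels,
                mean_intensity=tot / len(pixels),
                object_class=objs[members[0]].object_class,
            )
        )
    return out


def segment_channel_tiled(
    stack: VolumeStack,
    role: ChannelRole,
    cfg: PipelineConfig,
    tile: int = 128,
) -> list[Object3D]:
    """Tile-wise variant of :func:`segment_channel` for large mosaics.

    The channel is segmented per (tile x tile) x/y block; 2D objects are
    shifted back to mosaic coordinates and objects split by a tile seam
    are re-joined by the 4-adjacency seam rule before z-linking.
    """
    cc = cfg.classes[role]
    smoothed = gaussian_smooth(stack, role, cfg.preprocess_sigma)
    channel = smoothed.channel(role)
    nz, ny, nx = channel.shape
    all_2d: list[Object2D] = []
    for z in range(nz):
        slice_objs: list[Object2D] = []
        for y0 in range(0, ny, tile):
            for x0 in range(0, nx, tile):
                block = channel[z, y0 : y0 + tile, x0 : x0 + tile]
                graph = segment_slice(block, cc.mrs, slice_index=z)
                for o in merge_by_mdn(graph, cc.mdn, object_class=role):
                    shifted = frozenset(
                        (y + y0, x + x0) for y, x in o.pixel_set
                    )
                    slice_objs.append(
                        Object2D(
                            id=len(slice_objs),
                            slice_index=z,
                            pixel_set=shifted,
                            mean_intensity=o.mean_intensity,
                            object_class=role,
                        )
                    )
        all_2d.extend(merge_seam_objects(slice_objs))
    return link_objects(
        all_2d,
        stack.spacing,
        overlap_fraction=cfg.zlink_overlap_fraction,
        max_gap=cfg.zlink_max_gap,
    )
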