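"""Linking of per-slice 2D objects across z into 3D objects.

Two objects in adjacent slices belong to the same 3D object when their
(y, x) footprints overlap by at least ``overlap_fraction`` of the
smaller footprint; the transitive closure of this relation partitions
all 2D objects into 3D objects.  With ``overlap_fraction -> 0`` (any
shared pixel column links) this is exactly 3D connected-component
labeling with face connectivity.  An optional one-slice gap bridge is
available for stacks where an object drops out of a single slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mdn import Object2D
from .stack import ChannelRole, VoxelSpacing

__all__ = ["Object3D", "link_objects", "objects_from_label_volume"]


@dataclass
class Object3D:
    """A 3D object assembled from per-slice 2D objects.

    ``members`` are ordered by slice index; ``voxel_count`` equals the
    sum of member areas.  ``features`` and ``label`` are filled by the
    feature and classification stages.
    """

    id: int
    members: list[Object2D]
    object_class: ChannelRole = ChannelRole.GENERIC
    features: dict | None = None
    label: str | None = None

    @property
    def voxel_count(self) -> int:
        return sum(m.area for m in self.members)

    @property
    def slice_range(self) -> tuple[int, int]:
        zs = [m.slice_index for m in self.members]
        return min(zs), max(zs)

    @property
    def single_slice(self) -> bool:
        """True for objects confined to one slice (coarse z steps)."""
        lo, hi = self.slice_range
        return lo == hi

    def voxels(self) -> np.ndarray:
        """All member voxels as an ``(n, 3)`` array of (z, y, x)."""
        out = []
        for m in self.members:
            for y, x in m.pixel_set:
                out.append((m.slice_index, y, x))
        return np.asarray(sorted(out), dtype=np.int64)

    def mean_intensity(self) -> float:
        tot = sum(m.mean_intensity * m.area for m in self.members)
        return tot / self.voxel_count


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def link_objects(
    objects_2d: list[Object2D],
    spacing: VoxelSpacing | None = None,
    overlap_fraction: float = 0.1,
    max_gap: int = 0,
) -> list[Object3D]:
    """Group 2D objects into 3D objects by footprint overlap.

    Every 2D object is assigned to exactly one 3D object.  Objects of
    mixed classes may be passed; only same-class objects link.  The
    result is ordered deterministically by (first slice, first pixel)
    and ids are assigned in that order.
    """
    if not 0.0 < overlap_fraction <= 1.0 or max_gap < 0:
        raise ValueError("overlap_fraction in (0, 1] and max_gap >= 0 required")
    objs = list(objects_2d)
    uf = _UnionFind(len(objs))
    by_slice: dict[int, list[int]] = {}
    for i, o in enumerate(objs):
        by_slice.setdefault(o.slice_index, []).append(i)
    for z in sorted(by_slice):
        for dz in range(1, max_gap + 2):
            if z + dz not in by_slice:
                continue
            for i in by_slice[z]:
                for j in by_slice[z + dz]:
                    if objs[i].object_class != objs[j].object_class:
                        continue
                    inter = len(objs[i].pixel_set & objs[j].pixel_set)
                    if inter == 0:
                        continue
                    smaller = min(objs[i].area, objs[j].area)
                    if inter / smaller >= overlap_fraction:
                        uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(len(objs)):
        groups.setdefault(uf.find(i), []).append(i)

    def sort_key(members: list[int]):
        first = min(
            (objs[i].slice_index, min(objs[i].pixel_set)) for i in members
        )
        return first

    out = []
    for new_id, members in enumerate(sorted(groups.values(), key=sort_key)):
        ms = sorted(
            (objs[i] for i in members),
            key=lambda o: (o.slice_index, min(o.pixel_set)),
        )
        out.append(
            Object3D(id=new_id, members=ms, object_class=ms[0].object_class)
        )
    return out


def objects_from_label_volume(
    labels: np.ndarray,
    intensity: np.ndarray | None = None,
    object_class: ChannelRole = ChannelRole.GENERIC,
) -> list[Object3D]:
    """Build 3D objects directly from a labeled ``(z, y, x)`` volume.

    Each distinct positive label becomes one Object3D whose members are
    its per-slice footprints.  Used to turn ground-truth label masks
    into objects and to import external segmentations.
    """
    labels = np.asarray(labels)
    out = []
    for new_id, lab in enumerate(sorted(np.unique(labels[labels > 0]))):
        members = []
        for z in range(labels.shape[0]):
            ys, xs = np.nonzero(labels[z] == lab)
            if len(ys) == 0:
                continue
            if intensity is not None:
                mean = float(intensity[z][ys, xs].mean())
            else:
                mean = 0.0
            members.append(
                Object2D(
                    id=0,
                    slice_index=z,
                    pixel_set=frozenset(zip(ys.tolist(), xs.tolist())),
                    mean_intensity=mean,
                    object_class=object_class,
                )
            )
        out.append(Object3D(id=new_id, members=members, object_class=object_class))
    return out
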