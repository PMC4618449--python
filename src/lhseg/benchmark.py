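"""Benchmark harnesses tying the pipeline to synthetic ground truth.

These mirror the manual benchmarking protocols used to validate the
method on real data:

* segmentation — per-object 2D mask comparison: for each sizable truth
  object the slice with its largest footprint is selected (the slice a
  human would pick), a window around the object is cut out, and the
  truth mask is compared to the automated mask by Jaccard index.
  Dye-channel benchmarking uses the cells (debris is not a benchmark
  object); osteoblast benchmarking compares connected clusters, since
  touching same-reporter patches are one region to any annotator.
* classification — train on a small archetype set, test on held-out
  rendered objects, score precision/recall on the bona fide vs false
  distinction.
* distance — automated minimum distances of segmented cells matched to
  the brute-force truth distances under the 5 um rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .classify import BONA_FIDE, TrainingSet, train as _train_tree
from .evaluate import MATCH_TOLERANCE_UM, compare_masks, jaccard
from .features import compute_features
from .pipeline import PipelineConfig, default_config, label_mask, segment_channel
from .stack import ChannelRole, VolumeStack
from .synthetic import SceneTruth, generate_object_set, generate_training_archetypes
from .zlink import objects_from_label_volume

__all__ = [
    "windowed_object_jaccard",
    "segment_scene",
    "segmentation_benchmark",
    "suite_benchmark",
    "classifier_benchmark",
    "distance_benchmark",
]

_STRUCT6 = ndimage.generate_binary_structure(3, 1)
_MIN_BENCHMARK_VOXELS = 30


def windowed_object_jaccard(
    truth_labels: np.ndarray,
    automated_mask: np.ndarray,
    margin: int = 6,
    min_voxels: int = _MIN_BENCHMARK_VOXELS,
) -> list[float]:
    """Per-object 2D Jaccard on each object's largest-footprint slice.

    Objects below ``min_voxels`` are not benchmark objects (a human
    cannot reliably outline them either).  Within the window, only the
    automated components that overlap the truth object are compared --
    the benchmark scores THIS object's segmentation, not whichever
    unrelated neighbor happens to fall inside the window.  A component
    that wrongly merges the object with a neighbor still counts fully
    against it.
    """
    out = []
    for lab in np.unique(truth_labels[truth_labels > 0]):
        m3 = truth_labels == lab
        if m3.sum() < min_voxels:
            continue
        z = int(np.argmax(m3.sum(axis=(1, 2))))
        ys, xs = np.nonzero(m3[z])
        y0, y1 = max(0, ys.min() - margin), ys.max() + margin + 1
        x0, x1 = max(0, xs.min() - margin), xs.max() + margin + 1
        truth_win = m3[z][y0:y1, x0:x1]
        auto_win = automated_mask[z][y0:y1, x0:x1]
        comps, _ = ndimage.label(auto_win, structure=_STRUCT6[1])
        keep = np.unique(comps[truth_win & (comps > 0)])
        auto_obj = np.isin(comps, keep) & (comps > 0)
        c = compare_masks(truth_win, auto_obj)
        out.append(jaccard(c))
    return out


def _cell_truth_labels(truth: SceneTruth) -> np.ndarray:
    cells = truth.table.loc[
        truth.table["class"].isin(BONA_FIDE), "object_id"
    ].to_numpy()
    return np.where(np.isin(truth.did_labels, cells), truth.did_labels, 0)


def segment_scene(
    stack: VolumeStack, cfg: PipelineConfig | None = None
) -> dict[ChannelRole, list]:
    """Segment the three channels of one scene with one parameter set."""
    cfg = cfg or default_config()
    return {
        role: segment_channel(stack, role, cfg)
        for role in (ChannelRole.DID, ChannelRole.OSTEOBLAST, ChannelRole.BONE)
    }


def _segmentation_rows(i, stack, truth, objs_by_role):
    rows = []
    for role in (ChannelRole.DID, ChannelRole.OSTEOBLAST):
        auto = label_mask(objs_by_role[role], stack.shape_zyx) > 0
        if role is ChannelRole.DID:
            tl = _cell_truth_labels(truth)
        else:
            tl, _ = ndimage.label(truth.osteoblast_labels > 0, structure=_STRUCT6)
        for j in windowed_object_jaccard(tl, auto):
            rows.append({"scene": i, "channel": role.value, "jaccard": j})
    return rows


def segmentation_benchmark(
    scenes: list[tuple[VolumeStack, SceneTruth]],
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Windowed per-object Jaccard of cell and osteoblast-cluster
    segmentation over a list of scenes.  One row per benchmark object."""
    cfg = cfg or default_config()
    rows = []
    for i, (stack, truth) in enumerate(scenes):
        rows.extend(_segmentation_rows(i, stack, truth, segment_scene(stack, cfg)))
    return pd.DataFrame(rows)


def suite_benchmark(
    scenes: list[tuple[VolumeStack, SceneTruth]],
    cfg: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segmentation and distance benchmarks sharing one segmentation
    pass per scene."""
    cfg = cfg or default_config()
    seg_rows, dist_rows = [], []
    for i, (stack, truth) in enumerate(scenes):
        objs = segment_scene(stack, cfg)
        seg_rows.extend(_segmentation_rows(i, stack, truth, objs))
        dist_rows.extend(_distance_rows(i, stack, truth, objs))
    return pd.DataFrame(seg_rows), pd.DataFrame(dist_rows)


def _featurize_rendered(items):
    feats, labels = [], []
    for kind, stack, mask in items:
        obj = objects_from_label_volume(
            mask.astype(np.int32), stack.channel(ChannelRole.DID), ChannelRole.DID
        )[0]
        feats.append(compute_features(obj, stack))
        labels.append(kind)
    return feats, labels


def classifier_benchmark(
    seed: int = 0,
    n_train: tuple[int, int, int] = (2, 5, 11),
    n_test: tuple[int, int, int] = (15, 25, 60),
) -> dict:
    """Train on archetypes at the study's training-set sizes, test on
    held-out rendered objects; precision/recall for the bona fide class.
    """
    if tuple(n_train) == (2, 5, 11):
        train_items = generate_training_archetypes(seed)
    else:
        train_items = generate_object_set(seed, *n_train)
    test_items = generate_object_set(seed + 1, *n_test)
    feats, labels = _featurize_rendered(train_items)
    model = _train_tree(
        TrainingSet(features=feats, labels=labels), cv_folds=3, seed=seed
    )
    tfeats, tlabels = _featurize_rendered(test_items)
    pred = [model.predict_one(f) for f in tfeats]
    tp = sum(
        1
        for p, t in zip(pred, tlabels)
        if p in BONA_FIDE and t in BONA_FIDE
    )
    fp = sum(
        1
        for p, t in zip(pred, tlabels)
        if p in BONA_FIDE and t not in BONA_FIDE
    )
    fn = sum(
        1
        for p, t in zip(pred, tlabels)
        if p not in BONA_FIDE and t in BONA_FIDE
    )
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    return {
        "model": model,
        "n_test": len(tlabels),
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "precision": precision,
        "recall": recall,
        "resubstitution_accuracy": float(
            np.mean([model.predict_one(f) == l for f, l in zip(feats, labels)])
        ),
    }


def distance_benchmark(
    scenes: list[tuple[VolumeStack, SceneTruth]],
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Automated vs truth cell-to-niche distances, per truth cell.

    Each truth cell is matched to the automated dye-channel object with
    the largest voxel overlap; the automated object's minimum distances
    to the segmented osteoblast and bone objects are compared to the
    brute-force truth distances.  Rows carry both values and the match
    flag under the manual-measurement tolerance.
    """
    cfg = cfg or default_config()
    rows = []
    for i, (stack, truth) in enumerate(scenes):
        rows.extend(_distance_rows(i, stack, truth, segment_scene(stack, cfg)))
    return pd.DataFrame(rows)


def _distance_rows(i, stack, truth, objs_by_role):
    from .distance import measure_distances

    rows = []
    did_objs = objs_by_role[ChannelRole.DID]
    targets = {
        ChannelRole.OSTEOBLAST: objs_by_role[ChannelRole.OSTEOBLAST],
        ChannelRole.BONE: objs_by_role[ChannelRole.BONE],
    }
    auto_labels = label_mask(did_objs, stack.shape_zyx)
    cell_table = truth.table[truth.table["class"].isin(BONA_FIDE)]
    matched_objs, truth_rows = [], []
    for _, trow in cell_table.iterrows():
        tmask = truth.did_labels == trow.object_id
        overlap = auto_labels[tmask]
        overlap = overlap[overlap > 0]
        if overlap.size == 0:
            rows.append(
                {
                    "scene": i,
                    "truth_id": int(trow.object_id),
                    "target": "unmatched",
                    "truth_um": np.nan,
                    "auto_um": np.nan,
                    "matched": False,
                }
            )
            continue
        auto_id = int(np.bincount(overlap).argmax()) - 1
        matched_objs.append(next(o for o in did_objs if o.id == auto_id))
        truth_rows.append(trow)
    if matched_objs:
        recs = measure_distances(matched_objs, targets, stack.spacing)
        by_key = {(r.hsc_id, r.target_class): r for r in recs}
        for obj, trow in zip(matched_objs, truth_rows):
            for role, col in (
                (ChannelRole.OSTEOBLAST, "dist_osteoblast_um"),
                (ChannelRole.BONE, "dist_bone_um"),
            ):
                truth_um = trow[col]
                if not np.isfinite(truth_um):
                    continue
                rec = by_key[(obj.id, role)]
                rows.append(
                    {
                        "scene": i,
                        "truth_id": int(trow.object_id),
                        "target": role.value,
                        "truth_um": float(truth_um),
                        "auto_um": rec.distance_um,
                        "matched": bool(
                            np.isfinite(rec.distance_um)
                            and abs(rec.distance_um - truth_um)
                            <= MATCH_TOLERANCE_UM
                        ),
                    }
                )
    return rows
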