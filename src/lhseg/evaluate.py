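"""Accuracy framework: mask comparison, Jaccard, precision/recall, and
the percent-error of distance measurements under a 5 um match rule.

The benchmarking protocol is 2D: a user manually segments objects on a
chosen slice, the manual mask is overlaid on the automated one, and
pixels are tallied as true positive (both masks), false positive
(automated only) or false negative (manual only).  A 3D variant with
identical arithmetic is provided for synthetic volumes where full
ground-truth masks exist, but it is not the benchmark protocol.

Distance agreement uses the tolerance of manual 3D measurement: an
automated measure matches its manual counterpart when they differ by at
most 5 um, and the percent error over a benchmark set is
``100 * |n_benchmark - n_matched| / n_benchmark``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MATCH_TOLERANCE_UM",
    "MaskComparison",
    "EvaluationReport",
    "compare_masks",
    "compare_masks_3d",
    "jaccard",
    "precision_recall",
    "match_distances",
    "pct_error",
    "evaluate_distances",
]

MATCH_TOLERANCE_UM = 5.0


@dataclass(frozen=True)
class MaskComparison:
    """Pixel tallies of an automated mask against a manual benchmark."""

    tp_area: int
    fp_area: int
    fn_area: int

    @property
    def manual_area(self) -> int:
        return self.tp_area + self.fn_area

    @property
    def automated_area(self) -> int:
        return self.tp_area + self.fp_area


@dataclass
class EvaluationReport:
    """Bundle of the accuracy metrics for machine output."""

    jaccard: float | None = None
    precision: float | None = None
    recall: float | None = None
    pct_error: float | None = None
    per_object_match: list[tuple[int, float, float, bool]] = field(
        default_factory=list
    )

    def to_dict(self) -> dict:
        return {
            "jaccard": self.jaccard,
            "precision": self.precision,
            "recall": self.recall,
            "pct_error": self.pct_error,
            "per_object_match": [
                {"id": i, "manual_um": m, "auto_um": a, "matched": bool(f)}
                for i, m, a, f in self.per_object_match
            ],
        }

    def format(self) -> str:
        """Display formatting: precision/recall to 2 decimals, percent
        error to 1; raw floats stay in :meth:`to_dict`."""
        parts = []
        if self.jaccard is not None:
            parts.append(f"Jaccard {self.jaccard:.2f}")
        if self.precision is not None:
            parts.append(f"Precision {self.precision:.2f}")
        if self.recall is not None:
            parts.append(f"Recall {self.recall:.2f}")
        if self.pct_error is not None:
            parts.append(f"%Error {self.pct_error:.1f}")
        return ", ".join(parts)


def compare_masks(manual: np.ndarray, automated: np.ndarray) -> MaskComparison:
    """Pixel-wise TP/FP/FN tallies of two same-shape 2D binary masks."""
    manual = np.asarray(manual).astype(bool)
    automated = np.asarray(automated).astype(bool)
    if manual.ndim != 2:
        raise ValueError("benchmark mask comparison is 2D; see compare_masks_3d")
    if manual.shape != automated.shape:
        raise ValueError(f"mask shapes differ: {manual.shape} vs {automated.shape}")
    return MaskComparison(
        tp_area=int(np.sum(manual & automated)),
        fp_area=int(np.sum(automated & ~manual)),
        fn_area=int(np.sum(manual & ~automated)),
    )


def compare_masks_3d(manual: np.ndarray, automated: np.ndarray) -> MaskComparison:
    """Voxel-wise tallies over a full volume (non-benchmark variant)."""
    manual = np.asarray(manual).astype(bool)
    automated = np.asarray(automated).astype(bool)
    if manual.shape != automated.shape:
        raise ValueError(f"mask shapes differ: {manual.shape} vs {automated.shape}")
    return MaskComparison(
        tp_area=int(np.sum(manual & automated)),
        fp_area=int(np.sum(automated & ~manual)),
        fn_area=int(np.sum(manual & ~automated)),
    )


def jaccard(c: MaskComparison) -> float:
    """Intersection over union: TP / (TP + FP + FN)."""
    union = c.tp_area + c.fp_area + c.fn_area
    if union == 0:
        raise ValueError("Jaccard undefined for an empty union")
    return c.tp_area / union


def precision_recall(tp: int, fp: int, fn: int) -> tuple[float, float]:
    """Precision TP/(TP+FP) and recall TP/(TP+FN)."""
    if tp + fp == 0 or tp + fn == 0:
        raise ValueError("precision/recall undefined with a zero denominator")
    return tp / (tp + fp), tp / (tp + fn)


def match_distances(
    manual: list[float],
    automated: list[float],
    tolerance: float = MATCH_TOLERANCE_UM,
) -> list[bool]:
    """Per-object match flags: |manual - automated| <= tolerance (um),
    boundary inclusive."""
    if len(manual) != len(automated):
        raise ValueError("manual and automated distance lists differ in length")
    return [abs(m - a) <= tolerance for m, a in zip(manual, automated)]


def pct_error(n_benchmark: int, n_matched: int) -> float:
    """Percent of benchmark objects whose automated distance failed the
    match rule: ``100 * |n_benchmark - n_matched| / n_benchmark``."""
    if n_benchmark <= 0:
        raise ValueError("benchmark count must be positive")
    if n_matched > n_benchmark:
        raise ValueError("matched count cannot exceed benchmark count")
    return 100.0 * abs(n_benchmark - n_matched) / n_benchmark


def evaluate_distances(
    manual: list[float],
    automated: list[float],
    tolerance: float = MATCH_TOLERANCE_UM,
) -> EvaluationReport:
    """Full per-object distance evaluation with percent error."""
    flags = match_distances(manual, automated, tolerance)
    report = EvaluationReport(
        pct_error=pct_error(len(flags), sum(flags)),
        per_object_match=[
            (i, m, a, f)
            for i, (m, a, f) in enumerate(zip(manual, automated, flags))
        ],
    )
    return report
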