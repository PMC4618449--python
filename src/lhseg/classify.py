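"""Decision-tree classification of dye-labeled objects.

Segmentation cannot tell a genuine labeled cell from dye debris or an
aggregate: both are bright and similar in intensity.  The discriminating
signal is morphological, so each 3D object's feature vector is fed to a
CART decision tree trained on a small annotated set of three classes:

* HSC1 — round, smooth, quiescent-looking cells;
* HSC2 — less-round cells with a short uropod protrusion (migratory);
* FALSE — debris/aggregates with irregular morphology and protrusions
  longer than the object's own diameter.

Objects labeled HSC1 or HSC2 are the *bona fide* cells that downstream
distance analysis keeps.

The tree is grown with Gini impurity and pruned by minimal
cost-complexity, with the pruning strength selected by k-fold
cross-validation (3 folds by default; training sets in this regime are
tiny — on the order of 2/5/11 per class — and more folds do not help).
The implementation is in-house rather than delegated: with a handful of
training samples many features split the training set perfectly, and
the choice among those ties decides how well the tree generalizes.
Ties are therefore broken toward the split with the widest margin (the
largest gap between the classes it separates), then deterministically
by feature name — no random tie-breaking.  Trees are persisted as plain
JSON so the selected features and thresholds stay inspectable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import FEATURE_NAMES
from .zlink import Object3D

__all__ = ["CLASSES", "BONA_FIDE", "TrainingSet", "TreeModel", "train", "classify"]

CLASSES = ("HSC1", "HSC2", "FALSE")
BONA_FIDE = ("HSC1", "HSC2")
# deterministic tie order: HSC1 < HSC2 < FALSE
_CLASS_RANK = {c: i for i, c in enumerate(CLASSES)}


@dataclass
class TrainingSet:
    """Annotated feature vectors; every class must appear at least once
    and at least two classes must be present."""

    features: list[dict[str, float]]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels differ in length")
        bad = set(self.labels) - set(CLASSES)
        if bad:
            raise ValueError(f"unknown class labels: {sorted(bad)}")
        if len(set(self.labels)) < 2:
            raise ValueError("training needs at least two classes")

    def matrix(self, feature_names: list[str]) -> np.ndarray:
        return np.array(
            [[f[name] for name in feature_names] for f in self.features]
        )


@dataclass
class TreeModel:
    """A trained tree as an explicit node structure.

    Internal nodes: ``{"feature": name, "threshold": t, "left": ..,
    "right": ..}`` with the left branch taken when
    ``value <= threshold``; leaves: ``{"cls": label, "counts": {...}}``.
    """

    root: dict
    feature_names: list[str]
    metadata: dict = field(default_factory=dict)

    def predict_one(self, feats: dict[str, float]) -> str:
        node = self.root
        while "cls" not in node:
            name = node["feature"]
            if name not in feats:
                raise KeyError(f"feature {name!r} missing from object features")
            node = node["left"] if feats[name] <= node["threshold"] else node["right"]
        return node["cls"]

    def selected_features(self) -> list[str]:
        out: list[str] = []

        def walk(node: dict) -> None:
            if "cls" in node:
                return
            if node["feature"] not in out:
                out.append(node["feature"])
            walk(node["left"])
            walk(node["right"])

        walk(self.root)
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_names": self.feature_names,
                "metadata": self.metadata,
                "tree": self.root,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "TreeModel":
        payload = json.loads(text)
        return cls(
            root=payload["tree"],
            feature_names=payload["feature_names"],
            metadata=payload.get("metadata", {}),
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_json())
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TreeModel":
        return cls.from_json(Path(path).read_text())


# -------------------------------------------------------- tree growing


def _counts(y: list[str]) -> dict[str, int]:
    out: dict[str, int] = {}
    for c in y:
        out[c] = out.get(c, 0) + 1
    return out


def _gini(y: list[str]) -> float:
    n = len(y)
    if n == 0:
        return 0.0
    return 1.0 - sum((v / n) ** 2 for v in _counts(y).values())


def _majority(counts: dict[str, int]) -> str:
    """Majority class; exact ties resolved by HSC1 < HSC2 < FALSE."""
    best = max(counts.values())
    tied = [c for c, n in counts.items() if n == best]
    return min(tied, key=lambda c: _CLASS_RANK[c])


def _best_split(X: np.ndarray, y: list[str], names: list[str]):
    """Exhaustive Gini split search.

    Returns ``(gain, margin, feature_index, threshold)`` or ``None``.
    Thresholds are midpoints between consecutive distinct values; among
    equal-gain splits the one with the widest *relative* gap wins (gap
    divided by the feature's value spread at the node, so features on
    different scales compete fairly), then feature name, then the
    smaller threshold.
    """
    n = len(y)
    parent = _gini(y)
    best = None
    order_by_name = sorted(range(X.shape[1]), key=lambda j: names[j])
    for j in order_by_name:
        vals = X[:, j]
        spread = float(vals.max() - vals.min())
        if spread == 0.0:
            continue
        order = np.argsort(vals, kind="stable")
        sv = vals[order]
        sy = [y[i] for i in order]
        for i in range(n - 1):
            if sv[i] == sv[i + 1]:
                continue
            thr = (sv[i] + sv[i + 1]) / 2.0
            left, right = sy[: i + 1], sy[i + 1 :]
            gain = parent - (
                len(left) * _gini(left) + len(right) * _gini(right)
            ) / n
            margin = (sv[i + 1] - sv[i]) / spread
            key = (gain, margin)
            if best is None or key > best[0]:
                best = (key, j, float(thr))
    if best is None or best[0][0] <= 1e-12:
        return None
    (gain, margin), j, thr = best
    return gain, margin, j, thr


def _grow(X: np.ndarray, y: list[str], names: list[str]) -> dict:
    counts = _counts(y)
    if len(counts) == 1 or len(y) < 2:
        return {"cls": _majority(counts), "counts": counts}
    split = _best_split(X, y, names)
    if split is None:
        return {"cls": _majority(counts), "counts": counts}
    _, _, j, thr = split
    mask = X[:, j] <= thr
    return {
        "feature": names[j],
        "threshold": thr,
        "counts": counts,
        "left": _grow(X[mask], [c for c, m in zip(y, mask) if m], names),
        "right": _grow(X[~mask], [c for c, m in zip(y, mask) if not m], names),
    }


# ---------------------------------------------- cost-complexity pruning


def _node_counts(node: dict) -> dict[str, int]:
    return node["counts"]


def _leaf_error(node: dict) -> int:
    counts = _node_counts(node)
    return sum(counts.values()) - counts.get(_majority(counts), 0)


def _subtree_stats(node: dict) -> tuple[int, int]:
    """(misclassified samples over leaves, number of leaves)."""
    if "feature" not in node:
        return _leaf_error(node), 1
    el, nl = _subtree_stats(node["left"])
    er, nr = _subtree_stats(node["right"])
    return el + er, nl + nr


def _weakest_alpha(node: dict, n_total: int) -> float:
    """Smallest g(t) over internal nodes of the subtree."""
    if "feature" not in node:
        return math.inf
    err_sub, leaves = _subtree_stats(node)
    g = ((_leaf_error(node) - err_sub) / n_total) / max(leaves - 1, 1)
    return min(g, _weakest_alpha(node["left"], n_total),
               _weakest_alpha(node["right"], n_total))


def _pruned(node: dict, alpha: float, n_total: int) -> dict:
    """Collapse every subtree whose weakest-link strength is <= alpha."""
    if "feature" not in node:
        return dict(node)
    err_sub, leaves = _subtree_stats(node)
    g = ((_leaf_error(node) - err_sub) / n_total) / max(leaves - 1, 1)
    if g <= alpha + 1e-15:
        counts = _node_counts(node)
        return {"cls": _majority(counts), "counts": counts}
    return {
        "feature": node["feature"],
        "threshold": node["threshold"],
        "counts": node["counts"],
        "left": _pruned(node["left"], alpha, n_total),
        "right": _pruned(node["right"], alpha, n_total),
    }


def _alpha_path(root: dict, n_total: int) -> list[float]:
    alphas = [0.0]
    node = root
    while "feature" in node:
        a = _weakest_alpha(node, n_total)
        if not math.isfinite(a):
            break
        alphas.append(max(a, 0.0))
        node = _pruned(node, a, n_total)
    return sorted(set(alphas))


def _predict_node(node: dict, names: list[str], row: np.ndarray) -> str:
    while "cls" not in node:
        j = names.index(node["feature"])
        node = node["left"] if row[j] <= node["threshold"] else node["right"]
    return node["cls"]


def _strip_internal_counts(node: dict) -> dict:
    if "feature" not in node:
        return {"cls": node["cls"], "counts": node["counts"]}
    return {
        "feature": node["feature"],
        "threshold": node["threshold"],
        "counts": node["counts"],
        "left": _strip_internal_counts(node["left"]),
        "right": _strip_internal_counts(node["right"]),
    }


def train(
    ts: TrainingSet,
    cv_folds: int = 3,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> TreeModel:
    """Grow and prune a CART tree on an annotated training set.

    Candidate pruning strengths come from the full tree's weakest-link
    path; cross-validated accuracy picks one, with ties resolved toward
    the least-pruned tree.  Deterministic given (training set, seed);
    the seed only shuffles the CV folds.
    """
    names = list(feature_names or FEATURE_NAMES)
    X = ts.matrix(names)
    y = list(ts.labels)
    n = len(y)
    if cv_folds < 2 or cv_folds > n:
        raise ValueError("cv_folds must be between 2 and the sample count")

    full = _grow(X, y, names)
    alphas = _alpha_path(full, n)

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, cv_folds)
    fold_trees = []
    for te_idx in folds:
        tr_idx = np.setdiff1d(perm, te_idx, assume_unique=False)
        ytr = [y[i] for i in tr_idx]
        if len(set(ytr)) < 2:
            fold_trees.append(None)
            continue
        fold_trees.append((_grow(X[tr_idx], ytr, names), len(tr_idx), te_idx))
    scores = []
    for a in alphas:
        accs = []
        for entry in fold_trees:
            if entry is None:
                continue
            tree, ntr, te_idx = entry
            pt = _pruned(tree, a, ntr)
            accs.append(
                float(
                    np.mean(
                        [_predict_node(pt, names, X[i]) == y[i] for i in te_idx]
                    )
                )
            )
        scores.append(float(np.mean(accs)) if accs else 0.0)
    best_score = max(scores)
    best_alpha = min(a for a, s in zip(alphas, scores) if s == best_score)

    root = _strip_internal_counts(_pruned(full, best_alpha, n))
    return TreeModel(
        root=root,
        feature_names=names,
        metadata={
            "seed": int(seed),
            "cv_folds": int(cv_folds),
            "ccp_alpha": float(best_alpha),
            "cv_accuracy": float(best_score),
            "n_training": int(n),
        },
    )


def classify(model: TreeModel, objs: list[Object3D]) -> list[Object3D]:
    """Label each object HSC1, HSC2 or FALSE from its feature vector
    (computed beforehand); returns the same objects with ``label`` set."""
    for o in objs:
        if o.features is None:
            raise ValueError(
                f"object {o.id} has no features; run the feature stage first"
            )
        o.label = model.predict_one(o.features)
    return objs


def bona_fide(objs: list[Object3D]) -> list[Object3D]:
    """The objects classified as genuine cells (HSC1 or HSC2)."""
    return [o for o in objs if o.label in BONA_FIDE]
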