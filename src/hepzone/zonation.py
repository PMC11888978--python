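"""Cavity classification and the five-zone acinar map.

Detected cavities are classified into portal tract (PT), central vein (CV),
vessel/bile-duct, crack/sinusoid, or lipid vacuole with a binary decision tree
over their morphological features and surrounding collagen -- either an
inspectable built-in rule tree or a CART tree trained on labeled synthetic
objects. The hepatic acinus is then partitioned into five zones: the PT and CV
object pixels themselves, a periportal (PP) band within 100 um of any PT
boundary, a pericentral (PC) band within 100 um of any CV boundary, and the
transitional (TS) region in between. Where the two bands overlap, a pixel goes
to the nearer landmark class; exact ties go to PP (a deterministic, portal-
conservative convention).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage as ndi

from .segment import CavityObject

__all__ = [
    "ZONE_BACKGROUND",
    "ZONE_PT",
    "ZONE_PP",
    "ZONE_TS",
    "ZONE_PC",
    "ZONE_CV",
    "ZONE_NAMES",
    "CLASSES",
    "TreeNode",
    "ObjectClassTree",
    "default_rule_tree",
    "ClassificationError",
    "classify_objects",
    "fit_tree",
    "ZoneMap",
    "build_zone_map",
    "rasterize_landmarks",
    "cavities_to_landmark_masks",
]

ZONE_BACKGROUND, ZONE_PT, ZONE_PP, ZONE_TS, ZONE_PC, ZONE_CV = 0, 1, 2, 3, 4, 5
ZONE_NAMES = {
    ZONE_BACKGROUND: "background",
    ZONE_PT: "PT",
    ZONE_PP: "PP",
    ZONE_TS: "TS",
    ZONE_PC: "PC",
    ZONE_CV: "CV",
}

#: Object classes assigned by the tree.
CLASSES = ("PT", "CV", "vessel_duct", "crack", "vacuole")

#: Feature vector used by the trees, in fixed order.
TREE_FEATURES = (
    "border",
    "area_um2",
    "equivalent_diameter_um",
    "circularity",
    "solidity",
    "collagen_ring_fraction",
)


class ClassificationError(ValueError):
    """A cavity is missing a feature required by the decision tree."""


@dataclass
class TreeNode:
    """Internal node: ``feature <= threshold`` goes left, else right. Leaves
    carry ``label`` and no children."""

    feature: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    label: str | None = None

    @property
    def is_leaf(self) -> bool:
        return self.label is not None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"label": self.label}
        return {
            "feature": self.feature,
            "threshold": self.threshold,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        if "label" in d:
            return cls(label=d["label"])
        return cls(
            feature=d["feature"],
            threshold=d["threshold"],
            left=cls.from_dict(d["left"]),
            right=cls.from_dict(d["right"]),
        )


@dataclass
class ObjectClassTree:
    """A binary decision tree over cavity features."""

    root: TreeNode
    provenance: str = "rule-based default"
    feature_names: tuple[str, ...] = TREE_FEATURES

    def predict_one(self, obj: CavityObject) -> str:
        node = self.root
        while not node.is_leaf:
            value = getattr(obj, node.feature, None)
            if value is None:
                raise ClassificationError(
                    f"cavity id={obj.id} missing feature {node.feature!r}"
                )
            node = node.left if float(value) <= node.threshold else node.right
        return node.label

    @property
    def depth(self) -> int:
        def _d(n: TreeNode) -> int:
            return 0 if n.is_leaf else 1 + max(_d(n.left), _d(n.right))

        return _d(self.root)

    def to_json(self) -> str:
        return json.dumps(
            {"provenance": self.provenance, "features": list(self.feature_names),
             "root": self.root.to_dict()},
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ObjectClassTree":
        d = json.loads(text)
        return cls(
            root=TreeNode.from_dict(d["root"]),
            provenance=d.get("provenance", "deserialized"),
            feature_names=tuple(d.get("features", TREE_FEATURES)),
        )


def _leaf(label: str) -> TreeNode:
    return TreeNode(label=label)


_EPS = 1e-9


def default_rule_tree() -> ObjectClassTree:
    """Built-in rule tree encoding morphology + surrounding-collagen heuristics.

    In rule order: border-touching objects are cracks; large hollows
    (> 2000 um^2) without a collagen sheath are central veins; mid-sized
    lumens (300-20000 um^2) with a collagen ring covering >= 50% of a 5 um
    annulus are portal tracts; round hollows 5-40 um across with a bare rim
    (< 20% ring coverage) are lipid vacuoles; everything else is a vessel or
    bile duct.
    """
    vacuole_chain = TreeNode(  # circularity >= 0.6 branch
        feature="equivalent_diameter_um", threshold=5.0 - _EPS,
        left=_leaf("vessel_duct"),
        right=TreeNode(
            feature="equivalent_diameter_um", threshold=40.0,
            left=TreeNode(
                feature="collagen_ring_fraction", threshold=0.2 - _EPS,
                left=_leaf("vacuole"), right=_leaf("vessel_duct"),
            ),
            right=_leaf("vessel_duct"),
        ),
    )
    rule4 = TreeNode(
        feature="circularity", threshold=0.6 - _EPS,
        left=_leaf("vessel_duct"), right=vacuole_chain,
    )
    pt_chain = TreeNode(  # ring fraction >= 0.5 branch
        feature="area_um2", threshold=300.0 - _EPS,
        left=_leaf("vessel_duct"),
        right=TreeNode(
            feature="area_um2", threshold=20_000.0,
            left=_leaf("PT"), right=_leaf("vessel_duct"),
        ),
    )
    rule3 = TreeNode(
        feature="collagen_ring_fraction", threshold=0.5 - _EPS,
        left=rule4, right=pt_chain,
    )
    rule2 = TreeNode(
        feature="area_um2", threshold=2000.0,
        left=rule3,
        right=TreeNode(
            feature="collagen_ring_fraction", threshold=0.2 - _EPS,
            left=_leaf("CV"), right=rule3,
        ),
    )
    root = TreeNode(feature="border", threshold=0.5, left=rule2, right=_leaf("crack"))
    return ObjectClassTree(root=root, provenance="rule-based default")


def classify_objects(
    cavities: Sequence[CavityObject], tree: ObjectClassTree | None = None
) -> list[CavityObject]:
    """Assign exactly one class to every cavity.

    Border-flagged objects are never classed as vacuole: the default tree
    routes them to ``crack`` at the root, and trained trees are overridden the
    same way.
    """
    tree = tree or default_rule_tree()
    out = []
    for obj in cavities:
        label = tree.predict_one(obj)
        if obj.border and label == "vacuole":
            label = "crack"
        out.append(obj.with_label(label))
    return out


def fit_tree(
    labeled: Sequence[CavityObject],
    max_depth: int = 4,
    seed: int = 0,
) -> ObjectClassTree:
    """Fit a CART tree (Gini-impurity greedy binary splits) to labeled cavities.

    Deterministic given the seed and data order. A single-class input yields a
    trivial one-leaf tree with a warning.
    """
    labels = [obj.label for obj in labeled]
    if any(lbl is None for lbl in labels):
        raise ClassificationError("all training objects must carry a label")
    classes = sorted(set(labels))
    if len(classes) < 2:
        warnings.warn("single-class training data; returning a one-leaf tree",
                      stacklevel=2)
        return ObjectClassTree(
            root=_leaf(classes[0]), provenance="trained (single class)"
        )

    from sklearn.tree import DecisionTreeClassifier

    X = np.array([[obj.feature(f) for f in TREE_FEATURES] for obj in labeled])
    clf = DecisionTreeClassifier(
        criterion="gini", max_depth=max_depth, random_state=seed
    ).fit(X, labels)

    t = clf.tree_
    class_names = list(clf.classes_)

    def _convert(i: int) -> TreeNode:
        if t.children_left[i] == -1:
            return _leaf(class_names[int(np.argmax(t.value[i]))])
        return TreeNode(
            feature=TREE_FEATURES[t.feature[i]],
            threshold=float(t.threshold[i]),
            left=_convert(t.children_left[i]),
            right=_convert(t.children_right[i]),
        )

    return ObjectClassTree(
        root=_convert(0), provenance="trained on labeled synthetic objects"
    )


# ---------------------------------------------------------------------------
# Zone map
# ---------------------------------------------------------------------------


@dataclass
class ZoneMap:
    """Per-pixel acinar zone labels over {background, PT, PP, TS, PC, CV}."""

    labels: np.ndarray  # uint8 raster
    pixel_size_um: float
    band_um: float
    landmarks: list | None = None  # provenance: planted or detected landmarks

    def areas_um2(self) -> dict[str, float]:
        ps2 = self.pixel_size_um**2
        return {
            name: float(np.count_nonzero(self.labels == code) * ps2)
            for code, name in ZONE_NAMES.items()
            if code != ZONE_BACKGROUND
        }

    @property
    def tissue_px(self) -> int:
        return int(np.count_nonzero(self.labels != ZONE_BACKGROUND))


def build_zone_map(
    tissue: np.ndarray,
    pt_mask: np.ndarray,
    cv_mask: np.ndarray,
    pixel_size_um: float,
    band_um: float = 100.0,
    landmarks: list | None = None,
) -> ZoneMap:
    """Partition the tissue into the five acinar zones by 100 um distance bands.

    PT/CV zone pixels are the landmark object pixels themselves. PP is tissue
    within ``band_um`` (Euclidean, measured from the object boundary via the
    distance transform) of any PT object, PC likewise for CV; pixels within
    band of both go to the nearer landmark class (exact ties to PP); all
    remaining tissue is transitional. With no landmarks at all, the entire
    tissue is transitional and a warning is raised.
    """
    if not pixel_size_um > 0:
        raise ValueError("pixel_size_um must be positive")
    tissue = np.asarray(tissue, dtype=bool)
    pt_mask = np.asarray(pt_mask, dtype=bool) & tissue
    cv_mask = np.asarray(cv_mask, dtype=bool) & tissue
    labels = np.zeros(tissue.shape, dtype=np.uint8)
    labels[tissue] = ZONE_TS

    has_pt, has_cv = pt_mask.any(), cv_mask.any()
    if not has_pt and not has_cv:
        warnings.warn("no PT/CV landmarks; entire tissue labeled transitional",
                      stacklevel=2)
        return ZoneMap(labels, pixel_size_um, band_um, landmarks)

    inf = np.inf
    d_pt = (
        ndi.distance_transform_edt(~pt_mask) * pixel_size_um
        if has_pt
        else np.full(tissue.shape, inf)
    )
    d_cv = (
        ndi.distance_transform_edt(~cv_mask) * pixel_size_um
        if has_cv
        else np.full(tissue.shape, inf)
    )

    free = tissue & ~pt_mask & ~cv_mask
    pp = free & (d_pt <= band_um) & ((d_pt <= d_cv) | (d_cv > band_um))
    pc = free & (d_cv <= band_um) & ((d_cv < d_pt) | (d_pt > band_um))
    labels[pp] = ZONE_PP
    labels[pc] = ZONE_PC
    labels[pt_mask] = ZONE_PT
    labels[cv_mask] = ZONE_CV
    return ZoneMap(labels, pixel_size_um, band_um, landmarks)


def rasterize_landmarks(
    landmarks: Iterable, shape: tuple[int, int], pixel_size_um: float
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize circular (class, center, radius) landmarks into PT/CV masks."""
    pt = np.zeros(shape, dtype=bool)
    cv = np.zeros(shape, dtype=bool)
    for lm in landmarks:
        target = pt if lm.cls == "PT" else cv
        _paint_disc(target, lm.x_um / pixel_size_um, lm.y_um / pixel_size_um,
                    lm.radius_um / pixel_size_um)
    return pt, cv


def _paint_disc(mask: np.ndarray, cx: float, cy: float, r: float) -> None:
    h, w = mask.shape
    r0, r1 = max(0, int(cy - r) - 1), min(h, int(cy + r) + 2)
    c0, c1 = max(0, int(cx - r) - 1), min(w, int(cx + r) + 2)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.ogrid[r0:r1, c0:c1]
    mask[r0:r1, c0:c1] |= (yy + 0.5 - cy) ** 2 + (xx + 0.5 - cx) ** 2 <= r**2


def cavities_to_landmark_masks(
    labeled: Sequence[CavityObject], shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Paint PT- and CV-classified cavity pixels into landmark masks."""
    pt = np.zeros(shape, dtype=bool)
    cv = np.zeros(shape, dtype=bool)
    for obj in labeled:
        if obj.label == "PT":
            pt[obj.bbox] |= obj.mask
        elif obj.label == "CV":
            cv[obj.bbox] |= obj.mask
    return pt, cv
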