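import numpy as np
import pytest

import hepzone as hz
from hepzone.segment import CavityObject, detect_cavities, section_support, tissue_mask, collagen_mask
from hepzone.zonation import (
    ZONE_CV,
    ZONE_PC,
    ZONE_PP,
    ZONE_PT,
    ZONE_TS,
    ClassificationError,
    build_zone_map,
    classify_objects,
    default_rule_tree,
    fit_tree,
    rasterize_landmarks,
    ObjectClassTree,
)

from conftest import COARSE_PS


def _cavity(**kw) -> CavityObject:
    base = dict(
        id=1,
        bbox=(slice(0, 4), slice(0, 4)),
        mask=np.ones((4, 4), bool),
        centroid_um=(10.0, 10.0),
        area_um2=113.0,
        equivalent_diameter_um=12.0,
        circularity=0.95,
        solidity=0.98,
        collagen_ring_fraction=0.0,
        border=False,
    )
    base.update(kw)
    return CavityObject(**base)


class TestRuleTree:
    @pytest.mark.parametrize(
        "kw, expected",
        [
            (dict(), "vacuole"),  # 12 um round hollow, bare rim
            (dict(area_um2=1963.0, equivalent_diameter_um=50.0,
                  collagen_ring_fraction=0.6), "PT"),
            (dict(area_um2=5027.0, equivalent_diameter_um=80.0,
                  collagen_ring_fraction=0.05), "CV"),
            (dict(border=True), "crack"),
            (dict(collagen_ring_fraction=0.4), "vessel_duct"),  # sheathed, small
            (dict(circularity=0.3), "vessel_duct"),  # irregular hollow
            (dict(equivalent_diameter_um=3.0, area_um2=7.0), "vessel_duct"),
        ],
    )
    def test_rule_cases(self, kw, expected):
        [labeled] = classify_objects([_cavity(**kw)])
        assert labeled.label == expected

    def test_border_objects_never_vacuole(self):
        # even a tree that says "vacuole" is overridden for border objects
        from hepzone.zonation import TreeNode

        always_vacuole = ObjectClassTree(root=TreeNode(label="vacuole"))
        [labeled] = classify_objects([_cavity(border=True)], always_vacuole)
        assert labeled.label != "vacuole"

    def test_round_trip_json(self):
        tree = default_rule_tree()
        clone = ObjectClassTree.from_json(tree.to_json())
        obj = _cavity(area_um2=1963.0, collagen_ring_fraction=0.6)
        assert clone.predict_one(obj) == tree.predict_one(obj)

    def test_missing_feature_names_object(self):
        broken = _cavity()
        broken.circularity = None
        with pytest.raises(ClassificationError, match="id=1"):
            classify_objects([broken])

    def test_object_accuracy_on_synthetic_section(self, d2_section):
        image, gt = d2_section
        ps = image.pixel_size_um
        tissue = tissue_mask(image.tpef, ps)
        coll = collagen_mask(image.shg, section_support(tissue), ps)
        labeled = classify_objects(detect_cavities(image.tpef, tissue, coll, ps))
        # evaluate over the {PT, CV, vacuole} ground-truth objects
        import math

        correct = total = 0
        for lm in gt.landmark_list:
            total += 1
            hits = [
                c for c in labeled
                if math.hypot(c.centroid_um[0] - lm.x_um, c.centroid_um[1] - lm.y_um)
                < lm.radius_um
            ]
            correct += bool(hits and hits[0].label == lm.cls)
        from scipy import ndimage as ndi

        vac_labels, n_vac = ndi.label(gt.vacuole_mask)
        centers = ndi.center_of_mass(gt.vacuole_mask, vac_labels, range(1, n_vac + 1))
        by_px = {}
        for c in labeled:
            by_px[(c.bbox[0].start, c.bbox[1].start)] = c
        for cy, cx in centers:
            total += 1
            x_um, y_um = cx * ps, cy * ps
            hits = [
                c for c in labeled
                if math.hypot(c.centroid_um[0] - x_um, c.centroid_um[1] - y_um) < 12.0
            ]
            correct += bool(hits and hits[0].label == "vacuole")
        assert total > 50
        assert correct / total >= 0.95


class TestFitTree:
    def _training_set(self, rng, n=120):
        objs = []
        for i in range(n):
            if i % 2:  # vacuole-like
                o = _cavity(
                    id=i,
                    area_um2=rng.uniform(50, 400),
                    equivalent_diameter_um=rng.uniform(6, 20),
                    collagen_ring_fraction=rng.uniform(0, 0.1),
                ).with_label("vacuole")
            else:  # portal-like
                o = _cavity(
                    id=i,
                    area_um2=rng.uniform(1500, 3000),
                    equivalent_diameter_um=rng.uniform(40, 60),
                    collagen_ring_fraction=rng.uniform(0.5, 0.9),
                ).with_label("PT")
            objs.append(o)
        return objs

    def test_separable_classes_fit_perfectly(self):
        rng = np.random.default_rng(0)
        objs = self._training_set(rng)
        tree = fit_tree(objs, max_depth=3, seed=0)
        assert all(tree.predict_one(o) == o.label for o in objs)

    def test_single_class_yields_one_leaf_with_warning(self):
        objs = [_cavity(id=i).with_label("vacuole") for i in range(5)]
        with pytest.warns(UserWarning):
            tree = fit_tree(objs)
        assert tree.root.is_leaf and tree.root.label == "vacuole"

    def test_trained_tree_generalizes_across_seeds(self):
        rng_train, rng_test = np.random.default_rng(1), np.random.default_rng(2)
        tree = fit_tree(self._training_set(rng_train), max_depth=4, seed=0)
        test = self._training_set(rng_test)
        acc_trained = np.mean([tree.predict_one(o) == o.label for o in test])
        rule = default_rule_tree()
        acc_rule = np.mean([rule.predict_one(o) == o.label for o in test])
        assert acc_trained >= acc_rule

    def test_depth_bounded(self):
        tree = fit_tree(self._training_set(np.random.default_rng(3)), max_depth=2)
        assert tree.depth <= 2


class TestZoneMap:
    def _single_pt(self, size=400, r_um=25.0, ps=1.0, with_cv=False):
        tissue = np.ones((size, size), bool)
        lms = [hz.Landmark("PT", size * ps / 4, size * ps / 2, r_um)]
        if with_cv:
            lms.append(hz.Landmark("CV", 3 * size * ps / 4, size * ps / 2, 40.0))
        pt, cv = rasterize_landmarks(lms, (size, size), ps)
        return tissue, pt, cv, lms

    def test_band_membership_at_50_and_150_um(self):
        tissue, pt, cv, lms = self._single_pt()
        zm = build_zone_map(tissue, pt, cv, 1.0, 100.0)
        x0, y0, r = lms[0].x_um, lms[0].y_um, lms[0].radius_um
        assert zm.labels[int(y0), int(x0 + r + 50)] == ZONE_PP
        assert zm.labels[int(y0), int(x0 + r + 150)] == ZONE_TS
        assert zm.labels[int(y0), int(x0)] == ZONE_PT

    def test_overlap_resolved_to_nearer_landmark(self):
        # equal-radius landmarks placed symmetrically about a pixel center
        tissue = np.ones((300, 300), bool)
        lms = [hz.Landmark("PT", 50.5, 150.5, 20.0),
               hz.Landmark("CV", 250.5, 150.5, 20.0)]
        pt, cv = rasterize_landmarks(lms, (300, 300), 1.0)
        zm = build_zone_map(tissue, pt, cv, 1.0, 100.0)
        assert zm.labels[150, 130] == ZONE_PP  # 60 um from PT, 100 from CV
        assert zm.labels[150, 170] == ZONE_PC  # 60 um from CV, 100 from PT
        # midpoint is exactly equidistant: tie goes periportal
        assert zm.labels[150, 150] == ZONE_PP

    def test_no_landmarks_all_transitional_with_warning(self):
        tissue = np.ones((64, 64), bool)
        empty = np.zeros_like(tissue)
        with pytest.warns(UserWarning):
            zm = build_zone_map(tissue, empty, empty, 1.0)
        assert np.all(zm.labels[tissue] == ZONE_TS)

    def test_partition_of_tissue(self, d2_section):
        _, gt = d2_section
        labels = gt.zone_map_true.labels
        zones = [ZONE_PT, ZONE_PP, ZONE_TS, ZONE_PC, ZONE_CV]
        total = sum(int(np.count_nonzero(labels == z)) for z in zones)
        assert total == int(np.count_nonzero(labels > 0))

    def test_band_monotonicity(self):
        tissue, pt, cv, _ = self._single_pt(with_cv=True)
        a = build_zone_map(tissue, pt, cv, 1.0, 80.0)
        b = build_zone_map(tissue, pt, cv, 1.0, 120.0)
        for zone in (ZONE_PP, ZONE_PC):
            assert np.count_nonzero(b.labels == zone) >= np.count_nonzero(
                a.labels == zone
            )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_nearest_boundary_oracle(self, seed):
        # exhaustive per-pixel distance computation on a small image
        rng = np.random.default_rng(seed)
        size, ps, band = 96, 2.0, 100.0
        tissue = np.ones((size, size), bool)
        pt = np.zeros_like(tissue)
        cv = np.zeros_like(tissue)
        for mask, r in ((pt, 6), (cv, 9)):
            cy, cx = rng.integers(15, size - 15, 2)
            yy, xx = np.ogrid[:size, :size]
            mask[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = True
        pt &= ~cv
        zm = build_zone_map(tissue, pt, cv, ps, band)

        pts = np.argwhere(pt)
        cvs = np.argwhere(cv)
        coords = np.argwhere(tissue)
        d_pt = np.sqrt(
            ((coords[:, None, :] - pts[None, :, :]) ** 2).sum(-1).min(1)
        ) * ps
        d_cv = np.sqrt(
            ((coords[:, None, :] - cvs[None, :, :]) ** 2).sum(-1).min(1)
        ) * ps
        expected = np.full(len(coords), ZONE_TS)
        in_pp = (d_pt <= band) & ((d_pt <= d_cv) | (d_cv > band))
        in_pc = (d_cv <= band) & ((d_cv < d_pt) | (d_pt > band))
        expected[in_pp] = ZONE_PP
        expected[in_pc] = ZONE_PC
        expected[d_pt == 0] = ZONE_PT
        expected[(d_cv == 0)] = ZONE_CV
        got = zm.labels[coords[:, 0], coords[:, 1]]
        assert np.array_equal(got, expected)

    def test_agrees_with_generator_ground_truth(self, d2_section):
        # same geometry routine, perfect landmarks -> identical zone maps
        image, gt = d2_section
        ps = image.pixel_size_um
        support = gt.zone_map_true.labels > 0
        pt, cv = rasterize_landmarks(gt.landmark_list, image.shape, ps)
        rebuilt = build_zone_map(support, pt, cv, ps, 100.0)
        assert np.array_equal(rebuilt.labels, gt.zone_map_true.labels)
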