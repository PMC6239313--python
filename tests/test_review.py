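import itertools

import numpy as np
import pytest

from benthoscope.geometry import min_enclosing_circle
from benthoscope.proposals import TrainingProposal
from benthoscope.review import (CircleAnnotation, OracleBackend,
                                ThresholdBackend, TrainingSample,
                                boost_training_samples, filter_proposals,
                                inscribed_circle, make_training_samples,
                                masks_to_candidates, pad_to_multiple_64,
                                refine_proposal, render_circle_mask,
                                review_candidates, unpad)


def _ranked(n, image_id="im"):
    return [TrainingProposal(image_id, 0, 0, 30, float(n - i), i)
            for i in range(n)]


class TestFilterProposals:
    def test_per_class_limit_caps_acceptance(self):
        ranked = _ranked(700)
        decisions = {i: "shell" for i in range(700)}
        accepted, counts = filter_proposals(ranked, decisions, per_class_limit=600)
        assert len(accepted) == 600
        assert counts == {"shell": 600}

    def test_all_rejected_gives_empty_set(self):
        ranked = _ranked(10)
        accepted, counts = filter_proposals(ranked, {i: None for i in range(10)})
        assert accepted == [] and counts == {}

    def test_two_class_outcome_with_one_class_capped(self):
        # a review session where one class saturates the limit and the
        # other does not (the benchmark survey outcome shape: 440 + 600)
        ranked = _ranked(1200)
        decisions = {i: ("animal" if i % 3 == 0 else "shell") for i in range(1200)}
        accepted, counts = filter_proposals(ranked, decisions,
                                            per_class_limit=600)
        assert counts["shell"] == 600
        assert counts["animal"] == 400
        assert len(accepted) == 1000

    def test_decisions_must_form_ranking_prefix(self):
        with pytest.raises(ValueError):
            filter_proposals(_ranked(10), {0: "a", 2: "b"})

    def test_unknown_proposal_index_rejected(self):
        with pytest.raises(ValueError):
            filter_proposals(_ranked(3), {5: "a"})


class TestRefinement:
    def test_default_suggestion_is_inscribed_circle(self):
        p = TrainingProposal("im", 100, 100, 30, 1.0, 0)
        c = refine_proposal(p, "shell")
        assert (c.cx, c.cy) == (114.5, 114.5)
        assert c.radius == 15.0
        assert c.provenance == "refined"

    def test_adjusted_circle_passes_through(self):
        p = TrainingProposal("im", 100, 100, 30, 1.0, 0)
        adj = CircleAnnotation("im", 110.0, 112.0, 12.0, "shell", "refined")
        c = refine_proposal(p, "shell", adj, image_size=(500, 500))
        assert c.radius == 12.0 and (c.cx, c.cy) == (110.0, 112.0)

    def test_circle_outside_image_rejected(self):
        p = TrainingProposal("im", 100, 100, 30, 1.0, 0)
        adj = CircleAnnotation("im", 600.0, 10.0, 5.0, "shell", "refined")
        with pytest.raises(ValueError):
            refine_proposal(p, "shell", adj, image_size=(500, 500))

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            CircleAnnotation("im", 10, 10, 0.0, "x", "refined")


class TestTrainingSamples:
    def _image(self, h, w):
        rng = np.random.default_rng(0)
        return rng.random((h, w, 3)).astype(np.float32)

    def test_centred_crop_in_large_image(self):
        img = self._image(2000, 2000)
        c = CircleAnnotation("a", 1000.0, 1000.0, 20.0, "x", "refined")
        (s,) = make_training_samples([c], {"a": img})
        assert s.crop.shape == (500, 500, 3)
        assert (s.circles[0].cx, s.circles[0].cy) == (250.0, 250.0)

    def test_border_circle_shifts_crop_inward(self):
        img = self._image(800, 800)
        c = CircleAnnotation("a", 10.0, 10.0, 5.0, "x", "refined")
        (s,) = make_training_samples([c], {"a": img})
        assert s.origin == (0, 0)
        assert (s.circles[0].cx, s.circles[0].cy) == (10.0, 10.0)

    def test_nearby_circles_carried_into_same_crop(self):
        img = self._image(1000, 1000)
        c1 = CircleAnnotation("a", 400.0, 400.0, 10.0, "x", "refined")
        c2 = CircleAnnotation("a", 450.0, 420.0, 8.0, "y", "refined")
        samples = make_training_samples([c1, c2], {"a": img})
        assert all(len(s.circles) == 2 for s in samples)

    def test_small_image_shrinks_crop(self):
        img = self._image(300, 260)
        c = CircleAnnotation("a", 100.0, 100.0, 10.0, "x", "refined")
        (s,) = make_training_samples([c], {"a": img})
        assert s.crop.shape == (300, 260, 3)

    def test_circle_mask_marks_inside_pixels(self):
        img = self._image(600, 600)
        c = CircleAnnotation("a", 300.0, 300.0, 30.0, "x", "refined")
        (s,) = make_training_samples([c], {"a": img})
        mask = render_circle_mask(s)
        area = np.pi * 30**2
        assert abs(int((mask > 0).sum()) - area) / area < 0.05


class TestBoosting:
    def _sample(self):
        rng = np.random.default_rng(1)
        crop = rng.random((40, 40, 3)).astype(np.float32)
        circ = CircleAnnotation("a", 10.0, 16.0, 5.0, "x", "refined")
        return TrainingSample(crop=crop, circles=[circ], source_image_id="a")

    def test_first_eight_variants_are_distinct_dihedral(self):
        variants = list(boost_training_samples([self._sample()], 8, seed=0))
        assert len(variants) == 8
        keys = {v.crop.tobytes() for v in variants}
        assert len(keys) == 8

    def test_horizontal_flip_moves_circle_centre(self):
        crop = np.zeros((500, 500, 3), dtype=np.float32)
        circ = CircleAnnotation("a", 100.0, 100.0, 5.0, "x", "refined")
        s = TrainingSample(crop=crop, circles=[circ], source_image_id="a")
        # variant 1 in the dihedral enumeration is the horizontal flip
        v = list(boost_training_samples([s], 2, seed=0))[1]
        assert (v.circles[0].cx, v.circles[0].cy) == (399.0, 100.0)

    def test_same_seed_gives_identical_stream(self):
        s = self._sample()
        a = list(boost_training_samples([s], 20, seed=9))
        b = list(boost_training_samples([s], 20, seed=9))
        assert all(np.array_equal(x.crop, y.crop) for x, y in zip(a, b))
        assert all(x.circles[0] == y.circles[0] for x, y in zip(a, b))

    def test_augmented_circle_stays_on_planted_disk(self):
        # render a disk, transform, re-render from the transformed circle:
        # the two masks must align almost perfectly
        crop = np.zeros((64, 64, 3), dtype=np.float32)
        yy, xx = np.mgrid[0:64, 0:64]
        disk = (xx - 20) ** 2 + (yy - 28) ** 2 <= 8**2
        crop[disk] = 1.0
        circ = CircleAnnotation("a", 20.0, 28.0, 8.0, "x", "refined")
        s = TrainingSample(crop=crop, circles=[circ], source_image_id="a")
        for v in boost_training_samples([s], 24, seed=4):
            rendered = v.crop[:, :, 0] > 0.5
            c = v.circles[0]
            circle_mask = (xx - c.cx) ** 2 + (yy - c.cy) ** 2 <= c.radius**2
            inter = (rendered & circle_mask).sum()
            union = (rendered | circle_mask).sum()
            assert inter / union >= 0.9

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            list(boost_training_samples([], 5))


class TestPadding:
    @pytest.mark.parametrize("shape,expected", [
        ((2048, 2448), (2048, 2496)),
        ((64, 64), (64, 64)),
        ((1, 1), (64, 64)),
        ((65, 129), (128, 192)),
    ])
    def test_padded_shape(self, shape, expected):
        img = np.ones(shape + (3,), dtype=np.float32)
        padded, orig = pad_to_multiple_64(img)
        assert padded.shape[:2] == expected
        assert orig == shape
        assert padded[shape[0]:, :, :].sum() == 0
        assert padded[:, shape[1]:, :].sum() == 0

    def test_unpad_restores_original_exactly(self):
        rng = np.random.default_rng(0)
        img = rng.random((70, 100, 3)).astype(np.float32)
        padded, orig = pad_to_multiple_64(img)
        assert np.array_equal(unpad(padded, orig), img)


def brute_force_mec(points):
    """Exact minimum enclosing circle by trying all pairs and triples."""
    from benthoscope.geometry import _circle_three, _circle_two, _inside

    pts = [tuple(map(float, p)) for p in points]
    best = None
    if len(pts) == 1:
        return (pts[0][0], pts[0][1], 0.0)
    candidates = [_circle_two(p, q) for p, q in itertools.combinations(pts, 2)]
    candidates += [_circle_three(p, q, s)
                   for p, q, s in itertools.combinations(pts, 3)]
    for c in candidates:
        if all(_inside(c, p) for p in pts):
            if best is None or c[2] < best[2]:
                best = c
    return best


class TestMinEnclosingCircle:
    def test_single_pixel_degenerates_to_radius_zero(self):
        cx, cy, r = min_enclosing_circle([(5, 7)])
        assert (cx, cy, r) == (5.0, 7.0, 0.0)

    def test_3x3_square_has_sqrt2_radius_at_centre(self):
        pts = [(x, y) for x in range(3) for y in range(3)]
        cx, cy, r = min_enclosing_circle(pts)
        assert (cx, cy) == pytest.approx((1.0, 1.0))
        assert r == pytest.approx(np.sqrt(2.0))

    def test_matches_brute_force_on_random_small_regions(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            n = int(rng.integers(2, 26))
            pts = np.unique(rng.integers(0, 12, size=(n, 2)), axis=0)
            got = min_enclosing_circle(pts)
            ref = brute_force_mec(pts)
            assert got[2] == pytest.approx(ref[2], abs=1e-7)
            # every point inside the returned circle
            for p in pts:
                d = np.hypot(p[0] - got[0], p[1] - got[1])
                assert d <= got[2] + 1e-6

    def test_collinear_points(self):
        cx, cy, r = min_enclosing_circle([(0, 0), (2, 0), (5, 0)])
        assert (cx, cy, r) == pytest.approx((2.5, 0.0, 2.5))


class TestMasksToCandidates:
    def test_single_pixel_gets_displayable_radius(self):
        mask = np.zeros((10, 10), dtype=int)
        mask[4, 6] = 2
        (c,) = masks_to_candidates(mask, image_id="im")
        assert (c.cx, c.cy) == (6.0, 4.0)
        assert c.radius == 0.5
        assert c.provenance == "candidate"

    def test_3x3_region_radius(self):
        mask = np.zeros((10, 10), dtype=int)
        mask[2:5, 3:6] = 1
        (c,) = masks_to_candidates(mask)
        assert (c.cx, c.cy) == pytest.approx((4.0, 3.0))
        assert c.radius == pytest.approx(np.sqrt(2.0))

    def test_touching_regions_of_different_classes_merge(self):
        mask = np.zeros((8, 8), dtype=int)
        mask[2, 2:4] = 1
        mask[2, 4:6] = 2  # different class, 8-connected to the first
        cands = masks_to_candidates(mask)
        assert len(cands) == 1

    def test_empty_mask_gives_no_candidates(self):
        assert masks_to_candidates(np.zeros((5, 5), dtype=int)) == []


class TestCandidateReview:
    def _candidates(self, n):
        return [CircleAnnotation("im", float(i), float(i), 1.0, "ooi", "candidate")
                for i in range(n)]

    def test_accepted_subset_counted(self):
        cands = self._candidates(501)
        accepted, counts = review_candidates(cands, list(range(276)))
        assert len(accepted) == 276
        assert counts == {"ooi": 276}
        assert all(c.provenance == "accepted" for c in accepted)

    def test_none_accepted(self):
        accepted, counts = review_candidates(self._candidates(5), [])
        assert accepted == [] and counts == {}

    def test_accept_all_is_idempotent(self):
        cands = self._candidates(4)
        a1, _ = review_candidates(cands, range(4))
        a2, _ = review_candidates(a1, range(4))
        assert [(c.cx, c.cy) for c in a1] == [(c.cx, c.cy) for c in a2]

    def test_unknown_index_rejected(self):
        with pytest.raises(ValueError):
            review_candidates(self._candidates(2), [7])


class TestBackends:
    def test_threshold_backend_finds_bright_blob(self):
        img = np.full((70, 90, 3), 0.2, dtype=np.float32)
        yy, xx = np.mgrid[0:70, 0:90]
        img[(xx - 40) ** 2 + (yy - 30) ** 2 <= 36] = 0.9
        backend = ThresholdBackend(threshold=0.5)
        cands = backend.candidates(img, image_id="b")
        assert len(cands) == 1
        assert cands[0].cx == pytest.approx(40, abs=1)
        assert cands[0].cy == pytest.approx(30, abs=1)

    def test_oracle_backend_mask_shape_contract(self):
        img = np.zeros((50, 50, 3), dtype=np.float32)
        mask = np.zeros((50, 50), dtype=int)
        mask[10, 10] = 1
        cands = OracleBackend(mask).candidates(img, image_id="o")
        assert len(cands) == 1


class TestCocoExport:
    def test_circle_coco_json(self, tmp_path):
        import json

        from benthoscope.review import write_circles_coco

        circles = [CircleAnnotation("im", 10.0, 12.0, 4.0, "shell", "accepted")]
        path = tmp_path / "c.json"
        write_circles_coco(circles, path)
        data = json.loads(path.read_text())
        assert data["annotations"][0]["circle"] == [10.0, 12.0, 4.0]
        assert data["annotations"][0]["bbox"] == [6.0, 8.0, 8.0, 8.0]
        assert data["categories"] == [{"id": 1, "name": "shell"}]
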