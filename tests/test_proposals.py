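import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from benthoscope.novelty import NoveltyMap
from benthoscope.proposals import (TrainingProposal, compute_threshold,
                                   extract_regions, percentile99,
                                   proposals_from_map, rank_proposals,
                                   read_proposals_csv, region_to_proposal,
                                   segment_novelty_map, write_proposals_csv)


def _nm(values, image_id="im"):
    return NoveltyMap(image_id=image_id,
                      values=np.asarray(values, dtype=np.float32), dilated=True)


def percentile_oracle(values, q=99.0):
    """Sort-based percentile with linear interpolation between order stats."""
    v = np.sort(np.asarray(values, dtype=np.float64).ravel())
    pos = (len(v) - 1) * q / 100.0
    lo, hi = int(np.floor(pos)), int(np.ceil(pos))
    frac = pos - lo
    return v[lo] * (1 - frac) + v[hi] * frac


class TestThreshold:
    def test_mean_of_two_map_percentiles(self):
        # constant maps: P99 equals the constant
        t = compute_threshold([_nm(np.full((10, 10), 2.0)),
                               _nm(np.full((10, 10), 4.0))])
        assert t.t_k == pytest.approx(3.0)

    def test_single_constant_map(self):
        t = compute_threshold([_nm(np.full((5, 5), 1.25))])
        assert t.t_k == pytest.approx(1.25)

    def test_percentile_matches_sort_oracle(self):
        values = np.arange(10_000, dtype=np.float64).reshape(100, 100)
        assert percentile99(values) == pytest.approx(percentile_oracle(values))
        rng = np.random.default_rng(3)
        noisy = rng.random((57, 43))
        assert percentile99(noisy) == pytest.approx(percentile_oracle(noisy))

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            compute_threshold([])


class TestSegmentation:
    def test_all_below_threshold_gives_empty_mask(self):
        mask = segment_novelty_map(_nm(np.ones((4, 4))), 2.0)
        assert not mask.any()

    def test_zero_threshold_on_positive_map_gives_full_mask(self):
        mask = segment_novelty_map(_nm(np.ones((4, 4))), 0.0)
        assert mask.all()

    def test_strict_inequality(self):
        mask = segment_novelty_map(_nm(np.ones((4, 4))), 1.0)
        assert not mask.any()

    @given(st.floats(0, 2), st.floats(0, 2))
    @settings(max_examples=30, deadline=None)
    def test_mask_size_nonincreasing_in_threshold(self, t1, t2):
        rng = np.random.default_rng(5)
        nm = _nm(rng.random((12, 12)))
        lo, hi = sorted([t1, t2])
        assert segment_novelty_map(nm, lo).sum() >= segment_novelty_map(nm, hi).sum()


class TestRegions:
    def test_two_disjoint_squares(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[1:4, 1:4] = True
        mask[7:10, 7:10] = True
        regions = extract_regions(mask)
        assert len(regions) == 2
        assert sorted(len(r) for r in regions) == [9, 9]

    def test_empty_mask_gives_no_regions(self):
        assert extract_regions(np.zeros((5, 5), dtype=bool)) == []

    def test_diagonal_pixels_join_under_8_connectivity(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = mask[1, 1] = mask[2, 2] = True
        assert len(extract_regions(mask)) == 1


class TestRegionToProposal:
    def _map_with_region(self, h=100, w=100):
        values = np.zeros((h, w), dtype=np.float32)
        return _nm(values)

    def test_small_region_expands_to_minimum_30px_box(self):
        nm = self._map_with_region()
        # tight box 10 wide x 5 tall at (40..49, 50..54)
        region = np.array([(y, x) for y in range(50, 55) for x in range(40, 50)])
        p = region_to_proposal(region, nm)
        assert p.edge == 30
        # centred on the tight-box centre (44.5, 52)
        assert p.x + p.edge / 2 == pytest.approx(45, abs=1.0)
        assert p.y + p.edge / 2 == pytest.approx(52.5, abs=1.0)

    def test_large_region_uses_max_dimension(self):
        nm = self._map_with_region()
        region = np.array([(y, x) for y in range(10, 35) for x in range(20, 60)])
        p = region_to_proposal(region, nm)  # tight box 40 x 25
        assert p.edge == 40

    def test_score_is_region_novelty_sum(self):
        nm = self._map_with_region()
        nm.values[3, 4] = 0.5
        nm.values[3, 5] = 1.5
        region = np.array([(3, 4), (3, 5)])
        p = region_to_proposal(region, nm)
        assert p.score == pytest.approx(2.0)

    def test_box_near_border_shifted_inward_and_square(self):
        nm = self._map_with_region(h=60, w=60)
        region = np.array([(0, 0), (0, 1), (1, 0)])
        p = region_to_proposal(region, nm)
        assert p.edge == 30
        assert p.x == 0 and p.y == 0

    def test_box_contains_tight_box_when_space_allows(self):
        rng = np.random.default_rng(8)
        nm = self._map_with_region(h=200, w=200)
        for _ in range(20):
            ys = rng.integers(40, 160, size=6)
            xs = rng.integers(40, 160, size=6)
            region = np.column_stack([ys, xs])
            p = region_to_proposal(region, nm)
            assert p.x <= xs.min() and p.x + p.edge > xs.max()
            assert p.y <= ys.min() and p.y + p.edge > ys.max()

    def test_proposal_count_equals_region_count(self):
        values = np.zeros((80, 80), dtype=np.float32)
        values[10:14, 10:14] = 5.0
        values[50:52, 60:62] = 7.0
        nm = _nm(values)
        props = proposals_from_map(nm, t_k=1.0)
        assert len(props) == 2


class TestRanking:
    def _props(self, scores):
        return [TrainingProposal("im", 0, 0, 30, s, i)
                for i, s in enumerate(scores)]

    def test_descending_by_score(self):
        ranked = rank_proposals(self._props([1.0, 3.0, 2.0]))
        assert [p.score for p in ranked] == [3.0, 2.0, 1.0]

    def test_ties_preserve_input_order(self):
        ranked = rank_proposals(self._props([2.0, 2.0, 2.0]))
        assert [p.region_id for p in ranked] == [0, 1, 2]

    def test_idempotent(self):
        ranked = rank_proposals(self._props([5.0, 1.0, 4.0]))
        assert rank_proposals(ranked) == ranked


class TestCsvRoundtrip:
    def test_roundtrip_and_byte_determinism(self, tmp_path):
        props = [TrainingProposal("a", 1, 2, 30, 1.23456789012345, 0),
                 TrainingProposal("b", 5, 6, 42, 0.5, 3)]
        p1, p2 = tmp_path / "x.csv", tmp_path / "y.csv"
        write_proposals_csv(props, p1)
        write_proposals_csv(props, p2)
        assert p1.read_bytes() == p2.read_bytes()
        back = read_proposals_csv(p1)
        assert back == props


class TestExports:
    def test_coco_json_structure(self, tmp_path):
        import json

        from benthoscope.proposals import write_proposals_coco

        props = [TrainingProposal("a", 1, 2, 30, 2.0, 0),
                 TrainingProposal("b", 5, 6, 42, 1.0, 1)]
        path = tmp_path / "props.json"
        write_proposals_coco(props, path)
        data = json.loads(path.read_text())
        assert len(data["images"]) == 2
        assert data["annotations"][0]["bbox"] == [1, 2, 30, 30]
        assert data["categories"][0]["name"] == "interesting"

    def test_crops_named_by_rank(self, tmp_path):
        import numpy as np

        from benthoscope.proposals import export_proposal_crops

        rng = np.random.default_rng(0)
        pixels = {"a": rng.random((80, 80, 3)).astype(np.float32)}
        ranked = rank_proposals([TrainingProposal("a", 0, 0, 30, 1.0, 0),
                                 TrainingProposal("a", 40, 40, 30, 5.0, 1)])
        paths = export_proposal_crops(ranked, pixels, tmp_path / "crops")
        assert "rank00000" in paths[0] and "_r1" in paths[0]  # top score first
        assert all((tmp_path / "crops").glob("*.png"))
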