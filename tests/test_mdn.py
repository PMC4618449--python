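import numpy as np
import pytest

from lhseg.mdn import MdnParams, mdn_value, merge_by_mdn
from lhseg.mrs import MrsParams, segment_slice
from lhseg.stack import ChannelRole


def _column_graph(values, width=2, height=6):
    """Image of constant vertical stripes -> one segment per stripe."""
    img = np.repeat(
        np.repeat(np.array([values], dtype=float), height, axis=0),
        width,
        axis=1,
    )
    g = segment_slice(img, MrsParams(scale=1.0, shape_weight=0.0))
    assert len(g.segments) == len(values)
    return g


class TestMdnValue:
    def test_single_neighbor_weight_cancels(self):
        g = _column_graph([100.0, 40.0])
        v = next(i for i, s in g.segments.items() if s.mean_intensity[0] == 100)
        assert mdn_value(g, v, d=1.0) == pytest.approx(60.0)

    def test_equal_neighbors_give_zero(self):
        # a constant image collapses to one segment, so build stripes
        # with distinct-but-nearly-equal means to keep them separate
        img = np.zeros((6, 6))
        img[:, :2] = 70
        img[:, 2:4] = 70.0001
        img[:, 4:] = 70
        g = segment_slice(img, MrsParams(scale=0.001, shape_weight=0.0))
        mid = next(
            i
            for i, s in g.segments.items()
            if s.mean_intensity[0] == pytest.approx(70.0001)
        )
        assert mdn_value(g, mid, d=1.0) == pytest.approx(0.0, abs=1e-3)

    def test_two_equal_weight_neighbors(self):
        # center stripe flanked by 40 and 80 with equal border lengths:
        # MDN(100) = ((100-40) + (100-80)) / 2 = 40
        g = _column_graph([40.0, 100.0, 80.0])
        v = next(i for i, s in g.segments.items() if s.mean_intensity[0] == 100)
        assert mdn_value(g, v, d=1.0) == pytest.approx(40.0)

    def test_signed_statistic(self):
        g = _column_graph([100.0, 40.0])
        u = next(i for i, s in g.segments.items() if s.mean_intensity[0] == 40)
        assert mdn_value(g, u, d=1.0) == pytest.approx(-60.0)

    def test_unknown_segment_errors(self):
        g = _column_graph([1.0, 2.0])
        with pytest.raises(KeyError):
            mdn_value(g, 99)


DISC_PARAMS = MdnParams(
    threshold=60.0, distance_mode="auto", min_object_area=5,
    foreground_min_intensity=60.0,
)


def _disc_image(centers, radius=6, value=200.0, bg=10.0, shape=(48, 48), noise=3.0):
    rng = np.random.default_rng(0)
    yy, xx = np.indices(shape)
    img = np.full(shape, bg)
    truth = np.zeros(shape, dtype=bool)
    for cy, cx in centers:
        m = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        img[m] = value
        truth |= m
    return img + rng.normal(0, noise, shape), truth


class TestMergeByMdn:
    def test_uniform_background_gives_no_objects(self):
        rng = np.random.default_rng(1)
        img = rng.normal(10, 3, (32, 32)).clip(0)
        g = segment_slice(img, MrsParams(scale=15))
        assert merge_by_mdn(g, DISC_PARAMS, ChannelRole.DID) == []

    def test_single_disc_recovered(self):
        img, truth = _disc_image([(24, 24)])
        g = segment_slice(img, MrsParams(scale=15))
        objs = merge_by_mdn(g, DISC_PARAMS, ChannelRole.DID)
        assert len(objs) == 1
        auto = np.zeros_like(truth)
        for y, x in objs[0].pixel_set:
            auto[y, x] = True
        inter = (auto & truth).sum()
        union = (auto | truth).sum()
        assert inter / union >= 0.9

    def test_two_separated_discs(self):
        img, _ = _disc_image([(14, 14), (34, 34)])
        g = segment_slice(img, MrsParams(scale=15))
        objs = merge_by_mdn(g, DISC_PARAMS, ChannelRole.DID)
        assert len(objs) == 2

    def test_min_area_filter(self):
        img, _ = _disc_image([(24, 24)], radius=2)
        g = segment_slice(img, MrsParams(scale=15))
        params = MdnParams(
            threshold=60.0, min_object_area=200, foreground_min_intensity=60.0
        )
        assert merge_by_mdn(g, params, ChannelRole.DID) == []

    def test_deterministic(self):
        img, _ = _disc_image([(20, 28)])
        g1 = segment_slice(img, MrsParams(scale=15))
        g2 = segment_slice(img, MrsParams(scale=15))
        o1 = merge_by_mdn(g1, DISC_PARAMS, ChannelRole.DID)
        o2 = merge_by_mdn(g2, DISC_PARAMS, ChannelRole.DID)
        assert [o.pixel_set for o in o1] == [o.pixel_set for o in o2]

    def test_returned_objects_stand_out_from_final_neighborhood(self):
        img, _ = _disc_image([(24, 24)])
        g = segment_slice(img, MrsParams(scale=15))
        objs, regions = merge_by_mdn(
            g, DISC_PARAMS, ChannelRole.DID, return_regions=True
        )
        # the surviving foreground regions all exceed the threshold
        # against their final neighborhood (merging has terminated)
        from lhseg.mdn import _mdn, _neighborhoods

        neigh = _neighborhoods(regions, DISC_PARAMS)
        fg_means = {round(o.mean_intensity, 6) for o in objs}
        for rid in regions.alive:
            if round(regions.mean(rid), 6) in fg_means:
                val = _mdn(regions, rid, neigh[rid], DISC_PARAMS.weighting)
                assert val >= DISC_PARAMS.threshold

    def test_termination_bounded_by_segment_count(self):
        img, _ = _disc_image([(24, 24)])
        g = segment_slice(img, MrsParams(scale=8))
        n_before = len(g.segments)
        objs, regions = merge_by_mdn(
            g, DISC_PARAMS, ChannelRole.DID, return_regions=True
        )
        assert len(regions.alive) <= n_before

    def test_intensity_diff_weighting_mode(self):
        img, _ = _disc_image([(24, 24)])
        g = segment_slice(img, MrsParams(scale=15))
        params = MdnParams(
            threshold=60.0, min_object_area=5,
            foreground_min_intensity=60.0, weighting="intensity_diff",
        )
        objs = merge_by_mdn(g, params, ChannelRole.DID)
        assert len(objs) == 1


def test_bad_params_rejected():
    with pytest.raises(ValueError):
        MdnParams(threshold=0.0)
    with pytest.raises(ValueError):
        MdnParams(threshold=1.0, distance_mode="nope")
    with pytest.raises(ValueError):
        MdnParams(threshold=1.0, weighting="nope")
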