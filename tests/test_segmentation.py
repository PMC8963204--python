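"""Thresholding and ROI delineation against the phantom pixel oracle."""

import numpy as np
import pytest

from isletcoloc.phantom import CHANNELS, ChannelStack
from isletcoloc.segmentation import (
    DEFAULT_MIN_ISLET_AREA,
    DegenerateChannelError,
    ThresholdSet,
    compute_thresholds,
    foreground_for_pair,
    segment_islets,
)
from isletcoloc.validation import iou_per_structure


def _stack_from(channel_values: dict[str, np.ndarray], shape=None) -> ChannelStack:
    shape = shape or next(iter(channel_values.values())).shape
    data = np.zeros((len(CHANNELS), *shape), dtype=np.uint16)
    for name, img in channel_values.items():
        data[CHANNELS.index(name)] = img
    return ChannelStack(data=data)


def test_otsu_threshold_strictly_between_modes():
    img = np.zeros((64, 64), dtype=np.uint16)
    img[:8] = 100
    ts = compute_thresholds(_stack_from({"CHGA": img}), method="otsu", channels=("CHGA",))
    assert 0 < ts["CHGA"] < 100


def test_fixed_method_echoes_value_for_every_channel():
    stack = _stack_from({"CHGA": np.ones((8, 8), dtype=np.uint16)})
    ts = compute_thresholds(stack, method="fixed", value=500)
    assert all(ts[c] == 500.0 for c in ("INS", "GCG", "SST", "CHGA", "MDA5"))


def test_otsu_on_constant_channel_raises():
    stack = _stack_from({"CHGA": np.full((8, 8), 7, dtype=np.uint16)})
    with pytest.raises(DegenerateChannelError):
        compute_thresholds(stack, method="otsu", channels=("CHGA",))


def test_quantile_method_and_bad_method():
    img = np.arange(100, dtype=np.uint16).reshape(10, 10) + 1
    ts = compute_thresholds(_stack_from({"MDA5": img}), method="quantile",
                            channels=("MDA5",), q=0.9)
    assert ts["MDA5"] == pytest.approx(np.quantile(img, 0.9))
    with pytest.raises(ValueError):
        compute_thresholds(_stack_from({"MDA5": img}), method="nope", channels=("MDA5",))


def test_noiseless_foreground_equals_rendered_disks(nd_noiseless):
    _ph, stack, truth = nd_noiseless
    ts = compute_thresholds(stack)
    fg = stack.channel("CHGA") >= ts["CHGA"]
    # scattered endocrine cells are also CHGA+, so islet pixels are the
    # foreground restricted to the truth support
    assert np.array_equal(fg & (truth.roi_labels > 0), truth.roi_labels > 0)
    # and thresholding at ANY level between background and marker floor
    # recovers the same disks
    for t in (1000, 20000, 39000):
        assert np.array_equal(
            (stack.channel("CHGA") >= t) & (truth.roi_labels > 0), truth.roi_labels > 0
        )


def test_segmentation_matches_ground_truth_exactly_when_noiseless(nd_noiseless):
    _ph, stack, truth = nd_noiseless
    ts = compute_thresholds(stack)
    rois = segment_islets(stack, ts)
    assert len(rois) == len(truth.categories)
    ious = iou_per_structure(rois.labels, truth.roi_labels)
    assert all(v == 1.0 for v in ious.values())


def test_blank_image_yields_empty_roiset():
    stack = _stack_from({"CHGA": np.zeros((64, 64), dtype=np.uint16)})
    ts = ThresholdSet(values={c: 10.0 for c in ("INS", "GCG", "SST", "CHGA", "MDA5")},
                      method="fixed")
    rois = segment_islets(stack, ts)
    assert len(rois) == 0
    assert not rois.labels.any()


def test_min_islet_area_filters_small_components():
    img = np.zeros((64, 64), dtype=np.uint16)
    img[10:14, 10:14] = 1000  # 16 px blob
    stack = _stack_from({"CHGA": img})
    ts = ThresholdSet(values={"CHGA": 500.0}, method="fixed")
    assert len(segment_islets(stack, ts, min_islet_area=17)) == 0
    assert len(segment_islets(stack, ts, min_islet_area=16)) == 1


def test_labels_ordered_by_descending_area():
    img = np.zeros((128, 128), dtype=np.uint16)
    img[5:15, 5:15] = 1000     # 100 px
    img[60:80, 60:90] = 1000   # 600 px
    stack = _stack_from({"CHGA": img})
    ts = ThresholdSet(values={"CHGA": 500.0}, method="fixed")
    rois = segment_islets(stack, ts, min_islet_area=10)
    assert rois.areas[1] == 600 and rois.areas[2] == 100


def test_partition_background_plus_foreground_equals_roi(nd_noisy):
    _ph, stack, truth = nd_noisy
    ts = compute_thresholds(stack)
    rois = segment_islets(stack, ts)
    assert len(rois) > 0
    for roi_id in rois.roi_ids():
        fm = foreground_for_pair(stack, rois.mask(roi_id), ts, "MDA5", "GCG")
        assert fm.background_area + fm.foreground_area == fm.roi_area == rois.areas[roi_id]


def test_raising_threshold_never_grows_foreground(nd_noisy):
    _ph, stack, _truth = nd_noisy
    mda5 = stack.channel("MDA5")
    prev = None
    for t in (1000, 5000, 20000, 40000, 60000):
        mask = mda5 >= t
        if prev is not None:
            assert not (mask & ~prev).any()
        prev = mask


def test_pair_foreground_background_split_on_constructed_grid():
    # 10x10 ROI: 15 px A-only, 10 px B-only, 15 px both, 60 px neither
    a = np.zeros((10, 10), dtype=np.uint16)
    b = np.zeros((10, 10), dtype=np.uint16)
    flat_a = a.reshape(-1)
    flat_b = b.reshape(-1)
    flat_a[:15] = 1000            # A-only
    flat_b[15:25] = 1000          # B-only
    flat_a[25:40] = 1000          # both
    flat_b[25:40] = 1000
    stack = _stack_from({"MDA5": a, "INS": b})
    ts = ThresholdSet(values={"MDA5": 500.0, "INS": 500.0}, method="fixed")
    roi = np.ones((10, 10), dtype=bool)
    fm = foreground_for_pair(stack, roi, ts, "MDA5", "INS")
    assert fm.roi_area == 100
    assert fm.background_area == 60
    assert fm.foreground_area == 40


def test_saturated_and_blank_pairs():
    shape = (10, 10)
    ts = ThresholdSet(values={"MDA5": 500.0, "INS": 500.0}, method="fixed")
    roi = np.ones(shape, dtype=bool)
    blank = _stack_from({"MDA5": np.zeros(shape, np.uint16), "INS": np.zeros(shape, np.uint16)})
    fm = foreground_for_pair(blank, roi, ts, "MDA5", "INS")
    assert fm.foreground_area == 0 and fm.background_area == 100
    full = _stack_from({"MDA5": np.full(shape, 60000, np.uint16),
                        "INS": np.full(shape, 60000, np.uint16)})
    fm = foreground_for_pair(full, roi, ts, "MDA5", "INS")
    assert fm.foreground_area == 100 and fm.background_area == 0


def test_unknown_channel_rejected(nd_noisy):
    _ph, stack, _truth = nd_noisy
    ts = compute_thresholds(stack)
    with pytest.raises(KeyError, match="PP"):
        foreground_for_pair(stack, np.ones(stack.shape, bool), ts, "MDA5", "PP")
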