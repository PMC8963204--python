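"""Per-islet colocalization rates for marker pairs.

The rate follows the area-overlap (Manders-style) definition used in
islet immunofluorescence quantification: within one islet ROI,

    rate = 100 * colocalization area / image foreground

where the colocalization area is the number of pixels at/above threshold
in BOTH channels, and the image foreground is the ROI area minus the
background area (pixels below threshold in both channels).  All areas are
exact integer pixel counts; the division happens once at the end.  An
islet whose pair foreground is empty has an undefined rate and is flagged
rather than coerced to zero, so hormone-deficient islets never bias group
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import ChannelStack
from .segmentation import ForegroundMasks, ROISet, ThresholdSet, foreground_for_pair

#: The marker pairs quantified by default.
DEFAULT_PAIRS: tuple[tuple[str, str], ...] = (("MDA5", "INS"), ("MDA5", "GCG"))

MEASUREMENT_COLUMNS = [
    "islet_id",
    "pair",
    "roi_area_px",
    "background_area_px",
    "foreground_area_px",
    "coloc_area_px",
    "rate_percent",
    "defined",
]


@dataclass(frozen=True)
class ColocMeasurement:
    """One islet x one ordered marker pair."""

    islet_id: int
    marker_pair: tuple[str, str]
    roi_area_px: int
    background_area_px: int
    foreground_area_px: int
    coloc_area_px: int
    rate_percent: float  # NaN when undefined
    defined: bool

    def __post_init__(self) -> None:
        if self.foreground_area_px != self.roi_area_px - self.background_area_px:
            raise ValueError("foreground must equal ROI minus background")
        if self.coloc_area_px > self.foreground_area_px:
            raise ValueError("colocalization area cannot exceed the foreground")
        if self.defined and not 0.0 <= self.rate_percent <= 100.0:
            raise ValueError("rate must lie in [0, 100]")


def colocalization_rate(
    masks: ForegroundMasks, islet_id: int = 0, pair: tuple[str, str] | None = None
) -> ColocMeasurement:
    """Compute the rate from a pair's thresholded masks within one ROI."""
    if pair is None:
        names = tuple(masks.masks)
        if len(names) != 2:
            raise ValueError("masks must hold exactly two channels")
        pair = names  # insertion order = (a, b)
    a, b = masks.masks[pair[0]], masks.masks[pair[1]]
    if a.shape != b.shape:
        raise ValueError("pair masks must share a shape")
    coloc = int(np.count_nonzero(a & b))
    fg = masks.foreground_area
    defined = fg > 0
    rate = 100.0 * coloc / fg if defined else float("nan")
    return ColocMeasurement(
        islet_id=islet_id,
        marker_pair=tuple(pair),
        roi_area_px=masks.roi_area,
        background_area_px=masks.background_area,
        foreground_area_px=fg,
        coloc_area_px=coloc,
        rate_percent=rate,
        defined=defined,
    )


def quantify_image(
    stack: ChannelStack,
    rois: ROISet,
    thresholds: ThresholdSet,
    pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS,
) -> list[ColocMeasurement]:
    """One measurement per ROI per pair, ordered by (islet_id, pair).

    Undefined (empty-foreground) measurements are included and flagged.
    Work is done on per-ROI bounding-box crops for speed.
    """
    out: list[ColocMeasurement] = []
    for roi_id in rois.roi_ids():
        r0, c0, r1, c1 = rois.bboxes[roi_id]
        sub_mask = rois.labels[r0:r1, c0:c1] == roi_id
        sub_stack = ChannelStack(
            data=stack.data[:, r0:r1, c0:c1], names=stack.names, pixel_size=stack.pixel_size
        )
        for pair in pairs:
            fm = foreground_for_pair(sub_stack, sub_mask, thresholds, *pair)
            out.append(colocalization_rate(fm, islet_id=roi_id, pair=pair))
    return out


def channel_areas(
    stack: ChannelStack,
    rois: ROISet,
    thresholds: ThresholdSet,
    channels: tuple[str, ...] = ("INS", "GCG", "SST", "CHGA", "MDA5"),
) -> pd.DataFrame:
    """Per-ROI positive pixel area for each channel (input to classification)."""
    rows = []
    for roi_id in rois.roi_ids():
        r0, c0, r1, c1 = rois.bboxes[roi_id]
        sub_mask = rois.labels[r0:r1, c0:c1] == roi_id
        row = {"islet_id": roi_id, "roi_area_px": rois.areas[roi_id]}
        for name in channels:
            ch = stack.data[stack.names.index(name), r0:r1, c0:c1]
            row[f"area_{name}"] = int(np.count_nonzero((ch >= thresholds[name]) & sub_mask))
        rows.append(row)
    cols = ["islet_id", "roi_area_px"] + [f"area_{c}" for c in channels]
    return pd.DataFrame(rows, columns=cols)


def measurements_frame(measurements: list[ColocMeasurement]) -> pd.DataFrame:
    """Tidy table of measurements (pair rendered as 'A-B')."""
    rows = [
        {
            "islet_id": m.islet_id,
            "pair": "-".join(m.marker_pair),
            "roi_area_px": m.roi_area_px,
            "background_area_px": m.background_area_px,
            "foreground_area_px": m.foreground_area_px,
            "coloc_area_px": m.coloc_area_px,
            "rate_percent": m.rate_percent,
            "defined": m.defined,
        }
        for m in measurements
    ]
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
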