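"""Islet ROI delineation and per-channel foreground/background masks.

An islet ROI is a connected region of chromogranin-A (pan-endocrine)
signal.  Connected components are found on the morphologically closed CHGA
foreground — closing bridges the sub-cell-diameter gaps between packed
cells — but each ROI's pixel mask is the *raw* CHGA foreground inside its
component, so the mask never contains pixels without endocrine signal.
Components smaller than ``min_islet_area`` (default: three cell
footprints) are scattered single cells, not islets, and are excluded.

For a marker pair inside one ROI, background is the set of ROI pixels
below threshold in BOTH channels and foreground is the complement within
the ROI (signal in at least one channel), so background + foreground
always partitions the ROI exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_closing
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import disk as disk_footprint

from .phantom import CHANNELS, DEFAULT_CELL_AREA_PX, ChannelStack

#: Channels thresholded for analysis (the nuclear stain is context only).
ANALYSIS_CHANNELS = ("INS", "GCG", "SST", "CHGA", "MDA5")

DEFAULT_MIN_ISLET_AREA = 3 * DEFAULT_CELL_AREA_PX


class DegenerateChannelError(ValueError):
    """A constant channel cannot be thresholded automatically."""


@dataclass(frozen=True)
class ThresholdSet:
    values: dict[str, float]
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.values.values()):
            raise ValueError("thresholds must be strictly positive")

    def __getitem__(self, channel: str) -> float:
        try:
            return self.values[channel]
        except KeyError:
            raise KeyError(
                f"no threshold for channel {channel!r}; have: {', '.join(self.values)}"
            ) from None


@dataclass
class ROISet:
    """Labeled islet ROIs: 0 = non-islet, labels consecutive from 1,
    ordered by descending area (ties by centroid row, then col)."""

    labels: np.ndarray
    areas: dict[int, int]
    bboxes: dict[int, tuple[int, int, int, int]]  # (min_row, min_col, max_row, max_col)

    def __len__(self) -> int:
        return len(self.areas)

    def roi_ids(self) -> list[int]:
        return sorted(self.areas)

    def mask(self, roi_id: int) -> np.ndarray:
        return self.labels == roi_id


@dataclass
class ForegroundMasks:
    """Per-pair thresholded masks restricted to one ROI."""

    roi_mask: np.ndarray
    masks: dict[str, np.ndarray]  # channel -> binary positive mask within ROI
    roi_area: int
    background_area: int

    @property
    def foreground_area(self) -> int:
        return self.roi_area - self.background_area


def _otsu_threshold(img: np.ndarray, nbins: int = 256) -> float:
    """Otsu's criterion with plateau-midpoint tie-breaking.

    When the histogram has an empty gap between the background and signal
    modes (e.g. a noise-free image whose background is exactly zero), the
    between-class variance is flat over every split inside the gap; the
    conventional argmax then returns the lowest bin, which can be the
    image minimum.  Taking the midpoint of the optimal plateau places the
    threshold centrally between the modes instead.
    """
    counts, edges = np.histogram(img.ravel(), bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = counts.astype(np.float64) / counts.sum()
    omega0 = np.cumsum(w)
    mu_cum = np.cumsum(w * centers)
    mu_total = mu_cum[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * omega0 - mu_cum) ** 2 / (omega0 * (1.0 - omega0))
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    best = sigma_b.max()
    plateau = np.nonzero(sigma_b >= best * (1.0 - 1e-12))[0]
    return float(centers[plateau].mean())


def compute_thresholds(
    stack: ChannelStack,
    method: str = "otsu",
    channels: tuple[str, ...] = ANALYSIS_CHANNELS,
    **params,
) -> ThresholdSet:
    """One threshold per analyzed channel.

    ``otsu``   — Otsu's method on the full channel histogram (default).
    ``quantile`` — ``q``-quantile of the channel intensities.
    ``fixed``  — a single ``value`` (or per-channel dict) echoed as-is.
    """
    values: dict[str, float] = {}
    if method == "otsu":
        for name in channels:
            img = stack.channel(name)
            if np.ptp(img) == 0:
                raise DegenerateChannelError(
                    f"channel {name!r} is constant; Otsu thresholding is undefined"
                )
            values[name] = _otsu_threshold(img)
    elif method == "quantile":
        q = float(params.get("q", 0.95))
        if not 0.0 < q < 1.0:
            raise ValueError("quantile q must be in (0, 1)")
        for name in channels:
            values[name] = float(np.quantile(stack.channel(name), q))
    elif method == "fixed":
        value = params.get("value")
        if value is None:
            raise ValueError("fixed thresholding requires a 'value' parameter")
        for name in channels:
            values[name] = float(value[name] if isinstance(value, dict) else value)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return ThresholdSet(values=values, method=method, params=dict(params))


def segment_islets(
    stack: ChannelStack,
    thresholds: ThresholdSet,
    min_islet_area: int = DEFAULT_MIN_ISLET_AREA,
    closing_radius: int = 3,
    reference_channel: str = "CHGA",
) -> ROISet:
    """Delineate islet ROIs from the pan-endocrine reference channel.

    Returns an empty ROISet (no error) when no component survives the
    area filter.
    """
    fg = stack.channel(reference_channel) >= thresholds[reference_channel]
    closed = binary_closing(fg, structure=disk_footprint(closing_radius)) if closing_radius > 0 else fg
    comp = cc_label(closed, connectivity=2)

    candidates = []
    for region in regionprops(comp):
        r0, c0, r1, c1 = region.bbox
        sub = (comp[r0:r1, c0:c1] == region.label) & fg[r0:r1, c0:c1]
        area = int(sub.sum())
        if area < min_islet_area:
            continue
        rows, cols = np.nonzero(sub)
        centroid = (float(rows.mean()) + r0, float(cols.mean()) + c0)
        candidates.append((area, centroid, (r0, c0, r1, c1), sub))

    candidates.sort(key=lambda t: (-t[0], t[1][0], t[1][1]))
    labels = np.zeros(stack.shape, dtype=np.int32)
    areas: dict[int, int] = {}
    bboxes: dict[int, tuple[int, int, int, int]] = {}
    for new_id, (area, _centroid, bbox, sub) in enumerate(candidates, start=1):
        r0, c0, r1, c1 = bbox
        view = labels[r0:r1, c0:c1]
        view[sub] = new_id
        areas[new_id] = area
        bboxes[new_id] = bbox
    return ROISet(labels=labels, areas=areas, bboxes=bboxes)


def foreground_for_pair(
    stack: ChannelStack,
    roi_mask: np.ndarray,
    thresholds: ThresholdSet,
    channel_a: str,
    channel_b: str,
) -> ForegroundMasks:
    """Per-pair masks and the ROI's background/foreground split.

    Background = ROI pixels below threshold in both channels; foreground =
    ROI pixels at/above threshold in at least one of the two.
    """
    roi_area = int(np.count_nonzero(roi_mask))
    if roi_area == 0:
        raise ValueError("ROI mask is empty")
    masks = {
        name: (stack.channel(name) >= thresholds[name]) & roi_mask
        for name in (channel_a, channel_b)
    }
    union = masks[channel_a] | masks[channel_b]
    background = roi_area - int(np.count_nonzero(union))
    return ForegroundMasks(roi_mask=roi_mask, masks=masks, roi_area=roi_area,
                           background_area=background)
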