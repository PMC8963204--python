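"""End-to-end helpers binding generation, segmentation, quantification,
classification, and statistics into one reproducible run."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import ClassifierParams, classify_areas_table, records_frame
from .coloc import DEFAULT_PAIRS, channel_areas, measurements_frame, quantify_image
from .config import PipelineConfig
from .phantom import (
    PRESETS,
    ChannelStack,
    CohortPreset,
    GroundTruth,
    generate_phantom,
    render_channels,
)
from .segmentation import (
    DEFAULT_MIN_ISLET_AREA,
    ROISet,
    compute_thresholds,
    segment_islets,
)


@dataclass
class DonorResult:
    donor_id: str
    group: str
    stack: ChannelStack
    truth: GroundTruth
    rois: ROISet
    measurements: pd.DataFrame
    areas: pd.DataFrame
    records: pd.DataFrame
    dropped: list


def _classifier_params(config: PipelineConfig) -> ClassifierParams:
    c = config.classifier
    kwargs = dict(
        ins_min_frac=c.ins_min_frac,
        mda5_min_frac=c.mda5_min_frac,
        chga_min_frac=c.chga_min_frac,
        hormone_max_frac=c.hormone_max_frac,
        min_cluster_cells=c.min_cluster_cells,
    )
    if c.cell_area_px is not None:
        kwargs["cell_area_px"] = c.cell_area_px
    return ClassifierParams(**kwargs)


def quantify_stack(
    stack: ChannelStack,
    config: PipelineConfig = PipelineConfig(),
    donor_id: str = "donor",
    group: str = "",
    roi_labels: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, ROISet, list]:
    """Segment (or import masks), quantify pairs, and classify one image.

    Returns (measurements, areas, records, rois, dropped).
    """
    thresholds = compute_thresholds(
        stack, method=config.thresholds.method, **config.thresholds.params
    )
    if roi_labels is not None:
        labels = roi_labels.astype(np.int32)
        ids = [int(i) for i in np.unique(labels) if i]
        rois = ROISet(
            labels=labels,
            areas={i: int(np.count_nonzero(labels == i)) for i in ids},
            bboxes={
                i: (
                    int(np.nonzero(labels == i)[0].min()),
                    int(np.nonzero(labels == i)[1].min()),
                    int(np.nonzero(labels == i)[0].max()) + 1,
                    int(np.nonzero(labels == i)[1].max()) + 1,
                )
                for i in ids
            },
        )
    else:
        min_area = config.segmentation.min_islet_area or DEFAULT_MIN_ISLET_AREA
        rois = segment_islets(
            stack,
            thresholds,
            min_islet_area=min_area,
            closing_radius=config.segmentation.closing_radius,
            reference_channel=config.segmentation.reference_channel,
        )
    measurements = measurements_frame(quantify_image(stack, rois, thresholds, DEFAULT_PAIRS))
    measurements.insert(0, "donor_id", donor_id)
    measurements.insert(1, "group", group)
    areas = channel_areas(stack, rois, thresholds)
    kept, dropped = classify_areas_table(
        areas, _classifier_params(config), donor_id=donor_id, group=group
    )
    records = records_frame(kept)
    return measurements, areas, records, rois, dropped


def simulate_cohort(
    preset: str | CohortPreset,
    donors: int,
    seed: int,
    shape: tuple[int, int] = (1024, 1024),
    islets_per_donor: int | None = None,
):
    """Yield (donor_id, phantom, stack, truth) for each donor, with
    independent per-donor seeds derived from the master seed."""
    if isinstance(preset, str):
        preset = PRESETS[preset]
    donor_seeds = np.random.SeedSequence(seed).generate_state(donors) % (2**31)
    for d in range(donors):
        phantom = generate_phantom(
            preset, shape=shape, seed=int(donor_seeds[d]), n_islets=islets_per_donor
        )
        stack, truth = render_channels(phantom)
        yield f"{preset.name}_donor{d + 1}", phantom, stack, truth


def run_cohort(
    preset: str | CohortPreset,
    donors: int,
    seed: int,
    shape: tuple[int, int] = (1024, 1024),
    islets_per_donor: int | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> list[DonorResult]:
    """Simulate and fully analyze one donor cohort."""
    name = preset if isinstance(preset, str) else preset.name
    results = []
    for donor_id, phantom, stack, truth in simulate_cohort(
        preset, donors, seed, shape, islets_per_donor
    ):
        meas, areas, records, rois, dropped = quantify_stack(
            stack, config, donor_id=donor_id, group=name
        )
        results.append(
            DonorResult(donor_id, name, stack, truth, rois, meas, areas, records, dropped)
        )
    return results


def cohort_tables(results: list[DonorResult]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Concatenate per-donor measurement and record tables."""
    meas = pd.concat([r.measurements for r in results], ignore_index=True)
    recs = pd.concat([r.records for r in results], ignore_index=True)
    return meas, recs
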