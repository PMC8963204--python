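"""Five-way classification of detected structures and per-donor tabulation.

Each detected structure is assigned exactly one of five categories:

* ``ICI_MDA5pos`` / ``ICI_MDA5neg`` — insulin-containing islet, with /
  without an MDA5-positive area;
* ``IDI_MDA5pos`` / ``IDI_MDA5neg`` — insulin-deficient islet;
* ``HORMONE_NEG_CLUSTER`` — chromogranin-A-positive, insulin/glucagon/
  somatostatin-negative, MDA5-positive islet-like cluster.

The decision uses area fractions of the ROI, with explicit, configurable
cutoffs: no published numeric cutoffs exist for "MDA5-positive islet" or
for ICI vs IDI, so the defaults below make the unavoidable choices
auditable.  A size sanity gate drops cluster candidates whose estimated
cell count is implausibly small for an islet-like structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import CATEGORIES, DEFAULT_CELL_AREA_PX


@dataclass(frozen=True)
class ClassifierParams:
    ins_min_frac: float = 0.01      # ICI iff INS+ area >= this fraction of ROI
    mda5_min_frac: float = 0.01     # MDA5-positive iff MDA5+ area >= this fraction
    chga_min_frac: float = 0.5      # cluster needs dominant chromogranin-A signal
    hormone_max_frac: float = 0.01  # cluster: INS, GCG, SST each below this fraction
    min_cluster_cells: int = 5      # size gate for islet-like clusters
    cell_area_px: float = float(DEFAULT_CELL_AREA_PX)


@dataclass(frozen=True)
class IsletRecord:
    donor_id: str
    group: str
    islet_id: int
    insulin_status: str  # ICI | IDI
    mda5_status: str     # pos | neg
    is_hormone_neg_cluster: bool
    category: str
    roi_area_px: int
    areas: dict[str, int]  # per-channel positive area within the ROI

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.is_hormone_neg_cluster:
            if self.category != "HORMONE_NEG_CLUSTER" or self.mda5_status != "pos":
                raise ValueError("cluster records must be HORMONE_NEG_CLUSTER and MDA5-positive")
        elif self.category != f"{self.insulin_status}_MDA5{self.mda5_status}":
            raise ValueError("category must be the cross of insulin and MDA5 status")


def classify_structure(
    areas: dict[str, int],
    roi_area_px: int,
    params: ClassifierParams = ClassifierParams(),
    donor_id: str = "",
    group: str = "",
    islet_id: int = 0,
) -> IsletRecord:
    """Assign one category from per-channel positive areas within an ROI."""
    if roi_area_px <= 0:
        raise ValueError("ROI area must be positive")
    for name, a in areas.items():
        if a < 0 or a > roi_area_px:
            raise ValueError(f"area for {name} ({a}) outside [0, ROI area {roi_area_px}]")

    frac = {name: areas.get(name, 0) / roi_area_px for name in ("INS", "GCG", "SST", "CHGA", "MDA5")}
    insulin_status = "ICI" if frac["INS"] >= params.ins_min_frac else "IDI"
    mda5_status = "pos" if frac["MDA5"] >= params.mda5_min_frac else "neg"
    is_cluster = (
        frac["CHGA"] >= params.chga_min_frac
        and mda5_status == "pos"
        and frac["INS"] < params.hormone_max_frac
        and frac["GCG"] < params.hormone_max_frac
        and frac["SST"] < params.hormone_max_frac
    )
    if is_cluster:
        category = "HORMONE_NEG_CLUSTER"
        insulin_status = "IDI"  # clusters contain no insulin by definition
    else:
        category = f"{insulin_status}_MDA5{mda5_status}"
    return IsletRecord(
        donor_id=donor_id,
        group=group,
        islet_id=islet_id,
        insulin_status=insulin_status,
        mda5_status=mda5_status,
        is_hormone_neg_cluster=is_cluster,
        category=category,
        roi_area_px=roi_area_px,
        areas={k: int(v) for k, v in areas.items()},
    )


def cluster_sanity_filter(
    record: IsletRecord,
    n_cells_estimate: float | None = None,
    params: ClassifierParams = ClassifierParams(),
) -> tuple[bool, str]:
    """Size gate for hormone-negative cluster candidates.

    Returns (keep, reason).  Non-cluster records always pass.  The cell
    count is estimated as ROI area / default cell footprint (rounded)
    unless given explicitly.
    """
    if not record.is_hormone_neg_cluster:
        return True, "not a cluster candidate"
    if n_cells_estimate is None:
        n_cells_estimate = record.roi_area_px / params.cell_area_px
    n = int(round(n_cells_estimate))
    if n < params.min_cluster_cells:
        return False, f"estimated {n} cells < min_cluster_cells={params.min_cluster_cells}"
    return True, f"estimated {n} cells"


def classify_areas_table(
    areas_table: pd.DataFrame,
    params: ClassifierParams = ClassifierParams(),
    donor_id: str = "",
    group: str = "",
    apply_cluster_filter: bool = True,
) -> tuple[list[IsletRecord], list[tuple[IsletRecord, str]]]:
    """Classify every row of a per-ROI channel-area table.

    Returns (kept records, dropped (record, reason) pairs).
    """
    kept: list[IsletRecord] = []
    dropped: list[tuple[IsletRecord, str]] = []
    for row in areas_table.itertuples(index=False):
        areas = {c: getattr(row, f"area_{c}") for c in ("INS", "GCG", "SST", "CHGA", "MDA5")}
        rec = classify_structure(
            areas, int(row.roi_area_px), params,
            donor_id=donor_id, group=group, islet_id=int(row.islet_id),
        )
        if apply_cluster_filter:
            keep, reason = cluster_sanity_filter(rec, params=params)
            if not keep:
                dropped.append((rec, reason))
                continue
        kept.append(rec)
    return kept, dropped


def records_frame(records: list[IsletRecord]) -> pd.DataFrame:
    rows = [
        {
            "donor_id": r.donor_id,
            "group": r.group,
            "islet_id": r.islet_id,
            "insulin_status": r.insulin_status,
            "mda5_status": r.mda5_status,
            "is_hormone_neg_cluster": r.is_hormone_neg_cluster,
            "category": r.category,
            "roi_area_px": r.roi_area_px,
            **{f"area_{k}": v for k, v in sorted(r.areas.items())},
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def tabulate_distribution(records: pd.DataFrame | list[IsletRecord]) -> pd.DataFrame:
    """Per-donor counts and percentages over the five categories.

    Mirrors a whole-slide distribution table: one row per donor, a count
    and a percentage column per category, plus totals.  Percentages are
    over the donor's total detected structures and sum to 100.
    """
    df = records if isinstance(records, pd.DataFrame) else records_frame(records)
    if df.empty:
        raise ValueError("no records to tabulate")
    out_rows = []
    for (donor, group), sub in df.groupby(["donor_id", "group"], sort=True):
        total = len(sub)
        row: dict[str, object] = {"donor_id": donor, "group": group, "total": total}
        for cat in CATEGORIES:
            n = int((sub["category"] == cat).sum())
            row[f"n_{cat}"] = n
            row[f"pct_{cat}"] = 100.0 * n / total
        out_rows.append(row)
    cols = ["donor_id", "group", "total"]
    for cat in CATEGORIES:
        cols += [f"n_{cat}", f"pct_{cat}"]
    return pd.DataFrame(out_rows, columns=cols)
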