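"""Synthetic multiplex-immunofluorescence pancreas phantoms with per-cell ground truth.

The generator emulates the tissue facts that matter for validating an
islet-level colocalization pipeline: islets are compact clusters of
endocrine cells (glucagon+ alpha, insulin+ beta, somatostatin+ delta, plus
rare other endocrine cells), all chromogranin-A-positive, embedded in an
exocrine background that carries no endocrine marker.  MDA5, a cytoplasmic
viral dsRNA sensor, is expressed only in endocrine cells, with a higher
positive fraction in alpha- than beta-cells; disease-state presets shift
those fractions upward, remove beta-cells from a fraction of islets
(insulin-deficient islets, IDIs), and — in the recent-onset preset only —
add chromogranin-A-positive / hormone-negative / MDA5-positive islet-like
clusters.

Cells are non-overlapping disks on a 2-D plane.  MDA5 positivity is a
per-cell binary attribute: a positive cell expresses MDA5 over its whole
disk.  Ground truth (ROI label image, per-islet category, per-islet MDA5
area fractions) is derived from the pre-blur disk footprints, so optical
blur and noise affect intensities but never the truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numba
import numpy as np
from scipy import ndimage, stats
from skimage.draw import disk as disk_coords


@numba.njit(cache=True)
def _finalize_to_uint16(canvas: np.ndarray, background: float, sd: float, seed: int) -> np.ndarray:
    """Add background and per-pixel Gaussian noise, clip to [0, 1], quantize.

    A jitted loop: noise generation dominates render time at cohort scale.
    Deterministic for a fixed seed (single-threaded Mersenne Twister).
    """
    C, H, W = canvas.shape
    out = np.empty((C, H, W), dtype=np.uint16)
    if sd > 0.0:
        np.random.seed(seed)
    for c in range(C):
        for i in range(H):
            for j in range(W):
                v = canvas[c, i, j] + background
                if sd > 0.0:
                    v += sd * np.random.normal(0.0, 1.0)
                if v < 0.0:
                    v = 0.0
                elif v > 1.0:
                    v = 1.0
                out[c, i, j] = np.uint16(v * 65535.0 + 0.5)
    return out

#: Fixed channel order used everywhere (images, fixtures, thresholds).
CHANNELS = ("DAPI", "INS", "GCG", "SST", "CHGA", "MDA5")

#: Endocrine marker channels (everything except the nuclear stain).
MARKER_CHANNELS = ("INS", "GCG", "SST", "CHGA", "MDA5")

#: The five structure categories.
CATEGORIES = (
    "ICI_MDA5pos",
    "ICI_MDA5neg",
    "IDI_MDA5pos",
    "IDI_MDA5neg",
    "HORMONE_NEG_CLUSTER",
)

CELL_TYPES = ("alpha", "beta", "delta", "other_endocrine", "exocrine")

#: Default cell radius in pixels.
DEFAULT_CELL_RADIUS = 5.0

#: Pixel footprint of one default cell (rasterized disk), used for
#: cell-count estimates downstream.
DEFAULT_CELL_AREA_PX = len(disk_coords((50, 50), DEFAULT_CELL_RADIUS)[0])


class CapacityError(RuntimeError):
    """Raised when islets cannot be placed in the requested image shape."""


@dataclass(frozen=True)
class CellSpec:
    """One cell: a disk with per-channel relative marker intensities."""

    cell_id: int
    center: tuple[float, float]  # (row, col), 0-based
    radius: float
    cell_type: str
    marker_levels: dict[str, float]
    mda5_positive: bool

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("cell radius must be > 0")
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell type {self.cell_type!r}")
        lv = self.marker_levels
        if self.cell_type == "exocrine":
            if any(lv.get(c, 0.0) != 0.0 for c in ("INS", "GCG", "SST", "CHGA")):
                raise ValueError("exocrine cells carry no endocrine marker")
        else:
            if lv.get("CHGA", 0.0) <= 0.0:
                raise ValueError("endocrine cells must be chromogranin-A positive")
        if self.cell_type == "alpha" and not (lv.get("GCG", 0) > 0 and lv.get("INS", 0) == 0):
            raise ValueError("alpha cells are GCG+ / INS-")
        if self.cell_type == "beta" and not (lv.get("INS", 0) > 0 and lv.get("GCG", 0) == 0):
            raise ValueError("beta cells are INS+ / GCG-")
        if self.cell_type == "delta" and not (
            lv.get("SST", 0) > 0 and lv.get("INS", 0) == 0 and lv.get("GCG", 0) == 0
        ):
            raise ValueError("delta cells are SST+ / INS- / GCG-")
        mda5 = lv.get("MDA5", 0.0)
        if self.mda5_positive and mda5 <= 0:
            raise ValueError("mda5_positive cell must have MDA5 level > 0")
        if not self.mda5_positive and mda5 != 0:
            raise ValueError("MDA5-negative cell must have MDA5 level exactly 0")


@dataclass(frozen=True)
class IsletSpec:
    islet_id: int
    cells: list[CellSpec]
    true_category: str
    centroid: tuple[float, float]

    def __post_init__(self) -> None:
        if self.true_category not in CATEGORIES:
            raise ValueError(f"unknown category {self.true_category!r}")
        n_beta = sum(c.cell_type == "beta" for c in self.cells)
        if self.true_category.startswith("IDI") and n_beta:
            raise ValueError("IDI islet contains beta cells")
        if self.true_category.startswith("ICI") and not n_beta:
            raise ValueError("ICI islet contains no beta cell")
        if self.true_category == "HORMONE_NEG_CLUSTER":
            for c in self.cells:
                if c.cell_type != "other_endocrine" or not c.mda5_positive:
                    raise ValueError("cluster cells must be other_endocrine and MDA5+")


@dataclass(frozen=True)
class NoiseParams:
    """Imaging degradation: constant background, additive Gaussian noise,
    Gaussian point-spread blur.  All intensities relative in [0, 1]."""

    background_level: float = 0.05
    gaussian_sd: float = 0.02
    psf_sigma: float = 1.0
    seed: int = 0


NOISELESS = NoiseParams(background_level=0.0, gaussian_sd=0.0, psf_sigma=0.0, seed=0)


@dataclass(frozen=True)
class CohortPreset:
    """Donor-group calibration for the generator.

    ``f_mda5_alpha`` / ``f_mda5_beta`` are (mean, sd) of a truncated normal
    on [0, 1] from which each islet draws its target MDA5-glucagon /
    MDA5-insulin colocalization rate; the generator back-solves the
    per-cell-type MDA5-positive fractions so that the islet's noiseless
    measured rate matches the draw (see :func:`_solve_positive_fractions`).
    """

    name: str
    f_mda5_alpha: tuple[float, float]
    f_mda5_beta: tuple[float, float]
    idi_fraction: float
    cluster_fraction: float
    mda5_neg_islet_fraction: float
    islets_per_donor: int
    noise: NoiseParams = NoiseParams()

    def __post_init__(self) -> None:
        for f in (self.idi_fraction, self.cluster_fraction, self.mda5_neg_islet_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.name == "ND" and (self.idi_fraction or self.cluster_fraction):
            raise ValueError("ND preset has no IDIs and no hormone-negative clusters")
        if self.name in ("ND", "AAB_POS") and self.cluster_fraction:
            raise ValueError("clusters occur only in recent-onset T1D")


#: Donor-group presets.  Rate means/sds follow the reported cohort values
#: (nondiabetic 20.5±12.5 vs 14.4±10.6; recent-onset 28.5±17 vs 20.6±13.5;
#: long-standing 26.1±17.1 vs 11.9±10.8, in percent); the cluster fraction
#: default sits mid-range of the observed 3.2-15.9%.
PRESETS: dict[str, CohortPreset] = {
    "ND": CohortPreset(
        name="ND",
        f_mda5_alpha=(0.205, 0.125),
        f_mda5_beta=(0.144, 0.106),
        idi_fraction=0.0,
        cluster_fraction=0.0,
        mda5_neg_islet_fraction=0.0,
        islets_per_donor=15,
    ),
    "AAB_POS": CohortPreset(
        name="AAB_POS",
        f_mda5_alpha=(0.205, 0.125),
        f_mda5_beta=(0.144, 0.106),
        idi_fraction=0.0,
        cluster_fraction=0.0,
        mda5_neg_islet_fraction=0.0,
        islets_per_donor=15,
    ),
    "T1D_RO": CohortPreset(
        name="T1D_RO",
        f_mda5_alpha=(0.285, 0.170),
        f_mda5_beta=(0.206, 0.135),
        idi_fraction=0.45,
        cluster_fraction=0.10,
        mda5_neg_islet_fraction=0.0,
        islets_per_donor=25,
    ),
    "T1D_LS": CohortPreset(
        name="T1D_LS",
        f_mda5_alpha=(0.261, 0.171),
        f_mda5_beta=(0.119, 0.108),
        idi_fraction=0.60,
        cluster_fraction=0.0,
        mda5_neg_islet_fraction=0.0,
        islets_per_donor=15,
    ),
}


@dataclass(frozen=True)
class TissuePhantom:
    shape: tuple[int, int]
    pixel_size: float  # micrometres per pixel
    islets: list[IsletSpec]
    scattered_cells: list[CellSpec]
    preset: CohortPreset

    def __post_init__(self) -> None:
        if not self.islets:
            raise ValueError("phantom must contain at least one islet")


@dataclass
class ChannelStack:
    """Named multi-channel 2-D image; the common currency of the pipeline.

    ``data`` is (C, H, W) uint16, matching what the TIFF fixtures store, so
    in-memory analysis and fixture round-trips are bit-identical.
    """

    data: np.ndarray
    names: tuple[str, ...] = CHANNELS
    pixel_size: float = 0.5

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.data[self.names.index(name)]
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in stack; found: {', '.join(self.names)}"
            ) from None

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]


@dataclass
class GroundTruth:
    """Oracle for downstream modules: pre-blur ROI labels and per-islet truth."""

    roi_labels: np.ndarray  # uint16, 0 = non-islet
    categories: dict[int, str]
    frac_mda5_gcg: dict[int, float]  # MDA5+ area within GCG+ area; NaN if no GCG
    frac_mda5_ins: dict[int, float]
    n_cells: dict[int, int]
    centroids: dict[int, tuple[float, float]]

    def to_frame(self):
        import pandas as pd

        ids = sorted(self.categories)
        return pd.DataFrame(
            {
                "islet_id": ids,
                "true_category": [self.categories[i] for i in ids],
                "true_frac_mda5_gcg": [self.frac_mda5_gcg[i] for i in ids],
                "true_frac_mda5_ins": [self.frac_mda5_ins[i] for i in ids],
                "n_cells": [self.n_cells[i] for i in ids],
                "centroid_row": [self.centroids[i][0] for i in ids],
                "centroid_col": [self.centroids[i][1] for i in ids],
            }
        )


# ---------------------------------------------------------------------------
# generation


def _truncnorm01(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd <= 0:
        return float(np.clip(mean, 0.0, 1.0))
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _solve_positive_fractions(
    r_a: float, r_b: float, area_alpha: float, area_beta: float
) -> tuple[float, float]:
    """Invert target pair rates to per-type MDA5-positive area fractions.

    With x = MDA5+ alpha area and y = MDA5+ beta area, the noiseless
    measured rates are r_a = x / (A_alpha + y) and r_b = y / (A_beta + x)
    (pair foreground = union of the two channels' positive areas).  The
    system is linear in (x, y); fractions are clipped to [0, 1].
    """
    if area_alpha <= 0 and area_beta <= 0:
        return 0.0, 0.0
    if area_beta <= 0:  # no beta cells: rate_a = x / area_alpha directly
        return float(np.clip(r_a, 0.0, 1.0)), 0.0
    if area_alpha <= 0:
        return 0.0, float(np.clip(r_b, 0.0, 1.0))
    det = 1.0 - r_a * r_b
    x = r_a * (area_alpha + r_b * area_beta) / det
    y = r_b * (area_beta + r_a * area_alpha) / det
    f_a = float(np.clip(x / area_alpha, 0.0, 1.0))
    f_b = float(np.clip(y / area_beta, 0.0, 1.0))
    return f_a, f_b


def _level(rng: np.random.Generator, lo: float = 0.6, hi: float = 0.9) -> float:
    return float(rng.uniform(lo, hi))


def _islet_bounding_radius(n_cells: int, cell_radius: float) -> float:
    # sequential-attachment clusters stay compact; 1.5*sqrt(n) cell radii
    # plus margin bounds them comfortably
    return cell_radius * (1.5 * math.sqrt(n_cells) + 2.5)


def _place_cells(
    rng: np.random.Generator,
    n_cells: int,
    center: tuple[float, float],
    cell_radius: float,
    bound: float,
    max_attempts: int = 4000,
) -> list[tuple[float, float]]:
    """Sequential attachment: each new cell touches the cluster.

    Centers keep >= 2r apart (no disk overlap) and <= 2.5r from some
    existing cell, so the islet is a connected chain.
    """
    centers = [center]
    attempts = 0
    while len(centers) < n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise CapacityError("could not pack cells into islet")
        anchor = centers[rng.integers(len(centers))]
        d = rng.uniform(2.0 * cell_radius + 0.05, 2.5 * cell_radius)
        theta = rng.uniform(0.0, 2.0 * math.pi)
        cand = (anchor[0] + d * math.sin(theta), anchor[1] + d * math.cos(theta))
        if math.hypot(cand[0] - center[0], cand[1] - center[1]) > bound - cell_radius:
            continue
        if all(math.hypot(cand[0] - c[0], cand[1] - c[1]) >= 2.0 * cell_radius for c in centers):
            centers.append(cand)
    return centers


def _draw_cell_types(rng: np.random.Generator, n: int, kind: str) -> list[str]:
    """Cell-type composition; ICIs are beta-rich, IDIs alpha-rich."""
    if kind == "cluster":
        return ["other_endocrine"] * n
    if kind == "IDI":
        types = list(rng.choice(["alpha", "delta", "other_endocrine"], size=n, p=[0.75, 0.20, 0.05]))
        types[0] = "alpha"
        return types
    types = list(
        rng.choice(["beta", "alpha", "delta", "other_endocrine"], size=n, p=[0.55, 0.35, 0.08, 0.02])
    )
    # every ICI keeps at least one beta and one alpha cell
    types[0] = "beta"
    if n > 1:
        types[1] = "alpha"
    return types


def _make_cell(
    rng: np.random.Generator,
    cell_id: int,
    center: tuple[float, float],
    radius: float,
    cell_type: str,
    mda5_positive: bool,
    cluster_member: bool = False,
) -> CellSpec:
    levels = {c: 0.0 for c in MARKER_CHANNELS}
    if cell_type != "exocrine":
        levels["CHGA"] = _level(rng)
    if cell_type == "alpha":
        levels["GCG"] = _level(rng)
    elif cell_type == "beta":
        levels["INS"] = _level(rng)
    elif cell_type == "delta":
        levels["SST"] = _level(rng)
    if mda5_positive:
        # cluster cells show visibly brighter MDA5 than alpha/beta cells
        levels["MDA5"] = _level(rng, 0.75, 0.95) if cluster_member else _level(rng)
    return CellSpec(cell_id, center, radius, cell_type, levels, mda5_positive)


def _build_islet(
    rng: np.random.Generator,
    islet_id: int,
    center: tuple[float, float],
    n_cells: int,
    kind: str,  # "ICI" | "IDI" | "cluster"
    preset: CohortPreset,
    cell_radius: float,
    bound: float,
    next_cell_id: int,
) -> tuple[IsletSpec, int]:
    centers = _place_cells(rng, n_cells, center, cell_radius, bound)
    types = _draw_cell_types(rng, n_cells, kind)

    if kind == "cluster":
        positive = [True] * n_cells
    elif rng.random() < preset.mda5_neg_islet_fraction:
        positive = [False] * n_cells
    else:
        n_alpha = types.count("alpha")
        n_beta = types.count("beta")
        r_a = _truncnorm01(rng, *preset.f_mda5_alpha)
        r_b = _truncnorm01(rng, *preset.f_mda5_beta)
        f_a, f_b = _solve_positive_fractions(r_a, r_b, float(n_alpha), float(n_beta))
        k_a = int(round(f_a * n_alpha))
        k_b = int(round(f_b * n_beta))
        positive = [False] * n_cells
        alpha_idx = [i for i, t in enumerate(types) if t == "alpha"]
        beta_idx = [i for i, t in enumerate(types) if t == "beta"]
        for i in rng.choice(alpha_idx, size=k_a, replace=False) if k_a else []:
            positive[i] = True
        for i in rng.choice(beta_idx, size=k_b, replace=False) if k_b else []:
            positive[i] = True

    cells = [
        _make_cell(
            rng,
            next_cell_id + i,
            centers[i],
            cell_radius,
            types[i],
            positive[i],
            cluster_member=(kind == "cluster"),
        )
        for i in range(n_cells)
    ]

    # category from realized composition
    if kind == "cluster":
        cat = "HORMONE_NEG_CLUSTER"
    else:
        has_beta = any(c.cell_type == "beta" for c in cells)
        has_mda5 = any(c.mda5_positive for c in cells)
        cat = ("ICI" if has_beta else "IDI") + ("_MDA5pos" if has_mda5 else "_MDA5neg")
    centroid = tuple(np.mean([c.center for c in cells], axis=0))
    return IsletSpec(islet_id, cells, cat, centroid), next_cell_id + n_cells


def generate_phantom(
    preset: CohortPreset | str,
    shape: tuple[int, int] = (2048, 2048),
    seed: int = 0,
    n_islets: int | None = None,
    cell_radius: float = DEFAULT_CELL_RADIUS,
    pixel_size: float = 0.5,
    n_scattered_endocrine: int | None = None,
    n_exocrine: int | None = None,
    max_attempts_per_islet: int = 500,
) -> TissuePhantom:
    """Generate a seeded tissue phantom for one donor section.

    Deterministic for a fixed (preset, shape, seed).  Raises
    :class:`CapacityError` when the requested islet count cannot be placed
    without overlap after bounded rejection sampling.
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    n_islets = preset.islets_per_donor if n_islets is None else n_islets
    if n_islets < 1:
        raise ValueError("phantom needs at least one islet")

    ss = np.random.SeedSequence(seed)
    layout_ss, cells_parent_ss, scatter_ss, noise_ss = ss.spawn(4)
    layout_rng = np.random.default_rng(layout_ss)
    islet_streams = cells_parent_ss.spawn(n_islets)

    # structure skeletons: category kind and cell count per islet
    kinds: list[str] = []
    counts: list[int] = []
    for _ in range(n_islets):
        u = layout_rng.random()
        if u < preset.cluster_fraction:
            kinds.append("cluster")
            counts.append(int(layout_rng.integers(5, 16)))
        elif u < preset.cluster_fraction + (1 - preset.cluster_fraction) * preset.idi_fraction:
            kinds.append("IDI")
            counts.append(int(layout_rng.integers(8, 41)))
        else:
            kinds.append("ICI")
            counts.append(int(layout_rng.integers(8, 41)))

    bounds = [_islet_bounding_radius(n, cell_radius) for n in counts]
    margin = 12.0  # keeps islets separable by morphological closing
    # rejection-sample islet centers, largest structures first (better packing)
    order = sorted(range(n_islets), key=lambda k: -bounds[k])
    centers_arr = np.empty((n_islets, 2))
    placed_idx: list[int] = []
    for k in order:
        bound = bounds[k]
        lo_r, hi_r = bound + 1.0, shape[0] - bound - 1.0
        lo_c, hi_c = bound + 1.0, shape[1] - bound - 1.0
        if hi_r <= lo_r or hi_c <= lo_c:
            raise CapacityError(f"image shape {shape} too small for islet of radius {bound:.0f}")
        for attempt in range(max_attempts_per_islet):
            cand = (layout_rng.uniform(lo_r, hi_r), layout_rng.uniform(lo_c, hi_c))
            if all(
                math.hypot(cand[0] - centers_arr[j, 0], cand[1] - centers_arr[j, 1])
                >= bound + bounds[j] + margin
                for j in placed_idx
            ):
                centers_arr[k] = cand
                placed_idx.append(k)
                break
        else:
            raise CapacityError(
                f"failed to place islet {len(placed_idx) + 1}/{n_islets} in shape {shape} "
                f"after {max_attempts_per_islet} attempts"
            )
    centers = [tuple(centers_arr[k]) for k in range(n_islets)]

    islets: list[IsletSpec] = []
    next_cell_id = 0
    for k in range(n_islets):
        rng_k = np.random.default_rng(islet_streams[k])
        islet, next_cell_id = _build_islet(
            rng_k, k + 1, centers[k], counts[k], kinds[k], preset, cell_radius, bounds[k], next_cell_id
        )
        islets.append(islet)

    # scattered cells: rare MDA5+/CHGA+ endocrine singletons in the exocrine
    # parenchyma, plus plain exocrine (DAPI-only) cells for context
    scatter_rng = np.random.default_rng(scatter_ss)
    area_scale = shape[0] * shape[1] / (2048.0 * 2048.0)
    if n_scattered_endocrine is None:
        n_scattered_endocrine = max(2, int(round(6 * area_scale)))
    if n_exocrine is None:
        n_exocrine = max(5, int(round(120 * area_scale)))

    scattered: list[CellSpec] = []
    keepout = 15.0
    for i in range(n_scattered_endocrine + n_exocrine):
        for _ in range(200):
            cand = (
                scatter_rng.uniform(cell_radius + 1, shape[0] - cell_radius - 1),
                scatter_rng.uniform(cell_radius + 1, shape[1] - cell_radius - 1),
            )
            clear_islets = all(
                math.hypot(cand[0] - c[0], cand[1] - c[1]) >= b + keepout
                for c, b in zip(centers, bounds)
            )
            clear_cells = all(
                math.hypot(cand[0] - s.center[0], cand[1] - s.center[1]) >= 2 * cell_radius + 2
                for s in scattered
            )
            if clear_islets and clear_cells:
                break
        else:
            continue  # crowded frame: silently place fewer scattered cells
        if i < n_scattered_endocrine:
            # mostly glucagon-positive, frequently MDA5-positive
            ctype = "alpha" if scatter_rng.random() < 0.8 else "beta"
            mda5 = bool(scatter_rng.random() < 0.7)
            scattered.append(_make_cell(scatter_rng, next_cell_id, cand, cell_radius, ctype, mda5))
        else:
            scattered.append(
                CellSpec(next_cell_id, cand, cell_radius, "exocrine",
                         {c: 0.0 for c in MARKER_CHANNELS}, False)
            )
        next_cell_id += 1

    noise = replace(preset.noise, seed=int(noise_ss.generate_state(1)[0] % (2**31)))
    preset = replace(preset, noise=noise)
    return TissuePhantom(tuple(shape), pixel_size, islets, scattered, preset)


# ---------------------------------------------------------------------------
# rendering


def _footprint(cell: CellSpec, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    return disk_coords(cell.center, cell.radius, shape=shape)


def render_channels(phantom: TissuePhantom) -> tuple[ChannelStack, GroundTruth]:
    """Forward model: disks -> PSF blur -> background -> noise -> uint16.

    Ground truth comes from the pre-blur footprints: ``roi_labels`` covers
    exactly the union of each islet's endocrine disks, and the true MDA5
    area fractions are pixel counts on the pre-noise binary masks.
    """
    H, W = phantom.shape
    canvas = np.zeros((len(CHANNELS), H, W), dtype=np.float32)
    labels = np.zeros((H, W), dtype=np.uint16)
    mda5_mask = np.zeros((H, W), dtype=bool)
    gcg_mask = np.zeros((H, W), dtype=bool)
    ins_mask = np.zeros((H, W), dtype=bool)

    dapi_i = CHANNELS.index("DAPI")

    def paint(cell: CellSpec, islet_id: int) -> None:
        # cells never overlap, so direct assignment is safe
        rr, cc = _footprint(cell, (H, W))
        for name, level in cell.marker_levels.items():
            if level > 0:
                canvas[CHANNELS.index(name), rr, cc] = level
        # nucleus
        nr, nc = disk_coords(cell.center, max(1.5, 0.4 * cell.radius), shape=(H, W))
        canvas[dapi_i, nr, nc] = 0.85
        if islet_id and cell.cell_type != "exocrine":
            labels[rr, cc] = islet_id
        if cell.mda5_positive:
            mda5_mask[rr, cc] = True
        if cell.marker_levels.get("GCG", 0) > 0:
            gcg_mask[rr, cc] = True
        if cell.marker_levels.get("INS", 0) > 0:
            ins_mask[rr, cc] = True

    for islet in phantom.islets:
        for cell in islet.cells:
            paint(cell, islet.islet_id)
    for cell in phantom.scattered_cells:
        paint(cell, 0)

    noise = phantom.preset.noise
    if noise.psf_sigma > 0:
        for ci in range(len(CHANNELS)):
            ndimage.gaussian_filter(canvas[ci], noise.psf_sigma, output=canvas[ci])
    data = _finalize_to_uint16(
        canvas, float(noise.background_level), float(noise.gaussian_sd), noise.seed
    )

    n_lab = len(phantom.islets) + 1
    g_c = np.bincount(labels[gcg_mask], minlength=n_lab)
    i_c = np.bincount(labels[ins_mask], minlength=n_lab)
    mg_c = np.bincount(labels[mda5_mask & gcg_mask], minlength=n_lab)
    mi_c = np.bincount(labels[mda5_mask & ins_mask], minlength=n_lab)

    categories, f_gcg, f_ins, n_cells, centroids = {}, {}, {}, {}, {}
    for islet in phantom.islets:
        k = islet.islet_id
        categories[k] = islet.true_category
        f_gcg[k] = mg_c[k] / g_c[k] if g_c[k] else float("nan")
        f_ins[k] = mi_c[k] / i_c[k] if i_c[k] else float("nan")
        n_cells[k] = len(islet.cells)
        centroids[k] = islet.centroid

    stack = ChannelStack(data=data, names=CHANNELS, pixel_size=phantom.pixel_size)
    truth = GroundTruth(labels, categories, f_gcg, f_ins, n_cells, centroids)
    return stack, truth
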