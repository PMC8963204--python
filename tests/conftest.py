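"""Shared fixtures: hand-built phantoms with exactly known geometry."""

from __future__ import annotations

import numpy as np
import pytest
from skimage.draw import disk as disk_coords

from isletcoloc.phantom import (
    NOISELESS,
    PRESETS,
    CellSpec,
    CohortPreset,
    IsletSpec,
    NoiseParams,
    TissuePhantom,
    generate_phantom,
    render_channels,
)

CELL_R = 5.0
CELL_AREA = len(disk_coords((50, 50), CELL_R)[0])


def noiseless_preset(name: str = "ND") -> CohortPreset:
    import dataclasses

    return dataclasses.replace(PRESETS[name], noise=NOISELESS)


def grid_centers(center: tuple[float, float], n: int, spacing: float = 11.0):
    """n cell centers on a square grid: non-overlapping (spacing > 2r) and
    chain-connected (spacing < 2.5r)."""
    side = int(np.ceil(np.sqrt(n)))
    out = []
    for i in range(n):
        r, c = divmod(i, side)
        out.append((center[0] + r * spacing, center[1] + c * spacing))
    return out


def alpha_islet(islet_id: int, center, n_cells: int, n_mda5: int) -> IsletSpec:
    """All-alpha islet with exactly n_mda5 MDA5-positive cells, so the
    true MDA5-within-GCG area fraction is exactly n_mda5 / n_cells."""
    cells = []
    for i, c in enumerate(grid_centers(center, n_cells)):
        pos = i < n_mda5
        levels = {"INS": 0.0, "GCG": 0.8, "SST": 0.0, "CHGA": 0.7,
                  "MDA5": 0.8 if pos else 0.0}
        cells.append(CellSpec(islet_id * 100 + i, c, CELL_R, "alpha", levels, pos))
    cat = "IDI_MDA5pos" if n_mda5 else "IDI_MDA5neg"
    return IsletSpec(islet_id, cells, cat, center)


def alpha_phantom(
    fracs: list[float],
    n_cells: int = 20,
    islets_per_frac: int = 1,
    noise: NoiseParams = NOISELESS,
    shape=(512, 512),
) -> tuple[TissuePhantom, list[float]]:
    """Phantom whose islets have exact MDA5-within-GCG fractions ``fracs``.

    MDA5-positive area is a subset of the GCG area and GCG is the only
    hormone present, so the noiseless MDA5-GCG colocalization rate of
    islet i equals 100 * fracs[i % len(fracs)].
    """
    import dataclasses

    islets = []
    true_fracs = []
    k = 0
    spacing = 140
    per_row = max(1, (shape[1] - 80) // spacing)
    for rep in range(islets_per_frac):
        for f in fracs:
            r, c = divmod(k, per_row)
            center = (60.0 + r * spacing, 60.0 + c * spacing)
            islets.append(alpha_islet(k + 1, center, n_cells, int(round(f * n_cells))))
            true_fracs.append(int(round(f * n_cells)) / n_cells)
            k += 1
    preset = dataclasses.replace(PRESETS["ND"], noise=noise)
    return TissuePhantom(shape, 0.5, islets, [], preset), true_fracs


@pytest.fixture(scope="session")
def nd_noiseless():
    """Small noiseless ND phantom, shared across tests (read-only)."""
    ph = generate_phantom(noiseless_preset(), shape=(700, 700), seed=11, n_islets=6)
    stack, truth = render_channels(ph)
    return ph, stack, truth


@pytest.fixture(scope="session")
def nd_noisy():
    ph = generate_phantom("ND", shape=(700, 700), seed=11, n_islets=6)
    stack, truth = render_channels(ph)
    return ph, stack, truth
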