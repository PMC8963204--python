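"""Generator contracts: determinism, anatomy invariants, preset behavior."""

import dataclasses

import numpy as np
import pytest

from isletcoloc.phantom import (
    CHANNELS,
    NOISELESS,
    PRESETS,
    CapacityError,
    CellSpec,
    CohortPreset,
    IsletSpec,
    TissuePhantom,
    generate_phantom,
    render_channels,
)
from isletcoloc.io import read_fixture, write_fixture

from conftest import CELL_R, alpha_islet, noiseless_preset


def test_identical_seed_gives_bit_identical_phantom_and_render():
    a = generate_phantom("T1D_RO", shape=(700, 700), seed=42, n_islets=6)
    b = generate_phantom("T1D_RO", shape=(700, 700), seed=42, n_islets=6)
    assert a == b
    sa, ta = render_channels(a)
    sb, tb = render_channels(b)
    assert np.array_equal(sa.data, sb.data)
    assert np.array_equal(ta.roi_labels, tb.roi_labels)
    assert ta.frac_mda5_gcg == tb.frac_mda5_gcg


def test_different_seeds_differ():
    a = generate_phantom("ND", shape=(700, 700), seed=1, n_islets=4)
    b = generate_phantom("ND", shape=(700, 700), seed=2, n_islets=4)
    assert a != b


def test_nd_preset_emits_no_idi_and_no_clusters():
    ph = generate_phantom("ND", shape=(512, 512), seed=1, n_islets=5)
    cats = {islet.true_category for islet in ph.islets}
    assert not any(c.startswith("IDI") for c in cats)
    assert "HORMONE_NEG_CLUSTER" not in cats


def test_category_counts_conserve_total():
    ph = generate_phantom("T1D_RO", shape=(1024, 1024), seed=3, n_islets=12)
    _stack, truth = render_channels(ph)
    assert sum(1 for _ in truth.categories) == len(ph.islets)
    assert set(truth.roi_labels.ravel()) - {0} == set(truth.categories)


def test_cluster_count_within_binomial_99_interval():
    # 100 structures at cluster probability 0.10: central 99% binomial mass
    # lies in [3, 18] (enumeration of the binomial pmf)
    from scipy.stats import binom

    lo, hi = binom.ppf(0.005, 100, 0.1), binom.ppf(0.995, 100, 0.1)
    assert (lo, hi) == (3, 18)
    preset = dataclasses.replace(PRESETS["T1D_RO"], cluster_fraction=0.10)
    ph = generate_phantom(preset, shape=(2048, 2048), seed=7, n_islets=100)
    n_clusters = sum(i.true_category == "HORMONE_NEG_CLUSTER" for i in ph.islets)
    assert lo <= n_clusters <= hi


def test_cells_form_connected_chain_within_islet():
    ph = generate_phantom("T1D_LS", shape=(900, 900), seed=5, n_islets=6)
    for islet in ph.islets:
        centers = np.array([c.center for c in islet.cells])
        n = len(centers)
        d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        # no overlap
        off = d[~np.eye(n, dtype=bool)]
        assert (off >= 2 * CELL_R - 1e-6).all()
        # connected under the 2.5-radius adjacency
        adj = d <= 2.5 * CELL_R + 1e-6
        seen = {0}
        frontier = [0]
        while frontier:
            i = frontier.pop()
            for j in np.nonzero(adj[i])[0]:
                if j not in seen:
                    seen.add(int(j))
                    frontier.append(int(j))
        assert seen == set(range(n))


def test_capacity_error_when_image_too_small():
    with pytest.raises(CapacityError):
        generate_phantom("ND", shape=(256, 256), seed=0, n_islets=20)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(cell_type="exocrine", marker_levels={"INS": 0.5}, mda5_positive=False),
        dict(cell_type="alpha", marker_levels={"GCG": 0.0, "CHGA": 0.5}, mda5_positive=False),
        dict(cell_type="beta", marker_levels={"INS": 0.5, "GCG": 0.5, "CHGA": 0.5},
             mda5_positive=False),
        dict(cell_type="delta", marker_levels={"SST": 0.5, "CHGA": 0.5, "MDA5": 0.3},
             mda5_positive=False),
        dict(cell_type="alpha", marker_levels={"GCG": 0.5, "CHGA": 0.5}, mda5_positive=True),
    ],
)
def test_cell_invariants_rejected(kwargs):
    with pytest.raises(ValueError):
        CellSpec(cell_id=0, center=(10, 10), radius=5.0, **kwargs)


def test_idi_islet_with_beta_cell_rejected():
    beta = CellSpec(0, (10, 10), 5.0, "beta",
                    {"INS": 0.7, "GCG": 0.0, "CHGA": 0.6, "MDA5": 0.0}, False)
    with pytest.raises(ValueError):
        IsletSpec(1, [beta], "IDI_MDA5neg", (10, 10))


def test_single_alpha_cell_mda5_mask_equals_gcg_mask():
    islet = alpha_islet(1, (60.0, 60.0), n_cells=1, n_mda5=1)
    ph = TissuePhantom((128, 128), 0.5, [islet], [], noiseless_preset())
    stack, truth = render_channels(ph)
    assert np.array_equal(stack.channel("MDA5") > 0, stack.channel("GCG") > 0)
    assert truth.frac_mda5_gcg[1] == 1.0


def test_roi_labels_cover_one_label_per_islet():
    islet = alpha_islet(1, (60.0, 60.0), n_cells=4, n_mda5=0)
    ph = TissuePhantom((160, 160), 0.5, [islet], [], noiseless_preset())
    _stack, truth = render_channels(ph)
    assert set(np.unique(truth.roi_labels)) == {0, 1}


def test_ground_truth_fraction_matches_pixel_counting(nd_noiseless):
    # independent oracle: count pixels on the rendered noiseless masks
    _ph, stack, truth = nd_noiseless
    gcg = stack.channel("GCG") > 0
    mda5 = stack.channel("MDA5") > 0
    for k, frac in truth.frac_mda5_gcg.items():
        in_islet = truth.roi_labels == k
        g = np.count_nonzero(gcg & in_islet)
        if g == 0:
            assert np.isnan(frac)
        else:
            assert frac == np.count_nonzero(mda5 & gcg & in_islet) / g


def test_preset_invariants():
    with pytest.raises(ValueError):
        CohortPreset("ND", (0.2, 0.1), (0.1, 0.1), idi_fraction=0.3,
                     cluster_fraction=0.0, mda5_neg_islet_fraction=0.0,
                     islets_per_donor=5)
    with pytest.raises(ValueError):
        CohortPreset("AAB_POS", (0.2, 0.1), (0.1, 0.1), idi_fraction=0.0,
                     cluster_fraction=0.1, mda5_neg_islet_fraction=0.0,
                     islets_per_donor=5)


def test_fixture_round_trip_is_bit_exact(tmp_path, nd_noisy):
    _ph, stack, truth = nd_noisy
    write_fixture(stack, truth, tmp_path)
    stack2, labels2, truth_df = read_fixture(tmp_path)
    assert stack2.names == CHANNELS
    assert np.array_equal(stack2.data, stack.data)
    assert np.array_equal(labels2, truth.roi_labels)
    assert len(truth_df) == len(truth.categories)
    # float columns re-parse to full precision
    expect = truth.to_frame()
    for col in ("true_frac_mda5_gcg", "true_frac_mda5_ins"):
        a, b = truth_df[col].to_numpy(), expect[col].to_numpy()
        both_nan = np.isnan(a) & np.isnan(b)
        assert np.array_equal(a[~both_nan], b[~both_nan])
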