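"""Nonparametric summaries and tests against enumeration oracles."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from isletcoloc.stats import (
    clustered_bootstrap_p,
    compare_pipeline_outputs,
    kruskal_wallis_with_posthoc,
    mann_whitney,
    summarize,
)


def enumeration_mw_p(a, b):
    """Oracle: exact two-sided permutation p via midrank sums."""
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n1, n = len(a), len(pooled)
    mu = len(a) * len(b) / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    count = 0
    for sel in itertools.combinations(range(n), n1):
        u = ranks[list(sel)].sum() - n1 * (n1 + 1) / 2.0
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            count += 1
    return count / comb(n, n1)


# --- summaries --------------------------------------------------------------


def test_summarize_median_and_quartiles():
    s = summarize([10, 20, 30])
    assert s.median == 20 and s.n == 3

    s = summarize([5.0] * 6)
    assert s.sd == 0 and s.q1 == s.q3 == s.median == 5.0

    s = summarize(list(range(1, 9)))  # inclusive linear interpolation
    assert (s.q1, s.q3) == (2.75, 6.25)


def test_summarize_excludes_undefined_rates():
    s = summarize([10.0, np.nan, 30.0])
    assert s.n == 2 and s.mean == 20.0
    with pytest.raises(ValueError):
        summarize([np.nan])


# --- Mann-Whitney -----------------------------------------------------------


def test_identical_samples_give_central_u_and_large_p():
    a = [3.0, 1.0, 2.0]
    cmp = mann_whitney(a, list(a))
    assert cmp.statistic == len(a) ** 2 / 2
    assert cmp.p_value >= 0.9


def test_fully_separated_small_samples():
    cmp = mann_whitney([1, 2, 3], [4, 5, 6])
    assert cmp.statistic == 0.0
    assert cmp.p_value == pytest.approx(0.1)  # 2 / C(6,3)

    cmp = mann_whitney([1, 2, 3, 4], [101, 102, 103, 104])
    assert cmp.p_value == pytest.approx(2 / 70)  # minimum for n=(4,4)


def test_all_tied_is_uninformative():
    with pytest.warns(UserWarning, match="tied"):
        cmp = mann_whitney([2, 2, 2], [2, 2])
    assert cmp.p_value == 1.0


@pytest.mark.parametrize("n1,n2", [(2, 3), (3, 5), (4, 4), (5, 8), (8, 8)])
def test_exact_p_matches_enumeration_including_ties(n1, n2):
    rng = np.random.default_rng(n1 * 100 + n2)
    a = rng.integers(0, 5, size=n1).astype(float)  # discrete -> ties likely
    b = rng.integers(0, 5, size=n2).astype(float)
    if np.ptp(np.concatenate([a, b])) == 0:
        a[0] += 1
    cmp = mann_whitney(a, b)
    assert cmp.method_detail == "exact permutation"
    assert cmp.p_value == pytest.approx(enumeration_mw_p(a, b), abs=1e-12)


def test_large_samples_use_normal_approximation():
    rng = np.random.default_rng(0)
    cmp = mann_whitney(rng.normal(size=30), rng.normal(0.2, size=30))
    assert "normal approximation" in cmp.method_detail
    assert 0 <= cmp.p_value <= 1


# --- Kruskal-Wallis + Dunn --------------------------------------------------


def test_three_identical_groups_h_zero_adjusted_p_one():
    g = [1.0, 2.0, 3.0, 4.0]
    cmp = kruskal_wallis_with_posthoc({"a": g, "b": list(g), "c": list(g)})
    assert cmp.statistic == pytest.approx(0.0, abs=1e-12)
    assert (cmp.posthoc["p_adjusted"] >= 0.99).all()


def test_h_closed_form_on_ranks_one_to_nine():
    cmp = kruskal_wallis_with_posthoc(
        {"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]}
    )
    assert cmp.statistic == pytest.approx(7.2)
    assert cmp.posthoc is not None and len(cmp.posthoc) == 3


def test_h_invariant_under_monotone_shift():
    groups = {"a": [1.0, 5.0, 2.0], "b": [4.0, 9.0, 6.0], "c": [7.0, 3.0, 8.0]}
    h1 = kruskal_wallis_with_posthoc(groups).statistic
    shifted = {k: [x + 100.0 for x in v] for k, v in groups.items()}
    assert kruskal_wallis_with_posthoc(shifted).statistic == pytest.approx(h1)


def test_holm_adjusted_never_below_raw():
    rng = np.random.default_rng(3)
    groups = {k: rng.normal(loc, size=12) for k, loc in
              zip("abcd", (0.0, 0.3, 0.8, 0.1))}
    cmp = kruskal_wallis_with_posthoc(groups)
    assert (cmp.posthoc["p_adjusted"] >= cmp.posthoc["p_raw"] - 1e-15).all()
    cmp_b = kruskal_wallis_with_posthoc(groups, adjust="bonferroni")
    assert (cmp_b.posthoc["p_adjusted"] >= cmp_b.posthoc["p_raw"] - 1e-15).all()


def test_kw_input_validation():
    with pytest.raises(ValueError):
        kruskal_wallis_with_posthoc({"a": [1], "b": [2]})
    with pytest.raises(ValueError):
        kruskal_wallis_with_posthoc({"a": [1], "b": [2], "c": []})


# --- pipeline contrasts -----------------------------------------------------


def _toy_tables():
    rng = np.random.default_rng(7)
    rows_m, rows_r = [], []
    for group, gcg_mu in (("ND", 20.0), ("T1D_RO", 30.0)):
        for i in range(12):
            donor = f"{group}_d{i % 3}"
            for pair, mu in (("MDA5-GCG", gcg_mu), ("MDA5-INS", gcg_mu - 6)):
                rows_m.append({"donor_id": donor, "islet_id": i + 1, "pair": pair,
                               "rate_percent": max(0.0, rng.normal(mu, 4)),
                               "defined": True})
            rows_r.append({"donor_id": donor, "islet_id": i + 1, "group": group,
                           "insulin_status": "ICI" if i % 2 else "IDI",
                           "category": "ICI_MDA5pos" if i % 2 else "IDI_MDA5pos"})
    return pd.DataFrame(rows_m), pd.DataFrame(rows_r)


def test_contrast_report_structure():
    m, r = _toy_tables()
    report = compare_pipeline_outputs(m, r)
    labels = set(report["contrast"])
    assert "MDA5-GCG vs MDA5-INS within ND" in labels
    assert "MDA5-GCG: T1D_RO vs ND" in labels
    assert "MDA5-GCG: ICI vs IDI within T1D" in labels
    assert ((report["p_value"] >= 0) & (report["p_value"] <= 1)).all()


def test_empty_cell_contrast_skipped_with_warning():
    m, r = _toy_tables()
    m = m[m["pair"] != "MDA5-INS"]
    with pytest.warns(UserWarning, match="skipped"):
        report = compare_pipeline_outputs(m, r)
    assert not any("within ND" in c for c in report["contrast"])


def test_clustered_bootstrap_p_in_unit_interval():
    rng = np.random.default_rng(0)
    values = np.concatenate([rng.normal(10, 2, 40), rng.normal(14, 2, 40)])
    groups = np.array(["a"] * 40 + ["b"] * 40)
    donors = np.array([f"{g}{i % 4}" for i, g in enumerate(groups)])
    p = clustered_bootstrap_p(values, groups, donors, n_boot=200, seed=1)
    assert 0 < p <= 1
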