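"""Nonparametric summaries and group comparisons of per-islet rates.

Groups of per-islet colocalization rates are summarized as median with
interquartile range and compared with the Mann-Whitney U test (exact
permutation null for small samples, tie-corrected normal approximation
otherwise) or the Kruskal-Wallis test followed by Dunn pairwise z-tests
with Holm (or Bonferroni) adjustment.  Islets are treated as independent
observations; an optional donor-level clustered bootstrap is available as
a robustness check for the two-sample contrast.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class SummaryStats:
    n: int
    median: float
    q1: float
    q3: float
    mean: float
    sd: float


@dataclass(frozen=True)
class GroupComparison:
    grouping: str
    test: str  # mann_whitney | kruskal_wallis
    statistic: float
    p_value: float
    n: dict[str, int]
    alpha: float = 0.05
    method_detail: str = ""
    posthoc: pd.DataFrame | None = None  # pair, z, p_raw, p_adjusted

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def summarize(rates) -> SummaryStats:
    """Median/IQR (inclusive linear-interpolation quartiles) plus mean/sd.

    NaN entries (undefined rates) are excluded; the reported n counts
    defined rates only.
    """
    x = np.asarray(rates, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("no defined rates to summarize")
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation
    return SummaryStats(
        n=int(x.size),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)) if x.size > 1 else 0.0,
    )


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a: #{a_i > b_j} + 0.5 #{a_i == b_j}."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def _exact_mw_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided exact permutation p for the Mann-Whitney U.

    Enumerates all C(n1+n2, n1) label assignments of the pooled sample and
    counts assignments at least as extreme (|U - n1*n2/2|) as observed.
    Ties are handled by the 0.5 convention in U itself.
    """
    pooled = np.concatenate([a, b])
    n1, n = len(a), len(a) + len(b)
    mu = len(a) * len(b) / 2.0
    u_obs = _u_statistic(a, b)
    d_obs = abs(u_obs - mu)
    # pairwise win matrix; U(S) = sum_{i in S, j not in S} M[i, j]
    m = (pooled[:, None] > pooled[None, :]) + 0.5 * (pooled[:, None] == pooled[None, :])
    np.fill_diagonal(m, 0.0)
    subsets = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n), n1)),
        dtype=np.intp,
    ).reshape(-1, n1)
    z = np.zeros((len(subsets), n))
    np.put_along_axis(z, subsets, 1.0, axis=1)
    u_all = ((z @ m) * (1.0 - z)).sum(axis=1)
    count = int(np.count_nonzero(np.abs(u_all - mu) >= d_obs - 1e-9))
    return u_obs, count / comb(n, n1)


def mann_whitney(a, b, exact_below: int = 8, alpha: float = 0.05) -> GroupComparison:
    """Two-sided Mann-Whitney U test.

    Exact permutation null when both samples have at most ``exact_below``
    observations; otherwise the tie-corrected normal approximation with
    continuity correction.  If every pooled value is tied the test is
    uninformative and p = 1 is returned with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.ptp(np.concatenate([a, b])) == 0:
        warnings.warn("all values tied across both samples; Mann-Whitney is uninformative")
        return GroupComparison(
            grouping="a vs b", test="mann_whitney", statistic=a.size * b.size / 2.0,
            p_value=1.0, n={"a": int(a.size), "b": int(b.size)}, alpha=alpha,
            method_detail="degenerate (all tied)",
        )
    if a.size <= exact_below and b.size <= exact_below:
        u, p = _exact_mw_p(a, b)
        detail = "exact permutation"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        u, p = float(res.statistic), float(res.pvalue)
        detail = "normal approximation, tie-corrected, continuity-corrected"
    return GroupComparison(
        grouping="a vs b", test="mann_whitney", statistic=u, p_value=float(min(p, 1.0)),
        n={"a": int(a.size), "b": int(b.size)}, alpha=alpha, method_detail=detail,
    )


def _dunn_posthoc(groups: dict[str, np.ndarray], adjust: str) -> pd.DataFrame:
    """Dunn pairwise z-tests on pooled ranks, with tie correction."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    ranks = sps.rankdata(pooled)
    N = len(pooled)
    # mean rank per group
    mean_rank: dict[str, float] = {}
    start = 0
    for g in names:
        k = len(groups[g])
        mean_rank[g] = float(ranks[start:start + k].mean())
        start += k
    # tie correction term
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1)) if N > 1 else 0.0

    rows = []
    for g1, g2 in itertools.combinations(names, 2):
        se = np.sqrt(var_base * (1.0 / len(groups[g1]) + 1.0 / len(groups[g2])))
        z = (mean_rank[g1] - mean_rank[g2]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"pair": f"{g1} vs {g2}", "z": float(z), "p_raw": float(min(p, 1.0))})
    table = pd.DataFrame(rows, columns=["pair", "z", "p_raw"])
    table["p_adjusted"] = multipletests(table["p_raw"], method=adjust)[1]
    return table


def kruskal_wallis_with_posthoc(
    groups: dict[str, list | np.ndarray],
    adjust: str = "holm",
    alpha: float = 0.05,
) -> GroupComparison:
    """Kruskal-Wallis omnibus (tie-corrected H) + Dunn post-hoc z-tests.

    ``adjust`` is 'holm' (default) or 'bonferroni'.  Requires >= 3
    non-empty groups; the post-hoc table covers every pair.
    """
    if len(groups) < 3:
        raise ValueError("Kruskal-Wallis with post-hoc needs at least 3 groups")
    clean = {}
    for name, vals in groups.items():
        x = np.asarray(vals, dtype=float)
        x = x[~np.isnan(x)]
        if x.size == 0:
            raise ValueError(f"group {name!r} is empty")
        clean[name] = x
    if adjust not in ("holm", "bonferroni"):
        raise ValueError("adjust must be 'holm' or 'bonferroni'")
    pooled = np.concatenate(list(clean.values()))
    if np.ptp(pooled) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*clean.values())
    posthoc = _dunn_posthoc(clean, adjust)
    return GroupComparison(
        grouping=" vs ".join(clean),
        test="kruskal_wallis",
        statistic=float(h),
        p_value=float(p),
        n={g: int(len(v)) for g, v in clean.items()},
        alpha=alpha,
        method_detail=f"Dunn post-hoc, {adjust} adjustment",
        posthoc=posthoc,
    )


def clustered_bootstrap_p(
    values: np.ndarray,
    groups: np.ndarray,
    donors: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
) -> float:
    """Donor-level clustered bootstrap p for a two-group median difference.

    Robustness check for the default islet-level tests: donors (not
    islets) are resampled within each group and the achieved two-sided
    significance of the median difference is estimated from the bootstrap
    null distribution of the centered statistic.
    """
    rng = np.random.default_rng(seed)
    names = np.unique(groups)
    if len(names) != 2:
        raise ValueError("clustered bootstrap supports exactly two groups")
    obs = np.median(values[groups == names[0]]) - np.median(values[groups == names[1]])
    boots = []
    for _ in range(n_boot):
        diffs = []
        for g in names:
            d_ids = np.unique(donors[groups == g])
            take = rng.choice(d_ids, size=len(d_ids), replace=True)
            vals = np.concatenate([values[(donors == d) & (groups == g)] for d in take])
            diffs.append(np.median(vals))
        boots.append(diffs[0] - diffs[1])
    boots = np.asarray(boots) - np.mean(boots)  # center to form a null
    p = (np.sum(np.abs(boots) >= abs(obs)) + 1) / (n_boot + 1)
    return float(p)


# ---------------------------------------------------------------------------
# pipeline-level contrast set


def compare_pipeline_outputs(
    measurements: pd.DataFrame,
    records: pd.DataFrame,
    alpha: float = 0.05,
    exact_below: int = 8,
) -> pd.DataFrame:
    """The standard contrast set over joined measurement/record tables.

    Emits, as a tidy report table:

    * within each donor group: MDA5-GCG vs MDA5-INS rates;
    * for each pair: every non-reference group vs ND;
    * MDA5-GCG in ICI vs IDI islets within the T1D groups.

    Undefined rates are excluded, as are hormone-negative islet-like
    clusters (they are tabulated separately, not islets); contrasts with
    an empty cell are skipped with a warning.
    """
    need = {"donor_id", "islet_id", "pair", "rate_percent", "defined"}
    if not need.issubset(measurements.columns):
        raise ValueError(f"measurements table must have columns {sorted(need)}")
    m = measurements[measurements["defined"]].copy()
    # the record table is authoritative for grouping columns
    m = m.drop(columns=[c for c in ("group", "insulin_status", "category") if c in m], errors="ignore")
    joined = m.merge(
        records[["donor_id", "islet_id", "group", "insulin_status", "category"]],
        on=["donor_id", "islet_id"],
        how="inner",
    )
    joined = joined[joined["category"] != "HORMONE_NEG_CLUSTER"]
    if joined.empty:
        raise ValueError("empty join between measurements and records")

    rows = []

    def _run(label: str, a: np.ndarray, b: np.ndarray, sides: tuple[str, str]) -> None:
        if len(a) == 0 or len(b) == 0:
            warnings.warn(f"contrast {label!r} skipped: empty cell")
            return
        cmp = mann_whitney(a, b, exact_below=exact_below, alpha=alpha)
        sa, sb = summarize(a), summarize(b)
        rows.append(
            {
                "contrast": label,
                "side_a": sides[0], "side_b": sides[1],
                "n_a": sa.n, "n_b": sb.n,
                "median_a": sa.median, "median_b": sb.median,
                "q1_a": sa.q1, "q3_a": sa.q3, "q1_b": sb.q1, "q3_b": sb.q3,
                "test": cmp.test, "method": cmp.method_detail,
                "statistic": cmp.statistic, "p_value": cmp.p_value,
                "significant": cmp.p_value < alpha,
            }
        )

    groups_present = sorted(joined["group"].unique())
    for g in groups_present:
        sub = joined[joined["group"] == g]
        _run(
            f"MDA5-GCG vs MDA5-INS within {g}",
            sub.loc[sub["pair"] == "MDA5-GCG", "rate_percent"].to_numpy(),
            sub.loc[sub["pair"] == "MDA5-INS", "rate_percent"].to_numpy(),
            ("MDA5-GCG", "MDA5-INS"),
        )
    for pair in sorted(joined["pair"].unique()):
        ref = joined[(joined["group"] == "ND") & (joined["pair"] == pair)]
        for g in groups_present:
            if g == "ND":
                continue
            test = joined[(joined["group"] == g) & (joined["pair"] == pair)]
            _run(
                f"{pair}: {g} vs ND",
                test["rate_percent"].to_numpy(),
                ref["rate_percent"].to_numpy(),
                (g, "ND"),
            )
    t1d = joined[joined["group"].isin(["T1D_RO", "T1D_LS"]) & (joined["pair"] == "MDA5-GCG")]
    t1d = t1d[t1d["category"] != "HORMONE_NEG_CLUSTER"]
    _run(
        "MDA5-GCG: ICI vs IDI within T1D",
        t1d.loc[t1d["insulin_status"] == "ICI", "rate_percent"].to_numpy(),
        t1d.loc[t1d["insulin_status"] == "IDI", "rate_percent"].to_numpy(),
        ("ICI", "IDI"),
    )
    return pd.DataFrame(rows)
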