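"""Socio-spatial summaries of access and the HLI.

Reproduces, for any region, the descriptive analyses used to characterise
the index: median distances by deprivation decile with a group-difference
test, the goods-vs-bads composite-rank correlation (overall and by
deprivation quintile), and population shares by HLI class overall, by
deprivation quintile and by urban/rural class.

Median distances are meshblock-weighted (each area unit counts once);
population shares are population-weighted.  The group-difference test is
Kruskal–Wallis: a nonparametric test matches the rank-based framing and
the heavily skewed distance distributions.  Quintiles are derived from
deciles as ceil(decile / 2) (quintile 5 = most deprived).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import DOMAIN_ORDER, AccessTable, InputError

logger = logging.getLogger(__name__)


def dep_quintile(decile) -> np.ndarray:
    """Deprivation quintile from decile: ceil(decile / 2)."""
    return -(-np.asarray(decile, dtype=int) // 2)


def group_difference_test(values, groups, permutations: int | None = None,
                          seed: int = 0) -> tuple[float, float]:
    """Kruskal–Wallis H and p for a difference in location across groups.

    With ``permutations`` set, the p-value is instead estimated by
    permuting group labels (seeded); identical values in every group give
    H = 0, p = 1 by convention.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise InputError("group_difference_test: need >= 2 non-empty groups")
    samples = [values[groups == g] for g in levels]
    if np.ptp(values) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    if permutations is not None:
        rng = np.random.default_rng(seed)
        sizes = [len(s) for s in samples]
        cuts = np.cumsum(sizes)[:-1]
        count = 0
        for _ in range(permutations):
            perm = rng.permutation(values)
            h_b, _ = stats.kruskal(*np.split(perm, cuts))
            if h_b >= h:
                count += 1
        p = (count + 1) / (permutations + 1)
    return float(h), float(p)


@dataclass
class GradientTable:
    """Median distance (km) per domain, overall and by deprivation decile,
    with a per-domain group-difference test."""

    medians: pd.DataFrame  # rows "overall", "D1".."D10"; columns = domains
    tests: pd.DataFrame    # per-domain statistic and p_value


def median_distance_by_deprivation(access: AccessTable,
                                   meshblocks: pd.DataFrame
                                   ) -> GradientTable:
    """Meshblock-level median distances by deprivation decile plus a
    Kruskal–Wallis test per domain.

    ``meshblocks`` must carry a dep_decile column indexed by meshblock id.
    """
    if "dep_decile" not in meshblocks.columns:
        raise InputError("median_distance_by_deprivation: missing dep_decile")
    dep = meshblocks.loc[access.distances.index, "dep_decile"]
    if dep.isna().any():
        missing = list(dep.index[dep.isna()])
        raise InputError(f"missing dep_decile for ids {missing}")
    dep = dep.astype(int)

    rows = ["overall"] + [f"D{d}" for d in sorted(dep.unique())]
    medians = pd.DataFrame(index=rows, columns=list(DOMAIN_ORDER),
                           dtype=float)
    tests = pd.DataFrame(index=list(DOMAIN_ORDER),
                         columns=["statistic", "p_value"], dtype=float)
    for dom in DOMAIN_ORDER:
        vals = access.distances[dom]
        medians.loc["overall", dom] = vals.median()
        for d in sorted(dep.unique()):
            medians.loc[f"D{d}", dom] = vals[dep == d].median()
        if dep.nunique() >= 2:
            h, p = group_difference_test(vals.to_numpy(), dep.to_numpy())
        else:
            h, p = np.nan, np.nan
        tests.loc[dom] = [h, p]
    return GradientTable(medians=medians, tests=tests)


def population_share_by_hli(records: pd.DataFrame, meshblocks: pd.DataFrame,
                            grouping: str = "none") -> pd.DataFrame:
    """Population share (%) in each HLI class, optionally within deprivation
    quintiles or urban/rural classes.

    Returns a tidy frame (group, hli_label, population, share_pct); shares
    sum to 100 within every non-empty group.  Zero-population meshblocks
    contribute nothing; a level with zero total population is dropped with
    a warning.
    """
    if grouping not in ("none", "dep_quintile", "urban_rural"):
        raise InputError(f"unknown grouping {grouping!r}")
    df = records[["hli_label"]].join(
        meshblocks[["population", "dep_decile", "urban_rural"]])
    if grouping == "none":
        df["group"] = "all"
    elif grouping == "dep_quintile":
        df["group"] = "Q" + pd.Series(
            dep_quintile(df["dep_decile"]), index=df.index).astype(str)
    else:
        df["group"] = df["urban_rural"]
    tally = (df.groupby(["group", "hli_label"], sort=True)["population"]
             .sum().reset_index())
    out = []
    for g, sub in tally.groupby("group", sort=True):
        total = sub["population"].sum()
        if total == 0:
            logger.warning("grouping level %s has zero population; "
                           "reported as empty", g)
            continue
        sub = sub.assign(share_pct=100.0 * sub["population"] / total)
        out.append(sub)
    if not out:
        return pd.DataFrame(
            columns=["group", "hli_label", "population", "share_pct"])
    return pd.concat(out, ignore_index=True)


def goods_bads_rank_correlation(composite: pd.DataFrame,
                                meshblocks: pd.DataFrame,
                                by: str = "none") -> pd.Series:
    """Spearman correlation of goods vs bads composite ranks, overall and
    (with ``by='dep_quintile'``) per deprivation quintile.

    Groups with fewer than 3 meshblocks are reported as NaN (undefined).
    """
    if by not in ("none", "dep_quintile"):
        raise InputError(f"unknown grouping {by!r}")
    g = composite["goods_rank"].to_numpy()
    b = composite["bads_rank"].to_numpy()
    out = {"overall": float(stats.spearmanr(g, b).statistic)
           if len(g) >= 3 else np.nan}
    if by == "dep_quintile":
        q = dep_quintile(meshblocks.loc[composite.index, "dep_decile"])
        for level in sorted(np.unique(q)):
            mask = q == level
            if mask.sum() < 3:
                out[f"Q{level}"] = np.nan
            else:
                out[f"Q{level}"] = float(
                    stats.spearmanr(g[mask], b[mask]).statistic)
    return pd.Series(out, name="spearman_rho")


# ---------------------------------------------------------------------------
# presentation-only plots
# ---------------------------------------------------------------------------

def plot_share_bars(shares: pd.DataFrame, path: str) -> None:
    """Stacked bar chart of HLI population shares per group (file output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from .index import HEALTHINESS_ORDER

    pivot = shares.pivot_table(index="group", columns="hli_label",
                               values="share_pct", fill_value=0.0)
    cols = [c for c in HEALTHINESS_ORDER if c in pivot.columns]
    fig, ax = plt.subplots(figsize=(8, 4))
    pivot[cols].plot(kind="bar", stacked=True, ax=ax,
                     colormap="RdYlBu_r")
    ax.set_ylabel("population share (%)")
    ax.legend(title="HLI class", fontsize=7, ncol=3)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_rank_scatter(composite: pd.DataFrame, meshblocks: pd.DataFrame,
                      path: str) -> None:
    """Goods vs bads composite ranks coloured by deprivation quintile, with
    a per-quintile moving-median trend (presentation only)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    q = dep_quintile(meshblocks.loc[composite.index, "dep_decile"])
    fig, ax = plt.subplots(figsize=(6, 5))
    cmap = plt.get_cmap("viridis", 5)
    for level in range(1, 6):
        mask = q == level
        if not mask.any():
            continue
        g = composite.loc[mask, "goods_rank"]
        b = composite.loc[mask, "bads_rank"]
        ax.scatter(g, b, s=4, alpha=0.4, color=cmap(level - 1),
                   label=f"Q{level}")
        order = np.argsort(g.to_numpy())
        win = max(5, mask.sum() // 10)
        smooth = pd.Series(b.to_numpy()[order]).rolling(
            win, center=True, min_periods=1).median()
        ax.plot(g.to_numpy()[order], smooth, color=cmap(level - 1), lw=1.5)
    ax.set_xlabel("goods composite rank")
    ax.set_ylabel("bads composite rank")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
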