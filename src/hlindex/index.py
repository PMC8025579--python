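"""Ranked-access composite index (the Healthy Location Index proper).

Each meshblock is ranked 1..N within each of the ten domains (1 = closest).
The five 'goods' ranks and the five 'bads' ranks are summed separately and
each sum is ranked again, giving combined-access ranks that are cut into
equal-count deciles (decile 1 = best accessibility).  Deciles collapse to
three categories (1-3 -> 1, 4-7 -> 2, 8-10 -> 3) and the pair
(goods category, bads category) yields one of nine labels "g–b".

Label "1–3" (best goods access, worst bads access) is the healthiest
class; "3–1" the unhealthiest.  Domains are unweighted throughout, and all
outputs depend on the distances only through their within-domain order.

Ties are broken by ascending meshblock id (strict ordinal ranks, so each
domain's ranks are exactly a permutation of 1..N).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .types import (
    BAD_DOMAINS,
    DOMAIN_ORDER,
    GOOD_DOMAINS,
    AccessTable,
    ConfigurationError,
    InputError,
)

#: the nine labels ordered healthiest -> unhealthiest.  Only the extremes
#: ("1–3" healthiest, "3–1" unhealthiest) are substantive; the middle order
#: (sorted by goods_category + (4 - bads_category), then goods_category)
#: is this package's convention for sorting outputs.
HEALTHINESS_ORDER: tuple[str, ...] = (
    "1–3", "1–2", "2–3", "1–1", "2–2", "3–3", "2–1", "3–2", "3–1",
)
_HEALTHINESS_RANK = {lab: k + 1 for k, lab in enumerate(HEALTHINESS_ORDER)}


def rank_domain(distances: Sequence[float], ids: Sequence[str]) -> np.ndarray:
    """Ordinal ranks 1..N ascending by distance, ties by ascending id."""
    values = np.asarray(distances, dtype=float)
    ids_arr = np.asarray(ids)
    if len(values) != len(ids_arr):
        raise InputError("rank_domain: distances and ids differ in length")
    if not np.isfinite(values).all():
        bad = ids_arr[~np.isfinite(values)]
        raise InputError(f"rank_domain: non-finite distances for ids "
                         f"{list(bad)}")
    order = np.lexsort((ids_arr, values))
    ranks = np.empty(len(values), dtype=int)
    ranks[order] = np.arange(1, len(values) + 1)
    return ranks


def composite_rank(rank_table: pd.DataFrame,
                   domain_set: str | Sequence[str]
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Sum the per-domain ranks of one polarity side and rank the sums.

    ``domain_set`` may be ``"goods"`` / ``"bads"`` (the five domains of
    that side, count enforced) or an explicit column list (any non-empty
    subset, for degenerate testing).  Returns (rank_sums, composite_ranks).
    """
    if isinstance(domain_set, str):
        if domain_set == "goods":
            domains = list(GOOD_DOMAINS)
        elif domain_set == "bads":
            domains = list(BAD_DOMAINS)
        else:
            raise ConfigurationError(
                f"domain_set must be 'goods', 'bads' or a column list, "
                f"got {domain_set!r}")
        if not all(d in rank_table.columns for d in domains):
            missing = [d for d in domains if d not in rank_table.columns]
            raise ConfigurationError(
                f"rank table is missing domains {missing}; a composite "
                "side needs exactly its 5 domains")
    else:
        domains = list(domain_set)
        if len(domains) == 0:
            raise ConfigurationError("composite_rank: empty domain set")
    sums = rank_table[domains].sum(axis=1).to_numpy()
    comp = rank_domain(sums, rank_table.index.to_numpy())
    return sums, comp


def assign_deciles(ranks: Sequence[int]) -> np.ndarray:
    """Equal-count deciles: decile(r) = ceil(10 r / N) for ranks 1..N."""
    ranks = np.asarray(ranks, dtype=int)
    n = len(ranks)
    if n < 10:
        raise InputError(f"assign_deciles: need at least 10 units, got {n}")
    if sorted(ranks) != list(range(1, n + 1)):
        raise InputError("assign_deciles: ranks are not a permutation "
                         "of 1..N")
    return -(-10 * ranks // n)


def collapse_categories(decile) -> np.ndarray | int:
    """Deciles 1-3 -> category 1 (best access), 4-7 -> 2, 8-10 -> 3."""
    arr = np.asarray(decile, dtype=int)
    if ((arr < 1) | (arr > 10)).any():
        raise InputError(f"collapse_categories: decile outside 1..10")
    out = np.where(arr <= 3, 1, np.where(arr <= 7, 2, 3))
    return int(out) if np.isscalar(decile) else out


def combine_hli(goods_category: int, bads_category: int) -> tuple[str, int]:
    """Label "g–b" (en-dash) and its healthiness rank (1 = healthiest)."""
    g, b = int(goods_category), int(bads_category)
    if not (1 <= g <= 3 and 1 <= b <= 3):
        raise InputError(
            f"combine_hli: categories ({g}, {b}) outside 1..3")
    label = f"{g}–{b}"
    return label, _HEALTHINESS_RANK[label]


@dataclass
class HLIResult:
    """Full output of the index pipeline, all keyed by meshblock id."""

    rank_table: pd.DataFrame   # 10 domain rank columns
    composite: pd.DataFrame    # goods/bads rank sums, ranks, deciles
    records: pd.DataFrame      # categories, hli_label, healthiness_rank
    distances: pd.DataFrame    # the input access distances (km)

    def to_frame(self) -> pd.DataFrame:
        """One wide table: distances, ranks, composites, categories, label."""
        out = self.distances.copy()
        out.columns = [f"dist_{d}" for d in out.columns]
        ranks = self.rank_table.copy()
        ranks.columns = [f"rank_{d}" for d in ranks.columns]
        return pd.concat([out, ranks, self.composite, self.records], axis=1)


def compute_hli(access: AccessTable) -> HLIResult:
    """Run the full deterministic pipeline on a 10-domain access table."""
    access.validate()
    dist = access.distances
    n = len(dist)
    if n < 10:
        raise InputError(f"compute_hli: need at least 10 meshblocks, got {n}")
    ids = dist.index.to_numpy()

    rank_table = pd.DataFrame(
        {d: rank_domain(dist[d].to_numpy(), ids) for d in DOMAIN_ORDER},
        index=dist.index)

    composite = pd.DataFrame(index=dist.index)
    for side in ("goods", "bads"):
        sums, comp = composite_rank(rank_table, side)
        composite[f"{side}_rank_sum"] = sums
        composite[f"{side}_rank"] = comp
        composite[f"{side}_decile"] = assign_deciles(comp)

    records = pd.DataFrame(index=dist.index)
    records["goods_category"] = collapse_categories(
        composite["goods_decile"].to_numpy())
    records["bads_category"] = collapse_categories(
        composite["bads_decile"].to_numpy())
    labels, hranks = zip(*(combine_hli(g, b) for g, b in
                           zip(records["goods_category"],
                               records["bads_category"])))
    records["hli_label"] = labels
    records["healthiness_rank"] = hranks
    return HLIResult(rank_table=rank_table, composite=composite,
                     records=records, distances=dist.copy())
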