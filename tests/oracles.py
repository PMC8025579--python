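"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive — exhaustive scans, pure-Python
Dijkstra with explicit edge splitting, sort-and-enumerate ranking — and
shares no code with the package's implementations.
"""

from __future__ import annotations

import heapq
import math


def brute_snap(point, network):
    """Exhaustive point-to-segment scan.

    Returns (edge (u, v), offset_m, access_m) with ties broken by the
    lexicographically smallest node-id pair.
    """
    px, py = point
    best = None
    for u, v, length in sorted(network.edges):
        ux, uy = network.nodes[u]
        vx, vy = network.nodes[v]
        dx, dy = vx - ux, vy - uy
        seg2 = dx * dx + dy * dy
        t = 0.0 if seg2 == 0 else ((px - ux) * dx + (py - uy) * dy) / seg2
        t = min(max(t, 0.0), 1.0)
        qx, qy = ux + t * dx, uy + t * dy
        d = math.hypot(px - qx, py - qy)
        if best is None or d < best[0] - 1e-9:
            best = (d, (u, v), t * length)
    return best[1], best[2], best[0]


def brute_network_nearest(origin, facilities, network):
    """Shortest origin->nearest-facility distance (km) by explicit edge
    splitting and a pure-Python Dijkstra; math.inf if unreachable."""
    snaps = [brute_snap(p, network) for p in [origin] + list(facilities)]
    # build adjacency with every snap inserted into its edge
    by_edge = {}
    for k, (edge, off, _) in enumerate(snaps):
        by_edge.setdefault(edge, []).append((off, f"snap{k}"))
    adj = {}

    def link(a, b, w):
        adj.setdefault(a, []).append((b, w))
        adj.setdefault(b, []).append((a, w))

    for u, v, length in network.edges:
        if (u, v) in by_edge:
            chain = [(0.0, u)] + sorted(by_edge[(u, v)]) + [(length, v)]
            for (o1, n1), (o2, n2) in zip(chain, chain[1:]):
                link(n1, n2, max(o2 - o1, 0.0))
        else:
            link(u, v, length)

    dist = {"snap0": snaps[0][2]}  # origin access leg
    heap = [(snaps[0][2], "snap0")]
    while heap:
        d, node = heapq.heappop(heap)
        if d > dist.get(node, math.inf):
            continue
        for nb, w in adj.get(node, []):
            nd = d + w
            if nd < dist.get(nb, math.inf) - 1e-12:
                dist[nb] = nd
                heapq.heappush(heap, (nd, nb))
    best = math.inf
    for k in range(1, len(snaps)):
        d = dist.get(f"snap{k}", math.inf) + snaps[k][2]  # facility leg
        best = min(best, d)
    return best / 1000.0


def naive_ranks(values, ids):
    """Sort-then-enumerate ordinal ranks, ties by ascending id."""
    order = sorted(range(len(values)), key=lambda i: (values[i], ids[i]))
    ranks = [0] * len(values)
    for pos, i in enumerate(order):
        ranks[i] = pos + 1
    return ranks


def naive_hli(distances):
    """Full index pipeline, straight from the definitions.

    ``distances``: dict domain -> list of km values, plus an 'ids' key.
    Returns dict of per-meshblock lists: goods/bads rank sums, ranks,
    deciles, categories and labels.
    """
    ids = distances["ids"]
    n = len(ids)
    goods = ["green", "blue", "physical_activity", "fruit_veg", "supermarket"]
    bads = ["fast_food", "takeaway", "dairy_convenience", "alcohol", "gaming"]
    ranks = {d: naive_ranks(distances[d], ids)
             for d in goods + bads}
    out = {"ids": ids}
    for side, doms in (("goods", goods), ("bads", bads)):
        sums = [sum(ranks[d][i] for d in doms) for i in range(n)]
        comp = naive_ranks(sums, ids)
        deciles = [math.ceil(10 * r / n) for r in comp]
        cats = [1 if dec <= 3 else 2 if dec <= 7 else 3 for dec in deciles]
        out[f"{side}_rank_sum"] = sums
        out[f"{side}_rank"] = comp
        out[f"{side}_decile"] = deciles
        out[f"{side}_category"] = cats
    out["hli_label"] = [f"{g}–{b}" for g, b in
                        zip(out["goods_category"], out["bads_category"])]
    out["ranks"] = ranks
    return out


def naive_distance_transform(presence, resolution):
    """O(cells x true cells) exhaustive Euclidean distance transform."""
    import numpy as np
    rows, cols = presence.shape
    true_idx = [(i, j) for i in range(rows) for j in range(cols)
                if presence[i, j]]
    out = [[0.0] * cols for _ in range(rows)]
    for i in range(rows):
        for j in range(cols):
            out[i][j] = min(
                math.hypot(i - ti, j - tj) * resolution
                for ti, tj in true_idx)
    return np.array(out)
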