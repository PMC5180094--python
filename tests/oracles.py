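"""Independent brute-force reference implementations.

These deliberately avoid the library code paths (and the networkx/scipy
routines behind them): shortest paths by simple-path enumeration, dense
power iteration written out by hand, naive pruning loops, naive Borda
counting and exhaustive subset-pool scoring. They are only feasible on tiny
inputs, which is the point — they pin the semantics the fast code must match.
"""

from __future__ import annotations

import itertools
import math

from metacentrality import WeightedNetwork


# -- shortest paths / closeness -------------------------------------------


def enumerate_shortest_distance(net: WeightedNetwork, u: str, v: str) -> float:
    """Min total length (1/w per edge) over all simple paths, by enumeration."""
    if u == v:
        return 0.0
    nodes = net.nodes
    best = math.inf
    for r in range(2, len(nodes) + 1):
        for path in itertools.permutations([n for n in nodes if n not in (u, v)], r - 2):
            full = (u, *path, v)
            length = 0.0
            ok = True
            for a, b in zip(full, full[1:]):
                if b not in net.neighbors(a):
                    ok = False
                    break
                length += 1.0 / net.weight(a, b)
            if ok:
                best = min(best, length)
    return best


def naive_closeness(net: WeightedNetwork) -> dict[str, float]:
    n = net.n_nodes
    return {
        u: (n - 1) / sum(enumerate_shortest_distance(net, u, v) for v in net.nodes if v != u)
        for u in net.nodes
    }


# -- eigenvector by dense power iteration ----------------------------------


def naive_eigenvector(net: WeightedNetwork, iters: int = 10_000) -> dict[str, float]:
    # shifted iteration (I + W): same eigenvectors, but the dominant
    # eigenvalue 1 + lambda_max is strictly largest in magnitude even on
    # bipartite graphs, where plain power iteration oscillates
    nodes = net.nodes
    x = {n: 1.0 for n in nodes}
    for _ in range(iters):
        y = {
            n: x[n] + sum(net.weight(n, m) * x[m] for m in net.neighbors(n))
            for n in nodes
        }
        norm = math.sqrt(sum(v * v for v in y.values()))
        x = {n: v / norm for n, v in y.items()}
    return x


# -- k-shell by naive pruning ----------------------------------------------


def _prune(adj: dict[str, dict[str, float]], metric) -> dict[str, float]:
    adj = {u: dict(nbrs) for u, nbrs in adj.items()}
    shell: dict[str, float] = {}
    k = 1
    while adj:
        while True:
            doomed = sorted(u for u in adj if metric(adj, u) <= k)
            if not doomed:
                break
            for u in doomed:
                shell[u] = float(k)
                for v in adj[u]:
                    del adj[v][u]
                del adj[u]
        k += 1
    return shell


def naive_kshell(net: WeightedNetwork) -> dict[str, float]:
    adj = {u: {v: net.weight(u, v) for v in net.neighbors(u)} for u in net.nodes}
    return _prune(adj, lambda a, u: len(a[u]))


def naive_kshell_weighted(net: WeightedNetwork) -> dict[str, float]:
    adj = {u: {v: net.weight(u, v) for v in net.neighbors(u)} for u in net.nodes}

    def composite(a, u):
        k = len(a[u])
        s = sum(a[u].values())
        return math.floor(math.sqrt(k * s) + 0.5)

    return _prune(adj, composite)


# -- expected force by sequence enumeration --------------------------------


def naive_expected_force(net: WeightedNetwork, seed: str) -> float:
    """Enumerate ordered 2-event transmission sequences via permutations."""
    forces = []
    others = [n for n in net.nodes if n != seed]
    for first, second in itertools.permutations(others, 2):
        # event 1: seed infects a neighbour
        if first not in net.neighbors(seed):
            continue
        # event 2: cluster {seed, first} infects a neighbour of either
        if second not in set(net.neighbors(seed)) | set(net.neighbors(first)):
            continue
        cluster = {seed, first, second}
        d = 0.0
        for c in cluster:
            for nb in net.neighbors(c):
                if nb not in cluster:
                    d += net.weight(c, nb)
        forces.append(d)
    total = sum(forces)
    return -sum((d / total) * math.log(d / total) for d in forces if d > 0)


# -- Borda and spreading power ---------------------------------------------


def naive_positions(scores: dict[str, float]) -> dict[str, float]:
    """1-based tie-averaged positions under descending score order."""
    out = {}
    for z, s in scores.items():
        above = sum(1 for v in scores.values() if v > s)
        tied = sum(1 for v in scores.values() if v == s)
        out[z] = above + (1 + tied) / 2
    return out


def naive_borda(score_vectors: list[dict[str, float]]) -> dict[str, float]:
    """B(z) = sum_t (|C| - pos_t(z)) from raw score vectors."""
    items = sorted(score_vectors[0])
    n = len(items)
    b = {z: 0.0 for z in items}
    for scores in score_vectors:
        pos = naive_positions(scores)
        for z in items:
            b[z] += n - pos[z]
    return b


def naive_bfs_spreading_power(net: WeightedNetwork, seed: str) -> float:
    """Closed-form SI index in the deterministic limit (all weights equal).

    Coverage is a BFS wave: the index is the mean over steps t >= 1 of
    |ball(seed, t)| / n until the ball covers the graph.
    """
    n = net.n_nodes
    ball = {seed}
    ratios = []
    while len(ball) < n:
        ball = ball | {m for u in ball for m in net.neighbors(u)}
        ratios.append(len(ball) / n)
    return sum(ratios) / len(ratios)


# -- subset selection by exhaustive pool scoring ---------------------------


def naive_select(m, t_b: float, t_s: float):
    """Re-derive the candidate pool and pick the top two by entropy.

    Returns two (anchor, frozenset members, category) triples using the
    tie rule: higher entropy, then fewer members, then smaller anchor row,
    then category in the order H < HL < L.
    """
    n = len(m)
    pool = []
    for i in range(n):
        h = frozenset({i} | {j for j in range(n) if j != i and m[i][j] >= t_b})
        l = frozenset({i} | {j for j in range(n) if j != i and m[i][j] <= t_s})
        for cat, members in (("H", h), ("L", l), ("HL", h | l)):
            total = sum(m[i][j] for j in members)
            ent = 0.0
            for j in members:
                p = m[i][j] / total
                if p > 0:
                    ent -= p * math.log(p)
            pool.append((ent / len(members), i, cat, members))
    pool.sort(key=lambda t: (-t[0], len(t[3]), t[1], t[2]))
    top = pool[:2]
    return [(anchor, members, cat, ent) for ent, anchor, cat, members in top]
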