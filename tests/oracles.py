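"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: character-by-character loops,
explicit transitive closures, per-point silhouette sums, path lengths on
an explicit graph. None of it shares code with the package.
"""

from __future__ import annotations

import numpy as np

ACGT = set("ACGT")


def brute_p_distance(a: str, b: str) -> tuple[float, int]:
    """Site-by-site p-distance with pairwise deletion."""
    mism = comp = 0
    for x, y in zip(a, b):
        if x in ACGT and y in ACGT:
            comp += 1
            if x != y:
                mism += 1
    return 100.0 * mism / comp, comp


def brute_matrix(rows: list[str]) -> np.ndarray:
    n = len(rows)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                D[i, j] = brute_p_distance(rows[i], rows[j])[0]
    return D


def brute_components(D: np.ndarray, threshold: float) -> list[set[int]]:
    """Connected components of d(i,j) < threshold via explicit transitive closure."""
    n = D.shape[0]
    adj = [[D[i, j] < threshold and i != j for j in range(n)] for i in range(n)]
    unassigned = set(range(n))
    comps = []
    while unassigned:
        seed = min(unassigned)
        comp = {seed}
        changed = True
        while changed:
            changed = False
            for i in list(comp):
                for j in range(n):
                    if adj[i][j] and j not in comp:
                        comp.add(j)
                        changed = True
        comps.append(comp)
        unassigned -= comp
    return comps


def brute_within_max(D: np.ndarray, members: list[int]) -> float | None:
    if len(members) < 2:
        return None
    return max(D[i, j] for i in members for j in members if i < j)


def brute_between(D: np.ndarray, a: list[int], b: list[int]) -> tuple[float, float]:
    vals = [D[i, j] for i in a for j in b]
    return min(vals), max(vals)


def brute_silhouette(D: np.ndarray, labels: list[int]) -> float:
    """Per-point silhouette from first principles; singletons score 0."""
    n = len(labels)
    scores = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            scores.append(0.0)
            continue
        a = sum(D[i, j] for j in own) / len(own)
        b = min(
            sum(D[i, j] for j in range(n) if labels[j] == lab)
            / sum(1 for j in range(n) if labels[j] == lab)
            for lab in set(labels)
            if lab != labels[i]
        )
        scores.append((b - a) / max(a, b) if max(a, b) > 0 else 0.0)
    return float(np.mean(scores))


def brute_co_membership_diff(p1: dict, p2: dict) -> set[frozenset]:
    """All pairs whose co-membership differs between two partitions."""
    l1 = {m: k for k, ms in p1.items() for m in ms}
    l2 = {m: k for k, ms in p2.items() for m in ms}
    ids = sorted(l1)
    diff = set()
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if (l1[a] == l1[b]) != (l2[a] == l2[b]):
                diff.add(frozenset((a, b)))
    return diff


def random_additive_matrix(
    n: int, rng: np.random.Generator
) -> tuple[np.ndarray, set[frozenset]]:
    """Distance matrix of a random edge-weighted binary tree plus its splits.

    Returns the exact leaf-to-leaf path-length matrix and the set of
    non-trivial bipartitions (as frozensets of one side's leaf indices),
    which together characterize the unrooted topology.
    """
    import networkx as nx

    G = nx.Graph()
    G.add_edge("L0", "L1", w=float(rng.uniform(0.5, 5.0)))
    internal = 0
    for leaf in range(2, n):
        edges = sorted(G.edges)
        u, v = edges[int(rng.integers(0, len(edges)))]
        w = G.edges[u, v]["w"]
        G.remove_edge(u, v)
        internal += 1
        mid = f"I{internal}"
        s = float(rng.uniform(0.2, 0.8))
        G.add_edge(u, mid, w=w * s)
        G.add_edge(mid, v, w=w * (1 - s))
        G.add_edge(mid, f"L{leaf}", w=float(rng.uniform(0.5, 5.0)))
    lengths = dict(nx.all_pairs_dijkstra_path_length(G, weight="w"))
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            D[i, j] = lengths[f"L{i}"][f"L{j}"]
    splits = set()
    leaves = {f"L{i}" for i in range(n)}
    for u, v in G.edges:
        H = G.copy()
        H.remove_edge(u, v)
        import networkx as nx2

        side = {x for x in nx2.node_connected_component(H, u) if x in leaves}
        if 2 <= len(side) <= n - 2:
            splits.add(frozenset(int(x[1:]) for x in side))
    return D, splits


def tree_splits(tree, n: int) -> set[frozenset]:
    """Non-trivial splits of an skbio tree with leaves named L0..L{n-1}."""
    splits = set()
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(int(name[1:]) for name in node.subset())
        if 2 <= len(side) <= n - 2:
            splits.add(side)
    return normalize_splits(splits, n)


def normalize_splits(splits: set[frozenset], n: int) -> set[frozenset]:
    all_leaves = frozenset(range(n))
    out = set()
    for side in splits:
        comp = all_leaves - side
        out.add(
            side
            if len(side) < len(comp) or (len(side) == len(comp) and 0 not in side)
            else comp
        )
    return out
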