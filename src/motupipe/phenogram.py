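"""Neighbour-joining phenogram construction and group-collapsed rendering.

The tree built here is a phenogram — a visual summary of p-distance
similarity — not a phylogeny: no rooting, no support values, and no claim
of monophyly for the haplogroups drawn on it. The condensed rendering
replaces each haplogroup with a single pseudo-leaf annotated with its
locality, specimen count and within-group variation, the conventional way
a large barcode NJ network is displayed.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from motupipe.distances import DistanceMatrix
from motupipe.delimit import MOTUPartition


def neighbor_joining(D: DistanceMatrix) -> TreeNode:
    """Canonical Saitou–Nei neighbour joining on a p-distance matrix.

    Branch lengths are in percent divergence. At every step the pair
    minimizing the Q-criterion is joined, ties broken to the lowest index
    pair. A negative branch length is clamped to zero with the deficit
    transferred to its sister branch, preserving the path length between
    the joined nodes. The returned tree is arbitrarily rooted on the last
    edge (two children of the root) and should be read as unrooted.
    """
    n = len(D)
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 specimens")
    d = D.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=sid) for sid in D.ids]
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        flat = Q[iu]
        best = int(np.argmin(flat))  # argmin takes the first == lowest index pair
        ai, aj = int(iu[0][best]), int(iu[1][best])
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        # clamp-and-transfer: keep li + lj = dij
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)

        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.append(nodes[i])
        parent.append(nodes[j])

        new_row = np.zeros(d.shape[0] + 1)
        for ak in active:
            if ak in (i, j):
                continue
            new_row[ak] = 0.5 * (d[i, ak] + d[j, ak] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : d.shape[1] - 1] = new_row[: d.shape[1] - 1]
        d[: d.shape[0] - 1, -1] = new_row[: d.shape[0] - 1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    i, j = active
    root = TreeNode()
    half = max(d[i, j] / 2.0, 0.0)
    nodes[i].length = half
    nodes[j].length = d[i, j] - half
    root.append(nodes[i])
    root.append(nodes[j])
    return root


def to_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


@dataclass
class CondensedClade:
    """One haplogroup as drawn on the condensed phenogram."""

    label: str
    n: int
    variation: float | None  # max within-group p-distance, None for singletons
    localities: list[str]
    members: list[str]
    monophyletic: bool

    @property
    def display_label(self) -> str:
        from motupipe.distances import round_report

        var = "n/a" if self.variation is None else f"{round_report(self.variation):.1f}%"
        loc = "/".join(self.localities) if self.localities else "unknown"
        return f"{self.label} {loc} ({self.n}, {var})"

    @property
    def bar_width(self) -> float:
        """Width of the variation bar, proportional to within-group variation."""
        return self.variation or 0.0


@dataclass
class CondensedTree:
    clades: list[CondensedClade]
    tree: TreeNode
    non_monophyletic: list[str]

    def to_newick(self) -> str:
        return to_newick(self.tree)


def _sanitize(label: str) -> str:
    return re.sub(r"[\s(),:;]+", "_", label).strip("_")


def _find_clade(tree: TreeNode, names: frozenset[str]):
    for node in tree.traverse(include_self=True):
        if not node.is_tip() and frozenset(node.subset()) == names:
            return node
        if node.is_tip() and names == frozenset([node.name]):
            return node
    return None


def condense(
    tree: TreeNode,
    partition: MOTUPartition,
    D: DistanceMatrix | None = None,
    records=None,
) -> CondensedTree:
    """Collapse each haplogroup of the partition to one labelled pseudo-leaf.

    Monophyly is assessed in the unrooted sense (a group is collapsible
    iff some edge separates exactly its members). Groups that are not
    monophyletic in the phenogram are reported in ``non_monophyletic``
    and left uncollapsed rather than silently merged.
    """
    tips = frozenset(t.name for t in tree.tips())
    if partition.specimen_ids != set(tips):
        raise ValueError("partition members do not match the tree's leaves")
    from motupipe.census import group_variation

    morpho_loc = (
        {r.specimen_id: r.locality for r in records} if records else {}
    )
    work = tree.copy()
    clades: list[CondensedClade] = []
    non_mono: list[str] = []
    for label, members in partition.groups.items():
        G = frozenset(members)
        variation = group_variation(members, D) if D is not None else None
        localities: list[str] = []
        for m in members:
            loc = morpho_loc.get(m, "")
            if loc and loc not in localities:
                localities.append(loc)
        current_tips = frozenset(t.name for t in work.tips())
        node = _find_clade(work, G)
        mono = node is not None
        if node is None and G != current_tips:
            comp_node = _find_clade(work, current_tips - G)
            if comp_node is not None and not comp_node.is_tip():
                work = work.root_at(comp_node)
                node = _find_clade(work, G)
                mono = node is not None
        clade = CondensedClade(
            label=label,
            n=len(members),
            variation=variation,
            localities=localities,
            members=list(members),
            monophyletic=mono,
        )
        clades.append(clade)
        if not mono:
            non_mono.append(label)
            continue
        pseudo = TreeNode(name=_sanitize(clade.display_label))
        pseudo.length = node.length
        if node.parent is None:
            work = pseudo  # whole tree is one group
        else:
            parent = node.parent
            parent.remove(node)
            parent.append(pseudo)
            pseudo.length = node.length
    return CondensedTree(clades=clades, tree=work, non_monophyletic=non_mono)


def render_text(condensed: CondensedTree, width: int = 72) -> str:
    """Flat-text rendering of the condensed phenogram with variation bars."""
    lines = [condensed.tree.ascii_art()]
    lines.append("")
    max_var = max((c.bar_width for c in condensed.clades), default=0.0) or 1.0
    for c in condensed.clades:
        bar = "#" * int(round(20 * c.bar_width / max_var))
        mono = "" if c.monophyletic else "  [not monophyletic in tree]"
        lines.append(f"{c.display_label:<50s} |{bar}{mono}")
    return "\n".join(lines)
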