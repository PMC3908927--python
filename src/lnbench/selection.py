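"""Training-set selection by DIANA divisive clustering of R_i values.

DIANA (DIvisive ANAlysis) starts with one cluster holding every complex and
repeatedly splits the most heterogeneous cluster (largest diameter) by
seeding a splinter group with the most dissimilar object and migrating
objects that sit closer to the splinter, until every complex is a singleton.
Dissimilarity here is the 1-D absolute difference of R_i values.  From the
resulting dendrogram, a parameterization set of size k is read off by
cutting into k clusters and emitting each cluster's medoid.

Ties (in splinter seeding, in diameters, in medoids) are broken by
lexicographic complex id, so selection is deterministic.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping

__all__ = ["DianaNode", "diana", "select_sets", "cut_tree", "medoid", "to_newick"]


@dataclass
class DianaNode:
    """A dendrogram node: its leaf ids, its diameter, and two children."""

    ids: tuple[str, ...]
    diameter: float
    children: tuple["DianaNode", "DianaNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> tuple[str, ...]:
        return self.ids


def _dissim(values: Mapping[str, float], a: str, b: str) -> float:
    return abs(values[a] - values[b])


def _diameter(values: Mapping[str, float], ids: tuple[str, ...]) -> float:
    if len(ids) < 2:
        return 0.0
    vals = [values[i] for i in ids]
    return max(vals) - min(vals)  # 1-D: diameter is the range


def _avg_dissim(values: Mapping[str, float], x: str, group: list[str]) -> float:
    others = [g for g in group if g != x]
    if not others:
        return 0.0
    return sum(_dissim(values, x, g) for g in others) / len(others)


def _split(values: Mapping[str, float], ids: tuple[str, ...]) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """One DIANA split: splinter seeding followed by migration."""
    remainder = sorted(ids)
    # seed: object with maximal average dissimilarity to the rest
    # (ties -> lexicographically smallest id)
    seed = min(remainder, key=lambda x: (-_avg_dissim(values, x, remainder), x))
    splinter = [seed]
    remainder.remove(seed)
    while len(remainder) > 1:
        best, best_gain = None, 0.0
        for x in remainder:
            gain = _avg_dissim(values, x, remainder) - _avg_dissim(values, x, splinter + [x])
            if gain > best_gain:
                best, best_gain = x, gain
        if best is None:
            break
        splinter.append(best)
        remainder.remove(best)
    return tuple(sorted(splinter)), tuple(sorted(remainder))


def diana(values: Mapping[str, float]) -> DianaNode:
    """Build the full divisive dendrogram over the given R_i values."""
    if not values:
        raise ValueError("diana: empty input")
    ids = tuple(sorted(values))

    def build(node_ids: tuple[str, ...]) -> DianaNode:
        if len(node_ids) == 1:
            return DianaNode(node_ids, 0.0)
        left, right = _split(values, node_ids)
        return DianaNode(node_ids, _diameter(values, node_ids), (build(left), build(right)))

    return build(ids)


def cut_tree(root: DianaNode, k: int) -> list[DianaNode]:
    """Cut the dendrogram into k clusters.

    Splits proceed in order of decreasing node diameter (ties by
    lexicographically smallest leaf-id tuple), mirroring the divisive order.
    """
    n = len(root.ids)
    if not (1 <= k <= n):
        raise ValueError(f"cannot cut {n}-leaf tree into {k} clusters")
    clusters = [root]
    while len(clusters) < k:
        splittable = [c for c in clusters if not c.is_leaf]
        nxt = min(splittable, key=lambda c: (-c.diameter, c.ids))
        clusters.remove(nxt)
        clusters.extend(nxt.children)
    return sorted(clusters, key=lambda c: (-c.diameter, c.ids))


def medoid(values: Mapping[str, float], ids: tuple[str, ...]) -> str:
    """Leaf with minimum summed dissimilarity to its cluster (ties: lexicographic)."""
    return min(sorted(ids), key=lambda x: sum(_dissim(values, x, y) for y in ids))


def select_sets(root: DianaNode,
                sizes: tuple[int, int],
                values: Mapping[str, float]) -> tuple[list[str], list[str]]:
    """Extract the small and large parameterization sets.

    Each set of size k is generated independently: cut into k clusters and
    emit each cluster's medoid (clusters ordered by decreasing diameter).
    """
    k_small, k_large = sizes
    if not k_small < k_large:
        raise ValueError("k_small must be < k_large")
    out = []
    for k in (k_small, k_large):
        out.append([medoid(values, c.ids) for c in cut_tree(root, k)])
    return out[0], out[1]


def to_newick(node: DianaNode) -> str:
    """Newick-like nested-text export of the dendrogram (diameters as lengths)."""
    def rec(n: DianaNode) -> str:
        if n.is_leaf:
            return n.ids[0]
        l, r = n.children
        return f"({rec(l)},{rec(r)}):{n.diameter:.6g}"

    return rec(node) + ";"


def to_json(node: DianaNode) -> str:
    def rec(n: DianaNode):
        d = {"ids": list(n.ids), "diameter": n.diameter}
        if n.children:
            d["children"] = [rec(c) for c in n.children]
        return d

    return json.dumps(rec(node), indent=1)
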