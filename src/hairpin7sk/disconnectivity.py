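"""Disconnectivity graphs (superbasin trees) and funnel assignment.

At each energy threshold, minima below the threshold are grouped into
superbasins connected by transition states below the threshold; the
tree records at which level the groups merge.  Funnels are defined by
minimax-path attraction: each minimum belongs to the designated bottom
it can reach over the lowest highest-energy barrier.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .ktn import NetworkError, TransitionNetwork

#: figure palette for family-coloured leaves
FAMILY_COLORS = {
    "M1": "#1f4da0",      # blue
    "M2": "#2ca02c",      # green
    "M2STAR": "#145214",  # dark green
    "E": "#d62728",       # red
    None: "#555555",
}


@dataclass
class DGraphNode:
    level_energy: float
    members: frozenset[int]
    children: list["DGraphNode"] = field(default_factory=list)
    leaf_minimum: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.leaf_minimum is not None

    def leaves(self) -> list["DGraphNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def to_dict(self) -> dict:
        return {
            "level_energy": self.level_energy,
            "members": sorted(self.members),
            "leaf_minimum": self.leaf_minimum,
            "children": [c.to_dict() for c in self.children],
        }


class _DSU:
    def __init__(self, items: Sequence[int]) -> None:
        self.parent = {i: i for i in items}

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if rb < ra:
            ra, rb = rb, ra
        self.parent[rb] = ra
        return True


def build_dgraph(net: TransitionNetwork, level_spacing: float = 1.0,
                 e_top: float | None = None) -> DGraphNode | list[DGraphNode]:
    """Build the superbasin tree; a forest is returned if disconnected.

    Levels descend from ``e_top`` (default: highest TS energy plus one
    spacing) in steps of ``level_spacing``; leaves sit at the energies
    of their minima.
    """
    if level_spacing <= 0:
        raise ValueError("level_spacing must be positive")
    if not net.minima:
        raise NetworkError("empty network")
    ids = net.ids
    energies = {i: net.minima[i].energy for i in ids}
    edges = sorted(net.edges(), key=lambda e: e[2])
    max_ts = max((e for _, _, e in edges), default=max(energies.values()))
    if e_top is None:
        e_top = max(max_ts, max(energies.values())) + level_spacing
    e_min = min(energies.values())
    n_levels = max(1, int(math.ceil((e_top - e_min) / level_spacing)))
    levels = [e_top - level_spacing * k for k in range(n_levels)]
    levels = sorted([lv for lv in levels if lv > e_min]) or [e_top]

    # recompute superbasins at each ascending threshold and create an
    # internal node whenever previously separate basins coalesce
    top_node: dict[frozenset[int], DGraphNode] = {}
    for level in levels:
        active = [i for i in ids if energies[i] < level]
        dsu = _DSU(active)
        active_set = set(active)
        for m1, m2, e in edges:
            if e >= level:
                break
            if m1 in active_set and m2 in active_set:
                dsu.union(m1, m2)
        comps: dict[int, set[int]] = {}
        for i in active:
            comps.setdefault(dsu.find(i), set()).add(i)
        new_top: dict[frozenset[int], DGraphNode] = {}
        for members in map(frozenset, comps.values()):
            if members in top_node:
                new_top[members] = top_node[members]
                continue
            children = [nd for key, nd in top_node.items() if key <= members]
            covered = frozenset().union(*(c.members for c in children)) \
                if children else frozenset()
            for i in sorted(members - covered):  # newly active minima
                children.append(DGraphNode(energies[i], frozenset([i]),
                                           leaf_minimum=i))
            children.sort(key=lambda nd: min(nd.members))
            if len(children) == 1:
                new_top[members] = children[0]  # lone new leaf, no branch yet
            else:
                new_top[members] = DGraphNode(level, members,
                                              children=children)
        top_node = new_top

    roots = sorted(top_node.values(), key=lambda nd: min(nd.members))
    return roots[0] if len(roots) == 1 else roots


def superbasin_counts(net: TransitionNetwork, level_spacing: float = 1.0,
                      e_top: float | None = None) -> list[tuple[float, int]]:
    """(threshold, number of superbasins) over ascending levels."""
    ids = net.ids
    energies = {i: net.minima[i].energy for i in ids}
    edges = sorted(net.edges(), key=lambda e: e[2])
    max_ts = max((e for _, _, e in edges), default=max(energies.values()))
    if e_top is None:
        e_top = max(max_ts, max(energies.values())) + level_spacing
    out = []
    level = e_top
    while level > min(energies.values()):
        dsu = _DSU(ids)
        active = {i for i in ids if energies[i] < level}
        for m1, m2, e in edges:
            if e < level and m1 in active and m2 in active:
                dsu.union(m1, m2)
        out.append((level, len({dsu.find(i) for i in active})))
        level -= level_spacing
    return out[::-1]


def minimax_barrier(net: TransitionNetwork, a: int, b: int) -> float:
    """Lowest highest-TS-energy over all paths between two minima."""
    if a == b:
        return net.minima[a].energy
    best: dict[int, float] = {a: -math.inf}
    heap = [(-math.inf, a)]
    while heap:
        barrier, cur = heapq.heappop(heap)
        if cur == b:
            return barrier
        if barrier > best.get(cur, math.inf):
            continue
        for m1, m2, e in net.edges():
            if cur in (m1, m2):
                nxt = m2 if cur == m1 else m1
                nb = max(barrier, e)
                if nb < best.get(nxt, math.inf):
                    best[nxt] = nb
                    heapq.heappush(heap, (nb, nxt))
    return math.inf


def funnel_assignment(net: TransitionNetwork, bottoms: Sequence[int]
                      ) -> dict[int, int | str]:
    """Assign each minimum to the bottom reachable over the lowest
    minimax barrier; ties go to the lower-energy bottom (then lower id).
    Unreachable minima map to the sentinel string 'unassigned'.
    """
    bottoms = list(dict.fromkeys(bottoms))
    if not bottoms:
        raise NetworkError("bottoms must be non-empty")
    for b in bottoms:
        if b not in net.minima:
            raise NetworkError(f"unknown bottom {b}")
    order = sorted(bottoms, key=lambda b: (net.minima[b].energy, b))
    out: dict[int, int | str] = {}
    for i in net.ids:
        best_bottom: int | str = "unassigned"
        best_barrier = math.inf
        for b in order:
            barrier = minimax_barrier(net, i, b)
            if barrier < best_barrier - 1e-12:
                best_barrier = barrier
                best_bottom = b
        out[i] = best_bottom
    return out


# ---------------------------------------------------------------------------
# SVG rendering
# ---------------------------------------------------------------------------

def _order_leaves(node: DGraphNode) -> list[DGraphNode]:
    if node.is_leaf:
        return [node]
    children = sorted(node.children,
                      key=lambda c: (-len(c.members), min(c.members)))
    out = []
    for c in children:
        out.extend(_order_leaves(c))
    return out


def render_dgraph(root: DGraphNode | list[DGraphNode],
                  coloring: Mapping[int, str] | None = None,
                  sink=None, width: float = 640.0, height: float = 480.0
                  ) -> str:
    """Render the tree as an SVG string (vertical energy axis, kcal/mol).

    Leaf strokes are coloured by family; the layout orders subtrees by
    member count so renders are deterministic.
    """
    roots = root if isinstance(root, list) else [root]
    leaves: list[DGraphNode] = []
    for r in roots:
        leaves.extend(_order_leaves(r))
    coloring = coloring or {}
    xpos = {id(leaf): i for i, leaf in enumerate(leaves)}
    n = len(leaves)

    all_nodes: list[DGraphNode] = []

    def collect(nd: DGraphNode) -> None:
        all_nodes.append(nd)
        for c in nd.children:
            collect(c)

    for r in roots:
        collect(r)
    e_lo = min(nd.level_energy for nd in all_nodes)
    e_hi = max(nd.level_energy for nd in all_nodes)
    span = max(e_hi - e_lo, 1e-9)
    margin = 50.0

    def x_of(nd: DGraphNode) -> float:
        lv = [xpos[id(l)] for l in nd.leaves()]
        mean = sum(lv) / len(lv)
        return margin + (width - 2 * margin) * ((mean + 0.5) / max(n, 1))

    def y_of(e: float) -> float:
        return margin + (height - 2 * margin) * (e_hi - e) / span

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width:.0f}" '
        f'height="{height:.0f}" viewBox="0 0 {width:.0f} {height:.0f}">',
        f'<line x1="{margin}" y1="{y_of(e_hi)}" x2="{margin}" '
        f'y2="{y_of(e_lo)}" stroke="black" stroke-width="1"/>',
    ]
    n_ticks = 6
    for k in range(n_ticks):
        e = e_lo + span * k / (n_ticks - 1)
        y = y_of(e)
        parts.append(f'<line x1="{margin - 5}" y1="{y:.1f}" x2="{margin}" '
                     f'y2="{y:.1f}" stroke="black" stroke-width="1"/>')
        parts.append(f'<text x="{margin - 8}" y="{y + 4:.1f}" font-size="10" '
                     f'text-anchor="end">{e:.1f}</text>')
    parts.append(f'<text x="12" y="{margin - 14}" font-size="11">'
                 'energy / kcal mol^-1</text>')

    def draw(nd: DGraphNode, parent_x: float | None, parent_y: float | None) -> None:
        x, y = x_of(nd), y_of(nd.level_energy)
        if parent_x is not None:
            if nd.is_leaf:
                color = FAMILY_COLORS.get(coloring.get(nd.leaf_minimum),
                                          FAMILY_COLORS[None])
            else:
                color = "#333333"
            parts.append(
                f'<line x1="{parent_x:.1f}" y1="{parent_y:.1f}" x2="{x:.1f}" '
                f'y2="{y:.1f}" stroke="{color}" stroke-width="1.5"/>')
        elif nd.is_leaf:  # single-minimum network: one vertical stroke
            color = FAMILY_COLORS.get(coloring.get(nd.leaf_minimum),
                                      FAMILY_COLORS[None])
            parts.append(
                f'<line x1="{x:.1f}" y1="{y_of(e_hi):.1f}" x2="{x:.1f}" '
                f'y2="{y:.1f}" stroke="{color}" stroke-width="1.5"/>')
        for c in nd.children:
            draw(c, x, y)

    for r in roots:
        draw(r, None, None)
    parts.append("</svg>")
    svg = "\n".join(parts)
    if sink is not None:
        if hasattr(sink, "write"):
            sink.write(svg)
        else:
            with open(sink, "w") as fh:
                fh.write(svg)
    return svg
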