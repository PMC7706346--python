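"""Skeleton topology: branch points, end points and root segments.

The skeleton is read as a pixel graph.  Adjacency is 8-connected with a
redundancy reduction: a diagonal neighbor is ignored when an orthogonal
neighbor adjacent to both pixels exists, so a staircase of pixels is a
single path rather than a mesh of triangles.  End points (degree 1)
mark root tips; branch points (degree >= 3) terminate segments; the
segments partition the skeleton's edges and reconstruct it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .skeleton import NEIGHBOR_ORDER, Skeleton

_ORTHO = ((-1, 0), (0, 1), (1, 0), (0, -1))
_DIAG = ((-1, 1), (1, 1), (1, -1), (-1, -1))


@dataclass
class RootSegment:
    """Ordered 8-connected run of skeleton pixels between two terminal
    pixels (branch or end points), with no interior branch point.
    ``closed`` marks a cycle with no branch point, anchored at a
    deterministic pixel."""

    pixels: list[tuple[int, int]]
    closed: bool = False

    def __len__(self) -> int:
        return len(self.pixels)

    def length(self) -> float:
        """Euclidean chain length: 1 per orthogonal step, sqrt(2) per
        diagonal step (plus the closing step of a cycle)."""
        pts = np.asarray(self.pixels, dtype=float)
        if len(pts) < 2:
            return 0.0
        if self.closed:
            pts = np.vstack([pts, pts[:1]])
        steps = np.abs(np.diff(pts, axis=0))
        return float(np.hypot(steps[:, 0], steps[:, 1]).sum())


@dataclass
class TopologyGraph:
    branch_points: set[tuple[int, int]] = field(default_factory=set)
    end_points: set[tuple[int, int]] = field(default_factory=set)
    segments: list[RootSegment] = field(default_factory=list)
    isolated: set[tuple[int, int]] = field(default_factory=set)


def _reduced_neighbors(sk: np.ndarray, r: int, c: int) -> list[tuple[int, int]]:
    """8-neighbors of (r, c) in the skeleton with redundant diagonals
    removed, in fixed N, NE, E, SE, S, SW, W, NW order."""
    h, w = sk.shape

    def on(rr: int, cc: int) -> bool:
        return 0 <= rr < h and 0 <= cc < w and bool(sk[rr, cc])

    out: list[tuple[int, int]] = []
    for dr, dc in NEIGHBOR_ORDER:
        rr, cc = r + dr, c + dc
        if not on(rr, cc):
            continue
        if dr != 0 and dc != 0:
            # diagonal: skip if an orthogonal neighbor touches both
            if on(r + dr, c) or on(r, c + dc):
                continue
        out.append((rr, cc))
    return out


def build_topology(skel: Skeleton | np.ndarray) -> TopologyGraph:
    """Decompose a thin skeleton into branch points, end points and the
    root segments connecting them.

    Each branch point of reduced degree d terminates exactly d segments;
    end points terminate exactly one; pure cycles become a single closed
    segment anchored at their scan-order-first pixel.  Traversal order
    is deterministic, so outputs are byte-for-byte reproducible.
    """
    sk = skel.mask if isinstance(skel, Skeleton) else np.asarray(skel, bool)
    g = TopologyGraph()
    pixels = [tuple(p) for p in np.argwhere(sk)]
    if not pixels:
        return g

    nbrs = {p: _reduced_neighbors(sk, *p) for p in pixels}
    degree = {p: len(n) for p, n in nbrs.items()}
    for p, d in degree.items():
        if d == 0:
            g.isolated.add(p)
        elif d == 1:
            g.end_points.add(p)
        elif d >= 3:
            g.branch_points.add(p)

    used: set[frozenset[tuple[int, int]]] = set()

    def walk(start: tuple[int, int], first: tuple[int, int]) -> RootSegment:
        path = [start, first]
        used.add(frozenset((start, first)))
        prev, cur = start, first
        while degree[cur] == 2 and cur != start:
            a, b = nbrs[cur]
            nxt = b if a == prev else a
            edge = frozenset((cur, nxt))
            if edge in used:
                break
            used.add(edge)
            path.append(nxt)
            prev, cur = cur, nxt
        return RootSegment(pixels=path)

    # Segments out of every terminal (end or branch) pixel, scan order.
    terminals = sorted(g.end_points | g.branch_points)
    for t in terminals:
        for nb in nbrs[t]:
            if frozenset((t, nb)) not in used:
                g.segments.append(walk(t, nb))

    # Remaining untouched edges belong to pure cycles.
    in_segment = {p for s in g.segments for p in s.pixels}
    for p in pixels:
        if p in in_segment or degree[p] != 2:
            continue
        # trace the cycle from its scan-order-first pixel
        cyc = [p]
        prev, cur = p, nbrs[p][0]
        used.add(frozenset((p, cur)))
        while cur != p:
            cyc.append(cur)
            a, b = nbrs[cur]
            nxt = b if a == prev else a
            used.add(frozenset((cur, nxt)))
            prev, cur = cur, nxt
        g.segments.append(RootSegment(pixels=cyc, closed=True))
        in_segment.update(cyc)

    return g


def validate_reconstruction(g: TopologyGraph, skel: Skeleton | np.ndarray
                            ) -> bool:
    """True iff the union of segment pixels (plus isolated pixels)
    equals the skeleton pixel set."""
    sk = skel.mask if isinstance(skel, Skeleton) else np.asarray(skel, bool)
    expected = {tuple(p) for p in np.argwhere(sk)}
    got = set(g.isolated)
    for s in g.segments:
        got.update(s.pixels)
    return got == expected


def count_tips(g: TopologyGraph) -> int:
    """Number of root tips = number of skeleton end points."""
    return len(g.end_points)


def total_root_length(g: TopologyGraph) -> float:
    """Total Euclidean length of the medial axis: sum of segment chain
    lengths, each skeleton edge counted exactly once."""
    return float(sum(s.length() for s in g.segments))
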