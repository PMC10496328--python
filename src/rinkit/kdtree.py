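"""Balanced 3D kD-tree with radius and nearest-neighbour queries.

This is the performance core of contact detection: every detector maps its
distance gate onto closed-ball radius queries against an index built over the
relevant atom subset. The tree is static, built by lower-median splits along
axes cycling x->y->z, with median ties broken by the lower point id so that
identical input always yields an identical tree.

Construction costs O(n log^2 n) (a sort per level); radius/nearest queries
run in O(log n) expected time for bounded-density point sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from rinkit.errors import EmptyIndexError, RinkitError


@dataclass
class EvalCounter:
    """Counts point-distance evaluations performed by queries (for complexity probes)."""

    n: int = 0


@dataclass
class _Node:
    point: int  # row into the coords array
    axis: int
    left: "_Node | None" = None
    right: "_Node | None" = None


@dataclass
class KdTree:
    """Static balanced kD-tree (k = 3) over (id, coordinate) pairs."""

    ids: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=object))
    coords: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    root: _Node | None = None

    @property
    def size(self) -> int:
        return len(self.ids)

    @property
    def depth(self) -> int:
        def rec(node: _Node | None) -> int:
            if node is None:
                return 0
            return 1 + max(rec(node.left), rec(node.right))

        return rec(self.root)

    # -- construction -------------------------------------------------------

    @classmethod
    def build(cls, points) -> "KdTree":
        """Build an index from an iterable of (id, 3-vector) pairs.

        Ids must be unique and coordinates finite; duplicate coordinates are
        permitted. An empty iterable yields a valid empty index.
        """
        points = list(points)
        if not points:
            return cls()
        ids = np.array([p[0] for p in points], dtype=object)
        if len(set(ids.tolist())) != len(ids):
            raise RinkitError("KdTree.build: ids must be unique")
        coords = np.array([np.asarray(p[1], dtype=float) for p in points])
        if coords.shape[1] != 3 or not np.all(np.isfinite(coords)):
            raise RinkitError("KdTree.build: coordinates must be finite 3-vectors")
        tree = cls(ids=ids, coords=coords)
        order_keys = np.arange(len(ids))  # positional rank doubles as the id tie-break

        def rec(rows: np.ndarray, depth: int) -> _Node | None:
            if rows.size == 0:
                return None
            axis = depth % 3
            # stable sort by (coordinate along axis, id rank): deterministic shape
            rows = rows[np.lexsort((order_keys[rows], coords[rows, axis]))]
            mid = (rows.size - 1) // 2  # lower median
            node = _Node(point=int(rows[mid]), axis=axis)
            node.left = rec(rows[:mid], depth + 1)
            node.right = rec(rows[mid + 1:], depth + 1)
            return node

        tree.root = rec(np.arange(len(ids)), 0)
        return tree

    # -- queries ------------------------------------------------------------

    def query_radius(self, center, r: float, counter: EvalCounter | None = None) -> list:
        """Ids of all points with Euclidean distance <= r from ``center`` (closed ball)."""
        if r < 0:
            raise RinkitError("query_radius: r must be >= 0")
        center = np.asarray(center, dtype=float)
        out: list = []
        if self.root is None:
            return out
        coords = self.coords
        r2 = r * r
        stack = [self.root]
        while stack:
            node = stack.pop()
            delta = coords[node.point] - center
            if counter is not None:
                counter.n += 1
            if float(delta @ delta) <= r2:
                out.append(self.ids[node.point])
            diff = center[node.axis] - coords[node.point, node.axis]
            near, far = (node.left, node.right) if diff <= 0 else (node.right, node.left)
            if near is not None:
                stack.append(near)
            if far is not None and abs(diff) <= r:
                stack.append(far)
        return out

    def query_nearest(self, center, counter: EvalCounter | None = None):
        """Globally nearest (id, distance); ties broken by the smallest id."""
        if self.root is None:
            raise EmptyIndexError("query_nearest on an empty index")
        center = np.asarray(center, dtype=float)
        coords = self.coords
        ids = self.ids
        best: list = [np.inf, None]  # [distance, id]

        def rec(node: _Node | None) -> None:
            if node is None:
                return
            delta = coords[node.point] - center
            if counter is not None:
                counter.n += 1
            d = float(np.sqrt(delta @ delta))
            cand_id = ids[node.point]
            if d < best[0] or (d == best[0] and (best[1] is None or cand_id < best[1])):
                best[0], best[1] = d, cand_id
            diff = center[node.axis] - coords[node.point, node.axis]
            near, far = (node.left, node.right) if diff <= 0 else (node.right, node.left)
            rec(near)
            # the far side can hold an equal-distance point with a smaller id
            if abs(diff) <= best[0]:
                rec(far)

        rec(self.root)
        return best[1], best[0]


def build_index(points) -> KdTree:
    """Functional alias for :meth:`KdTree.build`."""
    return KdTree.build(points)
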