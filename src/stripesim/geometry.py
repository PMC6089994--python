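"""Periodic-in-x planar metric and neighbourhood counts.

The skin patch is periodic lengthwise (x) and bounded dorsoventrally (y):
distances use the minimum image in x and the plain difference in y, with no
mirroring at the top/bottom edges, so neighbourhoods are simply truncated
there.  Disk and annulus membership is closed (``<=`` on both boundaries),
and rule counts include the focal cell itself when it belongs to the queried
class.

Counts are accelerated with per-class KD-trees; the x-periodic metric is
obtained by giving the tree a toroidal box whose y period is padded far
beyond any query radius, so y wrap-around can never contribute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core_state import (
    N_CLASSES, CellPopulation, DomainState, class_index,
)

#: Tolerance subtracted from an annulus inner radius so that a cell at
#: exactly the inner boundary is counted (closed annulus) while the counts
#: remain a disk-count difference.
_INNER_EPS = 1e-9


@dataclass(frozen=True)
class NeighborhoodSpec:
    """A disk (``radius``) or annulus (``inner``/``outer``) neighbourhood, um."""

    kind: str = "disk"
    radius: float | None = None
    inner: float | None = None
    outer: float | None = None

    def __post_init__(self):
        if self.kind == "disk":
            if self.radius is None or self.radius <= 0:
                raise ValueError("disk radius must be positive")
        elif self.kind == "annulus":
            if self.inner is None or self.outer is None or not 0 < self.inner < self.outer:
                raise ValueError("annulus needs 0 < inner < outer")
        else:
            raise ValueError(f"unknown neighbourhood kind {self.kind!r}")


def wrap_x(x, length: float):
    """Map x-coordinates into [0, L)."""
    return np.mod(x, length)


def displacement(a, b, domain: DomainState) -> np.ndarray:
    """Minimum-image vector from ``a`` to ``b``: x wraps, y does not.

    The x component always has magnitude <= L/2, and
    ``displacement(a, b) == -displacement(b, a)``.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    d = b - a
    L = domain.length
    d[..., 0] -= L * np.round(d[..., 0] / L)
    return d


def periodic_distance(a, b, domain: DomainState) -> np.ndarray:
    """Scalar periodic distance(s) between points ``a`` and ``b``."""
    return np.linalg.norm(displacement(a, b, domain), axis=-1)


def _tree_points(points: np.ndarray, domain: DomainState, pad: float) -> tuple:
    """Wrap points into the toroidal box used for KD-tree queries."""
    box = (domain.length, domain.height + 2.0 * pad + 1.0)
    pts = points.copy()
    pts[:, 0] = np.mod(pts[:, 0], domain.length)
    # y already lies in [0, H] subset of [0, box_y); clamp defensively
    np.clip(pts[:, 1], 0.0, domain.height, out=pts[:, 1])
    return pts, box


class NeighborCounter:
    """Per-class KD-trees over one population snapshot.

    Build once per day after migration, then answer all disk/annulus counts
    for that day's rules.  ``max_radius`` bounds every query radius and sets
    the y padding that suppresses spurious y wrap-around.
    """

    def __init__(self, population: CellPopulation, domain: DomainState,
                 max_radius: float = 250.0) -> None:
        self.domain = domain
        self.max_radius = float(max_radius)
        self._trees = []
        for c in range(N_CLASSES):
            pts = population.positions(c)
            if pts.shape[0] == 0:
                self._trees.append(None)
                continue
            wrapped, box = _tree_points(pts, domain, self.max_radius)
            self._trees.append(cKDTree(wrapped, boxsize=box))

    def _prep_centers(self, centers) -> np.ndarray:
        centers = np.atleast_2d(np.asarray(centers, dtype=np.float64))
        wrapped, _ = _tree_points(centers, self.domain, self.max_radius)
        return wrapped

    def count_disk(self, cls, centers, radius: float) -> np.ndarray:
        """Number of class-``cls`` cells within ``radius`` (closed) of each center."""
        if radius <= 0:
            raise ValueError("radius must be positive")
        if radius > self.max_radius:
            raise ValueError("query radius exceeds counter's max_radius")
        c = class_index(cls)
        centers = self._prep_centers(centers)
        if self._trees[c] is None:
            return np.zeros(centers.shape[0], dtype=np.int64)
        out = self._trees[c].query_ball_point(centers, r=radius, return_length=True)
        return np.asarray(out, dtype=np.int64)

    def count_annulus(self, cls, centers, inner: float, outer: float) -> np.ndarray:
        """Cells with inner <= distance <= outer of each center (closed)."""
        if not 0 < inner < outer:
            raise ValueError("annulus needs 0 < inner < outer")
        return (self.count_disk(cls, centers, outer)
                - self.count_disk(cls, centers, inner - _INNER_EPS))

    def count(self, cls, centers, spec: NeighborhoodSpec) -> np.ndarray:
        if spec.kind == "disk":
            return self.count_disk(cls, centers, spec.radius)
        return self.count_annulus(cls, centers, spec.inner, spec.outer)


def count_in_disk(population: CellPopulation, cell_class, center, radius: float,
                  domain: DomainState) -> int:
    """Count cells of one class within a closed disk around ``center``."""
    counter = NeighborCounter(population, domain, max_radius=max(radius, 250.0))
    return int(counter.count_disk(cell_class, center, radius)[0])


def count_in_annulus(population: CellPopulation, cell_class, center,
                     inner: float, outer: float, domain: DomainState) -> int:
    """Count cells of one class within a closed annulus around ``center``."""
    counter = NeighborCounter(population, domain, max_radius=max(outer, 250.0))
    return int(counter.count_annulus(cell_class, center, inner, outer)[0])


def nearest_neighbor_distances(source: np.ndarray, target: np.ndarray,
                               domain: DomainState, exclude_self: bool,
                               max_radius: float = 1e9) -> np.ndarray:
    """Periodic distance from each source point to its nearest target point.

    ``exclude_self`` skips the zero self-match when source and target are the
    same array (same-class queries).
    """
    if source.shape[0] == 0 or target.shape[0] == 0:
        return np.full(source.shape[0], np.nan)
    pad = min(domain.height, 1000.0)
    wrapped_t, box = _tree_points(target.copy(), domain, pad)
    tree = cKDTree(wrapped_t, boxsize=box)
    wrapped_s, _ = _tree_points(source.copy(), domain, pad)
    k = 2 if exclude_self else 1
    dist, _ = tree.query(wrapped_s, k=k)
    if exclude_self:
        dist = np.where(np.isfinite(dist[:, 1]), dist[:, 1], np.nan)
    else:
        dist = np.atleast_1d(dist)
    return dist
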