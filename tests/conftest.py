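"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's KD-tree machinery: counts
and nearest-neighbour distances are recomputed with explicit O(N^2)
minimum-image arithmetic so they can certify the accelerated paths.
"""

import numpy as np
import pytest

from stripesim.core_state import (
    CellPopulation, DomainState, make_default_params,
)


@pytest.fixture()
def default_params():
    return make_default_params()


@pytest.fixture()
def domain():
    return DomainState()


def make_population(**class_points) -> CellPopulation:
    """Build a population from keyword class-name -> list of (x, y)."""
    pop = CellPopulation()
    for name, pts in class_points.items():
        if len(pts):
            pop.add(name, np.asarray(pts, dtype=float))
    return pop


def brute_pairwise_distances(a: np.ndarray, b: np.ndarray,
                             length: float) -> np.ndarray:
    """All-pairs periodic-in-x distances, plain double-loop arithmetic."""
    out = np.empty((a.shape[0], b.shape[0]))
    for i in range(a.shape[0]):
        for j in range(b.shape[0]):
            dx = abs(a[i, 0] - b[j, 0])
            dx = min(dx, length - dx)
            dy = a[i, 1] - b[j, 1]
            out[i, j] = np.hypot(dx, dy)
    return out


def brute_count_disk(points: np.ndarray, center, radius: float,
                     length: float) -> int:
    if points.shape[0] == 0:
        return 0
    d = brute_pairwise_distances(np.atleast_2d(np.asarray(center, float)),
                                 points, length)[0]
    return int(np.sum(d <= radius))


def brute_count_annulus(points: np.ndarray, center, inner: float,
                        outer: float, length: float) -> int:
    if points.shape[0] == 0:
        return 0
    d = brute_pairwise_distances(np.atleast_2d(np.asarray(center, float)),
                                 points, length)[0]
    return int(np.sum((d >= inner) & (d <= outer)))


def brute_nearest_neighbor(source: np.ndarray, target: np.ndarray,
                           length: float, exclude_self: bool) -> np.ndarray:
    d = brute_pairwise_distances(source, target, length)
    if exclude_self:
        np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def random_cloud(rng: np.random.Generator, n: int,
                 domain: DomainState) -> np.ndarray:
    pts = rng.random((n, 2))
    pts[:, 0] *= domain.length
    pts[:, 1] *= domain.height
    return pts
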