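"""Domain growth, developmental staging, and cell migration.

Growth is uniform epithelial stretching: each day the domain gains 38 um in
length and 27 um in height and every cell coordinate is multiplied by the
corresponding scale factor, so relative positions ride along with the
tissue.

Migration is kinematic (velocity proportional to force, no inertia).  The
force a source cell at A exerts on a target cell at B is

    F = -R * (1/2 + 1/2 * tanh((r - ||A - B||) / delta)) * (A - B)/||A - B||,

i.e. a smoothed contact force of signed strength R (positive repels) and
range r, integrated with 10 synchronous forward-Euler substeps of 0.1 day.
Within 50 um of the top or bottom edge, outward vertical velocity is zeroed
(no-flux boundaries); x wraps periodically.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .core_state import (
    ATTRACTIVE, CLASS_NAMES, INTERACTIONS, N_CLASSES,
    CellPopulation, DomainState, MigrationParams, class_index,
)
from .geometry import displacement, wrap_x, _tree_points


# ---------------------------------------------------------------------------
# Growth and staging
# ---------------------------------------------------------------------------

def grow_domain(domain: DomainState) -> DomainState:
    """Advance one day of uniform tissue growth."""
    return DomainState(
        day=domain.day + 1,
        length=domain.length + domain.growth_dx,
        height=domain.height + domain.growth_dy,
        growth_dx=domain.growth_dx,
        growth_dy=domain.growth_dy,
    )


def stretch_positions(population: CellPopulation, old: DomainState,
                      new: DomainState) -> CellPopulation:
    """Scale every coordinate by (L_new/L_old, H_new/H_old)."""
    if new.length < old.length or new.height < old.height:
        raise ValueError("stretching requires the new domain to be at least as large")
    sx = new.length / old.length
    sy = new.height / old.height
    out = population.copy()
    for c in range(N_CLASSES):
        pos = out.positions(c)
        if pos.size:
            out.set_positions(c, pos * np.array([sx, sy]))
    return out


#: Developmental-stage anchors: (label, SSL, onset day, milestone).
#: SSL is the standardized standard length, a body-size staging measure.
STAGE_ANCHORS = (
    ("PB", 7.5, 21, "faint central strip of dense iridophores"),
    ("PR", 8.5, 30, "loose iridophores spreading across stripes 1D & 1V"),
    ("SP", 9.5, 39, "dense iridophores present in interstripes X1V & X1D"),
    ("SA", 10.1, 44, "interstripes X1D & X1V forming"),
    ("J", 10.9, 51, "stripes 2V & 2D faint"),
    ("J+", 13.0, 70, "stripes 2V & 2D forming"),
)


def stage_for_day(day: int) -> tuple[str, float]:
    """Stage label and interpolated SSL for a day in [21, 75].

    The label is the latest stage whose onset is <= day; SSL interpolates
    linearly between anchors and is clamped beyond the last anchor.
    """
    if not 21 <= day <= 75:
        raise ValueError(f"day {day} outside the staged range [21, 75]")
    days = np.array([a[2] for a in STAGE_ANCHORS], dtype=float)
    ssls = np.array([a[1] for a in STAGE_ANCHORS], dtype=float)
    idx = int(np.searchsorted(days, day, side="right")) - 1
    label = STAGE_ANCHORS[idx][0]
    ssl = float(np.interp(day, days, ssls))
    return label, ssl


# ---------------------------------------------------------------------------
# Forces
# ---------------------------------------------------------------------------

def _pair_indices(pair) -> tuple[int, int]:
    if isinstance(pair, str):
        s, t = pair.split("_")
        return class_index(s), class_index(t)
    s, t = pair
    return class_index(s), class_index(t)


def force_magnitude(pair, distance, params: MigrationParams) -> np.ndarray:
    """|f(d)| = |R| * (1/2 + 1/2 tanh((r - d)/delta)); zero beyond the cutoff."""
    s, t = _pair_indices(pair)
    if (s, t) not in INTERACTIONS:
        raise ValueError(f"no interaction term {CLASS_NAMES[s]}->{CLASS_NAMES[t]}")
    d = np.asarray(distance, dtype=np.float64)
    mag = abs(params.R[s, t]) * (0.5 + 0.5 * np.tanh((params.r[s, t] - d) / params.delta))
    return np.where(d <= params.cutoff, mag, 0.0)


def pair_force(pair, a, b, params: MigrationParams, domain: DomainState) -> np.ndarray:
    """Force on the cell at ``b`` due to the source cell at ``a``.

    Coincident cells (periodic distance 0) exert no force: the direction is
    undefined there and daughters separate through other neighbours.
    """
    s, t = _pair_indices(pair)
    d_vec = displacement(a, b, domain)      # minimum image, a -> b
    dist = float(np.linalg.norm(d_vec))
    if dist == 0.0:
        return np.zeros(2)
    mag = float(force_magnitude(pair, dist, params))
    sign = -1.0 if (s, t) in ATTRACTIVE else 1.0
    # repulsion pushes b away from a (along a->b); attraction pulls b toward a
    return sign * mag * d_vec / dist


def net_velocity(cell: tuple, population: CellPopulation,
                 params: MigrationParams, domain: DomainState) -> np.ndarray:
    """Velocity of one cell: sum of pair forces over the ODE interaction terms.

    Reference (brute-force) implementation used for small configurations and
    as the oracle for the vectorized integrator.
    """
    cls, index = cell
    t = class_index(cls)
    b = population.positions(t)[index]
    v = np.zeros(2)
    for (s, tt) in INTERACTIONS:
        if tt != t:
            continue
        src = population.positions(s)
        for j in range(src.shape[0]):
            if s == t and j == index:
                continue
            v += pair_force((s, t), src[j], b, params, domain)
    return v


def apply_boundary(velocity, position, domain: DomainState,
                   margin: float = 50.0) -> np.ndarray:
    """Zero outward vertical velocity within ``margin`` of the top/bottom edge."""
    v = np.array(velocity, dtype=np.float64)
    y = position[1]
    if y >= domain.height - margin and v[1] > 0:
        v[1] = 0.0
    if y <= margin and v[1] < 0:
        v[1] = 0.0
    return v


# ---------------------------------------------------------------------------
# Fast synchronous Euler integration
# ---------------------------------------------------------------------------

def _velocities_fast(pos: np.ndarray, cls: np.ndarray, domain: DomainState,
                     params: MigrationParams) -> np.ndarray:
    """All-cell velocities from one synchronous snapshot.

    One KD-tree over all cells; every unordered pair within the global force
    cutoff contributes both directed terms, looked up in the (source,
    target) strength/range tables.  Accumulation uses bincount, so the
    result does not depend on pair enumeration order beyond float summation
    of identical addends.
    """
    n = pos.shape[0]
    v = np.zeros((n, 2))
    if n < 2:
        return v
    cutoff = params.cutoff
    wrapped, box = _tree_points(pos.copy(), domain, cutoff)
    tree = cKDTree(wrapped, boxsize=box)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    if pairs.shape[0] == 0:
        return v
    i, j = pairs[:, 0], pairs[:, 1]
    d = wrapped[j] - wrapped[i]                      # i -> j, minimum image in x
    L = domain.length
    d[:, 0] -= L * np.round(d[:, 0] / L)
    dist = np.hypot(d[:, 0], d[:, 1])
    ok = dist > 0.0                                   # coincident cells: no force
    i, j, d, dist = i[ok], j[ok], d[ok], dist[ok]
    ci, cj = cls[i], cls[j]
    unit = d / dist[:, None]
    # force on j from source i (signed R: positive repels along i->j)
    Rij = params.R[ci, cj]
    mij = Rij * (0.5 + 0.5 * np.tanh((params.r[ci, cj] - dist) / params.delta))
    # force on i from source j (direction j->i = -unit)
    Rji = params.R[cj, ci]
    mji = Rji * (0.5 + 0.5 * np.tanh((params.r[cj, ci] - dist) / params.delta))
    fx_j = mij * unit[:, 0]
    fy_j = mij * unit[:, 1]
    fx_i = -mji * unit[:, 0]
    fy_i = -mji * unit[:, 1]
    v[:, 0] += np.bincount(j, weights=fx_j, minlength=n)
    v[:, 1] += np.bincount(j, weights=fy_j, minlength=n)
    v[:, 0] += np.bincount(i, weights=fx_i, minlength=n)
    v[:, 1] += np.bincount(i, weights=fy_i, minlength=n)
    return v


def _apply_boundary_array(v: np.ndarray, pos: np.ndarray, domain: DomainState,
                          margin: float) -> np.ndarray:
    top = (pos[:, 1] >= domain.height - margin) & (v[:, 1] > 0)
    bot = (pos[:, 1] <= margin) & (v[:, 1] < 0)
    v[top | bot, 1] = 0.0
    return v


def integrate_day(population: CellPopulation, params: MigrationParams,
                  domain: DomainState) -> CellPopulation:
    """One day of migration: synchronous forward Euler substeps.

    Velocities in each substep are computed from the substep's initial
    positions; then all positions update together, x wrapping mod L and y
    clamping to [0, H].
    """
    out = population.copy()
    out.sort_by_id()  # canonical order: bit-exact invariance to input order
    pos, cls, _ = out.merged()
    if pos.shape[0] == 0:
        return out
    h = params.euler_step
    for _ in range(params.substeps_per_day):
        v = _velocities_fast(pos, cls, domain, params)
        v = _apply_boundary_array(v, pos, domain, params.boundary_margin)
        pos = pos + h * v
        pos[:, 0] = wrap_x(pos[:, 0], domain.length)
        np.clip(pos[:, 1], 0.0, domain.height, out=pos[:, 1])
    # split back per class, preserving per-class order
    offset = 0
    for c in range(N_CLASSES):
        k = out.n(c)
        out.set_positions(c, pos[offset:offset + k])
        offset += k
    return out
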