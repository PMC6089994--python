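"""Pattern quantification, snapshot files, and plotting.

Quantitative readouts of a simulated pattern:

* nearest-neighbour distance statistics per cell-class pair (periodic in x;
  same-class queries exclude the focal cell),
* the coefficient of variation CV = 100 * SD / mean of melanophore
  neighbour distances -- an empirical pattern-quality measure that decays
  as stripes organize,
* interstripe band detection from the y-profile of dense cells, plus a
  break census along each band,
* developmental milestone flags (central interstripe, X1D/X1V, off-center
  melanophore stripes) evaluated at the stage-onset days,
* orientation anisotropy and cluster counts used by the mutant phenotype
  classifiers.

Snapshots serialize to plain CSV (day, cell_id, class, x_um, y_um) at full
float precision, so a write/read round trip is bit-exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .core_state import (
    CLASS_INDEX, CLASS_NAMES, ID, IL, M, XD, XL,
    CellPopulation, DomainState, SimulationState, class_index,
)
from .geometry import nearest_neighbor_distances, _tree_points
from .kinetics import STAGE_ANCHORS


# ---------------------------------------------------------------------------
# Neighbour distances and CV
# ---------------------------------------------------------------------------

def neighbor_distance_stats(population: CellPopulation, class_pair,
                            domain: DomainState) -> dict:
    """Mean/SD/count of nearest-neighbour distances for a (source, target)
    class pair.  An empty source class yields ``defined: False`` rather than
    a number."""
    src, tgt = (class_index(c) for c in class_pair)
    source = population.positions(src)
    target = population.positions(tgt)
    if source.shape[0] == 0 or target.shape[0] == 0 or (
            src == tgt and source.shape[0] < 2):
        return {"mean": float("nan"), "sd": float("nan"), "n": 0, "defined": False}
    d = nearest_neighbor_distances(source, target, domain, exclude_self=(src == tgt))
    d = d[np.isfinite(d)]
    if d.size == 0:
        return {"mean": float("nan"), "sd": float("nan"), "n": 0, "defined": False}
    return {"mean": float(d.mean()), "sd": float(d.std(ddof=0)),
            "n": int(d.size), "defined": True}


def cv_of_neighbor_distances(distances, sample_sd: bool = False) -> float:
    """CV = 100 * SD / mean.  Population SD by default."""
    d = np.asarray(distances, dtype=np.float64)
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise ValueError("CV undefined for an empty distance set")
    mean = d.mean()
    if mean <= 0:
        raise ValueError("CV undefined for zero mean distance")
    sd = d.std(ddof=1 if (sample_sd and d.size > 1) else 0)
    return float(100.0 * sd / mean)


def melanophore_cv(population: CellPopulation, domain: DomainState) -> float:
    """CV of melanophore nearest-neighbour distances; NaN if < 2 cells."""
    pos = population.positions(M)
    if pos.shape[0] < 2:
        return float("nan")
    d = nearest_neighbor_distances(pos, pos, domain, exclude_self=True)
    d = d[np.isfinite(d)]
    return cv_of_neighbor_distances(d) if d.size else float("nan")


# ---------------------------------------------------------------------------
# Band detection and break census
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Band:
    """A detected interstripe (or stripe) band: a y-interval of high density."""

    y_lo: float
    y_hi: float
    y_center: float
    n_cells: int
    dominant_class: str

    @property
    def width(self) -> float:
        return self.y_hi - self.y_lo

    def contains(self, y: float) -> bool:
        return self.y_lo <= y <= self.y_hi


def _smoothed_profile(y: np.ndarray, height: float, bin_width: float,
                      smooth_bins: int) -> tuple[np.ndarray, np.ndarray]:
    edges = np.arange(0.0, height + bin_width, bin_width)
    hist, _ = np.histogram(y, bins=edges)
    kernel = np.ones(smooth_bins) / smooth_bins
    smooth = np.convolve(hist.astype(float), kernel, mode="same")
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, smooth


def detect_bands(positions: np.ndarray, domain: DomainState,
                 population: CellPopulation | None = None,
                 bin_width: float = 20.0, smooth_bins: int = 3,
                 fraction: float = 0.5, reference: str = "central",
                 min_width: float = 40.0) -> list[Band]:
    """Maximal y-intervals where the smoothed density of the given cells
    exceeds ``fraction`` of a reference peak.

    ``reference='central'`` uses the peak within 200 um of the midline
    (falling back to the global peak if the centre is empty), matching how
    new interstripes are judged against the central one; ``'global'`` uses
    the overall peak.
    """
    if positions.shape[0] == 0:
        return []
    centers, smooth = _smoothed_profile(positions[:, 1], domain.height,
                                        bin_width, smooth_bins)
    if reference == "central":
        near = np.abs(centers - domain.height / 2.0) <= 200.0
        peak = smooth[near].max() if near.any() and smooth[near].max() > 0 \
            else smooth.max()
    else:
        peak = smooth.max()
    if peak <= 0:
        return []
    above = smooth >= fraction * peak
    bands: list[Band] = []
    i = 0
    nbin = above.size
    while i < nbin:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < nbin and above[j + 1]:
            j += 1
        y_lo = centers[i] - bin_width / 2.0
        y_hi = centers[j] + bin_width / 2.0
        if y_hi - y_lo >= min_width:
            in_band = (positions[:, 1] >= y_lo) & (positions[:, 1] <= y_hi)
            dominant = ""
            if population is not None:
                counts = {
                    name: int(np.sum((population.positions(ci)[:, 1] >= y_lo)
                                     & (population.positions(ci)[:, 1] <= y_hi)))
                    for name, ci in (("Id", ID), ("Xd", XD), ("M", M))
                }
                dominant = max(counts, key=counts.get)
            bands.append(Band(float(y_lo), float(y_hi),
                              float(0.5 * (y_lo + y_hi)),
                              int(in_band.sum()), dominant))
        i = j + 1
    return bands


def dense_positions(population: CellPopulation) -> np.ndarray:
    """Positions of interstripe (dense) cells: dense iridophores + xanthophores."""
    parts = [population.positions(ID), population.positions(XD)]
    parts = [p for p in parts if p.shape[0]]
    return np.concatenate(parts) if parts else np.empty((0, 2))


def detect_interstripe_bands(population: CellPopulation, domain: DomainState,
                             **kw) -> list[Band]:
    """Interstripe bands from the dense-cell (Id + Xd) y-profile."""
    return detect_bands(dense_positions(population), domain,
                        population=population, **kw)


def count_breaks(population: CellPopulation, band: Band, domain: DomainState,
                 gap_threshold: float = 100.0, column_width: float = 50.0,
                 positions: np.ndarray | None = None) -> dict:
    """Break census of one band: x-columns empty of dense cells.

    The band's x-extent is partitioned into ``column_width`` columns; a break
    is a maximal run of empty columns spanning at least ``gap_threshold``,
    honouring x-periodicity (a void across the seam counts once).
    """
    pts = dense_positions(population) if positions is None else positions
    in_band = (pts[:, 1] >= band.y_lo) & (pts[:, 1] <= band.y_hi)
    x = np.mod(pts[in_band, 0], domain.length)
    ncol = max(1, int(np.ceil(domain.length / column_width)))
    occupied = np.zeros(ncol, dtype=bool)
    if x.size:
        occupied[np.minimum((x / column_width).astype(int), ncol - 1)] = True
    if not occupied.any():
        return {"n_breaks": 1, "gaps": [float(domain.length)]}
    if occupied.all():
        return {"n_breaks": 0, "gaps": []}
    # rotate so the scan starts at an occupied column: seam voids merge
    start = int(np.argmax(occupied))
    rolled = np.roll(occupied, -start)
    gaps = []
    run = 0
    for occ in rolled:
        if not occ:
            run += 1
        elif run:
            gaps.append(run * column_width)
            run = 0
    if run:
        gaps.append(run * column_width)
    gaps = [g for g in gaps if g >= gap_threshold]
    return {"n_breaks": len(gaps), "gaps": [float(g) for g in gaps]}


def central_interstripe_bands(population: CellPopulation, domain: DomainState,
                              off_center_margin: float = 100.0) -> dict:
    """The central band (X0) and nearest off-center bands (X1D above, X1V
    below), if present."""
    bands = detect_interstripe_bands(population, domain)
    mid = domain.height / 2.0
    x0 = next((b for b in bands if b.contains(mid)), None)
    above = [b for b in bands if b.y_center > mid + off_center_margin]
    below = [b for b in bands if b.y_center < mid - off_center_margin]
    x1d = min(above, key=lambda b: b.y_center - mid) if above else None
    x1v = min(below, key=lambda b: mid - b.y_center) if below else None
    return {"X0": x0, "X1D": x1d, "X1V": x1v, "all": bands}


def pattern_success(state: SimulationState, gap_threshold: float = 100.0) -> dict:
    """Unbroken-interstripe criterion: X0, X1D and X1V all detected with
    zero breaks at the given gap threshold."""
    trio = central_interstripe_bands(state.population, state.domain)
    found = all(trio[k] is not None for k in ("X0", "X1D", "X1V"))
    n_breaks = 0
    per_band = {}
    for key in ("X0", "X1D", "X1V"):
        band = trio[key]
        if band is None:
            per_band[key] = None
            continue
        census = count_breaks(state.population, band, state.domain,
                              gap_threshold=gap_threshold)
        per_band[key] = census["n_breaks"]
        n_breaks += census["n_breaks"]
    return {"success": bool(found and n_breaks == 0),
            "bands_found": found, "total_breaks": n_breaks,
            "per_band_breaks": per_band,
            "n_bands": len(trio["all"])}


# ---------------------------------------------------------------------------
# Milestones
# ---------------------------------------------------------------------------

def melanophore_stripe_bands(population: CellPopulation, domain: DomainState
                             ) -> list[Band]:
    """Melanophore bands (stripes), judged against the global M peak."""
    return detect_bands(population.positions(M), domain, population=population,
                        reference="global", fraction=0.35)


def off_center_m_stripes(population: CellPopulation, domain: DomainState,
                         margin: float = 100.0) -> list[Band]:
    mid = domain.height / 2.0
    return [b for b in melanophore_stripe_bands(population, domain)
            if abs(b.y_center - mid) > margin]


def _x_coverage(population: CellPopulation, band: Band, domain: DomainState,
                column_width: float = 50.0) -> float:
    pts = dense_positions(population)
    in_band = (pts[:, 1] >= band.y_lo) & (pts[:, 1] <= band.y_hi)
    x = np.mod(pts[in_band, 0], domain.length)
    ncol = max(1, int(np.ceil(domain.length / column_width)))
    occupied = np.zeros(ncol, dtype=bool)
    if x.size:
        occupied[np.minimum((x / column_width).astype(int), ncol - 1)] = True
    return float(occupied.mean())


def milestone_flags(trajectory) -> dict:
    """Per-stage booleans evaluated at each stage's onset day.

    PB: a central dense band exists.  SP: dense bands above and below the
    centre (X1D/X1V appearing).  SA: those bands span at least half the
    domain length.  J: melanophores present beyond X1D/X1V.  J+: at least
    two off-center melanophore stripes flanked by dense bands.
    Days not recorded in the trajectory evaluate to False.
    """
    flags = {}
    recorded = set(trajectory.days)
    for label, _ssl, day, _note in STAGE_ANCHORS:
        if day not in recorded:
            flags[label] = False
            continue
        state = trajectory.state_at(day)
        pop, domain = state.population, state.domain
        trio = central_interstripe_bands(pop, domain)
        if label == "PB":
            flags[label] = trio["X0"] is not None
        elif label == "PR":
            flags[label] = pop.n(IL) > 0
        elif label == "SP":
            flags[label] = trio["X1D"] is not None and trio["X1V"] is not None
        elif label == "SA":
            flags[label] = (
                trio["X1D"] is not None and trio["X1V"] is not None
                and _x_coverage(pop, trio["X1D"], domain) >= 0.5
                and _x_coverage(pop, trio["X1V"], domain) >= 0.5)
        elif label == "J":
            ok = False
            if trio["X1D"] is not None and trio["X1V"] is not None:
                my = pop.positions(M)[:, 1] if pop.n(M) else np.empty(0)
                ok = bool(np.any(my > trio["X1D"].y_hi)
                          and np.any(my < trio["X1V"].y_lo))
            flags[label] = ok
        elif label == "J+":
            stripes = off_center_m_stripes(pop, domain)
            flanked = 0
            dense_bands = trio["all"]
            for s in stripes:
                above = any(b.y_center > s.y_center for b in dense_bands)
                below = any(b.y_center < s.y_center for b in dense_bands)
                flanked += above and below
            flags[label] = flanked >= 2
    return flags


# ---------------------------------------------------------------------------
# Mutant-classifier helpers
# ---------------------------------------------------------------------------

def orientation_anisotropy(positions: np.ndarray, domain: DomainState,
                           bin_width: float = 50.0) -> float:
    """Horizontal-banding index of a point pattern, in [-1, 1].

    Contrast of the coefficients of variation of the two marginal density
    profiles, (cv_y - cv_x) / (cv_y + cv_x): near +1 for horizontal bands
    (strong y modulation, flat in x), near 0 for isotropic or labyrinthine
    patterns, negative for vertical banding.
    """
    if positions.shape[0] < 10:
        return float("nan")
    ny = max(2, int(np.round(domain.height / bin_width)))
    nx = max(2, int(np.round(domain.length / bin_width)))
    hy, _ = np.histogram(np.clip(positions[:, 1], 0, domain.height),
                         bins=ny, range=(0, domain.height))
    hx, _ = np.histogram(np.mod(positions[:, 0], domain.length),
                         bins=nx, range=(0, domain.length))
    cv_y = hy.std() / hy.mean() if hy.mean() > 0 else 0.0
    cv_x = hx.std() / hx.mean() if hx.mean() > 0 else 0.0
    if cv_x + cv_y == 0:
        return 0.0
    return float((cv_y - cv_x) / (cv_y + cv_x))


def cluster_count(positions: np.ndarray, domain: DomainState,
                  link_radius: float = 100.0, min_size: int = 3) -> int:
    """Number of single-linkage clusters of a point set (periodic in x)."""
    n = positions.shape[0]
    if n == 0:
        return 0
    wrapped, box = _tree_points(positions.copy(), domain, link_radius)
    tree = cKDTree(wrapped, boxsize=box)
    graph = tree.sparse_distance_matrix(tree, link_radius, output_type="coo_matrix")
    k, labels = connected_components(graph.tocsr(), directed=False)
    sizes = np.bincount(labels)
    return int(np.sum(sizes >= min_size))


def occupancy_fraction(positions: np.ndarray, domain: DomainState,
                       box: float = 100.0) -> float:
    """Fraction of box x box cells of the domain containing >= 1 point."""
    nx = max(1, int(np.ceil(domain.length / box)))
    ny = max(1, int(np.ceil(domain.height / box)))
    if positions.shape[0] == 0:
        return 0.0
    ix = np.minimum((np.mod(positions[:, 0], domain.length) / box).astype(int), nx - 1)
    iy = np.minimum((np.clip(positions[:, 1], 0, domain.height) / box).astype(int), ny - 1)
    grid = np.zeros((nx, ny), dtype=bool)
    grid[ix, iy] = True
    return float(grid.mean())


def dense_profile_correlation(population: CellPopulation, domain: DomainState,
                              x_range_a: tuple, x_range_b: tuple,
                              bin_width: float = 20.0, smooth_bins: int = 3
                              ) -> float:
    """Pearson correlation of the dense-cell y-profiles of two x-windows.

    High correlation means interstripes line up across the windows (aligned
    stripes); low correlation means lost directionality.
    """
    pts = dense_positions(population)
    profiles = []
    for (x0, x1) in (x_range_a, x_range_b):
        sel = (pts[:, 0] >= x0) & (pts[:, 0] <= x1)
        _, prof = _smoothed_profile(pts[sel, 1], domain.height, bin_width,
                                    smooth_bins)
        profiles.append(prof)
    a, b = profiles
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# Per-run metric bundle
# ---------------------------------------------------------------------------

def first_offcenter_band_day(trajectory, cls, margin: float = 100.0) -> float:
    """Earliest recorded day with an off-center band of the given class on
    both sides of the midline; NaN if never."""
    for state in trajectory.states:
        pop, domain = state.population, state.domain
        bands = detect_bands(pop.positions(class_index(cls)), domain,
                             reference="global", fraction=0.35)
        mid = domain.height / 2.0
        above = any(b.y_center > mid + margin for b in bands)
        below = any(b.y_center < mid - margin for b in bands)
        if above and below:
            return float(state.domain.day)
    return float("nan")


def standard_run_metrics(trajectory) -> dict:
    """Flat per-run summary used by ensembles and the acceptance checks."""
    state = trajectory.final
    pop, domain = state.population, state.domain
    out: dict = {}
    success = pattern_success(state)
    out["success"] = success["success"]
    out["n_bands"] = success["n_bands"]
    out["total_breaks"] = success["total_breaks"]
    for name, cls in (("mm", M), ("xdxd", XD), ("xlxl", XL),
                      ("idid", ID), ("ilil", IL)):
        st = neighbor_distance_stats(pop, (cls, cls), domain)
        out[f"nn_{name}_mean"] = st["mean"]
    out["cv_final"] = melanophore_cv(pop, domain)
    flags = milestone_flags(trajectory)
    for label, val in flags.items():
        out[f"milestone_{label}"] = bool(val)
    id_day = first_offcenter_band_day(trajectory, ID)
    xd_day = first_offcenter_band_day(trajectory, XD)
    out["first_offcenter_id_day"] = id_day
    out["first_offcenter_xd_day"] = xd_day
    out["id_before_xd"] = bool(np.nan_to_num(id_day, nan=1e9)
                               <= np.nan_to_num(xd_day, nan=1e9)) \
        and np.isfinite(id_day)
    trio = central_interstripe_bands(pop, domain)
    out["sp_bands_by_44"] = False
    if 44 in trajectory.days:
        t44 = central_interstripe_bands(trajectory.state_at(44).population,
                                        trajectory.state_at(44).domain)
        out["sp_bands_by_44"] = t44["X1D"] is not None and t44["X1V"] is not None
    out["n_offcenter_m_stripes"] = len(off_center_m_stripes(pop, domain))
    out["anisotropy_dense"] = orientation_anisotropy(dense_positions(pop), domain)
    counts = pop.counts
    for name in CLASS_NAMES:
        out[f"n_{name}"] = counts[name]
    # CV trace on selected days for trend analysis
    cv_curve = {}
    for s in trajectory.states:
        if s.domain.day % 5 == 0 or s.domain.day == domain.day:
            cv = melanophore_cv(s.population, s.domain)
            if np.isfinite(cv):
                cv_curve[s.domain.day] = cv
    out["cv_curve"] = cv_curve
    return out


# ---------------------------------------------------------------------------
# Snapshot CSV I/O
# ---------------------------------------------------------------------------

_SNAPSHOT_COLUMNS = ("day", "cell_id", "class", "x_um", "y_um")


def write_snapshots(trajectory, path) -> None:
    """Write recorded snapshots as CSV, one row per cell per day, at full
    float precision (round-trip exact)."""
    rows = []
    for state in trajectory.states:
        day = state.domain.day
        for c, name in enumerate(CLASS_NAMES):
            pos = state.population.positions(c)
            ids = state.population.ids(c)
            for k in range(pos.shape[0]):
                rows.append((day, int(ids[k]), name,
                             repr(float(pos[k, 0])), repr(float(pos[k, 1]))))
    df = pd.DataFrame(rows, columns=_SNAPSHOT_COLUMNS)
    df.to_csv(path, index=False)


def read_snapshots(path, domains: dict | None = None):
    """Read a snapshot CSV back into a Trajectory.

    Domain geometry is reconstructed from the default growth schedule unless
    ``domains`` maps day -> DomainState.  Malformed class tags are reported
    with their line number.
    """
    from .engine_scenarios import Trajectory

    df = pd.read_csv(path, dtype={"day": int, "cell_id": np.int64,
                                  "class": str, "x_um": float, "y_um": float},
                     float_precision="round_trip")
    missing = set(_SNAPSHOT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"snapshot file missing columns {sorted(missing)}")
    bad = ~df["class"].isin(CLASS_NAMES)
    if bad.any():
        line = int(np.argmax(bad.values)) + 2  # header is line 1
        raise ValueError(
            f"unknown class tag {df['class'][bad].iloc[0]!r} on line {line}")
    traj = Trajectory("from_file", -1, [])
    for day in sorted(df["day"].unique()):
        sub = df[df["day"] == day]
        if domains and day in domains:
            domain = domains[day]
        else:
            base = DomainState()
            domain = DomainState(day=int(day),
                                 length=base.length + base.growth_dx * (day - 21),
                                 height=base.height + base.growth_dy * (day - 21))
        pop = CellPopulation()
        for name in CLASS_NAMES:
            cls_rows = sub[sub["class"] == name]
            c = CLASS_INDEX[name]
            pop._pos[c] = cls_rows[["x_um", "y_um"]].to_numpy(dtype=np.float64)
            pop._ids[c] = cls_rows["cell_id"].to_numpy(dtype=np.int64)
        pop.next_id = int(df["cell_id"].max()) + 1 if len(df) else 0
        pop.sort_by_id()
        traj.states.append(SimulationState(pop, domain))
    return traj


def write_metrics_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# Plotting
# ---------------------------------------------------------------------------

#: Display colours follow the cells' appearance: black melanophores, orange
#: dense / yellow loose xanthophores, silver dense / blue loose iridophores.
CLASS_COLORS = {"M": "black", "Xd": "#ff8c00", "Xl": "#ffe135",
                "Id": "#c0c0c0", "Il": "#4169e1"}


def plot_state(state: SimulationState, ax=None, point_size: float = 6.0):
    """Scatter the five classes in their display colours (iridophores under
    xanthophores, melanophores at the bottom layer)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 9 * state.domain.height
                                      / state.domain.length))
    for name in ("M", "Il", "Id", "Xl", "Xd"):
        pos = state.population.positions(name)
        if pos.shape[0]:
            ax.scatter(pos[:, 0], pos[:, 1], s=point_size,
                       c=CLASS_COLORS[name], label=name, linewidths=0)
    ax.set_xlim(0, state.domain.length)
    ax.set_ylim(0, state.domain.height)
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    ax.set_title(f"day {state.domain.day}")
    ax.set_facecolor("#f5f5f5")
    return ax


def save_state_plot(state: SimulationState, path, dpi: int = 110) -> None:
    import matplotlib.pyplot as plt

    ax = plot_state(state)
    ax.figure.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(ax.figure)
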