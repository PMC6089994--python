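"""Daily update loop, initial conditions, scenario presets and calibration.

A run starts from an approximation of the fish at 21 dpf -- a faint central
band of dense iridophores over the horizontal myoseptum plus loose (larval)
xanthophores scattered across the skin -- and iterates one step per day to
the configured end day (default 70 dpf, onset of stage J+).  Each step:

1. scheduled perturbations (late iridophore seeding, ablation),
2. domain growth and uniform position stretching,
3. migration (10 forward-Euler substeps),
4. one synchronous rule pass: all birth, death and form-flip decisions are
   computed from the post-migration snapshot and applied together.

Scenario presets reproduce the classic experiments: mutants lacking cell
classes (pfeffer / nacre / shady and their double mutants), choker (no
initial iridophore band; 15 dense iridophores seeded at random at 31 dpf),
puma (melanophore birth reduced ~85%), rectangular ablation at 40 dpf, and
the mechanism-toggle variants of the iridophore cue network.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import cell_rules
from .cell_rules import apply_mechanism_toggles
from .core_state import (
    ID, IL, M, XD, XL,
    AblationEvent, CellPopulation, ChokerSeedEvent, CounterRng, DomainState,
    MigrationParams, RuleParams, ScenarioConfig, SimulationState,
    make_default_params,
)
from .geometry import NeighborCounter
from .kinetics import grow_domain, integrate_day, stretch_positions


# ---------------------------------------------------------------------------
# Scenario presets
# ---------------------------------------------------------------------------

def _preset(name: str, **kw) -> ScenarioConfig:
    return ScenarioConfig(name=name, **kw).validate()


def scenario_preset(name: str, end_day: int = 70) -> ScenarioConfig:
    """Named scenario presets for every experiment the model covers."""
    presets = {
        "wildtype": {},
        "pfeffer": {"suppress_x_birth": True, "no_initial_xl": True},
        "nacre": {"suppress_m_birth": True},
        "shady": {"suppress_i_birth": True, "no_initial_strip": True},
        "pfeffer_nacre": {"suppress_x_birth": True, "no_initial_xl": True,
                          "suppress_m_birth": True},
        "pfeffer_shady": {"suppress_x_birth": True, "no_initial_xl": True,
                          "suppress_i_birth": True, "no_initial_strip": True},
        "nacre_shady": {"suppress_m_birth": True, "suppress_i_birth": True,
                        "no_initial_strip": True},
        "choker": {"no_initial_strip": True,
                   "events": (ChokerSeedEvent(day=31, n_cells=15),)},
        "puma": {"m_birth_scale": 0.15},
        "ablation": {"events": (AblationEvent(day=40),)},
    }
    for toggle in cell_rules.TOGGLE_PRESETS:
        presets[toggle] = {"toggles": (toggle,)}
    if name not in presets:
        raise ValueError(f"unknown scenario {name!r}")
    return _preset(name, end_day=end_day, **presets[name])


SCENARIO_NAMES = (
    "wildtype", "pfeffer", "nacre", "shady", "pfeffer_nacre", "pfeffer_shady",
    "nacre_shady", "choker", "puma", "ablation",
) + tuple(cell_rules.TOGGLE_PRESETS)


# ---------------------------------------------------------------------------
# Initial condition
# ---------------------------------------------------------------------------

#: Calibrated initial-condition geometry (um).
STRIP_HALF_WIDTH = 50.0
STRIP_SPACING = 30.0
XL_SPACING = 85.0
JITTER_FRACTION = 0.4


def _jittered_grid(rng: CounterRng, tag: str, x_range, y_range,
                   spacing: float, domain: DomainState) -> np.ndarray:
    """Hex-free jittered square lattice of points over a rectangle."""
    xs = np.arange(x_range[0] + spacing / 2.0, x_range[1], spacing)
    ys = np.arange(y_range[0] + spacing / 2.0, y_range[1], spacing)
    if xs.size == 0 or ys.size == 0:
        return np.empty((0, 2))
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    jit = (rng.uniforms(20, tag, pts.shape[0], dim=2) - 0.5) * 2.0
    pts = pts + jit * JITTER_FRACTION * spacing
    pts[:, 0] = np.mod(pts[:, 0], domain.length)
    np.clip(pts[:, 1], 0.0, domain.height, out=pts[:, 1])
    return pts


def build_initial_state(scenario: ScenarioConfig, rng: CounterRng) -> SimulationState:
    """The 21 dpf state: central dense-iridophore band + scattered loose
    xanthophores; no melanophores, dense xanthophores or loose iridophores."""
    domain = DomainState()
    pop = CellPopulation()
    if not scenario.no_initial_strip and not scenario.suppress_i_birth:
        mid = domain.height / 2.0
        strip = _jittered_grid(
            rng, "init_id", (0.0, domain.length),
            (mid - STRIP_HALF_WIDTH, mid + STRIP_HALF_WIDTH),
            STRIP_SPACING, domain)
        np.clip(strip[:, 1], mid - STRIP_HALF_WIDTH, mid + STRIP_HALF_WIDTH,
                out=strip[:, 1])
        pop.add(ID, strip)
    if not scenario.no_initial_xl and not scenario.suppress_x_birth:
        xl = _jittered_grid(rng, "init_xl", (0.0, domain.length),
                            (0.0, domain.height), XL_SPACING, domain)
        pop.add(XL, xl)
    state = SimulationState(pop, domain, rng.root_seed)
    state.validate()
    return state


# ---------------------------------------------------------------------------
# Scheduled events
# ---------------------------------------------------------------------------

def apply_scheduled_events(state: SimulationState, scenario: ScenarioConfig,
                           rng: CounterRng, day: int | None = None
                           ) -> SimulationState:
    """Apply the events scheduled for ``day`` (default: the day about to be
    produced) to the state entering that day."""
    if day is None:
        day = state.domain.day + 1
    events = [ev for ev in scenario.events if ev.day == day]
    if not events:
        return state
    out = state.copy()
    pop, domain = out.population, out.domain
    for ev in events:
        if isinstance(ev, ChokerSeedEvent):
            z = rng.uniforms(day, "choker_seed", ev.n_cells, dim=2)
            z *= np.array([domain.length, domain.height])
            pop.add(ID, z)
            out.event_log.append((day, f"seeded {ev.n_cells} Id at random"))
        elif isinstance(ev, AblationEvent):
            xc = domain.length / 2.0 if ev.x_center is None else ev.x_center
            x0, x1 = xc - ev.length / 2.0, xc + ev.length / 2.0
            for cls in (M, XD, XL):
                pos = pop.positions(cls)
                inside = (pos[:, 0] >= x0) & (pos[:, 0] <= x1)
                pop.remove(cls, pop.ids(cls)[inside])
            for cls, tag in ((ID, "ablate_id"), (IL, "ablate_il")):
                pos, ids = pop.positions(cls), pop.ids(cls)
                inside = (pos[:, 0] >= x0) & (pos[:, 0] <= x1)
                u = rng.uniforms_for_ids(day, tag, ids) if ids.size else np.empty(0)
                pop.remove(cls, ids[inside & (u < ev.irido_fraction)])
            out.event_log.append((day, f"ablated rectangle [{x0:.0f}, {x1:.0f}]"))
        else:
            raise ValueError(f"unknown scheduled event {ev!r}")
    return out


# ---------------------------------------------------------------------------
# Daily step
# ---------------------------------------------------------------------------

def effective_rule_params(scenario: ScenarioConfig, rules: RuleParams) -> RuleParams:
    """Scenario-adjusted rule ledger: toggles, overrides, p override."""
    out = apply_mechanism_toggles(rules, scenario.toggles, scenario.overrides)
    if scenario.p_xl_dense is not None:
        out = replace(out, p=scenario.p_xl_dense)
    return out


def step_day(state: SimulationState, scenario: ScenarioConfig,
             mig: MigrationParams, rules: RuleParams, rng: CounterRng
             ) -> SimulationState:
    """Advance one day: events, growth, stretching, migration, rule pass."""
    day_new = state.domain.day + 1
    rules = effective_rule_params(scenario, rules)
    state = apply_scheduled_events(state, scenario, rng, day=day_new)
    old_domain = state.domain
    domain = grow_domain(old_domain)
    pop = stretch_positions(state.population, old_domain, domain)
    pop = integrate_day(pop, mig, domain)

    # Synchronous rule pass: all decisions from the post-migration snapshot.
    counter = NeighborCounter(pop, domain, rules.annulus_outer)
    decisions = []
    if not scenario.suppress_m_birth:
        decisions.append(cell_rules.melanophore_birth(
            pop, rules, domain, rng, day_new,
            birth_scale=scenario.m_birth_scale,
            thinning=scenario.puma_thinning, counter=counter))
    if not scenario.suppress_x_birth:
        decisions.append(cell_rules.xanthophore_division(
            pop, rules, domain, rng, day_new, counter=counter))
        decisions.append(cell_rules.random_loose_xanthophore_birth(
            pop, rules, domain, rng, day_new, counter=counter))
    if not scenario.suppress_i_birth:
        decisions.append(cell_rules.iridophore_division(
            pop, rules, domain, rng, day_new, counter=counter))
    decisions.append(cell_rules.melanophore_death(
        pop, rules, domain, rng, day_new, counter=counter))
    decisions.append(cell_rules.xanthophore_form_update(
        pop, rules, domain, rng, day_new, counter=counter))
    decisions.append(cell_rules.iridophore_form_update(
        pop, rules, domain, counter=counter))

    # Apply together: deaths, flips, then births (new ids in decision order).
    for dec in decisions:
        for cls, ids in dec.deaths:
            pop.remove(cls, ids)
    for dec in decisions:
        for cls_from, cls_to, ids in dec.flips:
            pop.flip(cls_from, cls_to, ids)
    for dec in decisions:
        for cls, positions, _tag in dec.births:
            pop.add(cls, positions)
    pop.sort_by_id()

    out = SimulationState(pop, domain, state.rng_root_seed, list(state.event_log))
    return out


# ---------------------------------------------------------------------------
# Trajectories and ensembles
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Recorded per-day snapshots of one run."""

    scenario: str
    root_seed: int
    states: list = field(default_factory=list)

    @property
    def days(self) -> list:
        return [s.domain.day for s in self.states]

    def state_at(self, day: int) -> SimulationState:
        for s in self.states:
            if s.domain.day == day:
                return s
        raise KeyError(f"no snapshot recorded for day {day}")

    @property
    def final(self) -> SimulationState:
        return self.states[-1]


def run_simulation(scenario: ScenarioConfig | str,
                   mig: MigrationParams | None = None,
                   rules: RuleParams | None = None,
                   seed: int = 0,
                   record_days=None,
                   progress: bool = False) -> Trajectory:
    """Run one scenario from 21 dpf to its end day.

    ``record_days`` limits which snapshots are kept (the initial and final
    states are always recorded); the run itself is unaffected.  Fully
    reproducible from (scenario, params, seed).
    """
    if isinstance(scenario, str):
        scenario = scenario_preset(scenario)
    scenario.validate()
    if mig is None or rules is None:
        dmig, drules = make_default_params()
        mig = mig or dmig
        rules = rules or drules
    rng = CounterRng(seed)
    state = build_initial_state(scenario, rng)
    traj = Trajectory(scenario.name, seed, [state])
    keep = None if record_days is None else set(record_days)
    for day in range(22, scenario.end_day + 1):
        state = step_day(state, scenario, mig, rules, rng)
        if keep is None or day in keep or day == scenario.end_day:
            traj.states.append(state)
        if progress:
            print(f"day {day}: {state.population.counts}", flush=True)
    return traj


def run_ensemble(scenario: ScenarioConfig | str, n_runs: int, root_seed: int = 0,
                 mig: MigrationParams | None = None,
                 rules: RuleParams | None = None,
                 record_days=None,
                 per_run_metrics=None) -> dict:
    """Run ``n_runs`` independent seeds; per-run metric dicts + aggregates.

    ``per_run_metrics`` maps a Trajectory to a flat dict of numbers; the
    default bundle (pattern success, neighbour distances, milestones) lives
    in :mod:`stripesim.metrics_io` and is used when None.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if per_run_metrics is None:
        from .metrics_io import standard_run_metrics
        per_run_metrics = standard_run_metrics
    runs = []
    for k in range(n_runs):
        seed = int(root_seed) + k
        traj = run_simulation(scenario, mig=mig, rules=rules, seed=seed,
                              record_days=record_days)
        row = {"seed": seed}
        row.update(per_run_metrics(traj))
        runs.append(row)
    keys = [k for k in runs[0] if k != "seed"
            and isinstance(runs[0][k], (int, float, np.floating, np.integer, bool))]
    aggregate = {}
    for k in keys:
        vals = np.array([float(r[k]) for r in runs if r[k] == r[k]])  # drop NaN
        if vals.size:
            aggregate[k] = {"mean": float(vals.mean()),
                            "sd": float(vals.std(ddof=0)),
                            "n": int(vals.size)}
    return {"scenario": scenario if isinstance(scenario, str) else scenario.name,
            "n_runs": n_runs, "root_seed": int(root_seed),
            "runs": runs, "aggregate": aggregate}


# ---------------------------------------------------------------------------
# Calibration of ledger constants not fixed by printed values
# ---------------------------------------------------------------------------

#: Target envelopes from published measurements: mean neighbour distances at
#: stage J+ (um) and melanophore speed (um/week).
CALIBRATION_TARGETS = {
    "mm_distance": 50.0,          # melanophore-melanophore, ~50 um
    "nn_envelope": (36.0, 82.0),  # every per-class mean NN distance
    "m_speed_week": (80.0, 100.0),
}

#: Search space (uniform) for the calibrated constants.
CALIBRATION_SPACE = {
    "n_diff": (200, 600),
    "n_rand": (20, 120),
    "eta": (6, 14),
    "phi": (12, 22),
    "psi": (3, 8),
    "rho": (15, 28),
}


def _calibration_residual(traj, rules) -> float:
    from .metrics_io import neighbor_distance_stats
    state = traj.final
    res = 0.0
    mm = neighbor_distance_stats(state.population, (M, M), state.domain)
    if mm["n"] == 0 or not np.isfinite(mm["mean"]):
        return 1e6
    res += ((mm["mean"] - CALIBRATION_TARGETS["mm_distance"]) / 10.0) ** 2
    lo, hi = CALIBRATION_TARGETS["nn_envelope"]
    for cls in (M, XD, XL, ID, IL):
        st = neighbor_distance_stats(state.population, (cls, cls), state.domain)
        if st["n"] == 0 or not np.isfinite(st["mean"]):
            continue
        over = max(0.0, st["mean"] - hi) + max(0.0, lo - st["mean"])
        res += (over / 5.0) ** 2
    return res


def calibrate_unknowns(targets: dict | None = None, iterations: int = 0,
                       seed: int = 0, end_day: int = 45,
                       space: dict | None = None
                       ) -> tuple[MigrationParams, RuleParams, dict]:
    """Random search over the calibrated ledger constants.

    Minimizes squared deviation from the measured spacing envelopes on a
    short wild-type run.  ``iterations == 0`` returns the shipped defaults
    unchanged (they are themselves the product of this procedure plus manual
    refinement).  Returns (migration, rules, report).
    """
    targets = targets or CALIBRATION_TARGETS
    space = space or CALIBRATION_SPACE
    mig, rules = make_default_params()
    best = (mig, rules)
    report = {"iterations": iterations, "evaluations": []}
    if iterations == 0:
        report["residual"] = None
        return best[0], best[1], report
    scen = scenario_preset("wildtype", end_day=end_day)
    gen = np.random.Generator(np.random.Philox(key=np.array([seed, 0xCA11B], dtype=np.uint64)))
    best_res = np.inf
    for it in range(iterations):
        if it == 0:
            cand = rules  # always evaluate the incumbent first
        else:
            draw = {k: (int(gen.integers(lo, hi + 1))
                        if isinstance(lo, int) else float(gen.uniform(lo, hi)))
                    for k, (lo, hi) in space.items()}
            if not (draw["phi"] > draw["psi"] and draw["phi"] < draw["rho"]):
                continue
            cand = replace(rules, **draw)
        traj = run_simulation(scen, mig=mig, rules=cand, seed=seed,
                              record_days=[end_day])
        res = _calibration_residual(traj, cand)
        report["evaluations"].append(
            {k: getattr(cand, k) for k in space} | {"residual": res})
        if res < best_res:
            best_res, best = res, (mig, cand)
    report["residual"] = float(best_res)
    return best[0], best[1], report
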