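"""Daily birth, death and form-transition rules.

All rules are threshold conditions on the numbers of cells inside short-range
disks and a long-range annulus around the cell (or candidate location) of
interest.  Every decision is computed from one synchronous snapshot of the
population; births, deaths and form flips are then applied together, so no
rule sees another rule's same-day outcome.  Melanophores are the only cells
that die; xanthophores and iridophores only change form.

The iridophore form-transition network is the model's core.  With M90 the
melanophore count within 90 um, Xd75 the dense-xanthophore count within
75 um and Xd_ann the dense-xanthophore count in the 210-250 um annulus:

* loose -> dense: M90 < c  AND  (Xd_ann < d  OR  Xd75 > e)
* dense -> loose: M90 > f  OR   (Xd_ann > g  AND  Xd75 < h_loc)

The six clauses are the building-block cues [A-tilde], [B-tilde], [C-tilde]
(to loose iridophores) and [A], [B], [C] (to dense iridophores); replacing a
threshold with a huge positive or negative sentinel disables a clause or
makes it vacuous without touching the rule code, which is how the
mechanism-toggle presets (other Danio species, reduced wild types) work.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core_state import (
    ID, IL, M, XD, XL, SENTINEL,
    CellPopulation, CounterRng, DomainState, RuleParams,
)
from .geometry import NeighborCounter


@dataclass
class UpdateDecision:
    """One day's decisions: births, deaths and form flips.

    births: list of (class, positions array, provenance tag)
    deaths: list of (class, id array)
    flips:  list of (class_from, class_to, id array)
    """

    births: list = field(default_factory=list)
    deaths: list = field(default_factory=list)
    flips: list = field(default_factory=list)

    def birth_positions(self, cls) -> np.ndarray:
        parts = [p for (c, p, _tag) in self.births if c == cls and len(p)]
        return np.concatenate(parts) if parts else np.empty((0, 2))

    def death_ids(self, cls) -> np.ndarray:
        parts = [i for (c, i) in self.deaths if c == cls and len(i)]
        return np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)

    def flip_ids(self, cls_from, cls_to) -> np.ndarray:
        parts = [i for (a, b, i) in self.flips
                 if a == cls_from and b == cls_to and len(i)]
        return np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)


# ---------------------------------------------------------------------------
# Birth rules
# ---------------------------------------------------------------------------

def melanophore_birth_condition(population: CellPopulation, locations,
                                params: RuleParams, domain: DomainState,
                                counter: NeighborCounter | None = None
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the two melanophore-birth conditions at given locations.

    Returns ``(promoted, empty)`` boolean masks: ``promoted`` is the
    deterministic long-range rule (annulus Xd + Id > alpha + beta * annulus
    M, local r_xm disk not overcrowded); ``empty`` marks locations whose
    local disk holds exactly ``gamma`` M + Xd, eligible for the rare
    ``p_empty`` birth.
    """
    z = np.atleast_2d(np.asarray(locations, dtype=np.float64))
    if counter is None:
        counter = NeighborCounter(population, domain, params.annulus_outer)
    ann_xd = counter.count_annulus(XD, z, params.annulus_inner, params.annulus_outer)
    ann_id = counter.count_annulus(ID, z, params.annulus_inner, params.annulus_outer)
    ann_m = counter.count_annulus(M, z, params.annulus_inner, params.annulus_outer)
    loc_xd = counter.count_disk(XD, z, params.r_xm)
    loc_m = counter.count_disk(M, z, params.r_xm)
    loc_id = counter.count_disk(ID, z, params.r_xm)
    promoted = (ann_xd + ann_id > params.alpha + params.beta * ann_m) \
        & (loc_xd + loc_m + loc_id <= params.eta)
    empty = (loc_m + loc_xd == params.gamma)
    return promoted, empty


def melanophore_birth(population: CellPopulation, params: RuleParams,
                      domain: DomainState, rng: CounterRng, day: int,
                      birth_scale: float = 1.0,
                      thinning: bool = False,
                      counter: NeighborCounter | None = None) -> UpdateDecision:
    """Long-range promoted, locally capped melanophore differentiation.

    Samples candidate locations uniformly; a melanophore appears where the
    annulus holds more dense xanthophores + dense iridophores than
    ``alpha + beta *`` melanophores and the local disk is not overcrowded
    (<= eta same-layer cells).  Additionally, a candidate whose local disk
    holds exactly ``gamma`` (default zero) M + Xd produces a birth with
    probability ``p_empty`` -- rare noise from scattered precursors.

    ``birth_scale`` models reduced differentiation (e.g. ~0.15): by default
    it shrinks the candidate count to ``ceil(scale * n_diff)``; with
    ``thinning`` the full candidate set is sampled and accepted births are
    kept with probability ``scale`` instead.
    """
    if not 0.0 <= birth_scale <= 1.0:
        raise ValueError("birth_scale must lie in [0, 1]")
    dec = UpdateDecision()
    n_cand = params.n_diff if thinning else int(np.ceil(birth_scale * params.n_diff))
    if n_cand == 0:
        return dec
    if counter is None:
        counter = NeighborCounter(population, domain, params.annulus_outer)
    z = rng.uniforms(day, "m_birth_loc", n_cand, dim=2)
    z *= np.array([domain.length, domain.height])
    promoted, empty_eligible = melanophore_birth_condition(
        population, z, params, domain, counter=counter)
    u_empty = rng.uniforms(day, "m_birth_empty", n_cand)
    empty = empty_eligible & (u_empty < params.p_empty)
    born = promoted | empty
    if thinning and birth_scale < 1.0:
        keep = rng.uniforms(day, "m_birth_thin", n_cand) < birth_scale
        born &= keep
    if born.any():
        dec.births.append((M, z[born], "precursor"))
    return dec


def _division(cls_parent: int, cap: float, count_classes: tuple,
              population: CellPopulation, params: RuleParams,
              domain: DomainState, rng: CounterRng, day: int, tag: str,
              counter: NeighborCounter) -> UpdateDecision:
    """Shared division rule: parents whose local disk holds at most ``cap``
    cells (of the crowding classes, focal included) place a same-form
    daughter uniformly in a 10 um square about themselves."""
    dec = UpdateDecision()
    pos = population.positions(cls_parent)
    if pos.shape[0] == 0:
        return dec
    crowd = sum(counter.count_disk(c, pos, params.r_xm) for c in count_classes)
    divide = crowd <= cap
    if not divide.any():
        return dec
    ids = population.ids(cls_parent)[divide]
    offsets = (rng.uniforms_for_ids(day, tag, ids, dim=2) - 0.5) * 10.0
    daughters = pos[divide] + offsets
    daughters[:, 0] = np.mod(daughters[:, 0], domain.length)
    np.clip(daughters[:, 1], 0.0, domain.height, out=daughters[:, 1])
    dec.births.append((cls_parent, daughters, "division"))
    return dec


def xanthophore_division(population: CellPopulation, params: RuleParams,
                         domain: DomainState, rng: CounterRng, day: int,
                         counter: NeighborCounter | None = None) -> UpdateDecision:
    """Xanthophore division, capped by local xanthophore crowding (both forms).

    Dense parents divide up to the higher cap ``phi`` (they pack tighter),
    loose parents up to ``psi``; the daughter inherits the parent's form.
    """
    if counter is None:
        counter = NeighborCounter(population, domain, params.annulus_outer)
    dec = _division(XD, params.phi, (XD, XL), population, params, domain,
                    rng, day, "xd_div", counter)
    dec_l = _division(XL, params.psi, (XD, XL), population, params, domain,
                      rng, day, "xl_div", counter)
    dec.births += dec_l.births
    return dec


def iridophore_division(population: CellPopulation, params: RuleParams,
                        domain: DomainState, rng: CounterRng, day: int,
                        counter: NeighborCounter | None = None) -> UpdateDecision:
    """Iridophore division, capped at ``rho`` iridophores (both forms) locally."""
    if counter is None:
        counter = NeighborCounter(population, domain, params.annulus_outer)
    dec = _division(ID, params.rho, (ID, IL), population, params, domain,
                    rng, day, "id_div", counter)
    dec_l = _division(IL, params.rho, (ID, IL), population, params, domain,
                      rng, day, "il_div", counter)
    dec.births += dec_l.births
    return dec


def random_loose_xanthophore_birth(population: CellPopulation, params: RuleParams,
                                   domain: DomainState, rng: CounterRng, day: int,
                                   counter: NeighborCounter | None = None
                                   ) -> UpdateDecision:
    """Loose-xanthophore birth from precursors where xanthophores are absent.

    ``n_rand`` uniform candidates per day; a birth occurs where the local
    disk holds exactly ``gamma`` (zero) xanthophores of either form.
    """
    dec = UpdateDecision()
    if params.n_rand == 0:
        return dec
    if counter is None:
        counter = NeighborCounter(population, domain, params.annulus_outer)
    z = rng.uniforms(day, "xl_rand_loc", params.n_rand, dim=2)
    z *= np.array([domain.length, domain.height])
    count = counter.count_disk(XD, z, params.r_xm) + counter.count_disk(XL, z, params.r_xm)
    born = count == params.gamma
    if born.any():
        dec.births.append((XL, z[born], "precursor"))
    return dec


# ---------------------------------------------------------------------------
# Death
# ---------------------------------------------------------------------------

def melanophore_death(population: CellPopulation, params: RuleParams,
                      domain: DomainState, rng: CounterRng, day: int,
                      counter: NeighborCounter | None = None) -> UpdateDecision:
    """Short-range competition and stochastic long-range inhibition.

    Deterministic: a melanophore dies when dense xanthophores within 90 um
    outnumber ``mu`` times the melanophores there (focal included).
    Stochastic (independent, same day): death with probability ``p_death``
    when annulus melanophores >= ``xi`` times annulus dense xanthophores and
    fewer than ``nu`` loose iridophores lie within 45 um (the loose-iridophore
    support signal that keeps stripe melanophores alive).
    """
    dec = UpdateDecision()
    pos = population.positions(M)
    if pos.shape[0] == 0:
        return dec
    if counter is None:
        counter = NeighborCounter(population, domain, params.annulus_outer)
    ids = population.ids(M)
    xd90 = counter.count_disk(XD, pos, params.r90)
    m90 = counter.count_disk(M, pos, params.r90)
    short_range = xd90 > params.mu * m90
    ann_m = counter.count_annulus(M, pos, params.annulus_inner, params.annulus_outer)
    ann_xd = counter.count_annulus(XD, pos, params.annulus_inner, params.annulus_outer)
    il45 = counter.count_disk(IL, pos, params.r45)
    u = rng.uniforms_for_ids(day, "m_death", ids)
    long_range = (ann_m >= params.xi * ann_xd) & (il45 < params.nu) & (u < params.p_death)
    dead = short_range | long_range
    if dead.any():
        dec.deaths.append((M, ids[dead]))
    return dec


# ---------------------------------------------------------------------------
# Form transitions
# ---------------------------------------------------------------------------

def xanthophore_form_update(population: CellPopulation, params: RuleParams,
                            domain: DomainState, rng: CounterRng, day: int,
                            counter: NeighborCounter | None = None
                            ) -> UpdateDecision:
    """Local xanthophore form selection.

    Dense -> loose when loose iridophores within 75 um exceed ``a`` plus
    dense iridophores within 45 um.  Loose -> dense when dense iridophores
    within 45 um, plus (with probability ``p``, redrawn per cell per day)
    dense xanthophores within 75 um, exceed ``b`` plus loose iridophores
    within 45 um plus melanophores within 75 um.
    """
    dec = UpdateDecision()
    if counter is None:
        counter = NeighborCounter(population, domain, params.annulus_outer)
    xd = population.positions(XD)
    if xd.shape[0]:
        il75 = counter.count_disk(IL, xd, params.r75)
        id45 = counter.count_disk(ID, xd, params.r45)
        go_loose = il75 > params.a + id45
        if go_loose.any():
            dec.flips.append((XD, XL, population.ids(XD)[go_loose]))
    xl = population.positions(XL)
    if xl.shape[0]:
        ids = population.ids(XL)
        id45 = counter.count_disk(ID, xl, params.r45)
        xd75 = counter.count_disk(XD, xl, params.r75)
        il45 = counter.count_disk(IL, xl, params.r45)
        m75 = counter.count_disk(M, xl, params.r75)
        P = (rng.uniforms_for_ids(day, "xl_P", ids) < params.p).astype(np.int64)
        go_dense = id45 + P * xd75 > params.b + il45 + m75
        if go_dense.any():
            dec.flips.append((XL, XD, ids[go_dense]))
    return dec


def iridophore_form_update(population: CellPopulation, params: RuleParams,
                           domain: DomainState,
                           counter: NeighborCounter | None = None,
                           loose_to_dense=None, dense_to_loose=None
                           ) -> UpdateDecision:
    """Deterministic iridophore form network (see module docstring).

    ``loose_to_dense`` / ``dense_to_loose`` allow injecting hand-specialized
    predicates (count dicts -> bool mask) for equivalence testing against
    the sentinel-toggle mechanism; by default the full compound rules run.
    """
    dec = UpdateDecision()
    if counter is None:
        counter = NeighborCounter(population, domain, params.annulus_outer)
    il = population.positions(IL)
    if il.shape[0]:
        counts = {
            "m90": counter.count_disk(M, il, params.r90),
            "xd_ann": counter.count_annulus(XD, il, params.annulus_inner,
                                            params.annulus_outer),
            "xd75": counter.count_disk(XD, il, params.r75),
        }
        if loose_to_dense is None:
            go_dense = (counts["m90"] < params.c) & (
                (counts["xd_ann"] < params.d) | (counts["xd75"] > params.e))
        else:
            go_dense = loose_to_dense(counts)
        if go_dense.any():
            dec.flips.append((IL, ID, population.ids(IL)[go_dense]))
    idp = population.positions(ID)
    if idp.shape[0]:
        counts = {
            "m90": counter.count_disk(M, idp, params.r90),
            "xd_ann": counter.count_annulus(XD, idp, params.annulus_inner,
                                            params.annulus_outer),
            "xd75": counter.count_disk(XD, idp, params.r75),
        }
        if dense_to_loose is None:
            go_loose = (counts["m90"] > params.f) | (
                (counts["xd_ann"] > params.g) & (counts["xd75"] < params.h_loc))
        else:
            go_loose = dense_to_loose(counts)
        if go_loose.any():
            dec.flips.append((ID, IL, population.ids(ID)[go_loose]))
    return dec


# ---------------------------------------------------------------------------
# Mechanism toggles
# ---------------------------------------------------------------------------

#: Named presets: threshold -> sentinel overrides.  A "< T" clause is
#: disabled with T = -SENTINEL and made vacuous with T = +SENTINEL; a
#: "> T" clause is disabled with T = +SENTINEL and made vacuous with
#: T = -SENTINEL.  Clause map: c is [A-tilde] "<", d is [B-tilde] "<",
#: e is [C-tilde] ">", f is [A] ">", g is [B] ">", h_loc is [C] "<".
TOGGLE_PRESETS = {
    # Danio variants
    "albolineatus": {"d": -SENTINEL},                  # loose->dense becomes [At & Ct]
    "albolineatus_reduced": {"d": -SENTINEL, "c": SENTINEL},   # -> [Ct]
    "margaritatus": {"h_loc": SENTINEL},               # dense->loose becomes [A || B]
    "margaritatus_reduced": {"h_loc": SENTINEL, "f": SENTINEL},  # -> [B]
    # wild-type robustness reductions
    "fig7a": {"g": SENTINEL, "h_loc": -SENTINEL},      # dense->loose: [A] only
    "fig7b": {"f": SENTINEL},                          # dense->loose: [B & C] only
    "fig7c": {"g": -SENTINEL},                         # dense->loose: [A || C]
    "fig7d": {"c": SENTINEL},                          # loose->dense: [Bt || Ct]
    "fig7e": {"e": SENTINEL},                          # loose->dense: [At & Bt]
    "fig7f": {"d": SENTINEL, "e": SENTINEL},           # loose->dense: [At] only
}

_TOGGLEABLE = ("c", "d", "e", "f", "g", "h_loc")


def apply_mechanism_toggles(params: RuleParams, toggles,
                            overrides: dict | None = None) -> RuleParams:
    """Return a ledger with the named presets' sentinel overrides applied.

    ``overrides`` allows arbitrary per-threshold values on top of the
    presets.  Unknown preset or threshold names raise ``ValueError``.
    """
    if isinstance(toggles, str):
        toggles = (toggles,)
    changes: dict = {}
    for name in toggles:
        if name not in TOGGLE_PRESETS:
            raise ValueError(f"unknown mechanism-toggle preset {name!r}")
        changes.update(TOGGLE_PRESETS[name])
    for key, val in (overrides or {}).items():
        if key not in _TOGGLEABLE:
            raise ValueError(f"cannot override unknown threshold {key!r}")
        changes[key] = val
    return replace(params, **changes) if changes else params
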