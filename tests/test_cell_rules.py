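"""Daily rule semantics: worked boundary examples, closure, toggles.

Geometric fixtures place cells at exact distances from a focal point so
every neighbourhood count is known by construction, letting each threshold
rule be checked at its boundary.
"""

import dataclasses

import numpy as np
import pytest

from stripesim import cell_rules
from stripesim.cell_rules import (
    TOGGLE_PRESETS, apply_mechanism_toggles, iridophore_division,
    iridophore_form_update, melanophore_birth, melanophore_birth_condition,
    melanophore_death, random_loose_xanthophore_birth,
    xanthophore_division, xanthophore_form_update,
)
from stripesim.core_state import (
    ID, IL, M, SENTINEL, XD, XL, CounterRng, DomainState, RuleParams,
)

from conftest import make_population

Z = np.array([1000.0, 500.0])


def ring(n, dist, center=Z):
    """n points at an exact distance from center (spread over angles)."""
    ang = np.linspace(0.0, 2 * np.pi, n, endpoint=False) + 0.123
    return center + dist * np.column_stack([np.cos(ang), np.sin(ang)])


@pytest.fixture()
def rules():
    return RuleParams().validate()


@pytest.fixture()
def rng():
    return CounterRng(0)


class TestMelanophoreBirth:
    def test_promoted_birth(self, rules, domain):
        # annulus: Xd=10, Id=5, M=3 -> 15 > 3 + 3.5*3 = 13.5; local count 2 <= eta
        pop = make_population(Xd=ring(10, 230.0), Id=ring(5, 240.0),
                              M=np.vstack([ring(3, 220.0), ring(2, 50.0)]))
        promoted, _ = melanophore_birth_condition(pop, Z, rules, domain)
        assert promoted[0]

    def test_boundary_not_strict_enough(self, rules, domain):
        # annulus Xd+Id = 13, M = 3 -> 13 <= 13.5: no deterministic birth
        pop = make_population(Xd=ring(9, 230.0), Id=ring(4, 240.0),
                              M=ring(3, 220.0))
        promoted, _ = melanophore_birth_condition(pop, Z, rules, domain)
        assert not promoted[0]

    def test_overcrowding_vetoes(self, rules, domain):
        # strong annulus signal but local disk holds eta+1 cells
        pop = make_population(Xd=ring(10, 230.0), Id=ring(5, 240.0),
                              M=ring(int(rules.eta) + 1, 60.0))
        promoted, _ = melanophore_birth_condition(pop, Z, rules, domain)
        assert not promoted[0]

    def test_empty_neighborhood_rate(self, rules, domain, rng):
        # bare domain: every candidate is empty-eligible; births ~ p_empty
        pop = make_population()
        r = dataclasses.replace(rules, n_diff=20_000)
        dec = melanophore_birth(pop, r, domain, rng, day=25)
        n = dec.birth_positions(M).shape[0]
        assert 120 <= n <= 280  # ~1% of 20000

    def test_birth_scale_shrinks_candidate_set(self, rules, domain, rng):
        # reduced birth evaluates ceil(scale * n_diff) candidates; verified
        # against a manual evaluation of the rule on the same stream
        xs = np.arange(45.0, domain.length, 90.0)
        ys = np.arange(45.0, domain.height, 90.0)
        gx, gy = np.meshgrid(xs, ys)
        pop = make_population(Id=np.column_stack([gx.ravel(), gy.ravel()]))
        n_cand = int(np.ceil(0.15 * rules.n_diff))
        scaled = melanophore_birth(pop, rules, domain, rng, day=25,
                                   birth_scale=0.15)
        z = rng.uniforms(25, "m_birth_loc", n_cand, dim=2) \
            * np.array([domain.length, domain.height])
        promoted, empty = melanophore_birth_condition(pop, z, rules, domain)
        u = rng.uniforms(25, "m_birth_empty", n_cand)
        expect = z[promoted | (empty & (u < rules.p_empty))]
        assert np.array_equal(scaled.birth_positions(M), expect)
        assert 0 < expect.shape[0] <= n_cand


class TestDivision:
    def test_isolated_dense_xanthophore_divides(self, rules, domain, rng):
        pop = make_population(Xd=[Z])
        dec = xanthophore_division(pop, rules, domain, rng, day=30)
        daughters = dec.birth_positions(XD)
        assert daughters.shape == (1, 2)
        assert np.all(np.abs(daughters[0] - Z) <= 5.0)

    def test_crowded_loose_xanthophore_does_not(self, rules, domain, rng):
        pop = make_population(Xl=np.vstack([[Z], ring(int(rules.psi), 30.0)]))
        dec = xanthophore_division(pop, rules, domain, rng, day=30)
        assert dec.birth_positions(XL).shape[0] == 0

    def test_cap_is_inclusive(self, rules, domain, rng):
        # count including self exactly phi -> still divides
        pop = make_population(Xd=np.vstack([[Z], ring(int(rules.phi) - 1, 40.0)]))
        dec = xanthophore_division(pop, rules, domain, rng, day=30)
        assert dec.birth_positions(XD).shape[0] == int(rules.phi)

    def test_isolated_loose_iridophore_divides(self, rules, domain, rng):
        pop = make_population(Il=[Z])
        dec = iridophore_division(pop, rules, domain, rng, day=30)
        assert dec.birth_positions(IL).shape == (1, 2)

    def test_mixed_crowd_above_rho_blocks(self, rules, domain, rng):
        crowd = ring(int(rules.rho), 30.0)  # + self = rho + 1
        pop = make_population(Id=np.vstack([[Z], crowd[:5]]), Il=crowd[5:])
        dec = iridophore_division(pop, rules, domain, rng, day=30)
        got = [b for b in dec.births if np.any([np.allclose(p, Z) for p in b[1]])]
        counts = pop.n(ID) + pop.n(IL)
        assert counts == int(rules.rho) + 1
        assert not got  # the focal dense iridophore did not divide

    def test_iridophores_divide_where_xanthophores_cannot(self, rules, domain, rng):
        # equally crowded neighbourhoods: count in (phi, rho]
        k = int(rules.phi)  # crowd so count incl. self = phi + 1 <= rho
        x_pop = make_population(Xd=np.vstack([[Z], ring(k, 35.0)]))
        i_pop = make_population(Id=np.vstack([[Z], ring(k, 35.0)]))
        assert xanthophore_division(x_pop, rules, domain, rng, 30).births == []
        assert iridophore_division(i_pop, rules, domain, rng, 30).births != []

    def test_daughter_form_follows_parent(self, rules, domain, rng):
        pop = make_population(Xl=[Z], Id=[Z + 400.0])
        dec_x = xanthophore_division(pop, rules, domain, rng, day=30)
        dec_i = iridophore_division(pop, rules, domain, rng, day=30)
        assert dec_x.birth_positions(XL).shape[0] == 1
        assert dec_x.birth_positions(XD).shape[0] == 0
        assert dec_i.birth_positions(ID).shape[0] == 1
        assert dec_i.birth_positions(IL).shape[0] == 0


class TestRandomLooseXanthophoreBirth:
    def test_occupied_location_blocks(self, rules, domain, rng):
        # cover the whole domain densely with Xl: no births anywhere
        xs = np.arange(20.0, domain.length, 40.0)
        ys = np.arange(20.0, domain.height, 40.0)
        gx, gy = np.meshgrid(xs, ys)
        pop = make_population(Xl=np.column_stack([gx.ravel(), gy.ravel()]))
        dec = random_loose_xanthophore_birth(pop, rules, domain, rng, day=30)
        assert dec.birth_positions(XL).shape[0] == 0

    def test_empty_domain_births_everywhere(self, rules, domain, rng):
        pop = make_population(M=ring(5, 100.0))  # melanophores are irrelevant
        dec = random_loose_xanthophore_birth(pop, rules, domain, rng, day=30)
        assert dec.birth_positions(XL).shape[0] == rules.n_rand


class TestMelanophoreDeath:
    def test_short_range_competition_kills(self, rules, domain, rng):
        # disk(90): Xd = 6, M = 4 (incl. self): 6 > 1.25*4 = 5 -> death
        pop = make_population(M=np.vstack([[Z], ring(3, 60.0)]),
                              Xd=ring(6, 70.0))
        dec = melanophore_death(pop, rules, domain, rng, day=40)
        assert pop.ids(M)[0] in dec.death_ids(M)

    def test_short_range_boundary_survives(self, rules, domain, rng):
        # Xd = 5, M = 4: 5 > 5 is false -> survives
        pop = make_population(M=np.vstack([[Z], ring(3, 60.0)]),
                              Xd=ring(5, 70.0))
        dec = melanophore_death(pop, rules, domain, rng, day=40)
        assert pop.ids(M)[0] not in dec.death_ids(M)

    def test_loose_iridophores_protect(self, rules, domain, rng):
        # annulus M=8 >= 2*annulus Xd=4 but Il within 45 is 3 (not < nu=3):
        # the stochastic rule cannot fire however the coin lands
        p1 = dataclasses.replace(rules, p_death=1.0)
        pop = make_population(M=np.vstack([[Z], ring(8, 230.0)]),
                              Xd=ring(4, 240.0), Il=ring(3, 30.0))
        dec = melanophore_death(pop, p1, domain, rng, day=40)
        assert pop.ids(M)[0] not in dec.death_ids(M)

    def test_unprotected_long_range_death(self, rules, domain, rng):
        p1 = dataclasses.replace(rules, p_death=1.0)
        pop = make_population(M=np.vstack([[Z], ring(8, 230.0)]),
                              Xd=ring(4, 240.0), Il=ring(2, 30.0))
        dec = melanophore_death(pop, p1, domain, rng, day=40)
        assert pop.ids(M)[0] in dec.death_ids(M)


class TestXanthophoreForm:
    def test_dense_goes_loose(self, rules, domain, rng):
        # disk(75) Il = 6 > a + disk(45) Id = 2 + 3
        pop = make_population(Xd=[Z], Il=ring(6, 60.0), Id=ring(3, 40.0))
        dec = xanthophore_form_update(pop, rules, domain, rng, day=40)
        assert pop.ids(XD)[0] in dec.flip_ids(XD, XL)

    def test_loose_goes_dense_with_coin_heads(self, rules, domain, rng):
        # Id45=2, P=1, Xd75=3, Il45=1, M75=1: 2+3 > 1+1+1
        p_one = dataclasses.replace(rules, p=1.0)
        pop = make_population(Xl=[Z], Id=ring(2, 40.0), Xd=ring(3, 60.0),
                              Il=ring(1, 30.0), M=ring(1, 70.0))
        dec = xanthophore_form_update(pop, p_one, domain, rng, day=40)
        assert pop.ids(XL)[0] in dec.flip_ids(XL, XD)

    def test_loose_stays_with_coin_tails(self, rules, domain, rng):
        # same configuration, P=0: 2 > 3 is false
        p_zero = dataclasses.replace(rules, p=0.0)
        pop = make_population(Xl=[Z], Id=ring(2, 40.0), Xd=ring(3, 60.0),
                              Il=ring(1, 30.0), M=ring(1, 70.0))
        dec = xanthophore_form_update(pop, p_zero, domain, rng, day=40)
        assert pop.ids(XL)[0] not in dec.flip_ids(XL, XD)

    def test_isolated_loose_stays(self, rules, domain, rng):
        pop = make_population(Xl=[Z])
        dec = xanthophore_form_update(pop, rules, domain, rng, day=40)
        assert dec.flips == []

    def test_shady_reduction(self, rules, domain, rng):
        # without iridophores rule (1) cannot fire and rule (2) reduces to
        # P * Xd75 > b + M75, checked against hand evaluation
        p_one = dataclasses.replace(rules, p=1.0)
        pop = make_population(Xl=[Z], Xd=ring(3, 60.0), M=ring(1, 70.0))
        dec = xanthophore_form_update(pop, p_one, domain, rng, day=40)
        assert pop.ids(XL)[0] in dec.flip_ids(XL, XD)      # 3 > 1 + 1
        pop2 = make_population(Xl=[Z], Xd=ring(2, 60.0), M=ring(1, 70.0))
        dec2 = xanthophore_form_update(pop2, p_one, domain, rng, day=40)
        assert pop2.ids(XL)[0] not in dec2.flip_ids(XL, XD)  # 2 > 2 false
        pop3 = make_population(Xd=[Z], Xl=ring(4, 30.0))
        dec3 = xanthophore_form_update(pop3, rules, domain, rng, day=40)
        assert len(dec3.flip_ids(XD, XL)) == 0               # (1) never fires


class TestIridophoreForm:
    def test_loose_to_dense_via_sparse_annulus(self, rules, domain):
        # M90 = 2 < c and annulus Xd = 8 < d
        pop = make_population(Il=[Z], M=ring(2, 70.0), Xd=ring(8, 230.0))
        dec = iridophore_form_update(pop, rules, domain)
        assert pop.ids(IL)[0] in dec.flip_ids(IL, ID)

    def test_loose_to_dense_via_local_support(self, rules, domain):
        # M90 = 2 < c; annulus Xd = 9 (not < d) but local Xd = 4 > e
        pop = make_population(Il=[Z], M=ring(2, 70.0),
                              Xd=np.vstack([ring(9, 230.0), ring(4, 60.0)]))
        dec = iridophore_form_update(pop, rules, domain)
        assert pop.ids(IL)[0] in dec.flip_ids(IL, ID)

    def test_dense_to_loose_via_melanophores(self, rules, domain):
        pop = make_population(Id=[Z], M=ring(4, 70.0))  # 4 > f = 3
        dec = iridophore_form_update(pop, rules, domain)
        assert pop.ids(ID)[0] in dec.flip_ids(ID, IL)

    def test_dense_to_loose_via_distant_xanthophores(self, rules, domain):
        # annulus Xd = 6 > g and local Xd = 1 < h
        pop = make_population(Id=[Z],
                              Xd=np.vstack([ring(6, 230.0), ring(1, 60.0)]))
        dec = iridophore_form_update(pop, rules, domain)
        assert pop.ids(ID)[0] in dec.flip_ids(ID, IL)

    def test_local_xanthophores_block_distant_cue(self, rules, domain):
        # same but local Xd = 2 (not < h = 2): stays dense
        pop = make_population(Id=[Z],
                              Xd=np.vstack([ring(6, 230.0), ring(2, 60.0)]))
        dec = iridophore_form_update(pop, rules, domain)
        assert len(dec.flip_ids(ID, IL)) == 0

    def test_m_exactly_at_threshold_gives_no_pressure(self, rules, domain):
        # M90 = 3 satisfies neither "< c" nor "> f" (f = c = 3)
        pop = make_population(Il=[Z], Id=[Z + np.array([0.0, 300.0])],
                              M=np.vstack([ring(3, 70.0),
                                           ring(3, 70.0, Z + [0.0, 300.0])]),
                              Xd=ring(9, 230.0))
        dec = iridophore_form_update(pop, rules, domain)
        assert dec.flips == []

    def test_monotonicity_in_cues(self, rules, domain):
        # adding one local Xd can only make the distant-cue rule harder
        base = make_population(Id=[Z],
                               Xd=np.vstack([ring(6, 230.0), ring(1, 60.0)]))
        assert len(iridophore_form_update(base, rules, domain).flip_ids(ID, IL)) == 1
        more = make_population(Id=[Z],
                               Xd=np.vstack([ring(6, 230.0), ring(2, 60.0)]))
        assert len(iridophore_form_update(more, rules, domain).flip_ids(ID, IL)) == 0
        # adding melanophores can only make loose-to-dense harder
        ok = make_population(Il=[Z], M=ring(2, 70.0), Xd=ring(8, 230.0))
        assert len(iridophore_form_update(ok, rules, domain).flip_ids(IL, ID)) == 1
        blocked = make_population(Il=[Z], M=ring(3, 70.0), Xd=ring(8, 230.0))
        assert len(iridophore_form_update(blocked, rules, domain).flip_ids(IL, ID)) == 0


class TestClosureAndOrderIndependence:
    def test_only_allowed_decision_types(self, rules, domain, rng):
        gen = np.random.default_rng(2)
        pop = make_population(
            M=gen.random((20, 2)) * [domain.length, domain.height],
            Xd=gen.random((20, 2)) * [domain.length, domain.height],
            Xl=gen.random((20, 2)) * [domain.length, domain.height],
            Id=gen.random((20, 2)) * [domain.length, domain.height],
            Il=gen.random((20, 2)) * [domain.length, domain.height])
        decs = [
            melanophore_birth(pop, rules, domain, rng, 30),
            xanthophore_division(pop, rules, domain, rng, 30),
            iridophore_division(pop, rules, domain, rng, 30),
            random_loose_xanthophore_birth(pop, rules, domain, rng, 30),
            melanophore_death(pop, rules, domain, rng, 30),
            xanthophore_form_update(pop, rules, domain, rng, 30),
            iridophore_form_update(pop, rules, domain),
        ]
        for dec in decs:
            for cls, _ids in dec.deaths:
                assert cls == M        # only melanophores die
            for a, b, _ids in dec.flips:
                assert {a, b} in ({XD, XL}, {ID, IL})  # forms flip within type
        assert all(not d.flips for d in decs[:5])

    def test_decisions_invariant_under_permutation(self, rules, domain, rng):
        gen = np.random.default_rng(6)
        pop = make_population(
            M=gen.random((15, 2)) * [domain.length, domain.height],
            Xd=gen.random((15, 2)) * [domain.length, domain.height],
            Il=gen.random((15, 2)) * [domain.length, domain.height])
        shuffled = pop.permuted(np.random.default_rng(8))
        for fn in (lambda p: melanophore_death(p, rules, domain, rng, 33),
                   lambda p: iridophore_form_update(p, rules, domain),
                   lambda p: xanthophore_form_update(p, rules, domain, rng, 33)):
            a, b = fn(pop), fn(shuffled)
            for cls in (M,):
                assert set(a.death_ids(cls)) == set(b.death_ids(cls))
            assert set(a.flip_ids(IL, ID)) == set(b.flip_ids(IL, ID))
            assert set(a.flip_ids(XL, XD)) == set(b.flip_ids(XL, XD))


class TestMechanismToggles:
    def test_empty_toggle_set_unchanged(self, rules):
        assert apply_mechanism_toggles(rules, ()) == rules

    def test_unknown_preset_rejected(self, rules):
        with pytest.raises(ValueError):
            apply_mechanism_toggles(rules, ("no_such_fish",))

    def test_unknown_override_rejected(self, rules):
        with pytest.raises(ValueError):
            apply_mechanism_toggles(rules, (), overrides={"beta": 1.0})

    def test_albolineatus_disables_annulus_cue(self, rules, domain):
        # an Il with zero Xd anywhere would flip dense via the sparse-annulus
        # branch in the full network, but never under the reduced [At & Ct]
        togged = apply_mechanism_toggles(rules, ("albolineatus",))
        pop = make_population(Il=[Z])
        full = iridophore_form_update(pop, rules, domain)
        reduced = iridophore_form_update(pop, togged, domain)
        assert len(full.flip_ids(IL, ID)) == 1
        assert len(reduced.flip_ids(IL, ID)) == 0
        # local dense xanthophores still induce the transition
        pop2 = make_population(Il=[Z], Xd=ring(4, 60.0))
        assert len(iridophore_form_update(pop2, togged, domain).flip_ids(IL, ID)) == 1

    def test_margaritatus_ignores_local_xanthophores(self, rules, domain):
        # distant Xd > g flips dense iridophores loose regardless of local Xd
        togged = apply_mechanism_toggles(rules, ("margaritatus",))
        pop = make_population(Id=[Z],
                              Xd=np.vstack([ring(6, 230.0), ring(5, 60.0)]))
        assert len(iridophore_form_update(pop, rules, domain).flip_ids(ID, IL)) == 0
        assert len(iridophore_form_update(pop, togged, domain).flip_ids(ID, IL)) == 1

    def test_sentinels_are_extreme(self):
        for preset, changes in TOGGLE_PRESETS.items():
            for key, val in changes.items():
                assert abs(val) == SENTINEL, (preset, key)
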