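import numpy as np
import pytest

import lobulesim as ls
from lobulesim import agents as ag
from lobulesim.fields import DiffusibleField
from lobulesim.lattice import (
    COLLAGEN_MFB,
    COLLAGEN_PF,
    DEAD_APOPTOTIC,
    DEAD_NECROTIC,
    EMPTY,
    HEPATOCYTE,
)


@pytest.fixture
def params():
    return ls.default_config().agents


def fields_like(grid, **values):
    out = {}
    for name in ("CCl4", "HMGB1", "TNFa", "TGFb"):
        f = DiffusibleField(name, (grid.height, grid.width), 0.3, 0.1)
        if name in values:
            f.values += values[name]
        out[name] = f
    return out


class TestHepatocyteDeath:
    def test_survives_zero_fields(self, small_grid, params):
        zeros = np.zeros((21, 21))
        res = ag.hepatocyte_death_check((3, 3), zeros, zeros, small_grid.zonation, params)
        assert res is None

    def test_toxin_above_threshold_causes_necrosis(self, small_grid, params):
        ccl4 = np.zeros((21, 21))
        pos = next(iter(small_grid.central_vein_sites))  # zonation weight 1
        ccl4[pos] = params.theta_ccl4 + 0.01
        res = ag.hepatocyte_death_check(pos, ccl4, np.zeros((21, 21)),
                                        small_grid.zonation, params)
        assert res == DEAD_NECROTIC

    def test_tnf_above_threshold_causes_apoptosis(self, small_grid, params):
        tnfa = np.full((21, 21), params.theta_tnf_death + 0.01)
        res = ag.hepatocyte_death_check((3, 3), np.zeros((21, 21)), tnfa,
                                        small_grid.zonation, params)
        assert res == DEAD_APOPTOTIC

    def test_toxin_takes_precedence_over_tnf(self, small_grid, params):
        pos = next(iter(small_grid.central_vein_sites))
        big = np.full((21, 21), 1e6)
        res = ag.hepatocyte_death_check(pos, big, big, small_grid.zonation, params)
        assert res == DEAD_NECROTIC

    def test_vectorised_masks_match_single_site_rule(self, params, rng):
        cfg = ls.default_config(seed=4, height=31, width=31, portal_inset=0.15)
        grid, _ = ls.build_lobule(cfg)
        ccl4 = rng.uniform(0, 3.0, (31, 31))
        tnfa = rng.uniform(0, 3.0, (31, 31))
        necro, apo = ag.death_masks(grid, ccl4, tnfa, params)
        for r in range(31):
            for c in range(31):
                if grid.occupancy[r, c] != HEPATOCYTE:
                    assert not necro[r, c] and not apo[r, c]
                    continue
                ref = ag.hepatocyte_death_check((r, c), ccl4, tnfa, grid.zonation, params)
                assert necro[r, c] == (ref == DEAD_NECROTIC)
                assert apo[r, c] == (ref == DEAD_APOPTOTIC)


class TestProliferation:
    def test_no_vacancy_no_division(self, small_grid, params, rng):
        for pos in [(5, 5)] + list(small_grid.moore_neighbors((5, 5))):
            small_grid.place(pos, HEPATOCYTE)
        assert ag.hepatocyte_proliferate(small_grid, (5, 5), rng, params) is None

    def test_division_fills_the_single_vacancy(self, small_grid, params, rng):
        small_grid.place((5, 5), HEPATOCYTE)
        for q in small_grid.moore_neighbors((5, 5)):
            if tuple(q) != (4, 4):
                small_grid.place(q, HEPATOCYTE)
        child = ag.hepatocyte_proliferate(small_grid, (5, 5), rng, params)
        assert tuple(child) == (4, 4)
        assert small_grid.occupancy[4, 4] == HEPATOCYTE
        assert small_grid.hep_cooldown[5, 5] == params.replication_cooldown

    def test_collagen_rich_neighbourhood_blocks_division(self, small_grid, params, rng):
        params.collagen_rich_threshold = 3
        small_grid.place((5, 5), HEPATOCYTE)
        for q in list(small_grid.moore_neighbors((5, 5)))[:3]:
            small_grid.place(q, COLLAGEN_MFB)
        assert ag.hepatocyte_proliferate(small_grid, (5, 5), rng, params) is None

    def test_cooldown_blocks_division(self, small_grid, params, rng):
        small_grid.place((5, 5), HEPATOCYTE)
        small_grid.hep_cooldown[5, 5] = 2
        assert ag.hepatocyte_proliferate(small_grid, (5, 5), rng, params) is None


class TestKupffer:
    def test_quiescent_stays_quiescent_without_stimulus(self, small_grid, params, rng):
        kc = ag.KupfferCell(10, 10)
        f = fields_like(small_grid)
        ag.kupffer_step(kc, small_grid, f["HMGB1"].values, f["TNFa"], f["TGFb"], rng, params)
        assert kc.state == ag.QUIESCENT
        assert f["TNFa"].total() == 0 and f["TGFb"].total() == 0

    def test_phagocytosis_clears_dead_cell_and_activates(self, small_grid, params, rng):
        # dead cells on the entire neighbourhood: wherever the cell moves it
        # lands on one
        for pos in small_grid.moore_neighbors((5, 10)):
            small_grid.place(pos, DEAD_NECROTIC)
        kc = ag.KupfferCell(5, 10)
        f = fields_like(small_grid)
        ag.kupffer_step(kc, small_grid, f["HMGB1"].values, f["TNFa"], f["TGFb"], rng, params)
        assert kc.state == ag.M1
        assert small_grid.occupancy[kc.row, kc.col] == EMPTY
        assert f["TNFa"].total() == pytest.approx(params.tnf_secretion)

    def test_hmgb1_above_threshold_activates(self, small_grid, params, rng):
        kc = ag.KupfferCell(10, 10)
        f = fields_like(small_grid, HMGB1=params.theta_hmgb1 + 1.0)
        ag.kupffer_step(kc, small_grid, f["HMGB1"].values, f["TNFa"], f["TGFb"], rng, params)
        assert kc.state == ag.M1

    def test_m1_switches_to_m2_after_tau_and_secretes_tgf(self, small_grid, params, rng):
        kc = ag.KupfferCell(10, 10, state=ag.M1,
                            steps_since_activation=params.tau_m1m2 - 1)
        f = fields_like(small_grid)
        ag.kupffer_step(kc, small_grid, f["HMGB1"].values, f["TNFa"], f["TGFb"], rng, params)
        assert kc.state == ag.M2
        assert f["TGFb"].total() == pytest.approx(params.tgf_secretion)
        assert f["TNFa"].total() == 0.0

    def test_replenish_rate_zero_and_one(self, small_grid, params, rng):
        pop = ag.Population([], [], [], [])
        for _ in range(10):
            ag.kupffer_replenish(small_grid, pop, 0.0, rng)
        assert pop.kupffer == []
        for _ in range(10):
            ag.kupffer_replenish(small_grid, pop, 1.0, rng)
        assert len(pop.kupffer) == 10 * len(small_grid.portal_tracts)
        tract_sites = set(small_grid.portal_tract_sites)
        assert all((k.row, k.col) in tract_sites for k in pop.kupffer)

    def test_replenish_binomial_mean(self, small_grid, rng):
        pop = ag.Population([], [], [], [])
        geo_tracts = len(small_grid.portal_tracts)
        for _ in range(1000):
            ag.kupffer_replenish(small_grid, pop, 0.5, rng)
        mean = len(pop.kupffer) / geo_tracts
        assert 450 <= mean <= 550  # 500 +- binomial noise


class TestStellateAndFibroblasts:
    def test_no_activation_without_tnf(self, params):
        hsc = ag.HSC(3, 3)
        assert ag.hsc_activation(hsc, np.zeros((21, 21)), params) is None

    def test_activation_replaces_in_place(self, params):
        hsc = ag.HSC(3, 3)
        tnfa = np.full((21, 21), params.theta_tnf_hsc + 0.01)
        mfb = ag.hsc_activation(hsc, tnfa, params)
        assert isinstance(mfb, ag.Myofibroblast)
        assert (mfb.row, mfb.col) == (3, 3) and mfb.age == 0

    def test_no_deposit_without_tgf(self, small_grid, params, rng):
        mfb = ag.Myofibroblast(5, 5)
        assert not ag.fibroblast_secrete(mfb, small_grid, np.zeros((21, 21)), rng, params)
        assert mfb.collagens_produced == 0

    def test_myofibroblast_deposits_origin_tagged_collagen(self, small_grid, params, rng):
        mfb = ag.Myofibroblast(5, 5)
        tgf = np.full((21, 21), params.theta_tgf + 1.0)
        assert ag.fibroblast_secrete(mfb, small_grid, tgf, rng, params)
        assert small_grid.occupancy[5, 5] == COLLAGEN_MFB  # own site was vacant
        assert mfb.collagens_produced == 1

    def test_portal_fibroblast_persists_and_tags_collagen(self, small_grid, params, rng):
        pf = ag.PortalFibroblast(5, 5)
        tgf = np.full((21, 21), params.theta_tgf + 1.0)
        assert ag.fibroblast_secrete(pf, small_grid, tgf, rng, params)
        assert small_grid.occupancy[5, 5] == COLLAGEN_PF

    def test_deposit_goes_to_nearest_vacant_site(self, small_grid, params, rng):
        small_grid.place((5, 5), HEPATOCYTE)
        for q in small_grid.moore_neighbors((5, 5)):
            if tuple(q) not in [(4, 4)]:
                small_grid.place(q, HEPATOCYTE)
        mfb = ag.Myofibroblast(5, 5)
        tgf = np.full((21, 21), params.theta_tgf + 1.0)
        # only the diagonal (4,4) is vacant
        assert ag.fibroblast_secrete(mfb, small_grid, tgf, rng, params)
        assert small_grid.occupancy[4, 4] == COLLAGEN_MFB

    def test_no_vacancy_skips_production(self, small_grid, params, rng):
        for pos in [(5, 5)] + list(small_grid.moore_neighbors((5, 5))):
            small_grid.place(pos, HEPATOCYTE)
        mfb = ag.Myofibroblast(5, 5)
        tgf = np.full((21, 21), params.theta_tgf + 1.0)
        assert not ag.fibroblast_secrete(mfb, small_grid, tgf, rng, params)
        assert mfb.collagens_produced == 0


class TestAgeAndCull:
    def test_infinite_lifespans_cull_nothing(self, small_grid, params):
        params.kupffer_lifespan = None
        params.hsc_lifespan = None
        pop = ag.Population([ag.KupfferCell(1, 1)], [ag.HSC(2, 2)], [], [])
        for _ in range(50):
            ag.age_and_cull(small_grid, pop, params)
        assert len(pop.kupffer) == 1 and len(pop.hscs) == 1
        assert pop.kupffer[0].age == 50

    def test_agent_absent_once_age_reaches_lifespan(self, small_grid, params):
        params.hsc_lifespan = 5
        pop = ag.Population([], [ag.HSC(2, 2)], [], [])
        for step in range(1, 6):
            ag.age_and_cull(small_grid, pop, params)
            assert bool(pop.hscs) == (step < 5)

    def test_cohort_step_function(self, small_grid, params):
        params.kupffer_lifespan = 7
        pop = ag.Population([ag.KupfferCell(1, 1) for _ in range(20)], [], [], [])
        counts = []
        for _ in range(10):
            ag.age_and_cull(small_grid, pop, params)
            counts.append(len(pop.kupffer))
        assert counts == [20] * 6 + [0] * 4

    def test_dead_cells_cull_to_blank(self, small_grid, params):
        params.dead_cell_lifespan = 3
        small_grid.place((4, 4), DEAD_NECROTIC)
        pop = ag.Population([], [], [], [])
        for _ in range(3):
            assert small_grid.occupancy[4, 4] == DEAD_NECROTIC
            ag.age_and_cull(small_grid, pop, params)
        assert small_grid.occupancy[4, 4] == EMPTY


class TestRunLevelInvariants:
    @pytest.fixture(scope="class")
    def run_result(self):
        return ls.run(ls.default_config(seed=11, n_steps=60))

    def test_sessile_cells_never_move(self):
        cfg = ls.default_config(seed=12, n_steps=40)
        state = ls.initialize(cfg)
        hsc0 = {id(h): (h.row, h.col) for h in state.population.hscs}
        for _ in range(40):
            ls.step(state)
        for h in state.population.hscs:
            assert (h.row, h.col) == hsc0[id(h)]
        # every myofibroblast sits where some stellate cell started
        hsc_sites = set(hsc0.values())
        for m in state.population.myofibroblasts:
            assert (m.row, m.col) in hsc_sites

    def test_myofibroblasts_bounded_by_initial_stellate_pool(self, run_result):
        tc = run_result.timecourse
        hsc0 = tc["hsc"].iloc[0]
        assert (tc["hsc"].diff().dropna() <= 0).all()  # no stellate source
        assert (tc["myofibroblasts"] <= hsc0 - tc["hsc"] + 0).all()

    def test_collagen_counts_non_decreasing(self, run_result):
        tc = run_result.timecourse
        assert (tc["collagen_mfb"].diff().dropna() >= 0).all()
        assert (tc["collagen_pf"].diff().dropna() >= 0).all()

    def test_no_hmgb1_without_necrosis(self):
        # infinite necrosis threshold: toxin kills nothing, so no DAMP release
        cfg = ls.default_config(seed=5, n_steps=60, theta_ccl4=9e9)
        state = ls.initialize(cfg)
        for _ in range(60):
            ls.step(state)
        assert state.hmgb1_deposited == 0.0
        assert state.fields["HMGB1"].total() == 0.0
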