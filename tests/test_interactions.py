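"""The six interaction rules and supporting molecular events."""

import numpy as np
import pytest

from melimm.entities import CellAgent, CellState, CellType
from melimm.interactions import (
    InteractionParams,
    gate_is_open,
    il2_factor,
    kill_probability,
    rule_b_th,
    rule_cd137_boost,
    rule_dc_capture,
    rule_duplicate,
    rule_ic_form,
    rule_infiltration_gate,
    rule_m_capture,
    rule_m_th,
    rule_tc_kill,
    rule_tc_prime,
)
from melimm.repertoire import complement

OVA = 0xAAA
ANTI_OVA = complement(OVA)


def _presenting(ctype, peptide=OVA, state=CellState.PRESENTING_MHC2, site=0):
    receptor = ANTI_OVA if ctype is CellType.B else None
    return CellAgent(ctype, state=state, site=site, receptor=receptor, presented_peptide=peptide)


def _th(receptor, site=0):
    return CellAgent(CellType.TH, state=CellState.NAIVE, receptor=receptor, site=site)


class TestHelperRules:
    def test_b_th_perfect_match_always_fires(self, inter, affinity, rng):
        il2 = np.zeros(4, dtype=np.int64)
        b = _presenting(CellType.B)
        th = _th(ANTI_OVA)
        events = rule_b_th(b, th, inter, affinity, rng, il2)
        assert {e.kind for e in events} == {"B_TH", "IL2_SECRETE"}
        assert th.state is CellState.DUPLICATING and th.dup_timer == inter.TH_dup
        assert b.state is CellState.DUPLICATING and b.dup_timer == inter.B_dup
        assert il2[0] == inter.il2_secretion_th

    def test_b_th_below_min_match_never_fires(self, inter, affinity, rng):
        il2 = np.zeros(4, dtype=np.int64)
        weak = ANTI_OVA ^ 0b11110  # 8 matching bits
        for _ in range(300):
            b = _presenting(CellType.B)
            assert rule_b_th(b, _th(weak), inter, affinity, rng, il2) == []
        assert il2[0] == 0

    def test_b_th_spawns_plasma_daughter_within_dup_window(self, inter, affinity, rng):
        il2 = np.zeros(1, dtype=np.int64)
        b = _presenting(CellType.B)
        rule_b_th(b, _th(ANTI_OVA), inter, affinity, rng, il2)
        daughter = None
        for _ in range(inter.B_dup + 1):
            il2[0] = 20  # saturating IL-2 at the site
            d = rule_duplicate(b, 1, float(il2[0]), inter, affinity, rng)
            if d is not None:
                daughter = d
                break
        assert daughter is not None
        assert daughter.type is CellType.P
        assert daughter.state is CellState.PLASMA_SECRETING

    def test_m_th_stimulates_helper_without_plasma_side(self, inter, affinity, rng):
        il2 = np.zeros(2, dtype=np.int64)
        m = _presenting(CellType.M, site=1)
        th = _th(ANTI_OVA, site=1)
        events = rule_m_th(m, th, inter, affinity, rng, il2)
        assert {e.kind for e in events} == {"M_TH", "IL2_SECRETE"}
        assert th.state is CellState.DUPLICATING
        assert m.state is CellState.PRESENTING_MHC2  # macrophage unchanged
        assert il2[1] > 0

    def test_m_th_requires_presented_peptide(self, inter, affinity, rng):
        il2 = np.zeros(1, dtype=np.int64)
        m = CellAgent(CellType.M, state=CellState.PRESENTING_MHC2)
        assert rule_m_th(m, _th(ANTI_OVA), inter, affinity, rng, il2) == []


class TestCaptureRules:
    def test_dc_capture_empirical_rate(self, inter, rng):
        hits = 0
        n = 100_000
        for _ in range(n):
            ag = {OVA: np.array([3], dtype=np.int64)}
            dc = CellAgent(CellType.CDC)
            if rule_dc_capture(dc, ag, inter, rng):
                hits += 1
                assert dc.state is CellState.PRESENTING_MHC1_AND_2
                assert dc.presented_peptide == OVA
                assert ag[OVA][0] == 2  # one quantum consumed
        sd = np.sqrt(n * 0.02 * 0.98)
        assert abs(hits - n * 0.02) < 3 * sd

    def test_dc_no_antigen_no_event(self, inter, rng):
        dc = CellAgent(CellType.CDC)
        assert rule_dc_capture(dc, {}, inter, rng) == []
        assert dc.state is CellState.NAIVE

    @pytest.mark.parametrize("route, prob", [("antigen", 1e-2), ("ic", 1e-1)])
    def test_macrophage_routes_present_mhc2_only(self, inter, rng, route, prob):
        hits = 0
        n = 30_000
        for _ in range(n):
            store = {OVA: np.array([1], dtype=np.int64)}
            m = CellAgent(CellType.M)
            ev = rule_m_capture(
                m,
                store if route == "antigen" else None,
                store if route == "ic" else None,
                inter,
                rng,
            )
            if ev:
                hits += 1
                assert m.state is CellState.PRESENTING_MHC2
        sd = np.sqrt(n * prob * (1 - prob))
        assert abs(hits - n * prob) < 3 * sd


class TestPriming:
    def test_ot1_primed_by_ova_presenting_dc(self, affinity, rng):
        dc = _presenting(CellType.CDC, state=CellState.PRESENTING_MHC1_AND_2)
        tc = CellAgent(CellType.TC, receptor=ANTI_OVA, is_ot1=True)
        assert rule_tc_prime(tc, dc, affinity, rng)
        assert tc.state is CellState.ACTIVE
        assert tc.is_activated_ot1

    def test_active_tc_not_reprimed(self, affinity, rng):
        dc = _presenting(CellType.CDC, state=CellState.PRESENTING_MHC1_AND_2)
        tc = CellAgent(CellType.TC, state=CellState.ACTIVE, receptor=ANTI_OVA)
        assert rule_tc_prime(tc, dc, affinity, rng) == []

    def test_weak_match_stays_naive(self, affinity, rng):
        dc = _presenting(CellType.CDC, state=CellState.PRESENTING_MHC1_AND_2)
        weak = ANTI_OVA ^ 0b11110
        for _ in range(300):
            tc = CellAgent(CellType.TC, receptor=weak)
            rule_tc_prime(tc, dc, affinity, rng)
            assert tc.state is CellState.NAIVE


class TestKillRule:
    def test_boost_strictly_increases_kill_probability(self, inter, affinity):
        tc = CellAgent(CellType.TC, state=CellState.ACTIVE, receptor=ANTI_OVA)
        p_plain = kill_probability(tc, OVA, 10.0, inter, affinity)
        tc.cd137_boosted = True
        p_boost = kill_probability(tc, OVA, 10.0, inter, affinity)
        assert 0 < p_plain < p_boost <= 1.0

    def test_naive_tc_never_kills(self, inter, affinity, rng):
        tc = CellAgent(CellType.TC, state=CellState.NAIVE, receptor=ANTI_OVA)
        tumor = CellAgent(CellType.TUMOR, receptor=OVA)
        for _ in range(200):
            assert rule_tc_kill(tc, tumor, 10.0, inter, affinity, rng) == []
        assert tumor.state is not CellState.DEAD

    def test_weak_match_never_kills(self, inter, affinity):
        tc = CellAgent(CellType.TC, state=CellState.ACTIVE, receptor=ANTI_OVA ^ 0b11110)
        assert kill_probability(tc, OVA, 10.0, inter, affinity) == 0.0

    def test_kill_requires_il2(self, inter, affinity):
        tc = CellAgent(CellType.TC, state=CellState.ACTIVE, receptor=ANTI_OVA)
        assert kill_probability(tc, OVA, 0.0, inter, affinity) == 0.0

    def test_successful_kill_marks_tumor_dead(self, inter, affinity, rng):
        tc = CellAgent(CellType.TC, state=CellState.ACTIVE, receptor=ANTI_OVA, cd137_boosted=True)
        killed = 0
        for _ in range(200):
            tumor = CellAgent(CellType.TUMOR, receptor=OVA)
            ev = rule_tc_kill(tc, tumor, 50.0, inter, affinity, rng)
            if ev:
                killed += 1
                assert tumor.state is CellState.DEAD
        assert killed > 0


class TestBoostRule:
    def test_active_tc_boosted_and_quantum_consumed(self, rng):
        tc = CellAgent(CellType.TC, state=CellState.ACTIVE, receptor=ANTI_OVA)
        used, ev = rule_cd137_boost(tc, 1, rng)
        assert used == 1 and tc.cd137_boosted
        assert ev[0].kind == "CD137_BOOST"

    def test_naive_tc_unchanged(self, rng):
        tc = CellAgent(CellType.TC, state=CellState.NAIVE, receptor=ANTI_OVA)
        used, ev = rule_cd137_boost(tc, 1, rng)
        assert used == 0 and not tc.cd137_boosted and ev == []

    def test_boost_shortens_time_to_first_daughter(self, inter, affinity):
        # duplication multiplier: boosted cells divide sooner on average
        def mean_first_division(boosted, n=400):
            times = []
            r = np.random.default_rng(0)
            for _ in range(n):
                tc = CellAgent(
                    CellType.TC, state=CellState.DUPLICATING, receptor=ANTI_OVA, cd137_boosted=boosted
                )
                tc.prev_state = CellState.ACTIVE
                tc.dup_timer = inter.TC_dup
                for t in range(inter.TC_dup):
                    if rule_duplicate(tc, 20, 2.0, inter, affinity, r) is not None:
                        times.append(t)
                        break
                else:
                    times.append(inter.TC_dup)
            return np.mean(times)

        assert mean_first_division(True) < mean_first_division(False)


class TestImmuneComplexes:
    def test_perfect_match_converts_all_pairs(self, affinity, rng):
        igg = np.array([5, 0, 2], dtype=np.int64)
        ag = np.array([3, 1, 2], dtype=np.int64)
        formed = rule_ic_form(igg, ag, ANTI_OVA, OVA, affinity, rng)
        assert (formed == [3, 0, 2]).all()
        assert (igg == [2, 0, 0]).all()
        assert (ag == [0, 1, 0]).all()

    def test_mass_balance(self, affinity, rng):
        igg = rng.integers(0, 10, size=50)
        ag = rng.integers(0, 10, size=50)
        igg0, ag0 = igg.sum(), ag.sum()
        formed = rule_ic_form(igg, ag, ANTI_OVA ^ 0b1, OVA, affinity, rng)
        assert igg0 - igg.sum() == formed.sum()
        assert ag0 - ag.sum() == formed.sum()


class TestInfiltrationGate:
    def test_open_requires_wt_mab_and_low_burden(self, inter):
        assert gate_is_open(True, True, 1e5, inter)
        assert not gate_is_open(False, True, 1e5, inter)  # endothelial KO
        assert not gate_is_open(True, False, 1e5, inter)  # no antibody
        assert not gate_is_open(True, True, 5e5, inter)  # established tumor

    def test_entry_probabilities_ordered(self, inter, rng):
        n = 20_000
        wt = sum(rule_infiltration_gate(True, inter, rng) for _ in range(n))
        ko = sum(rule_infiltration_gate(False, inter, rng) for _ in range(n))
        assert abs(wt / n - inter.infiltration_prob_wt) < 0.02
        assert abs(ko / n - inter.infiltration_prob_ko) < 0.01
        assert wt > ko


class TestDuplication:
    def test_timer_expires_after_configured_steps(self, inter, affinity, rng):
        th = CellAgent(CellType.TH, state=CellState.DUPLICATING, receptor=1)
        th.prev_state = CellState.ACTIVE
        th.dup_timer = inter.TH_dup
        for _ in range(inter.TH_dup):
            assert th.state is CellState.DUPLICATING
            rule_duplicate(th, 50, 0.0, inter, affinity, rng)
        assert th.state is CellState.ACTIVE

    def test_crowding_clamp_with_saturating_il2(self, inter, affinity):
        # one same-type cell, saturating IL-2: division probability clamps to ~IL2_eff
        r = np.random.default_rng(3)
        divisions = 0
        n = 300
        for _ in range(n):
            tc = CellAgent(CellType.TC, state=CellState.DUPLICATING, receptor=1)
            tc.prev_state = CellState.ACTIVE
            tc.dup_timer = 1
            if rule_duplicate(tc, 1, 1e6, inter, affinity, r) is not None:
                divisions += 1
        assert divisions / n > 0.95

    def test_no_il2_no_lymphocyte_division(self, inter, affinity, rng):
        tc = CellAgent(CellType.TC, state=CellState.DUPLICATING, receptor=1)
        tc.prev_state = CellState.ACTIVE
        tc.dup_timer = 5
        assert rule_duplicate(tc, 1, 0.0, inter, affinity, rng) is None

    def test_il2_eff_zero_blocks_division(self, affinity, rng):
        p = InteractionParams(IL2_eff=0.0)
        assert il2_factor(100.0, p) == 0.0
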