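"""Engine: determinism, audits, scheduling, observables, stopping rules."""

import numpy as np
import pandas as pd
import pytest

from melimm import ScenarioConfig, Simulation, run_experiment, run_replicate
from melimm.engine import STEPS_PER_DAY, Arm, Outcome, intratumoral_tc_count
from melimm.entities import CellAgent, CellState, CellType

from conftest import tiny_config


class TestDeterminism:
    def test_same_config_and_seed_bit_identical(self):
        cfg = tiny_config(arm=Arm.OT1_ACTIVE_PLUS_CD137, duration_days=8, seed=11)
        r1 = run_replicate(cfg)
        r2 = run_replicate(cfg)
        pd.testing.assert_frame_equal(r1.timeseries, r2.timeseries)
        assert r1.outcome == r2.outcome

    def test_different_seeds_differ(self):
        cfg = tiny_config(arm=Arm.OT1_ACTIVE_PLUS_CD137, duration_days=8)
        r1 = run_replicate(cfg, seed=1)
        r2 = run_replicate(cfg, seed=2)
        assert not r1.timeseries.equals(r2.timeseries)


class TestControlArm:
    def test_control_never_rejects_and_area_monotone(self):
        res = run_replicate(tiny_config(duration_days=20, seed=3))
        assert res.outcome is not Outcome.REJECTED
        area = res.timeseries["tumor_area_mm2"].to_numpy()
        assert (np.diff(area) >= 0).all()

    def test_day_horizon_bounds_timeseries(self):
        res = run_replicate(tiny_config(duration_days=33, seed=4))
        assert len(res.timeseries) <= 33 * STEPS_PER_DAY + 1
        assert res.timeseries["day"].iloc[-1] <= 33


class TestTreatmentScheduling:
    def test_day8_payload_lands_at_step_24(self):
        cfg = tiny_config(arm=Arm.ANTI_CD137, treatment_day=8, duration_days=10, seed=5)
        ts = run_replicate(cfg).timeseries
        assert ts.loc[ts["step"] == 23, "mab_pool"].iloc[0] == 0
        assert ts.loc[ts["step"] == 24, "mab_pool"].iloc[0] > 0

    def test_control_arm_no_payload(self):
        ts = run_replicate(tiny_config(duration_days=5, seed=6)).timeseries
        assert (ts["mab_pool"] == 0).all()
        assert (ts["circulating_tc"] == 0).all()

    def test_naive_plus_mab_delivers_both_payloads_naive(self):
        cfg = tiny_config(arm=Arm.OT1_NAIVE_PLUS_CD137, duration_days=4, seed=6)
        sim = Simulation(cfg, cfg.seed)
        res = sim.run()
        ts = res.timeseries
        after = ts[ts["step"] >= cfg.treatment_step]
        assert (after["mab_pool"] > 0).any()
        ot1 = [a for a in sim.cells[CellType.TC] if a.is_ot1] + sim.circulating
        assert ot1
        assert all(not a.is_activated_ot1 for a in ot1)


class TestCensusAudit:
    def test_population_balance_identity_every_step(self):
        # census(t+1) = census(t) + births(+divisions) - deaths, per type
        cfg = tiny_config(duration_days=8, seed=9, audit=True)
        ts = run_replicate(cfg).timeseries
        for t in ("B", "TH", "TC", "M", "cDC", "NK", "P"):
            total = ts[f"{t}_total"].to_numpy()
            births = ts[f"births_{t}"].to_numpy()
            deaths = ts[f"deaths_{t}"].to_numpy()
            assert (total[1:] == total[:-1] + births[1:] - deaths[1:]).all()

    def test_tumor_cell_conservation(self):
        # x0 + newborns - natural deaths - kills == final census (control: no kills)
        cfg = tiny_config(duration_days=12, seed=10, audit=True)
        sim = Simulation(cfg, cfg.seed)
        res = sim.run()
        ts = res.timeseries
        x0 = ts["tumor_cells"].iloc[0]
        balance = (
            x0
            + ts["newborns_cum"].iloc[-1]
            - ts["kills_cum"].iloc[-1]
            - ts["deaths_TUMOR"].sum()
        )
        assert balance == ts["tumor_cells"].iloc[-1]
        assert int(sim.tumor_counts.sum()) == ts["tumor_cells"].iloc[-1]


class TestHomeostasisInEngine:
    def test_resting_censuses_hover_at_targets(self):
        cfg = tiny_config(duration_days=30, seed=12)
        sim = Simulation(cfg, cfg.seed)
        res = sim.run()
        ts = res.timeseries
        for t in (CellType.B, CellType.TH, CellType.TC, CellType.M):
            target = sim.targets[t]
            mean = ts[f"{t.value}_total"].mean()
            assert abs(mean - target) / target < 0.05


class TestSiteLocality:
    def test_interactions_require_colocation(self, rng):
        # a presenting B and a perfectly matching TH on *different* sites never
        # interact within a step; co-located they do
        from melimm.repertoire import complement

        cfg = tiny_config(duration_days=1, seed=1)
        sim = Simulation(cfg, 1)
        for t in CellType:
            sim.cells[t] = []
        ova = cfg.ova_peptide
        b = CellAgent(CellType.B, state=CellState.PRESENTING_MHC2, site=50, presented_peptide=ova)
        th = CellAgent(CellType.TH, receptor=complement(ova), site=51)
        sim.cells[CellType.B] = [b]
        sim.cells[CellType.TH] = [th]
        by_site, tc = sim._build_occupancy()
        sim._phase_interactions(by_site, tc)
        assert th.state is CellState.NAIVE  # no action at a distance
        th.site = b.site
        by_site, tc = sim._build_occupancy()
        sim._phase_interactions(by_site, tc)
        assert th.state is CellState.DUPLICATING

    def test_mobile_agents_never_leave_lattice(self):
        cfg = tiny_config(duration_days=6, seed=13)
        sim = Simulation(cfg, cfg.seed)
        sim.run()
        n = sim.lattice.n_sites
        for t in CellType:
            for a in sim.cells[t]:
                assert 0 <= a.site < n


class TestIntratumoralCount:
    def test_no_tcs_counts_zero(self):
        cfg = tiny_config(duration_days=1, seed=2)
        sim = Simulation(cfg, 2)
        sim.cells[CellType.TC] = []
        assert intratumoral_tc_count(sim) == 0

    def test_all_tcs_on_tumor_equals_census(self):
        cfg = tiny_config(duration_days=1, seed=2)
        sim = Simulation(cfg, 2)
        site = int(np.flatnonzero(sim.tumor_counts)[0])
        for a in sim.cells[CellType.TC]:
            a.site = site
        assert intratumoral_tc_count(sim, mode="current") == len(sim.cells[CellType.TC])


class TestRunExperiment:
    def test_single_rep_equals_replicate(self):
        cfg = tiny_config(duration_days=6, seed=21)
        s = run_experiment(cfg, 1)
        single = run_replicate(cfg, cfg.seed)
        daily = single.timeseries[single.timeseries["step"] % STEPS_PER_DAY == 0]
        np.testing.assert_allclose(
            s["mean_area"][: len(daily)], daily["tumor_area_mm2"].to_numpy()
        )
        assert s["n_reps"] == 1

    def test_means_bounded_by_replicate_extremes(self):
        cfg = tiny_config(duration_days=6, seed=22)
        s = run_experiment(cfg, 3)
        areas = []
        for k in range(3):
            r = run_replicate(cfg, cfg.seed + k)
            daily = r.timeseries[r.timeseries["step"] % STEPS_PER_DAY == 0]
            areas.append(daily["tumor_area_mm2"].to_numpy())
        areas = np.vstack(areas)
        mean = np.asarray(s["mean_area"])[: areas.shape[1]]
        assert (mean <= areas.max(axis=0) + 1e-9).all()
        assert (mean >= areas.min(axis=0) - 1e-9).all()


class TestConfigValidation:
    def test_invalid_treatment_day(self):
        with pytest.raises(ValueError):
            ScenarioConfig(treatment_day=5)

    def test_invalid_entry_mode(self):
        with pytest.raises(ValueError):
            ScenarioConfig(entry_mode="teleport")
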