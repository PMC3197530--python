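"""The simulation engine: timestep loop, treatment arms, replicates.

One timestep is 8 hours (3 steps per day); a run covers at most 33 days
(99 steps) after tumor injection.  Each step executes a fixed 9-phase
sequence — (1) Gompertz newborn seeding, (2) molecular decay and diffusion,
(3) stochastic agent death, (4) site-local interactions, (5) duplication,
(6) movement with chemotaxis and the endothelial infiltration gate,
(7) bone-marrow homeostasis, (8) scheduled treatment, (9) observables — with
every random draw taken from one per-replicate generator, so a (config,
seed) pair reproduces bit-identically.

Treatment arms
--------------
CONTROL                 no treatment (rat IgG is inert)
ANTI_CD137              100 µg agonist anti-CD137 mAb i.p.
OT1_NAIVE               2e6 naive OT-1 CD8 T cells i.v.
OT1_NAIVE_PLUS_CD137    both, cohort naive
OT1_ACTIVE              2e6 antigen-activated OT-1 cells i.v.
OT1_ACTIVE_PLUS_CD137   both, cohort activated

given on day 3 or day 8 post-injection, in wild-type mice or in a virtual
knockout lacking CD137 on tumor endothelium.

Doses and densities are quoted at full lattice scale (L = 946 for a
60 mm x 60 mm section) and are rescaled by lattice area for reduced runs;
the Gompertz growth constant is shifted by b*ln(area_scale) so the reduced
tumor follows the same relative trajectory.
"""

from __future__ import annotations

import heapq
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .entities import (
    MOBILE_TYPES,
    CellAgent,
    CellState,
    CellType,
    MoleculeFields,
    PopulationParams,
    apply_homeostasis,
    decay_probability,
    initialize_populations,
    make_ot1_cohort,
)
from .interactions import (
    InteractionEvent,
    InteractionParams,
    gate_is_open,
    il2_factor,
    kill_probability,
    rule_b_capture,
    rule_b_th,
    rule_cd137_boost,
    rule_dc_capture,
    rule_duplicate,
    rule_ic_form,
    rule_m_capture,
    rule_m_th,
    rule_tc_prime,
)
from .lattice import ChemotaxisParams, HexLattice, diffuse_field, placement_iv, placement_tumor_seed
from .repertoire import AffinityParams, sample_repertoire
from .tumor_growth import (
    GompertzParams,
    TumorState,
    area_from_cells,
    euler_newborns,
    seed_initial_tumor,
)

__all__ = [
    "Arm",
    "Outcome",
    "ScenarioConfig",
    "SimulationResult",
    "Simulation",
    "run_replicate",
    "run_experiment",
    "intratumoral_tc_count",
]

STEPS_PER_DAY = 3  # 8-hour timestep


class Arm(str, Enum):
    CONTROL = "CONTROL"
    ANTI_CD137 = "ANTI_CD137"
    OT1_NAIVE = "OT1_NAIVE"
    OT1_NAIVE_PLUS_CD137 = "OT1_NAIVE_PLUS_CD137"
    OT1_ACTIVE = "OT1_ACTIVE"
    OT1_ACTIVE_PLUS_CD137 = "OT1_ACTIVE_PLUS_CD137"

    @property
    def gives_mab(self) -> bool:
        return self in (Arm.ANTI_CD137, Arm.OT1_NAIVE_PLUS_CD137, Arm.OT1_ACTIVE_PLUS_CD137)

    @property
    def gives_ot1(self) -> bool:
        return self in (Arm.OT1_NAIVE, Arm.OT1_NAIVE_PLUS_CD137, Arm.OT1_ACTIVE, Arm.OT1_ACTIVE_PLUS_CD137)

    @property
    def ot1_activated(self) -> bool:
        return self in (Arm.OT1_ACTIVE, Arm.OT1_ACTIVE_PLUS_CD137)


class Outcome(str, Enum):
    REJECTED = "REJECTED"
    SACRIFICED = "SACRIFICED"
    SURVIVED_TO_END = "SURVIVED_TO_END"


# Default Gompertz constants, per 8-h step at full scale: calibrated so the
# untreated tumor (x0 = 2e5) crosses the 450 mm^2 sacrifice threshold near
# day 29 (carrying capacity exp(a/b) ~ 1.33e6 cells ~ 531 mm^2).
DEFAULT_GOMPERTZ = GompertzParams(a=0.39477, b=0.028)


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of one in silico experiment."""

    arm: Arm = Arm.CONTROL
    treatment_day: int = 3
    cd137_on_endothelium: bool = True  # False = endothelial CD137 knockout
    duration_days: int = 33
    timestep_hours: float = 8.0
    lattice_L: int = 200
    seed: int = 0
    n_reps: int = 10

    # doses and tumor inoculum (full-scale / in vivo values)
    dose_ot1: float = 2e6
    dose_mab_ug: float = 100.0
    injected_tumor_cells: float = 5e5
    tumor_death_fraction: float = 0.6
    sacrifice_area_mm2: float = 450.0

    # tumor geometry
    cell_diameter_um: float = 20.0
    tumor_capacity: int = 8

    # delivery: "vessels" = circulating pool extravasating at endothelium
    # (CD137 gate at tumor-proximal vessels); "walls" = deposition on the
    # rigid wall rows.
    entry_mode: str = "vessels"
    ot1_tissue_fraction: float = 0.04  # share of an i.v. dose trafficking the section
    mab_quanta_per_ug: float = 4000.0
    tissue_extravasation_prob: float = 0.05  # per step, circulating -> random vessel

    ova_peptide: int = 0xAAA  # tumor antigen epitope bit-string
    self_peptide_count: int = 6
    scale_with_area: bool = True
    il2_diffusion_fraction: float = 0.2

    snapshot_days: Tuple[int, ...] = ()
    log_events: bool = False
    audit: bool = False

    gompertz: GompertzParams = DEFAULT_GOMPERTZ
    affinity: AffinityParams = field(default_factory=AffinityParams)
    population: PopulationParams = field(default_factory=PopulationParams)
    interaction: InteractionParams = field(default_factory=InteractionParams)
    chemotaxis: ChemotaxisParams = field(default_factory=ChemotaxisParams)

    def __post_init__(self) -> None:
        if self.treatment_day not in (3, 8):
            raise ValueError("treatment_day must be 3 or 8")
        if self.duration_days <= 0:
            raise ValueError("duration_days must be > 0")
        if self.timestep_hours != 8.0:
            raise ValueError("the model is parameterised for an 8-hour timestep")
        if self.entry_mode not in ("vessels", "walls"):
            raise ValueError("entry_mode must be 'vessels' or 'walls'")
        if not (0 <= self.ova_peptide < (1 << self.affinity.nbit_str)):
            raise ValueError("ova_peptide out of receptor range")
        if self.tumor_capacity <= 0:
            raise ValueError("tumor_capacity must be > 0")

    @property
    def n_steps(self) -> int:
        return self.duration_days * STEPS_PER_DAY

    @property
    def treatment_step(self) -> int:
        return self.treatment_day * STEPS_PER_DAY


@dataclass
class SimulationResult:
    """Per-timestep observables plus the terminal outcome of one replicate."""

    timeseries: pd.DataFrame
    outcome: Outcome
    outcome_day: float
    seed: int
    config: ScenarioConfig
    snapshots: Dict[int, Dict[str, np.ndarray]] = field(default_factory=dict)
    events: List[InteractionEvent] = field(default_factory=list)

    @property
    def rejected(self) -> bool:
        return self.outcome is Outcome.REJECTED

    def rejection_day_by_area(self, fraction_of_peak: float = 0.01) -> Optional[float]:
        """First day tumor area falls below ``fraction_of_peak`` of its running peak.

        This is the "almost totally rejected" reading of the area curve;
        strict rejection (zero cells) implies it.  None if never reached.
        """
        area = self.timeseries["tumor_area_mm2"].to_numpy()
        days = self.timeseries["day"].to_numpy()
        peak = np.maximum.accumulate(area)
        below = np.flatnonzero((area < fraction_of_peak * peak) & (peak > 0))
        if below.size == 0:
            return None
        return float(days[below[0]])


_DT_DAYS = 8.0 / 24.0

_SENSITIVE_TYPES = {CellType.TC, CellType.TH, CellType.M, CellType.CDC}


class Simulation:
    """One replicate: mutable world state plus the 9-phase step loop."""

    def __init__(self, config: ScenarioConfig, seed: int):
        self.config = config
        self.seed = int(seed)
        self.rng = np.random.default_rng(np.random.SeedSequence(self.seed))
        self.lattice = HexLattice(config.lattice_L)
        self.area_scale = self.lattice.area_scale if config.scale_with_area else 1.0
        self._center_rc = self.lattice.center
        L = self.lattice.L
        _rows = np.arange(self.lattice.n_sites) // L
        _cols = np.arange(self.lattice.n_sites) % L
        _cx = _cols + 0.5 * (_rows % 2)
        _cy = _rows * (math.sqrt(3.0) / 2.0)
        _c0x = self._center_rc[1] + 0.5 * (self._center_rc[0] % 2)
        _c0y = self._center_rc[0] * (math.sqrt(3.0) / 2.0)
        self._dist2 = (_cx - _c0x) ** 2 + (_cy - _c0y) ** 2

        aff = config.affinity
        pop = config.population
        inter = config.interaction

        self.self_peptides = sample_repertoire(config.self_peptide_count, aff.nbit_str, self.rng)
        self.pop_scale = pop.density_scale * self.area_scale
        self.targets = pop.target_counts(self.pop_scale)

        # endothelium first: its sites are the vessel layout
        n_ep = self.targets.get(CellType.EP, 0)
        self.ep_sites = np.sort(self.rng.integers(0, self.lattice.n_sites, size=n_ep))
        agents = initialize_populations(
            pop, self.lattice.n_sites, self.pop_scale, aff, self.self_peptides, self.rng,
            ep_sites=[int(s) for s in self.ep_sites],
        )
        self.cells: Dict[CellType, List[CellAgent]] = {t: [] for t in CellType}
        for a in agents:
            self.cells[a.type].append(a)
        self.circulating: List[CellAgent] = []

        # tumor: per-site counts (cells are immobile, identical, anonymous)
        x0 = seed_initial_tumor(round(config.injected_tumor_cells * self.area_scale), config.tumor_death_fraction)
        self.tumor = TumorState(x_t=float(x0))
        self.tumor_counts = self.lattice.new_field(np.int32)
        self.tumor_footprint = np.zeros(self.lattice.n_sites, dtype=bool)
        self._open_heap: List[Tuple[float, int]] = []
        self._in_heap: set[int] = set()
        self._seed_tumor(x0)

        # effective (scale-shifted) growth constants: x_scaled = s * x obeys
        # dx/dt = x (a + b ln s - b ln x)
        g = config.gompertz
        a_eff = g.a + g.b * math.log(self.area_scale) if self.area_scale != 1.0 and g.b > 0 else g.a
        self.gompertz_eff = GompertzParams(a=a_eff, b=g.b)

        self.fields = MoleculeFields.empty(self.lattice.n_sites)
        self.mab_pool = 0

        # decay probabilities per step
        self.p_die_cell = decay_probability(pop.cell_half_life_days, _DT_DAYS)
        self.p_die_tumor = decay_probability(pop.tumor_half_life_days, _DT_DAYS)
        self.p_decay = {
            "il2": decay_probability(pop.il2_half_life_days, _DT_DAYS),
            "ca": decay_probability(pop.ca_half_life_days, _DT_DAYS),
            "igg": decay_probability(pop.igg_half_life_days, _DT_DAYS),
            "ic": decay_probability(pop.ic_half_life_days, _DT_DAYS),
            "mab": decay_probability(pop.anti_cd137_half_life_days, _DT_DAYS),
        }

        self.inter = inter
        self.aff = aff
        self.burden_limit = inter.infiltration_burden_limit * self.area_scale
        self.sacrifice_area = config.sacrifice_area_mm2 * self.area_scale
        self.kills_total = 0
        self.newborns_total = 0
        self.events: List[InteractionEvent] = []
        self.rows: List[dict] = []
        self.snapshots: Dict[int, Dict[str, np.ndarray]] = {}
        self.t = 0
        self._gate_open = False
        self._audit_prev: Optional[Counter] = None

    # ------------------------------------------------------------------ setup
    def _seed_tumor(self, x0: int) -> None:
        """Fill a compact central patch at site capacity."""
        cap = self.config.tumor_capacity
        sites = placement_tumor_seed(self.lattice, x0, cap)
        remaining = x0
        for s in sites:
            add = min(cap, remaining)
            self.tumor_counts[s] = add
            self.tumor_footprint[s] = True
            remaining -= add
            if remaining == 0:
                break
        self._rebuild_open_heap()

    def _rebuild_open_heap(self) -> None:
        self._open_heap = []
        self._in_heap = set()
        occ = self.tumor_counts > 0
        cap = self.config.tumor_capacity
        # candidate sites: occupied-with-room, or empty neighbours of occupied
        for s in np.flatnonzero(occ):
            s = int(s)
            if self.tumor_counts[s] < cap:
                self._push_open(s)
            for j in self.lattice.neighbor_table[s]:
                j = int(j)
                if j >= 0 and self.tumor_counts[j] < cap:
                    self._push_open(j)

    def _push_open(self, site: int) -> None:
        if site not in self._in_heap:
            self._in_heap.add(site)
            heapq.heappush(self._open_heap, (float(self._dist2[site]), site))

    def _place_newborns(self, w: int) -> None:
        """Place w newborn tumor cells adjacent to existing tumor, innermost first."""
        cap = self.config.tumor_capacity
        placed = 0
        while placed < w:
            if not self._open_heap:
                self._rebuild_open_heap()
                if not self._open_heap:
                    # no tumor left to grow from (rejection edge); drop remainder
                    self.tumor.x_t -= (w - placed)
                    return
            _, s = heapq.heappop(self._open_heap)
            self._in_heap.discard(s)
            room = cap - int(self.tumor_counts[s])
            if room <= 0:
                continue
            add = min(room, w - placed)
            self.tumor_counts[s] += add
            self.tumor_footprint[s] = True
            placed += add
            if add == room:  # site filled: open its neighbours
                for j in self.lattice.neighbor_table[s]:
                    j = int(j)
                    if j >= 0 and self.tumor_counts[j] < cap:
                        self._push_open(j)
            else:
                self._push_open(s)
        self.newborns_total += w

    def _remove_tumor_cell(self, site: int) -> None:
        if self.tumor_counts[site] <= 0:
            return
        self.tumor_counts[site] -= 1
        self.tumor.x_t -= 1
        ag = self.fields.tagged(self.fields.antigen, self.config.ova_peptide)
        ag[site] += self.inter.antigen_per_death
        self._push_open(site)

    # ------------------------------------------------------------------ phases
    def _phase_tumor_growth(self) -> None:
        w = euler_newborns(self.tumor, self.gompertz_eff, dt=1.0)
        if w > 0:
            self._place_newborns(w)

    def _phase_molecules(self) -> None:
        f, rng = self.fields, self.rng
        f.il2 = rng.binomial(f.il2, 1.0 - self.p_decay["il2"])
        f.ca = rng.binomial(f.ca, 1.0 - self.p_decay["ca"])
        if self.mab_pool > 0:
            self.mab_pool = int(rng.binomial(self.mab_pool, 1.0 - self.p_decay["mab"]))
        for store, key in ((f.igg, "igg"), (f.ic, "ic"), (f.antigen, "igg")):
            dead = []
            for r, arr in store.items():
                store[r] = rng.binomial(arr, 1.0 - self.p_decay[key])
                if store[r].sum() == 0:
                    dead.append(r)
            for r in dead:
                del store[r]
        cfg = self.config
        if cfg.chemotaxis.ca_diffusion_fraction > 0:
            f.ca = diffuse_field(f.ca, self.lattice, cfg.chemotaxis.ca_diffusion_fraction, rng)
        if cfg.il2_diffusion_fraction > 0:
            f.il2 = diffuse_field(f.il2, self.lattice, cfg.il2_diffusion_fraction, rng)

    def _decay_list(self, agents: List[CellAgent], p: float) -> Tuple[List[CellAgent], int]:
        if not agents:
            return agents, 0
        keep = self.rng.random(len(agents)) >= p
        survivors = [a for a, k in zip(agents, keep) if k]
        return survivors, len(agents) - len(survivors)

    def _phase_agent_decay(self) -> Counter:
        deaths: Counter = Counter()
        for t in CellType:
            if t is CellType.TUMOR:
                continue
            self.cells[t], d = self._decay_list(self.cells[t], self.p_die_cell)
            deaths[t] += d
        self.circulating, d = self._decay_list(self.circulating, self.p_die_cell)
        deaths[CellType.TC] += d
        # tumor natural death (effectively immortal: half-life 10 years)
        x = int(self.tumor.x_t)
        if x > 0 and self.p_die_tumor > 0:
            n_die = int(self.rng.binomial(x, self.p_die_tumor))
            if n_die:
                occ = np.flatnonzero(self.tumor_counts > 0)
                for s in self.rng.choice(occ, size=min(n_die, occ.size), replace=True):
                    s = int(s)
                    if self.tumor_counts[s] > 0:
                        self._remove_tumor_cell(s)
                        deaths[CellType.TUMOR] += 1
        return deaths

    def _build_occupancy(self):
        by_site: Dict[int, List[CellAgent]] = {}
        type_counts: Dict[CellType, Counter] = {t: Counter() for t in CellType}
        for t in (CellType.B, CellType.TH, CellType.TC, CellType.CDC, CellType.M):
            cnt = type_counts[t]
            for a in self.cells[t]:
                by_site.setdefault(a.site, []).append(a)
                cnt[a.site] += 1
        return by_site, type_counts

    def _phase_interactions(self, by_site, type_counts) -> None:
        f, inter, aff, rng = self.fields, self.inter, self.aff, self.rng
        log = self.config.log_events
        ova = self.config.ova_peptide

        # plasma IgG release
        for p in self.cells[CellType.P]:
            if p.state is CellState.PLASMA_SECRETING:
                f.tagged(f.igg, p.receptor)[p.site] += inter.plasma_rel_quanta

        # antigen shedding from the living tumor mass
        x = int(self.tumor.x_t)
        if x > 0 and inter.antigen_shed_prob > 0:
            n_shed = int(rng.binomial(x, inter.antigen_shed_prob))
            if n_shed:
                occ = np.flatnonzero(self.tumor_counts > 0)
                ag = f.tagged(f.antigen, ova)
                for s in rng.choice(occ, size=n_shed, replace=True):
                    ag[int(s)] += 1

        # chemoattractant sources: tumor-proximal endothelium, presenting
        # macrophages, activated OT-1 cells (handled in the TC loop below)
        occ_mask = self.tumor_counts > 0
        if occ_mask.any():
            ep = self.ep_sites
            near = occ_mask[ep].copy()
            for k in range(6):
                nb = self.lattice.neighbor_table[ep, k]
                valid = nb >= 0
                near[valid] |= occ_mask[nb[valid]]
            if near.any():
                np.add.at(f.ca, ep[near], inter.ca_secretion)

        ag_store = f.antigen if f.antigen else None
        ic_store = f.ic if f.ic else None

        # systemic anti-CD137 exposure of activated TCs
        if self.mab_pool > 0:
            p_expose = min(1.0, self.mab_pool * inter.mab_exposure_eff)
            for tc in self.cells[CellType.TC]:
                if self.mab_pool <= 0:
                    break
                if tc.cd137_boosted or tc.state not in (CellState.ACTIVE, CellState.DUPLICATING):
                    continue
                if rng.random() < p_expose:
                    used, ev = rule_cd137_boost(tc, 1, rng)
                    self.mab_pool -= used
                    if log and ev:
                        self.events.extend(ev)

        # site-local cellular interactions
        for site, group in by_site.items():
            has_ag = ag_store is not None and any(arr[site] > 0 for arr in ag_store.values())
            has_ic = ic_store is not None and any(arr[site] > 0 for arr in ic_store.values())
            tumor_here = occ_mask[site]
            if len(group) == 1 and not (has_ag or has_ic or tumor_here):
                a = group[0]
                if not (a.type is CellType.TC and a.state is CellState.ACTIVE):
                    continue
            th_list = [a for a in group if a.type is CellType.TH]
            for a in group:
                at = a.type
                if at is CellType.CDC:
                    if has_ag and a.state in (CellState.NAIVE, CellState.ACTIVE):
                        ev = rule_dc_capture(a, ag_store, inter, rng)
                        if log:
                            self.events.extend(ev)
                elif at is CellType.M:
                    if (has_ag or has_ic) and a.state is not CellState.PRESENTING_MHC2:
                        ev = rule_m_capture(a, ag_store, ic_store, inter, rng)
                        if log:
                            self.events.extend(ev)
                    if a.state is CellState.PRESENTING_MHC2:
                        f.ca[site] += inter.ca_secretion  # activated macrophage
                        if th_list:
                            th = th_list[int(rng.integers(0, len(th_list)))]
                            ev = rule_m_th(a, th, inter, aff, rng, f.il2)
                            if log:
                                self.events.extend(ev)
                elif at is CellType.B:
                    if has_ag and a.state is CellState.NAIVE:
                        ev = rule_b_capture(a, ag_store, aff, rng)
                        if log:
                            self.events.extend(ev)
                    if a.state is CellState.PRESENTING_MHC2 and th_list:
                        th = th_list[int(rng.integers(0, len(th_list)))]
                        ev = rule_b_th(a, th, inter, aff, rng, f.il2)
                        if log:
                            self.events.extend(ev)
                elif at is CellType.TC:
                    if a.state is CellState.NAIVE:
                        for dc in group:
                            if dc.type is CellType.CDC and dc.state is CellState.PRESENTING_MHC1_AND_2:
                                ev = rule_tc_prime(a, dc, aff, rng)
                                if log:
                                    self.events.extend(ev)
                                break
                    if a.state is CellState.ACTIVE or (
                        a.state is CellState.DUPLICATING and a.prev_state is CellState.ACTIVE
                    ):
                        # effector IL-2 secretion (autocrine)
                        f.il2[site] += inter.il2_secretion_tc
                        if self.tumor_counts[site] > 0:
                            # engaged activated OT-1 release chemoattractant,
                            # recruiting further effectors to the tumor
                            if a.is_ot1:
                                f.ca[site] += inter.ca_secretion
                            p = kill_probability(a, ova, float(f.il2[site]), inter, aff)
                            if p > 0:
                                for _ in range(inter.kill_attempts_per_step):
                                    if self.tumor_counts[site] <= 0:
                                        break
                                    if rng.random() < p:
                                        self._remove_tumor_cell(site)
                                        self.kills_total += 1
                                        if log:
                                            self.events.append(
                                                InteractionEvent("TC_KILL", site, ("TC", "TUMOR"))
                                            )
                            # antigen-driven clonal expansion
                            if a.state is CellState.ACTIVE and rng.random() < inter.dup_trigger_prob:
                                a.prev_state = CellState.ACTIVE
                                a.state = CellState.DUPLICATING
                                a.dup_timer = inter.TC_dup

        # immune-complex formation (specificity-tagged mass balance)
        if f.igg and f.antigen:
            for r_igg, igg_arr in list(f.igg.items()):
                for epi, ag_arr in list(f.antigen.items()):
                    formed = rule_ic_form(igg_arr, ag_arr, r_igg, epi, aff, rng)
                    if formed.any():
                        f.tagged(f.ic, r_igg)[:] += formed

    def _phase_duplication(self, type_counts) -> Counter:
        births: Counter = Counter()
        inter, aff, rng = self.inter, self.aff, self.rng
        new_agents: List[CellAgent] = []
        for t in (CellType.B, CellType.TH, CellType.TC):
            cnt = type_counts[t]
            for a in self.cells[t]:
                if a.state is not CellState.DUPLICATING:
                    continue
                d = rule_duplicate(a, cnt.get(a.site, 1), float(self.fields.il2[a.site]), inter, aff, rng)
                if d is not None:
                    new_agents.append(d)
                    births[d.type] += 1
        for d in new_agents:
            self.cells[d.type].append(d)
        return births

    def _phase_movement(self) -> None:
        cfg, rng = self.config, self.rng
        ntable = self.lattice.neighbor_table
        ca = self.fields.ca
        chem = cfg.chemotaxis
        tumor_occ = self.tumor_counts > 0
        p_gate = (
            self.inter.infiltration_prob_wt if self._gate_open else self.inter.infiltration_prob_ko
        )

        for t in CellType:  # fixed order: set iteration is hash-dependent
            if t not in MOBILE_TYPES:
                continue
            agents = self.cells[t]
            if not agents:
                continue
            pos = np.fromiter((a.site for a in agents), dtype=np.int64, count=len(agents))
            cand = np.concatenate([pos[:, None], ntable[pos]], axis=1)  # (n, 7)
            valid = cand >= 0
            safe = np.where(valid, cand, 0)
            if t in _SENSITIVE_TYPES and chem.base_sensitivity > 0:
                if t is CellType.TC:
                    sens = np.fromiter(
                        (
                            chem.base_sensitivity * (chem.cd137_sensitivity_boost if a.cd137_boosted else 1.0)
                            for a in agents
                        ),
                        dtype=float,
                        count=len(agents),
                    )[:, None]
                else:
                    sens = chem.base_sensitivity
                w = np.where(valid, 1.0 + sens * ca[safe], 0.0)
            else:
                w = valid.astype(float)
            cum = np.cumsum(w, axis=1)
            u = rng.random(len(agents)) * cum[:, -1]
            idx = (cum < u[:, None]).sum(axis=1)
            dest = cand[np.arange(len(agents)), idx]
            if t is CellType.TC:
                entering = tumor_occ[dest] & ~tumor_occ[pos]
                if entering.any():
                    blocked = entering & (rng.random(len(agents)) >= p_gate)
                    dest = np.where(blocked, pos, dest)
                if self.inter.tc_arrest_on_tumor:
                    # conjugated effectors stay on their target site
                    effector = np.fromiter(
                        (
                            a.state is CellState.ACTIVE
                            or (a.state is CellState.DUPLICATING and a.prev_state is CellState.ACTIVE)
                            for a in agents
                        ),
                        dtype=bool,
                        count=len(agents),
                    )
                    arrested = effector & tumor_occ[pos]
                    dest = np.where(arrested, pos, dest)
            for a, s in zip(agents, dest):
                a.site = int(s)

        # circulating i.v. cells: extravasation through the vasculature
        if self.circulating:
            self._phase_extravasation(p_gate)

    def _phase_extravasation(self, p_gate: float) -> None:
        """Circulating transferred cells leave the blood.

        Each step a circulating TC extravasates at tumor-proximal endothelium
        with the gate probability (this is where CD137 ligation acts), or
        into random tissue at the background rate, or keeps circulating.
        """
        rng = self.rng
        cfg = self.config
        occ = np.flatnonzero(self.tumor_counts > 0)
        still: List[CellAgent] = []
        u = rng.random(len(self.circulating))
        p_bg = cfg.tissue_extravasation_prob
        for a, ui in zip(self.circulating, u):
            if occ.size > 0 and ui < p_gate:
                s = int(occ[int(rng.integers(0, occ.size))])
                nbrs = [int(j) for j in self.lattice.neighbor_table[s] if j >= 0]
                a.site = nbrs[int(rng.integers(0, len(nbrs)))] if nbrs else s
                self.cells[CellType.TC].append(a)
            elif ui < p_gate + p_bg:
                if cfg.entry_mode == "walls" or self.ep_sites.size == 0:
                    a.site = placement_iv(self.lattice, 1, rng)[0]
                else:
                    a.site = int(self.ep_sites[int(rng.integers(0, self.ep_sites.size))])
                self.cells[CellType.TC].append(a)
            else:
                still.append(a)
        self.circulating = still

    def _phase_homeostasis(self) -> Counter:
        pop = self.config.population
        census = {
            t: sum(1 for a in self.cells[t] if not a.is_ot1)
            for t in self.targets
        }
        births = apply_homeostasis(
            census, self.targets, pop, self.lattice.n_sites, self.aff, self.self_peptides, self.rng
        )
        for a in births:
            self.cells[a.type].append(a)
        out: Counter = Counter()
        for a in births:
            out[a.type] += 1
        return out

    def _phase_treatment(self) -> None:
        """Deliver the arm's payloads (public alias: :func:`apply_treatment`)."""
        cfg = self.config
        arm = cfg.arm
        if arm.gives_mab:
            self.mab_pool += round(cfg.dose_mab_ug * cfg.mab_quanta_per_ug * self.area_scale)
        if arm.gives_ot1:
            n = round(cfg.dose_ot1 * cfg.ot1_tissue_fraction * self.area_scale)
            cohort = make_ot1_cohort(n, arm.ot1_activated, cfg.ova_peptide, self.aff, self.rng)
            if cfg.entry_mode == "vessels":
                self.circulating.extend(cohort)
            else:
                sites = placement_iv(self.lattice, n, self.rng)
                for a, s in zip(cohort, sites):
                    a.site = s
                    self.cells[CellType.TC].append(a)

    def _record_row(self, deaths: Counter, births: Counter) -> None:
        x = int(round(self.tumor.x_t))
        row = {
            "step": self.t,
            "day": self.t / STEPS_PER_DAY,
            "tumor_cells": x,
            "tumor_area_mm2": area_from_cells(x, self.config.cell_diameter_um),
            "intratumoral_tc": intratumoral_tc_count(self),
            "mab_pool": self.mab_pool,
            "circulating_tc": len(self.circulating),
            "kills_cum": self.kills_total,
            "newborns_cum": self.newborns_total,
            "gate_open": int(self._gate_open),
        }
        counts: Counter = Counter()
        for t in CellType:
            for a in self.cells[t]:
                counts[(t.value, a.state.value)] += 1
        for (tv, sv), n in counts.items():
            row[f"{tv}_{sv}"] = n
        for t in CellType:
            if t is CellType.TUMOR:
                continue
            row[f"{t.value}_total"] = len(self.cells[t])
        if self.config.audit:
            for t in CellType:
                row[f"births_{t.value}"] = births.get(t, 0)
                row[f"deaths_{t.value}"] = deaths.get(t, 0)
        self.rows.append(row)

    # ------------------------------------------------------------------ loop
    def step(self) -> None:
        self.t += 1
        cfg = self.config
        self._gate_open = gate_is_open(
            cfg.cd137_on_endothelium,
            self.mab_pool > 0,
            float(self.tumor.x_t),
            self.inter,
            burden_limit_cells=self.burden_limit,
        )
        self._phase_tumor_growth()
        self._phase_molecules()
        deaths = self._phase_agent_decay()
        by_site, type_counts = self._build_occupancy()
        self._phase_interactions(by_site, type_counts)
        births = self._phase_duplication(type_counts)
        self._phase_movement()
        births += self._phase_homeostasis()
        if self.t == cfg.treatment_step:
            self._phase_treatment()
        self._record_row(deaths, births)
        if cfg.snapshot_days and self.t % STEPS_PER_DAY == 0:
            day = self.t // STEPS_PER_DAY
            if day in cfg.snapshot_days:
                self._take_snapshot(day)

    def _take_snapshot(self, day: int) -> None:
        L = self.lattice.L
        tc_grid = np.zeros(self.lattice.n_sites, dtype=np.int32)
        for a in self.cells[CellType.TC]:
            tc_grid[a.site] += 1
        self.snapshots[day] = {
            "tumor": self.tumor_counts.reshape(L, L).copy(),
            "tc": tc_grid.reshape(L, L),
        }

    def run(self) -> SimulationResult:
        cfg = self.config
        self._record_row(Counter(), Counter())  # initial state, step 0
        outcome = Outcome.SURVIVED_TO_END
        out_day = float(cfg.duration_days)
        while self.t < cfg.n_steps:
            self.step()
            x = self.tumor.x_t
            if x <= 0:
                outcome, out_day = Outcome.REJECTED, self.t / STEPS_PER_DAY
                break
            if area_from_cells(x, cfg.cell_diameter_um) >= self.sacrifice_area:
                outcome, out_day = Outcome.SACRIFICED, self.t / STEPS_PER_DAY
                break
        ts = pd.DataFrame(self.rows).fillna(0)
        return SimulationResult(
            timeseries=ts,
            outcome=outcome,
            outcome_day=out_day,
            seed=self.seed,
            config=cfg,
            snapshots=self.snapshots,
            events=self.events,
        )


def apply_treatment(sim: Simulation) -> None:
    """Place the scenario's treatment payloads into the running simulation.

    Anti-CD137 arms add the (area-scaled) antibody bolus to the systemic
    pool; OT-1 arms create the transfer cohort, activated or naive per arm,
    delivered through the circulation ("vessels" mode) or onto the wall rows
    ("walls" mode).  Control arms place nothing active (rat IgG is inert).
    """
    sim._phase_treatment()


def intratumoral_tc_count(sim: Simulation, mode: str = "footprint") -> int:
    """TC agents inside the tumor: on currently occupied sites, or anywhere
    on the tumor's historical footprint (default, so infiltration remains
    measurable while the tumor is being destroyed)."""
    mask = sim.tumor_footprint if mode == "footprint" else (sim.tumor_counts > 0)
    return sum(1 for a in sim.cells[CellType.TC] if mask[a.site])


def run_replicate(config: ScenarioConfig, seed: Optional[int] = None) -> SimulationResult:
    """Run one fully seeded replicate of a scenario."""
    return Simulation(config, config.seed if seed is None else seed).run()


def run_experiment(config: ScenarioConfig, n_reps: Optional[int] = None) -> dict:
    """Run ``n_reps`` replicates (seeds base_seed + k) and summarise.

    Returns per-day mean and sd of tumor area (areas carried forward after an
    early outcome so replicate curves align), the rejection-day list, and the
    outcome tally.
    """
    n = config.n_reps if n_reps is None else int(n_reps)
    if n < 1:
        raise ValueError("n_reps must be >= 1")
    results = [run_replicate(config, config.seed + k) for k in range(n)]
    n_days = config.duration_days
    areas = np.zeros((n, n_days + 1))
    for i, res in enumerate(results):
        ts = res.timeseries
        daily = ts[ts["step"] % STEPS_PER_DAY == 0]
        vals = daily["tumor_area_mm2"].to_numpy()
        areas[i, : len(vals)] = vals
        if len(vals) < n_days + 1:
            areas[i, len(vals):] = 0.0 if res.outcome is Outcome.REJECTED else vals[-1]
    tally = Counter(r.outcome.value for r in results)
    rejection_days = [r.outcome_day for r in results if r.outcome is Outcome.REJECTED]
    return {
        "arm": config.arm.value,
        "treatment_day": config.treatment_day,
        "cd137_on_endothelium": config.cd137_on_endothelium,
        "n_reps": n,
        "days": list(range(n_days + 1)),
        "mean_area": areas.mean(axis=0).tolist(),
        "sd_area": areas.std(axis=0).tolist(),
        "outcomes": dict(tally),
        "rejection_days": rejection_days,
        "results": results,
    }
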