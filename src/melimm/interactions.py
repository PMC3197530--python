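"""Site-local stochastic interaction rules.

All interactions happen between entities co-located on one lattice site
within one 8-hour step.  The cellular rules implemented here:

1.  B (presenting on MHC-II) + TH  -> TH proliferates and secretes IL-2;
    B proliferates and its daughters differentiate into plasma cells.
2.  M (presenting on MHC-II) + TH  -> TH proliferates and secretes IL-2.
3.  cDC + tumor antigen            -> cross-presentation on MHC-I and MHC-II.
4.  naive TC + presenting cDC      -> TC is primed (activated).
5.  activated TC + tumor cell      -> kill, requiring IL-2 and amplified by
    anti-CD137.
6.  anti-CD137 + activated TC      -> boosted cytotoxicity, duplication rate
    and chemotaxis sensitivity.

Supporting molecular events: macrophage capture of antigen and immune
complexes, B-cell antigen capture through the BCR, plasma IgG release,
immune-complex formation, and the CD137-dependent endothelial infiltration
gate that controls T-cell entry into tumor-occupied tissue.

The kill rule reads "in presence of IL-2 and anti-CD137": IL-2 enters as a
saturating availability factor (required) while anti-CD137 enters as a
multiplier on an activated cell's baseline cytotoxicity — a strict
conjunction would erase the partial effect that activated OT-1 cells alone
have on tumor area.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, NamedTuple, Optional, Tuple

import numpy as np

from .entities import CellAgent, CellState, CellType
from .repertoire import AffinityParams, bind_probability, hypermutate, match_bits

__all__ = [
    "InteractionParams",
    "InteractionEvent",
    "il2_factor",
    "rule_b_th",
    "rule_m_th",
    "rule_dc_capture",
    "rule_m_capture",
    "rule_b_capture",
    "rule_tc_prime",
    "rule_tc_kill",
    "rule_cd137_boost",
    "rule_ic_form",
    "gate_is_open",
    "rule_infiltration_gate",
    "rule_duplicate",
]


@dataclass(frozen=True)
class InteractionParams:
    """Interaction probabilities and effect sizes.

    The first block is fixed from the tuning table (per 8-hour step); the
    second block are free effect-size parameters whose shipped defaults are
    calibrated so the treatment arms reproduce their qualitative outcomes.
    """

    prob_M_Ag: float = 1e-2
    prob_M_IC: float = 1e-1
    prob_cDC_Ag: float = 2e-2
    plasma_rel_quanta: int = 1  # IgG quanta released per plasma cell per step
    B_dup: int = 16
    TH_dup: int = 16
    TC_dup: int = 16
    max_lfact: float = 5.0
    IL2_eff: float = 1.0

    # free, calibrated parameters
    base_kill_prob: float = 0.65
    cd137_kill_mult: float = 1.5
    cd137_dup_mult: float = 2.0
    cd137_chemo_mult: float = 2.0
    il2_k_half: float = 2.0
    dup_trigger_prob: float = 0.05
    infiltration_prob_wt: float = 0.6
    infiltration_prob_ko: float = 0.002
    infiltration_burden_limit: float = 4.3e5  # full-scale tumor cells
    kill_attempts_per_step: int = 4  # serial killing: CTL target contacts per 8 h
    tc_arrest_on_tumor: bool = True  # effector CTLs conjugate with targets and stop moving
    il2_secretion_th: int = 4
    il2_secretion_tc: int = 1
    ca_secretion: int = 1
    antigen_shed_prob: float = 2e-3  # per tumor cell per step
    antigen_per_death: int = 1
    mab_exposure_eff: float = 1e-3  # systemic pool -> per-step boost probability

    def __post_init__(self) -> None:
        for name in (
            "prob_M_Ag",
            "prob_M_IC",
            "prob_cDC_Ag",
            "base_kill_prob",
            "dup_trigger_prob",
            "infiltration_prob_wt",
            "infiltration_prob_ko",
            "antigen_shed_prob",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]; got {v}")
        for name in ("cd137_kill_mult", "cd137_dup_mult", "cd137_chemo_mult"):
            if getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be >= 1")
        if self.max_lfact <= 0:
            raise ValueError("max_lfact must be > 0")
        if not (0.0 <= self.IL2_eff <= 1.0):
            raise ValueError("IL2_eff must lie in [0, 1]")


class InteractionEvent(NamedTuple):
    """One resolved interaction, for the optional event log and audits."""

    kind: str
    site: int
    actors: Tuple[str, ...]


def il2_factor(quantity: float, params: InteractionParams) -> float:
    """Saturating IL-2 availability factor in [0, IL2_eff]."""
    if quantity <= 0:
        return 0.0
    return params.IL2_eff * quantity / (quantity + params.il2_k_half)


# ---------------------------------------------------------------------------
# rule 1 & 2: antigen presentation to helper T cells
# ---------------------------------------------------------------------------

def _th_stimulation(
    apc: CellAgent,
    th: CellAgent,
    params: InteractionParams,
    affinity: AffinityParams,
    rng: np.random.Generator,
) -> bool:
    if th.type is not CellType.TH or th.state in (CellState.DUPLICATING, CellState.DEAD):
        return False
    if apc.presented_peptide is None:
        return False
    m = match_bits(th.receptor, apc.presented_peptide, affinity.nbit_str, affinity.match_mode)
    return rng.random() < bind_probability(m, affinity)


def rule_b_th(
    b: CellAgent,
    th: CellAgent,
    params: InteractionParams,
    affinity: AffinityParams,
    rng: np.random.Generator,
    il2: np.ndarray,
) -> List[InteractionEvent]:
    """Presenting B cell + TH: cognate help.

    On a successful receptor/peptide bind the helper cell proliferates and
    secretes IL-2, and the B cell proliferates with daughters differentiating
    into plasma cells.
    """
    if b.type is not CellType.B or b.state is not CellState.PRESENTING_MHC2:
        return []
    if not _th_stimulation(b, th, params, affinity, rng):
        return []
    th.prev_state = CellState.ACTIVE
    th.state = CellState.DUPLICATING
    th.dup_timer = params.TH_dup
    il2[th.site] += params.il2_secretion_th
    b.prev_state = CellState.PRESENTING_MHC2
    b.state = CellState.DUPLICATING
    b.dup_timer = params.B_dup
    return [InteractionEvent("B_TH", b.site, ("B", "TH")), InteractionEvent("IL2_SECRETE", th.site, ("TH",))]


def rule_m_th(
    m: CellAgent,
    th: CellAgent,
    params: InteractionParams,
    affinity: AffinityParams,
    rng: np.random.Generator,
    il2: np.ndarray,
) -> List[InteractionEvent]:
    """Presenting macrophage + TH: helper proliferates and secretes IL-2 only."""
    if m.type is not CellType.M or m.state is not CellState.PRESENTING_MHC2:
        return []
    if not _th_stimulation(m, th, params, affinity, rng):
        return []
    th.prev_state = CellState.ACTIVE
    th.state = CellState.DUPLICATING
    th.dup_timer = params.TH_dup
    il2[th.site] += params.il2_secretion_th
    return [InteractionEvent("M_TH", m.site, ("M", "TH")), InteractionEvent("IL2_SECRETE", th.site, ("TH",))]


# ---------------------------------------------------------------------------
# rule 3 and the phagocyte analogues: antigen capture
# ---------------------------------------------------------------------------

def rule_dc_capture(
    dc: CellAgent,
    antigen_site: "dict[int, np.ndarray] | None",
    params: InteractionParams,
    rng: np.random.Generator,
) -> List[InteractionEvent]:
    """cDC internalises one antigen quantum and cross-presents (MHC-I and II)."""
    if dc.type is not CellType.CDC or dc.state is CellState.DEAD:
        return []
    if not antigen_site:
        return []
    for epitope, arr in antigen_site.items():
        if arr[dc.site] > 0:
            if rng.random() < params.prob_cDC_Ag:
                arr[dc.site] -= 1
                dc.state = CellState.PRESENTING_MHC1_AND_2
                dc.presented_peptide = epitope
                return [InteractionEvent("DC_AG", dc.site, ("cDC",))]
            return []
    return []


def rule_m_capture(
    m: CellAgent,
    antigen_site: "dict[int, np.ndarray] | None",
    ic_site: "dict[int, np.ndarray] | None",
    params: InteractionParams,
    rng: np.random.Generator,
) -> List[InteractionEvent]:
    """Macrophage phagocytosis: antigen at prob_M_Ag, immune complex at prob_M_IC.

    Either route leaves the macrophage presenting on MHC-II only.
    """
    if m.type is not CellType.M or m.state is CellState.DEAD:
        return []
    if ic_site:
        for epitope, arr in ic_site.items():
            if arr[m.site] > 0:
                if rng.random() < params.prob_M_IC:
                    arr[m.site] -= 1
                    m.state = CellState.PRESENTING_MHC2
                    m.presented_peptide = epitope
                    return [InteractionEvent("M_IC", m.site, ("M",))]
                break
    if antigen_site:
        for epitope, arr in antigen_site.items():
            if arr[m.site] > 0:
                if rng.random() < params.prob_M_Ag:
                    arr[m.site] -= 1
                    m.state = CellState.PRESENTING_MHC2
                    m.presented_peptide = epitope
                    return [InteractionEvent("M_AG", m.site, ("M",))]
                break
    return []


def rule_b_capture(
    b: CellAgent,
    antigen_site: "dict[int, np.ndarray] | None",
    affinity: AffinityParams,
    rng: np.random.Generator,
) -> List[InteractionEvent]:
    """B cell captures antigen through its BCR (specific) and presents on MHC-II."""
    if b.type is not CellType.B or b.state is not CellState.NAIVE:
        return []
    if not antigen_site:
        return []
    for epitope, arr in antigen_site.items():
        if arr[b.site] > 0:
            m = match_bits(b.receptor, epitope, affinity.nbit_str, affinity.match_mode)
            if rng.random() < bind_probability(m, affinity):
                arr[b.site] -= 1
                b.state = CellState.PRESENTING_MHC2
                b.presented_peptide = epitope
                return [InteractionEvent("B_AG", b.site, ("B",))]
            return []
    return []


# ---------------------------------------------------------------------------
# rule 4: priming
# ---------------------------------------------------------------------------

def rule_tc_prime(
    tc: CellAgent,
    dc: CellAgent,
    affinity: AffinityParams,
    rng: np.random.Generator,
) -> List[InteractionEvent]:
    """Naive TC primed by a cross-presenting cDC on a receptor/peptide bind."""
    if tc.type is not CellType.TC or tc.state is not CellState.NAIVE:
        return []
    if dc.type is not CellType.CDC or dc.state is not CellState.PRESENTING_MHC1_AND_2:
        return []
    m = match_bits(tc.receptor, dc.presented_peptide, affinity.nbit_str, affinity.match_mode)
    if rng.random() < bind_probability(m, affinity):
        tc.state = CellState.ACTIVE
        if tc.is_ot1:
            tc.is_activated_ot1 = True
        return [InteractionEvent("TC_PRIME", tc.site, ("TC", "cDC"))]
    return []


# ---------------------------------------------------------------------------
# rule 5: tumor kill
# ---------------------------------------------------------------------------

def kill_probability(
    tc: CellAgent,
    tumor_peptide: int,
    il2_quantity: float,
    params: InteractionParams,
    affinity: AffinityParams,
) -> float:
    """Per-contact kill probability of an activated TC against a tumor cell."""
    if tc.state not in (CellState.ACTIVE, CellState.DUPLICATING):
        return 0.0
    if tc.state is CellState.DUPLICATING and tc.prev_state is not CellState.ACTIVE:
        return 0.0
    m = match_bits(tc.receptor, tumor_peptide, affinity.nbit_str, affinity.match_mode)
    p = bind_probability(m, affinity) * params.base_kill_prob
    if tc.cd137_boosted:
        p *= params.cd137_kill_mult
    p *= il2_factor(il2_quantity, params)
    return min(1.0, p)


def rule_tc_kill(
    tc: CellAgent,
    tumor: CellAgent,
    il2_quantity: float,
    params: InteractionParams,
    affinity: AffinityParams,
    rng: np.random.Generator,
) -> List[InteractionEvent]:
    """Activated TC kills a co-located tumor cell (rule-level, agent form)."""
    if tumor.type is not CellType.TUMOR or tumor.state is CellState.DEAD:
        return []
    peptide = tumor.presented_peptide if tumor.presented_peptide is not None else tumor.receptor
    p = kill_probability(tc, peptide, il2_quantity, params, affinity)
    if rng.random() < p:
        tumor.state = CellState.DEAD
        return [InteractionEvent("TC_KILL", tc.site, ("TC", "TUMOR"))]
    return []


# ---------------------------------------------------------------------------
# rule 6: anti-CD137 boost
# ---------------------------------------------------------------------------

def rule_cd137_boost(
    tc: CellAgent, quanta_available: int, rng: np.random.Generator
) -> Tuple[int, List[InteractionEvent]]:
    """Agonist antibody engages CD137 on an *activated* TC.

    Consumes one antibody quantum and permanently boosts the cell's
    cytotoxicity, duplication rate and chemotaxis sensitivity.  Returns the
    number of quanta consumed (0 or 1) and the events.
    """
    if quanta_available <= 0 or tc.cd137_boosted:
        return 0, []
    if tc.type is not CellType.TC or tc.state not in (CellState.ACTIVE, CellState.DUPLICATING):
        return 0, []
    tc.cd137_boosted = True
    return 1, [InteractionEvent("CD137_BOOST", tc.site, ("TC",))]


# ---------------------------------------------------------------------------
# immune complexes
# ---------------------------------------------------------------------------

def rule_ic_form(
    igg: np.ndarray,
    antigen: np.ndarray,
    igg_receptor: int,
    epitope: int,
    affinity: AffinityParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Form immune complexes wherever IgG and antigen quanta are co-located.

    Each co-located (IgG, antigen) pair converts to one IC quantum with the
    bind probability of the paratope/epitope match.  Mutates the two input
    fields and returns the per-site IC increment (exact mass balance:
    dIgG = dAntigen = -dIC).
    """
    m = match_bits(igg_receptor, epitope, affinity.nbit_str, affinity.match_mode)
    p = bind_probability(m, affinity)
    pairs = np.minimum(igg, antigen)
    if p <= 0.0 or not pairs.any():
        return np.zeros_like(igg)
    formed = rng.binomial(pairs, p)
    igg -= formed
    antigen -= formed
    return formed


# ---------------------------------------------------------------------------
# endothelial CD137 infiltration gate
# ---------------------------------------------------------------------------

def gate_is_open(
    cd137_on_endothelium: bool,
    anti_cd137_present: bool,
    tumor_burden_cells: float,
    params: InteractionParams,
    burden_limit_cells: Optional[float] = None,
) -> bool:
    """Is tumor endothelium in its CD137-ligated, T-cell-admitting state?

    Requires CD137 expression on endothelium (wild type), systemic agonist
    antibody, and a tumor burden below ``infiltration_burden_limit`` — the
    vasculature of a large established tumor no longer supports efficient
    lymphocyte extravasation, which is what makes late treatment fail.
    """
    limit = params.infiltration_burden_limit if burden_limit_cells is None else burden_limit_cells
    return bool(cd137_on_endothelium and anti_cd137_present and tumor_burden_cells < limit)


def rule_infiltration_gate(
    gate_open: bool, params: InteractionParams, rng: np.random.Generator
) -> bool:
    """One TC's attempt to enter tumor-occupied tissue.

    Admitted with probability ``infiltration_prob_wt`` through competent
    (CD137-ligated) endothelium, else with the residual leak probability
    ``infiltration_prob_ko``.
    """
    p = params.infiltration_prob_wt if gate_open else params.infiltration_prob_ko
    return bool(rng.random() < p)


# ---------------------------------------------------------------------------
# duplication
# ---------------------------------------------------------------------------

_LYMPHOCYTES = (CellType.B, CellType.TH, CellType.TC)


def rule_duplicate(
    cell: CellAgent,
    local_same_type: int,
    il2_quantity: float,
    params: InteractionParams,
    affinity: AffinityParams,
    rng: np.random.Generator,
) -> Optional[CellAgent]:
    """One duplication-step of a cell in the DUPLICATING state.

    Division succeeds with probability min(1, max_lfact / n_local) x the
    IL-2 availability factor (lymphocytes only), x the anti-CD137 duplication
    multiplier for boosted cells.  The daughter inherits the receptor; B-cell
    daughters differentiate into plasma cells, with the antibody paratope
    passing through hypermutation.  The timer decrements each step and the
    cell reverts to its pre-duplication state at zero.
    """
    if cell.state is not CellState.DUPLICATING or cell.dup_timer <= 0:
        if cell.state is CellState.DUPLICATING:
            cell.state = cell.prev_state
        return None
    p = min(1.0, params.max_lfact / max(1, local_same_type))
    if cell.type in _LYMPHOCYTES:
        p *= il2_factor(il2_quantity, params)
    if cell.cd137_boosted:
        p = min(1.0, p * params.cd137_dup_mult)
    daughter: Optional[CellAgent] = None
    if p > 0 and rng.random() < p:
        if cell.type is CellType.B:
            daughter = CellAgent(
                type=CellType.P,
                state=CellState.PLASMA_SECRETING,
                receptor=hypermutate(cell.receptor, affinity.hyper_mut, rng, affinity.nbit_str),
                site=cell.site,
            )
        else:
            daughter = CellAgent(
                type=cell.type,
                state=CellState.ACTIVE,
                receptor=cell.receptor,
                site=cell.site,
                is_ot1=cell.is_ot1,
                is_activated_ot1=cell.is_ot1,
                cd137_boosted=cell.cd137_boosted,
            )
    cell.dup_timer -= 1
    if cell.dup_timer <= 0:
        cell.state = cell.prev_state
    return daughter
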