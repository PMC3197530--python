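"""Cell-agent and molecule bookkeeping.

Cell types follow the conceptual catalogue of the simulated tissue: B and T
lymphocytes (helper TH and cytotoxic TC), conventional dendritic cells (cDC
only — plasmacytoid DCs cannot present antigen and are omitted), macrophages
M, endothelial cells EP (immobile vessel sites), natural killer cells NK
(present and decaying but inert: no interaction rule is defined for them),
plasma cells P (antibody factories derived from B cells) and TUMOR cells.

Initial densities are per µL of blood-equivalent tissue and are mapped to
agent counts by a single ``density_scale`` factor; every population decays
stochastically according to its half-life, and the bone marrow replaces
lost naive cells (homeostasis) so resting censuses fluctuate around their
initial targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, List, Optional, Sequence

import numpy as np

from .repertoire import AffinityParams, complement, sample_repertoire, thymic_select

__all__ = [
    "CellType",
    "CellState",
    "CellAgent",
    "PopulationParams",
    "MoleculeFields",
    "decay_probability",
    "initialize_populations",
    "apply_homeostasis",
    "make_ot1_cohort",
]


class CellType(str, Enum):
    B = "B"
    TH = "TH"
    TC = "TC"
    CDC = "cDC"
    M = "M"
    EP = "EP"
    NK = "NK"
    P = "P"
    TUMOR = "TUMOR"


class CellState(str, Enum):
    NAIVE = "NAIVE"
    ACTIVE = "ACTIVE"
    PRESENTING_MHC2 = "PRESENTING_MHC2"
    PRESENTING_MHC1_AND_2 = "PRESENTING_MHC1_AND_2"
    DUPLICATING = "DUPLICATING"
    PLASMA_SECRETING = "PLASMA_SECRETING"
    DEAD = "DEAD"


#: cell types with an antigen-specific receptor
RECEPTOR_TYPES = {CellType.B, CellType.TH, CellType.TC, CellType.P}
#: cell types subject to thymic education
THYMUS_TYPES = {CellType.TH, CellType.TC}
#: mobile types (tumor cells never move; endothelium is vessel wall)
MOBILE_TYPES = {
    CellType.B,
    CellType.TH,
    CellType.TC,
    CellType.CDC,
    CellType.M,
    CellType.NK,
    CellType.P,
}


class CellAgent:
    """One discrete cell on the lattice.

    ``site`` is a flat lattice index.  ``receptor`` is None for types without
    specific receptors (EP, M, NK, cDC carry no BCR/TCR; presentation uses
    ``presented_peptide`` instead).  TUMOR agents are supported for rule-level
    tests; the engine aggregates tumor cells into a per-site count field.
    """

    __slots__ = (
        "type",
        "state",
        "receptor",
        "site",
        "dup_timer",
        "is_ot1",
        "is_activated_ot1",
        "cd137_boosted",
        "presented_peptide",
        "prev_state",
    )

    def __init__(
        self,
        type: CellType,
        state: CellState = CellState.NAIVE,
        receptor: Optional[int] = None,
        site: int = 0,
        dup_timer: int = 0,
        is_ot1: bool = False,
        is_activated_ot1: bool = False,
        cd137_boosted: bool = False,
        presented_peptide: Optional[int] = None,
    ):
        if is_activated_ot1 and not is_ot1:
            raise ValueError("is_activated_ot1 requires is_ot1")
        if state == CellState.PLASMA_SECRETING and type != CellType.P:
            raise ValueError("PLASMA_SECRETING is exclusive to plasma cells")
        self.type = type
        self.state = state
        self.receptor = receptor
        self.site = site
        self.dup_timer = dup_timer
        self.is_ot1 = is_ot1
        self.is_activated_ot1 = is_activated_ot1
        self.cd137_boosted = cd137_boosted
        self.presented_peptide = presented_peptide
        self.prev_state = state  # state to revert to when duplication ends

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"CellAgent({self.type.value}, {self.state.value}, r={self.receptor}, "
            f"site={self.site}, ot1={self.is_ot1}, boosted={self.cd137_boosted})"
        )


# Table of initial densities (per µL) and half-lives (days) for every entity.
_DENSITIES = {
    CellType.B: 260.0,
    CellType.TH: 200.0,
    CellType.TC: 434.0,
    CellType.CDC: 351.0,
    CellType.M: 351.0,
    CellType.EP: 351.0,
    CellType.NK: 351.0,
    CellType.P: 0.0,
}

_CELL_HALF_LIFE_DAYS = 3.3
_TUMOR_HALF_LIFE_DAYS = 10.0 * 365.0  # "10 years": effectively immortal


@dataclass(frozen=True)
class PopulationParams:
    """Initial densities, half-lives, and the density-to-agents scale.

    ``density_scale`` converts per-µL densities into agent counts for the
    simulated tissue section; it is quoted at full lattice scale (L = 946)
    and is rescaled by lattice area for reduced runs.
    """

    densities: Dict[CellType, float] = field(default_factory=lambda: dict(_DENSITIES))
    cell_half_life_days: float = _CELL_HALF_LIFE_DAYS
    tumor_half_life_days: float = _TUMOR_HALF_LIFE_DAYS
    ic_half_life_days: float = 4.0
    il2_half_life_days: float = 1.6
    ca_half_life_days: float = 1.6
    igg_half_life_days: float = 23.0
    anti_cd137_half_life_days: float = 23.0
    density_scale: float = 195.0  # at L = 946; total leukocytes ~2e4 at L = 200
    homeostasis_rate: float = 1.0  # fraction of the census deficit refilled per step
    replenish_plasma: bool = False

    def __post_init__(self) -> None:
        for t, d in self.densities.items():
            if d < 0:
                raise ValueError(f"density of {t} must be >= 0")
        for name in (
            "cell_half_life_days",
            "tumor_half_life_days",
            "ic_half_life_days",
            "il2_half_life_days",
            "ca_half_life_days",
            "igg_half_life_days",
            "anti_cd137_half_life_days",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.density_scale <= 0:
            raise ValueError("density_scale must be > 0")

    def target_counts(self, scale: float) -> Dict[CellType, int]:
        """Initial/homeostatic agent counts at the given effective scale."""
        return {t: round(d * scale) for t, d in self.densities.items()}


@dataclass
class MoleculeFields:
    """Per-site molecular quantities, integer quanta.

    Simple molecules (IL-2, chemoattractant) are flat integer arrays.
    Specificity-tagged molecules (IgG, antigen, immune complexes) map a
    bit-string receptor/epitope to a flat integer array.  Anti-CD137 is a
    single systemic pool: a circulating antibody equilibrates in plasma far
    faster than the 8-hour step, so spatial resolution carries no
    information.
    """

    il2: np.ndarray
    ca: np.ndarray
    anti_cd137: int = 0
    igg: Dict[int, np.ndarray] = field(default_factory=dict)
    antigen: Dict[int, np.ndarray] = field(default_factory=dict)
    ic: Dict[int, np.ndarray] = field(default_factory=dict)

    @classmethod
    def empty(cls, n_sites: int) -> "MoleculeFields":
        return cls(
            il2=np.zeros(n_sites, dtype=np.int64),
            ca=np.zeros(n_sites, dtype=np.int64),
        )

    def tagged(self, store: Dict[int, np.ndarray], receptor: int) -> np.ndarray:
        arr = store.get(receptor)
        if arr is None:
            arr = np.zeros_like(self.il2)
            store[receptor] = arr
        return arr


def decay_probability(half_life_days: float, dt_days: float) -> float:
    """Per-step death/decay probability from a half-life: 1 - 2**(-dt/half_life)."""
    if half_life_days <= 0 or dt_days <= 0:
        raise ValueError("half_life and dt must both be > 0")
    return 1.0 - 2.0 ** (-dt_days / half_life_days)


def _fresh_receptor(
    ctype: CellType,
    affinity: AffinityParams,
    self_peptides: Sequence[int],
    rng: np.random.Generator,
) -> Optional[int]:
    """Receptor for one bone-marrow/thymus export (thymus-selected for T cells)."""
    if ctype not in RECEPTOR_TYPES:
        return None
    while True:
        (r,) = sample_repertoire(1, affinity.nbit_str, rng)
        if ctype in THYMUS_TYPES:
            if not thymic_select([r], self_peptides, affinity, rng):
                continue  # deleted in the thymus; draw again
        return r


def initialize_populations(
    params: PopulationParams,
    n_sites: int,
    scale: float,
    affinity: AffinityParams,
    self_peptides: Sequence[int],
    rng: np.random.Generator,
    ep_sites: Optional[Sequence[int]] = None,
) -> List[CellAgent]:
    """Create the resting leukocyte populations, uniformly placed and naive.

    TH/TC receptors pass thymic selection; EP agents are placed on the
    supplied vessel layout when given (uniform random otherwise) and never
    move.
    """
    agents: List[CellAgent] = []
    targets = params.target_counts(scale)
    for ctype, n in targets.items():
        if n <= 0:
            continue
        if ctype is CellType.EP and ep_sites is not None:
            sites = list(ep_sites)
            if len(sites) != n:
                raise ValueError("ep_sites length must equal the EP target count")
        else:
            sites = [int(s) for s in rng.integers(0, n_sites, size=n)]
        for s in sites:
            agents.append(
                CellAgent(
                    type=ctype,
                    state=CellState.NAIVE,
                    receptor=_fresh_receptor(ctype, affinity, self_peptides, rng),
                    site=s,
                )
            )
    return agents


def apply_homeostasis(
    census: Dict[CellType, int],
    targets: Dict[CellType, int],
    params: PopulationParams,
    n_sites: int,
    affinity: AffinityParams,
    self_peptides: Sequence[int],
    rng: np.random.Generator,
) -> List[CellAgent]:
    """Bone-marrow replacement of depleted resting populations.

    For every non-tumor type below its target census, new naive agents are
    created at ``homeostasis_rate`` x deficit per step (fresh receptors,
    thymus-selected where applicable).  Plasma cells are not replenished
    unless configured otherwise; tumor cells never are.
    """
    births: List[CellAgent] = []
    for ctype, target in targets.items():
        if ctype is CellType.TUMOR:
            continue
        if ctype is CellType.P and not params.replenish_plasma:
            continue
        deficit = target - census.get(ctype, 0)
        if deficit <= 0:
            continue
        n_new = int(round(params.homeostasis_rate * deficit))
        for _ in range(n_new):
            births.append(
                CellAgent(
                    type=ctype,
                    state=CellState.NAIVE,
                    receptor=_fresh_receptor(ctype, affinity, self_peptides, rng),
                    site=int(rng.integers(0, n_sites)),
                )
            )
    return births


def make_ot1_cohort(
    n: int,
    activated: bool,
    ova_peptide: int,
    affinity: AffinityParams,
    rng: np.random.Generator,
) -> List[CellAgent]:
    """Adoptive-transfer cohort of OT-1 CD8 T cells.

    Every member carries the transgenic TCR exactly complementary to the OVA
    peptide (perfect match), so all recognise the tumor antigen.  Cohorts are
    created in circulation (site assigned on extravasation by the engine).
    """
    if n < 0:
        raise ValueError("cohort size must be >= 0")
    tcr = complement(ova_peptide, affinity.nbit_str)
    state = CellState.ACTIVE if activated else CellState.NAIVE
    return [
        CellAgent(
            type=CellType.TC,
            state=state,
            receptor=tcr,
            site=0,
            is_ot1=True,
            is_activated_ot1=activated,
        )
        for _ in range(n)
    ]
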