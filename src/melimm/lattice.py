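"""The L x L hexagonal tissue lattice.

Sites are addressed as (row, col) in odd-row offset coordinates; interior
sites have six neighbours.  Columns wrap (periodic left/right) while the top
and bottom rows are rigid walls: the simulated strip of tissue is a cylinder.
At full scale L = 946 represents a 60 mm x 60 mm section, so one site spans
about 63 µm of tissue.

Movement is a single-site biased random walk: the destination is drawn from
the current site plus its neighbours with weight 1 + sensitivity * CA, where
CA is the local chemoattractant quantity.  Molecular fields diffuse by
multinomial quantum splitting, which conserves total quanta exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

__all__ = [
    "HexLattice",
    "ChemotaxisParams",
    "neighbors",
    "choose_move",
    "diffuse_field",
    "placement_tumor_seed",
    "placement_iv",
]

FULL_SCALE_L = 946
FULL_SCALE_MM = 60.0

# Odd-row offset neighbour stencils: (drow, dcol) for even and odd rows.
_EVEN = ((0, -1), (0, 1), (-1, -1), (-1, 0), (1, -1), (1, 0))
_ODD = ((0, -1), (0, 1), (-1, 0), (-1, 1), (1, 0), (1, 1))


@dataclass(frozen=True)
class ChemotaxisParams:
    """Weights of the chemoattractant bias on cell movement."""

    base_sensitivity: float = 1.0
    cd137_sensitivity_boost: float = 2.0
    ca_diffusion_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.base_sensitivity < 0 or self.cd137_sensitivity_boost < 0:
            raise ValueError("chemotaxis sensitivities must be >= 0")
        if not (0.0 <= self.ca_diffusion_fraction <= 1.0):
            raise ValueError("ca_diffusion_fraction must lie in [0, 1]")


class HexLattice:
    """Hexagonal grid with periodic left/right columns and rigid top/bottom walls.

    Precomputes the flat-index neighbour table once; all engine hot paths use
    flat site indices ``row * L + col``.
    """

    def __init__(self, L: int, physical_mm: float | None = None):
        if L < 3:
            raise ValueError(f"lattice side must be >= 3; got {L}")
        self.L = int(L)
        self.n_sites = self.L * self.L
        # physical side length scales with L so site size matches full scale
        self.physical_mm = (
            physical_mm if physical_mm is not None else FULL_SCALE_MM * L / FULL_SCALE_L
        )
        self.site_mm = self.physical_mm / self.L
        self.area_scale = (L / FULL_SCALE_L) ** 2
        self._build_neighbor_table()

    def _build_neighbor_table(self) -> None:
        L = self.L
        table = np.full((self.n_sites, 6), -1, dtype=np.int64)
        counts = np.zeros(self.n_sites, dtype=np.int8)
        for r in range(L):
            stencil = _EVEN if r % 2 == 0 else _ODD
            for c in range(L):
                i = r * L + c
                k = 0
                for dr, dc in stencil:
                    rr = r + dr
                    if rr < 0 or rr >= L:  # rigid wall
                        continue
                    cc = (c + dc) % L  # periodic columns
                    table[i, k] = rr * L + cc
                    k += 1
                counts[i] = k
        self.neighbor_table = table
        self.neighbor_counts = counts

    # -- coordinate helpers -------------------------------------------------
    def flat(self, site: Tuple[int, int]) -> int:
        r, c = site
        if not (0 <= r < self.L and 0 <= c < self.L):
            raise IndexError(f"site {site} outside {self.L}x{self.L} lattice")
        return r * self.L + c

    def unflat(self, i: int) -> Tuple[int, int]:
        return divmod(int(i), self.L)

    @property
    def center(self) -> Tuple[int, int]:
        return (self.L // 2, self.L // 2)

    def new_field(self, dtype=np.int64) -> np.ndarray:
        """Fresh per-site quantity field (flat)."""
        return np.zeros(self.n_sites, dtype=dtype)


def neighbors(site: Tuple[int, int], lattice: HexLattice) -> List[Tuple[int, int]]:
    """Hex neighbourhood of ``site`` in deterministic stencil order."""
    i = lattice.flat(site)
    row = lattice.neighbor_table[i]
    return [lattice.unflat(j) for j in row if j >= 0]


def choose_move(
    site_flat: int,
    lattice: HexLattice,
    ca: np.ndarray,
    sensitivity: float,
    rng: np.random.Generator,
) -> int:
    """Draw the next site for one mobile agent.

    Candidates are the current site plus its neighbours; each candidate's
    weight is ``1 + sensitivity * CA(candidate)``.  With a flat CA field the
    walk is an unbiased choice over the candidates; chemotaxis-insensitive
    agents pass ``sensitivity = 0``.
    """
    nbrs = lattice.neighbor_table[site_flat]
    cand = [site_flat] + [int(j) for j in nbrs if j >= 0]
    if sensitivity <= 0.0:
        return cand[rng.integers(0, len(cand))]
    w = 1.0 + sensitivity * ca[cand]
    tot = w.sum()
    u = rng.random() * tot
    acc = 0.0
    for j, wj in zip(cand, w):
        acc += wj
        if u < acc:
            return j
    return cand[-1]


def move_weights(
    site_flat: int, lattice: HexLattice, ca: np.ndarray, sensitivity: float
) -> Tuple[List[int], np.ndarray]:
    """Candidate sites and their normalised move probabilities (for tests/analysis)."""
    nbrs = lattice.neighbor_table[site_flat]
    cand = [site_flat] + [int(j) for j in nbrs if j >= 0]
    w = 1.0 + sensitivity * ca[cand].astype(float)
    return cand, w / w.sum()


def diffuse_field(
    field: np.ndarray,
    lattice: HexLattice,
    fraction: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One multinomial diffusion step of an integer quantum field.

    Each site exports a Binomial(q, fraction) share of its quanta, split
    multinomially among its neighbours (quanta aimed at a rigid wall stay
    put).  The global sum is conserved exactly.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    if fraction == 0.0 or field.sum() == 0:
        return field.copy()
    out = field.copy()
    exported = rng.binomial(field, fraction)
    out -= exported
    remaining = exported.copy()
    # sequential binomial splitting over the 6 stencil directions
    table = lattice.neighbor_table
    for k in range(6):
        if k < 5:
            share = rng.binomial(remaining, 1.0 / (6 - k))
        else:
            share = remaining.copy()
        remaining -= share
        dest = table[:, k]
        valid = dest >= 0
        np.add.at(out, dest[valid], share[valid])
        # walls: quanta aimed out of the lattice stay on their source site
        out[~valid] += share[~valid]
    return out


def placement_tumor_seed(lattice: HexLattice, n_cells: int, site_capacity: int) -> List[int]:
    """Compact hex patch at the lattice centre large enough to host ``n_cells``.

    Returns flat site indices, centre first, then rings outward in BFS order;
    the patch is connected and holds at least ceil(n_cells / site_capacity)
    sites.
    """
    if site_capacity <= 0:
        raise ValueError("site_capacity must be > 0")
    need = max(1, -(-int(n_cells) // int(site_capacity)))
    start = lattice.flat(lattice.center)
    seen = {start}
    order = [start]
    frontier = [start]
    while len(order) < need:
        nxt: List[int] = []
        for i in frontier:
            for j in lattice.neighbor_table[i]:
                j = int(j)
                if j >= 0 and j not in seen:
                    seen.add(j)
                    order.append(j)
                    nxt.append(j)
        if not nxt:
            raise ValueError("tumor seed does not fit on the lattice")
        frontier = nxt
    return order[:need]


def placement_iv(lattice: HexLattice, n: int, rng: np.random.Generator) -> List[int]:
    """``n`` entry sites drawn uniformly from the rigid wall rows (0 and L-1).

    The walls stand in for vasculature entry when running in "walls" entry
    mode; the default engine mode delivers i.v. payloads through endothelial
    (vessel) sites instead.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return []
    L = lattice.L
    rows = rng.integers(0, 2, size=n) * (L - 1)
    cols = rng.integers(0, L, size=n)
    return [int(r) * L + int(c) for r, c in zip(rows, cols)]
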