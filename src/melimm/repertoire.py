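"""Bit-string receptor arithmetic.

Every specific recognition event in the simulator — T-cell receptor vs
presented peptide, antibody paratope vs tumor-antigen epitope — is scored on
fixed-width binary strings.  A receptor is an unsigned integer holding
``nbit_str`` bits (default 12, a potential repertoire of 4096 distinct
receptors).  Two binding sites "match" at every bit position where they are
complementary (Celada–Seiden convention: lock-and-key, so a receptor matches
its bitwise complement perfectly and never matches itself); an equality
convention is available behind ``match_mode`` for comparison studies.

Binding is probabilistic: zero below ``min_match`` matching bits,
``affinity_level`` exactly at ``min_match``, and geometrically interpolated
up to 1 at a perfect match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np

__all__ = [
    "AffinityParams",
    "repertoire_size",
    "complement",
    "match_bits",
    "bind_probability",
    "hypermutate",
    "thymic_select",
    "sample_repertoire",
]


@dataclass(frozen=True)
class AffinityParams:
    """Repertoire-wide affinity constants.

    Parameters
    ----------
    nbit_str : int
        Width of every binding site in bits; repertoire size is ``2**nbit_str``.
    min_match : int
        Minimal number of matching bits for a non-zero binding probability.
    affinity_level : float
        Binding probability at exactly ``min_match`` matching bits.
    hyper_mut : float
        Per-bit flip probability per timestep, applied to antibody lineages.
    thym_eff : float
        Probability that the thymus deletes a self-reactive thymocyte.
    match_mode : str
        ``"complement"`` (default) or ``"equality"``.
    """

    nbit_str: int = 12
    min_match: int = 9
    affinity_level: float = 5e-2
    hyper_mut: float = 1e-4
    thym_eff: float = 0.999
    match_mode: str = "complement"

    def __post_init__(self) -> None:
        if not (0 < self.min_match <= self.nbit_str):
            raise ValueError(
                f"min_match must lie in (0, nbit_str={self.nbit_str}]; got {self.min_match}"
            )
        if not (0.0 < self.affinity_level <= 1.0):
            raise ValueError(f"affinity_level must lie in (0, 1]; got {self.affinity_level}")
        if not (0.0 <= self.hyper_mut <= 1.0):
            raise ValueError(f"hyper_mut must lie in [0, 1]; got {self.hyper_mut}")
        if not (0.0 <= self.thym_eff <= 1.0):
            raise ValueError(f"thym_eff must lie in [0, 1]; got {self.thym_eff}")
        if self.match_mode not in ("complement", "equality"):
            raise ValueError(f"match_mode must be 'complement' or 'equality'; got {self.match_mode}")


def repertoire_size(nbit_str: int = 12) -> int:
    """Number of distinct receptors representable with ``nbit_str`` bits."""
    return 1 << nbit_str


def _check_receptor(r: int, nbit_str: int) -> None:
    if not (0 <= r < (1 << nbit_str)):
        raise ValueError(f"receptor {r!r} out of range for nbit_str={nbit_str}")


def complement(r: int, nbit_str: int = 12) -> int:
    """Bitwise complement of ``r`` within an ``nbit_str``-bit word."""
    _check_receptor(r, nbit_str)
    return r ^ ((1 << nbit_str) - 1)


def match_bits(r1: int, r2: int, nbit_str: int = 12, match_mode: str = "complement") -> int:
    """Number of matching bit positions between two binding sites.

    Under the default complementarity convention a position matches when the
    two bits differ, so ``match_bits(r, complement(r)) == nbit_str`` and
    ``match_bits(r, r) == 0``.  Symmetric in its arguments.
    """
    _check_receptor(r1, nbit_str)
    _check_receptor(r2, nbit_str)
    x = r1 ^ r2
    if match_mode == "equality":
        x ^= (1 << nbit_str) - 1
    return int(x).bit_count()


def bind_probability(match: int, params: AffinityParams) -> float:
    """Probability that two binding sites with ``match`` matching bits interact.

    Zero below ``min_match``; ``affinity_level`` at ``min_match``; geometric
    interpolation ``affinity_level ** ((nbit_str - match) / (nbit_str - min_match))``
    above it, reaching 1 at a perfect match.
    """
    if not (0 <= match <= params.nbit_str):
        raise ValueError(f"match must lie in [0, nbit_str={params.nbit_str}]; got {match}")
    if match < params.min_match:
        return 0.0
    if params.min_match == params.nbit_str:
        return 1.0 if match == params.nbit_str else float(params.affinity_level)
    expo = (params.nbit_str - match) / (params.nbit_str - params.min_match)
    return float(params.affinity_level**expo)


def hypermutate(r: int, hyper_mut: float, rng: np.random.Generator, nbit_str: int = 12) -> int:
    """Flip each bit of ``r`` independently with probability ``hyper_mut``."""
    _check_receptor(r, nbit_str)
    if hyper_mut <= 0.0:
        return r
    if hyper_mut >= 1.0:
        return complement(r, nbit_str)
    flips = rng.random(nbit_str) < hyper_mut
    if not flips.any():
        return r
    mask = 0
    for i in np.flatnonzero(flips):
        mask |= 1 << int(i)
    return r ^ mask


def is_self_reactive(
    r: int, self_peptides: Sequence[int], params: AffinityParams
) -> bool:
    """True when the receptor's best match against any self peptide reaches min_match."""
    return any(
        match_bits(r, s, params.nbit_str, params.match_mode) >= params.min_match
        for s in self_peptides
    )


def thymic_select(
    thymocytes: Sequence[int],
    self_peptides: Sequence[int],
    params: AffinityParams,
    rng: np.random.Generator,
) -> List[int]:
    """Negative selection: delete self-reactive thymocytes with probability thym_eff.

    A thymocyte is self-reactive when its best match against any self peptide
    reaches ``min_match``.  Survivors are returned in input order; the output
    is always a subset of the input.
    """
    if len(self_peptides) == 0:
        raise ValueError("thymic selection requires a non-empty self-peptide set")
    out: List[int] = []
    for r in thymocytes:
        if is_self_reactive(r, self_peptides, params) and rng.random() < params.thym_eff:
            continue
        out.append(r)
    return out


def sample_repertoire(n: int, nbit_str: int, rng: np.random.Generator) -> List[int]:
    """Draw ``n`` receptors uniformly with replacement from [0, 2**nbit_str)."""
    if n < 0:
        raise ValueError(f"n must be >= 0; got {n}")
    if n == 0:
        return []
    return [int(v) for v in rng.integers(0, 1 << nbit_str, size=n)]
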