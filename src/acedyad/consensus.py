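"""Position-wise spacer composition and threshold-based IUPAC consensus.

For each spacer length N, every observed spacer (one per dyad occurrence,
not per promoter) contributes its bases to a per-position composition
table.  A base qualifies at a position when its percentage clears an
asymmetric threshold — 25% for G or C, 40% for A or T — chosen for a
genome background of roughly 36% GC, where A/T are individually expected
near 32% and G/C near 18%.  The IUPAC code denoting exactly the qualifying
set is emitted (N when nothing qualifies); when several bases qualify the
full degenerate union code is used, the unique consistent extension of the
single-letter/S/N scheme.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .dyad_scan import SpacerPool

log = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")

#: IUPAC code for each subset of {A,C,G,T}; the empty set maps to N.
IUPAC_BY_SET: dict[frozenset[str], str] = {
    frozenset(): "N",
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y",
    frozenset("GC"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}


@dataclass
class PositionComposition:
    """Percentages of A,C,G,T at each position of the length-N spacer pool.

    Position 1 (index 0) is the base immediately 3' of the first motif copy.
    Ambiguous (N) characters are excluded from both numerator and
    denominator at their position, so columns sum to 100 whenever at least
    one unambiguous base was seen there.
    """

    N: int
    pct: np.ndarray  # shape (4, N), rows ordered A,C,G,T
    n_spacers: int

    def column(self, position: int) -> dict[str, float]:
        """Percentages at a 0-based position, keyed by base."""
        return {b: float(self.pct[i, position]) for i, b in enumerate(BASES)}


@dataclass
class ConsensusString:
    N: int
    text: str
    pct_gc: float
    pct_at: float

    @property
    def conserved_positions(self) -> int:
        """Count of positions with a non-N consensus call."""
        return sum(1 for c in self.text if c != "N")


def position_composition(pool_for_n: Sequence[str]) -> PositionComposition:
    """Tabulate base percentages per position for a pool of equal-length spacers."""
    if len(pool_for_n) == 0:
        raise ValueError("empty spacer pool")
    n = len(pool_for_n[0])
    for s in pool_for_n:
        if len(s) != n:
            raise ValueError("spacer pool contains unequal lengths")
    counts = np.zeros((4, n), dtype=int)
    ambiguous = 0
    base_index = {b: i for i, b in enumerate(BASES)}
    for s in pool_for_n:
        for pos, c in enumerate(s):
            if c in base_index:
                counts[base_index[c], pos] += 1
            else:
                ambiguous += 1
    if ambiguous:
        log.info("%d ambiguous characters excluded from composition", ambiguous)
    denom = counts.sum(axis=0).astype(float)
    pct = np.zeros((4, n), dtype=float)
    nonzero = denom > 0
    pct[:, nonzero] = 100.0 * counts[:, nonzero] / denom[nonzero]
    return PositionComposition(n, pct, len(pool_for_n))


def consensus_position(
    pct_column: Mapping[str, float], pct_gc: float = 25.0, pct_at: float = 40.0
) -> str:
    """IUPAC call for one position from its base percentages.

    Qualifying set: G or C at >= pct_gc, A or T at >= pct_at; the code for
    exactly that set is returned, N for the empty set.
    """
    qualifying = set()
    if pct_column.get("G", 0.0) >= pct_gc:
        qualifying.add("G")
    if pct_column.get("C", 0.0) >= pct_gc:
        qualifying.add("C")
    if pct_column.get("A", 0.0) >= pct_at:
        qualifying.add("A")
    if pct_column.get("T", 0.0) >= pct_at:
        qualifying.add("T")
    return IUPAC_BY_SET[frozenset(qualifying)]


def consensus_for_pool(
    pool_for_n: Sequence[str], pct_gc: float = 25.0, pct_at: float = 40.0
) -> ConsensusString:
    if len(pool_for_n) > 0 and len(pool_for_n[0]) == 0:
        return ConsensusString(0, "", pct_gc, pct_at)
    comp = position_composition(pool_for_n)
    text = "".join(
        consensus_position(comp.column(i), pct_gc, pct_at) for i in range(comp.N)
    )
    return ConsensusString(comp.N, text, pct_gc, pct_at)


def consensus_all(
    pool: SpacerPool,
    pct_gc: float = 25.0,
    pct_at: float = 40.0,
    max_spacer: int = 30,
) -> dict[int, ConsensusString]:
    """Per-N consensus strings for every non-empty pool up to max_spacer."""
    out: dict[int, ConsensusString] = {}
    for n in range(max_spacer + 1):
        strings = pool[n]
        if not strings:
            if n > 0:
                log.warning("no spacers of length %d; consensus skipped", n)
            if n == 0:
                out[0] = ConsensusString(0, "", pct_gc, pct_at)
            continue
        out[n] = consensus_for_pool(strings, pct_gc, pct_at)
    return out


@dataclass
class ConsensusSummary:
    fraction_first_G: float
    fraction_last_C: float
    conserved_by_N: dict[int, int]


def summarize_consensus(consensi: Mapping[int, ConsensusString]) -> ConsensusSummary:
    """Edge-position preference flags and per-N conservation scores.

    The flags quantify the expected G-box-like structure: G immediately 3'
    of the first core (spacer position 1) and C immediately 5' of the
    second core (spacer position N).
    """
    nonempty = [c for c in consensi.values() if c.N > 0]
    if not nonempty:
        return ConsensusSummary(0.0, 0.0, {n: c.conserved_positions for n, c in consensi.items()})
    first_g = sum(1 for c in nonempty if c.text[0] == "G") / len(nonempty)
    last_c = sum(1 for c in nonempty if c.text[-1] == "C") / len(nonempty)
    return ConsensusSummary(
        first_g, last_c, {n: c.conserved_positions for n, c in consensi.items()}
    )
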