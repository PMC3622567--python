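"""Scan promoters for co-occurring motif pairs MOTIF(N)MOTIF, 0 <= N <= max_spacer.

The primary motif is the ACGT core element; eight 4-mer controls provide the
null panel.  Scanning is single-stranded on the extracted promoter (ACGT is
its own reverse complement, so dyad hits for the primary motif are
strand-symmetric; controls are scanned under the identical convention).
By default every ordered pair of occurrences within range counts as one dyad
("all_pairs"): in a run ACGT-x-ACGT-y-ACGT all three in-range pairs are
reported, which is the only convention under which same-N comparisons remain
well defined when motifs nest inside spacers.  An "adjacent_only" mode
(consecutive occurrences) exists for sensitivity analysis.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

DEFAULT_MOTIF = "ACGT"
#: Control 4-mers used as the comparison panel (four dubbed palindromic,
#: four non-palindromic in the source data; implemented verbatim).
CONTROL_MOTIFS: tuple[str, ...] = (
    "TAGC", "CGTA", "GCTA", "ATGC",
    "AGCT", "TGCA", "CTAG", "GATC",
)
DEFAULT_MAX_SPACER = 30


@dataclass(frozen=True)
class Motif:
    text: str

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("motif must be non-empty")
        if set(self.text) - set("ACGT"):
            raise ValueError(f"motif must be uppercase over ACGT, got {self.text!r}")

    def __len__(self) -> int:
        return len(self.text)


@dataclass(frozen=True)
class DyadHit:
    """One co-occurrence: motif + spacer + motif at ``first_start`` (0-based)."""

    gene_id: str
    motif: str
    spacer_length: int
    first_start: int
    spacer: str


@dataclass
class SpacerFrequencyProfile:
    """Dyad counts indexed by spacer length N = 0..max_spacer for one motif."""

    motif: str
    counts: np.ndarray
    n_promoters: int
    species_label: str = ""

    @property
    def max_spacer(self) -> int:
        return len(self.counts) - 1

    @property
    def per_thousand(self) -> np.ndarray:
        """Dyads per 1000 promoters, elementwise (counts * 1000 / n_promoters)."""
        return self.counts.astype(float) * 1000.0 / self.n_promoters

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class SpacerPool:
    """For each N, the multiset of observed spacer strings."""

    motif: str
    pools: dict[int, list[str]] = field(default_factory=dict)

    def __getitem__(self, n: int) -> list[str]:
        return self.pools.get(n, [])


def find_motif_occurrences(sequence: str, motif: str) -> list[int]:
    """All 0-based start offsets of ``motif`` in ``sequence``, overlaps included.

    N in the sequence matches nothing (exact character comparison only).
    """
    hits: list[int] = []
    i = sequence.find(motif)
    while i != -1:
        hits.append(i)
        i = sequence.find(motif, i + 1)
    return hits


def scan_promoter(
    sequence: str,
    motif: str = DEFAULT_MOTIF,
    max_spacer: int = DEFAULT_MAX_SPACER,
    mode: str = "all_pairs",
    gene_id: str = "",
) -> list[DyadHit]:
    """Find all dyads MOTIF(N)MOTIF with 0 <= N <= max_spacer in one promoter."""
    if max_spacer < 0:
        raise ValueError("max_spacer must be >= 0")
    if mode not in {"all_pairs", "adjacent_only"}:
        raise ValueError(f"unknown mode {mode!r}")
    m = len(Motif(motif))
    occ = find_motif_occurrences(sequence, motif)
    hits: list[DyadHit] = []
    if mode == "adjacent_only":
        pairs: Iterable[tuple[int, int]] = zip(occ, occ[1:])
    else:
        pairs = (
            (i, j)
            for a, i in enumerate(occ)
            for j in occ[a + 1 :]
        )
    for i, j in pairs:
        gap = j - i - m
        if gap < 0:
            continue  # overlapping occurrences
        if gap > max_spacer:
            if mode == "all_pairs":
                continue
            break
        hits.append(DyadHit(gene_id, motif, gap, i, sequence[i + m : j]))
    return hits


def scan_hits(
    pset, motif: str = DEFAULT_MOTIF,
    max_spacer: int = DEFAULT_MAX_SPACER,
    mode: str = "all_pairs",
) -> list[DyadHit]:
    """All dyad hits over a PromoterSet, promoter order preserved."""
    hits: list[DyadHit] = []
    for gid, seq in pset.entries.items():
        hits.extend(scan_promoter(seq, motif, max_spacer, mode, gene_id=gid))
    return hits


def profile_from_hits(
    hits: Sequence[DyadHit], motif: str, n_promoters: int,
    max_spacer: int = DEFAULT_MAX_SPACER, species_label: str = "",
) -> SpacerFrequencyProfile:
    counts = np.zeros(max_spacer + 1, dtype=int)
    for h in hits:
        counts[h.spacer_length] += 1
    return SpacerFrequencyProfile(motif, counts, n_promoters, species_label)


def scan_set(
    pset, motif: str = DEFAULT_MOTIF,
    max_spacer: int = DEFAULT_MAX_SPACER,
    mode: str = "all_pairs",
) -> tuple[SpacerFrequencyProfile, SpacerPool]:
    """Scan every promoter; return the count profile and the spacer pool.

    ``n_promoters`` counts every promoter in the set, including those with
    zero hits — the per-1000 normalization is per promoter scanned, not per
    promoter with a dyad.
    """
    if len(pset.entries) == 0:
        raise ValueError("empty promoter set: per-1000 normalization undefined")
    hits = scan_hits(pset, motif, max_spacer, mode)
    profile = profile_from_hits(
        hits, motif, len(pset.entries), max_spacer, pset.species_label
    )
    pool = SpacerPool(motif)
    for h in hits:
        pool.pools.setdefault(h.spacer_length, []).append(h.spacer)
    return profile, pool


def control_panel(
    pset,
    motifs: Sequence[str] | None = None,
    max_spacer: int = DEFAULT_MAX_SPACER,
    mode: str = "all_pairs",
) -> dict[str, SpacerFrequencyProfile]:
    """Profile the test motif plus controls on one promoter set."""
    if motifs is None:
        motifs = (DEFAULT_MOTIF,) + CONTROL_MOTIFS
    if len(motifs) == 0:
        raise ValueError("motif panel must be non-empty")
    if len(set(motifs)) != len(motifs):
        raise ValueError("duplicate motifs in panel")
    return {m: scan_set(pset, m, max_spacer, mode)[0] for m in motifs}


def per_gene_counts(
    hits: Sequence[DyadHit], max_spacer: int = DEFAULT_MAX_SPACER
) -> dict[str, np.ndarray]:
    """Map gene_id -> per-N dyad count vector (genes with hits only)."""
    table: dict[str, np.ndarray] = {}
    for h in hits:
        if h.gene_id not in table:
            table[h.gene_id] = np.zeros(max_spacer + 1, dtype=int)
        table[h.gene_id][h.spacer_length] += 1
    return table


def genes_by_spacer(
    hits: Sequence[DyadHit], max_spacer: int = DEFAULT_MAX_SPACER
) -> dict[int, set[str]]:
    """Map N -> set of genes carrying at least one dyad with that spacer."""
    table: dict[int, set[str]] = {n: set() for n in range(max_spacer + 1)}
    for h in hits:
        table[h.spacer_length].add(h.gene_id)
    return table


def distinct_gene_profile(
    hits: Sequence[DyadHit], motif: str, n_promoters: int,
    max_spacer: int = DEFAULT_MAX_SPACER, species_label: str = "",
) -> SpacerFrequencyProfile:
    """Alternative profile counting dyad-carrying genes per N, not dyads."""
    by_n = genes_by_spacer(hits, max_spacer)
    counts = np.array([len(by_n[n]) for n in range(max_spacer + 1)], dtype=int)
    return SpacerFrequencyProfile(motif, counts, n_promoters, species_label)
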