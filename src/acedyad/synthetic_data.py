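"""Synthetic promoter sets with planted dyads and known enrichment.

The generator emulates the study conditions the pipeline was designed for:
fixed-length promoter sets (default 1 kb) over an i.i.d. background with a
controllable GC fraction (default 0.36, the Arabidopsis genome-wide value),
dyad constructs MOTIF+spacer+MOTIF planted at chosen spacer lengths and
Poisson rates, condition-regulated gene sets with a known true fold
enrichment over dyad-carrying genes, and families of parallel "species"
whose planted spacer-rate profiles are correlated.

Ground truth is defined *post-rescan*: after planting, the real scanner is
run and its output recorded, because background sequence creates incidental
motif occurrences and planted constructs can pair with each other.  Tests
against the post-rescan profile are therefore exact, not probabilistic.

Every generator takes an explicit integer seed; per-promoter substreams are
derived deterministically from it, so regenerating a subset reproduces the
same sequences.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .dyad_scan import (
    DEFAULT_MAX_SPACER,
    DEFAULT_MOTIF,
    SpacerFrequencyProfile,
    scan_set,
)
from .enrichment import RegulationSet
from .promoter_io import PromoterSet

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic promoter set."""

    n_promoters: int
    promoter_length: int = 1000
    gc_fraction: float = 0.36
    plant_rates: Mapping[int, float] = field(default_factory=dict)
    motif: str = DEFAULT_MOTIF
    seed: int = 0
    fixed_counts: bool = False  # plant exactly round(rate) constructs per promoter
    max_spacer: int = DEFAULT_MAX_SPACER
    species_label: str = "synthetic"

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc_fraction <= 1.0):
            raise ValueError("gc_fraction must lie in [0, 1]")
        for n in self.plant_rates:
            if not (0 <= n <= self.max_spacer):
                raise ValueError(f"plant rate key {n} outside [0, {self.max_spacer}]")

    @property
    def base_probs(self) -> np.ndarray:
        gc = self.gc_fraction
        return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


@dataclass
class GroundTruth:
    """What was planted, and what the scanner actually sees afterwards."""

    planted: dict[str, list[tuple[int, int, str]]]  # gene -> [(N, offset, spacer)]
    post_scan_profile: SpacerFrequencyProfile

    @property
    def planted_counts(self) -> np.ndarray:
        counts = np.zeros(self.post_scan_profile.max_spacer + 1, dtype=int)
        for rows in self.planted.values():
            for n, _, _ in rows:
                counts[n] += 1
        return counts


def _promoter_rng(seed: int, stream: int, index: int) -> np.random.Generator:
    # Deterministic substream per (stage, promoter); keeps subsets reproducible.
    return np.random.default_rng(np.random.SeedSequence((seed, stream, index)))


def _gene_id(i: int) -> str:
    return f"g{i:06d}"


def generate_background(spec: SyntheticSpec) -> PromoterSet:
    """i.i.d. background: P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2 per base."""
    pset = PromoterSet(
        species_label=spec.species_label, requested_length=spec.promoter_length
    )
    for i in range(spec.n_promoters):
        rng = _promoter_rng(spec.seed, 0, i)
        bases = rng.choice(_BASES, size=spec.promoter_length, p=spec.base_probs)
        pset.entries[_gene_id(i)] = "".join(bases)
    return pset


def _draw_offsets(
    rng: np.random.Generator, lengths: list[int], promoter_length: int, gene_id: str
) -> list[int]:
    """Non-overlapping insertion offsets, uniform by rejection sampling."""
    if sum(lengths) > promoter_length:
        raise ValueError(
            f"promoter {gene_id}: planted constructs need {sum(lengths)} bp, "
            f"promoter is {promoter_length} bp"
        )
    for _ in range(1000):
        offsets = [int(rng.integers(0, promoter_length - L + 1)) for L in lengths]
        intervals = sorted(zip(offsets, lengths))
        if all(
            intervals[k][0] + intervals[k][1] <= intervals[k + 1][0]
            for k in range(len(intervals) - 1)
        ):
            return offsets
    raise ValueError(
        f"promoter {gene_id}: could not place {len(lengths)} constructs without overlap"
    )


def plant_dyads(pset: PromoterSet, spec: SyntheticSpec) -> tuple[PromoterSet, GroundTruth]:
    """Overwrite promoter bases with motif+spacer+motif constructs.

    Per promoter and spacer length N, the construct count is Poisson with
    mean ``plant_rates[N]`` (or exactly round(rate) in fixed-count mode);
    offsets are uniform without overlap among planted constructs.  The
    returned ground truth records both the plants and the post-rescan
    profile of the final sequences.
    """
    m = spec.motif
    out = PromoterSet(
        species_label=pset.species_label, requested_length=pset.requested_length
    )
    planted: dict[str, list[tuple[int, int, str]]] = {}
    for i, (gid, seq) in enumerate(pset.entries.items()):
        rng = _promoter_rng(spec.seed, 1, i)
        constructs: list[int] = []  # spacer lengths to plant
        for n in sorted(spec.plant_rates):
            rate = spec.plant_rates[n]
            k = int(round(rate)) if spec.fixed_counts else int(rng.poisson(rate))
            constructs.extend([n] * k)
        if not constructs:
            out.entries[gid] = seq
            continue
        lengths = [2 * len(m) + n for n in constructs]
        offsets = _draw_offsets(rng, lengths, len(seq), gid)
        chars = list(seq)
        rows: list[tuple[int, int, str]] = []
        for n, off in zip(constructs, offsets):
            spacer = "".join(rng.choice(_BASES, size=n, p=spec.base_probs))
            construct = m + spacer + m
            chars[off : off + len(construct)] = construct
            rows.append((n, off, spacer))
        out.entries[gid] = "".join(chars)
        planted[gid] = rows
    profile, _ = scan_set(out, m, spec.max_spacer)
    return out, GroundTruth(planted, profile)


def generate_promoter_set(spec: SyntheticSpec) -> tuple[PromoterSet, GroundTruth]:
    """Background plus planting in one call."""
    return plant_dyads(generate_background(spec), spec)


def generate_condition_sets(
    universe: Sequence[str],
    dyad_genes: set[str],
    p_regulated: float,
    fold: float,
    seed: int,
    condition: str = "synthetic_condition",
    direction: str = "up",
) -> RegulationSet:
    """Regulated gene set with true fold enrichment ``fold`` on dyad genes.

    A dyad-carrying gene is regulated with probability fold * p_regulated;
    other genes with the probability q that keeps the marginal at
    p_regulated.  fold = 1 makes regulation independent of dyad carriage.
    """
    if fold * p_regulated > 1:
        raise ValueError("fold * p_regulated exceeds 1: infeasible")
    b = len(dyad_genes) / len(universe)
    if b < 1.0:
        q = p_regulated * (1 - fold * b) / (1 - b)
    else:
        q = 0.0
    if q < 0 or q > 1:
        raise ValueError(
            f"non-dyad regulation probability {q:.3f} outside [0,1]: infeasible "
            f"(fold={fold}, p={p_regulated}, |B|/|U|={b:.3f})"
        )
    rng = np.random.default_rng(np.random.SeedSequence((seed, 2)))
    ids = list(universe)
    probs = np.where(
        np.fromiter((g in dyad_genes for g in ids), dtype=bool, count=len(ids)),
        fold * p_regulated, q,
    )
    draws = rng.random(len(ids)) < probs
    regulated = frozenset(g for g, d in zip(ids, draws) if d)
    return RegulationSet(condition, direction, regulated, frozenset(universe))


def generate_species_family(
    base_spec: SyntheticSpec,
    k_species: int,
    profile_noise: float,
    seed: int,
) -> list[tuple[PromoterSet, GroundTruth]]:
    """k parallel "species" sharing perturbed planting profiles.

    Each species plants with rates base * exp(noise), noise ~ N(0,
    profile_noise^2) independently per species and spacer length; gene ids
    are aligned 1:1 across species, forming a trivial ortholog table.
    Cross-species profile correlation decreases as profile_noise grows.
    """
    if k_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 3)))
    family: list[tuple[PromoterSet, GroundTruth]] = []
    for s in range(k_species):
        rates = {
            n: r * float(np.exp(rng.normal(0.0, profile_noise)))
            for n, r in base_spec.plant_rates.items()
        }
        spec = replace(
            base_spec,
            plant_rates=rates,
            seed=int(rng.integers(0, 2**31 - 1)),
            species_label=f"sp{s + 1}",
        )
        family.append(generate_promoter_set(spec))
    return family
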