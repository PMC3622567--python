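"""Shared fixtures and independent oracles for the test suite."""
from __future__ import annotations

import re

import numpy as np
import pytest

from acedyad.promoter_io import PromoterSet


def brute_force_scan(sequence: str, motif: str, max_spacer: int):
    """Independent dyad oracle: test every (i, j) index pair directly.

    Occurrences come from a regex lookahead (overlap-safe) rather than the
    package's own finder; pairs are enumerated by an explicit double loop.
    Returns a sorted list of (first_start, spacer_length, spacer) tuples.
    """
    occ = [m.start() for m in re.finditer(f"(?={re.escape(motif)})", sequence)]
    hits = []
    for i in occ:
        for j in occ:
            if j <= i:
                continue
            gap = j - i - len(motif)
            if 0 <= gap <= max_spacer:
                spacer = sequence[i + len(motif) : j]
                assert sequence[i : i + len(motif)] == motif
                assert sequence[j : j + len(motif)] == motif
                hits.append((i, gap, spacer))
    return sorted(hits)


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.36) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


def make_promoter_set(seqs: dict[str, str], label: str = "toy",
                      requested_length: int = 1000) -> PromoterSet:
    pset = PromoterSet(species_label=label, requested_length=requested_length)
    pset.entries.update(seqs)
    return pset


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
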