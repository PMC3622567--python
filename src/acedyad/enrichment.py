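"""Likelihood-of-occurrence statistic and the Grubbs outlier screen.

The association between a condition-regulated gene set A and the
dyad-carrying gene set B(N) is measured as a fold enrichment

    L(N) = X / Y,   X = |A ∩ B(N)| / |B(N)|,   Y = |A| / |universe|,

i.e. P(regulated | dyad with spacer N) / P(regulated); L = 1 is chance.
The overall statistic uses B_any = union of B(N) over all N (genes carrying
at least one dyad of any spacer length).  Conditions whose test-motif
overall L exceeds a cutoff (default 1.30) are screened with a one-outlier
Grubbs test across the nine motifs (test + 8 controls); significance
additionally requires the test motif to BE the extreme point, otherwise an
outlying control would spuriously flag the condition.  No multiple-testing
correction is applied across conditions — the screen is exploratory and
downstream users should correct if they test many conditions.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dyad_scan import DEFAULT_MAX_SPACER

DEFAULT_CUTOFF = 1.30
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class RegulationSet:
    """Genes called regulated (up or down) under one condition."""

    condition: str
    direction: str
    genes: frozenset[str]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if self.direction not in {"up", "down"}:
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")
        if not self.universe:
            raise ValueError("universe must be non-empty")
        if not self.genes <= self.universe:
            raise ValueError("regulated genes must be a subset of the universe")


@dataclass
class LikelihoodResult:
    condition: str
    motif: str
    per_N: np.ndarray  # L(N), NaN where |B(N)| = 0
    overall: float
    n_universe: int
    n_regulated: int
    n_dyad_any: int
    n_overlap_any: int
    n_dyad_by_N: np.ndarray
    n_overlap_by_N: np.ndarray


def likelihood(
    regulation: RegulationSet,
    dyad_genes_by_N: Mapping[int, set[str]],
    max_spacer: int = DEFAULT_MAX_SPACER,
) -> LikelihoodResult:
    """Fold enrichment of regulation among dyad-carrying genes, per N and overall.

    L(N) is undefined (NaN) when no gene carries a dyad with spacer N; such
    lengths are excluded from summaries.
    """
    universe = regulation.universe
    A = regulation.genes
    if len(A) == 0:
        raise ValueError("empty regulated gene set: P(A) = 0, likelihood undefined")
    U = len(universe)
    pA = len(A) / U
    per_N = np.full(max_spacer + 1, np.nan)
    nB = np.zeros(max_spacer + 1, dtype=int)
    nAB = np.zeros(max_spacer + 1, dtype=int)
    b_any: set[str] = set()
    for n in range(max_spacer + 1):
        B = set(dyad_genes_by_N.get(n, set())) & universe
        b_any |= B
        nB[n] = len(B)
        nAB[n] = len(A & B)
        if B:
            per_N[n] = (nAB[n] / nB[n]) / pA
    overlap_any = len(A & b_any)
    overall = (overlap_any / len(b_any)) / pA if b_any else math.nan
    return LikelihoodResult(
        regulation.condition, "", per_N, overall,
        U, len(A), len(b_any), overlap_any, nB, nAB,
    )


def grubbs_statistic(values: Sequence[float]) -> tuple[float, int]:
    """Max studentized deviation G = max_i |x_i - mean| / sd and its index.

    Sample sd (n-1 denominator); ties broken to the lowest index.  G can
    never exceed (n-1)/sqrt(n).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    sd = float(x.std(ddof=1))
    if sd == 0:
        raise ValueError("zero standard deviation: no outlier definable")
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    return float(dev[idx] / sd), idx


def grubbs_critical(
    n: int, alpha: float = DEFAULT_ALPHA, sidedness: str = "two_sided"
) -> float:
    """Critical value of the single-outlier Grubbs test for sample size n.

    G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2)) with t the upper
    critical value of Student's t with n-2 df at alpha/(2n) (two-sided) or
    alpha/n (one-sided).
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if sidedness == "two_sided":
        q = alpha / (2 * n)
    elif sidedness == "one_sided":
        q = alpha / n
    else:
        raise ValueError(f"sidedness must be 'two_sided' or 'one_sided', got {sidedness!r}")
    t = float(stats.t.isf(q, n - 2))
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


@dataclass
class GrubbsResult:
    values: np.ndarray
    extreme_index: int
    G: float
    alpha: float
    sidedness: str
    critical: float
    significant: bool
    mean: float
    sd: float


def grubbs_test(
    values: Sequence[float],
    test_index: int = 0,
    alpha: float = DEFAULT_ALPHA,
    sidedness: str = "two_sided",
) -> GrubbsResult:
    """Grubbs screen: is the value at ``test_index`` a significant outlier?

    Significant only when the most extreme point IS the tested one and its
    G statistic exceeds the critical value.
    """
    x = np.asarray(values, dtype=float)
    G, idx = grubbs_statistic(x)
    crit = grubbs_critical(x.size, alpha, sidedness)
    return GrubbsResult(
        x, idx, G, alpha, sidedness, crit,
        significant=(idx == test_index and G > crit),
        mean=float(x.mean()), sd=float(x.std(ddof=1)),
    )


@dataclass
class ScreenRow:
    condition: str
    direction: str
    likelihoods: dict[str, float]  # motif -> overall L
    gated: bool  # test-motif L exceeded the cutoff
    grubbs: GrubbsResult | None
    significant: bool


def condition_screen(
    conditions: Sequence[RegulationSet],
    panel: Mapping[str, Mapping[int, set[str]]],
    test_motif: str = "ACGT",
    alpha: float = DEFAULT_ALPHA,
    cutoff: float = DEFAULT_CUTOFF,
    sidedness: str = "two_sided",
    max_spacer: int = DEFAULT_MAX_SPACER,
) -> list[ScreenRow]:
    """Per-condition likelihoods for every panel motif plus the Grubbs gate.

    ``panel`` maps motif -> (N -> dyad-carrying gene set); it must contain
    the test motif and at least two controls.  Conditions whose test-motif
    overall L is <= cutoff (or undefined) never reach the Grubbs stage.
    """
    if test_motif not in panel:
        raise ValueError(f"panel lacks the test motif {test_motif!r}")
    if len(panel) < 3:
        raise ValueError("panel needs the test motif and at least 2 controls")
    motifs = [test_motif] + [m for m in panel if m != test_motif]
    rows: list[ScreenRow] = []
    for reg in conditions:
        L = {
            m: likelihood(reg, panel[m], max_spacer).overall for m in motifs
        }
        l_test = L[test_motif]
        gated = bool(not math.isnan(l_test) and l_test > cutoff)
        grubbs: GrubbsResult | None = None
        significant = False
        if gated:
            vals = [L[m] for m in motifs]
            if all(not math.isnan(v) for v in vals) and np.std(vals) > 0:
                grubbs = grubbs_test(vals, test_index=0, alpha=alpha, sidedness=sidedness)
                significant = grubbs.significant
        rows.append(ScreenRow(reg.condition, reg.direction, L, gated, grubbs, significant))
    return rows


def screen_to_frame(rows: Sequence[ScreenRow]) -> pd.DataFrame:
    """Flatten screen rows to a condition x motif likelihood table."""
    records = []
    for row in rows:
        rec: dict[str, object] = {"condition": row.condition, "direction": row.direction}
        for m, v in row.likelihoods.items():
            rec[f"L_{m}"] = v
        rec["gated"] = row.gated
        rec["G"] = row.grubbs.G if row.grubbs else math.nan
        rec["G_critical"] = row.grubbs.critical if row.grubbs else math.nan
        rec["grubbs_mean"] = row.grubbs.mean if row.grubbs else math.nan
        rec["significant"] = row.significant
        records.append(rec)
    return pd.DataFrame.from_records(records)
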