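"""Statistics on spacer-frequency profiles.

Three ingredients: percentile-whisker outlier calling on a single profile
(potential peak/dip spacer lengths), sliding-window Pearson correlation
between two species' profiles (local regions of spacing conservation), and
profile restriction to a gene subset (ortholog groups, condition gene sets).

Correlations are computed on raw counts by default; per-1000 scaling is a
positive affine map of each profile and leaves Pearson r unchanged, so the
choice only matters for display.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .dyad_scan import DEFAULT_MAX_SPACER, SpacerFrequencyProfile

log = logging.getLogger(__name__)


@dataclass
class PercentileOutliers:
    low_pct: float
    high_pct: float
    low_value: float
    high_value: float
    peaks: set[int]
    dips: set[int]


def percentile_outliers(
    counts: Sequence[float] | np.ndarray, low: float = 10.0, high: float = 90.0
) -> PercentileOutliers:
    """Spacer lengths whose counts fall outside the [low, high] percentile whiskers.

    Percentiles use linear interpolation between order statistics (the
    inclusive, type-7 method).  Values strictly above the high whisker are
    peaks, strictly below the low whisker dips; a constant profile yields
    neither.
    """
    x = np.asarray(counts, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 values for whisker-based outliers")
    lo = float(np.percentile(x, low, method="linear"))
    hi = float(np.percentile(x, high, method="linear"))
    peaks = {int(n) for n in np.nonzero(x > hi)[0]}
    dips = {int(n) for n in np.nonzero(x < lo)[0]}
    return PercentileOutliers(low, high, lo, hi, peaks, dips)


def common_peaks(outliers: Mapping[str, PercentileOutliers]) -> set[int]:
    """Spacer lengths flagged as peaks in every species."""
    sets = [o.peaks for o in outliers.values()]
    return set.intersection(*sets) if sets else set()


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; errors on unequal length or zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def t_from_r(r: float, n: int) -> float:
    """t statistic for a Pearson coefficient from n paired observations.

    t = r * sqrt((n-2) / (1 - r^2)), df = n - 2.  |r| = 1 gives an infinite
    statistic (signalled as +/-inf).
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) > 1:
        raise ValueError(f"|r| must be <= 1, got {r}")
    if abs(r) == 1:
        return math.copysign(math.inf, r)
    return r * math.sqrt((n - 2) / (1.0 - r * r))


def p_from_t(t: float, df: int) -> float:
    """Two-sided tail probability of Student's t."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if math.isinf(t):
        return 0.0
    return float(2.0 * stats.t.sf(abs(t), df))


@dataclass
class CorrelationWindow:
    start_N: int
    width: int
    r: float
    t: float
    p: float

    @property
    def df(self) -> int:
        return self.width - 2

    @property
    def end_N(self) -> int:
        return self.start_N + self.width - 1


def window_correlations(
    profile_a: Sequence[float] | np.ndarray,
    profile_b: Sequence[float] | np.ndarray,
    min_width: int = 6,
) -> list[CorrelationWindow]:
    """Pearson r over every window of >= min_width consecutive spacer lengths.

    For profiles of length L there are sum_{k=min_width..L} (L - k + 1)
    windows (351 for L=31, min_width=6); the full-length window doubles as
    the whole-profile correlation.  Windows where either profile is constant
    are skipped with a warning.
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.size != b.size:
        raise ValueError("profiles must have equal length")
    L = a.size
    if min_width < 3:
        raise ValueError("min_width must be >= 3 for a defined t statistic")
    out: list[CorrelationWindow] = []
    for width in range(min_width, L + 1):
        for start in range(0, L - width + 1):
            xa = a[start : start + width]
            xb = b[start : start + width]
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                log.warning(
                    "window start=%d width=%d skipped: zero variance", start, width
                )
                continue
            r = pearson_r(xa, xb)
            t = t_from_r(r, width)
            p = p_from_t(t, width - 2)
            out.append(CorrelationWindow(start, width, r, t, p))
    return out


def best_window_per_width(
    windows: Sequence[CorrelationWindow],
) -> dict[int, CorrelationWindow]:
    """For each width, the window with the highest r (the most conserved run)."""
    best: dict[int, CorrelationWindow] = {}
    for w in windows:
        if w.width not in best or w.r > best[w.width].r:
            best[w.width] = w
    return best


def subset_profile(
    per_gene: Mapping[str, np.ndarray],
    gene_ids: Sequence[str],
    motif: str = "ACGT",
    max_spacer: int = DEFAULT_MAX_SPACER,
    species_label: str = "",
    scanned_genes: set[str] | None = None,
) -> SpacerFrequencyProfile:
    """Dyad-count profile restricted to a gene subset.

    ``per_gene`` is the map produced by :func:`acedyad.dyad_scan.per_gene_counts`
    over all scanned genes (genes without hits may be absent from it; they
    contribute zero counts).  When ``scanned_genes`` is supplied, subset ids
    outside it were never scanned and are skipped with a warning naming the
    count.  ``n_promoters`` is the number of subset genes retained, so
    ``per_thousand`` is per subset gene — used both for ortholog groups and
    condition gene lists.
    """
    counts = np.zeros(max_spacer + 1, dtype=int)
    known = 0
    skipped = 0
    seen: set[str] = set()
    for gid in gene_ids:
        if gid in seen:
            continue
        seen.add(gid)
        if scanned_genes is not None and gid not in scanned_genes:
            skipped += 1
            continue
        if gid in per_gene:
            vec = per_gene[gid]
            counts[: len(vec)] += vec[: max_spacer + 1]
        known += 1
    if skipped:
        log.warning("%d unknown gene ids skipped in subset_profile", skipped)
    return SpacerFrequencyProfile(motif, counts, known, species_label)
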