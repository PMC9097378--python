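"""LTR retrotransposon insertion dating.

The two LTRs of an element are identical at insertion and diverge
neutrally afterwards, so the Kimura two-parameter (K2P) distance K between
a locus's 5' and 3' LTRs converts into an insertion time

    T = K / (2 r)

with r the substitution rate per site per year (each LTR accumulates
substitutions independently, hence the factor 2). Per-family amplification
peaks are the mode of a Gaussian kernel density over the locus times.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from scipy import stats

logger = logging.getLogger(__name__)

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
MIN_LOCI_FOR_PEAK = 10


class SaturationError(ValueError):
    """K2P estimator undefined: divergence beyond the model's domain."""


@dataclass
class LTRPair:
    """Divergence record for one locus's LTR pair."""

    locus_id: str
    aligned_length: int
    P: float  # transition proportion
    Q: float  # transversion proportion
    K: Optional[float] = None  # substitutions/site
    T: Optional[float] = None  # insertion time, MYA
    saturated: bool = False


@dataclass
class FamilyAgeProfile:
    family: str
    times: list[float]
    peak_time: float
    n_loci: int


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


def align_ltr_pair(ltr5: str, ltr3: str) -> tuple[int, float, float]:
    """Globally align an LTR pair and count transition/transversion proportions.

    Returns (aligned_columns, P, Q) over columns that are neither gapped
    nor contain N.
    """
    if not ltr5 or not ltr3:
        raise ValueError("LTR sequences must be non-empty")
    ltr5, ltr3 = ltr5.upper(), ltr3.upper()
    aln = _aligner().align(ltr5, ltr3)[0]
    a, b = aln[0], aln[1]
    n_cols = transitions = transversions = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-" or x == "N" or y == "N":
            continue
        n_cols += 1
        if x == y:
            continue
        same_class = ({x, y} <= PURINES) or ({x, y} <= PYRIMIDINES)
        if same_class:
            transitions += 1
        else:
            transversions += 1
    if n_cols == 0:
        raise ValueError("no comparable columns after alignment")
    return n_cols, transitions / n_cols, transversions / n_cols


def k2p_distance(P: float, Q: float) -> float:
    """Kimura two-parameter distance K = -(1/2) ln[(1-2P-Q) sqrt(1-2Q)].

    Raises SaturationError outside the estimator's domain
    (1-2P-Q <= 0 or 1-2Q <= 0); such loci are excluded from dating.
    """
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"saturated divergence: P={P}, Q={Q}")
    return -0.5 * math.log(w1 * math.sqrt(w2))


def insertion_time(K: float, r: float = 1.3e-8) -> float:
    """Insertion time in million years: T = K / (2 r) years / 1e6."""
    if K < 0:
        raise ValueError("K must be >= 0")
    if r <= 0:
        raise ValueError("substitution rate must be > 0")
    return K / (2.0 * r) / 1e6


def date_ltr_pair(locus_id: str, ltr5: str, ltr3: str, r: float = 1.3e-8) -> LTRPair:
    """Full per-locus dating: align, estimate K2P distance, convert to MYA."""
    n_cols, P, Q = align_ltr_pair(ltr5, ltr3)
    pair = LTRPair(locus_id=locus_id, aligned_length=n_cols, P=P, Q=Q)
    try:
        pair.K = k2p_distance(P, Q)
        pair.T = insertion_time(pair.K, r)
    except SaturationError:
        pair.saturated = True
        logger.info("locus %s excluded from dating: saturated divergence", locus_id)
    return pair


def peak_insertion_time(times: Sequence[float], grid_points: int = 512) -> float:
    """Amplification-peak estimate: mode of a Gaussian KDE (Silverman bandwidth).

    The density is evaluated on a uniform grid over [0, max(times)]; the
    peak is the grid argmax (smallest time on exact ties). Requires at
    least 10 values.
    """
    times = np.asarray(times, dtype=float)
    if times.size < MIN_LOCI_FOR_PEAK:
        raise ValueError(f"need >= {MIN_LOCI_FOR_PEAK} insertion times, got {times.size}")
    if np.allclose(times, times[0]):
        return float(times[0])
    kde = stats.gaussian_kde(times, bw_method="silverman")
    grid = np.linspace(0.0, float(times.max()), grid_points)
    density = kde(grid)
    return float(grid[int(np.argmax(density))])  # argmax takes the first (smallest) tie


def family_age_profiles(
    dated: Sequence[tuple[str, LTRPair]],
) -> list[FamilyAgeProfile]:
    """Group per-locus times by family and estimate each family's peak.

    ``dated`` is a sequence of (family, LTRPair); saturated loci are
    dropped and families with fewer than 10 dated loci are skipped with a
    log notice.
    """
    by_family: dict[str, list[float]] = {}
    for family, pair in dated:
        if pair.T is not None:
            by_family.setdefault(family, []).append(pair.T)
    profiles = []
    for family, times in sorted(by_family.items()):
        if len(times) < MIN_LOCI_FOR_PEAK:
            logger.info("family %s skipped: only %d dated loci", family, len(times))
            continue
        profiles.append(
            FamilyAgeProfile(
                family=family,
                times=times,
                peak_time=peak_insertion_time(times),
                n_loci=len(times),
            )
        )
    return profiles
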