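"""Map-distance and crossover-interference statistics for tetrad counts.

Map distances use the Perkins equation for ordered-tetrad-free data,

    d (cM) = 100 * (TT/2 + 3*NPD) / n,

which corrects for double crossovers through the non-parental-ditype count.
Its sampling variance follows from the multinomial delta method: with
``t = TT/n`` and ``q = NPD/n``,

    Var(d) = (100^2 / n) * (t(1-t)/4 + 9 q(1-q) - 3 t q).

Genotype comparisons use a normal (Z) test on the difference of two Perkins
estimates.  Crossover interference between two adjacent intervals is
quantified by the interference ratio (IR): the Perkins distance of a test
interval among tetrads recombinant (TT or NPD) in the conditioning interval,
divided by the distance among non-recombinant (PD) tetrads.  IR = 1 when a
crossover in one interval does not alter recombination in its neighbour (no
interference); IR -> 0 under strong positive interference.  The test of
IR = 1 is the Z test on the difference of the two stratified distances,
which vanishes exactly when IR = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats as sps

from .classify import TetradClassCounts


class DegenerateTestError(ValueError):
    """Raised when a test statistic is undefined (zero variance, empty stratum)."""


@dataclass(frozen=True)
class MapDistanceEstimate:
    """Perkins map distance with delta-method sampling variance."""

    cM: float
    var: float
    n: int
    counts: tuple[int, int, int]  # (PD, TT, NPD)

    @property
    def sd(self) -> float:
        return math.sqrt(self.var)


@dataclass(frozen=True)
class InterferenceResult:
    """Interference ratio between two adjacent intervals, with its test."""

    test_interval: str
    conditioning_interval: str
    d_with_co: MapDistanceEstimate
    d_without_co: MapDistanceEstimate
    IR: float
    z: float
    p: float

    @property
    def se_IR(self) -> float:
        """Delta-method standard error of the ratio estimate."""
        dw, dwo = self.d_with_co, self.d_without_co
        return abs(self.IR) * math.sqrt(
            dw.var / dw.cM**2 + dwo.var / dwo.cM**2
        ) if dw.cM > 0 else math.sqrt(dw.var) / dwo.cM

    def confidence_interval(self, level: float = 0.95) -> tuple[float, float]:
        zq = sps.norm.ppf(0.5 + level / 2)
        se = self.se_IR
        return (self.IR - zq * se, self.IR + zq * se)


def perkins_distance(pd: int, tt: int, npd: int) -> MapDistanceEstimate:
    """Perkins map distance (cM) from (PD, TT, NPD) tetrad counts."""
    for name, v in (("PD", pd), ("TT", tt), ("NPD", npd)):
        if v < 0:
            raise ValueError(f"{name} count must be non-negative")
    n = pd + tt + npd
    if n == 0:
        raise DegenerateTestError("map distance undefined for zero scored tetrads")
    t = tt / n
    q = npd / n
    cm = 100.0 * (t / 2.0 + 3.0 * q)
    var = (100.0**2 / n) * (0.25 * t * (1 - t) + 9.0 * q * (1 - q) - 3.0 * t * q)
    return MapDistanceEstimate(cM=cm, var=max(var, 0.0), n=n, counts=(pd, tt, npd))


def map_distance(counts: TetradClassCounts, interval: str) -> MapDistanceEstimate:
    """Perkins distance of one interval from a joint class-count table."""
    return perkins_distance(*counts.marginal(interval))


def distance_z_test(
    a: MapDistanceEstimate, b: MapDistanceEstimate
) -> tuple[float, float]:
    """Two-sided Z test for equality of two independent map distances."""
    pooled = a.var + b.var
    if pooled <= 0:
        raise DegenerateTestError("both estimates have zero variance")
    z = (a.cM - b.cM) / math.sqrt(pooled)
    p = 2.0 * sps.norm.sf(abs(z))
    return z, p


def percent_change(
    mutant: MapDistanceEstimate, reference: MapDistanceEstimate
) -> float:
    """Relative distance change of ``mutant`` versus ``reference`` in percent."""
    if reference.cM == 0:
        raise DegenerateTestError("percent change undefined for a 0 cM reference")
    return 100.0 * (mutant.cM - reference.cM) / reference.cM


def interference_ratio(
    counts: TetradClassCounts,
    test: str = "I2b",
    conditioning: str = "I2a",
) -> InterferenceResult:
    """Interference ratio of ``test`` conditioned on ``conditioning``.

    Tetrads are stratified by the conditioning interval: recombinant
    (TT or NPD pooled) versus non-recombinant (PD).  The Perkins distance of
    the test interval is estimated inside each stratum; their ratio is the
    IR and the Z test on their difference tests IR = 1.
    """
    with_counts = counts.stratified(test, conditioning, with_co=True)
    without_counts = counts.stratified(test, conditioning, with_co=False)
    if sum(with_counts) == 0 or sum(without_counts) == 0:
        raise DegenerateTestError(
            "interference ratio requires tetrads in both conditioning strata"
        )
    d_with = perkins_distance(*with_counts)
    d_without = perkins_distance(*without_counts)
    if d_without.cM == 0:
        raise DegenerateTestError(
            "interference ratio undefined: zero distance in the no-CO stratum"
        )
    ir = d_with.cM / d_without.cM
    z, p = distance_z_test(d_with, d_without)
    return InterferenceResult(
        test_interval=test,
        conditioning_interval=conditioning,
        d_with_co=d_with,
        d_without_co=d_without,
        IR=ir,
        z=z,
        p=p,
    )


def welch_t_from_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
) -> tuple[float, float, float]:
    """Welch two-sample t test from group summaries (mean, SD, n).

    Returns ``(t, df, p)`` with the Welch-Satterthwaite degrees of freedom
    and a two-sided p value.  With both SDs zero the test degenerates:
    p = 1 for equal means, p = 0 otherwise.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    v1 = sd1**2 / n1
    v2 = sd2**2 / n2
    if v1 + v2 == 0:
        if mean1 == mean2:
            return 0.0, float(n1 + n2 - 2), 1.0
        return math.inf if mean1 > mean2 else -math.inf, float(n1 + n2 - 2), 0.0
    t = (mean1 - mean2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return t, df, p
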