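"""Tetrad classification into PD / TT / NPD categories.

For a pair of linked markers, the four spores of a tetrad reduce to
two-locus genotypes and fall into one of three classes: parental ditype
(two spore genotypes, both parental), tetratype (all four genotypes
present) or non-parental ditype (two genotypes, both recombinant).  The
joint (I2a, I2b) class table over two adjacent intervals is the sufficient
statistic for map-distance and interference-ratio estimation, so it is the
canonical internal representation; finer tetrad nomenclatures can be
derived from it but are not needed here.

Parental versus recombinant status is defined against the declared linkage
phase of the fluorescent transgenes (coupling by default): recombination is
undefined without a phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np

from .config import PHASE_HAPLOTYPES
from .simulate import Tetrad, TetradPopulation

INTERVALS = ("I2a", "I2b")
_INTERVAL_MARKERS = {"I2a": (0, 1), "I2b": (1, 2)}


class IntervalType(IntEnum):
    PD = 0
    TT = 1
    NPD = 2


class NonMendelianTetradError(ValueError):
    """Spore pattern incompatible with 2:2 segregation of a heterozygote."""


class UnscorableTetradError(ValueError):
    """One or more spores lack a fluorescence call at a needed marker."""


@dataclass
class TetradClassCounts:
    """Joint (I2a, I2b) class counts for a scored tetrad population.

    ``counts[i, j]`` is the number of tetrads of I2a type ``i`` and I2b
    type ``j`` in :class:`IntervalType` order (PD, TT, NPD); ``excluded``
    counts tetrads dropped as unscorable or non-Mendelian.
    """

    counts: np.ndarray
    excluded: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=np.int64)
        if arr.shape != (3, 3):
            raise ValueError("counts must be a 3x3 (I2a, I2b) table")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if self.excluded < 0:
            raise ValueError("excluded must be non-negative")
        self.counts = arr

    @property
    def n(self) -> int:
        """Number of scored tetrads."""
        return int(self.counts.sum())

    def marginal(self, interval: str) -> tuple[int, int, int]:
        """(PD, TT, NPD) counts of one interval, marginal over the other."""
        axis = 1 if interval == "I2a" else 0
        _check_interval(interval)
        m = self.counts.sum(axis=axis)
        return int(m[0]), int(m[1]), int(m[2])

    def stratified(self, test: str, conditioning: str, with_co: bool) -> tuple[int, int, int]:
        """(PD, TT, NPD) counts of ``test`` within a conditioning stratum.

        ``with_co=True`` selects tetrads recombinant (TT or NPD) in the
        conditioning interval, ``False`` the PD stratum.
        """
        _check_interval(test)
        _check_interval(conditioning)
        if test == conditioning:
            raise ValueError("test and conditioning intervals must differ")
        table = self.counts if conditioning == "I2a" else self.counts.T
        sub = table[1:3].sum(axis=0) if with_co else table[0]
        return int(sub[0]), int(sub[1]), int(sub[2])

    def __add__(self, other: "TetradClassCounts") -> "TetradClassCounts":
        return TetradClassCounts(self.counts + other.counts,
                                 self.excluded + other.excluded)


def _check_interval(interval: str) -> None:
    if interval not in INTERVALS:
        raise ValueError(f"interval must be one of {INTERVALS}")


# ---------------------------------------------------------------------------
# Per-tetrad classification
# ---------------------------------------------------------------------------

def _two_locus_codes(phase: str, interval: str) -> tuple[set[int], set[int]]:
    """Parental and recombinant two-locus genotype codes for an interval."""
    i, j = _INTERVAL_MARKERS[interval]
    hap1, hap2 = PHASE_HAPLOTYPES[phase]
    p1 = 2 * hap1[i] + hap1[j]
    p2 = 2 * hap2[i] + hap2[j]
    parental = {p1, p2}
    recombinant = {0, 1, 2, 3} - parental
    return parental, recombinant


def interval_type(
    tetrad: Tetrad, interval: str, phase: str = "coupling"
) -> IntervalType:
    """Classify one interval of a tetrad as PD, TT or NPD.

    Raises :class:`UnscorableTetradError` if any spore lacks a call at a
    flanking marker and :class:`NonMendelianTetradError` for spore
    multisets incompatible with 2:2 segregation (e.g. 3:1).
    """
    _check_interval(interval)
    i, j = _INTERVAL_MARKERS[interval]
    spores = tetrad.spores[:, [i, j]]
    if (spores < 0).any():
        raise UnscorableTetradError(
            f"tetrad {tetrad.meiosis_id}: missing call at a flanking marker of {interval}"
        )
    codes = 2 * spores[:, 0] + spores[:, 1]
    freq = np.bincount(codes, minlength=4)
    parental, recombinant = _two_locus_codes(phase, interval)
    if all(freq[c] == 2 for c in parental):
        return IntervalType.PD
    if all(freq[c] == 2 for c in recombinant):
        return IntervalType.NPD
    if (freq == 1).all():
        return IntervalType.TT
    raise NonMendelianTetradError(
        f"tetrad {tetrad.meiosis_id}: spore pattern {sorted(codes.tolist())} "
        f"violates 2:2 segregation in {interval}"
    )


def classify_tetrad(
    tetrad: Tetrad, phase: str = "coupling"
) -> tuple[IntervalType, IntervalType]:
    """Joint (I2a, I2b) class of a tetrad."""
    return (interval_type(tetrad, "I2a", phase),
            interval_type(tetrad, "I2b", phase))


# ---------------------------------------------------------------------------
# Population tallies
# ---------------------------------------------------------------------------

def _classify_array(genotypes: np.ndarray, phase: str) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised joint classification of an (n, 4, 3) genotype array.

    Returns ``(classes, ok)``: classes is (n, 2) of IntervalType codes
    (undefined where ok is False); ok flags tetrads scorable and Mendelian
    in both intervals.
    """
    n = genotypes.shape[0]
    classes = np.zeros((n, 2), dtype=np.int8)
    ok = np.ones(n, dtype=bool)
    scorable = (genotypes >= 0).all(axis=(1, 2))
    ok &= scorable
    for col, interval in enumerate(INTERVALS):
        i, j = _INTERVAL_MARKERS[interval]
        codes = 2 * genotypes[:, :, i] + genotypes[:, :, j]      # (n, 4)
        codes = np.where(codes < 0, 0, codes)                     # masked by ok
        freq = (codes[:, :, None] == np.arange(4)[None, None, :]).sum(axis=1)
        parental, recombinant = _two_locus_codes(phase, interval)
        is_pd = np.all(freq[:, sorted(parental)] == 2, axis=1)
        is_npd = np.all(freq[:, sorted(recombinant)] == 2, axis=1)
        is_tt = (freq == 1).all(axis=1)
        classes[:, col] = np.select(
            [is_pd, is_tt, is_npd],
            [IntervalType.PD, IntervalType.TT, IntervalType.NPD],
            default=-1,
        )
        ok &= classes[:, col] >= 0
    return classes, ok


def tally(
    tetrads: TetradPopulation | Iterable[Tetrad],
    phase: str = "coupling",
) -> TetradClassCounts:
    """Count joint (I2a, I2b) classes over a tetrad collection.

    Unscorable and non-Mendelian tetrads are excluded (whole tetrad) and
    reported in ``excluded``; ``n`` counts scored tetrads only.
    """
    if isinstance(tetrads, TetradPopulation):
        genotypes = tetrads.genotypes
    else:
        tetrads = list(tetrads)
        if not tetrads:
            return TetradClassCounts(np.zeros((3, 3), dtype=np.int64))
        genotypes = np.stack([t.spores for t in tetrads])
    classes, ok = _classify_array(genotypes, phase)
    kept = classes[ok]
    table = np.zeros((3, 3), dtype=np.int64)
    if kept.size:
        np.add.at(table, (kept[:, 0], kept[:, 1]), 1)
    return TetradClassCounts(table, excluded=int((~ok).sum()))
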