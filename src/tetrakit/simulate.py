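"""Two-pathway meiotic crossover simulator.

Class I (interfering) crossovers are placed by a stationary gamma-renewal
process on the genetic scale: inter-event distances are Gamma(nu, theta)
with ``theta = chrom_length / (lambda1 * nu)`` so that the expected event
count on the chromosome is ``lambda1``; the first event is drawn from the
equilibrium (stationary residual-life) distribution, sampled exactly as
``U * S`` with ``S ~ Gamma(nu + 1, theta)`` length-biased and
``U ~ Uniform(0, 1)``, which avoids edge effects at the chromosome start.
Class II (non-interfering) crossovers form an independent homogeneous
Poisson process with mean count ``lambda2``.  The two point processes are
superposed; each crossover then engages one maternal and one paternal
chromatid chosen uniformly and independently (no chromatid interference).

Tetrads are produced by tracing the four chromatids through the ordered
exchange points: an exchange at position ``p`` between maternal chromatid
``i`` and paternal chromatid ``j`` swaps the chromatid segments distal to
``p``, so every marker locus beyond ``p`` trades alleles between the two
strands.  Meiocyte outcomes score, per chromosome pair, whether at least
one crossover formed (bivalent) or none did (pair of univalents).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .config import PHASE_HAPLOTYPES, ConfigurationError, SimulationConfig

CLASS_I = "class_I"
CLASS_II = "class_II"


@dataclass(frozen=True)
class CrossoverEvent:
    """A single crossover on one bivalent.

    ``chromatids`` is ``(maternal, paternal)`` with each index in {0, 1},
    or ``None`` before chromatid resolution.  Sister-chromatid exchange is
    never modelled: every event pairs one maternal with one paternal
    chromatid.
    """

    position: float
    pathway: str
    chromatids: tuple[int, int] | None = None


@dataclass(frozen=True)
class Tetrad:
    """Four haploid spore genotypes from one meiosis.

    ``spores`` is a (4, 3) int8 array of fluorescence alleles (1 present,
    0 absent, -1 unscorable).  Mendelian segregation of a heterozygote
    implies a 2:2 allele balance at every scorable locus.
    """

    spores: np.ndarray
    meiosis_id: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.spores, dtype=np.int8)
        if arr.shape != (4, 3):
            raise ValueError("a tetrad holds exactly 4 spores x 3 markers")
        object.__setattr__(self, "spores", arr)

    def is_scorable(self) -> bool:
        return bool((self.spores >= 0).all())


@dataclass(frozen=True)
class MeiocyteOutcome:
    """Metaphase-I summary of one meiocyte."""

    bivalents: int
    univalent_pairs: int

    def __post_init__(self) -> None:
        if self.bivalents < 0 or self.univalent_pairs < 0:
            raise ValueError("counts must be non-negative")


class TetradPopulation(Sequence):
    """A simulated tetrad population backed by a dense genotype array.

    Behaves as an immutable sequence of :class:`Tetrad` while keeping the
    (n, 4, 3) genotype array available for vectorised classification.
    """

    def __init__(self, genotypes: np.ndarray, config: SimulationConfig):
        genotypes = np.asarray(genotypes, dtype=np.int8)
        if genotypes.ndim != 3 or genotypes.shape[1:] != (4, 3):
            raise ValueError("genotypes must have shape (n, 4, 3)")
        self.genotypes = genotypes
        self.config = config

    def __len__(self) -> int:
        return self.genotypes.shape[0]

    def __getitem__(self, i):
        if isinstance(i, slice):
            return [Tetrad(self.genotypes[j], meiosis_id=j)
                    for j in range(*i.indices(len(self)))]
        return Tetrad(self.genotypes[int(i)], meiosis_id=int(i))

    def __iter__(self) -> Iterator[Tetrad]:
        for j in range(len(self)):
            yield Tetrad(self.genotypes[j], meiosis_id=j)


# ---------------------------------------------------------------------------
# Event placement
# ---------------------------------------------------------------------------

def _class1_events(
    rng: np.random.Generator, n: int, nu: float, lam: float, length: float
) -> tuple[np.ndarray, np.ndarray]:
    """Draw class I positions for ``n`` chromosomes.

    Returns flat ``(rows, positions)`` with positions ascending within each
    row; rows are emitted in interleaved order and must be sorted by the
    caller after merging pathways.
    """
    if lam == 0:
        return np.empty(0, dtype=np.intp), np.empty(0)
    mu = length / lam          # mean inter-event distance (Morgans)
    theta = mu / nu            # gamma scale
    # stationary residual life: U * length-biased spacing
    cur = rng.uniform(size=n) * rng.gamma(nu + 1.0, theta, size=n)
    rows_out: list[np.ndarray] = []
    pos_out: list[np.ndarray] = []
    active = np.flatnonzero(cur <= length)
    while active.size:
        rows_out.append(active)
        pos_out.append(cur[active])
        cur[active] += rng.gamma(nu, theta, size=active.size)
        active = active[cur[active] <= length]
    if not rows_out:
        return np.empty(0, dtype=np.intp), np.empty(0)
    return np.concatenate(rows_out), np.concatenate(pos_out)


def _class2_events(
    rng: np.random.Generator, n: int, lam: float, length: float
) -> tuple[np.ndarray, np.ndarray]:
    """Homogeneous Poisson positions for ``n`` chromosomes, flat layout."""
    if lam == 0:
        return np.empty(0, dtype=np.intp), np.empty(0)
    counts = rng.poisson(lam, size=n)
    rows = np.repeat(np.arange(n, dtype=np.intp), counts)
    pos = rng.uniform(0.0, length, size=rows.size)
    return rows, pos


def draw_event_batch(
    config: SimulationConfig, rng: np.random.Generator, n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw merged crossover events for ``n`` chromosomes.

    Returns ``(rows, positions, pathways)`` sorted by (row, position);
    ``pathways`` is 1 for class I, 2 for class II.  Under ``obligate_co``
    chromosomes that drew zero events are resampled (rejection), which by
    construction leaves the event distribution conditional on >= 1 event
    unchanged.
    """
    r1, p1 = _class1_events(rng, n, config.nu, config.lambda1, config.chrom_length)
    r2, p2 = _class2_events(rng, n, config.lambda2, config.chrom_length)
    rows = np.concatenate([r1, r2])
    pos = np.concatenate([p1, p2])
    path = np.concatenate([
        np.ones(r1.size, dtype=np.int8),
        np.full(r2.size, 2, dtype=np.int8),
    ])

    if config.obligate_co:
        while True:
            counts = np.bincount(rows, minlength=n)
            empty = np.flatnonzero(counts == 0)
            if empty.size == 0:
                break
            er1, ep1 = _class1_events(
                rng, empty.size, config.nu, config.lambda1, config.chrom_length
            )
            er2, ep2 = _class2_events(
                rng, empty.size, config.lambda2, config.chrom_length
            )
            rows = np.concatenate([rows, empty[er1], empty[er2]])
            pos = np.concatenate([pos, ep1, ep2])
            path = np.concatenate([
                path,
                np.ones(er1.size, dtype=np.int8),
                np.full(er2.size, 2, dtype=np.int8),
            ])

    order = np.lexsort((pos, rows))
    return rows[order], pos[order], path[order]


def place_crossovers(
    config: SimulationConfig, rng: np.random.Generator
) -> list[CrossoverEvent]:
    """Crossover events for a single bivalent, sorted by position."""
    _, pos, path = draw_event_batch(config, rng, 1)
    return [
        CrossoverEvent(position=float(p), pathway=CLASS_I if w == 1 else CLASS_II)
        for p, w in zip(pos, path)
    ]


def resolve_chromatids(
    events: Sequence[CrossoverEvent], rng: np.random.Generator
) -> list[CrossoverEvent]:
    """Assign each event one maternal and one paternal chromatid.

    Choices are uniform over the four maternal/paternal pairs and
    independent across events (no chromatid interference).
    """
    if not events:
        return []
    picks = rng.integers(0, 2, size=(len(events), 2))
    return [
        CrossoverEvent(ev.position, ev.pathway, (int(m), int(p)))
        for ev, (m, p) in zip(events, picks)
    ]


# ---------------------------------------------------------------------------
# Chromatid tracing
# ---------------------------------------------------------------------------

def generate_tetrad(
    config: SimulationConfig,
    events: Sequence[CrossoverEvent],
    meiosis_id: int = 0,
) -> Tetrad:
    """Trace the four chromatids through resolved exchange points.

    Chromatids 0-1 are the sisters of one homolog, 2-3 of the other; which
    homolog carries the fluorescent transgenes is set by ``marker_phase``.
    An exchange joins the two named *original* chromatid molecules at its
    position, so the distal-segment swaps must be composed proximal-first:
    the content update is applied in decreasing position order.
    """
    hap1, hap2 = PHASE_HAPLOTYPES[config.marker_phase]
    G = np.array([hap1, hap1, hap2, hap2], dtype=np.int8)
    markers = np.asarray(config.marker_positions)
    last = -np.inf
    for ev in events:
        if ev.position < last:
            raise RuntimeError("crossover events must be sorted by position")
        last = ev.position
        if ev.chromatids is None:
            raise ValueError("events must have resolved chromatids")
    for ev in reversed(events):
        a = ev.chromatids[0]
        b = 2 + ev.chromatids[1]
        distal = markers > ev.position
        tmp = G[a, distal].copy()
        G[a, distal] = G[b, distal]
        G[b, distal] = tmp
    return Tetrad(spores=G, meiosis_id=meiosis_id)


def _trace_batch(
    n: int,
    rows: np.ndarray,
    pos: np.ndarray,
    cm: np.ndarray,
    cp: np.ndarray,
    marker_positions: Sequence[float],
    marker_phase: str,
) -> np.ndarray:
    """Vectorised chromatid tracing for ``n`` meioses.

    ``rows, pos, cm, cp`` are flat event arrays sorted by (row, position).
    Meioses are grouped by event count so that the sequential distal-segment
    swaps can be applied with fancy indexing; returns (n, 4, 3) genotypes.
    Equivalent to calling :func:`generate_tetrad` per meiosis (checked by
    the test suite against the scalar implementation).
    """
    hap = np.array(PHASE_HAPLOTYPES[marker_phase], dtype=np.int8)  # (2, 3)
    markers = np.asarray(marker_positions)
    n_mark = markers.size

    counts = np.bincount(rows, minlength=n)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    # origin[m, s, k]: index of the initial chromatid whose segment covers
    # marker k on output strand s of meiosis m
    origin = np.broadcast_to(
        np.arange(4, dtype=np.int8)[None, :, None], (n, 4, n_mark)
    ).copy()

    for c in np.unique(counts):
        if c == 0:
            continue
        members = np.flatnonzero(counts == c)          # meiosis ids, ascending
        ev_idx = offsets[members][:, None] + np.arange(c)[None, :]
        P = pos[ev_idx]                                # (g, c) ascending in c
        A = cm[ev_idx].astype(np.intp)                 # maternal strand 0/1
        B = 2 + cp[ev_idx].astype(np.intp)             # paternal strand 2/3
        O = origin[members]                            # (g, 4, n_mark) view copy
        g = members.size
        gi = np.arange(g)
        # proximal-first composition: content swaps applied distal event first
        for j in range(c - 1, -1, -1):
            a, b = A[:, j], B[:, j]
            for k in range(n_mark):
                hit = P[:, j] < markers[k]
                if not hit.any():
                    continue
                ii = gi[hit]
                tmp = O[ii, a[hit], k].copy()
                O[ii, a[hit], k] = O[ii, b[hit], k]
                O[ii, b[hit], k] = tmp
        origin[members] = O

    # allele = haplotype of the originating homolog at that marker
    return hap[(origin >> 1).astype(np.intp), np.arange(n_mark)[None, None, :]]


# ---------------------------------------------------------------------------
# Population-level simulation
# ---------------------------------------------------------------------------

def simulate_tetrad_population(config: SimulationConfig) -> TetradPopulation:
    """Simulate ``config.n_meioses`` tetrads; deterministic under the seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_meioses
    rows, pos, _ = draw_event_batch(config, rng, n)
    cm = rng.integers(0, 2, size=rows.size, dtype=np.int8)
    cp = rng.integers(0, 2, size=rows.size, dtype=np.int8)
    genotypes = _trace_batch(
        n, rows, pos, cm, cp, config.marker_positions, config.marker_phase
    )
    return TetradPopulation(genotypes, config)


def simulate_meiocytes(config: SimulationConfig) -> list[MeiocyteOutcome]:
    """Simulate metaphase-I outcomes for ``config.n_meioses`` meiocytes.

    Each of the ``n_chrom_pairs`` chromosome pairs draws crossovers
    independently under the same per-bivalent model; a pair with at least
    one crossover appears as a bivalent, otherwise as a pair of univalents.
    """
    rng = np.random.default_rng(config.seed)
    n_chrom = config.n_meioses * config.n_chrom_pairs
    rows, _, _ = draw_event_batch(config, rng, n_chrom)
    co_counts = np.bincount(rows, minlength=n_chrom)
    bivalents = (
        (co_counts.reshape(config.n_meioses, config.n_chrom_pairs) > 0)
        .sum(axis=1)
        .astype(int)
    )
    k = config.n_chrom_pairs
    return [MeiocyteOutcome(int(b), k - int(b)) for b in bivalents]
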