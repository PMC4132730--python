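"""Independent reference implementations used only by the test suite.

These deliberately use a different formulation from the package: tetrad
genotypes are obtained by *label walking* (follow a chromatid label through
the ordered exchange points), whereas the package swaps distal segment
contents.  Class probabilities given k crossovers come from exhaustive
enumeration of chromatid assignments.
"""

from __future__ import annotations

from itertools import product
from math import exp, factorial

import numpy as np

PHASE_HAPS = {
    "coupling": ((1, 1, 1), (0, 0, 0)),
    "repulsion": ((1, 0, 1), (0, 1, 0)),
}


def walk_trace(events, marker_positions, phase="coupling"):
    """Spore genotypes by walking chromatid labels through exchanges.

    ``events`` is a list of ``(position, (maternal, paternal))`` sorted by
    position.  Returns a (4, 3) int array in starting-chromatid order
    (0, 1 maternal; 2, 3 paternal).
    """
    haps = PHASE_HAPS[phase]
    spores = []
    for start in range(4):
        alleles = []
        for k, x in enumerate(marker_positions):
            cur = start
            for pos, (mi, pj) in events:
                if pos >= x:
                    break
                a, b = mi, 2 + pj
                if cur == a:
                    cur = b
                elif cur == b:
                    cur = a
            alleles.append(haps[cur // 2][k])
        spores.append(alleles)
    return np.array(spores, dtype=np.int8)


def recombinant_spores(events, interval_markers, marker_positions):
    """Number of recombinant chromatids for one interval, by label walking."""
    i, j = interval_markers
    xi, xj = marker_positions[i], marker_positions[j]
    rec = 0
    for start in range(4):
        cur = start
        for pos, (mi, pj) in events:
            if not (xi < pos < xj):
                continue
            a, b = mi, 2 + pj
            if cur == a:
                cur = b
            elif cur == b:
                cur = a
        if (cur < 2) != (start < 2):
            rec += 1
    return rec


def class_from_recombinants(rec: int) -> str:
    return {0: "PD", 2: "TT", 4: "NPD"}[rec]


def class_probs_given_k(k: int) -> tuple[float, float, float]:
    """(PD, TT, NPD) probabilities given k crossovers in an interval.

    Exhaustive enumeration over the 4**k chromatid assignments under
    uniform, independent chromatid choice.
    """
    if k == 0:
        return (1.0, 0.0, 0.0)
    tallies = {0: 0, 2: 0, 4: 0}
    for assign in product(range(4), repeat=k):
        events = [(0.1 * (t + 1), (a // 2, a % 2)) for t, a in enumerate(assign)]
        rec = recombinant_spores(events, (0, 1), (0.05, 10.0, 20.0))
        tallies[rec] += 1
    tot = 4**k
    return (tallies[0] / tot, tallies[2] / tot, tallies[4] / tot)


def poisson_class_probs(mean_bivalent_cos: float, kmax: int = 8):
    """(PD, TT, NPD) probabilities for Poisson crossover placement."""
    out = np.zeros(3)
    for k in range(kmax + 1):
        w = exp(-mean_bivalent_cos) * mean_bivalent_cos**k / factorial(k)
        out += w * np.asarray(class_probs_given_k(k))
    return out / out.sum()
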