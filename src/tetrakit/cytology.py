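"""Summaries of metaphase-I bivalent counts and recombination-focus counts.

Bivalent counts per meiocyte quantify how many of the chromosome pairs are
held together by at least one crossover at metaphase I; the complement,
pairs of univalents, marks chromosomes that failed to receive the obligate
crossover.  Focus counts per cell (e.g. MLH1 foci, a cytological proxy for
class I crossovers) are summarised as mean +/- sample SD.  Sample SD uses
the n-1 denominator throughout, matching the convention for small
cytology samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .simulate import MeiocyteOutcome


@dataclass(frozen=True)
class CellCountSample:
    """Per-cell integer counts for one genotype."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.size < 1:
            raise ValueError("a sample needs at least one cell")
        if (arr < 0).any():
            raise ValueError("cell counts must be non-negative")
        object.__setattr__(self, "values", arr)

    @property
    def n(self) -> int:
        return int(self.values.size)


class BivalentSummary(NamedTuple):
    mean_bivalents: float
    mean_univalent_pairs: float
    sd: float
    n: int


class FociSummary(NamedTuple):
    mean: float
    sd: float
    n: int


def _sample_sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1)) if values.size > 1 else 0.0


def bivalent_summary(
    sample: CellCountSample, n_chrom_pairs: int = 5
) -> BivalentSummary:
    """Mean bivalents and univalent pairs per meiocyte, with sample SD."""
    if (sample.values > n_chrom_pairs).any():
        raise ValueError(
            f"bivalent count exceeds {n_chrom_pairs} chromosome pairs"
        )
    mean_biv = float(np.mean(sample.values))
    return BivalentSummary(
        mean_bivalents=mean_biv,
        mean_univalent_pairs=n_chrom_pairs - mean_biv,
        sd=_sample_sd(sample.values),
        n=sample.n,
    )


def foci_summary(sample: CellCountSample) -> FociSummary:
    """Mean, sample SD and n of per-cell focus counts."""
    return FociSummary(
        mean=float(np.mean(sample.values)),
        sd=_sample_sd(sample.values),
        n=sample.n,
    )


def sample_from_meiocytes(
    meiocytes: Iterable[MeiocyteOutcome], label: str = ""
) -> CellCountSample:
    """Bivalent-count sample from simulated meiocyte outcomes."""
    return CellCountSample(
        values=np.array([m.bivalents for m in meiocytes], dtype=int),
        label=label,
    )
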