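"""Simulation configuration for the two-pathway crossover model.

Positions are genetic positions in Morgans throughout the package;
centiMorgans appear only at I/O boundaries.  The nominal genetic scale is
self-consistent when the total crossover intensity per bivalent equals
``2 * chrom_length`` (one crossover per chromatid per Morgan), which is how
the default configuration is calibrated.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

PHASES = ("coupling", "repulsion")

# Parental haplotypes over the three fluorescent markers.  In coupling one
# homolog carries all three transgenes; in repulsion the middle marker sits
# on the other homolog.
PHASE_HAPLOTYPES = {
    "coupling": ((1, 1, 1), (0, 0, 0)),
    "repulsion": ((1, 0, 1), (0, 1, 0)),
}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated meiotic population.

    Attributes
    ----------
    marker_positions:
        Strictly increasing genetic positions (Morgans) of the three
        fluorescent marker loci on one chromosome.  The two adjacent
        intervals they delimit are called I2a (markers 1-2) and I2b
        (markers 2-3) after the FTL interval pair the toolkit emulates.
    chrom_length:
        Chromosome genetic length in Morgans.
    nu:
        Gamma-renewal shape for class I (interfering) crossover spacing;
        ``nu = 1`` is a Poisson process (no interference), larger values
        produce stronger positive interference.
    lambda1:
        Expected class I crossovers per bivalent per meiosis.
    lambda2:
        Expected class II (non-interfering, Poisson) crossovers per
        bivalent per meiosis.
    obligate_co:
        If true, chromosome draws with zero crossovers are rejected and
        redrawn, enforcing the obligate crossover.
    n_chrom_pairs:
        Chromosome pairs per meiocyte (5 for Arabidopsis).
    n_meioses:
        Number of meioses (tetrads / meiocytes) to simulate.
    seed:
        Seed of the single numpy random stream; a fixed seed gives
        byte-identical output.
    marker_phase:
        'coupling' (one homolog carries all transgenes) or 'repulsion'.
    """

    marker_positions: tuple[float, float, float] = (0.15, 0.20, 0.25)
    chrom_length: float = 0.4
    nu: float = 1.0
    lambda1: float = 0.8
    lambda2: float = 0.0
    obligate_co: bool = False
    n_chrom_pairs: int = 5
    n_meioses: int = 1000
    seed: int = 0
    marker_phase: str = "coupling"

    def __post_init__(self) -> None:
        mp = tuple(float(x) for x in self.marker_positions)
        if len(mp) != 3:
            raise ConfigurationError("exactly three marker positions are required")
        object.__setattr__(self, "marker_positions", mp)
        if not all(math.isfinite(x) for x in mp):
            raise ConfigurationError("marker positions must be finite")
        if not (mp[0] < mp[1] < mp[2]):
            raise ConfigurationError("marker positions must be strictly increasing")
        if mp[0] < 0 or mp[2] > self.chrom_length:
            raise ConfigurationError(
                f"marker positions must lie within [0, {self.chrom_length}]"
            )
        if not (math.isfinite(self.chrom_length) and self.chrom_length > 0):
            raise ConfigurationError("chrom_length must be positive and finite")
        if not (math.isfinite(self.nu) and self.nu > 0):
            raise ConfigurationError("gamma shape nu must be positive and finite")
        for name in ("lambda1", "lambda2"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ConfigurationError(f"{name} must be finite and non-negative")
        if self.obligate_co and self.lambda1 + self.lambda2 == 0:
            raise ConfigurationError(
                "obligate_co requires a positive crossover intensity"
            )
        if self.n_chrom_pairs < 1:
            raise ConfigurationError("n_chrom_pairs must be >= 1")
        if self.n_meioses < 1:
            raise ConfigurationError("n_meioses must be >= 1")
        if self.marker_phase not in PHASES:
            raise ConfigurationError(f"marker_phase must be one of {PHASES}")

    # -- derived quantities -------------------------------------------------

    @property
    def interval_lengths(self) -> tuple[float, float]:
        """Genetic lengths (Morgans) of intervals I2a and I2b."""
        m1, m2, m3 = self.marker_positions
        return (m2 - m1, m3 - m2)

    @property
    def parental_haplotypes(self) -> tuple[tuple[int, int, int], tuple[int, int, int]]:
        return PHASE_HAPLOTYPES[self.marker_phase]

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["marker_positions"] = list(d["marker_positions"])
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SimulationConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**{k: (tuple(v) if k == "marker_positions" else v) for k, v in data.items()})

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Load a configuration from a YAML or JSON file."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: expected a mapping of config fields")
        return cls.from_dict(data)

    def replace(self, **kwargs: Any) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def content_hash(self) -> str:
        """Stable hash of the configuration (for run manifests)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def preset(name: str, **overrides: Any) -> SimulationConfig:
    """Named illustrative genotype presets.

    The presets reproduce the qualitative genetic architecture (a strong
    interfering class I pathway, a minor Poisson class II pathway boosted in
    anti-crossover mutants); their numeric values are illustrative, not
    fitted to any particular data set.
    """
    base = dict(
        marker_positions=(0.15, 0.20, 0.25),
        chrom_length=0.4,
        nu=8.0,
        lambda1=0.8,
        lambda2=0.08,
        obligate_co=True,
    )
    presets: dict[str, dict[str, Any]] = {
        # interfering class I dominates, rare class II events
        "wild_type": {},
        # class I crippled: few crossovers, frequent univalents
        "zmm": dict(lambda1=0.08, obligate_co=False),
        # class II strongly derepressed (helicase-null-like, ~3x distances)
        "fancm_like": dict(lambda2=1.8),
        # class II moderately derepressed (cofactor-null-like, ~1.6x)
        "mhf_like": dict(lambda2=0.56),
        # interference-free null used for calibration checks
        "poisson_null": dict(nu=1.0, lambda2=0.0, obligate_co=False),
    }
    if name not in presets:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {sorted(presets)}"
        )
    params = {**base, **presets[name], **overrides}
    return SimulationConfig(**params)
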