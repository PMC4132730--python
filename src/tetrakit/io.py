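"""Readers, writers and the end-to-end report pipeline.

Three plain-CSV table formats are defined (no standard bioinformatics
format exists for tetrad fluorescence tables):

* per-tetrad table: columns ``tetrad_id, spore_index, m1, m2, m3`` with
  marker values in {0, 1, NA}; exactly four spore rows per tetrad;
* class-count table: columns ``type_I2a, type_I2b, count`` (the nine joint
  categories), preceded by ``# n=`` and ``# excluded=`` metadata lines;
* cell-count table: columns ``cell_id, genotype, count``.

All writers emit RFC-4180 CSV with a fixed column order; readers accept LF
and CRLF.  Every pipeline run carries a :class:`RunManifest` (seed, config
hash, package version, row counts) so a re-run with the same manifest is
byte-identical apart from timestamps.
"""

from __future__ import annotations

import io as _io
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import __version__
from .classify import INTERVALS, IntervalType, TetradClassCounts, tally
from .config import SimulationConfig
from .cytology import CellCountSample, bivalent_summary, sample_from_meiocytes
from .simulate import Tetrad, TetradPopulation, simulate_meiocytes, simulate_tetrad_population
from .stats import interference_ratio, map_distance

logger = logging.getLogger("tetrakit")

TETRAD_COLUMNS = ["tetrad_id", "spore_index", "m1", "m2", "m3"]
COUNT_COLUMNS = ["type_I2a", "type_I2b", "count"]


class ParseError(ValueError):
    """Malformed input table; the message names the offending rows."""


# ---------------------------------------------------------------------------
# Per-tetrad tables
# ---------------------------------------------------------------------------

def write_tetrad_table(
    tetrads: TetradPopulation | Iterable[Tetrad], path: str | Path
) -> int:
    """Write a per-tetrad CSV (one row per spore); returns rows written."""
    if isinstance(tetrads, TetradPopulation):
        geno = tetrads.genotypes
        ids = np.arange(geno.shape[0])
    else:
        tetrads = list(tetrads)
        geno = (
            np.stack([t.spores for t in tetrads])
            if tetrads else np.empty((0, 4, 3), dtype=np.int8)
        )
        ids = np.array([t.meiosis_id for t in tetrads], dtype=int)
    n = geno.shape[0]
    df = pd.DataFrame({
        "tetrad_id": np.repeat(ids, 4),
        "spore_index": np.tile(np.arange(1, 5), n),
        "m1": geno[:, :, 0].ravel(),
        "m2": geno[:, :, 1].ravel(),
        "m3": geno[:, :, 2].ravel(),
    })
    for c in ("m1", "m2", "m3"):
        df[c] = df[c].astype("object").where(df[c] >= 0, "NA")
    df.to_csv(path, index=False, lineterminator="\r\n")
    return len(df)


def read_tetrad_table(path: str | Path) -> list[Tetrad]:
    """Read and validate a per-tetrad CSV.

    Raises :class:`ParseError` naming the tetrad or row for a wrong spore
    count, duplicate ``(tetrad_id, spore_index)`` or a marker value outside
    {0, 1, NA}.  Spores with NA markers are kept (alleles coded -1) and
    flagged unscorable downstream.
    """
    df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    missing = [c for c in TETRAD_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    df = df[TETRAD_COLUMNS]

    markers = df[["m1", "m2", "m3"]]
    valid = markers.isin(["0", "1", "NA"]) | markers.isna()
    if not valid.all().all():
        bad = np.where(~valid.to_numpy())[0][0]
        raise ParseError(
            f"{path}: row {bad + 2}: marker value must be 0, 1 or NA "
            f"(got {markers.iloc[bad].tolist()})"
        )
    dup = df.duplicated(subset=["tetrad_id", "spore_index"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ParseError(
            f"{path}: duplicate (tetrad_id={row.tetrad_id}, "
            f"spore_index={row.spore_index})"
        )
    sizes = df.groupby("tetrad_id", sort=False).size()
    wrong = sizes[sizes != 4]
    if not wrong.empty:
        raise ParseError(
            f"{path}: tetrad_id {wrong.index[0]} has {wrong.iloc[0]} spore rows "
            "(expected 4)"
        )

    coded = markers.fillna("NA").replace({"NA": "-1"}).astype(np.int8).to_numpy()
    tetrads: list[Tetrad] = []
    for k, (tid, grp) in enumerate(df.groupby("tetrad_id", sort=False)):
        spores = coded[grp.index.to_numpy()]
        try:
            tid_int = int(tid)
        except (TypeError, ValueError):
            tid_int = k
        tetrads.append(Tetrad(spores=spores, meiosis_id=tid_int))
    return tetrads


# ---------------------------------------------------------------------------
# Class-count tables
# ---------------------------------------------------------------------------

def write_class_counts(counts: TetradClassCounts, path: str | Path) -> None:
    """Write the nine joint class counts with n/excluded metadata lines."""
    buf = _io.StringIO()
    buf.write(f"# n={counts.n}\r\n# excluded={counts.excluded}\r\n")
    buf.write(",".join(COUNT_COLUMNS) + "\r\n")
    for i in IntervalType:
        for j in IntervalType:
            buf.write(f"{i.name},{j.name},{counts.counts[i, j]}\r\n")
    Path(path).write_text(buf.getvalue())


def read_class_counts(path: str | Path, allow_sparse: bool = False) -> TetradClassCounts:
    """Read a class-count CSV; absent categories default to 0 only with
    ``allow_sparse``."""
    meta: dict[str, int] = {}
    lines = Path(path).read_text().splitlines()
    body = []
    for ln in lines:
        if ln.startswith("#"):
            key, _, val = ln.lstrip("# ").partition("=")
            if key.strip() in ("n", "excluded"):
                meta[key.strip()] = int(val)
        elif ln.strip():
            body.append(ln)
    df = pd.read_csv(_io.StringIO("\n".join(body)))
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    table = np.zeros((3, 3), dtype=np.int64)
    seen = set()
    names = {t.name for t in IntervalType}
    for _, row in df.iterrows():
        a, b = str(row.type_I2a), str(row.type_I2b)
        if a not in names or b not in names:
            raise ParseError(f"{path}: unknown tetrad class ({a}, {b})")
        c = int(row["count"])
        if c < 0:
            raise ParseError(f"{path}: negative count for ({a}, {b})")
        table[IntervalType[a], IntervalType[b]] = c
        seen.add((a, b))
    if len(seen) < 9 and not allow_sparse:
        absent = [
            (i.name, j.name)
            for i in IntervalType for j in IntervalType
            if (i.name, j.name) not in seen
        ]
        raise ParseError(
            f"{path}: missing categories {absent}; pass allow_sparse to default "
            "them to 0"
        )
    counts = TetradClassCounts(table, excluded=meta.get("excluded", 0))
    if "n" in meta and meta["n"] != counts.n:
        raise ParseError(
            f"{path}: header n={meta['n']} disagrees with summed counts {counts.n}"
        )
    return counts


# ---------------------------------------------------------------------------
# Cell-count tables
# ---------------------------------------------------------------------------

def write_cell_counts(samples: Iterable[CellCountSample], path: str | Path) -> None:
    rows = []
    cell = 0
    for s in samples:
        for v in s.values:
            cell += 1
            rows.append((cell, s.label, int(v)))
    pd.DataFrame(rows, columns=["cell_id", "genotype", "count"]).to_csv(
        path, index=False, lineterminator="\r\n"
    )


def read_cell_counts(path: str | Path) -> list[CellCountSample]:
    df = pd.read_csv(path, comment="#")
    for col in ("cell_id", "genotype", "count"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col}")
    if (df["count"] < 0).any():
        raise ParseError(f"{path}: negative cell count")
    return [
        CellCountSample(values=grp["count"].to_numpy(), label=str(name))
        for name, grp in df.groupby("genotype", sort=False)
    ]


# ---------------------------------------------------------------------------
# Run manifest and end-to-end report
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    seed: int
    config_hash: str
    version: str = __version__
    timestamp: str = ""
    inputs: dict = field(default_factory=dict)
    row_counts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config_hash": self.config_hash,
            "version": self.version,
            "timestamp": self.timestamp,
            "inputs": self.inputs,
            "row_counts": self.row_counts,
        }


def run_report(
    config: SimulationConfig,
    outdir: str | Path,
    tetrad_table: str | Path | None = None,
) -> dict:
    """Run the full chain simulate/ingest -> classify -> distances -> IR.

    Writes ``report.json``, ``class_counts.csv`` and ``distances.csv``
    under ``outdir`` and returns the report dictionary.  With a fixed seed
    the JSON is identical across runs except for the timestamp.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        seed=config.seed,
        config_hash=config.content_hash(),
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )

    if tetrad_table is not None:
        tetrads: TetradPopulation | list[Tetrad] = read_tetrad_table(tetrad_table)
        manifest.inputs["tetrad_table"] = str(tetrad_table)
    else:
        tetrads = simulate_tetrad_population(config)
    counts = tally(tetrads, phase=config.marker_phase)
    manifest.row_counts["tetrads_scored"] = counts.n
    manifest.row_counts["tetrads_excluded"] = counts.excluded
    logger.info(
        "run %s: seed=%d scored=%d excluded=%d",
        manifest.config_hash, config.seed, counts.n, counts.excluded,
    )
    write_class_counts(counts, outdir / "class_counts.csv")

    distances = {iv: map_distance(counts, iv) for iv in INTERVALS}
    ir = interference_ratio(counts, test="I2b", conditioning="I2a")
    ci = ir.confidence_interval(0.95)

    meiocytes = simulate_meiocytes(config.replace(seed=config.seed + 1))
    biv = bivalent_summary(
        sample_from_meiocytes(meiocytes), n_chrom_pairs=config.n_chrom_pairs
    )

    pd.DataFrame(
        [
            {
                "interval": iv,
                "cM": d.cM,
                "sd": d.sd,
                "n": d.n,
                "PD": d.counts[0],
                "TT": d.counts[1],
                "NPD": d.counts[2],
            }
            for iv, d in distances.items()
        ]
    ).to_csv(outdir / "distances.csv", index=False, lineterminator="\r\n")

    report = {
        "manifest": manifest.to_dict(),
        "config": config.to_dict(),
        "distances": {
            iv: {"cM": d.cM, "sd": d.sd, "var": d.var, "n": d.n,
                 "counts": list(d.counts)}
            for iv, d in distances.items()
        },
        "interference": {
            "test": ir.test_interval,
            "conditioning": ir.conditioning_interval,
            "IR": ir.IR,
            "se": ir.se_IR,
            "ci95": list(ci),
            "z": ir.z,
            "p": ir.p,
            "d_with_co_cM": ir.d_with_co.cM,
            "d_without_co_cM": ir.d_without_co.cM,
        },
        "bivalents": {
            "mean": biv.mean_bivalents,
            "mean_univalent_pairs": biv.mean_univalent_pairs,
            "sd": biv.sd,
            "n": biv.n,
        },
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report
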