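"""Readers and writers for the plain-text formats the pipeline touches.

* BED3 for binary feature tracks, BED4/bedGraph for value tracks;
* ``chrom.sizes`` two-column files for genome models;
* a minimal variant TSV (``chrom  pos0  kind  af  patient_id``) — the
  analysis needs only position plus AF or patient id, so full VCF semantics
  are not carried around;
* a read-only VCF projection (CHROM / POS / INFO AF) for interoperability.

All coordinates are 0-based half-open on disk and in memory (VCF positions
are converted from 1-based on read).
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeModel
from .intervals import FeatureTrack
from .variants import COLUMNS, VariantSet

VARIANT_TSV_HEADER = "\t".join(COLUMNS)


def _open(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_bed(path, name: str | None = None) -> FeatureTrack:
    """Read BED3 (binary track) or BED4/bedGraph (value track).

    Malformed lines raise ``ValueError`` naming the offending line number.
    """
    rows: list[tuple] = []
    has_value: bool | None = None
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            if has_value is None:
                has_value = len(fields) >= 4
            if has_value:
                if len(fields) < 4:
                    raise ValueError(f"{path}:{lineno}: missing value column")
                try:
                    value = float(fields[3])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-numeric value") from exc
                rows.append((chrom, start, end, value))
            else:
                rows.append((chrom, start, end))
    return FeatureTrack(name or Path(path).stem, rows)


def write_bed(track: FeatureTrack, path) -> None:
    with _open(path, "wt") as fh:
        for chrom in track.chromosomes:
            iv = track.intervals(chrom)
            if track.is_valued:
                vals = track.interval_values(chrom)
                for (s, e), v in zip(iv, vals):
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")
            else:
                for s, e in iv:
                    fh.write(f"{chrom}\t{s}\t{e}\n")


def write_bedgraph_bins(path, chrom_arr, start_arr, values, bin_size: int) -> None:
    """Write per-bin scores as bedGraph, skipping missing (NaN) bins."""
    with _open(path, "wt") as fh:
        for chrom, start, v in zip(chrom_arr, start_arr, values):
            if np.isnan(v):
                continue
            fh.write(f"{chrom}\t{start}\t{start + bin_size}\t{v:.6g}\n")


def read_chrom_sizes(path) -> GenomeModel:
    chroms = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'name<TAB>length'")
            chroms.append((fields[0], int(fields[1])))
    return GenomeModel(chroms)


def write_chrom_sizes(genome: GenomeModel, path) -> None:
    with _open(path, "wt") as fh:
        for name, length in genome.chromosomes:
            fh.write(f"{name}\t{length}\n")


def read_variant_tsv(path) -> VariantSet:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"chrom": str, "pos": np.int64, "kind": str, "patient_id": object},
    )
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if "af" in df.columns:
        df["af"] = pd.to_numeric(df["af"], errors="coerce")
    return VariantSet(df[COLUMNS])


def write_variant_tsv(variants: VariantSet, path) -> None:
    variants.df.to_csv(path, sep="\t", index=False, na_rep="")


def read_vcf(path, kind: str = "germline") -> VariantSet:
    """Project a VCF onto the minimal variant table (CHROM, POS, INFO AF).

    Multi-allelic AF fields keep the first allele's frequency. Genotypes and
    all other fields are ignored; this reader exists only so real VCFs can
    feed the germline model.
    """
    chroms: list[str] = []
    positions: list[int] = []
    afs: list[float] = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise ValueError(f"{path}:{lineno}: expected >= 8 VCF columns")
            chroms.append(fields[0])
            positions.append(int(fields[1]) - 1)  # to 0-based
            af = np.nan
            for entry in fields[7].split(";"):
                if entry.startswith("AF="):
                    af = float(entry[3:].split(",")[0])
                    break
            afs.append(af)
    return VariantSet.from_arrays(chroms, positions, kind, af=afs)
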