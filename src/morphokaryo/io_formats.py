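"""Readers and writers for the external formats the pipeline touches.

TPS landmark files (tpsDig dialect), specimen metadata tables, square
distance matrices (CSV or PHYLIP) and diploid genotypes (GenePop or CSV).
All text I/O is UTF-8 with "." as decimal separator.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import MISSING_ALLELE, DistanceMatrix, GenotypeTable, LandmarkDataset

__all__ = [
    "read_tps",
    "write_tps",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_genotypes",
    "write_genepop",
    "read_metadata",
    "join_metadata",
]

_KEYVAL = re.compile(r"^\s*([A-Za-z_]+)\s*=\s*(.*?)\s*$")


def read_tps(path, apply_scale: bool = True) -> LandmarkDataset:
    """Read a TPS landmark file.

    Accepts ``LM=``/``lm=`` record headers, Windows or Unix line endings,
    and the optional ``IMAGE=``, ``ID=`` and ``SCALE=`` keys.  When a record
    carries ``SCALE=`` and ``apply_scale`` is true, its coordinates are
    multiplied by the scale factor on load (physical units).  Only 2-D
    records are supported.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    ids: list[str] = []
    coords: list[np.ndarray] = []
    i = 0
    record_no = 0
    k_expected: int | None = None
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        m = _KEYVAL.match(line)
        if not m or m.group(1).upper() != "LM":
            # LM3= (3-D records) deliberately falls through to this error
            raise ValueError(f"{path}: expected LM= record header at line {i + 1}, got {line!r}")
        try:
            k = int(m.group(2))
        except ValueError:
            raise ValueError(f"{path}: non-integer landmark count at line {i + 1}") from None
        record_no += 1
        if k_expected is None:
            k_expected = k
        elif k != k_expected:
            raise ValueError(
                f"{path}: record {record_no} has LM={k}, expected {k_expected} "
                "(landmark count must be constant across a dataset)"
            )
        i += 1
        pts = np.empty((k, 2))
        for j in range(k):
            if i >= len(lines):
                raise ValueError(f"{path}: record {record_no} truncated")
            fields = lines[i].split()
            if len(fields) == 3:
                raise ValueError(
                    f"{path}: line {i + 1} has 3 coordinates; 3-D landmarks are not supported"
                )
            if len(fields) != 2:
                raise ValueError(f"{path}: line {i + 1}: expected 2 coordinates")
            try:
                pts[j] = [float(fields[0]), float(fields[1])]
            except ValueError:
                raise ValueError(f"{path}: non-numeric coordinate at line {i + 1}") from None
            i += 1
        spec_id = None
        scale = None
        while i < len(lines):
            m = _KEYVAL.match(lines[i].strip())
            if not m:
                break
            key = m.group(1).upper()
            if key == "LM":
                break
            if key == "ID":
                spec_id = m.group(2)
            elif key == "SCALE":
                scale = float(m.group(2))
            # IMAGE= and other keys are tolerated and ignored
            i += 1
        if scale is not None and apply_scale:
            pts = pts * scale
        ids.append(spec_id if spec_id is not None else f"specimen_{record_no}")
        coords.append(pts)
    if not coords:
        raise ValueError(f"{path}: no TPS records found")
    return LandmarkDataset(ids, np.stack(coords))


def write_tps(dataset: LandmarkDataset, path) -> Path:
    """Write a dataset as TPS; lossless round trip with :func:`read_tps`."""
    if len(dataset) == 0:
        raise ValueError("cannot write an empty dataset")
    path = Path(path)
    out = []
    for spec_id, cfg in zip(dataset.ids, dataset.coords):
        out.append(f"LM={dataset.k}")
        for x, y in cfg:
            out.append(f"{float(x)!r} {float(y)!r}")
        out.append(f"ID={spec_id}")
    path.write_text("\n".join(out) + "\n", encoding="utf-8")
    return path


def read_distance_matrix(path, format: str = "csv_square") -> DistanceMatrix:
    """Read a labelled square distance matrix.

    ``csv_square``: header row and index column with specimen labels.
    ``phylip``: first line is the taxon count, then one row per taxon with
    its label followed by n distances.
    """
    path = Path(path)
    if format == "csv_square":
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        labels = [str(x) for x in df.index]
        if [str(c) for c in df.columns] != labels:
            raise ValueError(f"{path}: row and column labels differ or matrix not square")
        return DistanceMatrix(labels, df.to_numpy(dtype=float))
    if format == "phylip":
        lines = [ln for ln in path.read_text(encoding="utf-8").splitlines() if ln.strip()]
        n = int(lines[0].split()[0])
        if len(lines) != n + 1:
            raise ValueError(f"{path}: expected {n} matrix rows, found {len(lines) - 1}")
        labels, rows = [], []
        for ln in lines[1:]:
            fields = ln.split()
            if len(fields) != n + 1:
                raise ValueError(f"{path}: matrix is not square ({len(fields) - 1} values in a row)")
            labels.append(fields[0])
            rows.append([float(x) for x in fields[1:]])
        return DistanceMatrix(labels, np.array(rows))
    raise ValueError(f"unknown distance-matrix format {format!r}")


def write_distance_matrix(dm: DistanceMatrix, path, format: str = "csv_square") -> Path:
    path = Path(path)
    if format == "csv_square":
        dm.to_frame().to_csv(path, float_format="%.17g")
    elif format == "phylip":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{dm.n}\n")
            for label, row in zip(dm.labels, dm.values):
                fh.write(label + " " + " ".join(repr(float(v)) for v in row) + "\n")
    else:
        raise ValueError(f"unknown distance-matrix format {format!r}")
    return path


# ---------------------------------------------------------------------------
# genotypes


def _parse_genepop_code(code: str, digits: int) -> tuple[int, int]:
    a = int(code[:digits])
    b = int(code[digits:])
    return (
        a if a > 0 else MISSING_ALLELE,
        b if b > 0 else MISSING_ALLELE,
    )


def read_genotypes(path, format: str = "genepop") -> GenotypeTable:
    """Read diploid genotypes from GenePop or CSV.

    GenePop: title line, locus names (one per line or comma-separated), then
    ``Pop`` blocks with lines ``id , code code ...`` using 2- or 3-digit
    allele coding; ``0000``/``000000`` marks a missing genotype.

    CSV: an ``id`` column followed by two columns per locus named
    ``<locus>_1``/``<locus>_2`` (0 or empty = missing).
    """
    path = Path(path)
    if format == "csv":
        df = pd.read_csv(path)
        id_col = df.columns[0]
        allele_cols = list(df.columns[1:])
        if len(allele_cols) % 2:
            raise ValueError(f"{path}: odd number of allele columns; need two per locus")
        loci = []
        for c1, c2 in zip(allele_cols[::2], allele_cols[1::2]):
            loci.append(re.sub(r"[._-]?[12ab]$", "", str(c1)) or str(c1))
        raw = df[allele_cols].fillna(0).to_numpy(dtype=int)
        alleles = raw.reshape(len(df), len(loci), 2)
        alleles = np.where(alleles <= 0, MISSING_ALLELE, alleles)
        return GenotypeTable(df[id_col].astype(str).tolist(), loci, alleles)

    if format != "genepop":
        raise ValueError(f"unknown genotype format {format!r}")

    lines = path.read_text(encoding="utf-8").splitlines()
    if len(lines) < 3:
        raise ValueError(f"{path}: not a GenePop file (too short)")
    body = lines[1:]
    loci: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        loci.extend(x.strip() for x in body[i].split(",") if x.strip())
        i += 1
    if i == len(body):
        raise ValueError(f"{path}: no 'Pop' line found")
    ids, rows = [], []
    digits: int | None = None
    for ln in body[i:]:
        s = ln.strip()
        if not s:
            continue
        if s.lower() == "pop":
            continue
        if "," not in s:
            raise ValueError(f"{path}: genotype line lacks the 'id ,' separator: {s!r}")
        name, _, geno = s.partition(",")
        codes = geno.split()
        if len(codes) != len(loci):
            raise ValueError(
                f"{path}: individual {name.strip()!r} has {len(codes)} genotypes, "
                f"expected {len(loci)}"
            )
        row = []
        for code in codes:
            if len(code) not in (4, 6) or not code.isdigit():
                raise ValueError(f"{path}: bad genotype code {code!r} for {name.strip()!r}")
            d = len(code) // 2
            if digits is None:
                digits = d
            elif d != digits:
                raise ValueError(f"{path}: mixed 2- and 3-digit allele coding")
            row.append(_parse_genepop_code(code, d))
        ids.append(name.strip())
        rows.append(row)
    return GenotypeTable(ids, loci, np.array(rows, dtype=int))


def write_genepop(g: GenotypeTable, path, title: str = "morphokaryo export",
                  pops: Sequence[Sequence[str]] | None = None, digits: int = 3) -> Path:
    """Write genotypes in GenePop format (one Pop block unless given)."""
    path = Path(path)
    if pops is None:
        pops = [g.ids]
    index = {s: i for i, s in enumerate(g.ids)}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(title + "\n")
        for locus in g.loci:
            fh.write(locus + "\n")
        for block in pops:
            fh.write("Pop\n")
            for spec_id in block:
                row = g.alleles[index[spec_id]]
                codes = []
                for a, b in row:
                    a = 0 if a == MISSING_ALLELE else a
                    b = 0 if b == MISSING_ALLELE else b
                    codes.append(f"{a:0{digits}d}{b:0{digits}d}")
                fh.write(f"{spec_id} , " + " ".join(codes) + "\n")
    return path


# ---------------------------------------------------------------------------
# metadata

REQUIRED_METADATA = ("specimen_id", "race", "population")


def read_metadata(path) -> pd.DataFrame:
    """Read the per-specimen metadata table (CSV).

    Requires ``specimen_id``, ``race`` and ``population`` columns; optional
    columns are ``locality``, ``weight``, ``geo_x``, ``geo_y`` (or
    ``lon``/``lat``) and ``karyotype``.  Validates id uniqueness and the
    nesting of populations within races.
    """
    df = pd.read_csv(path, dtype={"specimen_id": str})
    missing = [c for c in REQUIRED_METADATA if c not in df.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    if df["specimen_id"].duplicated().any():
        dup = df.loc[df["specimen_id"].duplicated(), "specimen_id"].tolist()
        raise ValueError(f"duplicate specimen ids in metadata: {dup}")
    races_per_pop = df.groupby("population")["race"].nunique()
    bad = races_per_pop[races_per_pop > 1]
    if len(bad):
        raise ValueError(
            f"populations spanning more than one race (nesting violated): {list(bad.index)}"
        )
    for col in ("geo_x", "geo_y", "lon", "lat"):
        if col in df.columns and not np.all(np.isfinite(df[col].to_numpy(float))):
            raise ValueError(f"non-finite values in metadata column {col!r}")
    if "weight" in df.columns:
        w = df["weight"].dropna()
        if (w <= 0).any():
            raise ValueError("weights must be positive")
    return df.set_index("specimen_id", drop=False)


def join_metadata(dataset: LandmarkDataset, metadata: pd.DataFrame) -> pd.DataFrame:
    """Return metadata rows in dataset order; aggregate error on unresolved ids."""
    unresolved = [s for s in dataset.ids if s not in metadata.index]
    if unresolved:
        raise KeyError(
            f"{len(unresolved)} specimen ids missing from metadata: {unresolved}"
        )
    return metadata.loc[dataset.ids]
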