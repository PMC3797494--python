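"""Readers and writers for the text formats the pipeline touches.

Genotypes come in two dialects:

* **GenePop 4.x** — title line, locus names (one per line or comma-separated),
  ``pop`` blocks, then ``id ,  040230 ...`` rows with 2- or 3-digit diploid
  allele encodings; ``00``/``000`` codes are missing.
* **delimited** — a header row ``id[,population][,cluster],locus1,...`` with
  calls written ``a/b`` (``0/0``, empty or ``NA`` for missing), tab- or
  comma-separated.

Coordinates are a delimited ``id,x,y`` table in meters. Run summaries are
flat ``key<TAB>value`` text.
"""

from __future__ import annotations

import io as _io
import re
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeDataset, SpatialCoordinates, ValidationError

__all__ = [
    "ParseError",
    "read_genotype_table",
    "read_genepop",
    "read_delimited_genotypes",
    "write_genepop",
    "write_delimited_genotypes",
    "read_coordinates",
    "write_coordinates",
    "write_summary",
    "read_summary",
]

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


def read_genotype_table(path: PathLike, format: str = "genepop") -> GenotypeDataset:
    """Dispatch to the named genotype dialect ('genepop' or 'delimited')."""
    if format == "genepop":
        return read_genepop(path)
    if format == "delimited":
        return read_delimited_genotypes(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def _split_allele_string(s: str, lineno: int) -> tuple[int, int]:
    if len(s) == 4:
        a, b = s[:2], s[2:]
    elif len(s) == 6:
        a, b = s[:3], s[3:]
    else:
        raise ParseError(
            f"line {lineno}: allele string {s!r} is not a 4- or 6-digit diploid code"
        )
    try:
        return int(a), int(b)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: non-numeric allele code in {s!r}") from exc


def read_genepop(path: PathLike) -> GenotypeDataset:
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise ParseError("file too short to be a GenePop table")
    # line 1 is a free-text title
    cursor = 1
    loci: list[str] = []
    while cursor < len(lines) and lines[cursor].strip().lower() != "pop":
        row = lines[cursor].strip()
        if row:
            loci.extend(name.strip() for name in row.split(",") if name.strip())
        cursor += 1
    if not loci:
        raise ParseError("no locus names before the first 'pop' line")
    ids: list[str] = []
    pops: list[str] = []
    calls: list[list[tuple[int, int]]] = []
    pop_index = 0
    for lineno0, raw in enumerate(lines[cursor:], start=cursor):
        line = raw.strip()
        lineno = lineno0 + 1
        if not line:
            continue
        if line.lower() == "pop":
            pop_index += 1
            continue
        if pop_index == 0:
            raise ParseError(f"line {lineno}: genotype row before any 'pop' line")
        if "," not in line:
            raise ParseError(f"line {lineno}: missing ',' separator after individual id")
        ind_id, rest = line.split(",", 1)
        alleles = rest.split()
        if len(alleles) != len(loci):
            raise ParseError(
                f"line {lineno}: {len(alleles)} genotype field(s) for {len(loci)} declared loci"
            )
        ids.append(ind_id.strip())
        pops.append(f"pop{pop_index}")
        calls.append([_split_allele_string(s, lineno) for s in alleles])
    if not ids:
        raise ParseError("no genotype rows found")
    return GenotypeDataset(
        individual_ids=ids,
        loci=loci,
        calls=np.array(calls, dtype=np.int64),
        population_labels=pops,
    )


def write_genepop(g: GenotypeDataset, path: PathLike, title: str = "sgskit export") -> None:
    """GenePop text with 3-digit allele codes; populations become pop blocks."""
    if int(g.calls.max(initial=0)) > 999:
        raise ValueError("allele codes above 999 cannot be written as GenePop")
    pops = g.population_labels or ["pop1"] * g.n_individuals
    buf = _io.StringIO()
    buf.write(title + "\n")
    for locus in g.loci:
        buf.write(locus + "\n")
    current = None
    for i, ind in enumerate(g.individual_ids):
        if pops[i] != current:
            buf.write("pop\n")
            current = pops[i]
        row = " ".join(f"{a:03d}{b:03d}" for a, b in g.calls[i])
        buf.write(f"{ind} , {row}\n")
    Path(path).write_text(buf.getvalue())


_CALL_RE = re.compile(r"^\s*(\d+)\s*/\s*(\d+)\s*$")


def read_delimited_genotypes(path: PathLike) -> GenotypeDataset:
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except Exception as exc:
        raise ParseError(f"cannot parse delimited genotype table: {exc}") from exc
    if df.empty:
        raise ParseError("no records")
    cols = list(df.columns)
    if not cols or cols[0].lower() != "id":
        raise ParseError("first column must be 'id'")
    meta = {"population": None, "cluster": None}
    locus_start = 1
    for name in cols[1:3]:
        if name.lower() in meta:
            meta[name.lower()] = df[name].tolist()
            locus_start += 1
        else:
            break
    loci = cols[locus_start:]
    if not loci:
        raise ParseError("no locus columns after id/label columns")
    calls = np.zeros((len(df), len(loci), 2), dtype=np.int64)
    for j, locus in enumerate(loci):
        for i, cell in enumerate(df[locus].tolist()):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                continue
            text = str(cell).strip()
            if text in ("", "NA", "na", "-"):
                continue
            m = _CALL_RE.match(text)
            if not m:
                raise ParseError(
                    f"line {i + 2}: call {text!r} at locus {locus} is not 'a/b'"
                )
            calls[i, j] = (int(m.group(1)), int(m.group(2)))
    return GenotypeDataset(
        individual_ids=df[cols[0]].tolist(),
        loci=loci,
        calls=calls,
        population_labels=meta["population"],
        cluster_labels=meta["cluster"],
    )


def write_delimited_genotypes(g: GenotypeDataset, path: PathLike, sep: str = "\t") -> None:
    cols = {"id": g.individual_ids}
    if g.population_labels is not None:
        cols["population"] = g.population_labels
    if g.cluster_labels is not None:
        cols["cluster"] = g.cluster_labels
    for j, locus in enumerate(g.loci):
        cols[locus] = [f"{a}/{b}" for a, b in g.calls[:, j]]
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False)


def read_coordinates(path: PathLike) -> SpatialCoordinates:
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:
        raise ParseError(f"cannot parse coordinate table: {exc}") from exc
    if df.empty:
        raise ParseError("no records")
    cols = {c.lower(): c for c in df.columns}
    for required in ("id", "x", "y"):
        if required not in cols:
            raise ParseError(f"coordinate table lacks required column {required!r}")
    x = pd.to_numeric(df[cols["x"]], errors="coerce")
    y = pd.to_numeric(df[cols["y"]], errors="coerce")
    bad = df.index[x.isna() | y.isna()]
    if len(bad):
        raise ParseError(f"line {bad[0] + 2}: non-numeric coordinate")
    wrap = None
    if "wrap" in cols:  # periodic (simulated torus) domain marker
        wrap_vals = pd.to_numeric(df[cols["wrap"]], errors="coerce").unique()
        if len(wrap_vals) != 1 or np.isnan(wrap_vals[0]):
            raise ParseError("wrap column must hold one constant numeric value")
        wrap = float(wrap_vals[0])
    return SpatialCoordinates(
        individual_ids=df[cols["id"]].astype(str).tolist(),
        x=x.to_numpy(),
        y=y.to_numpy(),
        wrap=wrap,
    )


def write_coordinates(c: SpatialCoordinates, path: PathLike, sep: str = "\t") -> None:
    data = {"id": c.individual_ids, "x": c.x, "y": c.y}
    if c.wrap is not None:
        data["wrap"] = [c.wrap] * c.n_individuals
    pd.DataFrame(data).to_csv(path, sep=sep, index=False)


def write_summary(pairs: dict, path: PathLike) -> None:
    """Flat key–value run summary (one ``key<TAB>value`` per line)."""
    with open(path, "w") as fh:
        for key, value in pairs.items():
            fh.write(f"{key}\t{value}\n")


def read_summary(path: PathLike) -> dict:
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        key, _, value = line.partition("\t")
        out[key] = value
    return out
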