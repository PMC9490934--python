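"""Readers and writers for every file the pipeline touches.

All tabular formats are TSV (UTF-8, decimal point); gene sets use the
standard GMT dialect; networks are exported as SIF-style TSV for import
into graph viewers such as Cytoscape.

In-memory containers are deliberately plain:

* expression matrix -- :class:`pandas.DataFrame`, genes x samples,
  normalized log2 intensities;
* probe annotation -- :class:`pandas.DataFrame` indexed by gene id with
  ``symbol`` and ``biotype`` columns (biotype in {"lncRNA", "mRNA"});
* sample table -- :class:`pandas.DataFrame` indexed by sample id with an
  integer ``day`` column;
* edge list -- :class:`pandas.DataFrame` with ``gene_a``/``gene_b``
  columns, canonicalized so gene_a < gene_b lexicographically;
* gene sets -- :class:`GeneSetCollection`.

Readers validate rather than coerce: duplicate identifiers, non-numeric
cells and malformed lines raise :class:`FormatError`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BIOTYPES = ("lncRNA", "mRNA")


class FormatError(ValueError):
    """Malformed input file (duplicates, bad cells, short lines)."""


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions, GMT-round-trippable.

    ``sets`` maps set name -> member list (order preserved, unique);
    ``descriptions`` maps set name -> free-text description.
    """

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def add(self, name: str, members: list[str], description: str = "") -> None:
        if not members:
            raise FormatError(f"gene set {name!r} has no members")
        self.sets[name] = list(dict.fromkeys(members))
        self.descriptions[name] = description


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV of log2 intensities.

    First column holds gene ids, header row holds sample ids. Raises
    :class:`FormatError` on duplicate ids, non-numeric or non-finite cells.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    dup = df.index[df.index.duplicated()].unique()
    if len(dup):
        raise FormatError(f"duplicate gene id(s): {', '.join(map(str, dup))}")
    dup = df.columns[df.columns.duplicated()].unique()
    if len(dup):
        raise FormatError(f"duplicate sample id(s): {', '.join(map(str, dup))}")
    values = df.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-numeric cell at gene {df.index[r]!r}, sample {df.columns[c]!r}: "
            f"{df.iat[r, c]!r}"
        )
    if not np.isfinite(values.to_numpy()).all():
        raise FormatError("expression matrix contains missing or non-finite values")
    # re-parse through Python float(): correctly rounded, so write->read
    # round-trips to the exact same float64 bits
    return df.apply(lambda col: col.map(float))


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    # %.17g guarantees float64 round-trip through text
    matrix.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


# ---------------------------------------------------------------------------
# annotation and sample metadata
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read probe annotation TSV: gene_id, symbol, biotype."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    missing = {"symbol", "biotype"} - set(df.columns)
    if missing:
        raise FormatError(f"annotation missing column(s): {sorted(missing)}")
    dup = df.index[df.index.duplicated()].unique()
    if len(dup):
        raise FormatError(f"duplicate gene id(s) in annotation: {', '.join(dup)}")
    bad = set(df["biotype"]) - set(BIOTYPES)
    if bad:
        raise FormatError(f"unknown biotype(s): {sorted(bad)}; expected {BIOTYPES}")
    return df[["symbol", "biotype"]]


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t", index_label="gene_id")


def read_samples(path: str | Path, expression: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read sample metadata TSV: sample_id, day (non-negative integer).

    If ``expression`` is given, every expression sample id must be present.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "day" not in df.columns:
        raise FormatError("sample table missing 'day' column")
    days = pd.to_numeric(df["day"], errors="coerce")
    if days.isna().any() or (days < 0).any():
        raise FormatError("sample days must be non-negative numbers")
    df = df.assign(day=days.astype(int))
    if df["day"].nunique() < 2:
        raise FormatError("sample table must contain at least 2 distinct days")
    if expression is not None:
        missing = set(expression.columns) - set(df.index)
        if missing:
            raise FormatError(f"sample table missing expression sample(s): {sorted(missing)}")
    return df[["day"]]


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# edge lists
# ---------------------------------------------------------------------------

def canonical_edges(pairs) -> pd.DataFrame:
    """Canonicalize undirected edges: lexicographic order within each pair,
    self-loops dropped, duplicates removed, rows sorted."""
    edges = set()
    n_loops = 0
    for a, b in pairs:
        a, b = str(a), str(b)
        if a == b:
            n_loops += 1
            continue
        edges.add((a, b) if a < b else (b, a))
    if n_loops:
        logger.warning("dropped %d self-loop(s)", n_loops)
    out = pd.DataFrame(sorted(edges), columns=["gene_a", "gene_b"], dtype=str)
    return out


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Read a >= 2-column TSV edge list; extra columns (scores) are ignored."""
    pairs = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"edge list line {lineno}: fewer than 2 columns")
            pairs.append((fields[0], fields[1]))
    if not pairs:
        logger.warning("edge list %s is empty", path)
    return canonical_edges(pairs)


def write_edge_list(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def write_sif(edges: pd.DataFrame, path: str | Path, interaction: str | None = None) -> None:
    """Write edges as SIF-style TSV (source, interaction type, target).

    If the frame has an ``edge_type`` column it is used as the interaction
    type; otherwise ``interaction`` (default "co") labels every edge.
    """
    kind = edges["edge_type"] if "edge_type" in edges.columns else interaction or "co"
    out = pd.DataFrame(
        {"source": edges["gene_a"], "interaction": kind, "target": edges["gene_b"]}
    )
    out.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name TAB description TAB member [TAB member ...]."""
    coll = GeneSetCollection()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno}: fewer than 3 fields")
            coll.add(fields[0], fields[2:], description=fields[1])
    return coll


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")
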