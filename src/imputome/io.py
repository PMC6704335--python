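"""Readers and writers for every file the pipeline touches.

All tabular formats are plain TSV.  The canonical in-memory orientation for
abundance tables is samples-as-rows; on disk the classic OTU-table dialect
(OTUs as rows, first column of ids, header row of sample ids) is the default,
and orientation is auto-detected from id overlap with the sample metadata
when provided.

Writers are deterministic (stable row/column order); floats are serialized
with 6 significant digits.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = {"k": "kingdom", "p": "phylum", "c": "class", "o": "order",
                 "f": "family", "g": "genus", "s": "species"}
UNCLASSIFIED = "unclassified"

GROUPS = ("Vata", "Pitta", "Kapha")
GENDERS = ("F", "M")

TRAIT_VOCABULARY = (
    "aerobic", "anaerobic", "facultative_anaerobic",
    "gram_negative", "gram_positive",
    "potential_pathogen", "mobile_elements", "biofilm_forming",
    "stress_tolerant",
)


class ParseError(ValueError):
    """A file violated the format contract; the message names the line."""


def _fmt(x) -> str:
    """Serialize a scalar: integers exactly, floats at 6 significant digits."""
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    f = float(x)
    if f == int(f) and abs(f) < 1e15:
        return str(int(f))
    return format(f, ".6g")


def _check_nonempty(path: Path) -> None:
    if path.stat().st_size == 0:
        raise ParseError(f"{path}: file is empty")


def _read_matrix_tsv(path) -> pd.DataFrame:
    """Read a TSV matrix with row ids in the first column, checking shape."""
    path = Path(path)
    _check_nonempty(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ncol = len(header)
        rows, index = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != ncol:
                raise ParseError(
                    f"{path}:{lineno}: ragged row ({len(parts)} fields, "
                    f"expected {ncol})")
            index.append(parts[0])
            rows.append(parts[1:])
    cols = header[1:]
    if len(set(index)) != len(index):
        raise ParseError(f"{path}: duplicate row ids")
    if len(set(cols)) != len(cols):
        raise ParseError(f"{path}: duplicate column ids")
    try:
        values = np.asarray(rows, dtype=float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric value ({exc})") from None
    return pd.DataFrame(values, index=index, columns=cols)


def _write_matrix_tsv(df: pd.DataFrame, path, index_name: str) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(index_name + "\t" + "\t".join(map(str, df.columns)) + "\n")
        for rid, row in zip(df.index, df.to_numpy()):
            fh.write(str(rid) + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# OTU tables
# ---------------------------------------------------------------------------

def read_otu_table(path, metadata: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a classic OTU table into a samples x OTUs DataFrame.

    The classic dialect stores OTUs as rows.  If ``metadata`` is given,
    orientation is detected by intersecting row/column ids with the metadata
    sample ids; otherwise OTUs-as-rows is assumed and the table transposed.

    Raises :class:`ParseError` on empty files, ragged rows, duplicate ids or
    negative values (the offending line is named where possible).
    """
    path = Path(path)
    df = _read_matrix_tsv(path)
    neg = df.to_numpy() < 0
    if neg.any():
        i = int(np.argwhere(neg)[0, 0])
        raise ParseError(f"{path}:{i + 2}: negative count in row {df.index[i]!r}")
    if not np.isfinite(df.to_numpy()).all():
        raise ParseError(f"{path}: non-finite value")
    if metadata is not None:
        samples = set(metadata.index)
        row_hits = len(samples.intersection(df.index))
        col_hits = len(samples.intersection(df.columns))
        if row_hits >= col_hits and row_hits > 0:
            return df  # samples already as rows
        return df.T
    return df.T  # classic dialect: OTUs as rows on disk


def write_otu_table(table: pd.DataFrame, path) -> None:
    """Write a samples x OTUs table in the classic dialect (OTUs as rows)."""
    _write_matrix_tsv(table.T, path, "#OTU ID")


def read_biom_json(path) -> pd.DataFrame:
    """Read a BIOM v1 (JSON) OTU table into a samples x OTUs DataFrame.

    Supports both dense and sparse matrix_type.  BIOM stores observations
    (OTUs) as rows; the result is transposed to the canonical orientation.
    """
    path = Path(path)
    _check_nonempty(path)
    with open(path) as fh:
        doc = json.load(fh)
    otu_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    mat = np.zeros((len(otu_ids), len(sample_ids)))
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    else:
        mat[:] = np.asarray(doc["data"], dtype=float)
    if (mat < 0).any():
        raise ParseError(f"{path}: negative count in BIOM data")
    return pd.DataFrame(mat, index=otu_ids, columns=sample_ids).T


# ---------------------------------------------------------------------------
# Taxonomy lineages
# ---------------------------------------------------------------------------

def parse_lineage(lineage: str) -> tuple[str, ...]:
    """Parse a greengenes-style ``k__X; p__Y; ...`` string into 7 ranks.

    Rank prefixes are stripped; empty or missing ranks become "unclassified".
    Unknown rank prefixes raise :class:`ParseError`.
    """
    out = {r: UNCLASSIFIED for r in RANKS}
    for field in lineage.split(";"):
        field = field.strip()
        if not field:
            continue
        if len(field) < 3 or field[1:3] != "__":
            raise ParseError(f"malformed lineage field {field!r}")
        prefix, name = field[0], field[3:].strip()
        if prefix not in RANK_PREFIXES:
            raise ParseError(f"unknown rank prefix {prefix!r} in {field!r}")
        out[RANK_PREFIXES[prefix]] = name if name else UNCLASSIFIED
    return tuple(out[r] for r in RANKS)


def read_lineages(path) -> pd.DataFrame:
    """Read a two-column TSV of (otu_id, lineage) into an OTU x rank frame."""
    path = Path(path)
    _check_nonempty(path)
    records, index = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or (lineno == 1 and line.lower().startswith(("#otu", "otu_id"))):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            try:
                ranks = parse_lineage(parts[1])
            except ParseError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            index.append(parts[0])
            records.append(ranks)
    if len(set(index)) != len(index):
        raise ParseError(f"{path}: duplicate OTU ids")
    return pd.DataFrame(records, index=index, columns=list(RANKS))


def write_lineages(taxonomy: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("#OTU ID\tlineage\n")
        for otu, row in taxonomy.iterrows():
            fields = []
            for rank, prefix in zip(RANKS, "kpcofgs"):
                name = row[rank]
                fields.append(f"{prefix}__{'' if name == UNCLASSIFIED else name}")
            fh.write(f"{otu}\t" + "; ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata (sample_id, group, gender) indexed by sample."""
    path = Path(path)
    _check_nonempty(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"sample_id", "group", "gender"}
    if not needed.issubset(df.columns):
        raise ParseError(f"{path}: metadata needs columns {sorted(needed)}")
    if df["sample_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample ids")
    bad = set(df["group"]) - set(GROUPS)
    if bad:
        raise ParseError(f"{path}: unknown group(s) {sorted(bad)}")
    bad = set(df["gender"]) - set(GENDERS)
    if bad:
        raise ParseError(f"{path}: unknown gender(s) {sorted(bad)}")
    return df.set_index("sample_id")


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.rename_axis("sample_id").reset_index().to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# 16S copy numbers, gene content, hierarchy, traits
# ---------------------------------------------------------------------------

def read_copy_numbers(path) -> pd.Series:
    path = Path(path)
    _check_nonempty(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    ser = df.iloc[:, 0].astype(float)
    if (ser <= 0).any():
        bad = ser.index[ser <= 0][0]
        raise ParseError(f"{path}: non-positive copy number for {bad!r}")
    if ser.index.duplicated().any():
        raise ParseError(f"{path}: duplicate OTU ids")
    return ser


def write_copy_numbers(copies: pd.Series | Mapping, path) -> None:
    ser = pd.Series(copies)
    with open(path, "w") as fh:
        fh.write("#OTU ID\t16S_copies\n")
        for otu, v in ser.items():
            fh.write(f"{otu}\t{_fmt(v)}\n")


def read_gene_content(path) -> pd.DataFrame:
    """Read an OTU x gene-family copy matrix; values must be >= 0."""
    df = _read_matrix_tsv(Path(path))
    if (df.to_numpy() < 0).any():
        raise ParseError(f"{path}: negative gene copy number")
    return df


def write_gene_content(gc: pd.DataFrame, path) -> None:
    _write_matrix_tsv(gc, path, "#OTU ID")


def read_hierarchy(path) -> pd.DataFrame:
    """Read the 4-column function hierarchy TSV.

    One row per (function, level-3 pathway) pair, with the level-2 and
    level-1 parents; a gene family may map to several level-3 pathways, but
    each level-3 pathway has exactly one level-2 parent.
    """
    path = Path(path)
    _check_nonempty(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = ["function", "level3", "level2", "level1"]
    if list(df.columns) != needed:
        raise ParseError(f"{path}: hierarchy needs columns {needed}")
    l3_parents = df.groupby("level3")["level2"].nunique()
    if (l3_parents > 1).any():
        bad = l3_parents.index[l3_parents > 1][0]
        raise ParseError(f"{path}: level-3 pathway {bad!r} has multiple level-2 parents")
    if df.duplicated(["function", "level3"]).any():
        raise ParseError(f"{path}: duplicate (function, level3) pair")
    return df


def write_hierarchy(hierarchy: pd.DataFrame, path) -> None:
    hierarchy.to_csv(path, sep="\t", index=False)


def read_traits(path) -> pd.DataFrame:
    """Read an OTU x trait membership matrix with values in [0, 1]."""
    df = _read_matrix_tsv(Path(path))
    vals = df.to_numpy()
    if ((vals < 0) | (vals > 1)).any():
        raise ParseError(f"{path}: trait membership outside [0, 1]")
    unknown = set(df.columns) - set(TRAIT_VOCABULARY)
    if unknown:
        raise ParseError(f"{path}: unknown trait(s) {sorted(unknown)}")
    return df


def write_traits(traits: pd.DataFrame, path) -> None:
    _write_matrix_tsv(traits, path, "#OTU ID")


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

def write_network_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def write_network_edgelist(graph: nx.Graph, path) -> None:
    """Write the undirected edge list as TSV with r and p attributes."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\tr\tp\n")
        for u, v, d in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{_fmt(d.get('r', float('nan')))}\t"
                     f"{_fmt(d.get('p', float('nan')))}\n")


def read_network_edgelist(path) -> nx.Graph:
    path = Path(path)
    _check_nonempty(path)
    g = nx.Graph()
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("source\ttarget"):
            raise ParseError(f"{path}: bad edge-list header")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            g.add_edge(parts[0], parts[1], r=float(parts[2]), p=float(parts[3]))
    return g
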