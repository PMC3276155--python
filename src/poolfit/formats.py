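"""Readers and writers for every file the pipeline touches.

All files are UTF-8, LF-terminated, tab-delimited text: scan tables (a
minimal named-column TSV with a GenePix GPR import shim), strain keys,
GMT gene-set files, Cluster 3.0-style CDT/GTR pairs and flat results
tables.  Writers followed by their readers are identity on content.
"""

from __future__ import annotations

from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError

if TYPE_CHECKING:  # pragma: no cover
    from .cluster import Dendrogram

SCAN_COLUMNS = [
    "array_id",
    "day",
    "strain_id",
    "tag_kind",
    "replicate_index",
    "fg_exp",
    "bg_exp",
    "fg_ctl",
    "bg_ctl",
    "flag",
]

KEY_COLUMNS = [
    "strain_id",
    "gene",
    "zygosity",
    "in_pool",
    "annotation_class",
    "has_up_tag",
    "has_dn_tag",
]

#: GenePix channel conventions: Cy5 (635 nm) is the experimental sample,
#: Cy3 (532 nm) the day-1 control.
GPR_COLUMN_MAP = {
    "F635 Median": "fg_exp",
    "B635 Median": "bg_exp",
    "F532 Median": "fg_ctl",
    "B532 Median": "bg_ctl",
}

_TRUE = {"1", "true", "yes", "t", "y"}
_FALSE = {"0", "false", "no", "f", "n"}


def _parse_bool(value, column: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise FormatError(f"cannot parse {value!r} as boolean in column {column!r}")


def read_scan_table(path) -> pd.DataFrame:
    """Read a scan-table TSV into one SpotRecord row per data row.

    Rows flagged ``discarded`` are retained but marked; intensities must be
    nonnegative (a negative value is reported with its 1-based data row
    number).  Column order in the file is free.
    """
    df = pd.read_csv(path, sep="\t")
    for col in SCAN_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"scan table {path} is missing required column {col!r}")
    for col in ("fg_exp", "bg_exp", "fg_ctl", "bg_ctl"):
        vals = pd.to_numeric(df[col], errors="raise")
        neg = np.where(vals.to_numpy() < 0)[0]
        if neg.size:
            raise FormatError(
                f"negative intensity in column {col!r} at data row {neg[0] + 1} of {path}"
            )
        df[col] = vals.astype(float)
    bad = ~df["tag_kind"].isin(["UP", "DN"])
    if bad.any():
        raise FormatError(
            f"invalid tag_kind {df.loc[bad, 'tag_kind'].iloc[0]!r} in {path}"
        )
    df["flag"] = df["flag"].astype(str)
    df["replicate_index"] = df["replicate_index"].astype(int)
    df["day"] = df["day"].astype(int)
    return df[SCAN_COLUMNS + [c for c in df.columns if c not in SCAN_COLUMNS]]


def write_scan_table(spots: pd.DataFrame, path) -> None:
    spots = spots[SCAN_COLUMNS]
    spots.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_gpr_table(path, array_id: str, day: int) -> pd.DataFrame:
    """Import a GenePix GPR-style intensity table as a scan table.

    Expects ``Name`` rows encoded ``<strain_id>:<UP|DN>:<replicate>`` plus
    the four median foreground/background columns; ``Flags`` < 0 (the
    GenePix bad/absent convention) maps to ``discarded``.
    """
    df = pd.read_csv(path, sep="\t")
    for col in GPR_COLUMN_MAP:
        if col not in df.columns:
            raise FormatError(f"GPR file {path} is missing column {col!r}")
    if "Name" not in df.columns:
        raise FormatError(f"GPR file {path} is missing column 'Name'")
    parts = df["Name"].astype(str).str.split(":", expand=True)
    if parts.shape[1] < 3 or parts.isna().any().any():
        raise FormatError(f"GPR Name column in {path} must be 'strain:tag:replicate'")
    flags = (
        pd.to_numeric(df["Flags"], errors="coerce").fillna(0)
        if "Flags" in df.columns
        else pd.Series(0, index=df.index)
    )
    out = pd.DataFrame(
        {
            "array_id": array_id,
            "day": day,
            "strain_id": parts[0],
            "tag_kind": parts[1],
            "replicate_index": parts[2].astype(int),
            "fg_exp": pd.to_numeric(df["F635 Median"]),
            "bg_exp": pd.to_numeric(df["B635 Median"]),
            "fg_ctl": pd.to_numeric(df["F532 Median"]),
            "bg_ctl": pd.to_numeric(df["B532 Median"]),
            "flag": np.where(flags < 0, "discarded", "ok"),
        }
    )
    bad = ~out["tag_kind"].isin(["UP", "DN"])
    if bad.any():
        raise FormatError(f"invalid tag kind in GPR Name column of {path}")
    return out


def read_key(path) -> pd.DataFrame:
    """Read the strain key; strain_id must be unique, booleans dialect-free."""
    df = pd.read_csv(path, sep="\t")
    for col in ("strain_id", "gene", "in_pool"):
        if col not in df.columns:
            raise FormatError(f"key {path} is missing required column {col!r}")
    dups = df["strain_id"][df["strain_id"].duplicated()]
    if len(dups):
        raise FormatError(f"duplicate strain_id {dups.iloc[0]!r} in key {path}")
    df["in_pool"] = df["in_pool"].map(lambda v: _parse_bool(v, "in_pool"))
    for col in ("has_up_tag", "has_dn_tag"):
        if col in df.columns:
            df[col] = df[col].map(lambda v: _parse_bool(v, col))
    return df


def write_key(key: pd.DataFrame, path) -> None:
    key.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_gmt(path) -> dict[str, dict]:
    """Read a GMT gene-set file: ``name<TAB>description<TAB>member...``.

    Duplicate members within a line are dropped (order preserved); lines
    with fewer than three fields, and sets left empty, are format errors
    reported with their 1-based line number.
    """
    sets: dict[str, dict] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno} of {path} has fewer than 3 fields")
            name, desc = fields[0], fields[1]
            members = list(dict.fromkeys(m for m in fields[2:] if m))
            if not members:
                raise FormatError(f"GMT line {lineno} of {path} defines an empty set")
            if name in sets:
                raise FormatError(f"duplicate category {name!r} at GMT line {lineno}")
            sets[name] = {"description": desc, "members": members}
    return sets


def write_gmt(sets: dict[str, dict], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, rec in sets.items():
            fh.write("\t".join([name, rec["description"], *rec["members"]]) + "\n")


def write_cdt_gtr(
    matrix: pd.DataFrame,
    tree: "Dendrogram",
    cdt_path,
    gtr_path,
    gene_names: pd.Series | None = None,
) -> None:
    """Emit the CDT/GTR pair that Java TreeView-class software reads.

    The GTR lists merges bottom-up as ``NODEkX`` joining two child ids at a
    similarity of 1 - distance; CDT rows appear in dendrogram leaf order
    with a GID column linking them to the tree.  Missing values are
    serialized as empty fields (the TreeView convention).
    """
    n = len(matrix)
    if tree.n_leaves != n or sorted(tree.leaf_order) != list(range(n)):
        raise ConsistencyError("dendrogram leaves do not match matrix rows 1:1")

    def node_name(node_id: int) -> str:
        if node_id < n:
            return f"GENE{node_id}X"
        return f"NODE{node_id - n + 1}X"

    with open(gtr_path, "w", encoding="utf-8", newline="\n") as fh:
        for k, (a, b, dist) in enumerate(tree.merges, start=1):
            fh.write(
                f"NODE{k}X\t{node_name(a)}\t{node_name(b)}\t{1.0 - dist:.6g}\n"
            )

    ids = matrix.index.astype(str)
    names = (
        gene_names.astype(str).reset_index(drop=True)
        if gene_names is not None
        else pd.Series(ids)
    )
    cols = [str(c) for c in matrix.columns]
    with open(cdt_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("GID\tORF\tNAME\tGWEIGHT\t" + "\t".join(cols) + "\n")
        fh.write("EWEIGHT\t\t\t\t" + "\t".join(["1"] * len(cols)) + "\n")
        for row_idx in tree.leaf_order:
            vals = matrix.iloc[row_idx]
            cells = ["" if pd.isna(v) else repr(float(v)) for v in vals]
            fh.write(
                f"GENE{row_idx}X\t{ids[row_idx]}\t{names.iloc[row_idx]}\t1\t"
                + "\t".join(cells)
                + "\n"
            )


def read_cdt(path) -> pd.DataFrame:
    """Read back a CDT written by :func:`write_cdt_gtr` (row order = leaf order)."""
    df = pd.read_csv(path, sep="\t", skiprows=[1], dtype={"GID": str})
    for col in ("GID", "ORF", "NAME", "GWEIGHT"):
        if col not in df.columns:
            raise FormatError(f"CDT {path} is missing column {col!r}")
    data = df.drop(columns=["GID", "NAME", "GWEIGHT"]).set_index("ORF")
    data.index.name = None
    return data.astype(float)


def write_results_table(results: pd.DataFrame, path) -> None:
    """Write a flat results TSV; enrichment tables are sorted by adjusted P."""
    out = results
    if "p_adj" in results.columns:
        out = results.sort_values(["p_adj", "p_raw"], kind="stable")
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")
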