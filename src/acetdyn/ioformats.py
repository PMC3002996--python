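"""On-disk formats for the pipeline: probe tables, expression tables, GMT gene sets.

All tabular formats are plain TSV (UTF-8, no index column, ``.`` for missing
values) so that round trips are bit-exact and diffs are meaningful.

Column contracts
----------------
Probe table (``read_probe_table`` / ``write_probe_table``)::

    probe_id    gene_id    offset_bp    day    replicate    signal

``gene_id`` is ``.`` for control probes (which also carry no offset);
``offset_bp`` is the signed distance to the TSS, oriented 5'->3' along the
gene (0 = TSS, positive = downstream). ``signal`` is the background-subtracted
log-scale intensity. ``(probe_id, day, replicate)`` is a unique key.

Expression table (``read_expression_table`` / ``write_expression_table``)::

    gene_id    day    replicate    expression

``(gene_id, day, replicate)`` unique; day 0 must be present for every gene.

Gene sets use the standard GMT dialect: one set per line,
``name <tab> description <tab> member1 <tab> member2 ...``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

PROBE_COLUMNS = ["probe_id", "gene_id", "offset_bp", "day", "replicate", "signal"]
EXPR_COLUMNS = ["gene_id", "day", "replicate", "expression"]

MISSING = "."


class FormatError(ValueError):
    """A file violated its documented column contract."""


@dataclass
class GeneSetCollection:
    """Named, ordered gene-id sets with free-text descriptions.

    Member order within a set is preserved (GMT files are ordered); set names
    are unique and sets are non-empty.
    """

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
        for name in self.sets:
            self.descriptions.setdefault(name, "")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")


def _check_unique(df: pd.DataFrame, key: list[str], path) -> None:
    dup = df.duplicated(subset=key)
    if dup.any():
        row = df.loc[dup.idxmax()]
        keyval = tuple(row[k] for k in key)
        raise FormatError(
            f"{path}: duplicated key {key} = {keyval} at row {int(dup.idxmax())}"
        )


def _check_numeric(df: pd.DataFrame, col: str, path, allow_na: bool = False) -> pd.Series:
    coerced = pd.to_numeric(df[col], errors="coerce")
    bad = coerced.isna() & df[col].notna()
    if bad.any():
        i = int(bad.idxmax())
        raise FormatError(f"{path}: non-numeric {col}={df[col][i]!r} at row {i}")
    if not allow_na and coerced.isna().any():
        i = int(coerced.isna().idxmax())
        raise FormatError(f"{path}: missing {col} at row {i}")
    return coerced


def canonicalize_probe_table(table: pd.DataFrame) -> pd.DataFrame:
    """Stable row order (probe_id, day, replicate) and column order."""
    return (
        table[PROBE_COLUMNS]
        .sort_values(["probe_id", "day", "replicate"], kind="mergesort")
        .reset_index(drop=True)
    )


def read_probe_table(path) -> pd.DataFrame:
    """Read and validate a probe-level acetylation table.

    Control probes come back with ``gene_id`` = NaN. Raises
    :class:`FormatError` naming the offending row for missing columns,
    duplicate ``(probe_id, day, replicate)`` keys or non-numeric signal.
    """
    df = pd.read_csv(
        path, sep="\t", dtype={"probe_id": str, "gene_id": str},
        na_values=[MISSING], keep_default_na=False,
    )
    _require_columns(df, PROBE_COLUMNS, path)
    if len(df) == 0:
        return df[PROBE_COLUMNS]
    df["signal"] = _check_numeric(df, "signal", path)
    df["offset_bp"] = _check_numeric(df, "offset_bp", path, allow_na=True)
    df["day"] = _check_numeric(df, "day", path).astype(int)
    df["replicate"] = _check_numeric(df, "replicate", path).astype(int)
    _check_unique(df, ["probe_id", "day", "replicate"], path)
    return df[PROBE_COLUMNS]


def write_probe_table(table: pd.DataFrame, path) -> None:
    canonicalize_probe_table(table).to_csv(
        path, sep="\t", index=False, na_rep=MISSING
    )


def read_expression_table(path) -> pd.DataFrame:
    """Read and validate a gene x day x replicate expression table."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str},
                     na_values=[MISSING], keep_default_na=False)
    _require_columns(df, EXPR_COLUMNS, path)
    if len(df) == 0:
        return df[EXPR_COLUMNS]
    df["expression"] = _check_numeric(df, "expression", path)
    df["day"] = _check_numeric(df, "day", path).astype(int)
    df["replicate"] = _check_numeric(df, "replicate", path).astype(int)
    _check_unique(df, ["gene_id", "day", "replicate"], path)
    no_day0 = set(df["gene_id"]) - set(df.loc[df["day"] == 0, "gene_id"])
    if no_day0:
        raise FormatError(
            f"{path}: {len(no_day0)} gene(s) lack day-0 rows, e.g. {sorted(no_day0)[0]!r}"
        )
    return df[EXPR_COLUMNS]


def write_expression_table(table: pd.DataFrame, path) -> None:
    (
        table[EXPR_COLUMNS]
        .sort_values(["gene_id", "day", "replicate"], kind="mergesort")
        .reset_index(drop=True)
        .to_csv(path, sep="\t", index=False, na_rep=MISSING)
    )


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file, preserving member order."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicated set name {name!r}")
            if not members:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def filter_genes(
    probe_table: pd.DataFrame, min_probes: int = 10, window_bp: float = 3500
) -> pd.DataFrame:
    """Keep genes represented by strictly more than ``min_probes`` distinct
    probes within ``±window_bp`` of the TSS.

    Control probes (no gene assignment) are always retained. The filter is a
    gene-level decision: all rows of a kept gene survive, even probes outside
    the window. Idempotent.
    """
    genic = probe_table[probe_table["gene_id"].notna()]
    in_window = genic[genic["offset_bp"].abs() <= window_bp]
    counts = in_window.groupby("gene_id")["probe_id"].nunique()
    keep = set(counts.index[counts > min_probes])
    mask = probe_table["gene_id"].isna() | probe_table["gene_id"].isin(keep)
    return probe_table[mask].reset_index(drop=True)


def write_truth_labels(truth: Mapping[str, str] | pd.Series, path) -> None:
    """Two-column TSV gene_id -> label in {up, down, stable}."""
    s = pd.Series(truth, name="label")
    s.rename_axis("gene_id").sort_index().to_frame().to_csv(path, sep="\t")


def read_truth_labels(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["gene_id", "label"], path)
    return df.set_index("gene_id")["label"]


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
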