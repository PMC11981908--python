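"""Tabular I/O for DEG tables, functional-bin maps, manifests and result tables.

All artifacts are tab-separated UTF-8 text with a mandatory header row.
Numbers are serialized with fixed formatting so that write -> read is the
identity on every output schema; undefined percentages use the literal
token ``na`` and no-change pattern labels the token ``nc``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._common import FormatError, IntegrityError

NOT_ASSIGNED = "Not assigned"
NA_TOKEN = "na"

#: Controlled vocabulary for soil-water status at a sampling point:
#: pre-water-deficit, water deficit, well-watered/recovery, final harvest.
WATER_STATUSES = frozenset({"pwd", "wd", "ww", "rec", "harvest"})
STAGES = tuple(f"R{i}" for i in range(2, 9))

_BIN_CODE_RE = re.compile(r"^\d+(\.\d+)*$")


@dataclass(frozen=True)
class DEGRecord:
    """One gene's differential-expression result in one pairwise comparison."""

    gene_id: str
    log2fc: float
    p_adj: float
    direction: str | None = None  # "up"/"down", set by the DEG filter

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise IntegrityError("gene_id must be non-empty")
        if not (0.0 <= self.p_adj <= 1.0):
            raise IntegrityError(
                f"adjusted p-value for {self.gene_id!r} outside [0, 1]: {self.p_adj}"
            )
        if self.log2fc != self.log2fc or self.log2fc in (float("inf"), float("-inf")):
            raise IntegrityError(f"non-finite log2fc for {self.gene_id!r}")


def bin_code_key(code: str) -> tuple[int, ...]:
    """Sort key for a dotted-integer bin code ('1.10' sorts after '1.9')."""
    if not _BIN_CODE_RE.match(code):
        raise FormatError(f"malformed bin code {code!r}: expected dotted integers")
    return tuple(int(part) for part in code.split("."))


@dataclass
class BinMap:
    """Gene -> functional-bin mapping with a reserved bin for unmapped genes.

    Each gene resolves to exactly one (code, name) bin.  Genes listed under
    several bins in the source file are resolved to the bin with the
    lexicographically-lowest dotted code (numeric comparison per segment),
    so every DEG is counted once and per-bin counts sum to the totals.
    """

    entries: dict[str, tuple[str, str]] = field(default_factory=dict)
    not_assigned_name: str = NOT_ASSIGNED

    def add(self, gene_id: str, bin_code: str, bin_name: str) -> None:
        key = bin_code_key(bin_code)
        if bin_name == self.not_assigned_name:
            raise IntegrityError(
                f"bin name {bin_name!r} is reserved for unmapped genes"
            )
        current = self.entries.get(gene_id)
        if current is None or key < bin_code_key(current[0]):
            self.entries[gene_id] = (bin_code, bin_name)

    def lookup(self, gene_id: str) -> tuple[str | None, str]:
        """Return (bin_code, bin_name); unlisted genes -> (None, reserved name)."""
        entry = self.entries.get(gene_id)
        if entry is None:
            return None, self.not_assigned_name
        return entry

    def bin_name(self, gene_id: str) -> str:
        return self.lookup(gene_id)[1]

    def bins(self) -> list[tuple[str, str]]:
        """Distinct (code, name) pairs in bin-code order."""
        seen = {entry for entry in self.entries.values()}
        return sorted(seen, key=lambda cn: bin_code_key(cn[0]))


@dataclass(frozen=True)
class ComparisonEntry:
    comparison_id: str
    stage: str
    water_status: str
    deg_table: Path
    replicates: tuple[Path, ...] = ()

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise IntegrityError(
                f"unknown stage {self.stage!r}; expected one of {', '.join(STAGES)}"
            )
        if self.water_status not in WATER_STATUSES:
            raise IntegrityError(
                f"unknown water status {self.water_status!r}; "
                f"expected one of {sorted(WATER_STATUSES)}"
            )


@dataclass
class ExperimentManifest:
    """Ordered list of pairwise comparisons with stage/water-status metadata."""

    comparisons: list[ComparisonEntry]
    bin_map: Path | None = None

    def __post_init__(self) -> None:
        ids = [c.comparison_id for c in self.comparisons]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise IntegrityError(f"duplicate comparison ids: {sorted(dupes)}")

    def stage_label(self, entry: ComparisonEntry) -> str:
        return f"{entry.water_status} {entry.stage}"


# ---------------------------------------------------------------------------
# DEG tables
# ---------------------------------------------------------------------------

_DEG_REQUIRED = ("gene_id", "log2fc", "p_adj")


def read_deg_table(path: str | Path) -> list[DEGRecord]:
    """Read a per-comparison DEG table (TSV: gene_id, log2fc, p_adj, ...).

    Column order is free and extra columns are ignored.  Unparsable numeric
    cells raise a format error naming the row; duplicate gene ids raise an
    integrity error naming the gene.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except OSError as exc:
        raise FormatError(f"cannot read DEG table {path}: {exc}") from exc
    for col in _DEG_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if df.empty:
        return []
    dupes = df["gene_id"][df["gene_id"].duplicated()]
    if not dupes.empty:
        raise IntegrityError(
            f"{path}: duplicate gene_id {dupes.iloc[0]!r}"
        )
    for col in ("log2fc", "p_adj"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.loc[numeric.isna(), "gene_id"]
        if not bad.empty:
            raise FormatError(
                f"{path}: unparsable {col} for gene {bad.iloc[0]!r}"
            )
        df[col] = numeric
    return [
        DEGRecord(gene_id=row.gene_id, log2fc=row.log2fc, p_adj=row.p_adj)
        for row in df.itertuples(index=False)
    ]


def read_bin_map(path: str | Path) -> BinMap:
    """Read a MapMan-mapping-style TSV (bin_code, bin_name, gene_id)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("bin_code", "bin_name", "gene_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    binmap = BinMap()
    for row in df.itertuples(index=False):
        binmap.add(row.gene_id, row.bin_code, row.bin_name)
    return binmap


def write_bin_map(binmap: BinMap, path: str | Path) -> None:
    rows = sorted(
        ((code, name, gene) for gene, (code, name) in binmap.entries.items()),
        key=lambda r: (bin_code_key(r[0]), r[2]),
    )
    df = pd.DataFrame(rows, columns=["bin_code", "bin_name", "gene_id"])
    df.to_csv(path, sep="\t", index=False)


def write_deg_table(records: Iterable[DEGRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tlog2fc\tp_adj\n")
        for rec in records:
            fh.write(f"{rec.gene_id}\t{rec.log2fc:.4f}\t{rec.p_adj:.6g}\n")


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------


def read_manifest(path: str | Path) -> ExperimentManifest:
    """Read an experiment manifest (JSON)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"manifest file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    base = path.parent
    comparisons = [
        ComparisonEntry(
            comparison_id=c["comparison_id"],
            stage=c["stage"],
            water_status=c["water_status"],
            deg_table=base / c["deg_table"],
            replicates=tuple(base / r for r in c.get("replicates", [])),
        )
        for c in data["comparisons"]
    ]
    bin_map = base / data["bin_map"] if data.get("bin_map") else None
    return ExperimentManifest(comparisons=comparisons, bin_map=bin_map)


def write_manifest(manifest: ExperimentManifest, path: str | Path) -> None:
    path = Path(path)
    base = path.parent

    def rel(p: Path) -> str:
        try:
            return str(Path(p).relative_to(base))
        except ValueError:
            return str(p)

    data = {
        "comparisons": [
            {
                "comparison_id": c.comparison_id,
                "stage": c.stage,
                "water_status": c.water_status,
                "deg_table": rel(c.deg_table),
                "replicates": [rel(r) for r in c.replicates],
            }
            for c in manifest.comparisons
        ],
    }
    if manifest.bin_map is not None:
        data["bin_map"] = rel(manifest.bin_map)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(data, fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Result tables (versioned output schemas)
# ---------------------------------------------------------------------------

#: schema name -> column-name -> kind ("str", "int", "pct" = int-or-na)
#: dynamics_matrix columns are matched by prefix because stage/transition
#: columns are data-dependent.
SCHEMAS: Mapping[str, Mapping[str, str]] = {
    "table2_summary": {
        "comparison_id": "str",
        "stage": "str",
        "water_status": "str",
        "n_degs": "int",
        "n_assigned": "int",
        "n_unknown": "int",
        "n_up": "int",
        "n_down": "int",
        "pct_up": "int",
        "pct_down": "int",
    },
    "dynamics_matrix": {
        "bin": "str",
        "count:": "int",
        "pct_change:": "pct",
        "pattern:": "str",
        "composite": "str",
    },
    "pathway_summary": {
        "pathway": "str",
        "count:": "int",
        "total": "int",
        "unique": "int",
        "shared": "int",
    },
}


def _column_kind(schema: Mapping[str, str], column: str) -> str:
    if column in schema:
        return schema[column]
    for prefix, kind in schema.items():
        if prefix.endswith(":") and column.startswith(prefix):
            return kind
    raise FormatError(f"column {column!r} not part of schema")


def write_table(rows: pd.DataFrame, path: str | Path, schema: str) -> None:
    """Write a result table in one of the documented output schemas.

    Integers are serialized as integers, undefined percentages as ``na``;
    re-reading with :func:`read_table` yields identical values.
    """
    if schema not in SCHEMAS:
        raise FormatError(f"unknown output schema {schema!r}")
    spec = SCHEMAS[schema]
    cols = list(rows.columns)
    for col in cols:
        _column_kind(spec, col)  # raises on columns foreign to the schema

    def fmt(col: str, value: object) -> str:
        kind = _column_kind(spec, col)
        missing = value is None or value is pd.NA or (
            isinstance(value, float) and value != value
        )
        if kind == "str":
            return "" if missing else str(value)
        if missing:
            return NA_TOKEN if kind == "pct" else ""
        return str(int(value))

    path = Path(path)
    try:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\t".join(cols) + "\n")
            for _, row in rows.iterrows():
                fh.write("\t".join(fmt(c, row[c]) for c in cols) + "\n")
    except OSError as exc:
        raise FormatError(f"cannot write table {path}: {exc}") from exc


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read back a table written by :func:`write_table` (round-trip identity)."""
    if schema not in SCHEMAS:
        raise FormatError(f"unknown output schema {schema!r}")
    spec = SCHEMAS[schema]
    df = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    out: dict[str, Sequence[object]] = {}
    for col in df.columns:
        kind = _column_kind(spec, col)
        values = df[col]
        if kind == "str":
            out[col] = values.tolist()
        else:
            out[col] = [
                pd.NA if v in ("", NA_TOKEN) else int(v) for v in values
            ]
    return pd.DataFrame(out, columns=list(df.columns))
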