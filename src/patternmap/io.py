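"""Readers and writers for cohort tables, GMT gene-set databases and result exports.

A *cohort table* is a tab-delimited text file with one row per gene and, per
time point, a fold-change column (``FC``-prefixed) and optionally a p-value
column (``P``-prefixed), paired by order of appearance.  Fold changes may be
supplied on the signed linear scale (2 = two-fold up, -2 = two-fold down) or
already in log2; internally every profile is stored in log2, where 0 means no
change.  All result exports are plain delimited text or JSON with a provenance
comment so that identical inputs produce identical bytes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import pandas as pd

from ._version import __version__

__all__ = [
    "CohortFormatError",
    "DuplicateIDError",
    "GMTFormatError",
    "ExpressionProfile",
    "CohortTable",
    "Pathway",
    "RowIssue",
    "TableDialect",
    "read_cohort_table",
    "write_cohort_table",
    "read_gmt",
    "write_gmt",
    "write_export",
]


class CohortFormatError(ValueError):
    """The cohort table violates the expected tab-delimited layout."""


class DuplicateIDError(CohortFormatError):
    """Two or more rows share a gene identifier within one cohort."""

    def __init__(self, offenders: Sequence[str]):
        self.offenders = sorted(set(offenders))
        super().__init__(f"duplicate gene IDs within cohort: {', '.join(self.offenders)}")


class GMTFormatError(ValueError):
    """A GMT line does not carry name, description and at least one gene."""


@dataclass(frozen=True)
class ExpressionProfile:
    """One gene's trajectory: log2 fold change (and optional p-value) per time point."""

    gene_id: str
    fc: tuple[float, ...]
    pvalue: tuple[float, ...] | None = None
    entrez: str | None = None
    symbol: str | None = None
    imputed: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.pvalue is not None and len(self.pvalue) != len(self.fc):
            raise CohortFormatError(
                f"{self.gene_id}: {len(self.pvalue)} p-values for {len(self.fc)} fold changes"
            )
        for v in self.fc:
            if not math.isfinite(v):
                raise ValueError(f"{self.gene_id}: non-finite fold change {v!r}")


@dataclass(frozen=True)
class RowIssue:
    """A rejected (or repaired) input row and the reason, for the parse report."""

    row: int  # 1-based data-row index (header excluded)
    gene_id: str
    reason: str


@dataclass
class CohortTable:
    """Ordered time points plus the expression profiles of one cohort.

    ``rejected`` lists input rows that could not be parsed, so that
    ``len(profiles) + len(rejected)`` always equals the number of data rows
    read — no row is dropped silently.
    """

    cohort_id: str
    timepoints: tuple[str, ...]
    profiles: list[ExpressionProfile]
    rejected: list[RowIssue] = field(default_factory=list)
    source_scale: str = "log2"

    def __post_init__(self) -> None:
        if len(self.timepoints) < 2:
            raise CohortFormatError("a cohort needs at least two time points")
        seen: dict[str, int] = {}
        for p in self.profiles:
            if len(p.fc) != self.T:
                raise CohortFormatError(
                    f"{p.gene_id}: {len(p.fc)} fold changes for {self.T} time points"
                )
            seen[p.gene_id] = seen.get(p.gene_id, 0) + 1
        dupes = [g for g, c in seen.items() if c > 1]
        if dupes:
            raise DuplicateIDError(dupes)
        has_p = [p.pvalue is not None for p in self.profiles]
        if any(has_p) and not all(has_p):
            raise CohortFormatError("p-values must be present for all profiles or none")

    @property
    def T(self) -> int:
        return len(self.timepoints)

    def profile(self, gene_id: str) -> ExpressionProfile:
        for p in self.profiles:
            if p.gene_id == gene_id:
                return p
        raise KeyError(gene_id)


@dataclass(frozen=True)
class Pathway:
    """A named gene set (one GMT line)."""

    pathway_id: str
    name: str
    genes: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise GMTFormatError(f"{self.pathway_id}: empty gene set")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class TableDialect:
    """Column-naming conventions of a cohort table.

    Default: the ID column is named ``ID``; fold-change columns start with
    ``FC`` and p-value columns with ``P`` (excluding the named metadata
    columns), paired with the FC columns by order.  ``column_map`` overrides
    detection entirely: ``{"id": ..., "fc": [...], "p": [...] or None}``.
    """

    id_col: str = "ID"
    entrez_col: str = "Entrez Gene"
    symbol_col: str = "Symbol"
    fc_prefix: str = "FC"
    p_prefix: str = "P"
    fc_scale: str = "linear_signed"  # or "log2"
    allow_missing: bool = False
    column_map: Mapping[str, Any] | None = None


def _to_log2(value: float, scale: str) -> float:
    """Canonicalize a fold change to log2; signed-linear 0 maps to 0."""
    if scale == "log2":
        return value
    if value == 0.0:
        return 0.0
    if value >= 1.0:
        return math.log2(value)
    if value <= -1.0:
        return -math.log2(-value)
    raise ValueError(
        f"signed linear fold change {value} lies in (-1, 1); "
        "ratios between -1 and 1 have no signed-linear meaning (use fc_scale='log2'?)"
    )


def _from_log2(value: float, scale: str) -> float:
    if scale == "log2":
        return value
    if value == 0.0:
        return 0.0
    return 2.0 ** value if value > 0 else -(2.0 ** (-value))


def _detect_columns(columns: Sequence[str], dialect: TableDialect):
    if dialect.column_map is not None:
        cm = dialect.column_map
        return (
            cm["id"],
            cm.get("entrez"),
            cm.get("symbol"),
            list(cm["fc"]),
            list(cm["p"]) if cm.get("p") else None,
        )
    if dialect.id_col not in columns:
        raise CohortFormatError(f"missing ID column {dialect.id_col!r}; found {list(columns)}")
    named = {dialect.id_col, dialect.entrez_col, dialect.symbol_col}
    fcp = dialect.fc_prefix.upper()
    pp = dialect.p_prefix.upper()
    fc_cols = [c for c in columns if c.upper().startswith(fcp)]
    p_cols = [
        c
        for c in columns
        if c not in named and c not in fc_cols and c.upper().startswith(pp)
    ]
    if not fc_cols:
        raise CohortFormatError(f"no fold-change columns with prefix {dialect.fc_prefix!r}")
    if p_cols and len(p_cols) != len(fc_cols):
        raise CohortFormatError(
            f"{len(p_cols)} p-value columns for {len(fc_cols)} fold-change columns"
        )
    entrez = dialect.entrez_col if dialect.entrez_col in columns else None
    symbol = dialect.symbol_col if dialect.symbol_col in columns else None
    return dialect.id_col, entrez, symbol, fc_cols, (p_cols or None)


def _timepoint_labels(fc_cols: Sequence[str], prefix: str) -> tuple[str, ...]:
    labels = []
    for i, c in enumerate(fc_cols):
        tail = c[len(prefix):].lstrip("_. -") if c.upper().startswith(prefix.upper()) else c
        labels.append(tail or f"T{i + 1}")
    if len(set(labels)) != len(labels):  # non-informative headers
        labels = [f"T{i + 1}" for i in range(len(fc_cols))]
    return tuple(labels)


def read_cohort_table(
    path: str | Path,
    dialect: TableDialect = TableDialect(),
    cohort_id: str | None = None,
) -> CohortTable:
    """Parse a tab-delimited cohort table into a :class:`CohortTable`.

    Rows whose fold changes (or p-values) cannot be parsed are rejected and
    listed in ``table.rejected``; with ``dialect.allow_missing`` a missing
    fold-change cell is imputed as 0 (the neutral symbol) and the position is
    recorded in ``profile.imputed``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    id_col, entrez_col, symbol_col, fc_cols, p_cols = _detect_columns(list(df.columns), dialect)
    timepoints = _timepoint_labels(fc_cols, dialect.fc_prefix)

    profiles: list[ExpressionProfile] = []
    rejected: list[RowIssue] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rec = dict(zip(df.columns, row))
        gid = rec.get(id_col)
        if gid is None or pd.isna(gid) or not str(gid).strip():
            rejected.append(RowIssue(i, "", "missing gene ID"))
            continue
        gid = str(gid).strip()
        fc: list[float] = []
        imputed: list[int] = []
        bad: str | None = None
        for t, c in enumerate(fc_cols):
            cell = rec.get(c)
            if cell is None or pd.isna(cell) or not str(cell).strip():
                if dialect.allow_missing:
                    fc.append(0.0)
                    imputed.append(t)
                    continue
                bad = f"missing fold change in column {c!r}"
                break
            try:
                fc.append(_to_log2(float(cell), dialect.fc_scale))
            except ValueError as exc:
                bad = f"column {c!r}: {exc}"
                break
        pvals: list[float] | None = None
        if bad is None and p_cols is not None:
            pvals = []
            for c in p_cols:
                cell = rec.get(c)
                try:
                    v = float(cell)
                except (TypeError, ValueError):
                    bad = f"unparseable p-value in column {c!r}"
                    break
                if not 0.0 <= v <= 1.0:
                    bad = f"p-value {v} outside [0, 1] in column {c!r}"
                    break
                pvals.append(v)
        if bad is not None:
            rejected.append(RowIssue(i, gid, bad))
            continue
        profiles.append(
            ExpressionProfile(
                gene_id=gid,
                fc=tuple(fc),
                pvalue=tuple(pvals) if pvals is not None else None,
                entrez=str(rec[entrez_col]).strip() if entrez_col and not pd.isna(rec.get(entrez_col)) else None,
                symbol=str(rec[symbol_col]).strip() if symbol_col and not pd.isna(rec.get(symbol_col)) else None,
                imputed=tuple(imputed),
            )
        )
    return CohortTable(
        cohort_id=cohort_id or path.stem,
        timepoints=timepoints,
        profiles=profiles,
        rejected=rejected,
        source_scale=dialect.fc_scale,
    )


def write_cohort_table(table: CohortTable, path: str | Path, fc_scale: str = "log2") -> None:
    """Write a cohort table back to tab-delimited text (round-trips with log2 scale)."""
    path = Path(path)
    has_p = bool(table.profiles) and table.profiles[0].pvalue is not None
    has_entrez = any(p.entrez is not None for p in table.profiles)
    has_symbol = any(p.symbol is not None for p in table.profiles)
    cols = ["ID"]
    if has_entrez:
        cols.append("Entrez Gene")
    if has_symbol:
        cols.append("Symbol")
    for tp in table.timepoints:
        if has_p:
            cols.append(f"P_{tp}")
        cols.append(f"FC_{tp}")
    lines = ["\t".join(cols)]
    for p in table.profiles:
        row = [p.gene_id]
        if has_entrez:
            row.append(p.entrez or "")
        if has_symbol:
            row.append(p.symbol or "")
        for t in range(table.T):
            if has_p:
                row.append(_fmt_float(p.pvalue[t]))
            row.append(_fmt_float(_from_log2(p.fc[t], fc_scale)))
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")


def read_gmt(path: str | Path) -> list[Pathway]:
    """Parse a GMT file: per line ``name<TAB>description<TAB>gene...``.

    Empty gene fields are dropped and duplicate genes within a line are
    de-duplicated; a line without at least one gene is a format error.
    """
    pathways: list[Pathway] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            genes = [g.strip() for g in fields[2:] if g.strip()]
            if len(fields) < 3 or not genes:
                raise GMTFormatError(
                    f"{path}:{lineno}: expected name, description and at least one gene"
                )
            pathways.append(
                Pathway(
                    pathway_id=fields[0],
                    name=fields[0],
                    genes=frozenset(genes),
                    source=fields[1],
                )
            )
    return pathways


def write_gmt(pathways: Iterable[Pathway], path: str | Path) -> None:
    lines = []
    for pw in pathways:
        lines.append("\t".join([pw.pathway_id, pw.source or "na", *sorted(pw.genes)]))
    Path(path).write_text("\n".join(lines) + "\n")


# --- generic record export ---------------------------------------------------

def _fmt_float(v: float) -> str:
    if v == int(v) and abs(v) < 1e15:
        return str(int(v))
    return format(v, ".6g")


def _stable(value: Any) -> Any:
    if isinstance(value, float):
        return float(_fmt_float(value))
    if isinstance(value, (list, tuple)):
        return [_stable(v) for v in value]
    return value


def write_export(
    records: Sequence[Mapping[str, Any]],
    path: str | Path,
    format: str = "tsv",
    schema: Sequence[str] | None = None,
    provenance: Mapping[str, str] | None = None,
) -> None:
    """Serialize result records to TSV or JSON with byte-stable formatting.

    Keys follow ``schema`` (default: order of the first record), floats are
    written at 6 significant digits, and a provenance line (tool version plus
    any caller-supplied metadata such as the config hash) prefixes every file.
    """
    path = Path(path)
    prov = {"tool": "patternmap", "version": __version__, **(provenance or {})}
    if schema is None:
        schema = list(records[0].keys()) if records else []
    if format == "tsv":
        lines = ["# " + " ".join(f"{k}={v}" for k, v in prov.items()), "\t".join(schema)]
        for rec in records:
            lines.append("\t".join(_cell(rec.get(k)) for k in schema))
        path.write_text("\n".join(lines) + "\n")
    elif format == "json":
        payload = {
            "provenance": prov,
            "records": [{k: _stable(rec.get(k)) for k in schema} for rec in records],
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")
    else:
        raise ValueError(f"unknown export format {format!r}")


def _cell(v: Any) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        return _fmt_float(v)
    if isinstance(v, (list, tuple, set, frozenset)):
        items = sorted(str(x) for x in v) if isinstance(v, (set, frozenset)) else [str(x) for x in v]
        return ";".join(items)
    return str(v)
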