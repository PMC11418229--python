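"""Ingestion of GOstats-style enrichment result tables.

One hyperGTest summary per direction (over / under) per pairwise analysis:
columns GO*ID, Pvalue, OddsRatio, ExpCount, Count, Size, Term.  The two
directions are combined into a single record set per analysis (min-p policy),
attached to ontology terms through the alt-id index, and summarised as a fold
change (observed / expected DEG count) plus a significance flag.

The hypergeometric test itself is never computed here — this package
visualizes enrichment output, it does not re-derive it.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Literal, Mapping, Sequence

import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import TableFormatError, UndefinedFoldError
from .ontology import Ontology

logger = logging.getLogger(__name__)

Direction = Literal["over", "under"]

ID_COLUMN_RE = re.compile(r"GO[A-Z]*ID$", re.IGNORECASE)
MANDATORY_COLUMNS = ("Pvalue", "OddsRatio", "ExpCount", "Count", "Size", "Term")


@dataclass(frozen=True)
class EnrichmentRecord:
    """One term's statistics in one analysis, as reported by GOstats."""

    go_id: str
    p_value: float
    odds_ratio: float  # may be +inf (GOstats emits Inf for zero cells)
    expected_count: float
    observed_count: int
    gene_set_size: int
    term_name: str
    direction: Direction

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"{self.go_id}: p_value {self.p_value} outside [0,1]")
        if self.observed_count > self.gene_set_size:
            raise ValueError(
                f"{self.go_id}: Count {self.observed_count} exceeds Size "
                f"{self.gene_set_size}"
            )


@dataclass
class AnalysisSet:
    """Ordered pairwise analyses; order defines figure column order."""

    analyses: list[tuple[str, dict[str, EnrichmentRecord]]] = field(
        default_factory=list
    )
    alpha: float = 0.05
    adjust: Literal["none", "benjamini_hochberg"] = "none"

    def __post_init__(self):
        labels = [label for label, _ in self.analyses]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate analysis labels: {labels}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.analyses]

    def records_for(self, label: str) -> dict[str, EnrichmentRecord]:
        for lab, recs in self.analyses:
            if lab == label:
                return recs
        raise KeyError(label)

    def effective_p(self, label: str) -> dict[str, float]:
        """Raw or BH-adjusted p per go_id for one analysis, per ``adjust``."""
        recs = self.records_for(label)
        if self.adjust == "none":
            return {gid: r.p_value for gid, r in recs.items()}
        return adjusted_p(recs.values(), self.adjust)

    def significance(self, label: str) -> dict[str, bool]:
        eff = self.effective_p(label)
        return {gid: p < self.alpha for gid, p in eff.items()}


def _read_text(source: str | Path | IO[str]) -> str:
    if hasattr(source, "read"):
        return source.read()
    return Path(source).read_text()


def _read_frame(source: str | Path | IO[str]) -> pd.DataFrame:
    import io

    text = _read_text(source)
    header = text.splitlines()[0] if text.strip() else ""
    # delimiter auto-detection restricted to tab/comma
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(io.StringIO(text), sep=sep, dtype=str,
                       skipinitialspace=True)


def _locate_columns(df: pd.DataFrame) -> tuple[str, dict[str, str]]:
    id_col = None
    for col in df.columns:
        if ID_COLUMN_RE.fullmatch(col.strip()):
            id_col = col
            break
    if id_col is None:
        raise TableFormatError(
            f"no GO id column (GOBPID/GOMFID/GOCCID/GOID) among {list(df.columns)}"
        )
    lowered = {c.strip().lower(): c for c in df.columns}
    mapping = {}
    for want in MANDATORY_COLUMNS:
        if want.lower() not in lowered:
            raise TableFormatError(f"missing mandatory column {want!r}")
        mapping[want] = lowered[want.lower()]
    return id_col, mapping


def _parse_float(cell: str, what: str, row: int, errors: list[str]) -> float:
    try:
        return float(cell)  # float("Inf") handles GOstats' Inf
    except (TypeError, ValueError):
        errors.append(f"row {row}: unparseable {what} {cell!r}")
        return math.nan


def read_gostats_table(
    source: str | Path | IO[str],
    direction: Direction,
) -> list[EnrichmentRecord]:
    """Read one hyperGTest summary (tab- or comma-delimited) as records.

    The id column is the first whose name matches ``GO[A-Z]*ID``; the other
    mandatory columns are matched case-insensitively.  ``Inf`` odds ratios
    are accepted.  Rows with unparseable numerics raise a
    :class:`TableFormatError` citing every offending row number (1-based,
    excluding the header).
    """
    if direction not in ("over", "under"):
        raise ValueError(f"direction must be 'over' or 'under', got {direction!r}")
    df = _read_frame(source)
    id_col, cols = _locate_columns(df)
    if df.empty:
        return []
    records: list[EnrichmentRecord] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row_d = dict(zip(df.columns, row))
        p = _parse_float(row_d[cols["Pvalue"]], "Pvalue", i, errors)
        orat = _parse_float(row_d[cols["OddsRatio"]], "OddsRatio", i, errors)
        exp = _parse_float(row_d[cols["ExpCount"]], "ExpCount", i, errors)
        cnt = _parse_float(row_d[cols["Count"]], "Count", i, errors)
        size = _parse_float(row_d[cols["Size"]], "Size", i, errors)
        if any(math.isnan(v) for v in (p, orat, exp, cnt, size)):
            continue
        try:
            records.append(
                EnrichmentRecord(
                    go_id=str(row_d[id_col]).strip(),
                    p_value=p,
                    odds_ratio=orat,
                    expected_count=exp,
                    observed_count=int(cnt),
                    gene_set_size=int(size),
                    term_name=str(row_d[cols["Term"]]),
                    direction=direction,
                )
            )
        except ValueError as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise TableFormatError("; ".join(errors))
    return records


def read_combined_table(source: str | Path | IO[str]) -> list[EnrichmentRecord]:
    """Read a combined single-file-per-analysis table.

    Accepts a ``Direction`` column (over/under); without one, direction is
    inferred as under ⇔ OddsRatio < 1.
    """
    import io

    text = _read_text(source)
    df = _read_frame(io.StringIO(text))
    if df.empty:
        return []
    lowered = {c.strip().lower(): c for c in df.columns}
    if "direction" in lowered:
        dcol = lowered["direction"]
        over_df = df[df[dcol].str.lower() == "over"].drop(columns=[dcol])
        under_df = df[df[dcol].str.lower() == "under"].drop(columns=[dcol])
        out: list[EnrichmentRecord] = []
        for sub, direction in ((over_df, "over"), (under_df, "under")):
            if not sub.empty:
                buf = _df_to_stream(sub)
                out.extend(read_gostats_table(buf, direction))
        return out
    records = read_gostats_table(io.StringIO(text), "over")
    return [
        r if r.odds_ratio >= 1 else _with_direction(r, "under") for r in records
    ]


def _with_direction(r: EnrichmentRecord, direction: Direction) -> EnrichmentRecord:
    return EnrichmentRecord(
        go_id=r.go_id,
        p_value=r.p_value,
        odds_ratio=r.odds_ratio,
        expected_count=r.expected_count,
        observed_count=r.observed_count,
        gene_set_size=r.gene_set_size,
        term_name=r.term_name,
        direction=direction,
    )


def _df_to_stream(df: pd.DataFrame):
    import io

    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False)
    buf.seek(0)
    return buf


def combine_over_under(
    over: Iterable[EnrichmentRecord],
    under: Iterable[EnrichmentRecord],
) -> dict[str, EnrichmentRecord]:
    """Merge the two directions of one analysis into one record per term.

    Union of ids; where a term appears in both tables, the record with the
    smaller p-value wins (tie goes to over).  Direction is retained on the
    kept record.
    """
    combined: dict[str, EnrichmentRecord] = {r.go_id: r for r in over}
    for r in under:
        held = combined.get(r.go_id)
        if held is None or r.p_value < held.p_value:
            combined[r.go_id] = r
    return combined


def write_combined_table(
    over: Iterable[EnrichmentRecord],
    under: Iterable[EnrichmentRecord],
    dest: str | Path | IO[str],
    policy: Literal["min_p", "concat"] = "min_p",
) -> None:
    """Write the single-file-per-analysis format (+ a Direction column).

    ``min_p`` keeps one row per term (the combine rule); ``concat`` keeps
    every input row with its direction flag.
    """
    if policy == "min_p":
        rows = sorted(combine_over_under(over, under).values(),
                      key=lambda r: r.go_id)
    elif policy == "concat":
        rows = sorted(list(over) + list(under),
                      key=lambda r: (r.go_id, r.direction))
    else:
        raise ValueError(f"unknown combine policy {policy!r}")
    df = pd.DataFrame(
        {
            "GOID": [r.go_id for r in rows],
            "Pvalue": [r.p_value for r in rows],
            "OddsRatio": [r.odds_ratio for r in rows],
            "ExpCount": [r.expected_count for r in rows],
            "Count": [r.observed_count for r in rows],
            "Size": [r.gene_set_size for r in rows],
            "Term": [r.term_name for r in rows],
            "Direction": [r.direction for r in rows],
        }
    )
    df.to_csv(dest, sep="\t", index=False)


def fold_change(record: EnrichmentRecord) -> float:
    """Observed / expected DEG count; <1 for depleted terms, 0 is valid."""
    if record.expected_count <= 0:
        raise UndefinedFoldError(
            f"{record.go_id}: expected_count is {record.expected_count}"
        )
    return record.observed_count / record.expected_count


def adjusted_p(
    records: Iterable[EnrichmentRecord],
    mode: Literal["none", "benjamini_hochberg"],
) -> dict[str, float]:
    """Per-term adjusted p-values for one analysis (both directions pooled)."""
    recs = list(records)
    if mode == "none":
        return {r.go_id: r.p_value for r in recs}
    if mode != "benjamini_hochberg":
        raise ValueError(f"unknown adjustment mode {mode!r}")
    if not recs:
        return {}
    _, adj, _, _ = multipletests([r.p_value for r in recs], method="fdr_bh")
    return {r.go_id: float(a) for r, a in zip(recs, adj)}


def is_significant(record: EnrichmentRecord, analysis_set: AnalysisSet) -> bool:
    """Strict ``p < alpha`` on the raw or adjusted p, per the set's settings."""
    for label, recs in analysis_set.analyses:
        if recs.get(record.go_id) is record:
            return analysis_set.significance(label)[record.go_id]
    # record not part of the set: judge on its raw p (no cohort to adjust over)
    return record.p_value < analysis_set.alpha


@dataclass
class AnnotationIndex:
    """Per-term records in analysis label order, plus the unmatched-id report."""

    labels: list[str]
    records: dict[str, list[EnrichmentRecord | None]]
    unmatched: list[tuple[str, str]]  # (analysis label, go_id)
    analysis_set: AnalysisSet | None = None

    @property
    def unmatched_count(self) -> int:
        return len(self.unmatched)

    def per_analysis(self, go_id: str) -> list[EnrichmentRecord | None]:
        return self.records.get(go_id, [None] * len(self.labels))

    def write_unmatched_report(self, dest: str | Path | IO[str]) -> None:
        df = pd.DataFrame(self.unmatched, columns=["Analysis", "GOID"])
        df.to_csv(dest, sep="\t", index=False)


def attach(ontology: Ontology, analysis_set: AnalysisSet) -> AnnotationIndex:
    """File every record under its canonical term id, in label order.

    Ids are resolved through the alt-id index; ids that resolve nowhere go
    into the unmatched report rather than being dropped silently.
    """
    n = len(analysis_set.analyses)
    index: dict[str, list[EnrichmentRecord | None]] = {}
    unmatched: list[tuple[str, str]] = []
    for j, (label, recs) in enumerate(analysis_set.analyses):
        for gid, rec in recs.items():
            try:
                canonical = ontology.resolve(gid).id
            except Exception:
                unmatched.append((label, gid))
                continue
            slot = index.setdefault(canonical, [None] * n)
            slot[j] = rec
    if unmatched:
        logger.warning("%d enrichment record(s) cite unknown GO ids",
                       len(unmatched))
    return AnnotationIndex(
        labels=analysis_set.labels,
        records=index,
        unmatched=unmatched,
        analysis_set=analysis_set,
    )
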