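"""Writing the output bundle: TSV tables, FASTA, workbook, index page."""
from __future__ import annotations

import html
import math
from pathlib import Path

import pandas as pd

from .logutil import RunLog
from .mq_io import SequenceCatalog, Table

#: Fixed order of the index page sections.
INDEX_SECTIONS = (
    "Input parameters",
    "Identification results",
    "Summary and descriptive statistics",
    "Quantification based on isobaric labelling",
    "Miscellaneous",
    "Log file",
)

EXCEL_MAX_ROWS = 1_048_576


def write_table(table: Table, path: str | Path) -> Path:
    """Write a Table as tab-separated text (inverse of ``mq_io.read_table``)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["\t".join(table.column_titles)]
    for row in table.rows:
        lines.append("\t".join(row.get(t, "") for t in table.column_titles))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def write_dataframe(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def write_fasta(
    catalog: SequenceCatalog, accessions: list[str], path: str | Path
) -> Path:
    """Export the sequences of the reported lead accessions."""
    path = Path(path)
    lines = []
    for accession in accessions:
        entry = catalog.get(accession)
        if entry is None:
            continue
        desc = f" {entry.description}" if entry.description else ""
        lines.append(f">{accession}{desc}")
        seq = entry.sequence
        lines.extend(seq[i: i + 60] for i in range(0, len(seq), 60))
    path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    return path


def _is_nan_like(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, str) and value.strip().lower() in ("", "nan", "none"):
        return True
    return False


def _sheet_names(names: list[str]) -> list[str]:
    """Excel-safe sheet names: <=31 chars, invalid chars stripped, deduplicated."""
    out: list[str] = []
    seen: set[str] = set()
    for name in names:
        clean = "".join(c for c in name if c not in "[]:*?/\\")[:31] or "sheet"
        candidate = clean
        k = 2
        while candidate.lower() in seen:
            suffix = f"~{k}"
            candidate = clean[: 31 - len(suffix)] + suffix
            k += 1
        seen.add(candidate.lower())
        out.append(candidate)
    return out


def export_workbook(
    tables: list[tuple[str, Table | pd.DataFrame]],
    path: str | Path,
    log: RunLog | None = None,
) -> Path:
    """Combine all result tables into one spreadsheet workbook.

    One sheet per table; NaN-like placeholders become empty cells; sheets
    exceeding the row-format limit are truncated with a warning row.
    """
    from openpyxl import Workbook

    path = Path(path)
    wb = Workbook()
    wb.remove(wb.active)
    names = _sheet_names([name for name, _ in tables])
    for sheet_name, (_, table) in zip(names, tables):
        ws = wb.create_sheet(sheet_name)
        if isinstance(table, Table):
            header = table.column_titles
            data_rows = ([row.get(t, "") for t in header] for row in table.rows)
            n_rows = len(table.rows)
        else:
            header = [str(c) for c in table.columns]
            data_rows = (list(rec) for rec in table.itertuples(index=False))
            n_rows = len(table)
        ws.append(header)
        truncated = n_rows > EXCEL_MAX_ROWS - 2
        for i, row in enumerate(data_rows):
            if i >= EXCEL_MAX_ROWS - 2:
                break
            ws.append([None if _is_nan_like(v) else v for v in row])
        if truncated:
            ws.append([f"... truncated at {EXCEL_MAX_ROWS - 2} rows"])
            if log is not None:
                log.warn(f"workbook sheet {sheet_name!r} truncated")
    wb.save(path)
    return path


def build_index(
    manifest: dict[str, list[tuple[str, str]]],
    path: str | Path,
    title: str = "mqlibra report",
) -> Path:
    """Write the index page with its six fixed sections.

    *manifest* maps section name -> list of ``(label, relative href)``; a
    ``(text, "")`` pair renders as plain text (e.g. "not performed").
    Sections absent from the manifest render with an empty list.
    """
    path = Path(path)
    parts = [
        "<!DOCTYPE html>",
        "<html><head><meta charset='utf-8'>",
        f"<title>{html.escape(title)}</title></head><body>",
        f"<h1>{html.escape(title)}</h1>",
    ]
    for i, section in enumerate(INDEX_SECTIONS, start=1):
        parts.append(f"<h2>({_roman(i)}) {html.escape(section)}</h2>")
        items = manifest.get(section, [])
        parts.append("<ul>")
        for label, href in items:
            if href:
                parts.append(
                    f"<li><a href='{html.escape(href)}'>{html.escape(label)}</a></li>"
                )
            else:
                parts.append(f"<li>{html.escape(label)}</li>")
        parts.append("</ul>")
    parts.append("</body></html>")
    path.write_text("\n".join(parts) + "\n", encoding="utf-8")
    return path


def _roman(n: int) -> str:
    return ["i", "ii", "iii", "iv", "v", "vi"][n - 1]
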