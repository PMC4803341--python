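"""Reading MaxQuant-style tab-separated tables and FASTA sequence catalogs.

Tables keep every value as its raw string; typed accessors (`split_ids`,
`to_float`, `to_int`) convert lazily so that a read/write cycle is faithful.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .config import HeaderParseRule
from .logutil import RunLog


@dataclass
class Table:
    """A named tab-separated table: ordered column titles + rows of raw strings."""

    name: str
    column_titles: list[str]
    rows: list[dict[str, str]]
    source_path: Path | None = None

    def __len__(self) -> int:
        return len(self.rows)

    def has_column(self, title: str) -> bool:
        return title in self.column_titles

    def column(self, title: str) -> list[str]:
        return [row[title] for row in self.rows]

    def first_column(self, *candidates: str) -> str | None:
        """First of *candidates* present in this table (dialect tolerance)."""
        for title in candidates:
            if title in self.column_titles:
                return title
        return None

    def subset(self, titles: list[str]) -> "Table":
        keep = [t for t in titles if t in self.column_titles]
        rows = [{t: row[t] for t in keep} for row in self.rows]
        return Table(self.name, keep, rows, self.source_path)


def split_ids(value: str) -> list[str]:
    """Split a semicolon-joined MaxQuant multi-value field."""
    return [tok for tok in value.split(";") if tok != ""] if value else []


def to_float(value: str, default: float = float("nan")) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        return default


def to_int(value: str, default: int = 0) -> int:
    try:
        return int(float(value))
    except (TypeError, ValueError):
        return default


def _read_text(path: Path) -> str:
    data = path.read_bytes()
    try:
        return data.decode("utf-8")
    except UnicodeDecodeError:
        return data.decode("latin-1")


def read_table(
    path: str | Path,
    selected_titles: list[str] | None = None,
    name: str | None = None,
    log: RunLog | None = None,
) -> Table:
    """Read a header-first tab-delimited table.

    Rows whose field count does not match the header are skipped with a
    logged warning naming the line number.  When *selected_titles* is given,
    only those columns are retained, in the given order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"table file not found: {path}")
    text = _read_text(path)
    reader = csv.reader(text.splitlines(), delimiter="\t")
    try:
        header = next(reader)
    except StopIteration:
        raise ValueError(f"{path}: empty table file") from None
    keep = header
    if selected_titles is not None:
        keep = [t for t in selected_titles if t in header]
    idx = {t: header.index(t) for t in keep}
    rows: list[dict[str, str]] = []
    for lineno, fields in enumerate(reader, start=2):
        if not fields:
            continue
        if len(fields) != len(header):
            if log is not None:
                log.warn(
                    f"{path.name}: line {lineno} has {len(fields)} fields, "
                    f"expected {len(header)}; row skipped"
                )
            continue
        rows.append({t: fields[i] for t, i in idx.items()})
    return Table(name or path.stem, list(keep), rows, path)


def table_header(path: str | Path) -> list[str]:
    """Read only the column titles of a tab-separated table."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"table file not found: {path}")
    first = _read_text(path).split("\n", 1)[0].rstrip("\r")
    return first.split("\t")


# ---------------------------------------------------------------------------
# FASTA catalog

@dataclass
class CatalogEntry:
    sequence: str
    gene: str = ""
    description: str = ""
    source_index: int = 0


@dataclass
class SequenceCatalog:
    """Accession -> (sequence, gene, description) lookup built from FASTA files."""

    entries: dict[str, CatalogEntry]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, accession: str) -> bool:
        return accession in self.entries

    def get(self, accession: str) -> CatalogEntry | None:
        return self.entries.get(accession)

    def sequence(self, accession: str) -> str | None:
        entry = self.entries.get(accession)
        return entry.sequence if entry else None


def read_fasta(
    paths: list[str | Path],
    rules: list[HeaderParseRule],
    log: RunLog | None = None,
) -> SequenceCatalog:
    """Read FASTA files into a catalog, pairing each file with its parse rule.

    Files and rules are paired positionally and must be given in the same
    order.  The first occurrence of an accession wins; duplicates are logged.
    Headers the rule cannot parse keep the first whitespace-delimited token as
    accession with empty gene/description.
    """
    if len(paths) != len(rules):
        raise ValueError(
            f"{len(paths)} FASTA files but {len(rules)} parse rules; "
            "provide them in matching order"
        )
    entries: dict[str, CatalogEntry] = {}
    for source_index, (path, rule) in enumerate(zip(paths, rules)):
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"FASTA file not found: {path}")
        for record in SeqIO.parse(str(path), "fasta"):
            header = record.description
            accession, gene, description = rule.parse(header)
            if accession is None:
                accession = header.split()[0] if header.split() else record.id
                gene, description = "", ""
                if log is not None:
                    log.warn(
                        f"{path.name}: header not parseable by rule "
                        f"{rule.name!r}: {header[:60]!r}; kept first token"
                    )
            if accession in entries:
                if log is not None:
                    log.warn(
                        f"duplicate accession {accession!r} in {path.name}; "
                        "first occurrence kept"
                    )
                continue
            entries[accession] = CatalogEntry(
                sequence=str(record.seq).upper(),
                gene=gene,
                description=description,
                source_index=source_index,
            )
    return SequenceCatalog(entries)
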