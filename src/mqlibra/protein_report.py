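"""Protein-group filtering, minimum reporting and annotation.

MaxQuant groups accessions that share peptides.  For minimum reporting only
the accessions supported by the largest number of unique peptides — and,
among those, the largest total peptide count — are retained; the first
retained accession becomes the lead and is annotated with gene name and
description from the sequence catalog.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .logutil import RunLog
from .mq_io import SequenceCatalog, Table, split_ids, to_float, to_int


@dataclass
class ProteinGroupRecord:
    group_id: str
    accessions: list[str]
    unique_peptide_counts: list[int]
    total_peptide_counts: list[int]
    score: float
    is_reverse: bool
    is_contaminant: bool
    row_index: int
    retained_accessions: list[str] = field(default_factory=list)
    lead_accession: str = ""
    gene: str = ""
    description: str = ""

    @property
    def max_unique_count(self) -> int:
        return max(self.unique_peptide_counts, default=0)

    @property
    def max_total_count(self) -> int:
        return max(self.total_peptide_counts, default=0)


def _flagged(value: str) -> bool:
    return value.strip() == "+"


def records_from_table(table: Table, log: RunLog | None = None) -> list[ProteinGroupRecord]:
    """Build group records from a (possibly column-subsetted) proteinGroups table.

    Reverse/contaminant flags honor both the MaxQuant "+" marker columns and
    the ``REV__`` / ``CON__`` accession prefixes, which vary across versions.
    """
    id_col = table.first_column("id")
    acc_col = table.first_column("Protein IDs", "Majority protein IDs")
    uniq_col = table.first_column("Peptide counts (unique)")
    total_col = table.first_column("Peptide counts (all)")
    score_col = table.first_column("Score")
    rev_col = table.first_column("Reverse")
    con_col = table.first_column("Potential contaminant", "Contaminant")
    records: list[ProteinGroupRecord] = []
    counts_missing = False
    for row_index, row in enumerate(table.rows):
        accessions = split_ids(row.get(acc_col, "")) if acc_col else []
        uniques = [to_int(v) for v in split_ids(row.get(uniq_col, ""))] if uniq_col else []
        totals = [to_int(v) for v in split_ids(row.get(total_col, ""))] if total_col else []
        if len(uniques) != len(accessions) or len(totals) != len(accessions):
            counts_missing = True
            uniques = [0] * len(accessions)
            totals = [0] * len(accessions)
        is_reverse = (rev_col is not None and _flagged(row.get(rev_col, ""))) or any(
            a.startswith("REV__") for a in accessions
        )
        is_contaminant = (con_col is not None and _flagged(row.get(con_col, ""))) or any(
            a.startswith("CON__") for a in accessions
        )
        records.append(
            ProteinGroupRecord(
                group_id=row.get(id_col, str(row_index)) if id_col else str(row_index),
                accessions=accessions,
                unique_peptide_counts=uniques,
                total_peptide_counts=totals,
                score=to_float(row.get(score_col, ""), 0.0) if score_col else 0.0,
                is_reverse=is_reverse,
                is_contaminant=is_contaminant,
                row_index=row_index,
            )
        )
    if counts_missing and log is not None:
        log.warn(
            f"{table.name}: per-accession peptide counts missing or inconsistent "
            "for some groups; those groups retain all accessions"
        )
    return records


def filter_decoys_contaminants(
    records: list[ProteinGroupRecord], log: RunLog | None = None
) -> list[ProteinGroupRecord]:
    """Drop reverse (decoy) and contaminant groups, preserving order."""
    surviving = [r for r in records if not (r.is_reverse or r.is_contaminant)]
    removed = len(records) - len(surviving)
    if log is not None and removed:
        n_rev = sum(1 for r in records if r.is_reverse)
        n_con = sum(1 for r in records if r.is_contaminant and not r.is_reverse)
        log.info(
            f"removed {removed} protein groups "
            f"({n_rev} reverse, {n_con} contaminant)"
        )
    return surviving


def minimize_group(
    record: ProteinGroupRecord, log: RunLog | None = None
) -> ProteinGroupRecord:
    """Retain only the best-supported accessions of a group (in place).

    Kept are the accessions with the maximum unique-peptide count and, among
    those, the maximum total-peptide count; original order is preserved and
    the first retained accession becomes the lead.  Groups without usable
    counts retain every accession.
    """
    if not record.accessions:
        record.retained_accessions = []
        record.lead_accession = ""
        return record
    uniques = record.unique_peptide_counts
    totals = record.total_peptide_counts
    if len(uniques) != len(record.accessions) or len(totals) != len(record.accessions):
        if log is not None:
            log.warn(
                f"group {record.group_id}: per-accession counts unavailable; "
                "all accessions retained"
            )
        record.retained_accessions = list(record.accessions)
        record.lead_accession = record.accessions[0]
        return record
    best_unique = max(uniques)
    tied = [i for i, u in enumerate(uniques) if u == best_unique]
    best_total = max(totals[i] for i in tied)
    keep = [i for i in tied if totals[i] == best_total]
    record.retained_accessions = [record.accessions[i] for i in keep]
    record.lead_accession = record.retained_accessions[0]
    return record


def annotate(
    record: ProteinGroupRecord,
    catalog: SequenceCatalog,
    log: RunLog | None = None,
) -> ProteinGroupRecord:
    """Fill gene/description from the catalog entry of the lead accession."""
    entry = catalog.get(record.lead_accession)
    if entry is None:
        record.gene = ""
        record.description = ""
        if log is not None:
            log.warn(
                f"lead accession {record.lead_accession!r} of group "
                f"{record.group_id} not found in the sequence catalog"
            )
    else:
        record.gene = entry.gene
        record.description = entry.description
    return record


def resolve_best_group(
    candidate_group_ids: list[str],
    groups_by_id: dict[str, ProteinGroupRecord],
) -> str | None:
    """Pick the candidate group with the best (largest) score.

    Ties break by original protein-table row order.  Returns ``None`` when no
    candidate survives decoy/contaminant filtering (the caller drops the
    peptide or site with a log entry).
    """
    candidates = [groups_by_id[g] for g in candidate_group_ids if g in groups_by_id]
    if not candidates:
        return None
    best = max(candidates, key=lambda r: (r.score, -r.row_index))
    return best.group_id


def process_protein_groups(
    table: Table,
    catalog: SequenceCatalog,
    log: RunLog | None = None,
) -> tuple[list[ProteinGroupRecord], dict[str, ProteinGroupRecord]]:
    """Filter, minimize and annotate a proteinGroups table.

    Returns the reported records (order preserved) and an id -> record map.
    """
    records = records_from_table(table, log)
    surviving = filter_decoys_contaminants(records, log)
    for record in surviving:
        minimize_group(record, log)
        annotate(record, catalog, log)
    return surviving, {r.group_id: r for r in surviving}


def groups_to_table(records: list[ProteinGroupRecord]) -> Table:
    """Render reported groups as the protein-level output table."""
    titles = [
        "id",
        "Protein IDs",
        "Lead protein",
        "Gene name",
        "Protein description",
        "Peptide counts (unique)",
        "Peptide counts (all)",
        "Score",
    ]
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.group_id,
                "Protein IDs": ";".join(r.retained_accessions or r.accessions),
                "Lead protein": r.lead_accession,
                "Gene name": r.gene,
                "Protein description": r.description,
                "Peptide counts (unique)": str(r.max_unique_count),
                "Peptide counts (all)": str(r.max_total_count),
                "Score": repr(r.score),
            }
        )
    return Table("protein_groups.report", titles, rows)
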