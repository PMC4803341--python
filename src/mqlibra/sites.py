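"""PTM site tables: sequence windows, specific/ambiguous classification, and
recognition of protein N-terminal modification sites from MS/MS evidence.

MaxQuant writes ``<PTM>Sites.txt`` tables for ordinary PTMs but none for
protein N-terminal modifications (e.g. N-terminal acetylation); those are
reconstructed here from ``msms.txt`` by locating the modified peptide at the
start of the protein sequence.  Positions are 1-based on the protein
sequence; sites at position 2 cover initiator-methionine cleavage.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

from .config import ReportingConfig
from .logutil import RunLog
from .mq_io import SequenceCatalog, Table, split_ids, to_float, to_int
from .protein_report import ProteinGroupRecord, resolve_best_group

#: Window padding character beyond protein termini (MaxQuant convention).
PAD = "_"

SPECIFIC = "specific"
AMBIGUOUS = "ambiguous"


@dataclass
class SiteRecord:
    ptm_name: str
    accession: str
    position: int  # 1-based residue index in the protein sequence
    residue: str
    localization_probability: float | None
    site_class: str
    sequence_window: str
    scan_ids: list[str] = field(default_factory=list)
    peptide_sequence: str = ""
    group_id: str = ""
    score: float = 0.0


def extract_sequence_window(sequence: str, position: int, flank: int) -> str:
    """Residue context of length ``2*flank + 1`` centered on *position*.

    Positions past either terminus are padded with ``_``.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if not 1 <= position <= len(sequence):
        raise ValueError(
            f"site position {position} outside sequence of length {len(sequence)}"
        )
    i = position - 1
    left = sequence[max(0, i - flank): i]
    right = sequence[i + 1: i + 1 + flank]
    return PAD * (flank - len(left)) + left + sequence[i] + right + PAD * (flank - len(right))


def classify_site(
    localization_probability: float | None, threshold: float
) -> str:
    """``specific`` iff probability strictly exceeds the threshold.

    Sites whose position is fixed by the peptide termini (protein N-terminal
    sites) carry no probability and count as specific.
    """
    if localization_probability is None:
        return SPECIFIC
    if not 0.0 <= localization_probability <= 1.0:
        raise ValueError(
            f"localization probability {localization_probability} outside [0, 1]"
        )
    return SPECIFIC if localization_probability > threshold else AMBIGUOUS


_PROB_TOKEN = re.compile(r"([A-Z])(?:\((\d*\.?\d+)\))?")


def parse_probability_string(text: str) -> list[tuple[str, float | None]]:
    """Parse a MaxQuant-style probability string like ``A(0.9)PEPT``.

    Returns ``(residue, probability-or-None)`` per peptide position.
    """
    return [
        (residue, float(prob) if prob else None)
        for residue, prob in _PROB_TOKEN.findall(text)
    ]


def locate_peptide(sequence: str, peptide: str, ile_eq_leu: bool = False) -> list[int]:
    """0-based start offsets of *peptide* in *sequence*.

    With ``ile_eq_leu`` the match treats isoleucine and leucine as equal
    (they are isobaric and indistinguishable by standard fragmentation); the
    stored sequences themselves are never mutated.
    """
    if not peptide:
        return []
    if ile_eq_leu:
        sequence = sequence.replace("I", "L")
        peptide = peptide.replace("I", "L")
    hits, start = [], 0
    while True:
        pos = sequence.find(peptide, start)
        if pos < 0:
            return hits
        hits.append(pos)
        start = pos + 1


def detect_nterm_sites(
    msms: Table,
    groups_by_id: dict[str, ProteinGroupRecord],
    catalog: SequenceCatalog,
    config: ReportingConfig,
    ptm_name: str,
    log: RunLog | None = None,
) -> list[SiteRecord]:
    """Recognize protein N-terminal modification sites from the msms table.

    One record per distinct ``(accession, position)`` whose supporting scans
    carry *ptm_name* on a peptide mapping to protein position 1, or position
    2 after initiator-Met cleavage.  The window uses the best-scored group's
    lead accession sequence.
    """
    mod_col = msms.first_column("Modifications")
    seq_col = msms.first_column("Sequence")
    gid_col = msms.first_column("Protein group IDs")
    id_col = msms.first_column("id")
    score_col = msms.first_column("Score")
    prob_col = msms.first_column(f"{ptm_name} Probabilities")
    if mod_col is None or seq_col is None:
        if log is not None:
            log.warn("msms table lacks Modifications/Sequence columns; "
                     f"no {ptm_name} sites detected")
        return []
    found: dict[tuple[str, int], SiteRecord] = {}
    for row_index, row in enumerate(msms.rows):
        if ptm_name not in row.get(mod_col, ""):
            continue
        peptide = row.get(seq_col, "")
        group_id = resolve_best_group(
            split_ids(row.get(gid_col, "")) if gid_col else [], groups_by_id
        )
        if group_id is None:
            if log is not None:
                log.warn(
                    f"msms row {row_index}: no surviving protein group for "
                    f"N-terminal modified peptide {peptide!r}; scan dropped"
                )
            continue
        group = groups_by_id[group_id]
        accession = group.lead_accession
        sequence = catalog.sequence(accession)
        if sequence is None:
            if log is not None:
                log.warn(
                    f"accession {accession!r} missing from catalog; "
                    f"N-terminal site on {peptide!r} skipped"
                )
            continue
        offsets = locate_peptide(sequence, peptide, config.ile_eq_leu)
        if 0 in offsets:
            position = 1
        elif 1 in offsets and sequence.startswith("M"):
            position = 2  # initiator-Met cleaved N-terminus
        else:
            if log is not None:
                log.warn(
                    f"peptide {peptide!r} does not map to the start of "
                    f"{accession}; N-terminal site skipped"
                )
            continue
        prob: float | None = None
        if prob_col and row.get(prob_col, ""):
            parsed = parse_probability_string(row[prob_col])
            if parsed:
                prob = parsed[0][1]
        key = (accession, position)
        scan_id = row.get(id_col, str(row_index)) if id_col else str(row_index)
        score = to_float(row.get(score_col, ""), 0.0) if score_col else 0.0
        if key not in found:
            found[key] = SiteRecord(
                ptm_name=ptm_name,
                accession=accession,
                position=position,
                residue=sequence[position - 1],
                localization_probability=prob,
                site_class="",
                sequence_window=extract_sequence_window(
                    sequence, position, config.flank_length
                ),
                scan_ids=[scan_id],
                peptide_sequence=peptide,
                group_id=group_id,
                score=score,
            )
        else:
            rec = found[key]
            rec.scan_ids.append(scan_id)
            rec.score = max(rec.score, score)
            if prob is not None:
                rec.localization_probability = (
                    prob
                    if rec.localization_probability is None
                    else max(rec.localization_probability, prob)
                )
    records = list(found.values())
    for rec in records:
        rec.site_class = classify_site(
            rec.localization_probability, config.loc_prob_threshold
        )
    return records


def build_site_records_from_mq(
    ptm_name: str,
    site_table: Table,
    groups_by_id: dict[str, ProteinGroupRecord],
    catalog: SequenceCatalog,
    config: ReportingConfig,
    log: RunLog | None = None,
) -> list[SiteRecord]:
    """Convert a MaxQuant ``<PTM>Sites.txt`` table into site records.

    Reverse/contaminant rows and sites whose every candidate group was
    filtered out are dropped; windows are refilled from the catalog.
    """
    acc_col = site_table.first_column("Protein", "Proteins")
    pos_col = site_table.first_column("Position", "Positions within proteins")
    prob_col = site_table.first_column("Localization prob")
    aa_col = site_table.first_column("Amino acid")
    rev_col = site_table.first_column("Reverse")
    con_col = site_table.first_column("Potential contaminant", "Contaminant")
    gid_col = site_table.first_column("Protein group IDs")
    scan_col = site_table.first_column("MS/MS IDs")
    score_col = site_table.first_column("Score")
    records: list[SiteRecord] = []
    for row_index, row in enumerate(site_table.rows):
        if rev_col and row.get(rev_col, "").strip() == "+":
            continue
        if con_col and row.get(con_col, "").strip() == "+":
            continue
        group_id = resolve_best_group(
            split_ids(row.get(gid_col, "")) if gid_col else [], groups_by_id
        )
        if group_id is None:
            if log is not None:
                log.warn(
                    f"{site_table.name} row {row_index}: all candidate groups "
                    "filtered out; site dropped"
                )
            continue
        accession = split_ids(row.get(acc_col, ""))[0] if acc_col and row.get(acc_col) else ""
        position = to_int(split_ids(row.get(pos_col, "0"))[0]) if pos_col else 0
        prob_raw = row.get(prob_col, "") if prob_col else ""
        prob = to_float(prob_raw) if prob_raw.strip() else None
        if prob is not None and prob != prob:  # NaN guard
            prob = None
        sequence = catalog.sequence(accession)
        if sequence is not None and 1 <= position <= len(sequence):
            window = extract_sequence_window(sequence, position, config.flank_length)
            residue = sequence[position - 1]
        else:
            window = ""
            residue = row.get(aa_col, "") if aa_col else ""
            if log is not None:
                log.warn(
                    f"{site_table.name} row {row_index}: accession "
                    f"{accession!r} position {position} not resolvable against "
                    "the catalog; window left empty"
                )
        records.append(
            SiteRecord(
                ptm_name=ptm_name,
                accession=accession,
                position=position,
                residue=residue,
                localization_probability=prob,
                site_class=classify_site(prob, config.loc_prob_threshold),
                sequence_window=window,
                scan_ids=split_ids(row.get(scan_col, "")) if scan_col else [],
                peptide_sequence="",
                group_id=group_id,
                score=to_float(row.get(score_col, ""), 0.0) if score_col else 0.0,
            )
        )
    return records


def site_records_to_table(ptm_name: str, records: list[SiteRecord]) -> Table:
    """Unified site-table schema shared by MaxQuant-derived and detected sites."""
    titles = [
        "PTM",
        "Protein",
        "Position",
        "Amino acid",
        "Localization prob",
        "Site class",
        "Sequence window",
        "Protein group ID",
        "Peptide sequence",
        "MS/MS IDs",
        "Score",
    ]
    rows = []
    for r in records:
        rows.append(
            {
                "PTM": r.ptm_name,
                "Protein": r.accession,
                "Position": str(r.position),
                "Amino acid": r.residue,
                "Localization prob": (
                    "" if r.localization_probability is None
                    else repr(r.localization_probability)
                ),
                "Site class": r.site_class,
                "Sequence window": r.sequence_window,
                "Protein group ID": r.group_id,
                "Peptide sequence": r.peptide_sequence,
                "MS/MS IDs": ";".join(r.scan_ids),
                "Score": repr(r.score),
            }
        )
    return Table(f"sites.{ptm_name}", titles, rows)
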