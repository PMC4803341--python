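"""End-to-end processing of a MaxQuant project directory.

``run_project`` reads the ``combined/txt`` tables, filters and minimizes the
protein groups, builds peptide/site/scan reports, runs isobaric
quantification when reporter columns are present, computes descriptive
statistics, and writes the organized output folder with an ``index.html``.
On failure the log file records an ERROR line and no index page is written.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import libra, report, stats
from .config import (
    CorrectionMatrix,
    ExperimentalDesign,
    HeaderParseRule,
    ReportingConfig,
    is_nterm_ptm,
    load_correction_matrix,
    load_experimental_design,
    load_parse_rule,
    load_reporting_config,
    match_columns,
)
from .logutil import RunLog
from .mq_io import (
    SequenceCatalog,
    Table,
    read_fasta,
    read_table,
    split_ids,
    table_header,
)
from .protein_report import (
    ProteinGroupRecord,
    groups_to_table,
    process_protein_groups,
    resolve_best_group,
)
from .sites import (
    SiteRecord,
    build_site_records_from_mq,
    detect_nterm_sites,
    site_records_to_table,
)

#: Name of the output folder created inside the project directory.
OUTPUT_FOLDER = "mqlibra"


class PipelineError(RuntimeError):
    """A fatal processing failure; details are in the run log."""


@dataclass
class ProjectResult:
    project_dir: Path
    out_dir: Path
    config: ReportingConfig
    catalog: SequenceCatalog
    groups: list[ProteinGroupRecord]
    groups_by_id: dict[str, ProteinGroupRecord]
    protein_table: Table
    peptide_table: Table
    msms_table: Table
    site_records: dict[str, list[SiteRecord]]
    site_tables: dict[str, Table]
    design: ExperimentalDesign
    spectra: libra.SpectrumSet | None
    quant: dict[str, libra.QuantTables] = field(default_factory=dict)
    summary: stats.StatsSummary | None = None
    replication: dict[str, pd.DataFrame] = field(default_factory=dict)
    log: RunLog | None = None


def _read_selected(
    path: Path, logical_table: str, config: ReportingConfig, log: RunLog
) -> Table:
    header = table_header(path)
    selected = match_columns(header, config.table_specs[logical_table], log)
    return read_table(path, selected_titles=selected, log=log)


def _filter_by_groups(
    table: Table, groups_by_id: dict[str, ProteinGroupRecord], log: RunLog
) -> Table:
    """Keep rows referencing at least one surviving protein group."""
    gid_col = table.first_column("Protein group IDs")
    if gid_col is None:
        return table
    kept = [
        row
        for row in table.rows
        if any(g in groups_by_id for g in split_ids(row.get(gid_col, "")))
    ]
    dropped = len(table.rows) - len(kept)
    if dropped:
        log.info(
            f"{table.name}: dropped {dropped} rows whose protein groups were "
            "all filtered out"
        )
    return Table(table.name, table.column_titles, kept, table.source_path)


def _annotate_peptides(
    table: Table, groups_by_id: dict[str, ProteinGroupRecord]
) -> Table:
    gid_col = table.first_column("Protein group IDs")
    titles = table.column_titles + [
        "Resolved protein group", "Lead protein", "Gene name",
        "Protein description",
    ]
    rows = []
    for row in table.rows:
        resolved = resolve_best_group(
            split_ids(row.get(gid_col, "")) if gid_col else [], groups_by_id
        )
        group = groups_by_id.get(resolved) if resolved else None
        rows.append(
            {
                **row,
                "Resolved protein group": resolved or "",
                "Lead protein": group.lead_accession if group else "",
                "Gene name": group.gene if group else "",
                "Protein description": group.description if group else "",
            }
        )
    return Table(table.name, titles, rows, table.source_path)


def run_project(
    project_dir: str | Path,
    config: str | Path | ReportingConfig,
    fasta_paths: list[str | Path],
    rule_paths: list[str | Path | HeaderParseRule],
    correction_matrix: str | Path | CorrectionMatrix | None = None,
    design_template: str | Path | None = None,
    out_dir: str | Path | None = None,
    command_line: str = "",
) -> ProjectResult:
    """Process one project directory and write the report bundle."""
    project_dir = Path(project_dir)
    out_dir = Path(out_dir) if out_dir is not None else project_dir / OUTPUT_FOLDER
    if out_dir.exists():
        preexisting = True
    else:
        preexisting = False
    out_dir.mkdir(parents=True, exist_ok=True)
    log = RunLog(out_dir / "log.txt")
    if preexisting:
        log.info(f"output folder {out_dir} already existed; files overwritten")
    index_path = out_dir / "index.html"
    if index_path.exists():
        index_path.unlink()
    try:
        result = _run(project_dir, config, fasta_paths, rule_paths,
                      correction_matrix, design_template, out_dir,
                      command_line, log)
    except Exception as exc:
        log.error(f"processing failed: {exc}")
        raise PipelineError(str(exc)) from exc
    log.info("all processes completed")
    return result


def _run(
    project_dir: Path,
    config,
    fasta_paths,
    rule_paths,
    correction_matrix,
    design_template,
    out_dir: Path,
    command_line: str,
    log: RunLog,
) -> ProjectResult:
    txt = project_dir / "combined" / "txt"
    if not txt.is_dir():
        raise FileNotFoundError(f"no combined/txt folder under {project_dir}")
    if not isinstance(config, ReportingConfig):
        config = load_reporting_config(config, log)
        log.info("reporting configuration loaded")
    rules = [
        r if isinstance(r, HeaderParseRule) else load_parse_rule(r)
        for r in rule_paths
    ]
    catalog = read_fasta(fasta_paths, rules, log)
    log.info(f"sequence catalog built: {len(catalog)} accessions")

    protein_raw = _read_selected(txt / "proteinGroups.txt", "protein_groups", config, log)
    groups, groups_by_id = process_protein_groups(protein_raw, catalog, log)
    protein_table = groups_to_table(groups)
    log.info(f"{len(groups)} protein groups reported after filtering/minimization")

    peptide_raw = _read_selected(txt / "peptides.txt", "peptides", config, log)
    peptide_table = _annotate_peptides(
        _filter_by_groups(peptide_raw, groups_by_id, log), groups_by_id
    )
    msms_raw = _read_selected(txt / "msms.txt", "msms", config, log)
    msms_table = _filter_by_groups(msms_raw, groups_by_id, log)
    log.info(
        f"{len(peptide_table)} peptides and {len(msms_table)} MS/MS scans reported"
    )

    # ---- site tables -----------------------------------------------------
    site_records: dict[str, list[SiteRecord]] = {}
    site_tables: dict[str, Table] = {}
    for ptm in config.ptm_names:
        if is_nterm_ptm(ptm):
            records = detect_nterm_sites(
                msms_table, groups_by_id, catalog, config, ptm, log
            )
        else:
            site_path = txt / f"{ptm}Sites.txt"
            if not site_path.exists():
                log.warn(f"site table {site_path.name} not found; {ptm} skipped")
                continue
            raw = _read_selected(site_path, "sites", config, log)
            records = build_site_records_from_mq(
                ptm, raw, groups_by_id, catalog, config, log
            )
        site_records[ptm] = records
        site_tables[ptm] = site_records_to_table(ptm, records)
        log.info(f"{ptm}: {len(records)} sites reported")

    # ---- experimental design and quantification --------------------------
    summary_path = txt / "summary.txt"
    summary_table = (
        _read_selected(summary_path, "summary", config, log)
        if summary_path.exists()
        else None
    )
    design = load_experimental_design(summary_table, design_template, log)
    log.info(
        f"experimental design: {len(design.replicates)} replicate(s) "
        f"({', '.join(design.replicates)})"
    )
    if correction_matrix is not None and not isinstance(correction_matrix, CorrectionMatrix):
        correction_matrix = load_correction_matrix(correction_matrix, log)
    spectra = libra.prepare_spectra(msms_table, correction_matrix, config, log)
    quant: dict[str, libra.QuantTables] = {}
    if spectra is not None and spectra.n_spectra:
        entity_maps = {
            "protein_groups": libra.protein_entity_scans(
                msms_table, groups_by_id, config, log
            ),
            "peptides": libra.peptide_entity_scans(msms_table),
            "sites": {
                k: v
                for records in site_records.values()
                for k, v in libra.site_entity_scans(records).items()
            },
        }
        for level, scans in entity_maps.items():
            quant[level] = libra.quantify_level(
                level, scans, spectra, design, config, log
            )
            log.info(f"quantified {quant[level].n_quantified} {level}")

    # ---- statistics ------------------------------------------------------
    summary = stats.compute_identification_stats(
        groups, peptide_table, msms_table, site_records
    )
    stats.attach_quantification_stats(summary, spectra, quant)
    replication = stats.compute_replication_assignment(
        groups, peptide_table, msms_table, site_records, design, log
    )

    result = ProjectResult(
        project_dir=project_dir,
        out_dir=out_dir,
        config=config,
        catalog=catalog,
        groups=groups,
        groups_by_id=groups_by_id,
        protein_table=protein_table,
        peptide_table=peptide_table,
        msms_table=msms_table,
        site_records=site_records,
        site_tables=site_tables,
        design=design,
        spectra=spectra,
        quant=quant,
        summary=summary,
        replication=replication,
        log=log,
    )
    _write_outputs(result, command_line, log)
    return result


def _safe(name: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in name).strip("_")


def _write_outputs(result: ProjectResult, command_line: str, log: RunLog) -> None:
    out = result.out_dir
    manifest: dict[str, list[tuple[str, str]]] = {s: [] for s in report.INDEX_SECTIONS}
    manifest["Input parameters"].append(
        (command_line or "(invoked from the Python API)", "")
    )

    workbook_tables: list[tuple[str, Table | pd.DataFrame]] = []

    def _emit_table(table: Table, filename: str, section: str, label: str) -> None:
        report.write_table(table, out / filename)
        manifest[section].append((label, filename))
        workbook_tables.append((Path(filename).stem, table))

    _emit_table(result.protein_table, "proteinGroups.report.txt",
                "Identification results", "Protein groups (minimized)")
    _emit_table(result.peptide_table, "peptides.report.txt",
                "Identification results", "Peptides")
    _emit_table(result.msms_table, "msms.report.txt",
                "Identification results", "MS/MS scans (annotated spectra)")
    for ptm, table in result.site_tables.items():
        _emit_table(table, f"sites.{_safe(ptm)}.txt",
                    "Identification results", f"Sites: {ptm}")

    # statistics
    stats_df = stats.summary_to_table(result.summary)
    report.write_dataframe(stats_df, out / "statistics.txt")
    manifest["Summary and descriptive statistics"].append(
        ("Descriptive statistics", "statistics.txt")
    )
    workbook_tables.append(("statistics", stats_df))
    charts = stats.emit_charts(result.summary, out / "charts", log)
    for tsv, svg in charts:
        manifest["Summary and descriptive statistics"].append(
            (f"Chart data: {tsv.stem}", f"charts/{tsv.name}")
        )
        if svg is not None:
            manifest["Summary and descriptive statistics"].append(
                (f"Chart: {svg.stem}", f"charts/{svg.name}")
            )
    for level, df in result.replication.items():
        filename = f"replication.{level}.txt"
        report.write_dataframe(df, out / filename)
        manifest["Summary and descriptive statistics"].append(
            (f"Replication assignment: {level}", filename)
        )

    # quantification
    if result.quant:
        for level, tables in result.quant.items():
            for replicate, df in tables.per_replicate.items():
                if df.empty:
                    continue
                filename = f"quant.{level}.{_safe(replicate)}.txt"
                report.write_dataframe(df, out / filename)
                manifest["Quantification based on isobaric labelling"].append(
                    (f"{level} ({replicate})", filename)
                )
            filename = f"quant.{level}.merged.txt"
            report.write_dataframe(tables.merged, out / filename)
            manifest["Quantification based on isobaric labelling"].append(
                (f"{level} (merged)", filename)
            )
            workbook_tables.append((f"quant {level}", tables.merged))
        if result.spectra is not None:
            factors = pd.DataFrame(
                {
                    "channel": result.spectra.calibration.channel_labels,
                    "factor": result.spectra.calibration.factors,
                }
            )
            report.write_dataframe(factors, out / "calibration_factors.txt")
            manifest["Quantification based on isobaric labelling"].append(
                ("Calibration factors", "calibration_factors.txt")
            )
            workbook_tables.append(("calibration factors", factors))
    else:
        manifest["Quantification based on isobaric labelling"].append(
            ("not performed (no reporter-ion intensities found)", "")
        )

    # miscellaneous
    leads = [g.lead_accession for g in result.groups if g.lead_accession]
    report.write_fasta(result.catalog, leads, out / "sequences.fasta")
    manifest["Miscellaneous"].append(
        ("Extracted protein sequences", "sequences.fasta")
    )
    id_col = result.msms_table.first_column("id")
    scan_ids = result.msms_table.column(id_col) if id_col else []
    (out / "msms_scan_ids.txt").write_text(
        "\n".join(scan_ids) + ("\n" if scan_ids else ""), encoding="utf-8"
    )
    manifest["Miscellaneous"].append(("MS/MS scan identities", "msms_scan_ids.txt"))
    try:
        report.export_workbook(workbook_tables, out / "combined_report.xlsx", log)
        manifest["Miscellaneous"].append(
            ("Combined workbook", "combined_report.xlsx")
        )
    except Exception as exc:
        log.warn(f"workbook export failed: {exc}")

    manifest["Log file"].append(("Processing log", "log.txt"))
    report.build_index(manifest, out / "index.html")
    log.info("index page written")
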