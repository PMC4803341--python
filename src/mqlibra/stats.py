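"""Descriptive statistics over identification and quantification results.

Every chart is written twice: the numeric series as a TSV file (the
authoritative data contract) and an SVG rendering for viewing.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .config import ExperimentalDesign
from .libra import ChannelCalibration, QuantTables, SpectrumSet
from .logutil import RunLog
from .mq_io import Table, split_ids, to_int
from .protein_report import ProteinGroupRecord
from .sites import SPECIFIC, SiteRecord


@dataclass
class PtmStats:
    n_sites: int = 0
    n_specific: int = 0
    n_spectra: int = 0
    n_peptides: int = 0
    n_protein_groups: int = 0
    site_count_distribution: dict[int, int] = field(default_factory=dict)


@dataclass
class StatsSummary:
    n_protein_groups: int = 0
    n_peptides: int = 0
    n_spectra: int = 0
    ptm: dict[str, PtmStats] = field(default_factory=dict)
    peptide_count_distribution: dict[str, dict[int, int]] = field(default_factory=dict)
    replicate_presence: dict[str, pd.DataFrame] = field(default_factory=dict)
    calibration_factors: dict[str, float] | None = None
    quantified_counts: dict[str, int] = field(default_factory=dict)


def compute_identification_stats(
    protein_records: list[ProteinGroupRecord],
    peptide_table: Table,
    msms_table: Table,
    site_records: dict[str, list[SiteRecord]],
) -> StatsSummary:
    """Counts and distributions over the reported identification tables."""
    summary = StatsSummary(
        n_protein_groups=len(protein_records),
        n_peptides=len(peptide_table),
        n_spectra=len(msms_table),
    )
    summary.peptide_count_distribution = {
        "all": dict(Counter(r.max_total_count for r in protein_records)),
        "unique": dict(Counter(r.max_unique_count for r in protein_records)),
    }
    for ptm_name, records in site_records.items():
        stats = PtmStats(
            n_sites=len(records),
            n_specific=sum(1 for r in records if r.site_class == SPECIFIC),
            n_spectra=len({s for r in records for s in r.scan_ids}),
            n_peptides=len(
                {r.peptide_sequence for r in records if r.peptide_sequence}
            ),
            n_protein_groups=len({r.group_id for r in records}),
        )
        per_protein = Counter(r.accession for r in records)
        stats.site_count_distribution = dict(Counter(per_protein.values()))
        summary.ptm[ptm_name] = stats
    return summary


def compute_replication_assignment(
    protein_records: list[ProteinGroupRecord],
    peptide_table: Table,
    msms_table: Table,
    site_records: dict[str, list[SiteRecord]],
    design: ExperimentalDesign,
    log: RunLog | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-entity replicate presence matrices for all four reporting levels.

    Presence means the entity has at least one supporting scan in that
    replicate.  Designs with a single replicate are skipped with a log note.
    """
    if len(design.replicates) < 2:
        if log is not None:
            log.info(
                "single-replicate design; replication assignment files skipped"
            )
        return {}
    raw_col = msms_table.first_column("Raw file")
    id_col = msms_table.first_column("id")
    gid_col = msms_table.first_column("Protein group IDs")
    pep_col = msms_table.first_column("Peptide ID")
    scan_replicate: dict[str, str] = {}
    group_reps: dict[str, set[str]] = {}
    pep_reps: dict[str, set[str]] = {}
    scan_reps: dict[str, set[str]] = {}
    for i, row in enumerate(msms_table.rows):
        replicate = design.replicate_of(row.get(raw_col, ""), log) if raw_col else ""
        scan = row.get(id_col, str(i)) if id_col else str(i)
        scan_replicate[scan] = replicate
        scan_reps.setdefault(scan, set()).add(replicate)
        for gid in split_ids(row.get(gid_col, "")) if gid_col else []:
            group_reps.setdefault(gid, set()).add(replicate)
        pep = row.get(pep_col, "") if pep_col else ""
        if pep:
            pep_reps.setdefault(pep, set()).add(replicate)

    def _matrix(entity_reps: dict[str, set[str]], entity_order: list[str]) -> pd.DataFrame:
        rows = []
        for entity in entity_order:
            reps = entity_reps.get(entity, set())
            rows.append(
                {"id": entity, **{r: int(r in reps) for r in design.replicates}}
            )
        return pd.DataFrame(rows, columns=["id", *design.replicates])

    pep_id_col = peptide_table.first_column("id")
    peptide_ids = (
        [row.get(pep_id_col, "") for row in peptide_table.rows] if pep_id_col else []
    )
    out = {
        "protein_groups": _matrix(group_reps, [r.group_id for r in protein_records]),
        "peptides": _matrix(pep_reps, peptide_ids),
        "msms": _matrix(scan_reps, list(scan_reps)),
    }
    site_reps: dict[str, set[str]] = {}
    site_order: list[str] = []
    for ptm_name, records in site_records.items():
        for rec in records:
            entity = f"{ptm_name}:{rec.accession}:{rec.position}"
            site_order.append(entity)
            site_reps[entity] = {
                scan_replicate[s] for s in rec.scan_ids if s in scan_replicate
            }
    if site_order:
        out["sites"] = _matrix(site_reps, site_order)
    return out


def attach_quantification_stats(
    summary: StatsSummary,
    spectra: SpectrumSet | None,
    quant: dict[str, QuantTables],
) -> StatsSummary:
    """Record exported calibration factors and quantified-entity counts."""
    if spectra is not None:
        summary.calibration_factors = dict(
            zip(spectra.calibration.channel_labels,
                (float(f) for f in spectra.calibration.factors))
        )
    summary.quantified_counts = {
        level: tables.n_quantified for level, tables in quant.items()
    }
    return summary


# ---------------------------------------------------------------------------
# Chart emission (TSV series + SVG rendering)

def _write_series(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def chart_series(summary: StatsSummary) -> dict[str, pd.DataFrame]:
    """The numeric data series behind every chart, keyed by chart name."""
    series: dict[str, pd.DataFrame] = {
        "identification_summary": pd.DataFrame(
            {
                "category": ["protein groups", "peptides", "spectra"],
                "count": [
                    summary.n_protein_groups,
                    summary.n_peptides,
                    summary.n_spectra,
                ],
            }
        )
    }
    for which in ("all", "unique"):
        dist = summary.peptide_count_distribution.get(which, {})
        if dist:
            series[f"peptide_count_distribution_{which}"] = pd.DataFrame(
                sorted(dist.items()), columns=["peptides_per_group", "n_groups"]
            )
    for ptm_name, stats in summary.ptm.items():
        safe = _safe_name(ptm_name)
        series[f"ptm_summary_{safe}"] = pd.DataFrame(
            {
                "category": [
                    "sites", "specific sites", "spectra", "peptides",
                    "protein groups",
                ],
                "count": [
                    stats.n_sites, stats.n_specific, stats.n_spectra,
                    stats.n_peptides, stats.n_protein_groups,
                ],
            }
        )
        if stats.n_sites:
            n_ambiguous = stats.n_sites - stats.n_specific
            total = stats.n_sites
            series[f"site_class_proportions_{safe}"] = pd.DataFrame(
                {
                    "site_class": ["specific", "ambiguous"],
                    "count": [stats.n_specific, n_ambiguous],
                    "percent": [
                        100.0 * stats.n_specific / total,
                        100.0 * n_ambiguous / total,
                    ],
                }
            )
        if stats.site_count_distribution:
            series[f"site_count_distribution_{safe}"] = pd.DataFrame(
                sorted(stats.site_count_distribution.items()),
                columns=["sites_per_protein", "n_proteins"],
            )
    if summary.calibration_factors:
        series["calibration_factors"] = pd.DataFrame(
            summary.calibration_factors.items(), columns=["channel", "factor"]
        )
    if summary.quantified_counts:
        series["quantification_summary"] = pd.DataFrame(
            summary.quantified_counts.items(), columns=["level", "n_quantified"]
        )
    return series


def _safe_name(name: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in name).strip("_")


def emit_charts(
    summary: StatsSummary, out_dir: str | Path, log: RunLog | None = None
) -> list[tuple[Path, Path | None]]:
    """Write every chart as a TSV data series plus an SVG rendering.

    Returns ``(tsv_path, svg_path-or-None)`` pairs.  If the chart backend
    fails, the TSV is still written and a warning is logged — the numeric
    series is the contract, the rendering is presentation.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[tuple[Path, Path | None]] = []
    for name, df in chart_series(summary).items():
        tsv = out_dir / f"{name}.tsv"
        _write_series(df, tsv)
        svg: Path | None = out_dir / f"{name}.svg"
        try:
            _render_chart(name, df, svg)
        except Exception as exc:  # charting must never sink the run
            if log is not None:
                log.warn(f"chart {name} could not be rendered: {exc}")
            svg = None
        written.append((tsv, svg))
    return written


def _render_chart(name: str, df: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    try:
        if "site_class" in df.columns:
            ax.pie(df["count"], labels=df[df.columns[0]], autopct="%1.1f%%")
        else:
            labels = df[df.columns[0]].astype(str)
            ax.bar(labels, df[df.columns[-1]])
            ax.set_ylabel(df.columns[-1])
            ax.tick_params(axis="x", rotation=30)
        ax.set_title(name.replace("_", " "))
        fig.tight_layout()
        fig.savefig(path, format="svg")
    finally:
        plt.close(fig)


def summary_to_table(summary: StatsSummary) -> pd.DataFrame:
    """Flat key/value rendering of the summary for the statistics TSV."""
    rows: list[dict[str, object]] = [
        {"statistic": "protein groups", "value": summary.n_protein_groups},
        {"statistic": "peptides", "value": summary.n_peptides},
        {"statistic": "spectra", "value": summary.n_spectra},
    ]
    for ptm_name, stats in summary.ptm.items():
        rows += [
            {"statistic": f"{ptm_name}: sites", "value": stats.n_sites},
            {"statistic": f"{ptm_name}: specific sites", "value": stats.n_specific},
            {"statistic": f"{ptm_name}: spectra", "value": stats.n_spectra},
            {"statistic": f"{ptm_name}: peptides", "value": stats.n_peptides},
            {"statistic": f"{ptm_name}: protein groups", "value": stats.n_protein_groups},
        ]
    if summary.calibration_factors:
        for channel, factor in summary.calibration_factors.items():
            rows.append(
                {"statistic": f"calibration factor {channel}", "value": factor}
            )
    for level, count in summary.quantified_counts.items():
        rows.append({"statistic": f"quantified {level}", "value": count})
    return pd.DataFrame(rows)
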