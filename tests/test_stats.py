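"""Descriptive statistics, replication assignment and chart series."""
from __future__ import annotations

import pytest

from mqlibra.config import ExperimentalDesign
from mqlibra.logutil import RunLog
from mqlibra.mq_io import Table
from mqlibra.protein_report import ProteinGroupRecord, minimize_group
from mqlibra.sites import SiteRecord
from mqlibra.stats import (
    chart_series,
    compute_identification_stats,
    compute_replication_assignment,
    emit_charts,
)


def _group(gid, n_unique, n_total):
    return minimize_group(
        ProteinGroupRecord(gid, ["P" + gid], [n_unique], [n_total], 1.0,
                           False, False, int(gid))
    )


def _site(acc, pos, site_class="specific", scans=("0",), ptm="X"):
    return SiteRecord(
        ptm_name=ptm, accession=acc, position=pos, residue="A",
        localization_probability=0.9, site_class=site_class,
        sequence_window="A" * 13, scan_ids=list(scans), group_id="0",
    )


def _table(name, titles, rows):
    return Table(name, titles, rows)


def test_peptide_count_distribution():
    """3 proteins with total peptide counts [1,2,2] -> histogram {1:1, 2:2}."""
    groups = [_group("0", 1, 1), _group("1", 2, 2), _group("2", 2, 2)]
    summary = compute_identification_stats(
        groups,
        _table("pep", ["id"], [{"id": "0"}] * 5),
        _table("msms", ["id"], [{"id": str(i)} for i in range(9)]),
        {},
    )
    assert summary.n_protein_groups == 3
    assert summary.n_peptides == 5
    assert summary.n_spectra == 9
    assert summary.peptide_count_distribution["all"] == {1: 1, 2: 2}


def test_empty_site_table_gives_zero_counts():
    summary = compute_identification_stats(
        [_group("0", 1, 1)], _table("pep", ["id"], []),
        _table("msms", ["id"], []), {"Oxidation (M)": []},
    )
    stats = summary.ptm["Oxidation (M)"]
    assert stats.n_sites == stats.n_specific == stats.n_spectra == 0


def test_site_count_distribution_over_proteins():
    records = [_site("P1", 1), _site("P1", 5), _site("P2", 3)]
    summary = compute_identification_stats(
        [_group("0", 1, 1)], _table("pep", ["id"], []),
        _table("msms", ["id"], []), {"X": records},
    )
    assert summary.ptm["X"].site_count_distribution == {2: 1, 1: 1}
    # distribution totals equal the parent site count
    dist = summary.ptm["X"].site_count_distribution
    assert sum(k * v for k, v in dist.items()) == summary.ptm["X"].n_sites


def test_single_replicate_design_skips_assignment():
    log = RunLog()
    out = compute_replication_assignment(
        [], _table("pep", ["id"], []), _table("msms", ["id", "Raw file"], []),
        {}, ExperimentalDesign({"f1": "R1"}, ["R1"]), log,
    )
    assert out == {}
    assert any("skipped" in m for m in log.messages("INFO"))


def test_presence_matrix_matches_scan_layout():
    msms = _table(
        "msms", ["id", "Raw file", "Protein group IDs", "Peptide ID"],
        [
            {"id": "0", "Raw file": "f1", "Protein group IDs": "0", "Peptide ID": "0"},
            {"id": "1", "Raw file": "f1", "Protein group IDs": "1", "Peptide ID": "1"},
            {"id": "2", "Raw file": "f2", "Protein group IDs": "1", "Peptide ID": "1"},
        ],
    )
    design = ExperimentalDesign({"f1": "R1", "f2": "R2"}, ["R1", "R2"])
    out = compute_replication_assignment(
        [_group("0", 1, 1), _group("1", 1, 1)],
        _table("pep", ["id"], [{"id": "0"}, {"id": "1"}]), msms, {}, design,
    )
    groups = out["protein_groups"].set_index("id")
    assert groups.loc["0"].tolist() == [1, 0]
    assert groups.loc["1"].tolist() == [1, 1]


def test_every_chart_has_a_tsv_twin(tmp_path):
    summary = compute_identification_stats(
        [_group("0", 1, 1)], _table("pep", ["id"], [{"id": "0"}]),
        _table("msms", ["id"], [{"id": "0"}]),
        {"X": [_site("P1", 1), _site("P1", 2, site_class="ambiguous")]},
    )
    written = emit_charts(summary, tmp_path)
    assert written
    for tsv, svg in written:
        assert tsv.exists()
        if svg is not None:
            assert svg.exists()
            assert svg.stem == tsv.stem


def test_site_class_pie_sums_to_100():
    summary = compute_identification_stats(
        [], _table("pep", ["id"], []), _table("msms", ["id"], []),
        {"X": [_site("P1", 1), _site("P1", 2, site_class="ambiguous"),
               _site("P2", 3)]},
    )
    series = chart_series(summary)
    pie = series["site_class_proportions_X"]
    assert pie["percent"].sum() == pytest.approx(100.0)


def test_no_ptms_no_ptm_charts():
    summary = compute_identification_stats(
        [_group("0", 1, 1)], _table("pep", ["id"], []), _table("msms", ["id"], []), {}
    )
    assert not any(k.startswith("ptm_") for k in chart_series(summary))
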