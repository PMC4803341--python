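"""Sequence windows, site classification and N-terminal site detection."""
from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mqlibra.config import ReportingConfig
from mqlibra.logutil import RunLog
from mqlibra.mq_io import CatalogEntry, SequenceCatalog, Table
from mqlibra.protein_report import ProteinGroupRecord, minimize_group
from mqlibra.sites import (
    AMBIGUOUS,
    SPECIFIC,
    build_site_records_from_mq,
    classify_site,
    detect_nterm_sites,
    extract_sequence_window,
    locate_peptide,
    parse_probability_string,
    site_records_to_table,
)

NTERM = "Acetyl (Protein N-term)"


# ---------------------------------------------------------------------------
# sequence windows

@pytest.mark.parametrize(
    "sequence, position, flank, expected",
    [
        ("MKLV", 1, 6, "______MKLV___"),
        ("MKLV", 2, 0, "K"),
        ("ABCDEFGHIJKLM", 7, 6, "ABCDEFGHIJKLM"),  # exact fit, no padding
        ("MK", 2, 3, "__MK__"[0:3] + "K" + "___"[0:3]),
    ],
)
def test_window_examples(sequence, position, flank, expected):
    window = extract_sequence_window(sequence, position, flank)
    assert window == expected
    assert len(window) == 2 * flank + 1


def test_window_out_of_range_errors():
    with pytest.raises(ValueError, match="position 9"):
        extract_sequence_window("MKLV", 9, 6)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(data=st.data())
def test_window_stripped_is_substring_containing_position(data):
    sequence = data.draw(st.text(alphabet="ACDEFGHIKLM", min_size=1, max_size=30))
    position = data.draw(st.integers(1, len(sequence)))
    flank = data.draw(st.integers(0, 8))
    window = extract_sequence_window(sequence, position, flank)
    stripped = window.strip("_")
    assert len(window) == 2 * flank + 1
    assert stripped in sequence
    assert window[flank] == sequence[position - 1]


# ---------------------------------------------------------------------------
# classification

@pytest.mark.parametrize(
    "prob, threshold, expected",
    [
        (0.97, 0.5, SPECIFIC),
        (0.50, 0.5, AMBIGUOUS),  # strict inequality
        (None, 0.5, SPECIFIC),   # position fixed by peptide termini
        (0.0, 0.5, AMBIGUOUS),
    ],
)
def test_classify_site(prob, threshold, expected):
    assert classify_site(prob, threshold) == expected


def test_classify_rejects_out_of_range_probability():
    with pytest.raises(ValueError):
        classify_site(1.2, 0.5)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    p=st.floats(0, 1), q=st.floats(0, 1),
    threshold=st.floats(0, 1),
)
def test_classification_monotone_in_probability(p, q, threshold):
    lo, hi = sorted((p, q))
    if classify_site(lo, threshold) == SPECIFIC:
        assert classify_site(hi, threshold) == SPECIFIC


def test_parse_probability_string():
    parsed = parse_probability_string("A(0.9)PEP(0.1)T")
    assert parsed == [("A", 0.9), ("P", None), ("E", None), ("P", 0.1), ("T", None)]


# ---------------------------------------------------------------------------
# peptide location / Ile=Leu

def test_locate_peptide_all_occurrences():
    assert locate_peptide("ABABAB", "ABAB") == [0, 2]


def test_ile_eq_leu_matching_only_when_enabled():
    assert locate_peptide("MKIVR", "KLV") == []
    assert locate_peptide("MKIVR", "KLV", ile_eq_leu=True) == [1]


# ---------------------------------------------------------------------------
# N-terminal detection

SEQ1 = "MAPEPTIDEKLVNNNNNNNN"


def _groups():
    g0 = minimize_group(
        ProteinGroupRecord("0", ["PROT1"], [3], [3], 50.0, False, False, 0)
    )
    return {"0": g0}


def _catalog():
    return SequenceCatalog({"PROT1": CatalogEntry(SEQ1)})


def _msms(rows):
    titles = ["id", "Sequence", "Modifications", "Protein group IDs", "Score",
              f"{NTERM} Probabilities"]
    return Table("msms", titles, rows)


def _row(i, seq, mods=NTERM, prob=""):
    return {"id": str(i), "Sequence": seq, "Modifications": mods,
            "Protein group IDs": "0", "Score": "99", f"{NTERM} Probabilities": prob}


def test_detect_site_at_position_one():
    records = detect_nterm_sites(
        _msms([_row(0, "MAPEPTIDEK")]), _groups(), _catalog(),
        ReportingConfig(ptm_names=[NTERM]), NTERM,
    )
    assert len(records) == 1
    assert (records[0].accession, records[0].position) == ("PROT1", 1)
    assert records[0].residue == "M"
    assert records[0].site_class == SPECIFIC  # no probability -> specific


def test_detect_met_cleaved_site_at_position_two():
    records = detect_nterm_sites(
        _msms([_row(0, "APEPTIDEK")]), _groups(), _catalog(),
        ReportingConfig(ptm_names=[NTERM]), NTERM,
    )
    assert len(records) == 1
    assert records[0].position == 2
    assert records[0].residue == "A"


def test_internal_peptide_does_not_create_nterm_site():
    log = RunLog()
    records = detect_nterm_sites(
        _msms([_row(0, "PEPTIDEK")]), _groups(), _catalog(),
        ReportingConfig(ptm_names=[NTERM]), NTERM, log,
    )
    assert records == []
    assert len(log.messages("WARN")) == 1


def test_no_modified_scans_yields_empty_list():
    records = detect_nterm_sites(
        _msms([_row(0, "MAPEPTIDEK", mods="Unmodified")]), _groups(), _catalog(),
        ReportingConfig(ptm_names=[NTERM]), NTERM,
    )
    assert records == []


def test_supporting_scans_are_aggregated_and_probability_maxed():
    records = detect_nterm_sites(
        _msms([
            _row(0, "MAPEPTIDEK", prob="M(0.4)APEPTIDEK"),
            _row(1, "MAPEPTIDEK", prob="M(0.9)APEPTIDEK"),
        ]),
        _groups(), _catalog(), ReportingConfig(ptm_names=[NTERM]), NTERM,
    )
    assert len(records) == 1
    assert records[0].scan_ids == ["0", "1"]
    assert records[0].localization_probability == 0.9
    assert records[0].site_class == SPECIFIC


# ---------------------------------------------------------------------------
# MaxQuant-style site tables

def _site_table(rows):
    titles = ["id", "Protein", "Position", "Amino acid", "Localization prob",
              "Score", "MS/MS IDs", "Protein group IDs", "Reverse",
              "Potential contaminant"]
    return Table("Oxidation (M)Sites", titles, rows)


def _site_row(i, protein="PROT1", position="3", prob="0.8", gid="0",
              reverse="", contaminant=""):
    return {"id": str(i), "Protein": protein, "Position": position,
            "Amino acid": "P", "Localization prob": prob, "Score": "77",
            "MS/MS IDs": "0;1", "Protein group IDs": gid, "Reverse": reverse,
            "Potential contaminant": contaminant}


def test_reverse_rows_filtered_from_site_table():
    records = build_site_records_from_mq(
        "Oxidation (M)",
        _site_table([_site_row(0), _site_row(1, reverse="+"), _site_row(2),
                     _site_row(3)]),
        _groups(), _catalog(), ReportingConfig(),
    )
    assert len(records) == 3


def test_site_with_only_filtered_group_dropped():
    records = build_site_records_from_mq(
        "Oxidation (M)", _site_table([_site_row(0, gid="99")]),
        _groups(), _catalog(), ReportingConfig(),
    )
    assert records == []


def test_site_table_schema_shared_across_sources():
    mq = build_site_records_from_mq(
        "Oxidation (M)", _site_table([_site_row(0)]),
        _groups(), _catalog(), ReportingConfig(),
    )
    detected = detect_nterm_sites(
        _msms([_row(0, "MAPEPTIDEK")]), _groups(), _catalog(),
        ReportingConfig(ptm_names=[NTERM]), NTERM,
    )
    t1 = site_records_to_table("Oxidation (M)", mq)
    t2 = site_records_to_table(NTERM, detected)
    assert t1.column_titles == t2.column_titles
    assert len(t1) == 1 and len(t2) == 1
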