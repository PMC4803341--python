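"""Protein-group filtering, minimization and annotation."""
from __future__ import annotations

import numpy as np
import pytest

from mqlibra.logutil import RunLog
from mqlibra.mq_io import CatalogEntry, SequenceCatalog
from mqlibra.protein_report import (
    ProteinGroupRecord,
    annotate,
    filter_decoys_contaminants,
    minimize_group,
    records_from_table,
    resolve_best_group,
)
from mqlibra.mq_io import Table


def make_group(accessions, unique, total, score=10.0, group_id="g",
               reverse=False, contaminant=False, row_index=0):
    return ProteinGroupRecord(
        group_id=group_id,
        accessions=list(accessions),
        unique_peptide_counts=list(unique),
        total_peptide_counts=list(total),
        score=score,
        is_reverse=reverse,
        is_contaminant=contaminant,
        row_index=row_index,
    )


def brute_force_minimize(accessions, unique, total):
    """Independent oracle: lexicographic argmax over (unique, total)."""
    best = max(zip(unique, total))
    return [a for a, u, t in zip(accessions, unique, total) if (u, t) == best]


# ---------------------------------------------------------------------------
# decoy/contaminant filtering

def test_filter_counts():
    groups = [
        make_group("A", [1], [1], group_id="0"),
        make_group("B", [1], [1], group_id="1", reverse=True),
        make_group("C", [1], [1], group_id="2", contaminant=True),
        make_group("D", [1], [1], group_id="3"),
        make_group("E", [1], [1], group_id="4"),
    ]
    surviving = filter_decoys_contaminants(groups)
    assert [g.group_id for g in surviving] == ["0", "3", "4"]


def test_filter_is_identity_on_clean_input():
    groups = [make_group("A", [1], [1], group_id=str(i)) for i in range(3)]
    assert filter_decoys_contaminants(groups) == groups


def test_double_flagged_group_removed_once():
    groups = [make_group("A", [1], [1], reverse=True, contaminant=True)]
    assert filter_decoys_contaminants(groups) == []


def test_flags_honor_accession_prefixes():
    table = Table(
        "pg",
        ["id", "Protein IDs", "Peptide counts (all)", "Peptide counts (unique)",
         "Score", "Reverse", "Potential contaminant"],
        [
            {"id": "0", "Protein IDs": "REV__X", "Peptide counts (all)": "1",
             "Peptide counts (unique)": "1", "Score": "5", "Reverse": "",
             "Potential contaminant": ""},
            {"id": "1", "Protein IDs": "CON__Y", "Peptide counts (all)": "1",
             "Peptide counts (unique)": "1", "Score": "5", "Reverse": "",
             "Potential contaminant": ""},
            {"id": "2", "Protein IDs": "P1", "Peptide counts (all)": "1",
             "Peptide counts (unique)": "1", "Score": "5", "Reverse": "+",
             "Potential contaminant": ""},
        ],
    )
    records = records_from_table(table)
    assert [r.is_reverse for r in records] == [True, False, True]
    assert [r.is_contaminant for r in records] == [False, True, False]


# ---------------------------------------------------------------------------
# minimization

def test_minimize_prefers_unique_then_total():
    group = minimize_group(make_group(["A", "B", "C"], [3, 3, 1], [5, 4, 2]))
    assert group.retained_accessions == ["A"]
    assert group.lead_accession == "A"


def test_minimize_single_accession_identity():
    group = minimize_group(make_group(["A"], [2], [3]))
    assert group.retained_accessions == ["A"]


def test_minimize_tie_retains_both_first_leads():
    group = minimize_group(make_group(["A", "B"], [2, 2], [4, 4]))
    assert group.retained_accessions == ["A", "B"]
    assert group.lead_accession == "A"


def test_minimize_missing_counts_retains_all_with_warning():
    group = make_group(["A", "B"], [1], [1])
    log = RunLog()
    minimize_group(group, log)
    assert group.retained_accessions == ["A", "B"]
    assert len(log.messages("WARN")) == 1


def test_minimize_matches_brute_force_and_is_idempotent():
    """Randomized groups of <=8 accessions against an independent argmax."""
    rng = np.random.default_rng(1234)
    for _ in range(300):
        n = int(rng.integers(1, 9))
        accessions = [f"A{i}" for i in range(n)]
        unique = rng.integers(0, 5, size=n).tolist()
        total = [u + int(rng.integers(0, 5)) for u in unique]
        group = minimize_group(make_group(accessions, unique, total))
        assert group.retained_accessions == brute_force_minimize(
            accessions, unique, total
        )
        again = minimize_group(group)
        assert again.retained_accessions == group.retained_accessions
        assert set(group.retained_accessions) <= set(group.accessions)


# ---------------------------------------------------------------------------
# annotation

CATALOG = SequenceCatalog(
    {"P00924": CatalogEntry("MAVSKV", gene="ENO1", description="Enolase 1")}
)


def test_annotate_lookup():
    group = minimize_group(make_group(["P00924"], [3], [3]))
    annotate(group, CATALOG)
    assert group.gene == "ENO1"
    assert group.description == "Enolase 1"


def test_annotate_missing_lead_is_empty_with_warning():
    group = minimize_group(make_group(["UNKNOWN"], [1], [1]))
    log = RunLog()
    annotate(group, CATALOG, log)
    assert group.gene == "" and group.description == ""
    assert len(log.messages("WARN")) == 1


# ---------------------------------------------------------------------------
# best-group resolution

def test_resolve_best_group_by_score():
    by_id = {
        "0": make_group("A", [1], [1], score=12.1, group_id="0", row_index=0),
        "1": make_group("B", [1], [1], score=45.0, group_id="1", row_index=1),
    }
    assert resolve_best_group(["0", "1"], by_id) == "1"


def test_resolve_tie_breaks_by_table_order():
    by_id = {
        "0": make_group("A", [1], [1], score=7.0, group_id="0", row_index=0),
        "1": make_group("B", [1], [1], score=7.0, group_id="1", row_index=1),
    }
    assert resolve_best_group(["1", "0"], by_id) == "0"
    # brute-force check over random score vectors with a stable tie-break
    rng = np.random.default_rng(7)
    for _ in range(100):
        scores = rng.integers(0, 4, size=5).astype(float)
        groups = {
            str(i): make_group("A", [1], [1], score=s, group_id=str(i), row_index=i)
            for i, s in enumerate(scores)
        }
        expected = min(
            (i for i, s in enumerate(scores) if s == scores.max()),
        )
        assert resolve_best_group(list(groups), groups) == str(expected)


def test_resolve_with_no_surviving_candidates():
    assert resolve_best_group(["9"], {}) is None
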