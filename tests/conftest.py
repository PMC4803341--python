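"""Shared fixtures: synthetic projects generated once per session."""
from __future__ import annotations

import pytest

from mqlibra import FixtureSpec, PlantedSite, generate_project, run_project

#: Five protein N-terminal acetylation sites: three at position 1, two at
#: position 2 (initiator-Met cleaved), localization probabilities drawn from
#: {0.9, 0.4} so three sites are specific and two ambiguous under the
#: strict > 0.5 rule.
NTERM_PLAN = [
    PlantedSite(0, 1, 0.9),
    PlantedSite(1, 1, 0.4),
    PlantedSite(2, 1, 0.9),
    PlantedSite(3, 2, 0.4),
    PlantedSite(4, 2, 0.9),
]


def rich_spec(seed: int = 0) -> FixtureSpec:
    """A project exercising every pipeline feature at small scale."""
    return FixtureSpec(
        n_proteins=12,
        peptides_per_protein=3,
        spectra_per_peptide=4,
        n_channels=6,
        noise_cv=0.10,
        n_replicates=2,
        n_decoys=2,
        n_contaminants=1,
        n_isoform_groups=3,
        nterm_sites=list(NTERM_PLAN),
        plant_oxidation=True,
        seed=seed,
    )


def ratio_spec(seed: int = 0) -> FixtureSpec:
    """Spike-in design: 20 proteins at 2:1:1:1:1:1 inside a balancing
    background (equal total loading per channel), 30 spectra per protein,
    multiplicative noise CV 10%."""
    return FixtureSpec(
        n_proteins=20,
        peptides_per_protein=3,
        spectra_per_peptide=10,
        n_channels=6,
        default_profile=(2, 1, 1, 1, 1, 1),
        noise_cv=0.10,
        balanced_background_proteins=80,
        seed=seed,
    )


def run_generated(truth):
    return run_project(
        truth.project_dir,
        config=truth.config_path,
        fasta_paths=[truth.fasta_path],
        rule_paths=[truth.rule_path],
        correction_matrix=truth.matrix_path,
    )


@pytest.fixture(scope="session")
def rich_truth(tmp_path_factory):
    return generate_project(rich_spec(), tmp_path_factory.mktemp("rich"))


@pytest.fixture(scope="session")
def rich_result(rich_truth):
    return run_generated(rich_truth)


@pytest.fixture(scope="session")
def ratio_truth(tmp_path_factory):
    return generate_project(ratio_spec(), tmp_path_factory.mktemp("ratio"))


@pytest.fixture(scope="session")
def ratio_result(ratio_truth):
    return run_generated(ratio_truth)
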