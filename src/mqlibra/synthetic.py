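"""Synthetic MaxQuant-style projects with planted ground truth.

Generates a ``combined/txt`` folder (proteinGroups, peptides, msms, summary,
optional site tables) plus a FASTA file, header parse rule, reporting
configuration and correction matrix, emulating a TMT-style isobaric
experiment: each protein carries a per-channel abundance profile and every
spectrum's reporter intensities are that profile scaled by a lognormal
spectrum abundance and multiplicative lognormal noise of a chosen CV.

What is emulated: protein grouping with weaker isoform accessions, decoy and
contaminant groups, replicate assignment over raw files, protein N-terminal
modification evidence (positions 1 and 2 with localization probabilities),
an internal-PTM site table, and reporter channels with planted abundance
ratios including exact zeros.  What is not: chromatography, missing values
from MS1 sampling, interference/ratio compression, charge states, or real
search-engine score distributions — scores are uniform random.

A fixed seed yields a byte-identical directory.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import ReportingConfig, write_reporting_config

AA = "ACDEFGHIKLMNPQRSTVWY"

NTERM_PTM = "Acetyl (Protein N-term)"
OXIDATION_PTM = "Oxidation (M)"


@dataclass(frozen=True)
class PlantedSite:
    """A protein N-terminal modification site to plant.

    ``position`` is 1 (intact N-terminus) or 2 (initiator-Met cleaved);
    ``localization_prob`` None means position-determined (no probability
    column value written).
    """

    protein_index: int
    position: int
    localization_prob: float | None = None


@dataclass
class FixtureSpec:
    """Study conditions of a generated project."""

    n_proteins: int = 20
    peptides_per_protein: int = 3
    spectra_per_peptide: int = 10
    n_channels: int = 6
    #: per-channel abundance profile applied to every protein unless
    #: overridden per protein index in ``channel_profiles``.
    default_profile: tuple[float, ...] | None = None
    channel_profiles: dict[int, tuple[float, ...]] = field(default_factory=dict)
    noise_cv: float = 0.10
    n_replicates: int = 1
    n_decoys: int = 0
    n_contaminants: int = 0
    n_isoform_groups: int = 0
    nterm_sites: list[PlantedSite] = field(default_factory=list)
    plant_oxidation: bool = False
    with_reporters: bool = True
    #: extra background proteins whose common profile is chosen so that the
    #: overall per-channel loading of the whole project is equal — the
    #: equal-total-loading design of real isobaric experiments, and the
    #: validity condition of channel calibration.  0 disables.
    balanced_background_proteins: int = 0
    dialect: str = "1.5"
    seed: int = 0

    def profile(self, protein_index: int) -> np.ndarray:
        base = self.channel_profiles.get(
            protein_index,
            self.default_profile or tuple([1.0] * self.n_channels),
        )
        profile = np.asarray(base, dtype=float)
        if profile.size != self.n_channels:
            raise ValueError(
                f"profile for protein {protein_index} has {profile.size} "
                f"channels, expected {self.n_channels}"
            )
        return profile / profile.sum()


@dataclass
class GroundTruth:
    """What was planted, for assertions against pipeline output."""

    spec: FixtureSpec
    project_dir: Path
    accessions: list[str]
    background_accessions: list[str]
    profiles: dict[str, np.ndarray]
    planted_nterm_sites: list[tuple[str, int, float | None]]
    planted_oxidation_sites: list[tuple[str, int, float]]
    n_reported_groups: int
    n_reported_peptides: int
    n_reported_spectra: int
    peptide_counts: dict[str, int]
    raw_files: list[str]
    replicate_labels: list[str]
    config_path: Path
    fasta_path: Path
    rule_path: Path
    matrix_path: Path
    sequences: dict[str, str]


def _make_sequence(rng: np.random.Generator, length: int) -> str:
    body = "".join(AA[i] for i in rng.integers(0, len(AA), size=length - 1))
    return "M" + body


def _fmt(x: float) -> str:
    return f"{x:.4f}".rstrip("0").rstrip(".") if x else "0"


def _write_tsv(path: Path, header: list[str], rows: list[list[str]]) -> None:
    lines = ["\t".join(header)]
    lines += ["\t".join(row) for row in rows]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def generate_project(spec: FixtureSpec, out_dir: str | Path) -> GroundTruth:
    """Write a complete synthetic project under *out_dir*; return ground truth."""
    rng = np.random.default_rng(spec.seed)
    out_dir = Path(out_dir)
    txt = out_dir / "combined" / "txt"
    txt.mkdir(parents=True, exist_ok=True)
    con_title = "Potential contaminant" if spec.dialect == "1.5" else "Contaminant"
    sigma = math.sqrt(math.log(1.0 + spec.noise_cv**2))

    nterm_by_protein: dict[int, list[PlantedSite]] = {}
    for site in spec.nterm_sites:
        nterm_by_protein.setdefault(site.protein_index, []).append(site)

    seq_len = max(60, 14 + 12 * spec.peptides_per_protein)
    accessions = [f"P{i + 1:04d}" for i in range(spec.n_proteins)]
    background_accessions = [
        f"B{i + 1:04d}" for i in range(spec.balanced_background_proteins)
    ]

    def _n_extra(i: int) -> int:
        return len(nterm_by_protein.get(i, [])) + (
            1 if spec.plant_oxidation and i < 3 else 0
        )

    plan: list[tuple[str, np.ndarray]] = [
        (acc, spec.profile(i)) for i, acc in enumerate(accessions)
    ]
    if spec.balanced_background_proteins:
        spike_spectra = np.array(
            [
                (spec.peptides_per_protein + _n_extra(i)) * spec.spectra_per_peptide
                for i in range(spec.n_proteins)
            ],
            dtype=float,
        )
        loading = sum(n * p for n, p in zip(spike_spectra, (p for _, p in plan)))
        n_bg_spectra = (
            spec.balanced_background_proteins
            * spec.peptides_per_protein
            * spec.spectra_per_peptide
        )
        target = (spike_spectra.sum() + n_bg_spectra) / spec.n_channels
        bg_profile = (target - loading) / n_bg_spectra
        if np.any(bg_profile < 0):
            raise ValueError(
                "balanced background too small to equalize channel loading; "
                "increase balanced_background_proteins"
            )
        bg_profile = bg_profile / bg_profile.sum()
        plan += [(acc, bg_profile) for acc in background_accessions]

    sequences: dict[str, str] = {}
    for i, (acc, _) in enumerate(plan):
        seq = _make_sequence(rng, seq_len)
        if spec.plant_oxidation and i < 3:
            seq = seq[:30] + "M" + seq[31:]
        sequences[acc] = seq
    isoform_of: dict[str, str] = {}
    for i in range(min(spec.n_isoform_groups, spec.n_proteins)):
        acc = accessions[i]
        iso = f"{acc}-2"
        sequences[iso] = sequences[acc][:-5]
        isoform_of[acc] = iso

    # ---- peptides and spectra -------------------------------------------
    peptide_rows: list[dict] = []     # one per peptide
    msms_rows: list[dict] = []        # one per spectrum
    profiles: dict[str, np.ndarray] = {}
    peptide_counts: dict[str, int] = {}
    raw_files = [f"raw{r + 1}" for r in range(spec.n_replicates)]
    replicate_labels = [f"R{r + 1}" for r in range(spec.n_replicates)]

    planted_nterm: list[tuple[str, int, float | None]] = []
    planted_ox: list[tuple[str, int, float]] = []

    def _add_spectra(pep_id: int, peptide: str, group_id: int, profile: np.ndarray,
                     modifications: str, prob_value: str) -> list[int]:
        scan_ids = []
        for k in range(spec.spectra_per_peptide):
            scan_id = len(msms_rows)
            scan_ids.append(scan_id)
            base = rng.lognormal(math.log(1e6), 0.3)
            noise = rng.lognormal(0.0, sigma, size=spec.n_channels)
            intensities = np.where(profile > 0, base * profile * noise, 0.0)
            msms_rows.append(
                {
                    "id": scan_id,
                    "raw_file": raw_files[k % spec.n_replicates],
                    "sequence": peptide,
                    "modifications": modifications,
                    "peptide_id": pep_id,
                    "group_ids": str(group_id),
                    "score": rng.uniform(40.0, 150.0),
                    "intensities": intensities,
                    "prob": prob_value,
                }
            )
        return scan_ids

    for i, (acc, profile) in enumerate(plan):
        seq = sequences[acc]
        profiles[acc] = profile
        peptides = [
            seq[2 + j * 12: 12 + j * 12] for j in range(spec.peptides_per_protein)
        ]
        extra: list[tuple[str, str, str]] = []  # (peptide, modifications, prob string)
        for site in nterm_by_protein.get(i, []):
            if site.position not in (1, 2):
                raise ValueError("N-terminal sites must be at position 1 or 2")
            pep = seq[site.position - 1: site.position - 1 + 10]
            prob_value = (
                f"{pep[0]}({site.localization_prob})" + pep[1:]
                if site.localization_prob is not None
                else ""
            )
            extra.append((pep, NTERM_PTM, prob_value))
            planted_nterm.append((acc, site.position, site.localization_prob))
        if spec.plant_oxidation and i < 3:
            ox_prob = [0.95, 0.8, 0.3][i]
            extra.append((seq[26:36], OXIDATION_PTM, ""))
            planted_ox.append((acc, 31, ox_prob))
        for peptide in peptides:
            pep_id = len(peptide_rows)
            scans = _add_spectra(pep_id, peptide, i, profile, "Unmodified", "")
            peptide_rows.append(
                {
                    "id": pep_id,
                    "sequence": peptide,
                    "proteins": acc,
                    "group_ids": str(i),
                    "unique": "yes",
                    "score": rng.uniform(40.0, 150.0),
                    "scans": scans,
                }
            )
        for peptide, modification, prob_value in extra:
            pep_id = len(peptide_rows)
            scans = _add_spectra(pep_id, peptide, i, profile, modification, prob_value)
            peptide_rows.append(
                {
                    "id": pep_id,
                    "sequence": peptide,
                    "proteins": acc,
                    "group_ids": str(i),
                    "unique": "yes",
                    "score": rng.uniform(40.0, 150.0),
                    "scans": scans,
                }
            )
        peptide_counts[acc] = spec.peptides_per_protein + len(extra)

    n_reported_peptides = len(peptide_rows)
    n_reported_spectra = len(msms_rows)

    # ---- protein group table --------------------------------------------
    group_rows: list[list[str]] = []
    for i, (acc, _) in enumerate(plan):
        n_pep = peptide_counts[acc]
        accs, uniq, total = [acc], [n_pep], [n_pep]
        if acc in isoform_of:
            accs.append(isoform_of[acc])
            uniq.append(max(1, n_pep - 1))
            total.append(max(1, n_pep - 1))
        group_rows.append(
            [
                str(i),
                ";".join(accs),
                ";".join(map(str, total)),
                ";".join(map(str, uniq)),
                f"{rng.uniform(50.0, 250.0):.2f}",
                "",
                "",
            ]
        )
    # decoy / contaminant groups, each with one peptide and one spectrum
    flagged: list[tuple[str, str, str]] = []
    for k in range(spec.n_decoys):
        flagged.append((f"REV__D{k + 1:03d}", "+", ""))
    for k in range(spec.n_contaminants):
        flagged.append((f"CON__C{k + 1:03d}", "", "+"))
    decoy_site_rows: list[tuple[str, int]] = []  # (group_id, scan_id)
    for acc, rev, con in flagged:
        group_id = len(group_rows)
        peptide = "".join(AA[i] for i in rng.integers(0, len(AA), size=12))
        pep_id = len(peptide_rows)
        scan_id = len(msms_rows)
        base = rng.lognormal(math.log(1e6), 0.3)
        noise = rng.lognormal(0.0, sigma, size=spec.n_channels)
        msms_rows.append(
            {
                "id": scan_id,
                "raw_file": raw_files[0],
                "sequence": peptide,
                "modifications": "Unmodified",
                "peptide_id": pep_id,
                "group_ids": str(group_id),
                "score": rng.uniform(40.0, 150.0),
                "intensities": base * np.ones(spec.n_channels) / spec.n_channels * noise,
                "prob": "",
            }
        )
        peptide_rows.append(
            {
                "id": pep_id,
                "sequence": peptide,
                "proteins": acc,
                "group_ids": str(group_id),
                "unique": "yes",
                "score": rng.uniform(40.0, 150.0),
                "scans": [scan_id],
            }
        )
        group_rows.append(
            [str(group_id), acc, "1", "1", f"{rng.uniform(1.0, 40.0):.2f}", rev, con]
        )
        if rev == "+":
            decoy_site_rows.append((str(group_id), scan_id))

    _write_tsv(
        txt / "proteinGroups.txt",
        ["id", "Protein IDs", "Peptide counts (all)", "Peptide counts (unique)",
         "Score", "Reverse", con_title],
        group_rows,
    )

    # ---- peptides table --------------------------------------------------
    _write_tsv(
        txt / "peptides.txt",
        ["id", "Sequence", "Proteins", "Protein group IDs", "Unique (Groups)",
         "Score", "MS/MS IDs"],
        [
            [
                str(p["id"]), p["sequence"], p["proteins"], p["group_ids"],
                p["unique"], f"{p['score']:.2f}",
                ";".join(map(str, p["scans"])),
            ]
            for p in peptide_rows
        ],
    )

    # ---- msms table ------------------------------------------------------
    msms_header = [
        "id", "Raw file", "Scan number", "Sequence", "Modifications",
        "Modified sequence", "Proteins", "Peptide ID", "Protein group IDs",
        "Score",
    ]
    if spec.with_reporters:
        msms_header += [f"Reporter intensity {c}" for c in range(spec.n_channels)]
    msms_header.append(f"{NTERM_PTM} Probabilities")
    rendered_msms: list[list[str]] = []
    for m in msms_rows:
        row = [
            str(m["id"]), m["raw_file"], str(1000 + m["id"]), m["sequence"],
            m["modifications"], f"_{m['sequence']}_", "", str(m["peptide_id"]),
            m["group_ids"], f"{m['score']:.2f}",
        ]
        if spec.with_reporters:
            row += [_fmt(v) for v in m["intensities"]]
        row.append(m["prob"])
        rendered_msms.append(row)
    _write_tsv(txt / "msms.txt", msms_header, rendered_msms)

    # ---- summary table ---------------------------------------------------
    _write_tsv(
        txt / "summary.txt",
        ["Raw file", "Experiment"],
        [[raw, label] for raw, label in zip(raw_files, replicate_labels)],
    )

    # ---- MaxQuant-style site table for the internal PTM ------------------
    if spec.plant_oxidation:
        site_rows = []
        for sid, (acc, position, prob) in enumerate(planted_ox):
            i = accessions.index(acc)
            ox_pep_scans = next(
                p["scans"] for p in peptide_rows
                if p["proteins"] == acc and p["sequence"] == sequences[acc][26:36]
            )
            site_rows.append(
                [str(sid), acc, str(position), "M", f"{prob}",
                 f"{rng.uniform(40.0, 150.0):.2f}",
                 ";".join(map(str, ox_pep_scans)), str(i), "", ""]
            )
        for gid, scan_id in decoy_site_rows[:1]:
            site_rows.append(
                [str(len(site_rows)), "REV__D001", "5", "M", "0.99", "10.0",
                 str(scan_id), gid, "+", ""]
            )
        _write_tsv(
            txt / f"{OXIDATION_PTM}Sites.txt",
            ["id", "Protein", "Position", "Amino acid", "Localization prob",
             "Score", "MS/MS IDs", "Protein group IDs", "Reverse", con_title],
            site_rows,
        )

    # ---- FASTA + parse rule ---------------------------------------------
    fasta_path = out_dir / "sequences.fasta"
    fasta_lines = []
    for j, (acc, seq) in enumerate(sequences.items()):
        fasta_lines.append(
            f">sp|{acc}|{acc}_SYN Synthetic protein {j + 1} GN=G{j + 1}"
        )
        fasta_lines.append(seq)
    fasta_path.write_text("\n".join(fasta_lines) + "\n", encoding="utf-8")
    rule_path = out_dir / "sequences.rule.txt"
    rule_path.write_text("preset = uniprot\n", encoding="utf-8")

    # ---- reporting config + correction matrix ----------------------------
    ptms = [NTERM_PTM] + ([OXIDATION_PTM] if spec.plant_oxidation else [])
    cfg = ReportingConfig(ptm_names=ptms)
    config_path = out_dir / "report.config.txt"
    write_reporting_config(cfg, config_path)
    matrix_path = out_dir / "correction_matrix.txt"
    labels = [f"channel {c}" for c in range(spec.n_channels)]
    lines = ["# columns: true channel, rows: observed channel",
             "\t" + "\t".join(labels)]
    eye = np.eye(spec.n_channels)
    for label, row in zip(labels, eye):
        lines.append(label + "\t" + "\t".join(_fmt(v) for v in row))
    matrix_path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    return GroundTruth(
        spec=spec,
        project_dir=out_dir,
        accessions=accessions,
        background_accessions=background_accessions,
        profiles=profiles,
        planted_nterm_sites=planted_nterm,
        planted_oxidation_sites=planted_ox,
        n_reported_groups=len(plan),
        n_reported_peptides=n_reported_peptides,
        n_reported_spectra=n_reported_spectra,
        peptide_counts=peptide_counts,
        raw_files=raw_files,
        replicate_labels=replicate_labels,
        config_path=config_path,
        fasta_path=fasta_path,
        rule_path=rule_path,
        matrix_path=matrix_path,
        sequences=sequences,
    )
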