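"""Reporting configuration and auxiliary input files.

Owns every tunable default of the reporting pipeline: which columns are kept
from each MaxQuant table (exact / keyword title rules), which PTMs get site
tables, the sequence-window flank length, the site localization-probability
threshold, the outlier rejection multiplier, and the low-intensity cutoff.
Also loads FASTA header parse rules, isotope-impurity correction matrices and
the experimental (replicate) design.

Configuration file syntax
-------------------------
Plain UTF-8 text, line oriented.  ``#`` starts a comment, blank lines are
ignored.  ``[general]`` holds scalar settings as ``key = value`` plus repeated
``ptm = <name>`` lines; a section named after a logical table
(``protein_groups``, ``peptides``, ``sites``, ``msms``, ``summary``) holds
column-selection rules, one per line::

    [protein_groups]
    exact = Protein IDs
    keyword = Peptide counts

Exact rules select a column title iff it equals the pattern; keyword rules
select every title containing the pattern as a case-sensitive substring.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .logutil import RunLog

LOGICAL_TABLES = ("protein_groups", "peptides", "sites", "msms", "summary")

#: Replicate label assigned to raw files without an experiment label.
DEFAULT_REPLICATE = "all"


class ConfigError(ValueError):
    """Invalid configuration, parse rule, correction matrix or design input."""


@dataclass(frozen=True)
class TitleRule:
    """One column-selection rule: ``exact`` equality or ``keyword`` substring."""

    pattern: str
    mode: str = "exact"

    def __post_init__(self):
        if not self.pattern:
            raise ConfigError("title rule pattern must be non-empty")
        if self.mode not in ("exact", "keyword"):
            raise ConfigError(f"unknown title rule mode: {self.mode!r}")


# Default column rules for the MaxQuant 1.5-style dialect.  The keyword rule
# "ontaminant" deliberately matches both "Contaminant" (older versions) and
# "Potential contaminant" under case-sensitive substring matching.
DEFAULT_TABLE_SPECS: dict[str, tuple[TitleRule, ...]] = {
    "protein_groups": (
        TitleRule("id"),
        TitleRule("Protein IDs"),
        TitleRule("Peptide counts (all)"),
        TitleRule("Peptide counts (unique)"),
        TitleRule("Score"),
        TitleRule("Reverse"),
        TitleRule("ontaminant", "keyword"),
    ),
    "peptides": (
        TitleRule("id"),
        TitleRule("Sequence"),
        TitleRule("Proteins"),
        TitleRule("Protein group IDs"),
        TitleRule("Unique (Groups)"),
        TitleRule("Score"),
        TitleRule("MS/MS IDs"),
    ),
    "sites": (
        TitleRule("id"),
        TitleRule("Protein"),
        TitleRule("Position"),
        TitleRule("Amino acid"),
        TitleRule("Localization prob"),
        TitleRule("Score"),
        TitleRule("MS/MS IDs"),
        TitleRule("Protein group IDs"),
        TitleRule("Reverse"),
        TitleRule("ontaminant", "keyword"),
    ),
    "msms": (
        TitleRule("id"),
        TitleRule("Raw file"),
        TitleRule("Scan number"),
        TitleRule("Sequence"),
        TitleRule("Modifications"),
        TitleRule("Modified sequence"),
        TitleRule("Proteins"),
        TitleRule("Peptide ID"),
        TitleRule("Protein group IDs"),
        TitleRule("Score"),
        TitleRule("Reporter intensity", "keyword"),
        TitleRule("Probabilities", "keyword"),
    ),
    "summary": (
        TitleRule("Raw file"),
        TitleRule("Experiment"),
    ),
}


def _default_table_specs() -> dict[str, list[TitleRule]]:
    return {name: list(rules) for name, rules in DEFAULT_TABLE_SPECS.items()}


@dataclass
class ReportingConfig:
    """All tunable settings of a reporting run.

    Defaults follow standard practice for isobaric reporter quantification:
    sequence windows of six residues to both sides of a site, sites called
    specific when the localization probability exceeds 0.5, reporter outliers
    rejected beyond 1.96 sigma, and spectra kept whenever their summed
    reporter intensity is positive.
    """

    table_specs: dict[str, list[TitleRule]] = field(default_factory=_default_table_specs)
    ptm_names: list[str] = field(default_factory=list)
    flank_length: int = 6
    loc_prob_threshold: float = 0.5
    outlier_sigma: float = 1.96
    low_intensity_threshold: float = 0.0
    use_unique_peptides_only: bool = True
    ile_eq_leu: bool = False

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.flank_length < 0:
            raise ConfigError("flank_length must be >= 0")
        if not 0.0 <= self.loc_prob_threshold <= 1.0:
            raise ConfigError("loc_prob_threshold must be in [0, 1]")
        if self.outlier_sigma <= 0:
            raise ConfigError("outlier_sigma must be > 0")
        if self.low_intensity_threshold < 0:
            raise ConfigError("low_intensity_threshold must be >= 0")
        for name, rules in self.table_specs.items():
            if name not in LOGICAL_TABLES:
                raise ConfigError(f"unknown logical table {name!r}")
            if not rules:
                raise ConfigError(f"table {name!r} has no title rules")

    @property
    def nterm_ptm_names(self) -> list[str]:
        return [p for p in self.ptm_names if is_nterm_ptm(p)]


def is_nterm_ptm(name: str) -> bool:
    """Whether a PTM name denotes a protein N-terminal modification."""
    return "protein n-term" in name.lower()


def match_columns(
    header: list[str], rules: list[TitleRule], log: RunLog | None = None
) -> list[str]:
    """Select column titles from *header* by the given rules.

    Output preserves rule order, then header order within each rule;
    duplicates are removed.  An exact rule matching no title is a warning
    (the column may simply be absent in this MaxQuant version), never fatal.
    """
    selected: list[str] = []
    for rule in rules:
        if rule.mode == "exact":
            hits = [t for t in header if t == rule.pattern]
            if not hits and log is not None:
                log.warn(f"exact title {rule.pattern!r} not found in header")
        else:
            hits = [t for t in header if rule.pattern in t]
        for title in hits:
            if title not in selected:
                selected.append(title)
    return selected


# ---------------------------------------------------------------------------
# Reporting config file I/O

_GENERAL_FIELDS = {
    "flank_length": int,
    "loc_prob_threshold": float,
    "outlier_sigma": float,
    "low_intensity_threshold": float,
    "use_unique_peptides_only": bool,
    "ile_eq_leu": bool,
}

_TRUE = {"true", "yes", "1", "on"}
_FALSE = {"false", "no", "0", "off"}


def _parse_bool(text: str, lineno: int) -> bool:
    low = text.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise ConfigError(f"line {lineno}: not a boolean: {text!r}")


def load_reporting_config(path: str | Path, log: RunLog | None = None) -> ReportingConfig:
    """Load and validate a reporting configuration file.

    Fields the file omits keep their defaults.  Logical-table sections that
    appear replace the default rule set for that table.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"reporting configuration file not found: {path}")
    kwargs: dict = {}
    ptm_names: list[str] = []
    table_specs = _default_table_specs()
    seen_tables: set[str] = set()
    section = "general"
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1].strip()
            if section != "general" and section not in LOGICAL_TABLES:
                raise ConfigError(f"line {lineno}: unknown section [{section}]")
            if section in LOGICAL_TABLES and section not in seen_tables:
                table_specs[section] = []
                seen_tables.add(section)
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if section == "general":
            if key == "ptm":
                if value:
                    ptm_names.append(value)
                continue
            if key not in _GENERAL_FIELDS:
                if log is not None:
                    log.warn(f"line {lineno}: unknown setting {key!r} ignored")
                continue
            typ = _GENERAL_FIELDS[key]
            try:
                kwargs[key] = _parse_bool(value, lineno) if typ is bool else typ(value)
            except ValueError as exc:
                raise ConfigError(f"line {lineno}: bad value for {key}: {value!r}") from exc
        else:
            if key not in ("exact", "keyword"):
                raise ConfigError(
                    f"line {lineno}: rule mode must be 'exact' or 'keyword', got {key!r}"
                )
            if not value:
                raise ConfigError(f"line {lineno}: empty rule pattern")
            table_specs[section].append(TitleRule(value, key))
    return ReportingConfig(table_specs=table_specs, ptm_names=ptm_names, **kwargs)


def write_reporting_config(cfg: ReportingConfig, path: str | Path) -> None:
    """Write *cfg* in the documented config syntax; inverse of the loader."""
    lines = ["# mqlibra reporting configuration", "[general]"]
    for key, typ in _GENERAL_FIELDS.items():
        value = getattr(cfg, key)
        lines.append(f"{key} = {str(value).lower() if typ is bool else value}")
    for ptm in cfg.ptm_names:
        lines.append(f"ptm = {ptm}")
    for table, rules in cfg.table_specs.items():
        lines.append("")
        lines.append(f"[{table}]")
        for rule in rules:
            lines.append(f"{rule.mode} = {rule.pattern}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# FASTA header parse rules

@dataclass(frozen=True)
class HeaderParseRule:
    """Regex extractors applied to a FASTA header line (without '>').

    Each pattern must contain one capturing group; ``gene`` and
    ``description`` may be ``None`` when the dialect carries no such field.
    """

    accession: str
    gene: str | None = None
    description: str | None = None
    name: str = "custom"

    def parse(self, header: str) -> tuple[str | None, str, str]:
        """Return ``(accession, gene, description)``; accession ``None`` on failure."""

        def _extract(pattern: str | None) -> str:
            if not pattern:
                return ""
            m = re.search(pattern, header)
            return m.group(1).strip() if m else ""

        acc = _extract(self.accession)
        return (acc or None, _extract(self.gene), _extract(self.description))


#: Shipped presets for common FASTA header dialects.
PRESET_PARSE_RULES: dict[str, HeaderParseRule] = {
    "uniprot": HeaderParseRule(
        accession=r"^[a-z]{2}\|([^|\s]+)\|",
        gene=r"\bGN=(\S+)",
        description=r"^\S+\s+(.+?)(?=\s+[A-Z]{2}=|$)",
        name="uniprot",
    ),
    "ensembl": HeaderParseRule(
        accession=r"^(\S+)",
        gene=r"gene_symbol:(\S+)",
        description=r"description:(.+)$",
        name="ensembl",
    ),
    "ncbi": HeaderParseRule(
        accession=r"^(\S+)",
        gene=None,
        description=r"^\S+\s+(.+)$",
        name="ncbi",
    ),
}


def load_parse_rule(path: str | Path) -> HeaderParseRule:
    """Load a header parse-rule file.

    The file either names a preset (``preset = uniprot``) or gives regex
    extractors directly (``accession = ...``, optional ``gene = ...`` and
    ``description = ...``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"parse rule file not found: {path}")
    fields: dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        fields[key.strip()] = value.strip()
    if "preset" in fields:
        preset = fields["preset"].lower()
        if preset not in PRESET_PARSE_RULES:
            raise ConfigError(f"unknown parse-rule preset {preset!r}")
        return PRESET_PARSE_RULES[preset]
    if "accession" not in fields:
        raise ConfigError(f"{path}: parse rule needs 'accession' or 'preset'")
    return HeaderParseRule(
        accession=fields["accession"],
        gene=fields.get("gene"),
        description=fields.get("description"),
        name=path.stem,
    )


# ---------------------------------------------------------------------------
# Isotope-impurity correction matrix

@dataclass
class CorrectionMatrix:
    """Isotope-impurity bleed between reporter channels.

    Orientation: columns index the true (labelled) channel, rows the observed
    channel; entry ``(i, j)`` is the fraction of channel *j*'s signal that
    appears at channel *i*'s reporter mass.
    """

    channel_labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.channel_labels)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ConfigError("correction matrix must be square")
        if self.values.shape[0] != n:
            raise ConfigError(
                f"correction matrix dimension {self.values.shape[0]} does not match "
                f"{n} channel labels"
            )
        if np.any(self.values < 0):
            raise ConfigError("correction matrix entries must be non-negative")
        if np.any(np.diag(self.values) <= 0):
            raise ConfigError("correction matrix diagonal entries must be positive")

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    @classmethod
    def identity(cls, channel_labels: list[str]) -> "CorrectionMatrix":
        return cls(list(channel_labels), np.eye(len(channel_labels)))


def load_correction_matrix(path: str | Path, log: RunLog | None = None) -> CorrectionMatrix:
    """Load a tab-separated correction matrix (label row + label column).

    Columns whose entries sum above 1 (vendor sheets quoting percentages) are
    rescaled to unit sum with a warning, so both fractional and percent
    conventions load to the same matrix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"correction matrix file not found: {path}")
    rows: list[list[str]] = []
    for raw in path.read_text(encoding="utf-8").splitlines():
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        rows.append(raw.rstrip("\n").split("\t"))
    if not rows:
        raise ConfigError(f"{path}: empty correction matrix file")
    header = rows[0]
    labels = [c.strip() for c in header if c.strip()]
    n = len(labels)
    body = rows[1:]
    if len(body) != n:
        raise ConfigError(
            f"{path}: correction matrix has {n} channel labels but {len(body)} rows"
        )
    values = np.zeros((n, n))
    for i, fields in enumerate(body):
        cells = [c for c in fields if c.strip() != ""]
        if len(cells) == n + 1:  # leading row label
            cells = cells[1:]
        if len(cells) != n:
            raise ConfigError(
                f"{path}: row {i + 1} has {len(cells)} numeric fields, expected {n}"
            )
        try:
            values[i] = [float(c) for c in cells]
        except ValueError as exc:
            raise ConfigError(f"{path}: non-numeric entry in row {i + 1}") from exc
    colsums = values.sum(axis=0)
    over = colsums > 1.0 + 1e-9
    if np.any(over):
        if log is not None:
            bad = [labels[j] for j in np.where(over)[0]]
            log.warn(
                "correction matrix columns sum above 1 and were rescaled to unit "
                f"sum: {', '.join(bad)}"
            )
        values[:, over] = values[:, over] / colsums[over]
    return CorrectionMatrix(labels, values)


# ---------------------------------------------------------------------------
# Experimental design (replicate assignment)

@dataclass
class ExperimentalDesign:
    """Raw file -> replicate label mapping with a stable replicate order."""

    assignment: dict[str, str]
    replicates: list[str]

    def replicate_of(self, raw_file: str, log: RunLog | None = None) -> str:
        try:
            return self.assignment[raw_file]
        except KeyError:
            if log is not None:
                log.warn(
                    f"raw file {raw_file!r} absent from the experimental design; "
                    f"assigned to replicate {DEFAULT_REPLICATE!r}"
                )
            self.assignment[raw_file] = DEFAULT_REPLICATE
            if DEFAULT_REPLICATE not in self.replicates:
                self.replicates.append(DEFAULT_REPLICATE)
            return DEFAULT_REPLICATE


def load_experimental_design(
    summary_table=None,
    template_path: str | Path | None = None,
    log: RunLog | None = None,
) -> ExperimentalDesign:
    """Build the replicate design from ``summary.txt`` and/or a template file.

    The template (two tab-separated columns, header row required) overrides
    the summary assignment file-by-file.  Raw files with an empty experiment
    label fall into a single default replicate.
    """
    assignment: dict[str, str] = {}
    if summary_table is not None:
        for row in summary_table.rows:
            raw_file = row.get("Raw file", "").strip()
            if not raw_file or raw_file.lower() == "total":
                continue
            label = row.get("Experiment", "").strip()
            assignment[raw_file] = label or DEFAULT_REPLICATE
    if template_path is not None:
        template_path = Path(template_path)
        if not template_path.exists():
            raise FileNotFoundError(f"design template not found: {template_path}")
        lines = template_path.read_text(encoding="utf-8").splitlines()
        for line in lines[1:]:  # header row required and skipped
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ConfigError(f"design template line has < 2 columns: {line!r}")
            raw_file, label = fields[0].strip(), fields[1].strip()
            assignment[raw_file] = label or DEFAULT_REPLICATE
    replicates: list[str] = []
    for label in assignment.values():
        if label not in replicates:
            replicates.append(label)
    if not replicates:
        replicates = [DEFAULT_REPLICATE]
    return ExperimentalDesign(assignment, replicates)
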