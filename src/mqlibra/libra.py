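"""Libra-style isobaric reporter quantification.

Relative expression is reported directly per channel rather than as ratios
against a reference channel, so a channel with zero expression (gene
knockout vs. wild type) stays representable instead of producing an
undefined ratio.  Pipeline order, applied per spectrum and then per entity
group, is frozen as:

1. isotope-impurity correction (solve ``observed = M @ true``; negatives
   clamp to 0),
2. channel calibration (equalize overall per-channel totals to their mean),
3. low-intensity filtering (spectra whose summed intensity does not exceed
   the threshold are excluded),
4. per-spectrum sum-normalization to reporter fractions,
5. grouping of spectra per protein / peptide / site and replicate,
6. per-channel outlier rejection beyond ``k`` population sigma (default
   1.96; groups of fewer than 3 spectra are left untouched),
7. median, mean and population SD of the retained fractions.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CorrectionMatrix, ExperimentalDesign, ReportingConfig
from .logutil import RunLog
from .mq_io import Table, to_float


class QuantError(ValueError):
    """Fatal quantification configuration problem (singular matrix, dead channel)."""


@dataclass
class ChannelCalibration:
    """Per-channel multiplicative factors equalizing overall reporter totals."""

    channel_labels: list[str]
    factors: np.ndarray

    def __post_init__(self):
        self.factors = np.asarray(self.factors, dtype=float)
        if np.any(self.factors <= 0):
            raise QuantError("calibration factors must be positive")


def apply_correction(
    observed: np.ndarray, matrix: CorrectionMatrix
) -> tuple[np.ndarray, int]:
    """Undo isotope-impurity bleed by solving ``observed = M @ true``.

    Accepts a single channel vector or an ``(n_spectra, n_channels)`` matrix.
    Negative solutions (noise near zero) are clamped to 0; the clamp count is
    returned for logging.  An identity matrix is a no-op.
    """
    observed = np.asarray(observed, dtype=float)
    single = observed.ndim == 1
    obs2 = observed[None, :] if single else observed
    if obs2.shape[1] != matrix.n_channels:
        raise QuantError(
            f"spectrum has {obs2.shape[1]} channels but correction matrix "
            f"has {matrix.n_channels}"
        )
    try:
        corrected = np.linalg.solve(matrix.values, obs2.T).T
    except np.linalg.LinAlgError as exc:
        raise QuantError("correction matrix is singular") from exc
    n_clamped = int(np.count_nonzero(corrected < 0))
    corrected = np.clip(corrected, 0.0, None)
    return (corrected[0] if single else corrected), n_clamped


def compute_calibration_factors(
    intensities: np.ndarray, channel_labels: list[str]
) -> ChannelCalibration:
    """Factors that equalize per-channel totals to their across-channel mean.

    ``factor_c = mean(totals) / total_c``; a channel whose total is zero has
    no defined factor and aborts with a message naming the channel.
    """
    intensities = np.atleast_2d(np.asarray(intensities, dtype=float))
    totals = intensities.sum(axis=0)
    if np.any(totals <= 0):
        dead = [channel_labels[i] for i in np.where(totals <= 0)[0]]
        raise QuantError(
            f"channel(s) {', '.join(dead)} have zero total intensity; "
            "calibration factors are undefined"
        )
    return ChannelCalibration(list(channel_labels), totals.mean() / totals)


def normalize_spectra(
    intensities: np.ndarray, low_intensity_threshold: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-spectrum sum-normalization to reporter fractions.

    Returns ``(fractions, included)``; spectra whose summed intensity is at
    or below the threshold are excluded (fractions row left as NaN) rather
    than erroring.
    """
    intensities = np.atleast_2d(np.asarray(intensities, dtype=float))
    totals = intensities.sum(axis=1)
    included = totals > low_intensity_threshold
    fractions = np.full_like(intensities, np.nan, dtype=float)
    fractions[included] = intensities[included] / totals[included, None]
    return fractions, included


def outlier_retained_mask(values: np.ndarray, outlier_sigma: float) -> np.ndarray:
    """Boolean mask of values within ``outlier_sigma`` population SDs of the mean.

    Groups of fewer than 3 values, or with zero spread, are kept whole.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        return np.ones(values.size, dtype=bool)
    mu = values.mean()
    sigma = values.std()  # population SD
    if sigma == 0:
        return np.ones(values.size, dtype=bool)
    return np.abs(values - mu) <= outlier_sigma * sigma


@dataclass
class ChannelSummary:
    """Per-channel median/mean/SD of retained reporter fractions of one entity."""

    median: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_used: np.ndarray
    n_removed: np.ndarray
    n_spectra: int
    fallback_channels: list[int] = field(default_factory=list)


def summarize_group(fractions: np.ndarray, outlier_sigma: float) -> ChannelSummary:
    """Outlier-reject then summarize a group of spectra, channel by channel.

    Each channel is treated independently.  A channel left empty by the
    rejection falls back to its pre-rejection values and is flagged.
    """
    fractions = np.atleast_2d(np.asarray(fractions, dtype=float))
    n_spectra, n_channels = fractions.shape
    median = np.zeros(n_channels)
    mean = np.zeros(n_channels)
    sd = np.zeros(n_channels)
    n_used = np.zeros(n_channels, dtype=int)
    n_removed = np.zeros(n_channels, dtype=int)
    fallback: list[int] = []
    for c in range(n_channels):
        values = fractions[:, c]
        retained = values[outlier_retained_mask(values, outlier_sigma)]
        if retained.size == 0:
            retained = values
            fallback.append(c)
        median[c] = np.median(retained)
        mean[c] = retained.mean()
        sd[c] = retained.std()
        n_used[c] = retained.size
        n_removed[c] = n_spectra - retained.size
    return ChannelSummary(median, mean, sd, n_used, n_removed, n_spectra, fallback)


# ---------------------------------------------------------------------------
# Spectrum preparation from msms.txt

_REPORTER_COL = re.compile(r"^Reporter intensity (\d+)\s*(.*)$")


def reporter_columns(column_titles: list[str]) -> list[str]:
    """The raw reporter-intensity columns of an msms table, in channel order.

    Matches ``Reporter intensity <n>`` (with optional experiment suffix) but
    not the derived ``count``/``corrected`` variants.
    """
    hits: list[tuple[int, str]] = []
    for title in column_titles:
        m = _REPORTER_COL.match(title)
        if m and not m.group(2).strip().startswith(("count", "corrected")):
            hits.append((int(m.group(1)), title))
    hits.sort()
    return [title for _, title in hits]


@dataclass
class SpectrumSet:
    """Quantification-ready view of the msms table.

    Holds the per-spectrum reporter fractions after correction, calibration
    and low-intensity filtering; ``included`` marks spectra that survived the
    filter.  Row order matches the msms table rows used to build it.
    """

    scan_ids: list[str]
    raw_files: list[str]
    channel_labels: list[str]
    raw: np.ndarray
    corrected: np.ndarray
    calibrated: np.ndarray
    fractions: np.ndarray
    included: np.ndarray
    calibration: ChannelCalibration
    n_clamped: int = 0

    @property
    def n_spectra(self) -> int:
        return len(self.scan_ids)

    def index_of(self) -> dict[str, int]:
        return {scan: i for i, scan in enumerate(self.scan_ids)}


def prepare_spectra(
    msms: Table,
    matrix: CorrectionMatrix | None,
    config: ReportingConfig,
    log: RunLog | None = None,
) -> SpectrumSet | None:
    """Correct, calibrate, filter and normalize all reporter spectra.

    Returns ``None`` when the msms table carries no reporter-intensity
    columns (no isobaric labelling).  Missing intensity values count as 0.
    """
    cols = reporter_columns(msms.column_titles)
    if not cols:
        if log is not None:
            log.info("no reporter-intensity columns found; "
                     "isobaric quantification not performed")
        return None
    labels = [c.replace("Reporter intensity", "channel").strip() for c in cols]
    if matrix is None:
        matrix = CorrectionMatrix.identity(labels)
        if log is not None:
            log.info("no correction matrix supplied; using identity "
                     "(no isotope-impurity correction)")
    id_col = msms.first_column("id")
    raw_col = msms.first_column("Raw file")
    scan_ids = [
        row.get(id_col, str(i)) if id_col else str(i)
        for i, row in enumerate(msms.rows)
    ]
    raw_files = [row.get(raw_col, "") if raw_col else "" for row in msms.rows]
    raw = np.array(
        [[max(to_float(row.get(c, "0"), 0.0), 0.0) for c in cols] for row in msms.rows],
        dtype=float,
    )
    if raw.size == 0:
        raw = raw.reshape(0, len(cols))
    corrected, n_clamped = apply_correction(raw, matrix) if len(raw) else (raw, 0)
    if n_clamped and log is not None:
        log.info(f"isotope-impurity correction clamped {n_clamped} negative values to 0")
    calibration = compute_calibration_factors(corrected, labels)
    calibrated = corrected * calibration.factors[None, :]
    fractions, included = normalize_spectra(calibrated, config.low_intensity_threshold)
    if log is not None:
        n_excluded = int(np.count_nonzero(~included))
        if n_excluded:
            log.info(
                f"{n_excluded} spectra at or below the low-intensity threshold "
                f"({config.low_intensity_threshold}) excluded from quantification"
            )
    return SpectrumSet(
        scan_ids=scan_ids,
        raw_files=raw_files,
        channel_labels=labels,
        raw=raw,
        corrected=corrected,
        calibrated=calibrated,
        fractions=fractions,
        included=included,
        calibration=calibration,
        n_clamped=n_clamped,
    )


# ---------------------------------------------------------------------------
# Entity-level quantification and replicate merging

@dataclass
class QuantTables:
    """Per-replicate and merged quantification tables for one reporting level."""

    level: str
    channel_labels: list[str]
    per_replicate: dict[str, pd.DataFrame]
    merged: pd.DataFrame

    @property
    def n_quantified(self) -> int:
        return len(self.merged)


def quantify_level(
    level: str,
    entity_scans: dict[str, list[str]],
    spectra: SpectrumSet,
    design: ExperimentalDesign,
    config: ReportingConfig,
    log: RunLog | None = None,
) -> QuantTables:
    """Quantify every entity (protein group, peptide or site) per replicate.

    Each replicate is quantified separately over the spectra of its raw
    files, then the per-replicate tables are merged by entity id with empty
    cells where an entity was not quantified.
    """
    index = spectra.index_of()
    replicate_of = {
        raw: design.replicate_of(raw, log) for raw in set(spectra.raw_files)
    }
    per_replicate: dict[str, pd.DataFrame] = {}
    for replicate in design.replicates:
        rows = []
        for entity_id, scans in entity_scans.items():
            keep = [
                index[s]
                for s in scans
                if s in index
                and spectra.included[index[s]]
                and replicate_of.get(spectra.raw_files[index[s]]) == replicate
            ]
            if not keep:
                continue
            summary = summarize_group(
                spectra.fractions[keep], config.outlier_sigma
            )
            row: dict[str, object] = {"id": entity_id, "Spectra": summary.n_spectra}
            for c, label in enumerate(spectra.channel_labels):
                row[f"Median {label}"] = summary.median[c]
                row[f"Mean {label}"] = summary.mean[c]
                row[f"SD {label}"] = summary.sd[c]
                row[f"Removed {label}"] = summary.n_removed[c]
            rows.append(row)
        per_replicate[replicate] = pd.DataFrame(rows)
    merged = merge_replicates(per_replicate)
    return QuantTables(level, list(spectra.channel_labels), per_replicate, merged)


def merge_replicates(per_replicate: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Full outer join of per-replicate tables on entity id.

    Columns are prefixed with the replicate label; no cross-replicate
    averaging is performed.
    """
    merged: pd.DataFrame | None = None
    for replicate, df in per_replicate.items():
        if df.empty:
            continue
        renamed = df.rename(
            columns={c: f"{replicate}: {c}" for c in df.columns if c != "id"}
        )
        merged = (
            renamed
            if merged is None
            else merged.merge(renamed, on="id", how="outer")
        )
    return merged if merged is not None else pd.DataFrame(columns=["id"])


# ---------------------------------------------------------------------------
# Entity -> scan maps

def protein_entity_scans(
    msms: Table,
    groups_by_id: dict,
    config: ReportingConfig,
    log: RunLog | None = None,
) -> dict[str, list[str]]:
    """Assign each scan to its resolved protein group.

    With ``use_unique_peptides_only`` (the default), only scans whose peptide
    maps to exactly one surviving protein group contribute; proteins with
    only shared peptides remain unquantified.
    """
    from .mq_io import split_ids
    from .protein_report import resolve_best_group

    gid_col = msms.first_column("Protein group IDs")
    id_col = msms.first_column("id")
    out: dict[str, list[str]] = {}
    for i, row in enumerate(msms.rows):
        candidates = [
            g for g in split_ids(row.get(gid_col, "")) if g in groups_by_id
        ] if gid_col else []
        if not candidates:
            continue
        if config.use_unique_peptides_only and len(candidates) > 1:
            continue
        chosen = resolve_best_group(candidates, groups_by_id)
        scan = row.get(id_col, str(i)) if id_col else str(i)
        out.setdefault(chosen, []).append(scan)
    return out


def peptide_entity_scans(msms: Table) -> dict[str, list[str]]:
    """Assign each scan to its peptide id."""
    pep_col = msms.first_column("Peptide ID")
    id_col = msms.first_column("id")
    out: dict[str, list[str]] = {}
    for i, row in enumerate(msms.rows):
        pep = row.get(pep_col, "") if pep_col else ""
        if not pep:
            continue
        scan = row.get(id_col, str(i)) if id_col else str(i)
        out.setdefault(pep, []).append(scan)
    return out


def site_entity_scans(site_records: list) -> dict[str, list[str]]:
    """Assign scans to sites; only specific sites are quantified."""
    from .sites import SPECIFIC

    out: dict[str, list[str]] = {}
    for rec in site_records:
        if rec.site_class != SPECIFIC:
            continue
        entity = f"{rec.ptm_name}:{rec.accession}:{rec.position}"
        out[entity] = list(rec.scan_ids)
    return out
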