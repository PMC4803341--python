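"""Reporter-ion correction, calibration, normalization, outliers, summaries."""
from __future__ import annotations

import numpy as np
import pytest

from mqlibra.config import CorrectionMatrix, ExperimentalDesign, ReportingConfig
from mqlibra.libra import (
    QuantError,
    apply_correction,
    compute_calibration_factors,
    merge_replicates,
    normalize_spectra,
    outlier_retained_mask,
    quantify_level,
    reporter_columns,
    summarize_group,
)
import pandas as pd

from mqlibra.mq_io import Table


# ---------------------------------------------------------------------------
# correction

def test_identity_matrix_is_noop():
    matrix = CorrectionMatrix.identity(["a", "b", "c"])
    vec = np.array([5.0, 0.0, 3.0])
    corrected, n_clamped = apply_correction(vec, matrix)
    np.testing.assert_allclose(corrected, vec)
    assert n_clamped == 0


def test_two_channel_bleed_recovered():
    """M=[[0.9,0.1],[0.1,0.9]] applied to true [100,0] gives observed [90,10];
    correction recovers the true vector."""
    matrix = CorrectionMatrix(["a", "b"], [[0.9, 0.1], [0.1, 0.9]])
    corrected, _ = apply_correction(np.array([90.0, 10.0]), matrix)
    np.testing.assert_allclose(corrected, [100.0, 0.0], atol=1e-10)


def test_negative_solution_clamped_and_counted():
    matrix = CorrectionMatrix(["a", "b"], [[0.9, 0.1], [0.1, 0.9]])
    corrected, n_clamped = apply_correction(np.array([5.0, 100.0]), matrix)
    assert n_clamped == 1
    assert corrected[0] == 0.0


def test_singular_matrix_is_fatal():
    matrix = CorrectionMatrix(["a", "b"], [[0.5, 0.5], [0.5, 0.5]])
    with pytest.raises(QuantError, match="singular"):
        apply_correction(np.array([1.0, 1.0]), matrix)


def test_correction_inverts_forward_model_for_random_matrices():
    """Round trip M @ correct(v) == v for well-conditioned 6x6 matrices."""
    rng = np.random.default_rng(99)
    for _ in range(20):
        off = rng.uniform(0, 0.05, size=(6, 6))
        values = off + np.diag(1.0 - off.sum(axis=0))
        np.fill_diagonal(off, 0.0)
        matrix = CorrectionMatrix([f"c{i}" for i in range(6)], values)
        true = rng.uniform(10, 1e6, size=6)
        observed = values @ true
        corrected, _ = apply_correction(observed, matrix)
        np.testing.assert_allclose(corrected, true, rtol=1e-8)
        np.testing.assert_allclose(matrix.values @ corrected, observed, rtol=1e-8)


# ---------------------------------------------------------------------------
# calibration

def test_equal_totals_give_unit_factors():
    cal = compute_calibration_factors(
        np.array([[100.0, 100.0, 100.0]]), ["a", "b", "c"]
    )
    np.testing.assert_allclose(cal.factors, [1.0, 1.0, 1.0])


def test_factors_follow_mean_over_total():
    cal = compute_calibration_factors(
        np.array([[150.0, 80.0], [50.0, 20.0]]), ["a", "b"]
    )
    np.testing.assert_allclose(cal.factors, [0.75, 1.5])


def test_single_spectrum_calibration():
    cal = compute_calibration_factors(np.array([50.0, 100.0]), ["a", "b"])
    np.testing.assert_allclose(cal.factors, [1.5, 0.75])


def test_calibration_equalizes_totals():
    rng = np.random.default_rng(5)
    intensities = rng.lognormal(10, 1, size=(200, 6))
    cal = compute_calibration_factors(intensities, [f"c{i}" for i in range(6)])
    totals = (intensities * cal.factors).sum(axis=0)
    np.testing.assert_allclose(totals, totals.mean(), rtol=1e-6)


def test_zero_total_channel_is_fatal_and_named():
    with pytest.raises(QuantError, match="deadchan"):
        compute_calibration_factors(
            np.array([[1.0, 0.0], [2.0, 0.0]]), ["ok", "deadchan"]
        )


# ---------------------------------------------------------------------------
# normalization

def test_fractions_sum_to_one():
    fractions, included = normalize_spectra(np.array([[300.0, 100.0]]))
    np.testing.assert_allclose(fractions[0], [0.75, 0.25])
    assert included.all()


def test_uniform_spectrum_gives_equal_fractions():
    fractions, _ = normalize_spectra(np.full((1, 6), 100.0))
    np.testing.assert_allclose(fractions[0], 1 / 6)


def test_zero_total_spectrum_excluded_not_error():
    fractions, included = normalize_spectra(np.array([[0.0, 0.0], [3.0, 1.0]]))
    assert included.tolist() == [False, True]
    assert np.isnan(fractions[0]).all()


def test_low_intensity_threshold_excludes_spectra():
    _, included = normalize_spectra(np.array([[4.0, 4.0], [100.0, 100.0]]), 10.0)
    assert included.tolist() == [False, True]


# ---------------------------------------------------------------------------
# outlier rejection

def test_identical_values_nothing_removed():
    mask = outlier_retained_mask(np.full(10, 0.25), 1.96)
    assert mask.all()


def test_small_groups_skip_removal():
    assert outlier_retained_mask(np.array([0.1, 0.9]), 1.96).all()


def test_spec_example_computed_from_the_numbers():
    """values [0.1,0.1,0.1,0.1,0.9]: mu=0.26, population sigma=0.32, so the
    0.9 deviates by 0.64 > 1.96*0.32 = 0.6272 and is removed."""
    values = np.array([0.1, 0.1, 0.1, 0.1, 0.9])
    mu, sigma = values.mean(), values.std()
    assert mu == pytest.approx(0.26)
    assert sigma == pytest.approx(0.32)
    assert abs(0.9 - mu) > 1.96 * sigma
    mask = outlier_retained_mask(values, 1.96)
    assert mask.tolist() == [True, True, True, True, False]


def test_outlier_removal_idempotent_on_retained_set():
    rng = np.random.default_rng(3)
    for _ in range(50):
        values = rng.normal(0.3, 0.1, size=int(rng.integers(3, 40)))
        retained = values[outlier_retained_mask(values, 1.96)]
        again = retained[outlier_retained_mask(retained, 1.96)]
        # a second pass may tighten further only if the first removed nothing
        if retained.size == values.size:
            assert again.size == retained.size


# ---------------------------------------------------------------------------
# summaries

def test_single_spectrum_summary():
    summary = summarize_group(np.array([[0.75, 0.25]]), 1.96)
    np.testing.assert_allclose(summary.median, [0.75, 0.25])
    np.testing.assert_allclose(summary.mean, [0.75, 0.25])
    np.testing.assert_allclose(summary.sd, [0.0, 0.0])


def test_three_value_channel_summary():
    summary = summarize_group(
        np.array([[0.2, 0.8], [0.4, 0.6], [0.6, 0.4]]), 1.96
    )
    assert summary.median[0] == pytest.approx(0.4)
    assert summary.mean[0] == pytest.approx(0.4)
    assert summary.n_used[0] == 3


# ---------------------------------------------------------------------------
# level quantification and merging

def _spectrum_set(raw_files, intensities, labels=("c0", "c1")):
    from mqlibra.libra import SpectrumSet, ChannelCalibration

    intensities = np.asarray(intensities, dtype=float)
    fractions, included = normalize_spectra(intensities)
    return SpectrumSet(
        scan_ids=[str(i) for i in range(len(raw_files))],
        raw_files=list(raw_files),
        channel_labels=list(labels),
        raw=intensities,
        corrected=intensities,
        calibrated=intensities,
        fractions=fractions,
        included=included,
        calibration=ChannelCalibration(list(labels), np.ones(len(labels))),
    )


def test_single_replicate_merged_equals_replicate_table():
    spectra = _spectrum_set(["f1"], [[75.0, 25.0]])
    design = ExperimentalDesign({"f1": "R1"}, ["R1"])
    tables = quantify_level(
        "protein_groups", {"g0": ["0"]}, spectra, design, ReportingConfig()
    )
    assert tables.n_quantified == 1
    merged = tables.merged
    assert merged.loc[0, "R1: Median c0"] == pytest.approx(0.75)


def test_entity_quantified_in_one_of_two_replicates_keeps_empty_block():
    spectra = _spectrum_set(["f1", "f2"], [[75.0, 25.0], [50.0, 50.0]])
    design = ExperimentalDesign({"f1": "R1", "f2": "R2"}, ["R1", "R2"])
    tables = quantify_level(
        "protein_groups", {"g0": ["0"], "g1": ["1"]}, spectra, design,
        ReportingConfig(),
    )
    merged = tables.merged.set_index("id")
    assert np.isnan(merged.loc["g0", "R2: Median c0"])
    assert merged.loc["g1", "R2: Median c0"] == pytest.approx(0.5)


def test_merge_of_empty_tables_is_empty():
    assert merge_replicates({"R1": pd.DataFrame()}).empty


def test_reporter_column_detection_orders_and_filters():
    titles = ["Reporter intensity count 0", "Reporter intensity 1",
              "Reporter intensity 0", "Reporter intensity corrected 1",
              "Score"]
    assert reporter_columns(titles) == [
        "Reporter intensity 0", "Reporter intensity 1"
    ]
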