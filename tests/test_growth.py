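"""Generations formula, log-phase detection, growth rate, fitness table."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microsocial.growth import (
    DEFAULT_CONFIG,
    GrowthConfig,
    baseline_correct,
    build_fitness_table,
    compute_generations,
    compute_growth_rate,
    detect_log_phase,
    extract_features,
    STATUS_NO_GROWTH,
    STATUS_OK,
)
from microsocial.plate_io import ODTimeSeries, StrainPanel, build_layout
from microsocial.synthetic import logistic_od


def exponential_curve(rate=0.2, od0=0.01, hours=48):
    """Exact exponential whose baseline correction is the identity."""
    t = np.arange(0.0, hours + 0.5)
    return ODTimeSeries("w", t, od0 * 2 ** (rate * t))


@pytest.mark.parametrize(
    "B,b,expected",
    [(0.1, 0.8, 3.0), (0.25, 0.25, 0.0), (0.2, 0.5, math.log2(2.5)), (0.8, 0.1, -3.0)],
)
def test_generations_formula(B, b, expected):
    assert compute_generations(B, b) == pytest.approx(expected, abs=1e-12)


def test_generations_requires_positive_endpoints():
    for B, b in ((0.0, 0.5), (0.5, 0.0), (-0.1, 0.5)):
        with pytest.raises(ValueError, match="positive"):
            compute_generations(B, b)


@settings(max_examples=200, derandomize=True)
@given(
    B=st.floats(min_value=1e-3, max_value=10.0),
    b=st.floats(min_value=1e-3, max_value=10.0),
)
def test_generations_antisymmetry(B, b):
    assert compute_generations(B, b) == -compute_generations(b, B)


def test_exact_exponential_recovered_exactly():
    curve = exponential_curve(rate=0.2)
    start, end, B, b = detect_log_phase(curve)
    assert (start, end) == (0.0, 48.0)  # full span
    feat = extract_features(curve)
    assert feat.k == pytest.approx(0.2, abs=1e-10)
    assert feat.n == pytest.approx(0.2 * 48, abs=1e-9)
    assert feat.status == STATUS_OK


@pytest.mark.parametrize("rate", [0.05, 0.18, 0.4])
def test_n_equals_k_times_logphase_on_exponentials(rate):
    feat = extract_features(exponential_curve(rate=rate, hours=30))
    assert feat.n == pytest.approx(feat.k * feat.log_phase_time, abs=1e-9)


def test_logistic_window_matches_hand_application_of_rule():
    """The extractor agrees with a direct, independent application of the
    documented slope-threshold rule to a saturating logistic curve."""
    config = DEFAULT_CONFIG
    t = np.arange(0.0, 97.0)
    cells = logistic_od(t, 0.01, 0.8, 0.2)
    curve = ODTimeSeries("w", t, 0.05 + cells)  # blank + signal

    # hand application: blank-correct, log2, least-squares slopes in a
    # centered window, threshold at theta * max, expand the run
    corrected = np.maximum(cells + 0.01 - cells[:3].min(), 0.01)
    y = np.log2(corrected)
    half = config.slope_points // 2
    slopes = []
    for i in range(len(t)):
        lo, hi = max(i - half, 0), min(i + half, len(t) - 1)
        slopes.append(np.polyfit(t[lo : hi + 1], y[lo : hi + 1], 1)[0])
    slopes = np.array(slopes)
    imax = int(np.argmax(slopes))
    thr = config.theta * slopes[imax]
    lo = hi = imax
    while lo > 0 and slopes[lo - 1] >= thr:
        lo -= 1
    while hi < len(t) - 1 and slopes[hi + 1] >= thr:
        hi += 1
    expected_n = np.log2(corrected[hi] / corrected[lo])

    feat = extract_features(curve, config)
    assert (feat.log_phase_start, feat.log_phase_end) == (t[lo], t[hi])
    assert feat.n == pytest.approx(expected_n, rel=1e-9)
    # the theta=0.5 window runs from the start of growth up to (within the
    # slope-window resolution) the biomass inflection, where cells = K/2 and
    # the log-slope has fallen to half its maximum
    t_mid = np.log2(0.8 / 0.01 - 1) / 0.2
    assert feat.log_phase_start < t_mid
    assert abs(feat.log_phase_end - t_mid) <= 3.0


def test_flat_and_subfloor_curves_are_no_growth():
    t = np.arange(0.0, 96.0)
    flat = extract_features(ODTimeSeries("w", t, np.full_like(t, 0.1)))
    assert flat.status == STATUS_NO_GROWTH
    assert flat.n == 0.0 and flat.k == 0.0 and flat.log_phase_time == 0.0
    low = extract_features(ODTimeSeries("w", t, np.full_like(t, 0.001)))
    assert low.status == STATUS_NO_GROWTH  # no exception


def test_growth_rate_examples():
    curve = exponential_curve(rate=0.2, hours=20)  # doubling every 5 h
    assert compute_growth_rate(curve, (0.0, 20.0)) == pytest.approx(0.2, abs=1e-10)
    with pytest.raises(ValueError, match="< 2 points"):
        compute_growth_rate(curve, (3.2, 3.4))


def test_noisy_exponential_rate_recovery():
    rng = np.random.default_rng(11)
    t = np.arange(0.0, 49.0)
    od = 0.01 * 2 ** (0.18 * t) * np.exp(rng.normal(0, 0.01, t.size))
    feat = extract_features(ODTimeSeries("w", t, od))
    assert feat.k == pytest.approx(0.18, abs=0.01)


@settings(max_examples=100, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=2.0), min_size=4, max_size=50))
def test_baseline_correction_respects_floor(values):
    corrected = baseline_correct(np.array(values), DEFAULT_CONFIG)
    assert np.all(corrected >= DEFAULT_CONFIG.baseline_floor)


def test_growth_config_validation():
    with pytest.raises(ValueError):
        GrowthConfig(theta=0.0)
    with pytest.raises(ValueError):
        GrowthConfig(slope_points=4)


def test_fitness_table_aggregation(panel7, caplog):
    import logging

    from microsocial.growth import GrowthFeatures

    layout = build_layout(
        [("A1", ["MS2"], "MTBE", 1), ("A2", ["MS2"], "MTBE", 2), ("A3", ["MS2"], "MTBE", 3),
         ("B1", ["SH7"], "MTBE", 1), ("B2", ["SH7"], "MTBE", 2)],
        panel7,
    )
    feats = {
        "A1": GrowthFeatures("A1", 0.1, 0.8, 3.0, 0.1, 0.0, 30.0),
        "A2": GrowthFeatures("A2", 0.1, 0.9, 3.2, 0.11, 0.0, 30.0),
        "A3": GrowthFeatures("A3", 0.1, 1.0, 3.4, 0.12, 0.0, 30.0),
    }
    with caplog.at_level(logging.WARNING):
        table = build_fitness_table(feats, layout)
    assert table.consortium_means("n", "MTBE")["MS2"] == pytest.approx(3.2)
    assert ("SH7", "MTBE") in table.missing  # zero successful replicates
    assert any("zero successful replicates" in r.message for r in caplog.records)


def test_no_growth_replicate_included_in_mean(panel7):
    from microsocial.growth import GrowthFeatures

    layout = build_layout(
        [(f"A{i}", ["MS2"], "MTBE", i) for i in (1, 2, 3)], panel7
    )
    feats = {
        "A1": GrowthFeatures("A1", 0.1, 0.8, 3.0, 0.1, 0.0, 30.0),
        "A2": GrowthFeatures("A2", 0.1, 0.8, 3.0, 0.1, 0.0, 30.0),
        "A3": GrowthFeatures("A3", 0.01, 0.01, 0.0, 0.0, 0.0, 0.0, STATUS_NO_GROWTH),
    }
    table = build_fitness_table(feats, layout)
    assert table.consortium_means("n", "MTBE")["MS2"] == pytest.approx(2.0)
    assert table.summary()["status"].iloc[0] == STATUS_NO_GROWTH  # flagged


def test_full_design_row_count(study_table):
    # 127 consortia x 2 conditions x 2 metrics
    assert len(study_table.summary()) == 127 * 2 * 2
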