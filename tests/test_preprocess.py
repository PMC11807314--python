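"""Thresholding, gating, normalization and the trigonometric transform."""

import math

import numpy as np
import pandas as pd
import pytest

from timerflow import (
    ConfigurationError,
    DataError,
    GateThresholds,
    ThresholdSpec,
    apply_blue_multiplier,
    classify_timer_positive,
    compute_gate_thresholds,
    compute_normalization_params,
    gate_negative_cells,
    log_transform,
    normalize_channel,
    quadrant_classify,
    timer_transform_batch,
    transform_sample,
    trig_transform,
)
from timerflow.preprocess import NormalizationParams
from timerflow.synthetic import BLUE_CHANNEL, RED_CHANNEL

from conftest import toy_matrix


# --- log transform ---------------------------------------------------------

@pytest.mark.parametrize(
    "values,floor,expected",
    [
        ([1, 10, 100], 1.0, [0, 1, 2]),
        ([-5, 0.5], 1.0, [0, 0]),
        ([3.16227766016838], 1.0, [0.5]),
    ],
)
def test_log_transform(values, floor, expected):
    np.testing.assert_allclose(log_transform(values, floor), expected, atol=1e-12)


def test_log_transform_requires_positive_floor():
    with pytest.raises(ConfigurationError):
        log_transform([1.0], 0.0)


# --- thresholds ------------------------------------------------------------

def test_quantile_thresholds_linear_interpolation():
    neg = toy_matrix(np.arange(1, 101.0), np.arange(1, 101.0))
    thr = compute_gate_thresholds(neg, ThresholdSpec(quantile_q=0.5),
                                  BLUE_CHANNEL, RED_CHANNEL)
    assert thr.blue_threshold == pytest.approx(50.5, abs=1e-12)
    thr = compute_gate_thresholds(neg, ThresholdSpec(quantile_q=0.975),
                                  BLUE_CHANNEL, RED_CHANNEL)
    assert thr.blue_threshold == pytest.approx(97.525, abs=1e-9)


def test_manual_thresholds_passthrough():
    neg = toy_matrix([1.0], [1.0])
    spec = ThresholdSpec(method="manual", manual_blue=200.0, manual_red=300.0)
    thr = compute_gate_thresholds(neg, spec, BLUE_CHANNEL, RED_CHANNEL)
    assert (thr.blue_threshold, thr.red_threshold) == (200.0, 300.0)


def test_threshold_spec_validation():
    with pytest.raises(ConfigurationError):
        ThresholdSpec(quantile_q=1.5)
    with pytest.raises(ConfigurationError):
        ThresholdSpec(method="manual", manual_blue=1.0)
    with pytest.raises(ConfigurationError):
        ThresholdSpec(method="interactive")


def test_quantile_thresholds_require_enough_cells():
    neg = toy_matrix([1, 2, 3], [1, 2, 3])
    with pytest.raises(DataError):
        compute_gate_thresholds(neg, ThresholdSpec(), BLUE_CHANNEL, RED_CHANNEL)


# --- negative-control gating -----------------------------------------------

def test_gate_negative_corner_cells():
    neg = toy_matrix([1, 5, 1, 5] * 3, [1, 1, 5, 5] * 3)
    gated = gate_negative_cells(neg, GateThresholds(2, 2), BLUE_CHANNEL, RED_CHANNEL,
                                min_cells=1)
    assert gated.n_cells == 3  # only the (1,1) cells
    # inclusive boundary: thresholds at the data maxima keep everything
    gated = gate_negative_cells(neg, GateThresholds(5, 5), BLUE_CHANNEL, RED_CHANNEL)
    assert gated.n_cells == neg.n_cells


def test_gate_negative_matches_brute_force_count():
    rng = np.random.default_rng(42)
    blue = rng.uniform(0, 100, 1000)
    red = rng.uniform(0, 100, 1000)
    neg = toy_matrix(blue, red)
    thr = compute_gate_thresholds(neg, ThresholdSpec(quantile_q=0.9),
                                  BLUE_CHANNEL, RED_CHANNEL)
    gated = gate_negative_cells(neg, thr, BLUE_CHANNEL, RED_CHANNEL)
    expected = sum(
        1 for b, r in zip(blue, red)
        if b <= thr.blue_threshold and r <= thr.red_threshold
    )
    assert gated.n_cells == expected
    assert 700 < expected < 900  # ~0.81 * 1000 for independent channels


def test_gate_too_small_is_fatal():
    neg = toy_matrix(np.arange(1, 101.0), np.arange(1, 101.0))
    with pytest.raises(DataError, match="gated negative control"):
        gate_negative_cells(neg, GateThresholds(5, 5), BLUE_CHANNEL, RED_CHANNEL)


# --- normalization parameters ----------------------------------------------

def test_normalization_params_sd_and_mad():
    # log10 values 0.5, 1.0, 1.5 -> raw 10**x
    raw = 10.0 ** np.array([0.5, 1.0, 1.5])
    p3 = compute_normalization_params(
        toy_matrix(raw, raw), BLUE_CHANNEL, RED_CHANNEL, method="SD")
    assert p3.blue_max_log_neg == pytest.approx(1.5)
    assert p3.red_max_log_neg == pytest.approx(1.5)
    assert p3.blue_scale_log_neg == pytest.approx(0.5, abs=1e-12)  # n-1 SD of {0.5,1,1.5}
    pm = compute_normalization_params(
        toy_matrix(raw, raw), BLUE_CHANNEL, RED_CHANNEL, method="MAD")
    assert pm.blue_scale_log_neg == pytest.approx(0.5 * 1.4826, abs=1e-12)


def test_degenerate_control_is_fatal():
    gated = toy_matrix([10.0] * 20, [10.0] * 20)
    with pytest.raises(DataError, match="degenerate"):
        compute_normalization_params(gated, BLUE_CHANNEL, RED_CHANNEL)


@pytest.mark.parametrize(
    "x,loc,scale,expected",
    [(2.5, 1.5, 0.5, 2.0), (1.5, 1.5, 0.5, 0.0), (1.5, 1.5, 0.7413, 0.0)],
)
def test_normalize_channel(x, loc, scale, expected):
    assert normalize_channel([x], loc, scale)[0] == pytest.approx(expected, abs=1e-12)


def test_normalize_channel_rejects_nonpositive_scale():
    with pytest.raises(ConfigurationError):
        normalize_channel([1.0], 0.0, 0.0)


# --- positivity and quadrants ----------------------------------------------

THR = GateThresholds(100.0, 200.0)


@pytest.mark.parametrize(
    "blue,red,positive,quadrant",
    [
        (100.0, 200.0, False, "NegNeg"),     # exactly at threshold: background
        (101.0, 0.0, True, "BluePosRedNeg"),
        (0.0, 201.0, True, "BlueNegRedPos"),
        (101.0, 201.0, True, "BluePosRedPos"),
        (99.0, 199.0, False, "NegNeg"),
    ],
)
def test_positivity_and_quadrant(blue, red, positive, quadrant):
    assert classify_timer_positive([blue], [red], THR)[0] == positive
    assert quadrant_classify([blue], [red], THR)[0] == quadrant


def test_quadrants_partition_random_cells():
    rng = np.random.default_rng(7)
    blue = rng.uniform(0, 400, 100)
    red = rng.uniform(0, 400, 100)
    labels = quadrant_classify(blue, red, THR)
    counts = pd.Series(labels).value_counts()
    assert counts.sum() == 100
    assert set(counts.index) <= {"NegNeg", "BluePosRedNeg", "BluePosRedPos", "BlueNegRedPos"}


# --- trigonometric transform -----------------------------------------------

@pytest.mark.parametrize(
    "b,r,angle,intensity",
    [
        (1.0, 0.0, 0.0, 1.0),                      # pure blue
        (0.0, 1.0, 90.0, 1.0),                     # pure red
        (1.0, 1.0, 45.0, math.sqrt(2)),
        (3.0, 4.0, 53.13010235415598, 5.0),        # arccos(3/5)
        (-2.0, 1.0, 90.0, 1.0),                    # blue clamped to 0
        (5.0, -1.0, 0.0, 5.0),                     # red clamped to 0
    ],
)
def test_trig_transform_values(b, r, angle, intensity):
    a, i = trig_transform([b], [r])
    assert a[0] == pytest.approx(angle, abs=1e-9)
    assert i[0] == pytest.approx(intensity, rel=1e-12)


def test_trig_transform_origin_has_missing_angle():
    a, i = trig_transform([0.0, -1.0], [0.0, -2.0])
    assert np.all(i == 0.0)
    assert np.all(np.isnan(a))


# --- per-sample transform ---------------------------------------------------

def _params(loc_b=2.0, scale_b=0.25, loc_r=2.0, scale_r=0.25, method="SD", floor=1.0):
    return NormalizationParams(
        method=method, log_floor=floor,
        blue_max_log_neg=loc_b, blue_scale_log_neg=scale_b,
        red_max_log_neg=loc_r, red_scale_log_neg=scale_r, n_gated_neg=100,
    )


def test_transform_sample_all_negative_means_no_angles():
    sample = toy_matrix([10, 50, 100], [10, 50, 100])
    t = transform_sample(sample, GateThresholds(100, 100), _params(),
                         BLUE_CHANNEL, RED_CHANNEL)
    assert not t.data["timer_positive"].any()
    assert t.data["angle_deg"].isna().all()
    assert t.data["intensity"].isna().all()


def test_transform_sample_pure_blue_cell_is_zero_degrees():
    # raw blue far above threshold, red at the log floor
    sample = toy_matrix([1e5], [0.5])
    t = transform_sample(sample, GateThresholds(100, 100), _params(),
                         BLUE_CHANNEL, RED_CHANNEL)
    row = t.data.iloc[0]
    assert row.timer_positive
    assert row.angle_deg == pytest.approx(0.0, abs=1e-12)


def test_transform_sample_matches_hand_computation():
    """5-cell toy table against an independent elementwise evaluation."""
    blue = [1e4, 50.0, 400.0, 1e3, 0.2]
    red = [60.0, 1e4, 400.0, 1e3, 0.3]
    thr = GateThresholds(100.0, 100.0)
    prm = _params(loc_b=2.0, scale_b=0.25, loc_r=2.1, scale_r=0.5)
    t = transform_sample(toy_matrix(blue, red), thr, prm, BLUE_CHANNEL, RED_CHANNEL)
    for i, (b, r) in enumerate(zip(blue, red)):
        b_log = math.log10(max(b, 1.0))
        r_log = math.log10(max(r, 1.0))
        b_n = (b_log - 2.0) / 0.25
        r_n = (r_log - 2.1) / 0.5
        row = t.data.iloc[i]
        assert row.blue_norm == pytest.approx(b_n, abs=1e-12)
        assert row.red_norm == pytest.approx(r_n, abs=1e-12)
        positive = b > 100.0 or r > 100.0
        assert bool(row.timer_positive) == positive
        if positive:
            bc, rc = max(b_n, 0.0), max(r_n, 0.0)
            inten = math.hypot(bc, rc)
            assert row.intensity == pytest.approx(inten, rel=1e-12)
            if inten > 0:
                assert row.angle_deg == pytest.approx(
                    math.degrees(math.acos(bc / inten)), abs=1e-9)
        else:
            assert math.isnan(row.angle_deg) and math.isnan(row.intensity)


def test_non_normalized_mode_is_centered_only():
    sample = toy_matrix([1e4], [1e3])
    prm = _params(loc_b=2.0, scale_b=0.25, loc_r=2.0, scale_r=0.5)
    t = transform_sample(sample, GateThresholds(10, 10), prm,
                         BLUE_CHANNEL, RED_CHANNEL, normalize=False)
    assert t.data.blue_norm[0] == pytest.approx(4.0 - 2.0)
    assert t.data.red_norm[0] == pytest.approx(3.0 - 2.0)


# --- blue multiplier --------------------------------------------------------

def test_apply_blue_multiplier():
    mat = toy_matrix([1.0, 10.0], [5.0, 6.0])
    assert apply_blue_multiplier(mat, 1.0, BLUE_CHANNEL).data.equals(mat.data)
    m10 = apply_blue_multiplier(mat, 10.0, BLUE_CHANNEL)
    assert list(m10.channel(BLUE_CHANNEL)) == [10.0, 100.0]
    assert list(m10.channel(RED_CHANNEL)) == [5.0, 6.0]
    back = apply_blue_multiplier(apply_blue_multiplier(mat, 2.0, BLUE_CHANNEL),
                                 0.5, BLUE_CHANNEL)
    np.testing.assert_allclose(back.channel(BLUE_CHANNEL), mat.channel(BLUE_CHANNEL))
    with pytest.raises(ConfigurationError):
        apply_blue_multiplier(mat, 0.0, BLUE_CHANNEL)


# --- batch -------------------------------------------------------------------

def test_batch_outputs_and_counts(small_timecourse, tmp_path):
    manifest, _ = small_timecourse
    result = timer_transform_batch(manifest, output_dir=tmp_path)
    n_files = len(manifest.entries)
    assert len(result.samples) == n_files
    assert len(result.counts) == n_files
    assert len(list(tmp_path.glob("*_transformed.csv"))) == n_files
    assert (tmp_path / "normalization_parameters.csv").is_file()
    assert (tmp_path / "cell_counts.csv").is_file()
    assert (tmp_path / "sample_definition.csv").is_file()
    quad_cols = [c for c in result.counts.columns if c.startswith("n_") and
                 c not in ("n_total", "n_timer_positive")]
    assert (result.counts[quad_cols].sum(axis=1) == result.counts["n_total"]).all()
    assert (result.counts["n_timer_positive"] <= result.counts["n_total"]).all()


def test_batch_normalized_vs_centered_angles_close(small_timecourse):
    """With balanced gains the two modes differ only through the slightly
    different per-channel scale estimates, so angles barely move."""
    manifest, _ = small_timecourse
    norm = timer_transform_batch(manifest, normalize=True)
    cent = timer_transform_batch(manifest, normalize=False)
    diffs = []
    for sid in norm.samples:
        a = norm.samples[sid].data["angle_deg"].to_numpy()
        b = cent.samples[sid].data["angle_deg"].to_numpy()
        ok = ~np.isnan(a) & ~np.isnan(b)
        diffs.append(np.abs(a[ok] - b[ok]))
    assert np.median(np.concatenate(diffs)) < 5.0


def test_batch_empty_sample_is_fatal(tmp_path):
    rng = np.random.default_rng(0)
    neg = tmp_path / "neg.csv"
    pd.DataFrame({BLUE_CHANNEL: rng.uniform(10, 100, 50),
                  RED_CHANNEL: rng.uniform(10, 100, 50)}).to_csv(neg, index=False)
    bad = tmp_path / "bad.csv"
    bad.write_text(f"{BLUE_CHANNEL},{RED_CHANNEL}\n")
    from timerflow import build_manifest
    manifest = build_manifest([bad, neg], neg, BLUE_CHANNEL, RED_CHANNEL)
    with pytest.raises(DataError, match="bad"):
        timer_transform_batch(manifest)
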