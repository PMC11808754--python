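"""Spot integration, signal ratio, table arithmetic, %CV."""

import numpy as np
import pytest

from fastpass.errors import QuantError
from fastpass.io import Spot
from fastpass.quant import (
    FeatureTable,
    aggregate_titer,
    analyte_normalize,
    blank_subtract,
    integrate_spot,
    percent_cv,
    replicate_cv_report,
    signal_ratio,
)
from fastpass.trace import XICTrace


def _random_trace(rng, n=200):
    return XICTrace(300.0, 10.0, np.arange(n) * 50.0, rng.uniform(0, 100, n))


def test_integrate_all_zero_trace():
    trace = XICTrace(300.0, 10.0, np.arange(100) * 50.0, np.zeros(100))
    assert integrate_spot(trace, Spot("s", 2000.0, 1000.0)) == 0.0


def test_integrate_matches_brute_force_on_random_traces(rng):
    """Oracle: explicit per-pixel loop with the half-open interval rule."""
    for _ in range(1000):
        n = int(rng.integers(20, 120))
        trace = _random_trace(rng, n)
        center = float(rng.uniform(500, n * 50 - 500))
        width = float(rng.uniform(100, 2000))
        spot = Spot("s", center, width)
        expected = sum(
            float(v)
            for d, v in zip(trace.distances, trace.intensity)
            if spot.start <= d < spot.stop
        )
        if expected == 0 and not spot.contains(trace.distances).any():
            with pytest.raises(QuantError):
                integrate_spot(trace, spot)
        else:
            assert integrate_spot(trace, spot) == pytest.approx(expected)


def test_spot_plus_complement_partition_total(rng):
    trace = _random_trace(rng)
    spot = Spot("s", 3000.0, 1500.0)
    inside = integrate_spot(trace, spot)
    outside = trace.intensity[~spot.contains(trace.distances)].sum()
    assert inside + outside == pytest.approx(trace.intensity.sum())


def test_signal_ratio_self_is_one(rng):
    trace = _random_trace(rng)
    spot = Spot("s", 3000.0, 1500.0)
    assert signal_ratio(trace, spot, spot) == pytest.approx(1.0, rel=1e-6)


def test_signal_ratio_constructed_tenfold():
    n = 100
    d = np.arange(n) * 50.0
    intensity = np.ones(n)
    sample = Spot("s", 1000.0, 500.0)
    blank = Spot("b", 3000.0, 500.0)
    intensity[sample.contains(d)] = 10.0
    trace = XICTrace(300.0, 10.0, d, intensity)
    assert signal_ratio(trace, sample, blank) == pytest.approx(10.0, rel=1e-6)


def test_signal_ratio_matches_mean_of_pixels_oracle(rng):
    for _ in range(1000):
        trace = _random_trace(rng, 150)
        sample = Spot("s", float(rng.uniform(1000, 3000)), float(rng.uniform(300, 900)))
        blank = Spot("b", float(rng.uniform(4500, 6500)), float(rng.uniform(300, 900)))
        s_mask = sample.contains(trace.distances)
        b_mask = blank.contains(trace.distances)
        expected = trace.intensity[s_mask].mean() / (
            trace.intensity[b_mask].mean() + 1e-9 * trace.intensity.max()
        )
        assert signal_ratio(trace, sample, blank) == pytest.approx(expected, rel=1e-9)


def test_signal_ratio_invariant_under_rescaling(rng):
    trace = _random_trace(rng)
    scaled = XICTrace(300.0, 10.0, trace.distances, trace.intensity * 37.5)
    sample = Spot("s", 2000.0, 800.0)
    blank = Spot("b", 5000.0, 800.0)
    assert signal_ratio(scaled, sample, blank) == pytest.approx(
        signal_ratio(trace, sample, blank), rel=1e-6
    )


def test_signal_ratio_accepts_gap_mask(small_layout, rng):
    n = int(small_layout.scan_length / 50)
    trace = XICTrace(300.0, 10.0, np.arange(n) * 50.0, rng.uniform(1, 10, n))
    mask = small_layout.gap_mask(trace.distances)
    spot = small_layout.get("Spot 1")
    expected = trace.intensity[spot.contains(trace.distances)].mean() / (
        trace.intensity[mask].mean() + 1e-9 * trace.intensity.max()
    )
    assert signal_ratio(trace, spot, mask) == pytest.approx(expected, rel=1e-9)


def _table():
    return FeatureTable(
        spot_labels=["a", "b", "blank"],
        feature_mzs=[100.0, 200.0],
        values=np.array([[100.0, 10.0], [50.0, 40.0], [30.0, 30.0]]),
    )


def test_blank_subtract_arithmetic_and_floor():
    out = blank_subtract(_table(), "blank")
    assert out.stage == "blank_subtracted"
    assert out.row("a").tolist() == [70.0, 0.0]  # 10 - 30 floored at 0
    assert out.row("b").tolist() == [20.0, 10.0]
    assert out.row("blank").tolist() == [0.0, 0.0]
    assert "blank" in out.blank_labels


def test_blank_subtract_zero_blank_leaves_values():
    t = _table()
    t.values[2] = 0.0
    out = blank_subtract(t, "blank")
    assert np.allclose(out.values, t.values)
    assert out.stage == "blank_subtracted"


def test_blank_subtract_missing_label_rejected():
    with pytest.raises(QuantError):
        blank_subtract(_table(), "nope")


def test_analyte_normalize_columnwise_and_idempotent():
    t = FeatureTable(
        spot_labels=["a", "b", "c"],
        feature_mzs=[100.0],
        values=np.array([[70.0], [35.0], [0.0]]),
    )
    out = analyte_normalize(t)
    assert out.values[:, 0].tolist() == [1.0, 0.5, 0.0]
    again = analyte_normalize(out)
    assert np.allclose(again.values, out.values)
    assert out.feature_mzs == t.feature_mzs


def test_analyte_normalize_leaves_zero_column():
    t = FeatureTable(
        spot_labels=["a", "b"], feature_mzs=[1.0, 2.0],
        values=np.array([[5.0, 0.0], [10.0, 0.0]]),
    )
    out = analyte_normalize(t)
    assert np.all(out.values[:, 1] == 0.0)
    assert np.all(out.values[:, 0] <= 1.0)


def test_percent_cv_values():
    assert percent_cv([5.0, 5.0, 5.0]) == 0.0
    assert percent_cv([1.0, 2.0, 3.0]) == pytest.approx(50.0)


def test_percent_cv_scale_invariant(rng):
    x = rng.uniform(1, 10, 8)
    assert percent_cv(17.3 * x) == pytest.approx(percent_cv(x))


def test_percent_cv_degenerate_rejected():
    with pytest.raises(QuantError):
        percent_cv([5.0])
    with pytest.raises(QuantError):
        percent_cv([0.0, 0.0])


def test_aggregate_titer_single_cell_and_identical_replicates():
    t = FeatureTable(
        spot_labels=["a1", "a2", "b1"],
        feature_mzs=[100.0, 200.0],
        values=np.array([[3.0, 1.0], [3.0, 1.0], [7.0, 2.0]]),
    )
    out = aggregate_titer(t, [100.0, 200.0], {"a1": "A", "a2": "A", "b1": "B"})
    assert out.loc["A", "mean"] == pytest.approx(4.0)
    assert out.loc["A", "sd"] == pytest.approx(0.0)
    assert out.loc["B", "mean"] == pytest.approx(9.0)
    assert out.loc["B", "n"] == 1


def test_aggregate_titer_matches_group_sum_oracle(rng):
    for _ in range(200):
        n_spots, n_feat = int(rng.integers(4, 9)), int(rng.integers(2, 6))
        labels = [f"s{i}" for i in range(n_spots)]
        mzs = sorted(float(m) for m in rng.uniform(100, 900, n_feat))
        values = rng.uniform(0, 50, (n_spots, n_feat))
        table = FeatureTable(labels, mzs, values)
        groups = {lb: f"g{i % 2}" for i, lb in enumerate(labels)}
        subset = mzs[: int(rng.integers(1, n_feat + 1))]
        out = aggregate_titer(table, subset, groups)
        cols = [mzs.index(m) for m in subset]
        for g in ("g0", "g1"):
            members = [i for i, lb in enumerate(labels) if groups[lb] == g]
            sums = values[np.ix_(members, cols)].sum(axis=1)
            assert out.loc[g, "mean"] == pytest.approx(sums.mean())


def test_aggregate_titer_empty_subset_rejected():
    with pytest.raises(QuantError):
        aggregate_titer(_table(), [], {"a": "A", "b": "B", "blank": "Bl"})


def test_replicate_cv_report_mean_of_groups():
    t = FeatureTable(
        spot_labels=["a1", "a2", "b1", "b2"],
        feature_mzs=[100.0],
        values=np.array([[10.0], [12.0], [20.0], [20.0]]),
    )
    rep = replicate_cv_report(t, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
    assert rep.per_group_cv["B"] == pytest.approx(0.0)
    assert rep.overall_mean_cv == pytest.approx(rep.per_group_cv["A"] / 2)
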