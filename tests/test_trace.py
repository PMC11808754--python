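"""XIC/TIC extraction, lock-mass correction, spatial normalization."""

import numpy as np
import pytest
from dataclasses import replace

from fastpass.errors import CalibrationError, NormalizationError
from fastpass.io import LineScanRun, MassSpectrum
from fastpass.sim import AnalytePanelEntry, NoiseModel, simulate_run  # noqa: F401
from fastpass.trace import (
    XICTrace,
    extract_xic,
    lockmass_correct,
    spatial_normalize,
    total_ion_trace,
)


def _shift_run(run: LineScanRun, factor: float) -> LineScanRun:
    pixels = [
        (d, MassSpectrum(s.mz * factor, s.intensity.copy())) for d, s in run.pixels
    ]
    return replace(run, pixels=pixels)


@pytest.fixture
def lock_run(small_layout, single_analyte, quiet_noise, no_deloc_model):
    """Noiseless run carrying a lock-mass species at every pixel."""
    lock = AnalytePanelEntry(
        name="lock", formula="C28H37N5O7", adduct="[M-H]-",
        base_intensity=500.0, spot_labels=[],
    )
    run = simulate_run(
        small_layout, [single_analyte], rate=50.0, pixel_size=50.0,
        rate_model=no_deloc_model, noise=quiet_noise, lockmass=lock,
    )
    return run, lock.mz


def test_absent_mz_gives_all_zero_trace(clean_run):
    xic = extract_xic(clean_run, 999.999)
    assert np.all(xic.intensity == 0)


def test_xic_partition_additivity_matches_tic(clean_run):
    """Sum of XICs over a disjoint partition of the mass range equals TIC."""
    edges = np.linspace(50.0, 1200.0, 24)
    total = np.zeros(clean_run.n_pixels)
    for lo, hi in zip(edges, edges[1:]):
        center = (lo + hi) / 2
        tol_ppm = (hi - lo) / 2 / center * 1e6
        total += extract_xic(clean_run, center, tol_ppm).intensity
    tic = total_ion_trace(clean_run)
    assert np.allclose(total, tic.intensity)


def test_single_analyte_confined_to_its_spot(clean_run, small_layout, single_analyte):
    xic = extract_xic(clean_run, single_analyte.mz)
    spot = small_layout.get("Spot 3")
    outside = ~spot.contains(xic.distances)
    assert np.all(xic.intensity[outside] == 0)


def test_tic_dominates_any_xic(small_layout, single_analyte):
    run = simulate_run(small_layout, [single_analyte], rate=50.0, pixel_size=50.0,
                       noise=NoiseModel(seed=5))
    tic = total_ion_trace(run)
    xic = extract_xic(run, single_analyte.mz)
    assert np.all(tic.intensity >= xic.intensity - 1e-9)


def test_lockmass_recovers_planted_ten_ppm_shift(lock_run):
    run, lock_mz = lock_run
    shifted = _shift_run(run, 1.0 + 1e-5)
    corrected = lockmass_correct(shifted, lock_mz, search_ppm=50.0)
    for (_, orig), (_, corr) in zip(run.pixels, corrected.pixels):
        err = np.abs(corr.mz / orig.mz - 1.0) * 1e6
        assert np.all(err <= 0.1)


@pytest.mark.parametrize("shift_ppm", [-20.0, -5.0, 5.0, 20.0])
def test_lockmass_recovers_linear_distortions(lock_run, shift_ppm):
    run, lock_mz = lock_run
    shifted = _shift_run(run, 1.0 + shift_ppm * 1e-6)
    corrected = lockmass_correct(shifted, lock_mz, search_ppm=60.0)
    for (_, orig), (_, corr) in zip(run.pixels, corrected.pixels):
        err = np.abs(corr.mz / orig.mz - 1.0) * 1e6
        assert np.all(err <= 0.5)


def test_lockmass_near_identity_on_calibrated_run(lock_run):
    run, lock_mz = lock_run
    corrected = lockmass_correct(run, lock_mz, search_ppm=50.0)
    for (_, orig), (_, corr) in zip(run.pixels, corrected.pixels):
        err = np.abs(corr.mz / orig.mz - 1.0) * 1e6
        assert np.all(err <= 0.1)


def test_lockmass_rejects_absent_reference(clean_run):
    with pytest.raises(CalibrationError):
        lockmass_correct(clean_run, 999.999, search_ppm=20.0)


def test_normalize_identity_under_constant_lock(clean_run, single_analyte):
    xic = extract_xic(clean_run, single_analyte.mz)
    n = clean_run.n_pixels
    lock = XICTrace(500.0, 10.0, clean_run.distances, np.full(n, 3.0))
    out = spatial_normalize(xic, lock)
    assert out.normalized
    assert np.allclose(out.intensity, xic.intensity)


def test_normalize_flattens_covarying_drift():
    """Analyte co-doubling with the lock channel normalizes flat."""
    n = 100
    d = np.arange(n) * 50.0
    drift = np.where(np.arange(n) < n // 2, 1.0, 2.0)
    analyte = XICTrace(200.0, 10.0, d, 5.0 * drift)
    lock = XICTrace(500.0, 10.0, d, 100.0 * drift)
    out = spatial_normalize(analyte, lock, smooth_window=1)
    assert np.allclose(out.intensity, out.intensity[0])


def test_normalize_idempotent():
    n = 60
    d = np.arange(n) * 50.0
    rng = np.random.default_rng(0)
    lock = XICTrace(500.0, 10.0, d, rng.uniform(50, 150, n))
    analyte = XICTrace(200.0, 10.0, d, rng.uniform(0, 10, n))
    once_lock = spatial_normalize(lock, lock, smooth_window=1)
    once = spatial_normalize(analyte, lock, smooth_window=1)
    twice = spatial_normalize(once, once_lock, smooth_window=1)
    assert np.allclose(twice.intensity, once.intensity)


def test_normalize_rejects_zero_lock():
    n = 20
    d = np.arange(n) * 50.0
    lock_int = np.full(n, 2.0)
    lock_int[7:12] = 0.0  # wider than the median window
    lock = XICTrace(500.0, 10.0, d, lock_int)
    analyte = XICTrace(200.0, 10.0, d, np.ones(n))
    with pytest.raises(NormalizationError):
        spatial_normalize(analyte, lock)


def test_normalize_preserves_spot_ratios_under_constant_lock(clean_run, small_layout,
                                                             single_analyte):
    from fastpass.quant import integrate_spot

    xic = extract_xic(clean_run, single_analyte.mz)
    lock = XICTrace(500.0, 10.0, clean_run.distances,
                    np.full(clean_run.n_pixels, 7.0))
    out = spatial_normalize(xic, lock)
    s3 = small_layout.get("Spot 3")
    assert integrate_spot(out, s3) == pytest.approx(integrate_spot(xic, s3))
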