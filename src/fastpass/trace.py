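"""Distance-domain traces: XIC/TIC extraction, lock-mass correction, and
spatial normalization to the internal-standard channel.

In a line-scan acquisition the chromatographic retention-time axis is
replaced by physical distance along the raster, so an extracted ion
chromatogram (XIC) is the per-pixel intensity of one m/z window plotted
against distance. The lock-mass species (leucine enkephalin in the spray
solvent) provides both a per-pixel m/z recalibration anchor and a spatial
normalization channel that compensates ionization/spray drift along the
scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import median_filter

from .errors import CalibrationError, NormalizationError
from .io import LineScanRun, MassSpectrum

log = logging.getLogger(__name__)


@dataclass
class XICTrace:
    """Per-pixel intensity of one m/z window along the scan distance."""

    target_mz: float  # Th; 0.0 for the TIC
    tol_ppm: float
    distances: np.ndarray  # µm
    intensity: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.distances.shape != self.intensity.shape:
            raise ValueError("distances and intensity must have equal length")
        if self.tol_ppm <= 0:
            raise ValueError("tol_ppm must be positive")
        if np.any(self.intensity < 0):
            raise ValueError("negative trace intensities")

    def __len__(self) -> int:
        return self.distances.size

    def to_tsv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.distances, self.intensity]),
            delimiter="\t",
            header="distance_um\tintensity",
            comments="",
        )


def extract_xic(run: LineScanRun, target_mz: float, tol_ppm: float = 10.0) -> XICTrace:
    """Extract the per-pixel summed intensity within a ppm window of target_mz.

    A window that overlaps no recorded m/z in any pixel yields an all-zero
    trace with a logged warning (absence of signal is a valid observation,
    not an error).
    """
    if target_mz <= 0:
        raise ValueError("target_mz must be positive")
    half = target_mz * tol_ppm * 1e-6
    lo, hi = target_mz - half, target_mz + half
    out = np.zeros(run.n_pixels)
    hit = False
    for i, (_, spectrum) in enumerate(run.pixels):
        a = np.searchsorted(spectrum.mz, lo, side="left")
        b = np.searchsorted(spectrum.mz, hi, side="right")
        if b > a:
            hit = True
            out[i] = spectrum.intensity[a:b].sum()
    if not hit:
        log.warning(
            "XIC window %.4f +/- %.1f ppm overlaps no recorded m/z; "
            "returning all-zero trace",
            target_mz,
            tol_ppm,
        )
    return XICTrace(target_mz, tol_ppm, run.distances, out)


def total_ion_trace(run: LineScanRun) -> XICTrace:
    """Total ion current per pixel, projected along the scan distance."""
    tic = np.asarray([s.tic for s in run.spectra()])
    return XICTrace(0.0, 1.0, run.distances, tic)


def _lock_peak_mz(spectrum: MassSpectrum, reference_mz: float, search_ppm: float):
    half = reference_mz * search_ppm * 1e-6
    a = np.searchsorted(spectrum.mz, reference_mz - half, side="left")
    b = np.searchsorted(spectrum.mz, reference_mz + half, side="right")
    if b <= a:
        return None
    window_mz = spectrum.mz[a:b]
    window_int = spectrum.intensity[a:b]
    if np.all(window_int == 0):
        return None
    return float(window_mz[np.argmax(window_int)])


def lockmass_correct(
    run: LineScanRun,
    reference_mz: float,
    search_ppm: float = 50.0,
    min_coverage: float = 0.90,
) -> LineScanRun:
    """Per-pixel multiplicative m/z recalibration against a lock-mass peak.

    In each pixel the most intense peak within ``search_ppm`` of
    ``reference_mz`` is taken as the lock peak and all m/z values are scaled
    by reference_mz / observed_mz. Pixels without a detectable lock peak
    inherit the nearest pixel's factor. The lock peak must be found in at
    least ``min_coverage`` of pixels, otherwise the run is rejected with a
    per-pixel diagnostic.
    """
    observed = np.full(run.n_pixels, np.nan)
    for i, (_, spectrum) in enumerate(run.pixels):
        mz = _lock_peak_mz(spectrum, reference_mz, search_ppm)
        if mz is not None:
            observed[i] = mz
    found = ~np.isnan(observed)
    coverage = found.mean()
    if coverage < min_coverage:
        missing = np.flatnonzero(~found)
        raise CalibrationError(
            f"lock peak at m/z {reference_mz:.4f} found in {coverage:.0%} of "
            f"pixels (< {min_coverage:.0%}); first missing pixel indices: "
            f"{missing[:20].tolist()}"
        )
    factors = reference_mz / observed
    if not found.all():
        idx = np.arange(run.n_pixels)
        factors = np.interp(idx, idx[found], factors[found])
    pixels = [
        (d, MassSpectrum(s.mz * f, s.intensity.copy(), s.centroided))
        for (d, s), f in zip(run.pixels, factors)
    ]
    corrected = replace(run, pixels=pixels)
    residual = _residual_lock_error_ppm(corrected, reference_mz, search_ppm)
    log.info("lock-mass residual error: %.3g ppm", residual)
    return corrected


def _residual_lock_error_ppm(
    run: LineScanRun, reference_mz: float, search_ppm: float
) -> float:
    errs = []
    for _, spectrum in run.pixels:
        mz = _lock_peak_mz(spectrum, reference_mz, search_ppm)
        if mz is not None:
            errs.append(abs(mz - reference_mz) / reference_mz * 1e6)
    return float(np.mean(errs)) if errs else float("nan")


def _smooth_lock(intensity: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return intensity
    return median_filter(intensity, size=window, mode="nearest")


def spatial_normalize(
    target: XICTrace | LineScanRun,
    lock_xic: XICTrace,
    smooth_window: int = 5,
):
    """Divide per-pixel intensities by the relative lock-mass signal.

    The lock trace is smoothed with a short moving median (default 5 pixels)
    and scaled to its own mean, so the correction preserves overall scale:
    intensity / (lock / mean(lock)). Works on a single trace or on a whole
    run. Any zero lock intensity after smoothing is rejected with the
    offending pixel indices.
    """
    lock = _smooth_lock(lock_xic.intensity, smooth_window)
    zeros = np.flatnonzero(lock == 0)
    if zeros.size:
        raise NormalizationError(
            f"lock channel is zero after smoothing at pixel indices "
            f"{zeros[:20].tolist()}"
        )
    factor = lock / lock.mean()
    if isinstance(target, XICTrace):
        if len(target) != lock.size:
            raise NormalizationError("trace and lock channel lengths differ")
        return replace(target, intensity=target.intensity / factor, normalized=True)
    if target.n_pixels != lock.size:
        raise NormalizationError("run and lock channel lengths differ")
    pixels = [
        (d, MassSpectrum(s.mz.copy(), s.intensity / f, s.centroided))
        for (d, s), f in zip(target.pixels, factor)
    ]
    return replace(target, pixels=pixels)
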