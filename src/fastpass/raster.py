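"""Raster-rate optimization and acquisition-time arithmetic.

The raster rate (stage speed under the stationary DESI probe, µm/s) does not
change the pixel count — that is fixed by scan length and pixel size — but it
sets the dwell time per pixel and therefore the collected signal. Faster
scans lose analyte signal roughly as 1/rate, while the delocalized
background falls until a knee rate and then flattens, so the spot-to-blank
signal ratio peaks at an interior rate. This module sweeps a simulated
acquisition over a grid of rates, averages the signal ratio across sample
spot replicates, and selects the rate that maximizes it (ties broken toward
the faster rate, since throughput is the objective).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import panels as _panels
from .errors import FastPassError, QuantError
from .io import SpotLayout, default_layout
from .quant import reference_region, signal_ratio
from .sim import AnalytePanelEntry, NoiseModel, RateResponseModel, simulate_run
from .trace import XICTrace, extract_xic

DEFAULT_RATES = tuple(range(50, 226, 25))  # µm/s, eight rates


def acquisition_time(scan_length_mm: float, rate: float) -> float:
    """Seconds to scan ``scan_length_mm`` millimetres at ``rate`` µm/s."""
    if scan_length_mm <= 0 or rate <= 0:
        raise ValueError("scan_length and rate must be positive")
    return scan_length_mm * 1000.0 / rate


def per_sample_time(total_time: float, n_samples: int) -> float:
    """Throughput: seconds of acquisition per sample in the array."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if total_time < 0:
        raise ValueError("total_time must be >= 0")
    return total_time / n_samples


def pixel_dwell_time(pixel_size: float, rate: float) -> float:
    """Spectral scan time per pixel: pixel_size / rate, in seconds."""
    if pixel_size <= 0 or rate <= 0:
        raise ValueError("pixel_size and rate must be positive")
    return pixel_size / rate


def rate_to_mm_per_min(rate_um_s: float) -> float:
    """Convert a raster rate from µm/s to mm/min."""
    return rate_um_s * 60.0 / 1000.0


@dataclass
class SignalRatioCurve:
    """Mean +/- sd of the spot-to-blank signal ratio versus raster rate."""

    rates: np.ndarray  # µm/s, strictly increasing
    mean_ratio: np.ndarray
    sd_ratio: np.ndarray
    n_replicates: int

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=np.float64)
        self.mean_ratio = np.asarray(self.mean_ratio, dtype=np.float64)
        self.sd_ratio = np.asarray(self.sd_ratio, dtype=np.float64)
        if not (self.rates.shape == self.mean_ratio.shape == self.sd_ratio.shape):
            raise ValueError("curve arrays must have equal length")
        if np.any(np.diff(self.rates) <= 0):
            raise ValueError("rates must be strictly increasing")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def to_tsv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.rates, self.mean_ratio, self.sd_ratio]),
            delimiter="\t",
            header="rate_um_s\tmean_ratio\tsd_ratio",
            comments="",
        )


def optimal_rate(curve: SignalRatioCurve) -> float:
    """Rate at the maximal mean signal ratio; ties go to the faster rate."""
    if curve.rates.size == 0:
        raise ValueError("empty curve")
    best = 0
    for i in range(1, curve.rates.size):
        if curve.mean_ratio[i] >= curve.mean_ratio[best]:
            best = i
    return float(curve.rates[best])


@dataclass
class SweepConfig:
    """Simulated acquisition used for the rate sweep.

    The default geometry mirrors the optimization experiment: an 11-spot,
    3 mm spot, 50 mm edge-to-edge array on a 55 mm scan at 50 µm pixels,
    with sample spots (a fatty-acid standard mix) interleaved with
    solvent-blank spots, six sample replicates per run.
    """

    layout: SpotLayout | None = None
    panel: list[AnalytePanelEntry] | None = None
    rate_model: RateResponseModel | None = None
    noise: NoiseModel | None = None
    pixel_size: float = 50.0
    base_intensity: float = 1000.0
    reference_mode: str = "solvent_blank"
    n_spot_replicates: int = 6

    def resolve(self) -> "SweepConfig":
        cfg = SweepConfig(**self.__dict__)
        if cfg.layout is None:
            cfg.layout = sweep_layout(cfg.n_spot_replicates)
        if cfg.panel is None:
            sample_labels = [s.label for s in cfg.layout.by_role("sample")]
            cfg.panel = ffa_sweep_panel(sample_labels, cfg.base_intensity)
        if cfg.rate_model is None:
            cfg.rate_model = RateResponseModel()
        if cfg.noise is None:
            cfg.noise = NoiseModel()
        return cfg


def sweep_layout(n_sample: int = 6, n_spots: int = 11) -> SpotLayout:
    """11-spot array with sample and solvent-blank spots interleaved."""
    if n_sample >= n_spots:
        raise ValueError("need at least one blank spot")
    roles = []
    for i in range(n_spots):
        roles.append("sample" if (i % 2 == 0 and roles.count("sample") < n_sample)
                     else "solvent_blank")
    return default_layout(
        n_spots, spot_width=3000.0, span=50_000.0, margin=2500.0, roles=roles
    )


def ffa_sweep_panel(
    sample_labels: list[str], base_intensity: float = 1000.0
) -> list[AnalytePanelEntry]:
    """Equimolar fatty-acid standard mix deposited on every sample spot."""
    names = ["C8:0", "C10:0", "C12:0", "C14:0"]
    return [
        AnalytePanelEntry(
            name=n,
            formula=_panels.FFA_FORMULAS[n],
            adduct="[M-H]-",
            base_intensity=base_intensity,
            spatial_profile="uniform",
            spot_labels=list(sample_labels),
        )
        for n in names
    ]


def _combined_analyte_trace(run, panel, tol_ppm: float = 10.0) -> XICTrace:
    total = None
    for entry in panel:
        xic = extract_xic(run, entry.mz, tol_ppm)
        total = xic.intensity if total is None else total + xic.intensity
    return XICTrace(0.0, tol_ppm, run.distances, total)


def rate_sweep(
    config: SweepConfig | None = None,
    rates=DEFAULT_RATES,
    n_spot_replicates: int | None = None,
    seed: int = 0,
) -> SignalRatioCurve:
    """Simulate one run per rate and measure the spot-to-blank signal ratio.

    For each rate a run is simulated (noise seeded from ``seed`` and the
    rate index), the combined analyte XIC is extracted, and the signal ratio
    is computed for each sample-spot replicate against the configured
    reference region; the curve records mean and sd across replicates.
    """
    rates = np.asarray(sorted(rates), dtype=np.float64)
    if rates.size < 2:
        raise ValueError("need at least 2 rates")
    config = (config or SweepConfig())
    if n_spot_replicates is not None:
        config.n_spot_replicates = n_spot_replicates
    cfg = config.resolve()
    sample_spots = cfg.layout.by_role("sample")

    means, sds = [], []
    for k, rate in enumerate(rates):
        try:
            noise = NoiseModel(
                cfg.noise.baseline_level,
                cfg.noise.baseline_dispersion,
                seed=(cfg.noise.seed + seed * 1000 + k) % (2**31),
            )
            run = simulate_run(
                cfg.layout,
                cfg.panel,
                rate=float(rate),
                pixel_size=cfg.pixel_size,
                rate_model=cfg.rate_model,
                noise=noise,
            )
            trace = _combined_analyte_trace(run, cfg.panel)
            reference = reference_region(cfg.layout, trace, cfg.reference_mode)
            ratios = [signal_ratio(trace, s, reference) for s in sample_spots]
        except (FastPassError, ValueError) as exc:
            raise FastPassError(f"sweep failed at rate {rate:g} µm/s: {exc}") from exc
        ratios = np.asarray(ratios)
        means.append(ratios.mean())
        sds.append(ratios.std(ddof=1) if ratios.size > 1 else 0.0)
    return SignalRatioCurve(
        rates=rates,
        mean_ratio=np.asarray(means),
        sd_ratio=np.asarray(sds),
        n_replicates=len(sample_spots),
    )


def closed_form_ratio(
    rate: float,
    rate_model: RateResponseModel,
    noise: NoiseModel,
    panel: list[AnalytePanelEntry],
    mean_profile_weight: float = 0.5,
) -> float:
    """Expected signal ratio at a rate, evaluated analytically.

    The sweep measures the summed monoisotopic XICs of the panel analytes.
    With signal factor s(r), delocalization factor d(r), summed monoisotopic
    base intensity T, per-channel noise mean b and C monitored channels, the
    per-pixel means are s*wbar*T + C*b inside a sample spot and
    s*d*level*T + C*b in the background, so

        ratio(r) = (s(r)*wbar*T + C*b) / (s(r)*d(r)*level*T + C*b).

    This is the independent check that the interior optimum produced by the
    stochastic sweep follows from the rate model itself. Any spatial profile
    has mean in-spot density wbar ~= 0.5 because profiles integrate to 1
    over the normalized coordinate [-1, 1].
    """
    from .sim import rate_scaling

    s, d = rate_scaling(rate_model, rate)
    total = sum(entry.base_intensity for entry in panel)
    channels = len(panel)
    floor = channels * noise.baseline_level
    numerator = s * mean_profile_weight * total + floor
    denominator = s * d * rate_model.delocalization_level * total + floor
    if denominator <= 0:
        raise QuantError("zero expected background; ratio undefined")
    return numerator / denominator
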