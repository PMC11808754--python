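"""Line-scan MSI data containers and standard-format I/O.

A line-scan acquisition is an ordered sequence of pixels along a single
raster line; each pixel carries a centroided mass spectrum and a physical
distance coordinate. Distances are 0-based physical positions in µm measured
at the pixel start; spot intervals are closed on the left and open on the
right so that integration partitions never overlap.

On-disk formats: imzML (processed mode; the canonical format), mzML (scan
index standing in for the x-index), plus a plain-TSV trace table and a
YAML/JSON layout schema.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import FormatError, LayoutError

log = logging.getLogger(__name__)

ROLES = ("sample", "solvent_blank", "media_blank")


@dataclass
class MassSpectrum:
    """One centroided spectrum: parallel m/z (Th) and intensity arrays."""

    mz: np.ndarray
    intensity: np.ndarray
    centroided: bool = True

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise FormatError("mz and intensity must be equal-length 1-D arrays")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
            log.warning("unsorted m/z array repaired by sorting")
        if np.any(self.intensity < 0):
            raise FormatError("negative intensities")

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())


@dataclass
class LineScanRun:
    """Ordered pixels along one raster line.

    pixels: list of (distance_um, MassSpectrum), strictly increasing distance
    with uniform spacing equal to ``pixel_size`` (within 1%).
    """

    pixels: list[tuple[float, MassSpectrum]]
    raster_rate: float  # µm/s
    pixel_size: float  # µm along the scan axis
    polarity: str = "negative"
    scan_length: float | None = None  # µm

    def __post_init__(self) -> None:
        if not self.pixels:
            raise FormatError("empty pixel list")
        if self.raster_rate <= 0 or self.pixel_size <= 0:
            raise FormatError("raster_rate and pixel_size must be positive")
        d = self.distances
        if d.size > 1:
            steps = np.diff(d)
            if np.any(steps <= 0):
                raise FormatError("pixel distances must be strictly increasing")
            if np.any(np.abs(steps - self.pixel_size) > 0.01 * self.pixel_size):
                raise FormatError("pixel spacing deviates >1% from pixel_size")
        if self.scan_length is None:
            self.scan_length = float(d[-1] + self.pixel_size)
        elif self.scan_length < d[-1]:
            raise FormatError("scan_length shorter than last pixel distance")

    @property
    def distances(self) -> np.ndarray:
        return np.asarray([d for d, _ in self.pixels], dtype=np.float64)

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)

    def spectra(self):
        return (s for _, s in self.pixels)


@dataclass
class Spot:
    label: str
    center: float  # µm
    width: float  # µm
    role: str = "sample"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise LayoutError(f"spot {self.label!r}: non-positive width")
        if self.role not in ROLES:
            raise LayoutError(f"spot {self.label!r}: unknown role {self.role!r}")

    @property
    def start(self) -> float:
        return self.center - self.width / 2

    @property
    def stop(self) -> float:
        return self.center + self.width / 2

    def contains(self, distance) -> np.ndarray:
        """Membership of distances in [start, stop)."""
        d = np.asarray(distance, dtype=np.float64)
        return (d >= self.start) & (d < self.stop)


@dataclass
class SpotLayout:
    """Declared linear array of labeled, role-tagged spot intervals."""

    spots: list[Spot]
    scan_length: float  # µm

    def __post_init__(self) -> None:
        labels = [s.label for s in self.spots]
        if len(set(labels)) != len(labels):
            raise LayoutError("duplicate spot labels")
        ordered = sorted(self.spots, key=lambda s: s.center)
        eps = 1e-6  # µm; guards float round-off in computed geometries
        for a, b in zip(ordered, ordered[1:]):
            if a.stop > b.start + eps:
                raise LayoutError(f"spots {a.label!r} and {b.label!r} overlap")
        for s in self.spots:
            if s.start < -eps or s.stop > self.scan_length + eps:
                raise LayoutError(f"spot {s.label!r} outside [0, scan_length]")

    def __iter__(self):
        return iter(self.spots)

    def __len__(self) -> int:
        return len(self.spots)

    def get(self, label: str) -> Spot:
        for s in self.spots:
            if s.label == label:
                return s
        raise LayoutError(f"no spot labeled {label!r}")

    def by_role(self, role: str) -> list[Spot]:
        return [s for s in self.spots if s.role == role]

    def gap_mask(self, distances) -> np.ndarray:
        """True where a distance falls in no spot interval."""
        d = np.asarray(distances, dtype=np.float64)
        inside = np.zeros(d.shape, dtype=bool)
        for s in self.spots:
            inside |= s.contains(d)
        return ~inside


def default_layout(
    n_spots: int,
    spot_width: float,
    span: float,
    scan_length: float | None = None,
    margin: float = 0.0,
    roles: list[str] | None = None,
    labels: list[str] | None = None,
) -> SpotLayout:
    """Equally spaced linear array whose outer spot edges touch 0 and ``span``.

    The first spot's left edge sits at ``margin`` and the last spot's right
    edge at ``margin + span``; gaps between adjacent spot edges are equal.
    ``scan_length`` defaults to span + 2*margin.
    """
    if n_spots < 2:
        raise LayoutError("need at least 2 spots")
    if n_spots * spot_width > span:
        raise LayoutError(
            f"{n_spots} spots of width {spot_width} do not fit in span {span}"
        )
    if roles is not None and len(roles) != n_spots:
        raise LayoutError("roles length must equal n_spots")
    if labels is not None and len(labels) != n_spots:
        raise LayoutError("labels length must equal n_spots")
    pitch = (span - spot_width) / (n_spots - 1)
    spots = []
    for i in range(n_spots):
        center = margin + spot_width / 2 + i * pitch
        spots.append(
            Spot(
                label=labels[i] if labels else f"Spot {i + 1}",
                center=center,
                width=spot_width,
                role=roles[i] if roles else "sample",
            )
        )
    total = span + 2 * margin if scan_length is None else scan_length
    return SpotLayout(spots=spots, scan_length=total)


# ---------------------------------------------------------------------------
# layout YAML/JSON


def read_layout(path: str | Path) -> SpotLayout:
    """Layout schema: {scan_length_um, spots: [{label, center_um, width_um, role}]}."""
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
    try:
        spots = [
            Spot(s["label"], float(s["center_um"]), float(s["width_um"]),
                 s.get("role", "sample"))
            for s in doc["spots"]
        ]
        return SpotLayout(spots=spots, scan_length=float(doc["scan_length_um"]))
    except (KeyError, TypeError) as exc:
        raise FormatError(f"invalid layout file {path}: {exc}") from exc


def write_layout(layout: SpotLayout, path: str | Path) -> None:
    path = Path(path)
    doc = {
        "scan_length_um": layout.scan_length,
        "spots": [
            {"label": s.label, "center_um": s.center, "width_um": s.width,
             "role": s.role}
            for s in layout.spots
        ],
    }
    with open(path, "w") as fh:
        if path.suffix.lower() == ".json":
            json.dump(doc, fh, indent=2)
        else:
            yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# imzML / mzML


def write_imzml(run: LineScanRun, path: str | Path) -> Path:
    """Write a run as processed-mode imzML, x = 1-based pixel index, y = 1."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    path = Path(path)
    polarity = "negative" if run.polarity == "negative" else "positive"
    with ImzMLWriter(str(path), polarity=polarity, mode="processed") as writer:
        for i, (_, spectrum) in enumerate(run.pixels):
            writer.addSpectrum(spectrum.mz, spectrum.intensity, (i + 1, 1, 1))
    return path


def read_imzml(
    path: str | Path,
    raster_rate: float,
    pixel_size: float,
    polarity: str | None = None,
) -> LineScanRun:
    """Read processed-mode imzML into a LineScanRun.

    Pixels are ordered by their x-coordinate; distance = (x - 1) * pixel_size.
    Multi-row images (any y > 1 alongside y = 1) are rejected: the Fast-Pass
    workflow operates on a single raster line.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    parser = ImzMLParser(str(path))
    coords = parser.coordinates
    if not coords:
        raise FormatError(f"{path}: no spectra")
    ys = {c[1] for c in coords}
    if len(ys) > 1:
        raise FormatError(
            f"{path}: {len(ys)} raster rows found; Fast-Pass operates on a "
            "single line — extract one row or acquire a single raster"
        )
    if polarity is None:
        pol = getattr(parser, "polarity", None)
        polarity = pol if pol in ("positive", "negative") else "negative"
    order = sorted(range(len(coords)), key=lambda i: coords[i][0])
    pixels = []
    for i in order:
        mz, inten = parser.getspectrum(i)
        x = coords[i][0]
        pixels.append(
            ((x - 1) * pixel_size, MassSpectrum(np.asarray(mz), np.asarray(inten)))
        )
    return LineScanRun(
        pixels=pixels,
        raster_rate=raster_rate,
        pixel_size=pixel_size,
        polarity=polarity,
    )


def read_mzml(
    path: str | Path,
    raster_rate: float,
    pixel_size: float,
    polarity: str = "negative",
) -> LineScanRun:
    """Read mzML; the 0-based scan index stands in for the x-index."""
    from pyteomics import mzml as _mzml

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    pixels = []
    with _mzml.MzML(str(path)) as reader:
        for i, scan in enumerate(reader):
            spectrum = MassSpectrum(
                np.asarray(scan["m/z array"], dtype=np.float64),
                np.asarray(scan["intensity array"], dtype=np.float64),
            )
            pixels.append((i * pixel_size, spectrum))
    if not pixels:
        raise FormatError(f"{path}: no spectra")
    return LineScanRun(
        pixels=pixels,
        raster_rate=raster_rate,
        pixel_size=pixel_size,
        polarity=polarity,
    )


def expected_pixel_count(scan_length: float, pixel_size: float) -> int:
    """Number of pixels a scan of ``scan_length`` µm produces: ceil(L / px)."""
    if scan_length <= 0 or pixel_size <= 0:
        raise ValueError("scan_length and pixel_size must be positive")
    return math.ceil(scan_length / pixel_size)
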