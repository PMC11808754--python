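"""Spot-level quantification.

Integrates distance-domain traces over declared spot intervals, computes the
spot-to-blank signal ratio used for raster-rate optimization, applies
media-blank subtraction and analyte-by-analyte normalization to feature
tables, and quantifies replicate reproducibility as percent coefficient of
variation (%CV).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import QuantError
from .io import Spot, SpotLayout
from .trace import XICTrace

log = logging.getLogger(__name__)

STAGES = ("raw", "blank_subtracted", "normalized")


@dataclass
class FeatureTable:
    """Spots x features matrix of integrated intensities with provenance.

    ``stage`` records the processing state: raw integrals, media-blank
    subtracted, or analyte-by-analyte normalized (each feature column scaled
    to its own maximum).
    """

    spot_labels: list[str]
    feature_mzs: list[float]
    values: np.ndarray  # shape (n_spots, n_features)
    stage: str = "raw"
    blank_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.spot_labels), len(self.feature_mzs)):
            raise QuantError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.spot_labels)} spots x {len(self.feature_mzs)} features"
            )
        if self.stage not in STAGES:
            raise QuantError(f"unknown stage {self.stage!r}")

    @property
    def n_spots(self) -> int:
        return len(self.spot_labels)

    @property
    def n_features(self) -> int:
        return len(self.feature_mzs)

    def row(self, label: str) -> np.ndarray:
        try:
            return self.values[self.spot_labels.index(label)]
        except ValueError:
            raise QuantError(f"no spot labeled {label!r}") from None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.spot_labels, columns=self.feature_mzs
        )

    def to_tsv(self, path) -> None:
        df = self.to_dataframe()
        with open(path, "w") as fh:
            fh.write(f"# stage: {self.stage}\n")
            df.to_csv(fh, sep="\t", index_label="spot")

    @classmethod
    def from_tsv(cls, path) -> "FeatureTable":
        with open(path) as fh:
            first = fh.readline()
            stage = "raw"
            if first.startswith("# stage:"):
                stage = first.split(":", 1)[1].strip()
            else:
                fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col="spot")
        return cls(
            spot_labels=list(df.index),
            feature_mzs=[float(c) for c in df.columns],
            values=df.to_numpy(),
            stage=stage,
        )


def _pixels_in(trace: XICTrace, spot: Spot) -> np.ndarray:
    return spot.contains(trace.distances)


def integrate_spot(trace: XICTrace, spot: Spot) -> float:
    """Sum of pixel intensities whose distance lies in [start, stop)."""
    mask = _pixels_in(trace, spot)
    if not mask.any():
        raise QuantError(f"spot {spot.label!r} covers no pixels in the trace")
    return float(trace.intensity[mask].sum())


def signal_ratio(
    trace: XICTrace,
    sample_spot: Spot,
    reference: Spot | list[Spot] | np.ndarray,
    epsilon_frac: float = 1e-9,
) -> float:
    """Per-pixel mean intensity in the sample spot over that in the reference.

    ``reference`` is either a blank spot (or list of blank spots) or a
    boolean pixel mask (e.g. the inter-spot gap mask from
    ``SpotLayout.gap_mask``). Per-pixel means make regions of different
    length comparable; a small floor (``epsilon_frac`` of the trace maximum)
    guards a zero denominator.
    """
    sample_mask = _pixels_in(trace, sample_spot)
    if not sample_mask.any():
        raise QuantError(f"sample spot {sample_spot.label!r} covers no pixels")
    if isinstance(reference, Spot):
        ref_mask = _pixels_in(trace, reference)
    elif isinstance(reference, (list, tuple)):
        ref_mask = np.zeros(len(trace), dtype=bool)
        for spot in reference:
            ref_mask |= _pixels_in(trace, spot)
    else:
        ref_mask = np.asarray(reference, dtype=bool)
        if ref_mask.shape != trace.distances.shape:
            raise QuantError("reference mask length does not match trace")
    if not ref_mask.any():
        raise QuantError("reference region covers no pixels")
    eps = epsilon_frac * float(trace.intensity.max()) if trace.intensity.size else 0.0
    denom = float(trace.intensity[ref_mask].mean()) + eps
    if denom <= 0:
        raise QuantError("reference region has zero mean intensity")
    return float(trace.intensity[sample_mask].mean()) / denom


def reference_region(
    layout: SpotLayout, trace: XICTrace, mode: str = "solvent_blank"
):
    """Denominator region for the signal ratio.

    ``solvent_blank``: the solvent-blank spot intervals (the operational
    definition from the blank-spot comparison); ``gaps``: the inter-spot
    regions. Both readings of the background are supported because the
    delocalized background is described in both terms.
    """
    if mode == "solvent_blank":
        blanks = layout.by_role("solvent_blank")
        if not blanks:
            raise QuantError("layout declares no solvent_blank spots")
        return blanks
    if mode == "gaps":
        return layout.gap_mask(trace.distances)
    raise QuantError(f"unknown reference mode {mode!r}")


def blank_subtract(table: FeatureTable, media_blank_label: str) -> FeatureTable:
    """Subtract the media-blank row from every feature column, flooring at 0.

    The blank row is retained and flagged in ``blank_labels`` so downstream
    steps can exclude it from group statistics.
    """
    if media_blank_label not in table.spot_labels:
        raise QuantError(f"no spot labeled {media_blank_label!r} in table")
    blank = table.row(media_blank_label)
    values = np.clip(table.values - blank[None, :], 0.0, None)
    return replace(
        table,
        values=values,
        stage="blank_subtracted",
        blank_labels=sorted(set(table.blank_labels) | {media_blank_label}),
    )


def analyte_normalize(table: FeatureTable) -> FeatureTable:
    """Scale each feature column to its own maximum (analyte-by-analyte).

    All-zero columns are left at zero with a logged warning.
    """
    maxima = table.values.max(axis=0)
    zero_cols = np.flatnonzero(maxima == 0)
    if zero_cols.size:
        log.warning(
            "%d all-zero feature columns left unnormalized (m/z %s ...)",
            zero_cols.size,
            [round(table.feature_mzs[i], 4) for i in zero_cols[:5]],
        )
    safe = np.where(maxima > 0, maxima, 1.0)
    return replace(table, values=table.values / safe[None, :], stage="normalized")


def percent_cv(values) -> float:
    """100 x sample (n-1) standard deviation / mean of replicate intensities."""
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise QuantError("percent_cv needs at least 2 replicates")
    mean = v.mean()
    if mean <= 0:
        raise QuantError("percent_cv undefined for non-positive mean")
    return float(100.0 * v.std(ddof=1) / mean)


@dataclass
class ReproducibilityReport:
    per_group_cv: dict[str, float]
    overall_mean_cv: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "per_group_cv_percent": self.per_group_cv,
                    "overall_mean_cv_percent": self.overall_mean_cv,
                },
                fh,
                indent=2,
            )


def replicate_cv_report(
    table: FeatureTable, group_map: dict[str, str]
) -> ReproducibilityReport:
    """Mean %CV across features within each replicate group.

    For each group of spot labels and each feature with positive group mean,
    the %CV over replicates is computed; a group's value is the mean over
    those features, and the overall figure is the mean over groups.
    """
    per_group: dict[str, float] = {}
    for group in sorted(set(group_map.values())):
        labels = [lb for lb, g in group_map.items() if g == group]
        if len(labels) < 2:
            continue
        rows = np.stack([table.row(lb) for lb in labels])
        cvs = []
        for j in range(rows.shape[1]):
            col = rows[:, j]
            if col.mean() > 0:
                cvs.append(100.0 * col.std(ddof=1) / col.mean())
        if cvs:
            per_group[group] = float(np.mean(cvs))
    if not per_group:
        raise QuantError("no group with >= 2 replicates and positive signal")
    overall = float(np.mean(list(per_group.values())))
    return ReproducibilityReport(per_group_cv=per_group, overall_mean_cv=overall)


def aggregate_titer(
    table: FeatureTable,
    feature_subset: list[float],
    group_map: dict[str, str],
) -> pd.DataFrame:
    """Per-group mean +/- sd of the summed subset features (relative titers).

    ``feature_subset`` lists feature m/z values to sum per spot (e.g. the
    product fatty-acid channels); ``group_map`` maps spot labels to group
    names (strains). Returns a DataFrame indexed by group with columns
    mean, sd, n.
    """
    if not feature_subset:
        raise QuantError("empty feature subset")
    idx = []
    for mz in feature_subset:
        matches = [j for j, f in enumerate(table.feature_mzs) if np.isclose(f, mz)]
        if not matches:
            raise QuantError(f"feature m/z {mz} not in table")
        idx.append(matches[0])
    sums = table.values[:, idx].sum(axis=1)
    rows = {}
    for group in sorted(set(group_map.values())):
        labels = [lb for lb, g in group_map.items() if g == group]
        if not labels:
            raise QuantError(f"group {group!r} has no replicates")
        vals = np.asarray([sums[table.spot_labels.index(lb)] for lb in labels])
        rows[group] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            "n": int(vals.size),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
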